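"""Exciton band analysis: eigenstates, PR, coupling histogram, dark states."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chlorosim as cs
from chlorosim.analysis import (
    band_report,
    coupling_histogram,
    dark_state_report,
    diagonalize_frame,
    dipole_axis_angles,
    nn_peak_center,
    nnn_peak_centers,
    participation_ratio,
)
from chlorosim.constants import DIPOLE_DEBYE, OMEGA0_CM
from chlorosim.hamiltonian import HamiltonianFrame
from conftest import make_site_geometry


class TestDiagonalize:
    def test_diagonal_frame(self):
        g = make_site_geometry(
            [[0, 0, 0], [20, 0, 0], [40, 0, 0]], [[0, 0, 1]] * 3
        )
        f = HamiltonianFrame(np.diag([15100.0, 15390.0, 15800.0]))
        st_ = diagonalize_frame(f, g)
        np.testing.assert_allclose(st_.energies, [15100.0, 15390.0, 15800.0])
        np.testing.assert_allclose(st_.participation_ratios, 1.0)

    def test_homodimer_symmetric_split(self, parallel_dimer):
        g = parallel_dimer
        J = cs.coupling_matrix(g)[0, 1]
        f = cs.build_frame(g, np.zeros(2))
        st_ = diagonalize_frame(f, g)
        np.testing.assert_allclose(st_.energies, [OMEGA0_CM + J, OMEGA0_CM - J], atol=1e-8)
        # bright symmetric state carries f = 2 mu^2, dark antisymmetric zero
        assert st_.oscillator_strengths[0] == pytest.approx(2 * DIPOLE_DEBYE**2, rel=1e-10)
        assert st_.oscillator_strengths[1] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(st_.participation_ratios, [2.0, 2.0])

    def test_uniform_ring_closed_form(self):
        g = cs.fixture_geometry("ring6")
        # NN-only uniform-J ring (closed form); built directly, not from geometry
        J = -250.0
        h = np.diag([OMEGA0_CM] * 6).astype(float)
        for i in range(6):
            h[i, (i + 1) % 6] = h[(i + 1) % 6, i] = J
        st_ = diagonalize_frame(HamiltonianFrame(h), g)
        analytic = np.sort(OMEGA0_CM + 2 * J * np.cos(2 * np.pi * np.arange(6) / 6))
        np.testing.assert_allclose(st_.energies, analytic, atol=1e-8)

    def test_orthonormal_and_sum_rule(self, wildtype_500):
        g, traj = wildtype_500
        st_ = diagonalize_frame(traj.frame(0), g)
        c = st_.coefficients
        assert np.abs(c.T @ c - np.eye(g.n_sites)).max() < 1e-8
        assert st_.oscillator_strengths.sum() == pytest.approx(
            g.n_sites * DIPOLE_DEBYE**2, rel=1e-6
        )


class TestParticipationRatio:
    def test_localized_is_one(self):
        v = np.zeros(8)
        v[3] = 1.0
        assert participation_ratio(v) == pytest.approx(1.0)

    def test_uniform_is_n(self):
        v = np.full(16, 0.25)
        assert participation_ratio(v) == pytest.approx(16.0)

    def test_half_half_is_two(self):
        v = np.array([np.sqrt(0.5), np.sqrt(0.5), 0.0])
        assert participation_ratio(v) == pytest.approx(2.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            participation_ratio(np.zeros(4))

    @given(st.integers(2, 30), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_bounds(self, n, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=n)
        v /= np.linalg.norm(v)
        pr = participation_ratio(v)
        assert 1.0 - 1e-9 <= pr <= n + 1e-9


class TestCouplingHistogram:
    def test_wildtype_nn_peak(self, wildtype_1000):
        edges, counts, peaks = coupling_histogram(wildtype_1000)
        nn = nn_peak_center(peaks)
        assert nn < 0
        assert abs(abs(nn) - 450.0) / 450.0 < 0.10
        # histogram counts all pairs
        n = wildtype_1000.n_sites
        assert counts.sum() == n * (n - 1) // 2

    def test_wildtype_interstack_peaks(self, wildtype_1000):
        _, _, peaks = coupling_histogram(wildtype_1000)
        pos, neg = nnn_peak_centers(peaks)
        assert abs(pos - 200.0) / 200.0 < 0.15
        assert abs(neg + 200.0) / 200.0 < 0.15

    def test_two_distant_sites_single_zero_bin(self):
        g = make_site_geometry([[0, 0, 0], [1000.0, 0, 0]], [[0, 0, 1]] * 2)
        edges, counts, peaks = coupling_histogram(g)
        assert counts.sum() == 1
        b = np.argmax(counts)
        assert edges[b] <= 0.001 and edges[b + 1] >= -0.001
        assert peaks == []

    def test_single_site_rejected(self):
        g = cs.fixture_geometry("monomer")
        with pytest.raises(ValueError):
            coupling_histogram(g)


class TestDipoleAxisAngles:
    def test_parallel_dipoles_zero(self):
        g = make_site_geometry([[0, 0, 0], [10, 0, 0]], [[0, 0, 1], [0, 0, -1]])
        angles, mean, _ = dipole_axis_angles(g)
        assert mean == pytest.approx(0.0, abs=1e-10)  # axis sign folded

    def test_perpendicular_dipoles_ninety(self):
        g = make_site_geometry([[0, 0, 0], [10, 0, 0]], [[1, 0, 0], [0, 1, 0]])
        _, mean, _ = dipole_axis_angles(g)
        assert mean == pytest.approx(90.0, abs=1e-10)

    def test_wildtype_mean_54(self, wildtype_1000):
        _, mean, (edges, counts) = dipole_axis_angles(wildtype_1000)
        assert abs(mean - 54.0) <= 2.0
        assert counts.sum() == wildtype_1000.n_sites


class TestDarkStateReport:
    def test_homodimer_dark_state_capped_ratio(self, parallel_dimer):
        g = parallel_dimer
        st_ = diagonalize_frame(cs.build_frame(g, np.zeros(2)), g)
        rep = dark_state_report(st_, n_low=2)
        assert rep["f_ratio_to_max"].iloc[1] == pytest.approx(1e6)  # capped
        assert rep["participation_ratio"].iloc[1] == pytest.approx(2.0)
        assert bool(rep["dark_multichromophoric"].iloc[1])

    def test_uncoupled_disordered_frame_unflagged(self):
        rng = np.random.default_rng(0)
        n = 12
        g = make_site_geometry(
            np.column_stack([np.arange(n) * 1000.0, np.zeros(n), np.zeros(n)]),
            [[0, 0, 1]] * n,
        )
        f = HamiltonianFrame(np.diag(15390.0 + rng.normal(scale=300.0, size=n)))
        rep = dark_state_report(diagonalize_frame(f, g), n_low=10)
        np.testing.assert_allclose(rep["participation_ratio"], 1.0, atol=1e-6)
        assert not rep["dark_multichromophoric"].any()

    def test_requires_enough_states(self, parallel_dimer):
        st_ = diagonalize_frame(cs.build_frame(parallel_dimer, np.zeros(2)), parallel_dimer)
        with pytest.raises(ValueError):
            dark_state_report(st_, n_low=10)


class TestBandProperties:
    def test_band_mean_energy_is_trace(self, wildtype_500):
        g, traj = wildtype_500
        st_ = diagonalize_frame(traj.frame(5), g)
        offsets = traj.diagonals[5] - OMEGA0_CM
        assert st_.energies.mean() == pytest.approx(
            OMEGA0_CM + offsets.mean(), abs=1e-8
        )

    def test_localization_delocalization_crossover(self, wildtype_500):
        """Ensemble-mean PR peaks in the band interior, not at the edges."""
        g, traj = wildtype_500
        hits = 0
        frames = range(0, 240, 12)
        for k in frames:
            pr = diagonalize_frame(traj.frame(k), g).participation_ratios
            n = len(pr)
            edge = np.r_[pr[: n // 10], pr[-n // 10 :]].mean()
            mid = pr[4 * n // 10 : 6 * n // 10].mean()
            hits += mid > edge
        assert hits == len(list(frames))

    def test_brightest_state_low_but_not_lowest(self, wildtype_500):
        """argmax f has energy-rank > 0 and below the median in >= 90% of frames."""
        g, traj = wildtype_500
        ranks = []
        for k in range(0, 240, 12):
            st_ = diagonalize_frame(traj.frame(k), g)
            ranks.append(int(np.argmax(st_.oscillator_strengths)))
        ok = [0 < r < g.n_sites // 2 for r in ranks]
        assert np.mean(ok) >= 0.9

    def test_band_report_aggregates(self, minitube):
        g, traj = minitube
        rep = band_report(g, [traj.frame(k) for k in range(3)])
        assert rep.dos_counts.sum() == 3 * g.n_sites
        assert len(rep.states_table) == 3 * g.n_sites
        assert rep.n_frames == 3
        assert abs(rep.angle_mean_deg - 54.0) < 3.0
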