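"""Linear absorption and 2DES pathway responses."""

import numpy as np
import pytest

import chlorosim as cs
from chlorosim.constants import C_CM_PER_FS, OMEGA0_CM
from chlorosim.spectroscopy import (
    PHASES,
    SpectroscopyConfig,
    _RealizationEngine,
    assemble_absorptive,
    find_spectral_peaks,
    isotropic_parallel_average,
    linear_response,
    point_trace,
    third_order_pathway,
    twodes_spectrum,
)
from oracles import mc_parallel_average, sos_pathway_tensor


def static_trajectory(geometry, n_frames=220, offsets=None):
    n = geometry.n_sites
    diag = np.full((n_frames, n), OMEGA0_CM)
    if offsets is not None:
        diag = diag + np.asarray(offsets)[None, :]
    return cs.HamiltonianTrajectory(
        coupling=cs.coupling_matrix(geometry), diagonals=diag, dt=4.0
    )


class TestConfig:
    def test_defaults_match_protocol(self):
        c = SpectroscopyConfig()
        assert c.t1_max == 196.0 and c.t3_max == 196.0
        assert c.t2_list[0] == 0.0 and c.t2_list[-1] == 480.0
        assert np.all(np.diff(c.t2_list) == 24.0)
        n1, n3, s = c.grid_sizes(4.0)
        assert (n1, n3, s) == (50, 50, 1)

    @pytest.mark.parametrize(
        "kw",
        [
            {"t2_list": (48.0, 24.0)},
            {"t2_list": (-24.0,)},
            {"apod_tau": 0.0},
            {"pathway_mask": ("GSB", "XX")},
            {"coherence_step": -4.0},
            {"polarization": "magic"},
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            SpectroscopyConfig(**kw)

    def test_incommensurate_t2(self):
        c = SpectroscopyConfig()
        with pytest.raises(ValueError, match="multiple"):
            c.t2_frames(10.0, 4.0)


class TestLinearResponse:
    def test_monomer_peak_at_omega0(self):
        g, d = cs.make_fixture("monomer", n_frames=260)
        traj = cs.build_trajectory(g, d)
        om, ab = linear_response(traj, g, t_max=1000.0, apod_tau=300.0)
        assert om[np.argmax(ab)] == pytest.approx(OMEGA0_CM, abs=5.0)
        assert ab.max() > 0

    def test_parallel_homodimer_single_redshifted_peak(self, parallel_dimer):
        g = parallel_dimer
        traj = static_trajectory(g, n_frames=260)
        J = traj.coupling[0, 1]
        om, ab = linear_response(traj, g, t_max=1000.0, apod_tau=300.0)
        peaks = find_spectral_peaks(om, ab, min_rel_height=0.02)
        assert peaks[0] == pytest.approx(OMEGA0_CM + J, abs=6.0)
        # antisymmetric state at w0 - J carries no intensity
        i_dark = np.argmin(np.abs(om - (OMEGA0_CM - J)))
        assert abs(ab[i_dark]) < 0.01 * ab.max()

    def test_sum_rule(self, minitube):
        """Spectral integral equals sum_k f_k / (6 c dt) for any frame."""
        g, traj = minitube
        om, ab = linear_response(traj, g, t_max=500.0, apod_tau=300.0)
        integral = np.trapezoid(ab, om)
        sum_f = float((g.dipoles() ** 2).sum())  # = N mu^2
        expected = sum_f / (6.0 * traj.dt * C_CM_PER_FS)
        assert integral == pytest.approx(expected, rel=0.01)

    def test_spectrum_is_real_for_hermitian_response(self):
        g, d = cs.make_fixture("monomer", n_frames=260)
        traj = cs.build_trajectory(g, d)
        om, ab = linear_response(traj, g, t_max=800.0, apod_tau=300.0)
        assert np.isrealobj(ab)

    def test_too_short_trajectory(self):
        g, d = cs.make_fixture("monomer", n_frames=10)
        traj = cs.build_trajectory(g, d)
        with pytest.raises(ValueError, match="short"):
            linear_response(traj, g, t_max=1000.0, apod_tau=300.0)


class TestIsotropicAverage:
    def test_all_same_unit_vector_is_one_fifth(self):
        d = np.array([0.3, -0.4, np.sqrt(1 - 0.25)])
        t = np.einsum("a,b,c,d->abcd", d, d, d, d)
        assert isotropic_parallel_average(t) == pytest.approx(0.2, abs=1e-12)

    def test_orthogonal_pairs_one_fifteenth(self):
        d1 = np.array([1.0, 0.0, 0.0])
        d3 = np.array([0.0, 1.0, 0.0])
        t = np.einsum("a,b,c,d->abcd", d1, d1, d3, d3)
        assert isotropic_parallel_average(t) == pytest.approx(1.0 / 15.0, abs=1e-12)

    def test_monte_carlo_rotation_oracle(self):
        rng = np.random.default_rng(8)
        dips = rng.normal(size=(4, 3))
        dips /= np.linalg.norm(dips, axis=1, keepdims=True)

        def tensor():
            return np.einsum("a,b,c,d->abcd", *dips)

        mc = mc_parallel_average(tensor, n_samples=100_000, seed=5)
        exact = isotropic_parallel_average(tensor())
        assert mc == pytest.approx(exact, rel=0.01, abs=2e-3)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            isotropic_parallel_average(np.zeros((3, 3)))


class TestPathwayOracle:
    """Every pathway grid matches the sum-over-states construction."""

    @pytest.mark.parametrize("pathway", ["GSB", "SE", "ESA"])
    @pytest.mark.parametrize("phase", PHASES)
    def test_static_trimer_matches_sos(self, static_trimer, pathway, phase):
        g, traj = static_trimer
        cfg = SpectroscopyConfig(t1_max=40.0, t3_max=40.0, t2_list=(0.0, 24.0))
        eng = _RealizationEngine(traj, g, cfg, 0)
        n1, n3, _ = cfg.grid_sizes(traj.dt)
        for k2 in (0, 6):
            got = eng.pathway_tensor(pathway, phase, k2)
            want = sos_pathway_tensor(
                traj.frame(0).matrix, g.dipoles(), pathway, phase, n1, n3, k2, traj.dt
            )
            err = np.abs(got - want).max() / np.abs(want).max()
            assert err < 1e-6

    def test_esa_identically_zero_for_monomer(self):
        g, d = cs.make_fixture("monomer", n_frames=260)
        traj = cs.build_trajectory(g, d)
        cfg = SpectroscopyConfig(t1_max=40.0, t3_max=40.0, t2_list=(0.0,))
        grid = third_order_pathway(traj, g, "ESA", "rephasing", 0.0, cfg)
        assert np.all(grid.values == 0.0)

    def test_gsb_t2_invariant_for_static_hamiltonian(self, parallel_dimer):
        g = parallel_dimer
        traj = static_trajectory(g, n_frames=260)
        cfg = SpectroscopyConfig(t1_max=60.0, t3_max=60.0, t2_list=(0.0, 96.0))
        a = third_order_pathway(traj, g, "GSB", "rephasing", 0.0, cfg)
        b = third_order_pathway(traj, g, "GSB", "rephasing", 96.0, cfg)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12 * np.abs(a.values).max())

    def test_gsb_se_coincide_at_time_zero(self, static_trimer):
        """At t1 = t3 = t2 = 0 both reduce to the same dipole autocorrelation."""
        g, traj = static_trimer
        cfg = SpectroscopyConfig(t1_max=40.0, t3_max=40.0, t2_list=(0.0,))
        gsb = third_order_pathway(traj, g, "GSB", "rephasing", 0.0, cfg)
        se = third_order_pathway(traj, g, "SE", "rephasing", 0.0, cfg)
        assert gsb.values[0, 0] == pytest.approx(se.values[0, 0], rel=1e-10)


class TestAbsorptiveAssembly:
    def test_monomer_single_positive_diagonal_peak(self):
        g, d = cs.make_fixture("monomer", n_frames=260)
        traj = cs.build_trajectory(g, d)
        cfg = SpectroscopyConfig(t2_list=(0.0,), n_realizations=1)
        sp = twodes_spectrum(traj, g, cfg, 0.0, window=(14000.0, 17000.0))
        ij = np.unravel_index(np.argmax(np.abs(sp.amplitude)), sp.amplitude.shape)
        assert sp.amplitude[ij] > 0
        assert sp.omega1[ij[0]] == pytest.approx(OMEGA0_CM, abs=10.0)
        assert sp.omega3[ij[1]] == pytest.approx(OMEGA0_CM, abs=10.0)

    def test_homodimer_diagonal_bleach_and_esa_below(self, parallel_dimer):
        g = parallel_dimer
        traj = static_trajectory(g, n_frames=260)
        J = traj.coupling[0, 1]
        cfg = SpectroscopyConfig(t2_list=(0.0,), n_realizations=1)
        sp = twodes_spectrum(traj, g, cfg, 0.0, window=(13500.0, 17500.0))
        ij = np.unravel_index(np.argmax(np.abs(sp.amplitude)), sp.amplitude.shape)
        # positive (bleach) peak on the diagonal at the bright state w0 + J
        assert sp.amplitude[ij] > 0
        assert sp.omega1[ij[0]] == pytest.approx(OMEGA0_CM + J, abs=12.0)
        assert sp.omega3[ij[1]] == pytest.approx(OMEGA0_CM + J, abs=12.0)
        # negative (induced absorption) peak at (w0 + J, w0 - J):
        # pair energy 2 w0 minus bright energy
        i1 = np.argmin(np.abs(sp.omega1 - (OMEGA0_CM + J)))
        i3 = np.argmin(np.abs(sp.omega3 - (OMEGA0_CM - J)))
        assert sp.amplitude[i1, i3] < 0
        assert abs(sp.amplitude[i1, i3]) > 0.2 * sp.amplitude[ij]

    def test_pathway_linearity(self, static_trimer):
        g, traj = static_trimer
        cfg = SpectroscopyConfig(
            t1_max=60.0, t3_max=60.0, t2_list=(0.0,), n_realizations=1
        )
        grids = {}
        total = twodes_spectrum(traj, g, cfg, 0.0, pathway_grids=grids)
        parts = []
        for pw in ("GSB", "SE", "ESA"):
            cfg_pw = SpectroscopyConfig(
                t1_max=60.0, t3_max=60.0, t2_list=(0.0,), n_realizations=1,
                pathway_mask=(pw,),
            )
            parts.append(twodes_spectrum(traj, g, cfg_pw, 0.0))
        summed = parts[0].amplitude + parts[1].amplitude + parts[2].amplitude
        np.testing.assert_allclose(total.amplitude, summed, atol=1e-9 * np.abs(summed).max())

    def test_mismatched_grids_rejected(self, parallel_dimer):
        g = parallel_dimer
        traj = static_trajectory(g, n_frames=300)
        c1 = SpectroscopyConfig(t1_max=40.0, t3_max=40.0, t2_list=(0.0,))
        c2 = SpectroscopyConfig(t1_max=80.0, t3_max=80.0, t2_list=(0.0,))
        a = third_order_pathway(traj, g, "GSB", "rephasing", 0.0, c1)
        b = third_order_pathway(traj, g, "GSB", "nonrephasing", 0.0, c2)
        with pytest.raises(ValueError, match="shape"):
            assemble_absorptive([a, b], c1)

    def test_realization_averaging_reduces_variance(self):
        """Across-realization scatter of the averaged response shrinks ~ 1/n.

        32 independent disorder realizations of the stack dimer give 16
        two-realization averages and 4 eight-realization averages; the
        empirical variance of the latter must be markedly smaller (the
        theoretical ratio is 1/4).
        """
        g = cs.fixture_geometry("dimer")
        cfg = SpectroscopyConfig(t1_max=40.0, t3_max=40.0, t2_list=(0.0,))
        vals = []
        for r in range(32):
            d = cs.sample_disorder_trajectory(
                2, cs.DisorderParams(n_frames=30, seed=3, realization=r)
            )
            traj = cs.build_trajectory(g, d)
            eng = _RealizationEngine(traj, g, cfg, 0)
            t = eng.pathway_tensor("SE", "rephasing", 0)
            vals.append(isotropic_parallel_average(t)[8, 8])
        vals = np.asarray(vals)
        var2 = vals.reshape(16, 2).mean(axis=1).var()
        var8 = vals.reshape(4, 8).mean(axis=1).var()
        assert var8 < var2


class TestPointTrace:
    def test_static_site_constant_trace(self):
        g, d = cs.make_fixture("monomer", n_frames=400)
        traj = cs.build_trajectory(g, d)
        cfg = SpectroscopyConfig(
            t1_max=60.0, t3_max=60.0, t2_list=(0.0, 24.0, 48.0), n_realizations=1
        )
        spectra = [
            twodes_spectrum(traj, g, cfg, t2, window=(14000.0, 17000.0))
            for t2 in cfg.t2_list
        ]
        tr = point_trace(spectra, OMEGA0_CM, OMEGA0_CM)
        assert np.all(np.diff(tr.t2) > 0)
        np.testing.assert_allclose(tr.amplitude, tr.amplitude[0], rtol=1e-8)

    def test_zero_signal_point_all_zeros(self):
        g, d = cs.make_fixture("monomer", n_frames=400)
        traj = cs.build_trajectory(g, d)
        cfg = SpectroscopyConfig(t1_max=60.0, t3_max=60.0, t2_list=(0.0, 24.0), n_realizations=1)
        spectra = [
            twodes_spectrum(traj, g, cfg, t2, window=(13000.0, 17000.0))
            for t2 in cfg.t2_list
        ]
        # far off-resonant corner carries (numerically) no signal
        tr = point_trace(spectra, 13050.0, 13050.0)
        assert np.all(np.abs(tr.amplitude) < 1e-3 * np.abs(spectra[0].amplitude).max())

    def test_point_outside_window_rejected(self):
        g, d = cs.make_fixture("monomer", n_frames=400)
        traj = cs.build_trajectory(g, d)
        cfg = SpectroscopyConfig(t1_max=60.0, t3_max=60.0, t2_list=(0.0,), n_realizations=1)
        sp = twodes_spectrum(traj, g, cfg, 0.0, window=(15000.0, 16000.0))
        with pytest.raises(ValueError, match="outside"):
            point_trace([sp], 12000.0, 15500.0)
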