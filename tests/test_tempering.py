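"""Simulated tempering, Wang-Landau weights, and constant-velocity pulling."""

import numpy as np
import pytest

import nsh2kit as nk
from nsh2kit.constants import KB
from nsh2kit.model_systems import HarmonicBias, free_energy_quadrature
from nsh2kit.tempering import WangLandau


class TestLadder:
    def test_presets(self):
        opening = nk.ladder_preset("shp2_opening")
        np.testing.assert_allclose(opening.temperatures,
                                   np.arange(300.0, 401.0, 5.0))
        sheet = nk.ladder_preset("sheet_opening")
        np.testing.assert_allclose(sheet.temperatures,
                                   np.arange(300.0, 381.0, 10.0))
        with pytest.raises(ValueError, match="unknown ladder preset"):
            nk.ladder_preset("nope")

    def test_descending_rejected(self):
        with pytest.raises(ValueError):
            nk.TemperatureLadder(np.array([400.0, 300.0]))


class TestParkPandeWeights:
    def test_harmonic_hand_evaluation(self):
        """Ladder 300/350 K with exact harmonic means E = kBT/2."""
        lad = nk.TemperatureLadder(np.array([300.0, 350.0]))
        e = 0.5 * KB * lad.temperatures
        f = nk.park_pande_weights(e, lad)
        b = lad.betas
        expected = (b[1] - b[0]) * 0.5 * (e[0] + e[1])
        assert f[0] == 0.0
        assert f[1] == pytest.approx(expected, abs=1e-12)
        # trapezoid approximates the exact beta F difference 0.5 ln(b2/b1)
        assert f[1] == pytest.approx(0.5 * np.log(b[1] / b[0]), rel=0.01)

    def test_energy_offset_cancels_in_acceptance(self):
        """A constant added to all energies changes the weights by
        beta-weighted constants but leaves the acceptance exponent, evaluated
        with the shifted energies, unchanged."""
        lad = nk.ladder_preset("sheet_opening")
        e = 0.5 * KB * lad.temperatures
        c = 37.0
        f0 = nk.park_pande_weights(e, lad)
        f1 = nk.park_pande_weights(e + c, lad)
        b = lad.betas
        u = 1.23
        for i in range(lad.n_rungs - 1):
            j = i + 1
            log_acc0 = -(b[j] - b[i]) * u + (f0[j] - f0[i])
            log_acc1 = -(b[j] - b[i]) * (u + c) + (f1[j] - f1[i])
            assert log_acc1 == pytest.approx(log_acc0, abs=1e-10)

    def test_missing_energy_rejected(self):
        lad = nk.ladder_preset("sheet_opening")
        with pytest.raises(ValueError):
            nk.park_pande_weights(np.ones(3), lad)


class TestSTAttempt:
    def test_equal_rung_always_accepts(self):
        lad = nk.TemperatureLadder(np.array([300.0, 305.0]))
        rng = np.random.default_rng(0)
        assert nk.st_attempt(0, 0, 1e6, lad, rng) == 0

    def test_high_energy_uphill_rejected(self):
        lad = nk.TemperatureLadder(np.array([300.0, 400.0]))
        rng = np.random.default_rng(1)
        # moving to lower temperature (higher beta) with huge U: always reject
        results = [nk.st_attempt(1, 0, 1e5, lad, rng) for _ in range(100)]
        assert all(r == 1 for r in results)

    def test_out_of_range_and_non_adjacent_rejected(self):
        lad = nk.TemperatureLadder(np.array([300.0, 310.0, 320.0]))
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            nk.st_attempt(2, 3, 1.0, lad, rng)
        with pytest.raises(ValueError):
            nk.st_attempt(0, 2, 1.0, lad, rng)

    def test_detailed_balance_two_rungs(self):
        """Empirical transition ratio on a two-rung harmonic system matches
        the Metropolis ratio within Monte-Carlo error."""
        lad = nk.TemperatureLadder(np.array([300.0, 360.0]))
        sampler = nk.harmonic_energy_sampler(500.0)
        res = nk.run_simulated_tempering(sampler, lad, 200_000, seed=3)
        r = res.rungs
        occ0 = np.mean(r == 0)
        occ1 = np.mean(r == 1)
        # stationary marginal is prop. to Z_i e^{f_i}; with f=0 the ratio is
        # Z_1/Z_0 = sqrt(beta_0/beta_1) = sqrt(T_1/T_0)
        expected = np.sqrt(360.0 / 300.0)
        assert occ1 / occ0 == pytest.approx(expected, rel=0.05)


class TestWangLandau:
    def test_single_rung_relative_weights_unchanged(self):
        lad = nk.TemperatureLadder(np.array([300.0]))
        wl = WangLandau(delta=0.5)
        nk.wl_update(lad, 0, wl)
        nk.wl_update(lad, 0, wl)
        # only a global constant accumulates
        assert lad.weights[0] != 0.0
        assert len(lad.weights) == 1

    def test_two_rung_alternation_oscillates(self):
        lad = nk.TemperatureLadder(np.array([300.0, 310.0]))
        wl = WangLandau(delta=0.1, flatness=2.0)  # flatness never triggers
        diffs = []
        for k in range(10):
            wl = nk.wl_update(lad, k % 2, wl)
            diffs.append(lad.weights[1] - lad.weights[0])
        diffs = np.array(diffs)
        assert np.max(np.abs(diffs)) == pytest.approx(0.1, abs=1e-12)
        assert np.all(np.abs(np.diff(diffs)) == pytest.approx(0.1, abs=1e-12))

    def test_flatness_shrinks_increment_and_resets(self):
        lad = nk.TemperatureLadder(np.array([300.0, 310.0]))
        wl = WangLandau(delta=1.0, flatness=0.8, scale=0.5, min_visits=1)
        wl = nk.wl_update(lad, 0, wl)
        wl = nk.wl_update(lad, 1, wl)
        assert wl.delta == 0.5
        assert np.all(lad.histogram == 0)

    def test_converges_to_exact_weights(self):
        """WL from zero weights on the harmonic oscillator converges to the
        exact beta_i F_i profile within 0.2 (additive constant removed)."""
        lad = nk.ladder_preset("shp2_opening")
        res = nk.run_simulated_tempering(
            nk.harmonic_energy_sampler(1000.0), lad, 2_000_000, seed=4,
            wl=WangLandau(1.0, 0.8, 0.5), stop_delta=1e-4,
        )
        assert res.final_delta < 1e-3
        exact = nk.harmonic_exact_weights(lad, 1000.0)
        dev = (lad.weights - lad.weights[0]) - exact
        dev -= 0.5 * (dev.max() + dev.min())
        assert np.max(np.abs(dev)) < 0.2


class TestTemperingOccupancy:
    def test_exact_weights_flat_occupancy(self):
        """With exact harmonic-oscillator weights the rung occupancy is
        uniform within 3 sigma (multinomial) at 1e5 attempts."""
        lad = nk.ladder_preset("shp2_opening")
        lad.weights[:] = nk.harmonic_exact_weights(lad, 1000.0)
        res = nk.run_simulated_tempering(
            nk.harmonic_energy_sampler(1000.0), lad, 100_000, seed=5)
        counts = np.bincount(res.rungs, minlength=lad.n_rungs)
        n = len(res.rungs)
        p = 1.0 / lad.n_rungs
        sigma = np.sqrt(n * p * (1 - p))
        # correlated samples: allow 3 sigma with an autocorrelation factor
        tau = 2.0 * lad.n_rungs  # diffusion time across the ladder, attempts
        assert np.max(np.abs(counts - n * p)) < 3 * sigma * np.sqrt(tau)


class TestCvRestraint:
    def test_zero_at_center(self):
        e, g = nk.cv_restraint_energy(0.42, nk.CvRestraint(k=1000.0, center=0.42))
        assert e == 0.0 and g == 0.0

    def test_printed_example_value(self):
        # k = 1000 kJ/mol/nm^2 at 0.1 nm displacement: E = 5 kJ/mol
        e, g = nk.cv_restraint_energy(0.1, nk.CvRestraint(k=1000.0, center=0.0))
        assert e == pytest.approx(5.0)
        assert g == pytest.approx(100.0)

    def test_coordinate_gradient_along_collective_direction(self, two_state_noisy):
        from nsh2kit.analysis import superpose

        ens, _ = superpose(two_state_noisy.ensemble,
                           two_state_noisy.alpha_reference,
                           nk.core_fit_selection())
        cv = nk.pca(ens, nk.analysis_selection())[0]
        restraint = nk.CvRestraint(k=1000.0, center=0.3, vector=cv)
        coords = cv.mean_structure + 0.1 * cv.vector
        e, grad = nk.cv_restraint_energy(coords, restraint)
        assert e == pytest.approx(0.5 * 1000 * 0.2**2)
        # gradient is purely along the collective vector
        flat = grad.ravel()
        v = cv.vector.ravel()
        parallel = np.dot(flat, v) * v
        np.testing.assert_allclose(flat, parallel, atol=1e-10)

    def test_restrained_variance_gaussian_closed_form(self):
        """Applying a harmonic restraint to a Gaussian coordinate gives
        variance (1/var + beta k)^-1; verified by exact sampling."""
        K, k = 100.0, 400.0
        pot = nk.Potential1D("harmonic", K=K)
        s = nk.sample_boltzmann_1d(pot, HarmonicBias(k, 0.0), 300.0,
                                   n=100_000, seed=6)
        var0 = KB * 300.0 / K
        beta = 1.0 / (KB * 300.0)
        expected = 1.0 / (1.0 / var0 + beta * k)
        assert s.var() == pytest.approx(expected, rel=0.05)


class TestTemperedPull:
    def test_zero_velocity_zero_work(self):
        pot = nk.Potential1D("harmonic", K=50.0)
        sch = nk.PullSchedule(k=500.0, velocity=0.0, start=0.0, end=0.4,
                              attempt_interval=0.01)
        res = nk.run_tempered_pull(pot, sch, n_steps=500, n_replicas=3,
                                   dt=1e-4, seed=7, sample_interval=100)
        np.testing.assert_array_equal(res.final_work, 0.0)

    def test_quasi_static_work_reaches_reversible_limit(self):
        """Slow pulling of a stiff trap across a harmonic landscape: mean
        work within 5% of the quadrature free-energy difference."""
        pot = nk.Potential1D("harmonic", K=50.0)
        k = 1000.0
        sch = nk.PullSchedule(k=k, velocity=0.05, start=0.0, end=0.5,
                              attempt_interval=0.01)
        x0 = nk.sample_boltzmann_1d(pot, HarmonicBias(k, 0.0), 300.0, n=32,
                                    seed=8)
        res = nk.run_tempered_pull(pot, sch, n_replicas=32, x0=x0, dt=1e-4,
                                   friction=1.0, seed=9, sample_interval=10**6)
        truth = (free_energy_quadrature(pot, HarmonicBias(k, 0.5))
                 - free_energy_quadrature(pot, HarmonicBias(k, 0.0)))
        assert res.final_work.mean() == pytest.approx(truth, rel=0.05)

    def test_mean_dissipation_non_negative(self):
        dw = nk.Potential1D("double_well", h=10.0, a=0.5)
        sch = nk.PullSchedule(k=1000.0, velocity=0.5, start=-0.5, end=0.5,
                              attempt_interval=0.01)
        ws = nk.pull_work_sets(dw, sch, n_pulls=100, dt=1e-4, seed=10)
        assert ws.forward_work.mean() + ws.reverse_work.mean() >= 0.0

    def test_fast_pulls_bar_recovers_end_state_free_energy(self):
        """200 fast forward/reverse pulls on the double well: BAR recovers
        the quadrature free-energy difference between the restrained end
        states within 2 combined errors."""
        dw = nk.Potential1D("double_well", h=10.0, a=0.5)
        k = 1000.0
        sch = nk.PullSchedule(k=k, velocity=0.5, start=-0.5, end=0.25,
                              attempt_interval=0.01)
        truth = (free_energy_quadrature(dw, HarmonicBias(k, 0.25))
                 - free_energy_quadrature(dw, HarmonicBias(k, -0.5)))
        ws = nk.pull_work_sets(dw, sch, n_pulls=200, dt=5e-5, seed=11)
        bar = nk.bar_solve(ws)
        se = nk.work_bootstrap(ws, nk.bar_solve, n_boot=100, seed=12)
        assert abs(bar.value - truth) < 2 * se + 0.05

    def test_base_temperature_marginal_is_boltzmann(self):
        """The 300 K sub-ensemble of a tempered harmonic run matches the
        direct Boltzmann distribution (KS distance < 0.02)."""
        from scipy import stats

        K = 100.0
        pot = nk.Potential1D("harmonic", K=K)
        lad = nk.TemperatureLadder(np.arange(300.0, 361.0, 20.0))
        lad.weights[:] = nk.harmonic_exact_weights(lad, K)
        sch = nk.PullSchedule(k=0.0001, velocity=0.0, start=0.0, end=0.1,
                              attempt_interval=0.01)
        res = nk.run_tempered_pull(
            pot, sch, ladder=lad, n_steps=60_000, n_replicas=24, dt=1e-4,
            friction=0.2, seed=13, sample_interval=50,
        )
        burn = res.times > 1.0
        base = res.positions[burn][res.at_base[burn]]
        sd = np.sqrt(KB * 300.0 / K)
        ks = stats.kstest(base, lambda x: stats.norm.cdf(x, 0.0, sd)).statistic
        assert ks < 0.02

    def test_tempering_improves_sampling_and_flags_base(self):
        dw = nk.Potential1D("double_well", h=10.0, a=0.5)
        lad = nk.ladder_preset("sheet_opening")
        sch = nk.PullSchedule(k=200.0, velocity=0.05, start=-0.5, end=0.5,
                              attempt_interval=0.005)
        res = nk.run_tempered_pull(dw, sch, ladder=lad, n_replicas=4, dt=1e-4,
                                   seed=14, sample_interval=200)
        assert res.at_base.shape == res.rungs.shape
        assert res.acceptance_rate > 0.1
        assert np.any(res.at_base)

    def test_attempt_interval_must_be_dt_multiple(self):
        pot = nk.Potential1D("harmonic", K=50.0)
        sch = nk.PullSchedule(k=100.0, velocity=0.01, start=0.0, end=0.1,
                              attempt_interval=0.00015)
        with pytest.raises(ValueError, match="multiple of dt"):
            nk.run_tempered_pull(pot, sch, ladder=nk.ladder_preset("sheet_opening"),
                                 dt=1e-4, seed=0)
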