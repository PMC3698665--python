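"""MSD fitting, effective diffusion, empiric relations, percolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytocrowd.analysis import (EmpiricFit, MSDSeries, PercolationConfig,
                                compose_D_of_r, effective_diffusion,
                                eval_D_of_r, fit_alpha_vs_D, fit_alpha_vs_lnr,
                                fit_anomalous, logspace_subsample, msd,
                                percolation_threshold, spanning_probability)


class TestMsd:
    def test_stationary_molecules_zero(self):
        p = np.tile(np.array([[1.0, 2.0, 3.0]]), (5, 4, 1))
        s = msd(p)
        assert np.all(s.msd == 0)

    def test_ballistic_closed_form(self):
        t = np.arange(6, dtype=float)
        v = np.array([1.0, 2.0, -1.0])
        p = t[:, None, None] * v[None, None, :]
        p = np.repeat(p, 3, axis=1)
        s = msd(p, t)
        assert np.allclose(s.msd, (v @ v) * t[1:] ** 2)

    def test_matches_brute_force_average(self, rng):
        p = rng.random((7, 10, 3))
        s = msd(p)
        for k, tk in enumerate(range(1, 7)):
            expect = np.mean([((p[tk, i] - p[0, i]) ** 2).sum()
                              for i in range(10)])
            assert s.msd[k] == pytest.approx(expect)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            msd(np.empty((5, 0, 3)))


class TestFitAnomalous:
    def test_exact_linear_msd(self):
        t = np.linspace(1, 100, 300)
        fit = fit_anomalous(MSDSeries(times=t, msd=6 * t), window=(1, 100))
        assert fit.alpha == pytest.approx(1.0)
        assert fit.Gamma == pytest.approx(6.0)

    def test_recovers_reference_power_law_under_noise(self):
        """A subdiffusive curve with the magnitudes seen in reconstructed
        cytoplasm (Gamma=3.37, alpha=0.940) is recovered within the quoted
        uncertainties from 1% multiplicative noise."""
        rng = np.random.default_rng(0)
        t = np.logspace(-3, 0, 400)
        m = 3.37 * t ** 0.940 * (1 + 0.01 * rng.standard_normal(t.size))
        fit = fit_anomalous(MSDSeries(times=t, msd=m), window=(t[0], t[-1]))
        assert fit.alpha == pytest.approx(0.940, abs=0.004)
        assert fit.Gamma == pytest.approx(3.37, abs=0.14)

    def test_confined_msd_gives_zero_alpha(self):
        t = np.linspace(1, 100, 50)
        fit = fit_anomalous(MSDSeries(times=t, msd=np.full(50, 4.0)),
                            window=(1, 100))
        assert fit.alpha == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_regenerates_input(self):
        rng = np.random.default_rng(1)
        t = np.logspace(0, 3, 200)
        m = 2.5 * t ** 0.8 * (1 + 0.02 * rng.standard_normal(t.size))
        fit = fit_anomalous(MSDSeries(times=t, msd=m), window=(t[0], t[-1]))
        regen = fit.Gamma * t ** fit.alpha
        assert np.allclose(np.log(regen), np.log(m), atol=0.1)

    def test_nonpositive_msd_rejected(self):
        t = np.linspace(1, 100, 20)
        m = 6 * t
        m[5] = 0.0
        with pytest.raises(ValueError):
            fit_anomalous(MSDSeries(times=t, msd=m), window=(1, 100))

    def test_too_few_points_rejected(self):
        t = np.linspace(1, 10, 5)
        with pytest.raises(ValueError):
            fit_anomalous(MSDSeries(times=t, msd=6 * t), window=(1, 10))


class TestEffectiveDiffusion:
    def test_normal_diffusion_constant(self):
        t = np.linspace(1, 50, 100)
        d = effective_diffusion(MSDSeries(times=t, msd=6 * t), d=3, t0=0.0)
        assert np.allclose(d.msd, 1.0)

    def test_one_dimensional_form(self):
        t = np.linspace(1, 50, 100)
        d = effective_diffusion(MSDSeries(times=t, msd=2 * t), d=1, t0=0.0)
        assert np.allclose(d.msd, 1.0)

    def test_subdiffusion_strictly_decreasing(self):
        t = np.linspace(1, 50, 100)
        d = effective_diffusion(MSDSeries(times=t, msd=t ** 0.9), d=3, t0=0.0)
        assert np.all(np.diff(d.msd) < 0)

    def test_free_diffusion_deff_flat_in_time(self):
        """Slope of D_eff(t) for a linear MSD is statistically zero."""
        rng = np.random.default_rng(2)
        t = np.linspace(1, 100, 200)
        m = 6 * t * (1 + 0.01 * rng.standard_normal(t.size))
        d = effective_diffusion(MSDSeries(times=t, msd=m), d=3, t0=0.0)
        from scipy.stats import linregress
        res = linregress(t, d.msd)
        assert abs(res.slope) < 2 * res.stderr

    def test_invalid_dimension_rejected(self):
        t = np.linspace(1, 10, 20)
        with pytest.raises(ValueError):
            effective_diffusion(MSDSeries(times=t, msd=6 * t), d=2)


class TestEmpiricRelations:
    def test_exact_alpha_vs_D(self):
        D = np.array([5.0, 20.0, 35.0, 50.0])
        pts = np.stack([D, 0.0093 * D + 0.4606], axis=1)
        fit = fit_alpha_vs_D(pts)
        assert fit.slope == pytest.approx(0.0093)
        assert fit.intercept == pytest.approx(0.4606)

    def test_exact_alpha_vs_lnr(self):
        r = np.array([77.8, 155.6, 311.2, 389.0])
        pts = np.stack([r, 0.1302 * np.log(r) + 0.0976], axis=1)
        fit = fit_alpha_vs_lnr(pts)
        assert fit.slope == pytest.approx(0.1302)
        assert fit.intercept == pytest.approx(0.0976)

    def test_lnr_unit_change_shifts_intercept_only(self):
        r = np.array([1.0, 2.0, 4.0, 8.0])
        alpha = 0.13 * np.log(r) + 0.1
        fit_nm = fit_alpha_vs_lnr(np.stack([r, alpha], 1))
        fit_um = fit_alpha_vs_lnr(np.stack([r / 1000.0, alpha], 1))
        assert fit_um.slope == pytest.approx(fit_nm.slope)
        assert fit_um.intercept == pytest.approx(
            fit_nm.intercept + fit_nm.slope * np.log(1000.0))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_alpha_vs_D([[1.0, 0.5], [1.0, 0.5], [1.0, 0.5]])
        with pytest.raises(ValueError):
            fit_alpha_vs_lnr([[1.0, 0.5], [1.0, 0.6], [1.0, 0.7]])
        with pytest.raises(ValueError):
            fit_alpha_vs_lnr([[-1.0, 0.5], [2.0, 0.6], [3.0, 0.7]])

    def test_compose_reference_coefficients(self):
        c = compose_D_of_r(EmpiricFit(0.0093, 0.4606),
                           EmpiricFit(0.1302, 0.0976, transform="log"))
        assert c.slope == pytest.approx(14.0, abs=0.05)
        assert c.intercept == pytest.approx(-39.03, abs=0.005)

    def test_compose_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            compose_D_of_r(EmpiricFit(0.0, 0.5),
                           EmpiricFit(0.13, 0.1, transform="log"))

    def test_eval_reference_radii(self):
        fit = EmpiricFit(14.0, -39.0, transform="log")
        assert eval_D_of_r(fit, 77.8) == pytest.approx(21.96, abs=0.005)
        assert eval_D_of_r(fit, 389.0) == pytest.approx(44.49, abs=0.005)
        assert eval_D_of_r(fit, 1.0) == pytest.approx(-39.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a1=st.floats(0.005, 0.05), b1=st.floats(0.1, 0.9),
           a2=st.floats(0.05, 0.5), b2=st.floats(-0.5, 0.5))
    def test_compose_recovers_planted_relation(self, a1, b1, a2, b2):
        """Fitting both relations on data from a common latent alpha model
        and composing them recovers the planted D(ln r) relation."""
        r = np.array([50.0, 100.0, 200.0, 400.0, 800.0])
        alpha_r = a2 * np.log(r) + b2
        D = (alpha_r - b1) / a1                 # exact D for each alpha
        c = compose_D_of_r(fit_alpha_vs_D(np.stack([D, alpha_r], 1)),
                           fit_alpha_vs_lnr(np.stack([r, alpha_r], 1)))
        assert c.slope == pytest.approx(a2 / a1, rel=1e-6)
        assert c.intercept == pytest.approx((b2 - b1) / a1, rel=1e-5, abs=1e-8)


class TestPercolation:
    def test_extreme_occupancies(self, rng):
        assert spanning_probability(1.0, 8, 10, rng) == 1.0
        assert spanning_probability(0.0, 8, 10, rng) == 0.0

    def test_spanning_probability_nondecreasing_in_p(self, rng):
        ps = [0.20, 0.28, 0.32, 0.36, 0.45]
        vals = [spanning_probability(p, 12, 150, rng) for p in ps]
        assert all(b >= a - 0.07 for a, b in zip(vals, vals[1:]))

    def test_threshold_reference_value(self):
        """Finite-size crossing of 16^3 and 32^3 spanning curves lands on
        the known simple-cubic site percolation threshold 0.312."""
        res = percolation_threshold(PercolationConfig(
            lattice_sizes=(16, 32), replicates=100, seed=7))
        assert res["p_c"] == pytest.approx(0.312, abs=0.012)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PercolationConfig(lattice_sizes=(16,))
        with pytest.raises(ValueError):
            PercolationConfig(replicates=5)


class TestLogspaceSubsample:
    def test_preserves_endpoints_and_monotonicity(self):
        t = np.arange(1.0, 10001.0)
        s = logspace_subsample(MSDSeries(times=t, msd=6 * t), 20)
        assert s.times[0] == 1.0
        assert s.times[-1] == 10000.0
        assert np.all(np.diff(s.times) > 0)
        assert s.times.size < 150
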