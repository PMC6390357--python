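import math

import numpy as np
import pytest
from scipy.optimize import brentq

from illdeath.dosimetry import bed_iso
from illdeath.predict import (InfeasibleTargetError, average_profile,
                              baseline_hazard_ratio,
                              cumulative_transition_probability, dose_for_tcp,
                              tcp_curve, tdcov_hazard_ratio)
from illdeath.spline import MSplineBasis, PenalizedHazardFit, fit_penalized_hazard
from illdeath.synthetic import (BaselineHazard, paper_like_config,
                                simulate_illness_death)
from illdeath.prep import build_transition_datasets


def constant_fit(lam, beta=(), covariates=(), upper=60.0, scaling=None,
                 transition=1):
    """An exactly-constant-hazard spline model: h0(t) = lam for all t.

    M-splines scaled by their knot widths reproduce the B-spline
    partition of unity, so c_k = lam * width_k / order gives h0 == lam
    exactly.  Covariance is zero: these fits are analytic fixtures."""
    basis = MSplineBasis(0.0, upper, tuple(np.linspace(0, upper, 9)[1:-1]))
    t = basis.knots
    k = np.arange(basis.n_basis)
    widths = (t[k + basis.order] - t[k]) / basis.order
    c = lam * widths
    q = basis.n_basis + len(beta)
    return PenalizedHazardFit(
        transition=transition, basis=basis, coef_spline=c,
        coef=np.asarray(beta, dtype=float), covariates=list(covariates),
        kappa=0.0, sigma2=0.0, frailty_modes={}, loglik=0.0,
        loglik_unpenalized=0.0, covariance=np.zeros((q, q)),
        scaling=dict(scaling or {}))


LAM1, LAM2, LAM3 = 0.03, 0.02, 0.06   # lam3 != lam1+lam2 (closed forms)


@pytest.fixture(scope="module")
def const_fits():
    return (constant_fit(LAM1), constant_fit(LAM2, transition=2),
            constant_fit(LAM3, transition=3))


def _p2_closed(t, l1=LAM1, l2=LAM2):
    l12 = l1 + l2
    return l2 / l12 * (1 - np.exp(-l12 * t))


def _p3_closed(t, l1=LAM1, l2=LAM2, l3=LAM3):
    l12 = l1 + l2
    a = l1 / l12 * (1 - np.exp(-l12 * t))
    b = l1 * np.exp(-l3 * t) * (np.exp((l3 - l12) * t) - 1) / (l3 - l12)
    return a - b


class TestTcpCurve:
    def test_starts_at_one(self, const_fits):
        band = tcp_curve(const_fits[0], {}, np.array([0.0, 5.0]), mc_samples=10)
        assert band.estimate[0] == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_constant_hazard(self, const_fits):
        """H0(t) = lam*t with zero linear predictor: TCP = exp(-lam t),
        e.g. exp(-0.2) = 0.8187 at t = 0.2/lam."""
        t = np.array([0.2 / LAM1, 1.0, 10.0, 30.0])
        band = tcp_curve(const_fits[0], {}, t, mc_samples=10)
        assert np.allclose(band.estimate, np.exp(-LAM1 * t), atol=1e-6)
        assert band.estimate[0] == pytest.approx(0.818730753, abs=1e-6)

    def test_monotone_in_dose(self):
        fit = constant_fit(LAM1, beta=[-0.9], covariates=["bed_std"])
        t = np.linspace(1, 40, 20)
        low = tcp_curve(fit, {"bed_std": 0.0}, t, mc_samples=10).estimate
        high = tcp_curve(fit, {"bed_std": 1.0}, t, mc_samples=10).estimate
        assert (high > low).all()
        assert (np.diff(low) <= 0).all()

    def test_missing_covariate_rejected(self):
        fit = constant_fit(LAM1, beta=[-0.9], covariates=["bed_std"])
        with pytest.raises(KeyError):
            tcp_curve(fit, {}, np.array([1.0]), mc_samples=10)

    def test_band_brackets_estimate(self, datasets):
        fit = fit_penalized_hazard(datasets[1], kappa=1e4, sigma2=0.0)
        band = tcp_curve(fit, average_profile(datasets[1]),
                         np.linspace(0.5, 30, 25), mc_samples=200, seed=4)
        assert (band.lower <= band.estimate).all()
        assert (band.estimate <= band.upper).all()

    def test_band_converges_with_samples(self, datasets):
        fit = fit_penalized_hazard(datasets[1], kappa=1e4, sigma2=0.0)
        prof = average_profile(datasets[1])
        t = np.linspace(1, 30, 15)
        # same seed: the first 500 draws of the 1000-sample run coincide
        b1 = tcp_curve(fit, prof, t, mc_samples=500, seed=11)
        b2 = tcp_curve(fit, prof, t, mc_samples=1000, seed=11)
        assert np.max(np.abs(b1.lower - b2.lower)) < 0.02
        assert np.max(np.abs(b1.upper - b2.upper)) < 0.02


class TestDoseForTcp:
    def _fit(self):
        return constant_fit(LAM1, beta=[0.5, -0.8], covariates=["chemo", "bed_std"],
                            scaling={"bed_std": (130.0, 50.0)})

    def test_closed_form_inversion(self):
        """Brute-force root finding on the closed-form TCP agrees with
        the analytic inversion to 1e-6."""
        fit = self._fit()
        profile = {"chemo": 1.0}
        target, horizon = 0.9, 24.0

        def tcp_at_bed(bed):
            z = (bed - 130.0) / (2 * 50.0)
            return math.exp(-LAM1 * horizon * math.exp(0.5 + -0.8 * z)) - target

        bed_oracle = brentq(tcp_at_bed, 1.0, 5000.0, xtol=1e-10)
        rx, bed = dose_for_tcp(fit, profile, target, horizon, 3, 65.0)
        assert bed == pytest.approx(bed_oracle, abs=1e-6)
        assert bed_iso(rx).bed_iso == pytest.approx(bed, abs=1e-9)

    def test_fixed_point(self):
        """Asking for the TCP already achieved at a given BED returns
        that BED."""
        fit = self._fit()
        bed0 = 150.0
        z0 = (bed0 - 130.0) / 100.0
        horizon = 24.0
        tcp0 = math.exp(-LAM1 * horizon * math.exp(0.5 - 0.8 * z0))
        _, bed = dose_for_tcp(fit, {"chemo": 1.0}, tcp0, horizon, 5, 65.0)
        assert bed == pytest.approx(bed0, abs=1e-9)

    def test_nonprotective_dose_rejected(self):
        fit = constant_fit(LAM1, beta=[0.3], covariates=["bed_std"],
                           scaling={"bed_std": (130.0, 50.0)})
        with pytest.raises(InfeasibleTargetError):
            dose_for_tcp(fit, {}, 0.9, 24.0, 3, 65.0)

    def test_unreachable_target_flagged(self):
        # weak dose effect: the required standardized dose implies BED <= 0
        fit = constant_fit(2.0, beta=[-0.01], covariates=["bed_std"],
                           scaling={"bed_std": (130.0, 50.0)})
        with pytest.raises(InfeasibleTargetError):
            dose_for_tcp(fit, {}, 0.9999, 24.0, 3, 65.0)

    def test_bad_target_rejected(self):
        with pytest.raises(InfeasibleTargetError):
            dose_for_tcp(self._fit(), {"chemo": 0.0}, 1.2, 24.0, 3, 65.0)


class TestBaselineHazardRatio:
    def test_identical_fits_give_unity(self, const_fits):
        band = baseline_hazard_ratio(const_fits[1], const_fits[1],
                                     np.linspace(2, 40, 20), mc_samples=10)
        assert np.allclose(band.estimate, 1.0, atol=1e-12)

    def test_constant_ratio_closed_form(self, const_fits):
        band = baseline_hazard_ratio(const_fits[1], const_fits[2],
                                     np.linspace(2, 40, 20), mc_samples=10)
        assert np.allclose(band.estimate, LAM3 / LAM2, atol=1e-6)

    def test_generated_ratio_recovered(self):
        """h03 = 2 h02 in the generator: the estimated ratio sits near 2
        across the inner grid and the band covers 2."""
        cfg = paper_like_config(
            seed=31, n_hospitals=120,
            baseline_2=BaselineHazard("weibull", 30.0, 1.0),
            baseline_3=BaselineHazard("weibull", 15.0, 1.0),   # ratio 2
            baseline_1=BaselineHazard("weibull", 15.0, 1.0),   # plenty of relapses
            frailty_sd=(0.0, 0.0, 0.0), beta_2={}, beta_3={},
            censor_uniform=(30.0, 60.0), admin_horizon=60.0)
        coh = simulate_illness_death(cfg)
        ds = build_transition_datasets(coh.lesions, coh.patients,
                                       covariates={1: ["bed_std"], 2: ["volume_std"],
                                                   3: ["volume_std"]})
        f2 = fit_penalized_hazard(ds[2], kappa=1e6, sigma2=0.0)
        f3 = fit_penalized_hazard(ds[3], kappa=1e6, sigma2=0.0)
        grid = np.linspace(5, 30, 20)
        band = baseline_hazard_ratio(f2, f3, grid, mc_samples=300, seed=2)
        assert 1.4 < np.median(band.estimate) < 2.8
        assert np.all(band.lower <= 2.0) and np.any(band.upper >= 2.0)


class TestCumulativeTransitionProbability:
    def test_no_relapse_hazard_reduction(self, const_fits):
        """h1 = 0: P3 vanishes and P2 is the simple survival complement."""
        zero1 = constant_fit(0.0)
        t = np.linspace(1, 40, 15)
        P2, P3 = cumulative_transition_probability(
            zero1, const_fits[1], const_fits[2], {}, t, mc_samples=5)
        assert np.allclose(P3.estimate, 0.0, atol=1e-12)
        assert np.allclose(P2.estimate, 1 - np.exp(-LAM2 * t), atol=1e-6)

    def test_constant_hazard_closed_forms(self, const_fits):
        t = np.linspace(1, 40, 15)
        P2, P3 = cumulative_transition_probability(
            const_fits[0], const_fits[1], const_fits[2], {}, t, mc_samples=5)
        assert np.allclose(P2.estimate, _p2_closed(t), atol=1e-6)
        assert np.allclose(P3.estimate, _p3_closed(t), atol=1e-6)

    def test_probability_conservation(self, const_fits):
        """P2 + P3 + P(alive relapse-free) + P(alive post-relapse) = 1."""
        t = np.linspace(1, 40, 10)
        P2, P3 = cumulative_transition_probability(
            const_fits[0], const_fits[1], const_fits[2], {}, t, mc_samples=5)
        l12 = LAM1 + LAM2
        alive_free = np.exp(-l12 * t)
        alive_relapsed = (LAM1 * np.exp(-LAM3 * t)
                          * (np.exp((LAM3 - l12) * t) - 1) / (LAM3 - l12))
        total = P2.estimate + P3.estimate + alive_free + alive_relapsed
        assert np.allclose(total, 1.0, atol=1e-4)

    def test_monotone_and_bounded(self, datasets):
        f1 = fit_penalized_hazard(datasets[1], kappa=1e4, sigma2=0.0)
        f2 = fit_penalized_hazard(datasets[2], kappa=1e4, sigma2=0.0)
        f3 = fit_penalized_hazard(datasets[3], kappa=1e4, sigma2=0.0)
        prof = {**average_profile(datasets[2]), **average_profile(datasets[3]),
                **average_profile(datasets[1])}
        t = np.linspace(1, 30, 12)
        P2, P3 = cumulative_transition_probability(f1, f2, f3, prof, t,
                                                   mc_samples=50, seed=3)
        for band in (P2, P3):
            assert (np.diff(band.estimate) >= -1e-10).all()
            assert (band.estimate >= 0).all() and (band.estimate <= 1).all()

    def test_empirical_incidence_matches_analytic(self):
        """Simulated cumulative incidence of death-without-relapse agrees
        with the analytic competing-risks value for constant hazards."""
        cfg = paper_like_config(
            seed=41, n_hospitals=300, lesions_per_patient_probs=(1.0,),
            baseline_1=BaselineHazard("weibull", 1 / LAM1, 1.0),
            baseline_2=BaselineHazard("weibull", 1 / LAM2, 1.0),
            baseline_3=BaselineHazard("weibull", 1 / LAM3, 1.0),
            frailty_sd=(0.0, 0.0, 0.0), beta_1={}, beta_2={}, beta_3={},
            censor_uniform=(500.0, 500.0), admin_horizon=500.0)
        coh = simulate_illness_death(cfg)
        p = coh.patients
        for t in (10.0, 25.0):
            emp = float(((p["event_death"] == 1) & (p["relapse_observed"] == 0)
                         & (p["time_death"] <= t)).mean())
            assert emp == pytest.approx(_p2_closed(t), abs=0.02)


class TestTimeDependentCovariate:
    @pytest.fixture(scope="class")
    def shared_baseline_cohort(self):
        """h3 = exp(0.7) * h2 with a shared Weibull baseline (shape 1.1):
        scale3 = scale2 * exp(-0.7/1.1)."""
        shape = 1.1
        scale2 = 40.0
        scale3 = scale2 * math.exp(-0.7 / shape)
        cfg = paper_like_config(
            seed=29, n_hospitals=60,
            baseline_1=BaselineHazard("weibull", 25.0, 1.0),
            baseline_2=BaselineHazard("weibull", scale2, shape),
            baseline_3=BaselineHazard("weibull", scale3, shape),
            frailty_sd=(0.0, 0.0, 0.0), beta_2={}, beta_3={},
            censor_uniform=(40.0, 90.0), admin_horizon=90.0)
        return simulate_illness_death(cfg)

    def test_recovers_generating_ratio(self, shared_baseline_cohort):
        res = tdcov_hazard_ratio(shared_baseline_cohort.patients)
        assert abs(res["coef"] - 0.7) < 3 * res["se"]

    def test_no_relapse_rejected(self):
        cfg = paper_like_config(seed=3, baseline_1=BaselineHazard(
            "tabulated", grid=(0.0, 200.0), values=(0.0, 0.0)))
        coh = simulate_illness_death(cfg)
        with pytest.raises(ValueError):
            tdcov_hazard_ratio(coh.patients)

    def test_time_unit_invariance(self, shared_baseline_cohort):
        p = shared_baseline_cohort.patients
        res_m = tdcov_hazard_ratio(p, sigma2=0.0)
        p_days = p.copy()
        p_days["time_death"] = p["time_death"] * 30.4
        p_days["time_relapse"] = p["time_relapse"] * 30.4
        res_d = tdcov_hazard_ratio(p_days, sigma2=0.0)
        assert res_d["coef"] == pytest.approx(res_m["coef"], abs=1e-6)


class TestAverageProfile:
    def test_mean_and_mode(self, datasets):
        prof = average_profile(datasets[1])
        f = datasets[1].frame
        assert prof["bed_std"] == pytest.approx(float(f["bed_std"].mean()))
        assert prof["chemo"] == float(f["chemo"].mode().iloc[0])
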