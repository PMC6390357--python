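"""Simulation of clustered illness-death cohorts.

Generates lesion- and patient-level tables mimicking a multicenter SBRT
registry of colorectal liver/lung metastases: patients clustered in
hospitals, one to six treated lesions per patient, and the three-state
illness-death structure (treated -> local failure -> death, treated ->
death) with hospital-level Gaussian frailties on each transition's
log-hazard and right censoring.  Every generating parameter is explicit in
:class:`SimulationConfig`, so downstream estimators can be validated
against known truth.

Event times are drawn by inverse-transform sampling of the cause-specific
cumulative hazards: closed form for Weibull baselines, grid interpolation
for tabulated ones.  Post-relapse death follows the Markov (clock-forward)
convention — after a relapse at time r the death hazard is the
transition-3 hazard evaluated at time since treatment, so the cumulative
death hazard is H2 up to r and H2(r) + H3(t) - H3(r) beyond it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "BaselineHazard",
    "SimulationConfig",
    "Cohort",
    "paper_like_config",
    "draw_frailties",
    "simulate_illness_death",
    "inject_missingness",
    "LESION_COLUMNS",
    "PATIENT_COLUMNS",
]

#: Lesion-table columns (the LC analysis unit).  Times in months from first
#: treatment, volumes in ccm, BED in Gy_10.
LESION_COLUMNS = [
    "hospital_id", "patient_id", "lesion_id", "site", "volume_ccm",
    "ptv_volume_ccm", "chemo", "motion_advanced", "algo_advanced",
    "bed_iso", "time_lc", "event_lc",
]

#: Patient-table columns (the OS analysis unit).
PATIENT_COLUMNS = [
    "hospital_id", "patient_id", "sex_female", "age", "kps_ge90",
    "solitary", "n_treated_mets", "site", "chemo", "max_volume_ccm",
    "time_death", "event_death", "time_relapse", "relapse_observed",
]


@dataclass(frozen=True)
class BaselineHazard:
    """Parametric or tabulated baseline hazard for one transition.

    ``kind="weibull"`` uses h0(t) = (shape/scale) * (t/scale)**(shape-1),
    so H0(t) = (t/scale)**shape; shape 1 is constant hazard 1/scale.
    ``kind="tabulated"`` takes piecewise-constant values on a time grid.
    """

    kind: str = "weibull"
    scale: float = 50.0
    shape: float = 1.0
    grid: tuple[float, ...] | None = None
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "weibull":
            if not (self.scale > 0 and self.shape > 0):
                raise ValueError("Weibull scale and shape must be positive")
        elif self.kind == "tabulated":
            if self.grid is None or self.values is None:
                raise ValueError("tabulated hazard needs grid and values")
            v = np.asarray(self.values, dtype=float)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError("tabulated hazard values must be finite and >= 0")
        else:
            raise ValueError(f"unknown hazard kind {self.kind!r}")

    def cumulative(self, t: np.ndarray) -> np.ndarray:
        """H0(t), vectorised."""
        t = np.asarray(t, dtype=float)
        if self.kind == "weibull":
            return (np.maximum(t, 0.0) / self.scale) ** self.shape
        g = np.asarray(self.grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        widths = np.diff(g)
        cumH = np.concatenate([[0.0], np.cumsum(v[:-1] * widths)])
        out = np.interp(t, g, cumH)
        # extrapolate beyond the grid with the last hazard value
        beyond = t > g[-1]
        if np.any(beyond):
            out = np.where(beyond, cumH[-1] + (t - g[-1]) * v[-1], out)
        return out

    def inverse_cumulative(self, H: np.ndarray) -> np.ndarray:
        """Smallest t with H0(t) = H (inverse transform sampling)."""
        H = np.asarray(H, dtype=float)
        if self.kind == "weibull":
            return self.scale * H ** (1.0 / self.shape)
        g = np.asarray(self.grid, dtype=float)
        Hg = self.cumulative(g)
        out = np.interp(H, Hg, g)
        beyond = H > Hg[-1]
        if np.any(beyond):
            v_last = float(np.asarray(self.values)[-1])
            if v_last > 0:
                out = np.where(beyond, g[-1] + (H - Hg[-1]) / v_last, out)
            else:
                out = np.where(beyond, np.inf, out)
        return out


def _lesion_count_probs() -> tuple[float, ...]:
    # registry frequencies of 1..6 treated metastases per patient
    return (0.827, 0.108, 0.034, 0.018, 0.005, 0.008)


@dataclass(frozen=True)
class SimulationConfig:
    """Full generating model for one synthetic cohort.

    Defaults are the "paper-like" preset: 27 hospitals sized to give about
    388 patients and 500 lesions, registry marginal covariate frequencies,
    Weibull cause-specific baselines, and administrative plus uniform
    dropout censoring.  Missingness is injected separately
    (:func:`inject_missingness`), not here.
    """

    n_hospitals: int = 27
    mean_patients_per_hospital: float = 14.4
    lesions_per_patient_probs: tuple[float, ...] = field(default_factory=_lesion_count_probs)

    # per-transition frailty SDs (sigma_1, sigma_2, sigma_3)
    frailty_sd: tuple[float, float, float] = (0.3, 0.3, 0.3)

    # Weibull scales chosen so the preset reproduces the registry outcome
    # mix (~22% lesion failures, ~26% relapsed patients, ~53% deaths, most
    # relapsed patients dying within follow-up)
    baseline_1: BaselineHazard = field(default_factory=lambda: BaselineHazard("weibull", 320.0, 0.9))
    baseline_2: BaselineHazard = field(default_factory=lambda: BaselineHazard("weibull", 52.0, 1.1))
    baseline_3: BaselineHazard = field(default_factory=lambda: BaselineHazard("weibull", 8.0, 1.1))

    # fixed effects on the model scale (binary dummies; BED and volume
    # standardised with the centring constants below)
    beta_1: dict = field(default_factory=lambda: {
        "site_lung": -0.87, "chemo": 1.29, "volume_std": 0.18,
        "motion_advanced": -0.21, "algo_advanced": -0.15, "bed_std": -0.94,
    })
    beta_2: dict = field(default_factory=lambda: {
        "sex_female": -0.03, "age_ge66": 0.12, "kps_ge90": -0.75,
        "site_lung": -0.12, "solitary": -0.19, "multiple_mets": -0.04,
        "chemo": 0.17, "volume_std": 0.69,
    })
    beta_3: dict = field(default_factory=lambda: {
        "kps_ge90": 0.26, "site_lung": 0.26, "solitary": -0.60,
        "chemo": -1.66, "volume_std": 0.75,
    })

    # covariate-generation spec (registry marginals)
    p_site_liver: float = 0.582
    p_chemo_liver: float = 0.845
    p_chemo_lung: float = 0.685
    p_sex_female: float = 0.302
    p_kps_ge90: float = 0.657
    age_mean: float = 66.0
    age_sd: float = 11.0
    volume_logmean_liver: float = math.log(26.0)
    volume_logsd_liver: float = 1.2
    volume_logmean_lung: float = math.log(3.1)
    volume_logsd_lung: float = 1.4
    bed_mean_liver: float = 125.0
    bed_sd_liver: float = 45.0
    bed_mean_lung: float = 141.0
    bed_sd_lung: float = 55.0
    p_motion_advanced: float = 0.306
    p_algo_advanced: float = 0.599

    # standardisation constants used inside the generating linear predictor
    # (2-SD convention, matching the analysis scale)
    bed_center: float = 130.0
    bed_scale: float = 100.0
    volume_center: float = 30.0
    volume_scale: float = 120.0

    # censoring: dropout ~ Uniform(lo, hi), truncated at the admin horizon
    censor_uniform: tuple[float, float] = (6.0, 96.0)
    admin_horizon: float = 96.0

    # missingness rates (applied only by inject_missingness)
    missing_rates: dict = field(default_factory=lambda: {
        "volume_ccm": 0.316, "kps_ge90": 0.27, "chemo": 0.14, "n_treated_mets": 0.216,
    })
    #: fraction of masked volumes whose PTV surrogate stays observed
    ptv_observed_fraction: float = 0.63

    seed: int = 0

    # recorded-time resolution for the death-first tie convention
    time_resolution: float = 0.01

    def __post_init__(self) -> None:
        if self.n_hospitals < 1:
            raise ValueError("n_hospitals must be >= 1")
        if any(s < 0 for s in self.frailty_sd):
            raise ValueError("frailty SDs must be >= 0")
        p = np.asarray(self.lesions_per_patient_probs, dtype=float)
        if p.ndim != 1 or np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("lesion-count distribution must be non-negative and sum to 1")
        for bh in (self.baseline_1, self.baseline_2, self.baseline_3):
            if not isinstance(bh, BaselineHazard):
                raise ValueError("baselines must be BaselineHazard instances")
        for r in self.missing_rates.values():
            if not 0 <= r <= 1:
                raise ValueError("missingness rates must lie in [0, 1]")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def paper_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default preset sized like the registry cohort (27 hospitals,
    ~388 patients, ~500 lesions)."""
    return SimulationConfig(seed=seed).replace(**overrides)


class Cohort(NamedTuple):
    """A simulated cohort: one lesion-level and one patient-level table."""

    lesions: pd.DataFrame
    patients: pd.DataFrame


def draw_frailties(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-hospital Gaussian frailties, shape (n_hospitals, 3).

    Independent N(0, sigma_g^2) draws per transition; exactly zero when the
    corresponding SD is zero; reproducible under the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sd = np.asarray(config.frailty_sd, dtype=float)
    return rng.standard_normal((config.n_hospitals, 3)) * sd[None, :]


def _linpred(frame: pd.DataFrame, beta: dict) -> np.ndarray:
    lp = np.zeros(len(frame))
    for name, b in beta.items():
        if name not in frame.columns:
            raise KeyError(f"covariate {name!r} missing from design frame")
        lp = lp + b * frame[name].to_numpy(dtype=float)
    return lp


def _draw_event_time(bh: BaselineHazard, lp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-transform draw: t with H0(t) * exp(lp) = Exp(1)."""
    e = rng.exponential(size=len(lp))
    return bh.inverse_cumulative(e / np.exp(lp))


def simulate_illness_death(config: SimulationConfig) -> Cohort:
    """Simulate one cohort under the illness-death generating model.

    For each patient: every lesion gets a latent local-failure time from the
    transition-1 hazard (lesion covariates + hospital frailty); the latent
    relapse time is the minimum over that patient's lesions; death is drawn
    from the transition-2 hazard before relapse and switches to the
    transition-3 hazard afterwards on the shared time-since-treatment clock.
    Censoring truncates both processes; recorded ties between death and
    relapse are resolved as death-first (local control censored).
    """
    rng = np.random.default_rng(config.seed)
    frail = draw_frailties(config, rng)

    n_pat = rng.poisson(config.mean_patients_per_hospital, size=config.n_hospitals)
    n_pat = np.maximum(n_pat, 1)
    total_pat = int(n_pat.sum())
    hosp_of_pat = np.repeat(np.arange(config.n_hospitals), n_pat)

    # --- patient covariates -------------------------------------------------
    site_liver = rng.random(total_pat) < config.p_site_liver
    sex_female = (rng.random(total_pat) < config.p_sex_female).astype(int)
    kps = (rng.random(total_pat) < config.p_kps_ge90).astype(int)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, total_pat), 24, 93)
    p_chemo = np.where(site_liver, config.p_chemo_liver, config.p_chemo_lung)
    chemo = (rng.random(total_pat) < p_chemo).astype(int)
    n_lesions = rng.choice(
        np.arange(1, len(config.lesions_per_patient_probs) + 1),
        size=total_pat, p=np.asarray(config.lesions_per_patient_probs) / np.sum(config.lesions_per_patient_probs),
    )
    solitary = ((n_lesions == 1) & (rng.random(total_pat) < 0.44)).astype(int)

    # --- lesion covariates --------------------------------------------------
    pat_of_lesion = np.repeat(np.arange(total_pat), n_lesions)
    n_les_total = len(pat_of_lesion)
    les_site_liver = site_liver[pat_of_lesion]
    logmean = np.where(les_site_liver, config.volume_logmean_liver, config.volume_logmean_lung)
    logsd = np.where(les_site_liver, config.volume_logsd_liver, config.volume_logsd_lung)
    volume = np.exp(rng.normal(logmean, logsd))
    bed_mean = np.where(les_site_liver, config.bed_mean_liver, config.bed_mean_lung)
    bed_sd = np.where(les_site_liver, config.bed_sd_liver, config.bed_sd_lung)
    bed = np.clip(rng.normal(bed_mean, bed_sd), 37.5, 310.0)
    motion = (rng.random(n_les_total) < config.p_motion_advanced).astype(int)
    algo = (rng.random(n_les_total) < config.p_algo_advanced).astype(int)

    lesions = pd.DataFrame({
        "hospital_id": hosp_of_pat[pat_of_lesion] + 1,
        "patient_id": pat_of_lesion + 1,
        "lesion_id": np.arange(1, n_les_total + 1),
        "site": np.where(les_site_liver, "liver", "lung"),
        "volume_ccm": volume,
        "ptv_volume_ccm": volume * np.exp(rng.normal(0.35, 0.15, n_les_total)),
        "chemo": chemo[pat_of_lesion],
        "motion_advanced": motion,
        "algo_advanced": algo,
        "bed_iso": bed,
    })
    les_design = pd.DataFrame({
        "site_lung": (~les_site_liver).astype(float),
        "chemo": lesions["chemo"].astype(float),
        "volume_std": (volume - config.volume_center) / config.volume_scale,
        "motion_advanced": motion.astype(float),
        "algo_advanced": algo.astype(float),
        "bed_std": (bed - config.bed_center) / config.bed_scale,
    })

    # --- latent event times -------------------------------------------------
    lp1 = _linpred(les_design, config.beta_1) + frail[hosp_of_pat[pat_of_lesion], 0]
    t_fail = _draw_event_time(config.baseline_1, lp1, rng)

    # patient-level relapse time: min over the patient's lesions
    relapse = np.full(total_pat, np.inf)
    np.minimum.at(relapse, pat_of_lesion, t_fail)

    max_vol = np.zeros(total_pat)
    np.maximum.at(max_vol, pat_of_lesion, volume)

    pat_design = pd.DataFrame({
        "sex_female": sex_female.astype(float),
        "age_ge66": (age >= 66).astype(float),
        "kps_ge90": kps.astype(float),
        "site_lung": (~site_liver).astype(float),
        "solitary": solitary.astype(float),
        "multiple_mets": (n_lesions > 1).astype(float),
        "chemo": chemo.astype(float),
        "volume_std": (max_vol - config.volume_center) / config.volume_scale,
    })
    lp2 = _linpred(pat_design, config.beta_2) + frail[hosp_of_pat, 1]
    lp3 = _linpred(pat_design, config.beta_3) + frail[hosp_of_pat, 2]

    # death: cumulative hazard H2 before relapse, H2(r) + H3 - H3(r) after
    e_death = rng.exponential(size=total_pat)
    H2r = config.baseline_2.cumulative(relapse) * np.exp(lp2)
    before = e_death <= np.where(np.isfinite(relapse), H2r, np.inf)
    t_death = np.empty(total_pat)
    t_death[before] = config.baseline_2.inverse_cumulative(
        e_death[before] / np.exp(lp2[before]))
    after = ~before
    if np.any(after):
        # residual exponential budget spent on the transition-3 hazard
        resid = (e_death[after] - H2r[after]) / np.exp(lp3[after])
        H3r = config.baseline_3.cumulative(relapse[after])
        t_death[after] = config.baseline_3.inverse_cumulative(H3r + resid)

    # --- censoring and recorded outcomes ------------------------------------
    lo, hi = config.censor_uniform
    censor = np.minimum(rng.uniform(lo, hi, total_pat), config.admin_horizon)
    res = config.time_resolution
    rec = lambda t: np.round(np.asarray(t, dtype=float) / res) * res  # noqa: E731

    time_death = rec(np.minimum(t_death, censor))
    event_death = (t_death <= censor).astype(int)
    time_death = np.maximum(time_death, res)  # times strictly positive

    relapse_rec = np.maximum(rec(relapse), res)
    # observed relapse: latent relapse strictly before recorded end of follow-up
    relapse_obs = (np.isfinite(relapse) & (relapse_rec < time_death)).astype(int)
    time_relapse = np.where(relapse_obs == 1, relapse_rec, np.nan)

    patients = pd.DataFrame({
        "hospital_id": hosp_of_pat + 1,
        "patient_id": np.arange(1, total_pat + 1),
        "sex_female": sex_female,
        "age": age,
        "kps_ge90": kps,
        "solitary": solitary,
        "n_treated_mets": n_lesions,
        "site": np.where(site_liver, "liver", "lung"),
        "chemo": chemo,
        "max_volume_ccm": max_vol,
        "time_death": time_death,
        "event_death": event_death,
        "time_relapse": time_relapse,
        "relapse_observed": relapse_obs,
    })

    # lesion LC follow-up ends at death or censoring, death-first on ties
    end_fu = time_death[pat_of_lesion]
    t_fail_rec = rec(t_fail)
    event_lc = (t_fail_rec < end_fu).astype(int)
    time_lc = np.where(event_lc == 1, t_fail_rec, end_fu)
    time_lc = np.maximum(time_lc, res)
    lesions["time_lc"] = time_lc
    lesions["event_lc"] = event_lc

    return Cohort(lesions[LESION_COLUMNS].copy(), patients[PATIENT_COLUMNS].copy())


def inject_missingness(
    cohort: Cohort,
    rates: dict | None = None,
    seed: int = 0,
    mar_site_volume: bool = False,
    ptv_observed_fraction: float | None = None,
) -> Cohort:
    """Mask covariate cells to emulate registry missingness.

    MCAR by default: each cell of the named covariate is set missing with
    the stated rate, independently.  ``mar_site_volume=True`` switches
    tumour volume to an MAR mechanism that masks lung lesions at twice the
    liver rate (same expected overall rate).  When a lesion's volume is
    masked its PTV surrogate stays observed for a fraction of lesions,
    emulating planning volumes usable by the imputation; otherwise the PTV
    is masked too.
    """
    if rates is None:
        rates = SimulationConfig().missing_rates
    for r in rates.values():
        if not 0 <= r <= 1:
            raise ValueError(f"missingness rate {r} outside [0, 1]")
    if ptv_observed_fraction is None:
        ptv_observed_fraction = SimulationConfig().ptv_observed_fraction
    rng = np.random.default_rng(seed)
    lesions = cohort.lesions.copy()
    patients = cohort.patients.copy()

    lesion_cols = {"volume_ccm", "bed_iso", "motion_advanced", "algo_advanced"}
    for col, rate in rates.items():
        if rate == 0:
            continue
        if col == "chemo":
            # chemotherapy is a patient-level fact: mask per patient and
            # propagate to that patient's lesions
            mask = rng.random(len(patients)) < rate
            patients["chemo"] = patients["chemo"].astype(float).mask(mask)
            gone = set(patients.loc[mask, "patient_id"])
            lmask = lesions["patient_id"].isin(gone)
            lesions["chemo"] = lesions["chemo"].astype(float).mask(lmask)
        elif col in lesion_cols and col in lesions.columns:
            n = len(lesions)
            if col == "volume_ccm" and mar_site_volume:
                # lung masked at twice the liver probability, overall ~= rate
                lung = (lesions["site"] == "lung").to_numpy()
                p_liver = rate / (1.0 + lung.mean())
                p = np.where(lung, min(1.0, 2 * p_liver), p_liver)
                mask = rng.random(n) < p
            else:
                mask = rng.random(n) < rate
            lesions[col] = lesions[col].astype(float).mask(mask)
            if col == "volume_ccm":
                ptv_drop = mask & (rng.random(n) >= ptv_observed_fraction)
                lesions["ptv_volume_ccm"] = lesions["ptv_volume_ccm"].mask(ptv_drop)
                patients = _refresh_max_volume(lesions, patients)
        elif col in patients.columns:
            n = len(patients)
            mask = rng.random(n) < rate
            patients[col] = patients[col].astype(float).mask(mask)
        else:
            raise KeyError(f"unknown covariate {col!r}")
    return Cohort(lesions, patients)


def _refresh_max_volume(lesions: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Recompute per-patient max volume after masking (NaN if all masked)."""
    mv = lesions.groupby("patient_id")["volume_ccm"].max(numeric_only=True)
    patients = patients.copy()
    patients["max_volume_ccm"] = patients["patient_id"].map(mv).to_numpy()
    return patients
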