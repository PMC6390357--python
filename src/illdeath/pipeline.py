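"""End-to-end orchestration: simulate or ingest a cohort, prepare and
impute, fit all three transitions, and emit report and figure-data files.

Artifacts are delimited text (CSV) plus a JSON manifest carrying the
config hash, seed and package version, so a rerun with the same triple
reproduces the deterministic outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dosimetry import schedule_for_bed
from .frailty import fit_frailty_cox
from .predict import (average_profile, baseline_hazard_ratio,
                      cumulative_transition_probability, dose_for_tcp,
                      tcp_curve, InfeasibleTargetError)
from .prep import (DEFAULT_COVARIATES, build_transition_datasets,
                   descriptive_compare, impute_chained, pool_estimates)
from .spline import MSplineBasis, cross_validate_kappa, fit_penalized_hazard
from .synthetic import (Cohort, LESION_COLUMNS, PATIENT_COLUMNS,
                        inject_missingness, paper_like_config,
                        simulate_illness_death)

__all__ = ["RunConfig", "run_pipeline", "write_cohort", "read_cohort",
           "DATA_DICTIONARY"]

log = logging.getLogger("illdeath")

DATA_DICTIONARY = """\
# Cohort data dictionary
# All times are months from the first SBRT treatment.
#
# lesions.csv (one row per treated metastasis)
hospital_id     integer   treating hospital (cluster for the frailty)
patient_id      integer   patient the lesion belongs to
lesion_id       integer   unique lesion identifier
site            text      'liver' or 'lung'
volume_ccm      float     gross tumor volume [ccm]; may be missing
ptv_volume_ccm  float     planning target volume [ccm]; imputation aid
chemo           0/1       chemotherapy before SBRT; may be missing
motion_advanced 0/1       advanced motion management
algo_advanced   0/1       advanced dose calculation algorithm
bed_iso         float     biologically effective dose at isocenter [Gy_10]
time_lc         float     local-control follow-up time [months]
event_lc        0/1       local failure observed
#
# patients.csv (one row per patient)
hospital_id     integer   treating hospital
patient_id      integer   unique patient identifier
sex_female      0/1       sex
age             float     age at first treatment [years]
kps_ge90        0/1       Karnofsky performance status >= 90; may be missing
solitary        0/1       solitary metastasis
n_treated_mets  integer   number of treated metastases; may be missing
site            text      predominant metastasis site
chemo           0/1       chemotherapy before SBRT; may be missing
max_volume_ccm  float     largest treated tumor volume [ccm]
time_death      float     overall-survival follow-up time [months]
event_death     0/1       death observed
time_relapse    float     first observed local relapse [months]; empty if none
relapse_observed 0/1      any local relapse observed before death/censoring
"""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"                 # "simulate" | "ingest"
    lesions_path: str | None = None
    patients_path: str | None = None
    out_dir: str = "illdeath_run"
    seed: int = 0
    m_imputations: int = 5
    kappa: float | None = None             # None -> cross-validated
    kappa_grid: tuple[float, ...] = (1e2, 1e3, 1e4, 1e5, 1e6)
    mc_samples: int = 500
    complete_case: bool = False
    inject_missing: bool = True            # simulate mode only
    horizon_months: float = 24.0
    tcp_target: float = 0.9
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.m_imputations < 1:
            raise ValueError("m_imputations must be >= 1")
        if self.mode == "ingest":
            for p in (self.lesions_path, self.patients_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input table not found: {p}")

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "covariates" in data:
            data["covariates"] = {int(k): list(v) for k, v in data["covariates"].items()}
        if "kappa_grid" in data:
            data["kappa_grid"] = tuple(data["kappa_grid"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["kappa_grid"] = list(d["kappa_grid"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.lesions.to_csv(out / "lesions.csv", index=False)
    cohort.patients.to_csv(out / "patients.csv", index=False)
    (out / "data_dictionary.txt").write_text(DATA_DICTIONARY)


def read_cohort(lesions_path: str | Path, patients_path: str | Path) -> Cohort:
    lesions = pd.read_csv(lesions_path)
    patients = pd.read_csv(patients_path)
    _validate_schema(lesions, LESION_COLUMNS, "lesions")
    _validate_schema(patients, PATIENT_COLUMNS, "patients")
    return Cohort(lesions, patients)


def _validate_schema(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table lacks required columns {missing}")


def _site_descriptives(cohort: Cohort) -> pd.DataFrame:
    """Liver-vs-lung descriptive comparison rows."""
    les = cohort.lesions
    liver = les[les["site"] == "liver"]
    lung = les[les["site"] == "lung"]
    rows = []
    for var, kind in [("volume_ccm", "continuous"), ("bed_iso", "continuous"),
                      ("chemo", "categorical"), ("motion_advanced", "categorical"),
                      ("algo_advanced", "categorical"), ("event_lc", "categorical")]:
        res = descriptive_compare(liver[var].dropna(), lung[var].dropna(), kind)
        rows.append({"variable": var, "test": res["test"], "p_value": res["p_value"]})
    return pd.DataFrame(rows)


def _fit_transitions_pooled(copies, covariates, control=None):
    """Frailty Cox fits per completed copy, pooled by Rubin's rules."""
    per_transition: dict[int, dict] = {g: {"coef": [], "var": [], "sigma2": []} for g in (1, 2, 3)}
    for cohort in copies:
        ds = build_transition_datasets(cohort.lesions, cohort.patients, covariates)
        for g in (1, 2, 3):
            fit = fit_frailty_cox(ds[g], control=control)
            per_transition[g]["coef"].append(pd.Series(fit.coef, index=fit.covariates))
            per_transition[g]["var"].append(pd.Series(fit.se ** 2, index=fit.covariates))
            per_transition[g]["sigma2"].append(fit.sigma2)
    tables = {}
    for g in (1, 2, 3):
        P = pd.DataFrame(per_transition[g]["coef"])
        V = pd.DataFrame(per_transition[g]["var"])
        if len(P) >= 2:
            point, se = pool_estimates(P, V)
        else:
            point, se = P.iloc[0], np.sqrt(V.iloc[0])
        from scipy import stats
        z = point / se
        tables[g] = pd.DataFrame({
            "coef": point, "se": se, "hr": np.exp(point),
            "hr_lo": np.exp(point - 1.959963984540054 * se),
            "hr_hi": np.exp(point + 1.959963984540054 * se),
            "p": 2 * stats.norm.sf(np.abs(z)),
            "sigma2_median": float(np.median(per_transition[g]["sigma2"])),
        })
    return tables


def _dose_table(fit1, ds1, config: RunConfig) -> pd.DataFrame:
    """Dose-for-TCP table: BED and example schedules per site and
    chemotherapy status (schedules at the 65% isodose line)."""
    rows = []
    for site_lung in (1.0, 0.0):
        for chemo in (0.0, 1.0):
            profile = average_profile(ds1)
            profile["site_lung"] = site_lung
            profile["chemo"] = chemo
            site = "lung" if site_lung else "liver"
            try:
                _, bed = dose_for_tcp(fit1, profile, config.tcp_target,
                                      config.horizon_months, 3, 65.0)
                row = {"site": site, "chemo": int(chemo), "bed_iso": round(bed, 1)}
                for nfx in (3, 5):
                    rx = schedule_for_bed(bed, nfx, 65.0)
                    row[f"dose_per_fx_{nfx}fx_at65"] = round(rx.dose_per_fraction, 1)
            except InfeasibleTargetError as err:
                row = {"site": site, "chemo": int(chemo), "bed_iso": np.nan,
                       "note": str(err)}
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the artifact index.

    Stages: cohort acquisition -> descriptives -> chained imputation ->
    per-transition frailty Cox fits pooled across copies -> penalized
    spline-hazard fits (cross-validated kappa) -> predictions (TCP,
    dose-for-TCP, baseline hazard ratio, cumulative transition
    probabilities) -> delimited-text artifacts plus a JSON manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    config.to_yaml(out / "config.yaml")

    if config.mode == "simulate":
        cohort = simulate_illness_death(paper_like_config(seed=config.seed))
        if config.inject_missing:
            cohort = inject_missingness(cohort, seed=config.seed + 1)
    else:
        cohort = read_cohort(config.lesions_path, config.patients_path)
    write_cohort(cohort, out)
    log.info("cohort: %d patients, %d lesions", len(cohort.patients), len(cohort.lesions))

    _site_descriptives(cohort).to_csv(out / "descriptives_by_site.csv", index=False)

    has_missing = (cohort.lesions.isna().any().any()
                   or cohort.patients.drop(columns=["time_relapse"]).isna().any().any())
    if config.complete_case or not has_missing:
        copies = [cohort]
    else:
        imp = impute_chained(cohort, m=config.m_imputations, seed=config.seed + 2)
        copies = imp.copies

    if config.complete_case:
        # sensitivity analysis: only rows with no missing covariates
        ds_all = build_transition_datasets(cohort.lesions, cohort.patients,
                                           config.covariates, na_action="drop")
        tables = {}
        for g in (1, 2, 3):
            fit = fit_frailty_cox(ds_all[g])
            tables[g] = fit.summary().assign(sigma2_median=fit.sigma2)
    else:
        tables = _fit_transitions_pooled(copies, config.covariates)
        first = copies[0]
        ds_all = build_transition_datasets(first.lesions, first.patients, config.covariates)

    for g, tab in tables.items():
        tab.to_csv(out / f"hazard_ratios_transition{g}.csv")
    log.info("events per transition: %s", {g: int(ds_all[g].n_events) for g in ds_all})

    # spline baseline hazards on the (first) completed dataset
    spline_fits = {}
    kappas = {}
    for g in (1, 2, 3):
        basis = MSplineBasis.from_dataset(ds_all[g])
        if config.kappa is None:
            kp, _ = cross_validate_kappa(ds_all[g], basis, config.kappa_grid)
        else:
            kp = float(config.kappa)
        kappas[g] = kp
        spline_fits[g] = fit_penalized_hazard(ds_all[g], basis, kappa=kp, sigma2=0.0)

    # figure data
    t_max = float(np.quantile(ds_all[2].frame["exit"], 0.95))
    grid = np.linspace(0.5, t_max, 60)
    prof_all = {**average_profile(ds_all[2]), **average_profile(ds_all[3]),
                **average_profile(ds_all[1])}
    for site_lung, site in ((0.0, "liver"), (1.0, "lung")):
        prof1 = {**average_profile(ds_all[1]), "site_lung": site_lung}
        band = tcp_curve(spline_fits[1], prof1, grid, config.mc_samples, seed=config.seed + 3)
        band.to_frame().to_csv(out / f"tcp_{site}.csv", index=False)
        prof = {**prof_all, "site_lung": site_lung}
        P2, P3 = cumulative_transition_probability(
            spline_fits[1], spline_fits[2], spline_fits[3], prof, grid,
            config.mc_samples, seed=config.seed + 4)
        P2.to_frame().merge(P3.to_frame(), on="time", suffixes=("_t2", "_t3")).to_csv(
            out / f"cumulative_transitions_{site}.csv", index=False)

    earliest_relapse = float(ds_all[3].frame["entry"].min())
    hr_grid = np.linspace(max(earliest_relapse, 0.5), t_max, 60)
    hr_band = baseline_hazard_ratio(spline_fits[2], spline_fits[3], hr_grid,
                                    config.mc_samples, seed=config.seed + 5)
    hr_band.to_frame().to_csv(out / "hazard_ratio_over_time.csv", index=False)

    _dose_table(spline_fits[1], ds_all[1], config).to_csv(out / "dose_for_tcp.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "mode": config.mode,
        "n_patients": int(len(cohort.patients)),
        "n_lesions": int(len(cohort.lesions)),
        "m_imputations": len(copies),
        "kappa": kappas,
        "events": {str(g): int(ds_all[g].n_events) for g in ds_all},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
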