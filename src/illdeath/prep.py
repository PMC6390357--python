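"""Cohort preparation: counting-process datasets, standardisation,
chained-equation imputation and Rubin pooling.

The illness-death model is fit transition by transition on
counting-process data.  Transition 1 (treatment -> local failure) is
lesion-level with origin at treatment; transition 2 (treatment -> death
without prior relapse) is patient-level, censored at the first observed
relapse; transition 3 (relapse -> death) is patient-level with delayed
entry at the relapse time on the shared time-since-treatment clock
(Markov convention).

Continuous covariates (BED, tumour volume) are standardised by centring
and dividing by two standard deviations, so their hazard ratios compare
"high" vs "low" values roughly like a binary covariate's do.  Missing
covariates are handled by chained-equation imputation with predictive
mean matching and correlation-and-usability predictor screening, and per-copy fits
are pooled by Rubin's rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import Cohort

__all__ = [
    "TransitionDataset",
    "ImputationSet",
    "DEFAULT_COVARIATES",
    "standardize",
    "build_transition_datasets",
    "impute_chained",
    "pool_estimates",
    "descriptive_compare",
    "events_per_covariate_check",
]

#: Default covariate set per transition (model-scale column names).
DEFAULT_COVARIATES = {
    1: ["site_lung", "chemo", "volume_std", "motion_advanced", "algo_advanced", "bed_std"],
    2: ["sex_female", "age_ge66", "kps_ge90", "site_lung", "solitary",
        "multiple_mets", "chemo", "volume_std"],
    3: ["kps_ge90", "site_lung", "solitary", "chemo", "volume_std"],
}

#: Dichotomisation cut-points on the raw scale.
AGE_CUT = 66
MULTIPLE_METS_CUT = 1  # "> 1 treated metastasis"


class DegenerateCovariateError(ValueError):
    """A covariate is constant (zero variance) on the fitted data."""


class DataConsistencyError(ValueError):
    """Event bookkeeping violates the illness-death structure."""


@dataclass
class TransitionDataset:
    """Counting-process rows for one transition.

    ``frame`` holds columns ``cluster``, ``entry``, ``exit``, ``event`` plus
    the model-scale covariates named in ``covariates``.  ``scaling`` maps a
    standardised covariate name to its (mean, sd) so predictions can be
    back-transformed; ``unit`` is "lesion" or "patient".
    """

    transition: int
    frame: pd.DataFrame
    covariates: list[str]
    scaling: dict = field(default_factory=dict)
    unit: str = "patient"

    def __post_init__(self) -> None:
        need = {"cluster", "entry", "exit", "event"}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"frame lacks columns {sorted(missing)}")
        bad = self.frame["entry"] >= self.frame["exit"]
        if bad.any():
            raise DataConsistencyError(
                f"{int(bad.sum())} rows with entry >= exit in transition {self.transition}")

    @property
    def n_events(self) -> int:
        return int(self.frame["event"].sum())

    def dropna(self) -> "TransitionDataset":
        """Complete-case copy (rows with any missing covariate dropped)."""
        frame = self.frame.dropna(subset=self.covariates).reset_index(drop=True)
        return TransitionDataset(self.transition, frame, list(self.covariates),
                                 dict(self.scaling), self.unit)


def standardize(values, name: str = "x") -> tuple[np.ndarray, tuple[float, float]]:
    """Centre and scale by two standard deviations: (x - mean) / (2 sd).

    Constants are computed on the observed (non-missing) entries and
    returned so the transform can be inverted.  A constant column raises
    :class:`DegenerateCovariateError`.
    """
    x = np.asarray(values, dtype=float)
    obs = x[np.isfinite(x)]
    if len(np.unique(obs)) < 2:
        raise DegenerateCovariateError(f"covariate {name!r} has fewer than 2 distinct values")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    return (x - mean) / (2.0 * sd), (mean, sd)


def _model_scale_lesions(lesions: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    scaling: dict = {}
    out = pd.DataFrame(index=lesions.index)
    out["site_lung"] = (lesions["site"] == "lung").astype(float)
    out["chemo"] = lesions["chemo"].astype(float)
    out["motion_advanced"] = lesions["motion_advanced"].astype(float)
    out["algo_advanced"] = lesions["algo_advanced"].astype(float)
    out["volume_std"], scaling["volume_std"] = standardize(lesions["volume_ccm"], "volume_ccm")
    out["bed_std"], scaling["bed_std"] = standardize(lesions["bed_iso"], "bed_iso")
    return out, scaling


def _model_scale_patients(patients: pd.DataFrame, volume_scaling: tuple[float, float] | None = None) -> tuple[pd.DataFrame, dict]:
    scaling: dict = {}
    out = pd.DataFrame(index=patients.index)
    out["sex_female"] = patients["sex_female"].astype(float)
    out["age_ge66"] = (patients["age"] >= AGE_CUT).astype(float)
    out["kps_ge90"] = patients["kps_ge90"].astype(float)
    out["site_lung"] = (patients["site"] == "lung").astype(float)
    out["solitary"] = patients["solitary"].astype(float)
    out["chemo"] = patients["chemo"].astype(float)
    nmet = patients["n_treated_mets"].astype(float)
    out["multiple_mets"] = (nmet > MULTIPLE_METS_CUT).astype(float)
    out.loc[nmet.isna(), "multiple_mets"] = np.nan
    if volume_scaling is None:
        out["volume_std"], scaling["volume_std"] = standardize(
            patients["max_volume_ccm"], "max_volume_ccm")
    else:
        mean, sd = volume_scaling
        out["volume_std"] = (patients["max_volume_ccm"].astype(float) - mean) / (2 * sd)
        scaling["volume_std"] = volume_scaling
    # binary columns keep their NaN where the raw value was missing
    for col, raw in [("chemo", "chemo"), ("kps_ge90", "kps_ge90"), ("sex_female", "sex_female")]:
        out.loc[patients[raw].isna(), col] = np.nan
    return out, scaling


def build_transition_datasets(
    lesions: pd.DataFrame,
    patients: pd.DataFrame,
    covariates: dict | None = None,
    na_action: str = "keep",
) -> dict[int, TransitionDataset]:
    """Build the three counting-process datasets from the cohort tables.

    Transition 1 uses lesion rows (origin 0, event = local failure,
    follow-up ends at death or censoring with the death-first tie rule
    applied upstream).  Transition 2 uses patient rows censored at the
    first observed relapse; transition 3 covers relapsed patients only,
    entering the risk set at the relapse time (left truncation).

    ``na_action="drop"`` gives complete-case datasets.
    """
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    if na_action not in ("keep", "drop"):
        raise ValueError("na_action must be 'keep' or 'drop'")

    rel = patients["relapse_observed"].astype(bool)
    bad = rel & (patients["time_relapse"] >= patients["time_death"])
    if bad.any():
        raise DataConsistencyError(
            f"{int(bad.sum())} patients with relapse at/after recorded death")

    les_design, les_scaling = _model_scale_lesions(lesions)
    pat_design, pat_scaling = _model_scale_patients(patients)

    out: dict[int, TransitionDataset] = {}

    f1 = pd.DataFrame({
        "cluster": lesions["hospital_id"].to_numpy(),
        "entry": 0.0,
        "exit": lesions["time_lc"].to_numpy(dtype=float),
        "event": lesions["event_lc"].to_numpy(dtype=int),
    })
    for c in covariates[1]:
        f1[c] = les_design[c].to_numpy()
    out[1] = TransitionDataset(1, f1, list(covariates[1]), les_scaling, unit="lesion")

    exit2 = np.where(rel, patients["time_relapse"], patients["time_death"]).astype(float)
    event2 = ((~rel) & (patients["event_death"] == 1)).astype(int)
    f2 = pd.DataFrame({
        "cluster": patients["hospital_id"].to_numpy(),
        "entry": 0.0,
        "exit": exit2,
        "event": event2,
    })
    for c in covariates[2]:
        f2[c] = pat_design[c].to_numpy()
    out[2] = TransitionDataset(2, f2, list(covariates[2]), pat_scaling)

    sub = patients[rel.to_numpy()]
    f3 = pd.DataFrame({
        "cluster": sub["hospital_id"].to_numpy(),
        "entry": sub["time_relapse"].to_numpy(dtype=float),
        "exit": sub["time_death"].to_numpy(dtype=float),
        "event": sub["event_death"].to_numpy(dtype=int),
    })
    for c in covariates[3]:
        f3[c] = pat_design.loc[sub.index, c].to_numpy()
    out[3] = TransitionDataset(3, f3, list(covariates[3]), dict(pat_scaling))

    if na_action == "drop":
        out = {g: ds.dropna() for g, ds in out.items()}
    for g, ds in out.items():
        events_per_covariate_check(ds)
    return out


def events_per_covariate_check(ds: TransitionDataset, events_per_covariate: int = 15) -> bool:
    """Warn when the covariate count exceeds events/15 (overfitting guard)."""
    allowed = ds.n_events / events_per_covariate
    ok = len(ds.covariates) <= allowed
    if not ok:
        warnings.warn(
            f"transition {ds.transition}: {len(ds.covariates)} covariates for "
            f"{ds.n_events} events exceeds the events/{events_per_covariate} guideline",
            stacklevel=2)
    return ok


# ---------------------------------------------------------------------------
# Chained-equation imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationSet:
    """m completed copies of the cohort tables plus the imputation metadata."""

    copies: list[Cohort]
    m: int
    predictor_matrix: dict
    n_iter: int
    seed: int


def _spearman_screen(df: pd.DataFrame, target: str, pool: list[str],
                     min_corr: float, min_usable: float) -> list[str]:
    """predictor screen: keep those with |Spearman rho| >= min_corr
    (pairwise complete) and usable-case proportion >= min_usable."""
    y = df[target]
    miss = y.isna()
    chosen = []
    for p in pool:
        if p == target:
            continue
        x = df[p]
        both = y.notna() & x.notna()
        if both.sum() < 3 or x[both].nunique() < 2 or y[both].nunique() < 2:
            continue
        rho = stats.spearmanr(x[both], y[both]).statistic
        usable = x[miss].notna().mean() if miss.any() else 1.0
        if np.isfinite(rho) and abs(rho) >= min_corr and usable >= min_usable:
            chosen.append(p)
    return chosen


def _ols_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Least squares with a posterior draw of the coefficients (PMM type-1)."""
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(XtX)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    beta_star = beta + L @ rng.standard_normal(p)
    return beta, beta_star


def _logistic_irls(X: np.ndarray, y: np.ndarray, ridge: float = 1e-4,
                   max_iter: int = 50) -> np.ndarray:
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu) + 1e-10
        H = (X * W[:, None]).T @ X + ridge * np.eye(p)
        g = X.T @ (y - mu) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _pmm_impute(df: pd.DataFrame, target: str, predictors: list[str],
                rng: np.random.Generator, k_donors: int = 5) -> None:
    miss = df[target].isna()
    rows_obs = df.index[~miss]
    rows_mis = df.index[miss]
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in predictors])
    y = df.loc[rows_obs, target].to_numpy(dtype=float)
    Xo, Xm = X[~miss.to_numpy()], X[miss.to_numpy()]
    beta, beta_star = _ols_draw(Xo, y, rng)
    pred_obs = Xo @ beta
    pred_mis = Xm @ beta_star
    # nearest-k donors on predicted value, one drawn per missing row
    order = np.argsort(pred_obs)
    sorted_pred, sorted_y = pred_obs[order], y[order]
    for i, row in enumerate(rows_mis):
        pos = np.searchsorted(sorted_pred, pred_mis[i])
        lo = max(0, pos - k_donors)
        hi = min(len(sorted_y), pos + k_donors)
        cand = np.argsort(np.abs(sorted_pred[lo:hi] - pred_mis[i]))[:k_donors]
        df.loc[row, target] = sorted_y[lo:hi][rng.choice(cand)]


def _logistic_impute(df: pd.DataFrame, target: str, predictors: list[str],
                     rng: np.random.Generator) -> None:
    miss = df[target].isna()
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in predictors])
    y = df.loc[~miss, target].to_numpy(dtype=float)
    beta = _logistic_irls(X[~miss.to_numpy()], y)
    eta = np.clip(X[miss.to_numpy()] @ beta, -30, 30)
    prob = 1.0 / (1.0 + np.exp(-eta))
    df.loc[miss, target] = (rng.random(int(miss.sum())) < prob).astype(float)


def _marginal_impute(df: pd.DataFrame, target: str, rng: np.random.Generator) -> None:
    miss = df[target].isna()
    obs = df.loc[~miss, target].to_numpy(dtype=float)
    df.loc[miss, target] = rng.choice(obs, size=int(miss.sum()), replace=True)


def _chained_pass(df: pd.DataFrame, plan: dict, rng: np.random.Generator,
                  k_donors: int) -> None:
    for target, (predictors, binary) in plan.items():
        if not predictors:
            _marginal_impute(df, target, rng)
        elif binary:
            _logistic_impute(df, target, predictors, rng)
        else:
            _pmm_impute(df, target, predictors, rng, k_donors)


#: positive, right-skewed columns imputed on the log scale
LOG_SCALE_COLUMNS = {"volume_ccm", "ptv_volume_ccm", "max_volume_ccm"}


def _numeric_view(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "site" in out.columns:
        out["site"] = (out["site"] == "lung").astype(float)
    out = out.select_dtypes(include=[np.number]).astype(float)
    for col in LOG_SCALE_COLUMNS & set(out.columns):
        out[col] = np.log(out[col])
    return out


def _is_binary(s: pd.Series) -> bool:
    u = s.dropna().unique()
    return len(u) <= 2 and set(np.asarray(u, dtype=float)) <= {0.0, 1.0}


def impute_chained(
    cohort: Cohort,
    m: int = 50,
    screening: tuple[float, float] = (0.2, 0.25),
    seed: int = 0,
    n_iter: int = 8,
    k_donors: int = 5,
) -> ImputationSet:
    """Multiple imputation by chained equations on both cohort tables.

    Each incomplete variable is regressed on a predictor set passing the
    correlation/usability screen (Spearman on pairwise-complete cases,
    thresholds ``screening``); continuous variables are imputed by
    predictive mean matching with ``k_donors`` nearest donors, binaries by
    a logistic draw.  A variable with no eligible predictors falls back to
    marginal resampling (warning, not error).  Observed cells are
    identical across the ``m`` returned copies; only masked cells vary.
    The per-patient maximum tumour volume is refreshed from the completed
    lesion volumes in every copy.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    min_corr, min_usable = screening
    rng = np.random.default_rng(seed)

    tables = {"lesions": _numeric_view(cohort.lesions), "patients": _numeric_view(cohort.patients)}
    # outcome columns never get imputed; they may serve as predictors
    never_impute = {"hospital_id", "patient_id", "lesion_id",
                    "time_lc", "event_lc", "time_death", "event_death",
                    "time_relapse", "relapse_observed", "max_volume_ccm"}
    plans: dict[str, dict] = {}
    predictor_matrix: dict[str, list[str]] = {}
    for name, tab in tables.items():
        plan: dict = {}
        pool = [c for c in tab.columns if c not in {"patient_id", "lesion_id", "time_relapse"}]
        for col in tab.columns:
            if col in never_impute or not tab[col].isna().any():
                continue
            if name == "lesions" and col == "chemo":
                # patient-level fact: imputed on the patient table and
                # propagated to lesions afterwards
                continue
            preds = _spearman_screen(tab, col, pool, min_corr, min_usable)
            # predictors that are themselves incomplete are fine: the chained
            # passes fill them in before use
            if not preds:
                warnings.warn(f"{name}.{col}: no eligible predictors; marginal fallback",
                              stacklevel=2)
            plan[col] = (preds, _is_binary(tab[col]))
            predictor_matrix[f"{name}.{col}"] = preds
        plans[name] = plan

    copies: list[Cohort] = []
    for _ in range(m):
        les = tables["lesions"].copy()
        pat = tables["patients"].copy()
        # warm start: marginal draws so chained passes see complete predictors
        for name, df in (("lesions", les), ("patients", pat)):
            for col in plans[name]:
                _marginal_impute(df, col, rng)
        for _ in range(n_iter):
            for name, df in (("lesions", les), ("patients", pat)):
                for col in plans[name]:
                    df.loc[cohort_mask(tables[name], col), col] = np.nan
                    _chained_pass(df, {col: plans[name][col]}, rng, k_donors)
        les_full = cohort.lesions.copy()
        pat_full = cohort.patients.copy()
        for col in plans["lesions"]:
            vals = les[col].to_numpy()
            les_full[col] = np.exp(vals) if col in LOG_SCALE_COLUMNS else vals
        for col in plans["patients"]:
            vals = pat[col].to_numpy()
            pat_full[col] = np.exp(vals) if col in LOG_SCALE_COLUMNS else vals
        # propagate the completed patient-level chemotherapy to lesions
        if les_full["chemo"].isna().any():
            cmap = pat_full.set_index("patient_id")["chemo"]
            fill = les_full["patient_id"].map(cmap)
            les_full["chemo"] = les_full["chemo"].astype(float).fillna(fill)
        # refresh derived per-patient maximum volume from completed lesions
        if "volume_ccm" in plans["lesions"]:
            mv = les_full.groupby("patient_id")["volume_ccm"].max()
            pat_full["max_volume_ccm"] = pat_full["patient_id"].map(mv).to_numpy()
        copies.append(Cohort(les_full, pat_full))
    return ImputationSet(copies, m, predictor_matrix, n_iter, seed)


def cohort_mask(table: pd.DataFrame, col: str) -> pd.Series:
    """Boolean mask of the originally missing cells of ``col``."""
    return table[col].isna()


def pool_estimates(points, variances):
    """Rubin's rules: pooled point = mean; pooled variance = within-mean +
    (1 + 1/m) * between-variance.

    ``points`` and ``variances`` are (m, p) arrays or DataFrames with one
    row per completed-data fit; DataFrames must share identical columns.
    Returns (pooled point, pooled SE) as Series when columns are named.
    """
    if isinstance(points, pd.DataFrame):
        cols = list(points.columns)
        if not isinstance(variances, pd.DataFrame) or list(variances.columns) != cols:
            raise ValueError("mismatched covariate sets across copies")
        P, V = points.to_numpy(dtype=float), variances.to_numpy(dtype=float)
    else:
        P, V = np.atleast_2d(np.asarray(points, dtype=float)), np.atleast_2d(np.asarray(variances, dtype=float))
        cols = None
        if P.shape != V.shape:
            raise ValueError("points and variances must have the same shape")
    m = P.shape[0]
    if m < 2:
        raise ValueError("pooling needs m >= 2 copies")
    point = P.mean(axis=0)
    within = V.mean(axis=0)
    between = P.var(axis=0, ddof=1)
    total = within + (1.0 + 1.0 / m) * between
    se = np.sqrt(total)
    if cols is not None:
        return pd.Series(point, index=cols), pd.Series(se, index=cols)
    return point, se


# ---------------------------------------------------------------------------
# Descriptive comparisons (Table-1 style)
# ---------------------------------------------------------------------------

def descriptive_compare(group_a, group_b, kind: str = "auto",
                        mc_samples: int = 20000, seed: int = 0) -> dict:
    """Compare a variable between two groups, Table-1 style.

    Categorical variables get Fisher's exact test on the 2 x k contingency
    table (exact for k = 2; Monte-Carlo exact test, seeded, for k > 2);
    continuous variables get the two-sided Wilcoxon rank-sum test.
    Returns a dict with the test name, p-value and per-group summaries.
    """
    a = pd.Series(group_a).dropna()
    b = pd.Series(group_b).dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "auto":
        vals = pd.concat([a, b])
        kind = "categorical" if vals.nunique() <= 6 and not np.issubdtype(vals.dtype, np.floating) else "continuous"
    if kind == "continuous":
        res = stats.mannwhitneyu(a.astype(float), b.astype(float),
                                 alternative="two-sided", method="auto")
        return {
            "test": "wilcoxon-rank-sum", "p_value": float(res.pvalue),
            "summary_a": {"median": float(np.median(a)), "min": float(np.min(a)), "max": float(np.max(a))},
            "summary_b": {"median": float(np.median(b)), "min": float(np.min(b)), "max": float(np.max(b))},
        }
    levels = sorted(pd.concat([a, b]).unique(), key=str)
    table = np.array([[int((a == lv).sum()) for lv in levels],
                      [int((b == lv).sum()) for lv in levels]])
    if table.shape[1] == 1:
        p = 1.0
        test = "fisher-exact"
    elif table.shape[1] == 2:
        p = float(stats.fisher_exact(table)[1])
        test = "fisher-exact"
    else:
        p = _fisher_mc(table, mc_samples, seed)
        test = "fisher-exact-mc"
    return {
        "test": test, "p_value": p, "levels": [str(lv) for lv in levels],
        "counts_a": table[0].tolist(), "counts_b": table[1].tolist(),
    }


def _fisher_mc(table: np.ndarray, mc_samples: int, seed: int) -> float:
    """Monte-Carlo Fisher test for 2 x k tables: sample tables with the
    observed margins and count those with probability <= the observed."""
    rng = np.random.default_rng(seed)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    obs = _log_table_prob(table, row, col)
    count = 0
    pool = np.repeat(np.arange(len(col)), col)
    for _ in range(mc_samples):
        rng.shuffle(pool)
        top = pool[: row[0]]
        t0 = np.bincount(top, minlength=len(col))
        t = np.vstack([t0, col - t0])
        if _log_table_prob(t, row, col) <= obs + 1e-12:
            count += 1
    return (count + 1) / (mc_samples + 1)


def _log_table_prob(t: np.ndarray, row: np.ndarray, col: np.ndarray) -> float:
    from scipy.special import gammaln
    n = row.sum()
    return float(gammaln(row + 1).sum() + gammaln(col + 1).sum()
                 - gammaln(n + 1) - gammaln(np.asarray(t, dtype=float) + 1).sum())
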