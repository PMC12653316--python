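"""Statistical analysis: group tests, correlations, covariate-adjusted OLS.

Implements the analysis plan applied to the lobar log-ratio records:
dichotomization of plasma OAb at the clinical cutoff, Shapiro-Wilk
normality diagnostics, independent two-sample t-tests with Cohen's d,
Pearson correlations, unadjusted and covariate-adjusted ordinary least
squares, education-stratified models, and Bonferroni correction.

Regression coefficients are reported on the raw scale (log-ratio per
ng/mL) with classical standard errors; a standardized variant
(beta * sd(x)/sd(y)) is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sct

from .montage import LOBES

INDICES = ("tar", "tbr")
_LOG_COLUMN = {"tar": "log_tar", "tbr": "log_tbr"}


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the statistical layer.

    ``bonferroni_family_size`` defaults to 5 lobes x 2 indices = 10
    comparisons within each condition; set 20 to pool conditions.
    Education strata are <=6, 7-12, >12 years; models inside strata
    adjust for ``stratified_covariates`` only (education is the
    stratification variable, not a covariate there).
    """

    cutoff: float = 0.78
    covariates: tuple[str, ...] = ("age", "education_years", "kmmse")
    alpha_level: float = 0.05
    bonferroni_family_size: int = 10
    education_bounds: tuple[float, float] = (6.0, 12.0)
    stratified_covariates: tuple[str, ...] = ("age", "kmmse")
    welch_t: bool = False
    log_base: float = 10.0

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must be in (0, 1)")
        lo, hi = self.education_bounds
        if not lo < hi:
            raise ValueError("education bounds must be increasing")


@dataclass
class GroupTestResult:
    lobe: str
    index: str
    condition: str
    mean_low: float
    sd_low: float
    mean_high: float
    sd_high: float
    n_low: int
    n_high: int
    t_statistic: float
    p_value: float
    cohen_d: float


@dataclass
class CorrelationResult:
    lobe: str
    index: str
    condition: str
    r: float
    p_value: float
    n: int


@dataclass
class RegressionResult:
    lobe: str
    index: str
    condition: str
    model: str                       # "unadjusted" | "adjusted"
    beta: float                      # log-ratio units per ng/mL
    se: float
    p_value: float
    beta_standardized: float
    covariate_estimates: dict[str, float] = field(default_factory=dict)
    n_used: int = 0
    stratum: str | None = None
    empty: bool = False


def dichotomize(oab: float, cutoff: float = 0.78) -> str:
    """'high' iff oab >= cutoff (boundary inclusive), else 'low'."""
    if oab <= 0:
        raise ValueError(f"oab must be positive, got {oab:g}")
    return "high" if oab >= cutoff else "low"


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p, used as a logged diagnostic (not a hard gate).

    Requires 3 <= n <= 5000 and a non-constant sample; a constant vector
    raises ValueError (W is undefined for zero variance).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs at least 3 values, got {x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk supports at most 5000 values")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sct.shapiro(x)
    return float(w), float(p)


def two_sample_t(low_values, high_values, welch: bool = False
                 ) -> tuple[float, float, float]:
    """Independent two-sample t-test plus Cohen's d.

    Returns (t, two-sided p, d).  Student's pooled-variance form by
    default; d uses the pooled SD with sign convention (low - high), so
    positive d means larger values in the low-OAb group.
    """
    a = np.asarray(low_values, dtype=float)
    b = np.asarray(high_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = sct.ttest_ind(a, b, equal_var=not welch)
    pooled = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                     / (a.size + b.size - 2))
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    return float(t), float(p), float(d)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p (from the t transform of r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for a constant vector")
    r, p = sct.pearsonr(x, y)
    return float(r), float(p)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name columns whose removal does not lower the design-matrix rank."""
    full_rank = np.linalg.matrix_rank(X.to_numpy())
    out = []
    for col in X.columns:
        if col == "const":
            continue
        if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == full_rank:
            out.append(col)
    return out


def fit_linear_model(y, oab, covariates: pd.DataFrame | None = None
                     ) -> RegressionResult:
    """OLS of a log-ratio on OAb, optionally adjusting for covariates.

    Complete-case: rows with any missing value are dropped and the
    remaining count reported as ``n_used``.  Raises on rank-deficient
    designs, naming the collinear columns.
    """
    df = pd.DataFrame({"y": np.asarray(y, dtype=float),
                       "oab": np.asarray(oab, dtype=float)})
    if covariates is not None:
        cov = covariates.reset_index(drop=True).astype(float)
        df = pd.concat([df.reset_index(drop=True), cov], axis=1)
    df = df.dropna()
    X = sm.add_constant(df.drop(columns=["y"]), has_constant="add")
    n_params = X.shape[1]
    if df.shape[0] <= n_params + 1:
        raise ValueError(
            f"need more than {n_params + 1} complete cases, got {df.shape[0]}")
    if np.linalg.matrix_rank(X.to_numpy()) < n_params:
        bad = _collinear_columns(X)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(df["y"], X).fit()
    sd_x = df["oab"].std(ddof=1)
    sd_y = df["y"].std(ddof=1)
    beta = float(fit.params["oab"])
    return RegressionResult(
        lobe="", index="", condition="",
        model="adjusted" if covariates is not None else "unadjusted",
        beta=beta,
        se=float(fit.bse["oab"]),
        p_value=float(fit.pvalues["oab"]),
        beta_standardized=beta * sd_x / sd_y if sd_y > 0 else np.nan,
        covariate_estimates={k: float(v) for k, v in fit.params.items()
                             if k not in ("const", "oab")},
        n_used=int(df.shape[0]),
    )


def education_stratum(years: float, bounds: tuple[float, float] = (6.0, 12.0)
                      ) -> str:
    """Assign '<=6', '7-12' or '>12' years of education."""
    lo, hi = bounds
    if years <= lo:
        return f"<={lo:g}"
    if years <= hi:
        return f"{lo + 1:g}-{hi:g}"
    return f">{hi:g}"


def stratified_models(y, oab, education_years, covariates: pd.DataFrame,
                      cfg: AnalysisConfig) -> list[RegressionResult]:
    """Adjusted models fitted inside education strata.

    Strata with too few subjects are reported with ``empty=True`` and
    ``n_used`` set to the stratum size -- never silently omitted.
    """
    df = pd.DataFrame({"y": np.asarray(y, dtype=float),
                       "oab": np.asarray(oab, dtype=float),
                       "education_years": np.asarray(education_years, dtype=float)})
    cov = covariates.reset_index(drop=True).astype(float)
    df = pd.concat([df.reset_index(drop=True), cov], axis=1)
    strata = [f"<={cfg.education_bounds[0]:g}",
              f"{cfg.education_bounds[0] + 1:g}-{cfg.education_bounds[1]:g}",
              f">{cfg.education_bounds[1]:g}"]
    labels = df["education_years"].map(
        lambda e: education_stratum(e, cfg.education_bounds))
    results = []
    for stratum in strata:
        sub = df[labels == stratum]
        min_n = cov.shape[1] + 3   # parameters (const + oab + covs) + 1
        if sub.shape[0] <= min_n:
            results.append(RegressionResult(
                lobe="", index="", condition="", model="adjusted",
                beta=np.nan, se=np.nan, p_value=np.nan,
                beta_standardized=np.nan, n_used=int(sub.shape[0]),
                stratum=stratum, empty=True,
            ))
            continue
        res = fit_linear_model(sub["y"], sub["oab"],
                               sub[list(cov.columns)])
        res.stratum = stratum
        results.append(res)
    return results


def bonferroni(p_values, family_size: int) -> np.ndarray:
    """p_adj = min(1, p * family_size), elementwise."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if family_size < p.size:
        raise ValueError(
            f"family_size {family_size} smaller than the number of "
            f"p-values ({p.size})")
    return np.minimum(1.0, p * family_size)


# ---------------------------------------------------------------------------
# Cohort-level tables


def _merged(ratio_df: pd.DataFrame, metadata: pd.DataFrame,
            cfg: AnalysisConfig) -> pd.DataFrame:
    meta = metadata.copy()
    meta["amyloid_group"] = meta["oab_ng_ml"].map(
        lambda v: dichotomize(v, cfg.cutoff))
    return ratio_df.merge(meta, on="subject_id", how="inner")


def group_comparison_table(ratio_df: pd.DataFrame, metadata: pd.DataFrame,
                           cfg: AnalysisConfig) -> pd.DataFrame:
    """Low/high-OAb group means, SDs, t, p and Cohen's d per index x lobe.

    Emitted per condition plus a 'pooled' variant where each subject
    contributes the mean of their available conditions.
    """
    df = _merged(ratio_df, metadata, cfg)
    conditions = sorted(df["condition"].unique())
    rows = []
    for index in INDICES:
        col = _LOG_COLUMN[index]
        for lobe in LOBES:
            sub_l = df[df["lobe"] == lobe]
            variants = [(c, sub_l[sub_l["condition"] == c]) for c in conditions]
            pooled = (sub_l.groupby(["subject_id", "amyloid_group"])[col]
                      .mean().reset_index())
            variants.append(("pooled", pooled))
            for cond, sub in variants:
                low = sub.loc[sub["amyloid_group"] == "low", col].to_numpy()
                high = sub.loc[sub["amyloid_group"] == "high", col].to_numpy()
                t, p, d = two_sample_t(low, high, welch=cfg.welch_t)
                rows.append({
                    "index": index.upper(), "lobe": lobe, "condition": cond,
                    "total_mean": float(np.concatenate([low, high]).mean()),
                    "total_sd": float(np.concatenate([low, high]).std(ddof=1)),
                    "mean_low": float(low.mean()), "sd_low": float(low.std(ddof=1)),
                    "mean_high": float(high.mean()), "sd_high": float(high.std(ddof=1)),
                    "n_low": low.size, "n_high": high.size,
                    "t": t, "p_value": p, "cohen_d": d,
                })
    return pd.DataFrame(rows)


def correlation_table(ratio_df: pd.DataFrame, metadata: pd.DataFrame,
                      cfg: AnalysisConfig) -> pd.DataFrame:
    """Pearson r between OAb and each log ratio per index x lobe x condition."""
    df = _merged(ratio_df, metadata, cfg)
    rows = []
    for cond in sorted(df["condition"].unique()):
        block = []
        for index in INDICES:
            col = _LOG_COLUMN[index]
            for lobe in LOBES:
                sub = df[(df["condition"] == cond) & (df["lobe"] == lobe)]
                r, p = pearson(sub["oab_ng_ml"], sub[col])
                block.append({
                    "index": index.upper(), "lobe": lobe, "condition": cond,
                    "r": r, "p_value": p, "n": int(sub.shape[0]),
                })
        ps = [row["p_value"] for row in block]
        adj = bonferroni(ps, max(cfg.bonferroni_family_size, len(ps)))
        for row, pa in zip(block, adj):
            row["p_bonferroni"] = float(pa)
        rows.extend(block)
    return pd.DataFrame(rows)


def regression_table(ratio_df: pd.DataFrame, metadata: pd.DataFrame,
                     cfg: AnalysisConfig) -> pd.DataFrame:
    """Unadjusted and adjusted OLS per index x lobe x condition.

    The Bonferroni family is the lobes-by-indices grid within each
    condition x model.
    """
    df = _merged(ratio_df, metadata, cfg)
    rows = []
    for cond in sorted(df["condition"].unique()):
        for model in ("unadjusted", "adjusted"):
            block = []
            for index in INDICES:
                col = _LOG_COLUMN[index]
                for lobe in LOBES:
                    sub = df[(df["condition"] == cond) & (df["lobe"] == lobe)]
                    cov = (sub[list(cfg.covariates)]
                           if model == "adjusted" else None)
                    res = fit_linear_model(sub[col], sub["oab_ng_ml"], cov)
                    block.append({
                        "index": index.upper(), "lobe": lobe,
                        "condition": cond, "model": model,
                        "beta": res.beta, "se": res.se,
                        "p_value": res.p_value,
                        "beta_standardized": res.beta_standardized,
                        "n_used": res.n_used,
                    })
            ps = [row["p_value"] for row in block]
            adj = bonferroni(ps, max(cfg.bonferroni_family_size, len(ps)))
            for row, pa in zip(block, adj):
                row["p_bonferroni"] = float(pa)
            rows.extend(block)
    return pd.DataFrame(rows)


def stratified_table(ratio_df: pd.DataFrame, metadata: pd.DataFrame,
                     cfg: AnalysisConfig) -> pd.DataFrame:
    """Education-stratified adjusted models per index x lobe x condition."""
    df = _merged(ratio_df, metadata, cfg)
    rows = []
    for cond in sorted(df["condition"].unique()):
        for index in INDICES:
            col = _LOG_COLUMN[index]
            for lobe in LOBES:
                sub = df[(df["condition"] == cond) & (df["lobe"] == lobe)]
                results = stratified_models(
                    sub[col], sub["oab_ng_ml"], sub["education_years"],
                    sub[list(cfg.stratified_covariates)], cfg)
                for res in results:
                    rows.append({
                        "index": index.upper(), "lobe": lobe,
                        "condition": cond, "stratum": res.stratum,
                        "beta": res.beta, "se": res.se,
                        "p_value": res.p_value,
                        "beta_standardized": res.beta_standardized,
                        "n_used": res.n_used, "empty": res.empty,
                    })
    return pd.DataFrame(rows)


def normality_table(ratio_df: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk diagnostics of the log ratios per index x lobe x condition."""
    rows = []
    for cond in sorted(ratio_df["condition"].unique()):
        for index in INDICES:
            col = _LOG_COLUMN[index]
            for lobe in LOBES:
                sub = ratio_df[(ratio_df["condition"] == cond)
                               & (ratio_df["lobe"] == lobe)]
                w, p = shapiro_wilk(sub[col])
                rows.append({"index": index.upper(), "lobe": lobe,
                             "condition": cond, "W": w, "p_value": p,
                             "n": int(sub.shape[0])})
    return pd.DataFrame(rows)


def analyze_cohort(ratio_df: pd.DataFrame, metadata: pd.DataFrame,
                   cfg: AnalysisConfig | None = None) -> dict[str, pd.DataFrame]:
    """All report tables for one cohort of ratio records."""
    cfg = cfg or AnalysisConfig()
    cfg.validate()
    return {
        "group_comparison": group_comparison_table(ratio_df, metadata, cfg),
        "correlations": correlation_table(ratio_df, metadata, cfg),
        "regressions": regression_table(ratio_df, metadata, cfg),
        "stratified": stratified_table(ratio_df, metadata, cfg),
        "normality": normality_table(ratio_df),
    }
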