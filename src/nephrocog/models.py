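"""Nested cross-sectional, longitudinal, ordinal and trend analyses.

The adjustment scheme is strictly nested:

* Model 1 (M1): age, sex, education, depression (+ baseline cognitive score
  for the longitudinal model)
* Model 2 (M2): M1 + smoking, obesity, systolic/diastolic BP, number of CVD
  risk factors, diabetes, total cholesterol, HDL, CRP
* Model 3 (M3): M2 + Inflammation BS and Cardiovascular BS

Continuous variables are standardised to z-scores before fitting, so the
exposure coefficient is a standardised beta. Analyses are complete-case
within each tier. Pulse wave velocity is excluded from the default covariate
sets (its missingness is informative) but can be forced in.

Ordinary least squares, the random-intercept mixed model and the
proportional-odds (ordered logistic) model are fitted with statsmodels; the
Jonckheere-Terpstra trend test is implemented here, with an exact
permutation p-value for small samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "ModelSpec",
    "FitResult",
    "TIER_COVARIATES",
    "covariates_for_tier",
    "fit_nested_cross_sectional",
    "fit_longitudinal_decline",
    "vif",
    "jonckheere_terpstra",
    "JTResult",
    "wmh_to_ordinal",
    "fit_ordinal_wmh",
    "normalize_volumes",
    "bonferroni_threshold",
    "cbf_quartile_contrast",
]

_M1 = ["age", "female", "education", "depression"]
_M2_EXTRA = [
    "smoking",
    "obesity",
    "sbp",
    "dbp",
    "n_cvd_risk_factors",
    "diabetes",
    "total_chol",
    "hdl",
    "crp",
]
_M3_EXTRA = ["inflammation_bs", "cardiovascular_bs"]

TIER_COVARIATES = {
    "univariable": [],
    "M1": _M1,
    "M2": _M1 + _M2_EXTRA,
    "M3": _M1 + _M2_EXTRA + _M3_EXTRA,
}

#: columns treated as binary/ordinal codes, never z-scored
BINARY_COLUMNS = {
    "female",
    "smoking",
    "obesity",
    "diabetes",
    "hypertension",
    "cvd_condition",
    "mri_subset",
    "ckd_flag",
}


def covariates_for_tier(
    tier: str, *, longitudinal: bool = False, include_pwv: bool = False
) -> list[str]:
    """Covariate set for a nested adjustment tier.

    ``longitudinal`` adds the baseline cognitive score to M1+ tiers;
    ``include_pwv`` forces pulse wave velocity into M2+ tiers.
    """
    if tier not in TIER_COVARIATES:
        raise ValueError(f"unknown tier {tier!r}; expected {sorted(TIER_COVARIATES)}")
    cov = list(TIER_COVARIATES[tier])
    if longitudinal and tier != "univariable":
        cov.append("baseline_cognition")
    if include_pwv and tier in ("M2", "M3"):
        cov.append("pwv")
    return cov


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, kidney exposure, adjustment tier, sample filter."""

    outcome: str
    exposure: str
    tier: str = "univariable"
    sample_filter: str = "all"  # all | no_ckd | no_cvd | mri_subset
    include_pwv: bool = False
    extra_covariates: tuple[str, ...] = ()

    def covariates(self, *, longitudinal: bool = False) -> list[str]:
        cov = covariates_for_tier(
            self.tier, longitudinal=longitudinal, include_pwv=self.include_pwv
        )
        return cov + [c for c in self.extra_covariates if c not in cov]


@dataclass
class FitResult:
    """Standardised exposure coefficient with its uncertainty and diagnostics."""

    beta_std: float
    se: float
    p_value: float
    n_used: int
    model_kind: str
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    vif_max: float = float("nan")
    odds_ratio: float = float("nan")
    term: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be positive")


def apply_sample_filter(table: pd.DataFrame, sample_filter: str) -> pd.DataFrame:
    if sample_filter == "all":
        return table
    if sample_filter == "no_ckd":
        return table[table["egfr_epi_crecys"] >= 60.0]
    if sample_filter == "no_cvd":
        return table[table["cvd_condition"] == 0]
    if sample_filter == "mri_subset":
        return table[table["mri_subset"] == 1]
    raise ValueError(f"unknown sample filter {sample_filter!r}")


def _encode(table: pd.DataFrame) -> pd.DataFrame:
    """Map sex to a female indicator; leave everything else untouched."""
    out = table.copy()
    if "female" not in out.columns and "sex" in out.columns:
        out["female"] = (out["sex"].astype(str).str.lower() == "female").astype(float)
    return out


def _zscore_design(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Z-score the continuous columns of a complete-case design in place."""
    out = df.copy()
    for c in columns:
        if c in BINARY_COLUMNS:
            continue
        col = out[c].astype(float)
        if col.nunique() <= 2:
            continue
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero-variance design column: {c}")
        out[c] = (col - col.mean()) / sd
    return out


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError(
            "rank-deficient design: collinear or duplicated covariates "
            f"among {list(X.columns)}"
        )


def fit_nested_cross_sectional(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """OLS of a cognitive outcome on a kidney exposure, nested adjustment.

    Uses wave-1 rows (if a ``wave`` column exists), the spec's sample filter
    and complete cases for outcome + exposure + tier covariates. All
    continuous variables are z-scored, so ``beta_std`` is the standardised
    exposure coefficient.
    """
    df = _encode(table)
    if "wave" in df.columns:
        df = df[df["wave"] == 1]
    df = apply_sample_filter(df, spec.sample_filter)
    cov = spec.covariates()
    if spec.exposure in cov or spec.outcome in cov:
        raise ValueError("exposure/outcome may not appear among covariates")
    cols = [spec.outcome, spec.exposure] + cov
    cc = df[cols].dropna()
    if len(cc) < len(cols) + 10:
        raise ValueError(f"too few complete cases: {len(cc)}")
    cc = _zscore_design(cc, cols)
    X = cc[[spec.exposure] + cov]
    _check_rank(X)
    fit = sm.OLS(cc[spec.outcome], sm.add_constant(X)).fit()
    ci = fit.conf_int().loc[spec.exposure]
    vmax = max(vif(X).values()) if len(X.columns) >= 2 else float("nan")
    return FitResult(
        beta_std=float(fit.params[spec.exposure]),
        se=float(fit.bse[spec.exposure]),
        p_value=float(fit.pvalues[spec.exposure]),
        n_used=int(fit.nobs),
        model_kind="ols",
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        vif_max=float(vmax),
        term=spec.exposure,
    )


def fit_longitudinal_decline(
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    outcome: str = "global_cog",
    method: str = "mixed",
) -> FitResult:
    """Association of a kidney exposure with wave-1 -> wave-3 cognitive change.

    ``method='mixed'`` fits a random-intercept model on the repeated
    z-scored outcome with a wave indicator and an exposure x wave term; the
    interaction coefficient is the decline association. ``method='ancova'``
    regresses the wave-3 outcome on the exposure adjusting for the wave-1
    baseline instead.
    """
    df = _encode(table)
    df = apply_sample_filter(df, spec.sample_filter)
    cov = [c for c in spec.covariates(longitudinal=True) if c != "baseline_cognition"]
    w1 = df[df["wave"] == 1].set_index("pid")
    w3 = df[df["wave"] == 3].set_index("pid")
    both = w1.index.intersection(w3.index)
    if len(both) < 30:
        raise ValueError("need >= 30 participants observed at both waves")

    if method == "ancova":
        frame = w3.loc[both, [outcome]].rename(columns={outcome: "y3"})
        frame[["y1", spec.exposure] + cov] = w1.loc[both, [outcome, spec.exposure] + cov]
        cc = frame.dropna()
        cc = _zscore_design(cc, list(cc.columns))
        X = cc[[spec.exposure, "y1"] + cov]
        _check_rank(X)
        fit = sm.OLS(cc["y3"], sm.add_constant(X)).fit()
        ci = fit.conf_int().loc[spec.exposure]
        return FitResult(
            beta_std=float(fit.params[spec.exposure]),
            se=float(fit.bse[spec.exposure]),
            p_value=float(fit.pvalues[spec.exposure]),
            n_used=int(fit.nobs),
            model_kind="ancova",
            ci_low=float(ci[0]),
            ci_high=float(ci[1]),
            term=spec.exposure,
        )

    if method != "mixed":
        raise ValueError(f"unknown method {method!r}")

    long = df[df["pid"].isin(both)][["pid", "wave", outcome, spec.exposure] + cov].dropna()
    long = _zscore_design(long, [outcome, spec.exposure] + cov)
    long["wave3"] = (long["wave"] == 3).astype(float)
    long["exp_x_wave"] = long[spec.exposure] * long["wave3"]
    fixed = [spec.exposure, "wave3", "exp_x_wave"] + cov
    _check_rank(long[fixed])
    model = sm.MixedLM(
        long[outcome], sm.add_constant(long[fixed]), groups=long["pid"]
    )
    fit = model.fit(reml=True, method="lbfgs")
    term = "exp_x_wave"
    se = float(fit.bse[term])
    z = float(fit.params[term]) / se
    return FitResult(
        beta_std=float(fit.params[term]),
        se=se,
        p_value=float(2 * st.norm.sf(abs(z))),
        n_used=int(long["pid"].nunique()),
        model_kind="mixed",
        ci_low=float(fit.params[term] - 1.959963984540054 * se),
        ci_high=float(fit.params[term] + 1.959963984540054 * se),
        term="exposure x wave",
    )


def vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    Each covariate is regressed (with intercept) on all the others. Perfect
    collinearity yields ``inf``.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 covariates")
    X = design.to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, name in enumerate(cols):
        y = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


@dataclass(frozen=True)
class JTResult:
    statistic: float
    p_value: float
    expected: float
    variance: float
    method: str  # 'exact' or 'normal'


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for gi, gj in itertools.combinations(groups, 2):
        a = gi[:, None]
        b = gj[None, :]
        jt += np.sum(a < b) + 0.5 * np.sum(a == b)
    return float(jt)


def _jt_exact_p(groups: list[np.ndarray], observed: float, alternative: str) -> float:
    """Exhaustive permutation p by reallocating the pooled values to groups."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    idx = list(range(n))
    count = 0
    total = 0

    def assignments(remaining: list[int], k: int):
        if k == len(sizes) - 1:
            yield [remaining]
            return
        for combo in itertools.combinations(remaining, sizes[k]):
            rest = [i for i in remaining if i not in combo]
            for tail in assignments(rest, k + 1):
                yield [list(combo)] + tail

    for parts in assignments(idx, 0):
        stat = _jt_statistic([pooled[p] for p in parts])
        total += 1
        if alternative == "increasing":
            count += stat >= observed - 1e-12
        else:
            count += stat <= observed + 1e-12
    return count / total


def jonckheere_terpstra(
    groups, alternative: str = "increasing", *, exact_max_n: int = 9
) -> JTResult:
    """Jonckheere-Terpstra trend test across ordered groups.

    The statistic is the sum over ordered group pairs of Mann-Whitney
    counts, ties counting one half. The p-value is one-sided for the given
    ordered alternative; it is exact (exhaustive permutation) when the
    pooled sample size is at most ``exact_max_n``, otherwise a
    tie-corrected normal approximation.
    """
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 ordered groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("all groups must be non-empty")

    jt = _jt_statistic(gs)
    sizes = np.array([len(g) for g in gs], dtype=float)
    n = sizes.sum()
    expected = (n**2 - np.sum(sizes**2)) / 4.0

    pooled = np.concatenate(gs)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    term1 = (
        n * (n - 1) * (2 * n + 5)
        - np.sum(sizes * (sizes - 1) * (2 * sizes + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    term2 = (
        np.sum(sizes * (sizes - 1) * (sizes - 2))
        * np.sum(t * (t - 1) * (t - 2))
        / (36.0 * n * (n - 1) * (n - 2))
    )
    term3 = np.sum(sizes * (sizes - 1)) * np.sum(t * (t - 1)) / (8.0 * n * (n - 1))
    variance = term1 + term2 + term3

    if n <= exact_max_n:
        p = _jt_exact_p(gs, jt, alternative)
        return JTResult(jt, float(p), float(expected), float(variance), "exact")

    if variance <= 0:
        return JTResult(jt, 1.0, float(expected), float(variance), "normal")
    z = (jt - expected) / math.sqrt(variance)
    p = st.norm.sf(z) if alternative == "increasing" else st.norm.cdf(z)
    return JTResult(jt, float(p), float(expected), float(variance), "normal")


def wmh_to_ordinal(scheltens):
    """Bin a Scheltens white-matter-hyperintensity score into 4 ordered classes.

    0-9 -> 1, 10-19 -> 2, 20-29 -> 3, >=30 -> 4. Missing stays missing.
    """
    s = np.asarray(scheltens, dtype=float)
    if np.any(s[~np.isnan(s)] < 0):
        raise ValueError("Scheltens score must be non-negative")
    cat = np.select([s <= 9, s <= 19, s <= 29], [1.0, 2.0, 3.0], default=4.0)
    cat = np.where(np.isnan(s), np.nan, cat)
    if cat.shape == ():
        return float(cat) if np.isnan(cat) else int(cat)
    return cat


def fit_ordinal_wmh(
    table: pd.DataFrame, spec: ModelSpec, *, collapse_sparse: bool = True
) -> FitResult:
    """Proportional-odds (ordered logistic) model of the WMH ordinal class.

    Returns the exposure effect on the odds-ratio scale with a 95% CI. If
    fewer than 4 outcome classes are observed the model simply uses the
    observed ones (``collapse_sparse``); a constant outcome is an error.
    """
    df = _encode(table)
    if "wave" in df.columns:
        df = df[df["wave"] == 3]
    df = apply_sample_filter(df, spec.sample_filter)
    df = df.copy()
    df["_wmh_cat"] = wmh_to_ordinal(df[spec.outcome])
    cov = spec.covariates()
    cols = ["_wmh_cat", spec.exposure] + cov
    cc = df[cols].dropna()
    observed = np.sort(cc["_wmh_cat"].unique())
    if len(observed) < 2:
        raise ValueError("outcome is constant: ordered logistic model undefined")
    if len(observed) < 4 and not collapse_sparse:
        raise ValueError("fewer than 4 WMH categories observed")
    cc = _zscore_design(cc, [spec.exposure] + cov)
    endog = pd.Categorical(cc["_wmh_cat"], categories=observed, ordered=True)
    X = cc[[spec.exposure] + cov]
    _check_rank(X)
    model = OrderedModel(endog, X, distr="logit")
    fit = model.fit(method="bfgs", disp=False)
    beta = float(fit.params[spec.exposure])
    se = float(fit.bse[spec.exposure])
    z = beta / se
    return FitResult(
        beta_std=beta,
        se=se,
        p_value=float(2 * st.norm.sf(abs(z))),
        n_used=len(cc),
        model_kind="ordinal",
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        odds_ratio=float(np.exp(beta)),
        term=spec.exposure,
    )


def normalize_volumes(
    table: pd.DataFrame, regions, icv_col: str = "icv"
) -> pd.DataFrame:
    """Head-size-normalised, z-scored bilateral grey-matter volumes.

    For each region ``r`` with ``{r}_left`` / ``{r}_right`` columns the
    bilateral sum is divided by estimated intracranial volume and z-scored
    across the rows with data. Returns a frame of ``{r}_norm`` columns.
    """
    icv = table[icv_col].astype(float)
    if np.any(icv.dropna() <= 0):
        raise ValueError("intracranial volume must be positive")
    out = {}
    for r in regions:
        bilateral = table[f"{r}_left"].astype(float) + table[f"{r}_right"].astype(float)
        ratio = bilateral / icv
        sd = ratio.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"degenerate volume column for region {r}")
        out[f"{r}_norm"] = (ratio - ratio.mean()) / sd
    return pd.DataFrame(out, index=table.index)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold controlling the family-wise error rate."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def cbf_quartile_contrast(
    table: pd.DataFrame, tier: str = "univariable", *, invert: bool = False
) -> FitResult:
    """Grey-matter CBF contrast for the top cystatin C quartile, MRI subset.

    Regresses z-scored CBF on an indicator of the highest wave-1 cystatin
    quartile, optionally with nested-tier adjustment. ``invert`` flips the
    indicator (contrast for quartiles 1-3), for sign checks.
    """
    df = _encode(table)
    df = df[df["mri_subset"] == 1] if "mri_subset" in df.columns else df
    if "wave" in df.columns:
        df = df[df["wave"] == 3]
    df = df.copy()
    quart = df["cystatin_quartile"].astype(float)
    if quart.dropna().nunique() < 2:
        raise ValueError("CBF contrast needs more than one cystatin quartile")
    df["top_quartile"] = (quart == 4).astype(float)
    if invert:
        df["top_quartile"] = 1.0 - df["top_quartile"]
    cov = covariates_for_tier(tier)
    cols = ["cbf_gm", "top_quartile"] + cov
    cc = df[cols].dropna()
    cc = _zscore_design(cc, ["cbf_gm"] + cov)
    X = cc[["top_quartile"] + cov]
    _check_rank(X)
    fit = sm.OLS(cc["cbf_gm"], sm.add_constant(X)).fit()
    ci = fit.conf_int().loc["top_quartile"]
    return FitResult(
        beta_std=float(fit.params["top_quartile"]),
        se=float(fit.bse["top_quartile"]),
        p_value=float(fit.pvalues["top_quartile"]),
        n_used=int(fit.nobs),
        model_kind="ols",
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        term="top cystatin quartile",
    )
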