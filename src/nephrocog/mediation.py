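"""Regression-based causal mediation: natural direct and indirect effects.

For exposure A (ln-cystatin C), mediator M, outcome Y and confounders C the
decomposition rests on two linear regressions fitted by least squares on the
identical complete-case sample:

    E[M | A=a, C=c] = beta0 + beta1*a + beta2'c
    E[Y | A=a, M=m, C=c] = theta0 + theta1*a + theta2*m + theta4'c

Without an exposure-mediator interaction the natural direct effect of the
contrast (a - a*) is NDE = theta1*(a - a*), the natural indirect effect is
NIE = theta2*beta1*(a - a*), and the total effect TE = NDE + NIE equals, as
an algebraic identity, (a - a*) times the exposure coefficient of the
reduced regression Y ~ A + C on the same rows (product method == difference
method). The proportion mediated is 100 * NIE / TE.

Uncertainty comes from a seeded paired nonparametric bootstrap: rows are
resampled with replacement and both regressions refitted per replicate;
intervals are percentile-based and p-values use the bootstrap-SE normal
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .models import TIER_COVARIATES, _encode

__all__ = [
    "MediationModelSpec",
    "MediationCoefficients",
    "MediationResult",
    "fit_mediation",
    "percent_coefficient_reduction",
    "mediator_screen",
    "decompose_effects",
    "proportion_mediated",
]

#: |TE| below this leaves the proportion mediated undefined
TE_TOLERANCE = 1e-8


def decompose_effects(theta1: float, theta2: float, beta1: float, contrast: float = 1.0):
    """(NDE, NIE, TE) for an exposure contrast under the linear decomposition."""
    nde = theta1 * contrast
    nie = theta2 * beta1 * contrast
    return nde, nie, nde + nie


def proportion_mediated(nie: float, te: float) -> float:
    """NIE / TE as a percentage; NaN when the total effect is ~0.

    The raw signed value is returned (it can exceed 100% when NDE and NIE
    have opposite signs); truncation to [0, 100] is a display concern.
    """
    if abs(te) < TE_TOLERANCE:
        return float("nan")
    return 100.0 * nie / te


def percent_coefficient_reduction(beta_unadjusted: float, beta_adjusted: float) -> float:
    """Difference-method mediation summary: relative shrinkage of the
    exposure coefficient after entering the mediator, in percent."""
    if beta_unadjusted == 0:
        raise ValueError("percent reduction undefined for a zero unadjusted coefficient")
    return 100.0 * (beta_unadjusted - beta_adjusted) / beta_unadjusted


@dataclass(frozen=True)
class MediationModelSpec:
    """One mediation analysis: exposure, mediator, outcome, confounder tier."""

    mediator: str
    outcome: str = "global_cog"
    exposure: str = "ln_cystatin_c"
    confounders: tuple[str, ...] = ()
    tier: str | None = None          # if set, confounders come from the tier
    contrast: float = 1.0            # a - a*
    n_bootstrap: int = 1000
    seed: int = 0
    baseline_column: str | None = None  # e.g. wave-1 score for decline outcomes

    def resolved_confounders(self) -> list[str]:
        if self.tier is not None:
            cov = list(TIER_COVARIATES[self.tier])
        else:
            cov = list(self.confounders)
        # the mediator (and 'age' when age itself mediates) never confounds itself
        cov = [c for c in cov if c not in (self.mediator, self.exposure)]
        if self.mediator == "age" and "age" in cov:
            cov.remove("age")
        if self.baseline_column and self.baseline_column not in cov:
            cov.append(self.baseline_column)
        return cov

    def __post_init__(self) -> None:
        bad = {self.mediator, self.exposure} & set(self.confounders)
        if self.tier is None and bad:
            raise ValueError(f"mediator/exposure listed among confounders: {sorted(bad)}")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")


@dataclass(frozen=True)
class MediationCoefficients:
    beta0: float
    beta1: float
    beta2: tuple[float, ...]
    theta0: float
    theta1: float
    theta2: float
    theta4: tuple[float, ...]
    te_coefficient: float  # exposure coefficient of the reduced model Y ~ A + C


@dataclass
class MediationResult:
    """Decomposed effects per configured exposure contrast, with uncertainty."""

    nde: float
    nie: float
    te: float
    proportion_mediated: float
    pct_coefficient_reduction: float
    ci: dict = field(default_factory=dict)       # effect -> (low, high)
    p_value: dict = field(default_factory=dict)  # effect -> p
    se: dict = field(default_factory=dict)
    coefficients: MediationCoefficients | None = None
    n_used: int = 0
    n_bootstrap: int = 0
    seed: int = 0
    mediator: str = ""
    outcome: str = ""
    tier: str | None = None


def _ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    # normal equations via Cholesky-backed solve; designs here are tiny
    return np.linalg.solve(X.T @ X, X.T @ y)


def _batched_ols(X: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """OLS coefficients for every bootstrap replicate at once.

    X: (n, p) design, y: (n,) outcome, idx: (B, n) resample indices.
    Returns (B, p) coefficients.
    """
    Xb = X[idx]                       # (B, n, p)
    yb = y[idx]                       # (B, n)
    xtx = np.einsum("bni,bnj->bij", Xb, Xb)
    xty = np.einsum("bni,bn->bi", Xb, yb)
    return np.linalg.solve(xtx, xty[..., None])[..., 0]


def fit_mediation(table: pd.DataFrame, spec: MediationModelSpec) -> MediationResult:
    """Fit the two mediation regressions and decompose the exposure effect.

    Both regressions (and the reduced total-effect regression) are fitted on
    the identical complete-case sample, so TE = NDE + NIE holds to machine
    precision and the product and difference methods coincide exactly.
    """
    df = _encode(table)
    if "wave" in df.columns:
        # one row per participant: wave-1 rows carry the cross-sectional
        # outcomes and any pre-computed wave-difference columns
        w1 = df[df["wave"] == 1]
        df = w1 if w1[spec.outcome].notna().any() else df[df["wave"] == 3]
    conf = spec.resolved_confounders()
    cols = [spec.outcome, spec.exposure, spec.mediator] + conf
    cc = df[cols].dropna()
    n = len(cc)
    if n < len(cols) + 10:
        raise ValueError(f"too few complete cases for mediation: {n}")

    a = cc[spec.exposure].to_numpy(dtype=float)
    m = cc[spec.mediator].to_numpy(dtype=float)
    y = cc[spec.outcome].to_numpy(dtype=float)
    C = cc[conf].to_numpy(dtype=float) if conf else np.empty((n, 0))
    ones = np.ones((n, 1))

    X_m = np.column_stack([ones, a[:, None], C])          # M ~ A + C
    X_y = np.column_stack([ones, a[:, None], m[:, None], C])  # Y ~ A + M + C
    X_r = X_m                                              # Y ~ A + C
    for name, X in (("mediator", X_m), ("outcome", X_y)):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient {name}-model design")

    b = _ols_beta(X_m, m)
    t = _ols_beta(X_y, y)
    r = _ols_beta(X_r, y)
    beta1, theta1, theta2 = b[1], t[1], t[2]
    nde, nie, te = decompose_effects(theta1, theta2, beta1, spec.contrast)
    pm = proportion_mediated(nie, te)
    pct_red = (
        percent_coefficient_reduction(r[1], theta1) if r[1] != 0 else float("nan")
    )
    coefs = MediationCoefficients(
        beta0=float(b[0]),
        beta1=float(beta1),
        beta2=tuple(float(v) for v in b[2:]),
        theta0=float(t[0]),
        theta1=float(theta1),
        theta2=float(theta2),
        theta4=tuple(float(v) for v in t[3:]),
        te_coefficient=float(r[1]),
    )

    result = MediationResult(
        nde=float(nde),
        nie=float(nie),
        te=float(te),
        proportion_mediated=float(pm),
        pct_coefficient_reduction=float(pct_red),
        coefficients=coefs,
        n_used=n,
        n_bootstrap=spec.n_bootstrap,
        seed=spec.seed,
        mediator=spec.mediator,
        outcome=spec.outcome,
        tier=spec.tier,
    )
    if spec.n_bootstrap == 0:
        return result

    rng = np.random.default_rng(spec.seed)
    B = spec.n_bootstrap
    # chunked so the (B, n, p) gather stays modest in memory
    chunk = max(1, int(2.5e7 // (n * X_y.shape[1])))
    draws = {"nde": [], "nie": [], "pct_red": []}
    done = 0
    while done < B:
        k = min(chunk, B - done)
        idx = rng.integers(0, n, size=(k, n))
        bb = _batched_ols(X_m, m, idx)
        tb = _batched_ols(X_y, y, idx)
        rb = _batched_ols(X_r, y, idx)
        draws["nde"].append(tb[:, 1] * spec.contrast)
        draws["nie"].append(tb[:, 2] * bb[:, 1] * spec.contrast)
        with np.errstate(divide="ignore", invalid="ignore"):
            draws["pct_red"].append(100.0 * (rb[:, 1] - tb[:, 1]) / rb[:, 1])
        done += k
    nde_s = np.concatenate(draws["nde"])
    nie_s = np.concatenate(draws["nie"])
    te_s = nde_s + nie_s
    with np.errstate(divide="ignore", invalid="ignore"):
        pm_s = np.where(np.abs(te_s) < TE_TOLERANCE, np.nan, 100.0 * nie_s / te_s)
    pct_s = np.concatenate(draws["pct_red"])

    samples = {"nde": nde_s, "nie": nie_s, "te": te_s, "pm": pm_s, "pct_red": pct_s}
    estimates = {"nde": nde, "nie": nie, "te": te, "pm": pm, "pct_red": pct_red}
    for name, s in samples.items():
        s = s[np.isfinite(s)]
        if len(s) == 0:
            continue
        lo, hi = np.percentile(s, [2.5, 97.5])
        sd = float(np.std(s, ddof=1))
        result.ci[name] = (float(lo), float(hi))
        result.se[name] = sd
        est = estimates[name]
        if sd > 0 and np.isfinite(est):
            result.p_value[name] = float(2 * st.norm.sf(abs(est) / sd))
    return result


def mediator_screen(
    table: pd.DataFrame,
    outcomes,
    mediators,
    tiers=("univariable", "M1", "M2"),
    *,
    exposure: str = "ln_cystatin_c",
    contrast: float = 1.0,
    n_bootstrap: int = 1000,
    seed: int = 0,
    baseline_columns: dict | None = None,
) -> pd.DataFrame:
    """One mediation fit per (outcome, mediator, tier) combination.

    Age is dropped from the confounder set whenever age itself is the
    mediator. ``baseline_columns`` maps decline outcomes to their wave-1
    baseline column, which is then added to the adjustment set. Returns a
    tidy frame, one row per fit.
    """
    baseline_columns = baseline_columns or {}
    rows = []
    for outcome in outcomes:
        for mediator in mediators:
            for tier in tiers:
                spec = MediationModelSpec(
                    mediator=mediator,
                    outcome=outcome,
                    exposure=exposure,
                    tier=tier,
                    contrast=contrast,
                    n_bootstrap=n_bootstrap,
                    seed=seed,
                    baseline_column=baseline_columns.get(outcome),
                )
                res = fit_mediation(table, spec)
                ci_nie = res.ci.get("nie", (float("nan"), float("nan")))
                ci_pct = res.ci.get("pct_red", (float("nan"), float("nan")))
                rows.append(
                    {
                        "outcome": outcome,
                        "mediator": mediator,
                        "tier": tier,
                        "nde": res.nde,
                        "nie": res.nie,
                        "te": res.te,
                        "proportion_mediated_pct": res.proportion_mediated,
                        "nie_ci_low": ci_nie[0],
                        "nie_ci_high": ci_nie[1],
                        "nie_p": res.p_value.get("nie", float("nan")),
                        "pct_coef_reduction": res.pct_coefficient_reduction,
                        "pct_red_ci_low": ci_pct[0],
                        "pct_red_ci_high": ci_pct[1],
                        "n_used": res.n_used,
                    }
                )
    return pd.DataFrame(rows)
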