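"""Synthetic cohort generator with known structural ground truth.

Emulates a population cohort of community-dwelling adults aged 50+ with
repeated cognitive assessment (waves 1 and 3), serum kidney markers, plasma
biomarkers, vascular risk factors and an MRI sub-sample. The generating
model is linear-Gaussian along the exposure -> mediator -> outcome chain:

    A  = ln cystatin C, Gaussian given age (age confounds A, M and Y)
    M  = beta0 + beta1*A + b'C + eps_M          (latent cardiovascular burden)
    Y1 = theta0 + theta1*A + theta2*M + t'C + eps_Y   (wave-1 global cognition)
    Y3 = Y1 + d0 + d1*A + d2*M + eps_D                (wave-3 cognition)

so the natural direct and indirect effects of the exposure contrast
(a - a*) are theta1*(a-a*) and theta2*beta1*(a-a*) by construction, and the
generator can report them as ground truth for parameter-recovery tests.

Observable columns (biomarker concentrations, cognitive test scores, MRI
indices) are noisy monotone transforms of the latent variables, so every
downstream stage sees realistic inputs while the latent columns
(``cv_latent``, ``cognition_latent_w1``/``_w3``) carry exact truth.

Randomness uses one global seed with a named substream per variable block;
adding a new column never perturbs existing columns.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kidney import add_egfr_panel

__all__ = [
    "GeneratorConfig",
    "SimulationTruth",
    "generate_cohort",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
]


def _default_confounder_effects() -> dict:
    # age (per decade above 62, 'age_z') raises cardiovascular burden and
    # lowers cognition; sex has a small cognitive effect only
    return {
        "m": {"age_z": 0.30},
        "y": {"age_z": -0.30, "female": 0.05},
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort's structural model.

    The path coefficients (`path_beta1`, `path_theta1`, `path_theta2`) are
    the *generating* values of the mediator and outcome equations; the
    exposure contrast for the truth object is ``contrast`` units of
    ln-cystatin C (default 1).
    """

    n_participants: int = 4000
    seed: int = 0
    age_range: tuple[float, float] = (50.0, 85.0)
    exposure_sd: float = 0.18          # SD of ln-cystatin C given age
    path_beta1: float = 0.5            # mediator-model exposure coefficient
    path_theta1: float = -0.3          # outcome-model direct coefficient
    path_theta2: float = -0.4          # outcome-model mediator coefficient
    confounder_effects: dict = field(default_factory=_default_confounder_effects)
    noise_sd_m: float = 1.0
    noise_sd_y: float = 1.0
    mri_fraction: float = 0.15
    pwv_missing_rate: float = 0.12
    decline_slope: float = -0.15       # wave1->wave3 change per unit exposure
    decline_mediator_slope: float = -0.10
    decline_intercept: float = -0.10
    decline_noise_sd: float = 0.30
    contrast: float = 1.0              # a - a* for the truth object

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for name in ("exposure_sd", "noise_sd_m", "noise_sd_y", "decline_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.mri_fraction <= 1.0:
            raise ValueError("mri_fraction must be in [0, 1]")
        if not 0.0 <= self.pwv_missing_rate < 1.0:
            raise ValueError("pwv_missing_rate must be in [0, 1)")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be (low, high) with low < high")

    def truth(self) -> "SimulationTruth":
        d = self.contrast
        nde = self.path_theta1 * d
        nie = self.path_theta2 * self.path_beta1 * d
        te = nde + nie
        return SimulationTruth(
            nde_true=nde,
            nie_true=nie,
            te_true=te,
            pm_true=nie / te if te != 0 else float("nan"),
            decline_nde_true=self.decline_slope * d,
            decline_nie_true=self.decline_mediator_slope * self.path_beta1 * d,
        )


@dataclass(frozen=True)
class SimulationTruth:
    """Generating effect decomposition for the configured exposure contrast."""

    nde_true: float
    nie_true: float
    te_true: float
    pm_true: float
    decline_nde_true: float = float("nan")
    decline_nie_true: float = float("nan")


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent generator per variable block."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _confounder_term(effects: dict, frame: dict, n: int) -> np.ndarray:
    out = np.zeros(n)
    for name, coef in effects.items():
        if name not in frame:
            raise KeyError(f"unknown confounder in confounder_effects: {name}")
        out = out + coef * np.asarray(frame[name], dtype=float)
    return out


def _cognitive_tests(y: np.ndarray, seed: int, wave: int) -> dict:
    """Observable test battery given the latent global cognition y (z-scale)."""
    n = y.shape[0]
    r = _rng(seed, f"tests_w{wave}")
    mem = 0.8 * y + r.normal(0, 0.6, n)
    exe = 0.8 * y + r.normal(0, 0.6, n)
    return {
        "moca": np.clip(np.round(26.5 + 2.2 * y + r.normal(0, 1.2, n)), 0, 30),
        "mmse": np.clip(np.round(28.3 + 1.5 * y + r.normal(0, 1.0, n)), 0, 30),
        "recall_immediate": np.clip(np.round(12.0 + 2.5 * mem + r.normal(0, 1.5, n)), 0, 20),
        "recall_delayed": np.clip(np.round(6.5 + 2.2 * mem + r.normal(0, 1.5, n)), 0, 10),
        "ct1_time": np.exp(4.0 - 0.25 * exe + r.normal(0, 0.15, n)),
        "ct2_time": np.exp(4.7 - 0.25 * exe + r.normal(0, 0.15, n)),
        "sart_mean_rt": np.exp(5.8 - 0.10 * exe + r.normal(0, 0.10, n)),
    }


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate a long (person x wave) cohort table plus its ground truth.

    Returns the table with all columns downstream stages need (demographics,
    kidney markers plus the full eGFR panel, vascular risk factors, the six
    plasma biomarkers, cognitive tests at waves 1 and 3, and MRI indices for
    the MRI subset at wave 3) and the :class:`SimulationTruth` implied by the
    configured path coefficients. Pulse-wave-velocity missingness is injected
    per ``config.pwv_missing_rate``.
    """
    n = config.n_participants
    seed = config.seed
    lo, hi = config.age_range

    # right-skewed ages: most participants in their 50s/60s, mean ~62
    age = lo + _rng(seed, "age").beta(1.2, 2.3, n) * (hi - lo)
    age_z = (age - 62.0) / 10.0
    female = _rng(seed, "sex").random(n) < 0.54
    sex = np.where(female, "female", "male")
    education = _rng(seed, "education").integers(1, 4, n)  # 1 primary .. 3 tertiary
    depression = np.round(np.clip(_rng(seed, "depression").gamma(2.0, 2.5, n), 0, 60))

    # exposure: ln cystatin C Gaussian given age; intercept ln(0.92) so the
    # median sits near 0.92 mg/L at the mean age
    a = -0.083 + 0.25 * age_z + _rng(seed, "exposure").normal(0, config.exposure_sd, n)
    cystatin_c = np.exp(a)
    ln_scr = (
        -0.30
        + 0.20 * (~female)
        + 0.60 * (a + 0.15)
        + _rng(seed, "creatinine").normal(0, 0.10, n)
    )
    serum_creatinine = np.exp(ln_scr)

    frame = {"age_z": age_z, "female": female.astype(float)}

    # mediator: latent cardiovascular biomarker burden
    m = (
        0.0
        + config.path_beta1 * a
        + _confounder_term(config.confounder_effects.get("m", {}), frame, n)
        + _rng(seed, "mediator").normal(0, config.noise_sd_m, n)
    )

    # wave-1 latent global cognition (z-scale)
    y1 = (
        0.0
        + config.path_theta1 * a
        + config.path_theta2 * m
        + _confounder_term(config.confounder_effects.get("y", {}), frame, n)
        + _rng(seed, "outcome").normal(0, config.noise_sd_y, n)
    )
    # wave-3 cognition = wave-1 value plus exposure/mediator-dependent decline
    y3 = (
        y1
        + config.decline_intercept
        + config.decline_slope * a
        + config.decline_mediator_slope * m
        + _rng(seed, "decline").normal(0, config.decline_noise_sd, n)
    )

    rb = _rng(seed, "biomarkers")
    biomarkers = {
        # cardiovascular markers load on the latent burden M
        "nt_probnp": np.exp(4.6 + 0.60 * m + rb.normal(0, 0.30, n)),
        "gdf15": np.exp(6.9 + 0.50 * m + rb.normal(0, 0.30, n)),
        # inflammatory markers drift with age and kidney function
        "tnf_alpha": np.exp(0.9 + 0.15 * age_z + 0.20 * a + rb.normal(0, 0.40, n)),
        "il6": np.exp(0.3 + 0.25 * age_z + 0.25 * a + rb.normal(0, 0.50, n)),
        "il8": np.exp(1.6 + 0.10 * age_z + 0.15 * a + rb.normal(0, 0.45, n)),
        "il1ra": np.exp(5.5 + 0.10 * age_z + 0.20 * a + rb.normal(0, 0.40, n)),
    }

    rv = _rng(seed, "vascular")
    sbp = 125.0 + 8.0 * age_z + 3.0 * a + rv.normal(0, 14.0, n)
    dbp = 78.0 + 2.0 * age_z + rv.normal(0, 9.0, n)
    smoking = rv.random(n) < 0.20
    diabetes = rv.random(n) < _sigmoid(-2.9 + 0.4 * age_z + 0.5 * a)
    obesity = rv.random(n) < 0.35
    hypertension = (sbp > 140.0) | (rv.random(n) < 0.12)
    total_chol = 5.2 - 0.2 * a + rv.normal(0, 1.0, n)
    hdl = 1.5 + 0.12 * female - 0.05 * a + rv.normal(0, 0.35, n)
    crp = np.exp(0.7 + 0.25 * age_z + 0.20 * a + rv.normal(0, 0.70, n))
    pwv = 9.5 + 1.2 * age_z + 0.8 * a + rv.normal(0, 1.5, n)
    cvd_condition = rv.random(n) < _sigmoid(-2.8 + 0.5 * age_z + 0.4 * a)
    n_cvd_risk = (
        smoking.astype(int) + diabetes.astype(int) + hypertension.astype(int) + obesity.astype(int)
    )

    mri_subset = _rng(seed, "mri_selection").random(n) < config.mri_fraction
    rmri = _rng(seed, "mri")
    # proportional-odds latent for white matter disease: logistic noise at
    # fixed cutpoints guarantees the ordered-logit assumption in-distribution
    wmh_latent = 1.0 * a + 0.8 * age_z + rmri.logistic(0, 1, n)
    wmh_category = 1 + (wmh_latent > 0.8) + (wmh_latent > 2.0) + (wmh_latent > 3.2)
    bin_lo = np.array([0, 10, 20, 30])[wmh_category - 1]
    bin_hi = np.array([9, 19, 29, 45])[wmh_category - 1]
    scheltens = rmri.integers(bin_lo, bin_hi + 1)

    icv = rmri.normal(1.5e6, 1.2e5, n)
    gm_frac = 0.40 - 0.008 * age_z - 0.006 * a + rmri.normal(0, 0.012, n)
    lat = rmri.normal(0.5, 0.004, n)  # hemispheric split
    gm_total = gm_frac * icv
    hip_frac = 0.0052 - 0.00008 * age_z - 0.00006 * a + rmri.normal(0, 0.00025, n)
    hip_total = hip_frac * icv
    cbf_gm = 42.0 - 1.2 * age_z - 2.5 * a + rmri.normal(0, 5.0, n)

    base = pd.DataFrame(
        {
            "pid": np.arange(n),
            "age": age,
            "sex": sex,
            "education": education,
            "depression": depression,
            "serum_creatinine": serum_creatinine,
            "cystatin_c": cystatin_c,
            "ln_cystatin_c": a,
            "sbp": sbp,
            "dbp": dbp,
            "smoking": smoking.astype(int),
            "diabetes": diabetes.astype(int),
            "obesity": obesity.astype(int),
            "hypertension": hypertension.astype(int),
            "n_cvd_risk_factors": n_cvd_risk,
            "total_chol": total_chol,
            "hdl": hdl,
            "crp": crp,
            "pwv": pwv,
            "cvd_condition": cvd_condition.astype(int),
            "cv_latent": m,
            "mri_subset": mri_subset.astype(int),
            **biomarkers,
        }
    )

    rows = []
    for wave, y in ((1, y1), (3, y3)):
        w = base.copy()
        w["wave"] = wave
        w["cognition_latent"] = y
        for col, vals in _cognitive_tests(y, seed, wave).items():
            w[col] = vals
        if wave == 3:
            in_mri = mri_subset
            w["scheltens_score"] = np.where(in_mri, scheltens, np.nan)
            w["wmh_category"] = np.where(in_mri, wmh_category, np.nan)
            w["icv"] = np.where(in_mri, icv, np.nan)
            w["gm_total_left"] = np.where(in_mri, gm_total * lat, np.nan)
            w["gm_total_right"] = np.where(in_mri, gm_total * (1 - lat), np.nan)
            w["hippocampus_left"] = np.where(in_mri, hip_total * lat, np.nan)
            w["hippocampus_right"] = np.where(in_mri, hip_total * (1 - lat), np.nan)
            w["cbf_gm"] = np.where(in_mri, cbf_gm, np.nan)
        else:
            for col in (
                "scheltens_score",
                "wmh_category",
                "icv",
                "gm_total_left",
                "gm_total_right",
                "hippocampus_left",
                "hippocampus_right",
                "cbf_gm",
            ):
                w[col] = np.nan
        rows.append(w)

    table = pd.concat(rows, ignore_index=True)
    table = add_egfr_panel(table)
    table = inject_missingness(table, config)
    return table, config.truth()


def inject_missingness(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Blank out pulse wave velocity, preferentially at low eGFR.

    The overall missing fraction matches ``config.pwv_missing_rate`` in
    expectation; the per-row probability increases monotonically as the
    combined-equation eGFR decreases (logistic-weight tilt, renormalised to
    the target rate). Rate 0 returns the table unchanged.
    """
    rate = config.pwv_missing_rate
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    if rate == 0.0:
        return table
    for col in ("pwv", "egfr_epi_crecys"):
        if col not in table.columns:
            raise KeyError(f"required column missing: {col}")
    out = table.copy()
    egfr = out["egfr_epi_crecys"].to_numpy(dtype=float)
    score = -(egfr - np.nanmean(egfr)) / np.nanstd(egfr)  # higher = worse kidney
    w = np.exp(0.6 * score)
    p = np.clip(rate * w / np.mean(w), 0.0, 0.95)
    # one draw per participant so both wave rows lose PWV together
    pid = out["pid"].to_numpy()
    order = np.unique(pid)
    p_by_pid = pd.Series(p, index=pid).groupby(level=0).first()
    draws = _rng(config.seed, "pwv_missing").random(len(order))
    missing_pids = set(order[draws < p_by_pid.loc[order].to_numpy()])
    mask = out["pid"].isin(missing_pids).to_numpy()
    out.loc[mask, "pwv"] = np.nan
    return out


def write_cohort(
    table: pd.DataFrame,
    config: GeneratorConfig,
    truth: SimulationTruth,
    csv_path: str | Path,
) -> Path:
    """Write the cohort as CSV plus a JSON sidecar with config and truth."""
    csv_path = Path(csv_path)
    table.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    cfg = dataclasses.asdict(config)
    cfg["age_range"] = list(cfg["age_range"])
    payload = {"config": cfg, "truth": dataclasses.asdict(truth)}
    sidecar.write_text(json.dumps(payload, indent=2))
    return sidecar


def read_cohort(csv_path: str | Path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort`."""
    return pd.read_csv(csv_path)
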