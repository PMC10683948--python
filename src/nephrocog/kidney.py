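"""Estimated glomerular filtration rate (eGFR) panel.

Five published estimating equations are provided, all returning eGFR in
mL/min/1.73 m**2 from serum creatinine (mg/dL, IDMS-aligned), serum
cystatin C (mg/L), age (years) and sex:

* CKD-EPI 2009 creatinine equation,
* CKD-EPI 2012 cystatin C equation,
* CKD-EPI 2012 combined creatinine–cystatin C equation,
* 4-variable MDRD study equation (IDMS-traceable, 175 constant),
* Berlin Initiative Study equation 1 (BIS1, creatinine-based, age 70+
  derivation cohort but applied cohort-wide here).

Chronic kidney disease (CKD) is flagged as combined-equation eGFR < 60.
The race coefficients of the original CKD-EPI/MDRD publications default to
1.0 (no adjustment) but remain configurable.

All functions are vectorised: scalars, numpy arrays and pandas Series are
accepted and broadcast together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KidneyInput",
    "egfr_ckdepi_creatinine",
    "egfr_ckdepi_cystatin",
    "egfr_ckdepi_combined",
    "egfr_mdrd",
    "egfr_bis",
    "creatinine_umol_to_mgdl",
    "classify_ckd_and_quartiles",
    "add_egfr_panel",
    "CKD_EGFR_THRESHOLD",
]

#: eGFR (combined equation) below this value, strictly, defines CKD.
CKD_EGFR_THRESHOLD = 60.0

# Black-race multipliers of the original publications; default 1.0 = off.
RACE_COEF_CKDEPI_CRE = 1.159
RACE_COEF_CKDEPI_COMBINED = 1.08
RACE_COEF_MDRD = 1.212


@dataclass(frozen=True)
class KidneyInput:
    """One participant's kidney markers.

    serum_creatinine in mg/dL, cystatin_c in mg/L, age in years,
    sex as ``"male"`` / ``"female"``.
    """

    serum_creatinine: float
    cystatin_c: float
    age: float
    sex: str

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.serum_creatinine > 0:
            raise ValueError("serum creatinine must be positive")
        if not self.cystatin_c > 0:
            raise ValueError("cystatin C must be positive")
        if self.age < 50:
            warnings.warn(
                "age below 50: outside the cohort the pipeline targets",
                stacklevel=2,
            )


def _as_arrays(*values):
    return np.broadcast_arrays(*[np.asarray(v, dtype=float) for v in values])


def _female_mask(sex) -> np.ndarray:
    s = np.asarray(sex)
    if s.dtype.kind in "USO":
        female = np.char.lower(s.astype(str)) == "female"
        male = np.char.lower(s.astype(str)) == "male"
        if not np.all(female | male):
            bad = np.unique(s[~(female | male)])
            raise ValueError(f"unrecognised sex labels: {bad}")
        return female
    # accept 0/1 with 1 = female
    return s.astype(bool)


def _check_positive(x: np.ndarray, name: str) -> None:
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError(f"{name} must be positive and finite")


def creatinine_umol_to_mgdl(scr_umol) -> np.ndarray:
    """Convert serum creatinine from µmol/L to mg/dL (divide by 88.4)."""
    return np.asarray(scr_umol, dtype=float) / 88.4


def egfr_ckdepi_creatinine(scr, age, sex, *, race_black=False):
    """CKD-EPI 2009 creatinine equation.

    eGFR = 141 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^-1.209
           * 0.993^age * (1.018 if female) [* 1.159 if race_black]

    with k = 0.7 (female) / 0.9 (male) and alpha = -0.329 / -0.411.
    """
    scr, age = _as_arrays(scr, age)
    _check_positive(scr, "serum creatinine")
    female = np.broadcast_to(_female_mask(sex), scr.shape)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * np.where(female, 1.018, 1.0)
    )
    if race_black:
        egfr = egfr * RACE_COEF_CKDEPI_CRE
    return egfr if egfr.shape else float(egfr)


def egfr_ckdepi_cystatin(scys, age, sex):
    """CKD-EPI 2012 cystatin C equation.

    eGFR = 133 * min(Scys/0.8, 1)^-0.499 * max(Scys/0.8, 1)^-1.328
           * 0.996^age * (0.932 if female)
    """
    scys, age = _as_arrays(scys, age)
    _check_positive(scys, "cystatin C")
    female = np.broadcast_to(_female_mask(sex), scys.shape)
    ratio = scys / 0.8
    egfr = (
        133.0
        * np.minimum(ratio, 1.0) ** -0.499
        * np.maximum(ratio, 1.0) ** -1.328
        * 0.996 ** age
        * np.where(female, 0.932, 1.0)
    )
    return egfr if egfr.shape else float(egfr)


def egfr_ckdepi_combined(scr, scys, age, sex, *, race_black=False):
    """CKD-EPI 2012 combined creatinine–cystatin C equation.

    eGFR = 135 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^-0.601
           * min(Scys/0.8, 1)^-0.375 * max(Scys/0.8, 1)^-0.711
           * 0.995^age * (0.969 if female) [* 1.08 if race_black]

    with k = 0.7 (female) / 0.9 (male) and alpha = -0.248 / -0.207.
    """
    scr, scys, age = _as_arrays(scr, scys, age)
    _check_positive(scr, "serum creatinine")
    _check_positive(scys, "cystatin C")
    female = np.broadcast_to(_female_mask(sex), scr.shape)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.248, -0.207)
    r_cr = scr / kappa
    r_cys = scys / 0.8
    egfr = (
        135.0
        * np.minimum(r_cr, 1.0) ** alpha
        * np.maximum(r_cr, 1.0) ** -0.601
        * np.minimum(r_cys, 1.0) ** -0.375
        * np.maximum(r_cys, 1.0) ** -0.711
        * 0.995 ** age
        * np.where(female, 0.969, 1.0)
    )
    if race_black:
        egfr = egfr * RACE_COEF_CKDEPI_COMBINED
    return egfr if egfr.shape else float(egfr)


def egfr_mdrd(scr, age, sex, *, race_black=False):
    """4-variable MDRD study equation (IDMS-traceable).

    eGFR = 175 * Scr^-1.154 * age^-0.203 * (0.742 if female)
           [* 1.212 if race_black]
    """
    scr, age = _as_arrays(scr, age)
    _check_positive(scr, "serum creatinine")
    _check_positive(age, "age")
    female = np.broadcast_to(_female_mask(sex), scr.shape)
    egfr = 175.0 * scr ** -1.154 * age ** -0.203 * np.where(female, 0.742, 1.0)
    if race_black:
        egfr = egfr * RACE_COEF_MDRD
    return egfr if egfr.shape else float(egfr)


def egfr_bis(scr, age, sex):
    """Berlin Initiative Study creatinine equation (BIS1).

    eGFR = 3736 * Scr^-0.87 * age^-0.95 * (0.82 if female)
    """
    scr, age = _as_arrays(scr, age)
    _check_positive(scr, "serum creatinine")
    _check_positive(age, "age")
    female = np.broadcast_to(_female_mask(sex), scr.shape)
    egfr = 3736.0 * scr ** -0.87 * age ** -0.95 * np.where(female, 0.82, 1.0)
    return egfr if egfr.shape else float(egfr)


def panel_from_input(inp: KidneyInput, *, race_black=False) -> dict:
    """All five eGFR estimates plus the CKD flag for a single participant."""
    crecys = egfr_ckdepi_combined(
        inp.serum_creatinine, inp.cystatin_c, inp.age, inp.sex, race_black=race_black
    )
    return {
        "egfr_epi_cre": egfr_ckdepi_creatinine(
            inp.serum_creatinine, inp.age, inp.sex, race_black=race_black
        ),
        "egfr_epi_cys": egfr_ckdepi_cystatin(inp.cystatin_c, inp.age, inp.sex),
        "egfr_epi_crecys": crecys,
        "egfr_mdrd": egfr_mdrd(inp.serum_creatinine, inp.age, inp.sex, race_black=race_black),
        "egfr_bis": egfr_bis(inp.serum_creatinine, inp.age, inp.sex),
        "ckd_flag": bool(crecys < CKD_EGFR_THRESHOLD),
    }


def cystatin_quartiles(cystatin: pd.Series) -> pd.Series:
    """Sample-quartile stratum (1-4) of cystatin C; ties go to the lower stratum.

    Cut points are the 25/50/75% sample quantiles (linear interpolation);
    a value equal to a cut point is assigned to the stratum below it.
    """
    cys = pd.Series(cystatin, dtype=float)
    non_missing = cys.dropna()
    if len(non_missing) < 4:
        raise ValueError("need at least 4 non-missing cystatin C values for quartiles")
    q25, q50, q75 = non_missing.quantile([0.25, 0.50, 0.75]).to_numpy()
    out = pd.Series(np.nan, index=cys.index, dtype=float)
    valid = cys.notna()
    v = cys[valid].to_numpy()
    labels = np.select([v <= q25, v <= q50, v <= q75], [1, 2, 3], default=4)
    out[valid] = labels
    return out.astype("Int64")


def classify_ckd_and_quartiles(table: pd.DataFrame) -> pd.DataFrame:
    """Add CKD flag and wave-1 cystatin quartile stratum to an eGFR panel table.

    Requires ``egfr_epi_crecys`` and ``cystatin_c`` columns. CKD is
    ``egfr_epi_crecys < 60`` (strict). Returns a copy.
    """
    out = table.copy()
    out["ckd_flag"] = out["egfr_epi_crecys"] < CKD_EGFR_THRESHOLD
    out["cystatin_quartile"] = cystatin_quartiles(out["cystatin_c"])
    return out


def add_egfr_panel(table: pd.DataFrame, *, race_black=False) -> pd.DataFrame:
    """Vectorised panel over a cohort table.

    Expects columns ``serum_creatinine`` (mg/dL), ``cystatin_c`` (mg/L),
    ``age`` (years), ``sex`` ('male'/'female'). Adds the five eGFR columns,
    ``ckd_flag`` and ``cystatin_quartile``.
    """
    scr = table["serum_creatinine"].to_numpy(dtype=float)
    scys = table["cystatin_c"].to_numpy(dtype=float)
    age = table["age"].to_numpy(dtype=float)
    sex = table["sex"].to_numpy()
    out = table.copy()
    out["egfr_epi_cre"] = egfr_ckdepi_creatinine(scr, age, sex, race_black=race_black)
    out["egfr_epi_cys"] = egfr_ckdepi_cystatin(scys, age, sex)
    out["egfr_epi_crecys"] = egfr_ckdepi_combined(scr, scys, age, sex, race_black=race_black)
    out["egfr_mdrd"] = egfr_mdrd(scr, age, sex, race_black=race_black)
    out["egfr_bis"] = egfr_bis(scr, age, sex)
    return classify_ckd_and_quartiles(out)
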