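"""Composite biomarker scores and cognitive composites.

Biomarker scores are *sums* of z-standardised plasma concentrations:

* Inflammation BS  = z(TNF-alpha) + z(IL-6) + z(IL-8) + z(IL-1RA)
* Cardiovascular BS = z(NT-proBNP) + z(GDF15)

Cognitive composites are *means* of z-scores:

* global    = mean(z(MoCA), z(MMSE))
* memory    = mean(z(immediate recall), z(delayed recall))
* executive = mean(-z(Colour Trail 1 time), -z(Colour Trail 2 time),
                   -z(SART mean RT))

Timing-based z-scores are sign-flipped so every composite reads
"higher = better". Standardisation uses the sample SD (ddof=1) over a
reference sample (by default the wave-1 analysis sample); wave-3 scores are
standardised against the wave-1 moments so that wave differences are
measured on a fixed scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "zstandardize",
    "biomarker_scores",
    "cognitive_composites",
    "add_composite_scores",
    "INFLAMMATION_MARKERS",
    "CARDIOVASCULAR_MARKERS",
    "COGNITIVE_COMPONENTS",
]

INFLAMMATION_MARKERS = ["tnf_alpha", "il6", "il8", "il1ra"]
CARDIOVASCULAR_MARKERS = ["nt_probnp", "gdf15"]

# composite -> list of (column, orientation); -1 marks a timing score where
# larger raw values mean worse performance
COGNITIVE_COMPONENTS = {
    "global_cog": [("moca", +1), ("mmse", +1)],
    "memory_cog": [("recall_immediate", +1), ("recall_delayed", +1)],
    "executive_cog": [("ct1_time", -1), ("ct2_time", -1), ("sart_mean_rt", -1)],
}


def zstandardize(column, reference=None) -> pd.Series:
    """Z-standardise a numeric vector: mean 0, SD 1 (ddof=1) over the reference.

    Parameters
    ----------
    column : array-like
        Values to transform; NaN stays NaN.
    reference : boolean mask, optional
        Rows whose mean/SD define the transform (default: all rows). The
        returned series applies those moments to *every* row.
    """
    col = pd.Series(column, dtype=float)
    ref = col if reference is None else col[np.asarray(reference, dtype=bool)]
    ref = ref.dropna()
    if len(ref) < 2:
        raise ValueError("need at least 2 non-missing reference values")
    sd = ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zero-variance column cannot be standardized")
    return (col - ref.mean()) / sd


def _component_sum(table: pd.DataFrame, columns, reference, how: str) -> pd.Series:
    zcols = {c: zstandardize(table[c], reference) for c in columns}
    z = pd.DataFrame(zcols)
    if how == "sum":
        # missing if any component missing
        return z.sum(axis=1, skipna=False)
    if how == "mean":
        # mean over available components; all-missing -> missing
        return z.mean(axis=1, skipna=True)
    raise ValueError(how)


def biomarker_scores(panel: pd.DataFrame, reference=None) -> pd.DataFrame:
    """Inflammation and cardiovascular biomarker scores from a plasma panel.

    `panel` must hold the six marker columns (wave-1 concentrations). A row
    missing any component yields a missing score.
    """
    for c in INFLAMMATION_MARKERS + CARDIOVASCULAR_MARKERS:
        if c not in panel.columns:
            raise KeyError(f"biomarker column missing: {c}")
    return pd.DataFrame(
        {
            "inflammation_bs": _component_sum(panel, INFLAMMATION_MARKERS, reference, "sum"),
            "cardiovascular_bs": _component_sum(panel, CARDIOVASCULAR_MARKERS, reference, "sum"),
        },
        index=panel.index,
    )


def cognitive_composites(
    battery: pd.DataFrame,
    reference=None,
    moments: dict | None = None,
) -> pd.DataFrame:
    """Global, memory and executive composites from a test-score battery.

    Each composite is the mean of the z-scores of its components, timing
    scores sign-flipped so higher = better. ``moments`` may supply
    pre-computed ``{column: (mean, sd)}`` pairs (e.g. the wave-1 moments when
    scoring wave-3) that override standardisation against `reference`.
    """
    out = {}
    for name, parts in COGNITIVE_COMPONENTS.items():
        zcols = {}
        for col, orient in parts:
            if col not in battery.columns:
                raise KeyError(f"cognitive test column missing: {col}")
            if moments is not None and col in moments:
                mean, sd = moments[col]
                if sd <= 0:
                    raise ValueError(f"non-positive SD supplied for {col}")
                z = (pd.Series(battery[col], dtype=float) - mean) / sd
            else:
                z = zstandardize(battery[col], reference)
            zcols[col] = orient * z
        out[name] = pd.DataFrame(zcols).mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=battery.index)


def reference_moments(table: pd.DataFrame, columns, reference=None) -> dict:
    """(mean, sd) pairs (ddof=1) per column over the reference sample."""
    res = {}
    for c in columns:
        col = pd.Series(table[c], dtype=float)
        ref = col if reference is None else col[np.asarray(reference, dtype=bool)]
        ref = ref.dropna()
        sd = ref.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero-variance column: {c}")
        res[c] = (ref.mean(), sd)
    return res


def add_composite_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Attach biomarker scores and per-wave cognitive composites to a cohort table.

    The table is long over waves (``wave`` column, values 1 and 3);
    biomarkers are wave-1 measurements. Standardisation reference is the
    wave-1 sample throughout, so wave-3 composites are on the wave-1 scale.
    """
    out = table.copy()
    wave1 = out["wave"].to_numpy() == 1

    bs = biomarker_scores(out, reference=wave1)
    out[["inflammation_bs", "cardiovascular_bs"]] = bs

    test_cols = [c for parts in COGNITIVE_COMPONENTS.values() for c, _ in parts]
    moments = reference_moments(out, test_cols, reference=wave1)
    cogs = cognitive_composites(out, moments=moments)
    out[list(COGNITIVE_COMPONENTS)] = cogs
    return out
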