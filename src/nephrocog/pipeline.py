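"""End-to-end orchestration: cohort in, report tables out.

The pipeline chains generation (or loading), schema validation, the eGFR
panel, composite scoring, the nested association models, the MRI analyses
and the mediation screen, and writes each stage's results as delimited text
plus a JSON manifest (seed, package versions, row counts, output digests)
so a run is reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kidney import add_egfr_panel
from .mediation import mediator_screen
from .models import (
    ModelSpec,
    apply_sample_filter,
    cbf_quartile_contrast,
    fit_longitudinal_decline,
    fit_nested_cross_sectional,
    fit_ordinal_wmh,
    jonckheere_terpstra,
    normalize_volumes,
)
from .scores import add_composite_scores
from .synthetic import GeneratorConfig, generate_cohort, read_cohort

__all__ = ["RunConfig", "SchemaError", "validate_table", "prepare_cohort", "run_pipeline"]

DEFAULT_EXPOSURES = ["ln_cystatin_c", "egfr_epi_cys", "egfr_epi_cre", "egfr_mdrd", "egfr_bis"]
DEFAULT_OUTCOMES = ["global_cog", "memory_cog", "executive_cog"]
DEFAULT_MEDIATORS = ["age", "sbp", "dbp", "crp", "inflammation_bs", "cardiovascular_bs"]

#: column -> (kind, min, max); kind in {'numeric', 'binary', 'category'}
DATA_DICTIONARY = {
    "pid": ("numeric", 0, None),
    "wave": ("category", {1, 3}, None),
    "age": ("numeric", 18, 110),
    "sex": ("category", {"male", "female"}, None),
    "education": ("numeric", 0, 10),
    "depression": ("numeric", 0, 60),
    "serum_creatinine": ("numeric", 1e-6, 30),
    "cystatin_c": ("numeric", 1e-6, 20),
    "sbp": ("numeric", 50, 300),
    "dbp": ("numeric", 30, 200),
    "smoking": ("binary", None, None),
    "diabetes": ("binary", None, None),
    "obesity": ("binary", None, None),
    "hypertension": ("binary", None, None),
    "n_cvd_risk_factors": ("numeric", 0, 10),
    "total_chol": ("numeric", 0.5, 20),
    "hdl": ("numeric", 0.1, 6),
    "crp": ("numeric", 0, None),
    "pwv": ("numeric", 0, None),
    "cvd_condition": ("binary", None, None),
    "tnf_alpha": ("numeric", 0, None),
    "il6": ("numeric", 0, None),
    "il8": ("numeric", 0, None),
    "il1ra": ("numeric", 0, None),
    "nt_probnp": ("numeric", 0, None),
    "gdf15": ("numeric", 0, None),
    "moca": ("numeric", 0, 30),
    "mmse": ("numeric", 0, 30),
    "recall_immediate": ("numeric", 0, 20),
    "recall_delayed": ("numeric", 0, 10),
    "ct1_time": ("numeric", 0, None),
    "ct2_time": ("numeric", 0, None),
    "sart_mean_rt": ("numeric", 0, None),
    "mri_subset": ("binary", None, None),
    "scheltens_score": ("numeric", 0, 84),
    "icv": ("numeric", 0, None),
    "gm_total_left": ("numeric", 0, None),
    "gm_total_right": ("numeric", 0, None),
    "hippocampus_left": ("numeric", 0, None),
    "hippocampus_right": ("numeric", 0, None),
    "cbf_gm": ("numeric", 0, None),
}

CORE_REQUIRED = ["pid", "wave", "age", "sex", "serum_creatinine", "cystatin_c"]
REQUIRED_BY_ANALYSIS = {
    "cross_sectional": ["moca", "mmse", "recall_immediate", "recall_delayed",
                        "ct1_time", "ct2_time", "sart_mean_rt", "education", "depression"],
    "longitudinal": ["moca", "mmse"],
    "mri": ["mri_subset", "scheltens_score", "icv", "cbf_gm"],
    "mediation": ["cystatin_c", "sbp", "dbp", "crp",
                  "tnf_alpha", "il6", "il8", "il1ra", "nt_probnp", "gdf15"],
}


class SchemaError(ValueError):
    """Input table violates the data dictionary."""


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one pipeline run.

    Exactly one of ``input_path`` / ``generator`` must be given; all
    randomness (generation, bootstrap) flows from ``seed``.
    """

    input_path: str | None = None
    generator: dict | None = None
    seed: int = 0
    output_dir: str = "nephrocog_out"
    analyses: tuple[str, ...] = ("cross_sectional", "longitudinal", "mri", "mediation")
    sample_filter: str = "all"  # all | no_ckd | no_cvd
    exposures: tuple[str, ...] = tuple(DEFAULT_EXPOSURES)
    outcomes: tuple[str, ...] = tuple(DEFAULT_OUTCOMES)
    mediators: tuple[str, ...] = tuple(DEFAULT_MEDIATORS)
    n_bootstrap: int = 200
    include_pwv: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path / generator must be set")
        unknown = set(self.analyses) - set(REQUIRED_BY_ANALYSIS)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("analyses", "exposures", "outcomes", "mediators"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def validate_table(table: pd.DataFrame, analyses=("cross_sectional",)) -> pd.DataFrame:
    """Check a cohort table against the data dictionary.

    Missing required columns and out-of-range values raise
    :class:`SchemaError` naming the offending columns; unknown columns only
    warn. Returns the table (validated, not copied).
    """
    required = list(CORE_REQUIRED)
    for a in analyses:
        required += REQUIRED_BY_ANALYSIS.get(a, [])
    missing = [c for c in dict.fromkeys(required) if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    known = set(DATA_DICTIONARY) | {
        "ln_cystatin_c", "cv_latent", "cognition_latent", "wmh_category",
        "egfr_epi_cre", "egfr_epi_cys", "egfr_epi_crecys", "egfr_mdrd", "egfr_bis",
        "ckd_flag", "cystatin_quartile", "inflammation_bs", "cardiovascular_bs",
        "global_cog", "memory_cog", "executive_cog", "female",
    } | {f"{c}_decline" for c in DEFAULT_OUTCOMES}
    unknown = [c for c in table.columns if c not in known]
    if unknown:
        warnings.warn(f"unknown column(s) ignored by the pipeline: {unknown}", stacklevel=2)

    problems = []
    for col, (kind, lo, hi) in DATA_DICTIONARY.items():
        if col not in table.columns:
            continue
        vals = table[col].dropna()
        if kind == "category":
            bad = set(vals.unique()) - set(lo)
            if bad:
                problems.append(f"{col}: unexpected values {sorted(map(str, bad))}")
        elif kind == "binary":
            if not set(np.unique(vals)) <= {0, 1, True, False}:
                problems.append(f"{col}: not 0/1 coded")
        else:
            v = vals.astype(float)
            if lo is not None and (v < lo).any():
                problems.append(f"{col}: {(v < lo).sum()} value(s) below {lo}")
            if hi is not None and (v > hi).any():
                problems.append(f"{col}: {(v > hi).sum()} value(s) above {hi}")
    if problems:
        raise SchemaError("out-of-range values: " + "; ".join(problems))
    return table


def prepare_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Derived columns every analysis needs: eGFR panel, ln-exposure,
    composite scores, and per-participant wave-3 minus wave-1 decline
    columns attached to the wave-1 rows."""
    out = table.copy()
    if "egfr_epi_crecys" not in out.columns:
        out = add_egfr_panel(out)
    if "ln_cystatin_c" not in out.columns:
        out["ln_cystatin_c"] = np.log(out["cystatin_c"].astype(float))
    if "global_cog" not in out.columns:
        out = add_composite_scores(out)
    w1 = out[out["wave"] == 1].set_index("pid")
    w3 = out[out["wave"] == 3].set_index("pid")
    shared = w1.index.intersection(w3.index)
    for comp in DEFAULT_OUTCOMES:
        decl = (w3.loc[shared, comp] - w1.loc[shared, comp]).rename(f"{comp}_decline")
        mapped = out["pid"].map(decl)
        out[f"{comp}_decline"] = mapped.where(out["wave"] == 1)
    return out


def _descriptives_by_quartile(df: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) of continuous variables and counts of flags per
    wave-1 cystatin quartile, plus a Jonckheere-Terpstra trend p for the
    individual cognitive test scores."""
    w1 = df[df["wave"] == 1]
    cont = ["age", "cystatin_c", "serum_creatinine", "egfr_epi_cys", "egfr_epi_cre",
            "egfr_mdrd", "egfr_bis", "sbp", "dbp", "total_chol", "hdl", "crp", "pwv",
            "inflammation_bs", "cardiovascular_bs",
            "moca", "mmse", "recall_immediate", "recall_delayed",
            "ct1_time", "ct2_time", "sart_mean_rt"]
    flags = ["smoking", "diabetes", "hypertension", "obesity", "cvd_condition"]
    trend_cols = {"moca", "mmse", "recall_immediate", "recall_delayed",
                  "ct1_time", "ct2_time", "sart_mean_rt"}
    rows = []
    groups = {q: g for q, g in w1.groupby("cystatin_quartile")}
    quartiles = sorted(groups)
    rows.append({"variable": "n", **{f"q{q}": len(groups[q]) for q in quartiles}})
    for col in cont:
        if col not in w1.columns:
            continue
        row = {"variable": col}
        for q in quartiles:
            v = groups[q][col].dropna()
            if len(v) == 0:
                row[f"q{q}"] = ""
                continue
            med, lo, hi = v.quantile([0.5, 0.25, 0.75])
            row[f"q{q}"] = f"{med:.2f} ({lo:.2f}, {hi:.2f})"
        if col in trend_cols:
            samples = [groups[q][col].dropna().to_numpy() for q in quartiles]
            if all(len(s) for s in samples) and len(samples) >= 2:
                jt = jonckheere_terpstra(samples, alternative="decreasing")
                row["jt_trend_p"] = jt.p_value
        rows.append(row)
    for col in flags:
        if col not in w1.columns:
            continue
        row = {"variable": col}
        for q in quartiles:
            v = groups[q][col].dropna()
            row[f"q{q}"] = f"{int(v.sum())} ({100 * v.mean():.1f}%)"
        rows.append(row)
    return pd.DataFrame(rows)


def _fit_row(kind, outcome, exposure, tier, res):
    return {
        "analysis": kind,
        "outcome": outcome,
        "exposure": exposure,
        "tier": tier,
        "beta_std": res.beta_std,
        "se": res.se,
        "p_value": res.p_value,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "n_used": res.n_used,
        "vif_max": res.vif_max,
        "odds_ratio": res.odds_ratio,
        "model_kind": res.model_kind,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled analysis and write the report bundle.

    Returns a dict with the output paths and the in-memory result frames.
    Raises :class:`SchemaError` for input problems; model failures propagate
    with a stage label.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        gen = GeneratorConfig(**{**config.generator, "seed": config.seed})
        table, truth = generate_cohort(gen)
        truth_dict = dataclasses.asdict(truth)
    else:
        table = read_cohort(config.input_path)
        truth_dict = None
    validate_table(table, analyses=config.analyses)
    df = prepare_cohort(table)
    df = apply_sample_filter(df, config.sample_filter)

    outputs: dict[str, Path] = {}
    frames: dict[str, pd.DataFrame] = {}

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        outputs[name] = path
        frames[name] = frame

    def _stage(label, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"[stage: {label}] {exc}") from exc

    _write("descriptives_by_quartile", _stage("descriptives", _descriptives_by_quartile, df))

    if "cross_sectional" in config.analyses:
        rows = []
        for outcome in config.outcomes:
            for exposure in config.exposures:
                for tier in ("univariable", "M1", "M2", "M3"):
                    spec = ModelSpec(outcome=outcome, exposure=exposure, tier=tier,
                                     include_pwv=config.include_pwv)
                    res = _stage(f"cross-sectional {outcome}~{exposure} ({tier})",
                                 fit_nested_cross_sectional, df, spec)
                    rows.append(_fit_row("cross_sectional", outcome, exposure, tier, res))
        _write("nested_models", pd.DataFrame(rows))

    if "longitudinal" in config.analyses:
        rows = []
        for exposure in config.exposures:
            for tier in ("univariable", "M1", "M2", "M3"):
                spec = ModelSpec(outcome="global_cog", exposure=exposure, tier=tier,
                                 include_pwv=config.include_pwv)
                res = _stage(f"longitudinal global_cog~{exposure} ({tier})",
                             fit_longitudinal_decline, df, spec)
                rows.append(_fit_row("longitudinal", "global_cog", exposure, tier, res))
        _write("longitudinal_models", pd.DataFrame(rows))

    if "mri" in config.analyses:
        rows = []
        mri = df[(df["mri_subset"] == 1) & (df["wave"] == 3)].copy()
        norm = _stage("volume normalisation", normalize_volumes, mri,
                      ["gm_total", "hippocampus"])
        mri[norm.columns] = norm
        for exposure in ("ln_cystatin_c", "egfr_epi_cys", "egfr_epi_cre"):
            for tier in ("univariable", "M1"):
                spec = ModelSpec(outcome="scheltens_score", exposure=exposure, tier=tier,
                                 sample_filter="mri_subset")
                res = _stage(f"ordinal WMH ~{exposure} ({tier})", fit_ordinal_wmh, df, spec)
                rows.append(_fit_row("wmh_ordinal", "wmh_category", exposure, tier, res))
            for outcome in norm.columns:
                for tier in ("univariable", "M1"):
                    spec = ModelSpec(outcome=outcome, exposure=exposure, tier=tier)
                    res = _stage(f"volume {outcome}~{exposure} ({tier})",
                                 fit_nested_cross_sectional, mri.assign(wave=1), spec)
                    rows.append(_fit_row("gm_volume", outcome, exposure, tier, res))
        cbf = _stage("CBF quartile contrast", cbf_quartile_contrast, df)
        rows.append(_fit_row("cbf_contrast", "cbf_gm", "top_cystatin_quartile",
                             "univariable", cbf))
        _write("mri_models", pd.DataFrame(rows))

    if "mediation" in config.analyses:
        med_outcomes = list(config.outcomes) + ["global_cog_decline"]
        med = _stage(
            "mediation screen",
            mediator_screen,
            df,
            med_outcomes,
            list(config.mediators),
            ("univariable", "M1", "M2"),
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
            baseline_columns={"global_cog_decline": "global_cog"},
        )
        _write("mediation_screen", med)
        # Figure-style effect listing for the headline mediator
        head = med[(med["mediator"] == "cardiovascular_bs") & (med["tier"] == "M2")]
        _write("effect_decomposition", head[
            ["outcome", "nde", "nie", "te", "proportion_mediated_pct", "n_used"]
        ])

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {**dataclasses.asdict(config)},
        "n_rows_input": int(len(table)),
        "n_participants": int(table["pid"].nunique()),
        "simulation_truth": truth_dict,
        "outputs": {
            name: {
                "path": str(path),
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
                "n_rows": int(len(frames[name])),
            }
            for name, path in outputs.items()
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    outputs["manifest"] = manifest_path
    return {"outputs": outputs, "frames": frames, "manifest": manifest}
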