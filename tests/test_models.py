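"""Nested regression, mixed model, VIF, trend test, ordinal and MRI analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nephrocog import GeneratorConfig, generate_cohort
from nephrocog.models import (
    ModelSpec,
    TIER_COVARIATES,
    bonferroni_threshold,
    cbf_quartile_contrast,
    covariates_for_tier,
    fit_longitudinal_decline,
    fit_nested_cross_sectional,
    fit_ordinal_wmh,
    jonckheere_terpstra,
    normalize_volumes,
    vif,
    wmh_to_ordinal,
)
from nephrocog.pipeline import prepare_cohort


def test_adjustment_tiers_strictly_nested():
    u, m1, m2, m3 = (set(TIER_COVARIATES[t]) for t in ("univariable", "M1", "M2", "M3"))
    assert u < m1 < m2 < m3


def test_longitudinal_tier_adds_baseline_and_pwv_is_optional():
    assert "baseline_cognition" in covariates_for_tier("M1", longitudinal=True)
    assert "pwv" not in covariates_for_tier("M2")
    assert "pwv" in covariates_for_tier("M2", include_pwv=True)


def test_duplicated_exposure_raises_rank_error(small_cohort):
    df, _ = small_cohort
    df = df.copy()
    df["ln_cys_copy"] = df["ln_cystatin_c"]
    spec = ModelSpec(outcome="global_cog", exposure="ln_cystatin_c",
                     tier="univariable", extra_covariates=("ln_cys_copy",))
    with pytest.raises(ValueError, match="rank"):
        fit_nested_cross_sectional(df, spec)


def test_univariable_recovers_generating_total_effect():
    """Without confounding the standardised exposure coefficient equals the
    generating total effect rescaled by sd(A)/sd(Y), within 3 SE."""
    cfg = GeneratorConfig(
        n_participants=4000, seed=31,
        confounder_effects={"m": {}, "y": {}},
    )
    table, truth = generate_cohort(cfg)
    w1 = table[table["wave"] == 1]
    expected = truth.te_true * w1["ln_cystatin_c"].std() / w1["cognition_latent"].std()
    spec = ModelSpec(outcome="cognition_latent", exposure="ln_cystatin_c")
    res = fit_nested_cross_sectional(table, spec)
    assert abs(res.beta_std - expected) < 3 * res.se
    assert res.n_used == 4000
    assert res.p_value < 1e-6


def test_noise_outcome_is_null_in_almost_all_seeds(small_cohort):
    df, _ = small_cohort
    w1 = df[df["wave"] == 1].head(500).copy()
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        w1["noise_outcome"] = np.random.default_rng(seed).normal(size=len(w1))
        res = fit_nested_cross_sectional(
            w1, ModelSpec(outcome="noise_outcome", exposure="ln_cystatin_c")
        )
        hits += abs(res.beta_std) < 3 * res.se
    assert hits >= 99


def test_attenuation_when_true_mediator_enters_covariates(default_cohort):
    df, _ = default_cohort
    base = fit_nested_cross_sectional(
        df, ModelSpec(outcome="global_cog", exposure="ln_cystatin_c")
    )
    adj = fit_nested_cross_sectional(
        df,
        ModelSpec(outcome="global_cog", exposure="ln_cystatin_c",
                  extra_covariates=("cv_latent", "age")),
    )
    assert abs(adj.beta_std) < abs(base.beta_std)


def test_longitudinal_null_when_no_decline_paths():
    cfg = GeneratorConfig(n_participants=1500, seed=13,
                          decline_slope=0.0, decline_mediator_slope=0.0)
    table, _ = generate_cohort(cfg)
    df = prepare_cohort(table)
    res = fit_longitudinal_decline(df, ModelSpec(outcome="x", exposure="ln_cystatin_c"),
                                   outcome="cognition_latent")
    assert abs(res.beta_std) < 3 * res.se


def test_longitudinal_recovers_decline_slope():
    cfg = GeneratorConfig(n_participants=3000, seed=29,
                          decline_slope=-0.4, decline_mediator_slope=0.0)
    table, _ = generate_cohort(cfg)
    df = prepare_cohort(table)
    expected = -0.4 * df["ln_cystatin_c"].std() / df["cognition_latent"].std()
    res = fit_longitudinal_decline(df, ModelSpec(outcome="x", exposure="ln_cystatin_c"),
                                   outcome="cognition_latent")
    assert abs(res.beta_std - expected) < 3 * res.se
    assert res.p_value < 0.05


def test_ancova_agrees_in_direction_with_mixed_model():
    cfg = GeneratorConfig(n_participants=2000, seed=37, decline_slope=-0.4,
                          decline_mediator_slope=0.0)
    table, _ = generate_cohort(cfg)
    df = prepare_cohort(table)
    spec = ModelSpec(outcome="x", exposure="ln_cystatin_c")
    mixed = fit_longitudinal_decline(df, spec, outcome="cognition_latent", method="mixed")
    ancova = fit_longitudinal_decline(df, spec, outcome="cognition_latent", method="ancova")
    assert np.sign(mixed.beta_std) == np.sign(ancova.beta_std) == -1


def test_vif_orthogonal_covariates_are_one():
    X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0], "c": [1, -1, -1, 1.0]})
    assert all(v == pytest.approx(1.0, abs=1e-12) for v in vif(X).values())


def test_vif_perfect_collinearity_is_infinite():
    x = np.arange(10.0)
    X = pd.DataFrame({"x1": x, "x2": 2 * x + 1, "x3": np.random.default_rng(0).normal(size=10)})
    v = vif(X)
    assert np.isinf(v["x1"]) and np.isinf(v["x2"])
    assert np.isfinite(v["x3"])


def test_vif_matches_brute_force_auxiliary_regressions():
    rng = np.random.default_rng(5)
    z = rng.normal(size=300)
    X = pd.DataFrame(
        {
            "x1": z + 0.6 * rng.normal(size=300),
            "x2": z + 0.6 * rng.normal(size=300),
            "x3": rng.normal(size=300),
        }
    )
    v = vif(X)
    for j, name in enumerate(X.columns):
        y = X[name].to_numpy()
        others = np.column_stack([np.ones(300), X.drop(columns=name).to_numpy()])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        r2 = 1 - np.sum((y - others @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
        assert v[name] == pytest.approx(1 / (1 - r2), abs=1e-10)


# --- Jonckheere-Terpstra -----------------------------------------------------

def _jt_brute_force(groups):
    """Independent oracle: statistic by direct pair counting and exact
    one-sided p by enumerating every permutation of the pooled values."""
    def stat(gs):
        s = 0.0
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                for a in gs[i]:
                    for b in gs[j]:
                        s += (a < b) + 0.5 * (a == b)
        return s

    observed = stat(groups)
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    count = total = 0
    for perm in itertools.permutations(pooled):
        gs, k = [], 0
        for n in sizes:
            gs.append(perm[k:k + n])
            k += n
        total += 1
        count += stat(gs) >= observed - 1e-12
    return observed, count / total


def test_jt_maximal_separation_example():
    res = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
    assert res.statistic == 12
    assert res.method == "exact"
    assert res.p_value == pytest.approx(8 / 720, abs=1e-12)


def test_jt_identical_groups_are_null():
    res = jonckheere_terpstra([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert res.statistic == pytest.approx(res.expected)
    assert 0.4 <= res.p_value <= 0.75


def test_jt_reversal_maps_statistic_to_complement():
    rng = np.random.default_rng(2)
    groups = [rng.normal(size=4).tolist(), rng.normal(size=3).tolist(),
              rng.normal(size=5).tolist()]
    fwd = jonckheere_terpstra(groups)
    rev = jonckheere_terpstra(groups[::-1])
    total_pairs = 4 * 3 + 4 * 5 + 3 * 5
    assert fwd.statistic + rev.statistic == pytest.approx(total_pairs)


@pytest.mark.parametrize("sizes,seed", [((2, 2, 2), 0), ((3, 2, 2), 1), ((2, 3), 2),
                                        ((4, 3), 3), ((3, 3, 3), 4), ((2, 2, 2, 2), 5)])
def test_jt_exact_p_matches_exhaustive_permutation_oracle(sizes, seed):
    rng = np.random.default_rng(seed)
    # integers in a narrow range force ties
    groups = [rng.integers(0, 4, size=n).tolist() for n in sizes]
    res = jonckheere_terpstra(groups)
    stat, p = _jt_brute_force(groups)
    assert res.method == "exact"
    assert res.statistic == pytest.approx(stat)
    assert res.p_value == pytest.approx(p, abs=1e-12)


def test_jt_normal_approximation_detects_strong_trend(default_cohort):
    df, _ = default_cohort
    w1 = df[df["wave"] == 1]
    groups = [g["moca"].dropna().to_numpy()
              for _, g in w1.groupby("cystatin_quartile", observed=True)]
    res = jonckheere_terpstra(groups, alternative="decreasing")
    assert res.method == "normal"
    assert res.p_value < 1e-6


def test_jt_input_validation():
    with pytest.raises(ValueError):
        jonckheere_terpstra([[1, 2]])
    with pytest.raises(ValueError):
        jonckheere_terpstra([[1, 2], []])


# --- WMH ordinal model -------------------------------------------------------

def test_wmh_bin_edges():
    assert wmh_to_ordinal(0) == 1
    assert wmh_to_ordinal(9) == 1
    assert wmh_to_ordinal(10) == 2
    assert wmh_to_ordinal(19) == 2
    assert wmh_to_ordinal(20) == 3
    assert wmh_to_ordinal(29) == 3
    assert wmh_to_ordinal(30) == 4
    assert wmh_to_ordinal(35) == 4
    with pytest.raises(ValueError):
        wmh_to_ordinal(-1)


def test_wmh_generated_categories_match_binned_scores(default_cohort):
    df, _ = default_cohort
    mri = df[(df["wave"] == 3) & (df["mri_subset"] == 1)]
    np.testing.assert_array_equal(
        wmh_to_ordinal(mri["scheltens_score"]), mri["wmh_category"].to_numpy()
    )


def _po_data(n, log_or, seed):
    """Proportional-odds data with known exposure log-odds ratio."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    latent = log_or * x + rng.logistic(size=n)
    cat = 1 + (latent > -1.0) + (latent > 0.5) + (latent > 2.0)
    score = np.array([0, 0, 10, 20, 30])[cat] + rng.integers(0, 9, n)
    return pd.DataFrame({
        "scheltens_score": score, "exposure": x,
        "pid": np.arange(n), "mri_subset": 1, "wave": 3,
    })


def test_ordinal_model_recovers_generating_log_odds_ratio():
    df = _po_data(1500, log_or=1.2, seed=8)
    # exposure enters unstandardised so the coefficient is on the generating scale
    expected_std = 1.2 * df["exposure"].std()
    res = fit_ordinal_wmh(df, ModelSpec(outcome="scheltens_score", exposure="exposure"))
    assert abs(res.beta_std - expected_std) < 3 * res.se
    assert res.odds_ratio > 1.0
    assert res.ci_low < res.odds_ratio < res.ci_high


def test_ordinal_null_coverage_over_seeds():
    """Exposure independent of severity: the 95% CI covers OR=1 in ~95% of seeds."""
    cover = 0
    n_seeds = 60
    for seed in range(n_seeds):
        df = _po_data(300, log_or=0.0, seed=seed)
        res = fit_ordinal_wmh(df, ModelSpec(outcome="scheltens_score", exposure="exposure"))
        cover += res.ci_low <= 1.0 <= res.ci_high
    assert 0.85 <= cover / n_seeds <= 1.0


def test_ordinal_constant_outcome_rejected():
    df = _po_data(200, log_or=0.0, seed=1)
    df["scheltens_score"] = 5.0
    with pytest.raises(ValueError, match="constant"):
        fit_ordinal_wmh(df, ModelSpec(outcome="scheltens_score", exposure="exposure"))


# --- volumes, Bonferroni, CBF ------------------------------------------------

def test_volume_normalisation_matches_hand_arithmetic():
    t = pd.DataFrame({
        "gm_left": [300.0, 310.0, 290.0],
        "gm_right": [310.0, 300.0, 280.0],
        "icv": [1500.0, 1525.0, 1400.0],
    })
    out = normalize_volumes(t, ["gm"])
    ratio = (t["gm_left"] + t["gm_right"]) / t["icv"]
    expected = (ratio - ratio.mean()) / ratio.std(ddof=1)
    np.testing.assert_allclose(out["gm_norm"], expected, atol=1e-12)


def test_volume_hemisphere_swap_invariance():
    rng = np.random.default_rng(3)
    t = pd.DataFrame({
        "r_left": rng.normal(300, 10, 20), "r_right": rng.normal(300, 10, 20),
        "icv": rng.normal(1500, 50, 20),
    })
    swapped = t.rename(columns={"r_left": "r_right", "r_right": "r_left"})
    np.testing.assert_allclose(
        normalize_volumes(t, ["r"])["r_norm"],
        normalize_volumes(swapped, ["r"])["r_norm"],
        atol=1e-12,
    )


def test_volume_requires_positive_icv():
    t = pd.DataFrame({"r_left": [1.0, 2.0], "r_right": [1.0, 2.0], "icv": [100.0, -5.0]})
    with pytest.raises(ValueError):
        normalize_volumes(t, ["r"])


def test_bonferroni_threshold_values():
    assert bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
    assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
    with pytest.raises(ValueError):
        bonferroni_threshold(1.5, 10)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


def test_cbf_contrast_negative_for_top_quartile_and_sign_flips(default_cohort):
    df, _ = default_cohort
    res = cbf_quartile_contrast(df)
    assert res.beta_std < 0
    assert res.p_value < 0.05
    inv = cbf_quartile_contrast(df, invert=True)
    assert inv.beta_std == pytest.approx(-res.beta_std, abs=1e-9)


def test_cbf_contrast_null_when_cbf_permuted(default_cohort):
    df, _ = default_cohort
    df = df.copy()
    mri = (df["mri_subset"] == 1) & (df["wave"] == 3)
    vals = df.loc[mri, "cbf_gm"].to_numpy().copy()
    df.loc[mri, "cbf_gm"] = np.random.default_rng(0).permutation(vals)
    res = cbf_quartile_contrast(df)
    assert abs(res.beta_std) < 3 * res.se
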