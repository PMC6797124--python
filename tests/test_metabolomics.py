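"""Feature-table preprocessing and the native significance analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toxflux.metabolomics import (
    filter_near_constant,
    impute_missing,
    internal_standard_normalize,
    pareto_scale,
    pca_calls,
    plsda_permutation_test,
    plsda_vip_calls,
    preprocess,
    total_sum_normalize,
    ttest_fc_calls,
)
from toxflux.synthetic import INTERNAL_STANDARD, make_omics_scenario

from conftest import make_feature_table


def test_impute_half_global_minimum_positive():
    t = make_feature_table(
        {"f1": [0.4, np.nan, 2.0, 1.0], "f2": [np.nan, 5.0, 3.0, 0.9]}, n_control=2
    )
    out = impute_missing(t).intensities
    assert out.loc["f1"].iloc[1] == pytest.approx(0.2)
    assert out.loc["f2"].iloc[0] == pytest.approx(0.2)
    assert out.loc["f1"].iloc[0] == pytest.approx(0.4)  # untouched


def test_impute_identity_without_missing():
    t = make_feature_table({"f1": [1.0, 2.0, 3.0, 4.0]}, n_control=2)
    pd.testing.assert_frame_equal(impute_missing(t).intensities, t.intensities)


def test_impute_all_missing_errors():
    t = make_feature_table({"f1": [np.nan] * 4}, n_control=2)
    with pytest.raises(ValueError):
        impute_missing(t)


def test_filter_drops_floor_of_fraction():
    values = {f"f{i}": list(np.random.default_rng(i).uniform(1, 10, 6)) for i in range(100)}
    t = make_feature_table(values, n_control=3)
    assert len(filter_near_constant(t, 0.05).features) == 95
    assert filter_near_constant(t, 0.0).features == t.features


def test_filter_removes_constant_feature_first():
    t = make_feature_table(
        {"flat": [5.0] * 6, "varied": [1, 9, 2, 8, 3, 7.0], "wiggly": [2, 5, 1, 8, 4, 9.0]},
        n_control=3,
    )
    out = filter_near_constant(t, fraction=0.34)  # floor(0.34*3) = 1 feature
    assert "flat" not in out.features and len(out.features) == 2


def test_filter_protect_keeps_internal_standard():
    t = make_feature_table(
        {"flat": [5.0] * 6, "std": [5.0] * 6, "varied": [1, 9, 2, 8, 3, 7.0]},
        n_control=3,
    )
    out = filter_near_constant(t, fraction=0.34, protect={"std"})
    assert "std" in out.features and "flat" not in out.features


def test_total_sum_normalizes_to_percentages():
    t = make_feature_table({"f1": [1.0, 30.0], "f2": [3.0, 70.0]}, n_control=1)
    out = total_sum_normalize(t).intensities
    assert out.iloc[:, 0].tolist() == pytest.approx([25.0, 75.0])
    assert out.sum(axis=0).tolist() == pytest.approx([100.0, 100.0], abs=1e-9)


def test_total_sum_zero_sample_named():
    t = make_feature_table({"f1": [0.0, 1.0], "f2": [0.0, 2.0]}, n_control=1)
    with pytest.raises(ValueError, match="s1"):
        total_sum_normalize(t)


def test_internal_standard_division_and_drop():
    t = make_feature_table({"f1": [4.0, 8.0], "std": [2.0, 2.0]}, n_control=1)
    out = internal_standard_normalize(t, "std")
    assert out.intensities.loc["f1"].tolist() == pytest.approx([2.0, 4.0])
    assert "std" not in out.features


def test_internal_standard_scale_invariance():
    t = make_feature_table({"f1": [4.0, 8.0], "std": [2.0, 4.0]}, n_control=1)
    doubled = t.with_values(t.intensities * 2)
    pd.testing.assert_frame_equal(
        internal_standard_normalize(t, "std").intensities,
        internal_standard_normalize(doubled, "std").intensities,
    )


def test_internal_standard_missing_or_zero_errors():
    t = make_feature_table({"f1": [4.0, 8.0], "std": [2.0, 0.0]}, n_control=1)
    with pytest.raises(ValueError):
        internal_standard_normalize(t, "std")
    with pytest.raises(KeyError):
        internal_standard_normalize(t, "nope")


def test_pareto_scaling_values_and_degenerate_feature():
    t = make_feature_table({"f1": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]}, n_control=1)
    out = pareto_scale(t).intensities
    assert out.loc["f1"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
    assert out.loc["flat"].tolist() == pytest.approx([0.0, 0.0, 0.0])
    assert out.mean(axis=1).abs().max() < 1e-12


def test_pipeline_runs_stages_in_order():
    sc = make_omics_scenario(n_features=30, n_per_group=4, missing_rate=0.1, seed=0)
    log: list[str] = []
    stages = preprocess(sc.table, standard_feature=INTERNAL_STANDARD, _stage_log=log)
    assert log == ["imputed", "filtered", "normalized", "scaled"]
    assert INTERNAL_STANDARD not in stages["normalized"].features
    assert not stages["scaled"].intensities.isna().any().any()


def test_ttest_identical_groups_nothing_significant():
    rng = np.random.default_rng(1)
    data = rng.lognormal(3, 0.5, size=(40, 12))
    t = make_feature_table(
        {f"f{i}": list(row) for i, row in enumerate(data)}, n_control=6
    )
    # make the two groups literally identical
    X = t.intensities
    X.iloc[:, 6:] = X.iloc[:, :6].to_numpy()
    calls = ttest_fc_calls(t)
    assert not calls.significant.any()
    assert (calls.p == 1.0).all()  # zero between-group difference, paired columns
    assert calls.log2_fc.abs().max() < 1e-12


def test_bh_adjustment_dominates_raw_p():
    sc = make_omics_scenario(n_features=80, n_per_group=6, seed=4,
                             effects={"F0003": 1.5})
    calls = ttest_fc_calls(sc.table)
    assert (calls.p_adj >= calls.p - 1e-15).all()
    # BH adjusted p is monotone in the raw-p ranking
    ranked = calls.sort_values("p")
    assert (np.diff(ranked.p_adj) >= -1e-15).all()


def test_ttest_power_matches_noncentral_t_oracle():
    """Monte-Carlo detection rate agrees with the closed-form power of a
    Welch test under single-effect BH correction.

    Oracle: the planted feature (4-sd log2 shift, n=6/6) must reach raw
    p < alpha/m to survive BH when it carries the only real effect among
    m features; the probability of that is a noncentral-t tail."""
    n, m, effect, sd, alpha = 6, 50, 2.0, 0.5, 0.05
    df = 2 * n - 2
    nc = effect / (sd * np.sqrt(2 / n))
    crit = stats.t.ppf(1 - (alpha / m) / 2, df)
    oracle_power = 1 - stats.nct.cdf(crit, df, nc) + stats.nct.cdf(-crit, df, nc)
    sims, hits = 60, 0
    for seed in range(sims):
        sc = make_omics_scenario(n_features=m, n_per_group=n,
                                 effects={"F0001": effect}, noise_sd=sd, seed=seed)
        hits += bool(ttest_fc_calls(sc.table).loc["F0001", "significant"])
    rate = hits / sims
    margin = 3 * np.sqrt(oracle_power * (1 - oracle_power) / sims)
    assert abs(rate - oracle_power) <= margin + 0.02


def test_pca_two_anticorrelated_features_dominate_pc1():
    rng = np.random.default_rng(0)
    signal = np.linspace(-3, 3, 10)
    t = make_feature_table(
        {
            "up": list(signal),
            "down": list(-signal),
            "tiny1": list(rng.normal(0, 0.01, 10)),
            "tiny2": list(rng.normal(0, 0.01, 10)),
        },
        n_control=5,
    )
    res = pca_calls(pareto_scale(t), loading_threshold=0.1, components=(1,))
    assert bool(res["calls"].loc["up", "significant"])
    assert bool(res["calls"].loc["down", "significant"])
    # anticorrelated features: equal-magnitude PC1 loadings, opposite sign
    l1 = res["loadings"]["PC1"]
    assert abs(l1["up"]) == pytest.approx(abs(l1["down"]), rel=1e-6)


def test_pca_threshold_above_unit_norm_selects_nothing():
    sc = make_omics_scenario(n_features=20, n_per_group=4, seed=2)
    scaled = pareto_scale(impute_missing(sc.table))
    res = pca_calls(scaled, loading_threshold=1.1, components=(1, 2))
    assert not res["calls"].significant.any()


def test_pca_rank_limit_errors():
    t = make_feature_table({"f1": [1.0, 2.0, 3.0, 4.0], "f2": [2.0, 1.0, 4.0, 3.0]},
                           n_control=2)
    with pytest.raises(ValueError, match="rank"):
        pca_calls(pareto_scale(t), components=(1, 2, 3, 4))


def test_vip_mean_square_is_one_and_zero_weight_feature_insignificant():
    sc = make_omics_scenario(n_features=40, n_per_group=6, seed=8,
                             effects={"F0005": 2.0})
    stages = preprocess(sc.table, standard_feature=INTERNAL_STANDARD)
    res = plsda_vip_calls(stages["scaled"], components=(1, 2))
    for col in res["vip"]:
        assert (res["vip"][col] ** 2).mean() == pytest.approx(1.0, abs=1e-9)


def test_vip_maximal_for_planted_separating_feature():
    hits = 0
    for seed in range(20):
        sc = make_omics_scenario(n_features=30, n_per_group=6, seed=seed,
                                 effects={"F0001": 3.0}, noise_sd=0.3)
        # log2 scale so the planted shift is not drowned by baseline leverage
        scaled = pareto_scale(
            sc.table.with_values(np.log2(sc.table.intensities))
        )
        res = plsda_vip_calls(scaled, components=(1,))
        hits += res["vip"]["VIP1"].idxmax() == "F0001"
    assert hits >= 19


def test_plsda_single_group_errors():
    t = make_feature_table({"f1": [1.0, 2.0, 3.0, 4.0]}, n_control=4)
    with pytest.raises(ValueError):
        plsda_vip_calls(t)
    with pytest.raises(ValueError):
        plsda_permutation_test(t, n_perm=10)


def test_permutation_p_floor_for_fully_separated_groups():
    n_perm = 99
    t = make_feature_table(
        {"f1": [1, 1.1, 0.9, 5, 5.1, 4.9], "f2": [2, 2.1, 1.9, 9, 9.2, 8.8]},
        n_control=3,
    )
    res = plsda_permutation_test(pareto_scale(t), n_perm=n_perm, seed=0)
    assert res["p_value"] == pytest.approx(1 / (1 + n_perm))


def test_permutation_test_deterministic_given_seed():
    sc = make_omics_scenario(n_features=15, n_per_group=4, seed=3)
    scaled = pareto_scale(impute_missing(sc.table))
    a = plsda_permutation_test(scaled, n_perm=30, seed=11)
    b = plsda_permutation_test(scaled, n_perm=30, seed=11)
    assert a["p_value"] == b["p_value"]
    assert np.array_equal(a["null"], b["null"])
    with pytest.raises(ValueError):
        plsda_permutation_test(scaled, n_perm=0)
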