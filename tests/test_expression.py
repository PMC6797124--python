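"""Condition means, GPR capacity evaluation and E-Flux bound construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from toxflux.datasets import BC1_RULE, bc1_profiles
from toxflux.expression import (
    ConditionProfile,
    ExpressionMatrix,
    build_condition_models,
    condition_means,
    evaluate_gpr,
    library_size_normalize,
    normalize_capacities,
    reaction_capacities,
)
from toxflux.gpr import GPRNode, parse_gpr
from toxflux.synthetic import make_network_scenario

from conftest import build_chain_model


def matrix_from(genes, columns, condition_of):
    values = pd.DataFrame(columns, index=genes)
    return ExpressionMatrix(values=values, condition_of=condition_of)


def test_condition_means_and_fallback():
    m = matrix_from(
        ["g1", "g2"],
        {"a": [10.0, 30.0], "b": [20.0, 50.0], "c": [7.0, 7.0]},
        {"a": "ctl", "b": "ctl", "c": "trt"},
    )
    prof = condition_means(m, "ctl")
    assert prof.mean_expression["g1"] == 15.0
    assert prof.mean_expression["g2"] == 40.0
    assert prof.fallback_mean == pytest.approx(27.5)


def test_unknown_condition_raises():
    m = matrix_from(["g1"], {"a": [1.0]}, {"a": "ctl"})
    with pytest.raises(KeyError):
        condition_means(m, "nope")


def test_duplicate_gene_ids_rejected():
    values = pd.DataFrame([[1.0], [2.0]], index=["g1", "g1"], columns=["a"])
    with pytest.raises(ValueError, match="duplicate"):
        ExpressionMatrix(values=values, condition_of={"a": "ctl"})


@pytest.mark.parametrize(
    "rule,means,expected",
    [
        ("g1 and g2", {"g1": 2.0, "g2": 3.0}, 2.0),
        ("(g1 and g2) or g3", {"g1": 2.0, "g2": 3.0, "g3": 5.0}, 7.0),
        ("g1 or g2", {"g1": 2.0, "g2": 3.0}, 5.0),
    ],
)
def test_min_sum_evaluation(rule, means, expected):
    prof = ConditionProfile("c", means, fallback_mean=100.0)
    assert evaluate_gpr(parse_gpr(rule), prof) == expected


def test_measured_zero_is_a_value_not_missing():
    prof = ConditionProfile("c", {"g1": 0.0, "g2": 5.0}, fallback_mean=100.0)
    assert evaluate_gpr(parse_gpr("g1 and g2"), prof) == 0.0


def test_unmeasured_gene_uses_fallback():
    prof = ConditionProfile("c", {"g1": 50.0}, fallback_mean=7.0)
    assert evaluate_gpr(parse_gpr("g1 and gX"), prof) == 7.0


def test_bc1_complex_capacity_from_published_means():
    """Published subunit means: CYT1 is the conjunct minimum in both
    configurations and conditions; the or-sum doubles it."""
    gpr = parse_gpr(BC1_RULE)
    profs = bc1_profiles()
    assert evaluate_gpr(gpr, profs["control"]) == pytest.approx(2 * 122.69)
    assert evaluate_gpr(gpr, profs["treated"]) == pytest.approx(2 * 89.59)
    for conj in gpr.children:
        assert evaluate_gpr(conj, profs["control"]) == pytest.approx(122.69)
        assert evaluate_gpr(conj, profs["treated"]) == pytest.approx(89.59)


def test_normalize_capacities_linear_scaling():
    assert normalize_capacities({"r1": 200.0, "r2": 500.0}) == {"r1": 400.0, "r2": 1000.0}
    assert normalize_capacities({"r1": 7.0}) == {"r1": 1000.0}


def test_normalize_capacities_scale_invariance():
    caps = {"r1": 3.0, "r2": 11.0, "r3": 0.4}
    doubled = {k: 2 * v for k, v in caps.items()}
    assert normalize_capacities(caps) == pytest.approx(normalize_capacities(doubled))


def test_normalize_all_zero_errors():
    with pytest.raises(ValueError, match="zero"):
        normalize_capacities({"r1": 0.0})


def _bounded_chain(expr_cols):
    model = build_chain_model()
    model.reactions["R1"].gpr = parse_gpr("g1")
    matrix = matrix_from(["g1"], expr_cols, {"a": "control", "b": "treated"})
    return model, matrix


def test_equal_expression_gives_identical_condition_models():
    model, matrix = _bounded_chain({"a": [40.0], "b": [40.0]})
    models = build_condition_models(model, matrix)
    assert (
        models["control"].reactions["R1"].upper_bound
        == models["treated"].reactions["R1"].upper_bound
    )


def test_halved_bottleneck_gene_halves_treated_bound_joint_mode():
    model, matrix = _bounded_chain({"a": [40.0], "b": [20.0]})
    models = build_condition_models(model, matrix, mode="joint")
    ctl = models["control"].reactions["R1"].upper_bound
    trt = models["treated"].reactions["R1"].upper_bound
    assert ctl == pytest.approx(1000.0)  # joint maximum maps to the scale
    assert trt == pytest.approx(ctl / 2)


def test_per_condition_mode_erases_the_ratio():
    model, matrix = _bounded_chain({"a": [40.0], "b": [20.0]})
    models = build_condition_models(model, matrix, mode="per_condition")
    assert (
        models["control"].reactions["R1"].upper_bound
        == models["treated"].reactions["R1"].upper_bound
    )


def test_joint_normalization_preserves_capacity_ratios():
    sc = make_network_scenario(n_linear=4, seed=11, bottleneck_fraction=0.3)
    models = build_condition_models(sc.model, sc.expression, mode="joint")
    profiles = {
        c: condition_means(sc.expression, c) for c in ("control", "treated")
    }
    caps = {c: reaction_capacities(sc.model, p).raw_capacity for c, p in profiles.items()}
    for rid in caps["control"]:
        if caps["control"][rid] > 0 and caps["treated"][rid] > 0:
            bound_ratio = (
                models["treated"].reactions[rid].upper_bound
                / models["control"].reactions[rid].upper_bound
            )
            raw_ratio = caps["treated"][rid] / caps["control"][rid]
            assert bound_ratio == pytest.approx(raw_ratio, abs=1e-12)


def test_build_condition_model_keeps_structure_and_other_bounds():
    sc = make_network_scenario(n_linear=3, seed=5)
    models = build_condition_models(sc.model, sc.expression)
    for cond_model in models.values():
        assert cond_model.structural_signature() == sc.model.structural_signature()
        # non-GPR reactions keep their defaults
        assert cond_model.reactions["EX_M0"].lower_bound == -1000.0
        assert cond_model.reactions["BIOMASS"].upper_bound == 1000.0


def test_mirror_reversible_sets_negative_lower_bound():
    model = build_chain_model()
    model.reactions["R1"].gpr = parse_gpr("g1")
    model.reactions["R1"].lower_bound = -5.0
    matrix = matrix_from(["g1"], {"a": [40.0], "b": [40.0]}, {"a": "control", "b": "treated"})
    models = build_condition_models(model, matrix, mirror_reversible=True)
    r1 = models["control"].reactions["R1"]
    assert r1.lower_bound == -r1.upper_bound


# --- properties ---------------------------------------------------------------

_gene_pool = [f"g{i}" for i in range(6)]


def _random_tree(draw, depth=2):
    if depth == 0 or draw(st.booleans()):
        return GPRNode("gene", gene_id=draw(st.sampled_from(_gene_pool)))
    kind = draw(st.sampled_from(["and", "or"]))
    children = tuple(
        _random_tree(draw, depth - 1) for _ in range(draw(st.integers(2, 3)))
    )
    return GPRNode(kind, children=children)


@st.composite
def tree_and_profile(draw):
    tree = _random_tree(draw)
    means = {g: draw(st.floats(0.0, 100.0)) for g in _gene_pool}
    bump_gene = draw(st.sampled_from(_gene_pool))
    bump = draw(st.floats(0.1, 50.0))
    return tree, means, bump_gene, bump


@settings(max_examples=500, derandomize=True)
@given(tree_and_profile())
def test_capacity_monotone_in_any_gene(case):
    """Raising one gene's expression never lowers any rule's capacity."""
    tree, means, gene, bump = case
    base = evaluate_gpr(tree, ConditionProfile("c", means, 10.0))
    raised = dict(means)
    raised[gene] = raised[gene] + bump
    assert evaluate_gpr(tree, ConditionProfile("c", raised, 10.0)) >= base


@settings(max_examples=200, derandomize=True)
@given(tree_and_profile())
def test_and_bounded_by_members_or_sums_exactly(case):
    tree, means, _, _ = case
    prof = ConditionProfile("c", means, 10.0)
    if tree.kind == "and":
        cap = evaluate_gpr(tree, prof)
        for child in tree.children:
            assert cap <= evaluate_gpr(child, prof) + 1e-12
    elif tree.kind == "or":
        assert evaluate_gpr(tree, prof) == pytest.approx(
            sum(evaluate_gpr(c, prof) for c in tree.children)
        )


def test_library_size_normalization_undoes_depth_differences():
    rng = np.random.default_rng(0)
    base = pd.DataFrame(
        rng.uniform(10, 100, size=(50, 3)), columns=["a", "b", "c"],
        index=[f"g{i}" for i in range(50)],
    )
    scaled = base.copy()
    scaled["b"] *= 3.0  # sample b sequenced 3x deeper
    norm = library_size_normalize(scaled)
    pd.testing.assert_frame_equal(
        norm / norm.iloc[0], base / base.iloc[0], rtol=1e-9
    )
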