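"""Desk-scale synthetic fixtures with known ground truth.

Two generators, both pure functions of their parameters and seed:

* :func:`make_network_scenario` builds a small linear metabolic network
  (exchange -> chain -> biomass drain, optional parallel branches and
  complex/isoenzyme GPRs) together with a two-condition expression matrix
  in which one chosen gene's treated mean is a stated fraction of its
  control mean.  After expression-derived bounds, that gene's reaction is
  the unique binding constraint in the treated condition, so the limiting
  reaction/gene and the growth in both conditions are known in closed form.

* :func:`make_omics_scenario` draws a two-group feature table with
  log-normal intensities, planted log2 fold changes, uniform missingness
  and an internal-standard feature, emulating a replicated two-group MS
  design (default six biological replicates per group).

Expression replicates are drawn log-normally around the planted condition
means and then rescaled so their arithmetic mean equals the planted mean
exactly; condition means computed from the matrix therefore reproduce the
planted profile, making the closed-form growth exact rather than
asymptotic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ConditionProfile, ExpressionMatrix, evaluate_gpr
from .gpr import GPRNode
from .metabolomics import FeatureTable
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "NetworkScenario",
    "OmicsScenario",
    "make_network_scenario",
    "make_omics_scenario",
    "make_random_flux_network",
    "INTERNAL_STANDARD",
]

CONDITIONS = ("control", "treated")
INTERNAL_STANDARD = "internal_standard"


@dataclass(frozen=True)
class NetworkScenario:
    model: MetabolicModel
    expression: ExpressionMatrix
    planted_limiting_reaction: str
    planted_limiting_gene: str
    # closed-form optimal growth per condition (chain topology)
    analytic_growth: dict[str, float]
    bottleneck_fraction: float
    planted_means: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class OmicsScenario:
    table: FeatureTable
    planted_features: dict[str, float]  # feature -> log2 effect size
    noise_sd: float
    missing_rate: float
    seed: int


def _make_gpr(
    rng: np.random.Generator,
    gene_counter: list[int],
    spec: dict,
    force_conjunct: bool,
) -> tuple[GPRNode, list[str]]:
    """One reaction's GPR per the complexes spec; returns (tree, genes)."""

    def new_gene() -> str:
        gene_counter[0] += 1
        return f"g{gene_counter[0]:03d}"

    p_and = spec.get("p_and", 0.0)
    p_or = 0.0 if force_conjunct else spec.get("p_or", 0.0)
    lo, hi = spec.get("subunits", (2, 3))
    u = rng.random()
    if u < p_or:
        shared = new_gene() if spec.get("shared_gene") else None
        branches = []
        for _ in range(2):
            genes = [new_gene() for _ in range(int(rng.integers(lo, hi + 1)))]
            if shared:
                genes.append(shared)
            branches.append(
                GPRNode("and", children=tuple(GPRNode("gene", gene_id=g) for g in genes))
            )
        node = GPRNode("or", children=tuple(branches))
    elif u < p_or + p_and:
        genes = [new_gene() for _ in range(int(rng.integers(lo, hi + 1)))]
        node = GPRNode("and", children=tuple(GPRNode("gene", gene_id=g) for g in genes))
    else:
        node = GPRNode("gene", gene_id=new_gene())
    return node, sorted(set(node.genes()))


def make_network_scenario(
    n_linear: int = 3,
    n_branches: int = 0,
    complexes: dict | None = None,
    seed: int = 0,
    bottleneck_fraction: float = 0.5,
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    scale: float = 1000.0,
) -> NetworkScenario:
    """Linear network + two-condition expression with a planted bottleneck.

    The chain has ``n_linear`` GPR-bearing internal reactions between an
    uptake exchange and the biomass drain; ``n_branches`` adds parallel
    unconstrained reactions over an extra terminal segment (alternate
    optima for FVA exercises).  ``complexes`` controls GPR shapes:
    ``{"p_and": float, "p_or": float, "subunits": (lo, hi),
    "shared_gene": bool}``; the planted reaction is always a single gene or
    a pure complex so its capacity is a minimum.  One randomly chosen gene
    of one randomly chosen chain reaction has treated mean =
    ``bottleneck_fraction`` x control mean and the lowest mean in both
    conditions, so under joint normalization treated/control growth equals
    the fraction exactly.
    """
    if n_linear < 2:
        raise ValueError("n_linear must be >= 2")
    if not 0 < bottleneck_fraction < 1:
        raise ValueError("bottleneck_fraction must be in (0, 1) for the bound to bind")
    rng = np.random.default_rng(seed)
    spec = complexes or {}
    gene_counter = [0]

    model = MetabolicModel(name=f"synthetic-chain-{seed}", version="1")
    n_mets = n_linear + 1 + (1 if n_branches else 0)
    for i in range(n_mets):
        model.add_metabolite(Metabolite(id=f"M{i}", name=f"metabolite {i}", compartment="c"))

    # uptake = negative flux through the single-metabolite exchange
    model.add_reaction(
        Reaction(id="EX_M0", name="M0 exchange", stoichiometry={"M0": -1.0},
                 lower_bound=-scale, upper_bound=0.0)
    )
    planted_index = int(rng.integers(1, n_linear + 1))
    gprs: dict[str, GPRNode] = {}
    for i in range(1, n_linear + 1):
        gpr, _ = _make_gpr(rng, gene_counter, spec, force_conjunct=(i == planted_index))
        rid = f"R{i}"
        gprs[rid] = gpr
        model.add_reaction(
            Reaction(id=rid, name=f"chain step {i}",
                     stoichiometry={f"M{i - 1}": -1.0, f"M{i}": 1.0},
                     lower_bound=0.0, upper_bound=scale, gpr=gpr)
        )
    last = n_linear
    if n_branches:
        for b in range(n_branches):
            model.add_reaction(
                Reaction(id=f"B{b + 1}", name=f"parallel branch {b + 1}",
                         stoichiometry={f"M{n_linear}": -1.0, f"M{n_linear + 1}": 1.0},
                         lower_bound=0.0, upper_bound=scale)
            )
        last = n_linear + 1
    model.add_reaction(
        Reaction(id="BIOMASS", name="growth", stoichiometry={f"M{last}": -1.0},
                 lower_bound=0.0, upper_bound=scale)
    )
    model.objective_reaction_id = "BIOMASS"

    planted_rid = f"R{planted_index}"
    planted_genes = sorted(set(gprs[planted_rid].genes()))
    planted_gene = planted_genes[int(rng.integers(0, len(planted_genes)))]

    # control means: planted gene clearly below everything else so its
    # reaction is the unique capacity minimum in both conditions
    all_genes = sorted({g for gpr in gprs.values() for g in gpr.genes()})
    control_means = {g: float(rng.uniform(250.0, 400.0)) for g in all_genes}
    control_means[planted_gene] = float(rng.uniform(80.0, 120.0))
    treated_means = dict(control_means)
    treated_means[planted_gene] = bottleneck_fraction * control_means[planted_gene]

    samples, condition_of = [], {}
    columns = {}
    for cond, means in (("control", control_means), ("treated", treated_means)):
        for r in range(n_replicates):
            sid = f"{cond}_{r + 1}"
            samples.append(sid)
            condition_of[sid] = cond
        draws = {}
        for g in all_genes:
            raw = means[g] * np.exp(rng.normal(0.0, noise_sd, size=n_replicates))
            draws[g] = raw * (means[g] / raw.mean())  # exact realized mean
        for r in range(n_replicates):
            columns[f"{cond}_{r + 1}"] = {g: draws[g][r] for g in all_genes}
    values = pd.DataFrame({s: columns[s] for s in samples}).loc[all_genes]
    expression = ExpressionMatrix(values=values, condition_of=condition_of)

    # closed-form growth: bounds are scale * capacity / M with M the joint
    # maximum capacity; the chain transmits the minimum bound
    profiles = {
        cond: ConditionProfile(cond, means, float(np.mean(list(means.values()))))
        for cond, means in (("control", control_means), ("treated", treated_means))
    }
    caps = {
        cond: {rid: evaluate_gpr(gpr, prof) for rid, gpr in gprs.items()}
        for cond, prof in profiles.items()
    }
    M = max(max(c.values()) for c in caps.values())
    analytic = {
        cond: min(scale, min(scale * v / M for v in caps[cond].values()))
        for cond in CONDITIONS
    }
    return NetworkScenario(
        model=model,
        expression=expression,
        planted_limiting_reaction=planted_rid,
        planted_limiting_gene=planted_gene,
        analytic_growth=analytic,
        bottleneck_fraction=bottleneck_fraction,
        planted_means={"control": control_means, "treated": treated_means},
    )


def make_random_flux_network(seed: int = 0, max_reactions: int = 6) -> MetabolicModel:
    """Random tiny flux LP with finite bounds (zero flux always feasible).

    Every metabolite gets an exchange; internal reactions connect random
    metabolite pairs with coefficients in {1, 2}.  Small enough for the
    exhaustive vertex-enumeration reference solver; bounded because all
    bounds are finite and feasible because 0 lies in every bound interval.
    """
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(1, 4))
    model = MetabolicModel(name=f"random-lp-{seed}", version="1")
    for i in range(n_mets):
        model.add_metabolite(Metabolite(id=f"m{i}", compartment="c"))

    def bounds() -> tuple[float, float]:
        ub = float(np.round(rng.uniform(0.5, 10.0), 3))
        lb = 0.0 if rng.random() < 0.5 else -float(np.round(rng.uniform(0.5, 10.0), 3))
        return lb, ub

    count = 0
    for i in range(n_mets):
        lb, ub = bounds()
        model.add_reaction(
            Reaction(id=f"EX_m{i}", stoichiometry={f"m{i}": -1.0},
                     lower_bound=lb, upper_bound=ub)
        )
        count += 1
    n_internal = int(rng.integers(1, max_reactions - count + 1))
    for k in range(n_internal):
        if n_mets == 1:
            stoich = {"m0": float(rng.choice([-2.0, -1.0, 1.0, 2.0]))}
        else:
            a, b = rng.choice(n_mets, size=2, replace=False)
            stoich = {
                f"m{a}": -float(rng.choice([1.0, 2.0])),
                f"m{b}": float(rng.choice([1.0, 2.0])),
            }
        lb, ub = bounds()
        model.add_reaction(
            Reaction(id=f"R{k}", stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
        )
    rids = list(model.reactions)
    model.objective_reaction_id = rids[int(rng.integers(0, len(rids)))]
    return model


def make_omics_scenario(
    n_features: int = 200,
    n_per_group: int = 6,
    effects: dict[str, float] | None = None,
    noise_sd: float = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
    platform: str = "GC",
) -> OmicsScenario:
    """Two-group log-normal feature table with planted fold changes.

    ``effects`` maps feature ids (``F0001`` ...) to log2 effect sizes added
    to the treated group's mean.  An internal-standard feature with zero
    effect and no missingness is always appended.  log2 intensity ~
    Normal(baseline + group x effect, noise_sd); missing entries are masked
    uniformly at ``missing_rate``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    effects = dict(effects or {})
    features = [f"F{i + 1:04d}" for i in range(n_features)]
    unknown = set(effects) - set(features)
    if unknown:
        raise ValueError(f"effects reference unknown features: {sorted(unknown)}")

    baselines = rng.uniform(10.0, 20.0, size=n_features)
    samples = [f"control_{i + 1}" for i in range(n_per_group)] + [
        f"treated_{i + 1}" for i in range(n_per_group)
    ]
    group_of = {s: ("treated" if s.startswith("treated") else "control") for s in samples}
    is_treated = np.array([group_of[s] == "treated" for s in samples], dtype=float)

    effect_vec = np.array([effects.get(f, 0.0) for f in features])
    log2x = (
        baselines[:, None]
        + np.outer(effect_vec, is_treated)
        + rng.normal(0.0, noise_sd, size=(n_features, len(samples)))
    )
    X = np.power(2.0, log2x)
    if missing_rate > 0:
        mask = rng.random(size=X.shape) < missing_rate
        X = np.where(mask, np.nan, X)

    # internal standard: steady signal, never missing
    std_row = np.power(2.0, 12.0 + rng.normal(0.0, 0.05, size=len(samples)))
    values = pd.DataFrame(
        np.vstack([X, std_row]), index=features + [INTERNAL_STANDARD], columns=samples
    )
    table = FeatureTable(intensities=values, group_of=group_of, platform=platform)
    return OmicsScenario(
        table=table,
        planted_features=effects,
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        seed=seed,
    )
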