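"""Limiting-reaction and limiting-gene diagnosis.

A growth difference between two condition models (same network, different
expression-derived upper bounds) is traced to the bounds that cause it:

1. screen the slower model for reactions operating at (or within a
   tolerance of) their expression-derived upper bound;
2. rank candidates by slack, preferring reactions that are near-saturated
   in the faster (control) condition too;
3. transplant bounds between the models and re-solve to confirm that a
   candidate alone reproduces / rescues the growth difference;
4. iterate: after relaxing one limiting bound, newly saturated reactions
   form the next tier, until the control growth is recovered.

At the gene level, the lowest-expressed subunit of each complex
configuration (each or-branch of the GPR) is the capacity-limiting gene,
because capacity of an ``and`` conjunct is the minimum subunit expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .expression import ConditionProfile
from .fba import FluxRange, FluxSolution, flux_variability, solve_fba
from .gpr import GPRNode
from .model import DEFAULT_UPPER_BOUND, MetabolicModel

__all__ = [
    "SaturationRecord",
    "BoundExperiment",
    "LimitingGeneReport",
    "DiagnosisStep",
    "DiagnosisReport",
    "find_saturated",
    "bound_transplant",
    "test_limiting",
    "identify_limiting_set",
    "limiting_gene",
    "flux_ratio_table",
]


@dataclass(frozen=True)
class SaturationRecord:
    """A reaction whose attainable flux is within ``tolerance`` of its
    expression-derived upper bound."""

    reaction_id: str
    flux: float
    upper_bound: float
    condition: str = ""

    @property
    def slack(self) -> float:
        return self.upper_bound - self.flux


@dataclass(frozen=True)
class BoundExperiment:
    """Outcome of manually editing upper bounds and re-solving."""

    edits: dict[str, float]
    status: str
    objective_value: float | None
    edited_fluxes: dict[str, float] | None


@dataclass(frozen=True)
class ConjunctVerdict:
    """Per complex-configuration (or-branch) expression minima."""

    genes: tuple[str, ...]
    expression: dict[str, dict[str, float]]  # condition -> gene -> mean
    minima: dict[str, float]  # condition -> min expression
    argmin: dict[str, tuple[str, ...]]  # condition -> tied minimal genes


@dataclass(frozen=True)
class LimitingGeneReport:
    branches: tuple[ConjunctVerdict, ...]
    # condition -> genes minimal in EVERY branch (empty if no consensus)
    verdict: dict[str, tuple[str, ...]]


@dataclass(frozen=True)
class DiagnosisStep:
    reaction_id: str
    candidates: tuple[SaturationRecord, ...]
    objective_before: float
    objective_after: float
    # control model with this reaction's treated bound installed:
    control_with_treated_bound: float | None = None


@dataclass
class DiagnosisReport:
    control_objective: float
    treated_objective: float
    steps: list[DiagnosisStep] = field(default_factory=list)
    recovered: bool = False
    explanation: str = ""

    @property
    def limiting_reactions(self) -> list[str]:
        return [s.reaction_id for s in self.steps]


def find_saturated(
    solution: FluxSolution | None,
    ranges: list[FluxRange] | None,
    model: MetabolicModel,
    tolerance: float = 0.1,
    condition: str = "",
    bound_ceiling: float = DEFAULT_UPPER_BOUND,
    use_fva_max: bool = True,
) -> list[SaturationRecord]:
    """Reactions operating within ``tolerance`` of their upper bound.

    By default the attainable flux is the FVA maximum, which is robust to
    alternate optima; ``use_fva_max=False`` screens the single solution
    vector instead (vertex-dependent, matches a literal one-solution
    reading).  Reactions whose upper bound equals or exceeds
    ``bound_ceiling`` (the model default, carrying no expression
    information) are excluded.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    flux_of: dict[str, float] = {}
    if use_fva_max:
        if ranges is None:
            raise ValueError("FVA-based screening requires ranges")
        flux_of = {r.reaction_id: r.max_flux for r in ranges}
    else:
        if solution is None or not solution.optimal:
            raise ValueError("vertex screening requires an optimal solution")
        flux_of = dict(solution.fluxes)
    records = []
    for rid, flux in flux_of.items():
        ub = model.reactions[rid].upper_bound
        if ub >= bound_ceiling:
            continue
        if ub - flux <= tolerance:
            records.append(SaturationRecord(rid, flux, ub, condition))
    records.sort(key=lambda r: (r.slack, r.reaction_id))
    return records


def bound_transplant(
    target: MetabolicModel, source: MetabolicModel, reaction_ids: list[str]
) -> MetabolicModel:
    """Copy of ``target`` with the listed upper bounds taken from ``source``."""
    out = target.copy()
    for rid in reaction_ids:
        if rid not in target.reactions or rid not in source.reactions:
            raise KeyError(f"reaction {rid!r} absent from one of the models")
        out.reactions[rid].upper_bound = source.reactions[rid].upper_bound
        if out.reactions[rid].lower_bound > out.reactions[rid].upper_bound:
            out.reactions[rid].lower_bound = out.reactions[rid].upper_bound
    return out


def test_limiting(model: MetabolicModel, edits: dict[str, float]) -> BoundExperiment:
    """Re-solve the model with manually edited upper bounds."""
    if not edits:
        raise ValueError("edits must be nonempty")
    if any(ub < 0 for ub in edits.values()):
        raise ValueError("edited upper bounds must be nonnegative")
    probe = model.copy()
    for rid, ub in edits.items():
        if rid not in probe.reactions:
            raise KeyError(f"unknown reaction {rid!r}")
        probe.reactions[rid].upper_bound = ub
        if probe.reactions[rid].lower_bound > ub:
            probe.reactions[rid].lower_bound = ub
    sol = solve_fba(probe)
    return BoundExperiment(
        edits=dict(edits),
        status=sol.status,
        objective_value=sol.objective_value,
        edited_fluxes={rid: sol.fluxes[rid] for rid in edits} if sol.optimal else None,
    )


def _screen(model: MetabolicModel, tolerance: float, condition: str,
            bound_ceiling: float) -> list[SaturationRecord]:
    candidates = [
        rid for rid, rxn in model.reactions.items() if rxn.upper_bound < bound_ceiling
    ]
    if not candidates:
        return []
    ranges = flux_variability(model, fraction_of_optimum=1.0, reactions=candidates)
    return find_saturated(None, ranges, model, tolerance=tolerance, condition=condition,
                          bound_ceiling=bound_ceiling)


def identify_limiting_set(
    control: MetabolicModel,
    treated: MetabolicModel,
    tolerance: float = 0.1,
    recovery_tol: float = 1e-3,
    max_depth: int = 5,
    bound_ceiling: float = DEFAULT_UPPER_BOUND,
) -> DiagnosisReport:
    """Ordered list of reactions whose bounds explain the growth gap.

    Iteratively: screen the (working) treated model for saturated
    reactions, rank by slack with near-saturation in the control as a
    tie-preference, transplant the top candidate's control bound into the
    working model, re-solve, and repeat until the control objective is
    recovered within ``recovery_tol`` or ``max_depth`` is hit.  For the
    first candidate the reverse transplant (treated bound into control) is
    also solved as confirmation that it reproduces the treated growth.
    """
    ctrl_sol = solve_fba(control)
    tre_sol = solve_fba(treated)
    if not (ctrl_sol.optimal and tre_sol.optimal):
        raise RuntimeError("both condition models must be optimally solvable")
    report = DiagnosisReport(
        control_objective=ctrl_sol.objective_value,
        treated_objective=tre_sol.objective_value,
    )
    if abs(ctrl_sol.objective_value - tre_sol.objective_value) <= recovery_tol:
        report.recovered = True
        report.explanation = "no growth gap between the condition models"
        return report

    control_sat = {
        r.reaction_id for r in _screen(control, tolerance, "control", bound_ceiling)
    }
    work = treated.copy()
    current = tre_sol.objective_value
    for depth in range(max_depth):
        sats = _screen(work, tolerance, "treated", bound_ceiling)
        # only reactions whose control bound is actually looser can help
        sats = [
            s for s in sats
            if control.reactions[s.reaction_id].upper_bound > s.upper_bound + 1e-12
        ]
        if not sats:
            report.explanation = (
                "no saturated expression-bounded reaction with a looser control "
                "bound remains; the residual gap is not explained by single bounds"
            )
            return report
        # prefer candidates near-saturated in the control too, then slack order
        sats.sort(key=lambda s: (s.reaction_id not in control_sat, s.slack, s.reaction_id))
        step_made = False
        for cand in sats:
            confirm = None
            if depth == 0:
                confirmed = bound_transplant(control, treated, [cand.reaction_id])
                confirm_sol = solve_fba(confirmed)
                confirm = confirm_sol.objective_value if confirm_sol.optimal else math.nan
            trial = bound_transplant(work, control, [cand.reaction_id])
            sol = solve_fba(trial)
            if sol.optimal and sol.objective_value > current + 1e-9:
                report.steps.append(
                    DiagnosisStep(
                        reaction_id=cand.reaction_id,
                        candidates=tuple(sats),
                        objective_before=current,
                        objective_after=sol.objective_value,
                        control_with_treated_bound=confirm,
                    )
                )
                work = trial
                current = sol.objective_value
                step_made = True
                break
        if not step_made:
            report.explanation = "no single-bound transplant improves the objective"
            return report
        if current >= ctrl_sol.objective_value - recovery_tol:
            report.recovered = True
            return report
    report.explanation = f"max depth {max_depth} reached before recovery"
    return report


def limiting_gene(
    gpr: GPRNode, profiles: list[ConditionProfile]
) -> LimitingGeneReport:
    """Lowest-expressed subunit per complex configuration and condition.

    ``gpr`` must be an or-of-conjuncts (isoenzyme alternatives of AND
    complexes), a single conjunct, or a single gene.  Ties are reported
    jointly, never broken silently.
    """
    if gpr.kind == "or":
        conjuncts = gpr.children
    else:
        conjuncts = (gpr,)
    branches = []
    for conj in conjuncts:
        if conj.kind == "or":
            raise ValueError("rule is not an or-of-conjuncts")
        genes = (conj.gene_id,) if conj.kind == "gene" else tuple(
            c.gene_id if c.kind == "gene" else None for c in conj.children
        )
        if None in genes:
            raise ValueError("conjuncts must be flat (genes only)")
        expression = {
            p.condition: {g: p.expression_of(g) for g in genes} for p in profiles
        }
        minima = {cond: min(vals.values()) for cond, vals in expression.items()}
        argmin = {
            cond: tuple(g for g in genes if vals[g] == minima[cond])
            for cond, vals in expression.items()
        }
        branches.append(
            ConjunctVerdict(genes=genes, expression=expression, minima=minima, argmin=argmin)
        )
    verdict: dict[str, tuple[str, ...]] = {}
    for p in profiles:
        sets = [set(b.argmin[p.condition]) for b in branches]
        consensus = set.intersection(*sets) if sets else set()
        verdict[p.condition] = tuple(sorted(consensus))
    return LimitingGeneReport(branches=tuple(branches), verdict=verdict)


def flux_ratio_table(
    numerator: FluxSolution,
    denominator: FluxSolution,
    pathway_filter: set[str] | None = None,
):
    """Per-reaction flux ratios (numerator/denominator, e.g. treated/control).

    0/0 reactions are tagged ``"0/0"`` and nonzero-over-zero ``"inf"``; both
    carry NaN ratios and are meant to be excluded from summary statistics.
    Returns a pandas DataFrame (reaction, numerator_flux, denominator_flux,
    ratio, tag) suitable for map-overlay export.
    """
    import numpy as np
    import pandas as pd

    if not (numerator.optimal and denominator.optimal):
        raise ValueError("both solutions must be optimal")
    rows = []
    for rid, den in denominator.fluxes.items():
        if pathway_filter is not None and rid not in pathway_filter:
            continue
        num = numerator.fluxes.get(rid, 0.0)
        if den == 0.0:
            tag = "0/0" if num == 0.0 else "inf"
            ratio = np.nan
        else:
            tag = ""
            ratio = num / den
        rows.append((rid, num, den, ratio, tag))
    return pd.DataFrame(
        rows, columns=["reaction", "numerator_flux", "denominator_flux", "ratio", "tag"]
    )
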