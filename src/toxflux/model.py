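"""Constraint-based metabolic model containers.

A :class:`MetabolicModel` is a stoichiometric network: metabolites in
compartments, reactions with flux bounds in mmol/(gDW*hour), optional GPR
rules, and one designated objective reaction (growth, for the models this
package targets).  Sign convention: uptake through an exchange reaction is
negative flux, secretion positive; report tables flip uptake to positive
under "IN FLUXES".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gpr import GPRNode, gene_ids

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "validate_model",
]

DEFAULT_UPPER_BOUND = 1000.0


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A reaction with stoichiometry (metabolite id -> signed coefficient),
    flux bounds, and an optional GPR rule."""

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER_BOUND
    gpr: GPRNode | None = None

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions touch exactly one metabolite."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,  # GPR trees are immutable
        )


class ModelValidationError(ValueError):
    """Raised when a model violates structural invariants; lists all findings."""

    def __init__(self, findings: list[str]):
        super().__init__("; ".join(findings))
        self.findings = findings


@dataclass
class MetabolicModel:
    name: str = ""
    version: str = ""
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective_reaction_id: str = ""

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    @property
    def genes(self) -> list[str]:
        """Gene index collected from all GPR rules, sorted."""
        out: set[str] = set()
        for rxn in self.reactions.values():
            if rxn.gpr is not None:
                out.update(gene_ids(rxn.gpr))
        return sorted(out)

    def gpr_reactions(self) -> list[str]:
        return [rid for rid, rxn in self.reactions.items() if rxn.gpr is not None]

    def exchange_reactions(self) -> list[str]:
        return [rid for rid, rxn in self.reactions.items() if rxn.is_exchange]

    def copy(self, name: str | None = None) -> "MetabolicModel":
        return MetabolicModel(
            name=self.name if name is None else name,
            version=self.version,
            metabolites=dict(self.metabolites),
            reactions={rid: rxn.copy() for rid, rxn in self.reactions.items()},
            objective_reaction_id=self.objective_reaction_id,
        )

    def structural_signature(self) -> tuple:
        """Stoichiometry, objective and GPR identity; bounds excluded.

        Two models that differ only in flux bounds (e.g. condition models
        built from the same base) have equal signatures.
        """
        from .gpr import render_gpr

        return (
            self.objective_reaction_id,
            tuple(sorted(self.metabolites)),
            tuple(
                (
                    rid,
                    tuple(sorted(rxn.stoichiometry.items())),
                    render_gpr(rxn.gpr) if rxn.gpr else None,
                )
                for rid, rxn in sorted(self.reactions.items())
            ),
        )


def validate_model(model: MetabolicModel) -> list[str]:
    """Check structural invariants; returns findings (empty means valid).

    Findings are data, not exceptions: each names the offending entity and
    the violated rule.
    """
    findings: list[str] = []
    for mid, met in model.metabolites.items():
        if not mid:
            findings.append("metabolite with empty id")
        if not met.compartment:
            findings.append(f"metabolite {mid!r}: empty compartment")
    for rid, rxn in model.reactions.items():
        if not rid:
            findings.append("reaction with empty id")
        if not rxn.stoichiometry:
            findings.append(f"reaction {rid!r}: empty stoichiometry")
        for mid, coef in rxn.stoichiometry.items():
            if coef == 0:
                findings.append(f"reaction {rid!r}: zero coefficient for {mid!r}")
            if mid not in model.metabolites:
                findings.append(f"reaction {rid!r}: undefined metabolite {mid!r}")
        if rxn.lower_bound > rxn.upper_bound:
            findings.append(
                f"reaction {rid!r}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
    if not model.objective_reaction_id:
        findings.append("model has no objective reaction")
    elif model.objective_reaction_id not in model.reactions:
        findings.append(
            f"objective reaction {model.objective_reaction_id!r} not in model"
        )
    return findings
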