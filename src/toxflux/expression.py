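"""Expression-derived reaction bounds (adapted E-Flux).

A gene x sample expression matrix with condition labels is reduced to
per-condition mean profiles; each GPR-bearing reaction's catalytic
capacity is then the rule evaluated with ``min`` over complex subunits
(``and``) and ``sum`` over isoenzymes / alternative complexes (``or``).
Genes without expression data take the mean expression of all measured
genes in that condition.  Capacities are linearly rescaled to [0, scale]
(default 1000, the conventional default upper bound in genome-scale
models) and installed as reaction upper bounds, yielding one model per
condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gpr import GPRNode
from .model import MetabolicModel

__all__ = [
    "ExpressionMatrix",
    "ConditionProfile",
    "CapacityVector",
    "condition_means",
    "evaluate_gpr",
    "reaction_capacities",
    "normalize_capacities",
    "build_condition_model",
    "build_condition_models",
    "library_size_normalize",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values (normalized counts) plus a
    sample -> condition map.  Missing values are allowed (NaN)."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.condition_of[s])
        return list(seen)

    @classmethod
    def from_tsv(cls, expr_path: str | Path, conditions_path: str | Path) -> "ExpressionMatrix":
        """Read a gene x sample TSV (first column = gene id) and a
        two-column sample/condition TSV."""
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        cond = pd.read_csv(conditions_path, sep="\t", index_col=0)
        condition_of = cond.iloc[:, 0].astype(str).to_dict()
        return cls(values=values.astype(float), condition_of=condition_of)


@dataclass(frozen=True)
class ConditionProfile:
    """Per-condition mean expression with a fallback mean for genes the
    experiment did not measure."""

    condition: str
    mean_expression: Mapping[str, float]
    fallback_mean: float

    def expression_of(self, gene: str) -> float:
        return self.mean_expression.get(gene, self.fallback_mean)


@dataclass(frozen=True)
class CapacityVector:
    """Raw (un-normalized, expression-unit) capacities of GPR-bearing reactions."""

    condition: str
    raw_capacity: Mapping[str, float]


def condition_means(matrix: ExpressionMatrix, condition: str) -> ConditionProfile:
    """Arithmetic per-gene mean over the condition's samples.

    The fallback mean (used later for genes absent from the matrix) is the
    mean of the per-gene means of all genes with data in this condition.
    """
    samples = [s for s in matrix.samples if matrix.condition_of[s] == condition]
    if not samples:
        raise KeyError(f"unknown condition {condition!r}")
    sub = matrix.values[samples]
    means = sub.mean(axis=1, skipna=True).dropna()
    return ConditionProfile(
        condition=condition,
        mean_expression=means.to_dict(),
        fallback_mean=float(means.mean()),
    )


def evaluate_gpr(gpr: GPRNode, profile: ConditionProfile) -> float:
    """Reaction capacity implied by a GPR rule under a condition profile.

    Leaf: the gene's mean expression (fallback mean if unmeasured).
    ``and``: minimum over children — the scarcest complex subunit caps
    assembly.  ``or``: sum over children — isoenzymes contribute additively.
    A measured expression of exactly 0 is a value, not a missing entry.
    """
    if gpr.kind == "gene":
        return profile.expression_of(gpr.gene_id)
    vals = [evaluate_gpr(child, profile) for child in gpr.children]
    return min(vals) if gpr.kind == "and" else sum(vals)


def reaction_capacities(model: MetabolicModel, profile: ConditionProfile) -> CapacityVector:
    """Raw capacities for every GPR-bearing reaction; others are absent."""
    caps = {
        rid: evaluate_gpr(rxn.gpr, profile)
        for rid, rxn in model.reactions.items()
        if rxn.gpr is not None
    }
    return CapacityVector(condition=profile.condition, raw_capacity=caps)


def normalize_capacities(
    capacities: Mapping[str, float],
    scale: float = 1000.0,
    reference_max: float | None = None,
) -> dict[str, float]:
    """Rescale raw capacities linearly into [0, scale].

    ``reference_max`` supplies the normalizing maximum M; pass the maximum
    over BOTH conditions' capacities for joint-mode normalization (so the
    two condition models share a flux scale), or leave None to use this
    vector's own maximum (per-condition mode).
    """
    if not capacities:
        raise ValueError("empty capacity vector")
    if scale <= 0:
        raise ValueError("scale must be positive")
    M = max(capacities.values()) if reference_max is None else reference_max
    if M <= 0:
        raise ValueError("all capacities are zero; cannot normalize")
    return {rid: scale * v / M for rid, v in capacities.items()}


def build_condition_model(
    model: MetabolicModel,
    profile: ConditionProfile,
    scale: float = 1000.0,
    reference_max: float | None = None,
    mirror_reversible: bool = False,
) -> MetabolicModel:
    """Copy of ``model`` with expression-derived upper bounds installed.

    Only GPR-bearing reactions are re-bounded; lower bounds are left at
    model defaults unless ``mirror_reversible`` is set, in which case a
    reversible reaction's lower bound becomes minus its new upper bound
    (classic E-Flux behaviour).
    """
    caps = reaction_capacities(model, profile)
    bounds = normalize_capacities(caps.raw_capacity, scale=scale, reference_max=reference_max)
    mode = "per_condition" if reference_max is None else "joint"
    out = model.copy(name=f"{model.name}[{profile.condition},{mode}]")
    for rid, ub in bounds.items():
        rxn = out.reactions[rid]
        rxn.upper_bound = ub
        if mirror_reversible and rxn.lower_bound < 0:
            rxn.lower_bound = -ub
        elif rxn.lower_bound > ub:
            rxn.lower_bound = ub  # keep lb <= ub for irreversibly-forced reactions
    return out


def build_condition_models(
    model: MetabolicModel,
    matrix: ExpressionMatrix,
    conditions: list[str] | None = None,
    mode: str = "joint",
    scale: float = 1000.0,
    mirror_reversible: bool = False,
) -> dict[str, MetabolicModel]:
    """One expression-bounded model per condition.

    ``mode="joint"`` (default) normalizes all conditions by a single
    maximum capacity so growth ratios across conditions are meaningful;
    ``mode="per_condition"`` rescales each condition by its own maximum.
    """
    if mode not in ("joint", "per_condition"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    conditions = conditions or matrix.conditions
    profiles = {c: condition_means(matrix, c) for c in conditions}
    capacities = {c: reaction_capacities(model, p).raw_capacity for c, p in profiles.items()}
    reference = (
        max(max(v.values()) for v in capacities.values()) if mode == "joint" else None
    )
    return {
        c: build_condition_model(
            model,
            profiles[c],
            scale=scale,
            reference_max=reference,
            mirror_reversible=mirror_reversible,
        )
        for c in conditions
    }


def library_size_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios library-size normalization for raw counts.

    Size factor per sample = median over genes of count / geometric mean of
    the gene across samples (genes with any zero are excluded from the
    reference, as usual).
    """
    log_counts = np.log(counts.where(counts > 0))
    log_geo_mean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo_mean)
    if not usable.any():
        raise ValueError("no gene is positive in every sample; cannot normalize")
    log_ratios = log_counts.loc[usable].sub(log_geo_mean[usable], axis=0)
    size_factors = np.exp(log_ratios.median(axis=0))
    return counts.div(size_factors, axis=1)
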