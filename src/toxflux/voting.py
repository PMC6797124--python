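"""Majority-vote selection of relevant metabolites.

Nine analyses (t-test, PCA, PLS-DA, sPLS-DA, OPLS-DA, EBAM, SAM, Random
Forest, SVM) each contribute a 0/1 significance call per compound; a
compound is "relevant" when at least a threshold number of analyses
(default 5 of 9) call it significant.  Three of the columns are computed
natively by :mod:`toxflux.metabolomics`; the remaining analyses are
consumed as externally produced indicator columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "STANDARD_ANALYSES",
    "VoteMatrix",
    "assemble_votes",
    "select_relevant",
    "combine_platforms",
]

STANDARD_ANALYSES = (
    "t-test",
    "PCA",
    "PLS-DA",
    "sPLS-DA",
    "OPLS-DA",
    "EBAM",
    "SAM",
    "Random Forest",
    "SVM",
)


@dataclass(frozen=True)
class VoteMatrix:
    """Compound x analysis 0/1 indicator matrix with per-column provenance."""

    votes: pd.DataFrame  # index = compound ids, columns = analysis names, int 0/1
    provenance: Mapping[str, str] = field(default_factory=dict)  # column -> native|external

    def __post_init__(self) -> None:
        if self.votes.columns.duplicated().any():
            raise ValueError("duplicate analysis columns")
        vals = self.votes.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("vote entries must be 0 or 1")

    @property
    def compounds(self) -> list[str]:
        return list(self.votes.index)

    @property
    def analyses(self) -> list[str]:
        return list(self.votes.columns)

    def counts(self) -> pd.Series:
        return self.votes.sum(axis=1)


def assemble_votes(
    native_calls: Mapping[str, pd.Series],
    external_indicators: pd.DataFrame | None = None,
    compounds: list[str] | None = None,
) -> VoteMatrix:
    """Combine native boolean call series and external 0/1 indicator columns.

    ``native_calls`` maps analysis name -> boolean/0-1 Series indexed by
    compound.  Compounds absent from any one source get a 0 in that column
    (a feature a method's preprocessing dropped simply casts no vote).  The
    compound universe defaults to the union of all sources.
    """
    columns: dict[str, pd.Series] = {}
    provenance: dict[str, str] = {}
    for name, series in native_calls.items():
        columns[name] = series.astype(int)
        provenance[name] = "native"
    if external_indicators is not None:
        vals = external_indicators.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("external indicators must be strictly 0/1")
        for name in external_indicators.columns:
            if name in columns:
                raise ValueError(f"duplicate analysis column {name!r}")
            columns[name] = external_indicators[name].astype(int)
            provenance[name] = "external"
    if not columns:
        raise ValueError("no analysis columns supplied")
    if compounds is None:
        universe: dict[str, None] = {}
        for series in columns.values():
            for cid in series.index:
                universe.setdefault(cid)
        compounds = list(universe)
    votes = pd.DataFrame(0, index=pd.Index(compounds, name="compound"),
                         columns=list(columns))
    for name, series in columns.items():
        present = series.index.intersection(votes.index)
        votes.loc[present, name] = series.loc[present].to_numpy()
    return VoteMatrix(votes=votes, provenance=provenance)


def select_relevant(votes: VoteMatrix, threshold: int = 5) -> pd.DataFrame:
    """Compounds significant in at least ``threshold`` analyses.

    Returns a DataFrame (compound index, column ``votes``) sorted by vote
    count descending, then compound id.
    """
    if not 1 <= threshold <= len(votes.analyses):
        raise ValueError("threshold must be between 1 and the number of analyses")
    counts = votes.counts()
    selected = counts[counts >= threshold]
    out = selected.rename("votes").to_frame()
    out["_id"] = out.index
    out = out.sort_values(["votes", "_id"], ascending=[False, True]).drop(columns="_id")
    return out


def _normalize_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def combine_platforms(sel_a: set[str] | list[str], sel_b: set[str] | list[str]) -> dict:
    """Union report across platforms with name normalization
    (trim/case-fold/collapse whitespace; no synonym resolution)."""
    a = {_normalize_name(x) for x in sel_a}
    b = {_normalize_name(x) for x in sel_b}
    inter = sorted(a & b)
    return {
        "n_union": len(a | b),
        "n_intersection": len(inter),
        "intersection": inter,
    }
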