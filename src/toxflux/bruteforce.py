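"""Exhaustive vertex-enumeration reference solver for tiny flux LPs.

For  max c.v, S.v = 0, lb <= v <= ub  with all bounds finite, some optimum
lies at a vertex of the polytope, where at least n - rank(S) variables sit
on a bound.  This module enumerates every such candidate vertex directly
(all variable subsets x all bound assignments) and takes the best feasible
one.  Exponential in the network size, so only usable for networks of a
handful of reactions — which is exactly its purpose: an independent
cross-check of the simplex-based :func:`toxflux.fba.solve_fba` that shares
no code path with it.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from .model import MetabolicModel

__all__ = ["enumerate_optimum"]

_FEAS_TOL = 1e-8


def enumerate_optimum(model: MetabolicModel) -> float | None:
    """Optimal objective value by exhaustive vertex enumeration.

    Returns None when no feasible vertex exists (infeasible LP).  All
    bounds must be finite (the LP is then automatically bounded).
    """
    rids = list(model.reactions)
    n = len(rids)
    lb = np.array([model.reactions[r].lower_bound for r in rids], dtype=float)
    ub = np.array([model.reactions[r].upper_bound for r in rids], dtype=float)
    if not (np.isfinite(lb).all() and np.isfinite(ub).all()):
        raise ValueError("vertex enumeration requires finite bounds")
    mets = list(model.metabolites)
    S = np.zeros((len(mets), n))
    met_index = {m: i for i, m in enumerate(mets)}
    for j, rid in enumerate(rids):
        for mid, coef in model.reactions[rid].stoichiometry.items():
            S[met_index[mid], j] = coef
    c = np.zeros(n)
    c[rids.index(model.objective_reaction_id)] = 1.0

    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - rank
    best: float | None = None

    scale = max(1.0, np.abs(S).max() if S.size else 1.0)
    for fixed in combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        for choice in product((0, 1), repeat=n_fixed):
            v = np.empty(n)
            v[list(fixed)] = [lb[j] if c_ == 0 else ub[j] for j, c_ in zip(fixed, choice)]
            if free:
                A = S[:, free]
                b = -S[:, list(fixed)] @ v[list(fixed)] if n_fixed else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = sol
            residual = np.abs(S @ v).max() if S.size else 0.0
            if residual > _FEAS_TOL * scale:
                continue
            if (v < lb - _FEAS_TOL).any() or (v > ub + _FEAS_TOL).any():
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    return best
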