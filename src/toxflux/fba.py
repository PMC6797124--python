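"""Flux balance analysis on :class:`~toxflux.model.MetabolicModel`.

The growth LP is  max c.v  subject to  S.v = 0  and  lb <= v <= ub,
solved with HiGHS through :func:`scipy.optimize.linprog`.  Flux
variability analysis (FVA) re-optimizes each reaction's flux in both
directions while holding the objective at a stated fraction of its
optimum; phase planes sweep one exchange flux and record maximal growth.

Degenerate optima are the rule in genome-scale models: a single optimal
flux vector is solver-dependent, so everything downstream that must be
reproducible consumes FVA ranges or the objective value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "FluxSolution",
    "FluxRange",
    "PhasePlane",
    "solve_fba",
    "flux_variability",
    "phase_plane",
    "summarize_exchanges",
    "STEADY_STATE_TOL",
]

STEADY_STATE_TOL = 1e-6


@dataclass(frozen=True)
class FluxSolution:
    """One optimal flux vector (reaction id -> flux), its objective value,
    and the solver status ('optimal', 'infeasible' or 'unbounded')."""

    status: str
    objective_value: float | None = None
    fluxes: dict[str, float] | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float


@dataclass(frozen=True)
class PhasePlane:
    """Maximal growth as a function of one exchange reaction's uptake level.

    ``grid`` holds (uptake level, maximal growth) pairs; levels whose LP is
    infeasible are absent.
    """

    exchange_id: str
    grid: tuple[tuple[float, float], ...]


class _LinearProblem:
    """Cached LP data (S matrix, bounds, objective index) for one model."""

    def __init__(self, model: MetabolicModel):
        self.reaction_ids = list(model.reactions)
        self.met_index = {mid: i for i, mid in enumerate(model.metabolites)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(self.reaction_ids):
            for mid, coef in model.reactions[rid].stoichiometry.items():
                rows.append(self.met_index[mid])
                cols.append(j)
                vals.append(coef)
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.met_index), len(self.reaction_ids))
        )
        self.bounds = [
            (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
            for rid in self.reaction_ids
        ]
        self.obj_index = self.reaction_ids.index(model.objective_reaction_id)

    def optimize(
        self,
        sense_vector: np.ndarray,
        maximize: bool = True,
        extra_A_ub=None,
        extra_b_ub=None,
    ):
        c = -sense_vector if maximize else sense_vector
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=extra_A_ub,
            b_ub=extra_b_ub,
            bounds=self.bounds,
            method="highs",
        )
        return res


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def solve_fba(model: MetabolicModel, _lp: _LinearProblem | None = None) -> FluxSolution:
    """Maximize the objective reaction's flux at steady state.

    On success the steady-state residual max|S.v| is asserted below
    :data:`STEADY_STATE_TOL`.
    """
    lp = _lp or _LinearProblem(model)
    e = np.zeros(len(lp.reaction_ids))
    e[lp.obj_index] = 1.0
    res = lp.optimize(e, maximize=True)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status=status)
    v = res.x
    residual = np.abs(lp.S @ v).max() if lp.S.shape[0] else 0.0
    if residual > STEADY_STATE_TOL:
        raise ArithmeticError(f"steady-state violation {residual:.2e} exceeds tolerance")
    return FluxSolution(
        status="optimal",
        objective_value=float(v[lp.obj_index]),
        fluxes={rid: float(x) for rid, x in zip(lp.reaction_ids, v)},
    )


def flux_variability(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    reactions: list[str] | None = None,
    _lp: _LinearProblem | None = None,
) -> list[FluxRange]:
    """Min/max flux per reaction with the objective held at
    ``fraction_of_optimum`` times its optimum.

    A tiny slack (1e-9) is applied to the objective floor so the optimal
    face itself stays numerically feasible at fraction 1.
    """
    lp = _lp or _LinearProblem(model)
    base = solve_fba(model, _lp=lp)
    if not base.optimal:
        raise RuntimeError(f"base FBA problem is {base.status}; FVA undefined")
    n = len(lp.reaction_ids)
    floor = fraction_of_optimum * base.objective_value - 1e-9
    A_ub = np.zeros((1, n))
    A_ub[0, lp.obj_index] = -1.0
    b_ub = np.array([-floor])
    targets = reactions if reactions is not None else lp.reaction_ids
    index = {rid: i for i, rid in enumerate(lp.reaction_ids)}
    out: list[FluxRange] = []
    for rid in targets:
        j = index[rid]
        e = np.zeros(n)
        e[j] = 1.0
        lo = lp.optimize(e, maximize=False, extra_A_ub=A_ub, extra_b_ub=b_ub)
        hi = lp.optimize(e, maximize=True, extra_A_ub=A_ub, extra_b_ub=b_ub)
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA subproblem for {rid!r} failed")
        out.append(FluxRange(rid, float(lo.x[j]), float(hi.x[j])))
    return out


def phase_plane(
    model: MetabolicModel,
    exchange_id: str,
    levels: list[float] | None = None,
    points: int = 20,
) -> PhasePlane:
    """Maximal growth while the exchange reaction's uptake is pinned to each
    level.

    Levels are uptake magnitudes (nonnegative); internally uptake is
    negative flux, so the exchange bound is fixed at minus the level.  When
    ``levels`` is omitted, ``points`` levels are spread evenly from 0 to the
    exchange's current maximal uptake |lower bound|.
    """
    if exchange_id not in model.reactions:
        raise KeyError(f"unknown exchange reaction {exchange_id!r}")
    if levels is not None and len(levels) == 0:
        raise ValueError("levels must be nonempty")
    rxn = model.reactions[exchange_id]
    if levels is None:
        levels = list(np.linspace(0.0, abs(rxn.lower_bound), points))
    grid: list[tuple[float, float]] = []
    for level in levels:
        if level < 0:
            raise ValueError("uptake levels must be nonnegative")
        probe = model.copy()
        probe.reactions[exchange_id].lower_bound = -level
        probe.reactions[exchange_id].upper_bound = -level
        sol = solve_fba(probe)
        if sol.optimal:
            grid.append((float(level), max(sol.objective_value, 0.0)))
    return PhasePlane(exchange_id=exchange_id, grid=tuple(grid))


def summarize_exchanges(
    solution: FluxSolution,
    ranges: list[FluxRange],
    model: MetabolicModel,
    zero_tol: float = 1e-9,
):
    """Exchange fluxes split into IN (uptake) and OUT (secretion) tables.

    Mirrors the conventional FBA summary layout: uptake fluxes are shown
    positive under IN, each with its FVA range, sorted by |flux| descending,
    and the objective value is appended as its own row.  Returns a pandas
    DataFrame with columns (section, reaction, name, flux, range_min,
    range_max).
    """
    import pandas as pd

    if not solution.optimal:
        raise ValueError("cannot summarize a non-optimal solution")
    range_of = {r.reaction_id: r for r in ranges}
    rows = []
    for rid in model.exchange_reactions():
        flux = solution.fluxes.get(rid, 0.0)
        if abs(flux) <= zero_tol:
            continue
        rxn = model.reactions[rid]
        rng = range_of.get(rid)
        if flux < 0:  # uptake: flip sign for presentation, and flip the range
            rows.append(
                ("IN", rid, rxn.name, -flux,
                 -rng.max_flux if rng else np.nan, -rng.min_flux if rng else np.nan)
            )
        else:
            rows.append(
                ("OUT", rid, rxn.name, flux,
                 rng.min_flux if rng else np.nan, rng.max_flux if rng else np.nan)
            )
    rows.sort(key=lambda r: (r[0], -abs(r[3])))
    rows.append(
        ("OBJECTIVE", model.objective_reaction_id,
         model.reactions[model.objective_reaction_id].name,
         solution.objective_value, np.nan, np.nan)
    )
    return pd.DataFrame(
        rows, columns=["section", "reaction", "name", "flux", "range_min", "range_max"]
    )
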