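"""Budget-constrained minimum-shortfall site selection with a boundary penalty.

The objective, minimized over binary unit selections x subject to
sum(cost * x) <= budget_fraction * sum(cost) and locked-in units:

    sum_f max(0, T_f - sum_u a_fu x_u) / T_f
        + boundary_penalty * exposed_boundary(x)

where T_f = target_fraction * sum_u a_fu is each feature's representation
target (shortfalls are normalized by the target so features on different
scales are commensurate), and exposed_boundary counts cell sides between
selected and unselected units (full weight) plus selected cell sides on the
grid's outer perimeter (weighted by edge_factor, which softens the
penalization of coastline units).

Three solvers share this objective: an exact mixed-integer program
(HiGHS via scipy), a randomized greedy heuristic used for scenario
ensembles, and an exhaustive enumerator for small test instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse

from .occurrences import PlanningGrid


class InfeasibleProblemError(RuntimeError):
    """The constraints admit no solution (e.g., locked-in cost over budget)."""


def build_cost(landscape) -> np.ndarray:
    """Per-unit cost: mean of the three scaled (0-1) cost components,
    floored at 1e-6 to avoid zero-cost degeneracy."""
    comp = landscape.cost_components.to_numpy(float)
    if comp.min() < 0 or comp.max() > 1:
        raise ValueError("cost components must lie in [0, 1]")
    return np.maximum(comp.mean(axis=1), 1e-6)


@dataclass
class Problem:
    features: dict  # name -> per-unit non-negative amounts
    cost: np.ndarray  # per-unit positive
    grid: PlanningGrid
    budget_fraction: float = 0.20
    target_fraction: float = 0.30
    boundary_penalty: float = 0.003
    edge_factor: float = 0.5
    locked_in: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.cost = np.asarray(self.cost, float)
        self.features = {k: np.asarray(v, float) for k, v in self.features.items()}
        M = self.grid.n_units
        if len(self.cost) != M or (self.cost <= 0).any():
            raise ValueError("cost must be positive and match the grid")
        for name, a in self.features.items():
            if len(a) != M or (a < 0).any():
                raise ValueError(f"feature {name!r} must be non-negative, length {M}")
        if not 0 < self.budget_fraction <= 1 or not 0 < self.target_fraction <= 1:
            raise ValueError("budget_fraction and target_fraction must lie in (0, 1]")
        self.locked_in = frozenset(int(u) for u in self.locked_in)
        if self.locked_cost > self.budget + 1e-9:
            raise InfeasibleProblemError(
                f"locked-in cost {self.locked_cost:.4g} exceeds budget {self.budget:.4g}"
            )

    @property
    def budget(self) -> float:
        return self.budget_fraction * float(self.cost.sum())

    @property
    def locked_cost(self) -> float:
        return float(sum(self.cost[u] for u in self.locked_in))

    @property
    def targets(self) -> dict:
        return {
            name: self.target_fraction * float(a.sum())
            for name, a in self.features.items()
        }

    def with_features(self, names) -> "Problem":
        return Problem(
            features={n: self.features[n] for n in names},
            cost=self.cost,
            grid=self.grid,
            budget_fraction=self.budget_fraction,
            target_fraction=self.target_fraction,
            boundary_penalty=self.boundary_penalty,
            edge_factor=self.edge_factor,
            locked_in=self.locked_in,
        )


def boundary_length(problem: Problem, x: np.ndarray) -> float:
    """Exposed boundary in cell-side units (outer perimeter scaled by edge_factor)."""
    x = np.asarray(x, bool)
    inner = sum(1.0 for u, v in problem.grid.adjacency if x[u] != x[v])
    outer = float(problem.grid.outer_edges[x].sum()) * problem.edge_factor
    return inner + outer


def evaluate_solution(problem: Problem, x: np.ndarray, solver: str = "manual"):
    """Score a selection vector against the problem objective."""
    x = np.asarray(x, bool)
    attain = {n: float(a[x].sum()) for n, a in problem.features.items()}
    targets = problem.targets
    rel_short = {
        n: max(0.0, targets[n] - attain[n]) / targets[n] if targets[n] > 0 else 0.0
        for n in problem.features
    }
    blen = boundary_length(problem, x)
    obj = sum(rel_short.values()) + problem.boundary_penalty * blen
    return Solution(
        selected=x.copy(),
        attainment=attain,
        relative_shortfall=rel_short,
        boundary=blen,
        objective=float(obj),
        solver=solver,
        achieved_target=all(v <= 1e-9 for v in rel_short.values()),
        feasible=bool(
            problem.cost[x].sum() <= problem.budget + 1e-9
            and all(x[u] for u in problem.locked_in)
        ),
    )


@dataclass
class Solution:
    selected: np.ndarray
    attainment: dict
    relative_shortfall: dict
    boundary: float
    objective: float
    solver: str
    achieved_target: bool
    feasible: bool

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def summary(self) -> dict:
        return {
            "solver": self.solver,
            "n_selected": self.n_selected,
            "objective": self.objective,
            "boundary": self.boundary,
            "achieved_target": self.achieved_target,
            "attainment": self.attainment,
            "relative_shortfall": self.relative_shortfall,
        }


def solve_milp(problem: Problem, mip_gap: float = 1e-9) -> Solution:
    """Exact solution via mixed-integer programming (HiGHS).

    Variables: binary x_u; continuous shortfalls s_f >= T_f - a_f @ x; and
    continuous edge indicators y_e >= |x_u - x_v| for interior edges (tight
    at the optimum because the objective minimizes them).
    """
    M = problem.grid.n_units
    feats = [(n, a) for n, a in problem.features.items() if problem.targets[n] > 0]
    F = len(feats)
    edges = problem.grid.adjacency
    E = len(edges)
    nvar = M + F + E
    targets = problem.targets

    c = np.zeros(nvar)
    c[M : M + F] = [1.0 / targets[n] for n, _ in feats]
    c[M + F :] = problem.boundary_penalty
    c[:M] += problem.boundary_penalty * problem.edge_factor * problem.grid.outer_edges

    rows, cols, vals, lb, ub = [], [], [], [], []
    r = 0
    # budget: cost @ x <= budget
    for u in range(M):
        rows.append(r), cols.append(u), vals.append(problem.cost[u])
    lb.append(-np.inf), ub.append(problem.budget)
    r += 1
    # shortfall: a_f @ x + s_f >= T_f
    for fi, (name, a) in enumerate(feats):
        for u in range(M):
            if a[u]:
                rows.append(r), cols.append(u), vals.append(a[u])
        rows.append(r), cols.append(M + fi), vals.append(1.0)
        lb.append(targets[name]), ub.append(np.inf)
        r += 1
    # edge indicators: y_e - x_u + x_v >= 0 and y_e + x_u - x_v >= 0
    for ei, (u, v) in enumerate(edges):
        y = M + F + ei
        rows += [r, r, r]
        cols += [y, u, v]
        vals += [1.0, -1.0, 1.0]
        lb.append(0.0), ub.append(np.inf)
        r += 1
        rows += [r, r, r]
        cols += [y, u, v]
        vals += [1.0, 1.0, -1.0]
        lb.append(0.0), ub.append(np.inf)
        r += 1
    A = sparse.csc_matrix((vals, (rows, cols)), shape=(r, nvar))
    constraints = optimize.LinearConstraint(A, lb=lb, ub=ub)

    lo = np.zeros(nvar)
    hi = np.concatenate([np.ones(M), np.full(F, np.inf), np.ones(E)])
    for u in problem.locked_in:
        lo[u] = 1.0
    integrality = np.concatenate(
        [np.ones(M), np.zeros(F), np.zeros(E)]
    )
    res = optimize.milp(
        c=c,
        constraints=constraints,
        bounds=optimize.Bounds(lo, hi),
        integrality=integrality,
        options={"mip_rel_gap": mip_gap},
    )
    if not res.success or res.x is None:
        raise InfeasibleProblemError(f"MILP failed: {res.message}")
    x = res.x[:M] > 0.5
    return evaluate_solution(problem, x, solver="milp")


def solve_greedy(
    problem: Problem, seed: int = 0, cost_jitter_sd: float = 0.0
) -> Solution:
    """Randomized greedy: repeatedly add the affordable unit with the best

        (shortfall reduction - boundary_penalty * boundary change) / cost

    ratio, with optional multiplicative lognormal cost jitter and random
    tie-breaking under the given seed, until no unit fits the budget.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    M = problem.grid.n_units
    cost = problem.cost.copy()
    if cost_jitter_sd > 0:
        cost = cost * np.exp(rng.normal(0.0, cost_jitter_sd, size=M))
    targets = problem.targets
    feats = {n: a for n, a in problem.features.items() if targets[n] > 0}
    x = np.zeros(M, dtype=bool)
    for u in problem.locked_in:
        x[u] = True
    spent = float(problem.cost[x].sum())
    attain = {n: float(a[x].sum()) for n, a in feats.items()}
    neighbors = [[] for _ in range(M)]
    for u, v in problem.grid.adjacency:
        neighbors[u].append(v)
        neighbors[v].append(u)
    while True:
        budget_left = problem.budget - spent
        cand = np.flatnonzero(~x & (problem.cost <= budget_left + 1e-12))
        if cand.size == 0:
            break
        scores = np.empty(cand.size)
        for i, u in enumerate(cand):
            d_short = 0.0
            for n, a in feats.items():
                short = max(0.0, targets[n] - attain[n])
                d_short += (short - max(0.0, short - a[u])) / targets[n]
            d_boundary = problem.edge_factor * problem.grid.outer_edges[u]
            for v in neighbors[u]:
                d_boundary += -1.0 if x[v] else 1.0
            scores[i] = (d_short - problem.boundary_penalty * d_boundary) / cost[u]
        best = scores.max()
        ties = cand[scores >= best - 1e-12]
        u = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])
        x[u] = True
        spent += float(problem.cost[u])
        for n, a in feats.items():
            attain[n] += float(a[u])
    return evaluate_solution(problem, x, solver="greedy")


def brute_force(problem: Problem) -> Solution:
    """Exhaustive enumeration (test oracle); refuses more than 20 free units."""
    M = problem.grid.n_units
    free = [u for u in range(M) if u not in problem.locked_in]
    if len(free) > 20:
        raise ValueError("brute_force is limited to 20 free units")
    base = np.zeros(M, dtype=bool)
    for u in problem.locked_in:
        base[u] = True
    best = None
    for r in range(len(free) + 1):
        for combo in itertools.combinations(free, r):
            x = base.copy()
            x[list(combo)] = True
            if problem.cost[x].sum() > problem.budget + 1e-9:
                continue
            sol = evaluate_solution(problem, x, solver="brute_force")
            if best is None or sol.objective < best.objective - 1e-12:
                best = sol
    if best is None:
        raise InfeasibleProblemError("no feasible subset")
    return best
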