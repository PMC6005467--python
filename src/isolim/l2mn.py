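"""L2 minimum-norm solution of a LIM and the delta-15N grid search.

The L2MN solution minimises the sigma-weighted residual of the approximate
equations subject to the exact equalities and inequality priors; among
solutions attaining the minimal residual it selects the one with the
smallest sum of squared flows (the classical ``lsei`` semantics).

The grid-search variant rebuilds the isotope block of the approximate
equations for every candidate vector of unknown delta-15N values and keeps
the candidate with the lowest residual norm.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import _quadprog
from .foodweb import LIMProblem

__all__ = ["L2MNSolution", "GridSearchResult", "residual_norm",
           "solve_l2mn", "grid_search_l2mn15"]


@dataclass
class L2MNSolution:
    x: np.ndarray
    residual_norm: float
    sum_sq_flows: float
    active_inequalities: list[int]


@dataclass
class GridSearchResult:
    best_deltas: np.ndarray
    best_solution: L2MNSolution
    grid_spec: list[tuple[float, float, float]]
    n_evaluated: int
    n_infeasible: int


def residual_norm(x, A, b, sigma) -> float:
    """Weighted sum of squared residuals ``sum(((A x - b)/sigma)**2)``."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    r = (A @ np.asarray(x, dtype=float) - b) / sigma
    return float(r @ r)


def solve_l2mn(problem: LIMProblem, tol: float = 1e-9) -> L2MNSolution:
    """Two-stage equality/inequality-constrained least squares.

    Stage 1 minimises the weighted residual; stage 2 minimises ``sum(x**2)``
    over the stage-1 minimiser set (characterised by fixing the fitted
    values ``A x``), which resolves the tie exactly.
    """
    n = problem.n_flows
    if problem.A.shape[0]:
        Ahat = problem.A / problem.sigma[:, None]
        bhat = problem.b / problem.sigma
        H1 = Ahat.T @ Ahat
        # tiny ridge keeps stage 1 strictly convex; stage 2 removes the bias
        delta = 1e-12 * max(1.0, float(np.trace(H1)) / n)
        H1 = H1 + delta * np.eye(n)
        c1 = -Ahat.T @ bhat
        # start interior (measurement-anchored) — the apex of the conic
        # feasible set is a maximally degenerate vertex
        try:
            from .foodweb import find_feasible_point
            x_start = find_feasible_point(problem)
        except Exception:
            x_start = None
        x1, _ = _quadprog.solve_qp(H1, c1, problem.E, problem.f,
                                   problem.G, problem.h, x0=x_start)
        # stage 2: minimum norm over {x : Ahat x = Ahat x1} ∩ feasible set
        E2 = np.vstack([problem.E, Ahat])
        f2 = np.concatenate([problem.f, Ahat @ x1])
        x, active = _quadprog.solve_qp(np.eye(n), np.zeros(n), E2, f2,
                                       problem.G, problem.h, x0=x1)
    else:
        x, active = _quadprog.solve_qp(np.eye(n), np.zeros(n),
                                       problem.E, problem.f,
                                       problem.G, problem.h)
    res = residual_norm(x, problem.A, problem.b, problem.sigma) \
        if problem.A.shape[0] else 0.0
    # report only inequality rows truly binding at the solution
    scale = max(1.0, float(np.max(np.abs(x))))
    binding = [i for i in range(problem.G.shape[0])
               if problem.G[i] @ x - problem.h[i] <= 1e-7 * scale]
    return L2MNSolution(x=x, residual_norm=res,
                        sum_sq_flows=float(x @ x),
                        active_inequalities=binding)


def grid_search_l2mn15(
    problem_builder,
    grid_spec: list[tuple[float, float, float]],
    max_evaluations: int = 10_000_000,
    mode: str = "full",
    sweeps: int = 4,
) -> GridSearchResult:
    """Exhaustive (or coordinate-descent) search over unknown delta values.

    ``problem_builder(deltas)`` must return the :class:`LIMProblem` with the
    isotope rows rebuilt for the candidate delta vector.  ``grid_spec`` is a
    ``(lo, hi, step)`` triple per unknown.  Ties are broken by smaller sum of
    squared flows, then by lexicographically smaller delta vector.

    ``mode="coordinate"`` sweeps one axis at a time (for grids whose full
    product would exceed ``max_evaluations``).
    """
    axes = [np.arange(lo, hi + step * 0.5, step) for lo, hi, step in grid_spec]
    total = int(np.prod([len(a) for a in axes]))
    if mode == "full" and total > max_evaluations:
        raise ValueError(
            f"full grid has {total} points (> {max_evaluations}); "
            "shrink the grid or use mode='coordinate'"
        )

    best = None  # (residual, sum_sq, deltas_tuple, solution)
    n_eval = n_infeasible = 0

    def evaluate(deltas):
        nonlocal best, n_eval, n_infeasible
        n_eval += 1
        try:
            sol = solve_l2mn(problem_builder(np.asarray(deltas)))
        except Exception:
            n_infeasible += 1
            return None
        key = (sol.residual_norm, sol.sum_sq_flows, tuple(deltas))
        if best is None or key < (best[0], best[1], best[2]):
            best = (sol.residual_norm, sol.sum_sq_flows, tuple(deltas), sol)
        return sol

    if mode == "full":
        for combo in itertools.product(*axes):
            evaluate(combo)
    elif mode == "coordinate":
        current = [float(a[len(a) // 2]) for a in axes]
        evaluate(tuple(current))
        for _ in range(sweeps):
            changed = False
            for dim, axis in enumerate(axes):
                scores = {}
                for v in axis:
                    cand = tuple(current[:dim]) + (float(v),) + tuple(current[dim + 1:])
                    sol = evaluate(cand)
                    if sol is not None:
                        scores[float(v)] = (sol.residual_norm, sol.sum_sq_flows, cand)
                if scores:
                    v_best = min(scores, key=lambda v: scores[v])
                    if v_best != current[dim]:
                        current[dim] = v_best
                        changed = True
            if not changed:
                break
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if best is None:
        raise RuntimeError("every grid point was infeasible")
    return GridSearchResult(
        best_deltas=np.asarray(best[2]),
        best_solution=best[3],
        grid_spec=list(grid_spec),
        n_evaluated=n_eval,
        n_infeasible=n_infeasible,
    )
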