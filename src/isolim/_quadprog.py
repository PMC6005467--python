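"""Dense primal active-set solver for strictly convex quadratic programs.

Solves  min 1/2 x'Hx + c'x  s.t.  E x = f,  G x >= h  with H positive
definite.  Problems here are small (tens of variables), so everything is
dense and the KKT systems are solved by direct factorisation.  Falls back to
``scipy.optimize.minimize(method="trust-constr")`` if the active-set
iteration stalls (degenerate geometry).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from scipy.optimize import LinearConstraint, linprog, minimize


class QPError(RuntimeError):
    pass


def feasible_start(E, f, G, h):
    """Any point with Ex=f, Gx>=h via linear programming (phase 1)."""
    n = E.shape[1] if E is not None and E.size else G.shape[1]
    res = linprog(
        np.zeros(n),
        A_ub=-G if G is not None and G.size else None,
        b_ub=-h if G is not None and G.size else None,
        A_eq=E if E is not None and E.size else None,
        b_eq=f if E is not None and E.size else None,
        bounds=[(None, None)] * n,
        method="highs",
    )
    if not res.success:
        raise QPError("QP constraints are infeasible")
    return res.x


def _kkt_step(H, g, Aw):
    """Minimiser step and multipliers of the equality-constrained subproblem."""
    n = H.shape[0]
    if Aw.shape[0] == 0:
        return -linalg.solve(H, g, assume_a="pos"), np.empty(0)
    m = Aw.shape[0]
    K = np.zeros((n + m, n + m))
    K[:n, :n] = H
    K[:n, n:] = Aw.T
    K[n:, :n] = Aw
    rhs = np.concatenate([-g, np.zeros(m)])
    sol, *_ = linalg.lstsq(K, rhs, lapack_driver="gelsd")
    return sol[:n], sol[n:]


def _independent_rows(M, tol=1e-10):
    """Indices of a maximal independent subset of rows (QR with pivoting)."""
    if M.shape[0] == 0:
        return []
    _, R, piv = linalg.qr(M.T, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * max(diag[0], 1e-300))) if diag.size else 0
    return sorted(piv[:rank])


def solve_qp(H, c, E=None, f=None, G=None, h=None, x0=None,
             tol=1e-10, max_iter=500):
    """Active-set solution of the strictly convex QP.

    Returns ``(x, active)`` where ``active`` is the index set of inequality
    rows binding at the solution.
    """
    n = H.shape[0]
    E = np.zeros((0, n)) if E is None else np.atleast_2d(E)
    f = np.zeros(0) if f is None else np.atleast_1d(f)
    G = np.zeros((0, n)) if G is None else np.atleast_2d(G)
    h = np.zeros(0) if h is None else np.atleast_1d(h)
    if x0 is None:
        x0 = feasible_start(E, f, G, h)
    x = np.asarray(x0, dtype=float).copy()

    scale = max(1.0, float(np.max(np.abs(x))))
    act_tol = tol * scale * 100
    slack = G @ x - h
    work = set(np.nonzero(slack <= act_tol)[0].tolist())

    for _ in range(max_iter):
        g = H @ x + c
        widx = sorted(work)
        Aw_all = np.vstack([E, G[widx]]) if widx else E
        keep = _independent_rows(Aw_all)
        Aw = Aw_all[keep]
        p, lam = _kkt_step(H, g, Aw)
        if np.linalg.norm(p) <= tol * max(1.0, np.linalg.norm(x)):
            # multipliers of inequality rows in the pruned working set; with
            # the KKT convention Hx + c + Aw' lam = 0 a correctly binding
            # "Gx >= h" row carries lam <= 0, so positive lam rows are dropped
            n_eq = E.shape[0]
            lam_map = {}
            for pos, row in enumerate(keep):
                if row >= n_eq:
                    lam_map[widx[row - n_eq]] = lam[pos]
            if not lam_map:
                return x, sorted(work)
            worst = max(lam_map, key=lam_map.get)
            if lam_map[worst] <= tol * 100:
                return x, sorted(work)
            work.discard(worst)
            continue
        # ratio test against constraints not in the working set
        alpha, blocking = 1.0, None
        Gp = G @ p
        slack = G @ x - h
        for i in range(G.shape[0]):
            if i in work or Gp[i] >= -1e-14:
                continue
            a_i = slack[i] / (-Gp[i])
            if a_i < alpha - 1e-14:
                alpha, blocking = a_i, i
        x = x + max(alpha, 0.0) * p
        if blocking is not None:
            work.add(blocking)
    # stalled: polish with a generic solver
    return _fallback(H, c, E, f, G, h, x, tol)


def _fallback(H, c, E, f, G, h, x, tol):
    cons = []
    if E.shape[0]:
        cons.append(LinearConstraint(E, f, f))
    if G.shape[0]:
        cons.append(LinearConstraint(G, h, np.inf))
    res = minimize(
        lambda v: 0.5 * v @ H @ v + c @ v,
        x,
        jac=lambda v: H @ v + c,
        hess=lambda v: H,
        method="trust-constr",
        constraints=cons,
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 2000},
    )
    xs = res.x
    active = np.nonzero(G @ xs - h <= tol * 100 * max(1.0, np.max(np.abs(xs))))[0]
    return xs, sorted(active.tolist())
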