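"""Joint Metropolis sampling of ecosystem flows and unknown delta-15N values.

Each iteration moves both blocks of the state: a mirrored jump of the flow
vector and a bounded Gaussian jump of the six unknown delta-15N values,
each Metropolis-accepted against the shared likelihood (the isotope block
of the approximate equations is rebuilt for every proposed delta vector).
The stationary distribution couples trophic flows to the isotopic state:
flow configurations that cannot reproduce the measured deltas under 15N
mass balance are penalised even when they satisfy the rate measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .foodweb import LIMProblem, find_feasible_point
from .isotopes import UNKNOWN_DELTA_ORDER, IsotopeRowSet, steady_state_deltas
from .l2mn import residual_norm
from .sampler import (ChainConfig, SampleEnsemble, _direction_extents,
                      metropolis_accept, mirror_step, null_space_basis)

__all__ = ["JointState", "delta_jump", "run_joint_chain", "DELTA_COLUMNS"]

DELTA_COLUMNS = [f"d15N_{c}" for c in UNKNOWN_DELTA_ORDER]


@dataclass
class JointState:
    x: np.ndarray
    deltas: np.ndarray
    residual: float


def _fold(v, lo, hi):
    """Reflect values into [lo, hi] (repeated mirroring at both bounds)."""
    span = hi - lo
    y = np.mod(v - lo, 2.0 * span)
    return lo + np.where(y > span, 2.0 * span - y, y)


def delta_jump(deltas, bounds, scale, rng) -> np.ndarray:
    """Symmetric Gaussian jump reflected into the prior bounds.

    ``bounds`` is ``(lo, hi)`` arrays; ``scale`` a scalar or per-component
    standard deviation in permil.
    """
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    step = rng.standard_normal(len(deltas)) * np.asarray(scale, dtype=float)
    return _fold(np.asarray(deltas, dtype=float) + step, lo, hi)


def _joint_residual(x, deltas, problem, rows, sigma_iso_static):
    """Effective residual: weighted squares plus, when the isotope-row
    sigmas track the state, twice their log (the Gaussian normalisation —
    without it the chain drifts toward weak-constraint states)."""
    res = residual_norm(x, problem.A, problem.b, problem.sigma) \
        if problem.A.shape[0] else 0.0
    A_iso = rows.matrix_for(deltas)
    if sigma_iso_static is None:
        sig = rows.sigma_for(x, deltas)
        res += 2.0 * float(np.log(sig).sum())
    else:
        sig = sigma_iso_static
    r = (A_iso @ x) / sig
    return res + float(r @ r)


def initial_deltas(problem: LIMProblem, rows: IsotopeRowSet, x0) -> np.ndarray:
    """Start the unknown deltas at the steady-state solution implied by x0
    (clipped to the prior bounds); fall back to bound midpoints."""
    spec = rows.spec
    lo, hi = spec.bounds_arrays()
    try:
        ss = steady_state_deltas(problem.model, x0,
                                 delta_upno3=spec.delta_known["upno3"],
                                 delta_nfix=spec.delta_nfix,
                                 epsilons=spec.epsilons, r_n2=spec.r_n2)
        d0 = np.array([ss[c] for c in UNKNOWN_DELTA_ORDER])
    except Exception:
        d0 = (lo + hi) / 2.0
    return np.clip(d0, lo + 1e-9, hi - 1e-9)


def run_joint_chain(
    problem: LIMProblem,
    isotope_rows: IsotopeRowSet,
    config: ChainConfig | None = None,
    delta_jump_scale: float = 0.25,
    sigma_mode: str = "current",
    x0: np.ndarray | None = None,
) -> SampleEnsemble:
    """Sample (flows, unknown deltas) jointly on a LIM.

    ``problem`` holds the measurement rows only; the ten isotope rows are
    evaluated per proposal from ``isotope_rows``.  Every iteration performs
    a flow move and a delta move (sequential block Metropolis updates of
    the joint target), so both blocks travel each step while their step
    sizes adapt independently.  ``sigma_mode`` selects whether isotope-row
    uncertainties track the current flows (``"current"``) or stay fixed at
    the initial feasible point (``"initial"``).  Ensemble columns: 35 flows
    then the 6 deltas.
    """
    if sigma_mode not in ("current", "initial"):
        raise ValueError("sigma_mode must be 'current' or 'initial'")
    config = config or ChainConfig()
    rng = np.random.default_rng(config.seed)
    if x0 is None:
        x0 = find_feasible_point(problem)
    Z = null_space_basis(problem.E)
    k = Z.shape[1]
    Gz = problem.G @ Z
    hq = problem.h - problem.G @ x0
    lo, hi = isotope_rows.spec.bounds_arrays()

    js = np.asarray(config.jump_scale, dtype=float)
    if js.ndim == 0:
        cap = 10.0 * max(1.0, float(np.abs(x0).sum()))
        jump = float(js) * _direction_extents(problem, Z, x0, cap)
    else:
        jump = js.copy()
    tune_factor = 1.0

    sigma_static = (isotope_rows.sigma_for(x0) if sigma_mode == "initial" else None)
    q = np.zeros(k)
    x_cur = x0.copy()
    deltas = initial_deltas(problem, isotope_rows, x0)
    res_cur = _joint_residual(x_cur, deltas, problem, isotope_rows, sigma_static)

    tune_interval = min(config.tune_interval, max(50, config.burn_in // 10)) \
        if config.burn_in else config.tune_interval
    # the two blocks see very different likelihood sharpness, so each keeps
    # its own step-size factor tuned on its own acceptance rate; a single
    # jointly tuned factor lets whichever block limits acceptance freeze the
    # other block's walk
    tune_d = 1.0
    d_span = float(np.min(hi - lo))

    kept = []
    acc_x = acc_d = 0
    win_x = win_d = 0
    for it in range(config.n_iter):
        # flow block
        dq = rng.standard_normal(k) * (jump * tune_factor)
        q_prop, ok = mirror_step(q, dq, Gz, hq, config.max_reflections)
        if ok:
            x_prop = x0 + Z @ q_prop
            res_prop = _joint_residual(x_prop, deltas, problem, isotope_rows,
                                       sigma_static)
            if metropolis_accept(res_cur, res_prop, rng):
                q, x_cur, res_cur = q_prop, x_prop, res_prop
                acc_x += 1
                win_x += 1
        # delta block
        d_prop = delta_jump(deltas, (lo, hi), delta_jump_scale * tune_d, rng)
        res_prop = _joint_residual(x_cur, d_prop, problem, isotope_rows,
                                   sigma_static)
        if metropolis_accept(res_cur, res_prop, rng):
            deltas, res_cur = d_prop, res_prop
            acc_d += 1
            win_d += 1
        in_burn = it < config.burn_in
        if config.tune and in_burn and (it + 1) % tune_interval == 0:
            tlo, thi = config.tune_target
            mid = 0.5 * (tlo + thi)
            rate_x = win_x / tune_interval
            if not tlo <= rate_x <= thi:
                tune_factor *= float(np.clip((rate_x + 0.02) / mid, 0.2, 4.0))
                tune_factor = float(np.clip(tune_factor, 1e-4, 1e2))
            rate_d = win_d / tune_interval
            if not tlo <= rate_d <= thi:
                tune_d *= float(np.clip((rate_d + 0.02) / mid, 0.2, 4.0))
                tune_d = float(np.clip(tune_d, 1e-2,
                                       d_span / (2 * delta_jump_scale)))
            win_x = win_d = 0
        if not in_burn and (it - config.burn_in) % config.thin == 0:
            kept.append(np.concatenate([x_cur, deltas]))

    samples = np.array(kept)
    cols = [fl.key for fl in problem.model.flows] + DELTA_COLUMNS
    return SampleEnsemble(
        samples=samples, columns=cols,
        acceptance_rate=(acc_x + acc_d) / (2 * config.n_iter),
        seed=config.seed, n_flows=problem.n_flows,
        extra={"tune_factor": tune_factor, "tune_factor_delta": tune_d,
               "acceptance_flows": acc_x / config.n_iter,
               "acceptance_deltas": acc_d / config.n_iter,
               "sigma_mode": sigma_mode,
               "delta_jump_scale": delta_jump_scale},
    )
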