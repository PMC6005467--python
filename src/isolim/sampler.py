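"""Metropolis mirror-walk sampling of LIM solution polytopes.

The chain lives on the affine set ``{x : Ex = f}``; proposals are Gaussian
steps in an orthonormal null-space basis of E, reflected off the inequality
hyperplanes ``Gx = h`` so that every visited point stays feasible (the
"mirror" algorithm).  The approximate equations act as a Gaussian likelihood:
a proposal is accepted with probability ``min(1, exp(-(res1 - res0)/2))``
where ``res`` is the sigma-weighted sum of squared residuals.  With no
approximate rows the chain samples the polytope uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog

from .foodweb import LIMProblem, find_feasible_point
from .l2mn import residual_norm

__all__ = ["ChainConfig", "SampleEnsemble", "null_space_basis",
           "propose_mirror", "mirror_step", "metropolis_accept",
           "run_chain", "summarize"]


@dataclass
class ChainConfig:
    """Settings for one Metropolis mirror chain.

    ``jump_scale`` is either a scalar multiplier on the per-direction extents
    estimated from the polytope, or an explicit per-direction vector.  During
    burn-in the global step size is tuned toward an acceptance rate in
    ``tune_target``.
    """

    n_iter: int = 100_000
    burn_in: int = 10_000
    thin: int = 10
    jump_scale: float | np.ndarray = 0.05
    seed: int = 0
    tune: bool = True
    tune_target: tuple[float, float] = (0.2, 0.5)
    tune_interval: int = 1_000
    max_reflections: int = 1_000

    def __post_init__(self):
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if np.any(np.asarray(self.jump_scale) <= 0):
            raise ValueError("jump_scale must be positive")


@dataclass
class SampleEnsemble:
    """Accepted draws plus chain metadata; columns follow ``columns``."""

    samples: np.ndarray
    columns: list[str]
    acceptance_rate: float
    seed: int
    n_flows: int
    extra: dict = field(default_factory=dict)

    @property
    def flows(self) -> np.ndarray:
        return self.samples[:, : self.n_flows]

    def summary(self) -> pd.DataFrame:
        return summarize(self)


def null_space_basis(E: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of ``{z : Ez = 0}`` (rank-revealing; dependent rows
    of E are harmless)."""
    E = np.atleast_2d(np.asarray(E, dtype=float))
    if E.shape[0] == 0:
        return np.eye(E.shape[1])
    return null_space(E, rcond=rtol)


def mirror_step(q, dq, Gz, hq, max_reflections: int = 1_000, tol: float = 1e-12):
    """Reflect the step ``q -> q + dq`` off the hyperplanes ``Gz q = hq``.

    Returns ``(q_new, ok)``; ``ok`` is False if the reflection cascade failed
    to terminate (the caller should reject in place).  The map is an isometry
    composed of reflections, hence symmetric as a proposal.
    """
    q = np.asarray(q, dtype=float)
    d = np.asarray(dq, dtype=float).copy()
    cur = q.copy()
    target = cur + d
    for _ in range(max_reflections):
        resid = Gz @ target - hq
        if np.all(resid >= -tol):
            return target, True
        start = Gz @ cur - hq
        den = Gz @ d
        # first hyperplane crossed along cur -> cur + d (only planes the
        # step is moving out through can be crossed)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(den < -1e-300, np.maximum(start, 0.0) / (-den), np.inf)
        if not np.any(np.isfinite(t)):
            return q, False
        i = int(np.argmin(t))
        t_star = min(max(float(t[i]), 0.0), 1.0)
        cur = cur + t_star * d
        g = Gz[i]
        rest = (1.0 - t_star) * d
        rest = rest - 2.0 * (g @ rest) / (g @ g) * g
        d = rest
        target = cur + d
    return q, False


def propose_mirror(x, Z, jump, G, h, rng, max_reflections: int = 1_000):
    """One mirrored Gaussian proposal in flow space (convenience wrapper).

    ``jump`` is the per-direction standard deviation vector in the null-space
    coordinates.
    """
    Gz = G @ Z
    hq = h - G @ x
    dq = rng.standard_normal(Z.shape[1]) * jump
    q_new, ok = mirror_step(np.zeros(Z.shape[1]), dq, Gz, hq, max_reflections)
    return (x + Z @ q_new) if ok else np.asarray(x, dtype=float)


def metropolis_accept(res_old: float, res_new: float, rng) -> bool:
    """Accept with probability ``min(1, exp(-(res_new - res_old)/2))``."""
    if res_new <= res_old:
        return True
    return rng.random() < np.exp(-(res_new - res_old) / 2.0)


def _direction_extents(problem: LIMProblem, Z: np.ndarray, x0: np.ndarray,
                       cap: float) -> np.ndarray:
    """Feasible extent along each null-space direction via LP probes.

    Conic (unbounded) directions are capped so the auto-tuner has a finite
    starting point.
    """
    k = Z.shape[1]
    extents = np.empty(k)
    n = problem.n_flows
    for j in range(k):
        span = 0.0
        ok = True
        for sgn in (1.0, -1.0):
            res = linprog(sgn * Z[:, j], A_ub=-problem.G, b_ub=-problem.h,
                          A_eq=problem.E, b_eq=problem.f,
                          bounds=[(None, None)] * n, method="highs")
            if res.success:
                span += abs(res.fun - sgn * Z[:, j] @ x0)
            else:  # unbounded ray
                ok = False
        extents[j] = min(span, cap) if ok else cap
    extents[extents <= 0] = np.median(extents[extents > 0]) if np.any(extents > 0) else 1.0
    return extents


def run_chain(
    problem: LIMProblem,
    config: ChainConfig | None = None,
    x0: np.ndarray | None = None,
) -> SampleEnsemble:
    """Run one mirror chain on a LIM and return the thinned ensemble."""
    config = config or ChainConfig()
    rng = np.random.default_rng(config.seed)
    if x0 is None:
        x0 = find_feasible_point(problem)
    Z = null_space_basis(problem.E)
    k = Z.shape[1]
    Gz = problem.G @ Z
    hq = problem.h - problem.G @ x0

    js = np.asarray(config.jump_scale, dtype=float)
    if js.ndim == 0:
        cap = 10.0 * max(1.0, float(np.abs(x0).sum()))
        jump = float(js) * _direction_extents(problem, Z, x0, cap)
    else:
        if js.shape != (k,):
            raise ValueError(f"jump_scale vector must have length {k}")
        jump = js.copy()
    tune_factor = 1.0

    have_A = problem.A.shape[0] > 0
    q = np.zeros(k)
    res_cur = residual_norm(x0, problem.A, problem.b, problem.sigma) if have_A else 0.0

    # ensure several tuning windows fit inside the burn-in
    tune_interval = min(config.tune_interval, max(50, config.burn_in // 10)) \
        if config.burn_in else config.tune_interval

    kept = []
    n_accept = 0
    window_accept = 0
    for it in range(config.n_iter):
        dq = rng.standard_normal(k) * (jump * tune_factor)
        q_prop, ok = mirror_step(q, dq, Gz, hq, config.max_reflections)
        accepted = False
        if ok:
            if have_A:
                x_prop = x0 + Z @ q_prop
                res_prop = residual_norm(x_prop, problem.A, problem.b, problem.sigma)
            else:
                res_prop = 0.0
            if metropolis_accept(res_cur, res_prop, rng):
                q, res_cur = q_prop, res_prop
                accepted = True
        n_accept += accepted
        window_accept += accepted
        in_burn = it < config.burn_in
        # tuning targets the Metropolis acceptance rate; a uniform chain
        # (no approximate rows) accepts every mirrored proposal, so its
        # step size is left at the extent-based default
        if config.tune and have_A and in_burn and (it + 1) % tune_interval == 0:
            rate = window_accept / tune_interval
            lo, hi = config.tune_target
            if not lo <= rate <= hi:
                mid = 0.5 * (lo + hi)
                tune_factor *= float(np.clip((rate + 0.02) / mid, 0.2, 4.0))
                tune_factor = float(np.clip(tune_factor, 1e-4, 1e2))
            window_accept = 0
        if not in_burn and (it - config.burn_in) % config.thin == 0:
            kept.append(x0 + Z @ q)

    samples = np.array(kept)
    cols = [fl.key for fl in problem.model.flows]
    return SampleEnsemble(
        samples=samples, columns=cols,
        acceptance_rate=n_accept / config.n_iter,
        seed=config.seed, n_flows=problem.n_flows,
        extra={"jump": jump * tune_factor, "tune_factor": tune_factor},
    )


def summarize(ensemble: SampleEnsemble, derived_fns: dict | None = None) -> pd.DataFrame:
    """Per-variable mean, sd, quartiles and empirical 95% interval.

    ``derived_fns`` maps a name to a function of one sample row; derived
    statistics are computed per sample, then summarised (a CI of a sum is
    the CI of per-sample sums, not a sum of CIs).
    """
    if ensemble.samples.shape[0] == 0:
        raise ValueError("empty ensemble")
    data = ensemble.samples
    names = list(ensemble.columns)
    if derived_fns:
        extra = np.array([[fn(row) for fn in derived_fns.values()] for row in data])
        data = np.hstack([data, extra])
        names = names + list(derived_fns)
    qs = np.percentile(data, [2.5, 25, 75, 97.5], axis=0)
    return pd.DataFrame({
        "mean": data.mean(axis=0),
        "sd": data.std(axis=0, ddof=1) if data.shape[0] > 1 else np.zeros(data.shape[1]),
        "q25": qs[1], "q75": qs[2], "lo95": qs[0], "hi95": qs[3],
    }, index=pd.Index(names, name="variable"))
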