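"""Derived ecosystem indices and the composite evaluation statistic.

The fifteen indices summarise nitrogen biogeochemistry (fixation, uptake,
producer-specific production), grazer dynamics (grazing, carnivory,
secondary production, gross growth efficiency, trophic level) and the
routing of production (herbivorous, multivorous and microbial-loop shares
of net primary production).  They are computable both from a single flow
vector and per-sample across an MCMC ensemble.

Model evaluation pools every estimate of a given index, normalises the pool
with a two-parameter Box-Cox transform and standardises it, then scores a
run by the sum of squared standardised errors across the fifteen indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .foodweb import FoodWebModel, build_pelagic_foodweb

__all__ = ["INDEX_NAMES", "EcosystemIndices", "BoxCoxParams",
           "trophic_levels", "compute_indices", "boxcox_standardize",
           "fit_standardizers", "composite_sse"]

INDEX_NAMES = [
    "n2_fixation", "total_n_uptake", "cya_npp", "dtm_npp",
    "protozoan_grazing", "mes_carnivory", "protozoan_carnivory",
    "mes_secondary_production", "protozoan_gge", "mes_gge",
    "protozoan_tl", "mes_tl",
    "herbivorous_chain", "multivorous_chain", "microbial_loop",
]

_DEFAULT_MODEL: FoodWebModel | None = None


def _default_model() -> FoodWebModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = build_pelagic_foodweb()
    return _DEFAULT_MODEL


@dataclass
class EcosystemIndices:
    n2_fixation: float
    total_n_uptake: float
    cya_npp: float
    dtm_npp: float
    protozoan_grazing: float
    mes_carnivory: float
    protozoan_carnivory: float
    mes_secondary_production: float
    protozoan_gge: float
    mes_gge: float
    protozoan_tl: float
    mes_tl: float
    herbivorous_chain: float
    multivorous_chain: float
    microbial_loop: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in INDEX_NAMES}


def trophic_levels(x, model: FoodWebModel | None = None) -> dict[str, float]:
    """Diet-fraction trophic levels of the living compartments.

    Producers (and, by convention, detritus) sit at level 1; each consumer is
    one level above the ingestion-weighted mean level of its prey.  The MES
    self-loop makes the MES level an implicit equation, so the consumer
    levels are obtained from the induced linear system.  Raises on consumers
    with zero total ingestion.
    """
    model = model or _default_model()
    x = np.asarray(x, dtype=float)
    consumers = ["HNF", "MIC", "MES"]
    base_tl = {"CYA": 1.0, "DTM": 1.0, "DET": 1.0}
    diets = {
        "HNF": ["CYA", "DET"],
        "MIC": ["CYA", "DTM", "HNF", "DET"],
        "MES": ["DTM", "HNF", "MIC", "MES", "DET"],
    }
    idx = {c: i for i, c in enumerate(consumers)}
    M = np.eye(3)
    rhs = np.ones(3)
    for c in consumers:
        inflows = {prey: x[model.flow_id(prey, c)] for prey in diets[c]}
        total = sum(inflows.values())
        if total <= 0:
            raise ValueError(f"zero total ingestion for consumer {c!r}")
        for prey, v in inflows.items():
            frac = v / total
            if prey in base_tl:
                rhs[idx[c]] += frac * base_tl[prey]
            else:
                M[idx[c], idx[prey]] -= frac
    tl = np.linalg.solve(M, rhs)
    out = dict(base_tl)
    out.pop("DET")
    out.update({c: float(tl[idx[c]]) for c in consumers})
    return out


def compute_indices(x, model: FoodWebModel | None = None) -> EcosystemIndices:
    """All fifteen ecosystem indices from one flow vector."""
    model = model or _default_model()
    x = np.asarray(x, dtype=float)

    def g(src, dst):
        return float(x[model.flow_id(src, dst)])

    n2fix = g("NFX", "CYA") + g("NFX", "DTM")
    uptake = n2fix + g("NO3", "CYA") + g("NO3", "DTM") + g("NH4", "CYA") + g("NH4", "DTM")
    cya_npp = g("NFX", "CYA") + g("NO3", "CYA") + g("NH4", "CYA") - g("CYA", "DOM")
    dtm_npp = g("NFX", "DTM") + g("NO3", "DTM") + g("NH4", "DTM") - g("DTM", "DOM")
    npp = cya_npp + dtm_npp
    if npp <= 0:
        raise ValueError("net primary production is zero; ratio indices undefined")

    proto_grazing = g("CYA", "HNF") + g("CYA", "MIC") + g("DTM", "MIC")
    mes_carn = g("MES", "MES")
    proto_carn = g("HNF", "MIC")
    secprod = g("MES", "HTL")

    # guild-level gross growth efficiency: ingestion from outside the guild,
    # growth = ingestion - (NH4 + DOM + DET losses)
    proto_in = proto_grazing + g("DET", "HNF") + g("DET", "MIC")
    proto_loss = sum(g(z, pool) for z in ("HNF", "MIC")
                     for pool in ("NH4", "DOM", "DET"))
    mes_in = g("DTM", "MES") + g("HNF", "MES") + g("MIC", "MES") + g("DET", "MES")
    mes_loss = sum(g("MES", pool) for pool in ("NH4", "DOM", "DET"))
    proto_gge = (proto_in - proto_loss) / proto_in if proto_in > 0 else np.nan
    mes_gge = (mes_in - mes_loss) / mes_in if mes_in > 0 else np.nan

    tl = trophic_levels(x, model)
    hnf_in = g("CYA", "HNF") + g("DET", "HNF")
    mic_in = g("CYA", "MIC") + g("DTM", "MIC") + g("HNF", "MIC") + g("DET", "MIC")
    proto_tl = (tl["HNF"] * hnf_in + tl["MIC"] * mic_in) / (hnf_in + mic_in)

    return EcosystemIndices(
        n2_fixation=n2fix,
        total_n_uptake=uptake,
        cya_npp=cya_npp,
        dtm_npp=dtm_npp,
        protozoan_grazing=proto_grazing,
        mes_carnivory=mes_carn,
        protozoan_carnivory=proto_carn,
        mes_secondary_production=secprod,
        protozoan_gge=float(proto_gge),
        mes_gge=float(mes_gge),
        protozoan_tl=float(proto_tl),
        mes_tl=tl["MES"],
        herbivorous_chain=g("DTM", "MES") / npp,
        multivorous_chain=(g("HNF", "MES") + g("MIC", "MES")) / npp,
        microbial_loop=g("DOM", "NH4") / npp,
    )


# ---------------------------------------------------------------------------
# Box-Cox standardisation and the composite score
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxParams:
    """Fitted two-parameter Box-Cox transform plus pool moments.

    ``scale`` is the geometric-mean normalisation ``gm**(lambda1 - 1)`` of
    the fitting pool; dividing by it keeps the transformed values on the
    data scale for any power, which matters numerically on the flat ridge
    of the profile likelihood (large shift, compensating power).
    """

    lambda1: float
    lambda2: float
    mean: float
    sd: float
    scale: float = 1.0

    def raw_transform(self, y):
        y = np.asarray(y, dtype=float)
        shifted = np.maximum(y + self.lambda2, 1e-12)
        if abs(self.lambda1) < 1e-9:
            return np.log(shifted) / self.scale
        return (shifted ** self.lambda1 - 1.0) / (self.lambda1 * self.scale)

    def transform(self, y):
        """Standardised transform: mean 0, sd 1 on the fitting pool."""
        return (self.raw_transform(y) - self.mean) / self.sd


def boxcox_standardize(pooled_values) -> tuple[BoxCoxParams, np.ndarray]:
    """Two-parameter Box-Cox by profile maximum likelihood, then z-score.

    The shift ``lambda2`` is parameterised so the shifted pool stays
    strictly positive (and bounded, since beyond ~100 pool ranges the
    transform is affine and the likelihood flat); the power ``lambda1`` is
    unconstrained.
    """
    y = np.asarray(pooled_values, dtype=float)
    if y.size < 3 or not np.all(np.isfinite(y)):
        raise ValueError("pool must hold at least 3 finite values")
    if np.ptp(y) == 0:
        raise ValueError("degenerate (constant) pool")
    ymin = y.min()
    n = y.size
    spread = max(float(np.std(y)), 1e-8)
    u_max = np.log(100.0 * (np.ptp(y) + spread))

    def negllf(params):
        l1, u = params
        if u > u_max:
            return np.inf
        l2 = np.exp(u) - ymin
        shifted = y + l2
        if np.any(shifted <= 0):
            return np.inf
        logs = np.log(shifted)
        gm_pow = np.exp((l1 - 1.0) * logs.mean())  # gm**(l1-1)
        z = logs / gm_pow if abs(l1) < 1e-9 \
            else (shifted ** l1 - 1.0) / (l1 * gm_pow)
        if not np.all(np.isfinite(z)):
            return np.inf
        var = z.var()
        if var <= 0:
            return np.inf
        # Jacobian term absorbed by the geometric-mean scaling
        return 0.5 * n * np.log(var)

    best = None
    for u0 in (np.log(spread), min(np.log(spread) + 2.0, u_max), 0.0):
        res = minimize(negllf, x0=np.array([1.0, u0]), method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    l1, u = best.x
    l2 = float(np.exp(u) - ymin)
    gm_pow = float(np.exp((l1 - 1.0) * np.mean(np.log(y + l2))))
    params = BoxCoxParams(lambda1=float(l1), lambda2=l2, mean=0.0, sd=1.0,
                          scale=gm_pow)
    z = params.raw_transform(y)
    if z.std() <= 1e-10 * max(1.0, abs(z.mean())):
        # degenerate fit: fall back to the affine (power 1) transform
        params = BoxCoxParams(lambda1=1.0, lambda2=0.0, mean=0.0, sd=1.0)
        z = params.raw_transform(y)
    params.mean = float(z.mean())
    params.sd = float(z.std()) if z.std() > 0 else 1.0
    return params, params.transform(y)


def fit_standardizers(pools: dict[str, np.ndarray]) -> dict[str, BoxCoxParams]:
    """One Box-Cox standardiser per index from its pooled estimates."""
    return {name: boxcox_standardize(vals)[0] for name, vals in pools.items()}


def composite_sse(predicted: dict[str, float], true: dict[str, float],
                  standardizer: dict[str, BoxCoxParams]) -> float:
    """Sum of squared standardised errors over the fifteen indices.

    Both the prediction and the truth are passed through the *same* pooled
    transform per index, so every index carries equivalent weight.
    """
    total = 0.0
    for name in INDEX_NAMES:
        if name not in predicted or name not in true:
            raise KeyError(f"missing index {name!r}")
        bc = standardizer[name]
        d = float(bc.transform(predicted[name]) - bc.transform(true[name]))
        total += d * d
    return total
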