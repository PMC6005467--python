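"""delta-15N machinery: unit conversions, fractionation, isotope mass-balance
rows and steady-state delta solutions.

Isotope ratios are expressed as R = 15N/14N.  A delta value in permil maps to
a ratio via ``R = delta * R_N2 / 1000 + R_N2`` where ``R_N2`` is the ratio of
atmospheric dinitrogen.  A process with fractionation factor epsilon (permil)
multiplies the source ratio by ``alpha = exp(epsilon / 1000)`` on the
fractionating flow: nitrate and ammonium uptake, grazer excretion (to NH4 and
DOM), grazer egestion (to detritus), and remineralisation/solubilisation.

For each compartment the 15N inflow must balance the 15N outflow at steady
state; each balance is *linear in the flows* once the delta values are fixed,
which is what lets the rows join the approximate-equation block of a LIM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .foodweb import FoodWebModel

__all__ = [
    "R_N2_DEFAULT", "UNKNOWN_DELTA_ORDER", "DEFAULT_EPSILONS",
    "IsotopeSpec", "IsotopeRowSet",
    "delta_to_ratio", "ratio_to_delta", "frac_coefficient",
    "build_isotope_rows", "isotope_sigma", "steady_state_deltas",
]

#: 15N/14N ratio of atmospheric N2 (air standard).
R_N2_DEFAULT = 0.0036765

#: Compartments whose delta-15N is estimated rather than measured, in the
#: fixed order used by the grid search and the joint sampler.
UNKNOWN_DELTA_ORDER = ("NO3", "NH4", "CYA", "DTM", "HNF", "MIC")

#: Fractionation factors (permil) per process.
DEFAULT_EPSILONS = {"no3": -5.0, "nh4": -10.0, "exc": -5.0, "eg": -2.0, "sol": -1.0}

#: Default prior bounds (permil) on each unknown delta.
DEFAULT_DELTA_BOUNDS = (-2.0, 16.0)


def delta_to_ratio(delta_permil, r_n2: float = R_N2_DEFAULT):
    """Convert delta-15N (permil) to a 15N/14N ratio."""
    return np.asarray(delta_permil, dtype=float) * r_n2 / 1000.0 + r_n2


def ratio_to_delta(ratio, r_n2: float = R_N2_DEFAULT):
    """Inverse of :func:`delta_to_ratio`."""
    return (np.asarray(ratio, dtype=float) / r_n2 - 1.0) * 1000.0


def frac_coefficient(epsilon_permil):
    """Fractionation coefficient ``alpha = exp(epsilon / 1000)``."""
    return np.exp(np.asarray(epsilon_permil, dtype=float) / 1000.0)


@dataclass
class IsotopeSpec:
    """Fractionation factors plus known and unknown delta-15N values.

    ``delta_known`` must supply the exogenous-nitrate delta (key ``upno3``)
    and the deltas of MES, DET (sinking detritus) and DOM.  ``delta_unknown``
    holds current values for the six estimated compartments in
    :data:`UNKNOWN_DELTA_ORDER`; ``bounds`` are their prior ranges.
    """

    epsilons: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EPSILONS))
    r_n2: float = R_N2_DEFAULT
    delta_known: dict[str, float] = field(default_factory=dict)
    delta_unknown: dict[str, float] = field(
        default_factory=lambda: {k: 0.0 for k in UNKNOWN_DELTA_ORDER})
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: DEFAULT_DELTA_BOUNDS for k in UNKNOWN_DELTA_ORDER})
    delta_nfix: float = 0.0

    def __post_init__(self):
        for k, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {k}: lo must be < hi")
        for k, v in self.epsilons.items():
            if not np.isfinite(v):
                raise ValueError(f"epsilon {k} must be finite")

    def unknown_vector(self) -> np.ndarray:
        return np.array([self.delta_unknown[k] for k in UNKNOWN_DELTA_ORDER])

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[k][0] for k in UNKNOWN_DELTA_ORDER])
        hi = np.array([self.bounds[k][1] for k in UNKNOWN_DELTA_ORDER])
        return lo, hi

    def with_unknowns(self, values) -> "IsotopeSpec":
        du = dict(zip(UNKNOWN_DELTA_ORDER, np.asarray(values, dtype=float)))
        return IsotopeSpec(epsilons=dict(self.epsilons), r_n2=self.r_n2,
                           delta_known=dict(self.delta_known), delta_unknown=du,
                           bounds=dict(self.bounds), delta_nfix=self.delta_nfix)


# ---------------------------------------------------------------------------
# Term table: the ten 15N balance rows
# ---------------------------------------------------------------------------
# Each term: (flow "SRC->DST", sign, ratio label, process for alpha or None).
# Ratio labels are compartments (NO3..DOM), "upno3" (exogenous nitrate) or
# "nfix" (dinitrogen fixation).  MES->MES carries no term: with an
# unfractionated self-loop the 15N it moves is identical on both sides.

_ROW_TERMS: dict[str, list[tuple[str, float, str, str | None]]] = {
    "iso_NO3": [
        ("EXT->NO3", +1, "upno3", None),
        ("NO3->CYA", -1, "NO3", "no3"),
        ("NO3->DTM", -1, "NO3", "no3"),
    ],
    "iso_NH4": [
        ("NH4->DTM", -1, "NH4", "nh4"),
        ("NH4->CYA", -1, "NH4", "nh4"),
        ("HNF->NH4", +1, "HNF", "exc"),
        ("MIC->NH4", +1, "MIC", "exc"),
        ("MES->NH4", +1, "MES", "exc"),
        ("DOM->NH4", +1, "DOM", "sol"),
    ],
    "iso_CYA": [
        ("NFX->CYA", +1, "nfix", None),
        ("NO3->CYA", +1, "NO3", "no3"),
        ("NH4->CYA", +1, "NH4", "nh4"),
        ("CYA->HNF", -1, "CYA", None),
        ("CYA->MIC", -1, "CYA", None),
        ("CYA->DET", -1, "CYA", None),
        ("CYA->DOM", -1, "CYA", None),
    ],
    "iso_DTM": [
        ("NFX->DTM", +1, "nfix", None),
        ("NO3->DTM", +1, "NO3", "no3"),
        ("NH4->DTM", +1, "NH4", "nh4"),
        ("DTM->MIC", -1, "DTM", None),
        ("DTM->MES", -1, "DTM", None),
        ("DTM->DET", -1, "DTM", None),
        ("DTM->DOM", -1, "DTM", None),
    ],
    "iso_HNF": [
        ("CYA->HNF", +1, "CYA", None),
        ("DET->HNF", +1, "DET", None),
        ("HNF->MIC", -1, "HNF", None),
        ("HNF->MES", -1, "HNF", None),
        ("HNF->NH4", -1, "HNF", "exc"),
        ("HNF->DET", -1, "HNF", "eg"),
        ("HNF->DOM", -1, "HNF", "exc"),
    ],
    "iso_MIC": [
        ("CYA->MIC", +1, "CYA", None),
        ("DTM->MIC", +1, "DTM", None),
        ("HNF->MIC", +1, "HNF", None),
        ("DET->MIC", +1, "DET", None),
        ("MIC->MES", -1, "MIC", None),
        ("MIC->NH4", -1, "MIC", "exc"),
        ("MIC->DET", -1, "MIC", "eg"),
        ("MIC->DOM", -1, "MIC", "exc"),
    ],
    "iso_MES": [
        ("DTM->MES", +1, "DTM", None),
        ("HNF->MES", +1, "HNF", None),
        ("MIC->MES", +1, "MIC", None),
        ("DET->MES", +1, "DET", None),
        ("MES->HTL", -1, "MES", None),
        ("MES->NH4", -1, "MES", "exc"),
        ("MES->DET", -1, "MES", "eg"),
        ("MES->DOM", -1, "MES", "exc"),
    ],
    "iso_DET": [
        ("DTM->DET", +1, "DTM", None),
        ("CYA->DET", +1, "CYA", None),
        ("HNF->DET", +1, "HNF", "eg"),
        ("MIC->DET", +1, "MIC", "eg"),
        ("MES->DET", +1, "MES", "eg"),
        ("DET->HNF", -1, "DET", None),
        ("DET->MIC", -1, "DET", None),
        ("DET->MES", -1, "DET", None),
        ("DET->DOM", -1, "DET", "sol"),
        ("DET->SNK", -1, "DET", None),
    ],
    "iso_DOM": [
        ("DTM->DOM", +1, "DTM", None),
        ("CYA->DOM", +1, "CYA", None),
        ("HNF->DOM", +1, "HNF", "exc"),
        ("MIC->DOM", +1, "MIC", "exc"),
        ("MES->DOM", +1, "MES", "exc"),
        ("DET->DOM", +1, "DET", "sol"),
        ("DOM->NH4", -1, "DOM", "sol"),
    ],
    "iso_system": [
        ("EXT->NO3", +1, "upno3", None),
        ("NFX->CYA", +1, "nfix", None),
        ("NFX->DTM", +1, "nfix", None),
        ("DET->SNK", -1, "DET", None),
        ("MES->HTL", -1, "MES", None),
    ],
}

ROW_NAMES = list(_ROW_TERMS)

_RATIO_LABELS = ("upno3", "nfix", "NO3", "NH4", "CYA", "DTM", "HNF", "MIC",
                 "MES", "DET", "DOM")
_KNOWN_LABELS = ("MES", "DET", "DOM")


def _ratio_values(spec: IsotopeSpec, delta_unknown=None) -> np.ndarray:
    """Ratio per label in ``_RATIO_LABELS`` for the current spec state."""
    du = spec.unknown_vector() if delta_unknown is None \
        else np.asarray(delta_unknown, dtype=float)
    deltas = {}
    if "upno3" not in spec.delta_known:
        raise KeyError("delta of exogenous nitrate ('upno3') is required")
    deltas["upno3"] = spec.delta_known["upno3"]
    deltas["nfix"] = spec.delta_nfix
    for k, v in zip(UNKNOWN_DELTA_ORDER, du):
        deltas[k] = v
    for k in _KNOWN_LABELS:
        if k not in spec.delta_known:
            raise KeyError(f"delta-15N of {k} must be supplied in delta_known")
        deltas[k] = spec.delta_known[k]
    return delta_to_ratio(np.array([deltas[k] for k in _RATIO_LABELS]), spec.r_n2)


class IsotopeRowSet:
    """The ten 15N balance rows as a vectorised coefficient template.

    ``matrix_for(delta_unknown)`` re-evaluates the coefficient matrix for a
    new unknown-delta vector without re-walking the term table — the joint
    sampler calls this at every step.
    """

    def __init__(self, model: FoodWebModel, spec: IsotopeSpec):
        self.model = model
        self.spec = spec
        self.names = list(ROW_NAMES)
        rows, cols, signs, alphas, labels = [], [], [], [], []
        for r, name in enumerate(self.names):
            for flow_key, sign, label, process in _ROW_TERMS[name]:
                src, dst = flow_key.split("->")
                rows.append(r)
                cols.append(model.flow_id(src, dst))
                signs.append(float(sign))
                alphas.append(
                    1.0 if process is None
                    else float(frac_coefficient(spec.epsilons[process])))
                labels.append(_RATIO_LABELS.index(label))
        self._rows = np.array(rows)
        self._cols = np.array(cols)
        self._signs = np.array(signs)
        self._alphas = np.array(alphas)
        self._labels = np.array(labels)
        self.sigmas: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return len(self.names)

    def matrix_for(self, delta_unknown=None) -> np.ndarray:
        R = _ratio_values(self.spec, delta_unknown)
        coeff = self._signs * self._alphas * R[self._labels]
        A = np.zeros((self.n_rows, self.model.n_flows))
        np.add.at(A, (self._rows, self._cols), coeff)
        return A

    def matrix(self) -> np.ndarray:
        return self.matrix_for(None)

    def sigma_for(self, x_ref, delta_unknown=None, rel: float = 0.10,
                  floor_frac: float = 1e-4) -> np.ndarray:
        """Row uncertainties tied to mass flow times expected fractionation.

        Per row: ``rel * sum(|flow| * |R_source * (1 - alpha)|)`` over its
        fractionating terms, floored at ``floor_frac * R_N2``.
        """
        x = np.asarray(x_ref, dtype=float)
        R = _ratio_values(self.spec, delta_unknown)
        mag = np.abs(R[self._labels] * (1.0 - self._alphas))
        contrib = np.abs(x[self._cols]) * mag
        sig = np.zeros(self.n_rows)
        np.add.at(sig, self._rows, contrib)
        return np.maximum(rel * sig, floor_frac * self.spec.r_n2)

    def attach_sigma(self, x_ref) -> "IsotopeRowSet":
        self.sigmas = self.sigma_for(x_ref)
        return self

    def as_matrix(self, model: FoodWebModel):
        """(A, b, sigma, names) block for :func:`~isolim.foodweb.assemble_problem`."""
        if model is not self.model:
            raise ValueError("row set was built for a different model")
        if self.sigmas is None:
            raise RuntimeError("call attach_sigma(x_ref) before assembly")
        return self.matrix(), np.zeros(self.n_rows), self.sigmas, list(self.names)

    def residuals(self, x, delta_unknown=None) -> np.ndarray:
        return self.matrix_for(delta_unknown) @ np.asarray(x, dtype=float)


def build_isotope_rows(model: FoodWebModel, spec: IsotopeSpec) -> IsotopeRowSet:
    """Construct the ten 15N mass-balance rows for the pelagic web."""
    return IsotopeRowSet(model, spec)


def isotope_sigma(rows: IsotopeRowSet, x_ref, rel: float = 0.10) -> np.ndarray:
    """Per-row uncertainties at a reference flow vector (see ``sigma_for``)."""
    return rows.sigma_for(x_ref, rel=rel)


def steady_state_deltas(
    model: FoodWebModel,
    x,
    delta_upno3: float,
    delta_nfix: float = 0.0,
    epsilons: dict[str, float] | None = None,
    r_n2: float = R_N2_DEFAULT,
) -> dict[str, float]:
    """Solve the nine compartment 15N balances for every internal delta.

    Given a mass-balanced flow vector and the boundary deltas (exogenous
    nitrate and N2 fixation), the balances are linear in the unknown
    compartment ratios; the solution is the steady-state isotopic state the
    web would relax to.  Raises on singular systems (zero-throughput
    compartments).
    """
    x = np.asarray(x, dtype=float)
    eps = dict(DEFAULT_EPSILONS) if epsilons is None else dict(epsilons)
    internal = [c.name for c in model.internal_compartments]
    comp_idx = {n: i for i, n in enumerate(internal)}
    n = len(internal)
    M = np.zeros((n, n))
    rhs = np.zeros(n)
    known_R = {"upno3": float(delta_to_ratio(delta_upno3, r_n2)),
               "nfix": float(delta_to_ratio(delta_nfix, r_n2))}
    for r, name in enumerate(ROW_NAMES[:9]):  # compartment balances only
        for flow_key, sign, label, process in _ROW_TERMS[name]:
            src, dst = flow_key.split("->")
            alpha = 1.0 if process is None else float(frac_coefficient(eps[process]))
            coeff = sign * alpha * x[model.flow_id(src, dst)]
            if label in comp_idx:
                M[r, comp_idx[label]] += coeff
            else:
                rhs[r] -= coeff * known_R[label]
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "singular isotope balance (a compartment has ~zero throughput)")
    R = np.linalg.solve(M, rhs)
    resid = np.abs(M @ R - rhs)
    if resid.max() > 1e-10 * max(1.0, np.abs(rhs).max()):
        raise np.linalg.LinAlgError("isotope balance solve did not close")
    return {name: float(ratio_to_delta(R[i], r_n2)) for name, i in comp_idx.items()}
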