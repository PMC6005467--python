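"""Food-web data model and constraint assembly for linear inverse models.

A linear inverse model (LIM) describes a steady-state food web as a vector
``x`` of non-negative nitrogen flows (mmol N m-2 d-1) subject to

* exact mass balance,          ``E x = f``
* approximate measurements,    ``A x ~ b``  (per-row standard deviation sigma)
* inequality priors,           ``G x >= h``

The 9-compartment, 35-flow pelagic web built by :func:`build_pelagic_foodweb`
couples two phytoplankton groups (cyanobacteria/small phytoplankton CYA and
diatoms/large phytoplankton DTM), three grazer groups (heterotrophic
nanoflagellates HNF, microzooplankton MIC, mesozooplankton MES) and four
non-living pools (NO3, NH4, detritus DET, dissolved organic matter DOM), with
external sources (allochthonous nitrate EXT, dinitrogen fixation NFX) and
sinks (sinking particles SNK, higher trophic levels HTL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Compartment",
    "Flow",
    "FoodWebModel",
    "MeasurementConstraint",
    "Inequality",
    "LIMProblem",
    "InfeasibleProblemError",
    "build_pelagic_foodweb",
    "default_inequalities",
    "measurement_equations",
    "assemble_problem",
    "degrees_of_freedom",
    "find_feasible_point",
    "COMPARTMENT_ALIASES",
]

#: Alias table between the short codes used here and the descriptive names
#: used in schematic presentations of the same web.
COMPARTMENT_ALIASES = {
    "CYA": "SPHY",   # cyanobacteria == small phytoplankton
    "DTM": "LPHY",   # diatoms == large phytoplankton
    "SNK": "Sink",
    "NFX": "NFix",
}


@dataclass(frozen=True)
class Compartment:
    """A node of the food web.

    ``external`` compartments (sources/sinks) carry no mass-balance row;
    ``delta_known`` marks compartments whose delta-15N is supplied as a
    measurement rather than estimated.
    """

    name: str
    living: bool = False
    external: bool = False
    delta_known: bool = False


@dataclass(frozen=True)
class Flow:
    """A directed flow ``source -> target``; ``id`` indexes the vector x."""

    id: int
    source: str
    target: str

    @property
    def key(self) -> str:
        return f"{self.source}->{self.target}"


class FoodWebModel:
    """Compartments plus the ordered flow list defining the unknown vector x."""

    def __init__(self, compartments: list[Compartment], flows: list[tuple[str, str]]):
        names = [c.name for c in compartments]
        if len(set(names)) != len(names):
            raise ValueError("compartment names must be unique")
        if len(set(flows)) != len(flows):
            raise ValueError("(source, target) flow pairs must be unique")
        self.compartments = list(compartments)
        self._by_name = {c.name: c for c in self.compartments}
        for s, t in flows:
            if s not in self._by_name or t not in self._by_name:
                raise ValueError(f"flow {s}->{t} references unknown compartment")
        self.flows = [Flow(i, s, t) for i, (s, t) in enumerate(flows)]
        self._flow_index = {fl.key: fl.id for fl in self.flows}

    @property
    def n_flows(self) -> int:
        return len(self.flows)

    @property
    def internal_compartments(self) -> list[Compartment]:
        return [c for c in self.compartments if not c.external]

    def compartment(self, name: str) -> Compartment:
        return self._by_name[name]

    def flow_id(self, source: str, target: str) -> int:
        return self._flow_index[f"{source}->{target}"]

    def flow_vector(self, coeffs: dict[str, float]) -> np.ndarray:
        """Dense coefficient row from a ``{"SRC->DST": coeff}`` map."""
        row = np.zeros(self.n_flows)
        for key, c in coeffs.items():
            if key not in self._flow_index:
                raise KeyError(f"unknown flow {key!r}")
            row[self._flow_index[key]] = c
        return row

    def mass_balance(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Steady-state mass balance ``E x = 0`` over internal compartments.

        Each flow enters with +1 in its target's row and -1 in its source's
        row; self-loops cancel and contribute a zero column.
        """
        internal = self.internal_compartments
        rows = {c.name: i for i, c in enumerate(internal)}
        E = np.zeros((len(internal), self.n_flows))
        for fl in self.flows:
            if fl.target in rows:
                E[rows[fl.target], fl.id] += 1.0
            if fl.source in rows:
                E[rows[fl.source], fl.id] -= 1.0
        return E, np.zeros(len(internal)), [c.name for c in internal]

    # Ingestion / gross-production helpers used by inequalities and indices.
    def inflows(self, name: str, sources: list[str] | None = None) -> dict[str, float]:
        out = {}
        for fl in self.flows:
            if fl.target == name and (sources is None or fl.source in sources):
                out[fl.key] = 1.0
        return out

    def outflows(self, name: str, targets: list[str] | None = None) -> dict[str, float]:
        out = {}
        for fl in self.flows:
            if fl.source == name and (targets is None or fl.target in targets):
                out[fl.key] = 1.0
        return out


@dataclass
class MeasurementConstraint:
    """One approximate equality: ``sum(coeff * flow) ~ value`` with sd
    ``rel_uncertainty * value``."""

    name: str
    coefficients: dict[str, float]
    value: float
    rel_uncertainty: float = 0.10

    def __post_init__(self):
        if not self.value > 0:
            raise ValueError(f"measurement {self.name!r}: value must be > 0")
        if not self.rel_uncertainty > 0:
            raise ValueError(f"measurement {self.name!r}: rel_uncertainty must be > 0")

    @property
    def sigma(self) -> float:
        return self.rel_uncertainty * self.value


@dataclass
class Inequality:
    """One prior constraint ``sum(coeff * flow) >= bound``."""

    name: str
    coefficients: dict[str, float]
    bound: float = 0.0


@dataclass
class LIMProblem:
    """Assembled constraint algebra of one inverse problem."""

    model: FoodWebModel
    E: np.ndarray
    f: np.ndarray
    A: np.ndarray
    b: np.ndarray
    sigma: np.ndarray
    G: np.ndarray
    h: np.ndarray
    equality_names: list[str] = field(default_factory=list)
    approx_names: list[str] = field(default_factory=list)
    inequality_names: list[str] = field(default_factory=list)
    n_measurement_rows: int = 0

    def __post_init__(self):
        n = self.model.n_flows
        for name, M in (("E", self.E), ("A", self.A), ("G", self.G)):
            if M.shape[1] != n:
                raise ValueError(f"{name} has {M.shape[1]} columns, expected {n}")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")

    @property
    def n_flows(self) -> int:
        return self.model.n_flows


class InfeasibleProblemError(RuntimeError):
    """Raised when no flow vector satisfies the hard constraints."""


# ---------------------------------------------------------------------------
# The 35-flow pelagic web
# ---------------------------------------------------------------------------

_GRAZER_DIETS = {
    "HNF": ["CYA", "DET"],
    "MIC": ["CYA", "DTM", "HNF", "DET"],
    "MES": ["DTM", "HNF", "MIC", "MES", "DET"],
}


def build_pelagic_foodweb() -> FoodWebModel:
    """Build the fixed 9-compartment, 35-flow pelagic nitrogen web.

    Flow order: external inputs, uptake, grazing, detritivory, losses to DET
    and DOM, excretion to NH4, remineralisation, exports.  MES->MES
    (self-carnivory) is flow ``MES->MES``; it cancels in the MES mass-balance
    row and is constrained only through inequalities.
    """
    compartments = [
        Compartment("NO3"),
        Compartment("NH4"),
        Compartment("CYA", living=True),
        Compartment("DTM", living=True),
        Compartment("HNF", living=True),
        Compartment("MIC", living=True),
        Compartment("MES", living=True, delta_known=True),
        Compartment("DET", delta_known=True),
        Compartment("DOM", delta_known=True),
        Compartment("EXT", external=True, delta_known=True),
        Compartment("NFX", external=True, delta_known=True),
        Compartment("SNK", external=True),
        Compartment("HTL", external=True),
    ]
    flows: list[tuple[str, str]] = [
        ("EXT", "NO3"),
        ("NFX", "CYA"),
        ("NFX", "DTM"),
        ("NO3", "CYA"),
        ("NO3", "DTM"),
        ("NH4", "CYA"),
        ("NH4", "DTM"),
        # grazing
        ("CYA", "HNF"),
        ("CYA", "MIC"),
        ("DTM", "MIC"),
        ("DTM", "MES"),
        ("HNF", "MIC"),
        ("HNF", "MES"),
        ("MIC", "MES"),
        ("MES", "MES"),
        # detritivory
        ("DET", "HNF"),
        ("DET", "MIC"),
        ("DET", "MES"),
        # losses to detritus (phytoplankton mortality, grazer egestion)
        ("CYA", "DET"),
        ("DTM", "DET"),
        ("HNF", "DET"),
        ("MIC", "DET"),
        ("MES", "DET"),
        # losses to DOM (excretion / exudation)
        ("CYA", "DOM"),
        ("DTM", "DOM"),
        ("HNF", "DOM"),
        ("MIC", "DOM"),
        ("MES", "DOM"),
        # excretion to NH4
        ("HNF", "NH4"),
        ("MIC", "NH4"),
        ("MES", "NH4"),
        # remineralisation chain
        ("DET", "DOM"),
        ("DOM", "NH4"),
        # exports
        ("DET", "SNK"),
        ("MES", "HTL"),
    ]
    model = FoodWebModel(compartments, flows)
    assert model.n_flows == 35
    return model


def _scaled(coeffs: dict[str, float], s: float) -> dict[str, float]:
    return {k: v * s for k, v in coeffs.items()}


def _combine(*maps: dict[str, float]) -> dict[str, float]:
    out: dict[str, float] = {}
    for m in maps:
        for k, v in m.items():
            out[k] = out.get(k, 0.0) + v
    return out


def default_inequalities(
    model: FoodWebModel,
    gge: tuple[float, float] = (0.10, 0.40),
    assimilation: tuple[float, float] = (0.50, 0.90),
    excretion: tuple[float, float] = (0.10, 1.00),
    phyto_dom: tuple[float, float] = (0.02, 0.55),
) -> list[Inequality]:
    """Standard physiological priors on grazers and phytoplankton.

    All bounds are fractions of ingestion (grazers) or of gross production
    (phytoplankton): gross growth efficiency, assimilation efficiency,
    total excretion (NH4 + DOM release), and phytoplankton DOM exudation.
    Rows are homogeneous (``>= 0``); non-negativity of every flow is added
    separately at assembly time.
    """
    ineqs: list[Inequality] = []
    for grazer, diet in _GRAZER_DIETS.items():
        ingest = model.inflows(grazer, sources=diet)
        losses = _combine(
            model.outflows(grazer, targets=["NH4"]),
            model.outflows(grazer, targets=["DOM"]),
            model.outflows(grazer, targets=["DET"]),
        )
        growth = _combine(ingest, _scaled(losses, -1.0))
        egest = model.outflows(grazer, targets=["DET"])
        excrete = _combine(
            model.outflows(grazer, targets=["NH4"]),
            model.outflows(grazer, targets=["DOM"]),
        )
        ineqs += [
            Inequality(f"{grazer}_gge_lo", _combine(growth, _scaled(ingest, -gge[0]))),
            Inequality(f"{grazer}_gge_hi", _combine(_scaled(ingest, gge[1]), _scaled(growth, -1.0))),
            # assimilation efficiency (1 - egestion/ingestion) in [lo, hi]
            Inequality(f"{grazer}_ae_lo", _combine(_scaled(ingest, 1 - assimilation[0]), _scaled(egest, -1.0))),
            Inequality(f"{grazer}_ae_hi", _combine(egest, _scaled(ingest, -(1 - assimilation[1])))),
            Inequality(f"{grazer}_excr_lo", _combine(excrete, _scaled(ingest, -excretion[0]))),
            Inequality(f"{grazer}_excr_hi", _combine(_scaled(ingest, excretion[1]), _scaled(excrete, -1.0))),
        ]
    for phyto, nfix in (("CYA", "NFX->CYA"), ("DTM", "NFX->DTM")):
        gpp = _combine(
            model.inflows(phyto, sources=["NO3", "NH4"]), {nfix: 1.0}
        )
        dom = model.outflows(phyto, targets=["DOM"])
        ineqs += [
            Inequality(f"{phyto}_dom_lo", _combine(dom, _scaled(gpp, -phyto_dom[0]))),
            Inequality(f"{phyto}_dom_hi", _combine(_scaled(gpp, phyto_dom[1]), _scaled(dom, -1.0))),
        ]
    return ineqs


# ---------------------------------------------------------------------------
# Measurement rows
# ---------------------------------------------------------------------------

def measurement_equations(model: FoodWebModel, scenario) -> list[MeasurementConstraint]:
    """Measurement constraints for one scenario (sd = 10% of value).

    ``scenario`` is anything with attributes/keys ``npp``, and optionally
    ``nitrate_uptake``, ``mesozoo_grazing``, ``export`` (missing or None
    means withheld).  Net primary production is total uptake plus fixation
    minus phytoplankton DOM release, and is always required.
    """
    def get(k):
        if hasattr(scenario, k):
            return getattr(scenario, k)
        return scenario.get(k)

    npp = get("npp")
    if npp is None:
        raise ValueError("net primary production is required (never withheld)")
    rows = [
        MeasurementConstraint(
            "NPP",
            {
                "NFX->CYA": 1.0, "NO3->CYA": 1.0, "NH4->CYA": 1.0, "CYA->DOM": -1.0,
                "NFX->DTM": 1.0, "NO3->DTM": 1.0, "NH4->DTM": 1.0, "DTM->DOM": -1.0,
            },
            npp,
        )
    ]
    if get("nitrate_uptake") is not None:
        rows.append(MeasurementConstraint(
            "NitrateUptake", {"NO3->CYA": 1.0, "NO3->DTM": 1.0}, get("nitrate_uptake")))
    if get("mesozoo_grazing") is not None:
        rows.append(MeasurementConstraint(
            "MesozooGrazing", {"DTM->MES": 1.0}, get("mesozoo_grazing")))
    if get("export") is not None:
        rows.append(MeasurementConstraint(
            "SedimentTrapExport", {"DET->SNK": 1.0}, get("export")))
    return rows


def assemble_problem(
    model: FoodWebModel,
    measurements: list[MeasurementConstraint],
    inequalities: list[Inequality] | None = None,
    isotope_rows=None,
) -> LIMProblem:
    """Stack mass balance, measurement rows, optional isotope rows and
    inequality priors into a :class:`LIMProblem`.

    ``isotope_rows`` is an :class:`isolim.isotopes.IsotopeRowSet`; its rows are
    appended to the approximate block A with their own sigmas.
    """
    if inequalities is None:
        inequalities = default_inequalities(model)
    E, f, eq_names = model.mass_balance()

    A_rows, b_vals, sig, approx_names = [], [], [], []
    for m in measurements:
        A_rows.append(model.flow_vector(m.coefficients))
        b_vals.append(m.value)
        sig.append(m.sigma)
        approx_names.append(m.name)
    n_meas = len(A_rows)
    if isotope_rows is not None:
        A_iso, b_iso, sig_iso, names_iso = isotope_rows.as_matrix(model)
        A_rows += list(A_iso)
        b_vals += list(b_iso)
        sig += list(sig_iso)
        approx_names += names_iso
    A = np.array(A_rows) if A_rows else np.zeros((0, model.n_flows))
    b = np.array(b_vals)
    sigma = np.array(sig)

    G_rows = [np.eye(model.n_flows)]
    h_vals = [np.zeros(model.n_flows)]
    ineq_names = [f"nonneg_{fl.key}" for fl in model.flows]
    for iq in inequalities:
        G_rows.append(model.flow_vector(iq.coefficients)[None, :])
        h_vals.append(np.array([iq.bound]))
        ineq_names.append(iq.name)
    G = np.vstack(G_rows)
    h = np.concatenate(h_vals)
    return LIMProblem(
        model=model, E=E, f=f, A=A, b=b, sigma=sigma, G=G, h=h,
        equality_names=eq_names, approx_names=approx_names,
        inequality_names=ineq_names, n_measurement_rows=n_meas,
    )


def degrees_of_freedom(problem: LIMProblem) -> int:
    """Unknown flows minus the rank of the stacked constraining equations."""
    stacked = np.vstack([problem.E, problem.A]) if problem.A.size else problem.E
    return problem.n_flows - int(np.linalg.matrix_rank(stacked))


def find_feasible_point(
    problem: LIMProblem,
    tol: float = 1e-8,
    anchor_measurements: bool = True,
) -> np.ndarray:
    """A point satisfying ``Ex=f`` and ``Gx >= h - tol``.

    By default the measurement rows are first tried as exact equalities
    (which pins the overall scale and yields a well-centred start for
    sampling); if that system is infeasible they are dropped.  Among feasible
    points the minimum inequality slack is maximised (Chebyshev-like centre),
    with total flow capped to keep the program bounded on conic regions.
    """
    n = problem.n_flows

    def attempt(extra_eq: bool):
        A_eq = problem.E
        b_eq = problem.f
        if extra_eq and problem.n_measurement_rows:
            A_eq = np.vstack([A_eq, problem.A[: problem.n_measurement_rows]])
            b_eq = np.concatenate([b_eq, problem.b[: problem.n_measurement_rows]])
        # variables (x, t): maximise t with G x - h >= t * ||G_i||
        norms = np.linalg.norm(problem.G, axis=1)
        norms[norms == 0] = 1.0
        A_ub = np.hstack([-problem.G, norms[:, None]])
        b_ub = -problem.h
        # cap total flow so the conic case stays bounded
        scale = max(1.0, float(np.sum(np.abs(b_eq))) * 10.0) * 100.0
        A_ub = np.vstack([A_ub, np.hstack([np.ones((1, n)), np.zeros((1, 1))])])
        b_ub = np.append(b_ub, scale)
        c = np.zeros(n + 1)
        c[-1] = -1.0
        A_eq_t = np.hstack([A_eq, np.zeros((A_eq.shape[0], 1))])
        bounds = [(None, None)] * n + [(None, scale)]
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq_t, b_eq=b_eq,
                      bounds=bounds, method="highs")
        return res

    res = attempt(anchor_measurements)
    if (not res.success) and anchor_measurements:
        res = attempt(False)
    if not res.success:
        _raise_infeasible(problem, tol)
    x0 = res.x[:-1]
    viol = problem.h - problem.G @ x0
    eqv = problem.E @ x0 - problem.f
    if np.max(viol, initial=0.0) > tol or np.max(np.abs(eqv), initial=0.0) > tol:
        _raise_infeasible(problem, tol, x0)
    return x0


def _raise_infeasible(problem: LIMProblem, tol: float, x: np.ndarray | None = None):
    if x is None:
        # identify the worst constraint by phase-1 style relaxation
        msg = "no flow vector satisfies the equality and inequality constraints"
        n = problem.n_flows
        res = linprog(
            np.concatenate([np.zeros(n), np.ones(problem.G.shape[0])]),
            A_ub=np.hstack([-problem.G, -np.eye(problem.G.shape[0])]),
            b_ub=-problem.h,
            A_eq=np.hstack([problem.E, np.zeros((problem.E.shape[0], problem.G.shape[0]))]),
            b_eq=problem.f,
            bounds=[(None, None)] * n + [(0, None)] * problem.G.shape[0],
            method="highs",
        )
        if res.success:
            slacks = res.x[n:]
            worst = int(np.argmax(slacks))
            name = (problem.inequality_names[worst]
                    if worst < len(problem.inequality_names) else f"row {worst}")
            msg += f"; most violated constraint: {name!r} (needs slack {slacks[worst]:.3g})"
        raise InfeasibleProblemError(msg)
    viol = problem.h - problem.G @ x
    worst = int(np.argmax(viol))
    name = (problem.inequality_names[worst]
            if worst < len(problem.inequality_names) else f"row {worst}")
    raise InfeasibleProblemError(
        f"feasibility search stalled; constraint {name!r} violated by {viol[worst]:.3g}"
    )
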