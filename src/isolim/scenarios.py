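"""Built-in ecosystem scenarios, measurement-withholding sets, and a
synthetic ground-truth generator.

Four steady-state ecosystem snapshots ship as fixtures: two Amazon-plume
states (coastal, mesohaline — a diazotroph-friendly regime with substantial
N2 fixation) and two California-Current states (coastal upwelling, offshore
oligotrophic).  Each fixture carries the rate and delta-15N measurements
given to the inverse model plus the withheld "true" ecosystem indices used
for evaluation.

The synthetic generator replaces those snapshots with fully known ground
truths: a mass-balanced flow vector drawn uniformly from the model polytope,
its self-consistent steady-state delta-15N field, and noisy observations of
whatever a field program could measure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .foodweb import (FoodWebModel, Inequality, LIMProblem, assemble_problem,
                      build_pelagic_foodweb, default_inequalities,
                      find_feasible_point, measurement_equations)
from .indices import compute_indices
from .isotopes import (IsotopeRowSet, IsotopeSpec, build_isotope_rows,
                       steady_state_deltas)

__all__ = ["ScenarioFixture", "SyntheticTruth", "SCENARIO_NAMES",
           "table2_fixtures", "builtin_scenarios", "get_scenario",
           "withholding_scenarios", "isotope_spec_for", "build_problem",
           "grid_problem_builder", "generate_synthetic_truth",
           "fixture_checksum"]

MEASUREMENT_KEYS = ("npp", "nitrate_uptake", "mesozoo_grazing", "export")

SCENARIO_NAMES = ("diazo_coastal", "diazo_mesohaline",
                  "nemuro_coastal", "nemuro_offshore")


@dataclass
class ScenarioFixture:
    """One ecosystem snapshot: inverse-model inputs plus withheld truth."""

    name: str
    npp: float
    nitrate_uptake: float
    mesozoo_grazing: float
    export: float
    cya_biomass: float
    dtm_biomass: float
    mes_biomass: float
    temperature: float
    delta_upno3: float
    delta_mes: float
    delta_dom: float
    delta_sinking: float
    truth: dict[str, float] = field(default_factory=dict)

    def measurements(self, withheld: tuple[str, ...] = ()) -> dict[str, float | None]:
        """Measurement dict for :func:`~isolim.foodweb.measurement_equations`;
        withheld entries become None."""
        bad = set(withheld) - set(MEASUREMENT_KEYS)
        if bad:
            raise ValueError(f"unknown measurement(s) {sorted(bad)}")
        if "npp" in withheld:
            raise ValueError("net primary production cannot be withheld")
        vals = {k: getattr(self, k) for k in MEASUREMENT_KEYS}
        for k in withheld:
            vals[k] = None
        return vals


def table2_fixtures() -> dict[str, ScenarioFixture]:
    """The four built-in steady-state scenarios (values as printed; N2
    fixation converted from umol to mmol N m-2 d-1)."""
    common_gge = {"protozoan_gge": 0.3, "mes_gge": 0.3}
    fixtures = {
        "diazo_coastal": ScenarioFixture(
            name="diazo_coastal",
            npp=2.17, nitrate_uptake=0.72, mesozoo_grazing=1.09, export=0.42,
            cya_biomass=1.55, dtm_biomass=2.57, mes_biomass=6.38,
            temperature=28.0,
            delta_upno3=7.70, delta_mes=6.10, delta_dom=4.20, delta_sinking=3.98,
            truth={
                "n2_fixation": 0.00311, "total_n_uptake": 3.09,
                "cya_npp": 0.48, "dtm_npp": 1.69,
                "protozoan_grazing": 0.73, "mes_carnivory": 0.0,
                "protozoan_carnivory": 0.11, "mes_secondary_production": 0.30,
                **common_gge,
                "protozoan_tl": 2.12, "mes_tl": 2.15,
                "herbivorous_chain": 0.50, "multivorous_chain": 0.34,
                "microbial_loop": 0.80,
                "d15N_NO3": 13.25, "d15N_NH4": 13.25,
                "d15N_CYA": 3.03, "d15N_DTM": 3.17, "d15N_protozoans": 6.17,
            },
        ),
        "diazo_mesohaline": ScenarioFixture(
            name="diazo_mesohaline",
            npp=0.70, nitrate_uptake=0.04, mesozoo_grazing=0.24, export=0.10,
            cya_biomass=1.21, dtm_biomass=1.63, mes_biomass=2.14,
            temperature=28.0,
            delta_upno3=13.25, delta_mes=5.08, delta_dom=2.95, delta_sinking=2.88,
            truth={
                "n2_fixation": 0.10048, "total_n_uptake": 0.96,
                "cya_npp": 0.25, "dtm_npp": 0.45,
                "protozoan_grazing": 0.36, "mes_carnivory": 0.0,
                "protozoan_carnivory": 0.07, "mes_secondary_production": 0.04,
                **common_gge,
                "protozoan_tl": 2.22, "mes_tl": 2.21,
                "herbivorous_chain": 0.34, "multivorous_chain": 0.51,
                "microbial_loop": 0.83,
                "d15N_NO3": 11.96, "d15N_NH4": 11.96,
                "d15N_CYA": 1.73, "d15N_DTM": 1.59, "d15N_protozoans": 5.04,
            },
        ),
        "nemuro_coastal": ScenarioFixture(
            name="nemuro_coastal",
            npp=13.61, nitrate_uptake=8.44, mesozoo_grazing=8.11, export=7.28,
            cya_biomass=12.12, dtm_biomass=34.58, mes_biomass=18.38,
            temperature=12.0,
            delta_upno3=5.70, delta_mes=7.68, delta_dom=4.87, delta_sinking=4.42,
            truth={
                "n2_fixation": 0.0, "total_n_uptake": 17.16,
                "cya_npp": 2.51, "dtm_npp": 11.10,
                "protozoan_grazing": 0.53, "mes_carnivory": 1.89,
                "protozoan_carnivory": 0.0, "mes_secondary_production": 1.16,
                **common_gge,
                "protozoan_tl": 2.00, "mes_tl": 2.46,
                "herbivorous_chain": 0.23, "multivorous_chain": 0.01,
                "microbial_loop": 0.19,
                "d15N_NO3": 9.92, "d15N_NH4": 12.80,
                "d15N_CYA": 3.91, "d15N_DTM": 3.87, "d15N_protozoans": 6.52,
            },
        ),
        "nemuro_offshore": ScenarioFixture(
            name="nemuro_offshore",
            npp=2.42, nitrate_uptake=0.95, mesozoo_grazing=1.25, export=0.69,
            cya_biomass=14.65, dtm_biomass=10.94, mes_biomass=17.99,
            temperature=14.0,
            delta_upno3=5.70, delta_mes=7.23, delta_dom=4.66, delta_sinking=4.82,
            truth={
                "n2_fixation": 0.0, "total_n_uptake": 3.53,
                "cya_npp": 1.33, "dtm_npp": 1.09,
                "protozoan_grazing": 0.74, "mes_carnivory": 0.24,
                "protozoan_carnivory": 0.0, "mes_secondary_production": 0.26,
                **common_gge,
                "protozoan_tl": 2.00, "mes_tl": 2.37,
                "herbivorous_chain": 0.27, "multivorous_chain": 0.16,
                "microbial_loop": 0.28,
                "d15N_NO3": 8.84, "d15N_NH4": 13.60,
                "d15N_CYA": 3.65, "d15N_DTM": 3.64, "d15N_protozoans": 6.26,
            },
        ),
    }
    return fixtures


builtin_scenarios = table2_fixtures


def get_scenario(name: str) -> ScenarioFixture:
    fixtures = table2_fixtures()
    if name not in fixtures:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    return fixtures[name]


def fixture_checksum() -> str:
    """Stable digest of every numeric value in the built-in fixtures."""
    payload = {
        name: {
            "inputs": [getattr(fx, k) for k in (
                *MEASUREMENT_KEYS, "cya_biomass", "dtm_biomass", "mes_biomass",
                "temperature", "delta_upno3", "delta_mes", "delta_dom",
                "delta_sinking")],
            "truth": dict(sorted(fx.truth.items())),
        }
        for name, fx in sorted(table2_fixtures().items())
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


#: Digest of the shipped fixture values; guards against accidental edits.
FIXTURE_CHECKSUM = "31a533adf248978c2a05299d6136880ddd922f69a367c7d8753887d8af8fda83"


def withholding_scenarios(fixture: ScenarioFixture) -> list[dict]:
    """The seven measurement configurations: full, three singles withheld,
    three pairs withheld.  NPP is always retained."""
    optional = ("nitrate_uptake", "mesozoo_grazing", "export")
    sets: list[tuple[str, ...]] = [()]
    sets += [(k,) for k in optional]
    sets += [(optional[i], optional[j])
             for i in range(3) for j in range(i + 1, 3)]
    out = []
    for withheld in sets:
        label = "full" if not withheld else "no_" + "+".join(withheld)
        out.append({
            "name": label,
            "withheld": withheld,
            "measurements": fixture.measurements(withheld),
        })
    return out


def isotope_spec_for(fixture: ScenarioFixture,
                     bounds: tuple[float, float] | None = None) -> IsotopeSpec:
    """Isotope spec with the fixture's four measured deltas as known values."""
    spec = IsotopeSpec(delta_known={
        "upno3": fixture.delta_upno3,
        "MES": fixture.delta_mes,
        "DOM": fixture.delta_dom,
        "DET": fixture.delta_sinking,
    })
    if bounds is not None:
        spec.bounds = {k: tuple(bounds) for k in spec.bounds}
    return spec


def build_problem(
    fixture: ScenarioFixture,
    withheld: tuple[str, ...] = (),
    with_isotopes: bool = False,
    inequalities: list[Inequality] | None = None,
    model: FoodWebModel | None = None,
    x_ref: np.ndarray | None = None,
):
    """Assemble the LIM for a scenario.

    Returns ``(problem, rows)``; ``rows`` is the :class:`IsotopeRowSet`
    (with sigmas referenced to a feasible point) when ``with_isotopes`` is
    set, else None.  The isotope rows enter the approximate block with delta
    unknowns at the spec's current values; samplers and the grid search
    re-evaluate them as needed.
    """
    model = model or build_pelagic_foodweb()
    meas = measurement_equations(model, fixture.measurements(withheld))
    base = assemble_problem(model, meas, inequalities)
    if not with_isotopes:
        return base, None
    rows = build_isotope_rows(model, isotope_spec_for(fixture))
    if x_ref is None:
        x_ref = find_feasible_point(base)
    rows.attach_sigma(x_ref)
    problem = assemble_problem(model, meas, inequalities, isotope_rows=rows)
    return problem, rows


def grid_problem_builder(fixture: ScenarioFixture,
                         withheld: tuple[str, ...] = (),
                         inequalities: list[Inequality] | None = None):
    """A ``builder(deltas) -> LIMProblem`` closure for the L2MN grid search.

    Isotope-row sigmas are referenced once to the feasible point of the base
    problem, so grid points differ only in the row coefficients.
    """
    model = build_pelagic_foodweb()
    meas = measurement_equations(model, fixture.measurements(withheld))
    ineqs = inequalities if inequalities is not None else default_inequalities(model)
    base = assemble_problem(model, meas, ineqs)
    x_ref = find_feasible_point(base)

    def builder(deltas) -> LIMProblem:
        spec = isotope_spec_for(fixture).with_unknowns(deltas)
        rows = build_isotope_rows(model, spec).attach_sigma(x_ref)
        return assemble_problem(model, meas, ineqs, isotope_rows=rows)

    return builder


# ---------------------------------------------------------------------------
# Synthetic ground truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """A fully known ecosystem state for recovery experiments."""

    x_true: np.ndarray
    delta_true: dict[str, float]
    delta_upno3: float
    measurements: dict[str, float]
    seed: int
    noise_rel: float

    def to_fixture(self, model: FoodWebModel | None = None) -> ScenarioFixture:
        model = model or build_pelagic_foodweb()
        idx = compute_indices(self.x_true, model).as_dict()
        truth = dict(idx)
        truth.update({f"d15N_{k}": v for k, v in self.delta_true.items()})
        return ScenarioFixture(
            name=f"synthetic_{self.seed}",
            npp=self.measurements["npp"],
            nitrate_uptake=self.measurements["nitrate_uptake"],
            mesozoo_grazing=self.measurements["mesozoo_grazing"],
            export=self.measurements["export"],
            cya_biomass=np.nan, dtm_biomass=np.nan, mes_biomass=np.nan,
            temperature=np.nan,
            delta_upno3=self.delta_upno3,
            delta_mes=self.delta_true["MES"],
            delta_dom=self.delta_true["DOM"],
            delta_sinking=self.delta_true["DET"],
            truth=truth,
        )


def generate_synthetic_truth(
    seed: int,
    noise_rel: float = 0.10,
    npp_scale: float = 1.0,
    n_steps: int = 50_000,
    thin: int = 50,
) -> SyntheticTruth:
    """Draw a ground-truth ecosystem state from the model polytope.

    The inequality-constrained mass-balance set is a cone (every prior is a
    ratio), so the draw is made on its section at fixed net primary
    production ``npp_scale``, via a uniform mirror chain decorrelated from
    the feasible start.  Steady-state deltas use an exogenous-nitrate delta
    drawn uniformly from [4, 14] permil.  Rate measurements get
    multiplicative Gaussian noise of sd ``noise_rel``; the four measured
    deltas are passed through exactly.
    """
    from .sampler import ChainConfig, run_chain

    if noise_rel < 0:
        raise ValueError("noise_rel must be >= 0")
    rng = np.random.default_rng(seed)
    model = build_pelagic_foodweb()
    meas = measurement_equations(model, {"npp": npp_scale})
    base = assemble_problem(model, meas)
    # pin the NPP row as an exact equality: scale section of the cone
    E = np.vstack([base.E, base.A[:1]])
    f = np.concatenate([base.f, base.b[:1]])
    pinned = LIMProblem(
        model=model, E=E, f=f,
        A=np.zeros((0, model.n_flows)), b=np.zeros(0), sigma=np.zeros(0),
        G=base.G, h=base.h,
        equality_names=base.equality_names + ["NPP_pin"],
        inequality_names=base.inequality_names,
    )
    chain_seed = int(rng.integers(0, 2**31 - 1))
    ens = run_chain(pinned, ChainConfig(
        n_iter=n_steps, burn_in=n_steps // 5, thin=thin,
        seed=chain_seed))
    x_true = ens.samples[-1]

    delta_upno3 = float(rng.uniform(4.0, 14.0))
    delta_true = steady_state_deltas(model, x_true, delta_upno3)

    def observed(coeffs_row):
        return float(coeffs_row @ x_true)

    meas_rows = measurement_equations(model, {
        "npp": 1.0, "nitrate_uptake": 1.0, "mesozoo_grazing": 1.0, "export": 1.0})
    true_obs = {}
    for m in meas_rows:
        key = {"NPP": "npp", "NitrateUptake": "nitrate_uptake",
               "MesozooGrazing": "mesozoo_grazing",
               "SedimentTrapExport": "export"}[m.name]
        true_obs[key] = observed(model.flow_vector(m.coefficients))
    noisy = {}
    for key, val in true_obs.items():
        fac = 1.0 + noise_rel * rng.standard_normal() if noise_rel > 0 else 1.0
        while fac <= 0.01:
            fac = 1.0 + noise_rel * rng.standard_normal()
        noisy[key] = val * fac
    return SyntheticTruth(
        x_true=x_true, delta_true=delta_true, delta_upno3=delta_upno3,
        measurements=noisy, seed=seed, noise_rel=noise_rel,
    )
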