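"""Plain-text (YAML) declarations for models and scenarios.

A model declaration carries the compartment list, the ordered flows, the
measurement constraints, the inequality priors and an optional isotope
block; a scenario file carries one set of measurement values plus the
withheld truth.  Reading a written declaration reproduces the in-memory
objects exactly (round-trip identity on the parsed data)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .foodweb import (Compartment, FoodWebModel, Inequality,
                      MeasurementConstraint)
from .isotopes import UNKNOWN_DELTA_ORDER, IsotopeSpec
from .scenarios import ScenarioFixture, get_scenario, table2_fixtures

__all__ = [
    "model_to_dict", "model_from_dict", "save_model", "load_model",
    "scenario_to_dict", "scenario_from_dict", "save_scenario",
    "load_scenario", "resolve_scenario", "isotope_spec_to_dict",
    "isotope_spec_from_dict",
]


def model_to_dict(model: FoodWebModel,
                  measurements: list[MeasurementConstraint] | None = None,
                  inequalities: list[Inequality] | None = None,
                  isotopes: IsotopeSpec | None = None) -> dict:
    d: dict = {
        "compartments": [
            {"name": c.name, "living": c.living, "external": c.external,
             "delta_known": c.delta_known}
            for c in model.compartments
        ],
        "flows": [f"{fl.source} -> {fl.target}" for fl in model.flows],
    }
    if measurements is not None:
        d["measurements"] = [
            {"name": m.name, "coefficients": dict(m.coefficients),
             "value": m.value, "rel_sd": m.rel_uncertainty}
            for m in measurements
        ]
    if inequalities is not None:
        d["inequalities"] = [
            {"name": iq.name, "coefficients": dict(iq.coefficients),
             "bound": iq.bound, "direction": "ge"}
            for iq in inequalities
        ]
    if isotopes is not None:
        d["isotopes"] = isotope_spec_to_dict(isotopes)
    return d


def model_from_dict(d: dict):
    comps = [Compartment(**c) for c in d["compartments"]]
    flows = []
    for line in d["flows"]:
        src, dst = (s.strip() for s in line.split("->"))
        flows.append((src, dst))
    model = FoodWebModel(comps, flows)
    measurements = [
        MeasurementConstraint(m["name"], dict(m["coefficients"]),
                              m["value"], m["rel_sd"])
        for m in d.get("measurements", [])
    ]
    inequalities = [
        Inequality(iq["name"], dict(iq["coefficients"]), iq.get("bound", 0.0))
        for iq in d.get("inequalities", [])
    ]
    isotopes = (isotope_spec_from_dict(d["isotopes"])
                if "isotopes" in d else None)
    return model, measurements, inequalities, isotopes


def isotope_spec_to_dict(spec: IsotopeSpec) -> dict:
    return {
        "epsilons": dict(spec.epsilons),
        "r_n2": spec.r_n2,
        "delta_known": dict(spec.delta_known),
        "delta_unknown": {
            k: {"value": spec.delta_unknown[k],
                "lo": spec.bounds[k][0], "hi": spec.bounds[k][1]}
            for k in UNKNOWN_DELTA_ORDER
        },
        "delta_nfix": spec.delta_nfix,
    }


def isotope_spec_from_dict(d: dict) -> IsotopeSpec:
    du = {k: v["value"] for k, v in d["delta_unknown"].items()}
    bounds = {k: (v["lo"], v["hi"]) for k, v in d["delta_unknown"].items()}
    return IsotopeSpec(epsilons=dict(d["epsilons"]), r_n2=d["r_n2"],
                       delta_known=dict(d["delta_known"]),
                       delta_unknown=du, bounds=bounds,
                       delta_nfix=d.get("delta_nfix", 0.0))


def _clean(v):
    if isinstance(v, float) and np.isnan(v):
        return None
    return v


def scenario_to_dict(fx: ScenarioFixture) -> dict:
    return {
        "name": fx.name,
        "measurements": {
            "npp": fx.npp, "nitrate_uptake": fx.nitrate_uptake,
            "mesozoo_grazing": fx.mesozoo_grazing, "export": fx.export,
        },
        "stocks": {
            "cya_biomass": _clean(fx.cya_biomass),
            "dtm_biomass": _clean(fx.dtm_biomass),
            "mes_biomass": _clean(fx.mes_biomass),
            "temperature": _clean(fx.temperature),
        },
        "delta15n": {
            "exogenous_no3": fx.delta_upno3, "mesozooplankton": fx.delta_mes,
            "dom": fx.delta_dom, "sinking_detritus": fx.delta_sinking,
        },
        "truth": {k: float(v) for k, v in sorted(fx.truth.items())},
    }


def scenario_from_dict(d: dict) -> ScenarioFixture:
    s = d.get("stocks", {})

    def st(key):
        v = s.get(key)
        return np.nan if v is None else v

    return ScenarioFixture(
        name=d["name"],
        npp=d["measurements"]["npp"],
        nitrate_uptake=d["measurements"]["nitrate_uptake"],
        mesozoo_grazing=d["measurements"]["mesozoo_grazing"],
        export=d["measurements"]["export"],
        cya_biomass=st("cya_biomass"), dtm_biomass=st("dtm_biomass"),
        mes_biomass=st("mes_biomass"), temperature=st("temperature"),
        delta_upno3=d["delta15n"]["exogenous_no3"],
        delta_mes=d["delta15n"]["mesozooplankton"],
        delta_dom=d["delta15n"]["dom"],
        delta_sinking=d["delta15n"]["sinking_detritus"],
        truth=dict(d.get("truth", {})),
    )


def save_scenario(fx: ScenarioFixture, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(fx), sort_keys=False))


def load_scenario(path) -> ScenarioFixture:
    return scenario_from_dict(yaml.safe_load(Path(path).read_text()))


def resolve_scenario(name_or_path: str) -> ScenarioFixture:
    """A built-in scenario name, or a path to a scenario file."""
    if name_or_path in table2_fixtures():
        return get_scenario(name_or_path)
    p = Path(name_or_path)
    if p.exists():
        return load_scenario(p)
    raise KeyError(f"{name_or_path!r} is neither a built-in scenario nor a file")


def save_model(model, path, **kwargs) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model, **kwargs),
                                         sort_keys=False))


def load_model(path):
    return model_from_dict(yaml.safe_load(Path(path).read_text()))
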