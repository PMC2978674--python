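"""Run configuration: YAML/JSON parsing, defaults, and resolved-config echo.

Every analysis run is described by a serializable configuration; the
resolved configuration (defaults filled in) is written next to the outputs
so that every number in a result file is reproducible from its sibling
config alone.  Networks come either from a built-in model id
(``competence_reduced``, ``competence_full``) or from an inline network
specification with named propensity templates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .competence import (
    DEFAULT_COMPETENCE_THRESHOLD_NM,
    DEFAULT_HORIZON_S,
    DEFAULT_RETURN_THRESHOLD_NM,
    competence_threshold_molecules,
    full_competence_network,
    reduced_competence_network,
    return_threshold_molecules,
    vegetative_fixed_point,
)
from .network import (
    ExpressionPropensity,
    HillActivation,
    HillRepression,
    MassAction,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    SaturableDegradation,
)
from .statespace import Region

__all__ = ["RunConfig", "load_config", "build_network", "build_region", "dump_json"]

BUILTIN_MODELS = ("competence_reduced", "competence_full")

_DEFAULTS: dict[str, Any] = {
    "model": "competence_reduced",
    "params": {},
    "binding_params": None,
    "network": None,
    "bounds": [1200, 600],
    "regions": {},
    "horizon_s": DEFAULT_HORIZON_S,
    "time_grid": {"n": 25},
    "tolerances": {"solver": 1e-10, "target_eps": 1e-3},
    "ssa": {"n_runs": 1000, "delta": 0.01, "seed": 0},
    "sensitivity": {
        "parameters": ["ak", "bk", "bs", "delta_k", "delta_s"],
        "method": "both",
        "rel_step": 0.01,
    },
    "return_time": {"dt": 60.0, "t_max": DEFAULT_HORIZON_S},
    "initial_state": "vegetative",
    "output_dir": "results",
}


@dataclass
class RunConfig:
    """A fully resolved, serializable analysis configuration."""

    data: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = _merge(_DEFAULTS, self.data)
        unknown = set(merged) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unrecognized config key(s): {sorted(unknown)}")
        self.data = merged

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def resolved(self) -> dict[str, Any]:
        return json.loads(json.dumps(self.data, default=_jsonable))

    def echo(self, path: str | Path) -> None:
        """Write the resolved configuration next to the run's outputs."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=True)

    # -- derived objects ---------------------------------------------------

    def network(self) -> ReactionNetwork:
        return build_network(self.data)

    def bounds(self) -> tuple[int, ...]:
        return tuple(int(b) for b in self.data["bounds"])

    def regions(self, net: ReactionNetwork) -> dict[str, Region]:
        out = {}
        for name, spec in self.data["regions"].items():
            out[name] = build_region(spec, net.species, name=name)
        if not out and isinstance(net.params, ParameterSet) and net.n_species == 2:
            kc = competence_threshold_molecules(net.params)
            kr = return_threshold_molecules(net.params)
            out = {
                "competence": Region.rectangle(
                    [(kc, None), (None, None)], name=f"ComK >= {kc}"),
                "return": Region.rectangle(
                    [(None, kr), (None, None)], name=f"ComK <= {kr}"),
            }
        return out

    def time_grid(self) -> np.ndarray:
        T = float(self.data["horizon_s"])
        tg = self.data["time_grid"]
        if "dt" in tg:
            grid = np.arange(float(tg["dt"]), T + float(tg["dt"]) / 2, float(tg["dt"]))
            if len(grid) == 0 or grid[-1] < T:
                grid = np.append(grid, T)
            return grid
        return np.linspace(T / int(tg["n"]), T, int(tg["n"]))

    def initial_state(self, net: ReactionNetwork) -> np.ndarray:
        spec = self.data["initial_state"]
        if spec == "vegetative":
            return vegetative_fixed_point(net)
        return np.asarray(spec, dtype=np.int64)


def _merge(defaults: dict, overrides: dict) -> dict:
    out = dict(defaults)
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = {**out[key], **value}
        else:
            out[key] = value
    return out


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML (or JSON) config file and apply overrides."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    if overrides:
        data = _merge(data, overrides)
    return RunConfig(data)


def build_network(cfg: dict[str, Any]) -> ReactionNetwork:
    """Instantiate the configured model (built-in id or inline spec)."""
    if cfg.get("network"):
        return _network_from_spec(cfg["network"])
    model = cfg.get("model", "competence_reduced")
    if model not in BUILTIN_MODELS:
        raise ValueError(f"unknown model {model!r}; built-ins: {BUILTIN_MODELS}")
    params = ParameterSet(**(cfg.get("params") or {}))
    if model == "competence_reduced":
        return reduced_competence_network(params)
    return full_competence_network(params, cfg.get("binding_params"))


_TEMPLATES = ("hill_activation", "hill_repression", "saturable_degradation",
              "mass_action", "expression")


def _network_from_spec(spec: dict[str, Any]) -> ReactionNetwork:
    species = tuple(spec["species"])
    pset = ParameterSet(**spec["params"]) if spec.get("params") else None
    consts: dict[str, float] = dict(spec.get("constants") or {})

    def index_of(name: str) -> int:
        if name not in species:
            raise ValueError(f"unknown species {name!r} in network spec")
        return species.index(name)

    reactions = []
    for rspec in spec["reactions"]:
        prop = rspec["propensity"]
        template = prop.get("template")
        if template not in _TEMPLATES:
            raise ValueError(
                f"reaction {rspec.get('name')!r}: propensity template must be "
                f"one of {_TEMPLATES}, got {template!r}")
        if template == "mass_action":
            pname = prop.get("param_name", f"rate_{len(reactions)}")
            if "rate" in prop:
                consts.setdefault(pname, float(prop["rate"]))
            reactants = tuple(index_of(s) for s in prop.get("reactants", []))
            fn = MassAction(consts, reactants=reactants, param_name=pname,
                            omega=float(spec.get("omega", 1.0)))
        elif template == "expression":
            fn = ExpressionPropensity(prop["expr"], species, consts or pset)
        else:
            if pset is None:
                raise ValueError(f"template {template!r} requires a 'params' block")
            if template == "hill_activation":
                fn = HillActivation(pset, activator=index_of(prop.get("activator", species[0])))
            elif template == "hill_repression":
                fn = HillRepression(pset, repressor=index_of(prop.get("repressor", species[0])))
            else:
                fn = SaturableDegradation(
                    pset, target=index_of(prop["target"]),
                    rate_name=prop.get("rate_name", "delta_k"),
                    comk=index_of(prop.get("comk", species[0])),
                    coms=index_of(prop.get("coms", species[min(1, len(species) - 1)])))
        reactions.append(Reaction(rspec.get("name", f"reaction_{len(reactions)}"),
                                  tuple(int(v) for v in rspec["stoichiometry"]), fn))
    return ReactionNetwork(species=species, reactions=tuple(reactions),
                           params=pset if pset is not None else consts)


def build_region(spec: Any, species: tuple[str, ...], name: str = "") -> Region:
    """Region from a config entry: ``{rect: [[lo, hi], ...]}`` or
    ``{expr: "ComK >= 65"}``."""
    if isinstance(spec, Region):
        return spec
    if "rect" in spec:
        return Region.rectangle([tuple(pair) for pair in spec["rect"]], name=name)
    if "expr" in spec:
        return Region.from_expression(spec["expr"], species, name=name or spec["expr"])
    raise ValueError(f"region {name!r} needs a 'rect' or 'expr' entry")


def dump_json(obj: dict, path: str | Path) -> None:
    """Serialize scalars with 12 significant digits, stable key order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def round_sig(x: Any) -> Any:
        if isinstance(x, dict):
            return {k: round_sig(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [round_sig(v) for v in x]
        if isinstance(x, (float, np.floating)):
            return float(f"{float(x):.12g}")
        if isinstance(x, (np.integer,)):
            return int(x)
        return x

    with open(path, "w") as fh:
        json.dump(round_sig(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
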