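"""Configuration loading, serialization and run manifests.

A farm instance (plus, optionally, its stochastic environment) is described
by a flat YAML document with sections ``farm``, ``costs``, ``options``,
``deficit_grid``, ``et_profile`` and optionally ``models``.  Each section may
declare the units its numbers are written in (any unit known to
:mod:`irriplan.units`); omitted units mean canonical SI.  Loading converts
everything to SI and validates the instance, so a configuration written in
acres/inches/$-per-acre-inch loads to exactly the same instance as its SI
transcription.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scenarios import (
    PrecipWeekModel,
    PriceModel,
    ScenarioFan,
    ScenarioTree,
    WaterLimitModel,
    default_precip_models,
    default_price_model,
    default_water_limit_model,
)
from .types import FarmInstance, ManagementOption, validate_instance
from .units import convert

__all__ = [
    "load_instance",
    "load_config",
    "save_instance",
    "save_tree",
    "load_tree",
    "save_fan",
    "load_fan",
    "RunManifest",
    "write_manifest",
    "read_workbook_overrides",
]


class ConfigError(ValueError):
    """Schema violation in a configuration file."""


def _get(section: dict, key: str, where: str):
    if key not in section:
        raise ConfigError(f"missing required key {key!r} in section {where!r}")
    return section[key]


def _conv(value, unit: str | None, si_unit: str):
    if unit is None or unit == si_unit:
        return float(value)
    return convert(float(value), unit, si_unit)


def load_config(path) -> tuple[
    FarmInstance, PriceModel, WaterLimitModel, tuple[PrecipWeekModel, ...]
]:
    """Load an instance and its stochastic environment from YAML.

    The ``models`` section is optional; absent entries fall back to the
    default case-study distributions.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    instance = _parse_instance(doc)
    models = doc.get("models", {}) or {}
    price = _parse_price_model(models.get("price"))
    water = _parse_water_model(models.get("water_limit"))
    precip = _parse_precip_models(models.get("precipitation"), instance.n_periods)
    return instance, price, water, precip


def load_instance(path) -> FarmInstance:
    """Load just the farm instance (SI-converted and validated)."""
    return load_config(path)[0]


def _parse_instance(doc: dict) -> FarmInstance:
    farm = _get(doc, "farm", "<root>")
    funits = farm.get("units", {})
    costs = _get(doc, "costs", "<root>")
    cunits = costs.get("units", {})
    opts = _get(doc, "options", "<root>")
    ounits = opts.get("units", {})
    et = _get(doc, "et_profile", "<root>")
    dg = doc.get("deficit_grid", {"n_levels": 101})

    n_periods = int(farm.get("n_periods", 8))
    area = _conv(_get(farm, "area", "farm"), funits.get("area"), "m2")
    depth_u = funits.get("depth")
    instance_kwargs = dict(
        area=area,
        efficiency=float(_get(farm, "efficiency", "farm")),
        holding_capacity=_conv(_get(farm, "holding_capacity", "farm"), depth_u, "m"),
        pre_irrigation=_conv(_get(farm, "pre_irrigation", "farm"), depth_u, "m"),
        water_cost=_conv(_get(costs, "water_cost", "costs"),
                         cunits.get("water_cost"), "usd_per_m3"),
        fixed_irrigation_cost=_conv(
            _get(costs, "fixed_irrigation_cost", "costs"),
            cunits.get("areal_cost"), "usd_per_m2"),
        overhead=float(_get(costs, "overhead", "costs")),
        min_yield=_conv(costs.get("min_yield", 0.0), cunits.get("mass"), "kg"),
        n_periods=n_periods,
    )
    option_list = []
    for i, entry in enumerate(_get(opts, "list", "options")):
        option_list.append(ManagementOption(
            index=i,
            seed_cost=_conv(_get(entry, "seed_cost", f"options[{i}]"),
                            ounits.get("cost"), "usd_per_m2"),
            operating_cost=_conv(_get(entry, "operating_cost", f"options[{i}]"),
                                 ounits.get("cost"), "usd_per_m2"),
            max_yield=_conv(_get(entry, "max_yield", f"options[{i}]"),
                            ounits.get("yield"), "kg_per_m2"),
            response_factor=float(_get(entry, "response_factor", f"options[{i}]")),
            label=str(entry.get("label", f"option {i}")),
        ))
    if "levels" in dg:
        grid = np.asarray(dg["levels"], dtype=float)
    else:
        grid = np.linspace(0.0, 1.0, int(dg.get("n_levels", 101)))
    et_unit = et.get("unit")
    if "values" in et:
        et_values = np.array([_conv(v, et_unit, "m") for v in et["values"]])
    else:
        et_values = np.full(n_periods, _conv(_get(et, "value", "et_profile"),
                                             et_unit, "m"))
    return validate_instance(FarmInstance(
        options=tuple(option_list),
        max_et=et_values,
        deficit_grid=grid,
        **instance_kwargs,
    ))


def _parse_price_model(section) -> PriceModel:
    if not section:
        return default_price_model()
    unit = section.get("unit")
    kwargs = {"april_price": _conv(_get(section, "april_price", "models.price"),
                                   unit, "usd_per_kg")}
    if "mean_shift" in section:
        kwargs["mean_shift"] = _conv(section["mean_shift"], unit, "usd_per_kg")
    if "sd" in section:
        kwargs["sd"] = _conv(section["sd"], unit, "usd_per_kg")
    return PriceModel(**kwargs)


def _parse_water_model(section) -> WaterLimitModel:
    if not section:
        return default_water_limit_model()
    unit = section.get("unit")
    return WaterLimitModel(
        lower=_conv(_get(section, "lower", "models.water_limit"), unit, "m"),
        upper=_conv(_get(section, "upper", "models.water_limit"), unit, "m"),
    )


def _parse_precip_models(section, n_periods: int) -> tuple[PrecipWeekModel, ...]:
    if not section:
        return default_precip_models()
    unit = section.get("unit")
    persistence = float(section.get("persistence", 0.0))
    rows = _get(section, "weeks", "models.precipitation")
    if len(rows) != n_periods:
        raise ConfigError(
            f"precipitation table has {len(rows)} weeks, horizon is {n_periods}"
        )
    models = []
    for row in rows:
        mu = _conv(_get(row, "daily_mean", "precipitation week"), unit, "m")
        var = float(_get(row, "daily_variance", "precipitation week"))
        if unit is not None:
            var = var * convert(1.0, unit, "m") ** 2
        wk = _conv(_get(row, "weekly_mean", "precipitation week"), unit, "m")
        models.append(PrecipWeekModel.from_weekly_stats(mu, var, wk, persistence))
    return tuple(models)


def save_instance(instance: FarmInstance, path,
                  price: PriceModel | None = None,
                  water: WaterLimitModel | None = None,
                  precip: tuple[PrecipWeekModel, ...] | None = None) -> None:
    """Write a configuration in canonical SI units (round-trips exactly)."""
    doc: dict = {
        "farm": {
            "area": float(instance.area),
            "efficiency": float(instance.efficiency),
            "holding_capacity": float(instance.holding_capacity),
            "pre_irrigation": float(instance.pre_irrigation),
            "n_periods": int(instance.n_periods),
        },
        "costs": {
            "water_cost": float(instance.water_cost),
            "fixed_irrigation_cost": float(instance.fixed_irrigation_cost),
            "overhead": float(instance.overhead),
            "min_yield": float(instance.min_yield),
        },
        "options": {"list": [
            {
                "label": o.label,
                "seed_cost": float(o.seed_cost),
                "operating_cost": float(o.operating_cost),
                "max_yield": float(o.max_yield),
                "response_factor": float(o.response_factor),
            }
            for o in instance.options
        ]},
        "deficit_grid": {"levels": [float(v) for v in instance.deficit_grid]},
        "et_profile": {"values": [float(v) for v in instance.max_et]},
    }
    models: dict = {}
    if price is not None:
        models["price"] = {"april_price": float(price.april_price),
                           "mean_shift": float(price.mean_shift),
                           "sd": float(price.sd)}
    if water is not None:
        models["water_limit"] = {"lower": float(water.lower),
                                 "upper": float(water.upper)}
    if precip is not None:
        models["precipitation"] = {"weeks": [
            {"daily_mean": float(m.daily_mean),
             "daily_variance": float(m.daily_variance),
             "weekly_mean": float(m.weekly_mean)}
            for m in precip
        ]}
    if models:
        doc["models"] = models
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Tree / fan serialization
# ---------------------------------------------------------------------------

def save_tree(tree: ScenarioTree, path) -> None:
    """Node-table CSV plus a JSON sidecar with branching and seed."""
    path = Path(path)
    tree.to_frame().to_csv(path, index=False)
    header = {"branching": list(tree.branching), "seed": tree.seed}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))


def load_tree(path) -> ScenarioTree:
    path = Path(path)
    df = pd.read_csv(path)
    side = path.with_suffix(path.suffix + ".json")
    branching, seed = (), None
    if side.exists():
        header = json.loads(side.read_text())
        branching = tuple(header.get("branching", ()))
        seed = header.get("seed")
    return ScenarioTree.from_frame(df, branching=branching, seed=seed)


def save_fan(fan: ScenarioFan, path) -> None:
    fan.to_frame().to_csv(path, index=False)


def load_fan(path) -> ScenarioFan:
    return ScenarioFan.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    arguments: dict
    seeds: dict
    solver_options: dict
    package_version: str
    timestamp: str
    outputs: list


def write_manifest(path, command: str, arguments: dict, seeds: dict,
                   solver_options: dict, outputs: list) -> RunManifest:
    from . import __version__
    manifest = RunManifest(
        command=command,
        arguments={k: str(v) for k, v in arguments.items()},
        seeds=seeds,
        solver_options=solver_options,
        package_version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=[str(o) for o in outputs],
    )
    Path(path).write_text(json.dumps(asdict(manifest), indent=2))
    return manifest


# ---------------------------------------------------------------------------
# Cost-workbook overrides
# ---------------------------------------------------------------------------

def read_workbook_overrides(workbook_path, mapping_path) -> dict:
    """Read cost overrides for :func:`irriplan.fixtures.fixture_paper_instance`
    from a spreadsheet workbook via a declared cell mapping.

    The mapping file is YAML: top-level keys are override keys (any key of
    ``STANDIN_COSTS``, or ``options`` for the per-option table), each with
    ``sheet`` and ``cell`` (e.g. ``B3``); option tables use ``rows`` of
    ``[label_cell, seed_cost_cell, max_yield_cell, response_factor_cell]``.
    Tolerant of column order because every value is addressed by cell.
    """
    import openpyxl

    mapping = yaml.safe_load(Path(mapping_path).read_text())
    wb = openpyxl.load_workbook(workbook_path, data_only=True)
    overrides: dict = {}
    for key, spec in mapping.items():
        sheet = wb[spec["sheet"]]
        if key == "options":
            table = {}
            for row in spec["rows"]:
                label, seed_c, yield_c, k_c = row
                table[str(sheet[label].value)] = (
                    float(sheet[seed_c].value),
                    float(sheet[yield_c].value),
                    float(sheet[k_c].value),
                )
            overrides["options"] = table
        else:
            overrides[key] = float(sheet[spec["cell"]].value)
    return overrides
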