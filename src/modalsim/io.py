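"""Readers, writers, configuration and presets.

Data exchange uses one tidy long format: a CSV with a group column and a
numeric outcome column (one row per subject).  Results serialize to a
schema-versioned JSON document; simulation configurations load from YAML
or JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, SchemaError
from .samplers import GroupSpec

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

DESIGNS = ("trio_accumulation", "mc_power", "mc_anova", "categorical_null", "mcmc_compare")

_REQUIRED_PARAMS = {
    "trio_accumulation": ("n_max",),
    "mc_power": ("n_per_group",),
    "mc_anova": ("n_per_group",),
    "categorical_null": ("n_per_group",),
    "mcmc_compare": ("n_per_group",),
}


@dataclass(frozen=True)
class TidyTable:
    """Long-format (group, value) data plus the count of dropped rows."""

    frame: pd.DataFrame
    n_dropped: int = 0

    def groups(self) -> dict[str, np.ndarray]:
        return {str(g): sub["value"].to_numpy(dtype=float)
                for g, sub in self.frame.groupby("group", sort=True)}


@dataclass(frozen=True)
class RunConfig:
    groups: tuple[GroupSpec, ...]
    design: str
    params: dict
    test: str = "pooled_t"
    alpha: float = 0.05
    seed: int = 101
    out: str | None = None


def read_tidy_csv(path, group_column: str = "group",
                  value_column: str = "value") -> TidyTable:
    """Read tidy CSV data; non-numeric outcome rows are dropped with a warning."""
    df = pd.read_csv(path)
    for col in (group_column, value_column):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not found in {path}")
    values = pd.to_numeric(df[value_column], errors="coerce")
    keep = values.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("read_tidy_csv: dropped %d non-numeric rows from %s", n_dropped, path)
    out = pd.DataFrame({"group": df.loc[keep, group_column].astype(str),
                        "value": values[keep]}).reset_index(drop=True)
    if out.empty:
        raise EmptyInputError(f"no usable rows in {path}")
    return TidyTable(out, n_dropped)


def load_config(path) -> RunConfig:
    """Load a simulation RunConfig from YAML or JSON."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise SchemaError(f"config {path} is not a mapping")
    if "design" not in raw:
        raise SchemaError("config missing 'design'")
    design = raw["design"]
    if design not in DESIGNS:
        raise SchemaError(f"unknown design {design!r}; expected one of {DESIGNS}")
    groups = tuple(GroupSpec.from_dict(g) for g in raw.get("groups", []))
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise SchemaError(f"group names are not unique: {names}")
    params = dict(raw.get("params", {}))
    for key in _REQUIRED_PARAMS[design]:
        if key not in params:
            raise SchemaError(f"design {design!r} requires param {key!r}")
    return RunConfig(groups=groups, design=design, params=params,
                     test=raw.get("test", "pooled_t"),
                     alpha=float(raw.get("alpha", 0.05)),
                     seed=int(raw.get("seed", 101)),
                     out=raw.get("out"))


def load_preset(name: str = "basson") -> dict:
    """Load a named parameter preset shipped with the package.

    Returns a dict with ``groups`` (name -> GroupSpec for every fully
    specified group) and the raw ``montecarlo`` section.
    """
    ref = resources.files("modalsim") / "presets" / f"{name}.yaml"
    raw = yaml.safe_load(ref.read_text())
    groups = {}
    for g in raw.get("groups", []):
        if g.get("mean") is None and g.get("family") == "gaussian":
            logger.warning("preset %s: group %r has no printed parameters; skipped",
                           name, g.get("name"))
            continue
        spec = GroupSpec.from_dict({k: v for k, v in g.items() if k != "note"})
        groups[spec.name] = spec
    return {"groups": groups, "montecarlo": raw.get("montecarlo", {}),
            "raw": raw}


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_run_report(results, out_path, config: dict | None = None,
                     seed: int | None = None) -> dict:
    """Serialize result objects to schema-versioned JSON; returns the document."""
    doc = {"schema_version": SCHEMA_VERSION,
           "seed": seed,
           "config": _to_jsonable(config) if config is not None else None,
           "results": _to_jsonable(results)}
    Path(out_path).write_text(json.dumps(doc, indent=2))
    return doc


def read_run_report(path) -> dict:
    return json.loads(Path(path).read_text())
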