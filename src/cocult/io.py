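"""Config parsing, parameter/condition serialization and run manifests.

All files are plain text: parameters and priors are flat key-value JSON or
YAML blocks (chosen by file extension) that round-trip at full float
precision; results are delimited tables plus a JSON manifest echoing the
configuration, seeds, convergence diagnostics and output inventory.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import yaml

from . import __version__
from .data import Condition
from .params import DirectParams, InterventionSchedule, ResourceParams
from .priors import PriorSpec

__all__ = [
    "load_mapping",
    "dump_mapping",
    "load_params",
    "save_params",
    "load_conditions",
    "save_conditions",
    "load_prior",
    "RunConfig",
    "run_manifest",
]


def load_mapping(path) -> dict:
    """Read a JSON or YAML mapping (by extension; YAML otherwise)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        obj = json.loads(text)
    else:
        obj = yaml.safe_load(text)
    if not isinstance(obj, dict):
        raise ValueError(f"{path.name}: expected a mapping at top level")
    return obj


def dump_mapping(obj: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=True))


def load_params(path):
    """Load DirectParams or ResourceParams from a flat config block.

    The model is recognised from the key set.
    """
    d = load_mapping(path)
    keys = set(d)
    if keys >= set(DirectParams.names):
        return DirectParams.from_dict(d)
    if keys >= set(ResourceParams.names):
        return ResourceParams.from_dict(d)
    raise ValueError(
        f"config keys {sorted(keys)} match neither the direct nor the "
        "resource parameter set"
    )


def save_params(params, path) -> None:
    dump_mapping(params.to_dict(), path)


def _condition_to_dict(c: Condition) -> dict:
    d = {
        "id": c.id,
        "W0": c.W0,
        "P0": c.P0,
        "sample_days": list(c.sample_days),
    }
    if c.schedule is not None:
        d["schedule"] = {"t_dox": c.schedule.t_dox, "mode": c.schedule.mode}
    return d


def _condition_from_dict(d: dict) -> Condition:
    schedule = None
    if d.get("schedule") is not None:
        s = d["schedule"]
        schedule = InterventionSchedule(
            t_dox=s.get("t_dox"), mode=s.get("mode", "full")
        )
    return Condition(
        id=str(d["id"]),
        W0=float(d["W0"]),
        P0=float(d["P0"]),
        sample_days=tuple(float(x) for x in d["sample_days"]),
        schedule=schedule,
    )


def save_conditions(conditions: Sequence[Condition], path) -> None:
    dump_mapping({"conditions": [_condition_to_dict(c) for c in conditions]}, path)


def load_conditions(path) -> List[Condition]:
    d = load_mapping(path)
    if "conditions" not in d:
        raise ValueError(f"{Path(path).name}: missing 'conditions' key")
    return [_condition_from_dict(c) for c in d["conditions"]]


def load_prior(path) -> PriorSpec:
    return PriorSpec.from_dict(load_mapping(path))


@dataclass
class RunConfig:
    """Settings of one inference run, echoed into the manifest."""

    model: str = "direct"
    dt: float = 0.01
    n_chains: int = 5
    n_iter: int = 2500
    burn_frac: float = 0.5
    seed: int = 0
    sigma2_floor: float = 1.0
    data_path: Optional[str] = None
    out_dir: Optional[str] = None
    log_level: str = "info"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def run_manifest(config: RunConfig, results: Optional[dict] = None,
                 outputs: Optional[Sequence[str]] = None) -> dict:
    """JSON-able record of a run: config echo, seeds, version, diagnostics.

    ``results`` may carry convergence flags, per-parameter R-hat values,
    summaries etc.; ``outputs`` is the inventory of files the run wrote.
    """
    return {
        "package": "cocult",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "results": results or {},
        "outputs": list(outputs or []),
    }
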