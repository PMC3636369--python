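"""Configuration files, result writers and run manifests.

A single JSON dialect holds the full model input: nuclide library,
landscape (objects, schedules, edges), exposure habits and release
scenario.  All validation is done by the pydantic models themselves; the
machine-readable schema can be emitted with :func:`config_json_schema`.
Result CSV floats are pinned to 9 significant digits so reruns with the
same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import pandas as pd
from pydantic import BaseModel, Field

from .dose import DoseResult, ExposureHabits
from .landscape import LandscapeGraph
from .nuclides import NuclideLibrary, ValidationError
from .solver import ReleaseScenario

FLOAT_FORMAT = "%.9g"
CODE_VERSION = "0.1.0"


@dataclass
class ConfigBundle:
    """Validated model objects loaded from one configuration."""

    graph: LandscapeGraph
    library: NuclideLibrary
    habits: ExposureHabits
    scenario: Optional[ReleaseScenario] = None


def config_to_dict(
    graph: LandscapeGraph,
    library: NuclideLibrary,
    habits: Optional[ExposureHabits] = None,
    scenario: Optional[ReleaseScenario] = None,
) -> dict[str, Any]:
    config: dict[str, Any] = {
        "library": library.model_dump(mode="json"),
        "landscape": graph.model_dump(mode="json"),
        "habits": (habits or ExposureHabits()).model_dump(mode="json"),
    }
    if scenario is not None:
        config["scenario"] = scenario.model_dump(mode="json")
    return config


def load_config(source: dict[str, Any] | str | Path) -> ConfigBundle:
    """Validate a config dict or JSON file into model objects.

    All cross-references (nuclides, elements, objects, edges, schedules)
    are resolved by the model validators; violations raise with a
    human-readable message.
    """
    if not isinstance(source, dict):
        path = Path(source)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        source = json.loads(path.read_text())
    try:
        graph = LandscapeGraph.model_validate(source["landscape"])
        library = NuclideLibrary.model_validate(source["library"])
        habits = ExposureHabits.model_validate(source.get("habits", {}))
        scenario = (
            ReleaseScenario.model_validate(source["scenario"])
            if "scenario" in source
            else None
        )
    except KeyError as exc:
        raise ValidationError(f"config missing section {exc}") from None
    return ConfigBundle(graph=graph, library=library, habits=habits, scenario=scenario)


def save_config(config: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")


def config_hash(config: dict[str, Any]) -> str:
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def config_json_schema() -> dict[str, Any]:
    """JSON-schema documents for each config section."""
    return {
        "library": NuclideLibrary.model_json_schema(),
        "landscape": LandscapeGraph.model_json_schema(),
        "habits": ExposureHabits.model_json_schema(),
        "scenario": ReleaseScenario.model_json_schema(),
    }


def set_by_path(config: dict[str, Any], path: str, value: float) -> None:
    """Set a dotted-path leaf in a nested config dict.

    A numeric value assigned where a time series lives replaces it with a
    constant series (the usual case for sampled time-independent
    parameters).
    """
    keys = path.split(".")
    node = config
    for key in keys[:-1]:
        if key not in node:
            raise ValidationError(f"override path {path!r}: missing key {key!r}")
        node = node[key]
    leaf = keys[-1]
    if leaf not in node:
        raise ValidationError(f"override path {path!r}: missing key {leaf!r}")
    current = node[leaf]
    if isinstance(current, dict) and set(current) == {"t", "v"}:
        node[leaf] = {"t": [0.0], "v": [float(value)]}
    else:
        node[leaf] = float(value)


class RunManifest(BaseModel):
    """Provenance record written next to every result set."""

    config_hash: str
    seed: Optional[int] = None
    code_version: str = CODE_VERSION
    started: str = ""
    finished: str = ""
    warnings: list[str] = Field(default_factory=list)
    solver: dict[str, float] = Field(
        default_factory=lambda: {"refresh_years": 1.0, "negativity_tolerance": 1e-12}
    )


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_results(
    out_dir: str | Path,
    config: dict[str, Any],
    dose_results: Optional[list[DoseResult]] = None,
    mc_samples: Optional[pd.DataFrame] = None,
    sensitivity: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
    warnings: Optional[list[str]] = None,
    started: str = "",
) -> Path:
    """Write tidy CSV outputs plus a JSON run manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dose_results:
        rows = [
            {
                "nuclide": r.nuclide,
                "period": r.period,
                "mode": r.mode,
                "ldf": r.ldf,
                "argmax_object": r.argmax_object,
                "argmax_year": r.argmax_time,
            }
            for r in dose_results
        ]
        _write_csv(pd.DataFrame(rows), out / "ldf_table.csv")
        doses = pd.concat(
            [r.doses.assign(nuclide=r.nuclide, mode=r.mode) for r in dose_results],
            ignore_index=True,
        )
        _write_csv(doses, out / "dose_timeseries.csv")
        inventories = pd.concat(
            [r.solution.to_dataframe() for r in dose_results if r.solution is not None],
            ignore_index=True,
        )
        _write_csv(inventories, out / "inventories.csv")
    if mc_samples is not None:
        _write_csv(mc_samples, out / "mc_samples.csv")
    if sensitivity is not None:
        _write_csv(sensitivity, out / "sensitivity.csv")
    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=seed,
        warnings=warnings or [],
        started=started,
        finished=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.model_dump_json(indent=2) + "\n")
    return manifest_path
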