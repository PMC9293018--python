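"""File round-tripping: observation tables, model/fit configs, reports.

Tables are delimited text (comma by default, tab accepted) in tidy long
format; configuration files are flat JSON keyed exactly by the field names
of the corresponding dataclasses.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitConfig, FitResult, ObservationSet
from .model import (
    PARAMETER_FIELDS,
    STATE_FIELDS,
    ModelOptions,
    ModelParameters,
    SystemState,
)
from .simulate import SweepResult, Trajectory

__all__ = [
    "read_observations",
    "write_observations",
    "read_model_config",
    "write_model_config",
    "read_fit_config",
    "write_fit_config",
    "write_trajectory",
    "write_sweep",
    "write_fit_report",
    "RunManifest",
    "write_manifest",
]

_INIT_KEYS = ("B0", "D0", "DOM_E0", "DOM_B0")
_OPTION_KEYS = (
    "consumption_mode",
    "exudation_costs_biomass",
    "mu_B_resolution",
    "yield_cells_per_dom",
)
_REQUIRED_OBS_COLUMNS = ("time_days", "species", "replicate", "value")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_observations(path) -> ObservationSet:
    """Read a tidy observation table.

    Expected header: ``time_days, species, replicate, value`` (optional
    ``censored``).  Lines starting with ``#`` are metadata; ``# units:``
    lines of the form ``# units: B=CFU ml^-1`` are echoed into the result.
    """
    path = Path(path)
    units = {"B": "CFU ml^-1", "D": "cells ml^-1"}
    data_lines: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip().lstrip("#").strip()
                if body.lower().startswith("units:"):
                    for part in body[6:].split(","):
                        if "=" in part:
                            key, _, val = part.partition("=")
                            units[key.strip()] = val.strip()
                continue
            data_lines.append((lineno, line))
    if not data_lines:
        raise ValueError(f"{path}: no data rows")

    delim = _sniff_delimiter(data_lines[0][1])
    header = [c.strip() for c in next(csv.reader([data_lines[0][1]], delimiter=delim))]
    missing = [c for c in _REQUIRED_OBS_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header was {header}")

    rows = []
    for lineno, line in data_lines[1:]:
        cells = next(csv.reader([line], delimiter=delim))
        if len(cells) != len(header):
            raise ValueError(f"{path}: row {lineno} has {len(cells)} fields, expected {len(header)}")
        rec = dict(zip(header, (c.strip() for c in cells)))
        try:
            row = {
                "time_days": float(rec["time_days"]),
                "species": rec["species"],
                "replicate": int(rec["replicate"]),
                "value": float(rec["value"]),
            }
        except ValueError as exc:
            raise ValueError(f"{path}: row {lineno}: {exc}") from None
        if row["value"] < 0:
            raise ValueError(f"{path}: row {lineno}: negative value {row['value']}")
        if "censored" in rec:
            row["censored"] = rec["censored"].lower() in ("1", "true", "yes")
        rows.append(row)
    try:
        return ObservationSet(pd.DataFrame(rows), units=units)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_observations(obs: ObservationSet, path, delimiter: str = ",") -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("# units: " + ", ".join(f"{k}={v}" for k, v in sorted(obs.units.items())) + "\n")
        obs.data.to_csv(fh, sep=delimiter, index=False)


def read_model_config(path) -> tuple[ModelParameters, SystemState, ModelOptions]:
    """Read a flat JSON config holding parameters, initial state, options.

    Keys are the ModelParameters field names, ``B0/D0/DOM_E0/DOM_B0`` for
    the initial state (DOM pools default to 0), and the ModelOptions field
    names.  Unknown keys are rejected.  CC_B is accepted with a warning
    since it does not enter the dynamics.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    known = set(PARAMETER_FIELDS) | set(_INIT_KEYS) | set(_OPTION_KEYS)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {unknown}")
    missing = [k for k in PARAMETER_FIELDS if k not in raw and k != "CC_B"]
    if missing:
        raise ValueError(f"{path}: missing parameter key(s) {missing}")
    if "CC_B" in raw:
        warnings.warn("CC_B is accepted but does not affect the model dynamics")
    params = ModelParameters(**{k: float(raw[k]) for k in PARAMETER_FIELDS if k in raw})
    init = SystemState(
        B=float(raw.get("B0", 0.0)),
        D=float(raw.get("D0", 0.0)),
        DOM_E=float(raw.get("DOM_E0", 0.0)),
        DOM_B=float(raw.get("DOM_B0", 0.0)),
    )
    opt_kwargs = {k: raw[k] for k in _OPTION_KEYS if k in raw}
    options = ModelOptions(**opt_kwargs)
    return params, init, options


def write_model_config(params: ModelParameters, init: SystemState, options: ModelOptions, path) -> None:
    payload = params.to_dict()
    payload.update({f"{name}0": getattr(init, name) for name in STATE_FIELDS})
    payload.update(options.to_dict())
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fit_config(path) -> FitConfig:
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    field_names = {f.name for f in dataclasses.fields(FitConfig)}
    unknown = sorted(set(raw) - field_names)
    if unknown:
        raise ValueError(f"{path}: unknown fit-config key(s) {unknown}")
    if "free_parameters" in raw:
        raw["free_parameters"] = tuple(raw["free_parameters"])
    if "bounds" in raw:
        raw["bounds"] = {k: tuple(v) for k, v in raw["bounds"].items()}
    return FitConfig(**raw)


def write_fit_config(config: FitConfig, path) -> None:
    payload = dataclasses.asdict(config)
    payload["free_parameters"] = list(config.free_parameters)
    payload["bounds"] = {k: list(v) for k, v in config.bounds.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_trajectory(traj: Trajectory, path, delimiter: str = ",") -> None:
    traj.to_frame().to_csv(path, sep=delimiter, index=False)


def write_sweep(result: SweepResult, path, delimiter: str = ",") -> None:
    result.to_frame().to_csv(path, sep=delimiter, index=False)


def write_fit_report(result: FitResult, report_path, params_path=None) -> None:
    """Plain-text key-value report plus a simulator-ready parameter file."""
    lines = [
        f"objective_value = {result.objective_value:.10g}",
        f"n_evaluations = {result.n_evaluations}",
        f"converged = {result.converged}",
        f"seed = {result.seed}",
        f"at_bounds = {','.join(result.at_bounds) if result.at_bounds else 'none'}",
    ]
    for series, (r2, p) in result.gof.items():
        lines.append(f"R2[{series}] = {r2:.6g}")
        lines.append(f"p_value[{series}] = {p:.6g}")
    for name, value in result.params_hat.to_dict().items():
        lines.append(f"param[{name}] = {value:.10g}")
    for name, value in result.init_hat.to_dict().items():
        lines.append(f"init[{name}0] = {value:.10g}")
    Path(report_path).write_text("\n".join(lines) + "\n")
    if params_path is not None:
        write_model_config(result.params_hat, result.init_hat, ModelOptions(), params_path)


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    config: dict
    inputs: tuple
    outputs: tuple
    rng_seed: int | None
    package_version: str
    started_utc: str


def write_manifest(manifest: RunManifest, path) -> None:
    payload = dataclasses.asdict(manifest)
    payload["inputs"] = list(manifest.inputs)
    payload["outputs"] = list(manifest.outputs)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def new_manifest(command: str, config: dict, inputs, outputs, rng_seed=None) -> RunManifest:
    from . import __version__

    return RunManifest(
        command=command,
        config=config,
        inputs=tuple(str(p) for p in inputs),
        outputs=tuple(str(p) for p in outputs),
        rng_seed=rng_seed,
        package_version=__version__,
        started_utc=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
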