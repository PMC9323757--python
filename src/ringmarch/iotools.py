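"""Configuration parsing, snapshot/trace/result serialization, rendering.

Formats: JSON for state snapshots and oracle reports, JSON Lines for
per-step traces and run records, CSV for sweep tables.  Snapshots use the
documented coordinate convention (``x`` in ``[0, n)`` with clockwise = +x,
``y`` in ``[0, k)``, heading ``b`` in ``{1, -1}``) and round-trip
bit-exactly.  CSV floats carry six significant digits; JSON keeps full
precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .model import ConfigError, ModelConfig, RunRecord, SwarmState
from .observables import SWEEP_COLUMNS

__all__ = [
    "ARTIFACT_VERSION",
    "parse_config",
    "snapshot_dict",
    "state_from_snapshot",
    "save_snapshot",
    "load_snapshot",
    "render_state",
    "run_record_dict",
    "write_results",
    "read_results",
    "step_report_dict",
]

ARTIFACT_VERSION = "ringmarch-0.1.0"

_CONFIG_KEYS = {f.name for f in dataclasses.fields(ModelConfig)}
_RUN_KEYS = {"stop_mode"}


def parse_config(
    source: Union[str, Path, dict, None] = None, **overrides
) -> tuple[ModelConfig, dict]:
    """Resolve a model configuration from a file and/or explicit overrides.

    ``source`` may be a JSON or YAML file path or an already-loaded mapping;
    explicit keyword overrides (e.g. CLI flags) take precedence over file
    values.  Unknown keys are rejected by name; giving both ``m`` and
    ``density`` is ambiguous and rejected.  Returns the validated config
    plus the leftover run-level settings (currently just ``stop_mode``).
    """
    data: dict = {}
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        if str(source).endswith((".yaml", ".yml")):
            data = yaml.safe_load(text) or {}
        else:
            try:
                data = json.loads(text)
            except json.JSONDecodeError:
                data = yaml.safe_load(text) or {}
    elif isinstance(source, dict):
        data = dict(source)
    elif source is not None:
        raise TypeError(f"unsupported config source: {type(source)!r}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - _CONFIG_KEYS - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if data.get("m") is not None and data.get("density") is not None:
        raise ConfigError("give either m or density, not both")
    run_settings = {k: data.pop(k) for k in list(_RUN_KEYS) if k in data}
    run_settings.setdefault("stop_mode", "auto")
    return ModelConfig(**data), run_settings


# ---------------------------------------------------------------------------
# Snapshots
# ---------------------------------------------------------------------------


def snapshot_dict(state: SwarmState) -> dict:
    return {
        "n": state.n,
        "k": state.k,
        "t": state.t,
        "locusts": [
            {"id": i, "x": state.xs[i], "y": state.ys[i], "b": state.bs[i]}
            for i in range(state.m)
        ],
    }


def state_from_snapshot(data: dict) -> SwarmState:
    locusts = sorted(data["locusts"], key=lambda loc: loc["id"])
    if [loc["id"] for loc in locusts] != list(range(len(locusts))):
        raise ConfigError("snapshot locust ids must be 0..m-1")
    return SwarmState(
        n=data["n"],
        k=data["k"],
        xs=[loc["x"] for loc in locusts],
        ys=[loc["y"] for loc in locusts],
        bs=[loc["b"] for loc in locusts],
        t=data.get("t", 0),
    )


def save_snapshot(state: SwarmState, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(snapshot_dict(state), indent=1) + "\n")


def load_snapshot(path: Union[str, Path]) -> SwarmState:
    return state_from_snapshot(json.loads(Path(path).read_text()))


def render_state(state: SwarmState) -> str:
    """ASCII arena: '>' clockwise, '<' counterclockwise, '.' empty.

    The highest track prints first, matching top-track-up diagrams.
    """
    rows = []
    for y in range(state.k - 1, -1, -1):
        row = []
        for x in range(state.n):
            occ = state.grid[y * state.n + x]
            row.append("." if occ < 0 else (">" if state.bs[occ] == 1 else "<"))
        rows.append("".join(row))
    return "\n".join(rows)


# ---------------------------------------------------------------------------
# Run records, step reports, sweep tables
# ---------------------------------------------------------------------------


def run_record_dict(record: RunRecord) -> dict:
    cfg = dataclasses.asdict(record.config)
    return {
        "config": cfg,
        "stop_mode": record.stop_mode,
        "tstable": record.tstable,
        "reached": record.reached,
        "total_conflicts": record.total_conflicts,
        "total_switches_eligible": record.total_switches_eligible,
        "total_switches_erratic": record.total_switches_erratic,
        "seed": record.seed,
        "version": ARTIFACT_VERSION,
    }


def step_report_dict(report) -> dict:
    """JSON-able per-step trace line."""
    return {
        "horizontal_moves": report.horizontal_moves,
        "blocked": report.blocked,
        "idled_erratically": report.idled_erratically,
        "conflicts": [list(p) for p in report.conflicts],
        "flips": report.flips,
        "switches": report.switches,
    }


def diagnostics_dict(
    state: SwarmState,
    track: Optional[int] = None,
    interval: Optional[tuple] = None,
) -> dict:
    """Structural diagnostics of one configuration for trace lines.

    Always reports per-track segment counts and the number of deadlocked
    compact-set pairs; when a track and analysis interval are designated,
    also the potentials L1/L2/L3/L and F on that interval.
    """
    from .structure import deadlock_pairs, potentials, segment_counts

    out = {
        "t": state.t,
        "segment_counts": segment_counts(state),
        "deadlock_pairs": len(deadlock_pairs(state)),
    }
    if track is not None and interval is not None:
        s = potentials(state, track, tuple(interval))
        out["potentials"] = {
            "track": track,
            "interval": list(interval),
            "L1": s.L1,
            "L2": s.L2,
            "L3": s.L3,
            "L": s.L,
            "F": s.F,
        }
    return out


def write_results(
    table, path: Union[str, Path], fmt: str = "csv", meta: Optional[dict] = None
) -> None:
    """Write a sweep table (CSV) or run records (JSON Lines).

    CSV output starts with a ``#`` metadata line embedding the artifact
    version and any resolved settings; floats are fixed at six significant
    digits, so two writes of the same table are byte-identical.
    """
    path = Path(path)
    if fmt == "csv":
        if not isinstance(table, pd.DataFrame):
            table = pd.DataFrame(list(table), columns=SWEEP_COLUMNS)
        header = {"version": ARTIFACT_VERSION}
        if meta:
            header.update(meta)
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
            table.to_csv(fh, index=False, float_format="%.6g")
    elif fmt == "jsonl":
        with open(path, "w") as fh:
            for row in table:
                if isinstance(row, RunRecord):
                    row = run_record_dict(row)
                fh.write(json.dumps(row, sort_keys=True) + "\n")
    else:
        raise ValueError(f"format must be 'csv' or 'jsonl', got {fmt!r}")


def read_results(path: Union[str, Path], fmt: str = "csv"):
    """Read back what :func:`write_results` wrote."""
    path = Path(path)
    if fmt == "csv":
        return pd.read_csv(path, comment="#")
    if fmt == "jsonl":
        return [json.loads(line) for line in path.read_text().splitlines() if line]
    raise ValueError(f"format must be 'csv' or 'jsonl', got {fmt!r}")
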