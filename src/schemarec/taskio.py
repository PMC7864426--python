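"""Task-file formats: JSON canonical form, CSV export, monoid presets.

JSON is canonical because task tables are nested maps; a flat CSV export
(task, shape, stimulus, target rows) is provided for spreadsheet
inspection.  Validation reports the offending field path rather than
raising bare KeyErrors.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Optional, Union

from .finite_algebra import (
    Monoid,
    make_cyclic_monoid,
    make_klein_monoid,
    monoid_from_dict,
    monoid_to_dict,
)
from .paradigm import ExperimentSeries, TaskInstance
from .transfer import InformationTrial

__all__ = [
    "TaskFileError",
    "FORMAT_VERSION",
    "resolve_monoid",
    "series_to_dict",
    "series_from_dict",
    "read_task_file",
    "write_task_file",
    "export_series_csv",
    "read_trials",
]

FORMAT_VERSION = 1

PRESETS = {
    "trivial": lambda: make_cyclic_monoid(1),
    "klein4": make_klein_monoid,
    **{f"cyclic{n}": (lambda n=n: make_cyclic_monoid(n)) for n in range(1, 9)},
}


class TaskFileError(ValueError):
    """A malformed or schema-violating task file, with field context."""

    def __init__(self, path: str, message: str):
        self.field_path = path
        super().__init__(f"{path}: {message}")


def resolve_monoid(spec: Union[str, Mapping, Monoid]) -> Monoid:
    """Accept a preset name, an inline monoid object, or a Monoid."""
    if isinstance(spec, Monoid):
        return spec
    if isinstance(spec, str):
        if spec not in PRESETS:
            raise TaskFileError("monoid", f"unknown preset name {spec!r}")
        return PRESETS[spec]()
    if isinstance(spec, Mapping):
        try:
            return monoid_from_dict(spec)
        except ValueError as err:
            raise TaskFileError("monoid", str(err)) from err
    raise TaskFileError("monoid", f"expected preset name or object, got {type(spec).__name__}")


def series_to_dict(series: ExperimentSeries) -> dict:
    tasks = []
    for t in series.tasks:
        obj: dict = {
            "shapes": list(t.shapes),
            "stimuli": list(t.stimuli),
            "table": {
                str(sh): {str(s): t.table[(sh, s)] for s in t.stimuli}
                for sh in t.shapes
            },
        }
        if t.hidden_assignment is not None:
            obj["hidden_assignment"] = {str(sh): t.hidden_assignment[sh] for sh in t.shapes}
        if t.element_pool is not None:
            obj["element_pool"] = list(t.element_pool)
        tasks.append(obj)
    return {
        "format_version": FORMAT_VERSION,
        "monoid": monoid_to_dict(series.monoid),
        "condition": series.condition,
        "tasks": tasks,
    }


def _require(obj: Mapping, key: str, path: str):
    if key not in obj:
        raise TaskFileError(f"{path}.{key}", "missing required field")
    return obj[key]


def series_from_dict(obj: Mapping) -> ExperimentSeries:
    if not isinstance(obj, Mapping):
        raise TaskFileError("$", "task file must be a JSON object")
    version = obj.get("format_version", FORMAT_VERSION)
    if version != FORMAT_VERSION:
        raise TaskFileError("format_version", f"unsupported version {version!r}")
    monoid = resolve_monoid(_require(obj, "monoid", "$"))
    elems = set(monoid.elements)
    raw_tasks = _require(obj, "tasks", "$")
    if not isinstance(raw_tasks, list):
        raise TaskFileError("tasks", "must be a list")
    tasks = []
    for k, raw in enumerate(raw_tasks):
        path = f"tasks[{k}]"
        shapes = tuple(_require(raw, "shapes", path))
        stimuli = tuple(_require(raw, "stimuli", path))
        if len(set(shapes)) != len(shapes):
            raise TaskFileError(f"{path}.shapes", "duplicate shape symbols")
        if len(set(stimuli)) != len(stimuli):
            raise TaskFileError(f"{path}.stimuli", "duplicate stimulus symbols")
        raw_table = _require(raw, "table", path)
        by_shape = {str(sh): sh for sh in shapes}
        by_stim = {str(s): s for s in stimuli}
        table = {}
        for sh_key, row in raw_table.items():
            if sh_key not in by_shape:
                raise TaskFileError(f"{path}.table.{sh_key}", "unknown shape symbol")
            for s_key, target in row.items():
                if s_key not in by_stim:
                    raise TaskFileError(
                        f"{path}.table.{sh_key}.{s_key}", "unknown stimulus symbol"
                    )
                if target in set(stimuli):
                    tval = target
                elif isinstance(target, str) and target in by_stim:
                    tval = by_stim[target]
                else:
                    raise TaskFileError(
                        f"{path}.table.{sh_key}.{s_key}",
                        f"target {target!r} not in the stimulus vocabulary",
                    )
                table[(by_shape[sh_key], by_stim[s_key])] = tval
        for sh in shapes:
            for s in stimuli:
                if (sh, s) not in table:
                    raise TaskFileError(
                        f"{path}.table.{sh}.{s}", "missing cue-target entry"
                    )
        hidden = None
        if raw.get("hidden_assignment") is not None:
            hidden = {}
            for sh_key, e in raw["hidden_assignment"].items():
                if sh_key not in by_shape:
                    raise TaskFileError(
                        f"{path}.hidden_assignment.{sh_key}", "unknown shape symbol"
                    )
                if e not in elems:
                    raise TaskFileError(
                        f"{path}.hidden_assignment.{sh_key}",
                        f"element {e!r} not in the monoid",
                    )
                hidden[by_shape[sh_key]] = e
        pool = None
        if raw.get("element_pool") is not None:
            pool = tuple(raw["element_pool"])
            for e in pool:
                if e not in elems:
                    raise TaskFileError(
                        f"{path}.element_pool", f"element {e!r} not in the monoid"
                    )
        tasks.append(TaskInstance(shapes, stimuli, table, hidden, pool))
    return ExperimentSeries(monoid, tuple(tasks), obj.get("condition", "consistent"))


def read_task_file(path: Union[str, Path]) -> ExperimentSeries:
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise TaskFileError("$", f"malformed JSON: {err}") from err
    return series_from_dict(obj)


def write_task_file(series: ExperimentSeries, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(series_to_dict(series), indent=2, ensure_ascii=False) + "\n")


def export_series_csv(series: ExperimentSeries, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["task", "shape", "stimulus", "target"])
        for k, t in enumerate(series.tasks):
            for sh in t.shapes:
                for s in t.stimuli:
                    writer.writerow([k, sh, s, t.table[(sh, s)]])


def read_trials(path: Union[str, Path]) -> list[InformationTrial]:
    """Read ``[{"shape": ..., "stimulus": ..., "target": ...}, ...]``."""
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise TaskFileError("$", f"malformed JSON: {err}") from err
    if not isinstance(obj, list):
        raise TaskFileError("$", "trials file must be a JSON list")
    out = []
    for k, raw in enumerate(obj):
        for key in ("shape", "stimulus", "target"):
            if key not in raw:
                raise TaskFileError(f"[{k}].{key}", "missing required field")
        out.append(InformationTrial(raw["shape"], raw["stimulus"], raw["target"]))
    return out
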