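"""Plain-text configuration files for task and encoding specifications.

Schema: one ``key = value`` pair per line; ``#`` starts a comment; blank
lines are ignored.  A ``[task]`` or ``[encoding]`` section header selects
the target object.  Angles are radians by default; a ``deg`` suffix
(``rotation_angle = 45 deg``) converts from degrees.  Files written by
:func:`save_config` always store angles in radians.

Recognized keys
---------------
[task]      n_targets, target_radius, rotation_angle, n_baseline_trials,
            n_learning_trials, target_sequence_seed
[encoding]  kind (cosine2d | von_mises), n_input_units, precision
"""

from __future__ import annotations

import math
from pathlib import Path

from .task import InputEncoding, InvalidConfigError, TaskSpec

__all__ = ["load_config", "save_config"]

_ANGLE_KEYS = {"rotation_angle"}
_TASK_INT = {"n_targets", "n_baseline_trials", "n_learning_trials", "target_sequence_seed"}
_ENC_INT = {"n_input_units"}


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key == "kind":
        return raw
    degrees = False
    if raw.endswith("deg"):
        degrees = True
        raw = raw[:-3].strip()
    elif raw.endswith("rad"):
        raw = raw[:-3].strip()
    try:
        value = float(raw)
    except ValueError as err:
        raise InvalidConfigError(f"cannot parse value for {key!r}: {raw!r}") from err
    if degrees:
        if key not in _ANGLE_KEYS:
            raise InvalidConfigError(f"'deg' suffix only valid for angles, not {key!r}")
        value = math.radians(value)
    if key in _TASK_INT or key in _ENC_INT:
        if value != int(value):
            raise InvalidConfigError(f"{key!r} must be an integer")
        return int(value)
    return value


def load_config(path) -> tuple[TaskSpec, InputEncoding]:
    """Read a plain-text config file into (TaskSpec, InputEncoding)."""
    task_kwargs: dict = {}
    enc_kwargs: dict = {}
    section = "task"
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in ("task", "encoding"):
                raise InvalidConfigError(f"unknown section [{section}] at line {lineno}")
            continue
        if "=" not in line:
            raise InvalidConfigError(f"expected 'key = value' at line {lineno}: {line!r}")
        key, raw = (part.strip() for part in line.split("=", 1))
        target = task_kwargs if section == "task" else enc_kwargs
        target[key] = _parse_value(key, raw)
    return TaskSpec(**task_kwargs), InputEncoding(**enc_kwargs)


def save_config(path, task: TaskSpec, enc: InputEncoding) -> None:
    """Write a config file (angles in radians) that round-trips exactly."""
    lines = [
        "[task]",
        f"n_targets = {task.n_targets}",
        f"target_radius = {task.target_radius!r}",
        f"rotation_angle = {task.rotation_angle!r}",
        f"n_baseline_trials = {task.n_baseline_trials}",
        f"n_learning_trials = {task.n_learning_trials}",
        f"target_sequence_seed = {task.target_sequence_seed}",
        "",
        "[encoding]",
        f"kind = {enc.kind}",
    ]
    if enc.kind == "von_mises":
        lines += [
            f"n_input_units = {enc.n_input_units}",
            f"precision = {enc.precision!r}",
        ]
    Path(path).write_text("\n".join(lines) + "\n")
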