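"""Restart-file and pulse-log I/O.

The controller can drive an external MD engine by rewriting its restart
files between pulses.  Only the classic AMBER ASCII restart dialect
("rst7") is supported: a title line, an atom-count line (optionally with
the time in ps), coordinates as fixed-width %12.7f values six per line,
optionally velocities in the same layout, optionally a final box line of
six values.

Two boundary conventions are made explicit here because both are classic
pitfalls:

* AMBER restart velocities are in Å per 1/20.455 ps, not Å/ps; the factor
  is applied by :func:`convert_velocity_units` at this boundary only —
  everything inside the package is Å/ps.
* "no velocities" and "all-zero velocities" are different states; the
  reader distinguishes them (``velocities is None`` vs an array of zeros).

Pulse logs are plain CSV (one row per pulse) with a JSON sidecar manifest
carrying the run parameters, anchors, seed and a schema version; the
reader refuses logs whose schema major version differs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, RestartParseError, SchemaVersionError
from .protocol import TrajectoryResult

__all__ = [
    "AMBER_TIME_UNIT",
    "RestartState",
    "read_rst7",
    "write_rst7",
    "convert_velocity_units",
    "PULSE_LOG_SCHEMA",
    "write_pulse_log",
    "read_pulse_log",
]

# AMBER's internal time unit in ps: velocities in restart files are Å per
# (1/20.455) ps.
AMBER_TIME_UNIT = 20.455

_WIDTH = 12
_PER_LINE = 6

PULSE_LOG_SCHEMA = "1.0"

_PULSE_COLUMNS = [
    "index",
    "time_ps",
    "separation",
    "pre_pulse_velocity",
    "delta_v",
    "applied_force",
]


@dataclass
class RestartState:
    """Contents of one ASCII restart file (coordinates in Å)."""

    title: str
    n_atoms: int
    coordinates: np.ndarray  # (n, 3)
    velocities: np.ndarray | None = None  # (n, 3), engine units
    time_ps: float | None = None
    box: np.ndarray | None = None  # 6 numbers (lengths + angles)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.n_atoms, 3):
            raise InvalidArgumentError(
                f"coordinates must have shape ({self.n_atoms}, 3), "
                f"got {self.coordinates.shape}"
            )
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != (self.n_atoms, 3):
                raise InvalidArgumentError(
                    "velocities must match the coordinate shape or be None"
                )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (6,):
                raise InvalidArgumentError("box must hold exactly 6 numbers")


def _parse_fixed_line(line: str, lineno: int, expect: int | None = None) -> list[float]:
    text = line.rstrip("\n")
    if not text.strip():
        raise RestartParseError("unexpected blank line", line=lineno)
    n_fields = math.ceil(len(text) / _WIDTH)
    if expect is not None and n_fields != expect:
        raise RestartParseError(
            f"expected {expect} fixed-width fields, found {n_fields}", line=lineno
        )
    values = []
    for k in range(n_fields):
        chunk = text[k * _WIDTH : (k + 1) * _WIDTH]
        try:
            values.append(float(chunk))
        except ValueError:
            raise RestartParseError(
                f"field {k + 1} ({chunk!r}) is not a number", line=lineno
            ) from None
    return values


def read_rst7(path: str | Path) -> RestartState:
    """Parse an ASCII restart file.

    Trailing content is interpreted by line count: after the coordinate
    block, a full block of the same size is velocities; one extra 6-value
    line is a box.  A single trailing 6-value line on a 2-atom file is
    ambiguous between velocities and box; it is read as velocities (the
    state the pulling workflow round-trips), which is worth knowing if you
    hand-craft 2-atom boxes.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise RestartParseError("file has fewer than 2 lines", line=len(lines))
    title = lines[0].rstrip()
    header = lines[1].split()
    if not header:
        raise RestartParseError("missing atom count", line=2)
    try:
        n_atoms = int(header[0])
    except ValueError:
        raise RestartParseError(f"bad atom count {header[0]!r}", line=2) from None
    if n_atoms < 1:
        raise RestartParseError(f"atom count must be positive, got {n_atoms}", line=2)
    time_ps = None
    if len(header) > 1:
        try:
            time_ps = float(header[1])
        except ValueError:
            raise RestartParseError(f"bad time field {header[1]!r}", line=2) from None

    n_lines_block = math.ceil(3 * n_atoms / _PER_LINE)
    body = lines[2:]
    if len(body) < n_lines_block:
        raise RestartParseError(
            f"truncated coordinate block: need {n_lines_block} lines, have {len(body)}",
            line=len(lines),
        )

    def read_block(start: int) -> np.ndarray:
        values: list[float] = []
        remaining = 3 * n_atoms
        for offset in range(n_lines_block):
            expect = min(_PER_LINE, remaining)
            values.extend(
                _parse_fixed_line(body[start + offset], lineno=3 + start + offset, expect=expect)
            )
            remaining -= expect
        return np.array(values).reshape(n_atoms, 3)

    coords = read_block(0)
    rest = body[n_lines_block:]
    velocities = None
    box = None
    if len(rest) == 0:
        pass
    elif len(rest) == n_lines_block:
        velocities = read_block(n_lines_block)
    elif len(rest) == n_lines_block + 1:
        velocities = read_block(n_lines_block)
        box = np.array(
            _parse_fixed_line(rest[-1], lineno=3 + 2 * n_lines_block, expect=6)
        )
    elif len(rest) == 1:
        box = np.array(_parse_fixed_line(rest[0], lineno=3 + n_lines_block, expect=6))
    else:
        raise RestartParseError(
            f"unexpected trailing content: {len(rest)} lines after coordinates",
            line=3 + n_lines_block,
        )
    return RestartState(
        title=title,
        n_atoms=n_atoms,
        coordinates=coords,
        velocities=velocities,
        time_ps=time_ps,
        box=box,
    )


def _format_block(values: np.ndarray) -> list[str]:
    flat = values.reshape(-1)
    lines = []
    for start in range(0, flat.size, _PER_LINE):
        lines.append("".join(f"{x:12.7f}" for x in flat[start : start + _PER_LINE]))
    return lines


def write_rst7(state: RestartState, path: str | Path) -> None:
    """Write the ASCII restart dialect; byte-identical for identical states."""
    lines = [state.title]
    if state.time_ps is not None:
        lines.append(f"{state.n_atoms:5d}{state.time_ps:15.7e}")
    else:
        lines.append(f"{state.n_atoms:5d}")
    lines.extend(_format_block(state.coordinates))
    if state.velocities is not None:
        lines.extend(_format_block(state.velocities))
    if state.box is not None:
        lines.append("".join(f"{x:12.7f}" for x in state.box))
    Path(path).write_text("\n".join(lines) + "\n")


def convert_velocity_units(velocities: np.ndarray, direction: str) -> np.ndarray:
    """Convert velocities across the restart boundary.

    ``"amber_to_internal"`` multiplies by 20.455 (restart units → Å/ps);
    ``"internal_to_amber"`` divides.  Round trip is the identity.
    """
    velocities = np.asarray(velocities, dtype=float)
    if direction == "amber_to_internal":
        return velocities * AMBER_TIME_UNIT
    if direction == "internal_to_amber":
        return velocities / AMBER_TIME_UNIT
    raise InvalidArgumentError(
        "direction must be 'amber_to_internal' or 'internal_to_amber'"
    )


def write_pulse_log(
    trajectory: TrajectoryResult,
    csv_path: str | Path,
    manifest_path: str | Path | None = None,
) -> None:
    """One CSV row per pulse plus a JSON manifest of the run configuration.

    ``manifest_path`` defaults to the CSV path with a ``.json`` suffix.
    """
    csv_path = Path(csv_path)
    frame = pd.DataFrame(
        [
            {
                "index": p.index,
                "time_ps": p.time_ps,
                "separation": p.separation,
                "pre_pulse_velocity": p.pre_pulse_velocity,
                "delta_v": p.delta_v,
                "applied_force": p.applied_force,
            }
            for p in trajectory.pulses
        ],
        columns=_PULSE_COLUMNS,
    )
    frame.to_csv(csv_path, index=False)
    if manifest_path is None:
        manifest_path = csv_path.with_suffix(".json")
    from . import __version__

    manifest = {
        "schema_version": PULSE_LOG_SCHEMA,
        "package_version": __version__,
        "params": dataclasses.asdict(trajectory.params),
        "anchors": {
            "group1": list(trajectory.anchors.group1),
            "group2": list(trajectory.anchors.group2),
        },
        "pulling_mass_da": trajectory.pulling_mass(),
        "n_pulses_completed": len(trajectory.pulses),
        "error": trajectory.error,
    }
    Path(manifest_path).write_text(json.dumps(manifest, indent=2) + "\n")


def read_pulse_log(
    csv_path: str | Path, manifest_path: str | Path | None = None
) -> tuple[pd.DataFrame, dict | None]:
    """Read a pulse log and (if present) its manifest, checking the schema.

    Returns the DataFrame and the manifest dict (None when no manifest file
    exists).  A manifest whose schema major version differs raises
    :class:`SchemaVersionError`.
    """
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    missing = [c for c in _PULSE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaVersionError(f"pulse log is missing columns {missing}")
    if manifest_path is None:
        manifest_path = csv_path.with_suffix(".json")
    manifest = None
    if Path(manifest_path).exists():
        manifest = json.loads(Path(manifest_path).read_text())
        version = str(manifest.get("schema_version", "0"))
        if version.split(".")[0] != PULSE_LOG_SCHEMA.split(".")[0]:
            raise SchemaVersionError(
                f"pulse-log schema {version} is incompatible with {PULSE_LOG_SCHEMA}"
            )
    return frame, manifest
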