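"""G-code reading/writing and encoder-log parsing.

The motion controller consumes a RepRap-style G0/G1 subset (mm mode, modal
coordinates).  Two writers are provided because the controller could be fed
either Cartesian or joint-space programs:

* **Cartesian dialect** — ``G1 X.. Y.. Z.. A.. B.. F..`` where A/B encode the
  tool-axis tilt about x and y (degrees) such that
  ``axis = Ry(B) @ Rx(A) @ [0, 0, 1]``.  Extrusion is pneumatic on/off, so it
  is signalled by an M-code pair (default M8/M9) rather than by E lengths.
* **Joint dialect** — one ``G1`` line per joint state with ``J1..J5`` words in
  radians.

All numeric output is fixed to 3 decimals (6 for joint words) so files are
bit-reproducible.  Feeds are written in mm/min (internal speeds are mm/s).

The top-layer filter automates the manual step of deleting planar-perimeter
layers from slicer output, keeping only non-planar (conformal) layers.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GcodeParseError, ValidationError
from .planning import ToolPose, Toolpath

logger = logging.getLogger(__name__)

DEFAULT_EXTRUDE_ON = "M8"
DEFAULT_EXTRUDE_OFF = "M9"

_WORD_RE = re.compile(r"([A-Za-z])\s*([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)")
_PAREN_COMMENT_RE = re.compile(r"\([^)]*\)")


@dataclass
class GcodeMove:
    """One interpreted motion line."""

    kind: str                       # "travel" | "extrude"
    target: np.ndarray              # (3,) mm
    feed: float | None = None       # mm/min
    extrusion_amount: float | None = None
    line_number: int = 0            # 0-based source line

    def __post_init__(self):
        self.target = np.asarray(self.target, float)
        if self.kind not in ("travel", "extrude"):
            raise ValidationError("kind must be 'travel' or 'extrude'")
        if not np.all(np.isfinite(self.target)):
            raise ValidationError("move target must be finite")
        if (self.kind == "extrude" and self.extrusion_amount is not None
                and self.extrusion_amount <= 0):
            raise ValidationError("extrude moves must have extrusion_amount > 0")


@dataclass
class EncoderLog:
    """Joint angles recorded per executed G-code line."""

    records: list   # of (gcode_line_number, JointState)

    def __post_init__(self):
        lines = [ln for ln, _ in self.records]
        if any(b < a for a, b in zip(lines, lines[1:])):
            raise ValidationError("encoder log line numbers must be non-decreasing")

    def angles(self) -> np.ndarray:
        return np.array([js.angles for _, js in self.records])


# --------------------------------------------------------------------------- #
# Parsing
# --------------------------------------------------------------------------- #

def _strip_comments(line: str) -> str:
    line = line.split(";", 1)[0]
    return _PAREN_COMMENT_RE.sub(" ", line)


def parse_gcode(text: str,
                extrude_on: str = DEFAULT_EXTRUDE_ON,
                extrude_off: str = DEFAULT_EXTRUDE_OFF) -> list:
    """Parse a G0/G1 subset with modal coordinates.

    Coordinates absent from a line inherit the previous position; E is treated
    as absolute with ``G92 E0`` resets recognised; a move extrudes when its E
    word increases E or while the pneumatic-extrusion M-code state is on.
    Unknown commands are skipped with a logged warning.
    """
    pos = np.zeros(3)
    e_abs = 0.0
    feed = None
    pneumatic_on = False
    moves: list[GcodeMove] = []
    for ln, raw in enumerate(text.splitlines()):
        line = _strip_comments(raw).strip()
        if not line:
            continue
        words = []
        cursor = 0
        for m in _WORD_RE.finditer(line):
            between = line[cursor:m.start()].strip()
            if between:
                raise GcodeParseError(f"malformed word {between!r}", ln)
            words.append((m.group(1).upper(), m.group(2)))
            cursor = m.end()
        if line[cursor:].strip():
            raise GcodeParseError(f"malformed word {line[cursor:].strip()!r}", ln)
        if not words:
            continue
        letter, number = words[0]
        try:
            code = f"{letter}{int(float(number))}"
        except ValueError as exc:
            raise GcodeParseError(f"malformed command number {number!r}", ln) from exc

        if code == extrude_on:
            pneumatic_on = True
            continue
        if code == extrude_off:
            pneumatic_on = False
            continue
        if code == "G92":
            for w, v in words[1:]:
                if w == "E":
                    e_abs = _num(v, ln)
            continue
        if code in ("G21", "G90"):   # mm mode / absolute mode: our defaults
            continue
        if code not in ("G0", "G1"):
            logger.warning("skipping unsupported command %r (line %d)", code, ln)
            continue

        new_pos = pos.copy()
        de = 0.0
        for w, v in words[1:]:
            val = _num(v, ln)
            if w == "X":
                new_pos[0] = val
            elif w == "Y":
                new_pos[1] = val
            elif w == "Z":
                new_pos[2] = val
            elif w == "E":
                de = val - e_abs
                e_abs = val
            elif w == "F":
                feed = val
            # A/B (tool tilt) and other axis words do not affect position
        extruding = de > 0.0 or (pneumatic_on and code == "G1")
        moves.append(GcodeMove(
            kind="extrude" if extruding else "travel",
            target=new_pos,
            feed=feed,
            extrusion_amount=de if de > 0.0 else None,
            line_number=ln,
        ))
        pos = new_pos
    return moves


def _num(token: str, line: int) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise GcodeParseError(f"malformed numeric word {token!r}", line) from exc


def parse_pattern(text: str) -> list:
    """Read a single-layer 2D pattern from G-code: returns a list of (n, 2)
    polylines, one per contiguous run of extrude moves (for the projection
    planner)."""
    moves = parse_gcode(text)
    polylines: list[np.ndarray] = []
    current: list[np.ndarray] = []
    prev_target = np.zeros(3)
    for mv in moves:
        if mv.kind == "extrude":
            if not current:
                current = [prev_target[:2].copy()]
            current.append(mv.target[:2].copy())
        else:
            if current:
                polylines.append(np.asarray(current))
                current = []
        prev_target = mv.target
    if current:
        polylines.append(np.asarray(current))
    if not polylines:
        raise ValidationError("pattern G-code contains no extrude moves")
    return polylines


# --------------------------------------------------------------------------- #
# Layer segmentation / top-layer extraction
# --------------------------------------------------------------------------- #

def split_layers(moves: Sequence[GcodeMove], z_tolerance: float = 1e-3) -> list:
    """Segment moves into layers at travel-move z jumps."""
    layers: list[list[GcodeMove]] = []
    current: list[GcodeMove] = []
    z = None
    for mv in moves:
        if (mv.kind == "travel" and z is not None
                and abs(mv.target[2] - z) > z_tolerance and current):
            layers.append(current)
            current = []
        current.append(mv)
        z = mv.target[2]
    if current:
        layers.append(current)
    return layers


def extract_top_layers(moves: Sequence[GcodeMove],
                       z_tolerance: float = 1e-3) -> list:
    """Keep only moves belonging to non-planar layers.

    A layer is planar when the z-range of its extrude moves is at most
    ``z_tolerance`` (1e-3 mm default, far below a 0.6 mm layer step).  This
    reproduces, automatically, the manual edit of deleting planar-perimeter
    paths from slicer output so only the conformal top layers remain.
    """
    kept: list[GcodeMove] = []
    found = False
    for layer in split_layers(moves, z_tolerance):
        zs = [mv.target[2] for mv in layer if mv.kind == "extrude"]
        if not zs:
            continue
        if max(zs) - min(zs) > z_tolerance:
            kept.extend(layer)
            found = True
    if not found:
        raise ValidationError("no non-planar layer found")
    return kept


# --------------------------------------------------------------------------- #
# Writing
# --------------------------------------------------------------------------- #

def _tilt_from_axis(axis: np.ndarray) -> tuple:
    """(A, B) in degrees with axis = Ry(B) @ Rx(A) @ z."""
    a = -math.asin(max(-1.0, min(1.0, float(axis[1]))))
    b = math.atan2(float(axis[0]), float(axis[2]))
    return math.degrees(a), math.degrees(b)


def axis_from_tilt(a_deg: float, b_deg: float) -> np.ndarray:
    a, b = math.radians(a_deg), math.radians(b_deg)
    return np.array([math.sin(b) * math.cos(a),
                     -math.sin(a),
                     math.cos(b) * math.cos(a)])


def _fmt(v: float) -> str:
    """Fixed 3-decimal formatting without negative zero."""
    s = f"{v:.3f}"
    return "0.000" if s == "-0.000" else s


def write_gcode(path: Toolpath,
                extrude_on: str = DEFAULT_EXTRUDE_ON,
                extrude_off: str = DEFAULT_EXTRUDE_OFF) -> str:
    """Serialise a toolpath in the Cartesian XYZ+AB dialect.

    Tool-axis tilt goes into A/B words, feed into F (mm/min); pneumatic
    extrusion is switched by the M-code pair around extruding runs.
    """
    out = [f"; insituplan toolpath, frame={path.frame_label}", "G21", "G90"]
    extruding = False
    for i, layer in enumerate(path.layers):
        out.append(f"; layer {i + 1}")
        for pose in layer:
            if not np.all(np.isfinite(pose.position)):
                raise ValidationError("non-finite pose position")
            if pose.extruding and not extruding:
                out.append(extrude_on)
                extruding = True
            elif not pose.extruding and extruding:
                out.append(extrude_off)
                extruding = False
            a, b = _tilt_from_axis(pose.tool_axis)
            x, y, z = pose.position
            out.append(f"G1 X{_fmt(x)} Y{_fmt(y)} Z{_fmt(z)} "
                       f"A{_fmt(a)} B{_fmt(b)} F{_fmt(pose.speed * 60.0)}")
    if extruding:
        out.append(extrude_off)
    out.append("; end")
    return "\n".join(out) + "\n"


def write_joint_gcode(joints: Sequence) -> str:
    """Serialise a joint trajectory: one G1 line per state, J1..J5 words in
    radians (6 decimals)."""
    out = ["; insituplan joint trajectory (J words in radians)", "G21", "G90"]
    for js in joints:
        words = " ".join(f"J{k + 1}={a:.6f}" for k, a in enumerate(js.angles))
        out.append(f"G1 {words}")
    out.append("; end")
    return "\n".join(out) + "\n"


def toolpath_from_moves(moves: Sequence[GcodeMove], frame_label: str = "planning",
                        default_speed: float = 3.0) -> Toolpath:
    """Lift parsed Cartesian moves back into a single-layer toolpath
    (vertical tool axis; feed converted back to mm/s)."""
    layer = []
    for mv in moves:
        speed = mv.feed / 60.0 if mv.feed else default_speed
        layer.append(ToolPose(mv.target, np.array([0.0, 0.0, 1.0]),
                              extruding=mv.kind == "extrude", speed=speed))
    return Toolpath([layer], frame_label=frame_label)


# --------------------------------------------------------------------------- #
# Encoder logs
# --------------------------------------------------------------------------- #

def parse_encoder_log(text: str) -> EncoderLog:
    """Parse ``line_number a1 a2 a3 a4 a5`` rows (whitespace or commas;
    blank lines and ``#``/``;`` comments skipped)."""
    from .kinematics import JointState

    records = []
    for ln, raw in enumerate(text.splitlines()):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith(";"):
            continue
        fields = re.split(r"[,\s]+", line)
        if len(fields) != 6:
            raise GcodeParseError(
                f"expected 6 fields (line number + 5 angles), got {len(fields)}", ln)
        try:
            gline = int(fields[0])
            angles = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise GcodeParseError(f"malformed numeric field in {line!r}", ln) from exc
        records.append((gline, JointState(np.array(angles))))
    return EncoderLog(records)


def write_encoder_log(log: EncoderLog) -> str:
    lines = ["# gcode_line j1 j2 j3 j4 j5 (radians)"]
    for gline, js in log.records:
        lines.append(f"{gline} " + " ".join(f"{a:.9f}" for a in js.angles))
    return "\n".join(lines) + "\n"
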