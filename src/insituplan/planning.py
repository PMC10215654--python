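"""Toolpath generation on curved substrates.

Two planning strategies are provided, mirroring how an extrusion print head is
driven over an anatomical surface:

* **projection** — a single-layer 2D pattern is dropped vertically onto the
  substrate mesh and the tool axis follows the local surface normal
  (perpendicular deposition, for steep regions);
* **conformal (2.5D) slicing** — the curved base layer (the exposed dura
  surface of a constant-thickness defect) is filled with perimeter + rectilinear
  infill and repeated upward at fixed vertical offsets until the missing
  thickness is rebuilt, the tool held vertical.

The 45-degree rule of :func:`assign_orientation` switches between the vertical
and surface-normal tool axis pose by pose, depending on the local slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from shapely.geometry import LineString, MultiLineString, Polygon
from shapely import affinity

from .errors import ValidationError
from .mesh import Footprint2D, TriMesh, surface_probe_batch

try:  # Python 3.11+
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    import tomli as tomllib


# --------------------------------------------------------------------------- #
# Settings
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SliceSettings:
    """Print/slicing parameters.

    Defaults are the cranial-defect study conditions: 0.6 mm layers, 50%
    rectilinear infill at 45 deg alternating by 90 deg per layer, a single
    perimeter, a 1.6 mm extrusion width over an 18G (0.8 mm) needle, 3 mm/s.
    """

    layer_thickness: float = 0.6          # mm
    infill_density: float = 0.5           # fraction of area covered
    infill_angle_deg: float = 45.0
    n_layers: int = 10
    n_perimeters: int = 1
    extrusion_width: float = 1.6          # mm
    needle_diameter: float = 0.8          # mm
    slope_threshold_deg: float = 45.0
    print_speed: float = 3.0              # mm/s
    alternate_angle_deg: float = 90.0     # added to infill angle per layer
    sample_step: float = 1.0              # mm, pose spacing along polylines

    def __post_init__(self):
        if self.layer_thickness <= 0:
            raise ValidationError("layer_thickness must be > 0")
        if not 0.0 < self.infill_density <= 1.0:
            raise ValidationError("infill_density must be in (0, 1]")
        if self.extrusion_width < self.needle_diameter:
            raise ValidationError("extrusion_width must be >= needle_diameter")
        if not 0.0 < self.slope_threshold_deg < 90.0:
            raise ValidationError("slope_threshold_deg must be in (0, 90)")
        if self.n_layers < 1:
            raise ValidationError("n_layers must be >= 1")
        if self.n_perimeters < 0:
            raise ValidationError("n_perimeters must be >= 0")
        if self.sample_step <= 0 or self.print_speed <= 0:
            raise ValidationError("sample_step and print_speed must be > 0")

    @classmethod
    def from_toml(cls, path) -> "SliceSettings":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data = data.get("slice", data)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


@dataclass(frozen=True)
class PrintJobConfig:
    """Deposition-job metadata carried alongside a plan, never computed upon.

    The study deposits 2 sacrificial support layers (0.5 bar) under 10 bone
    substitute layers (0.7 bar); ``material`` may hold free-form rheology
    metadata such as Herschel-Bulkley parameters.
    """

    sacrificial_layers: int = 2
    bone_layers: int = 10
    sacrificial_pressure: float = 0.5     # bar
    bone_pressure: float = 0.7            # bar
    material: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sacrificial_layers < 0 or self.bone_layers < 0:
            raise ValidationError("layer counts must be >= 0")
        if self.sacrificial_pressure <= 0 or self.bone_pressure <= 0:
            raise ValidationError("pressures must be > 0")


# --------------------------------------------------------------------------- #
# Toolpath containers
# --------------------------------------------------------------------------- #

@dataclass
class ToolPose:
    """One commanded pose: tip position, tool-axis direction (tip toward
    mount, z > 0), extrusion state and feed."""

    position: np.ndarray
    tool_axis: np.ndarray
    extruding: bool
    speed: float

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        self.tool_axis = np.asarray(self.tool_axis, float)
        n = float(np.linalg.norm(self.tool_axis))
        if abs(n - 1.0) > 1e-9:
            raise ValidationError("tool_axis must be unit length")
        if self.tool_axis[2] <= 0:
            raise ValidationError("tool_axis must point upward (z > 0)")
        if not np.all(np.isfinite(self.position)):
            raise ValidationError("pose position must be finite")


@dataclass
class Toolpath:
    """Ordered layers of tool poses, tagged with the frame they live in."""

    layers: list
    frame_label: str = "planning"

    def __post_init__(self):
        if len(self.layers) < 1:
            raise ValidationError("toolpath must contain at least one layer")

    def poses(self) -> Iterator[ToolPose]:
        for layer in self.layers:
            yield from layer

    @property
    def n_poses(self) -> int:
        return sum(len(layer) for layer in self.layers)

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.poses()])

    def axes(self) -> np.ndarray:
        return np.array([p.tool_axis for p in self.poses()])

    def extruding_mask(self) -> np.ndarray:
        return np.array([p.extruding for p in self.poses()], bool)


# --------------------------------------------------------------------------- #
# 2D pattern generation
# --------------------------------------------------------------------------- #

def infill_spacing(settings: SliceSettings) -> float:
    """Centre-to-centre line spacing realising the requested infill density.

    For rectilinear infill the covered area fraction is extrusion width over
    line spacing, so ``spacing = extrusion_width / infill_density``
    (1.6 mm wide lines every 3.2 mm give 50%).
    """
    return settings.extrusion_width / settings.infill_density


def generate_infill_2d(footprint: Footprint2D, spacing: float,
                       angle_deg: float) -> list:
    """Rectilinear infill: parallel lines at ``angle_deg``, clipped to the
    footprint and serpentine-connected.

    Lines are placed at offsets ``ymin + spacing/2 + k*spacing`` in the frame
    rotated so the fill direction is the x axis; consecutive clipped segments
    are joined into one serpentine polyline when the join gap is at most
    ``2*spacing`` (otherwise a new polyline — i.e. a travel move — starts).

    Returns a list of (n, 2) arrays.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be > 0")
    if footprint.area <= 0:
        raise ValidationError("footprint must have positive area")
    poly_r = affinity.rotate(footprint.polygon, -angle_deg, origin=(0, 0))
    xmin, ymin, xmax, ymax = poly_r.bounds
    n_lines = int(math.floor((ymax - ymin - spacing / 2.0) / spacing)) + 1
    segments_per_line: list[list[np.ndarray]] = []
    for k in range(max(n_lines, 0)):
        y = ymin + spacing / 2.0 + k * spacing
        scan = LineString([(xmin - 1.0, y), (xmax + 1.0, y)])
        inter = poly_r.intersection(scan)
        segs: list[np.ndarray] = []
        geoms = (inter.geoms if isinstance(inter, MultiLineString)
                 else [inter] if isinstance(inter, LineString) else [])
        for g in geoms:
            if g.length > 1e-12:
                segs.append(np.asarray(g.coords, float))
        segs.sort(key=lambda s: min(s[0, 0], s[-1, 0]))
        segments_per_line.append(segs)

    polylines: list[np.ndarray] = []
    current: list[np.ndarray] | None = None
    forward = True
    for segs in segments_per_line:
        ordered = segs if forward else [s[::-1] for s in reversed(segs)]
        for seg in ordered:
            if current is not None:
                gap = float(np.linalg.norm(current[-1][-1] - seg[0]))
                if gap <= 2.0 * spacing:
                    current.append(seg)
                    continue
                polylines.append(np.vstack(current))
            current = [seg]
        forward = not forward
    if current is not None:
        polylines.append(np.vstack(current))
    if not polylines:
        raise ValidationError("footprint produced no infill lines at this spacing")
    # rotate back to the original frame
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    rot = np.array([[c, -s], [s, c]])
    return [pl @ rot.T for pl in polylines]


def perimeter_polylines(footprint: Footprint2D, extrusion_width: float,
                        n_perimeters: int) -> list:
    """Closed perimeter loops offset inward so the bead edge meets the outline.

    Perimeter ``k`` (0-based) is the footprint boundary offset inward by
    ``(k + 0.5) * extrusion_width``.
    """
    loops = []
    for k in range(n_perimeters):
        inner = footprint.polygon.buffer(-(k + 0.5) * extrusion_width,
                                         join_style="round")
        if inner.is_empty:
            break
        rings = ([inner.exterior] if isinstance(inner, Polygon)
                 else [g.exterior for g in inner.geoms])
        for ring in rings:
            loops.append(np.asarray(ring.coords, float))
    return loops


def layer_count(defect_thickness: float, layer_thickness: float) -> int:
    """Number of layers needed to rebuild a constant-thickness defect
    (ceil of thickness over layer height; 6 mm at 0.6 mm -> 10)."""
    if defect_thickness <= 0 or layer_thickness <= 0:
        raise ValidationError("thicknesses must be > 0")
    return int(math.ceil(defect_thickness / layer_thickness - 1e-12))


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Insert points so consecutive samples are at most ``step`` apart.

    Original vertices are preserved (corners are never cut)."""
    points = np.asarray(points, float)
    if len(points) < 2:
        return points
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        d = float(np.linalg.norm(b - a))
        if d > step:
            n = int(math.ceil(d / step))
            for t in np.linspace(0.0, 1.0, n + 1)[1:]:
                out.append(a + t * (b - a))
        else:
            out.append(b)
    return np.asarray(out)


# --------------------------------------------------------------------------- #
# Toolpath generation
# --------------------------------------------------------------------------- #

VERTICAL = np.array([0.0, 0.0, 1.0])


def _polylines_to_layer(mesh: TriMesh, polylines2d: Sequence[np.ndarray],
                        z_offset: float, speed: float, step: float,
                        tool_axis_from_normal: bool = False) -> list:
    """Probe 2D polylines onto the surface, lift by ``z_offset``; first pose of
    each polyline is a travel (non-extruding) move."""
    chunks = [resample_polyline(pl, step) for pl in polylines2d]
    flat = np.vstack(chunks)
    pos, normals, _ = surface_probe_batch(mesh, flat,
                                          interpolate_normals=tool_axis_from_normal)
    pos = pos.copy()
    pos[:, 2] += z_offset
    layer = []
    i = 0
    for chunk in chunks:
        for j in range(len(chunk)):
            axis = normals[i] if tool_axis_from_normal else VERTICAL
            layer.append(ToolPose(pos[i], axis, extruding=j > 0, speed=speed))
            i += 1
    return layer


def conformal_slice(patch: TriMesh, footprint: Footprint2D,
                    settings: SliceSettings,
                    infill_inset: float = 0.01) -> Toolpath:
    """2.5D non-planar slicing of a constant-thickness defect.

    The curved base surface (probed from ``patch``) is decorated with
    ``n_perimeters`` inward-offset perimeter loops plus rectilinear infill, and
    this base layer is repeated at vertical offsets ``i * layer_thickness``
    for layers ``i = 1..n_layers``.  The infill direction of layer ``i`` is
    ``infill_angle_deg + (i-1) * alternate_angle_deg``.  The tool axis is left
    vertical; apply :func:`assign_orientation` to enable the slope rule.

    ``infill_inset`` (mm) pulls the infill clipping region fractionally inside
    the footprint so line endpoints never sit exactly on the triangulated
    boundary of the probed patch (negligible against the bead width).
    """
    spacing = infill_spacing(settings)
    perims = perimeter_polylines(footprint, settings.extrusion_width,
                                 settings.n_perimeters)
    clip_region = footprint
    if infill_inset > 0:
        clip_region = Footprint2D(
            np.asarray(footprint.polygon.buffer(-infill_inset).exterior.coords))
    layers = []
    for i in range(1, settings.n_layers + 1):
        angle = settings.infill_angle_deg + (i - 1) * settings.alternate_angle_deg
        infill = generate_infill_2d(clip_region, spacing, angle)
        layer = _polylines_to_layer(patch, list(perims) + infill,
                                    z_offset=i * settings.layer_thickness,
                                    speed=settings.print_speed,
                                    step=settings.sample_step)
        layers.append(layer)
    return Toolpath(layers, frame_label="planning")


def project_pattern(pattern: Sequence[np.ndarray], mesh: TriMesh,
                    speed: float = 3.0) -> Toolpath:
    """Project a single-layer 2D pattern vertically onto the substrate.

    Each pattern point keeps its (x, y) and acquires the probed surface z; the
    tool axis is the local surface normal (deposition perpendicular to the
    printing surface).  Raises if any point misses the mesh.
    """
    pattern = [np.asarray(pl, float) for pl in pattern]
    if not pattern or all(len(pl) == 0 for pl in pattern):
        raise ValidationError("pattern is empty")
    layer = []
    for pl in pattern:
        if len(pl) == 0:
            continue
        pos, normals, _ = surface_probe_batch(mesh, pl, interpolate_normals=False)
        for j in range(len(pl)):
            layer.append(ToolPose(pos[j], normals[j], extruding=j > 0, speed=speed))
    return Toolpath([layer], frame_label="planning")


def with_vertical_axes(path: Toolpath) -> Toolpath:
    """Copy of a toolpath with every tool axis reset to vertical.

    Used after registration when executing in vertical-extruder mode: the
    registered frame may be slightly tilted (noisy fiducials), but the
    controller still holds the extruder vertical in the robot frame.
    """
    layers = [[ToolPose(p.position.copy(), VERTICAL.copy(),
                        extruding=p.extruding, speed=p.speed)
               for p in layer] for layer in path.layers]
    return Toolpath(layers, frame_label=path.frame_label)


def assign_orientation(path: Toolpath, mesh: TriMesh,
                       slope_threshold_deg: float = 45.0) -> Toolpath:
    """Apply the slope rule to every pose of a toolpath.

    Where the local surface slope exceeds the threshold the extruder is held
    perpendicular to the surface (tool axis = outward normal); elsewhere it is
    kept vertical.
    """
    new_layers = []
    for layer in path.layers:
        if not layer:
            new_layers.append([])
            continue
        xy = np.array([p.position[:2] for p in layer])
        _, normals, slopes = surface_probe_batch(mesh, xy)
        new_layer = []
        for p, n, s in zip(layer, normals, slopes):
            axis = n if s > slope_threshold_deg else VERTICAL
            new_layer.append(ToolPose(p.position.copy(), axis,
                                      extruding=p.extruding, speed=p.speed))
        new_layers.append(new_layer)
    return Toolpath(new_layers, frame_label=path.frame_label)
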