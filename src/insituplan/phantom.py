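"""Synthetic skull phantom and robot-execution simulation.

The physical study phantom (a segmented, FDM-printed half skull with a
silicone dura insert) is emulated here by an analytic spherical cap: a sphere
of skull-like radius, cut at a cap height, carrying a circular defect whose
floor (the exposed dura surface) is the outer surface recessed vertically by
the constant skull thickness.  Because every surface height and normal then
has a closed form, all downstream geometry (probing, conformal slicing,
registration, kinematics) can be asserted analytically.

Fiducial markers sit on the outer sphere on a geodesic ring around the defect,
mirroring semi-spherical markers implanted around the fracture.

The mesh is triangulated with curvature-adaptive resolution: radial ring
spacing and azimuth count are chosen from a vertical chordal-error tolerance
so that linear interpolation over the triangles reproduces the analytic sphere
height everywhere inside the defect — including the steep (~70 deg) rim —
to well under 1e-3 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .gcode import EncoderLog
from .kinematics import JointState, KinematicChain
from .mesh import Footprint2D, TriMesh, extract_patch
from .registration import FiducialSet, RigidTransform


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic skull phantom (mm, degrees).

    Defaults mirror the cranial case study magnitudes: ~6 mm constant skull
    thickness at the defect, a defect footprint of roughly 40 cm^2 (a 70 mm
    circle), and six artificial markers ringed around the defect on the outer
    surface.  ``chord_tol`` bounds the vertical deviation between the
    triangulated defect surface and the analytic sphere.
    """

    skull_radius: float = 80.0
    cap_height: float = 55.0
    defect_center_angle: float = 30.0    # degrees from the apex
    defect_diameter: float = 70.0        # planar footprint diameter
    n_artificial_fiducials: int = 6
    fiducial_ring_radius: float = 45.0   # geodesic distance from defect centre
    defect_thickness: float = 6.0
    noise_seed: int = 0
    chord_tol: float = 3e-4              # mm, defect-patch mesh fidelity
    outer_resolution: float = 2.0        # mm, ring spacing outside the defect

    def __post_init__(self):
        if self.skull_radius <= 0 or self.defect_thickness <= 0:
            raise ValidationError("radii and thickness must be positive")
        if not 0 < self.cap_height < self.skull_radius:
            raise ValidationError("cap_height must be in (0, skull_radius)")
        if self.n_artificial_fiducials < 3:
            raise ValidationError("need at least 3 fiducials")
        r_cap = math.sqrt(self.skull_radius ** 2
                          - (self.skull_radius - self.cap_height) ** 2)
        cx = self.skull_radius * math.sin(math.radians(self.defect_center_angle))
        if cx + self.defect_diameter / 2.0 > r_cap:
            raise ValidationError(
                f"defect (out to rho={cx + self.defect_diameter / 2:.1f} mm) "
                f"does not fit within the cap (rho<={r_cap:.1f} mm)")
        if self.defect_thickness >= self.skull_radius - self.cap_height:
            pass  # recess may dip below the cap cut; harmless, surface-only model

    @property
    def defect_center_xy(self) -> np.ndarray:
        cx = self.skull_radius * math.sin(math.radians(self.defect_center_angle))
        return np.array([cx, 0.0])


@dataclass(frozen=True)
class NoiseModel:
    """i.i.d. Gaussian measurement noise, seeded; stands in for touch-probe
    error and for the limited mechanical rigidity of the arm."""

    joint_noise_sd: float = 0.0      # radians, per joint
    fiducial_noise_sd: float = 0.0   # mm, isotropic
    seed: int = 0

    def __post_init__(self):
        if self.joint_noise_sd < 0 or self.fiducial_noise_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")


# --------------------------------------------------------------------------- #
# Mesh construction
# --------------------------------------------------------------------------- #

def _sphere_z(spec: PhantomSpec, x, y):
    return np.sqrt(spec.skull_radius ** 2 - x ** 2 - y ** 2)


def dura_height(spec: PhantomSpec, x, y):
    """Analytic height of the recessed defect floor at (x, y)."""
    return _sphere_z(spec, x, y) - spec.defect_thickness


def _radial_spacing(spec: PhantomSpec, r: float, cx: float) -> float:
    """Ring spacing bounding vertical chord error by chord_tol at the worst
    azimuth of local radius ``r`` (radial curvature of z is 1/(R cos^3 th))."""
    R = spec.skull_radius
    rho = min(cx + r, 0.999 * R)
    cos_th = math.sqrt(max(1.0 - (rho / R) ** 2, 1e-9))
    return math.sqrt(8.0 * spec.chord_tol * R * cos_th ** 3)


def make_phantom(spec: PhantomSpec = PhantomSpec()):
    """Build the phantom: returns ``(mesh, footprint, fiducials)``.

    The mesh is a spherical cap (z up, sphere centred at the origin) whose
    outer surface is recessed by ``defect_thickness`` inside the circular
    defect footprint, joined by a vertical wall at the footprint rim.
    Construction is fully deterministic for a given spec.
    """
    R = spec.skull_radius
    cx = float(spec.defect_center_xy[0])
    r_d = spec.defect_diameter / 2.0
    rho_cap = math.sqrt(R ** 2 - (R - spec.cap_height) ** 2)

    # adaptive ring radii for the defect patch
    radii = [0.0]
    while radii[-1] < r_d:
        radii.append(min(radii[-1] + _radial_spacing(spec, radii[-1], cx), r_d))
    radii = np.asarray(radii)
    # azimuth count from the tangential curvature at the steepest rim point
    n_phi = int(math.ceil(2.0 * math.pi * r_d
                          / _azimuthal_chord(spec, cx + r_d)))
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    cphi, sphi = np.cos(phi), np.sin(phi)

    def ring_xy(r):
        return cx + r * cphi, r * sphi

    verts = [np.array([cx, 0.0, float(dura_height(spec, cx, 0.0))])]
    faces = []
    # defect floor: fan + quad rings, recessed by the skull thickness
    for r in radii[1:]:
        x, y = ring_xy(r)
        z = _sphere_z(spec, x, y) - spec.defect_thickness
        verts.append(np.column_stack([x, y, z]))
    offsets = np.cumsum([1] + [n_phi] * (len(radii) - 1))
    # fan around the centre vertex
    first = offsets[0]
    for k in range(n_phi):
        faces.append([0, first + k, first + (k + 1) % n_phi])
    # quad strips between successive rings
    for ring in range(len(radii) - 2):
        a = offsets[ring]
        b = offsets[ring + 1]
        for k in range(n_phi):
            k2 = (k + 1) % n_phi
            faces.append([a + k, b + k, b + k2])
            faces.append([a + k, b + k2, a + k2])
    rim_recessed = offsets[-2]  # start index of the last (rim) defect ring

    # rim wall: recessed rim ring up to the outer-surface rim ring
    x, y = ring_xy(r_d)
    z_outer = _sphere_z(spec, x, y)
    rim_outer = offsets[-1]
    verts.append(np.column_stack([x, y, z_outer]))
    for k in range(n_phi):
        k2 = (k + 1) % n_phi
        faces.append([rim_recessed + k, rim_outer + k, rim_outer + k2])
        faces.append([rim_recessed + k, rim_outer + k2, rim_recessed + k2])

    # outer cap surface: rings from the defect rim out to the cap edge,
    # scaled per azimuth so the outermost ring follows the cap boundary circle
    edge = -cx * cphi + np.sqrt(np.maximum(
        (cx * cphi) ** 2 - cx ** 2 + rho_cap ** 2, 0.0))
    n_out = max(int(math.ceil(float(np.max(edge - r_d)) / spec.outer_resolution)), 1)
    prev = rim_outer
    base = rim_outer + n_phi
    for j in range(1, n_out + 1):
        rr = r_d + (edge - r_d) * (j / n_out)
        x = cx + rr * cphi
        y = rr * sphi
        verts.append(np.column_stack([x, y, _sphere_z(spec, x, y)]))
        cur = base + (j - 1) * n_phi
        for k in range(n_phi):
            k2 = (k + 1) % n_phi
            faces.append([prev + k, cur + k, cur + k2])
            faces.append([prev + k, cur + k2, prev + k2])
        prev = cur

    mesh = TriMesh(np.vstack([v.reshape(-1, 3) for v in verts]),
                   np.asarray(faces, np.int64), name="phantom")

    footprint = Footprint2D.circle(spec.defect_center_xy, r_d, n=360)
    fiducials = _fiducial_ring(spec)
    return mesh, footprint, fiducials


def _azimuthal_chord(spec: PhantomSpec, rho: float) -> float:
    """Max xy chord length keeping vertical error under chord_tol for the
    tangential curvature 1/(R cos th) at global radius rho."""
    R = spec.skull_radius
    cos_th = math.sqrt(max(1.0 - (min(rho, 0.999 * R) / R) ** 2, 1e-9))
    return math.sqrt(8.0 * spec.chord_tol * R * cos_th)


# markers must sit on intact bone: minimum arc clearance beyond the defect rim
_FIDUCIAL_CLEARANCE = 2.0  # mm


def _fiducial_ring(spec: PhantomSpec) -> FiducialSet:
    """Markers on the outer sphere, ringed around the defect.

    Each marker sits at geodesic distance ``fiducial_ring_radius`` (arc mm)
    from the defect centre direction, pushed further out where the planar
    defect footprint reaches beyond that (plus a 2 mm clearance), so every
    marker lies on the intact outer surface.
    """
    R = spec.skull_radius
    r_d = spec.defect_diameter / 2.0
    c = spec.defect_center_xy
    theta_c = math.radians(spec.defect_center_angle)
    d = np.array([math.sin(theta_c), 0.0, math.cos(theta_c)])
    e1 = np.array([math.cos(theta_c), 0.0, -math.sin(theta_c)])
    e2 = np.array([0.0, 1.0, 0.0])
    rho_cap = math.sqrt(R ** 2 - (R - spec.cap_height) ** 2)
    beta_cap = math.asin(min(rho_cap / R, 1.0))
    n = spec.n_artificial_fiducials
    pts = []
    for i in range(n):
        phi = 2.0 * math.pi * i / n
        e = math.cos(phi) * e1 + math.sin(phi) * e2

        def planar_dist(beta: float) -> float:
            u = math.cos(beta) * d + math.sin(beta) * e
            return math.hypot(R * u[0] - c[0], R * u[1] - c[1])

        # geodesic angle where this azimuth's great circle exits the footprint
        lo, hi = 0.0, math.pi / 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if planar_dist(mid) < r_d:
                lo = mid
            else:
                hi = mid
        beta = max(spec.fiducial_ring_radius / R,
                   hi + _FIDUCIAL_CLEARANCE / R)
        u = math.cos(beta) * d + math.sin(beta) * e
        polar = math.acos(max(-1.0, min(1.0, u[2])))
        if polar > beta_cap:
            raise ValidationError(
                f"fiducial {i + 1} falls outside the cap (polar angle "
                f"{math.degrees(polar):.1f} deg); enlarge the cap or shrink "
                "the fiducial ring")
        pts.append(R * u)
    labels = [f"F{i + 1}" for i in range(n)]
    return FiducialSet(labels, np.asarray(pts), frame_label="planning")


def curved_defect_area(mesh: TriMesh, footprint: Footprint2D) -> float:
    """Curved (on-surface) area of the defect patch, mm^2; the planar area is
    ``footprint.area``."""
    patch = extract_patch(mesh, footprint)
    tri = patch.triangles
    return float(0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum())


# --------------------------------------------------------------------------- #
# Simulated acquisition / execution
# --------------------------------------------------------------------------- #

def robot_frame_fiducials(fiducials: FiducialSet, ground_truth: RigidTransform,
                          noise: NoiseModel = NoiseModel()) -> FiducialSet:
    """Touch-probe acquisition stand-in: map planning-frame fiducials through
    the ground-truth transform and add isotropic Gaussian noise."""
    rng = np.random.default_rng(noise.seed)
    pts = ground_truth.apply(fiducials.points)
    if noise.fiducial_noise_sd > 0:
        pts = pts + rng.normal(0.0, noise.fiducial_noise_sd, pts.shape)
    return FiducialSet(list(fiducials.labels), pts, frame_label="robot")


def simulate_execution(chain: KinematicChain, joints: list,
                       noise: NoiseModel = NoiseModel()) -> EncoderLog:
    """Encoder acquisition stand-in: commanded joint angles plus seeded
    Gaussian noise, one record per G-code line."""
    rng = np.random.default_rng(noise.seed)
    records = []
    for i, js in enumerate(joints):
        angles = js.angles.copy()
        if noise.joint_noise_sd > 0:
            angles = angles + rng.normal(0.0, noise.joint_noise_sd, 5)
        records.append((i, JointState(angles)))
    return EncoderLog(records)
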