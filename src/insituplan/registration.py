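"""Point-based rigid registration between planning and robot frames.

Fiducial markers (implanted artificial landmarks and anatomical features) are
identified both in the pre-operative planning frame and, via the robot touch
probe, in the robot frame.  The best-fitting rigid transform in the
least-squares sense is solved in closed form (Kabsch/Umeyama SVD with proper-
rotation correction) and the per-fiducial residuals — the fiducial registration
error, FRE — are reported as mean, RMS and max, since a single "least mean
square error" figure is ambiguous between the first two.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
import numpy as np

from .errors import (CorrespondenceError, DegenerateConfigurationError,
                     ValidationError)
from .planning import ToolPose, Toolpath


@dataclass
class FiducialSet:
    """Labelled fiducial coordinates in one frame."""

    labels: list
    points: np.ndarray
    frame_label: str = "planning"

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError("points must be an (n, 3) array")
        if len(self.labels) != len(self.points):
            raise ValidationError("labels and points must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("fiducial labels must be unique")
        if len(self.points) < 3:
            raise ValidationError("at least 3 fiducials are required")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("fiducial coordinates must be finite")
        # non-collinearity: centred coordinates must have rank >= 2
        s = np.linalg.svd(self.points - self.points.mean(axis=0),
                          compute_uv=False)
        if s[1] <= 1e-6:
            raise DegenerateConfigurationError(
                "fiducials are collinear; cannot determine a rigid transform")

    @classmethod
    def from_csv(cls, path, frame_label: str | None = None) -> "FiducialSet":
        """Read ``label,x,y,z[,frame]`` rows (header optional)."""
        labels, pts, frames = [], [], []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().startswith("#"):
                    continue
                if row[0].strip().lower() == "label":
                    continue
                labels.append(row[0].strip())
                pts.append([float(v) for v in row[1:4]])
                if len(row) > 4:
                    frames.append(row[4].strip())
        frame = frame_label or (frames[0] if frames else "unknown")
        return cls(labels, np.asarray(pts), frame)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "x", "y", "z", "frame"])
            for lab, p in zip(self.labels, self.points):
                w.writerow([lab, f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}",
                            self.frame_label])


@dataclass
class RigidTransform:
    """Proper rigid transform p -> R p + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValidationError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValidationError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors, float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class RegistrationResult:
    transform: RigidTransform
    residuals: np.ndarray      # per-fiducial distances after alignment (mm)
    fre_mean: float
    fre_rms: float
    fre_max: float
    labels: list | None = None

    def __post_init__(self):
        self.residuals = np.asarray(self.residuals, float)
        if np.any(self.residuals < 0):
            raise ValidationError("residuals must be non-negative")

    def to_json(self, path=None) -> str:
        payload = {
            "rotation": self.transform.rotation.tolist(),
            "translation": self.transform.translation.tolist(),
            "residuals_mm": self.residuals.tolist(),
            "labels": self.labels,
            "fre_mean_mm": self.fre_mean,
            "fre_rms_mm": self.fre_rms,
            "fre_max_mm": self.fre_max,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def estimate_rigid(moving: FiducialSet, fixed: FiducialSet) -> RegistrationResult:
    """Least-squares rigid transform taking ``moving`` onto ``fixed``.

    Correspondence is by label.  The solution is the classical closed form:
    centre both sets, take the SVD of the cross-covariance matrix, and if the
    resulting rotation would be a reflection, negate the last singular
    direction so the transform is a proper rotation even for coplanar sets.
    """
    if set(moving.labels) != set(fixed.labels):
        raise CorrespondenceError(
            f"fiducial labels differ: {sorted(moving.labels)} vs "
            f"{sorted(fixed.labels)}")
    order = [fixed.labels.index(lab) for lab in moving.labels]
    m = moving.points
    f = fixed.points[order]

    mc = m.mean(axis=0)
    fc = f.mean(axis=0)
    h = (m - mc).T @ (f - fc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = fc - rotation @ mc
    transform = RigidTransform(rotation, translation)

    residuals = np.linalg.norm(transform.apply(m) - f, axis=1)
    return RegistrationResult(
        transform=transform,
        residuals=residuals,
        fre_mean=float(residuals.mean()),
        fre_rms=float(np.sqrt(np.mean(residuals ** 2))),
        fre_max=float(residuals.max()),
        labels=list(moving.labels),
    )


def transform_toolpath(path: Toolpath, transform: RigidTransform,
                       frame_label: str = "robot") -> Toolpath:
    """Map a planned toolpath into another frame.

    Positions map as R p + t, tool axes as R a (re-normalised); extrusion
    flags, speeds and the layer structure are preserved.
    """
    new_layers = []
    for layer in path.layers:
        new_layer = []
        for p in layer:
            axis = transform.apply_vectors(p.tool_axis)
            axis = axis / np.linalg.norm(axis)
            new_layer.append(ToolPose(transform.apply(p.position), axis,
                                      extruding=p.extruding, speed=p.speed))
        new_layers.append(new_layer)
    return Toolpath(new_layers, frame_label=frame_label)
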