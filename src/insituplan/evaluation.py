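"""Planned-versus-executed trajectory accuracy.

The executed trajectory is reconstructed from the encoder log by forward
kinematics (one Cartesian tip point per recorded G-code line) and compared
with the planned toolpath by Euclidean distance, either line-by-line (the
controller records one encoder sample per G-code line, so index pairing is the
natural choice) or by nearest neighbour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import PairingError, ValidationError
from .gcode import EncoderLog
from .kinematics import KinematicChain, forward_kinematics_batch
from .planning import Toolpath


@dataclass
class TrajectoryErrorReport:
    per_point_distance: np.ndarray   # mm
    mean: float
    std: float                       # population standard deviation
    max: float
    n_points: int
    pairing: str

    def __post_init__(self):
        self.per_point_distance = np.asarray(self.per_point_distance, float)
        if self.n_points != len(self.per_point_distance):
            raise ValidationError("n_points inconsistent with distance list")

    def to_json(self, path=None) -> str:
        payload = {
            "mean_mm": self.mean,
            "std_mm": self.std,
            "max_mm": self.max,
            "n_points": self.n_points,
            "pairing": self.pairing,
            "per_point_distance_mm": self.per_point_distance.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def executed_trajectory(chain: KinematicChain, log: EncoderLog) -> np.ndarray:
    """Cartesian tip positions of every encoder record, order preserved."""
    if not log.records:
        return np.zeros((0, 3))
    tips, _ = forward_kinematics_batch(chain, log.angles())
    return tips


def trajectory_error(planned: Toolpath, executed: np.ndarray,
                     pairing: str = "by_line",
                     include_travel: bool = False) -> TrajectoryErrorReport:
    """Distance statistics between planned poses and executed tip points.

    ``by_line`` pairs pose i with executed point i (requires equal counts —
    one encoder sample per planned G-code line) before optionally dropping
    travel moves; ``nearest`` measures each planned point against its closest
    executed point.  Mean/std/max are computed over the retained distances
    (std is the population standard deviation).
    """
    executed = np.asarray(executed, float)
    positions = planned.positions()
    mask = planned.extruding_mask() if not include_travel \
        else np.ones(len(positions), bool)

    if pairing == "by_line":
        if len(executed) != len(positions):
            raise PairingError(
                f"by_line pairing needs equal counts: {len(positions)} planned "
                f"poses vs {len(executed)} executed points")
        d = np.linalg.norm(positions[mask] - executed[mask], axis=1)
    elif pairing == "nearest":
        if len(executed) == 0 or not mask.any():
            raise PairingError("nearest pairing needs non-empty point sets")
        d, _ = cKDTree(executed).query(positions[mask])
        d = np.atleast_1d(d)
    else:
        raise ValidationError("pairing must be 'by_line' or 'nearest'")

    if len(d) == 0:
        raise PairingError("no points left to compare after filtering")
    return TrajectoryErrorReport(
        per_point_distance=d,
        mean=float(d.mean()),
        std=float(d.std()),
        max=float(d.max()),
        n_points=int(len(d)),
        pairing=pairing,
    )
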