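"""5-DoF serial-arm kinematics.

The deposition robot is modelled as five revolute joints in series (base yaw,
three pitch joints, wrist roll — MOVEO-like proportions), each joint being a
rotation about a fixed axis in its parent frame followed by a fixed link
transform.  A 5-DoF arm commands tip position plus tool-axis direction but not
spin about that axis, so the inverse kinematics solves exactly that
5-dimensional task with damped least squares.

The true arm's link dimensions are not public; the chain shipped in
``data/imagobot.toml`` is an editable fixture with plausible proportions
(~730 mm reach), not a measured model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
import numpy as np

from .errors import UnreachablePoseError, ValidationError
from .planning import Toolpath

try:
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    import tomli as tomllib


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def _rotation_about(axis_skew: np.ndarray, axis_skew2: np.ndarray,
                    angle: float) -> np.ndarray:
    """Rodrigues rotation from precomputed [axis]_x and [axis]_x^2."""
    return np.eye(3) + np.sin(angle) * axis_skew + (1.0 - np.cos(angle)) * axis_skew2


@dataclass
class Joint:
    """One revolute joint: rotate about ``axis`` (unit, in the parent frame),
    then apply the fixed link transform (rotation then translation offset)."""

    axis: np.ndarray
    link_translation: np.ndarray
    link_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    limits: tuple = (-np.pi, np.pi)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, float)
        self.link_translation = np.asarray(self.link_translation, float)
        self.link_rotation = np.asarray(self.link_rotation, float)
        n = np.linalg.norm(self.axis)
        if abs(n - 1.0) > 1e-9:
            raise ValidationError("joint axis must be unit length")
        if self.limits[0] >= self.limits[1]:
            raise ValidationError("joint limits must satisfy min < max")
        # cached for fast Rodrigues evaluation
        self._k = _skew(self.axis)
        self._k2 = self._k @ self._k


@dataclass
class KinematicChain:
    joints: list
    tool_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.tool_offset = np.asarray(self.tool_offset, float)
        if len(self.joints) != 5:
            raise ValidationError("chain must have exactly 5 joints")

    @property
    def limits(self) -> np.ndarray:
        return np.array([j.limits for j in self.joints])

    def random_state(self, rng: np.random.Generator) -> "JointState":
        lim = self.limits
        return JointState(rng.uniform(lim[:, 0], lim[:, 1]))

    @classmethod
    def from_toml(cls, path=None) -> "KinematicChain":
        """Load a chain description; default: the packaged arm fixture."""
        if path is None:
            source = resources.files("insituplan.data").joinpath("imagobot.toml")
            data = tomllib.loads(source.read_text())
        else:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        joints = []
        for j in data["joint"]:
            rot = np.eye(3)
            if "rotation" in j:
                rot = np.asarray(j["rotation"], float)
            lim = j.get("limits_deg", [-180.0, 180.0])
            joints.append(Joint(
                axis=np.asarray(j["axis"], float),
                link_translation=np.asarray(j["translation"], float),
                link_rotation=rot,
                limits=(np.radians(lim[0]), np.radians(lim[1])),
            ))
        return cls(joints, tool_offset=np.asarray(data["tool_offset"], float))


def default_chain() -> KinematicChain:
    """The packaged MOVEO-like 5-DoF arm fixture."""
    return KinematicChain.from_toml(None)


@dataclass
class JointState:
    angles: np.ndarray

    def __post_init__(self):
        self.angles = np.asarray(self.angles, float)
        if self.angles.shape != (5,):
            raise ValidationError("a joint state holds exactly 5 angles")
        if not np.all(np.isfinite(self.angles)):
            raise ValidationError("joint angles must be finite")

    @classmethod
    def home(cls) -> "JointState":
        return cls(np.zeros(5))


@dataclass
class ToolFrame:
    tip_position: np.ndarray
    tool_axis: np.ndarray

    def __post_init__(self):
        self.tip_position = np.asarray(self.tip_position, float)
        self.tool_axis = np.asarray(self.tool_axis, float)
        if abs(np.linalg.norm(self.tool_axis) - 1.0) > 1e-9:
            raise ValidationError("tool_axis must be unit length")


# --------------------------------------------------------------------------- #
# Forward kinematics
# --------------------------------------------------------------------------- #

def forward_kinematics(chain: KinematicChain, q: JointState) -> ToolFrame:
    """Compose the five joint transforms base-to-tip.

    The tool axis is the +z direction of the final frame (pointing from the
    tip toward the tool mount)."""
    r = np.eye(3)
    t = np.zeros(3)
    for joint, angle in zip(chain.joints, q.angles):
        r = r @ _rotation_about(joint._k, joint._k2, angle)
        t = t + r @ joint.link_translation
        r = r @ joint.link_rotation
    tip = t + r @ chain.tool_offset
    return ToolFrame(tip, r[:, 2].copy())


def forward_kinematics_batch(chain: KinematicChain, q: np.ndarray):
    """Vectorised FK over an (n, 5) array of joint angles.

    Returns ``(tips (n,3), axes (n,3))``."""
    q = np.asarray(q, float)
    n = len(q)
    r = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    t = np.zeros((n, 3))
    for j, joint in enumerate(chain.joints):
        ang = q[:, j][:, None, None]
        rj = (np.eye(3) + np.sin(ang) * joint._k
              + (1.0 - np.cos(ang)) * joint._k2)
        r = r @ rj
        t = t + np.einsum("nij,j->ni", r, joint.link_translation)
        r = r @ joint.link_rotation
    tips = t + np.einsum("nij,j->ni", r, chain.tool_offset)
    return tips, r[:, :, 2].copy()


# --------------------------------------------------------------------------- #
# Inverse kinematics
# --------------------------------------------------------------------------- #

# length scale (mm) weighting the tool-axis error against position error
_AXIS_SCALE = 100.0
_FD_STEP = 1e-6


def _task_error(chain: KinematicChain, angles: np.ndarray,
                target: ToolFrame) -> np.ndarray:
    frame = forward_kinematics(chain, JointState(angles))
    return np.concatenate([
        target.tip_position - frame.tip_position,
        _AXIS_SCALE * (target.tool_axis - frame.tool_axis),
    ])


def _split_error(e: np.ndarray):
    return float(np.linalg.norm(e[:3])), float(np.linalg.norm(e[3:]) / _AXIS_SCALE)


def _analytic_candidates(chain: KinematicChain, target: ToolFrame,
                         q5: float = 0.0) -> list:
    """Closed-form seed configurations for yaw + planar-3R + roll chains.

    For chains matching the default layout (z, y, y, y, z axes; links along
    local z; identity link rotations) the task decouples: the base yaw aligns
    the arm plane with the target azimuth, the pitch sum realises the in-plane
    tool tilt, and the two long links solve a planar 2R problem for the wrist
    point.  Returns up to four candidates (yaw flip x elbow branch); empty if
    the chain does not match the layout.
    """
    axes = np.array([j.axis for j in chain.joints])
    expected = np.array([[0, 0, 1], [0, 1, 0], [0, 1, 0], [0, 1, 0], [0, 0, 1]],
                        float)
    links = np.array([j.link_translation for j in chain.joints])
    if (not np.allclose(axes, expected) or np.any(links[:, :2] != 0.0)
            or chain.tool_offset[0] != 0.0 or chain.tool_offset[1] != 0.0
            or any(not np.allclose(j.link_rotation, np.eye(3))
                   for j in chain.joints)):
        return []
    l_base, a1, a2, w = links[0, 2], links[1, 2], links[2, 2], links[3, 2]
    toff = chain.tool_offset[2]
    tip, axis = target.tip_position, target.tool_axis
    sigma_mag = float(np.arccos(np.clip(axis[2], -1.0, 1.0)))
    horiz = float(np.hypot(axis[0], axis[1]))
    if horiz < 1e-9:
        azim = np.arctan2(tip[1], tip[0]) if np.hypot(tip[0], tip[1]) > 1e-9 else 0.0
        sigma0 = 0.0 if axis[2] > 0 else np.pi
        branches = [(azim, sigma0), (azim + np.pi, -sigma0)]
    else:
        azim = np.arctan2(axis[1], axis[0])
        branches = [(azim, sigma_mag), (azim + np.pi, -sigma_mag)]
    wrist = tip - (w + toff) * axis
    out = []
    for q1, sigma in branches:
        r3 = np.cos(q1) * wrist[0] + np.sin(q1) * wrist[1]
        z3 = wrist[2] - l_base
        d2 = r3 * r3 + z3 * z3
        c3 = (d2 - a1 * a1 - a2 * a2) / (2.0 * a1 * a2)
        if abs(c3) > 1.0 + 1e-9:
            continue
        c3 = np.clip(c3, -1.0, 1.0)
        for q3 in (np.arccos(c3), -np.arccos(c3)):
            q2 = np.arctan2(r3, z3) - np.arctan2(a2 * np.sin(q3),
                                                 a1 + a2 * np.cos(q3))
            q4 = sigma - q2 - q3
            cand = np.array([q1, q2, q3, q4, q5])
            cand = np.arctan2(np.sin(cand), np.cos(cand))  # wrap to [-pi, pi]
            out.append(cand)
    return out


def inverse_kinematics(chain: KinematicChain, target: ToolFrame,
                       seed: JointState | None = None,
                       max_iter: int = 200, damping: float = 0.01,
                       restarts: int = 5, restart_seed: int = 0,
                       pos_tol: float = 1e-4, axis_tol: float = 1e-5
                       ) -> JointState:
    """Damped-least-squares IK on the 5D task (3 position + tool-axis direction).

    Warm-started from ``seed`` (home if omitted); joint limits are enforced by
    clamping, with up to ``restarts`` deterministic random restarts on
    non-convergence.  The axis-direction error counts twice as two independent
    components, matching the arm's 5 degrees of freedom: spin about the tool
    axis is never constrained.

    Raises :class:`UnreachablePoseError` reporting the best residual reached.
    """
    lim = chain.limits
    rng = np.random.default_rng(restart_seed)
    start = (seed.angles if seed is not None else np.zeros(5)).copy()
    attempts = [start]
    attempts += _analytic_candidates(chain, target, q5=start[4])
    attempts += [rng.uniform(lim[:, 0], lim[:, 1]) for _ in range(restarts)]
    best_pos, best_ax = np.inf, np.inf
    for angles in attempts:
        angles = np.clip(angles, lim[:, 0], lim[:, 1])
        e = _task_error(chain, angles, target)
        lam = damping
        for _ in range(max_iter):
            pos_err, ax_err = _split_error(e)
            if pos_err <= pos_tol and ax_err <= axis_tol:
                return JointState(angles)
            jac = np.empty((6, 5))
            for j in range(5):
                bumped = angles.copy()
                bumped[j] += _FD_STEP
                jac[:, j] = (e - _task_error(chain, bumped, target)) / _FD_STEP
            # adaptive damping: retry the step with a stiffer lambda on failure
            improved = False
            while lam < 1e8:
                jtj = jac.T @ jac + (lam ** 2) * np.eye(5)
                dq = np.linalg.solve(jtj, jac.T @ e)
                new_angles = np.clip(angles + dq, lim[:, 0], lim[:, 1])
                new_e = _task_error(chain, new_angles, target)
                if np.linalg.norm(new_e) < np.linalg.norm(e):
                    angles, e = new_angles, new_e
                    lam = max(lam * 0.5, damping)
                    improved = True
                    break
                lam *= 8.0
            if not improved:
                break
        pos_err, ax_err = _split_error(e)
        if pos_err <= pos_tol and ax_err <= axis_tol:
            return JointState(angles)
        if pos_err < best_pos:
            best_pos, best_ax = pos_err, ax_err
    raise UnreachablePoseError(
        f"IK did not converge (best position error {best_pos:.4g} mm, "
        f"axis error {best_ax:.4g} rad)",
        best_position_error=best_pos, best_axis_error=best_ax)


def joints_for_toolpath(chain: KinematicChain, path: Toolpath,
                        seed: JointState | None = None) -> list:
    """Sequential IK over every pose of a toolpath, each solve warm-started
    from the previous solution so the joint trajectory is continuous."""
    solutions = []
    current = seed
    for idx, pose in enumerate(path.poses()):
        target = ToolFrame(pose.position, pose.tool_axis)
        try:
            current = inverse_kinematics(chain, target, seed=current)
        except UnreachablePoseError as exc:
            raise UnreachablePoseError(
                f"pose {idx} unreachable: {exc}",
                best_position_error=exc.best_position_error,
                best_axis_error=exc.best_axis_error,
                pose_index=idx) from exc
        solutions.append(current)
    return solutions
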