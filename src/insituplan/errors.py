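"""Exception hierarchy for the planning toolkit."""


class InSituPlanError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(InSituPlanError):
    """An object or argument violates a documented invariant."""


class MeshIOError(InSituPlanError):
    """A mesh file could not be read or written."""


class OutOfFootprintError(InSituPlanError):
    """A vertical probe line missed the substrate mesh.

    Carries the offending (x, y) coordinates in ``points``.
    """

    def __init__(self, points, message=None):
        self.points = [tuple(float(v) for v in p) for p in points]
        if message is None:
            shown = ", ".join(f"({p[0]:.3f}, {p[1]:.3f})" for p in self.points[:5])
            more = "" if len(self.points) <= 5 else f" and {len(self.points) - 5} more"
            message = f"no surface below probe point(s) {shown}{more}"
        super().__init__(message)


class CorrespondenceError(InSituPlanError):
    """Fiducial labels in the two frames do not match one-to-one."""


class DegenerateConfigurationError(InSituPlanError):
    """Fiducials are collinear (or otherwise rank-deficient) and cannot
    determine a unique rigid transform."""


class UnreachablePoseError(InSituPlanError):
    """Inverse kinematics failed to converge to the requested pose."""

    def __init__(self, message, best_position_error=None, best_axis_error=None,
                 pose_index=None):
        self.best_position_error = best_position_error
        self.best_axis_error = best_axis_error
        self.pose_index = pose_index
        super().__init__(message)


class GcodeParseError(InSituPlanError):
    """Malformed G-code or encoder-log input; carries the 0-based line number."""

    def __init__(self, message, line_number):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class PairingError(InSituPlanError):
    """Planned and executed trajectories cannot be paired as requested."""
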