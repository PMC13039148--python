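"""Helical (screw) and Cn point-group symmetry operators.

A pilus filament is generated from one pilin subunit by repeated application
of a screw operator: rotate by the twist about +z and translate by the rise
along +z.  The inverse problem — recovering twist and rise from a built or
deposited filament — is solved by least-squares rigid superposition of
consecutive subunits (Kabsch) followed by screw-axis decomposition of the
fitted rigid map.

Sign convention: positive twist is a right-handed rotation about +z; angles
are reported in (−180°, 180°].
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.spatial.transform import Rotation

from .model import (
    AssemblyModel,
    HelicalParams,
    ScrewTransform,
    SubunitModel,
)

#: Deterministic chain identifier sequence for generated assemblies.
CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def chain_id_for(index: int) -> str:
    return CHAIN_IDS[index % len(CHAIN_IDS)]


class InconsistentHelixError(ValueError):
    """Consecutive-pair screw fits disagree beyond tolerance."""

    def __init__(self, message: str, pairs: list[int]):
        super().__init__(message)
        self.pairs = pairs


@dataclass(frozen=True)
class CnParams:
    """n-fold rotational point-group symmetry about the +z axis."""

    order: int

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"Cn order must be >= 1, got {self.order}")

    @property
    def step(self) -> Fraction:
        """Exact per-subunit rotation step in degrees, as a rational."""
        return Fraction(360, self.order)

    @property
    def step_deg(self) -> float:
        return float(self.step)

    @property
    def step_deg_display(self) -> str:
        """The step rounded to 1 decimal for reporting (C13 → ``27.7``)."""
        return f"{self.step_deg:.1f}"


def rotation_about_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def apply_helical_symmetry(
    subunit: SubunitModel, params: HelicalParams, n: int
) -> AssemblyModel:
    """Generate an ``n``-subunit filament from one subunit.

    Subunit ``k`` receives coordinates ``Rz(k·twist)·x + (0, 0, k·rise)`` and
    the chain identifier ``A, B, …`` (wrapping).  Atom order within each
    subunit is preserved.
    """
    if n < 1:
        raise ValueError(f"subunit count must be >= 1, got {n}")
    subunits = []
    for k in range(n):
        R = rotation_about_z(k * params.twist_deg)
        t = np.array([0.0, 0.0, k * params.rise_A])
        subunits.append(subunit.transformed(R, t).with_chain(chain_id_for(k)))
    return AssemblyModel(subunits=subunits, kind="filament")


def build_cn_ring(subunit: SubunitModel, order: int) -> AssemblyModel:
    """Cn-expand a pre-placed subunit by rotation about +z.

    The subunit must already sit at its ring position; the operator only
    rotates.  The result is invariant under rotation by 360/order degrees.
    """
    params = CnParams(order)
    subunits = []
    for k in range(order):
        R = rotation_about_z(k * params.step_deg)
        subunits.append(
            subunit.transformed(R, np.zeros(3)).with_chain(chain_id_for(k))
        )
    return AssemblyModel(subunits=subunits, kind="ring")


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition ``target ≈ R·moving + t``.

    Proper rotation enforced by determinant correction of the SVD; if the
    unconstrained optimum is a reflection, a warning is issued and the best
    proper rotation returned.  Returns (R, t, rmsd).
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    if moving.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    cm = moving.mean(axis=0)
    ct = target.mean(axis=0)
    A = moving - cm
    B = target - ct
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.abs(A).max())) < 2:
        raise ValueError("degenerate (collinear) geometry; screw fit undefined")
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d < 0:
        warnings.warn(
            "optimal superposition is a reflection; forcing proper rotation",
            stacklevel=2,
        )
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    diff = (moving @ R.T + t) - target
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return R, t, rmsd


def decompose_screw(R: np.ndarray, t: np.ndarray, rmsd: float = 0.0) -> ScrewTransform:
    """Decompose the rigid map ``x → R x + t`` into a screw transform.

    The axis direction is normalised to the +z hemisphere so the reported
    angle carries the handedness sign (right-handed about +z positive); near
    the identity rotation the axis defaults to the translation direction.
    """
    rot = Rotation.from_matrix(R)
    rotvec = rot.as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-10:
        # pure translation: rotation axis undefined, use translation direction
        norm_t = float(np.linalg.norm(t))
        axis = t / norm_t if norm_t > 1e-12 else np.array([0.0, 0.0, 1.0])
        return ScrewTransform(
            rotation_angle_deg=0.0,
            axis_direction=axis,
            axis_point=np.zeros(3),
            translation_along_axis_A=norm_t,
            residual_rmsd_A=rmsd,
        )
    axis = rotvec / angle
    angle_deg = math.degrees(angle)
    if axis[2] < 0:
        axis = -axis
        angle_deg = -angle_deg
    d = float(axis @ t)
    # axis point: least-squares solution of (I - R) p = t_perp, min-norm (⊥ axis)
    t_perp = t - d * axis
    p, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    return ScrewTransform(
        rotation_angle_deg=angle_deg,
        axis_direction=axis,
        axis_point=p,
        translation_along_axis_A=d,
        residual_rmsd_A=rmsd,
    )


def fit_screw_transform(
    subunit_a: SubunitModel, subunit_b: SubunitModel
) -> ScrewTransform:
    """Fit the screw operator carrying subunit ``a`` onto subunit ``b``.

    Atoms correspond by order; superposition is a Kabsch fit with proper
    rotation enforced, decomposed into rotation about a fitted axis plus
    translation along it.  The residual RMSD of the fit is reported.
    """
    a = subunit_a.coords()
    b = subunit_b.coords()
    if a.shape != b.shape:
        raise ValueError(
            f"subunit atom counts differ ({a.shape[0]} vs {b.shape[0]})"
        )
    R, t, rmsd = kabsch(a, b)
    return decompose_screw(R, t, rmsd)


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.radians(angles_deg)
    return math.degrees(math.atan2(np.mean(np.sin(a)), np.mean(np.cos(a))))


@dataclass(frozen=True)
class HelixFit:
    """Result of recovering twist/rise from a built filament.

    ``degenerate`` flags filaments whose consecutive subunits are related by
    (near-)identity, where twist and rise are both ~0 and no valid
    :class:`HelicalParams` exists.
    """

    twist_deg: float
    rise_A: float
    max_residual_rmsd_A: float
    max_pair_deviation_deg: float
    max_pair_deviation_A: float
    degenerate: bool

    @property
    def params(self) -> HelicalParams:
        if self.degenerate:
            raise ValueError("degenerate helix fit has no helical parameters")
        return HelicalParams(twist_deg=self.twist_deg, rise_A=self.rise_A)


def fit_helical_parameters(
    filament: AssemblyModel,
    angle_tol_deg: float = 0.5,
    rise_tol_A: float = 0.5,
) -> HelixFit:
    """Recover twist/rise from a filament by consecutive-pair screw fits.

    The twist is the circular mean of the per-pair rotation angles and the
    rise the mean axial translation; maximum per-pair deviations and the
    worst superposition residual are reported alongside.  Pairs deviating
    from the mean by more than the tolerances raise
    :class:`InconsistentHelixError` naming them.
    """
    if filament.n_subunits < 2:
        raise ValueError("need at least 2 subunits to fit helical parameters")
    transforms = [
        fit_screw_transform(filament.subunits[k], filament.subunits[k + 1])
        for k in range(filament.n_subunits - 1)
    ]
    angles = np.array([tr.rotation_angle_deg for tr in transforms])
    rises = np.array([tr.translation_along_axis_A for tr in transforms])
    mean_angle = _circular_mean_deg(angles)
    mean_rise = float(np.mean(rises))
    ang_dev = np.abs((angles - mean_angle + 180.0) % 360.0 - 180.0)
    rise_dev = np.abs(rises - mean_rise)
    bad = [
        k
        for k in range(len(transforms))
        if ang_dev[k] > angle_tol_deg or rise_dev[k] > rise_tol_A
    ]
    if bad:
        raise InconsistentHelixError(
            "inconsistent consecutive-pair screw fits "
            f"(max deviation {ang_dev.max():.3f}°/{rise_dev.max():.3f} Å) "
            f"at pairs {bad}",
            pairs=bad,
        )
    max_rmsd = float(max(tr.residual_rmsd_A for tr in transforms))
    degenerate = abs(mean_angle) < 1e-6 and abs(mean_rise) < 1e-6
    return HelixFit(
        twist_deg=mean_angle,
        rise_A=mean_rise,
        max_residual_rmsd_A=max_rmsd,
        max_pair_deviation_deg=float(ang_dev.max()),
        max_pair_deviation_A=float(rise_dev.max()),
        degenerate=degenerate,
    )


def align_to_axis(model, axis_point_a, axis_point_b):
    """Rigidly map a model so the line a→b becomes +z through the origin.

    ``axis_point_a`` maps to the origin and the direction a→b to +z; all
    pairwise distances are preserved.  Works on subunits and assemblies.
    """
    pa = np.asarray(axis_point_a, dtype=float)
    pb = np.asarray(axis_point_b, dtype=float)
    u = pb - pa
    norm_u = np.linalg.norm(u)
    if norm_u < 1e-12:
        raise ValueError("axis points are coincident")
    u = u / norm_u
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(u, z)
    s = np.linalg.norm(v)
    c = float(u @ z)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else Rotation.from_rotvec([math.pi, 0, 0]).as_matrix()
    else:
        R = Rotation.from_rotvec(v / s * math.atan2(s, c)).as_matrix()
    t = -R @ pa
    if isinstance(model, AssemblyModel):
        return AssemblyModel(
            subunits=[sub.transformed(R, t) for sub in model.subunits],
            kind=model.kind,
        )
    return model.transformed(R, t)
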