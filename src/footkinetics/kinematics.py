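"""Segment coordinate frames, joint centers and Cardan joint angles.

The foot is modeled as four rigid segments — shank, hindfoot, forefoot and
hallux — articulated at the ankle, midtarsal (MT) and metatarsophalangeal
(MP) joints.  Every segment frame is right-handed with local y along the
segment long axis (anterior for foot segments), z up and x completing the
triad; x is the medial-lateral flexion axis.  Joint angles are Cardan angles
of the distal segment relative to the proximal one, decomposed in the order
dorsiflexion/plantarflexion -> abduction/adduction -> inversion/eversion
(intrinsic x-z-y) and zeroed at the upright standing static reference
posture.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, ValidationError
from .io import MarkerSet

logger = logging.getLogger(__name__)

__all__ = [
    "PointSpec",
    "FrameRecipe",
    "SegmentFrame",
    "JointCenterTrack",
    "CardanAngles",
    "JointAngles",
    "DEFAULT_FRAME_RECIPES",
    "DEFAULT_JOINT_CENTER_PAIRS",
    "PROXIMAL_SEGMENT",
    "JOINTS",
    "resolve_point",
    "build_segment_frame",
    "build_segment_frames",
    "joint_center",
    "compose_cardan",
    "cardan_angles",
    "joint_angles",
    "foot_angle",
]

JOINTS = ("ankle", "MT", "MP")
SEGMENTS = ("shank", "hindfoot", "forefoot", "hallux")

#: proximal segment whose frame expresses each joint's moments/angles
PROXIMAL_SEGMENT = {"ankle": "shank", "MT": "hindfoot", "MP": "forefoot"}
DISTAL_SEGMENT = {"ankle": "hindfoot", "MT": "forefoot", "MP": "hallux"}

# A point is a marker label or a pair of labels (their midpoint).
PointSpec = str | tuple[str, str]

_EPS = 1e-10


def resolve_point(markers: MarkerSet, spec: PointSpec) -> np.ndarray:
    """(frames, 3) trajectory of a marker or marker-pair midpoint."""
    if isinstance(spec, str):
        return markers.get(spec)
    a, b = spec
    return 0.5 * (markers.get(a) + markers.get(b))


@dataclass(frozen=True)
class FrameRecipe:
    """How to build one segment frame from markers.

    ``long_axis`` is an ordered point pair (A, B); the axis points from A to
    B and becomes local y (``axis='y'``, foot segments) or local z
    (``axis='z'``, the near-vertical shank).

    ``ref`` orients the frame about the long axis.  For ``axis='y'`` it is a
    (medial, lateral) point pair spanning the segment's transverse plane:
    z = unit((lateral - medial) x y), sign-corrected to point up.  For
    ``axis='z'`` it is a (posterior, anterior) pair whose direction,
    orthogonalized against z, gives local y.  ``ref=None`` (hallux, which
    carries a single distal marker) takes the global vertical as z.
    """

    segment: str
    origin: PointSpec
    long_axis: tuple[PointSpec, PointSpec]
    ref: tuple[PointSpec, PointSpec] | None
    axis: Literal["y", "z"] = "y"


#: Default recipes for the shoe-mounted multisegment marker set
#: (configurable: placements and model variants differ between labs).
DEFAULT_FRAME_RECIPES: dict[str, FrameRecipe] = {
    "shank": FrameRecipe(
        "shank", ("SH1", "SH2"), (("SH1", "SH2"), ("SH3", "SH4")), ("SH2", "SH1"), axis="z"
    ),
    "hindfoot": FrameRecipe("hindfoot", "C1", ("C1", "H2"), ("MC", "LC")),
    "forefoot": FrameRecipe(
        "forefoot", ("B1", "B5"), (("B1", "B5"), ("H1", "H3")), ("B1", "B5")
    ),
    "hallux": FrameRecipe("hallux", ("H1", "H3"), (("H1", "H3"), "HX"), None),
}

#: Medial/lateral marker pairs whose midpoints track the joint centers.
DEFAULT_JOINT_CENTER_PAIRS: dict[str, tuple[str, str]] = {
    "ankle": ("MC", "LC"),
    "MT": ("NV", "CU"),
    "MP": ("H1", "H3"),
}


@dataclass
class SegmentFrame:
    """Per-frame pose of one segment: origin (T, 3) and local->global
    rotation matrices (T, 3, 3), orthonormal with determinant +1."""

    segment: str
    origin: np.ndarray
    rotation: np.ndarray

    @property
    def frames(self) -> int:
        return self.origin.shape[0]


@dataclass
class JointCenterTrack:
    """Joint-center trajectory: midpoint of a medial/lateral marker pair."""

    joint: str
    position: np.ndarray  # (T, 3), meters, global frame
    recipe: tuple[str, str]


class CardanAngles(NamedTuple):
    dfpf: float
    abad: float
    inev: float
    gimbal: bool = False


@dataclass
class JointAngles:
    """Cardan angle time series (degrees) for one joint, zeroed at the
    static reference; positive = dorsiflexion, adduction, inversion."""

    joint: str
    dfpf: np.ndarray
    abad: np.ndarray
    inev: np.ndarray
    gimbal: np.ndarray | None = None


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < _EPS):
        raise DegenerateGeometryError(f"{what}: direction undefined (zero-length vector)")
    return v / n


def _frame_axes(
    a: np.ndarray, b: np.ndarray, ref: np.ndarray | None, axis: str
) -> np.ndarray:
    """Rotation matrices (T, 3, 3) with columns (x, y, z); see FrameRecipe."""
    long = _unit(b - a, "long axis")
    if axis == "y":
        y = long
        if ref is None:
            up = np.broadcast_to(np.array([0.0, 0.0, 1.0]), y.shape)
            x = np.cross(y, up)
            if np.any(np.linalg.norm(x, axis=-1) < _EPS):
                raise DegenerateGeometryError("long axis is vertical; global-up reference degenerate")
            x = _unit(x, "x axis")
            z = np.cross(x, y)
        else:
            z = np.cross(ref, y)
            if np.any(np.linalg.norm(z, axis=-1) < _EPS):
                raise DegenerateGeometryError("reference pair collinear with the long axis")
            z = _unit(z, "z axis")
            z = z * np.where(z[..., 2:3] < 0, -1.0, 1.0)  # z points up
            x = np.cross(y, z)
    elif axis == "z":
        z = long
        if ref is None:
            raise ValidationError("axis='z' recipes need an anterior reference pair")
        y = ref - np.sum(ref * z, axis=-1, keepdims=True) * z
        if np.any(np.linalg.norm(y, axis=-1) < _EPS):
            raise DegenerateGeometryError("anterior reference collinear with the long axis")
        y = _unit(y, "y axis")
        x = np.cross(y, z)
    else:
        raise ValidationError(f"unknown recipe axis {axis!r}")
    return np.stack([x, y, z], axis=-1)


def build_segment_frames(markers: MarkerSet, recipe: FrameRecipe) -> SegmentFrame:
    """Build a segment frame at every frame of the trial."""
    a = resolve_point(markers, recipe.long_axis[0])
    b = resolve_point(markers, recipe.long_axis[1])
    ref = None
    if recipe.ref is not None:
        ref = resolve_point(markers, recipe.ref[1]) - resolve_point(markers, recipe.ref[0])
    rot = _frame_axes(a, b, ref, recipe.axis)
    origin = resolve_point(markers, recipe.origin)
    return SegmentFrame(recipe.segment, origin, rot)


def build_segment_frame(
    markers: MarkerSet, recipe: FrameRecipe, frame_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """One (origin, rotation) sample at ``frame_index``."""
    sf = build_segment_frames(markers, recipe)
    return sf.origin[frame_index], sf.rotation[frame_index]


def joint_center(
    markers: MarkerSet, joint: str, recipe: tuple[str, str] | None = None
) -> JointCenterTrack:
    """Joint-center trajectory as the midpoint of a medial/lateral pair."""
    if recipe is None:
        recipe = DEFAULT_JOINT_CENTER_PAIRS[joint]
    a, b = markers.get(recipe[0]), markers.get(recipe[1])
    if np.allclose(a, b, atol=1e-12):
        logger.warning(
            "joint %s: recipe markers %s coincide; center equals both", joint, recipe
        )
    return JointCenterTrack(joint, 0.5 * (a + b), (recipe[0], recipe[1]))


# ---------------------------------------------------------------------------
# Cardan angles
# ---------------------------------------------------------------------------

#: intrinsic rotation order: flexion (x), abduction (z), inversion (y)
CARDAN_SEQUENCE = "XZY"


def compose_cardan(
    dfpf: float, abad: float, inev: float, sequence: str = CARDAN_SEQUENCE
) -> np.ndarray:
    """Rotation matrix from Cardan angles in degrees (inverse of
    :func:`cardan_angles`)."""
    return Rotation.from_euler(sequence, [dfpf, abad, inev], degrees=True).as_matrix()


def cardan_angles(r_rel: np.ndarray, sequence: str = CARDAN_SEQUENCE) -> CardanAngles:
    """Decompose a relative rotation into Cardan angles (degrees).

    Near gimbal lock (second angle within ~1e-6 deg of +/-90) the third
    angle is conventionally set to 0 and the result flagged.
    """
    r_rel = np.asarray(r_rel, dtype=float)
    if r_rel.shape != (3, 3) or not np.allclose(r_rel @ r_rel.T, np.eye(3), atol=1e-8):
        raise ValidationError("relative rotation is not a 3x3 orthonormal matrix")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ang = Rotation.from_matrix(r_rel).as_euler(sequence, degrees=True)
    gimbal = any("Gimbal lock" in str(w.message) for w in caught)
    gimbal = gimbal or abs(abs(ang[1]) - 90.0) < 1e-6
    if gimbal:
        ang[2] = 0.0
    return CardanAngles(float(ang[0]), float(ang[1]), float(ang[2]), gimbal)


def joint_angles(
    proximal: SegmentFrame,
    distal: SegmentFrame,
    static_proximal: SegmentFrame | None = None,
    static_distal: SegmentFrame | None = None,
    joint: str = "ankle",
) -> JointAngles:
    """Cardan joint-angle series relative to the static reference posture.

    The relative rotation at each frame is ``R_prox^T R_dist``; when a static
    reference is given its relative rotation is factored out first, so the
    standing posture reads exactly (0, 0, 0).
    """
    r_rel = np.einsum("tij,tik->tjk", proximal.rotation, distal.rotation)
    if static_proximal is not None and static_distal is not None:
        r0 = static_proximal.rotation[0].T @ static_distal.rotation[0]
        r_rel = np.einsum("ij,tjk->tik", r0.T, r_rel)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        out = Rotation.from_matrix(r_rel).as_euler(CARDAN_SEQUENCE, degrees=True)
    gim = np.zeros(out.shape[0], dtype=bool)
    if any("Gimbal lock" in str(w.message) for w in caught):
        gim = np.abs(np.abs(out[:, 1]) - 90.0) < 1e-6
        out[gim, 2] = 0.0
    return JointAngles(joint, out[:, 0], out[:, 1], out[:, 2], gim)


def foot_angle(c1: np.ndarray, h2: np.ndarray) -> float | np.ndarray:
    """Signed foot progression angle (rad): the angle of the ground-plane
    projection of the heel-to-forefoot vector (C1 -> H2) versus the global
    anterior +Y axis, positive toward +X (toe-out for a right foot), in
    (-pi, pi].
    """
    c1 = np.asarray(c1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    d = h2[..., :2] - c1[..., :2]
    if np.any(np.linalg.norm(d, axis=-1) < 1e-12):
        raise DegenerateGeometryError(
            "C1 and H2 coincide in the ground plane; foot axis undefined"
        )
    ang = np.arctan2(d[..., 0], d[..., 1])
    ang = np.where(np.isclose(ang, -np.pi), np.pi, ang)  # range (-pi, pi]
    return float(ang) if ang.ndim == 0 else ang
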