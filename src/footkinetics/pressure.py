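"""From pressure matrices to forces, centers of pressure and segment loads.

A pressure grid measures only the normal component of the contact force.
Each frame's resultant is the pressure-area sum over sensels and its center
of pressure (CoP) the pressure-weighted centroid of sensel centers.  Cells
are assigned to foot segments by comparing their coordinate along the foot's
anteroposterior axis with the joint centers': cells behind the midtarsal
(MT) joint belong to the hindfoot, cells between MT and the
metatarsophalangeal (MP) joint to the forefoot, cells at or beyond MP to the
hallux (half-open intervals; a cell exactly on a joint line goes to the
distal segment).  The in-shoe insole grid lives in the foot frame and is
placed into the global frame by a single rigid transform found by matching
the insole and platform CoPs 0.1 s after initial contact, with the rotation
given by the foot progression angle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import NoStanceError, RegistrationError, ValidationError
from .io import GridGeometry, MarkerSet, PressureSequence
from .kinematics import JointCenterTrack, foot_angle

logger = logging.getLogger(__name__)

__all__ = [
    "FrameForce",
    "RigidTransform2D",
    "SegmentedForces",
    "frame_force_cop",
    "sequence_forces",
    "detect_stance",
    "stance_threshold",
    "register_cop",
    "register_insole",
    "global_cell_centers",
    "segment_cells",
    "segmented_forces",
]

KPA = 1000.0  # kPa -> Pa

SEGMENT_ORDER = ("hindfoot", "forefoot", "hallux")
#: distal cell sets per joint: the hallux loads the MP joint, hallux+forefoot
#: the MT joint, and everything loads the ankle.
DISTAL_SEGMENTS = {
    "ankle": ("hindfoot", "forefoot", "hallux"),
    "MT": ("forefoot", "hallux"),
    "MP": ("hallux",),
}


@dataclass
class FrameForce:
    """Resultant normal force and CoP of one pressure frame.

    ``cop`` is NaN (and ``defined`` False) when the frame carries no load.
    """

    f_normal: float
    cop: np.ndarray  # (2,) global ground-plane coordinates, m
    n_active: int

    @property
    def defined(self) -> bool:
        return self.f_normal > 0


@dataclass
class RigidTransform2D:
    """Planar rigid transform p -> R(theta) p + t (counter-clockwise)."""

    theta: float
    t: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float).reshape(2)

    @property
    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.t

    def inverse(self) -> "RigidTransform2D":
        rinv = self.rotation.T
        return RigidTransform2D(-self.theta, -(rinv @ self.t))


@dataclass
class SegmentedForces:
    """Per-frame resultant and CoP of all cells distal to one joint."""

    joint: str
    f_normal: np.ndarray  # (T,) N
    cop: np.ndarray  # (T, 2) m, NaN where force is 0
    device: str


# ---------------------------------------------------------------------------
# force / CoP
# ---------------------------------------------------------------------------


def _force_cop_arrays(
    frames: np.ndarray, centers: np.ndarray, area: float, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized resultant force (T,), CoP (T, 2) and active count (T,).

    ``frames`` is (T, R, C) in kPa, ``centers`` (R, C, 2) in m.  ``weights``
    optionally masks cells (broadcastable to frames).
    """
    p = frames if weights is None else frames * weights
    f = p.sum(axis=(1, 2)) * area * KPA
    num = np.tensordot(p, centers, axes=([1, 2], [0, 1])) * area * KPA  # (T, 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cop = np.where(f[:, None] > 0, num / f[:, None], np.nan)
    n_active = (p > 0).sum(axis=(1, 2))
    return f, cop, n_active


def frame_force_cop(frame: np.ndarray, geometry: GridGeometry) -> FrameForce:
    """Resultant normal force (N) and CoP (m) of one pressure matrix (kPa).

    f = sum_i p_i A_i with A_i the sensel area; CoP is the pressure-weighted
    mean of sensel centers.  An all-zero frame yields f = 0 with a flagged
    (NaN) CoP.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (geometry.n_rows, geometry.n_cols):
        raise ValidationError(
            f"frame shape {frame.shape} does not match geometry "
            f"({geometry.n_rows}, {geometry.n_cols})"
        )
    f, cop, n = _force_cop_arrays(frame[None], geometry.cell_centers(), geometry.cell_area)
    return FrameForce(float(f[0]), cop[0], int(n[0]))


def sequence_forces(seq: PressureSequence, centers: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Total force (T,) and CoP (T, 2) for every frame of a sequence."""
    if centers is None:
        centers = seq.geometry.cell_centers()
    f, cop, _ = _force_cop_arrays(seq.frames, centers, seq.geometry.cell_area)
    return f, cop


# ---------------------------------------------------------------------------
# stance detection
# ---------------------------------------------------------------------------


def stance_threshold(body_mass: float, floor: float = 10.0, fraction: float = 0.015) -> float:
    """Default stance force threshold: max(10 N, 1.5 % of body weight)."""
    return max(floor, fraction * body_mass * 9.81)


def detect_stance(
    total_force: np.ndarray, threshold: float, min_frames: int = 3
) -> tuple[int, int]:
    """(onset, offset) frames of the longest run with force > threshold
    lasting at least ``min_frames``; offset is the run's last frame
    (inclusive)."""
    f = np.asarray(total_force, dtype=float)
    if f.size < min_frames:
        raise NoStanceError(f"series of {f.size} frames shorter than min_frames={min_frames}")
    above = f > threshold
    if not above.any():
        raise NoStanceError("force never exceeds the stance threshold")
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(f) - 1)
    runs = [(s, e) for s, e in zip(starts, ends) if e - s + 1 >= min_frames]
    if not runs:
        raise NoStanceError(f"no run of >= {min_frames} frames above threshold")
    onset, offset = max(runs, key=lambda r: r[1] - r[0])
    return int(onset), int(offset)


# ---------------------------------------------------------------------------
# insole registration
# ---------------------------------------------------------------------------


def register_cop(
    cop_insole_local: np.ndarray, cop_platform_global: np.ndarray, theta: float
) -> RigidTransform2D:
    """Rigid transform mapping insole-frame points into the global frame.

    ``theta`` rotates the insole's anteroposterior axis onto the foot's
    global direction; the translation is chosen so the rotated insole CoP
    lands exactly on the platform CoP at the matching instant.
    """
    tr = RigidTransform2D(theta, np.zeros(2))
    t = np.asarray(cop_platform_global, float) - tr.apply(np.asarray(cop_insole_local, float))
    return RigidTransform2D(theta, t)


def register_insole(
    insole: PressureSequence,
    platform: PressureSequence,
    markers: MarkerSet,
    onset: int,
    delay_s: float = 0.1,
) -> RigidTransform2D:
    """Place the insole grid into the global frame.

    The matching instant is ``onset + round(delay_s * rate)`` frames after
    the first initial ground contact.  The rotation comes from the foot
    progression angle (markers C1 and H2); the insole's local +y axis (its
    long, anteroposterior direction) is rotated onto the foot axis.  The
    translation matches the two devices' CoPs at the matching instant.  The
    transform is held constant for the whole stance (the stance foot is
    quasi-static on the ground).
    """
    match = onset + int(round(delay_s * platform.rate))
    if match >= min(insole.n_frames, platform.n_frames):
        raise RegistrationError("matching instant lies beyond the recorded frames")
    f_ins, cop_ins = sequence_forces(insole)
    f_plat, cop_plat = sequence_forces(platform)
    if f_ins[match] <= 0 or f_plat[match] <= 0:
        raise RegistrationError(
            f"zero force at the matching frame {match} on "
            f"{'insole' if f_ins[match] <= 0 else 'platform'}"
        )
    fa = foot_angle(markers.get("C1")[match], markers.get("H2")[match])
    # foot_angle is measured from +Y toward +X; a CCW rotation by -fa maps
    # the insole's local +y onto the global foot direction.
    theta = -float(fa)
    return register_cop(cop_ins[match], cop_plat[match], theta)


def global_cell_centers(
    seq: PressureSequence, transform: RigidTransform2D | None = None
) -> np.ndarray:
    """(R, C, 2) cell centers in the global frame.

    Foot-frame grids (insoles) require the registration transform.
    """
    centers = seq.geometry.cell_centers()
    if seq.geometry.frame_of_reference == "foot":
        if transform is None:
            raise ValidationError("insole grids need a registration transform")
        centers = transform.apply(centers.reshape(-1, 2)).reshape(centers.shape)
    return centers


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_cells(
    frame: np.ndarray,
    geometry: GridGeometry,
    jc_axis_coords: dict[str, float],
    axis: np.ndarray,
    transform: RigidTransform2D | None = None,
) -> dict[str, np.ndarray]:
    """Partition a frame's active cells into hindfoot/forefoot/hallux masks.

    Each cell's scalar coordinate along the anteroposterior unit vector
    ``axis`` is compared with the joint centers' (``jc_axis_coords``, which
    must be ordered "ankle" < "MT" < "MP").  Half-open convention: a cell
    exactly at a joint coordinate belongs to the distal segment.  The masks
    partition the active cells.
    """
    c_mt, c_mp = jc_axis_coords["MT"], jc_axis_coords["MP"]
    if not (jc_axis_coords["ankle"] < c_mt < c_mp):
        raise ValidationError(
            f"joint coordinates must be ordered ankle < MT < MP, got {jc_axis_coords}"
        )
    centers = geometry.cell_centers()
    if geometry.frame_of_reference == "foot":
        if transform is None:
            raise ValidationError("insole grids need a registration transform")
        centers = transform.apply(centers.reshape(-1, 2)).reshape(centers.shape)
    axis = np.asarray(axis, dtype=float)
    coords = centers @ (axis / np.linalg.norm(axis))
    active = np.asarray(frame) > 0
    if active.shape != coords.shape:
        raise ValidationError("frame shape does not match geometry")
    return {
        "hindfoot": active & (coords < c_mt),
        "forefoot": active & (coords >= c_mt) & (coords < c_mp),
        "hallux": active & (coords >= c_mp),
    }


def segmented_forces(
    seq: PressureSequence,
    jc_tracks: dict[str, JointCenterTrack],
    stance: tuple[int, int],
    axis: np.ndarray | None = None,
    transform: RigidTransform2D | None = None,
    markers: MarkerSet | None = None,
) -> dict[str, SegmentedForces]:
    """Per-joint distal force and CoP over the stance interval.

    The segmentation axis defaults to the foot long axis (per-frame C1->H2
    ground-plane direction from ``markers``); pass ``axis`` (a unit 2-vector,
    or (T, 2)) to override, e.g. the global +Y anteroposterior axis.  Joint
    centers and axis are evaluated at every frame.  An empty distal set
    yields zero force and a flagged (NaN) CoP for that frame.
    """
    onset, offset = stance
    T = offset - onset + 1
    if T < 1:
        raise ValidationError("empty stance interval")
    centers = global_cell_centers(seq, transform)  # (R, C, 2)
    frames = seq.frames[onset : offset + 1]

    if axis is None:
        if markers is None:
            raise ValidationError("segmentation needs either an axis or markers for the foot axis")
        fa = foot_angle(markers.get("C1")[onset : offset + 1], markers.get("H2")[onset : offset + 1])
        axis_t = np.stack([np.sin(fa), np.cos(fa)], axis=-1)  # (T, 2) unit vectors
    else:
        axis = np.asarray(axis, dtype=float)
        axis_t = np.broadcast_to(axis / np.linalg.norm(axis, axis=-1, keepdims=True), (T, 2))

    # scalar coordinates along the axis: cells (T, R, C), joints (T,)
    cell_c = np.einsum("rcx,tx->trc", centers, axis_t)
    jc_c = {
        j: np.einsum("tx,tx->t", jc_tracks[j].position[onset : offset + 1, :2], axis_t)
        for j in ("ankle", "MT", "MP")
    }
    if not (np.all(jc_c["ankle"] < jc_c["MT"]) and np.all(jc_c["MT"] < jc_c["MP"])):
        raise ValidationError("joint centers not ordered ankle < MT < MP along the axis")

    area = seq.geometry.cell_area
    out: dict[str, SegmentedForces] = {}
    for joint in ("ankle", "MT", "MP"):
        if joint == "ankle":
            w = np.ones_like(frames)
        else:
            thresh = jc_c[joint][:, None, None]
            w = (cell_c >= thresh).astype(float)
        f, cop, _ = _force_cop_arrays(frames, centers, area, weights=w)
        out[joint] = SegmentedForces(joint, f, cop, seq.device)
    return out
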