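"""External 3-D joint moments from segmented normal contact forces.

Because pressure grids measure only the normal (vertical) force component,
the external moment about a joint is the cross product of the distal
resultant with the lever arm from the joint center to the center of
pressure, M = (cop - jc) x F with F = (0, 0, f).  Segment weight, inertia
and friction are neglected.  Moments are expressed in the proximal
segment's local frame (x = flexion, y = long axis, z = vertical), low-pass
filtered, divided by body mass (N·m/kg) and resampled to 101 points over
0..100 % of stance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .curve_stats import butterworth_lowpass, resample_stance
from .errors import TrialRejectedError, ValidationError
from .io import GridGeometry, Trial, TrialMeta
from .kinematics import (
    DEFAULT_FRAME_RECIPES,
    PROXIMAL_SEGMENT,
    build_segment_frames,
    joint_center,
)
from .pressure import (
    SegmentedForces,
    detect_stance,
    register_insole,
    segmented_forces,
    sequence_forces,
    stance_threshold,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MomentCurve",
    "ForceCurve",
    "TrialCurves",
    "joint_moment",
    "per_cell_moment_oracle",
    "normalize_moment",
    "moment_curves",
]

KPA = 1000.0


@dataclass
class MomentCurve:
    """Body-weight-normalized joint moment vs % stance (101 samples per
    component, N·m/kg, proximal-segment frame)."""

    joint: str
    dfpf: np.ndarray
    abad: np.ndarray
    inev: np.ndarray
    meta: TrialMeta

    def __post_init__(self) -> None:
        for name in ("dfpf", "abad", "inev"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (101,):
                raise ValidationError(f"{name} must have 101 samples, got {v.shape}")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"{name} contains non-finite values")
            setattr(self, name, v)

    def component(self, motion: str) -> np.ndarray:
        return getattr(self, motion)


@dataclass
class ForceCurve:
    """Segmented normal contact force distal to one joint vs % stance (N)."""

    joint: str
    force: np.ndarray  # (101,)
    meta: TrialMeta


@dataclass
class TrialCurves:
    """All per-joint outputs of one trial processed with one device."""

    moments: dict[str, MomentCurve]
    forces: dict[str, ForceCurve]
    stance: tuple[int, int]
    device: str


def joint_moment(
    f_normal: float | np.ndarray,
    cop: np.ndarray,
    jc: np.ndarray,
    proximal_rotation: np.ndarray,
) -> np.ndarray:
    """External moment (N·m) of a vertical resultant about a joint center,
    expressed in the proximal segment's frame.

    M_global = (cop_3d - jc) x (0, 0, f) with the CoP lifted to the ground
    plane z = 0; the result is rotated by ``proximal_rotation``^T.  Zero
    force gives a zero moment.  Accepts stacked inputs: f (T,), cop (T, 2),
    jc (T, 3), rotation (T, 3, 3).
    """
    f = np.asarray(f_normal, dtype=float)
    cop = np.asarray(cop, dtype=float)
    jc = np.asarray(jc, dtype=float)
    single = f.ndim == 0
    f = np.atleast_1d(f)
    cop = np.atleast_2d(cop)
    jc = np.atleast_2d(jc)
    rot = np.asarray(proximal_rotation, dtype=float)
    if rot.ndim == 2:
        rot = np.broadcast_to(rot, (f.shape[0], 3, 3))
    cop3 = np.concatenate([cop, np.zeros((cop.shape[0], 1))], axis=1)
    r = cop3 - jc
    # (rx, ry, rz) x (0, 0, f) = (ry f, -rx f, 0)
    m_global = np.stack([r[:, 1] * f, -r[:, 0] * f, np.zeros_like(f)], axis=1)
    m_global = np.where(f[:, None] > 0, m_global, 0.0)
    m_local = np.einsum("tij,ti->tj", rot, m_global)  # R^T m
    return m_local[0] if single else m_local


def per_cell_moment_oracle(
    frame: np.ndarray, geometry: GridGeometry, mask: np.ndarray, jc: np.ndarray
) -> np.ndarray:
    """Independent check: moment as the direct per-cell cross-product sum,
    M = sum_i (r_i - jc) x (0, 0, p_i A_i), in the global frame.

    For parallel (vertical-only) cell forces this is algebraically identical
    to the resultant-and-CoP formula; an empty mask gives zero.
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    jc = np.asarray(jc, dtype=float)
    centers = geometry.cell_centers()  # (R, C, 2)
    p = np.where(mask, frame, 0.0)
    fi = p * geometry.cell_area * KPA  # per-cell vertical force, N
    rx = centers[..., 0] - jc[0]
    ry = centers[..., 1] - jc[1]
    # r x (0,0,fi) summed over cells; rz contributes nothing for vertical forces
    return np.array([(ry * fi).sum(), -(rx * fi).sum(), 0.0])


def normalize_moment(m: np.ndarray, mass: float) -> np.ndarray:
    """Componentwise division by body mass: N·m -> N·m/kg."""
    if not mass > 0:
        raise ValidationError("body mass must be positive")
    return np.asarray(m, dtype=float) / mass


def moment_curves(
    trial: Trial, device: str, config: PipelineConfig | None = None
) -> TrialCurves:
    """Full per-trial kinetics for one device.

    Steps: stance detection on the device's total force; marker low-pass
    (10 Hz default); insole registration when ``device='insole'``; per-frame
    segmentation of cells by joint-center location along the foot axis;
    joint moments in the proximal frames; kinetic low-pass (50 Hz nominal,
    clipped below Nyquist); body-mass normalization; resampling to 101
    %-stance points.  A stance shorter than 0.2 s rejects the trial.
    """
    cfg = config or PipelineConfig()
    if device not in ("platform", "insole"):
        raise ValidationError(f"unknown device {device!r}")
    seq = trial.platform if device == "platform" else trial.insole
    rate = seq.rate

    total, _ = sequence_forces(seq) if device == "platform" else _insole_total(trial)
    threshold = stance_threshold(trial.meta.body_mass, cfg.stance_floor_n, cfg.stance_bw_fraction)
    onset, offset = detect_stance(total, threshold, cfg.stance_min_frames)
    if (offset - onset + 1) / rate < cfg.min_stance_s:
        raise TrialRejectedError(
            f"stance of {(offset - onset + 1) / rate:.2f} s shorter than "
            f"{cfg.min_stance_s} s; trial rejected"
        )

    markers = trial.markers
    if cfg.marker_cutoff_hz:
        filt_pos = butterworth_lowpass(markers.positions, rate, cfg.marker_cutoff_hz, axis=0)
        markers = type(markers)(list(markers.names), filt_pos, rate)

    transform = None
    if device == "insole":
        plat_total, _ = sequence_forces(trial.platform)
        p_onset, _ = detect_stance(plat_total, threshold, cfg.stance_min_frames)
        transform = register_insole(
            trial.insole, trial.platform, markers, p_onset, cfg.registration_delay_s
        )

    jc_tracks = {
        j: joint_center(markers, j, cfg.joint_center_pairs.get(j)) for j in ("ankle", "MT", "MP")
    }
    axis = None if cfg.segmentation_axis == "foot" else np.array([0.0, 1.0])
    seg = segmented_forces(
        seq, jc_tracks, (onset, offset), axis=axis, transform=transform, markers=markers
    )

    recipes = {**DEFAULT_FRAME_RECIPES, **cfg.frame_recipes}
    frames = {
        name: build_segment_frames(markers, recipes[name])
        for name in set(PROXIMAL_SEGMENT.values())
    }

    moments: dict[str, MomentCurve] = {}
    forces: dict[str, ForceCurve] = {}
    T = offset - onset + 1
    for joint in ("ankle", "MT", "MP"):
        sf: SegmentedForces = seg[joint]
        prox = frames[PROXIMAL_SEGMENT[joint]]
        jc = jc_tracks[joint].position[onset : offset + 1]
        rot = prox.rotation[onset : offset + 1]
        cop = np.where(np.isfinite(sf.cop), sf.cop, 0.0)  # zero-force frames: moment is 0 anyway
        m_local = joint_moment(sf.f_normal, cop, jc, rot)  # (T, 3)
        m_filt = butterworth_lowpass(m_local, rate, cfg.kinetic_cutoff_hz, axis=0)
        m_norm = normalize_moment(m_filt, trial.meta.body_mass)
        m_101 = resample_stance(m_norm, 0, T - 1, cfg.resample_points)
        meta = type(trial.meta)(
            trial.meta.subject_id, trial.meta.body_mass, trial.meta.shoe,
            device, trial.meta.trial_index,
        )
        moments[joint] = MomentCurve(joint, m_101[:, 0], m_101[:, 2], m_101[:, 1], meta)
        f_filt = butterworth_lowpass(sf.f_normal, rate, cfg.kinetic_cutoff_hz)
        forces[joint] = ForceCurve(joint, resample_stance(f_filt, 0, T - 1, cfg.resample_points), meta)
    return TrialCurves(moments, forces, (onset, offset), device)


def _insole_total(trial: Trial) -> tuple[np.ndarray, np.ndarray]:
    """Total insole force/CoP in the insole's own frame (registration-free;
    the resultant magnitude does not depend on the planar placement)."""
    return sequence_forces(trial.insole)
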