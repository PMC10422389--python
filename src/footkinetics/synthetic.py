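"""Synthetic gait trials with exact ground truth.

A trial is generated from one continuous plantar-pressure field

    p(x, y, t) = F(t) * sum_k w_k(t) * phi_k(x, y)

where F is a double-hump vertical ground-reaction-force profile (in units of
body weight), the phi_k are unit-mass 2-D Gaussian blobs truncated at
3 sigma (heel, metatarsal heads, hallux) fixed in the foot frame, and the
weights w_k shift smoothly from heel to toe over stance.  Both devices
sample this same field: the platform grid in the global frame, the insole
grid in the foot frame (related by a known planar rigid transform), each
clipped to its sensing range.  Markers sit on a rigid articulated foot in
the same pose, so every pipeline stage — stance detection, registration,
segmentation, moments, parameter extraction — can be checked against the
field's exact (1 mm quadrature) segmented forces, CoPs and moments.

Blob truncation keeps supports compact (a blob strictly posterior to a
joint line contributes exactly zero distal force) while symmetric, so each
blob's centroid stays at its center and the continuous total CoP is the
closed form sum_k w_k(t) mu_k.

The loading-weight ramps are clamped smoothsteps: exactly 0 before their
window and 1 after, for the same compact-support reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import ValidationError
from .io import (
    GridGeometry,
    MarkerSet,
    PressureSequence,
    Trial,
    TrialMeta,
)
from .kinematics import PROXIMAL_SEGMENT, DEFAULT_FRAME_RECIPES, build_segment_frames, joint_center
from .kinetics import MomentCurve, joint_moment, normalize_moment
from .curve_stats import resample_stance
from .pressure import RigidTransform2D

__all__ = [
    "GaitModel",
    "GroundTruth",
    "simulate_trial",
    "ground_truth_moments",
    "make_device_pair",
    "simulate_design",
    "default_model",
]

G = 9.81  # m/s^2
TRUNC = 3.0  # blob truncation radius in sigmas
_TRUNC_MASS = 1.0 - np.exp(-0.5 * TRUNC**2)  # mass kept by truncation


def _smoothstep(s: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """0 below lo, 1 above hi, C1 cubic in between."""
    u = np.clip((np.asarray(s, float) - lo) / (hi - lo), 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass(frozen=True)
class Blob:
    """One truncated-Gaussian loading center, in foot-length fractions."""

    x_frac: float
    y_frac: float
    sigma_frac: float


@dataclass(frozen=True)
class ForceProfile:
    """Double-hump vertical GRF in body-weight units vs % stance."""

    peak1: float = 1.10
    peak2: float = 1.05
    t1: float = 25.0
    t2: float = 75.0
    width: float = 13.0
    valley: float = 0.45
    valley_width: float = 10.0
    ramp: float = 8.0

    def __call__(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        g = lambda mu, sig: np.exp(-0.5 * ((s - mu) / sig) ** 2)
        shape = (
            self.peak1 * g(self.t1, self.width)
            + self.peak2 * g(self.t2, self.width)
            + self.valley * g(50.0, self.valley_width)
        )
        edges = _smoothstep(s, 0.0, self.ramp) * _smoothstep(100.0 - s, 0.0, self.ramp)
        return shape * edges

    def peak_bw(self) -> float:
        """Actual profile maximum in body weights (dense evaluation)."""
        s = np.linspace(0, 100, 4001)
        return float(self(s).max())


@dataclass(frozen=True)
class LoadSchedule:
    """Smoothstep breakpoints (% stance) of the heel->toe weight shift."""

    heel_off: tuple[float, float] = (30.0, 60.0)
    met_on: tuple[float, float] = (20.0, 45.0)
    met_off: tuple[float, float] = (80.0, 100.0)
    hallux_on: tuple[float, float] = (65.0, 90.0)

    def weights(self, s: np.ndarray) -> np.ndarray:
        """(T, 3) nonnegative weights (heel, met, hallux) summing to 1."""
        heel = 1.0 - _smoothstep(s, *self.heel_off)
        met = _smoothstep(s, *self.met_on) * (1.0 - _smoothstep(s, *self.met_off))
        hallux = _smoothstep(s, *self.hallux_on)
        w = np.stack([heel, met, hallux], axis=-1)
        tot = w.sum(axis=-1, keepdims=True)
        if np.any(tot <= 0):
            raise ValidationError("loading schedule leaves an instant with zero weight")
        return w / tot


@dataclass(frozen=True)
class GaitModel:
    """All parameters of one synthetic trial."""

    foot_length: float = 0.26  # m
    ankle_frac: float = 0.25
    mt_frac: float = 0.45
    mp_frac: float = 0.75
    body_mass: float = 71.0  # kg
    stance_duration: float = 0.70  # s
    rate: float = 100.0  # Hz
    profile: ForceProfile = field(default_factory=ForceProfile)
    schedule: LoadSchedule = field(default_factory=LoadSchedule)
    blobs: tuple[Blob, Blob, Blob] = (
        Blob(-0.012, 0.14, 0.058),  # heel
        Blob(0.023, 0.70, 0.058),  # metatarsal heads
        Blob(0.046, 0.90, 0.042),  # hallux
    )
    theta: float = np.deg2rad(7.0)  # foot progression (toe-out), rad
    heel_pos: tuple[float, float] = (-0.02, -0.13)  # m, global
    shank_pitch_deg: tuple[float, float] = (-10.0, 20.0)  # over stance
    noise_sd: float = 2.0  # kPa, on loaded sensels
    insole_bias: float = 1.0  # multiplicative field scale seen by the insole
    platform_pitch: float = 0.010  # m (1 sensel/cm^2)
    insole_pitch: float = 0.00506  # m (~3.9 sensels/cm^2)
    platform_size: float = 0.40  # m, square
    platform_range: tuple[float, float] = (4.0, 1000.0)  # kPa
    insole_range: tuple[float, float] = (4.0, 862.0)  # kPa
    lead_frames: int = 15
    tail_frames: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ankle_frac < self.mt_frac < self.mp_frac < 1):
            raise ValidationError("joint fractions must satisfy 0 < ankle < MT < MP < 1")
        if self.body_mass <= 0 or self.foot_length <= 0 or self.stance_duration <= 0:
            raise ValidationError("mass, foot length and stance duration must be positive")
        if self.insole_bias <= 0:
            raise ValidationError("insole bias must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")

    # -- derived geometry --------------------------------------------------

    @property
    def n_stance(self) -> int:
        return int(round(self.stance_duration * self.rate))

    @property
    def n_frames(self) -> int:
        return self.lead_frames + self.n_stance + self.tail_frames

    @property
    def pose(self) -> RigidTransform2D:
        """Foot-frame -> global planar transform."""
        return RigidTransform2D(self.theta, np.asarray(self.heel_pos))

    def joint_y(self) -> dict[str, float]:
        """Joint-line coordinates along the foot axis (foot frame, m)."""
        L = self.foot_length
        return {"ankle": self.ankle_frac * L, "MT": self.mt_frac * L, "MP": self.mp_frac * L}

    def stance_percent(self) -> np.ndarray:
        """% stance of each stance frame."""
        return 100.0 * np.arange(self.n_stance) / (self.n_stance - 1)

    def force_newton(self) -> np.ndarray:
        """Total vertical force (N) at every frame of the full trial."""
        f = np.zeros(self.n_frames)
        f[self.lead_frames : self.lead_frames + self.n_stance] = (
            self.profile(self.stance_percent()) * self.body_mass * G
        )
        return f

    def blob_params(self) -> tuple[np.ndarray, np.ndarray]:
        """Blob centers (3, 2) and sigmas (3,) in meters (foot frame)."""
        L = self.foot_length
        mu = np.array([[b.x_frac * L, b.y_frac * L] for b in self.blobs])
        sig = np.array([b.sigma_frac * L for b in self.blobs])
        return mu, sig


def default_model(**overrides) -> GaitModel:
    return replace(GaitModel(), **overrides) if overrides else GaitModel()


# ---------------------------------------------------------------------------
# field evaluation
# ---------------------------------------------------------------------------


def _blob_density(points: np.ndarray, mu: np.ndarray, sig: np.ndarray) -> np.ndarray:
    """phi_k at foot-frame points: (K, N) unit-mass truncated Gaussians (1/m^2)."""
    d2 = ((points[None, :, :] - mu[:, None, :]) ** 2).sum(axis=2)  # (K, N)
    dens = np.exp(-0.5 * d2 / sig[:, None] ** 2) / (2 * np.pi * sig[:, None] ** 2 * _TRUNC_MASS)
    dens[d2 > (TRUNC * sig[:, None]) ** 2] = 0.0
    return dens


def _field_kpa(
    model: GaitModel, points_foot: np.ndarray
) -> np.ndarray:
    """Noise-free pressure (T, N) in kPa at foot-frame points for the whole trial."""
    mu, sig = model.blob_params()
    phi = _blob_density(points_foot, mu, sig)  # (3, N), 1/m^2
    s = model.stance_percent()
    w = model.schedule.weights(s)  # (n_stance, 3)
    f = model.profile(s) * model.body_mass * G  # N
    press = np.zeros((model.n_frames, points_foot.shape[0]))
    press[model.lead_frames : model.lead_frames + model.n_stance] = (
        (w * f[:, None]) @ phi
    ) / 1000.0  # Pa -> kPa
    return press


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------


def _marker_layout(model: GaitModel) -> dict[str, np.ndarray]:
    """Foot-frame marker positions (m) of the static neutral pose."""
    L = model.foot_length
    ay, mty, mpy = model.ankle_frac * L, model.mt_frac * L, model.mp_frac * L
    return {
        "C1": np.array([0.0, 0.01, 0.04]),
        "C2": np.array([0.015, 0.035, 0.06]),
        "MC": np.array([0.035, ay, 0.07]),
        "LC": np.array([-0.035, ay, 0.07]),
        "NV": np.array([0.030, mty, 0.05]),
        "CU": np.array([-0.030, mty, 0.04]),
        "B1": np.array([0.040, 0.55 * L, 0.035]),
        "B5": np.array([-0.045, 0.54 * L, 0.030]),
        "H1": np.array([0.035, mpy, 0.035]),
        "H3": np.array([-0.035, mpy, 0.035]),
        "H2": np.array([0.0, 0.78 * L, 0.03]),
        "HX": np.array([0.012, 0.92 * L, 0.025]),
        "SH1": np.array([0.0, ay + 0.030, 0.15]),
        "SH2": np.array([0.0, ay - 0.030, 0.15]),
        "SH3": np.array([0.0, ay + 0.030, 0.35]),
        "SH4": np.array([0.0, ay - 0.030, 0.35]),
    }


def _markers(model: GaitModel) -> tuple[MarkerSet, MarkerSet]:
    """(trial markers, static reference) for the whole trial.

    The stance foot is planted (rigid, flat on the ground); the shank
    pitches forward about the ankle over stance, emulating tibial
    progression.  The static reference is the neutral upright pose at the
    global origin.
    """
    layout = _marker_layout(model)
    names = list(layout)
    base = np.stack([layout[n] for n in names])  # (M, 3), foot frame
    T = model.n_frames
    pos = np.broadcast_to(base, (T, *base.shape)).copy()

    # shank pitch about the ankle medial-lateral axis
    p0, p1 = model.shank_pitch_deg
    s = np.zeros(T)
    s[model.lead_frames : model.lead_frames + model.n_stance] = model.stance_percent()
    s[model.lead_frames + model.n_stance :] = 100.0
    pitch = np.deg2rad(p0 + (p1 - p0) * s / 100.0)
    ankle = np.array([0.0, model.ankle_frac * model.foot_length, 0.07])
    shank_idx = [names.index(n) for n in ("SH1", "SH2", "SH3", "SH4")]
    rel = base[shank_idx] - ankle  # (4, 3)
    c, sn = np.cos(pitch), np.sin(pitch)
    # rotation about +x: y' = c y - s z, z' = s y + c z
    ry = c[:, None] * rel[None, :, 1] - sn[:, None] * rel[None, :, 2]
    rz = sn[:, None] * rel[None, :, 1] + c[:, None] * rel[None, :, 2]
    for j, idx in enumerate(shank_idx):
        pos[:, idx, 1] = ankle[1] + ry[:, j]
        pos[:, idx, 2] = ankle[2] + rz[:, j]

    # foot-frame -> global planar pose
    xy = pos[:, :, :2].reshape(-1, 2)
    pos[:, :, :2] = model.pose.apply(xy).reshape(T, len(names), 2)

    static = MarkerSet(names, base[None, :, :].copy(), model.rate)
    return MarkerSet(names, pos, model.rate), static


# ---------------------------------------------------------------------------
# trial synthesis
# ---------------------------------------------------------------------------


def _platform_geometry(model: GaitModel) -> GridGeometry:
    n = int(round(model.platform_size / model.platform_pitch))
    half = (n - 1) / 2.0
    return GridGeometry(
        n_rows=n, n_cols=n, pitch_x=model.platform_pitch, pitch_y=model.platform_pitch,
        origin=(-half * model.platform_pitch, -half * model.platform_pitch),
        orientation=0.0, frame_of_reference="global",
    )


def _insole_geometry(model: GaitModel) -> GridGeometry:
    pitch = model.insole_pitch
    n_cols = int(round(0.11 / pitch)) + 1
    n_rows = int(round((model.foot_length + 0.05) / pitch)) + 1
    return GridGeometry(
        n_rows=n_rows, n_cols=n_cols, pitch_x=pitch, pitch_y=pitch,
        origin=(-(n_cols - 1) / 2.0 * pitch, -0.01),
        orientation=0.0, frame_of_reference="foot",
    )


def simulate_trial(
    model: GaitModel,
    meta: TrialMeta | None = None,
    with_ground_truth: bool = True,
) -> tuple[Trial, "GroundTruth | None"]:
    """Generate one synchronized trial (markers + both pressure streams).

    Deterministic for a fixed model (the model's seed drives all noise).
    Returns the Trial and, unless disabled, its 1 mm-quadrature GroundTruth.
    """
    rng = np.random.default_rng(model.seed)
    markers, static = _markers(model)

    # platform: global grid -> foot frame -> field
    plat_geom = _platform_geometry(model)
    inv = model.pose.inverse()
    plat_pts_foot = inv.apply(plat_geom.cell_centers().reshape(-1, 2))
    plat_kpa = _field_kpa(model, plat_pts_foot).reshape(
        model.n_frames, plat_geom.n_rows, plat_geom.n_cols
    )

    ins_geom = _insole_geometry(model)
    ins_pts = ins_geom.cell_centers().reshape(-1, 2)  # already foot frame
    ins_kpa = model.insole_bias * _field_kpa(model, ins_pts).reshape(
        model.n_frames, ins_geom.n_rows, ins_geom.n_cols
    )

    for arr in (plat_kpa, ins_kpa):
        if model.noise_sd > 0:
            loaded = arr > 0
            arr[loaded] = np.maximum(
                0.0, arr[loaded] + rng.normal(0.0, model.noise_sd, loaded.sum())
            )

    platform = PressureSequence.from_raw(
        plat_geom, plat_kpa, model.rate, "platform", *model.platform_range
    )
    insole = PressureSequence.from_raw(
        ins_geom, ins_kpa, model.rate, "insole", *model.insole_range
    )
    if meta is None:
        meta = TrialMeta("S01", model.body_mass, "A", "platform", 1)
    trial = Trial(meta, markers, platform, insole, static)
    gt = ground_truth(model) if with_ground_truth else None
    return trial, gt


def make_device_pair(model: GaitModel, insole_bias: float = 1.0) -> tuple[Trial, Trial]:
    """Two views of the same walk: a platform trial from the unbiased field
    and an insole trial whose field is scaled by ``insole_bias`` (modeling
    the insole's incomplete capture of the contact forces).
    """
    if insole_bias <= 0:
        raise ValidationError("insole bias must be positive")
    base, _ = simulate_trial(replace(model, insole_bias=1.0), with_ground_truth=False)
    biased, _ = simulate_trial(replace(model, insole_bias=insole_bias), with_ground_truth=False)
    plat_meta = replace(base.meta, device="platform")
    ins_meta = replace(base.meta, device="insole")
    trial_platform = Trial(plat_meta, base.markers, base.platform, base.insole, base.static_reference)
    trial_insole = Trial(ins_meta, biased.markers, biased.platform, biased.insole, biased.static_reference)
    return trial_platform, trial_insole


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Exact field-level reference quantities for one model.

    Forces/CoPs/moments are 1 mm-quadrature integrals of the continuous
    field over the stance window; curves are on the 101-point % stance grid
    with moments mass-normalized (N·m/kg) in the proximal-segment frames.
    """

    model: GaitModel
    stance: tuple[int, int]
    contact: tuple[int, int]
    transform_theta: float
    transform_t: np.ndarray
    total_force: np.ndarray  # (n_stance,) N
    total_cop_foot: np.ndarray  # (n_stance, 2) closed form, foot frame
    total_cop_global: np.ndarray  # (n_stance, 2)
    seg_force: dict[str, np.ndarray]  # per joint (n_stance,)
    seg_cop_global: dict[str, np.ndarray]  # per joint (n_stance, 2)
    moment_curves: dict[str, MomentCurve]
    force_curves: dict[str, np.ndarray]  # per joint (101,) N
    peak_force: float  # configured profile peak x body weight, N

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        data = {
            "stance": list(self.stance),
            "transform": {"theta": self.transform_theta, "t": self.transform_t.tolist()},
            "peak_force": self.peak_force,
            "seg_force": {k: v.tolist() for k, v in self.seg_force.items()},
            "force_curves": {k: v.tolist() for k, v in self.force_curves.items()},
            "moment_curves": {
                j: {m: getattr(c, m).tolist() for m in ("dfpf", "abad", "inev")}
                for j, c in self.moment_curves.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(data, fh)
        return path


def ground_truth(model: GaitModel, quad_step: float = 0.001) -> GroundTruth:
    """Quadrature ground truth of the continuous field (default 1 mm grid)."""
    mu, sig = model.blob_params()
    # quadrature grid covering all truncated blobs, foot frame
    lo = (mu - TRUNC * sig[:, None]).min(axis=0) - quad_step
    hi = (mu + TRUNC * sig[:, None]).max(axis=0) + quad_step
    xs = np.arange(lo[0], hi[0] + quad_step, quad_step)
    ys = np.arange(lo[1], hi[1] + quad_step, quad_step)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    phi = _blob_density(pts, mu, sig) * quad_step**2  # (3, N) cell masses

    s = model.stance_percent()
    w = model.schedule.weights(s)  # (T, 3)
    f_t = model.profile(s) * model.body_mass * G  # (T,)
    jy = model.joint_y()

    # per-blob mass and first moments over each distal region (time-invariant)
    y = pts[:, 1]
    seg_force: dict[str, np.ndarray] = {}
    seg_cop_foot: dict[str, np.ndarray] = {}
    for joint in ("ankle", "MT", "MP"):
        distal = np.ones_like(y, dtype=bool) if joint == "ankle" else y >= jy[joint]
        mass_k = phi[:, distal].sum(axis=1)  # (3,)
        mx_k = (phi[:, distal] * pts[distal, 0]).sum(axis=1)
        my_k = (phi[:, distal] * pts[distal, 1]).sum(axis=1)
        frac = w @ mass_k  # (T,)
        seg_force[joint] = f_t * frac
        with np.errstate(invalid="ignore", divide="ignore"):
            cop = np.stack([(w @ mx_k), (w @ my_k)], axis=1) / frac[:, None]
        seg_cop_foot[joint] = np.where(frac[:, None] > 0, cop, np.nan)

    pose = model.pose
    seg_cop_global = {
        j: np.where(
            np.isfinite(c).all(axis=1, keepdims=True), pose.apply(np.nan_to_num(c)), np.nan
        )
        for j, c in seg_cop_foot.items()
    }
    total_cop_foot = w @ mu  # closed form: truncation is symmetric
    total_cop_global = pose.apply(total_cop_foot)

    # moments with the same marker-derived frames and conventions as the pipeline
    markers, _ = _markers(model)
    onset = model.lead_frames
    offset = model.lead_frames + model.n_stance - 1
    jc_tracks = {j: joint_center(markers, j) for j in ("ankle", "MT", "MP")}
    frames = {
        name: build_segment_frames(markers, DEFAULT_FRAME_RECIPES[name])
        for name in set(PROXIMAL_SEGMENT.values())
    }
    moment_curves_out: dict[str, MomentCurve] = {}
    force_curves: dict[str, np.ndarray] = {}
    T = model.n_stance
    for joint in ("ankle", "MT", "MP"):
        jc = jc_tracks[joint].position[onset : offset + 1]
        rot = frames[PROXIMAL_SEGMENT[joint]].rotation[onset : offset + 1]
        cop = np.nan_to_num(seg_cop_global[joint])
        m_local = joint_moment(seg_force[joint], cop, jc, rot)
        m_norm = normalize_moment(m_local, model.body_mass)
        m_101 = resample_stance(m_norm, 0, T - 1)
        meta = TrialMeta("GT", model.body_mass, "A", "field", 1)
        moment_curves_out[joint] = MomentCurve(
            joint, m_101[:, 0], m_101[:, 2], m_101[:, 1], meta
        )
        force_curves[joint] = resample_stance(seg_force[joint], 0, T - 1)

    f_full = model.force_newton()
    nz = np.flatnonzero(f_full > 0)
    return GroundTruth(
        model=model,
        stance=(onset, offset),
        contact=(int(nz[0]), int(nz[-1])) if nz.size else (onset, offset),
        transform_theta=model.theta,
        transform_t=np.asarray(model.heel_pos, float),
        total_force=f_t,
        total_cop_foot=total_cop_foot,
        total_cop_global=total_cop_global,
        seg_force=seg_force,
        seg_cop_global=seg_cop_global,
        moment_curves=moment_curves_out,
        force_curves=force_curves,
        peak_force=model.profile.peak_bw() * model.body_mass * G,
    )


def ground_truth_moments(model: GaitModel) -> dict[str, MomentCurve]:
    """Exact joint-moment curves of the continuous field (per joint)."""
    return ground_truth(model).moment_curves


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """A subjects x shoes x devices x trials simulated study."""

    n_subjects: int = 10
    n_trials: int = 5
    shoes: tuple[str, ...] = ("A", "B")
    insole_bias: float = 1.0
    noise_sd: float = 2.0
    seed: int = 0


def _subject_model(rng: np.random.Generator, spec: DesignSpec) -> GaitModel:
    """Draw one subject's gait characteristics (population per the study
    cohort: adults, mass 71 +/- 12 kg)."""
    mass = float(np.clip(rng.normal(71.0, 12.0), 45.0, 110.0))
    foot = float(np.clip(rng.normal(0.26, 0.012), 0.22, 0.30))
    stance = float(np.clip(rng.normal(0.70, 0.05), 0.58, 0.82))
    theta = float(rng.normal(np.deg2rad(7.0), np.deg2rad(3.0)))
    prof = ForceProfile(
        peak1=float(rng.normal(1.10, 0.03)),
        peak2=float(rng.normal(1.05, 0.03)),
        t1=float(rng.normal(25.0, 1.5)),
        t2=float(rng.normal(75.0, 1.5)),
    )
    blobs = (
        Blob(float(rng.normal(-0.012, 0.004)), 0.14, 0.058),
        Blob(float(rng.normal(0.023, 0.005)), float(rng.normal(0.70, 0.01)), 0.058),
        Blob(float(rng.normal(0.046, 0.004)), 0.90, 0.042),
    )
    return replace(
        GaitModel(),
        body_mass=mass,
        foot_length=foot,
        stance_duration=stance,
        theta=theta,
        profile=prof,
        blobs=blobs,
        noise_sd=spec.noise_sd,
    )


def simulate_design(spec: DesignSpec) -> Iterator[tuple[GaitModel, Trial, Trial]]:
    """Yield (model, platform trial, insole trial) for every design cell.

    Subject characteristics are drawn once per subject; trials add small
    within-subject jitter (stance timing, pose, GRF peaks); the shoe adds a
    small systematic shift of the forefoot loading.  Each walk yields both
    device trials via :func:`make_device_pair`.
    """
    rng = np.random.default_rng(spec.seed)
    for i in range(spec.n_subjects):
        subj = _subject_model(rng, spec)
        sid = f"S{i + 1:02d}"
        for shoe in spec.shoes:
            shoe_dx = 0.0 if shoe == "A" else 0.006
            for trial_idx in range(1, spec.n_trials + 1):
                blobs = tuple(
                    Blob(
                        b.x_frac + shoe_dx + float(rng.normal(0, 0.0015)),
                        b.y_frac,
                        b.sigma_frac,
                    )
                    for b in subj.blobs
                )
                model = replace(
                    subj,
                    blobs=blobs,
                    stance_duration=float(
                        np.clip(subj.stance_duration + rng.normal(0, 0.02), 0.5, 0.9)
                    ),
                    theta=subj.theta + float(rng.normal(0, np.deg2rad(1.0))),
                    heel_pos=(
                        -0.02 + float(rng.normal(0, 0.005)),
                        -0.13 + float(rng.normal(0, 0.005)),
                    ),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                tp, ti = make_device_pair(model, spec.insole_bias)
                meta_kw = dict(
                    subject_id=sid, body_mass=model.body_mass, shoe=shoe, trial_index=trial_idx
                )
                tp = Trial(
                    TrialMeta(device="platform", **meta_kw),
                    tp.markers, tp.platform, tp.insole, tp.static_reference,
                )
                ti = Trial(
                    TrialMeta(device="insole", **meta_kw),
                    ti.markers, ti.platform, ti.insole, ti.static_reference,
                )
                yield model, tp, ti
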