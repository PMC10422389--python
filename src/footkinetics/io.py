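"""Record types and readers/writers for gait trials.

Internal unit policy (enforced by every reader): meters, seconds, newtons,
N·m, kilopascals for pressure, kilograms for mass.  Marker files on disk are
usually in millimetres (the motion-capture convention) and are converted on
read.

Native exchange formats are plain text: a wide CSV for marker trajectories,
a long CSV (``frame,row,col,kpa,sat``) plus a JSON geometry sidecar for
pressure sequences, and CSVs for result curves and parameter tables.  TRC is
supported read-only; C3D read requires the optional ``ezc3d`` dependency.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MissingMarkerError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerSet",
    "GridGeometry",
    "PressureSequence",
    "TrialMeta",
    "Trial",
    "read_markers",
    "write_markers_csv",
    "read_pressure",
    "write_pressure",
    "write_results",
    "read_parameter_table",
]

# Marker labels of the multisegment shoe-mounted set: calcaneus (C1, C2),
# malleolar pair (MC, LC), metatarsal bases (B1, B5), metatarsal heads
# (H1, H2, H3), hallux (HX), navicular (NV), cuboid (CU), plus four shank
# markers for the proximal segment.
FOOT_MARKERS = ("C1", "C2", "MC", "LC", "B1", "H2", "HX", "H1", "H3", "NV", "CU", "B5")
SHANK_MARKERS = ("SH1", "SH2", "SH3", "SH4")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MarkerSet:
    """Named 3-D marker trajectories in the global frame.

    positions has shape (frames, n_markers, 3) in meters; missing samples are
    NaN and reported by :attr:`missing` rather than silently interpolated.
    """

    names: list[str]
    positions: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValidationError(
                f"positions must be (frames, markers, 3), got {self.positions.shape}"
            )
        if self.positions.shape[1] != len(self.names):
            raise ValidationError("number of position columns does not match names")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValidationError(f"duplicate marker labels: {dupes}")
        if not self.rate > 0:
            raise ValidationError("sampling rate must be positive")

    @property
    def frames(self) -> int:
        return self.positions.shape[0]

    @property
    def missing(self) -> np.ndarray:
        """(frames, n_markers) boolean mask of missing samples."""
        return np.isnan(self.positions).any(axis=2)

    def get(self, name: str) -> np.ndarray:
        """Trajectory of one marker, shape (frames, 3)."""
        try:
            idx = self.names.index(name)
        except ValueError:
            raise MissingMarkerError(name) from None
        return self.positions[:, idx, :]

    def has(self, name: str) -> bool:
        return name in self.names

    def gap_fill(self, max_gap: int = 10) -> "MarkerSet":
        """Linearly interpolate missing runs of at most ``max_gap`` frames.

        Longer gaps (and gaps touching the series ends) are left as NaN.
        Returns a new MarkerSet; the original is untouched.
        """
        pos = self.positions.copy()
        for m in range(pos.shape[1]):
            bad = np.isnan(pos[:, m, :]).any(axis=1)
            if not bad.any() or bad.all():
                continue
            idx = np.flatnonzero(bad)
            # split into consecutive runs
            splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            for run in splits:
                lo, hi = run[0] - 1, run[-1] + 1
                if lo < 0 or hi >= pos.shape[0] or len(run) > max_gap:
                    continue
                t = (run - lo) / (hi - lo)
                pos[run, m, :] = (1 - t)[:, None] * pos[lo, m, :] + t[:, None] * pos[hi, m, :]
        return MarkerSet(list(self.names), pos, self.rate)


@dataclass
class GridGeometry:
    """Geometry of a rectangular pressure grid.

    ``origin`` is the coordinate of the center of cell (row 0, col 0) in the
    grid's frame of reference; columns advance along local +x, rows along
    local +y; ``orientation`` rotates the grid axes counter-clockwise with
    respect to that frame's axes.
    """

    n_rows: int
    n_cols: int
    pitch_x: float
    pitch_y: float
    origin: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0
    frame_of_reference: Literal["global", "foot"] = "global"

    def __post_init__(self) -> None:
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise ValidationError("grid pitch must be positive")
        if not (-np.pi < self.orientation <= np.pi):
            raise ValidationError("orientation must lie in (-pi, pi]")
        if self.frame_of_reference not in ("global", "foot"):
            raise ValidationError("frame_of_reference must be 'global' or 'foot'")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def cell_area(self) -> float:
        """Area of one sensel in m^2."""
        return self.pitch_x * self.pitch_y

    def cell_centers(self) -> np.ndarray:
        """(n_rows, n_cols, 2) cell-center coordinates in the grid's frame."""
        cols = np.arange(self.n_cols) * self.pitch_x
        rows = np.arange(self.n_rows) * self.pitch_y
        local = np.stack(np.meshgrid(cols, rows), axis=-1)  # (R, C, 2) = (x, y)
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        rot = np.array([[c, -s], [s, c]])
        return local @ rot.T + np.asarray(self.origin)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pitch_x": self.pitch_x,
            "pitch_y": self.pitch_y,
            "origin": list(self.origin),
            "orientation": self.orientation,
            "frame_of_reference": self.frame_of_reference,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            pitch_x=float(d["pitch_x"]),
            pitch_y=float(d["pitch_y"]),
            origin=tuple(d.get("origin", (0.0, 0.0))),
            orientation=float(d.get("orientation", 0.0)),
            frame_of_reference=d.get("frame_of_reference", "global"),
        )


@dataclass
class PressureSequence:
    """Time series of pressure matrices from one device.

    frames: (T, n_rows, n_cols) in kPa, already range-conditioned: values
    above ``p_max`` are clipped (and flagged in ``saturated``), values below
    the sensing floor ``p_min`` are zero.
    """

    geometry: GridGeometry
    frames: np.ndarray
    rate: float
    device: Literal["platform", "insole"]
    p_min: float = 4.0
    p_max: float = 1000.0
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError("pressure frames must be (T, rows, cols)")
        if self.frames.shape[1:] != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValidationError(
                f"frame shape {self.frames.shape[1:]} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )
        if np.any(self.frames < 0):
            raise ValidationError("negative pressure values")
        if self.saturated is None:
            self.saturated = np.zeros(self.frames.shape, dtype=bool)
        else:
            self.saturated = np.asarray(self.saturated, dtype=bool)
            if self.saturated.shape != self.frames.shape:
                raise ValidationError("saturated mask shape mismatch")
        if not self.rate > 0:
            raise ValidationError("sampling rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @classmethod
    def from_raw(
        cls,
        geometry: GridGeometry,
        raw: np.ndarray,
        rate: float,
        device: Literal["platform", "insole"],
        p_min: float,
        p_max: float,
        extra_saturated: np.ndarray | None = None,
    ) -> "PressureSequence":
        """Apply the device sensing range to raw kPa values.

        Pressures above ``p_max`` are clipped and flagged as saturated;
        pressures strictly between 0 and ``p_min`` fall below the sensing
        floor and are stored as 0.  Negative input is a validation error.
        """
        raw = np.asarray(raw, dtype=float)
        if np.any(raw < 0):
            raise ValidationError("negative pressure values in input")
        sat = raw > p_max
        if extra_saturated is not None:
            sat = sat | np.asarray(extra_saturated, dtype=bool)
        vals = np.where(raw > p_max, p_max, raw)
        vals = np.where(vals < p_min, 0.0, vals)
        n_sat = int(sat.sum())
        if n_sat:
            logger.warning("%s: %d saturated sensel samples clipped to %.0f kPa",
                           device, n_sat, p_max)
        return cls(geometry, vals, rate, device, p_min, p_max, sat)


@dataclass(frozen=True)
class TrialMeta:
    subject_id: str
    body_mass: float
    shoe: str  # "A" | "B"
    device: str = "platform"  # which stream the downstream results refer to
    trial_index: int = 1

    def __post_init__(self) -> None:
        if not self.body_mass > 0:
            raise ValidationError("body mass must be positive")
        if self.trial_index < 1:
            raise ValidationError("trial index starts at 1")


@dataclass
class Trial:
    """One synchronized walking trial: markers plus both pressure streams.

    All streams share the sampling rate and time origin (the acquisition
    hardware is synchronized; an integer frame offset can be applied at read
    time if a stream was started late).
    """

    meta: TrialMeta
    markers: MarkerSet
    platform: PressureSequence
    insole: PressureSequence
    static_reference: MarkerSet | None = None

    def __post_init__(self) -> None:
        rates = {self.markers.rate, self.platform.rate, self.insole.rate}
        if len(rates) != 1:
            raise ValidationError(f"streams have differing rates: {sorted(rates)}")

    @property
    def rate(self) -> float:
        return self.markers.rate


# ---------------------------------------------------------------------------
# marker I/O
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"rate=([0-9.eE+-]+)\s+units=(\w+)")
_UNIT_SCALE = {"mm": 1e-3, "cm": 1e-2, "m": 1.0}


def read_markers(path: str | Path, format: str = "csv", units: str | None = None) -> MarkerSet:
    """Read marker trajectories from ``csv``, ``trc`` or ``c3d``.

    ``units`` overrides the file's declared units (``mm``/``cm``/``m``);
    coordinates are always returned in meters.  Missing samples become NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_markers_csv(path, units)
    if format == "trc":
        return _read_markers_trc(path, units)
    if format == "c3d":
        return _read_markers_c3d(path, units)
    raise FormatError(f"unknown marker format {format!r} (expected csv, trc or c3d)")


def _read_markers_csv(path: Path, units: str | None) -> MarkerSet:
    with open(path) as fh:
        first = fh.readline()
    rate, file_units = 100.0, "mm"
    if first.startswith("#"):
        m = _HEADER_RE.search(first)
        if m:
            rate, file_units = float(m.group(1)), m.group(2)
    scale = _unit_scale(units or file_units)
    # check the raw header ourselves: pandas silently renames duplicates
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = [c.strip() for c in line.rstrip("\n").split(",")]
                break
        else:
            raise FormatError(f"{path} has no header row")
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ValidationError(f"duplicate marker columns: {dupes}")
    df = pd.read_csv(path, comment="#")
    coord_cols = [c for c in df.columns if c.endswith(("_x", "_y", "_z"))]
    names: list[str] = []
    for c in coord_cols:
        base = c[:-2]
        if base not in names:
            names.append(base)
    T = len(df)
    pos = np.full((T, len(names), 3), np.nan)
    for i, n in enumerate(names):
        for j, ax in enumerate(("x", "y", "z")):
            col = f"{n}_{ax}"
            if col not in df.columns:
                raise ValidationError(f"marker {n!r} missing {ax} column")
            pos[:, i, j] = df[col].to_numpy(dtype=float)
    return MarkerSet(names, pos * scale, rate)


def _read_markers_trc(path: Path, units: str | None) -> MarkerSet:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise FormatError(f"{path} is not a TRC file")
    hdr_keys = lines[1].split("\t")
    hdr_vals = lines[2].split("\t")
    hdr = dict(zip(hdr_keys, hdr_vals))
    rate = float(hdr.get("DataRate", 100.0))
    file_units = hdr.get("Units", "mm")
    scale = _unit_scale(units or file_units)
    name_row = lines[3].split("\t")
    names = [n for n in name_row[2:] if n.strip()]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate marker labels in TRC header")
    data_rows = [ln for ln in lines[5:] if ln.strip()]
    T = len(data_rows)
    pos = np.full((T, len(names), 3), np.nan)
    for t, ln in enumerate(data_rows):
        cells = ln.split("\t")
        vals = cells[2 : 2 + 3 * len(names)]
        for i in range(len(names)):
            trip = vals[3 * i : 3 * i + 3]
            if len(trip) == 3 and all(v.strip() for v in trip):
                pos[t, i, :] = [float(v) for v in trip]
    return MarkerSet(names, pos * scale, rate)


def _read_markers_c3d(path: Path, units: str | None) -> MarkerSet:
    try:
        import ezc3d  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "C3D reading requires the optional 'ezc3d' dependency "
            "(pip install footkinetics[c3d]); convert to TRC or CSV otherwise"
        ) from exc
    c3d = ezc3d.c3d(str(path))  # pragma: no cover
    labels = list(c3d["parameters"]["POINT"]["LABELS"]["value"])
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate marker labels in C3D")
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    file_units = str(c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["mm"])[0])
    scale = _unit_scale(units or file_units)
    pts = np.asarray(c3d["data"]["points"])  # (4, M, T)
    pos = np.transpose(pts[:3], (2, 1, 0)) * scale
    return MarkerSet(labels, pos, rate)


def _unit_scale(units: str) -> float:
    try:
        return _UNIT_SCALE[units.lower()]
    except KeyError:
        raise FormatError(f"unknown length unit {units!r}") from None


def write_markers_csv(markers: MarkerSet, path: str | Path, units: str = "mm") -> Path:
    """Write a MarkerSet to the native wide-CSV format (default mm on disk)."""
    path = Path(path)
    scale = 1.0 / _unit_scale(units)
    cols: dict[str, np.ndarray] = {
        "time": np.arange(markers.frames) / markers.rate
    }
    for i, n in enumerate(markers.names):
        for j, ax in enumerate(("x", "y", "z")):
            cols[f"{n}_{ax}"] = markers.positions[:, i, j] * scale
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# footkinetics-markers rate={markers.rate} units={units}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# pressure I/O
# ---------------------------------------------------------------------------


def read_pressure(path: str | Path, geometry_meta: str | Path) -> PressureSequence:
    """Read a pressure sequence from a long CSV plus its JSON geometry sidecar.

    The CSV lists nonzero sensels only (``frame,row,col,kpa[,sat]``); the
    sidecar carries the grid geometry, device identity, sensing range, rate
    and total frame count.  The device range is (re-)applied on read, so
    reading is idempotent on written files.
    """
    path, geometry_meta = Path(path), Path(geometry_meta)
    with open(geometry_meta) as fh:
        meta = json.load(fh)
    geom = GridGeometry.from_dict(meta["geometry"])
    n_frames = int(meta["n_frames"])
    df = pd.read_csv(path)
    for col in ("frame", "row", "col", "kpa"):
        if col not in df.columns:
            raise FormatError(f"pressure CSV missing column {col!r}")
    raw = np.zeros((n_frames, geom.n_rows, geom.n_cols))
    fr = df["frame"].to_numpy(int)
    rr = df["row"].to_numpy(int)
    cc = df["col"].to_numpy(int)
    if len(fr) and (fr.max() >= n_frames or rr.max() >= geom.n_rows or cc.max() >= geom.n_cols):
        raise ValidationError("pressure CSV indices exceed the declared grid/frame range")
    raw[fr, rr, cc] = df["kpa"].to_numpy(float)
    extra_sat = None
    if "sat" in df.columns:
        extra_sat = np.zeros(raw.shape, dtype=bool)
        extra_sat[fr, rr, cc] = df["sat"].to_numpy(bool)
    return PressureSequence.from_raw(
        geom, raw, float(meta["rate"]), meta["device"],
        float(meta["p_min"]), float(meta["p_max"]), extra_saturated=extra_sat,
    )


def write_pressure(seq: PressureSequence, path: str | Path, geometry_meta: str | Path) -> tuple[Path, Path]:
    """Write a PressureSequence to long CSV + JSON sidecar (inverse of read)."""
    path, geometry_meta = Path(path), Path(geometry_meta)
    fr, rr, cc = np.nonzero((seq.frames > 0) | seq.saturated)
    df = pd.DataFrame(
        {
            "frame": fr,
            "row": rr,
            "col": cc,
            "kpa": seq.frames[fr, rr, cc],
            "sat": seq.saturated[fr, rr, cc].astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "geometry": seq.geometry.to_dict(),
        "rate": seq.rate,
        "device": seq.device,
        "p_min": seq.p_min,
        "p_max": seq.p_max,
        "n_frames": seq.n_frames,
    }
    with open(geometry_meta, "w") as fh:
        json.dump(meta, fh, indent=1)
    return path, geometry_meta


# ---------------------------------------------------------------------------
# results I/O
# ---------------------------------------------------------------------------

PARAM_COLUMNS = ["subject", "shoe", "device", "trial", "joint", "motion", "parameter", "value"]


def write_results(curves: Iterable, params: pd.DataFrame, path: str | Path) -> dict[str, Path]:
    """Write moment/force curves (wide CSV, 101 %-stance rows) and the
    long-format parameter table to ``path``; returns a file manifest.

    Each curve object must expose ``joint``, ``meta`` and the three motion
    components ``dfpf``/``abad``/``inev`` on the 0..100 % stance grid.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    wide: dict[str, np.ndarray] = {"percent": np.arange(101, dtype=float)}
    for cv in curves:
        m = cv.meta
        key = f"{m.subject_id}|{m.shoe}|{m.device}|{m.trial_index}|{cv.joint}"
        for motion in ("dfpf", "abad", "inev"):
            series = np.asarray(getattr(cv, motion), dtype=float)
            if series.shape != (101,):
                raise ValidationError(f"curve {key} {motion} is not on the 101-point grid")
            wide[f"{key}|{motion}"] = series
    curves_path = path / "curves.csv"
    pd.DataFrame(wide).to_csv(curves_path, index=False, float_format="%.10g")

    params_path = path / "parameters.csv"
    if params is None or len(params) == 0:
        logger.warning("parameter table is empty; writing header-only CSV")
        params = pd.DataFrame(columns=PARAM_COLUMNS)
    missing = [c for c in PARAM_COLUMNS if c not in params.columns]
    if missing:
        raise ValidationError(f"parameter table missing columns {missing}")
    params[PARAM_COLUMNS].to_csv(params_path, index=False, float_format="%.12g")
    return {"curves": curves_path, "parameters": params_path}


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject": str, "shoe": str, "device": str})
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"parameter table missing columns {missing}")
    return df
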