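"""Curve descriptors, group curves, the long parameter table, and ICC.

Every force/moment curve is summarized by its extreme values and their
timing on the 0..100 % stance grid: MaxVal/TMax and MinVal/TMin.  Group
curves are the pointwise mean across subjects (trials averaged within each
subject first) with a t-based 95 % confidence ribbon.  Device agreement and
test-retest reliability are quantified with two-way mixed-effects,
mean-rating intraclass correlation coefficients: consistency ICC(3,k)
ignores a systematic device offset, absolute agreement ICC(2,k) penalizes
it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CurveParams",
    "ICCResult",
    "butterworth_lowpass",
    "resample_stance",
    "extract_params",
    "mean_ci_curves",
    "build_parameter_table",
    "icc",
]

STANCE_GRID = np.arange(101, dtype=float)  # % stance stations

_clip_warned: set[tuple[float, float]] = set()  # (fc, fs) pairs already logged


@dataclass(frozen=True)
class CurveParams:
    """Peak descriptors of one curve: extreme values (curve units) and the
    %-stance instants at which they occur (first occurrence on ties)."""

    max_val: float
    t_max: float
    min_val: float
    t_min: float

    def __post_init__(self) -> None:
        if self.max_val < self.min_val:
            raise ValidationError("max_val < min_val")


@dataclass(frozen=True)
class ICCResult:
    """Mean-rating intraclass correlations from a two-way model.

    consistency = ICC(3,k) = (MS_R - MS_E) / MS_R;
    agreement   = ICC(2,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n).
    """

    consistency: float
    agreement: float
    k: int
    n: int
    p_consistency: float
    p_agreement: float


# ---------------------------------------------------------------------------
# filtering and resampling
# ---------------------------------------------------------------------------


def butterworth_lowpass(
    x: np.ndarray, fs: float, fc: float, order: int = 4, axis: int = 0
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass.

    The effective attenuation is the squared single-pass magnitude, so the
    gain at ``fc`` is 0.5 rather than the single-pass -3 dB.  Cutoffs at or
    above the Nyquist frequency are clipped to 0.95 x Nyquist with a logged
    warning (a digital filter cannot realize them).  Reflective (even)
    padding of 3 x order samples is used at both ends; shorter series raise.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    if fc <= 0:
        raise ValidationError("cutoff frequency must be positive")
    if fc >= nyq:
        clipped = 0.95 * nyq
        if (fc, fs) not in _clip_warned:
            _clip_warned.add((fc, fs))
            logger.warning(
                "cutoff %.6g Hz is at/above Nyquist (%.6g Hz); clipping to %.6g Hz",
                fc, nyq, clipped,
            )
        fc = clipped
    padlen = 3 * order
    if x.shape[axis] <= padlen:
        raise ValidationError(
            f"series of length {x.shape[axis]} too short for padlen {padlen}"
        )
    sos = signal.butter(order, fc / nyq, btype="low", output="sos")
    return signal.sosfiltfilt(sos, x, axis=axis, padtype="even", padlen=padlen)


def resample_stance(
    x: np.ndarray, onset: int, offset: int, n: int = 101
) -> np.ndarray:
    """Linearly interpolate a frame-sampled series onto ``n`` equispaced
    stations spanning [onset, offset]; the endpoints are reproduced exactly.

    ``x`` is indexed in frames of the original recording (x[onset] is the
    first stance sample).  Works on (T,) or (T, k) arrays.
    """
    if n < 2:
        raise ValidationError("need at least 2 resampling stations")
    if offset <= onset:
        raise ValidationError("offset must exceed onset")
    x = np.asarray(x, dtype=float)
    stations = onset + (offset - onset) * np.linspace(0.0, 1.0, n)
    frames = np.arange(x.shape[0], dtype=float)
    if x.ndim == 1:
        return np.interp(stations, frames, x)
    return np.stack([np.interp(stations, frames, x[:, j]) for j in range(x.shape[1])], axis=1)


# ---------------------------------------------------------------------------
# curve descriptors
# ---------------------------------------------------------------------------


def extract_params(curve: np.ndarray, grid: np.ndarray | None = None) -> CurveParams:
    """MaxVal/TMax and MinVal/TMin of a %-stance curve.

    Times are the grid stations of the first occurrence of each extreme.
    """
    curve = np.asarray(curve, dtype=float)
    if not np.all(np.isfinite(curve)):
        raise ValidationError("curve contains non-finite values")
    if grid is None:
        if curve.shape[0] == 101:
            grid = STANCE_GRID
        else:
            grid = np.linspace(0.0, 100.0, curve.shape[0])
    i_max = int(np.argmax(curve))  # argmax/argmin take the first occurrence
    i_min = int(np.argmin(curve))
    return CurveParams(
        max_val=float(curve[i_max]),
        t_max=float(grid[i_max]),
        min_val=float(curve[i_min]),
        t_min=float(grid[i_min]),
    )


def mean_ci_curves(
    curves: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and t-based confidence ribbon across subjects.

    ``curves`` is (n_subjects, n_points): one (trial-averaged) curve per
    subject, the sampling unit.  CI = mean +/- t_{n-1, (1+level)/2} * sd/sqrt(n).
    """
    curves = np.asarray(curves, dtype=float)
    n = curves.shape[0]
    if n < 2:
        raise ValidationError("confidence band needs at least 2 subjects")
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1)
    tq = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    half = tq * sd / np.sqrt(n)
    return mean, mean - half, mean + half


# ---------------------------------------------------------------------------
# parameter table
# ---------------------------------------------------------------------------

_DESIGN_COLS = ["subject", "shoe", "device", "trial", "joint", "motion"]


def build_parameter_table(records: pd.DataFrame | list[dict]) -> pd.DataFrame:
    """Assemble the long-format parameter table consumed by external
    mixed-model software.

    Input records carry the design columns (subject, shoe, device, trial,
    joint, motion) plus ``parameter`` and ``value``; one row per design cell
    per parameter.  A complete S subjects x 2 shoes x 2 devices x R trials
    design yields S*2*2*R rows per (joint, motion, parameter).  Duplicate
    design cells raise; rejected trials simply contribute no rows (logged by
    the pipeline that rejected them).
    """
    df = pd.DataFrame(records)
    needed = _DESIGN_COLS + ["parameter", "value"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"parameter records missing columns {missing}")
    key_cols = _DESIGN_COLS + ["parameter"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        raise ValidationError(
            f"duplicate design cells in parameter table: "
            f"{df.loc[dup, key_cols].head().to_dict('records')}"
        )
    return df[needed].sort_values(key_cols, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------


def icc(ratings: np.ndarray) -> ICCResult:
    """Two-way mixed-effects, mean-rating intraclass correlations.

    ``ratings`` is an (n subjects x k measurements) matrix with no missing
    cells.  Mean squares come from the two-way ANOVA decomposition (rows =
    subjects, columns = raters/repetitions); the significance test is
    F = MS_R / MS_E with (n-1, (n-1)(k-1)) degrees of freedom.  Zero
    between-subject variance yields 0 with a warning.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("ratings must be an (n >= 2) x (k >= 2) matrix")
    if not np.all(np.isfinite(x)):
        raise ValidationError("ratings contain missing/non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    if ms_r <= 0:
        logger.warning("zero between-subject variance; ICC undefined, reporting 0")
        return ICCResult(0.0, 0.0, k, n, 1.0, 1.0)

    consistency = (ms_r - ms_e) / ms_r
    agreement = (ms_r - ms_e) / (ms_r + (ms_c - ms_e) / n)
    if ms_e > 0:
        f_obs = ms_r / ms_e
        p = float(stats.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0
    return ICCResult(float(consistency), float(agreement), k, n, p, p)
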