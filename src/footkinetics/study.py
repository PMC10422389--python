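"""Study-level orchestration: designs, parameter tables, device agreement.

Ties the per-trial pipeline together into the full repeated-measures design
(subjects x shoes x devices x trials), producing the long-format parameter
table, per-condition mean +/- CI curves, device peak-difference summaries
and the two ICC layouts (device-pair agreement with k = 2, and per-device
test-retest across the k = 5 repeated trials).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .curve_stats import build_parameter_table, extract_params, icc, mean_ci_curves
from .errors import TrialRejectedError, ValidationError
from .io import Trial
from .kinetics import TrialCurves, moment_curves
from .synthetic import DesignSpec, simulate_design

logger = logging.getLogger(__name__)

__all__ = [
    "DesignResult",
    "trial_parameter_records",
    "process_trial",
    "run_design",
    "device_agreement",
    "test_retest",
    "device_difference",
    "condition_mean_curves",
]

MOTIONS = ("dfpf", "abad", "inev")
#: which descriptor summarizes each motion in comparison reports: the
#: sagittal peak is a maximum (dorsiflexion), the frontal peak a minimum
#: (eversion); transverse (ab/adduction) moments are near zero and excluded.
REPORT_PARAMS = {
    "dfpf": ("max_val", "t_max"),
    "inev": ("min_val", "t_min"),
    "force": ("max_val", "t_max"),
}


def trial_parameter_records(tc: TrialCurves) -> list[dict]:
    """Peak-descriptor rows (long format) for one processed trial."""
    rows: list[dict] = []
    for joint, mc in tc.moments.items():
        m = mc.meta
        base = dict(
            subject=m.subject_id, shoe=m.shoe, device=m.device,
            trial=m.trial_index, joint=joint,
        )
        for motion in MOTIONS:
            p = extract_params(mc.component(motion))
            for name in ("max_val", "t_max", "min_val", "t_min"):
                rows.append({**base, "motion": motion, "parameter": name,
                             "value": getattr(p, name)})
        p = extract_params(tc.forces[joint].force)
        for name in ("max_val", "t_max", "min_val", "t_min"):
            rows.append({**base, "motion": "force", "parameter": name,
                         "value": getattr(p, name)})
    return rows


def process_trial(trial: Trial, device: str, config: PipelineConfig | None = None) -> TrialCurves:
    """Run the full kinetics pipeline for one trial and device."""
    return moment_curves(trial, device, config)


@dataclass
class DesignResult:
    """Everything a processed design yields."""

    params: pd.DataFrame
    curves: list  # MomentCurve, all joints/trials/devices
    rejected: list[str] = field(default_factory=list)

    def rows_per_parameter(self) -> int:
        """Row count of one (joint, motion, parameter) cell of the table."""
        counts = self.params.groupby(["joint", "motion", "parameter"]).size()
        return int(counts.iloc[0]) if len(counts) else 0


def run_design(spec: DesignSpec, config: PipelineConfig | None = None) -> DesignResult:
    """Simulate and process a full design with both devices per walk."""
    records: list[dict] = []
    curves: list = []
    rejected: list[str] = []
    for model, trial_platform, trial_insole in simulate_design(spec):
        for trial, device in ((trial_platform, "platform"), (trial_insole, "insole")):
            tag = (f"{trial.meta.subject_id}/{trial.meta.shoe}/"
                   f"{device}/{trial.meta.trial_index}")
            try:
                tc = process_trial(trial, device, config)
            except TrialRejectedError as exc:
                logger.warning("rejected trial %s: %s", tag, exc)
                rejected.append(tag)
                continue
            records.extend(trial_parameter_records(tc))
            curves.extend(tc.moments.values())
    return DesignResult(build_parameter_table(records), curves, rejected)


def _pivot(params: pd.DataFrame, joint: str, motion: str, parameter: str,
           columns: str, index: list[str]) -> pd.DataFrame:
    sub = params[
        (params["joint"] == joint)
        & (params["motion"] == motion)
        & (params["parameter"] == parameter)
    ]
    wide = sub.pivot_table(index=index, columns=columns, values="value")
    return wide.dropna()


def device_agreement(params: pd.DataFrame) -> pd.DataFrame:
    """Device-pair ICCs: targets are subject x shoe x trial cells, the k = 2
    devices are the raters.  Ab/adduction moments are excluded (their
    amplitudes are negligible throughout stance)."""
    rows = []
    for joint in ("ankle", "MT", "MP"):
        for motion, pnames in REPORT_PARAMS.items():
            for pname in pnames:
                wide = _pivot(params, joint, motion, pname, "device",
                              ["subject", "shoe", "trial"])
                if wide.shape[1] != 2 or wide.shape[0] < 2:
                    raise ValidationError(
                        f"incomplete device pairs for {joint}/{motion}/{pname}"
                    )
                r = icc(wide.to_numpy())
                rows.append(dict(joint=joint, motion=motion, parameter=pname,
                                 consistency=r.consistency, agreement=r.agreement,
                                 n=r.n, k=r.k, p_value=r.p_consistency))
    return pd.DataFrame(rows)


def test_retest(params: pd.DataFrame, device: str) -> pd.DataFrame:
    """Test-retest ICCs for one device: targets are subject x shoe cells,
    the k repeated trials are the ratings (mean-rating form, k = 5 in the
    full design)."""
    sub = params[params["device"] == device]
    rows = []
    for joint in ("ankle", "MT", "MP"):
        for motion, pnames in REPORT_PARAMS.items():
            for pname in pnames:
                wide = _pivot(sub, joint, motion, pname, "trial", ["subject", "shoe"])
                if wide.shape[1] < 2 or wide.shape[0] < 2:
                    raise ValidationError(
                        f"too few trials/subjects for {joint}/{motion}/{pname}"
                    )
                r = icc(wide.to_numpy())
                rows.append(dict(joint=joint, motion=motion, parameter=pname,
                                 device=device, consistency=r.consistency,
                                 agreement=r.agreement, n=r.n, k=r.k,
                                 p_value=r.p_consistency))
    return pd.DataFrame(rows)


def device_difference(params: pd.DataFrame, motion: str = "dfpf",
                      parameter: str = "max_val") -> pd.DataFrame:
    """Per-joint difference of device mean peaks, as a signed percentage of
    the platform mean."""
    rows = []
    for joint in ("ankle", "MT", "MP"):
        sub = params[
            (params["joint"] == joint)
            & (params["motion"] == motion)
            & (params["parameter"] == parameter)
        ]
        means = sub.groupby("device")["value"].mean()
        if "platform" not in means or "insole" not in means:
            raise ValidationError(f"missing a device for {joint}/{motion}/{parameter}")
        plat, ins = means["platform"], means["insole"]
        if plat == 0:
            raise ValidationError("platform mean peak is zero; difference undefined")
        rows.append(dict(joint=joint, motion=motion, parameter=parameter,
                         platform_mean=plat, insole_mean=ins,
                         pct_difference=100.0 * (ins - plat) / plat))
    return pd.DataFrame(rows)


def condition_mean_curves(curves: list, joint: str, motion: str, shoe: str,
                          device: str, level: float = 0.95):
    """Mean and CI ribbon across subjects for one joint/motion/condition
    (trials averaged within subject first)."""
    per_subject: dict[str, list[np.ndarray]] = {}
    for cv in curves:
        m = cv.meta
        if cv.joint == joint and m.shoe == shoe and m.device == device:
            per_subject.setdefault(m.subject_id, []).append(cv.component(motion))
    if len(per_subject) < 2:
        raise ValidationError("need curves from at least 2 subjects")
    subj_means = np.stack([np.mean(v, axis=0) for v in per_subject.values()])
    return mean_ci_curves(subj_means, level)
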