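"""Mean +/- CI figure layouts for moment curves (one panel grid per joint:
motion rows x device columns, both shoe conditions overlaid)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .study import condition_mean_curves

MOTION_LABELS = {"dfpf": "DF/PF", "abad": "AB/AD", "inev": "IN/EV"}


def plot_joint_moments(curves: list, joint: str, path: str | Path,
                       level: float = 0.95) -> Path:
    """Write a mean +/- CI panel figure for one joint, Fig.-style layout:
    rows = motion components, columns = devices, shoes overlaid."""
    devices = sorted({c.meta.device for c in curves if c.joint == joint})
    shoes = sorted({c.meta.shoe for c in curves if c.joint == joint})
    motions = ("dfpf", "abad", "inev")
    fig, axes = plt.subplots(len(motions), len(devices),
                             figsize=(4 * len(devices), 7), sharex=True, squeeze=False)
    x = np.arange(101)
    for i, motion in enumerate(motions):
        for j, device in enumerate(devices):
            ax = axes[i][j]
            for shoe in shoes:
                mean, lo, hi = condition_mean_curves(curves, joint, motion, shoe,
                                                     device, level)
                ax.plot(x, mean, label=f"shoe {shoe}")
                ax.fill_between(x, lo, hi, alpha=0.25)
            if i == 0:
                ax.set_title(device)
            if j == 0:
                ax.set_ylabel(f"{MOTION_LABELS[motion]} (N·m/kg)")
    axes[-1][0].set_xlabel("% stance")
    axes[0][0].legend(fontsize=8)
    fig.suptitle(f"{joint} joint moments")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
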