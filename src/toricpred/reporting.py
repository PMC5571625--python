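"""Results tables and figures.

Tables are tidy CSVs rounded to the declared precision (diopters to 3
decimals, degrees to 2).  Figures: per-stratum double-angle scatter plots
with 0.5 D rings and centroid marker, and a grouped-bar chart of the
proportions of eyes within |0.5| and |1.0| D per modality.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .double_angle import Astigmatism

_ROUND = {"_d": 3, "_deg": 2, "pct_": 2, "icc_": 3, "p_adj": 4}


def round_results(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        if col.endswith("_deg"):
            out[col] = out[col].round(2)
        elif col.endswith("_d"):
            out[col] = out[col].round(3)
        elif col.startswith(("pct_", "icc_", "p_adj")):
            out[col] = out[col].round(4)
    return out


def write_results_csv(df: pd.DataFrame, path: str | Path) -> None:
    round_results(df).to_csv(path, index=False)


def double_angle_plot(
    errors: list[Astigmatism],
    centroid: Optional[Astigmatism],
    title: str,
    path: str | Path,
    ring_step_d: float = 0.5,
) -> None:
    """Double-angle scatter of prediction errors with 0.5 D rings.

    Plot angle is twice the meridional axis, so an error at axis 90°
    appears at plot angle 180°.
    """
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(111, projection="polar")
    if errors:
        theta = [np.radians(2.0 * e.axis) for e in errors]
        r = [e.magnitude for e in errors]
        ax.scatter(theta, r, s=18, alpha=0.6, color="tab:gray", label="per-eye error")
        rmax = max(max(r), ring_step_d)
    else:
        ax.annotate("no data", (0.5, 0.5), xycoords="axes fraction",
                    ha="center", va="center", fontsize=14)
        rmax = ring_step_d
    if centroid is not None:
        ax.scatter([np.radians(2.0 * centroid.axis)], [centroid.magnitude],
                   s=80, color="black", marker="X", zorder=5, label="centroid")
    top = ring_step_d * np.ceil(rmax / ring_step_d)
    ax.set_rmax(top)
    ax.set_rticks(np.arange(ring_step_d, top + ring_step_d / 2, ring_step_d))
    ax.set_xticks(np.radians(np.arange(0, 360, 45)))
    ax.set_xticklabels([f"{d // 2}°" for d in range(0, 360, 45)])
    ax.set_title(f"{title}\n(each ring = {ring_step_d} D; plot angle = 2 × axis)", fontsize=9)
    if errors or centroid is not None:
        ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=7)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def proportions_plot(summary: pd.DataFrame, subgroup: str, timepoint: str, path: str | Path) -> None:
    """Grouped bars: % of eyes with |error| ≤ 0.5 D and ≤ 1.0 D by modality."""
    sel = summary[(summary["subgroup"] == subgroup) & (summary["timepoint"] == timepoint)]
    fig, ax = plt.subplots(figsize=(8, 4))
    if sel.empty:
        ax.annotate("no data", (0.5, 0.5), xycoords="axes fraction",
                    ha="center", va="center", fontsize=14)
    else:
        x = np.arange(len(sel))
        ax.bar(x - 0.2, sel["pct_within_050"], width=0.4, label="within ±0.50 D")
        ax.bar(x + 0.2, sel["pct_within_100"], width=0.4, label="within ±1.00 D")
        ax.set_xticks(x)
        ax.set_xticklabels(sel["modality"], rotation=45, ha="right", fontsize=8)
        ax.set_ylim(0, 105)
        ax.legend(fontsize=8)
    ax.set_ylabel("% of eyes")
    ax.set_title(f"Absolute prediction error within thresholds — {subgroup}, {timepoint}")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
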