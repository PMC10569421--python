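"""Four-panel polar "iris plot" of the leading frequency ratios.

Each panel shows one stratum; every ranked condition is one radial bar whose
length is its frequency ratio, on a per-panel radial scale. Bars are grouped
into sectors by disease group; sectors run clockwise from 12 o'clock in a
fixed clock-face order (bleeding at 12, then cancer, cardiac,
cerebrovascular, endocrine & frailty, gastrointestinal, haematological &
infection, osteoarticular & other, peripheral vascular, renal, respiratory),
with each sector's angular width proportional to its bar count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Patch

from .grouping import GROUP_LABELS, GROUPS, GroupScheme
from .types import ALL_STRATA, StratumKey

#: Clock-face ordering of the 14 groups, from 12 o'clock going clockwise.
CLOCK_ORDER = (
    "bleeding", "cancer", "cardiac", "cerebrovascular", "endocrine",
    "frailty", "gastrointestinal", "haematological", "infection",
    "osteoarticular", "other", "vascular", "renal", "respiratory",
)

_CMAP = plt.get_cmap("tab20")
GROUP_COLORS = {g: _CMAP(i % 20) for i, g in enumerate(CLOCK_ORDER)}


@dataclass
class IrisLayout:
    """Angular layout of one panel: sectors per group plus per-bar angles."""

    sectors: Dict[str, Tuple[float, float]]  # group -> (start_deg, end_deg)
    bar_angles_deg: np.ndarray               # one angle per bar, clockwise
    bar_order: pd.DataFrame                  # bars in drawing order
    max_ratio: float


def layout(results: pd.DataFrame, scheme: Optional[GroupScheme] = None) -> IrisLayout:
    """Compute sector bounds and bar angles for one ranked result table.

    Bars are ordered within each sector by descending frequency ratio; sector
    width is proportional to the group's bar count. Angles are degrees
    clockwise from 12 o'clock.
    """
    if results.empty:
        raise ValueError("cannot lay out an empty result table")
    if "disease_group" not in results.columns:
        raise ValueError("results must carry a disease_group column")
    frames: List[pd.DataFrame] = []
    sectors: Dict[str, Tuple[float, float]] = {}
    n_total = len(results)
    angle = 0.0
    angles: List[float] = []
    for group in CLOCK_ORDER:
        sub = results.loc[results["disease_group"] == group]
        if sub.empty:
            continue
        sub = sub.sort_values(["freq_ratio", "code"],
                              ascending=[False, True], kind="stable")
        width = 360.0 * len(sub) / n_total
        sectors[group] = (angle, angle + width)
        step = width / len(sub)
        angles.extend(angle + (j + 0.5) * step for j in range(len(sub)))
        angle += width
        frames.append(sub)
    order = pd.concat(frames, ignore_index=True)
    return IrisLayout(sectors=sectors,
                      bar_angles_deg=np.asarray(angles),
                      bar_order=order,
                      max_ratio=float(results["freq_ratio"].max()))


PANEL_TITLES = {
    StratumKey("secondary", "pre"): "Hospitalisation, pre-index",
    StratumKey("secondary", "post"): "Hospitalisation, post-index",
    StratumKey("primary", "pre"): "GP consultation, pre-index",
    StratumKey("primary", "post"): "GP consultation, post-index",
}
PANEL_ORDER = (
    StratumKey("secondary", "pre"), StratumKey("secondary", "post"),
    StratumKey("primary", "pre"), StratumKey("primary", "post"),
)


def render(results_by_stratum: Dict[StratumKey, pd.DataFrame],
           out_base, scheme: Optional[GroupScheme] = None,
           log_radius: bool = False) -> Dict[str, Path]:
    """Render the four-panel iris plot to ``<out_base>.svg`` and ``.png``.

    Deterministic for identical inputs: the SVG hash salt is pinned and no
    timestamps are embedded.
    """
    non_empty = [s for s in PANEL_ORDER
                 if s in results_by_stratum and not results_by_stratum[s].empty]
    if not non_empty:
        raise ValueError("no results to plot")

    with plt.rc_context({"svg.hashsalt": "ehrwas-iris",
                         "svg.fonttype": "none"}):
        fig, axes = plt.subplots(2, 2, figsize=(11, 11),
                                 subplot_kw={"projection": "polar"})
        for ax, stratum in zip(axes.ravel(), PANEL_ORDER):
            ax.set_theta_zero_location("N")
            ax.set_theta_direction(-1)  # clockwise
            results = results_by_stratum.get(stratum)
            ax.set_title(PANEL_TITLES[stratum], fontsize=11)
            if results is None or results.empty:
                ax.set_xticks([])
                continue
            lay = layout(results, scheme)
            theta = np.deg2rad(lay.bar_angles_deg)
            radii = lay.bar_order["freq_ratio"].to_numpy(dtype=float)
            if log_radius:
                radii = np.log10(radii + 1.0)
            width = 2 * math.pi / len(radii)
            colors = [GROUP_COLORS[g] for g in lay.bar_order["disease_group"]]
            ax.bar(theta, radii, width=width * 0.9, bottom=0.0, color=colors,
                   linewidth=0)
            ax.set_xticks([])
            ax.tick_params(labelsize=8)
        handles = [Patch(color=GROUP_COLORS[g], label=GROUP_LABELS[g])
                   for g in CLOCK_ORDER]
        fig.legend(handles=handles, loc="lower center", ncol=4, fontsize=8,
                   frameon=False)
        fig.subplots_adjust(bottom=0.16, hspace=0.3)

        out_base = Path(out_base)
        out_base.parent.mkdir(parents=True, exist_ok=True)
        svg_path = out_base.with_suffix(".svg")
        png_path = out_base.with_suffix(".png")
        fig.savefig(svg_path, format="svg", metadata={"Date": None})
        fig.savefig(png_path, format="png", dpi=120)
        plt.close(fig)
    return {"svg": svg_path, "png": png_path}
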