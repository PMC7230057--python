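"""QA report figures: per-acquisition displacement boxes and the
distortion-vs-isocenter-distance profile."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analysis import DistortionStats

__all__ = ["plot_displacement_boxes", "plot_distance_profile"]


def plot_displacement_boxes(
    stats_by_acquisition: dict[str, dict[str, DistortionStats]], path: str | Path
) -> None:
    """Side-by-side box summaries (median, quartile box, '+' at the maximum)
    of both methods' CP displacement distributions per acquisition."""
    names = list(stats_by_acquisition)
    methods = ["template_matching", "registration"]
    fig, ax = plt.subplots(figsize=(1.6 * max(len(names), 2) + 2, 4))
    width = 0.35
    colors = {"template_matching": "tab:blue", "registration": "tab:orange"}
    for mi, method in enumerate(methods):
        pos = np.arange(len(names)) + (mi - 0.5) * width
        data = [np.asarray(stats_by_acquisition[n][method].magnitudes) for n in names]
        bp = ax.boxplot(
            data,
            positions=pos,
            widths=width * 0.9,
            whis=(0, 100),
            showfliers=False,
            patch_artist=True,
            label=method.replace("_", " "),
        )
        for box in bp["boxes"]:
            box.set_facecolor(colors[method])
            box.set_alpha(0.5)
        maxima = [d.max() for d in data]
        ax.plot(pos, maxima, "+", color=colors[method], markersize=10)
    ax.set_xticks(np.arange(len(names)))
    ax.set_xticklabels(names, rotation=30, ha="right")
    ax.set_ylabel("CP displacement (mm)")
    ax.axhline(1.0, ls="--", c="gray", lw=0.8)
    ax.axhline(2.0, ls=":", c="gray", lw=0.8)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_distance_profile(profile: pd.DataFrame, path: str | Path) -> None:
    """Displacement magnitude vs distance from the isocenter with binned means."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(profile["radius_mm"], profile["magnitude_mm"], ".", ms=3, alpha=0.5)
    binned = profile.drop_duplicates("bin_mm").sort_values("bin_mm")
    ax.plot(binned["bin_mm"], binned["bin_mean_mm"], "o-", c="tab:red", label="10 mm bin mean")
    ax.set_xlabel("distance from isocenter (mm)")
    ax.set_ylabel("CP displacement (mm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
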