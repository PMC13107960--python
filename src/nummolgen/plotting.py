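"""Plots for functional-group profiles and property distributions.

Bar charts of per-group frequency ratio and average count across named
molecule collections, and overlaid histograms of per-molecule properties
(docking score, QED, SA) — the figures typically used to compare a generated
set against its reference corpus.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import FGProfile


def plot_fg_profiles(
    profiles: Mapping[str, FGProfile],
    group_names: Sequence[str],
    path: str | Path,
    groups: Sequence[str] | None = None,
) -> Path:
    """Grouped bars of frequency ratio (top) and average count (bottom).

    ``groups`` selects a subset of functional-group names to display
    (default: the six with the highest frequency in the first collection —
    minor groups compress the axis to illegibility).
    """
    names = list(group_names)
    first = next(iter(profiles.values()))
    if groups is None:
        order = np.argsort(first.frequency_ratio)[::-1][:6]
    else:
        order = [names.index(g) for g in groups]
    shown = [names[i] for i in order]
    short = [n.split(".")[-1] for n in shown]

    fig, (ax_freq, ax_avg) = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    width = 0.8 / max(len(profiles), 1)
    x = np.arange(len(order))
    for k, (label, prof) in enumerate(profiles.items()):
        offset = (k - (len(profiles) - 1) / 2) * width
        ax_freq.bar(x + offset, prof.frequency_ratio[order], width, label=label)
        ax_avg.bar(x + offset, prof.average_count[order], width, label=label)
    ax_freq.set_ylabel("Frequency ratio")
    ax_freq.set_ylim(0, 1.05)
    ax_avg.set_ylabel("Average number")
    ax_avg.set_xticks(x)
    ax_avg.set_xticklabels(short, rotation=30, ha="right")
    ax_freq.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_property_distributions(
    values_by_set: Mapping[str, Mapping[str, Sequence[float]]],
    path: str | Path,
) -> Path:
    """Overlaid histograms, one panel per property.

    ``values_by_set`` maps collection name -> {property name -> values};
    every collection should provide the same property keys.
    """
    properties = list(next(iter(values_by_set.values())).keys())
    fig, axes = plt.subplots(1, len(properties), figsize=(4 * len(properties), 3.2))
    if len(properties) == 1:
        axes = [axes]
    for ax, prop in zip(axes, properties):
        for label, by_prop in values_by_set.items():
            vals = np.asarray(by_prop[prop], dtype=float)
            ax.hist(vals, bins=20, alpha=0.5, label=label, density=True)
        ax.set_xlabel(prop)
        ax.set_ylabel("density")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
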