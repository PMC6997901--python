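"""Plots: mean-configuration scatter (with group ellipses) and violin pairs.

Styling is deliberately minimal; the two group colours are taken from a
colorblind-safe pair.  Unicode phone labels are data — axes and annotations
render them directly; pass an ``alias`` mapping when the output medium
cannot.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse

from .geometry import GeometryStat
from .pcoa import AggregateConfiguration

GROUP_COLORS = ("#0072B2", "#D55E00")  # colorblind-safe blue / vermillion


def _covariance_ellipse(points: np.ndarray, n_sd: float = 2.0, **kwargs) -> Ellipse:
    """n_sd-sigma covariance ellipse of a 2-D point cloud."""
    mean = points.mean(axis=0)
    cov = np.cov(points.T)
    vals, vecs = np.linalg.eigh(cov)
    angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
    width, height = 2.0 * n_sd * np.sqrt(np.maximum(vals[::-1], 0.0))
    return Ellipse(mean, width, height, angle=angle, **kwargs)


def plot_mds(
    config: AggregateConfiguration,
    groups: Mapping[str, Sequence[str]] | None = None,
    comparisons: Sequence[tuple[str, str]] | None = None,
    alias: Mapping[str, str] | None = None,
    ax=None,
):
    """Scatter of mean object coordinates, with optional group ellipses.

    Parameters
    ----------
    config
        Aggregate configuration (mean coordinates + per-participant clouds).
    groups
        Optional ``{group name: [labels]}`` partition; each group gets a
        colour and a 2-sigma covariance ellipse computed from the
        per-participant coordinates of its members.
    comparisons
        Optional label pairs to join with a line (the distances under test).
    alias
        Optional label -> display-string map for media without IPA glyphs.
    """
    if config.mean_coordinates.shape[1] != 2:
        raise ValueError("plot_mds supports 2-D configurations only")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    alias = alias or {}
    labels = list(config.labels)
    mean = config.mean_coordinates
    pos = {lab: mean[i] for i, lab in enumerate(labels)}

    label_color = {}
    if groups:
        for (gname, members), color in zip(groups.items(), GROUP_COLORS):
            for m in members:
                label_color[m] = color
            member_idx = [labels.index(m) for m in members]
            cloud = np.concatenate(
                [m[member_idx] for m in config.per_participant_coordinates]
            )
            ax.add_patch(
                _covariance_ellipse(
                    cloud, facecolor=color, alpha=0.12, edgecolor=color, label=gname
                )
            )

    if comparisons:
        for a, b in comparisons:
            (x1, y1), (x2, y2) = pos[a], pos[b]
            ax.plot([x1, x2], [y1, y2], color="0.5", lw=1.0, zorder=1)

    for lab in labels:
        x, y = pos[lab]
        ax.scatter(x, y, color=label_color.get(lab, "0.2"), s=35, zorder=3)
        ax.annotate(
            alias.get(lab, lab), (x, y), textcoords="offset points",
            xytext=(6, 6), fontsize=11,
        )
    ax.set_xlabel("dimension 1 (p.u.)")
    ax.set_ylabel("dimension 2 (p.u.)")
    ax.axhline(0, color="0.9", lw=0.8, zorder=0)
    ax.axvline(0, color="0.9", lw=0.8, zorder=0)
    if groups:
        ax.legend(frameon=False, fontsize=9)
    ax.figure.tight_layout()
    return ax


def plot_violin(
    stats_a: Sequence[GeometryStat | float],
    stats_b: Sequence[GeometryStat | float],
    labels: tuple[str, str] | None = None,
    ax=None,
):
    """Violin pair with individual per-participant points overlaid."""
    def values(stats):
        return np.asarray(
            [s.value if isinstance(s, GeometryStat) else float(s) for s in stats]
        )

    a, b = values(stats_a), values(stats_b)
    kinds = {
        s.kind for s in list(stats_a) + list(stats_b) if isinstance(s, GeometryStat)
    }
    unit = "p.u.²" if kinds == {"area"} else "p.u."
    if labels is None:
        def default_label(stats, fallback):
            for s in stats:
                if isinstance(s, GeometryStat):
                    return "-".join(s.members)
            return fallback
        labels = (default_label(stats_a, "A"), default_label(stats_b, "B"))

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    parts = ax.violinplot([a, b], positions=[1, 2], showmeans=True, showextrema=False)
    for body, color in zip(parts["bodies"], GROUP_COLORS):
        body.set_facecolor(color)
        body.set_alpha(0.4)
    rng = np.random.default_rng(0)  # display jitter only
    for pos, vals, color in ((1, a, GROUP_COLORS[0]), (2, b, GROUP_COLORS[1])):
        ax.scatter(
            pos + rng.uniform(-0.06, 0.06, len(vals)), vals,
            s=12, color=color, alpha=0.7, zorder=3,
        )
    ax.set_xticks([1, 2], labels)
    kind = "area" if kinds == {"area"} else "distance"
    ax.set_ylabel(f"{kind} ({unit})")
    ax.figure.tight_layout()
    return ax
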