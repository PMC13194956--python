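"""Plots: profile with marked peaks, ROI overlay, raincloud per region."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_profile", "plot_roi_overlay", "raincloud"]


def plot_profile(profile, peaks=None, ax=None):
    """Axial reflectivity profile with the detected ELM/EZ peaks marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(profile.row_depths, profile.values, color="black", lw=1.2)
    if peaks is not None:
        for row, val, name in (
            (peaks.elm_row, peaks.elm_intensity, "ELM"),
            (peaks.ez_row, peaks.ez_intensity, "EZ"),
        ):
            depth = row * profile.axial_scale
            ax.plot([depth], [val], "o", ms=5)
            ax.annotate(name, (depth, val), textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("depth from ROI top (µm)")
    ax.set_ylabel("mean grey value")
    ax.set_ylim(bottom=0)
    return ax


def plot_roi_overlay(scan, rois, ax=None):
    """B-scan with the measurement windows drawn on top."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.imshow(scan.pixels, cmap="gray", vmin=0, vmax=255, aspect="auto")
    for roi in rois:
        color = {"planned": "yellow", "shifted": "orange", "excluded": "red"}[roi.status]
        top = roi.top_row if roi.top_row is not None else 0
        ax.add_patch(
            Rectangle(
                (roi.columns[0], top),
                roi.width_px,
                roi.height_px,
                fill=False,
                edgecolor=color,
                lw=1.0,
            )
        )
        ax.annotate(
            roi.location.code,
            (roi.centre_col, max(top - 4, 4)),
            color=color,
            ha="center",
            fontsize=7,
        )
    ax.set_xlabel("lateral (px)")
    ax.set_ylabel("axial (px)")
    return ax


def raincloud(eye_table, region, group_col="dr_stage", ax=None, seed=0):
    """Half-violin + box + jittered raw points of a region per DR group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(seed)
    groups = [g for g in ("noDR", "NPDR", "PDR") if (eye_table[group_col] == g).any()]
    data = [
        eye_table.loc[eye_table[group_col] == g, region].dropna().to_numpy()
        for g in groups
    ]
    parts = ax.violinplot(
        data, positions=range(len(groups)), showextrema=False, side="high", widths=0.8
    )
    for pc in parts["bodies"]:
        pc.set_alpha(0.4)
    ax.boxplot(
        data,
        positions=range(len(groups)),
        widths=0.12,
        showfliers=False,
        medianprops={"color": "black"},
    )
    for i, vals in enumerate(data):
        x = i - 0.22 + rng.uniform(-0.06, 0.06, size=len(vals))
        ax.plot(x, vals, ".", ms=3, alpha=0.6)
    ax.set_xticks(range(len(groups)), groups)
    ax.set_ylabel(f"rEZR ({region})")
    return ax
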