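"""Overlay and heat-map figures for consensus analyses."""

from __future__ import annotations

import io
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .matching import MatchResult
from .metrics import SweepGrid
from .roi import ROISet


def plot_match_overlay(
    set_a: ROISet,
    set_b: ROISet,
    match: MatchResult,
    path: str | Path | None = None,
) -> bytes:
    """Overlay of both detector outputs with matched (consensus) cells marked.

    Returns the PNG bytes; also writes them to ``path`` when given.
    """
    fig, ax = plt.subplots(figsize=(6, 6))
    ca, cb = set_a.coords, set_b.coords
    if len(ca):
        ax.scatter(ca[:, 0], ca[:, 1], s=18, marker="o", facecolors="none",
                   edgecolors="tab:blue", label=set_a.source or "set A")
    if len(cb):
        ax.scatter(cb[:, 0], cb[:, 1], s=18, marker="s", facecolors="none",
                   edgecolors="tab:orange", label=set_b.source or "set B")
    cc = match.consensus.coords
    if len(cc):
        ax.scatter(cc[:, 0], cc[:, 1], s=30, marker="x", c="tab:green",
                   label=f"consensus (n={len(cc)})")
    ax.set_xlim(0, set_a.field_width)
    ax.set_ylim(set_a.field_height, 0)  # image convention: y grows downward
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"consensus match, threshold {match.threshold:g} px")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_aspect("equal")
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110)
    plt.close(fig)
    png = buf.getvalue()
    if path is not None:
        Path(path).write_bytes(png)
    return png


def plot_sweep_heatmap(grid: SweepGrid, path: str | Path | None = None) -> bytes:
    """Heat map of a 2-D parameter sweep (rows = first axis)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(grid.values, aspect="auto", origin="upper", cmap="viridis")
    ax.set_xticks(range(len(grid.axis_b_values)))
    ax.set_xticklabels([f"{v:g}" if isinstance(v, float) else str(v)
                        for v in grid.axis_b_values], rotation=90, fontsize=7)
    ax.set_yticks(range(len(grid.axis_a_values)))
    ax.set_yticklabels([f"{v:g}" if isinstance(v, float) else str(v)
                        for v in grid.axis_a_values], fontsize=7)
    ax.set_xlabel(grid.axis_b_name)
    ax.set_ylabel(grid.axis_a_name)
    ax.set_title(grid.metric_name)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110)
    plt.close(fig)
    png = buf.getvalue()
    if path is not None:
        Path(path).write_bytes(png)
    return png
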