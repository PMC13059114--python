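"""Figure-style outputs: trajectory maps, vector maps, hue-vs-time curves.

All plots color detections by FUCCI phase (G1 red, S gold, G2/M green)
and render headlessly via the Agg backend.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .tracking import PhaseCall, Trajectory

PHASE_COLORS = {
    PhaseCall.G1: "#d62728",
    PhaseCall.S: "#e6b800",
    PhaseCall.G2M: "#2ca02c",
    PhaseCall.UNKNOWN: "#999999",
}


def trajectory_map(
    trajectories: Sequence[Trajectory], path: str | Path
) -> None:
    """Per-cell paths with phase-colored points, y axis image-down."""
    fig, ax = plt.subplots(figsize=(6, 6))
    for tr in trajectories:
        pts = tr.points
        ax.plot(pts[:, 0], pts[:, 1], "-", lw=0.6, color="#bbbbbb", zorder=1)
        for d in tr.detections:
            ax.plot(d.x, d.y, ".", ms=3, color=PHASE_COLORS[d.phase], zorder=2)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title("cell trajectories (G1 red / S gold / G2M green)")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def vector_map(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    """Start-to-end displacement arrows, colored by dominant phase."""
    from .metrics import dominant_phase

    fig, ax = plt.subplots(figsize=(6, 6))
    for tr in trajectories:
        pts = tr.points
        color = PHASE_COLORS[dominant_phase(tr)]
        ax.annotate(
            "",
            xy=tuple(pts[-1]),
            xytext=tuple(pts[0]),
            arrowprops=dict(arrowstyle="->", color=color, lw=1.0),
        )
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title("displacement vectors")
    ax.autoscale_view()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def hue_curves(
    trajectories: Sequence[Trajectory],
    path: str | Path,
    max_cells: int = 8,
) -> None:
    """Per-cell hue over time; rising hue marks G1 -> S -> G2/M entry."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for tr in trajectories[:max_cells]:
        ax.plot(tr.frames, [d.hue for d in tr.detections], "-o", ms=3,
                label=f"cell {tr.cell_id}")
    ax.set_xlabel("frame")
    ax.set_ylabel("hue (half-angle deg)")
    ax.set_ylim(-2, 62)
    ax.legend(fontsize=7, ncol=2)
    fig.savefig(path, dpi=150)
    plt.close(fig)
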