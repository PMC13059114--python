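"""Migration analytics: per-cell metrics and cohort summaries.

The central motility surrogate is the convex hull area (CHA): the area of
the smallest convex polygon containing every point of one cell's
trajectory, which captures the territory a wandering cell explores more
comprehensively than linear distance alone. Cells are ranked by CHA and
the phase composition of top-N vs bottom-N cohorts compared via the
G2/M : G1 ratio, mirroring the top-50 / bottom-50 analysis used on
assembloid invasion assays. A classical (equal-variance, two-tailed)
two-sample t-test supports two-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import MultiPoint

from .errors import MetricError
from .segmentation import AssembloidMask
from .tracking import PhaseCall, Trajectory


def path_length(traj: Trajectory, pixel_size_um: float = 1.0) -> float:
    """Cumulative Euclidean path length in microns."""
    pts = traj.points
    if len(pts) < 2:
        raise MetricError("path length undefined for fewer than 2 detections")
    steps = np.diff(pts, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum() * pixel_size_um)


def net_displacement(traj: Trajectory, pixel_size_um: float = 1.0) -> float:
    """Straight-line start-to-end displacement in microns."""
    pts = traj.points
    if len(pts) < 2:
        raise MetricError("net displacement undefined for fewer than 2 detections")
    return float(np.hypot(*(pts[-1] - pts[0])) * pixel_size_um)


def cha(traj: Trajectory | np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Convex hull area of the trajectory's points in square microns.

    Fewer than 3 points, or collinear points, give area 0.
    """
    pts = traj.points if isinstance(traj, Trajectory) else np.asarray(traj, float)
    if len(pts) == 0:
        raise MetricError("CHA undefined for an empty trajectory")
    if len(pts) < 3:
        return 0.0
    return float(MultiPoint([tuple(p) for p in pts]).convex_hull.area
                 * pixel_size_um**2)


def dominant_phase(traj: Trajectory) -> PhaseCall:
    """Modal phase over a track's detections, ignoring UNKNOWN.

    Ties break toward the phase occurring later in the trajectory; a track
    with no informative calls is UNKNOWN.
    """
    counts: dict[PhaseCall, int] = {}
    last_seen: dict[PhaseCall, int] = {}
    for i, ph in enumerate(traj.phases):
        if ph is PhaseCall.UNKNOWN:
            continue
        counts[ph] = counts.get(ph, 0) + 1
        last_seen[ph] = i
    if not counts:
        return PhaseCall.UNKNOWN
    best = max(counts.values())
    tied = [ph for ph, c in counts.items() if c == best]
    return max(tied, key=lambda ph: last_seen[ph])


@dataclass
class MigrationMetrics:
    cell_id: int
    n_points: int
    path_length_um: float
    net_displacement_um: float
    cha_um2: float
    dominant_phase: PhaseCall


def compute_metrics(
    trajectories: Sequence[Trajectory], pixel_size_um: float = 1.0
) -> list[MigrationMetrics]:
    out = []
    for tr in trajectories:
        out.append(
            MigrationMetrics(
                cell_id=tr.cell_id,
                n_points=len(tr.detections),
                path_length_um=path_length(tr, pixel_size_um),
                net_displacement_um=net_displacement(tr, pixel_size_um),
                cha_um2=cha(tr, pixel_size_um),
                dominant_phase=dominant_phase(tr),
            )
        )
    return out


@dataclass
class CohortSummary:
    """Top-N / bottom-N CHA-ranked cohorts and their phase composition.

    ``g2m_to_g1_ratio`` is None ("missing") when the set has no G1 cell;
    ``overlapping`` flags cohorts smaller than 2N, where the two sets
    cannot be disjoint.
    """

    n: int
    top_ids: list[int]
    bottom_ids: list[int]
    top_counts: dict[str, int]
    bottom_counts: dict[str, int]
    top_ratio: float | None
    bottom_ratio: float | None
    overlapping: bool


def _phase_counts(metrics: Sequence[MigrationMetrics]) -> dict[str, int]:
    counts = {p.value: 0 for p in PhaseCall}
    for m in metrics:
        counts[m.dominant_phase.value] += 1
    return counts


def _ratio(counts: dict[str, int]) -> float | None:
    if counts["G1"] == 0:
        return None
    return counts["G2M"] / counts["G1"]


def rank_and_ratio(
    metrics: Sequence[MigrationMetrics], n: int = 50
) -> CohortSummary:
    """Rank cells by CHA (descending, ties by cell_id) and compare cohorts.

    UNKNOWN-phase cells stay in the rankings but never enter the
    G2/M : G1 ratios.
    """
    if not metrics:
        raise MetricError("rank_and_ratio needs at least one cell")
    ranked = sorted(metrics, key=lambda m: (-m.cha_um2, m.cell_id))
    k = min(n, len(ranked))
    top = ranked[:k]
    bottom = ranked[-k:]
    top_counts = _phase_counts(top)
    bottom_counts = _phase_counts(bottom)
    return CohortSummary(
        n=k,
        top_ids=[m.cell_id for m in top],
        bottom_ids=[m.cell_id for m in bottom],
        top_counts=top_counts,
        bottom_counts=bottom_counts,
        top_ratio=_ratio(top_counts),
        bottom_ratio=_ratio(bottom_counts),
        overlapping=len(ranked) < 2 * n,
    )


def infiltration_percentage(
    organoid_mask: AssembloidMask | np.ndarray,
    tumor_channel: np.ndarray,
    threshold: float,
) -> float:
    """Percent of the organoid area covered by thresholded tumor signal.

    100 x (tumor pixels above threshold inside the organoid mask) /
    (organoid mask pixels).
    """
    mask = (
        organoid_mask.mask
        if isinstance(organoid_mask, AssembloidMask)
        else np.asarray(organoid_mask, bool)
    )
    tumor = np.asarray(tumor_channel, float)
    if mask.shape != tumor.shape:
        raise MetricError("organoid mask and tumor channel shapes differ")
    total = int(mask.sum())
    if total == 0:
        raise MetricError("empty organoid mask")
    inside = int(((tumor > threshold) & mask).sum())
    return 100.0 * inside / total


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> dict[str, float]:
    """Classical (equal-variance) two-sample t-test, two-tailed.

    Degenerate input — zero variance in both groups with equal means —
    returns t = 0, p = 1 by convention.
    """
    from scipy import stats

    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise MetricError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return dict(mean_a=float(a.mean()), mean_b=float(b.mean()),
                    t_statistic=0.0, p_value=1.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return dict(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        t_statistic=float(t), p_value=float(p),
    )


def metrics_table(metrics: Sequence[MigrationMetrics]):
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                cell_id=m.cell_id, n_points=m.n_points,
                path_length_um=m.path_length_um,
                net_displacement_um=m.net_displacement_um,
                cha_um2=m.cha_um2, dominant_phase=m.dominant_phase.value,
            )
            for m in metrics
        ],
        columns=[
            "cell_id", "n_points", "path_length_um",
            "net_displacement_um", "cha_um2", "dominant_phase",
        ],
    )


def summary_table(summary: CohortSummary):
    import pandas as pd

    def row(which: str, counts: dict[str, int], ratio: float | None):
        return dict(
            set=which, n=summary.n,
            g1=counts["G1"], s=counts["S"], g2m=counts["G2M"],
            unknown=counts["UNKNOWN"],
            g2m_to_g1_ratio=np.nan if ratio is None else ratio,
            overlapping=summary.overlapping,
        )

    return pd.DataFrame(
        [
            row("top", summary.top_counts, summary.top_ratio),
            row("bottom", summary.bottom_counts, summary.bottom_ratio),
        ]
    )
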