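"""FUCCI cell detection, hue-based phase calling, and track linking.

FUCCI reporters color a nucleus red in G1, yellow in S, and green in G2/M.
After registration the assembloid is motion-fixed, so nuclei can be
detected per frame (multi-scale Laplacian-of-Gaussian blobs on the
red + green sum image), given a hue from their mean red/green intensities,
classified into a cycle phase by hue thresholds, and linked across frames
into per-cell trajectories by greedy nearest-pair association with gap
closing.

Hue lives on the half-angle [0, 180) scale (the 0-360 color wheel divided
by two), so the occupied red-to-green range is [0, 60]: pure red -> 0,
equal red/green (yellow) -> 30, pure green -> 60.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from skimage.feature import blob_log

from .errors import ConfigError, MetricError


class PhaseCall(str, Enum):
    G1 = "G1"
    S = "S"
    G2M = "G2M"
    UNKNOWN = "UNKNOWN"


@dataclass
class CellDetection:
    t: int
    x: float
    y: float
    red_i: float
    green_i: float
    hue: float  # [0, 180); NaN when both channels are below floor
    area_px: float
    phase: PhaseCall = PhaseCall.UNKNOWN


@dataclass
class Trajectory:
    cell_id: int
    detections: list[CellDetection] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.t for d in self.detections])

    @property
    def points(self) -> np.ndarray:
        return np.array([[d.x, d.y] for d in self.detections])

    @property
    def phases(self) -> list[PhaseCall]:
        return [d.phase for d in self.detections]


def hue_of(red_i: float, green_i: float) -> float:
    """Half-angle hue of the color (R=red_i, G=green_i, B=0).

    Standard HSV hue with a zero blue channel, divided by two:
    pure red -> 0, equal red/green -> 30, pure green -> 60.
    """
    if red_i < 0 or green_i < 0:
        raise ValueError("intensities must be non-negative")
    if red_i + green_i == 0:
        raise MetricError("hue undefined for zero red and green intensity")
    if red_i >= green_i:
        h = 60.0 * green_i / red_i  # max = R: H = 60 * (G - B) / (max - min)
    else:
        h = 60.0 * (2.0 - red_i / green_i)  # max = G: H = 60 * (2 + (B-R)/delta)
    return h / 2.0


@dataclass
class PhaseThresholds:
    """Hue cut points on the occupied [0, 60] range: G1 | S | G2M."""

    t_g1s: float = 25.0
    t_sg2m: float = 45.0

    def __post_init__(self) -> None:
        if not (0 < self.t_g1s < self.t_sg2m < 60):
            raise ConfigError(
                f"phase thresholds must satisfy 0 < t_g1s < t_sg2m < 60; "
                f"got ({self.t_g1s}, {self.t_sg2m})"
            )


def classify_phase(
    hue: float,
    red_i: float,
    green_i: float,
    thresholds: PhaseThresholds | None = None,
    intensity_floor: float = 0.0,
) -> PhaseCall:
    """Map a detection's hue to a cycle phase; dim detections are UNKNOWN."""
    thr = thresholds or PhaseThresholds()
    if red_i < intensity_floor and green_i < intensity_floor:
        return PhaseCall.UNKNOWN
    if hue < thr.t_g1s:
        return PhaseCall.G1
    if hue < thr.t_sg2m:
        return PhaseCall.S
    return PhaseCall.G2M


@dataclass
class DetectionParams:
    min_intensity: float = 0.0  # summed mean intensity floor; 0 = auto (5% of max)
    sigma_min_px: float = 2.0
    sigma_max_px: float = 5.0
    n_sigma: int = 4
    min_area_px: float = 4.0
    log_threshold: float = 0.02  # LoG response floor, fraction of dynamic range


def detect_cells(
    red: np.ndarray,
    green: np.ndarray,
    t: int = 0,
    params: DetectionParams | None = None,
    thresholds: PhaseThresholds | None = None,
    intensity_floor: float | None = None,
) -> list[CellDetection]:
    """Detect fluorescent nuclei in one registered frame.

    Local maxima of a multi-scale Laplacian-of-Gaussian response on the
    red + green sum image; positions are refined to subpixel by an
    intensity-weighted centroid in a 3x3 neighborhood, and per-channel
    intensities averaged over a disc of the detected scale.
    """
    p = params or DetectionParams()
    red = np.asarray(red, float)
    green = np.asarray(green, float)
    total = red + green
    dyn = float(total.max())
    if dyn <= 0:
        return []
    norm = total / dyn
    blobs = blob_log(
        norm,
        min_sigma=p.sigma_min_px,
        max_sigma=p.sigma_max_px,
        num_sigma=p.n_sigma,
        threshold=p.log_threshold,
    )
    min_int = p.min_intensity if p.min_intensity > 0 else 0.05 * dyn
    floor = intensity_floor if intensity_floor is not None else 0.05 * dyn / 2
    h, w = total.shape
    yy, xx = np.mgrid[0:h, 0:w]
    out: list[CellDetection] = []
    for by, bx, sigma in blobs:
        iy, ix = int(round(by)), int(round(bx))
        # subpixel: intensity-weighted centroid over a 3x3 window
        y0, y1 = max(0, iy - 1), min(h, iy + 2)
        x0, x1 = max(0, ix - 1), min(w, ix + 2)
        win = total[y0:y1, x0:x1]
        wsum = win.sum()
        if wsum > 0:
            cy = float((np.arange(y0, y1)[:, None] * win).sum() / wsum)
            cx = float((np.arange(x0, x1)[None, :] * win).sum() / wsum)
        else:
            cy, cx = float(by), float(bx)
        r_foot = max(1.0, np.sqrt(2.0) * sigma)
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_foot**2
        area = float(disc.sum())
        if area < p.min_area_px:
            continue
        red_i = float(red[disc].mean())
        green_i = float(green[disc].mean())
        if red_i + green_i < min_int:
            continue
        hue = hue_of(max(red_i, 0.0), max(green_i, 0.0)) \
            if red_i + green_i > 0 else float("nan")
        phase = classify_phase(hue, red_i, green_i, thresholds, floor)
        out.append(
            CellDetection(
                t=t, x=cx, y=cy, red_i=red_i, green_i=green_i,
                hue=hue, area_px=area, phase=phase,
            )
        )
    return out


@dataclass
class LinkParams:
    max_link_dist_px: float = 30.0  # per-frame motion budget (~39 um at 1.3 um/px)
    max_gap: int = 2


def link_tracks(
    detections: Sequence[CellDetection], params: LinkParams | None = None
) -> list[Trajectory]:
    """Greedy globally-nearest-pair linking with gap closing.

    Per frame, candidate (track, detection) pairs within the distance
    budget are sorted by distance and matched one-to-one; a track may
    bridge up to ``max_gap`` missing frames with its budget scaled by the
    gap length. Tracks with fewer than 2 detections are discarded.
    """
    p = params or LinkParams()
    by_frame: dict[int, list[CellDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.t, []).append(d)
    if not by_frame:
        return []
    tracks: list[list[CellDetection]] = []
    active: list[int] = []  # indices into tracks
    for t in sorted(by_frame):
        dets = by_frame[t]
        active = [
            i for i in active if t - tracks[i][-1].t <= p.max_gap + 1
        ]
        pairs = []
        for i in active:
            last = tracks[i][-1]
            gap = t - last.t
            budget = p.max_link_dist_px * gap
            for j, d in enumerate(dets):
                dist = np.hypot(d.x - last.x, d.y - last.y)
                if dist <= budget:
                    pairs.append((dist, i, j))
        pairs.sort(key=lambda z: z[0])
        used_i: set[int] = set()
        used_j: set[int] = set()
        for dist, i, j in pairs:
            if i in used_i or j in used_j:
                continue
            tracks[i].append(dets[j])
            used_i.add(i)
            used_j.add(j)
        for j, d in enumerate(dets):
            if j not in used_j:
                tracks.append([d])
                active.append(len(tracks) - 1)
    out = [
        Trajectory(cell_id=k, detections=tr)
        for k, tr in enumerate(tr for tr in tracks if len(tr) >= 2)
    ]
    return out


def detections_table(detections: Sequence[CellDetection]):
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                t=d.t, x=d.x, y=d.y, red_i=d.red_i, green_i=d.green_i,
                hue=d.hue, area_px=d.area_px, phase=d.phase.value,
            )
            for d in detections
        ],
        columns=["t", "x", "y", "red_i", "green_i", "hue", "area_px", "phase"],
    )


def trajectories_table(trajectories: Sequence[Trajectory]):
    import pandas as pd

    rows = []
    for tr in trajectories:
        for d in tr.detections:
            rows.append(
                dict(cell_id=tr.cell_id, t=d.t, x=d.x, y=d.y,
                     hue=d.hue, phase=d.phase.value)
            )
    return pd.DataFrame(rows, columns=["cell_id", "t", "x", "y", "hue", "phase"])
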