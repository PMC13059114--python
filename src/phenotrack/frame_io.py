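"""Image-sequence and table I/O.

A time-lapse is held in memory as a :class:`FrameStack`: an ordered
``(T, C, H, W)`` array of per-timepoint channel images plus the physical
calibration (``pixel_size_um``, ``frame_interval_min``) and a mapping from
channel *roles* (``brightfield``, ``red``, ``green``) to channel indices.
All downstream analysis works in floating point; integer imagery is
preserved bit-exactly through load/save round trips.

Supported containers: multi-page TIFF (page order t-major then channel)
and directories of lexicographically ordered per-frame images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError, FormatError, InputError

KNOWN_ROLES = ("brightfield", "red", "green")


@dataclass
class FrameStack:
    """Ordered multi-channel image sequence with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, C, H, W)
        Per-timepoint channel images, non-negative intensities.
    channel_roles : mapping of str to int
        Role ("brightfield" | "red" | "green") to channel index.
    pixel_size_um : float
        Microns per pixel (> 0).
    frame_interval_min : float
        Minutes between consecutive frames (> 0).
    """

    frames: np.ndarray
    channel_roles: Mapping[str, int]
    pixel_size_um: float = 1.0
    frame_interval_min: float = 60.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise FormatError(
                f"frames must be (T, C, H, W); got shape {self.frames.shape}"
            )
        if self.n_frames < 2:
            raise FormatError("a FrameStack needs at least 2 frames")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        if self.frame_interval_min <= 0:
            raise ConfigError("frame_interval_min must be > 0")
        for role, idx in self.channel_roles.items():
            if role not in KNOWN_ROLES:
                raise ConfigError(
                    f"unknown channel role {role!r}; expected one of {KNOWN_ROLES}"
                )
            if not 0 <= idx < self.n_channels:
                raise ConfigError(
                    f"channel index {idx} for role {role!r} out of range "
                    f"(stack has {self.n_channels} channels)"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[1]

    @property
    def height(self) -> int:
        return self.frames.shape[2]

    @property
    def width(self) -> int:
        return self.frames.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """All frames of one role, shape (T, H, W)."""
        if role not in self.channel_roles:
            raise ConfigError(f"stack has no channel with role {role!r}")
        return self.frames[:, self.channel_roles[role]]

    def minutes(self) -> np.ndarray:
        """Physical time of each frame in minutes from frame 0."""
        return np.arange(self.n_frames) * float(self.frame_interval_min)


@dataclass
class GrayFrame:
    """Single grayscale working image with provenance."""

    pixels: np.ndarray
    timepoint: int = 0
    recipe: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FormatError("GrayFrame must be 2D")


def load_stack(
    path: str | os.PathLike,
    channel_map: Mapping[str, int],
    calibration: Mapping[str, float] | None = None,
) -> FrameStack:
    """Read a multi-page TIFF or an image directory into a FrameStack.

    For a multi-page TIFF the page order must be t-major then channel
    (t0c0, t0c1, ..., t1c0, ...) and ``n_channels`` is inferred from
    ``channel_map`` (max index + 1). A directory is read as one grayscale
    or multi-channel image per frame, in lexicographic filename order.
    """
    calibration = dict(calibration or {})
    if "red" not in channel_map or "green" not in channel_map:
        raise ConfigError("channel_map must cover roles 'red' and 'green'")
    p = Path(path)
    if not p.exists():
        raise InputError(f"input path does not exist: {p}")

    if p.is_dir():
        files = sorted(
            f for f in p.iterdir()
            if f.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise InputError(f"no image files found in directory {p}")
        import imageio.v3 as iio

        planes = [np.asarray(iio.imread(f)) for f in files]
        shapes = {pl.shape for pl in planes}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent frame shapes in {p}: {sorted(shapes)}")
        arr = np.stack(planes)  # (T, H, W) or (T, H, W, C)
        if arr.ndim == 3:
            arr = arr[:, None]
        elif arr.ndim == 4:
            arr = np.moveaxis(arr, -1, 1)
        else:
            raise FormatError(f"unsupported image dimensionality {arr.ndim - 1}")
    else:
        try:
            with tifffile.TiffFile(p) as tf:
                pages = [pg.asarray() for pg in tf.pages]
        except Exception as exc:  # tifffile raises several low-level types
            raise FormatError(f"cannot read TIFF {p}: {exc}") from exc
        if not pages:
            raise FormatError(f"TIFF has no pages: {p}")
        shapes = {pg.shape for pg in pages}
        if len(shapes) != 1 or pages[0].ndim != 2:
            raise FormatError(f"inconsistent or non-2D page shapes in {p}")
        n_channels = max(channel_map.values()) + 1
        if len(pages) % n_channels != 0:
            raise FormatError(
                f"page count {len(pages)} is not a multiple of the "
                f"{n_channels} channels implied by channel_map"
            )
        arr = np.stack(pages).reshape(
            len(pages) // n_channels, n_channels, *pages[0].shape
        )

    return FrameStack(frames=arr, channel_roles=dict(channel_map), **calibration)


def save_stack(stack: FrameStack, path: str | os.PathLike) -> None:
    """Write a FrameStack as a multi-page TIFF, t-major then channel."""
    pages = stack.frames.reshape(-1, stack.height, stack.width)
    tifffile.imwrite(os.fspath(path), pages)


def project_z(
    volume: np.ndarray,
    channel_roles: Mapping[str, int],
    calibration: Mapping[str, float] | None = None,
) -> FrameStack:
    """Maximum-intensity z-projection of a (T, Z, C, H, W) volume.

    Collapses each timepoint's z-stack per channel so that the brightest
    plane of every structure survives, then wraps the result as a
    FrameStack.
    """
    volume = np.asarray(volume)
    if volume.ndim != 5:
        raise InputError(f"volume must be (T, Z, C, H, W); got {volume.shape}")
    if volume.shape[1] == 0:
        raise InputError("volume has an empty z dimension")
    projected = volume.max(axis=1)
    return FrameStack(
        frames=projected, channel_roles=dict(channel_roles), **dict(calibration or {})
    )


def to_gray(
    frame_channels: np.ndarray,
    channel_roles: Mapping[str, int],
    recipe: str | Mapping[str, float] = "brightfield",
    timepoint: int = 0,
) -> GrayFrame:
    """Convert one frame's channels to a working grayscale image.

    ``recipe`` is either a single role name (that channel, unchanged) or a
    role->weight mapping; weighted sums are normalized by the weight total.
    """
    frame_channels = np.asarray(frame_channels, dtype=np.float64)
    if isinstance(recipe, str):
        if recipe not in channel_roles:
            raise ConfigError(f"recipe names absent channel role {recipe!r}")
        return GrayFrame(frame_channels[channel_roles[recipe]], timepoint, recipe)
    weights = dict(recipe)
    if any(w < 0 for w in weights.values()):
        raise ConfigError("grayscale recipe weights must be non-negative")
    total = sum(weights.values())
    if total == 0:
        raise ConfigError("grayscale recipe weights are all zero")
    out = np.zeros(frame_channels.shape[1:], dtype=np.float64)
    for role, w in weights.items():
        if role not in channel_roles:
            raise ConfigError(f"recipe names absent channel role {role!r}")
        out += w * frame_channels[channel_roles[role]]
    label = "+".join(f"{w:g}*{r}" for r, w in sorted(weights.items()))
    return GrayFrame(out / total, timepoint, label)


# ---------------------------------------------------------------------------
# result tables

TABLE_COLUMNS = {
    "transforms": [
        "t", "dx_px", "dy_px", "theta_deg",
        "cum_dx_px", "cum_dy_px", "cum_theta_deg",
        "iterations", "converged", "residual",
    ],
    "detections": ["t", "x", "y", "red_i", "green_i", "hue", "area_px", "phase"],
    "trajectories": ["cell_id", "t", "x", "y", "hue", "phase"],
    "metrics": [
        "cell_id", "n_points", "path_length_um",
        "net_displacement_um", "cha_um2", "dominant_phase",
    ],
    "summary": None,  # free-form
}


def write_tables(
    results: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike
) -> dict[str, Path]:
    """Write each result table as ``<kind>.csv`` under out_dir.

    Known kinds get their documented column order; unknown kinds are
    written as-is. Floats are serialized at full precision so a re-read
    reproduces the values exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for kind, df in results.items():
        cols = TABLE_COLUMNS.get(kind)
        if cols is not None:
            df = df.reindex(columns=cols) if len(df) else pd.DataFrame(columns=cols)
        dest = out / f"{kind}.csv"
        df.to_csv(dest, index=False)
        written[kind] = dest
    return written


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
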