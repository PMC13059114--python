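"""Ground-truthed synthetic assembloid videos.

The generator emulates the test conditions of a free-floating FUCCI
assembloid assay: a bright, band-pass-textured disc (the assembloid body,
imaged brightfield-like) undergoing scripted per-frame rigid motion, with
fluorescent nuclei embedded inside it that follow scripted trajectories in
disc coordinates and scripted cell-cycle phase schedules (G1: red channel,
S: red + green, G2/M: green channel). Additive Gaussian noise models
camera noise. Every random draw comes from the scene seed, so a (params,
seed) pair renders a byte-identical stack.

Scenes carry their ground truth — per-pair rigid transforms, per-cell
tracks and phases — and provide evaluators that score a registration
result or a set of extracted trajectories against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError, InputError
from .frame_io import FrameStack
from .registration import RegistrationResult, RigidTransform, _rot
from .tracking import PhaseCall, Trajectory

DYNAMIC_RANGE = 60000  # uint16 rendering scale


@dataclass
class SceneParams:
    """Knobs of the synthetic assay (defaults = the standard test scene)."""

    n_frames: int = 30
    height: int = 512
    width: int = 512
    disc_radius_px: float = 150.0
    growth_rate_px: float = 0.0  # radius increase per frame (rigid stress test)
    texture_scale_px: tuple[float, float] = (8.0, 32.0)  # band-pass feature band
    t_max_px: float = 6.0  # per-pair |dx|, |dy| bound
    r_max_deg: float = 4.0  # per-pair |dtheta| bound
    n_cells: int = 40
    spot_sigma_px: float = 2.5
    spot_peak: float = 0.6  # fraction of dynamic range
    step_sigma_px: float = 2.0  # per-frame cell step scale
    motion_mode: str = "brownian"  # brownian | directed | phase_coupled
    phase_mode: str = "cycling"  # cycling | static
    g2m_speed_factor: float = 2.0  # phase_coupled: G2M step scale vs G1
    cell_margin_frac: float = 0.85  # cells confined to this fraction of radius
    cell_min_sep_px: float = 16.0  # initial nucleus spacing (hard core 10 px)
    noise_sigma_frac: float = 0.02  # additive noise, fraction of dynamic range

    def __post_init__(self) -> None:
        if self.motion_mode not in ("brownian", "directed", "phase_coupled"):
            raise ConfigError(f"unknown motion_mode {self.motion_mode!r}")
        if self.phase_mode not in ("cycling", "static"):
            raise ConfigError(f"unknown phase_mode {self.phase_mode!r}")
        margin = min(self.height, self.width) / 2 - self.t_max_px
        if self.disc_radius_px >= margin:
            raise ConfigError(
                "infeasible geometry: disc_radius_px must be < frame/2 - t_max"
            )


_HARD_CORE_PX = 10.0  # nuclei exclude each other's footprint


@dataclass
class SyntheticScene:
    """A fully scripted scene: parameters, motion, tracks, and phases."""

    params: SceneParams
    seed: int
    dxy: np.ndarray  # (n_frames-1, 2) per-pair translation of the disc center
    dtheta: np.ndarray  # (n_frames-1,) per-pair rotation, degrees
    cell_tracks: np.ndarray  # (n_cells, n_frames, 2) disc coordinates
    cell_phases: np.ndarray  # (n_cells, n_frames) of {"G1","S","G2M"}
    texture: np.ndarray  # frame-0 brightfield image (float, 0..1)

    @property
    def center0(self) -> tuple[float, float]:
        return ((self.params.width - 1) / 2.0, (self.params.height - 1) / 2.0)

    @property
    def cum_theta(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.dtheta)])

    @property
    def cum_center(self) -> np.ndarray:
        c0 = np.asarray(self.center0)
        return np.vstack([c0, c0 + np.cumsum(self.dxy, axis=0)])

    # -- ground truth in the registration module's conventions ------------

    def truth_cumulative(
        self, recenter_shift: tuple[int, int] = (0, 0)
    ) -> list[RigidTransform]:
        """Motion of frame-0 content to each frame, pivot at frame-0 center.

        ``recenter_shift`` is the integer shift register_stack applied to
        every frame before estimating (zero when the disc starts centered).
        """
        s = np.asarray(recenter_shift, float)
        c0 = np.asarray(self.center0) + s
        out = []
        for t in range(self.params.n_frames):
            phi = self.cum_theta[t]
            ct = self.cum_center[t] + s
            d = _rot(-phi) @ (ct - c0)
            out.append(RigidTransform(d[0], d[1], phi, tuple(c0)))
        return out

    def truth_pairs(
        self, recenter_shift: tuple[int, int] = (0, 0)
    ) -> list[RigidTransform]:
        """Per-pair residual transforms matching RegistrationResult.pair_transforms."""
        cum = self.truth_cumulative(recenter_shift)
        pairs = [RigidTransform(center=cum[0].center)]
        for t in range(1, len(cum)):
            pairs.append(cum[t].then(cum[t - 1].inverse()))
        return pairs

    def registered_cell_positions(
        self, recenter_shift: tuple[int, int] = (0, 0)
    ) -> np.ndarray:
        """(n_cells, n_frames, 2) truth positions in the frame-0 pose."""
        c0 = np.asarray(self.center0) + np.asarray(recenter_shift, float)
        return self.cell_tracks + c0[None, None, :]

    def world_cell_positions(self) -> np.ndarray:
        """(n_cells, n_frames, 2) positions in the raw (unregistered) frames."""
        out = np.empty_like(self.cell_tracks)
        for t in range(self.params.n_frames):
            r = _rot(self.cum_theta[t])
            out[:, t, :] = self.cell_tracks[:, t, :] @ r.T + self.cum_center[t]
        return out


def generate_scene(params: SceneParams | None = None, seed: int = 0) -> SyntheticScene:
    """Draw a reproducible scene from (params, seed)."""
    p = params or SceneParams()
    rng = np.random.default_rng([int(seed), 0])

    # disc motion: bounded random walk; steps that would push the disc
    # within t_max of the border are reflected
    margin = min(p.height, p.width) / 2.0 - p.disc_radius_px - p.t_max_px
    c0 = np.array([(p.width - 1) / 2.0, (p.height - 1) / 2.0])
    dxy = np.empty((p.n_frames - 1, 2))
    dtheta = rng.uniform(-p.r_max_deg, p.r_max_deg, p.n_frames - 1)
    pos = c0.copy()
    for t in range(p.n_frames - 1):
        step = rng.uniform(-p.t_max_px, p.t_max_px, 2)
        for ax in range(2):
            if abs(pos[ax] + step[ax] - c0[ax]) > margin:
                step[ax] = -step[ax]
        pos += step
        dxy[t] = step

    phases = _draw_phases(p, rng)
    tracks = _draw_tracks(p, phases, rng)
    texture = _draw_texture(p, rng)
    return SyntheticScene(
        params=p, seed=int(seed), dxy=dxy, dtheta=dtheta,
        cell_tracks=tracks, cell_phases=phases, texture=texture,
    )


def _draw_phases(p: SceneParams, rng: np.random.Generator) -> np.ndarray:
    phases = np.empty((p.n_cells, p.n_frames), dtype=object)
    if p.phase_mode == "static":
        # half G1, half G2/M — a clean two-population contrast design
        for i in range(p.n_cells):
            phases[i, :] = "G1" if i % 2 == 0 else "G2M"
        return phases
    for i in range(p.n_cells):
        # cyclic schedule with realistic dwell times (hourly frames):
        # long G1, short S, intermediate G2/M
        seq: list[str] = []
        while len(seq) < 2 * p.n_frames:
            seq += ["G1"] * int(rng.integers(8, 15))
            seq += ["S"] * int(rng.integers(3, 6))
            seq += ["G2M"] * int(rng.integers(4, 9))
        offset = int(rng.integers(0, len(seq) - p.n_frames))
        phases[i, :] = seq[offset : offset + p.n_frames]
    return phases


def _speed_factor(p: SceneParams, phase: str) -> float:
    if p.motion_mode != "phase_coupled":
        return 1.0
    if phase == "G2M":
        return p.g2m_speed_factor
    if phase == "S":
        return 0.5 * (1.0 + p.g2m_speed_factor)
    return 1.0


def _draw_tracks(
    p: SceneParams, phases: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    r_lim = p.cell_margin_frac * p.disc_radius_px
    # initial positions: uniform in the allowed disc with a minimum spacing
    pts: list[np.ndarray] = []
    while len(pts) < p.n_cells:
        cand = rng.uniform(-r_lim, r_lim, 2)
        if np.hypot(*cand) > r_lim:
            continue
        if all(np.hypot(*(cand - q)) >= p.cell_min_sep_px for q in pts):
            pts.append(cand)
    tracks = np.empty((p.n_cells, p.n_frames, 2))
    if p.n_cells == 0:
        return tracks
    tracks[:, 0, :] = np.array(pts)
    for t in range(1, p.n_frames):
        current = tracks[:, t - 1, :].copy()
        for i in range(p.n_cells):
            sf = _speed_factor(p, phases[i, t - 1])
            for _ in range(8):
                if p.motion_mode == "directed":
                    r = np.hypot(*current[i])
                    outward = current[i] / r if r > 1e-9 else np.zeros(2)
                    step = (
                        p.step_sigma_px * outward
                        + rng.normal(0.0, 0.5 * p.step_sigma_px, 2)
                    )
                else:
                    step = rng.normal(0.0, sf * p.step_sigma_px, 2)
                cand = current[i] + step
                if np.hypot(*cand) > r_lim:
                    continue
                others = np.delete(current, i, axis=0)
                if (np.hypot(others[:, 0] - cand[0],
                             others[:, 1] - cand[1]) < _HARD_CORE_PX).any():
                    continue
                current[i] = cand
                break
            # all proposals rejected -> the nucleus holds its position
        tracks[:, t, :] = current
    return tracks


def _draw_texture(p: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Frame-0 brightfield: band-pass noise texture on a bright disc."""
    noise = rng.standard_normal((p.height, p.width))
    lo, hi = p.texture_scale_px
    band = ndimage.gaussian_filter(noise, lo / 2.0) - ndimage.gaussian_filter(
        noise, hi / 2.0
    )
    band = (band - band.mean()) / (band.std() + 1e-12)
    tex = 0.65 + 0.15 * np.clip(band, -2.0, 2.0)  # 0.35 .. 0.95
    yy, xx = np.mgrid[0 : p.height, 0 : p.width]
    cx, cy = (p.width - 1) / 2.0, (p.height - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy)
    edge = np.clip((p.disc_radius_px - r) / 2.0 + 0.5, 0.0, 1.0)  # soft rim
    return tex * edge


def _warp_texture(scene: SyntheticScene, t: int) -> np.ndarray:
    """Frame t brightfield: the frame-0 texture under the scripted motion."""
    p = scene.params
    if t == 0 and p.growth_rate_px == 0.0:
        return scene.texture.copy()
    phi = scene.cum_theta[t]
    ct = scene.cum_center[t]
    c0 = np.asarray(scene.center0)
    scale = 1.0
    if p.growth_rate_px:
        scale = p.disc_radius_px / (p.disc_radius_px + p.growth_rate_px * t)
    # sample coordinate: x_src = scale * R(-phi) (q - c_t) + c0
    m_xy = scale * _rot(-phi)
    m_rc = m_xy[::-1, ::-1]
    offset = c0[::-1] - m_rc @ ct[::-1]
    return ndimage.affine_transform(
        scene.texture, m_rc, offset=offset, order=1, mode="constant", cval=0.0
    )


_PHASE_RGB = {"G1": (1.0, 0.0), "S": (1.0, 1.0), "G2M": (0.0, 1.0)}


def render_stack(scene: SyntheticScene) -> FrameStack:
    """Render the scene to a 3-channel uint16 FrameStack.

    Channels: 0 = brightfield (textured disc), 1 = red, 2 = green.
    Nuclei are 2D Gaussian spots whose red/green weights follow the FUCCI
    convention (G1 red, S red+green, G2/M green); additive Gaussian noise
    is applied per channel and the result quantized to uint16.
    """
    p = scene.params
    noise_rng = np.random.default_rng([scene.seed, 1])
    world = scene.world_cell_positions()
    frames = np.empty((p.n_frames, 3, p.height, p.width), dtype=np.uint16)
    half = int(np.ceil(4.0 * p.spot_sigma_px))
    for t in range(p.n_frames):
        bf = _warp_texture(scene, t)
        red = np.zeros_like(bf)
        green = np.zeros_like(bf)
        for i in range(p.n_cells):
            wx, wy = world[i, t]
            rw, gw = _PHASE_RGB[scene.cell_phases[i, t]]
            x0, x1 = int(np.floor(wx)) - half, int(np.floor(wx)) + half + 2
            y0, y1 = int(np.floor(wy)) - half, int(np.floor(wy)) + half + 2
            x0, x1 = max(0, x0), min(p.width, x1)
            y0, y1 = max(0, y0), min(p.height, y1)
            if x0 >= x1 or y0 >= y1:
                continue
            ys = np.arange(y0, y1)[:, None]
            xs = np.arange(x0, x1)[None, :]
            spot = p.spot_peak * np.exp(
                -((xs - wx) ** 2 + (ys - wy) ** 2) / (2.0 * p.spot_sigma_px**2)
            )
            red[y0:y1, x0:x1] += rw * spot
            green[y0:y1, x0:x1] += gw * spot
        chans = np.stack([bf, red, green])
        if p.noise_sigma_frac > 0:
            chans = chans + noise_rng.normal(
                0.0, p.noise_sigma_frac, chans.shape
            )
        frames[t] = np.clip(chans * DYNAMIC_RANGE, 0, 65535).astype(np.uint16)
    return FrameStack(
        frames=frames,
        channel_roles={"brightfield": 0, "red": 1, "green": 2},
        pixel_size_um=1.3,
        frame_interval_min=60.0,
    )


# ---------------------------------------------------------------------------
# evaluation against ground truth


def evaluate_registration(
    result: RegistrationResult, scene: SyntheticScene
) -> dict:
    """Per-pair (estimate - truth) errors and their summary medians."""
    truth = scene.truth_pairs(result.recenter_shift)
    est = result.pair_transforms
    if len(est) != len(truth):
        raise InputError(
            f"frame-count mismatch: {len(est)} estimates vs {len(truth)} truths"
        )
    dx_err = np.array([e.dx_px - t.dx_px for e, t in zip(est, truth)])[1:]
    dy_err = np.array([e.dy_px - t.dy_px for e, t in zip(est, truth)])[1:]
    th_err = np.array(
        [
            (e.theta_deg - t.theta_deg + 180.0) % 360.0 - 180.0
            for e, t in zip(est, truth)
        ]
    )[1:]
    cum_truth = scene.truth_cumulative(result.recenter_shift)
    cum_th_err = np.array(
        [
            (e.theta_deg - t.theta_deg + 180.0) % 360.0 - 180.0
            for e, t in zip(result.cumulative, cum_truth)
        ]
    )
    return dict(
        dx_err=dx_err,
        dy_err=dy_err,
        theta_err=th_err,
        cum_theta_err=cum_th_err,
        median_abs_dx=float(np.median(np.abs(dx_err))),
        median_abs_dy=float(np.median(np.abs(dy_err))),
        median_abs_theta=float(np.median(np.abs(th_err))),
    )


def evaluate_tracking(
    trajectories: list[Trajectory],
    scene: SyntheticScene,
    recenter_shift: tuple[int, int] = (0, 0),
    match_radius_px: float = 3.0,
) -> dict:
    """Score trajectories against scripted tracks by greedy truth matching.

    recall = matched truth points / truth points; precision likewise over
    reported detections; link accuracy = fraction of consecutive matched
    truth pairs carried by one trajectory identity; phase accuracy over
    matched detections.
    """
    p = scene.params
    truth_pos = scene.registered_cell_positions(recenter_shift)
    # matches[(cell, t)] = (traj_id, detection)
    matches: dict[tuple[int, int], tuple[int, object]] = {}
    n_dets = 0
    for t in range(p.n_frames):
        cands = []
        for tr in trajectories:
            for d in tr.detections:
                if d.t == t:
                    n_dets += 1
                    for i in range(p.n_cells):
                        dist = np.hypot(
                            d.x - truth_pos[i, t, 0], d.y - truth_pos[i, t, 1]
                        )
                        if dist <= match_radius_px:
                            cands.append((dist, i, tr.cell_id, d))
        cands.sort(key=lambda z: z[0])
        used_truth: set[int] = set()
        used_det: set[int] = set()
        for dist, i, tid, d in cands:
            if i in used_truth or id(d) in used_det:
                continue
            matches[(i, t)] = (tid, d)
            used_truth.add(i)
            used_det.add(id(d))
    n_truth = p.n_cells * p.n_frames
    recall = len(matches) / n_truth
    precision = len(matches) / n_dets if n_dets else 0.0
    n_pairs = n_links = 0
    for i in range(p.n_cells):
        for t in range(p.n_frames - 1):
            a = matches.get((i, t))
            b = matches.get((i, t + 1))
            if a is not None and b is not None:
                n_pairs += 1
                n_links += a[0] == b[0]
    link_acc = n_links / n_pairs if n_pairs else 0.0
    n_ph = n_ph_ok = 0
    for (i, t), (_, d) in matches.items():
        n_ph += 1
        n_ph_ok += d.phase.value == scene.cell_phases[i, t]
    phase_acc = n_ph_ok / n_ph if n_ph else 0.0
    return dict(
        recall=recall,
        precision=precision,
        link_accuracy=link_acc,
        phase_accuracy=phase_acc,
        n_matched=len(matches),
        n_truth=n_truth,
    )


def truth_tables(scene: SyntheticScene):
    """truth_transforms.csv / truth_tracks.csv companions for a render."""
    import pandas as pd

    pairs = scene.truth_pairs()
    tf = pd.DataFrame(
        dict(
            t=np.arange(scene.params.n_frames),
            dx_px=[p.dx_px for p in pairs],
            dy_px=[p.dy_px for p in pairs],
            theta_deg=[p.theta_deg for p in pairs],
        )
    )
    pos = scene.registered_cell_positions()
    rows = []
    for i in range(scene.params.n_cells):
        for t in range(scene.params.n_frames):
            rows.append(
                dict(cell_id=i, t=t, x=pos[i, t, 0], y=pos[i, t, 1],
                     phase=scene.cell_phases[i, t])
            )
    return tf, pd.DataFrame(rows)
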