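"""Rigid frame-to-frame registration of free-floating assembloids.

Free-floating assembloids translate and rotate between timepoints, which
scrambles the apparent trajectories of the cells inside them. This module
estimates a per-frame-pair rigid correction (dx, dy, theta) and composes
the corrections back to frame 0 so the assembloid stays centered and
orientation-fixed across the stack.

Translation is estimated by template matching: >= 6 high-variance patches
from inside the assembloid hull are matched against the moving frame with
the zero-normalized cross-correlation score, and the per-template
displacements are combined by a median. Rotation is estimated after polar
unwrapping both frames about the assembloid center — a rotation of the
source becomes a horizontal (angular) shift of the polar image — by
matching up to 40 rectangular regions of the reference polar image against
the moving one with the normalized squared-difference score. Both scores
are computed from their explicit formulas:

    zncc(T, I)   = sum((T - mean T)(I - mean I))
                   / sqrt(sum (T - mean T)^2 * sum (I - mean I)^2)
    nsd(T, I)    = sum((T - I)^2) / sqrt(sum T^2 * sum I^2)

The translation-rotation estimate is refined iteratively with a damped
update (typically converging in well under the iteration cap), and every
match is restricted to the assembloid hull so background never votes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .errors import RegistrationError
from .frame_io import GrayFrame
from .segmentation import AssembloidMask

_EXACT_EPS = 1e-9  # peak treated as an exact integer match; no subpixel fit


# ---------------------------------------------------------------------------
# rigid transforms


def _rot(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


@dataclass
class RigidTransform:
    """Translate-then-rotate rigid motion about a fixed pivot.

    Applied to a point p (x, y):  T(p) = R(theta) (p + d - c) + c
    where d = (dx_px, dy_px) and c = ``center``. theta_deg > 0 rotates
    x-axis toward y-axis (clockwise on screen with y pointing down).
    """

    dx_px: float = 0.0
    dy_px: float = 0.0
    theta_deg: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        # normalize to (-180, 180]
        t = (float(self.theta_deg) + 180.0) % 360.0 - 180.0
        self.theta_deg = 180.0 if t == -180.0 else t

    @property
    def d(self) -> np.ndarray:
        return np.array([self.dx_px, self.dy_px], float)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        c = np.asarray(self.center, float)
        out = (p + self.d - c) @ _rot(self.theta_deg).T + c
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "RigidTransform":
        dinv = -(_rot(self.theta_deg) @ self.d)
        return RigidTransform(dinv[0], dinv[1], -self.theta_deg, self.center)

    def then(self, other: "RigidTransform") -> "RigidTransform":
        """Composition: apply ``self`` first, then ``other`` (other o self)."""
        d = self.d + _rot(self.theta_deg).T @ other.d
        return RigidTransform(
            d[0], d[1], self.theta_deg + other.theta_deg, self.center
        )

    def is_identity(self, tol_px: float = 0.0, tol_deg: float = 0.0) -> bool:
        return (
            abs(self.dx_px) <= tol_px
            and abs(self.dy_px) <= tol_px
            and abs(self.theta_deg) <= tol_deg
        )


def apply_transform(
    frame_channels: np.ndarray, transform: RigidTransform
) -> np.ndarray:
    """Warp channels so their content moves by ``transform``.

    Bilinear interpolation; pixels pulled from outside the frame are zero.
    Identity transforms are passed through bit-exactly.
    """
    frame_channels = np.asarray(frame_channels)
    if transform.is_identity():
        return frame_channels.copy()
    # output(q) = input(T^{-1}(q));  T^{-1}(q) = R(-th)(q - c) + c - d
    inv_rot_xy = _rot(-transform.theta_deg)
    # switch to (row, col) = (y, x) index order for ndimage
    m = inv_rot_xy[::-1, ::-1]
    c_rc = np.asarray(transform.center, float)[::-1]
    d_rc = transform.d[::-1]
    offset = c_rc - m @ c_rc - d_rc
    single = frame_channels.ndim == 2
    stackin = frame_channels[None] if single else frame_channels
    out = np.empty_like(stackin, dtype=float)
    for i, ch in enumerate(stackin):
        out[i] = ndimage.affine_transform(
            ch.astype(float), m, offset=offset, order=1, mode="constant", cval=0.0
        )
    return out[0] if single else out


# ---------------------------------------------------------------------------
# template selection and translation matching


@dataclass
class Template:
    """A reference patch: top-left corner (x0, y0) plus its pixel block."""

    x0: int
    y0: int
    pixels: np.ndarray

    @property
    def center(self) -> tuple[float, float]:
        h, w = self.pixels.shape
        return (self.x0 + (w - 1) / 2, self.y0 + (h - 1) / 2)


def select_templates(
    gray: GrayFrame | np.ndarray,
    mask: AssembloidMask,
    n_templates: int = 6,
    template_size_px: int = 64,
) -> list[Template]:
    """Pick the n highest-local-variance patches inside the eroded hull.

    Patch centers are pairwise >= template_size_px apart and lie far enough
    inside the hull that the whole patch is on assembloid. A constant
    (zero-variance) texture triggers a warning, not an error.
    """
    img = gray.pixels if isinstance(gray, GrayFrame) else np.asarray(gray, float)
    half = template_size_px // 2
    dist = ndimage.distance_transform_edt(mask.mask)
    # inset by the patch half-diagonal so whole patches sit on assembloid
    allowed = dist >= half * np.sqrt(2.0) + 1
    if not allowed.any():
        raise RegistrationError(
            f"assembloid too small for {template_size_px} px templates; "
            "reduce template_size_px or n_templates"
        )
    mean = ndimage.uniform_filter(img, template_size_px)
    var = ndimage.uniform_filter(img**2, template_size_px) - mean**2
    var = np.where(allowed, var, -np.inf)
    order = np.argsort(var, axis=None)[::-1]
    ys, xs = np.unravel_index(order, var.shape)
    chosen: list[tuple[int, int]] = []
    for y, x in zip(ys, xs):
        if not np.isfinite(var[y, x]):
            break
        if all(np.hypot(x - cx, y - cy) >= template_size_px for cx, cy in chosen):
            chosen.append((x, y))
            if len(chosen) == n_templates:
                break
    if len(chosen) < n_templates:
        raise RegistrationError(
            f"only {len(chosen)} of {n_templates} requested templates fit inside "
            "the assembloid; reduce n_templates or template_size_px"
        )
    out = []
    for cx, cy in chosen:
        x0, y0 = cx - half, cy - half
        patch = img[y0 : y0 + template_size_px, x0 : x0 + template_size_px]
        if patch.std() == 0:
            warnings.warn("zero-variance template selected (flat texture)")
        out.append(Template(x0=x0, y0=y0, pixels=patch.copy()))
    return out


def _quadratic_peak(sm1: float, s0: float, sp1: float) -> float:
    """Subpixel offset of a parabola through three equispaced samples."""
    denom = sm1 - 2.0 * s0 + sp1
    if denom == 0:
        return 0.0
    off = 0.5 * (sm1 - sp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_translation(
    ref: GrayFrame | np.ndarray,
    mov: GrayFrame | np.ndarray,
    templates: Sequence[Template],
    search_window_px: int = 48,
    score_floor: float = 0.5,
) -> tuple[float, float, float]:
    """Median per-template displacement of mov relative to ref.

    Each template is matched inside a bounded window of mov with the
    zero-normalized cross-correlation score; the best-score location is
    refined to subpixel by a separable quadratic fit around the peak
    (skipped when the peak is an exact match, so integer shifts of
    identical imagery are recovered exactly). Templates whose peak score
    falls below ``score_floor`` do not vote.

    Returns (dx, dy, quality) where quality is the median peak score of
    the voting templates.
    """
    if len(templates) < 1:
        raise RegistrationError("no templates supplied")
    img = mov.pixels if isinstance(mov, GrayFrame) else np.asarray(mov, float)
    h, w = img.shape
    dxs, dys, scores = [], [], []
    for t in templates:
        th, tw = t.pixels.shape
        y0 = max(0, t.y0 - search_window_px)
        x0 = max(0, t.x0 - search_window_px)
        y1 = min(h, t.y0 + th + search_window_px)
        x1 = min(w, t.x0 + tw + search_window_px)
        crop = img[y0:y1, x0:x1]
        if crop.shape[0] < th or crop.shape[1] < tw:
            continue
        if t.pixels.std() == 0 or crop.std() == 0:
            continue
        # zero-normalized cross-correlation over all placements in the crop
        score = match_template(crop, t.pixels, pad_input=False)
        iy, ix = np.unravel_index(np.argmax(score), score.shape)
        peak = float(score[iy, ix])
        if peak < score_floor:
            continue
        fy, fx = float(iy), float(ix)
        if peak < 1.0 - _EXACT_EPS:
            if 0 < iy < score.shape[0] - 1:
                fy += _quadratic_peak(
                    score[iy - 1, ix], peak, score[iy + 1, ix]
                )
            if 0 < ix < score.shape[1] - 1:
                fx += _quadratic_peak(
                    score[iy, ix - 1], peak, score[iy, ix + 1]
                )
        dxs.append(x0 + fx - t.x0)
        dys.append(y0 + fy - t.y0)
        scores.append(peak)
    if not dxs:
        raise RegistrationError(
            "all templates scored below the correlation floor; no match"
        )
    return float(np.median(dxs)), float(np.median(dys)), float(np.median(scores))


# ---------------------------------------------------------------------------
# polar unwrapping and rotation matching


@dataclass
class PolarImage:
    """Polar-unwrapped view: rows = radius (px), columns = angle bins.

    Column j samples the source along angle ``j * bin_deg`` measured from
    the +x axis toward +y; the angular axis wraps (column 0 is adjacent to
    the last). A rotation of the source by delta about ``center`` shifts
    the columns circularly by ``delta / bin_deg``.
    """

    pixels: np.ndarray
    center: tuple[float, float]
    bin_deg: float

    @property
    def n_radii(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_angles(self) -> int:
        return self.pixels.shape[1]


def polar_unwrap(
    gray: GrayFrame | np.ndarray,
    center: tuple[float, float],
    r_max: int,
    bin_deg: float = 0.25,
) -> PolarImage:
    """Bilinear resampling onto a (radius, angle) grid about ``center``."""
    from .errors import ConfigError

    if r_max <= 0:
        raise ConfigError("r_max must be > 0")
    if not (359.9 <= round(360.0 / bin_deg) * bin_deg <= 360.1):
        raise ConfigError("bin_deg must divide 360 evenly")
    img = gray.pixels if isinstance(gray, GrayFrame) else np.asarray(gray, float)
    n_angles = int(round(360.0 / bin_deg))
    radii = np.arange(r_max + 1, dtype=float)
    angles = np.deg2rad(np.arange(n_angles) * bin_deg)
    xs = center[0] + radii[:, None] * np.cos(angles)[None, :]
    ys = center[1] + radii[:, None] * np.sin(angles)[None, :]
    sampled = ndimage.map_coordinates(
        img.astype(float), [ys, xs], order=1, mode="constant", cval=0.0
    )
    return PolarImage(pixels=sampled, center=tuple(center), bin_deg=bin_deg)


def estimate_rotation(
    polar_ref: PolarImage,
    polar_mov: PolarImage,
    n_regions: int = 40,
    radius_band: tuple[int, int] | None = None,
    max_search_deg: float = 10.0,
    score_ceiling: float = 0.3,
    n_radial: int = 4,
) -> float:
    """Rotation (deg) of the source of polar_mov relative to polar_ref.

    Up to ``n_regions`` rectangular regions tiled across the informative
    radius band of polar_ref are matched against polar_mov by the
    normalized squared-difference score over circular (wraparound) angular
    offsets; per-region offsets are refined to subpixel-bin by a quadratic
    fit around the minimum, regions scoring above ``score_ceiling`` are
    rejected, and the result is the median accepted offset times the bin
    width. Equal scores resolve to the smallest |offset|.
    """
    if (
        polar_ref.bin_deg != polar_mov.bin_deg
        or polar_ref.pixels.shape != polar_mov.pixels.shape
    ):
        raise RegistrationError("polar images must share bins and shape")
    bin_deg = polar_ref.bin_deg
    if radius_band is None:
        radius_band = (
            int(0.25 * (polar_ref.n_radii - 1)),
            int(0.95 * (polar_ref.n_radii - 1)),
        )
    r0, r1 = radius_band
    band_ref = polar_ref.pixels[r0 : r1 + 1]
    band_mov = polar_mov.pixels[r0 : r1 + 1]
    n_rows, n_cols = band_ref.shape
    if n_rows < n_radial:
        n_radial = max(1, n_rows)
    n_angular = max(1, n_regions // n_radial)
    row_edges = np.linspace(0, n_rows, n_radial + 1).astype(int)
    col_edges = np.linspace(0, n_cols, n_angular + 1).astype(int)

    k_max = int(round(max_search_deg / bin_deg))
    offsets = np.arange(-k_max, k_max + 1)
    # scores[region, offset]; nsd = sum((T - M_k)^2) / sqrt(sum T^2 sum M_k^2)
    n_reg = n_radial * n_angular
    scores = np.full((n_reg, offsets.size), np.inf)
    t_sq = np.empty(n_reg)
    for idx in range(n_reg):
        i, j = divmod(idx, n_angular)
        reg = band_ref[row_edges[i] : row_edges[i + 1],
                       col_edges[j] : col_edges[j + 1]]
        t_sq[idx] = float((reg**2).sum())
    for ki, k in enumerate(offsets):
        # region at cols [a, b) of ref matches mov cols [a+k, b+k) (wrapped)
        shifted = np.roll(band_mov, -int(k), axis=1)
        for idx in range(n_reg):
            i, j = divmod(idx, n_angular)
            t = band_ref[row_edges[i] : row_edges[i + 1],
                         col_edges[j] : col_edges[j + 1]]
            m = shifted[row_edges[i] : row_edges[i + 1],
                        col_edges[j] : col_edges[j + 1]]
            m_sq = float((m**2).sum())
            if t_sq[idx] == 0 or m_sq == 0:
                continue
            scores[idx, ki] = float(((t - m) ** 2).sum()) / np.sqrt(
                t_sq[idx] * m_sq
            )

    accepted: list[float] = []
    for idx in range(n_reg):
        s = scores[idx]
        if not np.isfinite(s).any():
            continue
        best = s.min()
        if best > score_ceiling:
            continue
        # ties resolve to the smallest |offset|
        cand = np.flatnonzero(s == best)
        ki = int(cand[np.argmin(np.abs(offsets[cand]))])
        k = float(offsets[ki])
        if best > _EXACT_EPS and 0 < ki < s.size - 1:
            k += _quadratic_peak(s[ki - 1], s[ki], s[ki + 1])
        accepted.append(k * bin_deg)
    if not accepted:
        raise RegistrationError(
            "no polar region matched below the score ceiling; no rotation estimate"
        )
    return _circular_median(accepted)


def _circular_median(angles_deg: Sequence[float]) -> float:
    """Median of angles, computed on the circle via the mean-direction cut."""
    a = np.deg2rad(np.asarray(angles_deg, float))
    mean_dir = np.arctan2(np.sin(a).mean(), np.cos(a).mean())
    unwrapped = (a - mean_dir + np.pi) % (2 * np.pi) - np.pi
    med = np.median(unwrapped) + mean_dir
    return float((np.rad2deg(med) + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# pairwise and stack registration


@dataclass
class PairDiagnostics:
    iterations_used: int
    converged: bool
    final_residual_px: float
    final_residual_deg: float
    quality: float = 0.0


@dataclass
class RegistrationParams:
    """Tunable knobs of the pair-registration loop (see docs/methods.md)."""

    n_templates: int = 6
    template_size_px: int = 64
    n_regions: int = 40
    bin_deg: float = 0.25
    search_window_px: int = 48
    max_search_deg: float = 10.0
    score_floor: float = 0.5
    score_ceiling: float = 0.3
    conv_tol_px: float = 0.5
    conv_tol_deg: float = 0.1
    max_iterations: int = 15
    damping: float = 0.5
    smooth_theta: bool = False  # optional 3-point median over the pair series


def register_pair(
    ref: GrayFrame | np.ndarray,
    mov: GrayFrame | np.ndarray,
    mask: AssembloidMask,
    params: RegistrationParams | None = None,
    init: RigidTransform | None = None,
    templates: Sequence[Template] | None = None,
) -> tuple[RigidTransform, PairDiagnostics]:
    """Estimate the rigid motion carrying ref content onto mov content.

    Iterative refinement: (1) translation from template matching, damped
    update; (2) rotation from polar-unwrapped region matching about the
    current center, damped update; (3) translation re-estimated with the
    updated transform. The loop stops when one full iteration's updates
    fall below (conv_tol_px, conv_tol_deg) or at max_iterations. The
    returned transform T satisfies apply_transform(mov, T.inverse()) ~ ref.

    ``init`` seeds the accumulated transform (used by register_stack to
    fold in the cumulative correction so each pair only resolves the small
    frame-to-frame residual).
    """
    p = params or RegistrationParams()
    ref_img = ref.pixels if isinstance(ref, GrayFrame) else np.asarray(ref, float)
    mov_img = mov.pixels if isinstance(mov, GrayFrame) else np.asarray(mov, float)
    h, w = ref_img.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    if templates is None:
        templates = select_templates(
            ref_img, mask, p.n_templates, p.template_size_px
        )
    r_hull = mask.hull_radius
    r_max = int(min(r_hull * 1.05, center[0], center[1],
                    w - 1 - center[0], h - 1 - center[1]))
    band = (int(0.25 * r_hull), min(int(0.95 * r_hull), r_max))
    polar_ref = polar_unwrap(ref_img, center, r_max, p.bin_deg)

    acc = init if init is not None else RigidTransform(center=center)
    acc = RigidTransform(acc.dx_px, acc.dy_px, acc.theta_deg, center)
    iterations = 0
    converged = False
    last_px, last_deg, quality = np.inf, np.inf, 0.0
    for iterations in range(1, p.max_iterations + 1):
        px_updates = []
        # (1) translation
        cur = apply_transform(mov_img, acc.inverse())
        ddx, ddy, quality = estimate_translation(
            ref_img, cur, templates, p.search_window_px, p.score_floor
        )
        step = RigidTransform(p.damping * ddx, p.damping * ddy, 0.0, center)
        acc = step.then(acc)
        px_updates.append(np.hypot(step.dx_px, step.dy_px))
        # (2) rotation about the updated center
        cur = apply_transform(mov_img, acc.inverse())
        polar_cur = polar_unwrap(cur, center, r_max, p.bin_deg)
        dth = estimate_rotation(
            polar_ref, polar_cur, p.n_regions, band,
            p.max_search_deg, p.score_ceiling,
        )
        rot_step = RigidTransform(0.0, 0.0, p.damping * dth, center)
        acc = rot_step.then(acc)
        deg_update = abs(rot_step.theta_deg)
        # (3) translation again with the updated transform
        cur = apply_transform(mov_img, acc.inverse())
        ddx, ddy, quality = estimate_translation(
            ref_img, cur, templates, p.search_window_px, p.score_floor
        )
        step = RigidTransform(p.damping * ddx, p.damping * ddy, 0.0, center)
        acc = step.then(acc)
        px_updates.append(np.hypot(step.dx_px, step.dy_px))

        last_px, last_deg = max(px_updates), deg_update
        if last_px < p.conv_tol_px and last_deg < p.conv_tol_deg:
            converged = True
            break
    diag = PairDiagnostics(
        iterations_used=iterations,
        converged=converged,
        final_residual_px=float(last_px),
        final_residual_deg=float(last_deg),
        quality=quality,
    )
    return acc, diag


@dataclass
class RegistrationResult:
    """Per-pair and cumulative transforms plus diagnostics for one stack.

    ``pair_transforms[k]`` is the residual motion between corrected frame
    k-1 and frame k (identity at k=0); ``cumulative[k]`` composes pairs
    back to frame 0: cumulative[k] = pair[k] then cumulative[k-1].
    ``recenter_shift`` is the integer shift that put the frame-0 centroid
    at the image center (applied to every frame before estimation).
    """

    pair_transforms: list[RigidTransform]
    cumulative: list[RigidTransform]
    diagnostics: list[PairDiagnostics]
    recenter_shift: tuple[int, int]
    mask0: AssembloidMask | None = None


def register_stack(
    stack,
    params: RegistrationParams | None = None,
    gray_recipe: str | dict = "brightfield",
    seg_kwargs: dict | None = None,
) -> RegistrationResult:
    """Register every frame of a stack back to the frame-0 pose.

    Frame 0 is segmented and recentered on its assembloid centroid; each
    consecutive pair is then registered with :func:`register_pair`, seeding
    the accumulated transform with the previous cumulative correction so
    only the small frame-to-frame residual must be resolved. A failed pair
    is recorded as identity (with a warning) and registration continues.
    """
    from .frame_io import to_gray
    from .segmentation import recenter_frame, segment_assembloid

    p = params or RegistrationParams()
    seg_kwargs = seg_kwargs or {}
    if isinstance(gray_recipe, str) and gray_recipe not in stack.channel_roles:
        gray_recipe = {"red": 1.0, "green": 1.0}

    gray0 = to_gray(stack.frames[0], stack.channel_roles, gray_recipe, 0)
    mask_pre = segment_assembloid(gray0, **seg_kwargs)
    _, shift = recenter_frame(stack.frames[0], mask_pre.centroid)

    grays = []
    for t in range(stack.n_frames):
        shifted, _ = _shift_channels(stack.frames[t], shift)
        grays.append(
            to_gray(shifted, stack.channel_roles, gray_recipe, t).pixels
        )
    mask0 = segment_assembloid(grays[0], **seg_kwargs)
    h, w = grays[0].shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    templates = select_templates(grays[0], mask0, p.n_templates, p.template_size_px)

    identity = RigidTransform(center=center)
    pair_transforms = [identity]
    cumulative = [identity]
    diagnostics = [PairDiagnostics(0, True, 0.0, 0.0, 1.0)]
    for t in range(1, stack.n_frames):
        try:
            cum_t, diag = register_pair(
                grays[0], grays[t], mask0, p,
                init=cumulative[t - 1], templates=templates,
            )
            # pair s.t. cumulative[t] = pair.then(cumulative[t-1])
            pair = cum_t.then(cumulative[t - 1].inverse())
        except RegistrationError as err:
            warnings.warn(f"pair {t - 1}->{t} failed ({err}); carrying identity")
            pair = identity
            cum_t = cumulative[t - 1]
            diag = PairDiagnostics(p.max_iterations, False, np.inf, np.inf, 0.0)
        pair_transforms.append(pair)
        cumulative.append(cum_t)
        diagnostics.append(diag)

    if p.smooth_theta and stack.n_frames >= 3:
        thetas = np.array([tr.theta_deg for tr in pair_transforms])
        sm = ndimage.median_filter(thetas, size=3, mode="nearest")
        pair_transforms = [
            RigidTransform(tr.dx_px, tr.dy_px, th, center)
            for tr, th in zip(pair_transforms, sm)
        ]
        cumulative = [pair_transforms[0]]
        for tr in pair_transforms[1:]:
            cumulative.append(tr.then(cumulative[-1]))

    return RegistrationResult(
        pair_transforms=pair_transforms,
        cumulative=cumulative,
        diagnostics=diagnostics,
        recenter_shift=shift,
        mask0=mask0,
    )


def _shift_channels(
    frame_channels: np.ndarray, shift: tuple[int, int]
) -> tuple[np.ndarray, tuple[int, int]]:
    """Integer-shift channels by (dx, dy) with zero fill."""
    dx, dy = shift
    frame_channels = np.asarray(frame_channels)
    h, w = frame_channels.shape[-2:]
    if dx == 0 and dy == 0:
        return frame_channels.copy(), (0, 0)
    out = np.zeros_like(frame_channels)
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[..., dst_y, dst_x] = frame_channels[..., src_y, src_x]
    return out, shift


def registered_stack_frames(stack, result: RegistrationResult) -> np.ndarray:
    """All frames recentered and warped into the frame-0 pose (float32)."""
    out = np.empty(stack.frames.shape, dtype=np.float32)
    for t in range(stack.n_frames):
        shifted, _ = _shift_channels(stack.frames[t], result.recenter_shift)
        out[t] = apply_transform(shifted, result.cumulative[t].inverse())
    return out


def transforms_table(result: RegistrationResult):
    """transforms.csv rows: per-pair and cumulative corrections."""
    import pandas as pd

    rows = []
    for t, (pair, cum, d) in enumerate(
        zip(result.pair_transforms, result.cumulative, result.diagnostics)
    ):
        rows.append(
            dict(
                t=t,
                dx_px=pair.dx_px, dy_px=pair.dy_px, theta_deg=pair.theta_deg,
                cum_dx_px=cum.dx_px, cum_dy_px=cum.dy_px,
                cum_theta_deg=cum.theta_deg,
                iterations=d.iterations_used, converged=d.converged,
                residual=max(d.final_residual_px, d.final_residual_deg),
            )
        )
    return pd.DataFrame(rows)
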