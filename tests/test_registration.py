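import numpy as np
import pytest
from hypothesis import given, strategies as st

from phenotrack.errors import RegistrationError
from phenotrack.registration import (
    RegistrationParams,
    RigidTransform,
    apply_transform,
    estimate_rotation,
    estimate_translation,
    polar_unwrap,
    register_pair,
    register_stack,
    select_templates,
)
from phenotrack.segmentation import segment_assembloid
from phenotrack.synthetic import SceneParams, generate_scene, render_stack


# ---------------------------------------------------------------------- rigid


@given(
    dx=st.floats(-50, 50), dy=st.floats(-50, 50), theta=st.floats(-179, 179),
    px=st.floats(-100, 100), py=st.floats(-100, 100),
)
def test_transform_inverse_is_identity(dx, dy, theta, px, py):
    t = RigidTransform(dx, dy, theta, center=(64.0, 48.0))
    p = np.array([px, py])
    np.testing.assert_allclose(t.inverse()(t(p)), p, atol=1e-9)


def test_theta_normalized_to_half_open_interval():
    assert RigidTransform(theta_deg=270.0).theta_deg == -90.0
    assert RigidTransform(theta_deg=-180.0).theta_deg == 180.0
    assert RigidTransform(theta_deg=540.0).theta_deg == 180.0


def test_apply_identity_is_bit_exact():
    rng = np.random.default_rng(0)
    img = rng.random((2, 32, 32))
    out = apply_transform(img, RigidTransform(center=(15.5, 15.5)))
    np.testing.assert_array_equal(out, img)


def test_rotation_sign_convention():
    # theta=90 rotates +x toward +y: pixel at (c+50, c) lands at (c, c+50)
    img = np.zeros((101, 101))
    img[50, 100] = 1.0
    out = apply_transform(img, RigidTransform(0, 0, 90.0, center=(50.0, 50.0)))
    assert out[100, 50] == pytest.approx(1.0, abs=1e-6)


def test_transform_then_inverse_round_trips_interior(noise_free_disc):
    g0 = noise_free_disc
    t = RigidTransform(4.0, -6.0, 2.0, center=(127.5, 127.5))
    back = apply_transform(apply_transform(g0, t), t.inverse())
    # compare on the smooth disc interior, away from the steep rim
    yy, xx = np.mgrid[0:256, 0:256]
    interior = np.hypot(xx - 127.5, yy - 127.5) < 68
    dyn = g0.max() - g0.min()
    assert np.abs(back - g0)[interior].max() < 0.03 * dyn


# ------------------------------------------------------------------ templates


def test_template_selection_contract(textured_pair):
    g0, _, mask, _ = textured_pair
    tpls = select_templates(g0, mask, n_templates=6, template_size_px=32)
    assert len(tpls) == 6
    centers = np.array([t.center for t in tpls])
    c = np.asarray(mask.centroid)
    assert (np.hypot(*(centers - c).T) < mask.hull_radius).all()
    for i in range(6):
        for j in range(i + 1, 6):
            assert np.hypot(*(centers[i] - centers[j])) >= 32

def test_template_selection_too_small_mask_raises():
    img = np.zeros((128, 128))
    yy, xx = np.mgrid[0:128, 0:128]
    img[(xx - 64) ** 2 + (yy - 64) ** 2 <= 20**2] = 1.0
    mask = segment_assembloid(img, min_area_px=100)
    with pytest.raises(RegistrationError):
        select_templates(img, mask, n_templates=6, template_size_px=64)


def test_constant_texture_warns_but_selects(textured_pair):
    _, _, mask, _ = textured_pair
    flat = mask.mask.astype(float)  # perfectly flat disc
    with pytest.warns(UserWarning, match="zero-variance"):
        select_templates(flat, mask, n_templates=3, template_size_px=16)


# ---------------------------------------------------------------- translation


def test_integer_shift_recovered_exactly(textured_pair):
    g0, _, mask, _ = textured_pair
    tpls = select_templates(g0, mask, 6, 32)
    moved = np.roll(g0, (-3, 5), axis=(0, 1))  # content moves by (+5, -3)
    dx, dy, q = estimate_translation(g0, moved, tpls, search_window_px=24)
    assert (dx, dy) == (5.0, -3.0)
    assert q > 0.99
    dx0, dy0, _ = estimate_translation(g0, g0, tpls, search_window_px=24)
    assert (dx0, dy0) == (0.0, 0.0)


def test_subpixel_shift_recovered_within_half_pixel(textured_pair):
    from scipy.ndimage import shift as nd_shift

    g0, _, mask, _ = textured_pair
    tpls = select_templates(g0, mask, 6, 32)
    moved = nd_shift(g0, (0.0, 2.5), order=1)  # content moves +2.5 in x
    dx, dy, _ = estimate_translation(g0, moved, tpls, search_window_px=24)
    assert abs(dx - 2.5) < 0.5 and abs(dy) < 0.5


def test_featureless_moving_frame_raises(textured_pair):
    g0, _, mask, _ = textured_pair
    tpls = select_templates(g0, mask, 6, 32)
    noise = np.random.default_rng(0).random(g0.shape)
    with pytest.raises(RegistrationError):
        estimate_translation(g0, noise, tpls, search_window_px=24)


# ---------------------------------------------------------------------- polar


def test_radial_gradient_unwraps_to_constant_rows():
    yy, xx = np.mgrid[0:201, 0:201]
    r = np.hypot(xx - 100, yy - 100)
    polar = polar_unwrap(r, (100.0, 100.0), r_max=80, bin_deg=1.0)
    assert polar.n_angles == 360
    row_spread = polar.pixels.max(axis=1) - polar.pixels.min(axis=1)
    # rows away from the angularly degenerate center are flat
    assert row_spread[5:].max() < 0.05
    np.testing.assert_allclose(polar.pixels[:, 0], np.arange(81), atol=0.01)


def test_bright_spot_lands_at_expected_polar_bin():
    img = np.zeros((201, 201))
    # angle 90 deg (+y direction), radius 50
    img[150, 100] = 1.0
    polar = polar_unwrap(img, (100.0, 100.0), r_max=80, bin_deg=0.5)
    row, col = np.unravel_index(polar.pixels.argmax(), polar.pixels.shape)
    assert row == 50 and col == int(90 / 0.5)


def test_source_rotation_equals_polar_column_shift(noise_free_disc):
    g0 = noise_free_disc
    center = (127.5, 127.5)
    bin_deg = 0.5
    rotated = apply_transform(g0, RigidTransform(0, 0, 2 * bin_deg, center))
    p_ref = polar_unwrap(g0, center, r_max=70, bin_deg=bin_deg)
    p_rot = polar_unwrap(rotated, center, r_max=70, bin_deg=bin_deg)
    shifted = np.roll(p_ref.pixels, 2, axis=1)
    band = np.s_[20:65, :]  # informative radii
    dyn = g0.max() - g0.min()
    assert np.abs(p_rot.pixels[band] - shifted[band]).max() < 0.02 * dyn


# ------------------------------------------------------------------- rotation


def test_rotation_of_identical_polar_images_is_zero(textured_pair):
    g0, _, mask, _ = textured_pair
    polar = polar_unwrap(g0, (127.5, 127.5), r_max=80, bin_deg=0.25)
    assert estimate_rotation(polar, polar, radius_band=(20, 76)) == 0.0


def test_constructed_column_shift_gives_exact_angle(textured_pair):
    from dataclasses import replace

    g0, _, _, _ = textured_pair
    polar = polar_unwrap(g0, (127.5, 127.5), r_max=80, bin_deg=0.25)
    shifted = replace(polar, pixels=np.roll(polar.pixels, 12, axis=1))
    dth = estimate_rotation(polar, shifted, radius_band=(20, 76))
    assert dth == pytest.approx(3.0, abs=1e-9)


def test_true_rotation_recovered_within_stated_uncertainty(textured_pair):
    g0, _, _, _ = textured_pair
    center = (127.5, 127.5)
    rotated = apply_transform(g0, RigidTransform(0, 0, 3.0, center))
    p_ref = polar_unwrap(g0, center, r_max=80, bin_deg=0.25)
    p_rot = polar_unwrap(rotated, center, r_max=80, bin_deg=0.25)
    dth = estimate_rotation(p_ref, p_rot, radius_band=(20, 76))
    assert abs(dth - 3.0) < 0.5


@pytest.mark.parametrize("delta", [-2.0, 1.5])
def test_rotation_equivariance(textured_pair, delta):
    # adding delta to the true rotation changes the estimate by delta
    g0, _, _, _ = textured_pair
    center = (127.5, 127.5)
    p_ref = polar_unwrap(g0, center, r_max=80, bin_deg=0.25)

    def estimate(angle):
        rot = apply_transform(g0, RigidTransform(0, 0, angle, center))
        p = polar_unwrap(rot, center, r_max=80, bin_deg=0.25)
        return estimate_rotation(p_ref, p, radius_band=(20, 76))

    base = estimate(2.0)
    assert abs(estimate(2.0 + delta) - base - delta) < 0.5


# ---------------------------------------------------------------------- pairs


def test_identity_pair_converges_immediately(textured_pair, small_reg_params):
    g0, _, mask, _ = textured_pair
    tr, diag = register_pair(g0, g0, mask, small_reg_params)
    assert diag.converged and diag.iterations_used == 1
    assert tr.is_identity(tol_px=0.2, tol_deg=0.05)


def test_known_transform_recovered(textured_pair, small_reg_params):
    g0, _, mask, _ = textured_pair
    truth = RigidTransform(4.0, -6.0, 2.0, center=(127.5, 127.5))
    mov = apply_transform(g0, truth)
    tr, diag = register_pair(g0, mov, mask, small_reg_params)
    assert abs(tr.dx_px - 4.0) < 1.0
    assert abs(tr.dy_px + 6.0) < 1.0
    assert abs(tr.theta_deg - 2.0) < 0.5
    assert diag.iterations_used <= 15


def test_rotation_under_noise_monte_carlo(textured_pair, small_reg_params):
    """5 deg rotation plus 10% noise: theta within 0.5 deg, mostly converged."""
    g0, _, mask, _ = textured_pair
    truth = RigidTransform(0.0, 0.0, 5.0, center=(127.5, 127.5))
    mov_clean = apply_transform(g0, truth)
    dyn = g0.max() - g0.min()
    ok = conv = 0
    n = 20
    for seed in range(n):
        rng = np.random.default_rng(seed)
        mov = mov_clean + rng.normal(0, 0.10 * dyn, mov_clean.shape)
        tr, diag = register_pair(g0, mov, mask, small_reg_params)
        ok += abs(tr.theta_deg - 5.0) < 0.5
        conv += diag.converged
    assert ok >= int(0.9 * n)
    assert conv >= int(0.9 * n)


# ---------------------------------------------------------------------- stack


def _small_stack(seed=3, n_frames=6, **kw):
    base = dict(
        n_frames=n_frames, height=256, width=256, disc_radius_px=80.0,
        n_cells=0, t_max_px=4.0, r_max_deg=3.0,
    )
    base.update(kw)
    scene = generate_scene(SceneParams(**base), seed=seed)
    return scene, render_stack(scene)


def test_scripted_stack_recovered_within_tolerance(small_reg_params):
    from phenotrack.synthetic import evaluate_registration

    scene, stack = _small_stack()
    result = register_stack(stack, small_reg_params)
    ev = evaluate_registration(result, scene)
    assert np.abs(ev["dx_err"]).max() < 1.0
    assert np.abs(ev["dy_err"]).max() < 1.0
    assert np.abs(ev["theta_err"]).max() < 0.5
    assert np.abs(ev["cum_theta_err"]).max() < 1.5
    for k in range(1, len(result.cumulative)):
        expected = result.pair_transforms[k].then(result.cumulative[k - 1])
        assert np.allclose(
            [expected.dx_px, expected.dy_px, expected.theta_deg],
            [result.cumulative[k].dx_px, result.cumulative[k].dy_px,
             result.cumulative[k].theta_deg],
        )


def test_static_scene_registers_to_identity(small_reg_params):
    scene, stack = _small_stack(seed=4, n_frames=4, t_max_px=0.0, r_max_deg=0.0)
    result = register_stack(stack, small_reg_params)
    for tr in result.pair_transforms:
        assert tr.is_identity(tol_px=0.5, tol_deg=0.2)


def test_failed_pair_carries_identity_and_warns(small_reg_params):
    scene, stack = _small_stack(seed=5, n_frames=4, t_max_px=0.0, r_max_deg=0.0,
                                noise_sigma_frac=0.0)
    frames = stack.frames.copy()
    rng = np.random.default_rng(0)
    frames[2] = (rng.random(frames[2].shape) * 60000).astype(np.uint16)
    bad = type(stack)(frames, stack.channel_roles,
                      stack.pixel_size_um, stack.frame_interval_min)
    with pytest.warns(UserWarning, match="carrying identity"):
        result = register_stack(bad, small_reg_params)
    assert not result.diagnostics[2].converged
    assert result.pair_transforms[2].is_identity()
    # downstream frame still registered (static scene -> identity)
    assert result.pair_transforms[3].is_identity(tol_px=0.5, tol_deg=0.2)
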