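import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene_params():
    """A fast scene for unit tests: 256 px frame, 80 px disc."""
    from phenotrack.synthetic import SceneParams

    return SceneParams(
        n_frames=2, height=256, width=256, disc_radius_px=80.0,
        n_cells=0, t_max_px=5.0, r_max_deg=4.0,
    )


@pytest.fixture(scope="session")
def small_reg_params():
    """Registration parameters sized for the 80 px test disc."""
    from phenotrack.registration import RegistrationParams

    return RegistrationParams(template_size_px=32, search_window_px=24)


@pytest.fixture(scope="session")
def textured_pair(small_scene_params):
    """(gray0, gray1, mask, scene): one noisy textured-disc frame pair."""
    from phenotrack.frame_io import to_gray
    from phenotrack.segmentation import segment_assembloid
    from phenotrack.synthetic import generate_scene, render_stack

    scene = generate_scene(small_scene_params, seed=7)
    stack = render_stack(scene)
    g0 = to_gray(stack.frames[0], stack.channel_roles, "brightfield").pixels
    g1 = to_gray(stack.frames[1], stack.channel_roles, "brightfield").pixels
    mask = segment_assembloid(g0)
    return g0, g1, mask, scene


@pytest.fixture(scope="session")
def noise_free_disc(small_scene_params):
    """Noise-free textured-disc brightfield frame (interpolation tests)."""
    from dataclasses import replace

    from phenotrack.frame_io import to_gray
    from phenotrack.synthetic import generate_scene, render_stack

    params = replace(small_scene_params, noise_sigma_frac=0.0)
    scene = generate_scene(params, seed=7)
    stack = render_stack(scene)
    return to_gray(stack.frames[0], stack.channel_roles, "brightfield").pixels


@pytest.fixture(scope="session")
def tiny_tracked_scene():
    """A fast full-pipeline scene: 160 px frame, 52 px disc, 5 cells."""
    from phenotrack.synthetic import SceneParams, generate_scene

    params = SceneParams(
        n_frames=5, height=160, width=160, disc_radius_px=52.0,
        n_cells=5, t_max_px=3.0, r_max_deg=2.0, step_sigma_px=1.5,
        cell_margin_frac=0.7, cell_min_sep_px=14.0,
    )
    return generate_scene(params, seed=11)


@pytest.fixture(scope="session")
def tiny_reg_config():
    """RunConfig adapted to the tiny 52 px disc."""
    from phenotrack.config import RunConfig

    cfg = RunConfig()
    cfg.update(
        {
            "registration": {"template_size_px": 16, "search_window_px": 16},
            "segmentation": {"min_area_px": 500},
            "ranking": {"top_n": 3},
        }
    )
    return cfg
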