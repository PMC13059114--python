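import numpy as np
import pytest
from hypothesis import given, strategies as st

from phenotrack.errors import MetricError
from phenotrack.metrics import (
    MigrationMetrics,
    cha,
    compare_groups,
    dominant_phase,
    infiltration_percentage,
    net_displacement,
    path_length,
    rank_and_ratio,
)
from phenotrack.tracking import CellDetection, PhaseCall, Trajectory


def traj(points, phases=None, cell_id=0):
    phases = phases or [PhaseCall.G1] * len(points)
    dets = [
        CellDetection(t=t, x=float(x), y=float(y), red_i=1, green_i=0,
                      hue=0.0, area_px=1, phase=ph)
        for t, ((x, y), ph) in enumerate(zip(points, phases))
    ]
    return Trajectory(cell_id=cell_id, detections=dets)


# ------------------------------------------------------------------ distances


def test_path_length_cases():
    assert path_length(traj([(5, 5)] * 5)) == 0.0
    assert path_length(traj([(0, 0), (3, 4), (3, 4)])) == 5.0
    with pytest.raises(MetricError):
        path_length(traj([(0, 0)]))


def test_path_length_matches_stepwise_sum_oracle():
    rng = np.random.default_rng(0)
    pts = rng.normal(0, 10, (40, 2))
    oracle = sum(
        float(np.hypot(*(pts[i + 1] - pts[i]))) for i in range(len(pts) - 1)
    )
    assert path_length(traj(pts), 0.7) == pytest.approx(0.7 * oracle, abs=1e-9)


def test_net_displacement_cases():
    loop = traj([(0, 0), (10, 0), (10, 10), (0, 0)])
    assert net_displacement(loop) == 0.0
    straight = traj([(0, 0), (4, 0), (10, 0)])
    assert net_displacement(straight, 0.65) == pytest.approx(6.5)


@given(st.integers(0, 1000))
def test_path_length_dominates_net_displacement(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(0, 5, (rng.integers(2, 15), 2))
    t = traj(pts)
    assert path_length(t) >= net_displacement(t) - 1e-12


# ------------------------------------------------------------------------ CHA


def brute_force_hull_area(pts):
    """Monotone-chain hull + shoelace; independent of shapely."""
    pts = sorted(map(tuple, np.asarray(pts, float)))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for i in range(len(hull)):
        x0, y0 = hull[i]
        x1, y1 = hull[(i + 1) % len(hull)]
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0


def test_cha_reference_cases():
    square = traj([(0, 0), (1, 0), (1, 1), (0, 1)])
    assert cha(square) == pytest.approx(1.0, abs=1e-12)
    line = traj([(i, 2 * i) for i in range(10)])
    assert cha(line) == 0.0
    assert cha(traj([(0, 0), (1, 1)])) == 0.0
    with pytest.raises(MetricError):
        cha(np.zeros((0, 2)))


@pytest.mark.parametrize("seed", range(5))
def test_cha_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(0, 20, (50, 2))
    assert cha(traj(pts), 1.3) == pytest.approx(
        1.3**2 * brute_force_hull_area(pts), abs=1e-9
    )


def test_cha_permutation_invariant_and_monotone():
    rng = np.random.default_rng(3)
    pts = rng.normal(0, 10, (20, 2))
    base = cha(traj(pts))
    shuffled = pts[rng.permutation(20)]
    assert cha(traj(shuffled)) == pytest.approx(base, abs=1e-9)
    grown = np.vstack([pts, [[100.0, 100.0]]])
    assert cha(traj(grown)) >= base


# ------------------------------------------------------------- phase and rank


def test_dominant_phase_majority_and_tiebreak():
    g1, g2m = PhaseCall.G1, PhaseCall.G2M
    assert dominant_phase(traj([(0, 0)] * 4, [g1] * 4)) is g1
    assert dominant_phase(traj([(0, 0)] * 10, [g1] * 6 + [g2m] * 4)) is g1
    # tie resolves toward the later-occurring phase
    assert dominant_phase(traj([(0, 0)] * 10, [g1] * 5 + [g2m] * 5)) is g2m
    unk = [PhaseCall.UNKNOWN] * 3
    assert dominant_phase(traj([(0, 0)] * 3, unk)) is PhaseCall.UNKNOWN


def _metric(cell_id, cha_val, phase):
    return MigrationMetrics(
        cell_id=cell_id, n_points=10, path_length_um=0.0,
        net_displacement_um=0.0, cha_um2=cha_val, dominant_phase=phase,
    )


def test_rank_and_ratio_constructed_extremes():
    cells = [
        _metric(i, float(i), PhaseCall.G2M if i >= 50 else PhaseCall.G1)
        for i in range(100)
    ]
    s = rank_and_ratio(cells, n=50)
    assert s.top_ratio is None  # no G1 in the top set
    assert s.bottom_ratio == 0.0
    assert set(s.top_ids) == set(range(50, 100))
    assert not s.overlapping
    assert sum(s.top_counts.values()) == 50


def test_rank_and_ratio_small_cohort_overlaps():
    cells = [_metric(i, float(i), PhaseCall.G1) for i in range(30)]
    s = rank_and_ratio(cells, n=50)
    assert s.n == 30 and s.overlapping
    assert set(s.top_ids) == set(s.bottom_ids) == set(range(30))


def test_rank_and_ratio_deterministic_under_ties():
    cells = [_metric(i, 1.0, PhaseCall.G1) for i in range(10)]
    a = rank_and_ratio(cells, n=3)
    b = rank_and_ratio(list(reversed(cells)), n=3)
    assert a.top_ids == b.top_ids == [0, 1, 2]


# --------------------------------------------------------------- infiltration


def test_infiltration_reference_cases():
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:15] = True
    tumor = np.zeros((20, 20))
    assert infiltration_percentage(mask, tumor, 0.5) == 0.0
    tumor[mask] = 1.0
    assert infiltration_percentage(mask, tumor, 0.5) == 100.0
    tumor[:] = 0.0
    tumor[5:15, 5:10] = 1.0  # exactly half of the mask
    assert infiltration_percentage(mask, tumor, 0.5) == 50.0
    with pytest.raises(MetricError):
        infiltration_percentage(np.zeros((20, 20), bool), tumor, 0.5)


def test_infiltration_bounded_and_monotone():
    rng = np.random.default_rng(0)
    mask = rng.random((30, 30)) > 0.3
    tumor = rng.random((30, 30))
    vals = [infiltration_percentage(mask, tumor, thr) for thr in (0.8, 0.5, 0.2)]
    assert all(0.0 <= v <= 100.0 for v in vals)
    assert vals == sorted(vals)  # lower threshold -> more covered area


# ------------------------------------------------------------------- t - test


def test_identical_groups_give_p_one():
    out = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert out["t_statistic"] == 0.0 and out["p_value"] == 1.0
    out = compare_groups([1, 2, 3], [1, 2, 3])
    assert out["p_value"] == pytest.approx(1.0)
    assert out["t_statistic"] == pytest.approx(0.0, abs=1e-12)


def test_t_statistic_matches_closed_form():
    rng = np.random.default_rng(0)
    a = np.zeros(4) + rng.normal(0, 1e-3, 4)
    b = np.ones(4) + rng.normal(0, 1e-3, 4)
    out = compare_groups(a, b)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    assert out["t_statistic"] == pytest.approx(t_oracle, abs=1e-9)
    with pytest.raises(MetricError):
        compare_groups([1.0], [1.0, 2.0])
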