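"""Trajectory pairing, correlation angles, coupling profile and transition."""

import numpy as np
import pandas as pd
import pytest

import rdomainscope as rds
from rdomainscope import coupling
from rdomainscope.coupling import TrackSet, TrajectoryPair


def make_tracks(rows, frame_interval=0.5):
    return TrackSet(pd.DataFrame(rows, columns=["track_id", "channel", "frame",
                                                "x_nm", "y_nm"]),
                    frame_interval)


def make_pair(pos1, pos2):
    pos1 = np.asarray(pos1, dtype=float)
    pos2 = np.asarray(pos2, dtype=float)
    return TrajectoryPair(("a", "b"), np.arange(len(pos1)), pos1, pos2)


# ---------------------------------------------------------------------------
# linking


def test_link_single_drifting_particle():
    det = pd.DataFrame({"frame": np.arange(10), "channel": "ch1",
                        "x_nm": 20.0 * np.arange(10), "y_nm": 0.0})
    tracks = coupling.link_tracks(det, max_step=100.0)
    assert tracks.data["track_id"].nunique() == 1
    assert len(tracks.data) == 10


def test_link_two_distant_particles_never_swap():
    rows = []
    for f in range(8):
        rows.append({"frame": f, "channel": "ch1", "x_nm": 10.0 * f, "y_nm": 0.0})
        rows.append({"frame": f, "channel": "ch1", "x_nm": 2000.0 - 10.0 * f,
                     "y_nm": 0.0})
    tracks = coupling.link_tracks(pd.DataFrame(rows), max_step=100.0)
    groups = {tid: g for tid, g in tracks.data.groupby("track_id")}
    assert len(groups) == 2
    for g in groups.values():
        assert len(g) == 8
        # each track stays monotone in x (no identity swap)
        dx = np.diff(g.sort_values("frame")["x_nm"].to_numpy())
        assert np.all(dx > 0) or np.all(dx < 0)


def test_link_track_ends_on_large_jump():
    det = pd.DataFrame({"frame": [0, 1, 2, 3], "channel": "ch1",
                        "x_nm": [0.0, 10.0, 5000.0, 5010.0], "y_nm": 0.0})
    tracks = coupling.link_tracks(det, max_step=100.0)
    sizes = tracks.data.groupby("track_id").size().tolist()
    assert sorted(sizes) == [2, 2]


# ---------------------------------------------------------------------------
# pairing rules (2 Hz: steps = seconds * 2)


@pytest.mark.parametrize("n_frames,expected_steps", [
    (21, None),      # 10 s overlap: below the 15-s floor -> excluded
    (41, 40),        # 20 s: included in full
    (161, 100),      # 80 s: truncated to 50 s from the start
])
def test_pair_duration_rules(n_frames, expected_steps):
    rows = []
    for f in range(n_frames):
        rows.append({"track_id": 0, "channel": "ch1", "frame": f,
                     "x_nm": 1.0 * f, "y_nm": 0.0})
        rows.append({"track_id": 1, "channel": "ch2", "frame": f,
                     "x_nm": 1.0 * f + 100.0, "y_nm": 0.0})
    pairs = coupling.pair_trajectories(make_tracks(rows))
    if expected_steps is None:
        assert pairs == []
    else:
        assert len(pairs) == 1
        assert len(pairs[0].frames) - 1 == expected_steps


def test_pair_distance_filter():
    rows = []
    for f in range(41):
        rows.append({"track_id": 0, "channel": "ch1", "frame": f,
                     "x_nm": 0.0, "y_nm": 1.0 * f})
        rows.append({"track_id": 1, "channel": "ch2", "frame": f,
                     "x_nm": 3000.0, "y_nm": 1.0 * f})
    assert coupling.pair_trajectories(make_tracks(rows),
                                      max_pair_distance=1000.0) == []
    assert len(coupling.pair_trajectories(make_tracks(rows),
                                          max_pair_distance=5000.0)) == 1


# ---------------------------------------------------------------------------
# correlation angle


@pytest.mark.parametrize("u,v,expected", [
    ((10, 0), (10, 0), 0.0),        # parallel: complete coupling
    ((10, 0), (0, 10), 90.0),       # orthogonal
    ((10, 0), (-5, 0), 180.0),      # antiparallel
])
def test_alpha_exact_values(u, v, expected):
    pair = make_pair([(0, 0), u], [(100, 0), (100 + v[0], v[1])])
    alpha, mean_alpha, _, skipped = coupling.correlation_angles(pair)
    assert mean_alpha == pytest.approx(expected, abs=1e-9)
    assert skipped == 0


def test_alpha_skips_zero_displacements():
    pos1 = [(0, 0), (0, 0), (10, 0)]      # first step has |u| = 0
    pos2 = [(100, 0), (110, 0), (120, 0)]
    alpha, mean_alpha, _, skipped = coupling.correlation_angles(make_pair(pos1, pos2))
    assert skipped == 1
    assert len(alpha) == 1


def test_alpha_invariant_to_rotation_and_scale(rng):
    p1 = np.cumsum(rng.normal(0, 10, (30, 2)), axis=0)
    p2 = np.cumsum(rng.normal(0, 10, (30, 2)), axis=0) + [500.0, 0.0]
    base = coupling.correlation_angles(make_pair(p1, p2))[0]
    th = 1.1
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    rotated = coupling.correlation_angles(make_pair(p1 @ rot.T, p2 @ rot.T))[0]
    assert np.allclose(base, rotated, atol=1e-9)
    scaled = coupling.correlation_angles(make_pair(3.0 * p1, 3.0 * p2))[0]
    assert np.allclose(base, scaled, atol=1e-9)


# ---------------------------------------------------------------------------
# profile + transition


def test_profile_identical_tracks_zero_alpha(rng):
    steps = rng.normal(0, 20, (41, 2))
    pos = np.cumsum(steps, axis=0)
    pairs = [make_pair(pos, pos + 1e-9) for _ in range(4)]
    prof = coupling.coupling_profile(pairs)
    assert prof.n_pairs == 4
    assert len(prof.bin_centers_nm) == 1
    assert prof.bin_mean_deg[0] == pytest.approx(0.0, abs=1e-3)
    assert prof.bin_sd_deg[0] == pytest.approx(0.0, abs=1e-3)


def test_profile_independent_walks_near_90(rng):
    pairs = []
    for _ in range(100):
        p1 = np.cumsum(rng.normal(0, 20, (41, 2)), axis=0)
        p2 = np.cumsum(rng.normal(0, 20, (41, 2)), axis=0) + [800.0, 0.0]
        pairs.append(make_pair(p1, p2))
    prof = coupling.coupling_profile(pairs)
    weighted = np.average(prof.bin_mean_deg, weights=prof.bin_n)
    assert weighted == pytest.approx(90.0, abs=3.0)
    assert prof.bin_n.sum() == 100          # binning conserves pair count


def test_transition_exact_line_intersection():
    # line A through (0, 60) and (400, 80): y = 60 + 0.05 d; line B flat 90
    rng = np.random.default_rng(0)
    d_near = rng.uniform(0, 399, 50)
    d_far = rng.uniform(601, 1400, 50)
    prof = coupling.CouplingProfile(
        mean_distance_nm=np.concatenate([d_near, d_far]),
        mean_alpha_deg=np.concatenate([60.0 + 0.05 * d_near,
                                       np.full(50, 90.0)]),
        bin_centers_nm=np.array([]), bin_mean_deg=np.array([]),
        bin_sd_deg=np.array([]), bin_n=np.array([]), bin_width_nm=50.0)
    fit = coupling.fit_transition(prof)
    assert fit.found
    assert fit.d_star_nm == pytest.approx(600.0, rel=1e-6)
    assert fit.alpha_star_deg == pytest.approx(90.0, rel=1e-6)


def test_transition_parallel_lines_not_found():
    rng = np.random.default_rng(0)
    d = np.concatenate([rng.uniform(0, 399, 30), rng.uniform(601, 1200, 30)])
    prof = coupling.CouplingProfile(d, np.full(60, 90.0), np.array([]),
                                    np.array([]), np.array([]), np.array([]),
                                    50.0)
    fit = coupling.fit_transition(prof, slope_tol=1e-9)
    assert not fit.found
    assert np.isnan(fit.d_star_nm)


def test_mean_alpha_strictly_decreasing_in_coupling(rng):
    """Against the Monte-Carlo mixture oracle at c in {0,.25,.5,.75,1}."""
    s = 45.0
    n = 100_000
    means = []
    for c in (0.0, 0.25, 0.5, 0.75, 1.0):
        shared = rng.normal(0, s, (n, 2))
        u = np.sqrt(c) * shared + np.sqrt(1 - c) * rng.normal(0, s, (n, 2))
        v = np.sqrt(c) * shared + np.sqrt(1 - c) * rng.normal(0, s, (n, 2))
        cosang = (u * v).sum(1) / (np.linalg.norm(u, axis=1)
                                   * np.linalg.norm(v, axis=1))
        means.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))).mean())
    assert np.all(np.diff(means) < 0)
    assert means[0] == pytest.approx(90.0, abs=0.5)
    assert means[-1] == pytest.approx(0.0, abs=0.5)


# ---------------------------------------------------------------------------
# resampling


def test_resample_identity_and_decimation():
    rows = [{"track_id": 0, "channel": "ch1", "frame": f,
             "x_nm": 1.0 * f, "y_nm": 0.0} for f in range(100)]
    tracks = make_tracks(rows)
    same = coupling.resample_time_step(tracks, 0.5)
    assert len(same.data) == 100
    coarse = coupling.resample_time_step(tracks, 10.0)
    assert len(coarse.data) == 5                      # frames 0,20,40,60,80
    assert coarse.frame_interval == 10.0
    with pytest.raises(ValueError):
        coupling.resample_time_step(tracks, 0.25)
    with pytest.raises(ValueError):
        coupling.resample_time_step(tracks, 0.7)
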