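"""Generator guarantees: geometry, count law, noise models, reproducibility."""

import numpy as np
import pandas as pd
import pytest

import rdomainscope as rds
from rdomainscope import coupling
from rdomainscope.synthetic import shifted_geometric_median


def test_shifted_geometric_median_matches_cdf():
    # brute-force CDF check: median 4 requires P(K<=3) < 0.5 <= P(K<=4)
    for p in (0.05, 0.16, 0.3, 0.7, 1.0):
        ks = np.arange(1, 200)
        cdf = 1.0 - (1.0 - p) ** ks
        expected = int(ks[np.argmax(cdf >= 0.5)])
        assert shifted_geometric_median(p) == expected
    assert shifted_geometric_median(0.16) == 4


def test_degenerate_single_stretch_scene(rng):
    cfg = rds.SceneConfig(n_rds=1, stretch_p=1.0, solitary_fraction=0.0,
                          field_size=(1000.0, 1000.0))
    scene = rds.sample_scene(cfg, rng)
    assert scene.stretch_counts.tolist() == [1]
    assert len(scene.solitary) == 0
    dist = np.linalg.norm(scene.stretches[0][0] - scene.rd_centers[0])
    assert dist <= cfg.rd_diameter / 2


def test_scene_invariants(default_scene):
    scene = default_scene
    cfg_diam = 150.0
    for center, pts in zip(scene.rd_centers, scene.stretches):
        assert len(pts) >= 1
        # containment: all stretches inside the domain disc
        assert np.all(np.linalg.norm(pts - center, axis=1) <= cfg_diam / 2 + 1e-9)
        # max pairwise distance bounded by the disc diameter
        if len(pts) > 1:
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            assert d.max() <= cfg_diam + 1e-9
    # solitary stretches are out of clustering reach of everything
    all_clustered = np.concatenate(scene.stretches)
    for i, s in enumerate(scene.solitary):
        d_cl = np.linalg.norm(all_clustered - s, axis=1).min()
        others = np.delete(scene.solitary, i, axis=0)
        d_sol = np.linalg.norm(others - s, axis=1).min() if len(others) else np.inf
        assert min(d_cl, d_sol) >= 140.0
    # everything inside the field
    tab = scene.stretch_table()
    assert (tab[["x_nm", "y_nm"]].to_numpy() >= 0).all()
    assert (tab[["x_nm", "y_nm"]].to_numpy() <= 6000.0).all()


def test_scene_statistics_converge():
    """Over >= 10^4 RDs the realized median count hits the law median and
    the realized intra-RD NND median lands within 5% of the target."""
    counts, nnds = [], []
    for seed in range(20):
        scene = rds.sample_scene(
            rds.SceneConfig(n_rds=500, field_size=(30000.0, 30000.0),
                            solitary_fraction=0.0),
            np.random.default_rng(seed))
        counts.extend(scene.stretch_counts.tolist())
        for pts in scene.stretches:
            if len(pts) > 1:
                d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
                np.fill_diagonal(d, np.inf)
                nnds.extend(d.min(axis=1).tolist())
    assert len(counts) >= 10_000
    assert np.median(counts) == shifted_geometric_median(0.16) == 4
    assert abs(np.median(nnds) - 63.0) / 63.0 < 0.05


def test_infeasible_geometry_raises(rng):
    cfg = rds.SceneConfig(rd_diameter=50.0, target_intra_nnd=120.0)
    with pytest.raises(rds.PlacementError, match="rd_diameter"):
        rds.sample_scene(cfg, rng)


def test_event_list_zero_noise_limit(default_scene, rng):
    img = rds.ImagingConfig(loc_precision_sigma=0.0, n_frames=100,
                            drift_model=None)
    ev = rds.simulate_event_list(default_scene, img, rng)
    truth = default_scene.stretch_table().set_index("stretch_id")
    assert np.allclose(ev.x, truth.loc[ev.stretch_id, "x_nm"])
    assert np.allclose(ev.y, truth.loc[ev.stretch_id, "y_nm"])


def test_event_list_linear_drift_ramp(default_scene, rng):
    """1 nm/frame in x over 100 frames: last-decile events sit ~90 nm to
    the right of first-decile events once the emitter term is removed."""
    img = rds.ImagingConfig(loc_precision_sigma=0.0, n_frames=100,
                            drift_model=("linear", 1.0, 0.0),
                            events_per_stretch_mean=200.0)
    ev = rds.simulate_event_list(default_scene, img, rng)
    truth = default_scene.stretch_table().set_index("stretch_id")
    dx = ev.x - truth.loc[ev.stretch_id, "x_nm"].to_numpy()
    order = np.argsort(ev.frame, kind="stable")
    dec = len(ev) // 10
    ramp = dx[order[-dec:]].mean() - dx[order[:dec]].mean()
    assert ramp == pytest.approx(90.0, abs=3.0)


def test_event_counts_poisson_and_bookkeeping(default_scene, rng):
    img = rds.ImagingConfig(events_per_stretch_mean=50.0, n_frames=500)
    ev = rds.simulate_event_list(default_scene, img, rng)
    tab = default_scene.stretch_table()
    n_stretch = len(tab)
    # every event maps to an existing stretch, totals are Poisson-consistent
    assert set(np.unique(ev.stretch_id)) <= set(tab["stretch_id"])
    expected = 50.0 * n_stretch
    assert abs(len(ev) - expected) < 4 * np.sqrt(expected)
    assert ev.photons.min() > 0


def test_confocal_single_spot_centroid(rng):
    cfg = rds.SceneConfig(n_rds=1, stretch_p=1.0, solitary_fraction=0.0,
                          field_size=(2000.0, 2000.0, 2400.0),
                          min_center_separation=1.0)
    scene = rds.sample_scene(cfg, rng)
    stack = rds.simulate_confocal_stack(scene, rds.ImagingConfig())
    arr = stack.channels["ch1"]
    z, y, x = np.unravel_index(np.argmax(arr), arr.shape)
    true = scene.stretches[0][0]
    assert abs((x + 0.5) * 90 - true[0]) <= 90
    assert abs((y + 0.5) * 90 - true[1]) <= 90
    assert abs((z + 0.5) * 200 - true[2]) <= 200


def test_confocal_nearby_stretches_form_single_blob():
    """Two stretches 63 nm apart render as one diffraction-limited blob:
    no intensity minimum between the two maxima-free interior."""
    scene = rds.GroundTruthScene(
        rd_centers=np.array([[1000.0, 1000.0]]),
        stretches=[np.array([[968.5, 1000.0], [1031.5, 1000.0]])],
        stretch_channels=[np.array(["ch1", "ch1"])],
        solitary=np.empty((0, 2)), solitary_channels=np.empty(0, dtype="<U3"),
        field_size=(2000.0, 2000.0))
    stack = rds.simulate_confocal_stack(scene, rds.ImagingConfig())
    arr = stack.channels["ch1"]
    sl = arr[arr.shape[0] // 2]
    row = sl[sl.sum(axis=1).argmax()]
    nz = row[row > row.max() * 0.05]
    # profile through the pair is unimodal (single connected blob)
    peak = nz.argmax()
    assert np.all(np.diff(nz[:peak + 1]) >= -1e-12)
    assert np.all(np.diff(nz[peak:]) <= 1e-12)


def test_confocal_intensity_proportional_to_stretch_count(rng):
    img = rds.ImagingConfig()
    totals = []
    for k in (1, 3):
        pts = np.array([[1000.0 + 200 * i, 1000.0] for i in range(k)])
        scene = rds.GroundTruthScene(
            rd_centers=pts.mean(axis=0, keepdims=True), stretches=[pts],
            stretch_channels=[np.full(k, "ch1")],
            solitary=np.empty((0, 2)), solitary_channels=np.empty(0, dtype="<U3"),
            field_size=(3000.0, 3000.0))
        totals.append(rds.simulate_confocal_stack(scene, img).channels["ch1"].sum())
    assert totals[1] == pytest.approx(3 * totals[0], rel=1e-6)


def test_full_coupling_identical_steps(rng):
    motion = rds.MotionModel(loc_noise_sigma=0.0)
    tracks, truth = rds.simulate_trajectory_pairs(5, [0.0] * 5, motion, 20, rng)
    assert np.all(truth["coupling"] == 1.0)
    pairs = coupling.pair_trajectories(tracks, min_duration=5.0,
                                       max_pair_distance=10_000.0)
    for p in pairs:
        assert np.allclose(np.diff(p.pos1, axis=0), np.diff(p.pos2, axis=0))
        alpha, mean_alpha, _, _ = coupling.correlation_angles(p)
        assert mean_alpha == pytest.approx(0.0, abs=1e-5)


def test_uncoupled_alpha_near_90(rng):
    motion = rds.MotionModel(loc_noise_sigma=0.0)
    tracks, truth = rds.simulate_trajectory_pairs(300, [2000.0] * 300, motion,
                                                  41, rng)
    assert np.all(truth["coupling"] == 0.0)
    pairs = coupling.pair_trajectories(tracks, max_pair_distance=10_000.0)
    alphas = np.concatenate([coupling.correlation_angles(p)[0] for p in pairs])
    # angle between independent isotropic vectors is uniform on [0, 180):
    # SE = (180/sqrt(12)) / sqrt(n)
    se = 180.0 / np.sqrt(12.0) / np.sqrt(len(alphas))
    assert len(alphas) >= 10_000
    assert abs(alphas.mean() - 90.0) < 3 * se


def test_half_coupling_alpha_strictly_between(rng):
    """Monte-Carlo oracle over >= 1e5 draws of the mixture model itself."""
    n = 200_000
    s = 45.0
    shared = rng.normal(0, s, (n, 2))
    i1 = rng.normal(0, s, (n, 2))
    i2 = rng.normal(0, s, (n, 2))
    w = np.sqrt(0.5)
    u = w * shared + w * i1
    v = w * shared + w * i2
    cosang = (u * v).sum(1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    oracle = np.degrees(np.arccos(np.clip(cosang, -1, 1))).mean()
    assert 0.0 < oracle < 90.0
    # the trajectory simulator at c = 0.5 reproduces the oracle
    motion = rds.MotionModel(coupling_cutoff=1000.0, loc_noise_sigma=0.0)
    tracks, truth = rds.simulate_trajectory_pairs(300, [500.0] * 300, motion,
                                                  41, rng)
    assert np.allclose(truth["coupling"], 0.5)
    pairs = coupling.pair_trajectories(tracks, max_pair_distance=10_000.0)
    alphas = np.concatenate([coupling.correlation_angles(p)[0] for p in pairs])
    assert alphas.mean() == pytest.approx(oracle, abs=1.5)


def test_mean_alpha_monotone_in_distance(rng):
    motion = rds.MotionModel()
    means = []
    for d in (0.0, 200.0, 400.0, 600.0, 2000.0):
        tracks, _ = rds.simulate_trajectory_pairs(150, [d] * 150, motion, 41, rng)
        pairs = coupling.pair_trajectories(tracks, max_pair_distance=10_000.0)
        alphas = [coupling.correlation_angles(p)[1] for p in pairs]
        means.append(np.mean(alphas))
    assert np.all(np.diff(means) > 0)


def test_combed_fiber_exact_and_clt(rng):
    fib = rds.simulate_combed_fibers([4.36, 23.13], 1.77, 0.0, rng)
    lengths = fib.data.set_index("known_kbp")["length_um"]
    assert lengths.loc[4.36] == pytest.approx(2.463, abs=1e-3)
    assert lengths.loc[23.13] == pytest.approx(13.068, abs=1e-3)
    noisy = rds.simulate_combed_fibers([4.36, 9.41, 23.13], 1.77, 0.1, rng,
                                       n_per_class=1000)
    for kbp, grp in noisy.data.groupby("known_kbp"):
        assert grp["length_um"].mean() == pytest.approx(kbp / 1.77, rel=0.01)


def test_reproducibility_bit_identical():
    cfg = rds.SceneConfig(n_rds=10, field_size=(4000.0, 4000.0))
    img = rds.ImagingConfig(n_frames=200)
    out = []
    for _ in range(2):
        rng = np.random.default_rng(7)
        scene = rds.sample_scene(cfg, rng)
        ev = rds.simulate_event_list(scene, img, rng)
        out.append((scene.stretch_table(), ev))
    pd.testing.assert_frame_equal(out[0][0], out[1][0])
    assert np.array_equal(out[0][1].x, out[1][1].x)
    assert np.array_equal(out[0][1].photons, out[1][1].photons)
    assert np.array_equal(out[0][1].frame, out[1][1].frame)
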