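import numpy as np
import pytest

import rdomainscope as rds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_scene(rng):
    """A territory-sized single-color scene under the default presets."""
    return rds.sample_scene(
        rds.SceneConfig(n_rds=25, field_size=(6000.0, 6000.0)), rng)


@pytest.fixture
def sharp_imaging():
    """Imaging preset used by the recovery suites: 8-nm precision,
    50 events/stretch, no drift."""
    return rds.ImagingConfig(loc_precision_sigma=8.0, n_frames=2000,
                             events_per_stretch_mean=50.0)


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int):
    """Independent density-reachability oracle.

    Core points have >= min_pts neighbors within eps (the point itself
    counts); clusters are the transitive closure of core-core reachability;
    border points may join any cluster holding a core neighbor.  Returns
    (core mask, core labels by component, list of valid cluster sets per
    point, noise mask).
    """
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts
    labels = np.full(n, -1)
    comp = 0
    for i in np.nonzero(core)[0]:
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = comp
        while stack:
            j = stack.pop()
            for k in np.nonzero(neigh[j] & core)[0]:
                if labels[k] < 0:
                    labels[k] = comp
                    stack.append(k)
        comp += 1
    valid = []
    for i in range(n):
        if core[i]:
            valid.append({labels[i]})
        else:
            valid.append({labels[j] for j in np.nonzero(neigh[i] & core)[0]})
    noise = np.array([not core[i] and not valid[i] for i in range(n)])
    return core, labels, valid, noise
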