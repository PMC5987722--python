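"""Ground-truth scene generator emulating the replication-domain imaging data.

A scene is a set of replication domains (RDs): discs of ~150-nm diameter,
each holding a shifted-geometric number of co-replicating stretches
(median 4) spaced ~63 nm apart, plus a configurable fraction of solitary
stretches placed outside clustering reach.  From a scene the module
simulates (1) STORM blinking event lists with localization noise, photon
statistics and stage drift, (2) diffraction-limited confocal stacks
(250/750-nm PSF on a 90/200-nm voxel grid), including dual-color scenes
whose cross-channel center offsets grow with the pulse interval Δt, (3)
pairs of diffusing particles with distance-dependent coupled motion, and
(4) combed-fiber length measurements.  Every operation takes one seeded
``numpy.random.Generator``; identical seed and configuration give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .combing import FiberMeasurements
from .coupling import TrackSet
from .registration import ConfocalStack
from .storm_qc import EventList

# qualitative Δt -> (median nm, geometric SD) spacing progression of the
# dual-color scenes; only the 60-min median (300 nm) is a measured anchor,
# the others interpolate the observed monotone increase
DEFAULT_SPACING_LAW: Dict[float, Tuple[float, float]] = {
    0: (120.0, 1.4), 15: (180.0, 1.4), 30: (240.0, 1.4), 45: (270.0, 1.4),
    60: (300.0, 1.4), 90: (350.0, 1.4), 120: (400.0, 1.4),
}


class PlacementError(RuntimeError):
    """Raised when a scene configuration cannot be realized geometrically."""


@dataclass
class SceneConfig:
    """Geometry and statistics of a ground-truth scene.

    ``stretch_p`` parameterizes the shifted-geometric stretch-count law
    P(K = k) = p (1-p)^(k-1), k >= 1; the default 0.16 puts the median at
    4.  ``target_intra_nnd`` steers the sequential rejection placement of
    stretches inside each disc.  ``solitary_fraction`` is the fraction of
    all stretches placed unclustered, at least ``solitary_exclusion_nm``
    (the clustering reach) from every other stretch.
    """

    n_rds: int = 25
    stretch_p: float = 0.16
    rd_diameter: float = 150.0            # nm
    target_intra_nnd: float = 63.0        # nm
    solitary_fraction: float = 0.126
    field_size: Tuple[float, ...] = (6000.0, 6000.0)   # nm; 2 or 3 entries
    min_center_separation: float = 400.0  # nm between RD (anchor) centers
    solitary_exclusion_nm: float = 140.0  # DBSCAN reach: solitary by construction
    delta_t: Optional[float] = None       # minutes; None = single color
    neighbor_spacing_law: Mapping[float, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SPACING_LAW))

    def __post_init__(self):
        if not (0.0 < self.stretch_p <= 1.0):
            raise ValueError("stretch_p must be in (0, 1]")
        if not (0.0 <= self.solitary_fraction < 1.0):
            raise ValueError("solitary_fraction must be in [0, 1)")
        if self.rd_diameter <= 0:
            raise ValueError("rd_diameter must be > 0")
        if len(self.field_size) not in (2, 3):
            raise ValueError("field_size must be 2D or 3D")

    @property
    def ndim(self) -> int:
        return len(self.field_size)


@dataclass
class ImagingConfig:
    """Acquisition parameters shared by the STORM and confocal simulators.

    ``loc_precision_sigma`` is the per-axis 1-sigma localization precision
    (12 nm, the value estimated from sub-diffraction peak fitting;
    interpreted as sigma, not FWHM).  ``photons_law`` is
    ("lognormal", median, sigma_ln), ("exponential", mean) or
    ("constant", value).  ``drift_model`` is None, ("linear", dx, dy) in
    nm/frame, ("sinusoidal", amp_x, amp_y, period_frames), or a callable
    frame -> (dx, dy).
    """

    storm_pixel: float = 10.0
    confocal_voxel: Tuple[float, float, float] = (90.0, 90.0, 200.0)
    loc_precision_sigma: float = 12.0
    events_per_stretch_mean: float = 50.0
    photons_law: Tuple = ("lognormal", 1000.0, 0.5)
    n_frames: int = 2000
    drift_model: Union[None, Tuple, Callable[[np.ndarray], Tuple]] = None
    psf_fwhm: Tuple[float, float] = (250.0, 750.0)   # lateral, axial nm
    shot_noise_photons: Optional[float] = None       # confocal: photons/stretch

    def __post_init__(self):
        if self.storm_pixel <= 0 or any(v <= 0 for v in self.confocal_voxel):
            raise ValueError("pixel/voxel sizes must be > 0")
        if self.loc_precision_sigma < 0:
            raise ValueError("loc_precision_sigma must be >= 0")


@dataclass
class MotionModel:
    """Coupled diffusion of particle pairs.

    Per-frame displacements mix a shared and an independent isotropic
    Gaussian step with sqrt(c) / sqrt(1-c) weights, c(d) = max(0, 1 -
    d/d_c), so per-particle step variance is independent of the coupling.
    ``loc_noise_sigma`` adds per-frame measurement noise (30 nm, the
    stated tracking precision); it is what lifts the observed mean angle
    at zero distance to ~60 deg.
    """

    step_sigma: float = 45.0          # nm / frame / axis
    coupling_cutoff: float = 550.0    # d_c, nm
    frame_interval: float = 0.5       # s
    loc_noise_sigma: float = 30.0     # nm
    confinement_radius: Optional[float] = None

    def coupling(self, d) -> np.ndarray:
        """c(d) = max(0, 1 - d/d_c): 1 at contact, 0 beyond the cutoff."""
        return np.maximum(0.0, 1.0 - np.asarray(d, dtype=float) / self.coupling_cutoff)


@dataclass
class GroundTruthScene:
    """Realized scene: RD centers, per-RD stretch positions, solitary
    stretches, per-stretch channel labels and the (optional) pulse gap."""

    rd_centers: np.ndarray                 # (R, ndim) nm
    stretches: List[np.ndarray]            # per RD, (K_i, ndim) nm
    stretch_channels: List[np.ndarray]     # per RD, (K_i,) '<U3'
    solitary: np.ndarray                   # (S, ndim) nm
    solitary_channels: np.ndarray          # (S,)
    field_size: Tuple[float, ...]
    delta_t: Optional[float] = None
    rd_pairs: Optional[np.ndarray] = None  # (n_pairs, 2) RD indices, Δt>0 scenes

    @property
    def ndim(self) -> int:
        return len(self.field_size)

    @property
    def stretch_counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.stretches], dtype=int)

    def stretch_table(self) -> pd.DataFrame:
        """One row per stretch: scene-wide stretch_id, rd_id (-1 solitary),
        position (nm) and channel — the ground-truth linkage tests rely on."""
        rows = []
        sid = 0
        for rid, (pts, chans) in enumerate(zip(self.stretches, self.stretch_channels)):
            for p, c in zip(pts, chans):
                rows.append((sid, rid, *p, *([0.0] * (3 - self.ndim)), c))
                sid += 1
        for p, c in zip(self.solitary, self.solitary_channels):
            rows.append((sid, -1, *p, *([0.0] * (3 - self.ndim)), c))
            sid += 1
        return pd.DataFrame(rows, columns=["stretch_id", "rd_id", "x_nm", "y_nm",
                                           "z_nm", "channel"])

    def positions(self, channel: Optional[str] = None,
                  include_solitary: bool = True) -> np.ndarray:
        tab = self.stretch_table()
        if not include_solitary:
            tab = tab[tab["rd_id"] >= 0]
        if channel is not None:
            tab = tab[tab["channel"] == channel]
        return tab[["x_nm", "y_nm", "z_nm"][:self.ndim]].to_numpy()

    def observable_stats(self) -> Dict[str, float]:
        """Ground truth expressed in the clustering pipeline's observables.

        A density-based clustering can only report clusters of two or more
        members, so an RD holding a single stretch is observationally a
        solitary peak.  Recovery tests therefore compare against: the
        median stretch count over RDs with >= 2 stretches, the pooled
        intra-RD nearest-neighbor median over those RDs, and the solitary
        fraction counting both placed solitaries and single-stretch RDs.
        """
        counts = self.stretch_counts
        multi = counts[counts >= 2]
        nnds: List[float] = []
        for pts in self.stretches:
            if len(pts) < 2:
                continue
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            nnds.extend(d.min(axis=1).tolist())
        total = int(counts.sum()) + len(self.solitary)
        n_sol = len(self.solitary) + int((counts == 1).sum())
        return {
            "median_stretches_per_rd": float(np.median(multi)) if multi.size else float("nan"),
            "median_intra_nnd_nm": float(np.median(nnds)) if nnds else float("nan"),
            "solitary_fraction": n_sol / total if total else float("nan"),
            "n_stretches": total,
        }

    def validate(self) -> None:
        """Assert the geometric invariants the generator guarantees."""
        for c, pts in zip(self.rd_centers, self.stretches):
            if len(pts) < 1:
                raise AssertionError("every RD must hold at least one stretch")
        for pts in self.stretches:
            for p in pts:
                if np.any(p < 0) or np.any(p > np.asarray(self.field_size)):
                    raise AssertionError("stretch outside the field")


# ---------------------------------------------------------------------------
# scene sampling


def _uniform_in_ball(rng: np.random.Generator, radius: float, ndim: int) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, size=ndim)
        if np.dot(p, p) <= radius * radius:
            return p


def _random_direction(rng: np.random.Generator, ndim: int) -> np.ndarray:
    v = rng.normal(size=ndim)
    return v / np.linalg.norm(v)


def _place_stretches(rng: np.random.Generator, center: np.ndarray, k: int,
                     radius: float, target: float, max_tries: int = 200
                     ) -> np.ndarray:
    """Sequential rejection placement of k stretches in a disc/ball.

    Each new stretch sits target*(0.95..1.05) nm from a random existing
    one, at least 0.9*target from all others, inside the disc.  When the
    disc is full (all retries exhausted) the count is truncated at the
    realized capacity; the infeasible two-point case raises instead.
    """
    pts = [center + _uniform_in_ball(rng, radius, len(center))]
    for _ in range(k - 1):
        placed = False
        for _ in range(max_tries):
            anchor = pts[rng.integers(len(pts))]
            step = target * rng.uniform(0.95, 1.05)
            cand = anchor + step * _random_direction(rng, len(center))
            if np.linalg.norm(cand - center) > radius:
                continue
            d = np.linalg.norm(np.asarray(pts) - cand, axis=1)
            if np.all(d >= 0.9 * target):
                pts.append(cand)
                placed = True
                break
        if not placed:
            break   # capacity truncation; median count is far below capacity
    return np.asarray(pts)


def _place_centers(rng: np.random.Generator, n: int, lo: np.ndarray,
                   hi: np.ndarray, min_sep: float, max_tries: int = 2000
                   ) -> np.ndarray:
    centers: List[np.ndarray] = []
    for _ in range(n):
        for attempt in range(max_tries):
            c = rng.uniform(lo, hi)
            if all(np.linalg.norm(c - o) >= min_sep for o in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"cannot place {n} RD centers at separation {min_sep} nm in the field")
    return np.asarray(centers)


def sample_scene(cfg: SceneConfig, rng: np.random.Generator) -> GroundTruthScene:
    """Draw one ground-truth scene from the configured laws.

    Single-color scenes label everything ``ch1``.  With ``delta_t = 0``
    each RD's stretches are split stochastically between the channels
    (same domains, two label subsets).  With ``delta_t > 0`` every
    first-pulse RD gets a second-pulse partner RD displaced by a lognormal
    center-to-center distance drawn from ``neighbor_spacing_law[delta_t]``.
    """
    radius = cfg.rd_diameter / 2.0
    if 0.9 * cfg.target_intra_nnd > cfg.rd_diameter:
        raise PlacementError(
            f"infeasible geometry: rd_diameter={cfg.rd_diameter} nm cannot hold "
            f"two stretches at target_intra_nnd={cfg.target_intra_nnd} nm")
    field = np.asarray(cfg.field_size, dtype=float)
    margin = radius
    lo = np.full(cfg.ndim, margin)
    hi = field - margin
    if np.any(hi <= lo):
        raise PlacementError("field smaller than one RD")
    paired = cfg.delta_t is not None and cfg.delta_t > 0
    anchors = _place_centers(rng, cfg.n_rds, lo, hi, cfg.min_center_separation)
    centers = [c for c in anchors]
    rd_pairs = []
    if paired:
        med, gsd = cfg.neighbor_spacing_law[cfg.delta_t]
        for i, c in enumerate(anchors):
            partner = None
            for _ in range(50):
                # keep the drawn distance, resample only the direction, so
                # the field border does not bias the spacing law downward
                dist = med * np.exp(rng.normal(0.0, np.log(gsd)))
                for _ in range(200):
                    cand = c + dist * _random_direction(rng, cfg.ndim)
                    if np.all(cand >= lo) and np.all(cand <= hi):
                        partner = cand
                        break
                if partner is not None:
                    break
            if partner is None:
                raise PlacementError("cannot place a partner RD inside the field")
            centers.append(partner)
            rd_pairs.append((i, len(centers) - 1))
    centers = np.asarray(centers)

    counts = rng.geometric(cfg.stretch_p, size=len(centers))
    stretches = [_place_stretches(rng, c, k, radius, cfg.target_intra_nnd)
                 for c, k in zip(centers, counts)]

    if paired:
        chans = [np.full(len(s), "ch1" if i < cfg.n_rds else "ch2")
                 for i, s in enumerate(stretches)]
    elif cfg.delta_t is not None:     # Δt = 0: stochastic label subsets
        chans = []
        for s in stretches:
            lab = np.where(rng.random(len(s)) < 0.5, "ch1", "ch2")
            chans.append(lab.astype("<U3"))
    else:
        chans = [np.full(len(s), "ch1") for s in stretches]

    n_clustered = int(sum(len(s) for s in stretches))
    n_sol = int(round(cfg.solitary_fraction / (1.0 - cfg.solitary_fraction)
                      * n_clustered))
    all_pts = np.concatenate(stretches) if stretches else np.empty((0, cfg.ndim))
    solitary: List[np.ndarray] = []
    for _ in range(n_sol):
        for _ in range(5000):
            p = rng.uniform(lo, hi)
            others = np.concatenate([all_pts, np.asarray(solitary)]) if solitary else all_pts
            if len(others) == 0 or np.min(np.linalg.norm(others - p, axis=1)) \
                    >= cfg.solitary_exclusion_nm:
                solitary.append(p)
                break
        else:
            raise PlacementError("cannot place solitary stretches: field too crowded")
    solitary_arr = np.asarray(solitary) if solitary else np.empty((0, cfg.ndim))
    if cfg.delta_t is None:
        sol_chan = np.full(len(solitary_arr), "ch1")
    else:
        sol_chan = np.where(rng.random(len(solitary_arr)) < 0.5, "ch1", "ch2"
                            ).astype("<U3")
    scene = GroundTruthScene(centers, stretches, chans, solitary_arr, sol_chan,
                             tuple(field), cfg.delta_t,
                             np.asarray(rd_pairs) if rd_pairs else None)
    scene.validate()
    return scene


def shifted_geometric_median(p: float) -> int:
    """Median of P(K = k) = p(1-p)^(k-1): smallest k with CDF >= 1/2."""
    return int(np.ceil(np.log(0.5) / np.log(1.0 - p))) if p < 1 else 1


# ---------------------------------------------------------------------------
# STORM event simulation


def _drift_at(drift_model, frames: np.ndarray) -> np.ndarray:
    if drift_model is None:
        return np.zeros((len(frames), 2))
    if callable(drift_model):
        dx, dy = drift_model(frames)
        return np.column_stack([np.broadcast_to(dx, len(frames)),
                                np.broadcast_to(dy, len(frames))])
    kind = drift_model[0]
    if kind == "linear":
        _, vx, vy = drift_model
        return np.column_stack([vx * frames, vy * frames])
    if kind == "sinusoidal":
        _, ax, ay, period = drift_model
        ph = 2 * np.pi * frames / period
        return np.column_stack([ax * np.sin(ph), ay * np.sin(ph)])
    raise ValueError(f"unknown drift model {kind!r}")


def _draw_photons(law: Tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "lognormal":
        _, median, sigma = law
        return median * np.exp(rng.normal(0.0, sigma, size=n))
    if kind == "exponential":
        return rng.exponential(law[1], size=n)
    if kind == "constant":
        return np.full(n, float(law[1]))
    raise ValueError(f"unknown photon law {kind!r}")


def simulate_event_list(scene: GroundTruthScene, img: ImagingConfig,
                        rng: np.random.Generator,
                        channel: Optional[str] = None) -> EventList:
    """Blinking event list: Poisson event counts per stretch, frame-uniform
    timing, isotropic Gaussian localization noise, drift and photon draws.

    The ground-truth stretch id of every event is retained in
    ``EventList.stretch_id`` (indices into ``scene.stretch_table()``).
    """
    tab = scene.stretch_table()
    if channel is not None:
        tab = tab[tab["channel"] == channel]
    xy = tab[["x_nm", "y_nm"]].to_numpy()
    sids = tab["stretch_id"].to_numpy()
    counts = rng.poisson(img.events_per_stretch_mean, size=len(xy))
    total = int(counts.sum())
    pos = np.repeat(xy, counts, axis=0).astype(float)
    stretch_id = np.repeat(sids, counts)
    frames = rng.integers(0, img.n_frames, size=total)
    if img.loc_precision_sigma > 0:
        pos += rng.normal(0.0, img.loc_precision_sigma, size=pos.shape)
    pos += _drift_at(img.drift_model, frames)
    photons = _draw_photons(img.photons_law, total, rng)
    order = np.argsort(frames, kind="stable")
    return EventList(frames[order], pos[order, 0], pos[order, 1], photons[order],
                     img.n_frames, img.storm_pixel, stretch_id[order])


# ---------------------------------------------------------------------------
# confocal stack simulation


def simulate_confocal_stack(scene: GroundTruthScene, img: ImagingConfig,
                            rng: Optional[np.random.Generator] = None,
                            z_extent: float = 3000.0) -> ConfocalStack:
    """Diffraction-limited rendering: each stretch becomes a 3D Gaussian of
    the configured PSF FWHM (250 nm lateral / 750 nm axial), unit integral,
    sampled on the confocal voxel grid; optional Poisson shot noise when
    ``shot_noise_photons`` is set.  2D scenes sit at the axial mid-plane.
    One stack per channel present in the scene.
    """
    vx, vy, vz = img.confocal_voxel
    slat = img.psf_fwhm[0] / 2.355
    sax = img.psf_fwhm[1] / 2.355
    if scene.ndim == 3:
        fx, fy, fz = scene.field_size
    else:
        fx, fy = scene.field_size
        fz = z_extent
    if fx < 3 * img.psf_fwhm[0] or fy < 3 * img.psf_fwhm[0] or fz < 3 * img.psf_fwhm[1]:
        raise ValueError("field smaller than three PSF widths")
    nx = int(np.ceil(fx / vx))
    ny = int(np.ceil(fy / vy))
    nz = int(np.ceil(fz / vz))
    tab = scene.stretch_table()
    channels = {}
    zc = (np.arange(nz) + 0.5) * vz
    yc = (np.arange(ny) + 0.5) * vy
    xc = (np.arange(nx) + 0.5) * vx
    for chan in np.unique(tab["channel"]):
        sub = tab[tab["channel"] == chan]
        stack = np.zeros((nz, ny, nx))
        for _, row in sub.iterrows():
            px, py = row["x_nm"], row["y_nm"]
            pz = row["z_nm"] if scene.ndim == 3 else fz / 2.0
            gz = np.exp(-0.5 * ((zc - pz) / sax) ** 2)
            gy = np.exp(-0.5 * ((yc - py) / slat) ** 2)
            gx = np.exp(-0.5 * ((xc - px) / slat) ** 2)
            g = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
            s = g.sum()
            if s > 0:
                stack += g / s
        if img.shot_noise_photons is not None:
            if rng is None:
                raise ValueError("shot noise requested without an RNG")
            stack = rng.poisson(stack * img.shot_noise_photons).astype(float)
        channels[str(chan)] = stack
    return ConfocalStack(channels, (vx, vy, vz))


# ---------------------------------------------------------------------------
# coupled trajectory pairs


def simulate_trajectory_pairs(n_pairs: int, distances: Sequence[float],
                              motion: MotionModel, n_frames: int,
                              rng: np.random.Generator
                              ) -> Tuple[TrackSet, pd.DataFrame]:
    """Pairs of 2D tracks with distance-dependent coupled displacements.

    Per frame the two displacement vectors are sqrt(c) S + sqrt(1-c) I_i
    with S shared and I_1, I_2 independent isotropic Gaussians (per-axis
    sigma ``step_sigma``), c = c(d) from the motion model; the per-particle
    step variance is thus independent of c.  Measured positions add
    ``loc_noise_sigma`` Gaussian noise per frame.  Returns the track table
    (channels ch1/ch2, pair i -> track ids 2i, 2i+1) and a ground-truth
    frame with each pair's initial distance and coupling c.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    distances = np.broadcast_to(np.asarray(distances, dtype=float), n_pairs)
    c = motion.coupling(distances)
    s = motion.step_sigma
    shared = rng.normal(0.0, s, size=(n_pairs, n_frames - 1, 2))
    ind = rng.normal(0.0, s, size=(2, n_pairs, n_frames - 1, 2))
    w_c = np.sqrt(c)[:, None, None]
    w_i = np.sqrt(1.0 - c)[:, None, None]
    steps1 = w_c * shared + w_i * ind[0]
    steps2 = w_c * shared + w_i * ind[1]
    theta = rng.uniform(0.0, 2 * np.pi, size=n_pairs)
    offset = np.column_stack([np.cos(theta), np.sin(theta)]) * distances[:, None]
    # pairs are laid out on a coarse grid so different pairs never interact
    grid = 50_000.0 * np.column_stack([np.arange(n_pairs) % 1000,
                                       np.arange(n_pairs) // 1000])
    p1 = np.concatenate([grid[:, None, :],
                         grid[:, None, :] + np.cumsum(steps1, axis=1)], axis=1)
    p2 = np.concatenate([(grid + offset)[:, None, :],
                         (grid + offset)[:, None, :] + np.cumsum(steps2, axis=1)],
                        axis=1)
    if motion.confinement_radius is not None:
        for p, org in ((p1, grid), (p2, grid + offset)):
            rel = p - org[:, None, :]
            r = np.linalg.norm(rel, axis=-1, keepdims=True)
            over = r > motion.confinement_radius
            np.divide(rel * motion.confinement_radius, r, out=rel, where=over)
            p[...] = np.where(over, org[:, None, :] + rel, p)
    if motion.loc_noise_sigma > 0:
        p1 = p1 + rng.normal(0.0, motion.loc_noise_sigma, size=p1.shape)
        p2 = p2 + rng.normal(0.0, motion.loc_noise_sigma, size=p2.shape)
    frames = np.arange(n_frames)
    tid = np.repeat(np.arange(n_pairs), n_frames)
    fr = np.tile(frames, n_pairs)
    data = pd.DataFrame({
        "track_id": np.concatenate([2 * tid, 2 * tid + 1]),
        "channel": np.repeat(["ch1", "ch2"], n_pairs * n_frames),
        "frame": np.concatenate([fr, fr]),
        "x_nm": np.concatenate([p1[..., 0].ravel(), p2[..., 0].ravel()]),
        "y_nm": np.concatenate([p1[..., 1].ravel(), p2[..., 1].ravel()]),
    })
    truth = pd.DataFrame({"pair": np.arange(n_pairs), "track1": 2 * np.arange(n_pairs),
                          "track2": 2 * np.arange(n_pairs) + 1,
                          "distance_nm": distances, "coupling": c})
    return TrackSet(data, motion.frame_interval), truth


# ---------------------------------------------------------------------------
# combed fibers


def simulate_combed_fibers(true_lengths_kbp: Sequence[float], rate_kb_per_um: float,
                           length_noise_cv: float, rng: np.random.Generator,
                           n_per_class: int = 1) -> FiberMeasurements:
    """Measured fiber lengths: true_kbp / rate, with multiplicative Gaussian
    measurement noise of the given coefficient of variation."""
    if rate_kb_per_um <= 0:
        raise ValueError("stretching rate must be > 0")
    rows = []
    for kbp in true_lengths_kbp:
        base = kbp / rate_kb_per_um
        noise = 1.0 + rng.normal(0.0, length_noise_cv, size=n_per_class) \
            if length_noise_cv > 0 else np.ones(n_per_class)
        for L in base * noise:
            rows.append({"length_um": float(L), "known_kbp": float(kbp),
                         "label": f"{kbp}kbp"})
    return FiberMeasurements(pd.DataFrame(rows))
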