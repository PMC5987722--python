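"""Mechanical coupling of neighboring replication domains from live tracks.

For every cross-channel pair of RD trajectories the correlation angle
alpha_t between the two simultaneous displacement vectors is computed per
time step (0 deg = fully coupled, mean 90 deg = uncoupled).  Pair means
(mean separation, mean alpha) populate the coupling profile <alpha>(d);
two independent regression lines — on pairs closer than 400 nm and
farther than 600 nm — intersect at the coupling transition point
(d*, alpha*), the distance beyond which motion correlation is lost.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class TrackSet:
    """Particle tracks: one row per (track, frame) with nm positions.

    ``data`` columns: track_id, channel, frame, x_nm, y_nm.  Frames within
    a track are strictly increasing.
    """

    data: pd.DataFrame
    frame_interval: float = 0.5    # s

    def __post_init__(self):
        required = {"track_id", "channel", "frame", "x_nm", "y_nm"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"track table missing columns {sorted(missing)}")
        if len(self.data):
            d = self.data.sort_values("track_id", kind="stable")
            same = d["track_id"].to_numpy()[1:] == d["track_id"].to_numpy()[:-1]
            if np.any(same & (np.diff(d["frame"].to_numpy()) <= 0)):
                raise ValueError("within-track frames must be strictly increasing")

    def tracks(self, channel: Optional[str] = None):
        d = self.data if channel is None else self.data[self.data["channel"] == channel]
        return {tid: g.sort_values("frame") for tid, g in d.groupby("track_id")}


@dataclass
class TrajectoryPair:
    """A cross-channel track pair over their (possibly truncated) overlap."""

    track_ids: Tuple[object, object]
    frames: np.ndarray             # (n,) common frame indices
    pos1: np.ndarray               # (n, 2) nm
    pos2: np.ndarray               # (n, 2) nm


@dataclass
class TransitionFit:
    found: bool
    d_star_nm: float = float("nan")
    alpha_star_deg: float = float("nan")
    near_slope: float = float("nan")
    near_intercept: float = float("nan")
    far_slope: float = float("nan")
    far_intercept: float = float("nan")
    n_near: int = 0
    n_far: int = 0


@dataclass
class CouplingProfile:
    """Per-pair (mean distance, mean alpha) points plus a binned display curve."""

    mean_distance_nm: np.ndarray
    mean_alpha_deg: np.ndarray
    bin_centers_nm: np.ndarray
    bin_mean_deg: np.ndarray
    bin_sd_deg: np.ndarray
    bin_n: np.ndarray
    bin_width_nm: float

    @property
    def n_pairs(self) -> int:
        return len(self.mean_distance_nm)

    @property
    def sparse_bins(self) -> np.ndarray:
        """Centers of display bins backed by fewer than 3 pairs."""
        return self.bin_centers_nm[self.bin_n < 3]


# ---------------------------------------------------------------------------


def link_tracks(detections: pd.DataFrame, max_step: float,
                frame_interval: float = 0.5) -> TrackSet:
    """Greedy frame-to-frame nearest-neighbor linking within ``max_step`` nm.

    No gap closing: a track ends on its first miss.  Equidistant candidate
    detections resolve to the lower row index (logged).  Channels are
    linked independently.  ``detections`` columns: frame, channel, x_nm,
    y_nm.
    """
    if detections["frame"].nunique() < 2:
        raise ValueError("need detections in at least two frames")
    rows = []
    next_id = 0
    for channel, det in detections.groupby("channel"):
        frames = np.sort(det["frame"].unique())
        active: List[Tuple[int, float, float]] = []   # (track_id, x, y)
        prev_frame = None
        for f in frames:
            cur = det[det["frame"] == f][["x_nm", "y_nm"]].to_numpy()
            claimed = np.zeros(len(cur), dtype=bool)
            new_active: List[Tuple[int, float, float]] = []
            if prev_frame is not None and f == prev_frame + 1:
                for tid, px, py in active:
                    d = np.hypot(cur[:, 0] - px, cur[:, 1] - py)
                    d[claimed] = np.inf
                    if len(d) == 0 or d.min() > max_step:
                        continue
                    j = int(np.argmin(d))        # argmin: lowest index on ties
                    if (d == d.min()).sum() > 1:
                        log.info("ambiguous link at frame %s: tie at %.3f nm", f, d.min())
                    claimed[j] = True
                    new_active.append((tid, cur[j, 0], cur[j, 1]))
                    rows.append((tid, channel, f, cur[j, 0], cur[j, 1]))
            for j in np.nonzero(~claimed)[0]:
                rows.append((next_id, channel, f, cur[j, 0], cur[j, 1]))
                new_active.append((next_id, cur[j, 0], cur[j, 1]))
                next_id += 1
            active = new_active
            prev_frame = f
    data = pd.DataFrame(rows, columns=["track_id", "channel", "frame", "x_nm", "y_nm"])
    return TrackSet(data, frame_interval)


def pair_trajectories(tracks: TrackSet, min_duration: float = 15.0,
                      max_duration: float = 50.0,
                      max_pair_distance: float = float("inf"),
                      channels: Tuple[str, str] = ("ch1", "ch2")
                      ) -> List[TrajectoryPair]:
    """Cross-channel pairs with a usable temporal overlap.

    The overlap duration (steps x frame interval) must reach
    ``min_duration`` seconds; overlaps longer than ``max_duration`` are
    truncated to that length from their start.  Pairs whose mean
    separation over the kept overlap exceeds ``max_pair_distance`` are
    dropped.
    """
    dt = tracks.frame_interval
    t1 = tracks.tracks(channels[0])
    t2 = tracks.tracks(channels[1])
    max_steps = int(round(max_duration / dt))
    ids1 = list(t1)
    ids2 = list(t2)
    a1 = {tid: (g["frame"].to_numpy(), g[["x_nm", "y_nm"]].to_numpy())
          for tid, g in t1.items()}
    a2 = {tid: (g["frame"].to_numpy(), g[["x_nm", "y_nm"]].to_numpy())
          for tid, g in t2.items()}
    # exact prefilter: a pair's mean separation is at least the distance
    # between the two tracks' bounding boxes, so boxes farther apart than
    # max_pair_distance can never qualify (vectorized over all id pairs)
    if np.isfinite(max_pair_distance) and ids1 and ids2:
        def boxes(a, ids):
            return np.array([[a[t][1][:, 0].min(), a[t][1][:, 0].max(),
                              a[t][1][:, 1].min(), a[t][1][:, 1].max()]
                             for t in ids])
        b1 = boxes(a1, ids1)
        b2 = boxes(a2, ids2)
        gx = np.maximum(0.0, np.maximum(b1[:, None, 0] - b2[None, :, 1],
                                        b2[None, :, 0] - b1[:, None, 1]))
        gy = np.maximum(0.0, np.maximum(b1[:, None, 2] - b2[None, :, 3],
                                        b2[None, :, 2] - b1[:, None, 3]))
        cand = np.hypot(gx, gy) <= max_pair_distance
        candidates = [(ids1[i], ids2[j]) for i, j in zip(*np.nonzero(cand))]
    else:
        candidates = [(i, j) for i in ids1 for j in ids2]
    pairs = []
    for id1, id2 in candidates:
        f1, pos1 = a1[id1]
        f2, pos2 = a2[id2]
        common, i1, i2 = np.intersect1d(f1, f2, return_indices=True)
        if len(common) < 2:
            continue
        if (len(common) - 1) * dt < min_duration:
            continue
        if len(common) - 1 > max_steps:
            common = common[:max_steps + 1]
            i1 = i1[:max_steps + 1]
            i2 = i2[:max_steps + 1]
        p1 = pos1[i1]
        p2 = pos2[i2]
        if np.mean(np.linalg.norm(p1 - p2, axis=1)) > max_pair_distance:
            continue
        pairs.append(TrajectoryPair((id1, id2), common, p1, p2))
    return pairs


def correlation_angles(pair: TrajectoryPair
                       ) -> Tuple[np.ndarray, float, float, int]:
    """Per-step correlation angles of one pair.

    alpha_t = arccos(u.v / |u||v|) in degrees for the simultaneous
    displacement vectors u, v; steps where either displacement is exactly
    zero are skipped (alpha undefined) and counted.  Returns
    (alpha series, mean alpha, mean separation, number of skipped steps).
    """
    u = np.diff(pair.pos1, axis=0)
    v = np.diff(pair.pos2, axis=0)
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 0) & (nv > 0)
    if not ok.any():
        warnings.warn("trajectory pair has no defined displacement steps")
        return np.empty(0), float("nan"), float("nan"), int((~ok).sum())
    cosang = np.clip((u[ok] * v[ok]).sum(axis=1) / (nu[ok] * nv[ok]), -1.0, 1.0)
    alpha = np.degrees(np.arccos(cosang))
    mean_dist = float(np.mean(np.linalg.norm(pair.pos1 - pair.pos2, axis=1)))
    return alpha, float(alpha.mean()), mean_dist, int((~ok).sum())


def coupling_profile(pairs: Sequence[TrajectoryPair], bin_width: float = 50.0
                     ) -> CouplingProfile:
    """Per-pair (mean distance, mean alpha) points plus the binned curve.

    The per-pair points stay unbinned (regression uses them directly); the
    binned means/SDs are for display, with bins of fewer than 3 pairs
    flagged.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two trajectory pairs")
    d, a = [], []
    for p in pairs:
        _, ma, md, _ = correlation_angles(p)
        if np.isfinite(ma):
            d.append(md)
            a.append(ma)
    d = np.asarray(d)
    a = np.asarray(a)
    edges = np.arange(0.0, d.max() + bin_width, bin_width)
    idx = np.digitize(d, edges) - 1
    centers, means, sds, ns = [], [], [], []
    for b in range(len(edges) - 1):
        m = idx == b
        if not m.any():
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        means.append(a[m].mean())
        sds.append(a[m].std(ddof=1) if m.sum() > 1 else 0.0)
        ns.append(int(m.sum()))
    return CouplingProfile(d, a, np.asarray(centers), np.asarray(means),
                           np.asarray(sds), np.asarray(ns), bin_width)


def fit_transition(profile: CouplingProfile, near_cut: float = 400.0,
                   far_cut: float = 600.0, use_binned: bool = False,
                   slope_tol: float = 1e-6) -> TransitionFit:
    """Two-regime regression and its intersection, the coupling transition.

    Ordinary least squares of mean alpha on mean distance for pairs closer
    than ``near_cut`` and, independently, farther than ``far_cut`` (the
    400-600-nm gap enters neither fit); the transition (d*, alpha*) is the
    exact intersection of the two lines.  Near-parallel lines (slope
    difference below ``slope_tol``) yield ``found=False``.
    """
    if use_binned:
        x, y = profile.bin_centers_nm, profile.bin_mean_deg
    else:
        x, y = profile.mean_distance_nm, profile.mean_alpha_deg
    near = x < near_cut
    far = x > far_cut
    if near.sum() < 2 or far.sum() < 2:
        raise ValueError("need at least 2 points on each side of the cuts")
    mA, bA = np.polyfit(x[near], y[near], 1)
    mB, bB = np.polyfit(x[far], y[far], 1)
    fit = TransitionFit(False, near_slope=mA, near_intercept=bA,
                        far_slope=mB, far_intercept=bB,
                        n_near=int(near.sum()), n_far=int(far.sum()))
    if abs(mA - mB) < slope_tol:
        return fit
    d_star = (bB - bA) / (mA - mB)
    fit.found = True
    fit.d_star_nm = float(d_star)
    fit.alpha_star_deg = float(mA * d_star + bA)
    return fit


def resample_time_step(tracks: TrackSet, step: float) -> TrackSet:
    """Keep every k-th frame (k = step / frame_interval), e.g. for the
    10-s reanalysis control; the downstream analysis is unchanged."""
    dt = tracks.frame_interval
    if step < dt:
        raise ValueError("step must be at least the frame interval")
    k = step / dt
    if abs(k - round(k)) > 1e-9:
        raise ValueError("step must be an integer multiple of the frame interval")
    k = int(round(k))
    if k == 1:
        return tracks
    keep = (tracks.data["frame"] % k) == 0
    return TrackSet(tracks.data[keep].reset_index(drop=True), step)
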