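"""Correlative confocal-STORM overlay.

The STORM image is 2D while the confocal stack covers the whole nuclear
volume; because the STORM microscope runs in epifluorescence the events
come from a ~1-um slab around the focal plane.  The overlay therefore (1)
resamples the confocal slices to the STORM pixel grid, (2) forms moving
sum-intensity z-projections over a sliding window, (3) rigid-registers
each projection against the STORM image, and (4) keeps the window with the
highest normalized cross-correlation.  Regions outside the chosen window
(out-of-focus structure) are cropped away via per-territory ROI polygons.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.transform import rotate as _sk_rotate

from .storm_qc import EventList, RenderedImage, _xcorr_shift

log = logging.getLogger(__name__)


@dataclass
class ConfocalStack:
    """Per-channel 3D voxel arrays, axis order (z, y, x), voxel sizes in nm."""

    channels: Dict[str, np.ndarray]
    voxel: Tuple[float, float, float] = (90.0, 90.0, 200.0)   # (x, y, z) nm

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel):
            raise ValueError("voxel sizes must be > 0")

    @property
    def n_slices(self) -> int:
        return next(iter(self.channels.values())).shape[0]


@dataclass
class RigidTransform:
    """Rotation (degrees, about image center) + translation (nm) with its NCC score."""

    rotation_deg: float
    translation_nm: Tuple[float, float]    # (dx, dy)
    score: float


@dataclass
class OverlayResult:
    window: Tuple[int, int]                # chosen substack [z_start, z_end)
    scores: List[float]                    # per-projection best NCC
    transform: RigidTransform
    crops: Optional[List[np.ndarray]] = None


# ---------------------------------------------------------------------------


def rescale_confocal(stack: ConfocalStack, channel: str,
                     target_pixel: float = 10.0,
                     flip: Tuple[bool, bool] = (False, False)) -> List[np.ndarray]:
    """Resample each confocal slice to the STORM pixel grid.

    Linear interpolation, value-preserving (a constant slice stays at the
    same value; pixel *sums* therefore scale with the resampling ratio
    squared — the NCC downstream is intensity-scale invariant anyway).
    ``flip = (flip_x, flip_y)`` mirrors the slices to match the STORM
    camera orientation.
    """
    if target_pixel > stack.voxel[0]:
        raise ValueError("target_pixel must not exceed the source pixel")
    zoom = (stack.voxel[1] / target_pixel, stack.voxel[0] / target_pixel)
    out = []
    for sl in stack.channels[channel]:
        sl = np.asarray(sl, dtype=float)
        if flip[0]:
            sl = sl[:, ::-1]
        if flip[1]:
            sl = sl[::-1, :]
        out.append(ndimage.zoom(sl, zoom, order=1, grid_mode=True, mode="nearest"))
    return out


def moving_projections(slices: Sequence[np.ndarray], window: int = 5) -> List[np.ndarray]:
    """Sliding-window sum-intensity z-projections (window of 5 slices)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(slices) < window:
        raise ValueError("need at least `window` slices")
    arr = np.asarray(slices, dtype=float)
    return [arr[i:i + window].sum(axis=0) for i in range(len(slices) - window + 1)]


def _ncc_at_shift(fixed: np.ndarray, moving: np.ndarray, dr: int, dc: int) -> float:
    """Pearson correlation of the overlapping support after an integer shift."""
    rows, cols = fixed.shape
    # moving[i + d] overlays fixed[i] when moving is displaced by +d
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    if r1 - r0 < 2 or c1 - c0 < 2:
        return -1.0
    a = fixed[r0:r1, c0:c1]
    b = moving[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return -1.0
    return float((a * b).sum() / denom)


def register_rigid(moving: np.ndarray, fixed: np.ndarray, pixel: float = 10.0,
                   rot_range_deg: float = 5.0, rot_step_deg: float = 0.5,
                   init: Optional[RigidTransform] = None) -> RigidTransform:
    """Rotation + translation maximizing the NCC of ``moving`` onto ``fixed``.

    Coarse search: FFT cross-correlation over a rotation grid (default
    +/-5 deg in 0.5-deg steps); the rotation score is refined by a parabolic
    fit through the best grid point and the translation by a quadratic fit
    of the correlation peak.  No scaling — pixel calibration is trusted.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        # pad to a common shape (top-left anchored)
        rows = max(moving.shape[0], fixed.shape[0])
        cols = max(moving.shape[1], fixed.shape[1])
        m = np.zeros((rows, cols)); m[:moving.shape[0], :moving.shape[1]] = moving
        f = np.zeros((rows, cols)); f[:fixed.shape[0], :fixed.shape[1]] = fixed
        moving, fixed = m, f
    if moving.std() == 0 or fixed.std() == 0:
        raise ValueError("no contrast: constant image cannot be registered")
    init_rot = init.rotation_deg if init is not None else 0.0
    angles = init_rot + np.arange(-rot_range_deg, rot_range_deg + rot_step_deg / 2,
                                  rot_step_deg)

    def evaluate(angle: float) -> Tuple[float, float, float]:
        rot = _sk_rotate(moving, angle, preserve_range=True, order=1)
        dr, dc = _xcorr_shift(fixed, rot)
        score = _ncc_at_shift(fixed, rot, int(round(dr)), int(round(dc)))
        return score, dr, dc

    results = [evaluate(a) for a in angles]
    scores = np.array([r[0] for r in results])
    k = int(np.argmax(scores))
    best_angle = angles[k]
    if 0 < k < len(angles) - 1:
        cm, c0, cp = scores[k - 1], scores[k], scores[k + 1]
        denom = cm - 2 * c0 + cp
        if denom < 0:
            best_angle = angles[k] + 0.5 * (cm - cp) / denom * rot_step_deg
    score, dr, dc = evaluate(best_angle)
    # convention: rotation_deg is the counterclockwise rotation applied to
    # `moving` that aligns it; translation_nm is the residual displacement of
    # the rotated moving image relative to fixed (shift by its negative to
    # overlay them).
    return RigidTransform(float(best_angle), (dc * pixel, dr * pixel), score)


def select_best_substack(projections: Sequence[np.ndarray], storm_image: np.ndarray,
                         window: int = 5, pixel: float = 10.0,
                         **reg_kwargs) -> OverlayResult:
    """Register every moving projection and keep the best-correlating window.

    Ties (equal best NCC) resolve toward the lower z-start and are logged.
    """
    if len(projections) == 0:
        raise ValueError("need at least one projection")
    transforms = []
    scores = []
    for proj in projections:
        try:
            tf = register_rigid(proj, storm_image, pixel=pixel, **reg_kwargs)
        except ValueError:
            tf = RigidTransform(0.0, (0.0, 0.0), -np.inf)
        transforms.append(tf)
        scores.append(tf.score)
    if not np.isfinite(np.max(scores)):
        raise ValueError("all projection registrations failed")
    best = int(np.argmax(scores))   # argmax returns the first (lowest z) maximum
    if np.sum(np.asarray(scores) == scores[best]) > 1:
        log.info("substack NCC tie at score %.4f; keeping lower z-start %d",
                 scores[best], best)
    return OverlayResult((best, best + window), [float(s) for s in scores],
                         transforms[best])


def crop_to_rois(storm_image: np.ndarray | RenderedImage,
                 rois: Sequence[Sequence[Tuple[float, float]]]) -> List[np.ndarray]:
    """Mask the STORM image with per-territory ROI polygons (pixel coords).

    Each polygon is a sequence of (x, y) vertices in pixel coordinates of
    the STORM frame; pixels outside the polygon are zeroed.  Degenerate or
    empty ROIs are skipped with a warning.
    """
    img = storm_image.counts if isinstance(storm_image, RenderedImage) else storm_image
    out = []
    for i, poly in enumerate(rois):
        pts = np.asarray(poly, dtype=float)
        if pts.ndim != 2 or len(pts) < 3:
            warnings.warn(f"ROI {i} is degenerate; skipped")
            continue
        # polygon2mask takes (row, col) vertices
        mask = polygon2mask(img.shape, pts[:, ::-1])
        if not mask.any():
            warnings.warn(f"ROI {i} covers no pixels; skipped")
            continue
        out.append(np.where(mask, img, 0))
    return out


def events_in_roi(events: EventList, roi_polygon_px: Sequence[Tuple[float, float]],
                  pixel: float = 10.0,
                  origin: Tuple[float, float] = (0.0, 0.0)) -> EventList:
    """Event-space counterpart of :func:`crop_to_rois` (matplotlib-free point test)."""
    from shapely.geometry import Point, Polygon
    poly = Polygon(roi_polygon_px)
    px = (events.x - origin[0]) / pixel
    py = (events.y - origin[1]) / pixel
    mask = np.array([poly.covers(Point(cx, cy)) for cx, cy in zip(px, py)])
    return events.select(mask)


def load_rois_geojson(path) -> List[List[Tuple[float, float]]]:
    """Read ROI polygons (STORM-frame pixel coordinates) from a GeoJSON file."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    polys = []
    for feat in feats:
        geom = feat.get("geometry", feat)
        if geom["type"] != "Polygon":
            continue
        polys.append([tuple(pt) for pt in geom["coordinates"][0]])
    return polys
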