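"""Quality control of STORM localization streams.

The single-molecule acquisition produces an *event list*: one row per
localization with its frame index, position (nm) and photon count.  Before
any morphometry the stream is gated on photon count (localization
precision), corrected for lateral stage drift with a correlation-based
block routine, rendered into a 2D count histogram (one gray value per
event, 10-nm pixels), and finally gated on image resolution estimated by
Fourier ring correlation (FRC).

Pixel convention (package-wide): half-open binning, origin at the top-left
pixel edge, x increases with column index, y with row index; positions are
continuous nm.  An event at x = 100.0 with 10-nm pixels falls into column
10 (the higher-index pixel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class EventList:
    """STORM localizations: per-event frame, position (nm) and photon count.

    ``stretch_id`` optionally carries the ground-truth emitter identity of
    each event (filled in by the synthetic generator, ``-1`` otherwise);
    downstream analysis never reads it, tests do.
    """

    frame: np.ndarray          # (n,) int
    x: np.ndarray              # (n,) float, nm
    y: np.ndarray              # (n,) float, nm
    photons: np.ndarray        # (n,) float
    n_frames: int
    pixel_hint: float = 10.0   # nm, preferred rendering pixel
    stretch_id: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.frame)
        for name in ("x", "y", "photons"):
            if len(getattr(self, name)) != n:
                raise ValueError("event columns must have equal length")
        if n:
            if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y)):
                raise ValueError("positions must be finite")
            if self.frame.min() < 0 or self.frame.max() >= self.n_frames:
                raise ValueError("frames must lie in [0, n_frames)")

    def __len__(self) -> int:
        return len(self.frame)

    def select(self, mask: np.ndarray) -> "EventList":
        sid = None if self.stretch_id is None else self.stretch_id[mask]
        return EventList(self.frame[mask], self.x[mask], self.y[mask],
                         self.photons[mask], self.n_frames, self.pixel_hint, sid)


@dataclass
class RenderedImage:
    """2D event-count histogram: integer counts, pixel size and origin in nm."""

    counts: np.ndarray         # (rows, cols)
    pixel: float               # nm
    origin: Tuple[float, float] = (0.0, 0.0)   # nm offset of pixel (0, 0)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.counts.shape


@dataclass
class DriftEstimate:
    """Per-block lateral drift (nm) relative to the first temporal block."""

    block_centers: np.ndarray  # (b,) frame coordinate of each block center
    dx: np.ndarray             # (b,) nm
    dy: np.ndarray             # (b,) nm
    residual_nm: float         # max block displacement after correction

    def trajectory(self, frames: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Interpolated (dx, dy) at arbitrary frame coordinates."""
        return (np.interp(frames, self.block_centers, self.dx),
                np.interp(frames, self.block_centers, self.dy))


@dataclass
class FRCResult:
    frequency: np.ndarray      # (q,) 1/nm
    frc: np.ndarray            # (q,) correlation per ring
    threshold: np.ndarray      # (q,) threshold curve
    resolution_nm: float       # nan when undefined
    passed: bool
    max_resolution_nm: float = 50.0


# ---------------------------------------------------------------------------
# operations


def filter_by_photons(events: EventList, min_photons: float = 500) -> EventList:
    """Drop events below the photon-count gate (default 500 photons).

    Events at exactly the threshold are kept; order is preserved.
    """
    if min_photons < 0:
        raise ValueError("min_photons must be >= 0")
    return events.select(events.photons >= min_photons)


def render(events: EventList, pixel: float = 10.0,
           roi: Optional[Tuple[float, float, float, float]] = None) -> RenderedImage:
    """Histogram events into a count image (one gray value per event).

    ``roi`` is an (x0, y0, x1, y1) rectangle in nm defining the grid origin
    and extent; without it the grid is anchored at (0, 0) for non-negative
    coordinates (floored to the pixel grid otherwise) and sized to the data.
    Events outside the roi are dropped (their number is not part of the
    image; the pixel sum equals the number of rendered events).
    """
    if pixel <= 0:
        raise ValueError("pixel must be > 0")
    if roi is not None:
        x0, y0, x1, y1 = roi
        if x1 <= x0 or y1 <= y0:
            raise ValueError("roi must have positive area")
    elif len(events) == 0:
        x0 = y0 = 0.0
        x1 = y1 = pixel
    else:
        x0 = min(0.0, np.floor(events.x.min() / pixel) * pixel)
        y0 = min(0.0, np.floor(events.y.min() / pixel) * pixel)
        x1 = events.x.max() + pixel
        y1 = events.y.max() + pixel
    cols = int(np.ceil((x1 - x0) / pixel))
    rows = int(np.ceil((y1 - y0) / pixel))
    ci = np.floor((events.x - x0) / pixel).astype(int)
    ri = np.floor((events.y - y0) / pixel).astype(int)
    # half-open roi semantics: the grid may overhang x1/y1 by a partial
    # pixel, but events beyond the roi itself are dropped
    keep = ((ci >= 0) & (ci < cols) & (ri >= 0) & (ri < rows)
            & (events.x >= x0) & (events.x < x1)
            & (events.y >= y0) & (events.y < y1))
    img = np.zeros((rows, cols), dtype=np.int64)
    np.add.at(img, (ri[keep], ci[keep]), 1)
    return RenderedImage(img, pixel, (x0, y0))


def _xcorr_shift(reference: np.ndarray, moving: np.ndarray) -> Tuple[float, float]:
    """Sub-pixel (row, col) displacement of ``moving`` relative to ``reference``.

    FFT cross-correlation peak, refined by a quadratic fit of the 3x3
    neighborhood along each axis.  Positive result means ``moving`` is
    shifted toward larger indices.
    """
    a = reference.astype(float)
    b = moving.astype(float)
    a = a - a.mean()
    b = b - b.mean()
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    corr = np.fft.irfft2(fb * np.conj(fa), s=a.shape)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    out = []
    for axis, p in enumerate(peak):
        n = corr.shape[axis]
        cm = corr[(p - 1) % n if axis == 0 else peak[0],
                  peak[1] if axis == 0 else (p - 1) % n]
        c0 = corr[peak]
        cp = corr[(p + 1) % n if axis == 0 else peak[0],
                  peak[1] if axis == 0 else (p + 1) % n]
        denom = cm - 2 * c0 + cp
        delta = 0.0 if denom == 0 else 0.5 * (cm - cp) / denom
        delta = float(np.clip(delta, -1, 1))
        shift = p + delta
        if shift > n / 2:
            shift -= n
        out.append(shift)
    return out[0], out[1]


def _block_shifts(events: EventList, edges: np.ndarray, roi, render_pixel: float
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimate per-block (dx, dy) in nm against the first non-empty block."""
    n_blocks = len(edges) - 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    dx = np.full(n_blocks, np.nan)
    dy = np.full(n_blocks, np.nan)
    ref = None
    ref_idx = None
    for i in range(n_blocks):
        mask = (events.frame >= edges[i]) & (events.frame < edges[i + 1])
        if not mask.any():
            warnings.warn(f"drift block {i} has no events; interpolating its shift")
            continue
        img = render(events.select(mask), render_pixel, roi).counts
        if ref is None:
            ref, ref_idx = img, i
            dx[i] = dy[i] = 0.0
            continue
        dr, dc = _xcorr_shift(ref, img)
        dx[i] = dc * render_pixel
        dy[i] = dr * render_pixel
    if ref is None:
        raise ValueError("no events in any drift block")
    good = np.isfinite(dx)
    if good.sum() < n_blocks:
        dx = np.interp(centers, centers[good], dx[good])
        dy = np.interp(centers, centers[good], dy[good])
    # anchor the trajectory at the first block
    dx = dx - dx[0]
    dy = dy - dy[0]
    return centers, dx, dy


def estimate_and_correct_drift(events: EventList, block_frames: int,
                               render_pixel: float = 10.0
                               ) -> Tuple[EventList, DriftEstimate]:
    """Correlation-based lateral drift correction in temporal blocks.

    The movie is cut into blocks of ``block_frames`` frames; each block is
    rendered on a common grid and its displacement against the first block
    estimated from the cross-correlation peak (sub-pixel).  The per-event
    correction interpolates the block trajectory at the event's frame.
    ``residual_nm`` re-runs the estimate on the corrected stream and
    reports the largest remaining block displacement (Euclidean norm).
    """
    if block_frames < 1:
        raise ValueError("block_frames must be >= 1")
    if events.n_frames < 2 * block_frames:
        raise ValueError("need at least two blocks of frames")
    if len(events) == 0:
        raise ValueError("empty event list")
    edges = np.arange(0, events.n_frames + block_frames, block_frames, dtype=float)
    edges[-1] = max(edges[-1], events.n_frames)
    pad = 4 * render_pixel
    roi = (events.x.min() - pad, events.y.min() - pad,
           events.x.max() + pad, events.y.max() + pad)
    centers, dx, dy = _block_shifts(events, edges, roi, render_pixel)
    ex = events.x - np.interp(events.frame, centers, dx)
    ey = events.y - np.interp(events.frame, centers, dy)
    corrected = EventList(events.frame, ex, ey, events.photons,
                          events.n_frames, events.pixel_hint, events.stretch_id)
    _, rdx, rdy = _block_shifts(corrected, edges, roi, render_pixel)
    residual = float(np.max(np.hypot(rdx, rdy)))
    return corrected, DriftEstimate(centers, dx, dy, residual)


def _radial_bins(shape: Tuple[int, int]) -> Tuple[np.ndarray, int]:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    q = np.hypot(fy, fx)
    n = min(shape) // 2
    ring = np.minimum((q * min(shape)).astype(int), n)
    return ring, n


def frc_curve(img1: np.ndarray, img2: np.ndarray
              ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fourier ring correlation of two equally-shaped images.

    Returns (ring index array, FRC per ring, pixels per ring); ring q
    collects spatial frequencies |f| in [q, q+1) / (N * pixel).
    """
    if img1.shape != img2.shape:
        raise ValueError("images must share a shape")
    f1 = np.fft.fft2(img1.astype(float))
    f2 = np.fft.fft2(img2.astype(float))
    ring, n = _radial_bins(img1.shape)
    flat = ring.ravel()
    num = np.bincount(flat, weights=(f1 * np.conj(f2)).real.ravel(), minlength=n + 1)
    p1 = np.bincount(flat, weights=np.abs(f1).ravel() ** 2, minlength=n + 1)
    p2 = np.bincount(flat, weights=np.abs(f2).ravel() ** 2, minlength=n + 1)
    npix = np.bincount(flat, minlength=n + 1)
    denom = np.sqrt(p1 * p2)
    frc = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    return np.arange(1, n), frc[1:n], npix[1:n]


def frc_resolution(events: EventList, pixel: float = 10.0,
                   threshold_rule: str = "3sigma",
                   max_resolution_nm: float = 50.0,
                   smooth_rings: int = 5) -> FRCResult:
    """FRC resolution of an event list, split into two temporal halves.

    Events are ordered by frame (stable) and split in half; each half is
    rendered on a common square grid; the correlation per frequency ring is
    compared against the threshold curve (``"3sigma"``: 3/sqrt(N_q / 2)
    with N_q pixels in ring q, or the fixed ``"fixed_1_over_7"`` rule).
    The resolution is 1/q* at the first crossing below the threshold; a
    curve that never drops below it resolves to the finest representable
    scale (two pixels).  ``passed`` applies the resolution gate
    (default 50 nm).
    """
    if len(events) < 2:
        raise ValueError("need at least two events")
    order = np.argsort(events.frame, kind="stable")
    half = len(order) // 2
    first = events.select(np.isin(np.arange(len(events)), order[:half]))
    second = events.select(np.isin(np.arange(len(events)), order[half:]))
    if len(first) == 0 or len(second) == 0:
        raise ValueError("both temporal halves must be non-empty")
    allx = events.x
    ally = events.y
    pad = 2 * pixel
    side = max(allx.max() - allx.min(), ally.max() - ally.min()) + 2 * pad
    roi = (allx.min() - pad, ally.min() - pad,
           allx.min() - pad + side, ally.min() - pad + side)
    i1 = render(first, pixel, roi).counts
    i2 = render(second, pixel, roi).counts
    rings, frc, npix = frc_curve(i1, i2)
    if threshold_rule == "3sigma":
        thr = 3.0 / np.sqrt(npix / 2.0)
    elif threshold_rule == "fixed_1_over_7":
        thr = np.full_like(frc, 1.0 / 7.0)
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    if smooth_rings > 1:
        # single-ring estimates are noisy (innermost rings hold only a few
        # pixels, so both curves jitter); the same short moving average on
        # both stabilizes the crossing without displacing it
        kernel = np.ones(smooth_rings) / smooth_rings
        pad = smooth_rings // 2

        def _smooth(c):
            return np.convolve(np.pad(c, pad, mode="edge"), kernel,
                               mode="valid")[:len(rings)]
        frc = _smooth(frc)
        thr = _smooth(thr)
    n_side = i1.shape[0]
    freq = rings / (n_side * pixel)          # cycles / nm
    above = frc >= thr
    # the 3-sigma curve exceeds 1 in the innermost rings (few pixels per
    # ring); the resolution is the first downward crossing after the FRC
    # first clears the threshold curve
    if not above.any():
        resolution = float("nan")
        passed = False
    else:
        start = int(np.argmax(above))
        rest = np.nonzero(~above[start:])[0]
        if rest.size == 0:
            resolution = 2.0 * pixel
            passed = resolution <= max_resolution_nm
        else:
            k = start + int(rest[0])         # first ring back below threshold
            # linear interpolation of the crossing between rings k-1 and k
            d0 = frc[k - 1] - thr[k - 1]
            d1 = frc[k] - thr[k]
            t = d0 / (d0 - d1) if d0 != d1 else 0.0
            qstar = freq[k - 1] + t * (freq[k] - freq[k - 1])
            resolution = float(1.0 / qstar)
            passed = resolution <= max_resolution_nm
    return FRCResult(freq, frc, thr, resolution, passed, max_resolution_nm)
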