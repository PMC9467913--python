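"""Sample-drift estimation and correction by redundant cross-correlation.

Events are split into overlapping time windows of roughly equal event count
(about 2000 events per window on real data).  Each window's event mean
positions are rendered to an image by placing a 2 nm Gaussian at every
position; the relative sample shift between every pair of windows is the
sub-pixel offset of the fitted cross-correlation peak.  A per-window drift
offset is then solved from all pairwise shifts in a least-squares sense
(the redundancy averages down the per-pair estimation error), joined by a
cubic spline over time, and subtracted from the event coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit
from scipy.signal import correlate

from .events import BindingEvent
from .image import RenderedImage, gaussian_render

__all__ = [
    "WindowPairShift",
    "DriftTrace",
    "window_events",
    "render_positions",
    "pairwise_shift",
    "solve_drift",
    "estimate_drift",
    "correct",
]


@dataclass(frozen=True)
class WindowPairShift:
    """Estimated spatial shift of window j relative to window i."""

    i: int
    j: int
    shift: np.ndarray   # nm, (ndim,)
    quality: float      # normalized correlation-peak height in [0, 1]


@dataclass
class DriftTrace:
    """Smooth per-axis drift offset as a function of time.

    Gauge-fixed so the mean offset over the knots is zero; evaluation
    outside the knot span clamps to the end knots.
    """

    times: np.ndarray     # knot times (window centers), s
    offsets: np.ndarray   # (n_knots, ndim), nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.offsets = np.asarray(self.offsets, float)
        order = np.argsort(self.times)
        self.times = self.times[order]
        self.offsets = self.offsets[order]
        self._spline = CubicSpline(self.times, self.offsets, axis=0)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t, float), self.times[0], self.times[-1])
        return np.atleast_2d(self._spline(t))

    @property
    def ndim(self) -> int:
        return self.offsets.shape[1]


def window_events(n_events: int, target_per_window: int = 2000,
                  overlap_fraction: float = 0.5) -> list[tuple[int, int]]:
    """Overlapping index windows ``[start, stop)`` over the event sequence.

    Consecutive windows share ``overlap_fraction`` of their events; every
    event falls in at least one window.  A single window is returned when
    fewer than two fit (downstream drift estimation then refuses).
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if n_events <= 0:
        raise ValueError("no events to window")
    size = min(target_per_window, n_events)
    stride = max(1, int(round(size * (1.0 - overlap_fraction))))
    starts = list(range(0, max(n_events - size, 0) + 1, stride))
    if starts[-1] + size < n_events:
        starts.append(n_events - size)
    return [(s, s + size) for s in starts]


def render_positions(positions: np.ndarray, sigma: float = 2.0,
                     pixel: float = 1.0,
                     bounds: np.ndarray | None = None) -> RenderedImage:
    """Render positions with a 2 nm Gaussian per point (see Methods of the
    drift procedure); thin wrapper over :func:`minfluxpaint.image.gaussian_render`."""
    return gaussian_render(positions, sigma=sigma, pixel=pixel, bounds=bounds)


def _gaussian(x, a, mu, s, c):
    return a * np.exp(-0.5 * ((x - mu) / s) ** 2) + c


def _subpixel_offset(line: np.ndarray, center: int) -> float:
    """Sub-pixel offset of the peak of a 1D correlation profile around
    ``center`` via a Gaussian fit (parabolic fallback)."""
    if center < 1 or center > len(line) - 2:
        return 0.0
    x = np.arange(len(line), dtype=float) - center
    try:
        p0 = (float(line[center] - line.min()), 0.0, 1.5, float(line.min()))
        popt, _ = curve_fit(_gaussian, x, line, p0=p0, maxfev=2000)
        mu = float(popt[1])
        if abs(mu) <= len(line) / 2:
            return mu
    except (RuntimeError, ValueError):
        pass
    # parabola through the three samples around the peak
    y0, y1, y2 = line[center - 1], line[center], line[center + 1]
    denom = y0 - 2 * y1 + y2
    return 0.0 if denom == 0 else float(0.5 * (y0 - y2) / denom)


def pairwise_shift(img_i: RenderedImage, img_j: RenderedImage,
                   i: int = 0, j: int = 1,
                   fit_halfwidth: int = 3) -> WindowPairShift:
    """Shift of ``img_j`` relative to ``img_i`` from the cross-correlation
    peak, refined per axis by a 1D Gaussian fit over ``2*fit_halfwidth + 1``
    samples through the peak.

    A structureless (flat) correlation yields quality 0 and a zero shift;
    callers should drop such pairs before the least-squares solve.
    """
    if not img_i.same_grid(img_j):
        raise ValueError("images must share the same grid")
    a, b = img_i.data, img_j.data
    norm = np.sqrt(float(np.sum(a * a)) * float(np.sum(b * b)))
    if norm == 0:
        return WindowPairShift(i, j, np.zeros(a.ndim), 0.0)
    c = correlate(b, a, mode="full", method="fft")
    peak = np.unravel_index(np.argmax(c), c.shape)
    centers = np.array(a.shape) - 1
    quality = float(c[peak] / norm)
    m = fit_halfwidth
    shift_px = np.empty(a.ndim)
    for ax in range(a.ndim):
        idx = list(peak)
        lo = max(peak[ax] - m, 0)
        hi = min(peak[ax] + m + 1, c.shape[ax])
        sl = tuple(slice(lo, hi) if k == ax else idx[k]
                   for k in range(a.ndim))
        line = np.asarray(c[sl], float)
        shift_px[ax] = peak[ax] + _subpixel_offset(line, peak[ax] - lo) \
            - centers[ax]
    return WindowPairShift(i, j, shift_px * img_i.pixel, quality)


def _connected(n: int, pairs: list[tuple[int, int]]) -> list[set[int]]:
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in pairs:
        parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for k in range(n):
        comps.setdefault(find(k), set()).add(k)
    return list(comps.values())


def solve_drift(shifts: list[WindowPairShift],
                window_times: np.ndarray) -> DriftTrace:
    """Least-squares per-window offsets from all pairwise shifts.

    Minimizes ``sum_(i,j) || p_j - p_i - d_ij ||^2`` subject to the gauge
    ``mean(p) = 0`` and joins the solution with a cubic spline over the
    window-center times.  Raises if the pair graph does not connect all
    windows.
    """
    window_times = np.asarray(window_times, float)
    nw = len(window_times)
    if nw < 2:
        raise ValueError("need at least two windows to estimate drift")
    if not shifts:
        raise ValueError("no pairwise shifts supplied")
    comps = _connected(nw, [(s.i, s.j) for s in shifts])
    if len(comps) > 1:
        raise ValueError("pairwise-shift graph is disconnected; components: "
                         + ", ".join(str(sorted(c)) for c in comps))
    ndim = len(shifts[0].shift)
    rows = len(shifts) + 1
    A = np.zeros((rows, nw))
    d = np.zeros((rows, ndim))
    for r, s in enumerate(shifts):
        A[r, s.j] = 1.0
        A[r, s.i] = -1.0
        d[r] = s.shift
    A[-1, :] = 1.0  # gauge row: offsets sum to zero
    p, *_ = np.linalg.lstsq(A, d, rcond=None)
    p -= p.mean(axis=0)
    return DriftTrace(times=window_times, offsets=p)


def estimate_drift(events: list[BindingEvent],
                   target_per_window: int = 2000,
                   overlap_fraction: float = 0.5,
                   sigma: float = 2.0,
                   pixel: float | None = None,
                   quality_threshold: float = 0.05,
                   ndim: int | None = None) -> DriftTrace:
    """End-to-end drift estimation from binding events.

    Renders one image per event window from the event mean positions (one
    point per trace ID) on a common grid, estimates all pairwise shifts,
    drops low-quality pairs and solves for the drift curve.
    """
    if len(events) < 2:
        raise ValueError("not enough events")
    positions = np.array([e.mean_pos for e in events])
    times = np.array([e.t_start for e in events])
    if ndim is None:
        ndim = positions.shape[1]
    if pixel is None:
        pixel = 1.0 if ndim == 2 else 2.0
    windows = window_events(len(events), target_per_window, overlap_fraction)
    if len(windows) < 2:
        raise ValueError("fewer than two event windows; drift estimation "
                         "refused (reduce target_per_window)")
    pad = 4.0 * sigma + 50.0  # leave room for the drift excursion itself
    lo = np.floor((positions.min(axis=0) - pad) / pixel) * pixel
    hi = positions.max(axis=0) + pad
    bounds = np.column_stack([lo, hi])
    images = [render_positions(positions[a:b], sigma, pixel, bounds)
              for a, b in windows]
    centers = np.array([times[a:b].mean() for a, b in windows])
    shifts = []
    for i in range(len(images)):
        for j in range(i + 1, len(images)):
            s = pairwise_shift(images[i], images[j], i, j)
            if s.quality >= quality_threshold:
                shifts.append(s)
    return solve_drift(shifts, centers)


def correct(events: list[BindingEvent], trace: DriftTrace) -> list[BindingEvent]:
    """Subtract the interpolated drift at each event's start time from the
    event's coordinates; event structure is otherwise untouched."""
    pos_cols = ["x", "y", "z"][: trace.ndim]
    out = []
    for ev in events:
        offset = trace(np.array([ev.t_start]))[0]
        locs = ev.locs.copy()
        for c, o in zip(pos_cols, offset):
            locs[c] = locs[c] - o
        out.append(replace(ev, locs=locs,
                           mean_pos=ev.mean_pos - offset[: len(ev.mean_pos)]))
    return out
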