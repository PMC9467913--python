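"""Fourier ring correlation (FRC) resolution of a localization dataset.

The dataset of *combined* localizations (one mean x/y position per trace
ID) is split at random into two halves, each half is rendered to a 2D
histogram image, and the correlation of the two Fourier transforms is
averaged over rings of constant spatial frequency:

    FRC(q) = Re sum_ring F_A conj(F_B)
             / sqrt(sum_ring |F_A|^2 * sum_ring |F_B|^2).

The inverse of the spatial frequency where the curve first drops below 1/7
(and stays below for one further ring, to resist single-ring noise dips) is
the FRC resolution; the split is repeated several times and the resolutions
averaged.  Combined localizations are used because with raw localizations
the repeated localizations of one binding event dominate the correlation
and the result merely reports the single-localization precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .events import BindingEvent
from .image import RenderedImage, histogram_image

__all__ = [
    "FRCCurve",
    "FRCResult",
    "combined_positions",
    "frc_curve",
    "frc_resolution",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 1.0 / 7.0


@dataclass(frozen=True)
class FRCCurve:
    frequencies: np.ndarray  # ring centers, nm^-1
    values: np.ndarray       # dimensionless, in [-1, 1] up to fp noise
    ring_width: float        # nm^-1


@dataclass(frozen=True)
class FRCResult:
    resolution: float               # nm, mean over repeats (NaN if none)
    per_repeat: np.ndarray          # nm, NaN where no crossing was found
    n_repeats: int
    threshold: float
    pixel: float


def combined_positions(events: list[BindingEvent]) -> np.ndarray:
    """One mean (x, y) position per binding event, nm (z is ignored)."""
    if not events:
        return np.empty((0, 2))
    return np.array([e.mean_pos[:2] for e in events], float)


def frc_curve(img_a: RenderedImage, img_b: RenderedImage) -> FRCCurve:
    """Ring-averaged Fourier correlation of two equally gridded square
    images, up to the Nyquist frequency with one-bin-wide rings."""
    if not img_a.same_grid(img_b):
        raise ValueError("images must share the same grid")
    n = img_a.data.shape[0]
    if img_a.data.shape != (n, n):
        raise ValueError("FRC requires square images")
    fa = np.fft.fftshift(np.fft.fft2(img_a.data))
    fb = np.fft.fftshift(np.fft.fft2(img_b.data))
    ky, kx = np.indices((n, n))
    center = n // 2
    ring = np.rint(np.hypot(kx - center, ky - center)).astype(int)
    n_rings = n // 2
    cross = np.bincount(ring.ravel(), (fa * np.conj(fb)).real.ravel(),
                        minlength=n_rings)[:n_rings]
    pa = np.bincount(ring.ravel(), np.abs(fa).ravel() ** 2,
                     minlength=n_rings)[:n_rings]
    pb = np.bincount(ring.ravel(), np.abs(fb).ravel() ** 2,
                     minlength=n_rings)[:n_rings]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = cross / np.sqrt(pa * pb)
    vals = np.nan_to_num(vals, nan=0.0)
    ring_width = 1.0 / (n * img_a.pixel)
    freqs = np.arange(n_rings) * ring_width
    return FRCCurve(frequencies=freqs, values=vals, ring_width=ring_width)


def _first_crossing(curve: FRCCurve, threshold: float) -> float:
    """Spatial frequency of the first sustained drop below the threshold
    (linear interpolation between the bracketing rings); NaN if none."""
    v, f = curve.values, curve.frequencies
    for k in range(1, len(v) - 1):
        if v[k] < threshold and v[k + 1] < threshold:
            if v[k - 1] == v[k]:
                return f[k]
            frac = (threshold - v[k - 1]) / (v[k] - v[k - 1])
            return f[k - 1] + frac * (f[k] - f[k - 1])
    return float("nan")


def _square_bounds(positions: np.ndarray, pixel: float) -> np.ndarray:
    lo = np.floor(positions.min(axis=0) / pixel) * pixel
    extent = (positions.max(axis=0) - lo).max() + pixel
    n = 1 << int(np.ceil(np.log2(max(extent / pixel, 2))))
    return np.column_stack([lo, lo + n * pixel])


def frc_resolution(positions: np.ndarray, pixel: float = 2.0,
                   n_repeats: int = 10, seed: int = 0,
                   min_positions: int = 100,
                   threshold: float = DEFAULT_THRESHOLD) -> FRCResult:
    """FRC resolution of a set of combined localizations, nm.

    Each repeat splits the positions into random halves, renders both
    halves as count histograms on a common power-of-two square grid, and
    locates the threshold crossing of the ring correlation.  Repeats whose
    curve never drops below the threshold (resolution beyond the Nyquist
    limit of the chosen pixel) are excluded with a warning.
    """
    positions = np.asarray(positions, float)[:, :2]
    if len(positions) < min_positions:
        raise ValueError(f"need at least {min_positions} combined positions, "
                         f"got {len(positions)}")
    rng = np.random.default_rng(seed)
    bounds = _square_bounds(positions, pixel)
    res = np.full(n_repeats, np.nan)
    for rep in range(n_repeats):
        idx = rng.permutation(len(positions))
        half = len(positions) // 2
        img_a = histogram_image(positions[idx[:half]], pixel, bounds)
        img_b = histogram_image(positions[idx[half:]], pixel, bounds)
        curve = frc_curve(img_a, img_b)
        f_cross = _first_crossing(curve, threshold)
        if np.isfinite(f_cross) and f_cross > 0:
            res[rep] = 1.0 / f_cross
    good = res[np.isfinite(res)]
    if good.size < n_repeats:
        warnings.warn(f"{n_repeats - good.size} of {n_repeats} repeats had "
                      "no threshold crossing (resolution beyond the Nyquist "
                      "limit); excluded from the average")
    mean = float(good.mean()) if good.size else float("nan")
    return FRCResult(resolution=mean, per_repeat=res, n_repeats=n_repeats,
                     threshold=threshold, pixel=pixel)
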