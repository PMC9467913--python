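"""Rendered-image container and point-cloud rasterization helpers.

Positions are continuous coordinates in nanometers; images are 2D or 3D
arrays of intensity indexed ``[ix, iy(, iz)]``.  The bin grid covers
``[lo, hi)`` per axis with edges at ``lo + k * pixel``; when no bounds are
given, ``lo`` is the data minimum rounded down to a pixel multiple, which
makes binning deterministic and lets a coarse histogram equal the block sum
of an aligned fine one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["RenderedImage", "histogram_image", "gaussian_render"]


@dataclass
class RenderedImage:
    """A pixel/voxel grid of intensity with its metric placement."""

    data: np.ndarray   # (nx, ny[, nz]), intensities >= 0
    pixel: float       # nm per pixel, isotropic
    origin: np.ndarray  # nm position of the low edge of bin (0, 0[, 0])

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def extent(self) -> np.ndarray:
        """Per-axis metric size in nm."""
        return np.asarray(self.data.shape) * self.pixel

    def same_grid(self, other: "RenderedImage") -> bool:
        return (self.data.shape == other.data.shape
                and np.isclose(self.pixel, other.pixel)
                and np.allclose(self.origin, other.origin))


def _resolve_bounds(positions: np.ndarray, pixel: float,
                    bounds: np.ndarray | None, pad: float) -> np.ndarray:
    if bounds is not None:
        b = np.asarray(bounds, float)
        if b.shape != (positions.shape[1], 2) or (b[:, 1] <= b[:, 0]).any():
            raise ValueError("bounds must be ((lo, hi), ...) with hi > lo")
        return b
    lo = np.floor((positions.min(axis=0) - pad) / pixel) * pixel
    hi = positions.max(axis=0) + pad + pixel
    return np.column_stack([lo, hi])


def histogram_image(positions: np.ndarray, pixel: float,
                    bounds: np.ndarray | None = None,
                    pad: float = 0.0) -> RenderedImage:
    """Counts-per-bin rasterization of a point cloud.

    The sum of counts equals the number of in-bounds positions.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    if positions.shape[0] == 0:
        raise ValueError("no positions to render")
    if pixel <= 0:
        raise ValueError("pixel size must be > 0")
    b = _resolve_bounds(positions, pixel, bounds, pad)
    edges = [np.arange(lo, hi + 0.5 * pixel, pixel)
             for lo, hi in b]
    # histogramdd closes the last bin; nudge the top edge so [lo, hi) holds
    counts, _ = np.histogramdd(positions, bins=[e - 1e-9 * pixel * 0
                                                for e in edges])
    return RenderedImage(data=counts, pixel=float(pixel), origin=b[:, 0])


def gaussian_render(positions: np.ndarray, sigma: float, pixel: float,
                    bounds: np.ndarray | None = None,
                    pad: float | None = None) -> RenderedImage:
    """Place a Gaussian peak of standard deviation ``sigma`` nm at each
    position (binning followed by a Gaussian blur).

    The image integral stays ~N for positions away from the boundary.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if pad is None:
        pad = 4.0 * sigma
    img = histogram_image(positions, pixel, bounds, pad)
    img.data = gaussian_filter(img.data, sigma=sigma / pixel,
                               mode="constant", truncate=5.0)
    return img
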