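"""Physical simulation of the center-frequency ratio (CFR).

MINFLUX probes a molecule with a donut-shaped excitation beam at the
positions of a targeted coordinate pattern (TCP): the pattern center plus
``n_outer`` points on a circle of diameter L.  The CFR -- the emission
frequency at the center exposure over the mean frequency at the outer
exposures -- is a localization quality metric, but freely diffusing imager
strands contribute background that grows with concentration and pinhole
size.  This module computes that dependence for a molecule sitting exactly
at the pattern center:

* the excitation donut ``h_exc`` is the focal intensity of a circularly
  polarized vortex beam (topological charge 1, handedness matched so the
  on-axis field vanishes exactly), via the Richards-Wolf vectorial
  diffraction integral at high numerical aperture;
* the confocal detection PSF ``h_det`` is the emission-wavelength focal
  intensity integrated over the back-projected pinhole disc
  (1 Airy unit = 1.22 lambda_det / NA diameter in the sample plane);
* the effective PSF per exposure i is ``h_eff,i = h_exc,i * h_det`` with
  the excitation shifted to the exposure position and the detection fixed;
* background per exposure is ``B_i = integral h_eff,i * c_imager dV`` and
  the signal of the centered molecule is ``I_i = h_eff,i(0, 0, 0)``; with
  a perfect donut zero ``I_center = 0``;
* ``CFR = (B_center + I_center) / (B_outer_mean + I_outer_mean)`` with the
  outer means weighted by the time share of each exposure.

All intensities are relative to the respective PSF peak (= 1); the
concentration enters as molecules per nm^3 (1 nM = 6.022e-10 nm^-3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import shift as ndshift
from scipy.signal import fftconvolve
from scipy.special import jv

__all__ = [
    "OpticalConfig",
    "TCP",
    "PSFGrid",
    "CFRScenario",
    "excitation_donut",
    "detection_psf",
    "effective_psf",
    "background_intensity",
    "simulate_cfr",
    "sweep_cfr",
    "NM3_PER_NM",
]

#: molecules per nm^3 at 1 nM concentration
NM3_PER_NM = 6.022e-10


@dataclass(frozen=True)
class OpticalConfig:
    """Microscope model parameters.

    The objective properties (NA, immersion index) are package defaults for
    a high-NA oil objective; wavelengths follow the red imager dye
    (excitation 642 nm, detection at the 680 nm emission maximum).
    """

    lambda_exc: float = 642.0   # nm
    lambda_det: float = 680.0   # nm
    na: float = 1.4
    n_immersion: float = 1.518
    pinhole_au: float = 1.0     # pinhole diameter in Airy units at lambda_det
    grid_spacing: float = 20.0  # nm
    grid_halfspan: float | None = None  # nm; default 3 * lambda_det / NA
    n_theta: int = 256          # aperture-angle quadrature points

    def __post_init__(self) -> None:
        if not 0 < self.na < self.n_immersion:
            raise ValueError("need 0 < NA < n_immersion")
        if self.pinhole_au <= 0:
            raise ValueError("pinhole diameter must be > 0")
        if self.grid_spacing > self.lambda_exc / (8 * self.na):
            warnings.warn("grid spacing coarser than lambda/(8 NA); PSF "
                          "features may be undersampled")

    @property
    def halfspan(self) -> float:
        return (self.grid_halfspan if self.grid_halfspan is not None
                else 3.0 * self.lambda_det / self.na)

    @property
    def airy_radius(self) -> float:
        """Airy-disc radius at the detection wavelength, nm (half of 1 AU)."""
        return 0.61 * self.lambda_det / self.na

    def axis(self) -> np.ndarray:
        n = int(np.floor(self.halfspan / self.grid_spacing))
        return np.arange(-n, n + 1) * self.grid_spacing


@dataclass(frozen=True)
class TCP:
    """Targeted coordinate pattern: the center plus ``n_outer`` points
    equally spaced on a circle of diameter L; exposure 0 is the center."""

    L: float                       # nm
    n_outer: int = 6
    center_dwell_fraction: float = 0.5  # time share of the center exposure

    def positions(self) -> np.ndarray:
        ang = 2 * np.pi * np.arange(self.n_outer) / self.n_outer
        outer = 0.5 * self.L * np.column_stack([np.cos(ang), np.sin(ang)])
        return np.vstack([[0.0, 0.0], outer])

    def dwell_fractions(self) -> np.ndarray:
        f = np.full(self.n_outer + 1,
                    (1.0 - self.center_dwell_fraction) / self.n_outer)
        f[0] = self.center_dwell_fraction
        return f


class _RadialProfile:
    """Azimuthally symmetric intensity I(r, z) with bilinear evaluation."""

    def __init__(self, r: np.ndarray, z: np.ndarray, intensity: np.ndarray):
        self.r, self.z, self.intensity = r, z, intensity
        self._interp = RegularGridInterpolator(
            (r, z), intensity, bounds_error=False, fill_value=0.0)

    def __call__(self, r, z):
        rb, zb = np.broadcast_arrays(np.asarray(r, float),
                                     np.asarray(z, float))
        out = self._interp(np.stack([rb.ravel(), zb.ravel()], axis=-1))
        return out.reshape(rb.shape) if rb.shape else float(out[0])

    def on_grid(self, axes, center=(0.0, 0.0)) -> np.ndarray:
        x, y, z = axes
        rr = np.hypot(x[:, None] - center[0], y[None, :] - center[1])
        out = np.empty((len(x), len(y), len(z)))
        for iz, zz in enumerate(z):
            out[:, :, iz] = self(rr, np.full_like(rr, zz))
        return out


@dataclass
class PSFGrid:
    """Sampled 3D intensity on a symmetric metric grid (0 at the center
    sample of every axis)."""

    data: np.ndarray                 # (nx, ny, nz), >= 0
    axes: tuple[np.ndarray, np.ndarray, np.ndarray]  # nm
    normalization: str = "peak"
    radial: _RadialProfile | None = None

    @property
    def spacing(self) -> float:
        return float(self.axes[0][1] - self.axes[0][0])

    @property
    def center_index(self) -> tuple[int, int, int]:
        return tuple(len(a) // 2 for a in self.axes)

    def at_origin(self) -> float:
        return float(self.data[self.center_index])

    def integral(self) -> float:
        """Riemann sum, nm^3 units of the sampled intensity."""
        return float(self.data.sum()) * self.spacing ** 3


def _debye_integrals(r: np.ndarray, z: np.ndarray, wavelength: float,
                     cfg: OpticalConfig, orders_weights) -> list[np.ndarray]:
    """1D aperture-angle integrals of the Richards-Wolf focal field.

    Each entry of ``orders_weights`` is ``(bessel_order, weight(theta))``;
    returns the complex field component on the (r, z) product grid.
    """
    k = 2 * np.pi * cfg.n_immersion / wavelength
    theta_max = np.arcsin(cfg.na / cfg.n_immersion)
    theta = np.linspace(0.0, theta_max, cfg.n_theta)
    st, ct = np.sin(theta), np.cos(theta)
    apod = np.sqrt(ct) * st
    phase = np.exp(1j * k * np.outer(ct, z))          # (ntheta, nz)
    dtheta = theta[1] - theta[0]
    w_trap = np.ones_like(theta)
    w_trap[0] = w_trap[-1] = 0.5
    out = []
    for order, weight in orders_weights:
        bess = jv(order, k * np.outer(st, r))         # (ntheta, nr)
        integrand = (apod * weight(ct) * w_trap)[:, None] * bess
        comp = np.tensordot(integrand, phase, axes=(0, 0))  # (nr, nz)
        out.append(comp * dtheta)
    return out


def _vortex_intensity(r: np.ndarray, z: np.ndarray,
                      cfg: OpticalConfig) -> np.ndarray:
    """Focal intensity of a circularly polarized charge-1 vortex beam.

    Handedness matches the vortex charge, so every field component carries
    a Bessel function of order >= 1 and the on-axis intensity is exactly
    zero (the MINFLUX donut null).
    """
    comps = _debye_integrals(r, z, cfg.lambda_exc, cfg, [
        (1, lambda ct: 1.0 + ct),   # co-rotating transverse component
        (3, lambda ct: 1.0 - ct),   # counter-rotating transverse component
        (2, lambda ct: np.sqrt(2.0) * np.sqrt(1.0 - ct**2)),  # longitudinal
    ])
    return sum(np.abs(c) ** 2 for c in comps)


def _scalar_intensity(r: np.ndarray, z: np.ndarray, wavelength: float,
                      cfg: OpticalConfig) -> np.ndarray:
    """Scalar high-NA focal intensity (order-0 Debye integral)."""
    (comp,) = _debye_integrals(r, z, wavelength, cfg,
                               [(0, lambda ct: 1.0 + ct)])
    return np.abs(comp) ** 2


def _radial_grid(cfg: OpticalConfig) -> tuple[np.ndarray, np.ndarray]:
    r_max = np.sqrt(2.0) * cfg.halfspan + 250.0
    r = np.arange(0.0, r_max, cfg.grid_spacing / 2.0)
    return r, cfg.axis()


def excitation_donut(cfg: OpticalConfig) -> PSFGrid:
    """The 2D-donut excitation PSF, peak-normalized, with an attached
    radial profile for exact shifted evaluation."""
    r, z = _radial_grid(cfg)
    intensity = _vortex_intensity(r, z, cfg)
    intensity /= intensity.max()
    prof = _RadialProfile(r, z, intensity)
    ax = cfg.axis()
    return PSFGrid(data=prof.on_grid((ax, ax, ax)), axes=(ax, ax, ax),
                   normalization="peak", radial=prof)


def detection_psf(cfg: OpticalConfig) -> PSFGrid:
    """Confocal detection PSF: the emission-wavelength focal intensity
    integrated over the back-projected pinhole disc, peak-normalized."""
    r, z = _radial_grid(cfg)
    em = _RadialProfile(r, z, _scalar_intensity(r, z, cfg.lambda_det, cfg))
    ax = cfg.axis()
    grid = em.on_grid((ax, ax, ax))
    # hard-disc pinhole kernel in the conjugate sample plane
    r_ph = cfg.pinhole_au * cfg.airy_radius
    n_k = int(np.ceil(r_ph / cfg.grid_spacing))
    ka = np.arange(-n_k, n_k + 1) * cfg.grid_spacing
    kernel = (np.hypot(ka[:, None], ka[None, :]) <= r_ph).astype(float)
    out = np.empty_like(grid)
    for iz in range(grid.shape[2]):
        out[:, :, iz] = fftconvolve(grid[:, :, iz], kernel, mode="same")
    out = np.clip(out, 0.0, None)
    out /= out[len(ax) // 2, len(ax) // 2, len(ax) // 2]
    return PSFGrid(data=out, axes=(ax, ax, ax), normalization="peak")


def effective_psf(h_exc: PSFGrid, h_det: PSFGrid,
                  exposure_pos=(0.0, 0.0)) -> PSFGrid:
    """Effective PSF of one exposure: the excitation donut shifted to the
    exposure position times the centered confocal detection."""
    if h_exc.data.shape != h_det.data.shape:
        raise ValueError("excitation and detection grids differ")
    dx, dy = float(exposure_pos[0]), float(exposure_pos[1])
    half = h_exc.axes[0][-1]
    if abs(dx) > half or abs(dy) > half:
        raise ValueError("exposure position outside the PSF grid")
    if h_exc.radial is not None:
        shifted = h_exc.radial.on_grid(h_exc.axes, center=(dx, dy))
    elif dx == dy == 0.0:
        shifted = h_exc.data
    else:
        px = h_exc.spacing
        shifted = ndshift(h_exc.data, (dx / px, dy / px, 0.0),
                          order=1, cval=0.0)
    return PSFGrid(data=shifted * h_det.data, axes=h_exc.axes,
                   normalization="relative")


def background_intensity(h_eff: PSFGrid, c_imager: float) -> float:
    """Background from freely diffusing imager at ``c_imager`` nM:
    the volume integral of the effective PSF times the concentration."""
    if c_imager < 0:
        raise ValueError("concentration must be >= 0")
    return h_eff.integral() * c_imager * NM3_PER_NM


@dataclass(frozen=True)
class CFRScenario:
    """Per-exposure signal/background decomposition of one CFR evaluation."""

    c_imager: float             # nM
    L: float                    # nm
    pinhole_au: float
    b_exposures: np.ndarray     # background per exposure (center first)
    i_exposures: np.ndarray     # signal per exposure (center first)
    cfr: float

    @property
    def b_center(self) -> float:
        return float(self.b_exposures[0])

    @property
    def i_center(self) -> float:
        return float(self.i_exposures[0])


def simulate_cfr(cfg: OpticalConfig, tcp: TCP, c_imager: float,
                 epsilon_zero: float = 0.0,
                 _psfs: tuple[PSFGrid, PSFGrid] | None = None) -> CFRScenario:
    """CFR of a molecule at the TCP center under background from diffusing
    imager strands.

    ``epsilon_zero`` adds a residual excitation floor of that fraction of
    the donut peak at the pattern center, to model an imperfect zero; the
    default 0 is the ideal null with ``I_center = 0``.  Returns NaN CFR
    when both signal and background vanish (no molecule bound, c = 0).
    """
    h_exc, h_det = _psfs if _psfs is not None else (
        excitation_donut(cfg), detection_psf(cfg))
    pos = tcp.positions()
    dwell = tcp.dwell_fractions()
    n_exp = len(pos)
    b = np.empty(n_exp)
    i_sig = np.empty(n_exp)
    det0 = h_det.at_origin()
    for k, p in enumerate(pos):
        h_eff = effective_psf(h_exc, h_det, p)
        b[k] = background_intensity(h_eff, c_imager)
        # molecule fixed at the origin: signal = h_eff at (0, 0, 0)
        i_sig[k] = h_eff.at_origin()
    i_sig[0] = (h_exc.radial(0.0, 0.0) if h_exc.radial is not None
                else h_exc.at_origin()) * det0 + epsilon_zero * det0
    w_outer = dwell[1:] / dwell[1:].sum()
    denom = float(np.sum(w_outer * (b[1:] + i_sig[1:])))
    numer = float(b[0] + i_sig[0])
    cfr = numer / denom if denom > 0 else float("nan")
    return CFRScenario(c_imager=c_imager, L=tcp.L, pinhole_au=cfg.pinhole_au,
                       b_exposures=b, i_exposures=i_sig, cfr=cfr)


def sweep_cfr(cfg: OpticalConfig, concentrations, pinholes=None, Ls=None,
              tcp: TCP | None = None, epsilon_zero: float = 0.0) -> pd.DataFrame:
    """CFR over grids of imager concentration, pinhole diameter and TCP
    diameter L (the published-figure style parameter exploration).

    Returns a long-format table with columns ``c_imager``, ``pinhole_au``,
    ``L``, ``cfr``, ``b_center``, ``i_center``, ``b_outer_mean``,
    ``i_outer_mean``.
    """
    pinholes = list(pinholes) if pinholes is not None else [cfg.pinhole_au]
    base_tcp = tcp or TCP(L=40.0)
    Ls = list(Ls) if Ls is not None else [base_tcp.L]
    h_exc = excitation_donut(cfg)
    rows = []
    for ph in pinholes:
        cfg_ph = replace(cfg, pinhole_au=float(ph))
        h_det = detection_psf(cfg_ph)
        for L in Ls:
            t = replace(base_tcp, L=float(L))
            for c in concentrations:
                sc = simulate_cfr(cfg_ph, t, float(c), epsilon_zero,
                                  _psfs=(h_exc, h_det))
                rows.append({
                    "c_imager": float(c), "pinhole_au": float(ph),
                    "L": float(L), "cfr": sc.cfr,
                    "b_center": sc.b_center, "i_center": sc.i_center,
                    "b_outer_mean": float(np.mean(sc.b_exposures[1:])),
                    "i_outer_mean": float(np.mean(sc.i_exposures[1:])),
                })
    return pd.DataFrame(rows)
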