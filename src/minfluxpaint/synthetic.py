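"""Synthetic MINFLUX-export generator with known ground truth.

DNA-PAINT imaging localizes transient binding events of dye-labeled imager
strands to docking sites on the structure of interest.  The generator
emulates the *export layer* of such an acquisition -- binding kinetics,
repeated localizations per event, terminal non-valid attempts, background
frequency and sample drift -- without modeling photon statistics or the
on-line position estimator.  Every estimator in the package has a
parameter-recovery test against the returned ground truth.

Binding model
-------------
Each docking site binds imagers as a renewal process: after an event ends,
the next event at the same site starts after an exponential waiting time
with rate ``k_on * c_imager`` (events per second).  Event durations are
exponential with mean ``mean_event_duration``.  At low duty cycle the merged
event-start process over all sites is close to Poisson with rate
``k_on * c_imager * n_sites``, which is what :func:`expected_t_btw`
evaluates in closed form.

During an event the instrument re-localizes the bound imager on a fixed
duty cycle, so localizations are emitted at regular intervals
``1 / loc_rate``; each is the drifted true site position plus isotropic
Gaussian noise ``sigma_true``.  The event is terminated by
``n_invalid_tail`` non-valid attempts (``vld = 0`` rows with NaN positions);
the first of these defines the event end time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Any, Callable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io import Dataset, FINAL_ITERATION

__all__ = [
    "StructureModel",
    "AcquisitionConfig",
    "DriftModel",
    "SyntheticTruth",
    "make_structure",
    "make_drift_function",
    "simulate_acquisition",
    "expected_t_btw",
]


@dataclass(frozen=True)
class StructureModel:
    """A set of docking-site coordinates (nm) standing in for a labeled
    cellular structure."""

    kind: str
    sites: np.ndarray  # (n_sites, ndim)
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def ndim(self) -> int:
        return self.sites.shape[1]

    @property
    def n_sites(self) -> int:
        return self.sites.shape[0]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Parameters of a simulated DNA-PAINT MINFLUX acquisition.

    The binding-kinetics constants are arbitrary test settings chosen to
    give realistic event statistics (single-digit-second waiting times at
    nanomolar imager concentrations), not measured values.
    """

    c_imager: float = 2.0            # imager concentration, nM
    k_on: float = 0.01               # events / (s * nM) per site
    mean_event_duration: float = 0.2  # s
    loc_rate: float = 100.0          # localizations / s during an event
    sigma_true: float = 2.0          # lateral localization noise, nm
    sigma_z_true: float | None = None  # axial noise, nm (defaults to lateral)
    n_invalid_tail: int = 2          # terminal non-valid attempts per event
    fbg_true: float = 20000.0        # background emission frequency, Hz
    fbg_jitter: float = 0.05         # relative sd of the reported fbg
    duration: float = 600.0          # total acquisition time, s
    false_event_rate: float = 0.0    # spurious events / s (anywhere in FOV)
    cfr_median: float = 0.4          # median of the lognormal CFR draw
    cfr_sigma_log: float = 0.3       # log-sd of the CFR draw
    efo_mean: float = 100000.0       # effective emission frequency scale, Hz

    def __post_init__(self) -> None:
        for name in ("c_imager", "k_on", "mean_event_duration", "loc_rate",
                     "fbg_true", "duration", "false_event_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma_true <= 0:
            raise ValueError("sigma_true must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class DriftModel:
    """Smooth sample-drift trajectory specification; drift(0) = 0.

    kinds: ``none``; ``linear`` (param ``velocity``: per-axis nm/s, scalar
    applied to x); ``spline_random_walk`` (params ``knot_spacing`` s and
    ``step_sigma`` nm: cumulative Gaussian steps at the knots joined by a
    cubic spline).
    """

    kind: str = "none"
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated acquisition."""

    events: pd.DataFrame  # tid, site, x, y[, z], t_start, t_end, n
    sites: np.ndarray
    drift_fn: Callable[[np.ndarray], np.ndarray]  # t -> (len(t), ndim) nm
    config: AcquisitionConfig

    def drift_at(self, t: np.ndarray) -> np.ndarray:
        return self.drift_fn(np.asarray(t, float))


def make_structure(kind: str, params: dict[str, Any] | None = None,
                   seed: int | None = None, **kwargs: Any) -> StructureModel:
    """Build a docking-site layout.

    kinds
    -----
    grid
        ``nx`` x ``ny`` lattice with ``spacing`` nm (defaults 3 x 3, 50 nm).
    ring_array
        Array of rings of ``n_corners`` sites on circles of ``diameter`` nm
        (default 8 corners, 100 nm -- a synthetic convenience, not a claim
        about any real complex), rings on an ``array_shape`` lattice with
        ``array_spacing`` nm.
    filament
        Sites every ``spacing`` nm along a gently curved line of ``length``
        nm (sinusoidal offset of amplitude ``wiggle``).
    random
        ``n_sites`` uniform sites in a box of ``extent`` nm.

    ``ndim=3`` adds a z coordinate (zero except for ``random``).
    Deterministic for a fixed seed.
    """
    p = dict(params or {})
    p.update(kwargs)
    ndim = int(p.pop("ndim", 2))
    rng = np.random.default_rng(seed)

    if kind == "grid":
        nx, ny = int(p.get("nx", 3)), int(p.get("ny", 3))
        s = float(p.get("spacing", 50.0))
        xs, ys = np.meshgrid(np.arange(nx) * s, np.arange(ny) * s,
                             indexing="ij")
        sites = np.column_stack([xs.ravel(), ys.ravel()])
    elif kind == "ring_array":
        n_corners = int(p.get("n_corners", 8))
        diameter = float(p.get("diameter", 100.0))
        shape = tuple(p.get("array_shape", (2, 2)))
        spacing = float(p.get("array_spacing", 300.0))
        ang = 2 * np.pi * np.arange(n_corners) / n_corners
        ring = 0.5 * diameter * np.column_stack([np.cos(ang), np.sin(ang)])
        centers = np.array([(i * spacing, j * spacing)
                            for i in range(shape[0]) for j in range(shape[1])])
        sites = (centers[:, None, :] + ring[None, :, :]).reshape(-1, 2)
    elif kind == "filament":
        length = float(p.get("length", 1000.0))
        s = float(p.get("spacing", 10.0))
        wiggle = float(p.get("wiggle", 30.0))
        t = np.arange(0.0, length + 0.5 * s, s)
        sites = np.column_stack([t, wiggle * np.sin(2 * np.pi * t / length)])
    elif kind == "random":
        n = int(p.get("n_sites", 100))
        extent = p.get("extent", (1000.0,) * ndim)
        extent = np.broadcast_to(np.asarray(extent, float), (ndim,))
        sites = rng.uniform(0.0, 1.0, size=(n, ndim)) * extent
    else:
        raise ValueError(f"unknown structure kind {kind!r}")

    if ndim == 3 and sites.shape[1] == 2:
        sites = np.column_stack([sites, np.zeros(len(sites))])
    return StructureModel(kind=kind, sites=np.asarray(sites, float), params=p)


def make_drift_function(model: DriftModel, duration: float,
                        ndim: int) -> Callable[[np.ndarray], np.ndarray]:
    """Realize a drift model as a callable ``t -> (len(t), ndim)`` in nm."""
    if model.kind == "none":
        return lambda t: np.zeros((np.size(t), ndim))
    if model.kind == "linear":
        vel = np.zeros(ndim)
        raw = np.atleast_1d(np.asarray(model.params.get("velocity", 0.0),
                                       float))
        vel[: min(len(raw), ndim)] = raw[:ndim]
        return lambda t: np.asarray(t, float).reshape(-1, 1) * vel
    if model.kind == "spline_random_walk":
        knot_spacing = float(model.params.get("knot_spacing", 60.0))
        step_sigma = float(model.params.get("step_sigma", 3.0))
        rng = np.random.default_rng(model.seed)
        knots = np.arange(0.0, duration + 2 * knot_spacing, knot_spacing)
        steps = rng.normal(0.0, step_sigma, size=(len(knots), ndim))
        steps[0] = 0.0
        offsets = np.cumsum(steps, axis=0)
        spline = CubicSpline(knots, offsets, axis=0)
        t0, t1 = knots[0], knots[-1]
        return lambda t: spline(np.clip(np.asarray(t, float), t0, t1))
    raise ValueError(f"unknown drift kind {model.kind!r}")


def expected_t_btw(config: AcquisitionConfig, structure: StructureModel,
                   statistic: str = "mean") -> float:
    """Closed-form waiting time between events of the merged binding process.

    The merged event-start process over ``n_sites`` independent sites has
    rate ``R = k_on * c_imager * n_sites``; the mean gap is ``1/R`` and the
    median (which is what the t_btw statistic reports) is ``ln(2)/R``.
    Returns ``inf`` for a zero rate.
    """
    rate = config.k_on * config.c_imager * structure.n_sites
    if rate <= 0:
        return np.inf
    if statistic == "mean":
        return 1.0 / rate
    if statistic == "median":
        return np.log(2.0) / rate
    raise ValueError(f"unknown statistic {statistic!r}")


def _site_event_times(rng: np.random.Generator, rate: float, duration: float,
                      mean_duration: float, loc_rate: float) -> list[tuple[float, int]]:
    """Renewal sequence of (start, n_locs) for one site; events never overlap."""
    out = []
    t = rng.exponential(1.0 / rate)
    while t < duration:
        dur = rng.exponential(mean_duration)
        n = max(1, int(np.floor(dur * loc_rate)) + 1)
        out.append((t, n))
        t_end = t + n / loc_rate
        t = t_end + rng.exponential(1.0 / rate)
    return out


def simulate_acquisition(structure: StructureModel,
                         config: AcquisitionConfig | None = None,
                         drift: DriftModel | None = None,
                         seed: int = 0) -> tuple[Dataset, SyntheticTruth]:
    """Simulate a DNA-PAINT MINFLUX acquisition over a structure.

    Returns a :class:`~minfluxpaint.io.Dataset` in the export schema (valid
    final-iteration rows plus terminal ``vld=0`` rows per event, time sorted)
    and the matching :class:`SyntheticTruth`.  Identical seeds give identical
    output.
    """
    config = config or AcquisitionConfig()
    drift = drift or DriftModel()
    if structure.n_sites < 1:
        raise ValueError("structure has no sites")
    ndim = structure.ndim
    final_itr = FINAL_ITERATION[ndim]
    rng = np.random.default_rng(seed)
    drift_fn = make_drift_function(drift, config.duration, ndim)

    rate = config.k_on * config.c_imager
    raw_events: list[tuple[float, int, int]] = []  # (t_start, site, n)
    if rate > 0:
        for s in range(structure.n_sites):
            for t0, n in _site_event_times(rng, rate, config.duration,
                                           config.mean_event_duration,
                                           config.loc_rate):
                raw_events.append((t0, s, n))
    n_false = rng.poisson(config.false_event_rate * config.duration)
    if n_false:
        lo = structure.sites.min(axis=0) - 50.0
        hi = structure.sites.max(axis=0) + 50.0
        for t0 in rng.uniform(0.0, config.duration, n_false):
            raw_events.append((float(t0), -1, 1))
    raw_events.sort(key=lambda e: e[0])

    sigma = np.full(ndim, config.sigma_true)
    if ndim == 3:
        sigma[2] = (config.sigma_z_true if config.sigma_z_true is not None
                    else config.sigma_true)
    pos_cols = ["x", "y", "z"][:ndim]
    rows: list[dict[str, Any]] = []
    truth_rows: list[dict[str, Any]] = []

    for tid, (t0, site, n) in enumerate(raw_events, start=1):
        if site >= 0:
            true_pos = structure.sites[site]
        else:
            true_pos = rng.uniform(lo, hi)
        times = t0 + np.arange(n) / config.loc_rate
        noise = rng.normal(0.0, 1.0, size=(n, ndim)) * sigma
        pos = true_pos + drift_fn(times) + noise
        cfr = np.exp(rng.normal(np.log(config.cfr_median),
                                config.cfr_sigma_log, n))
        efo = config.efo_mean * np.exp(rng.normal(0.0, 0.2, n))
        fbg = config.fbg_true * (
            1.0 + config.fbg_jitter * rng.normal(size=n + config.n_invalid_tail))
        for k in range(n):
            row = {"tid": tid, "tim": times[k], "vld": True, "itr": final_itr,
                   "efo": efo[k], "fbg": fbg[k], "cfr": cfr[k]}
            row.update(dict(zip(pos_cols, pos[k])))
            rows.append(row)
        # terminal non-valid attempts continue the localization cadence
        for k in range(config.n_invalid_tail):
            t = t0 + (n + k) / config.loc_rate
            row = {"tid": tid, "tim": t, "vld": False, "itr": final_itr,
                   "efo": np.nan, "fbg": fbg[n + k], "cfr": np.nan}
            row.update({c: np.nan for c in pos_cols})
            rows.append(row)
        t_end = t0 + n / config.loc_rate
        tr = {"tid": tid, "site": site, "t_start": t0, "t_end": t_end, "n": n}
        tr.update({f"{c}_true": v for c, v in zip(pos_cols, true_pos)})
        truth_rows.append(tr)

    columns = ["tid", "tim", "vld", "itr", *pos_cols, "efo", "fbg", "cfr"]
    if rows:
        df = pd.DataFrame(rows)[columns]
        df = df.sort_values("tim", kind="stable").reset_index(drop=True)
    else:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in columns})
        df["tid"] = df["tid"].astype(np.int64)
        df["itr"] = df["itr"].astype(np.int64)
        df["vld"] = df["vld"].astype(bool)

    metadata = {"generator": "minfluxpaint.synthetic", "seed": int(seed),
                "config": asdict(config),
                "drift": {"kind": drift.kind, "params": drift.params,
                          "seed": drift.seed},
                "structure_kind": structure.kind,
                "n_sites": int(structure.n_sites)}
    ds = Dataset(records=df, ndim=ndim, final_iteration=final_itr,
                 metadata=metadata)
    truth = SyntheticTruth(events=pd.DataFrame(truth_rows), sites=structure.sites,
                           drift_fn=drift_fn, config=config)
    return ds, truth
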