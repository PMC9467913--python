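"""Per-event and combined localization-precision estimators.

For every binding event with at least ``min_locs`` (default 5) valid
localizations the lateral precision is the RMS of the x and y sample
standard deviations,

    sigma_r = sqrt((s_x^2 + s_y^2) / 2),

and the axial precision sigma_z is the sample SD of z alone.  The stated
precision of a measurement is the median per-event sigma.  Because each
event combines n localizations of the same molecule, the *combined*
precision divides by sqrt(n) and weights by how often each n occurs:

    sigma_rc = <<sigma_r> / sqrt(n)>_n
             = <sigma_r> * sum_n w_n n^(-1/2) / sum_n w_n,

with <sigma_r> the mean per-event sigma over eligible events and w_n the
number of eligible events with exactly n localizations.  An alternative
reading -- the per-event mean of sigma_i / sqrt(n_i) -- is available via
``per_event=True`` for sensitivity checks; the two agree when sigma and n
are uncorrelated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .events import BindingEvent

__all__ = [
    "PrecisionSummary",
    "event_sigma",
    "event_sigma_r",
    "dataset_sigma",
    "combined_sigma",
    "precision_summary",
]

MIN_LOCS = 5


def event_sigma(ev: BindingEvent, axis: str = "r",
                min_locs: int = MIN_LOCS) -> float:
    """Per-event precision in nm; NaN if the event has fewer than
    ``min_locs`` localizations (the event is excluded, not an error).

    axis "r": sqrt((s_x^2 + s_y^2)/2); axis "z": sample SD of z.
    Sample SDs use the n-1 denominator.
    """
    if ev.n < min_locs:
        return float("nan")
    if axis == "r":
        sx = np.std(ev.coord("x"), ddof=1)
        sy = np.std(ev.coord("y"), ddof=1)
        return float(np.sqrt((sx**2 + sy**2) / 2.0))
    if axis == "z":
        if "z" not in ev.locs.columns:
            raise ValueError("event has no z coordinate")
        return float(np.std(ev.coord("z"), ddof=1))
    raise ValueError(f"unknown axis {axis!r}")


def event_sigma_r(ev: BindingEvent, min_locs: int = MIN_LOCS) -> float:
    return event_sigma(ev, "r", min_locs)


def _eligible(events: list[BindingEvent], axis: str,
              min_locs: int) -> tuple[np.ndarray, np.ndarray]:
    sig = np.array([event_sigma(e, axis, min_locs) for e in events])
    ns = np.array([e.n for e in events])
    keep = np.isfinite(sig)
    return sig[keep], ns[keep]


def dataset_sigma(events: list[BindingEvent], axis: str = "r",
                  min_locs: int = MIN_LOCS) -> float:
    """Median per-event precision over eligible events, nm (NaN if none)."""
    sig, _ = _eligible(events, axis, min_locs)
    if sig.size == 0:
        return float("nan")
    return float(np.median(sig))


def combined_sigma(events: list[BindingEvent], axis: str = "r",
                   min_locs: int = MIN_LOCS, per_event: bool = False) -> float:
    """Combined precision sigma_rc (or sigma_zc), nm.

    Default: mean per-event sigma times the n-histogram-weighted mean of
    1/sqrt(n).  ``per_event=True`` instead averages sigma_i/sqrt(n_i).
    """
    sig, ns = _eligible(events, axis, min_locs)
    if sig.size == 0:
        return float("nan")
    if per_event:
        return float(np.mean(sig / np.sqrt(ns)))
    weights = Counter(ns.tolist())
    w = np.array(list(weights.values()), float)
    n = np.array(list(weights.keys()), float)
    return float(np.mean(sig) * np.sum(w / np.sqrt(n)) / np.sum(w))


@dataclass(frozen=True)
class PrecisionSummary:
    sigma_r: float          # nm, median over events
    sigma_rc: float         # nm
    sigma_z: float          # nm, NaN for 2D data
    sigma_zc: float         # nm, NaN for 2D data
    n_events_used: int
    n_histogram: dict[int, int]  # n -> number of eligible events


def precision_summary(events: list[BindingEvent], ndim: int = 2,
                      min_locs: int = MIN_LOCS) -> PrecisionSummary:
    sig, ns = _eligible(events, "r", min_locs)
    hist = dict(sorted(Counter(ns.tolist()).items()))
    if ndim == 3:
        sz = dataset_sigma(events, "z", min_locs)
        szc = combined_sigma(events, "z", min_locs)
    else:
        sz = szc = float("nan")
    return PrecisionSummary(
        sigma_r=dataset_sigma(events, "r", min_locs),
        sigma_rc=combined_sigma(events, "r", min_locs),
        sigma_z=sz, sigma_zc=szc,
        n_events_used=int(sig.size), n_histogram={int(k): int(v)
                                                  for k, v in hist.items()})
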