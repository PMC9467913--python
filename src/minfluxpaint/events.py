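"""Binding-event extraction and acquisition statistics.

A bound imager is localized repeatedly while it stays hybridized; all
attempts of one binding event share a trace ID (TID).  The instrument
terminates a trace after a preset number of non-valid localization attempts,
and the time stamp of the first of those trailing non-valid attempts defines
the event end.  From the extracted events this module computes the three
per-measurement quality statistics:

* ``t_btw`` -- median time between consecutive valid events (start of the
  next minus end of the previous), over the first 100 events;
* median CFR of all valid last-iteration localizations;
* median background emission frequency ``f_bg``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Dataset, filter_final_valid

__all__ = [
    "BindingEvent",
    "EventSummary",
    "extract_events",
    "time_between_events",
    "median_cfr",
    "median_fbg",
    "summarize",
]


@dataclass
class BindingEvent:
    """All final-iteration localizations of one trace ID.

    ``t_end`` is the time of the first non-valid attempt following the last
    valid localization of the trace; if the export holds no such row the
    last valid time stamp is used as a fallback.
    """

    tid: int
    t_start: float
    t_end: float
    locs: pd.DataFrame  # the valid final-iteration member records
    mean_pos: np.ndarray  # nm

    @property
    def n(self) -> int:
        return len(self.locs)

    def coord(self, axis: str) -> np.ndarray:
        return self.locs[axis].to_numpy(float)


@dataclass(frozen=True)
class EventSummary:
    t_btw: float            # s (NaN if fewer than two events)
    median_cfr: float       # dimensionless
    median_fbg: float       # Hz
    n_events: int


def extract_events(ds: Dataset) -> list[BindingEvent]:
    """Group valid final-iteration localizations into binding events by TID.

    ``ds`` should be the full record stream: non-valid rows do not become
    event members but provide the event end times.  Events are returned
    sorted by start time.
    """
    df = ds.records
    pos_cols = ds.position_columns
    valid = df[(df["itr"] == ds.final_iteration) & df["vld"]]
    events: list[BindingEvent] = []
    invalid_by_tid = {tid: g for tid, g in
                      df[~df["vld"].to_numpy(bool)].groupby("tid")}
    for tid, g in valid.groupby("tid", sort=False):
        t_start = float(g["tim"].iloc[0])
        t_last = float(g["tim"].iloc[-1])
        t_end = t_last
        inv = invalid_by_tid.get(tid)
        if inv is not None:
            after = inv["tim"].to_numpy(float)
            after = after[after > t_last]
            if after.size:
                t_end = float(after.min())
        events.append(BindingEvent(
            tid=int(tid), t_start=t_start, t_end=t_end,
            locs=g.reset_index(drop=True),
            mean_pos=g[pos_cols].to_numpy(float).mean(axis=0)))
    events.sort(key=lambda e: e.t_start)
    return events


def time_between_events(events: list[BindingEvent],
                        first_n: int = 100) -> float:
    """Median gap between consecutive valid events, seconds.

    The gap is the start time of an event minus the end time of the previous
    one; negative raw gaps (overlapping traces) are clipped to zero with a
    warning.  The median is taken over the first ``first_n`` events (all of
    them if fewer).  Returns NaN if fewer than two events exist.
    """
    if len(events) < 2:
        warnings.warn("fewer than two events; t_btw undefined")
        return float("nan")
    use = events[:first_n]
    gaps = np.array([b.t_start - a.t_end for a, b in zip(use, use[1:])])
    if (gaps < 0).any():
        warnings.warn(f"{int((gaps < 0).sum())} negative inter-event gaps "
                      "clipped to 0 (overlapping traces)")
        gaps = np.clip(gaps, 0.0, None)
    return float(np.median(gaps))


def _median_column(ds: Dataset, column: str, valid_only: bool) -> float:
    if column not in ds.records.columns:
        raise KeyError(f"dataset has no {column!r} column")
    df = ds.records[ds.records["itr"] == ds.final_iteration]
    if valid_only:
        df = df[df["vld"]]
    vals = df[column].to_numpy(float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no finite {column!r} values in the last iteration")
    return float(np.median(vals))


def median_cfr(ds: Dataset) -> float:
    """Median CFR of all valid localizations in the last iteration."""
    return _median_column(ds, "cfr", valid_only=True)


def median_fbg(ds: Dataset) -> float:
    """Median background emission frequency, Hz.

    The instrument estimates f_bg continuously (also between valid events),
    so the median is taken over the fbg field of all last-iteration records,
    valid and non-valid alike; no re-estimation from photon streams is done.
    """
    return _median_column(ds, "fbg", valid_only=False)


def summarize(ds: Dataset, first_n: int = 100) -> EventSummary:
    """The per-measurement event statistics in one record."""
    events = extract_events(ds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_btw = time_between_events(events, first_n) if len(events) >= 2 \
            else float("nan")

    def _try(fn):
        try:
            return fn(ds)
        except (KeyError, ValueError):
            return float("nan")

    return EventSummary(t_btw=t_btw, median_cfr=_try(median_cfr),
                        median_fbg=_try(median_fbg), n_events=len(events))
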