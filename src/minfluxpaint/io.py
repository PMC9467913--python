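"""Reading, writing and filtering of MINFLUX export tables.

A MINFLUX acquisition exports one row per *localization attempt*: valid
localizations carry an estimated position, while discarded (non-valid)
attempts are kept because they terminate binding events.  The columns mirror
the instrument's exported parameters:

========  =====================================================
column    meaning
========  =====================================================
tid       trace identifier -- all attempts of one binding event
tim       time stamp, seconds from acquisition start
vld       validity flag (1 = valid localization)
itr       iteration index (0 = prelocalization)
x, y, z   estimated position, nanometers (z only for 3D runs)
efo       effective emission frequency, Hz (optional)
fbg       background emission frequency, Hz (optional)
cfr       center-frequency ratio, dimensionless (optional)
========  =====================================================

The on-disk format is a plain CSV with these columns plus a JSON metadata
sidecar (``<path>.meta.json``) carrying ``ndim``, ``final_iteration`` and
free-form acquisition metadata, or a single ``.npz`` archive holding the same
content.  Non-valid rows may have NaN positions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "IterationSequence",
    "IterationSpec",
    "SchemaError",
    "read_records",
    "write_records",
    "read_sequence",
    "default_sequence",
    "filter_final_valid",
]

MANDATORY_COLUMNS = ("tid", "tim", "vld", "itr", "x", "y")
OPTIONAL_COLUMNS = ("z", "efo", "fbg", "cfr")

#: final MINFLUX iteration index by dimensionality (four iterations after one
#: prelocalization in 2D, nine in 3D)
FINAL_ITERATION = {2: 4, 3: 9}


class SchemaError(ValueError):
    """Raised when an export table violates the column schema."""


@dataclass
class Dataset:
    """A MINFLUX export table plus the metadata the analysis needs.

    Parameters
    ----------
    records
        One row per localization attempt, sorted by ``tim``.
    ndim
        2 or 3; whether a ``z`` column is present.
    final_iteration
        Index of the last iteration of the sequence; all quantification uses
        only valid records of this iteration.
    metadata
        Free-form acquisition metadata (laser power, pinhole AU, imager
        concentration, ...).
    """

    records: pd.DataFrame
    ndim: int = 2
    final_iteration: int | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ndim not in (2, 3):
            raise ValueError(f"ndim must be 2 or 3, got {self.ndim}")
        if self.final_iteration is None:
            self.final_iteration = FINAL_ITERATION[self.ndim]

    @property
    def position_columns(self) -> list[str]:
        return ["x", "y", "z"][: self.ndim]

    def positions(self) -> np.ndarray:
        """(N, ndim) position array of all records."""
        return self.records[self.position_columns].to_numpy(float)

    def __len__(self) -> int:
        return len(self.records)

    def copy(self) -> "Dataset":
        return replace(self, records=self.records.copy(),
                       metadata=dict(self.metadata))


@dataclass(frozen=True)
class IterationSpec:
    """Parameters of one iteration of a MINFLUX sequence."""

    name: str
    L: float  # TCP diameter, nm
    photon_limit: int | None  # minimal photon count, None if unspecified
    dwell_ms: float | None
    cfr_limit: float | None  # None encodes "off"
    power_factor: float


@dataclass(frozen=True)
class IterationSequence:
    """Ordered iteration parameters, prelocalization first.

    The TCP diameter ``L`` shrinks over the iterations after the
    prelocalization; the default sequences end at L = 40 nm.
    """

    iterations: tuple[IterationSpec, ...]
    ndim: int = 2

    def __len__(self) -> int:
        return len(self.iterations)

    def __getitem__(self, i: int) -> IterationSpec:
        return self.iterations[i]

    @property
    def final_L(self) -> float:
        return self.iterations[-1].L

    def validate(self) -> None:
        Ls = [it.L for it in self.iterations[1:]]
        if any(b >= a for a, b in zip(Ls, Ls[1:])):
            raise ValueError("L must strictly decrease over iterations "
                             "after prelocalization")


def _coerce_schema(df: pd.DataFrame) -> pd.DataFrame:
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing")
    df = df.copy()
    df["tid"] = df["tid"].astype(np.int64)
    df["itr"] = df["itr"].astype(np.int64)
    df["vld"] = df["vld"].astype(float).astype(bool)
    df["tim"] = df["tim"].astype(float)
    for col in ("x", "y", "z", "efo", "fbg", "cfr"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    if not df["tim"].is_monotonic_increasing:
        warnings.warn("time stamps not monotone; re-sorting records")
        df = df.sort_values("tim", kind="stable")
    return df.reset_index(drop=True)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_records(path: str | Path, format: str | None = None) -> Dataset:
    """Read a MINFLUX export table from CSV (+ sidecar) or an ``.npz`` archive.

    ``ndim`` is inferred from the presence of a ``z`` column; records are
    sorted by ``tim``.  Missing optional columns stay absent rather than being
    filled with zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "csv"

    meta: dict[str, Any] = {}
    if format == "csv":
        df = pd.read_csv(path)
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
    elif format == "npz":
        with np.load(path, allow_pickle=False) as npz:
            cols = {k: npz[k] for k in npz.files if k != "_metadata"}
            if "_metadata" in npz.files:
                meta = json.loads(str(npz["_metadata"]))
        df = pd.DataFrame(cols)
    else:
        raise ValueError(f"unknown format {format!r}")

    df = _coerce_schema(df)
    ndim = 3 if "z" in df.columns else 2
    final_iteration = meta.pop("final_iteration", None)
    meta.pop("ndim", None)
    return Dataset(records=df, ndim=ndim,
                   final_iteration=final_iteration, metadata=meta)


def write_records(ds: Dataset, path: str | Path, format: str | None = None) -> None:
    """Write a :class:`Dataset` so that :func:`read_records` round-trips it.

    CSV output is accompanied by a ``<path>.meta.json`` sidecar; ``.npz``
    output embeds the metadata in the archive.
    """
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix == ".npz" else "csv"
    meta = dict(ds.metadata)
    meta["ndim"] = ds.ndim
    meta["final_iteration"] = ds.final_iteration

    if format == "csv":
        out = ds.records.copy()
        out["vld"] = out["vld"].astype(int)
        out.to_csv(path, index=False)
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif format == "npz":
        arrays = {c: ds.records[c].to_numpy() for c in ds.records.columns}
        np.savez(path, _metadata=np.str_(json.dumps(meta)), **arrays)
    else:
        raise ValueError(f"unknown format {format!r}")


def _parse_limit(value: Any) -> float | None:
    if value is None:
        return None
    if isinstance(value, str):
        if value.strip().lower() in ("off", "none", ""):
            return None
        return float(value)
    return float(value)


def read_sequence(path: str | Path) -> IterationSequence:
    """Read a MINFLUX iteration-sequence description from JSON.

    The file holds one entry per iteration (prelocalization included) with
    the TCP diameter ``L`` in nm, a photon limit, a dwell time in ms, a CFR
    limit (number or ``"off"``) and a laser power factor.
    """
    path = Path(path)
    raw = json.loads(path.read_text())
    if isinstance(raw, list):
        entries, ndim = raw, 2
    else:
        entries = raw.get("iterations")
        if entries is None:
            raise ValueError("sequence file lacks an 'iterations' list")
        ndim = int(raw.get("ndim", 2))
    specs = []
    for i, e in enumerate(entries):
        if "L" not in e:
            raise ValueError(f"iteration entry {i} lacks the TCP diameter 'L'")
        specs.append(IterationSpec(
            name=e.get("name", f"iteration_{i}"),
            L=float(e["L"]),
            photon_limit=(None if e.get("photon_limit") is None
                          else int(e["photon_limit"])),
            dwell_ms=(None if e.get("dwell_ms") is None
                      else float(e["dwell_ms"])),
            cfr_limit=_parse_limit(e.get("cfr_limit")),
            power_factor=float(e.get("power_factor", 1.0)),
        ))
    seq = IterationSequence(iterations=tuple(specs), ndim=ndim)
    seq.validate()
    return seq


def default_sequence(ndim: int = 2) -> IterationSequence:
    """The packaged default iteration sequence (2D) or a synthetic 3D stand-in."""
    name = {2: "seq_2d_default.json", 3: "seq_3d_synthetic.json"}[ndim]
    with resources.as_file(resources.files("minfluxpaint.data") / name) as p:
        return read_sequence(p)


def filter_final_valid(ds: Dataset) -> Dataset:
    """Keep only valid localizations of the last MINFLUX iteration.

    All quantification statistics are computed on records with
    ``itr == final_iteration`` and ``vld == 1``; ordering is preserved.
    Idempotent.
    """
    mask = (ds.records["itr"] == ds.final_iteration) & ds.records["vld"]
    out = ds.records.loc[mask].reset_index(drop=True)
    if len(out) == 0 and len(ds.records) > 0:
        warnings.warn("no valid final-iteration records survive the filter")
    return Dataset(records=out, ndim=ds.ndim,
                   final_iteration=ds.final_iteration,
                   metadata=dict(ds.metadata))
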