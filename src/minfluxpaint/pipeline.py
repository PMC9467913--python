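"""Orchestration of the full analysis: filter -> events -> precision ->
drift -> FRC -> render, plus synthetic-measurement series.

The pipeline consumes either a recorded export table or a synthetic
acquisition described inline in the config, and emits a JSON report with
stable key order, the drift trace as CSV, and rendered images.  Every
random stage derives its seed from the config seed, so a config runs to a
byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import drift as drift_mod
from . import events as events_mod
from . import frc as frc_mod
from . import precision as precision_mod
from . import render as render_mod
from .io import Dataset, read_records, write_records
from .synthetic import (AcquisitionConfig, DriftModel, make_structure,
                        simulate_acquisition)

__all__ = ["PipelineConfig", "run_pipeline", "run_measurement_series"]

ALL_STAGES = ("events", "precision", "drift", "frc", "render")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    input: str | None = None            # export-table path; None => simulate
    output_dir: str | None = None       # None => report only, no files
    seed: int = 0
    simulate: dict[str, Any] | None = None  # structure/acquisition/drift spec
    stages: tuple[str, ...] = ALL_STAGES
    drift_params: dict[str, Any] = field(default_factory=dict)
    frc_params: dict[str, Any] = field(default_factory=dict)
    render_params: dict[str, Any] = field(default_factory=dict)
    precision_pre_post: bool = True     # report precision before & after drift
    label: str | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.input is None and self.simulate is None:
            raise ValueError("config needs either an input path or a "
                             "'simulate' section")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_dataset(cfg: PipelineConfig) -> Dataset:
    if cfg.input is not None:
        return read_records(cfg.input)
    sim = dict(cfg.simulate or {})
    struct_spec = dict(sim.get("structure", {"kind": "grid"}))
    kind = struct_spec.pop("kind", "grid")
    structure = make_structure(kind, struct_spec, seed=cfg.seed)
    acq = AcquisitionConfig(**sim.get("acquisition", {}))
    drift_spec = dict(sim.get("drift", {"kind": "none"}))
    drift_kind = drift_spec.pop("kind", "none")
    drift_seed = drift_spec.pop("seed", cfg.seed)
    drift_model = DriftModel(kind=drift_kind, params=drift_spec,
                             seed=drift_seed)
    ds, _ = simulate_acquisition(structure, acq, drift_model, seed=cfg.seed)
    return ds


def _precision_dict(events, ndim: int) -> dict[str, Any]:
    s = precision_mod.precision_summary(events, ndim=ndim)
    return {"sigma_r": s.sigma_r, "sigma_rc": s.sigma_rc,
            "sigma_z": s.sigma_z, "sigma_zc": s.sigma_zc,
            "n_events_used": s.n_events_used}


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run the configured stages on one dataset and return the report.

    Stage failures are isolated: a failing stage records its error string
    and the remaining independent stages still run.
    """
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "label": cfg.label, "seed": cfg.seed, "config_hash": cfg.hash(),
        "metadata": cfg.metadata, "stages": list(cfg.stages),
        "errors": {},
    }

    ds = _load_dataset(cfg)
    report["n_records"] = int(len(ds))
    report["ndim"] = ds.ndim
    evs = events_mod.extract_events(ds)
    report["n_events"] = len(evs)

    if "events" in cfg.stages:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                summary = events_mod.summarize(ds)
            report["events"] = {"t_btw": summary.t_btw,
                                "median_cfr": summary.median_cfr,
                                "median_fbg": summary.median_fbg,
                                "n_events": summary.n_events}
        except Exception as exc:  # noqa: BLE001 - stage isolation
            report["errors"]["events"] = str(exc)

    corrected = evs
    if "drift" in cfg.stages:
        try:
            trace = drift_mod.estimate_drift(evs, **cfg.drift_params)
            corrected = drift_mod.correct(evs, trace)
            report["drift"] = {
                "n_knots": len(trace.times),
                "rms_nm": float(np.sqrt(np.mean(trace.offsets ** 2))),
                "span_s": [float(trace.times[0]), float(trace.times[-1])],
            }
            if out:
                cols = ["t"] + ["dx", "dy", "dz"][: trace.ndim]
                pd.DataFrame(np.column_stack([trace.times, trace.offsets]),
                             columns=cols).to_csv(out / "drift_trace.csv",
                                                  index=False)
                report["drift"]["trace_path"] = "drift_trace.csv"
        except Exception as exc:  # noqa: BLE001
            report["errors"]["drift"] = str(exc)

    if "precision" in cfg.stages:
        try:
            report["precision"] = _precision_dict(corrected, ds.ndim)
            if cfg.precision_pre_post and corrected is not evs:
                report["precision_uncorrected"] = _precision_dict(evs, ds.ndim)
        except Exception as exc:  # noqa: BLE001
            report["errors"]["precision"] = str(exc)

    if "frc" in cfg.stages:
        try:
            pos = frc_mod.combined_positions(corrected)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = frc_mod.frc_resolution(pos, seed=cfg.seed,
                                             **cfg.frc_params)
            report["frc"] = {"resolution_nm": res.resolution,
                             "n_repeats": res.n_repeats,
                             "pixel_nm": res.pixel,
                             "threshold": res.threshold}
        except Exception as exc:  # noqa: BLE001
            report["errors"]["frc"] = str(exc)

    if "render" in cfg.stages and out:
        try:
            rcfg = render_mod.RenderConfig(**cfg.render_params)
            pos_cols = ds.position_columns
            valid = ds.records[ds.records["vld"]
                               & (ds.records["itr"] == ds.final_iteration)]
            positions = valid[pos_cols].to_numpy(float)
            if ds.ndim == 3:
                img = render_mod.render_3d(positions, rcfg)
            else:
                img = render_mod.histogram_2d(positions, rcfg)
            render_mod.save_tiff(img, out / "rendered.tiff")
            render_mod.save_png(img, out / "rendered.png")
            report["render"] = {"image_path": "rendered.tiff",
                                "preview_path": "rendered.png",
                                "bin_nm": rcfg.bin_size}
        except Exception as exc:  # noqa: BLE001
            report["errors"]["render"] = str(exc)

    if out:
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=float))
        write_records(ds, out / "records.csv")
    return report


def run_measurement_series(cfgs: list[PipelineConfig],
                           varied: str) -> pd.DataFrame:
    """Run a series of configs in which one acquisition parameter varies
    (the parameter-exploration experiment design) and tabulate the
    per-measurement statistics against the varied value.

    ``varied`` names a key of each config's ``simulate.acquisition``
    section or of its ``metadata``.
    """
    if len(cfgs) < 1:
        raise ValueError("need at least one config")
    rows = []
    for cfg in cfgs:
        value = None
        if cfg.simulate and varied in cfg.simulate.get("acquisition", {}):
            value = cfg.simulate["acquisition"][varied]
        elif varied in cfg.metadata:
            value = cfg.metadata[varied]
        else:
            raise ValueError(f"config {cfg.label!r} does not define the "
                             f"varied parameter {varied!r}")
        rep = run_pipeline(cfg)
        ev = rep.get("events", {})
        prec = rep.get("precision", {})
        rows.append({varied: value, "label": cfg.label,
                     "t_btw": ev.get("t_btw"),
                     "median_cfr": ev.get("median_cfr"),
                     "median_fbg": ev.get("median_fbg"),
                     "sigma_r": prec.get("sigma_r"),
                     "n_events": rep.get("n_events")})
    return pd.DataFrame(rows).sort_values(varied).reset_index(drop=True)
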