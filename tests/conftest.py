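"""Shared fixtures: the worked toy trace, reusable synthetic acquisitions,
and precomputed optical PSFs (expensive, session scope)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import minfluxpaint as mp


@pytest.fixture()
def toy_trace() -> mp.Dataset:
    """The ten-attempt toy trace: four molecules, interleaved valid (VLD=1)
    and non-valid (VLD=0) localization attempts at TIM = 1..10.

    Molecule 2's trailing non-valid attempt is at TIM = 5 (its event end);
    molecule 4's first valid localization is at TIM = 7, so the gap between
    the two consecutive valid events is 2 time units.  Molecule 3 never
    yields a valid localization.
    """
    rows = [
        # tid, tim, vld
        (1, 1.0, 1), (1, 2.0, 0),
        (2, 3.0, 1), (2, 4.0, 1), (2, 5.0, 0),
        (3, 6.0, 0),
        (4, 7.0, 1), (4, 8.0, 1), (4, 9.0, 0), (4, 10.0, 0),
    ]
    df = pd.DataFrame(rows, columns=["tid", "tim", "vld"])
    df["itr"] = 4
    df["x"] = np.where(df["vld"] == 1, 10.0, np.nan)
    df["y"] = np.where(df["vld"] == 1, 20.0, np.nan)
    df["vld"] = df["vld"].astype(bool)
    return mp.Dataset(records=df, ndim=2, final_iteration=4)


@pytest.fixture(scope="session")
def grid_acquisition():
    """A drift-free acquisition over a 5x5 site grid, with ground truth."""
    struct = mp.make_structure("grid", nx=5, ny=5, spacing=100.0)
    acq = mp.AcquisitionConfig(duration=300.0, c_imager=2.0, sigma_true=2.0)
    ds, truth = mp.simulate_acquisition(struct, acq, seed=11)
    return struct, acq, ds, truth


def _drift_run(drift_model: mp.DriftModel, seed: int):
    struct = mp.make_structure("ring_array", array_shape=(3, 3),
                               array_spacing=250.0)
    acq = mp.AcquisitionConfig(duration=1800.0, c_imager=4.0)
    ds, truth = mp.simulate_acquisition(struct, acq, drift_model, seed=seed)
    events = mp.extract_events(ds)
    per_window = max(200, len(events) // 10)
    trace = mp.estimate_drift(events, target_per_window=per_window)
    corrected = mp.correct(events, trace)
    trace2 = mp.estimate_drift(corrected, target_per_window=per_window)
    return {"events": events, "truth": truth, "trace": trace,
            "corrected": corrected, "trace2": trace2}


@pytest.fixture(scope="session")
def spline_drift_run():
    """Spline random-walk drift (amplitude well under 30 nm) injected,
    estimated over >= 10 windows, and re-estimated after correction."""
    model = mp.DriftModel("spline_random_walk",
                          {"knot_spacing": 180.0, "step_sigma": 8.0}, seed=7)
    return _drift_run(model, seed=2)


@pytest.fixture(scope="session")
def linear_drift_run():
    """Linear drift of 10 nm/h on both axes, same protocol."""
    model = mp.DriftModel("linear", {"velocity": [10 / 3600, 10 / 3600]})
    return _drift_run(model, seed=3)


@pytest.fixture(scope="session")
def optics():
    """Default optical model with precomputed donut and detection PSFs."""
    cfg = mp.OpticalConfig()
    return cfg, mp.excitation_donut(cfg), mp.detection_psf(cfg)


def drift_recovery_rms(run) -> float:
    """RMS distance between estimated and true drift, both gauge-centered,
    over the event start times."""
    t = np.array([e.t_start for e in run["events"]])
    est = run["trace"](t)
    true = run["truth"].drift_at(t)
    resid = (est - est.mean(axis=0)) - (true - true.mean(axis=0))
    return float(np.sqrt((resid ** 2).mean()))


def trace_rms(trace) -> float:
    return float(np.sqrt((trace.offsets ** 2).mean()))
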