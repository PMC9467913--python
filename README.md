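# minfluxpaint

Post-processing and quantification of **DNA-PAINT MINFLUX** localization
data.

MINFLUX localizes single fluorophores by probing them with a donut-shaped
excitation beam at the positions of a targeted coordinate pattern (TCP) that
iteratively shrinks around the molecule (down to L = 40 nm in the final
iteration). Combined with DNA-PAINT — transient binding of dye-labeled
imager strands to docking strands on the target — it reaches low-nanometer
localization precision in cells. This package implements the analysis chain
downstream of the microscope export for users of such data: quality
statistics per measurement, precision estimators, drift correction, FRC
resolution, image rendering, a physical simulator of the center-frequency
ratio, and a synthetic-acquisition generator with ground truth that gives
every estimator a parameter-recovery test.

## What it computes

Working on export tables with one row per localization attempt
(`tid, tim, vld, itr, x, y[, z], efo, fbg, cfr`), using only valid records
of the final MINFLUX iteration:

- **Binding events** — all attempts sharing a trace ID (TID); the event ends
  at the first trailing non-valid attempt. **t_btw** is the median time
  between consecutive valid events (start of the next minus end of the
  previous) over the first 100 events, an inverse throughput measure driven
  by imager concentration.
- **Median CFR** — the center-frequency ratio (emission frequency at the TCP
  center over the mean over the outer positions) of all valid final-iteration
  localizations; a localization quality metric.
- **Localization precision** — per event (≥ 5 localizations),
  σ_r = √((σ_x² + σ_y²)/2); the dataset precision is the median σ_r. The
  *combined* precision divides by √n and weights by the occurrence of n:
  σ_rc = ⟨⟨σ_r⟩/√n⟩_n (σ_z and σ_zc analogously for 3D data).
- **Drift correction** — overlapping windows of ≈ 2000 events are rendered
  (2 nm Gaussian per event position), all window pairs are cross-correlated,
  each correlation peak is Gaussian-fitted for a sub-pixel shift, the drift
  curve is solved from all pairs in a least-squares sense, interpolated by a
  cubic spline and subtracted from the coordinates.
- **FRC resolution** — combined (per-TID mean) x/y positions are randomly
  split in half, both halves rendered, and the Fourier-ring correlation's
  first sustained drop below 1/7 gives the resolution; repeated splits are
  averaged.
- **CFR simulation** — a vectorial (Richards–Wolf) donut excitation PSF at
  642 nm and a pinhole-integrated confocal detection PSF at 680 nm are
  combined per TCP exposure; with a molecule at the pattern center and
  diffusing-imager background B_i = ∫ h_eff,i·c dV, the CFR
  (B_c + I_c)/⟨B̄_out + Ī_out⟩ is evaluated versus concentration, pinhole
  size and L.
- **Rendering** — 2D count histograms (4 nm / 1 nm bins) and 3D Gaussian
  renderings (σ 5 nm) with the z coordinate scaled by 0.7.

## Worked example

```python
import minfluxpaint as mp

structure = mp.make_structure("ring_array", n_corners=8, diameter=100.0,
                              array_shape=(2, 2), array_spacing=300.0)
acq = mp.AcquisitionConfig(c_imager=2.0, sigma_true=2.0, duration=600.0)
ds, truth = mp.simulate_acquisition(structure, acq, seed=42)

events = mp.extract_events(ds)
print(f"{len(ds)} localization attempts, {len(events)} binding events")
print(f"t_btw        = {mp.time_between_events(events):.2f} s "
      f"(analytic median {mp.expected_t_btw(acq, structure, 'median'):.2f} s)")
print(f"median CFR   = {mp.median_cfr(ds):.3f}")
print(f"median f_bg  = {mp.median_fbg(ds):.0f} Hz")
s = mp.precision_summary(events)
print(f"sigma_r      = {s.sigma_r:.2f} nm   sigma_rc = {s.sigma_rc:.2f} nm")
res = mp.frc_resolution(mp.combined_positions(events), pixel=1.0, seed=0)
print(f"FRC resolution = {res.resolution:.1f} nm")
```

prints

```
9106 localization attempts, 392 binding events
t_btw        = 1.03 s (analytic median 1.08 s)
median CFR   = 0.400
median f_bg  = 19991 Hz
sigma_r      = 1.99 nm   sigma_rc = 0.49 nm
FRC resolution = 2.2 nm
```

The 32 docking sites (four 8-corner rings of 100 nm diameter) bind imagers
at k_on·c ≈ 0.02 events/s each, so consecutive events over the whole field
are ≈ 1 s apart; the per-event scatter recovers the injected 2 nm noise,
and combining the ~13 localizations of a typical event brings the combined
precision to ~0.5 nm. The FRC resolution of the combined positions reflects
the 2 nm rendering-independent scatter, not the repeated localizations.

The same stages are available from the shell:

```bash
mfx simulate --structure grid --c-imager 4 --out run.csv
mfx events run.csv
mfx precision run.csv
mfx drift run.csv --trace-out drift.csv
mfx frc run.csv --pixel 1
mfx cfr-sim --conc 0.5 --conc 2 --pinhole 0.6 --pinhole 1.4
mfx render run.csv --bin 4 --out run.tiff
```

## Layout

- `src/minfluxpaint/io.py` — export-table and iteration-sequence I/O, the
  final-iteration validity filter
- `src/minfluxpaint/synthetic.py` — ground-truth acquisition generator
- `src/minfluxpaint/events.py` — binding events, t_btw, median CFR / f_bg
- `src/minfluxpaint/precision.py` — σ_r, σ_z, σ_rc, σ_zc
- `src/minfluxpaint/drift.py` — redundant cross-correlation drift correction
- `src/minfluxpaint/frc.py` — Fourier ring correlation resolution
- `src/minfluxpaint/cfr.py` — vectorial PSF models and the CFR simulator
- `src/minfluxpaint/render.py` — 2D/3D image rendering
- `src/minfluxpaint/pipeline.py`, `cli.py` — orchestration and the `mfx` CLI

See `docs/methods.md` for the models, assumptions and numerical choices.
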