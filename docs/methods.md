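# Methods

This note records the models behind each stage, the parameters that matter,
and the numerical and design choices made where the procedure left room.

## Export schema and filtering

The instrument's export is re-specified as an open tabular schema: one CSV
row per localization attempt with columns `tid` (trace ID), `tim` (s),
`vld` (validity flag), `itr` (iteration index, 0 = prelocalization),
`x, y[, z]` (nm), and optionally `efo`, `fbg` (Hz) and `cfr`; `ndim`,
`final_iteration` and free-form acquisition metadata live in a JSON sidecar
(or inside an equivalent `.npz` archive). Non-valid attempts are stored as
full rows with `vld = 0` and NaN positions — they are required to determine
event end times. All quantification uses only valid records of the final
iteration (the fourth in 2D, the ninth in 3D, after one prelocalization);
`filter_final_valid` applies exactly that cut and is idempotent.

Iteration-sequence files are JSON with one entry per iteration: TCP
diameter `L` (nm), photon limit, dwell (ms), CFR limit (number or "off"),
laser power factor. The packaged 2D default ends at L = 40 nm
(288 → 151 → 76 → 40 after a 160 nm prelocalization). No public parameter
set exists for the 3D sequence beyond its shape (nine iterations plus
prelocalization, final L = 40 nm), so the packaged 3D file is a synthetic
stand-in, labeled as such, carrying only those facts.

## Binding events and t_btw

Successive localizations of one bound imager share a TID. An event's start
is the time stamp of its first valid final-iteration localization; its end
is the time stamp of the first non-valid attempt following its last valid
one (the instrument terminates traces after a preset number of non-valid
attempts; that count is instrument configuration and is not needed — only
the first trailing non-valid row matters). If the export contains no such
row the last valid time stamp is used as a fallback.

t_btw is the median of gaps `start(k+1) − end(k)` over the first 100
events (all of them when fewer, with the count reported). Negative raw gaps
— overlapping traces, which the instrument can produce — are clipped to
zero with a warning rather than dropped, keeping the median well defined
while logging the occurrence.

f_bg is taken from the `fbg` field of all last-iteration records (valid and
non-valid), since the microscope estimates it continuously between events;
no re-estimation from photon streams is attempted. The median CFR uses
valid last-iteration records only.

## Precision estimators

Per event with at least `min_locs = 5` localizations (the threshold applies
to all σ statistics, combined ones included):

    sigma_r = sqrt((s_x^2 + s_y^2) / 2),     sigma_z = s_z,

with sample standard deviations using the n−1 denominator (unbiased
variance at small n; the choice is ours). The dataset precision is the
median over eligible events. The combined precision is

    sigma_rc = <sigma_r> * sum_n w_n / sqrt(n) / sum_n w_n,

i.e. the global mean per-event σ scaled by the n-histogram-weighted mean of
1/√n. The verbal definition ("weighted average of the average … divided by
√n and weighted by the occurrence of n") admits a second reading — the mean
over events of σ_i/√n_i — which is provided behind `per_event=True` for
sensitivity checks; the two coincide when σ and n are uncorrelated, which
holds for the generator and approximately for real data.

## Synthetic acquisition generator

The generator emulates the export layer, not the microscope: no photon
counts, no on-line position estimation, no photophysics (blinking,
bleaching) or diffusion-limited transport. What it does model:

- **Binding kinetics.** Each docking site is an independent renewal
  process: after an event ends, the next starts after an exponential
  waiting time with rate k_on·c_imager. At low duty cycle the merged start
  process is close to Poisson with rate R = k_on·c_imager·N_sites, so the
  mean merged gap is 1/R and its median — the statistic t_btw reports — is
  ln 2 / R. `expected_t_btw` returns either. Defaults (k_on = 0.01
  events·s⁻¹·nM⁻¹, c = 2 nM, mean event duration 0.2 s, 100 localizations/s
  during an event) are arbitrary test settings chosen for realistic event
  statistics (roughly second-scale waiting times, tens of localizations per
  event); they are not measured constants.
- **Localizations.** Emitted on a fixed duty cycle at intervals 1/loc_rate
  (the instrument repeats the last iterations on a fixed cycle); position =
  site + drift(t) + isotropic Gaussian noise σ_true (σ_z configurable
  separately). Each event is closed by `n_invalid_tail` non-valid rows
  continuing the cadence; the first of them defines the true end time.
- **Ancillary columns.** CFR is drawn lognormal around a configurable
  median (0.4) so median-CFR code paths are exercised without the optics
  model (the physical CFR lives in the simulator module); `fbg` is the
  configured background with 5% relative jitter; `efo` is lognormal around
  100 kHz.
- **Drift.** `none`, `linear` (nm/s per axis), or `spline_random_walk`
  (cumulative Gaussian steps at regular knots joined by a cubic spline);
  drift(0) = 0 always.
- **Structures.** Grid, ring array (default ring diameter 100 nm — a
  synthetic convenience, not a claim about any real complex), wiggly
  filament, or uniform random sites.

Identical seeds give byte-identical datasets. Because events are regular
within a trace and noise is exactly Gaussian, passing recovery tests shows
estimator correctness under the stated model — it does not validate
behavior under real-data pathologies (non-Gaussian tails, CFR-position
correlations, index hopping between nearby sites).

## Drift correction

One point per event (the mean position of its TID — event positions, not
raw localizations), windows of `target_per_window` events with 50% overlap
(both exposed as configuration; the event count per window follows the
≈2000-events practice on real data, scaled to the dataset). Each window is
rendered with a 2 nm Gaussian per point (1 nm pixels in 2D, 2 nm voxels in
3D to bound memory); cross-correlations are computed spectrally on the
common grid, and the integer peak is refined per axis by a 1D Gaussian fit
over 7 samples through the peak (parabolic log-fit fallback; small
neighborhoods resist secondary peaks). Pairs whose normalized peak height
falls below a quality threshold (default 0.05) are excluded. Per-window
offsets p minimize Σ‖p_j − p_i − d_ij‖² over all retained pairs
(unweighted), with the gauge mean(p) = 0; a disconnected pair graph is an
error naming the components. A cubic spline through (window-center time,
offset) is evaluated at each event's start time (events are short against
drift timescales) and subtracted; extrapolation clamps to the end knots.

The method assumes drift is quasi-static within one window: the drift
correlation time must exceed the window time span, or window images blur
and the least squares degrades. The test fixture (spline knots every 180 s
over 30 min, 8 nm steps, ≥ 10 windows) respects that regime; recovery there
is below 1 nm RMS with a second-pass correction under 10% of the first.

## FRC resolution

Combined (per-TID mean) x/y positions are split into random halves; each
half is rendered as a plain 2D count histogram (no Gaussian blur — blurring
multiplies both spectra by the same transfer function and biases the
threshold crossing) with default 2 nm pixels on a common power-of-two
square grid. The ring statistic is

    FRC(q) = Re Σ_ring F_A conj(F_B) / sqrt(Σ|F_A|² Σ|F_B|²)

over one-bin rings up to Nyquist. The resolution is the inverse of the
first frequency where the raw curve drops below 1/7 and stays below for one
further ring (a guard against single-ring noise dips), located by linear
interpolation between the bracketing rings; no curve smoothing by default.
Ten seeded random splits are averaged; repeats without a crossing (the
structure is resolved to the Nyquist limit of the chosen pixel) are
excluded with a warning. Combined positions are used because repeated
localizations within an event otherwise dominate the correlation and the
result degenerates to the single-localization precision.

## CFR simulator

The donut is the focal intensity of a charge-1 vortex beam with circular
polarization co-rotating with the vortex, computed with the Richards–Wolf
vectorial diffraction integral (apodization √cosθ, NA 1.4 oil, n = 1.518 —
package defaults for a high-NA oil objective). With that handedness every
focal-field component carries a Bessel function of order ≥ 1, so the
on-axis intensity is *exactly* zero — the ideal donut null is analytic, not
numerical. The azimuthal integrals are done in closed form (Bessel
decomposition); the aperture-angle integral uses a 256-point trapezoid
rule. A chirp-z-accelerated field evaluation would be an optimization only;
the direct quadrature is exact to the same physics.

Detection: the scalar focal intensity at 680 nm convolved per z-plane with
the back-projected hard pinhole disc (1 AU = 1.22·λ_det/NA diameter in the
sample plane), normalized to 1 on axis.

Per TCP exposure i (center plus n_outer = 6 points on the circle of
diameter L; the exposure count is not a published value and is
parameterized — the symmetric outer mean makes the default not
load-bearing), the effective PSF is the shifted donut times the centered
detection; the shifted donut is evaluated exactly from its radial profile,
never by grid interpolation of a shifted array. Background per exposure is
B_i = ∫h_eff,i dV × c (1 nM = 6.022×10⁻¹⁰ molecules·nm⁻³), exactly linear
in c. The molecule sits at the origin, so its signal is I_i = h_eff,i(0);
for the central exposure of an ideal null, I_center = 0. An imperfect zero
is modeled as an additive excitation floor ε·peak acting on the central
signal (default ε = 0). Since the CFR compares emission *frequencies*
(count rates), equal outer dwell shares cancel; unequal dwell fractions are
supported as weights on the outer mean.

CFR = (B_center + I_center)/⟨B̄_outer + Ī_outer⟩. Defaults: 20 nm grid over
a cube of half-span 3·λ_det/NA (≈1.46 µm; contributions outside are
negligible at default pinholes — halving the grid spacing moves the CFR by
≈ 0.2%). The simulator reproduces the qualitative dependencies: CFR → 0 as
c → 0 for a perfect zero, monotone growth with concentration and with
pinhole diameter. Shot noise on the CFR and aberrations are out of scope.

## Rendering

2D: count histograms, bin origin anchored at the data minimum rounded down
to a bin multiple, half-open bins — this makes a 4 nm image the exact 4×4
block sum of the aligned 1 nm image. 3D: z is scaled by 0.7 at render time
only (stored coordinates stay unscaled, so σ_z statistics are computed on
unscaled z; the alternative — scaling before statistics — would shrink σ_z
by the same factor and is intentionally not done), then a 5 nm Gaussian per
localization. Output is 32-bit float TIFF (counts exact to 2²⁴) plus a PNG
preview.

## Pipeline

`run_pipeline` executes filter → events → drift → precision (after, and
optionally before, correction) → FRC → render on a loaded or simulated
dataset; stage failures are isolated and reported. Reports are JSON with
sorted keys, embedding the seed and a config hash, so identical configs
reproduce byte-identical reports. `run_measurement_series` runs configs
varying one acquisition parameter (e.g. imager concentration) and tabulates
t_btw, median CFR, median f_bg and σ_r against it. Drift correction
precedes precision and FRC by default, matching the 3D workflow order.

## Problem sizes and known limitations

The test suite and the acceptance script run on desk-scale synthetic data:
hundreds to a few thousand events, 30-minute simulated acquisitions,
128–1024-pixel FRC images and the default 20 nm PSF grid (the
grid-refinement check uses 10 nm). These sizes were chosen as the smallest
at which the Monte-Carlo bands in the tests are meaningful. Known
limitations: the event end-time rule encodes the trailing-non-valid-row
convention of the open schema, not the instrument's hidden attempt count;
the drift solver weights all retained pairs equally; FRC is 2D only (no
Fourier shell correlation); the CFR simulator ignores shot noise and
aberrations; and the generator's kinetics constants are test settings, so
absolute t_btw values are only meaningful relative to its own model.
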