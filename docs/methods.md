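# Methods

## Sensor model and unit conventions

A Zn²⁺ sensor with dissociation constant *K*d and Hill coefficient *n*
follows the Hill isotherm FS(c) = cⁿ/(Kdⁿ + cⁿ). The package carries
concentrations internally in pM and accepts *K*d in nM, converting once at
`SensorParams` construction; this avoids silent unit mixing between the
nM-scale binding constants and the pM-scale intracellular results.

Two sensors ship as built-ins: the FluoZin-3 intensity dye (*K*d 9.1 nM,
*n* = 1 — a single-site dye) and the NES-ZapCV2 FRET sensor (*K*d 5.3 nM).
The FRET sensor's Hill coefficient is not a published constant and biosensor
response curves are often sub-cooperative, so *n* is a required input for
that sensor rather than a guessed default.

Fractional saturation FS = (X − F_min)/(F_max − F_min) is clipped to [0, 1]
with a `clipped` flag when noise pushes a measurement past a calibration
endpoint; clipping instead of raising keeps whole-experiment batch analysis
alive while leaving the affected cells identifiable and excludable. The
inversion [Zn²⁺] = Kd/(1/FS − 1)^(1/n) diverges at FS = 1, which is
reported as a saturated-signal error (per-cell, it becomes a QC flag and a
NaN concentration).

## Titration fitting

`fit_titration` performs one pooled least-squares fit of
R(c) = f_min + (f_max − f_min)·cⁿ/(Kdⁿ + cⁿ) across all replicates,
matching the convention of reporting a single apparent *K*d from a batch of
titration experiments rather than averaging per-replicate fits. *K*d and
*n* are optimized on a log scale, which enforces positivity without
constraint handling; responses are normalized by their maximum inside the
fitter, making the fit exactly equivariant under rescaling of the response
units. Starting values are self-started from the data (endpoints from the
response range, *K*d from the concentration nearest the half-range
response, *n* = 1). Standard errors come from the local curvature
(s²·(JᵀJ)⁻¹ with a delta-method back-transform for the log-scale
parameters). Non-convergence returns a diagnosable failed-fit record, not
an exception; too few distinct concentrations for the number of free
parameters is a hard error.

## Trace pipeline

Per cell: background-subtract each channel per frame; form the working
signal — FRET/donor ratio for two-channel sensors (frames with donor ≤ 0
after subtraction are masked as NaN, not interpolated; a cell with > 20%
masked frames is excluded), or the background-subtracted intensity for a
dye. Calibration endpoints are the minimum of the boxcar-smoothed signal in
the chelator phase and the maximum in the ionophore phase (default window
5 frames, configurable) — a reproducible surrogate for manual inspection of
calibration records. The resting value is the baseline-phase mean; the peak
is the maximum of the smoothed signal from stimulation onset to the start
of the calibration, since cells peak at different delays and recover at
different rates. A peak below resting + 2×(baseline SD) is flagged
`peak_within_noise`. Summaries report mean ± SEM (sample SD/√n) across
included cells; per-cell concentrations are computed first and averaged
after, with no error propagation through the Hill inversion.

Known estimator biases, visible in the recovery tests: the smoothed-extrema
endpoint rule biases F_min slightly low (minimum over many noisy frames),
and the smoothed-maximum peak rule biases the peak slightly high. At 2%
signal-proportional noise these contribute a few percent upward bias to
recovered concentrations, growing toward low saturations (≈ +15–18% at
50 pM for FluoZin-3, where FS ≈ 0.005); resting-concentration recovery
across 50–500 pM still shows a pooled median absolute error well under 15%.

## Synthetic data

The generators define the conditions the recovery tests certify:

* **Protocols.** The stimulation protocol is 60 s baseline, 10 s
  stimulation, 900 s washout imaging, 120 s chelator, 180 s ionophore; the
  calibration-only protocol is 120/180/60/180 s. Frame interval defaults to
  2 s, a typical spinning-disk time-lapse cadence for quarter-hour
  acquisitions.
* **Kinetics.** True FS relaxes first-order toward the active phase's
  target (resting FS, peak FS, 0 in chelator, 1 in ionophore) with a single
  τ = 20 s; the depolarization-driven rise uses a fast τ = 2 s so cells
  reach their peak within the 10 s stimulation. Transient cells relax back
  to baseline during washout; sustained cells (default fraction 0.3, a free
  parameter — the split is not a measured quantity) hold a plateau at 80%
  of their rise.
* **Signal scales.** FluoZin-3 traces are single-channel with
  F_max/F_min = 50 (the dye brightens ~50-fold on Zn²⁺ binding); FRET
  traces are two channels (donor ≈ 1000 a.u., ratio endpoints 1–3) whose
  ratio follows the model, so the ratio-computation stage is exercised.
  Both ride on a constant 50 a.u. background emitted as a separate series.
* **Variability and noise.** Cell-to-cell endpoint variability uses
  lognormal multipliers (CV 0.2) applied to F_min and to the dynamic range
  separately, so F_max > F_min is preserved; true per-cell concentrations
  are lognormal around the group means (CV 0.15), with each cell's peak
  scaled from its own resting level so peak ≥ resting holds in truth.
  Noise is additive Gaussian with SD proportional to the local noiseless
  signal (default 2%), the simplest model consistent with EMCCD shot+read
  noise at typical exposures. Optional monoexponential bleaching is off by
  default.
* **Images.** Puncta fields are Gaussian spots (σ 1.5 px, amplitude
  lognormal around 1) on a 128² grid; a controllable fraction of channel-B
  spots share channel-A centers, the rest are independent, and channel B is
  integer-translated before noise.

What the generators do **not** emulate: spatially resolved cells (signals
are ROI-level), focus drift, movement artifacts, autofluorescence,
compartmentalized dye, or non-stationary backgrounds. Passing recovery
tests therefore certify the analysis chain under the stated noise model,
not robustness to every artifact of real microscopy.

All generators are deterministic under a fixed seed, which is echoed into
each ground-truth record.

## Exact nonparametric tests

The signed-rank null is built by convolution over ranks 1..n (each rank
contributes 0 or itself to V); the Mann–Whitney null by the
bounded-partition dynamic program (partitions with ≤ n1 parts each ≤ n2),
both in exact integer arithmetic. Tests are exact when sizes ≤ 50 and the
data are tie-free, else a normal approximation with continuity and tie
corrections is used — mirroring the convention of the standard statistical
environment, which is required to reproduce published p-values computed
there. Zero differences are dropped (with the reduced n reported);
two-sided p = min(1, 2·min(lower tail, upper tail)), tails including the
observed value. `p_from_statistic` evaluates the same exact nulls directly
from a reported V or U with the sample sizes, so published statistics can
be re-checked without raw data. Shapiro–Wilk normality screening is
deliberately delegated to `scipy.stats.shapiro` rather than reimplemented.

## Colocalization

Registration is translation-only — chromatic displacement between channels
on one camera is translational to first order — estimated as the integer
shift maximizing FFT cross-correlation of mean-subtracted references, with
ties broken toward the smallest |dx|+|dy| then lexicographically, so the
estimate is deterministic. Applied shifts zero-fill the vacated border and
return a validity mask; correlations are always computed on the overlap so
the border never inflates r. Adaptive thresholding marks a pixel foreground
when it exceeds its window-local mean scaled by f = 2·(1 − sensitivity)
(window default 2·⌊min(dims)/16⌋ + 1); the scale rule is this package's
declared surrogate for the unspecified internals of the MATLAB-style
`sensitivity` parameter, chosen to satisfy the monotone contract that
higher sensitivity admits more foreground. The pipeline reports, per field,
Pearson correlation both on raw intensities and restricted to the union of
the two channels' foreground masks (both labeled, since either convention
is defensible and they answer slightly different questions).

## Problem sizes and numerical choices

Recovery experiments in the test suite run at the published designs: 11
titration replicates on a 0.1–100 nM grid (12 concentrations), 32- and
18-cell stimulation arms at 2% noise, 14-cell calibration summaries, 20
seeded repetitions for rate-type claims and 50 for bias medians. These
sizes make the full suite run in seconds while keeping every claim at the
scale it is stated for. Tolerances asserted in tests were fixed from
closed-form expectations where available (e.g. 2/2³²) and otherwise from
the generators' measured noise floor; optimizer tolerances are set to
1e-15 so fit results are reproducible to well below any asserted tolerance.

## Limitations

* In-cell *K*d may differ from the in-vitro value used for inversion; the
  package deliberately performs no in-cell re-estimation, so reported
  concentrations are approximate by construction.
* No spectral bleed-through or photophysics correction beyond endpoint
  calibration.
* Exact tests require tie-free data; heavily tied data silently (but
  flaggedly) fall back to the corrected normal approximation.
* Object-based colocalization measures (Manders coefficients, object
  overlap) are out of scope; Pearson 2D correlation is a pixel-intensity
  co-occurrence proxy only.
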