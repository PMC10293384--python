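# Methods

`megslow` reimplements, as a tested and reusable pipeline, a source-space
resting-state MEG analysis of longitudinal Parkinson's-disease progression:
band-specific relative spectral power and dominant-peak frequency, corrected
amplitude envelope correlation (AEC-c) on a 90-region parcellation,
connection-level permutation statistics, and linear mixed-model analyses of
group differences, longitudinal change and clinical associations.  Because
the patient recordings such analyses are run on are not publicly available,
the package ships a synthetic-cohort generator with exactly known ground
truth; every claim the test suite makes is a claim about recovering that
ground truth, not about any particular patient population.

## Parcellation

All computations run on region-of-interest (ROI) time series labelled by an
AAL-style atlas of 90 regions: 78 cortical and 12 subcortical (bilateral
hippocampus, amygdala, caudate, putamen, pallidum, thalamus).  The packaged
default ordering places cortical regions at positions 1–78 and subcortical
at 79–90; a user-supplied atlas file may permute this freely, since every
downstream reduction depends only on the count and the cortical/subcortical
partition.  Indices are 0-based internally and 1-based in reports.

## Segmentation and filtering

Continuous recordings are split into consecutive, non-overlapping epochs of
4096 samples — 13.11 s at the 312.5 Hz working sample rate — and the first
`n_epochs` (default 10) are retained.  Recordings acquired at higher rates
are FIR-low-pass filtered and decimated first (e.g. 1250 Hz / 4 → 312.5 Hz);
a decimation that would drop the rate to 60 Hz or below is rejected because
the analysis range extends to 30 Hz.

Band filtering uses five canonical bands that tile the 0.5–30 Hz analysis
range exactly: delta (0.5–4 Hz), theta (4–8), alpha1 (8–10), alpha2 (10–13)
and beta (13–30).  The gamma band is outside the scope of the pipeline.
Filtering is performed per epoch by multiplying the real FFT with a
raised-cosine amplitude mask whose −6 dB points sit on the band edges, with
transition width `min(0.5 · low, 2)` Hz.  This choice (rather than a
time-domain FIR kernel) is deliberate: for the delta band the prescribed
transition width (0.25 Hz) would need a kernel longer than the epoch itself,
whereas the frequency-domain mask is exactly zero-phase at every length —
and zero phase matters because envelope connectivity is sensitive to
envelope timing.  The zero-lag property is asserted by test.

## Spectral measures

Per-region spectra are single-taper periodograms of whole epochs (no
sub-windowing), averaged over epochs, keeping the native grid spacing
fs/L = 312.5/4096 ≈ 0.076 Hz.  The default taper is a Hann window for
leakage control; a boxcar can be requested where the closed-form
periodogram of a tone is wanted (the Hann kernel spreads even an on-grid
tone over three bins, so single-bin concentration statements only hold for
the boxcar).  Spectra may be area-normalized over 0.5–30 Hz for plotting;
relative band power is scale-free and identical either way.

Relative band power assigns bins half-open, `low ≤ f < high`, against a
denominator summed over `0.5 ≤ f < 30`, so the five bands sum to one per
region to 1e-9.  Peak frequency is the argmax of the epoch-averaged
spectrum on the closed 4–13 Hz range; ties break toward the lower
frequency (a determinism convention; ties have measure zero on real data).
Whole-brain summaries are unweighted means over the 78 cortical and the 12
subcortical regions, computed after epoch averaging.

## AEC-c

For each unordered region pair and each epoch, both signals are demeaned;
each is orthogonalized against the other by removing its zero-lag
least-squares projection; envelopes are magnitudes of the analytic
(Hilbert) signal; the envelope of each original is Pearson-correlated with
the envelope of the other's orthogonalized residual; the two directed
correlations are averaged and mapped through (r + 1)/2.  Epoch values are
averaged last (the affine map commutes with averaging).  The first and
last 5% of each epoch's envelope are discarded before correlating, to keep
analytic-signal edge artifacts out of the estimate.  The orthogonalization
is the pairwise two-direction procedure, not the multivariate
joint-whitening variant; the pipeline computes pairwise values throughout.

Values lie in [0, 1] with 0.5 marking no coupling.  At the study geometry
(alpha2 band, 10 epochs × 4096 samples) the measured null across 2000
independent epoch-pairs is 0.4956 with standard error 0.0015: estimating
the orthogonalization regression per epoch induces a small negative
finite-sample bias (about −0.004 here), a known property of the corrected
measure.  The calibration tests therefore assert the operative bracket
[0.48, 0.52] rather than exact centering.

The vectorized matrix path exploits linearity of the Hilbert transform
(the analytic signal of `y − βx` equals `H(y) − βH(x)`) and is verified
against a literal loop-over-pairs reference to 1e-10.

## Permutation tests and FDR

Connection-level group differences use the difference of group means per
connection as statistic, a null built by full label exchange (independent
groups) or within-subject condition swaps (paired longitudinal contrast),
two-sided p-values with the add-one correction p = (b+1)/(N+1), and
Benjamini–Hochberg FDR across the 4005 unique connections.  The statistic,
the exchangeability scheme and the BH variant are field-default
conventions; all are isolated behind the function's arguments.

A structural consequence worth stating: the smallest attainable adjusted
q for a solitary non-null connection is `m/(N+1)` — about 2.0 at N = 2000
permutations and 0.08 even at N = 50 000, both above 0.05.  An isolated
effect on a single connection therefore cannot survive BH correction at
these permutation counts regardless of its size; detectability requires
either many affected connections (which lower each other's BH threshold)
or a permutation count N ≥ 20·m.  The acceptance test that demands ≥90%
detection of one planted edge documents this floor in its failure message
and fails by design; the companion global-null calibration (expected
false-discovery proportion ≤ 0.05 over 100 repetitions) passes.

## Mixed models

All longitudinal models are linear mixed models with a subject random
intercept, estimated by REML via statsmodels, with large-sample Wald
p-values (recorded in each result's metadata).  Missing visits contribute
through the likelihood; there is no imputation and no listwise deletion.

* Progression: measure ~ visit dummies (baseline reference) + baseline age
  + baseline disease duration + sex + dichotomized education + LEDD,
  patients only.  Significance flags use Bonferroni 0.05/6 (three
  group/time contrasts × two region sets, per band family).
* Baseline group comparison: measure ~ group dummies (controls reference)
  + age + sex + education, baseline rows only.  Each subject contributes
  exactly one row, so a subject random intercept is not identifiable
  (confounded with the residual); the model is fitted by OLS, whose
  fixed-effect estimates coincide with the degenerate mixed model.
* Group × location interaction: baseline measure in long form (cortical
  and subcortical row per subject), controls vs de novo patients, with
  the interaction term testing whether the de novo deviation differs by
  location; random intercept ties the two rows.
* Clinical associations: CAMCOG or UPDRS-III ~ one spectral measure +
  age + disease duration + sex + LEDD + recording system (a dummy for
  the final visit, which used a different MEG system), plus education
  for CAMCOG only; patients only, flagged at 0.05.  One spectral
  predictor per model — the spectral measures are too collinear to
  combine.  Whole-brain connectivity is summarized but deliberately not
  fed into the clinical models.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes, and
nothing more:

* **Signals.** White noise is spectrally shaped in the frequency domain to
  a model PSD: background `f^(−χ)` (default χ = 1, flattened below
  0.5 Hz) plus a Gaussian oscillatory bump (σ = 0.6 Hz) at the subject's
  peak frequency, scaled so bump power is `peak_power_ratio` (default 1.0)
  times the 0.5–30 Hz background power, with optional per-band
  multiplicative tilts.  The implied true band powers and true peak are
  available in closed form and returned as ground truth.
* **Envelope coupling.** Designated region pairs share a <1 Hz unit-SD
  modulator applied as a log-normal gain exp(a·m) to their band-limited
  components (re-filtered to the band support, so out-of-band content is
  untouched; band RMS preserved).  A linear gain saturates near envelope
  correlation 0.57, below useful planting levels, which motivated the
  log-normal form (reaching ≈0.9 in alpha2).  The gain for a requested
  correlation is calibrated numerically once per (band, sample rate) with
  a fixed internal seed and cached.
* **Cohort.** Defaults mirror the target study population: 16 healthy
  controls (baseline only), 17 de novo and 44 treated patients, visits
  BL/FU1/FU2, group-specific baseline demographics (age, sex, education,
  disease duration, LEDD with ≈ +370 mg/visit), subject peak frequencies
  N(10.0/9.5/9.0, 0.8²) Hz by group, 0.5 Hz/visit slowing in patients,
  ±4%/visit band tilts in the slowing direction, and missing-at-random
  dropout (default 0.2 per transition, monotone: once dropped, absent
  thereafter — the mixed models are exercised against exactly this
  missingness).  Clinical scores are noisy linear functions of the true
  peak frequency plus a subject random intercept: CAMCOG = 60 + 4·peak +
  b + ε (b SD 2, ε SD 3), UPDRS-III = 70 − 6·peak + b + ε (ε SD 4),
  undefined for controls.  Everything is reproducible bit-for-bit from
  the design seed via spawned seed sequences.

What the generator does **not** emulate: sensor-level physics and source
leakage between ROIs (leakage robustness is exercised by explicit
instantaneous mixing in the connectivity tests instead), artifacts and
their visual rejection, non-stationarity, spatial correlation structure
across regions, and any nonlinear clinical dose–response.  Passing tests
therefore demonstrate that the pipeline recovers known structure of this
generative family under realistic cohort geometry — not that the same
effect sizes hold in patients.

## Problem sizes used by the test suite

Simulation-heavy checks run at sizes chosen for a single CPU:

* AEC-c null calibration: 200 pairs × 10 epochs × 4096 samples.
* Leakage robustness: 100 realizations per mixing level, 5 epochs each.
* Parameter recovery: 100 cohorts of 61 patients, recordings shortened to
  2 epochs × 1024 samples (peak-frequency resolution 0.305 Hz; averaging
  over 78 cortical regions keeps the measurement error of the cortical
  mean near 0.04 Hz, negligible against the 0.8 Hz between-subject SD).
* FDR calibration: 100 repetitions of 20 vs 20 subjects at 2000
  permutations, with exchangeable null matrices drawn directly around the
  0.5 null point (the permutation/FDR layer is distribution-free under
  exchangeability, so signal simulation adds nothing to this check);
  the planted-edge runs do use full signal-based AEC-c matrices
  (3 epochs × 1024 samples).

## Known limitations

* The atlas's region ordering is a packaged convention; no claim is made
  that it reproduces any specific published ordering, and no geometry is
  attached to regions.
* Peak frequency is a grid argmax, not a parametric (1/f-separated) peak
  fit; on spectra without a clear alpha-range peak it returns the
  lower range edge.
* The AEC-c null sits slightly below 0.5 at finite epoch counts (above).
* Wald p-values from REML fits are large-sample approximations; no
  small-sample degree-of-freedom correction is applied.
* Single-connection effects cannot survive BH-FDR at practical
  permutation counts (the `m/(N+1)` floor above).
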