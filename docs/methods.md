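# Methods

This note documents the models, the estimators, the synthetic data the
package is validated on, and the numerical choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Signal model and synthetic data

The pipeline operates on source-level trial data from two regions, olfactory
bulb (OB) and piriform cortex (PC): a real-valued array of trials × regions
× samples with a time axis spanning −1.0 to +4.0 s around odor onset at
512 Hz by default, with the odor on from 0 to 2.0 s. The generator emulates
the study conditions of 46 participants × 123 trials at those defaults;
tests and the acceptance script run scaled-down configurations (typically
6 participants × 40 trials, 128–512 Hz, 3 s epochs, coarser time–frequency
grids) chosen so the full calibration experiments complete on one CPU in
minutes. The statistical structure being tested does not depend on these
sizes, only the Monte-Carlo precision of the checks does, and the binomial
bands used by the calibration tests account for the replicate counts used.

**Background.** Gaussian 1/f^α noise with α = 1, synthesized in the
frequency domain (white complex spectrum shaped by f^(−α/2)) and scaled to
unit standard deviation per trial. This matches the broadband spectral decay
of EEG-like signals and keeps the generator analytic. There is no sniff
waveform, no evoked transient, no cross-region background correlation, and
no non-stationarity other than the injected effects — so passing tests
demonstrate correctness of the estimators under the assumed model, not
robustness to every property of real recordings.

**Ratings.** Perceived intensity is a two-component Gaussian mixture tied to
the balanced Low/High concentration condition, clipped to [0, 10]. The
published class means (3.36 ± 2.14 low, 6.80 ± 1.86 high) describe the
classes *after* a within-participant median split, and a median split
exaggerates the separation of the underlying mixture components; the
generator therefore solves analytically (truncated-normal moments plus root
finding) for component means such that the expected post-split class means
equal the targets. With the default SDs the calibrated components sit at
≈ 4.23 and ≈ 5.92. Because the components overlap, the median-split class
is deliberately not identical to the concentration condition — mirroring
the dissociation between physical concentration and percept that the
analyses probe. Valence is near-neutral noise; sniff AUC carries a weak
positive intensity link (slope 0.03 per rating unit), matching its role as
a nuisance covariate.

**Injected effects.** Each effect adds a contribution computed from the
pristine background using its own child random stream, so effects superpose
exactly and removing one leaves the rest unchanged. The per-trial gain is
`1 + magnitude · (intensity − participant mean intensity)`, clipped at
zero: a within-participant slope the mixed model can recover. Kinds:

- *power_modulation*: unit-SD narrowband noise in the target band, Tukey
  windowed to the target interval, scaled by `amplitude · gain`.
- *pac*: the amplitude-band component of the background is multiplied by
  `depth · cos(φ)` (φ = phase-band instantaneous phase) and added back, so
  the amplitude envelope becomes `A(t)(1 + depth · cos φ)`; depth 0 is a
  bit-exact identity.
- *directed_coupling*: `gain ·` band-passed, lag-delayed source region added
  to the target region (pure x→y influence).
- *burst_train*: Poisson-distributed Hann-tapered oscillations (default
  5 cycles) with uniform frequency in the band and uniform onset in the
  window; the Poisson rate carries the intensity link.

The magnitudes used in the tests (power slope 0.18 at amplitude 0.9; PAC
depth 0.6 with slope 0.25; coupling gain 0.8; burst rate 1.5 Hz, slope 0.5,
amplitude 4) are free parameters — no physical effect sizes are available
for any band — chosen once so that recovery tests have high power at the
scaled-down n while null calibrations stay at their nominal level.

## Superlet time–frequency maps

The multiplicative superlet at frequency f with order o(f) is the geometric
mean of Morlet magnitude responses with cycle counts c, 2c, …, o·c
(base cycles c = 8 by default, reading the method's single width parameter
as the base wavelet cycle count; it is exposed as configuration). The order
ramps linearly from 1 at the lowest analysis frequency to 8 at 100 Hz,
rounded up. Each wavelet has a Gaussian envelope holding its cycle count
within ±2.5 SD and is amplitude-normalized so a unit sinusoid at its center
frequency yields magnitude 1; power therefore scales quadratically with
amplitude, and the order-1 transform is elementwise identical to a plain
Morlet spectrogram (a test verifies rtol 1e-10 against an independent
time-domain implementation). Complex coefficients for coherence come from
the base wavelet, whose phase is not distorted by the geometric mean.
Signals are reflection-padded by one longest-wavelet half-support; frames
whose support touches the padding are flagged, not dropped. Output frames
default to 100 Hz (10 ms). No baseline correction is applied before the
mixed models — the rank transform absorbs overall scale.

## Mass-univariate mixed-effects maps and WCM correction

Per time–frequency cell the response is the Blom rank inverse-normal
transform of power, `Φ⁻¹((r − 3/8)/(n + 1/4))`, and the model is a linear
mixed model with fixed effects intensity (or concentration), valence, sniff
amplitude and sniff AUC, plus a participant random intercept. A
Shapiro–Wilk check of residual normality is available as a QC layer.

Because cluster-based permutation inference needs hundreds of re-fits of
thousands of cells, the fitter is a vectorized profiled-REML solver
specialized to the random-intercept structure: with variance ratio
λ = σ²_participant/σ²_residual the marginal covariance is
σ²(I + λZZ'), whose inverse acts through per-participant group sums, so the
GLS estimates and the REML criterion for all cells are a handful of dense
matrix products. λ is optimized per cell on a log grid (0 and 13 points
over 10⁻³–10³) refined by eight golden-section steps. The estimator is
validated against statsmodels' general MixedLM (t statistics agree to ~1%);
t-based voxel p-values use residual degrees of freedom n − p, which is
immaterial for the permutation-calibrated cluster inference. Cells whose
response has no variance or whose fit degenerates are flagged; more than
20% flagged cells aborts the analysis.

Cluster correction: cells with two-sided voxel p below the forming
threshold (default .05) are joined by 8-connectivity within sign on the
1 Hz × 10 ms grid (frequency and time treated isotropically), each
cluster's mass is Σ|t|^w with w = 2 (exposed as configuration), and the
corrected p-value is the rank of the observed mass among per-permutation
maximum masses, never below 1/(n_perm + 1). Permutations shuffle only the
predictor of interest within participant; covariates stay with their trial,
preserving the nuisance structure under the null. Restricted-window
analyses reuse the same operation with a frame mask.

Cluster tables report the mass, the corrected p, and the peak-cell t; no
attempt is made to define a single "cluster-level t".

## Directed connectivity

Cross-spectral matrices use DPSS multitapers over the whole 0–2 s stimulus
window with 3 Hz half-bandwidth smoothing (taper count 2TW − 1 = 11 at
T = 2 s), averaged over trials and tapers; hemispheres are represented as
already averaged (one signal per region). Granger spectra are nonparametric:
Wilson's iterative spectral matrix factorization yields S = HΣH*, and the
Geweke measure per direction is
`GC_{y→x}(f) = ln(Sxx / (Sxx − (Σyy − Σ²xy/Σxx)|Hxy|²))`. Numerical
details: diagonal loading 1e-8·trace before factorization; the causal
("plus") operator keeps positive lags and the upper-triangular half of the
halved zero-lag coefficient; and the spectrum is sinc-interpolated onto a
progressively finer frequency grid (lag-domain zero padding, factors 1–16)
until the relative Frobenius reconstruction error of HΣH* drops below 1e-6
— sharply resonant spectra need more lag coefficients than the raw rfft
grid offers, and runs that cannot reach the tolerance raise rather than
return a biased factor. The estimator is validated against the parametric
Geweke spectrum computed from the true coefficients of a simulated VAR(2).
The group direction contrast is the per-participant band-mean difference
GC(x→y) − GC(y→x) tested against zero with a two-tailed one-sample t test;
trials are averaged in the spectral domain (tapered trial spectra averaged
before factorization), not concatenated.

## Searchlight decoding

Features are per-participant trial-averaged OB–PC coherence spectrograms per
median-split class — one example per participant per class. The spectrogram
is tiled into 12 Hz × 100 ms bins sliding with 50% overlap; bins with fewer
than 10 neighboring bins within Chebyshev radius 2 on the bin grid are
excluded (the alternative reading — cells within the bin — is available
behind a flag). Per bin, a linear SVM (C = 1, features z-scored with
training-fold statistics) is evaluated leave-one-participant-out, keeping
per-class accuracies for confusion reporting. The Monte-Carlo null swaps
the two class labels within participant; the per-bin one-sided p is the
rank of the observed accuracy among shuffles. Cluster correction maps
accuracy p-values to one-sided z maps on the bin grid (each shuffle ranked
against the full shuffle set) and reuses the WCM machinery.

Because the null requires hundreds of thousands of SVM fits on tiny folds,
the classifier is a batched dual coordinate-descent solver for the linear
SVM with hinge loss — the same dual objective liblinear optimizes, with the
bias handled as a regularized constant feature — vectorized across label
shuffles, which share the training Gram matrix. It is validated against
sklearn's SVC on matched problems (identical accuracies in the median;
occasional one-example differences trace to the bias convention).

## Phase–amplitude coupling

The Tort modulation index bins amplitude by phase into 18 bins of 20° (the
conventional count; it is configurable), normalizes the bin means to a
distribution and reports KL divergence from uniform scaled by 1/ln 18.
Band-passing (zero-phase FIR, ~3 cycles of the band's low edge) and the
Hilbert transform run on the full epoch before cropping to the 150 ms
analysis window, avoiding filter edge artifacts inside a window that holds
only ~2 beta cycles. Single-trial MI from such a window is necessarily
noisy, so the unit of inference is the trial and the statistics come from
the same mixed model as the power maps, with rank-transformed MI as the
response. Both the phase and amplitude signals default to the OB (the
region pair is configurable, since feedback-driven gamma modulation could
equally be probed with PC phase). The default window centre (1.025 s)
represents the epoch where inter-regional beta coherence indicates
top-down transfer.

## Bursts

Bursts are defined on the superlet power maps inside the 0–2 s window:
band power (collapsed across the band's frequencies by the maximum —
bursts are narrowband, and the maximum is robust to band width; a mean
collapse is available) exceeding the mean plus 1 SD of the trial's
10-trial block, for at least 3 cycles of the band's arithmetic-mean
frequency. Blocks are non-overlapping consecutive groups of 10 trials (a
global single-block mode is available); a short trailing block folds into
its predecessor, and fewer than 10 trials total fall back to one block with
a warning. Suprathreshold runs separated by at most one frame merge.
Detection is fully deterministic in the TFR, and scaling all powers by a
positive constant scales thresholds identically, leaving the event set
unchanged. Events carry onset, offset, peak frequency/power and duration
in cycles. Burst rates bin onsets per frame and smooth with a 100 ms
boxcar whose edge mass is reflected back, so each trial's rate series
integrates exactly to its event count. Frame-wise mixed models use
Box-Cox(rate + 1) responses (shift because rates contain zeros; λ by
profile likelihood per frame) with the standard covariates, and 1-D WCM
correction along time.

## Known limitations

- The generator's effects are stylized: no cross-frequency interactions
  beyond the injected PAC, no trial-to-trial latency jitter, no volume
  conduction between regions.
- The profiled-REML fitter supports exactly one random intercept; random
  slopes would require a different solver.
- The decoding null swaps labels within participant, which is the only
  exchangeable transformation under the one-example-per-class-per-participant
  design; with very few participants the null has limited resolution.
- Burst detection with a relative (mean + 1 SD) threshold flags events in
  any sufficiently variable background; "burst rates" on noise are
  therefore nonzero by construction, and only differences or covariate
  effects on rates are interpretable.
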