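# Methods

This note documents the models and numerical choices behind `stnmes`:
what each stage computes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Motor metrics and the Motor Error Score

Eight instantaneous metrics are computed from cursor `C(t)` and target
`T(t)` traces. Tremor magnitude uses the 3–10 Hz band of the raw cursor
(per-axis Hilbert envelopes, Euclidean norm); all other metrics use the
< 3 Hz band of both traces. Both behavioral filters are linear-phase FIR
(Hamming-windowed sinc) applied with zero phase by centered convolution,
so band-limited components remain aligned with the epoch grid shared with
the neural data; the nominal design is 2 s of taps at the trace sample
rate, with the low-pass normalized to exact unit DC gain and the
band-pass to an exact DC null. Traces shorter than 1 s are rejected;
traces shorter than the nominal filter get a coarser design with a
warning.

Displacement segments use one sample period as the finite-difference
step. Speeds are expressed in screen units per millisecond because the
slowness constant 0.042 is dimensionful in that unit; on the generator's
±10-unit display, cursor speeds of a few units/s put SL in a narrow range
near 1, which is harmless because every metric is z-scored before the SVM
(only the metric's variance direction matters, not its absolute spread).
Angles clip their cosine argument to [−1, 1]; samples where any
participating segment norm falls below 1e−12 are flagged invalid and
excluded from epoch means rather than imputed — imputing 0 would bias
toward "good" performance. Epochs aggregate by arithmetic mean (median
available via `agg=`); the trailing partial epoch is dropped, and the
epoch count derives from the nominal grid duration n/fs so that
segment-based series (one sample short) still fill the final epoch.

The MES model is a linear maximal-margin classifier
(`sklearn.svm.LinearSVC`, C = 1) on z-scored metrics, with the control
pool re-subsampled per Monte Carlo fold to match the patient epoch count.
Monte Carlo cross-validation (100 folds, 2:1) estimates held-out AUC
only; the reported hyperplane is a single refit on the full balanced set,
which gives a deterministic, serializable `(w, b)`. The normal is
oriented so patient epochs score positive; the score `(w·z + b)/‖w‖` is
invariant to rescaling of `(w, b)`. Zero-variance metrics have their SD
floor-clamped at 1e−8 with a warning.

The MES autocorrelation timescale is the span of contiguous lags around
zero whose normalized autocorrelation exceeds the baseline mean + 3 SD,
with the baseline estimated from lags ≥ 30 s. A white-noise score series
yields the minimal width of one epoch (0.1 s at 100 ms epochs); an
AR(1)-like impairment process widens it monotonically with its
correlation time. Subtype classification is tremor-dominant iff the
tremor/PIGD sub-score ratio is ≥ 1.5 (the rule defines only the < 1.5
side as non-tremor-dominant, so the boundary is inclusive); a zero
denominator with positive tremor is TD, both zero is indeterminate.

## LFP preprocessing and the filter bank

Preprocessing order: notch filters (Q = 30) at 60, 120, 180, 240, 300 Hz;
global z-score; samples with |z| > 4 masked and linearly interpolated
(the mask is retained and OR-pooled through decimation); zero-phase
Butterworth band-pass 3–400 Hz; polyphase decimation to 1 kHz. Note that
|z| > 4 can by itself mask at most 1/16 of samples (Chebyshev), so the
"> 20 % masked → flagged" warning practically fires only when a recording
arrives with a pre-marked artifact mask. Masked-and-interpolated samples
never contribute to epoch features.

Spectral estimation: one low-pass prototype (half the 2 Hz bandwidth,
3 s of taps at 1 kHz) is modulated to every integer center frequency
4–400 Hz. The implementation evaluates the prototype's zero-phase
frequency response once on a padded FFT grid (padding rounded to whole
seconds so each 1 Hz shift is an exact integer number of bins) and
obtains each band's analytic signal by masking negative frequencies
before the inverse FFT — algebraically identical to FFT convolution with
the modulated FIR followed by a Hilbert transform, at a fraction of the
cost. Per-sample power is the squared analytic-signal magnitude, read as
the squared envelope. Features average power over epoch samples and over
the centers inside each sub-band, then log, then z-score per column (the
normalization parameters are stored). Sub-band edges are geometrically
spaced within each canonical band, `edge_k = lo·(hi/lo)^(k/7)`, so width
grows with frequency within every band; linear spacing is available as a
config option. Width is not globally monotone at canonical-band
boundaries (the bands' edge ratios differ) — an unavoidable property of
any within-band rule on these fixed canonical edges. The 1 Hz centers
overlap (2 Hz bandwidth); the top center at 400 Hz is assigned to the
last vhf sub-band so no center is orphaned.

## Decoding

SVR (`sklearn.svm.SVR`; linear for interpretable weights, RBF as a
performance reference; ε = 0.01 applied to the z-scored target) is
evaluated by 100-fold Monte Carlo cross-validation with 2:1 splits drawn
from the fold seed, so two runs with one seed share identical folds —
this is what makes band-restricted vs broadband comparisons exactly
paired. Accuracy is Pearson's r between held-out predictions and observed
MES ("r" read as Pearson; Spearman obtainable by ranking the inputs).
Folds with constant test targets are excluded with a log message.

The regularization constant defaults to C = 0.1 rather than the more
customary 1.0: with 42 standardized features and the ~10² epochs of a
single session, C = 1 is variance-dominated — in our experiments it cost
~0.2 held-out r on broadband decoding (a ridge-regression cross-check
agreed) and could invert the broadband-vs-band ordering by overfitting
precisely the model the comparison is designed to favor. C is exposed
everywhere.

Shuffle controls permute the epoch correspondence between MES and
features and re-run the identical CV decoding; the observed fold
accuracies are compared against the shuffle means by one-sided
Mann-Whitney U plus an add-one empirical p. Note that on sessions whose
features and target are both slowly autocorrelated, interleaved Monte
Carlo splits allow genuine temporal leakage: observed "decoding" of a
coupling-free session can be positive even though the shuffle null stays
centered on zero. This mirrors the behavior of Monte Carlo CV on real
recordings and is why the shuffle control, not a zero observed r, is the
null reference.

The generic decoder max-normalizes each recording's fold-mean linear
coefficients, averages them within subject weighted by max(mean r, 0),
and averages subjects equally; its intercept is 0 because features and
target are standardized, and it is applied to within-recording z-scored
features (the only frame in which a foreign weight vector is meaningful).
For a cohort of subjects with orthonormal true coupling vectors the
population mean vector is not zero, so the generic decoder retains
roughly half of each subject's autologous correlation; a generic decoder
only collapses to chance when couplings cancel in the population mean
(e.g. sign-balanced pairs). Cross-decoding fits on one full recording and
scores another; the matrix keeps the best r per subject pair, with
held-out Monte Carlo accuracy on the diagonal.

## Weight statistics

The contiguity permutation test shuffles the 42-entry mean-weight profile
across frequency positions (default 10 000 permutations) and pools the
null window means over all start positions within each window length
3–7 — pooled because the test asks about runs of adjacent bands
regardless of where they start. Flags are two-sided at the α/2 null
quantiles; p-values use the add-one convention (k+1)/(n+1), with ties up
to floating-point error counted as ties so a constant profile returns
p = 1 everywhere. Empirical false-positive rates match α at 0.01 and
0.05.

Cross-frequency weight correlations are Pearson correlations over models
between the weights at each feature pair; the null independently permutes
each model's frequency labels (1000 iterations) and the per-cell p is the
add-one fraction of null magnitudes at least as large as observed. The
diagonal is non-data and is imputed from adjacent cells for display only.
At least 10 models are required — below that the 42×42 correlations are
too unstable to interpret.

Benjamini-Hochberg is the standard step-up procedure (hand-written;
cross-checked against an exhaustive oracle and statsmodels in the tests).
Rank tests wrap scipy's Mann-Whitney U and Wilcoxon signed-rank with
midrank ties; paired zero differences are dropped and an all-zero
difference vector returns p = 1.

## The synthetic generator

The generator emulates the study's structure, not STN biophysics. A
stationary Ornstein–Uhlenbeck latent `s(t)` (τ = 7 s, matching the
multi-second timescale of motor fluctuation; SD 0.4) is rectified through
a softplus into an impairment drive that is strictly positive — a patient
has a baseline impairment level that waxes and wanes — and smooth, which
matters because the MES inherits any kink in the latent-to-behavior map
and the coefficient-recovery analyses presuppose an approximately linear
latent→MES relation. The latent SD of 0.4 keeps the softplus in its
near-linear region (the residual quadratic component of MES on the latent
is ≲ 0.15 in standardized units) while the behavioral gains (tremor 1.1
screen-units, lag 1.8×, bradykinesia exponent 1.4, heading noise 1.1 rad
per unit drive) keep epoch-level MES correlated with the latent at
r ≈ 0.95.

Behaviorally, a cursor pursues a lagged Lissajous-mixture target through
a first-order visuomotor loop updated at 100 Hz (interpolated to 1 kHz);
the drive inflates the lag, shrinks the pursuit speed, adds heading
noise, and adds 4–8 Hz tremor. Controls run the identical loop with the
drive clamped to zero, which is exactly a smoothed, delayed target plus
low-amplitude positional noise.

The LFP is a 1/f^1.5 background plus six band-limited Gaussian carriers
whose amplitudes follow `a_b·max(1 + w_b·ŝ, 0)` with the standardized
latent ŝ and default couplings (+0.5, +0.5, 0, 0, 0, −0.5) on
(θ/α, β, …, vhf); carrier levels are `band_snr` (default 2) times the
background's in-band RMS, and 60 Hz line interference with harmonics is
added last. Two lognormal amplitude processes complete the model, both
essential to realistic decoding structure: an independent slow
fluctuation per band (SD 0.35 in log-amplitude, τ = 5 s — endogenous
power bursts unrelated to behavior) and a common gain drift shared by
background and all bands (SD 0.6, τ = 7 s — electrode impedance/arousal).
Without the per-band term every coupled band is a nearly noiseless copy
of the latent, so single-band decoding trivially equals broadband
decoding; without the common term there is no structural reason for
multi-spectral superiority at all. With both, the per-band term caps each
single band's ceiling and the common term is removable only by
contrasting bands — including the uncoupled γ bands, which the linear
decoder recruits with small negative weights as drift references. This is
the package's mechanistic account of why broadband decoding robustly
outperforms any canonical band.

What the generator does **not** emulate: spiking activity and spike-field
coupling, non-stationary tremor frequency, medication or stimulation
effects, task learning, electrode repositioning between sessions,
anatomical heterogeneity of recording sites, and any cross-frequency
phase structure. Passing tests therefore show that the pipeline recovers
the statistical structure it assumes — a one-dimensional slow impairment
state linearly coupled to band powers — not that real STN recordings
satisfy those assumptions.

## Problem sizes and determinism

The default analyses use a 600 s session (85 epochs at the 7 s decoding
timescale) and 300 s sessions for the four-subject cohorts; these sizes
give stable Monte Carlo estimates while keeping a full pipeline run in
tens of seconds. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical config and seed reproduce every
number bit-for-bit, and the permutation/bootstrap statistics are
seed-deterministic as well.

## Known limitations

The exact sub-band edges of the original band scheme are not public, so
the geometric rule here is a reasoned reconstruction (the function is a
single swap point). The printed power expression ("conjugate of the
Hilbert transform times the filtered signal") is read as the squared
analytic envelope; the alternative literal product differs only by a
2·f-frequency interference term that epoch averaging suppresses. Whether
the original MES used a fold-averaged or refit hyperplane is unstated; a
single refit was chosen for determinism. Artifact samples are interpolated
rather than deleted to preserve the epoch grid. The timescale sweep
refits the MES model per epoch length, so scores at different lengths are
not nested readouts of one model.
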