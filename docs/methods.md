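# Methods

This note records the models, conventions, and free design choices behind
`ramanscreen`, and what the synthetic-data validation does and does not
establish about real patient data.

## Spectral preprocessing

Raw line-map traces live on a shared ascending wavenumber grid covering the
600–1700 cm⁻¹ fingerprint window (the canonical synthetic grid uses 1 cm⁻¹
steps, 1101 channels). Grids must match exactly after loading; there is no
implicit resampling. The chain applied to each trace is despike → smooth →
baseline-subtract → SNV, and each stage sets a monotone state flag.

**Cosmic-ray removal.** Candidate channels are those adjacent to a
first-difference whose modified z-score `0.6745·(d − median d)/MAD(d)`
exceeds the threshold (default 8). A candidate is confirmed as a spike only
if it also deviates from the linear interpolation across non-candidate
channels by more than the same robust threshold; without this confirmation
the clean channel immediately after a spike would be flagged too, because a
spike produces two extreme first differences. Confirmed runs longer than 3
channels are released (too wide for a cosmic ray), confirmed channels are
replaced by linear interpolation between the nearest clean neighbors, and a
trace with more than 10% of channels flagged is refused as corrupt rather
than silently rewritten. Spike-free traces pass through bit-identical.

**Savitzky–Golay smoothing** uses polynomial order 9 over a 27-point window
(the published settings; the window must be odd and larger than the order).
Interior channels equal the center value of the least-squares fit over their
window; edges are evaluated from the polynomial fitted to the truncated
available window. Degree-≤9 polynomials are reproduced exactly at interior
channels.

**Modpoly baseline.** The fluorescence background is estimated by the
iterative modified-polynomial fit: least-squares fit a degree-11 polynomial
to the working trace, clip the working trace to the fit wherever it exceeds
it, repeat. The published threshold 10⁻⁴ is interpreted as the relative
change of the residual standard deviation between iterations (the criterion
the original modpoly literature leaves loosely specified); iteration is
capped at 500, and hitting the cap sets `converged = False` without raising
— the residual-SD sequence is non-increasing by construction, so a capped
fit is still usable. The grid is mapped to [−1, 1] and the projection is
precomputed from a QR factorization of the Vandermonde basis, so each
iteration is two thin matrix–vector products. Smoothing runs *before*
baseline estimation: the iterative clip compares signal to fit per channel
and noise destabilizes it.

Two intrinsic limitations are worth knowing. A degree-11 polynomial carries
a least-squares wiggle of a few percent of the band amplitude, which bounds
how exactly the true background can be recovered even noiselessly; and broad
Lorentzian tails of very strong bands (amplitude several times the baseline
range) form a smooth pedestal that the polynomial legitimately follows, so
baseline accuracy is only guaranteed in the fluorescence-dominated regime
the instrument actually produces (background several-fold larger than the
bands — the regime the synthetic generator simulates).

**SNV** normalizes each trace to zero mean and unit sample SD (n − 1
denominator; either convention satisfies the contracts, one had to be
fixed). Constant traces are an error. Traces are SNV-normalized per trace
and then averaged channel-wise into one spectrum per sample (the published
processing order does not say where the per-sample reduction happens; it
must happen before classification, which operates on samples).

## Ratiometric features

Each of the 39 dictionary bands is quantified as the maximum intensity
within ±5 cm⁻¹ of its nominal position (ties resolve to the channel nearest
the nominal center). The window tolerates the 1–2 cm⁻¹ calibration drift
typical of dispersive instruments. Because SNV output is zero-mean, each
aggregated spectrum is first shifted by its minimum so intensities are
non-negative and the 1448 cm⁻¹ reference strictly positive; ratios
`I(ν)/I(1448)` are then invariant to any per-trace multiplicative gain.
Samples whose reference is still non-positive are excluded with a log entry.

Redundancy reduction keeps, for each metabolite assigned at several
wavenumbers, the single band with the highest cohort-mean feature (pooled
over both classes, so the retained band is common to all samples; ties break
to the lower wavenumber), and drops the reference self-ratio. On the shipped
dictionary this collapses tryptophan (757/1551), DNA/RNA (788/805), tyrosine
(828/1615), lipids (1060/1078), carotenoids (1155/1516), and phenylalanine
(1002/1030/1585/1604), giving exactly 30 features.

## Statistics

Correlations are plain Pearson; against the 0/1 class coding this is the
point-biserial correlation, with the two-sided p from
`t = r·√((n−2)/(1−r²))`, df = n − 2. Strength bands are cut at |r| = 0.295
and 0.505 — midpoints bridging the published band edges (0.29→0.30,
0.50→0.51) so every |r| is categorized. No multiple-testing correction is
applied anywhere, matching the source analysis; consumers should treat
per-pair p-values accordingly.

t-tests are unpaired, homoscedastic (pooled variance), df = n₁ + n₂ − 2,
with identical raw-vector and summary-statistic entry points. Tail mode is
an explicit parameter defaulting to two-sided; the one-tailed option exists
because the published comorbidity comparison (6/34 vs 1/34 indicators,
t = 2.026, df = 66) reproduces its printed p = 0.0234 only one-tailed.
Comorbidity is compared by a t-test on the 0/1 indicator, not a proportion
test, because the source declares Student's t-tests for all comparisons.

## Model evaluation

SVMs use `gamma="scale"` (1/(n_features · training-fold feature variance)),
balanced class weights, and a one-vs-one decision shape. Features are
standardized *inside each training fold only* — ratio features, clinical
variables, and protein levels are on incommensurate scales — and the same
fold discipline applies to the grid search (default C ∈ {0.01, 0.1, 1, 10,
100}, degree ∈ {2, 3, 4}; ties to smaller C, then smaller degree).

Five-fold CV records per-fold accuracy and, where the held-out fold contains
both classes, a per-fold ROC/AUC (single-class held-out folds warn and are
skipped in the AUC mean). Leave-one-out CV pools all held-out decision
scores into one ROC, since a per-fold ROC is undefined for one sample.
Accuracy is summarized as mean ± population SD of per-fold accuracies; for
leave-one-out the per-fold accuracy is binary, so the SD is exactly
√(p̂(1−p̂)) — the convention that reproduces "95.6% ± 20.5%"-style summaries.
AUC is trapezoidal and equals the Mann–Whitney concordance with ties counted
½. Fold construction is unshuffled by default (mirroring the default CV
splitters of the toolchain the study used); shuffling with a seed is
available and required for synthetic cohorts written in class order.
Averaged linear coefficients are the element-wise mean of per-fold weight
vectors (positive = associated with the disease class). Permutation
importance shuffles each feature's held-out values 30 times per fold and
reports the mean ± SD accuracy drop pooled over folds × repeats.

PCA centers internally and returns covariance-eigenvector scores;
t-SNE runs the exact (non-approximate) algorithm with Chebyshev
high-dimensional distances, perplexity 30, early exaggeration 3, PCA
initialization, and a fixed seed; perplexity is clipped below the sample
count and a warning is issued when n ≤ 3 × perplexity.

## Synthetic cohorts

The generator emulates the study's acquisition design: per sample, 10 line
maps × 10 spectra (tests and the acceptance script scale this down, e.g.
2 × 5 or 1 × 1, to keep runtimes short; the scaling is stated per use).
Bands are Lorentzian with FWHM 12 cm⁻¹ — the conventional Raman line shape,
with a width matching plasma bands on a 1 cm⁻¹ grid. Band amplitudes come
from a fixed deterministic profile in [0.3, 0.8] with two physically
motivated anchors: the 1448 cm⁻¹ reference is the strongest band (1.0) and
the 1002 cm⁻¹ phenylalanine ring-breathing band dominates the aromatic bands
(0.9), as it does in real plasma spectra. Each sample draws a per-band
lognormal amplitude factor (σ = 0.1) shared across all of its traces — line
maps of one film share biology and differ only in noise — and disease
samples scale the nine designed bands (745, 757, 828, 878, 1002, 1013, 1206,
1657, 1670 cm⁻¹) by the configured ratio, default 1.2. Nuisances per trace:
Gaussian noise (SD 0.02 in reference-amplitude units, i.e. band SNR ≈
15–50), a degree-5 polynomial fluorescence background drawn at 5–20× the
median band amplitude (below the degree-11 correction capacity), and cosmic
rays with probability 0.05 per trace, 1–2 channels wide, 20–100× the largest
band. Negative class-effect directions exist in `EffectConfig` but default
to off, since no magnitudes are published for them.

Clinical variables are drawn per class at the published cohort summary
parameters (age, BMI truncated at ≥ 15 kg/m², gestational age, rounded
non-negative gravida/parity/loss counts, late-pregnancy blood sugar,
Bernoulli comorbidity at 17.6%/2.9%). The protein panel is log-normal
(σ = 0.4 on the log scale, a realistic ~40% biological CV), normalized to a
simulated total protein, with standardized log-scale class effects
d = 0.9 (fetuin-A), 0.5 (FGF-19), 0.2 (FGF-21), 0.0 (LECT2) — matching the
published significance pattern (fetuin-A strongly significant, LECT2 null).

**What passing tests show — and don't.** The synthetic cohorts verify the
machinery: known amplitudes are recovered through the full chain, null
cohorts yield calibrated AUC (≈ 0.5) and uniform correlation p-values
(confirming fold-wise standardization leaks nothing), and designed effects
are detected with the designed sign. They do not validate the biology: real
plasma spectra have correlated band structure, instrument drift, film
heterogeneity, and effect sizes the source reports only as box plots, none
of which the generator claims to reproduce. Published patient-data
performance numbers are therefore not reproduction targets of the synthetic
harness.

## Problem sizes used in validation

The acceptance checks run at: 3 samples/class (feature-count reduction),
the published summary statistics (t-tests, n = 34/34), 34 samples/class with
2 maps × 5 spectra through the full preprocessing chain (effect-detection,
five fixed seeds), 34 samples/class single-trace noiseless cohorts for the
100-seed null-AUC calibration and 500-seed p-uniformity checks, and 50
null seeds in the acceptance script. These sizes were chosen to exercise
the study-scale sample count (n = 68) while keeping the whole suite inside
a few minutes on one CPU.

## Known limitations

* Modpoly at degree 11 carries an intrinsic least-squares wiggle (a few
  percent of band amplitude) and follows the broad tail pedestal of
  overlapping bands; extracted ratios remain accurate to ~5% but the
  baseline itself is only trustworthy in the fluorescence-dominated regime.
* Overlapping neighbor bands (e.g. 1002/1013 at FWHM 12) contribute to each
  other's windowed maxima; truth-recovery guarantees hold for isolated
  bands.
* With all nine collinear designed bands active, a linear SVM occasionally
  assigns a small negative weight to one member of a strongly overlapping
  pair — an expected consequence of collinearity, quantified in the
  acceptance suite as a ≥ 95% pooled positivity rate rather than a per-seed
  guarantee.
* The identity of the nine removed redundant bands is fixed by the
  cohort-mean rule; the source's own retained-band list is in supplementary
  material unavailable here, so only the count (30) is anchored.
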