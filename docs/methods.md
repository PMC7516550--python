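# Methods

`ceemdboost` detects epileptic seizures in EEG by decomposing each signal
segment into intrinsic mode functions (IMFs), extracting a multi-domain
feature catalogue from the raw segment and every decomposed component,
pruning the features by boosted-tree importance, and classifying with
gradient-boosted trees under stratified cross-validation. This note
records the model, its assumptions, the parameters that matter, and the
choices made where the procedure was genuinely open.

## Empirical mode decomposition and its ensembles

EMD represents a series x(n) as Σⱼ IMFⱼ + R. An IMF is an oscillation
whose zero-crossing and extrema counts differ by at most one and whose
local envelope mean is near zero; R is the leftover trend. One sifting
iteration subtracts the pointwise mean of the cubic-spline upper envelope
(through local maxima) and lower envelope (through local minima).

Decisions where the classical recipe leaves freedom:

- **Extrema.** Strict local extrema; a flat plateau that forms a peak or
  trough contributes the midpoint index of its tied samples.
- **Boundary handling.** The two extrema nearest each end are mirrored
  across it before spline fitting. Mirroring is the standard low-cost
  remedy for spline divergence at the ends; it does not eliminate end
  effects, it bounds them.
- **Sifting stop.** A Cauchy-type criterion — the normalized squared
  change Σ(h_prev − h)² / Σ h_prev² must fall below
  `sift_sd_threshold` (default 0.2) — *and* the candidate must satisfy
  the IMF conditions (crossing/extrema counts within one, envelope mean
  within 10% of peak amplitude). The combined rule matters: on broadband
  input the Cauchy ratio alone is satisfied almost immediately, leaving
  under-sifted modes. A cap of `max_sift_iters` (100) guarantees
  termination.
- **IMF cap.** `max_imfs=None` applies floor(log₂ n), the dyadic
  filter-bank expectation that each successive IMF roughly halves in
  frequency: 12 modes for a 4097-sample segment, 14 for 17,664 samples.

EEMD averages EMD over `n_pairs` independent white-noise perturbations
of amplitude `noise_amplitude`·sd(x) (defaults 50 and 0.2; the ensemble
conventions of the EEMD literature). CEEMD instead uses complementary
±noise pairs — 2·`n_pairs` members — so the injected noise cancels in
the averaged modes; the tests verify that its pre-subtraction ensemble
residual is smaller than EEMD's at the same seed. In both ensembles,
members that run out of extrema early are zero-padded to the common
floor(log₂ n) mode count before averaging, and the residue is defined as
x − Σ averaged IMFs, making reconstruction exact by construction (for
plain EMD it is exact telescopically). Noise is Gaussian, drawn from
per-pair spawned substreams of the seed, so increasing `n_pairs` never
reshuffles earlier pairs.

A multi-channel window is flattened to one series (channels concatenated
end-to-end by default; time-major interleaving available) and decomposed
once, which is how a 3-s, 23-channel window becomes a single
17,664-sample decomposition with 14 modes.

## Feature catalogue

Features are computed per component — raw series, each IMF, residue —
with provenance-prefixed names (`imf_3__change_quantiles__0.1_0.2`).
Four domains:

- **Time:** absolute energy; per-chunk energy ratios (10 chunks);
  autocorrelations at lags 1–10 with mean/median/variance aggregates;
  Yule-Walker partial autocorrelations at lags 1–5; least-squares AR(10)
  coefficients; linear-trend slope/intercept/stderr/r; mean absolute
  change and absolute sum of changes; mean absolute change inside six
  quantile corridors; order statistics and moments; 0.2/0.8 quantiles;
  peak counts at supports 1 and 3; crossings of level 1; counts in
  [−1, 1); reoccurring-value percentage; unique-value ratio; linear trend
  over chunked maxima.
- **Frequency:** the first 20 DFT coefficients (real, imaginary,
  magnitude) and the centroid/skewness/kurtosis of the magnitude
  spectrum treated as a distribution over frequency index.
- **Time-frequency:** Ricker (Mexican-hat) continuous-wavelet
  coefficients at widths 2, 5, 10, 20 (mean, sd, absolute maximum per
  width) and a CWT-based peak count.
- **Entropy:** the six estimators below.

A feature that is undefined for a series (constant mode, too short,
no template matches) is NaN — never an abort — and the boosted trees
handle NaN natively. Log bases follow each estimator's definition:
Shannon and SVD entropy in bits, the rest natural log.

### Entropy estimators

| Estimator | Parameters (default) | Convention |
|---|---|---|
| Permutation | order 3, delay 1 | ordinal-pattern frequencies; ties broken by temporal order |
| Shannon | 100 equal-width bins | amplitude histogram; constant series → 0 |
| Spectral | 100 components to Nyquist | mean-removed periodogram folded into equal-width bins |
| Approximate | m=2, r=0.15·sd, delay 1 | Pincus rolling form, self-matches included |
| Sample | m=2, r=0.2·sd, delay 1 | Richman–Moorman, self-matches excluded; −ln(A/B); NaN if A or B is 0 |
| SVD | embedding 3, delay 1 | entropy of normalized singular values of the delay matrix |

Template matching uses the Chebyshev distance. Internally the m- and
(m+1)-length template distances are built as running maxima over one
shared pairwise-distance matrix; above 6000 samples this switches to a
chunked path to bound memory. Every estimator is checked against an
independent O(N²) / dense-SVD brute-force implementation to 1e-10.

Known small-sample property: the approximate-entropy estimator is
negatively biased for very short series and can dip below zero for
N ≲ 30; this is inherent to the definition (the brute-force oracle
reproduces it), not an implementation artifact.

## Classification and evaluation

The boosting core is xgboost; this package owns its configuration — 200
trees, learning rate 0.1, depth 6, L2 penalty λ=1, optional leaf cap,
single-thread histogram method for bit-reproducibility — and the
selection/evaluation protocol around it. Gain importances are normalized
to sum 1; features with importance ≥ 0.001 are kept. Selection is refit
*inside each training fold* so no held-out information shapes the
feature subset; a `global_selection` flag reproduces the leakier
select-once reading for comparison. Evaluation is stratified k-fold
(k = 10) with seeded shuffling, reporting per-fold and mean ± sd
sensitivity, specificity, and accuracy (percent); for three-class runs
SEN/SPE are reported one-vs-rest per class and accuracy is the headline.

## Synthetic benchmark

The generator emulates the two signal regimes the detector must
distinguish. Background: 1/f pink noise (spectrally shaped white noise)
plus an alpha-band (8–13 Hz) sinusoid of amplitude 1 at unit noise sd.
Seizure: the same background plus a 3–5 Hz spike-wave train (fundamental
plus two harmonics at relative amplitudes 1, 0.5, 0.25) scaled to 4×
the background sd — mimicking the high-amplitude rhythmic discharges of
ictal EEG. The standard benchmark is 100 segments per class, single
channel, 3 s at 256 Hz, seed 7; a 23-channel configuration reproduces
the 17,664-point multi-channel window shape.

What the surrogates do **not** contain: electrode/muscle artifacts,
inter-patient variability, seizure onset/offset evolution, channel
correlation structure, or non-stationary background. Passing the
benchmark therefore demonstrates that the pipeline's plumbing and
statistics behave as designed — not clinical-grade performance; on the
benchmark the full pipeline reaches ≥95% mean 10-fold CV accuracy while
a permuted-label control stays at chance.

Problem sizes used in the automated checks are deliberately desk-scale:
CEEMD ensembles of 10 noise pairs for the IMF-count checks and the
benchmark, and an ablation comparison (decomposition features vs.
raw-only features, the raw-only arm being the `raw__*` column subset of
the same table) on 30 segments per class with 2 noise pairs across 5
seeds. These sizes keep the runs reproducible on a laptop while leaving
every algorithmic path exercised.

## Numerical notes and limitations

- Exact additive reconstruction is guaranteed (≤1e-9 relative) for all
  three decomposition methods; for the ensembles it holds by the residue
  definition.
- EMD on pure noise yields fewer "natural" modes than floor(log₂ n);
  ensemble members are zero-padded to the cap, so trailing averaged IMFs
  of a short-on-extrema signal can be identically zero.
- The EDF writer is minimal (16-bit, 1-s records): integer sampling
  rates and whole-second lengths only; amplitudes survive round-trips to
  within the 16-bit quantization of each channel's physical span.
- Windows that straddle a seizure-annotation boundary are discarded, not
  labeled; time is 0-based with half-open [start, end) intervals.
- The catalogue is an extensible registry, not a clone of any external
  feature package; numeric parity with such packages is a non-goal.
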