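# Methods

## Measures

**Coarse-graining.**  At scale τ the series x₁..x_N is replaced by the
means of consecutive non-overlapping windows of τ samples; the final
incomplete window (N mod τ samples) is discarded, giving length
⌊N/τ⌋ — the convention of the original multiscale-entropy literature.
Defaults: τ up to 15 for RR-interval comparisons, up to 20 for the
noise experiments.

**MNCSE.**  Each coarse-grained series is binarized at its own mean
(symbol 1 when yᵢ ≥ mean(y); the tie yᵢ = mean(y) maps to 1).
Recomputing the threshold per scale makes the symbolization
amplitude-invariant and self-referential at each scale.  Overlapping
windows of L symbols (step 1) are encoded positionally,
w = Σₖ₌₀^{L−1} s₍ⱼ₊ₖ₎ ξᵏ, so a series of n symbols yields n − L + 1
words over M = ξᴸ indices.  The word histogram gives

- SE  = −Σ p_w log₂ p_w  (bits; 0·log 0 := 0),
- CSE = SE + (C_R − 1)/(2 M ln 2),
- CSE_max = log₂ M + (M − 1)/(2 M ln 2),
- NCSE = CSE / CSE_max.

The correction is the leading-order (Miller–Madow-type) bias term with
the number of *possible* words M in the denominator.  With that
convention uniform occupation of all M words makes CSE equal CSE_max
exactly, so NCSE attains 1; a lone occurring word gives SE = 0 and a
vanishing correction, so NCSE attains 0.  All logarithms that produce
entropy are base 2 (bits); "ln 2" in the correction denominators is the
natural log of 2 — the only reading under which the normalization is
exact.  Defaults L = 3, ξ = 2 (M = 8); only the binary mean-threshold
scheme is defined, larger alphabets require an explicit partition.  A
scale whose coarse-grained length is below L is marked undefined (NaN)
with a warning — with the defaults that needs ⌊N/τ⌋ < 3, so in practice
MNCSE is total.

**MSE comparator.**  SampEn(m, r) = −ln(A/B) with Chebyshev distance,
ordered template pairs i ≠ j over the common index range i ≤ N − m, and
self-matches excluded.  Defaults m = 2, r = 0.15 × SD of the *scale-1*
series (population SD), held fixed across scales — the original-MSE
convention whose failure modes motivate the symbolic measure; an
`r_reference="per_scale"` option recomputes r per scale for sensitivity
studies.  When A = 0 or B = 0 the value is an explicit NaN marker,
propagated into profiles, excluded from ensemble means, and counted.
The O(N²) pair count is numba-compiled, with a vectorized numpy
fallback when numba is unavailable.

## Synthetic signals

WGN is drawn i.i.d. from N(0, 1).  1/f noise starts from uniform white
noise; its FFT amplitudes at positive frequencies are scaled by 1/√f
(power ∝ 1/f), the DC bin is zeroed (avoiding a divide-by-zero and an
arbitrary offset), phases are inherited from the white-noise spectrum,
and the inverse transform is standardized to zero mean, unit variance.
The measured log–log spectral slope is −1.00 ± 0.05 over the central
decades.  DC/Nyquist handling is an engineering choice; nothing
downstream depends on it beyond the spectral exponent.  Generators are
pure functions of (n, seed); ensembles use consecutive seeds.

These signals emulate the two correlation extremes of heart-rate data —
none and long-range — but not its nonstationarity, ectopy/artifact
structure, or circadian trends; passing the noise experiments says the
measures behave as designed on controlled correlation structure, not
that clinical discrimination follows.  RR files are read one interval
per line ('#' comments allowed), with units auto-detected (median > 10
⇒ milliseconds) and artifacts removed by the >2 s / ≤0 s rule.

## Observed ensemble behavior, and a discrepancy

On 20-seed ensembles at N = 20000, scales 1–20: ensemble-mean MSE of
WGN decreases strictly with scale while 1/f noise stays flat, and WGN
exceeds 1/f at scales < 4 — the classic picture.  For the symbolic
measure, however, MNCSE(WGN) ≈ 0.999 exceeds MNCSE(1/f) ≈ 0.84 at
*every* scale.  This is forced by information theory: binarizing
coarse-grained WGN yields an i.i.d. fair coin, whose word distribution
maximizes entropy over all stationary binary processes, so no signal
can sit above it.  The reported ordering for these two reference
signals in the source literature (1/f above WGN throughout) is
therefore not reproducible under the stated construction; the
corresponding acceptance test asserts the reported direction and fails,
deliberately.  The curves do separate cleanly (non-overlapping
mean ± SE bands for N ≥ 1000), so the measure's discriminative claim
survives with the direction reversed.  Similarly, "MSE produces
undefined values on short series" reproduces robustly at N = 100
(every realization loses 7–17 of 20 scales) but at N = 500 only ~5% of
realizations lose any scale under m = 2, r = 0.15, τ ≤ 20.

## Statistics layer

Per scale, subjects' entropy values are pooled and midranked jointly;
mean ranks per group, a Mann–Whitney p (two groups) or Kruskal–Wallis p
(more), and AUC are reported.  AUC is computed by the rank identity
AUC = U/(n₁n₂) = P(X>Y) + ½P(X=Y).  Mann–Whitney uses exact
enumeration when n₁·n₂ ≤ 400 and the pooled sample is tie-free,
otherwise the tie-corrected normal approximation.  Per-scale p-values
are reported without multiplicity correction by default (matching how
such tables are conventionally presented); a Bonferroni option exists.
Undefined entropy values are dropped per subject and scale; a scale is
skipped when a whole group lacks defined values.

## Classification layer

Features per subject: entropy at scale 1 and at the "optimal" scale,
per method.  The optimal scale maximizes the direction-free separation
max(AUC, 1 − AUC) — chosen because group ordering can invert at scale 1
while the scale still separates; ties go to the smallest scale.
Selection on the full dataset precedes cross-validation (as the feature
definition implies, and leaking selection information accordingly); a
nested mode reselects the scale inside each training split.
Classifiers are scikit-learn's SVC(rbf), RandomForestClassifier and
KNeighborsClassifier(3), all at library defaults (k = 3 aside, no
hyperparameter basis exists); features are not rescaled.  10×10 FCV
uses ten independent seeded stratified 10-fold partitions
(stratification prevents degenerate folds under class imbalance) with
CA averaged over repetitions; LOOCV is deterministic.  Confusion counts
for FCV are stored summed over repetitions next to `n_repetitions`.

## Numerical choices and problem sizes

- Symbol-word encodings use exact integer arithmetic; entropies are
  float64, and the pipeline matches a literal brute-force evaluation to
  1e−12 on series up to length 50 (SampEn likewise up to 60).
- Ensemble experiments in the test suite use 20 realizations at
  N = 20000 and 40 at N ≤ 1000; the fuzz suite uses 10,000 series of
  lengths 10–5000.  These sizes make the full suite run in a few
  minutes while keeping Monte-Carlo error far below the asserted
  margins.
- Seeding: every stochastic component takes an integer seed;
  `scripts/acceptance.py` derives per-series seeds from its `--seed`
  via `numpy.random.SeedSequence`.

## Limitations

- Only the binary mean-threshold symbolization is implemented;
  data-driven partitions for ξ > 2 are out of scope.
- The clinical cohort results require Physionet RR downloads; the
  machinery (RR reading, filtering, comparison and classification) is
  complete, but no clinical numbers are claimed or tested here.
- The CSE bias correction divides by the number of possible words M,
  not the sample size; the classical correction differs, and the
  convention is kept as defined for this measure.
- Composite/refined coarse-graining variants and multivariate
  extensions are intentionally absent.
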