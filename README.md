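# mncse

Scale-based symbolic entropy analysis of physiological time series —
multiscale normalized corrected Shannon entropy (MNCSE) alongside the
classic multiscale sample entropy (MSE), with the statistical and
classification machinery used to compare heart-rate-variability
cohorts.

## The problem

Healthy physiological regulation produces signals that are complex on
many time scales; disease and aging flatten that structure.  Multiscale
entropy quantifies this by coarse-graining a series at scales
τ = 1, 2, … (non-overlapping window means) and estimating an entropy at
each scale.  The original MSE uses sample entropy,
SampEn(m, r) = −ln(A/B), where B counts pairs of m-point templates
within Chebyshev tolerance r (self-matches excluded) and A the same for
m+1 points.  On short coarse-grained series no template pair may match,
so SampEn becomes *undefined* — the estimate simply disappears at the
scales where it is most needed.

MNCSE replaces the metric template match with symbolic word statistics,
which stay defined for any series long enough to hold one word:

1. coarse-grain at scale τ;
2. binarize: sᵢ = 1 if yᵢ ≥ mean(y), else 0 (the threshold is the mean
   of the coarse-grained series at *this* scale);
3. slide a window of L symbols with step 1 and encode each window as a
   base-ξ word, w = Σₖ s₍ⱼ₊ₖ₎ ξᵏ (ξ = 2, L = 3 by default, so M = ξᴸ = 8
   possible words);
4. Shannon entropy of the word histogram in bits, plus the small-sample
   bias correction:  CSE = SE + (C_R − 1)/(2 M ln 2), where C_R is the
   number of words that actually occur;
5. normalize by the maximum, CSE_max = log₂ M + (M − 1)/(2 M ln 2),
   attained when all M words occur equiprobably:

   NCSE = CSE / CSE_max ∈ [0, 1].

NCSE across scales is the MNCSE profile.  The package also implements
the evaluation layer around the measure: white-Gaussian and 1/f noise
generators (FFT spectral shaping), RR-interval file reading with
artifact filtering (intervals > 2 s or ≤ 0 s dropped), per-scale
nonparametric group comparison (joint midranks, Kruskal–Wallis,
Wilcoxon–Mann–Whitney, AUC = U/(n₁n₂)), and cross-validated
classification (SVM-RBF / random forest / 3-NN under 10×10 stratified
FCV and LOOCV, accuracy CA = (TP+TN)/(TP+TN+FP+FN)·100).

## Worked example

```python
import numpy as np
from mncse import (generate_wgn, generate_pink, mncse_profile,
                   compare_profiles)

wgn  = [generate_wgn(5000, s, label="wgn")        for s in range(1, 11)]
pink = [generate_pink(5000, 100 + s, label="pink") for s in range(1, 11)]

prof_w = [mncse_profile(x, tau_max=5) for x in wgn]
prof_p = [mncse_profile(x, tau_max=5) for x in pink]

print("mean MNCSE, WGN :", np.round(np.mean([p.values for p in prof_w], 0), 4))
print("mean MNCSE, 1/f :", np.round(np.mean([p.values for p in prof_p], 0), 4))

table = compare_profiles({"wgn": prof_w, "pink": prof_p})
print(table[["scale", "mean_rank_wgn", "mean_rank_pink", "p_value", "auc"]]
      .to_string(index=False))
```

Output:

```
mean MNCSE, WGN : [0.9998 0.9997 0.9994 0.9992 0.9991]
mean MNCSE, 1/f : [0.8644 0.8546 0.8548 0.8549 0.8593]
 scale  mean_rank_wgn  mean_rank_pink  p_value  auc
     1           15.5             5.5 0.000011  1.0
     2           15.5             5.5 0.000011  1.0
     3           15.5             5.5 0.000011  1.0
     4           15.5             5.5 0.000011  1.0
     5           15.5             5.5 0.000011  1.0
```

White noise sits at the entropy ceiling (its binarized symbols are an
i.i.d. fair coin, so the 8 words are near-uniform and NCSE ≈ 1), while
the long-range-correlated 1/f noise produces runs of identical symbols
and a skewed word histogram, hence lower NCSE.  The ten realizations of
each type separate completely at every scale: the pooled mean ranks are
the extreme values 15.5 vs 5.5, AUC = 1.0, and the exact Mann–Whitney
p-value is 2/C(20,10) ≈ 1.1 × 10⁻⁵.  Unlike sample entropy, every
profile value is defined — on short series MSE loses scales while MNCSE
does not (see `mse_profile` and the `defined` flags on profiles).

The same workflow is available from the shell:

```bash
mncse simulate --kind wgn --n 5000 --n-realizations 10 --seed-base 1 --out-dir sig
mncse simulate --kind pink --n 5000 --n-realizations 10 --seed-base 101 --out-dir sig
mncse entropy sig/*.txt --method both --tau-max 5 --out profiles.csv
mncse compare profiles.csv labels.csv --out table.csv
mncse classify profiles.csv labels.csv --classifier knn3 --scheme loocv --out ca.csv
```

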