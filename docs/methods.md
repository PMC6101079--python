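# Methods

## Model and assumptions

Protein identification scores (protein probabilities in [0, 1]) are
treated as a test statistic. Scores of identifications mapping to decoy
(shuffled) sequences are assumed to be draws from the same distribution
as false-positive target identifications; that distribution — the null —
is estimated empirically by pooling decoy scores over repeated
shuffle-and-search rounds rather than by a parametric model. p-values
are bin-tail probabilities under this empirical null, and FDR control is
plain Benjamini–Hochberg (independence-style step-up; no
Benjamini–Yekutieli correction, no π₀ estimation — estimates are
therefore conservative by a factor 1/π₀ at the acceptance cutoff).

The off-line component assumes that across samples the cumulative null
probability of each score bin varies smoothly with sample-level
features, specifically logit-linearly. Fitting is least squares on the
logit scale, not binomial maximum likelihood: the per-bin response is a
derived probability, not a count, and a pluggable residual loss (squared
error by default, Huber for robustness to an atypical stored sample) is
exactly the estimator the framework defines.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `bin_width` | 0.003 | null histogram bin length on [0, 1]; gives K = 334 bins |
| `n_repeats` | 20 | shuffle/search rounds pooled into the null |
| `n_feature_bins` | 10 | bins of the per-sample score histogram feeding the KL feature |
| `kl_eps` | 1e-9 | pseudo-probability added to every histogram bin before the log |
| `clip_eps` | 1e-6 | clipping of cumulative probabilities into [ε, 1−ε] before the logit |
| `feature_tolerance` | 0.05 | max \|r₀ − r_i\| for reusing a stored null (J = 1) |
| `corr_threshold` | 0.9 | min Pearson correlation of feature vectors (J ≥ 2) |
| `nominal_m` | 1e6 | synthetic total mass assigned to inferred nulls |

## Numerical choices

- **Bin domain.** Fixed to [0, 1] (the protein-probability scale) rather
  than the observed score range: K = 334 at w = 0.003 is consistent only
  with the unit domain. 334 × 0.003 = 1.002, so the last bin is
  truncated to [0.999, 1]; bins are half-open [left, right) with the top
  edge clamped into the last bin, so every score has exactly one bin.
- **Zero p-values.** The bin-tail formula returns p = 0 for a score
  above every decoy. That is valid input for BH and is the default; an
  optional conservative mode replaces the tail with
  (count + 1)/(M + 1).
- **Logit clipping.** Leading bins of a null are typically empty
  (Pr = 0) and the last fitted bins can reach Pr = 1; both are clipped
  to ±logit(1 − 1e-6) ≈ ±13.8 before fitting. Predicted linear terms are
  clamped to ±700 before the logistic to avoid overflow.
- **Monotone repair.** Independent per-bin fits can yield a decreasing
  predicted CDF and hence negative density increments. The predicted
  cumulative sequence is projected onto the monotone cone by isotonic
  regression (L2, scikit-learn) with the final value pinned at 1; the
  differenced density is then non-negative and sums to 1 exactly.
  Renormalization after truncation was the alternative; isotonic
  projection was chosen because it is the minimal-L2 repair and keeps
  total mass without rescaling untouched bins.
- **Fractional counts.** `NullDistribution.counts` is float64. Nulls
  built from scores carry integer values; inferred and synthetic nulls
  carry exact fractional mass (density × nominal M). Rounding to
  integers at any practical M would quantize the cumulative
  probabilities and break exact coefficient recovery in the noiseless
  logit-linear family.
- **Degenerate fits.** A per-bin fit requires at least J + 1 samples and
  a full-rank design; identical feature vectors across samples are
  rejected as rank-deficient. Ties in p-values are sorted stably by
  input index; a tie at the BH boundary is accepted as a block.
- **KL smoothing.** Both histograms get +ε on every bin and are
  renormalized; D(P‖P) is still exactly 0 since every log ratio is
  exactly 1. Natural log by default (the feature is only compared, never
  interpreted in bits).

## Design choices where the design was open

- **Shuffling** is a Fisher–Yates permutation of the whole sequence; no
  cleavage-site-preserving variant. One decoy per target per repeat,
  repeats driven by distinct seeds. Decoys are labelled by a
  case-sensitive accession prefix (`DECOY_` by default).
- **Similarity for the single-feature case.** Pearson correlation of
  length-1 feature vectors is undefined, so J = 1 matching uses the
  absolute feature difference against a tolerance; the correlation rule
  is kept for J ≥ 2.
- **Decoy-only identifications** do not count toward N in the BH
  denominator; features are computed from target entries only.
- **Feature database** is a single versioned JSON document embedding the
  nulls, feature table, coefficient table and the reference sample's
  10-bin histogram (so new-sample feature extraction needs no access to
  the reference's raw scores). Adding a sample marks the coefficient
  table stale until an explicit refit; resolving never mutates the
  database.

## What the synthetic generator does and does not emulate

`simulate_sample` draws true-positive scores from Beta(8, 1)
(concentrated near 1), and false-positive target scores and all decoy
scores i.i.d. from Beta(1, 8) (concentrated near 0) — the generating
model under which the decoy-based null is exactly correct. Defaults are
300 true + 700 false targets and 20 decoy repeats (M = 20 000).
`simulate_null_family` draws null CDF families that are exactly
logit-linear in a scalar feature, optionally with Gaussian noise on the
logit scale.

Real data differ in ways the generator does not model: decoy scores only
approximate the false-positive score distribution, protein scores are
discretized and boundary-inflated by inference software, identifications
are correlated through shared peptides, and null shape varies with
sample complexity in ways one KL feature cannot fully capture. Passing
tests therefore certify the statistical machinery under its own
assumptions — calibration of Permutation+BH when decoys match false
positives, and exact recovery of a logit-linear family — not performance
on any particular mass-spectrometry dataset.

## Problem sizes used in the test suite

Module and acceptance tests run at desk scale, chosen so the full suite
finishes in seconds: calibration uses 1000-target samples with 20 decoy
repeats over 20 seeds; coefficient recovery uses I = 5 samples and
K = 50 bins; the anti-conservatism check averages 50 seeds; the
repeats-help check uses 100-target samples where a single repeat leaves
the null visibly data-limited.

## Known limitations

- No π₀ correction: the estimated FDR at the cutoff exceeds the realized
  FDR by roughly α(1 − π₀) when many targets are true.
- The empirical p-value is a step function with resolution 1/M; small M
  (few repeats on a small sample) coarsens q-values.
- A single KL feature cannot represent all between-sample variation in
  null shape; the interfaces accept J-feature vectors but the shipped
  feature extractor is J = 1.
- Inference is only as good as the stored family: a new sample far
  outside the stored feature range is extrapolated by the logistic
  curves without warning beyond the `inferred` provenance flag.
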