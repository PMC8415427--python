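# Methods

This note documents the statistical model behind `tissuehet`, the
parameters that matter, what the synthetic corpus generator does and does
not emulate, and the numerical choices made where the design was open.

## Per-sample rank enrichment

The core statistic is a one-sided Wilcoxon–Mann–Whitney test computed
*within* one sample: signature genes versus all other measured genes
("background"), alternative "signature genes rank higher". Mid-ranks
resolve ties. Two modes:

- **Exact** (`mode="exact"`, and the default whenever the sample has at
  most 25 measured genes): p = P(U ≥ u) over all C(N, k) equally likely
  placements of the signature ranks. Without ties this is computed by an
  integer convolution over rank sums; with ties, by enumeration of the
  smaller partition (falling back to the approximation above 500 000
  combinations).
- **Normal approximation** (default at corpus scale): tie-corrected
  variance and a continuity correction of ½, O(N log N) per sample for
  all signatures at once.

The approximation is accurate on the log₁₀ scale for continuous values
(|Δlog₁₀ p| ≲ 0.2 against enumeration for N ≤ 12), but degrades in two
regimes, which is why the exact mode exists and is the default at small
N: (a) the most extreme rank configurations at N ≈ 12 (deviations up to
~0.32); (b) heavily tied small samples, e.g. values drawn from half a
dozen discrete levels (deviations up to ~0.43, the ½ continuity
correction over-corrects when mid-rank steps are 0.5). Corpus-scale
matrices (thousands of genes, continuous values) are far from both
regimes.

Choices: the background is the measured genes not in the signature (the
test is within-sample by construction, not against a gene universe);
p-values are floored at 1e-300 before any |log₁₀| transform; NaN values
are treated as missing and dropped from the affected sample's ranking
(pairwise complete); signatures with fewer than `min_genes` (default 5)
matched genes are dropped with a warning. Gene matching is by uppercase
symbol only — probe-to-symbol mapping is the caller's responsibility.

## Signature generation and cross-validation

Per-gene tissue profiles are the median expression across each tissue's
samples (median for robustness to outlier samples). A gene joins tissue
t's signature when

1. the Gini index of its profile is ≥ `gini_min` (default 0.8),
2. t is among the `rank_max` (default 3) highest-expressing tissues —
   competition ranking, so exact ties at the boundary are included, and
3. its median in t is positive (without this, a gene expressed in exactly
   one tissue would enter *every* signature through rank ties at zero).

Signatures are truncated to `max_genes` (default 200) by descending
profile value. Gini and ranks are scale-free, so any global rescaling of
the matrix yields identical signatures.

A consequence of the Gini arithmetic worth knowing: for a gene at a
uniform positive background in T−1 tissues and F-fold elevated in one,
G = (F−1)(T−1)/(T(T+F−1)), which is ≤ ~0.75 for F = 50 at any T and
reaches 0.8 only around F ≈ 80 at T = 9. Genes passing the default
threshold are therefore strongly tissue-restricted (hundreds-fold, or
near-zero elsewhere) — which matches what curated marker sets look like.
The cross-validation experiments accordingly simulate atlas data with
fold-change 200.

Cross-validation scores every sample of an independent labelled dataset
against every signature; a sample's *top hit* is the signature with the
smallest p-value, per-tissue sensitivity is the fraction of samples whose
top-hit tissue matches the annotation, and the confusion matrix counts
(annotated, top-hit) pairs. Selection of which validated signatures to
promote to reference status is left to the user via this report.

## Heterogeneity detection

Defaults: FDR threshold τ = 0.01, exclusion slope threshold 0.01,
severity threshold p_ref > 0.05, bootstrap n = 1000, CI level 0.95.

- **BH family.** q-values are computed jointly over all (sample, query
  signature) pairs of the run — the corpus-level framing; a per-tissue
  family is available via `DetectionConfig(bh_family="per_tissue")`.
  Reference-signature self-tests are not part of the family.
- **Exclusion fits** use *all* samples annotated with the tissue,
  including samples that fail the FDR screen; Huber M-estimation
  (tuning constant 1.345, MAD scale, IRLS to 1e-8 or 50 iterations) with
  intercept. Zero-variance x yields slope 0 by contract; an exact linear
  relation is returned directly since the MAD scale degenerates there.
  Tissues with fewer than 3 samples get no fit and no exclusion.
  Samples are pooled across studies within a tissue.
- **Self signatures.** A query signature of the sample's own annotated
  tissue never counts as heterogeneity evidence (it would otherwise
  trivially flag every healthy sample; in practice it is also excluded by
  the slope rule, as it tracks the reference almost perfectly).
- **Severity** is a sample-level property: one p_ref per sample decides
  moderate vs severe for all of its triggering signatures.
- **Bootstrap CIs** are percentile intervals over resampled per-sample
  binary flags, seeded via `DetectionConfig.rng_seed`; tissues are
  processed in sorted order so results are independent of input order.
  Percentile intervals on a binomial proportion at n ≈ 200 have true
  coverage a little below nominal (≈ 94–96% at 95%), which the coverage
  experiment measures directly.

## Corpus filtering

Free-text tissue terms are normalized (lowercase, whitespace collapsed,
trailing punctuation stripped) and looked up exactly in the controlled
vocabulary — no fuzzy matching, unmapped is a value, not an error.
Filtering drops, in order: unmapped samples; samples of tissues without a
reference signature; whole studies detected as per-gene normalized;
studies below `min_samples_per_study` (default 1 — no study-size floor).
The per-gene-normalization heuristic flags a study when > 25% of entries
are negative or > 50% of gene rows have |row mean| below 1% of the global
interdecile range; both thresholds are arguments. Rank-based testing is
meaningless on per-gene standardized profiles, hence the whole study is
removed rather than repaired.

## Synthetic corpus generator

The generator emulates the structure the detector relies on, with full
ground truth:

- Background genes draw a gene-specific baseline from
  LogNormal(meanlog 3, sdlog 1); each tissue owns a disjoint block of
  `signature_genes_per_tissue` marker genes (80 of 4000 by default)
  elevated `fold_change`-fold (default 8) in that tissue.
- Marker genes share a common baseline abundance (the genome-typical
  level e³). Without this, every random gene set carries a fixed
  baseline-rank bias that couples its p-value to per-sample noise and
  mimics genuine signature correlation — real data has such biases, and
  the exclusion step absorbs them there; in the simulator they would
  randomly poison ground-truth-based power measurements.
- Per-sample **program strength** s ~ LogNormal(0, `signal_sd`= 0.6)
  rescales the planted elevation (effective fold = fold_change · s),
  modelling tissue purity and expression-program intensity differences.
  This is what spreads |log₁₀ p_ref| within a tissue and makes the
  exclusion slope statistically meaningful, as in real corpora where
  reference p-values span many orders of magnitude.
- Contaminated samples (fraction 0.10) mix profiles linearly on the
  natural scale, (1−λ)·own + λ·contaminant with λ = 0.3 — cell admixture
  is additive in transcript abundance; log-scale mixing was rejected as
  non-physical. The contaminant program draws its own strength.
- Mislabelled samples (fraction 0.02) carry another tissue's full
  profile under the wrong annotation.
- Multiplicative log-normal noise is applied last, with a per-sample
  noise level uniform in noise_sd ± noise_sd_jitter (1.0 ± 0.25),
  emulating platform/quality variation.
- `signature_overlap` > 0 elevates the leading fraction of each block in
  the next tissue as well, manufacturing correlated signatures for
  exclusion-logic experiments.

Identical configs give bit-identical corpora; annotations carry
free-text tissue variants, study structure, platform and year so the
corpus-filter path is exercised.

**What it does not emulate:** probe-level microarray artifacts, count
sampling noise, batch effects, correlated marker baselines, partial
signature overlap between real tissues, or study-specific processing.
Passing the synthetic experiments therefore demonstrates that the
statistics are implemented correctly and calibrated under the stated
generative model — not that real-corpus prevalence estimates are
unbiased, which additionally depends on signature quality and curation.

## Experiment sizes

The evaluation experiments (test suite and `scripts/acceptance.py`) use:
a 9-tissue, 1 998-sample clean corpus for FDR calibration; a 4 500-sample
corpus (450 mixtures, 90 mislabels) for power and severity; 3 tissues ×
300 samples for the exclusion experiment; 500 instances (N ≤ 12, k ≤ 4)
for enumeration agreement; 1 000 random vectors each for the Gini and BH
closed-form oracles; 500 replicate tissues of 200 samples for bootstrap
coverage; and two independently noised 270-sample atlases for signature
cross-validation. These sizes give the binomial margins the assertions
need (e.g. 90 mislabels put the expected severe rate ≈ 0.95 about 1.7
binomial standard deviations above the 0.9 bound).

## Known limitations

- Gene identity is by symbol; cross-species use assumes harmonized
  symbols (no ortholog mapping).
- The exclusion fit pools samples across studies; per-study fits might
  behave differently in corpora with strong study effects.
- The severity grade depends on a single unadjusted p_ref threshold; for
  a sample whose reference signature is weakly measured this can flip
  between moderate and severe.
- `bh_adjust` and `fit_robust_line` delegate to statsmodels
  (`multipletests(method="fdr_bh")`, `RLM` with HuberT/MAD) behind the
  package's interface; independent step-up and outlier-contamination
  oracles in the test suite verify both.
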