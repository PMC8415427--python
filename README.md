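# tissuehet

Detection and quantification of **tissue heterogeneity** — expression
signal from cells of other origins than the annotated tissue — in bulk
gene expression corpora.

Bulk samples in public repositories are frequently contaminated by blood
or proximal tissue, infiltrated by immune cells, or outright mislabelled.
All of these leave a characteristic fingerprint: genes specific to a
*foreign* tissue rank unexpectedly high within the sample. `tissuehet`
turns that fingerprint into per-sample calls and per-tissue prevalence
estimates. It is aimed at anyone mining heterogeneous expression
compendia (GEO/ARCHS4-style corpora, in-house microarray and RNA-seq
collections) who needs to quality-control tissue identity before
analysis.

## Method

For a sample *s* annotated as tissue *t*, every gene signature *k* (a set
of tissue-marker genes) is scored with a one-sided
**Wilcoxon–Mann–Whitney rank test** within the sample: with signature
genes at ranks summing to rank-sum *R* among *N* measured genes,

  U = R − k(k+1)/2,   z = (U − km/2 − ½) / √Var(U),

with mid-ranks for ties, tie-corrected variance and continuity
correction; p = P(U ≥ u) under the permutation null (exact enumeration
for small *N*, normal approximation at corpus scale). Small *p* ⇒
signature genes concentrate at the top of the sample's expression
ranking. Because only ranks enter, any within-sample monotone
normalization gives identical results.

Detection then proceeds in five steps, using *query* signatures (broad,
sensitive scanners, one or more per tissue) and validated *reference*
signatures (one per tissue, defining what the annotated tissue must
express):

1. Benjamini–Hochberg adjust the query p-values (q-values) jointly over
   all (sample, query signature) pairs in the run.
2. For every (annotated tissue *t*, query *k*) pair, fit a Huber robust
   line of |log₁₀ p_query| on |log₁₀ p_ref| over all samples annotated *t*.
3. Exclude pairs with slope ≥ 0.01 — their query signature tracks the
   reference (physiologically or developmentally related tissues) and
   would inflate false discoveries.
4. Flag sample *s* if a retained *foreign* query signature has q < 0.01;
   grade it **severe** if additionally the sample's own reference
   signature is *not* detected (unadjusted p_ref > 0.05, the pattern of
   mislabelling), else **moderate** (partial contamination/infiltration).
5. Report per-tissue heterogeneous fractions with percentile bootstrap
   confidence intervals (n = 1000 resamples) and an annotated-tissue ×
   detected-tissue confusion matrix.

The package also generates tissue signatures from an atlas matrix (genes
kept when the **Gini index** of their per-tissue median profile is
≥ 0.8 and the target tissue ranks in the top 3), cross-validates them on
an independent dataset, applies corpus filters (controlled-vocabulary
tissue mapping, removal of per-gene-normalized studies that break the
rank assumption), and ships a fully ground-truthed synthetic corpus
generator for end-to-end testing.

## Worked example

```python
import tissuehet as th

# synthetic 9-tissue corpus: 360 samples, 10% contaminated (70:30
# mixtures), 2% mislabelled, with full ground truth
cfg = th.SimConfig(samples_per_tissue=40, rng_seed=5)
expr, ann, truth = th.simulate_corpus(cfg)

queries, refs = th.planted_signatures(truth)
vocab = th.default_vocabulary(cfg.tissues)
ann = th.apply_vocabulary(ann, vocab)
expr, ann, _ = th.filter_corpus(expr, ann, vocab)

table = th.run_enrichment(expr, queries + refs)       # 360 x 18 p-values
calls, exclusions = th.detect(table, ann, th.reference_map(refs))

print(th.truth_confusion(calls, truth).round(3))
for s in th.tissue_fractions(calls)[:3]:
    print(f"{s.tissue}: {s.n_moderate_or_severe}/{s.n_samples} heterogeneous "
          f"({100*s.fraction:.1f}%, 95% CI [{100*s.ci_low:.1f}%, {100*s.ci_high:.1f}%]), "
          f"{s.n_severe} severe")
```

prints

```
sensitivity                0.930
specificity                1.000
mislabel_severe_rate       1.000
mixture_moderate_rate      0.917
pure_severe_rate           0.000
n_mixture                 36.000
n_mislabel                 7.000
n_pure                   317.000
dtype: float64
blood: 3/40 heterogeneous (7.5%, 95% CI [0.0%, 17.5%]), 3 severe
brain: 3/40 heterogeneous (7.5%, 95% CI [0.0%, 15.0%]), 0 severe
heart: 5/40 heterogeneous (12.5%, 95% CI [2.5%, 22.5%]), 1 severe
```

i.e. 93% of the planted mixtures/mislabels are flagged, every mislabel is
graded severe, no pure sample is graded severe, and each tissue gets a
prevalence estimate with a bootstrap CI.

The same pipeline runs from the shell on TSV/MatrixMarket + GMT inputs:

```
tissuehet simulate --out corpus/ --seed 5
tissuehet filter --expr corpus/expression.tsv --annotations corpus/annotations.tsv \
    --vocabulary vocab.tsv --out filtered/
tissuehet enrich --expr filtered/expression.filtered.tsv \
    --gmt corpus/query_signatures.gmt --gmt corpus/reference_signatures.gmt \
    --out enrichment.tsv
tissuehet detect --enrichment enrichment.tsv --annotations filtered/annotations.filtered.tsv \
    --query-gmt corpus/query_signatures.gmt --reference-gmt corpus/reference_signatures.gmt \
    --out results/
tissuehet report --bundle results/
```

(`tissuehet run-all --config run.yaml` and `tissuehet simulate-and-detect`
wrap the whole chain.)

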