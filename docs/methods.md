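# Methods

## The model

`metaborank` prioritizes chemicals (in the motivating use case, gut
microbial metabolites) for a disease by *molecular convergence*: a chemical
is a candidate if the biological functions perturbed by its associated genes
coincide with the functions perturbed by the disease's associated genes.

The unit of comparison is the **molecular profile**. For an entity with gene
set *Q* and a collection of features (pathways, or mouse mutational
phenotypes) over a gene universe *U*, each feature *F* is tested for
over-representation:

* observed statistic: `obs = |Q ∩ F| / |Q|`;
* null: the same statistic for `n_resamples` gene sets of size `|Q|` drawn
  uniformly without replacement from *U* (default 1000 draws);
* p-value: one-sided t-test of the observed fraction against the resampled
  null — `t = (obs − mean(null)) / sd(null)` referred to a Student *t* with
  `n_resamples − 1` degrees of freedom, small when the observed overlap
  exceeds the null;
* fold enrichment: `obs / mean(null)` (`+inf` when the null mean is 0 and
  the overlap positive; 1 when both are 0).

The profile is the list of features with `p < alpha` (default 0.05) and
fold > 1, ordered by ascending p-value, then descending fold (infinite fold
first), then feature name.

Chemicals are ranked against the disease by a set similarity of profile
feature names — `overlap` (|A∩B|), `jaccard` (|A∩B|/|A∪B|) or `cosine`
(|A∩B|/√(|A|·|B|)) — sorted descending; ties take the average of the rank
positions they span, and the reported "top %" percentile is
`100 · rank / total` (smaller is better; a random chemical sits at 50% in
expectation). Rankings are evaluated against a known-positive list by
recall, mean/median percentile, a one-sample t-test of the found percentiles
against 50%, and a decile histogram over (0,10], …, (90,100].

A top-ranked chemical is characterized by the features its profile shares
with the disease profile. A shared feature at 1-based position *i* in a
profile of size *N* gets the rank score `(N − i + 1)/N ∈ (0,1]`, and the two
sides are combined by the harmonic mean
`2·r_d·r_m/(r_d + r_m)`, which is high only when *both* sides rank the
feature highly. The shared-phenotype variant first maps human genes to
mouse homologs (one-to-many allowed, unmapped genes dropped with a logged
count) and profiles both entities over a gene→phenotype annotation
collection.

## Interpretation choices

* **The significance test.** The source procedure is described only as "a
  t-test" against 1000 random gene sets. Read literally as a one-sample
  t-test of the null sample versus the observed value, the test statistic is
  scaled by the standard error of the null *mean*, so with 1000 resamples
  any observed fraction epsilon above the null mean is declared significant:
  measured type-I rate ≈ 0.4 at α = 0.05, and profiles absorb ~half the
  collection. We instead score the observed fraction as a single draw from
  the resampled null (scale = null standard deviation). This is the only
  reading under which the test approximates the exact hypergeometric tail
  (the overlap of a uniform same-size draw is exactly hypergeometric) and
  keeps the type-I rate near α. The exact tail is exposed as
  `hypergeometric_tail` and serves as the independent oracle in tests.
* **Null sampling.** Because the null overlap count is exactly
  Hypergeometric(|U|, |F|, |Q|), null draws are sampled by inverse-CDF from
  a cached hypergeometric CDF instead of materializing gene sets — an exact,
  distributionally identical shortcut (cross-checked in the test suite
  against brute-force gene-set draws), roughly 30× faster.
* **Rank scores for the harmonic combination.** The combination formula is
  given, the per-profile "ranking score" is not. Percentile-style scores
  where *small* is good would make the harmonic mean reward one-sided
  excellence, contradicting the stated "ranks highly if and only if it ranks
  highly for both" behavior; we therefore use top-normalized larger-is-better
  scores `(N − i + 1)/N`. Whether the original scores were positions,
  percentiles or p-values is not recoverable from the text.
* **Ties.** Tie handling in the ranked list is unspecified upstream; average
  ranks keep percentile statistics unbiased under full ties (a list of all
  ties has mean percentile `100·(n+1)/2n ≈ 50%`).
* **Multiple testing.** No correction is applied by default (none is
  described upstream); Benjamini–Hochberg is available via
  `correction="bh"`.
* **Depletion** is not tested (profiles keep fold > 1 only); the method's
  unit is set overlap, not gene-level statistics.
* **Disease phenotype profile** is built from the disease genes directly
  (not from disease-pathway genes).

## Reproducibility

All randomness descends from one integer seed. Every (entity, feature) pair
derives its own substream — `SeedSequence([seed, blake2b64(entity),
blake2b64(feature)])` feeding a PCG64 generator — so results are independent
of feature/entity evaluation order, bulk profiling equals per-entity
profiling, and identical seeds give bitwise-identical profiles. The
synthetic generator uses named substreams (`pathways`, `disease`,
`chemicals`, `phenotypes`) off the config seed, so regenerating one stage
never perturbs another.

## Numerical conventions

* Zero-variance null: p = 1 when the observed fraction does not exceed the
  null mean (e.g. a feature equal to the universe), p = 0 on complete
  separation.
* Zero-variance evaluation percentiles: p = 1 when all equal 50, 0 otherwise;
  p is NaN when fewer than two knowns are found (t-test needs n ≥ 2).
* Decile bins are upper-inclusive so percentile 100 falls in the tenth bin.
* Presentation rounding is half-away-from-zero (recall to 3 decimals,
  shared-pathway fraction to 1 decimal, shared-phenotype fraction to an
  integer); stored values keep full precision. TSV floats print with 6
  significant digits.
* Human symbols are uppercased on input; mouse symbols are matched
  case-sensitively (HGNC vs MGI conventions).

## The synthetic universe

`metaborank.simulate` generates all six inputs plus ground truth. Defaults
(chosen once as a desk-scale caricature of genome-scale resources): 1000
genes, 200 pathways of 10–50 genes, 500 chemicals with 5–20 genes each
(sparse bipartite links), 50 disease genes, 10 disease pathways with half
their members replaced by disease genes, 30 planted positive chemicals
drawing a `signal_strength` fraction (default 0.8) of their genes from the
disease-pathway gene pool, 200 phenotypes built the same way over a
mouse-gene mirror (`GENE0001 → Gene0001`) with an identity homolog map.
Category labels cycle through six metabolite-class names purely as fixture
vocabulary.

The generator emulates the *statistical* structure the method assumes —
overlapping random gene sets, sparse chemical–gene links, a planted minority
sharing disease-pathway genes. It does not emulate real pathway topology,
hub-gene degree distributions, correlated pathway membership, curation
biases, or STITCH confidence-score distributions. A green end-to-end test
therefore establishes that the pipeline recovers planted convergence signal
and is calibrated under the null — not that it reproduces any particular
database-dependent ranking.

## What the acceptance script recomputes

`scripts/acceptance.py --seed S --out results/acceptance.json` regenerates
20 null universes (signal strength 0; 500 chemicals, 200 pathways, 1000
genes; replicate seeds derived from `S`), profiles everything at 1000
resamples and α = 0.05, ranks with Jaccard similarity, and reports the mean
"top %" percentile of each universe's 30-chemical random known set averaged
over replicates — the calibration check that a random known set ranks at
50% when no signal exists. Runtime ≈ 3 minutes on one CPU.

## Known limitations

* The t-statistic uses a normal-tail approximation of a discrete, often
  coarse null; it is mildly liberal (measured type-I ≈ 0.075 at α = 0.05
  for features of 10–50 genes in a 1000-gene universe). Use
  `hypergeometric_tail` when exactness matters, or `correction="bh"`.
* Recall is bounded by the coverage of the chemical–gene table: chemicals
  absent from it are absent from the ranked list.
* Bulk profiling is single-threaded; cost is O(chemicals × features ×
  resamples) with small constants (~7 s for the default synthetic universe).
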