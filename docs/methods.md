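# Methods

This note records the model, the defaults and the judgment calls behind
`reograde`, in the spirit of a statistical package's methods appendix.
It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## The ordering model

The unit of information is the within-sample relative expression
ordering (REO) of a gene pair: sign(xᵢ − xⱼ) inside one sample. Every
inference in the package is a function of these signs only, which gives
the two properties the approach is built on:

* **invariance** — any strictly increasing transformation applied
  per sample (log scaling, quantile shifts, monotone batch distortion)
  leaves all orderings, hence all downstream results, bit-identical;
* **individual-sample applicability** — no cross-sample statistics
  enter classification, so one sample can be graded alone.

**Stability test.** For a pair observed in its majority direction in
*s* of *n* evaluable samples of a group, significance is the one-sided
binomial upper tail P(X ≥ s), X ~ Binomial(n, p₀ = 0.5), computed as
`scipy.stats.binom.sf(s-1, n, p0)`. The tested direction is the
observed majority; with an exact 50/50 split the canonical direction
(gene_a > gene_b, pairs stored with gene_a < gene_b as strings) is
reported, and such pairs are never significant anyway. Samples where
either gene is missing or the two values tie exactly are excluded from
both *s* and *n*: exclusion avoids biasing the direction count, and a
tie carries no ordering information. Pairs with n < 2 are skipped and
logged. P-values are Benjamini–Hochberg adjusted (statsmodels,
`fdr_bh`) within one (dataset × group) testing family — each screen
controls its own FDR — and pairs pass at FDR < 0.1 by default.

**Reversal and consensus.** A reversal pair must pass the FDR screen
in both grade groups with opposite directions; pairs stable in the
same direction in both groups (the vast majority — most orderings
reflect gene-specific baselines, not phenotype) are discarded.
Consensus across datasets requires presence in *every* dataset with
identical orientation; the operation is commutative and associative
over dataset order.

**Stepwise selection.** Greedy forward selection maximizes the
F-score — the harmonic mean of sensitivity (pHG3 called HG3) and
specificity (pHG1 called HG1), *not* the precision/recall F1 — of the
majority-vote classifier, evaluated on all pooled training samples.
Pooling (rather than averaging per-dataset F-scores) was chosen
because a single training F-score is the natural objective once
cohorts are merged on common genes; the evaluation already weights
datasets by size. Selection stops when no remaining candidate strictly
improves F; it does not target a fixed signature size, so the final
size is data-driven. The first step always accepts the best single
pair (the empty signature has no defined F). Ties in incremental F are
broken deterministically: larger consensus margin first — the margin
of a reversal pair is min over the two groups of |2s − n|, summed over
datasets at the consensus step, i.e. the weakest-link distance of its
ordering counts from a coin flip — then lexicographic pair order.
Re-running selection on identical input is bit-identical; there is no
randomness anywhere in discovery or selection.

A note on the stability formula: the source literature for this class
of tests occasionally prints the tail with a constant exponent
(1 − p₀)^{n−1} on every term; that expression is not a probability
mass function, and the standard binomial upper tail with exponent
n − i is the only coherent form. The package implements the standard
tail and verifies it against exhaustive enumeration of all 2ⁿ
equiprobable ordering sequences.

## Classification

Each signature pair is oriented (A, B) = "A above B in HG1". Per
sample, a pair votes HG1 if A > B, HG3 if A < B, and is non-evaluable
on a missing gene or an exact floating-point tie (no epsilon:
determinism matters more, and continuous expression values essentially
never tie). A sample is called HG3 iff HG3 votes ≥ ⌈k/2⌉ over its k
evaluable pairs — "at least a half", generalized gracefully when some
pairs cannot vote — and is reported `not_evaluable` rather than
silently called when fewer than `min_evaluable_fraction` (default 0.5)
of the signature's pairs are evaluable. Fail-loud protects
clinical-style use on platforms missing signature genes.

The bundled 10-pair signature (`TEN_GENE_PAIR_SIGNATURE`) is keyed by
Entrez ID; note TRIP13 appears as the HG3-high gene of three pairs, so
its pair votes are correlated in real data.

**Closed-form accuracy.** If each of k pairs independently votes for
the sample's true class with probability q, a pHG3 sample is called
correctly with P(Binomial(k, q) ≥ ⌈k/2⌉). For even k the rule is
asymmetric: the tie at k/2 votes goes to HG3, so a pHG1 sample needs
HG3 votes *strictly below* k/2 and its accuracy is
P(Binomial(k, q) ≥ k/2 + 1) — at k = 10, q = 0.75 the two forms differ
by about 0.06, far more than Monte-Carlo noise at the test's sample
sizes, so the acceptance test checks each class against its own exact
form. `expected_classifier_accuracy(k, q, true_class=...)` exposes
both. For odd k they coincide.

## Survival evaluation

Standard machinery, delegated to `lifelines` behind the module
surface: Kaplan–Meier product-limit curves; the two-group log-rank
test with the hypergeometric variance and standard tied-risk-table
handling; univariate Cox proportional hazards with Efron tie handling
and a Wald 95% CI on the log-hazard scale; Harrell's C-index
(censored–censored pairs unusable, tied risks count 0.5 — the package
negates the risk score before calling lifelines, whose convention is
"higher prediction, longer survival"). The tests cross-check log-rank
against a hand risk-table tabulation and the C-index against
brute-force pair enumeration, so the wrapper conventions are pinned
independently of the library. A group with no events triggers a
warning and an effectively unbounded Wald CI rather than an error.

## Preprocessing rules

* Probe collapse: probes mapped to zero or multiple genes are dropped;
  surviving probes are averaged per gene *on the incoming scale* (log2
  in, log2 mean out). Missing probe values are excluded from the mean;
  a gene-sample cell with no contributing probe stays missing. Gene
  IDs are opaque strings — the method is identifier-agnostic.
* RNA-seq zeros: genes with zeros in strictly more than 75% of samples
  (`> 0.75`, a deliberate strict inequality: a gene at exactly 3/4
  zeros is retained) are removed first; remaining zeros are then
  filled with the smallest positive value of the post-filter matrix,
  so the fill value cannot come from an already-removed gene and no
  zeros (which would create artificial ties) survive.
* Cross-platform harmonization is a plain gene-ID intersection with a
  canonical sorted row order — no between-platform normalization is
  needed because only within-sample orderings are consumed downstream.

Raw microarray (.cel/RMA) processing, limma-voom differential calling,
batch correction and pathway enrichment are out of scope; use the
dedicated tools and feed their outputs in as matrices or signed gene
lists (`direction_concordance` consumes the latter).

## The synthetic generator

`simulate_grade_cohort` emulates exactly the assumptions the method
relies on, and its defaults are the package's reference study
conditions: 520 genes of which 10 planted reversal pairs (disjoint
genes), 20 samples per grade group, fidelity q = 1.0, gene baselines
N(8, 2²) log2 units with N(0, 0.5²) within-gene noise, a 1.0-unit
planted-pair mean separation, exponential survival at baseline hazard
0.1 per time unit with hazard ratio 2 for HG3 and 20% censoring.

Design points worth knowing:

* **Fidelity is exact by construction.** The two planted genes' values
  are drawn around offset means and then *assigned* — the larger value
  to whichever gene the sampled orientation says is higher — so the
  orientation follows the class direction with probability exactly q,
  independent of the noise level. This turns the binomial closed form
  into an exact oracle for classifier accuracy rather than an
  approximation.
* **Planted pairs use disjoint genes by default** so pair votes are
  independent and the closed form applies; `reuse_genes=True` allows
  the correlated-vote situation the bundled signature's TRIP13 reuse
  exemplifies.
* **Censoring is calibrated exactly:** censoring times are exponential
  at rate c/(1−c) times each sample's event hazard, giving per-sample
  censoring probability c; an optional administrative horizon can
  truncate on top.
* Monotone distortion draws an independent affine-plus-softplus warp
  per sample (derivative ≥ b > 0 everywhere), preserving orderings and
  ties exactly. Batch shifts are additive per-sample constants. Zero
  inflation exponentiates to a linear scale and zeroes random cells —
  the one knob that *does* break orderings, deliberately, to exercise
  evaluability handling.

What the generator does **not** emulate: probe-level microarray
structure, realistic count distributions (a zeroing Bernoulli is not a
negative binomial), gene–gene correlation beyond the planted pairs,
label noise in the pathological grades, or non-proportional hazards.
Exponential survival was chosen precisely so proportional hazards
holds exactly and hazard-ratio recovery is a clean target.
Consequently, passing tests demonstrate correctness of the algorithms
under the stated model, not clinical performance on real cohorts — the
published signature's real-data behavior can only be reproduced from
the original cohort accessions, which the package intentionally does
not download.

## Problem sizes and numerics

The test and acceptance workloads are sized for a laptop-class single
CPU: all-pairs discovery at 520 genes (≈135k pairs × 40 samples,
vectorized over a genes × genes comparison count matrix), 20-seed
recovery and rank-invariance sweeps, 5,000 samples/class for
Monte-Carlo accuracy at a 99% interval, and 50 Cox fits at 2,000
samples/group; together they run in about a minute. Exhaustive
binomial enumeration is checked to n = 15 (2¹⁵ sequences) at 1e−12.
All-pairs discovery is O(g² · n) time and O(g²) memory; for g beyond a
few thousand genes, pass `candidate_pairs` (e.g. from a variance
pre-filter) instead.

Degenerate inputs are errors, not guesses: empty matrices, all-zero
RNA-seq matrices (no positive fill value exists), empty gene
intersections, a missing truth class in confusion metrics, no events
in a survival contrast, and signatures with duplicate or self pairs
all raise with a message naming the offender.

## Known limitations

* Discovery treats pairs independently; the BH family is all tested
  pairs of one group/dataset screen, and heavily correlated pairs
  (shared genes) will co-discover.
* Greedy stepwise selection has no optimality guarantee beyond its
  non-decreasing trace; the tests verify it never exceeds, and on
  separable data attains, the exhaustive-subset optimum at small
  candidate counts.
* The classifier is intentionally binary (HG1/HG3); grade-2 samples
  are reclassified into one of the two, never given a third label, and
  no confidence measure is attached to a call.
* The C-index follows Harrell's definition; other variants (Uno's,
  time-dependent) are out of scope.
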