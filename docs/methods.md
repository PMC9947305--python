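# Methods

This note documents the models, estimators, defaults and numerical choices
behind `beetol`, and what the synthetic-data generator does and does not
emulate.

## The half-sib liability model

A colony has one diploid queen mated to k haploid drones.  Worker i in
colony c with sire s has 24-h death probability

    logit(p_death) = mu + a_c + b_s + Σ_g e_g(h_s,g)

with colony effects a_c ~ N(0, σ_c²), patriline effects b_s ~ N(0, σ_p²)
i.i.d. on the logit scale, and e_g(·) a per-gene offset determined by the
sire's CYP9Q haplotype label h.  Survival is Bernoulli given the linear
predictor.  The logit-normal form is the standard threshold-liability
analogue for a binary trait; it makes the heritability target of the
deviance-partition estimator a well-defined function of (mu, σ_p) that can
be computed to arbitrary precision by integrating over the patriline-effect
distribution.

Genetics: loci are unlinked, allele "fragment lengths" are integers on a
per-locus ladder, population allele frequencies are Dirichlet-distributed
(concentration `allele_freq_model`, default 1.0 — markedly skewed
frequencies, the harder case for queen inference), each worker receives one
uniformly chosen queen allele plus the sire's allele.  There are no null
alleles, no mutation, no inbreeding, no queen turnover and no drifting
workers; passing tests therefore demonstrate correctness of the inference
under Mendelian transmission and miscall noise, not robustness to those
real-data phenomena.

### Generator defaults (the emulated study design)

| parameter | default | rationale |
|---|---|---|
| colonies × workers | 2 × (247, 249) | the analyzed acute-dose cohort sizes |
| k patrilines | (26, 21) | observed mating numbers in the two colonies |
| loci | 11, 8 alleles each | 11 hypervariable microsatellites |
| mu_logit | logit(0.22) | pooled observed 24-h mortality (109/496) |
| σ_colony | 0.25 | reproduces a colony share of a few percent |
| σ_patriline | 1.0 | patriline-level heterogeneity of the observed order (estimated H² in the 0.3–0.6 range at this design; see bias note below) |
| patriline_concentration | 1.0 | mating share skew is unreported; symmetric Dirichlet is the least-informative choice, exposed as a parameter |
| consumed_below_min_rate | 0.05 | a small minority of bees fail the ≥90 % consumption rule |
| control_death_prob | 0.05 | control mortality comfortably under the 10 %/24 h QC bound |

CYP9Q haplotype labels are drawn per drone from a frequency table; the
default per-gene amino-acid profiles use exactly the published event
vocabulary for these genes (CYP9Q3 carrying the Thr302 in-frame deletion,
a truncating CYP9Q1 haplotype, conservative-only CYP9Q2 changes), and the
default effect table plants the structure the association stages should
find: CYP9Q3 {L, N, P} strongly deleterious (+1.6 on the death logit),
CYP9Q1 {B, E} moderately (+0.8), CYP9Q2 inert.  Dose groups are labels
only; the survival model applies to the lethal group, other groups get a
fixed small death probability.

## Queen and patriline reconstruction

Per locus, every candidate diploid pair over the observed alleles is scored
by the number of workers sharing at least one allele with it; the maximizer
is the queen genotype, and a locus whose best consistency falls below
1 − `max_mismatch_fraction` (default 0.05) is uninformative.  Co-maximal
ties are resolved deterministically — heterozygous preferred, then the pair
with the highest summed worker-allele frequency, then lexicographic — and
recorded in an ambiguity field.  A consequence worth knowing: for a truly
homozygous queen (q, q), any pair (q, x) with x a sufficiently common
paternal allele can be co-maximal, and the heterozygous-preference then
picks (q, x).  This does not disturb patriline grouping (the paternal
allele is still recovered at such loci up to an ambiguity set that contains
it) and the true pair remains visible in the ambiguity record.

Paternal extraction per locus: one non-queen allele → that allele; both
alleles queen alleles under a heterozygous queen → ambiguity set of both;
no shared allele → mismatch, counted per worker, both alleles retained as
candidates (error tolerance).  Grouping is greedy compatibility
clustering: workers visited by (resolved-locus count descending, id
ascending), joining the first cluster whose running per-locus consensus
(set intersections) intersects the worker's sets at every mutually typed
locus.  Workers with fewer than `min_resolved_loci` (default 6) singleton
loci are left unassigned.  Two drones sharing a full multilocus haplotype
are one patriline by construction, matching the operational definition.
Greedy clustering is order-dependent in principle; the deterministic visit
order makes results reproducible, and on error-free 11-locus colonies with
k ≤ 30 the recovered partition equals the simulated truth exactly
(adjusted Rand index 1 across the tested seed range).

## Deviance partition and H²

For factor-only designs the binomial-GLM MLE is closed form — the fitted
probability in each cell is the observed cell proportion — so D₀, D₁, D₂
are computed directly with 0·log 0 := 0; perfectly separated cells
contribute zero deviance.  An IRLS route (statsmodels) exists for general
designs and is required by tests to agree with the closed form to 1e-8.
Shares are raw proportions of D₀ (they sum to 1 exactly, as the published
share triplets do); the adjusted variant
D²_adj = 1 − [(n−1)/(n−p)](1−D²) is attached on request, with the
patriline share then the difference of adjusted cumulative D² values.

H² = 2 × patriline share, reported clamped to [0, 1] with the raw value
alongside (values above 1 are reachable from 2·D² and must stay visible).

**Finite-sample bias.** With few bees per patriline, the cell-mean fit
overfits and the raw patriline share — hence H² — is biased upward; at the
default design (~10 bees per patriline) the raw estimate can exceed the
generative target by ten or more percentage points.  The bias is positive
under the null (σ_p = 0) and shrinks as bees-per-patriline grows, which the
suite tests directionally.  The adjusted-D² estimator removes most of it:
in the parameter-recovery check (200 simulated colonies of 50 patrilines ×
100 bees per σ_p level), the mean adjusted estimate matches the
large-sample truth — computed by simulating the patriline-effect and
mating-share distributions at the same k and averaging the analytic
per-colony share — within Monte Carlo error.  Users comparing designs of
different depth should prefer the adjusted values.

Type-II analysis of deviance: per term, LR χ² = deviance(all other terms)
− deviance(full), df the difference in design-matrix ranks, p from the χ²
upper tail.  Aliased terms get df 0, LR 0, p 1, flagged.  Nested ML fits
cannot produce negative LRs; small negative values from IRLS convergence
are clamped at zero, materially negative ones are clamped and flagged
rather than reported.

Pearson χ² tests default to the Yates continuity correction on 2×2 tables
(the convention under which the published colony comparison's 9.510 is
reproduced; the uncorrected value is ≈10.19).  Monte Carlo p values use
sequential multivariate-hypergeometric sampling of tables with both
margins fixed (the null conditional distribution, Patefield-equivalent;
5000 replicates by default) and the add-one estimator
(1 + #{stat ≥ observed})/(B + 1) on the uncorrected statistic.  Note that
for moderate cell counts the discrete conditional distribution genuinely
differs from the asymptotic χ² tail by more than simulation noise; the two
agree on large null tables.

## Haplotype calling

Sequences arrive aligned to the reference CDS (strict same-length mode;
the CLI gene config carries the sequenced-window offsets so positions are
reported in full-CDS protein numbering).  Deletions must cover whole
codons — a gap touching part of a codon raises an error naming the
alignment column.  A premature stop is reported as a truncation event and
ends the comparison, since downstream codons are not part of the protein.
Synonymous changes are ignored; ambiguous codons translate to X with a
warning and are skipped in comparison.  Catalog labels are
frequency-ranked letters (wild type always `wt`), a pure function of the
profile multiset, with a user label map for concordance with any published
lettering (which is not derivable from profiles alone).  Each consensus
sequence is treated as one haplotype call per bee per gene; heterozygous
peak deconvolution is out of scope.

The generator realizes profiles as minimal codon edits (substitutions and
premature stops pick the codon closest to the reference codon, ties
lexicographic; deletions become `---` codon gaps), and the
simulate→call round trip is exact for all three event kinds.

## Classification tree

Bee-level rows (the default unit; a patriline-mean mode can be emulated by
aggregating upstream), categorical gene predictors.  Splits minimize
weighted Gini impurity; for a binary outcome the optimal label subset is
found by ordering labels by node survival rate and scanning the k−1 cut
points, which the suite verifies against exhaustive subset search on nodes
with ≤ 8 labels.  Ties break by gene order, then smaller left subset, then
lexicographic — determinism, not statistics.  Defaults `min_split` 20,
`min_bucket` 7, 10-fold CV, complexity floor 0.01 follow the conventions
of the standard recursive-partitioning implementation in R, made explicit
and configurable.

Pruning is cost-complexity/weakest-link on resubstitution
misclassification error, with complexity values expressed relative to the
root error.  Candidates below the floor are discarded; each remaining
candidate is evaluated at the geometric mean of adjacent complexity values
on outcome-stratified, seeded CV folds (trees regrown per fold), and the
subtree at minimum cross-validated error is returned, ties favouring the
smaller tree.  xstd is a binomial approximation to the CV-error standard
error.  Because pruning scores misclassification, a split that separates
two nodes on the same side of 50 % survival can be pruned even when the
rates differ substantially — inherent to classification-error pruning, and
the reason the planted-structure tests give the modulating gene an effect
that crosses the majority class.  Unseen labels at prediction time are
routed in the majority direction and flagged; there are no surrogate
splits.

## Pipeline

`beetol run` derives per-stage child seeds from the top-level seed via
`SeedSequence(seed, spawn_key=(stage,))`, so reports regenerate
byte-identically.  QC applied before analysis: the ≥90 % consumption rule
(boundary kept), the ≤10 % control-mortality check, and restriction to
scored lethal-dose bees.  The haplotype and association stages run on
patrilines with at least `min_workers` (default 5) tested bees, mirroring
the published selection; in input mode (user-supplied genotype and
phenotype CSVs without sequences) those stages are skipped with a note.

## Problem sizes used in checks

The test suite and acceptance script size their simulations to be
informative while staying light: the default two-colony design for
end-to-end runs and patriline recovery; 200 colonies × (50 patrilines ×
100 bees) per σ level for H² recovery; 60 colonies per depth for the null
bias direction; 50 seeds × 800 bees for planted-tree recovery; 1000 random
factor designs for the closed-form/IRLS equivalence.

## Known limitations

* No likelihood-based sibship reconstruction (COLONY-style) or
  genotyping-error EM; the compatibility rule with ambiguity sets is
  deliberately simple and transparent.
* H² confidence intervals are not provided beyond the adjusted/raw spread;
  a patriline bootstrap is straightforward downstream but not a claim this
  package makes.
* The logit-normal generative model is one of many consistent with a
  patriline effect on survival; heritability recovery statements are
  relative to that model.
* Classification-error pruning limits which modulating effects survive CV
  (see above); impurity-based pruning is not implemented.
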