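# Methods

This note documents the models, parameter choices and numerical
conventions implemented in `driversel`, and what the synthetic benchmark
does and does not show.

## Long-term conservation rates

Per-gene protein alignments are projected onto the reference species by
dropping columns where the reference has a gap; retained columns map 1:1
onto protein positions.  Each column's substitution count is the Fitch
small-parsimony minimum on the species tree (bottom-up set-intersection
pass).  Gaps and ambiguous residues in non-reference species are treated
as missing data: the leaf contributes the full residue alphabet and never
forces a substitution.  The count is invariant to root placement
(property-tested), so the tree may be rooted arbitrarily.

Rates are expressed in substitutions per billion years by dividing the
count by the **total branch length** of the tree.  (Tree depth would be an
alternative divisor; total length is the convention here and only rescales
all rates by a shared constant, which the downstream z-scoring removes.)

Gene-level features: `E.gene` is the unweighted mean rate over the
*distinct* mutated positions (not mutation occurrences — recurrently hit
sites are not up-weighted, since recurrence is captured separately by the
hotspot features); `E.summit` is the rate at the position with the most
coding mutations, ties resolved toward the lowest position.  Genes whose
mutated positions lack rate coverage get both features imputed (median of
the available `E.gene` values, configurable) and are flagged.

## Short-term somatic selection

For each gene, every possible point mutation of the coding sequence is
enumerated through the standard genetic code ("saturated" mutagenesis) and
weighted by a relative mutation-rate model (uniform by default; a
transition/transversion model with configurable κ is provided).  This
yields neutral expected proportions `(p_syn, p_mis, p_trunc)` and
per-codon class weights.  A trailing stop codon is excluded; internal
stops are rejected.

Observed counts `(n_syn, n_mis, n_trunc)` — truncating = nonsense +
frameshift — enter a three-category multinomial with probabilities
proportional to `(p_syn, ω·p_mis, φ·p_trunc)`.  The MLE is the
observed/expected odds ratio against the synonymous baseline:

    ω̂ = (n_mis / n_syn) · (p_syn / p_mis),   φ̂ = (n_trunc / n_syn) · (p_syn / p_trunc)

verified against a numerical maximizer in the acceptance battery.  Logs
are natural and clamped to [−5, 5]; zero counts saturate the clamp rather
than producing infinities, and no pseudocounts are added — a gene with no
observed truncating mutations reports `log φ = −5` (strong negative
selection on truncation, the oncogene signature).  This three-category
likelihood is deliberately minimal: per-site hotspot terms and
context-dependent mutation signatures are outside its scope, which is a
known fidelity limit.

Frameshift indels have no point-mutation opportunity; observed frameshifts
count into `n_trunc`, and the expected truncating proportion is the
nonsense opportunity plus a configurable indel-opportunity term (default
0, i.e. nonsense-only expectation).

Calibration (recomputed by `scripts/acceptance.py` and the acceptance
tests): at 300 mutations per gene, neutral genes give mean `log ω` and
`log φ` within ±0.15 of zero over 500 replicates, and the pooled mean
absolute error of `log ω` over true values {−3, 0, +3} (200 replicates
each) is below 0.3.  At strongly positive `log ω` the synonymous baseline
shrinks to a handful of counts, so per-gene estimates there carry
irreducible sampling noise of roughly ±0.45 — a property of the data, not
of the estimator.

## Mutation-distribution features

All fractions use the same denominator N = all coding mutations
(synonymous included).  The summit is the position with the most
non-synonymous mutations (ties → lowest position; genes with only
synonymous coding mutations fall back to all coding counts so the summit
is always defined).  `C.summit` counts coding mutations at the summit;
`R.summit = C.summit / N`; `R.peak` is the fraction of coding mutations
within ±5 amino acids of the summit (window configurable).  `R.length` is
the mean relative protein position of truncating mutations, 1.0 when there
are none; low values (early truncation) are the tumor-suppressor
signature.  Genes require at least five coding mutations to enter
classification; `other` consequences never count.

These six definitions are reconstructions of briefly named quantities;
each choice (window width, summit counting rule, denominator) is exposed
as a parameter with the defaults above.

## Random forest

CART with Gini impurity, built from scratch because the transfer operators
must rewrite trees node by node: every node exposes its split feature,
threshold and cached training class distribution (the cache is what a
snipped node predicts).  Defaults: 200 trees, bootstrap resamples of the
input size, ⌊√10⌋ = 3 candidate features per split, minimum leaf size 2,
no depth limit.  Candidate thresholds are midpoints of consecutive sorted
unique values; ties in impurity decrease resolve to the lowest feature
index then the lowest threshold, so builds are bit-for-bit reproducible.
Rows are placed in a canonical sort order before bagging, making training
invariant to input row order at a fixed seed.  Leaf prediction is the
class distribution, not a hard vote, giving graded gene probabilities.

## Transductive transfer

Features are z-scored with source-domain center/scale before any distance
is computed (raw-scale Euclidean distance would be dominated by
`C.summit`, an unbounded count); the same affine map is applied to target
genes.  A node's D is the mean pairwise Euclidean distance among the
target genes routed to it; with fewer than two genes D is undefined and
treated as 0 (a singleton is a maximally tight cluster), so an
empty/singleton child never triggers a snip by itself.

*Structure reduction* proceeds top-down (the only order under which
"snip the clade below" is well defined once triggered); recursion stops at
nodes with ≤1 routed gene, which are left unmodified.

*Threshold shifting* evaluates, at each internal node, the original
threshold plus all midpoints of consecutive sorted unique target values of
the split feature, and keeps the candidate minimizing the **sum of
within-child pairwise distances** `S_a + S_b` (ties → closest to the
original threshold, then smaller).  The design was genuinely open between
this pair-sum objective and the sum of the two child *mean* distances
`D_a + D_b`; the mean form is degenerate — it is minimized by splitting a
single extreme gene off an otherwise coherent cluster (`D_a ≈ D_parent`,
`D_b = 0`), which collapses routing and, empirically, halves end-to-end
accuracy.  The pair-sum form is equivalent to maximizing the summed
distance *across* children and places thresholds at cluster boundaries;
both forms agree on the canonical two-cluster example
({0, 1, 10, 11} → threshold 5.5).  Targets are re-routed with the new
threshold before descending.  Pruning and shifting are parallel operators
applied to the same source tree (never composed); the adapted ensemble is
the concatenation of all pruned and all shifted variants, exactly 2× the
source tree count.

Adaptation refuses an empty target matrix and warns below 20 target genes
— tumors with few mutated genes should reuse a previously adapted model
rather than adapt to themselves.

## Synthetic benchmark

The generator runs the selection model forward.  Per gene: a random CDS
(ATG…stop, no internal stops, GC ≈ 0.45), class counts from the
multinomial with probabilities ∝ `(p_syn, e^{log ω} p_mis, e^{log φ}
p_trunc)`, positions from the per-site neutral weights except a fraction
*h* of missense pinned to one hotspot site and, for the TSG archetype,
truncations restricted to the first 40% of the protein.  Mutation counts
per gene are 5 + NegBin(r = 2, mean 7) — at least five, averaging ~12,
matching the inclusion filter and the per-gene mutation loads of the
mouse tumor exome datasets this emulates.  Archetypes: OG `log ω ~
N(3.5, 1)`, `log φ ~ N(−3.5, 1)`, h = 0.5; TSG `log φ ~ N(3.5, 1)`,
`log ω ~ N(0.5, 1)`, early truncations; PG both `~ N(0, 0.5)`, no hotspot
(all truncated to [−5, 5]).  Long-term rate features are drawn directly
from class-conditional distributions (drivers at conserved sites, location
0.4 s/bys vs. 1.2 for passengers) rather than through per-gene alignments;
the alignment/tree generator exists separately and feeds the rate
machinery's own tests.  The default scenario has 150 source and 60 target
genes per class, and the target's covariate shift adds +0.5 source SD to
`E.gene`, `R.peak` and `C.summit`, emulating the accelerated tumorigenesis
and restricted genetic background of engineered models.

What the benchmark does not emulate: trinucleotide-context mutation
signatures, copy-number and expression alterations, inter-sample
heterogeneity of mutation rates, and real ortholog structure.  Passing
tests therefore demonstrate the internal correctness and calibration of
the estimators and operators under the stated generative model, not
clinical-grade accuracy on real exomes.

A benchmark observation worth stating plainly: under the default +0.5 SD
shift the un-adapted source forest already classifies the target at ~0.97
accuracy (the shifted features are not decision-critical when `log ω` and
`log φ` are unshifted), so adaptation has no systematic error to correct
and matches the source forest in only about two-thirds of seeded
replicates rather than consistently improving on it.  The adapted-forest
accuracy itself stays ~0.97.  Larger shifts do not change this picture —
the forest is simply robust to location shifts in a minority of features.

## Numerical conventions and degenerate inputs

Natural logs throughout; clamp ±5 applied after the log.  Routing is
`value ≤ threshold → left`.  Probabilities are exact rational averages of
leaf distributions and sum to 1 to machine precision.  Model files are
versioned JSON (schema version 1); loading any other version fails
explicitly.  Degenerate cases: a gene with zero coding mutations has no
feature vector (skipped, logged); all-zero mutation counts raise an
undefined-estimate error; observations in a class with zero neutral
opportunity raise an impossible-observation error; constant features get
standardization scale 1 with a warning; a single-sample training input
yields a single-leaf tree.
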