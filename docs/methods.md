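# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `markerani`.

## Gene-level ANI and the concatenate statistic

Gene ANI is a p-distance complement: for two aligned rows, a column is
*compared* iff both rows carry an unambiguous A/C/G/T (case-folded), and
`ANIg = 100·(1 − diffs/sites)`. Gap and ambiguity handling is **pairwise
deletion** by default: each pair keeps every column where both of its rows are
unambiguous. This maximizes usable data for amplicon-style inputs, which
routinely contain IUPAC ambiguity codes; a `gap_mode="complete"` switch on
`gene_ani_table` applies complete deletion (drop a column if *any* row is
gapped/ambiguous) for sensitivity analysis. The two modes can shift ANI by a
few tenths of a percent on gappy alignments, which is why the choice is
explicit and configurable rather than implicit.

The concatenate ANI (ANIstt for a three-gene marker set) is defined on the
concatenated alignment, which is identical to pooling `diffs` and `sites`
across member genes. This is the length-weighted combination; averaging
per-gene ANIg values would weight a 300 bp gene equally with a 1.5 kb gene and
is deliberately not what the function computes (the equivalence of
concatenate-counting and pooled counting is property-tested). Strains missing
from any member gene are a hard error — the statistic is only defined over
strains sequenced for all member genes.

Unaligned gene pairs (e.g. a query strain against reference amplicons) are
aligned with global Needleman–Wunsch (match +1, mismatch −1, gap open −4, gap
extend −1, via Biopython's PairwiseAligner) before counting; pre-aligned rows
are used as-is. ANI values are carried at full float precision and rounded
only for display.

## Fragment-seeded genome ANI

Genome ANI is a self-contained fragment estimator in the ANIb/ANIm tradition,
not a wrapper around an external aligner. The query genome is cut into
consecutive, non-overlapping fragments of `fragment_len` (default 1020 bp; the
trailing sub-fragment remainder is not used). Each fragment is placed on the
subject by exact `seed_k`-mer lookup (default k = 15) on both strands, keeping
the diagonal with the most seed hits (k-mers are sampled every 4 positions;
ties break toward the smaller diagonal for determinism). The fragment is then
aligned globally against a subject window extending `window_margin` (50 bp)
beyond the seed diagonal using edlib's bit-vector alignment, which plays the
role of a banded global aligner around the seed diagonal; identity is matched
columns over alignment columns from the extended CIGAR. Fragments pass the
classic filter `identity ≥ 30%` and `coverage ≥ 0.70`; qualifying fragments
contribute their identity weighted by aligned length, and the reported ANI is
the mean of the two directional estimates. `aligned_fraction` is the fraction
of attempted fragments that qualified. When no fragment qualifies the result
is *no homology detected* (`ani = None`), deliberately distinct from ANI 0.

Accuracy on indel-free simulated pairs is limited by seed availability: at
divergence d the chance of an exact 15-mer seed per position is (1−d)^15,
which is still ~20% per position at d = 0.10, so 1020 bp fragments essentially
always seed; measured recovery error across a 1–10% divergence ladder is below
0.1 percentage points (the acceptance script reports the measured maximum).
At divergences far beyond 0.2, seeding and the identity floor start to censor
fragments and the estimator is no longer meaningful — consistent with how
fragment-ANI tools behave on inter-genus comparisons.

## Marker screening

The screening criterion is **boundary concordance**: the genome table assigns
each pair "same species" iff ANIm ≥ 95 (closed boundary: a tie at exactly
95.00 is same-species; the threshold is configurable). A gene is concordant
iff some t ∈ {95, 96} makes `ANIg ≥ t` match the genome assignment on every
shared pair; the smallest satisfying t is reported so boundaries err toward
lumping. Screening also computes the gene's ANI gap (minimum intra-species
ANI minus maximum inter-species ANI, with violators of the 96/94 floors
listed), the gene length excluding all-gap columns (the <1.5 kb preference
refers to gene length, not alignment width), and — when a reference tree is
supplied — the normalized Robinson–Foulds distance of the gene's
neighbor-joining tree to it as a congruence score. Ranking is lexicographic:
concordant first, then larger gap, then smaller RF distance, then shorter
gene, then gene name (a deterministic tie-break that makes screening invariant
to input order). Genes whose statistics cannot be computed are reported as
screened-out with the reason instead of silently dropped. RF congruence is a
topological stand-in for likelihood-based congruence testing, which is out of
scope here; when no reference tree is given the term is simply omitted from
the ranking.

## Species delimitation, audit and assignment

Pair classification is one-dimensional in the marker-concatenate ANI: intra
iff ANIstt ≥ 96, inter iff ANIstt ≤ 94, intermediate in the open interval
between. The boundaries are closed on the observed extremes because they are
defined *as* observed extremes (highest inter-species value 94, lowest
intra-species value 96); tie behaviour at exactly 94.00/96.00 follows that
convention and is configurable. When genome ANI is also available, the 2-D
regions use strict inequalities — inter region ANIm < 93 and ANIstt < 94,
intra region ANIm > 95 and ANIstt > 96 — so boundary points fall "between" by
construction and the three region counts always partition the total.

The type-strain audit counts inter-species pairs below the 94% ceiling (the
strict "supported" criterion) and, because the 96% floor is also used as a
lenient bound in the literature, reports the below-96 count as well. Species
whose type strains reach ANIstt ≥ 96 are linked, and connected components of
that graph are reported as merge candidates (prospective synonymies); which
name has nomenclatural priority is not a computational question and is left
to the user. Query assignment computes ANIstt between the query's marker
genes and every type strain (aligning per gene when inputs are unaligned):
assigned to the best-scoring species at ≥ 96, a novel-species candidate at
≤ 94, ambiguous otherwise; a type-strain query assigned to another species is
flagged as a later-synonym candidate.

## Concordance statistics

Pearson correlation is the product-moment formula; Spearman is Pearson on
average ranks (ties share the mean rank, the common statistical-package
default). Polynomial fits (degree 1 or 2) solve least squares on a Vandermonde
design; R² = 1 − SSE/SST, overall F = (SSR/p)/(SSE/(n−p−1)). The nested
comparison uses the extra sum-of-squares statistic
F = (SSE_lin − SSE_quad)/(SSE_quad/(n−3)) on (1, n−3) df. A numerically exact
fit leaves SSE as rounding dust rather than zero, so SSE below 1e−12 of the
linear SSE is treated as zero; a perfect quadratic over an imperfect line is
reported as infinite F with a flagged p = 0 convention. P-values below 1e−4
are displayed as "<0.0001". These implementations are deliberately
independent of scipy's correlation/regression routines, which serve as
oracles in the tests.

## Trees and recombination

Neighbor joining runs on distances 100 − ANI through scikit-bio's standard
implementation (asymmetric, negative or non-hollow matrices are rejected
first). RF distance enumerates nontrivial bipartitions per tree and counts
the symmetric difference, normalized by 2(n−3) on request; the tests validate
it against an independent split-enumeration oracle over all 105 six-leaf
topologies.

The recombination check is a PHI-style permutation test. The *refined
incompatibility* of two aligned columns is the cycle rank E − V + C of their
bipartite state graph (nodes: observed states at each site; edges: observed
joint states), after dropping taxa with gaps/ambiguities pairwise. This is 0
iff the two characters can both evolve without homoplasy on a single tree and
generalizes the four-gamete test to multistate characters; the tests verify
it equals the exhaustive minimal-extra-steps parsimony oracle on ≤6 taxa. The
statistic averages incompatibility over pairs of parsimony-informative sites
(≥2 states each seen ≥2 times) at most `window_w` apart in informative-site
index space (default 100, configurable; the simulations in the tests use 25
so that the window is small relative to gene length and the local-compatibility
signal is not diluted). The null permutes informative-site order; because
recombination concentrates compatibility locally, significance is an
unusually *low* observed statistic, and the p-value is the add-one-corrected
fraction of permutations with statistic ≤ observed — never exactly 0, with a
"<0.0001" display floor.

## Synthetic panels

The generator emulates the data regime the method targets: species clusters
with a clean ANI gap. It builds a fixed-depth star of species (no birth–death
or coalescent machinery — only pairwise divergences matter to ANI methods):
species ancestors sit at depths drawn from half the inter-species divergence
range (default 0.06–0.20 per site) below the root, strains at depths from
half the intra range (default 0–0.03) below their ancestor. Each gene (length
900–1500 bp by default) evolves along these edges under a uniform
equal-rates substitution model scaled by its rate multiplier; intergenic
filler (multiplier 1.0) pads the genome. Transfer events overwrite a
cross-species recipient's gene with the donor's copy, distributed round-robin
over the designated transferable genes so coverage is deterministic. No
indels are simulated by default, so alignments are trivial and the logged
truth — realized differing-site fractions from direct comparison of the final
sequences — is exact rather than distributional. Identical seeds give
byte-identical panels.

What the generator does *not* emulate: indel/rearrangement structure, plasmid
and symbiosis-island architecture, codon and GC-content biases, rate
heterogeneity along a gene, and realistic phylogenetic tree shapes. Passing
tests therefore demonstrate correctness of the counting, screening and
testing machinery under the stated divergence structure, not robustness to
alignment error or compositional artifacts in real amplicon data.

## Problem sizes and determinism

The test suite and acceptance script size their simulations to what the
statistics need rather than to realism: 200 kb genome pairs for the ANI
ladder (sampling error ≪ 0.1 points), 50 twenty-gene panels for marker
recovery, 200/50 replicates for PHI error rates with 200 permutations per
test, and exhaustive enumeration at six taxa where oracles are exhaustive.
Every stochastic routine takes an explicit seed; the acceptance script
derives all sub-seeds from its `--seed` argument.

## Known limitations

- The fragment genome-ANI is validated by property tests against simulated
  truth, not bit-compatible with NUCmer/JSpecies output; on real genomes with
  repeats or rearrangements, best-diagonal seeding can pick paralogous
  placements that a maximal-unique-match chainer would avoid.
- Pairwise-deletion ANI on very gappy alignments uses different site sets for
  different pairs; the support field records per-pair compared sites so users
  can filter.
- The delimitation boundaries (93/94/95/96) are empirical constants of the
  rhizobial study system they come from; they are defaults, not universals,
  and every report echoes the thresholds used.
- The PHI permutation test reports an add-one-corrected p-value, so its floor
  is 1/(n_permutations+1).
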