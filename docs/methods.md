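# Methods

## Covariation statistic

Column pairs are scored with the G-test of independence over the 16 joint
residue categories, computed on rows with no gap at either position:
G = 2 Σ n_ab ln(n_ab N / (n_a n_b)), zero terms dropped, G clipped at 0 and
defined as 0 when fewer than two gap-free rows remain. Rows with a gap at
either position are excluded rather than treated as a fifth symbol: gaps
reflect alignment uncertainty, not substitution signal. The all-pairs
computation is vectorized through a one-hot tensor contraction and agrees
with a direct dictionary-count implementation to floating-point accuracy
(tested).

## Null model and E-values

Significance uses a permutation null: each column of the alignment is
permuted independently across rows, destroying inter-column dependence while
preserving exact column composition. The all-pairs G statistics of
`n_null` shuffled alignments (default 20) are pooled into an empirical
survival function with an add-one boundary rule, P(g) = (1 + #{null ≥ g}) /
(1 + N_pool), so the smallest attainable P is 1/(N_pool+1) and P(0) = 1.
With 20 shuffles this is exactly the resolution needed to call E ≤ 0.05 on
an 80-column alignment. A gamma distribution fitted to the exceedances over
the pooled 95th percentile extrapolates the survival function beyond the
largest null statistic (capped by the add-one bound so monotonicity is
preserved); without a usable tail fit the add-one rule stands alone. The
pair E-value is `n_pairs_tested × P(g)`.

Rows are treated as exchangeable. For alignments with strong phylogenetic
structure this null is anti-conservative — shared ancestry itself induces
covariation that a tree-aware null would absorb. The synthetic generators
deliberately draw rows independently from one ancestor (a star tree), under
which the permutation null is exact, so the calibration tests are honest;
real alignments with deep clade structure will need externally supplied
null statistics, which `annotate_pairs(calibration=...)` accepts.

## Power proxy

Covariation requires variation: a perfectly conserved pair cannot covary.
Per column we count gap-free rows differing from the majority residue (ties
broken alphabetically); a pair "has power" when both columns have at least
`s_min = 2` substitutions. This is a deliberately simple proxy for
calibrated per-pair detection power; pairs with power but no significant
covariation ("negative pairs") are prohibited in the fold.

## Constrained fold

The fold organizes covarying pairs rather than predicting thermodynamic
stability, so scoring is pair-count based: each eligible pair (WC/wobble on
the column consensus, N matching anything, hairpin loops ≥ 3) scores 1,
plus `w_cov = 10` for significant pairs. A Nussinov-style O(n³) dynamic
program maximizes total weight subject to: significant pairs forced in (a
greedy non-conflicting subset by ascending E-value), negative pairs
excluded. Forced pairs that cross the nested layer — or violate the loop
minimum — are emitted in pseudoknot layers assigned greedily by descending
weight, so no significant pair is silently dropped. DP optimality is tested
against exhaustive enumeration of all nested structures for lengths ≤ 12.
Traceback prefers the unpaired branch, then the smallest closing partner,
making output deterministic among co-optimal structures.

Stems are maximal stacking runs (i+1, j−1) within one layer;
`bulge_tol = k` lets a run jump up to k unpaired positions per strand.
The default is the strictest reading (`bulge_tol = 0`); the helix-boundary
convention for the "same stem" criterion is genuinely underdetermined, so
the tolerance is exposed rather than fixed.

## Candidate criteria and aggregation

An alignment passes when it has ≥ 3 significant pairs (E ≤ 0.05) and ≥ 2 of
them in one stem of the proposed structure. A non-passing alignment with
any pair below the rescue threshold 10⁻⁴ becomes `rescue`: primary-sequence
alignments can be too poor for covariation analysis, and one exceptionally
strong pair warrants a structure-informed second pass — implemented here as
a re-fold with the rescuing pair forced.

Significant pairs' E-values are aggregated by Fisher's method as if they
were P-values: −2 Σ ln pᵢ is referred to χ² with 2n degrees of freedom and
the survival probability reported. E-values above 1 are clamped to 1 before
taking logs (the clamp count is recorded); with three E-values of
6.5×10⁻⁷, 0.0053 and 0.0204 the aggregate is 2.1×10⁻⁸, and a screen of
134,000 alignments at that threshold expects 134000 × 2.1×10⁻⁸ ≈ 0.003
false positives. Alignments with more than `max_codon_like = 3` significant
covariations at ungapped-consensus distance 1–2 are flagged as likely
protein-coding; distance is measured on consensus positions (columns with
> 50% gaps unmapped) so gap columns cannot mask within-codon spacing.

## Query geometry

Windowing tiles regions longer than 1000 nt with a uniform 500-nt stride
and a final remainder-covering window ending at the region end (a 2500-nt
region gives 1–1000, 501–1500, 1001–2000, 1501–2500); regions under 100 nt
are skipped as too short for a specific homology hit. Coding-flanked
queries cap the UTR at the 2000 nt nearest the CDS junction and the CDS at
the 1000 nt nearest it, strand-independently (capping is junction-relative).
After non-coding extraction, rows need ≥ 50 residues in the extracted span;
every non-gap symbol counts toward that threshold. Per genome only the
top-scoring hit is kept (ties keep the earlier row), since extra copies are
often pseudogenes whose decayed pairing dilutes covariation.

## H/ACA guide–target search

The pocket geometry is the canonical one: the target U (ψ) and the residue
3′ of it stay unpaired; the guide's 3′ strand pairs antiparallel with the
target upstream of ψ and the 5′ strand downstream from ψ+2. A match needs
at least 4 consecutive WC/wobble pairs on each flank with no internal
mismatches; `N` in a consensus-derived guide pairs with nothing and breaks
a run. The false-positive rate of a match is the fraction of mononucleotide
(composition-preserving) shuffles of the target containing a pocket with at
least as many total pairs and no more wobbles; dinucleotide shuffling is
not the default because simple composition preservation matches the
negative-control construction used for the guide search. A degenerate
zero-pair requirement is vacuously satisfied by every shuffle (FPR 1.0).

## Synthetic generators

`simulate_structured_alignment` draws rows independently from one uniform
ancestor whose planted stems are forced complementary. Unpaired sites
substitute independently at `per_site_sub_prob`; planted pairs substitute
jointly — the 5′ residue changes and the partner is switched to a
complementary residue (wobble included) with `compensation_prob`, else
redrawn freely. Defaults (40 rows, length 120, one 6-pair stem, sub 0.3,
comp 0.9) put the planted signal at moderate divergence: strong enough to
detect, weak enough that calibration matters. Conserved spans (e.g. H/ACA
boxes) never mutate. What this generator does *not* emulate: indels,
phylogenetic correlation between rows, GC-content heterogeneity, and
alignment error — so passing tests demonstrate correctness of the
statistical machinery under its stated model, not performance on real
genomic alignments.

`simulate_coding_alignment` gives each codon slot two variants differing at
all three positions; a row copies a variant wholesale with probability
`within_codon_corr`, else draws positions independently, producing the
short-range covariation the codon filter targets. `make_snorna_fixture`
plants exactly one strict-WC pocket in a random target and verifies (with
the same seeded generator) uniqueness and that ablating the U abolishes it.

## Problem sizes and numerical choices

The test suite and acceptance script use: 500 (tests) / 150 (script)
structure-free 30×80 alignments with 20 shuffles each for type-I control
(band 0.02–0.10 around the nominal 0.05); 100 / 50 planted-stem replicates
with shuffled twins; 200 / 100 random sequences of length ≤ 12 for the fold
oracle; 100 / 50 guide-pocket seeds. All randomness flows from explicit
seeds; identical inputs reproduce identical bytes. Ties everywhere break
deterministically (alphabetical residues, earlier rows, smaller pairs).
Degenerate inputs are defined, not exceptional: empty extraction results
are empty alignments, single-row shuffles are identities, an alignment with
no significant pairs aggregates to P = 1.

## Known limitations

The permutation null ignores phylogeny (see above); the power proxy is not
a calibrated detection-power curve; the fold has no energy model and one
pseudoknot cascade level only; the codon filter is a spacing heuristic, not
a coding-potential test; guide extraction from alignments relies on the
consensus being definite (N breaks pairing runs), so poorly conserved
guides go undetected.
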