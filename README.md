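# covscreen

Screening genomic regions for evidence of conserved RNA structure from
multiple sequence alignments.

Structural non-coding RNAs keep their base pairs across evolution even as
their primary sequence drifts: a conserved pair (i, j) accumulates
*compensatory substitutions* — joint changes at both positions that
preserve Watson–Crick or G:U wobble pairing. The correlated variation
(covariation) of two alignment columns is therefore the one evolutionary
signature specific to conserved structure, unlike raw sequence conservation
or mere foldability. `covscreen` quantifies it, calibrates it against a
permutation null, and turns the result into a candidate call. It is aimed
at comparative genomicists triaging unannotated regions (intergenic
windows, introns, UTRs) for structural RNA candidates without any external
binaries.

## Method

For columns *i*, *j* of an alignment, restricted to rows with no gap at
either position, the covariation score is the G-test of independence on the
4×4 joint residue counts:

    G(i,j) = 2 Σ_ab n_ab ln( n_ab N / (n_a n_b) )

Significance is calibrated by column shuffling: each column is permuted
independently across rows, which destroys covariation while preserving
composition and per-column conservation. Pooling all-pairs G statistics
over many shuffled alignments gives an empirical survival function S(g)
(gamma-smoothed beyond its maximum), and each pair receives an E-value
E = n_pairs · S(G) — the expected number of false pairs per alignment at
that score. Per column, the substitution count against the majority residue
proxies *covariation power*: a pair with power at both columns but no
significant covariation is a *negative pair*.

The consensus is then folded by a Nussinov-style dynamic program that
maximizes pair count (plus a bonus per significant pair), forces significant
pairs in — crossing ones are emitted as pseudoknot layers, never dropped —
and excludes negative pairs. An alignment is a **candidate** when it has
(i) at least 3 significant covarying pairs (E ≤ 0.05) and (ii) at least 2
of them in one stem; alignments failing that but holding one pair with
E < 10⁻⁴ are routed to a *rescue* re-fold for a structure-informed second
pass. Significant pairs' E-values p₁…pₙ combine by Fisher's method,
−2 Σ ln pᵢ ~ χ²(2n), into an aggregated P-value; multiplied by the number of
alignments screened this bounds the expected false positives. Alignments
with more than three significant covariations at consensus distance 1–2 are
flagged as likely protein-coding (codon structure).

The package also prepares screen queries (1000-nt IGR windows with 500-nt
overlap, 100-nt minimum; UTR/CDS capping for coding-flanked queries;
≥50-nt row filtering after non-coding extraction; top-hit-per-genome
deduplication) and searches rRNA targets for H/ACA snoRNA pseudouridylation
pockets (H box ANANNA, 3′ ACA box, ≥4 consecutive WC/wobble pairs on both
flanks of the target U) with a shuffle-based false-positive rate.

## Worked example

Generate a 40-sequence alignment with a planted 6-pair stem maintained by
compensatory substitutions (30% per-site substitution rate, 90%
compensation), then scan it:

```bash
$ covscreen simulate --kind structured --seed 7 --out-dir fixtures
$ covscreen scan fixtures/structured.sto --out-dir scan_out
structured.sto: verdict=pass n_significant=6 max_same_stem=6 aggregated_p=7.79e-17
$ cat scan_out/structure.txt
...................((((((.......................................))))))...
```

All six planted pairs are recovered as significant (E ≤ 0.05), all six sit
in one stem, so both candidate criteria hold and the verdict is `pass`; the
aggregated P-value 7.8×10⁻¹⁷ is the Fisher combination of the six E-values.
Scanning the column-shuffled twin of the same alignment yields
`verdict=fail n_significant=0`. The library surface mirrors the CLI:
`scan_alignment`, `annotate_pairs`, `constrained_fold`, `classify`,
`fisher_aggregate`, `guide_target_search`, and the `simulate_*` generators.

Window geometry, e.g. a 2500-nt intergenic region:

```bash
$ covscreen window 2500
1	1000
501	1500
1001	2000
1501	2500
```

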