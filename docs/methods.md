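# Methods

This document defines the statistical model behind each `diphic` module,
the default parameters, and known limitations. All defaults live in code
(`SimConfig` and module-level constants) and are repeated here for
reference; units are base pairs (bp) unless stated.

## Synthetic diploid genome (`diphic.simulate`)

`SimConfig` describes an F1 hybrid between two breeds (haplotype 1 and
haplotype 2, default `("broiler", "layer")`). `make_truth` plants, per
chromosome:

- **Variants**: heterozygous SNVs at `snv_density` = 4.42 per kb (Poisson),
  of which `indel_fraction` = 0.05 are indels with geometric lengths.
- **Compartments**: alternating A/B blocks of `compartment_block_bp` = 1 Mb;
  same-compartment contacts are enriched by `compartment_strength` = 2.0.
  GC content is simulated higher in A, providing the orientation covariate.
- **TADs**: domain sizes drawn from `tad_sizes_bp`; within-domain contacts
  enriched by `tad_strength` = 3.0.
- **PEI**: `n_pei_per_chrom` = 8 promoter–enhancer pairs per chromosome with
  fold `pei_fold` = 5.0 over the local expected.
- **Pairing blocks**: optional `(chrom, start, end, fold)` regions with
  elevated inter-homolog contact.
- **Genes**: `genes_per_mb` = 8.0; a `breed_effect_fraction` = 0.1 subset
  expresses one breed's haplotype `breed_effect_fold` = 4.0 higher in both
  cross directions (a breed effect, not imprinting — the generator plants
  no parent-of-origin effects).
- **Population genotypes**: `n_pop_sites` = 500 sites for `n_per_pop` = 12
  diploid individuals per breed under a Balding–Nichols model with
  `fst_target` = 0.1.

Contacts (default `n_contacts` = 500 000) follow a power-law distance decay
with exponent `decay_exponent` = −1.0, modulated by the planted structure;
`inter_homolog_fraction` = 0.05 of contacts are between homologs (more in
pairing blocks), `heterolog_fraction` = 0.005 between different
chromosomes' homolog pairs, and `random_ligation_fraction` = 0.02 is
uniform noise. Each contact end carries haplotype "votes" from overlapping
SNVs within `read_span` = 150 bp, flipped with `vote_error` = 0.001.

Determinism: every sampling stream is derived from
`np.random.SeedSequence([seed, k])` with fixed stream indices, and
per-sample seeds use CRC-32 of the sample name, so results are
byte-identical across runs and platforms for a given seed.

## Phasing (`diphic.phasing`)

Each read end's votes are reduced to a haplotype label: unanimous → that
haplotype, no votes → unknown, mixed → conflict. Contact classes:

- `intra_haplotype`: both ends same haplotype, same chromosome (a single
  phased end suffices for cis contacts — the unphased end is assumed to be
  on the same homolog);
- `inter_homolog`: same chromosome, opposite haplotypes (both ends must be
  phased);
- `heterolog`: different chromosomes, both ends phased;
- `unphased`: insufficient evidence; `conflict`: any conflicted end.

The class counts partition the input exactly. Phased contacts populate
per-chromosome matrices M11, M22 (cis per homolog) and M12
(inter-homolog). `impute_local` allocates each unphased cis contact
(i, j) to M11 or M22 by a Bernoulli draw with probability proportional to
the phased mass in the (i±5, j±5) window of each matrix (computed with
integral images); totals are conserved.

`map_resolution` selects the smallest candidate bin size for which ≥ 80%
of bins contain ≥ 1000 read ends.

## Matrix operations (`diphic.matrix_ops`)

**KR balancing** uses the damped fixed point x ← x/√(Mx·x) until the
coefficient of variation of row sums is < 1e-6 (raises `BalanceError`
otherwise). Bins with zero marginals are masked out and restored as
NaN-free zero rows.

**Quantile normalization** equalizes value distributions across matrices
within each |i−j| distance stratum. When all matrices have the same
nonzero count in a stratum the reference is the mean of order statistics
(exact); otherwise a 101-point quantile interpolation is used. A fixed
external reference can be supplied via `reference_matrices`; rank order
within each matrix and stratum is preserved, and zeros stay zero.
Note: with the default self-derived reference, adding a matrix to the set
changes the reference, so normalized values are only invariant under
monotone perturbations when a fixed reference is used.

**GenomeDISCO** concordance smooths both matrices by random walks
(t = 3 steps on the row-normalized matrix) and scores
1 − Σ|R1³ − R2³| / mean(nonzero rows); identical matrices score 1.

**Expected-by-distance** fits a log-log linear model of mean contact vs
distance over a configurable fit range.

## Homolog pairing (`diphic.pairing`)

The homolog pairing score for bin i is
log2((w_i + 1)/(μ + 1)) where w_i is the M12 mass in the window i±2
(edge-truncated) and μ the chromosome mean of the same window sums. Tight
regions are bins above Q3 + 1.5 × IQR (type-7 quantiles) of the pooled
genome-wide track; flagged bins separated by one masked bin are merged.
`feature_enrichment` compares features inside vs outside tight regions
with Fisher's exact test (binary) or rank-sums (continuous).

## Compartments (`diphic.compartments`)

The A/B index is PC1 of the Pearson correlation of the observed/expected
matrix, computed per chromosome on the balanced matrix. The sign is
oriented so the index correlates positively with GC content; if
|r| < 0.2 against the covariate, PC2 is tried. The concatenated genome
track is scaled to SD = 1. Differential analysis between two replicate
groups classifies bins as **switched** (opposite signs with |mean| > 0.1
in both groups) or **variable** (|Δmean| strictly above a threshold — 1.0
for stage comparisons, 0.3 for breed/parent — with paired t-test
p < 0.05); adjacent flagged bins merge into regions reported in Mb.

## TADs (`diphic.tads`)

The directionality index contrasts upstream vs downstream contact sums in
a 2-Mb window (the canonical A = 10, B = 30 case gives +10). The
insulation index is the log2 ratio of the sliding-square mean
(100-kb square) to its chromosome mean, NaN at edges. Boundaries are
insulation minima gated by a DI sign change (− → +) within ±2 bins;
domains tile the chromosome. The local boundary score ∈ [0, 1] measures
contact depletion across a boundary. Partition similarity uses the
overlap matrix: Measure of Concordance (identical partitions → 1;
1-domain vs k equal domains → 0) and variation of information
(identical → 0; the same degenerate pair → ln k).

## Promoter–enhancer interactions (`diphic.pei`)

A two-level expected model combines a genome-wide log-log distance decay
with per-TAD refits (domains with < 20 positive pairs fall back to the
background fit). Candidate enhancer bins within 25 kb–1 Mb of a promoter
are tested with a Poisson upper tail, p = sf(⌈obs⌉ − 1, expected), and
BH-FDR across all pairs. The regulatory potential score of a gene is
RPS = log2(1 + Σ max(O/E − 1, 0)) over its significant pairs.
`differential_rps` flags genes with |ΔRPS| strictly greater than 3.0
(stage axis) or 0.3 (breed/parent axes) and paired-test p < 0.05.

**Limitation**: the expected model is intentionally simple. When strong
compartment checkerboards are present, same-compartment pairs at long
range systematically exceed the distance-decay expected, which inflates
the empirical false-discovery rate well above the nominal q even though
the Poisson test itself is calibrated. FDR control should be interpreted
relative to the matched background (decay + TADs); see the acceptance
test for the construction.

## Allelic expression (`diphic.ase`)

SNV-level allelic counts are aggregated per gene and sample. Genes with
total ≥ 20 counts and TPM ≥ 0.5 are tested with an exact binomial test
against 0.5 and BH-corrected within the testable set; significant genes
with hap1 ratio outside [0.3, 0.7] are called hap1/hap2-biased,
otherwise biallelic. The imprinting screen pools counts per cross
direction of a reciprocal design: a gene biased toward the same parental
role in both directions is an `imprinting_candidate`; toward the same
breed, a `breed_effect`; otherwise `not_biased` or `inconsistent`.

## Variants and population genetics (`diphic.variants`)

Per-site FST follows Weir & Cockerham (1984) (variance components a, b, c
from genotype matrices coded 0/1/2; negative codes are missing). Sites
with FST ≥ 0.75 are "high-FST". The haplotype identity score of a region
is 1 − (mismatched bp)/(region length), counting 1 bp per SNV and the
in-region clipped length per indel; a 1-kb region with 5 SNVs and a 10-bp
indel scores 0.985. `high_fst_enrichment` compares genes whose enhancers
contain high-FST sites against the rest (rank-sum on ΔRPS and expression
difference, Fisher on differential status and enhancer redundancy).

## Pipeline (`diphic.pipeline`, `diphic.cli`)

`run_pipeline` simulates both cross directions, replicates and stages,
phases and balances the matrices, and runs every analysis axis
(breed = haplotype 1 vs 2 within stage; stage = E15 vs D1; parent =
maternal vs paternal via the reciprocal design), writing `summary.json`,
`summary.tsv`, BED/bedGraph/TSV artifacts. Default problem sizes in the
shipped configs (a few Mb per chromosome, 10⁵–10⁶ contacts) are package
choices sized for tests and demonstration; all scale linearly in contacts
and quadratically in bins per chromosome.
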