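"""Synthetic diploid Hi-C generator with planted, recoverable structure.

Emulates the study design that motivates the pipeline: an F1 hybrid of two
divergent breeds carrying ~4.42 heterozygous SNVs per kb, assayed by in situ
Hi-C (PE150). Contacts follow a power-law distance decay modulated by a
planted compartment checkerboard, planted TAD blocks, planted promoter-
enhancer peaks, and planted inter-homolog pairing blocks; read ends pick up
haplotype votes from overlapping phased variants. Allelic expression counts
carry planted breed effects (and, by default, no parent-of-origin effect);
two-population genotypes are drawn from Balding-Nichols frequency divergence
with a per-site target FST.

All randomness flows from ``SimConfig.seed``. Every planted element is
recorded in ``SyntheticTruth`` so downstream callers can score recovery
without re-deriving truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBinning

HAP1, HAP2 = 1, 2

STAGES = ("E15", "D1", "D30")
CROSSES = ("BxL", "LxB")  # sire breed x dam breed


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of one simulated diploid genome and its assays.

    Folds are multiplicative enrichments (>= 1); ``seed`` fixes all
    randomness. Coordinates are 0-based half-open bp.
    """

    chrom_lengths: dict
    bin_size: int = 20_000
    snv_density: float = 4.42          # het sites per kb
    indel_fraction: float = 0.05       # fraction of het variants that are indels
    decay_exponent: float = -1.0
    compartment_block_bp: int = 1_000_000
    compartment_strength: float = 2.0  # same-label contact enrichment
    tad_sizes_bp: tuple = (400_000, 600_000, 300_000, 500_000)
    tad_strength: float = 3.0
    pairing_blocks: tuple = ()         # (chrom, start_bp, end_bp, fold)
    pei_truth: tuple = ()              # (chrom, promoter_bin, enhancer_bin, fold); () -> generated
    n_pei_per_chrom: int = 8
    pei_fold: float = 5.0
    n_contacts: int = 500_000
    inter_homolog_fraction: float = 0.05
    heterolog_fraction: float = 0.005
    random_ligation_fraction: float = 0.02
    read_span: int = 150               # bp scanned for informative SNVs per end
    vote_error: float = 0.001          # per-vote haplotype flip probability
    genes_per_mb: float = 8.0
    expression_depth: float = 200.0    # mean informative reads per expressed gene
    breed_effect_fold: float = 4.0     # allelic fold for planted breed-effect genes
    breed_effect_fraction: float = 0.1
    n_replicates: int = 2              # families per cross direction
    stage: str = "E15"
    cross: str = "BxL"
    hap_breeds: tuple = ("broiler", "layer")   # breed of hap1, hap2
    fst_target: float = 0.1
    n_pop_sites: int = 500
    n_per_pop: int = 12
    seed: int = 0

    def validate(self):
        if not self.chrom_lengths:
            raise ConfigurationError("no chromosomes")
        for c, L in self.chrom_lengths.items():
            if L <= 0:
                raise ConfigurationError(f"chromosome {c} length must be > 0")
        if self.bin_size <= 0:
            raise ConfigurationError("bin_size must be > 0")
        for f in (self.compartment_strength, self.tad_strength, self.pei_fold):
            if f < 1:
                raise ConfigurationError("folds must be >= 1")
        for c, s, e, f in self.pairing_blocks:
            if c not in self.chrom_lengths or s < 0 or e > self.chrom_lengths[c] or s >= e:
                raise ConfigurationError(f"pairing block ({c},{s},{e}) out of range")
            if f < 1:
                raise ConfigurationError("pairing fold must be >= 1")
        if self.snv_density < 0:
            raise ConfigurationError("snv_density must be >= 0")
        if self.expression_depth < 0:
            raise ConfigurationError("expression depth must be >= 0")

    @property
    def binning(self) -> GenomeBinning:
        return GenomeBinning(self.chrom_lengths, self.bin_size)


@dataclass
class SyntheticTruth:
    """Planted structure emitted alongside every simulated dataset."""

    config: SimConfig
    variant_table: pd.DataFrame          # CHROM POS REF ALT GT is_indel indel_len
    compartment_truth: dict              # chrom -> per-bin label (+1 = A, -1 = B)
    tad_truth: dict                      # chrom -> sorted boundary bin indices
    tad_domains: dict                    # chrom -> list of (start_bin, end_bin) half-open
    gc_content: dict                     # chrom -> per-bin GC fraction (A blocks richer)
    pairing_truth: dict                  # chrom -> per-bin bool (tightly paired)
    pei_truth: list                      # (chrom, promoter_bin, enhancer_bin, fold)
    gene_table: pd.DataFrame             # gene, chrom, start, end, tss, strand, n_enhancers
    expression_truth: pd.DataFrame       # gene, base_mean, breed_effect_fold, favored_breed
    population_freq_truth: pd.DataFrame  # site CHROM POS p_pop1 p_pop2 target_fst


def _simulate_variants(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    bases = np.array(list("ACGT"))
    frames = []
    for chrom, length in config.chrom_lengths.items():
        n = rng.poisson(length / 1000.0 * config.snv_density)
        n = min(n, length)  # cannot exceed one variant per bp
        pos = np.sort(rng.choice(length, size=n, replace=False)) if n else np.array([], int)
        ref_i = rng.integers(0, 4, n)
        alt_i = (ref_i + rng.integers(1, 4, n)) % 4
        gt = np.where(rng.random(n) < 0.5, "0|1", "1|0")
        is_indel = rng.random(n) < config.indel_fraction
        indel_len = np.where(is_indel, 1 + rng.geometric(0.3, n), 0)
        frames.append(pd.DataFrame({
            "CHROM": chrom, "POS": pos,
            "REF": bases[ref_i], "ALT": bases[alt_i],
            "GT": gt, "is_indel": is_indel, "indel_len": indel_len,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["CHROM", "POS", "REF", "ALT", "GT", "is_indel", "indel_len"])


def _compartment_labels(config: SimConfig, chrom: str) -> np.ndarray:
    binning = config.binning
    n = binning.n_bins(chrom)
    starts = binning.bin_starts(chrom)
    block = (starts // config.compartment_block_bp).astype(int)
    labels = np.where(block % 2 == 0, 1, -1)
    assert labels.shape == (n,)
    return labels


def _tad_layout(config: SimConfig, chrom: str) -> tuple:
    """Tile the chromosome with domains cycling through tad_sizes_bp."""
    binning = config.binning
    n = binning.n_bins(chrom)
    length = config.chrom_lengths[chrom]
    edges_bp, pos, k = [0], 0, 0
    while pos < length:
        pos = min(pos + config.tad_sizes_bp[k % len(config.tad_sizes_bp)], length)
        edges_bp.append(pos)
        k += 1
    edges = sorted({min(int(e // config.bin_size), n) for e in edges_bp})
    domains = [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]
    boundaries = [b for _, b in domains[:-1]]
    return np.array(boundaries, int), domains


def make_truth(config: SimConfig) -> SyntheticTruth:
    """Plant all structure for one simulated genome. Deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    binning = config.binning

    variants = _simulate_variants(config, rng)
    compartments = {c: _compartment_labels(config, c) for c in config.chrom_lengths}
    tad_truth, tad_domains = {}, {}
    for c in config.chrom_lengths:
        tad_truth[c], tad_domains[c] = _tad_layout(config, c)

    # GC tracks the planted compartments: A blocks are GC- and gene-richer,
    # which is what orients the compartment eigenvector on real data.
    gc = {c: 0.45 + 0.03 * (compartments[c] == 1)
          + rng.normal(0, 0.005, len(compartments[c]))
          for c in config.chrom_lengths}

    pairing = {}
    for c in config.chrom_lengths:
        flag = np.zeros(binning.n_bins(c), bool)
        for bc, s, e, _f in config.pairing_blocks:
            if bc == c:
                flag[int(s // config.bin_size):int(np.ceil(e / config.bin_size))] = True
        pairing[c] = flag

    # Genes: uniform TSS placement, enhancer count drives both PEI truth and
    # expression level (more enhancers -> higher planted expression).
    gene_rows = []
    gid = 0
    for c, L in config.chrom_lengths.items():
        n_genes = max(1, int(round(L / 1e6 * config.genes_per_mb)))
        tss = np.sort(rng.choice(max(L - 20_000, 1), size=min(n_genes, max(L - 20_000, 1)),
                                 replace=False))
        for t in tss:
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(2_000, 20_000))
            start, end = (t, min(t + glen, L)) if strand == "+" else (max(t - glen, 0), t + 1)
            gene_rows.append((f"gene_{gid:05d}", c, int(start), int(end), int(t), strand))
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["gene", "chrom", "start", "end", "tss", "strand"])

    if config.pei_truth:
        pei = [tuple(p) for p in config.pei_truth]
        for c, pb, eb, f in pei:
            nb = binning.n_bins(c)
            if not (0 <= pb < nb and 0 <= eb < nb):
                raise ConfigurationError(f"PEI ({c},{pb},{eb}) out of range")
            if f < 1:
                raise ConfigurationError("PEI fold must be >= 1")
    else:
        pei = []
        for c in config.chrom_lengths:
            nb = binning.n_bins(c)
            cg = genes[genes.chrom == c]
            if cg.empty or nb < 5:
                continue
            pick = cg.sample(n=min(config.n_pei_per_chrom, len(cg)),
                             random_state=int(rng.integers(2**31)))
            for t in pick.tss:
                pb = int(t // config.bin_size)
                # enhancer 25 kb - 300 kb away, within the chromosome
                off = int(rng.integers(max(25_000 // config.bin_size, 2),
                                       max(300_000 // config.bin_size, 3)))
                eb = pb + off if pb + off < nb else pb - off
                if 0 <= eb < nb and eb != pb:
                    pei.append((c, pb, eb, float(config.pei_fold)))

    n_enh = genes.apply(
        lambda g: sum(1 for (c, pb, _e, _f) in pei
                      if c == g.chrom and pb == int(g.tss // config.bin_size)), axis=1)
    genes["n_enhancers"] = n_enh.astype(int)

    base = np.exp(rng.normal(np.log(50), 0.8, len(genes))) * (1.0 + 0.8 * genes.n_enhancers)
    eff = rng.random(len(genes)) < config.breed_effect_fraction
    expression = pd.DataFrame({
        "gene": genes.gene,
        "base_mean": base,
        "breed_effect_fold": np.where(eff, config.breed_effect_fold, 1.0),
        "favored_breed": np.where(eff, config.hap_breeds[0], "none"),
    })

    # Two-population site frequencies (Balding-Nichols around a common ancestral
    # frequency, per-site target FST).
    f = np.broadcast_to(np.asarray(config.fst_target, float), (config.n_pop_sites,)).copy()
    anc = rng.uniform(0.1, 0.9, config.n_pop_sites)
    with np.errstate(divide="ignore"):
        a = anc * (1 - f) / np.maximum(f, 1e-12)
        b = (1 - anc) * (1 - f) / np.maximum(f, 1e-12)
    p1 = np.where(f > 0, rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9)), anc)
    p2 = np.where(f > 0, rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9)), anc)
    chrom0 = next(iter(config.chrom_lengths))
    pop = pd.DataFrame({
        "CHROM": chrom0,
        "POS": np.sort(rng.choice(config.chrom_lengths[chrom0],
                                  size=min(config.n_pop_sites, config.chrom_lengths[chrom0]),
                                  replace=False)),
        "p_pop1": p1[:min(config.n_pop_sites, config.chrom_lengths[chrom0])],
        "p_pop2": p2[:min(config.n_pop_sites, config.chrom_lengths[chrom0])],
        "target_fst": f[:min(config.n_pop_sites, config.chrom_lengths[chrom0])],
    })

    return SyntheticTruth(config, variants, compartments, tad_truth, tad_domains,
                          gc, pairing, pei, genes, expression, pop)


def _cis_weight_matrix(truth: SyntheticTruth, chrom: str) -> np.ndarray:
    """Upper-triangular bin-pair weights: decay x checkerboard x TAD x PEI."""
    config = truth.config
    n = config.binning.n_bins(chrom)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    dist_bp = np.maximum(d, 0.5) * config.bin_size
    w = dist_bp ** config.decay_exponent

    lab = truth.compartment_truth[chrom]
    w *= np.where(lab[:, None] == lab[None, :], config.compartment_strength, 1.0)
    dom = np.full(n, -1)
    for k, (a, b) in enumerate(truth.tad_domains[chrom]):
        dom[a:b] = k
    same = (dom[:, None] == dom[None, :]) & (dom[:, None] >= 0)
    w *= np.where(same, config.tad_strength, 1.0)
    for c, pb, eb, f in truth.pei_truth:
        if c == chrom:
            w[pb, eb] *= f
            w[eb, pb] *= f
    # uniform random-ligation floor
    w = (1 - config.random_ligation_fraction) * w / w.sum() \
        + config.random_ligation_fraction / w.size
    return np.triu(w)


def _trans_weight_matrix(truth: SyntheticTruth, chrom: str) -> np.ndarray:
    """Inter-homolog weights: decay plus elevated aligned-diagonal pairing blocks."""
    config = truth.config
    n = config.binning.n_bins(chrom)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    w = (np.maximum(d, 0.5) * config.bin_size) ** config.decay_exponent
    paired = truth.pairing_truth[chrom]
    for c, s, e, f in config.pairing_blocks:
        if c != chrom:
            continue
        a, b = int(s // config.bin_size), int(np.ceil(e / config.bin_size))
        block = np.zeros(n, bool)
        block[a:b] = True
        near = d <= 2
        w[np.ix_(block, block)] = np.where(near[np.ix_(block, block)],
                                           w[np.ix_(block, block)] * f,
                                           w[np.ix_(block, block)])
    _ = paired
    return w / w.sum()


def _sample_pairs(w: np.ndarray, n: int, rng: np.random.Generator,
                  symmetric_upper: bool) -> tuple:
    flat = w.ravel()
    flat = flat / flat.sum()
    counts = rng.multinomial(n, flat)
    nz = np.nonzero(counts)[0]
    reps = counts[nz]
    i, j = np.unravel_index(nz, w.shape)
    i = np.repeat(i, reps)
    j = np.repeat(j, reps)
    if symmetric_upper:
        swap = rng.random(len(i)) < 0.5
        i2 = np.where(swap, j, i)
        j2 = np.where(swap, i, j)
        return i2, j2
    return i, j


def _positions_in_bins(bins: np.ndarray, config: SimConfig, chrom: str,
                       rng: np.random.Generator) -> np.ndarray:
    starts = bins * config.bin_size
    ends = np.minimum(starts + config.bin_size, config.chrom_lengths[chrom])
    return starts + (rng.random(len(bins)) * (ends - starts)).astype(np.int64)


def _votes_for_ends(pos: np.ndarray, true_hap: np.ndarray, snv_pos: np.ndarray,
                    config: SimConfig, rng: np.random.Generator) -> tuple:
    """Count haplotype votes on each read end (span = read_span bp)."""
    lo = np.searchsorted(snv_pos, pos)
    hi = np.searchsorted(snv_pos, pos + config.read_span)
    n_votes = hi - lo
    flips = rng.binomial(n_votes, config.vote_error)
    correct = n_votes - flips
    v_h1 = np.where(true_hap == HAP1, correct, flips)
    v_h2 = np.where(true_hap == HAP2, correct, flips)
    return v_h1.astype(np.int32), v_h2.astype(np.int32)


def simulate_contacts(truth: SyntheticTruth, config: SimConfig = None) -> pd.DataFrame:
    """Draw allele-informative contact records.

    Returns a table with one row per read pair: chrom/pos of both ends,
    per-end haplotype vote counts (v{1,2}_h{1,2}) and the true haplotype
    labels (true1, true2; 1 or 2). Intra-haplotype, inter-homolog and
    heterolog classes are drawn in the configured proportions.
    """
    config = config or truth.config
    if config.n_contacts <= 0:
        raise ConfigurationError("n_contacts must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    binning = config.binning

    lengths = np.array([config.chrom_lengths[c] for c in config.chrom_lengths], float)
    chrom_names = list(config.chrom_lengths)
    n_het = int(round(config.n_contacts * config.heterolog_fraction))
    n_trans = int(round(config.n_contacts * config.inter_homolog_fraction))
    n_cis = config.n_contacts - n_het - n_trans
    per_chrom_cis = rng.multinomial(n_cis, lengths / lengths.sum())
    per_chrom_trans = rng.multinomial(n_trans, lengths / lengths.sum())

    snv_by_chrom = {
        c: np.asarray(truth.variant_table.loc[truth.variant_table.CHROM == c, "POS"])
        for c in chrom_names}

    frames = []
    for ci, chrom in enumerate(chrom_names):
        snvs = snv_by_chrom[chrom]
        nc = per_chrom_cis[ci]
        if nc:
            w = _cis_weight_matrix(truth, chrom)
            bi, bj = _sample_pairs(w, nc, rng, symmetric_upper=True)
            hap = np.where(rng.random(nc) < 0.5, HAP1, HAP2).astype(np.int8)
            p1 = _positions_in_bins(bi, config, chrom, rng)
            p2 = _positions_in_bins(bj, config, chrom, rng)
            v1h1, v1h2 = _votes_for_ends(p1, hap, snvs, config, rng)
            v2h1, v2h2 = _votes_for_ends(p2, hap, snvs, config, rng)
            frames.append(pd.DataFrame({
                "chrom1": chrom, "pos1": p1, "chrom2": chrom, "pos2": p2,
                "v1_h1": v1h1, "v1_h2": v1h2, "v2_h1": v2h1, "v2_h2": v2h2,
                "true1": hap, "true2": hap}))
        nt = per_chrom_trans[ci]
        if nt:
            w = _trans_weight_matrix(truth, chrom)
            bi, bj = _sample_pairs(w, nt, rng, symmetric_upper=False)
            p1 = _positions_in_bins(bi, config, chrom, rng)
            p2 = _positions_in_bins(bj, config, chrom, rng)
            h1 = np.full(nt, HAP1, np.int8)
            h2 = np.full(nt, HAP2, np.int8)
            v1h1, v1h2 = _votes_for_ends(p1, h1, snvs, config, rng)
            v2h1, v2h2 = _votes_for_ends(p2, h2, snvs, config, rng)
            frames.append(pd.DataFrame({
                "chrom1": chrom, "pos1": p1, "chrom2": chrom, "pos2": p2,
                "v1_h1": v1h1, "v1_h2": v1h2, "v2_h1": v2h1, "v2_h2": v2h2,
                "true1": h1, "true2": h2}))
    if n_het and len(chrom_names) > 1:
        c1 = rng.integers(0, len(chrom_names), n_het)
        c2 = (c1 + rng.integers(1, len(chrom_names), n_het)) % len(chrom_names)
        rows = {"chrom1": [], "pos1": [], "chrom2": [], "pos2": []}
        p1 = np.empty(n_het, np.int64)
        p2 = np.empty(n_het, np.int64)
        for k in range(n_het):
            p1[k] = rng.integers(0, config.chrom_lengths[chrom_names[c1[k]]])
            p2[k] = rng.integers(0, config.chrom_lengths[chrom_names[c2[k]]])
        h1 = np.where(rng.random(n_het) < 0.5, HAP1, HAP2).astype(np.int8)
        h2 = np.where(rng.random(n_het) < 0.5, HAP1, HAP2).astype(np.int8)
        v1h1 = np.empty(n_het, np.int32); v1h2 = np.empty(n_het, np.int32)
        v2h1 = np.empty(n_het, np.int32); v2h2 = np.empty(n_het, np.int32)
        for k in range(n_het):
            a, b = _votes_for_ends(p1[k:k + 1], h1[k:k + 1],
                                   snv_by_chrom[chrom_names[c1[k]]], config, rng)
            v1h1[k], v1h2[k] = a[0], b[0]
            a, b = _votes_for_ends(p2[k:k + 1], h2[k:k + 1],
                                   snv_by_chrom[chrom_names[c2[k]]], config, rng)
            v2h1[k], v2h2[k] = a[0], b[0]
        frames.append(pd.DataFrame({
            "chrom1": [chrom_names[i] for i in c1], "pos1": p1,
            "chrom2": [chrom_names[i] for i in c2], "pos2": p2,
            "v1_h1": v1h1, "v1_h2": v1h2, "v2_h1": v2h1, "v2_h2": v2h2,
            "true1": h1, "true2": h2}))
    out = pd.concat(frames, ignore_index=True)
    _ = binning
    return out


def simulate_matrix(truth: SyntheticTruth, chrom: str, n_contacts: int = None,
                    rng: np.random.Generator = None, trans: bool = False) -> np.ndarray:
    """Draw a binned count matrix for one chromosome directly in matrix space.

    Skips the read-level vote layer; counts are Poisson around the same
    planted-structure weight field used by :func:`simulate_contacts`. Use for
    stages downstream of phasing where per-read evidence is irrelevant.
    """
    config = truth.config
    n_contacts = n_contacts or config.n_contacts
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence([config.seed, 2]))
    if trans:
        w = _trans_weight_matrix(truth, chrom)
        lam = w * n_contacts
        m = rng.poisson(lam).astype(float)
        return (m + m.T) / 2.0
    w = _cis_weight_matrix(truth, chrom)
    w = w + np.triu(w, 1).T  # symmetric field
    lam = w / w.sum() * n_contacts
    m = np.triu(rng.poisson(lam)).astype(float)
    return m + np.triu(m, 1).T


@dataclass
class SimulatedOmics:
    """Allelic expression counts plus two-population genotypes."""

    gene_counts: pd.DataFrame   # gene, sample, stage, cross, replicate,
                                # maternal_count, paternal_count,
                                # maternal_breed, paternal_breed, tpm
    snv_counts: pd.DataFrame    # CHROM POS gene sample hap1_count hap2_count
                                # (hap1 = maternal)
    genotypes: dict             # pop -> (sites x individuals) alt-allele dosage
    site_table: pd.DataFrame    # CHROM POS p_pop1 p_pop2 target_fst


def simulate_expression_and_population(truth: SyntheticTruth,
                                       config: SimConfig = None) -> SimulatedOmics:
    """Draw allelic expression for a reciprocal-cross design plus genotypes.

    Planted effects are breed effects only: the favored breed's haplotype gets
    ``breed_effect_fold`` more reads regardless of which parent carried it, so
    a correct parent-of-origin screen must classify these genes as breed
    effects, never as imprinting.
    """
    config = config or truth.config
    if config.expression_depth < 0:
        raise ConfigurationError("negative depth")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    genes = truth.gene_table.merge(truth.expression_truth, on="gene")

    rows = []
    snv_rows = []
    var = truth.variant_table
    snv_pos = {c: np.asarray(var.loc[(var.CHROM == c) & (~var.is_indel), "POS"])
               for c in config.chrom_lengths}
    for cross in CROSSES:
        sire, dam = ("broiler", "layer") if cross == "BxL" else ("layer", "broiler")
        for rep in range(config.n_replicates):
            sample = f"{config.stage}_{cross}_r{rep + 1}"
            mat_breed, pat_breed = dam, sire   # maternal haplotype from the dam
            depth = rng.poisson(np.maximum(genes.base_mean / genes.base_mean.mean()
                                           * config.expression_depth, 0.0))
            fold = genes.breed_effect_fold.to_numpy()
            fav = genes.favored_breed.to_numpy()
            mat_w = np.where(fav == mat_breed, fold, 1.0)
            pat_w = np.where(fav == pat_breed, fold, 1.0)
            p_mat = mat_w / (mat_w + pat_w)
            mat = rng.binomial(depth, p_mat)
            pat = depth - mat
            tpm = depth / max(depth.sum(), 1) * 1e6 / 1000.0  # nominal per-kb scale
            for g, m, p, t in zip(genes.itertuples(), mat, pat, tpm):
                rows.append((g.gene, sample, config.stage, cross, rep + 1,
                             int(m), int(p), mat_breed, pat_breed, float(t)))
                # distribute the gene's reads over its exonic SNVs
                sp = snv_pos[g.chrom]
                in_gene = sp[(sp >= g.start) & (sp < g.end)]
                if len(in_gene) and (m + p) > 0:
                    alloc_m = rng.multinomial(m, np.full(len(in_gene), 1 / len(in_gene)))
                    alloc_p = rng.multinomial(p, np.full(len(in_gene), 1 / len(in_gene)))
                    for pos, am, ap in zip(in_gene, alloc_m, alloc_p):
                        snv_rows.append((g.chrom, int(pos), g.gene, sample,
                                         int(am), int(ap)))
    gene_counts = pd.DataFrame(rows, columns=[
        "gene", "sample", "stage", "cross", "replicate", "maternal_count",
        "paternal_count", "maternal_breed", "paternal_breed", "tpm"])
    snv_counts = pd.DataFrame(snv_rows, columns=[
        "CHROM", "POS", "gene", "sample", "hap1_count", "hap2_count"])

    st = truth.population_freq_truth
    genotypes = {
        "pop1": rng.binomial(2, st.p_pop1.to_numpy()[:, None],
                             (len(st), config.n_per_pop)),
        "pop2": rng.binomial(2, st.p_pop2.to_numpy()[:, None],
                             (len(st), config.n_per_pop)),
    }
    return SimulatedOmics(gene_counts, snv_counts, genotypes, st.copy())
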