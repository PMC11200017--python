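"""Sequence divergence between haplotypes and between populations.

The identity score (IDS) is the fraction of identical nucleotides between
the two haplotypes of a region, counting every differing SNV site as one
mismatched base and every indel by its length clipped to the region
(insertions contribute their inserted length at the anchor point).

Population differentiation uses the Weir-Cockerham (1984) variance-
components estimator of FST per site; sites with FST >= 0.75 form the
high-FST screen, whose enhancer-variant enrichment report follows the
regulatory-divergence analysis: genes whose enhancers carry high-FST
variants are compared with the remaining genes for |delta RPS|, membership
in the differential-RPS set, enhancer count (redundancy), and expression
differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

HIGH_FST = 0.75


def identity_score(region_start: int, region_end: int,
                   variants: pd.DataFrame) -> float:
    """IDS of [region_start, region_end) given inter-haplotype variants.

    ``variants`` needs POS, is_indel and indel_len columns (SNVs have
    indel_len 0); only variants differing between the haplotypes should be
    supplied. Indels are counted by their length overlapping the region;
    the result is floored at 0.
    """
    length = region_end - region_start
    if length <= 0:
        raise ValueError("region length must be > 0")
    if len(variants) == 0:
        return 1.0
    pos = variants.POS.to_numpy()
    is_indel = variants.is_indel.to_numpy().astype(bool)
    ilen = variants.indel_len.to_numpy()
    mism = 0.0
    snv_in = (~is_indel) & (pos >= region_start) & (pos < region_end)
    mism += int(snv_in.sum())
    for p, L in zip(pos[is_indel], ilen[is_indel]):
        lo = max(p, region_start)
        hi = min(p + L, region_end)
        if hi > lo:
            mism += hi - lo
    return max(1.0 - mism / length, 0.0)


def weir_cockerham_fst(genotypes_a: np.ndarray,
                       genotypes_b: np.ndarray) -> np.ndarray:
    """Per-site Weir-Cockerham theta for two diploid populations.

    Inputs are (sites x individuals) alt-allele dosage matrices (0/1/2;
    negative = missing). Monomorphic sites and sites with an empty
    population are NaN. The estimator can be slightly negative.
    """
    ga = np.asarray(genotypes_a, float)
    gb = np.asarray(genotypes_b, float)
    if ga.shape[0] != gb.shape[0]:
        raise ValueError("site dimension mismatch")
    r = 2.0
    out = np.full(ga.shape[0], np.nan)

    def summarize(g):
        called = g >= 0
        n = called.sum(1).astype(float)              # diploid individuals
        with np.errstate(invalid="ignore"):
            p = np.where(n > 0, np.where(called, g, 0).sum(1) / (2 * n), np.nan)
            h = np.where(n > 0, np.where(called, g == 1, False).sum(1) / n, np.nan)
        return n, p, h

    na, pa, ha = summarize(ga)
    nb, pb, hb = summarize(gb)
    ok = (na > 0) & (nb > 0)
    n_bar = (na + nb) / r
    nc = (r * n_bar - (na ** 2 + nb ** 2) / (r * n_bar)) / (r - 1)
    p_bar = (na * pa + nb * pb) / (r * n_bar)
    s2 = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (na * ha + nb * hb) / (r * n_bar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2
                                  - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2
                                     - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar)
        c = h_bar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    mono = (p_bar <= 0) | (p_bar >= 1)
    out[ok & ~mono] = theta[ok & ~mono]
    return out


@dataclass
class EnrichmentReport:
    """High-FST enhancer-variant enrichment across five figure-wise tests."""

    n_with: int
    n_without: int
    delta_rps_test: dict        # Wilcoxon of |delta RPS|
    differential_fisher: dict   # 2x2 of high-FST x differential-RPS membership
    redundancy_test: dict       # Wilcoxon of enhancer counts per gene
    expression_test: dict       # Wilcoxon of |expression differences|
    warnings: list


def high_fst_enrichment(gene_table: pd.DataFrame,
                        fst_threshold: float = HIGH_FST) -> EnrichmentReport:
    """Partition genes by high-FST enhancer variants and run the report.

    ``gene_table`` has one row per gene with columns:
    ``max_enhancer_fst`` (max FST over variants in the gene's enhancers;
    NaN if none), ``abs_delta_rps``, ``is_differential_rps`` (bool),
    ``n_enhancers`` and optionally ``abs_expr_diff``. Sites at exactly the
    threshold count as high-FST. Each of the four comparisons is reported
    raw (no cross-test correction).
    """
    fstv = gene_table.max_enhancer_fst.fillna(-np.inf)
    has = fstv >= fst_threshold
    with_g = gene_table[has]
    without_g = gene_table[~has]
    warnings = []

    def wilcox(col):
        if len(with_g) == 0 or len(without_g) == 0:
            return None
        a, b = with_g[col].dropna(), without_g[col].dropna()
        if len(a) == 0 or len(b) == 0:
            return None
        res = stats.ranksums(a, b)
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
                "median_with": float(a.median()), "median_without": float(b.median())}

    if len(with_g) == 0 or len(without_g) == 0:
        warnings.append("one partition is empty; tests skipped")
        return EnrichmentReport(int(has.sum()), int((~has).sum()),
                                None, None, None, None, warnings)

    fisher = None
    if "is_differential_rps" in gene_table.columns:
        t = np.array([
            [int((with_g.is_differential_rps).sum()),
             int((~with_g.is_differential_rps.astype(bool)).sum())],
            [int((without_g.is_differential_rps).sum()),
             int((~without_g.is_differential_rps.astype(bool)).sum())]])
        odds, p = stats.fisher_exact(t)
        fisher = {"table": t, "odds_ratio": float(odds), "p_value": float(p)}

    return EnrichmentReport(
        int(has.sum()), int((~has).sum()),
        wilcox("abs_delta_rps"), fisher, wilcox("n_enhancers"),
        wilcox("abs_expr_diff") if "abs_expr_diff" in gene_table.columns else None,
        warnings)
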