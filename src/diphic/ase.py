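"""Allele-specific expression and the reciprocal-cross imprinting screen.

SNV-level allelic read counts are aggregated to genes over their exonic
phased heterozygous sites, tested for allelic bias with a two-sided
binomial test against 0.5 (BH-FDR, plus a ratio window so tiny but
significant deviations at high depth are not called biased), and screened
for parent-of-origin effects. The reciprocal-cross design separates
imprinting from breed effects: a genuinely imprinted gene favors the same
parental role (maternal or paternal) in both cross directions, whereas a
cis-regulatory breed effect follows the breed of the haplotype and
therefore switches parental role between the two directions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

MIN_TPM = 0.5          # expressed if TPM >= 0.5 in at least one sample
MIN_TOTAL = 20         # informative reads needed to test a gene
RATIO_WINDOW = (0.3, 0.7)


def gene_allelic_counts(snv_counts: pd.DataFrame,
                        gene_model: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-SNV haplotype counts to genes.

    ``snv_counts``: CHROM POS hap1_count hap2_count (optionally sample).
    ``gene_model``: gene chrom start end. SNVs falling in two overlapping
    genes count for both (flagged). Genes without informative exonic SNVs
    appear with zero counts and ``n_snvs = 0`` (untestable downstream).
    """
    group_cols = ["sample"] if "sample" in snv_counts.columns else []
    rows = []
    for g in gene_model.itertuples():
        on = snv_counts[(snv_counts.CHROM == g.chrom)
                        & (snv_counts.POS >= g.start)
                        & (snv_counts.POS < g.end)]
        if group_cols:
            for sample, grp in on.groupby("sample"):
                rows.append((g.gene, sample, int(grp.hap1_count.sum()),
                             int(grp.hap2_count.sum()), len(grp)))
        else:
            rows.append((g.gene, None, int(on.hap1_count.sum()),
                         int(on.hap2_count.sum()), len(on)))
    cols = ["gene", "sample", "hap1_count", "hap2_count", "n_snvs"]
    out = pd.DataFrame(rows, columns=cols)
    if not group_cols:
        out = out.drop(columns=["sample"])
    # flag SNVs claimed by more than one gene
    dup = 0
    for g1 in gene_model.itertuples():
        for g2 in gene_model.itertuples():
            if g1.gene < g2.gene and g1.chrom == g2.chrom \
                    and g1.start < g2.end and g2.start < g1.end:
                dup += 1
    if dup:
        log.warning("%d overlapping gene pairs: shared SNVs counted for both", dup)
    return out


def allelic_bias_test(table: pd.DataFrame, min_total: int = MIN_TOTAL,
                      fdr: float = 0.05, min_tpm: float = MIN_TPM) -> pd.DataFrame:
    """Two-sided binomial test of hap1 fraction against 0.5, BH-corrected.

    A gene is *biased* when q < fdr and its allelic ratio falls outside the
    [0.3, 0.7] window; *untestable* when its total informative count is
    below ``min_total``, it has no informative SNVs, or (when a ``tpm``
    column is present) it never reaches ``min_tpm`` in any sample.
    """
    out = table.copy()
    total = out.hap1_count + out.hap2_count
    out["total"] = total
    out["ratio"] = np.where(total > 0, out.hap1_count / np.maximum(total, 1), np.nan)
    expressed = pd.Series(True, index=out.index)
    if "tpm" in out.columns:
        if "gene" in out.columns:
            max_tpm = out.groupby("gene").tpm.transform("max")
        else:
            max_tpm = out.tpm
        expressed = max_tpm >= min_tpm
    testable = (total >= min_total) & expressed
    if "n_snvs" in out.columns:
        testable &= out.n_snvs > 0
    p = np.ones(len(out))
    idx = np.where(testable)[0]
    for k in idx:
        p[k] = stats.binomtest(int(out.hap1_count.iloc[k]),
                               int(total.iloc[k]), 0.5).pvalue
    out["p"] = p
    q = np.ones(len(out))
    if len(idx):
        q[idx] = multipletests(p[idx], method="fdr_bh")[1]
    out["q"] = q
    lo, hi = RATIO_WINDOW
    biased = testable & (out.q < fdr) & ((out.ratio < lo) | (out.ratio > hi))
    out["category"] = np.where(~testable, "untestable",
                               np.where(biased,
                                        np.where(out.ratio > 0.5, "hap1", "hap2"),
                                        "biallelic"))
    return out


def imprinting_screen(sample_tables: pd.DataFrame, min_total: int = MIN_TOTAL,
                      fdr: float = 0.05) -> pd.DataFrame:
    """Classify biased genes as imprinting candidates or breed effects.

    ``sample_tables`` is a long table with one row per gene x sample:
    columns gene, sample, cross (direction), maternal_count, paternal_count,
    maternal_breed, paternal_breed and optionally tpm. Both cross directions
    must be present. Within each direction, counts are pooled over samples
    and tested for maternal bias; a gene is an *imprinting candidate* when
    significantly biased toward the same parental role in both directions,
    and a *breed effect* when biased toward the same breed in both
    directions.
    """
    crosses = sorted(sample_tables.cross.unique())
    if len(crosses) < 2:
        raise ValueError("both reciprocal cross directions are required")

    per_dir = {}
    for cross, grp in sample_tables.groupby("cross"):
        pooled = grp.groupby("gene", as_index=False).agg(
            hap1_count=("maternal_count", "sum"),
            hap2_count=("paternal_count", "sum"),
            maternal_breed=("maternal_breed", "first"),
            paternal_breed=("paternal_breed", "first"),
            **({"tpm": ("tpm", "max")} if "tpm" in grp.columns else {}))
        tested = allelic_bias_test(pooled, min_total=min_total, fdr=fdr)
        per_dir[cross] = tested.set_index("gene")

    genes = sorted(set.intersection(*(set(t.index) for t in per_dir.values())))
    rows = []
    for g in genes:
        roles, breeds = [], []
        for cross in crosses:
            row = per_dir[cross].loc[g]
            if row.category == "hap1":        # maternal-biased
                roles.append("maternal")
                breeds.append(row.maternal_breed)
            elif row.category == "hap2":      # paternal-biased
                roles.append("paternal")
                breeds.append(row.paternal_breed)
            else:
                roles.append(None)
                breeds.append(None)
        if all(r is not None for r in roles):
            if len(set(breeds)) == 1:
                cls = "breed_effect"
            elif len(set(roles)) == 1:
                cls = "imprinting_candidate"
            else:
                cls = "inconsistent"
        else:
            cls = "not_biased"
        rows.append((g, roles[0], breeds[0], cls))
    return pd.DataFrame(rows, columns=["gene", "role_forward", "breed_forward",
                                       "classification"])
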