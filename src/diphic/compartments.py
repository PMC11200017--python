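"""A/B compartment calling and three-axis differential classification.

Compartments are called per chromosome from the first principal component
of the Pearson correlation matrix of the observed/expected-transformed
balanced contact map. The eigenvector sign is arbitrary, so each
chromosome's component is oriented against an external covariate (gene
density or GC content, both higher in active A chromatin). The
concatenated genome-wide track is scaled to unit standard deviation — the
"A-B index" — which makes the printed differential thresholds (|delta| > 1
between neighboring stages, > 0.3 between breeds or parents of origin)
scale-meaningful. Positive index = A, negative = B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

AXIS_THRESHOLDS = {"stage": 1.0, "breed": 0.3, "parent": 0.3}
MIN_SWITCH_MAGNITUDE = 0.1   # |mean index| required on both sides of a switch


@dataclass
class CompartmentProfile:
    """Genome-wide A-B index (SD = 1) with per-chromosome metadata."""

    index: dict          # chrom -> per-bin A-B index (NaN on masked bins)
    labels: dict         # chrom -> per-bin label: +1 (A), -1 (B), 0 masked
    metadata: dict       # chrom -> {pc_used, covariate_r}
    bin_size: int

    def genome_values(self):
        return np.concatenate([v[~np.isnan(v)] for v in self.index.values()])


@dataclass
class CompartmentDiff:
    """Bins/regions with switched or variable compartment status."""

    per_bin: dict        # chrom -> DataFrame-like dict of arrays
    regions: list        # (chrom, start_bin, end_bin, class, mean_delta)
    axis: str
    threshold: float

    def total_mb(self, cls: str, bin_size: int) -> float:
        n = sum(e - s for c, s, e, k, d in self.regions if k == cls)
        return n * bin_size / 1e6


def _oe_transform(matrix: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    oe = np.zeros_like(matrix, dtype=float)
    for d in range(n):
        diag = np.diagonal(matrix, d)
        mu = diag.mean()
        if mu > 0:
            vals = diag / mu
            idx = np.arange(n - d)
            oe[idx, idx + d] = vals
            oe[idx + d, idx] = vals
    return oe


def ab_index_chromosome(matrix: np.ndarray, covariate: np.ndarray,
                        min_bins: int = 10) -> tuple:
    """Unscaled compartment eigenvector for one chromosome.

    Returns (track, pc_used, covariate_r) or None when the chromosome has
    fewer than ``min_bins`` usable bins. If PC1 tracks the covariate weakly
    (|r| < 0.2, typically an arm-level signal), PC2 is substituted.
    """
    m = np.asarray(matrix, float)
    usable = m.sum(1) > 0
    if usable.sum() < min_bins:
        return None
    sub = m[np.ix_(usable, usable)]
    oe = _oe_transform(sub)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    cov = np.asarray(covariate, float)[usable]

    pc_used, vec, r = 1, vecs[:, order[0]], 0.0
    r = _safe_corr(vecs[:, order[0]], cov)
    if abs(r) < 0.2 and len(order) > 1:
        r2 = _safe_corr(vecs[:, order[1]], cov)
        if abs(r2) > abs(r):
            pc_used, r = 2, r2
            vec = vecs[:, order[1]]
    if r < 0:
        vec = -vec
        r = -r
    track = np.full(m.shape[0], np.nan)
    track[usable] = vec
    return track, pc_used, float(r)


def _safe_corr(a, b):
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def ab_index(matrices: dict, covariates: dict, bin_size: int,
             min_bins: int = 10) -> CompartmentProfile:
    """Genome-wide A-B index from balanced intra-haplotype matrices.

    ``matrices``/``covariates`` map chromosome -> per-chromosome inputs.
    Chromosomes with fewer than ``min_bins`` usable bins are skipped with a
    warning. The concatenated index is scaled to genome-wide SD 1.
    """
    index, labels, meta = {}, {}, {}
    for chrom, m in matrices.items():
        res = ab_index_chromosome(m, covariates[chrom], min_bins)
        if res is None:
            log.warning("chromosome %s has <%d usable bins; skipped", chrom, min_bins)
            index[chrom] = np.full(np.asarray(m).shape[0], np.nan)
            labels[chrom] = np.zeros(np.asarray(m).shape[0], int)
            meta[chrom] = {"pc_used": None, "covariate_r": None}
            continue
        track, pc, r = res
        index[chrom] = track
        meta[chrom] = {"pc_used": pc, "covariate_r": r}
    allv = np.concatenate([v[~np.isnan(v)] for v in index.values()])
    sd = allv.std()
    if sd > 0:
        for chrom in index:
            index[chrom] = index[chrom] / sd
    for chrom, v in index.items():
        lab = np.zeros(len(v), int)
        lab[v > 0] = 1
        lab[v < 0] = -1
        lab[np.isnan(v)] = 0
        labels[chrom] = lab
    return CompartmentProfile(index, labels, meta, bin_size)


def differential_compartments(profiles_a: list, profiles_b: list,
                              axis: str, threshold: float = None,
                              alpha: float = 0.05) -> CompartmentDiff:
    """Classify bins as compartment-switched or compartment-variable.

    ``profiles_a``/``profiles_b`` are paired replicate lists (same length,
    same order). Per bin: delta = mean(A) - mean(B); *switched* when the two
    group means carry opposite signs (both above a small magnitude floor);
    *variable* when signs agree, |delta| exceeds the axis threshold and the
    paired t-test rejects at ``alpha``. Adjacent same-class bins merge into
    regions.
    """
    if len(profiles_a) != len(profiles_b) or not profiles_a:
        raise ValueError("paired replicate lists required")
    if len(profiles_a) < 2:
        raise ValueError("need >=2 paired replicates for the paired t-test")
    threshold = AXIS_THRESHOLDS[axis] if threshold is None else threshold
    chroms = list(profiles_a[0].index)
    per_bin = {}
    regions = []
    for chrom in chroms:
        A = np.vstack([p.index[chrom] for p in profiles_a])
        B = np.vstack([p.index[chrom] for p in profiles_b])
        ok = ~(np.isnan(A).any(0) | np.isnan(B).any(0))
        ma, mb = A.mean(0), B.mean(0)
        delta = ma - mb
        diffs = A - B
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_rel(A, B, axis=0)
        p = np.where(np.isnan(p), 1.0, p)
        switched = ok & (np.sign(ma) != np.sign(mb)) \
            & (np.abs(ma) > MIN_SWITCH_MAGNITUDE) & (np.abs(mb) > MIN_SWITCH_MAGNITUDE)
        variable = ok & ~switched & (np.sign(ma) == np.sign(mb)) \
            & (np.abs(delta) > threshold) & (p < alpha)
        per_bin[chrom] = {"delta": delta, "p": p, "switched": switched,
                          "variable": variable, "mean_a": ma, "mean_b": mb}
        _ = diffs
        for cls, flags in (("switched", switched), ("variable", variable)):
            for s, e in _runs(flags):
                regions.append((chrom, s, e, cls, float(delta[s:e].mean())))
    return CompartmentDiff(per_bin, regions, axis, threshold)


def _runs(flags: np.ndarray):
    out = []
    start = None
    for k, f in enumerate(flags):
        if f and start is None:
            start = k
        elif not f and start is not None:
            out.append((start, k))
            start = None
    if start is not None:
        out.append((start, len(flags)))
    return out
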