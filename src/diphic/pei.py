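"""Promoter-enhancer interaction calling and regulatory potential scores.

PEIs are promoter-anchored contacts enriched over a domain-aware
distance-decay background: contacts decay faster across TAD boundaries than
within a TAD, so the expected model fits one power law per TAD (falling
back to a genome-wide background for sparse domains and inter-domain
pairs). Candidate promoter-enhancer bin pairs between 25 kb and 1 Mb are
tested with a Poisson upper tail against the expected count and controlled
by Benjamini-Hochberg FDR.

The regulatory potential score (RPS) of a gene aggregates its PEIs:
RPS = log2(1 + sum of max(O/E - 1, 0)), monotone in enhancer count and
intensity, zero for genes without PEIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

MIN_DISTANCE_BP = 25_000
MAX_DISTANCE_BP = 1_000_000
AXIS_THRESHOLDS = {"stage": 3.0, "breed": 0.3, "parent": 0.3}


@dataclass
class ExpectedModel:
    """Two-level distance-decay background for one chromosome."""

    background: tuple          # (intercept, slope) of log-log fit
    domain_fits: dict          # domain index -> (intercept, slope)
    domains: list              # (start_bin, end_bin)
    bin_size: int

    def expected(self, i, j) -> np.ndarray:
        i = np.atleast_1d(np.asarray(i))
        j = np.atleast_1d(np.asarray(j))
        d = np.abs(i - j).astype(float)
        d = np.maximum(d, 1.0)
        dom = np.full(i.shape, -1)
        for k, (a, b) in enumerate(self.domains):
            inside = (i >= a) & (i < b) & (j >= a) & (j < b)
            dom = np.where(inside, k, dom)
        out = np.empty(i.shape, float)
        bi, bs = self.background
        out[:] = np.exp(bi + bs * np.log(d))
        for k, (ik, sk) in self.domain_fits.items():
            sel = dom == k
            if sel.any():
                out[sel] = np.exp(ik + sk * np.log(d[sel]))
        return out[()] if out.shape == () else out


def fit_expected(matrix: np.ndarray, tads, bin_size: int,
                 min_pairs: int = 20) -> ExpectedModel:
    """Fit per-TAD power laws plus a genome-wide background.

    TADs with fewer than ``min_pairs`` positive pair observations fall back
    to the background fit. ``tads`` is a domain list or a TADPartition.
    """
    domains = getattr(tads, "domains", tads)
    m = np.asarray(matrix, float)
    n = m.shape[0]

    def loglog_fit(pairs_i, pairs_j):
        d = np.abs(pairs_i - pairs_j).astype(float)
        v = m[pairs_i, pairs_j]
        ok = (d >= 1) & (v > 0)
        if ok.sum() < 3:
            return None
        slope, intercept = np.polyfit(np.log(d[ok]), np.log(v[ok]), 1)
        return float(intercept), float(slope)

    iu, ju = np.triu_indices(n, 1)
    background = loglog_fit(iu, ju)
    if background is None:
        raise ValueError("matrix too sparse for a background fit")

    domain_fits = {}
    for k, (a, b) in enumerate(domains):
        di, dj = np.triu_indices(b - a, 1)
        di, dj = di + a, dj + a
        v = m[di, dj]
        if (v > 0).sum() < min_pairs:
            continue
        fit = loglog_fit(di, dj)
        if fit is not None:
            domain_fits[k] = fit
    return ExpectedModel(background, domain_fits, list(domains), bin_size)


def call_peis(matrix: np.ndarray, expected: ExpectedModel, promoter_bins,
              enhancer_candidate_bins, fdr: float = 0.05,
              min_distance_bp: int = MIN_DISTANCE_BP,
              max_distance_bp: int = MAX_DISTANCE_BP) -> pd.DataFrame:
    """Poisson-test promoter x candidate pairs against the expected model.

    ``promoter_bins`` maps gene -> promoter bin (genes whose promoter falls
    outside the binning are skipped with a warning). Returns the retained
    pairs with observed/expected intensities, O/E ratio, p and BH q-values.
    """
    m = np.asarray(matrix, float)
    n = m.shape[0]
    bs = expected.bin_size
    min_bins = int(np.ceil(min_distance_bp / bs))
    max_bins = int(max_distance_bp // bs)
    cand = np.asarray(sorted(set(int(c) for c in enhancer_candidate_bins)))

    rows = []
    for gene, pb in promoter_bins.items():
        if not (0 <= pb < n):
            log.warning("promoter of %s outside binning; skipped", gene)
            continue
        d = np.abs(cand - pb)
        ebs = cand[(d >= min_bins) & (d <= max_bins)]
        if not len(ebs):
            continue
        obs = m[pb, ebs]
        exp = expected.expected(np.full(len(ebs), pb), ebs)
        rows.extend((gene, int(pb), int(eb), float(o), float(e))
                    for eb, o, e in zip(ebs, obs, exp))
    if not rows:
        return _empty_pei_table()
    df = pd.DataFrame(rows, columns=["gene", "promoter_bin", "enhancer_bin",
                                     "observed", "expected"])
    df["oe"] = df.observed / np.maximum(df.expected, 1e-12)
    df["distance_bp"] = np.abs(df.enhancer_bin - df.promoter_bin) * bs
    # Poisson upper tail: P(X >= obs | lambda = expected)
    df["p"] = stats.poisson.sf(np.ceil(df.observed) - 1, df.expected)
    df["q"] = multipletests(df.p, method="fdr_bh")[1]
    kept = df[df.q <= fdr].reset_index(drop=True)
    return kept


def _empty_pei_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["gene", "promoter_bin", "enhancer_bin",
                                 "observed", "expected", "oe", "distance_bp",
                                 "p", "q"])


def compute_rps(gene: str, peis: pd.DataFrame, use_oe: bool = True) -> float:
    """Regulatory potential of one gene from its called PEIs.

    log2(1 + sum over PEIs of max(O/E - 1, 0)); with ``use_oe=False`` the
    raw observed intensities are summed instead.
    """
    sub = peis[peis.gene == gene] if len(peis) else peis
    if len(sub) == 0:
        return 0.0
    if use_oe:
        excess = np.maximum(sub.oe.to_numpy() - 1.0, 0.0)
    else:
        excess = sub.observed.to_numpy()
    return float(np.log2(1.0 + excess.sum()))


def rps_table(peis: pd.DataFrame, genes) -> pd.Series:
    """RPS for every gene in ``genes`` (0 when it has no PEIs)."""
    return pd.Series({g: compute_rps(g, peis) for g in genes}, name="rps")


def differential_rps(tables_a: list, tables_b: list, axis: str,
                     threshold: float = None, alpha: float = 0.05) -> pd.DataFrame:
    """Genes with axis-significant RPS differences between paired groups.

    ``tables_a``/``tables_b`` are paired lists of per-gene RPS Series.
    Flags genes with |mean paired delta| above the axis threshold (3 between
    neighboring stages, 0.3 between breeds or parents of origin) and paired
    t-test p < ``alpha``.
    """
    if len(tables_a) != len(tables_b) or len(tables_a) < 2:
        raise ValueError("need >=2 paired replicates per group")
    threshold = AXIS_THRESHOLDS[axis] if threshold is None else threshold
    genes = tables_a[0].index
    A = np.vstack([t.reindex(genes).to_numpy() for t in tables_a])
    B = np.vstack([t.reindex(genes).to_numpy() for t in tables_b])
    delta = (A - B).mean(0)
    d = A - B
    const = np.isclose(d.var(0), 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_rel(A, B, axis=0).pvalue
    p = np.where(const, np.where(np.abs(delta) > 0, 0.0, 1.0), p)
    p = np.where(np.isnan(p), 1.0, p)
    out = pd.DataFrame({"gene": genes, "delta_rps": delta, "p": p})
    out["flagged"] = (np.abs(out.delta_rps) > threshold) & (out.p < alpha)
    return out


def merge_stage_peis(pei_sets: list) -> pd.DataFrame:
    """Union same-stage PEI sets by (promoter bin, enhancer bin).

    Intensity becomes the mean O/E of the contributing samples; the number
    of contributing samples is kept as provenance.
    """
    frames = [df.assign(_src=k) for k, df in enumerate(pei_sets) if len(df)]
    if not frames:
        return _empty_pei_table().assign(n_samples=pd.Series(dtype=int))
    allp = pd.concat(frames, ignore_index=True)
    merged = (allp.groupby(["gene", "promoter_bin", "enhancer_bin"], as_index=False)
              .agg(observed=("observed", "mean"), expected=("expected", "mean"),
                   oe=("oe", "mean"), distance_bp=("distance_bp", "first"),
                   p=("p", "min"), q=("q", "min"), n_samples=("_src", "nunique")))
    return merged
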