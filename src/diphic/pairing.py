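"""Homolog pairing score and tightly-paired region calling.

The homolog pairing score (HPS) quantifies how strongly the two homologous
copies of a chromosome co-localize at each locus: it is the log2 ratio of
the local aligned-diagonal inter-homolog contact intensity to the
chromosome-wide mean of the same windowed statistic, so it is invariant to
overall sequencing depth. Tightly-paired loci are bins whose HPS exceeds
Q3 + 1.5 x IQR of the genome-wide distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class PairingTrack:
    chrom: str
    hps: np.ndarray          # per-bin HPS (NaN on masked bins)
    bin_size: int
    mask: np.ndarray         # True = usable bin


@dataclass
class TightRegionSet:
    """Merged intervals of tightly-paired bins (bin coordinates, half-open)."""

    regions: dict            # chrom -> list of (start_bin, end_bin)
    threshold: float         # Q3 + 1.5*IQR of genome-wide HPS
    flagged: dict            # chrom -> boolean per-bin flag


def hps_track(M12: np.ndarray, chrom: str, bin_size: int,
              window_bins: int = 2, mask: np.ndarray = None,
              epsilon: float = 1.0) -> PairingTrack:
    """Per-bin homolog pairing score from one inter-homolog matrix.

    HPS_i = log2((S_i + eps) / (mean_j S_j + eps)) where S_i sums M12 over
    the aligned-diagonal window (i +/- w) x (i +/- w).
    """
    m = np.asarray(M12, float)
    n = m.shape[0]
    mask = np.ones(n, bool) if mask is None else np.asarray(mask, bool)
    if m.sum() == 0:
        log.warning("all-zero inter-homolog matrix on %s; HPS track is 0", chrom)
        return PairingTrack(chrom, np.where(mask, 0.0, np.nan), bin_size, mask)
    S = np.zeros((n + 1, n + 1))
    S[1:, 1:] = m.cumsum(0).cumsum(1)
    i = np.arange(n)
    i0 = np.clip(i - window_bins, 0, n)
    i1 = np.clip(i + window_bins + 1, 0, n)
    s = S[i1, i1] - S[i0, i1] - S[i1, i0] + S[i0, i0]
    mean_s = s[mask].mean()
    hps = np.log2((s + epsilon) / (mean_s + epsilon))
    hps[~mask] = np.nan
    return PairingTrack(chrom, hps, bin_size, mask)


def call_tight_regions(tracks: list, merge_gap: int = 1) -> TightRegionSet:
    """Flag bins above Q3 + 1.5 x IQR of the genome-wide HPS distribution.

    Quartiles use linear interpolation (type 7). Flagged bins separated by
    up to ``merge_gap`` masked bins are merged into one region; a constant
    track (IQR 0) yields an empty set.
    """
    tracks = list(tracks)
    values = np.concatenate([t.hps[t.mask] for t in tracks])
    if len(values) < 4:
        raise ValueError("need at least 4 non-masked bins genome-wide")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    threshold = q3 + 1.5 * iqr
    if iqr == 0:
        log.info("constant HPS track: IQR 0, no tightly-paired regions")
    regions, flagged = {}, {}
    for t in tracks:
        flag = np.zeros(len(t.hps), bool)
        flag[t.mask] = t.hps[t.mask] > threshold
        flagged[t.chrom] = flag
        regions[t.chrom] = _merge_flags(flag, t.mask, merge_gap)
    return TightRegionSet(regions, float(threshold), flagged)


def _merge_flags(flag: np.ndarray, mask: np.ndarray, merge_gap: int) -> list:
    """Merge runs of flagged bins, bridging up to merge_gap masked bins."""
    out = []
    start = None
    end = None
    k = 0
    n = len(flag)
    while k < n:
        if flag[k]:
            if start is None:
                start = k
            end = k + 1
            k += 1
        elif start is not None and not mask[k]:
            # look ahead across a masked gap of tolerable size
            g = 0
            j = k
            while j < n and not mask[j] and g < merge_gap:
                g += 1
                j += 1
            if j < n and flag[j]:
                k = j
            else:
                out.append((start, end))
                start = None
                k += 1
        else:
            if start is not None:
                out.append((start, end))
                start = None
            k += 1
    if start is not None:
        out.append((start, end))
    return out


def feature_enrichment(region_set: TightRegionSet, feature,
                       continuous: bool = False) -> dict:
    """Test association of tightly-paired bins with a genomic feature.

    Binary features (``feature``: chrom -> boolean per-bin overlap): Fisher's
    exact test on the 2x2 table of bins (in/out region x feature yes/no).
    Continuous features (chrom -> per-bin values, e.g. GC content): Wilcoxon
    rank-sum of in-region vs out-region bin values.
    """
    in_bins, out_bins = [], []
    for chrom, flag in region_set.flagged.items():
        f = np.asarray(feature[chrom])
        in_bins.append(f[flag])
        out_bins.append(f[~flag])
    inside = np.concatenate(in_bins)
    outside = np.concatenate(out_bins)
    if inside.size == 0:
        raise ValueError("empty region set")
    if continuous:
        res = stats.ranksums(inside, outside)
        return {"test": "wilcoxon_rank_sum", "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "median_in": float(np.median(inside)),
                "median_out": float(np.median(outside))}
    ib = inside.astype(bool)
    ob = outside.astype(bool)
    table = np.array([[int(ib.sum()), int((~ib).sum())],
                      [int(ob.sum()), int((~ob).sum())]])
    odds, p = stats.fisher_exact(table)
    return {"test": "fisher_exact", "table": table, "odds_ratio": float(odds),
            "p_value": float(p)}
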