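"""TAD calling by directionality and insulation, boundary strength, and
partition similarity.

Topologically associating domains are self-interacting contact blocks. Two
complementary per-bin tracks locate their boundaries: the directionality
index (DI) measures the up/downstream imbalance of a bin's contacts and
flips sign across a boundary, while the insulation index (IS) measures how
much contact crosses over a bin and dips at boundaries. The caller takes IS
local minima gated by a DI negative-to-positive regime change. The local
boundary score (LBS, in [0,1]) quantifies an individual boundary's
strength: 1 means no cross-boundary contact relative to the flanks.
Partition agreement is summarized by the Measure of Concordance (MoC) and
Variation of Information (VI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

log = logging.getLogger(__name__)


@dataclass
class TADPartition:
    chrom: str
    bin_size: int
    domains: list          # (start_bin, end_bin), half-open, sorted, disjoint
    boundaries: list       # boundary bin indices separating adjacent domains
    di: np.ndarray = None
    ins: np.ndarray = None
    lbs: dict = None       # boundary bin -> LBS


@dataclass
class PartitionSimilarity:
    moc: float             # in [0, 1]; 1 for identical partitions
    vi: float              # >= 0; 0 for identical partitions


def directionality_index(matrix: np.ndarray, bin_size: int,
                         window_bp: int = 500_000) -> np.ndarray:
    """Per-bin directionality index.

    A/B are the bin's total contacts with the upstream/downstream window;
    DI = sign(B-A) * ((A-E)^2 + (B-E)^2)/E with E = (A+B)/2, 0 when A = B
    or E = 0. Windows truncated at chromosome edges.
    """
    m = np.asarray(matrix, float)
    n = m.shape[0]
    w = max(int(window_bp // bin_size), 1)
    di = np.zeros(n)
    for i in range(n):
        a = m[i, max(i - w, 0):i].sum()
        b = m[i, i + 1:min(i + w + 1, n)].sum()
        e = (a + b) / 2.0
        if e == 0 or a == b:
            continue
        di[i] = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
    return di


def insulation_index(matrix: np.ndarray, bin_size: int,
                     square_bp: int = 100_000) -> np.ndarray:
    """Per-bin insulation index: log2 of the mean contact in the square
    crossing the bin, relative to the chromosome mean of that statistic.

    Edge bins without a complete square are NaN.
    """
    m = np.asarray(matrix, float)
    n = m.shape[0]
    s = max(int(square_bp // bin_size), 1)
    raw = np.full(n, np.nan)
    for i in range(s, n - s):
        raw[i] = m[i - s:i, i + 1:i + s + 1].mean()
    ok = ~np.isnan(raw)
    if not ok.any():
        return raw
    mu = raw[ok].mean()
    out = np.full(n, np.nan)
    if mu > 0:
        out[ok] = np.log2(np.maximum(raw[ok], 1e-12) / mu)
    else:
        out[ok] = 0.0
    return out


def call_tads(di: np.ndarray, ins: np.ndarray, chrom: str, bin_size: int,
              prominence: float = 0.1, di_window: int = 2,
              min_domain_bins: int = 3) -> TADPartition:
    """Consensus TAD partition from the DI and IS tracks.

    Boundary candidates are IS local minima with the given prominence,
    retained when DI switches from a negative to a positive regime within
    +/- ``di_window`` bins. Domains are the intervals between retained
    boundaries; a chromosome shorter than one minimal domain is a single
    domain.
    """
    n = len(ins)
    filled = np.where(np.isnan(ins), np.nanmax(ins) if np.isfinite(np.nanmax(ins))
                      else 0.0, ins)
    minima, _ = signal.find_peaks(-filled, prominence=prominence)
    boundaries = []
    for b in minima:
        lo = max(b - di_window, 0)
        hi = min(b + di_window + 1, n)
        left = di[lo:b + 1]
        right = di[b:hi]
        if (left < 0).any() and (right > 0).any():
            boundaries.append(int(b))
    # enforce minimal domain size between consecutive boundaries
    kept = []
    for b in boundaries:
        if not kept or b - kept[-1] >= min_domain_bins:
            kept.append(b)
    edges = [0] + kept + [n]
    domains = [(a, b) for a, b in zip(edges[:-1], edges[1:])
               if b - a >= min_domain_bins]
    if not domains:
        domains = [(0, n)]
        kept = []
    boundary_bins = [b for b in kept if any(d[0] == b for d in domains)]
    return TADPartition(chrom, bin_size, domains, boundary_bins, di, ins)


def local_boundary_score(matrix: np.ndarray, bin_idx: int,
                         window_bins: int = 10) -> float:
    """Boundary strength at one bin, in [0, 1].

    LBS = 1 - mean(cross-boundary square) / mean(flanking within-side
    triangles); NaN when the flanks carry no signal or the windows do not
    fit.
    """
    m = np.asarray(matrix, float)
    n = m.shape[0]
    w = window_bins
    if bin_idx - w < 0 or bin_idx + w >= n:
        return float("nan")
    cross = m[bin_idx - w:bin_idx, bin_idx + 1:bin_idx + w + 1]
    left = m[bin_idx - w:bin_idx, bin_idx - w:bin_idx]
    right = m[bin_idx + 1:bin_idx + w + 1, bin_idx + 1:bin_idx + w + 1]
    lt = left[np.triu_indices(w, 1)]
    rt = right[np.triu_indices(w, 1)]
    within = (lt.mean() + rt.mean()) / 2.0
    if within <= 0:
        return float("nan")
    return float(np.clip(1.0 - cross.mean() / within, 0.0, 1.0))


def shifted_boundaries(matrices_a: list, matrices_b: list, boundary_bins,
                       window_bins: int = 10, delta_threshold: float = 0.2,
                       alpha: float = 0.05) -> list:
    """Boundary bins whose LBS differs between two paired replicate groups.

    For each candidate boundary bin, LBS is computed in every replicate of
    each group; the bin is flagged when |mean paired delta| >= 0.2 and the
    paired t-test rejects at ``alpha``. Returns (bin, delta, p) tuples.
    """
    if len(matrices_a) != len(matrices_b) or len(matrices_a) < 2:
        raise ValueError("need >=2 paired replicates per group")
    out = []
    for b in boundary_bins:
        la = np.array([local_boundary_score(m, b, window_bins) for m in matrices_a])
        lb = np.array([local_boundary_score(m, b, window_bins) for m in matrices_b])
        if np.isnan(la).any() or np.isnan(lb).any():
            continue
        d = la - lb
        delta = float(d.mean())
        if np.allclose(d, d[0]):
            # zero-variance paired differences: perfectly consistent shift
            p = 0.0 if abs(delta) > 0 else 1.0
        else:
            p = float(stats.ttest_rel(la, lb).pvalue)
        if abs(delta) >= delta_threshold and p < alpha:
            out.append((int(b), delta, p))
    return out


def partition_similarity(p: TADPartition, q: TADPartition) -> PartitionSimilarity:
    """Measure of Concordance and Variation of Information of two partitions.

    MoC = (1/(sqrt(Np*Nq)-1)) * (sum_ij F_ij^2/(|P_i||Q_j|) - 1) with F_ij
    the overlap length; defined as 1 when both partitions are a single
    domain. VI = H(P) + H(Q) - 2*MI over length-weighted domain
    distributions (natural log).
    """
    P = [(a * p.bin_size, b * p.bin_size) for a, b in p.domains]
    Q = [(a * q.bin_size, b * q.bin_size) for a, b in q.domains]
    if not P or not Q:
        raise ValueError("empty partition")
    np_, nq = len(P), len(Q)
    overlaps = np.zeros((np_, nq))
    for i, (a1, b1) in enumerate(P):
        for j, (a2, b2) in enumerate(Q):
            overlaps[i, j] = max(0, min(b1, b2) - max(a1, a2))
    lp = np.array([b - a for a, b in P], float)
    lq = np.array([b - a for a, b in Q], float)
    if np_ == 1 and nq == 1:
        moc = 1.0
    else:
        s = (overlaps ** 2 / np.outer(lp, lq)).sum()
        moc = (s - 1.0) / (np.sqrt(np_ * nq) - 1.0)

    lt = overlaps.sum()
    if lt == 0:
        raise ValueError("partitions share no covered length")
    r = overlaps / lt
    rp, rq = r.sum(1), r.sum(0)
    h_p = -np.sum(rp[rp > 0] * np.log(rp[rp > 0]))
    h_q = -np.sum(rq[rq > 0] * np.log(rq[rq > 0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        mi_terms = r * (np.log(r) - np.log(np.outer(rp, rq)))
    mi = float(np.nansum(np.where(r > 0, mi_terms, 0.0)))
    vi = max(h_p + h_q - 2 * mi, 0.0)
    return PartitionSimilarity(float(moc), float(vi))
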