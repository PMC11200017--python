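"""Haplotype assignment of Hi-C contacts from informative SNV votes.

Each read end carries votes from the phased heterozygous variants it
overlaps. Unanimous votes assign the end to a haplotype; a pair with one
phased end and one unknown end on the same chromosome is accepted as
intra-haplotype evidence (cis contacts dominate), opposite-haplotype ends on
the same chromosome are inter-homolog, pairs bridging different chromosomes
with any haplotype evidence are heterologs, and both-unknown intra-
chromosomal pairs enter a pool for local imputation. Any end with mixed
votes marks the pair as a conflict and discards it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBinning

log = logging.getLogger(__name__)

UNKNOWN, CONFLICT = 0, -1
HAP1, HAP2 = 1, 2
_LABEL_NAMES = {HAP1: "hap1", HAP2: "hap2", UNKNOWN: "unknown", CONFLICT: "conflict"}


def assign_allele(votes) -> str:
    """Label one read end from its haplotype votes.

    Unanimous votes give that haplotype, no votes give ``unknown``, mixed
    votes give ``conflict``. Total function: never raises.
    """
    votes = list(votes)
    h1 = sum(1 for v in votes if v in (HAP1, "hap1"))
    h2 = sum(1 for v in votes if v in (HAP2, "hap2"))
    if h1 + h2 != len(votes):
        # unrecognized vote symbols count as conflicting evidence
        return "conflict"
    return _LABEL_NAMES[_label_from_counts(h1, h2)]


def _label_from_counts(h1, h2):
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    out = np.full(h1.shape, UNKNOWN, np.int8)
    out = np.where((h1 > 0) & (h2 == 0), HAP1, out)
    out = np.where((h2 > 0) & (h1 == 0), HAP2, out)
    out = np.where((h1 > 0) & (h2 > 0), CONFLICT, out)
    return out[()] if out.shape == () else out


@dataclass
class PhasedContactMap:
    """Per-sample phased matrices plus classification statistics.

    M11/M22 are symmetric intra-haplotype matrices per chromosome; M12 the
    (symmetrized) inter-homolog matrix. The unphased pool retains bin pairs
    for local imputation; heterologs are kept as a table.
    """

    binning: GenomeBinning
    M11: dict            # chrom -> dense symmetric ndarray
    M22: dict
    M12: dict
    heterolog: pd.DataFrame
    unphased_pool: pd.DataFrame   # chrom, bin1, bin2 for intra-chrom both-unknown pairs
    stats: dict                   # counts of each class
    assigned: pd.DataFrame = field(default=None, repr=False)  # per-record labels

    @property
    def fractions(self) -> dict:
        total = sum(self.stats.values())
        return {k: v / total for k, v in self.stats.items()} if total else {}


def phase_contacts(records: pd.DataFrame, binning: GenomeBinning,
                   keep_assignments: bool = False) -> PhasedContactMap:
    """Classify contact records and accumulate phased matrices.

    ``records`` needs columns chrom1/pos1/chrom2/pos2 and per-end vote counts
    v1_h1, v1_h2, v2_h1, v2_h2.
    """
    for c in pd.unique(pd.concat([records.chrom1, records.chrom2])):
        if c not in binning.chrom_lengths:
            raise ValueError(f"records reference unknown chromosome {c!r}")

    lab1 = _label_from_counts(records.v1_h1.to_numpy(), records.v1_h2.to_numpy())
    lab2 = _label_from_counts(records.v2_h1.to_numpy(), records.v2_h2.to_numpy())
    same_chrom = (records.chrom1 == records.chrom2).to_numpy()

    conflict = (lab1 == CONFLICT) | (lab2 == CONFLICT)
    both_unknown = (lab1 == UNKNOWN) & (lab2 == UNKNOWN)
    any_phased = ~conflict & ~both_unknown

    # pair-level classes
    cis_hap = np.zeros(len(records), np.int8)  # 1/2 -> M11/M22 cis evidence
    inter_homolog = np.zeros(len(records), bool)
    heterolog = np.zeros(len(records), bool)

    opp = any_phased & (lab1 > 0) & (lab2 > 0) & (lab1 != lab2)
    agree = any_phased & ~opp
    # single-end or agreeing evidence: haplotype = the phased end's label
    ev = np.where(lab1 > 0, lab1, lab2)
    cis_hap = np.where(agree & same_chrom, ev, 0).astype(np.int8)
    inter_homolog = opp & same_chrom
    heterolog = any_phased & ~same_chrom

    unphased = both_unknown & ~conflict

    M11 = {c: np.zeros((binning.n_bins(c),) * 2) for c in binning.chroms}
    M22 = {c: np.zeros((binning.n_bins(c),) * 2) for c in binning.chroms}
    M12 = {c: np.zeros((binning.n_bins(c),) * 2) for c in binning.chroms}

    pool_rows = []
    for chrom in binning.chroms:
        on_c = (records.chrom1 == chrom).to_numpy() & same_chrom
        if not on_c.any():
            continue
        b1 = binning.bin_of(chrom, records.pos1.to_numpy()[on_c])
        b2 = binning.bin_of(chrom, records.pos2.to_numpy()[on_c])
        for hap, M in ((HAP1, M11), (HAP2, M22)):
            sel = cis_hap[on_c] == hap
            if sel.any():
                np.add.at(M[chrom], (b1[sel], b2[sel]), 1)
                np.add.at(M[chrom], (b2[sel], b1[sel]), 1)
        sel = inter_homolog[on_c]
        if sel.any():
            np.add.at(M12[chrom], (b1[sel], b2[sel]), 1)
            np.add.at(M12[chrom], (b2[sel], b1[sel]), 1)
        sel = unphased[on_c]
        if sel.any():
            pool_rows.append(pd.DataFrame(
                {"chrom": chrom, "bin1": b1[sel], "bin2": b2[sel]}))
    # halve double-added exact diagonals
    for M in (M11, M22, M12):
        for chrom in M:
            np.fill_diagonal(M[chrom], np.diagonal(M[chrom]) / 2)

    het = records.loc[heterolog, ["chrom1", "pos1", "chrom2", "pos2"]].copy()
    het["hap1_label"] = [_LABEL_NAMES[v] for v in lab1[heterolog]]
    het["hap2_label"] = [_LABEL_NAMES[v] for v in lab2[heterolog]]

    pool = (pd.concat(pool_rows, ignore_index=True) if pool_rows
            else pd.DataFrame(columns=["chrom", "bin1", "bin2"]))
    trans_unphased = int((unphased & ~same_chrom).sum())

    stats = {
        "intra_haplotype": int((cis_hap > 0).sum()),
        "inter_homolog": int(inter_homolog.sum()),
        "heterolog": int(heterolog.sum()),
        "unphased": int(unphased.sum()),
        "conflict": int(conflict.sum()),
    }
    assert sum(stats.values()) == len(records)
    if trans_unphased:
        log.debug("%d both-unknown inter-chromosomal pairs left unphased",
                  trans_unphased)

    assigned = None
    if keep_assignments:
        cls = np.where(conflict, "conflict",
              np.where(cis_hap == HAP1, "hap1",
              np.where(cis_hap == HAP2, "hap2",
              np.where(inter_homolog, "inter_homolog",
              np.where(heterolog, "heterolog", "unphased")))))
        assigned = pd.DataFrame({"class": cls})
    return PhasedContactMap(binning, M11, M22, M12, het, pool, stats, assigned)


def impute_local(pmap: PhasedContactMap, window_bins: int = 5,
                 seed: int = 0) -> PhasedContactMap:
    """Allocate the unphased intra-chromosomal pool to M11/M22.

    Each pooled contact at (i, j) is assigned to haplotype 1 with probability
    proportional to the phased M11 mass in the (i±w, j±w) window, else to
    haplotype 2 (stochastic rounding; expectation preserves the window
    ratio). Zero evidence in both windows falls back to a fair coin.
    Returns a new map; total added contacts equal the pool size.
    """
    rng = np.random.default_rng(seed)
    M11 = {c: m.copy() for c, m in pmap.M11.items()}
    M22 = {c: m.copy() for c, m in pmap.M22.items()}
    n_fallback = 0
    for chrom, grp in pmap.unphased_pool.groupby("chrom", sort=False):
        n = pmap.binning.n_bins(chrom)
        # 2-D summed-area tables for O(1) window sums
        S11 = _integral(pmap.M11[chrom])
        S22 = _integral(pmap.M22[chrom])
        i = grp.bin1.to_numpy()
        j = grp.bin2.to_numpy()
        w11 = _window_sum(S11, i, j, window_bins, n)
        w22 = _window_sum(S22, i, j, window_bins, n)
        tot = w11 + w22
        p1 = np.where(tot > 0, np.divide(w11, np.maximum(tot, 1e-300)), 0.5)
        n_fallback += int((tot == 0).sum())
        to_h1 = rng.random(len(i)) < p1
        for sel, M in ((to_h1, M11), (~to_h1, M22)):
            if sel.any():
                np.add.at(M[chrom], (i[sel], j[sel]), 1)
                off = i[sel] != j[sel]
                np.add.at(M[chrom], (j[sel][off], i[sel][off]), 1)
    if n_fallback:
        log.info("imputation: %d contacts allocated 50/50 (no phased evidence "
                 "in window)", n_fallback)
    stats = dict(pmap.stats)
    return PhasedContactMap(pmap.binning, M11, M22, pmap.M12, pmap.heterolog,
                            pmap.unphased_pool.iloc[0:0], stats)


def _integral(m: np.ndarray) -> np.ndarray:
    s = np.zeros((m.shape[0] + 1, m.shape[1] + 1))
    s[1:, 1:] = m.cumsum(0).cumsum(1)
    return s


def _window_sum(S, i, j, w, n):
    i0 = np.clip(i - w, 0, n); i1 = np.clip(i + w + 1, 0, n)
    j0 = np.clip(j - w, 0, n); j1 = np.clip(j + w + 1, 0, n)
    return S[i1, j1] - S[i0, j1] - S[i1, j0] + S[i0, j0]


@dataclass
class ResolutionReport:
    """Map-resolution estimate: smallest bin size where >=80% of bins hold
    >=1000 reads."""

    candidate_sizes: list
    fractions: dict              # size -> fraction of bins with >= min_reads
    selected: int | None         # bp, or None if no candidate passes
    min_reads: int = 1000
    min_fraction: float = 0.80


def map_resolution(end_positions: dict, chrom_lengths: dict,
                   candidate_sizes, min_reads: int = 1000,
                   min_fraction: float = 0.80) -> ResolutionReport:
    """Apply the map-resolution rule to raw read-end positions.

    ``end_positions`` maps chromosome -> array of read end coordinates
    (each contact contributes both ends). Only chromosomes with any reads
    enter the per-size fraction. Selected size is the smallest candidate
    whose fraction of bins holding at least ``min_reads`` reads reaches
    ``min_fraction``.
    """
    sizes = sorted(int(s) for s in candidate_sizes)
    fractions = {}
    used = {c: np.asarray(p) for c, p in end_positions.items() if len(p)}
    for size in sizes:
        n_ok = n_bins = 0
        for chrom, pos in used.items():
            nb = int(np.ceil(chrom_lengths[chrom] / size))
            counts = np.bincount(pos // size, minlength=nb)
            n_ok += int((counts >= min_reads).sum())
            n_bins += nb
        fractions[size] = n_ok / n_bins if n_bins else 0.0
    selected = next((s for s in sizes if fractions[s] >= min_fraction), None)
    return ResolutionReport(sizes, fractions, selected, min_reads, min_fraction)
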