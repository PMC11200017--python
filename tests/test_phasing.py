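import numpy as np
import pandas as pd
import pytest

from diphic import phasing
from diphic.genome import GenomeBinning


# ---------------------------------------------------------------- assign_allele

@pytest.mark.parametrize("votes,expected", [
    (["hap1", "hap1"], "hap1"),
    (["hap2"], "hap2"),
    ([], "unknown"),
    (["hap1", "hap2"], "conflict"),
    (["hap1", "garbage"], "conflict"),
])
def test_assign_allele_total_function(votes, expected):
    assert phasing.assign_allele(votes) == expected


def test_label_from_counts_vectorized():
    h1 = np.array([2, 0, 0, 1])
    h2 = np.array([0, 3, 0, 1])
    lab = phasing._label_from_counts(h1, h2)
    assert np.array_equal(lab, [phasing.HAP1, phasing.HAP2,
                                phasing.UNKNOWN, phasing.CONFLICT])


# -------------------------------------------------------------- phase_contacts

def _records(rows):
    return pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2",
                                       "v1_h1", "v1_h2", "v2_h1", "v2_h2"])


def test_phase_contacts_classes_by_hand():
    b = GenomeBinning({"chrA": 40_000, "chrB": 40_000}, 10_000)
    rec = _records([
        ("chrA", 5_000, "chrA", 15_000, 2, 0, 1, 0),   # both ends hap1 -> M11
        ("chrA", 5_000, "chrA", 25_000, 0, 1, 0, 2),   # both ends hap2 -> M22
        ("chrA", 5_000, "chrA", 35_000, 1, 0, 0, 0),   # single-end cis -> M11
        ("chrA", 5_000, "chrA", 15_000, 1, 0, 0, 1),   # opposite haps -> M12
        ("chrA", 5_000, "chrA", 15_000, 0, 0, 0, 0),   # unphased pool
        ("chrA", 5_000, "chrA", 15_000, 1, 1, 0, 0),   # conflict, dropped
        ("chrA", 5_000, "chrB", 15_000, 1, 0, 0, 0),   # heterolog
    ])
    pmap = phasing.phase_contacts(rec, b)
    assert pmap.stats == {"intra_haplotype": 3, "inter_homolog": 1,
                          "heterolog": 1, "unphased": 1, "conflict": 1}
    assert pmap.M11["chrA"][0, 1] == 1 and pmap.M11["chrA"][0, 3] == 1
    assert pmap.M22["chrA"][0, 2] == 1
    assert pmap.M12["chrA"][0, 1] == 1 and pmap.M12["chrA"][1, 0] == 1
    assert len(pmap.unphased_pool) == 1
    assert len(pmap.heterolog) == 1
    # conservation: classes partition the input
    assert sum(pmap.stats.values()) == len(rec)


def test_phase_contacts_matrices_symmetric(small_truth, small_cfg):
    from diphic.simulate import simulate_contacts
    rec = simulate_contacts(small_truth, small_cfg)
    pmap = phasing.phase_contacts(rec, small_cfg.binning)
    for c in small_cfg.binning.chroms:
        for M in (pmap.M11, pmap.M22, pmap.M12):
            assert np.allclose(M[c], M[c].T)
    assert sum(pmap.stats.values()) == len(rec)


def test_label_swap_symmetry(small_truth, small_cfg):
    """Swapping every haplotype-1 vote with haplotype 2 swaps M11 and M22."""
    from diphic.simulate import simulate_contacts
    rec = simulate_contacts(small_truth, small_cfg)
    swapped = rec.rename(columns={"v1_h1": "v1_h2", "v1_h2": "v1_h1",
                                  "v2_h1": "v2_h2", "v2_h2": "v2_h1"})
    a = phasing.phase_contacts(rec, small_cfg.binning)
    b = phasing.phase_contacts(swapped, small_cfg.binning)
    for c in small_cfg.binning.chroms:
        assert np.array_equal(a.M11[c], b.M22[c])
        assert np.array_equal(a.M22[c], b.M11[c])
        assert np.array_equal(a.M12[c], b.M12[c])
    assert a.stats == b.stats


def test_unknown_chromosome_rejected():
    b = GenomeBinning({"chrA": 40_000}, 10_000)
    rec = _records([("chrZ", 0, "chrZ", 1, 0, 0, 0, 0)])
    with pytest.raises(ValueError):
        phasing.phase_contacts(rec, b)


# ---------------------------------------------------------------- impute_local

def test_impute_conservation_and_determinism(small_truth, small_cfg):
    from diphic.simulate import simulate_contacts
    rec = simulate_contacts(small_truth, small_cfg)
    pmap = phasing.phase_contacts(rec, small_cfg.binning)
    pool_n = len(pmap.unphased_pool)
    imp1 = phasing.impute_local(pmap, seed=99)
    imp2 = phasing.impute_local(pmap, seed=99)
    added = 0
    for c in small_cfg.binning.chroms:
        assert np.array_equal(imp1.M11[c], imp2.M11[c])
        assert np.array_equal(imp1.M22[c], imp2.M22[c])
        d11 = imp1.M11[c] - pmap.M11[c]
        d22 = imp1.M22[c] - pmap.M22[c]
        assert (d11 >= 0).all() and (d22 >= 0).all()
        # each pooled contact adds 1 to the upper triangle (2 symmetric cells)
        added += (np.triu(d11).sum() + np.triu(d22).sum())
    assert added == pool_n
    assert len(imp1.unphased_pool) == 0


def test_impute_follows_local_evidence():
    b = GenomeBinning({"chrA": 200_000}, 10_000)
    M11 = {"chrA": np.zeros((20, 20))}
    M22 = {"chrA": np.zeros((20, 20))}
    M11["chrA"][4, 6] = M11["chrA"][6, 4] = 50.0   # all evidence on hap1
    pool = pd.DataFrame({"chrom": ["chrA"] * 30, "bin1": 5, "bin2": 6})
    pmap = phasing.PhasedContactMap(
        b, M11, M22, {"chrA": np.zeros((20, 20))},
        pd.DataFrame(), pool,
        {"intra_haplotype": 1, "inter_homolog": 0, "heterolog": 0,
         "unphased": 30, "conflict": 0})
    imp = phasing.impute_local(pmap, seed=5)
    assert imp.M11["chrA"][5, 6] == 30     # every pooled contact goes to hap1
    assert imp.M22["chrA"][5, 6] == 0


# -------------------------------------------------------------- map_resolution

def test_map_resolution_selects_smallest_passing():
    # 10 bins of 5 kb: 8 bins at exactly 1000 reads, 2 just below -> 80%
    pos = [np.full(1000 if k < 8 else 999, k * 5_000 + 100) for k in range(10)]
    ends = {"chr1": np.concatenate(pos)}
    rep = phasing.map_resolution(ends, {"chr1": 50_000},
                                 [2_000, 5_000, 10_000])
    assert rep.selected == 5_000
    assert rep.fractions[5_000] == pytest.approx(0.8)
    assert rep.fractions[2_000] < 0.8
    assert rep.fractions[10_000] == 1.0


def test_map_resolution_none_when_all_fail():
    ends = {"chr1": np.array([100, 200, 300])}
    rep = phasing.map_resolution(ends, {"chr1": 50_000}, [5_000, 10_000])
    assert rep.selected is None
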