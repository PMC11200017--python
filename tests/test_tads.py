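import numpy as np
import pytest

from diphic import tads
from diphic.tads import TADPartition


def _block_matrix(n, edges, inside=10.0, outside=1.0):
    """Block-diagonal contact matrix with domains between consecutive edges."""
    m = np.full((n, n), outside)
    for a, b in zip(edges[:-1], edges[1:]):
        m[a:b, a:b] = inside
    return m


# -------------------------------------------------------- directionality_index

def test_di_hand_case():
    """Upstream sum A = 10, downstream B = 30 -> E = 20,
    DI = +((10-20)^2/20 + (30-20)^2/20) = +10."""
    n = 11
    m = np.zeros((n, n))
    i = 5
    m[i, 3] = 10.0          # upstream contact
    m[i, 7] = 30.0          # downstream contact
    di = tads.directionality_index(m, bin_size=100_000, window_bp=500_000)
    assert di[i] == pytest.approx(10.0)


def test_di_zero_when_balanced_or_empty():
    n = 11
    m = np.zeros((n, n))
    m[5, 3] = m[5, 7] = 10.0
    di = tads.directionality_index(m, 100_000)
    assert di[5] == 0.0
    assert di[0] == 0.0 or np.isfinite(di[0])


def test_di_sign_reflection_symmetry():
    """Mirroring the matrix about the anti-diagonal negates the DI track."""
    rng = np.random.default_rng(0)
    m = rng.gamma(2, 5, (30, 30))
    m = (m + m.T) / 2
    di = tads.directionality_index(m, 20_000)
    di_rev = tads.directionality_index(m[::-1, ::-1], 20_000)
    assert np.allclose(di, -di_rev[::-1])


# ------------------------------------------------------------ insulation_index

def test_insulation_edges_nan_and_dip_at_boundary():
    m = _block_matrix(40, [0, 20, 40])
    ins = tads.insulation_index(m, bin_size=20_000, square_bp=100_000)
    s = 5
    assert np.isnan(ins[:s]).all() and np.isnan(ins[-s:]).all()
    interior = ins[s:-s]
    # the square fully straddles the boundary for bins 19 and 20, so the
    # dip is a plateau; the boundary bin sits on it
    assert ins[20] == np.nanmin(interior)
    assert ins[20] < ins[10] and ins[20] < ins[30]


def test_insulation_uniform_matrix_is_zero():
    ins = tads.insulation_index(np.ones((30, 30)), 20_000, square_bp=100_000)
    ok = ~np.isnan(ins)
    assert np.allclose(ins[ok], 0.0)


# ------------------------------------------------------------------- call_tads

def test_call_tads_recovers_block_boundaries():
    edges = [0, 15, 35, 50]
    m = _block_matrix(50, edges)
    di = tads.directionality_index(m, 20_000)
    ins = tads.insulation_index(m, 20_000)
    part = tads.call_tads(di, ins, "chr1", 20_000)
    for b in (15, 35):
        assert any(abs(c - b) <= 1 for c in part.boundaries)
    # domains tile [0, n) without overlap
    assert part.domains[0][0] == 0 and part.domains[-1][1] == 50
    for (a1, b1), (a2, b2) in zip(part.domains[:-1], part.domains[1:]):
        assert b1 == a2


def test_call_tads_flat_matrix_single_domain():
    m = np.ones((30, 30))
    di = tads.directionality_index(m, 20_000)
    ins = tads.insulation_index(m, 20_000)
    part = tads.call_tads(di, ins, "chr1", 20_000)
    assert part.domains == [(0, 30)]
    assert part.boundaries == []


# ------------------------------------------------------- local_boundary_score

def test_lbs_perfect_boundary_is_one():
    m = _block_matrix(40, [0, 20, 40], inside=10.0, outside=0.0)
    assert tads.local_boundary_score(m, 20, window_bins=10) == 1.0


def test_lbs_uniform_matrix_is_zero():
    assert tads.local_boundary_score(np.ones((40, 40)), 20) == 0.0


def test_lbs_nan_when_window_does_not_fit():
    m = np.ones((15, 15))
    assert np.isnan(tads.local_boundary_score(m, 2, window_bins=10))
    assert np.isnan(tads.local_boundary_score(np.zeros((40, 40)), 20))


def test_lbs_in_unit_interval():
    rng = np.random.default_rng(1)
    m = rng.gamma(2, 5, (50, 50))
    m = (m + m.T) / 2
    for b in range(12, 38):
        v = tads.local_boundary_score(m, b)
        assert 0.0 <= v <= 1.0


# --------------------------------------------------------- shifted_boundaries

def test_shifted_boundaries_flags_planted_difference():
    strong = _block_matrix(40, [0, 20, 40], inside=10.0, outside=0.5)
    weak = _block_matrix(40, [0, 40], inside=10.0)          # no boundary
    rng = np.random.default_rng(2)

    def jitter(m):
        e = rng.normal(0, 0.01, m.shape)
        return np.abs(m + (e + e.T) / 2)

    a = [jitter(strong) for _ in range(3)]
    b = [jitter(weak) for _ in range(3)]
    res = tads.shifted_boundaries(a, b, [20])
    assert len(res) == 1 and res[0][0] == 20
    assert res[0][1] > 0.2                     # boundary present only in group A
    # identical groups: nothing flagged
    assert tads.shifted_boundaries(a, a, [20]) == []


def test_shifted_boundaries_needs_replicates():
    m = np.ones((40, 40))
    with pytest.raises(ValueError):
        tads.shifted_boundaries([m], [m], [20])


# ------------------------------------------------------- partition_similarity

def _partition(domains, bin_size=20_000):
    bounds = [b for _, b in domains[:-1]]
    return TADPartition("chr1", bin_size, domains, bounds)


def test_moc_vi_identity_for_identical_partitions():
    p = _partition([(0, 10), (10, 25), (25, 40)])
    sim = tads.partition_similarity(p, p)
    assert sim.moc == pytest.approx(1.0)
    assert sim.vi == pytest.approx(0.0, abs=1e-12)


def test_moc_vi_one_vs_equal_split():
    n, k = 40, 5
    one = _partition([(0, n)])
    even = _partition([(i * n // k, (i + 1) * n // k) for i in range(k)])
    sim = tads.partition_similarity(one, even)
    assert sim.moc == pytest.approx(0.0, abs=1e-12)
    assert sim.vi == pytest.approx(np.log(k))


def test_moc_single_domain_both_sides():
    sim = tads.partition_similarity(_partition([(0, 10)]), _partition([(0, 10)]))
    assert sim.moc == 1.0 and sim.vi == pytest.approx(0.0, abs=1e-12)


def test_partition_similarity_symmetric():
    p = _partition([(0, 12), (12, 40)])
    q = _partition([(0, 20), (20, 30), (30, 40)])
    s1 = tads.partition_similarity(p, q)
    s2 = tads.partition_similarity(q, p)
    assert s1.moc == pytest.approx(s2.moc)
    assert s1.vi == pytest.approx(s2.vi)


def test_empty_partition_rejected():
    with pytest.raises(ValueError):
        tads.partition_similarity(_partition([]), _partition([(0, 10)]))
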