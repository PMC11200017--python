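import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diphic import pei


def _power_law_matrix(n, exponent=-1.0, scale=1000.0, bin_size=20_000):
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        m = scale * np.maximum(d, 0.5) ** exponent
    return m


# ---------------------------------------------------------------- fit_expected

def test_expected_model_recovers_background_power_law():
    m = _power_law_matrix(100)
    model = pei.fit_expected(m, [(0, 100)], bin_size=20_000, min_pairs=20)
    # the domain covers everything and fits the exact power law
    for i, j in [(10, 20), (30, 80), (5, 6)]:
        assert model.expected(i, j)[0] == pytest.approx(m[i, j], rel=1e-6)


def test_small_domains_fall_back_to_background():
    m = _power_law_matrix(50)
    model = pei.fit_expected(m, [(0, 4), (4, 50)], bin_size=20_000, min_pairs=20)
    assert 0 not in model.domain_fits          # 4-bin domain: too few pairs
    assert 1 in model.domain_fits


def test_per_tad_fit_captures_domain_elevation():
    m = _power_law_matrix(60)
    m[20:40, 20:40] *= 5.0                     # elevated domain
    model = pei.fit_expected(m, [(0, 20), (20, 40), (40, 60)], 20_000)
    inside = model.expected(25, 30)[0]
    outside = model.expected(5, 10)[0]
    assert inside == pytest.approx(m[25, 30], rel=1e-6)
    assert outside == pytest.approx(m[5, 10], rel=1e-6)


# ------------------------------------------------------------------- call_peis

def test_poisson_tail_probability_matches_scipy():
    m = _power_law_matrix(100)
    pb, eb = 10, 20                            # 200 kb apart
    m[pb, eb] = m[eb, pb] = m[pb, eb] * 6.0
    model = pei.fit_expected(m, [(0, 100)], 20_000)
    called = pei.call_peis(m, model, {"g": pb}, [eb], fdr=1.0)
    row = called[(called.promoter_bin == pb) & (called.enhancer_bin == eb)].iloc[0]
    expected_p = stats.poisson.sf(np.ceil(row.observed) - 1, row.expected)
    assert row.p == pytest.approx(expected_p, abs=1e-12)


def test_distance_window_enforced():
    m = _power_law_matrix(120)
    model = pei.fit_expected(m, [(0, 120)], 20_000)
    # candidates at 1 bin (20 kb < 25 kb) and 60 bins (1.2 Mb > 1 Mb): excluded
    called = pei.call_peis(m, model, {"g": 30}, [31, 90, 40], fdr=1.0)
    assert set(called.enhancer_bin) == {40}


def test_promoter_outside_binning_skipped():
    m = _power_law_matrix(50)
    model = pei.fit_expected(m, [(0, 50)], 20_000)
    called = pei.call_peis(m, model, {"bad": 200, "good": 10}, [20], fdr=1.0)
    assert set(called.gene) == {"good"}


def test_bh_correction_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(5)
    m = _power_law_matrix(100)
    noise = rng.poisson(m)
    noisy = np.triu(noise) + np.triu(noise, 1).T
    model = pei.fit_expected(noisy.astype(float), [(0, 100)], 20_000)
    cands = list(range(0, 100, 3))
    called = pei.call_peis(noisy.astype(float), model, {"g": 50}, cands, fdr=1.0)
    q = multipletests(called.p, method="fdr_bh")[1]
    assert np.allclose(np.sort(called.q), np.sort(q))


# ------------------------------------------------------------------------ RPS

def test_rps_hand_value():
    df = pd.DataFrame({"gene": ["g"], "promoter_bin": [10], "enhancer_bin": [20],
                       "observed": [50.0], "expected": [10.0], "oe": [5.0],
                       "distance_bp": [200_000], "p": [1e-9], "q": [1e-8]})
    # log2(1 + max(5 - 1, 0)) = log2(5)
    assert pei.compute_rps("g", df) == pytest.approx(np.log2(5.0))
    assert pei.compute_rps("absent", df) == 0.0


def test_rps_strictly_monotone_in_enhancer_count():
    vals = []
    for k in range(1, 6):
        df = pd.DataFrame({"gene": ["g"] * k, "promoter_bin": [10] * k,
                           "enhancer_bin": list(range(20, 20 + k)),
                           "observed": [50.0] * k, "expected": [10.0] * k,
                           "oe": [5.0] * k, "distance_bp": [200_000] * k,
                           "p": [1e-9] * k, "q": [1e-8] * k})
        vals.append(pei.compute_rps("g", df))
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_rps_ignores_depleted_pairs():
    df = pd.DataFrame({"gene": ["g"], "promoter_bin": [10], "enhancer_bin": [20],
                       "observed": [5.0], "expected": [10.0], "oe": [0.5],
                       "distance_bp": [200_000], "p": [0.9], "q": [0.9]})
    assert pei.compute_rps("g", df) == 0.0     # max(O/E - 1, 0) clips to 0


# ----------------------------------------------------------- differential_rps

def _tables(values_by_gene, jitters):
    return [pd.Series({g: v + j for g, v in values_by_gene.items()}, name="rps")
            for j in jitters]


def test_differential_rps_axis_thresholds():
    a = _tables({"big": 5.0, "small": 1.35, "null": 2.0}, [0.0, 0.01, -0.01])
    b = _tables({"big": 1.0, "small": 1.0, "null": 2.0}, [0.0, 0.01, -0.01])
    stage = pei.differential_rps(a, b, axis="stage").set_index("gene")
    assert bool(stage.loc["big", "flagged"])           # delta 4 > 3
    assert not bool(stage.loc["small", "flagged"])     # delta 0.35 < 3
    assert not bool(stage.loc["null", "flagged"])
    breed = pei.differential_rps(a, b, axis="breed").set_index("gene")
    assert bool(breed.loc["big", "flagged"])
    assert bool(breed.loc["small", "flagged"])         # delta 0.35 > 0.3
    assert not bool(breed.loc["null", "flagged"])
    # exactly at the threshold: not flagged (strict inequality)
    a2 = _tables({"edge": 0.3}, [0.0, 0.0])   # delta exactly the 0.3 double
    b2 = _tables({"edge": 0.0}, [0.0, 0.0])
    edge = pei.differential_rps(a2, b2, axis="breed").set_index("gene")
    assert not bool(edge.loc["edge", "flagged"])


def test_differential_rps_requires_pairs():
    t = _tables({"g": 1.0}, [0.0])
    with pytest.raises(ValueError):
        pei.differential_rps(t, t, axis="breed")


# ------------------------------------------------------------ merge_stage_peis

def test_merge_stage_peis_union_and_mean():
    base = dict(gene="g", promoter_bin=10, enhancer_bin=20,
                observed=50.0, expected=10.0, distance_bp=200_000,
                p=1e-9, q=1e-8)
    d1 = pd.DataFrame([dict(base, oe=4.0)])
    d2 = pd.DataFrame([dict(base, oe=6.0),
                       dict(base, enhancer_bin=30, oe=3.0)])
    merged = pei.merge_stage_peis([d1, d2])
    assert len(merged) == 2
    shared = merged[merged.enhancer_bin == 20].iloc[0]
    assert shared.oe == pytest.approx(5.0)
    assert shared.n_samples == 2
    only = merged[merged.enhancer_bin == 30].iloc[0]
    assert only.n_samples == 1
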