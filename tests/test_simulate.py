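import numpy as np
import pandas as pd
import pytest

from diphic.simulate import (ConfigurationError, SimConfig, make_truth,
                             simulate_contacts, simulate_expression_and_population,
                             simulate_matrix)
from diphic import matrix_ops


def test_config_validation_errors():
    with pytest.raises(ConfigurationError):
        SimConfig(chrom_lengths={}).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(chrom_lengths={"chr1": 0}).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(chrom_lengths={"chr1": 1000}, bin_size=0).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(chrom_lengths={"chr1": 1000}, tad_strength=0.5).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(chrom_lengths={"chr1": 1000},
                  pairing_blocks=(("chr1", 0, 2000, 2.0),)).validate()


def test_zero_contacts_rejected(small_truth, small_cfg):
    from dataclasses import replace
    with pytest.raises(ConfigurationError):
        simulate_contacts(small_truth, replace(small_cfg, n_contacts=0))


def test_truth_determinism(small_cfg):
    t1 = make_truth(small_cfg)
    t2 = make_truth(small_cfg)
    pd.testing.assert_frame_equal(t1.variant_table, t2.variant_table)
    for c in small_cfg.chrom_lengths:
        assert np.array_equal(t1.compartment_truth[c], t2.compartment_truth[c])
        assert np.array_equal(t1.tad_truth[c], t2.tad_truth[c])
        assert np.allclose(t1.gc_content[c], t2.gc_content[c])
    pd.testing.assert_frame_equal(t1.gene_table, t2.gene_table)


def test_variant_density_and_bounds(small_truth, small_cfg):
    v = small_truth.variant_table
    total_kb = sum(small_cfg.chrom_lengths.values()) / 1000.0
    expected = total_kb * small_cfg.snv_density
    # Poisson draw: within 5 sigma of the configured density
    assert abs(len(v) - expected) < 5 * np.sqrt(expected)
    for c, L in small_cfg.chrom_lengths.items():
        on = v[v.CHROM == c]
        assert (on.POS >= 0).all() and (on.POS < L).all()
        assert on.POS.is_monotonic_increasing
    assert set(v.GT.unique()) <= {"0|1", "1|0"}
    assert (v.loc[~v.is_indel, "indel_len"] == 0).all()
    assert (v.loc[v.is_indel, "indel_len"] > 0).all()


def test_planted_elements_in_bounds(small_truth, small_cfg):
    binning = small_cfg.binning
    for c, pb, eb, f in small_truth.pei_truth:
        assert 0 <= pb < binning.n_bins(c)
        assert 0 <= eb < binning.n_bins(c)
        assert f >= 1
    for g in small_truth.gene_table.itertuples():
        assert 0 <= g.start < g.end <= small_cfg.chrom_lengths[g.chrom]
        assert 0 <= g.tss < small_cfg.chrom_lengths[g.chrom]
    for c in small_cfg.chrom_lengths:
        n = binning.n_bins(c)
        assert all(0 < b < n for b in small_truth.tad_truth[c])
        assert len(small_truth.compartment_truth[c]) == n
        assert set(np.unique(small_truth.compartment_truth[c])) <= {-1, 1}


def test_contact_record_schema_and_positions(small_truth, small_cfg):
    rec = simulate_contacts(small_truth, small_cfg)
    assert len(rec) == small_cfg.n_contacts
    for col in ("chrom1", "pos1", "chrom2", "pos2",
                "v1_h1", "v1_h2", "v2_h1", "v2_h2", "true1", "true2"):
        assert col in rec.columns
    for c, L in small_cfg.chrom_lengths.items():
        assert rec.loc[rec.chrom1 == c, "pos1"].between(0, L - 1).all()
        assert rec.loc[rec.chrom2 == c, "pos2"].between(0, L - 1).all()
    assert set(rec.true1.unique()) <= {1, 2}
    # inter-homolog records are planted with true1 != true2 on one chromosome
    trans = rec[(rec.chrom1 == rec.chrom2) & (rec.true1 != rec.true2)]
    frac = len(trans) / len(rec)
    assert abs(frac - small_cfg.inter_homolog_fraction) < 0.01


def test_decay_exponent_recovery_without_structure():
    # no checkerboard, no TAD elevation, no PEIs, no random ligation:
    # the log-log fit over distance must recover the planted exponent.
    cfg = SimConfig(chrom_lengths={"chr1": 10_000_000}, seed=4,
                    compartment_strength=1.0, tad_strength=1.0,
                    n_pei_per_chrom=0, random_ligation_fraction=0.0,
                    decay_exponent=-1.0)
    truth = make_truth(cfg)
    m = simulate_matrix(truth, "chr1", n_contacts=2_000_000,
                        rng=np.random.default_rng(8))
    _, _, slope = matrix_ops.expected_by_distance(m, fit_range=(1, 100))
    assert abs(slope - cfg.decay_exponent) < 0.05


def test_simulate_matrix_symmetric(small_truth):
    m = simulate_matrix(small_truth, "chr1", n_contacts=50_000,
                        rng=np.random.default_rng(0))
    assert np.allclose(m, m.T)
    assert (m >= 0).all()


def test_expression_design_and_breed_effect(small_truth, small_cfg):
    om = simulate_expression_and_population(small_truth, small_cfg)
    gc = om.gene_counts
    assert set(gc.cross.unique()) == {"BxL", "LxB"}
    # maternal haplotype comes from the dam: layer in BxL, broiler in LxB
    assert (gc.loc[gc.cross == "BxL", "maternal_breed"] == "layer").all()
    assert (gc.loc[gc.cross == "LxB", "maternal_breed"] == "broiler").all()
    # planted breed-effect genes favor the same breed in both directions
    eff = small_truth.expression_truth
    fav = eff[eff.breed_effect_fold > 1]
    pooled = gc.groupby(["gene", "cross"])[["maternal_count", "paternal_count"]].sum()
    for g in fav.gene:
        for cross in ("BxL", "LxB"):
            row = pooled.loc[(g, cross)]
            total = row.maternal_count + row.paternal_count
            if total < 50:
                continue
            breed_is_maternal = (cross == "BxL") == (fav.set_index("gene")
                                                     .loc[g, "favored_breed"] == "layer")
            ratio = row.maternal_count / total
            assert (ratio > 0.5) == breed_is_maternal


def test_population_genotypes_shape(small_truth, small_cfg):
    om = simulate_expression_and_population(small_truth, small_cfg)
    for pop in ("pop1", "pop2"):
        g = om.genotypes[pop]
        assert g.shape == (small_cfg.n_pop_sites, small_cfg.n_per_pop)
        assert set(np.unique(g)) <= {0, 1, 2}
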