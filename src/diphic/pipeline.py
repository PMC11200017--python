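"""End-to-end orchestration of the diploid Hi-C pipeline on synthetic data.

``run_pipeline`` takes one structured config, simulates a reciprocal-cross
design (stages x cross directions x replicate families), runs every stage
— phasing, imputation, balancing, homolog pairing, compartments, TADs,
PEIs/RPS, allelic expression, FST — and assembles a summary table of the
three comparison axes:

* breed axis: the two haplotypes of the same sample are a natural pair;
* parent axis: maternal vs paternal haplotypes across reciprocal families;
* stage axis: the same family sampled at neighboring stages.

Reruns with the same config and seed are byte-identical; every derived
random stream is seeded deterministically from the single global seed. All
pinned thresholds are logged per run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase, compartments, io, matrix_ops, pairing, pei, phasing, tads
from .simulate import (SimConfig, make_truth, simulate_contacts,
                       simulate_expression_and_population)
from . import variants as var_mod

log = logging.getLogger(__name__)

PINNED_THRESHOLDS = {
    "ab_index_stage": 1.0, "ab_index_breed_parent": 0.3,
    "lbs_delta": 0.2, "rps_stage": 3.0, "rps_breed_parent": 0.3,
    "high_fst": 0.75, "min_tpm": 0.5,
}


@dataclass
class PipelineConfig:
    sim: SimConfig
    stages: tuple = ("E15", "D1")
    out_dir: str = "pipeline_out"
    candidate_resolutions: tuple = (5_000, 20_000, 100_000)

    @classmethod
    def from_yaml(cls, path):
        import yaml
        raw = yaml.safe_load(Path(path).read_text())
        sim = SimConfig(**raw["sim"])
        kw = {k: v for k, v in raw.items() if k != "sim"}
        if "stages" in kw:
            kw["stages"] = tuple(kw["stages"])
        return cls(sim=sim, **kw)


def _sample_seed(base: int, stage: str, cross: str, rep: int) -> int:
    # stable across processes (Python's hash() is salted per run)
    import zlib
    h = zlib.crc32(f"{stage}|{cross}|{rep}".encode()) % 100_000
    return (base * 1_000_003 + h) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write tracks, tables and the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pinned thresholds: %s", PINNED_THRESHOLDS)
    base = config.sim

    # --- simulate and process each sample -------------------------------
    samples = {}
    truth0 = None
    for stage in config.stages:
        for cross in ("BxL", "LxB"):
            for rep in range(1, base.n_replicates + 1):
                seed = _sample_seed(base.seed, stage, cross, rep)
                cfg = replace(base, stage=stage, cross=cross, seed=seed)
                truth = make_truth(cfg)
                if truth0 is None:
                    truth0 = truth
                samples[(stage, cross, rep)] = _process_sample(cfg, truth)
    binning = base.binning

    # --- map resolution on the first sample's raw ends ------------------
    first = next(iter(samples.values()))
    res = phasing.map_resolution(first["end_positions"], base.chrom_lengths,
                                 config.candidate_resolutions)

    # --- homolog pairing (pooled M12 across samples) ---------------------
    tracks = []
    for chrom in binning.chroms:
        pooled = sum(s["pmap"].M12[chrom] for s in samples.values())
        tracks.append(pairing.hps_track(pooled, chrom, base.bin_size,
                                        mask=binning.full_bin_mask(chrom)))
    tight = pairing.call_tight_regions(tracks)
    for t in tracks:
        io.write_bedgraph(out / f"hps_{t.chrom}.bedgraph", t.chrom, t.hps,
                          base.bin_size, base.chrom_lengths[t.chrom])
    io.write_bed(out / "tight_regions.bed",
                 [(c, s * base.bin_size, e * base.bin_size)
                  for c, regs in tight.regions.items() for s, e in regs])

    # --- per-axis differential summaries ---------------------------------
    summary = {}
    reps = [(cross, rep) for cross in ("BxL", "LxB")
            for rep in range(1, base.n_replicates + 1)]

    def profiles(stage, hap):
        return [samples[(stage, c, r)][f"profile_h{hap}"] for c, r in reps]

    def rps_tables(stage, hap):
        return [samples[(stage, c, r)][f"rps_h{hap}"] for c, r in reps]

    def matrices(stage, hap, chrom):
        return [samples[(stage, c, r)][f"bal_h{hap}"][chrom] for c, r in reps]

    # breed axis: hap1 (breed A) vs hap2 (breed B) within each stage
    for stage in config.stages:
        diff = compartments.differential_compartments(
            profiles(stage, 1), profiles(stage, 2), axis="breed")
        drps = pei.differential_rps(rps_tables(stage, 1), rps_tables(stage, 2),
                                    axis="breed")
        shifts = _boundary_shifts(samples, reps, stage, binning)
        summary[f"breed_{stage}"] = {
            "switched_mb": diff.total_mb("switched", base.bin_size),
            "variable_mb": diff.total_mb("variable", base.bin_size),
            "shifted_boundaries": len(shifts),
            "differential_rps_genes": int(drps.flagged.sum()),
            "similarity_genomedisco": _mean_disco(samples, reps, stage, binning),
        }

    # stage axis: neighboring stages, same family, same haplotype
    for s1, s2 in zip(config.stages[:-1], config.stages[1:]):
        diff = compartments.differential_compartments(
            profiles(s1, 1) + profiles(s1, 2),
            profiles(s2, 1) + profiles(s2, 2), axis="stage")
        drps = pei.differential_rps(rps_tables(s1, 1) + rps_tables(s1, 2),
                                    rps_tables(s2, 1) + rps_tables(s2, 2),
                                    axis="stage")
        summary[f"stage_{s1}_vs_{s2}"] = {
            "switched_mb": diff.total_mb("switched", base.bin_size),
            "variable_mb": diff.total_mb("variable", base.bin_size),
            "differential_rps_genes": int(drps.flagged.sum()),
        }

    # parent axis: maternal vs paternal haplotype across reciprocal families.
    # hap1 carries hap_breeds[0]; in a BxL cross (sire x dam) the dam is
    # hap_breeds[1], so the maternal haplotype is hap2 for BxL and hap1 for LxB.
    for stage in config.stages:
        mat, pat = [], []
        for cross, rep in reps:
            s = samples[(stage, cross, rep)]
            m_h = 2 if cross == "BxL" else 1
            p_h = 1 if cross == "BxL" else 2
            mat.append(s[f"profile_h{m_h}"])
            pat.append(s[f"profile_h{p_h}"])
        diff = compartments.differential_compartments(mat, pat, axis="parent")
        mat_r = [samples[(stage, c, r)][f"rps_h{2 if c == 'BxL' else 1}"]
                 for c, r in reps]
        pat_r = [samples[(stage, c, r)][f"rps_h{1 if c == 'BxL' else 2}"]
                 for c, r in reps]
        drps = pei.differential_rps(mat_r, pat_r, axis="parent")
        summary[f"parent_{stage}"] = {
            "switched_mb": diff.total_mb("switched", base.bin_size),
            "variable_mb": diff.total_mb("variable", base.bin_size),
            "differential_rps_genes": int(drps.flagged.sum()),
        }

    # --- allelic expression & imprinting screen --------------------------
    omics = simulate_expression_and_population(truth0, replace(base, seed=base.seed))
    screen = ase.imprinting_screen(omics.gene_counts)
    screen.to_csv(out / "imprinting_screen.tsv", sep="\t", index=False)
    summary["imprinting_candidates"] = int(
        (screen.classification == "imprinting_candidate").sum())
    summary["breed_effect_genes"] = int(
        (screen.classification == "breed_effect").sum())

    # --- population FST ----------------------------------------------------
    fst = var_mod.weir_cockerham_fst(omics.genotypes["pop1"], omics.genotypes["pop2"])
    site_fst = omics.site_table.assign(fst=fst)
    site_fst.to_csv(out / "site_fst.tsv", sep="\t", index=False)
    summary["high_fst_sites"] = int((site_fst.fst >= var_mod.HIGH_FST).sum())
    summary["phasing"] = {k: round(v, 4)
                          for k, v in first["pmap"].fractions.items()}
    summary["selected_resolution_bp"] = res.selected

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_summary_table(out / "summary.tsv", summary)
    return {"summary": summary, "samples": samples, "tight": tight,
            "resolution": res, "screen": screen, "site_fst": site_fst,
            "truth": truth0}


def _process_sample(cfg: SimConfig, truth) -> dict:
    records = simulate_contacts(truth, cfg)
    binning = cfg.binning
    pmap = phasing.phase_contacts(records, binning)
    pmap = phasing.impute_local(pmap, seed=cfg.seed + 7)
    ends = {}
    for chrom in binning.chroms:
        p1 = records.loc[records.chrom1 == chrom, "pos1"].to_numpy()
        p2 = records.loc[records.chrom2 == chrom, "pos2"].to_numpy()
        ends[chrom] = np.concatenate([p1, p2])
    sample = {"pmap": pmap, "end_positions": ends}
    for hap, M in ((1, pmap.M11), (2, pmap.M22)):
        bal, covs, mats = {}, {}, {}
        for chrom in binning.chroms:
            bal[chrom] = matrix_ops.kr_balance(M[chrom]).matrix
            covs[chrom] = truth.gc_content[chrom]
            mats[chrom] = bal[chrom]
        sample[f"bal_h{hap}"] = mats
        sample[f"profile_h{hap}"] = compartments.ab_index(mats, covs, cfg.bin_size)
        # TADs + PEI on the first chromosome's raw counts (finer stages)
        chrom0 = binning.chroms[0]
        raw = M[chrom0]
        di = tads.directionality_index(raw, cfg.bin_size)
        ins = tads.insulation_index(raw, cfg.bin_size)
        part = tads.call_tads(di, ins, chrom0, cfg.bin_size)
        sample[f"tads_h{hap}"] = part
        model = pei.fit_expected(raw, part, cfg.bin_size)
        promoters = {g.gene: int(g.tss // cfg.bin_size)
                     for g in truth.gene_table.itertuples() if g.chrom == chrom0}
        cands = sorted({eb for c, pb, eb, f in truth.pei_truth if c == chrom0}
                       | set(np.arange(0, binning.n_bins(chrom0), 7)))
        called = pei.call_peis(raw, model, promoters, cands)
        sample[f"pei_h{hap}"] = called
        sample[f"rps_h{hap}"] = pei.rps_table(called, sorted(promoters))
    return sample


def _boundary_shifts(samples, reps, stage, binning):
    chrom0 = binning.chroms[0]
    bounds = sorted({b for c, r in reps
                     for b in samples[(stage, c, r)]["tads_h1"].boundaries}
                    | {b for c, r in reps
                       for b in samples[(stage, c, r)]["tads_h2"].boundaries})
    m1 = [samples[(stage, c, r)]["bal_h1"][chrom0] for c, r in reps]
    m2 = [samples[(stage, c, r)]["bal_h2"][chrom0] for c, r in reps]
    if len(m1) < 2:
        return []
    return tads.shifted_boundaries(m1, m2, bounds)


def _mean_disco(samples, reps, stage, binning):
    chrom0 = binning.chroms[0]
    vals = []
    for c, r in reps:
        s = samples[(stage, c, r)]
        vals.append(matrix_ops.genomedisco_score(
            s["bal_h1"][chrom0], s["bal_h2"][chrom0]).score)
    return float(np.mean(vals))


def _write_summary_table(path, summary: dict):
    rows = []
    for key, val in summary.items():
        if isinstance(val, dict):
            for k2, v2 in val.items():
                rows.append((key, k2, v2))
        else:
            rows.append((key, "", val))
    pd.DataFrame(rows, columns=["comparison", "measure", "value"]).to_csv(
        path, sep="\t", index=False)
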