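"""Plain-text I/O: sparse contact matrices, BED/bedGraph/BEDPE tracks.

The sparse contact format is three whitespace-separated columns
``bin_i bin_j count`` (upper triangle only) with a sidecar
``<name>.bins.tsv`` describing the binning. All interval output is
0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeBinning


def write_sparse_matrix(path, matrix: np.ndarray, chrom: str, bin_size: int):
    m = np.asarray(matrix)
    iu, ju = np.triu_indices(m.shape[0])
    nz = m[iu, ju] != 0
    df = pd.DataFrame({"bin_i": iu[nz], "bin_j": ju[nz], "count": m[iu, ju][nz]})
    df.to_csv(path, sep="\t", index=False)
    side = Path(str(path) + ".bins.tsv")
    side.write_text(f"chrom\tbin_size\tn_bins\n{chrom}\t{bin_size}\t{m.shape[0]}\n")


def read_sparse_matrix(path) -> tuple:
    side = pd.read_csv(str(path) + ".bins.tsv", sep="\t")
    n = int(side.n_bins.iloc[0])
    df = pd.read_csv(path, sep="\t")
    m = np.zeros((n, n))
    m[df.bin_i, df.bin_j] = df["count"]
    m[df.bin_j, df.bin_i] = df["count"]
    return m, str(side.chrom.iloc[0]), int(side.bin_size.iloc[0])


def write_bed(path, intervals, extra_cols=None):
    """``intervals``: iterable of (chrom, start_bp, end_bp, *rest)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
    _ = extra_cols


def write_bedgraph(path, chrom: str, values: np.ndarray, bin_size: int,
                   chrom_length: int = None):
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if np.isnan(v):
                continue
            end = (i + 1) * bin_size
            if chrom_length is not None:
                end = min(end, chrom_length)
            fh.write(f"{chrom}\t{i * bin_size}\t{end}\t{v:.6g}\n")


def write_bedpe(path, pairs: pd.DataFrame, chrom: str, bin_size: int):
    """PEI pairs (promoter_bin, enhancer_bin, oe, q) as BEDPE."""
    with open(path, "w") as fh:
        for r in pairs.itertuples():
            fh.write("\t".join(map(str, [
                chrom, r.promoter_bin * bin_size, (r.promoter_bin + 1) * bin_size,
                chrom, r.enhancer_bin * bin_size, (r.enhancer_bin + 1) * bin_size,
                getattr(r, "gene", "."), f"{r.oe:.4g}", f"{r.q:.3g}"])) + "\n")


def write_variants_tsv(path, variants: pd.DataFrame):
    """Minimal VCF-like TSV: CHROM POS REF ALT GT (phased)."""
    variants[["CHROM", "POS", "REF", "ALT", "GT"]].to_csv(path, sep="\t", index=False)


def binning_from_config(chrom_lengths: dict, bin_size: int) -> GenomeBinning:
    return GenomeBinning(chrom_lengths, bin_size)
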