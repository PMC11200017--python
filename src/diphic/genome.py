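"""Genome binning shared by all stages.

Coordinates are 0-based, half-open throughout. The last bin of a chromosome
may be partial; it is kept but flagged so normalization statistics can
exclude it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-width binning of a genome.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp.
    bin_size
        Bin width in bp.
    """

    chrom_lengths: dict
    bin_size: int
    _n_bins: dict = field(init=False, repr=False, default=None)
    _offsets: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for c, L in self.chrom_lengths.items():
            if L <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")
        n_bins = {c: int(np.ceil(L / self.bin_size)) for c, L in self.chrom_lengths.items()}
        offsets = {}
        off = 0
        for c in self.chrom_lengths:
            offsets[c] = off
            off += n_bins[c]
        object.__setattr__(self, "_n_bins", n_bins)
        object.__setattr__(self, "_offsets", offsets)

    @property
    def chroms(self) -> list:
        return list(self.chrom_lengths)

    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    @property
    def total_bins(self) -> int:
        return sum(self._n_bins.values())

    def offset(self, chrom: str) -> int:
        """Global bin index of the chromosome's first bin."""
        return self._offsets[chrom]

    def bin_of(self, chrom: str, pos) -> np.ndarray:
        """Chromosome-local bin index of position(s)."""
        pos = np.asarray(pos)
        if np.any(pos < 0) or np.any(pos >= self.chrom_lengths[chrom]):
            raise ValueError(f"position out of range on {chrom}")
        return pos // self.bin_size

    def partial_last_bin(self, chrom: str) -> bool:
        return self.chrom_lengths[chrom] % self.bin_size != 0

    def full_bin_mask(self, chrom: str) -> np.ndarray:
        """Boolean mask of bins spanning a full bin_size of sequence."""
        m = np.ones(self._n_bins[chrom], dtype=bool)
        if self.partial_last_bin(chrom):
            m[-1] = False
        return m

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self._n_bins[chrom]) * self.bin_size

    def bin_ends(self, chrom: str) -> np.ndarray:
        return np.minimum(self.bin_starts(chrom) + self.bin_size, self.chrom_lengths[chrom])
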