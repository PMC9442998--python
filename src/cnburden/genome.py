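"""Fixed genomic bin frame shared by all copy-number profiles.

The analysis operates on a constant-width binning of the reference genome
(GRCh37 chromosome lengths, 500-kb bins, half-open 0-based coordinates).
Burden statistics are restricted to autosomal bins; sex-chromosome bins may
be carried through profiles but are flagged non-autosomal and excluded from
every burden denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_SIZE = 500_000

#: GRCh37 (hg19) chromosome lengths in bp.
GRCH37_LENGTHS = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}

AUTOSOMES = tuple(str(c) for c in range(1, 23))
CHROM_ORDER = AUTOSOMES + ("X", "Y")


def chrom_sort_key(chrom: str) -> int:
    return CHROM_ORDER.index(str(chrom))


@dataclass(frozen=True)
class GenomeBins:
    """Ordered, non-overlapping fixed-width bins over a reference genome.

    ``df`` has columns ``chrom`` (str), ``start``, ``end`` (int, 0-based
    half-open) and ``autosome`` (bool), sorted by (chromosome order, start).
    """

    df: pd.DataFrame
    bin_size: int = BIN_SIZE
    _chrom_slices: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        chroms = self.df["chrom"].to_numpy()
        starts = self.df["start"].to_numpy()
        # validate ordering / overlap within chromosome
        for chrom in pd.unique(chroms):
            idx = np.flatnonzero(chroms == chrom)
            if not np.all(np.diff(idx) == 1):
                raise ValueError(f"bins of chromosome {chrom} are not contiguous in the frame")
            sub = self.df.iloc[idx]
            if not sub["start"].is_monotonic_increasing:
                raise ValueError(f"bins of chromosome {chrom} not sorted by start")
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping bins on chromosome {chrom}")
            object.__setattr__(self, "_chrom_slices",
                               {**self._chrom_slices, str(chrom): slice(idx[0], idx[-1] + 1)})
        _ = starts  # ordering validated per chromosome above

    @classmethod
    def grch37(cls, bin_size: int = BIN_SIZE, include_sex: bool = False) -> "GenomeBins":
        """Build the standard 500-kb frame (5,772 autosomal bins)."""
        rows = []
        chroms = CHROM_ORDER if include_sex else AUTOSOMES
        for chrom in chroms:
            length = GRCH37_LENGTHS[chrom]
            for start in range(0, length, bin_size):
                rows.append((chrom, start, min(start + bin_size, length), chrom in AUTOSOMES))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "autosome"])
        return cls(df=df, bin_size=bin_size)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def autosomal(self) -> np.ndarray:
        """Boolean mask of autosomal bins."""
        return self.df["autosome"].to_numpy()

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        """Global bin-index slice of one chromosome."""
        return self._chrom_slices[str(chrom)]

    def bin_span(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Half-open global bin-index range overlapping [start, end) on ``chrom``."""
        sl = self.chrom_slice(chrom)
        starts = self.df["start"].to_numpy()[sl]
        ends = self.df["end"].to_numpy()[sl]
        hit = np.flatnonzero((starts < end) & (ends > start))
        if hit.size == 0:
            raise ValueError(f"no bins overlap {chrom}:{start}-{end}")
        return sl.start + hit[0], sl.start + hit[-1] + 1

    def key_frame(self) -> pd.DataFrame:
        """(chrom, start, end) key columns, for joins against on-disk tables."""
        return self.df[["chrom", "start", "end"]].copy()
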