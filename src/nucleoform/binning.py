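"""Genome binning: fixed-size, half-open bins with a contiguous global index.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``. Each chromosome is tiled by ``ceil(length / bin_size)``
bins; the last bin may be shorter than ``bin_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["GenomeBinning", "bin_genome", "read_chrom_sizes", "write_chrom_sizes"]


@dataclass(frozen=True)
class GenomeBinning:
    """Partition of a genome into fixed-size bins.

    Attributes
    ----------
    chroms : tuple of str
        Chromosome names in genome order; the global bin index follows
        this order.
    chrom_lengths : dict
        Chromosome lengths in base pairs.
    bin_size : int
        Nominal bin width in base pairs.
    """

    chroms: tuple[str, ...]
    chrom_lengths: dict[str, int]
    bin_size: int
    # derived arrays, filled in __post_init__
    bin_chrom_idx: np.ndarray = field(repr=False, compare=False, default=None)
    bin_start: np.ndarray = field(repr=False, compare=False, default=None)
    bin_end: np.ndarray = field(repr=False, compare=False, default=None)
    chrom_offsets: dict[str, int] = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        chrom_idx, starts, ends = [], [], []
        offsets: dict[str, int] = {}
        for ci, name in enumerate(self.chroms):
            length = self.chrom_lengths[name]
            offsets[name] = len(starts)
            n = -(-length // self.bin_size)  # ceil division
            for b in range(n):
                s = b * self.bin_size
                chrom_idx.append(ci)
                starts.append(s)
                ends.append(min(s + self.bin_size, length))
        object.__setattr__(self, "bin_chrom_idx", np.asarray(chrom_idx, dtype=np.int64))
        object.__setattr__(self, "bin_start", np.asarray(starts, dtype=np.int64))
        object.__setattr__(self, "bin_end", np.asarray(ends, dtype=np.int64))
        object.__setattr__(self, "chrom_offsets", offsets)

    @property
    def n_bins(self) -> int:
        return len(self.bin_start)

    def n_bins_of(self, chrom: str) -> int:
        length = self.chrom_lengths[chrom]
        return -(-length // self.bin_size)

    def bin_index(self, chrom: str, start: int) -> int:
        """Global index of the bin whose start coordinate is ``start``."""
        if chrom not in self.chrom_offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start % self.bin_size != 0:
            raise ValueError(
                f"{start} is not a bin start for bin size {self.bin_size}"
            )
        if not 0 <= start < self.chrom_lengths[chrom]:
            raise ValueError(f"start {start} outside {chrom} "
                             f"(length {self.chrom_lengths[chrom]})")
        return self.chrom_offsets[chrom] + start // self.bin_size

    def bins_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of bins overlapping ``[start, end)`` on ``chrom``."""
        if chrom not in self.chrom_offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        length = self.chrom_lengths[chrom]
        if start < 0 or end > length or end <= start:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds "
                f"(length {length})"
            )
        first = start // self.bin_size
        last = (end - 1) // self.bin_size  # inclusive
        off = self.chrom_offsets[chrom]
        return np.arange(off + first, off + last + 1, dtype=np.int64)

    def chrom_slice(self, chrom: str) -> slice:
        off = self.chrom_offsets[chrom]
        return slice(off, off + self.n_bins_of(chrom))

    def bin_widths(self) -> np.ndarray:
        """Per-bin width in bp (terminal bins may be short)."""
        return (self.bin_end - self.bin_start).astype(np.int64)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [self.chroms[i] for i in self.bin_chrom_idx],
                "start": self.bin_start,
                "end": self.bin_end,
            }
        )

    def same_grid(self, other: "GenomeBinning") -> bool:
        return (
            self.chroms == other.chroms
            and self.chrom_lengths == other.chrom_lengths
            and self.bin_size == other.bin_size
        )


def bin_genome(chrom_sizes: Mapping[str, int], bin_size: int) -> GenomeBinning:
    """Partition chromosomes into fixed-size half-open bins.

    Parameters
    ----------
    chrom_sizes : mapping
        Chromosome name -> length in bp. Iteration order defines the
        genome order and hence the global bin index.
    bin_size : int
        Bin width in bp.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    for name, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
    return GenomeBinning(
        chroms=tuple(chrom_sizes),
        chrom_lengths=dict(chrom_sizes),
        bin_size=int(bin_size),
    )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str})
    if df["length"].isna().any() or not np.issubdtype(df["length"].dtype, np.integer):
        raise ValueError(f"{path}: lengths must be integers")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")
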