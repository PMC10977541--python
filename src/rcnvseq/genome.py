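"""Reference coordinate system: chromosome lengths and the fixed-width bin grid.

Low-pass copy-number calling never needs the genome sequence itself, only a
coordinate frame: 24 chromosome lengths (hg19) and a tiling of each chromosome
into fixed-width bins (default 20 kb) that every downstream count, estimate and
call refers back to.  GC content per bin is carried on the grid; since no
sequence is shipped, GC tracks are synthetic (a smooth, seeded random field)
and serve to exercise the bias-correction stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("chrX", "chrY")

DEFAULT_BIN_WIDTH = 20_000


def _data_path(name: str) -> Path:
    return Path(str(resources.files("rcnvseq").joinpath("data").joinpath(name)))


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names and lengths; the coordinate authority.

    Parameters
    ----------
    lengths : dict mapping chromosome name to length in bp (1-based inclusive
        coordinates end at this value).  Order of insertion is preserved and
        defines plotting/reporting order.
    name : free-text label ("hg19", "toy", ...).
    """

    lengths: dict[str, int]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.lengths)) != len(self.lengths):
            raise ValueError("chromosome names must be unique")
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def is_autosome(self, chrom: str) -> bool:
        return chrom not in ("chrX", "chrY")


def hg19() -> GenomeModel:
    """The packaged hg19 chromosome lengths (chr1..chr22, chrX, chrY)."""
    df = pd.read_csv(_data_path("hg19_chrom_sizes.tsv"), sep="\t")
    return GenomeModel(dict(zip(df["chrom"], df["length"].astype(int))), name="hg19")


def toy_genome(scale: int = 50) -> GenomeModel:
    """hg19 shrunk by an integer factor — 24 chromosomes of a few Mb for fast tests.

    Band-level coordinates do not transfer; the toy genome is for count-level
    and profile-level behaviour only.
    """
    full = hg19()
    lengths = {c: max(length // scale, 200_000) for c, length in full.lengths.items()}
    return GenomeModel(lengths, name=f"toy/{scale}")


class BinGrid:
    """The genome tiled into fixed-width, 1-based inclusive bins.

    Bin k of a chromosome covers [w*(k-1)+1, w*k], the last bin truncated at
    the chromosome end.  Bins tile each chromosome without gap or overlap.
    """

    def __init__(self, genome: GenomeModel, bin_width: int, gc: np.ndarray | None = None):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.genome = genome
        self.bin_width = int(bin_width)

        chroms, starts, ends = [], [], []
        offsets = {}
        n = 0
        for chrom, length in genome.lengths.items():
            k = -(-length // bin_width)  # ceil
            offsets[chrom] = n
            chroms.append(np.full(k, chrom, dtype=object))
            s = np.arange(k, dtype=np.int64) * bin_width + 1
            e = np.minimum(s + bin_width - 1, length)
            starts.append(s)
            ends.append(e)
            n += k
        self.chrom = np.concatenate(chroms)
        self.start = np.concatenate(starts)
        self.end = np.concatenate(ends)
        self._offsets = offsets
        self.n_bins = n
        if gc is None:
            gc = np.full(n, 0.41)
        gc = np.asarray(gc, dtype=float)
        if gc.shape != (n,):
            raise ValueError(f"gc must have one value per bin ({n})")
        if np.any((gc < 0) | (gc > 1)):
            raise ValueError("GC fractions must lie in [0, 1]")
        self.gc = gc
        self.autosomal = np.array([genome.is_autosome(c) for c in self.chrom])

    # -- indexing helpers -------------------------------------------------
    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index range of a chromosome's bins."""
        if chrom not in self._offsets:
            raise KeyError(chrom)
        off = self._offsets[chrom]
        k = -(-self.genome.lengths[chrom] // self.bin_width)
        return slice(off, off + k)

    def n_chrom_bins(self, chrom: str) -> int:
        s = self.chrom_slice(chrom)
        return s.stop - s.start

    def bin_index(self, chrom: str, pos: int) -> int:
        """Index of the bin containing a 1-based position (boundary -> lower bin)."""
        if chrom not in self._offsets:
            raise KeyError(chrom)
        if pos < 1 or pos > self.genome.lengths[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return self._offsets[chrom] + (pos - 1) // self.bin_width

    def mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of bins whose interval overlaps [start, end] (1-based)."""
        m = np.zeros(self.n_bins, dtype=bool)
        s = self.chrom_slice(chrom)
        m[s] = (self.start[s] <= end) & (self.end[s] >= start)
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end, "gc": self.gc}
        )

    def with_synthetic_gc(self, seed: int = 0, mean: float = 0.41, sd: float = 0.05,
                          smooth: int = 25) -> "BinGrid":
        """Attach a smooth synthetic GC field (moving-average Gaussian noise).

        Emulates the local autocorrelation of real GC content without any
        sequence; values are clipped to [0.25, 0.65].
        """
        rng = np.random.default_rng(seed)
        raw = rng.normal(0.0, 1.0, self.n_bins + smooth)
        kernel = np.ones(smooth) / smooth
        field = np.convolve(raw, kernel, mode="valid")[: self.n_bins]
        field = field / field.std() * sd + mean
        gc = np.clip(field, 0.25, 0.65)
        return BinGrid(self.genome, self.bin_width, gc=gc)


def build_bin_grid(genome: GenomeModel, bin_width: int = DEFAULT_BIN_WIDTH,
                   gc: np.ndarray | None = None) -> BinGrid:
    """Tile every chromosome of `genome` into `bin_width` bins (default 20 kb)."""
    return BinGrid(genome, bin_width, gc=gc)
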