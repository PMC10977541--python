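"""From aligned-read positions to per-bin counts.

The sequencing design: ~5 million single-end 45 bp raw reads per sample,
trimmed to the 36 bp genomic portion, aligned, and only uniquely mapped reads
kept (~2.8-3.2 million per sample).  Each surviving read is assigned to the
20-kb bin containing its leftmost mapped position.  Coordinates are 1-based
inclusive throughout; BED input (0-based half-open) is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import BinGrid

log = logging.getLogger(__name__)

TARGET_READ_LENGTH = 36  # genomic bases retained after adapter removal


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read: chromosome, leftmost mapped 1-based position."""

    chrom: str
    pos: int
    unique: bool = True
    length: int = TARGET_READ_LENGTH

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.length <= 0:
            raise ValueError("read length must be positive")


@dataclass
class BinCounts:
    """One sample's per-bin read counts on a BinGrid.

    `counts` are non-negative; real-valued after GC correction, integer from
    raw assignment.  `total` always equals counts.sum().
    """

    sample_id: str
    grid: BinGrid
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.grid.n_bins,):
            raise ValueError("counts must have one entry per grid bin")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["count"] = self.counts
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, grid: BinGrid | None = None, sample_id: str = "sample") -> "BinCounts":
        """Read a bin-count TSV (chrom, start, end, gc, count; 1-based inclusive)."""
        df = pd.read_csv(path, sep="\t")
        if grid is None:
            from .genome import GenomeModel

            lengths = df.groupby("chrom", sort=False)["end"].max().to_dict()
            width = int((df["end"] - df["start"] + 1).max())
            grid = BinGrid(GenomeModel({c: int(v) for c, v in lengths.items()}), width,
                           gc=df["gc"].to_numpy())
        if len(df) != grid.n_bins:
            raise ValueError("bin-count table does not match grid")
        return cls(sample_id, grid, df["count"].to_numpy(float),
                   meta={"source": str(path)})


def trim_reads(raw_len: int, adapter_policy: str = "adapter36") -> int:
    """Length of genomic sequence retained after adapter trimming.

    The library design leaves 36 bp of genomic sequence in a 45 bp raw read;
    the policy caps any read at 36 bp.  Shorter reads pass through with a
    warning (degenerate input, nothing to trim to).
    """
    if adapter_policy != "adapter36":
        raise ValueError(f"unknown adapter policy {adapter_policy!r}")
    if raw_len < TARGET_READ_LENGTH:
        log.warning("read length %d below %d bp target; passing through",
                    raw_len, TARGET_READ_LENGTH)
        return raw_len
    return TARGET_READ_LENGTH


def filter_unique(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Keep uniquely mapped reads only, preserving order."""
    reads = list(reads)
    kept = [r for r in reads if r.unique]
    dropped = len(reads) - len(kept)
    if reads and not kept:
        log.warning("all %d reads non-unique; empty output", len(reads))
    elif dropped:
        log.info("dropped %d non-unique reads of %d", dropped, len(reads))
    return kept


def assign_reads_to_bins(reads: Sequence[ReadRecord], grid: BinGrid,
                         sample_id: str = "sample") -> BinCounts:
    """Tally reads into the bin containing each read's leftmost position.

    Reads on unknown chromosomes or outside chromosome bounds are rejected and
    counted in the log; the returned total equals the number of accepted reads.
    """
    counts = np.zeros(grid.n_bins, dtype=float)
    rejected = 0
    for r in reads:
        try:
            counts[grid.bin_index(r.chrom, r.pos)] += 1
        except (KeyError, ValueError):
            rejected += 1
    if rejected:
        log.warning("rejected %d reads outside the bin grid", rejected)
    return BinCounts(sample_id, grid, counts,
                     meta={"n_input": len(reads), "n_rejected": rejected,
                           "filters": "unique;in-bounds"})


def read_sam(path, mapq_min: int = 30) -> list[ReadRecord]:
    """Read aligned positions from SAM/BAM; uniqueness = mapped and MAPQ >= threshold."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            reads.append(ReadRecord(
                chrom=aln.reference_name,
                pos=aln.reference_start + 1,  # pysam is 0-based
                unique=(aln.mapping_quality >= mapq_min and not aln.is_secondary
                        and not aln.is_supplementary),
                length=aln.query_length or TARGET_READ_LENGTH,
            ))
    return reads


def read_bed(path, dialect: str = "bed0") -> list[ReadRecord]:
    """Read chrom/pos records from a BED-like TSV.

    dialect "bed0": 0-based half-open starts (standard BED) -> pos = start + 1.
    dialect "bed1": already 1-based positions, taken as-is.
    """
    if dialect not in ("bed0", "bed1"):
        raise ValueError(f"unknown dialect {dialect!r}")
    offset = 1 if dialect == "bed0" else 0
    reads = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            reads.append(ReadRecord(chrom=parts[0], pos=int(parts[1]) + offset))
    return reads
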