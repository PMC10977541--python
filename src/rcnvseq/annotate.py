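"""Reporting vocabulary: cytobands, ISCN-style call strings, triage categories.

A called event is reported three ways: an ISCN-like region string built from
cytoband lookup ("dup(21)(q11.2q22.3)", "(mos)" suffix for mosaics), an
HGVS-like genomic string ("chr21:g.14300000_48129895dup"), and a fragment size
(Mb to two decimals).  Case-level triage follows the diagnostic categories of
a prenatal cohort: common autosomal aneuploidy (chr 21/18/13), sex-chromosome
aneuploidy (with karyotype label from X/Y dosage), rare autosomal aneuploidy,
multiple-chromosome abnormality, then pathogenic vs uncertain-significance
CNVs for sub-chromosomal events.

The packaged cytoband table is a hand-reconstructed hg19-like banding
(synthetic stand-in for the UCSC cytoBand track, see
``data/cytoband_hg19_synthetic.tsv``): boundaries around clinically pinned
coordinates are accurate; elsewhere the banding is coarse but tiling.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CopyNumberResults, Segment, mosaic_fraction

log = logging.getLogger(__name__)

CATEGORIES = (
    "multiple_chromosome_abnormality",
    "common_autosomal_aneuploidy",
    "sex_chromosome_aneuploidy",
    "rare_autosomal_aneuploidy",
    "pathogenic_cnv",
    "vus_cnv",
    "normal",
)


class CytobandTable:
    """Banding table: per chromosome, UCSC-style half-open [start, end) bands.

    Starts in the file are 0-based (UCSC convention) and kept so internally;
    the two lookup sides implement the coordinate conventions of CNV
    reporting: an interval *start* that falls on a band boundary belongs to
    the band beginning there, an interval *end* to the band ending there.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "start", "end", "band"}
        if not required.issubset(frame.columns):
            raise ValueError(f"cytoband table needs columns {sorted(required)}")
        self._by_chrom: dict[str, pd.DataFrame] = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            sub = sub.sort_values("start").reset_index(drop=True)
            if sub["band"].duplicated().any():
                raise ValueError(f"duplicate band names on {chrom}")
            if (sub["start"].iloc[1:].to_numpy() != sub["end"].iloc[:-1].to_numpy()).any():
                raise ValueError(f"bands do not tile {chrom}")
            self._by_chrom[chrom] = sub

    @classmethod
    def load(cls, path=None) -> "CytobandTable":
        if path is None:
            path = Path(str(resources.files("rcnvseq").joinpath("data")
                            .joinpath("cytoband_hg19_synthetic.tsv")))
        df = pd.read_csv(path, sep="\t", comment=None)
        df.columns = [c.lstrip("#") for c in df.columns]
        return cls(df)

    def chromosome_span(self, chrom: str) -> tuple[int, int]:
        sub = self._by_chrom[chrom]
        return int(sub["start"].iloc[0]) + 1, int(sub["end"].iloc[-1])

    def callable_start(self, chrom: str) -> int:
        """Start of the first euchromatic band (skipping acen/gvar/stalk blocks).

        Whole-chromosome events on acrocentric chromosomes are reported from
        here rather than from base 1: the short arm carries no callable
        sequence, so e.g. a chr21 trisomy reports as starting at the q11.2
        boundary (14.3 Mb).  Returns the UCSC (0-based) band start, floored
        at 1 so metacentric chromosomes report from base 1.
        """
        if chrom not in self._by_chrom:
            return 1
        sub = self._by_chrom[chrom]
        if "stain" not in sub.columns:
            return 1
        for _, row in sub.iterrows():
            if row["stain"] not in ("acen", "gvar", "stalk"):
                return max(int(row["start"]), 1)
        return 1

    def band_at(self, chrom: str, pos: int, side: str = "end") -> str:
        """Band name at a 1-based position.

        side="start": boundary positions map to the band starting there
        (pos is compared as a 0-based band start).  side="end": boundary
        positions map to the band ending there (ordinary 1-based containment).
        """
        if chrom not in self._by_chrom:
            raise KeyError(f"no banding for {chrom}")
        sub = self._by_chrom[chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if side == "start":
            idx = np.searchsorted(starts, pos, side="right") - 1
            if pos >= ends[-1]:
                idx = -1
        elif side == "end":
            idx = np.searchsorted(ends, pos, side="left")
            if idx == len(ends):
                idx = -1
        else:
            raise ValueError("side must be 'start' or 'end'")
        if idx < 0 or pos < 1 or pos > ends[-1]:
            raise ValueError(f"position {chrom}:{pos} outside band table")
        return str(sub["band"].iloc[int(idx)])


def band_lookup(chrom: str, start: int, end: int, bands: CytobandTable) -> str:
    """Region string "<band(start)><band(end)>", collapsed when both agree."""
    if end < start:
        raise ValueError("end must be >= start")
    b1 = bands.band_at(chrom, start, side="start")
    b2 = bands.band_at(chrom, end, side="end")
    return b1 if b1 == b2 else b1 + b2


def fragment_size(start: int, end: int) -> int:
    """Inclusive span in bp; end < start rejected."""
    if end < start:
        raise ValueError(f"end {end} before start {start}")
    return end - start + 1


def size_mb(start: int, end: int) -> float:
    """Fragment size rendered in Mb to 2 decimals (reporting convention)."""
    return round(fragment_size(start, end) / 1e6, 2)


@dataclass
class CNVCall:
    """One reportable event with its nomenclature strings."""

    chrom: str
    start: int
    end: int
    event_type: str  # dup | del
    mosaic: bool
    cn: float
    fraction: float
    band: str = ""
    iscn: str = ""
    g_notation: str = ""
    whole_chromosome: bool = False
    confident: bool = True
    z: float = float("nan")

    def __post_init__(self) -> None:
        if self.event_type not in ("dup", "del"):
            raise ValueError("event_type must be 'dup' or 'del'")

    @property
    def size(self) -> int:
        return fragment_size(self.start, self.end)

    @property
    def size_mb(self) -> float:
        return size_mb(self.start, self.end)


def format_call(call: CNVCall, bands: CytobandTable | None = None) -> tuple[str, str]:
    """(ISCN-like string, g.-notation string) for a call; fills the call in place."""
    if bands is not None:
        call.band = band_lookup(call.chrom, call.start, call.end, bands)
    short = call.chrom[3:] if call.chrom.startswith("chr") else call.chrom
    mos = "(mos)" if call.mosaic else ""
    iscn = f"{call.event_type}({short})({call.band}){mos}"
    g = f"chr{short}:g.{call.start}_{call.end}{call.event_type}"
    call.iscn, call.g_notation = iscn, g
    return iscn, g


_ISCN_RE = re.compile(r"^(dup|del)\(([0-9XY]+)\)\(([pq][\d.]+(?:[pq][\d.]+)?)\)(\(mos\))?$")
_G_RE = re.compile(r"^chr([0-9XY]+):g\.(\d+)_(\d+)(dup|del)$")


def parse_call(iscn: str, g_notation: str) -> CNVCall:
    """Invert format_call; the round-trip is the identity on its fields."""
    m1 = _ISCN_RE.match(iscn.strip())
    if not m1:
        raise ValueError(f"cannot parse ISCN string {iscn!r}")
    m2 = _G_RE.match(g_notation.strip())
    if not m2:
        raise ValueError(f"cannot parse g. string {g_notation!r}")
    ev, chrom_b, band, mos = m1.groups()
    chrom_g, start, end, ev_g = m2.groups()
    if ev != ev_g or chrom_b != chrom_g:
        raise ValueError("ISCN and g. strings disagree")
    call = CNVCall(chrom="chr" + chrom_g, start=int(start), end=int(end),
                   event_type=ev, mosaic=mos is not None,
                   cn=3.0 if ev == "dup" else 1.0,
                   fraction=0.5 if mos else 1.0, band=band)
    call.iscn, call.g_notation = iscn.strip(), g_notation.strip()
    return call


# ---------------------------------------------------------------------------
# triage

#: (X copies, Y copies) -> karyotype label
SEX_KARYOTYPE_MAP = {
    (1, 0): "45,X", (2, 0): "46,XX", (1, 1): "46,XY",
    (2, 1): "47,XXY", (1, 2): "47,XYY", (3, 0): "47,XXX", (1, 3): "48,XYYY",
}


@dataclass(frozen=True)
class PathogenicRegion:
    name: str
    chrom: str
    start: int
    end: int

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start <= self.end and end >= self.start


@dataclass
class TriageRules:
    """Case-triage configuration.

    Sub-chromosomal calls are pathogenic when they overlap a curated region
    (seeded with the Xp22.31/STS deletion region, the dominant pathogenic CNV
    class) or reach `pathogenic_size_bp`; otherwise they are variants of
    uncertain significance.
    """

    common_chromosomes: tuple[str, ...] = ("chr21", "chr18", "chr13")
    pathogenic_size_bp: int = 1_000_000
    pathogenic_regions: tuple[PathogenicRegion, ...] = (
        PathogenicRegion("Xp22.31_STS", "chrX", 6_000_000, 9_500_000),
    )


@dataclass
class TriageResult:
    category: str
    karyotype_label: str | None = None
    notes: list[str] = field(default_factory=list)


def _sex_dosage_label(x_cn: float, y_cn: float) -> str:
    key = (int(round(x_cn)), int(round(y_cn)))
    if key in SEX_KARYOTYPE_MAP:
        return SEX_KARYOTYPE_MAP[key]
    return f"{44 + key[0] + key[1]},{'X' * key[0]}{'Y' * key[1]}"


def triage_case(calls: list[CNVCall], sex: str, rules: TriageRules | None = None,
                x_cn: float | None = None, y_cn: float | None = None) -> TriageResult:
    """Assign the single diagnostic category of a case.

    Precedence: multiple-chromosome abnormality (whole-chromosome events on
    >= 2 chromosomes) > common autosomal aneuploidy (21/18/13) > sex-chromosome
    aneuploidy > rare autosomal aneuploidy > pathogenic CNV > VUS > normal.

    Only confident sub-chromosomal calls count toward the CNV categories; a
    case whose only findings are low-confidence segments is triaged normal
    (the call list still carries them for review).
    """
    rules = rules or TriageRules()
    whole = [c for c in calls if c.whole_chromosome]
    whole_chroms = sorted({c.chrom for c in whole})
    sub = [c for c in calls if not c.whole_chromosome and c.confident]

    if len(whole_chroms) >= 2:
        return TriageResult("multiple_chromosome_abnormality",
                            notes=[f"whole-chromosome events on {', '.join(whole_chroms)}"])
    if any(c.chrom in rules.common_chromosomes for c in whole):
        call = next(c for c in whole if c.chrom in rules.common_chromosomes)
        kind = "trisomy" if call.event_type == "dup" else "monosomy"
        label = f"{kind} {call.chrom[3:]}" + (" (mos)" if call.mosaic else "")
        return TriageResult("common_autosomal_aneuploidy", karyotype_label=label)
    if any(c.chrom in ("chrX", "chrY") for c in whole):
        if x_cn is None:
            x_cn = 2.0 if sex == "XX" else 1.0
        if y_cn is None:
            y_cn = 0.0 if sex == "XX" else 1.0
        label = _sex_dosage_label(x_cn, y_cn)
        notes = []
        mos = [c for c in whole if c.chrom in ("chrX", "chrY") and c.mosaic]
        if mos:
            notes.append("mosaic sex-chromosome dosage")
        return TriageResult("sex_chromosome_aneuploidy", karyotype_label=label, notes=notes)
    if whole:
        call = whole[0]
        kind = "trisomy" if call.event_type == "dup" else "monosomy"
        label = f"{kind} {call.chrom[3:]}" + (" (mos)" if call.mosaic else "")
        return TriageResult("rare_autosomal_aneuploidy", karyotype_label=label)
    if sub:
        for c in sub:
            hit = next((r for r in rules.pathogenic_regions
                        if r.overlaps(c.chrom, c.start, c.end)), None)
            if hit is not None:
                return TriageResult("pathogenic_cnv", notes=[f"overlaps {hit.name}"])
            if c.size >= rules.pathogenic_size_bp:
                return TriageResult(
                    "pathogenic_cnv",
                    notes=[f"{c.size_mb} Mb >= {rules.pathogenic_size_bp/1e6:.1f} Mb floor"])
        return TriageResult("vus_cnv")
    return TriageResult("normal")


# ---------------------------------------------------------------------------
# from fitted results to annotated calls

@dataclass
class AnnotatedCase:
    """Calls + triage for one fitted sample."""

    sample_id: str
    sex: str
    calls: list[CNVCall]
    triage: TriageResult

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append({
                "sample_id": self.sample_id, "chrom": c.chrom, "start": c.start,
                "end": c.end, "type": c.event_type, "mosaic": c.mosaic,
                "cn": round(c.cn, 3), "fraction": round(c.fraction, 3),
                "size_bp": c.size, "size_mb": c.size_mb,
                "band": c.band, "iscn": c.iscn, "g_notation": c.g_notation,
                "whole_chromosome": c.whole_chromosome,
                "confident": c.confident, "z": round(float(c.z), 2),
                "category": self.triage.category,
            })
        return pd.DataFrame(rows)


def annotate_results(results: CopyNumberResults, cytobands: CytobandTable | None = None,
                     rules: TriageRules | None = None) -> AnnotatedCase:
    """Turn fitted whole-chromosome and segmental events into reportable calls."""
    bands = cytobands or CytobandTable.load()
    genome = results.profile.grid.genome
    calls: list[CNVCall] = []

    track = results.chromosome_cn
    for chrom, row in results.whole_chromosome_events.iterrows():
        gain = row.adjusted_cn > 2.0
        mosaic = row.state in ("mosaic_trisomy", "mosaic_monosomy")
        cs = bands.callable_start(chrom)
        if cs >= genome.lengths[chrom]:
            cs = 1  # band table does not fit this genome (e.g. scaled toy grids)
        call = CNVCall(chrom=chrom, start=cs,
                       end=genome.lengths[chrom],
                       event_type="dup" if gain else "del", mosaic=mosaic,
                       cn=float(row.mean_cn), fraction=float(row.mosaic_fraction),
                       whole_chromosome=True)
        format_call(call, bands)
        calls.append(call)

    for seg in results.event_segments:
        gain = seg.mean_cn > 2.0
        mosaic = seg.state in ("mosaic_trisomy", "mosaic_monosomy")
        if seg.state in ("mosaic_trisomy", "duplication"):
            f = mosaic_fraction(max(seg.mean_cn, 2.0), "gain")
        else:
            f = mosaic_fraction(min(seg.mean_cn, 2.0), "loss")
        call = CNVCall(chrom=seg.chrom, start=seg.start, end=seg.end,
                       event_type="dup" if gain else "del", mosaic=mosaic,
                       cn=float(seg.mean_cn), fraction=f,
                       confident=seg.confident, z=float(seg.z))
        format_call(call, bands)
        calls.append(call)

    x_cn = float(track.loc["chrX", "mean_cn"]) if "chrX" in track.index else None
    y_cn = float(track.loc["chrY", "mean_cn"]) if "chrY" in track.index else None
    triage = triage_case(calls, results.sex, rules, x_cn=x_cn, y_cn=y_cn)
    return AnnotatedCase(results.model.counts.sample_id, results.sex, calls, triage)
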