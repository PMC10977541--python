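"""Parser for G-banding karyotype strings.

Handles the vocabulary of a prenatal diagnostic cohort: numeric count + sex
chromosomes ("47,XY"), whole-chromosome gains/losses ("+21"), Robertsonian
and reciprocal translocations ("rob(14;21)", "t(9;15)"), inversions
("inv(9)"), heteromorphisms ("14ps+", "1qh+"), marker chromosomes ("+mar"),
and mosaic multi-line forms "47,XX+13[46]/46,XX[26]" where the bracketed cell
counts may be absent ("[]" = mosaic with unknown proportions).  "X0"/"XO" is
normalised to a bare "X" (45,X).  Whitespace is ignored throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_STRUCT_RE = re.compile(r"^(rob|t|inv|der|dup|del)\(([^)]*)\)(?:\(([^)]*)\))?$")
_HETERO_RE = re.compile(r"^\d+[pq][sh]\+$")
_GAIN_RE = re.compile(r"^\+(\d+|mar)$")
_LINE_RE = re.compile(r"^(?P<body>[^\[\]]+)(?:\[(?P<cells>\d*)\])?$")


class KaryotypeError(ValueError):
    """Unparseable karyotype token; carries the offending token."""

    def __init__(self, token: str, context: str = ""):
        self.token = token
        super().__init__(f"cannot parse karyotype token {token!r}"
                         + (f" in {context!r}" if context else ""))


@dataclass
class CellLine:
    """One karyotypic cell line of a (possibly mosaic) result."""

    count: int
    sex: str                       # e.g. "XY", "X", "XXY"
    gains: list[int] = field(default_factory=list)   # trisomic chromosomes
    losses: list[int] = field(default_factory=list)  # monosomic chromosomes
    structural: list[str] = field(default_factory=list)
    markers: int = 0
    n_cells: int | None = None     # bracketed cell count; None when "[]" or absent

    def format(self) -> str:
        parts = [str(self.count), self.sex]
        parts += self.structural
        parts += [f"+{c}" for c in sorted(self.gains)]
        parts += ["+mar"] * self.markers
        s = ",".join(parts)
        return s


@dataclass
class KaryotypeRecord:
    """Parsed karyotype: one or more cell lines, mosaic if more than one."""

    raw: str
    lines: list[CellLine]

    @property
    def mosaic(self) -> bool:
        return len(self.lines) > 1

    @property
    def primary(self) -> CellLine:
        """The abnormal line if identifiable, else the first line."""
        for line in self.lines:
            if line.gains or line.losses or line.count != 46 or line.sex not in ("XX", "XY"):
                return line
        return self.lines[0]

    def format(self) -> str:
        out = []
        for line in self.lines:
            s = line.format()
            if self.mosaic:
                s += f"[{'' if line.n_cells is None else line.n_cells}]"
            out.append(s)
        return "/".join(out)

    # -- dosage view used by concordance ----------------------------------
    def sex_dosage(self) -> tuple[int, int]:
        """(X copies, Y copies) of the primary line."""
        sex = self.primary.sex
        return sex.count("X"), sex.count("Y")

    def trisomies(self) -> set[int]:
        return set(self.primary.gains)


def _parse_line(body: str, raw: str) -> CellLine:
    tokens = [t for t in body.split(",") if t != ""]
    if len(tokens) < 2:
        raise KaryotypeError(body, raw)
    try:
        count = int(tokens[0])
    except ValueError:
        raise KaryotypeError(tokens[0], raw) from None
    sex = tokens[1].upper().replace("0", "").replace("O", "")
    gains_inline = 0
    # forms like "XX+21" glue the first gain to the sex token
    m = re.match(r"^([XY]+)((?:\+(?:\d+|mar))+)$", tokens[1].upper()
                 .replace("O", "0").replace("0", ""))
    extra: list[str] = []
    if m:
        sex = m.group(1)
        extra = re.findall(r"\+(?:\d+|mar)", m.group(2))
    if not sex or not set(sex) <= {"X", "Y"}:
        raise KaryotypeError(tokens[1], raw)

    line = CellLine(count=count, sex=sex)
    for tok in extra + tokens[2:]:
        tok = tok.strip()
        g = _GAIN_RE.match(tok)
        if g:
            if g.group(1) == "mar":
                line.markers += 1
            else:
                line.gains.append(int(g.group(1)))
            continue
        if _STRUCT_RE.match(tok) or _HETERO_RE.match(tok):
            # structural tokens may themselves carry a glued gain: "rob(15;22)+21"
            line.structural.append(tok)
            continue
        m2 = re.match(r"^((?:rob|t|inv)\([^)]*\))\+(\d+)$", tok)
        if m2:
            line.structural.append(m2.group(1))
            line.gains.append(int(m2.group(2)))
            continue
        m3 = re.match(r"^(\d+[pq][sh]\+)\+(\d+)$", tok)
        if m3:
            line.structural.append(m3.group(1))
            line.gains.append(int(m3.group(2)))
            continue
        raise KaryotypeError(tok, raw)
    return line


def parse_karyotype(s: str) -> KaryotypeRecord:
    """Parse a karyotype string, mosaic lines split on '/'.

    Whitespace-insensitive; "45,X0"-style zeros normalised away.  Raises
    KaryotypeError naming the first unparseable token.
    """
    if not s or not s.strip():
        raise KaryotypeError(s, "empty string")
    compact = re.sub(r"\s+", "", s)
    lines = []
    for part in compact.split("/"):
        m = _LINE_RE.match(part)
        if not m:
            raise KaryotypeError(part, s)
        cells = m.group("cells")
        line = _parse_line(m.group("body"), s)
        line.n_cells = int(cells) if cells else None
        lines.append(line)
    return KaryotypeRecord(raw=s, lines=lines)
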