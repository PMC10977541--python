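"""Synthetic bin-count generator with truth labels.

Emulates the study's sequencing design so every downstream stage is testable
without raw data: ~5 million 45 bp raw reads trimmed to 36 bp, of which
2.8-3.2 million map uniquely and are spread over 20-kb bins genome-wide.

The dosage model is a cell-line mixture: a region carried at target copy
number `cn` by a fraction `f` of the DNA has expected copy number
2 + f*(cn - 2) on the diploid scale.  f = 1 is a non-mosaic event; 0 < f < 1
covers mosaicism (and, formally, fetal fraction in a cfDNA reading of the
assay).  The expected read count of bin i is

    lambda_i = N * w_i * (c_i / 2) * g(GC_i) / W,

where N is the mapped-read budget, w_i the bin-width share, c_i the expected
copy number of bin i, g a GC-bias curve (identity when disabled) and W the
normalising total weight.  Counts are drawn Poisson (default), multinomial
(exact conservation of N) or negative-binomial (overdispersed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .binning import BinCounts
from .genome import BinGrid, GenomeModel

MAPPED_READ_RANGE = (2_800_000, 3_200_000)

SEX_BASELINE = {  # expected copy number of (chrX, chrY)
    "XX": (2.0, 0.0),
    "XY": (1.0, 1.0),
}


@dataclass(frozen=True)
class SequencingConfig:
    """Per-sample sequencing budget and noise model.

    n_mapped=None draws uniformly from the 2.8-3.2 million uniquely-mapped
    range; fix it for analytic comparisons.  gc_bias holds (linear, quadratic)
    coefficients of the bias curve around GC=0.41; None disables bias.
    """

    n_raw_reads: int = 5_000_000
    raw_read_len: int = 45
    trimmed_read_len: int = 36
    n_mapped: int | None = None
    noise: str = "poisson"  # poisson | multinomial | negbin
    nb_dispersion: float = 0.1
    gc_bias: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trimmed_read_len > self.raw_read_len:
            raise ValueError("trimmed length cannot exceed raw length")
        if self.n_mapped is not None and self.n_mapped > self.n_raw_reads:
            raise ValueError("mapped count cannot exceed raw read count")
        if self.noise not in ("poisson", "multinomial", "negbin"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass(frozen=True)
class TruthEvent:
    """Ground-truth copy-number event of one cell line.

    copy_number is the integer CN of the affected line; fraction f in (0, 1]
    is its share of the DNA (f=1: constitutional).  Coordinates are 1-based
    inclusive.
    """

    chrom: str
    start: int
    end: int
    copy_number: int
    fraction: float = 1.0
    kind: str = "segmental"  # segmental | whole_chromosome

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid event interval")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"mixture fraction must lie in (0, 1], got {self.fraction}")
        if self.copy_number < 0:
            raise ValueError("copy number must be non-negative")

    @property
    def expected_cn(self) -> float:
        """Mixture dosage 2 + f*(cn - 2) on the diploid scale."""
        return 2.0 + self.fraction * (self.copy_number - 2.0)

    @classmethod
    def whole_chromosome(cls, genome: GenomeModel, chrom: str, copy_number: int,
                         fraction: float = 1.0) -> "TruthEvent":
        return cls(chrom, 1, genome.lengths[chrom], copy_number, fraction,
                   kind="whole_chromosome")


def gc_bias_curve(gc: np.ndarray, coeffs: tuple[float, float] | None,
                  gc0: float = 0.41) -> np.ndarray:
    """Multiplicative bias g(GC) = exp(b1*(GC-gc0) + b2*(GC-gc0)^2); identity if None."""
    if coeffs is None:
        return np.ones_like(gc)
    b1, b2 = coeffs
    d = gc - gc0
    return np.exp(b1 * d + b2 * d * d)


def expected_copy_number(grid: BinGrid, truth: list[TruthEvent], sex: str = "XX") -> np.ndarray:
    """Per-bin expected CN: sex-chromosome baseline plus mixture events.

    Events on one chromosome must not overlap.  A bin under an event takes the
    event's mixture dosage relative to that chromosome's baseline.
    """
    if sex not in SEX_BASELINE:
        raise ValueError(f"sex must be one of {sorted(SEX_BASELINE)}")
    cn = np.full(grid.n_bins, 2.0)
    x_cn, y_cn = SEX_BASELINE[sex]
    if "chrX" in grid.genome:
        cn[grid.chrom_slice("chrX")] = x_cn
    if "chrY" in grid.genome:
        cn[grid.chrom_slice("chrY")] = y_cn

    by_chrom: dict[str, list[TruthEvent]] = {}
    for ev in truth:
        if ev.chrom not in grid.genome:
            raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
        if ev.end > grid.genome.lengths[ev.chrom]:
            raise ValueError(f"event end {ev.end} beyond {ev.chrom}")
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping events on {chrom}")
        for ev in evs:
            mask = grid.mask(ev.chrom, ev.start, ev.end)
            base = cn[mask]
            cn[mask] = base + ev.fraction * (ev.copy_number - base)
    return cn


def expected_bin_rates(grid: BinGrid, truth: list[TruthEvent],
                       seq: SequencingConfig, sex: str = "XX",
                       n_mapped: int | None = None) -> np.ndarray:
    """Expected count per bin, normalised to sum to the mapped-read budget."""
    if n_mapped is None:
        n_mapped = seq.n_mapped if seq.n_mapped is not None else int(np.mean(MAPPED_READ_RANGE))
    widths = (grid.end - grid.start + 1).astype(float)
    cn = expected_copy_number(grid, truth, sex=sex)
    weights = widths / grid.bin_width * (cn / 2.0) * gc_bias_curve(grid.gc, seq.gc_bias)
    return n_mapped * weights / weights.sum()


def simulate_case(grid: BinGrid, truth: list[TruthEvent], seq: SequencingConfig,
                  sex: str = "XX", sample_id: str = "sim") -> BinCounts:
    """Draw one sample's bin counts under the configured noise model.

    Identical grid + truth + config (including seed) reproduce identical
    counts.  The truth record travels in `meta["truth"]`.
    """
    rng = np.random.default_rng(seq.seed)
    n_mapped = seq.n_mapped
    if n_mapped is None:
        n_mapped = int(rng.integers(MAPPED_READ_RANGE[0], MAPPED_READ_RANGE[1] + 1))
    lam = expected_bin_rates(grid, truth, seq, sex=sex, n_mapped=n_mapped)
    if seq.noise == "poisson":
        counts = rng.poisson(lam).astype(float)
    elif seq.noise == "multinomial":
        counts = rng.multinomial(n_mapped, lam / lam.sum()).astype(float)
    else:  # negbin: var = lam + d*lam^2
        d = seq.nb_dispersion
        if d <= 0:
            counts = rng.poisson(lam).astype(float)
        else:
            shape = 1.0 / d
            counts = rng.poisson(rng.gamma(shape, lam * d)).astype(float)
    return BinCounts(sample_id, grid, counts, meta={
        "truth": list(truth), "sex": sex, "n_mapped": n_mapped,
        "noise": seq.noise, "seed": seq.seed,
    })


# ---------------------------------------------------------------------------
# cohort-level generation

#: category -> (sex or None meaning draw, builder of truth events)
_CATEGORY_BUILDERS = {
    "normal": lambda g, sex: [],
    "T21": lambda g, sex: [TruthEvent.whole_chromosome(g, "chr21", 3)],
    "T18": lambda g, sex: [TruthEvent.whole_chromosome(g, "chr18", 3)],
    "T13": lambda g, sex: [TruthEvent.whole_chromosome(g, "chr13", 3)],
    "mosaic_T21": lambda g, sex: [TruthEvent.whole_chromosome(g, "chr21", 3, 0.5)],
    "45,X": lambda g, sex: [TruthEvent.whole_chromosome(g, "chrX", 1)],
    "47,XXY": lambda g, sex: [TruthEvent.whole_chromosome(g, "chrX", 2)],
    "47,XYY": lambda g, sex: [TruthEvent.whole_chromosome(g, "chrY", 2)],
    "47,XXX": lambda g, sex: [TruthEvent.whole_chromosome(g, "chrX", 3)],
    "rare_T7": lambda g, sex: [TruthEvent.whole_chromosome(g, "chr7", 3)],
}

_CATEGORY_SEX = {"45,X": "XX", "47,XXY": "XY", "47,XYY": "XY", "47,XXX": "XX"}


def simulate_cohort(n_cases: int, category_mix: dict[str, float], seed: int,
                    grid: BinGrid | None = None,
                    seq: SequencingConfig | None = None) -> list[BinCounts]:
    """Reproducible cohort of simulated cases with per-case truth labels.

    Category proportions must sum to 1; each case's category, sex and seed are
    drawn from a single generator seeded by `seed`, so the same call is
    byte-identical.  Unknown categories raise.
    """
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    total = sum(category_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"category proportions must sum to 1, got {total}")
    unknown = set(category_mix) - set(_CATEGORY_BUILDERS)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    if grid is None:
        from .genome import build_bin_grid, toy_genome

        grid = build_bin_grid(toy_genome()).with_synthetic_gc(seed=0)
    if seq is None:
        seq = SequencingConfig(n_mapped=3_000_000)

    rng = np.random.default_rng(seed)
    cats = list(category_mix)
    probs = np.array([category_mix[c] for c in cats])
    cases = []
    for i in range(n_cases):
        cat = cats[rng.choice(len(cats), p=probs)]
        sex = _CATEGORY_SEX.get(cat) or ("XX" if rng.random() < 0.5 else "XY")
        case_seed = int(rng.integers(0, 2**31 - 1))
        truth = _CATEGORY_BUILDERS[cat](grid.genome, sex)
        bc = simulate_case(grid, truth, replace(seq, seed=case_seed), sex=sex,
                           sample_id=f"case{i:04d}")
        bc.meta["category"] = cat
        cases.append(bc)
    return cases
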