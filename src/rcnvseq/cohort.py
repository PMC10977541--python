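"""Cohort aggregation: case records, detection rates, demographics, concordance.

The aggregation substrate is a table of per-case records (triage category,
calls, optional G-banding karyotype, pregnancy outcome).  Detection rates are
reported as round-half-up percentages over explicit denominators; demographic
strata follow the standard high-risk-pregnancy presentation (age bands 16-24,
25-29, 30-34, 35-39, 40-44, >=45; second/third trimester).

`study_cohort()` rebuilds the 424-case study population from the published
per-category tables (anomalous-zone rows, karyotype rows, demographic strata
and follow-up narrative).  It is a reconstruction for exact aggregate
checks — case-level detail beyond the printed aggregates (e.g. which T21 case
was karyotyped) is assigned arbitrarily but deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .karyotype import KaryotypeRecord, parse_karyotype

log = logging.getLogger(__name__)

OUTCOMES = ("continued_gestation", "live_birth", "miscarriage",
            "termination_of_pregnancy", "failure_to_follow_up")

# half-open [lo, hi) so continuous ages partition the cohort
AGE_BANDS = ((16, 25), (25, 30), (30, 35), (35, 40), (40, 45), (45, 200))
AGE_BAND_LABELS = ("16-24", "25-29", "30-34", "35-39", "40-44", ">=45")

ABNORMAL_CATEGORIES = ("common_autosomal_aneuploidy", "sex_chromosome_aneuploidy",
                       "multiple_chromosome_abnormality", "rare_autosomal_aneuploidy")
CNV_CATEGORIES = ("pathogenic_cnv", "vus_cnv")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the rounding used for printed percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denom: int) -> float:
    return round_half_up(100.0 * count / denom)


@dataclass
class CaseRecord:
    """One pregnancy: triage result, optional karyotype and follow-up outcome."""

    case_id: str
    age: float | None = None
    ga_weeks: float | None = None
    category: str = "normal"
    label: str | None = None          # e.g. "trisomy 21", "47,XXY"
    zone: str | None = None           # ISCN-like region string of the main call
    mosaic: bool = False
    cnv_size_mb: float | None = None  # main sub-chromosomal call, if any
    karyotype: str | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        if self.outcome is not None and self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; "
                             f"expected one of {OUTCOMES}")


class CohortTable:
    """A list of CaseRecords with tabular views and aggregation."""

    def __init__(self, cases: list[CaseRecord]):
        if not cases:
            raise ValueError("empty cohort")
        self.cases = list(cases)

    def __len__(self) -> int:
        return len(self.cases)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.cases])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        df = pd.read_csv(path, sep="\t")
        cases = []
        for _, row in df.iterrows():
            d = {k: (None if pd.isna(v) else v) for k, v in row.items()}
            cases.append(CaseRecord(**d))
        return cls(cases)


# ---------------------------------------------------------------------------
# aggregation operations

def detection_rates(cohort: CohortTable) -> pd.DataFrame:
    """Category counts and round-half-up percentages with explicit denominators.

    Includes the derived rows "any_chromosomal_abnormality" (aneuploidy
    categories) and "any_cnv" (pathogenic + VUS), and karyotype-side rates
    over the subset of karyotyped cases.
    """
    n = len(cohort)
    df = cohort.to_frame()
    rows = []

    def add(name, count, denom):
        rows.append((name, count, denom, percent(count, denom) if denom else float("nan")))

    cat_counts = df["category"].value_counts()
    add("any_chromosomal_abnormality",
        int(df["category"].isin(ABNORMAL_CATEGORIES).sum()), n)
    for cat in ABNORMAL_CATEGORIES:
        add(cat, int(cat_counts.get(cat, 0)), n)
    add("any_cnv", int(df["category"].isin(CNV_CATEGORIES).sum()), n)
    for cat in CNV_CATEGORIES:
        add(cat, int(cat_counts.get(cat, 0)), n)
    add("normal", int(cat_counts.get("normal", 0)), n)

    karyotyped = df[df["karyotype"].notna()]
    nk = len(karyotyped)
    if nk:
        classes = karyotyped["karyotype"].map(lambda s: karyotype_class(parse_karyotype(s)))
        for cls_name in ("autosomal_aneuploidy", "sex_chromosome_aneuploidy",
                         "polyploid"):
            add(f"karyotype_{cls_name}", int((classes == cls_name).sum()), nk)
        add("karyotyped", nk, n)
    out = pd.DataFrame(rows, columns=["group", "count", "denominator", "percent"])
    return out.set_index("group")


def karyotype_class(rec: KaryotypeRecord) -> str:
    """Whole-chromosome classification of a parsed karyotype.

    autosomal_aneuploidy: any autosomal trisomy/monosomy; polyploid: count
    >= 69; sex_chromosome_aneuploidy: abnormal X/Y dosage or abnormal count;
    other: structural findings only; normal: 46,XX / 46,XY.
    """
    primary = rec.primary
    if primary.gains or primary.losses:
        return "autosomal_aneuploidy"
    if primary.count >= 69:
        return "polyploid"
    x, y = rec.sex_dosage()
    if (x, y) not in ((2, 0), (1, 1)) or primary.count != 46:
        return "sex_chromosome_aneuploidy"
    if primary.structural or primary.markers:
        return "other"
    return "normal"


def concordance(case: CaseRecord) -> str:
    """Compare a case's sequencing triage with its karyotype at whole-chromosome level.

    Returns "concordant", "discordant", "discordant_expected" (a
    sub-karyotype-resolution CNV, < 5 Mb, against a normal karyotype —
    G-banding cannot see it) or "not_compared" (no karyotype).
    """
    if case.karyotype is None:
        return "not_compared"
    rec = parse_karyotype(case.karyotype)
    kclass = karyotype_class(rec)

    if case.category == "common_autosomal_aneuploidy":
        want = int(case.label.split()[1]) if case.label else None
        return "concordant" if want in rec.trisomies() else "discordant"
    if case.category == "rare_autosomal_aneuploidy":
        want = int(case.label.split()[1]) if case.label else None
        return "concordant" if want in rec.trisomies() else "discordant"
    if case.category == "sex_chromosome_aneuploidy":
        if kclass != "sex_chromosome_aneuploidy":
            return "discordant"
        if case.label and case.label in ("45,X", "47,XXY", "47,XYY", "47,XXX", "48,XYYY"):
            want = (case.label.split(",")[1].count("X"), case.label.split(",")[1].count("Y"))
            if rec.sex_dosage() == want or rec.primary.count != 46:
                return "concordant"
            return "discordant"
        return "concordant"
    if case.category == "multiple_chromosome_abnormality":
        return "concordant" if kclass != "normal" else "discordant"
    if case.category in CNV_CATEGORIES:
        if kclass == "normal":
            small = case.cnv_size_mb is not None and case.cnv_size_mb < 5.0
            return "discordant_expected" if small else "discordant"
        return "concordant"
    # sequencing-normal case
    return "concordant" if kclass == "normal" else "discordant"


def stratify_demographics(cohort: CohortTable) -> pd.DataFrame:
    """Age-band and trimester strata: n, share, mean, population SD, median."""
    df = cohort.to_frame()
    rows = []

    def describe(name, values, denom):
        values = np.asarray([v for v in values if v is not None and not pd.isna(v)],
                            dtype=float)
        n = len(values)
        mean = float(values.mean()) if n else float("nan")
        sd = float(values.std(ddof=0)) if n else 0.0
        med = float(np.median(values)) if n else float("nan")
        rows.append((name, n, percent(n, denom) if denom else float("nan"),
                     round_half_up(mean), round_half_up(sd), med))

    ages = df["age"]
    bad = ages.dropna()
    flagged = bad[(bad < 16) | (bad > 60)]
    if len(flagged):
        log.warning("%d ages outside the plausible 16-60 range", len(flagged))
    describe("age_overall", ages, len(cohort))
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        describe(f"age_{label}", ages[(ages >= lo) & (ages < hi)], len(cohort))
    ga = df["ga_weeks"]
    describe("ga_overall", ga, len(cohort))
    describe("ga_second_trimester", ga[(ga >= 14) & (ga <= 28)], len(cohort))
    describe("ga_third_trimester", ga[ga > 28], len(cohort))
    return pd.DataFrame(rows, columns=["stratum", "n", "percent", "mean", "sd",
                                       "median"]).set_index("stratum")


def outcome_table(cohort: CohortTable) -> pd.DataFrame:
    """Category x outcome contingency table; row/column sums conserve the cohort.

    Cases without a recorded outcome fall into the "not_recorded" column, so
    the grand total always equals the cohort size.
    """
    df = cohort.to_frame()
    df["outcome"] = df["outcome"].fillna("not_recorded")
    bad = set(df["outcome"]) - set(OUTCOMES) - {"not_recorded"}
    if bad:
        raise ValueError(f"unknown outcome values: {sorted(bad)}")
    table = pd.crosstab(df["category"], df["outcome"])
    table["total"] = table.sum(axis=1)
    return table


# ---------------------------------------------------------------------------
# the reconstructed study cohort

def _data(name: str) -> Path:
    return Path(str(resources.files("rcnvseq").joinpath("data").joinpath(name)))


def _stratum_values(n: int, mean: float, sd: float, lo: float | None = None) -> list[float]:
    """n deterministic values with exactly the given mean and population SD.

    Even n: alternating mean+/-sd.  Odd n: one value at the mean, the rest
    alternating +/- sd*sqrt(n/(n-1)).  When a lower bound would be violated an
    asymmetric three-level pattern is used instead.
    """
    if n == 1:
        return [mean]
    if n % 2 == 0:
        vals = [mean + sd if i % 2 == 0 else mean - sd for i in range(n)]
    else:
        a = sd * np.sqrt(n / (n - 1))
        vals = [mean] + [mean + a if i % 2 == 0 else mean - a for i in range(n - 1)]
    if lo is not None and min(vals) < lo:
        vals = _solve_bounded(n, mean, sd, lo)
    return vals


def _solve_bounded(n: int, mean: float, sd: float, lo: float) -> list[float]:
    """k values at the bound and two free upper values matching mean and SD."""
    k = n - 2
    d0 = lo - mean
    s = k * d0  # sum of deviations so far
    q = k * d0 * d0
    # two values with deviations u, v: u+v = -s, u^2+v^2 = n*sd^2 - q
    rhs = n * sd * sd - q
    uv = ((s * s) - rhs) / 2.0
    disc = s * s - 4 * uv
    if disc < 0 or rhs <= 0:
        return [mean] * n
    u = (-s + np.sqrt(disc)) / 2.0
    v = -s - u
    return [lo] * k + [mean + v, mean + u]


def _expand_outcomes(spec: list[tuple[str | None, int]]) -> list[str | None]:
    out: list[str | None] = []
    for outcome, k in spec:
        out.extend([outcome] * k)
    return out


def study_cohort() -> CohortTable:
    """The 424-case high-risk cohort reconstructed from the published tables.

    Per-category counts, anomalous zones, karyotype strings, demographic
    strata and follow-up outcomes all come from the packaged study tables;
    assignments below the printed aggregates (which karyotype string goes
    with which case) are deterministic but arbitrary.
    """
    events = pd.read_csv(_data("study_aneuploidy_events.tsv"), sep="\t")
    kar_auto = pd.read_csv(_data("study_karyotypes_autosomal.tsv"), sep="\t")
    kar_sex = pd.read_csv(_data("study_karyotypes_sex.tsv"), sep="\t")

    cases: list[CaseRecord] = []

    def add(n, **kw):
        for _ in range(n):
            cases.append(CaseRecord(case_id=f"case{len(cases):04d}", **kw))

    # --- common autosomal aneuploidy (203) --------------------------------
    t21 = events[events["chrom"] == "chr21"]
    for _, row in t21.iterrows():
        add(int(row.n), category="common_autosomal_aneuploidy", label="trisomy 21",
            zone=row.zone, mosaic=bool(row.mosaic))
    t18 = events[events["chrom"] == "chr18"].iloc[0]
    add(int(t18.n), category="common_autosomal_aneuploidy", label="trisomy 18",
        zone=t18.zone, mosaic=False)
    for _, row in events[events["chrom"] == "chr13"].iterrows():
        add(int(row.n), category="common_autosomal_aneuploidy", label="trisomy 13",
            zone=row.zone, mosaic=bool(row.mosaic))

    # --- sex chromosome aneuploidy (91), mapped from the X/Y event rows ----
    # 47,XXY: 35 (6 mosaic) <- X dup rows in an XY background
    add(29, category="sex_chromosome_aneuploidy", label="47,XXY",
        zone="dup(X)(p22.33q28)", mosaic=False)
    add(6, category="sex_chromosome_aneuploidy", label="47,XXY",
        zone="dup(X)(p22.33q28)(mos)", mosaic=True)
    # 45,X: 22 (13 mosaic) <- X del rows
    add(9, category="sex_chromosome_aneuploidy", label="45,X",
        zone="del(X)(p22.33q28)", mosaic=False)
    add(13, category="sex_chromosome_aneuploidy", label="45,X",
        zone="del(X)(p22.33q28)(mos)", mosaic=True)
    # 47,XYY: 19 (3 mosaic) <- Y dup rows
    add(16, category="sex_chromosome_aneuploidy", label="47,XYY",
        zone="dup(Y)(p11.32q12)", mosaic=False)
    add(3, category="sex_chromosome_aneuploidy", label="47,XYY",
        zone="dup(Y)(p11.32q12)(mos)", mosaic=True)
    # 47,XXX: 15 <- X dup rows in an XX background
    add(15, category="sex_chromosome_aneuploidy", label="47,XXX",
        zone="dup(X)(p22.33q28)", mosaic=False)

    # --- rare autosomal aneuploidy (3) ------------------------------------
    add(1, category="rare_autosomal_aneuploidy", label="trisomy 7",
        zone="dup(7)(p22.3q36.3)(mos)", mosaic=True)
    add(2, category="rare_autosomal_aneuploidy", label="trisomy 15",
        zone="dup(15)(q11.1q26.3)(mos)", mosaic=True)

    # --- abnormalities in multiple chromosomes (33) ------------------------
    add(33, category="multiple_chromosome_abnormality")

    # --- copy number variation (94: 63 pathogenic, 31 VUS) -----------------
    add(24, category="pathogenic_cnv", label="Xp22.31 (STS) deletion",
        zone="del(X)(p22.31)", cnv_size_mb=1.2)
    add(39, category="pathogenic_cnv", cnv_size_mb=1.5)
    add(31, category="vus_cnv", cnv_size_mb=0.3)

    assert len(cases) == 424

    # --- outcomes from the follow-up narrative -----------------------------
    by_label: dict[str, list[CaseRecord]] = {}
    for c in cases:
        by_label.setdefault(c.label or c.category, []).append(c)
    narrative = {
        "trisomy 21": [("termination_of_pregnancy", 125), ("live_birth", 1), (None, 43)],
        "trisomy 18": [("termination_of_pregnancy", 23), ("failure_to_follow_up", 1)],
        "trisomy 13": [("termination_of_pregnancy", 9), ("failure_to_follow_up", 1)],
        "47,XXY": [("termination_of_pregnancy", 22), ("failure_to_follow_up", 7),
                   ("live_birth", 6)],
        "45,X": [("miscarriage", 1), ("termination_of_pregnancy", 21)],
        "47,XYY": [("termination_of_pregnancy", 3), ("continued_gestation", 2),
                   ("failure_to_follow_up", 14)],
        "47,XXX": [("failure_to_follow_up", 15)],
        "trisomy 7": [("termination_of_pregnancy", 1)],
        "trisomy 15": [("termination_of_pregnancy", 2)],
    }
    for label, spec in narrative.items():
        outcomes = _expand_outcomes(spec)
        assert len(outcomes) == len(by_label[label]), label
        for c, o in zip(by_label[label], outcomes):
            c.outcome = o

    # --- karyotypes for the 245 compared cases -----------------------------
    kar_strings: dict[str, list[str]] = {}
    for _, row in kar_auto.iterrows():
        key = {"trisomy_21": "trisomy 21", "trisomy_21_mos": "trisomy 21",
               "trisomy_18": "trisomy 18", "trisomy_13": "trisomy 13",
               "trisomy_13_mos": "trisomy 13"}[row.group]
        kar_strings.setdefault(key, []).extend([row.karyotype] * int(row.n))
    sex_key = {"klinefelter": "47,XXY", "klinefelter_mos": "47,XXY", "jacob": "47,XYY",
               "superman": "47,XYY", "triple_x": "47,XXX", "turner": "45,X",
               "turner_mos": "45,X"}
    for _, row in kar_sex.iterrows():
        kar_strings.setdefault(sex_key[row.group], []).extend([row.karyotype] * int(row.n))
    for label, strings in kar_strings.items():
        group = by_label[label]
        # mosaic karyotype strings go to mosaic sequencing calls where possible
        mosaic_first = sorted(group, key=lambda c: not c.mosaic)
        is_mos = [("/" in s) for s in strings]
        ordered = [s for s, m in zip(strings, is_mos) if m] + \
                  [s for s, m in zip(strings, is_mos) if not m]
        for c, s in zip(mosaic_first, ordered):
            c.karyotype = s
    # one tetraploid result, attached to a multiple-chromosome case
    by_label["multiple_chromosome_abnormality"][0].karyotype = "92,XXXX"
    # 20 further karyotyped cases among the CNV group: 1 normal result (the
    # single sequencing/karyotype discordance) and 19 incidental findings
    sts = by_label["Xp22.31 (STS) deletion"]
    sts[0].karyotype = "46,XX"
    others = [c for c in cases if c.category in CNV_CATEGORIES and c.karyotype is None]
    for c in others[:19]:
        c.karyotype = "46,XX,inv(9)"

    n_kar = sum(c.karyotype is not None for c in cases)
    assert n_kar == 245, n_kar

    # --- demographics ------------------------------------------------------
    demo = pd.read_csv(_data("study_demographics.tsv"), sep="\t")
    ages: list[float] = []
    for _, row in demo[demo["variable"] == "age"].iterrows():
        lo = 45.0 if row.stratum == ">=45" else None
        ages.extend(_stratum_values(int(row.n), float(row["mean"]), float(row["sd"]), lo=lo))
    ga: list[float] = []
    for _, row in demo[demo["variable"] == "ga"].iterrows():
        ga.extend(_stratum_values(int(row.n), float(row["mean"]), float(row["sd"])))
    assert len(ages) == 424 and len(ga) == 424
    for c, a, g in zip(cases, ages, ga):
        c.age, c.ga_weeks = round(a, 4), round(g, 4)

    return CohortTable(cases)
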