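# Methods

## The assay being modelled

rcnvseq models a rapid, PCR-free low-pass whole-genome sequencing assay for
prenatal detection of chromosomal abnormalities (rCNV-seq). Per sample, about
5 million single-end 45 bp reads are produced, trimmed to their 36 bp genomic
portion, aligned to hg19, and reduced to the 2.8–3.2 million uniquely mapped
read positions. Reads are tallied into 20-kb bins along each chromosome
(154,794 bins genome-wide), and copy number (CN) is read off the bin-count
profile on a scale where normal diploid dosage = 2.

### Copy-number estimation

For bin *i* with (GC-corrected) count `c_i` and a robust baseline `b`,

    CN_i = 2 · c_i / b .

`b` defaults to a 10 %-trimmed mean of autosomal corrected counts. A trimmed
mean rather than the plain median: at ~19 reads per bin the median of integer
counts is itself an integer, which quantises the scale and can bias genome-wide
mean CN by up to ±2.5 %; the trimmed mean is smooth in the counts and still
robust to a whole-chromosome trisomy, which shifts fewer than 8 % of autosomal
bins. `baseline="median"` and an explicit reference-panel value remain
available.

GC correction is stratified-median scaling: bins are grouped into GC strata of
width 0.02 and each count is rescaled by (global autosomal median)/(stratum
median). Uniform-GC input passes through unchanged; empty or zero-median
strata are left unscaled and logged.

### Classification thresholds

The five dosage states use fixed CN cut-offs:

| state            | CN interval  |
|------------------|--------------|
| deletion         | [0, 1.2)     |
| mosaic monosomy  | [1.2, 1.8)   |
| disomy           | [1.8, 2.2]   |
| mosaic trisomy   | (2.2, 2.8]   |
| duplication      | (2.8, ∞)     |

The published inequalities for this assay family are strict on both sides and
leave the four boundary points unassigned; this implementation closes the
disomy band at 1.8/2.2 (conservative: a boundary value is *not* reported
abnormal) and assigns 1.2 and 2.8 to the adjacent mosaic states, making the
partition total — a property the test suite checks on a dense grid.

A mosaic state maps to the latent cell fraction through the mixture relation
CN = 2 + f·(CN_line − 2), so f = |CN − 2| for single-copy gains and losses.
The same algebra describes fetal fraction in a cfDNA reading of the assay; the
simulator exposes the fraction as a free parameter but, matching the assay's
stated thresholds, all classification happens on the pure mixture CN scale
with no separate fetal-fraction deconvolution.

### Two-tier event calling

Whole-chromosome aneuploidy is called from the per-chromosome mean CN (the
24-panel CN plot track). With ≥2,400 bins per chromosome the standard error of
a chromosome mean is below 0.01 CN, so whole-chromosome states — including
mosaics down to the CN 2.2 boundary, i.e. f = 0.2 — are essentially
deterministic at this depth. Sex chromosomes are assessed as deviation from
the inferred sex's expected dosage (XX: X=2, Y=0; XY: X=1, Y=1); sex is
inferred as male when chrY mean CN exceeds 0.5. X/Y dosage anomalies map to
karyotype labels via total copy counts ({2,1}→47,XXY, {1,0}→45,X, …).

Sub-chromosomal events come from greedy run-merging segmentation, chosen over
CBS/HMM approaches for determinism and auditability:

1. classify each bin's dosage deviation as gain (CN > 2.2), loss (CN < 1.8)
   or neutral;
2. merge maximal same-direction runs; bridge same-direction runs separated by
   at most `bridge_bins` (default 1) neutral bins;
3. a run one bin short of `min_bins` absorbs its better-supporting neighbour
   bin (a floor-size event loses a boundary bin to shot noise ~25 % of the
   time);
4. drop runs shorter than `min_bins` (default 5 bins = 100 kb, the assay's
   detectability floor) or with fewer than `min_bins − 1` non-neutral bins or
   with mean-dosage evidence below `z_min` (default 2.5) standard errors;
5. re-average CN over each surviving run and classify the segment state from
   the mean; surviving runs spanning ≥90 % of a chromosome are treated as
   whole-chromosome events.

**Sensitivity/specificity at the floor is a genuine trade-off, not a tuning
failure.** A 100-kb single-copy gain at 3.0M mapped reads carries ≈ +48 reads
over a ≈ 10-read noise SD — about 4.9σ of total evidence. Controlling
family-wise error over ~150,000 bins would demand a ≈ 4.5σ threshold and cap
floor-size sensitivity near 65 %. The caller therefore runs sensitivity-first
(`z_min = 2.5`, recovering ≥90 % of floor-size constitutional CNVs, as the
acceptance suite measures) and marks each segment with a `confident` flag
(|z| ≥ `z_conf`, default 4.0). On an event-free full-depth genome the
sensitivity tier emits on the order of a thousand boundary-noise segments and
the confident tier a few tens (bounded by a regression test); none of the
noise segments approaches 1 Mb. Case triage counts only confident
sub-chromosomal calls, and the 1-Mb pathogenicity floor (below) is effectively
noise-free. Users wanting genome-wide specificity should filter the segment
table on `z`.

### Reporting and triage

Calls are rendered as ISCN-like region strings from cytoband lookup
(`dup(21)(q11.2q22.3)`, with `(mos)` for mosaics), HGVS-like genomic strings
(`chr21:g.14300000_48129895dup`) and fragment sizes in Mb to two decimals.
Coordinates are 1-based inclusive throughout; BED input is converted on read.
Band lookup convention: an interval start lying exactly on a band boundary
belongs to the band *beginning* there, an interval end to the band *ending*
there — this is the convention under which the study tables' coordinate and
band columns agree (g. starts such as chr21:14,300,000 and chr13:19,500,000
are exactly UCSC band starts of q11.2 and q12.11).

Case triage assigns one category per case with precedence
multiple-chromosome abnormality (whole-chromosome events on ≥2 chromosomes) >
common autosomal aneuploidy (chr 21/18/13) > sex-chromosome aneuploidy >
rare autosomal aneuploidy > pathogenic CNV > VUS > normal. A sub-chromosomal
call is pathogenic when it overlaps a curated region list (seeded with the
Xp22.31/STS deletion region, chrX:6.0–9.5 Mb — the recurrent 0.98–1.70 Mb
deletion causing X-linked ichthyosis and the dominant pathogenic CNV class in
this setting) or reaches the configurable 1 Mb size floor; ACMG-style scoring
is out of scope.

## The synthetic-data generator

No raw sequencing from the study is available, so the generator is the test
substrate. It draws bin counts with expectation

    λ_i = N · w_i · (c_i / 2) · g(GC_i) / W ,

where N is the mapped-read budget (fixed, or drawn uniformly from
2.8–3.2 million), `w_i` the bin-width share, `c_i` the expected copy number
from the sex baseline plus mixture events, `g` a monotone (log-quadratic)
GC-bias curve disabled by default, and W the normalising total weight. Noise
models: independent Poisson (default — the shot-noise floor at ~19 reads/bin),
multinomial (exact conservation of N, used to check count-conservation
invariants) and negative-binomial (overdispersion `d`, var = λ + dλ²). Same
configuration and seed reproduce identical counts.

What it emulates: the read-budget, binning geometry, dosage mixtures
(aneuploidy, mosaicism, segmental CNVs), GC bias and counting noise. What it
does not: mappability holes, real GC tracks (the packaged GC field is a
smooth seeded random surface), real population CNV polymorphism, duplicate
reads, or maternal/fetal cfDNA composition. Passing recovery tests therefore
demonstrates correctness of the estimation chain under the stated noise
models, not performance on real libraries.

A scaled "toy" genome (hg19 lengths ÷ 50, ~3,100 bins) backs the per-commit
unit tests; recovery and detectability checks run on the full hg19 grid at
3.0M mapped reads with 20 seeds per claim — sizes chosen to give sub-minute
suites while leaving simulation standard errors well inside the asserted
tolerances (chromosome-mean CN SE ≈ 0.01 against a ±0.05 recovery band).

## The reconstructed study cohort

`rcnvseq.cohort.study_cohort()` rebuilds the 424-case high-risk cohort from
the packaged per-category tables: 203 common autosomal aneuploidies (169
trisomy 21, 24 trisomy 18, 10 trisomy 13, with their mosaic counts and
anomalous-zone strings), 91 sex-chromosome aneuploidies (35 47,XXY; 22 45,X;
19 47,XYY; 15 47,XXX), 3 rare autosomal trisomies (chr7, chr15×2), 33
multiple-chromosome cases, and 94 CNV cases (63 pathogenic, of which 24
Xp22.31/STS deletions; 31 VUS). Follow-up outcomes are populated where the
study narrative states them; the remainder are left unrecorded and surface in
a `not_recorded` column so contingency tables still conserve the cohort.
245 cases carry karyotype strings (156 autosomal-aneuploidy karyotypes, 68
sex-chromosome karyotypes, 1 tetraploid, 20 others including the single
CNV-with-normal-karyotype discordance). Assignments below the printed
aggregates — which karyotype string belongs to which case — are deterministic
but arbitrary, and per-case ages/gestational weeks are synthetic values
constructed so every demographic stratum reproduces its published n, mean and
SD exactly (deterministic ± patterns; a bounded asymmetric pattern where a
symmetric one would leave the stratum). The cohort is a reconstruction for
aggregate-level computation, not deposited data.

Percentages are rendered round-half-up to two decimals, the rule consistent
with the study's printed figures; denominators are always explicit. Two
printed figures differ from the recomputed values in the final digit
(203/424 → 47.88 and 415/424 → 97.88); the package reports the arithmetic
result.

## Numerical and degenerate-input conventions

- Bins are 1-based inclusive `[w(k−1)+1, wk]`, last bin truncated; a position
  on a bin boundary belongs to the lower bin.
- Reads shorter than the 36 bp target pass through trimming with a warning;
  reads on unknown chromosomes or out of bounds are rejected and counted.
- Zero baseline or an all-zero sample aborts estimation with a diagnostic.
- A single-case stratum reports SD 0 by convention.
- Karyotype parsing is whitespace-insensitive, normalises X0/XO to X, and
  reports the first unparseable token in its error.
- Empty mosaic brackets `[]` parse as mosaic-with-unknown-proportions.

## Known limitations

- Segmental calling below ~250 kb operates in the high-sensitivity /
  low-specificity regime described above; the confident tier is the
  reportable one.
- Whole-chromosome mosaicism below f = 0.2 lands inside the disomy band by
  construction of the thresholds and is (correctly, per those thresholds)
  not reported, although the assay family is sometimes described as
  detecting mosaic fractions above 5 %; resolving that tension would require
  changing the published thresholds.
- Sub-bin breakpoint refinement, HMM/CBS segmentation, duplicate marking,
  fetal-fraction deconvolution and gene-level annotation are out of scope.
- The packaged cytoband table is a hand-reconstructed hg19-like banding
  (accurate at the coordinates the reporting layer is tested on, coarse
  elsewhere); swap in a full UCSC `cytoBand.txt` via
  `CytobandTable.load(path)` for production use.
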