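# Methods

## Scope and model

`wgsqc` rates a matched normal/tumour pair of whole-genome alignments
with five measures and a 0–5 half-star summary. Inputs are taken as
aligned and flagged; no realignment, duplicate marking or recalibration
is performed. All measures share one read-exclusion policy — no
duplicates, no MAPQ-0 reads, no supplementary or secondary alignments —
and one contig inclusion set. Secondary alignments are excluded
together with supplementary ones because both are non-primary
placements of a read. Coordinates are 0-based, half-open everywhere,
including the report.

**Contig inclusion.** All measures are restricted to the autosomes plus
X and Y (dialect "1"/"chr1" auto-detected; for non-human references all
contigs are used). Only the inter-chromosomal measure strictly requires
this restriction; applying it uniformly keeps every denominator (mean
coverage, windows, callable bases) consistent, at the cost of ignoring
MT and decoy reads everywhere. This was a genuinely open choice; the
uniform rule is simpler to reason about and is what the package does.

## Mean coverage

`C̄ = (1/n) Σ xᵢ` over included positions whose reference base is not N
(excluded from numerator and denominator alike). Depth counts the
reference-consumed span of each filtered read (CIGAR M/=/X/D).
`clip_mate_overlaps` (default off) counts positions covered by both
mates of one pair once; it is off by default because large-insert
protocols rarely overlap, but short-insert libraries should enable it
to avoid inflated coverage. Thresholds: ≥ 25× normal, ≥ 30× tumour,
inclusive.

## Evenness

Windowed read counts are the unit of analysis: each filtered read is
assigned to exactly one 10 kb window — the one containing its alignment
midpoint — so window counts sum to the read count. Windows with > 50%
N bases (gaps) are dropped before normalization; the cut-off is
configurable. Normalized coverage is the window count divided by the
mean count over retained windows.

**MoM** = median/mean of the retained window counts; computed on the
10 kb grid and also on a 5 Mb grid. The pass/fail decision uses the
10 kb value and the 5 Mb value is reported as a diagnostic: the two
grids are both part of the measure's definition but only one value can
be thresholded, and the 10 kb grid is the one shared with FWHM. The
5 Mb grid tiles the included contigs rather than being forced to a
fixed window count, keeping it genome-size-agnostic. Ranges:
0.99–1.06 normal, 0.92–1.09 tumour, endpoints inclusive.

**FWHM** requires a GC-bias model first. Two-step lowess
(statsmodels, span 0.3 of points, 3 robustifying iterations — smooth
enough for a monotone-ish bias curve, configurable in the module
constants):

1. fit 1 on (GC, normalized coverage) of all retained windows;
2. residuals from fit 1 are density-estimated; windows whose residual
   falls inside the half-maximum interval of the tallest peak are the
   *main copy-number state* (≥ 10% of windows required, else error);
3. fit 2, on main-state windows only, is the correction function
   (interpolated between fitted points, clamped to its end values
   outside the fitted GC range, required strictly positive).

Corrected coverage = normalized / correction(GC). The residual-density
gate is deterministic and matches the "main cloud" picture of
GC-vs-coverage plots; assignment rules based on explicit copy-number
segmentation were deliberately avoided as out of scope.

KDE everywhere: Gaussian kernel, Silverman's rule
(0.9·min(sd, IQR/1.34)·n^−1/5), evaluated on a fixed 2048-point grid
spanning the data range ± 3 bandwidths; half-maximum crossings are
linearly interpolated between grid points, taking the crossings nearest
the global peak (with a warning if the density is multimodal above the
half-max level). FWHM is the right minus left crossing. The estimator
is biased upward by the bandwidth (≈ +1–3% at a few thousand windows),
well inside the 10% tolerance the validation suite uses. The whole
evenness path is deterministic given the BAM. Thresholds: FWHM ≤ 0.20
normal, ≤ 0.34 tumour. Preconditions: ≥ 200 retained windows with GC
range > 0.05 for the fit, ≥ 100 main-state windows for the FWHM.

## Callable coverage

Positions with normal depth ≥ 8 and tumour depth ≥ 14 (inclusive),
N positions excluded, using the same filtered depth as mean coverage —
one read filter for every measure rather than a caller-specific one,
since base-quality filters of any particular somatic caller are not
part of this framework. The pass threshold is 2.6 Gb for a full human
genome; by default it is expressed as the equivalent fraction
2.6e9 / 2,835,690,481 ≈ 0.9169 of included known bases so the measure
is meaningful on references of any size (the absolute form is available
via `callable_threshold_bases`; the two are mutually exclusive).

## Paired-read discordance

**Inter-chromosomal rate**: numerator — paired, both-ends-mapped reads
with both contigs included and own ≠ mate contig; denominator — the
same without the last condition. Counting reads (not pairs) matches the
percentage-of-reads phrasing; with complete mate information the two
coincide. Single-mapped reads are excluded outright: a missing mate has
no chromosome to differ on. Pass: ≤ 3.0, endpoint passing.

**Edit ratio**: an edit is a substituted base; indels are not edits.
Per-read edits come from the MD tag (count of substitution letters,
deletion runs after `^` ignored); reads without MD fall back to NM
minus the CIGAR's inserted plus deleted bases, floored at zero. Reads
with neither tag are tallied as unscored and excluded; > 10% unscored
is an error. The statistic is max/min of the read-1 and read-2 totals;
both-zero gives 1.0 by convention, one-sided zero gives +inf (which
fails). Fail at ≥ 2.0 — the only measure whose printed threshold value
itself fails, following the "two-fold or greater" rule.

## Star rating

Per paired measure: 1 star if normal and tumour pass, 0.5 if only the
normal, else 0; callable is joint, 1 or 0. Total is the sum. Thresholds
come from `QCThresholds` (defaults above) or a flat YAML file and are
echoed in the report provenance. The report is a one-row TSV; VCF
annotation inserts exactly one header line before `#CHROM` and
stripping it restores the input byte-for-byte.

## Synthetic data

The generator emulates the data regime the thresholds were designed
for, at desk scale. Defaults (the experiment every test and the
acceptance script run unless a defect is the point): two 1 Mb contigs
at GC 0.41 and 0.45 with one 4 kb N run each; 100 bp paired reads;
insert sizes Normal(450, 100) clipped to [200, 800] bp, the insert
range of large cancer cohorts; 30× normal, 35× tumour; 5% duplicates,
2% MAPQ-0, 1% supplementary reads; 1% chimeric pairs (below the 3%
threshold, above the < 1% biological background); balanced per-base
mismatch rates of 0.002 (≈ Q27 effective substitution error); no GC
bias and no copy segments. Contig GC varies between 10 kb blocks
(SD 0.08, recentred to the contig target) so the GC-bias fit has real
abscissa spread.

Mechanics: fragment counts per 10 kb window are Poisson with mean
`depth × window / (2 × read length)`, scaled by the window's copy ratio
(tumour segments) and GC efficiency; starts are uniform within the
window; reads are emitted as if perfectly aligned — placement is truth,
no aligner in the loop — with proper flags, reciprocal mate fields, and
NM/MD tags exactly consistent with the injected substitutions
(substitution at a still-N reference base is skipped). Chimeric pairs
keep each mate's own placement valid and differ only in the mate
contig, as PCR chimeras present in real BAMs. Duplicate, MAPQ-0 and
supplementary reads are extra copies of existing fragments drawn from
an RNG stream independent of the fragment stream, so the
policy-filtered content of a simulation is bit-identical across defect
settings at a fixed seed — filter invariance holds exactly, by
construction. Everything is deterministic given the seed.

What the generator does **not** emulate: alignment error and mapping
ambiguity, quality-score models and homopolymer errors, indels in
reads, insert-size pathology, contamination. Passing tests therefore
show the measures recover injected truths from well-formed alignments;
they do not certify behaviour under aligner artefacts.

## Problem sizes and tolerances

Tests and the acceptance script run on 2 Mb genomes at 15–35×
(0.2–0.7 M reads per sample), sizes at which every statistical check
has comfortable margin: mean coverage concentrates to ±0.3%, chimera
and edit totals to a few per-mille, and the FWHM noise floor
(Poisson counting, ≈ 2.355·CV of the window counts) sits at 0.04–0.08,
far below the 0.20 threshold. Exact checks (oracle equivalence, star
arithmetic, filter invariance, boundary semantics) use no tolerance at
all; stochastic checks use 3-SD or 5–15% bands stated inline.

## Known limitations

* The lowess spans, the residual-density main-state gate and the KDE
  settings are this package's own calibration of the two-step
  correction idea; other implementations of the same idea may differ in
  the third decimal of FWHM.
* MoM on the 5 Mb grid of a 2 Mb synthetic genome collapses to two
  windows and is reported but uninformative at that scale.
* The edit-ratio MD-first rule counts soft-clipped bases as whatever MD
  says (MD does not describe clips); aligners that populate MD
  differently around clips could shift totals slightly.
* Inter-chromosomal percentages are read-level; orphaned mates
  (mate filtered but not unmapped) are still counted by their flags.
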