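# Methods

## Data model and coordinates

Internal coordinates are 0-based half-open everywhere; Bismark-dialect
coverage files (1-based inclusive) and BED (0-based) are converted only at
the I/O boundary. CG dinucleotides are indexed at the plus-strand C, and
coverage rows reported at the G (position C+1) are folded onto the C by
summing counts when a genome index is available. Folding halves the index
and matches counting "genomic CG occurrences" once per dinucleotide;
per-strand counting remains available (`fold_strands=False`) because
upstream callers differ on this convention. Records with zero total calls
are skipped with a warning rather than rejected — sparse single-cell files
legitimately contain them after strand splitting.

## Quantitation

All methylation percentages are call-weighted: 100·Σm/(Σm+Σu) pooled over
positions (and, for groups, over cells) — not means of per-position or
per-tile percentages. A region yields a percentage only when enough
*distinct CG positions* were observed in it ("5 separate CG observations"
is read as positions, not calls): 5 for 500-CG tiles, 10 for domains. The
global mean is call-weighted over all CpG calls; an unweighted
mean-of-tile-percentages alternative is exposed (`mean_of_tile_pcts`)
because summary conventions differ between tools.

## Tiling and segmentation

Tiles hold a fixed number of consecutive genomic CG positions (500 for the
unbiased landscape, 100 for segmentation). The trailing partial tile of a
chromosome is kept and flagged rather than dropped; the minimum-CG filters
handle it naturally. Tile classes use strict cutoffs: hyper >75%,
hypo <25%, intermediate otherwise.

Segmentation run-length-encodes 100-CG tile states (methylated vs
unmethylated at 50%). Two conventions required a decision:

- a tile at exactly 50% is methylated by default (`tie_state="M"`,
  configurable) — the >50/<50 definition leaves the boundary open and a
  deterministic rule is required;
- unquantified tiles are absorbed into the surrounding run without
  contributing a state. Segmentation operates on deeply pooled data where
  nulls are rare, and breaking runs on every coverage gap would fragment
  domains arbitrarily; `break_on_gap=True` provides the alternative.

Domains never span chromosomes and adjacent domains always alternate state.

## Statistics

**Pooled mode** (merged single cells per group): Pearson χ² on the 2×2
methylated/unmethylated table, one degree of freedom, no Yates continuity
correction (matching standard contingency quantitation of pooled
bisulfite counts; Yates available by flag). A region passes at raw
p < α (default 0.05) **and** absolute difference ≥ 10 points. No multiple-
testing correction is applied in this mode by default — the pooled tile
analysis is reported at uncorrected p < 0.05 with the effect-size filter
doing the heavy lifting — but BH can be switched on (`correction="bh"`).
Tables with a zero margin are undefined and reported with a null p;
p-values that underflow to exactly zero are reported as the smallest
positive double and flagged `underflow`.

**Replicate mode** (cells as biological replicates): two-sided
pooled-variance Student t on per-cell percentages (Welch by flag),
Benjamini–Hochberg across all tested regions, significant at adjusted
p < α. Regions with fewer than two quantified cells in a group, or a
degenerate statistic (zero pooled variance), are excluded from the test
and from the BH family rather than mis-scored. Cells, not donors, are the
replicates; the NS and S collections from the same donors are treated as
unpaired samples of cells.

**BH step-up with family-size override.** `bh_adjust(p, m)` implements
`adj_i = min_{j≥i} p_(j)·m/j` (capped at 1, input order preserved) with
`m ≥ len(p)`. The override exists because a reported panel table may be the
significant subset of a larger tested family: the unreported tests occupy
trailing ranks and cannot change the adjusted values of the reported ones
when their p-values are larger. The implementation is a dozen lines of
numpy; statsmodels' `multipletests` (which has no such override) serves as
the independent oracle in the tests for `m == len(p)`.

**Panel analysis** quantitates each gene/CGI feature pooled per group,
reports the percent of genomic CGs observed per group, tests each feature
by χ², and BH-adjusts over the panel with `m_override` available. The
"difference" column is defined as |pct_A − pct_B| of the pooled
percentages.

## Contamination QC

Three filters, each inconclusive (never failed) when its input has no
coverage, a library discarded when any filter fails:

| filter            | quantity                              | default cutoff |
|-------------------|---------------------------------------|----------------|
| context inversion | overall CH methylation                | < 2.5% fails   |
| exemplar region   | CG methylation over a declared region | > 10% fails    |
| ChrX CGI          | pooled methylation over ChrX CGIs     | > 30% fails    |

The CH threshold sits halfway between the oocyte expectation (~5%) and the
somatic level (~0.5%). The exemplar region is configurable, not hard-coded:
the genuine coordinates of such a region are assembly-specific (on the real
bovine assembly it is a ~1.3 Mbp stretch of chromosome 5); the synthetic
genome declares its own. The largest-autosome CGI methylation is always
reported alongside the ChrX value as a control. Thresholding replaces the
original by-eye two-group separation with an explicit reproducible rule; a
2-means split on (CG%, CH%) is provided as an alternative mode
(`context_split_2means`). At a 50% somatic mixture the exemplar-region
filter is the decisive one (mixed CH ≈ 2.75% and mixed ChrX CGI ≈ 25% both
sit on the "clean" side of their cutoffs); the CH and ChrX filters engage
at heavier contamination.

Mislabelled samples (metadata errors) are outside this data model; the QC
detects contamination signatures only.

## Synthetic study generator

The generator defines the study conditions; defaults are fixed, not tuning
knobs.

**Design**: 45 libraries — 15 NS (6/4/5 per donor) and 30 S (9/6/15) from
3 donors; 17 libraries (fraction 17/45) contaminated at somatic mixture
0.5. Genome: three 3-Mbp chromosomes (chr1 control autosome, chr5 carrying
the imprinted panel and a 600-kbp exemplar demethylated region, chrX) at
CG density 0.02/bp with 20 CG-dense CpG islands per chromosome. This scale
holds ≈370 500-CG tiles and ≈250 methylation domains — enough that the
calibration checks below have small Monte Carlo error — while the full
45-library study simulates in under a second.

**Oocyte truth**: a two-state Markov chain along CG positions assigns
methylated/unmethylated domains (mean run 900 CGs, M-state stationary
fraction 0.70); each domain draws its level from a beta around the state
mean (M: mean 76%, concentration 4.0; U: mean 20%, concentration 22.4).
CpG islands are overridden to ~2% (autosomes) / ~1% (chrX), the exemplar
region to ~1%, and panel features to their configured per-group
percentages (defaults mirror the reported imprinted-locus values, e.g.
KvDMR1 100 vs 58.57). NS and S share one base landscape — the groups are
oocytes from the same animals — and differ only at panel features. The
landscape constants were calibrated once, by grid search on the truth
process, so the *measured* study reproduces a ~52% global mean and
~25.5%/18.75% hyper/hypo tile fractions; the calibrated expectations are
recorded in the config (`expected_*`).

**Somatic contaminant**: per-domain beta around 75% everywhere, CGIs ~5%
on autosomes and ~50% on chrX, CH 0.5% (vs the oocyte's 5%).

**Capture model**: each CG observed independently with probability 0.05
(real per-cell scPBAT capture is of this order); an observed CG receives
1 + Poisson(0.3) calls; methylated counts are binomial in the true level.
Contamination acts at the call level — each call of a contaminated library
comes from the somatic truth with the mixture probability — because a PBAT
library pools all fragments in the well. CH calls are drawn at depth 1
over a fixed 100,000-site non-CG cytosine panel. Coverage files are
written with counts split across strands (binomial/hypergeometric), so
reading them back exercises strand folding.

**What the generator does not emulate**: read-level sequences and
bisulfite-conversion errors, 5hmC, donor-to-donor landscape variation,
replication- or transcription-coupled methylation structure, non-uniform
capture (real coverage is biased by CpG density and mappability), and
mislabelled samples. Passing tests therefore demonstrate the correctness
and statistical behaviour of the pipeline under a faithful sparsity and
contamination model — not performance on every artefact of real libraries.

## Numerical and testing notes

- All randomness flows from `numpy.random.SeedSequence(seed)` spawns in a
  fixed order; identical (config, seed) reproduce outputs byte-for-byte.
- Results tables write floats with shortest-round-trip repr, so p-values
  survive write/read bit-identically.
- Monte Carlo checks on study-level quantities (global mean ±1.5 points,
  tile-class fractions ±5 points) average over 10 fixed seeds; one
  3-Mbp-genome study holds ~250 domains, giving a per-study SD of ~2
  points on the global mean, so the averaged estimate sits well inside the
  bands. QC sensitivity/specificity pools decisions over 20 seeded
  studies.
- BH false-discovery behaviour on an almost-null panel is asserted in
  aggregate (total false flags across 20 seeds within the step-up's
  expected budget) rather than per seed, where single uniform-tail events
  would dominate.

## Known limitations

- The χ² test on pooled single cells ignores cell-to-cell overdispersion;
  the replicate-mode t-test is the conservative counterpart, and no
  beta-binomial model is provided.
- Domain segmentation has no smoothing/HMM; a single mis-classified tile
  between long runs creates a (short) domain of its own.
- Strand folding assumes symmetric CpG methylation; hemimethylation is not
  modelled.
- The panel's family-size override must be supplied by the user when a
  table is a reported subset; nothing infers it.
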