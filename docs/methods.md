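# Methods

## The assay and its model

The pipeline analyses CCGG cytosine methylation assayed by a dual
restriction digest with the isoschizomers HpaII and MspI (the
MSAP/AFSM family of reduced-representation protocols). Both enzymes
recognise 5'-CCGG-3' and cut between the two cytosines (C^CGG), but
respond differently to methylation: the joint pattern of *cleavage*
reads (fragment ends at the cut coordinate) and *body* reads (fragments
spanning the intact site) across the two libraries identifies the
site's state. Per sample and site four read counts are tallied —
HpaII cleavage, MspI cleavage, HpaII body, MspI body — and mapped to a
state:

| pattern | state |
|---|---|
| HpaII cleavage + MspI body, no MspI cleavage | `hemi_mCCGG` (hemi-methylated outer C) |
| MspI cleavage + HpaII body, no HpaII cleavage | `full_CmCGG` (fully methylated inner C) |
| body in both digests, no cleavage in either | `full_mCCGG` (fully methylated outer C) |
| cleavage in both digests | `unmethylated` |

A site is callable only with at least 4 reads total and at least 2 reads
in each enzyme library; the "at least 2 + 2" floor is taken as the
operative definition (a strict "more than 4" would contradict its own
2 + 2 parenthetical). Any pattern matching none of the four rows is
conservatively `no_call` rather than `unmethylated`: partial patterns
are more often depth artefacts than biology.

Coordinates are 0-based half-open internally; the cut coordinate of the
site at `position` is `position + 1`. Reads are classified purely by
alignment coordinates (start/end at the cut coordinate vs. spanning the
4-mer); no in-silico digestion is simulated. Soft-clipped ends are not
given special treatment: `reference_start`/`reference_end` of the
aligned portion are what count, which is the conservative reading when
the upstream aligner already trims adapters.

## Population-level classification

Sites are retained when *identically* methylated in at least 2 samples
(the stricter of the two readings of "similarly methylated"; the looser
any-methylated-state variant is available via `require_identical=False`).
Among methylated calls at a retained site, the site is classed `hemi`
or `full` when the respective fraction exceeds 2/3 (the two full states
pooled), else `mixed`; a site is `monomorphic` when every called sample
shares one state and `polymorphic` otherwise — a strict partition.

### Heritability classes

With both parental calls available, each site falls into one of twelve
classes determined by the parental pattern and the F1 pattern. The
published class table is not reproduced in any accessible source, so
the package ships a declared default table consistent with every
textual constraint (A = parents identical and F1 uniformly parental,
split hemi/full; B = parents identical, F1 segregating or novel;
C = parents unmethylated, F1 methylated, split hemi/full; D = parents
disparate, with D1 uniform parental and D2–D4 the differing F1
patterns, where the D group dominates real data). The sub-labels are
fixed as:

* B1/B3 — segregating F1 under hemi/full parents; B2/B4 — uniform novel
  F1 state under hemi/full parents;
* C1/C2 — gains that are predominantly (> 2/3) hemi vs. full;
* D1 uniform parental, D2 segregating among parental states, D3
  segregating including a novel methylated state, D4 uniform novel.

Two deliberate conventions: "novel" means a *methylated* state absent
from both parents (an unmethylated F1 plant is a loss, not a novelty),
and parents carrying the two different full states count as disparate
(D), not as "identical full". The table is a constructor argument, so a
corrected empirical table can be swapped in without code changes. The
simulator draws each site's parental and F1 states from per-class
generating rules that are the exact inverses of this classification —
one shared source of truth, which is what makes the noiseless
round-trip tests exact.

## Landscape statistics

The region methylation level of a bin is read-weighted: the sum over
methylated CCGG sites of reads from methylated fragments, divided by
the sum over all CCGG sites of all reads. Metaprofiles split each gene
body plus 2,000-bp flanks into 80 windows of mean depth; flanks get a
fixed quarter of the windows each (fixed physical width) and the body
the remaining half (proportional width), the standard metaplot
convention — with `flank=0` all windows divide the body. Minus-strand
regions are reversed so profiles read 5'→3'; profiles are pooled across
samples by default (per-sample profiles are a flag away). Context
proportions report the share of `full_CmCGG` / `hemi_mCCGG` /
`full_mCCGG` among methylated calls, overall and restricted to gene
bodies plus promoters (2,000 bp upstream of the TSS, strand-aware).

## DMR scan

Calls are binarised (hemi or full = methylated) and two call sets
compared on their shared callable sites over non-overlapping windows
(default 1,000 bp — the original window geometry is unstated, so both
width and tiling are configuration). A window is a DMR when at least 5
sites switch status and the 2×2 chi-squared on
(methylated, unmethylated) × (set a, set b), without Yates correction,
gives p ≤ 0.05; expected counts below 5 fall back to Fisher's exact
test, since small windows are the norm. DMRs intersect genes through
body or promoter overlap and are reported as DMR-DEGs only for genes
whose differential-expression table row passes the FDR < 0.001 flag —
expression analysis itself is upstream input, not part of this package.

## Trait indices

Level-count indices (cold tolerance CTIG/CTIF, recovery RIG/RIF) use
the weighted-mean-over-maximum form
`100 × Σ(level_i × n_i) / (max_level × Σ n_i)`. The original equations
survive only as images, so this standard phenology index — bounded on
[0, 100] and using exactly the defined symbols — is adopted and flagged
as interpretive. Greenhouse recovery levels run 1–4; they are shifted
by their minimum so the index still spans [0, 100]. Leaf fall is
`100 × NLF / NL`; dry weight is `100 × w2 / w1` on the designed 200-g
fresh aliquot; relative yield is a plain ratio; starch content converts
dry basis to fresh basis via DW%/100. All indices are invariant to
replicate scaling and monotone in level shifts (property-tested).

## Association scans

**epiQTL.** Sites are scored 1 / 2⁄3 / 0 (full / hemi / none) and each
polymorphic site is correlated with each trait over pairwise-complete
samples. Pairs with N < 20 overlapping samples are non-evaluable, as
are zero-variance vectors (with the reason recorded rather than a
silent NaN). The test is `t = r·sqrt((N−2)/(1−r²))` against Student's t
with **N − 2** degrees of freedom, two-tailed, α = 0.01 — the source
prose says N − 1 in one sentence but its own CDF call and the standard
Pearson test both use N − 2, which is implemented. A site significant
in ≥ 2 independent trials of one trait family (e.g. CTIF1 and CTIF4) is
flagged *repeatable*. No multiple-testing correction is applied, by
design parity with the original scan; the null-calibration check
confirms the nominal α is honest.

**Markers.** Dominant markers are typed from parental presence
(female-only → lm×ll, male-only → nn×np, both → hk×hk) with expected
segregation 1:1, 1:1, 3:1. Filters: ≥ 2 supporting reads; scored
(non-missing) in > 50 % of individuals — read as call rate, since band
*presence* in a 1:1 marker is 50 % by construction and a presence
filter would discard half of all true markers; goodness-of-fit
chi-squared p ≥ 0.01; markers present in neither parent but observed in
progeny are flagged inconsistent and removed. Heterozygous-ambiguous
calls are treated as missing. The optional Fisher independence check of
the original filter cascade has no stated contrast and is omitted from
the default path.

**Two-point linkage.** rf = mismatching presence calls / informative
progeny (both markers scored), capped at 0.5;
`LOD = n_nonrec·log10(2(1−rf)) + n_rec·log10(2·rf)`, so LOD = 0 at
rf = 0.5 and n·log10 2 at rf = 0. Grouping requires rf < 0.4 and LOD
above a configurable threshold (default 1.0, the only unambiguous
figure in the garbled source sentence). Pairs need ≥ 10 shared
informative progeny and matching phase type. Map ordering and distances
are out of scope.

**Kruskal–Wallis scan.** Per marker and raw trait, tie-corrected H over
the genotype classes against chi-squared with k−1 df, α = 0.001;
markers need ≥ 2 classes with ≥ 2 observations. All-tied traits give
H = 0, p = 1 rather than an error.

## Synthetic data

The generator emulates the study design: 186 F1 clones from two
heterozygous parents, CCGG sites planted every 50 bp on random
scaffolds scrubbed of spurious CCGG (so site discovery recovers exactly
the planted set), per-class inheritance draws, dominant markers
segregating Bernoulli(1/2) or Bernoulli(3/4), and traits as
Σ β·score + Gaussian noise with quantile binning onto 0–4 levels for
the level-based indices. Read depth per enzyme library is
Poisson(mean 5 by default, matching the study's per-sample coverage)
floored at the 2-read callability minimum; setting
`min_library_depth=0` exposes genuine depth dropout. Evidence noise is
a per-read cleavage↔body category flip within a library. Default class
frequencies put mass only on the A and D classes (the B and C gain
classes were absent in the population this emulates), with D2–D4
heaviest; round-trip tests use an equal-mass all-twelve configuration.
Everything is reproducible bit-for-bit from the seed.

What the simulation does *not* emulate: sequence-level reads (no
FASTQ), alignment error and soft clipping, linkage disequilibrium
between sites, recombination maps, shared environmental/block effects
in phenotypes, and SNP-driven methylation differences. Passing tests
therefore demonstrate correctness of the statistical machinery under
the declared generative model, not robustness to alignment artefacts
or population structure.

## Problem sizes and numerical choices

The shipped checks use 2,000 sites × 50 F1 for exact round trips,
10,000 null sites × 186 samples for calibration (the significant
fraction must sit within 3 Monte-Carlo standard errors of α = 0.01),
20 replicates × 400 sites for the planted-effect power grid
(β ∈ {0.1, 0.25, 0.5, 1}, noise SD 1), and 5,000 markers per ratio for
filter retention (≈ 99 % at the p < 0.01 GOF cut) — sizes chosen so the
Monte-Carlo error is small relative to every tolerance asserted.
Chi-squared tests are computed without continuity correction; 2×2
tables with expected counts < 5 use Fisher's exact probability;
degenerate tables (a zero margin) are treated as non-significant.
Pearson r is computed from centred sums and clipped into [−1, 1] before
the t transform; |r| = 1 maps to p = 0 exactly.

## Known limitations

* The heritability class table and the level-index equations are
  declared reconstructions (see above); both are configurable or
  clearly isolated so corrected definitions can be substituted.
* The DMR window geometry (width, tiled vs. sliding) is unstated in the
  source protocol; non-overlapping 1-kb tiles are the default.
* The epiQTL scan inherits the original design's lack of genome-wide
  multiple-testing control; interpret per-site p-values accordingly.
* Evidence extraction assumes coordinate-faithful alignments; it does
  not model chimeric or partially clipped fragments.
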