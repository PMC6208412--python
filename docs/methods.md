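# Methods

## Signal model

i-BLESS marks DNA double-strand breaks (DSBs) by ligating an 11-nt
*proximal* barcode (`TCGAGGTAGTA`) to the blunted break end and an 11-nt
*distal* barcode (`TCGAGACGACG`) to the sonication-sheared far end of each
captured fragment. After barcode removal, only proximal reads start at a
break; the toolkit therefore reduces sequencing data to a **break
profile**: strand-separated counts of read 5' ends at single-nucleotide
resolution. All coordinates are 0-based, half-open. A plus-strand read
contributes one count at its leftmost position; a minus-strand read at
`start + length − 1`. Reads are assumed uniquely mapped (multi-mappers are
excluded when reading SAM, mirroring a bowtie `-m1` policy); this
assumption is what the mappability track makes explicit.

### Break-end convention at enzyme cut sites

Cut geometry is stored as top/bottom cut coordinates relative to the
recognition start (`cut_top`/`cut_bottom`; `cut_top < cut_bottom` is a 5'
overhang, `>` a 3' overhang, `=` blunt). End blunting — fill-in of 5'
overhangs, chew-back of 3' overhangs — leaves the left fragment ending at
`cut_bottom` (exclusive) and the right fragment starting at `cut_top`, in
both chemistries. The labeled break-end bases are therefore:

* plus strand: `site_start + cut_top`
* minus strand: `site_start + cut_bottom − 1` (the rightmost base of the
  left fragment, which is where a minus-strand read's 5' end lands under
  the profile convention above)

For BamHI (`G^GATCC`, cuts 1/5) in `AAGGATCCAA` the site is `[2, 8)` with
break ends at 3 (+) and 6 (−). The minus-end convention is chosen so that
a simulated digest, its emitted reads, the resulting profile and the
precision metrics are all mutually consistent at the base level.

## Mappability

A position is *mappable* iff the k-mer starting there occurs exactly once
across both strands (canonical k-mer counting; a palindromic k-mer at one
locus counts once, since an aligner reports a single alignment there).
Uniqueness is exact-match; the aligner's one-mismatch tolerance is not
modeled — single-mismatch uniqueness has quadratic cost and changes the
track only at near-duplicated loci. k defaults to the trimmed read length
(50 when unknown). k-mers containing N and the trailing k−1 positions of
each chromosome are unmappable.

## Fragile-region test

The genome is tiled into non-overlapping windows (default 1000 nt — gene
scale in budding yeast; the window size is a free parameter). With
genome-wide totals T (treatment) and C (control) and window counts t and
c, the one-sided hypergeometric upper tail P[X ≥ t] with
X ~ Hypergeom(N = T+C, K = T, n = t+c) tests for break enrichment.
Bonferroni multiplies by the number of *tested* windows; windows with
fewer than `min_mappable` (default 20 nt) mappable positions are excluded
from testing and from the multiplier. Mappability correction is realized
as window exclusion, not count rescaling — no rescaling formula is
published for the original implementation, and exclusion is conservative.
Significant windows (default adjusted P < 0.001) are reported sorted by
adjusted P with coordinate tie-breaks; book-ended merging is available but
off by default. Raw (integer) counts are required; normalized profiles are
rejected.

## Correlation QC

Pearson r is computed per integer lag over all positions where both
(shifted) signals are defined, accumulated across chromosomes without ever
pairing positions across a chromosome boundary. Defaults follow the
protocol the statistics were designed around: 1 nt bins, 800 nt lag range.
Zero-variance overlaps give a missing value (never 0). Autocorrelation is
the self case restricted to non-negative lags.

**Period estimation.** The autocorrelation is smoothed with a centered
moving average (width 5 — wide enough to suppress single-lag noise, narrow
enough to resolve 80 vs 162 bp); local maxima in the search range
(default 50–400 bp) must exceed a null band of 3/√N, N being the number of
contributing pairs. Two corrections make the estimate well-defined for
lattice-like backgrounds, whose harmonics (P, 2P, 3P…) have asymptotically
*equal* peak heights so the raw argmax is a coin flip among them:

1. *Fundamental preference*: if the argmax lag is an integer multiple of a
   smaller significant peak within 80% of its height, the smaller lag wins.
2. *Harmonic-comb refinement*: each integer candidate period P is scored
   by the mean smoothed r over its multiples within range, and the score
   parabola is interpolated around its maximum. A single broad peak (the
   peak sd is √2 × the positional jitter sd) localizes the repeat only to
   ±3–4 lags; the comb pins it down exactly (verified: 60/60 exact
   recoveries of repeats 120/162/200 under the default simulation).

**Noise classification.** Cross-correlation of breaks against
linker-elevated MNase coverage over ±400 nt. A significant peak at
|lag| ≤ 20 within 80% of the global maximum → `inter_nucleosomal` (breaks
between nucleosomes). Otherwise, significant local maxima in both the
+[60, 100] and −[100, 60] bands → `nucleosomal_noise` (breaks at dyads;
the half-repeat signature near ±80 bp). Otherwise `unpatterned`. The
"within tolerance of the global maximum" formulation, rather than "the two
largest maxima", is again needed because harmonic peaks (±80, ±240, …) tie
in height; all thresholds are keyword arguments.

## G-quadruplex scanning

A motif is four guanine tracts of 3–5 nt separated by three loops of
1–`max_loop` nt. `max_loop` defaults to 7 (the canonical
G3–5N1–7 definition); loop-length analyses extend it to 16. Configurations:
`intra+` (G tracts on the reference strand), `intra−` (C tracts — G tracts
on the minus strand; found by scanning the reverse complement, which makes
reverse-complementing the genome swap the two sets exactly) and `inter`
(each tract independently G or C with at least one of each; pure-letter
decompositions are intra by definition). The inter rule — any mixed tract
order — is the permissive reading of inter-strand topology; the original
software's exact constraint set is not restated in the sources available
here.

**Disambiguation.** The default scan reports a maximal set of
non-overlapping motifs per configuration by a leftmost-start greedy; at
each feasible start the decomposition is chosen by depth-first preference
for longer tracts, then shorter loops, reading left to right. An
`mode="all"` scan enumerating *every* decomposition exists for oracle
comparisons and set-level invariants.

Loop categories: `L1-4` (all loops ≤ 4), `L5-7` (all ≤ 7, at least one
> 4), `L8-16` (all ≤ 16, at least one > 7); the fine group Lk is keyed by
the longest loop. Flanks are the adjacent regions jointly as long as the
motif, split left/right; for odd spans the left flank takes the extra base.
DSB density is combined-strand counts divided by region length.

Statistics: inside-vs-flank per category by one-sided paired Wilcoxon
signed-rank (scipy; all-zero difference vectors report P = 1);
intra-vs-inter inside densities by two-sided Kolmogorov–Smirnov; a paired
profile (e.g. a pif1 helicase mutant) by per-motif paired Wilcoxon.
Meta-profiles average the signal in a 200 bp window centered on motif
centers (even spans center left-of-center) in 10 bp bins. Loop
breakability compares mean density in loops of each length 1–7 against
seeded random same-length (optionally fully mappable) control regions.

## Enzyme cut precision and off-targets

Recognition sites are scanned on both strands with IUPAC expansion;
palindromic sites are reported once (plus strand). The exact fraction is
the share of all profile reads sitting exactly at expected break ends
(strand-aware when the profile is stranded; on the combined view for
profiles read back from bedGraph, which cannot carry strand); the
within-tolerance fraction uses ±1 nt by default. A site is detected when
at least `detect_min` reads fall in its windows. Off-target search slides
the canonical recognition sequence (both orientations, ungapped) across
each candidate region padded by one site length and reports the best
match count; candidates at or above `min_identity` (default 10) are kept.
Ungapped identity is the documented interpretation of "bp identity" —
no alignment details are published.

## Enrichment permutation test

Observed overlap = mappable nt in (DSB-rich windows ∩ feature) / mappable
nt in DSB-rich windows; expected overlap = the same over all windows. The
null distribution of observed/expected comes from permuting the DSB-rich
label multiset over windows (default 1000 permutations, seed required);
P = (1 + #{null ≥ observed}) / (1 + n_perm) for enrichment, ≤ for
depletion — one-sided in the observed direction, ties counted toward the
tail, never exactly 0. A ratio of exactly 1 reports neither direction.
A promoter helper (fixed 500 nt upstream of the 5' gene end) is provided
as a convenience convention.

## Simulator

The generator reproduces the study conditions at desk scale, with every
output deterministic under a seed:

* **Genome**: i.i.d. bases at a chosen GC fraction (default 0.38, the
  budding-yeast genome average).
* **Nucleosomal background**: breaks at dyads (phase repeat/2) or linker
  midpoints (phase 0) of a regular lattice with repeat 162 nt (the yeast
  nucleosome repeat) plus rounded Gaussian jitter (default sd 20 nt).
* **MNase-like coverage**: positions within linker_len/2 (circular
  distance) of lattice boundaries carry `enrichment_fold` (default 10)
  times the core weight, modeling linker/NDR-elevated MNase signal.
* **Digest**: per site, Poisson cut counts with mean
  `n_cells × cutting_fraction × dilution` (dilution = fraction of cells
  carrying the site, e.g. 1e-5 for a 1:100,000 mixture); each cut yields
  the two blunted break ends, optionally jittered; uniform Poisson
  background at a per-nucleotide rate.
* **Reads**: read 1 = proximal barcode + genomic sequence from the break
  end into the fragment, read 2 = distal barcode at the sheared end;
  fragment lengths clipped normal (mean 400, sd 80 — sonication to
  ~400 bp); substitution errors at a per-base rate; optional resection
  (geometric 5'→3' loss) shifts labeled ends unidirectionally into the
  fragment. Truth alignments accompany the FASTQ so the pipeline is
  testable without an external aligner.

The simulator is a lattice idealization: it has no replication-origin
structure, no GC/PCR bias, no indels, no homopolymer mappability loss and
perfectly regular nucleosome phasing (real chromatin shows phase
diffusion, which *damps* higher autocorrelation harmonics — the harmonic
tie handled above is an artifact of the idealization, not of real data).
Passing tests therefore demonstrate the correctness of the statistics and
conventions, not the biology of any particular dataset.

## Numerical choices and degenerate inputs

* Hypergeometric tails via `scipy.stats.hypergeom.sf` (log-space stable);
  verified against exact pmf enumeration for all totals ≤ 30.
* Pearson accumulations in float64 from cumulative sums plus one dot
  product per lag; r is NaN (missing) on zero-variance overlaps, and
  missing values are excluded from smoothing and peak search.
* Wilcoxon uses scipy's automatic exact/normal switch; the all-ties case
  short-circuits to P = 1.
* Bonferroni multiplies before clipping at 1; adjusted P never falls below
  raw P.
* Sorting ties are always broken by genomic coordinate, so outputs are
  independent of chromosome processing order.
* Problem sizes used by the test suite and the acceptance script (1 Mb
  genomes, 1e5 breaks, 100 kb scanner oracles, 1e4-window calibrations)
  were chosen as the smallest scales at which the estimators' discreteness
  is negligible relative to the quantities asserted.

## Known limitations

* Mappability ignores the aligner's mismatch tolerance (documented above).
* bedGraph round trips lose strand; strand-aware analyses need profiles
  built in-process or per-strand tracks.
* The inter-strand G4 rule is permissive about tract order.
* Enzyme geometries ship as a standard reference table
  (`data/enzymes.json`) and are not independently re-derived at build
  time.
* No FDR alternatives to Bonferroni; no absolute per-cell DSB
  quantification (spike-in calibration is out of scope).
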