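# ibless

Analysis toolkit for **i-BLESS** double-strand-break (DSB) sequencing in
budding yeast (and any genome): from barcoded read pairs to
single-nucleotide break profiles, statistically called fragile regions,
nucleosome-periodicity quality control, G-quadruplex fragility statistics,
endonuclease cut-precision/off-target metrics and feature-enrichment
tests — plus a ground-truth simulator so every stage is testable without
sequencing data.

i-BLESS ligates an 11-nt *proximal* barcode (`TCGAGGTAGTA`) directly to
each blunted break end and a *distal* barcode (`TCGAGACGACG`) to the
sheared far end of the captured fragment. Reads starting with the proximal
barcode mark true break positions at single-nucleotide resolution; the
library is organized around that signal:

* **barcodes** — classify/trim barcodes (Hamming ≤ `max_mismatch`,
  5'-anchored), select proximal reads, summarize fragment classes.
* **core_io** — FASTA/SAM/BED/bedGraph IO and the `BreakProfile`
  container: strand-separated counts of read 5' ends per nucleotide.
* **mappability** — exact k-mer-uniqueness track (both strands), the
  uniqueness assumption of a bowtie `-m1` mapping made explicit.
* **fragile** — windowed one-sided hypergeometric test of treatment vs
  control counts, P[X ≥ t] with X ~ Hypergeom(T+C, T, t+c), Bonferroni
  over testable (sufficiently mappable) windows, default adjusted
  P < 0.001.
* **qc_corr** — Pearson auto/cross-correlation per integer lag (1 nt bins,
  800 nt range, never across chromosome boundaries), repeat-length
  estimation, and classification of nucleosome-linked noise: artifact
  breaks are periodic with the ~162 bp yeast nucleosome repeat, and
  cross-correlation against linker-elevated MNase coverage peaks at 0
  (breaks between nucleosomes) or ±80 bp (breaks within nucleosomes).
* **g4** — intra- and inter-strand G-quadruplex motif scanning
  (G3–5 N1–max ×4, loops up to 16 nt), loop-length categories
  (L1–4/L5–7/L8–16, Lk), inside-vs-flank Wilcoxon, intra-vs-inter
  Kolmogorov–Smirnov, paired mutant comparisons, meta-profiles and
  per-loop-length breakability.
* **enzymes** — IUPAC recognition-site scanning with cut geometry (BamHI,
  NotI, SrfI, AsiSI, I-SceI built in), exact/±1 nt cut-precision
  fractions, per-site read tables, ungapped off-target identity search.
* **enrichment** — permutation test (label shuffling over windows) for
  feature enrichment/depletion in DSB-rich regions on mappable
  nucleotides.
* **simulate** — seeded generator of genomes, nucleosome-phased
  backgrounds, MNase-like coverage, enzyme digests with dilution (down to
  1 cut cell in 100,000) and barcoded FASTQ with truth alignments.

See `docs/methods.md` for the statistical conventions and their
rationale.

## Worked example

Simulate a BamHI digest with 0.2% background breaks, demultiplex the
barcoded reads, profile them, and score cut precision:

```sh
ibless simulate genome --length 50000 --seed 5 --out g.fa
ibless simulate digest --genome g.fa --enzyme BamHI --fraction 1.0 \
    --n-cells 50 --background-rate 0.002 --seed 9 \
    --out digest.bedgraph --fastq-prefix sim
ibless barcodes --r1 sim_R1.fastq --r2 sim_R2.fastq --out prox.fq
ibless profile --alignments sim_truth.bed --genome g.fa --out profile.bedgraph
ibless enzymes precision --breaks profile.bedgraph --genome g.fa --enzyme BamHI
```

which prints

```
924 labeled ends -> digest.bedgraph
   fragment_class  count  fraction
  proximal-distal    924       1.0
proximal-proximal      0       0.0
    distal-distal      0       0.0
            other      0       0.0
924 reads profiled -> profile.bedgraph
{
  "n_sites": 8,
  "n_detected": 8,
  "fraction_exact": 0.8961038961038961,
  ...
}
```

Every fragment carries one proximal and one distal barcode (fraction 1.0),
all 8 BamHI sites in this 50 kb genome are detected, and ~90% of reads sit
exactly at a predicted cut base — the remainder are the simulated uniform
background (~100 of 924 ends), not mapping error.

Quality control on a simulated over-fixation background (breaks at
nucleosome dyads, repeat 162 nt):

```sh
ibless simulate background --length 50000 --n-breaks 20000 --seed 6 --out b.bedgraph
ibless simulate mnase --length 50000 --seed 11 --n-reads 30000 --out mnase.bedgraph
ibless qc --breaks b.bedgraph --genome g.fa --mnase mnase.bedgraph --out qc.tsv
```

```
dominant autocorrelation period: 162
noise classification: nucleosomal_noise (peaks: [(-241, 0.313), (-80, 0.311), (81, 0.314), (244, 0.313)])
```

The autocorrelation period equals the nucleosome repeat and the
cross-correlation peaks at ±80 bp (half the repeat) — the signature of
artifactual breaks sitting *within* nucleosomes.

Fragile-region calling on a treatment with one 10× hot window over a
matched control:

```sh
ibless fragile --treatment treat.bedgraph --control control.bedgraph \
    --genome g.fa --window 1000 --alpha 0.001 --out fragile.tsv --bed fragile.bed
```

```
1 significant windows of 50 tested (alpha=0.001)
chrom  start   end    t  c  mappable_len    ratio         p_raw         p_adj
 chrI  12000 13000 1116 96          1000 9.875063  8.885426e-206 4.442713e-204
```

Exactly the spiked window is called, with its enrichment ratio
(t/T)/(c/C) ≈ 9.9 matching the constructed 10×.

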