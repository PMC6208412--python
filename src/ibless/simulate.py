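"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study conditions the pipeline was designed for:
an enzyme-cut genome with chosen per-site cutting fractions and dilution
(cells carrying a cut site mixed into cells without), nucleosome-periodic
artifact breaks (repeat length 162 nt, the budding-yeast nucleosome
spacing), MNase-like coverage elevated in linkers, and barcoded paired
reads (11-nt proximal barcode at the labeled break end, distal barcode at
the sonication-sheared end; fragments ~400 bp, normal sd 80).  Reads are
emitted together with truth alignments so the pipeline can be exercised
without an external aligner.  Everything is reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import barcodes
from .core_io import (
    AlignedReadRecord,
    BreakProfile,
    GenomeSequence,
    reverse_complement,
)
from .enzymes import EnzymeSite, EnzymeSpec, find_sites

DEFAULT_CHROM = "chrI"
FRAGMENT_MEAN = 400.0
FRAGMENT_SD = 80.0


def simulate_genome(length: int, gc: float = 0.38, seed: int = 0) -> GenomeSequence:
    """Random i.i.d. genome at the given GC fraction (one chromosome)."""
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seq = "".join(bases[rng.choice(4, size=length, p=p)])
    return GenomeSequence({DEFAULT_CHROM: seq})


def _profile_from_positions(
    positions: np.ndarray, strands: np.ndarray, length: int, chrom: str = DEFAULT_CHROM
) -> BreakProfile:
    plus = np.bincount(positions[strands], minlength=length).astype(float)
    minus = np.bincount(positions[~strands], minlength=length).astype(float)
    return BreakProfile({chrom: plus}, {chrom: minus})


def simulate_nucleosomal_background(
    genome_length: int,
    repeat: int = 162,
    jitter_sd: float = 20.0,
    n_breaks: int = 100_000,
    seed: int = 0,
    mode: str = "dyad",
) -> BreakProfile:
    """Nucleosome-phased artifact breaks.

    Break positions sit at dyads (phase repeat/2) or linker midpoints
    (phase 0) of a regular nucleosome lattice, plus rounded Gaussian jitter.
    """
    if repeat < 20:
        raise ValueError("repeat must be >= 20")
    if n_breaks < 1:
        raise ValueError("n_breaks must be >= 1")
    if mode not in ("dyad", "linker"):
        raise ValueError("mode must be 'dyad' or 'linker'")
    rng = np.random.default_rng(seed)
    phase = repeat // 2 if mode == "dyad" else 0
    centers = np.arange(phase, genome_length, repeat)
    idx = rng.integers(0, len(centers), size=n_breaks)
    pos = centers[idx] + np.rint(rng.normal(0.0, jitter_sd, size=n_breaks)).astype(int)
    pos = np.clip(pos, 0, genome_length - 1)
    strands = rng.random(n_breaks) < 0.5
    return _profile_from_positions(pos, strands, genome_length)


def simulate_mnase(
    genome_length: int,
    repeat: int = 162,
    linker_len: int = 20,
    enrichment_fold: float = 10.0,
    n_reads: int = 100_000,
    seed: int = 0,
) -> BreakProfile:
    """Linker-elevated MNase-like coverage on the same nucleosome lattice.

    Positions within ``linker_len/2`` of lattice boundaries (phase 0) carry
    ``enrichment_fold`` times the weight of nucleosome-core positions.
    """
    if linker_len >= repeat:
        raise ValueError("linker_len must be smaller than repeat")
    rng = np.random.default_rng(seed)
    phase = np.arange(genome_length) % repeat
    # circular distance to the lattice boundary keeps the linker centered
    # exactly on phase 0 (so cross-correlation peaks sit at +-repeat/2)
    dist = np.minimum(phase, repeat - phase)
    in_linker = dist <= linker_len // 2
    weights = np.where(in_linker, enrichment_fold, 1.0)
    weights = weights / weights.sum()
    pos = rng.choice(genome_length, size=n_reads, p=weights)
    strands = rng.random(n_reads) < 0.5
    return _profile_from_positions(pos, strands, genome_length)


@dataclass(frozen=True)
class BreakEvent:
    """One labeled break end with its provenance."""

    chrom: str
    position: int  # 5' labeled base
    strand: str
    origin: str    # "<enzyme>:<site index>" or "background"


def simulate_digest(
    genome: GenomeSequence,
    enzymes: dict[EnzymeSpec, float],
    n_cells: int = 10_000,
    dilution: float = 1.0,
    background_rate: float = 0.0,
    end_jitter_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BreakProfile, list[BreakEvent]]:
    """Enzyme digestion of a diluted cell population.

    Each site's expected number of cut cells is
    ``n_cells * cutting_fraction * dilution`` (dilution is the fraction of
    cells carrying the site, e.g. 1e-5 for a 1:100,000 mixture); the
    realized count is Poisson.  Each cut produces two labeled ends, the
    plus- and minus-strand blunted break ends of the site, jittered by a
    rounded Gaussian of sd ``end_jitter_sd``.  Background breaks arrive
    uniformly as a Poisson process at ``background_rate`` expected events
    per nucleotide, each contributing one labeled end on a random strand.
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    events: list[BreakEvent] = []

    def jitter(p: int, clen: int) -> int:
        if end_jitter_sd > 0:
            p = p + int(np.rint(rng.normal(0.0, end_jitter_sd)))
        return int(np.clip(p, 0, clen - 1))

    for spec, fraction in enzymes.items():
        if not (0.0 <= fraction <= 1.0):
            raise ValueError("cutting fractions must be in [0, 1]")
        sites = find_sites(genome, spec)
        lam = n_cells * fraction * dilution
        for i, site in enumerate(sites):
            clen = lengths[site.chrom]
            n_cut = rng.poisson(lam)
            for _ in range(n_cut):
                events.append(
                    BreakEvent(site.chrom, jitter(site.plus_break_end, clen),
                               "+", f"{spec.name}:{i}")
                )
                events.append(
                    BreakEvent(site.chrom, jitter(site.minus_break_end, clen),
                               "-", f"{spec.name}:{i}")
                )
    if background_rate > 0:
        for chrom, clen in lengths.items():
            n_bg = rng.poisson(background_rate * clen)
            positions = rng.integers(0, clen, size=n_bg)
            strands = rng.random(n_bg) < 0.5
            for p, s in zip(positions, strands):
                events.append(BreakEvent(chrom, int(p), "+" if s else "-",
                                         "background"))

    profile = BreakProfile.zeros(lengths)
    for ev in events:
        (profile.plus if ev.strand == "+" else profile.minus)[ev.chrom][ev.position] += 1
    profile.total_mapped = float(len(events))
    return profile, events


@dataclass
class FastqTruth:
    """Ground truth emitted alongside the simulated FASTQ pair."""

    alignments: list[AlignedReadRecord]  # truth placement of each proximal read
    table: pd.DataFrame                  # read id, break position, strand, origin


def emit_fastq(
    events: list[BreakEvent],
    genome: GenomeSequence,
    out_r1,
    out_r2,
    read_len: int = 75,
    error_rate: float = 0.0,
    seed: int = 0,
    fragment_mean: float = FRAGMENT_MEAN,
    fragment_sd: float = FRAGMENT_SD,
    resection_mean: float | None = None,
) -> FastqTruth:
    """Write barcoded read pairs for a list of labeled break ends.

    Read 1 starts with the proximal barcode followed by genomic sequence
    from the (possibly resected) break end into the fragment; read 2 starts
    with the distal barcode at the sonication-sheared end.  Fragment
    lengths are clipped normal; substitution errors are applied at
    ``error_rate`` per base.  Optional resection shifts the labeled end
    away from the break by a geometric number of nucleotides (mean
    ``resection_mean``), emulating blunted 3'-overhang loss.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise ValueError("error_rate must be in [0, 1]")
    genomic_len = read_len - barcodes.BARCODE_LEN
    if genomic_len < 1:
        raise ValueError("read_len must exceed the 11-nt barcode")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def add_errors(seq: str) -> str:
        if error_rate == 0:
            return seq
        arr = np.array(list(seq))
        hit = rng.random(len(arr)) < error_rate
        if hit.any():
            # substitute with one of the three other bases
            for i in np.nonzero(hit)[0]:
                choices = [b for b in "ACGT" if b != arr[i]]
                arr[i] = choices[rng.integers(3)]
        return "".join(arr)

    alignments: list[AlignedReadRecord] = []
    rows = []
    with open(out_r1, "w") as f1, open(out_r2, "w") as f2:
        for i, ev in enumerate(events):
            seq = genome[ev.chrom]
            clen = len(seq)
            pos = ev.position
            if resection_mean is not None and resection_mean > 0:
                shift = rng.geometric(1.0 / resection_mean)
                # resection moves the blunted end into the fragment body
                pos = pos + shift if ev.strand == "+" else pos - shift
                pos = int(np.clip(pos, 0, clen - 1))
            frag = int(np.clip(np.rint(rng.normal(fragment_mean, fragment_sd)),
                               genomic_len + 1, None))
            if ev.strand == "+":
                # a read must fit the chromosome; ends this close to the
                # boundary are shifted inward (truth table keeps the break)
                pos = min(pos, clen - genomic_len)
                frag = min(frag, clen - pos)
                if frag <= genomic_len:
                    frag = genomic_len
                g1 = seq[pos:pos + genomic_len]
                align = AlignedReadRecord(ev.chrom, pos, "+", genomic_len)
                shear = pos + frag
                g2 = reverse_complement(seq[max(0, shear - genomic_len):shear])
            else:
                pos = max(pos, genomic_len - 1)
                frag = min(frag, pos + 1)
                if frag <= genomic_len:
                    frag = genomic_len
                g1 = reverse_complement(seq[pos - genomic_len + 1:pos + 1])
                align = AlignedReadRecord(ev.chrom, pos - genomic_len + 1, "-",
                                          genomic_len)
                shear = pos - frag + 1
                g2 = seq[shear:shear + genomic_len]
            rid = f"ev{i}"
            r1 = add_errors(barcodes.PROXIMAL + g1)
            r2 = add_errors(barcodes.DISTAL + g2)
            f1.write(f"@{rid}\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}\n{r2}\n+\n{'I' * len(r2)}\n")
            alignments.append(align)
            rows.append(
                {
                    "read_id": rid,
                    "chrom": ev.chrom,
                    "break_position": ev.position,
                    "strand": ev.strand,
                    "origin": ev.origin,
                }
            )
    return FastqTruth(alignments, pd.DataFrame(rows))
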