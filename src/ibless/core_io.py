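"""Genomic primitives shared by the whole toolkit.

Coordinates are 0-based, half-open everywhere; strands are "+", "-" or "."
(unstranded).  A :class:`BreakProfile` stores strand-separated per-nucleotide
break-end counts: each uniquely mapping, barcode-trimmed read contributes a
single count at its 5' end (the base that was ligated to the proximal
adapter) -- the leftmost position for a plus-strand read and the rightmost
(``start + length - 1``) for a minus-strand read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_COMPLEMENT_BYTES = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement_bytes(seq: bytes) -> bytes:
    return seq.translate(_COMPLEMENT_BYTES)[::-1]


class GenomeSequence:
    """Ordered mapping of chromosome name to uppercase ACGTN sequence."""

    def __init__(self, chromosomes: Mapping[str, str]):
        if not chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        clean: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if name in clean:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            seq = seq.upper()
            extra = set(seq) - _ALPHABET
            if extra:
                raise ValueError(
                    f"chromosome {name!r} contains characters outside ACGTN: "
                    f"{sorted(extra)}"
                )
            clean[name] = seq
        self.chromosomes = clean

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    def reverse_complemented(self) -> "GenomeSequence":
        return GenomeSequence(
            {name: reverse_complement(seq) for name, seq in self.chromosomes.items()}
        )


def read_genome(path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; characters outside ACGTN are replaced with N
    (a warning is logged with the per-chromosome count).
    """
    chroms: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chroms:
            raise ValueError(f"duplicate FASTA record name: {record.id!r}")
        seq = str(record.seq).upper()
        n_bad = sum(1 for ch in set(seq) if ch not in _ALPHABET)
        if n_bad:
            bad = [ch for ch in set(seq) if ch not in _ALPHABET]
            count = sum(seq.count(ch) for ch in bad)
            logger.warning(
                "chromosome %s: %d non-ACGTN characters replaced with N",
                record.id, count,
            )
            seq = "".join(ch if ch in _ALPHABET else "N" for ch in seq)
        chroms[record.id] = seq
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(chroms)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedReadRecord:
    """Minimal uniquely-mapped read: placement, strand and length."""

    chrom: str
    start: int  # leftmost 0-based position
    strand: str
    length: int
    unique: bool = True

    def five_prime_end(self) -> int:
        """Position of the read 5' end (the break-proximal base)."""
        return self.start if self.strand == "+" else self.start + self.length - 1


class BreakProfile:
    """Strand-aware per-nucleotide break-end counts for one genome.

    ``plus``/``minus`` map chromosome name to a float array of counts (raw
    profiles hold integers; per-million normalization produces floats).  The
    combined view is always the elementwise sum of the two strands.
    """

    def __init__(
        self,
        plus: Mapping[str, np.ndarray],
        minus: Mapping[str, np.ndarray],
        total_mapped: float | None = None,
        normalized: bool = False,
        scale: float = 1.0,
        stranded: bool = True,
    ):
        if set(plus) != set(minus):
            raise ValueError("plus/minus strand chromosome sets differ")
        self.plus = {c: np.asarray(a, dtype=float) for c, a in plus.items()}
        self.minus = {c: np.asarray(a, dtype=float) for c, a in minus.items()}
        for c in self.plus:
            if self.plus[c].shape != self.minus[c].shape:
                raise ValueError(f"strand array lengths differ on {c}")
            if (self.plus[c] < 0).any() or (self.minus[c] < 0).any():
                raise ValueError("break counts must be non-negative")
        if total_mapped is None:
            total_mapped = float(self.total_counts())
        self.total_mapped = total_mapped
        self.normalized = normalized
        self.scale = scale
        # False for profiles read back from bedGraph, where per-strand
        # attribution is not representable
        self.stranded = stranded

    @classmethod
    def zeros(cls, lengths: Mapping[str, int]) -> "BreakProfile":
        plus = {c: np.zeros(n) for c, n in lengths.items()}
        minus = {c: np.zeros(n) for c, n in lengths.items()}
        return cls(plus, minus, total_mapped=0.0)

    @property
    def chroms(self) -> list[str]:
        return list(self.plus)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.plus.items()}

    def combined(self, chrom: str) -> np.ndarray:
        return self.plus[chrom] + self.minus[chrom]

    def total_counts(self) -> float:
        return float(
            sum(a.sum() for a in self.plus.values())
            + sum(a.sum() for a in self.minus.values())
        )

    def same_genome_as(self, other: "BreakProfile") -> bool:
        return self.lengths == other.lengths


def profile_from_alignments(
    records: Iterable[AlignedReadRecord], genome: GenomeSequence
) -> BreakProfile:
    """Build a break profile from uniquely mapped, barcode-trimmed reads.

    Each record increments exactly one position: the 5' end of the read.
    Multi-mapping records must have been excluded upstream.
    """
    profile = BreakProfile.zeros(genome.lengths)
    n = 0
    for rec in records:
        if rec.chrom not in genome:
            raise ValueError(f"read on unknown chromosome {rec.chrom!r}")
        clen = genome.length(rec.chrom)
        if rec.start < 0 or rec.start + rec.length > clen:
            raise ValueError(
                f"read at {rec.chrom}:{rec.start} (length {rec.length}) "
                f"exceeds chromosome length {clen}"
            )
        pos = rec.five_prime_end()
        if rec.strand == "+":
            profile.plus[rec.chrom][pos] += 1
        elif rec.strand == "-":
            profile.minus[rec.chrom][pos] += 1
        else:
            raise ValueError(f"read with invalid strand {rec.strand!r}")
        n += 1
    profile.total_mapped = float(n)
    return profile


def normalize_per_million(profile: BreakProfile) -> BreakProfile:
    """Scale counts so that the genome-wide sum is 1e6 reads."""
    if profile.normalized:
        raise ValueError("profile is already normalized")
    if profile.total_mapped <= 0:
        raise ValueError("cannot normalize a profile with total_mapped = 0")
    factor = 1e6 / profile.total_mapped
    plus = {c: a * factor for c, a in profile.plus.items()}
    minus = {c: a * factor for c, a in profile.minus.items()}
    return BreakProfile(
        plus, minus,
        total_mapped=profile.total_mapped,
        normalized=True,
        scale=factor,
    )


# ---------------------------------------------------------------------------
# bedGraph / BED readers and writers


def write_profile(profile: BreakProfile, path, track: str = "combined") -> None:
    """Write a profile track to bedGraph (0-based half-open).

    Runs of equal nonzero values are merged into single lines.  ``track``
    selects ``combined``, ``plus`` or ``minus``.
    """
    if track == "combined":
        arrays = {c: profile.combined(c) for c in profile.chroms}
    elif track == "plus":
        arrays = profile.plus
    elif track == "minus":
        arrays = profile.minus
    else:
        raise ValueError(f"unknown track {track!r}")
    with open(path, "w") as fh:
        for chrom, arr in arrays.items():
            (nz,) = np.nonzero(arr)
            if len(nz) == 0:
                continue
            # merge consecutive positions sharing the same value
            run_start = nz[0]
            prev = nz[0]
            val = arr[nz[0]]
            for p in nz[1:]:
                if p == prev + 1 and arr[p] == val:
                    prev = p
                    continue
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{_fmt(val)}\n")
                run_start = prev = p
                val = arr[p]
            fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{_fmt(val)}\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_profile(path, lengths: Mapping[str, int] | GenomeSequence) -> BreakProfile:
    """Read a bedGraph file into an unstranded profile.

    Strand information is not representable in bedGraph; all counts are
    stored on the plus strand (the combined view is what downstream
    statistics use).
    """
    if isinstance(lengths, GenomeSequence):
        lengths = lengths.lengths
    plus = {c: np.zeros(n) for c, n in lengths.items()}
    minus = {c: np.zeros(n) for c, n in lengths.items()}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed bedGraph line {i}")
            chrom, start, end, value = parts
            try:
                start, end, value = int(start), int(end), float(value)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed bedGraph line {i}") from exc
            if chrom not in plus:
                raise ValueError(f"{path}: line {i}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"{path}: line {i}: interval out of bounds")
            plus[chrom][start:end] += value
    return BreakProfile(plus, minus, stranded=False)


def read_intervals(path) -> list[GenomicInterval]:
    """Read a BED file (3-6 columns tolerated) into intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if not (3 <= len(parts) <= 12):
                raise ValueError(f"{path}: malformed BED line {i}")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {i}") from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {i}: {exc}") from exc
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path, names=None) -> None:
    """Write intervals as BED6 (name column optional, score 0)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_alignments_sam(path) -> list[AlignedReadRecord]:
    """Read mapped, primary alignments from SAM/BAM via pysam.

    Secondary/supplementary records and reads flagged as multi-mapping
    (NH tag > 1) are excluded, mirroring a bowtie ``-m1`` alignment policy.
    """
    import pysam

    records: list[AlignedReadRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.has_tag("NH") and read.get_tag("NH") > 1:
                continue
            records.append(
                AlignedReadRecord(
                    chrom=read.reference_name,
                    start=read.reference_start,
                    strand="-" if read.is_reverse else "+",
                    length=read.query_alignment_length or read.query_length,
                )
            )
    return records


def read_alignments_bed(path) -> list[AlignedReadRecord]:
    """Read alignments from a 6-column BED (as emitted by the simulator)."""
    return [
        AlignedReadRecord(iv.chrom, iv.start, iv.strand, iv.length)
        for iv in read_intervals(path)
    ]
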