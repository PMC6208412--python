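"""k-mer uniqueness mappability.

A position is mappable iff the k-mer starting there occurs exactly once
across both strands of the genome, mirroring the unique-alignment policy
(bowtie ``-m1``) under which the break profiles were produced.  Uniqueness
is exact-match: the aligner's single-mismatch tolerance (``-v1``) is not
modeled.  A palindromic k-mer present at a single locus reads identically
on both strands but an aligner reports one alignment there, so it counts
as one location and is mappable.  k-mers containing N are unmappable, as
are the k-1 trailing positions of each chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import GenomeSequence, GenomicInterval, reverse_complement_bytes

logger = logging.getLogger(__name__)


@dataclass
class MappabilityTrack:
    k: int
    mappable: dict[str, np.ndarray]  # bool array, one entry per position

    def fraction_mappable(self) -> float:
        total = sum(len(a) for a in self.mappable.values())
        hits = sum(int(a.sum()) for a in self.mappable.values())
        return hits / total if total else 0.0


def compute_mappability(genome: GenomeSequence, k: int) -> MappabilityTrack:
    """Exact k-mer-uniqueness track over both strands of ``genome``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if all(genome.length(c) < k for c in genome):
        logger.warning("k=%d exceeds every chromosome length; track is empty", k)
        return MappabilityTrack(
            k, {c: np.zeros(genome.length(c), dtype=bool) for c in genome}
        )

    # count canonical k-mers (min of forward and reverse complement) over
    # every plus-strand position; this counts each genomic locus once while
    # collapsing the two strands
    counts: dict[bytes, int] = {}
    encoded: dict[str, tuple[bytes, bytes]] = {}
    for chrom in genome:
        fwd = genome[chrom].encode()
        rev = reverse_complement_bytes(fwd)
        encoded[chrom] = (fwd, rev)
        L = len(fwd)
        for p in range(L - k + 1):
            kmer = fwd[p:p + k]
            rc = rev[L - p - k:L - p]
            canon = kmer if kmer <= rc else rc
            counts[canon] = counts.get(canon, 0) + 1

    mappable: dict[str, np.ndarray] = {}
    for chrom in genome:
        fwd, rev = encoded[chrom]
        L = len(fwd)
        track = np.zeros(L, dtype=bool)
        has_n = np.frombuffer(fwd, dtype=np.uint8) == ord("N")
        n_cum = np.concatenate(([0], np.cumsum(has_n)))
        for p in range(L - k + 1):
            if n_cum[p + k] - n_cum[p]:
                continue
            kmer = fwd[p:p + k]
            rc = rev[L - p - k:L - p]
            canon = kmer if kmer <= rc else rc
            track[p] = counts[canon] == 1
        mappable[chrom] = track
    return MappabilityTrack(k, mappable)


def mappable_length(track: MappabilityTrack, interval: GenomicInterval) -> int:
    """Number of mappable positions inside ``[start, end)``."""
    arr = track.mappable[interval.chrom]
    return int(arr[interval.start:interval.end].sum())


def mappable_blocks(track: MappabilityTrack) -> list[GenomicInterval]:
    """Maximal runs of mappable positions, as intervals (for BED output)."""
    blocks: list[GenomicInterval] = []
    for chrom, arr in track.mappable.items():
        padded = np.concatenate(([False], arr, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        blocks.extend(
            GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
        )
    return blocks
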