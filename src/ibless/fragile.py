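"""Fragile (DSB-rich) region detection.

The genome is tiled into fixed-size windows and each window's treatment vs
control break counts are tested with a one-sided hypergeometric test
(enrichment only): with genome-wide totals T (treatment) and C (control),
the window counts t and c are compared against drawing t + c reads from an
urn of T treatment and C control reads, P = P[X >= t].  Bonferroni
correction multiplies by the number of tested windows; windows with fewer
than ``min_mappable`` uniquely mappable positions are excluded from testing
and from the Bonferroni count (mappability correction by exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_io import BreakProfile, GenomeSequence, GenomicInterval
from .mappability import MappabilityTrack, mappable_length


@dataclass
class WindowCounts:
    interval: GenomicInterval
    t: int = 0
    c: int = 0
    mappable_len: int = 0


@dataclass
class FragileRegion:
    interval: GenomicInterval
    t: int
    c: int
    ratio: float
    p_raw: float
    p_adj: float


def window_partition(
    lengths,
    window_size: int,
    mappability: MappabilityTrack | None = None,
    min_mappable: int = 0,
) -> list[WindowCounts]:
    """Tile chromosomes into non-overlapping windows; keep testable ones.

    ``lengths`` is a GenomeSequence or a chrom->length mapping.  The final
    partial window of each chromosome is kept.  Windows whose mappable
    length falls below ``min_mappable`` are dropped (they are untestable
    and do not enter the Bonferroni count).  Without a mappability track
    every position counts as mappable.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if isinstance(lengths, GenomeSequence):
        lengths = lengths.lengths
    windows: list[WindowCounts] = []
    for chrom, clen in lengths.items():
        for start in range(0, clen, window_size):
            end = min(start + window_size, clen)
            iv = GenomicInterval(chrom, start, end)
            if mappability is None:
                m = iv.length
            else:
                m = mappable_length(mappability, iv)
            if m < min_mappable:
                continue
            windows.append(WindowCounts(iv, mappable_len=m))
    return windows


def hypergeom_window_p(t: int, c: int, T: int, C: int) -> float:
    """Upper-tail P[X >= t], X ~ Hypergeom(N=T+C, K=T, n=t+c)."""
    if not (0 <= t <= T and 0 <= c <= C):
        raise ValueError("require 0 <= t <= T and 0 <= c <= C")
    if T + C == 0:
        raise ValueError("T + C must be positive")
    return float(hypergeom.sf(t - 1, T + C, T, t + c))


def _fill_window_counts(windows: list[WindowCounts], treatment, control) -> None:
    cumsums_t = {c: np.concatenate(([0.0], np.cumsum(treatment.combined(c))))
                 for c in treatment.chroms}
    cumsums_c = {c: np.concatenate(([0.0], np.cumsum(control.combined(c))))
                 for c in control.chroms}
    for w in windows:
        iv = w.interval
        ct = cumsums_t[iv.chrom]
        cc = cumsums_c[iv.chrom]
        w.t = int(round(ct[iv.end] - ct[iv.start]))
        w.c = int(round(cc[iv.end] - cc[iv.start]))


def evaluate_windows(
    treatment: BreakProfile,
    control: BreakProfile,
    window_size: int = 1000,
    mappability: MappabilityTrack | None = None,
    min_mappable: int = 20,
) -> pd.DataFrame:
    """Hypergeometric enrichment test on every testable window.

    Returns a DataFrame with one row per tested window (chrom, start, end,
    t, c, mappable_len, ratio, p_raw, p_adj), Bonferroni-adjusted over the
    tested windows.  Profiles must be raw (integer) counts.
    """
    if not treatment.same_genome_as(control):
        raise ValueError("treatment and control profiles are on different genomes")
    if treatment.normalized or control.normalized:
        raise ValueError("fragile-region testing requires raw (unnormalized) counts")
    T = int(round(treatment.total_counts()))
    C = int(round(control.total_counts()))
    if C == 0:
        raise ValueError("control profile has no reads")
    windows = window_partition(
        treatment.lengths, window_size, mappability, min_mappable
    )
    _fill_window_counts(windows, treatment, control)
    m = len(windows)
    t = np.array([w.t for w in windows])
    c = np.array([w.c for w in windows])
    p_raw = hypergeom.sf(t - 1, T + C, T, t + c)
    p_adj = np.minimum(1.0, p_raw * m)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (t / T) / np.where(c > 0, c / C, np.nan)
        ratio = np.where(c > 0, ratio, np.where(t > 0, np.inf, np.nan))
    return pd.DataFrame(
        {
            "chrom": [w.interval.chrom for w in windows],
            "start": [w.interval.start for w in windows],
            "end": [w.interval.end for w in windows],
            "t": t,
            "c": c,
            "mappable_len": [w.mappable_len for w in windows],
            "ratio": ratio,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )


def call_fragile_regions(
    treatment: BreakProfile,
    control: BreakProfile,
    window_size: int = 1000,
    alpha: float = 0.001,
    mappability: MappabilityTrack | None = None,
    min_mappable: int = 20,
) -> list[FragileRegion]:
    """Windows significantly enriched in treatment breaks (p_adj < alpha).

    Sorted by adjusted P, ties broken by genomic coordinate (chromosome
    order as in the profile, then start), so output is deterministic.
    """
    table = evaluate_windows(treatment, control, window_size, mappability, min_mappable)
    chrom_order = {c: i for i, c in enumerate(treatment.chroms)}
    hits = table[table["p_adj"] < alpha]
    regions = [
        FragileRegion(
            GenomicInterval(row.chrom, int(row.start), int(row.end)),
            int(row.t), int(row.c), float(row.ratio),
            float(row.p_raw), float(row.p_adj),
        )
        for row in hits.itertuples()
    ]
    regions.sort(
        key=lambda r: (r.p_adj, chrom_order[r.interval.chrom], r.interval.start)
    )
    return regions


def merge_adjacent(regions: list[FragileRegion]) -> list[GenomicInterval]:
    """Merge book-ended significant windows into maximal intervals."""
    by_coord = sorted(
        regions, key=lambda r: (r.interval.chrom, r.interval.start)
    )
    merged: list[GenomicInterval] = []
    for r in by_coord:
        iv = r.interval
        if merged and merged[-1].chrom == iv.chrom and merged[-1].end >= iv.start:
            merged[-1] = GenomicInterval(
                iv.chrom, merged[-1].start, max(merged[-1].end, iv.end)
            )
        else:
            merged.append(iv)
    return merged
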