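"""Endonuclease site scanning, cut-precision metrics and off-target search.

Cut geometry convention: ``cut_top`` and ``cut_bottom`` are 0-based
coordinates of the top- and bottom-strand cuts relative to the recognition
start (a cut at coordinate c falls between bases c-1 and c).
``cut_top < cut_bottom`` leaves a 5' overhang, ``>`` a 3' overhang, ``==``
a blunt end.  After end blunting (fill-in of 5' overhangs, chew-back of 3'
overhangs) the left fragment ends at ``cut_bottom`` (exclusive) and the
right fragment starts at ``cut_top``, so the labeled 5' break ends are:
plus strand at ``site_start + cut_top`` and minus strand at
``site_start + cut_bottom - 1`` (the rightmost base of the left fragment).

The shipped geometry table (data/enzymes.json) follows standard
REBASE-style definitions; these are conventions of the enzymes, not
measured quantities.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core_io import BreakProfile, GenomeSequence, GenomicInterval, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class EnzymeSpec:
    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self):
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters in recognition: {sorted(bad)}")
        L = len(self.recognition)
        for c in (self.cut_top, self.cut_bottom):
            if not (0 <= c <= L):
                raise ValueError("cut offsets must lie within or adjacent to the site")

    @property
    def overhang(self) -> str:
        if self.cut_top < self.cut_bottom:
            return "5'"
        if self.cut_top > self.cut_bottom:
            return "3'"
        return "blunt"

    @property
    def is_palindromic(self) -> bool:
        rc = self.recognition.upper().translate(_IUPAC_COMPLEMENT)[::-1]
        return rc == self.recognition.upper()


def load_enzymes() -> dict[str, EnzymeSpec]:
    """Built-in enzyme geometry table."""
    text = resources.files("ibless.data").joinpath("enzymes.json").read_text()
    raw = json.loads(text)
    return {
        name: EnzymeSpec(name, d["recognition"], d["cut_top"], d["cut_bottom"])
        for name, d in raw.items()
    }


@dataclass(frozen=True)
class EnzymeSite:
    chrom: str
    start: int
    end: int
    strand: str
    plus_break_end: int   # labeled 5' break base on the plus strand
    minus_break_end: int  # labeled 5' break base on the minus strand

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile(
        "".join(f"[{IUPAC[ch]}]" if len(IUPAC[ch]) > 1 else IUPAC[ch]
                for ch in pattern.upper())
    )


def find_sites(genome: GenomeSequence, enzyme: EnzymeSpec) -> list[EnzymeSite]:
    """Recognition sites on both strands; palindromic sites reported once."""
    L = len(enzyme.recognition)
    fwd = _iupac_regex(enzyme.recognition)
    sites: list[EnzymeSite] = []
    for chrom, seq in genome.chromosomes.items():
        pos = 0
        while True:
            m = fwd.search(seq, pos)
            if m is None:
                break
            s = m.start()
            sites.append(
                EnzymeSite(chrom, s, s + L, "+",
                           s + enzyme.cut_top, s + enzyme.cut_bottom - 1)
            )
            pos = s + 1
        if not enzyme.is_palindromic:
            rev = _iupac_regex(reverse_complement(enzyme.recognition))
            pos = 0
            while True:
                m = rev.search(seq, pos)
                if m is None:
                    break
                s = m.start()
                # cut geometry mirrored onto the reference strand
                sites.append(
                    EnzymeSite(chrom, s, s + L, "-",
                               s + L - enzyme.cut_bottom,
                               s + L - enzyme.cut_top - 1)
                )
                pos = s + 1
    sites.sort(key=lambda x: (x.chrom, x.start))
    return sites


@dataclass
class SitePrecision:
    n_sites: int
    n_detected: int
    fraction_exact: float
    fraction_within: float
    tolerance: int
    per_site_counts: np.ndarray  # reads within +-tolerance per site
    no_reads: bool = False


def site_precision(
    profile: BreakProfile,
    sites: list[EnzymeSite],
    tolerance: int = 1,
    detect_min: int = 1,
) -> SitePrecision:
    """How precisely break reads land at expected cut positions.

    ``fraction_exact`` is the fraction of all profile reads sitting exactly
    at an expected break end (strand-aware); ``fraction_within`` allows a
    +-tolerance window.  A site is detected when at least ``detect_min``
    reads fall within its windows.
    """
    if not sites:
        raise ValueError("no sites supplied")
    total = sum(a.sum() for a in profile.plus.values()) + \
        sum(a.sum() for a in profile.minus.values())
    if total == 0:
        return SitePrecision(len(sites), 0, 0.0, 0.0, tolerance,
                             np.zeros(len(sites)), no_reads=True)
    exact = 0.0
    per_site = np.zeros(len(sites))
    stranded = getattr(profile, "stranded", True)
    for i, site in enumerate(sites):
        if stranded:
            plus = profile.plus[site.chrom]
            minus = profile.minus[site.chrom]
        else:
            # bedGraph round trips lose strand; match on the combined view
            plus = minus = profile.combined(site.chrom)
        L = len(plus)
        exact += plus[site.plus_break_end] if 0 <= site.plus_break_end < L else 0.0
        exact += minus[site.minus_break_end] if 0 <= site.minus_break_end < L else 0.0
        w = 0.0
        lo = max(0, site.plus_break_end - tolerance)
        w += plus[lo:site.plus_break_end + tolerance + 1].sum()
        lo = max(0, site.minus_break_end - tolerance)
        w += minus[lo:site.minus_break_end + tolerance + 1].sum()
        per_site[i] = w
    n_detected = int((per_site >= detect_min).sum())
    return SitePrecision(
        n_sites=len(sites),
        n_detected=n_detected,
        fraction_exact=float(exact / total),
        fraction_within=float(per_site.sum() / total),
        tolerance=tolerance,
        per_site_counts=per_site,
    )


def per_site_read_table(
    profile: BreakProfile,
    site_lists: dict[str, list[EnzymeSite]],
    tolerance: int = 1,
) -> pd.DataFrame:
    """Long-format per-site read counts for several enzymes (box-plot input)."""
    rows = []
    for name, sites in site_lists.items():
        if not sites:
            continue
        prec = site_precision(profile, sites, tolerance=tolerance)
        for site, count in zip(sites, prec.per_site_counts):
            rows.append(
                {
                    "enzyme": name,
                    "chrom": site.chrom,
                    "start": site.start,
                    "end": site.end,
                    "strand": site.strand,
                    "reads": float(count),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OfftargetHit:
    region: GenomicInterval
    identity: int
    position: int       # reference start of the best-matching placement
    orientation: str    # "+" or "-"
    skipped: bool = False


def offtarget_scan(
    genome: GenomeSequence,
    canonical_site: str,
    candidate_regions: list[GenomicInterval],
    min_identity: int = 10,
) -> list[OfftargetHit]:
    """Best ungapped identity of the canonical site inside each region.

    The canonical sequence is slid (both orientations) across the region
    extended by its length on each side; identity is the count of matching
    bases at the best offset.  Regions shorter than the site after padding
    are skipped with a flag; hits with identity >= ``min_identity`` are
    retained (skipped regions are also returned, flagged).
    """
    canonical = canonical_site.upper()
    L = len(canonical)
    if L < min_identity:
        raise ValueError("canonical site shorter than min_identity")
    queries = {"+": canonical, "-": reverse_complement(canonical)}
    hits: list[OfftargetHit] = []
    for region in candidate_regions:
        seq_full = genome[region.chrom]
        lo = max(0, region.start - L)
        hi = min(len(seq_full), region.end + L)
        segment = seq_full[lo:hi]
        if len(segment) < L:
            hits.append(OfftargetHit(region, 0, lo, "+", skipped=True))
            continue
        best = (-1, lo, "+")
        arr = np.frombuffer(segment.encode(), dtype=np.uint8)
        for orient, q in queries.items():
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            for off in range(len(segment) - L + 1):
                ident = int((arr[off:off + L] == qa).sum())
                if ident > best[0]:
                    best = (ident, lo + off, orient)
        if best[0] >= min_identity:
            hits.append(OfftargetHit(region, best[0], best[1], best[2]))
    return hits
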