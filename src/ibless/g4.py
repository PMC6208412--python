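"""G-quadruplex motif scanning and break-density fragility statistics.

A canonical intra-strand G4 motif is four guanine tracts of 3-5 nt
separated by three loops of 1 to ``max_loop`` nt
(G3-5 N1-max G3-5 N1-max G3-5 N1-max G3-5).  Motifs whose guanine tracts
all sit on the minus strand (C tracts on the reference) are ``intra-``;
inter-strand motifs mix G and C tracts (at least one of each), modeling
quadruplexes whose tetrads are contributed by both strands.

The default scan reports a maximal set of non-overlapping motifs per
configuration: positions are visited left to right and at each feasible
start the decomposition is chosen greedily, preferring longer tracts, then
shorter loops, reading left to right.  An exhaustive mode enumerating every
(start, tracts, loops) decomposition is available for cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BreakProfile, GenomeSequence, GenomicInterval
from .mappability import MappabilityTrack

CONFIGURATIONS = ("intra+", "intra-", "inter")


@dataclass(frozen=True)
class G4ScanConfig:
    tract_min: int = 3
    tract_max: int = 5
    loop_min: int = 1
    max_loop: int = 7
    configurations: tuple[str, ...] = CONFIGURATIONS

    def __post_init__(self):
        if not (1 <= self.tract_min <= self.tract_max):
            raise ValueError("invalid tract length range")
        if not (1 <= self.loop_min <= self.max_loop):
            raise ValueError("invalid loop length range")
        unknown = set(self.configurations) - set(CONFIGURATIONS)
        if unknown:
            raise ValueError(f"unknown configurations: {sorted(unknown)}")


@dataclass(frozen=True)
class G4Motif:
    chrom: str
    start: int
    end: int
    configuration: str
    tracts: tuple[int, int, int, int]
    loops: tuple[int, int, int]
    tract_letters: tuple[str, str, str, str] = ("G", "G", "G", "G")

    def __post_init__(self):
        if self.end - self.start != sum(self.tracts) + sum(self.loops):
            raise ValueError("motif span inconsistent with tract/loop lengths")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def span(self) -> int:
        return self.end - self.start

    def loop_intervals(self) -> tuple[GenomicInterval, GenomicInterval, GenomicInterval]:
        """Genomic sub-intervals of the three loops (reference coordinates)."""
        out = []
        p = self.start
        for i in range(3):
            p += self.tracts[i]
            out.append(GenomicInterval(self.chrom, p, p + self.loops[i]))
            p += self.loops[i]
        return tuple(out)


def _run_lengths(seq: str, letter: str) -> np.ndarray:
    """run[i] = number of consecutive ``letter`` starting at position i."""
    mask = np.frombuffer(seq.encode(), dtype=np.uint8) == ord(letter)
    run = np.zeros(len(seq), dtype=np.int32)
    acc = 0
    for i in range(len(seq) - 1, -1, -1):
        acc = acc + 1 if mask[i] else 0
        run[i] = acc
    return run


def _find_first(pos, runs, cfg, inter: bool):
    """First decomposition at ``pos`` in preference order (t desc, l asc)."""
    tmin, tmax = cfg.tract_min, cfg.tract_max

    def dfs(p, idx, tracts, loops, letters):
        run = 0
        letter = None
        for lt, r in runs.items():
            if p < len(r) and r[p] >= tmin:
                run, letter = int(r[p]), lt
                break
        if letter is None:
            return None
        for t in range(min(tmax, run), tmin - 1, -1):
            if idx == 3:
                full_letters = letters + (letter,)
                if inter and len(set(full_letters)) < 2:
                    continue
                return tracts + (t,), loops, full_letters
            for l in range(cfg.loop_min, cfg.max_loop + 1):
                got = dfs(p + t + l, idx + 1, tracts + (t,), loops + (l,),
                          letters + (letter,))
                if got is not None:
                    return got
        return None

    return dfs(pos, 0, (), (), ())


def _iter_all(pos, runs, cfg, inter: bool):
    """Every decomposition starting at ``pos``."""
    tmin, tmax = cfg.tract_min, cfg.tract_max

    def dfs(p, idx, tracts, loops, letters):
        run = 0
        letter = None
        for lt, r in runs.items():
            if p < len(r) and r[p] >= tmin:
                run, letter = int(r[p]), lt
                break
        if letter is None:
            return
        for t in range(min(tmax, run), tmin - 1, -1):
            if idx == 3:
                full = letters + (letter,)
                if inter and len(set(full)) < 2:
                    continue
                yield tracts + (t,), loops, full
            else:
                for l in range(cfg.loop_min, cfg.max_loop + 1):
                    yield from dfs(p + t + l, idx + 1, tracts + (t,),
                                   loops + (l,), letters + (letter,))

    yield from dfs(pos, 0, (), (), ())


def _scan_sequence(seq: str, cfg: G4ScanConfig, letters: tuple[str, ...],
                   inter: bool, mode: str):
    """Yield (start, tracts, loops, letters) on one sequence."""
    runs = {lt: _run_lengths(seq, lt) for lt in letters}
    min_span = 4 * cfg.tract_min + 3 * cfg.loop_min
    L = len(seq)
    if mode == "greedy":
        pos = 0
        while pos <= L - min_span:
            got = _find_first(pos, runs, cfg, inter)
            if got is None:
                pos += 1
                continue
            tracts, loops, lts = got
            yield pos, tracts, loops, lts
            pos += sum(tracts) + sum(loops)
    elif mode == "all":
        for pos in range(0, L - min_span + 1):
            for tracts, loops, lts in _iter_all(pos, runs, cfg, inter):
                yield pos, tracts, loops, lts
    else:
        raise ValueError(f"unknown scan mode {mode!r}")


def find_intrastrand_g4(
    genome: GenomeSequence, config: G4ScanConfig | None = None, mode: str = "greedy"
) -> list[G4Motif]:
    """Intra-strand motifs on both strands, in reference coordinates.

    ``intra-`` motifs are found by scanning the reverse complement with the
    same left-to-right greedy rule, so reverse-complementing the genome
    swaps intra+ and intra- motif sets exactly.
    """
    cfg = config or G4ScanConfig()
    motifs: list[G4Motif] = []
    for chrom, seq in genome.chromosomes.items():
        L = len(seq)
        if "intra+" in cfg.configurations:
            for pos, tracts, loops, _ in _scan_sequence(seq, cfg, ("G",), False, mode):
                span = sum(tracts) + sum(loops)
                motifs.append(G4Motif(chrom, pos, pos + span, "intra+", tracts, loops))
        if "intra-" in cfg.configurations:
            from .core_io import reverse_complement

            rc = reverse_complement(seq)
            for pos, tracts, loops, _ in _scan_sequence(rc, cfg, ("G",), False, mode):
                span = sum(tracts) + sum(loops)
                # map [pos, pos+span) on the reverse strand back to forward
                # coordinates; tract/loop order reverses
                motifs.append(
                    G4Motif(chrom, L - pos - span, L - pos, "intra-",
                            tracts[::-1], loops[::-1],
                            ("C", "C", "C", "C"))
                )
    motifs.sort(key=lambda m: (m.chrom, m.start, m.configuration))
    return motifs


def find_interstrand_g4(
    genome: GenomeSequence, config: G4ScanConfig | None = None, mode: str = "greedy"
) -> list[G4Motif]:
    """Inter-strand motifs: tracts independently G or C, at least one of each."""
    cfg = config or G4ScanConfig()
    if "inter" not in cfg.configurations:
        raise ValueError("config does not include the inter configuration")
    motifs: list[G4Motif] = []
    for chrom, seq in genome.chromosomes.items():
        for pos, tracts, loops, lts in _scan_sequence(seq, cfg, ("G", "C"), True, mode):
            span = sum(tracts) + sum(loops)
            motifs.append(G4Motif(chrom, pos, pos + span, "inter", tracts, loops, lts))
    motifs.sort(key=lambda m: (m.chrom, m.start))
    return motifs


def scan_genome(
    genome: GenomeSequence, config: G4ScanConfig | None = None, mode: str = "greedy"
) -> list[G4Motif]:
    """All requested configurations in one sorted list."""
    cfg = config or G4ScanConfig()
    motifs = []
    if {"intra+", "intra-"} & set(cfg.configurations):
        motifs.extend(find_intrastrand_g4(genome, cfg, mode))
    if "inter" in cfg.configurations:
        motifs.extend(find_interstrand_g4(genome, cfg, mode))
    motifs.sort(key=lambda m: (m.chrom, m.start, m.configuration))
    return motifs


def classify_loops(motif: G4Motif) -> tuple[str, str]:
    """3-way loop category and fine Lk group (k = longest loop).

    Categories: ``L1-4`` all loops <= 4 nt; ``L5-7`` all <= 7 with at least
    one > 4; ``L8-16`` all <= 16 with at least one > 7.
    """
    k = max(motif.loops)
    if k <= 4:
        cat = "L1-4"
    elif k <= 7:
        cat = "L5-7"
    elif k <= 16:
        cat = "L8-16"
    else:
        cat = f"L>{16}"
    return cat, f"L{k}"


@dataclass(frozen=True)
class Flanks:
    left: GenomicInterval | None
    right: GenomicInterval | None
    truncated: bool


def flanks(motif: G4Motif, chrom_length: int) -> Flanks:
    """Left/right regions adjacent to the motif, together as long as it.

    Left flank is ceil(span/2), right floor(span/2) (left takes the extra
    base for odd spans); flanks are truncated at chromosome ends and the
    result flagged.
    """
    span = motif.span
    left_len = math.ceil(span / 2)
    right_len = span // 2
    truncated = False
    ls = motif.start - left_len
    if ls < 0:
        ls = 0
        truncated = True
    left = GenomicInterval(motif.chrom, ls, motif.start) if ls < motif.start else None
    if left is None:
        truncated = True
    re = motif.end + right_len
    if re > chrom_length:
        re = chrom_length
        truncated = True
    right = GenomicInterval(motif.chrom, motif.end, re) if re > motif.end else None
    if right is None and right_len > 0:
        truncated = True
    return Flanks(left, right, truncated)


def dsb_density(profile: BreakProfile, interval: GenomicInterval) -> float:
    """Combined-strand break count in the interval divided by its length."""
    if interval.length <= 0:
        raise ValueError("zero-length interval")
    arr = profile.combined(interval.chrom)
    return float(arr[interval.start:interval.end].sum()) / interval.length


def _inside_flank_densities(profile: BreakProfile, motifs: list[G4Motif]):
    lengths = profile.lengths
    inside, flank, kept = [], [], []
    for m in motifs:
        fl = flanks(m, lengths[m.chrom])
        total = 0.0
        length = 0
        for iv in (fl.left, fl.right):
            if iv is not None:
                total += profile.combined(iv.chrom)[iv.start:iv.end].sum()
                length += iv.length
        if length == 0:
            continue
        inside.append(dsb_density(profile, m.interval))
        flank.append(total / length)
        kept.append(m)
    return np.array(inside), np.array(flank), kept


def _paired_wilcoxon_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided paired Wilcoxon signed-rank P(x > y); 1.0 when all ties."""
    d = x - y
    if np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(x, y, alternative="greater").pvalue)


def meta_profile(
    profile: BreakProfile,
    motifs: list[G4Motif],
    window: int = 200,
    bin_size: int = 10,
) -> pd.DataFrame:
    """Averaged signal in a window centered on motif centers, binned.

    Motif centers are ``start + span // 2`` (left-of-center base for even
    spans); motifs whose window leaves the chromosome are skipped.
    """
    half = window // 2
    n_bins = window // bin_size
    acc = np.zeros(n_bins)
    n_used = 0
    lengths = profile.lengths
    for m in motifs:
        center = m.start + m.span // 2
        lo, hi = center - half, center + half
        if lo < 0 or hi > lengths[m.chrom]:
            continue
        sig = profile.combined(m.chrom)[lo:hi]
        acc += sig.reshape(n_bins, bin_size).mean(axis=1)
        n_used += 1
    if n_used:
        acc /= n_used
    offsets = np.arange(n_bins) * bin_size - half
    return pd.DataFrame(
        {"offset": offsets, "mean_signal": acc, "n_motifs": n_used}
    )


def g4_fragility_report(
    profile: BreakProfile,
    motifs: list[G4Motif],
    paired_profile: BreakProfile | None = None,
) -> dict:
    """Break-density statistics of a motif set.

    Per loop category (and overall), inside vs flank densities are compared
    with a one-sided paired Wilcoxon signed-rank test; intra vs inter
    inside densities with a two-sided Kolmogorov-Smirnov test; and, when a
    second (e.g. helicase-mutant) profile is given, per-motif inside
    densities paired mutant > wild type.  Also returns the 200-bp/10-bp-bin
    meta-profile around motif centers.
    """
    if len(motifs) < 2:
        raise ValueError("fragility statistics require at least 2 motifs")
    inside, flank, kept = _inside_flank_densities(profile, motifs)
    cats = np.array([classify_loops(m)[0] for m in kept])

    rows = []
    for cat in ["all", "L1-4", "L5-7", "L8-16"]:
        sel = np.ones(len(kept), dtype=bool) if cat == "all" else cats == cat
        if sel.sum() < 2:
            continue
        rows.append(
            {
                "category": cat,
                "n_motifs": int(sel.sum()),
                "mean_inside": float(inside[sel].mean()),
                "mean_flank": float(flank[sel].mean()),
                "p_inside_gt_flank": _paired_wilcoxon_greater(inside[sel], flank[sel]),
            }
        )
    report: dict = {"inside_vs_flank": pd.DataFrame(rows)}

    intra = inside[np.array([m.configuration.startswith("intra") for m in kept])]
    inter = inside[np.array([m.configuration == "inter" for m in kept])]
    if len(intra) >= 2 and len(inter) >= 2:
        ks = stats.ks_2samp(intra, inter, alternative="two-sided")
        report["intra_vs_inter"] = {
            "n_intra": len(intra),
            "n_inter": len(inter),
            "ks_statistic": float(ks.statistic),
            "p_value": float(ks.pvalue),
        }

    if paired_profile is not None:
        other, _, kept2 = _inside_flank_densities(paired_profile, motifs)
        if [m.interval for m in kept2] != [m.interval for m in kept]:
            raise ValueError("paired profile covers a different motif set")
        report["paired_comparison"] = {
            "n_motifs": len(kept),
            "mean_primary": float(inside.mean()),
            "mean_paired": float(other.mean()),
            "p_paired_gt_primary": _paired_wilcoxon_greater(other, inside),
        }

    report["meta_profile"] = meta_profile(profile, motifs)
    return report


def loop_breakability(
    profile: BreakProfile,
    motifs: list[G4Motif],
    seed: int,
    n_controls: int = 1000,
    mappability: MappabilityTrack | None = None,
    max_length: int = 7,
) -> pd.DataFrame:
    """Mean break density in loops of each length vs random control regions.

    For each loop length 1..max_length the mean density over all loops of
    that length is compared with the mean density over ``n_controls``
    randomly placed (seeded) same-length regions, drawn from mappable
    positions when a track is supplied.  Lengths with no loops are reported
    with NaN and flagged missing.
    """
    rng = np.random.default_rng(seed)
    lengths = profile.lengths
    chroms = list(lengths)
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    rows = []
    for L in range(1, max_length + 1):
        loops = [
            iv
            for m in motifs
            for iv, ll in zip(m.loop_intervals(), m.loops)
            if ll == L
        ]
        if loops:
            loop_density = float(
                np.mean([dsb_density(profile, iv) for iv in loops])
            )
        else:
            loop_density = float("nan")
        controls = []
        tries = 0
        while len(controls) < n_controls and tries < 50 * n_controls:
            tries += 1
            ci = rng.integers(len(chroms))
            chrom = chroms[ci]
            if lengths[chrom] <= L:
                continue
            s = int(rng.integers(0, lengths[chrom] - L))
            if mappability is not None:
                if not mappability.mappable[chrom][s:s + L].all():
                    continue
            controls.append(dsb_density(profile, GenomicInterval(chrom, s, s + L)))
        rows.append(
            {
                "loop_length": L,
                "n_loops": len(loops),
                "loop_density": loop_density,
                "control_density": float(np.mean(controls)) if controls else float("nan"),
                "n_controls": len(controls),
                "missing": not loops,
            }
        )
    return pd.DataFrame(rows)
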