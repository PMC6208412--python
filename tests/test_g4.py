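"""G-quadruplex scanner vs exhaustive oracle; loop classes; fragility stats."""

import numpy as np
import pytest

from ibless.core_io import BreakProfile, GenomeSequence, GenomicInterval
from ibless.g4 import (
    G4Motif,
    G4ScanConfig,
    classify_loops,
    dsb_density,
    find_interstrand_g4,
    find_intrastrand_g4,
    flanks,
    g4_fragility_report,
    loop_breakability,
    meta_profile,
)
from ibless.simulate import simulate_genome


def oracle_decompositions(seq, max_loop, letters=("G",), require_mixed=False):
    """Every (start, tracts, loops, letters) decomposition by direct slicing."""
    found = set()

    def tract_letter(p, t):
        for lt in letters:
            if seq[p:p + t] == lt * t and p + t <= len(seq):
                return lt
        return None

    def recurse(p, depth, tracts, loops, lts):
        for t in (3, 4, 5):
            lt = tract_letter(p, t)
            if lt is None:
                continue
            if depth == 3:
                full = lts + (lt,)
                if require_mixed and len(set(full)) < 2:
                    continue
                found.add((p - sum(tracts) - sum(loops), tracts + (t,),
                           loops, full))
            else:
                for l in range(1, max_loop + 1):
                    recurse(p + t + l, depth + 1, tracts + (t,), loops + (l,),
                            lts + (lt,))

    for start in range(len(seq)):
        recurse(start, 0, (), (), ())
    return found


def motif_key(m):
    return (m.start, m.tracts, m.loops, m.tract_letters)


class TestIntrastrandScanner:
    def test_minimal_plus_motif(self):
        genome = GenomeSequence({"c": "GGGAGGGAGGGAGGG"})
        (m,) = find_intrastrand_g4(genome, G4ScanConfig(configurations=("intra+",)))
        assert (m.start, m.end) == (0, 15)
        assert m.tracts == (3, 3, 3, 3)
        assert m.loops == (1, 1, 1)
        assert m.configuration == "intra+"

    def test_minimal_minus_motif(self):
        genome = GenomeSequence({"c": "CCCTCCCTCCCTCCC"})
        (m,) = find_intrastrand_g4(genome, G4ScanConfig(configurations=("intra-",)))
        assert (m.start, m.end) == (0, 15)
        assert m.tracts == (3, 3, 3, 3)
        assert m.loops == (1, 1, 1)
        assert m.configuration == "intra-"

    def test_short_tracts_rejected(self):
        genome = GenomeSequence({"c": "GGAGGAGGAGG"})
        assert find_intrastrand_g4(genome) == []

    def test_greedy_prefers_long_tracts_then_short_loops(self):
        genome = GenomeSequence({"c": "GGGGGAGGGTAGGGAGGGG"})
        (m,) = find_intrastrand_g4(genome, G4ScanConfig(configurations=("intra+",)))
        assert m.tracts[0] == 5  # longest first tract taken

    @pytest.mark.parametrize("max_loop", [4, 7])
    def test_all_mode_equals_oracle(self, max_loop):
        genome = simulate_genome(8000, 0.5, seed=51)
        seq = genome["chrI"]
        cfg = G4ScanConfig(max_loop=max_loop, configurations=("intra+",))
        got = {
            motif_key(m)
            for m in find_intrastrand_g4(genome, cfg, mode="all")
        }
        expected = {
            (s, tr, lo, lt)
            for s, tr, lo, lt in oracle_decompositions(seq, max_loop)
        }
        assert got == expected

    def test_strand_symmetry_under_reverse_complement(self):
        genome = simulate_genome(6000, 0.55, seed=52)
        rc_genome = genome.reverse_complemented()
        cfg = G4ScanConfig(max_loop=7)
        fwd = find_intrastrand_g4(genome, cfg, mode="all")
        rev = find_intrastrand_g4(rc_genome, cfg, mode="all")
        L = genome.length("chrI")

        def as_set(motifs, config):
            return {
                (m.start, m.end, m.tracts, m.loops)
                for m in motifs if m.configuration == config
            }

        def mirror(motifs, config):
            return {
                (L - m.end, L - m.start, m.tracts[::-1], m.loops[::-1])
                for m in motifs if m.configuration == config
            }

        assert as_set(fwd, "intra+") == mirror(rev, "intra-")
        assert as_set(fwd, "intra-") == mirror(rev, "intra+")

    def test_greedy_motifs_do_not_overlap(self):
        genome = simulate_genome(20000, 0.6, seed=53)
        for cfg_name in ("intra+", "intra-"):
            motifs = [
                m for m in find_intrastrand_g4(
                    genome, G4ScanConfig(configurations=(cfg_name,))
                )
            ]
            for a, b in zip(motifs, motifs[1:]):
                assert a.end <= b.start


class TestInterstrandScanner:
    def test_mixed_tract_motif(self):
        genome = GenomeSequence({"c": "GGGACCCAGGGACCC"})
        (m,) = find_interstrand_g4(genome)
        assert m.tract_letters == ("G", "C", "G", "C")
        assert m.tracts == (3, 3, 3, 3)
        assert m.loops == (1, 1, 1)

    def test_pure_g_excluded(self):
        genome = GenomeSequence({"c": "GGGAGGGAGGGAGGG"})
        assert find_interstrand_g4(genome) == []

    def test_all_mode_equals_oracle(self):
        genome = simulate_genome(6000, 0.5, seed=54)
        seq = genome["chrI"]
        got = {
            motif_key(m)
            for m in find_interstrand_g4(genome, G4ScanConfig(max_loop=4),
                                         mode="all")
        }
        expected = oracle_decompositions(seq, 4, letters=("G", "C"),
                                         require_mixed=True)
        # oracle includes pure intra decompositions filter already
        assert got == expected

    def test_inter_set_preserved_under_reverse_complement(self):
        genome = simulate_genome(5000, 0.55, seed=55)
        rc_genome = genome.reverse_complemented()
        L = genome.length("chrI")
        fwd = find_interstrand_g4(genome, G4ScanConfig(max_loop=4), mode="all")
        rev = find_interstrand_g4(rc_genome, G4ScanConfig(max_loop=4), mode="all")
        swap = {"G": "C", "C": "G"}
        mirrored = {
            (L - m.end, L - m.start, m.tracts[::-1], m.loops[::-1],
             tuple(swap[x] for x in m.tract_letters[::-1]))
            for m in rev
        }
        assert {
            (m.start, m.end, m.tracts, m.loops, m.tract_letters) for m in fwd
        } == mirrored


class TestLoopClassification:
    @pytest.mark.parametrize(
        "loops,category,group",
        [
            ((1, 1, 1), "L1-4", "L1"),
            ((4, 7, 2), "L5-7", "L7"),
            ((8, 1, 1), "L8-16", "L8"),
            ((16, 16, 16), "L8-16", "L16"),
        ],
    )
    def test_categories(self, loops, category, group):
        span = 12 + sum(loops)
        m = G4Motif("c", 0, span, "intra+", (3, 3, 3, 3), loops)
        assert classify_loops(m) == (category, group)

    def test_every_motif_in_exactly_one_category(self):
        genome = simulate_genome(30000, 0.6, seed=56)
        cfg = G4ScanConfig(max_loop=16)
        for m in find_intrastrand_g4(genome, cfg):
            cat, group = classify_loops(m)
            k = max(m.loops)
            assert cat == ("L1-4" if k <= 4 else "L5-7" if k <= 7 else "L8-16")
            assert group == f"L{k}"


class TestFlanks:
    def test_even_span(self):
        m = G4Motif("c", 100, 120, "intra+", (3, 3, 3, 3), (3, 3, 2))
        fl = flanks(m, 1000)
        assert (fl.left.start, fl.left.end) == (90, 100)
        assert (fl.right.start, fl.right.end) == (120, 130)
        assert not fl.truncated

    def test_truncation_at_chromosome_start(self):
        m = G4Motif("c", 0, 20, "intra+", (3, 3, 3, 3), (3, 3, 2))
        fl = flanks(m, 1000)
        assert fl.left is None
        assert fl.truncated
        assert (fl.right.start, fl.right.end) == (20, 30)

    def test_odd_span_left_gets_extra_base(self):
        m = G4Motif("c", 100, 115, "intra+", (3, 3, 3, 3), (1, 1, 1))
        fl = flanks(m, 1000)
        assert fl.left.length == 8
        assert fl.right.length == 7


class TestDsbDensity:
    def test_simple_arithmetic(self):
        arr = np.zeros(100)
        arr[10:20] = 1.0
        prof = BreakProfile({"c": arr}, {"c": np.zeros(100)})
        assert dsb_density(prof, GenomicInterval("c", 5, 25)) == 0.5

    def test_empty_region_zero(self):
        prof = BreakProfile({"c": np.zeros(50)}, {"c": np.zeros(50)})
        assert dsb_density(prof, GenomicInterval("c", 0, 10)) == 0.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(57)
        arr = rng.poisson(2.0, 300).astype(float)
        prof = BreakProfile({"c": arr}, {"c": np.zeros(300)})
        iv = GenomicInterval("c", 37, 181)
        explicit = sum(arr[p] for p in range(iv.start, iv.end)) / iv.length
        assert dsb_density(prof, iv) == pytest.approx(explicit)


def _genome_with_motifs(n_motifs=200, spacing=200, seed=58):
    """Random genome with planted minimal G4 motifs at known positions."""
    rng = np.random.default_rng(seed)
    motif = "GGGAGGGAGGGAGGG"
    length = (n_motifs + 2) * spacing
    # AT-only background cannot create extra G tracts
    seq = list("".join(rng.choice(list("AT"), size=length)))
    starts = []
    for i in range(n_motifs):
        s = (i + 1) * spacing
        seq[s:s + len(motif)] = motif
        starts.append(s)
    return GenomeSequence({"chrI": "".join(seq)}), starts


class TestFragilityReport:
    def test_inside_enrichment_detected(self):
        genome, starts = _genome_with_motifs()
        motifs = find_intrastrand_g4(genome)
        assert len(motifs) == len(starts)
        L = genome.length("chrI")
        rng = np.random.default_rng(59)
        arr = rng.poisson(0.05, L).astype(float)  # uniform background
        for m in motifs:  # 10x spike inside motifs
            arr[m.start:m.end] += rng.poisson(0.5, m.span)
        prof = BreakProfile({"chrI": arr}, {"chrI": np.zeros(L)})
        report = g4_fragility_report(prof, motifs)
        row = report["inside_vs_flank"].set_index("category").loc["all"]
        assert row["p_inside_gt_flank"] < 1e-6
        assert row["mean_inside"] > row["mean_flank"]

    def test_identical_densities_give_p_one(self):
        genome, _ = _genome_with_motifs(n_motifs=30)
        motifs = find_intrastrand_g4(genome)
        L = genome.length("chrI")
        prof = BreakProfile({"chrI": np.ones(L)}, {"chrI": np.zeros(L)})
        report = g4_fragility_report(prof, motifs)
        row = report["inside_vs_flank"].set_index("category").loc["all"]
        assert row["p_inside_gt_flank"] == 1.0

    def test_uniform_profile_density_equals_global_rate(self):
        genome, _ = _genome_with_motifs(n_motifs=20)
        motifs = find_intrastrand_g4(genome)
        L = genome.length("chrI")
        prof = BreakProfile({"chrI": np.full(L, 2.0)}, {"chrI": np.zeros(L)})
        for m in motifs:
            assert dsb_density(prof, m.interval) == pytest.approx(2.0)
            fl = flanks(m, L)
            assert dsb_density(prof, fl.left) == pytest.approx(2.0)

    def test_paired_profile_increase_detected(self):
        genome, _ = _genome_with_motifs(n_motifs=100)
        motifs = find_intrastrand_g4(genome)
        L = genome.length("chrI")
        rng = np.random.default_rng(60)
        wt = rng.poisson(0.2, L).astype(float)
        mut = wt.copy()
        for m in motifs:
            mut[m.start:m.end] += rng.poisson(1.0, m.span)
        p_wt = BreakProfile({"chrI": wt}, {"chrI": np.zeros(L)})
        p_mut = BreakProfile({"chrI": mut}, {"chrI": np.zeros(L)})
        report = g4_fragility_report(p_wt, motifs, paired_profile=p_mut)
        assert report["paired_comparison"]["p_paired_gt_primary"] < 1e-6

    def test_too_few_motifs_rejected(self):
        genome, _ = _genome_with_motifs(n_motifs=1)
        motifs = find_intrastrand_g4(genome)
        prof = BreakProfile(
            {"chrI": np.ones(genome.length("chrI"))},
            {"chrI": np.zeros(genome.length("chrI"))},
        )
        with pytest.raises(ValueError):
            g4_fragility_report(prof, motifs)

    def test_ks_null_calibration(self):
        """Equal inside-density distributions rarely reject at 0.05."""
        rng = np.random.default_rng(61)
        from scipy.stats import ks_2samp

        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            a = rng.poisson(5.0, 80) / 10.0
            b = rng.poisson(5.0, 80) / 10.0
            if ks_2samp(a, b).pvalue < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.06  # discrete KS is conservative


class TestMetaProfile:
    def test_spike_at_center_lands_in_center_bin(self):
        genome, _ = _genome_with_motifs(n_motifs=50)
        motifs = find_intrastrand_g4(genome)
        L = genome.length("chrI")
        arr = np.zeros(L)
        for m in motifs:
            arr[m.start + m.span // 2] = 10.0
        prof = BreakProfile({"chrI": arr}, {"chrI": np.zeros(L)})
        mp = meta_profile(prof, motifs)
        assert len(mp) == 20
        center_bin = mp.loc[mp["offset"] == 0, "mean_signal"].item()
        assert center_bin == mp["mean_signal"].max() > 0


class TestLoopBreakability:
    def _uniform_setup(self):
        genome, _ = _genome_with_motifs(n_motifs=120, seed=62)
        cfg = G4ScanConfig(max_loop=7)
        motifs = find_intrastrand_g4(genome, cfg)
        L = genome.length("chrI")
        return genome, motifs, L

    def test_uniform_profile_loops_match_controls(self):
        genome, motifs, L = self._uniform_setup()
        prof = BreakProfile({"chrI": np.full(L, 1.0)}, {"chrI": np.zeros(L)})
        table = loop_breakability(prof, motifs, seed=1, n_controls=200)
        present = table[~table["missing"]]
        assert np.allclose(present["loop_density"], present["control_density"])

    def test_spiked_length_one_loops_stand_out(self):
        genome, motifs, L = self._uniform_setup()
        arr = np.zeros(L)
        for m in motifs:
            for iv, ll in zip(m.loop_intervals(), m.loops):
                if ll == 1:
                    arr[iv.start:iv.end] += 50.0
        prof = BreakProfile({"chrI": arr}, {"chrI": np.zeros(L)})
        table = loop_breakability(prof, motifs, seed=2, n_controls=300).set_index(
            "loop_length"
        )
        # random controls occasionally land inside spiked loops, so the
        # control mean is small but nonzero; an order of magnitude apart
        # is the discriminating signal
        assert table.loc[1, "loop_density"] > 10 * max(
            table.loc[1, "control_density"], 1e-9
        )

    def test_seed_reproducibility(self):
        genome, motifs, L = self._uniform_setup()
        rng = np.random.default_rng(63)
        prof = BreakProfile({"chrI": rng.poisson(1.0, L).astype(float)},
                            {"chrI": np.zeros(L)})
        t1 = loop_breakability(prof, motifs, seed=9, n_controls=100)
        t2 = loop_breakability(prof, motifs, seed=9, n_controls=100)
        assert t1.equals(t2)

    def test_missing_lengths_flagged(self):
        genome, motifs, L = self._uniform_setup()
        prof = BreakProfile({"chrI": np.ones(L)}, {"chrI": np.zeros(L)})
        table = loop_breakability(prof, motifs, seed=3, n_controls=50).set_index(
            "loop_length"
        )
        # planted motifs only have loops of length 1
        assert not table.loc[1, "missing"]
        assert table.loc[5, "missing"]
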