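"""Folding, structure decomposition, criteria and conservation windows."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirclone import hairpin as hp


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(n))


class TestFold:
    @pytest.mark.parametrize(
        "seq, dotbracket, score",
        [
            ("AAAAAA", "......", 0),
            ("GGGAAACCC", "(((...)))", 9),
            ("GAAAC", "(...)", 3),
            ("GAAC", "....", 0),  # hairpin loop must be >= 3 nt
        ],
    )
    def test_examples(self, seq, dotbracket, score):
        f = hp.fold(seq)
        assert f.score == score
        assert f.dotbracket == dotbracket

    def test_matches_bruteforce_on_short_sequences(self):
        rng = random.Random(42)
        for _ in range(200):
            s = random_seq(rng, rng.randint(1, 12))
            assert hp.fold(s).score == hp.fold_bruteforce(s)

    def test_invalid_alphabet_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            hp.fold("ACGXACG")

    @pytest.mark.parametrize("alphabet", ["AT", "GC"])
    def test_strand_symmetry(self, alphabet):
        # on G:U-free alphabets the reverse complement folds to the mirror
        # structure with the same score
        rng = random.Random(7)
        for _ in range(40):
            s = random_seq(rng, rng.randint(5, 30), alphabet)
            f = hp.fold(s)
            g = hp.fold(hp.revcomp(s))
            assert f.score == g.score
            n = len(s)
            mirrored = sorted((n - 1 - j, n - 1 - i) for i, j in f.pairs)
            # the mirror of an optimum is an optimum of the reverse complement
            enc = [hp._ENC[c] for c in hp.revcomp(s)]
            mirror_score = sum(hp._W[enc[i], enc[j]] for i, j in mirrored)
            assert mirror_score == g.score

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_dotbracket_roundtrip(self, seq):
        f = hp.fold(seq)
        assert hp.dotbracket_to_pairs(f.dotbracket) == sorted(f.pairs)

    @given(st.text(alphabet="ACGT", min_size=2, max_size=40))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_structure_is_nested_with_min_loop(self, seq):
        f = hp.fold(seq)
        for i, j in f.pairs:
            assert j - i > hp.MIN_HAIRPIN_LOOP
        for (i, j), (k, l) in zip(f.pairs, f.pairs[1:]):
            assert k > j or l < j  # no crossing pairs for sorted starts


class TestWindowScan:
    def test_single_window_when_region_is_110(self):
        rng = random.Random(0)
        genome = random_seq(rng, 110)
        scan = hp.window_scan(genome, 44, 66)
        assert scan.n_windows == 1

    def test_window_count_for_centered_mature(self):
        # 22-nt mature centered in a 198-nt extended region, step 5:
        # admissible windows = floor((110-22)/5) + 1
        rng = random.Random(1)
        genome = random_seq(rng, 198)
        scan = hp.window_scan(genome, 88, 110)
        assert scan.n_windows == (110 - 22) // 5 + 1 == 18

    def test_locus_longer_than_window_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            hp.window_scan("A" * 400, 100, 250)

    def test_planted_hairpin_best_window_contains_both_arms(self):
        rng = random.Random(3)
        arm = "GCGGCCGCAGGCACGGACCGGC"
        pre = arm + "AAAAAAA" + hp.revcomp(arm)
        genome = random_seq(rng, 150) + pre + random_seq(rng, 150)
        start = 150
        scan = hp.window_scan(genome, start, start + len(arm))
        ws = scan.fold.window_start
        assert ws <= start and ws + len(scan.fold.seq) >= start + len(pre)
        partner = scan.fold.partner
        ms, me = scan.mature_span
        assert (partner[ms:me] >= 0).sum() == len(arm)


def report_from_dotbracket(db, mature_span, thresholds=None):
    f = hp.FoldResult(seq="A" * len(db), pairs=hp.dotbracket_to_pairs(db), score=0)
    return hp.evaluate_criteria(f, mature_span, thresholds)


class TestCriteria:
    def test_mature_pairing_boundary(self):
        db = "(" * 20 + "." * 5 + ")" * 20
        # span covering exactly 17 paired positions passes, 16 fails
        assert report_from_dotbracket(db, (3, 25)).b is True
        assert report_from_dotbracket(db, (4, 25)).b is False
        assert report_from_dotbracket(db, (3, 25)).mature_paired_nt == 17

    @pytest.mark.parametrize("loop, ok", [(19, True), (20, False)])
    def test_terminal_loop_boundary(self, loop, ok):
        db = "(" * 18 + "." * loop + ")" * 18
        rep = report_from_dotbracket(db, (0, 18))
        assert rep.c is ok
        assert rep.terminal_loop_size == loop

    @pytest.mark.parametrize("left, right, ok", [(4, 5, True), (5, 5, False)])
    def test_internal_loop_boundary(self, left, right, ok):
        db = "(" * 10 + "." * left + "(" * 8 + "." * 5 + ")" * 8 + "." * right + ")" * 10
        rep = report_from_dotbracket(db, (0, 23))
        assert rep.d is ok
        assert rep.max_internal_loop == left + right

    @pytest.mark.parametrize("bulge, ok", [(4, True), (5, False)])
    def test_bulge_boundary(self, bulge, ok):
        db = "(" * 10 + "." * bulge + "(" * 8 + "." * 5 + ")" * 18
        rep = report_from_dotbracket(db, (0, 22))
        assert rep.e is ok
        assert rep.max_bulge == bulge

    def test_two_terminal_loops_fail_stem_loop(self):
        # mature arm rooted in the outer stem, which branches into two
        # sub-hairpins below it: not a stem-loop configuration
        db = "(" * 5 + "((((...))))" + "((((...))))" + ")" * 5
        rep = report_from_dotbracket(db, (0, 16))
        assert rep.a is False
        assert rep.n_terminal_loops == 2

    def test_unpaired_mature_fails(self):
        rep = report_from_dotbracket("." * 30, (5, 27))
        assert not rep.a and not rep.b

    def test_weakening_thresholds_never_flips_pass_to_fail(self):
        rng = random.Random(11)
        loose = hp.CriteriaThresholds(
            min_mature_paired=12, max_terminal_loop=25, max_internal_loop=14, max_bulge=9
        )
        for _ in range(30):
            s = random_seq(rng, 80)
            f = hp.fold(s)
            span = (20, 42)
            strict = hp.evaluate_criteria(f, span)
            relaxed = hp.evaluate_criteria(f, span, loose)
            for crit in "abcde":
                if getattr(strict, crit):
                    assert getattr(relaxed, crit)


class TestConservation:
    def _oracle(self, fold, track, window=15, cutoff=0.8):
        """All-windows scan: every 15 consecutive genomic positions, all paired."""
        partner = fold.partner
        n = len(fold.seq)
        paired = set()
        for idx in np.flatnonzero(partner >= 0):
            g = fold.window_start + (idx if fold.strand == "+" else n - 1 - idx)
            paired.add(int(g))
        best = None
        for g0 in range(fold.window_start, fold.window_start + n - window + 1):
            if all(g in paired for g in range(g0, g0 + window)):
                m = float(np.mean(track[g0 : g0 + window]))
                best = m if best is None else max(best, m)
        if best is None:
            return False, None
        return best >= cutoff, best

    def test_constant_tracks(self):
        arm = "GCGGCCGCAGGCACGGACCGGC"
        f = hp.fold(arm + "AAAAAAA" + hp.revcomp(arm))
        ones = np.ones(200)
        ok, mean, flag = hp.stem_conservation(f, ones)
        assert ok and mean == pytest.approx(1.0)
        ok, mean, flag = hp.stem_conservation(f, np.zeros(200))
        assert not ok

    def test_short_stem_flagged(self):
        f = hp.fold("GGGGGAAACCCCC")
        ok, mean, flag = hp.stem_conservation(f, np.ones(50))
        assert not ok and flag == "stem-too-short"

    def test_matches_bruteforce_scan(self):
        rng = random.Random(13)
        nprng = np.random.default_rng(13)
        for trial in range(150):
            s = random_seq(rng, 60)
            f = hp.fold(s)
            f.window_start = rng.randint(0, 20)
            f.strand = "+" if trial % 2 == 0 else "-"
            track = nprng.random(100)
            got_ok, got_mean, _ = hp.stem_conservation(f, track)
            exp_ok, exp_mean = self._oracle(f, track)
            assert got_ok == exp_ok
            if exp_mean is not None:
                assert got_mean == pytest.approx(exp_mean)

    def test_planted_conserved_run_detected_only_in_stem(self):
        arm = "GCGGCCGCAGGCACGGACCGGC"
        pre = arm + "AAAAAAA" + hp.revcomp(arm)
        f = hp.fold(pre)
        f.window_start = 10
        track = np.zeros(200)
        track[10 : 10 + len(arm)] = 0.8  # exactly over the 5' arm
        ok, mean, _ = hp.stem_conservation(f, track)
        assert ok and mean == pytest.approx(0.8)
        track2 = np.zeros(200)
        track2[10 + len(arm) : 10 + len(arm) + 15] = 0.8  # over the loop
        ok2, _, _ = hp.stem_conservation(f, track2)
        assert not ok2


class TestPruning:
    def test_short_helices_removed_long_kept(self):
        db = "((...))." + "((((((((((...))))))))))"
        f = hp.FoldResult(seq="A" * len(db), pairs=hp.dotbracket_to_pairs(db), score=0)
        pruned = hp.prune_short_helices(f, min_stack=3)
        assert len(pruned.pairs) == 10
        assert min(i for i, _ in pruned.pairs) == 8
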