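import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msatforge import (
    SequenceRecord,
    canonical_motif,
    dedupe_loci,
    find_ssrs,
    match_loci,
    revcomp,
    select_candidates,
)
from msatforge.ssr_mining import DEFAULT_MIN_REPEATS, LocusMatch, SsrLocus
from oracles import brute_force_ssrs, canonical_motif_by_enumeration

dna = st.text(alphabet="ACGT", min_size=1, max_size=6)


class TestCanonicalMotif:
    @pytest.mark.parametrize("motif, expected", [
        ("AT", "AT"),
        ("GAT", "ATC"),
        ("TTC", "AAG"),
        ("A", "A"),
        ("GCAGTA", canonical_motif_by_enumeration("GCAGTA")),
    ])
    def test_examples(self, motif, expected):
        assert canonical_motif(motif) == expected

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(dna)
    def test_matches_enumeration_oracle(self, motif):
        assert canonical_motif(motif) == canonical_motif_by_enumeration(motif)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(dna)
    def test_idempotent_and_strand_invariant(self, motif):
        canon = canonical_motif(motif)
        assert canonical_motif(canon) == canon
        assert canonical_motif(revcomp(motif)) == canon

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError):
            canonical_motif("ANT")


class TestFindSsrs:
    def test_simple_trinucleotide_run(self):
        rec = SequenceRecord("s", "GAT" * 7)
        (locus,) = find_ssrs(rec, min_repeats_by_motif_len={3: 7})
        assert (locus.start, locus.end) == (0, 21)
        assert locus.motif == "ATC" and locus.repeats == 7

    def test_no_run_reaches_threshold(self):
        assert find_ssrs(SequenceRecord("s", "ACGTACGA")) == []

    def test_periodic_motif_reported_under_smallest_period(self):
        rec = SequenceRecord("s", "AT" * 8)
        (locus,) = find_ssrs(rec)
        assert locus.motif_raw == "AT" and locus.repeats == 8

    def test_flanks_attached_and_clipped(self):
        left = "AGGATACACACTCTCCTTTTAGCAATTACG"  # 30 bp, no detectable repeat
        right = "AGCTGATTAG"
        (locus,) = find_ssrs(SequenceRecord("s", left + "GAT" * 7 + right),
                             flank_len=50)
        assert locus.flank_left == left
        assert locus.flank_right == right

    def test_reported_loci_never_overlap(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(4, size=1000)]) + "A" * 14 + "TA" * 9
        loci = sorted(find_ssrs(SequenceRecord("s", seq)), key=lambda l: l.start)
        for a, b in zip(loci, loci[1:]):
            assert a.end <= b.start

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_scanner_on_random_sequence(self, seed):
        seq = _sequence_with_implants(seed, 2000)
        loci = find_ssrs(SequenceRecord("s", seq))
        got = sorted((l.start, l.end, l.motif_raw) for l in loci)
        assert got == brute_force_ssrs(seq, DEFAULT_MIN_REPEATS)


def _sequence_with_implants(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = list(bases[rng.integers(4, size=length)])
    for _ in range(8):
        p = int(rng.integers(1, 7))
        reps = int(rng.integers(DEFAULT_MIN_REPEATS[p], DEFAULT_MIN_REPEATS[p] + 6))
        motif = "".join(bases[rng.integers(4, size=p)])
        pos = int(rng.integers(0, length - p * reps))
        seq[pos : pos + p * reps] = list(motif * reps)
    return "".join(seq)


def _locus(seq_id="s", start=100, repeats=7, motif="GAT", left=None, right=None):
    left = left if left is not None else "ACGTC" * 10
    right = right if right is not None else "TTGCA" * 10
    return SsrLocus(seq_id=seq_id, start=start, end=start + len(motif) * repeats,
                    motif=canonical_motif(motif), repeats=repeats,
                    flank_left=left, flank_right=right, motif_raw=motif)


class TestMatchLoci:
    def test_identical_flanks_polymorphic_when_repeats_differ(self):
        matches = match_loci([_locus(repeats=7)], [_locus(repeats=9)])
        assert len(matches) == 1 and matches[0].polymorphic

    def test_identical_repeats_is_monomorphic_match(self):
        (m,) = match_loci([_locus()], [_locus()])
        assert not m.polymorphic and m.flank_identity == 1.0

    def test_identity_threshold(self):
        left = "ACGTC" * 10
        right = "TTGCA" * 10
        one_mm_left = "T" + left[1:]
        one_mm_right = right[:-1] + "A"
        close = _locus(left=one_mm_left, right=one_mm_right)  # 49/50 each side
        assert match_loci([_locus()], [close])  # identity 0.98 >= 0.95

        def mutate(s, k):
            out = list(s)
            for i in range(k):
                pos = 3 * i
                out[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[pos]]
            return "".join(out)

        far = _locus(left=mutate(left, 4), right=mutate(right, 4))  # 46/50 = 0.92
        assert match_loci([_locus()], [far]) == []

    def test_motifs_must_agree(self):
        assert match_loci([_locus(motif="GAT")], [_locus(motif="GAA")]) == []


class TestDedupe:
    def test_exact_duplicates_collapse(self):
        m = LocusMatch(_locus(), _locus(repeats=9), 1.0, True)
        m2 = LocusMatch(_locus(start=500), _locus(start=500, repeats=9), 1.0, True)
        assert dedupe_loci([m, m2]) == [m]

    def test_unrelated_flanks_both_kept(self):
        other = _locus(start=500, left="GGGCC" * 10, right="AATAT" * 10)
        m1 = LocusMatch(_locus(), _locus(repeats=9), 1.0, True)
        m2 = LocusMatch(other, _locus(start=500, repeats=9,
                                      left=other.flank_left,
                                      right=other.flank_right), 1.0, True)
        assert len(dedupe_loci([m1, m2])) == 2

    def test_three_way_cluster_keeps_longest_run(self):
        ms = [
            LocusMatch(_locus(start=s, repeats=r), _locus(start=s, repeats=r + 1), 1.0, True)
            for s, r in [(100, 7), (300, 9), (600, 8)]
        ]
        (survivor,) = dedupe_loci(ms)
        assert survivor.locus_a.repeats == 9


class TestSelectCandidates:
    def _match(self, motif="GAT", repeats=(7, 9), flank=150):
        a = _locus(motif=motif, repeats=repeats[0],
                   left="ACGTC" * (flank // 5), right="TTGCA" * (flank // 5))
        b = _locus(motif=motif, repeats=repeats[1],
                   left=a.flank_left, right=a.flank_right)
        return LocusMatch(a, b, 1.0, repeats[0] != repeats[1])

    def test_dinucleotide_motif_rejected(self):
        assert select_candidates([self._match(motif="AT", repeats=(8, 10))]) == []

    def test_short_repeat_rejected(self):
        assert select_candidates([self._match(repeats=(6, 5))]) == []

    def test_feasible_candidate_kept(self):
        assert len(select_candidates([self._match()])) == 1

    def test_window_must_admit_product(self):
        tight = self._match(flank=20)  # window 40+21+... too small for 100 bp
        assert select_candidates([tight]) == []

    def test_monomorphic_rejected(self):
        assert select_candidates([self._match(repeats=(7, 7))]) == []
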