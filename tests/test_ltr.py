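import numpy as np
import pytest

from retroscout.domains import DomainHit
from retroscout.formats_io import GenomicInterval
from retroscout.ltr import LtrPair, classify_element, find_direct_repeats
from retroscout.synthio import mutate_nt


def rand_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def hit(model, start, end, contig="c", strand="+"):
    return DomainHit(GenomicInterval(contig, start, end, strand),
                     frame=1 if strand == "+" else -1, model=model, score=99.0)


def gapless_score(a, b):
    """Match +1 / mismatch -1 score of two equal-length substrings."""
    assert len(a) == len(b)
    return sum(1 if x == y else -1 for x, y in zip(a, b))


def brute_force_gapless_local(up, down):
    """Best gapless local alignment over ALL substring pairs of (up, down):
    exhaustive per-diagonal maximum-subarray scan, independent of any seeded
    or banded search."""
    best = (-1, (0, 0, 0))
    for d in range(-(len(up) - 1), len(down)):
        i0 = max(0, -d)
        run_score, run_start = 0, i0
        for i in range(i0, min(len(up), len(down) - d)):
            step = 1 if up[i] == down[i + d] else -1
            if run_score <= 0:
                run_score, run_start = step, i
            else:
                run_score += step
            if run_score > best[0]:
                length = i - run_start + 1
                best = (run_score, (run_start, run_start + d, length))
    return best


class TestFindDirectRepeats:
    def test_exact_planted_repeats_found_at_exact_coordinates(self):
        rng = np.random.default_rng(0)
        ltr = rand_nt(rng, 300)
        seq = rand_nt(rng, 2000) + ltr + rand_nt(rng, 1500) + ltr + rand_nt(rng, 2000)
        # anchor = the middle 'internal' region
        anchor = (2300 + 200, 2300 + 1300)
        pairs = find_direct_repeats(seq, anchor)
        assert pairs
        best = pairs[0]
        # repeat borders are maximal-scoring local-alignment ends, which can
        # include a few chance-matching bases beyond an exact repeat
        assert abs(best.left.start - 2000) <= 5
        assert abs(best.left.end - 2300) <= 5
        assert abs(best.right.start - 3800) <= 5
        assert abs(best.right.end - 4100) <= 5
        assert best.identity >= 0.98

    def test_diverged_repeats_identity_estimate(self):
        rng = np.random.default_rng(1)
        ltr = rand_nt(rng, 300)
        right = mutate_nt(ltr, 0.15, rng)
        true_identity = sum(a == b for a, b in zip(ltr, right)) / 300
        seq = rand_nt(rng, 1200) + ltr + rand_nt(rng, 900) + right + rand_nt(rng, 1200)
        pairs = find_direct_repeats(seq, (1550, 2350))
        assert pairs
        assert pairs[0].identity == pytest.approx(true_identity, abs=0.03)

    def test_shuffled_sequence_has_no_qualifying_pair(self):
        rng = np.random.default_rng(2)
        ltr = rand_nt(rng, 300)
        seq = rand_nt(rng, 1200) + ltr + rand_nt(rng, 900) + ltr + rand_nt(rng, 1200)
        shuffled = list(seq)
        rng.shuffle(shuffled)
        pairs = find_direct_repeats("".join(shuffled), (1550, 2350))
        assert all(p.repeat_length < 100 or p.identity < 0.80 for p in pairs)
        assert pairs == []

    def test_agreement_with_substring_pair_brute_force(self):
        """On short substitution-only instances the seeded search attains the
        optimal gapless local score over all substring pairs (independent
        per-diagonal maximum-subarray oracle)."""
        rng = np.random.default_rng(3)
        for trial in range(5):
            rep = rand_nt(rng, 40)
            up = rand_nt(rng, 40) + rep + rand_nt(rng, 40)
            down = rand_nt(rng, 60) + mutate_nt(rep, 0.05, rng) + rand_nt(rng, 20)
            seq = up + "ACGT" * 10 + down
            anchor = (len(up), len(up) + 40)
            pairs = find_direct_repeats(seq, anchor, flank=200, k=8,
                                        min_len=20, min_identity=0.8)
            assert pairs, trial
            best = pairs[0]
            score_bf, (ls, rs, length) = brute_force_gapless_local(up, down)
            reported = gapless_score(
                up[best.left.start : best.left.end],
                down[best.right.start - anchor[1] : best.right.end - anchor[1]],
            )
            assert reported == score_bf
            assert abs(best.left.start - ls) <= 2
            assert abs(best.right.start - (anchor[1] + rs)) <= 2
            assert abs(best.repeat_length - length) <= 2

    def test_identity_symmetric_in_the_two_repeats(self):
        """Reverse-complementing the whole locus swaps the roles of the two
        repeat copies; the reported identity must not depend on which copy
        is upstream."""
        from retroscout.formats_io import revcomp

        rng = np.random.default_rng(4)
        ltr = rand_nt(rng, 200)
        other = mutate_nt(ltr, 0.1, rng)
        mid = rand_nt(rng, 600)
        seq = rand_nt(rng, 800) + ltr + mid + other + rand_nt(rng, 800)
        anchor = (1100, 1500)
        pa = find_direct_repeats(seq, anchor)[0]
        rc_anchor = (len(seq) - anchor[1], len(seq) - anchor[0])
        pb = find_direct_repeats(revcomp(seq), rc_anchor)[0]
        assert pa.identity == pytest.approx(pb.identity, abs=0.02)

    def test_truncated_flank_searched_as_is(self):
        rng = np.random.default_rng(5)
        ltr = rand_nt(rng, 150)
        seq = ltr + rand_nt(rng, 500) + ltr + rand_nt(rng, 100)
        pairs = find_direct_repeats(seq, (200, 600), flank=5000)
        assert pairs and pairs[0].left.start == 0


class TestClassifyElement:
    REGION = GenomicInterval("c", 2000, 4000)

    def pair(self):
        return LtrPair(left=GenomicInterval("c", 1000, 1300),
                       right=GenomicInterval("c", 4500, 4800),
                       identity=0.96, repeat_length=300)

    def test_full_length_requires_rt_integrase_and_pair(self):
        hits = [hit("gag", 2000, 2360), hit("reverse_transcriptase", 2400, 2940),
                hit("integrase", 3000, 3420)]
        call = classify_element(self.REGION, hits, [self.pair()])
        assert call.element_class == "full_length"
        assert (call.interval.start, call.interval.end) == (1000, 4800)

    def test_single_domain_is_partial(self):
        call = classify_element(self.REGION, [hit("rnase_h", 2400, 2730)], [])
        assert call.element_class == "partial"
        assert (call.interval.start, call.interval.end) == (2400, 2730)

    def test_rt_and_integrase_without_pair_is_partial(self):
        hits = [hit("reverse_transcriptase", 2400, 2940),
                hit("integrase", 3000, 3420)]
        assert classify_element(self.REGION, hits, []).element_class == "partial"

    def test_lone_ltr_far_from_domains_is_solo(self):
        call = classify_element(self.REGION, [], [],
                                lone_ltr=GenomicInterval("c", 9000, 9300))
        assert call.element_class == "solo_LTR"

    def test_no_evidence_no_call(self):
        assert classify_element(self.REGION, [], []) is None

    def test_minus_strand_cassette_sets_strand(self):
        hits = [hit("integrase", 2000, 2420, strand="-"),
                hit("reverse_transcriptase", 2500, 3040, strand="-")]
        call = classify_element(self.REGION, hits, [self.pair()])
        assert call.element_class == "full_length"
        assert call.interval.strand == "-"
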