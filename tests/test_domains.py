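import math

import numpy as np
import pytest

from retroscout import references
from retroscout.domains import (
    DomainModel,
    build_model,
    calibrate_threshold,
    resolve_overlapping_hits,
    scan_domains,
    six_frame_translate,
)
from retroscout.formats_io import GenomeSequence, GenomicInterval


class TestSixFrameTranslate:
    def test_plus_one_frame(self):
        frames = {f.frame: f.aa for f in six_frame_translate("ATGGCC")}
        assert frames[1] == "MA"

    def test_reverse_frames_are_revcomp_translation(self):
        fwd = {f.frame: f.aa for f in six_frame_translate("ATG")}
        rc = {f.frame: f.aa for f in six_frame_translate("CAT")}
        assert fwd[-1] == rc[1]

    def test_coordinate_map_frame_plus_two(self):
        ft = next(f for f in six_frame_translate("ACGTACG") if f.frame == 2)
        assert ft.nt_interval(0, 1, 7) == (1, 4)

    def test_reverse_coordinate_map_round_trips(self):
        seq = "ACGTACGTACGT"
        for ft in six_frame_translate(seq):
            for i in range(len(ft.aa)):
                s, e = ft.nt_interval(i, i + 1, len(seq))
                assert 0 <= s < e <= len(seq) and e - s == 3

    def test_all_n_translates_to_unknowns(self):
        frames = six_frame_translate("N" * 9)
        assert all(set(f.aa) <= {"X"} for f in frames)


class TestBuildModel:
    def test_column_score_hand_arithmetic(self):
        # column all 'W', N=4, pc=0.5 -> log2((4.5/14)/0.05)
        model = build_model(["W", "W", "W", "W"])
        expected = math.log2((4.5 / 14) / 0.05)
        w = "ACDEFGHIKLMNPQRSTVWY".index("W")
        assert model.pssm[0, w] == pytest.approx(expected)

    def test_uniform_column_all_scores_equal(self):
        col = list("ACDEFGHIKLMNPQRSTVWY")  # one of each residue
        model = build_model(col)
        assert np.allclose(model.pssm[0], model.pssm[0][0])

    def test_absent_residue_scores_below_present(self):
        model = build_model(["WY", "WY", "WF", "WY"])
        row = model.pssm[1]
        idx = {a: i for i, a in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        assert row[idx["A"]] < min(row[idx["Y"]], row[idx["F"]])

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_model(["WW", "W"])


@pytest.fixture(scope="module")
def model():
    rows = references.load_domain_alignments()["protease"]
    return build_model([s for _, _, s in rows], name="protease")


class TestCalibrateThreshold:

    def test_deterministic_under_seed(self, model):
        a = calibrate_threshold(model, seed=5)
        b = calibrate_threshold(model, seed=5)
        assert a == b

    def test_alpha_one_gives_minimum_null_score(self, model):
        thr = calibrate_threshold(model, null_draws=200, alpha=1.0, seed=3)
        # independently reproduce the null with the same generator settings
        rng = np.random.default_rng(3)
        draws = rng.choice(20, size=(200, model.length), p=np.full(20, 0.05))
        scores = model.pssm[np.arange(model.length)[None, :], draws].sum(axis=1)
        assert thr == pytest.approx(scores.min())

    def test_threshold_increases_as_alpha_decreases(self, model):
        t_loose = calibrate_threshold(model, alpha=1e-1, seed=0)
        t_mid = calibrate_threshold(model, alpha=1e-2, seed=0)
        t_tight = calibrate_threshold(model, alpha=1e-3, seed=0)
        assert t_loose <= t_mid <= t_tight


class TestScanDomains:
    def test_planted_cassette_all_domains_hit(self, small_dataset,
                                              domain_models):
        _, genome, truth = small_dataset
        el = truth.of_class("full_length")[0]
        region = GenomicInterval(el.interval.contig, el.interval.start,
                                 el.interval.end)
        hits = resolve_overlapping_hits(scan_domains(region, genome,
                                                     domain_models))
        models_hit = {h.model for h in hits}
        truth_models = {d for d, _ in el.domains}
        assert truth_models <= models_hit
        # hit coordinates reproduce the planted domain intervals
        by_model = {h.model: h.interval for h in hits}
        for name, iv in el.domains:
            assert by_model[name].start == iv.start
            assert by_model[name].end == iv.end

    def test_hits_within_scanned_region(self, small_dataset, domain_models):
        _, genome, truth = small_dataset
        el = truth.of_class("full_length")[0]
        region = GenomicInterval(el.interval.contig, el.interval.start - 500,
                                 el.interval.end + 500)
        for h in scan_domains(region, genome, domain_models):
            assert region.start <= h.interval.start < h.interval.end <= region.end

    def test_false_hit_rate_on_random_background(self, domain_models):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=10_000,
                                 p=[0.3, 0.2, 0.2, 0.3]))
        genome = GenomeSequence({"r": seq})
        hits = scan_domains(GenomicInterval("r", 0, 10_000), genome,
                            domain_models, reduce_overlaps=False)
        n_windows = sum(
            max(0, (10_000 - 3 * m.length) // 3 + 1) * 6 for m in domain_models
        )
        alpha = 1e-3
        assert len(hits) <= 3 * alpha * n_windows

    def test_agreement_with_all_window_rescoring_oracle(self, small_dataset,
                                                        domain_models):
        """Every reported hit, and no other window, clears the threshold when
        each window is rescored independently."""
        _, genome, truth = small_dataset
        el = truth.of_class("full_length")[0]
        start = el.interval.start + 1500
        region = GenomicInterval(el.interval.contig, start, start + 2000)
        got = {
            (h.model, h.frame, h.interval.start, h.interval.end)
            for h in scan_domains(region, genome, domain_models,
                                  reduce_overlaps=False)
        }
        expected = set()
        seq = genome.fetch(GenomicInterval(region.contig, region.start,
                                           region.end))
        for ft in six_frame_translate(seq):
            for model in domain_models:
                for w in range(len(ft.aa) - model.length + 1):
                    window = ft.aa[w : w + model.length]
                    if "*" in window or "X" in window:
                        continue
                    if model.score_sequence(window) >= model.threshold:
                        s, e = ft.nt_interval(w, w + model.length, len(seq))
                        expected.add((model.name, ft.frame, region.start + s,
                                      region.start + e))
        assert got == expected

    def test_consensus_beats_single_mutants(self, domain_models):
        model = next(m for m in domain_models if m.name == "chromodomain")
        cons = model.consensus
        base = model.score_sequence(cons)
        rng = np.random.default_rng(1)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(25):
            i = int(rng.integers(len(cons)))
            sub = aa[int(rng.integers(20))]
            mutant = cons[:i] + sub + cons[i + 1 :]
            assert model.score_sequence(mutant) <= base

    def test_short_region_empty(self, small_dataset, domain_models):
        _, genome, _ = small_dataset
        contig = next(iter(genome.contigs))
        assert scan_domains(GenomicInterval(contig, 0, 30), genome,
                            domain_models) == []
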