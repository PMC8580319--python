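"""Background estimation, PWM construction, exact p-values, scanning,
architecture assessment, and MEME-format round-trips."""

import numpy as np
import pytest

from _oracles import enumerate_score_pmf, enumeration_p_value
from acsarch.meme_io import read_meme, write_meme
from acsarch.motifs import (
    AA_ALPHABET,
    BackgroundModel,
    MotifError,
    MotifHit,
    assess_architecture,
    best_hit,
    build_motif_model,
    estimate_background,
    scan_sequence,
    score_distribution,
    sequence_p_value,
)
from conftest import random_protein


class TestBackground:
    def test_pseudocounted_frequencies(self):
        bg = estimate_background(["AAAA"])
        assert bg["A"] == pytest.approx(5 / 24)
        assert bg["C"] == pytest.approx(1 / 24)

    def test_one_of_each_letter_gives_uniform(self):
        bg = estimate_background([AA_ALPHABET])
        assert np.allclose(bg.frequencies, 1 / 20)

    def test_large_sample_recovers_generating_composition(self):
        rng = np.random.default_rng(42)
        probs = np.linspace(1, 3, 20)
        probs /= probs.sum()
        seq = "".join(AA_ALPHABET[j] for j in rng.choice(20, 10_000, p=probs))
        bg = estimate_background([seq])
        assert np.abs(bg.frequencies - probs).max() < 0.01

    def test_ambiguous_letters_are_not_counted(self):
        assert estimate_background(["AXXA"]).frequencies.tolist() == \
            estimate_background(["AA"]).frequencies.tolist()

    @pytest.mark.parametrize("seqs", [[], ["XXX*"]])
    def test_unusable_input_errors(self, seqs):
        with pytest.raises(MotifError):
            estimate_background(seqs)


class TestBuildMotif:
    def test_identical_instances_give_certain_consensus(self, uniform_bg):
        m = build_motif_model(["ACDEFG", "ACDEFG"], uniform_bg, pseudocount=0.0)
        assert m.consensus == "ACDEFG"
        assert np.allclose(m.probabilities.max(axis=1), 1.0)

    def test_hand_computed_log_odds(self, uniform_bg):
        m = build_motif_model(["AC", "AG"], uniform_bg, pseudocount=0.0,
                              allow_any_width=True)
        col2 = dict(zip(AA_ALPHABET, m.probabilities[1]))
        assert col2["C"] == pytest.approx(0.5)
        assert col2["G"] == pytest.approx(0.5)
        lo = dict(zip(AA_ALPHABET, m.log_odds[1]))
        assert lo["C"] == pytest.approx(np.log2(0.5 / 0.05), abs=1e-9)

    def test_log_odds_invariant(self, uniform_bg):
        m = build_motif_model(["ACDEFG", "AADEFG", "ACDEFA"], uniform_bg)
        expected = np.log2(m.probabilities / uniform_bg.frequencies)
        assert np.allclose(m.log_odds, expected, atol=1e-9)

    def test_width_bound_enforced_without_override(self, uniform_bg):
        with pytest.raises(MotifError):
            build_motif_model(["ABCDE"[:4]], uniform_bg)
        build_motif_model(["ACDE"], uniform_bg, allow_any_width=True)

    def test_ragged_or_empty_instances_error(self, uniform_bg):
        with pytest.raises(MotifError):
            build_motif_model(["ACDEFG", "ACDEF"], uniform_bg)
        with pytest.raises(MotifError):
            build_motif_model([], uniform_bg)


class TestScoreDistribution:
    def test_single_column_support(self, uniform_bg):
        m = build_motif_model(["A"], uniform_bg, pseudocount=1.0,
                              allow_any_width=True)
        d = score_distribution(m, uniform_bg)
        assert len(d.pmf[d.pmf > 0]) <= 20
        assert d.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        masses = d.pmf[d.pmf > 0]
        assert np.allclose(np.round(masses * 20), masses * 20)

    @pytest.mark.parametrize("width", [2, 3, 4])
    def test_pmf_matches_brute_force_enumeration(self, width):
        bg = BackgroundModel(np.array([0.4, 0.3, 0.2, 0.1]), "ACGT")
        rng = np.random.default_rng(width)
        insts = ["".join("ACGT"[j] for j in rng.integers(0, 4, width))
                 for _ in range(5)]
        m = build_motif_model(insts, bg, allow_any_width=True)
        d = score_distribution(m, bg)
        oracle = enumerate_score_pmf(d.int_scores[:, :4], bg.frequencies)
        # every achievable score's p-value must agree exactly
        for s in oracle:
            assert d.p_value(s) == pytest.approx(
                enumeration_p_value(oracle, s), abs=1e-9)
        assert sum(oracle.values()) == pytest.approx(1.0, abs=1e-9)

    def test_null_best_hit_p_values_super_uniform(self, uniform_bg):
        rng = np.random.default_rng(0)
        m = build_motif_model(
            [random_protein(rng, 12) for _ in range(8)], uniform_bg)
        d = score_distribution(m, uniform_bg)
        ps = np.sort([
            sequence_p_value(random_protein(rng, 150), m, uniform_bg, dist=d)
            for _ in range(500)
        ])
        n = len(ps)
        d_plus = np.max(np.arange(1, n + 1) / n - ps)
        assert d_plus < 1.517 / np.sqrt(n)   # one-sided KS, alpha = 0.01


class TestScan:
    def test_vacuous_threshold_returns_every_window(self, uniform_bg):
        rng = np.random.default_rng(1)
        m = build_motif_model([random_protein(rng, 8)], uniform_bg)
        seq = random_protein(rng, 60)
        hits = scan_sequence(seq, m, uniform_bg, p_threshold=1.0)
        assert len(hits) == 60 - 8 + 1
        assert [h.start for h in hits] == sorted(h.start for h in hits)

    def test_planted_consensus_is_best_hit(self, uniform_bg):
        rng = np.random.default_rng(2)
        m = build_motif_model(["WWCHYKQWDD"], uniform_bg)
        seq = random_protein(rng, 17) + "WWCHYKQWDD" + random_protein(rng, 30)
        hits = scan_sequence(seq, m, uniform_bg, p_threshold=1.0)
        assert best_hit(hits).start == 17

    def test_short_sequence_warns_and_returns_empty(self, uniform_bg):
        m = build_motif_model(["WWCHYKQWDD"], uniform_bg)
        with pytest.warns(UserWarning):
            assert scan_sequence("ACD", m, uniform_bg) == []

    def test_mostly_ambiguous_windows_skipped(self, uniform_bg):
        m = build_motif_model(["ACDEFG"], uniform_bg)
        hits = scan_sequence("XXXXXXXXACDEFG", m, uniform_bg, p_threshold=1.0)
        starts = {h.start for h in hits}
        assert 0 not in starts          # 6/6 ambiguous
        assert 8 in starts

    def test_planted_family_yields_nine_disjoint_hits(self, perfect_family):
        spec, records, truth, models = perfect_family
        sid, seq = records[0]
        t = truth.truths[sid]
        hits = []
        for mid in sorted(models):
            if mid == "AAT":
                continue
            hits.extend(scan_sequence(seq, models[mid], spec.background,
                                      p_threshold=1e-4, sequence_id=sid))
        arch = assess_architecture(hits)
        assert arch.complete
        kept = [arch.presence[m] for m in sorted(arch.presence)]
        for i, h in enumerate(kept):
            for other in kept[i + 1:]:
                assert not h.overlaps(other)


def _hit(motif_id, start, width=10, p=1e-9, seq="s"):
    return MotifHit(motif_id=motif_id, sequence_id=seq, start=start,
                    width=width, score=30.0, p_value=p)


class TestArchitecture:
    def test_empty_hits_incomplete(self):
        arch = assess_architecture([])
        assert not arch.complete
        assert all(v is None for v in arch.presence.values())

    def test_ordered_nine_hits_complete(self):
        hits = [_hit(f"ACS{i + 1}", start=i * 20) for i in range(9)]
        arch = assess_architecture(hits)
        assert arch.complete and arch.ordered

    def test_scrambled_order_rejected(self):
        starts = [160, 20, 40, 60, 80, 100, 120, 140, 0]   # ACS9 before ACS1
        hits = [_hit(f"ACS{i + 1}", start=s) for i, s in enumerate(starts)]
        arch = assess_architecture(hits)
        assert not arch.complete and not arch.ordered

    def test_overlapping_hits_not_ordered(self):
        hits = [_hit(f"ACS{i + 1}", start=i * 20) for i in range(9)]
        hits[3] = _hit("ACS4", start=45)   # overlaps ACS3's [40, 50)
        arch = assess_architecture(hits)
        assert not arch.ordered and not arch.complete

    def test_lowest_p_hit_retained_with_start_tiebreak(self):
        hits = ([_hit(f"ACS{i + 1}", start=i * 20) for i in range(9)]
                + [_hit("ACS5", start=300, p=1e-12)]
                + [_hit("ACS5", start=310, p=1e-12)])
        arch = assess_architecture(hits)
        assert arch.presence["ACS5"].start == 300
        assert not arch.ordered            # ACS5 retained after ACS9's start

    def test_aat_flag_is_independent(self):
        hits = [_hit(f"ACS{i + 1}", start=i * 20) for i in range(9)]
        arch = assess_architecture(hits + [_hit("AAT", start=400)])
        assert arch.complete and arch.aat_present

    def test_mixed_sequence_ids_rejected(self):
        with pytest.raises(MotifError):
            assess_architecture([_hit("ACS1", 0, seq="a"),
                                 _hit("ACS2", 30, seq="b")])


class TestMemeIO:
    def test_roundtrip_preserves_models(self, tmp_path, uniform_bg):
        rng = np.random.default_rng(5)
        models = [
            build_motif_model([random_protein(rng, 9) for _ in range(4)],
                              uniform_bg, motif_id=f"ACS{k}")
            for k in (1, 2)
        ]
        path = tmp_path / "motifs.meme"
        write_meme(models, path, uniform_bg)
        loaded = read_meme(path)
        assert [m.motif_id for m in loaded] == ["ACS1", "ACS2"]
        for orig, new in zip(models, loaded):
            assert np.abs(orig.probabilities - new.probabilities).max() < 1e-5
            assert new.consensus == orig.consensus

    def test_out_of_bound_width_needs_override(self, tmp_path, uniform_bg):
        m = build_motif_model(["ACDE"], uniform_bg, allow_any_width=True)
        path = tmp_path / "w4.meme"
        write_meme([m], path, uniform_bg)
        with pytest.raises(MotifError):
            read_meme(path)
        assert read_meme(path, allow_any_width=True)[0].width == 4

    def test_non_meme_file_rejected(self, tmp_path):
        path = tmp_path / "bogus.txt"
        path.write_text("not a motif file\n")
        with pytest.raises(MotifError):
            read_meme(path)
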