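"""RDM construction, rank correlation and simulated pattern similarity."""

import numpy as np
import pytest
from scipy import stats

from predspeech.models import PRESETS
from predspeech.rsa import (
    RDM,
    Z_CEILING,
    cross_subject_consistency,
    hypothesis_rdm,
    pattern_rdm,
    rdm_correlation,
    simulate_rsa,
    simulate_subject_rdms,
)


class TestPatternRDM:
    def test_identical_and_opposite_patterns(self):
        base = np.array([1.0, 2.0, 0.5, 3.0])
        rdm = pattern_rdm(np.stack([base, base, -base]))
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert rdm.matrix[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_pairwise_oracle(self):
        # independent oracle: per-pair Pearson via scipy
        patterns = np.random.default_rng(0).normal(size=(10, 37))
        rdm = pattern_rdm(patterns)
        for i in range(10):
            for j in range(10):
                expected = 1 - stats.pearsonr(patterns[i], patterns[j]).statistic
                assert rdm.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_diagonal_is_masked(self):
        rdm = pattern_rdm(np.random.default_rng(1).normal(size=(4, 8)))
        assert rdm.mask.diagonal().all()
        assert rdm.unmasked_cells().sum() == 6

    def test_zero_variance_pattern_is_named(self):
        patterns = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="flat"):
            pattern_rdm(patterns, labels=("flat", "ramp"))

    def test_csv_round_trip_preserves_mask(self, tmp_path):
        rdm = pattern_rdm(np.random.default_rng(2).normal(size=(5, 9)))
        path = tmp_path / "rdm.csv"
        rdm.to_csv(path)
        back = RDM.from_csv(path)
        np.testing.assert_array_equal(back.mask, rdm.mask)
        cells = rdm.unmasked_cells()
        np.testing.assert_allclose(back.matrix[cells], rdm.matrix[cells], atol=1e-12)


class TestHypothesisRDM:
    def test_vowel_triple_cell_counts(self, lexicon):
        rdm = hypothesis_rdm(lexicon, "vowel-triple")
        vals = rdm.values()
        assert len(vals) == 276  # C(24, 2) off-diagonal pairs
        assert (vals == 0).sum() == 24  # 8 triples x 3 within-triple pairs
        assert (vals == 1).sum() == 252

    def test_triple_mates_predicted_similar(self, lexicon):
        rdm = hypothesis_rdm(lexicon, "vowel-triple")
        i, j, k = (lexicon.index(w) for w in ("sing", "thing", "bath"))
        assert rdm.matrix[i, j] == 0
        assert rdm.matrix[i, k] == 1

    def test_segment_level_is_graded(self, lexicon):
        rdm = hypothesis_rdm(lexicon, "segment")
        i, j = lexicon.index("sing"), lexicon.index("sit")
        # sing/sit share C1 and V -> dissimilarity 1/3
        assert rdm.matrix[i, j] == pytest.approx(1 / 3)
        assert rdm.matrix[i, i] == 0

    def test_feature_level_matches_row_correlations(self, lexicon, W):
        rdm = hypothesis_rdm(lexicon, "feature", W=W)
        i, j = lexicon.index("sing"), lexicon.index("thing")
        expected = 1 - stats.pearsonr(W.matrix[i], W.matrix[j]).statistic
        assert rdm.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_cross_condition_cells_masked(self, lexicon):
        rdm = hypothesis_rdm(lexicon, "vowel-triple", n_conditions=4)
        assert rdm.matrix.shape == (96, 96)
        assert rdm.mask[0, 24]  # same word, different condition
        assert not rdm.mask[0, 1]
        assert rdm.unmasked_cells().sum() == 4 * 276

    def test_unknown_level_rejected(self, lexicon):
        with pytest.raises(ValueError):
            hypothesis_rdm(lexicon, "acoustic")


class TestRDMCorrelation:
    def test_fisher_z_of_half(self):
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_matches_rank_oracle_on_small_case(self, lexicon):
        hyp = hypothesis_rdm(lexicon, "vowel-triple")
        rng = np.random.default_rng(3)
        observed = RDM(
            matrix=hyp.matrix + rng.normal(0, 0.01, hyp.matrix.shape),
            mask=hyp.mask,
        )
        r, z = rdm_correlation(observed, hyp)
        cells = hyp.unmasked_cells()
        expected = stats.spearmanr(observed.matrix[cells], hyp.matrix[cells]).statistic
        assert r == pytest.approx(expected, abs=1e-12)
        assert z == pytest.approx(np.arctanh(expected), abs=1e-12)
        # jitter preserves the 0/1 separation, so r sits at the
        # tie-limited maximum for a 24/252 binary split
        tie_max = stats.spearmanr(
            np.arange(276), np.r_[np.zeros(24), np.ones(252)]
        ).statistic
        assert r == pytest.approx(tie_max, abs=0.02)

    def test_invariant_to_monotone_transforms(self, lexicon):
        hyp = hypothesis_rdm(lexicon, "vowel-triple")
        rng = np.random.default_rng(4)
        m = np.abs(hyp.matrix + rng.normal(0, 0.3, hyp.matrix.shape))
        m = (m + m.T) / 2
        observed = RDM(matrix=m, mask=hyp.mask)
        transformed = RDM(matrix=np.exp(3 * m), mask=hyp.mask)
        assert rdm_correlation(observed, hyp)[0] == pytest.approx(
            rdm_correlation(transformed, hyp)[0], abs=1e-12
        )

    def test_perfect_correlation_raises(self, lexicon):
        hyp = hypothesis_rdm(lexicon, "vowel-triple")
        with pytest.raises(ValueError, match="infinite"):
            rdm_correlation(hyp, hyp)


class TestSimulateRSA:
    def test_noiseless_single_replication_is_deterministic(self, W):
        params = PRESETS["pe_paper"]
        a = simulate_rsa("pe", params, reps=1, seed=9, measurement_noise_sd=0.0, W=W)
        b = simulate_rsa("pe", params, reps=1, seed=9, measurement_noise_sd=0.0, W=W)
        assert a == b

    @pytest.mark.parametrize("model,preset", [("pe", "pe_paper"), ("sharpened", "sharpened_paper")])
    def test_fisher_z_values_are_small(self, W, model, preset):
        # measurement noise (sd 2) dwarfs the feature-scale signal, so
        # correlations stay far below 0.5, as in comparable studies
        z = simulate_rsa(model, PRESETS[preset], reps=100, seed=10, W=W)
        assert all(abs(v) < 0.5 for v in z.values())


class TestCrossSubjectConsistency:
    def test_identical_subjects_hit_documented_ceiling(self):
        rng = np.random.default_rng(5)
        rdm = pattern_rdm(rng.normal(size=(6, 12)))
        assert cross_subject_consistency([rdm] * 5) == Z_CEILING

    def test_independent_subjects_have_no_consistency(self):
        rng = np.random.default_rng(6)
        rdms = [pattern_rdm(rng.normal(size=(24, 37))) for _ in range(21)]
        assert abs(cross_subject_consistency(rdms)) < 0.05

    def test_requires_two_subjects(self):
        rdm = pattern_rdm(np.random.default_rng(7).normal(size=(4, 6)))
        with pytest.raises(ValueError):
            cross_subject_consistency([rdm])

    def test_simulated_subjects_show_pe_crossover(self, W):
        # simulated participants' RDMs carry the same interaction as
        # the group-level simulation: more consistent structure for
        # neutral-12 than neutral-4 and for match-4 than match-12
        params = PRESETS["pe_paper"]
        subjects = [
            simulate_subject_rdms("pe", params, reps=30, seed=100 + s, W=W)
            for s in range(8)
        ]
        scores = {
            c: cross_subject_consistency([s[c] for s in subjects])
            for c in ("match4", "match12", "neutral4", "neutral12")
        }
        assert scores["neutral12"] > scores["neutral4"]
        assert scores["match4"] > scores["match12"]
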