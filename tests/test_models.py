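"""Settling dynamics of the Sharpened Signal and Prediction Error models."""

import numpy as np
import pytest

from predspeech._rng import child_rng
from predspeech.lexicon import make_prior
from predspeech.models import (
    PRESETS,
    ModelParams,
    first_iteration_features,
    params_from_printed,
    pe_settle,
    settle,
    settle_batch,
    sharpened_settle,
)
from predspeech.readout import simulate_condition
from predspeech.sensory import degrade_features


@pytest.fixture(scope="module")
def pe_params():
    return PRESETS["pe_paper"]


@pytest.fixture(scope="module")
def sharp_params():
    return PRESETS["sharpened_paper"]


class TestParams:
    def test_printed_vectors_are_clarity_levels(self):
        p = params_from_printed([0.3559, 0.5825, 0.03414, 0.407, 1.327, 0.00281])
        assert p.noise_4ch == pytest.approx(1 - 0.3559)
        assert p.noise_12ch == pytest.approx(1 - 0.5825)
        # 4-channel speech is the more degraded input
        assert p.noise_4ch > p.noise_12ch
        np.testing.assert_allclose(
            p.to_vector(), [0.3559, 0.5825, 0.03414, 0.407, 1.327, 0.00281]
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(0.5, 0.3, -1.0, 0.4, 1.0, 0.0)
        with pytest.raises(ValueError):
            ModelParams(1.5, 0.3, 0.1, 0.4, 1.0, 0.0)


class TestPredictionError:
    def test_perfect_prediction_settles_immediately(self, W, pe_params):
        # one-hot prior on the presented word with a clear input means
        # zero prediction error: settling ends on iteration 1
        for w in range(24):
            prior = np.zeros(24)
            prior[w] = 1.0
            res = pe_settle(W.matrix[w], prior, pe_params, W)
            assert res.iterations_used == 1
            assert res.converged
            np.testing.assert_allclose(res.first_iteration_features, 0.0, atol=1e-12)

    def test_uniform_prior_precision_is_input_term_only(self, W, pe_params):
        # sd of a uniform prior is 0, so precision reduces to the
        # input's sd/sum
        inp = degrade_features(
            W.row("doom"), 0.4, np.random.default_rng(0), W.scheme
        ).values
        res = pe_settle(inp, make_prior("neutral").values, pe_params, W,
                        record_trajectory=True)
        expected = inp.std() / inp.sum()
        assert res.trajectory[0]["precision"] == pytest.approx(expected, rel=1e-12)

    def test_clear_input_uniform_prior_points_at_target(self, W, pe_params):
        # brute-force oracle: expected features are the column means of
        # W under a uniform prior, and the prediction-error word vector
        # peaks at the presented word
        col_means = W.matrix.mean(axis=0)
        for w in (0, 7, 23):
            res = pe_settle(W.matrix[w], make_prior("neutral").values, pe_params, W,
                            record_trajectory=True)
            np.testing.assert_allclose(
                res.trajectory[0]["expected_features"], col_means, atol=1e-12
            )
            pe_word = (W.matrix[w] - col_means) @ W.matrix.T
            assert pe_word.argmax() == w

    def test_degenerate_prior_raises(self, W, pe_params):
        with pytest.raises(FloatingPointError):
            pe_settle(W.matrix[0], np.zeros(24), pe_params, W)


class TestSharpenedSignal:
    def test_clear_input_first_iteration_prefers_target(self, W, sharp_params):
        for w in (0, 11, 23):
            res = sharpened_settle(
                W.matrix[w], make_prior("neutral").values,
                sharp_params.replace(max_iterations=1), W,
            )
            assert res.final_word_vector.argmax() == w

    def test_matching_prior_settles_no_slower_than_neutral(self, W, sharp_params):
        match_iters, neutral_iters = [], []
        for w in range(24):
            match = make_prior("match", w, report_accuracy=0.8214).values
            neutral = make_prior("neutral").values
            match_iters.append(sharpened_settle(W.matrix[w], match, sharp_params, W).iterations_used)
            neutral_iters.append(sharpened_settle(W.matrix[w], neutral, sharp_params, W).iterations_used)
        assert np.mean(match_iters) <= np.mean(neutral_iters)


class TestSettleContracts:
    @pytest.mark.parametrize("model,preset", [("pe", "pe_paper"), ("sharpened", "sharpened_paper")])
    def test_iteration_cap_and_convergence_flag(self, W, model, preset):
        params = PRESETS[preset]
        rng = np.random.default_rng(5)
        inputs = np.stack(
            [degrade_features(W.matrix[w], params.noise_4ch, rng, W.scheme).values
             for w in range(24)]
        )
        priors = np.full((24, 24), 1 / 24)
        iters, _, converged, _, _ = settle_batch(model, inputs, priors, params, W)
        assert np.all((iters >= 1) & (iters <= params.max_iterations))
        # converged is False exactly when the cap was hit
        np.testing.assert_array_equal(~converged, iters == params.max_iterations)

    @pytest.mark.parametrize("model,preset", [("pe", "pe_paper"), ("sharpened", "sharpened_paper")])
    def test_settling_is_faster_with_matching_prior(self, W, model, preset):
        # the univariate signature: fewer settling iterations (lower
        # BOLD proxy) under matching than neutral priors at both
        # clarity levels
        params = PRESETS[preset]
        for lvl in ("4", "12"):
            match = simulate_condition(model, f"match{lvl}", params, 50, seed=2, W=W)
            neutral = simulate_condition(model, f"neutral{lvl}", params, 50, seed=2, W=W)
            assert match.mean_iterations < neutral.mean_iterations


class TestFirstIterationFeatures:
    def test_pe_representation_is_nonnegative(self, W, pe_params):
        inp = degrade_features(W.row("kite"), 0.6, np.random.default_rng(2), W.scheme)
        feats = first_iteration_features(
            "pe", inp, make_prior("neutral").values, pe_params, W,
            measurement_noise_sd=0.0,
        )
        assert np.all(feats >= 0)

    def test_sharpened_representation_is_group_normalised(self, W, sharp_params):
        inp = degrade_features(W.row("kite"), 0.6, np.random.default_rng(2), W.scheme)
        feats = first_iteration_features(
            "sharpened", inp, make_prior("neutral").values, sharp_params, W,
            measurement_noise_sd=0.0,
        )
        for sl in W.scheme.block_slices():
            assert feats[sl].sum() == pytest.approx(1.0, abs=1e-9)

    def test_measurement_noise_reproducibility(self, W, pe_params):
        inp = degrade_features(W.row("zone"), 0.5, np.random.default_rng(0), W.scheme)
        prior = make_prior("neutral").values
        a = first_iteration_features("pe", inp, prior, pe_params, W, 2.0, child_rng(1, "m"))
        b = first_iteration_features("pe", inp, prior, pe_params, W, 2.0, child_rng(1, "m"))
        c = first_iteration_features("pe", inp, prior, pe_params, W, 2.0, child_rng(2, "m"))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_noise_requires_rng(self, W, pe_params):
        with pytest.raises(ValueError):
            first_iteration_features(
                "pe", W.matrix[0], make_prior("neutral").values, pe_params, W, 2.0
            )
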