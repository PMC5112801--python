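"""Behavioural and univariate read-outs of the settling models.

Word report is simulated by a softmax over the final lexical vector
(p ∝ exp(x / temperature)) followed by additive Gaussian response noise
on the probabilities; the noisy maximum is the reported word.  The
univariate BOLD proxy is the mean number of settling iterations divided
by the iteration cap (500), on the logic that longer settling means more
neural processing and a larger hemodynamic response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import child_rng
from .lexicon import WordFeatureMatrix, word_feature_matrix
from .models import MODELS, ModelParams, settle_batch
from .sensory import CONDITIONS, generate_condition_inputs

__all__ = [
    "ConditionOutcome",
    "softmax_choice",
    "softmax_probabilities",
    "simulate_condition",
    "simulate_study",
    "simulate_condition_samples",
]


@dataclass(frozen=True)
class ConditionOutcome:
    """Aggregate simulation outcome for one condition."""

    condition: str
    accuracy: float
    mean_iterations: float
    bold_proxy: float
    n_trials: int


def softmax_probabilities(word_vector: np.ndarray, temperature: float) -> np.ndarray:
    """p ∝ exp(x / temperature); larger temperature = flatter."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    x = np.asarray(word_vector, dtype=float) / temperature
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_choice(
    word_vector: np.ndarray,
    temperature: float,
    behavioural_noise: float,
    rng: np.random.Generator | None = None,
) -> tuple[int, np.ndarray]:
    """Pick a word from a lexical vector.

    Gaussian noise of sd ``behavioural_noise`` is added to the softmax
    probabilities; the argmax of the noisy values is the choice.  The
    returned probability vector is the pre-noise softmax.
    """
    p = softmax_probabilities(word_vector, temperature)
    noisy = p
    if behavioural_noise > 0:
        if rng is None:
            raise ValueError("rng is required when behavioural_noise > 0")
        noisy = p + rng.normal(0.0, behavioural_noise, size=p.shape)
    return int(np.argmax(noisy)), p


def _run_condition(
    model: str,
    condition: str,
    params: ModelParams,
    reps: int,
    seed: int,
    W: WordFeatureMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Settle reps×24 trials; return (correct, iterations, targets)."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    items = generate_condition_inputs(condition, params, reps, seed, W)
    inputs = np.stack([inp.values for inp, _, _ in items])
    priors = np.stack([pri.values for _, pri, _ in items])
    targets = np.array([t for _, _, t in items])

    iterations, words, _, _, _ = settle_batch(model, inputs, priors, params, W)

    p = softmax_probabilities(words, params.temperature)
    if params.behavioural_noise > 0:
        rng = child_rng(seed, "behaviour", model, condition)
        p = p + rng.normal(0.0, params.behavioural_noise, size=p.shape)
    chosen = np.argmax(p, axis=1)
    return (chosen == targets).astype(float), iterations.astype(float), targets


def simulate_condition(
    model: str,
    condition: str,
    params: ModelParams,
    reps: int,
    seed: int,
    W: WordFeatureMatrix | None = None,
) -> ConditionOutcome:
    """Simulate ``reps`` replications of all 24 words in one condition."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    W = W if W is not None else word_feature_matrix()
    correct, iterations, _ = _run_condition(model, condition, params, reps, seed, W)
    mean_iter = float(iterations.mean())
    return ConditionOutcome(
        condition=condition,
        accuracy=float(correct.mean()),
        mean_iterations=mean_iter,
        bold_proxy=mean_iter / params.max_iterations,
        n_trials=len(correct),
    )


def simulate_study(
    model: str,
    params: ModelParams,
    reps: int,
    seed: int,
    W: WordFeatureMatrix | None = None,
) -> dict[str, ConditionOutcome]:
    """Simulate all four conditions; returns {condition: outcome}."""
    W = W if W is not None else word_feature_matrix()
    return {
        c: simulate_condition(model, c, params, reps, seed, W) for c in CONDITIONS
    }


def simulate_condition_samples(
    model: str,
    condition: str,
    params: ModelParams,
    reps: int,
    seed: int,
    W: WordFeatureMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replication outcome samples for one condition.

    Returns (accuracy, bold_proxy) arrays of length ``reps``: each
    replication is one pass over the 24 words, so accuracy has
    granularity 1/24 and the proxy is that replication's mean iteration
    count divided by the cap.  These per-replication samples feed the
    Monte-Carlo kernel-density likelihoods in model comparison.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    W = W if W is not None else word_feature_matrix()
    correct, iterations, _ = _run_condition(model, condition, params, reps, seed, W)
    n = len(W.lexicon)
    acc = correct.reshape(reps, n).mean(axis=1)
    proxy = iterations.reshape(reps, n).mean(axis=1) / params.max_iterations
    return acc, proxy
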