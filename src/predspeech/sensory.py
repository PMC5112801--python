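"""Probabilistic degradation of phonetic feature vectors.

This is the package's surrogate for noise-vocoding: instead of filtering
audio into spectral channels, a word's clear binary feature row is
corrupted group by group.  With noise level nu, the active feature of a
group of size k keeps mass (1 - nu) and a random mass summing to nu —
uniform draws renormalised — is spread over all k features of the group,
so every (position, group) block still sums to 1 and can be read as a
probability distribution over that group's labels.  nu = 0 leaves the
row untouched; nu = 1 destroys all information about the group.

Noise is drawn once per trial and held fixed over the settling
iterations of the recognition models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .lexicon import (
    PriorVector,
    WordFeatureMatrix,
    FeatureScheme,
    make_prior,
    word_feature_matrix,
    MATCH_PRIOR_BASE,
    WRITTEN_ONLY_ACCURACY,
)

__all__ = [
    "SensoryInput",
    "CONDITIONS",
    "degrade_features",
    "degrade_batch",
    "condition_noise",
    "condition_prior_kind",
    "generate_condition_inputs",
    "inputs_to_frame",
]

#: Canonical condition order used throughout the package: prior type
#: (match/neutral) crossed with vocoding channels (4 = low detail,
#: 12 = high detail).
CONDITIONS = ("match4", "match12", "neutral4", "neutral12")


@dataclass(frozen=True)
class SensoryInput:
    """One degraded 37-dimensional input vector."""

    values: np.ndarray
    word: int
    noise_level: float
    condition: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("sensory input entries must be nonnegative")


def degrade_batch(
    clear_rows: np.ndarray,
    nu: float,
    rng: np.random.Generator,
    scheme: FeatureScheme,
) -> np.ndarray:
    """Degrade a (n, 37) stack of clear feature rows at noise level ``nu``.

    Each row and each (position, group) block receives an independent
    uniform reallocation: out = (1 - nu) * row + nu * u / sum(u).
    """
    if not (0.0 <= nu <= 1.0):
        raise ValueError(f"noise level must lie in [0, 1], got {nu!r}")
    rows = np.atleast_2d(np.asarray(clear_rows, dtype=float))
    out = (1.0 - nu) * rows
    if nu > 0.0:
        for sl in scheme.block_slices():
            u = rng.uniform(size=(rows.shape[0], sl.stop - sl.start))
            out[:, sl] += nu * u / u.sum(axis=1, keepdims=True)
    return out


def degrade_features(
    clear_row: np.ndarray,
    nu: float,
    rng: np.random.Generator,
    scheme: FeatureScheme,
    word: int = -1,
    condition: str | None = None,
) -> SensoryInput:
    """Degrade one clear feature row; see module docstring for the rule."""
    values = degrade_batch(clear_row, nu, rng, scheme)[0]
    return SensoryInput(values=values, word=word, noise_level=nu, condition=condition)


def condition_noise(condition: str, params) -> float:
    """Noise level for a condition tag (4-channel is the noisier input)."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    return params.noise_4ch if condition.endswith("4") else params.noise_12ch


def condition_prior_kind(condition: str) -> str:
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    return "match" if condition.startswith("match") else "neutral"


def generate_condition_inputs(
    condition: str,
    params,
    reps: int,
    seed: int,
    W: WordFeatureMatrix | None = None,
) -> list[tuple[SensoryInput, PriorVector, int]]:
    """Generate ``reps`` degraded inputs per word for one condition.

    Returns ``reps * 24`` (input, prior, target) triples, replication by
    replication in lexicon order.  Match conditions pair each word with
    its matching prior (base rate scaled by written-only report
    accuracy); neutral conditions use the uniform prior.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    W = W if W is not None else word_feature_matrix()
    nu = condition_noise(condition, params)
    kind = condition_prior_kind(condition)
    rng = child_rng(seed, "inputs", condition)

    n = len(W.lexicon)
    priors = [
        make_prior(kind, target=w, match_base=MATCH_PRIOR_BASE,
                   report_accuracy=WRITTEN_ONLY_ACCURACY, n_words=n)
        if kind == "match"
        else make_prior("neutral", n_words=n)
        for w in range(n)
    ]
    items: list[tuple[SensoryInput, PriorVector, int]] = []
    for _ in range(reps):
        degraded = degrade_batch(W.matrix, nu, rng, W.scheme)
        for w in range(n):
            items.append(
                (
                    SensoryInput(degraded[w], word=w, noise_level=nu, condition=condition),
                    priors[w],
                    w,
                )
            )
    return items


def inputs_to_frame(
    items: Sequence[tuple[SensoryInput, PriorVector, int]],
    W: WordFeatureMatrix | None = None,
) -> pd.DataFrame:
    """Tabulate generated inputs (one row per item, 37 feature columns)."""
    W = W if W is not None else word_feature_matrix()
    cols = W.scheme.column_labels()
    records = []
    for inp, prior, target in items:
        rec = {
            "word": W.lexicon[target].orthography,
            "condition": inp.condition,
            "noise_level": inp.noise_level,
            "prior_kind": prior.kind,
        }
        rec.update(dict(zip(cols, inp.values)))
        records.append(rec)
    return pd.DataFrame(records)
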