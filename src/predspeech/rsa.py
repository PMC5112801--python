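"""Representational similarity analysis of model feature patterns.

An observed representational dissimilarity matrix (RDM) holds
1 - Pearson correlation between item-wise activity patterns; a
hypothesis RDM holds the predicted structure (0 = similar, 1 =
dissimilar, NaN/masked = excluded).  The headline read-out correlates
each condition's observed RDM with the vowel-triple hypothesis (words in
the same triple share their vowel and most other features, so their
patterns should be similar) using Spearman rank correlation over the
unmasked off-diagonal cells, Fisher-z transformed (atanh).

The simulated "voxel pattern" for a word is its iteration-1 feature
representation (sharpened features or |prediction-error features|) plus
Gaussian measurement noise of sd 2 — deliberately large relative to the
feature scale, which is why simulated correlations are small, as in
comparable neuroimaging work.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .lexicon import Lexicon, WordFeatureMatrix, default_lexicon, word_feature_matrix
from .models import ModelParams, first_iteration_features_batch
from .sensory import CONDITIONS, condition_noise, generate_condition_inputs

__all__ = [
    "RDM",
    "HYPOTHESIS_LEVELS",
    "Z_CEILING",
    "pattern_rdm",
    "hypothesis_rdm",
    "rdm_correlation",
    "simulate_rsa",
    "simulate_rsa_samples",
    "simulate_subject_rdms",
    "cross_subject_consistency",
]

HYPOTHESIS_LEVELS = ("vowel-triple", "segment", "feature")

#: Documented ceiling for Fisher-z when a rank correlation is exactly
#: +-1 (degenerate, e.g. identical subjects in the consistency score).
Z_CEILING = 15.0


@dataclass(frozen=True)
class RDM:
    """A symmetric dissimilarity matrix with an exclusion mask.

    ``mask[i, j] == True`` marks a cell excluded from comparisons (the
    diagonal always is; cross-condition cells are in multi-condition
    matrices).  For observed RDMs entries are 1 - Pearson in [0, 2];
    hypothesis RDMs are binary or graded in [0, 1].
    """

    matrix: np.ndarray
    mask: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")
        if self.mask.shape != m.shape:
            raise ValueError("mask shape must match matrix")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def unmasked_cells(self) -> np.ndarray:
        """Boolean selector of unmasked upper-triangle (i < j) cells."""
        upper = np.triu(np.ones_like(self.mask, dtype=bool), k=1)
        return upper & ~self.mask

    def values(self) -> np.ndarray:
        """Unmasked upper-triangle dissimilarities, row-major order."""
        return self.matrix[self.unmasked_cells()]

    def to_frame(self) -> pd.DataFrame:
        m = self.matrix.copy()
        m[self.mask] = np.nan  # masked cells written as empty (NaN)
        labels = self.labels if self.labels is not None else range(self.n)
        return pd.DataFrame(m, index=labels, columns=labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RDM":
        df = pd.read_csv(path, index_col=0)
        m = df.to_numpy(dtype=float)
        mask = np.isnan(m)
        np.fill_diagonal(mask, True)
        m = np.nan_to_num(m)
        return cls(matrix=m, mask=mask, labels=tuple(map(str, df.index)))


def pattern_rdm(
    patterns: np.ndarray,
    mask: np.ndarray | None = None,
    labels: tuple[str, ...] | None = None,
) -> RDM:
    """1 - Pearson correlation RDM over row-wise patterns.

    Raises :class:`ValueError`, naming the item, if any pattern has zero
    variance (its correlations are undefined).
    """
    p = np.atleast_2d(np.asarray(patterns, dtype=float))
    if p.shape[0] < 2:
        raise ValueError("need at least 2 patterns")
    sd = p.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        name = labels[bad] if labels is not None else str(bad)
        raise ValueError(f"pattern {name!r} has zero variance")
    corr = np.corrcoef(p)
    m = 1.0 - corr
    if mask is None:
        mask = np.zeros_like(m, dtype=bool)
    mask = mask.copy()
    np.fill_diagonal(mask, True)
    return RDM(matrix=m, mask=mask, labels=labels)


def _segment_shared(a, b) -> int:
    return sum(x == y for x, y in ((a.c1, b.c1), (a.v, b.v), (a.c2, b.c2)))


def hypothesis_rdm(
    lexicon: Lexicon | None = None,
    level: str = "vowel-triple",
    n_conditions: int = 1,
    W: WordFeatureMatrix | None = None,
) -> RDM:
    """Predicted dissimilarity structure over the word set.

    ``vowel-triple``: 0 for same-triple pairs, 1 otherwise (the main
    hypothesis).  ``segment``: 1 - (shared position-specific segments)/3.
    ``feature``: 1 - Pearson between clear feature rows.  With
    ``n_conditions`` > 1 the matrix is tiled block-diagonally and all
    cross-condition cells are masked, mirroring the NaN convention of
    condition-wise neuroimaging RDMs.
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    n = len(lexicon)
    if level == "vowel-triple":
        triples = lexicon.triples()
        block = (triples[:, None] != triples[None, :]).astype(float)
    elif level == "segment":
        block = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                block[i, j] = 1.0 - _segment_shared(lexicon[i], lexicon[j]) / 3.0
    elif level == "feature":
        W = W if W is not None else word_feature_matrix(lexicon=lexicon)
        block = 1.0 - np.corrcoef(W.matrix)
    else:
        raise ValueError(f"unknown hypothesis level {level!r}; expected one of {HYPOTHESIS_LEVELS}")

    total = n * n_conditions
    m = np.ones((total, total))
    mask = np.ones((total, total), dtype=bool)
    for c in range(n_conditions):
        sl = slice(c * n, (c + 1) * n)
        m[sl, sl] = block
        mask[sl, sl] = False
    np.fill_diagonal(mask, True)
    labels = tuple(
        f"{w.orthography}" if n_conditions == 1 else f"cond{c + 1}:{w.orthography}"
        for c in range(n_conditions)
        for w in lexicon
    )
    return RDM(matrix=m, mask=mask, labels=labels)


def rdm_correlation(observed: RDM, hypothesis: RDM) -> tuple[float, float]:
    """Spearman correlation (average ranks for ties) between the
    unmasked common cells of two RDMs, and its Fisher-z transform.

    Raises :class:`ValueError` on |r| = 1 exactly (infinite z); this
    cannot happen for continuous observed RDMs.
    """
    if observed.matrix.shape != hypothesis.matrix.shape:
        raise ValueError("RDMs must have the same shape")
    cells = observed.unmasked_cells() & hypothesis.unmasked_cells()
    if cells.sum() < 3:
        raise ValueError("need at least 3 unmasked common cells")
    r = stats.spearmanr(observed.matrix[cells], hypothesis.matrix[cells]).statistic
    if abs(r) >= 1.0:
        raise ValueError("|r| = 1: Fisher z is infinite")
    return float(r), float(np.arctanh(r))


def _condition_priors(cond: str, W: WordFeatureMatrix) -> np.ndarray:
    from .lexicon import MATCH_PRIOR_BASE, WRITTEN_ONLY_ACCURACY, make_prior

    n = len(W.lexicon)
    if cond.startswith("match"):
        return np.stack(
            [
                make_prior("match", w, MATCH_PRIOR_BASE, WRITTEN_ONLY_ACCURACY, n).values
                for w in range(n)
            ]
        )
    return np.full((n, n), 1.0 / n)


def simulate_rsa_samples(
    model: str,
    params: ModelParams,
    reps: int,
    seed: int,
    measurement_noise_sd: float = 2.0,
    W: WordFeatureMatrix | None = None,
    word_space: bool = False,
) -> dict[str, np.ndarray]:
    """Per-replication Fisher-z samples for each condition.

    One replication draws one degraded input per word, takes the
    iteration-1 feature representations plus measurement noise as the 24
    patterns, builds their 1 - Pearson RDM, and correlates it with the
    vowel-triple hypothesis.  With ``word_space`` the noisy feature
    patterns are projected through W.T first (the lexical-pattern
    surrogate).

    Within a replication the four conditions share the same uniform
    degradation draws (scaled by each condition's noise level) and the
    same measurement-noise pattern — a paired, common-random-numbers
    design: each condition's marginal distribution is unchanged, but
    between-condition contrasts are estimated with far less Monte-Carlo
    error than independent streams would give.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    W = W if W is not None else word_feature_matrix()
    hyp = hypothesis_rdm(W.lexicon, "vowel-triple")
    n = len(W.lexicon)
    slices = W.scheme.block_slices()
    priors = {c: _condition_priors(c, W) for c in CONDITIONS}
    nus = {c: condition_noise(c, params) for c in CONDITIONS}

    input_rng = child_rng(seed, "rsa-degrade", model)
    noise_rng = child_rng(seed, "rsa-noise", model)
    out = {c: np.empty(reps) for c in CONDITIONS}
    for r in range(reps):
        # one shared uniform reallocation per (word, group), one shared
        # measurement-noise pattern; both reused across conditions
        u_norm = np.empty((n, W.scheme.total_dims))
        for sl in slices:
            u = input_rng.uniform(size=(n, sl.stop - sl.start))
            u_norm[:, sl] = u / u.sum(axis=1, keepdims=True)
        meas = (
            noise_rng.normal(0.0, measurement_noise_sd, size=(n, W.scheme.total_dims))
            if measurement_noise_sd > 0
            else 0.0
        )
        for cond in CONDITIONS:
            nu = nus[cond]
            inputs = (1.0 - nu) * W.matrix + nu * u_norm
            feats = first_iteration_features_batch(
                model, inputs, priors[cond], params, W, measurement_noise_sd=0.0
            )
            feats = feats + meas
            if word_space:
                feats = feats @ W.matrix.T
            rdm = pattern_rdm(feats)
            _, out[cond][r] = rdm_correlation(rdm, hyp)
    return out


def simulate_rsa(
    model: str,
    params: ModelParams,
    reps: int,
    seed: int,
    measurement_noise_sd: float = 2.0,
    W: WordFeatureMatrix | None = None,
    word_space: bool = False,
) -> dict[str, float]:
    """Mean Fisher-z per condition over ``reps`` replications."""
    samples = simulate_rsa_samples(
        model, params, reps, seed, measurement_noise_sd, W, word_space
    )
    return {c: float(z.mean()) for c, z in samples.items()}


def simulate_subject_rdms(
    model: str,
    params: ModelParams,
    reps: int,
    seed: int,
    measurement_noise_sd: float = 2.0,
    W: WordFeatureMatrix | None = None,
) -> dict[str, RDM]:
    """One simulated participant's per-condition RDMs.

    The subject's RDM per condition is the cell-wise mean of ``reps``
    single-replication RDMs, emulating averaging across that subject's
    stimulus repetitions.
    """
    W = W if W is not None else word_feature_matrix()
    n = len(W.lexicon)
    out: dict[str, RDM] = {}
    for cond in CONDITIONS:
        rng = child_rng(seed, "rsa-noise", model, cond)
        items = generate_condition_inputs(cond, params, reps, seed, W)
        inputs = np.stack([inp.values for inp, _, _ in items])
        priors = np.stack([pri.values for _, pri, _ in items])
        feats = first_iteration_features_batch(
            model, inputs, priors, params, W, measurement_noise_sd, rng
        )
        mats = [pattern_rdm(feats[r * n : (r + 1) * n]).matrix for r in range(reps)]
        mean = np.mean(mats, axis=0)
        mask = np.zeros_like(mean, dtype=bool)
        np.fill_diagonal(mask, True)
        out[cond] = RDM(matrix=mean, mask=mask, labels=tuple(W.lexicon.orthographies()))
    return out


def cross_subject_consistency(subject_rdms: list[RDM]) -> float:
    """Leave-one-out consistency of a set of subject RDMs.

    Each subject's unmasked cells are Spearman-correlated with the
    cell-wise mean of all other subjects' RDMs; the score is the mean
    Fisher-z over subjects.  Degenerate |r| = 1 correlations are capped
    at ``Z_CEILING`` instead of returning an infinite z.
    """
    if len(subject_rdms) < 2:
        raise ValueError("need at least 2 subjects")
    cells = subject_rdms[0].unmasked_cells()
    vals = np.stack([s.matrix[cells] for s in subject_rdms])
    zs = []
    for i in range(len(subject_rdms)):
        others = np.delete(vals, i, axis=0).mean(axis=0)
        r = stats.spearmanr(vals[i], others).statistic
        zs.append(Z_CEILING * np.sign(r) if abs(r) >= 1.0 else np.arctanh(r))
    return float(np.mean(zs))
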