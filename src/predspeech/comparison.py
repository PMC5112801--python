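"""Monte-Carlo likelihoods and Akaike-weight evidence ratios.

For each model, 1,000 replications per condition produce a sample of
predicted outcomes (word-report proportion, max-normalised BOLD proxy,
or RSA Fisher-z).  A fixed-bandwidth Gaussian kernel density (width 0.1
on each data type's natural scale) evaluated at the observed group mean
gives a per-condition likelihood; the joint likelihood is the product
over the four conditions.  Because both models have six free
parameters, the Akaike-weight evidence ratio reduces to the plain
likelihood ratio L_pe / L_sharpened.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitting import ObservedData
from .models import ModelParams
from .readout import simulate_condition_samples
from .rsa import simulate_rsa_samples
from .sensory import CONDITIONS

__all__ = [
    "DATA_TYPES",
    "OutcomeDistribution",
    "LikelihoodResult",
    "simulate_outcome_distribution",
    "simulate_joint_distributions",
    "likelihood_of_observed",
    "evidence_ratio",
    "compare_models",
]

DATA_TYPES = ("behaviour", "univariate", "rsa")

DEFAULT_KERNEL_WIDTH = 0.1


@dataclass(frozen=True)
class OutcomeDistribution:
    """Per-condition Monte-Carlo samples of one model's predicted outcome."""

    model: str
    data_type: str
    samples: dict[str, np.ndarray]

    def __post_init__(self):
        ns = {len(v) for v in self.samples.values()}
        if len(ns) != 1:
            raise ValueError("all conditions must have equal sample counts")

    @property
    def n_replications(self) -> int:
        return len(next(iter(self.samples.values())))


@dataclass(frozen=True)
class LikelihoodResult:
    """KDE likelihood of one observed 4-condition vector under one model."""

    per_condition: dict[str, float]
    joint: float
    kernel_width: float


def simulate_outcome_distribution(
    model: str,
    params: ModelParams,
    data_type: str,
    reps: int = 1000,
    seed: int = 0,
    W=None,
) -> OutcomeDistribution:
    """Sample a model's predicted outcome distribution per condition.

    Each replication is one pass over the 24 words.  For ``univariate``
    the four conditions' per-replication BOLD proxies are jointly
    max-normalised (each replication's largest condition becomes 1), so
    samples live on the same scale as max-normalised observed betas.
    """
    if data_type not in DATA_TYPES:
        raise ValueError(f"unknown data type {data_type!r}; expected one of {DATA_TYPES}")
    if data_type == "rsa":
        samples = simulate_rsa_samples(model, params, reps, seed, W=W)
        return OutcomeDistribution(model, data_type, samples)

    acc = {}
    proxy = {}
    for cond in CONDITIONS:
        acc[cond], proxy[cond] = simulate_condition_samples(
            model, cond, params, reps, seed, W
        )
    if data_type == "behaviour":
        return OutcomeDistribution(model, data_type, acc)
    mat = np.stack([proxy[c] for c in CONDITIONS])  # (4, reps)
    mat = mat / mat.max(axis=0, keepdims=True)
    return OutcomeDistribution(
        model, data_type, {c: mat[i] for i, c in enumerate(CONDITIONS)}
    )


def simulate_joint_distributions(
    model: str,
    params: ModelParams,
    reps: int = 1000,
    seed: int = 0,
    W=None,
) -> dict[str, OutcomeDistribution]:
    """Behaviour and univariate outcome distributions from one pass.

    Both read-outs derive from the same settling runs, so sampling them
    together halves the simulation cost relative to two calls of
    :func:`simulate_outcome_distribution`.
    """
    acc = {}
    proxy = {}
    for cond in CONDITIONS:
        acc[cond], proxy[cond] = simulate_condition_samples(
            model, cond, params, reps, seed, W
        )
    mat = np.stack([proxy[c] for c in CONDITIONS])
    mat = mat / mat.max(axis=0, keepdims=True)
    return {
        "behaviour": OutcomeDistribution(model, "behaviour", acc),
        "univariate": OutcomeDistribution(
            model, "univariate", {c: mat[i] for i, c in enumerate(CONDITIONS)}
        ),
    }


def likelihood_of_observed(
    distribution: OutcomeDistribution,
    observed,
    width: float = DEFAULT_KERNEL_WIDTH,
) -> LikelihoodResult:
    """Gaussian-kernel density of the observed values under the samples.

    The per-condition density is the mean of Gaussian kernels of fixed
    bandwidth ``width`` centred on the Monte-Carlo samples, evaluated at
    the observed value; the joint likelihood is the product over the
    four conditions.
    """
    if width <= 0:
        raise ValueError("kernel width must be > 0")
    if isinstance(observed, dict):
        obs = {c: float(observed[c]) for c in CONDITIONS}
    else:
        arr = np.asarray(observed, dtype=float)
        if arr.shape != (4,):
            raise ValueError("expected 4 observed values in order " + str(CONDITIONS))
        obs = dict(zip(CONDITIONS, arr))
    per: dict[str, float] = {}
    for cond in CONDITIONS:
        s = distribution.samples[cond]
        if len(s) < 2:
            raise ValueError("need at least 2 samples per condition")
        z = (obs[cond] - s) / width
        per[cond] = float(np.mean(np.exp(-0.5 * z**2) / (width * math.sqrt(2 * math.pi))))
    joint = float(np.prod(list(per.values())))
    return LikelihoodResult(per_condition=per, joint=joint, kernel_width=width)


def evidence_ratio(likelihood_pe: float, likelihood_sharpened: float) -> float:
    """Akaike-weight evidence ratio w_PE / w_Sharpened.

    With equal parameter counts this is the likelihood ratio.  Returns
    ``math.inf`` as a documented sentinel when the Sharpened likelihood
    is exactly 0 while the Prediction Error likelihood is positive.
    """
    if likelihood_pe < 0 or likelihood_sharpened < 0:
        raise ValueError("likelihoods must be nonnegative")
    if likelihood_pe == 0 and likelihood_sharpened == 0:
        raise ValueError("both likelihoods are 0: evidence ratio undefined")
    if likelihood_sharpened == 0:
        return math.inf
    return likelihood_pe / likelihood_sharpened


def compare_models(
    observed: ObservedData,
    params_pe: ModelParams,
    params_sharpened: ModelParams,
    data_type: str = "behaviour",
    reps: int = 1000,
    width: float = DEFAULT_KERNEL_WIDTH,
    seed: int = 0,
    W=None,
) -> dict:
    """End-to-end model comparison on one data type.

    Returns per-model likelihood results and the evidence ratio
    w_PE / w_Sharpened.
    """
    obs = {
        "behaviour": observed.behaviour,
        "univariate": observed.univariate,
        "rsa": observed.rsa,
    }[data_type]
    if obs is None:
        raise ValueError(f"observed data has no {data_type!r} values")
    dists = {
        "pe": simulate_outcome_distribution(
            "pe", params_pe, data_type, reps, seed, W
        ),
        "sharpened": simulate_outcome_distribution(
            "sharpened", params_sharpened, data_type, reps, seed, W
        ),
    }
    likes = {m: likelihood_of_observed(d, obs, width) for m, d in dists.items()}
    return {
        "data_type": data_type,
        "likelihoods": likes,
        "evidence_ratio": evidence_ratio(
            likes["pe"].joint, likes["sharpened"].joint
        ),
    }
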