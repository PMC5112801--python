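"""Synthetic group-level observations for end-to-end validation.

Generates the kind of data the fitting and model-comparison stages
consume — behavioural proportions, max-normalised univariate responses
and RSA Fisher-z values for the four conditions — from a chosen
generating model, so parameter recovery and model-recovery checks can
run without any external measurements.

Each simulated participant runs the full simulation pipeline with a
subject-specific random stream and receives i.i.d. Gaussian
between-subject jitter on every summary statistic (the settling models
themselves have no subject-level parameters, so a simple additive noise
model on summaries is the appropriate minimal emulation).  Defaults
mirror the study: 21 participants and 6 stimulus repetitions per word
and condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import child_rng
from .fitting import ObservedData
from .models import ModelParams
from .readout import simulate_study
from .rsa import simulate_rsa
from .sensory import CONDITIONS

__all__ = ["SyntheticStudy", "generate_observed_dataset"]


@dataclass(frozen=True)
class SyntheticStudy:
    """A synthetic group dataset and the settings that generated it."""

    model: str
    params: ModelParams
    n_subjects: int
    subjects: tuple[ObservedData, ...]
    group: ObservedData
    seed: int


def generate_observed_dataset(
    model: str,
    params: ModelParams,
    n_subjects: int = 21,
    reps_per_subject: int = 6,
    subject_noise_sd: float = 0.05,
    seed: int = 0,
    include_rsa: bool = True,
    W=None,
) -> SyntheticStudy:
    """Simulate a group study and summarise it as observed data.

    Per subject: ``reps_per_subject`` replications of each condition
    give behavioural accuracy and the BOLD proxy, and the same number
    of RSA replications give per-condition Fisher-z values; each
    summary then receives N(0, subject_noise_sd) jitter.  Univariate
    values are max-normalised within subject (and the group mean
    re-normalised, preserving the convention that the largest condition
    equals 1).  Group values are arithmetic means over subjects, with
    behaviour clipped to [0, 1].
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    subjects = []
    for s in range(n_subjects):
        sub_seed = int(child_rng(seed, "subject", s).integers(2**31 - 1))
        jitter = child_rng(seed, "jitter", s)
        outcomes = simulate_study(model, params, reps_per_subject, sub_seed, W)
        acc = np.array([outcomes[c].accuracy for c in CONDITIONS])
        proxy = np.array([outcomes[c].bold_proxy for c in CONDITIONS])
        if subject_noise_sd > 0:
            acc = acc + jitter.normal(0, subject_noise_sd, 4)
            proxy = proxy + jitter.normal(0, subject_noise_sd, 4)
        acc = np.clip(acc, 0.0, 1.0)
        proxy = np.clip(proxy, 1e-6, None)
        proxy = proxy / proxy.max()
        rsa = None
        if include_rsa:
            z = simulate_rsa(model, params, reps_per_subject, sub_seed, W=W)
            rsa = np.array([z[c] for c in CONDITIONS])
            if subject_noise_sd > 0:
                rsa = rsa + jitter.normal(0, subject_noise_sd, 4)
        subjects.append(ObservedData(behaviour=acc, univariate=proxy, rsa=rsa))

    beh = np.mean([s.behaviour for s in subjects], axis=0)
    uni = np.mean([s.univariate for s in subjects], axis=0)
    uni = uni / uni.max()
    rsa = (
        np.mean([s.rsa for s in subjects], axis=0) if include_rsa else None
    )
    group = ObservedData(behaviour=beh, univariate=uni, rsa=rsa)
    return SyntheticStudy(
        model=model,
        params=params,
        n_subjects=n_subjects,
        subjects=tuple(subjects),
        group=group,
        seed=seed,
    )
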