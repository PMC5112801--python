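# Methods

## Overview

`predspeech` simulates how prior knowledge combines with degraded speech
input during spoken-word recognition, contrasting two coding schemes:

- **Sharpened Signal (SS)** — expected features of the input are
  multiplicatively enhanced (gain modulation), so representations of
  expected speech come to resemble representations of clearer speech.
- **Prediction Error (PE)** — expected features are subtracted
  ("explained away"), so only the unexpected part of the input is
  carried forward.

Both models operate over the same representations: a 24-word CVC
lexicon arranged in 8 same-vowel triples, a 37-dimensional binary
articulatory feature space, and a 24 × 37 word–feature matrix **W**
used as connection weights in both directions.  Each model is read out
three ways — word report (behaviour), settling time (a univariate BOLD
proxy), and first-iteration feature patterns (a multivariate RSA
surrogate) — and the two models are compared by Monte-Carlo
kernel-density likelihoods and Akaike-weight evidence ratios.

## Representations

**Feature scheme.** Each consonant position contributes four groups
(place 6, manner 3, nasality 2, voicing 2 = 13 features); the vowel
contributes four (height 5, backness 2, rounding 2, length 2 = 11).
One label per group is active per segment, so every word row of **W**
holds exactly 12 ones.  The published description of the scheme counts
"three" nasality features but lists two labels; only two labels make
the block sizes, the 13-feature consonant total and the 12-per-row
count mutually consistent, so the scheme uses two.  The per-segment
label assignments shipped in `lexicon.py` are a documented
reconstruction of citation-form Southern British English (non-rhotic;
diphthongs coded by nucleus height/backness, length = long).  They are
data, not code, and can be replaced via CSV or a custom table.

**Priors.** Neutral trials use the uniform prior 1/24 ≈ 0.042.  Match
trials put p = (288/336) × 0.8214 ≈ 0.704 on the cued word — the design
base rate of matching trials, scaled by how accurately participants
report the written word alone — and spread the remainder equally.

**Degradation (vocoding surrogate).** With noise level ν, each
(position, group) block of a clear row becomes
(1 − ν)·onehot + ν·u/Σu with u ~ U(0,1)^k, so block mass stays exactly 1
and blocks remain probability distributions.  ν = 0 is clear speech;
ν = 1 leaves no information.  Noise is drawn once per trial and held
fixed over settling.  The fitted clarity parameters are printed as the
first two entries of each model's six-parameter vector; the noise
applied is their complement (ν = 1 − clarity), with the first entry
belonging to 4-channel and the second to 12-channel vocoding.  This is
the only reading under which 4-channel speech is the more degraded
input and the simulated condition ordering matches the observed
behaviour; the shipped presets are

| parameter | Sharpened | Prediction Error |
|---|---|---|
| ν (4-channel) | 0.7544 | 0.6441 |
| ν (12-channel) | 0.5906 | 0.4175 |
| update weight | 0.002022 | 0.03414 |
| stopping criterion | 2.198 | 0.407 |
| temperature | 2.556 | 1.327 |
| behavioural noise | 0.01057 | 0.00281 |

## Settling dynamics

Both models run at most 500 iterations; standard deviations use the
population formula.

**Sharpened Signal.** Expectations are fixed at the trial prior
(expected = prior·W).  Per iteration the current input is sharpened,
renormalised per group, folded back into the input (again renormalised),
and projected to the lexicon:

    sharpened  = groupnorm(input_t ⊙ (1 + expected))
    input_t+1  = groupnorm(input_t + update_weight · sharpened)
    word       = input_t+1 · Wᵀ
    stop when max(word) − (mean(word) + sd(word)) > criterion

The accumulating input is the mechanism by which the prior's small
per-iteration gain bias compounds into a behavioural advantage.  Two
alternatives were examined and rejected because they erase all
prior-knowledge effects (match ≈ neutral in both accuracy and settling
time, contrary to the fitted results): keeping the input fixed and
feeding the normalised word vector back as the next prior, and updating
the prior alongside the accumulating input.  Both remain available via
`ModelParams.sharpened_update_prior` for comparison.

**Prediction Error.** The input is fixed; the lexical state evolves:

    pe        = input − prior_t · W
    pe_word   = pe · Wᵀ
    precision = sd(prior_t)/sum(prior_t) + sd(input)/sum(input)
    prior_t+1 = prior_t + update_weight · precision · pe_word
    stop when Σ|pe_word| < criterion

The evolving state is carried raw (not renormalised): the precision
term divides by its sum, which presupposes an unnormalised vector.  A
`pe_normalize_feedback` switch provides the alternative.  Precision is
recomputed every iteration from the current lexical state.  A state
summing to ~0 raises an error (degenerate precision denominator).

## Read-outs

**Behaviour.** The final word vector passes through a softmax
p ∝ exp(x/τ) (larger temperature = flatter); Gaussian noise of sd
`behavioural_noise` is added to the probabilities and the noisy argmax
is the reported word.

**Univariate BOLD proxy.** Mean settling iterations divided by the cap
(500) — longer settling stands in for more neural processing and a
larger hemodynamic response.

**Multivariate (RSA).** The iteration-1 feature representation — the
sharpened feature vector, or |prediction-error features| (sign removed
before noise) — plus i.i.d. Gaussian measurement noise of sd 2 serves
as the simulated voxel pattern.  Per replication and condition, the 24
patterns give a 1 − Pearson RDM, which is Spearman-correlated (average
ranks; ties are inherent to binary hypotheses) with the vowel-triple
hypothesis RDM (0 within triples, 1 across, diagonal and
cross-condition cells excluded) and Fisher-z transformed.  Measurement
noise dwarfs the feature-scale signal by design, so mean z values are
small (|z| < 0.05), comparable to neuroimaging RSA effect sizes.

Within a replication the four conditions share the same uniform
degradation draws and measurement-noise pattern (common random
numbers).  Each condition's marginal distribution is unchanged, but
condition contrasts — the quantities of interest — are estimated with
roughly twenty-fold less Monte-Carlo error, which is what makes the
crossover interaction resolvable at 1,000 replications.

Cross-subject consistency is leave-one-out: each simulated subject's
RDM cells are Spearman-correlated with the cell-wise mean of the other
subjects', and scores are averaged on the Fisher-z scale.  The exact
published formula is not printed; this is the package's documented
choice.  Degenerate |r| = 1 cases are capped at z = 15.

## Fitting

Six parameters are fit per model by minimising the summed squared error
between simulated and observed group means: four behavioural
proportions plus four max-normalised univariate values (predicted
proxies are max-normalised the same way), equally weighted, averaging
10 replications per condition.  Optimisation is Nelder-Mead on a
transformed space (logit for the noise levels, log for the positive
parameters), with common random numbers across evaluations so the
stochastic objective is deterministic given the seed.  The simplex is
restarted (default twice) from the incumbent best with a fresh simplex
— without restarts Nelder-Mead reliably stalls in this sloppy
six-dimensional landscape with other parameters compensating for a
mis-set noise level.  Fitting is fixed-effects on group means.  The
shipped presets are treated as named parameter sets, not as re-derivable
fit targets (the original objective's noise realisations and starting
points are unknown).

## Model comparison

Per condition, a Gaussian kernel density with fixed bandwidth 0.1 (on
the natural scale of each data type: proportions, max-normalised
responses, Fisher-z) is centred on the Monte-Carlo samples and
evaluated at the observed value; the joint likelihood is the product
over the four conditions, and the evidence ratio is the likelihood
ratio (equal parameter counts).  A zero denominator with a positive
numerator returns `inf` as a documented sentinel.

## Synthetic observations

`generate_observed_dataset` emulates a group study: per subject, a
subject-specific stream drives the full behavioural/univariate/RSA
pipeline, and every summary receives i.i.d. Gaussian between-subject
jitter (default sd 0.05) before univariate max-normalisation.  Defaults
mirror the study design: 21 participants, 6 repetitions per word and
condition.  What this emulates — and what it does not: summaries vary
across subjects, but there is no subject-level variation in model
parameters, no trial-level serial structure, no hemodynamics and no
voxel sampling.  Passing recovery tests therefore show that the
fitting and comparison machinery works on data of the assumed form,
not that it would be robust to real fMRI artefacts.

## Problem sizes and numerical choices

Simulation sizes used by the test suite and acceptance script — 1,000
replications for outcome distributions and RSA means, 10 replications
per objective evaluation, 21 × 6 for synthetic groups — are the
package's standard operating sizes; smaller sizes appear only in
smoke-level unit tests.  Settling is vectorised across trials with an
active-row mask, so a 1,000-replication condition settles as one batch.
Group renormalisation treats an all-zero block as unnormalisable and
leaves it at zero.  Softmax subtracts the row maximum before
exponentiation.  Spearman correlations use average ranks; |r| = 1 in
`rdm_correlation` raises (it cannot occur with continuous observed
RDMs).

## Known limitations

- The acoustic stage is a surrogate: group-wise probabilistic feature
  corruption, not channel vocoding of audio; fine-grained perceptual
  confusions are out of scope.
- Both models are single-level and parallel: no hierarchy, no separate
  prediction-unit population, no segment-by-segment temporal unfolding.
- The published univariate (0.8149) and multivariate (1.898 × 10¹¹)
  evidence ratios depend on empirical values shown only in figures and
  are demonstrated qualitatively, not matched numerically.  Notably,
  an RSA-based evidence ratio of the published magnitude is not
  attainable from this pipeline's own simulated RSA values: with mean
  Fisher-z values of order 10⁻³–10⁻² and a fixed kernel bandwidth of
  0.1, the per-condition densities of the two models can differ by at
  most a few percent, bounding the joint ratio near 1 (measured ≈ 1.1;
  the same holds in the word-space pattern variant).  A ratio of 10¹¹
  requires observed values separated from one model's samples by
  several bandwidths, i.e. z values two orders of magnitude larger
  than either simulation produces under sd-2 measurement noise.
- Behavioural fits saturate near ceiling in the easiest condition
  (matching prior, 12-channel): simulated accuracy reaches ~0.94 (SS)
  to ~1.0 (PE) against an observed 0.897, the largest single
  deviation in either model's fit (~10 percentage points for PE).
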