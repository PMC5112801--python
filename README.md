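# predspeech

Computational simulations of how prior knowledge shapes the perception
of degraded speech — for cognitive neuroscientists who want to
distinguish two long-standing accounts of expectation in perception:

- **Sharpened Signal**: expected features of the sensory input are
  multiplicatively enhanced (interactive-activation style gain), so
  informative priors act like extra sensory clarity.
- **Prediction Error**: expected features are subtracted ("explained
  away"), so what is carried forward is the mismatch between input and
  expectation — the core claim of predictive coding.

Both models recognise noise-degraded spoken words from a 24-word CVC
lexicon (8 triples sharing their vowel: thing/sing/sit, bath/path/pass,
…) coded as 37 binary articulatory features, with a 24 × 37
word–feature matrix **W** as bidirectional connection weights.  A trial
presents a degraded feature vector and a lexical prior — uniform
(neutral) or concentrated on a cued word (match) — and the model
settles iteratively:

    Sharpened Signal                      Prediction Error
    e = prior · W                         e = priorₜ · W
    s = norm(xₜ ⊙ (1 + e))                pe = x − e
    xₜ₊₁ = norm(xₜ + λ·s)                 pe_w = pe · Wᵀ
    w = xₜ₊₁ · Wᵀ                         π = sd(priorₜ)/Σpriorₜ + sd(x)/Σx
    stop: max w − (mean w + sd w) > θ     priorₜ₊₁ = priorₜ + λ·π·pe_w
                                          stop: Σ|pe_w| < θ

Three read-outs connect the models to data: a softmax over the final
lexical vector simulates word report; settling iterations / 500 proxy
the univariate BOLD response; and first-iteration feature patterns
(plus sd-2 measurement noise) feed representational similarity analysis
(1 − Pearson RDMs, Spearman correlation with a same-vowel-triple
hypothesis RDM, Fisher-z).  Six parameters per model (two sensory-noise
levels, update weight, stopping criterion, softmax temperature,
behavioural noise) are fit to group condition means by Nelder-Mead on a
summed-squared-error objective, and models are compared by Monte-Carlo
kernel-density likelihoods combined into Akaike-weight evidence ratios.
A synthetic-observations generator (21 simulated participants, 6
repetitions per word and condition) closes the loop for parameter- and
model-recovery validation, and a design module reproduces the
816-trial scanning protocol.

See `docs/methods.md` for the full model description and the package's
design choices.

## Worked example

```python
from predspeech import PRESETS, simulate_study, simulate_rsa

params = PRESETS["pe_paper"]          # fitted Prediction Error preset
study = simulate_study("pe", params, reps=300, seed=5)
for cond, o in study.items():
    print(f"{cond:>10}: accuracy {o.accuracy:.3f}  "
          f"mean iterations {o.mean_iterations:.0f}")

z = simulate_rsa("pe", params, reps=1000, seed=5)
print({c: round(v, 4) for c, v in z.items()})
```

prints

```
    match4: accuracy 0.763  mean iterations 473
   match12: accuracy 0.997  mean iterations 330
  neutral4: accuracy 0.426  mean iterations 498
 neutral12: accuracy 0.845  mean iterations 459
{'match4': 0.0023, 'match12': 0.0013, 'neutral4': 0.0033, 'neutral12': 0.0064}
```

Matching priors and clearer (12-channel) input both raise word report
and shorten settling — accuracy tracks the observed group means
(79.2 / 89.7 / 43.5 / 83.5 %).  The RSA values show the Prediction
Error model's signature crossover: more sensory detail *increases*
pattern information under neutral priors (0.0064 > 0.0033) but
*decreases* it under matching priors (0.0023 > 0.0013), because
expected input is explained away most completely when it is clearest.
The Sharpened Signal model instead predicts maximal similarity for
matching, 12-channel speech.

A command-line interface wraps the same functions:

```bash
predspeech simulate --model pe --reps 100 --seed 1
predspeech design --seed 1 --out design.csv
predspeech synth --model pe --out observed.yaml
predspeech fit --model pe --observed observed.yaml
predspeech compare --observed observed.yaml --data-type behaviour
```

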