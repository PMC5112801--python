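"""Trial-level experimental design generator.

Reconstructs the scanning protocol's trial table: 6 runs of 136 trials
(816 total).  Per run, every word appears once in each of match/neutral
crossed with 4-/12-channel vocoding (96 spoken trials) and once written
only (24), plus 8 partial-mismatch and 8 total-mismatch trials (96
mismatch trials overall, 11.8%).  One sixth of all trials (136) are
catch trials requiring overt report.  Trial durations partition each
run into 76 x 3 s (no null event), 45 x 6 s and 15 x 9 s, giving
633 s = 211 TRs per run at TR = 3 s.

Summary counts are invariant across seeds; only orderings, mismatch
pairings, catch placement and null-event positions are randomised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import child_rng
from .lexicon import Lexicon, default_lexicon

__all__ = [
    "N_RUNS",
    "TRIALS_PER_RUN",
    "TR_SECONDS",
    "build_design",
    "summarize_design",
]

N_RUNS = 6
TRIALS_PER_RUN = 136
TR_SECONDS = 3
_DURATIONS = {3: 76, 6: 45, 9: 15}  # seconds -> trials per run

SPOKEN_CONDITIONS = ("match", "neutral")
VOCODING_LEVELS = (4, 12)


def _mismatch_pairings(lexicon: Lexicon, rng: np.random.Generator) -> list[dict]:
    """Partial (same-triple) and total (cross-triple) written/spoken pairs.

    Each spoken word occurs once per vocoding level per mismatch type;
    partial cues use each triple-mate once across the two levels, total
    cues are a cross-triple permutation per level, so no written/spoken
    pair repeats at the word level.
    """
    n = len(lexicon)
    triples = lexicon.triples()
    words = lexicon.orthographies()
    trials: list[dict] = []

    # partial mismatch: written cue from the same triple
    for w in range(n):
        mates = [i for i in range(n) if triples[i] == triples[w] and i != w]
        order = rng.permutation(2)
        for lvl, mate in zip(VOCODING_LEVELS, (mates[order[0]], mates[order[1]])):
            trials.append(
                {
                    "condition": "partial_mismatch",
                    "vocoding": lvl,
                    "written": words[mate].upper(),
                    "spoken": words[w],
                }
            )

    # total mismatch: written cue from a different triple, one
    # permutation per level with no same-triple assignment
    for lvl in VOCODING_LEVELS:
        while True:
            perm = rng.permutation(n)
            if np.all(triples[perm] != triples):
                break
        for w in range(n):
            trials.append(
                {
                    "condition": "total_mismatch",
                    "vocoding": lvl,
                    "written": words[perm[w]].upper(),
                    "spoken": words[w],
                }
            )
    return trials


def build_design(seed: int = 0, lexicon: Lexicon | None = None) -> pd.DataFrame:
    """Generate the full randomized 816-trial design table.

    Columns: run, trial (position within run), condition, vocoding
    (4/12 or 0 for written-only), written token, spoken word (empty for
    written-only), catch flag, duration_s.
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    rng = child_rng(seed, "design")
    words = lexicon.orthographies()

    mismatch = _mismatch_pairings(lexicon, rng)
    rng.shuffle(mismatch)
    per_run_mismatch = len(mismatch) // N_RUNS

    rows: list[dict] = []
    for run in range(1, N_RUNS + 1):
        trials: list[dict] = []
        for w in words:
            for lvl in VOCODING_LEVELS:
                trials.append({"condition": "match", "vocoding": lvl, "written": w.upper(), "spoken": w})
                trials.append({"condition": "neutral", "vocoding": lvl, "written": "XXXX", "spoken": w})
            trials.append({"condition": "written_only", "vocoding": 0, "written": w.upper(), "spoken": ""})
        lo = (run - 1) * per_run_mismatch
        trials.extend(mismatch[lo : lo + per_run_mismatch])
        assert len(trials) == TRIALS_PER_RUN

        durations = np.repeat(
            list(_DURATIONS.keys()), list(_DURATIONS.values())
        )
        rng.shuffle(durations)
        order = rng.permutation(len(trials))
        for pos, (i, dur) in enumerate(zip(order, durations), start=1):
            t = dict(trials[i])
            t.update({"run": run, "trial": pos, "duration_s": int(dur), "catch": False})
            rows.append(t)

    # catch trials: exactly 1/6 of all trials, uniform over the study
    n_total = len(rows)
    catch_idx = rng.choice(n_total, size=n_total // 6, replace=False)
    for i in catch_idx:
        rows[i]["catch"] = True

    df = pd.DataFrame(rows)
    return df[["run", "trial", "condition", "vocoding", "written", "spoken", "catch", "duration_s"]]


def summarize_design(design: pd.DataFrame) -> dict:
    """Headline counts of a design table (seed-invariant)."""
    spoken = design[design.condition.isin(SPOKEN_CONDITIONS)]
    mismatch = design[design.condition.str.endswith("mismatch")]
    per_run_trs = (
        design.groupby("run")["duration_s"].sum() // TR_SECONDS
    )
    return {
        "total_trials": int(len(design)),
        "catch_trials": int(design.catch.sum()),
        "match_neutral_spoken_trials": int(len(spoken)),
        "written_only_trials": int((design.condition == "written_only").sum()),
        "mismatch_trials": int(len(mismatch)),
        "mismatch_percent": round(100 * len(mismatch) / len(design), 1),
        "trs_per_run": int(per_run_trs.iloc[0]) if per_run_trs.nunique() == 1 else None,
        "runs": int(design.run.nunique()),
        "trials_per_run": int(len(design) / design.run.nunique()),
    }
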