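"""Cognitive outcome scores.

Reasoning tests (number series, verbal analogies) arrive already scored on a
T-score metric (mean 50, SD 10) and are simply carried through.  The
Stop-and-Go Switch task — a task-switching/inhibitory-control measure — is
scored here from trial-level latencies: respondents with fewer than 70%
correct trials are excluded as invalid; otherwise the score is the negated
average of the median correct-trial latencies for switch and nonswitch
trials of the mixed condition (negation makes higher = better; the baseline
conditions measure simple choice RT and are ignored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StopGoResult", "score_stop_go"]

MIXED = "mixed"


@dataclass
class StopGoResult:
    scores: pd.DataFrame      # person_id, test_name, score
    excluded: pd.DataFrame    # person_id, reason


def score_stop_go(
    trials: pd.DataFrame,
    min_correct: float = 0.70,
    gate_conditions: str = "all",
) -> StopGoResult:
    """Score the Stop-and-Go Switch task from trial-level data.

    ``trials`` columns: person_id, condition ({baseline, reverse_baseline,
    mixed}), trial_type ({switch, nonswitch}), latency_ms (> 0), correct
    (bool/0-1).  The accuracy gate is computed over all trials
    (``gate_conditions="all"``, default) or the mixed condition only
    (``"mixed"``).  Scores are in negated milliseconds.
    """
    if (trials["latency_ms"] <= 0).any():
        raise ValueError("latency_ms must be positive")
    if gate_conditions not in ("all", "mixed"):
        raise ValueError("gate_conditions must be 'all' or 'mixed'")

    rows, dropped = [], []
    for pid, g in trials.groupby("person_id", sort=True):
        gate_pool = g if gate_conditions == "all" else g[g["condition"] == MIXED]
        if len(gate_pool) == 0:
            dropped.append((pid, "no trials for accuracy gate"))
            continue
        frac = gate_pool["correct"].astype(bool).mean()
        if frac < min_correct:
            dropped.append((pid, f"accuracy {frac:.2f} below {min_correct:.2f} gate"))
            continue
        mixed = g[(g["condition"] == MIXED) & g["correct"].astype(bool)]
        med = {}
        for tt in ("switch", "nonswitch"):
            lat = mixed.loc[mixed["trial_type"] == tt, "latency_ms"]
            if len(lat) == 0:
                med = None
                dropped.append((pid, f"no correct {tt} trials in mixed condition"))
                break
            med[tt] = float(np.median(lat))
        if med is None:
            continue
        rows.append((pid, -(med["switch"] + med["nonswitch"]) / 2.0))

    scores = pd.DataFrame(rows, columns=["person_id", "score"])
    scores.insert(1, "test_name", "stop_go")
    excluded = pd.DataFrame(dropped, columns=["person_id", "reason"])
    return StopGoResult(scores=scores, excluded=excluded)
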