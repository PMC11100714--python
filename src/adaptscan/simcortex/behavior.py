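"""Behavioral trial tables: recognition accuracy per participant and task.

Three tasks mirror the study's battery: a face memory task (60 trials,
3-alternative choice), an object (novel bicycle-like exemplar) memory task
(3-alternative choice; total trials an artifact choice of 60) and a word
same/different matching task (96 trials, 2-alternative).  Correct-trial
counts are binomial draws around group x task probabilities anchored to the
reported accuracy table.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .._seeds import derive_rng
from .cohort import DEFAULT_ACCURACY, DEFAULT_TRIALS, CohortSpec, participant_records

__all__ = ["simulate_behavior", "CHANCE_LEVELS"]

#: chance accuracy per task (3-AFC faces/objects, 2-AFC words)
CHANCE_LEVELS = {"faces": 1.0 / 3.0, "objects": 1.0 / 3.0, "words": 0.5}


def simulate_behavior(
    spec: CohortSpec,
    task_params: Mapping[str, Mapping[str, float]] | None = None,
    trial_counts: Mapping[str, int] | None = None,
    seed: int | None = None,
    records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Binomial accuracy table, one row per participant x task.

    ``task_params[group][task]`` overrides the default success probabilities;
    ``spec.effect_deltas[group]["accuracy"]`` shifts them additively.
    """
    probs = {g: dict(DEFAULT_ACCURACY[g]) for g in DEFAULT_ACCURACY}
    if task_params:
        for g, tasks in task_params.items():
            probs.setdefault(g, {}).update(tasks)
    trials = dict(DEFAULT_TRIALS, **(trial_counts or {}))
    if any(n < 1 for n in trials.values()):
        raise ValueError("trial counts must be >= 1")
    if records is None:
        records = participant_records(spec)
    rng = derive_rng(spec.seed if seed is None else seed, "behavior")
    rows = []
    for rec in records.to_dict("records"):
        for task, n in trials.items():
            p = probs[rec["group"]][task] + spec.delta(rec["group"], "accuracy", task)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"accuracy probability {p} outside [0, 1]")
            k = int(rng.binomial(n, p))
            rows.append(
                {
                    "participant_id": rec["participant_id"],
                    "group": rec["group"],
                    "preserved_hemisphere": rec["preserved_hemisphere"],
                    "age": rec["age"],
                    "task": task,
                    "n_trials": n,
                    "n_correct": k,
                    "accuracy": k / n,
                }
            )
    return pd.DataFrame(rows)
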