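"""Scoring of the 10-item CES-D short form and classification of wave sequences
into five depressive-symptom states.

The five states are

    1  no symptom
    2  new symptom episode   (first wave with total score at or above the cutoff)
    3  symptom persistence   (score still at/above the cutoff at the next visit)
    4  symptom remission     (score back below the cutoff after an episode)
    5  symptom relapse       (a new episode after remission; absorbing in a
                              four-wave window)

A symptom episode is a total score >= 12 on the 10-item form (range 0-30, items
"hopeful" and "happy" reverse-scored).  The boundary score of 12 is treated as
symptomatic everywhere: the episode definition (>= 12) takes precedence over the
remission wording, so remission requires a score strictly below 12.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import DataError, ExclusionError

#: total-score cutoff defining a symptomatic wave (score >= cutoff).
SYMPTOM_CUTOFF = 12

N_ITEMS = 10
#: zero-based positions of the positively-worded items ("hopeful", "happy"),
#: scored as 3 - raw.
REVERSED_ITEMS = (4, 7)
MAX_MISSING_ITEMS = 2  # three or more missing items invalidate the wave

NO_SYMPTOM, NEW_EPISODE, PERSISTENCE, REMISSION, RELAPSE = 1, 2, 3, 4, 5
SYMPTOMATIC_STATES = frozenset({NEW_EPISODE, PERSISTENCE, RELAPSE})

#: the permissible transition paths h -> g, written "hg".
TRANSITION_PATHS = ("12", "23", "24", "34", "45")

#: outgoing paths by origin state; state 5 is absorbing.
OUT_PATHS = {1: ("12",), 2: ("23", "24"), 3: ("34",), 4: ("45",), 5: ()}


def score_cesd(items: Sequence[float | None], cutoff: int = SYMPTOM_CUTOFF) -> int | None:
    """Total CES-D score for one subject-wave, or None for an invalid wave.

    ``items`` holds the 10 raw responses in {0,1,2,3}; missing entries may be
    None or NaN.  Items 5 and 8 (1-based) contribute ``3 - raw``.  Up to two
    missing items are imputed as the rounded person-mean of the non-missing
    (post-reversal) items; three or more missing yield None.
    """
    if len(items) != N_ITEMS:
        raise DataError(f"expected {N_ITEMS} item responses, got {len(items)}")
    reversed_vals: list[float | None] = []
    n_missing = 0
    for idx, raw in enumerate(items):
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            reversed_vals.append(None)
            n_missing += 1
            continue
        value = float(raw)
        if value not in (0.0, 1.0, 2.0, 3.0):
            raise DataError(f"item {idx + 1} response {raw!r} outside {{0,1,2,3}}")
        reversed_vals.append(3.0 - value if idx in REVERSED_ITEMS else value)
    if n_missing > MAX_MISSING_ITEMS:
        return None
    observed = [v for v in reversed_vals if v is not None]
    if n_missing:
        # person-mean imputation, rounded half-up to an integer item value
        fill = math.floor(sum(observed) / len(observed) + 0.5)
        total = sum(observed) + n_missing * fill
    else:
        total = sum(observed)
    return int(total)


def states_from_symptomatic(symptomatic: Sequence[bool]) -> list[int]:
    """Map a per-wave symptomatic indicator to state labels.

    The first wave must be non-symptomatic (subjects symptomatic at baseline
    are excluded from the study).  State 5 is absorbing: once relapsed, the
    label stays 5 regardless of later scores.
    """
    if len(symptomatic) == 0:
        raise DataError("empty wave sequence")
    if symptomatic[0]:
        raise ExclusionError("subject symptomatic at baseline")
    states = [NO_SYMPTOM]
    for flag in symptomatic[1:]:
        prev = states[-1]
        if prev == NO_SYMPTOM:
            states.append(NEW_EPISODE if flag else NO_SYMPTOM)
        elif prev in (NEW_EPISODE, PERSISTENCE):
            states.append(PERSISTENCE if flag else REMISSION)
        elif prev == REMISSION:
            states.append(RELAPSE if flag else REMISSION)
        else:  # relapse, absorbing
            states.append(RELAPSE)
    return states


@dataclass
class StateSequence:
    """Ordered state labels over a subject's observed waves.

    ``events`` lists (path, wave_time) pairs, one per observed state change,
    with the event timed at the wave where the new state is first seen.
    """

    subject_id: object
    wave_times: tuple[float, ...]
    states: tuple[int, ...]
    events: tuple[tuple[str, float], ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.wave_times) != len(self.states):
            raise DataError("wave_times and states length mismatch")
        events = []
        for k in range(len(self.states) - 1):
            h, g = self.states[k], self.states[k + 1]
            if h == g:
                continue
            path = f"{h}{g}"
            if path not in TRANSITION_PATHS:
                raise DataError(f"forbidden transition {h}->{g} for subject {self.subject_id}")
            events.append((path, float(self.wave_times[k + 1])))
        self.events = tuple(events)


def classify_state_sequence(
    scores: Sequence[int],
    wave_times: Sequence[float],
    subject_id: object = 0,
    cutoff: int = SYMPTOM_CUTOFF,
) -> StateSequence:
    """Classify a subject's per-wave total scores into a StateSequence.

    Raises ExclusionError if the baseline score is symptomatic and DataError
    if any score is the invalid-wave marker (such subjects are removed
    upstream: the inclusion rule requires complete scores at every wave).
    """
    if len(scores) != len(wave_times):
        raise DataError("scores and wave_times length mismatch")
    if any(s is None for s in scores):
        raise DataError("invalid wave (>=3 missing items) in score sequence; subject must be excluded")
    flags = [s >= cutoff for s in scores]
    states = states_from_symptomatic(flags)
    return StateSequence(subject_id, tuple(float(t) for t in wave_times), tuple(states))


def classify_panel(
    panel: pd.DataFrame, cutoff: int = SYMPTOM_CUTOFF, drop_excluded: bool = True
) -> list[StateSequence]:
    """Classify a wave-level panel table into per-subject StateSequences.

    Accepts either dialect: item columns ``item_1..item_10`` (scored here) or a
    precomputed ``cesd_total`` column.  Subjects with an invalid wave or a
    symptomatic baseline are dropped when ``drop_excluded`` (mirroring the
    study's inclusion rules) or raise otherwise.
    """
    item_cols = [f"item_{j}" for j in range(1, N_ITEMS + 1)]
    has_items = all(c in panel.columns for c in item_cols)
    if not has_items and "cesd_total" not in panel.columns:
        raise DataError("panel must carry item_1..item_10 or cesd_total")
    sequences = []
    for sid, grp in panel.groupby("subject_id", sort=True):
        grp = grp.sort_values("wave_time")
        if has_items:
            scores = [score_cesd(row, cutoff=cutoff) for row in grp[item_cols].to_numpy()]
        else:
            scores = [int(s) for s in grp["cesd_total"]]
        try:
            sequences.append(
                classify_state_sequence(scores, grp["wave_time"].to_numpy(), subject_id=sid, cutoff=cutoff)
            )
        except (ExclusionError, DataError):
            if not drop_excluded:
                raise
    return sequences


def tabulate_events(sequences: Iterable[StateSequence]) -> dict[str, int]:
    """Count observed events per transition path across subjects."""
    counts: Counter[str] = Counter()
    for seq in sequences:
        counts.update(path for path, _ in seq.events)
    return {path: counts.get(path, 0) for path in TRANSITION_PATHS}


def sequences_to_frame(sequences: Iterable[StateSequence]) -> pd.DataFrame:
    """Long states table (subject_id, wave_time, state)."""
    rows = [
        (seq.subject_id, t, s)
        for seq in sequences
        for t, s in zip(seq.wave_times, seq.states)
    ]
    return pd.DataFrame(rows, columns=["subject_id", "wave_time", "state"])


def events_to_frame(sequences: Iterable[StateSequence]) -> pd.DataFrame:
    """Long events table (subject_id, path, time)."""
    rows = [(seq.subject_id, path, t) for seq in sequences for path, t in seq.events]
    return pd.DataFrame(rows, columns=["subject_id", "path", "time"])
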