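"""Interference analysis of two-class nine-item repetition trials.

Repetition trials present only two of the five classes: one shown once
and one repeated, at 32 ms ISI.  Forward interference = the single item
comes first (switch at serial position 2); backward interference = the
single item comes last (switch at 9).  The relevant analysis window is
TRs 2-7, a fixed constant for this trial geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timecourse import ProbabilityTimecourse

__all__ = [
    "RepetitionTrial",
    "TransitionTally",
    "TRANSITION_CATEGORIES",
    "REPETITION_WINDOW",
    "repetition_trial_from_timecourse",
    "event_type_probabilities",
    "classify_transitions",
    "condition_contrast",
]

#: Inclusive 1-based TR window used for all repetition-trial analyses.
REPETITION_WINDOW = (2, 7)

TRANSITION_CATEGORIES = (
    "forward",
    "backward",
    "repetition_first",
    "repetition_second",
    "outward",
    "inward",
    "outside",
    "repetition_nonseq",
)


@dataclass
class RepetitionTrial:
    """One repetition trial: its time course and the two sequence classes."""

    timecourse: ProbabilityTimecourse
    first_class: int
    second_class: int
    condition: str  # forward_interference | backward_interference | intermediate(k)
    window: tuple[int, int] = REPETITION_WINDOW
    participant_id: int | None = None

    def __post_init__(self) -> None:
        if self.first_class == self.second_class:
            raise ValueError("first and second class must differ")


def _condition_label(switch_position, n_items: int) -> str:
    sp = int(switch_position)
    if sp == 2:
        return "forward_interference"
    if sp == n_items:
        return "backward_interference"
    return f"intermediate({sp})"


def repetition_trial_from_timecourse(tc: ProbabilityTimecourse) -> RepetitionTrial:
    """Build a RepetitionTrial from a simulated repetition time course."""
    first = tc.meta.get("first_class")
    second = tc.meta.get("second_class")
    if first is None or second is None:
        raise ValueError("time course lacks repetition metadata")
    n_items = tc.speed.n_items if tc.speed is not None else 9
    return RepetitionTrial(
        tc, int(first), int(second), _condition_label(tc.meta.get("switch_position"), n_items)
    )


def event_type_probabilities(trial: RepetitionTrial, window: tuple[int, int] | None = None) -> dict:
    """Window means of first-event, second-event and non-sequence probability.

    ``non_sequence`` averages over the three classes absent from the
    trial.
    """
    lo, hi = window if window is not None else trial.window
    probs = trial.timecourse.probabilities
    if not (1 <= lo <= hi <= probs.shape[0]):
        raise ValueError("window outside the trial's TR range")
    block = probs[lo - 1 : hi]
    others = [c for c in range(probs.shape[1]) if c not in (trial.first_class, trial.second_class)]
    return {
        "first": float(block[:, trial.first_class].mean()),
        "second": float(block[:, trial.second_class].mean()),
        "non_sequence": float(block[:, others].mean()),
    }


@dataclass
class TransitionTally:
    """Counts of consecutive decoded-class transitions by category."""

    counts: dict
    n_transitions: int

    def proportions(self, exclude_repetitions: bool = False) -> dict:
        """Category proportions; optionally repetitions leave the denominator."""
        rep = ("repetition_first", "repetition_second", "repetition_nonseq")
        denom = self.n_transitions
        if exclude_repetitions:
            denom -= sum(self.counts[c] for c in rep)
        cats = [c for c in TRANSITION_CATEGORIES if not (exclude_repetitions and c in rep)]
        if denom == 0:
            return {c: np.nan for c in cats}
        return {c: self.counts[c] / denom for c in cats}


def classify_transitions(decoded_labels, trial: RepetitionTrial) -> TransitionTally:
    """Assign each consecutive decoded pair to exactly one category.

    Categories: forward (first -> second event), backward (second ->
    first), repetitions of either sequence item, outward (sequence item ->
    non-sequence item), inward (non-sequence -> sequence), outside
    (between distinct non-sequence items) and repetitions among
    non-sequence items.
    """
    labels = np.asarray(decoded_labels, dtype=int)
    if labels.size < 2:
        raise ValueError("need at least 2 TRs")
    n_classes = trial.timecourse.n_classes
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("decoded labels outside the class range")
    first, second = trial.first_class, trial.second_class
    seq = {first, second}
    counts = {c: 0 for c in TRANSITION_CATEGORIES}
    for a, b in zip(labels[:-1], labels[1:]):
        if a == first and b == second:
            cat = "forward"
        elif a == second and b == first:
            cat = "backward"
        elif a == b == first:
            cat = "repetition_first"
        elif a == b == second:
            cat = "repetition_second"
        elif a in seq and b not in seq:
            cat = "outward"
        elif a not in seq and b in seq:
            cat = "inward"
        elif a == b:
            cat = "repetition_nonseq"
        else:
            cat = "outside"
        counts[cat] += 1
    return TransitionTally(counts, int(labels.size - 1))


def condition_contrast(trials: list[RepetitionTrial]) -> pd.DataFrame:
    """Per-condition means of event-type probabilities and transition shares.

    Trials are aggregated within participant first (if participant ids
    are present), then across participants per condition.
    """
    from .seqmetrics import decoded_position  # local import avoids a cycle

    rows = []
    for tr in trials:
        probs = event_type_probabilities(tr)
        tc = tr.timecourse
        lo, hi = tr.window
        decoded = [
            int(np.argmax(tc.probabilities[i - 1]))
            for i in range(lo, min(hi, tc.n_trs) + 1)
        ]
        tally = classify_transitions(decoded, tr) if len(decoded) >= 2 else None
        row = {
            "participant": tr.participant_id if tr.participant_id is not None else 0,
            "condition": tr.condition,
            **probs,
        }
        if tally is not None:
            row.update(tally.proportions())
        rows.append(row)
    df = pd.DataFrame(rows)
    per_part = df.groupby(["participant", "condition"], sort=True).mean(numeric_only=True)
    return per_part.groupby("condition", sort=True).mean()
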