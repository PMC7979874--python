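"""The probability-time-course container shared by all metric modules.

Every analysis in this package operates on per-trial matrices of TR-wise
class probabilities (one row per TR, one column per stimulus class)
together with the mapping from classes to their true serial position in
the sequence shown on that trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import SpeedCondition

__all__ = ["ProbabilityTimecourse", "timecourses_to_frame", "timecourses_from_frame"]


@dataclass
class ProbabilityTimecourse:
    """TR x class probability matrix for one trial (or rest run).

    Attributes
    ----------
    probabilities
        Array of shape (n_trs, n_classes).  Simulated and normalized data
        have unit row sums; raw one-vs-rest classifier outputs need not.
    order
        Classes (column indices) in true serial order: ``order[k]`` is the
        class shown at serial position ``k + 1``.  A pseudo order is
        assigned for rest data.
    speed
        The trial's speed condition, if it has one.
    """

    probabilities: np.ndarray
    order: tuple = (0, 1, 2, 3, 4)
    speed: Optional[SpeedCondition] = None
    condition: str = "sequence"
    trial_id: Optional[int] = None
    run_id: Optional[int] = None
    participant_id: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 2:
            raise ValueError("probabilities must be 2-D (TR x class)")
        self.order = tuple(int(c) for c in self.order)
        if sorted(self.order) != list(range(len(self.order))):
            raise ValueError("order must be a permutation of class indices")

    @property
    def n_trs(self) -> int:
        return self.probabilities.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probabilities.shape[1]

    @property
    def positions(self) -> np.ndarray:
        """Serial position (1-based) of each class column."""
        pos = np.empty(len(self.order), dtype=int)
        for p, c in enumerate(self.order, start=1):
            pos[c] = p
        return pos

    def slice_trs(self, first_tr: int, last_tr: int) -> "ProbabilityTimecourse":
        """Inclusive 1-based TR slice."""
        if not (1 <= first_tr <= last_tr <= self.n_trs):
            raise ValueError("TR slice out of range")
        return replace(self, probabilities=self.probabilities[first_tr - 1 : last_tr])


def timecourses_to_frame(tcs: Sequence[ProbabilityTimecourse]) -> pd.DataFrame:
    """Long-format table keyed by (participant, run, trial, TR, class)."""
    rows = []
    for tc in tcs:
        for i in range(tc.n_trs):
            for c in range(tc.n_classes):
                rows.append(
                    {
                        "participant": tc.participant_id,
                        "run": tc.run_id,
                        "trial": tc.trial_id,
                        "condition": tc.condition,
                        "tr": i + 1,
                        "class": c,
                        "serial_position": tc.positions[c],
                        "isi_seconds": tc.speed.isi_seconds if tc.speed else np.nan,
                        "probability": tc.probabilities[i, c],
                    }
                )
    return pd.DataFrame(rows)


def timecourses_from_frame(frame: pd.DataFrame) -> list[ProbabilityTimecourse]:
    """Rebuild trial time courses from the long-format table."""
    tcs = []
    for (part, run, trial), g in frame.groupby(["participant", "run", "trial"], dropna=False, sort=True):
        g = g.sort_values(["tr", "class"])
        n_trs = g["tr"].nunique()
        n_cls = g["class"].nunique()
        probs = g["probability"].to_numpy().reshape(n_trs, n_cls)
        pos = g.drop_duplicates("class").sort_values("class")["serial_position"].to_numpy(dtype=int)
        order = tuple(int(c) for c in np.argsort(pos))
        isi = g["isi_seconds"].iloc[0]
        speed = SpeedCondition(float(isi)) if np.isfinite(isi) else None
        tcs.append(
            ProbabilityTimecourse(
                probs,
                order=order,
                speed=speed,
                condition=str(g["condition"].iloc[0]),
                trial_id=None if pd.isna(trial) else int(trial),
                run_id=None if pd.isna(run) else int(run),
                participant_id=None if pd.isna(part) else int(part),
            )
        )
    return tcs
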