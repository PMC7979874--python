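"""TR-wise sequentiality statistics on sequence-trial probability time courses.

All metrics quantify, within a single TR, how strongly the classifier
probabilities of the five items are ordered by their true serial position:

* slope — sign-flipped least-squares slope of probability on position
  (positive = forward ordering);
* rank correlation — Kendall's tau, sign-flipped to the same convention;
* mean step — mean successive difference of the serial positions of the
  probability-ordered items (+1 for a perfectly forward-ordered TR);
* decoded position — serial position of the most probable item.

Metrics are NaN-aware: entries masked to NaN (by item removal) are
excluded from the per-TR computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .core import PeriodWindows, SpeedCondition, compute_periods, delta_trs
from .timecourse import ProbabilityTimecourse

__all__ = [
    "SequentialityResult",
    "normalize_trialwise",
    "normalize_rows",
    "tr_slope",
    "tr_rank_corr",
    "tr_mean_step",
    "decoded_position",
    "slope_timecourse",
    "decoded_position_timecourse",
    "transition_steps",
    "early_late_transition_means",
    "period_aggregate",
    "item_removal_variant",
    "sequentiality",
]


def normalize_trialwise(tc: ProbabilityTimecourse) -> ProbabilityTimecourse:
    """Divide each class column by its sum over the trial's TRs.

    After this, every class's probability mass is comparable across TRs
    (columns sum to 1); zero columns are left untouched with a warning.
    """
    probs = tc.probabilities.copy()
    sums = np.nansum(probs, axis=0)
    zero = sums <= 0
    if zero.any():
        warnings.warn("zero-probability class column left unnormalized")
        sums = np.where(zero, 1.0, sums)
    return replace(tc, probabilities=probs / sums)


def normalize_rows(tc: ProbabilityTimecourse) -> ProbabilityTimecourse:
    """Per-TR simplex normalization (each row scaled to unit sum)."""
    probs = tc.probabilities.copy()
    sums = np.nansum(probs, axis=1, keepdims=True)
    sums[sums <= 0] = 1.0
    return replace(tc, probabilities=probs / sums)


def _row_and_positions(tc: ProbabilityTimecourse, tr: int) -> tuple[np.ndarray, np.ndarray]:
    if not 1 <= tr <= tc.n_trs:
        raise ValueError(f"TR {tr} outside 1..{tc.n_trs}")
    row = tc.probabilities[tr - 1]
    pos = tc.positions.astype(float)
    ok = np.isfinite(row)
    return row[ok], pos[ok]


def tr_slope(tc: ProbabilityTimecourse, tr: int) -> float:
    """Sign-flipped OLS slope of probability on serial position at one TR."""
    y, x = _row_and_positions(tc, tr)
    xc = x - x.mean()
    return float(-(xc @ (y - y.mean())) / (xc @ xc))


def slope_timecourse(tc: ProbabilityTimecourse) -> np.ndarray:
    """Per-TR sequentiality slopes for the whole trial (vectorized)."""
    probs = tc.probabilities
    pos = tc.positions.astype(float)
    if np.isnan(probs).any():
        return np.array([tr_slope(tc, i) for i in range(1, tc.n_trs + 1)])
    xc = pos - pos.mean()
    yc = probs - probs.mean(axis=1, keepdims=True)
    return -(yc @ xc) / (xc @ xc)


def tr_rank_corr(tc: ProbabilityTimecourse, tr: int) -> float:
    """Sign-flipped Kendall's tau between probability and serial position."""
    y, x = _row_and_positions(tc, tr)
    tau = sps.kendalltau(x, y).statistic
    return float(-tau)


def tr_mean_step(tc: ProbabilityTimecourse, tr: int) -> float:
    """Mean step of probability-ordered events within one TR.

    Items are sorted by descending probability (ties broken by lower class
    index); the mean of the successive differences of their serial
    positions is +1 for a perfectly forward-ordered TR and -1 for a
    perfectly backward-ordered one.
    """
    y, x = _row_and_positions(tc, tr)
    ordering = np.argsort(-y, kind="stable")
    return float(np.mean(np.diff(x[ordering])))


def decoded_position(tc: ProbabilityTimecourse, tr: int) -> int:
    """Serial position of the most probable class (ties: lowest class index)."""
    if not 1 <= tr <= tc.n_trs:
        raise ValueError(f"TR {tr} outside 1..{tc.n_trs}")
    row = np.where(np.isfinite(tc.probabilities[tr - 1]), tc.probabilities[tr - 1], -np.inf)
    return int(tc.positions[int(np.argmax(row))])


def decoded_position_timecourse(tc: ProbabilityTimecourse) -> np.ndarray:
    return np.array([decoded_position(tc, i) for i in range(1, tc.n_trs + 1)])


def transition_steps(positions) -> np.ndarray:
    """Step sizes between consecutively decoded serial positions.

    Decoding position 2 then 4 is a forward step of +2; 3 then 2 is a
    backward step of -1.
    """
    positions = np.asarray(positions)
    if positions.size < 2:
        raise ValueError("need at least 2 TRs")
    return np.diff(positions)


#: TR pairs over which early/late forward/backward step means are taken,
#: keyed by ISI (ms).  A pair (i, j) is the transition from TR i to TR j.
_TRANSITION_SETS = {
    isi: {
        "early_forward": [(2, 3)],
        "late_forward": [(3, 4)],
        "early_backward": [(5, 6)],
        "late_backward": [(6, 7)],
    }
    for isi in (32, 64, 128)
}
_TRANSITION_SETS[512] = {
    "early_forward": [(2, 3)],
    "late_forward": [(4, 5)],
    "early_backward": [(6, 7)],
    "late_backward": [(8, 9)],
}
_TRANSITION_SETS[2048] = {
    "early_forward": [(2, 3), (3, 4)],
    "late_forward": [(5, 6), (6, 7)],
    "early_backward": [(8, 9), (9, 10)],
    "late_backward": [(11, 12), (12, 13)],
}


def early_late_transition_means(steps, speed: SpeedCondition) -> dict:
    """Mean step size in the early/late halves of the two periods.

    The TR pairs entering each mean are speed-specific literals (e.g. at
    32-128 ms: 2->3 early forward, 3->4 late forward, 5->6 early backward,
    6->7 late backward; at 2048 ms each phase spans two transitions).
    ``steps[i-1]`` must be the transition from TR i to TR i+1.
    """
    steps = np.asarray(steps, dtype=float)
    isi_ms = round(speed.isi_seconds * 1000)
    if isi_ms not in _TRANSITION_SETS:
        raise ValueError(f"no transition definition for ISI {isi_ms} ms")
    out = {}
    for phase, pairs in _TRANSITION_SETS[isi_ms].items():
        idx = [a - 1 for a, _ in pairs]
        if max(idx) >= steps.size:
            raise ValueError(f"step series too short for phase {phase!r}")
        out[phase] = float(steps[idx].mean())
    return out


def period_aggregate(values, windows: PeriodWindows) -> tuple[float, float]:
    """Means of a per-TR metric over the forward and backward windows."""
    values = np.asarray(values, dtype=float)
    if windows.backward_end > values.size:
        raise ValueError("metric series shorter than the backward window")
    fwd = values[windows.forward_start - 1 : windows.forward_end].mean()
    bwd = values[windows.backward_start - 1 : windows.backward_end].mean()
    return float(fwd), float(bwd)


def item_removal_variant(tc: ProbabilityTimecourse, mode: str) -> ProbabilityTimecourse:
    """Control analyses that remove one item's probability.

    mode="drop_max_per_tr"
        Mask each TR's most probable item (NaN) and renormalize the rest
        of the row.
    mode="drop_first_item" / "drop_last_item"
        Drop the class at serial position 1 (or n) entirely, renormalize
        rows, and shorten the trial's speed condition by one item so that
        downstream period windows use the reduced span.
    """
    probs = tc.probabilities.copy()
    if mode == "drop_max_per_tr":
        for i in range(probs.shape[0]):
            row = np.where(np.isfinite(probs[i]), probs[i], -np.inf)
            probs[i, int(np.argmax(row))] = np.nan
        sums = np.nansum(probs, axis=1, keepdims=True)
        sums[sums <= 0] = 1.0
        return replace(tc, probabilities=probs / sums)
    if mode in ("drop_first_item", "drop_last_item"):
        drop_cls = tc.order[0] if mode == "drop_first_item" else tc.order[-1]
        keep = [c for c in range(tc.n_classes) if c != drop_cls]
        probs = probs[:, keep]
        sums = np.nansum(probs, axis=1, keepdims=True)
        sums[sums <= 0] = 1.0
        new_order = tuple(keep.index(c) for c in tc.order if c != drop_cls)
        new_speed = None
        if tc.speed is not None:
            new_speed = SpeedCondition(
                tc.speed.isi_seconds, tc.speed.stim_duration_seconds, tc.speed.n_items - 1
            )
        return replace(tc, probabilities=probs / sums, order=new_order, speed=new_speed)
    raise ValueError(f"unknown mode: {mode!r}")


@dataclass
class SequentialityResult:
    """Per-TR sequentiality metrics and their period means for one trial."""

    slopes: np.ndarray
    rank_corrs: np.ndarray
    mean_steps: np.ndarray
    decoded_positions: np.ndarray
    windows: PeriodWindows
    forward_mean_slope: float
    backward_mean_slope: float


def sequentiality(
    tc: ProbabilityTimecourse,
    wavelength_trs: float,
    onset_delay_trs: float,
    normalize: bool = True,
) -> SequentialityResult:
    """Full per-trial sequentiality profile with speed-adjusted windows."""
    if tc.speed is None:
        raise ValueError("time course has no speed condition")
    work = normalize_trialwise(tc) if normalize else tc
    slopes = slope_timecourse(work)
    taus = np.array([tr_rank_corr(work, i) for i in range(1, work.n_trs + 1)])
    steps = np.array([tr_mean_step(work, i) for i in range(1, work.n_trs + 1)])
    decoded = decoded_position_timecourse(work)
    windows = compute_periods(wavelength_trs, onset_delay_trs, delta_trs(tc.speed), tc.n_trs)
    fwd, bwd = period_aggregate(slopes, windows)
    return SequentialityResult(slopes, taus, steps, decoded, windows, fwd, bwd)
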