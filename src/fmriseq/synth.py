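"""Synthetic trial schedules and data at probability and voxel tier.

Schedules reproduce the counterbalancing structure of the task: slow
trials cover all 120 orderings of the five images with a 20% upside-down
cover task; sequence trials show 15 orders (each class first and last in
exactly 3) at five ISI levels; repetition trials present two classes over
nine (or sixteen) items with the switch position swept from 2 to 9.

The data generators forward-simulate the flattened-sine response model:
every stimulus event contributes one shifted single-event response to its
class, and per-TR class probabilities are the normalized contributions
plus optional noise.  The rest generator is a synthetic stand-in for real
resting-state decoding output (which the model does not describe): an
AR(1) logistic-normal process on the probability simplex whose low
"concentration" mimics the wild single-class fluctuations seen in real
rest decoding.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AcquisitionParams, ResponseParams, SpeedCondition, eval_response, DEFAULT_ISIS_MS
from .timecourse import ProbabilityTimecourse

__all__ = [
    "VoxelPatternSpec",
    "BlendSpec",
    "VoxelRun",
    "InsertionResult",
    "make_slow_schedule",
    "make_sequence_schedule",
    "make_repetition_schedule",
    "simulate_probabilities",
    "simulate_voxels",
    "simulate_rest",
    "insert_events",
    "truncated_poisson",
]

N_CLASSES = 5
SLOW_STIM_SECONDS = 0.5
FAST_STIM_SECONDS = 0.1
#: TRs blended into rest per inserted sequence event (the relevant period).
INSERT_LEN_TRS = 12

SCHEDULE_COLUMNS = [
    "trial_id",
    "condition",
    "run_id",
    "onset",
    "duration",
    "item_class",
    "serial_position",
    "orientation",
    "isi_seconds",
    "target_position",
]


def truncated_poisson(rng: np.random.Generator, lam: float, low: int, high: int, size: int) -> np.ndarray:
    """Poisson(lam) samples truncated (by rejection) to the closed range [low, high]."""
    out = np.empty(size, dtype=int)
    n = 0
    while n < size:
        draw = rng.poisson(lam, size=max(size - n, 8))
        keep = draw[(draw >= low) & (draw <= high)]
        take = min(keep.size, size - n)
        out[n : n + take] = keep[:take]
        n += take
    return out


def _truncated_exponential_iti(rng: np.random.Generator, size: int, mean: float = 2.5, low: float = 1.0) -> np.ndarray:
    # X = low + Exp(mean - low) has mean `mean` and lower limit `low`.
    return low + rng.exponential(mean - low, size=size)


def make_slow_schedule(seed: int = 0, n_runs: int = 8) -> pd.DataFrame:
    """Schedule of 600 single-image (slow) trials in 120 sets of five.

    Every one of the 120 order permutations of the five classes appears
    exactly once; 20% of events (24 per class) are shown upside-down as
    oddball targets.  Inter-trial intervals are drawn from a truncated
    exponential (mean 2.5 s, lower limit 1 s).
    """
    rng = np.random.default_rng(seed)
    perms = list(itertools.permutations(range(N_CLASSES)))
    rng.shuffle(perms)

    # Exactly 24 oddballs per class: pick 24 of each class's 120 events.
    occurrence = {c: 0 for c in range(N_CLASSES)}
    odd_picks = {c: set(rng.choice(120, size=24, replace=False)) for c in range(N_CLASSES)}

    rows = []
    sets_per_run = len(perms) // n_runs
    for set_id, perm in enumerate(perms):
        run_id = min(set_id // sets_per_run, n_runs - 1)
        for pos, cls in enumerate(perm, start=1):
            upside_down = occurrence[cls] in odd_picks[cls]
            occurrence[cls] += 1
            rows.append(
                {
                    "trial_id": set_id,
                    "condition": "slow",
                    "run_id": run_id,
                    "onset": np.nan,
                    "duration": SLOW_STIM_SECONDS,
                    "item_class": cls,
                    "serial_position": pos,
                    "orientation": "upside_down" if upside_down else "upright",
                    "isi_seconds": np.nan,
                    "target_position": np.nan,
                }
            )
    df = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)

    # Run-relative onsets: stimulus duration plus a truncated-exponential ITI.
    onsets = np.empty(len(df))
    for run_id, idx in df.groupby("run_id").groups.items():
        itis = _truncated_exponential_iti(rng, len(idx))
        t = 3.85
        for j, i in enumerate(idx):
            onsets[i] = t
            t += SLOW_STIM_SECONDS + itis[j]
    df["onset"] = onsets
    return df


def _balanced_orders(rng: np.random.Generator) -> list[tuple[int, ...]]:
    """15 orderings with each class first in exactly 3 and last in exactly 3."""
    labels = rng.permutation(N_CLASSES)
    orders = []
    for i in range(N_CLASSES):
        for k in (1, 2, 3):
            first, last = int(labels[i]), int(labels[(i + k) % N_CLASSES])
            middle = [int(labels[j]) for j in range(N_CLASSES) if labels[j] not in (first, last)]
            rng.shuffle(middle)
            orders.append((first, *middle, last))
    rng.shuffle(orders)
    return orders


def make_sequence_schedule(seed: int = 0, n_runs: int = 8, isis_ms=DEFAULT_ISIS_MS) -> pd.DataFrame:
    """Schedule of 75 five-item sequence trials (15 orders x 5 speeds).

    Target serial positions are drawn from a Poisson(1.9) truncated to
    [1, 5], biasing targets toward later positions.  Trials are laid on a
    16-TR (20 s) grid so that the 13-TR analysis windows never overlap.
    """
    rng = np.random.default_rng(seed)
    orders = _balanced_orders(rng)
    trials = [(order, isi) for order in orders for isi in isis_ms]
    rng.shuffle(trials)
    targets = truncated_poisson(rng, 1.9, 1, N_CLASSES, len(trials))

    rows = []
    per_run = math.ceil(len(trials) / n_runs)
    trial_stride = 16 * 1.25  # one trial per 16 TRs
    for tid, (order, isi_ms) in enumerate(trials):
        run_id = tid // per_run
        trial_onset = 3.85 + (tid % per_run) * trial_stride
        isi = isi_ms / 1000.0
        for pos, cls in enumerate(order, start=1):
            rows.append(
                {
                    "trial_id": tid,
                    "condition": "sequence",
                    "run_id": run_id,
                    "onset": trial_onset + (pos - 1) * (isi + FAST_STIM_SECONDS),
                    "duration": FAST_STIM_SECONDS,
                    "item_class": cls,
                    "serial_position": pos,
                    "orientation": "upright",
                    "isi_seconds": isi,
                    "target_position": targets[tid],
                }
            )
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def make_repetition_schedule(seed: int = 0, n_runs: int = 8) -> pd.DataFrame:
    """Schedule of 45 repetition trials (40 nine-item plus 5 sixteen-item).

    For each first class there are 8 nine-item trials whose switch to the
    second class sweeps serial positions 2..9; each of the other four
    classes follows a given first class exactly twice, on paired switch
    positions (2, 9), (3, 8), (4, 7) or (5, 6), so that the average first
    occurrence of every second class is position 5.5.  Five long trials
    repeat the first class 15 times with the switch at position 16.  The
    ISI is fixed at 32 ms.
    """
    rng = np.random.default_rng(seed)
    pairs = [(2, 9), (3, 8), (4, 7), (5, 6)]
    trials = []
    for first in range(N_CLASSES):
        others = [c for c in range(N_CLASSES) if c != first]
        rng.shuffle(others)
        for second, pair in zip(others, pairs):
            for switch in pair:
                trials.append((first, second, switch, 9))
    shift = int(rng.integers(1, N_CLASSES))  # derangement for the long trials
    for first in range(N_CLASSES):
        trials.append((first, (first + shift) % N_CLASSES, 16, 16))
    rng.shuffle(trials)

    isi = 0.032
    rows = []
    per_run = math.ceil(len(trials) / n_runs)
    trial_stride = 16 * 1.25
    for tid, (first, second, switch, n_items) in enumerate(trials):
        run_id = tid // per_run
        trial_onset = 3.85 + (tid % per_run) * trial_stride
        for pos in range(1, n_items + 1):
            cls = first if pos < switch else second
            rows.append(
                {
                    "trial_id": tid,
                    "condition": "repetition",
                    "run_id": run_id,
                    "onset": trial_onset + (pos - 1) * (isi + FAST_STIM_SECONDS),
                    "duration": FAST_STIM_SECONDS,
                    "item_class": cls,
                    "serial_position": pos,
                    "orientation": "upright",
                    "isi_seconds": isi,
                    "target_position": switch,
                }
            )
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def _trial_window_trs(condition: str, acq: AcquisitionParams) -> int:
    return 7 if condition == "slow" else acq.n_trs_trial


def simulate_probabilities(
    schedule: pd.DataFrame,
    params: ResponseParams,
    acq: AcquisitionParams = AcquisitionParams(),
    noise_sd: float = 0.0,
    noise_model: str = "gaussian",
    dirichlet_concentration: float = 100.0,
    sharpening: float = 60.0,
    seed: int | None = None,
) -> list[ProbabilityTimecourse]:
    """Forward-simulate per-trial TR x class probability matrices.

    Each stimulus event adds one onset-shifted single-event response to
    its class; per-TR probabilities are the (noisy) contributions
    normalized to unit row sums.  Slow trials get a 7-TR window, sequence
    and repetition trials the full per-trial window.

    ``sharpening`` raises the normalized contributions to a power before
    the final renormalization.  It emulates the saturation of logistic
    classifiers, which turn small pattern-evidence differences into
    strongly dispersed probabilities; without it, heavily overlapping
    fast-sequence responses would yield near-uniform rows far less
    dispersed than real decoder output.  The exponent is monotone per TR,
    so orderings within a TR (and hence all sign-based sequentiality
    structure) are unchanged.

    noise_model="gaussian"
        Additive Gaussian noise on the contributions, clipped and
        renormalized.
    noise_model="dirichlet"
        Rows resampled from a Dirichlet centered on the clean
        probabilities with total concentration ``dirichlet_concentration``.
    """
    rng = np.random.default_rng(seed)
    known = {"slow", "sequence", "repetition"}
    bad = set(schedule["condition"].unique()) - known
    if bad:
        raise ValueError(f"unknown condition(s): {sorted(bad)}")

    def trial_groups():
        # slow events decode one at a time (their own 7-TR window);
        # sequence/repetition trials share one window per trial
        for tid, g in schedule.groupby("trial_id", sort=True):
            g = g.sort_values("serial_position")
            if g["condition"].iloc[0] == "slow":
                for j in range(len(g)):
                    yield tid * len(g) + j, g.iloc[[j]]
            else:
                yield tid, g

    tcs = []
    for tid, g in trial_groups():
        condition = g["condition"].iloc[0]
        n_trs = _trial_window_trs(condition, acq)
        t_grid = np.arange(n_trs, dtype=float)  # TR i acquired at t = i - 1
        t0 = g["onset"].iloc[0]
        contrib = np.full((n_trs, N_CLASSES), params.baseline)
        for _, ev in g.iterrows():
            shift = (ev["onset"] - t0) / acq.tr_seconds
            contrib[:, int(ev["item_class"])] += (
                eval_response(params, t_grid - shift) - params.baseline
            )
        if noise_sd > 0 and noise_model == "gaussian":
            contrib = contrib + rng.normal(0.0, noise_sd, contrib.shape)
        probs = np.clip(contrib, 1e-9, None)
        probs /= probs.sum(axis=1, keepdims=True)
        if sharpening != 1.0:
            probs = probs**sharpening
            probs /= probs.sum(axis=1, keepdims=True)
        if noise_sd > 0 and noise_model == "dirichlet":
            probs = np.vstack(
                [rng.dirichlet(dirichlet_concentration * row) for row in probs]
            )
        elif noise_model not in ("gaussian", "dirichlet"):
            raise ValueError(f"unknown noise model: {noise_model!r}")

        classes_by_pos = [int(c) for c in g["item_class"]]
        if condition == "sequence":
            order = tuple(classes_by_pos)
        else:  # slow / repetition: pad the shown class(es) into a full order
            rest = [c for c in range(N_CLASSES) if c not in classes_by_pos]
            seen = list(dict.fromkeys(classes_by_pos))
            order = tuple(seen + rest)
        isi = g["isi_seconds"].iloc[0]
        tcs.append(
            ProbabilityTimecourse(
                probs,
                order=order,
                speed=SpeedCondition(float(isi), FAST_STIM_SECONDS, len(g)) if np.isfinite(isi) else None,
                condition=condition,
                trial_id=int(tid),
                run_id=int(g["run_id"].iloc[0]),
                meta={
                    "first_class": classes_by_pos[0],
                    "second_class": next((c for c in classes_by_pos if c != classes_by_pos[0]), None),
                    "switch_position": g["target_position"].iloc[0] if condition == "repetition" else None,
                },
            )
        )
    return tcs


@dataclass(frozen=True)
class VoxelPatternSpec:
    """Geometry of the synthetic voxel tier.

    Class templates are unit-norm vectors with exact pairwise correlation
    ``pattern_correlation`` (default -1/4, the centered-simplex value,
    emulating the negative mean-pattern correlations seen empirically).
    """

    n_voxels: int = 60
    noise_sd: float = 1.0
    pattern_correlation: float = -0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < N_CLASSES:
            raise ValueError("n_voxels must be >= number of classes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class VoxelRun:
    """One simulated run of voxel data with its ground-truth events."""

    run_id: int
    data: np.ndarray  # n_volumes x n_voxels
    volume_onsets: np.ndarray  # seconds
    events: pd.DataFrame


def class_templates(spec: VoxelPatternSpec) -> np.ndarray:
    """5 x n_voxels unit-norm templates with exact pairwise correlation."""
    rho = spec.pattern_correlation
    gram = np.full((N_CLASSES, N_CLASSES), rho) + (1 - rho) * np.eye(N_CLASSES)
    vals, vecs = np.linalg.eigh(gram)
    vals = np.clip(vals, 0.0, None)
    factors = vecs @ np.diag(np.sqrt(vals))  # 5 x 5, F F' = gram
    rng = np.random.default_rng(spec.seed)
    basis, _ = np.linalg.qr(rng.standard_normal((spec.n_voxels, N_CLASSES)))
    return factors @ basis.T  # rows have unit norm, pairwise dot = rho


def simulate_voxels(
    schedule: pd.DataFrame,
    spec: VoxelPatternSpec,
    params: ResponseParams,
    acq: AcquisitionParams = AcquisitionParams(),
    seed: int = 0,
) -> tuple[list[VoxelRun], np.ndarray]:
    """Simulate per-run samples x voxels matrices from a schedule.

    Every event adds ``template[class] * (response(t) - baseline)`` to the
    volumes of its run; Gaussian noise of SD ``noise_sd / sqrt(n_voxels)``
    per voxel is added (so noise_sd is on the scale of the unit pattern
    norm).  Returns the runs and the class templates.
    """
    templates = class_templates(spec)
    rng = np.random.default_rng(seed)
    runs = []
    for run_id, g in schedule.groupby("run_id", sort=True):
        t_end = g["onset"].max() + 16.0
        n_vol = int(math.ceil(t_end / acq.tr_seconds)) + 1
        onsets = np.arange(n_vol) * acq.tr_seconds
        data = np.zeros((n_vol, spec.n_voxels))
        for _, ev in g.iterrows():
            amp = eval_response(params, (onsets - ev["onset"]) / acq.tr_seconds) - params.baseline
            data += np.outer(amp, templates[int(ev["item_class"])])
        if spec.noise_sd > 0:
            data += rng.normal(0.0, spec.noise_sd / math.sqrt(spec.n_voxels), data.shape)
        runs.append(VoxelRun(int(run_id), data, onsets, g.reset_index(drop=True)))
    return runs, templates


def simulate_rest(
    n_trs: int = 233,
    seed: int | None = None,
    concentration: float = 0.5,
    ar_coef: float = 0.3,
    n_classes: int = N_CLASSES,
) -> ProbabilityTimecourse:
    """Synthetic rest-period classifier probabilities (a stand-in for real rest).

    An AR(1) Gaussian process on class logits, mapped to the simplex by
    softmax: a logistic-normal approximation of Dirichlet draws with
    concentration ``concentration`` (logit scale 1/concentration), with
    temporal autocorrelation ``ar_coef``.  Low concentration yields the
    wildly fluctuating, single-class-dominated probabilities that real
    rest decoding shows.
    """
    if n_trs < 1:
        raise ValueError("n_trs must be >= 1")
    rng = np.random.default_rng(seed)
    scale = 1.0 / concentration
    z = np.empty((n_trs, n_classes))
    z[0] = rng.normal(0.0, scale, n_classes)
    innov_sd = scale * math.sqrt(max(1.0 - ar_coef**2, 1e-12))
    for i in range(1, n_trs):
        z[i] = ar_coef * z[i - 1] + rng.normal(0.0, innov_sd, n_classes)
    expz = np.exp(z - z.max(axis=1, keepdims=True))
    probs = expz / expz.sum(axis=1, keepdims=True)
    return ProbabilityTimecourse(probs, order=tuple(range(n_classes)), speed=None, condition="rest")


@dataclass(frozen=True)
class BlendSpec:
    """How sequence events are blended into rest data.

    ``kappa`` is the signal fraction: inserted segments are
    ``kappa * trial + (1 - kappa) * rest_donor`` where the donor rows come
    from independent non-overlapping rest locations, so that kappa = 0
    still carries pure concatenation artifacts.
    """

    kappa: float
    n_inserts: int = 6
    insert_len_trs: int = INSERT_LEN_TRS
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must be in [0, 1]")
        if self.n_inserts < 1:
            raise ValueError("n_inserts must be >= 1")


def _sample_nonoverlapping(rng: np.random.Generator, n_segments: int, seg_len: int, n_total: int, max_retries: int) -> list[int]:
    if n_segments * seg_len > n_total:
        raise ValueError("segments do not fit into the rest run")
    for _ in range(max_retries):
        starts = sorted(rng.integers(0, n_total - seg_len + 1, size=n_segments))
        if all(b - a >= seg_len for a, b in zip(starts, starts[1:])):
            return starts
    raise RuntimeError("could not place non-overlapping segments")


@dataclass
class InsertionResult:
    """Blended rest time course plus ground-truth insertion locations."""

    timecourse: ProbabilityTimecourse
    segments: list[tuple[int, int]]  # 0-based [start, end) rows
    trial_indices: list[int]


def insert_events(
    rest: ProbabilityTimecourse,
    trials: list[ProbabilityTimecourse],
    blend: BlendSpec,
    seed: int | None = None,
) -> InsertionResult:
    """Blend sequence-trial segments into a rest run at random locations.

    Trials are drawn without replacement; only their first
    ``insert_len_trs`` rows are used (slice trials to the relevant period
    beforehand).  Insertion targets and donor rest rows are each sampled
    at non-overlapping random locations.
    """
    rng = np.random.default_rng(seed)
    L, k = blend.insert_len_trs, blend.n_inserts
    if k > len(trials):
        raise ValueError("not enough trials to draw from without replacement")
    picks = list(rng.choice(len(trials), size=k, replace=False))
    targets = _sample_nonoverlapping(rng, k, L, rest.n_trs, blend.max_retries)
    donors = _sample_nonoverlapping(rng, k, L, rest.n_trs, blend.max_retries)
    out = rest.probabilities.copy()
    for ti, tgt, don in zip(picks, targets, donors):
        seg = trials[ti].probabilities[:L]
        if seg.shape[0] < L:
            raise ValueError("trial shorter than insert_len_trs")
        out[tgt : tgt + L] = blend.kappa * seg + (1.0 - blend.kappa) * rest.probabilities[don : don + L]
    tc = ProbabilityTimecourse(
        out, order=rest.order, speed=None, condition="blended", meta={"kappa": blend.kappa}
    )
    return InsertionResult(tc, [(s, s + L) for s in targets], [int(i) for i in picks])
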