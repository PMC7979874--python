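"""One-vs-rest probabilistic decoding of voxel-tier data.

Five independent L2-regularized logistic regression classifiers (one per
stimulus class, all other classes relabeled to a common "other" class)
are trained on single-volume patterns extracted at the expected response
peak (~4 s after stimulus onset) and applied TR-by-TR to produce the
probability time courses that all downstream metrics consume.  Training
follows a leave-one-run-out cross-validation over the eight task runs;
runs are linearly detrended and features z-scored per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend as _linear_detrend
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.linear_model import LogisticRegression

from .core import AcquisitionParams, SpeedCondition
from .synth import VoxelRun, N_CLASSES, FAST_STIM_SECONDS
from .timecourse import ProbabilityTimecourse

__all__ = [
    "ClassifierConfig",
    "OneVsRestEnsemble",
    "detrend_run",
    "zscore_features",
    "peak_tr_index",
    "select_features",
    "train_ovr",
    "predict_timecourses",
    "peak_samples_from_run",
    "leave_one_run_out_accuracy",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Settings of the logistic-regression ensemble."""

    cost_c: float = 1.0
    max_iterations: int = 4000
    tol: float = 1e-4
    class_weight: str | dict | None = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cost_c <= 0:
            raise ValueError("cost_c must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def detrend_run(matrix: np.ndarray) -> np.ndarray:
    """Remove each feature's within-run linear trend (mean included)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        import warnings

        warnings.warn("single-sample run: detrending skipped")
        return matrix.copy()
    return _linear_detrend(matrix, axis=0, type="linear")


def zscore_features(matrix: np.ndarray) -> np.ndarray:
    """Standardize features to mean 0, SD 1; zero-variance features -> 0."""
    matrix = np.asarray(matrix, dtype=float)
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (matrix - mean) / sd_safe
    out[:, sd == 0] = 0.0
    return out


def peak_tr_index(onset_seconds: float, tr_seconds: float = 1.25) -> int:
    """0-based index of the volume closest to onset + 4 s.

    At a 1.25 s TR this selects the fourth volume after onset (the
    3.75-5 s window covering the expected response peak).
    """
    if onset_seconds < 0:
        raise ValueError("onset must be >= 0")
    return int(math.floor((onset_seconds + 4.0) / tr_seconds + 0.5))


def select_features(train_X: np.ndarray, train_y: np.ndarray, k: int) -> np.ndarray:
    """Top-k features by class-separability F-statistic on the training fold.

    A simplified substitute for voxel selection; returns a boolean mask.
    """
    k = min(k, train_X.shape[1])
    sel = SelectKBest(f_classif, k=k).fit(train_X, train_y)
    return sel.get_support()


@dataclass
class OneVsRestEnsemble:
    """Five fitted binary classifiers, one per stimulus class."""

    classifiers: list
    config: ClassifierConfig

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class one-vs-rest probabilities, shape (n_samples, 5).

        Each column is that binary classifier's P(class | data); columns
        are not forced to sum to 1 (normalization is downstream).
        """
        cols = [clf.predict_proba(X)[:, list(clf.classes_).index(1)] for clf in self.classifiers]
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def train_ovr(train_X: np.ndarray, train_y: np.ndarray, config: ClassifierConfig = ClassifierConfig()) -> OneVsRestEnsemble:
    """Fit the five one-vs-rest logistic regressions.

    Class weights are adjusted inversely proportional to training
    frequencies (a balanced 5-class set gives 1/5 vs 4/5).  A fold in
    which some class is absent (or universal) raises with the class named.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    clfs = []
    for cls in range(N_CLASSES):
        y_bin = (train_y == cls).astype(int)
        if y_bin.min() == y_bin.max():
            raise ValueError(f"degenerate training fold for class {cls}: one class only")
        # L2 regularization (sklearn's default penalty) with fixed C
        clf = LogisticRegression(
            C=config.cost_c,
            solver="lbfgs",
            max_iter=config.max_iterations,
            tol=config.tol,
            class_weight=config.class_weight,
            random_state=config.seed,
        )
        clf.fit(train_X, y_bin)
        clfs.append(clf)
    return OneVsRestEnsemble(clfs, config)


def peak_samples_from_run(
    run: VoxelRun,
    acq: AcquisitionParams = AcquisitionParams(),
    preprocess: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Training samples: peak-TR patterns and labels of a run's slow events.

    Only upright slow events are used (the classifier-training set).
    """
    X = run.data
    if preprocess:
        X = zscore_features(detrend_run(X))
    ev = run.events
    ev = ev[(ev["condition"] == "slow") & (ev["orientation"] == "upright")]
    idx = np.array([peak_tr_index(o, acq.tr_seconds) for o in ev["onset"]])
    ok = idx < X.shape[0]
    return X[idx[ok]], ev["item_class"].to_numpy(dtype=int)[ok]


def predict_timecourses(
    ensemble: OneVsRestEnsemble,
    run: VoxelRun,
    acq: AcquisitionParams = AcquisitionParams(),
    window_trs: int | None = None,
    conditions=("sequence", "repetition"),
    preprocess: bool = True,
) -> list[ProbabilityTimecourse]:
    """Apply the ensemble to a run's trial windows.

    For each trial, ``window_trs`` volumes from sequence onset (13 for
    sequence/repetition trials, 7 for slow trials) are decoded into raw
    per-class probabilities.  Trials whose window exceeds the run raise,
    listing the offending trial ids.
    """
    X = run.data
    if preprocess:
        X = zscore_features(detrend_run(X))
    tcs = []
    out_of_bounds = []
    ev = run.events[run.events["condition"].isin(conditions)]
    for tid, g in ev.groupby("trial_id", sort=True):
        g = g.sort_values("serial_position")
        condition = g["condition"].iloc[0]
        n_trs = window_trs if window_trs is not None else (7 if condition == "slow" else acq.n_trs_trial)
        start = int(math.floor(g["onset"].iloc[0] / acq.tr_seconds + 0.5))
        if start + n_trs > X.shape[0]:
            out_of_bounds.append(int(tid))
            continue
        probs = ensemble.predict_proba(X[start : start + n_trs])
        classes_by_pos = [int(c) for c in g["item_class"]]
        seen = list(dict.fromkeys(classes_by_pos))
        order = tuple(seen + [c for c in range(N_CLASSES) if c not in seen])
        isi = g["isi_seconds"].iloc[0]
        tcs.append(
            ProbabilityTimecourse(
                probs,
                order=order,
                speed=SpeedCondition(float(isi), FAST_STIM_SECONDS, len(g)) if np.isfinite(isi) else None,
                condition=condition,
                trial_id=int(tid),
                run_id=run.run_id,
                meta={
                    "first_class": classes_by_pos[0],
                    "second_class": next((c for c in classes_by_pos if c != classes_by_pos[0]), None),
                    "switch_position": g["target_position"].iloc[0] if condition == "repetition" else None,
                },
            )
        )
    if out_of_bounds:
        raise ValueError(f"trial window(s) exceed run bounds: {out_of_bounds}")
    return tcs


def leave_one_run_out_accuracy(
    runs: list[VoxelRun],
    acq: AcquisitionParams = AcquisitionParams(),
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[float, list[float]]:
    """Leave-one-run-out decoding accuracy on slow-trial peak patterns.

    Each run is held out once; classifiers train on the peak samples of
    the remaining runs and are scored on the held-out run's peaks.
    """
    samples = [peak_samples_from_run(r, acq) for r in runs]
    fold_acc = []
    for held in range(len(runs)):
        train_X = np.vstack([samples[i][0] for i in range(len(runs)) if i != held])
        train_y = np.concatenate([samples[i][1] for i in range(len(runs)) if i != held])
        ens = train_ovr(train_X, train_y, config)
        test_X, test_y = samples[held]
        fold_acc.append(float(np.mean(ens.predict(test_X) == test_y)))
    return float(np.mean(fold_acc)), fold_acc
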