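"""Single-event response model and sequence-timing predictions.

The slow multivariate decoding time course that follows a single visual
event is modeled as a single sine cycle, flattened to baseline outside the
cycle::

    h(t) = A/2 * sin(2*pi*f*t - 2*pi*f*d - pi/2) + b + A/2   for d <= t <= d + lambda
    h(t) = b                                                 otherwise

with amplitude ``A`` (peak deviation from baseline), response duration
``lambda = 1/f`` (in TR units), onset delay ``d`` (TRs) and baseline ``b``.
Time is counted in TRs throughout; one TR is 1.25 s by default.

The difference between two such responses shifted by ``delta`` TRs is again
a (single-cycle) sine with stretched wavelength ``lambda + delta`` and
amplitude ``A*sin(pi*delta/lambda)``.  This closed form drives everything
downstream: the forward/backward analysis windows per sequence speed and
the frequency at which sequential events surface in slope spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "AcquisitionParams",
    "ResponseParams",
    "SpeedCondition",
    "DifferenceModel",
    "PeriodWindows",
    "FitResult",
    "DEFAULT_ISIS_MS",
    "eval_response",
    "fit_response",
    "delta_trs",
    "delta_seconds_total",
    "predicted_frequency",
    "difference_waveform",
    "difference_model",
    "compute_periods",
]

#: ISI levels (ms) of the five sequence-speed conditions.
DEFAULT_ISIS_MS = (32, 64, 128, 512, 2048)


def _round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (for x >= 0)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class AcquisitionParams:
    """fMRI acquisition timing.

    Parameters
    ----------
    tr_seconds
        Duration of one repetition time (TR) in seconds.
    n_trs_trial
        Number of TRs in the per-trial analysis window (the ~16 s from
        sequence onset to the end of the delay period spans 13 TRs at a
        1.25 s TR).
    """

    tr_seconds: float = 1.25
    n_trs_trial: int = 13

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if int(self.n_trs_trial) < 1:
            raise ValueError("n_trs_trial must be >= 1")


@dataclass(frozen=True)
class ResponseParams:
    """Parameters of the flattened-sine single-event response.

    ``wavelength`` is the response duration lambda in TRs; the model's
    frequency is ``1/wavelength`` (per TR).
    """

    amplitude: float
    wavelength: float
    onset_delay: float
    baseline: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be >= 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")

    @property
    def frequency(self) -> float:
        """Angular frequency f = 1/lambda in per-TR units."""
        return 1.0 / self.wavelength

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseParams":
        return cls(**{k: d[k] for k in ("amplitude", "wavelength", "onset_delay", "baseline")})


#: Group-average fit reported for occipito-temporal decoding time courses.
REFERENCE_WAVELENGTH_TRS = 5.24
REFERENCE_ONSET_DELAY_TRS = 0.56


def default_response_params() -> "ResponseParams":
    """Canonical simulation parameters: the group-average response duration
    and onset delay, with a realistic amplitude and baseline."""
    return ResponseParams(
        amplitude=0.6,
        wavelength=REFERENCE_WAVELENGTH_TRS,
        onset_delay=REFERENCE_ONSET_DELAY_TRS,
        baseline=0.05,
    )


@dataclass(frozen=True)
class SpeedCondition:
    """Geometry of one sequence-speed condition.

    Parameters
    ----------
    isi_seconds
        Inter-stimulus interval (blank gap between items), seconds.
    stim_duration_seconds
        Presentation time per item, seconds (100 ms in the task).
    n_items
        Items per sequence (5 for sequence trials, 9/16 for repetitions).
    """

    isi_seconds: float
    stim_duration_seconds: float = 0.1
    n_items: int = 5

    def __post_init__(self) -> None:
        if self.isi_seconds < 0:
            raise ValueError("isi_seconds must be >= 0")
        if self.stim_duration_seconds <= 0:
            raise ValueError("stim_duration_seconds must be > 0")
        if self.n_items < 2:
            raise ValueError("n_items must be >= 2")

    @property
    def soa_seconds(self) -> float:
        """Stimulus-onset asynchrony: onset-to-onset spacing of items."""
        return self.isi_seconds + self.stim_duration_seconds


@dataclass(frozen=True)
class DifferenceModel:
    """Closed-form description of the two-event difference wave."""

    amplitude_scale: float
    freq_delta: float
    onset_delay: float


@dataclass(frozen=True)
class PeriodWindows:
    """Inclusive 1-based TR windows of the forward and backward periods.

    TR 1 is the acquisition beginning at sequence onset.
    """

    forward_start: int
    forward_end: int
    backward_start: int
    backward_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.forward_start <= self.forward_end):
            raise ValueError("invalid forward window")
        if self.backward_start != self.forward_end + 1:
            raise ValueError("backward window must start right after the forward window")
        if self.backward_end < self.backward_start:
            raise ValueError("invalid backward window")

    @property
    def forward_trs(self) -> np.ndarray:
        return np.arange(self.forward_start, self.forward_end + 1)

    @property
    def backward_trs(self) -> np.ndarray:
        return np.arange(self.backward_start, self.backward_end + 1)


def eval_response(params: ResponseParams, t) -> np.ndarray:
    """Evaluate the flattened-sine response at time(s) ``t`` (TR units).

    Returns ``h(t)`` inside the single cycle ``d <= t <= d + lambda`` and
    the baseline ``b`` outside.  Vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    A, lam, d, b = params.amplitude, params.wavelength, params.onset_delay, params.baseline
    f = 1.0 / lam
    h = 0.5 * A * np.sin(2 * np.pi * f * t - 2 * np.pi * f * d - 0.5 * np.pi) + b + 0.5 * A
    inside = (t >= d) & (t <= d + lam)
    out = np.where(inside, h, b)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-event response fit."""

    params: ResponseParams
    loss: float
    converged: bool
    n_evaluations: int = 0


def _default_init(y: np.ndarray, t: np.ndarray) -> ResponseParams:
    # A from the data range, b from the first sample, d at half a TR,
    # lambda from twice the (delay-corrected) time of the maximum.
    a0 = max(float(y.max() - y.min()), 1e-3)
    b0 = float(np.clip(y[0], 0.0, 1.0))
    d0 = 0.5
    lam0 = float(np.clip(2.0 * (t[int(np.argmax(y))] - d0), 1.0, 13.0))
    return ResponseParams(a0, lam0, d0, b0)


DEFAULT_FIT_BOUNDS = ((0.0, 1.0), (1.0, 13.0), (0.0, 3.0), (0.0, 1.0))


def fit_response(
    y,
    t=None,
    init: ResponseParams | None = None,
    bounds=DEFAULT_FIT_BOUNDS,
    maxiter: int = 4000,
) -> FitResult:
    """Fit (A, lambda, d, b) to one class's probability time course.

    Minimizes the sum of squared residuals between :func:`eval_response`
    and the data under box constraints, using the derivative-free COBYLA
    algorithm.  Non-convergence is reported through ``FitResult.converged``
    rather than raised.

    Parameters
    ----------
    y
        Observed probabilities, one value per TR.
    t
        Time grid in TRs; defaults to ``0..len(y)-1``.
    init
        Starting parameters; a data-driven default is used when omitted.
    bounds
        Box constraints for (A, lambda, d, b).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValueError("need a 1-D time course of at least 5 TRs")
    t = np.arange(y.size, dtype=float) if t is None else np.asarray(t, dtype=float)
    if init is None:
        init = _default_init(y, t)
    x0 = np.array([init.amplitude, init.wavelength, init.onset_delay, init.baseline])
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x0 = np.clip(x0, lo, hi)

    def loss(x: np.ndarray) -> float:
        p = ResponseParams(*np.clip(x, lo, hi))
        r = eval_response(p, t) - y
        return float(r @ r)

    # COBYLA handles the box constraints; a short run suffices to land in
    # the right basin, after which a Nelder-Mead polish tightens the
    # optimum to numerical precision (bounds enforced by clipping).
    res = minimize(
        loss,
        x0,
        method="COBYLA",
        bounds=list(zip(lo, hi)),
        options={"maxiter": min(maxiter, 100), "rhobeg": 0.5, "tol": 1e-6},
    )
    res2 = minimize(
        loss,
        np.clip(res.x, lo, hi),
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-10, "fatol": 1e-14},
    )
    best = res2 if res2.fun <= res.fun else res
    x = np.clip(best.x, lo, hi)
    return FitResult(
        params=ResponseParams(*x),
        loss=float(best.fun),
        converged=bool(res.success or res2.success),
        n_evaluations=int(res.nfev + res2.nfev),
    )


def delta_trs(speed: SpeedCondition, acq: AcquisitionParams = AcquisitionParams()) -> float:
    """Onset-of-first to onset-of-last event offset, in TRs.

    ``delta = (n_items - 1) * (ISI + stimulus duration) / TR``.  This is
    the delta entering the forward/backward period windows.
    """
    return (speed.n_items - 1) * speed.soa_seconds / acq.tr_seconds


def delta_seconds_total(speed: SpeedCondition) -> float:
    """Onset-of-first to offset-of-last event span, in seconds.

    ``delta = (n_items - 1) * ISI + n_items * stimulus duration`` — the
    total sequence duration, used for frequency prediction.
    """
    return (speed.n_items - 1) * speed.isi_seconds + speed.n_items * speed.stim_duration_seconds


def predicted_frequency(
    wavelength_trs: float,
    delta: float,
    convention: str = "paper",
    tr_seconds: float = 1.25,
) -> float:
    """Frequency of the two-event difference wave, f_delta = f/(1 + f*delta).

    convention="paper"
        ``delta`` is the total sequence span in **seconds** and lambda is
        in TRs; the mixed-unit quotient ``1/(lambda + delta)`` is returned
        and conventionally labeled Hz (0.17 for the 32 ms condition, 0.07
        for 2048 ms).
    convention="strict"
        ``delta`` is in TRs; the per-TR ``1/(lambda + delta)`` is converted
        to true Hz via ``tr_seconds``.
    """
    if wavelength_trs <= 0:
        raise ValueError("wavelength must be > 0")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if convention == "paper":
        return 1.0 / (wavelength_trs + delta)
    if convention == "strict":
        return 1.0 / ((wavelength_trs + delta) * tr_seconds)
    raise ValueError(f"unknown convention: {convention!r}")


def difference_model(params: ResponseParams, delta_trs: float) -> DifferenceModel:
    """Closed-form amplitude/frequency of the difference of two shifted responses."""
    if delta_trs < 0:
        raise ValueError("delta must be >= 0")
    f = params.frequency
    # The sine amplitude factor is meaningful as a signed quantity only up
    # to delta = lambda/2 (it grows monotonically until there); for larger
    # shifts the magnitude is kept and the canonical forward-early sign of
    # the difference wave is preserved.
    return DifferenceModel(
        amplitude_scale=params.amplitude * abs(math.sin(2 * np.pi * f * delta_trs / 2.0)),
        freq_delta=f / (1.0 + f * delta_trs),
        onset_delay=params.onset_delay,
    )


def difference_waveform(params: ResponseParams, delta_trs: float, t) -> np.ndarray:
    """Predicted difference wave h_delta(t) between two events shifted by delta TRs.

    ``h_delta(t) = A*sin(2*pi*f*delta/2) * sin(2*pi*f_delta*t - 2*pi*f_delta*d)``
    inside ``[d, d + lambda + delta]`` and zero outside.  Positive on the
    first half cycle (the forward period), negative on the second (the
    backward period).
    """
    t = np.asarray(t, dtype=float)
    dm = difference_model(params, delta_trs)
    d = params.onset_delay
    wave = dm.amplitude_scale * np.sin(2 * np.pi * dm.freq_delta * t - 2 * np.pi * dm.freq_delta * d)
    inside = (t >= d) & (t <= d + params.wavelength + delta_trs)
    out = np.where(inside, wave, 0.0)
    return out if out.ndim else float(out)


def compute_periods(
    wavelength_trs: float,
    onset_delay_trs: float,
    delta_trs: float,
    n_trs: int = 13,
) -> PeriodWindows:
    """Speed-adjusted forward/backward analysis windows as inclusive TR indices.

    In continuous time the difference wave is positive on
    ``[d, 0.5*(lambda+delta)+d]`` and negative on
    ``[0.5*(lambda+delta)+d, lambda+delta+d]``.  Boundaries are mapped to
    1-based TR indices (TR 1 at sequence onset) by half-up rounding of the
    start, a ceiling at the forward/backward split, and capping the final
    TR at the window length.
    """
    lam, d, dl = wavelength_trs, onset_delay_trs, delta_trs
    if lam <= 0 or d < 0 or dl < 0:
        raise ValueError("invalid period parameters")
    forward_start = _round_half_up(d) + 1
    backward_start = int(math.ceil(0.5 * (lam + dl) + d)) + 1
    forward_end = backward_start - 1
    backward_end = min(_round_half_up(lam + dl + d) + 1, int(n_trs))
    if forward_start > int(n_trs):
        raise ValueError("analysis window too short to contain the forward period")
    return PeriodWindows(forward_start, forward_end, backward_start, backward_end)
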