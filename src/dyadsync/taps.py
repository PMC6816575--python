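"""Tap events, intertap intervals and lag-correlation statistics.

The action oscillators stand in for finger taps: a tap is emitted whenever
an action oscillator's unwrapped phase crosses a successive multiple of
2*pi, with the crossing time located by linear interpolation between the
bracketing phase samples.  Intertap intervals (ITIs) are the successive
differences of tap times, and the synchronization strategy of a dyad is
read off the Pearson correlations between the two units' ITI series at lags
-1, 0 and +1.

Lag-sign convention: ``r_plus1`` correlates unit-1 intervals ``a_t`` with
unit-2 intervals ``b_{t+1}``, so a positive ``r_plus1`` reads "unit 2
follows unit 1 by one tap".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    ACTION_OSCILLATORS,
    TWO_PI,
    ModelSpec,
    PhaseEnsemble,
    PhaseTrajectory,
    SimulationConfig,
    integrate_ensemble,
)


class InsufficientEventsError(ValueError):
    """Raised when a series holds too few taps/intervals for the statistic."""


class ConditionFailedError(RuntimeError):
    """Raised when every trial of a condition yields undefined correlations."""


@dataclass
class TapSeries:
    """Tap event times (s) of one unit, strictly increasing."""

    unit_id: int
    tap_times: np.ndarray

    def __post_init__(self) -> None:
        self.tap_times = np.asarray(self.tap_times, dtype=float)
        if self.tap_times.size and np.any(np.diff(self.tap_times) <= 0):
            raise ValueError("tap_times must be strictly increasing")

    def __len__(self) -> int:
        return self.tap_times.size


@dataclass
class ITISeries:
    """Intertap intervals (s) of one unit; all positive."""

    unit_id: int
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.size and np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")

    def __len__(self) -> int:
        return self.intervals.size


@dataclass(frozen=True)
class LagPattern:
    """Pearson correlations of two ITI series at lags -1, 0, +1.

    Components are NaN when a correlation is undefined (constant series);
    such patterns are excluded from downstream averages.
    """

    r_minus1: float
    r_0: float
    r_plus1: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r_minus1, self.r_0, self.r_plus1])

    @property
    def is_defined(self) -> bool:
        return bool(np.all(np.isfinite(self.as_array())))

    def mirrored(self) -> "LagPattern":
        """The pattern seen from the other unit's perspective (lags flipped)."""
        return LagPattern(self.r_plus1, self.r_0, self.r_minus1)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "LagPattern":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))


def _crossing_times(times: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Interpolated times at which ``theta`` first crosses each 2*pi multiple.

    Noise can make the sampled unwrapped phase locally non-monotone; only the
    first upward crossing of each multiple is emitted (running-maximum
    guard), which keeps the tap series strictly increasing.
    """
    # tiny tolerance so a sample sitting numerically just below a multiple
    # of 2*pi still counts as having crossed it
    k = np.floor((theta + 1e-9) / TWO_PI)
    kc = np.maximum.accumulate(k)
    dk = np.diff(kc).astype(np.int64)
    out = []
    (idx,) = np.nonzero(dk > 0)
    simple = idx[dk[idx] == 1]
    if simple.size:
        levels = (kc[simple] + 1.0) * TWO_PI
        frac = (levels - theta[simple]) / (theta[simple + 1] - theta[simple])
        out.append(times[simple] + frac * (times[simple + 1] - times[simple]))
    for i in idx[dk[idx] > 1]:  # rare: several multiples crossed in one interval
        levels = (kc[i] + 1.0 + np.arange(dk[i])) * TWO_PI
        frac = (levels - theta[i]) / (theta[i + 1] - theta[i])
        out.append(times[i] + frac * (times[i + 1] - times[i]))
    if not out:
        return np.empty(0)
    return np.sort(np.concatenate(out))


def _unit_of_oscillator(variant: str, oscillator: int) -> int:
    a1, a2 = ACTION_OSCILLATORS[variant]
    return {a1: 1, a2: 2}[oscillator]


def extract_taps(
    traj: PhaseTrajectory, oscillator: int, discard: Optional[float] = None
) -> TapSeries:
    """Tap events of one action oscillator, dropping taps at ``t <= discard``.

    ``oscillator`` is a 0-based index and must be an action oscillator
    (1 or 2 in the four-oscillator layout, 0 or 1 in the reduced one).
    """
    if oscillator not in ACTION_OSCILLATORS[traj.spec.variant]:
        raise ValueError(
            f"oscillator {oscillator} is not an action oscillator of "
            f"{traj.spec.variant}; expected one of "
            f"{ACTION_OSCILLATORS[traj.spec.variant]}"
        )
    if discard is None:
        discard = traj.config.discard
    if traj.times[-1] <= discard:
        raise InsufficientEventsError("trajectory does not extend past discard time")
    taps = _crossing_times(traj.times, traj.phases[:, oscillator])
    taps = taps[taps > discard]
    return TapSeries(unit_id=_unit_of_oscillator(traj.spec.variant, oscillator), tap_times=taps)


def intertap_intervals(taps: TapSeries) -> ITISeries:
    """Successive differences of the tap times."""
    if len(taps) < 2:
        raise InsufficientEventsError("need at least 2 taps to form intervals")
    return ITISeries(unit_id=taps.unit_id, intervals=np.diff(taps.tap_times))


#: ITI variation below one nanosecond is numerical, not physical: such a
#: series counts as constant and its correlations as undefined.
_CONSTANT_TOL = 1e-9


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) < _CONSTANT_TOL or np.ptp(y) < _CONSTANT_TOL:
        return np.nan
    xs = x - x.mean()
    ys = y - y.mean()
    denom = np.sqrt((xs**2).sum() * (ys**2).sum())
    if denom == 0:
        return np.nan
    return float(np.clip((xs * ys).sum() / denom, -1.0, 1.0))


def lagged_crosscorr(a: ITISeries, b: ITISeries) -> LagPattern:
    """Lag -1/0/+1 Pearson correlations of two ITI series.

    The series are truncated to their common length from the start
    (simulated trials yield near-synchronous taps, so index k of one series
    aligns with index k of the other).  ``r_k`` correlates ``a_t`` with
    ``b_{t+k}``.
    """
    L = min(len(a), len(b))
    if L < 3:
        raise InsufficientEventsError(
            f"need at least 3 common intervals, got {L}"
        )
    x = a.intervals[:L]
    y = b.intervals[:L]
    return LagPattern(
        r_minus1=_pearson(x[1:], y[:-1]),
        r_0=_pearson(x, y),
        r_plus1=_pearson(x[:-1], y[1:]),
    )


def resultant_length(rel_phases: np.ndarray) -> float:
    """Mean resultant length of a sample of relative phases (rad)."""
    rel_phases = np.asarray(rel_phases, dtype=float)
    return float(np.abs(np.exp(1j * rel_phases).mean()))


def synchronization_index(
    traj: PhaseTrajectory, osc_a: int, osc_b: int, discard: Optional[float] = None
) -> float:
    """Phase-locking of two oscillators, in [0, 1].

    Mean resultant length of the relative phase over the post-discard
    samples, R = |mean exp(i*(theta_a - theta_b))|; equals 1 minus the
    circular variance of the relative phase.  1 means perfect locking.
    """
    if discard is None:
        discard = traj.config.discard
    mask = traj.times > discard
    if mask.sum() < 2:
        raise InsufficientEventsError("need at least 2 post-discard samples")
    rel = traj.phases[mask, osc_a] - traj.phases[mask, osc_b]
    return resultant_length(rel)


def _ensemble_sync(ens: PhaseEnsemble, osc_a: int, osc_b: int, discard: float) -> np.ndarray:
    mask = ens.times > discard
    rel = ens.phases[:, mask, osc_a] - ens.phases[:, mask, osc_b]
    return np.abs(np.exp(1j * rel).mean(axis=1))


def ensemble_lag_patterns(ens: PhaseEnsemble) -> np.ndarray:
    """Per-trial lag-correlation triplets of an ensemble, shape (n_trials, 3).

    Rows are NaN where a trial yields too few taps or a constant ITI series.
    """
    a_idx, b_idx = ACTION_OSCILLATORS[ens.spec.variant]
    discard = ens.config.discard
    out = np.full((ens.n_trials, 3), np.nan)
    for t in range(ens.n_trials):
        taps_a = _crossing_times(ens.times, ens.phases[t, :, a_idx])
        taps_b = _crossing_times(ens.times, ens.phases[t, :, b_idx])
        taps_a = taps_a[taps_a > discard]
        taps_b = taps_b[taps_b > discard]
        L = min(taps_a.size, taps_b.size) - 1
        if L < 3:
            continue
        x = np.diff(taps_a)[:L]
        y = np.diff(taps_b)[:L]
        out[t] = (_pearson(x[1:], y[:-1]), _pearson(x, y), _pearson(x[:-1], y[1:]))
    return out


@dataclass
class ConditionResult:
    """Aggregate of ``n_trials`` independent simulations of one condition."""

    spec: ModelSpec
    config: SimulationConfig
    patterns: np.ndarray  # (n_trials, 3); NaN rows = undefined trials
    mean_pattern: LagPattern
    mean_sync: float
    n_trials: int
    n_undefined: int


def run_condition(
    spec: ModelSpec,
    config: SimulationConfig,
    n_trials: int,
    rng: Optional[np.random.Generator] = None,
    *,
    initial_phases: Optional[np.ndarray] = None,
    frequencies: Optional[np.ndarray] = None,
    noise: Optional[np.ndarray] = None,
) -> ConditionResult:
    """Simulate a coupling condition and average its lag patterns.

    Runs ``n_trials`` independent simulations (fresh phases, frequencies and
    noise per trial), extracts taps from the two action oscillators, computes
    the per-trial lag patterns and the action-pair synchronization index, and
    returns them with componentwise means.  Trials with undefined
    correlations are excluded from the means and counted.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ens = integrate_ensemble(
        spec,
        config,
        n_trials,
        rng,
        initial_phases=initial_phases,
        frequencies=frequencies,
        noise=noise,
    )
    patterns = ensemble_lag_patterns(ens)
    defined = np.all(np.isfinite(patterns), axis=1)
    n_undefined = int(n_trials - defined.sum())
    if not defined.any():
        raise ConditionFailedError(
            "all trials produced undefined lag correlations"
        )
    a_idx, b_idx = ACTION_OSCILLATORS[spec.variant]
    mean_sync = float(_ensemble_sync(ens, a_idx, b_idx, config.discard).mean())
    mean = patterns[defined].mean(axis=0)
    return ConditionResult(
        spec=spec,
        config=config,
        patterns=patterns,
        mean_pattern=LagPattern.from_array(mean),
        mean_sync=mean_sync,
        n_trials=n_trials,
        n_undefined=n_undefined,
    )
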