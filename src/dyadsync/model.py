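"""Stochastic Kuramoto dynamics for dyadic sensorimotor synchronization.

A tapping dyad is abstracted as two *units* (people), each composed of a
perception oscillator and an action oscillator.  Within a unit the two
oscillators are coupled bidirectionally with weight ``i`` (intrapersonal
action--perception coupling); between units each action oscillator drives the
partner's perception oscillator unidirectionally with weight ``e`` (hearing
the partner's taps).  A reduced two-oscillator variant keeps one oscillator
per unit with reciprocal couplings ``e1``/``e2``.

The phase of oscillator ``n`` evolves as

    dtheta_n/dt = omega_n + sum_p K[n, p] * sin(theta_p - theta_n) + noise,

integrated with an explicit Euler--Maruyama scheme.  Coupling weights are in
1/s and multiplied by the step ``dt`` inside the update, so a weight has the
same meaning at any temporal resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import yaml

TWO_PI = 2.0 * np.pi

TWO_OSC = "two_osc"
FOUR_OSC = "four_osc"

#: 0-based indices of the action oscillators per variant.  In the
#: four-oscillator layout the oscillators are ordered (unit-1 perception,
#: unit-1 action, unit-2 action, unit-2 perception); in the reduced variant
#: each unit's single oscillator stands in for its action oscillator.
ACTION_OSCILLATORS = {TWO_OSC: (0, 1), FOUR_OSC: (1, 2)}

#: Phase-noise standard deviations (rad per nominal 500 ms tap interval)
#: calibrated to the intertap-interval variability of the two empirical
#: tapping datasets the model was validated on (musicians / non-musicians).
SIGMA_DATASET1 = 0.2513
SIGMA_DATASET2 = 0.4335


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite phase."""


def timing_sd_to_phase_sd(timing_sd_s: float, freq_hz: float) -> float:
    """Convert a tap-timing spread in seconds to phase radians at ``freq_hz``.

    A timing jitter of ``dt`` seconds at tapping frequency ``f`` corresponds
    to a phase jitter of ``dt * 2 * pi * f`` radians (20 ms at 2 Hz is
    0.2513 rad).
    """
    return float(timing_sd_s * TWO_PI * freq_hz)


def hz_to_rad_per_s(freq_hz: float) -> float:
    """Convert a frequency in Hz to angular frequency in rad/s."""
    return float(TWO_PI * freq_hz)


@dataclass(frozen=True)
class ModelSpec:
    """Coupling weights and variant selecting the coupling matrix.

    Parameters
    ----------
    variant:
        ``"four_osc"`` (two oscillators per unit) or ``"two_osc"`` (one per
        unit).
    e1, e2:
        Between-unit coupling weights, 1/s.  ``e1`` is received by unit 1
        (from unit 2's action oscillator), ``e2`` by unit 2.
    i1, i2:
        Within-unit coupling weights, 1/s (four-oscillator variant only).
    """

    variant: str
    e1: float
    e2: float
    i1: Optional[float] = None
    i2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.variant not in (TWO_OSC, FOUR_OSC):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == FOUR_OSC:
            if self.i1 is None or self.i2 is None:
                raise ValueError("four_osc spec requires i1 and i2")
            weights = (self.i1, self.e1, self.i2, self.e2)
        else:
            if self.i1 is not None or self.i2 is not None:
                raise ValueError("two_osc spec must not define i1/i2")
            weights = (self.e1, self.e2)
        for w in weights:
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"coupling weights must be finite and >= 0, got {w}")

    @property
    def n_oscillators(self) -> int:
        return 4 if self.variant == FOUR_OSC else 2

    def weights(self) -> dict:
        if self.variant == FOUR_OSC:
            return {"i1": self.i1, "e1": self.e1, "i2": self.i2, "e2": self.e2}
        return {"e1": self.e1, "e2": self.e2}

    def swapped_units(self) -> "ModelSpec":
        """The spec with the two units' roles exchanged."""
        if self.variant == FOUR_OSC:
            return ModelSpec(FOUR_OSC, e1=self.e2, e2=self.e1, i1=self.i2, i2=self.i1)
        return ModelSpec(TWO_OSC, e1=self.e2, e2=self.e1)

    def to_dict(self) -> dict:
        return {"variant": self.variant, **self.weights()}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            variant=d["variant"],
            e1=float(d["e1"]),
            e2=float(d["e2"]),
            i1=None if d.get("i1") is None else float(d["i1"]),
            i2=None if d.get("i2") is None else float(d["i2"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, s: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(s))


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical and stochastic settings for one simulation run.

    ``noise_sd`` is the standard deviation (rad) of the phase noise
    accumulated over one nominal tap interval (``noise_ref_interval``,
    500 ms at the 2 Hz tapping rate).  The per-step injection is scaled by
    ``sqrt(dt / noise_ref_interval)`` so the accumulated variance per tap is
    independent of the integration resolution.
    """

    duration: float = 12.0
    dt: float = 0.025
    sample_interval: float = 0.5
    discard: float = 2.0
    freq_mean: float = 2.0
    freq_sd: float = 0.2
    noise_sd: float = SIGMA_DATASET1
    noise_ref_interval: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.dt <= self.sample_interval <= self.duration):
            raise ValueError("require 0 < dt <= sample_interval <= duration")
        if not (0 <= self.discard < self.duration):
            raise ValueError("require 0 <= discard < duration")
        if self.freq_mean <= 0:
            raise ValueError("freq_mean must be > 0")
        if self.freq_sd < 0 or self.noise_sd < 0:
            raise ValueError("freq_sd and noise_sd must be >= 0")
        if self.noise_ref_interval <= 0:
            raise ValueError("noise_ref_interval must be > 0")
        ratio = self.sample_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("sample_interval must be an integer multiple of dt")

    @property
    def steps_per_sample(self) -> int:
        return int(round(self.sample_interval / self.dt))

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def sigma_step(self) -> float:
        """Per-step noise SD implementing the per-tap-interval calibration."""
        return self.noise_sd * np.sqrt(self.dt / self.noise_ref_interval)

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "dt": self.dt,
            "sample_interval": self.sample_interval,
            "discard": self.discard,
            "freq_mean": self.freq_mean,
            "freq_sd": self.freq_sd,
            "noise_sd": self.noise_sd,
            "noise_ref_interval": self.noise_ref_interval,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "SimulationConfig":
        return cls.from_dict(json.loads(s))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, s: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(s))

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def build_coupling_matrix(spec: ModelSpec) -> np.ndarray:
    """Coupling matrix ``K[n, p]``: weight of sender ``p`` onto receiver ``n``.

    Four-oscillator layout (0-based indices): 0 = unit-1 perception,
    1 = unit-1 action, 2 = unit-2 action, 3 = unit-2 perception.  Nonzero
    entries: the bidirectional within-unit pairs (0,1)/(1,0) = ``i1`` and
    (2,3)/(3,2) = ``i2``, plus the unidirectional between-unit links
    (0,2) = ``e1`` (unit-2 action onto unit-1 perception) and (3,1) = ``e2``.

    The two-oscillator variant couples the two units reciprocally:
    ``K = [[0, e1], [e2, 0]]``.
    """
    if spec.variant == TWO_OSC:
        return np.array([[0.0, spec.e1], [spec.e2, 0.0]])
    K = np.zeros((4, 4))
    K[0, 1] = spec.i1
    K[1, 0] = spec.i1
    K[0, 2] = spec.e1
    K[2, 3] = spec.i2
    K[3, 2] = spec.i2
    K[3, 1] = spec.e2
    return K


def draw_frequencies(
    config: SimulationConfig, n_oscillators: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw intrinsic frequencies in rad/s, Normal(2*pi*mean, 2*pi*sd)."""
    return rng.normal(
        TWO_PI * config.freq_mean, TWO_PI * config.freq_sd, size=n_oscillators
    )


@dataclass
class PhaseTrajectory:
    """Sampled unwrapped phases of one simulation run.

    Attributes
    ----------
    times:
        Sample times in s, uniformly spaced by ``config.sample_interval``,
        starting at 0.
    phases:
        Array of shape (n_samples, n_oscillators), unwrapped phase in rad.
    frequencies:
        Drawn intrinsic frequency per oscillator, rad/s.
    """

    times: np.ndarray
    phases: np.ndarray
    frequencies: np.ndarray
    spec: ModelSpec
    config: SimulationConfig
    seed: Optional[int] = None

    @property
    def n_oscillators(self) -> int:
        return self.phases.shape[1]

    def to_csv(self, path, sidecar_path=None) -> None:
        """Write the sampled phases as CSV with a JSON metadata sidecar."""
        import pandas as pd

        cols = {"time_s": self.times}
        for j in range(self.n_oscillators):
            cols[f"phase_osc{j + 1}_rad"] = self.phases[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)
        if sidecar_path is None:
            sidecar_path = str(path) + ".json"
        meta = {
            "spec": self.spec.to_dict(),
            "config": self.config.to_dict(),
            "seed": self.seed,
            "frequencies_rad_s": [float(f) for f in self.frequencies],
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)


@dataclass
class PhaseEnsemble:
    """Sampled phases of a batch of independent runs (trials).

    ``phases`` has shape (n_trials, n_samples, n_oscillators) and
    ``frequencies`` shape (n_trials, n_oscillators).
    """

    times: np.ndarray
    phases: np.ndarray
    frequencies: np.ndarray
    spec: ModelSpec
    config: SimulationConfig

    @property
    def n_trials(self) -> int:
        return self.phases.shape[0]

    def trajectory(self, i: int) -> PhaseTrajectory:
        return PhaseTrajectory(
            times=self.times,
            phases=self.phases[i],
            frequencies=self.frequencies[i],
            spec=self.spec,
            config=self.config,
        )


def _euler_maruyama(
    K: np.ndarray,
    omega: np.ndarray,
    theta0: np.ndarray,
    dt: float,
    n_steps: int,
    record_every: int,
    sigma_step: float,
    rng: Optional[np.random.Generator],
    noise: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Integrate the batched Kuramoto SDE, recording every ``record_every`` steps.

    ``theta0`` and ``omega`` have shape (B, n); returns (B, n_records, n)
    including the initial state as the first record.  ``noise`` may supply
    the per-step increments explicitly, shape (n_steps, B, n).
    """
    B, n = theta0.shape
    n_records = n_steps // record_every + 1
    out = np.empty((B, n_records, n))
    theta = np.array(theta0, dtype=float)
    out[:, 0] = theta
    if noise is None and sigma_step > 0:
        if rng is None:
            raise ValueError("rng required when sigma_step > 0 and no noise given")
        noise = rng.normal(0.0, sigma_step, size=(n_steps, B, n))
    rec = 1
    for step in range(1, n_steps + 1):
        diffs = np.sin(theta[:, None, :] - theta[:, :, None])  # [b, n, p]
        drift = omega + np.einsum("np,bnp->bn", K, diffs)
        theta = theta + drift * dt
        if noise is not None:
            theta = theta + noise[step - 1]
        if step % record_every == 0:
            if not np.all(np.isfinite(theta)):
                raise IntegrationError(f"non-finite phase at step {step}")
            out[:, rec] = theta
            rec += 1
    return out


def integrate_ensemble(
    spec: ModelSpec,
    config: SimulationConfig,
    n_trials: int,
    rng: Optional[np.random.Generator] = None,
    *,
    initial_phases: Optional[np.ndarray] = None,
    frequencies: Optional[np.ndarray] = None,
    noise: Optional[np.ndarray] = None,
) -> PhaseEnsemble:
    """Simulate ``n_trials`` independent runs of the model.

    Initial phases are Uniform[0, 2*pi) and intrinsic frequencies
    Normal(2*pi*freq_mean, 2*pi*freq_sd), drawn fresh per trial unless
    supplied explicitly (the overrides exist for exact reproducibility and
    symmetry checks).  Returned phases are unwrapped: the integrator never
    wraps, so multiples of 2*pi accumulate.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = spec.n_oscillators
    K = build_coupling_matrix(spec)
    if initial_phases is None:
        initial_phases = rng.uniform(0.0, TWO_PI, size=(n_trials, n))
    else:
        initial_phases = np.asarray(initial_phases, dtype=float).reshape(n_trials, n)
    if frequencies is None:
        frequencies = rng.normal(
            TWO_PI * config.freq_mean, TWO_PI * config.freq_sd, size=(n_trials, n)
        )
    else:
        frequencies = np.asarray(frequencies, dtype=float).reshape(n_trials, n)
    phases = _euler_maruyama(
        K,
        frequencies,
        initial_phases,
        config.dt,
        config.n_steps,
        config.steps_per_sample,
        config.sigma_step,
        rng,
        noise=noise,
    )
    n_records = phases.shape[1]
    times = np.arange(n_records) * config.sample_interval
    return PhaseEnsemble(
        times=times, phases=phases, frequencies=frequencies, spec=spec, config=config
    )


def integrate(
    spec: ModelSpec,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    *,
    initial_phases: Optional[np.ndarray] = None,
    frequencies: Optional[np.ndarray] = None,
    noise: Optional[np.ndarray] = None,
) -> PhaseTrajectory:
    """Simulate a single run; see :func:`integrate_ensemble`."""
    seed = config.seed if rng is None else None
    if noise is not None:
        noise = np.asarray(noise, dtype=float)
        if noise.ndim == 2:  # (n_steps, n) for a single trial
            noise = noise[:, None, :]
    ens = integrate_ensemble(
        spec,
        config,
        1,
        rng,
        initial_phases=None if initial_phases is None else np.asarray(initial_phases)[None, :],
        frequencies=None if frequencies is None else np.asarray(frequencies)[None, :],
        noise=noise,
    )
    traj = ens.trajectory(0)
    traj.seed = seed
    return traj
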