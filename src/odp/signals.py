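"""Synthetic corneal-pulse-like signals and harmonic test signals.

The corneal pulse (CP) is a micrometre-scale cyclic displacement of the
corneal surface driven by the cardiovascular system, recorded without
contact by an ultrasonic distance sensor.  Real recordings are 10 s long,
sampled at 400 Hz, and contain a ~1 Hz cardiac fundamental with harmonics,
a 0.2-0.3 Hz respiratory component, wide-band measurement noise, and
cycle-to-cycle variability in period and shape.  The ocular dicrotic pulse
(ODP) appears as a double peak within a cardiac cycle.

This module generates the reference harmonic test signals (1 Hz sinusoid,
1 Hz + 2 Hz composite, additive white Gaussian noise at a prescribed SNR,
additive 0.3 Hz breathing component) and labelled CP-like dicrotic /
non-dicrotic signals, so that every downstream stage of the pipeline can
be exercised without any recorded data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Signal",
    "SynthConfig",
    "DEFAULT_CP_CONFIG",
    "harmonic",
    "add_noise",
    "add_breathing",
    "derivative",
    "simulate_cp",
    "make_dataset",
    "ConfigError",
]

DICROTIC = "dicrotic"
NON_DICROTIC = "non_dicrotic"
UNKNOWN = "unknown"
LABELS = (DICROTIC, NON_DICROTIC)


class ConfigError(ValueError):
    """Raised for inconsistent synthesis or run configuration."""


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples : ndarray
        Displacement values (arbitrary units); must be finite, length >= 2.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        One of ``"dicrotic"``, ``"non_dicrotic"``, ``"unknown"``.
    id : str
        Free-text identifier.
    """

    samples: np.ndarray
    fs: float
    label: str = UNKNOWN
    id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise ConfigError("signal must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ConfigError("signal contains non-finite samples")
        if self.label not in (DICROTIC, NON_DICROTIC, UNKNOWN):
            raise ConfigError(f"unknown label {self.label!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def replace(self, **kwargs) -> "Signal":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic-signal generator.

    Defaults match the acquisition protocol of the real recordings:
    10 s at 400 Hz, unit fundamental amplitude, zero mean.  ``snr_db`` is
    the target signal-to-noise ratio in dB (``inf`` disables noise);
    ``breathing_amp`` of 0 disables the respiratory component.
    """

    fs: float = 400.0
    duration: float = 10.0
    component_freqs: tuple[float, ...] = (1.0,)
    component_amps: tuple[float, ...] = (1.0,)
    component_phases: tuple[float, ...] | None = None
    snr_db: float = math.inf
    breathing_freq: float = 0.3
    breathing_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.component_freqs)
        amps = tuple(float(a) for a in self.component_amps)
        object.__setattr__(self, "component_freqs", freqs)
        object.__setattr__(self, "component_amps", amps)
        phases = self.component_phases
        if phases is None:
            phases = (0.0,) * len(freqs)
        phases = tuple(float(p) for p in phases)
        object.__setattr__(self, "component_phases", phases)
        if not (len(freqs) == len(amps) == len(phases)):
            raise ConfigError(
                "component_freqs, component_amps and component_phases must "
                f"have equal lengths (got {len(freqs)}, {len(amps)}, {len(phases)})"
            )
        if self.fs <= 0 or self.duration <= 0:
            raise ConfigError("fs and duration must be positive")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(f"duration*fs must be an integer sample count, got {n}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


#: Study conditions used for the labelled CP-like dataset: 25 dB SNR,
#: additive 0.3 Hz breathing at half the fundamental amplitude.
DEFAULT_CP_CONFIG = SynthConfig(snr_db=25.0, breathing_amp=0.5)


def harmonic(config: SynthConfig) -> Signal:
    """Sum-of-sinusoids test signal, noise and breathing disabled.

    ``samples[t] = sum_k amps[k] * sin(2*pi*freqs[k]*t/fs + phases[k])``.
    """
    t = np.arange(config.n_samples) / config.fs
    x = np.zeros_like(t)
    for f, a, p in zip(
        config.component_freqs, config.component_amps, config.component_phases
    ):
        x += a * np.sin(2 * np.pi * f * t + p)
    return Signal(x, config.fs, id="harmonic")


def _signal_power(x: np.ndarray) -> float:
    # power about the mean: a DC offset carries no signal information here
    return float(np.mean((x - x.mean()) ** 2))


def noise_variance(x: np.ndarray, snr_db: float) -> float:
    """Noise variance achieving ``snr_db`` dB against the power of ``x``."""
    return _signal_power(x) / 10.0 ** (snr_db / 10.0)


def add_noise(
    signal: Signal, snr_db: float, seed: int | np.random.Generator = 0
) -> Signal:
    """Add white Gaussian noise at the given SNR (dB); ``inf`` is a no-op.

    SNR is defined as ``10*log10(P_signal / P_noise)`` with signal power
    taken about the signal mean.
    """
    if math.isinf(snr_db):
        return signal
    power = _signal_power(signal.samples)
    if power == 0.0:
        raise ConfigError("cannot set a finite SNR on a zero-power signal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = math.sqrt(power / 10.0 ** (snr_db / 10.0))
    return signal.replace(samples=signal.samples + rng.normal(0.0, sigma, signal.n))


def add_breathing(
    signal: Signal, freq: float = 0.3, amp: float = 0.5, mode: str = "additive"
) -> Signal:
    """Superimpose a slow respiratory component.

    ``mode="additive"`` (default) adds ``amp*sin(2*pi*freq*t)``;
    ``mode="multiplicative"`` modulates the signal by ``1 + amp*sin(...)``
    instead, for experiments on amplitude-modulated respiration.
    """
    if freq >= signal.fs / 2:
        raise ConfigError(f"breathing frequency {freq} Hz exceeds Nyquist")
    carrier = np.sin(2 * np.pi * freq * signal.times)
    if mode == "additive":
        out = signal.samples + amp * carrier
    elif mode == "multiplicative":
        out = signal.samples * (1.0 + amp * carrier)
    else:
        raise ConfigError(f"unknown breathing mode {mode!r}")
    return signal.replace(samples=out)


def derivative(signal: Signal) -> Signal:
    """Central-difference derivative, same length and sampling rate.

    The wavelet analysis matches pulse features on the derivative of the
    recorded trace; the transform is scale-invariant so the derivative is
    left in per-sample units.
    """
    return signal.replace(samples=np.gradient(signal.samples))


# -- CP-like cycle synthesis -------------------------------------------------

#: Relative second-harmonic amplitude of the dicrotic / non-dicrotic cycle
#: templates, and its phase offset.  r=0.5 produces a morphologically clear
#: double peak; r=0.05 keeps the cycle single-peaked.
DICROTIC_HARMONIC = 0.5
NON_DICROTIC_HARMONIC = 0.05
HARMONIC_PHASE = np.pi / 3


def _cycle_template(u: np.ndarray, dicrotic: bool, amp: float) -> np.ndarray:
    r = DICROTIC_HARMONIC if dicrotic else NON_DICROTIC_HARMONIC
    return amp * (
        np.sin(2 * np.pi * u) + r * np.sin(4 * np.pi * u + HARMONIC_PHASE)
    )


def simulate_cp(
    dicrotic: bool,
    config: SynthConfig = DEFAULT_CP_CONFIG,
    jitter: float = 0.05,
    seed: int = 0,
) -> Signal:
    """Generate one labelled CP-like signal.

    Cardiac-like cycles with nominal period ``1/component_freqs[0]`` are
    concatenated; each cycle's period is perturbed by a uniform factor in
    ``[1-jitter, 1+jitter]`` and the unit-period analytic template is
    evaluated on the jittered grid.  Dicrotic cycles carry a strong second
    harmonic producing a double peak per cycle; non-dicrotic cycles are
    single-peaked.  Breathing and additive white Gaussian noise are applied
    per ``config``.  Reproducible given ``seed``.
    """
    if not 0.0 <= jitter <= 0.2:
        raise ConfigError(f"jitter must lie in [0, 0.2], got {jitter}")
    rng = np.random.default_rng(seed)
    n = config.n_samples
    period = 1.0 / config.component_freqs[0]
    amp = config.component_amps[0]

    chunks: list[np.ndarray] = []
    total = 0
    while total < n:
        m = int(round(period * config.fs * (1.0 + jitter * rng.uniform(-1, 1))))
        m = max(m, 2)
        u = np.arange(m) / m
        chunks.append(_cycle_template(u, dicrotic, amp))
        total += m
    x = np.concatenate(chunks)[:n]

    label = DICROTIC if dicrotic else NON_DICROTIC
    sig = Signal(x, config.fs, label=label, id=f"cp-{label}-{seed}")
    if config.breathing_amp:
        sig = add_breathing(sig, config.breathing_freq, config.breathing_amp * amp)
    if not math.isinf(config.snr_db):
        sig = add_noise(sig, config.snr_db, rng)
    return sig


def make_dataset(
    n_per_class: int,
    config: SynthConfig = DEFAULT_CP_CONFIG,
    jitter: float = 0.05,
    seed: int = 0,
) -> list[Signal]:
    """Balanced collection of ``2*n_per_class`` labelled CP-like signals.

    Per-signal seeds are spawned deterministically from the master seed,
    so the same master seed always yields the identical collection.
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] >> 1)
    child_seeds = [(base + i) % 2**31 for i in range(2 * n_per_class)]
    signals = []
    for i, child in enumerate(child_seeds):
        dic = i < n_per_class
        signals.append(simulate_cp(dic, config, jitter=jitter, seed=child))
    return signals
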