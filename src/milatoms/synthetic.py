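"""Synthetic motor-imagery EEG with a class-dependent ERD effect.

The generator emulates the statistical structure the whole pipeline relies
on: a small number of band-limited oscillatory sources are mixed linearly to
the sensor montage, and exactly one source carries the class information as
an event-related desynchronization (ERD) — its variance inside a known
mu-band and a known sub-interval of the trial is reduced for one class.
Everything else (1/f background sources, white sensor noise) is class
independent, so recovery tests can check that the method finds the planted
band, interval and spatial pattern and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import ParameterError
from .preprocess import EEGTrialSet

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset"]

#: length of the raised-cosine amplitude ramps flanking the ERD interval (s)
RAMP_S = 0.1


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic ERD dataset.

    Defaults mirror a 22-channel, 250 Hz motor-imagery recording with 72
    trials per class and a mu-band (10-13 Hz) desynchronization sustained
    over most of a 2 s analysis segment: the ERD sets in after a ~250 ms
    onset latency and persists while the movement is imagined, which is the
    typical time course; pass a shorter ``erd_interval`` to emulate a
    transient response instead.  ``erd_depth`` is the ratio of class -1 to
    class +1 source variance inside the ERD band and interval; 0.3 is a
    deep but physiologically plausible desynchronization.
    """

    n_channels: int = 22
    fs: float = 250.0
    trial_len: float = 2.0
    n_trials_per_class: int = 72
    erd_band: tuple[float, float] = (10.0, 13.0)
    erd_depth: float = 0.3
    erd_interval: tuple[float, float] = (0.25, 1.75)
    n_background_sources: int = 8
    noise_snr_db: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        n = self.trial_len * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ParameterError("trial_len * fs must be an integer sample count")
        lo, hi = self.erd_band
        if not (0 < lo < hi < self.fs / 2):
            raise ParameterError(
                f"erd_band {self.erd_band} must satisfy 0 < low < high < Nyquist"
            )
        if not self.erd_depth > 0:
            raise ParameterError("erd_depth must be positive")
        a, b = self.erd_interval
        if not (0.0 <= a < b <= self.trial_len):
            raise ParameterError("erd_interval must lie within the trial")
        if self.n_channels < 1 or self.n_trials_per_class < 1:
            raise ParameterError("counts must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_len * self.fs))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery tests."""

    mixing_matrix: np.ndarray  # channels x sources, unit-norm columns
    discriminative_source_index: int
    erd_interval_samples: tuple[int, int]
    erd_band: tuple[float, float]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int,
                fs: float) -> np.ndarray:
    """1/f-shaped noise along the last axis, unit variance per row."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _erd_envelope(cfg: SyntheticConfig) -> np.ndarray:
    """Amplitude envelope applying the ERD to the affected class.

    Inside ``erd_interval`` the amplitude is exactly ``sqrt(erd_depth)``;
    raised-cosine ramps of 100 ms sit *outside* the interval so that the
    in-interval variance ratio equals ``erd_depth``, while avoiding the edge
    artifacts a hard gate would excite in later band-pass filtering.
    """
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    a, b = cfg.erd_interval
    depth_amp = np.sqrt(cfg.erd_depth)
    env = np.ones(n)
    inside = (t >= a) & (t < b)
    env[inside] = depth_amp
    ramp_in = (t >= a - RAMP_S) & (t < a)
    x = (t[ramp_in] - (a - RAMP_S)) / RAMP_S  # 0 -> 1 approaching the interval
    env[ramp_in] = 1.0 + (depth_amp - 1.0) * (1 - np.cos(np.pi * x)) / 2.0
    ramp_out = (t >= b) & (t < b + RAMP_S)
    x = (t[ramp_out] - b) / RAMP_S
    env[ramp_out] = depth_amp + (1.0 - depth_amp) * (1 - np.cos(np.pi * x)) / 2.0
    return env


def generate_dataset(config: SyntheticConfig) -> tuple[EEGTrialSet, GroundTruth]:
    """Generate a balanced, labeled synthetic ERD dataset.

    Source 0 is the discriminative one: white noise band-pass filtered to
    ``erd_band`` (zero-phase), normalized to unit variance per trial, and
    multiplied by the ERD envelope for class -1 trials only.  Background
    sources are 1/f noise, identical in distribution for both classes.
    Sources are mixed through a seeded column-normalized Gaussian matrix and
    white sensor noise is added to reach ``noise_snr_db``.  Fully reproducible
    from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    C, n, fs = config.n_channels, config.n_samples, config.fs
    R = 2 * config.n_trials_per_class
    S = 1 + config.n_background_sources

    # mixing matrix: drawn once, unit-norm columns, full column rank
    for _ in range(100):
        A = rng.standard_normal((C, S))
        if np.linalg.matrix_rank(A) == min(C, S):
            break
    A = A / np.linalg.norm(A, axis=0, keepdims=True)

    sos = signal.butter(4, config.erd_band, btype="bandpass", fs=fs,
                        output="sos")
    disc = signal.sosfiltfilt(sos, rng.standard_normal((R, n)), axis=-1)
    disc = disc / disc.std(axis=-1, keepdims=True)

    labels = np.r_[np.ones(config.n_trials_per_class, dtype=np.int64),
                   -np.ones(config.n_trials_per_class, dtype=np.int64)]
    env = _erd_envelope(config)
    disc = np.where((labels == -1)[:, None], disc * env[None, :], disc)

    background = _pink_noise(rng, (R, config.n_background_sources), n, fs)
    sources = np.concatenate([disc[:, None, :], background], axis=1)

    data = np.einsum("cs,rsn->rcn", A, sources)
    p_signal = np.mean(data ** 2)
    noise_sd = np.sqrt(p_signal / 10.0 ** (config.noise_snr_db / 10.0))
    data = data + noise_sd * rng.standard_normal(data.shape)

    order = rng.permutation(R)
    trials = EEGTrialSet(data=data[order], labels=labels[order], fs=fs)
    truth = GroundTruth(
        mixing_matrix=A,
        discriminative_source_index=0,
        erd_interval_samples=(int(round(config.erd_interval[0] * fs)),
                              int(round(config.erd_interval[1] * fs))),
        erd_band=config.erd_band,
    )
    return trials, truth
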