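"""Filter-bank decomposition and overlapped time windowing of EEG trials.

The raw input of the pipeline is a set of labeled multichannel trials at a
fixed sampling rate (:class:`EEGTrialSet`).  Preprocessing turns each trial
into a time-frequency tensor: the signal is band-pass filtered through a bank
of overlapped Butterworth filters and then cut into heavily overlapped short
time windows.  Each (band, window) cell later yields one block of a
"time-frequency atom".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .exceptions import DataError, ParameterError

__all__ = [
    "EEGTrialSet",
    "FilterBankConfig",
    "WindowScheme",
    "design_filter_bank",
    "apply_filter_bank",
    "plan_windows",
    "segment_trials",
]


@dataclass
class EEGTrialSet:
    """Labeled multichannel EEG trials of equal length.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial signals in volts (or any consistent unit; the pipeline is
        amplitude-scale invariant).
    labels : ndarray, shape (n_trials,)
        Class labels, restricted to {+1, -1} (e.g. left hand / right hand).
    fs : float
        Sampling rate in Hz.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise DataError("data must be (trials, channels, samples)")
        if self.labels.shape != (self.data.shape[0],):
            raise DataError("labels must have one entry per trial")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise DataError("labels must be +1 or -1")
        if not self.fs > 0:
            raise DataError("sampling rate must be positive")
        self.labels = self.labels.astype(np.int64)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def save(self, path: str | Path) -> None:
        """Write the trial set to a single ``.npz`` container."""
        np.savez(Path(path), data=self.data, labels=self.labels, fs=self.fs)

    @classmethod
    def load(cls, path: str | Path) -> "EEGTrialSet":
        with np.load(Path(path)) as f:
            return cls(data=f["data"], labels=f["labels"], fs=float(f["fs"]))


@dataclass(frozen=True)
class FilterBankConfig:
    """Bank of overlapped band-pass filters covering ``[f_min, f_max]`` Hz."""

    f_min: float
    f_max: float
    bandwidth: float
    step: float
    order: int = 5
    bands: tuple[tuple[float, float], ...] = field(default=())

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def centers(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.bands])


def design_filter_bank(
    f_min: float, f_max: float, bandwidth: float, step: float, order: int = 5
) -> FilterBankConfig:
    """Lay out overlapped band edges covering ``[f_min, f_max]``.

    Band i spans ``(f_min + i*step, f_min + i*step + bandwidth)``; the number
    of bands ``(f_max - f_min - bandwidth)/step + 1`` must come out a positive
    integer, otherwise the bank does not tile the range and a
    :class:`ParameterError` is raised.  The default 4-40 Hz bank with 4 Hz
    bandwidth and 2 Hz step yields 17 bands.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    if f_min + bandwidth > f_max:
        raise ParameterError("f_min + bandwidth must not exceed f_max")
    count_f = (f_max - f_min - bandwidth) / step + 1.0
    count = int(round(count_f))
    if abs(count_f - count) > 1e-9 or count < 1:
        raise ParameterError(
            f"({f_max}-{f_min}-{bandwidth})/{step}+1 = {count_f} is not a "
            "positive integer band count"
        )
    bands = tuple(
        (f_min + i * step, f_min + i * step + bandwidth) for i in range(count)
    )
    return FilterBankConfig(f_min, f_max, bandwidth, step, order, bands)


def apply_filter_bank(
    trials: EEGTrialSet, bank: FilterBankConfig, causal: bool = False
) -> np.ndarray:
    """Band-pass each channel through every filter of the bank.

    Filtering is zero-phase (forward-backward) by default so that rhythm
    envelopes are not delayed; pass ``causal=True`` for single-pass filtering.

    Returns
    -------
    ndarray, shape (n_trials, n_bands, n_channels, n_samples)
    """
    nyq = trials.fs / 2.0
    if bank.bands and bank.bands[-1][1] >= nyq:
        raise ParameterError(
            f"filter bank upper edge {bank.bands[-1][1]} Hz is at or above "
            f"Nyquist ({nyq} Hz)"
        )
    out = np.empty(
        (trials.n_trials, bank.n_bands, trials.n_channels, trials.n_samples)
    )
    for i, (lo, hi) in enumerate(bank.bands):
        sos = signal.butter(bank.order, (lo, hi), btype="bandpass",
                            fs=trials.fs, output="sos")
        if causal:
            out[:, i] = signal.sosfilt(sos, trials.data, axis=-1)
        else:
            out[:, i] = signal.sosfiltfilt(sos, trials.data, axis=-1)
    return out


def _snap_ceil(x: float) -> int:
    # guard against float dust around exact values (e.g. 7.5 or 5.0)
    return math.ceil(round(x, 9))


@dataclass(frozen=True)
class WindowScheme:
    """Placement of overlapped analysis windows inside a segment."""

    tau: float
    overlap: float
    fs: float
    win_samples: int
    step_samples: int
    n_windows: int
    starts: tuple[int, ...]

    @property
    def centers_s(self) -> np.ndarray:
        """Window center times in seconds, relative to the segment start."""
        return (np.asarray(self.starts) + (self.win_samples - 1) / 2.0) / self.fs


def plan_windows(
    segment_len_samples: int, tau: float, fs: float, overlap: float = 0.9
) -> WindowScheme:
    """Plan the overlapped windows of length ``tau`` seconds over a segment.

    The window hop is ``ceil((1 - overlap) * tau * fs)`` samples, and windows
    are placed at ``0, step, 2*step, ...`` as long as they fit entirely inside
    the segment.  With a 500-sample segment at 250 Hz and 90% overlap this
    yields 91 windows at tau=0.2 s down to a single window at tau=2.0 s.
    """
    win = int(round(tau * fs))
    if win < 1:
        raise ParameterError("window shorter than one sample")
    if win > segment_len_samples:
        raise ParameterError(
            f"window of {win} samples exceeds segment of {segment_len_samples}"
        )
    if not (0.0 <= overlap < 1.0):
        raise ParameterError("overlap must be in [0, 1)")
    step = _snap_ceil((1.0 - overlap) * tau * fs)
    step = max(step, 1)
    n_windows = (segment_len_samples - win) // step + 1
    starts = tuple(range(0, segment_len_samples - win + 1, step))
    assert len(starts) == n_windows
    return WindowScheme(tau, overlap, fs, win, step, n_windows, starts)


def segment_trials(filtered: np.ndarray, scheme: WindowScheme) -> np.ndarray:
    """Cut band-filtered trials into the planned overlapped windows.

    Parameters
    ----------
    filtered : ndarray, shape (..., n_samples)
        Typically (trials, bands, channels, samples) from
        :func:`apply_filter_bank`.

    Returns
    -------
    ndarray, shape (trials, bands, n_windows, channels, win_samples)
        Window i holds samples ``[starts[i], starts[i] + win_samples)``.
    """
    L = filtered.shape[-1]
    if scheme.starts[-1] + scheme.win_samples > L:
        raise ParameterError("window scheme was planned for a longer segment")
    parts = [filtered[..., s:s + scheme.win_samples] for s in scheme.starts]
    # (trials, bands, channels, win) stacked on a new window axis before channels
    return np.stack(parts, axis=-3)
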