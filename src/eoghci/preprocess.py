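"""Notch filtering and 2-Hz band decomposition of EOG trials.

Each trial channel is (optionally) notch-filtered at the mains
frequency and then split into eight contiguous 2-Hz bands covering
0.1-16 Hz with zero-phase Butterworth band-pass filters.  The band
signals are the inputs to the convolution-theorem feature extractor.

The notch deserves a note: at the protocol rate of 100 Hz, 50 Hz mains
sits exactly at Nyquist, where a conventional IIR notch is degenerate.
For that case the notch reduces to zeroing the Nyquist bin of the real
FFT; below Nyquist a standard IIR notch (forward-backward, zero phase)
is used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .synthetic import TrialRecord

__all__ = [
    "BAND_EDGES",
    "PreprocessConfig",
    "BandDecomposition",
    "PreprocessError",
    "notch_filter",
    "band_split",
    "preprocess_trial",
]


class PreprocessError(ValueError):
    """Invalid filtering input (bad rates, too-short signal...)."""


#: The eight 2-Hz analysis bands (low, high) in Hz.
BAND_EDGES: Tuple[Tuple[float, float], ...] = (
    (0.1, 2.0), (2.0, 4.0), (4.0, 6.0), (6.0, 8.0),
    (8.0, 10.0), (10.0, 12.0), (12.0, 14.0), (14.0, 16.0),
)

#: Shortest signal the band splitter accepts (filter warm-up).
MIN_SIGNAL_LENGTH = 16

_NOTCH_Q = 30.0


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering configuration.

    ``filter_order`` is the overall band-pass order (4 = the default
    4th-order Butterworth, i.e. 2 pole pairs per edge).
    """

    sampling_rate: float = 100.0
    notch_enabled: bool = True
    notch_freq: float = 50.0
    band_edges: Tuple[Tuple[float, float], ...] = BAND_EDGES
    filter_order: int = 4

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["band_edges"] = [list(e) for e in self.band_edges]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PreprocessConfig":
        d = json.loads(text)
        d["band_edges"] = tuple(tuple(e) for e in d["band_edges"])
        return cls(**d)


@dataclass
class BandDecomposition:
    """8 bands x 2 channels of band-limited signals for one trial.

    ``bands[b, j]`` is band ``b`` (0-based; band_edges[b]) of channel
    ``j`` (0 = horizontal, 1 = vertical), same length as the input
    trial.
    """

    trial_ref: str
    bands: np.ndarray  # shape (8, 2, n)
    band_edges: Tuple[Tuple[float, float], ...] = BAND_EDGES


@lru_cache(maxsize=None)
def _band_sos(low: float, high: float, fs: float, order: int) -> np.ndarray:
    # order//2 pole pairs -> overall band-pass order `order`
    return sps.butter(max(order // 2, 1), [low, high],
                      btype="bandpass", fs=fs, output="sos")


@lru_cache(maxsize=None)
def _notch_ba(freq: float, fs: float) -> tuple:
    b, a = sps.iirnotch(freq, _NOTCH_Q, fs=fs)
    return tuple(b), tuple(a)


def notch_filter(x: Sequence[float], mains_freq: float,
                 sampling_rate: float) -> np.ndarray:
    """Remove a narrow mains-frequency component, zero phase.

    At ``mains_freq == sampling_rate/2`` (the degenerate Nyquist case)
    the highest real-FFT bin is zeroed instead of running an IIR notch.
    """
    x = np.asarray(x, dtype=float)
    if sampling_rate <= 0:
        raise PreprocessError("sampling_rate must be > 0")
    nyq = sampling_rate / 2.0
    if not (0 < mains_freq <= nyq):
        raise PreprocessError(
            f"mains_freq {mains_freq} Hz outside (0, Nyquist={nyq} Hz]")
    n = len(x)
    if n < 2:
        raise PreprocessError("signal too short to notch-filter")
    if mains_freq >= nyq * (1 - 1e-12):
        spec = np.fft.rfft(x)
        spec[-1] = 0.0
        return np.fft.irfft(spec, n=n)
    b, a = _notch_ba(float(mains_freq), float(sampling_rate))
    padlen = min(n - 1, 3 * max(len(b), len(a)))
    return sps.filtfilt(np.asarray(b), np.asarray(a), x, padlen=padlen)


def band_split(x: Sequence[float], sampling_rate: float,
               band_edges: Tuple[Tuple[float, float], ...] = BAND_EDGES,
               filter_order: int = 4) -> np.ndarray:
    """Split a signal into the eight 2-Hz bands.

    Returns an array of shape ``(len(band_edges), len(x))``; each row is
    the zero-phase (forward-backward) Butterworth band-pass output for
    one band.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise PreprocessError("band_split expects a 1-D signal")
    if len(x) < MIN_SIGNAL_LENGTH:
        raise PreprocessError(
            f"signal of {len(x)} samples is shorter than the minimum "
            f"filterable length ({MIN_SIGNAL_LENGTH})")
    out = np.empty((len(band_edges), len(x)), dtype=float)
    for b, (low, high) in enumerate(band_edges):
        sos = _band_sos(float(low), float(high), float(sampling_rate),
                        int(filter_order))
        padlen = min(len(x) - 1, 3 * (2 * sos.shape[0] + 1))
        out[b] = sps.sosfiltfilt(sos, x, padlen=padlen)
    return out


def preprocess_trial(trial: TrialRecord,
                     config: PreprocessConfig = PreprocessConfig()
                     ) -> BandDecomposition:
    """Notch (when enabled) then band-split both channels of a trial."""
    trial.validate()
    fs = config.sampling_rate
    channels = []
    for ch in (trial.horizontal, trial.vertical):
        y = np.asarray(ch, dtype=float)
        if config.notch_enabled:
            y = notch_filter(y, config.notch_freq, fs)
        channels.append(band_split(y, fs, config.band_edges,
                                   config.filter_order))
    bands = np.stack(channels, axis=1)  # (8, 2, n)
    ref = f"{trial.subject_id}/{trial.task.value}/{trial.trial_index}"
    return BandDecomposition(trial_ref=ref, bands=bands,
                             band_edges=config.band_edges)
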