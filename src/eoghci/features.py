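"""Convolution-theorem feature extraction.

Per band and channel the feature is the summed pointwise product of the
signal's DFT with the DFT of its time reversal:

    f(x) = Re sum_k  X[k] * R[k],   X = DFT(x), R = DFT(reverse(x)).

For real x this is analytically real and, by the DFT reversal identity
combined with Wiener-Khinchin, equals

    f(x) = N * sum_n x[n] * x[(n+1) mod N],

i.e. N times the circular autocorrelation at lag 1 — a closed form used
as the independent oracle in the tests.  Two channels x eight bands
give the 16-dimensional trial feature vector, min-max normalized to
[0, 1] on the training split.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import BandDecomposition

__all__ = [
    "FeatureError",
    "FeatureVector",
    "NormalizationState",
    "reverse_signal",
    "convolution_feature",
    "extract_features",
    "fit_normalizer",
    "apply_normalizer",
    "write_features_csv",
    "read_features_csv",
    "FEATURE_COLUMNS",
]

N_FEATURES = 16
FEATURE_COLUMNS = [f"f{i:02d}" for i in range(1, N_FEATURES + 1)]


class FeatureError(ValueError):
    """Invalid feature-extraction input."""


@dataclass
class FeatureVector:
    """The 16 per-trial features, channel-major.

    ``values[c*8 + b]`` is band ``b+1`` of channel ``c`` (0 horizontal,
    1 vertical).
    """

    trial_ref: str
    values: np.ndarray
    normalized: bool = False


def reverse_signal(x: Sequence[float]) -> np.ndarray:
    """Time-reverse a signal; reverse(reverse(x)) == x."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise FeatureError("cannot reverse an empty signal")
    return x[::-1].copy()


def convolution_feature(x_band: Sequence[float]) -> float:
    """The per-band scalar: Re sum_k DFT(x)[k] * DFT(reverse(x))[k]."""
    x = np.asarray(x_band, dtype=float)
    if x.size < 2:
        raise FeatureError("convolution_feature needs at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise FeatureError("non-finite input signal")
    spec = np.fft.fft(x)
    rspec = np.fft.fft(x[::-1])
    s = np.sum(spec * rspec)
    # analytically real for real input; assert the numerical residual
    tol = 1e-9 * max(abs(s.real), 1.0)
    if abs(s.imag) > tol:
        raise FeatureError(
            f"imaginary residual {s.imag:.3e} exceeds tolerance {tol:.3e}")
    return float(s.real)


def extract_features(decomp: BandDecomposition) -> FeatureVector:
    """Assemble the 16-feature vector from an 8-band, 2-channel decomposition."""
    bands = np.asarray(decomp.bands, dtype=float)
    if bands.ndim != 3 or bands.shape[0] != 8 or bands.shape[1] != 2:
        raise FeatureError(
            f"expected bands of shape (8, 2, n), got {bands.shape}")
    values = np.empty(N_FEATURES, dtype=float)
    for c in range(2):
        for b in range(8):
            values[c * 8 + b] = convolution_feature(bands[b, c])
    return FeatureVector(trial_ref=decomp.trial_ref, values=values,
                         normalized=False)


# --------------------------------------------------------------------------
# Min-max normalization (fit on the training split only by default)
# --------------------------------------------------------------------------

@dataclass
class NormalizationState:
    """Per-feature min/max of the fitted (training) data."""

    min_: np.ndarray
    max_: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map rows of X to [0, 1]; degenerate features map to 0.5."""
        X = np.asarray(X, dtype=float)
        span = self.max_ - self.min_
        degenerate = span == 0
        safe = np.where(degenerate, 1.0, span)
        out = np.clip((X - self.min_) / safe, 0.0, 1.0)
        if np.any(degenerate):
            out[..., degenerate] = 0.5
        return out

    def to_json(self) -> str:
        return json.dumps({"min": self.min_.tolist(),
                           "max": self.max_.tolist()}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NormalizationState":
        d = json.loads(text)
        return cls(min_=np.asarray(d["min"], dtype=float),
                   max_=np.asarray(d["max"], dtype=float))


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.atleast_2d(np.asarray(features, dtype=float))
    return np.vstack([np.asarray(f.values, dtype=float) for f in features])


def fit_normalizer(train_features) -> NormalizationState:
    """Fit per-feature min/max; accepts FeatureVectors or an (n, 16) array."""
    X = _as_matrix(list(train_features)
                   if not isinstance(train_features, np.ndarray)
                   else train_features)
    if X.shape[0] < 2:
        raise FeatureError("fit_normalizer needs at least 2 feature vectors")
    return NormalizationState(min_=X.min(axis=0), max_=X.max(axis=0))


def apply_normalizer(state: NormalizationState,
                     fv: FeatureVector) -> FeatureVector:
    """Min-max map a feature vector to [0, 1] (clipped)."""
    if state is None or state.min_ is None:
        raise FeatureError("normalizer has not been fitted")
    values = state.transform(np.asarray(fv.values, dtype=float))
    return FeatureVector(trial_ref=fv.trial_ref, values=values,
                         normalized=True)


# --------------------------------------------------------------------------
# Wide-format features CSV
# --------------------------------------------------------------------------

def write_features_csv(df: pd.DataFrame, path) -> None:
    cols = ["subject_id", "task", "trial_index"] + FEATURE_COLUMNS
    df.loc[:, cols].to_csv(path, index=False, float_format="%.17g")


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = ({"subject_id", "task", "trial_index"} | set(FEATURE_COLUMNS)) \
        - set(df.columns)
    if missing:
        raise FeatureError(f"features CSV missing columns: {sorted(missing)}")
    return df
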