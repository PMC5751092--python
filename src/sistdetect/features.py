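"""Per-epoch feature extraction, range normalization and lagged epochs.

Eleven features per channel and epoch, in fixed order: standard deviation,
entropy, coefficient of variation, mean, maximum, minimum, median, slope,
maximum-to-RMS ratio, RMS-to-mean ratio and fractal dimension — 154
features per epoch over the 14 channels.

Conventions for the estimators the order above leaves open:

* entropy — Shannon entropy in bits of a 10-bin equal-width histogram over
  the epoch's own range; a constant epoch has zero entropy.
* slope — ordinary-least-squares slope against time, reported per second.
* fractal dimension — Higuchi's method with ``k_max = 8``; a constant
  epoch reports 1.0 (the dimension of a smooth line).
* ratios guard near-zero denominators with 1e-12 so constant-zero epochs
  stay finite.

Features are scaled to [-1, 1] per column with the symmetric min-max map
``x' = 2 (x - min x) / (max x - min x) - 1`` whose bounds are learned from
training rows only; columns that are constant on the training data map to
0, and test values outside the training range are not clipped.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURES_PER_CHANNEL",
    "extract_features",
    "extract_feature_matrix",
    "feature_column_names",
    "SymmetricMinMaxScaler",
    "lag_concat",
    "lagged_column_names",
]

FEATURE_NAMES = [
    "std", "entropy", "cv", "mean", "max", "min", "median",
    "slope", "max_rms_ratio", "rms_mean_ratio", "fractal_dim",
]
N_FEATURES_PER_CHANNEL = len(FEATURE_NAMES)

_EPS = 1e-12
_ENTROPY_BINS = 10
_HIGUCHI_KMAX = 8
MAX_LAG = 10


def _entropy_bits(rows: np.ndarray) -> np.ndarray:
    """Histogram Shannon entropy (bits) of each row over its own range."""
    n_rows, n = rows.shape
    lo = rows.min(axis=1, keepdims=True)
    hi = rows.max(axis=1, keepdims=True)
    span = hi - lo
    degenerate = span[:, 0] <= 0
    span[degenerate] = 1.0
    bins = np.minimum((rows - lo) / span * _ENTROPY_BINS,
                      _ENTROPY_BINS - 1).astype(np.intp)
    flat = bins + _ENTROPY_BINS * np.arange(n_rows)[:, None]
    counts = np.bincount(flat.ravel(), minlength=n_rows * _ENTROPY_BINS)
    p = counts.reshape(n_rows, _ENTROPY_BINS) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    h = -terms.sum(axis=1)
    h[degenerate] = 0.0
    return h


def _higuchi_fd(rows: np.ndarray, k_max: int = _HIGUCHI_KMAX) -> np.ndarray:
    """Higuchi fractal dimension of each row."""
    n_rows, n = rows.shape
    log_k = []
    log_l = []
    for k in range(1, k_max + 1):
        lengths = np.zeros(n_rows)
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            seg = np.abs(np.diff(rows[:, idx], axis=1)).sum(axis=1)
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths += seg * norm / k
        lengths /= k
        log_k.append(np.log(1.0 / k))
        log_l.append(lengths)
    log_k_arr = np.array(log_k)
    log_l_arr = np.array(log_l)                      # k_max x n_rows
    ok = np.all(log_l_arr > 0, axis=0)
    fd = np.ones(n_rows)
    if np.any(ok):
        y = np.log(log_l_arr[:, ok])
        xk = log_k_arr - log_k_arr.mean()
        slope = (xk[:, None] * (y - y.mean(axis=0))).sum(axis=0) / (xk ** 2).sum()
        fd[ok] = slope
    return fd


def _feature_block(rows: np.ndarray, sample_rate: float) -> np.ndarray:
    """All 11 features for a batch of single-channel epochs (rows x time)."""
    n = rows.shape[1]
    mean = rows.mean(axis=1)
    sd = rows.std(axis=1)
    mx = rows.max(axis=1)
    mn = rows.min(axis=1)
    med = np.median(rows, axis=1)
    rms = np.sqrt((rows ** 2).mean(axis=1))

    t = np.arange(n)
    tc = t - t.mean()
    slope = rows @ tc / (tc ** 2).sum() * sample_rate

    mean_guard = np.where(np.abs(mean) < _EPS, _EPS, mean)
    rms_guard = np.where(np.abs(rms) < _EPS, _EPS, rms)

    return np.column_stack([
        sd,
        _entropy_bits(rows),
        sd / mean_guard,
        mean,
        mx,
        mn,
        med,
        slope,
        mx / rms_guard,
        rms / mean_guard,
        _higuchi_fd(rows),
    ])


def extract_features(epoch_block: np.ndarray,
                     sample_rate: float = 500.0) -> np.ndarray:
    """154-dimensional feature vector of one channels x samples epoch."""
    block = np.asarray(epoch_block, dtype=float)
    if block.ndim != 2:
        raise ValueError("epoch block must be 2-D (channels x samples)")
    if not np.all(np.isfinite(block)):
        raise ValueError("epoch block contains non-finite values")
    return _feature_block(block, sample_rate).ravel()


def extract_feature_matrix(epochs: np.ndarray,
                           sample_rate: float = 500.0) -> np.ndarray:
    """Feature matrix of an epoched trial.

    ``epochs`` has shape (n_epochs, channels, epoch_length); the result is
    (n_epochs, channels * 11) with channel-major column order, identical to
    stacking :func:`extract_features` per epoch but vectorized over epochs.
    """
    x = np.asarray(epochs, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (n_epochs, channels, epoch_length)")
    if not np.all(np.isfinite(x)):
        raise ValueError("epochs contain non-finite values")
    n_epochs, n_ch, _ = x.shape
    out = np.empty((n_epochs, n_ch * N_FEATURES_PER_CHANNEL))
    for ch in range(n_ch):
        cols = slice(ch * N_FEATURES_PER_CHANNEL,
                     (ch + 1) * N_FEATURES_PER_CHANNEL)
        out[:, cols] = _feature_block(x[:, ch, :], sample_rate)
    return out


def feature_column_names(channels: list[str]) -> list[str]:
    return [f"{ch}:{feat}" for ch in channels for feat in FEATURE_NAMES]


class SymmetricMinMaxScaler(BaseEstimator, TransformerMixin):
    """Map each column onto [-1, 1] using training min/max bounds.

    Training columns attain both endpoints; transform does not clip, so
    out-of-range test values land outside [-1, 1].  Degenerate columns
    (``max == min`` on the training data) map to 0.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        span = self.data_max_ - self.data_min_
        degenerate = span <= 0
        safe = np.where(degenerate, 1.0, span)
        out = 2.0 * (X - self.data_min_) / safe - 1.0
        out[:, degenerate] = 0.0
        return out

    def inverse_transform(self, X):
        check_is_fitted(self, "data_min_")
        span = self.data_max_ - self.data_min_
        return (np.asarray(X, dtype=float) + 1.0) / 2.0 * span + self.data_min_


def lag_concat(feature_matrix: np.ndarray, k: int) -> np.ndarray:
    """Concatenate each epoch's features with its ``k - 1`` predecessors.

    Row ``e`` of the result is ``concat(rows e-k+1 ... e)`` — strictly
    causal.  Rows before the first full window repeat row 0 as padding, so
    the row count is preserved.  ``k`` must lie in 1..10.
    """
    if not 1 <= k <= MAX_LAG:
        raise ValueError(f"lag count must be in 1..{MAX_LAG}, got {k}")
    X = np.asarray(feature_matrix)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if k == 1:
        return X.copy()
    n, p = X.shape
    out = np.empty((n, p * k), dtype=X.dtype)
    for lag in range(k):                  # lag 0 = oldest epoch in the window
        shift = k - 1 - lag
        src = np.vstack([np.repeat(X[:1], min(shift, n), axis=0),
                         X[:max(0, n - shift)]]) if shift else X
        out[:, lag * p:(lag + 1) * p] = src
    return out


def lagged_column_names(channels: list[str], k: int) -> list[str]:
    base = feature_column_names(channels)
    return [f"{name}@lag{k - 1 - lag}" for lag in range(k) for name in base]
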