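"""Denoising, epoching and epoch-level ground-truth labeling.

Raw channels are denoised with translation-invariant wavelet shrinkage (the
stationary wavelet transform with soft universal thresholding, equivalent to
full cycle-spinning), cut into non-overlapping 0.2 s epochs of 100 samples,
and labeled:

* SiSt transition regions are found automatically from the knee
  potentiometer: the knee angle crossing 45 degrees downward marks the
  transition midpoint, and the region boundaries are where the knee angular
  velocity magnitude passes 5% of the event's peak velocity.
* An epoch is labeled positive when the majority (>50%, ties counting as
  positive) of its samples fall inside a region / carry the sitting posture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import savgol_filter

__all__ = [
    "denoise",
    "epoch",
    "annotate_transitions",
    "label_epochs",
    "label_sitting",
    "EpochedTrial",
    "preprocess_trial",
]

EPOCH_LENGTH = 100          # samples, 0.2 s at 500 Hz
MIDPOINT_ANGLE = 45.0       # deg, SiSt midpoint annotation rule
VELOCITY_FRACTION = 0.05    # region boundary: 5% of the event peak velocity

_WAVELET = "db4"
_LEVEL = 4


def denoise(signal_matrix: np.ndarray, wavelet: str = _WAVELET,
            level: int = _LEVEL) -> np.ndarray:
    """Translation-invariant wavelet shrinkage, independently per channel.

    Uses the stationary (undecimated) wavelet transform with a soft
    universal threshold per channel; the noise scale is estimated from the
    median absolute deviation of the finest detail coefficients.  Signals
    whose length is not a multiple of ``2**level`` are reflect-padded and
    cropped, which confines boundary effects to the padded ends.
    """
    x = np.asarray(signal_matrix, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    n = x.shape[1]
    block = 2 ** level
    if n < 2 * block:
        raise ValueError(f"need at least {2 * block} samples for level {level}")
    pad = (-n) % block
    out = np.empty_like(x)
    for ch in range(x.shape[0]):
        row = np.pad(x[ch], (0, pad), mode="reflect") if pad else x[ch]
        coeffs = pywt.swt(row, wavelet, level=level, trim_approx=True,
                          norm=True)
        details = coeffs[1:]
        sigma = np.median(np.abs(details[-1])) / 0.6745
        thresh = sigma * np.sqrt(2.0 * np.log(row.size))
        shrunk = [coeffs[0]] + [pywt.threshold(d, thresh, mode="soft")
                                for d in details]
        rec = pywt.iswt(shrunk, wavelet, norm=True)
        out[ch] = rec[:n]
    return out[0] if single else out


def epoch(signal_matrix: np.ndarray, epoch_length: int = EPOCH_LENGTH) -> np.ndarray:
    """Cut channels x T into consecutive non-overlapping blocks.

    Returns an array of shape (n_epochs, channels, epoch_length); trailing
    remainder samples are discarded.
    """
    if epoch_length < 2:
        raise ValueError("epoch_length must be >= 2")
    x = np.asarray(signal_matrix)
    if x.ndim == 1:
        x = x[None, :]
    n_ch, T = x.shape
    if T < epoch_length:
        raise ValueError("signal shorter than one epoch")
    n_epochs = T // epoch_length
    trimmed = x[:, :n_epochs * epoch_length]
    return trimmed.reshape(n_ch, n_epochs, epoch_length).transpose(1, 0, 2)


def annotate_transitions(knee_angle_deg: np.ndarray, sample_rate: int,
                         ) -> tuple[list[tuple[int, int]], list[int]]:
    """Locate SiSt events on the (denoised) knee-angle channel.

    A SiSt midpoint is the first sample at or below 45 degrees of a
    sustained downward crossing; the event region extends to where the knee
    angular velocity magnitude falls below 5% of the event's peak.  Returns
    ``(regions, midpoints)`` with half-open sample regions.  A signal with
    no crossing yields an empty result.
    """
    angle = np.asarray(knee_angle_deg, dtype=float)
    n = angle.size
    if n < 3:
        return [], []
    window = min(201, n if n % 2 == 1 else n - 1)
    velocity = savgol_filter(angle, window, 2, deriv=1) * sample_rate

    guard = int(round(0.25 * sample_rate))  # sustained-crossing check window
    gap = int(round(0.05 * sample_rate))     # tolerated sub-threshold gap
    below = angle <= MIDPOINT_ANGLE
    crossing_idx = np.flatnonzero(below[1:] & ~below[:-1]) + 1

    regions: list[tuple[int, int]] = []
    midpoints: list[int] = []
    last_end = 0
    for c in crossing_idx:
        if c < last_end:
            continue
        before = angle[max(0, c - guard):c]
        after = angle[c:c + guard]
        if before.size == 0 or after.size == 0:
            continue
        if not (before.mean() > MIDPOINT_ANGLE + 1.0
                and after.mean() < MIDPOINT_ANGLE - 1.0):
            continue
        span = int(round(2.5 * sample_rate))
        lo, hi = max(0, c - span), min(n, c + span)
        peak = np.max(np.abs(velocity[lo:hi]))
        if peak <= 0:
            continue
        active = np.abs(velocity) >= VELOCITY_FRACTION * peak
        onset = _expand(active, c, lo, -1, gap)
        offset = _expand(active, c, hi - 1, +1, gap)
        regions.append((onset, offset + 1))
        midpoints.append(int(c))
        last_end = offset + 1
    return regions, midpoints


def _expand(active: np.ndarray, start: int, limit: int, step: int,
            gap: int) -> int:
    """Last active sample reachable from ``start`` tolerating short gaps."""
    i = last_active = start
    stall = 0
    while i != limit:
        i += step
        if active[i]:
            last_active = i
            stall = 0
        else:
            stall += 1
            if stall > gap:
                break
    return last_active


def label_epochs(regions: list[tuple[int, int]], n_epochs: int,
                 epoch_length: int = EPOCH_LENGTH) -> np.ndarray:
    """Majority-vote epoch labels from sample regions (ties label 1)."""
    total = n_epochs * epoch_length
    covered = np.zeros(total, dtype=bool)
    for a, b in regions:
        if a < 0 or b > total:
            raise ValueError(f"region ({a}, {b}) exceeds trial bounds")
        covered[a:b] = True
    frac = covered.reshape(n_epochs, epoch_length).mean(axis=1)
    return (frac >= 0.5).astype(np.int8)


def label_sitting(truth_posture: np.ndarray, n_epochs: int,
                  epoch_length: int = EPOCH_LENGTH,
                  sit_code: int = 0) -> np.ndarray:
    """Majority-vote sitting labels from the per-sample posture code."""
    total = n_epochs * epoch_length
    sit = (np.asarray(truth_posture[:total]) == sit_code)
    frac = sit.reshape(n_epochs, epoch_length).mean(axis=1)
    return (frac >= 0.5).astype(np.int8)


@dataclass
class EpochedTrial:
    """A denoised, epoched trial with its epoch-level ground truth."""

    epoch_length: int
    n_epochs: int
    epochs: np.ndarray              # n_epochs x channels x epoch_length
    sit_labels: np.ndarray          # per-epoch {0,1}
    transition_labels: np.ndarray   # per-epoch {0,1}, SiSt only
    transition_regions: list[tuple[int, int]]   # annotated, sample units
    midpoint_samples: list[int]


def preprocess_trial(trial, epoch_length: int = EPOCH_LENGTH,
                     apply_denoise: bool = True) -> EpochedTrial:
    """Full preprocessing of a simulated trial.

    Denoises all channels, epochs them, annotates SiSt regions from the
    denoised knee channel and derives the epoch labels.  Sitting labels come
    from the simulator's exact posture code; transition labels come from the
    automatic annotator (which replaces the study's manual raters).
    """
    from .orthosim import KNEE_CHANNEL

    signal = denoise(trial.signal) if apply_denoise else trial.signal
    blocks = epoch(signal, epoch_length)
    n_epochs = blocks.shape[0]
    regions, midpoints = annotate_transitions(signal[KNEE_CHANNEL],
                                              trial.sample_rate)
    regions = [(a, min(b, n_epochs * epoch_length)) for a, b in regions]
    return EpochedTrial(
        epoch_length=epoch_length,
        n_epochs=n_epochs,
        epochs=blocks,
        sit_labels=label_sitting(trial.truth_posture, n_epochs, epoch_length),
        transition_labels=label_epochs(regions, n_epochs, epoch_length),
        transition_regions=regions,
        midpoint_samples=midpoints,
    )
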