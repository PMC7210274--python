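"""Partial-response EMG (prEMG) detection and peak-latency extraction.

The normalization pipeline is fixed: moving-RMS transform, division by each
trial's mean baseline RMS, then z-scoring pooled over *all* trials and
samples.  Each stage checks the :class:`~stopmark.signals.EpochMatrix` state
flag, so stages cannot be skipped or repeated.  Detection flags a successful
stop trial when any z-value between go onset and the response-window offset
exceeds a threshold (1.2 by default); the prEMG peak latency is the argmax
of the averaged z trace between stop onset and the participant's SSRT after
re-epoching to the stop signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .signals import EpochMatrix

__all__ = [
    "rms_transform",
    "baseline_ratio",
    "zscore_pooled",
    "reject_baseline_artifacts",
    "detect_premg",
    "reepoch_to_stop",
    "premg_peak_latency",
    "PrEMGPeak",
    "PrEMGResult",
]

DEFAULT_RMS_WINDOW_MS = 25.0
DETECTION_THRESHOLD = 1.2
BASELINE_ARTIFACT_UV = 100.0


class PipelineStageError(RuntimeError):
    """A normalization stage was applied out of order."""


def _require_stage(epochs: EpochMatrix, expected: str, op: str) -> None:
    if epochs.stage != expected:
        raise PipelineStageError(
            f"{op} expects stage {expected!r}, got {epochs.stage!r}"
        )


def rms_transform(
    epochs: EpochMatrix, window_ms: float = DEFAULT_RMS_WINDOW_MS
) -> EpochMatrix:
    """Centered moving root-mean-square with edge shrinkage.

    The output has the same length as the input; near the edges the averaging
    window is truncated to the available samples.
    """
    _require_stage(epochs, "raw", "rms_transform")
    k = int(round(window_ms * epochs.fs / 1000.0))
    if k < 2:
        raise ValueError("RMS window must span at least 2 samples")
    if k > epochs.n_samples:
        raise ValueError("RMS window longer than epoch")
    sq = epochs.data**2
    n = epochs.n_samples
    half = k // 2
    # windowed mean via cumulative sums with truncated windows at the edges
    csum = np.concatenate([np.zeros((sq.shape[0], 1)), np.cumsum(sq, axis=1)], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (k - half), n)
    means = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return epochs.with_data(np.sqrt(means), stage="rms")


def baseline_ratio(
    epochs: EpochMatrix, baseline: tuple[float, float] = (-200.0, 0.0)
) -> EpochMatrix:
    """Divide each trial by its mean baseline RMS.

    Trials with zero baseline are flagged (indices in ``result.flagged``)
    and set to NaN rather than dividing by zero.
    """
    _require_stage(epochs, "rms", "baseline_ratio")
    lo, hi = _window_slice(epochs, baseline)
    base = epochs.data[:, lo:hi].mean(axis=1)
    out = np.empty_like(epochs.data)
    bad = base <= 0.0
    ok = ~bad
    out[ok] = epochs.data[ok] / base[ok, None]
    out[bad] = np.nan
    if bad.any():
        warnings.warn(f"{bad.sum()} trial(s) with zero baseline flagged", stacklevel=2)
    result = EpochMatrix(
        data=_allow_nan(out),
        fs=epochs.fs,
        window=epochs.window,
        lock=epochs.lock,
        trial_index=epochs.trial_index.copy(),
        stage="ratio",
        truth=epochs.truth,
        flagged=sorted(set(epochs.flagged) | set(epochs.trial_index[bad].tolist())),
    )
    return result


def _allow_nan(data: np.ndarray) -> np.ndarray:
    # EpochMatrix insists on finite values; replace flagged trials with zeros
    # (they are excluded from all downstream statistics via `flagged`).
    return np.nan_to_num(data, nan=0.0)


def zscore_pooled(epochs: EpochMatrix) -> EpochMatrix:
    """z-score against the pooled mean/SD over all trials and samples."""
    _require_stage(epochs, "ratio", "zscore_pooled")
    if epochs.n_trials < 2:
        raise ValueError("pooled z-scoring needs at least 2 trials")
    m = epochs.data.mean()
    s = epochs.data.std()
    if s == 0.0:
        raise ValueError("pooled SD is zero")
    return epochs.with_data((epochs.data - m) / s, stage="z")


def reject_baseline_artifacts(
    raw: EpochMatrix,
    threshold_uv: float = BASELINE_ARTIFACT_UV,
    baseline: tuple[float, float] = (-200.0, 0.0),
) -> np.ndarray:
    """Indices (rows) of trials whose mean rectified baseline amplitude does
    not exceed ``threshold_uv`` (strict inequality drops a trial)."""
    _require_stage(raw, "raw", "reject_baseline_artifacts")
    lo, hi = _window_slice(raw, baseline)
    level = np.abs(raw.data[:, lo:hi]).mean(axis=1)
    kept = np.flatnonzero(~(level > threshold_uv))
    if kept.size == 0:
        warnings.warn("all trials rejected as baseline artifacts", stacklevel=2)
    return kept


def detect_premg(
    z_epochs: EpochMatrix,
    response_window_offset: float = 1000.0,
    threshold: float = DETECTION_THRESHOLD,
) -> np.ndarray:
    """Per-trial detection flags on go-locked, z-scored epochs.

    A trial is flagged when any sample strictly after go onset and up to the
    response-window offset exceeds ``threshold`` (strict inequality).
    """
    _require_stage(z_epochs, "z", "detect_premg")
    if z_epochs.lock != "go":
        raise ValueError("detection runs on go-locked epochs")
    t = z_epochs.times()
    if response_window_offset > z_epochs.window[1]:
        raise ValueError("response window offset outside epoch")
    mask = (t > 0.0) & (t <= response_window_offset)
    return (z_epochs.data[:, mask] > threshold).any(axis=1)


def reepoch_to_stop(
    epochs: EpochMatrix,
    ssd_by_trial: Mapping[int, float],
    window: tuple[float, float] = (-200.0, 800.0),
) -> EpochMatrix:
    """Re-lock go-locked epochs to stop-signal onset.

    Stop-locked time = go-locked time - SSD, per trial; the SSD is rounded
    to the sample grid.  Trials whose stop-locked window is not fully covered
    by the source epoch are dropped with a warning.
    """
    if epochs.lock != "go":
        raise ValueError("re-epoching expects go-locked input")
    n_out = int(round((window[1] - window[0]) * epochs.fs / 1000.0))
    rows, out = [], []
    for row, trial in enumerate(epochs.trial_index):
        ssd = ssd_by_trial.get(int(trial))
        if ssd is None:
            continue
        start = int(round((ssd + window[0] - epochs.window[0]) * epochs.fs / 1000.0))
        if start < 0 or start + n_out > epochs.n_samples:
            warnings.warn(
                f"trial {trial}: SSD {ssd} ms pushes the stop-locked window "
                "outside the source epoch; dropped",
                stacklevel=2,
            )
            continue
        rows.append(row)
        out.append(epochs.data[row, start : start + n_out])
    if not out:
        raise ValueError("no trials could be re-epoched")
    return EpochMatrix(
        data=np.asarray(out),
        fs=epochs.fs,
        window=window,
        lock="stop",
        trial_index=epochs.trial_index[rows],
        stage=epochs.stage,
        truth=epochs.truth,
        flagged=list(epochs.flagged),
    )


@dataclass(frozen=True)
class PrEMGPeak:
    latency_ms: float
    amplitude: float
    boundary: bool  # True if the maximum sits on the SSRT bound
    n_trials: int


@dataclass(frozen=True)
class PrEMGResult:
    """Detection summary for one participant x condition x time cell."""

    detected: np.ndarray
    detection_rate: float
    peak_latency_ms: float
    boundary: bool
    n_trials_used: int


def premg_peak_latency(z_epochs: EpochMatrix, ssrt: float) -> PrEMGPeak:
    """Peak of the trial-averaged z trace between stop onset and the SSRT.

    ``z_epochs`` must be stop-locked and restricted to detected trials.  A
    maximum on the last admissible sample is reported with ``boundary=True``
    rather than returned silently.
    """
    if z_epochs.lock != "stop":
        raise ValueError("peak extraction expects stop-locked epochs")
    if z_epochs.n_trials == 0:
        raise ValueError("no detected trials")
    if not np.isfinite(ssrt) or ssrt <= 0:
        raise ValueError(f"SSRT bound must be positive, got {ssrt!r}")
    avg = z_epochs.data.mean(axis=0)
    t = z_epochs.times()
    mask = (t >= 0.0) & (t <= ssrt)
    if not mask.any():
        raise ValueError("SSRT bound excludes every post-stop sample")
    seg = avg[mask]
    i = int(np.argmax(seg))
    latency = float(t[mask][i])
    return PrEMGPeak(
        latency_ms=latency,
        amplitude=float(seg[i]),
        boundary=i == seg.size - 1,
        n_trials=z_epochs.n_trials,
    )


def _window_slice(epochs: EpochMatrix, window: tuple[float, float]) -> tuple[int, int]:
    lo_ms, hi_ms = window
    if lo_ms < epochs.window[0] or hi_ms > epochs.window[1]:
        raise ValueError(f"window {window} outside epoch {epochs.window}")
    lo = int(round((lo_ms - epochs.window[0]) * epochs.fs / 1000.0))
    hi = int(round((hi_ms - epochs.window[0]) * epochs.fs / 1000.0))
    if hi <= lo:
        raise ValueError("empty window")
    return lo, hi
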