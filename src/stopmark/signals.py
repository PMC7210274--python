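"""Synthetic EMG and EEG epochs with retrievable ground truth.

``EpochMatrix`` is the shared trials x samples container for both
modalities; ``synthesize_emg`` and ``synthesize_erp_epochs`` populate it
from simulated trials.  Every synthesized latency (EMG burst peak, P3 onset
and peak) is stored in ``EpochMatrix.truth`` so downstream extraction can be
validated against the generator.

EMG traces are go-locked (-200..+1600 ms), already rectified: a positive
burst envelope over tonic Gaussian background activity.  On responded trials
a full-response burst peaks shortly before the keypress; on a configurable
fraction of successful stop trials a smaller partial burst rises and then
declines at ``stop onset + suppression_lag`` - the moment inhibition reaches
the muscle.  EEG epochs are stop-locked (-200..+800 ms) and contain a
P3-like triangular deflection whose half-amplitude onset is available in
closed form; the background noise is low-pass-shaped, emulating the
band-limited residual of a filtered recording.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import RaceModelParams, TrialRecord

__all__ = ["SignalConfig", "EpochMatrix", "synthesize_emg", "synthesize_erp_epochs"]


@dataclass(frozen=True)
class SignalConfig:
    """Shapes and noise levels of the synthesized signals (ms, uV, Hz)."""

    fs: float = 500.0
    emg_window: tuple[float, float] = (-200.0, 1600.0)
    eeg_window: tuple[float, float] = (-200.0, 800.0)
    # full-response EMG burst (Hann envelope)
    burst_amp: float = 100.0
    burst_width: float = 200.0
    motor_time: float = 30.0  # burst peak precedes the keypress by this much
    # partial-response burst (asymmetric triangle, peak = suppression point)
    partial_amp: float = 60.0
    partial_rise: float = 80.0
    partial_fall: float = 50.0
    p_partial: float = 0.30
    suppression_lag: float = 160.0  # ms from stop onset to prEMG decline
    # stop-P3 component (triangle: onset implied by half-amplitude geometry)
    p3_onset: float = 302.0
    p3_peak: float = 374.0
    p3_amp: float = 8.0
    p3_fall: float = 150.0
    # noise
    noise_sd_emg: float = 10.0
    noise_sd_eeg: float = 5.0
    eeg_noise_smooth_ms: float = 25.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        for w in (self.emg_window, self.eeg_window):
            if not (w[0] <= 0.0 < w[1]):
                raise ValueError(f"epoch window {w} must contain time 0")
        if not self.p3_onset < self.p3_peak:
            raise ValueError("p3_onset must precede p3_peak")
        if not 0.0 <= self.p_partial <= 1.0:
            raise ValueError("p_partial must lie in [0, 1]")
        if min(self.noise_sd_emg, self.noise_sd_eeg) < 0:
            raise ValueError("noise SDs must be >= 0")


_STAGES = ("raw", "rms", "ratio", "z")


@dataclass
class EpochMatrix:
    """trials x samples amplitude matrix with epoch-window metadata.

    ``stage`` tracks the EMG normalization pipeline (raw -> rms -> ratio ->
    z); each transform checks and advances it so that, e.g., z-scoring twice
    is a type error rather than a silent bug.
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    lock: str  # "go" | "stop"
    trial_index: np.ndarray
    stage: str = "raw"
    truth: Optional[pd.DataFrame] = None
    flagged: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (trials x samples)")
        if len(self.trial_index) != self.data.shape[0]:
            raise ValueError("trial_index length must match number of trials")
        if self.lock not in ("go", "stop"):
            raise ValueError("lock must be 'go' or 'stop'")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        expected = int(round((self.window[1] - self.window[0]) * self.fs / 1000.0))
        if self.data.shape[1] != expected:
            raise ValueError(
                f"window {self.window} at fs={self.fs} implies {expected} samples, "
                f"got {self.data.shape[1]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        """Sample times in ms relative to the locking event (half-open window)."""
        return self.window[0] + np.arange(self.n_samples) * 1000.0 / self.fs

    def index_of(self, t_ms: float) -> int:
        """Index of the sample at time ``t_ms`` (nearest sample on the grid)."""
        i = int(round((t_ms - self.window[0]) * self.fs / 1000.0))
        if not 0 <= i < self.n_samples:
            raise ValueError(f"time {t_ms} ms outside window {self.window}")
        return i

    def with_data(self, data: np.ndarray, stage: Optional[str] = None) -> "EpochMatrix":
        return EpochMatrix(
            data=data,
            fs=self.fs,
            window=self.window,
            lock=self.lock,
            trial_index=self.trial_index.copy(),
            stage=self.stage if stage is None else stage,
            truth=self.truth,
            flagged=list(self.flagged),
        )

    def subset(self, rows: Sequence[int] | np.ndarray) -> "EpochMatrix":
        rows = np.asarray(rows)
        rows = np.flatnonzero(rows) if rows.dtype == bool else rows.astype(int)
        return EpochMatrix(
            data=self.data[rows],
            fs=self.fs,
            window=self.window,
            lock=self.lock,
            trial_index=self.trial_index[rows],
            stage=self.stage,
            truth=self.truth,
            flagged=list(self.flagged),
        )

    # -- on-disk form: float32 .npy next to a JSON sidecar ------------------
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.data.astype(np.float32))
        sidecar = {
            "fs": self.fs,
            "window_ms": list(self.window),
            "lock": self.lock,
            "stage": self.stage,
            "trial_index": self.trial_index.tolist(),
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, prefix: str | Path) -> "EpochMatrix":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        data = np.load(prefix.with_suffix(".npy")).astype(float)
        return cls(
            data=data,
            fs=float(meta["fs"]),
            window=tuple(meta["window_ms"]),
            lock=meta["lock"],
            trial_index=np.asarray(meta["trial_index"]),
            stage=meta.get("stage", "raw"),
        )


def _hann_bump(times: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    """Hann envelope of full width ``width`` centered at ``center``."""
    x = (times - center) / width
    y = np.where(np.abs(x) < 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * x)), 0.0)
    return amp * y


def _triangle(
    times: np.ndarray, start: float, peak_t: float, end: float, amp: float
) -> np.ndarray:
    """Piecewise-linear pulse: 0 at start, ``amp`` at peak_t, 0 at end."""
    rise = np.clip((times - start) / (peak_t - start), 0.0, 1.0)
    fall = np.clip((end - times) / (end - peak_t), 0.0, 1.0)
    return amp * np.minimum(rise, fall)


def synthesize_emg(
    trials: Sequence[TrialRecord],
    sig: SignalConfig = SignalConfig(),
    rng: Optional[np.random.Generator] = None,
) -> EpochMatrix:
    """Build go-locked rectified EMG epochs for every trial.

    Responded trials receive a full-response burst peaking ``motor_time`` ms
    before the recorded RT.  Successful stop trials receive, with probability
    ``p_partial``, a partial burst whose amplitude declines at
    ``ssd + suppression_lag`` (go-locked); that decline point is the
    ground-truth prEMG peak stored per trial in ``truth``.
    """
    if rng is None:
        rng = np.random.default_rng()
    start, end = sig.emg_window
    burst_support = max(sig.burst_width, sig.partial_rise + sig.partial_fall)
    if end - start < burst_support:
        raise ValueError("EMG epoch window shorter than burst support")

    n = len(trials)
    n_samp = int(round((end - start) * sig.fs / 1000.0))
    times = start + np.arange(n_samp) * 1000.0 / sig.fs
    if sig.noise_sd_emg > 0:
        data = np.abs(rng.standard_normal((n, n_samp))) * sig.noise_sd_emg
    else:
        data = np.zeros((n, n_samp))

    rows = []
    for i, t in enumerate(trials):
        kind, peak_go, peak_stop = "none", np.nan, np.nan
        if t.responded and t.rt is not None:
            peak_go = t.rt - sig.motor_time
            data[i] += _hann_bump(times, peak_go, sig.burst_width, sig.burst_amp)
            kind = "full"
        elif t.kind == "stop" and t.stop_success and rng.random() < sig.p_partial:
            peak_go = t.ssd + sig.suppression_lag
            peak_stop = sig.suppression_lag
            data[i] += _triangle(
                times,
                peak_go - sig.partial_rise,
                peak_go,
                peak_go + sig.partial_fall,
                sig.partial_amp,
            )
            kind = "partial"
        rows.append(
            {
                "trial": t.index,
                "burst": kind,
                "peak_go_ms": peak_go,
                "peak_stop_ms": peak_stop,
            }
        )

    return EpochMatrix(
        data=data,
        fs=sig.fs,
        window=sig.emg_window,
        lock="go",
        trial_index=np.array([t.index for t in trials]),
        stage="raw",
        truth=pd.DataFrame(rows),
    )


def _lowpass_noise(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, fs: float, smooth_ms: float
) -> np.ndarray:
    """Band-limited Gaussian noise with marginal SD ``sd`` (Hann-kernel FIR)."""
    white = rng.standard_normal(shape)
    k = int(round(smooth_ms * fs / 1000.0))
    if k < 2:
        return sd * white
    kernel = np.hanning(k + 2)[1:-1]
    kernel /= math.sqrt(np.sum(kernel**2))  # unit power -> output SD preserved
    out = np.apply_along_axis(lambda x: np.convolve(x, kernel, mode="same"), 1, white)
    return sd * out


def synthesize_erp_epochs(
    trials: Sequence[TrialRecord],
    sig: SignalConfig = SignalConfig(),
    rng: Optional[np.random.Generator] = None,
    successful_only: bool = True,
) -> EpochMatrix:
    """Build stop-locked Cz-like epochs containing a P3 deflection.

    The component is a triangular pulse rising from ``2*p3_onset - p3_peak``
    to ``p3_amp`` at ``p3_peak`` and decaying over ``p3_fall`` ms, so its
    half-amplitude onset is exactly ``p3_onset`` in the noiseless limit.
    Only stop trials are epoched (successful ones by default).
    """
    stops = [t for t in trials if t.kind == "stop"]
    if successful_only:
        stops = [t for t in stops if t.stop_success]
    if not stops:
        raise ValueError("no stop trials to epoch")
    if rng is None:
        rng = np.random.default_rng()
    if not 250.0 <= sig.p3_peak <= 500.0:
        warnings.warn(
            f"p3_peak={sig.p3_peak} ms lies outside the standard 250-500 ms "
            "search window; downstream peak search will clip",
            stacklevel=2,
        )

    start, end = sig.eeg_window
    n_samp = int(round((end - start) * sig.fs / 1000.0))
    times = start + np.arange(n_samp) * 1000.0 / sig.fs
    rise_start = 2.0 * sig.p3_onset - sig.p3_peak
    template = _triangle(times, rise_start, sig.p3_peak, sig.p3_peak + sig.p3_fall, sig.p3_amp)

    n = len(stops)
    if sig.noise_sd_eeg > 0:
        data = _lowpass_noise(
            rng, (n, n_samp), sig.noise_sd_eeg, sig.fs, sig.eeg_noise_smooth_ms
        )
    else:
        data = np.zeros((n, n_samp))
    data += template

    truth = pd.DataFrame(
        {
            "trial": [t.index for t in stops],
            "p3_onset_ms": sig.p3_onset if sig.p3_amp > 0 else np.nan,
            "p3_peak_ms": sig.p3_peak if sig.p3_amp > 0 else np.nan,
            "p3_amp": sig.p3_amp,
        }
    )
    return EpochMatrix(
        data=data,
        fs=sig.fs,
        window=sig.eeg_window,
        lock="stop",
        trial_index=np.array([t.index for t in stops]),
        stage="raw",
        truth=truth,
    )
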