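"""SSRT estimation and behavioral summaries for the stop-signal task.

Implements the integration method (go-RT quantile at the stop-failure
probability minus mean SSD, with go omissions replaced by the maximum go RT)
and the mean method, the race-model sanity check (unsuccessful-stop RTs must
be faster than go RTs), Table-style behavioral summaries, and a univariate
z-score outlier screen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .task import TrialRecord, trials_from_table

__all__ = [
    "BehavioralDataset",
    "BehavioralSummary",
    "RaceModelCheck",
    "estimate_ssrt_integration",
    "estimate_ssrt_mean",
    "race_model_check",
    "race_model_paired_test",
    "summarize",
    "screen_outliers",
]


class SSRTUndefinedError(ValueError):
    """Raised when stop accuracy is 0 or 1 and the go-RT quantile is undefined."""


@dataclass
class BehavioralDataset:
    """Trials of one participant x condition x time cell."""

    trials: list[TrialRecord]
    participant: str = "s01"
    condition: str = "SHAM"  # IFG | VC | SHAM
    time: str = "pre"  # pre | peri | post

    def __post_init__(self) -> None:
        if not any(t.kind == "go" and t.responded for t in self.trials):
            raise ValueError("dataset needs at least one responded go trial")
        if any(t.kind == "stop" and t.ssd is None for t in self.trials):
            raise ValueError("stop trials must carry SSDs")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "BehavioralDataset":
        first = df.iloc[0]
        return cls(
            trials=trials_from_table(df),
            participant=str(first["participant"]),
            condition=str(first["condition"]),
            time=str(first["time"]),
        )

    # -- trial views --------------------------------------------------------
    @property
    def go_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.kind == "go"]

    @property
    def stop_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.kind == "stop"]

    def go_rts(self, correct_only: bool = True) -> np.ndarray:
        """RTs of responded go trials; wrong-hand responses excluded by default."""
        return np.array(
            [
                t.rt
                for t in self.go_trials
                if t.responded and (t.correct or not correct_only)
            ]
        )

    def usrts(self) -> np.ndarray:
        """RTs of unsuccessful stop trials."""
        return np.array(
            [t.rt for t in self.stop_trials if t.responded and t.rt is not None]
        )

    def ssds(self) -> np.ndarray:
        return np.array([t.ssd for t in self.stop_trials])

    def p_respond_stop(self) -> float:
        stops = self.stop_trials
        if not stops:
            raise ValueError("no stop trials")
        return float(np.mean([t.responded for t in stops]))

    def go_distribution(self) -> np.ndarray:
        """All go trials' RTs with omissions replaced by the maximum go RT.

        Wrong-hand responses stay in the distribution (they reflect a
        finished go process); only unanswered go trials are replaced.
        """
        responded = self.go_rts(correct_only=False)
        if responded.size == 0:
            raise ValueError("no responded go trials")
        n_omit = sum(1 for t in self.go_trials if not t.responded)
        dist = np.concatenate([responded, np.full(n_omit, responded.max())])
        return np.sort(dist)


@dataclass(frozen=True)
class BehavioralSummary:
    goRT_mean: float
    USRT_mean: float
    SSD_mean: float
    SSRT_integration: float
    SSRT_mean_method: float
    stop_accuracy: float
    go_accuracy: float
    go_omission_rate: float
    n_go: int
    n_stop: int


def estimate_ssrt_integration(ds: BehavioralDataset) -> float:
    """Integration-method SSRT with replacement of go omissions.

    The nth go RT (1-based rank ``ceil(p * n_go)``, no interpolation) of the
    omission-replaced go distribution, minus the mean SSD, where p is the
    probability of responding on a stop trial.
    """
    p = ds.p_respond_stop()
    if p <= 0.0 or p >= 1.0:
        raise SSRTUndefinedError(
            f"stop accuracy {1 - p:.0%}: go-RT quantile undefined at p={p}"
        )
    dist = ds.go_distribution()
    rank = math.ceil(p * dist.size)
    quantile_rt = dist[rank - 1]
    return float(quantile_rt - ds.ssds().mean())


def estimate_ssrt_mean(ds: BehavioralDataset) -> float:
    """Mean-method SSRT: mean omission-replaced go RT minus mean SSD."""
    if not ds.stop_trials:
        raise ValueError("no stop trials")
    return float(ds.go_distribution().mean() - ds.ssds().mean())


@dataclass(frozen=True)
class RaceModelCheck:
    diff_ms: float  # mean goRT - mean USRT
    satisfied: bool  # True iff diff > 0
    n_usrt: int


def race_model_check(ds: BehavioralDataset) -> RaceModelCheck:
    """Check the race-model prediction that USRTs are faster than go RTs.

    Session-level check only; the paired Bayes-factor test across
    participants is :func:`race_model_paired_test`.
    """
    usrts = ds.usrts()
    if usrts.size == 0:
        raise ValueError("no unsuccessful stop trials with an RT")
    diff = float(ds.go_rts().mean() - usrts.mean())
    return RaceModelCheck(diff_ms=diff, satisfied=diff > 0, n_usrt=usrts.size)


def race_model_paired_test(go_means: Sequence[float], usrt_means: Sequence[float]):
    """Paired JZS t-test of per-participant goRT vs USRT means."""
    from .stats import jzs_bf_paired

    return jzs_bf_paired(np.asarray(go_means), np.asarray(usrt_means))


def summarize(ds: BehavioralDataset) -> BehavioralSummary:
    """All standard behavioral measures of one cell.

    go_accuracy is the proportion of responded go trials with the correct
    hand; go_omission_rate is unanswered go trials over all go trials.
    """
    if not ds.trials:
        raise ValueError("empty dataset")
    go = ds.go_trials
    stops = ds.stop_trials
    responded_go = [t for t in go if t.responded]
    usrts = ds.usrts()
    return BehavioralSummary(
        goRT_mean=float(ds.go_rts().mean()),
        USRT_mean=float(usrts.mean()) if usrts.size else float("nan"),
        SSD_mean=float(ds.ssds().mean()) if stops else float("nan"),
        SSRT_integration=_safe_ssrt(estimate_ssrt_integration, ds),
        SSRT_mean_method=_safe_ssrt(estimate_ssrt_mean, ds),
        stop_accuracy=float(np.mean([t.stop_success for t in stops]))
        if stops
        else float("nan"),
        go_accuracy=float(np.mean([t.correct for t in responded_go]))
        if responded_go
        else float("nan"),
        go_omission_rate=float(np.mean([not t.responded for t in go])),
        n_go=len(go),
        n_stop=len(stops),
    )


def _safe_ssrt(fn, ds: BehavioralDataset) -> float:
    try:
        return fn(ds)
    except (SSRTUndefinedError, ValueError):
        return float("nan")


def screen_outliers(
    values: Sequence[float], z_threshold: float = 3.5
) -> tuple[np.ndarray, np.ndarray]:
    """Univariate outlier screen: drop values with |z| > ``z_threshold``.

    z-scores use the sample mean and population SD of the full vector.
    Returns (kept indices, removed indices).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sd = x.std()
    if sd == 0.0:
        warnings.warn("zero variance: no outliers removable", stacklevel=2)
        return np.arange(x.size), np.array([], dtype=int)
    z = (x - x.mean()) / sd
    removed = np.flatnonzero(np.abs(z) > z_threshold)
    kept = np.flatnonzero(np.abs(z) <= z_threshold)
    return kept, removed
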