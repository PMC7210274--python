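"""Stop-signal task simulation under the independent horse-race model.

The simulator implements the standard account of stopping behavior: on every
trial a go process races toward response execution; on stop trials a stop
process, launched at the stop-signal delay (SSD), races it.  The response is
emitted iff the go process finishes first.  Go finishing times are
ex-Gaussian, stop latencies Gaussian, and the overt keypress lags the central
finishing time by a fixed motor conduction delay.  The SSD is adapted with a
one-up/one-down staircase (+step after a successful stop, -step after a
failed one) which converges on ~50% stop accuracy.

Times are in milliseconds throughout; the reaction time recorded for a trial
is the central finishing time plus ``motor_delay``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "RaceModelParams",
    "TaskConfig",
    "TrialRecord",
    "FeedbackEvent",
    "Session",
    "simulate_session",
    "trials_to_table",
    "trials_from_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RaceModelParams:
    """Generative parameters of the independent horse-race model.

    Go finishing times are ex-Gaussian(go_mu, go_sigma, go_tau); stop
    latencies are Gaussian(stop_mu, stop_sigma).  The expected go RT is
    ``go_mu + go_tau + motor_delay`` and the ground-truth behavioral SSRT is
    ``stop_mu + motor_delay``: the stop process acts on the central stage, so
    the motor conduction delay is absorbed into any estimate derived from
    overt reaction times.
    """

    go_mu: float = 380.0
    go_sigma: float = 50.0
    go_tau: float = 70.0
    stop_mu: float = 160.0
    stop_sigma: float = 25.0
    motor_delay: float = 50.0
    p_go_omission: float = 0.01
    p_choice_error: float = 0.01
    p_trigger_failure: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("go_mu", "go_sigma", "go_tau", "stop_sigma", "motor_delay"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not math.isfinite(self.stop_mu) or self.stop_mu < 0:
            raise ValueError(f"stop_mu must be finite and >= 0, got {self.stop_mu!r}")
        if not 0.0 <= self.p_go_omission < 0.05:
            raise ValueError("p_go_omission must lie in [0, 0.05)")
        if not 0.0 <= self.p_choice_error < 1.0:
            raise ValueError("p_choice_error must lie in [0, 1)")
        if not 0.0 <= self.p_trigger_failure <= 1.0:
            raise ValueError("p_trigger_failure must lie in [0, 1]")

    @property
    def expected_go_rt(self) -> float:
        return self.go_mu + self.go_tau + self.motor_delay

    @property
    def true_ssrt(self) -> float:
        """Ground-truth SSRT as recovered from overt behavior."""
        return self.stop_mu + self.motor_delay

    def with_overrides(self, **kwargs) -> "RaceModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TaskConfig:
    """Stop-signal task structure: 450 trials, stop probability 0.24,
    +/-50 ms SSD tracking, performance feedback every 75th trial."""

    n_trials: int = 450
    p_stop: float = 0.24
    staircase_step: float = 50.0
    ssd_start: float = 200.0
    ssd_min: float = 50.0
    ssd_max: float = 900.0
    response_window: float = 1000.0
    feedback_interval: int = 75
    feedback_rt_threshold: float = 600.0
    feedback_acc_threshold: float = 0.40

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 < self.p_stop < 1.0:
            raise ValueError("p_stop must lie in (0, 1)")
        if self.staircase_step <= 0:
            raise ValueError("staircase_step must be > 0")
        if not self.ssd_min <= self.ssd_start <= self.ssd_max:
            raise ValueError("require ssd_min <= ssd_start <= ssd_max")


@dataclass
class TrialRecord:
    """One stop-signal-task trial.

    ``ssd`` and ``stop_success`` are ``None`` on go trials; ``rt`` is ``None``
    when no response was emitted.  ``correct`` is False for wrong-hand
    responses and omissions on go trials, and equals ``stop_success`` on stop
    trials.
    """

    index: int
    kind: str  # "go" | "stop"
    ssd: Optional[float] = None
    rt: Optional[float] = None
    responded: bool = False
    correct: bool = False
    stop_success: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.kind not in ("go", "stop"):
            raise ValueError(f"kind must be 'go' or 'stop', got {self.kind!r}")
        if self.kind == "stop":
            if self.ssd is None:
                raise ValueError("stop trials require an SSD")
            if self.stop_success is None:
                self.stop_success = not self.responded
            if self.stop_success == self.responded:
                raise ValueError("stop_success must equal NOT responded")


@dataclass(frozen=True)
class FeedbackEvent:
    """Performance feedback shown after every ``feedback_interval`` trials.

    Logged for provenance only: the simulated participant does not adjust
    behavior in response (no strategic-adjustment model)."""

    after_trial: int
    mean_go_rt: float
    stop_accuracy: float
    message: str  # "ok" | "faster" | "more accurate" | "faster & more accurate"


class Session(list):
    """A list of :class:`TrialRecord` carrying the session's feedback log
    and the per-trial generative ground truth used by recovery tests."""

    def __init__(self, trials: Iterable[TrialRecord], feedback=(), truth=None):
        super().__init__(trials)
        self.feedback: list[FeedbackEvent] = list(feedback)
        #: DataFrame with columns trial, go_finish_ms, stop_latency_ms (NaN on go trials)
        self.truth: Optional[pd.DataFrame] = truth


def _feedback_message(mean_rt: float, stop_acc: float, cfg: TaskConfig) -> str:
    slow = np.isfinite(mean_rt) and mean_rt > cfg.feedback_rt_threshold
    inacc = np.isfinite(stop_acc) and stop_acc < cfg.feedback_acc_threshold
    if slow and inacc:
        return "faster & more accurate"
    if slow:
        return "faster"
    if inacc:
        return "more accurate"
    return "ok"


def simulate_session(
    params: RaceModelParams,
    cfg: TaskConfig = TaskConfig(),
    rng: Optional[np.random.Generator] = None,
) -> Session:
    """Simulate one task run and return its trials.

    The returned :class:`Session` behaves as a plain list of
    :class:`TrialRecord`; ``session.feedback`` holds the feedback events and
    ``session.truth`` the latent finishing times for recovery tests.

    Parameters
    ----------
    params
        Race-model parameters; ``params.seed`` seeds a fresh generator when
        ``rng`` is not given.
    cfg
        Task structure (trial counts, staircase, feedback rule).
    rng
        Optional numpy generator; takes precedence over ``params.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n = cfg.n_trials
    is_stop = rng.random(n) < cfg.p_stop
    go_finish = params.go_mu + params.go_sigma * rng.standard_normal(n)
    go_finish += rng.exponential(params.go_tau, n)
    go_finish = np.maximum(go_finish, 1.0)  # finishing times are positive
    stop_lat = params.stop_mu + params.stop_sigma * rng.standard_normal(n)
    omit = rng.random(n) < params.p_go_omission
    wrong_hand = rng.random(n) < params.p_choice_error
    trig_fail = rng.random(n) < params.p_trigger_failure

    trials: list[TrialRecord] = []
    feedback: list[FeedbackEvent] = []
    ssd = cfg.ssd_start
    for i in range(n):
        rt = go_finish[i] + params.motor_delay
        responds = (not omit[i]) and rt <= cfg.response_window
        if is_stop[i]:
            stop_wins = (not trig_fail[i]) and go_finish[i] >= ssd + stop_lat[i]
            responded = responds and not stop_wins
            rec = TrialRecord(
                index=i,
                kind="stop",
                ssd=ssd,
                rt=rt if responded else None,
                responded=responded,
                correct=not responded,
                stop_success=not responded,
            )
            ssd += cfg.staircase_step if rec.stop_success else -cfg.staircase_step
            ssd = float(np.clip(ssd, cfg.ssd_min, cfg.ssd_max))
        else:
            rec = TrialRecord(
                index=i,
                kind="go",
                rt=rt if responds else None,
                responded=responds,
                correct=responds and not wrong_hand[i],
            )
        trials.append(rec)

        if (i + 1) % cfg.feedback_interval == 0:
            block = trials[max(0, i + 1 - cfg.feedback_interval) : i + 1]
            go_rts = [t.rt for t in block if t.kind == "go" and t.responded]
            stops = [t for t in block if t.kind == "stop"]
            mean_rt = float(np.mean(go_rts)) if go_rts else float("nan")
            acc = (
                float(np.mean([t.stop_success for t in stops]))
                if stops
                else float("nan")
            )
            ev = FeedbackEvent(i + 1, mean_rt, acc, _feedback_message(mean_rt, acc, cfg))
            feedback.append(ev)
            logger.debug("feedback after trial %d: %s", ev.after_trial, ev.message)

    truth = pd.DataFrame(
        {
            "trial": np.arange(n),
            "go_finish_ms": go_finish,
            "stop_latency_ms": np.where(is_stop, stop_lat, np.nan),
        }
    )
    return Session(trials, feedback, truth)


_TABLE_COLUMNS = [
    "participant",
    "condition",
    "time",
    "trial",
    "kind",
    "ssd_ms",
    "rt_ms",
    "responded",
    "correct",
    "stop_success",
]


def trials_to_table(
    trials: Iterable[TrialRecord],
    participant: str = "s01",
    condition: str = "SHAM",
    time: str = "pre",
) -> pd.DataFrame:
    """Flatten trials into the TSV-ready long table used on disk."""
    rows = []
    for t in trials:
        rows.append(
            {
                "participant": participant,
                "condition": condition,
                "time": time,
                "trial": t.index,
                "kind": t.kind,
                "ssd_ms": t.ssd if t.ssd is not None else np.nan,
                "rt_ms": t.rt if t.rt is not None else np.nan,
                "responded": int(t.responded),
                "correct": int(t.correct),
                "stop_success": ""
                if t.stop_success is None
                else int(t.stop_success),
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def trials_from_table(df: pd.DataFrame) -> list[TrialRecord]:
    """Rebuild :class:`TrialRecord` objects from a trial table (one cell)."""
    trials = []
    for _, r in df.iterrows():
        stop_success = r["stop_success"]
        if stop_success in ("", None) or (
            isinstance(stop_success, float) and np.isnan(stop_success)
        ):
            stop_success = None
        else:
            stop_success = bool(int(stop_success))
        trials.append(
            TrialRecord(
                index=int(r["trial"]),
                kind=str(r["kind"]),
                ssd=None if pd.isna(r["ssd_ms"]) else float(r["ssd_ms"]),
                rt=None if pd.isna(r["rt_ms"]) else float(r["rt_ms"]),
                responded=bool(int(r["responded"])),
                correct=bool(int(r["correct"])),
                stop_success=stop_success,
            )
        )
    return trials
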