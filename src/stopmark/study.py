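"""End-to-end synthetic study: simulate a cohort, extract all stopping-
latency markers, and run the inference layer.

A study is 18 participants x 3 stimulation conditions (IFG, VC, SHAM) x 3
time points (pre, peri, post).  Between-participant heterogeneity is modeled
as Gaussian jitter on the generator parameters around the cohort means, with
the EMG suppression point and the P3 latencies coupled to each participant's
stop-process speed so that the markers correlate across participants the way
latent inhibitory speed would make them.  Cell-level seeds derive
deterministically from the master seed, so a full run is reproducible
bit-for-bit from (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import behavior as bh
from . import emg as emg_mod
from . import erp as erp_mod
from .signals import SignalConfig, synthesize_emg, synthesize_erp_epochs
from .stats import PooledCorrelation, pool_correlations, remove_bivariate_outliers, pearson_r, rm_anova_gg
from .task import RaceModelParams, Session, TaskConfig, simulate_session, trials_to_table

__all__ = [
    "StudyConfig",
    "StudyResult",
    "draw_participant",
    "extract_markers",
    "run_study",
    "reproduce_table2",
    "MEASURE_PAIRS",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("IFG", "VC", "SHAM")
TIMES = ("pre", "peri", "post")

# first-named measure is the Cook's-d regression predictor
MEASURE_PAIRS = [
    ("SSRT", "P3 ol"),
    ("SSRT", "P3 pl"),
    ("SSRT", "prEMG"),
    ("prEMG", "P3 ol"),
    ("prEMG", "P3 pl"),
    ("GoRT", "P3 ol"),
    ("GoRT", "P3 pl"),
    ("GoRT", "prEMG"),
    ("GoRT", "SSRT"),
]

MEASURE_COLUMNS = {
    "GoRT": "go_rt_ms",
    "SSRT": "ssrt_integration_ms",
    "prEMG": "premg_peak_ms",
    "P3 pl": "p3_peak_ms",
    "P3 ol": "p3_onset_ms",
}

ANOVA_MEASURES = ["go_rt_ms", "ssrt_integration_ms", "premg_peak_ms", "p3_peak_ms", "p3_onset_ms"]


@dataclass(frozen=True)
class StudyConfig:
    n_participants: int = 18
    conditions: tuple[str, ...] = CONDITIONS
    times: tuple[str, ...] = TIMES
    params: RaceModelParams = field(default_factory=RaceModelParams)
    task: TaskConfig = field(default_factory=TaskConfig)
    signals: SignalConfig = field(default_factory=SignalConfig)
    # between-participant SDs of the jittered generator parameters (ms)
    sd_go_mu: float = 25.0
    sd_stop_mu: float = 15.0
    sd_suppression: float = 5.0
    sd_p3_onset: float = 10.0
    sd_p3_rise: float = 8.0
    # ms of P3-onset shift per ms of stop-latency shift (latent coupling)
    p3_coupling: float = 0.9
    erp_smooth_ms: float = 20.0
    # per-cell parameter shifts: {(condition, time): {param: delta_ms}}
    effects: Mapping[tuple[str, str], Mapping[str, float]] = field(default_factory=dict)
    master_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "params" in d:
            d["params"] = RaceModelParams(**d["params"])
        if "task" in d:
            d["task"] = TaskConfig(**d["task"])
        if "signals" in d:
            d["signals"] = SignalConfig(**d["signals"])
        if "effects" in d:
            d["effects"] = {
                tuple(k.split("/")): dict(v) for k, v in d["effects"].items()
            }
        for key in ("conditions", "times"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class ParticipantSpec:
    """Generator parameters of one simulated participant."""

    params: RaceModelParams
    signals: SignalConfig


def draw_participant(cfg: StudyConfig, index: int) -> ParticipantSpec:
    """Draw one participant's generator parameters around the cohort means.

    The participant's EMG suppression point tracks their stop latency, and
    the P3 onset shifts by ``p3_coupling`` ms per ms of stop-latency shift;
    the P3 rise time (peak minus onset) jitters independently.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.master_seed, 7, index]))
    p, s = cfg.params, cfg.signals
    stop_mu = float(np.clip(rng.normal(p.stop_mu, cfg.sd_stop_mu), 80.0, 400.0))
    go_mu = float(np.clip(rng.normal(p.go_mu, cfg.sd_go_mu), 200.0, 800.0))
    lag = float(max(stop_mu + rng.normal(0.0, cfg.sd_suppression), 40.0))
    p3_onset = float(
        s.p3_onset + cfg.p3_coupling * (stop_mu - p.stop_mu) + rng.normal(0.0, cfg.sd_p3_onset)
    )
    p3_rise = float(max(s.p3_peak - s.p3_onset + rng.normal(0.0, cfg.sd_p3_rise), 20.0))
    return ParticipantSpec(
        params=replace(p, stop_mu=stop_mu, go_mu=go_mu),
        signals=replace(s, suppression_lag=lag, p3_onset=p3_onset, p3_peak=p3_onset + p3_rise),
    )


def _apply_effects(spec: ParticipantSpec, deltas: Mapping[str, float]) -> ParticipantSpec:
    params, signals = spec.params, spec.signals
    for key, delta in deltas.items():
        if hasattr(params, key):
            params = replace(params, **{key: getattr(params, key) + delta})
            if key == "stop_mu":  # peripheral suppression follows the stop process
                signals = replace(
                    signals, suppression_lag=signals.suppression_lag + delta
                )
        elif hasattr(signals, key):
            if key == "p3_onset":
                signals = replace(
                    signals,
                    p3_onset=signals.p3_onset + delta,
                    p3_peak=signals.p3_peak + delta,
                )
            else:
                signals = replace(signals, **{key: getattr(signals, key) + delta})
        else:
            raise KeyError(f"unknown effect parameter {key!r}")
    return ParticipantSpec(params, signals)


def extract_markers(
    session: Session,
    sig: SignalConfig,
    task: TaskConfig,
    rng: np.random.Generator,
    erp_smooth_ms: float = 20.0,
) -> dict:
    """All four latency markers plus behavior for one simulated cell."""
    ds = bh.BehavioralDataset(list(session))
    summary = bh.summarize(ds)
    ssrt = summary.SSRT_integration

    # ---- EMG: rms -> baseline ratio -> pooled z -> detection -> stop-locked peak
    emg_raw = synthesize_emg(session, sig, rng)
    kept = emg_mod.reject_baseline_artifacts(emg_raw)
    z = emg_mod.zscore_pooled(
        emg_mod.baseline_ratio(emg_mod.rms_transform(emg_raw.subset(kept)))
    )
    succ = {t.index for t in ds.stop_trials if t.stop_success}
    z_stop = z.subset(np.isin(z.trial_index, sorted(succ)))
    detected = emg_mod.detect_premg(z_stop, task.response_window)
    detection_rate = float(detected.mean()) if detected.size else float("nan")
    premg_peak = float("nan")
    premg_boundary = False
    if detected.any() and np.isfinite(ssrt):
        ssd_map = {t.index: t.ssd for t in ds.stop_trials}
        stop_locked = emg_mod.reepoch_to_stop(z_stop.subset(detected), ssd_map)
        peak = emg_mod.premg_peak_latency(stop_locked, ssrt)
        premg_peak, premg_boundary = peak.latency_ms, peak.boundary

    # ---- EEG: baseline correction -> artifact gate -> average -> P3 latencies
    eeg = synthesize_erp_epochs(session, sig, rng)
    base_cols = slice(0, eeg.index_of(0.0))
    eeg_bc = eeg.with_data(eeg.data - eeg.data[:, base_cols].mean(axis=1, keepdims=True))
    accepted = erp_mod.reject_amplitude_artifacts(eeg_bc)
    erp = erp_mod.average_erp(eeg_bc.subset(accepted), smooth_ms=erp_smooth_ms)
    p3 = erp_mod.extract_p3(erp)

    return {
        "go_rt_ms": summary.goRT_mean,
        "usrt_ms": summary.USRT_mean,
        "ssd_ms": summary.SSD_mean,
        "ssrt_integration_ms": summary.SSRT_integration,
        "ssrt_mean_ms": summary.SSRT_mean_method,
        "stop_accuracy": summary.stop_accuracy,
        "go_accuracy": summary.go_accuracy,
        "go_omission_rate": summary.go_omission_rate,
        "detection_rate": detection_rate,
        "premg_peak_ms": premg_peak,
        "premg_boundary": premg_boundary,
        "p3_peak_ms": p3.peak_ms,
        "p3_onset_ms": p3.onset_ms,
        "p3_flags": ";".join(p3.flags),
        "n_eeg_trials": p3.n_trials,
    }


@dataclass
class StudyResult:
    markers: pd.DataFrame
    anovas: dict
    correlations: dict
    recovery: pd.DataFrame
    config: StudyConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.markers.to_csv(out / "markers.csv", index=False)
        self.recovery.to_csv(out / "recovery.csv", index=False)
        rows = []
        for pair, (grid, pooled) in self.correlations.items():
            grid.to_csv(out / f"grid_{pair.replace(' ', '_')}.csv", index=False)
            rows.append(
                {
                    "pair": pair,
                    "m_r": pooled.m_r,
                    "ci95_low": pooled.ci95[0],
                    "ci95_high": pooled.ci95[1],
                    "bf10": pooled.bf10,
                }
            )
        pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)
        anova_json = {
            measure: {
                effect: {
                    "F": res.value,
                    "df": list(res.df),
                    "p": res.p,
                    "epsilon": res.epsilon,
                    "mauchly_w": res.mauchly_w,
                    "df_gg": list(res.df_gg),
                    "p_gg": res.p_gg,
                }
                for effect, res in effects.items()
            }
            for measure, effects in self.anovas.items()
        }
        (out / "anova.json").write_text(json.dumps(anova_json, indent=2))


def simulate_cohort(cfg: StudyConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate every cell; returns (markers table, sessions dict)."""
    rows, sessions = [], {}
    for pi in range(cfg.n_participants):
        spec = draw_participant(cfg, pi)
        pid = f"s{pi + 1:02d}"
        for ci, cond in enumerate(cfg.conditions):
            for ti, time in enumerate(cfg.times):
                cell_spec = _apply_effects(spec, cfg.effects.get((cond, time), {}))
                rng = np.random.default_rng(
                    np.random.SeedSequence([cfg.master_seed, pi, ci, ti])
                )
                session = simulate_session(cell_spec.params, cfg.task, rng)
                sessions[(pid, cond, time)] = (session, cell_spec)
                row = {
                    "participant": pid,
                    "condition": cond,
                    "time": time,
                    **extract_markers(
                        session, cell_spec.signals, cfg.task, rng, cfg.erp_smooth_ms
                    ),
                    "true_ssrt_ms": cell_spec.params.true_ssrt,
                    "true_premg_ms": cell_spec.signals.suppression_lag,
                    "true_p3_onset_ms": cell_spec.signals.p3_onset,
                    "true_p3_peak_ms": cell_spec.signals.p3_peak,
                    "true_go_rt_ms": cell_spec.params.expected_go_rt,
                }
                rows.append(row)
                logger.info("cell %s/%s/%s done", pid, cond, time)
    return pd.DataFrame(rows), sessions


_RECOVERY = [
    ("ssrt_integration_ms", "true_ssrt_ms"),
    ("premg_peak_ms", "true_premg_ms"),
    ("p3_onset_ms", "true_p3_onset_ms"),
    ("p3_peak_ms", "true_p3_peak_ms"),
    ("go_rt_ms", "true_go_rt_ms"),
]


def recovery_table(markers: pd.DataFrame) -> pd.DataFrame:
    """Bias and RMSE of every marker against the generator ground truth."""
    rows = []
    for est, truth in _RECOVERY:
        err = (markers[est] - markers[truth]).dropna()
        rows.append(
            {
                "marker": est,
                "bias_ms": float(err.mean()),
                "rmse_ms": float(np.sqrt((err**2).mean())),
                "mae_ms": float(err.abs().mean()),
                "n_cells": int(err.size),
            }
        )
    return pd.DataFrame(rows)


def correlation_grids(markers: pd.DataFrame) -> dict:
    """Per-cell Pearson r with Cook's-d outlier removal, pooled per pair."""
    out = {}
    for a, b in MEASURE_PAIRS:
        col_a, col_b = MEASURE_COLUMNS[a], MEASURE_COLUMNS[b]
        cells = []
        grid_rows = []
        for (cond, time), cell in markers.groupby(["condition", "time"], sort=False):
            sub = cell[[col_a, col_b]].dropna()
            x, y = sub[col_a].to_numpy(), sub[col_b].to_numpy()
            kept, removed = remove_bivariate_outliers(x, y)
            r = pearson_r(x[kept], y[kept])
            cells.append((r, kept.size))
            grid_rows.append(
                {
                    "condition": cond,
                    "time": time,
                    "r": r,
                    "n": kept.size,
                    "outlier_removed": removed.size > 0,
                }
            )
        pooled = pool_correlations(cells)
        out[f"{a} - {b}"] = (pd.DataFrame(grid_rows), pooled)
    return out


def run_study(cfg: StudyConfig = StudyConfig()) -> StudyResult:
    """Simulate, extract and analyze the full synthetic study."""
    try:
        markers, _ = simulate_cohort(cfg)
    except Exception as e:  # pragma: no cover - diagnostics only
        raise RuntimeError(f"[simulate] stage failed: {e}") from e

    anovas = {}
    for measure in ANOVA_MEASURES:
        sub = markers[["participant", "condition", "time", measure]].rename(
            columns={measure: "value"}
        )
        if sub["value"].isna().any():
            logger.warning("skipping rmANOVA for %s: missing cells", measure)
            continue
        try:
            anovas[measure] = rm_anova_gg(sub, dv="value")
        except Exception as e:
            raise RuntimeError(f"[stats:anova:{measure}] stage failed: {e}") from e

    try:
        correlations = correlation_grids(markers)
    except Exception as e:
        raise RuntimeError(f"[stats:correlations] stage failed: {e}") from e

    return StudyResult(
        markers=markers,
        anovas=anovas,
        correlations=correlations,
        recovery=recovery_table(markers),
        config=cfg,
    )


def load_table2_fixture() -> pd.DataFrame:
    """The packaged grid of per-cell correlation coefficients (synthetic
    transcription of a published reference surface, two-decimal values)."""
    with resources.files("stopmark.data").joinpath("table2_correlations.csv").open() as f:
        df = pd.read_csv(f)
    expected = {"pair", "condition", "time", "r", "n", "m_r_printed"}
    if not expected.issubset(df.columns):
        raise ValueError(f"malformed fixture: columns {sorted(df.columns)}")
    return df


def reproduce_table2(fixture: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Pool each measure pair's printed r grid and compare with printed M_r.

    Returns one row per pair with the recomputed M_r (two-decimal inputs in,
    pooled on the Fisher-z scale with n-3 weights), the printed M_r, and
    whether they agree within +/-0.01.
    """
    df = load_table2_fixture() if fixture is None else fixture
    required = {"pair", "r", "n", "m_r_printed"}
    if not required.issubset(df.columns):
        raise ValueError(f"malformed correlation grid: need columns {sorted(required)}")
    rows = []
    for pair, grp in df.groupby("pair", sort=False):
        pooled = pool_correlations(list(zip(grp["r"], grp["n"])))
        printed = float(grp["m_r_printed"].iloc[0])
        rows.append(
            {
                "pair": pair,
                "m_r": round(pooled.m_r, 2),
                "m_r_printed": printed,
                "recovered": abs(pooled.m_r - printed) <= 0.01 + 1e-9,
                "ci95_low": pooled.ci95[0],
                "ci95_high": pooled.ci95[1],
                "bf10": pooled.bf10,
            }
        )
    return pd.DataFrame(rows)


def cohort_trial_table(cfg: StudyConfig) -> pd.DataFrame:
    """Long trial table for every cell of the design (TSV-ready)."""
    frames = []
    for pi in range(cfg.n_participants):
        spec = draw_participant(cfg, pi)
        pid = f"s{pi + 1:02d}"
        for ci, cond in enumerate(cfg.conditions):
            for ti, time in enumerate(cfg.times):
                cell_spec = _apply_effects(spec, cfg.effects.get((cond, time), {}))
                rng = np.random.default_rng(
                    np.random.SeedSequence([cfg.master_seed, pi, ci, ti])
                )
                session = simulate_session(cell_spec.params, cfg.task, rng)
                frames.append(trials_to_table(session, pid, cond, time))
    return pd.concat(frames, ignore_index=True)
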