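"""First-level GLM: 11-regressor design with parametric modulators.

The task design has three condition regressors (choice, anticipation,
outcome), outcome-locked parametric modulators, and six motion parameters.
In the ``rpe`` variant the modulators are the unbiased RPE and the
momentum-bias difference (11 named regressors total); the ``momentum``
variant swaps them for a single momentum modulator (10 regressors).
Modulator values are mean-centered at the event level across the session
before convolution; no serial orthogonalization is applied (the difference
coding of the bias modulator exists precisely to keep collinearity low).

Estimation is ordinary least squares per run, with per-run intercept,
linear and quadratic drift nuisance columns, and equal-weight averaging of
betas across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rpe_models import ModelParams, biased_rpes, momentum_series
from .synthetic_bold import ROITimeSeries, SimConfig, _event_train, hrf
from .task_design import TrialSchedule

__all__ = [
    "DesignMatrix",
    "FirstLevelResult",
    "GLMError",
    "build_design",
    "fit_glm",
    "extract_contrast",
    "fit_participant",
    "cohort_contrasts",
]

VARIANT_RPE = "rpe"
VARIANT_MOMENTUM = "momentum"

# contrast/regressor names
OUTCOME_X_DELTA = "outcome_x_delta"
OUTCOME_X_MOMENTUM_BIAS = "outcome_x_momentum_bias"
OUTCOME_X_MOMENTUM = "outcome_x_momentum"
MOTION_NAMES = tuple(f"motion_{i + 1}" for i in range(6))


class GLMError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Named task/motion regressors per run, sampled on the scan grid.

    ``runs[r]`` is an ``(n_scans_r, n_task_regressors)`` array whose columns
    follow ``names``; nuisance intercept/drift columns are appended at fit
    time.
    """

    names: list[str]
    runs: list[np.ndarray]
    tr: float
    variant: str

    @property
    def n_task_regressors(self) -> int:
        return len(self.names)

    def condition_numbers(self) -> list[float]:
        return [float(np.linalg.cond(X)) for X in self.runs]

    def to_frame(self, run: int = 0) -> pd.DataFrame:
        return pd.DataFrame(self.runs[run], columns=self.names)


@dataclass
class FirstLevelResult:
    """Run-averaged OLS betas for one participant and one ROI."""

    pid: str | None
    names: list[str]
    betas: dict[str, float]
    per_run: np.ndarray  # (n_runs, n_regressors incl. nuisance)
    resid_var: float

    def beta_vector(self) -> np.ndarray:
        return np.array([self.betas[n] for n in self.names])


def _variant_pmod_names(variant: str) -> list[str]:
    if variant == VARIANT_RPE:
        return [OUTCOME_X_DELTA, OUTCOME_X_MOMENTUM_BIAS]
    if variant == VARIANT_MOMENTUM:
        return [OUTCOME_X_MOMENTUM]
    raise GLMError(f"unknown model variant {variant!r}")


def build_design(
    schedule: TrialSchedule,
    pmods: dict[str, np.ndarray],
    motion: list[np.ndarray],
    tr: float,
    n_scans: list[int] | None = None,
    variant: str = VARIANT_RPE,
    sim: SimConfig | None = None,
) -> DesignMatrix:
    """Build the per-run design matrix of named task + motion regressors.

    ``pmods`` maps modulator names (``outcome_x_delta`` etc., per variant)
    to per-trial value arrays over the whole session.  Event regressors are
    built on a fine grid, convolved with the canonical HRF and sampled at
    the scan grid; modulators are mean-centered across all outcome events
    first.  ``n_scans`` defaults to what the motion arrays imply.
    """
    sim = sim or SimConfig(tr=tr)
    pmod_names = _variant_pmod_names(variant)
    missing = [n for n in pmod_names if n not in pmods]
    if missing:
        raise GLMError(f"variant {variant!r} requires pmods {missing}")
    n_trials = len(schedule)
    for name in pmod_names:
        if len(pmods[name]) != n_trials:
            raise GLMError(
                f"pmod {name!r} has length {len(pmods[name])} but the schedule "
                f"has {n_trials} outcome events"
            )
    run_ids = schedule.run_ids()
    if len(motion) != len(run_ids):
        raise GLMError(f"{len(motion)} motion arrays for {len(run_ids)} runs")
    if n_scans is None:
        n_scans = [len(m) for m in motion]

    centered = {name: np.asarray(pmods[name], dtype=float) for name in pmod_names}
    centered = {name: v - v.mean() for name, v in centered.items()}
    for name, v in centered.items():
        if np.allclose(v, 0.0):
            warnings.warn(f"modulator column {name!r} is identically zero after centering")

    kernel = hrf(sim.dt, sim.hrf_duration)
    names = ["choice", "anticipation", "outcome", *pmod_names, *MOTION_NAMES]
    run_mats: list[np.ndarray] = []
    for r, run in enumerate(run_ids):
        trials = schedule.run_trials(run)
        idx = schedule.run_trial_indices(run)
        ns = n_scans[r]
        mot = np.asarray(motion[r], dtype=float)
        if mot.shape != (ns, 6):
            raise GLMError(f"run {run}: motion shape {mot.shape}, expected ({ns}, 6)")
        n_fine = int(np.round((ns - 1) * sim.tr / sim.dt)) + int(sim.hrf_duration / sim.dt)
        onset_choice = np.array([t.onset_choice for t in trials])
        onset_ant = np.array([t.onset_anticipation for t in trials])
        onset_out = np.array([t.onset_outcome for t in trials])
        dur_choice = onset_ant - onset_choice
        dur_ant = onset_out - onset_ant
        outcome_dur = schedule.config.outcome_duration if schedule.config else 2.0
        dur_out = np.full(len(trials), outcome_dur)
        ones = np.ones(len(trials))

        scan_idx = np.round(np.arange(ns) * sim.tr / sim.dt).astype(int)
        scan_idx = np.clip(scan_idx, 0, n_fine - 1)

        def column(onsets, amps, durs):
            train = _event_train(n_fine, sim.dt, onsets, amps, durs, sim.stick)
            return np.convolve(train, kernel)[:n_fine][scan_idx]

        cols = [
            column(onset_choice, ones, dur_choice),
            column(onset_ant, ones, dur_ant),
            column(onset_out, ones, dur_out),
        ]
        for name in pmod_names:
            cols.append(column(onset_out, centered[name][idx], dur_out))
        X = np.column_stack(cols + [mot])
        run_mats.append(X)
    return DesignMatrix(names=names, runs=run_mats, tr=sim.tr, variant=variant)


def _nuisance(n: int) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, n)
    return np.column_stack([np.ones(n), t, t**2])


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # flag columns whose QR diagonal collapses
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        scale = diag.max() if diag.max() > 0 else 1.0
        bad = [names[i] for i in np.nonzero(diag / scale < 1e-10)[0]]
        raise GLMError(f"design is rank deficient; collinear columns: {bad or names}")


def fit_glm(ts: ROITimeSeries, design: DesignMatrix) -> FirstLevelResult:
    """OLS fit per run with intercept + linear + quadratic drift nuisance,
    then equal-weight averaging of betas across runs."""
    if ts.n_runs != len(design.runs):
        raise GLMError(f"{ts.n_runs} data runs but {len(design.runs)} design runs")
    all_names = design.names + ["drift_const", "drift_lin", "drift_quad"]
    per_run = []
    rss = 0.0
    dof = 0
    for y, X in zip(ts.runs, design.runs):
        if len(y) != X.shape[0]:
            raise GLMError(f"run length mismatch: {len(y)} scans vs {X.shape[0]} design rows")
        Xa = np.column_stack([X, _nuisance(len(y))])
        _check_rank(Xa, all_names)
        beta, res, *_ = np.linalg.lstsq(Xa, np.asarray(y, dtype=float), rcond=None)
        per_run.append(beta)
        resid = y - Xa @ beta
        rss += float(resid @ resid)
        dof += len(y) - Xa.shape[1]
    per_run = np.array(per_run)
    mean_beta = per_run.mean(axis=0)
    return FirstLevelResult(
        pid=None,
        names=all_names,
        betas=dict(zip(all_names, mean_beta)),
        per_run=per_run,
        resid_var=rss / max(dof, 1),
    )


def extract_contrast(result: FirstLevelResult, name: str) -> float:
    """Run-averaged beta for a named regressor (identity contrast)."""
    if name not in result.betas:
        raise KeyError(
            f"unknown regressor {name!r}; available: {sorted(result.betas)}"
        )
    return float(result.betas[name])


def default_pmods(
    schedule: TrialSchedule, model_params: ModelParams, variant: str
) -> dict[str, np.ndarray]:
    """Model-derived parametric modulators for a schedule."""
    if variant == VARIANT_RPE:
        trace = biased_rpes(schedule, model_params)
        return {
            OUTCOME_X_DELTA: trace.delta,
            OUTCOME_X_MOMENTUM_BIAS: trace.pmod_momentum_bias,
        }
    if variant == VARIANT_MOMENTUM:
        return {OUTCOME_X_MOMENTUM: momentum_series(schedule, model_params)}
    raise GLMError(f"unknown model variant {variant!r}")


def fit_participant(
    participant,
    model_params: ModelParams,
    variant: str = VARIANT_RPE,
    roi: str = "ventral_striatum",
    sim: SimConfig | None = None,
) -> FirstLevelResult:
    """Convenience wrapper: design + fit for one simulated participant."""
    ts = participant.timeseries[roi]
    pmods = default_pmods(participant.schedule, model_params, variant)
    design = build_design(
        participant.schedule,
        pmods,
        ts.motion,
        tr=ts.tr,
        n_scans=[len(y) for y in ts.runs],
        variant=variant,
        sim=sim,
    )
    result = fit_glm(ts, design)
    result.pid = participant.pid
    return result


def cohort_contrasts(
    cohort,
    variant: str = VARIANT_RPE,
    roi: str = "ventral_striatum",
    contrasts: list[str] | None = None,
) -> pd.DataFrame:
    """Per-participant contrast table (pid, group, one column per contrast)."""
    if contrasts is None:
        contrasts = _variant_pmod_names(variant)
    sim = cohort.sim
    rows = []
    for p in cohort.participants:
        result = fit_participant(p, cohort.model_params, variant, roi, sim=sim)
        row = {"pid": p.pid, "group": p.group}
        for c in contrasts:
            row[c] = extract_contrast(result, c)
        rows.append(row)
    return pd.DataFrame(rows)
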