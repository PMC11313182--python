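"""Generalized psychophysiological interaction (gPPI) on ROI time series.

The interaction is formed at the BOLD level: per run, the seed series is
mean-centered and multiplied elementwise by the (also centered) convolved
psychological regressor — outcome events weighted by the trialwise
modulator.  The target is then regressed on {seed, psychological regressor,
their product, motion, drift}; the product's coefficient indexes how the
seed-target coupling varies with the modulator.  A deconvolve-to-neural
variant is deliberately not implemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .first_level_glm import GLMError, _check_rank, _nuisance
from .rpe_models import ModelParams, biased_rpes, unbiased_rpes
from .synthetic_bold import ROITimeSeries, SimConfig, _event_train, hrf
from .task_design import TrialSchedule

__all__ = ["PPIResult", "ppi_fit", "ppi_specificity", "cohort_ppi"]

PSYCH_MOMENTUM_BIAS = "momentum_bias"
PSYCH_DELTA = "delta"


@dataclass
class PPIResult:
    """Run-averaged gPPI coefficients for one seed-target pair."""

    pid: str | None
    beta_seed: float
    beta_psych: float
    beta_ppi: float
    psych_name: str
    degenerate: bool = False  # psychological regressor was identically zero


def _psych_regressor(
    schedule: TrialSchedule, pmod: np.ndarray, run: int, n_scans: int, sim: SimConfig
) -> np.ndarray:
    trials = schedule.run_trials(run)
    idx = schedule.run_trial_indices(run)
    onset_out = np.array([t.onset_outcome for t in trials])
    n_fine = int(np.round((n_scans - 1) * sim.tr / sim.dt)) + int(sim.hrf_duration / sim.dt)
    kernel = hrf(sim.dt, sim.hrf_duration)
    outcome_dur = schedule.config.outcome_duration if schedule.config else 2.0
    train = _event_train(
        n_fine, sim.dt, onset_out, pmod[idx], np.full(len(trials), outcome_dur), sim.stick
    )
    scan_idx = np.clip(
        np.round(np.arange(n_scans) * sim.tr / sim.dt).astype(int), 0, n_fine - 1
    )
    return np.convolve(train, kernel)[:n_fine][scan_idx]


def _condition_columns(
    schedule: TrialSchedule, run: int, n_scans: int, sim: SimConfig
) -> np.ndarray:
    """Convolved unit choice/anticipation/outcome regressors (gPPI includes
    the task conditions so event-locked target activity cannot masquerade as
    an interaction)."""
    trials = schedule.run_trials(run)
    n_fine = int(np.round((n_scans - 1) * sim.tr / sim.dt)) + int(sim.hrf_duration / sim.dt)
    kernel = hrf(sim.dt, sim.hrf_duration)
    scan_idx = np.clip(
        np.round(np.arange(n_scans) * sim.tr / sim.dt).astype(int), 0, n_fine - 1
    )
    outcome_dur = schedule.config.outcome_duration if schedule.config else 2.0
    ones = np.ones(len(trials))
    cols = []
    for onsets, durs in (
        (np.array([t.onset_choice for t in trials]),
         np.array([t.onset_anticipation - t.onset_choice for t in trials])),
        (np.array([t.onset_anticipation for t in trials]),
         np.array([t.onset_outcome - t.onset_anticipation for t in trials])),
        (np.array([t.onset_outcome for t in trials]), np.full(len(trials), outcome_dur)),
    ):
        train = _event_train(n_fine, sim.dt, onsets, ones, durs, sim.stick)
        cols.append(np.convolve(train, kernel)[:n_fine][scan_idx])
    return np.column_stack(cols)


def ppi_fit(
    seed_ts: ROITimeSeries,
    target_ts: ROITimeSeries,
    schedule: TrialSchedule,
    pmod: np.ndarray,
    sim: SimConfig | None = None,
    psych_name: str = PSYCH_MOMENTUM_BIAS,
) -> PPIResult:
    """Fit the gPPI model per run and average coefficients across runs.

    ``pmod`` holds one value per trial (whole session); it is mean-centered
    across the session before building the psychological regressor.  If the
    regressor is identically zero the interaction is undefined and all
    coefficients involving it are reported as 0 with ``degenerate=True``.
    """
    sim = sim or SimConfig(tr=seed_ts.tr)
    if seed_ts.n_runs != target_ts.n_runs:
        raise GLMError(
            f"seed has {seed_ts.n_runs} runs but target has {target_ts.n_runs}"
        )
    run_ids = schedule.run_ids()
    if seed_ts.n_runs != len(run_ids):
        raise GLMError(f"{seed_ts.n_runs} data runs but schedule has {len(run_ids)}")
    pmod = np.asarray(pmod, dtype=float)
    if len(pmod) != len(schedule):
        raise GLMError(
            f"pmod length {len(pmod)} does not match {len(schedule)} trials"
        )
    pmod_c = pmod - pmod.mean()

    if np.allclose(pmod_c, 0.0):
        warnings.warn(
            f"psychological regressor {psych_name!r} is identically zero; "
            "PPI coefficient reported as 0"
        )
        return PPIResult(None, 0.0, 0.0, 0.0, psych_name, degenerate=True)

    betas = []
    names = ["seed", "psych", "ppi", "choice", "anticipation", "outcome",
             *[f"motion_{i+1}" for i in range(6)],
             "drift_const", "drift_lin", "drift_quad"]
    for r, run in enumerate(run_ids):
        seed = np.asarray(seed_ts.runs[r], dtype=float)
        target = np.asarray(target_ts.runs[r], dtype=float)
        if len(seed) != len(target):
            raise GLMError(f"run {run}: seed has {len(seed)} scans, target {len(target)}")
        psych = _psych_regressor(schedule, pmod_c, run, len(seed), sim)
        conditions = _condition_columns(schedule, run, len(seed), sim)
        seed_c = seed - seed.mean()
        psych_c = psych - psych.mean()
        ppi_term = seed_c * psych_c
        X = np.column_stack(
            [seed_c, psych_c, ppi_term, conditions,
             np.asarray(seed_ts.motion[r], dtype=float), _nuisance(len(seed))]
        )
        _check_rank(X, names)
        beta, *_ = np.linalg.lstsq(X, target, rcond=None)
        betas.append(beta[:3])
    mean = np.mean(betas, axis=0)
    return PPIResult(
        pid=None,
        beta_seed=float(mean[0]),
        beta_psych=float(mean[1]),
        beta_ppi=float(mean[2]),
        psych_name=psych_name,
    )


def ppi_specificity(
    seed_ts: ROITimeSeries,
    target_ts: ROITimeSeries,
    schedule: TrialSchedule,
    delta_pmod: np.ndarray,
    sim: SimConfig | None = None,
) -> PPIResult:
    """Same machinery with the unbiased-RPE modulator (specificity check)."""
    return ppi_fit(seed_ts, target_ts, schedule, delta_pmod, sim, psych_name=PSYCH_DELTA)


def cohort_ppi(
    cohort,
    psych: str = PSYCH_MOMENTUM_BIAS,
    seed_roi: str = "ventral_striatum",
    target_roi: str = "left_insula",
) -> pd.DataFrame:
    """Per-participant gPPI table for a simulated cohort."""
    rows = []
    for p in cohort.participants:
        if psych == PSYCH_MOMENTUM_BIAS:
            pmod = biased_rpes(p.schedule, cohort.model_params).pmod_momentum_bias
        elif psych == PSYCH_DELTA:
            pmod = unbiased_rpes(p.schedule).delta
        else:
            raise ValueError(f"unknown psychological modulator {psych!r}")
        res = ppi_fit(
            p.timeseries[seed_roi], p.timeseries[target_roi], p.schedule, pmod,
            sim=cohort.sim, psych_name=psych,
        )
        rows.append(
            {
                "pid": p.pid,
                "group": p.group,
                "beta_seed": res.beta_seed,
                "beta_psych": res.beta_psych,
                "beta_ppi": res.beta_ppi,
                "psych_name": psych,
            }
        )
    return pd.DataFrame(rows)
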