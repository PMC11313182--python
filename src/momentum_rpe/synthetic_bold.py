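"""Synthetic ROI BOLD generator for the two-group momentum-bias study.

ROI signals are simulated directly as ROI means (one series per region per
run), not voxel grids.  For each participant, neural event trains are built
on a fine time grid, convolved with the canonical double-gamma HRF, sampled
at the scanner TR, and corrupted with AR(1) noise, slow drift and
motion-correlated nuisance:

* ventral striatum (VS): outcome impulses with amplitude
  ``beta_outcome + beta_delta * delta_t + beta_momentum_bias * Delta_t``
  (modulator values mean-centered across the session, matching the GLM
  centering convention) plus choice/anticipation condition impulses;
* left anterior insula: condition impulses, a momentum term
  ``beta_momentum * h_t`` at outcomes, and coupling
  ``(gamma0 + gamma1 * Delta_t) * (VS neural)`` injected at the neural
  level before convolution;
* right anterior insula: as the left but with no momentum term and no
  ``gamma1`` modulation (baseline coupling only).

Group ground-truth distributions default to values calibrated to the
study's printed per-group summaries of recovered effect sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .rpe_models import ModelParams, biased_rpes, momentum_series
from .task_design import ScheduleConfig, TrialSchedule, generate_schedule, write_events

__all__ = [
    "BIPOLAR_LIKE",
    "CONTROL_LIKE",
    "SimConfig",
    "EffectSpec",
    "ParticipantGroundTruth",
    "ROITimeSeries",
    "Participant",
    "Cohort",
    "hrf",
    "simulate_participant",
    "simulate_cohort",
    "write_cohort",
]

BIPOLAR_LIKE = "bipolar_like"
CONTROL_LIKE = "control_like"
GROUPS = (BIPOLAR_LIKE, CONTROL_LIKE)

ROI_VS = "ventral_striatum"
ROI_LINS = "left_insula"
ROI_RINS = "right_insula"
ROIS = (ROI_VS, ROI_LINS, ROI_RINS)


class EffectSpecError(ValueError):
    """Raised for inconsistent cohort effect specifications."""


def hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled every ``tr`` s.

    Difference of two gamma densities (shapes 6 and 16, unit scale, the
    undershoot weighted 1/6), peak-normalized to 1.  Zero at t = 0, peak
    near 5 s, undershoot around 15 s.
    """
    if tr <= 0:
        raise ValueError(f"tr must be > 0, got {tr}")
    t = np.arange(0.0, duration, tr)
    resp = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    peak = resp.max()
    if peak > 0:
        resp = resp / peak
    return resp


@dataclass(frozen=True)
class SimConfig:
    """Scanner/simulation settings shared across a cohort."""

    tr: float = 2.0
    dt: float = 0.1  # fine grid for neural trains before convolution
    hrf_duration: float = 32.0
    pad: float = 16.0  # post-run padding so late responses are sampled
    stick: bool = True  # impulse events; False -> boxcar over event duration
    drift_period: float = 128.0
    motion_step_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.dt <= 0:
            raise ValueError("tr and dt must be > 0")


@dataclass(frozen=True)
class ParticipantGroundTruth:
    """Per-participant generative parameters (the recovery ledger entries)."""

    group: str
    beta_outcome: float = 1.0
    beta_choice: float = 0.5
    beta_anticipation: float = 0.5
    beta_delta: float = 0.25
    beta_momentum_bias: float = 0.5
    beta_momentum: float = 0.3
    gamma0: float = 0.3
    gamma1: float = 0.1
    noise_sigma: float = 0.5
    ar1_rho: float = 0.3
    drift_amplitude: float = 0.3
    motion_leak: float = 0.05
    seed: int = 0


@dataclass
class ROITimeSeries:
    """BOLD samples for one ROI: one array per run plus paired motion."""

    roi: str
    tr: float
    runs: list[np.ndarray]
    motion: list[np.ndarray]  # each (n_scans, 6)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if len(self.runs) != len(self.motion):
            raise ValueError("runs and motion must pair one-to-one")
        for r, (y, m) in enumerate(zip(self.runs, self.motion)):
            if len(y) != len(m):
                raise ValueError(f"run {r}: {len(y)} scans but {len(m)} motion rows")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.runs)


# Group distributions (mean, sd) calibrated to the study's printed
# per-group summaries of recovered ROI effect estimates.
_DEFAULT_GROUP_EFFECTS: dict[str, dict[str, tuple[float, float]]] = {
    BIPOLAR_LIKE: {
        "beta_delta": (0.28, 0.22),
        "beta_momentum_bias": (0.75, 1.37),
        "beta_momentum": (0.33, 1.0),
        "gamma1": (-0.11, 0.30),
    },
    CONTROL_LIKE: {
        "beta_delta": (0.20, 0.14),
        "beta_momentum_bias": (0.19, 1.08),
        "beta_momentum": (0.33, 1.0),
        "gamma1": (0.22, 0.31),
    },
}

# Demographic/symptom distributions per group: (mean, sd) for continuous
# scores, probability for binary ones.  Calibrated to the printed group
# summary table.
_DEFAULT_DEMOGRAPHICS: dict[str, dict[str, tuple[float, float] | float]] = {
    BIPOLAR_LIKE: {
        "age": (35.95, 8.34),
        "female_p": 11 / 21,
        "HAMD": (3.83, 2.96),
        "MAS": (3.55, 3.09),
        "BIS": (76.95, 9.94),
    },
    CONTROL_LIKE: {
        "age": (33.25, 9.32),
        "female_p": 9 / 21,
        "HAMD": (0.60, 1.04),
        "MAS": (0.38, 1.11),
        "BIS": (62.62, 6.00),
    },
}


@dataclass(frozen=True)
class EffectSpec:
    """Cohort-level generative specification.

    ``group_effects[group][name] = (mean, sd)`` for the per-participant
    draws; scalar fields are shared across participants.
    """

    group_effects: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in _DEFAULT_GROUP_EFFECTS.items()}
    )
    demographics: dict[str, dict] = field(
        default_factory=lambda: {g: dict(v) for g, v in _DEFAULT_DEMOGRAPHICS.items()}
    )
    beta_outcome: float = 1.0
    beta_choice: float = 0.5
    beta_anticipation: float = 0.5
    gamma0: float = 0.3
    noise_sigma: float = 0.5
    ar1_rho: float = 0.3
    drift_amplitude: float = 0.3
    motion_leak: float = 0.05

    def __post_init__(self) -> None:
        for g in GROUPS:
            if g not in self.group_effects:
                raise EffectSpecError(f"group_effects missing group {g!r}")
            for name, (mu, sd) in self.group_effects[g].items():
                if sd < 0:
                    raise EffectSpecError(f"{g}/{name}: sd must be >= 0, got {sd}")
        if self.noise_sigma < 0:
            raise EffectSpecError("noise_sigma must be >= 0")


@dataclass
class Participant:
    pid: str
    group: str
    schedule: TrialSchedule
    truth: ParticipantGroundTruth
    timeseries: dict[str, ROITimeSeries] | None = None
    demographics: dict[str, float] = field(default_factory=dict)


@dataclass
class Cohort:
    participants: list[Participant]
    effect_spec: EffectSpec
    model_params: ModelParams
    sim: SimConfig
    seed: int

    def __len__(self) -> int:
        return len(self.participants)

    def group(self, name: str) -> list[Participant]:
        return [p for p in self.participants if p.group == name]

    def ground_truth_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            row = {"pid": p.pid, "group": p.group}
            row.update(dataclasses.asdict(p.truth))
            row.update(p.demographics)
            rows.append(row)
        return pd.DataFrame(rows)


def _event_train(
    n_fine: int, dt: float, onsets: np.ndarray, amplitudes: np.ndarray,
    durations: np.ndarray | None, stick: bool,
) -> np.ndarray:
    train = np.zeros(n_fine)
    for i, onset in enumerate(onsets):
        j = int(round(onset / dt))
        if j >= n_fine:
            continue
        if stick or durations is None:
            train[j] += amplitudes[i]
        else:
            k = max(j + 1, min(n_fine, j + int(round(durations[i] / dt))))
            train[j:k] += amplitudes[i]
    return train


def _ar1_noise(rng: np.random.Generator, n: int, sigma: float, rho: float) -> np.ndarray:
    if sigma == 0 or n == 0:
        return np.zeros(n)
    innov = rng.standard_normal(n) * sigma * np.sqrt(max(1.0 - rho**2, 0.0))
    if n:
        innov[0] = rng.standard_normal() * sigma  # stationary start
    return signal.lfilter([1.0], [1.0, -rho], innov)


def _centered(x: np.ndarray) -> np.ndarray:
    return x - x.mean() if len(x) else x


def simulate_participant(
    schedule: TrialSchedule,
    truth: ParticipantGroundTruth,
    model_params: ModelParams | None = None,
    sim: SimConfig | None = None,
) -> dict[str, ROITimeSeries]:
    """Simulate the three ROI time series for one participant.

    Deterministic given ``truth.seed``.  Raises ``FloatingPointError`` if a
    non-finite sample is produced.
    """
    model_params = model_params or ModelParams()
    sim = sim or SimConfig()
    trace = biased_rpes(schedule, model_params)
    delta_c = _centered(trace.delta)
    dmod_c = _centered(trace.pmod_momentum_bias)
    h_c = _centered(momentum_series(schedule, model_params))

    kernel = hrf(sim.dt, sim.hrf_duration)
    rng = np.random.default_rng(truth.seed)

    per_roi_runs: dict[str, list[np.ndarray]] = {roi: [] for roi in ROIS}
    motion_runs: list[np.ndarray] = []
    leak_weights = rng.standard_normal(6)

    for run in schedule.run_ids():
        trials = schedule.run_trials(run)
        idx = schedule.run_trial_indices(run)
        duration = schedule.run_duration(run, pad=sim.pad)
        n_fine = int(np.ceil(duration / sim.dt))
        n_scans = int(np.floor(duration / sim.tr))

        onset_choice = np.array([t.onset_choice for t in trials])
        onset_ant = np.array([t.onset_anticipation for t in trials])
        onset_out = np.array([t.onset_outcome for t in trials])
        dur_choice = onset_ant - onset_choice
        dur_ant = onset_out - onset_ant
        outcome_dur = schedule.config.outcome_duration if schedule.config else 2.0
        dur_out = np.full(len(trials), outcome_dur)

        ones = np.ones(len(trials))
        vs_out_amp = (
            truth.beta_outcome
            + truth.beta_delta * delta_c[idx]
            + truth.beta_momentum_bias * dmod_c[idx]
        )
        cond = (
            _event_train(n_fine, sim.dt, onset_choice, truth.beta_choice * ones, dur_choice, sim.stick)
            + _event_train(n_fine, sim.dt, onset_ant, truth.beta_anticipation * ones, dur_ant, sim.stick)
        )
        vs_base = cond + _event_train(
            n_fine, sim.dt, onset_out, truth.beta_outcome * ones, dur_out, sim.stick
        )
        vs = cond + _event_train(n_fine, sim.dt, onset_out, vs_out_amp, dur_out, sim.stick)
        vs_mod = _event_train(
            n_fine, sim.dt, onset_out, dmod_c[idx] * vs_out_amp, dur_out, sim.stick
        )
        ins_l = (
            cond
            + _event_train(
                n_fine, sim.dt, onset_out,
                truth.beta_outcome + truth.beta_momentum * h_c[idx], dur_out, sim.stick,
            )
            + truth.gamma0 * vs
            + truth.gamma1 * vs_mod
        )
        # right insula: no momentum term and baseline coupling only, restricted
        # to the unmodulated VS signal so no momentum-correlated cross-talk
        # leaks in (the study's momentum tracking was left-selective)
        ins_r = (
            cond
            + _event_train(n_fine, sim.dt, onset_out, truth.beta_outcome * ones, dur_out, sim.stick)
            + truth.gamma0 * vs_base
        )

        scan_idx = np.round(np.arange(n_scans) * sim.tr / sim.dt).astype(int)
        scan_idx = np.clip(scan_idx, 0, n_fine - 1)
        scan_t = np.arange(n_scans) * sim.tr

        motion = np.cumsum(
            rng.normal(0.0, sim.motion_step_sd, size=(n_scans, 6)), axis=0
        )
        motion_runs.append(motion)

        drift_phase = rng.uniform(0, 2 * np.pi)
        drift = truth.drift_amplitude * (
            np.cos(2 * np.pi * scan_t / sim.drift_period + drift_phase)
            + (scan_t / max(scan_t[-1], 1.0)) * rng.normal(0, 0.5)
        )

        for roi, train in ((ROI_VS, vs), (ROI_LINS, ins_l), (ROI_RINS, ins_r)):
            bold_fine = np.convolve(train, kernel)[:n_fine]
            y = bold_fine[scan_idx]
            y = y + drift + truth.motion_leak * (motion @ leak_weights)
            y = y + _ar1_noise(rng, n_scans, truth.noise_sigma, truth.ar1_rho)
            if not np.all(np.isfinite(y)):
                raise FloatingPointError(f"non-finite BOLD sample in {roi} run {run}")
            per_roi_runs[roi].append(y)

    return {
        roi: ROITimeSeries(roi=roi, tr=sim.tr, runs=per_roi_runs[roi], motion=motion_runs)
        for roi in ROIS
    }


def _draw(rng: np.random.Generator, mean_sd: tuple[float, float]) -> float:
    mu, sd = mean_sd
    return float(rng.normal(mu, sd)) if sd > 0 else float(mu)


def _draw_demographics(rng: np.random.Generator, spec: dict) -> dict[str, float]:
    demo: dict[str, float] = {}
    for name in ("age", "HAMD", "MAS", "BIS"):
        mu, sd = spec[name]
        lo = 18.0 if name == "age" else 0.0
        demo[name] = max(lo, float(rng.normal(mu, sd)))
    demo["female"] = float(rng.random() < spec["female_p"])
    return demo


def simulate_cohort(
    n_per_group: int = 21,
    effect_spec: EffectSpec | None = None,
    seed: int = 0,
    schedule_config: ScheduleConfig | None = None,
    model_params: ModelParams | None = None,
    sim: SimConfig | None = None,
    simulate_timeseries: bool = True,
) -> Cohort:
    """Simulate a two-group cohort with a full ground-truth ledger.

    Each participant gets an independently pseudorandomized schedule and an
    independent noise seed; identical arguments produce a bit-identical
    cohort.
    """
    if n_per_group < 2:
        raise EffectSpecError(f"n_per_group must be >= 2, got {n_per_group}")
    effect_spec = effect_spec or EffectSpec()
    schedule_config = schedule_config or ScheduleConfig()
    model_params = model_params or ModelParams()
    sim = sim or SimConfig()
    rng = np.random.default_rng(seed)

    participants: list[Participant] = []
    counter = 0
    for group in GROUPS:
        eff = effect_spec.group_effects[group]
        demo_spec = effect_spec.demographics[group]
        for _ in range(n_per_group):
            counter += 1
            pid = f"sub-{counter:03d}"
            sched_seed = int(rng.integers(0, 2**31 - 1))
            noise_seed = int(rng.integers(0, 2**31 - 1))
            truth = ParticipantGroundTruth(
                group=group,
                beta_outcome=effect_spec.beta_outcome,
                beta_choice=effect_spec.beta_choice,
                beta_anticipation=effect_spec.beta_anticipation,
                beta_delta=_draw(rng, eff["beta_delta"]),
                beta_momentum_bias=_draw(rng, eff["beta_momentum_bias"]),
                beta_momentum=_draw(rng, eff["beta_momentum"]),
                gamma0=effect_spec.gamma0,
                gamma1=_draw(rng, eff["gamma1"]),
                noise_sigma=effect_spec.noise_sigma,
                ar1_rho=effect_spec.ar1_rho,
                drift_amplitude=effect_spec.drift_amplitude,
                motion_leak=effect_spec.motion_leak,
                seed=noise_seed,
            )
            schedule = generate_schedule(schedule_config, seed=sched_seed)
            ts = (
                simulate_participant(schedule, truth, model_params, sim)
                if simulate_timeseries
                else None
            )
            participants.append(
                Participant(
                    pid=pid,
                    group=group,
                    schedule=schedule,
                    truth=truth,
                    timeseries=ts,
                    demographics=_draw_demographics(rng, demo_spec),
                )
            )
    return Cohort(
        participants=participants,
        effect_spec=effect_spec,
        model_params=model_params,
        sim=sim,
        seed=seed,
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write a cohort to disk: events, per-ROI per-run BOLD TSVs, 6-column
    motion text files, a participant manifest, cohort metadata and the
    ground-truth ledger."""
    import yaml
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for p in cohort.participants:
        pdir = outdir / p.pid
        pdir.mkdir(exist_ok=True)
        events_path = pdir / f"{p.pid}_events.tsv"
        write_events(p.schedule, events_path)
        row = {"pid": p.pid, "group": p.group, "events": str(events_path.relative_to(outdir))}
        row.update(p.demographics)
        if p.timeseries is not None:
            for roi, ts in p.timeseries.items():
                for r, y in enumerate(ts.runs):
                    bold_path = pdir / f"{p.pid}_{roi}_run-{r + 1}.tsv"
                    pd.DataFrame({"bold": y}).to_csv(
                        bold_path, sep="\t", index=False, float_format="%.17g"
                    )
            for r, m in enumerate(p.timeseries[ROI_VS].motion):
                np.savetxt(pdir / f"{p.pid}_run-{r + 1}_motion.txt", m, fmt="%.17g")
        manifest_rows.append(row)
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    cohort.ground_truth_frame().to_csv(
        outdir / "ground_truth.tsv", sep="\t", index=False, float_format="%.17g"
    )
    meta = {
        "seed": cohort.seed,
        "model": dataclasses.asdict(cohort.model_params),
        "sim": dataclasses.asdict(cohort.sim),
    }
    with open(outdir / "cohort.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_cohort(outdir) -> Cohort:
    """Reload a written cohort (events, BOLD, motion, metadata) from disk.

    Ground-truth parameters are restored from the ledger so recovery tests
    can be run against re-read data.
    """
    import yaml
    from pathlib import Path

    from .task_design import read_events

    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t")
    truth_df = pd.read_csv(outdir / "ground_truth.tsv", sep="\t").set_index("pid")
    with open(outdir / "cohort.yaml") as fh:
        meta = yaml.safe_load(fh)
    model_params = ModelParams(**meta["model"])
    sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in meta["sim"].items()})

    truth_fields = {f.name for f in dataclasses.fields(ParticipantGroundTruth)}
    participants = []
    for _, row in manifest.iterrows():
        pid, group = row["pid"], row["group"]
        pdir = outdir / pid
        schedule = read_events(outdir / row["events"])
        tkw = {k: truth_df.loc[pid, k] for k in truth_fields if k in truth_df.columns}
        tkw["group"] = group
        tkw["seed"] = int(tkw.get("seed", 0))
        truth = ParticipantGroundTruth(**tkw)
        n_runs = schedule.n_runs
        motion = [
            np.loadtxt(pdir / f"{pid}_run-{r + 1}_motion.txt").reshape(-1, 6)
            for r in range(n_runs)
        ]
        timeseries = {}
        for roi in ROIS:
            runs = [
                pd.read_csv(
                    pdir / f"{pid}_{roi}_run-{r + 1}.tsv", sep="\t",
                    float_precision="round_trip",
                )["bold"].to_numpy()
                for r in range(n_runs)
            ]
            timeseries[roi] = ROITimeSeries(roi=roi, tr=sim.tr, runs=runs, motion=motion)
        demo_cols = [c for c in manifest.columns if c not in ("pid", "group", "events")]
        participants.append(
            Participant(
                pid=pid,
                group=group,
                schedule=schedule,
                truth=truth,
                timeseries=timeseries,
                demographics={c: float(row[c]) for c in demo_cols},
            )
        )
    return Cohort(
        participants=participants,
        effect_spec=EffectSpec(),
        model_params=model_params,
        sim=sim,
        seed=int(meta["seed"]),
    )
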