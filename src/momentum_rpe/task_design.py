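"""Balanced Roulette-task trial schedules and BIDS-style events I/O.

A session is ``n_blocks`` runs of ``trials_per_block`` trials.  Win
probability (25%/75%) and stake (low/high) are crossed and exactly balanced
at the session level; within each block, the two probability levels appear
equally often.  Outcomes are realized by exact-frequency assignment — a
fixed multiset of win/loss labels is shuffled within each probability level
— so that the realized win rate equals the nominal probability exactly for
every seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScheduleConfig",
    "Trial",
    "TrialSchedule",
    "ScheduleError",
    "EventsParseError",
    "generate_schedule",
    "write_events",
    "read_events",
]

WIN = "win"
LOSS = "loss"

_EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "run",
    "trial",
    "probability",
    "stake",
    "outcome",
]


class ScheduleError(ValueError):
    """Raised when a schedule configuration cannot be balanced exactly."""


class EventsParseError(ValueError):
    """Raised when an events file is malformed."""


@dataclass(frozen=True)
class ScheduleConfig:
    """Configuration for one task session.

    Defaults give the 272-trial session: 8 blocks of 34 trials, win
    probabilities {0.25, 0.75}, stakes {3, 9}, with timings sized so each
    block lasts about six minutes.
    """

    n_blocks: int = 8
    trials_per_block: int = 34
    probabilities: tuple[float, ...] = (0.25, 0.75)
    stakes: tuple[float, ...] = (3.0, 9.0)
    choice_duration: float = 4.0
    anticipation_duration: tuple[float, float] = (3.0, 4.0)
    outcome_duration: float = 2.0
    iti_duration: tuple[float, float] = (1.0, 2.0)
    seed: int = 0

    @property
    def total_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class Trial:
    """One trial with condition labels and within-run event onsets (seconds)."""

    block: int
    index_in_block: int
    probability: float
    stake: float
    outcome: str
    onset_choice: float
    onset_anticipation: float
    onset_outcome: float

    def __post_init__(self) -> None:
        if self.outcome not in (WIN, LOSS):
            raise ScheduleError(f"outcome must be {WIN!r} or {LOSS!r}, got {self.outcome!r}")
        if not (self.onset_choice < self.onset_anticipation < self.onset_outcome):
            raise ScheduleError(
                f"onsets must be strictly increasing within trial "
                f"(block {self.block}, trial {self.index_in_block})"
            )

    @property
    def outcome_signed(self) -> float:
        """Signed monetary outcome: +stake on a win, -stake on a loss."""
        return self.stake if self.outcome == WIN else -self.stake


@dataclass
class TrialSchedule:
    """An ordered session of trials, grouped into blocks (runs)."""

    trials: list[Trial]
    config: ScheduleConfig | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __eq__(self, other: object) -> bool:
        # config is not round-tripped through events files; equality is
        # defined on the trial sequence alone.
        if not isinstance(other, TrialSchedule):
            return NotImplemented
        return self.trials == other.trials

    # -- array accessors -------------------------------------------------
    @property
    def probability(self) -> np.ndarray:
        return np.array([t.probability for t in self.trials])

    @property
    def stake(self) -> np.ndarray:
        return np.array([t.stake for t in self.trials])

    @property
    def outcome_signed(self) -> np.ndarray:
        return np.array([t.outcome_signed for t in self.trials])

    @property
    def is_win(self) -> np.ndarray:
        return np.array([t.outcome == WIN for t in self.trials])

    @property
    def blocks(self) -> np.ndarray:
        return np.array([t.block for t in self.trials])

    @property
    def n_runs(self) -> int:
        return len({t.block for t in self.trials})

    def run_ids(self) -> list[int]:
        return sorted({t.block for t in self.trials})

    def run_trials(self, run: int) -> list[Trial]:
        return [t for t in self.trials if t.block == run]

    def run_trial_indices(self, run: int) -> np.ndarray:
        """Session-level indices of the trials belonging to ``run``."""
        return np.array([i for i, t in enumerate(self.trials) if t.block == run])

    def run_duration(self, run: int, pad: float = 0.0) -> float:
        trials = self.run_trials(run)
        if not trials:
            raise ScheduleError(f"run {run} has no trials")
        last = max(trials, key=lambda t: t.onset_outcome)
        outcome_dur = self.config.outcome_duration if self.config else 2.0
        return last.onset_outcome + outcome_dur + pad


def _validate_balance(config: ScheduleConfig) -> None:
    n_prob = len(config.probabilities)
    n_stake = len(config.stakes)
    total = config.total_trials
    if total % (n_prob * n_stake):
        raise ScheduleError(
            f"{total} trials cannot be split evenly over "
            f"{n_prob} probabilities x {n_stake} stakes"
        )
    if config.trials_per_block % n_prob:
        raise ScheduleError(
            f"{config.trials_per_block} trials per block cannot be split evenly "
            f"over {n_prob} probability levels"
        )
    per_prob = total // n_prob
    if per_prob % n_stake:
        raise ScheduleError(
            f"{per_prob} trials per probability level cannot be split evenly "
            f"over {n_stake} stakes"
        )
    per_cell = per_prob // n_stake
    for p in config.probabilities:
        for s in config.stakes:
            wins = p * per_cell
            if abs(wins - round(wins)) > 1e-9:
                raise ScheduleError(
                    f"cell p={p}, stake={s}: {p} x {per_cell} trials = {wins} "
                    f"wins is not an integer; exact outcome balance impossible"
                )


def generate_schedule(config: ScheduleConfig | None = None, **overrides) -> TrialSchedule:
    """Generate a pseudorandomized, exactly balanced trial schedule.

    Balance is seed-invariant: for any seed the session has equal counts per
    probability x stake cell and exactly nominal win frequencies per
    probability level; only the trial order and event jitter vary.
    """
    if config is None:
        config = ScheduleConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    _validate_balance(config)
    rng = np.random.default_rng(config.seed)

    n_prob = len(config.probabilities)
    per_prob = config.total_trials // n_prob
    per_block_per_prob = config.trials_per_block // n_prob
    per_cell = per_prob // len(config.stakes)

    # Session-level multisets per probability level with exact outcome
    # frequencies per probability x stake cell, shuffled within level.
    per_prob_lists: dict[float, list[tuple[float, str]]] = {}
    for p in config.probabilities:
        pairs: list[tuple[float, str]] = []
        for s in config.stakes:
            n_wins = round(p * per_cell)
            pairs.extend((float(s), WIN) for _ in range(n_wins))
            pairs.extend((float(s), LOSS) for _ in range(per_cell - n_wins))
        order = rng.permutation(len(pairs))
        per_prob_lists[p] = [pairs[i] for i in order]

    trials: list[Trial] = []
    for block in range(config.n_blocks):
        conditions: list[tuple[float, float, str]] = []
        for p in config.probabilities:
            chunk = per_prob_lists[p][
                block * per_block_per_prob : (block + 1) * per_block_per_prob
            ]
            conditions.extend((p, stake, outcome) for stake, outcome in chunk)
        order = rng.permutation(len(conditions))
        t = 0.0
        for k, idx in enumerate(order):
            p, stake, outcome = conditions[idx]
            onset_choice = t
            t += config.choice_duration
            onset_ant = t
            t += rng.uniform(*config.anticipation_duration)
            onset_out = t
            t += config.outcome_duration + rng.uniform(*config.iti_duration)
            trials.append(
                Trial(
                    block=block,
                    index_in_block=k,
                    probability=p,
                    stake=stake,
                    outcome=outcome,
                    onset_choice=onset_choice,
                    onset_anticipation=onset_ant,
                    onset_outcome=onset_out,
                )
            )
    return TrialSchedule(trials=trials, config=config)


def schedule_from_arrays(
    probability: Sequence[float],
    stake: Sequence[float],
    outcome: Sequence[str],
    block: Sequence[int] | None = None,
    trial_spacing: float = 11.0,
    config: ScheduleConfig | None = None,
) -> TrialSchedule:
    """Build a schedule directly from condition arrays (fixed event timings).

    Convenience constructor for tests and hand-built examples; onsets are
    laid out on a regular grid within each block.
    """
    n = len(probability)
    if not (len(stake) == len(outcome) == n):
        raise ScheduleError("probability, stake and outcome must have equal length")
    blocks = list(block) if block is not None else [0] * n
    trials = []
    counters: dict[int, int] = {}
    for i in range(n):
        b = blocks[i]
        k = counters.get(b, 0)
        counters[b] = k + 1
        t0 = k * trial_spacing
        trials.append(
            Trial(
                block=b,
                index_in_block=k,
                probability=float(probability[i]),
                stake=float(stake[i]),
                outcome=str(outcome[i]),
                onset_choice=t0,
                onset_anticipation=t0 + 4.0,
                onset_outcome=t0 + 7.5,
            )
        )
    return TrialSchedule(trials=trials, config=config)


def _schedule_frame(schedule: TrialSchedule) -> pd.DataFrame:
    rows = []
    for t in schedule:
        common = dict(
            run=t.block,
            trial=t.index_in_block,
            probability=t.probability,
            stake=t.stake,
            outcome=t.outcome,
        )
        rows.append(
            dict(
                onset=t.onset_choice,
                duration=t.onset_anticipation - t.onset_choice,
                trial_type="choice",
                **common,
            )
        )
        rows.append(
            dict(
                onset=t.onset_anticipation,
                duration=t.onset_outcome - t.onset_anticipation,
                trial_type="anticipation",
                **common,
            )
        )
        outcome_dur = (
            schedule.config.outcome_duration if schedule.config is not None else 2.0
        )
        rows.append(
            dict(onset=t.onset_outcome, duration=outcome_dur, trial_type="outcome", **common)
        )
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def write_events(schedule: TrialSchedule, path) -> None:
    """Write a BIDS-style tab-separated events file (three rows per trial)."""
    df = _schedule_frame(schedule)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path) -> TrialSchedule:
    """Read an events file written by :func:`write_events` back to a schedule.

    Round-trips bit-exactly: ``read_events(write_events(s)) == s``.
    """
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise EventsParseError(f"cannot parse events file {path}: {exc}") from exc
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventsParseError(f"events file {path} is missing columns: {missing}")
    if len(df) == 0:
        return TrialSchedule(trials=[])
    neg = df.index[df["onset"] < 0]
    if len(neg):
        # +2: one for the header row, one for 1-based line numbering
        raise EventsParseError(f"negative onset at line {neg[0] + 2} of {path}")
    trials = []
    for (run, idx), grp in df.groupby(["run", "trial"], sort=True):
        phases = dict(zip(grp["trial_type"], grp["onset"]))
        expected = {"choice", "anticipation", "outcome"}
        if set(phases) != expected:
            line = grp.index[0] + 2
            raise EventsParseError(
                f"trial run={run} trial={idx} near line {line}: expected phases "
                f"{sorted(expected)}, got {sorted(phases)}"
            )
        row = grp.iloc[0]
        trials.append(
            Trial(
                block=int(run),
                index_in_block=int(idx),
                probability=float(row["probability"]),
                stake=float(row["stake"]),
                outcome=str(row["outcome"]),
                onset_choice=float(phases["choice"]),
                onset_anticipation=float(phases["anticipation"]),
                onset_outcome=float(phases["outcome"]),
            )
        )
    trials.sort(key=lambda t: (t.block, t.onset_choice))
    return TrialSchedule(trials=trials)
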