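"""Reward-prediction-error traces with a recursive momentum bias.

The unbiased RPE on trial ``t`` is ``delta_t = o_t - EV_t`` where ``o_t`` is
the signed monetary outcome and ``EV_t = (2 p_t - 1) * stake_t``.  The
biased model maintains a momentum ``h`` — an exponentially integrated
history of recent biased RPEs — that distorts the perception of the next
outcome:

    additive form:        o~_t = o_t + w * h_{t-1}
    multiplicative form:  o~_t = o_t * (1 + w * h_{t-1} / max_stake)

    delta~_t = o~_t - EV_t
    h_t      = (1 - eta) * h_{t-1} + eta * delta~_t

The quantity entered downstream as the momentum-bias parametric modulator is
the difference ``Delta_t = delta~_t - delta_t``, which under the additive
form equals ``w * h_{t-1}`` and is therefore determined entirely by outcomes
before trial ``t``.  Two reduced models are provided for confirmatory
analyses: lag-1 carryover regressors and a momentum-only accumulator with no
bias feedback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_design import TrialSchedule

__all__ = [
    "ModelParams",
    "RPETrace",
    "expected_value",
    "unbiased_rpes",
    "biased_rpes",
    "momentum_series",
    "carryover_regressors",
    "momentum_only_regressor",
    "write_trace",
    "read_trace",
]

ADDITIVE = "additive"
MULTIPLICATIVE = "multiplicative"


@dataclass(frozen=True)
class ModelParams:
    """Momentum-model parameters.

    ``eta`` is the momentum-update rate, ``bias_weight`` (w) the strength
    with which momentum distorts perceived outcomes.  Either being zero
    degenerates the model to the unbiased one.  Defaults are documented
    pipeline placeholders, not fitted values.
    """

    eta: float = 0.3
    bias_weight: float = 0.5
    bias_form: str = ADDITIVE
    h0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must be in [0, 1], got {self.eta}")
        if self.bias_weight < 0:
            raise ValueError(f"bias_weight must be >= 0, got {self.bias_weight}")
        if self.bias_form not in (ADDITIVE, MULTIPLICATIVE):
            raise ValueError(f"bias_form must be additive|multiplicative, got {self.bias_form}")


@dataclass
class RPETrace:
    """Per-trial model quantities.

    ``h`` is the momentum *entering* each trial (so ``h[0] == h0``);
    ``h_post`` is the updated momentum after each trial's outcome, i.e. the
    series aligned to outcome events for the insula analysis.
    """

    ev: np.ndarray
    outcome_signed: np.ndarray
    delta: np.ndarray
    h: np.ndarray | None = None
    o_perceived: np.ndarray | None = None
    delta_biased: np.ndarray | None = None
    pmod_momentum_bias: np.ndarray | None = None
    h_post: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.delta)

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "ev": self.ev,
            "outcome_signed": self.outcome_signed,
            "delta": self.delta,
            "h": self.h,
            "o_perceived": self.o_perceived,
            "delta_biased": self.delta_biased,
            "pmod_momentum_bias": self.pmod_momentum_bias,
            "h_post": self.h_post,
        }
        return pd.DataFrame({k: v for k, v in cols.items() if v is not None})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RPETrace":
        kwargs = {}
        for name in (
            "ev",
            "outcome_signed",
            "delta",
            "h",
            "o_perceived",
            "delta_biased",
            "pmod_momentum_bias",
            "h_post",
        ):
            if name in df.columns:
                kwargs[name] = df[name].to_numpy(dtype=float)
        return cls(**kwargs)


def expected_value(probability: float, stake: float) -> float:
    """Expected signed value of a gamble: ``(2 p - 1) * stake``."""
    if not 0.0 < probability < 1.0:
        raise ValueError(f"probability must be in (0, 1), got {probability}")
    if stake <= 0:
        raise ValueError(f"stake must be > 0, got {stake}")
    return (2.0 * probability - 1.0) * stake


def unbiased_rpes(schedule: TrialSchedule) -> RPETrace:
    """Expected values, signed outcomes and unbiased RPEs for a schedule."""
    ev = np.array([expected_value(t.probability, t.stake) for t in schedule])
    o = schedule.outcome_signed
    return RPETrace(ev=ev, outcome_signed=o, delta=o - ev)


def biased_rpes(schedule: TrialSchedule, params: ModelParams) -> RPETrace:
    """Run the forward momentum-bias recursion over a schedule."""
    trace = unbiased_rpes(schedule)
    n = len(trace)
    ev, o = trace.ev, trace.outcome_signed
    max_stake = float(np.max(schedule.stake)) if n else 1.0

    h_pre = np.empty(n)
    h_post = np.empty(n)
    o_perc = np.empty(n)
    d_biased = np.empty(n)
    h = float(params.h0)
    for t in range(n):
        h_pre[t] = h
        if params.bias_form == ADDITIVE:
            o_perc[t] = o[t] + params.bias_weight * h
        else:
            o_perc[t] = o[t] * (1.0 + params.bias_weight * h / max_stake)
        d_biased[t] = o_perc[t] - ev[t]
        h = (1.0 - params.eta) * h + params.eta * d_biased[t]
        h_post[t] = h
        if not np.isfinite(h):
            raise FloatingPointError(f"non-finite momentum at trial {t}")

    trace.h = h_pre
    trace.h_post = h_post
    trace.o_perceived = o_perc
    trace.delta_biased = d_biased
    trace.pmod_momentum_bias = d_biased - trace.delta
    return trace


def momentum_series(schedule: TrialSchedule, params: ModelParams) -> np.ndarray:
    """Momentum values aligned to outcome events (post-update ``h_t``)."""
    return biased_rpes(schedule, params).h_post


def carryover_regressors(schedule: TrialSchedule) -> dict[str, np.ndarray]:
    """Model-free lag-1 regressors: previous RPE, current RPE, and product.

    The first trial's lagged terms are zero.
    """
    delta = unbiased_rpes(schedule).delta
    if len(delta) < 2:
        raise ValueError("carryover regressors need at least 2 trials")
    delta_prev = np.concatenate([[0.0], delta[:-1]])
    return {
        "delta_prev": delta_prev,
        "delta": delta,
        "delta_prev_x_delta": delta_prev * delta,
    }


def momentum_only_regressor(schedule: TrialSchedule, eta: float) -> np.ndarray:
    """Accumulated RPE history with no bias feedback into perception.

    ``h_t = (1 - eta) h_{t-1} + eta delta_t`` on the *unbiased* RPEs,
    starting from 0; returns the post-update series.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    delta = unbiased_rpes(schedule).delta
    h = np.empty(len(delta))
    acc = 0.0
    for t, d in enumerate(delta):
        acc = (1.0 - eta) * acc + eta * d
        h[t] = acc
    return h


def write_trace(trace: RPETrace, path) -> None:
    """Write a trace as TSV, one row per trial."""
    trace.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trace(path) -> RPETrace:
    return RPETrace.from_frame(pd.read_csv(path, sep="\t"))
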