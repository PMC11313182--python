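"""End-to-end orchestration: simulate -> RPEs -> GLM -> PPI -> group stats.

Runs the whole analysis on a simulated cohort and writes a diffable TSV
report mirroring the study's results structure, a plain-text narrative, and
a reproducibility manifest with every resolved setting and seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import first_level_glm as glm
from . import group_stats as gs
from . import ppi as ppi_mod
from .rpe_models import ModelParams
from .synthetic_bold import (
    BIPOLAR_LIKE,
    CONTROL_LIKE,
    EffectSpec,
    ROI_LINS,
    ROI_RINS,
    ROI_VS,
    SimConfig,
    simulate_cohort,
    write_cohort,
)
from .task_design import ScheduleConfig

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("momentum_rpe")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_per_group: int = 21
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    model: ModelParams = field(default_factory=ModelParams)
    sim: SimConfig = field(default_factory=SimConfig)
    effects: EffectSpec = field(default_factory=EffectSpec)
    alpha: float = 0.05
    write_data: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        kwargs = {}
        for key, sub in (
            ("schedule", ScheduleConfig),
            ("model", ModelParams),
            ("sim", SimConfig),
        ):
            if key in raw:
                kwargs[key] = sub(**raw.pop(key))
        if "effects" in raw:
            eff = raw.pop("effects")
            if "group_effects" in eff:
                eff["group_effects"] = {
                    g: {k: tuple(v) for k, v in d.items()}
                    for g, d in eff["group_effects"].items()
                }
            kwargs["effects"] = EffectSpec(**eff)
        kwargs.update(raw)
        return cls(**kwargs)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"]["group_effects"] = {
            g: {k: list(v) for k, v in eff.items()}
            for g, eff in d["effects"]["group_effects"].items()
        }
        return d


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


def _summary_rows(cohort, config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All group-level tests; returns (summary, contrast table, PPI table)."""
    vs = glm.cohort_contrasts(cohort, variant=glm.VARIANT_RPE, roi=ROI_VS)
    ins_l = glm.cohort_contrasts(cohort, variant=glm.VARIANT_MOMENTUM, roi=ROI_LINS)
    ins_r = glm.cohort_contrasts(cohort, variant=glm.VARIANT_MOMENTUM, roi=ROI_RINS)
    ppi_bias = ppi_mod.cohort_ppi(cohort, psych=ppi_mod.PSYCH_MOMENTUM_BIAS)
    ppi_delta = ppi_mod.cohort_ppi(cohort, psych=ppi_mod.PSYCH_DELTA)

    results: list[gs.GroupResult] = []

    def by_group(df, col):
        return (
            df.loc[df.group == BIPOLAR_LIKE, col].to_numpy(),
            df.loc[df.group == CONTROL_LIKE, col].to_numpy(),
        )

    # VS tracking: one-sample per group, directional
    for contrast, label in (
        (glm.OUTCOME_X_DELTA, "vs_unbiased_rpe"),
        (glm.OUTCOME_X_MOMENTUM_BIAS, "vs_momentum_bias_rpe"),
    ):
        bd, cg = by_group(vs, contrast)
        results.append(gs.one_sample_t(bd, tail=gs.GREATER, name=f"{label}:bipolar_like"))
        results.append(gs.one_sample_t(cg, tail=gs.GREATER, name=f"{label}:control_like"))
    bd, cg = by_group(vs, glm.OUTCOME_X_MOMENTUM_BIAS)
    results.append(
        gs.two_sample_t(bd, cg, variant="pooled", tail=gs.GREATER,
                        name="vs_momentum_bias_rpe:group_diff")
    )

    # Insular momentum tracking across all participants, Bonferroni over 2 ROIs
    momentum_results = [
        gs.one_sample_t(ins_l[glm.OUTCOME_X_MOMENTUM], tail=gs.GREATER,
                        name="left_insula_momentum:all"),
        gs.one_sample_t(ins_r[glm.OUTCOME_X_MOMENTUM], tail=gs.GREATER,
                        name="right_insula_momentum:all"),
    ]
    bonf = gs.bonferroni([r.p for r in momentum_results], k=2, alpha=config.alpha)
    for r, sig in zip(momentum_results, bonf["significant"]):
        r.extras["bonferroni_threshold"] = bonf["threshold"]
        r.extras["bonferroni_significant"] = sig
    results.extend(momentum_results)

    # PPI: per-group directional + between-group + specificity
    bd, cg = by_group(ppi_bias, "beta_ppi")
    results.append(gs.one_sample_t(cg, tail=gs.GREATER, name="ppi_momentum_bias:control_like"))
    results.append(gs.one_sample_t(bd, tail=gs.LESS, name="ppi_momentum_bias:bipolar_like"))
    results.append(
        gs.two_sample_t(cg, bd, variant="pooled", tail=gs.GREATER,
                        name="ppi_momentum_bias:group_diff")
    )
    bd_d, cg_d = by_group(ppi_delta, "beta_ppi")
    results.append(gs.one_sample_t(bd_d, name="ppi_unbiased_rpe:bipolar_like"))
    results.append(gs.one_sample_t(cg_d, name="ppi_unbiased_rpe:control_like"))

    # Symptom regression (bipolar-like group): PPI beta on MAS + BIS
    demo = cohort.ground_truth_frame()[["pid", "group", "MAS", "HAMD", "BIS"]]
    merged = ppi_bias.merge(demo, on=["pid", "group"])
    bd_rows = merged[merged.group == BIPOLAR_LIKE]
    try:
        results.extend(
            gs.symptom_regression(
                bd_rows["beta_ppi"],
                bd_rows[["MAS", "BIS"]],
                log_transform={"MAS": True},
                name="ppi_symptoms",
            )
        )
    except ValueError as exc:
        log.warning("symptom regression skipped: %s", exc)

    summary = pd.DataFrame([r.to_row() for r in results])
    contrasts = vs.merge(
        ins_l.rename(columns={glm.OUTCOME_X_MOMENTUM: "left_insula_momentum"}),
        on=["pid", "group"],
    ).merge(
        ins_r.rename(columns={glm.OUTCOME_X_MOMENTUM: "right_insula_momentum"}),
        on=["pid", "group"],
    )
    ppi_table = pd.concat([ppi_bias, ppi_delta], ignore_index=True)
    return summary, contrasts, ppi_table


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full pipeline and write the report bundle to ``outdir``.

    Deterministic: identical config and seed give byte-identical outputs.
    Returns a dict with the in-memory tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.n_per_group < 5:
        log.warning("n_per_group = %d is very small; group tests will be unstable",
                    config.n_per_group)

    cohort = _stage("simulate_cohort")(simulate_cohort)(
        n_per_group=config.n_per_group,
        effect_spec=config.effects,
        seed=config.seed,
        schedule_config=config.schedule,
        model_params=config.model,
        sim=config.sim,
    )
    if config.write_data:
        _stage("write_cohort")(write_cohort)(cohort, outdir / "cohort")

    summary, contrasts, ppi_table = _stage("group_analysis")(_summary_rows)(cohort, config)

    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False, float_format="%.10g")
    contrasts.to_csv(outdir / "contrasts.tsv", sep="\t", index=False, float_format="%.10g")
    ppi_table.to_csv(outdir / "ppi.tsv", sep="\t", index=False, float_format="%.10g")
    cohort.ground_truth_frame().to_csv(
        outdir / "ground_truth.tsv", sep="\t", index=False, float_format="%.10g"
    )
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(config.to_manifest(), fh, sort_keys=True)

    lines = ["Momentum-biased RPE pipeline summary", "=" * 40]
    for _, row in summary.iterrows():
        lines.append(
            f"{row['name']}: stat={row['statistic']:.3f} df={row['df']:.4g} "
            f"p={row['p']:.4g} ({row['tail']})"
            + (f" d={row['cohen_d']:.3f}" if pd.notna(row["cohen_d"]) else "")
        )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")

    return {
        "summary": summary,
        "contrasts": contrasts,
        "ppi": ppi_table,
        "cohort": cohort,
    }
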