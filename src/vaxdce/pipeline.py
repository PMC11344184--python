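"""End-to-end study orchestration and subgroup estimation.

``run_pipeline`` composes the stages — design → (simulate | load) → fit →
WTP → uptake → report — writing each table as delimited text plus a YAML
manifest sufficient to re-run the pipeline bit-identically.  One global
seed fans out to per-stage seeds by fixed offsets (design +1, blocking
+2, population +3, choices +4, demographics +5, bootstrap +6) so any
stage can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .data import LongChoiceTable, load_choice_table, summarize_sample
from .design import ChoiceDesign, StudyDesignSpec, block_design, build_choice_design
from .errors import ConfigurationError, PipelineStageError
from .mixlogit import EstimationResult, ModelSpec, fit_mixed_logit
from .simulate import SimulatedStudy, SyntheticStudyConfig, TrueParameters, simulate_study
from .study import hz_study_spec, hz_true_parameters
from .uptake import tornado_deltas
from .wtp import WTPTable, wtp_confidence_intervals

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    spec: StudyDesignSpec = field(default_factory=hz_study_spec)
    mode: str = "simulate"                  # "simulate" or "load"
    data_path: str | Path | None = None     # for mode="load"
    n_respondents: int = 2864
    true_params: TrueParameters | None = None
    model: ModelSpec | None = None
    wtp_method: str = "parametric"
    wtp_replicates: int = 1000
    uptake_draws: int = 10000
    outdir: str | Path = "vaxdce_run"
    seed: int = 12345

    def __post_init__(self):
        if self.mode not in ("simulate", "load"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "load":
            if self.data_path is None:
                raise ConfigurationError("mode='load' requires data_path")
            if not Path(self.data_path).exists():
                raise ConfigurationError(f"data path {self.data_path} does not exist")


@dataclass
class PipelineResult:
    result: EstimationResult
    wtp: WTPTable
    tornado: pd.DataFrame
    sample_summary: pd.DataFrame | None
    paths: dict[str, Path]
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raised with stage name
                raise PipelineStageError(name, str(e)) from e
            logger.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full study and write all report artifacts to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    spec = config.spec

    @_stage("design")
    def do_design() -> ChoiceDesign:
        d = build_choice_design(spec, "auto", seed=config.seed + 1)
        return block_design(d, spec.n_blocks, seed=config.seed + 2, spec=spec)

    design = do_design()
    paths["design"] = outdir / "design.csv"
    design.to_frame(spec).to_csv(paths["design"], index=False)

    @_stage("data")
    def do_data() -> LongChoiceTable:
        if config.mode == "load":
            return load_choice_table(config.data_path, spec)
        params = config.true_params or hz_true_parameters()
        sim = simulate_study(SyntheticStudyConfig(
            spec=spec, params=params, n_respondents=config.n_respondents,
            design=design, seed=config.seed))
        paths["truth"] = outdir / "truth.yaml"
        paths["truth"].write_text(yaml.safe_dump(sim.truth, sort_keys=False))
        return sim.table

    table = do_data()
    paths["choices"] = outdir / "choices.csv"
    table.write(paths["choices"])

    sample = None
    if table.demographics is not None:
        sample = summarize_sample(table.demographics)
        paths["sample_summary"] = outdir / "sample_summary.csv"
        sample.to_csv(paths["sample_summary"], index=False)

    @_stage("fit")
    def do_fit() -> EstimationResult:
        model = config.model or ModelSpec()
        return fit_mixed_logit(table, model)

    result = do_fit()
    paths["coefficients"] = outdir / "coefficients.csv"
    result.summary().to_csv(paths["coefficients"], index=False)
    paths["result"] = outdir / "estimation_result.yaml"
    paths["result"].write_text(yaml.safe_dump(result.to_dict(), sort_keys=False))

    @_stage("wtp")
    def do_wtp() -> WTPTable:
        return wtp_confidence_intervals(
            result, method=config.wtp_method, replicates=config.wtp_replicates,
            seed=config.seed + 6, data=table)

    wtp = do_wtp()
    paths["wtp"] = outdir / "wtp.csv"
    wtp.table.to_csv(paths["wtp"], index=False)

    @_stage("uptake")
    def do_uptake() -> pd.DataFrame:
        return tornado_deltas(result, n_draws=config.uptake_draws,
                              seed=config.seed + 7, spec=spec)

    tornado = do_uptake()
    paths["uptake"] = outdir / "uptake_tornado.csv"
    tornado.to_csv(paths["uptake"], index=False)

    manifest = {
        "seed": config.seed,
        "stage_seeds": {"design": config.seed + 1, "blocking": config.seed + 2,
                        "population": config.seed + 3, "choices": config.seed + 4,
                        "demographics": config.seed + 5, "wtp": config.seed + 6,
                        "uptake": config.seed + 7},
        "mode": config.mode,
        "n_respondents": int(table.n_respondents),
        "design_provenance": design.provenance,
        "model": {"n_draws": result.model.n_draws, "seed": result.model.seed,
                  "draw_scheme": result.model.draw_scheme,
                  "random_coefficients": list(result.random_names)},
        "loglik": float(result.loglik),
        "converged": bool(result.converged),
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["manifest"] = outdir / "manifest.yaml"
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=False))
    return PipelineResult(result, wtp, tornado, sample, paths, manifest)


def subgroup_fit(data: LongChoiceTable, grouping: str,
                 model: ModelSpec | None = None,
                 min_size: int = 50) -> dict[str, EstimationResult]:
    """Independent fits per category of a demographic column.

    Groups smaller than ``min_size`` respondents are skipped with a logged
    warning.  Raises :class:`ConfigurationError` if the grouping column is
    absent from the demographics.
    """
    if data.demographics is None or grouping not in data.demographics.columns:
        raise ConfigurationError(f"no demographic column {grouping!r}")
    model = model or ModelSpec()
    results: dict[str, EstimationResult] = {}
    groups = data.demographics.groupby(grouping, observed=True)["respondent_id"]
    for category, ids in groups:
        if len(ids) < min_size:
            logger.warning("skipping group %s=%r: %d respondents < min_size=%d",
                           grouping, category, len(ids), min_size)
            continue
        sub = data.data[data.data["respondent_id"].isin(ids)].reset_index(drop=True)
        demo = data.demographics[data.demographics["respondent_id"].isin(ids)]
        results[str(category)] = fit_mixed_logit(
            LongChoiceTable(sub, data.spec, demo.reset_index(drop=True)), model)
    return results


def subgroup_summary(results: dict[str, EstimationResult]) -> pd.DataFrame:
    """Combined comparison table: one summary per group, stacked."""
    frames = []
    for group, res in results.items():
        frames.append(res.summary().assign(group=group))
    return pd.concat(frames, ignore_index=True)
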