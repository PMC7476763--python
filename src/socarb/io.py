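"""File formats, run configuration and the end-to-end pipeline.

All tables are comma-separated with a header row; floats are serialized with
12 significant digits, lossless enough for reproducibility checks. Every
pipeline run writes a manifest recording the package version, seeds and a
hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bms import BmsResult, LmeMatrix, rfx_bms
from .inversion import FitResult, OptimizerConfig, map_fit
from .params import MODEL_SPACE, model_by_name
from .recovery import PopulationSpec
from .task import (GeneratorConfig, SubjectData, TaskSchedule,
                   generate_schedule, simulate_agent)

__all__ = [
    "SchemaError",
    "read_schedule", "write_schedule",
    "read_responses", "write_responses",
    "read_lme_matrix", "write_lme_matrix",
    "write_fit_result", "write_bms_result",
    "RunConfig", "pipeline_run",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"

_RESPONSE_COLUMNS = ("trial_index", "choice", "wager")
_SCHEDULE_COLUMNS = ("trial_index", "card_phase", "advice_phase", "p_blue",
                     "outcome_color", "advisor_info", "advice_color",
                     "advice_accurate")


class SchemaError(ValueError):
    """A table violates the expected schema; names the offending row/column."""


def write_schedule(schedule: TaskSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_schedule(path) -> TaskSchedule:
    df = pd.read_csv(path)
    missing = set(_SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"schedule file missing columns: {sorted(missing)}")
    return TaskSchedule(
        trial_index=df["trial_index"].to_numpy(int),
        card_phase=df["card_phase"].to_numpy(str),
        advice_phase=df["advice_phase"].to_numpy(str),
        p_blue=df["p_blue"].to_numpy(float),
        outcome_color=df["outcome_color"].to_numpy(int),
        advisor_info=df["advisor_info"].to_numpy(int),
        advice_color=df["advice_color"].to_numpy(int),
        advice_accurate=df["advice_accurate"].to_numpy(int),
    )


def write_responses(data: SubjectData, path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_responses(path) -> SubjectData:
    """Read and validate a responses table (choice 1 = advice taken)."""
    df = pd.read_csv(path)
    missing = set(_RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"responses file missing columns: {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.choice not in (0, 1):
            raise SchemaError(f"row {i}: choice must be 0 or 1, got {row.choice!r}")
        if not (isinstance(row.wager, (int, np.integer)) or float(row.wager).is_integer()):
            raise SchemaError(f"row {i}: wager must be an integer, got {row.wager!r}")
        if not 1 <= int(row.wager) <= 10:
            raise SchemaError(f"row {i}: wager must lie in [1, 10], got {row.wager!r}")
    return SubjectData(trial_index=df["trial_index"].to_numpy(int),
                       choice=df["choice"].to_numpy(int),
                       wager=df["wager"].to_numpy(int))


def write_lme_matrix(lme: LmeMatrix, path) -> None:
    lme.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_lme_matrix(path, column_map: dict[str, str] | None = None) -> LmeMatrix:
    """Read an LME table: first column subject IDs, remaining columns models.

    ``column_map`` optionally renames file columns to canonical model names,
    so externally deposited evidence tables can be ingested after a one-line
    mapping.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    subject_col = df.columns[0]
    models = [c for c in df.columns if c != subject_col]
    return LmeMatrix(subjects=[str(s) for s in df[subject_col]],
                     models=models,
                     values=df[models].to_numpy(float))


def write_fit_result(fit: FitResult, path) -> None:
    rec = {
        "model": fit.model,
        "free_parameters": list(fit.free_names),
        "map_estimates_native": {k: float(v) for k, v in fit.natives.items()},
        "map_estimates_estimation_space": [float(x) for x in fit.x_est],
        "log_posterior": float(fit.log_posterior),
        "log_likelihood": float(fit.log_likelihood),
        "log_model_evidence": None if fit.lme is None else float(fit.lme),
        "converged": bool(fit.converged),
        "diagnostics": {k: (bool(v) if isinstance(v, (bool, np.bool_)) else v)
                        for k, v in fit.diagnostics.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(rec, fh, sort_keys=False)


def write_bms_result(result: BmsResult, path) -> None:
    rec = {
        "models": result.models,
        "dirichlet_alpha": [float(a) for a in result.dirichlet_alpha],
        "p_m_y": [float(x) for x in result.expected_frequencies],
        "exceedance_prob": [float(x) for x in result.exceedance_prob],
        "protected_exceedance_prob": [float(x) for x in result.protected_exceedance_prob],
        "bayes_omnibus_risk": float(result.bayes_omnibus_risk),
        "winning_model": result.winning_model,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(rec, fh, sort_keys=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    out_dir: str
    n_subjects: int = 5
    seed: int = 0
    schedule: GeneratorConfig = field(default_factory=GeneratorConfig)
    models: tuple[str, ...] = tuple(s.name for s in MODEL_SPACE)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    population: PopulationSpec | None = None
    responses_dir: str | None = None   # load instead of simulate
    schedule_path: str | None = None

    def content_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(str(type(o)))

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=enc).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def pipeline_run(config: RunConfig) -> pathlib.Path:
    """Simulate (or load) subjects, fit all models, run BMS, write artifacts.

    Stages: schedule -> responses -> per-subject-per-model MAP fits ->
    LME matrix -> random-effects BMS. Each stage writes its tables; failures
    abort with the stage name, leaving earlier outputs in place.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    timings: dict[str, float] = {}
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "models": list(config.models),
        "n_subjects": config.n_subjects,
    }
    try:
        t0 = time.perf_counter()
        stage = "schedule"
        ss = np.random.SeedSequence(config.seed)
        s_sched, s_pop, s_resp, s_opt = ss.spawn(4)
        if config.schedule_path:
            schedule = read_schedule(config.schedule_path)
        else:
            sched_seed = int(s_sched.generate_state(1)[0] % (2**31 - 1))
            schedule = generate_schedule(
                dataclasses.replace(config.schedule, seed=sched_seed))
        write_schedule(schedule, out / "schedule.csv")
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", stage, timings[stage])

        stage = "responses"
        t0 = time.perf_counter()
        subjects: list[tuple[str, SubjectData]] = []
        if config.responses_dir:
            rdir = pathlib.Path(config.responses_dir)
            for p in sorted(rdir.glob("*.csv")):
                subjects.append((p.stem, read_responses(p)))
        else:
            pop = config.population or PopulationSpec.default()
            from .recovery import _draw_population

            rng = np.random.default_rng(s_pop)
            gen_model = model_by_name("hgf3_arb")
            truths = _draw_population(pop, gen_model, config.n_subjects, rng)
            for i, (truth, child) in enumerate(zip(truths, s_resp.spawn(config.n_subjects))):
                perc, resp = gen_model.build_params(truth)
                data = simulate_agent(schedule, perc, resp, gen_model, seed=child)
                sid = f"sub{i + 1:03d}"
                write_responses(data, out / f"responses_{sid}.csv")
                subjects.append((sid, data))
        if not subjects:
            raise SchemaError("no subject responses found")
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", stage, timings[stage])

        stage = "fit"
        t0 = time.perf_counter()
        lme_values = np.empty((len(subjects), len(config.models)))
        fits_dir = out / "fits"
        fits_dir.mkdir(exist_ok=True)
        for j, mname in enumerate(config.models):
            spec = model_by_name(mname)
            for i, (sid, data) in enumerate(subjects):
                opt = dataclasses.replace(
                    config.optimizer,
                    seed=int(s_opt.generate_state(1)[0] % 2**31) + i * 131 + j)
                fit = map_fit(data, schedule, spec, optimizer=opt)
                write_fit_result(fit, fits_dir / f"{sid}_{mname}.yaml")
                lme_values[i, j] = fit.lme if fit.lme is not None else -np.inf
        lme = LmeMatrix(subjects=[sid for sid, _ in subjects],
                        models=list(config.models), values=lme_values)
        write_lme_matrix(lme, out / "lme_matrix.csv")
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", stage, timings[stage])

        stage = "bms"
        t0 = time.perf_counter()
        bms_seed = int(np.random.SeedSequence(config.seed + 1).generate_state(1)[0] % 2**31)
        result = rfx_bms(lme, seed=bms_seed)
        write_bms_result(result, out / "bms_result.yaml")
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", stage, timings[stage])
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = repr(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    manifest["stage_seconds"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
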