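"""Run configuration and the all-in-one pipeline driver.

A single YAML file holds every tunable of the pipeline stages; unknown keys
are rejected so typos fail fast, and a fully-resolved copy of the config is
written next to every output directory together with a machine-readable
JSON log of row counts and drop reasons per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, harmonization, imputation, preprocessing
from .io_formats import (MinuteSeries, ParticipantData, read_metadata_csv,
                         read_minute_summary, write_metadata_csv,
                         write_minute_summary)
from .preprocessing import PreprocessParams
from .qc import QCParams
from .synthetic_data import SimProfile, generate_minute_cohort

log = logging.getLogger(__name__)

HARMONIZED_MEASURES = ["mims", "enmo", "mad", "ai"]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


class DataError(ValueError):
    """A pipeline stage failed on the data."""


@dataclass
class ImputeParams:
    k_max: int = 10
    pve: float = 0.95
    n_basis: int = 30


@dataclass
class EvaluateParams:
    cutoffs: list = field(default_factory=lambda: list(evaluation.DEFAULT_CUTOFFS))
    age_breaks: list = field(default_factory=lambda: list(evaluation.DEFAULT_AGE_BREAKS))


@dataclass
class RunConfig:
    seed: int = 0
    qc: QCParams = field(default_factory=QCParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    impute: ImputeParams = field(default_factory=ImputeParams)
    harmonize: harmonization.HarmonizeParams = field(
        default_factory=harmonization.HarmonizeParams)
    evaluate: EvaluateParams = field(default_factory=EvaluateParams)
    simulate: SimProfile = field(default_factory=SimProfile)
    # input paths; when None the simulated cohort is used
    minutes_dir: str | None = None
    metadata_csv: str | None = None

    def validate(self) -> None:
        try:
            self.qc.validate()
            self.preprocess.validate()
        except ValueError as e:
            raise ConfigError(str(e)) from e
        if not 0 < self.impute.pve <= 1:
            raise ConfigError("impute.pve must be in (0, 1]")
        if self.impute.k_max < 1:
            raise ConfigError("impute.k_max must be >= 1")
        if self.harmonize.n_basis < 5:
            raise ConfigError("harmonize.n_basis must be >= 5")
        if any(c <= 0 for c in self.evaluate.cutoffs):
            raise ConfigError("cut-offs must be positive")


def _from_mapping(cls, data: dict, path: str = ""):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} at '{path or cls.__name__}'")
    kwargs = {}
    for k, v in data.items():
        ftype = fields[k].type
        fdefault = fields[k].default_factory() if fields[k].default_factory is not dataclasses.MISSING else None
        if dataclasses.is_dataclass(fdefault) and isinstance(v, dict):
            kwargs[k] = _from_mapping(type(fdefault), v, f"{path}.{k}" if path else k)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    cfg = _from_mapping(RunConfig, data)
    cfg.validate()
    return cfg


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=True)


def load_cohort(minutes_dir: str, metadata_csv: str) -> list[ParticipantData]:
    meta = read_metadata_csv(metadata_csv)
    cohort = []
    for pid, row in meta.iterrows():
        f = Path(minutes_dir) / f"{pid}.csv"
        if not f.exists():
            raise DataError(f"minute file missing for participant {pid}: {f}")
        series = read_minute_summary(f, participant_id=str(pid))
        cohort.append(ParticipantData(str(pid), float(row["age"]), row["sex"],
                                      float(row["bmi"]), series))
    return cohort


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """simulate/load → preprocess → winsorize → impute → harmonize → evaluate.

    Writes all stage outputs under ``outdir`` and returns the JSON-able run
    log (also written as run_log.json). Deterministic for a fixed config.
    """
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    runlog: dict = {"stages": []}

    def stage(name, **info):
        runlog["stages"].append({"stage": name, **info})
        log.info("stage %s: %s", name, info)

    if cfg.minutes_dir:
        if not cfg.metadata_csv:
            raise ConfigError("metadata_csv required with minutes_dir")
        cohort = load_cohort(cfg.minutes_dir, cfg.metadata_csv)
        stage("load", participants=len(cohort))
    else:
        profile = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        cohort, _ = generate_minute_cohort(profile)
        stage("simulate", participants=len(cohort),
              minutes=sum(p.minutes.n_minutes for p in cohort))

    total_in = sum(p.minutes.n_minutes for p in cohort)
    for p in cohort:
        preprocessing.preprocess_participant(p, cfg.preprocess)
    retained = preprocessing.select_participants(cohort, cfg.preprocess.min_valid_days)
    if not retained:
        raise DataError("no participants retained after valid-day selection")
    total_kept = sum(p.minutes.n_minutes for p in retained)
    stage("preprocess", minutes_in=total_in, minutes_retained=total_kept,
          minutes_dropped=total_in - total_kept,
          participants_retained=len(retained),
          participants_dropped=len(cohort) - len(retained))
    preprocessing.validity_report(retained).to_csv(out / "validity_report.csv",
                                                   index=False)

    caps = preprocessing.winsorize_cohort(retained, cfg.preprocess.winsor_quantile)
    stage("winsorize", caps={k: float(v) for k, v in caps.items()})

    for p in retained:
        imputation.impute_participant(p, ["ac", *HARMONIZED_MEASURES],
                                      k_max=cfg.impute.k_max, pve=cfg.impute.pve,
                                      n_basis=cfg.impute.n_basis)
    stage("impute", participants=len(retained))

    models = {}
    ac_all = np.concatenate([
        p.minutes.data["ac"].to_numpy(dtype=float)[
            p.minutes.data["valid"].fillna(False).to_numpy(dtype=bool)]
        for p in retained])
    for m in HARMONIZED_MEASURES:
        mv = np.concatenate([
            p.minutes.data[m].to_numpy(dtype=float)[
                p.minutes.data["valid"].fillna(False).to_numpy(dtype=bool)]
            for p in retained])
        try:
            model = harmonization.fit_mapping(ac_all, mv, cfg.harmonize,
                                              measure_name=m)
        except ValueError as e:
            raise DataError(f"harmonization failed for {m}: {e}") from e
        model.to_json(out / f"model_{m}.json")
        models[m] = model
    stage("harmonize", n_fit={m: models[m].n_fit for m in models})

    cut_rows = []
    for m, model in models.items():
        for c in cfg.evaluate.cutoffs:
            cut_rows.append({"measure": m, "ac_cutoff": c,
                             "measure_cutoff": harmonization.translate_cutoff(model, c)})
    pd.DataFrame(cut_rows).to_csv(out / "cutoffs.csv", index=False,
                                  float_format="%.6f")

    corr_frames, reg_frames, err_frames, cls_frames, curve_frames = [], [], [], [], []
    curve_mapes = {}
    for m, model in models.items():
        rec = evaluation.participant_correlations(retained, m)
        rec.insert(0, "measure", m)
        corr_frames.append(rec)
        for adjusted in (False, True):
            try:
                tab = evaluation.correlation_regression(rec, adjusted=adjusted)
                tab.insert(0, "measure", m)
                tab.insert(1, "model", "adjusted" if adjusted else "unadjusted")
                reg_frames.append(tab)
            except ValueError as e:
                log.warning("correlation regression skipped for %s: %s", m, e)
        err = evaluation.total_ac_errors(retained, model, m)
        err.insert(0, "measure", m)
        err_frames.append(err)
        for c in cfg.evaluate.cutoffs:
            cl = evaluation.cutoff_classification(retained, model, m, c)
            cl.insert(0, "measure", m)
            cls_frames.append(cl)
        curves, cmape = evaluation.daily_median_curves(
            retained, model, m, age_breaks=tuple(cfg.evaluate.age_breaks))
        curves.insert(0, "measure", m)
        curve_frames.append(curves)
        curve_mapes[m] = cmape
    pd.concat(corr_frames).to_csv(out / "correlations.csv", index=False,
                                  float_format="%.6f")
    if reg_frames:
        pd.concat(reg_frames).to_csv(out / "correlation_regression.csv",
                                     index=False, float_format="%.6f")
    pd.concat(err_frames).to_csv(out / "errors.csv", index=False,
                                 float_format="%.6f")
    pd.concat(cls_frames).to_csv(out / "classification.csv", index=False,
                                 float_format="%.6f")
    pd.concat(curve_frames).to_csv(out / "curves.csv", index=False,
                                   float_format="%.6f")
    stage("evaluate", curve_mape={k: float(v) for k, v in curve_mapes.items()})

    minutes_dir = out / "minutes"
    minutes_dir.mkdir(exist_ok=True)
    for p in retained:
        write_minute_summary(p.minutes, minutes_dir / f"{p.participant_id}.csv")
    write_metadata_csv(retained, out / "metadata.csv")

    dump_config(cfg, out / "resolved_config.yaml")
    with open(out / "run_log.json", "w") as fh:
        json.dump(runlog, fh, indent=1, sort_keys=True)
    return runlog
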