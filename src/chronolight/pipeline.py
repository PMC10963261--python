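"""End-to-end orchestration: simulate (or load) → DLMO → outcomes → Bayes.

A :class:`RunConfig` is the single source of truth for a run: stage toggles,
the analysis thresholds (AOI = 5 pg ml⁻¹, PVT validity ≥ 100 ms, 20-epoch
sleep-onset run, frequency bands), Bayes-factor settings and the seed.  The
same config and seed produce an identical report; each stage can also be
run standalone with identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes as bayes_mod
from .dlmo import (MelatoninProfile, fit_hockeystick, phase_shift,
                   suppression_series, read_melatonin_csv)
from .eeg import alpha_theta_ratio, swa_deciles
from .sleep import Hypnogram, segment_cycles, sleep_latency_10min, sleep_efficiency
from .vigilance import PVTSession, summarize_pvt, visual_comfort_score
from .synthetic import StudyConfig, StudyDataset, generate_study
from .protocol import EXPOSURE_START_MIN, EXPOSURE_DURATION_MIN

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline"]

log = logging.getLogger("chronolight.pipeline")

ALL_STAGES = ("simulate", "dlmo", "outcomes", "bayes")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, cause: Exception, report: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.report = report


@dataclass
class RunConfig:
    seed: int = 1
    stages: tuple = ALL_STAGES
    output_dir: str | None = None
    input_dir: str | None = None      # load CSVs instead of simulating
    aoi_threshold: float = 5.0
    pvt_valid_ms: float = 100.0
    slat_run_epochs: int = 20
    bayes_draws: int = 20_000
    bayes_rank: bool = False
    study: dict = field(default_factory=dict)   # StudyConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def validate_config(config: RunConfig) -> list[str]:
    """All schema/referential problems at once; empty list means OK."""
    errors = []
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        errors.append(f"unknown stages: {sorted(unknown)}")
    for name in ("aoi_threshold", "pvt_valid_ms", "slat_run_epochs",
                 "bayes_draws"):
        if getattr(config, name) <= 0:
            errors.append(f"{name} must be positive")
    if config.input_dir is not None and not Path(config.input_dir).exists():
        errors.append(f"input directory not found: {config.input_dir}")
    if config.input_dir is None and "simulate" not in config.stages:
        errors.append("no input directory and the simulate stage is disabled")
    if config.study:
        try:
            StudyConfig(**config.study)
        except (TypeError, ValueError) as exc:
            errors.append(f"invalid study override: {exc}")
    return errors


def _load_dataset(input_dir: str) -> StudyDataset:
    directory = Path(input_dir)
    tables = {}
    for name in ("melatonin", "pvt", "kss", "comfort"):
        tables[name] = pd.read_csv(directory / f"{name}.csv")
    hyp_table = pd.read_csv(directory / "hypnograms.csv")
    hypnograms = {}
    for (pid, cond), grp in hyp_table.groupby(["participant", "condition"]):
        stages = tuple(grp.sort_values("epoch")["stage"])
        hypnograms[(pid, cond)] = Hypnogram(stages)
    truth = {"participants": {}, "records": {}}
    ppath = directory / "participants.csv"
    if ppath.exists():
        for _, row in pd.read_csv(ppath).iterrows():
            truth["participants"][row["participant"]] = {"sex": row["sex"]}

    def load_npz(path, key_parts):
        if not path.exists():
            return {}
        out: dict = {}
        with np.load(path) as z:
            for key in z.files:
                *head, ch = key.split("|")
                head = tuple(float(h) if h.replace(".", "", 1).isdigit() else h
                             for h in head)
                out.setdefault(head if len(head) > 1 else head[0], {})[ch] = z[key]
        return out

    kdt = load_npz(directory / "kdt_eeg.npz", 3)
    sleep_eeg = load_npz(directory / "sleep_eeg.npz", 2)
    return StudyDataset(tables["melatonin"], tables["pvt"], tables["kss"],
                        tables["comfort"], hypnograms, kdt, sleep_eeg,
                        truth, StudyConfig(), seed=0)


def _dlmo_stage(dataset: StudyDataset, config: RunConfig) -> dict:
    profiles = {}
    for (pid, cond, ev), grp in dataset.melatonin.groupby(
            ["participant", "condition", "evening"], sort=True):
        grp = grp.sort_values("time_min_rel_hbt")
        profiles[(pid, cond, int(ev))] = MelatoninProfile(
            str(pid), str(cond), int(ev),
            grp["time_min_rel_hbt"].to_numpy(float),
            grp["concentration_pg_ml"].to_numpy(float))

    fits, shifts, suppression_rows = {}, [], []
    for (pid, cond, ev), profile in profiles.items():
        try:
            fits[(pid, cond, ev)] = fit_hockeystick(
                profile, aoi_threshold=config.aoi_threshold)
        except ValueError as exc:
            log.warning("DLMO fit failed for %s/%s evening %s: %s",
                        pid, cond, ev, exc)
    for (pid, cond, ev), fit in fits.items():
        if ev != 1 or (pid, cond, 2) not in fits:
            continue
        f1, f2 = fit, fits[(pid, cond, 2)]
        if f1.status == "ok" and f2.status == "ok":
            shifts.append({"participant": pid, "condition": cond,
                           "shift_min": phase_shift(f1, f2)})
    for (pid, cond, ev), profile in profiles.items():
        if ev == 1:
            suppression_rows.append(suppression_series(profile))

    shift_table = pd.DataFrame(shifts)
    by_condition = (shift_table.groupby("condition")["shift_min"]
                    .agg(["mean", "std", "count"]).to_dict("index")
                    if not shift_table.empty else {})
    return {
        "fits": {f"{p}|{c}|{e}": fit.as_dict()
                 for (p, c, e), fit in fits.items()},
        "shift_table": shift_table,
        "suppression": pd.concat(suppression_rows, ignore_index=True)
        if suppression_rows else pd.DataFrame(),
        "phase_shift_by_condition": by_condition,
    }


def _outcomes_stage(dataset: StudyDataset, config: RunConfig) -> dict:
    out: dict = {}
    pvt_rows = []
    for (pid, cond, ev, tick), grp in dataset.pvt.groupby(
            ["participant", "condition", "evening", "time_min_rel_hbt"]):
        session = PVTSession(str(pid), str(cond), int(ev), float(tick),
                             grp["rt_ms"].to_numpy(float))
        try:
            s = summarize_pvt(session, config.pvt_valid_ms)
        except ValueError:
            continue
        pvt_rows.append({"participant": pid, "condition": cond, "evening": ev,
                         "time_min_rel_hbt": tick, "n_valid": s.n_valid,
                         "median_ms": s.median_ms,
                         "fastest_decile_ms": s.fastest_decile_ms,
                         "slowest_decile_ms": s.slowest_decile_ms})
    pvt_table = pd.DataFrame(pvt_rows)
    out["pvt_table"] = pvt_table
    if not pvt_table.empty:
        out["pvt_median_by_condition"] = (
            pvt_table.groupby("condition")["median_ms"].mean().to_dict())

    out["kss_by_condition"] = (
        dataset.kss.groupby("condition")["kss"].mean().to_dict())

    comfort_items = ["pleasantness", "brightness", "glare",
                     "colour_temperature"]
    scores = dataset.comfort.copy()
    scores["comfort_score"] = [
        visual_comfort_score(row) for row in
        scores[comfort_items].to_numpy(float)]
    out["comfort_table"] = scores
    out["comfort_by_condition"] = (
        scores.groupby("condition")["comfort_score"].mean().to_dict())

    if dataset.kdt_eeg:
        rate = dataset.config.eeg_rate_hz
        rows = []
        for (pid, cond, tick), chans in dataset.kdt_eeg.items():
            r = alpha_theta_ratio(chans, rate)
            rows.append({"participant": pid, "condition": cond,
                         "time_min_rel_hbt": tick,
                         "alpha_theta_ratio": r.alpha_theta_ratio,
                         "alpha_power": r.alpha_power,
                         "theta_power": r.theta_power})
        kdt_table = pd.DataFrame(rows)
        out["kdt_table"] = kdt_table
        out["alpha_theta_by_condition"] = (
            kdt_table.groupby("condition")["alpha_theta_ratio"].mean().to_dict())

    slat_rows, swa_rows = [], []
    for (pid, cond), hyp in dataset.hypnograms.items():
        slat = sleep_latency_10min(hyp, config.slat_run_epochs)
        seff, flagged = sleep_efficiency(hyp)
        slat_rows.append({"participant": pid, "condition": cond,
                          "slat_min": slat, "sleep_efficiency": seff,
                          "low_efficiency_flag": flagged})
        if dataset.sleep_eeg.get((pid, cond)):
            cycles = segment_cycles(hyp)
            first = cycles[0]
            if not first.open_cycle:
                profile = swa_deciles(dataset.sleep_eeg[(pid, cond)],
                                      dataset.config.sleep_eeg_rate_hz,
                                      first, hyp)
                swa_rows.append({"participant": pid, "condition": cond,
                                 **{f"nrem_d{i+1}": v for i, v in
                                    enumerate(profile.nrem_deciles)},
                                 **{f"rem_d{i+1}": v for i, v in
                                    enumerate(profile.rem_deciles)}})
    out["sleep_table"] = pd.DataFrame(slat_rows)
    out["slat_by_condition"] = (
        out["sleep_table"].dropna(subset=["slat_min"])
        .groupby("condition")["slat_min"].mean().to_dict())
    if swa_rows:
        out["swa_table"] = pd.DataFrame(swa_rows)
    return out


def _bayes_stage(dataset: StudyDataset, dlmo_out: dict, outcomes_out: dict,
                 config: RunConfig) -> dict:
    sex = {pid: info.get("sex", "U") for pid, info in
           dataset.ground_truth.get("participants", {}).items()}

    def add_sex(frame):
        frame = frame.copy()
        frame["gender"] = [sex.get(p, "U") for p in frame["participant"]]
        return frame

    results = {}

    shift_table = dlmo_out.get("shift_table")
    if shift_table is not None and not shift_table.empty:
        results["phase_shift_condition"] = bayes_mod.lm_bf(
            add_sex(shift_table), "shift_min", fixed=["condition"],
            random=["participant", "gender"], draws=config.bayes_draws,
            seed=config.seed, rank=config.bayes_rank)

    suppression = dlmo_out.get("suppression")
    if suppression is not None and not suppression.empty:
        supp = add_sex(suppression)
        supp["time"] = supp["time_min_rel_hbt"].astype(str)
        results["exposure_melatonin_condition"] = bayes_mod.lm_bf(
            supp, "concentration_pg_ml", fixed=["condition"],
            random=["participant", "gender"], draws=config.bayes_draws,
            seed=config.seed, rank=config.bayes_rank)

    pvt_table = outcomes_out.get("pvt_table")
    if pvt_table is not None and not pvt_table.empty:
        exposure = pvt_table[
            (pvt_table["evening"] == 1)
            & (pvt_table["time_min_rel_hbt"] >= EXPOSURE_START_MIN)
            & (pvt_table["time_min_rel_hbt"]
               <= EXPOSURE_START_MIN + EXPOSURE_DURATION_MIN)]
        if not exposure.empty:
            results["pvt_median_condition"] = bayes_mod.lm_bf(
                add_sex(exposure), "median_ms", fixed=["condition"],
                random=["participant", "gender"], draws=config.bayes_draws,
                seed=config.seed, rank=config.bayes_rank)

    table = {
        name: {"bf10": r.bf10, "bf01": r.bf01, "error": r.error,
               "method": r.method, "category": r.category}
        for name, r in results.items()
    }
    return {"results": results, "table": table}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the structured report; with ``output_dir`` set, also writes
    ``report.json`` and the resolved config for provenance.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    dataset = None
    stage = "setup"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            log.info("stage=simulate seed=%d", config.seed)
            dataset = generate_study(StudyConfig(**config.study), config.seed)
            report["simulate"] = {"n_participants": dataset.config.n_participants,
                                  "conditions": list(dataset.config.conditions)}
        else:
            stage = "load"
            dataset = _load_dataset(config.input_dir)

        dlmo_out: dict = {}
        if "dlmo" in config.stages:
            stage = "dlmo"
            log.info("stage=dlmo")
            dlmo_out = _dlmo_stage(dataset, config)
            report["dlmo"] = {
                "phase_shift_by_condition": dlmo_out["phase_shift_by_condition"],
                "n_shifts": int(len(dlmo_out["shift_table"])),
            }

        outcomes_out: dict = {}
        if "outcomes" in config.stages:
            stage = "outcomes"
            log.info("stage=outcomes")
            outcomes_out = _outcomes_stage(dataset, config)
            report["outcomes"] = {
                k: outcomes_out[k] for k in
                ("pvt_median_by_condition", "kss_by_condition",
                 "comfort_by_condition", "alpha_theta_by_condition",
                 "slat_by_condition") if k in outcomes_out}

        if "bayes" in config.stages:
            stage = "bayes"
            log.info("stage=bayes")
            bayes_out = _bayes_stage(dataset, dlmo_out, outcomes_out, config)
            report["bayes"] = bayes_out["table"]
    except Exception as exc:  # typed error naming the stage, partial report kept
        raise PipelineError(stage, exc, report) from exc

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
        config.to_yaml(out / "resolved_config.yaml")
    return report
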