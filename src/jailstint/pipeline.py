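"""End-to-end pipeline: generate/ingest -> reconcile -> merge -> clean ->
census -> cohort statistics -> cap simulation.

A single :class:`PipelineConfig` (constructible from a YAML/JSON
mapping) names either three input snapshot CSVs or a synthetic
generation block, plus the coverage window, data date, focus week and
cap grid.  ``run_pipeline`` writes every stage output and report under
the output directory and returns a manifest of row counts, report
counts and headline statistics.  With synthetic inputs a rerun under
the same config is byte-identical: the single seed fans out to the
generator and corruptor by fixed offsets and no wall-clock data enters
any output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import capsim as capsim_mod
from . import census as census_mod
from . import clean as clean_mod
from . import cohort_stats as cs
from . import ingest as ingest_mod
from . import merge as merge_mod
from . import synthetic_data as synth

log = logging.getLogger("jailstint")

_SEED_MOD = 2**31


def _parse_date(v) -> date:
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v))


@dataclass
class PipelineConfig:
    output_dir: str = "jailstint_out"
    seed: int = 0
    coverage_window: tuple[date, date] = (date(2014, 1, 1), date(2020, 12, 31))
    data_date: date = date(2021, 1, 9)
    focus_week: tuple[tuple[int, int], tuple[int, int]] = cs.FOCUS_WEEK_DEFAULT
    focus_year: int = 2020
    cap_grid: tuple[int, ...] = capsim_mod.DEFAULT_CAP_GRID
    log_level: str = "INFO"
    inputs: dict[str, str] | None = None          # ads/dds/current paths
    synthetic: synth.TruthConfig | None = None
    corruption: synth.CorruptionConfig | None = None

    def validate(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("config must provide exactly one of "
                             "'inputs' and 'synthetic'")
        if self.inputs is not None:
            missing = {"ads", "dds", "current"} - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing {sorted(missing)}")
        if self.coverage_window[0] >= self.coverage_window[1]:
            raise ValueError("coverage window start must precede its end")
        if self.data_date < self.coverage_window[1]:
            raise ValueError("data_date must not precede the coverage "
                             "window end")

    @staticmethod
    def from_mapping(cfg: dict) -> "PipelineConfig":
        cfg = dict(cfg)
        kwargs: dict = {}
        for key in ("output_dir", "seed", "focus_year", "log_level"):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "coverage_window" in cfg:
            cw = cfg["coverage_window"]
            kwargs["coverage_window"] = (_parse_date(cw["start"]),
                                         _parse_date(cw["end"]))
        if "data_date" in cfg:
            kwargs["data_date"] = _parse_date(cfg["data_date"])
        if "cap_grid" in cfg:
            kwargs["cap_grid"] = tuple(int(d) for d in cfg["cap_grid"])
        if "focus_week" in cfg:
            lo, hi = str(cfg["focus_week"]).split(":")
            kwargs["focus_week"] = (tuple(int(x) for x in lo.split("-")),
                                    tuple(int(x) for x in hi.split("-")))
        if "inputs" in cfg:
            kwargs["inputs"] = dict(cfg["inputs"])
        if "synthetic" in cfg:
            block = dict(cfg["synthetic"])
            corr = block.pop("corruption", None)
            for key in ("admission_window",):
                if key in block:
                    block[key] = tuple(_parse_date(d) for d in block[key])
            for key in ("coverage_start", "data_date"):
                if key in block:
                    block[key] = _parse_date(block[key])
            if "focus_week_effect" in block:
                fx = dict(block["focus_week_effect"])
                if "week_start" in fx:
                    fx["week_start"] = _parse_date(fx["week_start"])
                block["focus_week_effect"] = synth.FocusWeekEffect(**fx)
            if "duration_law" in block:
                block["duration_law"] = synth.DurationLaw(**block["duration_law"])
            kwargs["synthetic"] = synth.TruthConfig(**block)
            if corr is not None:
                kwargs["corruption"] = synth.CorruptionConfig(**corr)
        return PipelineConfig(**kwargs)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_mapping(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Hash of the analytic configuration (not output location)."""
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, date):
                return o.isoformat()
            return str(o)
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write outputs, and return the manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed,
                      "config_hash": config.config_hash(),
                      "stages": {}}

    # --- acquire ---------------------------------------------------------
    if config.synthetic is not None:
        truth_cfg = dataclasses.replace(
            config.synthetic, seed=config.seed % _SEED_MOD)
        corruption = config.corruption or synth.CorruptionConfig()
        corruption = dataclasses.replace(
            corruption, seed=(config.seed + 1) % _SEED_MOD)
        truth = synth.generate_truth(truth_cfg)
        ads_t, dds_t, cur_t, ledger = synth.corrupt_to_snapshots(
            truth, corruption)
        snapdir = outdir / "snapshots"
        paths = synth.write_snapshots(ads_t, dds_t, cur_t, snapdir,
                                      ledger=ledger)
        log.info("synthetic truth: %d episodes, %d individuals",
                 len(truth.episodes), len(truth.persons))
        manifest["stages"]["synthetic"] = {
            "truth_episodes": len(truth.episodes),
            "ledger_counts": ledger.counts}
    else:
        paths = dict(config.inputs)

    ads = ingest_mod.read_raw_table(paths["ads"], "ADS")
    dds = ingest_mod.read_raw_table(paths["dds"], "DDS")
    current = ingest_mod.read_raw_table(paths["current"], "CURRENT")
    manifest["stages"]["ingest"] = {"ads_rows": len(ads),
                                    "dds_rows": len(dds),
                                    "current_rows": len(current)}
    log.info("ingested %d ADS, %d DDS, %d current rows",
             len(ads), len(dds), len(current))

    # --- reconcile -------------------------------------------------------
    ads, dds, removal = ingest_mod.reconcile(ads, dds)
    _write_json(outdir / "removal_report.json", removal.to_dict())
    manifest["stages"]["reconcile"] = removal.to_dict() | {
        "ads_surviving": len(ads), "dds_surviving": len(dds)}
    log.info("reconciliation removed %d records (%s)",
             removal.total_removed, removal.to_dict())

    # --- merge -----------------------------------------------------------
    episodes, merge_report = merge_mod.merge_records(
        ads, dds, current, config.data_date,
        coverage_start=config.coverage_window[0])
    _write_json(outdir / "merge_report.json", merge_report.to_dict())
    manifest["stages"]["merge"] = merge_report.to_dict()
    log.info("merge accepted %d episodes: %s", merge_report.total_accepted,
             merge_report.category_counts)

    # --- clean -----------------------------------------------------------
    episodes, clean_report = clean_mod.clean_episodes(
        episodes, config.data_date)
    _write_json(outdir / "clean_report.json", clean_report.to_dict())
    final_cols = ["id", "admit_dt", "discharge_dt", "ongoing",
                  "merge_category", "race", "gender", "status_code",
                  "top_charge", "age_at_discharge", "duration_days"]
    episodes[final_cols].to_csv(outdir / "episodes.csv", index=False)
    manifest["stages"]["clean"] = clean_report.to_dict() | {
        "final_episodes": len(episodes)}
    log.info("cleaning kept %d episodes", len(episodes))

    # --- census ----------------------------------------------------------
    series = census_mod.daily_census(episodes, config.coverage_window,
                                     config.data_date)
    series.rename_axis("date").to_csv(outdir / "census.csv")
    weekly = census_mod.weekly_net_change(series)
    weekly.table.to_csv(outdir / "weekly_change.csv", index=False)
    min_week = weekly.minimum_week
    min_change = int(weekly.table["net_change"].min())
    manifest["stages"]["census"] = {
        "days": len(series),
        "min_week_start": str(min_week.date()),
        "min_week_net_change": min_change}
    log.info("largest weekly decrease %d in week of %s",
             min_change, min_week.date())

    # --- cohort statistics -----------------------------------------------
    years = range(config.coverage_window[0].year, config.focus_year + 1)
    cohorts = cs.focus_week_cohorts(episodes, years,
                                    month_day_window=config.focus_week)
    focus = cohorts[config.focus_year]
    prior = pd.concat([cohorts[y] for y in years if y != config.focus_year])
    ks_duration = cs.ks_one_sided(focus["duration_days"],
                                  prior["duration_days"])
    focus_age = focus["age_at_discharge"].dropna().astype(float)
    prior_age = prior["age_at_discharge"].dropna().astype(float)
    ks_age = cs.ks_one_sided(focus_age, prior_age)

    obs = cs.readmission_flags(episodes, focus_year=config.focus_year,
                               month_day_window=config.focus_week)
    model1, model2 = cs.readmission_models(obs)
    model1.summary_frame().to_csv(outdir / "readmission_model1.csv",
                                  index=False)
    model2.summary_frame().to_csv(outdir / "readmission_model2.csv",
                                  index=False)
    _write_json(outdir / "ks_results.json", {
        "duration": dataclasses.asdict(ks_duration),
        "age": dataclasses.asdict(ks_age)})
    manifest["stages"]["cohorts"] = {
        "focus_n": len(focus), "prior_n": len(prior),
        "ks_duration_D": ks_duration.statistic,
        "ks_duration_p": ks_duration.p_value,
        "ks_age_D": ks_age.statistic,
        "ks_age_p": ks_age.p_value,
        "model1": dict(zip(model1.terms, model1.estimates.tolist())),
        "model2": dict(zip(model2.terms, model2.estimates.tolist()))}
    log.info("focus-week cohort %d vs %d prior; duration D=%.3f p=%.2g",
             len(focus), len(prior), ks_duration.statistic,
             ks_duration.p_value)

    # --- cap simulation ---------------------------------------------------
    sweep = capsim_mod.cap_sweep(episodes, config.coverage_window,
                                 config.data_date, cap_grid=config.cap_grid)
    sweep.table.to_csv(outdir / "cap_sweep.csv", index=False)
    manifest["stages"]["capsim"] = {
        "uncapped_person_days": sweep.uncapped_person_days,
        "reduction_by_cap": dict(zip(
            sweep.table["cap_days"].astype(int).astype(str),
            sweep.table["reduction"].round(6)))}

    _write_json(outdir / "manifest.json", manifest)
    return manifest
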