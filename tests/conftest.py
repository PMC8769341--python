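from datetime import date

import pandas as pd
import pytest

import jailstint as js


@pytest.fixture(scope="session")
def small_truth() -> js.Truth:
    """A compact population with pre-window admissions and ongoing stays."""
    cfg = js.TruthConfig(
        n_individuals=2000, seed=11,
        admission_window=(date(2013, 6, 1), date(2020, 12, 31)),
        coverage_start=date(2014, 1, 1))
    return js.generate_truth(cfg)


def run_chain(truth: js.Truth, corruption: js.CorruptionConfig):
    """Run snapshots -> reconcile -> merge -> clean; return all artifacts."""
    ads, dds, cur, ledger = js.corrupt_to_snapshots(truth, corruption)
    ads2, dds2, removal = js.reconcile(ads, dds)
    episodes, merge_report = js.merge_records(
        ads2, dds2, cur, truth.config.resolved_data_date,
        coverage_start=truth.config.resolved_coverage_start)
    cleaned, clean_report = js.clean_episodes(
        episodes, truth.config.resolved_data_date)
    return {"ads": ads, "dds": dds, "current": cur, "ledger": ledger,
            "removal": removal, "merge_report": merge_report,
            "episodes": episodes, "cleaned": cleaned,
            "clean_report": clean_report}


@pytest.fixture(scope="session")
def clean_baseline(small_truth):
    """Zero-corruption pipeline artifacts for the small population."""
    return run_chain(small_truth, js.CorruptionConfig())


def truth_durations(truth: js.Truth) -> pd.Series:
    """Date-level durations of the truth episodes (data-date clipped,
    same-day stays = 0.5), the convention the cleaning stage derives."""
    data_ts = pd.Timestamp(truth.config.resolved_data_date)
    eff = truth.episodes["discharge_dt"].clip(upper=data_ts)
    d = (eff.dt.normalize()
         - truth.episodes["admit_dt"].dt.normalize()).dt.days.astype(float)
    d[d == 0] = 0.5
    return d
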