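"""End-to-end runs: cohort -> strategies -> coverage/capture -> statistics.

A run generates (or loads) a cohort, realizes every requested charting
strategy on every visit, computes per-visit coverage and per-event capture,
runs the variable-schedule grid search and the optimizer, compares each
strategy against actual charting, and writes all tables as CSV plus a JSON
manifest that suffices to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .capture import capture, cohort_capture_summary, detect_events, events_table
from .coverage import coverage, per_event_informativeness
from .optimizer import PlacementProblem, optimal_placement
from .preprocessing import read_cohort_csv, write_cohort_csv
from .stats import (
    bootstrap_median_diff,
    prop_test_cc,
    ratio_of_means_ci,
    ratio_of_proportions_ci,
    two_sample_t,
    wilcoxon_signed_rank,
)
from .strategies import (
    DEFAULT_LARGE_GRID,
    DEFAULT_SMALL_GRID,
    actual_events_per_visit,
    event_decile_distribution,
    grid_search,
    realize_charting,
    strategy_times,
)
from .synthetic import CohortConfig, generate_cohort
from .types import ABNORMALITY_TYPES, COVERAGE_BOUNDS, ChartEvent, Visit

logger = logging.getLogger(__name__)

DEFAULT_STRATEGIES = ("actual", "equal_spacing", "fixed_schedule", "variable_schedule", "optimized")


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    output_dir: str = "vitalsched_run"
    seed: int = 0
    n_visits: int = 500
    cohort_long_csv: Optional[str] = None  # load instead of generate when set
    cohort_visits_csv: Optional[str] = None
    strategies: tuple[str, ...] = DEFAULT_STRATEGIES
    large_step: int = 80
    small_step: int = 40
    budget: str = "actual"  # "actual" or an integer string
    run_grid_search: bool = True
    large_grid: tuple[int, ...] = DEFAULT_LARGE_GRID
    small_grid: tuple[int, ...] = DEFAULT_SMALL_GRID
    use_selected_steps: bool = True  # adopt the grid-search winner for variable_schedule
    bootstrap_replicates: int = 10_000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.strategies:
            raise ValueError("at least one strategy is required")
        unknown = set(self.strategies) - set(DEFAULT_STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")

    def budget_for(self, visit: Visit) -> int:
        if self.budget == "actual":
            return len(visit.actual_charting)
        return int(self.budget)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build_cohort(config: RunConfig) -> list[Visit]:
    if config.cohort_long_csv is not None:
        if config.cohort_visits_csv is None:
            raise ValueError("loading a cohort requires both CSV paths")
        return read_cohort_csv(config.cohort_long_csv, config.cohort_visits_csv)
    return generate_cohort(CohortConfig(n_visits=config.n_visits, seed=config.seed))


def realize_all_strategies(
    cohort: Sequence[Visit],
    config: RunConfig,
    large_step: Optional[int] = None,
    small_step: Optional[int] = None,
) -> dict[str, dict[str, list[ChartEvent]]]:
    """Charting events per strategy per visit."""
    large = large_step if large_step is not None else config.large_step
    small = small_step if small_step is not None else config.small_step
    out: dict[str, dict[str, list[ChartEvent]]] = {}
    for kind in config.strategies:
        per_visit = {}
        for visit in cohort:
            if kind == "actual":
                events = list(visit.actual_charting)
            elif kind == "optimized":
                problem = PlacementProblem(visit, budget=config.budget_for(visit))
                events = realize_charting(visit, optimal_placement(problem).minutes)
            else:
                times = strategy_times(visit, kind, large_step=large, small_step=small)
                events = realize_charting(visit, times)
            per_visit[visit.visit_id] = events
        out[kind] = per_visit
    return out


def coverage_table(
    cohort: Sequence[Visit], charting: dict[str, dict[str, list[ChartEvent]]]
) -> pd.DataFrame:
    rows = []
    for kind, per_visit in charting.items():
        for visit in cohort:
            events = per_visit[visit.visit_id]
            res = coverage(visit, events)
            for mod, frac in res.fractions.items():
                rows.append((visit.visit_id, kind, mod, frac, len(events)))
    return pd.DataFrame(rows, columns=["visit_id", "strategy", "modality", "coverage", "n_events"])


def capture_tables(
    cohort: Sequence[Visit], charting: dict[str, dict[str, list[ChartEvent]]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    event_frames = []
    summary_frames = []
    for kind, per_visit in charting.items():
        all_events = []
        for visit in cohort:
            evs = capture(detect_events(visit), per_visit[visit.visit_id])
            all_events.extend(evs)
        event_frames.append(events_table(all_events, strategy=kind))
        summary = cohort_capture_summary(cohort, per_visit)
        summary.insert(0, "strategy", kind)
        summary_frames.append(summary)
    nonempty = [f for f in event_frames if len(f)] or event_frames[:1]
    return (
        pd.concat(nonempty, ignore_index=True),
        pd.concat(summary_frames, ignore_index=True),
    )


def comparison_table(
    coverage_df: pd.DataFrame,
    capture_events_df: pd.DataFrame,
    seed: int,
    bootstrap_replicates: int = 10_000,
) -> pd.DataFrame:
    """Every strategy vs actual charting: coverage, capture, and lag comparisons."""
    rows = []
    strategies = [s for s in coverage_df["strategy"].unique() if s != "actual"]

    def add(strategy, measure, target, res):
        rows.append(
            (
                strategy,
                target,
                measure,
                res.estimate,
                res.ci_low,
                res.ci_high,
                res.p_value,
                res.n_a,
                res.n_b,
            )
        )

    for strat in strategies:
        for mod in sorted(coverage_df["modality"].unique()):
            a = coverage_df.query("strategy == @strat and modality == @mod")["coverage"].to_numpy()
            b = coverage_df.query("strategy == 'actual' and modality == @mod")["coverage"].to_numpy()
            add(strat, "coverage_mean_difference", mod, two_sample_t(a, b))
            if b.mean() > 0:
                add(strat, "coverage_ratio_of_means", mod, ratio_of_means_ci(a, b))
        ev_a = capture_events_df[capture_events_df["strategy"] == strat]
        ev_b = capture_events_df[capture_events_df["strategy"] == "actual"]
        for abn in ABNORMALITY_TYPES:
            sub_a = ev_a[ev_a["type"] == abn]
            sub_b = ev_b[ev_b["type"] == abn]
            if not len(sub_a) or not len(sub_b):
                continue
            xa, na = int(sub_a["captured"].sum()), len(sub_a)
            xb, nb = int(sub_b["captured"].sum()), len(sub_b)
            add(strat, "capture_prop_test", abn, prop_test_cc(xa, na, xb, nb))
            if xb > 0:
                add(strat, "capture_ratio_of_proportions", abn, ratio_of_proportions_ci(xa, na, xb, nb))
            merged = sub_a[sub_a["captured"]].merge(
                sub_b[sub_b["captured"]], on=["visit_id", "type"], suffixes=("_a", "_b")
            )
            if len(merged) >= 1:
                add(
                    strat,
                    "lag_signed_rank",
                    abn,
                    wilcoxon_signed_rank(merged["lag_a"].to_numpy(), merged["lag_b"].to_numpy()),
                )
            lags_a = sub_a.loc[sub_a["captured"], "lag"].to_numpy(dtype=float)
            lags_b = sub_b.loc[sub_b["captured"], "lag"].to_numpy(dtype=float)
            if len(lags_a) and len(lags_b):
                add(
                    strat,
                    "lag_median_difference",
                    abn,
                    bootstrap_median_diff(
                        lags_a, lags_b, replicates=bootstrap_replicates, seed=seed
                    ),
                )
    return pd.DataFrame(
        rows,
        columns=[
            "strategy",
            "target",
            "measure",
            "estimate",
            "ci_low",
            "ci_high",
            "p_value",
            "n_a",
            "n_b",
        ],
    )


def run(config: RunConfig) -> dict:
    """Execute a full analysis run and write artifacts to the output directory.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = _build_cohort(config)
    write_cohort_csv(cohort, outdir / "cohort_long.csv", outdir / "cohort_visits.csv")

    selected = (config.large_step, config.small_step)
    grid_result = None
    if config.run_grid_search and "variable_schedule" in config.strategies:
        grid_result = grid_search(cohort, config.large_grid, config.small_grid)
        grid_result.table.to_csv(outdir / "gridsearch.csv", index=False)
        if config.use_selected_steps:
            selected = grid_result.selected

    charting = realize_all_strategies(cohort, config, *selected)

    cov_df = coverage_table(cohort, charting)
    cov_df.to_csv(outdir / "coverage.csv", index=False)

    info_rows = []
    for visit in cohort:
        for (i, mod), value in per_event_informativeness(visit, visit.actual_charting).items():
            info_rows.append(
                (visit.visit_id, i, visit.actual_charting[i].minute, mod, value)
            )
    pd.DataFrame(
        info_rows, columns=["visit_id", "event_index", "minute", "modality", "informativeness"]
    ).to_csv(outdir / "informativeness.csv", index=False)

    if "optimized" in charting:
        placement_rows = [
            (vid, ";".join(str(e.minute) for e in events), len(events))
            for vid, events in charting["optimized"].items()
        ]
        pd.DataFrame(placement_rows, columns=["visit_id", "minutes", "n_events"]).to_csv(
            outdir / "placements.csv", index=False
        )

    events_df, summary_df = capture_tables(cohort, charting)
    events_df.to_csv(outdir / "capture_events.csv", index=False)
    summary_df.to_csv(outdir / "capture_summary.csv", index=False)

    stats_df = comparison_table(
        cov_df, events_df, seed=config.seed, bootstrap_replicates=config.bootstrap_replicates
    )
    stats_df.to_csv(outdir / "comparisons.csv", index=False)

    decile_frames = []
    for kind, per_visit in charting.items():
        dist = event_decile_distribution(
            cohort, {vid: [e.minute for e in evs] for vid, evs in per_visit.items()}
        )
        dist.insert(0, "strategy", kind)
        decile_frames.append(dist)
    pd.concat(decile_frames, ignore_index=True).to_csv(
        outdir / "event_distribution.csv", index=False
    )

    import pandas
    import scipy

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_visits": len(cohort),
        "actual_events_per_visit": actual_events_per_visit(cohort),
        "selected_steps": {"large": selected[0], "small": selected[1]},
        "grid_search_feasible": None if grid_result is None else grid_result.feasible,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "outputs": sorted(p.name for p in outdir.glob("*.csv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
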