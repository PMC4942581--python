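"""End-to-end analysis pipeline: score trials, build the landscape, and run
the learning analyses, mirroring the full study workflow on any trial set."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinematics as kin
from .chunking import detect_chunk_boundaries
from .kinematics import TrialKinematics
from .learning import (
    ScoredTrial,
    daily_summaries,
    fit_day_transition_model,
    fit_degenerate_trend,
    percentile_score,
    prevalence_efficiency_correlation,
    rank_scenarios,
    simulate_null_walkers,
    summaries_table,
)
from .minjerk import SequenceGeometry, fit_model_to_trial, goodness_of_fit
from .pareto import landscape_table, pareto_frontier, tradeoff_landscape

__all__ = ["score_trial", "analyze_dataset", "AnalysisResult"]

log = logging.getLogger("chunkopt")


def score_trial(
    trial: TrialKinematics,
    geom: SequenceGeometry = SequenceGeometry(),
    min_frac: float = 0.05,
    max_frac: float = 0.25,
    min_halt_ms: float = 25.0,
    fit_model: bool = True,
) -> ScoredTrial:
    """Detect the trial's chunk structure and score its efficiency.

    Detection runs on the raw-time smoothed speed profile (with capture
    times when present, else a uniform schedule); efficiency on the
    duration-normalized trace; the minimum-jerk model fit and its
    goodness of fit on the normalized trial.
    """
    speed = kin.compute_speed(kin.smooth_positions(trial))
    if trial.capture_times is not None:
        element_times = trial.capture_times
    else:
        element_times = trial.t[0] + trial.duration * \
            np.arange(1, geom.n_elements + 1) / geom.n_elements
    det = detect_chunk_boundaries(speed, element_times, min_frac=min_frac,
                                  max_frac=max_frac, min_halt_ms=min_halt_ms,
                                  n_elements=geom.n_elements)
    norm = kin.normalize_duration(trial, target_s=geom.total_duration_s)
    sq = kin.squared_jerk(norm)
    gof = None
    if fit_model:
        model = fit_model_to_trial(norm, det, geom)
        gof = goodness_of_fit(model, norm)
    return ScoredTrial(trial_id=trial.trial_id, day=trial.day,
                       structure=det.structure, efficiency=-sq,
                       squared_jerk=sq, gof=gof)


@dataclass
class AnalysisResult:
    tables: dict[str, pd.DataFrame]
    scored: list[ScoredTrial]
    percentile: float | None

    def __getitem__(self, key: str) -> pd.DataFrame:
        return self.tables[key]


def analyze_dataset(
    trials: list[TrialKinematics],
    geom: SequenceGeometry = SequenceGeometry(),
    outlier_percentile: float = 95.0,
    n_walkers: int = 5000,
    seed: int | None = 0,
    fit_models: bool = True,
    top_k_sets: int = 8,
) -> AnalysisResult:
    """Run the full analysis on a set of trials.

    Stages: score every trial (detection + efficiency + optional model
    fit) -> drop squared-jerk outliers above the batch percentile ->
    model landscape and Pareto frontier -> daily summaries -> scenario
    ranking -> random-walk null test of the observed complexity path ->
    degenerate-set trend fit -> prevalence/efficiency correlation.
    Stages whose preconditions are unmet (too few days/sets) are skipped
    with a log entry and their table left out.
    """
    scored = [score_trial(tr, geom, fit_model=fit_models) for tr in trials]
    log.info("scored %d trials", len(scored))
    jerks = np.asarray([s.squared_jerk for s in scored])
    thr = float(np.percentile(jerks, outlier_percentile)) if scored else np.inf
    kept = [s for s in scored if s.squared_jerk <= thr]
    log.info("outlier filter (p%.0f = %.4g): kept %d / %d trials",
             outlier_percentile, thr, len(kept), len(scored))

    points = tradeoff_landscape(geom)
    frontier = pareto_frontier(points)
    tables: dict[str, pd.DataFrame] = {}
    tables["trials"] = pd.DataFrame([{
        "trial_id": s.trial_id, "day": s.day,
        "structure": s.structure.to_bitstring(),
        "chunk_lengths": s.structure.to_lengths_string(),
        "n_chunks": s.structure.n_chunks, "complexity": s.complexity,
        "squared_jerk": s.squared_jerk, "efficiency": s.efficiency,
        "gof": s.gof,
    } for s in kept])
    tables["landscape"] = landscape_table(points, frontier)
    tables["frontier"] = landscape_table(frontier.points)
    summaries = daily_summaries(kept)
    tables["daily"] = summaries_table(summaries)
    tables["scenarios"] = rank_scenarios()

    percentile = None
    if len(summaries) >= 3:
        transition = fit_day_transition_model(summaries)
        null = simulate_null_walkers(
            start_complexity=summaries[0].mean_complexity,
            n_days=len(summaries), transition=transition,
            n_walkers=n_walkers, seed=seed,
        )
        percentile = percentile_score(summaries, null)
        tables["null"] = null.summary().assign(observed_percentile=percentile)
        log.info("null test: percentile %.2f", percentile)
    else:
        log.info("skipping null test: fewer than 3 days")

    try:
        trend = fit_degenerate_trend(kept, top_k=top_k_sets)
        tables["trend"] = trend.table()
    except ValueError as err:
        log.info("skipping degenerate-set trend: %s", err)
    try:
        rho, p = prevalence_efficiency_correlation(kept, points)
        tables["prevalence"] = pd.DataFrame(
            [{"spearman_rho": rho, "p_value": p, "mode": "pooled"}])
    except ValueError as err:
        log.info("skipping prevalence correlation: %s", err)
    return AnalysisResult(tables=tables, scored=kept, percentile=percentile)
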