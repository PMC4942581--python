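"""Learning-path analyses over the efficiency-computation space.

Covers: per-day summaries of scored trials; the cost-effectiveness scenario
simulation (how much cumulative computation different learning strategies
spend to reach the same final efficiency); the Monte-Carlo random-walk null
test for whether an observed path keeps complexity low; the degenerate-set
exponential mixed-effects trend fit; and the prevalence-vs-efficiency rank
correlation control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
import statsmodels.formula.api as smf

from .chunking import ChunkStructure, hamming
from .pareto import TradeoffPoint

__all__ = [
    "ScoredTrial",
    "DailySummary",
    "ScenarioSpec",
    "GaussianStep",
    "NullDistribution",
    "TrendFit",
    "daily_summaries",
    "efficiency_curve",
    "complexity_curve",
    "cumulative_complexity",
    "rank_scenarios",
    "fit_day_transition_model",
    "simulate_null_walkers",
    "percentile_score",
    "fit_degenerate_trend",
    "prevalence_efficiency_correlation",
    "DEFAULT_CURVATURES",
    "DEFAULT_RATES",
    "COMPLEXITY_RANGE",
]

#: attainable complexity extremes for the 10-element task:
#: ten 1-element chunks (1 + ln 10) up to a single 10-element chunk (10).
COMPLEXITY_RANGE = (1.0 + math.log(10.0), 10.0)

#: scenario grid: trade-off-curvature parameters 1..5 (along-frontier to
#: away-from-frontier) and efficiency-improvement rate curves E1..E3.
DEFAULT_CURVATURES = (0.05, 0.25, 0.5, 1.0, 2.0)
DEFAULT_RATES = (0.1, 0.25, 0.4)


@dataclass
class ScoredTrial:
    """Per-trial analysis record: detected structure plus efficiency scores."""

    trial_id: int
    day: int
    structure: ChunkStructure
    efficiency: float
    squared_jerk: float
    gof: float | None = None

    @property
    def complexity(self) -> float:
        from .chunking import complexity as _c
        return _c(self.structure)


@dataclass
class DailySummary:
    day: int
    mean_efficiency: float
    mean_complexity: float
    n_trials: int
    n_unique_structures: int
    mean_consecutive_hamming: float


def daily_summaries(trials: list[ScoredTrial]) -> list[DailySummary]:
    """Group scored trials by day; consecutive-Hamming uses within-day trial order."""
    out = []
    by_day: dict[int, list[ScoredTrial]] = {}
    for tr in trials:
        by_day.setdefault(tr.day, []).append(tr)
    for day in sorted(by_day):
        rows = sorted(by_day[day], key=lambda r: r.trial_id)
        if not rows:
            continue
        structs = [r.structure for r in rows]
        ham = [hamming(a, b) for a, b in zip(structs, structs[1:])]
        out.append(DailySummary(
            day=day,
            mean_efficiency=float(np.mean([r.efficiency for r in rows])),
            mean_complexity=float(np.mean([r.complexity for r in rows])),
            n_trials=len(rows),
            n_unique_structures=len(set(structs)),
            mean_consecutive_hamming=float(np.mean(ham)) if ham else 0.0,
        ))
    return out


def summaries_table(summaries: list[DailySummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


# ----------------------------------------------------------------------
# cost-effectiveness scenario simulation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """One learning strategy in normalized efficiency-computation space.

    ``rate_c`` is the time constant of the saturating-exponential efficiency
    improvement E(t) on the unit learning interval; ``curvature_ce`` shapes
    the complexity-vs-efficiency path X(E): small values hug the Pareto
    frontier (complexity spent late), large values leave it (complexity
    spent early).
    """

    rate_c: float
    curvature_ce: float

    def __post_init__(self) -> None:
        if self.rate_c <= 0 or self.curvature_ce <= 0:
            raise ValueError("scenario parameters must be positive")


def _sat_exp(u, c: float):
    """Normalized saturating exponential mapping [0,1]->[0,1], 0->0, 1->1.

    f(u) = (1 - exp(-u/c)) / (1 - exp(-1/c)); strictly increasing, concave,
    and -> identity as c -> infinity.
    """
    if c <= 0:
        raise ValueError("curve parameter must be positive")
    u = np.asarray(u, dtype=float)
    if np.isinf(c):
        return u if u.ndim else float(u)
    # numerically safe for small c (expm1 keeps precision)
    out = np.expm1(-u / c) / np.expm1(-1.0 / c)
    return out if out.ndim else float(out)


def efficiency_curve(t, rate_c: float):
    """Normalized efficiency E(t) over the unit learning interval."""
    return _sat_exp(t, rate_c)


def complexity_curve(e, curvature_ce: float):
    """Normalized complexity X(E) spent to support efficiency E.

    Same saturating-exponential family with a signed exponent
    k = 2 - 1/curvature_ce:

        X(E) = (1 - exp(-k E)) / (1 - exp(-k)),   X(E) = E when k = 0.

    curvature_ce < 1/2 gives k < 0: a convex path hugging the Pareto
    frontier (complexity deferred until efficiency is high);
    curvature_ce = 1/2 is the diagonal (constant resource rate);
    curvature_ce > 1/2 gives a concave path away from the frontier
    (complexity spent early). X is pointwise increasing in curvature_ce on
    (0, 1), so smaller curvature always means less complexity en route.
    """
    if curvature_ce <= 0:
        raise ValueError("curvature_ce must be positive")
    e = np.asarray(e, dtype=float)
    k = 2.0 - 1.0 / curvature_ce
    if abs(k) < 1e-12:
        return e if e.ndim else float(e)
    out = np.expm1(-k * e) / np.expm1(-k)
    return out if out.ndim else float(out)


def cumulative_complexity(scenario: ScenarioSpec, tol: float = 1e-8) -> float:
    """Integral of X(E(t)) over the unit learning interval (adaptive quadrature)."""
    val, _ = integrate.quad(
        lambda t: complexity_curve(efficiency_curve(t, scenario.rate_c),
                                   scenario.curvature_ce),
        0.0, 1.0, epsabs=tol, epsrel=tol, limit=200,
    )
    return float(val)


def rank_scenarios(
    curvatures=DEFAULT_CURVATURES,
    rates=DEFAULT_RATES,
) -> pd.DataFrame:
    """Rank scenarios by cumulative computational outlay, per rate curve.

    Rank 1 = least cumulative computation; ties broken by scenario order.
    """
    if len(curvatures) < 2:
        raise ValueError("need at least 2 scenarios to rank")
    rows = []
    for ri, rate in enumerate(rates):
        outlays = [cumulative_complexity(ScenarioSpec(rate, c)) for c in curvatures]
        order = np.argsort(np.asarray(outlays), kind="stable")
        ranks = np.empty(len(outlays), dtype=int)
        ranks[order] = np.arange(1, len(outlays) + 1)
        for si, (c, o) in enumerate(zip(curvatures, outlays)):
            rows.append({
                "rate_curve": f"E{ri + 1}", "rate_c": rate,
                "scenario": si + 1, "curvature_ce": c,
                "cumulative_complexity": o, "rank": int(ranks[si]),
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Monte-Carlo random-walk null test
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianStep:
    """Gaussian day-to-day complexity transition, fitted from data."""

    mean: float
    sd: float


def fit_day_transition_model(summaries: list[DailySummary]) -> GaussianStep:
    """Sample mean/sd of successive day-to-day changes in mean complexity."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 days to fit a transition model")
    path = np.asarray([s.mean_complexity for s in
                       sorted(summaries, key=lambda s: s.day)])
    steps = np.diff(path)
    return GaussianStep(mean=float(steps.mean()), sd=float(steps.std(ddof=1)))


@dataclass
class NullDistribution:
    """Per-walker average complexity under the random-walk null."""

    walker_mean_complexities: np.ndarray
    transition: GaussianStep
    n_walkers: int
    n_days: int
    start_complexity: float
    seed: int | None

    def summary(self) -> pd.DataFrame:
        m = self.walker_mean_complexities
        return pd.DataFrame([{
            "n_walkers": self.n_walkers, "n_days": self.n_days,
            "start_complexity": self.start_complexity,
            "step_mean": self.transition.mean, "step_sd": self.transition.sd,
            "null_mean": float(m.mean()), "null_sd": float(m.std(ddof=1)),
            "seed": self.seed,
        }])


def simulate_null_walkers(
    start_complexity: float,
    n_days: int,
    transition: GaussianStep,
    n_walkers: int = 5000,
    seed: int | None = None,
    clip: tuple[float, float] = COMPLEXITY_RANGE,
) -> NullDistribution:
    """Random walkers through complexity space, one Gaussian step per day.

    Walkers start at the observed day-1 complexity; each daily state is
    clipped to the attainable range (a walker cannot plan less than ten
    single-element chunks nor more than one whole-sequence chunk). The
    statistic kept per walker is its average complexity across days.
    """
    if n_days < 2:
        raise ValueError("need n_days >= 2")
    rng = np.random.default_rng(seed)
    steps = rng.normal(transition.mean, transition.sd, size=(n_walkers, n_days - 1))
    state = np.full(n_walkers, float(np.clip(start_complexity, *clip)))
    total = state.copy()
    for d in range(n_days - 1):
        state = np.clip(state + steps[:, d], *clip)
        total += state
    return NullDistribution(
        walker_mean_complexities=total / n_days,
        transition=transition, n_walkers=n_walkers, n_days=n_days,
        start_complexity=start_complexity, seed=seed,
    )


def percentile_score(observed, null: NullDistribution) -> float:
    """Percentile of the observed path's average complexity in the null.

    ``observed`` is the per-day mean-complexity path (or a list of
    DailySummary). Low percentile = the learner kept its cumulative
    complexity lower than random-walk learners: cost-effective.
    """
    if len(observed) and isinstance(observed[0], DailySummary):
        observed = [s.mean_complexity for s in sorted(observed, key=lambda s: s.day)]
    observed = np.asarray(observed, dtype=float)
    if observed.size != null.n_days:
        raise ValueError("observed path and null must cover the same days")
    stat = observed.mean()
    frac = np.mean(null.walker_mean_complexities < stat)
    return float(100.0 * frac)


# ----------------------------------------------------------------------
# degenerate-set efficiency trend (exponential mixed model)
# ----------------------------------------------------------------------

@dataclass
class TrendFit:
    """Shared exponential learning rate across degenerate sets.

    Model: squared_jerk = a_i * exp(b * repeat) * noise, fitted on the log
    scale as a linear mixed model with a per-set random intercept; b < 0
    means jerk decays (efficiency improves) with repeats.
    """

    amplitude: float
    rate_b: float
    rate_se: float
    z_statistic: float
    p_value: float
    set_offsets: dict = field(default_factory=dict)
    n_trials: int = 0
    n_sets: int = 0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "amplitude": self.amplitude, "rate_b": self.rate_b,
            "rate_se": self.rate_se, "z": self.z_statistic,
            "p_value": self.p_value, "n_trials": self.n_trials,
            "n_sets": self.n_sets,
        }])


def _trend_frame(trials: list[ScoredTrial], top_k: int, min_per_set: int) -> pd.DataFrame:
    df = pd.DataFrame({
        "signature": ["-".join(map(str, tr.structure.signature)) for tr in trials],
        "squared_jerk": [tr.squared_jerk for tr in trials],
        "order": [tr.trial_id for tr in trials],
    })
    df = df[df.squared_jerk > 0]
    counts = df.signature.value_counts()
    keep = counts.head(top_k)
    keep = keep[keep >= min_per_set]
    df = df[df.signature.isin(keep.index)].sort_values("order").copy()
    # repeats covariate: cumulative 0-based presentation index within each set
    df["repeat"] = df.groupby("signature").cumcount()
    return df


def fit_degenerate_trend(
    trials: list[ScoredTrial],
    top_k: int = 8,
    min_per_set: int = 10,
) -> TrendFit:
    """Fit the shared jerk-decay rate across the most frequent degenerate sets.

    Keeps the ``top_k`` most frequent degenerate sets (dropping any with
    fewer than ``min_per_set`` trials), fits log squared jerk against the
    within-set repeat index with a random intercept per set, and z-tests the
    fixed-effect rate b.
    """
    df = _trend_frame(trials, top_k, min_per_set)
    if df.signature.nunique() < 2:
        raise ValueError("need at least 2 degenerate sets with enough trials")
    df["log_jerk"] = np.log(df.squared_jerk)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("log_jerk ~ repeat", df, groups=df["signature"])
        res = model.fit(method="lbfgs", reml=True)
    b = float(res.params["repeat"])
    se = float(res.bse["repeat"])
    z = b / se
    p = 2.0 * stats.norm.sf(abs(z))
    try:
        offsets = {k: float(v.iloc[0]) for k, v in res.random_effects.items()}
    except (ValueError, np.linalg.LinAlgError):
        # random-effect variance collapsed to ~0; fall back to mean residuals
        resid = df.log_jerk - (res.params["Intercept"] + b * df["repeat"])
        offsets = resid.groupby(df.signature).mean().astype(float).to_dict()
    return TrendFit(
        amplitude=float(np.exp(res.params["Intercept"])),
        rate_b=b, rate_se=se, z_statistic=z, p_value=float(p),
        set_offsets=offsets, n_trials=len(df), n_sets=df.signature.nunique(),
    )


# ----------------------------------------------------------------------
# prevalence vs efficiency within degenerate sets
# ----------------------------------------------------------------------

def prevalence_efficiency_correlation(
    trials: list[ScoredTrial],
    landscape: list[TradeoffPoint],
    mode: str = "pooled",
) -> tuple[float, float]:
    """Do animals prefer the more efficient structures within a degenerate set?

    For every degenerate set with >= 2 member structures, the observed
    selection frequency of each member (zero for unselected members of sets
    that were visited) is compared with the member's model efficiency.

    mode="pooled" (default): frequencies and efficiencies are rank-
    transformed within each set, pooled across sets, and a single Spearman
    correlation computed. mode="per_set": one Spearman rho per set with >= 3
    members; returns the mean rho and a two-sided one-sample t-test of the
    per-set rhos against zero.
    """
    eff = {p.structure: p.efficiency for p in landscape}
    counts: dict[ChunkStructure, int] = {}
    for tr in trials:
        counts[tr.structure] = counts.get(tr.structure, 0) + 1
    sets: dict[tuple, list[ChunkStructure]] = {}
    for s in eff:
        sets.setdefault(s.signature, []).append(s)
    visited = {sig for sig, members in sets.items()
               if any(counts.get(m, 0) > 0 for m in members)}

    if mode == "pooled":
        freq_ranks, eff_ranks = [], []
        for sig in visited:
            members = sets[sig]
            if len(members) < 2:
                continue
            f = np.asarray([counts.get(m, 0) for m in members], dtype=float)
            e = np.asarray([eff[m] for m in members])
            freq_ranks.append(stats.rankdata(f) - (len(members) + 1) / 2)
            eff_ranks.append(stats.rankdata(e) - (len(members) + 1) / 2)
        if not freq_ranks:
            raise ValueError("no degenerate set with >= 2 members was visited")
        rho, p = stats.spearmanr(np.concatenate(freq_ranks),
                                 np.concatenate(eff_ranks))
        return float(rho), float(p)
    if mode == "per_set":
        rhos = []
        for sig in visited:
            members = sets[sig]
            if len(members) < 3:
                continue
            f = [counts.get(m, 0) for m in members]
            e = [eff[m] for m in members]
            if len(set(f)) < 2:
                continue
            rho, _ = stats.spearmanr(f, e)
            if np.isfinite(rho):
                rhos.append(rho)
        if len(rhos) < 2:
            raise ValueError("too few usable degenerate sets for per-set mode")
        t, p = stats.ttest_1samp(rhos, 0.0)
        return float(np.mean(rhos)), float(p)
    raise ValueError(f"unknown mode: {mode!r}")
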