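"""End-to-end orchestration: simulate, value, assess.

One experiment runs, per regime (clear-cut baseline plus the gap-cut grid):

1. *Simulate* stochastic stand trajectories in 5-year steps.  Each run
   starts from bare soil; a single stand-wide uniform draw per step decides
   cohort failures against their age-dependent (and, for sheltered cohorts,
   reduced) hazard rates; the deterministic management schedule (gap cut,
   thinnings, final harvest, replanting) is applied around the disturbance
   events; growth follows the yield table with competition modifiers.
   Draw streams are common random numbers: identical across regimes within
   a run.
2. *Value* the event stream into two provision series per run — net-revenue
   cash flows (EUR/ha) and gross carbon sequestration (tC/ha).
3. *Estimate* present values by the moving-window estimator and pool them
   by stand state; extract the SEV distribution from the bare-soil starts.
4. *Assess* resilience: thresholds from the baseline, per-event recovery
   times on the re-joined value paths, counterfactual pairing against the
   baseline, and the SEV-per-recovery-year trade-off tau.

Within a step the order of operations is: record the (pre-event) state,
resolve disturbance at start-of-step ages, apply scheduled management, then
grow the survivors over the step and advance ages.  Cash flows are booked
at the step in which they occur; the carbon of a step's growth is booked at
the end of the step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fixtures as fx
from .config import RunConfig
from .disturbance import (
    DrawStream,
    HazardReduction,
    HazardTable,
    WeibullSurvival,
    hazard_from_survival,
    make_draw_streams,
)
from .es_valuation import CarbonParams, ValuationParams, net_revenue, planting_cost
from .growth_yield import GrowthModifiers, GrowthTable, interpolate_young_ages
from .resilience import (
    Threshold,
    classify_disturbance,
    compute_threshold,
    match_counterfactual,
    tradeoff,
)
from .stand_model import (
    ORIGIN_GAP,
    ORIGIN_PLANTING,
    ORIGIN_SALVAGE,
    Regime,
    clearcut_baseline,
    enumerate_regimes,
)
from .value_estimation import (
    DiscountSpec,
    aggregate_by_state,
    collect_value_samples,
    sev_distribution,
)

__all__ = ["ParamSet", "RunTrajectory", "ExperimentResult", "load_params",
           "simulate_run", "simulate_regime", "run_experiment"]

logger = logging.getLogger("standres")

ES_NAMES = ("financial", "carbon")


@dataclass(frozen=True)
class ParamSet:
    """All model parameters of one experiment, resolved and ready to use."""

    hazard: HazardTable
    reduction: HazardReduction
    growth: GrowthTable  # young ages already interpolated
    modifiers: GrowthModifiers
    valuation: ValuationParams
    carbon: CarbonParams


def load_params(config: RunConfig) -> ParamSet:
    """Resolve parameter tables from the config paths, falling back to the
    shipped synthetic defaults."""
    if config.survival_yaml:
        survival, reduction = fx.load_survival_yaml(config.survival_yaml)
    else:
        survival, reduction = fx.default_survival_model(), fx.default_hazard_reduction()
    if config.growth_table_csv:
        growth = GrowthTable.from_csv(config.growth_table_csv)
    else:
        growth = fx.default_growth_table(config.rotation_years)
    growth = interpolate_young_ages(growth)
    if config.valuation_yaml:
        valuation, carbon = fx.load_valuation_yaml(config.valuation_yaml)
    else:
        valuation, carbon = fx.default_valuation_params(), fx.default_carbon_params()
    hazard = hazard_from_survival(
        survival, max_age=config.rotation_years, step_years=config.step_years
    )
    return ParamSet(
        hazard, reduction, growth, fx.default_growth_modifiers(), valuation, carbon
    )


@dataclass
class RunTrajectory:
    """Raw per-run simulation output on the time grid ``0..T`` (5-yr steps)."""

    times: np.ndarray
    lead_age: np.ndarray  # pre-event leading-cohort age, -1 for bare soil
    gap_age: np.ndarray  # pre-event younger-cohort age, -1 if absent
    cf: np.ndarray  # cash flow booked at each time (EUR/ha)
    carbon: np.ndarray  # carbon sequestration booked at each time (tC/ha)
    events: list[dict] = field(default_factory=list)


def simulate_run(
    regime: Regime,
    params: ParamSet,
    draws: np.ndarray,
    series_years: int,
    step_years: int = 5,
    zero_hazard: bool = False,
) -> RunTrajectory:
    """Simulate one run of one regime against one common draw stream."""
    n_times = series_years // step_years + 1
    if len(draws) < n_times:
        raise ValueError("draw stream shorter than the simulated series")
    rotation = regime.rotation_u
    gt = params.growth
    # Age-indexed lookup arrays (index = age // step).
    vol_t = gt.data["standing_volume"].to_numpy()
    thin_t = gt.data["thinning_removal"].to_numpy()
    dbh_t = gt.data["mean_dbh"].to_numpy()
    thin_dbh_t = gt.data["thinning_dbh"].to_numpy()
    hz_t = params.hazard.hz
    red = params.reduction
    mods = params.modifiers
    val = params.valuation
    conv = params.carbon.conversion_t_per_m3
    s_gap = regime.s_gap if regime.kind == "gapcut" else None
    age_gap = regime.age_gap if regime.kind == "gapcut" else None

    times = np.arange(n_times, dtype=np.int64) * step_years
    lead_age_rec = np.full(n_times, -1, dtype=np.int64)
    gap_age_rec = np.full(n_times, -1, dtype=np.int64)
    cf = np.zeros(n_times)
    carbon = np.zeros(n_times)
    events: list[dict] = []

    # Cohort state: parallel lists, index 0 = leading (older) cohort.
    ages: list[int] = []
    shares: list[float] = []
    origins: list[str] = []
    vols: list[float] = []  # effective standing volume, full-stocking basis
    thin_due: list[float] = []  # thinning volume to remove this step, full basis
    years_since_gap = math.inf

    def rank_and_merge() -> None:
        """Keep cohorts ordered oldest-first; merge equal ages."""
        if len(ages) == 2:
            if ages[0] == ages[1]:
                keep = 0 if shares[0] >= shares[1] else 1
                tot = shares[0] + shares[1]
                # Full-stocking quantities merge share-weighted.
                vols[keep] = (shares[0] * vols[0] + shares[1] * vols[1]) / tot
                thin_due[keep] = (
                    shares[0] * thin_due[0] + shares[1] * thin_due[1]
                ) / tot
                shares[keep] = tot
                for lst in (ages, shares, origins, vols, thin_due):
                    del lst[1 - keep]
            elif ages[0] < ages[1]:
                for lst in (ages, shares, origins, vols, thin_due):
                    lst.reverse()

    for i in range(n_times):
        t = int(times[i])
        # --- record pre-event state --------------------------------------
        if ages:
            lead_age_rec[i] = ages[0]
            if len(ages) == 2:
                gap_age_rec[i] = ages[1]
        # --- disturbance -------------------------------------------------
        y = draws[i]
        if ages and not zero_hazard:
            hazards = []
            for j in range(len(ages)):
                hz = hz_t[min(ages[j] // step_years, len(hz_t) - 1)]
                if j > 0:  # sheltered, non-leading cohort
                    hz *= red.factor(ages[0] - ages[j], shares[j])
                hazards.append(hz)
            failed = [j for j, hz in enumerate(hazards) if y <= hz]
            if failed:
                pre_lead, pre_gap = ages[0], (ages[1] if len(ages) == 2 else -1)
                dtype = classify_disturbance(
                    n_cohorts=len(ages),
                    lead_failed=0 in failed,
                    gap_failed=1 in failed,
                    lead_origin=origins[0],
                )
                events.append(
                    {
                        "run": -1,  # filled by the caller
                        "t": t,
                        "pre_lead_age": pre_lead,
                        "pre_gap_age": pre_gap,
                        "lead_failed": 0 in failed,
                        "gap_failed": 1 in failed,
                        "dtype": dtype,
                    }
                )
                for j in failed:
                    removed = shares[j] * vols[j]
                    dbh = dbh_t[min(ages[j] // step_years, len(dbh_t) - 1)]
                    cf[i] += net_revenue(removed, dbh, "salvage", val)
                    cf[i] -= planting_cost("salvage", val, shares[j])
                    ages[j] = 0
                    vols[j] = 0.0
                    thin_due[j] = 0.0
                    origins[j] = ORIGIN_SALVAGE
                if len(failed) == len(ages):
                    years_since_gap = math.inf  # stand-replacing: gap gone
                rank_and_merge()
        # --- scheduled management ---------------------------------------
        if not ages:
            # Bare soil: establish the stand.
            ages, shares, origins = [0], [1.0], [ORIGIN_PLANTING]
            vols, thin_due = [0.0], [0.0]
            cf[i] -= planting_cost("regular", val, 1.0)
        else:
            for j in range(len(ages)):
                if ages[j] >= rotation:
                    removed = shares[j] * vols[j]
                    dbh = dbh_t[min(ages[j] // step_years, len(dbh_t) - 1)]
                    cf[i] += net_revenue(removed, dbh, "harvest", val)
                    cf[i] -= planting_cost("regular", val, shares[j])
                    ages[j] = 0
                    vols[j] = 0.0
                    thin_due[j] = 0.0
                    origins[j] = ORIGIN_PLANTING
            rank_and_merge()
            if (
                len(ages) == 1
                and age_gap is not None
                and ages[0] == age_gap
            ):
                removed = s_gap * shares[0] * vols[0]
                dbh = dbh_t[min(ages[0] // step_years, len(dbh_t) - 1)]
                cf[i] += net_revenue(removed, dbh, "gap", val)
                cf[i] -= planting_cost("gap", val, s_gap * shares[0])
                new_share = s_gap * shares[0]
                shares[0] *= 1.0 - s_gap
                ages.append(0)
                shares.append(new_share)
                origins.append(ORIGIN_GAP)
                vols.append(0.0)
                thin_due.append(0.0)
                years_since_gap = 0.0
            else:
                for j in range(len(ages)):
                    if ages[j] > 0 and thin_due[j] > 0.0:
                        removed = shares[j] * thin_due[j]
                        dbh = thin_dbh_t[min(ages[j] // step_years, len(dbh_t) - 1)]
                        cf[i] += net_revenue(removed, dbh, "thinning", val)
                        vols[j] -= thin_due[j]
                        thin_due[j] = 0.0
        # --- growth over [t, t + step) -----------------------------------
        if i + 1 < n_times:
            two = len(ages) == 2
            for j in range(len(ages)):
                a = ages[j]
                idx0 = a // step_years
                idx1 = idx0 + 1
                base_inc = vol_t[idx1] - vol_t[idx0] + thin_t[idx1]
                m = 1.0
                if two:
                    if j > 0:
                        m = mods.suppression(ages[0] - a, shares[j])
                    elif years_since_gap < mods.accel_window and s_gap is not None:
                        m = mods.acceleration(s_gap, years_since_gap)
                inc = m * base_inc
                vols[j] += inc
                thin_due[j] = m * thin_t[idx1]
                carbon[i + 1] += conv * shares[j] * inc
            for j in range(len(ages)):
                ages[j] += step_years
            years_since_gap += step_years
            rank_and_merge()
        if abs(sum(shares) - 1.0) > 1e-9:
            raise RuntimeError(
                f"share conservation violated at t={t}: shares={shares}"
            )
    return RunTrajectory(times, lead_age_rec, gap_age_rec, cf, carbon, events)


@dataclass
class RegimeSimulation:
    """Stacked trajectories of all runs of one regime."""

    regime: Regime
    times: np.ndarray
    lead_age: np.ndarray  # (n_runs, n_times)
    gap_age: np.ndarray
    cf: np.ndarray
    carbon: np.ndarray
    events: pd.DataFrame  # run, t, pre-state, failed flags, dtype

    def state_keys(self) -> np.ndarray:
        return np.stack([self.lead_age, self.gap_age], axis=-1)


_EVENT_COLUMNS = [
    "run", "t", "pre_lead_age", "pre_gap_age", "lead_failed", "gap_failed", "dtype",
]


def simulate_regime(
    regime: Regime,
    params: ParamSet,
    streams: list[DrawStream],
    series_years: int,
    step_years: int = 5,
    zero_hazard: bool = False,
) -> RegimeSimulation:
    runs = []
    for stream in streams:
        traj = simulate_run(
            regime, params, stream.draws, series_years, step_years, zero_hazard
        )
        for ev in traj.events:
            ev["run"] = stream.run_id
        runs.append(traj)
    events = pd.DataFrame(
        [ev for traj in runs for ev in traj.events], columns=_EVENT_COLUMNS
    )
    logger.info(
        "regime %s: %d runs, %d disturbance events", regime.id, len(runs), len(events)
    )
    return RegimeSimulation(
        regime=regime,
        times=runs[0].times,
        lead_age=np.stack([r.lead_age for r in runs]),
        gap_age=np.stack([r.gap_age for r in runs]),
        cf=np.stack([r.cf for r in runs]),
        carbon=np.stack([r.carbon for r in runs]),
        events=events,
    )


def _value_paths(
    samples: pd.DataFrame, table: pd.DataFrame
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Re-join per-state mean values with the trajectories: for each run the
    value path over the truncated sample-time grid."""
    merged = samples.merge(
        table[["lead_age", "gap_age", "mean"]], on=["lead_age", "gap_age"], how="left"
    )
    if merged["mean"].isna().any():
        raise RuntimeError("state missing from the value table")
    paths = {}
    for run, df in merged.groupby("run"):
        df = df.sort_values("t")
        paths[int(run)] = (df["t"].to_numpy(float), df["mean"].to_numpy(float))
    return paths


@dataclass
class ExperimentResult:
    """Everything an experiment produces, ready for export or inspection."""

    config: RunConfig
    regimes: list[Regime]
    simulations: dict[str, RegimeSimulation]
    samples: dict[tuple[str, str], pd.DataFrame]  # (regime_id, es) -> samples
    value_tables: dict[tuple[str, str], pd.DataFrame]
    sev: dict[tuple[str, str], pd.DataFrame]
    thresholds: dict[str, Threshold]  # es -> baseline threshold
    records: dict[tuple[str, str], pd.DataFrame]  # paired recovery records
    summary: pd.DataFrame  # one row per (regime, es)


def run_experiment(config: RunConfig, zero_hazard: bool = False) -> ExperimentResult:
    """Execute the full pipeline for the baseline and every gap-cut regime."""
    params = load_params(config)
    baseline = clearcut_baseline(config.rotation_years)
    regimes = [baseline] + enumerate_regimes(
        config.gap_sizes, config.gap_ages, config.rotation_years
    )
    n_times = config.series_years // config.step_years + 1
    streams = make_draw_streams(config.n_runs, config.seed, n_times)
    specs = {
        "financial": DiscountSpec(config.rate_financial, config.horizon_years),
        "carbon": DiscountSpec(config.rate_carbon, config.horizon_years),
    }

    simulations: dict[str, RegimeSimulation] = {}
    samples: dict[tuple[str, str], pd.DataFrame] = {}
    value_tables: dict[tuple[str, str], pd.DataFrame] = {}
    sev: dict[tuple[str, str], pd.DataFrame] = {}
    paths: dict[tuple[str, str], dict[int, tuple[np.ndarray, np.ndarray]]] = {}

    for regime in regimes:
        sim = simulate_regime(
            regime, params, streams, config.series_years, config.step_years,
            zero_hazard=zero_hazard,
        )
        simulations[regime.id] = sim
        keys = sim.state_keys()
        for es, series in (("financial", sim.cf), ("carbon", sim.carbon)):
            smp = collect_value_samples(
                sim.times, series, keys, specs[es], config.step_years
            )
            samples[(regime.id, es)] = smp
            table = aggregate_by_state(smp, config.min_state_samples)
            value_tables[(regime.id, es)] = table
            sev[(regime.id, es)] = sev_distribution(smp)
            paths[(regime.id, es)] = _value_paths(smp, table)

    thresholds = {
        es: compute_threshold(samples[(baseline.id, es)]["value"], es)
        for es in ES_NAMES
    }

    # Events are assessable only while the truncated value path still has a
    # post-disturbance observation.
    t_max = config.series_years - config.horizon_years
    def assessable(events: pd.DataFrame) -> pd.DataFrame:
        return events.loc[events["t"] <= t_max - config.step_years]

    records: dict[tuple[str, str], pd.DataFrame] = {}
    rows = []
    base_events = assessable(simulations[baseline.id].events)
    for regime in regimes:
        sim = simulations[regime.id]
        ev = assessable(sim.events)
        type_counts = ev["dtype"].value_counts().to_dict()
        n_ev = int(len(ev))
        share_34 = (
            (type_counts.get(3, 0) + type_counts.get(4, 0)) / n_ev if n_ev else math.nan
        )
        for es in ES_NAMES:
            rec = match_counterfactual(
                ev,
                base_events,
                paths[(regime.id, es)],
                paths[(baseline.id, es)],
                thresholds[es].value,
                config.step_years,
            )
            records[(regime.id, es)] = rec
            trade = tradeoff(
                sev[(regime.id, es)]["value"],
                sev[(baseline.id, es)]["value"],
                rec,
                regime_id=regime.id,
                es=es,
            )
            own = rec.loc[rec["gap_failed"] & ~rec["censored"], "t_recov_gap"]
            rows.append(
                {
                    "regime": regime.id,
                    "es": es,
                    "s_gap": regime.s_gap,
                    "age_gap": regime.age_gap,
                    "sev_mean": float(sev[(regime.id, es)]["value"].mean()),
                    "sev_delta": trade.mean_sev_delta,
                    "mean_recovery_gain": trade.mean_recovery_gain,
                    "mean_own_recovery": float(own.mean()) if len(own) else math.nan,
                    "tau": trade.tau,
                    "dominant": trade.dominant,
                    "n_events": trade.n_events,
                    "n_censored": trade.n_censored,
                    "share_type_3_4": share_34,
                }
            )
    summary = pd.DataFrame(rows)
    return ExperimentResult(
        config=config,
        regimes=regimes,
        simulations=simulations,
        samples=samples,
        value_tables=value_tables,
        sev=sev,
        thresholds=thresholds,
        records=records,
        summary=summary,
    )
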