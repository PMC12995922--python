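"""Recovery-time resilience assessment and SEV trade-off analysis.

Resilience is read off the value paths: re-joining per-state mean values
with the simulated trajectories gives, for every run, a path of present
values over time.  A disturbance knocks the stand into a lower-valued state;
its *recovery time* is the time until the value path regains a reference
threshold, defined as the average value under the clear-cut baseline regime
(separately for the financial and the carbon ES).  Because the exact
crossing falls between grid points, it is interpolated linearly between the
two bracketing observations; an event whose path never regains the
threshold before the (truncated) series end is flagged censored and counted
but excluded from mean gains.

Disturbance events are classified into four types by the pre-disturbance
composition and the failing cohorts:

1. complete failure of a stand without regeneration (no gap cut yet);
2. complete failure of a two-cohort stand (regeneration present but lost);
3. failure of only the older cohort of a two-cohort stand;
4. failure of a leading cohort that itself originated as gap regeneration.

Common random numbers make every disturbance in the baseline an exact
counterfactual analogue of the same step under each gap-cut regime, so
recovery times can be compared event by event: the paired event set of a
run is the union of failure steps across the two regimes, and a regime
without its own failure at a paired step contributes the (possibly zero)
time its value path still needs to reach the threshold from that step.

The trade-off metric tau divides the mean SEV difference of a gap-cut
regime versus the baseline by its mean recovery-time gain: the SEV change
bought per year of average recovery-time reduction.  Non-negative tau marks
a *dominant* regime — better resilience at no performance cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Threshold",
    "TradeoffResult",
    "compute_threshold",
    "classify_disturbance",
    "recovery_time",
    "match_counterfactual",
    "tradeoff",
]

from .stand_model import ORIGIN_GAP


@dataclass(frozen=True)
class Threshold:
    """Recovery reference level: the average baseline value of one ES."""

    value: float
    es: str  # "financial" | "carbon"
    n_samples: int


def compute_threshold(baseline_values: Sequence[float], es: str = "financial") -> Threshold:
    """Average value under the clear-cut baseline over all runs and time
    steps (unweighted occupancy mean of the baseline value path)."""
    values = np.asarray(baseline_values, dtype=float)
    if values.size == 0:
        raise ValueError("no baseline values supplied")
    return Threshold(value=float(values.mean()), es=es, n_samples=int(values.size))


def classify_disturbance(
    n_cohorts: int,
    lead_failed: bool,
    gap_failed: bool,
    lead_origin: str,
) -> int:
    """Disturbance type from pre-state composition and failing cohorts.

    The partition is total on all failure combinations reachable under an
    age-increasing hazard with shared stand-wide draws (the younger,
    hazard-reduced cohort cannot fail alone); anything else raises.
    """
    if not (lead_failed or gap_failed):
        raise ValueError("classification requires at least one failed cohort")
    if n_cohorts == 1:
        if not lead_failed:
            raise ValueError("single-cohort stand can only lose its leading cohort")
        return 4 if lead_origin == ORIGIN_GAP else 1
    if lead_failed and gap_failed:
        return 2
    if lead_failed:
        return 4 if lead_origin == ORIGIN_GAP else 3
    raise ValueError(
        "gap cohort failed while the leading cohort survived — "
        "impossible under shared draws with reduced, age-increasing hazard"
    )


def recovery_time(
    times: Sequence[float],
    values: Sequence[float],
    threshold: float,
) -> tuple[float, bool]:
    """First threshold-crossing time of a post-disturbance value path.

    ``times`` are relative to the first post-disturbance observation (so
    ``times[0] == 0``); returns ``(t_recov, censored)``.  0 if the path
    already starts at or above the threshold; otherwise linear interpolation
    between the bracketing grid points; ``censored=True`` (with ``t = nan``)
    if no crossing occurs before the path ends.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("empty value path")
    if values[0] >= threshold:
        return 0.0, False
    above = np.nonzero(values >= threshold)[0]
    if above.size == 0:
        return math.nan, True
    j = int(above[0])
    t_lo, t_hi = times[j - 1], times[j]
    v_lo, v_hi = values[j - 1], values[j]
    t_rec = t_lo + (t_hi - t_lo) * (threshold - v_lo) / (v_hi - v_lo)
    return float(t_rec), False


def _path_recovery(
    path_times: np.ndarray,
    path_values: np.ndarray,
    event_time: float,
    threshold: float,
    step_years: int,
) -> tuple[float, bool]:
    """Recovery time measured from the first observation after the event.

    The state recorded at the event step still describes the pre-disturbance
    stand; the first grid point reflecting the disturbed composition is one
    step later, which serves as relative time zero of the recovery clock.
    """
    mask = path_times >= event_time + step_years
    if not mask.any():
        return math.nan, True
    rel_times = path_times[mask] - (event_time + step_years)
    return recovery_time(rel_times, path_values[mask], threshold)


def match_counterfactual(
    gap_events: pd.DataFrame,
    base_events: pd.DataFrame,
    gap_paths: dict[int, tuple[np.ndarray, np.ndarray]],
    base_paths: dict[int, tuple[np.ndarray, np.ndarray]],
    threshold: float,
    step_years: int = 5,
) -> pd.DataFrame:
    """Pair disturbance events across a gap-cut regime and the baseline.

    ``*_events`` carry columns ``run, t`` (plus ``dtype`` for the gap
    regime); ``*_paths`` map run id to ``(times, values)`` value paths built
    from the same common-random-number draws.  For every (run, step) at
    which either regime registers a failure, both recovery times are
    measured from that step; the gain is baseline minus gap-cut time.
    Events too close to the truncated path end to observe any
    post-disturbance value, and pairs with a censored side, are flagged.
    """
    if set(gap_paths) != set(base_paths):
        raise ValueError("regime and baseline were simulated with different runs")
    gap_by_run = {run: set(ts) for run, ts in gap_events.groupby("run")["t"]}
    dtype_lookup = (
        gap_events.set_index(["run", "t"])["dtype"].to_dict()
        if "dtype" in gap_events.columns
        else {}
    )
    base_by_run = {run: set(ts) for run, ts in base_events.groupby("run")["t"]}
    records = []
    for run in sorted(base_paths):
        event_times = sorted(gap_by_run.get(run, set()) | base_by_run.get(run, set()))
        g_times, g_vals = gap_paths[run]
        b_times, b_vals = base_paths[run]
        for t in event_times:
            t_gap, c_gap = _path_recovery(g_times, g_vals, t, threshold, step_years)
            t_base, c_base = _path_recovery(b_times, b_vals, t, threshold, step_years)
            censored = c_gap or c_base
            records.append(
                {
                    "run": run,
                    "t": t,
                    "dtype": dtype_lookup.get((run, t), 0),
                    "gap_failed": t in gap_by_run.get(run, set()),
                    "base_failed": t in base_by_run.get(run, set()),
                    "t_recov_gap": t_gap,
                    "t_recov_base": t_base,
                    "censored": censored,
                    "gain": (t_base - t_gap) if not censored else math.nan,
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "run",
            "t",
            "dtype",
            "gap_failed",
            "base_failed",
            "t_recov_gap",
            "t_recov_base",
            "censored",
            "gain",
        ],
    )


@dataclass(frozen=True)
class TradeoffResult:
    """SEV-versus-resilience trade-off of one gap-cut regime."""

    regime_id: str
    es: str
    mean_sev_delta: float  # mean SEV(gap) - mean SEV(baseline)
    mean_recovery_gain: float  # mean over paired, uncensored events (years)
    tau: float  # SEV change per year of recovery-time reduction
    dominant: bool  # tau >= 0: resilience gain at no performance cost
    n_events: int
    n_censored: int


def tradeoff(
    regime_sevs: Sequence[float],
    baseline_sevs: Sequence[float],
    records: pd.DataFrame,
    regime_id: str = "",
    es: str = "financial",
) -> TradeoffResult:
    """Trade-off metric tau = mean SEV difference / mean recovery gain.

    Undefined (nan, non-dominant) when the mean recovery gain is zero.
    Censored event pairs are excluded from the mean gain but counted.
    """
    sev_delta = float(np.mean(regime_sevs) - np.mean(baseline_sevs))
    ok = records.loc[~records["censored"], "gain"]
    n_censored = int(records["censored"].sum())
    if len(ok) == 0:
        mean_gain = math.nan
    else:
        mean_gain = float(ok.mean())
    if not math.isfinite(mean_gain) or mean_gain == 0.0:
        tau_val = math.nan
        dominant = False
    else:
        tau_val = sev_delta / mean_gain
        dominant = tau_val >= 0.0
    return TradeoffResult(
        regime_id=regime_id,
        es=es,
        mean_sev_delta=sev_delta,
        mean_recovery_gain=mean_gain,
        tau=tau_val,
        dominant=dominant,
        n_events=int(len(records)),
        n_censored=n_censored,
    )
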