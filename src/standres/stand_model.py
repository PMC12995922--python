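"""Domain types for management regimes, cohorts and stand states.

A stand is managed under a *regime*: either the even-aged clear-cut baseline
(plant, thin, harvest at rotation age, replant) or a gap-cut regime that
additionally removes a canopy share ``s_gap`` at stand age ``age_gap`` to
establish a second, younger regeneration cohort.  The stand state is the
discrete cohort composition — at most two age-homogeneous cohorts, each with
an area share — which together with the regime id keys every present-value
estimate downstream.

This module also contains the deterministic management scheduler: which
actions (gap cut, thinning, final harvest, replanting) a regime prescribes
for a given state, and how actions transform states.  Stochastic disturbance
is layered on top by :mod:`standres.disturbance` and
:mod:`standres.pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "STEP_YEARS",
    "Regime",
    "Cohort",
    "StandState",
    "ManagementAction",
    "clearcut_baseline",
    "enumerate_regimes",
    "scheduled_actions",
    "apply_action",
    "advance_one_step",
    "enumerate_reachable_states",
]

#: Internal time resolution of the whole framework (years).  Ages are stored
#: in years but are always multiples of this step.
STEP_YEARS = 5

# Cohort origins
ORIGIN_PLANTING = "planting"
ORIGIN_GAP = "gap_regeneration"
ORIGIN_SALVAGE = "salvage_replant"
_ORIGINS = (ORIGIN_PLANTING, ORIGIN_GAP, ORIGIN_SALVAGE)

_SHARE_TOL = 1e-9


@dataclass(frozen=True)
class Regime:
    """A management rule: clear-cut baseline or a gap-cut variant.

    Parameters
    ----------
    id
        Stable label, e.g. ``"clearcut"`` or ``"gap_s0.30_a40"``.
    kind
        ``"clearcut"`` or ``"gapcut"``.
    s_gap
        Canopy share removed at the gap cut (0 < s_gap < 1); gap-cut only.
    age_gap
        Stand age of the gap cut in years (0 < age_gap < rotation); gap-cut
        only.
    rotation_u
        Rotation age in years at which any cohort is finally harvested.
    """

    id: str
    kind: str
    s_gap: Optional[float] = None
    age_gap: Optional[int] = None
    rotation_u: int = 85

    def __post_init__(self) -> None:
        if self.kind not in ("clearcut", "gapcut"):
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if self.rotation_u <= 0 or self.rotation_u % STEP_YEARS:
            raise ValueError("rotation_u must be a positive multiple of the step")
        if self.kind == "clearcut":
            if self.s_gap is not None or self.age_gap is not None:
                raise ValueError("clearcut regime must not set s_gap/age_gap")
        else:
            if self.s_gap is None or not 0.0 < self.s_gap < 1.0:
                raise ValueError("gapcut requires 0 < s_gap < 1")
            if self.age_gap is None or not 0 < self.age_gap < self.rotation_u:
                raise ValueError("gapcut requires 0 < age_gap < rotation_u")
            if self.age_gap % STEP_YEARS:
                raise ValueError("age_gap must be a multiple of the step")


@dataclass(frozen=True)
class Cohort:
    """An age-homogeneous stand portion.

    ``age`` in years (multiple of the step), ``share`` the occupied area
    fraction, ``origin`` how the cohort came to be, ``leading`` whether this
    is the (older) leading cohort.
    """

    age: int
    share: float
    origin: str = ORIGIN_PLANTING
    leading: bool = True

    def __post_init__(self) -> None:
        if self.age < 0 or self.age % STEP_YEARS:
            raise ValueError("cohort age must be a non-negative multiple of the step")
        if not 0.0 < self.share <= 1.0 + _SHARE_TOL:
            raise ValueError("cohort share must lie in (0, 1]")
        if self.origin not in _ORIGINS:
            raise ValueError(f"unknown cohort origin {self.origin!r}")


@dataclass(frozen=True)
class StandState:
    """Discrete cohort composition of a stand under a regime.

    At most two cohorts; exactly one is leading (the older; equal ages are
    merged).  An empty cohort tuple represents bare forest soil.  Shares of a
    complete state sum to 1; transient states produced while applying an
    action list (e.g. after a final harvest, before the paired replanting)
    may sum to less.
    """

    cohorts: tuple[Cohort, ...]
    regime_id: str = ""

    def __post_init__(self) -> None:
        if len(self.cohorts) > 2:
            raise ValueError("at most 2 simultaneous cohorts are supported")
        if self.cohorts:
            total = sum(c.share for c in self.cohorts)
            if total > 1.0 + 1e-6:
                raise ValueError(f"cohort shares sum to {total} > 1")
            leaders = [c for c in self.cohorts if c.leading]
            if len(leaders) != 1:
                raise ValueError("exactly one cohort must be leading")
            if len(self.cohorts) == 2:
                lead = leaders[0]
                other = next(c for c in self.cohorts if not c.leading)
                if lead.age <= other.age:
                    raise ValueError("leading cohort must be strictly older")

    @property
    def leading_cohort(self) -> Optional[Cohort]:
        for c in self.cohorts:
            if c.leading:
                return c
        return None

    @property
    def gap_cohort(self) -> Optional[Cohort]:
        for c in self.cohorts:
            if not c.leading:
                return c
        return None

    @property
    def leading_age(self) -> Optional[int]:
        c = self.leading_cohort
        return None if c is None else c.age

    @property
    def gap_age(self) -> Optional[int]:
        c = self.gap_cohort
        return None if c is None else c.age

    def key(self) -> tuple[str, int, int]:
        """Canonical aggregation key ``(regime_id, leading_age, gap_age)``.

        Bare soil is encoded as ``(-1, -1)``; a missing gap cohort as
        gap_age ``-1``.
        """
        la = self.leading_age
        ga = self.gap_age
        return (self.regime_id, -1 if la is None else la, -1 if ga is None else ga)

    def share_total(self) -> float:
        return sum(c.share for c in self.cohorts)


@dataclass(frozen=True)
class ManagementAction:
    """A single scheduled management event.

    ``kind`` is one of ``gap_cut``, ``thinning``, ``final_harvest``,
    ``salvage``, ``replant``.  ``cohort_index`` addresses the target cohort
    in the state's tuple (``-1`` for replanting onto vacated area).  For
    ``gap_cut`` the removed canopy share is carried in ``share``; for
    ``replant`` the planted area share and origin are carried.
    """

    kind: str
    cohort_index: int = 0
    share: Optional[float] = None
    origin: str = ORIGIN_PLANTING

    _KINDS = ("gap_cut", "thinning", "final_harvest", "salvage", "replant")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown action kind {self.kind!r}")


def clearcut_baseline(rotation_u: int = 85) -> Regime:
    """The even-aged clear-cut baseline regime."""
    return Regime(id="clearcut", kind="clearcut", rotation_u=rotation_u)


def enumerate_regimes(
    sizes: Sequence[float],
    ages: Sequence[int],
    rotation_u: int = 85,
) -> list[Regime]:
    """Build the gap-cut regime grid: the Cartesian product of gap sizes and
    gap ages, in stable (size-major, ascending) order with unique ids.

    The clear-cut baseline is *not* included; append it separately via
    :func:`clearcut_baseline`.  Duplicate grid entries are rejected.
    """
    sizes = list(sizes)
    ages = list(ages)
    if len(set(sizes)) != len(sizes):
        raise ValueError(f"duplicate gap sizes in grid: {sizes}")
    if len(set(ages)) != len(ages):
        raise ValueError(f"duplicate gap ages in grid: {ages}")
    regimes = []
    for s in sorted(sizes):
        for a in sorted(ages):
            regimes.append(
                Regime(
                    id=f"gap_s{s:.2f}_a{a}",
                    kind="gapcut",
                    s_gap=float(s),
                    age_gap=int(a),
                    rotation_u=rotation_u,
                )
            )
    return regimes


def scheduled_actions(state: StandState, regime: Regime) -> list[ManagementAction]:
    """Deterministic management schedule for ``state`` under ``regime``.

    Rules (total on valid states):

    * bare soil -> replant the whole area;
    * any cohort at rotation age -> final harvest plus immediate replanting
      of the vacated share;
    * a single cohort at exactly ``age_gap`` under a gap-cut regime -> gap
      cut establishing a regeneration cohort of share ``s_gap``;
    * every other cohort older than 0 -> thinning per the yield table (the
      removed volume is resolved by the growth module; the table may
      prescribe zero removal at some ages).
    """
    if not state.cohorts:
        return [ManagementAction("replant", -1, share=1.0, origin=ORIGIN_PLANTING)]
    actions: list[ManagementAction] = []
    single = len(state.cohorts) == 1
    for i, cohort in enumerate(state.cohorts):
        if cohort.age >= regime.rotation_u:
            actions.append(ManagementAction("final_harvest", i))
            actions.append(
                ManagementAction("replant", -1, share=cohort.share, origin=ORIGIN_PLANTING)
            )
        elif (
            single
            and regime.kind == "gapcut"
            and cohort.age == regime.age_gap
        ):
            actions.append(ManagementAction("gap_cut", i, share=regime.s_gap))
        elif cohort.age > 0:
            actions.append(ManagementAction("thinning", i))
    return actions


def _merge_and_rank(cohorts: Iterable[Cohort]) -> tuple[Cohort, ...]:
    """Merge equal-age cohorts and (re)assign the leading flag to the oldest."""
    by_age: dict[int, Cohort] = {}
    for c in cohorts:
        if c.age in by_age:
            prev = by_age[c.age]
            # Merged cohort keeps the origin of the larger share.
            origin = prev.origin if prev.share >= c.share else c.origin
            by_age[c.age] = Cohort(c.age, prev.share + c.share, origin, leading=False)
        else:
            by_age[c.age] = replace(c, leading=False)
    ordered = sorted(by_age.values(), key=lambda c: -c.age)
    if not ordered:
        return ()
    ordered[0] = replace(ordered[0], leading=True)
    return tuple(ordered)


def apply_action(state: StandState, action: ManagementAction) -> StandState:
    """Apply one management action, returning the new state.

    Shares are conserved across a full scheduled action list (a
    ``final_harvest`` leaves a transient deficit that the paired ``replant``
    fills).  Replanted cohorts start at age 0; equal-age cohorts merge.
    """
    cohorts = list(state.cohorts)
    if action.kind == "replant":
        share = action.share
        if share is None or share <= 0:
            raise ValueError("replant requires a positive share")
        new = Cohort(0, share, action.origin, leading=False)
        merged = _merge_and_rank(cohorts + [new])
        return StandState(merged, state.regime_id)
    if action.cohort_index < 0 or action.cohort_index >= len(cohorts):
        raise ValueError(f"action targets missing cohort {action.cohort_index}")
    target = cohorts[action.cohort_index]
    if action.kind == "thinning":
        return state  # composition unchanged; volumes handled by growth module
    if action.kind == "gap_cut":
        if len(cohorts) != 1:
            raise ValueError("gap_cut requires a single-cohort stand")
        s = action.share
        if s is None or not 0.0 < s < 1.0:
            raise ValueError("gap_cut requires 0 < share < 1")
        remaining = Cohort(target.age, target.share * (1.0 - s), target.origin, True)
        regen = Cohort(0, target.share * s, ORIGIN_GAP, False)
        return StandState(_merge_and_rank([remaining, regen]), state.regime_id)
    if action.kind in ("final_harvest", "salvage"):
        del cohorts[action.cohort_index]
        return StandState(_merge_and_rank(cohorts), state.regime_id)
    raise ValueError(f"unknown action kind {action.kind!r}")


def advance_one_step(state: StandState, regime: Regime) -> StandState:
    """One zero-hazard step: apply the schedule, then age cohorts by 5 years.

    Used for deterministic trajectories and reachable-state enumeration; the
    stochastic pipeline interleaves disturbance draws with the same schedule.
    """
    for action in scheduled_actions(state, regime):
        state = apply_action(state, action)
    aged = [replace(c, age=c.age + STEP_YEARS) for c in state.cohorts]
    return StandState(_merge_and_rank(aged), state.regime_id)


def enumerate_reachable_states(
    regime: Regime, max_steps: int = 10_000
) -> set[tuple[str, int, int]]:
    """Breadth-first closure of the zero-hazard step map from bare soil.

    Returns canonical state keys.  The reachable space under a fixed regime
    and 5-year steps is finite (the step map is deterministic, so this is a
    single cycle detection); ``max_steps`` guards against a non-terminating
    schedule bug.
    """
    state = StandState((), regime.id)
    seen: set[tuple[str, int, int]] = set()
    for _ in range(max_steps):
        key = state.key()
        if key in seen:
            return seen
        seen.add(key)
        state = advance_one_step(state, regime)
    raise RuntimeError("state space did not close within max_steps")
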