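"""Valuation of trajectory events: net-revenue cash flows and carbon uptake.

Every removal (thinning, final harvest, gap cut, salvage logging) is valued
as ``volume * (price(dbh) - cost(dbh))`` with DBH-dependent timber price and
harvest cost functions (EUR/m3).  Salvage logging after a disturbance sells
at a degraded price (factor 0.74 of the regular price) and incurs elevated
logging costs (factor 1.15), reflecting quality losses and regional
oversupply after damage events.  Planting costs are fixed per hectare and
scaled by the replanted area share: 2000 EUR/ha after regular harvests,
doubled (4000) after salvage loggings (harder site conditions), and halved
(1000) within gap cuts where natural regeneration replaces roughly half of
the artificial planting.

The shipped price/cost functional forms are synthetic package defaults — an
increasing, saturating price in DBH and a mechanized-to-motor-manual cost
shape — and are fully pluggable via configuration; only the baseline price
(92.47 EUR/m3 for the reference assortment) and the salvage/planting factors
above are fixed domain constants.

Aboveground carbon sequestration is the gross stem-volume increment of each
step converted to carbon mass: wood density 410 kg/m3 times a carbon
fraction of 0.5 kgC/kg gives 205 kgC per m3 of volume growth (0.205 tC/m3).
Harvests and disturbances do not create negative sequestration in the
default gross mode; an optional net mode (debiting removed stock) exists for
sensitivity analyses but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

__all__ = [
    "ValuationParams",
    "CarbonParams",
    "StepEvent",
    "default_price_fn",
    "default_cost_fn",
    "net_revenue",
    "planting_cost",
    "cash_flow_at_step",
    "carbon_at_step",
]

#: Removal contexts understood by :func:`net_revenue`.
CONTEXTS = ("thinning", "harvest", "gap", "salvage")
#: Planting contexts understood by :func:`planting_cost`.
PLANT_CONTEXTS = ("regular", "salvage", "gap")


def default_price_fn(dbh: float, base_price: float = 92.47) -> float:
    """Synthetic timber price (EUR/m3), increasing and saturating in DBH.

    Anchored at ``base_price`` for the reference assortment (DBH >= 45 cm).
    A package default, not an empirical price system.
    """
    return base_price * (0.3 + 0.7 * min(dbh, 45.0) / 45.0)


def default_cost_fn(dbh: float) -> float:
    """Synthetic harvest cost (EUR/m3): cheap mechanized harvesting at small
    to medium DBH, rising motor-manual costs beyond 45 cm.  A package
    default, not an empirical cost system."""
    return 45.0 - 0.4 * min(dbh, 45.0) + 0.012 * max(0.0, dbh - 45.0) ** 2


@dataclass(frozen=True)
class ValuationParams:
    """Prices, costs and planting-cost constants for the financial ES."""

    base_price: float = 92.47
    salvage_price_factor: float = 0.74
    salvage_cost_factor: float = 1.15
    planting_cost_regular: float = 2000.0
    planting_cost_salvage: float = 4000.0
    planting_cost_gap: float = 1000.0
    price_fn: Callable[[float], float] = default_price_fn
    cost_fn: Callable[[float], float] = default_cost_fn

    def __post_init__(self) -> None:
        if self.salvage_price_factor >= 1.0 or self.salvage_cost_factor <= 1.0:
            raise ValueError(
                "salvage must degrade price (< 1) and inflate cost (> 1)"
            )
        if not (
            0
            < self.planting_cost_gap
            < self.planting_cost_regular
            < self.planting_cost_salvage
        ):
            raise ValueError("planting costs must satisfy gap < regular < salvage")


@dataclass(frozen=True)
class CarbonParams:
    """Volume-to-carbon conversion constants.

    ``conversion_t_per_m3`` must equal density times carbon fraction
    (checked at construction): 410 kg/m3 * 0.5 kgC/kg = 205 kgC/m3.
    """

    wood_density_kg_m3: float = 410.0
    carbon_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.wood_density_kg_m3 <= 0 or not 0 < self.carbon_fraction < 1:
            raise ValueError("invalid carbon parameters")

    @property
    def conversion_kg_per_m3(self) -> float:
        return self.wood_density_kg_m3 * self.carbon_fraction

    @property
    def conversion_t_per_m3(self) -> float:
        return self.conversion_kg_per_m3 / 1000.0


def net_revenue(
    volume: float, dbh: float, context: str, params: ValuationParams
) -> float:
    """Net revenue (EUR per stand hectare) of a removal.

    ``volume * (price(dbh) - cost(dbh))``; the ``salvage`` context degrades
    the price by the salvage price factor and inflates the cost by the
    salvage cost factor.
    """
    if volume < 0:
        raise ValueError("removal volume must be non-negative")
    if context not in CONTEXTS:
        raise ValueError(f"unknown removal context {context!r}")
    price = params.price_fn(dbh)
    cost = params.cost_fn(dbh)
    if context == "salvage":
        price *= params.salvage_price_factor
        cost *= params.salvage_cost_factor
    return volume * (price - cost)


def planting_cost(context: str, params: ValuationParams, share: float = 1.0) -> float:
    """Planting cost (EUR per stand hectare) scaled by the replanted share."""
    if context not in PLANT_CONTEXTS:
        raise ValueError(f"unknown planting context {context!r}")
    if not 0.0 <= share <= 1.0:
        raise ValueError("replanted share must lie in [0, 1]")
    cost = {
        "regular": params.planting_cost_regular,
        "salvage": params.planting_cost_salvage,
        "gap": params.planting_cost_gap,
    }[context]
    return cost * share


@dataclass(frozen=True)
class StepEvent:
    """One valued event within a trajectory step.

    ``kind`` is a removal context (``thinning``/``harvest``/``gap``/
    ``salvage``) with ``volume``/``dbh`` set, or ``plant_<context>`` with
    ``share`` set.
    """

    kind: str
    volume: float = 0.0
    dbh: float = 0.0
    share: float = 1.0


def cash_flow_at_step(events: Iterable[StepEvent], params: ValuationParams) -> float:
    """Cash flow of one trajectory step: the sum over all cohorts of net
    revenues from thinnings, final harvests, gap cuts and salvage loggings,
    minus all planting costs incurred at that step."""
    cf = 0.0
    for ev in events:
        if ev.kind in CONTEXTS:
            cf += net_revenue(ev.volume, ev.dbh, ev.kind, params)
        elif ev.kind.startswith("plant_"):
            cf -= planting_cost(ev.kind.removeprefix("plant_"), params, ev.share)
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return cf


def carbon_at_step(volume_increment: float, params: CarbonParams) -> float:
    """Aboveground carbon sequestration (tC per stand hectare) of one step's
    gross volume increment."""
    if volume_increment < 0:
        raise ValueError("gross volume increment must be non-negative")
    return volume_increment * params.conversion_t_per_m3
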