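"""Synthetic but structurally faithful parameter tables.

The framework is parameterized by three external inputs that are site- and
literature-specific: a survival function, a yield table and a timber
price/cost system.  This module generates a self-contained synthetic bundle
with the right structure and qualitative behaviour, so the full pipeline
runs without any download:

* survival: Weibull (scale 90 a, shape 2.75) — monotone decreasing survival
  with a steeply age-increasing hazard, the regime typical of storm-driven
  spruce mortality under a hot climate; roughly half of all stands are
  disturbed within an 85-year rotation;
* growth: a Chapman-Richards-type volume curve
  ``V(a) = Vmax * (1 - exp(-k a)) ** p`` (Vmax = 900 m3/ha, k = 0.025,
  p = 3), linear mean DBH 0 -> 45 cm over 0 -> 85 a, and thinning removals
  as a fraction of the step's gross increment declining from 0.4 at young
  ages to 0.1 near rotation (first thinning at age 20, none at rotation);
* valuation: the DBH-dependent default price/cost shapes of
  :mod:`standres.es_valuation` with the 92.47 EUR/m3 reference price.

All values are deterministic analytic defaults (the ``seed`` argument is
accepted for interface symmetry but the tables involve no randomness); they
are *synthetic* stand-ins for empirical parameterizations, not empirical
values themselves.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .disturbance import HazardReduction, WeibullSurvival
from .es_valuation import CarbonParams, ValuationParams
from .growth_yield import GrowthModifiers, GrowthTable
from .stand_model import STEP_YEARS

__all__ = [
    "default_survival_model",
    "default_hazard_reduction",
    "default_growth_table",
    "default_growth_modifiers",
    "default_valuation_params",
    "default_carbon_params",
    "generate_fixtures",
    "load_survival_yaml",
    "load_valuation_yaml",
]


def default_survival_model() -> WeibullSurvival:
    # Shape 2.75 follows published Weibull fits for Norway spruce stand
    # survival; scale 90 places cumulative rotation-age risk in the high
    # range expected under the hot-climate conditions this setting targets.
    return WeibullSurvival(scale=90.0, shape=2.75)


def default_hazard_reduction() -> HazardReduction:
    return HazardReduction()


def default_growth_modifiers() -> GrowthModifiers:
    return GrowthModifiers()


def default_valuation_params() -> ValuationParams:
    return ValuationParams()


def default_carbon_params() -> CarbonParams:
    return CarbonParams()


def _potential_volume(age: np.ndarray) -> np.ndarray:
    """Chapman-Richards-type cumulative gross volume production (m3/ha)."""
    return 900.0 * (1.0 - np.exp(-0.025 * age)) ** 3


def default_growth_table(rotation_years: int = 85) -> GrowthTable:
    """Synthetic yield table on ages 15..rotation, young ages not yet filled
    (apply :func:`standres.growth_yield.interpolate_young_ages`)."""
    ages = np.arange(0, rotation_years + STEP_YEARS, STEP_YEARS)
    vp = _potential_volume(ages)
    gross_inc = np.diff(vp, prepend=0.0)
    # Thinning fraction of the step's increment: 0.4 young -> 0.1 old,
    # no thinning before age 20 or at rotation age.
    frac = 0.4 - 0.3 * ages / rotation_years
    thin = frac * gross_inc
    thin[ages < 20] = 0.0
    thin[ages >= rotation_years] = 0.0
    standing = vp - np.cumsum(thin)
    dbh = 45.0 * ages / 85.0
    df = pd.DataFrame(
        {
            "age": ages,
            "standing_volume": standing,
            "mean_dbh": dbh,
            "thinning_removal": thin,
            "thinning_dbh": 0.8 * dbh,
        }
    )
    df = df[df["age"] >= 15].reset_index(drop=True)
    return GrowthTable(df)


def load_survival_yaml(path) -> tuple[WeibullSurvival, HazardReduction]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    surv = WeibullSurvival(**raw["survival"])
    red = HazardReduction(**raw.get("hazard_reduction", {}))
    return surv, red


def load_valuation_yaml(path) -> tuple[ValuationParams, CarbonParams]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    val = ValuationParams(**raw.get("valuation", {}))
    carbon = CarbonParams(**raw.get("carbon", {}))
    return val, carbon


def generate_fixtures(outdir, seed: int = 0) -> dict[str, Path]:
    """Write the synthetic parameter bundle (growth CSV, survival YAML,
    valuation YAML) to ``outdir``; deterministic for any seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "growth_table": outdir / "growth_table.csv",
        "survival": outdir / "survival.yaml",
        "valuation": outdir / "valuation.yaml",
    }
    default_growth_table().to_csv(paths["growth_table"])
    surv = default_survival_model()
    with open(paths["survival"], "w") as fh:
        yaml.safe_dump(
            {
                "survival": asdict(surv),
                "hazard_reduction": asdict(default_hazard_reduction()),
            },
            fh,
            sort_keys=False,
        )
    val = default_valuation_params()
    with open(paths["valuation"], "w") as fh:
        yaml.safe_dump(
            {
                "valuation": {
                    k: v
                    for k, v in asdict(val).items()
                    if not callable(getattr(val, k))
                },
                "carbon": asdict(default_carbon_params()),
            },
            fh,
            sort_keys=False,
        )
    return paths
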