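"""Demographic strata for the simulated Indian adult population.

The national population aged 25-65 is partitioned into 24 cells by age band
(25-44 / 45-65 years), sex, urban/rural location, and income tertile of the
standard of living index.  Every simulated person belongs to exactly one
stratum, and national population weights (in millions of persons) attach to
strata, not individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

import pandas as pd

AGE_BANDS = ("25-44", "45-65")
SEXES = ("male", "female")
LOCATIONS = ("urban", "rural")
INCOMES = ("low", "mid", "high")

#: Age range (years) covered by each band, used when drawing continuous ages.
AGE_RANGES = {"25-44": (25.0, 45.0), "45-65": (45.0, 65.0)}


@dataclass(frozen=True, order=True)
class StratumKey:
    """One age x sex x location x income cell."""

    age_band: str
    sex: str
    location: str
    income: str

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.income not in INCOMES:
            raise ValueError(f"unknown income tertile {self.income!r}")


def all_strata() -> tuple[StratumKey, ...]:
    """The 24 strata in a fixed, deterministic order."""
    return tuple(
        StratumKey(a, s, l, i)
        for a, s, l, i in product(AGE_BANDS, SEXES, LOCATIONS, INCOMES)
    )


# Default marginal shares: mild urban minority, equal sexes, income tertiles
# equal by construction; the younger band holds the larger share of adults
# aged 25-65.  Marginals are combined independently across families.
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "age_band": {"25-44": 0.58, "45-65": 0.42},
    "sex": {"male": 0.5, "female": 0.5},
    "location": {"urban": 1.0 / 3.0, "rural": 2.0 / 3.0},
    "income": {"low": 1.0 / 3.0, "mid": 1.0 / 3.0, "high": 1.0 / 3.0},
}


class DemographicTable:
    """Population weights (millions of persons) for the 24 strata."""

    def __init__(self, weights: Mapping[StratumKey, float]):
        strata = all_strata()
        missing = [k for k in strata if k not in weights]
        if missing:
            raise ValueError(f"weights missing for {len(missing)} strata")
        for key, w in weights.items():
            if w < 0:
                raise ValueError(f"negative weight {w} for stratum {key}")
        self.weights: dict[StratumKey, float] = {k: float(weights[k]) for k in strata}

    @property
    def total_population(self) -> float:
        return sum(self.weights.values())

    def shares(self) -> dict[StratumKey, float]:
        tot = self.total_population
        return {k: w / tot for k, w in self.weights.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "age_band": k.age_band,
                "sex": k.sex,
                "location": k.location,
                "income": k.income,
                "weight_millions": w,
            }
            for k, w in self.weights.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DemographicTable":
        weights = {
            StratumKey(r.age_band, r.sex, r.location, r.income): float(r.weight_millions)
            for r in df.itertuples()
        }
        return cls(weights)


def make_demographics(
    total_millions: float,
    stratum_shares: Mapping[StratumKey, float] | str = "default",
) -> DemographicTable:
    """Build the national demographic table.

    Parameters
    ----------
    total_millions
        Total population aged 25-65, in millions (586 for India in 2015).
    stratum_shares
        Either ``"default"`` (product of the documented marginal shares) or a
        mapping from every :class:`StratumKey` to its population share.
        Shares must sum to 1 within 1e-9.
    """
    if total_millions <= 0:
        raise ValueError("total_millions must be positive")
    if isinstance(stratum_shares, str):
        if stratum_shares != "default":
            raise ValueError(f"unknown share preset {stratum_shares!r}")
        m = DEFAULT_MARGINALS
        shares = {
            k: m["age_band"][k.age_band]
            * m["sex"][k.sex]
            * m["location"][k.location]
            * m["income"][k.income]
            for k in all_strata()
        }
    else:
        shares = {k: float(v) for k, v in stratum_shares.items()}
    total_share = sum(shares.values())
    if abs(total_share - 1.0) > 1e-9:
        raise ValueError(f"stratum shares sum to {total_share}, expected 1")
    return DemographicTable({k: total_millions * v for k, v in shares.items()})
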