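"""Screening instruments: survey risk scores, glucometer, and combinators.

The three questionnaire instruments used in Indian community screening
(Chaturvedi, Mohan/IDRS, Ramachandran) are encoded declaratively — each item
maps a risk factor to ordered, mutually exclusive categories with integer
points, and a person screens positive when the summed score reaches the
published cut point.  The encodings ship as YAML data files under
``screensim/data`` and are loaded, not hard-coded.

Random glucometer screening adds a Normal device error (Bland-Altman SD) to
the person's true random glucose and refers at a fixed threshold.  Serial
(both positive) and parallel (either positive) combinations compose any two
strategies; the serial combinator records which persons actually receive the
second-stage test so costs can be staged.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .population import RiskFactorProfile

#: Diagnostic (confirmatory) fasting plasma glucose threshold, mmol/l.
FASTING_DIAGNOSTIC_THRESHOLD = 7.0

#: Default random-glucose referral threshold (inclusive), mmol/l.
GLUCOMETER_THRESHOLD = 6.1

#: Glucometer vs laboratory measurement error SD, mmol/l.
GLUCOMETER_ERROR_SD = 0.9


class ScoreItem(abc.ABC):
    """One instrument item; assigns integer points per person."""

    name: str

    @abc.abstractmethod
    def points_array(self, df: pd.DataFrame) -> np.ndarray: ...

    @abc.abstractmethod
    def point_values(self) -> tuple[int, ...]:
        """Distinct point values achievable on this item."""

    @property
    def max_points(self) -> int:
        return max(self.point_values())


@dataclass
class RangeItem(ScoreItem):
    """Points from ordered numeric bins on one continuous factor.

    Each bin may carry a ``sex`` restriction (for waist items).  Bounds use
    ``min``/``max`` with per-bound inclusivity; defaults are closed-below,
    open-above.  Bins must be disjoint and exhaustive over positive reals
    (per sex where restricted); a gap raises an error naming the factor.
    """

    name: str
    factor: str
    bins: Sequence[Mapping[str, object]]

    def _bin_mask(self, b: Mapping[str, object], values: np.ndarray, sex: np.ndarray | None) -> np.ndarray:
        mask = np.ones(len(values), dtype=bool)
        if "min" in b:
            lo = float(b["min"])  # type: ignore[arg-type]
            mask &= values >= lo if b.get("min_inclusive", True) else values > lo
        if "max" in b:
            hi = float(b["max"])  # type: ignore[arg-type]
            mask &= values <= hi if b.get("max_inclusive", False) else values < hi
        if "sex" in b:
            if sex is None:
                raise ValueError(
                    f"item {self.name!r}: sex-specific bins require a sex column"
                )
            mask &= sex == b["sex"]
        return mask

    def points_array(self, df: pd.DataFrame) -> np.ndarray:
        if self.factor not in df.columns:
            raise ValueError(f"profile lacks factor {self.factor!r}")
        values = df[self.factor].to_numpy(dtype=float)
        sex = df["sex"].to_numpy() if "sex" in df.columns else None
        points = np.full(len(df), -1, dtype=int)
        assigned = np.zeros(len(df), dtype=bool)
        for b in self.bins:
            mask = self._bin_mask(b, values, sex)
            overlap = mask & assigned
            if overlap.any():
                raise ValueError(
                    f"item {self.name!r}: overlapping category predicates on "
                    f"factor {self.factor!r}"
                )
            points[mask] = int(b["points"])  # type: ignore[arg-type]
            assigned |= mask
        if not assigned.all():
            raise ValueError(
                f"item {self.name!r}: no category matches factor "
                f"{self.factor!r} for some values (predicate gap)"
            )
        return points

    def point_values(self) -> tuple[int, ...]:
        return tuple(sorted({int(b["points"]) for b in self.bins}))  # type: ignore[arg-type]


@dataclass
class CategoricalItem(ScoreItem):
    """Points by level of a categorical factor; must cover every level."""

    name: str
    factor: str
    points: Mapping[str, int]

    def points_array(self, df: pd.DataFrame) -> np.ndarray:
        if self.factor not in df.columns:
            raise ValueError(f"profile lacks factor {self.factor!r}")
        levels = df[self.factor].astype(str)
        unknown = set(levels.unique()) - set(self.points)
        if unknown:
            raise ValueError(
                f"item {self.name!r}: no category for levels {sorted(unknown)} "
                f"of factor {self.factor!r}"
            )
        return levels.map(self.points).to_numpy(dtype=int)

    def point_values(self) -> tuple[int, ...]:
        return tuple(sorted(set(int(v) for v in self.points.values())))


@dataclass
class MaxOfItem(ScoreItem):
    """Worst (highest-scoring) category across sub-items.

    Encodes 'X or Y' table rows such as blood pressure, where the person is
    scored on whichever of systolic or diastolic pressure falls in the worse
    band.
    """

    name: str
    children: Sequence[ScoreItem]

    def points_array(self, df: pd.DataFrame) -> np.ndarray:
        stacked = np.stack([c.points_array(df) for c in self.children])
        return stacked.max(axis=0)

    def point_values(self) -> tuple[int, ...]:
        from itertools import product

        combos = {max(c) for c in product(*[c.point_values() for c in self.children])}
        return tuple(sorted(combos))


@dataclass
class InstrumentSpec:
    """A survey risk score: items, cut point, maximum achievable score."""

    name: str
    items: Sequence[ScoreItem]
    cut_point: int
    max_score: int = field(init=False)

    def __post_init__(self) -> None:
        for item in self.items:
            if min(item.point_values()) < 0:
                raise ValueError(f"item {item.name!r}: negative points")
        self.max_score = sum(item.max_points for item in self.items)
        if not (0 < self.cut_point <= self.max_score):
            raise ValueError(
                f"cut point {self.cut_point} outside (0, {self.max_score}]"
            )

    def score(self, df: pd.DataFrame) -> np.ndarray:
        total = np.zeros(len(df), dtype=int)
        for item in self.items:
            total += item.points_array(df)
        return total

    def positive(self, df: pd.DataFrame) -> np.ndarray:
        return self.score(df) >= self.cut_point

    def enumerate_scores(self) -> list[int]:
        """All achievable total scores by exhaustive enumeration of every
        combination of item categories."""
        from itertools import product

        totals = {
            sum(combo) for combo in product(*[i.point_values() for i in self.items])
        }
        return sorted(totals)

    def n_category_combinations(self) -> int:
        n = 1
        for item in self.items:
            n *= len(item.point_values())
        return n


def score_instrument(
    spec: InstrumentSpec, profile: RiskFactorProfile, sex: str = "male"
) -> tuple[int, bool]:
    """Score one person; positive iff score >= cut point (inclusive)."""
    df = _profile_frame(profile, sex)
    s = int(spec.score(df)[0])
    return s, s >= spec.cut_point


def _profile_frame(profile: RiskFactorProfile, sex: str) -> pd.DataFrame:
    row = {f: getattr(profile, f) for f in (
        "age", "systolic_bp", "diastolic_bp", "bmi", "waist",
        "family_history", "physical_activity",
        "random_glucose_true", "fasting_glucose_true", "hba1c", "ldl",
        "smoker", "cvd_history",
    )}
    row["sex"] = sex
    return pd.DataFrame([row])


# ---------------------------------------------------------------------------
# YAML loading

_ITEM_KINDS = {"range", "categorical", "max_of"}


def _item_from_dict(d: Mapping[str, object]) -> ScoreItem:
    kind = d.get("kind")
    if kind not in _ITEM_KINDS:
        raise ValueError(f"unknown item kind {kind!r}")
    name = str(d.get("name", d.get("factor", kind)))
    if kind == "range":
        return RangeItem(name=name, factor=str(d["factor"]), bins=list(d["bins"]))  # type: ignore[arg-type]
    if kind == "categorical":
        return CategoricalItem(
            name=name, factor=str(d["factor"]),
            points={str(k): int(v) for k, v in dict(d["points"]).items()},  # type: ignore[arg-type]
        )
    return MaxOfItem(
        name=name, children=[_item_from_dict(c) for c in d["children"]]  # type: ignore[union-attr]
    )


def instrument_from_dict(d: Mapping[str, object]) -> InstrumentSpec:
    spec = InstrumentSpec(
        name=str(d["name"]),
        items=[_item_from_dict(i) for i in d["items"]],  # type: ignore[union-attr]
        cut_point=int(d["cut_point"]),  # type: ignore[arg-type]
    )
    declared = d.get("total_score")
    if declared is not None and int(declared) != spec.max_score:  # type: ignore[arg-type]
        raise ValueError(
            f"{spec.name}: declared total score {declared} != computed "
            f"{spec.max_score}"
        )
    return spec


def load_instrument(name: str) -> InstrumentSpec:
    """Load one of the shipped instrument encodings by name."""
    path = resources.files("screensim.data").joinpath(f"{name}.yaml")
    with path.open("r") as fh:
        return instrument_from_dict(yaml.safe_load(fh))


INSTRUMENT_NAMES = ("chaturvedi", "mohan", "ramachandran")


def load_all_instruments() -> dict[str, InstrumentSpec]:
    return {name: load_instrument(name) for name in INSTRUMENT_NAMES}


# ---------------------------------------------------------------------------
# Screens and strategies


@dataclass(frozen=True)
class GlucometerSpec:
    threshold: float = GLUCOMETER_THRESHOLD  # inclusive, mmol/l
    meter_error_sd: float = GLUCOMETER_ERROR_SD  # mmol/l

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.meter_error_sd < 0:
            raise ValueError("meter_error_sd must be >= 0")


@dataclass
class ScreenOutcome:
    """Per-person screen results plus staged testing bookkeeping.

    ``stages`` lists (activity, tested_mask) pairs in the order tests are
    administered; a serial second stage is only administered (and only
    costed) for first-stage positives.
    """

    positive: np.ndarray
    value: np.ndarray
    stages: list[tuple[str, np.ndarray]]


class ScreeningStrategy(abc.ABC):
    name: str

    @abc.abstractmethod
    def apply(self, df: pd.DataFrame, rng: np.random.Generator) -> ScreenOutcome: ...


class InstrumentStrategy(ScreeningStrategy):
    """Questionnaire risk score applied to everyone."""

    def __init__(self, spec: InstrumentSpec, cut_point: int | None = None):
        self.spec = spec
        self.cut_point = spec.cut_point if cut_point is None else int(cut_point)
        self.name = spec.name

    def apply(self, df: pd.DataFrame, rng: np.random.Generator) -> ScreenOutcome:
        score = self.spec.score(df)
        return ScreenOutcome(
            positive=score >= self.cut_point,
            value=score,
            stages=[("questionnaire", np.ones(len(df), dtype=bool))],
        )


class GlucometerStrategy(ScreeningStrategy):
    """Random capillary glucose with additive device error."""

    def __init__(self, spec: GlucometerSpec | None = None, threshold: float | None = None):
        self.spec = spec or GlucometerSpec()
        if threshold is not None:
            self.spec = GlucometerSpec(threshold=threshold, meter_error_sd=self.spec.meter_error_sd)
        self.name = "glucometer"

    def apply(self, df: pd.DataFrame, rng: np.random.Generator) -> ScreenOutcome:
        true_value = df["random_glucose_true"].to_numpy(dtype=float)
        measured = true_value + self.spec.meter_error_sd * rng.standard_normal(len(df))
        return ScreenOutcome(
            positive=measured >= self.spec.threshold,
            value=measured,
            stages=[("glucometer", np.ones(len(df), dtype=bool))],
        )


class CoinFlipStrategy(ScreeningStrategy):
    """Uninformative comparator: refer with probability p regardless of risk."""

    def __init__(self, p: float = 0.5):
        if not 0.0 <= p <= 1.0:
            raise ValueError("p must be in [0,1]")
        self.p = p
        self.name = f"coin_flip_{p:g}"

    def apply(self, df: pd.DataFrame, rng: np.random.Generator) -> ScreenOutcome:
        u = rng.random(len(df))
        return ScreenOutcome(
            positive=u < self.p,
            value=u,
            stages=[("coin_flip", np.ones(len(df), dtype=bool))],
        )


class SerialStrategy(ScreeningStrategy):
    """Both tests must be positive; second test given only to first-positives."""

    def __init__(self, first: ScreeningStrategy, second: ScreeningStrategy):
        self.first = first
        self.second = second
        self.name = f"{first.name}_then_{second.name}"

    def apply(self, df: pd.DataFrame, rng: np.random.Generator) -> ScreenOutcome:
        out1 = self.first.apply(df, rng)
        out2 = self.second.apply(df, rng)
        stages = list(out1.stages)
        stages += [(act, mask & out1.positive) for act, mask in out2.stages]
        return ScreenOutcome(
            positive=out1.positive & out2.positive,
            value=out2.value,
            stages=stages,
        )


class ParallelStrategy(ScreeningStrategy):
    """Both tests administered to everyone; either positive refers."""

    def __init__(self, a: ScreeningStrategy, b: ScreeningStrategy):
        self.a = a
        self.b = b
        self.name = f"{a.name}_or_{b.name}"

    def apply(self, df: pd.DataFrame, rng: np.random.Generator) -> ScreenOutcome:
        out_a = self.a.apply(df, rng)
        out_b = self.b.apply(df, rng)
        return ScreenOutcome(
            positive=out_a.positive | out_b.positive,
            value=np.maximum(out_a.value, out_b.value),
            stages=list(out_a.stages) + list(out_b.stages),
        )


def combine_serial(first: ScreeningStrategy, second: ScreeningStrategy) -> SerialStrategy:
    return SerialStrategy(first, second)


def combine_parallel(a: ScreeningStrategy, b: ScreeningStrategy) -> ParallelStrategy:
    return ParallelStrategy(a, b)


def glucometer_screen(
    spec: GlucometerSpec, profile: RiskFactorProfile, rng: np.random.Generator
) -> tuple[float, bool]:
    """Screen one person with a handheld glucometer; fresh error each call."""
    measured = profile.random_glucose_true + spec.meter_error_sd * rng.standard_normal()
    return float(measured), bool(measured >= spec.threshold)


def confirmatory_test(profile_or_df) -> bool | np.ndarray:
    """Laboratory fasting glucose diagnosis, positive at >= 7.0 mmol/l."""
    if isinstance(profile_or_df, pd.DataFrame):
        return (
            profile_or_df["fasting_glucose_true"].to_numpy(dtype=float)
            >= FASTING_DIAGNOSTIC_THRESHOLD
        )
    return bool(profile_or_df.fasting_glucose_true >= FASTING_DIAGNOSTIC_THRESHOLD)
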