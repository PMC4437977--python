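"""End-to-end Monte Carlo orchestration and credible intervals.

One *draw* is a full pass through the model: sample prevalence-model
coefficients from their fitted sampling distributions, rebuild the weighted
national population, screen it with every configured strategy, and tally
diagnostics, burden, costs and (optionally) complication outcomes.  Draws
use hierarchical random-number substreams (one child seed per draw), so each
draw's result is independent of execution order, and a run is fully
reproducible from its root seed.

Reported quantities are summarised as 95% credible intervals: the 2.5th,
50th (point estimate) and 97.5th empirical percentiles across draws, with
linear interpolation between order statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .complications import (
    TreatmentTargets,
    cost_per_complication_prevented,
    default_risk_equations,
    nnst,
)
from .costs import CostModel, cost_strategy
from .instruments import (
    CoinFlipStrategy,
    GlucometerSpec,
    GlucometerStrategy,
    InstrumentStrategy,
    ParallelStrategy,
    ScreeningStrategy,
    SerialStrategy,
    load_all_instruments,
)
from .meta_regression import (
    MetaRegressionFit,
    _surface_from_betas,
    fit_meta_regression,
)
from .population import PopulationSample, build_population
from .screening_eval import (
    comorbidity_codetection,
    evaluate_strategy,
    false_true_ratio,
    staged_test_millions,
    _case_mask,
)
from .strata import make_demographics
from .synthetic_inputs import (
    OUTCOMES,
    GroundTruth,
    default_ground_truth,
    simulate_cohort_studies,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``n_draws`` defaults to the desk-scale 500; 10,000 draws reproduce the
    full uncertainty analysis at proportionally higher cost.
    """

    seed: int = 0
    n_persons: int = 200_000
    n_draws: int = 500
    year: float = 2015.0
    total_millions: float = 586.0
    n_studies: int = 60
    strategies: tuple[str, ...] = (
        "chaturvedi", "mohan", "ramachandran", "glucometer",
    )
    scale: str = "logit"
    include_complications: bool = True
    include_comorbidity: bool = True

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not self.strategies:
            raise ValueError("at least one strategy required")
        if self.scale not in ("logit", "linear"):
            raise ValueError("scale must be 'logit' or 'linear'")
        self.strategies = tuple(self.strategies)

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)  # type: ignore[arg-type]


@dataclass
class CredibleInterval:
    """Median point estimate with equal-tailed 95% bounds across draws."""

    point: float
    lower: float
    upper: float
    mean: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ValueError("interval must satisfy lower <= point <= upper")


def summarize(draws: Sequence[float], quantity: str = "") -> CredibleInterval:
    """Empirical 2.5/50/97.5 percentiles with linear interpolation."""
    values = np.asarray(list(draws), dtype=float)
    if values.size == 0:
        raise ValueError(f"no draws to summarise for {quantity!r}")
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return CredibleInterval(np.nan, np.nan, np.nan, np.nan)
    if finite.size < values.size:
        logger.warning(
            "%s: %d of %d draws undefined, summarising the rest",
            quantity, values.size - finite.size, values.size,
        )
    lo, med, hi = np.percentile(finite, [2.5, 50.0, 97.5])
    return CredibleInterval(point=float(med), lower=float(lo), upper=float(hi),
                            mean=float(finite.mean()))


def resolve_strategy(name: str) -> ScreeningStrategy:
    """Build a strategy from its name.

    Base names: the three instruments, ``glucometer``, ``coin_flip``.
    Composites: ``A_then_B`` (serial) and ``A_or_B`` (parallel), e.g.
    ``chaturvedi_then_glucometer``.
    """
    if "_then_" in name:
        first, second = name.split("_then_", 1)
        return SerialStrategy(resolve_strategy(first), resolve_strategy(second))
    if "_or_" in name:
        a, b = name.split("_or_", 1)
        return ParallelStrategy(resolve_strategy(a), resolve_strategy(b))
    if name == "glucometer":
        return GlucometerStrategy(GlucometerSpec())
    if name == "coin_flip":
        return CoinFlipStrategy(0.5)
    instruments = load_all_instruments()
    if name in instruments:
        return InstrumentStrategy(instruments[name])
    raise ValueError(f"unknown strategy {name!r}")


def fit_all_outcomes(
    studies, scale: str = "logit"
) -> dict[str, MetaRegressionFit]:
    return {o: fit_meta_regression(studies, o, scale=scale) for o in OUTCOMES}


def _draw_betas(
    fits: Mapping[str, MetaRegressionFit], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    return {
        o: rng.multivariate_normal(f.beta, f.vcov, method="eigh")
        for o, f in fits.items()
    }


def run_pipeline(
    config: RunConfig,
    truth: GroundTruth | None = None,
    cost_model: CostModel | None = None,
) -> dict:
    """Run the full microsimulation with Monte Carlo uncertainty.

    Returns a nested report: per-strategy credible intervals for the
    diagnostic metrics, national burden counts (millions), discounted costs,
    and complication-prevention yield, plus overall disease-burden
    quantities.  Failed draws are logged, discarded and counted.
    """
    truth = truth or default_ground_truth()
    cost_model = cost_model or CostModel()
    eqs = default_risk_equations()
    targets = TreatmentTargets()
    demo = make_demographics(config.total_millions)
    root = np.random.SeedSequence(config.seed)
    seed_studies, _reserved, *draw_seeds = root.spawn(2 + config.n_draws)

    studies = simulate_cohort_studies(truth, config.n_studies, seed_studies)
    fits = fit_all_outcomes(studies, scale=config.scale)
    strategies = {name: resolve_strategy(name) for name in config.strategies}

    overall_draws: dict[str, list[float]] = {
        "eligible_millions": [], "undiagnosed_millions": [], "prevalence": [],
        "undiagnosed_fraction": [],
    }
    strat_draws: dict[str, dict[str, list[float]]] = {
        name: {} for name in strategies
    }
    n_failed = 0

    for d in range(config.n_draws):
        rng = np.random.default_rng(draw_seeds[d])
        try:
            betas = _draw_betas(fits, rng)
            surface = _surface_from_betas(fits, betas, config.year)
            pop = build_population(
                demo, surface, truth.risk_factors, config.n_persons, rng
            )
            eligible = pop.eligible_subset()
            df = eligible.frame
            w = df["weight"].to_numpy(dtype=float)
            case = _case_mask(df)
            overall_draws["eligible_millions"].append(float(w.sum()))
            overall_draws["undiagnosed_millions"].append(float(w[case].sum()))
            full = pop.frame
            prev = float(
                full.loc[full["has_diabetes"], "weight"].sum() / full["weight"].sum()
            )
            overall_draws["prevalence"].append(prev)
            overall_draws["undiagnosed_fraction"].append(
                float(
                    full.loc[
                        full["has_diabetes"] & ~full["previously_diagnosed"], "weight"
                    ].sum()
                    / max(full.loc[full["has_diabetes"], "weight"].sum(), 1e-12)
                )
            )

            for name, strategy in strategies.items():
                counts, metrics, outcome = evaluate_strategy(eligible, strategy, rng)
                staged = staged_test_millions(df, outcome)
                cost = cost_strategy(counts, staged, cost_model)
                rec = strat_draws[name]
                values = {
                    "sensitivity": metrics.sensitivity,
                    "specificity": metrics.specificity,
                    "ppv": metrics.ppv,
                    "npv": metrics.npv,
                    "nns": metrics.nns,
                    "tp_millions": counts.tp,
                    "fp_millions": counts.fp,
                    "tn_millions": counts.tn,
                    "fn_millions": counts.fn,
                    "referred_millions": counts.referred_total,
                    "false_true_ratio": false_true_ratio(counts),
                    "total_cost_millions": cost.total_cost,
                    "cost_per_case": cost.cost_per_case_found,
                }
                if config.include_comorbidity:
                    codet = comorbidity_codetection(
                        eligible, strategy, rng, outcome=outcome
                    )
                    values["codetect_hypertension"] = codet["hypertension"]
                    values["codetect_obesity"] = codet["obesity"]
                if config.include_complications:
                    detected = df[outcome.positive & case]
                    if len(detected) > 0:
                        res = nnst(detected, eqs, targets)
                        values["fraction_avoiding_complication"] = (
                            res.fraction_avoiding_any
                        )
                        values["min_nnst"] = min(
                            (v for v in res.nnst.values() if np.isfinite(v)),
                            default=np.nan,
                        )
                        values["cost_per_complication_prevented"] = (
                            cost_per_complication_prevented(cost, res)
                        )
                for k, v in values.items():
                    rec.setdefault(k, []).append(float(v))
        except Exception:  # noqa: BLE001 - draw-level failures are discarded
            n_failed += 1
            logger.exception("draw %d failed; discarded", d)

    n_ok = config.n_draws - n_failed
    if n_ok == 0:
        raise RuntimeError("every draw failed")

    report = {
        "config": asdict(config),
        "n_draws_completed": n_ok,
        "n_draws_failed": n_failed,
        "overall": {
            q: asdict(summarize(v, q)) for q, v in overall_draws.items() if v
        },
        "strategies": {
            name: {q: asdict(summarize(v, f"{name}.{q}")) for q, v in rec.items()}
            for name, rec in strat_draws.items()
        },
    }
    return report


# ---------------------------------------------------------------------------
# Report writers


def _format_ci(ci: Mapping[str, float], digits: int = 1) -> str:
    return (
        f"{ci['point']:.{digits}f} "
        f"({ci['lower']:.{digits}f}-{ci['upper']:.{digits}f})"
    )


def metrics_table(report: Mapping) -> pd.DataFrame:
    """Diagnostic-performance table: one row per metric, one column per
    strategy, percentages with 95% credible intervals."""
    rows = []
    percent = {"sensitivity", "specificity", "ppv", "npv"}
    for metric in ("sensitivity", "specificity", "ppv", "npv", "nns"):
        row: dict[str, str] = {"metric": metric}
        for name, rec in report["strategies"].items():
            if metric not in rec:
                continue
            ci = dict(rec[metric])
            if metric in percent:
                ci = {k: (v * 100 if isinstance(v, float) else v) for k, v in ci.items()}
            row[name] = _format_ci(ci)
        rows.append(row)
    return pd.DataFrame(rows)


def burden_table(report: Mapping) -> pd.DataFrame:
    """Health-system burden table: weighted millions and costs per strategy."""
    quantities = (
        ("tp_millions", 1), ("fn_millions", 1), ("tn_millions", 1),
        ("fp_millions", 1), ("referred_millions", 1),
        ("false_true_ratio", 1),
        ("total_cost_millions", 2), ("cost_per_case", 2),
    )
    rows = []
    for q, digits in quantities:
        row: dict[str, str] = {"quantity": q}
        for name, rec in report["strategies"].items():
            if q in rec:
                row[name] = _format_ci(rec[q], digits)
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: Mapping, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
    metrics_table(report).to_csv(out / "instrument_performance.csv", index=False)
    burden_table(report).to_csv(out / "health_system_burden.csv", index=False)
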