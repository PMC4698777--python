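"""One-way deterministic sensitivity sweeps and break-even threshold search.

Each sweepable quantity is registered with a getter and a setter over
:class:`~igtcea.parameters.ParameterSet`, so quantities the literature
reports on different scales (an incidence rate, a direct probability
override, a unit cost) share one sweep interface.  One-way sweeps
re-run the full 50-year pipeline at each range endpoint with every other
parameter at base case.  Threshold search bisects the scalar map
parameter -> incremental discounted cost to the value at which the two
strategies' cumulative costs are equal, to a residual below one cent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .economics import EconomicSummary, IncrementalResult, accrue, compare
from .lifetable import LifeTable
from .markov import Strategy, run_cohort
from .parameters import ParameterError, ParameterSet, rate_to_probability

__all__ = [
    "ModelContext",
    "SweptParameter",
    "SWEEPABLE",
    "TABLE_SWEEP_ORDER",
    "THRESHOLD_DEFAULTS",
    "SensitivityResult",
    "ThresholdResult",
    "run_strategies",
    "incremental_result",
    "incremental_cost",
    "one_way",
    "threshold_search",
    "sensitivity_table",
    "threshold_table",
]


@dataclass(frozen=True)
class ModelContext:
    """Everything needed to run the two-strategy pipeline end to end."""

    params: ParameterSet
    life_table: LifeTable
    horizon: int | None = None
    start_age: float | None = None

    def with_params(self, params: ParameterSet) -> "ModelContext":
        return replace(self, params=params)


def run_strategies(ctx: ModelContext) -> tuple[EconomicSummary, EconomicSummary]:
    """Run SMS and control arms; returns (sms_summary, control_summary)."""
    out = []
    for strategy in (Strategy.SMS, Strategy.CONTROL):
        trace = run_cohort(strategy, ctx.params, ctx.life_table,
                           horizon=ctx.horizon, start_age=ctx.start_age)
        out.append(accrue(trace, ctx.params))
    return out[0], out[1]


def incremental_result(ctx: ModelContext) -> IncrementalResult:
    sms, control = run_strategies(ctx)
    return compare(sms, control)


def incremental_cost(ctx: ModelContext) -> float:
    """Incremental discounted cost of SMS versus control (US$ per subject)."""
    return incremental_result(ctx).delta_cost


@dataclass(frozen=True)
class SweptParameter:
    """A named scalar that one-way sweeps and threshold search can vary."""

    name: str
    label: str
    get: Callable[[ParameterSet], float]
    set: Callable[[ParameterSet, float], ParameterSet]


def _field_param(name: str, label: str) -> SweptParameter:
    return SweptParameter(
        name=name,
        label=label,
        get=lambda p, _n=name: getattr(p, _n),
        set=lambda p, v, _n=name: p.replace(**{_n: v}),
    )


def _sms_override_param(name: str, year: int, label: str) -> SweptParameter:
    # base value = current override if set, else RR-derived probability
    return SweptParameter(
        name=name,
        label=label,
        get=lambda p, _y=year: p.p_onset_sms_retained(_y),
        set=lambda p, v, _n=name: p.replace(**{_n: v}),
    )


SWEEPABLE: dict[str, SweptParameter] = {
    sp.name: sp
    for sp in (
        _field_param("dropout_year1", "SMS drop-out rate at year 1"),
        _field_param("dropout_year2", "SMS drop-out rate at year 2"),
        _field_param("incidence_igt_to_t2dm_y1_3",
                     "IGT to T2DM incidence, control, years 1-3"),
        _field_param("incidence_igt_to_t2dm_y4plus",
                     "IGT to T2DM incidence, control, year 4+"),
        _field_param("rr_t2dm_year1", "Relative risk of T2DM onset, SMS year 1"),
        _field_param("rr_t2dm_year2", "Relative risk of T2DM onset, SMS year 2"),
        _sms_override_param("p_igt_to_t2dm_sms_y1", 1,
                            "Annual probability IGT to T2DM, SMS year 1"),
        _sms_override_param("p_igt_to_t2dm_sms_y2", 2,
                            "Annual probability IGT to T2DM, SMS year 2"),
        _field_param("p_igt_to_ngt", "Annual probability IGT to NGT"),
        _field_param("p_ngt_to_igt", "Annual probability NGT to IGT"),
        _field_param("rr_mortality_igt", "Relative risk of mortality, IGT"),
        _field_param("rr_mortality_t2dm", "Relative risk of mortality, T2DM"),
        _field_param("discount_rate", "Discount rate"),
        _field_param("cost_sms_year1", "SMS intervention cost, year 1"),
        _field_param("cost_sms_year2", "SMS intervention cost, year 2"),
    )
}

# The published one-way sensitivity table, in row order.
TABLE_SWEEP_ORDER: tuple[str, ...] = (
    "dropout_year1",
    "dropout_year2",
    "incidence_igt_to_t2dm_y1_3",
    "p_igt_to_t2dm_sms_y1",
    "p_igt_to_t2dm_sms_y2",
    "p_igt_to_ngt",
    "p_ngt_to_igt",
    "rr_mortality_igt",
    "rr_mortality_t2dm",
    "discount_rate",
)

# Default search brackets for the break-even analysis (parameter -> (lo, hi)).
THRESHOLD_DEFAULTS: dict[str, tuple[float, float]] = {
    "cost_sms_year1": (34.38, 10_000.0),
    "cost_sms_year2": (7.64, 20_000.0),
    "p_igt_to_t2dm_sms_y1": (0.0093, 0.5),
    "p_igt_to_t2dm_sms_y2": (0.0093, 0.5),
}


@dataclass(frozen=True)
class SensitivityResult:
    """Incremental cost at the two endpoints of a one-way sweep."""

    name: str
    label: str
    base_value: float
    bounds: tuple[float, float]
    result_low: IncrementalResult
    result_high: IncrementalResult

    @property
    def cost_range(self) -> tuple[float, float]:
        return (self.result_low.delta_cost, self.result_high.delta_cost)


@dataclass(frozen=True)
class ThresholdResult:
    """Break-even value of a parameter at which incremental cost vanishes."""

    name: str
    label: str
    base_value: float
    threshold: float
    residual_cost: float
    bracket: tuple[float, float]


def _swept(name: str) -> SweptParameter:
    try:
        return SWEEPABLE[name]
    except KeyError:
        raise ParameterError(
            name, None, f"not sweepable; choose from {sorted(SWEEPABLE)}"
        ) from None


def one_way(
    param_name: str,
    ctx: ModelContext,
    bounds: tuple[float, float] | None = None,
) -> SensitivityResult:
    """Re-run the full pipeline at each endpoint of one parameter's range."""
    sp = _swept(param_name)
    if bounds is None:
        try:
            bounds = ctx.params.sensitivity_ranges[param_name]
        except KeyError:
            raise ParameterError(
                param_name, None, "no sensitivity range declared; pass bounds explicitly"
            ) from None
    lo, hi = float(bounds[0]), float(bounds[1])
    res_lo = incremental_result(ctx.with_params(sp.set(ctx.params, lo)))
    res_hi = incremental_result(ctx.with_params(sp.set(ctx.params, hi)))
    return SensitivityResult(
        name=sp.name,
        label=sp.label,
        base_value=sp.get(ctx.params),
        bounds=(lo, hi),
        result_low=res_lo,
        result_high=res_hi,
    )


def threshold_search(
    param_name: str,
    ctx: ModelContext,
    bracket: tuple[float, float] | None = None,
    tolerance: float = 0.01,
    max_iter: int = 64,
) -> ThresholdResult:
    """Bisect for the parameter value at which incremental cost crosses zero.

    Requires a sign change of the incremental discounted cost over
    ``bracket``; incremental cost is monotone in every supported
    parameter, so bisection cannot stall.
    """
    sp = _swept(param_name)
    if bracket is None:
        if param_name not in THRESHOLD_DEFAULTS:
            raise ParameterError(
                param_name, None,
                f"no default bracket; defaults exist for {sorted(THRESHOLD_DEFAULTS)}",
            )
        bracket = THRESHOLD_DEFAULTS[param_name]
    lo, hi = float(bracket[0]), float(bracket[1])

    def f(x: float) -> float:
        return incremental_cost(ctx.with_params(sp.set(ctx.params, x)))

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0 or f_hi == 0.0:
        x = lo if f_lo == 0.0 else hi
        return ThresholdResult(sp.name, sp.label, sp.get(ctx.params), x, 0.0, (lo, hi))
    if np.sign(f_lo) == np.sign(f_hi):
        raise ParameterError(
            param_name, bracket,
            f"incremental cost does not change sign: f({lo:g}) = {f_lo:.2f}, "
            f"f({hi:g}) = {f_hi:.2f}",
        )
    x_mid = 0.5 * (lo + hi)
    f_mid = f(x_mid)
    for _ in range(max_iter):
        if abs(f_mid) < tolerance:
            break
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = x_mid, f_mid
        else:
            hi, f_hi = x_mid, f_mid
        x_mid = 0.5 * (lo + hi)
        f_mid = f(x_mid)
    else:
        raise RuntimeError(
            f"threshold for {param_name!r} did not converge below ${tolerance} "
            f"in {max_iter} bisections (residual {f_mid:.4f})"
        )
    return ThresholdResult(
        name=sp.name,
        label=sp.label,
        base_value=sp.get(ctx.params),
        threshold=x_mid,
        residual_cost=f_mid,
        bracket=(float(bracket[0]), float(bracket[1])),
    )


def _fmt_dominance(res: IncrementalResult) -> str:
    if res.is_dominant:
        return "dominant"
    if res.delta_cost == 0 and res.delta_qaly == 0:
        return "equivalent"
    if res.delta_cost > 0 and res.delta_qaly < 0:
        return "dominated"
    return "trade-off"


def sensitivity_table(
    ctx: ModelContext, names: Sequence[str] = TABLE_SWEEP_ORDER
) -> pd.DataFrame:
    """One row per swept parameter: base value, range, incremental-cost range."""
    rows = []
    for name in names:
        r = one_way(name, ctx)
        rows.append(
            {
                "parameter": r.name,
                "label": r.label,
                "base_value": r.base_value,
                "range_min": r.bounds[0],
                "range_max": r.bounds[1],
                "inc_cost_at_min": r.result_low.delta_cost,
                "inc_cost_at_max": r.result_high.delta_cost,
                "dominance_at_min": _fmt_dominance(r.result_low),
                "dominance_at_max": _fmt_dominance(r.result_high),
            }
        )
    return pd.DataFrame(rows)


def threshold_table(
    ctx: ModelContext,
    names: Sequence[str] = tuple(THRESHOLD_DEFAULTS),
    tolerance: float = 0.01,
) -> pd.DataFrame:
    """Break-even table; per-parameter errors are recorded, not raised."""
    rows = []
    for name in names:
        try:
            r = threshold_search(name, ctx, tolerance=tolerance)
            rows.append(
                {
                    "parameter": r.name,
                    "label": r.label,
                    "base_value": r.base_value,
                    "threshold": r.threshold,
                    "residual_cost": r.residual_cost,
                    "error": "",
                }
            )
        except (ParameterError, RuntimeError) as exc:
            rows.append(
                {
                    "parameter": name,
                    "label": SWEEPABLE[name].label if name in SWEEPABLE else name,
                    "base_value": np.nan,
                    "threshold": np.nan,
                    "residual_cost": np.nan,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)
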