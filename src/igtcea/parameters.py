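"""Model inputs and elementary epidemiological conversions.

The model compares two strategies for managing subjects with impaired
glucose tolerance (IGT): a two-year short-message-service (SMS)
lifestyle-support programme delivered on top of usual clinical practice,
versus usual clinical practice alone.  Every scalar the downstream Markov
engine and economics layer consume — annual transition inputs, the trial's
relative risks and drop-out rates, unit costs, state utilities, the
discount rate — lives in :class:`ParameterSet`, together with the one-way
sensitivity range declared for each swept quantity.

Incidence and mortality inputs arrive as *rates* (events per person-year)
and are converted to per-cycle probabilities with the standard constant-
hazard identity ``p = 1 - exp(-r t)``; its inverse ``r = -ln(1 - p) / t``
is provided for round-trip validation and for sweeping quantities that the
literature reports on the probability scale.

Conventions adopted here (see the package methods note for rationale):

* The intervention's relative risk acts multiplicatively on the annual
  onset *probability* (capped at 1), which reproduces the published
  year-2 SMS onset probability of 6.25% exactly.
* Mortality relative risks act on the *rate* scale and are converted back
  to probabilities, i.e. ``q_adj = 1 - (1 - q)**rr``, which stays inside
  [0, 1) for any relative risk.
* Discounting uses end-of-cycle weights ``(1 + r)**(-t)`` with the first
  cycle discounted (t = 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace as _dc_replace
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ParameterError",
    "RateSpec",
    "AnnualProbability",
    "ParameterSet",
    "rate_to_probability",
    "probability_to_rate",
    "apply_relative_risk",
    "adjusted_mortality",
    "discount_factor",
    "load_parameters",
]

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    """A model input violates its declared bounds.

    Carries the offending field name so configuration errors surface with
    an actionable message rather than a bare ValueError.
    """

    def __init__(self, name: str, value: Any, constraint: str):
        self.parameter = name
        self.value = value
        self.constraint = constraint
        super().__init__(f"parameter {name!r} = {value!r} violates: {constraint}")


@dataclass(frozen=True)
class RateSpec:
    """An event rate in events per person-year.

    ``value=0.110`` encodes the published "11.0 cases per 100 person-years".
    """

    value: float
    period: float = 1.0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ParameterError("RateSpec.value", self.value, "rate must be >= 0")
        if self.period <= 0:
            raise ParameterError("RateSpec.period", self.period, "period must be > 0")


@dataclass(frozen=True)
class AnnualProbability:
    """A probability attached to one annual model cycle."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ParameterError(
                "AnnualProbability.value", self.value, "probability must be in [0, 1]"
            )


def _as_float(x: float | RateSpec | AnnualProbability) -> float:
    return float(x.value) if isinstance(x, (RateSpec, AnnualProbability)) else float(x)


def rate_to_probability(rate: float | RateSpec, t: float = 1.0) -> float:
    """Convert a constant event rate to the probability of >=1 event in ``t`` years.

    Implements ``p = 1 - exp(-r t)`` under the constant-hazard assumption.
    """
    r = _as_float(rate)
    if r < 0:
        raise ParameterError("rate", r, "rate must be >= 0")
    if t <= 0:
        raise ParameterError("t", t, "time must be > 0")
    return -math.expm1(-r * t)


def probability_to_rate(p: float | AnnualProbability, t: float = 1.0) -> float:
    """Invert :func:`rate_to_probability`: ``r = -ln(1 - p) / t``.

    Undefined at ``p = 1`` (infinite rate), hence the strict upper bound.
    """
    pv = _as_float(p)
    if not 0.0 <= pv < 1.0:
        raise ParameterError("p", pv, "probability must be in [0, 1)")
    if t <= 0:
        raise ParameterError("t", t, "time must be > 0")
    return -math.log1p(-pv) / t


def apply_relative_risk(p: float | AnnualProbability, rr: float) -> float:
    """Scale an annual probability by a relative risk, capping at 1.

    The cap is a safety valve for extreme sensitivity sweeps; base-case and
    published ranges never trigger it.  Cap events are logged.
    """
    pv = _as_float(p)
    if not 0.0 <= pv <= 1.0:
        raise ParameterError("p", pv, "probability must be in [0, 1]")
    if rr <= 0:
        raise ParameterError("rr", rr, "relative risk must be > 0")
    scaled = rr * pv
    if scaled > 1.0:
        logger.warning("relative risk %g scales probability %g past 1; capping", rr, pv)
        return 1.0
    return scaled


def adjusted_mortality(q_background: float | AnnualProbability, rr_state: float) -> float:
    """Adjust a background annual death probability by a state relative risk.

    The relative risk multiplies the underlying mortality *rate*: the
    probability is converted to a rate, scaled, and converted back, so the
    result stays in [0, 1) for any positive relative risk.
    """
    q = _as_float(q_background)
    if not 0.0 <= q < 1.0:
        raise ParameterError("q_background", q, "probability must be in [0, 1)")
    if rr_state <= 0:
        raise ParameterError("rr_state", rr_state, "relative risk must be > 0")
    return rate_to_probability(probability_to_rate(q) * rr_state)


def discount_factor(rate: float, cycle: int) -> float:
    """End-of-cycle discount weight ``(1 + rate)**(-cycle)``; cycle 1 is discounted."""
    if rate < 0:
        raise ParameterError("discount_rate", rate, "discount rate must be >= 0")
    if cycle < 1:
        raise ParameterError("cycle", cycle, "cycle index is 1-based")
    return (1.0 + rate) ** (-cycle)


_DEFAULT_COST_COMPONENTS: dict[str, float] = {
    "delivery_year1": 4.15,
    "staff_year1": 30.23,
    "delivery_year2": 0.92,
    "staff_year2": 6.72,
}

# Sweep ranges for the one-way sensitivity analysis.  Keys are sweepable
# parameter names (see igtcea.sensitivity); values are (min, max).
_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "dropout_year1": (0.0, 1.0),
    "dropout_year2": (0.0, 1.0),
    "incidence_igt_to_t2dm_y1_3": (0.098, 0.123),
    "incidence_igt_to_t2dm_y4plus": (0.048, 0.065),
    "rr_t2dm_year1": (0.10, 1.00),
    "rr_t2dm_year2": (0.10, 1.00),
    "p_igt_to_t2dm_sms_y1": (0.0093, 0.1157),
    "p_igt_to_t2dm_sms_y2": (0.0093, 0.1157),
    "p_igt_to_ngt": (0.05, 0.25),
    "p_ngt_to_igt": (0.05, 0.25),
    "rr_mortality_igt": (1.1, 2.0),
    "rr_mortality_t2dm": (1.6, 3.2),
    "discount_rate": (0.0, 0.05),
}

_PROBABILITY_FIELDS = (
    "dropout_year1",
    "dropout_year2",
    "p_igt_to_ngt",
    "p_ngt_to_igt",
    "utility_ngt",
    "utility_igt",
    "utility_t2dm",
    "utility_dead",
)
_NONNEG_FIELDS = (
    "incidence_igt_to_t2dm_y1_3",
    "incidence_igt_to_t2dm_y4plus",
    "cost_sms_year1",
    "cost_sms_year2",
    "cost_t2dm_annual",
    "discount_rate",
)
_POSITIVE_FIELDS = (
    "rr_t2dm_year1",
    "rr_t2dm_year2",
    "rr_mortality_igt",
    "rr_mortality_t2dm",
)


@dataclass(frozen=True)
class ParameterSet:
    """Base-case model inputs plus sensitivity ranges.

    Costs are 2011 US$ (Hong Kong dollars pegged at HKD 7.8 per US$).
    ``p_igt_to_t2dm_sms_y1``/``_y2`` are optional direct overrides of the
    SMS-arm annual onset probability in intervention years 1 and 2; when
    ``None`` (the default) those probabilities are derived as
    ``rr_t2dm_year{1,2} x`` the control-arm probability.  The override
    exists because the published base case prints a year-1 SMS probability
    of 3.53% where the rounded relative risk of 0.34 yields 3.54%.
    """

    # Intervention effect (trial, complete-case analysis)
    rr_t2dm_year1: float = 0.34
    rr_t2dm_year2: float = 0.60
    dropout_year1: float = 0.3889
    dropout_year2: float = 0.3030
    # Natural history
    incidence_igt_to_t2dm_y1_3: float = 0.110
    incidence_igt_to_t2dm_y4plus: float = 0.056
    p_igt_to_ngt: float = 0.1620
    p_ngt_to_igt: float = 0.1630
    rr_mortality_igt: float = 1.5
    rr_mortality_t2dm: float = 2.3
    # Utilities (per year alive in state)
    utility_ngt: float = 0.76
    utility_igt: float = 0.76
    utility_t2dm: float = 0.72
    utility_dead: float = 0.0
    # Costs (US$, 2011)
    cost_sms_year1: float = 34.38
    cost_sms_year2: float = 7.64
    cost_t2dm_annual: float = 1727.90
    # Analysis settings
    discount_rate: float = 0.03
    horizon_years: int = 50
    start_age: float = 55.0
    # Direct SMS onset-probability overrides (None = derive from RR)
    p_igt_to_t2dm_sms_y1: float | None = None
    p_igt_to_t2dm_sms_y2: float | None = None
    # Which retained states incur the programme cost: all retained alive
    # non-diabetic mass, or only those still in IGT
    intervention_cost_states: str = "all_retained"
    cost_components: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COST_COMPONENTS)
    )
    sensitivity_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES)
    )

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(name, v, "must be in [0, 1]")
        for name in _NONNEG_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(name, v, "must be >= 0")
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if v <= 0:
                raise ParameterError(name, v, "must be > 0")
        for name in ("p_igt_to_t2dm_sms_y1", "p_igt_to_t2dm_sms_y2"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ParameterError(name, v, "must be in [0, 1] or null")
        if self.horizon_years < 1:
            raise ParameterError("horizon_years", self.horizon_years, "must be >= 1")
        if self.intervention_cost_states not in ("all_retained", "igt_only"):
            raise ParameterError(
                "intervention_cost_states",
                self.intervention_cost_states,
                "must be 'all_retained' or 'igt_only'",
            )

    def replace(self, **changes: Any) -> "ParameterSet":
        """Return a validated copy with the given fields changed."""
        return _dc_replace(self, **changes)

    # -- derived per-cycle onset probabilities ---------------------------

    def p_onset_control(self, cycle: int) -> float:
        """Control-arm annual IGT->T2DM probability for a 1-based cycle.

        Incidence is roughly double in the first three years after IGT
        diagnosis, so cycles 1-3 use the early rate and cycles >=4 the
        late rate.
        """
        rate = (
            self.incidence_igt_to_t2dm_y1_3
            if cycle <= 3
            else self.incidence_igt_to_t2dm_y4plus
        )
        return rate_to_probability(rate)

    def p_onset_sms_retained(self, cycle: int) -> float:
        """SMS-arm annual onset probability for a retained subject.

        Only cycles 1 and 2 (the intervention window) differ from control;
        a direct probability override, if configured, wins over the
        RR-derived value.
        """
        if cycle == 1:
            if self.p_igt_to_t2dm_sms_y1 is not None:
                return self.p_igt_to_t2dm_sms_y1
            return apply_relative_risk(self.p_onset_control(1), self.rr_t2dm_year1)
        if cycle == 2:
            if self.p_igt_to_t2dm_sms_y2 is not None:
                return self.p_igt_to_t2dm_sms_y2
            return apply_relative_risk(self.p_onset_control(2), self.rr_t2dm_year2)
        return self.p_onset_control(cycle)

    def utilities(self) -> dict[str, float]:
        return {
            "ngt": self.utility_ngt,
            "igt": self.utility_igt,
            "t2dm": self.utility_t2dm,
            "dead": self.utility_dead,
        }


def _bundled_defaults() -> dict[str, Any]:
    with resources.files("igtcea.data").joinpath("basecase.yaml").open("r") as fh:
        return yaml.safe_load(fh)


def load_parameters(
    source: str | Path | Mapping[str, Any] | None = None, **overrides: Any
) -> ParameterSet:
    """Build a :class:`ParameterSet` from the bundled base case plus overrides.

    Parameters
    ----------
    source
        Optional YAML/JSON file path or mapping whose keys override the
        bundled base-case document.  SMS unit costs may be given either as
        totals (``cost_sms_year1``/``cost_sms_year2``) or via the
        ``cost_components`` block, in which case totals are summed from
        the components.
    **overrides
        Field-level overrides applied last (highest precedence).

    Raises
    ------
    ParameterError
        If any resulting field violates its bounds, naming the field.
    """
    doc = _bundled_defaults()
    if source is not None:
        if isinstance(source, Mapping):
            user = dict(source)
        else:
            with open(source, "r") as fh:
                user = yaml.safe_load(fh) or {}
        doc.update(user)
    doc.update(overrides)

    # Component-level unit costs are authoritative: totals are summed from
    # them unless a total is given explicitly.
    components = dict(doc.get("cost_components") or _DEFAULT_COST_COMPONENTS)
    doc["cost_components"] = components
    if doc.get("cost_sms_year1") is None:
        doc["cost_sms_year1"] = components["delivery_year1"] + components["staff_year1"]
    if doc.get("cost_sms_year2") is None:
        doc["cost_sms_year2"] = components["delivery_year2"] + components["staff_year2"]

    ranges = doc.get("sensitivity_ranges") or {}
    merged = dict(_DEFAULT_RANGES)
    for k, v in ranges.items():
        merged[k] = (float(v[0]), float(v[1]))
    doc["sensitivity_ranges"] = merged

    known = {f.name for f in fields(ParameterSet)}
    unknown = set(doc) - known
    if unknown:
        raise ParameterError(
            sorted(unknown)[0], doc[sorted(unknown)[0]], f"unknown parameter(s): {sorted(unknown)}"
        )
    return ParameterSet(**doc)
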