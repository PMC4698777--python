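"""Discounted cost, life-year and QALY accrual, and incremental outcomes.

Accrual conventions: the annual T2DM medical cost is charged on the
end-of-cycle diabetic occupancy (a subject pays the full annual cost in
the onset year); the SMS programme cost is charged, in cycles 1-2 of the
SMS strategy only, on the retained alive non-diabetic mass at cycle start
after drop-out — drop-outs incur no programme cost.  Life years and QALYs
are evaluated on end-of-cycle occupancy; the dead state carries zero cost
and zero utility.  All three streams are discounted with end-of-cycle
weights ``(1 + r)**(-t)``.  Cumulative T2DM onset is a clinical event
count and is reported undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import CohortTrace, State, Strategy
from .parameters import ParameterSet

__all__ = ["EconomicSummary", "IncrementalResult", "accrue", "compare",
           "DOMINANT", "DOMINATED"]

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class EconomicSummary:
    """Per-subject discounted totals for one strategy over one horizon."""

    strategy: Strategy
    horizon: int
    cost: float
    cost_t2dm_component: float
    cost_intervention_component: float
    life_years: float
    qalys: float
    onset: float

    def __post_init__(self) -> None:
        if self.cost < 0 or not 0.0 <= self.onset <= 1.0 + 1e-12:
            raise ValueError("economic summary outside feasible bounds")


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental outcomes of intervention minus comparator.

    Effect deltas are oriented so that positive means the intervention is
    better (onsets *prevented*, life years and QALYs *gained*).  Each ICER
    is a float when the cost and effect deltas share a sign, the string
    ``"dominant"``/``"dominated"`` when one strategy is both cheaper and
    more effective, and ``None`` when the effect delta is zero (ratio
    undefined).
    """

    delta_cost: float
    delta_onset: float
    delta_ly: float
    delta_qaly: float
    icer_per_onset_prevented: float | str | None
    icer_per_ly: float | str | None
    icer_per_qaly: float | str | None

    @property
    def is_dominant(self) -> bool:
        """True when the intervention is cheaper and gains QALYs."""
        return self.delta_cost < 0 and self.delta_qaly > 0


def accrue(trace: CohortTrace, params: ParameterSet) -> EconomicSummary:
    """Accrue discounted economics over a cohort trace.

    ``params`` must be the ParameterSet the trace was generated under; a
    mismatch is an error because costs and utilities must be consistent
    with the transition structure.
    """
    if params != trace.params:
        raise ValueError("trace was generated under a different ParameterSet")
    H = trace.horizon
    t = np.arange(1, H + 1)
    df = (1.0 + params.discount_rate) ** (-t.astype(float))

    occ_end = trace.occupancy[1:]
    cost_t2dm = params.cost_t2dm_annual * occ_end[:, State.T2DM]

    cost_int = np.zeros(H)
    if trace.strategy is Strategy.SMS:
        exposure = (
            trace.igt_ret_exposure
            if params.intervention_cost_states == "igt_only"
            else trace.ret_exposure
        )
        if H >= 1:
            cost_int[0] = params.cost_sms_year1 * exposure[0]
        if H >= 2:
            cost_int[1] = params.cost_sms_year2 * exposure[1]

    u = params.utilities()
    util_vec = np.array([u["ngt"], u["igt"], u["ngt"], u["igt"], u["t2dm"], u["dead"]])
    ly = 1.0 - occ_end[:, State.DEAD]
    qaly = occ_end @ util_vec

    return EconomicSummary(
        strategy=trace.strategy,
        horizon=H,
        cost=float(((cost_t2dm + cost_int) * df).sum()),
        cost_t2dm_component=float((cost_t2dm * df).sum()),
        cost_intervention_component=float((cost_int * df).sum()),
        life_years=float((ly * df).sum()),
        qalys=float((qaly * df).sum()),
        onset=trace.cumulative_onset,
    )


def _icer(delta_cost: float, delta_effect: float) -> float | str | None:
    if delta_effect == 0:
        return None
    if delta_cost < 0 and delta_effect > 0:
        return DOMINANT
    if delta_cost > 0 and delta_effect < 0:
        return DOMINATED
    return delta_cost / delta_effect


def compare(intervention: EconomicSummary, comparator: EconomicSummary) -> IncrementalResult:
    """Incremental cost-effectiveness of ``intervention`` versus ``comparator``."""
    if intervention.horizon != comparator.horizon:
        raise ValueError("summaries cover different horizons")
    d_cost = intervention.cost - comparator.cost
    d_onset = comparator.onset - intervention.onset
    d_ly = intervention.life_years - comparator.life_years
    d_qaly = intervention.qalys - comparator.qalys
    return IncrementalResult(
        delta_cost=d_cost,
        delta_onset=d_onset,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer_per_onset_prevented=_icer(d_cost, d_onset),
        icer_per_ly=_icer(d_cost, d_ly),
        icer_per_qaly=_icer(d_cost, d_qaly),
    )
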