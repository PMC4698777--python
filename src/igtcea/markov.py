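"""Cohort state-transition engine.

Four health states — normal glucose tolerance (NGT), impaired glucose
tolerance (IGT), type 2 diabetes (T2DM) and death — are expanded to six by
splitting NGT and IGT into *retained* (still receiving the SMS programme)
and *dropped* strata.  The split only carries mass for the SMS strategy
during the two-year intervention window; the control cohort, drop-outs,
and everyone after the window live in the ``_drop`` strata, which evolve
with control-arm probabilities and incur no programme cost.  T2DM is
absorbing except for death (subjects who convert stop receiving SMS), and
death is absorbing.

Within a cycle the composition order is mortality-first: the state-specific
death probability is applied, and the published inter-state probabilities
act on the surviving mass (scaled by ``1 - q``).  This keeps every row of
the transition matrix exactly stochastic across the whole sensitivity
range.  Drop-out is applied at the *start* of cycles 1 and 2, before any
transition, so the year-1 onset probability in the SMS arm is a
drop-out-weighted mixture of the treated and control probabilities; with
100% year-1 drop-out the SMS cohort is identical to control from the first
transition onward.  Retention labels persist through NGT<->IGT moves during
the window (messages were sent for two years regardless of interim
glycaemic state).  No half-cycle correction is applied; occupancy is
evaluated at cycle end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .parameters import ParameterError, ParameterSet, adjusted_mortality

__all__ = ["State", "Strategy", "CohortTrace", "build_transition_matrix",
           "apply_dropout", "run_cohort", "N_STATES"]


class State(IntEnum):
    NGT_RET = 0
    IGT_RET = 1
    NGT_DROP = 2
    IGT_DROP = 3
    T2DM = 4
    DEAD = 5


N_STATES = len(State)

STATE_LABELS = {
    State.NGT_RET: "NGT (retained)",
    State.IGT_RET: "IGT (retained)",
    State.NGT_DROP: "NGT",
    State.IGT_DROP: "IGT",
    State.T2DM: "T2DM",
    State.DEAD: "Dead",
}

# utility key per state, for QALY weighting
STATE_UTILITY_KEY = {
    State.NGT_RET: "ngt",
    State.IGT_RET: "igt",
    State.NGT_DROP: "ngt",
    State.IGT_DROP: "igt",
    State.T2DM: "t2dm",
    State.DEAD: "dead",
}

_ROW_SUM_TOL = 1e-9


class Strategy(str, Enum):
    SMS = "sms"
    CONTROL = "control"


def _igt_row(q: float, p_onset: float, p_regress: float,
             stay: State, to_ngt: State) -> np.ndarray:
    if p_onset + p_regress > 1.0:
        raise ParameterError(
            "p_igt_to_t2dm + p_igt_to_ngt", p_onset + p_regress,
            "competing IGT exit probabilities must sum to <= 1",
        )
    row = np.zeros(N_STATES)
    surv = 1.0 - q
    row[State.T2DM] = p_onset * surv
    row[to_ngt] = p_regress * surv
    row[stay] = (1.0 - p_onset - p_regress) * surv
    row[State.DEAD] = q
    return row


def _ngt_row(q: float, p_relapse: float, stay: State, to_igt: State) -> np.ndarray:
    row = np.zeros(N_STATES)
    surv = 1.0 - q
    row[to_igt] = p_relapse * surv
    row[stay] = (1.0 - p_relapse) * surv
    row[State.DEAD] = q
    return row


def build_transition_matrix(
    cycle_index: int,
    age: float,
    strategy: Strategy,
    params: ParameterSet,
    life_table: LifeTable,
) -> np.ndarray:
    """One-cycle transition matrix for the given cycle, age and strategy.

    Rows/columns are indexed by :class:`State`.  The retained IGT row uses
    the RR-reduced onset probability only for the SMS strategy during
    cycles 1-2; everything else uses control-arm probabilities.  Death
    probabilities come from the life table adjusted by the state mortality
    relative risks (rate-scale adjustment).
    """
    if cycle_index < 1:
        raise ParameterError("cycle_index", cycle_index, "cycles are 1-based")
    q_bg = life_table.death_probability(age)
    q_ngt = q_bg
    q_igt = adjusted_mortality(q_bg, params.rr_mortality_igt)
    q_t2dm = adjusted_mortality(q_bg, params.rr_mortality_t2dm)

    p_onset_ctrl = params.p_onset_control(cycle_index)
    in_window = strategy is Strategy.SMS and cycle_index <= 2
    p_onset_ret = params.p_onset_sms_retained(cycle_index) if in_window else p_onset_ctrl

    P = np.zeros((N_STATES, N_STATES))
    # Retained strata: labels persist through NGT<->IGT moves during the
    # window; outside it any residual retained mass is routed to the
    # dropped strata (run_cohort collapses it anyway).
    if in_window:
        P[State.IGT_RET] = _igt_row(q_igt, p_onset_ret, params.p_igt_to_ngt,
                                    stay=State.IGT_RET, to_ngt=State.NGT_RET)
        P[State.NGT_RET] = _ngt_row(q_ngt, params.p_ngt_to_igt,
                                    stay=State.NGT_RET, to_igt=State.IGT_RET)
    else:
        P[State.IGT_RET] = _igt_row(q_igt, p_onset_ctrl, params.p_igt_to_ngt,
                                    stay=State.IGT_DROP, to_ngt=State.NGT_DROP)
        P[State.NGT_RET] = _ngt_row(q_ngt, params.p_ngt_to_igt,
                                    stay=State.NGT_DROP, to_igt=State.IGT_DROP)
    # Dropped strata always follow control-arm natural history
    P[State.IGT_DROP] = _igt_row(q_igt, p_onset_ctrl, params.p_igt_to_ngt,
                                 stay=State.IGT_DROP, to_ngt=State.NGT_DROP)
    P[State.NGT_DROP] = _ngt_row(q_ngt, params.p_ngt_to_igt,
                                 stay=State.NGT_DROP, to_igt=State.IGT_DROP)
    # T2DM: absorbing except for death
    P[State.T2DM, State.T2DM] = 1.0 - q_t2dm
    P[State.T2DM, State.DEAD] = q_t2dm
    # Death: absorbing
    P[State.DEAD, State.DEAD] = 1.0

    err = np.abs(P.sum(axis=1) - 1.0).max()
    if err > _ROW_SUM_TOL:
        raise RuntimeError(f"transition matrix rows off unity by {err:g}")
    return P


def apply_dropout(occupancy: np.ndarray, cycle_index: int, params: ParameterSet) -> np.ndarray:
    """Move a drop-out fraction of retained mass to the dropped strata.

    Applies at the start of cycle 1 (``dropout_year1`` of retained mass)
    or cycle 2 (``dropout_year2`` of the mass still retained).  Total mass
    is conserved exactly.
    """
    if cycle_index not in (1, 2):
        raise ParameterError("cycle_index", cycle_index, "drop-out occurs at cycles 1 and 2 only")
    d = params.dropout_year1 if cycle_index == 1 else params.dropout_year2
    occ = np.array(occupancy, dtype=float)
    for ret, drop in ((State.NGT_RET, State.NGT_DROP), (State.IGT_RET, State.IGT_DROP)):
        moved = d * occ[ret]
        occ[ret] -= moved
        occ[drop] += moved
    return occ


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle record of a deterministic cohort run.

    ``occupancy`` has ``horizon + 1`` rows (row 0 is the initial state,
    row t the end of cycle t) over the six expanded states.  ``onsets``
    holds the new mass entering T2DM each cycle; ``ret_exposure`` and
    ``igt_ret_exposure`` the retained alive non-diabetic mass at cycle
    start (after drop-out), which carries the programme cost.
    """

    strategy: Strategy
    start_age: float
    horizon: int
    ages: np.ndarray
    occupancy: np.ndarray
    onsets: np.ndarray
    ret_exposure: np.ndarray
    igt_ret_exposure: np.ndarray
    params: ParameterSet = field(repr=False)

    @property
    def cumulative_onset(self) -> float:
        """Undiscounted cumulative T2DM onset, as a fraction of the cohort."""
        return float(self.onsets.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(cycle, state) occupancy table."""
        cycles = np.repeat(np.arange(self.horizon + 1), N_STATES)
        states = np.tile([s.name for s in State], self.horizon + 1)
        return pd.DataFrame(
            {"cycle": cycles, "state": states, "occupancy": self.occupancy.ravel()}
        )

    def summary_frame(self) -> pd.DataFrame:
        """Per-cycle summary: age, new onsets, alive and diabetic mass."""
        return pd.DataFrame(
            {
                "cycle": np.arange(1, self.horizon + 1),
                "age": self.ages,
                "new_onsets": self.onsets,
                "alive": 1.0 - self.occupancy[1:, State.DEAD],
                "t2dm": self.occupancy[1:, State.T2DM],
                "retained_exposure": self.ret_exposure,
            }
        )


def run_cohort(
    strategy: Strategy,
    params: ParameterSet,
    life_table: LifeTable,
    horizon: int | None = None,
    start_age: float | None = None,
) -> CohortTrace:
    """Propagate a cohort that starts 100% in IGT through ``horizon`` cycles.

    The SMS cohort starts in the retained IGT stratum and the control
    cohort in the dropped-equivalent stratum.  Each cycle applies
    drop-out (SMS, cycles 1-2), collapses any residual retained mass after
    the window, then multiplies by the cycle's transition matrix.  Fully
    deterministic.
    """
    strategy = Strategy(strategy)
    H = int(horizon if horizon is not None else params.horizon_years)
    age0 = float(start_age if start_age is not None else params.start_age)
    if H < 1:
        raise ParameterError("horizon", H, "must be >= 1")
    if not life_table.covers(age0, age0 + H - 1):
        raise ParameterError(
            "life_table", (life_table.min_age, life_table.max_age),
            f"must cover ages [{age0}, {age0 + H - 1}]; extend the table",
        )

    occ = np.zeros(N_STATES)
    occ[State.IGT_RET if strategy is Strategy.SMS else State.IGT_DROP] = 1.0

    occupancy = np.zeros((H + 1, N_STATES))
    occupancy[0] = occ
    onsets = np.zeros(H)
    ret_exposure = np.zeros(H)
    igt_ret_exposure = np.zeros(H)
    ages = age0 + np.arange(H)

    live = [s for s in State if s != State.T2DM]
    for t in range(1, H + 1):
        age = age0 + t - 1
        if strategy is Strategy.SMS and t in (1, 2):
            occ = apply_dropout(occ, t, params)
        if t > 2 and (occ[State.NGT_RET] or occ[State.IGT_RET]):
            # intervention window over: collapse retained strata
            occ = occ.copy()
            occ[State.NGT_DROP] += occ[State.NGT_RET]
            occ[State.IGT_DROP] += occ[State.IGT_RET]
            occ[State.NGT_RET] = occ[State.IGT_RET] = 0.0
        if strategy is Strategy.SMS and t <= 2:
            ret_exposure[t - 1] = occ[State.NGT_RET] + occ[State.IGT_RET]
            igt_ret_exposure[t - 1] = occ[State.IGT_RET]
        P = build_transition_matrix(t, age, strategy, params, life_table)
        onsets[t - 1] = float(occ[live] @ P[live, State.T2DM])
        occ = occ @ P
        occupancy[t] = occ

    return CohortTrace(
        strategy=strategy,
        start_age=age0,
        horizon=H,
        ages=ages,
        occupancy=occupancy,
        onsets=onsets,
        ret_exposure=ret_exposure,
        igt_ret_exposure=igt_ret_exposure,
        params=params,
    )
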