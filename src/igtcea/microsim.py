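"""Individual-level Monte Carlo oracle and synthetic trial cohorts.

The cohort engine propagates *expected* state occupancies; this module
realises the same per-cycle probabilities at the individual level, so the
law of large numbers provides an independent check: empirical state
frequencies from ``n`` simulated subjects must bracket the deterministic
trace within binomial sampling error.  A second generator emulates the
two-arm trial structure behind the intervention's relative risks, for
parameter-recovery tests (can an empirical RR computed from simulated
individual outcomes recover the input RR?).

All randomness flows through one ``numpy.random.Generator`` seeded per
run, so every estimate is bit-reproducible given ``(seed, n)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .markov import N_STATES, State, Strategy, build_transition_matrix
from .parameters import ParameterError, ParameterSet, discount_factor

__all__ = ["MicrosimEstimate", "microsimulate", "generate_trial_cohort", "empirical_rr"]


@dataclass(frozen=True)
class MicrosimEstimate:
    """Empirical analogue of a cohort trace plus Monte Carlo economics.

    ``state_freq[t, s]`` is the fraction of subjects in state ``s`` at the
    end of cycle ``t`` (row 0 = initial); ``state_se`` the matching
    binomial standard errors ``sqrt(p(1-p)/n)``.
    """

    strategy: Strategy
    n: int
    seed: int
    state_freq: np.ndarray
    state_se: np.ndarray
    cumulative_onset: float
    mean_cost: float
    se_cost: float
    mean_life_years: float
    se_life_years: float
    mean_qalys: float
    se_qalys: float


def microsimulate(
    strategy: Strategy,
    params: ParameterSet,
    life_table: LifeTable,
    n: int,
    seed: int,
    horizon: int | None = None,
    start_age: float | None = None,
) -> MicrosimEstimate:
    """Simulate ``n`` subjects through the same per-cycle probabilities.

    Drop-out is sampled per subject at the start of cycles 1-2
    (SMS strategy); transitions are sampled from the cycle's transition
    matrix rows (which already compose mortality first).  Per-subject
    discounted cost, life years and QALYs use the same accrual
    conventions as the deterministic economics layer.
    """
    strategy = Strategy(strategy)
    if n < 1:
        raise ParameterError("n", n, "need at least one subject")
    H = int(horizon if horizon is not None else params.horizon_years)
    age0 = float(start_age if start_age is not None else params.start_age)
    rng = np.random.default_rng(seed)

    state = np.full(n, State.IGT_RET if strategy is Strategy.SMS else State.IGT_DROP,
                    dtype=np.int64)
    disc_cost = np.zeros(n)
    disc_ly = np.zeros(n)
    disc_qaly = np.zeros(n)
    ever_t2dm = np.zeros(n, dtype=bool)

    u = params.utilities()
    util_vec = np.array([u["ngt"], u["igt"], u["ngt"], u["igt"], u["t2dm"], u["dead"]])
    freq = np.zeros((H + 1, N_STATES))
    freq[0] = np.bincount(state, minlength=N_STATES) / n

    for t in range(1, H + 1):
        age = age0 + t - 1
        if strategy is Strategy.SMS and t in (1, 2):
            d = params.dropout_year1 if t == 1 else params.dropout_year2
            for ret, drop in ((State.NGT_RET, State.NGT_DROP),
                              (State.IGT_RET, State.IGT_DROP)):
                mask = state == ret
                leaves = mask & (rng.random(n) < d)
                state[leaves] = drop
        if t > 2:
            state[state == State.NGT_RET] = State.NGT_DROP
            state[state == State.IGT_RET] = State.IGT_DROP

        df = discount_factor(params.discount_rate, t)
        if strategy is Strategy.SMS and t <= 2:
            if params.intervention_cost_states == "igt_only":
                exposed = state == State.IGT_RET
            else:
                exposed = (state == State.NGT_RET) | (state == State.IGT_RET)
            unit = params.cost_sms_year1 if t == 1 else params.cost_sms_year2
            disc_cost[exposed] += unit * df

        P = build_transition_matrix(t, age, strategy, params, life_table)
        cum = np.cumsum(P, axis=1)
        draws = rng.random(n)
        new_state = state.copy()
        for s in range(N_STATES):
            mask = state == s
            if mask.any():
                new_state[mask] = np.searchsorted(cum[s], draws[mask], side="right")
        np.minimum(new_state, N_STATES - 1, out=new_state)  # guard float edge
        ever_t2dm |= new_state == State.T2DM
        state = new_state

        disc_cost[state == State.T2DM] += params.cost_t2dm_annual * df
        disc_ly += (state != State.DEAD) * df
        disc_qaly += util_vec[state] * df
        freq[t] = np.bincount(state, minlength=N_STATES) / n

    se = np.sqrt(freq * (1.0 - freq) / n)
    return MicrosimEstimate(
        strategy=strategy,
        n=n,
        seed=seed,
        state_freq=freq,
        state_se=se,
        cumulative_onset=float(ever_t2dm.mean()),
        mean_cost=float(disc_cost.mean()),
        se_cost=float(disc_cost.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        mean_life_years=float(disc_ly.mean()),
        se_life_years=float(disc_ly.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        mean_qalys=float(disc_qaly.mean()),
        se_qalys=float(disc_qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
    )


def generate_trial_cohort(n: int, params: ParameterSet, seed: int) -> pd.DataFrame:
    """Simulate a two-arm prevention trial of ``n`` subjects per arm.

    Emulates the statistical structure behind the trial-derived relative
    risks: every subject starts in IGT; SMS-arm subjects may drop out at
    the start of each year (drop-outs revert to the control onset
    probability); annual onset is a Bernoulli draw at the arm- and
    retention-specific probability.  Mortality is ignored over the
    two-year trial window.  Returns one row per subject with columns
    ``arm`` (``sms``/``control``), ``dropout_y1``, ``dropout_y2``,
    ``onset_y1``, ``onset_y2``.
    """
    if n < 1:
        raise ParameterError("n", n, "need at least one subject per arm")
    rng = np.random.default_rng(seed)
    p_ctrl = params.p_onset_control(1)
    p_sms_y1 = params.p_onset_sms_retained(1)
    p_sms_y2 = params.p_onset_sms_retained(2)

    frames = []
    for arm in ("control", "sms"):
        if arm == "sms":
            drop1 = rng.random(n) < params.dropout_year1
            drop2 = drop1 | (rng.random(n) < params.dropout_year2)
            p1 = np.where(drop1, p_ctrl, p_sms_y1)
            p2 = np.where(drop2, params.p_onset_control(2), p_sms_y2)
        else:
            drop1 = np.zeros(n, dtype=bool)
            drop2 = np.zeros(n, dtype=bool)
            p1 = np.full(n, p_ctrl)
            p2 = np.full(n, params.p_onset_control(2))
        onset1 = rng.random(n) < p1
        onset2 = ~onset1 & (rng.random(n) < p2)
        frames.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "dropout_y1": drop1,
                    "dropout_y2": drop2,
                    "onset_y1": onset1,
                    "onset_y2": onset2,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def empirical_rr(records: pd.DataFrame, year: int = 1) -> float:
    """Complete-case relative risk of onset, SMS versus control.

    Year-1 RR compares SMS subjects retained through year 1 with all
    controls; year-2 RR conditions on no year-1 onset and retention
    through year 2.
    """
    if year not in (1, 2):
        raise ParameterError("year", year, "trial records cover years 1 and 2")
    ctrl = records[records["arm"] == "control"]
    sms = records[records["arm"] == "sms"]
    if year == 1:
        completers = sms[~sms["dropout_y1"]]
        risk_sms = completers["onset_y1"].mean()
        risk_ctrl = ctrl["onset_y1"].mean()
    else:
        completers = sms[~sms["dropout_y2"] & ~sms["onset_y1"]]
        at_risk_ctrl = ctrl[~ctrl["onset_y1"]]
        risk_sms = completers["onset_y2"].mean()
        risk_ctrl = at_risk_ctrl["onset_y2"].mean()
    if risk_ctrl == 0:
        raise ZeroDivisionError("no control-arm onsets; RR undefined")
    return float(risk_sms / risk_ctrl)
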