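"""Cohort Markov engine: transition matrices, traces, discounted accrual.

One cycle is one year.  The cohort is run until the death state holds at
least ``1 - absorption_tol`` of the cohort or ``max_cycles`` cycles have
accrued, whichever comes first.  Cycle ``t`` rewards are discounted by
``(1 + r) ** -t`` (the first cycle is undiscounted); an optional
half-cycle correction halves the first and last cycle rewards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelSettings, ParameterDraw, ParameterSet, mean_draw
from .states import ARM_STATES, Arm, HealthState

__all__ = [
    "TransitionMatrix",
    "CohortTrace",
    "ArmResult",
    "ContractError",
    "build_transition_matrix",
    "run_cohort",
    "accrue_outcomes",
    "run_arm",
    "run_base_case",
    "trace_frame",
]

ROW_TOL = 1e-9


class ContractError(ValueError):
    """An engine precondition was violated."""


_TRANSITION_IDS = {
    Arm.ICD: {
        (HealthState.HOSPITALIZATION, HealthState.WELL): "tp_icd_hosp_to_well",
        (HealthState.HOSPITALIZATION, HealthState.DEATH): "tp_icd_hosp_to_death",
        (HealthState.COMPLICATION, HealthState.WELL): "tp_icd_compl_to_well",
        (HealthState.COMPLICATION, HealthState.REJECTION): "tp_icd_compl_to_rejection",
        (HealthState.COMPLICATION, HealthState.DEATH): "tp_icd_compl_to_death",
        (HealthState.REJECTION, HealthState.WELL): "tp_icd_rej_to_well",
        (HealthState.REJECTION, HealthState.DEATH): "tp_icd_rej_to_death",
        (HealthState.WELL, HealthState.HOSPITALIZATION): "tp_icd_well_to_hosp",
        (HealthState.WELL, HealthState.COMPLICATION): "tp_icd_well_to_compl",
        (HealthState.WELL, HealthState.DEATH): "tp_icd_well_to_death",
    },
    Arm.PHARM: {
        (HealthState.HOSPITALIZATION, HealthState.WELL): "tp_pharm_hosp_to_well",
        (HealthState.HOSPITALIZATION, HealthState.DEATH): "tp_pharm_hosp_to_death",
        (HealthState.WELL, HealthState.HOSPITALIZATION): "tp_pharm_well_to_hosp",
        (HealthState.WELL, HealthState.DEATH): "tp_pharm_well_to_death",
    },
}


@dataclass(frozen=True)
class TransitionMatrix:
    arm: Arm
    states: tuple[HealthState, ...]
    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        n = len(self.states)
        if p.shape != (n, n):
            raise ContractError(f"matrix shape {p.shape} != ({n}, {n})")
        if np.any(p < -ROW_TOL) or np.any(p > 1.0 + ROW_TOL):
            raise ContractError("transition probabilities outside [0, 1]")
        rowsums = p.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-8):
            bad = self.states[int(np.argmax(np.abs(rowsums - 1.0)))]
            raise ContractError(f"row {bad.value} sums to {rowsums.max()!r}, not 1")
        death = self.states.index(HealthState.DEATH)
        ident = np.zeros(n)
        ident[death] = 1.0
        if not np.allclose(p[death], ident, atol=ROW_TOL):
            raise ContractError("death row is not absorbing")

    @property
    def death_index(self) -> int:
        return self.states.index(HealthState.DEATH)


def build_transition_matrix(arm: Arm, draw: ParameterDraw) -> TransitionMatrix:
    """Assemble the arm's row-stochastic matrix from a parameter draw.

    The well-state residual (staying well) is one minus the free exit
    probabilities; a negative residual is a validation error.
    """
    states = tuple(ARM_STATES[arm])
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    p = np.zeros((n, n))
    for (src, dst), pid in _TRANSITION_IDS[arm].items():
        p[idx[src], idx[dst]] = draw[pid]
    # residuals: well stays well; death absorbs
    well = idx[HealthState.WELL]
    exit_mass = p[well].sum()
    if exit_mass > 1.0 + ROW_TOL:
        raise ContractError(
            f"well-state exits ({arm.value}) sum to {exit_mass}; residual negative"
        )
    p[well, well] = max(1.0 - exit_mass, 0.0)
    p[idx[HealthState.DEATH], idx[HealthState.DEATH]] = 1.0
    return TransitionMatrix(arm=arm, states=states, probs=p)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy; row ``t`` is the start of cycle ``t``."""

    states: tuple[HealthState, ...]
    occupancy: np.ndarray  # (n_cycles, n_states)
    entered_death: np.ndarray  # (n_cycles,)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]


def run_cohort(
    matrix: TransitionMatrix,
    initial: np.ndarray | HealthState | None = None,
    max_cycles: int = 100,
    absorption_tol: float = 1e-4,
) -> CohortTrace:
    """Propagate the cohort, recording occupancy and new deaths per cycle."""
    if max_cycles < 1:
        raise ContractError("max_cycles must be >= 1")
    n = len(matrix.states)
    if initial is None:
        initial = HealthState.HOSPITALIZATION
    if isinstance(initial, HealthState):
        occ0 = np.zeros(n)
        occ0[matrix.states.index(initial)] = 1.0
    else:
        occ0 = np.asarray(initial, dtype=float)
        if occ0.shape != (n,) or abs(occ0.sum() - 1.0) > 1e-9 or np.any(occ0 < 0):
            raise ContractError("initial occupancy must be a distribution over states")
    death = matrix.death_index
    occ_rows = [occ0]
    entered = [0.0]
    occ = occ0
    while len(occ_rows) < max_cycles and occ[death] < 1.0 - absorption_tol:
        new = occ @ matrix.probs
        entered.append(new[death] - occ[death])
        occ_rows.append(new)
        occ = new
    return CohortTrace(
        states=matrix.states,
        occupancy=np.vstack(occ_rows),
        entered_death=np.asarray(entered),
    )


@dataclass(frozen=True)
class ArmResult:
    """Discounted lifetime totals for one strategy."""

    arm: Arm
    discounted_cost: float
    discounted_qaly: float
    trace: CohortTrace | None = None


def accrue_outcomes(
    trace: CohortTrace,
    arm: Arm,
    draw: ParameterDraw,
    params: ParameterSet,
    r_cost: float = 0.06,
    r_outcome: float = 0.03,
    half_cycle: bool = False,
    cycle_length: float = 1.0,
) -> ArmResult:
    """Discounted cost and QALY totals along a cohort trace.

    Live states accrue their per-cycle cost and utility; death accrues a
    one-time transition cost on the fraction newly dead each cycle and
    nothing thereafter.
    """
    live = [s for s in trace.states if s is not HealthState.DEATH]
    try:
        costs = np.array([draw.cost(params, arm, s) for s in live])
        utils = np.array([draw.utility(params, arm, s) for s in live])
        death_cost = draw.cost(params, arm, HealthState.DEATH)
    except KeyError as exc:
        raise ContractError(str(exc)) from None
    T = trace.n_cycles
    t = np.arange(T)
    disc_c = (1.0 + r_cost) ** -t
    disc_o = (1.0 + r_outcome) ** -t
    weights = np.ones(T)
    if half_cycle:
        weights[0] = 0.5
        weights[-1] = 0.5
    live_idx = [trace.states.index(s) for s in live]
    occ_live = trace.occupancy[:, live_idx]
    cost_increments = weights * disc_c * (occ_live @ costs)
    cost_increments = cost_increments + disc_c * trace.entered_death * death_cost
    qaly_increments = weights * disc_o * (occ_live @ utils) * cycle_length
    return ArmResult(
        arm=arm,
        discounted_cost=float(cost_increments.sum()),
        discounted_qaly=float(qaly_increments.sum()),
        trace=trace,
    )


def run_arm(
    params: ParameterSet,
    arm: Arm,
    draw: ParameterDraw | None = None,
    settings: ModelSettings | None = None,
) -> ArmResult:
    """Build the matrix, run the cohort and accrue outcomes for one arm."""
    s = settings or params.settings
    if draw is None:
        draw = mean_draw(params)
    matrix = build_transition_matrix(arm, draw)
    trace = run_cohort(
        matrix,
        initial=s.initial_state,
        max_cycles=s.max_cycles,
        absorption_tol=s.absorption_tol,
    )
    return accrue_outcomes(
        trace,
        arm,
        draw,
        params,
        r_cost=s.discount_rate_cost,
        r_outcome=s.discount_rate_outcome,
        half_cycle=s.half_cycle,
        cycle_length=s.cycle_length,
    )


def run_base_case(params: ParameterSet) -> dict[Arm, ArmResult]:
    """Deterministic run of both arms with every parameter at its mean."""
    draw = mean_draw(params)
    return {arm: run_arm(params, arm, draw=draw) for arm in Arm}


def trace_frame(result: ArmResult, params: ParameterSet) -> pd.DataFrame:
    """Per-cycle trace with discounted increments, ready for CSV export."""
    trace = result.trace
    if trace is None:
        raise ContractError("result carries no trace")
    s = params.settings
    draw = mean_draw(params)
    live = [st for st in trace.states if st is not HealthState.DEATH]
    costs = np.array([draw.cost(params, result.arm, st) for st in live])
    utils = np.array([draw.utility(params, result.arm, st) for st in live])
    death_cost = draw.cost(params, result.arm, HealthState.DEATH)
    t = np.arange(trace.n_cycles)
    disc_c = (1.0 + s.discount_rate_cost) ** -t
    disc_o = (1.0 + s.discount_rate_outcome) ** -t
    live_idx = [trace.states.index(st) for st in live]
    occ_live = trace.occupancy[:, live_idx]
    frame = pd.DataFrame(trace.occupancy, columns=[st.value for st in trace.states])
    frame.insert(0, "cycle", t)
    frame["entered_death"] = trace.entered_death
    frame["discounted_cost_increment"] = disc_c * (
        occ_live @ costs + trace.entered_death * death_cost
    )
    frame["discounted_qaly_increment"] = disc_o * (occ_live @ utils) * s.cycle_length
    return frame
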