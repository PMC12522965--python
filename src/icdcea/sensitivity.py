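"""Deterministic and probabilistic sensitivity analyses.

One-way analysis swings a single parameter over its 95% range (normal
approximation, +/-25% where no SD is published) and records the ICER at
each bound; the tornado sorts those swings by width.  The two-way
analysis maps the preferred strategy over a lattice of two parameters.
The PSA samples every distribution-tagged parameter per iteration with
an independent, reproducible substream and feeds the cost-effectiveness
acceptability curve and CE-plane scatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ArmResult, run_arm
from .metrics import icer, nmb
from .parameters import (
    ParameterSet,
    ci95_bounds,
    draw_at,
    mean_draw,
    sample_parameters,
)
from .states import Arm, HealthState

__all__ = [
    "TornadoEntry",
    "PSASample",
    "CEACCurve",
    "dsa_bounds",
    "one_way_dsa",
    "tornado",
    "two_way_dsa",
    "run_psa",
    "ceac",
    "ceac_at",
    "ce_scatter_export",
    "default_wtp_grid",
]

#: Settings-level parameters that the DSA can vary alongside table rows.
SETTING_PARAMETERS = ("discount_rate_cost", "discount_rate_outcome")


@dataclass(frozen=True)
class TornadoEntry:
    parameter_id: str
    low_value: float
    high_value: float
    low_icer: float | None
    high_icer: float | None

    @property
    def range_width(self) -> float:
        if self.low_icer is None or self.high_icer is None:
            return float("inf")
        return abs(self.high_icer - self.low_icer)


def dsa_bounds(params: ParameterSet, parameter_id: str) -> tuple[float, float]:
    """95% swing range for one parameter (discount rates use their stated range)."""
    if parameter_id in SETTING_PARAMETERS:
        return params.settings.discount_range
    return ci95_bounds(params.spec(parameter_id), params.domain(parameter_id))


def _icer_at(params: ParameterSet, parameter_id: str, value: float) -> float | None:
    """Base-case ICER with one parameter pinned to ``value``; None if invalid."""
    try:
        if parameter_id in SETTING_PARAMETERS:
            p = params.with_settings(**{parameter_id: value})
            draw = mean_draw(p)
        else:
            p = params
            draw = draw_at(params, {parameter_id: value})
        results = {arm: run_arm(p, arm, draw=draw) for arm in Arm}
        cea = icer(results[Arm.ICD], results[Arm.PHARM], wtp=p.settings.wtp)
    except (ValueError, KeyError) as exc:
        warnings.warn(f"DSA bound {parameter_id}={value} invalid: {exc}")
        return None
    return cea.icer if cea.icer is not None else None


def one_way_dsa(
    params: ParameterSet,
    parameter_id: str,
    bounds: tuple[float, float] | None = None,
) -> TornadoEntry:
    """Evaluate the ICER at both bounds with everything else at base case."""
    low, high = bounds if bounds is not None else dsa_bounds(params, parameter_id)
    return TornadoEntry(
        parameter_id=parameter_id,
        low_value=low,
        high_value=high,
        low_icer=_icer_at(params, parameter_id, low),
        high_icer=_icer_at(params, parameter_id, high),
    )


def default_dsa_parameter_ids(params: ParameterSet) -> list[str]:
    """Parameters the one-way analysis varies by default.

    SD-less *stated* transition probabilities (hospitalization->well and
    friends) are complements of their beta-tagged siblings, so swinging
    them independently would double-count that uncertainty; they are
    excluded.  Costs, utilities, distribution-tagged transitions, free
    (calibrated) transitions and the two discount rates are all varied.
    """
    pids = []
    for pid in params.parameter_ids():
        row = params.rows[pid]
        if (
            row.category == "transition"
            and row.spec.is_fixed
            and row.source_state is not HealthState.WELL
        ):
            continue
        pids.append(pid)
    return pids + list(SETTING_PARAMETERS)


def tornado(
    params: ParameterSet, parameter_ids: list[str] | None = None
) -> list[TornadoEntry]:
    """One entry per parameter, widest ICER swing first (ties by id)."""
    if parameter_ids is None:
        parameter_ids = default_dsa_parameter_ids(params)
    entries = [one_way_dsa(params, pid) for pid in parameter_ids]
    return sorted(entries, key=lambda e: (-e.range_width, e.parameter_id))


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter_id": e.parameter_id,
                "low_value": e.low_value,
                "high_value": e.high_value,
                "low_icer": e.low_icer,
                "high_icer": e.high_icer,
                "width": e.range_width,
            }
            for e in entries
        ]
    )


@dataclass(frozen=True)
class TwoWayGrid:
    parameter_a: str
    parameter_b: str
    a_values: np.ndarray
    b_values: np.ndarray
    icd_preferred: np.ndarray  # (len(a), len(b)) booleans
    wtp: float

    def frame(self) -> pd.DataFrame:
        recs = []
        for i, a in enumerate(self.a_values):
            for j, b in enumerate(self.b_values):
                recs.append(
                    {
                        self.parameter_a: a,
                        self.parameter_b: b,
                        "icd_preferred": bool(self.icd_preferred[i, j]),
                    }
                )
        return pd.DataFrame(recs)


def two_way_dsa(
    params: ParameterSet,
    param_a: str,
    range_a: tuple[float, float],
    param_b: str,
    range_b: tuple[float, float],
    grid_n: int = 20,
    wtp: float | None = None,
) -> TwoWayGrid:
    """Preferred strategy (higher NMB) on a grid_n x grid_n lattice."""
    wtp = params.settings.wtp if wtp is None else wtp
    a_vals = np.linspace(range_a[0], range_a[1], grid_n)
    b_vals = np.linspace(range_b[0], range_b[1], grid_n)
    pref = np.zeros((grid_n, grid_n), dtype=bool)
    for i, a in enumerate(a_vals):
        for j, b in enumerate(b_vals):
            draw = draw_at(params, {param_a: a, param_b: b})
            results = {arm: run_arm(params, arm, draw=draw) for arm in Arm}
            pref[i, j] = nmb(results[Arm.ICD], wtp) > nmb(results[Arm.PHARM], wtp)
    return TwoWayGrid(param_a, param_b, a_vals, b_vals, pref, wtp)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSASample:
    """Paired per-iteration lifetime (cost, QALY) results for both arms."""

    seed: int
    cost_icd: np.ndarray
    qaly_icd: np.ndarray
    cost_pharm: np.ndarray
    qaly_pharm: np.ndarray
    n_clamped: int

    @property
    def iterations(self) -> int:
        return self.cost_icd.shape[0]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_icd - self.cost_pharm

    @property
    def delta_effect(self) -> np.ndarray:
        return self.qaly_icd - self.qaly_pharm

    @property
    def clamp_rate(self) -> float:
        return self.n_clamped / self.iterations

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.iterations),
                "cost_icd": self.cost_icd,
                "qaly_icd": self.qaly_icd,
                "cost_pharm": self.cost_pharm,
                "qaly_pharm": self.qaly_pharm,
                "delta_cost": self.delta_cost,
                "delta_effect": self.delta_effect,
            }
        )


def run_psa(
    params: ParameterSet, n_iter: int | None = None, seed: int | None = None
) -> PSASample:
    """Seeded Monte-Carlo run of both arms.

    Iteration ``i`` uses the substream ``default_rng([seed, i])``, so
    growing ``n_iter`` never changes earlier iterations.  Free
    (calibrated) transition probabilities stay at their point values.
    """
    if n_iter is None:
        n_iter = params.settings.psa_iterations
    if seed is None:
        seed = params.settings.seed
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    cost = {arm: np.empty(n_iter) for arm in Arm}
    qaly = {arm: np.empty(n_iter) for arm in Arm}
    n_clamped = 0
    for i in range(n_iter):
        rng = np.random.default_rng([seed, i])
        draw = sample_parameters(params, rng)
        n_clamped += draw.n_clamped
        for arm in Arm:
            res = run_arm(params, arm, draw=draw)
            cost[arm][i] = res.discounted_cost
            qaly[arm][i] = res.discounted_qaly
    sample = PSASample(
        seed=seed,
        cost_icd=cost[Arm.ICD],
        qaly_icd=qaly[Arm.ICD],
        cost_pharm=cost[Arm.PHARM],
        qaly_pharm=qaly[Arm.PHARM],
        n_clamped=n_clamped,
    )
    if sample.clamp_rate > 0.01:
        warnings.warn(
            f"PSA clamped draws in {n_clamped} of {n_iter} iterations "
            f"({100 * sample.clamp_rate:.1f}%)"
        )
    return sample


@dataclass(frozen=True)
class CEACCurve:
    """Acceptability of the intervention across willingness-to-pay values."""

    wtp_grid: np.ndarray
    prob_ce: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "prob_ce": self.prob_ce})


def default_wtp_grid() -> np.ndarray:
    """0 to 50,000 USD/QALY in steps of 500 (brackets threshold and base ICER)."""
    return np.arange(0.0, 50_001.0, 500.0)


def ceac_at(sample: PSASample, wtp: float) -> float:
    """Fraction of iterations in which the intervention has the higher NMB."""
    if sample.iterations == 0:
        raise ValueError("empty PSA sample")
    return float(np.mean(wtp * sample.delta_effect - sample.delta_cost > 0.0))


def ceac(sample: PSASample, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    if sample.iterations == 0:
        raise ValueError("empty PSA sample")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("wtp_grid must be sorted ascending")
    prob = np.array([ceac_at(sample, w) for w in grid])
    return CEACCurve(wtp_grid=grid, prob_ce=prob)


def ce_scatter_export(sample: PSASample, wtp: float | None = None) -> pd.DataFrame:
    """Per-iteration incremental pairs plus the WTP threshold line slope."""
    if sample.iterations == 0:
        raise ValueError("empty PSA sample")
    frame = pd.DataFrame(
        {
            "iteration": np.arange(sample.iterations),
            "delta_effect": sample.delta_effect,
            "delta_cost": sample.delta_cost,
        }
    )
    if wtp is not None:
        frame["wtp_line_slope"] = wtp
    return frame
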