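"""Synthetic inputs: the bundled parameter file, toy oracle models, and
randomized-but-valid parameter sets for property testing."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import parameters as P
from .parameters import (
    CSV_COLUMNS,
    DEFAULT_ROWS,
    ModelSettings,
    ParameterSet,
    _row_from_record,
)
from .states import Arm, HealthState

__all__ = [
    "default_parameter_csv_text",
    "write_default_parameter_file",
    "ToyModelSpec",
    "make_toy_two_state",
    "random_valid_parameter_set",
]


def default_parameter_csv_text() -> str:
    """Canonical serialization of the bundled parameter table."""
    lines = [",".join(CSV_COLUMNS)]
    for pid, arm, cat, src, dst, mean, sd, family in DEFAULT_ROWS:
        lines.append(
            ",".join(
                [
                    pid,
                    arm,
                    cat,
                    src,
                    dst or "",
                    repr(float(mean)),
                    "" if sd is None else repr(float(sd)),
                    family,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_default_parameter_file(path: str | Path) -> Path:
    """Write the bundled parameter CSV; repeated writes are byte-identical."""
    path = Path(path)
    path.write_text(default_parameter_csv_text())
    return path


# ---------------------------------------------------------------------------
# Toy two-state oracle models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModelSpec:
    """Alive/dead chain with closed-form discounted totals.

    An alive state survives with probability ``p_survive`` each cycle and
    accrues ``utility`` QALYs and ``cost`` USD.  Counting the t=0 cycle,
    the discounted total of a per-cycle reward ``w`` is the geometric
    series ``w / (1 - p / (1 + r))``.
    """

    p_survive: float
    utility: float
    cost: float
    r_cost: float = 0.0
    r_outcome: float = 0.0

    def _series(self, reward: float, rate: float) -> float:
        ratio = self.p_survive / (1.0 + rate)
        if ratio >= 1.0:
            raise ValueError(
                "discounted series diverges: p_survive >= 1 + discount rate"
            )
        return reward / (1.0 - ratio)

    @property
    def closed_form_qaly(self) -> float:
        return self._series(self.utility, self.r_outcome)

    @property
    def closed_form_cost(self) -> float:
        return self._series(self.cost, self.r_cost)

    def parameter_rows(self) -> pd.DataFrame:
        """The toy expressed in the standard parameter-file schema.

        The alive state is mapped onto the pharmaceutical arm's well
        state (which the cohort never leaves except to death), so the
        toy exercises the real IO and engine path.
        """
        rows = [
            ("toy_well_to_hosp", "pharm", "transition", "well", "hospitalization", 0.0, "", "fixed"),
            ("toy_well_to_death", "pharm", "transition", "well", "death", 1.0 - self.p_survive, "", "fixed"),
            ("toy_cost_well", "pharm", "cost", "well", "", self.cost, "", "fixed"),
            ("toy_util_well", "pharm", "utility", "well", "", self.utility, "", "fixed"),
            ("toy_cost_death", "pharm", "cost", "death", "", 0.0, "", "fixed"),
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def to_parameter_set(
        self, max_cycles: int = 5000, absorption_tol: float = 1e-10
    ) -> ParameterSet:
        """A ParameterSet whose PHARM arm reproduces the toy chain."""
        overrides = {
            "tp_pharm_well_to_hosp": ("transition", 0.0),
            "tp_pharm_well_to_death": ("transition", 1.0 - self.p_survive),
            "cost_pharm_well": ("cost", self.cost),
            "util_pharm_well": ("utility", self.utility),
            "cost_pharm_death": ("cost", 0.0),
        }
        ps = P.default_parameter_set()
        for pid, (_cat, value) in overrides.items():
            ps = ps.with_parameter(pid, value)
        return ps.with_settings(
            initial_state=HealthState.WELL,
            max_cycles=max_cycles,
            absorption_tol=absorption_tol,
            discount_rate_cost=self.r_cost,
            discount_rate_outcome=self.r_outcome,
        )


def make_toy_two_state(
    p_survive: float,
    utility: float = 1.0,
    cost: float = 0.0,
    r_cost: float = 0.0,
    r_outcome: float = 0.0,
) -> ToyModelSpec:
    """Build a two-state oracle chain; ``p_survive`` must lie in [0, 1)."""
    if not 0.0 <= p_survive < 1.0:
        raise ValueError("p_survive must lie in [0, 1)")
    return ToyModelSpec(p_survive, utility, cost, r_cost, r_outcome)


# ---------------------------------------------------------------------------
# Randomized valid parameter sets
# ---------------------------------------------------------------------------

def random_valid_parameter_set(seed: int) -> ParameterSet:
    """A randomized, always-valid parameter set for property testing.

    Exit-probability groups are drawn from a Dirichlet so rows sum to
    one; beta SDs stay below 0.8 * sqrt(m (1 - m)); costs are positive
    with gamma SDs.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    records = {r[0]: list(r[1:]) for r in DEFAULT_ROWS}

    def set_row(pid: str, mean: float, sd: float | None, family: str) -> None:
        rec = records[pid]
        rec[4], rec[5], rec[6] = float(mean), sd, family

    # transition groups (stated): Dirichlet over each state's exits
    groups = {
        "icd_hosp": ("tp_icd_hosp_to_well", "tp_icd_hosp_to_death"),
        "icd_compl": ("tp_icd_compl_to_well", "tp_icd_compl_to_rejection", "tp_icd_compl_to_death"),
        "icd_rej": ("tp_icd_rej_to_well", "tp_icd_rej_to_death"),
        "pharm_hosp": ("tp_pharm_hosp_to_well", "tp_pharm_hosp_to_death"),
    }
    for pids in groups.values():
        probs = rng.dirichlet(np.full(len(pids), 4.0))
        # the death exit (last pid) carries beta uncertainty
        for pid, p in zip(pids, probs):
            p = float(np.clip(p, 1e-4, 1 - 1e-4))
            if pid.endswith("_to_death"):
                sd = 0.8 * np.sqrt(p * (1 - p)) * rng.uniform(0.05, 0.9)
                set_row(pid, p, float(sd), "beta")
            else:
                set_row(pid, p, None, "fixed")
        # exact row sum: residual absorbed by the largest exit
        total = sum(records[pid][4] for pid in pids)
        largest = max(pids, key=lambda pid: records[pid][4])
        records[largest][4] += 1.0 - total

    # free well exits: keep the row feasible
    for pids in (P.FREE_TRANSITION_IDS[Arm.ICD], P.FREE_TRANSITION_IDS[Arm.PHARM]):
        exits = rng.dirichlet(np.full(len(pids) + 1, 2.0))[:-1] * 0.6
        for pid, p in zip(pids, exits):
            set_row(pid, float(p), None, "fixed")

    # costs and utilities
    for pid, rec in records.items():
        cat = rec[1]
        if cat == "cost":
            mean = float(rng.uniform(50.0, 10_000.0))
            sd = float(mean * rng.uniform(0.1, 1.5)) if rec[6] == "gamma" else None
            set_row(pid, mean, sd, rec[6])
        elif cat == "utility":
            mean = float(rng.uniform(0.2, 0.95))
            if rec[6] == "beta":
                sd = float(0.8 * np.sqrt(mean * (1 - mean)) * rng.uniform(0.05, 0.9))
            else:
                sd = None
            set_row(pid, mean, sd, rec[6])

    rows = {
        pid: _row_from_record(dict(zip(CSV_COLUMNS, [pid] + rec)))
        for pid, rec in records.items()
    }
    ps = ParameterSet(rows=rows, settings=ModelSettings(seed=seed))
    ps.validate()
    return ps
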