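"""Model inputs: distributions, parameter table IO, validation and sampling.

The parameter file is a flat CSV with columns
``parameter_id, arm, category, source_state, target_state, mean, sd,
distribution`` plus an optional YAML/JSON settings block for discount
rates, willingness-to-pay, horizon and PSA settings.

Probabilities and utilities carry beta uncertainty, costs gamma
uncertainty; both are fitted from a (mean, SD) pair by the method of
moments.  Quantities without an SD are treated as fixed in probabilistic
analyses and varied +/-25% in deterministic ones.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .states import ARM_STATES, Arm, HealthState

__all__ = [
    "DistributionSpec",
    "ModelSettings",
    "ParameterSet",
    "ParameterDraw",
    "ValidationError",
    "SchemaError",
    "InfeasibleMomentsError",
    "beta_from_moments",
    "gamma_from_moments",
    "fixed_spec",
    "ci95_bounds",
    "sample_spec",
    "load_parameter_table",
    "default_parameter_set",
    "sample_parameters",
    "mean_draw",
    "draw_at",
]

MOMENT_RTOL = 1e-9
#: Relative half-width used for deterministic ranges of SD-less parameters.
FALLBACK_FRACTION = 0.25
#: Rial per USD conversion constant used by the source cost data (documentation
#: only; every amount handled by this package is already in USD).
RIAL_PER_USD = 42_000


class ValidationError(ValueError):
    """A parameter value violates its domain or a feasibility constraint."""


class SchemaError(ValueError):
    """The parameter file does not conform to the expected schema."""


class InfeasibleMomentsError(ValidationError):
    """No distribution of the requested family has the given mean and SD."""


# ---------------------------------------------------------------------------
# Distribution specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """A sampling description fitted from a (mean, SD) pair.

    ``shape1``/``shape2`` are (alpha, beta) for the beta family and
    (shape, scale) for the gamma family; both are ``None`` for fixed
    quantities.
    """

    family: str  # "beta" | "gamma" | "fixed"
    mean: float
    sd: float | None = None
    shape1: float | None = None
    shape2: float | None = None

    @property
    def is_fixed(self) -> bool:
        return self.family == "fixed"

    def analytic_moments(self) -> tuple[float, float]:
        """Mean and SD implied by the fitted shape parameters."""
        if self.family == "beta":
            a, b = self.shape1, self.shape2
            m = a / (a + b)
            v = a * b / ((a + b) ** 2 * (a + b + 1.0))
            return m, math.sqrt(v)
        if self.family == "gamma":
            k, theta = self.shape1, self.shape2
            return k * theta, math.sqrt(k) * theta
        return self.mean, 0.0


def fixed_spec(mean: float) -> DistributionSpec:
    return DistributionSpec(family="fixed", mean=float(mean))


def beta_from_moments(mean: float, sd: float) -> DistributionSpec:
    """Fit a beta distribution by the method of moments.

    alpha = mean * nu, beta = (1 - mean) * nu with
    nu = mean (1 - mean) / sd^2 - 1.  A zero SD degenerates to a fixed
    value; an SD with sd^2 >= mean (1 - mean) is infeasible.
    """
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"beta mean must lie in (0, 1); got {mean!r}")
    if sd < 0.0:
        raise ValidationError(f"sd must be non-negative; got {sd!r}")
    if sd == 0.0:
        return fixed_spec(mean)
    if sd * sd >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"no beta distribution has mean {mean} and sd {sd}: "
            f"requires sd^2 < mean*(1-mean) = {mean * (1 - mean):.6g}"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return DistributionSpec("beta", float(mean), float(sd), mean * nu, (1.0 - mean) * nu)


def gamma_from_moments(mean: float, sd: float) -> DistributionSpec:
    """Fit a gamma distribution by the method of moments.

    shape = mean^2 / sd^2, scale = sd^2 / mean.
    """
    if mean <= 0.0:
        raise ValidationError(f"gamma mean must be positive; got {mean!r}")
    if sd < 0.0:
        raise ValidationError(f"sd must be non-negative; got {sd!r}")
    if sd == 0.0:
        return fixed_spec(mean)
    return DistributionSpec(
        "gamma", float(mean), float(sd), mean * mean / (sd * sd), sd * sd / mean
    )


def spec_from_moments(family: str, mean: float, sd: float | None) -> DistributionSpec:
    if family == "fixed" or sd in (None, 0.0) or (sd is not None and np.isnan(sd)):
        return fixed_spec(mean)
    if family == "beta":
        return beta_from_moments(mean, float(sd))
    if family == "gamma":
        return gamma_from_moments(mean, float(sd))
    raise SchemaError(f"unknown distribution family {family!r}")


def ci95_bounds(
    spec: DistributionSpec,
    domain: str,
    fallback_fraction: float = FALLBACK_FRACTION,
) -> tuple[float, float]:
    """Normal-approximation 95% range, clamped to the quantity's domain.

    SD-less parameters fall back to ``mean * (1 -/+ fallback_fraction)``.
    """
    if spec.sd is not None and not spec.is_fixed:
        low = spec.mean - 1.96 * spec.sd
        high = spec.mean + 1.96 * spec.sd
    else:
        low = spec.mean * (1.0 - fallback_fraction)
        high = spec.mean * (1.0 + fallback_fraction)
    if domain in ("probability", "utility"):
        low, high = max(low, 0.0), min(high, 1.0)
    elif domain == "cost":
        low = max(low, 0.0)
    else:
        raise ValueError(f"unknown domain {domain!r}")
    return low, high


def sample_spec(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One draw from a fitted spec; fixed specs return the mean exactly."""
    if spec.is_fixed:
        return spec.mean
    if spec.family == "beta":
        return float(rng.beta(spec.shape1, spec.shape2))
    if spec.family == "gamma":
        return float(rng.gamma(spec.shape1, spec.shape2))
    raise ValueError(f"cannot sample family {spec.family!r}")


# ---------------------------------------------------------------------------
# Settings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSettings:
    """Analysis settings shared by both arms."""

    discount_rate_cost: float = 0.06
    discount_rate_outcome: float = 0.03
    discount_range: tuple[float, float] = (0.03, 0.09)
    wtp: float = 13_002.0
    cycle_length: float = 1.0
    max_cycles: int = 100
    absorption_tol: float = 1e-4
    psa_iterations: int = 1000
    seed: int = 20210
    half_cycle: bool = False
    initial_state: HealthState = HealthState.HOSPITALIZATION

    def replace(self, **kwargs) -> "ModelSettings":
        if "initial_state" in kwargs and not isinstance(
            kwargs["initial_state"], HealthState
        ):
            kwargs["initial_state"] = HealthState(kwargs["initial_state"])
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Default parameter table
# ---------------------------------------------------------------------------

# (parameter_id, arm, category, source_state, target_state, mean, sd, family)
# Free well-state exit probabilities carry the defaults produced by
# ``icdcea.calibration`` against the published per-arm lifetime totals;
# rerun ``icdcea calibrate`` to regenerate them.
DEFAULT_ROWS: tuple[tuple, ...] = (
    # stated transition probabilities
    ("tp_icd_hosp_to_well", "icd", "transition", "hospitalization", "well", 0.822, None, "fixed"),
    ("tp_icd_hosp_to_death", "icd", "transition", "hospitalization", "death", 0.178, 0.008, "beta"),
    ("tp_icd_compl_to_well", "icd", "transition", "complication", "well", 0.768, None, "fixed"),
    ("tp_icd_compl_to_rejection", "icd", "transition", "complication", "rejection", 0.022, None, "fixed"),
    ("tp_icd_compl_to_death", "icd", "transition", "complication", "death", 0.21, 0.109, "beta"),
    ("tp_icd_rej_to_well", "icd", "transition", "rejection", "well", 0.822, None, "fixed"),
    ("tp_icd_rej_to_death", "icd", "transition", "rejection", "death", 0.178, 0.008, "beta"),
    ("tp_pharm_hosp_to_well", "pharm", "transition", "hospitalization", "well", 0.716, None, "fixed"),
    ("tp_pharm_hosp_to_death", "pharm", "transition", "hospitalization", "death", 0.284, 0.009, "beta"),
    # free (calibrated) well-state exits; values regenerated by `icdcea calibrate`
    ("tp_icd_well_to_hosp", "icd", "transition", "well", "hospitalization", 0.0, None, "fixed"),
    ("tp_icd_well_to_compl", "icd", "transition", "well", "complication", 0.13370649001838975, None, "fixed"),
    ("tp_icd_well_to_death", "icd", "transition", "well", "death", 0.0, None, "fixed"),
    ("tp_pharm_well_to_hosp", "pharm", "transition", "well", "hospitalization", 0.1177247494855285, None, "fixed"),
    ("tp_pharm_well_to_death", "pharm", "transition", "well", "death", 0.0, None, "fixed"),
    # state costs (USD per cycle; death is a one-time transition cost)
    ("cost_icd_well", "icd", "cost", "well", None, 3398.0, 1105.0, "gamma"),
    ("cost_icd_compl", "icd", "cost", "complication", None, 3221.0, 933.0, "gamma"),
    ("cost_icd_hosp", "icd", "cost", "hospitalization", None, 2925.0, 1247.0, "gamma"),
    ("cost_icd_death", "icd", "cost", "death", None, 2777.0, None, "fixed"),
    ("cost_pharm_well", "pharm", "cost", "well", None, 741.0, 1246.0, "gamma"),
    ("cost_pharm_hosp", "pharm", "cost", "hospitalization", None, 1465.0, 2024.0, "gamma"),
    ("cost_pharm_death", "pharm", "cost", "death", None, 467.0, None, "fixed"),
    # state utilities
    ("util_icd_well", "icd", "utility", "well", None, 0.845, 0.124, "beta"),
    ("util_icd_compl", "icd", "utility", "complication", None, 0.75, None, "fixed"),
    ("util_icd_hosp", "icd", "utility", "hospitalization", None, 0.725, None, "fixed"),
    ("util_pharm_well", "pharm", "utility", "well", None, 0.88, 0.10, "beta"),
    ("util_pharm_hosp", "pharm", "utility", "hospitalization", None, 0.85, None, "fixed"),
)

CSV_COLUMNS = [
    "parameter_id",
    "arm",
    "category",
    "source_state",
    "target_state",
    "mean",
    "sd",
    "distribution",
]

#: Well-state exit probabilities are not published and must be calibrated.
FREE_TRANSITION_IDS = {
    Arm.ICD: ("tp_icd_well_to_hosp", "tp_icd_well_to_compl", "tp_icd_well_to_death"),
    Arm.PHARM: ("tp_pharm_well_to_hosp", "tp_pharm_well_to_death"),
}
_ALL_FREE_IDS = frozenset(
    pid for ids in FREE_TRANSITION_IDS.values() for pid in ids
)

#: Exit probabilities of each transient non-well state must sum to one.
_EXIT_GROUPS = {
    (Arm.ICD, HealthState.HOSPITALIZATION): (
        "tp_icd_hosp_to_well",
        "tp_icd_hosp_to_death",
    ),
    (Arm.ICD, HealthState.COMPLICATION): (
        "tp_icd_compl_to_well",
        "tp_icd_compl_to_rejection",
        "tp_icd_compl_to_death",
    ),
    (Arm.ICD, HealthState.REJECTION): (
        "tp_icd_rej_to_well",
        "tp_icd_rej_to_death",
    ),
    (Arm.PHARM, HealthState.HOSPITALIZATION): (
        "tp_pharm_hosp_to_well",
        "tp_pharm_hosp_to_death",
    ),
}


@dataclass(frozen=True)
class ParameterRow:
    parameter_id: str
    arm: Arm
    category: str
    source_state: HealthState
    target_state: HealthState | None
    spec: DistributionSpec


@dataclass(frozen=True)
class ParameterSet:
    """Validated model inputs for both arms plus analysis settings."""

    rows: Mapping[str, ParameterRow]
    settings: ModelSettings = field(default_factory=ModelSettings)
    free_calibrated: bool = True

    # -- lookup helpers -----------------------------------------------------
    def spec(self, parameter_id: str) -> DistributionSpec:
        try:
            return self.rows[parameter_id].spec
        except KeyError:
            raise KeyError(f"unknown parameter {parameter_id!r}") from None

    def mean(self, parameter_id: str) -> float:
        return self.spec(parameter_id).mean

    def parameter_ids(self, category: str | None = None) -> list[str]:
        return [
            pid
            for pid, row in self.rows.items()
            if category is None or row.category == category
        ]

    def domain(self, parameter_id: str) -> str:
        cat = self.rows[parameter_id].category
        return {"transition": "probability", "cost": "cost", "utility": "utility"}[cat]

    def cost_spec(self, arm: Arm, state: HealthState) -> DistributionSpec:
        return self._by_role("cost", arm, state)

    def utility_spec(self, arm: Arm, state: HealthState) -> DistributionSpec:
        return self._by_role("utility", arm, state)

    def _by_role(self, category: str, arm: Arm, state: HealthState) -> DistributionSpec:
        for row in self.rows.values():
            if row.category == category and row.arm == arm and row.source_state == state:
                return row.spec
        # REJECTION reuses the arm's hospitalization cost/utility by default
        if state is HealthState.REJECTION:
            return self._by_role(category, arm, HealthState.HOSPITALIZATION)
        raise KeyError(f"no {category} for ({arm.value}, {state.value})")

    def with_parameter(self, parameter_id: str, mean: float) -> "ParameterSet":
        """A copy with one parameter pinned to a fixed value."""
        row = self.rows[parameter_id]
        new_row = dataclasses.replace(row, spec=fixed_spec(mean))
        rows = dict(self.rows)
        rows[parameter_id] = new_row
        return dataclasses.replace(self, rows=rows)

    def with_settings(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, settings=self.settings.replace(**kwargs))

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        errors: list[str] = []
        for pid, row in self.rows.items():
            m = row.spec.mean
            if row.category == "transition" and not 0.0 <= m <= 1.0:
                errors.append(f"E_DOMAIN: probability {pid} = {m} outside [0, 1]")
            if row.category == "utility" and not 0.0 <= m <= 1.0:
                errors.append(f"E_DOMAIN: utility {pid} = {m} outside [0, 1]")
            if row.category == "cost" and m < 0.0:
                errors.append(f"E_DOMAIN: cost {pid} = {m} negative")
            if not row.spec.is_fixed:
                am, asd = row.spec.analytic_moments()
                if abs(am - m) > MOMENT_RTOL * max(1.0, abs(m)):
                    errors.append(f"E_MOMENTS: fitted mean of {pid} drifted")
        for (arm, state), pids in _EXIT_GROUPS.items():
            total = sum(self.rows[p].spec.mean for p in pids if p in self.rows)
            if abs(total - 1.0) > 1e-9:
                errors.append(
                    f"E_ROWSUM: exits of {state.value} ({arm.value}) sum to {total!r}"
                )
        for arm, pids in FREE_TRANSITION_IDS.items():
            total = sum(self.rows[p].spec.mean for p in pids if p in self.rows)
            if total > 1.0 + 1e-9:
                errors.append(
                    f"E_ROWSUM: free well exits ({arm.value}) sum to {total} > 1"
                )
        if errors:
            raise ValidationError("\n".join(errors))


# ---------------------------------------------------------------------------
# Parameter draws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterDraw:
    """One concrete value per parameter, row-stochastic after renormalization."""

    values: Mapping[str, float]
    n_clamped: int = 0

    def __getitem__(self, parameter_id: str) -> float:
        return self.values[parameter_id]

    def cost(self, params: ParameterSet, arm: Arm, state: HealthState) -> float:
        return self._role(params, "cost", arm, state)

    def utility(self, params: ParameterSet, arm: Arm, state: HealthState) -> float:
        return self._role(params, "utility", arm, state)

    def _role(self, params: ParameterSet, category: str, arm: Arm, state: HealthState) -> float:
        for pid, row in params.rows.items():
            if row.category == category and row.arm == arm and row.source_state == state:
                return self.values[pid]
        if state is HealthState.REJECTION:
            return self._role(params, category, arm, HealthState.HOSPITALIZATION)
        raise KeyError(f"no {category} for ({arm.value}, {state.value})")


def _renormalize_exits(
    params: ParameterSet, values: dict[str, float], overridden: set[str]
) -> int:
    """Restore row-stochasticity after sampling/overriding exit probabilities.

    Within each exit group the untouched sibling with the largest mean
    absorbs the residual; smaller-mean siblings stay at their values.
    Negative residuals are clamped to zero and the overridden entries are
    scaled down to keep the row sum at one.
    """
    n_clamped = 0
    for (_arm, _state), pids in _EXIT_GROUPS.items():
        present = [p for p in pids if p in values]
        touched = [p for p in present if p in overridden]
        if not touched:
            continue
        untouched = [p for p in present if p not in overridden]
        if not untouched:
            continue
        residual_pid = max(untouched, key=lambda p: params.rows[p].spec.mean)
        others = sum(values[p] for p in present if p != residual_pid)
        residual = 1.0 - others
        if residual < 0.0:
            n_clamped += 1
            residual = 0.0
            scale = (1.0 - sum(values[p] for p in untouched if p != residual_pid)) / sum(
                values[p] for p in touched
            )
            for p in touched:
                values[p] *= max(scale, 0.0)
        values[residual_pid] = residual
    return n_clamped


def sample_parameters(
    params: ParameterSet, rng: np.random.Generator
) -> ParameterDraw:
    """Draw every distribution-tagged parameter; fixed values pass through.

    Free (calibrated) well-state transitions are never sampled — no
    uncertainty is published for them.  Exit probabilities are
    renormalized so each transient state's exits sum to one.
    """
    values: dict[str, float] = {}
    sampled: set[str] = set()
    n_clamped = 0
    for pid, row in params.rows.items():
        if row.spec.is_fixed or pid in _ALL_FREE_IDS:
            values[pid] = row.spec.mean
        else:
            v = sample_spec(row.spec, rng)
            if row.category in ("transition", "utility"):
                clamped = min(max(v, 0.0), 1.0)
                if clamped != v:
                    n_clamped += 1
                v = clamped
            values[pid] = v
            sampled.add(pid)
    n_clamped += _renormalize_exits(params, values, sampled)
    return ParameterDraw(values=values, n_clamped=n_clamped)


def mean_draw(params: ParameterSet) -> ParameterDraw:
    """The deterministic draw: every parameter at its mean."""
    return ParameterDraw(values={pid: r.spec.mean for pid, r in params.rows.items()})


def draw_at(params: ParameterSet, overrides: Mapping[str, float]) -> ParameterDraw:
    """Means with selected parameters overridden, then renormalized.

    Used by deterministic sensitivity analysis: overriding one exit
    probability adjusts its complement sibling exactly as sampling would.
    """
    values = {pid: r.spec.mean for pid, r in params.rows.items()}
    for pid, v in overrides.items():
        if pid not in values:
            raise KeyError(f"unknown parameter {pid!r}")
        values[pid] = float(v)
    n_clamped = _renormalize_exits(params, values, set(overrides))
    return ParameterDraw(values=values, n_clamped=n_clamped)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_SETTING_KEYS = {f.name for f in dataclasses.fields(ModelSettings)}


def _row_from_record(rec: Mapping) -> ParameterRow:
    pid = str(rec["parameter_id"])
    try:
        arm = Arm(str(rec["arm"]).strip().lower())
    except ValueError:
        raise SchemaError(f"E_SCHEMA: row {pid!r} has unknown arm {rec['arm']!r}")
    category = str(rec["category"]).strip().lower()
    if category not in ("transition", "cost", "utility"):
        raise SchemaError(f"E_SCHEMA: row {pid!r} has unknown category {category!r}")
    try:
        source = HealthState(str(rec["source_state"]).strip().lower())
    except ValueError:
        raise SchemaError(
            f"E_SCHEMA: row {pid!r} has unknown source_state {rec['source_state']!r}"
        )
    target = None
    raw_target = rec.get("target_state")
    if raw_target not in (None, "") and not (
        isinstance(raw_target, float) and np.isnan(raw_target)
    ):
        try:
            target = HealthState(str(raw_target).strip().lower())
        except ValueError:
            raise SchemaError(
                f"E_SCHEMA: row {pid!r} has unknown target_state {raw_target!r}"
            )
    try:
        mean = float(rec["mean"])
    except (TypeError, ValueError):
        raise SchemaError(f"E_SCHEMA: row {pid!r} has non-numeric mean {rec['mean']!r}")
    sd = rec.get("sd")
    if sd in (None, "") or (isinstance(sd, float) and np.isnan(sd)):
        sd = None
    else:
        sd = float(sd)
    family = str(rec.get("distribution") or "fixed").strip().lower()
    if category == "transition" and not 0.0 <= mean <= 1.0:
        raise ValidationError(f"E_DOMAIN: probability {pid} = {mean} outside [0, 1]")
    if category == "utility" and not 0.0 <= mean <= 1.0:
        raise ValidationError(f"E_DOMAIN: utility {pid} = {mean} outside [0, 1]")
    if category == "cost" and mean < 0.0:
        raise ValidationError(f"E_DOMAIN: cost {pid} = {mean} negative")
    try:
        spec = spec_from_moments(family, mean, sd)
    except ValidationError as exc:
        raise type(exc)(f"{pid}: {exc}") from None
    return ParameterRow(pid, arm, category, source, target, spec)


def _default_rows() -> dict[str, ParameterRow]:
    return {
        r[0]: _row_from_record(dict(zip(CSV_COLUMNS, r)))
        for r in DEFAULT_ROWS
    }


def default_parameter_set(settings: ModelSettings | None = None) -> ParameterSet:
    """The bundled published parameter table with calibrated free transitions."""
    ps = ParameterSet(rows=_default_rows(), settings=settings or ModelSettings())
    ps.validate()
    return ps


def load_settings(path: str | Path) -> dict:
    """Read a YAML or JSON settings block, keeping only known keys."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if not isinstance(data, dict):
        raise SchemaError(f"E_SCHEMA: settings file {path} is not a mapping")
    unknown = set(data) - _SETTING_KEYS
    if unknown:
        raise SchemaError(f"E_SCHEMA: unknown settings {sorted(unknown)}")
    if "discount_range" in data:
        data["discount_range"] = tuple(data["discount_range"])
    return data


def load_parameter_table(
    path: str | Path,
    settings: Mapping | None = None,
    settings_path: str | Path | None = None,
    strict: bool = False,
) -> ParameterSet:
    """Load and validate a parameter CSV.

    Rows omitted from the file are filled from the bundled defaults
    (``strict=True`` turns an omitted mandatory row into a
    :class:`SchemaError` instead).  If every free well-state transition
    row is omitted the returned set is flagged ``free_calibrated=False``
    and carries the documented calibratable defaults.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"E_SCHEMA: parameter file {path} does not exist")
    try:
        frame = pd.read_csv(path, dtype={"parameter_id": str}, float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"E_SCHEMA: cannot parse {path}: {exc}") from None
    missing_cols = set(CSV_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise SchemaError(f"E_SCHEMA: missing columns {sorted(missing_cols)}")

    rows = _default_rows()
    seen: set[str] = set()
    for rec in frame.to_dict("records"):
        row = _row_from_record(rec)
        if row.parameter_id in seen:
            raise SchemaError(f"E_SCHEMA: duplicate parameter {row.parameter_id!r}")
        seen.add(row.parameter_id)
        rows[row.parameter_id] = row
    if strict:
        mandatory = {r[0] for r in DEFAULT_ROWS} - _ALL_FREE_IDS
        omitted = mandatory - seen
        if omitted:
            raise SchemaError(f"E_SCHEMA: missing mandatory rows {sorted(omitted)}")

    free_calibrated = any(pid in seen for pid in _ALL_FREE_IDS)

    kwargs: dict = {}
    if settings_path is not None:
        kwargs.update(load_settings(settings_path))
    if settings:
        kwargs.update(settings)
    model_settings = ModelSettings().replace(**kwargs) if kwargs else ModelSettings()

    ps = ParameterSet(rows=rows, settings=model_settings, free_calibrated=free_calibrated)
    ps.validate()
    return ps


def parameter_frame(params: ParameterSet) -> pd.DataFrame:
    """The parameter table as a DataFrame in canonical column order."""
    records = []
    for pid, row in params.rows.items():
        records.append(
            {
                "parameter_id": pid,
                "arm": row.arm.value,
                "category": row.category,
                "source_state": row.source_state.value,
                "target_state": row.target_state.value if row.target_state else "",
                "mean": row.spec.mean,
                "sd": "" if row.spec.sd is None else row.spec.sd,
                "distribution": row.spec.family,
            }
        )
    return pd.DataFrame.from_records(records, columns=CSV_COLUMNS)
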