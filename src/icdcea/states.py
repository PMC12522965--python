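"""Health states and treatment arms of the arrhythmia Markov model."""

from __future__ import annotations

from enum import Enum


class Arm(str, Enum):
    """Treatment strategy being modelled."""

    ICD = "icd"
    PHARM = "pharm"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class HealthState(str, Enum):
    """Markov health state.

    DEATH is absorbing in every matrix.  REJECTION (device rejection) is
    reachable only in the ICD arm.
    """

    WELL = "well"
    HOSPITALIZATION = "hospitalization"
    COMPLICATION = "complication"
    REJECTION = "rejection"
    DEATH = "death"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: State ordering used for every transition matrix, per arm.
ARM_STATES = {
    Arm.ICD: [
        HealthState.WELL,
        HealthState.HOSPITALIZATION,
        HealthState.COMPLICATION,
        HealthState.REJECTION,
        HealthState.DEATH,
    ],
    Arm.PHARM: [
        HealthState.WELL,
        HealthState.HOSPITALIZATION,
        HealthState.DEATH,
    ],
}

#: Live (non-absorbing) states per arm.
LIVE_STATES = {arm: states[:-1] for arm, states in ARM_STATES.items()}
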