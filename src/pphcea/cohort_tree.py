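"""Clinical cascade of the decision tree.

Each birth enters by delivery mode (vaginal or Caesarean section), receives
prophylaxis with oxytocin or carbetocin, and may then progress through
postpartum hemorrhage (PPH, blood loss >= 500 mL), massive PPH (>= 1,500 mL),
emergency hysterectomy, and death. The tree ends in one of five terminal
states per mode; all probabilities below hysterectomy are arm-independent,
so every cohort event rate under carbetocin is exactly the relative risk
times the oxytocin rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .parameters import ParameterSet

__all__ = [
    "Arm",
    "Mode",
    "TerminalState",
    "ARMS",
    "MODES",
    "TERMINAL_STATES",
    "PathProbabilities",
    "EventRates",
    "pph_probability",
    "path_probabilities",
    "expected_event_rates",
    "mode_weights",
]

Arm = Literal["oxytocin", "carbetocin"]
Mode = Literal["vaginal", "csection"]
TerminalState = Literal[
    "no_pph",
    "pph_non_massive",
    "massive_no_hyst",
    "hysterectomy_survive",
    "hysterectomy_death",
]

ARMS: tuple[Arm, ...] = ("oxytocin", "carbetocin")
MODES: tuple[Mode, ...] = ("vaginal", "csection")
TERMINAL_STATES: tuple[TerminalState, ...] = (
    "no_pph",
    "pph_non_massive",
    "massive_no_hyst",
    "hysterectomy_survive",
    "hysterectomy_death",
)


@dataclass(frozen=True)
class PathProbabilities:
    """Terminal-state probabilities conditional on one delivery mode."""

    arm: Arm
    mode: Mode
    p_no_pph: float
    p_pph_non_massive: float
    p_massive_no_hysterectomy: float
    p_hysterectomy_survive: float
    p_hysterectomy_death: float

    def as_dict(self) -> dict[TerminalState, float]:
        return {
            "no_pph": self.p_no_pph,
            "pph_non_massive": self.p_pph_non_massive,
            "massive_no_hyst": self.p_massive_no_hysterectomy,
            "hysterectomy_survive": self.p_hysterectomy_survive,
            "hysterectomy_death": self.p_hysterectomy_death,
        }

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())


@dataclass(frozen=True)
class EventRates:
    """Expected per-birth event probabilities after mixing delivery modes."""

    arm: Arm
    pph_500_per_birth: float
    pph_1500_per_birth: float
    hysterectomy_per_birth: float
    death_per_birth: float


def mode_weights(params: ParameterSet) -> dict[Mode, float]:
    """Cohort mix over delivery modes."""
    return {"vaginal": 1.0 - params.p_csection, "csection": params.p_csection}


def pph_probability(params: ParameterSet, arm: Arm, mode: Mode) -> float:
    """Probability of PPH >= 500 mL for one arm and delivery mode.

    Oxytocin uses the mode-specific base probability; carbetocin multiplies
    it by the relative risk, capped at 1.
    """
    base = (
        params.p_pph_oxy_vaginal if mode == "vaginal" else params.p_pph_oxy_csection
    )
    if arm == "oxytocin":
        return base
    if arm == "carbetocin":
        return min(1.0, base * params.rr_carbetocin)
    raise ValueError(f"unknown arm {arm!r}")


def _massive_fraction(params: ParameterSet, mode: Mode) -> float:
    return (
        params.p_massive_given_pph_vaginal
        if mode == "vaginal"
        else params.p_massive_given_pph_csection
    )


def path_probabilities(params: ParameterSet, arm: Arm, mode: Mode) -> PathProbabilities:
    """Terminal-state probabilities by chain multiplication down the tree."""
    p_pph = pph_probability(params, arm, mode)
    p_massive = p_pph * _massive_fraction(params, mode)
    p_hyst = p_massive * params.p_hysterectomy_given_massive
    p_death = p_hyst * params.p_death_given_hysterectomy
    return PathProbabilities(
        arm=arm,
        mode=mode,
        p_no_pph=1.0 - p_pph,
        p_pph_non_massive=p_pph - p_massive,
        p_massive_no_hysterectomy=p_massive - p_hyst,
        p_hysterectomy_survive=p_hyst - p_death,
        p_hysterectomy_death=p_death,
    )


def expected_event_rates(params: ParameterSet, arm: Arm) -> EventRates:
    """Cohort event rates per birth, mixing vaginal and C-section births."""
    weights = mode_weights(params)
    pph = massive = hyst = death = 0.0
    for mode, w in weights.items():
        pp = path_probabilities(params, arm, mode)
        pph += w * (1.0 - pp.p_no_pph)
        massive += w * (
            pp.p_massive_no_hysterectomy
            + pp.p_hysterectomy_survive
            + pp.p_hysterectomy_death
        )
        hyst += w * (pp.p_hysterectomy_survive + pp.p_hysterectomy_death)
        death += w * pp.p_hysterectomy_death
    return EventRates(
        arm=arm,
        pph_500_per_birth=pph,
        pph_1500_per_birth=massive,
        hysterectomy_per_birth=hyst,
        death_per_birth=death,
    )
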