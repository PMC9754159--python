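"""Expected PPH-related direct medical cost per birth.

Costing rule (one table, shared with the QALY model and the microsimulation
oracle through :func:`path_stay_days` and :func:`path_day_rate`):

==================== ========== =========== ========================= =============================
terminal state       prevention first-line  procedures                PPH-attributable stay
==================== ========== =========== ========================= =============================
no_pph               yes        --          --                        none (baseline delivery stay
                                                                      is not PPH-related)
pph_non_massive      yes        uterotonics --                        mode base LOS x PPH multiplier
massive_no_hyst      yes        uterotonics second-line               second-line LOS (6 d)
hysterectomy_*       yes        uterotonics second-line + hysterectomy hysterectomy LOS (6.7 d)
==================== ========== =========== ========================= =============================

Stays on paths without hysterectomy are charged at the PPH-without-
hysterectomy day rate and hysterectomy stays at the PPH-with-hysterectomy
day rate (both equal the general-ward rate at base case; their sensitivity
upper limits are the high-dependency and intensive-care rates). Death paths
cost the same as surviving hysterectomy paths.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort_tree import (
    MODES,
    Arm,
    Mode,
    TerminalState,
    mode_weights,
    path_probabilities,
)
from .parameters import ParameterSet

__all__ = [
    "PathCost",
    "ArmCost",
    "path_stay_days",
    "path_day_rate",
    "path_cost",
    "expected_arm_cost",
]

_HYST_STATES = ("hysterectomy_survive", "hysterectomy_death")


@dataclass(frozen=True)
class PathCost:
    """Cost components (USD) of one terminal path."""

    arm: Arm
    mode: Mode
    terminal: TerminalState
    prevention_cost: float
    treatment_drug_cost: float
    procedure_cost: float
    stay_cost: float

    @property
    def total(self) -> float:
        return (
            self.prevention_cost
            + self.treatment_drug_cost
            + self.procedure_cost
            + self.stay_cost
        )


@dataclass(frozen=True)
class ArmCost:
    """Expected PPH-related cost per birth with the per-path breakdown."""

    arm: Arm
    expected_cost_per_birth: float
    #: (PathCost, unconditional path probability) over both delivery modes
    breakdown: tuple[tuple[PathCost, float], ...]

    @property
    def prevention_component(self) -> float:
        return sum(pc.prevention_cost * p for pc, p in self.breakdown)

    @property
    def treatment_component(self) -> float:
        """Expected cost excluding prophylaxis (drugs, procedures, stay)."""
        return self.expected_cost_per_birth - self.prevention_component


def path_stay_days(params: ParameterSet, mode: Mode, terminal: TerminalState) -> float:
    """PPH-attributable hospital stay (days) on one terminal path."""
    if terminal == "no_pph":
        return 0.0
    if terminal == "pph_non_massive":
        base = (
            params.los_vaginal_no_pph
            if mode == "vaginal"
            else params.los_csection_no_pph
        )
        return base * params.los_pph_multiplier
    if terminal == "massive_no_hyst":
        return params.los_second_line
    if terminal in _HYST_STATES:
        return params.los_hysterectomy
    raise ValueError(f"unknown terminal state {terminal!r}")


def path_day_rate(params: ParameterSet, terminal: TerminalState) -> float:
    """USD per hospital day charged on one terminal path."""
    if terminal == "no_pph":
        return params.cost_day_general
    if terminal in _HYST_STATES:
        return params.cost_day_pph_hyst
    return params.cost_day_pph_no_hyst


def path_cost(
    params: ParameterSet, arm: Arm, mode: Mode, terminal: TerminalState
) -> PathCost:
    """Cost the terminal path per the module-level costing table."""
    prevention = (
        params.cost_prevention_oxytocin
        if arm == "oxytocin"
        else params.cost_prevention_carbetocin
    )
    if terminal == "no_pph":
        drug = procedure = stay = 0.0
    elif terminal == "pph_non_massive":
        drug = params.cost_uterotonic_treatment
        procedure = 0.0
        stay = path_stay_days(params, mode, terminal) * path_day_rate(params, terminal)
    elif terminal == "massive_no_hyst":
        drug = params.cost_uterotonic_treatment
        procedure = params.cost_second_line
        stay = path_stay_days(params, mode, terminal) * path_day_rate(params, terminal)
    elif terminal in _HYST_STATES:
        drug = params.cost_uterotonic_treatment
        procedure = params.cost_second_line + params.cost_hysterectomy
        stay = path_stay_days(params, mode, terminal) * path_day_rate(params, terminal)
    else:
        raise ValueError(f"unknown terminal state {terminal!r}")
    return PathCost(
        arm=arm,
        mode=mode,
        terminal=terminal,
        prevention_cost=prevention,
        treatment_drug_cost=drug,
        procedure_cost=procedure,
        stay_cost=stay,
    )


def expected_arm_cost(params: ParameterSet, arm: Arm) -> ArmCost:
    """Probability-weighted cost over all ten (mode, terminal) paths."""
    weights = mode_weights(params)
    breakdown: list[tuple[PathCost, float]] = []
    total = 0.0
    for mode in MODES:
        probs = path_probabilities(params, arm, mode).as_dict()
        for terminal, p_cond in probs.items():
            pc = path_cost(params, arm, mode, terminal)
            p = weights[mode] * p_cond
            breakdown.append((pc, p))
            total += p * pc.total
    return ArmCost(arm=arm, expected_cost_per_birth=total, breakdown=tuple(breakdown))
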