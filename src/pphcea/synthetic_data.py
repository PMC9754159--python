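"""Synthetic inputs and the individual-level microsimulation oracle.

Three generators:

* :func:`generate_life_table` — a smooth, plausible female life table (age
  versus remaining life expectancy) pinned to an exact remaining life
  expectancy at age 33, standing in for a published national life table;
* :func:`simulate_cohort` — an individual-level Monte Carlo cohort that
  walks each birth through the decision tree with independent Bernoulli
  draws, costing and QALY-scoring each birth with the *same* per-path
  formulas the analytic modules use. Cohort means therefore converge to the
  analytic expected values, which makes the simulator an independent oracle
  for the expectation engine's wiring;
* :func:`random_parameter_set` — uniform draws within the sensitivity
  ranges, for property-testing model invariants across the legal input
  space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .cohort_tree import Arm, MODES, TERMINAL_STATES, path_probabilities
from .cost_model import path_cost
from .parameters import ParameterSet, SensitivityRange
from .qaly_model import LifeTable, path_qaly_loss

__all__ = [
    "MicrosimCohort",
    "generate_life_table",
    "simulate_cohort",
    "random_parameter_set",
]

_EVENT_FLAGS = {
    # terminal state -> (pph_500, pph_1500, hysterectomy, death)
    "no_pph": (0, 0, 0, 0),
    "pph_non_massive": (1, 0, 0, 0),
    "massive_no_hyst": (1, 1, 0, 0),
    "hysterectomy_survive": (1, 1, 1, 0),
    "hysterectomy_death": (1, 1, 1, 1),
}


def generate_life_table(
    le_at_birth: float = 87.7,
    le_at_33_target: float = 55.0,
    max_age: float = 110.0,
) -> LifeTable:
    """Generate a smooth decreasing life table hitting the age-33 target.

    Remaining life expectancy follows a power law in the years left to
    ``max_age``, LE(a) = c (max_age - a)^g, with c and g solved so that
    LE(0) = ``le_at_birth`` and LE(33) = ``le_at_33_target`` exactly. The
    table covers integer ages 0 to max_age - 1.
    """
    if not 0 < le_at_33_target < le_at_birth < max_age:
        raise ValueError(
            "need 0 < le_at_33_target < le_at_birth < max_age, got "
            f"({le_at_birth}, {le_at_33_target}, {max_age})"
        )
    if le_at_33_target >= max_age - 33:
        raise ValueError(
            f"le_at_33_target {le_at_33_target} implies survival past "
            f"max_age {max_age}"
        )
    g = np.log(le_at_birth / le_at_33_target) / np.log(max_age / (max_age - 33.0))
    c = le_at_birth / max_age**g
    ages = np.arange(0, int(max_age))
    remaining = c * (max_age - ages) ** g
    return LifeTable(ages, remaining)


@dataclass(frozen=True)
class MicrosimCohort:
    """Individual-level simulated cohort with per-birth records.

    ``records`` columns: mode, terminal, pph_500, pph_1500, hysterectomy,
    death, cost, qaly_loss.
    """

    arm: Arm
    n_births: int
    seed: int
    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Cohort means with Monte Carlo standard errors, one row per outcome."""
        cols = ["pph_500", "pph_1500", "hysterectomy", "death", "cost", "qaly_loss"]
        means = self.records[cols].mean()
        ses = self.records[cols].std(ddof=1) / np.sqrt(self.n_births)
        return pd.DataFrame({"mean": means, "se": ses})

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def simulate_cohort(
    params: ParameterSet,
    arm: Arm,
    n_births: int,
    seed: int,
    life_table: LifeTable,
) -> MicrosimCohort:
    """Simulate ``n_births`` individual births through the decision tree.

    Delivery mode and each cascade step are independent Bernoulli draws;
    per-birth cost and QALY loss come from the same path formulas as the
    analytic cost and QALY models. Reproducible given ``seed``.
    """
    if n_births < 1:
        raise ValueError("n_births must be >= 1")
    rng = np.random.default_rng(seed)
    is_csection = rng.random(n_births) < params.p_csection
    u_pph = rng.random(n_births)
    u_massive = rng.random(n_births)
    u_hyst = rng.random(n_births)
    u_death = rng.random(n_births)

    # per-(mode, terminal) lookup tables computed once
    cost_lut: dict[tuple[str, str], float] = {}
    qaly_lut: dict[tuple[str, str], float] = {}
    for mode in MODES:
        for terminal in TERMINAL_STATES:
            cost_lut[(mode, terminal)] = path_cost(params, arm, mode, terminal).total
            qaly_lut[(mode, terminal)] = path_qaly_loss(
                params, mode, terminal, life_table
            )

    mode_arr = np.where(is_csection, "csection", "vaginal")
    terminal = np.full(n_births, "no_pph", dtype=object)
    for mode in MODES:
        sel = mode_arr == mode
        if not sel.any():
            continue
        pp = path_probabilities(params, arm, mode)
        p_pph = 1.0 - pp.p_no_pph
        with np.errstate(invalid="ignore"):
            # conditional step probabilities down the cascade
            massive_frac = (
                params.p_massive_given_pph_vaginal
                if mode == "vaginal"
                else params.p_massive_given_pph_csection
            )
        pph = sel & (u_pph < p_pph)
        massive = pph & (u_massive < massive_frac)
        hyst = massive & (u_hyst < params.p_hysterectomy_given_massive)
        death = hyst & (u_death < params.p_death_given_hysterectomy)
        terminal[pph & ~massive] = "pph_non_massive"
        terminal[massive & ~hyst] = "massive_no_hyst"
        terminal[hyst & ~death] = "hysterectomy_survive"
        terminal[death] = "hysterectomy_death"

    cost = np.array([cost_lut[(m, t)] for m, t in zip(mode_arr, terminal)])
    qaly = np.array([qaly_lut[(m, t)] for m, t in zip(mode_arr, terminal)])
    flags = np.array([_EVENT_FLAGS[t] for t in terminal])
    records = pd.DataFrame(
        {
            "mode": mode_arr,
            "terminal": terminal,
            "pph_500": flags[:, 0],
            "pph_1500": flags[:, 1],
            "hysterectomy": flags[:, 2],
            "death": flags[:, 3],
            "cost": cost,
            "qaly_loss": qaly,
        }
    )
    return MicrosimCohort(arm=arm, n_births=n_births, seed=seed, records=records)


def random_parameter_set(
    ranges: Iterable[SensitivityRange] | Mapping[str, SensitivityRange],
    seed: int,
    base: Optional[ParameterSet] = None,
) -> ParameterSet:
    """Draw a parameter set uniformly within the given sensitivity ranges.

    Parameters without a range keep their base value. The returned set
    passes all parameter invariants by construction of the ranges.
    """
    from .parameters import load_parameters

    if base is None:
        base = load_parameters()
    if isinstance(ranges, Mapping):
        ranges = list(ranges.values())
    rng = np.random.default_rng(seed)
    values = base.to_dict()
    for r in ranges:
        values[r.parameter_name] = float(rng.uniform(r.low, r.high))
    return ParameterSet(**values)
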