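"""Expected PPH-related QALY loss per birth.

Two components per arm:

* morbidity — each PPH path contributes its probability times the health-state
  disutility (0.347 without hysterectomy, 0.435 with) times the stay in years
  (days / 365). Stays mirror the costing rule exactly: multiplied base stay on
  non-massive paths, the dedicated second-line and hysterectomy stays on the
  escalated paths. The stay is short relative to a year, so it is not
  discounted.
* mortality — the death-path probability times the QALY value of the remaining
  lifetime: baseline utility times the discounted remaining life expectancy at
  the maternal age, with annual end-of-year discounting and the fractional
  final year prorated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .cohort_tree import Arm, MODES, mode_weights, path_probabilities
from .cost_model import path_stay_days
from .parameters import ParameterSet

__all__ = [
    "LifeTable",
    "ArmQALYLoss",
    "discounted_life_years",
    "death_qaly_loss",
    "path_qaly_loss",
    "expected_arm_qaly_loss",
    "default_life_table_path",
]

DAYS_PER_YEAR = 365.0


class LifeTable:
    """Age-indexed remaining life expectancy (years).

    Ages must be strictly increasing and remaining life expectancy positive
    and strictly decreasing. Lookups at non-tabulated ages interpolate
    linearly; ages outside the tabulated span raise ``ValueError``.
    """

    def __init__(self, ages: np.ndarray, remaining: np.ndarray) -> None:
        ages = np.asarray(ages, dtype=float)
        remaining = np.asarray(remaining, dtype=float)
        if ages.ndim != 1 or ages.shape != remaining.shape or ages.size < 2:
            raise ValueError("life table needs matching 1-d age/LE columns")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("life table ages must be strictly increasing")
        if not np.all(remaining > 0):
            raise ValueError("remaining life expectancy must be positive")
        if not np.all(np.diff(remaining) < 0):
            raise ValueError("remaining life expectancy must decrease with age")
        self.ages = ages
        self.remaining = remaining

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "LifeTable":
        """Read a two-column CSV (age, remaining_life_expectancy)."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"life table CSV {path} needs two columns")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "remaining_life_expectancy": self.remaining}
        )

    def remaining_life_expectancy(self, age: float) -> float:
        if age < self.ages[0] or age > self.ages[-1]:
            raise ValueError(
                f"age {age} outside life table span "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        return float(np.interp(age, self.ages, self.remaining))


def default_life_table_path() -> Path:
    """Path of the packaged synthetic female life table (LE at 33 = 55.0 y)."""
    from importlib import resources

    return Path(
        resources.files("pphcea").joinpath("data/synthetic_female_life_table.csv")
    )


def load_default_life_table() -> LifeTable:
    return LifeTable.from_csv(default_life_table_path())


def discounted_life_years(remaining_years: float, discount_rate: float) -> float:
    """Present value of one life-year per year over ``remaining_years``.

    Annual end-of-year discounting: sum of (1+r)^-t for t = 1..floor(L),
    plus the fractional final year prorated at (1+r)^-ceil(L). At r = 0 this
    returns ``remaining_years`` exactly.
    """
    if remaining_years < 0:
        raise ValueError(f"remaining_years must be >= 0, got {remaining_years}")
    if discount_rate < 0:
        raise ValueError(f"discount_rate must be >= 0, got {discount_rate}")
    if discount_rate == 0.0:
        return remaining_years
    full_years = int(np.floor(remaining_years))
    v = 1.0 / (1.0 + discount_rate)
    annuity = v * (1.0 - v**full_years) / (1.0 - v)
    fraction = remaining_years - full_years
    if fraction > 0:
        annuity += fraction * v ** (full_years + 1)
    return annuity


def death_qaly_loss(params: ParameterSet, life_table: LifeTable) -> float:
    """QALYs lost by one maternal death at the base maternal age."""
    le = life_table.remaining_life_expectancy(params.maternal_age)
    return params.utility_baseline * discounted_life_years(
        le, params.annual_discount_rate
    )


def _path_disutility(params: ParameterSet, terminal: str) -> float:
    if terminal in ("hysterectomy_survive", "hysterectomy_death"):
        return params.disutility_pph_hyst
    if terminal in ("pph_non_massive", "massive_no_hyst"):
        return params.disutility_pph_no_hyst
    return 0.0


def path_qaly_loss(
    params: ParameterSet, mode: str, terminal: str, life_table: LifeTable
) -> float:
    """QALY loss on one terminal path (morbidity plus, on death, mortality)."""
    loss = (
        _path_disutility(params, terminal)
        * path_stay_days(params, mode, terminal)
        / DAYS_PER_YEAR
    )
    if terminal == "hysterectomy_death":
        loss += death_qaly_loss(params, life_table)
    return loss


@dataclass(frozen=True)
class ArmQALYLoss:
    """Expected QALY loss per birth, split into morbidity and mortality."""

    arm: Arm
    morbidity_loss: float
    mortality_loss: float

    @property
    def qaly_loss_per_birth(self) -> float:
        return self.morbidity_loss + self.mortality_loss


def expected_arm_qaly_loss(
    params: ParameterSet, arm: Arm, life_table: LifeTable
) -> ArmQALYLoss:
    """Probability-weighted QALY loss over all paths of one arm."""
    weights = mode_weights(params)
    morbidity = 0.0
    mortality = 0.0
    per_death = death_qaly_loss(params, life_table)
    for mode in MODES:
        probs = path_probabilities(params, arm, mode).as_dict()
        for terminal, p_cond in probs.items():
            p = weights[mode] * p_cond
            morbidity += (
                p
                * _path_disutility(params, terminal)
                * path_stay_days(params, mode, terminal)
                / DAYS_PER_YEAR
            )
            if terminal == "hysterectomy_death":
                mortality += p * per_death
    return ArmQALYLoss(arm=arm, morbidity_loss=morbidity, mortality_loss=mortality)
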