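"""Cost-effectiveness engine.

Combines the clinical cascade, cost model and QALY model into incremental
results for carbetocin versus oxytocin, and runs the sensitivity analyses:

* base-case expected values and the incremental cost-effectiveness ratio
  (ICER = incremental cost / incremental QALY saved), with the decision
  rule: carbetocin is accepted when it saves QALYs at lower cost
  (dominance), or saves QALYs with an ICER at or below the
  willingness-to-pay (WTP) threshold;
* one-way deterministic sensitivity analysis over each parameter's range,
  flagging decision flips;
* threshold search (bisection to 1e-6 on the parameter) for the value at
  which carbetocin stops being cost-saving or cost-effective;
* two-way threshold curve over a grid of one parameter, solving for the
  threshold of a second;
* probabilistic sensitivity analysis: all distributed inputs redrawn
  simultaneously for each Monte Carlo iteration, seeded and reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .cohort_tree import expected_event_rates
from .cost_model import ArmCost, expected_arm_cost
from .parameters import DistributionSpec, ParameterSet, SensitivityRange
from .qaly_model import ArmQALYLoss, LifeTable, expected_arm_qaly_loss

__all__ = [
    "CEAResult",
    "ThresholdResult",
    "PSAResult",
    "base_case",
    "one_way_dsa",
    "find_threshold",
    "two_way_threshold_curve",
    "run_psa",
]

logger = logging.getLogger(__name__)

THRESHOLD_XTOL = 1e-6


@dataclass(frozen=True)
class CEAResult:
    """Incremental cost-effectiveness of carbetocin versus oxytocin."""

    cost_oxytocin: ArmCost
    cost_carbetocin: ArmCost
    qaly_loss_oxytocin: ArmQALYLoss
    qaly_loss_carbetocin: ArmQALYLoss
    wtp: float

    @property
    def incremental_cost(self) -> float:
        """Cost difference, carbetocin minus oxytocin (USD/birth)."""
        return (
            self.cost_carbetocin.expected_cost_per_birth
            - self.cost_oxytocin.expected_cost_per_birth
        )

    @property
    def incremental_qaly_saved(self) -> float:
        """QALY-loss reduction achieved by carbetocin (QALY/birth)."""
        return (
            self.qaly_loss_oxytocin.qaly_loss_per_birth
            - self.qaly_loss_carbetocin.qaly_loss_per_birth
        )

    @property
    def dominant(self) -> bool:
        """Carbetocin both cheaper and more effective (ICER undefined)."""
        return self.incremental_cost < 0 and self.incremental_qaly_saved > 0

    @property
    def icer(self) -> Optional[float]:
        """USD per QALY saved; None when dominance makes it undefined."""
        if self.dominant or self.incremental_qaly_saved == 0:
            return None
        return self.incremental_cost / self.incremental_qaly_saved

    @property
    def decision(self) -> str:
        """Preferred prophylaxis at the stored WTP threshold."""
        dq = self.incremental_qaly_saved
        dc = self.incremental_cost
        if dq >= 0 and dc <= 0:
            return "carbetocin"
        if dq > 0 and dc / dq <= self.wtp:
            return "carbetocin"
        return "oxytocin"

    def summary(self) -> dict[str, float | str | None]:
        return {
            "cost_oxytocin": self.cost_oxytocin.expected_cost_per_birth,
            "cost_carbetocin": self.cost_carbetocin.expected_cost_per_birth,
            "qaly_loss_oxytocin": self.qaly_loss_oxytocin.qaly_loss_per_birth,
            "qaly_loss_carbetocin": self.qaly_loss_carbetocin.qaly_loss_per_birth,
            "incremental_cost": self.incremental_cost,
            "incremental_qaly_saved": self.incremental_qaly_saved,
            "icer": self.icer,
            "dominant": self.dominant,
            "wtp": self.wtp,
            "decision": self.decision,
        }


def base_case(
    params: ParameterSet,
    life_table: LifeTable,
    wtp: Optional[float] = None,
) -> CEAResult:
    """Expected-value analysis of both arms at the given parameter set."""
    if wtp is None:
        wtp = params.wtp_threshold
    return CEAResult(
        cost_oxytocin=expected_arm_cost(params, "oxytocin"),
        cost_carbetocin=expected_arm_cost(params, "carbetocin"),
        qaly_loss_oxytocin=expected_arm_qaly_loss(params, "oxytocin", life_table),
        qaly_loss_carbetocin=expected_arm_qaly_loss(params, "carbetocin", life_table),
        wtp=wtp,
    )


def one_way_dsa(
    params: ParameterSet,
    ranges: Iterable[SensitivityRange],
    life_table: LifeTable,
    wtp: Optional[float] = None,
) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis (tornado table).

    Each parameter is set to its low and high limit in turn, all others at
    base case. Returns one row per parameter with the incremental cost,
    incremental QALY saved, and decision at both ends, plus a flag for
    parameters whose decision differs between ends or from base case.
    """
    if wtp is None:
        wtp = params.wtp_threshold
    base_decision = base_case(params, life_table, wtp).decision
    rows = []
    for rng in ranges:
        out: dict[str, object] = {
            "parameter": rng.parameter_name,
            "low": rng.low,
            "high": rng.high,
        }
        for end, value in (("low", rng.low), ("high", rng.high)):
            res = base_case(
                params.replace(**{rng.parameter_name: value}), life_table, wtp
            )
            out[f"incremental_cost_{end}"] = res.incremental_cost
            out[f"incremental_qaly_saved_{end}"] = res.incremental_qaly_saved
            out[f"decision_{end}"] = res.decision
        out["decision_flips"] = (
            out["decision_low"] != base_decision
            or out["decision_high"] != base_decision
        )
        rows.append(out)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a one-parameter threshold search."""

    parameter_name: str
    criterion: str
    wtp: float
    found: bool
    threshold: Optional[float]
    search_interval: tuple[float, float]
    tolerance: float
    #: decision on the whole interval when no threshold exists
    constant_decision: Optional[str] = None


def _criterion_margin(
    params: ParameterSet,
    life_table: LifeTable,
    criterion: str,
    wtp: float,
) -> float:
    """Signed margin, positive when carbetocin meets the criterion.

    ``cost_saving``: minus the incremental cost. ``cost_effective_at_wtp``:
    net monetary benefit, WTP x incremental QALY saved minus incremental
    cost.
    """
    res = base_case(params, life_table, wtp)
    if criterion == "cost_saving":
        return -res.incremental_cost
    if criterion == "cost_effective_at_wtp":
        return wtp * res.incremental_qaly_saved - res.incremental_cost
    raise ValueError(f"unknown criterion {criterion!r}")


def find_threshold(
    params: ParameterSet,
    param_name: str,
    criterion: str,
    wtp: Optional[float] = None,
    life_table: Optional[LifeTable] = None,
    search_interval: tuple[float, float] = (1e-9, 1.0),
) -> ThresholdResult:
    """Locate the parameter value at which the criterion flips.

    Bisects the signed criterion margin over ``search_interval`` to an
    absolute tolerance of 1e-6 on the parameter. When the margin does not
    change sign over the interval, returns a no-threshold result carrying
    the decision that holds throughout (not an exception).
    """
    if life_table is None:
        raise ValueError("life_table is required")
    if wtp is None:
        wtp = params.wtp_threshold

    def margin(value: float) -> float:
        return _criterion_margin(
            params.replace(**{param_name: value}), life_table, criterion, wtp
        )

    lo, hi = search_interval
    m_lo, m_hi = margin(lo), margin(hi)
    if m_lo == 0.0 or m_hi == 0.0:
        root = lo if m_lo == 0.0 else hi
        return ThresholdResult(
            param_name, criterion, wtp, True, root, search_interval, THRESHOLD_XTOL
        )
    if np.sign(m_lo) == np.sign(m_hi):
        return ThresholdResult(
            parameter_name=param_name,
            criterion=criterion,
            wtp=wtp,
            found=False,
            threshold=None,
            search_interval=search_interval,
            tolerance=THRESHOLD_XTOL,
            constant_decision="carbetocin" if m_lo > 0 else "oxytocin",
        )
    root = bisect(margin, lo, hi, xtol=THRESHOLD_XTOL)
    return ThresholdResult(
        param_name, criterion, wtp, True, float(root), search_interval, THRESHOLD_XTOL
    )


def two_way_threshold_curve(
    params: ParameterSet,
    x_param: str,
    y_param: str,
    x_grid: Sequence[float],
    wtp: Optional[float] = None,
    life_table: Optional[LifeTable] = None,
    y_search: tuple[float, float] = (1e-9, 1.0),
    criterion: str = "cost_effective_at_wtp",
) -> pd.DataFrame:
    """Threshold curve partitioning the (x, y) plane between the two arms.

    For each x value (e.g. the C-section proportion) the y threshold (e.g.
    the carbetocin relative risk) is solved at the given WTP. Grid points
    with no threshold in the search interval appear with a NaN threshold
    and the decision that holds throughout.
    """
    if wtp is None:
        wtp = params.wtp_threshold
    rows = []
    for x in x_grid:
        res = find_threshold(
            params.replace(**{x_param: x}),
            y_param,
            criterion,
            wtp=wtp,
            life_table=life_table,
            search_interval=y_search,
        )
        rows.append(
            {
                x_param: x,
                f"{y_param}_threshold": res.threshold if res.found else np.nan,
                "found": res.found,
                "constant_decision": res.constant_decision,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo cloud of incremental outcomes with acceptance fractions."""

    n_draws: int
    seed: int
    incremental_cost: np.ndarray
    incremental_qaly_saved: np.ndarray
    wtp_list: tuple[float, ...]
    n_redraws: int = 0
    drawn_values: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def fraction_cost_saving(self) -> float:
        return float(np.mean(self.incremental_cost < 0))

    @property
    def fraction_qaly_saving(self) -> float:
        return float(np.mean(self.incremental_qaly_saved > 0))

    def fraction_cost_effective(self, wtp: float) -> float:
        """Fraction of draws where carbetocin is accepted at the given WTP.

        A draw is accepted when carbetocin saves QALYs at no extra cost, or
        saves QALYs with an ICER at or below the WTP.
        """
        dc = self.incremental_cost
        dq = self.incremental_qaly_saved
        accept = ((dq >= 0) & (dc <= 0)) | ((dq > 0) & (dc <= wtp * dq))
        return float(np.mean(accept))

    def to_frame(self) -> pd.DataFrame:
        """Cloud as a DataFrame, QALY saved first for direct scatter plotting."""
        return pd.DataFrame(
            {
                "incremental_qaly_saved": self.incremental_qaly_saved,
                "incremental_cost": self.incremental_cost,
            }
        )

    def summary(self) -> dict[str, float]:
        out = {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "n_redraws": self.n_redraws,
            "mean_incremental_cost": float(np.mean(self.incremental_cost)),
            "mean_incremental_qaly_saved": float(
                np.mean(self.incremental_qaly_saved)
            ),
            "fraction_cost_saving": self.fraction_cost_saving,
            "fraction_qaly_saving": self.fraction_qaly_saving,
        }
        for wtp in self.wtp_list:
            out[f"fraction_cost_effective_at_wtp_{wtp:g}"] = (
                self.fraction_cost_effective(wtp)
            )
        return out


def run_psa(
    params: ParameterSet,
    dists: Iterable[DistributionSpec] | Mapping[str, DistributionSpec],
    n_draws: int,
    seed: int,
    wtp_list: Sequence[float] = (0.0, 49630.0),
    life_table: Optional[LifeTable] = None,
    keep_draws: bool = False,
) -> PSAResult:
    """Probabilistic sensitivity analysis by Monte Carlo simulation.

    Every distributed parameter is redrawn independently for each of the
    ``n_draws`` iterations; parameters without a distribution stay at their
    base value. Both arms are re-evaluated per draw. A draw that fails
    parameter validation (possible only for pathological user-supplied
    specs) is redrawn, with the count reported.
    """
    if life_table is None:
        raise ValueError("life_table is required")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if isinstance(dists, Mapping):
        dists = list(dists.values())
    else:
        dists = list(dists)
    rng = np.random.default_rng(seed)
    base_values = params.to_dict()
    dc = np.empty(n_draws)
    dq = np.empty(n_draws)
    drawn_rows: list[dict[str, float]] = []
    n_redraws = 0
    for i in range(n_draws):
        while True:
            values = dict(base_values)
            for spec in dists:
                values[spec.parameter_name] = float(spec.sample(rng))
            try:
                p = ParameterSet(**values)
                break
            except Exception:
                n_redraws += 1
                if n_redraws > 100 * n_draws:
                    raise RuntimeError(
                        "parameter redraw limit exceeded; check distribution specs"
                    )
        res = base_case(p, life_table, wtp=params.wtp_threshold)
        dc[i] = res.incremental_cost
        dq[i] = res.incremental_qaly_saved
        if keep_draws:
            drawn_rows.append({s.parameter_name: values[s.parameter_name] for s in dists})
    if n_redraws:
        logger.warning("PSA redrew %d out-of-domain parameter draws", n_redraws)
    return PSAResult(
        n_draws=n_draws,
        seed=seed,
        incremental_cost=dc,
        incremental_qaly_saved=dq,
        wtp_list=tuple(wtp_list),
        n_redraws=n_redraws,
        drawn_values=pd.DataFrame(drawn_rows) if keep_draws else None,
    )
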