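"""Report writers: rounded summary tables, CSV/JSON artifacts, run manifest.

Display rounding follows the published precision (costs to integer USD,
per-1,000 event rates to one decimal, hysterectomy and death rates to two
decimals, QALY loss to five decimals); machine-readable outputs keep full
precision. Every written artifact sits next to a manifest recording the
config hash, seed(s), package version, timestamp and command line.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cea_engine import CEAResult, PSAResult, base_case
from .cohort_tree import ARMS, expected_event_rates
from .parameters import ModelConfig, ParameterSet
from .qaly_model import LifeTable

__all__ = [
    "RunManifest",
    "basecase_table",
    "write_basecase",
    "write_dsa",
    "write_twoway",
    "write_psa",
]


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one report run."""

    command: str
    config_path: str
    config_sha256: str
    life_table_path: str
    seed: Optional[int]
    package_version: str
    timestamp: str

    @classmethod
    def create(
        cls,
        command: str,
        config_path: Optional[Path],
        life_table_path: Optional[Path],
        seed: Optional[int] = None,
    ) -> "RunManifest":
        return cls(
            command=command,
            config_path=str(config_path) if config_path else "<packaged default>",
            config_sha256=_sha256(config_path) if config_path else "",
            life_table_path=(
                str(life_table_path) if life_table_path else "<packaged default>"
            ),
            seed=seed,
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


def _sha256(path: Optional[Path]) -> str:
    if path is None:
        return ""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def basecase_table(
    params: ParameterSet, life_table: LifeTable, rounded: bool = True
) -> pd.DataFrame:
    """Per-arm summary: cost, event rates per 1,000 births, QALY loss.

    With ``rounded=True`` values are rounded to the published display
    precision; otherwise full precision is kept.
    """
    res = base_case(params, life_table)
    cost = {
        "oxytocin": res.cost_oxytocin.expected_cost_per_birth,
        "carbetocin": res.cost_carbetocin.expected_cost_per_birth,
    }
    qaly = {
        "oxytocin": res.qaly_loss_oxytocin.qaly_loss_per_birth,
        "carbetocin": res.qaly_loss_carbetocin.qaly_loss_per_birth,
    }
    rows = []
    for arm in ARMS:
        ev = expected_event_rates(params, arm)
        row = {
            "arm": arm,
            "total_cost_usd_per_birth": cost[arm],
            "pph_500_per_1000": ev.pph_500_per_birth * 1000,
            "pph_1500_per_1000": ev.pph_1500_per_birth * 1000,
            "hysterectomy_per_1000": ev.hysterectomy_per_birth * 1000,
            "death_per_1000": ev.death_per_birth * 1000,
            "qaly_loss_per_birth": qaly[arm],
        }
        if rounded:
            row["total_cost_usd_per_birth"] = round(row["total_cost_usd_per_birth"])
            row["pph_500_per_1000"] = round(row["pph_500_per_1000"], 1)
            row["pph_1500_per_1000"] = round(row["pph_1500_per_1000"], 1)
            row["hysterectomy_per_1000"] = round(row["hysterectomy_per_1000"], 2)
            row["death_per_1000"] = round(row["death_per_1000"], 2)
            row["qaly_loss_per_birth"] = round(row["qaly_loss_per_birth"], 5)
        rows.append(row)
    return pd.DataFrame(rows)


def _incremental_summary(res: CEAResult) -> dict:
    return res.summary()


def write_basecase(
    params: ParameterSet,
    life_table: LifeTable,
    out_dir: Path,
    manifest: RunManifest,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    basecase_table(params, life_table, rounded=True).to_csv(
        out_dir / "basecase_rounded.csv", index=False
    )
    basecase_table(params, life_table, rounded=False).to_csv(
        out_dir / "basecase_full.csv", index=False
    )
    res = base_case(params, life_table)
    (out_dir / "incremental.json").write_text(
        json.dumps(_incremental_summary(res), indent=2) + "\n"
    )
    # per-path cost audit trail
    audit = []
    for arm_cost in (res.cost_oxytocin, res.cost_carbetocin):
        for pc, p in arm_cost.breakdown:
            audit.append(
                {
                    "arm": pc.arm,
                    "mode": pc.mode,
                    "terminal": pc.terminal,
                    "probability": p,
                    "prevention_cost": pc.prevention_cost,
                    "treatment_drug_cost": pc.treatment_drug_cost,
                    "procedure_cost": pc.procedure_cost,
                    "stay_cost": pc.stay_cost,
                    "total": pc.total,
                }
            )
    pd.DataFrame(audit).to_csv(out_dir / "path_costs.csv", index=False)
    manifest.write(out_dir)


def write_dsa(tornado: pd.DataFrame, out_dir: Path, manifest: RunManifest) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tornado.to_csv(out_dir / "tornado.csv", index=False)
    manifest.write(out_dir)


def write_twoway(curve: pd.DataFrame, out_dir: Path, manifest: RunManifest) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curve.to_csv(out_dir / "threshold_curve.csv", index=False)
    manifest.write(out_dir)


def write_psa(result: PSAResult, out_dir: Path, manifest: RunManifest) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out_dir / "psa_cloud.csv", index=False)
    (out_dir / "psa_summary.json").write_text(
        json.dumps(result.summary(), indent=2) + "\n"
    )
    manifest.write(out_dir)
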