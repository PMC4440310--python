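"""Projection tables, summary statistics of the ensemble, and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import pandas as pd

from .engine import EnsembleSummary
from .errors import ReportError, UndefinedStatisticError
from .marginals import round_half_up
from . import __version__

#: Quantities reported in the projection table, with display labels.
TABLE_QUANTITIES = {
    "n_training": "Training position",
    "n_transition": "Transition positions",
    "n_fixed": "Fixed positions",
    "n_retired": "Retirees",
}


def make_table2(summary: EnsembleSummary) -> pd.DataFrame:
    """Projection table: one row per year, "median (lo to hi)" per quantity.

    Medians and bands are rounded to integers for display; use
    ``EnsembleSummary.summary()`` for full precision.
    """
    missing = [q for q in TABLE_QUANTITIES if q not in summary.quantities]
    if missing:
        raise ReportError(f"summary lacks quantities {missing!r}")
    if len(summary.years) == 0:
        raise ReportError("summary covers no years")
    tidy = summary.summary().set_index(["year", "quantity"])
    rows = {}
    for year in summary.years:
        cells = {}
        for q, label in TABLE_QUANTITIES.items():
            med, lo, hi = tidy.loc[(int(year), q), ["median", "lo95", "hi95"]]
            cells[label] = (
                f"{round_half_up(med)} ({round_half_up(lo)} to {round_half_up(hi)})"
            )
        rows[int(year)] = cells
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "Year"
    return table


def decline_percent(
    summary: EnsembleSummary, quantity: str, year_a: int, year_b: int
) -> int:
    """Integer percent decline of a quantity's median between two years."""
    med_a = summary.median(quantity, year_a)
    med_b = summary.median(quantity, year_b)
    if med_a == 0:
        raise UndefinedStatisticError(f"{quantity} median is zero in {year_a}")
    return round_half_up(100.0 * (med_a - med_b) / med_a)


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def config_checksum(config: dict) -> str:
    """SHA-256 of the canonical JSON rendering of a config document."""
    canonical = json.dumps(_stringify_keys(config), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every set of output files.

    The timestamp is informational; all result files are byte-identical across
    re-runs of the same (config, seed, replicates) triple.
    """

    scenario: dict
    config_checksum: str
    master_seed: object
    n_replicates: int
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "config_checksum": self.config_checksum,
            "master_seed": self.master_seed,
            "n_replicates": self.n_replicates,
            "version": self.version,
            "timestamp": self.timestamp,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)
            fh.write("\n")
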