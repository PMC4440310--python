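"""Full-time-equivalent coverage of transition (senior-registrar) posts.

Headcounts overstate staffing when part of the workforce works part-time, so
transition coverage is expressed in FTE: each occupant contributes 1.0 if
full-time and a weight ``w`` in (0, 1) if part-time. The published survey never
states the part-timers' hours fraction, so ``w`` is calibrated from the
published baseline-year gap (10% of transition FTE unfilled at the end of the
first projected year), leaving the end-of-horizon gap as genuine validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort as _c
from .engine import EnsembleSummary
from .errors import CalibrationError, ValidationError


@dataclass(frozen=True)
class FTEParameters:
    """Weights and demand baseline for the FTE gap computation."""

    part_time_weight: float          # w, fraction of full time, in (0, 1]
    transition_demand_fte: float     # full-time posts needed
    calibration_anchor: float | None = None  # baseline-year gap (%), if calibrated

    def __post_init__(self) -> None:
        if not 0.0 < self.part_time_weight <= 1.0:
            raise ValidationError("part_time_weight must lie in (0, 1]")
        if self.transition_demand_fte <= 0:
            raise ValidationError("transition_demand_fte must be positive")


def fte_filled(census: pd.DataFrame) -> float:
    """Sum of FTE weights over the transition occupants of a roster census."""
    occ = census[census["state"] == _c.STATE_LABELS[_c.TRANSITION]]
    return float(occ["fte_weight"].sum())


def calibrate_part_time_weight(
    part_time_share: float,
    baseline_headcount: float,
    demand: float,
    anchor_gap_percent: float,
) -> float:
    """Solve the part-time weight from the baseline-year gap anchor.

    With part-time share ``p`` among the baseline transition occupants, filled
    FTE is ``(1 - p + p*w) * headcount``; setting the gap
    ``100 * (1 - filled/demand)`` equal to the anchor and inverting gives ``w``.
    Raises if no solution lies strictly inside (0, 1).
    """
    if not 0.0 < part_time_share <= 1.0:
        raise CalibrationError(
            f"part-time share must be in (0, 1], got {part_time_share}"
        )
    if baseline_headcount <= 0 or demand <= 0:
        raise CalibrationError("baseline headcount and demand must be positive")
    w = ((1.0 - anchor_gap_percent / 100.0) * demand / baseline_headcount
         - (1.0 - part_time_share)) / part_time_share
    if not 0.0 < w < 1.0:
        raise CalibrationError(
            f"no admissible part-time weight: solution w={w:.4f} outside (0, 1) "
            f"(share={part_time_share:.4f}, headcount={baseline_headcount}, "
            f"demand={demand}, anchor={anchor_gap_percent}%)"
        )
    return float(w)


def calibrate_from_census(
    baseline_census: pd.DataFrame,
    demand: float,
    anchor_gap_percent: float,
) -> float:
    """As :func:`calibrate_part_time_weight`, with p and headcount read off a census."""
    occ = baseline_census[baseline_census["state"] == _c.STATE_LABELS[_c.TRANSITION]]
    if occ.empty:
        raise CalibrationError("baseline census has no transition occupants")
    share = float(occ["part_time"].mean())
    return calibrate_part_time_weight(share, len(occ), demand, anchor_gap_percent)


def gap_matrix(ensemble: EnsembleSummary, params: FTEParameters) -> np.ndarray:
    """(replicates, years) matrix of gap percentages.

    Filled FTE is reconstructed from the per-year transition headcount and its
    part-time subcount, so the gap can be re-evaluated for any weight without
    re-running the simulation.
    """
    n = ensemble.replicate_matrix("n_transition")
    n_pt = ensemble.replicate_matrix("n_transition_part_time")
    filled = (n - n_pt) + params.part_time_weight * n_pt
    return 100.0 * (1.0 - filled / params.transition_demand_fte)


def fte_gap_series(ensemble: EnsembleSummary, params: FTEParameters) -> pd.DataFrame:
    """Per-year median and 95% band of the unfilled-FTE percentage."""
    gaps = gap_matrix(ensemble, params)
    return pd.DataFrame({
        "year": ensemble.years.astype(int),
        "median": np.median(gaps, axis=0),
        "lo95": np.percentile(gaps, 2.5, axis=0),
        "hi95": np.percentile(gaps, 97.5, axis=0),
    })
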