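"""Annual-step Markov microsimulation of the four-state workforce.

Each person occupies one of TRAINING, TRANSITION (senior registrar), FIXED
(permanent post) or RETIRED; DEPARTED tracks foreign staff leaving under the
return policy. One simulated year applies, in order:

1. ageing (+1 year of age and of state residence for all actives);
2. retirement of every active whose age has reached their desired retirement age;
3. certification of trainees who completed the official training residence —
   foreign certificants depart under a strict return policy, the rest move to
   transition posts;
4. attrition of foreign transition occupants at an annual departure hazard;
5. vacancy-chain promotion: fixed posts are refilled from the transition pool
   up to capacity, by seniority (longest state residence, then older age, then
   lower person id);
6. quota refill of the training pool with new entrants.

Uncertainty is Monte-Carlo: each replicate draws a fresh cohort and trajectory
from an independent substream of a master seed, and summaries are empirical
medians with 2.5/97.5 percentile bands.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cohort as _c
from .errors import ValidationError
from .marginals import LEGAL_RETIREMENT_AGE, SurveyMarginals

QUANTITIES = (
    "n_training", "n_transition", "n_fixed",
    "n_retired", "n_departed", "n_entrants",
    "n_transition_part_time", "fte_transition_filled",
)

DEFAULT_STATE_COUNTS = {"TRAINING": 66, "TRANSITION": 99, "FIXED": 248}


@dataclass(frozen=True)
class PolicyScenario:
    """Quota/return-policy scenario settings.

    ``foreign_departure_hazard`` is the annual probability that a foreign
    transition occupant leaves the country; it is not published and is normally
    obtained from :func:`calibrate_hazard` (``None`` means "to be calibrated").
    """

    start_year: int = 2014
    horizon_year: int = 2024
    quota: int = 66
    fixed_capacity: int = 244
    transition_demand: float | None = None
    training_state_years: float = 5.0
    return_policy: bool = True
    foreign_departure_hazard: float | None = None
    legal_retirement_age: Mapping[str, float] = field(
        default_factory=lambda: dict(LEGAL_RETIREMENT_AGE)
    )

    def __post_init__(self) -> None:
        if self.quota < 0:
            raise ValidationError("quota must be non-negative")
        if self.fixed_capacity < 0:
            raise ValidationError("fixed_capacity must be non-negative")
        if self.start_year > self.horizon_year:
            raise ValidationError("start_year must not exceed horizon_year")
        h = self.foreign_departure_hazard
        if h is not None and not 0.0 <= h <= 1.0:
            raise ValidationError("foreign_departure_hazard must lie in [0, 1]")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.horizon_year + 1)

    def replace(self, **kw) -> "PolicyScenario":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PolicyScenario":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"scenario: unknown fields {sorted(unknown)!r}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["legal_retirement_age"] = dict(d["legal_retirement_age"])
        return d


# ------------------------------------------------------------- the annual step
def _step(
    a: dict,
    scenario: PolicyScenario,
    rng: np.random.Generator,
    marginals: SurveyMarginals,
    part_time_weight: float,
) -> dict:
    """Advance the arrays ``a`` by one year in place; return the year record."""
    state = a["state"]
    hazard = scenario.foreign_departure_hazard or 0.0

    # 1. ageing
    active = state <= _c.FIXED
    a["age"][active] += 1.0
    a["years_in_state"][active] += 1.0

    # 2. retirement at the desired age
    retiring = active & (a["age"] >= a["desired_retirement_age"])
    state[retiring] = _c.RETIRED
    n_retired = int(retiring.sum())

    # 3. certification out of training
    certifying = (state == _c.TRAINING) & (
        a["years_in_state"] >= scenario.training_state_years
    )
    if scenario.return_policy:
        leaving = certifying & a["foreign"]
        state[leaving] = _c.DEPARTED
        certifying &= ~a["foreign"]
    state[certifying] = _c.TRANSITION
    a["years_in_state"][certifying] = 0.0

    # 4. foreign attrition in transition posts
    at_risk = (state == _c.TRANSITION) & a["foreign"]
    if hazard > 0.0 and at_risk.any():
        departs = at_risk & (rng.random(len(state)) < hazard)
        state[departs] = _c.DEPARTED

    # 5. vacancy-chain promotion into fixed posts
    vacancies = scenario.fixed_capacity - int((state == _c.FIXED).sum())
    if vacancies > 0:
        pool = np.flatnonzero(state == _c.TRANSITION)
        if pool.size:
            order = np.lexsort((
                a["person_id"][pool],
                -a["age"][pool],
                -a["years_in_state"][pool],
            ))
            chosen = pool[order[:vacancies]]
            state[chosen] = _c.FIXED
            a["years_in_state"][chosen] = 0.0

    # 6. quota refill of the training pool
    n_new = scenario.quota - int((state == _c.TRAINING).sum())
    if n_new > 0:
        entrants = _c._sample_entrant_arrays(
            n_new, marginals, rng, part_time_weight,
            start_id=int(a["person_id"].max(initial=-1)) + 1,
        )
        for key in entrants:
            a[key] = np.concatenate([a[key], entrants[key]])
        state = a["state"]

    in_transition = state == _c.TRANSITION
    n_dep_total = int((state == _c.DEPARTED).sum())
    record = {
        "n_training": int((state == _c.TRAINING).sum()),
        "n_transition": int(in_transition.sum()),
        "n_fixed": int((state == _c.FIXED).sum()),
        "n_retired": n_retired,
        "n_departed": n_dep_total - a["_departed_before"],
        "n_entrants": max(n_new, 0),
        "n_transition_part_time": int((in_transition & a["part_time"]).sum()),
        "fte_transition_filled": float(a["fte_weight"][in_transition].sum()),
    }
    a["_departed_before"] = n_dep_total
    return record


def annual_step(
    roster: pd.DataFrame,
    scenario: PolicyScenario,
    rng,
    marginals: SurveyMarginals,
    part_time_weight: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """One simulated year on a roster DataFrame.

    Returns the updated roster and the end-of-year record (censuses and flows).
    """
    rng = _c._as_rng(rng)
    a = _c._frame_to_arrays(roster)
    a["_departed_before"] = int((a["state"] == _c.DEPARTED).sum())
    record = _step(a, scenario, rng, marginals, part_time_weight)
    a.pop("_departed_before")
    return _c._arrays_to_frame(a), record


def simulate_replicate(
    initial_roster: pd.DataFrame,
    scenario: PolicyScenario,
    rng,
    marginals: SurveyMarginals,
    part_time_weight: float = 1.0,
) -> pd.DataFrame:
    """One full trajectory: the annual step applied start_year..horizon_year.

    Returns a DataFrame with one row per year (end-of-year censuses and
    within-year flows).
    """
    rng = _c._as_rng(rng)
    a = _c._frame_to_arrays(initial_roster)
    return _simulate_arrays(a, scenario, rng, marginals, part_time_weight)


def _simulate_arrays(a, scenario, rng, marginals, part_time_weight) -> pd.DataFrame:
    a["_departed_before"] = int((a["state"] == _c.DEPARTED).sum())
    records = []
    for year in scenario.years:
        rec = _step(a, scenario, rng, marginals, part_time_weight)
        rec["year"] = int(year)
        records.append(rec)
    return pd.DataFrame(records)[["year", *QUANTITIES]]


# --------------------------------------------------------------- Monte Carlo
@dataclass(frozen=True)
class EnsembleSummary:
    """Per-year medians and 95% percentile bands across replicates.

    ``values`` has shape (replicates, years, quantities); percentile bands use
    the empirical 2.5/97.5 percentiles with linear interpolation.
    """

    years: np.ndarray
    quantities: tuple
    values: np.ndarray
    n_replicates: int
    master_seed: object

    def replicate_matrix(self, quantity: str) -> np.ndarray:
        """(replicates, years) array for one quantity."""
        return self.values[:, :, self.quantities.index(quantity)]

    def median(self, quantity: str, year: int) -> float:
        iy = int(np.where(self.years == year)[0][0])
        return float(np.median(self.replicate_matrix(quantity)[:, iy]))

    def summary(self) -> pd.DataFrame:
        """Tidy frame: year, quantity, median, lo95, hi95."""
        rows = []
        for qi, q in enumerate(self.quantities):
            mat = self.values[:, :, qi]
            med = np.median(mat, axis=0)
            lo = np.percentile(mat, 2.5, axis=0)
            hi = np.percentile(mat, 97.5, axis=0)
            for yi, year in enumerate(self.years):
                rows.append((int(year), q, med[yi], lo[yi], hi[yi]))
        return pd.DataFrame(rows, columns=["year", "quantity", "median", "lo95", "hi95"])


def run_monte_carlo(
    marginals: SurveyMarginals,
    state_counts: Mapping[str, int],
    scenario: PolicyScenario,
    n_replicates: int,
    master_seed,
    part_time_weight: float = 1.0,
) -> EnsembleSummary:
    """Monte-Carlo ensemble: fresh cohort + trajectory per replicate.

    Each replicate consumes an independent child of
    ``numpy.random.SeedSequence(master_seed)``, so results are reproducible
    bit-for-bit given the master seed.
    """
    if n_replicates < 2:
        raise ValidationError("n_replicates must be at least 2 to form percentiles")
    if scenario.foreign_departure_hazard is None:
        raise ValidationError(
            "scenario.foreign_departure_hazard is unset; calibrate it first or "
            "set an explicit value"
        )
    ss = (master_seed if isinstance(master_seed, np.random.SeedSequence)
          else np.random.SeedSequence(master_seed))
    years = scenario.years
    values = np.empty((n_replicates, len(years), len(QUANTITIES)))
    for i, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        a = _c._sample_arrays(marginals, state_counts, rng, part_time_weight)
        traj = _simulate_arrays(a, scenario, rng, marginals, part_time_weight)
        values[i] = traj[list(QUANTITIES)].to_numpy()
    return EnsembleSummary(
        years=years, quantities=tuple(QUANTITIES), values=values,
        n_replicates=n_replicates, master_seed=master_seed,
    )


# ---------------------------------------------------------------- calibration
@dataclass(frozen=True)
class HazardCalibration:
    hazard: float
    sse: float
    grid: np.ndarray
    errors: np.ndarray          # SSE per grid point
    anchors: dict               # year -> target transition median
    achieved: dict              # year -> simulated transition median at optimum
    at_boundary: bool

    def to_dict(self) -> dict:
        return {
            "hazard": self.hazard,
            "sse": self.sse,
            "anchors": {int(k): float(v) for k, v in self.anchors.items()},
            "achieved": {int(k): float(v) for k, v in self.achieved.items()},
            "at_boundary": self.at_boundary,
        }


def calibrate_hazard(
    marginals: SurveyMarginals,
    state_counts: Mapping[str, int],
    scenario: PolicyScenario,
    anchors: Mapping[int, float],
    master_seed,
    n_replicates: int = 200,
    grid: Sequence[float] | None = None,
) -> HazardCalibration:
    """Grid-search the foreign departure hazard against trajectory anchors.

    ``anchors`` are (year, target transition-median) pairs; the squared error of
    the simulated medians at those years is minimised over hazard values 0-0.5
    in steps of 0.01. All grid points share the same master seed (common random
    numbers), so the search is deterministic.
    """
    if not anchors:
        raise ValidationError("calibrate_hazard: no anchors supplied")
    years = set(int(y) for y in anchors)
    if not years <= set(int(y) for y in scenario.years):
        raise ValidationError("calibrate_hazard: anchor years outside the horizon")
    if grid is None:
        grid = np.round(np.arange(0.0, 0.5 + 1e-9, 0.01), 10)
    grid = np.asarray(grid, dtype=float)

    errors = np.empty(len(grid))
    medians = []
    for gi, h in enumerate(grid):
        ens = run_monte_carlo(
            marginals, state_counts, scenario.replace(foreign_departure_hazard=float(h)),
            n_replicates=n_replicates, master_seed=master_seed,
        )
        med = {int(y): ens.median("n_transition", int(y)) for y in anchors}
        medians.append(med)
        errors[gi] = sum((med[int(y)] - float(t)) ** 2 for y, t in anchors.items())

    best = int(np.argmin(errors))
    return HazardCalibration(
        hazard=float(grid[best]),
        sse=float(errors[best]),
        grid=grid,
        errors=errors,
        anchors={int(y): float(t) for y, t in anchors.items()},
        achieved=medians[best],
        at_boundary=best in (0, len(grid) - 1),
    )
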