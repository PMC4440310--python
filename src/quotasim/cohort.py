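"""Synthetic individual-level roster of anaesthetists.

The person-level survey data behind the published marginals are not available,
so the cohort is re-created synthetically: every attribute is drawn from its
published marginal, except that nationality is drawn conditional on position
and hospital type conditional on nationality (the two published
cross-tabulations), and age is drawn conditional on career stage (training,
transition, fixed). Any joint structure beyond that is a modelling choice, not
data, and is documented in the methods note.

Rosters are plain :class:`pandas.DataFrame` objects with one row per person
(column order in :data:`ROSTER_COLUMNS`); the simulation engine converts them
to flat arrays internally.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SamplingError, ValidationError
from .marginals import (
    AGE_BANDS,
    SurveyMarginals,
    TRAINING_DURATION_TOP,
)

# State codes (ints for fast array work). RETIRED and DEPARTED are absorbing;
# DEPARTED is a bookkeeping state for foreign staff leaving under the return
# policy, kept separate so the four-state census is unaffected.
TRAINING, TRANSITION, FIXED, RETIRED, DEPARTED = range(5)
STATE_LABELS = {
    TRAINING: "TRAINING",
    TRANSITION: "TRANSITION",
    FIXED: "FIXED",
    RETIRED: "RETIRED",
    DEPARTED: "DEPARTED",
}
STATE_CODES = {v: k for k, v in STATE_LABELS.items()}
ACTIVE_STATES = (TRAINING, TRANSITION, FIXED)

#: Canonical roster column order for CSV round-trips. ``part_time`` is kept
#: alongside ``fte_weight`` so the weight can be recalibrated without
#: resampling the roster.
ROSTER_COLUMNS = [
    "person_id", "age", "gender", "nationality", "state", "hospital",
    "part_time", "fte_weight", "desired_retirement_age", "years_in_state",
    "total_training_duration",
]

# Age ranges by career stage (years). The bounds are chosen so that the
# state-conditional mixture reproduces the published overall age-band marginal;
# see docs/methods.md.
TRAINING_AGE_RANGE = (26.0, 35.0)
TRANSITION_AGE_RANGE = (33.0, 45.0)
FIXED_MIN_AGE = 33.0
ENTRANT_AGE_RANGE = (26.0, 30.0)

#: Minimum admissible desired retirement age (years).
RETIREMENT_FLOOR = 55.0

def draw_retirement_age(
    gender: str,
    marginals: SurveyMarginals,
    rng: np.random.Generator,
    size: int | None = None,
    lower: float = RETIREMENT_FLOOR,
) -> float | np.ndarray:
    """Desired retirement age: gendered normal truncated to [lower, legal age]."""
    mean, sd = marginals.retirement_age[gender]
    upper = marginals.legal_retirement_age[gender]
    n = 1 if size is None else size
    if sd == 0:
        out = np.full(n, min(max(mean, lower), upper))
    else:
        a, b = (lower - mean) / sd, (upper - mean) / sd
        out = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return float(out[0]) if size is None else out


def _length_biased_retirement_age(
    gender: str,
    marginals: SurveyMarginals,
    rng: np.random.Generator,
    size: int,
    lower: float = 57.0,
    origin: float = 56.0,
) -> np.ndarray:
    """Retirement-age draws weighted by time remaining past ``origin``.

    Someone observed still active past ``origin`` is more likely to have a late
    desired retirement age (stationary-renewal length bias); draws come from the
    truncated normal reweighted by ``ret - origin``, via rejection sampling.
    """
    mean, sd = marginals.retirement_age[gender]
    upper = marginals.legal_retirement_age[gender]
    if sd == 0:
        return np.full(size, min(max(mean, lower), upper))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    max_w = upper - origin
    out = np.empty(size)
    filled = 0
    while filled < size:
        k = 2 * (size - filled) + 8
        cand = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=k, random_state=rng)
        accepted = cand[rng.random(k) < (cand - origin) / max_w]
        take = accepted[: size - filled]
        out[filled:filled + take.size] = take
        filled += take.size
    return out


def draw_training_duration(
    marginals: SurveyMarginals,
    rng: np.random.Generator,
    size: int | None = None,
) -> int | np.ndarray:
    """Graduation-to-certification interval from the empirical distribution.

    The open top category is drawn as its lower bound (15 years).
    """
    counts = marginals.training_duration_counts
    values = np.array(
        [15 if k == TRAINING_DURATION_TOP else int(k) for k in counts], dtype=np.int64
    )
    weights = np.array([counts[k] for k in counts], dtype=float)
    if weights.sum() <= 0:
        raise SamplingError("training duration distribution is empty")
    probs = weights / weights.sum()
    out = rng.choice(values, size=1 if size is None else size, p=probs)
    return int(out[0]) if size is None else out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _fixed_band_probs(n_training: int, n_transition: int, n_fixed: int,
                      marginals: SurveyMarginals) -> np.ndarray:
    """Residual age-band distribution for FIXED occupants.

    Training and transition stages occupy fixed age windows, so the fixed pool
    receives whatever probability mass remains of the overall band marginal;
    this makes the cohort-level band frequencies match the published marginal
    in expectation.
    """
    band_probs = np.array(
        [marginals.probabilities("age_band")[b] for b in AGE_BANDS]
    )
    total = n_training + n_transition + n_fixed
    lo, hi = TRANSITION_AGE_RANGE
    p_trans_le35 = max(0.0, min(36.0, hi) - lo) / (hi - lo)
    young = np.array([
        n_training + n_transition * p_trans_le35,
        n_transition * (1.0 - p_trans_le35),
        0.0,
    ])
    residual = np.maximum(band_probs * total - young, 0.0)
    if residual.sum() <= 0:
        raise SamplingError("no age-band probability mass left for FIXED occupants")
    return residual / residual.sum()


def _sample_arrays(
    marginals: SurveyMarginals,
    state_counts: Mapping[str, int],
    rng: np.random.Generator,
    part_time_weight: float = 1.0,
) -> dict:
    """Column arrays for a fresh cohort (internal; see :func:`sample_cohort`)."""
    for state, n in state_counts.items():
        if state not in STATE_CODES:
            raise ValidationError(f"unknown state {state!r}")
        if n < 0:
            raise ValidationError(f"state_counts[{state}] is negative")
    n_tr = int(state_counts.get("TRAINING", 0))
    n_ts = int(state_counts.get("TRANSITION", 0))
    n_fx = int(state_counts.get("FIXED", 0))
    n = n_tr + n_ts + n_fx

    state = np.concatenate([
        np.full(n_tr, TRAINING, dtype=np.int8),
        np.full(n_ts, TRANSITION, dtype=np.int8),
        np.full(n_fx, FIXED, dtype=np.int8),
    ])

    p_male = marginals.probabilities("gender")["male"]
    male = rng.random(n) < p_male
    p_part = marginals.probabilities("parttime")["part_time"]
    part_time = rng.random(n) < p_part

    foreign_by_pos = marginals.foreign_share_by_position()
    p_foreign = np.concatenate([
        np.full(n_tr, foreign_by_pos["training"]),
        np.full(n_ts, foreign_by_pos["transition"]),
        np.full(n_fx, foreign_by_pos["fixed"]),
    ])
    foreign = rng.random(n) < p_foreign

    hospital = np.empty(n, dtype=object)
    for is_foreign, nat in ((False, "swiss"), (True, "foreign")):
        mask = foreign == is_foreign
        k = int(mask.sum())
        if k == 0:
            continue
        probs = marginals.hospital_probs(nat)
        cats = np.array(list(probs), dtype=object)
        hospital[mask] = rng.choice(cats, size=k, p=np.array(list(probs.values())))

    ret = np.empty(n)
    for is_male, g in ((True, "male"), (False, "female")):
        mask = male == is_male
        if mask.any():
            ret[mask] = draw_retirement_age(g, marginals, rng, size=int(mask.sum()))

    # ages conditional on career stage
    age = np.empty(n)
    age[:n_tr] = rng.uniform(*TRAINING_AGE_RANGE, size=n_tr)
    age[n_tr:n_tr + n_ts] = rng.uniform(*TRANSITION_AGE_RANGE, size=n_ts)
    if n_fx:
        probs = _fixed_band_probs(n_tr, n_ts, n_fx, marginals)
        bands = rng.choice(len(AGE_BANDS), size=n_fx, p=probs)
        fage = np.empty(n_fx)
        fslice = slice(n_tr + n_ts, n)
        for bi, band in enumerate(AGE_BANDS):
            bmask = bands == bi
            k = int(bmask.sum())
            if k == 0:
                continue
            if band == "<=35":
                fage[bmask] = rng.uniform(33.0, 36.0, size=k)
            elif band == "36-55":
                # Residual of a flat cohort-wide age density over [36, 56):
                # transition posts already occupy [36, 45), so fixed posts get
                # what remains there plus the full density on [45, 56).
                t_lo, t_hi = TRANSITION_AGE_RANGE
                d_trans = n_ts / (t_hi - t_lo)
                w_lo, w_hi = 45.0 - 36.0, 56.0 - 45.0
                target = n_fx * probs[bi]
                d = (target + w_lo * d_trans) / (w_lo + w_hi)
                if d < d_trans:          # transition alone overfills [36, 45)
                    d_low = 0.0
                    d = target / w_hi
                else:
                    d_low = d - d_trans
                p_low = np.clip(w_lo * d_low / target, 0.0, 1.0) if target > 0 else 0.0
                low = rng.random(k) < p_low
                fage[bmask] = np.where(
                    low,
                    rng.uniform(36.0, 45.0, size=k),
                    rng.uniform(45.0, np.minimum(56.0, ret[fslice][bmask]), size=k),
                )
            else:  # ">=56"
                # Still active at 56+: retirement preference is length-biased
                # towards late retirement; age is then uniform below it.
                idx = np.where(bmask)[0] + n_tr + n_ts
                for is_male, g in ((True, "male"), (False, "female")):
                    gm = male[idx] == is_male
                    if gm.any():
                        ret[idx[gm]] = _length_biased_retirement_age(
                            g, marginals, rng, size=int(gm.sum())
                        )
                fage[bmask] = rng.uniform(56.0, ret[idx])
        age[fslice] = fage

    years_in_state = np.empty(n)
    years_in_state[:n_tr] = rng.uniform(0.0, 5.0, size=n_tr)
    years_in_state[n_tr:n_tr + n_ts] = rng.uniform(0.0, 4.0, size=n_ts)
    years_in_state[n_tr + n_ts:] = rng.uniform(
        0.0, np.maximum(age[n_tr + n_ts:] - FIXED_MIN_AGE, 0.0)
    )

    duration = draw_training_duration(marginals, rng, size=n) if n else np.array([], dtype=np.int64)

    return {
        "person_id": np.arange(n, dtype=np.int64),
        "age": age,
        "male": male,
        "foreign": foreign,
        "state": state,
        "hospital": hospital,
        "part_time": part_time,
        "fte_weight": np.where(part_time, float(part_time_weight), 1.0),
        "desired_retirement_age": ret,
        "years_in_state": years_in_state,
        "total_training_duration": np.asarray(duration, dtype=np.int64),
    }


def _sample_entrant_arrays(
    n: int,
    marginals: SurveyMarginals,
    rng: np.random.Generator,
    part_time_weight: float,
    start_id: int,
) -> dict:
    """New training entrants under the quota refill rule.

    Entrants are young (uniform 26-30), with gender and part-time status from
    the overall marginals and the nationality mix of the current trainee pool.
    """
    male = rng.random(n) < marginals.probabilities("gender")["male"]
    part_time = rng.random(n) < marginals.probabilities("parttime")["part_time"]
    foreign = rng.random(n) < marginals.foreign_share_by_position()["training"]
    ret = np.empty(n)
    for is_male, g in ((True, "male"), (False, "female")):
        mask = male == is_male
        if mask.any():
            ret[mask] = draw_retirement_age(g, marginals, rng, size=int(mask.sum()))
    hospital = np.empty(n, dtype=object)
    for is_foreign, nat in ((False, "swiss"), (True, "foreign")):
        mask = foreign == is_foreign
        k = int(mask.sum())
        if k:
            probs = marginals.hospital_probs(nat)
            hospital[mask] = rng.choice(
                np.array(list(probs), dtype=object), size=k,
                p=np.array(list(probs.values())),
            )
    return {
        "person_id": np.arange(start_id, start_id + n, dtype=np.int64),
        "age": rng.uniform(*ENTRANT_AGE_RANGE, size=n),
        "male": male,
        "foreign": foreign,
        "state": np.full(n, TRAINING, dtype=np.int8),
        "hospital": hospital,
        "part_time": part_time,
        "fte_weight": np.where(part_time, float(part_time_weight), 1.0),
        "desired_retirement_age": ret,
        "years_in_state": np.zeros(n),
        "total_training_duration": draw_training_duration(marginals, rng, size=n),
    }


def _arrays_to_frame(arrays: Mapping[str, np.ndarray]) -> pd.DataFrame:
    df = pd.DataFrame({
        "person_id": arrays["person_id"],
        "age": arrays["age"],
        "gender": np.where(arrays["male"], "male", "female"),
        "nationality": np.where(arrays["foreign"], "foreign", "swiss"),
        "state": np.array([STATE_LABELS[s] for s in arrays["state"]], dtype=object),
        "hospital": arrays["hospital"],
        "part_time": arrays["part_time"],
        "fte_weight": arrays["fte_weight"],
        "desired_retirement_age": arrays["desired_retirement_age"],
        "years_in_state": arrays["years_in_state"],
        "total_training_duration": arrays["total_training_duration"],
    })
    return df[ROSTER_COLUMNS]


def _frame_to_arrays(roster: pd.DataFrame) -> dict:
    state = np.array([STATE_CODES[s] for s in roster["state"]], dtype=np.int8)
    return {
        "person_id": roster["person_id"].to_numpy(dtype=np.int64),
        "age": roster["age"].to_numpy(dtype=float),
        "male": (roster["gender"].to_numpy() == "male"),
        "foreign": (roster["nationality"].to_numpy() == "foreign"),
        "state": state,
        "hospital": roster["hospital"].to_numpy(dtype=object),
        "part_time": roster["part_time"].to_numpy(dtype=bool),
        "fte_weight": roster["fte_weight"].to_numpy(dtype=float),
        "desired_retirement_age": roster["desired_retirement_age"].to_numpy(dtype=float),
        "years_in_state": roster["years_in_state"].to_numpy(dtype=float),
        "total_training_duration": roster["total_training_duration"].to_numpy(dtype=np.int64),
    }


def sample_cohort(
    marginals: SurveyMarginals,
    state_counts: Mapping[str, int],
    seed,
    part_time_weight: float = 1.0,
) -> pd.DataFrame:
    """Sample a synthetic roster of active anaesthetists.

    Parameters
    ----------
    marginals : SurveyMarginals
        Published survey distributions.
    state_counts : mapping
        Initial headcount per state, e.g. ``{"TRAINING": 66, "TRANSITION": 99,
        "FIXED": 248}``.
    seed : int, SeedSequence or Generator
        Randomness source; identical seeds give identical rosters.
    part_time_weight : float
        FTE weight assigned to part-time staff (full-timers weigh 1.0).
    """
    rng = _as_rng(seed)
    return _arrays_to_frame(_sample_arrays(marginals, state_counts, rng, part_time_weight))


# --------------------------------------------------------------- validation
def validate_cohort(
    roster: pd.DataFrame,
    marginals: SurveyMarginals,
    alpha: float = 0.01,
    min_expected: float = 5.0,
) -> pd.DataFrame:
    """Chi-square goodness of fit of a roster against each sampled marginal.

    Returns one row per marginal with the statistic, p-value and a pass flag;
    marginals whose expected counts fall below ``min_expected`` are flagged as
    having insufficient counts instead of being tested.
    """
    if roster.empty:
        raise ValidationError("validate_cohort: empty roster")
    n = len(roster)
    rows = []

    def add(name, observed, expected):
        observed = np.asarray(observed, dtype=float)
        expected = np.asarray(expected, dtype=float)
        keep = expected > 0
        if not np.all(observed[~keep] == 0):
            rows.append((name, np.inf, 0.0, False,
                         "observations in a zero-probability category"))
            return
        observed, expected = observed[keep], expected[keep]
        note = ""
        # Cochran's rule: pool the sparsest cells until every expected count
        # is large enough for the chi-square approximation.
        while len(expected) > 2 and expected.min() < min_expected:
            order = np.argsort(expected)
            i, j = order[0], order[1]
            expected[j] += expected[i]
            observed[j] += observed[i]
            expected = np.delete(expected, i)
            observed = np.delete(observed, i)
            note = "sparse cells pooled"
        if expected.min() < min_expected or len(expected) < 2:
            rows.append((name, np.nan, np.nan, None, "insufficient counts"))
            return
        stat, p = stats.chisquare(observed, expected)
        rows.append((name, float(stat), float(p), bool(p >= alpha), note))

    gender = marginals.probabilities("gender")
    obs = [(roster["gender"] == g).sum() for g in gender]
    add("gender", obs, [gender[g] * n for g in gender])

    part = marginals.probabilities("parttime")["part_time"]
    n_part = roster["part_time"].sum()
    add("part_time", [n_part, n - n_part], [part * n, (1 - part) * n])

    bands = marginals.probabilities("age_band")
    edges = [-np.inf, 36.0, 56.0, np.inf]
    obs = np.histogram(roster["age"], bins=edges)[0]
    add("age_band", obs, [bands[b] * n for b in AGE_BANDS])

    # nationality expectation depends on the roster's own state mix
    foreign_by_pos = marginals.foreign_share_by_position()
    pos_of_state = {"TRAINING": "training", "TRANSITION": "transition", "FIXED": "fixed"}
    exp_foreign = sum(
        (roster["state"] == s).sum() * foreign_by_pos[p] for s, p in pos_of_state.items()
    )
    n_foreign = (roster["nationality"] == "foreign").sum()
    add("nationality", [n_foreign, n - n_foreign], [exp_foreign, n - exp_foreign])

    for nat in ("swiss", "foreign"):
        sub = roster[roster["nationality"] == nat]
        if len(sub) == 0:
            rows.append((f"hospital|{nat}", np.nan, np.nan, None, "no such records"))
            continue
        probs = marginals.hospital_probs(nat)
        obs = [(sub["hospital"] == h).sum() for h in probs]
        add(f"hospital|{nat}", obs, [p * len(sub) for p in probs.values()])

    return pd.DataFrame(rows, columns=["marginal", "chi2", "pvalue", "passed", "note"])


# ------------------------------------------------------------------- CSV I/O
def roster_to_csv(roster: pd.DataFrame, path) -> None:
    """Write a roster with the documented column order."""
    roster[ROSTER_COLUMNS].to_csv(path, index=False)


def roster_from_csv(path) -> pd.DataFrame:
    roster = pd.read_csv(path)
    missing = [c for c in ROSTER_COLUMNS if c not in roster.columns]
    if missing:
        raise ValidationError(f"roster CSV missing columns {missing!r}")
    bad = set(roster["state"]) - set(STATE_CODES)
    if bad:
        raise ValidationError(f"roster CSV has unknown states {sorted(bad)!r}")
    return roster[ROSTER_COLUMNS]
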