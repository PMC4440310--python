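"""Survey-derived model inputs and the descriptive statistics computed from them.

The package models the anaesthesia workforce of the French- and Italian-speaking
("Latin") cantons of Switzerland. All quantitative inputs are the published
marginal distributions of a cross-sectional workforce survey: age bands, gender,
part-/full-time mix, nationality, position held and hospital type (the latter
two cross-tabulated by nationality group), desired retirement age by gender, and
the empirical distribution of the interval between medical graduation and
specialty certification (the FMH title).

The survey allowed item non-response, so different marginals have different
observed totals; each marginal is normalised within its own total when converted
to sampling probabilities.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError, UndefinedStatisticError, ValidationError

CONFIG_SCHEMA = "quotasim-params-v1"

AGE_BANDS = ("<=35", "36-55", ">=56")
GENDERS = ("female", "male")
PARTTIME = ("part_time", "full_time")
NATIONALITIES_RAW = ("swiss", "european", "other")
NATIONALITY_GROUPS = ("swiss", "foreign")  # "foreign" pools European + extra-European
POSITIONS = ("fixed", "transition", "training")
HOSPITALS = ("university", "district", "private", "office")
TRAINING_DURATION_TOP = "15+"

#: Statutory retirement ages (years) used to truncate desired-retirement draws.
LEGAL_RETIREMENT_AGE = {"male": 65.0, "female": 64.0}

#: Slack allowed between the nationality cross-tab column sums and the position
#: headcounts used for initialisation; the printed table itself disagrees by 1
#: in two of the three positions.
_CROSSTAB_SLACK = 2


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _check_counts(name: str, mapping: Mapping, keys: Sequence) -> None:
    missing = [k for k in keys if k not in mapping]
    if missing:
        raise ValidationError(f"{name}: missing categories {missing!r}")
    for k, v in mapping.items():
        if not isinstance(v, (int, float)) or v != int(v):
            raise ValidationError(f"{name}[{k!r}]: count must be an integer, got {v!r}")
        if v < 0:
            raise ValidationError(f"{name}[{k!r}]: negative count {v}")


@dataclass(frozen=True)
class SurveyMarginals:
    """Validated container for every printed model input.

    All ``*_counts`` fields are raw respondent counts; probabilities are derived
    on demand so the unrounded values are retained.
    """

    age_band_counts: dict
    gender_counts: dict
    parttime_counts: dict
    nationality_counts: dict
    position_by_nationality: dict
    hospital_by_nationality: dict
    retirement_age: dict            # gender -> (mean, sd) in years
    training_duration_counts: dict  # years (5..14, "15+") -> count
    listed_n: int = 506
    responded_n: int = 416
    legal_retirement_age: dict = field(
        default_factory=lambda: dict(LEGAL_RETIREMENT_AGE)
    )

    def __post_init__(self) -> None:
        _check_counts("age_band_counts", self.age_band_counts, AGE_BANDS)
        _check_counts("gender_counts", self.gender_counts, GENDERS)
        _check_counts("parttime_counts", self.parttime_counts, PARTTIME)
        _check_counts("nationality_counts", self.nationality_counts, NATIONALITIES_RAW)
        for nat in NATIONALITY_GROUPS:
            if nat not in self.position_by_nationality:
                raise ValidationError(f"position_by_nationality: missing group {nat!r}")
            _check_counts(
                f"position_by_nationality[{nat!r}]",
                self.position_by_nationality[nat], POSITIONS,
            )
            if nat not in self.hospital_by_nationality:
                raise ValidationError(f"hospital_by_nationality: missing group {nat!r}")
            _check_counts(
                f"hospital_by_nationality[{nat!r}]",
                self.hospital_by_nationality[nat], HOSPITALS,
            )
        _check_counts(
            "training_duration_counts", self.training_duration_counts,
            list(range(5, 15)) + [TRAINING_DURATION_TOP],
        )
        if self.listed_n <= 0 or self.responded_n < 0:
            raise ValidationError("listed_n must be positive, responded_n non-negative")
        if self.responded_n > self.listed_n:
            raise ValidationError(
                f"responded_n ({self.responded_n}) exceeds listed_n ({self.listed_n})"
            )
        for name, counts in (
            ("age_band_counts", self.age_band_counts),
            ("gender_counts", self.gender_counts),
            ("parttime_counts", self.parttime_counts),
            ("nationality_counts", self.nationality_counts),
        ):
            if sum(counts.values()) > self.responded_n:
                raise ValidationError(f"{name}: total exceeds responded_n")
        for gender in GENDERS:
            if gender not in self.retirement_age:
                raise ValidationError(f"retirement_age: missing gender {gender!r}")
            mean, sd = self.retirement_age[gender]
            if sd < 0:
                raise ValidationError(f"retirement_age[{gender!r}]: negative SD")
            legal = self.legal_retirement_age[gender]
            if mean >= legal:
                raise ValidationError(
                    f"retirement_age[{gender!r}]: desired mean {mean} is not below "
                    f"the legal age {legal}"
                )

    # ------------------------------------------------------------------ totals
    def position_totals(self) -> dict:
        """Position headcounts pooled over nationality groups."""
        return {
            pos: sum(self.position_by_nationality[nat][pos] for nat in NATIONALITY_GROUPS)
            for pos in POSITIONS
        }

    def check_state_counts(self, state_counts: Mapping[str, int]) -> None:
        """Verify initialisation headcounts against the nationality cross-tab.

        The printed cross-tab column sums differ from the pooled position counts
        by at most one person, so a small slack is allowed.
        """
        pooled = self.position_totals()
        by_state = {"TRAINING": "training", "TRANSITION": "transition", "FIXED": "fixed"}
        for state, pos in by_state.items():
            n = state_counts.get(state, 0)
            if abs(n - pooled[pos]) > _CROSSTAB_SLACK:
                raise ValidationError(
                    f"state_counts[{state}]={n} deviates from the Table-derived "
                    f"position total {pooled[pos]} by more than {_CROSSTAB_SLACK}"
                )

    # -------------------------------------------------------- probabilities
    def probabilities(self, which: str) -> dict:
        """Normalised category probabilities for a one-way marginal."""
        counts = getattr(self, f"{which}_counts")
        total = sum(counts.values())
        if total <= 0:
            raise ValidationError(f"{which}: empty marginal")
        return {k: v / total for k, v in counts.items()}

    def foreign_share_by_position(self) -> dict:
        """P(foreign | position) from the printed cross-tabulation."""
        out = {}
        for pos in POSITIONS:
            sw = self.position_by_nationality["swiss"][pos]
            fo = self.position_by_nationality["foreign"][pos]
            if sw + fo == 0:
                raise ValidationError(f"position {pos!r}: empty cross-tab cell")
            out[pos] = fo / (sw + fo)
        return out

    def hospital_probs(self, nationality: str) -> dict:
        counts = self.hospital_by_nationality[nationality]
        total = sum(counts.values())
        if total <= 0:
            raise ValidationError(f"hospital_by_nationality[{nationality!r}]: empty")
        return {k: v / total for k, v in counts.items()}

    # --------------------------------------------------------- serialisation
    def to_dict(self) -> dict:
        return {
            "listed_n": self.listed_n,
            "responded_n": self.responded_n,
            "age_band_counts": dict(self.age_band_counts),
            "gender_counts": dict(self.gender_counts),
            "parttime_counts": dict(self.parttime_counts),
            "nationality_counts": dict(self.nationality_counts),
            "position_by_nationality": copy.deepcopy(self.position_by_nationality),
            "hospital_by_nationality": copy.deepcopy(self.hospital_by_nationality),
            "retirement_age": {
                g: {"mean": float(m), "sd": float(s)}
                for g, (m, s) in self.retirement_age.items()
            },
            "training_duration_counts": dict(self.training_duration_counts),
            "legal_retirement_age": dict(self.legal_retirement_age),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SurveyMarginals":
        try:
            retirement = {
                g: (float(v["mean"]), float(v["sd"]))
                for g, v in d["retirement_age"].items()
            }
            duration = {
                (int(k) if str(k) != TRAINING_DURATION_TOP else TRAINING_DURATION_TOP): v
                for k, v in d["training_duration_counts"].items()
            }
            return cls(
                age_band_counts=dict(d["age_band_counts"]),
                gender_counts=dict(d["gender_counts"]),
                parttime_counts=dict(d["parttime_counts"]),
                nationality_counts=dict(d["nationality_counts"]),
                position_by_nationality=copy.deepcopy(d["position_by_nationality"]),
                hospital_by_nationality=copy.deepcopy(d["hospital_by_nationality"]),
                retirement_age=retirement,
                training_duration_counts=duration,
                listed_n=int(d["listed_n"]),
                responded_n=int(d["responded_n"]),
                legal_retirement_age=dict(
                    d.get("legal_retirement_age", LEGAL_RETIREMENT_AGE)
                ),
            )
        except KeyError as exc:
            raise ConfigError(f"survey section: missing field {exc.args[0]!r}") from None


# ----------------------------------------------------------------- config I/O
def default_config() -> dict:
    """The packaged parameter file (survey marginals + default scenario)."""
    text = resources.files("quotasim").joinpath("data/params.yaml").read_text()
    return yaml.safe_load(text)


def load_config(source: str | Path | Mapping | None = None) -> dict:
    """Load and schema-check a full configuration document.

    ``source`` may be a path to a YAML/JSON file, an already-parsed mapping, or
    ``None`` for the packaged defaults.
    """
    if source is None:
        doc = default_config()
    elif isinstance(source, Mapping):
        doc = dict(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError("configuration document is not a mapping")
    if doc.get("schema") != CONFIG_SCHEMA:
        raise ConfigError(
            f"unsupported schema {doc.get('schema')!r}; expected {CONFIG_SCHEMA!r}"
        )
    if "survey" not in doc:
        raise ConfigError("configuration document: missing 'survey' section")
    return doc


def load_marginals(source: str | Path | Mapping | None = None) -> SurveyMarginals:
    """Parse and validate the survey marginals from a config document."""
    doc = load_config(source)
    marginals = SurveyMarginals.from_dict(doc["survey"])
    if "state_counts" in doc:
        marginals.check_state_counts(doc["state_counts"])
    return marginals


# ------------------------------------------------------ descriptive statistics
def proportion(numerator_count: float, category_counts: Sequence[float]) -> int:
    """Percentage of ``numerator_count`` within ``sum(category_counts)``.

    Rounded half-up to the nearest integer percent, matching the published style.
    """
    total = sum(category_counts)
    if total <= 0:
        raise UndefinedStatisticError("proportion: zero category total")
    if numerator_count < 0:
        raise ValidationError("proportion: negative numerator")
    return round_half_up(100.0 * numerator_count / total)


def percent_change(before: float, after: float) -> int:
    """Integer percent change from ``before`` to ``after``."""
    if before <= 0:
        raise UndefinedStatisticError("percent_change: non-positive baseline")
    return round_half_up(100.0 * (after - before) / before)


def response_rate(responded: int, listed: int) -> int:
    """Survey response rate as an integer percent."""
    if listed <= 0:
        raise UndefinedStatisticError("response_rate: no listed individuals")
    if not 0 <= responded <= listed:
        raise ValidationError(
            f"response_rate: responded ({responded}) outside [0, listed={listed}]"
        )
    return round_half_up(100.0 * responded / listed)


def describe(config: Mapping | None = None) -> dict:
    """The descriptive statistics reported alongside the projection.

    Returns integer percentages keyed by a short name; the `value` entries give
    the raw counts behind each figure.
    """
    doc = load_config(config)
    m = load_marginals(doc)
    pos = m.position_by_nationality
    hosp = m.hospital_by_nationality
    out = {
        "response_rate_pct": response_rate(m.responded_n, m.listed_n),
        "male_pct": proportion(m.gender_counts["male"], list(m.gender_counts.values())),
        "part_time_pct": proportion(
            m.parttime_counts["part_time"], list(m.parttime_counts.values())
        ),
        "trainee_share_foreign_pct": proportion(
            pos["foreign"]["training"], list(pos["foreign"].values())
        ),
        "trainee_share_swiss_pct": proportion(
            pos["swiss"]["training"], list(pos["swiss"].values())
        ),
        "district_share_foreign_pct": proportion(
            hosp["foreign"]["district"], list(hosp["foreign"].values())
        ),
    }
    figures = doc.get("printed_figures", {})
    grads = figures.get("swiss_medical_graduates")
    if grads:
        out["graduate_change_pct"] = percent_change(
            grads["graduates_before"], grads["graduates_after"]
        )
    return out
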