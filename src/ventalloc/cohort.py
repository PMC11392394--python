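"""Encounter-level cohorts: reading, validation, exclusion filtering, synthesis.

The synthetic generator is calibrated so that its marginal distributions
(age bands, sex, race/ethnicity, COVID positivity by race, SOFA by race) and
its survival process (a logistic model in SOFA, age and Elixhauser score)
match the published summary statistics of the reference cohort of 3707
ventilated adult admissions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm, truncnorm

__all__ = [
    "SEXES",
    "RACES",
    "AGE_BANDS",
    "Encounter",
    "CohortSpec",
    "CohortError",
    "ConfigurationError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
    "generate_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
]

SEXES = ("male", "female")
RACES = ("white_nh", "black_nh", "hispanic", "aapi_nh", "aian_nh", "multi_nh", "unknown")

# Reporting age bands: [18-24], [25-34], ..., [75-84], [85+].
AGE_BANDS = ((18, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 74), (75, 84), (85, 95))

# Cohort counts per age band / sex / race used to default the generator.
_AGE_BAND_COUNTS = (104, 235, 247, 456, 868, 980, 629, 188)
_SEX_COUNTS = {"male": 2197, "female": 1510}
_RACE_COUNTS = {
    "white_nh": 2752,
    "black_nh": 577,
    "hispanic": 152,
    "aapi_nh": 50,
    "aian_nh": 3,
    "multi_nh": 16,
    "unknown": 157,
}
_N_REFERENCE = 3707

CANONICAL_COLUMNS = (
    "encounter_id",
    "age",
    "sex",
    "race_ethnicity",
    "covid_positive",
    "sofa",
    "elixhauser",
    "charlson_points",
    "survived",
)


class CohortError(ValueError):
    """Base class for cohort-related failures."""


class ConfigurationError(CohortError):
    """A structural problem with inputs (e.g. a missing required column)."""


class ValidationError(CohortError):
    """Row-level data that cannot be parsed or violates field constraints."""


@dataclass
class Encounter:
    """One ventilated admission.

    ``life_expectancy`` is filled by :mod:`ventalloc.life_expectancy` before
    any life-years metric is computed; it remains ``None`` until then.
    """

    encounter_id: str
    age: int
    sex: str
    race_ethnicity: str
    covid_positive: bool
    sofa: int
    elixhauser: int
    charlson_points: int
    survived: bool
    life_expectancy: float | None = None

    def validate(self) -> None:
        if self.age < 18:
            raise ValidationError(f"encounter {self.encounter_id}: age {self.age} < 18")
        if not 0 <= self.sofa <= 24:
            raise ValidationError(
                f"encounter {self.encounter_id}: sofa {self.sofa} outside [0, 24]"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"encounter {self.encounter_id}: unknown sex {self.sex!r}")
        if self.race_ethnicity not in RACES:
            raise ValidationError(
                f"encounter {self.encounter_id}: unknown race {self.race_ethnicity!r}"
            )
        if self.charlson_points < 0:
            raise ValidationError(
                f"encounter {self.encounter_id}: charlson_points {self.charlson_points} < 0"
            )
        if self.life_expectancy is not None and self.life_expectancy < 0:
            raise ValidationError(
                f"encounter {self.encounter_id}: negative life expectancy"
            )


def _default_age_band_probs() -> np.ndarray:
    return np.asarray(_AGE_BAND_COUNTS, dtype=float) / _N_REFERENCE


def _default_sex_probs() -> dict[str, float]:
    return {k: v / _N_REFERENCE for k, v in _SEX_COUNTS.items()}


def _default_race_probs() -> dict[str, float]:
    return {k: v / _N_REFERENCE for k, v in _RACE_COUNTS.items()}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the reference cohort's marginals: race-conditional age
    means (Black/Hispanic patients younger than White), race-conditional COVID
    positivity and mean SOFA at intubation, and a survival logistic with odds
    ratios 0.896 (per SOFA point), 0.964 (per year of age) and 1.054 (per
    Elixhauser point) whose intercept is calibrated so overall survival is the
    configured target (default 0.72).
    """

    n: int = _N_REFERENCE
    seed: int = 0
    age_band_probs: np.ndarray = field(default_factory=_default_age_band_probs)
    sex_probs: dict[str, float] = field(default_factory=_default_sex_probs)
    race_probs: dict[str, float] = field(default_factory=_default_race_probs)
    # Race-conditional age: (mean, sd) of a truncated normal; races absent
    # from this map sample an age band from age_band_probs instead.
    age_mean_by_race: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"black_nh": (56.0, 17.0), "hispanic": (53.0, 18.0)}
    )
    covid_rate_by_race: dict[str, float] = field(
        default_factory=lambda: {"black_nh": 0.45, "hispanic": 0.39, "white_nh": 0.33}
    )
    covid_rate_default: float = 0.34
    sofa_mean_by_race: dict[str, float] = field(
        default_factory=lambda: {"white_nh": 3.69, "black_nh": 3.46, "hispanic": 3.14}
    )
    sofa_mean_default: float = 3.6
    sofa_dispersion: float = 2.0  # negative-binomial size parameter
    # Elixhauser: round(Gamma(shape, scale)) - offset, with scale solved so
    # P(elixhauser >= severe_threshold) == severe_tail. A Gaussian rank copula
    # ties the Elixhauser quantile to the age rank (comorbidity rises with
    # age) without disturbing the calibrated marginal.
    elixhauser_shape: float = 1.2
    elixhauser_offset: int = 2
    elixhauser_severe_threshold: int = 12
    elixhauser_severe_tail: float = 0.10
    elixhauser_age_corr: float = 0.0
    charlson_geometric_p: float = 0.5
    charlson_cap: int = 8
    # Survival model: log-odds slopes; intercept calibrated at generation time.
    beta_sofa: float = float(np.log(0.896))
    beta_age: float = float(np.log(0.964))
    beta_elixhauser: float = float(np.log(1.054))
    survival_target: float = 0.72
    covid_fraction_override: float | None = None

    def validate(self) -> None:
        if self.n < 0:
            raise ValidationError("n must be non-negative")
        probs = np.asarray(self.age_band_probs, dtype=float)
        if probs.shape != (len(AGE_BANDS),):
            raise ValidationError(
                f"age_band_probs must have {len(AGE_BANDS)} entries, got {probs.shape}"
            )
        for name, vec in (
            ("age_band_probs", probs),
            ("sex_probs", np.asarray(list(self.sex_probs.values()))),
            ("race_probs", np.asarray(list(self.race_probs.values()))),
        ):
            if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
                raise ValidationError(f"{name} must be a probability vector summing to 1")
        if set(self.sex_probs) != set(SEXES):
            raise ValidationError("sex_probs must cover exactly {male, female}")
        if not set(self.race_probs) <= set(RACES):
            raise ValidationError("race_probs contains unknown race categories")
        if self.covid_fraction_override is not None and not (
            0.0 <= self.covid_fraction_override <= 1.0
        ):
            raise ValidationError("covid_fraction_override must lie in [0, 1]")
        if not 0.0 < self.survival_target < 1.0:
            raise ValidationError("survival_target must lie in (0, 1)")
        if not 0.0 < self.elixhauser_severe_tail < 1.0:
            raise ValidationError("elixhauser_severe_tail must lie in (0, 1)")
        if not -1.0 < self.elixhauser_age_corr < 1.0:
            raise ValidationError("elixhauser_age_corr must lie in (-1, 1)")

    def with_covid_fraction(self, fraction: float) -> "CohortSpec":
        """Patient-mix variant: force the overall COVID-positive fraction."""
        return replace(self, covid_fraction_override=fraction)


def _parse_bool(value: str, column: str, row: int) -> bool:
    v = value.strip().lower()
    if v in {"1", "true", "t", "yes", "y"}:
        return True
    if v in {"0", "false", "f", "no", "n"}:
        return False
    raise ValidationError(f"row {row}: cannot parse {column}={value!r} as boolean")


def _parse_int(value: str, column: str, row: int) -> int:
    try:
        return int(float(value))
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: non-numeric {column}={value!r}") from None


def read_cohort(path, dialect: Mapping[str, str] | None = None) -> list[Encounter]:
    """Read a cohort CSV into validated :class:`Encounter` records.

    ``dialect`` maps external column names to the canonical ones
    (``{"external_name": "canonical_name"}``). Unparseable race values map to
    ``"unknown"``; unparseable sex or outcome values are rejected.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {', '.join(missing)}")

    encounters: list[Encounter] = []
    errors: list[str] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        rec = {c: getattr(row, c) for c in df.columns if c in CANONICAL_COLUMNS}
        try:
            race = str(rec["race_ethnicity"]).strip()
            sex = str(rec["sex"]).strip().lower()
            if sex not in SEXES:
                raise ValidationError(f"row {row_idx}: unknown sex {rec['sex']!r}")
            le_raw = str(getattr(row, "life_expectancy", "")).strip() if hasattr(
                row, "life_expectancy"
            ) else ""
            enc = Encounter(
                encounter_id=str(rec["encounter_id"]),
                age=_parse_int(rec["age"], "age", row_idx),
                sex=sex,
                race_ethnicity=race if race in RACES else "unknown",
                covid_positive=_parse_bool(rec["covid_positive"], "covid_positive", row_idx),
                sofa=_parse_int(rec["sofa"], "sofa", row_idx),
                elixhauser=_parse_int(rec["elixhauser"], "elixhauser", row_idx),
                charlson_points=_parse_int(rec["charlson_points"], "charlson_points", row_idx),
                survived=_parse_bool(rec["survived"], "survived", row_idx),
                life_expectancy=float(le_raw) if le_raw else None,
            )
            enc.validate()
            encounters.append(enc)
        except ValidationError as exc:
            errors.append(str(exc))
    if errors:
        raise ValidationError(
            f"{len(errors)} invalid row(s): " + "; ".join(errors[:10])
        )
    return encounters


def write_cohort(encounters: Sequence[Encounter], path) -> None:
    cohort_to_frame(encounters).to_csv(path, index=False)


def cohort_to_frame(encounters: Sequence[Encounter]) -> pd.DataFrame:
    cols = list(CANONICAL_COLUMNS) + ["life_expectancy"]
    if not encounters:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame([vars(e) for e in encounters])
    return df[cols]


def frame_to_cohort(df: pd.DataFrame) -> list[Encounter]:
    out = []
    for rec in df.to_dict("records"):
        le = rec.get("life_expectancy")
        if le is not None and (isinstance(le, float) and np.isnan(le)):
            le = None
        enc = Encounter(
            encounter_id=str(rec["encounter_id"]),
            age=int(rec["age"]),
            sex=str(rec["sex"]),
            race_ethnicity=str(rec["race_ethnicity"]),
            covid_positive=bool(rec["covid_positive"]),
            sofa=int(rec["sofa"]),
            elixhauser=int(rec["elixhauser"]),
            charlson_points=int(rec["charlson_points"]),
            survived=bool(rec["survived"]),
            life_expectancy=None if le is None else float(le),
        )
        enc.validate()
        out.append(enc)
    return out


# Exclusion reasons, applied in order; a record matching several is counted
# once under the first matching reason.
EXCLUSION_REASONS = ("missing_sofa", "no_outcome_data", "ambiguous_reintubation")


def apply_exclusions(
    raw: Iterable[Mapping],
) -> tuple[list[Encounter], dict[str, int]]:
    """Filter raw admission records down to the modelling cohort.

    Each raw record is a mapping with the canonical Encounter fields plus the
    nullable screening fields ``sofa`` (None when no SOFA was recorded at
    initial intubation), ``has_disposition`` / ``has_icd10`` /
    ``has_covid_data`` (availability of outcome data) and
    ``ambiguous_reintubation`` (multiple intubations with no way to identify
    the initial one).

    Returns the retained encounters and a per-reason exclusion report.
    """
    report = {reason: 0 for reason in EXCLUSION_REASONS}
    report["retained"] = 0
    retained: list[Encounter] = []
    for rec in raw:
        if rec.get("sofa") is None:
            report["missing_sofa"] += 1
            continue
        if not (
            rec.get("has_disposition", True)
            or rec.get("has_icd10", True)
            or rec.get("has_covid_data", True)
        ):
            report["no_outcome_data"] += 1
            continue
        if rec.get("ambiguous_reintubation", False):
            report["ambiguous_reintubation"] += 1
            continue
        enc = Encounter(
            encounter_id=str(rec["encounter_id"]),
            age=int(rec["age"]),
            sex=str(rec["sex"]),
            race_ethnicity=str(rec["race_ethnicity"]),
            covid_positive=bool(rec["covid_positive"]),
            sofa=int(rec["sofa"]),
            elixhauser=int(rec["elixhauser"]),
            charlson_points=int(rec["charlson_points"]),
            survived=bool(rec["survived"]),
            life_expectancy=rec.get("life_expectancy"),
        )
        enc.validate()
        retained.append(enc)
        report["retained"] += 1
    return retained, report


def _sample_ages(spec: CohortSpec, race: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Band-uniform ages by default; truncated-normal for races with a mean."""
    n = race.size
    ages = np.empty(n, dtype=int)
    band_probs = np.asarray(spec.age_band_probs, dtype=float)
    default_mask = np.ones(n, dtype=bool)
    for r, (mu, sd) in spec.age_mean_by_race.items():
        mask = race == r
        if not mask.any():
            continue
        default_mask &= ~mask
        a, b = (18.0 - mu) / sd, (100.0 - mu) / sd
        draws = truncnorm.rvs(a, b, loc=mu, scale=sd, size=int(mask.sum()), random_state=rng)
        ages[mask] = np.rint(draws).astype(int)
    m = int(default_mask.sum())
    if m:
        bands = rng.choice(len(AGE_BANDS), size=m, p=band_probs)
        lows = np.array([lo for lo, _ in AGE_BANDS])[bands]
        highs = np.array([hi for _, hi in AGE_BANDS])[bands]
        ages[default_mask] = rng.integers(lows, highs + 1)
    return np.clip(ages, 18, 100)


def _elixhauser_scale(spec: CohortSpec) -> float:
    # Solve Gamma scale so that round(g) - offset >= threshold has the target
    # tail mass, i.e. P(g >= threshold + offset - 0.5) == severe_tail.
    cut = spec.elixhauser_severe_threshold + spec.elixhauser_offset - 0.5
    return cut / float(gamma_dist.isf(spec.elixhauser_severe_tail, spec.elixhauser_shape))


def calibrate_intercept(
    linpred: np.ndarray, target: float, lo: float = -30.0, hi: float = 30.0
) -> float:
    """Root-find the logistic intercept so mean survival equals ``target``."""

    def gap(a: float) -> float:
        return float(np.mean(expit(linpred + a))) - target

    return float(brentq(gap, lo, hi, xtol=1e-10))


def generate_cohort(spec: CohortSpec) -> list[Encounter]:
    """Draw a synthetic cohort; deterministic for a fixed spec and seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if n == 0:
        return []

    races = list(spec.race_probs)
    race = rng.choice(races, size=n, p=list(spec.race_probs.values()))
    sexes = list(spec.sex_probs)
    sex = rng.choice(sexes, size=n, p=list(spec.sex_probs.values()))
    age = _sample_ages(spec, race, rng)

    if spec.covid_fraction_override is not None:
        covid_p = np.full(n, spec.covid_fraction_override)
    else:
        covid_p = np.array(
            [spec.covid_rate_by_race.get(r, spec.covid_rate_default) for r in race]
        )
    covid = rng.random(n) < covid_p

    sofa_mu = np.array([spec.sofa_mean_by_race.get(r, spec.sofa_mean_default) for r in race])
    r_disp = spec.sofa_dispersion
    sofa = rng.negative_binomial(r_disp, r_disp / (r_disp + sofa_mu))
    sofa = np.clip(sofa, 0, 24).astype(int)

    # Elixhauser via a Gaussian rank copula against age: the uniform driving
    # the gamma quantile is correlated with the (jittered) age rank, so the
    # marginal stays exactly as calibrated.
    scale = _elixhauser_scale(spec)
    rho = spec.elixhauser_age_corr
    age_rank = pd.Series(age + rng.random(n)).rank().to_numpy() / (n + 1)
    z_age = norm.ppf(age_rank)
    z = rho * z_age + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    elix = np.rint(gamma_dist.ppf(norm.cdf(z), spec.elixhauser_shape, scale=scale))
    elix = elix.astype(int) - spec.elixhauser_offset

    charlson = np.minimum(rng.geometric(spec.charlson_geometric_p, size=n) - 1, spec.charlson_cap)

    linpred = spec.beta_sofa * sofa + spec.beta_age * age + spec.beta_elixhauser * elix
    intercept = calibrate_intercept(linpred, spec.survival_target)
    survived = rng.random(n) < expit(linpred + intercept)

    return [
        Encounter(
            encounter_id=f"synth-{i:06d}",
            age=int(age[i]),
            sex=str(sex[i]),
            race_ethnicity=str(race[i]),
            covid_positive=bool(covid[i]),
            sofa=int(sofa[i]),
            elixhauser=int(elix[i]),
            charlson_points=int(charlson[i]),
            survived=bool(survived[i]),
        )
        for i in range(n)
    ]
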