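"""Priority scoring for the six allocation protocols.

Each protocol maps an encounter to an integer priority band (lower band =
higher priority). Ties within a band are broken by lottery: a fresh uniform
tiebreak is drawn per decision, and (band, tiebreak) compares
lexicographically.

Banding rules:

* ``lottery`` — a single band; ordering is the tiebreak alone.
* ``age`` — the reporting age bands [18-24], [25-34], ..., [75-84], [85+].
* ``pure_sofa`` — band equals the SOFA score (0-24).
* ``new_york_15`` — tier 1 for SOFA <=7, tier 2 for 8-11, tier 3 for >=12.
* ``maryland_21`` — SOFA points (<=8 -> 1, 9-11 -> 2, 12-14 -> 3, >14 -> 4)
  plus 3 points for a severe comorbidity (Elixhauser summary >= 12).
* ``colorado_20`` — SOFA points (<=5 -> 1, 6-9 -> 2, 10-12 -> 3, >12 -> 4)
  plus an age-adjusted Charlson contribution: per-age-band points from a
  configurable table plus the encounter's condition points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .cohort import Encounter, ValidationError

__all__ = [
    "PROTOCOL_NAMES",
    "MARYLAND_SEVERE_ELIXHAUSER",
    "ColoradoTable",
    "score_lottery",
    "score_age",
    "score_pure_sofa",
    "score_new_york",
    "score_maryland",
    "score_colorado",
    "compute_bands",
    "rank_pair",
]

PROTOCOL_NAMES = ("lottery", "age", "pure_sofa", "new_york_15", "maryland_21", "colorado_20")

# Elixhauser (van Walraven) summary score treated as a "severe" comorbidity.
MARYLAND_SEVERE_ELIXHAUSER = 12

_AGE_BAND_EDGES = np.array([25, 35, 45, 55, 65, 75, 85])


@dataclass
class ColoradoTable:
    """SOFA band points and age-band Charlson points for the Colorado rule.

    ``sofa_upper``/``sofa_points``: band k covers SOFA values up to and
    including ``sofa_upper[k]``; bands must tile 0-24 without gap or overlap.
    ``age_upper``/``age_points``: likewise for age (last upper bound open-ended
    in practice). Condition points are read off the encounter itself
    (``charlson_points``), so only the age contribution lives in the table.

    The default age points (0 below 50, then 1/2/3 for the 50s/60s/>=70) follow
    the conventional age-adjusted Charlson index and can be overridden from a
    YAML file.
    """

    sofa_upper: tuple[int, ...] = (5, 9, 12, 24)
    sofa_points: tuple[int, ...] = (1, 2, 3, 4)
    age_upper: tuple[int, ...] = (49, 59, 69, 200)
    age_points: tuple[int, ...] = (0, 1, 2, 3)

    def __post_init__(self) -> None:
        if len(self.sofa_upper) != len(self.sofa_points):
            raise ValidationError("sofa_upper and sofa_points must align")
        if len(self.age_upper) != len(self.age_points):
            raise ValidationError("age_upper and age_points must align")
        if list(self.sofa_upper) != sorted(set(self.sofa_upper)) or self.sofa_upper[-1] < 24:
            raise ValidationError("sofa bands must be increasing and cover 0-24")
        if list(self.age_upper) != sorted(set(self.age_upper)):
            raise ValidationError("age bands must be increasing")

    @classmethod
    def from_yaml(cls, path) -> "ColoradoTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("sofa_upper", "sofa_points", "age_upper", "age_points"):
            if key in raw:
                kwargs[key] = tuple(int(v) for v in raw[key])
        return cls(**kwargs)

    def sofa_band_points(self, sofa: np.ndarray | int) -> np.ndarray | int:
        idx = np.searchsorted(self.sofa_upper, sofa, side="left")
        return np.asarray(self.sofa_points)[idx]

    def age_band_points(self, age: np.ndarray | int) -> np.ndarray | int:
        idx = np.searchsorted(self.age_upper, age, side="left")
        if np.any(idx >= len(self.age_points)):
            raise ValidationError("age outside Colorado table coverage")
        return np.asarray(self.age_points)[idx]


def _check_sofa(sofa: int) -> None:
    if not 0 <= sofa <= 24:
        raise ValidationError(f"sofa {sofa} outside [0, 24]")


def score_lottery(e: Encounter) -> int:
    return 0


def score_age(e: Encounter) -> int:
    if e.age < 18:
        raise ValidationError(f"age {e.age} < 18")
    return int(np.searchsorted(_AGE_BAND_EDGES, e.age, side="right"))


def score_pure_sofa(e: Encounter) -> int:
    _check_sofa(e.sofa)
    return int(e.sofa)


def score_new_york(e: Encounter) -> int:
    _check_sofa(e.sofa)
    return 1 + (e.sofa >= 8) + (e.sofa >= 12)


def score_maryland(e: Encounter) -> int:
    _check_sofa(e.sofa)
    pts = 1 + (e.sofa >= 9) + (e.sofa >= 12) + (e.sofa >= 15)
    if e.elixhauser >= MARYLAND_SEVERE_ELIXHAUSER:
        pts += 3
    return int(pts)


def score_colorado(e: Encounter, table: ColoradoTable | None = None) -> int:
    table = table or ColoradoTable()
    _check_sofa(e.sofa)
    if e.age < 18:
        raise ValidationError(f"age {e.age} < 18")
    if e.charlson_points < 0:
        raise ValidationError("charlson_points must be >= 0")
    return int(
        table.sofa_band_points(e.sofa) + table.age_band_points(e.age) + e.charlson_points
    )


_SCORERS = {
    "lottery": score_lottery,
    "age": score_age,
    "pure_sofa": score_pure_sofa,
    "new_york_15": score_new_york,
    "maryland_21": score_maryland,
    "colorado_20": score_colorado,
}


def score(e: Encounter, protocol: str, colorado_table: ColoradoTable | None = None) -> int:
    """Deterministic priority band for ``e`` under ``protocol``."""
    if protocol not in _SCORERS:
        raise ValidationError(
            f"unknown protocol {protocol!r}; expected one of {PROTOCOL_NAMES}"
        )
    if protocol == "colorado_20":
        return score_colorado(e, colorado_table)
    return _SCORERS[protocol](e)


def compute_bands(
    encounters: Sequence[Encounter],
    protocol: str,
    colorado_table: ColoradoTable | None = None,
) -> np.ndarray:
    """Vectorised priority bands for a whole cohort (used by the simulator)."""
    if protocol not in _SCORERS:
        raise ValidationError(
            f"unknown protocol {protocol!r}; expected one of {PROTOCOL_NAMES}"
        )
    n = len(encounters)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if protocol == "lottery":
        return np.zeros(n, dtype=np.int64)
    age = np.array([e.age for e in encounters])
    sofa = np.array([e.sofa for e in encounters])
    if age.min() < 18:
        raise ValidationError("all ages must be >= 18")
    if sofa.min() < 0 or sofa.max() > 24:
        raise ValidationError("all SOFA scores must lie in [0, 24]")
    if protocol == "age":
        return np.searchsorted(_AGE_BAND_EDGES, age, side="right").astype(np.int64)
    if protocol == "pure_sofa":
        return sofa.astype(np.int64)
    if protocol == "new_york_15":
        return (1 + (sofa >= 8) + (sofa >= 12)).astype(np.int64)
    if protocol == "maryland_21":
        elix = np.array([e.elixhauser for e in encounters])
        pts = 1 + (sofa >= 9) + (sofa >= 12) + (sofa >= 15)
        return (pts + 3 * (elix >= MARYLAND_SEVERE_ELIXHAUSER)).astype(np.int64)
    # colorado_20
    table = colorado_table or ColoradoTable()
    charlson = np.array([e.charlson_points for e in encounters])
    if charlson.min() < 0:
        raise ValidationError("charlson_points must be >= 0")
    return (
        table.sofa_band_points(sofa) + table.age_band_points(age) + charlson
    ).astype(np.int64)


def rank_pair(
    a: Encounter,
    b: Encounter,
    protocol: str,
    rng: np.random.Generator,
    colorado_table: ColoradoTable | None = None,
) -> Encounter:
    """Return the higher-priority member of a pair; ties broken by lottery.

    Tiebreak uniforms are drawn fresh from ``rng`` on every call.
    """
    band_a = score(a, protocol, colorado_table)
    band_b = score(b, protocol, colorado_table)
    tie_a, tie_b = rng.random(), rng.random()
    return a if (band_a, tie_a) <= (band_b, tie_b) else b
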