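"""Subject / cohort / survey value types shared across modules.

Kept separate from the generator so the biomechanics layer can scale models
to a :class:`SubjectProfile` without importing the signal synthesis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

SEXES = ("female", "male")


@dataclass(frozen=True)
class SubjectProfile:
    """One participant: the subject adjustment variables used for model
    scaling (sex, age, body mass, height, dominant side, weekly activity)."""

    id: str
    sex: str
    age: float
    body_mass: float  # kg
    height: float  # m
    dominant_side: str = "right"
    activity: float = 2.0  # workout sessions per week

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.body_mass <= 0 or self.height <= 0:
            raise ValueError("body mass and height must be positive")
        if not 20.0 <= self.age <= 50.0:
            raise ValueError("age must lie in [20, 50] years")
        if self.dominant_side not in ("left", "right"):
            raise ValueError("dominant_side must be 'left' or 'right'")


@dataclass(frozen=True)
class AttributeDist:
    """Truncated-normal distribution for one subject attribute."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not self.lo <= self.mean <= self.hi:
            raise ValueError("mean must lie inside the truncation bounds")


def _default_dists() -> dict[str, dict[str, AttributeDist]]:
    # Cohort moments of the twenty-participant study population:
    # female 24+/-3.0 y, 59+/-10.6 kg, 1.65+/-0.07 m, 3.0+/-1.9 sessions/wk;
    # male 27+/-3.1 y, 74+/-11.7 kg, 1.78+/-0.06 m, 1.0+/-1.7 sessions/wk.
    return {
        "female": {
            "age": AttributeDist(24.0, 3.0, 20.0, 50.0),
            "body_mass": AttributeDist(59.0, 10.6, 44.0, 100.0),
            "height": AttributeDist(1.65, 0.07, 1.45, 1.90),
            "activity": AttributeDist(3.0, 1.9, 0.0, 10.0),
        },
        "male": {
            "age": AttributeDist(27.0, 3.1, 20.0, 50.0),
            "body_mass": AttributeDist(74.0, 11.7, 50.0, 115.0),
            "height": AttributeDist(1.78, 0.06, 1.55, 2.05),
            "activity": AttributeDist(1.0, 1.7, 0.0, 10.0),
        },
    }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition: ``n_per_sex`` subjects per sex drawn from
    sex-specific truncated normals; 9 of 10 subjects right-dominant."""

    n_per_sex: int = 10
    distributions: Mapping[str, Mapping[str, AttributeDist]] = field(
        default_factory=_default_dists
    )
    right_handed_frac: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_sex < 1:
            raise ValueError("n_per_sex must be at least 1")
        for sex in SEXES:
            if sex not in self.distributions:
                raise ValueError(f"missing distributions for sex {sex!r}")


@dataclass(frozen=True)
class SurveyResponse:
    """Structured post-trial survey: ordinal fatigue level per protocol
    phase, self-reported fatigue sites, and comfort on a 1-10 scale."""

    comfort: int
    fatigue_level: tuple[int, ...] = ()
    fatigue_sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= int(self.comfort) <= 10:
            raise ValueError("comfort must lie in [1, 10]")
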