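"""Simulation configuration for the synthetic EMR corpus.

The defaults encode the study conditions the generator emulates: an Ontario
primary-care cohort of singleton term infants (April 2002 - March 2013) in
which ~80% of charts carry a Rourke Baby Record, ~11.8% have no recoverable
feeding documentation, and population exclusive-breastfeeding (EBF) survival
is 39.5% / 32.4% / 25.1% at 60 / 122 / 182 days of age.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date

import yaml

from .errors import ConfigError

#: Sentinel for an unknown residential income quintile (1-5 otherwise).
INCOME_UNKNOWN = 0

#: Target ages (days) at which EBF status is assessed: 2, 4 and 6 months.
TARGET_AGES = (60, 122, 182)

#: Maximum chart age (days) retained for feeding ascertainment.
HORIZON_DAYS = 750


@dataclass(frozen=True)
class VisitSlot:
    """One nominal well-baby visit: schedule age, attendance, timing noise.

    ``jitter_sd`` is the scale (days) of a half-normal delay added to the
    nominal age - families attend on or after the scheduled age.
    """

    age: int
    attend_prob: float = 0.9
    jitter_sd: float = 7.0


def _default_schedule() -> tuple[VisitSlot, ...]:
    # Newborn + 2/4/6-month immunization-schedule anchors.
    return (VisitSlot(7), VisitSlot(60), VisitSlot(122), VisitSlot(182))


def _default_covariate_effects() -> dict[str, float]:
    # Log hazard ratios on EBF discontinuation, applied to mean-centred
    # covariates. Negative = longer exclusive breastfeeding. Chosen to give
    # the qualitative gradients seen in practice (older, urban, higher-income
    # and immigrant mothers breastfeed longer) while leaving population
    # survival at the configured targets.
    return {
        "maternal_age_per_decade": -0.35,
        "urban": -0.25,
        "immigrant": -0.08,
        "income_quintile_per_level": -0.06,
    }


def _default_region_probs() -> dict[str, float]:
    # Maternal world region of birth, EMR-cohort marginals.
    return {
        "Canada": 0.876,
        "Europe/Western": 0.041,
        "Africa/Caribbean": 0.015,
        "Middle East/N Africa": 0.014,
        "Latin America": 0.014,
        "South Asia": 0.015,
        "East Asia": 0.025,
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic EMR generator. ``seed`` is mandatory."""

    n_infants: int
    seed: int

    # --- documentation structure ---
    rourke_prob: float = 0.80
    undocumented_prob: float = 0.118
    structured_field_prob: float = 0.30
    historical_mention_prob: float = 0.75

    # --- feeding trajectory model ---
    ebf_survival_targets: tuple[float, float, float] = (0.395, 0.324, 0.251)
    ebf_init_prob: float = 0.90
    covariate_effects: dict[str, float] = field(
        default_factory=_default_covariate_effects
    )

    # --- visit process ---
    visit_schedule: tuple[VisitSlot, ...] = field(default_factory=_default_schedule)

    # --- registry marginals ---
    urban_prob: float = 0.756
    maternal_age_mean: float = 30.2
    maternal_age_sd: float = 5.3
    primiparous_prob: float = 0.47
    income_quintile_probs: tuple[float, ...] = (
        0.175, 0.188, 0.218, 0.216, 0.199, 0.004,  # Q1..Q5, unknown
    )
    world_region_probs: dict[str, float] = field(default_factory=_default_region_probs)
    birthweight_mean: float = 3490.0
    birthweight_sd: float = 464.0
    gestational_age_mean: float = 39.3
    gestational_age_sd: float = 1.1
    male_prob: float = 0.514
    early_band_prob: float = 0.23  # P(birth in 2002-2007 band)
    study_start: date = date(2002, 4, 1)
    study_end: date = date(2013, 3, 31)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_infants < 1:
            raise ConfigError("n_infants must be >= 1")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        probs = {
            "rourke_prob": self.rourke_prob,
            "undocumented_prob": self.undocumented_prob,
            "structured_field_prob": self.structured_field_prob,
            "historical_mention_prob": self.historical_mention_prob,
            "ebf_init_prob": self.ebf_init_prob,
            "urban_prob": self.urban_prob,
            "primiparous_prob": self.primiparous_prob,
            "male_prob": self.male_prob,
            "early_band_prob": self.early_band_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        s = tuple(self.ebf_survival_targets)
        if len(s) != 3 or any(not 0.0 <= x <= 1.0 for x in s):
            raise ConfigError("ebf_survival_targets must be three probabilities")
        if not s[0] >= s[1] >= s[2]:
            raise ConfigError("ebf_survival_targets must be non-increasing")
        if self.ebf_init_prob > 0 and s[0] > self.ebf_init_prob:
            raise ConfigError(
                "survival target at 60 d cannot exceed ebf_init_prob"
            )
        if abs(sum(self.income_quintile_probs) - 1.0) > 1e-6:
            raise ConfigError("income_quintile_probs must sum to 1")
        if abs(sum(self.world_region_probs.values()) - 1.0) > 1e-3:
            raise ConfigError("world_region_probs must sum to 1")
        for slot in self.visit_schedule:
            if not 0.0 <= slot.attend_prob <= 1.0:
                raise ConfigError("visit attend_prob must be in [0, 1]")
            if slot.jitter_sd < 0 or slot.age < 0:
                raise ConfigError("visit age and jitter_sd must be >= 0")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        d["visit_schedule"] = [dataclasses.asdict(v) for v in self.visit_schedule]
        d["ebf_survival_targets"] = list(self.ebf_survival_targets)
        d["income_quintile_probs"] = list(self.income_quintile_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "seed" not in d:
            raise ConfigError("seed is mandatory in the simulation config")
        if "study_start" in d and isinstance(d["study_start"], str):
            d["study_start"] = date.fromisoformat(d["study_start"])
        if "study_end" in d and isinstance(d["study_end"], str):
            d["study_end"] = date.fromisoformat(d["study_end"])
        if "visit_schedule" in d:
            d["visit_schedule"] = tuple(
                v if isinstance(v, VisitSlot) else VisitSlot(**v)
                for v in d["visit_schedule"]
            )
        if "ebf_survival_targets" in d:
            d["ebf_survival_targets"] = tuple(d["ebf_survival_targets"])
        if "income_quintile_probs" in d:
            d["income_quintile_probs"] = tuple(d["income_quintile_probs"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:  # missing required key
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError("simulation config must be a YAML mapping")
        return cls.from_dict(d)
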