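"""Birth-registry generation: one row per singleton term infant.

The generated registry plays the role of the provincial birth record linked
to the EMR cohort. Covariates are drawn from configurable marginals; the
defaults reproduce the EMR cohort's published marginal frequencies (urban
residence, income quintile, maternal world region of birth, birthweight and
gestational-age distributions).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import INCOME_UNKNOWN, SimConfig

REGISTRY_COLUMNS = [
    "infant_id",
    "maternal_age",
    "parity",
    "urban",
    "immigrant",
    "income_quintile",
    "world_region",
    "birth_date",
    "birthweight_g",
    "gestational_age_wk",
    "infant_sex",
    "plurality",
]


@dataclass(frozen=True)
class MaternalBirthRecord:
    """One infant-mother pair with sociodemographic covariates."""

    infant_id: str
    maternal_age: int
    parity: int
    urban: bool
    immigrant: bool
    income_quintile: int  # 1..5, or INCOME_UNKNOWN (0)
    world_region: str
    birth_date: date
    birthweight_g: int
    gestational_age_wk: int
    infant_sex: str  # "M" / "F"
    plurality: int

    @property
    def birth_year_band(self) -> str:
        return "2002-2007" if self.birth_date.year <= 2007 else "2008-2013"


def _draw_birth_date(rng: np.random.Generator, config: SimConfig) -> date:
    """Band-then-day draw: EMR uptake grew over time, so late-band births
    dominate even though the study window starts in 2002."""
    early_end = date(2007, 12, 31)
    late_start = date(2008, 1, 1)
    if rng.random() < config.early_band_prob:
        lo, hi = config.study_start, min(early_end, config.study_end)
    else:
        lo, hi = max(late_start, config.study_start), config.study_end
    span = (hi - lo).days
    return lo + timedelta(days=int(rng.integers(0, span + 1)))


def generate_birth_registry(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[MaternalBirthRecord]:
    """Draw ``config.n_infants`` cohort-eligible records (singleton, term).

    Deterministic given ``config.seed``; marginal covariate frequencies match
    the configured values up to binomial noise.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    regions = list(config.world_region_probs)
    region_p = np.array([config.world_region_probs[r] for r in regions], dtype=float)
    region_p = region_p / region_p.sum()
    records: list[MaternalBirthRecord] = []
    width = max(6, len(str(config.n_infants)))
    for i in range(config.n_infants):
        age = int(np.clip(round(rng.normal(config.maternal_age_mean,
                                           config.maternal_age_sd)), 12, 55))
        # parity = number of previous live births; primiparous <=> parity 0
        parity = 0 if rng.random() < config.primiparous_prob else int(rng.geometric(0.5))
        region = regions[rng.choice(len(regions), p=region_p)]
        immigrant = region != "Canada"
        q_idx = int(rng.choice(6, p=np.asarray(config.income_quintile_probs)))
        quintile = INCOME_UNKNOWN if q_idx == 5 else q_idx + 1
        bw = int(max(500, round(rng.normal(config.birthweight_mean,
                                           config.birthweight_sd))))
        ga = int(np.clip(round(rng.normal(config.gestational_age_mean,
                                          config.gestational_age_sd)), 37, 42))
        records.append(
            MaternalBirthRecord(
                infant_id=f"inf{i:0{width}d}",
                maternal_age=age,
                parity=parity,
                urban=bool(rng.random() < config.urban_prob),
                immigrant=immigrant,
                income_quintile=quintile,
                world_region=region,
                birth_date=_draw_birth_date(rng, config),
                birthweight_g=bw,
                gestational_age_wk=ga,
                infant_sex="M" if rng.random() < config.male_prob else "F",
                plurality=1,
            )
        )
    return records


def registry_frame(records: list[MaternalBirthRecord]) -> pd.DataFrame:
    """Tabular view with the documented column order."""
    return pd.DataFrame(
        [
            {
                "infant_id": r.infant_id,
                "maternal_age": r.maternal_age,
                "parity": r.parity,
                "urban": r.urban,
                "immigrant": r.immigrant,
                "income_quintile": r.income_quintile,
                "world_region": r.world_region,
                "birth_date": r.birth_date.isoformat(),
                "birthweight_g": r.birthweight_g,
                "gestational_age_wk": r.gestational_age_wk,
                "infant_sex": r.infant_sex,
                "plurality": r.plurality,
            }
            for r in records
        ],
        columns=REGISTRY_COLUMNS,
    )


def records_from_frame(df: pd.DataFrame) -> list[MaternalBirthRecord]:
    return [
        MaternalBirthRecord(
            infant_id=str(row.infant_id),
            maternal_age=int(row.maternal_age),
            parity=int(row.parity),
            urban=bool(row.urban),
            immigrant=bool(row.immigrant),
            income_quintile=int(row.income_quintile),
            world_region=str(row.world_region),
            birth_date=date.fromisoformat(str(row.birth_date)),
            birthweight_g=int(row.birthweight_g),
            gestational_age_wk=int(row.gestational_age_wk),
            infant_sex=str(row.infant_sex),
            plurality=int(row.plurality),
        )
        for row in df.itertuples(index=False)
    ]
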