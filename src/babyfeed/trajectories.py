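"""Latent feeding trajectories behind the rendered notes.

The model: with probability ``1 - ebf_init_prob`` an infant is never
exclusively breastfed (``ebf_end_age = 0``). Conditional on initiation, the
age at which exclusive breastfeeding (EBF) ends follows a piecewise-constant
hazard on (0,60], (60,122], (122,182], (182,750], solved so that the
*unconditional* survival at 60/122/182 days equals the configured targets at
reference covariate values. Covariates act as multiplicative hazard ratios
on mean-centred values, so population-level survival stays at the targets
while strata show realistic gradients (older, urban, higher-income and
immigrant mothers persisting longer).

Discontinuation beyond the 750-day chart horizon is coded with a large
sentinel age (``NEVER_ENDED``): the infant is exclusively breastfed at every
observable visit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import HORIZON_DAYS, INCOME_UNKNOWN, SimConfig
from .errors import ConfigError
from .registry import MaternalBirthRecord

#: Sentinel age for "EBF did not end within the observable chart window".
NEVER_ENDED = 10_000

_BREAKS = (0, 60, 122, 182, HORIZON_DAYS)


@dataclass(frozen=True)
class FeedingTrajectory:
    """Ground truth for one infant.

    ``ebf_end_age``: latent age (days) at which exclusive breastfeeding ends
    (0 = never exclusively breastfed). ``mixed_end_age``: age at which any
    breastfeeding ends (>= ebf_end_age). Status at age ``a`` is EBF iff
    ``a < ebf_end_age``, MIXED iff ``ebf_end_age <= a < mixed_end_age``,
    FORMULA otherwise.
    """

    infant_id: str
    ebf_end_age: int
    mixed_end_age: int
    ever_formula: bool

    def __post_init__(self) -> None:
        if not 0 <= self.ebf_end_age <= self.mixed_end_age:
            raise ValueError("require 0 <= ebf_end_age <= mixed_end_age")

    def status_at(self, age_days: int) -> str:
        if age_days < self.ebf_end_age:
            return "EBF"
        if age_days < self.mixed_end_age:
            return "MIXED"
        return "FORMULA"


def solve_hazards(config: SimConfig) -> np.ndarray:
    """Baseline hazards (per day) on the four age pieces.

    Solved from the unconditional survival targets S(60), S(122), S(182) and
    the initiation probability; the last piece reuses the (122,182] hazard,
    which the three targets leave unidentified.
    """
    init = config.ebf_init_prob
    if init == 0.0:
        if any(t > 0 for t in config.ebf_survival_targets):
            raise ConfigError("nonzero survival targets need ebf_init_prob > 0")
        return np.zeros(4)
    cond = np.asarray(config.ebf_survival_targets, dtype=float) / init
    if np.any(cond > 1.0):
        raise ConfigError("survival targets exceed the initiation probability")
    log_s = np.log(np.concatenate([[1.0], cond]))
    lam = np.empty(4)
    for k in range(3):
        lam[k] = (log_s[k] - log_s[k + 1]) / (_BREAKS[k + 1] - _BREAKS[k])
    lam[3] = lam[2]
    if np.any(lam < 0):
        raise ConfigError("survival targets must be non-increasing")
    return lam


def _mean_income_quintile(config: SimConfig) -> float:
    p = np.asarray(config.income_quintile_probs[:5], dtype=float)
    return float(np.dot(np.arange(1, 6), p) / p.sum())


def hazard_multiplier(record: MaternalBirthRecord, config: SimConfig) -> float:
    """exp(sum of log hazard ratios on mean-centred covariates).

    Unknown income quintile contributes the population mean (zero deviation).
    Returns 1.0 at reference (population-mean) covariates.
    """
    eff = config.covariate_effects
    z = 0.0
    if "maternal_age_per_decade" in eff:
        z += eff["maternal_age_per_decade"] * (
            (record.maternal_age - config.maternal_age_mean) / 10.0
        )
    if "urban" in eff:
        z += eff["urban"] * (float(record.urban) - config.urban_prob)
    if "immigrant" in eff:
        p_imm = 1.0 - config.world_region_probs.get("Canada", 1.0)
        z += eff["immigrant"] * (float(record.immigrant) - p_imm)
    if "income_quintile_per_level" in eff and record.income_quintile != INCOME_UNKNOWN:
        z += eff["income_quintile_per_level"] * (
            record.income_quintile - _mean_income_quintile(config)
        )
    return float(np.exp(z))


def _invert_cumulative_hazard(lam: np.ndarray, target: float) -> float:
    """Smallest t with integrated baseline hazard Lambda0(t) = target."""
    acc = 0.0
    for k in range(4):
        width = _BREAKS[k + 1] - _BREAKS[k]
        piece = lam[k] * width
        if acc + piece >= target and lam[k] > 0:
            return _BREAKS[k] + (target - acc) / lam[k]
        acc += piece
    return float(NEVER_ENDED)


def generate_feeding_trajectory(
    record: MaternalBirthRecord,
    config: SimConfig,
    rng: np.random.Generator,
    hazards: np.ndarray | None = None,
) -> FeedingTrajectory:
    """Draw one latent trajectory. Covariates shift the hazard; the point
    mass at zero (never-EBF) is shared across covariate patterns."""
    lam = solve_hazards(config) if hazards is None else hazards
    m = hazard_multiplier(record, config)
    if rng.random() >= config.ebf_init_prob:
        ebf_end = 0.0
    else:
        u = rng.random()
        target = -np.log(u) / m if u > 0 else np.inf
        ebf_end = _invert_cumulative_hazard(lam, target)
    ebf_end_i = NEVER_ENDED if ebf_end >= HORIZON_DAYS else int(np.ceil(ebf_end))
    if ebf_end_i >= NEVER_ENDED:
        return FeedingTrajectory(record.infant_id, NEVER_ENDED, NEVER_ENDED, False)
    # After EBF ends (or never starts): either a mixed-feeding phase, then
    # formula, or formula directly.
    if rng.random() < 0.6:
        mixed_len = int(np.ceil(rng.exponential(120.0 if ebf_end_i == 0 else 60.0)))
        mixed_end = min(ebf_end_i + mixed_len, HORIZON_DAYS)
    else:
        mixed_end = ebf_end_i
    return FeedingTrajectory(record.infant_id, ebf_end_i, mixed_end, True)


def generate_trajectories(
    registry: list[MaternalBirthRecord],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[FeedingTrajectory]:
    """Vectorised driver; one shared RNG stream in registry order."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    lam = solve_hazards(config)
    return [generate_feeding_trajectory(r, config, rng, lam) for r in registry]
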