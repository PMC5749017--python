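"""Rates, rate ratios (Katz log-normal CI), standardized differences,
Cohen's kappa, and the stratified rate-ratio / covariate-balance tables.

Display conventions match the field's tables: rates to 1 decimal place, rate
ratios and CI bounds to 2, standardized differences to 1, all rounded half
away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import INCOME_UNKNOWN, TARGET_AGES
from .errors import BabyfeedError, DataIntegrityError
from .extract import round_half_away

Z95 = float(sps.norm.ppf(0.975))


@dataclass(frozen=True)
class RateRow:
    """One stratum of a rate-ratio table."""

    stratum_label: str
    n: int
    rate: float  # percent
    rr: float
    ci_low: float
    ci_high: float
    is_referent: bool


@dataclass(frozen=True)
class BalanceRow:
    characteristic: str
    value_a: str
    value_b: str
    std_diff: float


def rate(numerator: int, denominator: int) -> float:
    """Percentage numerator/denominator."""
    if denominator <= 0:
        raise BabyfeedError("rate undefined: denominator is zero")
    if not 0 <= numerator <= denominator:
        raise BabyfeedError("rate requires 0 <= numerator <= denominator")
    return 100.0 * numerator / denominator


def rate_ratio(
    p1: float, n1: int, p0: float, n0: int
) -> tuple[float, float, float]:
    """Rate ratio p1/p0 with the Katz log-transform 95% CI:

        exp( ln(p1/p0) +/- z * sqrt((1-p1)/(n1*p1) + (1-p0)/(n0*p0)) )

    Returns (rr, ci_low, ci_high); CI bounds are NaN when either arm has a
    zero numerator (the log method is undefined there).
    """
    if p0 <= 0:
        raise BabyfeedError("rate ratio undefined: referent rate is zero")
    if n1 <= 0 or n0 <= 0:
        raise BabyfeedError("rate ratio requires positive denominators")
    rr = p1 / p0
    if p1 <= 0:
        return rr, float("nan"), float("nan")
    se = np.sqrt((1 - p1) / (n1 * p1) + (1 - p0) / (n0 * p0))
    return rr, float(rr * np.exp(-Z95 * se)), float(rr * np.exp(Z95 * se))


def standardized_difference(summary_a, summary_b) -> float:
    """Scale-free covariate difference between two cohorts.

    Binary: pass proportions (p_a, p_b) or ``{"p": value}`` mappings.
    Continuous: pass ``(mean, sd)`` tuples. Sign is a minus b.
    """

    def _parse(s):
        if isinstance(s, dict):
            if "p" in s:
                return ("binary", float(s["p"]))
            return ("continuous", (float(s["mean"]), float(s["sd"])))
        if isinstance(s, (tuple, list)) and len(s) == 2:
            return ("continuous", (float(s[0]), float(s[1])))
        return ("binary", float(s))

    kind_a, a = _parse(summary_a)
    kind_b, b = _parse(summary_b)
    if kind_a != kind_b:
        raise BabyfeedError("summaries must be of the same kind")
    if kind_a == "binary":
        pooled = (a * (1 - a) + b * (1 - b)) / 2.0
        if pooled == 0:
            if a == b:
                return 0.0
            raise BabyfeedError("zero pooled variance with unequal proportions")
        return float((a - b) / np.sqrt(pooled))
    (ma, sa), (mb, sb) = a, b
    pooled = (sa**2 + sb**2) / 2.0
    if pooled == 0:
        if ma == mb:
            return 0.0
        raise BabyfeedError("zero pooled variance with unequal means")
    return float((ma - mb) / np.sqrt(pooled))


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement (p_o - p_e)/(1 - p_e), expected agreement
    from the raters' marginal label distributions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.shape != b.shape:
        raise BabyfeedError("kappa needs two equal-length non-empty vectors")
    levels = np.union1d(np.unique(a), np.unique(b))
    idx = {lev: i for i, lev in enumerate(levels)}
    table = np.zeros((len(levels), len(levels)))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    table /= table.sum()
    p_o = float(np.trace(table))
    p_e = float(np.dot(table.sum(axis=1), table.sum(axis=0)))
    if p_e >= 1.0:
        raise BabyfeedError("degenerate agreement: expected agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


# ----------------------------------------------------------------------
# Covariate stratifications over the registry


def _age_band(age: int) -> str:
    if age < 20:
        return "<20"
    if age >= 40:
        return ">=40"
    lo = (age // 5) * 5
    return f"{lo}-{lo + 4}"


def _birthweight_band(bw: int) -> str:
    if bw < 2500:
        return "<2500"
    if bw < 3000:
        return "2500-<3000"
    if bw < 3500:
        return "3000-<3500"
    return ">=3500"


def _joint_income_immigrant(row) -> str:
    if row["income_quintile"] == INCOME_UNKNOWN:
        return "Unknown"
    q1 = row["income_quintile"] == 1
    imm = "immigrant" if row["immigrant"] else "non-immigrant"
    return f"Q1 & {imm}" if q1 else f"Q2-Q5 & {imm}"


COVARIATES: dict[str, dict] = {
    "maternal_age_band": {
        "derive": lambda df: df["maternal_age"].map(_age_band),
        "order": ["<20", "20-24", "25-29", "30-34", "35-39", ">=40"],
        "fixed_referent": "<20",
    },
    "parity_group": {
        "derive": lambda df: np.where(df["parity"] == 0, "Primiparous", "Multiparous"),
        "order": ["Multiparous", "Primiparous"],
        "fixed_referent": "Multiparous",
    },
    "urban": {
        "derive": lambda df: np.where(df["urban"], "Yes", "No"),
        "order": ["No", "Yes"],
        "fixed_referent": "No",
    },
    "immigrant": {
        "derive": lambda df: np.where(df["immigrant"], "Yes", "No"),
        "order": ["No", "Yes"],
        "fixed_referent": "No",
    },
    "income_quintile": {
        "derive": lambda df: df["income_quintile"].map(
            lambda q: "Unknown" if q == INCOME_UNKNOWN else f"Q{q}"
        ),
        "order": ["Q1", "Q2", "Q3", "Q4", "Q5", "Unknown"],
        "fixed_referent": "Q1",
    },
    "income_immigrant": {
        "derive": lambda df: df.apply(_joint_income_immigrant, axis=1),
        "order": [
            "Q1 & non-immigrant", "Q1 & immigrant",
            "Q2-Q5 & non-immigrant", "Q2-Q5 & immigrant", "Unknown",
        ],
        "fixed_referent": "Q1 & non-immigrant",
    },
    "birthweight_band": {
        "derive": lambda df: df["birthweight_g"].map(_birthweight_band),
        "order": ["<2500", "2500-<3000", "3000-<3500", ">=3500"],
        "fixed_referent": "<2500",
    },
    "birth_year_band": {
        "derive": lambda df: df["birth_date"].map(
            lambda d: "2002-2007" if int(str(d)[:4]) <= 2007 else "2008-2013"
        ),
        "order": ["2002-2007", "2008-2013"],
        "fixed_referent": "2002-2007",
    },
}


def stratified_rr_table(
    statuses: pd.DataFrame,
    registry: pd.DataFrame,
    covariate: str,
    target_age: int,
    referent: str = "fixed",
) -> list[RateRow]:
    """Per-stratum EBF rate and rate ratio vs a referent stratum at one
    target age.

    ``statuses`` is the timepoint table (frame form), ``registry`` the
    registry frame. ``referent`` is ``"fixed"`` (conventional referent per
    covariate) or ``"lowest"`` (stratum with the lowest rate, excluding
    Unknown and empty strata).
    """
    if covariate not in COVARIATES:
        raise BabyfeedError(f"unknown covariate: {covariate}")
    if target_age not in TARGET_AGES:
        raise BabyfeedError(f"target_age must be one of {TARGET_AGES}")
    spec = COVARIATES[covariate]
    reg = registry.copy()
    reg["stratum"] = spec["derive"](reg)
    det = statuses[
        (statuses["target_age"] == target_age)
        & statuses["in_denominator"]
        & (statuses["status"] != "UNDETERMINED")
    ].merge(reg[["infant_id", "stratum"]], on="infant_id", how="left")
    if det["stratum"].isna().any():
        raise DataIntegrityError("statuses contain infants missing from registry")

    levels = [
        lev for lev in spec["order"] if lev in set(det["stratum"])
        or lev in set(reg["stratum"])
    ]
    counts: dict[str, tuple[int, int]] = {}
    for lev in levels:
        sub = det[det["stratum"] == lev]
        counts[lev] = (int((sub["status"] == "EBF").sum()), int(len(sub)))

    if referent == "lowest":
        candidates = [
            lev for lev in levels if lev != "Unknown" and counts[lev][1] > 0
        ]
        ref_level = min(candidates, key=lambda lev: counts[lev][0] / counts[lev][1])
    elif referent == "fixed":
        ref_level = spec["fixed_referent"]
    else:
        raise BabyfeedError("referent must be 'fixed' or 'lowest'")
    num0, den0 = counts.get(ref_level, (0, 0))
    degenerate = den0 == 0 or num0 == 0  # RR undefined against this referent
    p0 = num0 / den0 if den0 else float("nan")

    rows: list[RateRow] = []
    nan = float("nan")
    for lev in levels:
        num, den = counts[lev]
        if den == 0:
            rows.append(RateRow(lev, 0, nan, nan, nan, nan, lev == ref_level))
            continue
        p1 = num / den
        if degenerate:
            rows.append(RateRow(lev, den, rate(num, den), nan, nan, nan,
                                lev == ref_level))
        elif lev == ref_level:
            rows.append(RateRow(lev, den, rate(num, den), 1.0,
                                *rate_ratio(p1, den, p0, den0)[1:], True))
        else:
            rr, lo, hi = rate_ratio(p1, den, p0, den0)
            rows.append(RateRow(lev, den, rate(num, den), rr, lo, hi, False))
    return rows


def rate_table_frame(rows: list[RateRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum_label,
                "n": r.n,
                "rate_pct": round_half_away(r.rate, 1) if np.isfinite(r.rate) else np.nan,
                "rr": round_half_away(r.rr, 2) if np.isfinite(r.rr) else np.nan,
                "ci_low": round_half_away(r.ci_low, 2) if np.isfinite(r.ci_low) else np.nan,
                "ci_high": round_half_away(r.ci_high, 2) if np.isfinite(r.ci_high) else np.nan,
                "is_referent": r.is_referent,
            }
            for r in rows
        ]
    )


# ----------------------------------------------------------------------
# Covariate balance between two registries

_BALANCE_CONTINUOUS = [
    ("Maternal age, years", "maternal_age"),
    ("Birthweight, g", "birthweight_g"),
    ("Gestational age, weeks", "gestational_age_wk"),
]
_BALANCE_BINARY = [
    ("Rural residence", lambda df: ~df["urban"].astype(bool)),
    ("Immigrant", lambda df: df["immigrant"].astype(bool)),
    ("Infant male sex", lambda df: df["infant_sex"] == "M"),
    ("Primiparous", lambda df: df["parity"] == 0),
]


def balance_table(registry_a: pd.DataFrame, registry_b: pd.DataFrame) -> list[BalanceRow]:
    """Standardized differences between two birth cohorts (a minus b)."""
    for col in ("maternal_age", "urban", "immigrant", "parity",
                "birthweight_g", "gestational_age_wk", "infant_sex"):
        if col not in registry_a.columns or col not in registry_b.columns:
            raise BabyfeedError(f"registries must share the covariate schema ({col})")
    rows: list[BalanceRow] = []
    for label, col in _BALANCE_CONTINUOUS:
        a = (registry_a[col].mean(), registry_a[col].std(ddof=1))
        b = (registry_b[col].mean(), registry_b[col].std(ddof=1))
        rows.append(BalanceRow(
            label,
            f"{a[0]:.1f} ({a[1]:.1f})",
            f"{b[0]:.1f} ({b[1]:.1f})",
            standardized_difference(a, b),
        ))
    for label, fn in _BALANCE_BINARY:
        pa = float(fn(registry_a).mean())
        pb = float(fn(registry_b).mean())
        rows.append(BalanceRow(
            label, f"{100 * pa:.1f}%", f"{100 * pb:.1f}%",
            standardized_difference(pa, pb),
        ))
    return rows


def balance_frame(rows: list[BalanceRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "characteristic": r.characteristic,
                "cohort_a": r.value_a,
                "cohort_b": r.value_b,
                "std_diff": round_half_away(r.std_diff, 1),
            }
            for r in rows
        ]
    )
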