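"""Recompute the published cohort's summary statistics from printed inputs.

The bundled ``data/reference_cohort.yaml`` holds the published raw numbers
(flow counts, stratum denominators and rates); the functions here push them
back through the package's own arithmetic - :func:`babyfeed.stats.rate`,
:func:`babyfeed.stats.rate_ratio`, :func:`babyfeed.stats.standardized_difference` -
so agreement with the printed rates, rate ratios, CIs and standardized
differences is a computation, not a lookup.
"""

from __future__ import annotations

import importlib.resources

import yaml

from .extract import round_half_away
from .stats import rate, rate_ratio, standardized_difference


def load_reference() -> dict:
    ref = importlib.resources.files("babyfeed") / "data" / "reference_cohort.yaml"
    return yaml.safe_load(ref.read_text())


def recovered_numerator(n: int, rate_pct: float) -> int:
    """Invert a printed rate to its integer numerator: round(n * rate/100)."""
    return int(round_half_away(n * rate_pct / 100.0))


def flow_rates(ref: "dict | None" = None) -> dict[str, dict]:
    """Chart-flow percentages recomputed from printed counts."""
    ref = ref or load_reference()
    c = ref["flow_counts"]
    return {
        "undocumented_pct": {
            "value": round_half_away(
                rate(c["no_feeding_documentation"], c["total_infants"]), 1
            ),
            "n": c["total_infants"],
        },
        "rourke_pct": {
            "value": round_half_away(rate(c["any_rourke_record"], c["total_infants"]), 1),
            "n": c["total_infants"],
        },
        "auto_classified_pct": {
            "value": round_half_away(
                rate(c["auto_classified_among_rourke"], c["any_rourke_record"]), 1
            ),
            "n": c["any_rourke_record"],
        },
    }


def recompute_rate_ratios(ref: "dict | None" = None) -> dict[str, dict]:
    """Each published stratified comparison recomputed from the printed
    denominators and rates."""
    ref = ref or load_reference()
    out: dict[str, dict] = {}
    for row in ref["rate_ratio_rows"]:
        exp, base = row["exposed"], row["referent"]
        n1, n0 = exp["n"], base["n"]
        # printed rates are used directly as the stratum proportions:
        # recovering integer numerators first would stack a second rounding
        # on top of the printed 1-dp rounding and can flip the last digit
        p1 = exp["rate_pct"] / 100.0
        p0 = base["rate_pct"] / 100.0
        rr, lo, hi = rate_ratio(p1, n1, p0, n0)
        out[row["id"]] = {
            "rr": round_half_away(rr, 2),
            "ci_low": round_half_away(lo, 2),
            "ci_high": round_half_away(hi, 2),
            "n": n1 + n0,
            "printed": dict(row["printed"]),
        }
    return out


def rural_std_diff(ref: "dict | None" = None) -> float:
    """Rural-residence standardized difference, provincial cohort vs EMR
    subsample, from printed proportions."""
    ref = ref or load_reference()
    b = ref["balance"]["rural_residence"]
    return round_half_away(standardized_difference(b["p_a"], b["p_b"]), 1)


def maternal_age_std_diff(ref: "dict | None" = None) -> float:
    ref = ref or load_reference()
    b = ref["balance"]["maternal_age"]
    return round_half_away(
        standardized_difference((b["mean_a"], b["sd_a"]), (b["mean_b"], b["sd_b"])), 1
    )
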