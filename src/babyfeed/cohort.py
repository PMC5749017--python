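"""Cohort eligibility, index-visit selection, and timepoint inference.

Eligibility: singleton (plurality 1), term (>= 37 completed weeks), with at
least one visit before 190 days of age; observations beyond 750 days are
dropped (infant retained).

Exclusive-breastfeeding (EBF) status at each target age (60, 122, 182 days)
is resolved from the infant's observations:

1. no visit at/after the target        -> out of denominator, UNDETERMINED;
2. index visit = earliest visit at/after the target ("closest to but not
   preceding"); current EBF there      -> EBF;
3. a non-EBF current status at an index visit within ``window`` days of the
   target                              -> NOT_EBF;
4. otherwise, any later current-EBF observation, or a historical statement
   "exclusively breastfed for d days": d >= target -> EBF; a historical
   statement with d < target -> NOT_EBF (exclusive breastfeeding, once
   ended, does not resume); nothing    -> UNDETERMINED;
5. EBF at a later target back-propagates to every earlier target.

UNDETERMINED infants stay in the visit denominator flag but are excluded
from numerator and denominator when rates are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import HORIZON_DAYS, TARGET_AGES
from .errors import DataIntegrityError
from .extract import FeedingObservation
from .registry import MaternalBirthRecord

logger = logging.getLogger(__name__)

TERM_WEEKS = 37
MAX_FIRST_VISIT_AGE = 190

#: Carry-forward window (days) per target age: gap to the next target, and
#: effectively unbounded (to the 750-day horizon) for the last target.
DEFAULT_WINDOWS = {60: 62, 122: 60, 182: HORIZON_DAYS - 182}

STATUS_COLUMNS = ["infant_id", "target_age", "in_denominator", "status", "evidence"]


@dataclass(frozen=True)
class TimepointStatus:
    infant_id: str
    target_age: int
    in_denominator: bool
    status: str  # EBF | NOT_EBF | UNDETERMINED
    evidence: str  # index_visit | future_current_ebf | future_historical_ebf | none


@dataclass
class EligibleCohort:
    """Registry records plus per-infant observations, post-eligibility."""

    records: list[MaternalBirthRecord]
    observations: dict[str, list[FeedingObservation]]
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def infant_ids(self) -> list[str]:
        return [r.infant_id for r in self.records]


def build_cohort(
    registry: list[MaternalBirthRecord],
    observations: list[FeedingObservation],
) -> EligibleCohort:
    """Apply the eligibility rules; excluded infants get reason codes."""
    by_id: dict[str, list[FeedingObservation]] = {r.infant_id: [] for r in registry}
    for obs in observations:
        if obs.infant_id not in by_id:
            raise DataIntegrityError(
                f"observation for unknown infant {obs.infant_id!r}"
            )
        if obs.age_days <= HORIZON_DAYS:
            by_id[obs.infant_id].append(obs)
    for obs_list in by_id.values():
        obs_list.sort(key=lambda o: (o.age_days, o.tense))

    kept: list[MaternalBirthRecord] = []
    excl: list[tuple[str, str]] = []
    for rec in registry:
        if rec.plurality > 1:
            excl.append((rec.infant_id, "multiple_birth"))
            continue
        if rec.gestational_age_wk < TERM_WEEKS:
            excl.append((rec.infant_id, "preterm"))
            continue
        visits = [o for o in by_id[rec.infant_id] if o.tense == "current"]
        if not any(o.age_days < MAX_FIRST_VISIT_AGE for o in visits):
            excl.append((rec.infant_id, "no_visit_before_190d"))
            continue
        kept.append(rec)
    if excl:
        logger.info("excluded %d infants (%s...)", len(excl), excl[0][1])
    return EligibleCohort(
        records=kept,
        observations={r.infant_id: by_id[r.infant_id] for r in kept},
        exclusions=excl,
    )


def select_index_visit(
    observations: list[FeedingObservation], target_age: int
) -> "FeedingObservation | None":
    """The visit closest to but not preceding the target age."""
    candidates = [
        o for o in observations if o.tense == "current" and o.age_days >= target_age
    ]
    return min(candidates, key=lambda o: o.age_days) if candidates else None


def infer_status_at_timepoint(
    observations: list[FeedingObservation],
    target_age: int,
    window: "int | None" = None,
) -> TimepointStatus:
    """Resolve one infant's EBF status at one target age (no back-propagation;
    see :func:`timepoint_table` for the cross-target pass)."""
    if window is None:
        window = DEFAULT_WINDOWS.get(target_age, HORIZON_DAYS)
    infant_id = observations[0].infant_id if observations else "?"
    index = select_index_visit(observations, target_age)
    if index is None:
        return TimepointStatus(infant_id, target_age, False, "UNDETERMINED", "none")
    within = index.age_days - target_age <= window
    if index.status == "EBF":
        ev = "index_visit" if within else "future_current_ebf"
        return TimepointStatus(infant_id, target_age, True, "EBF", ev)
    if within and index.status in ("FORMULA", "MIXED"):
        return TimepointStatus(infant_id, target_age, True, "NOT_EBF", "index_visit")
    # index visit is undocumented or too far past the target: look across
    # all observations for current or historical EBF evidence
    later_ebf = any(
        o.tense == "current" and o.status == "EBF" and o.age_days >= target_age
        for o in observations
    )
    if later_ebf:
        return TimepointStatus(
            infant_id, target_age, True, "EBF", "future_current_ebf"
        )
    durations = [
        o.historical_duration
        for o in observations
        if o.tense == "historical"
        and o.status == "EBF"
        and o.historical_duration is not None
    ]
    if durations:
        if max(durations) >= target_age:
            return TimepointStatus(
                infant_id, target_age, True, "EBF", "future_historical_ebf"
            )
        return TimepointStatus(
            infant_id, target_age, True, "NOT_EBF", "future_historical_ebf"
        )
    return TimepointStatus(infant_id, target_age, True, "UNDETERMINED", "none")


def timepoint_table(
    cohort: EligibleCohort, windows: "dict[int, int] | None" = None
) -> list[TimepointStatus]:
    """Three rows per infant (one per target age), with EBF at a later
    target back-propagated to every earlier target."""
    windows = dict(DEFAULT_WINDOWS) if windows is None else windows
    rows: list[TimepointStatus] = []
    for infant_id in cohort.infant_ids:
        obs = cohort.observations[infant_id]
        per_target = {
            t: infer_status_at_timepoint(obs, t, windows.get(t)) for t in TARGET_AGES
        }
        for i, t in enumerate(TARGET_AGES):
            for later in TARGET_AGES[i + 1:]:
                if per_target[later].status == "EBF" and per_target[t].status != "EBF":
                    old = per_target[t]
                    per_target[t] = TimepointStatus(
                        infant_id, t, old.in_denominator or True,
                        "EBF", per_target[later].evidence,
                    )
                    break
        rows.extend(per_target[t] for t in TARGET_AGES)
    return rows


def ebf_duration(observations: list[FeedingObservation]) -> "int | None":
    """Age (days) of the latest visit with confirmed current exclusive
    breastfeeding; None if no such visit."""
    ages = [
        o.age_days
        for o in observations
        if o.tense == "current" and o.status == "EBF"
    ]
    return max(ages) if ages else None


def complete_case_subset(
    cohort: EligibleCohort, statuses: list[TimepointStatus]
) -> EligibleCohort:
    """Infants with documented feeding at all three targets (index-visit
    evidence, non-UNDETERMINED) - the sensitivity-analysis subset that needs
    no inference from future visits."""
    ok: dict[str, int] = {}
    for s in statuses:
        if s.status != "UNDETERMINED" and s.evidence == "index_visit":
            ok[s.infant_id] = ok.get(s.infant_id, 0) + 1
    keep = {iid for iid, k in ok.items() if k == len(TARGET_AGES)}
    records = [r for r in cohort.records if r.infant_id in keep]
    return EligibleCohort(
        records=records,
        observations={r.infant_id: cohort.observations[r.infant_id] for r in records},
        exclusions=cohort.exclusions
        + [(i, "incomplete_documentation") for i in cohort.infant_ids if i not in keep],
    )


def statuses_frame(statuses: list[TimepointStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "infant_id": s.infant_id,
                "target_age": s.target_age,
                "in_denominator": s.in_denominator,
                "status": s.status,
                "evidence": s.evidence,
            }
            for s in statuses
        ],
        columns=STATUS_COLUMNS,
    )


def ebf_rates(statuses: list[TimepointStatus]) -> dict[int, tuple[int, int, float]]:
    """Per target age: (numerator, denominator, rate %) among infants with a
    qualifying visit and determined status."""
    out: dict[int, tuple[int, int, float]] = {}
    for t in TARGET_AGES:
        det = [
            s for s in statuses
            if s.target_age == t and s.in_denominator and s.status != "UNDETERMINED"
        ]
        num = sum(1 for s in det if s.status == "EBF")
        den = len(det)
        out[t] = (num, den, 100.0 * num / den if den else float("nan"))
    return out
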