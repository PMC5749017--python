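"""Well-baby visit-note rendering and corpus I/O.

Each infant attends a configurable visit schedule; each attended visit
becomes a :class:`VisitNote` whose free text is assembled from controlled
templates consistent with the infant's latent feeding trajectory at that
age. With probability ``rourke_prob`` an infant's well-baby notes carry a
Rourke Baby Record header (one of several real-world name variants, in
randomized case); with probability ``undocumented_prob`` an infant's notes
contain no feeding terms at all, emulating charts from which feeding could
not be recovered.

Durations in historical statements ("previously exclusively breastfed for
9 weeks") are phrased in days below two weeks, integer weeks below twelve
weeks, and months to one decimal beyond - the precision a clinician would
plausibly chart, and fine enough that parsing the phrase back recovers the
true duration to within a few days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import DataIntegrityError
from .registry import (
    MaternalBirthRecord,
    REGISTRY_COLUMNS,
    records_from_frame,
    registry_frame,
)
from .trajectories import FeedingTrajectory

ROURKE_VARIANTS = (
    "Rourke",
    "Rourke Baby Record",
    "Well Baby Visit",
    "Well Baby Check Up",
    "Newborn Visit",
    "1 month visit",
    "2 month visit",
    "4 month visit",
    "6 month visit",
)

_EBF_TEMPLATES = (
    "exclusively breastfeeding, latching well",
    "breast milk only, feeding q3h",
    "feeding: exclusively breastfed",
    "EBF, voiding and stooling normally",
)
_MIXED_TEMPLATES = (
    "feeding both breast and formula",
    "breastfeeding with formula supplementation",
    "breast and formula, supplementing after evening feeds",
)
_FORMULA_TEMPLATES = (
    "formula feeding, tolerating well",
    "on Similac formula, approx 120 mL q4h",
    "formula fed, no issues reported",
)
_HISTORICAL_TEMPLATES = (
    "previously exclusively breastfed for {dur}",
    "was exclusively breastfed for {dur}",
)
_FILLER_TEMPLATES = (
    "wt {wt} kg, growing along curve",
    "wt {wt} kg, immunizations given, development on track",
    "wt {wt} kg, exam unremarkable",
)


@dataclass(frozen=True)
class VisitNote:
    """A dated clinical note for one infant.

    ``style`` records how the note was generated (test oracle only) and is
    ignored by extraction.
    """

    infant_id: str
    visit_date: "str | None"
    age_days: int
    text: str
    structured_fields: dict = field(default_factory=dict)
    style: str = "progress_note"


def format_duration(days: int) -> str:
    """Phrase an age in days the way a chart note would."""
    if days < 14:
        return f"{days} days"
    if days < 12 * 7:
        return f"{int(round(days / 7.0))} weeks"
    return f"{days / 30.44:.1f} months"


def _case_variant(phrase: str, rng: np.random.Generator) -> str:
    u = rng.random()
    if u < 0.25:
        return phrase.upper()
    if u < 0.5:
        return phrase.lower()
    return phrase


def _feeding_sentence(
    traj: FeedingTrajectory, age: int, config: SimConfig, rng: np.random.Generator
) -> str:
    status = traj.status_at(age)
    if status == "EBF":
        return str(rng.choice(_EBF_TEMPLATES))
    parts = [
        str(
            rng.choice(
                _MIXED_TEMPLATES if status == "MIXED" else _FORMULA_TEMPLATES
            )
        )
    ]
    if 0 < traj.ebf_end_age <= age and rng.random() < config.historical_mention_prob:
        tmpl = str(rng.choice(_HISTORICAL_TEMPLATES))
        parts.append(tmpl.format(dur=format_duration(traj.ebf_end_age)))
    return "; ".join(parts)


def _approx_weight_kg(age: int, rng: np.random.Generator) -> float:
    # crude newborn growth curve, for filler text only
    return round(3.4 + 0.028 * age + rng.normal(0, 0.3), 1)


def render_visit_corpus(
    registry: list[MaternalBirthRecord],
    trajectories: list[FeedingTrajectory],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[VisitNote]:
    """Render every attended visit of every infant into a note.

    Raises :class:`DataIntegrityError` if an infant lacks a trajectory.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    traj_by_id = {t.infant_id: t for t in trajectories}
    missing = [r.infant_id for r in registry if r.infant_id not in traj_by_id]
    if missing:
        raise DataIntegrityError(
            f"no feeding trajectory for {len(missing)} infants, e.g. {missing[0]}"
        )
    notes: list[VisitNote] = []
    for rec in registry:
        traj = traj_by_id[rec.infant_id]
        is_rourke = rng.random() < config.rourke_prob
        undocumented = rng.random() < config.undocumented_prob
        for slot in config.visit_schedule:
            if rng.random() >= slot.attend_prob:
                continue
            delay = abs(rng.normal(0.0, slot.jitter_sd)) if slot.jitter_sd > 0 else 0.0
            age = slot.age + int(round(delay))
            pieces: list[str] = []
            structured: dict = {}
            if is_rourke:
                variant = _case_variant(str(rng.choice(ROURKE_VARIANTS)), rng)
                pieces.append(variant)
            if undocumented:
                style = "undocumented"
            elif is_rourke and rng.random() < config.structured_field_prob:
                style = "rourke_structured"
                status = traj.status_at(age)
                structured["feeding"] = {
                    "EBF": "breast",
                    "MIXED": "both",
                    "FORMULA": "formula",
                }[status]
            else:
                style = "rourke_freetext" if is_rourke else "progress_note"
                pieces.append(_feeding_sentence(traj, age, config, rng))
            pieces.append(
                str(rng.choice(_FILLER_TEMPLATES)).format(
                    wt=_approx_weight_kg(age, rng)
                )
            )
            notes.append(
                VisitNote(
                    infant_id=rec.infant_id,
                    visit_date=(rec.birth_date + timedelta(days=age)).isoformat(),
                    age_days=age,
                    text=". ".join(pieces),
                    structured_fields=structured,
                    style=style,
                )
            )
    return notes


# ----------------------------------------------------------------------
# I/O


def write_corpus(
    registry: list[MaternalBirthRecord],
    notes: list[VisitNote],
    out_dir,
) -> dict[str, Path]:
    """Write ``registry.csv`` + ``notes.jsonl`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reg_path = out / "registry.csv"
    notes_path = out / "notes.jsonl"
    registry_frame(registry).to_csv(reg_path, index=False)
    with open(notes_path, "w") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "infant_id": n.infant_id,
                        "visit_date": n.visit_date,
                        "age_days": n.age_days,
                        "text": n.text,
                        "structured_fields": n.structured_fields,
                        "style": n.style,
                    }
                )
                + "\n"
            )
    return {"registry": reg_path, "notes": notes_path}


def read_registry(path) -> list[MaternalBirthRecord]:
    df = pd.read_csv(path, dtype={"infant_id": str})
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise DataIntegrityError(f"registry.csv missing columns: {sorted(missing)}")
    return records_from_frame(df[REGISTRY_COLUMNS])


def read_notes(path) -> list[VisitNote]:
    notes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            notes.append(
                VisitNote(
                    infant_id=str(d["infant_id"]),
                    visit_date=d.get("visit_date"),
                    age_days=int(d["age_days"]),
                    text=str(d["text"]),
                    structured_fields=d.get("structured_fields") or {},
                    style=str(d.get("style", "progress_note")),
                )
            )
    return notes


def simulate_corpus(config: SimConfig):
    """One-call generator: registry, trajectories, notes (shared seed tree)."""
    from .trajectories import generate_trajectories

    seeds = np.random.SeedSequence(config.seed).spawn(3)
    registry = generate_birth_registry_seeded(config, seeds[0])
    trajectories = generate_trajectories(
        registry, config, np.random.default_rng(seeds[1])
    )
    notes = render_visit_corpus(
        registry, trajectories, config, np.random.default_rng(seeds[2])
    )
    return registry, trajectories, notes


def generate_birth_registry_seeded(config: SimConfig, seed_seq):
    from .registry import generate_birth_registry

    return generate_birth_registry(config, np.random.default_rng(seed_seq))
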