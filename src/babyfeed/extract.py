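"""Rule-based feeding extraction from well-baby note text.

The algorithm mirrors simple EMR free-text search: case-insensitive,
whitespace-normalized, word-boundary-anchored phrase matching, a short
pre-term negation window, and regex capture of duration-bearing historical
statements ("was exclusively breastfed for 9 weeks").

Per note the classifier emits exactly one current-status observation
(EBF / FORMULA / MIXED / NONE_DOCUMENTED) plus one historical companion
observation per historical statement found. Decision order for the current
status:

1. a structured Rourke feeding field, when present, overrides the text;
2. breast term AND formula term or mixed marker  -> MIXED;
3. breast term + exclusivity marker, no formula  -> EBF;
4. breast term alone (not negated)               -> EBF;
5. formula term alone                            -> FORMULA;
6. no surviving feeding terms                    -> NONE_DOCUMENTED.

Historical statements are masked out of the text before rules 2-6 run, so
"was exclusively breastfed until 4 months, now on formula" classifies as
current FORMULA with an EBF companion of duration 122 days.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .corpus import VisitNote
from .lexicon import Lexicon

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44

OBSERVATION_COLUMNS = [
    "infant_id",
    "age_days",
    "status",
    "tense",
    "historical_duration",
    "source",
]


@dataclass(frozen=True)
class RourkeDetection:
    detected: bool
    matched_variant: "str | None" = None
    char_span: "tuple[int, int] | None" = None


@dataclass(frozen=True)
class FeedingObservation:
    """Per-visit extracted feeding status."""

    infant_id: str
    age_days: int
    status: str  # EBF | FORMULA | MIXED | NONE_DOCUMENTED
    tense: str = "current"  # current | historical
    historical_duration: "int | None" = None
    source: str = "progress_note"
    matched_terms: tuple[str, ...] = field(default_factory=tuple)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (table-display convention)."""
    factor = 10.0**ndigits
    y = math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
    return y if ndigits > 0 else y


def _phrase_regex(phrase: str) -> re.Pattern:
    parts = [re.escape(tok) for tok in phrase.split()]
    return re.compile(r"\b" + r"\s+".join(parts) + r"\b", re.IGNORECASE)


class _CompiledLexicon:
    """Compiled regex view of a Lexicon, cached per Lexicon instance."""

    _cache: dict[int, "_CompiledLexicon"] = {}

    def __init__(self, lex: Lexicon):
        self.rourke = [(v, _phrase_regex(v)) for v in lex.rourke_variants]
        self.breast = [(t, _phrase_regex(t)) for t in lex.breast_terms]
        self.formula = [(t, _phrase_regex(t)) for t in lex.formula_terms]
        self.mixed = [(t, _phrase_regex(t)) for t in lex.mixed_markers]
        self.exclusive = [(t, _phrase_regex(t)) for t in lex.exclusivity_markers]
        self.negation = set(lex.negation_markers)
        self.historical = [re.compile(p, re.IGNORECASE) for p in lex.historical_patterns]

    @classmethod
    def of(cls, lex: Lexicon) -> "_CompiledLexicon":
        key = id(lex)
        if key not in cls._cache:
            if len(cls._cache) > 8:
                cls._cache.clear()
            cls._cache[key] = cls(lex)
        return cls._cache[key]


def detect_rourke_record(text: str, lexicon: Lexicon) -> RourkeDetection:
    """Earliest Rourke form-name variant in the text wins; among ties at the
    same start position, the longest match wins."""
    comp = _CompiledLexicon.of(lexicon)
    best: tuple[int, int, str] | None = None  # (start, -end, variant)
    for variant, rx in comp.rourke:
        m = rx.search(text)
        if m is None:
            continue
        cand = (m.start(), -m.end(), variant)
        if best is None or cand < best:
            best = cand
    if best is None:
        return RourkeDetection(False)
    return RourkeDetection(True, best[2], (best[0], -best[1]))


def parse_duration_days(num: str, unit: str) -> "int | None":
    """Stated duration -> days; months use 30.44 d, rounded half away."""
    try:
        value = float(num)
    except ValueError:
        return None
    u = unit.casefold()
    if u.startswith("mo"):
        return int(round_half_away(value * DAYS_PER_MONTH))
    if u.startswith("w"):
        return int(round_half_away(value * 7.0))
    if u.startswith("d"):
        return int(round_half_away(value))
    return None


def _find_feeding_terms(
    text: str, comp: "_CompiledLexicon"
) -> dict[str, list[str]]:
    """Breast / formula / mixed matches surviving negation.

    A negation marker within 3 tokens before a feeding term cancels that
    term, but only the *nearest* following term: in "no formula, breast milk
    only" the "no" is consumed by "formula" and leaves "breast milk" intact.
    """
    tokens = [(m.group(0).casefold(), m.start()) for m in re.finditer(r"\w+", text)]
    starts = [s for _, s in tokens]

    def token_index(char_pos: int) -> int:
        for i, s in enumerate(starts):
            if s >= char_pos:
                return i
        return len(starts)

    raw: list[tuple[int, str, str]] = []  # (token index, category, term)
    for category, compiled in (
        ("breast", comp.breast),
        ("formula", comp.formula),
        ("mixed", comp.mixed),
    ):
        for term, rx in compiled:
            for m in rx.finditer(text):
                raw.append((token_index(m.start()), category, term))
    term_positions = sorted({idx for idx, _, _ in raw})

    out: dict[str, list[str]] = {"breast": [], "formula": [], "mixed": []}
    for idx, category, term in raw:
        window = tokens[max(0, idx - 3): idx]
        negated = False
        for off, (word, _) in enumerate(window):
            neg_idx = max(0, idx - 3) + off
            if word not in comp.negation:
                continue
            # cancelled only if no other feeding term sits between the
            # negation and this one
            if not any(neg_idx < p < idx for p in term_positions):
                negated = True
                break
        if not negated and term not in out[category]:
            out[category].append(term)
    return out


def _find_terms(text: str, compiled, negation: set[str]) -> list[str]:
    """Matched phrases for a single category (no cross-category blocking)."""
    tokens = [(m.group(0).casefold(), m.start()) for m in re.finditer(r"\w+", text)]
    starts = [s for _, s in tokens]
    hits: list[str] = []
    for term, rx in compiled:
        for m in rx.finditer(text):
            lo = len(starts)
            for i, s in enumerate(starts):
                if s >= m.start():
                    lo = i
                    break
            window = tokens[max(0, lo - 3): lo]
            if any(w in negation for w, _ in window):
                continue
            hits.append(term)
            break
    return hits


_STRUCTURED_KEYS = ("feeding", "nutrition", "feeding_mode")
_STRUCTURED_MAP = {
    "breast": "EBF",
    "breastfeeding": "EBF",
    "breast milk": "EBF",
    "formula": "FORMULA",
    "both": "MIXED",
    "mixed": "MIXED",
}


def classify_feeding(note: VisitNote, lexicon: Lexicon) -> list[FeedingObservation]:
    """Classify one note; current-status observation first, then historical
    companions. See the module docstring for the decision order."""
    comp = _CompiledLexicon.of(lexicon)
    rourke = detect_rourke_record(note.text, lexicon)

    # historical statements: capture, then mask from the working text
    companions: list[FeedingObservation] = []
    masked = note.text
    spans: list[tuple[int, int]] = []
    for rx in comp.historical:
        for m in rx.finditer(note.text):
            if any(m.start() < e and m.end() > s for s, e in spans):
                continue
            spans.append((m.start(), m.end()))
    structured_status = None
    for key in _STRUCTURED_KEYS:
        for k, v in note.structured_fields.items():
            if k.casefold() == key:
                structured_status = _STRUCTURED_MAP.get(str(v).casefold())
                break
        if structured_status:
            break
    source = (
        "rourke_structured"
        if structured_status
        else ("rourke_freetext" if rourke.detected else "progress_note")
    )
    for s, e in sorted(spans):
        frag = note.text[s:e]
        masked = masked[:s] + " " * (e - s) + masked[e:]
        m = None
        for rx in comp.historical:
            m = rx.search(frag)
            if m:
                break
        dur = parse_duration_days(m.group("num"), m.group("unit")) if m else None
        companions.append(
            FeedingObservation(
                infant_id=note.infant_id,
                age_days=note.age_days,
                status="EBF",
                tense="historical",
                historical_duration=dur,
                source=source,
                matched_terms=(" ".join(frag.split()),),
            )
        )

    if structured_status is not None:
        current = FeedingObservation(
            note.infant_id, note.age_days, structured_status,
            source=source, matched_terms=("structured:feeding",),
        )
        return [current] + companions

    feeding = _find_feeding_terms(masked, comp)
    breast, formula, mixed = feeding["breast"], feeding["formula"], feeding["mixed"]
    exclusive = _find_terms(masked, comp.exclusive, comp.negation)

    if breast and (formula or mixed):
        status, terms = "MIXED", breast + formula + mixed
    elif breast and exclusive:
        status, terms = "EBF", breast + exclusive
    elif breast:
        status, terms = "EBF", breast
    elif formula:
        status, terms = "FORMULA", formula
    else:
        status, terms = "NONE_DOCUMENTED", []
    current = FeedingObservation(
        note.infant_id, note.age_days, status,
        source=source, matched_terms=tuple(terms),
    )
    return [current] + companions


def extract_all(notes: list[VisitNote], lexicon: Lexicon) -> list[FeedingObservation]:
    """Run the classifier over a corpus, sorted per infant by age.

    Pure function of (notes, lexicon): rerunning yields identical output.
    Duplicate (infant, visit_date) notes are both processed and logged.
    """
    ordered = sorted(notes, key=lambda n: (n.infant_id, n.age_days, n.visit_date or ""))
    seen: set[tuple[str, str]] = set()
    out: list[FeedingObservation] = []
    for note in ordered:
        key = (note.infant_id, note.visit_date or f"age{note.age_days}")
        if key in seen:
            logger.warning("duplicate note for infant %s on %s", *key)
        seen.add(key)
        out.extend(classify_feeding(note, lexicon))
    return out


def observations_frame(observations: list[FeedingObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "infant_id": o.infant_id,
                "age_days": o.age_days,
                "status": o.status,
                "tense": o.tense,
                "historical_duration": o.historical_duration,
                "source": o.source,
            }
            for o in observations
        ],
        columns=OBSERVATION_COLUMNS,
    )


def observations_from_frame(df: pd.DataFrame) -> list[FeedingObservation]:
    out = []
    for row in df.itertuples(index=False):
        dur = row.historical_duration
        dur = None if pd.isna(dur) else int(dur)
        out.append(
            FeedingObservation(
                infant_id=str(row.infant_id),
                age_days=int(row.age_days),
                status=str(row.status),
                tense=str(row.tense),
                historical_duration=dur,
                source=str(row.source),
            )
        )
    return out
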