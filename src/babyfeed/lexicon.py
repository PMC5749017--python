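"""Feeding-search lexicon: load, validate, save.

The default lexicon ships with the package (``data/lexicon.yaml``) and is a
reconstruction of the kind of term list used for rule-based feeding search
in family-practice EMRs; every category is user-overridable, so no analysis
depends on the exact shipped wording.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields

import yaml

from .errors import ConfigError

CATEGORIES = (
    "rourke_variants",
    "breast_terms",
    "formula_terms",
    "mixed_markers",
    "exclusivity_markers",
    "negation_markers",
    "historical_patterns",
)


@dataclass(frozen=True)
class Lexicon:
    """Seven phrase categories driving detection and classification.

    Phrases are stored case-normalized; ``historical_patterns`` holds regular
    expressions with named groups ``num`` and ``unit``.
    """

    rourke_variants: tuple[str, ...]
    breast_terms: tuple[str, ...]
    formula_terms: tuple[str, ...]
    mixed_markers: tuple[str, ...]
    exclusivity_markers: tuple[str, ...]
    negation_markers: tuple[str, ...]
    historical_patterns: tuple[str, ...]

    def to_dict(self) -> dict[str, list[str]]:
        return {f.name: list(getattr(self, f.name)) for f in fields(self)}


def _validate(d: dict) -> Lexicon:
    if not isinstance(d, dict):
        raise ConfigError("lexicon must be a mapping of category -> phrase list")
    for cat in CATEGORIES:
        if cat not in d:
            raise ConfigError(f"lexicon is missing category: {cat}")
        val = d[cat]
        if not isinstance(val, (list, tuple)) or not val:
            raise ConfigError(f"lexicon category must be a non-empty list: {cat}")
    kwargs = {}
    for cat in CATEGORIES:
        norm = tuple(
            str(p) if cat == "historical_patterns" else " ".join(str(p).casefold().split())
            for p in d[cat]
        )
        kwargs[cat] = norm
    return Lexicon(**kwargs)


def load_lexicon(path=None) -> Lexicon:
    """Load and validate a lexicon YAML; ``None`` loads the shipped default."""
    if path is None:
        ref = importlib.resources.files("babyfeed") / "data" / "lexicon.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return _validate(yaml.safe_load(text))


def save_lexicon(lexicon: Lexicon, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(lexicon.to_dict(), fh, sort_keys=False, allow_unicode=True)
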