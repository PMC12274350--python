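"""Concept and cue lexicons: loading, validation and regex compilation.

Stem patterns use a trailing ``*`` to match any run of word characters
(``fluctuat*`` matches fluctuate, fluctuating, fluctuation ...). A
two-word pattern such as ``bad dream*`` matches the bigram with
arbitrary whitespace between the words. All matching is
case-insensitive. One concept — visual hallucinations — is defined by a
proximity rule instead: two stems that must co-occur in one sentence
within a bounded token gap.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from .types import Concept


def _stem_regex(stem: str) -> str:
    if stem.endswith("*"):
        return re.escape(stem[:-1]) + r"\w*"
    return re.escape(stem)


def compile_pattern(pattern: str) -> re.Pattern[str]:
    """Compile a (possibly multi-word) stem pattern to a word-bounded regex."""
    parts = [_stem_regex(p) for p in pattern.split()]
    return re.compile(r"\b" + r"\s+".join(parts) + r"\b", re.IGNORECASE)


@dataclass(frozen=True)
class ProximityRule:
    """Two stems that must co-occur within ``max_gap`` intervening tokens."""

    stem_a: str
    stem_b: str
    max_gap: int

    def regexes(self) -> tuple[re.Pattern[str], re.Pattern[str]]:
        return (re.compile(r"\A" + _stem_regex(self.stem_a) + r"\Z", re.IGNORECASE),
                re.compile(r"\A" + _stem_regex(self.stem_b) + r"\Z", re.IGNORECASE))


@dataclass(frozen=True)
class ConceptLexicon:
    concept: Concept
    patterns: tuple[str, ...] = ()
    proximity_rule: ProximityRule | None = None

    def __post_init__(self) -> None:
        if bool(self.patterns) == (self.proximity_rule is not None):
            raise ValueError(
                f"{self.concept.value}: exactly one of patterns / "
                "proximity_rule must be given")

    def compiled(self) -> tuple[re.Pattern[str], ...]:
        return tuple(compile_pattern(p) for p in self.patterns)


@dataclass(frozen=True)
class CueLexicon:
    """Cue phrase lists for the rule-based mention classifier."""

    negation: tuple[str, ...]
    uncertainty: tuple[str, ...]
    irrelevant: tuple[str, ...]

    def token_cues(self) -> list[tuple[tuple[str, ...], str]]:
        """All cues as lowercase token tuples paired with their sublabel."""
        out: list[tuple[tuple[str, ...], str]] = []
        for phrases, sub in ((self.negation, "negated"),
                             (self.uncertainty, "unknown"),
                             (self.irrelevant, "irrelevant")):
            for phrase in phrases:
                toks = tuple(re.findall(r"[a-z0-9]+", phrase.lower()))
                if toks:
                    out.append((toks, sub))
        return out


def load_lexicons(path: str | Path | None = None) -> dict[Concept, ConceptLexicon]:
    """Load concept lexicons from YAML (packaged defaults if no path)."""
    raw = _load_yaml(path, "lexicons.yaml")
    lexicons: dict[Concept, ConceptLexicon] = {}
    for name, spec in raw["concepts"].items():
        concept = Concept(name)
        prox = None
        if "proximity" in (spec or {}):
            stems = spec["proximity"]["stems"]
            prox = ProximityRule(stems[0], stems[1],
                                 int(spec["proximity"].get("max_gap", 5)))
        lexicons[concept] = ConceptLexicon(
            concept=concept,
            patterns=tuple((spec or {}).get("patterns", ())),
            proximity_rule=prox)
    return lexicons


def load_cues(path: str | Path | None = None) -> CueLexicon:
    """Load cue lists from YAML (packaged defaults if no path)."""
    raw = _load_yaml(path, "cues.yaml")
    return CueLexicon(negation=tuple(raw.get("negation", ())),
                      uncertainty=tuple(raw.get("uncertainty", ())),
                      irrelevant=tuple(raw.get("irrelevant", ())))


def _load_yaml(path: str | Path | None, default_name: str) -> dict:
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    ref = resources.files("dlbtext.data") / default_name
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


@lru_cache(maxsize=1)
def default_lexicons() -> dict[Concept, ConceptLexicon]:
    return load_lexicons()


@lru_cache(maxsize=1)
def default_cues() -> CueLexicon:
    return load_cues()
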