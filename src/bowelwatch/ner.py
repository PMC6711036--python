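"""Lexicon-based named entity recognition over normalized tweets.

The matcher uses *inverted* recognition: the tweet's own 1–3-grams are the
lookup keys into a large normalized lexicon, which is cheap because a tweet
holds far fewer n-grams than the lexicon holds terms. Matching prefers the
longest n-gram; a matched span consumes its tokens, so no shorter
overlapping mention can be reported. Each surface window is tried verbatim
first, then in lemmatized form; spans whose tokens came from abbreviation
expansion are flagged as abbreviation matches.

Source vocabularies roll up to five meta-categories: DOID -> Disease,
FoodOn -> Food and Diet, SYMP -> Symptom, NCIT-Intervention -> Treatment,
DrugBank -> Drug.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

from .normalize import CleanTweet, default_lemmatizer

__all__ = [
    "META_CATEGORIES",
    "SOURCE_TO_META",
    "Lexicon",
    "EntityMention",
    "map_meta_category",
    "build_lexicon",
    "recognize",
]

logger = logging.getLogger(__name__)

META_CATEGORIES = ("Disease", "Symptom", "Food and Diet", "Treatment", "Drug")

SOURCE_TO_META = {
    "DOID": "Disease",
    "FoodOn": "Food and Diet",
    "SYMP": "Symptom",
    "NCIT-Intervention": "Treatment",
    "DrugBank": "Drug",
}

MIN_TERM_CHARS = 2
MAX_TERM_CHARS = 280  # maximum tweet length

_WS_RE = re.compile(r"\s+")
_SPECIAL_TO_SPACE_RE = re.compile(r"[^0-9a-z\s]+")
_APOSTROPHE_RE = re.compile(r"['’ʼ]")


def map_meta_category(source_vocabulary: str) -> str:
    """Meta-category for a source vocabulary; unknown sources are an error."""
    try:
        return SOURCE_TO_META[source_vocabulary]
    except KeyError:
        raise ValueError(
            f"unknown source vocabulary {source_vocabulary!r}; "
            f"expected one of {sorted(SOURCE_TO_META)}"
        ) from None


@dataclass(frozen=True)
class EntityMention:
    tweet_id: str
    term: str
    meta_category: str
    token_span: tuple[int, int]  # half-open over CleanTweet.tokens
    match_kind: str = "exact"  # exact | lemma | abbreviation


@dataclass
class Lexicon:
    """Normalized term table plus a lemma-form variant index."""

    entries: dict[str, tuple[str, str, str]]  # normalized -> (canonical, source, meta)
    variants: dict[str, str]  # lemma form -> normalized canonical

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    def terms_in_category(self, meta_category: str) -> list[str]:
        return sorted(
            t for t, (_, _, meta) in self.entries.items() if meta == meta_category
        )


def _normalize_term(term: str) -> str:
    """Lowercase, squeeze whitespace, map special characters (and hyphens)
    to spaces so lexicon entries align with the tweet token stream."""
    term = term.lower()
    term = _APOSTROPHE_RE.sub("", term)
    term = _SPECIAL_TO_SPACE_RE.sub(" ", term)
    return _WS_RE.sub(" ", term).strip()


def build_lexicon(
    raw_entries: Iterable[tuple[str, str, Optional[str]]],
    lemmatizer: Callable[[str], str] = default_lemmatizer,
) -> Lexicon:
    """Normalize raw ``(term, source, category)`` rows into a matchable table.

    Normalization rules, applied in order: lowercase; collapse extra
    whitespace; drop terms shorter than 2 characters or longer than the
    maximum tweet length; replace special characters by whitespace; drop any
    normalized term attached to more than one meta-category (both entries
    are purged). The category column may be blank, in which case it is
    derived from the source vocabulary.
    """
    staged: dict[str, tuple[str, str, str]] = {}
    clashing: set[str] = set()
    n_raw = 0
    for row in raw_entries:
        n_raw += 1
        term, source = row[0], row[1]
        category = row[2] if len(row) > 2 and row[2] else None
        meta = category if category in META_CATEGORIES else map_meta_category(source)
        normalized = _normalize_term(term)
        if len(normalized) < MIN_TERM_CHARS or len(normalized) > MAX_TERM_CHARS:
            continue
        previous = staged.get(normalized)
        if previous is not None and previous[2] != meta:
            clashing.add(normalized)
        if previous is None:
            staged[normalized] = (normalized, source, meta)
    for term in clashing:  # cross-category duplicates are purged entirely
        del staged[term]
    if n_raw == 0:
        logger.warning("building a lexicon from zero raw entries")
    variants = {}
    for normalized in staged:
        lemma_form = " ".join(lemmatizer(w) for w in normalized.split())
        if lemma_form != normalized and lemma_form not in staged:
            variants.setdefault(lemma_form, normalized)
    return Lexicon(entries=staged, variants=variants)


def _lookup(
    surface: str, lemma_form: str, lexicon: Lexicon
) -> Optional[tuple[str, str, str]]:
    """Try a window verbatim, then by lemma; returns (canonical, meta, kind)."""
    hit = lexicon.entries.get(surface)
    if hit is not None:
        return hit[0], hit[2], "exact"
    canonical = lexicon.variants.get(surface) or lexicon.variants.get(lemma_form)
    if canonical is None and lemma_form != surface:
        direct = lexicon.entries.get(lemma_form)
        if direct is not None:
            canonical = lemma_form
    if canonical is not None:
        entry = lexicon.entries[canonical]
        return entry[0], entry[2], "lemma"
    return None


def recognize(
    clean: CleanTweet,
    lexicon: Lexicon,
    max_n: int = 3,
    allow_overlap: bool = False,
) -> list[EntityMention]:
    """Longest-first inverted dictionary matching over content tokens.

    Windows are tried from trigrams down to unigrams, left to right; a match
    consumes its token positions unless ``allow_overlap`` is set. Output is
    sorted by span start.
    """
    tokens = clean.tokens
    if not tokens:
        return []
    surfaces = [t.surface for t in tokens]
    lemmas = [t.lemma for t in tokens]
    consumed = [False] * len(tokens)
    mentions: list[EntityMention] = []
    for n in range(min(max_n, len(tokens)), 0, -1):
        for start in range(0, len(tokens) - n + 1):
            span = range(start, start + n)
            if not allow_overlap and any(consumed[i] for i in span):
                continue
            surface = " ".join(surfaces[start : start + n])
            lemma_form = " ".join(lemmas[start : start + n])
            hit = _lookup(surface, lemma_form, lexicon)
            if hit is None:
                continue
            canonical, meta, kind = hit
            if any(tokens[i].origin == "abbrev" for i in span):
                kind = "abbreviation"
            mentions.append(
                EntityMention(
                    tweet_id=clean.id,
                    term=canonical,
                    meta_category=meta,
                    token_span=(start, start + n),
                    match_kind=kind,
                )
            )
            if not allow_overlap:
                for i in span:
                    consumed[i] = True
    mentions.sort(key=lambda m: (m.token_span[0], m.token_span[1]))
    return mentions
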