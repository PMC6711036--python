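"""User characterization: gender, account type, and geolocation.

Three independent inferences per account:

* **Gender** — two-step strategy: a gender-name dictionary lookup on the
  first token of the display name; if the name is absent or ambiguous, a
  pluggable profile-image classifier is consulted (``no-face`` or no image
  at all resolves to ``unknown``).
* **Account type** — a fixed rule cascade. Organization evidence is checked
  first (country/continent token in the name, URL domain in the name,
  non-personal keywords in the description). Only accounts with no
  organization evidence are tested against the individual rules (resolved
  gender, contributor/translator flag, first-person pronouns, emoji or
  emoticons, person abbreviations); individuals carrying expert keywords
  (Dr, Prof, MD, PhD, ...) become ``expert``, the rest ``patient``.
* **Location** — free-text location matched against a gazetteer, with time
  zone and UTC offset used to break ties between same-name cities; a tie
  that survives both filters across different countries stays unresolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import Callable, Iterable, Mapping, Optional

import yaml

from .normalize import _ASCII_EMOTICON_RE, _EMOJI_RE

__all__ = [
    "UserRecord",
    "UserProfile",
    "GazetteerEntry",
    "KeywordConfig",
    "Gazetteer",
    "NameGenderTable",
    "UserProfiler",
    "infer_gender",
    "classify_account",
    "resolve_location",
    "load_default_keywords",
]

GENDERS = ("female", "male", "unknown")
ACCOUNT_TYPES = ("organization", "patient", "expert", "unknown")

_TOKEN_RE = re.compile(r"[a-z0-9]+")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class UserRecord:
    screen_name: str
    display_name: str = ""
    description: str = ""
    location_text: Optional[str] = None
    time_zone: Optional[str] = None
    utc_offset: Optional[int] = None
    has_profile_image: bool = False
    is_contributor_or_translator: bool = False
    profile_image_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.screen_name:
            raise ValueError("screen_name must be non-empty")


@dataclass
class UserProfile:
    screen_name: str
    gender: str = "unknown"
    account_type: str = "unknown"
    location: Optional[tuple[str, str, str]] = None  # (city, country, continent)
    matched_rule: str = "none"


@dataclass(frozen=True)
class GazetteerEntry:
    name: str
    country: str
    continent: str
    time_zone: str
    utc_offset: int


@dataclass
class KeywordConfig:
    """Editable keyword lists behind the account-type cascade."""

    nonpersonal: frozenset[str]
    first_person_pronouns: frozenset[str]
    person_abbreviations: frozenset[str]
    expert: frozenset[str]
    url_domains: tuple[str, ...]
    country_codes: frozenset[str]

    @classmethod
    def from_mapping(cls, data: Mapping) -> "KeywordConfig":
        return cls(
            nonpersonal=frozenset(map(str.lower, data.get("nonpersonal", ()))),
            first_person_pronouns=frozenset(
                map(str.lower, data.get("first_person_pronouns", ()))
            ),
            person_abbreviations=frozenset(
                map(str.lower, data.get("person_abbreviations", ()))
            ),
            expert=frozenset(map(str.lower, data.get("expert", ()))),
            url_domains=tuple(map(str.lower, data.get("url_domains", ()))),
            country_codes=frozenset(map(str.lower, data.get("country_codes", ()))),
        )

    @classmethod
    def from_yaml(cls, path) -> "KeywordConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def load_default_keywords() -> KeywordConfig:
    ref = _importlib_resources.files("bowelwatch.resources") / "keywords.yaml"
    return KeywordConfig.from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


class NameGenderTable:
    """First-name -> gender lookup with an explicit ambiguity flag."""

    def __init__(self, entries: Iterable[tuple[str, str, bool]]) -> None:
        self._table: dict[str, tuple[str, bool]] = {}
        for name, gender, ambiguous in entries:
            self._table[name.lower()] = (gender, bool(ambiguous))

    def lookup(self, first_name: str) -> Optional[str]:
        """Return a gender only on a unique (non-ambiguous) match."""
        hit = self._table.get(first_name.lower())
        if hit is None:
            return None
        gender, ambiguous = hit
        if ambiguous or gender not in ("female", "male"):
            return None
        return gender


class Gazetteer:
    """Name-indexed city table used for location disambiguation."""

    def __init__(self, entries: Iterable[GazetteerEntry]) -> None:
        self.entries = list(entries)
        seen = set()
        for e in self.entries:
            key = (e.name.lower(), e.country)
            if key in seen:
                raise ValueError(f"duplicate gazetteer entry {key}")
            seen.add(key)
        self._by_name: dict[str, list[GazetteerEntry]] = {}
        for e in self.entries:
            self._by_name.setdefault(e.name.lower(), []).append(e)

    def lookup(self, name: str) -> list[GazetteerEntry]:
        return list(self._by_name.get(name.lower().strip(), ()))

    @property
    def countries(self) -> frozenset[str]:
        return frozenset(e.country for e in self.entries)

    @property
    def continents(self) -> frozenset[str]:
        return frozenset(e.continent for e in self.entries)


# ---------------------------------------------------------------------------
# operations


def _tokens(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def infer_gender(
    display_name: str,
    has_profile_image: bool,
    name_table: NameGenderTable,
    image_classifier: Optional[Callable[[Optional[str]], str]] = None,
    image_ref: Optional[str] = None,
) -> str:
    """Two-step gender inference: name dictionary, then image classifier.

    The dictionary is consulted with the first whitespace-delimited token of
    the display name. The classifier contract is ``image-ref ->
    {"female", "male", "no-face"}``.
    """
    parts = display_name.split()
    if parts:
        gender = name_table.lookup(parts[0])
        if gender is not None:
            return gender
    if has_profile_image and image_classifier is not None:
        verdict = image_classifier(image_ref)
        if verdict in ("female", "male"):
            return verdict
    return "unknown"


def _has_emoji_or_emoticon(text: str) -> bool:
    if _EMOJI_RE.search(text):
        return True
    return any(_ASCII_EMOTICON_RE.match(tok) for tok in text.split())


def classify_account(
    user: UserRecord,
    gender: str,
    keywords: KeywordConfig,
    geo_names: frozenset[str] = frozenset(),
) -> tuple[str, str]:
    """Rule cascade deciding organization / patient / expert / unknown.

    ``geo_names`` holds lowercase country and continent names used by the
    first organization rule. Returns ``(account_type, matched_rule)``; the
    audit tag names the first rule that fired.
    """
    name_tokens = _tokens(user.display_name)
    desc_lower = user.description.lower()
    desc_tokens = _tokens(desc_lower)

    # organization evidence, in cascade order
    geo_or_code = geo_names | keywords.country_codes
    if any(tok in geo_or_code for tok in name_tokens):
        return "organization", "org:geo-token-in-name"
    if any(dom in user.display_name.lower() for dom in keywords.url_domains):
        return "organization", "org:url-domain-in-name"
    if any(tok in keywords.nonpersonal for tok in desc_tokens):
        return "organization", "org:nonpersonal-keyword"

    # individual evidence, in cascade order
    individual_rule = None
    if gender in ("female", "male"):
        individual_rule = "ind:gender"
    elif user.is_contributor_or_translator:
        individual_rule = "ind:contributor-flag"
    elif any(tok in keywords.first_person_pronouns for tok in desc_tokens):
        individual_rule = "ind:first-person"
    elif _has_emoji_or_emoticon(user.description):
        individual_rule = "ind:emoji"
    elif any(tok in keywords.person_abbreviations for tok in desc_tokens):
        individual_rule = "ind:person-abbrev"

    if individual_rule is None:
        return "unknown", "none"

    # experts are individuals carrying expert keywords
    if any(tok in keywords.expert for tok in desc_tokens) or any(
        tok in keywords.expert for tok in name_tokens
    ):
        return "expert", individual_rule + "+expert-keyword"
    return "patient", individual_rule


def resolve_location(
    location_text: Optional[str],
    time_zone: Optional[str],
    utc_offset: Optional[int],
    gazetteer: Gazetteer,
    aliases: Optional[Mapping[str, str]] = None,
) -> Optional[tuple[str, str, str]]:
    """Match free-text location against the gazetteer.

    Ambiguous names are narrowed by time zone and then UTC offset; a filter
    is applied only when it leaves at least one candidate. Same-name
    same-zone cities in different countries stay unresolved.
    """
    if not location_text or not location_text.strip():
        return None
    query = location_text.strip().lower()
    if aliases:
        query = aliases.get(query, query)
    candidates = gazetteer.lookup(query)
    if not candidates:
        return None
    if len(candidates) > 1 and time_zone:
        narrowed = [e for e in candidates if e.time_zone == time_zone]
        if narrowed:
            candidates = narrowed
    if len(candidates) > 1 and utc_offset is not None:
        narrowed = [e for e in candidates if e.utc_offset == utc_offset]
        if narrowed:
            candidates = narrowed
    if len(candidates) != 1:
        return None  # still ambiguous across countries -> unknown
    hit = candidates[0]
    return hit.name, hit.country, hit.continent


# ---------------------------------------------------------------------------
# facade


def _default_image_classifier(image_ref: Optional[str]) -> str:
    """Deterministic stub honouring the ``synthetic://face/<gender>/...``
    scheme used by the synthetic corpus; anything else reports no face."""
    if image_ref and image_ref.startswith("synthetic://face/"):
        gender = image_ref.split("/")[3]
        if gender in ("female", "male"):
            return gender
    return "no-face"


class UserProfiler:
    """Bundles the three inferences behind one call per user."""

    def __init__(
        self,
        name_table: NameGenderTable,
        gazetteer: Gazetteer,
        keywords: Optional[KeywordConfig] = None,
        image_classifier: Optional[Callable[[Optional[str]], str]] = None,
        aliases: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.name_table = name_table
        self.gazetteer = gazetteer
        self.keywords = keywords or load_default_keywords()
        self.image_classifier = image_classifier or _default_image_classifier
        self.aliases = {k.lower(): v.lower() for k, v in (aliases or {}).items()}
        self._geo_names = frozenset(
            n.lower() for n in (self.gazetteer.countries | self.gazetteer.continents)
        )

    def profile(self, user: UserRecord) -> UserProfile:
        gender = infer_gender(
            user.display_name,
            user.has_profile_image,
            self.name_table,
            self.image_classifier,
            image_ref=user.profile_image_ref,
        )
        account_type, rule = classify_account(
            user, gender, self.keywords, geo_names=self._geo_names
        )
        location = resolve_location(
            user.location_text,
            user.time_zone,
            user.utc_offset,
            self.gazetteer,
            aliases=self.aliases,
        )
        return UserProfile(
            screen_name=user.screen_name,
            gender=gender,
            account_type=account_type,
            location=location,
            matched_rule=rule,
        )
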