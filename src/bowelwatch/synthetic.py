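"""Synthetic tweet corpus with planted ground truth.

The generator emulates the structure of a harvested bowel-disease tweet
corpus — JSON-lines records with a Twitter-API-v1.1-style field subset —
together with every auxiliary fixture the pipeline needs (gazetteer,
gender-name table, abbreviation and spelling dictionaries, five-category
term lexicon, valence lexicon). Every latent property is recorded as ground
truth so each downstream stage's recovery is measurable:

* user accounts are built to satisfy *exactly* the classification-cascade
  rule of their true type (organizations carry "official"/"news"/".org"/
  country cues, patients first-person descriptions, experts additionally
  "Dr"/"MD" cues);
* tweet text is assembled from templates — a polarity-bearing clause, the
  planted lexicon terms separated by neutral filler words, and optional
  hashtags, user mentions and URLs — so ground-truth alignment is exact;
* a configurable fraction of planted term tokens is perturbed by one edit
  whose unique nearest dictionary suggestion is the original token, so the
  spelling-correction stage can provably recover it;
* tweets inside the event window get interaction counts scaled by the
  event multiplier, mimicking an awareness-day surge.

Defaults mirror the reference study conditions: a seven-month window
(2018-02-01 .. 2018-08-31), 24,634 tweets from 13,295 users, ~4.1%
non-English records, a 58.6% patient share, the printed patient gender
shares, sentiment shares renormalized from the printed patient-tweet
polarity counts, and a May–June event window with tripled interactions.

The generator is fully deterministic given the config seed: the same
configuration yields byte-identical JSONL output.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional

from .ner import META_CATEGORIES, Lexicon, build_lexicon
from .normalize import DictionarySuggester, correct_spelling
from .profiler import GazetteerEntry

__all__ = [
    "ConfigurationError",
    "SyntheticConfig",
    "GroundTruth",
    "Fixtures",
    "generate_fixtures",
    "generate_corpus",
    "corpus_to_jsonl",
    "write_outputs",
]

USER_TYPES = ("organization", "patient", "expert", "unknown")
GENDERS = ("female", "male", "unknown")
SENTIMENTS = ("negative", "neutral", "positive")


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


def _check_proportions(name: str, mix: dict, keys: tuple[str, ...]) -> None:
    if set(mix) != set(keys):
        raise ConfigurationError(f"{name} must have keys {keys}, got {sorted(mix)}")
    if any(v < 0 for v in mix.values()):
        raise ConfigurationError(f"{name} proportions must be non-negative")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} proportions must sum to 1")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic corpus."""

    n_tweets: int = 24634
    n_users: int = 13295
    date_range: tuple[str, str] = ("2018-02-01T00:00:00Z", "2018-08-31T23:59:59Z")
    frac_non_english: float = 0.041
    user_type_mix: dict = field(
        default_factory=lambda: {
            "organization": 0.12,
            "patient": 0.5863,
            "expert": 0.08,
            "unknown": 0.2137,
        }
    )
    gender_mix: dict = field(
        default_factory=lambda: {"female": 0.3592, "male": 0.4951, "unknown": 0.1457}
    )
    # mean planted lexicon mentions per tweet per meta-category
    mention_rate_per_category: dict = field(
        default_factory=lambda: {
            "Disease": 0.47,
            "Food and Diet": 0.34,
            "Symptom": 0.24,
            "Treatment": 0.20,
            "Drug": 0.085,
        }
    )
    misspell_rate: float = 0.05
    sentiment_mix: dict = field(
        default_factory=lambda: {"negative": 0.5306, "neutral": 0.1428, "positive": 0.3266}
    )
    event_window: Optional[tuple[str, str]] = ("2018-05-01T00:00:00Z", "2018-06-30T23:59:59Z")
    interaction_multiplier: float = 3.0
    tweets_per_user_rate: float = 0.35  # long-tail author weight parameter
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_tweets <= 0 or self.n_users <= 0:
            raise ConfigurationError("n_tweets and n_users must be positive")
        start, end = (_parse_iso(t) for t in self.date_range)
        if not start < end:
            raise ConfigurationError("date_range start must precede end")
        for rate_name in ("frac_non_english", "misspell_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{rate_name} must lie in [0, 1]")
        _check_proportions("user_type_mix", self.user_type_mix, USER_TYPES)
        _check_proportions("gender_mix", self.gender_mix, GENDERS)
        _check_proportions("sentiment_mix", self.sentiment_mix, SENTIMENTS)
        for cat, rate in self.mention_rate_per_category.items():
            if cat not in META_CATEGORIES or rate < 0:
                raise ConfigurationError(f"bad mention rate for {cat!r}")
        if self.event_window is not None and self.interaction_multiplier < 1:
            raise ConfigurationError("interaction_multiplier must be >= 1")
        return self


@dataclass
class GroundTruth:
    """Planted latent state: per-user and per-tweet truths."""

    users: dict = field(default_factory=dict)
    # screen_name -> {"type", "gender", "country"}
    tweets: dict = field(default_factory=dict)
    # tweet_id -> {"lang", "mentions": [(term, category)], "polarity",
    #              "misspellings": {original: perturbed}}

    def to_json(self) -> str:
        return json.dumps(
            {"users": self.users, "tweets": self.tweets}, sort_keys=True, indent=1
        )


# ---------------------------------------------------------------------------
# fixtures


_GAZETTEER_ROWS = [
    # (name, country, continent, time_zone, utc_offset_seconds)
    ("Guadalajara", "Spain", "Europe", "Europe/Madrid", 3600),
    ("Guadalajara", "Mexico", "America", "America/Mexico_City", -21600),
    # same name, same zone, different countries: must resolve to unknown
    ("Springfield", "United States", "America", "America/New_York", -18000),
    ("Springfield", "Canada", "America", "America/New_York", -18000),
    ("New York City", "United States", "America", "America/New_York", -18000),
    ("Chicago", "United States", "America", "America/Chicago", -21600),
    ("London", "United Kingdom", "Europe", "Europe/London", 0),
    ("Manchester", "United Kingdom", "Europe", "Europe/London", 0),
    ("Dublin", "Ireland", "Europe", "Europe/Dublin", 0),
    ("Toronto", "Canada", "America", "America/Toronto", -18000),
    ("Vancouver", "Canada", "America", "America/Vancouver", -28800),
    ("Sydney", "Australia", "Australia", "Australia/Sydney", 36000),
    ("Melbourne", "Australia", "Australia", "Australia/Sydney", 36000),
    ("Perth", "Australia", "Australia", "Australia/Perth", 28800),
    ("Mumbai", "India", "Asia", "Asia/Kolkata", 19800),
    ("Dhaka", "Bangladesh", "Asia", "Asia/Dhaka", 21600),
    ("Manila", "Philippines", "Asia", "Asia/Manila", 28800),
    ("Cape Town", "South Africa", "Africa", "Africa/Johannesburg", 7200),
]

_ALIASES = {"nyc": "new york city"}

_FEMALE_NAMES = [
    "Mary", "Alice", "Emma", "Olivia", "Sophia", "Isabella",
    "Grace", "Lily", "Chloe", "Hannah", "Nora", "Ruth",
]
_MALE_NAMES = [
    "John", "David", "Michael", "James", "Robert", "Liam",
    "Noah", "Henry", "Samuel", "Peter", "George", "Oscar",
]
_AMBIGUOUS_NAMES = ["Alex", "Sam", "Taylor", "Jordan", "Casey", "Riley", "Morgan"]
_SURNAMES = [
    "Smith", "Jones", "Brown", "Wilson", "Moore", "Clark", "Hall",
    "Young", "King", "Wright", "Scott", "Green", "Baker", "Adams", "Hill",
]

_ABBREVIATIONS = {
    "sbbos": "small bowel bacterial overgrowth syndrome",
    "ibs": "irritable bowel syndrome",
    "ibd": "inflammatory bowel disease",
    "uc": "ulcerative colitis",
    "gf": "gluten free",
}

_LEXICON_RAW = [
    # Disease (DOID) — nested pair: bigram inside trigram
    ("bowel disease", "DOID", "Disease"),
    ("inflammatory bowel disease", "DOID", "Disease"),
    ("irritable bowel syndrome", "DOID", "Disease"),
    ("crohn disease", "DOID", "Disease"),
    ("ulcerative colitis", "DOID", "Disease"),
    ("celiac disease", "DOID", "Disease"),
    ("diarrhea", "DOID", "Disease"),
    ("constipation", "DOID", "Disease"),
    ("cancer", "DOID", "Disease"),
    ("anxiety disorder", "DOID", "Disease"),
    ("depression", "DOID", "Disease"),
    ("fibromyalgia", "DOID", "Disease"),
    ("arthritis", "DOID", "Disease"),
    ("asthma", "DOID", "Disease"),
    ("obesity", "DOID", "Disease"),
    # Symptom (SYMP) — nested pair: "abdominal pain" in "chronic abdominal pain"
    ("pain", "SYMP", "Symptom"),
    ("abdominal pain", "SYMP", "Symptom"),
    ("chronic abdominal pain", "SYMP", "Symptom"),
    ("bloating", "SYMP", "Symptom"),
    ("flatulence", "SYMP", "Symptom"),
    ("fatigue", "SYMP", "Symptom"),
    ("nausea", "SYMP", "Symptom"),
    ("cramping", "SYMP", "Symptom"),
    # Food and Diet (FoodOn) — nested pair: "gluten free" in "gluten free diet"
    ("gluten", "FoodOn", "Food and Diet"),
    ("gluten free", "FoodOn", "Food and Diet"),
    ("gluten free diet", "FoodOn", "Food and Diet"),
    ("probiotic", "FoodOn", "Food and Diet"),
    ("dietary supplement", "FoodOn", "Food and Diet"),
    ("fiber", "FoodOn", "Food and Diet"),
    ("magnesium", "FoodOn", "Food and Diet"),
    ("vitamin d", "FoodOn", "Food and Diet"),
    # Treatment (NCIT interventions) — nested pair
    ("surgery", "NCIT-Intervention", "Treatment"),
    ("resection surgery", "NCIT-Intervention", "Treatment"),
    ("bowel resection surgery", "NCIT-Intervention", "Treatment"),
    ("hypnotherapy", "NCIT-Intervention", "Treatment"),
    ("colonoscopy", "NCIT-Intervention", "Treatment"),
    ("acupuncture", "NCIT-Intervention", "Treatment"),
    # Drug (DrugBank) — nested pair
    ("medical cannabis", "DrugBank", "Drug"),
    ("medical cannabis oil", "DrugBank", "Drug"),
    ("cannabidiol", "DrugBank", "Drug"),
    ("loperamide", "DrugBank", "Drug"),
    ("lactulose", "DrugBank", "Drug"),
    ("L-Glutamine", "DrugBank", "Drug"),
    ("prednisone", "DrugBank", "Drug"),
    ("mesalamine", "DrugBank", "Drug"),
    # deliberately cross-listed term: must be purged by lexicon building
    ("ginger", "FoodOn", "Food and Diet"),
    ("ginger", "DrugBank", "Drug"),
]

_VALENCE = {
    "grateful": 2.0, "wonderful": 2.4, "happy": 1.9, "amazing": 2.5,
    "relieved": 1.6, "good": 1.9, "thankful": 1.8, "hopeful": 1.7,
    "awful": -2.1, "terrible": -2.3, "miserable": -2.4, "sad": -1.8,
    "exhausted": -1.5, "horrible": -2.5, "frustrated": -1.9, "worse": -1.6,
}

_NEG_CLAUSES = [
    ["feeling", "{neg}", "and", "{neg2}", "today"],
    ["another", "{neg}", "flare", "this", "week"],
    ["honestly", "{neg}", "and", "{neg2}", "again"],
]
_POS_CLAUSES = [
    ["so", "{pos}", "and", "{pos2}", "today"],
    ["feeling", "{pos}", "after", "this", "week"],
    ["really", "{pos}", "and", "{pos2}", "news"],
]
_NEU_CLAUSES = [
    ["sharing", "todays", "journal", "update"],
    ["weekly", "thread", "for", "the", "community"],
    ["posting", "a", "short", "note", "tonight"],
]

_FILLERS = [
    "today", "morning", "evening", "update", "journal",
    "thread", "posting", "note", "entry", "week",
]

_EXTRA_DICT_WORDS = [
    "feeling", "another", "flare", "this", "honestly", "again", "after",
    "really", "news", "sharing", "todays", "weekly", "community", "short",
    "tonight", "gut", "health", "ask", "about", "living", "with", "sharing",
    "advice", "daily", "supporting",
]

_DECORATIVE_HASHTAGS = ["IBDAwareness", "gutHealth2018", "BowelDisease"]

_URL_POOL = [
    "https://guts4life.example/portal",
    "https://news.example/ibs-article",
    "https://nature.example/microbiome-paper",
    "https://bmj.example/ibd-study",
    "https://health.example/crohns-guide",
    "https://blog.example/gluten-free-living",
    "https://shop.example/cannabis-products",
    "https://science.example/probiotic-trial",
]

_NON_ENGLISH = {
    "es": "hola amigos hoy hablamos de salud intestinal y bienestar",
    "fr": "bonjour a tous nous parlons de sante intestinale aujourdhui",
    "it": "ciao a tutti oggi parliamo di salute intestinale",
}


@dataclass
class Fixtures:
    """Auxiliary lookup tables shipped alongside the corpus."""

    gazetteer: list[GazetteerEntry]
    aliases: dict
    name_gender: list[tuple[str, str, bool]]  # (name, gender, ambiguous)
    abbreviations: dict
    spelling_dictionary: set
    lexicon_raw: list[tuple[str, str, str]]
    valence: dict

    def build_lexicon(self) -> Lexicon:
        return build_lexicon(self.lexicon_raw)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(
            out / "gazetteer.tsv",
            ["name", "country", "continent", "time_zone", "utc_offset"],
            [(e.name, e.country, e.continent, e.time_zone, e.utc_offset) for e in self.gazetteer],
        )
        _write_tsv(
            out / "aliases.tsv", ["alias", "name"], sorted(self.aliases.items())
        )
        _write_tsv(
            out / "name_gender.tsv",
            ["name", "gender", "ambiguous"],
            [(n, g, int(a)) for n, g, a in self.name_gender],
        )
        _write_tsv(
            out / "abbreviations.tsv",
            ["abbreviation", "expansion"],
            sorted(self.abbreviations.items()),
        )
        _write_tsv(
            out / "spelling_dictionary.tsv",
            ["word"],
            [(w,) for w in sorted(self.spelling_dictionary)],
        )
        _write_tsv(
            out / "lexicon.tsv", ["term", "source", "category"], self.lexicon_raw
        )
        _write_tsv(
            out / "valence.tsv", ["term", "valence"], sorted(self.valence.items())
        )


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def generate_fixtures(config: SyntheticConfig) -> Fixtures:
    """Deterministic fixture tables for a validated configuration."""
    config.validate()
    dictionary: set[str] = set()
    for term, _, _ in _LEXICON_RAW:
        for word in term.lower().replace("-", " ").split():
            if word.isalpha() and len(word) >= 2:
                dictionary.add(word)
    for expansion in _ABBREVIATIONS.values():
        dictionary.update(expansion.split())
    dictionary.update(_VALENCE)
    dictionary.update(_FILLERS)
    dictionary.update(w for w in _EXTRA_DICT_WORDS if w.isalpha())
    name_gender = (
        [(n, "female", False) for n in _FEMALE_NAMES]
        + [(n, "male", False) for n in _MALE_NAMES]
        + [(n, "female", True) for n in _AMBIGUOUS_NAMES]
    )
    return Fixtures(
        gazetteer=[GazetteerEntry(*row) for row in _GAZETTEER_ROWS],
        aliases=dict(_ALIASES),
        name_gender=name_gender,
        abbreviations=dict(_ABBREVIATIONS),
        spelling_dictionary=dictionary,
        lexicon_raw=list(_LEXICON_RAW),
        valence=dict(_VALENCE),
    )


# ---------------------------------------------------------------------------
# corpus generation helpers


def _parse_iso(value: str) -> datetime:
    return datetime.fromisoformat(value.replace("Z", "+00:00")).astimezone(timezone.utc)


def _iso(dt: datetime) -> str:
    return dt.strftime("%Y-%m-%dT%H:%M:%SZ")


def _poisson(rng: random.Random, mean: float) -> int:
    """Knuth sampler; fine for the small means used here."""
    if mean <= 0:
        return 0
    threshold = math.exp(-mean)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= threshold:
            return k
        k += 1


def _weighted_draw(rng: random.Random, items: list, weights: dict) -> object:
    r = rng.random()
    acc = 0.0
    for item in items:
        acc += weights[item]
        if r < acc:
            return item
    return items[-1]


def _perturb_token(
    rng: random.Random,
    token: str,
    dictionary: frozenset,
    suggester: DictionarySuggester,
) -> Optional[str]:
    """One random edit whose best spelling suggestion is the original."""
    for _ in range(12):
        op = rng.choice(("delete", "double", "swap"))
        pos = rng.randrange(len(token))
        if op == "delete" and len(token) > 4:
            candidate = token[:pos] + token[pos + 1 :]
        elif op == "double":
            candidate = token[:pos] + token[pos] + token[pos:]
        elif op == "swap" and pos < len(token) - 1 and token[pos] != token[pos + 1]:
            candidate = (
                token[:pos] + token[pos + 1] + token[pos] + token[pos + 2 :]
            )
        else:
            continue
        if candidate == token or candidate in dictionary:
            continue
        if correct_spelling(candidate, dictionary, suggester) == token:
            return candidate
    return None


# ---------------------------------------------------------------------------
# user construction


def _make_users(
    rng: random.Random, config: SyntheticConfig, fixtures: Fixtures
) -> tuple[list[dict], GroundTruth]:
    truth = GroundTruth()
    users: list[dict] = []
    geo_single_tokens = ["UK", "USA", "Canada", "Australia", "India", "Ireland", "Europe", "Asia"]
    org_prefixes = ["IBD Support", "Colitis Care", "Gut Wellness", "Digestive Health"]
    loc_resolvable = [
        e for e in fixtures.gazetteer
        if e.name not in ("Guadalajara", "Springfield")
    ]
    guadalajara_mx = next(
        e for e in fixtures.gazetteer if e.name == "Guadalajara" and e.country == "Mexico"
    )
    springfield = next(e for e in fixtures.gazetteer if e.name == "Springfield")
    nyc = next(e for e in fixtures.gazetteer if e.name == "New York City")

    for i in range(config.n_users):
        screen_name = f"u{i:05d}"
        utype = _weighted_draw(rng, list(USER_TYPES), config.user_type_mix)
        gender = "unknown"
        display_name = ""
        description = ""
        has_image = False
        image_ref = None
        is_translator = False

        if utype == "organization":
            cue = rng.choice(("geo", "url", "keyword"))
            if cue == "geo":
                display_name = f"{rng.choice(org_prefixes)} {rng.choice(geo_single_tokens)}"
                description = "Supporting the community since 2010."
            elif cue == "url":
                display_name = f"{rng.choice(org_prefixes).replace(' ', '')}.org"
                description = "Resources for the community."
            else:
                display_name = f"{rng.choice(org_prefixes)} Daily"
                description = "Official news and info about bowel conditions."
        elif utype in ("patient", "expert"):
            gender = _weighted_draw(rng, list(GENDERS), config.gender_mix)
            surname = rng.choice(_SURNAMES)
            if gender in ("female", "male"):
                if rng.random() < 0.7:
                    first = rng.choice(_FEMALE_NAMES if gender == "female" else _MALE_NAMES)
                    has_image = rng.random() < 0.5
                    image_ref = f"synthetic://face/{gender}/{i}" if has_image else None
                else:  # ambiguous name, resolved through the profile image
                    first = rng.choice(_AMBIGUOUS_NAMES)
                    has_image = True
                    image_ref = f"synthetic://face/{gender}/{i}"
            else:
                first = rng.choice(_AMBIGUOUS_NAMES)
                has_image = rng.random() < 0.3
                image_ref = f"synthetic://noface/{i}" if has_image else None
            display_name = f"{first} {surname}"
            if utype == "patient":
                description = rng.choice(
                    [
                        "I am living with crohns and sharing my journey",
                        "my gut story matters and I post about flares",
                        "we fight colitis together in my family",
                    ]
                )
                if rng.random() < 0.3:
                    description += " \U0001f4aa"
                is_translator = rng.random() < 0.05
            else:
                description = rng.choice(
                    [
                        "I am a Dr and gastroenterologist sharing advice",
                        "MD focused on bowel conditions and my research work",
                        "I work as a dietitian helping my patients with diets",
                    ]
                )
        else:  # unknown type: nothing for any rule to latch on to
            display_name = rng.choice(["BD Observer", "Quiet Account", "Reader 42"])
            description = rng.choice(["", "Posts about digestion.", "Occasional reposts."])

        # location scenario, independent of account type
        location_text: Optional[str] = None
        time_zone_: Optional[str] = None
        utc_offset: Optional[int] = None
        country: Optional[str] = None
        # scenario mix tuned so ~60% of users carry a resolvable location,
        # mirroring the geolocated share of the emulated study population
        draw = rng.random()
        if draw < 0.50:
            entry = rng.choice(loc_resolvable)
            location_text = entry.name
            time_zone_, utc_offset, country = entry.time_zone, entry.utc_offset, entry.country
        elif draw < 0.55:
            location_text = "NYC"
            time_zone_, utc_offset, country = nyc.time_zone, nyc.utc_offset, nyc.country
        elif draw < 0.60:  # ambiguous, resolvable via time zone
            location_text = "Guadalajara"
            time_zone_ = guadalajara_mx.time_zone
            utc_offset = guadalajara_mx.utc_offset
            country = guadalajara_mx.country
        elif draw < 0.63:  # ambiguous across countries within one zone: unknown
            location_text = "Springfield"
            time_zone_, utc_offset = springfield.time_zone, springfield.utc_offset
            country = None
        elif draw < 0.70:
            location_text = rng.choice(["the moon", "everywhere", "my couch"])
            country = None

        users.append(
            {
                "screen_name": screen_name,
                "name": display_name,
                "description": description,
                "location": location_text,
                "time_zone": time_zone_,
                "utc_offset": utc_offset,
                "profile_image_url": image_ref,
                "is_translator": is_translator,
            }
        )
        truth.users[screen_name] = {
            "type": utype,
            "gender": gender if utype in ("patient", "expert") else "unknown",
            "country": country,
        }
    return users, truth


# ---------------------------------------------------------------------------
# tweet construction


def _assemble_text(
    rng: random.Random,
    config: SyntheticConfig,
    lexicon: Lexicon,
    terms_by_category: dict[str, list[str]],
    dictionary: frozenset,
    suggester: DictionarySuggester,
    mention_targets: list[str],
) -> tuple[str, dict]:
    polarity = _weighted_draw(rng, list(SENTIMENTS), config.sentiment_mix)
    negs = rng.sample([w for w, v in _VALENCE.items() if v < 0], 2)
    poss = rng.sample([w for w, v in _VALENCE.items() if v > 0], 2)
    clause = rng.choice(
        {"negative": _NEG_CLAUSES, "positive": _POS_CLAUSES, "neutral": _NEU_CLAUSES}[polarity]
    )
    words = [
        w.format(neg=negs[0], neg2=negs[1], pos=poss[0], pos2=poss[1]) for w in clause
    ]
    if rng.random() < 0.08:
        words.append(rng.choice(["\U0001f62b", "\U0001f64f", "\U0001f4aa"]))

    planted: list[tuple[str, str]] = []
    misspellings: dict[str, str] = {}
    for category in META_CATEGORIES:
        rate = config.mention_rate_per_category.get(category, 0.0)
        pool = terms_by_category[category]
        count = min(_poisson(rng, rate), len(pool))
        for term in rng.sample(pool, count):
            planted.append((term, category))
            term_words = term.split()
            if rng.random() < config.misspell_rate:
                candidates = [w for w in term_words if len(w) >= 5]
                if candidates:
                    target = max(candidates, key=len)
                    perturbed = _perturb_token(rng, target, dictionary, suggester)
                    if perturbed is not None:
                        term_words = [
                            perturbed if w == target else w for w in term_words
                        ]
                        misspellings[target] = perturbed
            words.append(rng.choice(_FILLERS))
            words.extend(term_words)

    hashtags: list[str] = []
    if planted and rng.random() < 0.25:
        term = rng.choice(planted)[0]
        hashtags.append("".join(w.capitalize() for w in term.split()))
    if rng.random() < 0.10:
        hashtags.append(rng.choice(_DECORATIVE_HASHTAGS))
    mentions: list[str] = []
    if mention_targets and rng.random() < 0.25:
        mentions = rng.sample(mention_targets, min(len(mention_targets), rng.choice((1, 1, 2))))
    urls: list[str] = []
    if rng.random() < 0.15:
        urls.append(rng.choice(_URL_POOL))

    def render() -> str:
        parts = [f"@{m}" for m in mentions] + words
        parts += [f"#{h}" for h in hashtags] + urls
        return " ".join(parts)

    text = render()
    while len(text) > 280:
        if hashtags:
            hashtags.pop()
        elif urls:
            urls.pop()
        elif planted:
            term, _ = planted.pop()
            # drop the trailing "filler + term words" block and any
            # misspelling recorded for that term
            words = words[: len(words) - (len(term.split()) + 1)]
            for w in term.split():
                misspellings.pop(w, None)
        else:
            words = words[:3]
        text = render()
    info = {
        "polarity": polarity,
        "mentions": planted,
        "misspellings": misspellings,
        "hashtags": hashtags,
        "user_mentions": mentions,
        "urls": urls,
    }
    return text, info


def generate_corpus(config: SyntheticConfig) -> tuple[list[dict], GroundTruth]:
    """Generate tweet records (JSON-ready dicts) plus the ground truth."""
    config.validate()
    rng = random.Random(config.seed)
    fixtures = generate_fixtures(config)
    lexicon = fixtures.build_lexicon()
    terms_by_category = {
        cat: lexicon.terms_in_category(cat) for cat in META_CATEGORIES
    }
    dictionary = frozenset(fixtures.spelling_dictionary)
    suggester = DictionarySuggester(dictionary)

    users, truth = _make_users(rng, config, fixtures)
    by_name = {u["screen_name"]: u for u in users}
    org_names = [
        name for name, info in truth.users.items() if info["type"] == "organization"
    ]
    all_names = list(by_name)
    # long-tailed posting activity per user
    author_weights = [1 + int(rng.expovariate(config.tweets_per_user_rate)) for _ in users]
    author_cum = list(_accumulate(author_weights))
    # communication targets lean toward organizations (information seekers)
    target_weights = [
        5 if truth.users[name]["type"] == "organization" else 1 for name in all_names
    ]
    target_cum = list(_accumulate(target_weights))

    start, end = (_parse_iso(t) for t in config.date_range)
    span = (end - start).total_seconds()
    window = (
        tuple(_parse_iso(t) for t in config.event_window)
        if config.event_window
        else None
    )

    records: list[dict] = []
    for j in range(config.n_tweets):
        tweet_id = f"t{j:07d}"
        author = rng.choices(all_names, cum_weights=author_cum, k=1)[0]
        created = start + timedelta(seconds=rng.random() * span)
        in_window = window is not None and window[0] <= created <= window[1]
        scale = config.interaction_multiplier if in_window else 1.0
        retweet_count = int(rng.expovariate(1 / 3.0) * scale)
        favorite_count = int(rng.expovariate(1 / 5.0) * scale)

        if rng.random() < config.frac_non_english:
            lang = rng.choice(sorted(_NON_ENGLISH))
            record = {
                "id_str": tweet_id,
                "text": _NON_ENGLISH[lang],
                "lang": lang,
                "created_at": _iso(created),
                "retweet_count": retweet_count,
                "favorite_count": favorite_count,
                "in_reply_to_screen_name": None,
                "retweeted_status": None,
                "entities": {"hashtags": [], "urls": [], "user_mentions": []},
                "user": by_name[author],
            }
            records.append(record)
            truth.tweets[tweet_id] = {
                "lang": lang, "mentions": [], "polarity": None, "misspellings": {}
            }
            continue

        candidate_targets = [n for n in all_names if n != author]
        mention_pool = (
            rng.choices(all_names, cum_weights=target_cum, k=4)
            if candidate_targets
            else []
        )
        mention_pool = list(dict.fromkeys(n for n in mention_pool if n != author))
        text, info = _assemble_text(
            rng, config, lexicon, terms_by_category, dictionary, suggester, mention_pool
        )
        retweet_of = None
        if rng.random() < 0.15 and candidate_targets:
            retweet_of = rng.choices(all_names, cum_weights=target_cum, k=1)[0]
            if retweet_of == author:
                retweet_of = None
        reply_to = None
        if retweet_of is None and rng.random() < 0.10 and candidate_targets:
            reply_to = rng.choices(all_names, cum_weights=target_cum, k=1)[0]
            if reply_to == author or reply_to in info["user_mentions"]:
                reply_to = None

        record = {
            "id_str": tweet_id,
            "text": text,
            "lang": "en",
            "created_at": _iso(created),
            "retweet_count": retweet_count,
            "favorite_count": favorite_count,
            "in_reply_to_screen_name": reply_to,
            "retweeted_status": (
                {"user": {"screen_name": retweet_of}} if retweet_of else None
            ),
            "entities": {
                "hashtags": [{"text": h} for h in info["hashtags"]],
                "urls": [{"expanded_url": u} for u in info["urls"]],
                "user_mentions": [{"screen_name": m} for m in info["user_mentions"]],
            },
            "user": by_name[author],
        }
        records.append(record)
        truth.tweets[tweet_id] = {
            "lang": "en",
            "mentions": info["mentions"],
            "polarity": info["polarity"],
            "misspellings": info["misspellings"],
        }
    return records, truth


def _accumulate(values):
    total = 0
    for v in values:
        total += v
        yield total


def corpus_to_jsonl(records: list[dict]) -> str:
    return "\n".join(json.dumps(r, sort_keys=True) for r in records) + "\n"


def write_outputs(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write corpus.jsonl, fixture TSVs, and ground_truth.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = generate_corpus(config)
    fixtures = generate_fixtures(config)
    corpus_path = out / "corpus.jsonl"
    corpus_path.write_text(corpus_to_jsonl(records), encoding="utf-8")
    fixtures.write(out / "fixtures")
    truth_path = out / "ground_truth.json"
    truth_path.write_text(truth.to_json(), encoding="utf-8")
    return corpus_path, out / "fixtures", truth_path
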