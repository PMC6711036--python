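"""Tweet text cleaning and normalization.

Turns raw tweet text into a token stream ready for dictionary-based entity
recognition. The stages run in a fixed order:

1. structural stripping — pull out hashtags, @-mentions and URLs, and drop
   uninformative special characters (``& ( ) * + < >``);
2. hashtag splitting — reveal the words hidden in camel-case hashtags
   (``InflammatoryBowelDisease`` -> ``Inflammatory Bowel Disease``);
3. repeat squeezing — collapse runs of three or more identical characters to
   two (``haaaapppyy`` -> ``haappyy``), a common social-media emphasis habit;
4. spelling correction — out-of-dictionary tokens are replaced by the
   suggestion with the highest normalized Levenshtein similarity;
5. abbreviation expansion — shorthand such as ``SBBOS`` becomes
   ``small bowel bacterial overgrowth syndrome``;
6. tokenization — stop-word removal, a light suffix-stripping lemmatizer,
   optional POS tagging, and construction of 1/2/3-grams.

Steps 4–6 operate on lowercase tokens; emoji and ASCII emoticons are kept
aside during cleaning (the user profiler consumes them) and never enter the
n-gram stream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

__all__ = [
    "RawTweet",
    "Token",
    "CleanTweet",
    "strip_structure",
    "split_hashtag",
    "squeeze_repeats",
    "normalized_levenshtein",
    "DictionarySuggester",
    "correct_spelling",
    "expand_abbreviations",
    "default_lemmatizer",
    "tokenize",
    "TweetNormalizer",
    "DEFAULT_STOPWORDS",
    "is_emoji_token",
]

MAX_TWEET_LENGTH = 280

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@(\w+)")
_HASHTAG_RE = re.compile(r"#(\w+)")
# characters the cleaning stage drops outright
_SPECIAL_RE = re.compile(r"[&()*+<>“”\"]")
_WS_RE = re.compile(r"\s+")
_REPEAT_RE = re.compile(r"(.)\1{2,}", re.DOTALL)
# case and letter/digit boundaries used for hashtag segmentation
_CAMEL_RE = re.compile(
    r"(?<=[a-z])(?=[A-Z])|(?<=[A-Za-z])(?=[0-9])|(?<=[0-9])(?=[A-Za-z])"
)
_APOSTROPHE_RE = re.compile(r"['’ʼ]")

_EMOJI_RE = re.compile(
    "["
    "\U0001f300-\U0001faff"  # symbols, pictographs, emoticons, supplement
    "\U00002600-\U000027bf"  # misc symbols + dingbats
    "❤️⭐"
    "]"
)
_ASCII_EMOTICON_RE = re.compile(r"^[:;=8xX][-'^o]?[)(\[\]DPpO3/\\|]+$|^[)(D]?[-'^o]?[:;=8]$")

DEFAULT_STOPWORDS = frozenset(
    """
    a an the and or but if then than that this these those is are was were be
    been being am i me my we us you your he she it they them to of in on at by
    for with about from as so such not no nor do does did have has had will
    would can could should may might there here what which who whom its his
    her their our out up down over under again once when where why how all any
    both each few more most other some own same very s t just dont isnt wasnt
    im ive
    """.split()
)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RawTweet:
    """One post as read from the corpus (subset of Twitter API v1.1 fields)."""

    id: str
    text: str
    lang: str = "en"
    created_at: str = ""
    retweet_count: int = 0
    favorite_count: int = 0
    in_reply_to_user: Optional[str] = None
    retweet_of_user: Optional[str] = None
    hashtags: list[str] = field(default_factory=list)
    urls: list[str] = field(default_factory=list)
    user_mentions: list[str] = field(default_factory=list)
    user: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.retweet_count < 0 or self.favorite_count < 0:
            raise ValueError("interaction counts must be non-negative")


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    pos: str = ""
    origin: str = "text"  # text | hashtag | abbrev


@dataclass
class CleanTweet:
    """Normalized tweet: content tokens (stop words removed) plus n-grams."""

    id: str
    clean_text: str
    tokens: list[Token]
    ngrams: list[str]
    hashtags: list[str] = field(default_factory=list)
    mentions: list[str] = field(default_factory=list)
    urls: list[str] = field(default_factory=list)
    emojis: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# individual cleaning operations


def strip_structure(text: str) -> tuple[str, list[str], list[str], list[str]]:
    """Extract hashtags/mentions/URLs and drop special characters.

    Hashtag bodies stay in the running text (only the ``#`` marker is
    removed); mentions and URLs are removed entirely.
    """
    urls = _URL_RE.findall(text)
    text = _URL_RE.sub(" ", text)
    mentions = _MENTION_RE.findall(text)
    text = _MENTION_RE.sub(" ", text)
    hashtags = _HASHTAG_RE.findall(text)
    text = _HASHTAG_RE.sub(lambda m: m.group(1), text)
    text = _SPECIAL_RE.sub(" ", text)
    text = _WS_RE.sub(" ", text).strip()
    return text, hashtags, mentions, urls


def split_hashtag(tag: str) -> list[str]:
    """Split a hashtag body at case and letter/digit boundaries.

    All-lowercase multiword tags are left unsplit: without a segmentation
    dictionary there is no reliable boundary evidence.
    """
    if not tag:
        return []
    return [part for part in _CAMEL_RE.split(tag) if part]


def squeeze_repeats(token: str) -> str:
    """Reduce every run of >= 3 identical characters to exactly two."""
    return _REPEAT_RE.sub(r"\1\1", token)


def normalized_levenshtein(a: str, b: str) -> float:
    """Similarity ``1 - d(a, b) / max(|a|, |b|)`` with unit edit costs.

    Two empty strings compare as identical (similarity 1).
    """
    if not a and not b:
        return 1.0
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la > lb:  # keep the inner loop over the shorter string
        a, b, la, lb = b, a, lb, la
    prev = list(range(la + 1))
    for j in range(1, lb + 1):
        cur = [j] + [0] * la
        bj = b[j - 1]
        for i in range(1, la + 1):
            cost = 0 if a[i - 1] == bj else 1
            cur[i] = min(prev[i] + 1, cur[i - 1] + 1, prev[i - 1] + cost)
        prev = cur
    return 1.0 - prev[la] / max(la, lb)


class DictionarySuggester:
    """Suggest in-dictionary replacements for an out-of-dictionary token.

    Candidates are dictionary words within ``max_len_diff`` characters of the
    token's length whose normalized Levenshtein similarity reaches
    ``min_similarity``. Length bucketing keeps the scan linear in the number
    of plausible candidates.
    """

    def __init__(
        self,
        dictionary: Iterable[str],
        min_similarity: float = 0.7,
        max_len_diff: int = 2,
    ) -> None:
        self.min_similarity = float(min_similarity)
        self.max_len_diff = int(max_len_diff)
        self._by_length: dict[int, list[str]] = {}
        for word in sorted(set(dictionary)):
            self._by_length.setdefault(len(word), []).append(word)

    def __call__(self, token: str) -> list[str]:
        out = []
        for length in range(
            max(1, len(token) - self.max_len_diff), len(token) + self.max_len_diff + 1
        ):
            for word in self._by_length.get(length, ()):
                if normalized_levenshtein(token, word) >= self.min_similarity:
                    out.append(word)
        return out


def correct_spelling(
    token: str,
    dictionary: frozenset[str] | set[str],
    suggester: Callable[[str], Sequence[str]],
) -> str:
    """Return the best in-dictionary replacement for ``token``.

    In-dictionary tokens pass through untouched. Otherwise the suggestion
    maximizing normalized Levenshtein similarity wins; ties break to the
    lexicographically smallest suggestion for reproducibility. No suggestion
    means no change.
    """
    if token in dictionary:
        return token
    best, best_sim = None, -1.0
    for cand in suggester(token):
        sim = normalized_levenshtein(token, cand)
        if sim > best_sim or (sim == best_sim and (best is None or cand < best)):
            best, best_sim = cand, sim
    return best if best is not None else token


def expand_abbreviations(token: str, abbrev_dict: Mapping[str, str]) -> str:
    """Case-insensitive shorthand expansion; misses pass through."""
    return abbrev_dict.get(token.lower(), token)


_LEMMA_SUFFIXES: tuple[tuple[str, str, int], ...] = (
    # (suffix, replacement, minimum token length)
    ("ies", "y", 5),
    ("sses", "ss", 6),
    ("s", "", 4),
)


def default_lemmatizer(token: str) -> str:
    """Tiny suffix-stripping stub covering regular English plurals.

    Stands in for a full morphological analyzer; the tagging/lemmatization
    slot of :class:`TweetNormalizer` is pluggable.
    """
    low = token.lower()
    for suffix, repl, min_len in _LEMMA_SUFFIXES:
        if low.endswith(suffix) and len(low) >= min_len:
            if suffix == "s" and (low.endswith("ss") or low.endswith("us") or low.endswith("is")):
                continue
            return low[: -len(suffix)] + repl
    return low


def is_emoji_token(token: str) -> bool:
    return bool(_EMOJI_RE.fullmatch(token)) or bool(_ASCII_EMOTICON_RE.match(token))


def _segment(text: str) -> list[str]:
    """Lowercase word segmentation keeping emoji as standalone tokens.

    Apostrophes are deleted (``crohn's`` -> ``crohns``) and hyphens become
    spaces (``gluten-free`` -> ``gluten free``) so tokens line up with the
    normalized lexicon.
    """
    text = _APOSTROPHE_RE.sub("", text)
    text = _EMOJI_RE.sub(lambda m: f" {m.group(0)} ", text)
    pieces: list[str] = []
    for raw in text.split():
        if _EMOJI_RE.fullmatch(raw) or _ASCII_EMOTICON_RE.match(raw):
            pieces.append(raw)
            continue
        cleaned = re.sub(r"[^0-9A-Za-z]+", " ", raw)
        pieces.extend(w.lower() for w in cleaned.split())
    return pieces


def build_ngrams(tokens: Sequence[str], max_n: int = 3) -> list[str]:
    """All contiguous 1..max_n-grams, unigrams first, then bigrams, trigrams."""
    out: list[str] = []
    for n in range(1, max_n + 1):
        out.extend(
            " ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)
        )
    return out


def tokenize(
    stripped_text: str,
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
    lemmatizer: Callable[[str], str] = default_lemmatizer,
    pos_tagger: Optional[Callable[[Sequence[str]], Sequence[str]]] = None,
    origins: Optional[Sequence[str]] = None,
) -> tuple[list[Token], list[str], list[str]]:
    """Final tokenization stage: returns (tokens, ngrams, emojis).

    ``stripped_text`` must already have passed structural stripping, hashtag
    splitting, repeat squeezing, spelling correction and abbreviation
    expansion. Stop words are removed before n-gram construction.
    """
    words = _segment(stripped_text)
    if origins is not None and len(origins) != len(words):
        origins = None
    emojis = [w for w in words if is_emoji_token(w)]
    kept: list[tuple[str, str]] = []
    for idx, w in enumerate(words):
        if is_emoji_token(w) or w in stopwords:
            continue
        kept.append((w, origins[idx] if origins else "text"))
    surfaces = [w for w, _ in kept]
    tags = list(pos_tagger(surfaces)) if pos_tagger else [""] * len(surfaces)
    tokens = [
        Token(surface=w, lemma=lemmatizer(w), pos=tags[i], origin=kept[i][1])
        for i, w in enumerate(surfaces)
    ]
    return tokens, build_ngrams(surfaces), emojis


# ---------------------------------------------------------------------------
# the full pipeline


class TweetNormalizer:
    """Runs the cleaning cascade in its fixed order on whole tweets.

    Parameters
    ----------
    spelling_dictionary:
        Known-good word forms; out-of-dictionary alphabetic tokens are run
        through the suggester.
    abbreviations:
        Lowercase shorthand -> expansion phrase.
    stopwords:
        Tokens removed before n-gram construction.
    suggester:
        Callable token -> candidate list. Defaults to a
        :class:`DictionarySuggester` over ``spelling_dictionary``.
    lemmatizer / pos_tagger:
        Pluggable analysis hooks; defaults are a suffix-stripping stub and no
        tagging.
    """

    def __init__(
        self,
        spelling_dictionary: Iterable[str] = (),
        abbreviations: Optional[Mapping[str, str]] = None,
        stopwords: Iterable[str] = DEFAULT_STOPWORDS,
        suggester: Optional[Callable[[str], Sequence[str]]] = None,
        lemmatizer: Callable[[str], str] = default_lemmatizer,
        pos_tagger: Optional[Callable[[Sequence[str]], Sequence[str]]] = None,
        min_similarity: float = 0.7,
    ) -> None:
        self.dictionary = frozenset(w.lower() for w in spelling_dictionary)
        self.abbreviations = {
            k.lower(): v.lower() for k, v in (abbreviations or {}).items()
        }
        self.stopwords = frozenset(w.lower() for w in stopwords)
        self.suggester = suggester or DictionarySuggester(
            self.dictionary, min_similarity=min_similarity
        )
        self.lemmatizer = lemmatizer
        self.pos_tagger = pos_tagger

    # -- stages -------------------------------------------------------------

    def _token_pass(self, words: list[str], origins: list[str]) -> tuple[list[str], list[str]]:
        """squeeze -> spell-correct -> abbreviation-expand, token by token."""
        out_words: list[str] = []
        out_origins: list[str] = []
        for word, origin in zip(words, origins):
            if is_emoji_token(word):
                out_words.append(word)
                out_origins.append(origin)
                continue
            word = squeeze_repeats(word)
            if word.isalpha() and word not in self.dictionary:
                word = correct_spelling(word, self.dictionary, self.suggester)
            expanded = expand_abbreviations(word, self.abbreviations)
            if expanded != word:
                for part in expanded.split():
                    out_words.append(part)
                    out_origins.append("abbrev")
            else:
                out_words.append(word)
                out_origins.append(origin)
        return out_words, out_origins

    def normalize_text(self, text: str, tweet_id: str = "") -> CleanTweet:
        stripped, hashtags, mentions, urls = strip_structure(text)
        words = _segment(stripped)
        origins = ["text"] * len(words)
        # reveal words hidden in multiword hashtags; the unsplit body is
        # already inline, the split form is appended so the matcher sees it
        for tag in hashtags:
            parts = split_hashtag(tag)
            if len(parts) > 1:
                for part in parts:
                    words.extend(_segment(part))
                    origins.extend(["hashtag"] * (len(words) - len(origins)))
        words, origins = self._token_pass(words, origins)
        tokens, ngrams, emojis = tokenize(
            " ".join(words),
            stopwords=self.stopwords,
            lemmatizer=self.lemmatizer,
            pos_tagger=self.pos_tagger,
            origins=origins,
        )
        clean_text = " ".join(t.surface for t in tokens)
        return CleanTweet(
            id=tweet_id,
            clean_text=clean_text,
            tokens=tokens,
            ngrams=ngrams,
            hashtags=hashtags,
            mentions=mentions,
            urls=urls,
            emojis=emojis,
        )

    def normalize(self, tweet: RawTweet) -> CleanTweet:
        clean = self.normalize_text(tweet.text, tweet_id=tweet.id)
        # structural fields recorded by the collector take precedence over
        # what the regexes recover from the text
        if tweet.hashtags:
            clean.hashtags = list(dict.fromkeys(clean.hashtags + tweet.hashtags))
        if tweet.user_mentions:
            clean.mentions = list(dict.fromkeys(clean.mentions + tweet.user_mentions))
        if tweet.urls:
            clean.urls = list(dict.fromkeys(clean.urls + tweet.urls))
        return clean
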