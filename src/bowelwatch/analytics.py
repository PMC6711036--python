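"""Descriptive summary tables for a processed tweet corpus.

These routines assemble the study's result artifacts: a term-frequency
table with engagement counts, sentiment distribution by semantic category,
monthly activity with event-window uplift arithmetic, a top-URL table split
by poster type, and per-country/continent user counts.

Percentages are computed with half-up rounding to two decimals (integers
for uplifts) so every printed share is exactly reproducible from the
printed counts of the same row.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from datetime import datetime, timezone
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Optional, Sequence
from urllib.parse import urlparse

import pandas as pd

from .ner import EntityMention, Lexicon
from .normalize import CleanTweet, RawTweet, default_lemmatizer, split_hashtag
from .profiler import UserProfile
from .sentiment import SentimentResult

__all__ = [
    "share_percentage",
    "term_frequency_table",
    "sentiment_by_category",
    "monthly_activity",
    "event_uplift",
    "url_table",
    "geo_distribution",
]

SENTIMENT_LABELS = ("negative", "neutral", "positive")


def share_percentage(count: int, total: int) -> float:
    """``100 * count / total`` rounded half-up to two decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _round_half_up(value: float) -> int:
    return int(Decimal(value).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _parse_timestamp(value: str) -> datetime:
    dt = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


# ---------------------------------------------------------------------------
# Table 1 shape: term frequency with engagement counts


def _hashtag_matches_term(
    hashtag: str, term: str, lemmatizer: Callable[[str], str]
) -> bool:
    """A hashtag counts toward a term when its split, lowercased form equals
    the term, the term's lemma form, or a leading word-prefix of the term
    (``#anxiety`` counts toward ``anxiety disorder``)."""
    words = [w.lower() for w in split_hashtag(hashtag)]
    if not words:
        return False
    term_words = term.split()
    lemma_words = [lemmatizer(w) for w in term_words]
    lemma_tag = [lemmatizer(w) for w in words]
    for tag_words in (words, lemma_tag):
        if tag_words in (term_words, lemma_words):
            return True
        if len(tag_words) < len(term_words) and (
            term_words[: len(tag_words)] == tag_words
            or lemma_words[: len(tag_words)] == tag_words
        ):
            return True
    return False


def term_frequency_table(
    mentions: Iterable[EntityMention],
    tweets: Mapping[str, RawTweet],
    hashtags_by_tweet: Optional[Mapping[str, Sequence[str]]] = None,
    lemmatizer: Callable[[str], str] = default_lemmatizer,
    top_k: Optional[int] = None,
) -> pd.DataFrame:
    """Per-term tweet counts plus summed favorites/retweets/hashtag uses.

    A term counts once per tweet regardless of repeats; favorites and
    retweets sum over the distinct tweets mentioning the term; the hashtag
    column counts hashtag occurrences (corpus-wide) whose normalized form
    matches the term or a variation of it.
    """
    tweets_by_term: dict[str, set[str]] = {}
    category: dict[str, str] = {}
    for m in mentions:
        tweets_by_term.setdefault(m.term, set()).add(m.tweet_id)
        category[m.term] = m.meta_category
    all_hashtags: list[str] = []
    if hashtags_by_tweet is not None:
        for tags in hashtags_by_tweet.values():
            all_hashtags.extend(tags)
    else:
        for t in tweets.values():
            all_hashtags.extend(t.hashtags)
    rows = []
    for term, tweet_ids in tweets_by_term.items():
        favorites = sum(tweets[tid].favorite_count for tid in tweet_ids if tid in tweets)
        retweets = sum(tweets[tid].retweet_count for tid in tweet_ids if tid in tweets)
        n_hashtags = sum(
            1 for tag in all_hashtags if _hashtag_matches_term(tag, term, lemmatizer)
        )
        rows.append(
            {
                "term": term,
                "meta_category": category[term],
                "n_tweets": len(tweet_ids),
                "n_favorites": favorites,
                "n_retweets": retweets,
                "n_hashtags": n_hashtags,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "term",
            "meta_category",
            "n_tweets",
            "n_favorites",
            "n_retweets",
            "n_hashtags",
        ],
    )
    frame = frame.sort_values(
        ["n_tweets", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_k is not None:
        frame = frame.head(top_k)
    return frame


# ---------------------------------------------------------------------------
# Table 2 shape: sentiment by semantic category


def sentiment_by_category(
    mentions: Iterable[EntityMention],
    sentiments: Mapping[str, SentimentResult | str],
    profiles: Optional[Mapping[str, UserProfile]] = None,
    tweet_user: Optional[Mapping[str, str]] = None,
    account_filter: Optional[str] = None,
) -> pd.DataFrame:
    """Polarity counts and shares per meta-category.

    A tweet contributes to every category it mentions (once per category).
    With ``account_filter`` set (e.g. ``"patient"``), only tweets whose
    poster's profile carries that account type are counted; this requires
    ``profiles`` and the ``tweet_user`` tweet-id -> screen-name map.
    Categories with no tweets are omitted.
    """
    allowed: Optional[set[str]] = None
    if account_filter is not None:
        if profiles is None or tweet_user is None:
            raise ValueError("account_filter requires profiles and tweet_user")
        allowed = {
            tid
            for tid, screen_name in tweet_user.items()
            if profiles.get(screen_name)
            and profiles[screen_name].account_type == account_filter
        }
    cats_by_tweet: dict[str, set[str]] = {}
    for m in mentions:
        if allowed is not None and m.tweet_id not in allowed:
            continue
        cats_by_tweet.setdefault(m.tweet_id, set()).add(m.meta_category)
    counts: dict[str, Counter] = {}
    for tweet_id, cats in cats_by_tweet.items():
        res = sentiments.get(tweet_id)
        if res is None:
            continue
        label = res.label if isinstance(res, SentimentResult) else res
        for cat in cats:
            counts.setdefault(cat, Counter())[label] += 1
    rows = []
    for cat in sorted(counts):
        c = counts[cat]
        total = sum(c.values())
        if total == 0:
            continue
        row = {"meta_category": cat, "n_total": total}
        for label in SENTIMENT_LABELS:
            row[f"n_{label}"] = c.get(label, 0)
            row[f"pct_{label}"] = share_percentage(c.get(label, 0), total)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "meta_category",
            "n_negative",
            "n_neutral",
            "n_positive",
            "n_total",
            "pct_negative",
            "pct_neutral",
            "pct_positive",
        ],
    )


# ---------------------------------------------------------------------------
# Table 3 shape: monthly activity and event uplift


def monthly_activity(tweets: Iterable[RawTweet]) -> pd.DataFrame:
    """Tweet and interaction volume per UTC calendar month.

    Months are contiguous over the corpus range (empty months appear with
    zero counts). Interactions are retweets + favorites; the two components
    are also reported separately for uplift arithmetic.
    """
    buckets: dict[str, dict[str, int]] = {}
    stamps = []
    for tweet in tweets:
        dt = _parse_timestamp(tweet.created_at)
        stamps.append(dt)
        key = f"{dt.year:04d}-{dt.month:02d}"
        b = buckets.setdefault(
            key, {"n_tweets": 0, "n_retweets": 0, "n_favorites": 0}
        )
        b["n_tweets"] += 1
        b["n_retweets"] += tweet.retweet_count
        b["n_favorites"] += tweet.favorite_count
    if not stamps:
        return pd.DataFrame(
            columns=["month", "n_tweets", "n_retweets", "n_favorites", "n_interactions"]
        )
    first, last = min(stamps), max(stamps)
    months = []
    year, month = first.year, first.month
    while (year, month) <= (last.year, last.month):
        months.append(f"{year:04d}-{month:02d}")
        month += 1
        if month == 13:
            year, month = year + 1, 1
    rows = []
    for key in months:
        b = buckets.get(key, {"n_tweets": 0, "n_retweets": 0, "n_favorites": 0})
        rows.append(
            {
                "month": key,
                "n_tweets": b["n_tweets"],
                "n_retweets": b["n_retweets"],
                "n_favorites": b["n_favorites"],
                "n_interactions": b["n_retweets"] + b["n_favorites"],
            }
        )
    return pd.DataFrame(rows)


def event_uplift(
    rows: pd.DataFrame,
    window_months: Sequence[str],
    column: str = "n_retweets",
) -> int:
    """Event-window mean over baseline mean, as an integer percentage.

    ``100 * mean(column inside window) / mean(column outside window)``,
    rounded half-up. The complement of the window must be non-empty.
    """
    window = set(window_months)
    unknown = window - set(rows["month"])
    if unknown:
        raise ValueError(f"window months {sorted(unknown)} not in the covered range")
    inside = rows[rows["month"].isin(window)][column]
    outside = rows[~rows["month"].isin(window)][column]
    if outside.empty:
        raise ValueError("baseline (non-window) months must be non-empty")
    baseline = outside.mean()
    if baseline == 0:
        raise ValueError("baseline mean is zero; uplift undefined")
    return _round_half_up(100 * inside.mean() / baseline)


def uplift_from_means(window_mean: float, baseline_mean: float) -> int:
    """Uplift percentage straight from the two means (half-up integer)."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return _round_half_up(100 * window_mean / baseline_mean)


# ---------------------------------------------------------------------------
# Tables 4-5 shape: external sources, and the geography summary


def url_table(
    tweets: Iterable[RawTweet],
    profiles: Optional[Mapping[str, UserProfile]] = None,
    poster_type: Optional[str] = None,
    top_k: Optional[int] = 10,
    domain_categories: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Distinct URLs with tweet/retweet/favorite counts, most engaging first.

    Rows sort by the sum of the three counts, descending. ``poster_type``
    restricts to tweets posted by that account type (any account whose
    profile is missing counts as ``other``). URL categories come from an
    optional domain -> category map, defaulting to ``uncategorized``.
    """
    stats: dict[str, dict] = {}
    for tweet in tweets:
        user = tweet.user or {}
        screen_name = user.get("screen_name")
        ptype = "other"
        if profiles and screen_name in profiles:
            ptype = profiles[screen_name].account_type
            if ptype not in ("organization", "patient"):
                ptype = "other"
        if poster_type is not None and ptype != poster_type:
            continue
        for url in dict.fromkeys(tweet.urls):
            entry = stats.setdefault(
                url,
                {
                    "url": url,
                    "domain": urlparse(url).netloc.lower(),
                    "n_tweets": 0,
                    "n_retweets": 0,
                    "n_favorites": 0,
                    "poster_type": ptype,
                },
            )
            entry["n_tweets"] += 1
            entry["n_retweets"] += tweet.retweet_count
            entry["n_favorites"] += tweet.favorite_count
    rows = []
    for entry in stats.values():
        domain = entry["domain"]
        entry["category"] = (
            domain_categories.get(domain, "uncategorized")
            if domain_categories
            else "uncategorized"
        )
        entry["sort_key"] = entry["n_tweets"] + entry["n_retweets"] + entry["n_favorites"]
        rows.append(entry)
    frame = pd.DataFrame(
        rows,
        columns=[
            "url",
            "domain",
            "category",
            "n_tweets",
            "n_retweets",
            "n_favorites",
            "poster_type",
            "sort_key",
        ],
    )
    if not frame.empty:
        frame = frame.sort_values(
            ["sort_key", "url"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    if top_k is not None:
        frame = frame.head(top_k)
    return frame


def geo_distribution(
    profiles: Iterable[UserProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """User counts per country and per continent over resolved locations."""
    country_counts: Counter = Counter()
    continent_counts: Counter = Counter()
    continent_of: dict[str, str] = {}
    for profile in profiles:
        if profile.location is None:
            continue
        _, country, continent = profile.location
        country_counts[country] += 1
        continent_counts[continent] += 1
        continent_of[country] = continent
    countries = pd.DataFrame(
        [
            {"country": c, "continent": continent_of[c], "n_users": n}
            for c, n in sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ],
        columns=["country", "continent", "n_users"],
    )
    continents = pd.DataFrame(
        [
            {"continent": c, "n_users": n}
            for c, n in sorted(continent_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ],
        columns=["continent", "n_users"],
    )
    return countries, continents
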