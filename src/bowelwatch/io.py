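"""Reading and writing the corpus, fixture tables and stage outputs.

The corpus is JSON-lines, one tweet per line, using a subset of the
historical Twitter API v1.1 field names (``id_str``, ``text``, ``lang``,
``created_at``, ``retweet_count``, ``favorite_count``, ``entities``,
``user``) so archived real data can flow through the same reader. Fixture
tables are plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .normalize import RawTweet
from .profiler import GazetteerEntry, Gazetteer, NameGenderTable, UserRecord

__all__ = [
    "parse_tweet",
    "parse_user",
    "load_corpus",
    "read_jsonl",
    "write_jsonl",
    "load_gazetteer",
    "load_aliases",
    "load_name_table",
    "load_abbreviations",
    "load_spelling_dictionary",
    "load_lexicon_rows",
    "load_valence",
    "load_stopwords",
]


def parse_user(user: dict) -> UserRecord:
    image_ref = user.get("profile_image_url")
    return UserRecord(
        screen_name=user["screen_name"],
        display_name=user.get("name", ""),
        description=user.get("description", "") or "",
        location_text=user.get("location"),
        time_zone=user.get("time_zone"),
        utc_offset=user.get("utc_offset"),
        has_profile_image=image_ref is not None,
        is_contributor_or_translator=bool(
            user.get("is_translator") or user.get("contributors_enabled")
        ),
        profile_image_ref=image_ref,
    )


def parse_tweet(record: dict) -> RawTweet:
    entities = record.get("entities", {}) or {}
    retweeted = record.get("retweeted_status") or {}
    return RawTweet(
        id=record.get("id_str") or str(record.get("id", "")),
        text=record.get("text", "") or record.get("full_text", ""),
        lang=record.get("lang", "en"),
        created_at=record.get("created_at", ""),
        retweet_count=int(record.get("retweet_count", 0)),
        favorite_count=int(record.get("favorite_count", 0)),
        in_reply_to_user=record.get("in_reply_to_screen_name"),
        retweet_of_user=(retweeted.get("user") or {}).get("screen_name"),
        hashtags=[h["text"] for h in entities.get("hashtags", ())],
        urls=[u["expanded_url"] for u in entities.get("urls", ())],
        user_mentions=[m["screen_name"] for m in entities.get("user_mentions", ())],
        user=record.get("user"),
    )


def load_corpus(
    path: str | Path,
    english_only: bool = True,
    dedupe: bool = True,
) -> list[RawTweet]:
    """Read a JSONL corpus, keeping English records and dropping duplicates.

    The ``lang`` tag is trusted; duplicate tweet ids keep their first
    occurrence.
    """
    tweets: list[RawTweet] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            tweet = parse_tweet(json.loads(line))
            if english_only and tweet.lang != "en":
                continue
            if dedupe:
                if tweet.id in seen:
                    continue
                seen.add(tweet.id)
            tweets.append(tweet)
    return tweets


def read_jsonl(path: str | Path) -> list[dict]:
    with open(path, "r", encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_jsonl(path: str | Path, rows: Iterable[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write(json.dumps(row, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# fixture tables


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_gazetteer(path: str | Path) -> Gazetteer:
    frame = _read_tsv(path)
    return Gazetteer(
        GazetteerEntry(
            name=row["name"],
            country=row["country"],
            continent=row["continent"],
            time_zone=row["time_zone"],
            utc_offset=int(row["utc_offset"]),
        )
        for row in frame.to_dict("records")
    )


def load_aliases(path: str | Path) -> dict[str, str]:
    frame = _read_tsv(path)
    return {row["alias"].lower(): row["name"].lower() for row in frame.to_dict("records")}


def load_name_table(path: str | Path) -> NameGenderTable:
    frame = _read_tsv(path)
    return NameGenderTable(
        (row["name"], row["gender"], bool(int(row["ambiguous"])))
        for row in frame.to_dict("records")
    )


def load_abbreviations(path: str | Path) -> dict[str, str]:
    frame = _read_tsv(path)
    return {
        row["abbreviation"].lower(): row["expansion"].lower()
        for row in frame.to_dict("records")
    }


def load_spelling_dictionary(path: str | Path) -> frozenset[str]:
    frame = _read_tsv(path)
    return frozenset(frame["word"].str.lower())


def load_lexicon_rows(path: str | Path) -> list[tuple[str, str, str]]:
    frame = _read_tsv(path)
    return [
        (row["term"], row["source"], row.get("category", ""))
        for row in frame.to_dict("records")
    ]


def load_valence(path: str | Path) -> dict[str, float]:
    frame = _read_tsv(path)
    return {row["term"]: float(row["valence"]) for row in frame.to_dict("records")}


def load_stopwords(path: str | Path) -> frozenset[str]:
    with open(path, "r", encoding="utf-8") as fh:
        return frozenset(w.strip().lower() for w in fh if w.strip())
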