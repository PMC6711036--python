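"""End-to-end orchestration: ingest -> normalize -> profile -> ner ->
sentiment -> graphs -> analytics, with a reproducibility manifest.

The run consumes either a pre-generated corpus directory (corpus.jsonl +
fixtures/) or a synthetic-generation config, and writes every intermediate
and final artifact under the output directory. All outputs are
deterministic functions of the inputs and the seed; two runs with the same
configuration produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

from . import io as bw_io
from .analytics import (
    event_uplift,
    geo_distribution,
    monthly_activity,
    sentiment_by_category,
    term_frequency_table,
    url_table,
)
from .graphs import build_cooccurrence_graph, build_interaction_graph, extract_communities
from .ner import build_lexicon, recognize
from .normalize import TweetNormalizer
from .profiler import UserProfiler
from .sentiment import SentimentScorer
from .synthetic import SyntheticConfig, write_outputs

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: Path
    corpus_dir: Optional[Path] = None  # holds corpus.jsonl + fixtures/
    synthetic: Optional[SyntheticConfig] = None
    event_window_months: tuple[str, ...] = ("2018-05", "2018-06")
    community_min_size: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        synthetic = None
        if "synthetic" in data:
            synthetic = SyntheticConfig(**data["synthetic"])
        return cls(
            out_dir=Path(data["out_dir"]),
            corpus_dir=Path(data["corpus_dir"]) if data.get("corpus_dir") else None,
            synthetic=synthetic,
            event_window_months=tuple(
                data.get("event_window_months", ("2018-05", "2018-06"))
            ),
            community_min_size=int(data.get("community_min_size", 5)),
        )


@dataclass
class PipelineResult:
    out_dir: Path
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    n_tweets: int = 0
    n_users: int = 0
    uplifts: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _frame_to_markdown(frame) -> str:
    cols = list(frame.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for row in frame.itertuples(index=False):
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def _write_table(frame, path: Path) -> None:
    frame.to_csv(path, index=False, lineterminator="\n")
    path.with_suffix(".md").write_text(_frame_to_markdown(frame), encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables_dir = out / "tables"
    tables_dir.mkdir(exist_ok=True)

    # -- ingest -------------------------------------------------------------
    if config.corpus_dir is not None:
        corpus_dir = Path(config.corpus_dir)
    else:
        synth = config.synthetic or SyntheticConfig()
        corpus_dir = out / "corpus"
        write_outputs(synth, corpus_dir)
    corpus_path = corpus_dir / "corpus.jsonl"
    fixtures_dir = corpus_dir / "fixtures"
    tweets = bw_io.load_corpus(corpus_path, english_only=True, dedupe=True)
    tweets_by_id = {t.id: t for t in tweets}

    dictionary = bw_io.load_spelling_dictionary(fixtures_dir / "spelling_dictionary.tsv")
    abbreviations = bw_io.load_abbreviations(fixtures_dir / "abbreviations.tsv")
    gazetteer = bw_io.load_gazetteer(fixtures_dir / "gazetteer.tsv")
    aliases = bw_io.load_aliases(fixtures_dir / "aliases.tsv")
    name_table = bw_io.load_name_table(fixtures_dir / "name_gender.tsv")
    lexicon = build_lexicon(bw_io.load_lexicon_rows(fixtures_dir / "lexicon.tsv"))
    valence = bw_io.load_valence(fixtures_dir / "valence.tsv")

    # -- normalize ----------------------------------------------------------
    normalizer = TweetNormalizer(
        spelling_dictionary=dictionary, abbreviations=abbreviations
    )
    clean = [normalizer.normalize(t) for t in tweets]
    bw_io.write_jsonl(
        out / "clean.jsonl",
        (
            {
                "id": c.id,
                "clean_text": c.clean_text,
                "tokens": [t.surface for t in c.tokens],
                "hashtags": c.hashtags,
                "mentions": c.mentions,
                "urls": c.urls,
            }
            for c in clean
        ),
    )

    # -- profile ------------------------------------------------------------
    profiler = UserProfiler(
        name_table=name_table, gazetteer=gazetteer, aliases=aliases
    )
    profiles = {}
    for tweet in tweets:
        if tweet.user and tweet.user["screen_name"] not in profiles:
            profiles[tweet.user["screen_name"]] = profiler.profile(
                bw_io.parse_user(tweet.user)
            )
    bw_io.write_jsonl(
        out / "profiles.jsonl",
        (
            {
                "screen_name": p.screen_name,
                "gender": p.gender,
                "account_type": p.account_type,
                "location": list(p.location) if p.location else None,
                "matched_rule": p.matched_rule,
            }
            for p in sorted(profiles.values(), key=lambda p: p.screen_name)
        ),
    )

    # -- ner ----------------------------------------------------------------
    mentions = []
    for c in clean:
        mentions.extend(recognize(c, lexicon))
    bw_io.write_jsonl(
        out / "mentions.jsonl",
        (
            {
                "tweet_id": m.tweet_id,
                "term": m.term,
                "meta_category": m.meta_category,
                "span": list(m.token_span),
                "match_kind": m.match_kind,
            }
            for m in mentions
        ),
    )

    # -- sentiment ----------------------------------------------------------
    scorer = SentimentScorer(valence)
    sentiments = {t.id: scorer.result(t.id, t.text) for t in tweets}
    bw_io.write_jsonl(
        out / "sentiments.jsonl",
        (
            {"tweet_id": s.tweet_id, "compound": round(s.compound, 6), "label": s.label}
            for s in sentiments.values()
        ),
    )

    # -- graphs -------------------------------------------------------------
    interaction = build_interaction_graph(
        tweets, profiles, mentions_by_tweet={c.id: c.mentions for c in clean}
    )
    cooccurrence = build_cooccurrence_graph(mentions, sentiments)
    nx.write_graphml(interaction, out / "interaction.graphml")
    nx.write_graphml(cooccurrence, out / "cooccurrence.graphml")
    with open(out / "interaction_edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for a, b, data in sorted(interaction.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']}\n")
    with open(out / "cooccurrence_edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("term_a\tterm_b\tweight\tsentiment_majority\n")
        for a, b, data in sorted(cooccurrence.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']}\t{data['sentiment_majority']}\n")
    communities = extract_communities(interaction, min_size=config.community_min_size)

    # -- analytics ----------------------------------------------------------
    tables = {}
    tables["term_frequency"] = term_frequency_table(
        mentions, tweets_by_id, hashtags_by_tweet={c.id: c.hashtags for c in clean}
    )
    tweet_user = {
        t.id: t.user["screen_name"] for t in tweets if t.user
    }
    tables["sentiment_by_category"] = sentiment_by_category(
        mentions, sentiments, profiles, tweet_user, account_filter="patient"
    )
    tables["sentiment_by_category_all"] = sentiment_by_category(mentions, sentiments)
    tables["monthly_activity"] = monthly_activity(tweets)
    tables["url_table_organization"] = url_table(
        tweets, profiles, poster_type="organization"
    )
    tables["url_table_patient"] = url_table(tweets, profiles, poster_type="patient")
    countries, continents = geo_distribution(profiles.values())
    tables["geo_countries"] = countries
    tables["geo_continents"] = continents
    for name, frame in tables.items():
        _write_table(frame, tables_dir / f"{name}.csv")

    uplifts = {}
    months = set(tables["monthly_activity"]["month"])
    window = [m for m in config.event_window_months if m in months]
    if window and len(window) < len(months):
        uplifts["retweets"] = event_uplift(
            tables["monthly_activity"], window, "n_retweets"
        )
        uplifts["favorites"] = event_uplift(
            tables["monthly_activity"], window, "n_favorites"
        )

    manifest = {
        "seed": config.synthetic.seed if config.synthetic else None,
        "corpus_sha256": _sha256(corpus_path),
        "n_tweets_english": len(tweets),
        "n_users": len(profiles),
        "n_mentions": len(mentions),
        "n_communities": len(communities),
        "event_uplift": uplifts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )
    return PipelineResult(
        out_dir=out,
        tables=tables,
        n_tweets=len(tweets),
        n_users=len(profiles),
        uplifts=uplifts,
        manifest=manifest,
    )
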