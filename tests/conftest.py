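"""Shared fixtures: one small synthetic corpus reused across the suite."""

from __future__ import annotations

import pytest

from bowelwatch.io import parse_tweet
from bowelwatch.ner import build_lexicon
from bowelwatch.normalize import TweetNormalizer
from bowelwatch.profiler import Gazetteer, NameGenderTable, UserProfiler
from bowelwatch.sentiment import SentimentScorer
from bowelwatch.synthetic import SyntheticConfig, generate_corpus, generate_fixtures


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_tweets=400, n_users=250, seed=5)


@pytest.fixture(scope="session")
def corpus_and_truth(small_config):
    return generate_corpus(small_config)


@pytest.fixture(scope="session")
def fixtures_obj(small_config):
    return generate_fixtures(small_config)


@pytest.fixture(scope="session")
def lexicon(fixtures_obj):
    return build_lexicon(fixtures_obj.lexicon_raw)


@pytest.fixture(scope="session")
def normalizer(fixtures_obj):
    return TweetNormalizer(
        spelling_dictionary=fixtures_obj.spelling_dictionary,
        abbreviations=fixtures_obj.abbreviations,
    )


@pytest.fixture(scope="session")
def english_tweets(corpus_and_truth):
    records, _ = corpus_and_truth
    return [parse_tweet(r) for r in records if r["lang"] == "en"]


@pytest.fixture(scope="session")
def profiler_obj(fixtures_obj):
    return UserProfiler(
        name_table=NameGenderTable(fixtures_obj.name_gender),
        gazetteer=Gazetteer(fixtures_obj.gazetteer),
        aliases=fixtures_obj.aliases,
    )


@pytest.fixture(scope="session")
def scorer(fixtures_obj):
    return SentimentScorer(fixtures_obj.valence)
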