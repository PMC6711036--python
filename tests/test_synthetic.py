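"""Generator determinism, composition recovery, and fixture properties."""

from __future__ import annotations

from collections import Counter

import pytest
from scipy import stats

from bowelwatch.synthetic import (
    ConfigurationError,
    SyntheticConfig,
    corpus_to_jsonl,
    generate_corpus,
    generate_fixtures,
)


class TestConfigValidation:
    def test_bad_proportions_rejected(self):
        config = SyntheticConfig(user_type_mix={"organization": 0.5, "patient": 0.6, "expert": 0.0, "unknown": 0.0})
        with pytest.raises(ConfigurationError):
            config.validate()

    def test_bad_date_range_rejected(self):
        config = SyntheticConfig(date_range=("2018-08-01T00:00:00Z", "2018-02-01T00:00:00Z"))
        with pytest.raises(ConfigurationError):
            config.validate()

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(misspell_rate=1.5).validate()


class TestDeterminism:
    def test_same_seed_gives_identical_jsonl(self):
        config = SyntheticConfig(n_tweets=100, n_users=60, seed=7)
        first, _ = generate_corpus(config)
        second, _ = generate_corpus(SyntheticConfig(n_tweets=100, n_users=60, seed=7))
        assert corpus_to_jsonl(first) == corpus_to_jsonl(second)

    def test_different_seed_differs(self):
        a, _ = generate_corpus(SyntheticConfig(n_tweets=50, n_users=30, seed=1))
        b, _ = generate_corpus(SyntheticConfig(n_tweets=50, n_users=30, seed=2))
        assert corpus_to_jsonl(a) != corpus_to_jsonl(b)


class TestComposition:
    def test_non_english_fraction_in_binomial_band(self):
        records, _ = generate_corpus(
            SyntheticConfig(n_tweets=1000, n_users=300, frac_non_english=0.1, seed=1)
        )
        non_english = sum(1 for r in records if r["lang"] != "en")
        assert 60 <= non_english <= 140

    def test_zero_mention_rate_plants_nothing(self):
        config = SyntheticConfig(
            n_tweets=60,
            n_users=30,
            mention_rate_per_category={c: 0.0 for c in ("Disease", "Symptom", "Food and Diet", "Treatment", "Drug")},
            seed=3,
        )
        _, truth = generate_corpus(config)
        assert all(not t["mentions"] for t in truth.tweets.values())

    def test_user_type_and_gender_mix_recovered(self):
        """Empirical compositions at 2,000 users are chi-square-consistent
        with the config. A single draw rejects with probability alpha by
        construction, so the check runs five fixed seeds and allows at most
        one rejection at alpha = 0.01 (chance of a spurious failure under
        the null is about 1e-3)."""
        type_rejections = gender_rejections = 0
        for seed in range(5):
            config = SyntheticConfig(n_tweets=10, n_users=2000, seed=seed)
            _, truth = generate_corpus(config)
            types = Counter(u["type"] for u in truth.users.values())
            observed = [types[k] for k in config.user_type_mix]
            expected = [p * 2000 for p in config.user_type_mix.values()]
            type_rejections += stats.chisquare(observed, expected).pvalue <= 0.01
            individuals = [
                u for u in truth.users.values() if u["type"] in ("patient", "expert")
            ]
            genders = Counter(u["gender"] for u in individuals)
            observed_g = [genders[k] for k in config.gender_mix]
            expected_g = [p * len(individuals) for p in config.gender_mix.values()]
            gender_rejections += (
                stats.chisquare(observed_g, expected_g).pvalue <= 0.01
            )
        assert type_rejections <= 1
        assert gender_rejections <= 1


class TestGroundTruthInvariants:
    def test_planted_terms_exist_in_lexicon(self, corpus_and_truth, lexicon):
        _, truth = corpus_and_truth
        for info in truth.tweets.values():
            for term, category in info["mentions"]:
                assert term in lexicon.entries
                assert lexicon.entries[term][2] == category

    def test_perturbed_tokens_differ_from_originals(self, corpus_and_truth):
        _, truth = corpus_and_truth
        seen = 0
        for info in truth.tweets.values():
            for original, perturbed in info["misspellings"].items():
                assert perturbed != original
                seen += 1
        assert seen > 0

    def test_tweet_count_and_length_contract(self, corpus_and_truth, small_config):
        records, truth = corpus_and_truth
        assert len(records) == small_config.n_tweets
        assert len(truth.tweets) == small_config.n_tweets
        assert all(len(r["text"]) <= 280 for r in records)

    def test_event_window_scales_interactions(self):
        quiet = SyntheticConfig(n_tweets=600, n_users=100, seed=9, event_window=None)
        loud = SyntheticConfig(n_tweets=600, n_users=100, seed=9, interaction_multiplier=10.0)
        quiet_records, _ = generate_corpus(quiet)
        loud_records, _ = generate_corpus(loud)
        window = ("2018-05", "2018-06")

        def mean_interactions(records, inside):
            rows = [
                r["retweet_count"] + r["favorite_count"]
                for r in records
                if (r["created_at"][:7] in window) == inside
            ]
            return sum(rows) / len(rows)

        ratio_loud = mean_interactions(loud_records, True) / mean_interactions(loud_records, False)
        ratio_quiet = mean_interactions(quiet_records, True) / mean_interactions(quiet_records, False)
        assert ratio_loud > 3 * ratio_quiet


class TestFixtures:
    def test_gazetteer_has_ambiguous_city_pairs(self, fixtures_obj):
        names = Counter((e.name) for e in fixtures_obj.gazetteer)
        duplicated = {n for n, c in names.items() if c > 1}
        assert duplicated  # same name in distinct countries
        # one pair differs by time zone, one shares it
        by_name = {}
        for e in fixtures_obj.gazetteer:
            by_name.setdefault(e.name, []).append(e)
        assert any(
            len({e.time_zone for e in entries}) > 1
            for entries in by_name.values()
            if len(entries) > 1
        )
        assert any(
            len({e.time_zone for e in entries}) == 1 and len({e.country for e in entries}) > 1
            for entries in by_name.values()
            if len(entries) > 1
        )

    def test_lexicon_has_nested_pair_per_category(self, fixtures_obj, lexicon):
        raw_terms = {t for t, _, _ in fixtures_obj.lexicon_raw}
        assert {"bowel disease", "inflammatory bowel disease"} <= raw_terms
        for category in ("Disease", "Symptom", "Food and Diet", "Treatment", "Drug"):
            terms = lexicon.terms_in_category(category)
            assert any(
                a != b and f" {a} " in f" {b} " and len(b.split()) == len(a.split()) + 1
                for a in terms
                for b in terms
                if len(a.split()) == 2
            ), category

    def test_abbreviation_fixture(self, fixtures_obj):
        assert (
            fixtures_obj.abbreviations["sbbos"]
            == "small bowel bacterial overgrowth syndrome"
        )

    def test_cross_listed_term_present_in_raw(self, fixtures_obj):
        sources = {s for t, s, _ in fixtures_obj.lexicon_raw if t == "ginger"}
        assert len(sources) == 2

    def test_fixture_files_round_trip(self, tmp_path, fixtures_obj):
        from bowelwatch import io as bw_io

        fixtures_obj.write(tmp_path)
        gaz = bw_io.load_gazetteer(tmp_path / "gazetteer.tsv")
        assert len(gaz.entries) == len(fixtures_obj.gazetteer)
        assert (
            bw_io.load_abbreviations(tmp_path / "abbreviations.tsv")
            == fixtures_obj.abbreviations
        )
        assert bw_io.load_spelling_dictionary(
            tmp_path / "spelling_dictionary.tsv"
        ) == frozenset(fixtures_obj.spelling_dictionary)
        assert bw_io.load_valence(tmp_path / "valence.tsv") == fixtures_obj.valence
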