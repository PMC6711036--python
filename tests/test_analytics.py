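"""Summary-table arithmetic: shares, uplift, bucketing, URL and geo tables."""

from __future__ import annotations

import pandas as pd
import pytest

from bowelwatch.analytics import (
    event_uplift,
    geo_distribution,
    monthly_activity,
    sentiment_by_category,
    share_percentage,
    term_frequency_table,
    uplift_from_means,
    url_table,
    _hashtag_matches_term,
)
from bowelwatch.ner import EntityMention
from bowelwatch.normalize import RawTweet, default_lemmatizer
from bowelwatch.profiler import UserProfile


class TestSharePercentage:
    @pytest.mark.parametrize(
        "count, total, expected",
        [
            (11688, 32794, 35.64),
            (7975, 13295, 59.98),
            (0, 10, 0.00),
            (1, 3, 33.33),
            (1, 8, 12.50),
        ],
    )
    def test_half_up_rounding(self, count, total, expected):
        assert share_percentage(count, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            share_percentage(1, 0)

    def test_count_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            share_percentage(5, 4)


def _mention(tweet_id, term, category="Disease"):
    return EntityMention(tweet_id, term, category, (0, 1))


def _tweet(i, favorites=0, retweets=0, created="2018-02-10T00:00:00Z", hashtags=(), urls=(), user="u"):
    return RawTweet(
        id=f"t{i}",
        text="",
        created_at=created,
        favorite_count=favorites,
        retweet_count=retweets,
        hashtags=list(hashtags),
        urls=list(urls),
        user={"screen_name": user},
    )


class TestTermFrequencyTable:
    def test_counts_and_sums(self):
        tweets = {
            "t0": _tweet(0, favorites=2),
            "t1": _tweet(1, favorites=0),
            "t2": _tweet(2, favorites=5),
        }
        mentions = [_mention(f"t{i}", "diarrhea") for i in range(3)]
        # duplicate mention records must not inflate counts
        mentions.append(_mention("t0", "diarrhea"))
        row = term_frequency_table(mentions, tweets).iloc[0]
        assert row["n_tweets"] == 3
        assert row["n_favorites"] == 7
        assert row["n_hashtags"] == 0

    def test_hashtag_variation_matching(self):
        lem = default_lemmatizer
        assert _hashtag_matches_term("anxiety", "anxiety disorder", lem)
        assert _hashtag_matches_term("AnxietyDisorder", "anxiety disorder", lem)
        assert not _hashtag_matches_term("disorder", "anxiety disorder", lem)
        assert not _hashtag_matches_term("gluten", "anxiety disorder", lem)

    def test_hashtag_column_counts_variations(self):
        tweets = {"t0": _tweet(0, hashtags=["anxiety"]), "t1": _tweet(1, hashtags=["AnxietyDisorder", "IBD"])}
        frame = term_frequency_table(
            [_mention("t0", "anxiety disorder")], tweets
        )
        assert frame.iloc[0]["n_hashtags"] == 2

    def test_order_invariance(self, english_tweets, normalizer, lexicon):
        from bowelwatch.ner import recognize

        mentions = []
        for tweet in english_tweets[:100]:
            mentions.extend(recognize(normalizer.normalize(tweet), lexicon))
        tweets = {t.id: t for t in english_tweets[:100]}
        forward = term_frequency_table(mentions, tweets)
        backward = term_frequency_table(list(reversed(mentions)), tweets)
        pd.testing.assert_frame_equal(forward, backward)


class TestSentimentByCategory:
    def test_printed_distribution_reproduced(self):
        """A 5691/1686/3161 split yields the 54.00/16.00/30.00 shares."""
        mentions = []
        sentiments = {}
        i = 0
        for label, count in (("negative", 5691), ("neutral", 1686), ("positive", 3161)):
            for _ in range(count):
                mentions.append(_mention(f"t{i}", "diarrhea"))
                sentiments[f"t{i}"] = label
                i += 1
        row = sentiment_by_category(mentions, sentiments).iloc[0]
        assert (row["pct_negative"], row["pct_neutral"], row["pct_positive"]) == (
            54.00,
            16.00,
            30.00,
        )
        assert row["n_total"] == 10538

    def test_symmetric_thirds(self):
        mentions = [_mention(f"t{i}", "diarrhea") for i in range(3)]
        sentiments = {"t0": "negative", "t1": "neutral", "t2": "positive"}
        row = sentiment_by_category(mentions, sentiments).iloc[0]
        assert (
            row["pct_negative"] == row["pct_neutral"] == row["pct_positive"] == 33.33
        )

    def test_empty_category_omitted(self):
        frame = sentiment_by_category([], {})
        assert frame.empty

    def test_multi_category_tweet_counts_in_each(self):
        mentions = [
            _mention("t0", "diarrhea", "Disease"),
            _mention("t0", "pain", "Symptom"),
        ]
        frame = sentiment_by_category(mentions, {"t0": "negative"})
        assert set(frame["meta_category"]) == {"Disease", "Symptom"}
        assert (frame["n_total"] == 1).all()

    def test_account_filter(self):
        mentions = [_mention("t0", "pain"), _mention("t1", "pain")]
        sentiments = {"t0": "negative", "t1": "positive"}
        profiles = {
            "alice": UserProfile("alice", account_type="patient"),
            "borg": UserProfile("borg", account_type="organization"),
        }
        frame = sentiment_by_category(
            mentions,
            sentiments,
            profiles,
            {"t0": "alice", "t1": "borg"},
            account_filter="patient",
        )
        assert frame.iloc[0]["n_total"] == 1
        assert frame.iloc[0]["n_negative"] == 1

    def test_row_percentages_sum_to_100(self, english_tweets, normalizer, lexicon, scorer):
        from bowelwatch.ner import recognize

        mentions = []
        sentiments = {}
        for tweet in english_tweets:
            mentions.extend(recognize(normalizer.normalize(tweet), lexicon))
            sentiments[tweet.id] = scorer.label(tweet.text)
        frame = sentiment_by_category(mentions, sentiments)
        for _, row in frame.iterrows():
            total = row["pct_negative"] + row["pct_neutral"] + row["pct_positive"]
            assert total == pytest.approx(100.0, abs=0.02)


class TestMonthlyActivityAndUplift:
    def test_bucketing_and_contiguity(self):
        tweets = [
            _tweet(0, created="2018-02-03T10:00:00Z", retweets=2, favorites=1),
            _tweet(1, created="2018-02-27T10:00:00Z", retweets=1),
            _tweet(2, created="2018-04-01T00:00:00Z", favorites=4),
        ]
        frame = monthly_activity(tweets)
        assert list(frame["month"]) == ["2018-02", "2018-03", "2018-04"]
        assert list(frame["n_tweets"]) == [2, 0, 1]
        assert list(frame["n_interactions"]) == [4, 0, 4]

    def test_printed_retweet_uplift(self):
        months = [f"2018-0{m}" for m in range(2, 9)]
        values = [3314 if m in ("2018-05", "2018-06") else 1902 for m in months]
        frame = pd.DataFrame({"month": months, "n_retweets": values})
        assert event_uplift(frame, ["2018-05", "2018-06"], "n_retweets") == 174

    def test_printed_favorite_uplift(self):
        assert uplift_from_means(13585, 4130) == 329

    def test_identical_means_is_100(self):
        frame = pd.DataFrame({"month": ["2018-02", "2018-03"], "n_retweets": [7, 7]})
        assert event_uplift(frame, ["2018-03"], "n_retweets") == 100

    def test_empty_baseline_rejected(self):
        frame = pd.DataFrame({"month": ["2018-02"], "n_retweets": [7]})
        with pytest.raises(ValueError):
            event_uplift(frame, ["2018-02"], "n_retweets")


class TestUrlAndGeoTables:
    def test_sort_key_is_sum(self):
        tweets = [
            _tweet(0, retweets=31, favorites=50, urls=["https://a.example/x"]),
            _tweet(1, urls=["https://a.example/x"]),
            _tweet(2, retweets=1, urls=["https://b.example/y"]),
        ]
        frame = url_table(tweets)
        assert frame.iloc[0]["url"] == "https://a.example/x"
        assert frame.iloc[0]["sort_key"] == 83
        assert frame.iloc[0]["n_tweets"] == 2

    def test_no_urls_empty(self):
        assert url_table([_tweet(0)]).empty

    def test_poster_type_split(self):
        profiles = {"org1": UserProfile("org1", account_type="organization")}
        tweets = [
            _tweet(0, urls=["https://a.example/x"], user="org1"),
            _tweet(1, urls=["https://b.example/y"], user="someone"),
        ]
        org_rows = url_table(tweets, profiles, poster_type="organization")
        assert list(org_rows["url"]) == ["https://a.example/x"]

    def test_geo_counts(self):
        profiles = [
            UserProfile("a", location=("London", "United Kingdom", "Europe")),
            UserProfile("b", location=("London", "United Kingdom", "Europe")),
            UserProfile("c", location=("Mumbai", "India", "Asia")),
            UserProfile("d", location=None),
        ]
        countries, continents = geo_distribution(profiles)
        assert countries.set_index("country")["n_users"].to_dict() == {
            "United Kingdom": 2,
            "India": 1,
        }
        assert continents["n_users"].sum() == 3
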