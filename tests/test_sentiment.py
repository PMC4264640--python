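"""Count-difference scoring, polarity classification and aggregation."""

from datetime import datetime, timezone

import numpy as np
import pytest

from pharmasent.normalize import TokenizedTweet
from pharmasent.sentiment import (
    ScoredTweet,
    classify,
    monthly_counts,
    score_tweet,
    summarize_by_treatment,
)


@pytest.mark.parametrize(
    "tokens, expected",
    [
        (["love", "this", "great", "drug"], 2),
        ([], 0),
        (["bad", "bad", "nasty"], -3),  # occurrences, not unique words
        (["good", "bad"], 0),
        (["good"] * 5, 5),
    ],
)
def test_score_is_occurrence_count_difference(fixture_lexicon, tokens, expected):
    assert score_tweet(tokens, fixture_lexicon) == expected


def test_scoring_matches_brute_force_scan(fixture_lexicon):
    """Independent oracle: per-token lookup accumulating +/-1."""
    rng = np.random.default_rng(42)
    vocab = ["good", "great", "love", "bad", "nasty", "the", "drug", "day", "x9"]
    for _ in range(300):
        tokens = list(rng.choice(vocab, size=rng.integers(0, 20)))
        oracle = 0
        for tok in tokens:
            if tok in fixture_lexicon.positive:
                oracle += 1
            if tok in fixture_lexicon.negative:
                oracle -= 1
        assert score_tweet(tokens, fixture_lexicon) == oracle


@pytest.mark.parametrize(
    "score, polarity",
    [(1, "positive"), (0, "neutral"), (-2, "negative"), (100, "positive"), (-1, "negative")],
)
def test_polarity_partition(score, polarity):
    assert classify(score) == polarity


def _scored(scores, label="Gilenya", month=(2012, 1)):
    return [
        ScoredTweet(
            tweet_id=f"s{i}",
            treatments=frozenset({label}),
            month=month,
            score=s,
            polarity=classify(s),
        )
        for i, s in enumerate(scores)
    ]


def test_summary_arithmetic_balanced_scores(catalog):
    (summary,) = summarize_by_treatment(_scored([1, -1, 0]), catalog)
    assert summary.n_tweets == 3
    assert summary.prop_positive == pytest.approx(1 / 3)
    assert summary.prop_negative == pytest.approx(1 / 3)
    assert summary.prop_neutral == pytest.approx(1 / 3)
    assert summary.summed_score == 0 and summary.mean_score == 0


def test_singleton_summary_reports_zero_sd(catalog):
    (summary,) = summarize_by_treatment(_scored([2]), catalog)
    assert (summary.prop_positive, summary.prop_negative, summary.prop_neutral) == (1, 0, 0)
    assert summary.summed_score == 2 and summary.mean_score == 2 and summary.sd_score == 0


def test_equal_scores_have_zero_sample_sd(catalog):
    (summary,) = summarize_by_treatment(_scored([1, 1]), catalog)
    assert summary.summed_score == 2 and summary.mean_score == 1 and summary.sd_score == 0


def test_sample_sd_uses_n_minus_1(catalog):
    (summary,) = summarize_by_treatment(_scored([1, -1]), catalog)
    assert summary.sd_score == pytest.approx(np.std([1, -1], ddof=1))


def test_multi_treatment_tweet_contributes_to_each_summary(catalog):
    tweet = ScoredTweet(
        tweet_id="s0",
        treatments=frozenset({"Copaxone", "Gilenya"}),
        month=(2012, 1),
        score=1,
        polarity="positive",
    )
    summaries = summarize_by_treatment([tweet], catalog)
    assert {s.treatment_label for s in summaries} == {"Copaxone", "Gilenya"}
    assert all(s.n_tweets == 1 and s.summed_score == 1 for s in summaries)


def test_summaries_partition_and_sum_exactly(catalog):
    rng = np.random.default_rng(3)
    scores = list(rng.integers(-3, 4, size=500))
    (summary,) = summarize_by_treatment(_scored(scores), catalog)
    n = summary.n_tweets
    assert n * (summary.prop_positive + summary.prop_negative + summary.prop_neutral) == pytest.approx(n)
    assert summary.summed_score == sum(scores)


def test_adding_a_positive_token_translates_sum_and_mean(catalog, fixture_lexicon):
    rng = np.random.default_rng(4)
    base = [list(rng.choice(["good", "bad", "day"], size=5)) for _ in range(100)]
    scores = [score_tweet(t, fixture_lexicon) for t in base]
    shifted = [score_tweet(t + ["love"], fixture_lexicon) for t in base]
    (s0,) = summarize_by_treatment(_scored(scores), catalog)
    (s1,) = summarize_by_treatment(_scored(shifted), catalog)
    assert s1.summed_score == s0.summed_score + s0.n_tweets
    assert s1.mean_score == pytest.approx(s0.mean_score + 1)


def test_empty_input_yields_empty_summaries(catalog):
    assert summarize_by_treatment([], catalog) == []


# -- monthly grouping ---------------------------------------------------


def test_monthly_counts_fill_interior_gaps():
    scored = [
        ScoredTweet("a", frozenset({"Rebif"}), (2008, 1), 0, "neutral"),
        ScoredTweet("b", frozenset({"Rebif"}), (2008, 1), 0, "neutral"),
        ScoredTweet("c", frozenset({"Rebif"}), (2008, 3), 0, "neutral"),
    ]
    table = monthly_counts(scored)
    assert list(table["month"]) == ["2008-01", "2008-02", "2008-03"]
    assert list(table["n_tweets"]) == [2, 0, 1]


def test_monthly_counts_empty_and_singleton():
    assert monthly_counts([]).empty
    one = monthly_counts(
        [ScoredTweet("a", frozenset({"Rebif"}), (2010, 6), 1, "positive")]
    )
    assert len(one) == 1 and one.loc[0, "n_tweets"] == 1


def test_monthly_counts_sum_to_treatment_totals(catalog):
    rng = np.random.default_rng(5)
    scored = [
        ScoredTweet(
            f"m{i}",
            frozenset({rng.choice(["Rebif", "Tysabri"])}),
            (2009, int(rng.integers(1, 13))),
            0,
            "neutral",
        )
        for i in range(200)
    ]
    table = monthly_counts(scored)
    totals = table.groupby("treatment")["n_tweets"].sum()
    for label in ("Rebif", "Tysabri"):
        expected = sum(1 for tw in scored if label in tw.treatments)
        assert totals[label] == expected
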