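"""Lexicon sentiment scoring and per-treatment aggregation.

The score of a tweet is the count-difference statistic

    score = (# positive-lexicon token occurrences)
          - (# negative-lexicon token occurrences)

computed over normalized tokens; repeated tokens count once per
occurrence.  A tweet is classified positive if its score is > 0,
negative if < 0, and neutral at exactly 0.  There is no negation
handling ("not good" scores +1) and no valence weighting: the statistic
is the plain count difference, which keeps it transparent but blind to
the intricacies of human language (sarcasm, context).

Aggregation mirrors the standard per-treatment reporting: polarity
proportions, summed score, mean score and sample standard deviation per
treatment, plus tweet counts per calendar month.  A tweet matched to k
treatments contributes to all k summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus_io import SentimentLexicon, TreatmentCatalog
from .normalize import TokenizedTweet

__all__ = [
    "ScoredTweet",
    "TreatmentSummary",
    "score_tweet",
    "classify",
    "score_corpus",
    "summarize_by_treatment",
    "monthly_counts",
]


@dataclass(frozen=True)
class ScoredTweet:
    tweet_id: str
    treatments: frozenset[str]
    month: tuple[int, int]  # (year, month), UTC calendar
    score: int
    polarity: str  # "positive" | "negative" | "neutral"


@dataclass(frozen=True)
class TreatmentSummary:
    """One treatment's sentiment profile over its matched tweets."""

    treatment_label: str
    n_tweets: int
    prop_positive: float
    prop_negative: float
    prop_neutral: float
    summed_score: int
    mean_score: float
    sd_score: float


def score_tweet(tokens: Iterable[str], lexicon: SentimentLexicon) -> int:
    """Count-difference score over token occurrences."""
    score = 0
    for tok in tokens:
        if tok in lexicon.positive:
            score += 1
        elif tok in lexicon.negative:
            score -= 1
    return score


def classify(score: int) -> str:
    if score > 0:
        return "positive"
    if score < 0:
        return "negative"
    return "neutral"


def score_corpus(
    tokenized: Sequence[TokenizedTweet],
    timestamps: dict[str, datetime],
    lexicon: SentimentLexicon,
) -> list[ScoredTweet]:
    """Score every tokenized tweet; ``timestamps`` maps tweet_id -> UTC time."""
    out = []
    for tw in tokenized:
        s = score_tweet(tw.tokens, lexicon)
        ts = timestamps[tw.tweet_id]
        out.append(
            ScoredTweet(
                tweet_id=tw.tweet_id,
                treatments=tw.treatments,
                month=(ts.year, ts.month),
                score=s,
                polarity=classify(s),
            )
        )
    return out


def summarize_by_treatment(
    scored: Sequence[ScoredTweet], catalog: TreatmentCatalog
) -> list[TreatmentSummary]:
    """One summary per treatment with at least one tweet, in catalog order.

    Proportions partition exactly (they are counts over n); the summed
    score is integer-exact; the standard deviation is the sample (n-1)
    form, reported as 0 for a single tweet.
    """
    by_label: dict[str, list[int]] = {}
    for tw in scored:
        for label in tw.treatments:
            by_label.setdefault(label, []).append(tw.score)

    summaries = []
    for label in catalog.labels:
        scores = by_label.get(label)
        if not scores:
            continue
        arr = np.asarray(scores, dtype=np.int64)
        n = arr.size
        sd = float(arr.std(ddof=1)) if n > 1 else 0.0
        summaries.append(
            TreatmentSummary(
                treatment_label=label,
                n_tweets=n,
                prop_positive=float((arr > 0).sum()) / n,
                prop_negative=float((arr < 0).sum()) / n,
                prop_neutral=float((arr == 0).sum()) / n,
                summed_score=int(arr.sum()),
                mean_score=float(arr.sum()) / n,
                sd_score=sd,
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[TreatmentSummary]) -> pd.DataFrame:
    """Tabular form of the per-treatment summaries (one row per treatment)."""
    return pd.DataFrame(
        [
            {
                "treatment": s.treatment_label,
                "n_tweets": s.n_tweets,
                "prop_positive": s.prop_positive,
                "prop_negative": s.prop_negative,
                "prop_neutral": s.prop_neutral,
                "summed_score": s.summed_score,
                "mean_score": s.mean_score,
                "sd_score": s.sd_score,
            }
            for s in summaries
        ]
    )


def monthly_counts(scored: Sequence[ScoredTweet]) -> pd.DataFrame:
    """Tweet counts per (treatment, UTC calendar month).

    Months with zero tweets between a treatment's first and last active
    month are emitted explicitly with count 0, so time series plot
    without gaps.  Columns: treatment, month ("YYYY-MM"), n_tweets.
    """
    rows = [
        {"treatment": label, "month": pd.Period(year=tw.month[0], month=tw.month[1], freq="M")}
        for tw in scored
        for label in tw.treatments
    ]
    if not rows:
        return pd.DataFrame(columns=["treatment", "month", "n_tweets"])
    df = pd.DataFrame(rows)
    out_frames = []
    for label, grp in df.groupby("treatment", sort=True):
        counts = grp.groupby("month").size()
        full = pd.period_range(counts.index.min(), counts.index.max(), freq="M")
        counts = counts.reindex(full, fill_value=0)
        out_frames.append(
            pd.DataFrame(
                {
                    "treatment": label,
                    "month": counts.index.astype(str),
                    "n_tweets": counts.to_numpy(),
                }
            )
        )
    return pd.concat(out_frames, ignore_index=True)
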