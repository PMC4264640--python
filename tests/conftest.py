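from datetime import datetime, timezone

import pytest

from pharmasent.corpus_io import (
    Corpus,
    SentimentLexicon,
    TreatmentCatalog,
    TweetRecord,
)


@pytest.fixture(scope="session")
def catalog() -> TreatmentCatalog:
    return TreatmentCatalog.default()


@pytest.fixture(scope="session")
def fixture_lexicon() -> SentimentLexicon:
    """Tiny hand-checkable lexicon used throughout the unit tests."""
    return SentimentLexicon(
        positive=frozenset({"good", "great", "love"}),
        negative=frozenset({"bad", "nasty"}),
    )


def make_record(
    i: int,
    text: str,
    ts: datetime | None = None,
    source: str = "",
) -> TweetRecord:
    return TweetRecord(
        tweet_id=f"id{i:04d}",
        source_ref=source or f"https://twitter.com/u{i}/status/{i}",
        text=text,
        timestamp=ts or datetime(2010, 1, 1, 12, 0, i % 60, tzinfo=timezone.utc),
    )


def make_corpus(texts, **kwargs) -> Corpus:
    return Corpus(records=[make_record(i, t, **kwargs) for i, t in enumerate(texts)])
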