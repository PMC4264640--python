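"""Tweet-record, lexicon and stopword ingestion."""

import json
import random
from datetime import datetime, timezone

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmasent.corpus_io import (
    Corpus,
    LexiconError,
    SentimentLexicon,
    TreatmentCatalog,
    TweetRecord,
    read_lexicon,
    read_stopwords,
    read_tweets,
    write_tweets,
)

from .conftest import make_corpus, make_record


def _write_jsonl(path, rows):
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write(json.dumps(row) + "\n")


GOOD_ROWS = [
    {
        "tweet_id": f"t{i}",
        "permalink": f"https://twitter.com/u/status/{i}",
        "text": f"tweet number {i}",
        "created_at": f"2012-03-0{i + 1}T10:00:00+00:00",
    }
    for i in range(3)
]


@pytest.mark.parametrize("dialect", ["jsonl", "csv"])
def test_well_formed_records_ingest_in_order(tmp_path, dialect):
    corpus = Corpus(
        records=[
            TweetRecord(
                tweet_id=r["tweet_id"],
                source_ref=r["permalink"],
                text=r["text"],
                timestamp=datetime.fromisoformat(r["created_at"]),
            )
            for r in GOOD_ROWS
        ]
    )
    path = tmp_path / f"tweets.{dialect}"
    write_tweets(corpus, path, dialect)
    loaded, report = read_tweets(path, dialect)
    assert [r.tweet_id for r in loaded.records] == ["t0", "t1", "t2"]
    assert report.n_loaded == 3 and report.n_read == 3


def test_empty_text_records_dropped_and_counted(tmp_path):
    rows = [GOOD_ROWS[0], {**GOOD_ROWS[1], "text": ""}, GOOD_ROWS[2]]
    path = tmp_path / "tweets.jsonl"
    _write_jsonl(path, rows)
    corpus, report = read_tweets(path)
    assert len(corpus) == 2
    assert report.n_empty_text == 1


def test_bad_timestamp_and_missing_field_are_skipped_not_fatal(tmp_path):
    rows = [
        GOOD_ROWS[0],
        {**GOOD_ROWS[1], "created_at": "not a date"},
        {k: v for k, v in GOOD_ROWS[2].items() if k != "permalink"},
    ]
    path = tmp_path / "tweets.jsonl"
    _write_jsonl(path, rows)
    corpus, report = read_tweets(path)
    assert [r.tweet_id for r in corpus.records] == ["t0"]
    assert report.n_bad_timestamp == 1 and report.n_missing_field == 1


def test_missing_file_is_fatal(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_tweets(tmp_path / "absent.jsonl")


def test_naive_timestamps_are_taken_as_utc(tmp_path):
    path = tmp_path / "tweets.jsonl"
    _write_jsonl(path, [{**GOOD_ROWS[0], "created_at": "2012-03-01T10:00:00"}])
    corpus, _ = read_tweets(path)
    assert corpus.records[0].timestamp == datetime(2012, 3, 1, 10, tzinfo=timezone.utc)


_text_alphabet = st.characters(
    codec="utf-8", exclude_categories=("Cs", "Cc"), exclude_characters="\r\n"
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    texts=st.lists(
        st.text(alphabet=_text_alphabet, min_size=1).filter(lambda s: s.strip()),
        min_size=1,
        max_size=8,
    ),
    dialect=st.sampled_from(["jsonl", "csv"]),
)
def test_round_trip_is_identity_on_all_fields(tmp_path_factory, texts, dialect):
    corpus = make_corpus(texts)
    path = tmp_path_factory.mktemp("rt") / f"c.{dialect}"
    write_tweets(corpus, path, dialect)
    loaded, _ = read_tweets(path, dialect)
    assert [
        (r.tweet_id, r.source_ref, r.text, r.timestamp) for r in loaded.records
    ] == [(r.tweet_id, r.source_ref, r.text, r.timestamp) for r in corpus.records]


# -- lexicon ------------------------------------------------------------


def _write_terms(path, terms):
    path.write_text("\n".join(terms) + "\n", encoding="utf-8")


def test_lexicon_counts_comments_and_blanks(tmp_path):
    _write_terms(tmp_path / "pos.txt", ["; opinion words", "", "good", "great", "love"])
    _write_terms(tmp_path / "neg.txt", ["bad", "; a comment", "nasty", ""])
    lex = read_lexicon(tmp_path / "pos.txt", tmp_path / "neg.txt")
    assert (len(lex.positive), len(lex.negative)) == (3, 2)


def test_lexicon_comment_only_files_yield_empty_sets(tmp_path):
    _write_terms(tmp_path / "pos.txt", ["; nothing", ""])
    _write_terms(tmp_path / "neg.txt", [";", ""])
    lex = read_lexicon(tmp_path / "pos.txt", tmp_path / "neg.txt")
    assert (len(lex.positive), len(lex.negative)) == (0, 0)


def test_lexicon_casefolds_and_dedups(tmp_path):
    _write_terms(tmp_path / "pos.txt", ["Good", "good"])
    _write_terms(tmp_path / "neg.txt", ["bad"])
    lex = read_lexicon(tmp_path / "pos.txt", tmp_path / "neg.txt")
    assert lex.positive == frozenset({"good"})


def test_lexicon_overlap_is_fatal_and_names_the_term(tmp_path):
    _write_terms(tmp_path / "pos.txt", ["good", "odd"])
    _write_terms(tmp_path / "neg.txt", ["bad", "odd"])
    with pytest.raises(LexiconError, match="odd"):
        read_lexicon(tmp_path / "pos.txt", tmp_path / "neg.txt")


def test_multiword_lexicon_entries_rejected(tmp_path):
    _write_terms(tmp_path / "pos.txt", ["very good"])
    _write_terms(tmp_path / "neg.txt", ["bad"])
    with pytest.raises(LexiconError, match="multiword"):
        read_lexicon(tmp_path / "pos.txt", tmp_path / "neg.txt")


def test_lexicon_loading_is_order_independent(tmp_path):
    terms = ["alpha", "bravo", "charlie", "delta"]
    shuffled = terms[:]
    random.Random(7).shuffle(shuffled)
    _write_terms(tmp_path / "a.txt", terms)
    _write_terms(tmp_path / "b.txt", shuffled)
    _write_terms(tmp_path / "neg.txt", ["zulu"])
    lex_a = read_lexicon(tmp_path / "a.txt", tmp_path / "neg.txt")
    lex_b = read_lexicon(tmp_path / "b.txt", tmp_path / "neg.txt")
    assert lex_a.positive == lex_b.positive


def test_overlapping_sets_rejected_at_construction():
    with pytest.raises(LexiconError):
        SentimentLexicon(positive=frozenset({"x"}), negative=frozenset({"x"}))


# -- stopwords ----------------------------------------------------------


@pytest.mark.parametrize(
    "lines, expected",
    [
        (["the", "and", "of"], {"the", "and", "of"}),
        ([], set()),
        (["The", "the"], {"the"}),
    ],
)
def test_stopword_reading(tmp_path, lines, expected):
    path = tmp_path / "stop.txt"
    path.write_text("\n".join(lines), encoding="utf-8")
    assert read_stopwords(path) == frozenset(expected)


# -- treatment catalog --------------------------------------------------


def test_default_catalog_structure(catalog):
    assert len(catalog.labels) == 11
    assert catalog.terms_for("Betaferon") == ("betaferon", "betaseron")
    singles = [lab for lab in catalog.labels if lab != "Betaferon"]
    assert all(len(catalog.terms_for(lab)) == 1 for lab in singles)
    assert len(set(catalog.match_terms)) == len(catalog.match_terms) == 12


def test_catalog_rejects_duplicate_match_terms():
    with pytest.raises(ValueError, match="two entries"):
        TreatmentCatalog((("A", ("drugx",)), ("B", ("drugx",))))
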