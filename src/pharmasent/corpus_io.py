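"""Reading and writing tweet corpora, sentiment lexicons, stopword lists
and the treatment catalog.

Tweet records travel in a record-per-line JSON dialect (``jsonl``) or a
delimited (``csv``) dialect with the same field names.  The field names
``permalink`` and ``created_at`` are kept deliberately close to the data
classes of the archive service the corpus format emulates: ``permalink``
is the URL-like source string of a tweet, ``text`` its body.

Sentiment lexicons use the opinion-lexicon dialect: one term per line,
lines starting with ``;`` are comments, blank lines are ignored.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TweetRecord",
    "Corpus",
    "SentimentLexicon",
    "TreatmentCatalog",
    "LoadReport",
    "LexiconError",
    "read_tweets",
    "write_tweets",
    "read_lexicon",
    "read_stopwords",
]


class LexiconError(ValueError):
    """Raised when a sentiment lexicon fails validation at load time."""


@dataclass(frozen=True)
class TweetRecord:
    """One tweet: opaque id, URL-like source string, raw text, UTC timestamp.

    ``treatments`` is empty at ingestion and is filled by treatment
    matching; it only ever contains labels from the treatment catalog.
    """

    tweet_id: str
    source_ref: str
    text: str
    timestamp: datetime
    treatments: frozenset[str] = frozenset()

    def with_treatments(self, labels: Iterable[str]) -> "TweetRecord":
        return replace(self, treatments=frozenset(labels))


@dataclass
class Corpus:
    """An ordered tweet collection plus the names of operations applied to it.

    Filters preserve record order; ``provenance`` grows monotonically and
    never records the same operation twice.
    """

    records: list[TweetRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def derive(self, records: Sequence[TweetRecord], op_name: str) -> "Corpus":
        """New corpus with ``records`` and ``op_name`` appended to provenance."""
        prov = list(self.provenance)
        if op_name not in prov:
            prov.append(op_name)
        return Corpus(records=list(records), provenance=prov)


@dataclass(frozen=True)
class SentimentLexicon:
    """Positive and negative opinion-term sets.

    Terms are lowercase, single-word, and the two sets are disjoint;
    violations are ingestion errors, not silent precedence rules, because
    the count-difference score is ambiguous for a term on both lists.
    """

    positive: frozenset[str]
    negative: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.positive & self.negative
        if overlap:
            raise LexiconError(
                "term(s) present in both polarity lists: "
                + ", ".join(sorted(overlap)[:10])
            )


#: The 11 disease-modifying-therapy brand names used for treatment matching.
#: Betaferon and Betaseron are the same interferon product under two brand
#: names and share one catalog entry.
DEFAULT_TREATMENT_ENTRIES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("Aubagio", ("aubagio",)),
    ("Avonex", ("avonex",)),
    ("Betaferon", ("betaferon", "betaseron")),
    ("Copaxone", ("copaxone",)),
    ("Extavia", ("extavia",)),
    ("Gilenya", ("gilenya",)),
    ("Lemtrada", ("lemtrada",)),
    ("Novantrone", ("novantrone",)),
    ("Rebif", ("rebif",)),
    ("Tecfidera", ("tecfidera",)),
    ("Tysabri", ("tysabri",)),
)


@dataclass(frozen=True)
class TreatmentCatalog:
    """Treatment labels and the lowercase brand-name terms that match them."""

    entries: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, terms in self.entries:
            if not terms:
                raise ValueError(f"catalog entry {label!r} has no match terms")
            for t in terms:
                tl = t.lower()
                if tl in seen:
                    raise ValueError(f"match term {t!r} appears in two entries")
                seen.add(tl)

    @classmethod
    def default(cls) -> "TreatmentCatalog":
        return cls(DEFAULT_TREATMENT_ENTRIES)

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.entries]

    @property
    def match_terms(self) -> list[str]:
        """All lowercase match terms across entries."""
        return [t.lower() for _, terms in self.entries for t in terms]

    def terms_for(self, label: str) -> tuple[str, ...]:
        for lab, terms in self.entries:
            if lab == label:
                return tuple(t.lower() for t in terms)
        raise KeyError(label)


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping for records dropped at ingestion."""

    n_read: int
    n_loaded: int
    n_empty_text: int
    n_bad_timestamp: int
    n_missing_field: int


_REQUIRED_KEYS = ("tweet_id", "permalink", "text", "created_at")


def _parse_timestamp(value: str) -> datetime:
    """ISO-8601 to an aware UTC datetime; naive input is taken as UTC."""
    ts = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _record_from_mapping(raw: dict, where: str) -> TweetRecord | None:
    missing = [k for k in _REQUIRED_KEYS if raw.get(k) in (None, "")]
    # empty text is reported separately from a missing column
    if missing and missing != ["text"]:
        logger.warning("%s: missing field(s) %s; record skipped", where, missing)
        raise KeyError(where)
    text = str(raw.get("text") or "")
    if not text.strip():
        return None
    try:
        ts = _parse_timestamp(raw["created_at"])
    except (ValueError, TypeError):
        logger.warning("%s: unparseable timestamp %r; record skipped", where, raw["created_at"])
        raise ValueError(where)
    return TweetRecord(
        tweet_id=str(raw["tweet_id"]),
        source_ref=str(raw["permalink"]),
        text=text,
        timestamp=ts,
    )


def read_tweets(path: str | Path, dialect: str = "jsonl") -> tuple[Corpus, LoadReport]:
    """Read a tweet-record file into a :class:`Corpus`, preserving input order.

    Records with empty text or an unparseable timestamp are dropped and
    counted in the returned :class:`LoadReport`; a missing file is a fatal
    ``FileNotFoundError``.  Undecodable bytes are replaced, not fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("jsonl", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")

    rows: list[dict]
    if dialect == "jsonl":
        rows = []
        with open(path, encoding="utf-8", errors="replace") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
    else:
        with open(path, encoding="utf-8", errors="replace", newline="") as fh:
            rows = list(csv.DictReader(fh))

    records: list[TweetRecord] = []
    n_empty = n_bad_ts = n_missing = 0
    for i, raw in enumerate(rows):
        where = f"{path.name}:{i + 1}"
        try:
            rec = _record_from_mapping(raw, where)
        except KeyError:
            n_missing += 1
            continue
        except ValueError:
            n_bad_ts += 1
            continue
        if rec is None:
            n_empty += 1
            continue
        records.append(rec)

    report = LoadReport(
        n_read=len(rows),
        n_loaded=len(records),
        n_empty_text=n_empty,
        n_bad_timestamp=n_bad_ts,
        n_missing_field=n_missing,
    )
    return Corpus(records=records, provenance=[f"read_tweets[{dialect}]"]), report


def write_tweets(corpus: Corpus, path: str | Path, dialect: str = "jsonl") -> None:
    """Write a corpus in the jsonl or csv dialect (UTF-8, ISO-8601 timestamps)."""
    path = Path(path)
    if dialect == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in corpus.records:
                fh.write(
                    json.dumps(
                        {
                            "tweet_id": rec.tweet_id,
                            "permalink": rec.source_ref,
                            "text": rec.text,
                            "created_at": rec.timestamp.isoformat(),
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif dialect == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_REQUIRED_KEYS)
            for rec in corpus.records:
                writer.writerow(
                    [rec.tweet_id, rec.source_ref, rec.text, rec.timestamp.isoformat()]
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_term_lines(path: str | Path) -> list[str]:
    terms = []
    with open(path, encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(";"):
                continue
            terms.append(line.lower())
    return terms


def read_lexicon(positive_path: str | Path, negative_path: str | Path) -> SentimentLexicon:
    """Load a sentiment lexicon from two opinion-lexicon-dialect files.

    Terms are lowercased and deduplicated.  Multiword terms are rejected
    (the scorer matches single tokens, so a multiword entry could never
    fire and would silently distort reported lexicon sizes).  A term on
    both lists is a fatal error naming the term.
    """
    pos_terms = _read_term_lines(positive_path)
    neg_terms = _read_term_lines(negative_path)
    for term in pos_terms + neg_terms:
        if any(ch.isspace() for ch in term):
            raise LexiconError(f"multiword lexicon entry not supported: {term!r}")
    lex = SentimentLexicon(positive=frozenset(pos_terms), negative=frozenset(neg_terms))
    logger.info(
        "loaded lexicon: %d positive, %d negative terms",
        len(lex.positive),
        len(lex.negative),
    )
    return lex


def read_stopwords(path: str | Path) -> frozenset[str]:
    """One term per line; returns a lowercased, deduplicated set."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return frozenset(_read_term_lines(path))
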