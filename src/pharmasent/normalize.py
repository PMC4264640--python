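"""Tweet tokenization and normalization for scoring and word counting.

Tweets are short and noisy: typos, ad-hoc abbreviations, character
elongation ("soooo"), hashtags, @-mentions, URLs and emoticons are all
common and defeat standard text tooling.  This module applies a small,
deterministic normalizer:

1. lowercase;
2. delete URLs (http/https/www spans) and @-mentions;
3. strip the ``#`` marker from hashtags, keeping the tag word;
4. map a fixed emoticon table to sentiment-bearing sentinel words
   (``:)`` -> "good", ``:(`` -> "bad"), so emoticons contribute to the
   score — the mapping is plain data and configurable;
5. collapse characters repeated three or more times to two ("soooo" ->
   "soo"): collapsing to two never corrupts legitimate double letters
   ("good"), at the cost of residual misses such as "loove";
6. split on any non-alphanumeric character (apostrophes are removed, so
   contractions split);
7. expand tokens found in the abbreviation table ("gr8" -> "great").

Drug brand names are never altered: catalog match terms bypass steps 5
and 7 unchanged, so treatment labels recomputed from tokens always equal
those computed from the raw text.

The procedure is idempotent: normalizing the space-joined token list
returns the same tokens.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .corpus_io import TreatmentCatalog

__all__ = [
    "TokenizedTweet",
    "normalize_tweet",
    "normalize_corpus",
    "load_emoticons",
    "load_abbreviations",
    "default_emoticons",
    "default_abbreviations",
]

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)")
_MENTION_RE = re.compile(r"@\w+")
_ELONG_RE = re.compile(r"(.)\1{2,}")
_SPLIT_RE = re.compile(r"[^a-z0-9]+")
_TOKEN_OK = re.compile(r"^[a-z0-9]+$")


@dataclass(frozen=True)
class TokenizedTweet:
    """A tweet reduced to lowercase tokens, with treatments copied through."""

    tweet_id: str
    tokens: tuple[str, ...]
    treatments: frozenset[str] = frozenset()


def _validate_table(table: Mapping[str, str], kind: str) -> dict[str, str]:
    """Replacement values must be stable under re-normalization, or the
    normalizer would not be idempotent."""
    out: dict[str, str] = {}
    for key, value in table.items():
        words = value.lower().split()
        for w in words:
            if not _TOKEN_OK.match(w):
                raise ValueError(f"{kind} expansion {value!r} is not plain tokens")
            if _ELONG_RE.search(w):
                raise ValueError(f"{kind} expansion {value!r} contains an elongation")
            if w in table:
                raise ValueError(f"{kind} expansion {value!r} is itself a table key")
        out[key.lower()] = " ".join(words)
    return out


def _read_two_column_csv(path) -> dict[str, str]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if len(header) != 2:
            raise ValueError(f"{path}: expected a two-column table")
        return {row[0]: row[1] for row in reader if row}


def load_emoticons(path: str | Path) -> dict[str, str]:
    """Two-column csv mapping emoticon -> sentinel word."""
    return _validate_table(_read_two_column_csv(path), "emoticon")


def load_abbreviations(path: str | Path) -> dict[str, str]:
    """Two-column csv mapping slang token -> expansion (may be multiword)."""
    return _validate_table(_read_two_column_csv(path), "abbreviation")


def _package_table(filename: str) -> dict[str, str]:
    ref = resources.files("pharmasent.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return _read_two_column_csv(path)


def default_emoticons() -> dict[str, str]:
    """The packaged emoticon table (about 20 common western emoticons)."""
    return _validate_table(_package_table("emoticons.csv"), "emoticon")


def default_abbreviations() -> dict[str, str]:
    """The packaged tweet-slang table (about 30 common abbreviations)."""
    return _validate_table(_package_table("abbreviations.csv"), "abbreviation")


def normalize_tweet(
    text: str,
    catalog: TreatmentCatalog,
    abbreviations: Mapping[str, str] | None = None,
    emoticons: Mapping[str, str] | None = None,
) -> tuple[str, ...]:
    """Normalize one tweet text to a tuple of lowercase tokens.

    ``abbreviations`` and ``emoticons`` default to the packaged tables;
    pass ``{}`` to disable either step.
    """
    if abbreviations is None:
        abbreviations = default_abbreviations()
    if emoticons is None:
        emoticons = default_emoticons()
    drug_terms = frozenset(catalog.match_terms)

    s = text.lower()
    s = _URL_RE.sub(" ", s)
    s = _MENTION_RE.sub(" ", s)
    s = s.replace("#", "")
    # longest emoticon first so ":-(" wins over ":("
    for emo in sorted(emoticons, key=len, reverse=True):
        if emo in s:
            s = s.replace(emo, f" {emoticons[emo]} ")

    tokens: list[str] = []
    for tok in _SPLIT_RE.split(s):
        if not tok:
            continue
        if tok in drug_terms:
            tokens.append(tok)
            continue
        tok = _ELONG_RE.sub(r"\1\1", tok)
        if tok in abbreviations:
            tokens.extend(abbreviations[tok].split())
        else:
            tokens.append(tok)
    return tuple(tokens)


def normalize_corpus(
    records,
    catalog: TreatmentCatalog,
    abbreviations: Mapping[str, str] | None = None,
    emoticons: Mapping[str, str] | None = None,
) -> list[TokenizedTweet]:
    """Normalize every record of a (matched) corpus."""
    if abbreviations is None:
        abbreviations = default_abbreviations()
    if emoticons is None:
        emoticons = default_emoticons()
    return [
        TokenizedTweet(
            tweet_id=rec.tweet_id,
            tokens=normalize_tweet(rec.text, catalog, abbreviations, emoticons),
            treatments=rec.treatments,
        )
        for rec in records
    ]
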