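"""Per-treatment term-frequency rankings.

Replaces graphical word clouds with deterministic ranked lists: token
occurrences are counted over all tweets matched to a treatment,
stopwords and every drug brand name are excluded, and the top-k tokens
are returned sorted by descending count with lexicographic tie-breaks
(graphical rendering and the original service's unpublished stopword
list are deliberately out of scope).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .corpus_io import TreatmentCatalog, read_stopwords
from .normalize import TokenizedTweet

__all__ = ["TermRanking", "top_words", "default_stopwords", "rankings_to_frame"]


@dataclass(frozen=True)
class TermRanking:
    """Ordered (token, count) list for one treatment; counts non-increasing."""

    treatment_label: str
    entries: tuple[tuple[str, int], ...]


def default_stopwords() -> frozenset[str]:
    """The packaged English common-word list (configurable by callers)."""
    ref = resources.files("pharmasent.data").joinpath("stopwords_en.txt")
    with resources.as_file(ref) as path:
        return read_stopwords(path)


def top_words(
    tokenized: Sequence[TokenizedTweet],
    treatment: str,
    stopwords: Iterable[str],
    catalog: TreatmentCatalog,
    k: int,
) -> TermRanking:
    """Top-k tokens for one treatment, excluding stopwords and drug names.

    Returns fewer than k entries when the remaining vocabulary is
    smaller.  An unknown treatment label is a fatal error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if treatment not in catalog.labels:
        raise ValueError(f"unknown treatment label {treatment!r}")
    excluded = frozenset(stopwords) | frozenset(catalog.match_terms)
    counts: Counter[str] = Counter()
    for tw in tokenized:
        if treatment in tw.treatments:
            counts.update(tok for tok in tw.tokens if tok not in excluded)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return TermRanking(treatment_label=treatment, entries=tuple(ordered[:k]))


def rankings_to_frame(rankings: Sequence[TermRanking]) -> pd.DataFrame:
    """Long-form table: treatment, rank (1-based), token, count."""
    rows = [
        {"treatment": r.treatment_label, "rank": i + 1, "token": tok, "count": cnt}
        for r in rankings
        for i, (tok, cnt) in enumerate(r.entries)
    ]
    return pd.DataFrame(rows, columns=["treatment", "rank", "token", "count"])
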