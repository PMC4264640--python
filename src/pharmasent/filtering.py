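"""The three corpus-cleaning stages applied before sentiment analysis.

1. ``deduplicate`` — collapse directly copied retweets so each distinct
   tweet text is scored once.
2. ``apply_keyword_filter`` with the stock/share keyword lists — drop
   stock-market and share-price tweets.
3. ``apply_keyword_filter`` with the manufacturer-name list — drop tweets
   naming the pharmaceutical companies behind the treatments (a stringent
   filter: it removes most remaining finance tweets at the cost of some
   patient tweets).

Plus ``match_treatments``, which assigns each surviving tweet to the
treatments whose brand names it mentions.

All keyword matching is case-insensitive SUBSTRING matching on the raw
(un-normalized) text and source string: the filter lists contain multiword
terms ("dow jones") and a punctuation-bearing term ("business:") that
cannot be single tokens.  Consequence: "sec" also fires inside words such
as "second"; this over-removal is inherent to the rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .corpus_io import Corpus, TreatmentCatalog, TweetRecord

__all__ = [
    "FilterReport",
    "KeywordFilterSpec",
    "STOCK_FILTER",
    "COMPANY_FILTER",
    "deduplicate",
    "apply_keyword_filter",
    "match_treatments",
    "strip_retweet_prefix",
]


@dataclass(frozen=True)
class FilterReport:
    """Per-stage bookkeeping: ``n_in == n_removed + n_out`` always holds."""

    stage_name: str
    n_in: int
    n_removed: int
    n_out: int
    removed_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.n_in == self.n_removed + self.n_out
        assert len(self.removed_ids) == self.n_removed


@dataclass(frozen=True)
class KeywordFilterSpec:
    """Lowercase substrings matched against the source string and the text."""

    name: str
    source_terms: tuple[str, ...]
    text_terms: tuple[str, ...]

    def matches(self, record: TweetRecord) -> bool:
        src = record.source_ref.lower()
        txt = record.text.lower()
        return any(t in src for t in self.source_terms) or any(
            t in txt for t in self.text_terms
        )


#: Stage-2 filter: share-price / stock-market tweets.
STOCK_FILTER = KeywordFilterSpec(
    name="stock_filter",
    source_terms=("market_jp", "thestreet", "rtebusiness", "pharma", "pharmsales"),
    text_terms=(
        "bloomberg",
        "forbes",
        "dow jones",
        "financial times",
        "stockpickr",
        "marketwatch",
        "business:",
        "profit",
        "shares",
        "sec",
    ),
)

#: Stage-3 filter: tweets naming the manufacturing companies.
COMPANY_FILTER = KeywordFilterSpec(
    name="company_filter",
    source_terms=(),
    text_terms=(
        "novartis",
        "elan",
        "biogen",
        "merck",
        "bayer",
        "genzyme",
        "sanofi",
        "teva",
        "serono",
    ),
)

_RT_PREFIX = re.compile(r"^\s*rt\s+@\w+\s*:\s*", re.IGNORECASE)


def strip_retweet_prefix(text: str) -> str:
    """Strip one leading ``RT @handle:`` prefix and surrounding whitespace."""
    return _RT_PREFIX.sub("", text, count=1).strip()


def deduplicate(corpus: Corpus) -> tuple[Corpus, FilterReport]:
    """Remove directly copied retweets, keeping one record per distinct text.

    Two records are copies if their texts are byte-identical after
    stripping a leading retweet prefix.  The survivor of a duplicate group
    is the earliest by timestamp (the original precedes its retweets),
    ties broken by input order; output preserves input order.
    """
    keys = [strip_retweet_prefix(rec.text) for rec in corpus.records]
    keeper: dict[str, int] = {}
    for i, key in enumerate(keys):
        j = keeper.get(key)
        if j is None or (corpus.records[i].timestamp, i) < (
            corpus.records[j].timestamp,
            j,
        ):
            keeper[key] = i
    kept_idx = set(keeper.values())
    retained = [rec for i, rec in enumerate(corpus.records) if i in kept_idx]
    removed = tuple(
        rec.tweet_id for i, rec in enumerate(corpus.records) if i not in kept_idx
    )
    report = FilterReport(
        stage_name="deduplicate",
        n_in=len(corpus.records),
        n_removed=len(removed),
        n_out=len(retained),
        removed_ids=removed,
    )
    return corpus.derive(retained, "deduplicate"), report


def apply_keyword_filter(
    corpus: Corpus, spec: KeywordFilterSpec, stage_name: str | None = None
) -> tuple[Corpus, FilterReport]:
    """Drop every record matching ``spec``; retained order is preserved."""
    stage = stage_name or spec.name
    retained, removed = [], []
    for rec in corpus.records:
        (removed if spec.matches(rec) else retained).append(rec)
    report = FilterReport(
        stage_name=stage,
        n_in=len(corpus.records),
        n_removed=len(removed),
        n_out=len(retained),
        removed_ids=tuple(rec.tweet_id for rec in removed),
    )
    return corpus.derive(retained, stage), report


def match_treatments(
    corpus: Corpus, catalog: TreatmentCatalog
) -> tuple[Corpus, FilterReport]:
    """Fill each record's treatment set by case-insensitive substring scan.

    A record matching several brand names carries every matched label (it
    will later contribute to each matched treatment's summary); records
    matching no treatment are dropped and counted.
    """
    if not catalog.entries:
        raise ValueError("treatment catalog is empty")
    retained, removed = [], []
    for rec in corpus.records:
        txt = rec.text.lower()
        labels = {
            label
            for label, terms in catalog.entries
            if any(t.lower() in txt for t in terms)
        }
        if labels:
            retained.append(rec.with_treatments(labels))
        else:
            removed.append(rec)
    report = FilterReport(
        stage_name="match_treatments",
        n_in=len(corpus.records),
        n_removed=len(removed),
        n_out=len(retained),
        removed_ids=tuple(rec.tweet_id for rec in removed),
    )
    return corpus.derive(retained, "match_treatments"), report
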