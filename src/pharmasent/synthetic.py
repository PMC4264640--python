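"""Synthetic tweet-corpus generator with exact ground truth.

The archive the original treatment-opinion corpus came from no longer
exists, so every pipeline stage is exercised on generated corpora whose
structure mirrors realistic corpus conditions: per-treatment tweet volumes and
first-activity months, per-treatment positive/negative/neutral mixture
weights, exact-duplicate retweets at a configurable rate, and
contaminating finance/company tweets that mention a drug (as real
financial tweets do) and must therefore be removed by the keyword
filters, not by treatment matching.

Ground truth is exact, not approximate, by construction:

* sentiment words are planted from the loaded lexicon itself, so the
  generator and the scorer share one vocabulary source;
* filler vocabulary is screened at generation time against the lexicon,
  the filter keyword lists, the abbreviation table and the drug names,
  so a clean tweet's score equals its intended score and no clean tweet
  can be caught by a filter;
* typo noise (character elongation) is applied to filler words only and
  re-screened after the normalizer's collapse rule, so it never changes
  a score;
* every non-duplicate text is unique, so deduplication removes exactly
  the injected retweet copies.

Same config + same seed -> byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus_io import (
    Corpus,
    SentimentLexicon,
    TreatmentCatalog,
    TweetRecord,
)
from .filtering import COMPANY_FILTER, STOCK_FILTER, KeywordFilterSpec
from .normalize import _ELONG_RE, default_abbreviations

__all__ = [
    "TreatmentMix",
    "SyntheticCorpusConfig",
    "GroundTruth",
    "generate_corpus",
    "expected_summary",
    "default_lexicon",
]


def default_lexicon() -> SentimentLexicon:
    """The packaged synthetic stand-in lexicon (not the published lists)."""
    from importlib import resources

    from .corpus_io import read_lexicon

    data = resources.files("pharmasent.data")
    with resources.as_file(data.joinpath("synthetic_positive_words.txt")) as pos:
        with resources.as_file(data.joinpath("synthetic_negative_words.txt")) as neg:
            return read_lexicon(pos, neg)


#: Neutral filler vocabulary; screened again at generation time.
FILLER_VOCABULARY: tuple[str, ...] = (
    "today", "tomorrow", "week", "month", "morning", "evening", "night",
    "dose", "doses", "doctor", "nurse", "clinic", "visit", "appointment",
    "started", "starting", "taking", "took", "switched", "switching",
    "treatment", "therapy", "tablet", "pill", "pills", "needle",
    "symptoms", "energy", "walking", "legs", "arm", "hands", "eyes",
    "vision", "brain", "scan", "mri", "blood", "results", "waiting",
    "reading", "news", "story", "update", "thoughts", "questions",
    "answers", "people", "friends", "family", "support", "group",
    "meeting", "talk", "talking", "wrote", "blog", "post", "video",
    "coffee", "lunch", "dinner", "sleep", "weather", "rain", "year",
    "journey", "routine", "schedule", "dosing", "monthly", "weekly",
)

#: Marker terms planted at elevated frequency for designated treatments,
#: echoing the side-effect vocabulary that dominates real drug tweets
#: (flu-like symptoms for the injectable interferons; infusion and PML
#: risk for natalizumab).
DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "Avonex": ("flu", "injection"),
    "Rebif": ("flu", "injection"),
    "Tysabri": ("pml", "infusion"),
}

#: Default corpus structure: per-treatment volume, positive/negative
#: mixture weights, and first active month (all series end 2014-07).
_DEFAULT_STRUCTURE: tuple[tuple[str, int, float, float, tuple[int, int]], ...] = (
    ("Aubagio", 2814, 0.303, 0.118, (2009, 2)),
    ("Avonex", 4643, 0.277, 0.224, (2008, 4)),
    ("Betaferon", 1615, 0.241, 0.218, (2008, 5)),
    ("Copaxone", 11634, 0.293, 0.216, (2008, 4)),
    ("Extavia", 511, 0.233, 0.162, (2008, 9)),
    ("Gilenya", 9376, 0.318, 0.155, (2008, 4)),
    ("Lemtrada", 5634, 0.299, 0.180, (2008, 10)),
    ("Novantrone", 110, 0.164, 0.300, (2008, 12)),
    ("Rebif", 4236, 0.265, 0.248, (2008, 4)),
    ("Tecfidera", 4922, 0.330, 0.123, (2008, 10)),
    ("Tysabri", 14542, 0.323, 0.252, (2008, 1)),
)

_END_MONTH = (2014, 7)


@dataclass(frozen=True)
class TreatmentMix:
    """Per-treatment generation parameters."""

    n_tweets: int
    p_positive: float
    p_negative: float
    p_neutral: float
    start_month: tuple[int, int] = (2008, 1)
    end_month: tuple[int, int] = _END_MONTH

    def __post_init__(self) -> None:
        total = self.p_positive + self.p_negative + self.p_neutral
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {total!r}, not 1")
        if min(self.p_positive, self.p_negative, self.p_neutral) < 0:
            raise ValueError("mixture weights must be non-negative")
        if self.n_tweets < 0:
            raise ValueError("n_tweets must be non-negative")


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Generator parameters; ``default()`` supplies a realistic default structure."""

    treatments: Mapping[str, TreatmentMix]
    duplicate_rate: float = 0.2
    stock_rate: float = 0.055
    company_rate: float = 0.26
    typo_rate: float = 0.05
    s_positive: int = 1
    s_negative: int = 1
    markers: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS)
    )
    marker_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplicate_rate", "stock_rate", "company_rate", "typo_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.s_positive < 0 or self.s_negative < 0:
            raise ValueError("planted word counts must be non-negative")

    @classmethod
    def default(cls, scale: float = 1.0, seed: int = 0, **overrides) -> "SyntheticCorpusConfig":
        """Default-structure config; ``scale`` shrinks per-treatment volumes
        (minimum 30 tweets per treatment) for tractable simulations."""
        mixes = {}
        for label, n, p_pos, p_neg, start in _DEFAULT_STRUCTURE:
            mixes[label] = TreatmentMix(
                n_tweets=max(30, round(n * scale)),
                p_positive=p_pos,
                p_negative=p_neg,
                p_neutral=round(1.0 - p_pos - p_neg, 9),
                start_month=start,
            )
        return cls(treatments=mixes, seed=seed, **overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCorpusConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        mixes = {
            label: TreatmentMix(
                n_tweets=int(m["n_tweets"]),
                p_positive=float(m["p_positive"]),
                p_negative=float(m["p_negative"]),
                p_neutral=float(m["p_neutral"]),
                start_month=tuple(m.get("start_month", (2008, 1))),
                end_month=tuple(m.get("end_month", _END_MONTH)),
            )
            for label, m in raw.pop("treatments").items()
        }
        markers = {k: tuple(v) for k, v in raw.pop("markers", DEFAULT_MARKERS).items()}
        return cls(treatments=mixes, markers=markers, **raw)


@dataclass
class GroundTruth:
    """Per-record injection bookkeeping plus closed-form expectations.

    ``records`` columns: tweet_id, treatment, category (clean, duplicate,
    stock, company), polarity, intended_score, duplicate_of.
    ``expected`` columns: treatment, p_positive, p_negative, p_neutral,
    expected_mean_score.
    """

    records: pd.DataFrame
    expected: pd.DataFrame

    def ids(self, category: str) -> frozenset[str]:
        sel = self.records.loc[self.records["category"] == category, "tweet_id"]
        return frozenset(sel)


def expected_summary(config: SyntheticCorpusConfig) -> pd.DataFrame:
    """Closed-form per-treatment expectations under the mixture model:
    expected mean score = s_pos * p_positive - s_neg * p_negative."""
    rows = [
        {
            "treatment": label,
            "p_positive": mix.p_positive,
            "p_negative": mix.p_negative,
            "p_neutral": mix.p_neutral,
            "expected_mean_score": config.s_positive * mix.p_positive
            - config.s_negative * mix.p_negative,
        }
        for label, mix in config.treatments.items()
    ]
    return pd.DataFrame(rows)


def _screen_pool(
    words: Sequence[str],
    forbidden_substrings: Sequence[str],
    forbidden_tokens: frozenset[str],
) -> list[str]:
    """Keep words that contain no forbidden substring and are not
    forbidden tokens; sorted for run-to-run determinism."""
    out = []
    for w in sorted(set(words)):
        if w in forbidden_tokens:
            continue
        if any(sub in w for sub in forbidden_substrings):
            continue
        if _ELONG_RE.search(w):
            continue
        out.append(w)
    return out


def _month_bounds(start: tuple[int, int], end: tuple[int, int]) -> tuple[int, int]:
    t0 = datetime(start[0], start[1], 1, tzinfo=timezone.utc)
    if end[1] == 12:
        t1 = datetime(end[0] + 1, 1, 1, tzinfo=timezone.utc)
    else:
        t1 = datetime(end[0], end[1] + 1, 1, tzinfo=timezone.utc)
    if t1 <= t0:
        raise ValueError("end_month precedes start_month")
    return int(t0.timestamp()), int(t1.timestamp()) - 1


class _Generator:
    def __init__(
        self,
        config: SyntheticCorpusConfig,
        lexicon: SentimentLexicon,
        catalog: TreatmentCatalog,
        stock_spec: KeywordFilterSpec,
        company_spec: KeywordFilterSpec,
    ) -> None:
        self.config = config
        self.catalog = catalog
        self.stock_spec = stock_spec
        self.company_spec = company_spec
        self.rng = np.random.default_rng(config.seed)
        self.serial = 0
        self.seen_texts: set[str] = set()
        self.records: list[tuple[TweetRecord, dict]] = []

        for label in config.treatments:
            if label not in catalog.labels:
                raise ValueError(f"config treatment {label!r} not in catalog")

        filter_subs = list(stock_spec.text_terms) + list(company_spec.text_terms)
        abbrev_keys = frozenset(default_abbreviations())
        drug_terms = frozenset(catalog.match_terms)
        lex_terms = lexicon.positive | lexicon.negative

        self.pos_pool = _screen_pool(lexicon.positive, filter_subs, abbrev_keys | drug_terms)
        self.neg_pool = _screen_pool(lexicon.negative, filter_subs, abbrev_keys | drug_terms)
        self.filler_pool = _screen_pool(
            FILLER_VOCABULARY, filter_subs, abbrev_keys | drug_terms | lex_terms
        )
        if not self.pos_pool or not self.neg_pool or len(self.filler_pool) < 10:
            raise ValueError("word pools too small after screening")
        for terms in config.markers.values():
            bad = [
                t
                for t in terms
                if t in lex_terms
                or t in abbrev_keys
                or any(sub in t for sub in filter_subs)
            ]
            if bad:
                raise ValueError(f"marker terms collide with lexicon/filters: {bad}")
        self._lex_terms = lex_terms
        self._abbrev_keys = abbrev_keys
        self._filter_subs = tuple(filter_subs)

    # -- helpers ---------------------------------------------------------

    def _next_id(self) -> str:
        self.serial += 1
        return f"t{self.serial:07d}"

    def _source_ref(self) -> str:
        uid = int(self.rng.integers(1, 10**6))
        return f"https://twitter.com/u{uid}/status/{self.serial}"

    def _pick(self, pool: Sequence[str], n: int = 1) -> list[str]:
        idx = self.rng.integers(0, len(pool), size=n)
        return [pool[int(i)] for i in idx]

    def _maybe_typo(self, word: str) -> str:
        """Elongate one character; reject the typo when the collapsed form
        would hit the lexicon or abbreviation table (keeps scores exact)."""
        if self.rng.random() >= self.config.typo_rate or len(word) < 3:
            return word
        j = int(self.rng.integers(0, len(word)))
        typo = word[:j] + word[j] * 2 + word[j:]
        collapsed = _ELONG_RE.sub(r"\1\1", typo)
        if (
            collapsed in self._lex_terms
            or collapsed in self._abbrev_keys
            or any(sub in typo for sub in self._filter_subs)
        ):
            return word
        return typo

    def _drug_token(self, label: str) -> str:
        term = self._pick(self.catalog.terms_for(label))[0]
        style = int(self.rng.integers(0, 3))
        return (term, term.capitalize(), term.upper())[style]

    def _assemble(self, words: list[str]) -> str:
        order = self.rng.permutation(len(words))
        text = " ".join(words[int(i)] for i in order)
        # uniqueness guard: duplicate-text groups must be exactly the
        # injected retweet copies
        while text.lower() in self.seen_texts:
            extra = self._pick(self.filler_pool)[0]
            text = text + " " + extra
        self.seen_texts.add(text.lower())
        return text

    def _timestamp(self, label: str) -> datetime:
        mix = self.config.treatments[label]
        lo, hi = _month_bounds(mix.start_month, mix.end_month)
        epoch = int(self.rng.integers(lo, hi + 1))
        return datetime.fromtimestamp(epoch, tz=timezone.utc)

    def _emit(self, record: TweetRecord, truth: dict) -> TweetRecord:
        self.records.append((record, truth))
        return record

    # -- record builders -------------------------------------------------

    def _clean_tweet(self, label: str) -> TweetRecord:
        cfg = self.config
        mix = cfg.treatments[label]
        cls = ("positive", "negative", "neutral")[
            int(
                self.rng.choice(
                    3, p=[mix.p_positive, mix.p_negative, mix.p_neutral]
                )
            )
        ]
        words = [self._maybe_typo(w) for w in self._pick(self.filler_pool, int(self.rng.integers(3, 8)))]
        if cls == "positive":
            words += self._pick(self.pos_pool, cfg.s_positive)
            score = cfg.s_positive
        elif cls == "negative":
            words += self._pick(self.neg_pool, cfg.s_negative)
            score = -cfg.s_negative
        else:
            score = 0
        for marker in cfg.markers.get(label, ()):
            if self.rng.random() < cfg.marker_rate:
                words.append(marker)
        words.append(self._drug_token(label))
        tweet_id = self._next_id()
        rec = TweetRecord(
            tweet_id=tweet_id,
            source_ref=self._source_ref(),
            text=self._assemble(words),
            timestamp=self._timestamp(label),
        )
        assert not self.stock_spec.matches(rec) and not self.company_spec.matches(rec)
        return self._emit(
            rec,
            {
                "tweet_id": tweet_id,
                "treatment": label,
                "category": "clean",
                "polarity": cls,
                "intended_score": score,
                "duplicate_of": "",
            },
        )

    def _retweet(self, original: TweetRecord, truth_of_original: dict) -> None:
        handle = f"fan{int(self.rng.integers(1, 10**6))}"
        tweet_id = self._next_id()
        delay = int(self.rng.integers(60, 7 * 86400))
        rec = TweetRecord(
            tweet_id=tweet_id,
            source_ref=self._source_ref(),
            text=f"RT @{handle}: {original.text}",
            timestamp=original.timestamp + timedelta(seconds=delay),
        )
        self._emit(
            rec,
            {
                "tweet_id": tweet_id,
                "treatment": truth_of_original["treatment"],
                "category": "duplicate",
                "polarity": truth_of_original["polarity"],
                "intended_score": truth_of_original["intended_score"],
                "duplicate_of": original.tweet_id,
            },
        )

    def _contaminant(self, label: str, kind: str) -> None:
        words = [self._maybe_typo(w) for w in self._pick(self.filler_pool, int(self.rng.integers(3, 8)))]
        source_ref = None
        if kind == "stock":
            # finance tweets carry either a flagged source string or a
            # stock keyword in the text
            if self.rng.random() < 0.5 and self.stock_spec.source_terms:
                term = self._pick(self.stock_spec.source_terms)[0]
                source_ref = f"https://{term}.example.com/item/{self.serial + 1}"
            else:
                words.append(self._pick(self.stock_spec.text_terms)[0])
        else:
            words.append(self._pick(self.company_spec.text_terms)[0])
        words.append(self._drug_token(label))
        tweet_id = self._next_id()
        rec = TweetRecord(
            tweet_id=tweet_id,
            source_ref=source_ref or self._source_ref(),
            text=self._assemble(words),
            timestamp=self._timestamp(label),
        )
        if kind == "stock":
            assert self.stock_spec.matches(rec)
            assert not self.company_spec.matches(rec)
        else:
            assert self.company_spec.matches(rec)
            assert not self.stock_spec.matches(rec)
        self._emit(
            rec,
            {
                "tweet_id": tweet_id,
                "treatment": label,
                "category": kind,
                "polarity": "neutral",
                "intended_score": 0,
                "duplicate_of": "",
            },
        )

    # -- main ------------------------------------------------------------

    def run(self) -> tuple[Corpus, GroundTruth]:
        cfg = self.config
        for label, mix in cfg.treatments.items():
            clean: list[tuple[TweetRecord, dict]] = []
            for _ in range(mix.n_tweets):
                rec = self._clean_tweet(label)
                clean.append((rec, self.records[-1][1]))
            for rec, truth in clean:
                if self.rng.random() < cfg.duplicate_rate:
                    self._retweet(rec, truth)
            n_stock = int(self.rng.binomial(mix.n_tweets, cfg.stock_rate))
            n_company = int(self.rng.binomial(mix.n_tweets, cfg.company_rate))
            for _ in range(n_stock):
                self._contaminant(label, "stock")
            for _ in range(n_company):
                self._contaminant(label, "company")

        ordered = sorted(
            self.records, key=lambda item: (item[0].timestamp, item[0].tweet_id)
        )
        corpus = Corpus(
            records=[rec for rec, _ in ordered],
            provenance=["generate_corpus"],
        )
        truth_df = pd.DataFrame([truth for _, truth in ordered])
        return corpus, GroundTruth(records=truth_df, expected=expected_summary(cfg))


def generate_corpus(
    config: SyntheticCorpusConfig,
    lexicon: SentimentLexicon | None = None,
    catalog: TreatmentCatalog | None = None,
    stock_spec: KeywordFilterSpec = STOCK_FILTER,
    company_spec: KeywordFilterSpec = COMPANY_FILTER,
) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus plus exact ground truth (see module docstring)."""
    return _Generator(
        config,
        lexicon or default_lexicon(),
        catalog or TreatmentCatalog.default(),
        stock_spec,
        company_spec,
    ).run()
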