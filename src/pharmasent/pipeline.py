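"""End-to-end orchestration: ingest -> dedup -> stock filter -> company
filter -> treatment matching -> normalization -> scoring -> aggregation
-> rank test -> word rankings.

The three analysis levels

* ``all``                        — unique tweets (after deduplication),
* ``stock_removed``              — stock/share tweets also removed,
* ``stock_and_company_removed``  — company-name tweets also removed,

are produced in ONE run by checkpointing the corpus after each filter
stage, which guarantees the level-nesting invariant
n(all) >= n(stock_removed) >= n(stock_and_company_removed) for every
treatment by construction.  Each unique tweet is normalized and scored
once; level tables are computed over id subsets.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import normalize as norm
from .corpus_io import (
    Corpus,
    LoadReport,
    SentimentLexicon,
    TreatmentCatalog,
    read_lexicon,
    read_stopwords,
    read_tweets,
)
from .filtering import (
    COMPANY_FILTER,
    STOCK_FILTER,
    FilterReport,
    KeywordFilterSpec,
    apply_keyword_filter,
    deduplicate,
    match_treatments,
)
from .sentiment import (
    ScoredTweet,
    TreatmentSummary,
    monthly_counts,
    score_corpus,
    summaries_to_frame,
    summarize_by_treatment,
)
from .stats import RankTestResult, kruskal_wallis
from .wordfreq import default_stopwords, rankings_to_frame, top_words

logger = logging.getLogger(__name__)

LEVELS = ("all", "stock_removed", "stock_and_company_removed")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_outputs", "LEVELS"]


class DegenerateDataError(RuntimeError):
    """Raised under strict mode when an analysis level has no tweets left."""


@dataclass
class PipelineConfig:
    """Paths, defaults and switches for one pipeline run.

    ``level`` selects the analysis level used for word rankings; the
    sentiment tables and rank test are always produced for all three
    levels.  Lexicon, stopword and table paths default to the packaged
    data files.
    """

    tweets_path: str | Path
    dialect: str = "jsonl"
    positive_path: str | Path | None = None
    negative_path: str | Path | None = None
    stopwords_path: str | Path | None = None
    abbreviations_path: str | Path | None = None
    emoticons_path: str | Path | None = None
    catalog: TreatmentCatalog = field(default_factory=TreatmentCatalog.default)
    stock_spec: KeywordFilterSpec = STOCK_FILTER
    company_spec: KeywordFilterSpec = COMPANY_FILTER
    level: str = "all"
    top_k: int = 50
    strict: bool = False

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    def load_lexicon(self) -> SentimentLexicon:
        if self.positive_path and self.negative_path:
            return read_lexicon(self.positive_path, self.negative_path)
        data = resources.files("pharmasent.data")
        with resources.as_file(data.joinpath("synthetic_positive_words.txt")) as pos:
            with resources.as_file(data.joinpath("synthetic_negative_words.txt")) as neg:
                return read_lexicon(pos, neg)

    def load_stopwords(self) -> frozenset[str]:
        if self.stopwords_path:
            return read_stopwords(self.stopwords_path)
        return default_stopwords()

    def load_tables(self) -> tuple[dict, dict]:
        abbr = (
            norm.load_abbreviations(self.abbreviations_path)
            if self.abbreviations_path
            else norm.default_abbreviations()
        )
        emo = (
            norm.load_emoticons(self.emoticons_path)
            if self.emoticons_path
            else norm.default_emoticons()
        )
        return abbr, emo


@dataclass
class PipelineResult:
    load_report: LoadReport
    filter_reports: list[FilterReport]
    counts: pd.DataFrame
    summaries: dict[str, list[TreatmentSummary]]
    monthly: pd.DataFrame
    rank_tests: dict[str, RankTestResult | None]
    rankings: pd.DataFrame
    scored: dict[str, list[ScoredTweet]]
    warnings: list[str]


def _level_counts(corpus: Corpus, catalog: TreatmentCatalog) -> dict[str, int]:
    counts = dict.fromkeys(catalog.labels, 0)
    for rec in corpus.records:
        txt = rec.text.lower()
        for label, terms in catalog.entries:
            if any(t.lower() in txt for t in terms):
                counts[label] += 1
    return counts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; see module docstring for the stage order."""
    lexicon = config.load_lexicon()
    stopwords = config.load_stopwords()
    abbreviations, emoticons = config.load_tables()

    corpus, load_report = read_tweets(config.tweets_path, config.dialect)
    filter_reports: list[FilterReport] = []
    run_warnings: list[str] = []

    deduped, rep = deduplicate(corpus)
    filter_reports.append(rep)
    stock_filtered, rep = apply_keyword_filter(deduped, config.stock_spec)
    filter_reports.append(rep)
    company_filtered, rep = apply_keyword_filter(stock_filtered, config.company_spec)
    filter_reports.append(rep)

    checkpoints = {
        "all": deduped,
        "stock_removed": stock_filtered,
        "stock_and_company_removed": company_filtered,
    }

    # per-treatment counts at the three filter levels (nested by construction)
    counts = pd.DataFrame(
        {f"n_{lvl}": _level_counts(checkpoints[lvl], config.catalog) for lvl in LEVELS}
    )
    counts.index.name = "treatment"
    counts = counts.reset_index()

    # match + normalize + score each unique tweet once, on the widest level
    matched, rep = match_treatments(deduped, config.catalog)
    filter_reports.append(rep)
    tokenized = norm.normalize_corpus(
        matched.records, config.catalog, abbreviations, emoticons
    )
    timestamps = {rec.tweet_id: rec.timestamp for rec in matched.records}
    scored_all = score_corpus(tokenized, timestamps, lexicon)
    scored_by_id = {tw.tweet_id: tw for tw in scored_all}

    summaries: dict[str, list[TreatmentSummary]] = {}
    rank_tests: dict[str, RankTestResult | None] = {}
    scored_by_level: dict[str, list[ScoredTweet]] = {}
    for lvl in LEVELS:
        level_ids = {rec.tweet_id for rec in checkpoints[lvl].records}
        scored = [tw for tid, tw in scored_by_id.items() if tid in level_ids]
        # keep deterministic corpus order
        order = {rec.tweet_id: i for i, rec in enumerate(matched.records)}
        scored.sort(key=lambda tw: order[tw.tweet_id])
        scored_by_level[lvl] = scored
        level_summaries = summarize_by_treatment(scored, config.catalog)
        summaries[lvl] = level_summaries
        if not level_summaries:
            msg = f"analysis level {lvl!r} has no tweets after filtering"
            run_warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
            if config.strict:
                raise DegenerateDataError(msg)
        groups = [
            [tw.score for tw in scored if s.treatment_label in tw.treatments]
            for s in level_summaries
        ]
        if len(groups) >= 2 and sum(len(g) for g in groups) >= 3:
            rank_tests[lvl] = kruskal_wallis(groups)
        else:
            rank_tests[lvl] = None
            msg = f"rank test skipped at level {lvl!r}: fewer than two treatment groups"
            run_warnings.append(msg)
            logger.warning(msg)

    monthly = monthly_counts(scored_by_level["all"])

    # word rankings on the configured level
    level_ids = {rec.tweet_id for rec in checkpoints[config.level].records}
    level_tokens = [tw for tw in tokenized if tw.tweet_id in level_ids]
    present = {s.treatment_label for s in summaries[config.level]}
    rankings = rankings_to_frame(
        [
            top_words(level_tokens, label, stopwords, config.catalog, config.top_k)
            for label in config.catalog.labels
            if label in present
        ]
    )

    n_multi = sum(1 for tw in scored_all if len(tw.treatments) > 1)
    if n_multi:
        logger.info(
            "%d tweets match multiple treatments; per-treatment counts "
            "exceed unique-tweet totals",
            n_multi,
        )

    return PipelineResult(
        load_report=load_report,
        filter_reports=filter_reports,
        counts=counts,
        summaries=summaries,
        monthly=monthly,
        rank_tests=rank_tests,
        rankings=rankings,
        scored=scored_by_level,
        warnings=run_warnings,
    )


_SCHEMAS = {
    "counts": ["treatment", "n_all", "n_stock_removed", "n_stock_and_company_removed"],
    "sentiment": [
        "treatment",
        "n_tweets",
        "prop_positive",
        "prop_negative",
        "prop_neutral",
        "summed_score",
        "mean_score",
        "sd_score",
    ],
    "monthly": ["treatment", "month", "n_tweets"],
    "rankings": ["treatment", "rank", "token", "count"],
}


def _checked_write(df: pd.DataFrame, schema: list[str], path: Path) -> None:
    if list(df.columns) != schema:
        raise ValueError(f"{path.name}: columns {list(df.columns)} != schema {schema}")
    if df[schema[0]].isna().any():
        raise ValueError(f"{path.name}: null keys")
    df.to_csv(path, index=False)


def write_outputs(result: PipelineResult, config: PipelineConfig, out_dir: str | Path) -> None:
    """Write all result tables and the run log under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _checked_write(result.counts, _SCHEMAS["counts"], out / "counts_by_treatment.csv")
    for lvl in LEVELS:
        frame = summaries_to_frame(result.summaries[lvl])
        if frame.empty:
            frame = pd.DataFrame(columns=_SCHEMAS["sentiment"])
        _checked_write(frame, _SCHEMAS["sentiment"], out / f"sentiment_{lvl}.csv")
    _checked_write(result.monthly, _SCHEMAS["monthly"], out / "monthly_counts.csv")
    _checked_write(result.rankings, _SCHEMAS["rankings"], out / "top_words.csv")

    kw_rows = []
    for lvl in LEVELS:
        res = result.rank_tests[lvl]
        if res is not None:
            kw_rows.append(
                {
                    "level": lvl,
                    "H": res.H,
                    "df": res.df,
                    "p_value": res.p_value,
                    "n_groups": len(res.n_per_group),
                    "n_total": sum(res.n_per_group),
                }
            )
    pd.DataFrame(
        kw_rows, columns=["level", "H", "df", "p_value", "n_groups", "n_total"]
    ).to_csv(out / "kruskal_wallis.csv", index=False)

    log = {
        "config": {
            "tweets_path": str(config.tweets_path),
            "dialect": config.dialect,
            "level": config.level,
            "top_k": config.top_k,
            "strict": config.strict,
            "stock_filter": {
                "source_terms": list(config.stock_spec.source_terms),
                "text_terms": list(config.stock_spec.text_terms),
            },
            "company_filter": {
                "source_terms": list(config.company_spec.source_terms),
                "text_terms": list(config.company_spec.text_terms),
            },
            "treatments": {
                label: list(terms) for label, terms in config.catalog.entries
            },
        },
        "load_report": vars(result.load_report),
        "filter_reports": [
            {
                "stage_name": r.stage_name,
                "n_in": r.n_in,
                "n_removed": r.n_removed,
                "n_out": r.n_out,
                "removed_ids": list(r.removed_ids),
            }
            for r in result.filter_reports
        ],
        "warnings": result.warnings,
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
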