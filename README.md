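# pharmasent

Lexicon-based sentiment analysis of drug-mention tweets, packaged as a
tested, reusable pipeline. The motivating application is infodemiology
for multiple sclerosis (MS): gauging patient opinion about the eleven
disease-modifying therapies (DMTs) — Aubagio, Avonex,
Betaferon/Betaseron, Copaxone, Extavia, Gilenya, Lemtrada, Novantrone,
Rebif, Tecfidera and Tysabri — from tweets that mention them by brand
name. The package is for researchers in pharmacovigilance and health
text mining who want a transparent, fully reproducible version of this
kind of analysis, including every filtering and bookkeeping step.

## What the pipeline does

Starting from a tweet-record file (jsonl or csv: `tweet_id`,
`permalink`, `text`, `created_at`), the pipeline applies, in order:

1. **Deduplication** — directly copied retweets (byte-identical text
   after stripping one leading `RT @handle:` prefix) are collapsed onto
   the earliest record, yielding unique tweets.
2. **Stock/share filter** — case-insensitive substring removal of
   finance tweets, using fixed keyword lists over the source string
   (`market_jp`, `thestreet`, `rtebusiness`, `pharma`, `pharmsales`)
   and the text (`bloomberg`, `forbes`, `dow jones`, `financial times`,
   `stockpickr`, `marketwatch`, `business:`, `profit`, `shares`, `sec`).
3. **Company filter** — removal of tweets naming the manufacturers
   (`novartis`, `elan`, `biogen`, `merck`, `bayer`, `genzyme`,
   `sanofi`, `teva`, `serono`).
4. **Treatment matching** — each tweet is assigned to every treatment
   whose brand name occurs (case-insensitively) in its text.
5. **Normalization** — lowercasing; URL/@-mention removal; hashtag
   unmarking; emoticon-to-word mapping; elongation collapse
   ("soooo" → "soo"); tokenization; slang expansion ("gr8" → "great").
   Drug names are never altered.
6. **Sentiment scoring** — per tweet,

   `score = #(positive-lexicon tokens) − #(negative-lexicon tokens)`

   with polarity positive (score > 0), negative (score < 0) or neutral
   (score = 0), against an opinion lexicon in the standard
   one-term-per-line dialect.
7. **Aggregation** — per treatment and per filter level: polarity
   proportions, summed score, mean score, sample SD, tweet counts, and
   monthly tweet counts.
8. **Rank test** — a tie-corrected Kruskal–Wallis test
   (H, df = k−1, chi-square p) comparing score distributions across
   treatments, at the conventional α = 0.05.
9. **Word frequency** — per-treatment top-k token rankings excluding
   stopwords and drug names (a deterministic replacement for word
   clouds).

All three analysis levels (all unique tweets / stock removed / stock
and company removed) are produced in a single run by checkpointing, so
the per-treatment counts are nested by construction.

Because the original tweet archive service is defunct, the package
ships a synthetic corpus generator (`pharmasent.synthetic`) that
emulates realistic corpus conditions — per-treatment volumes and monthly
spans, per-treatment sentiment mixtures, retweet duplication, and
finance/company contamination — with exact per-record ground truth, so
every stage of the pipeline is testable end to end.

## Worked example

```bash
pharmasent simulate --scale 0.02 --seed 7 --out demo.jsonl --truth demo_truth.csv
pharmasent run --tweets demo.jsonl --out demo_out --top-k 5
```

prints

```
wrote 1879 records to demo.jsonl
all: H=27.442 df=10 p=0.00222 (11 treatments, 1624 tweets)
stock_removed: H=27.258 df=10 p=0.00237 (11 treatments, 1564 tweets)
stock_and_company_removed: H=27.266 df=10 p=0.00236 (11 treatments, 1249 tweets)
outputs written to demo_out
```

The simulated corpus of 1879 records contains 1249 clean tweets, 255 retweet copies, 60
finance tweets and 315 company tweets (per the ground-truth sidecar); the three `H` lines are the
omnibus rank test at each filter level — here the between-treatment
sentiment differences planted by the generator are detected
(p < 0.05 at every level). `demo_out/` then contains
`counts_by_treatment.csv` (per-treatment counts at the three levels,
e.g. Aubagio 68 → 67 → 56), `sentiment_<level>.csv` (one row per
treatment), e.g.

```
treatment,n_tweets,prop_positive,prop_negative,prop_neutral,summed_score,mean_score,sd_score
Aubagio,56,0.3036,0.1429,0.5536,9,0.1607,0.6544
```

meaning: of Aubagio's 56 fully filtered tweets, 30.4% were positive and
14.3% negative, summing to a sentiment score of +9 (mean +0.16 per
tweet) — plus `monthly_counts.csv`, `top_words.csv` (ranked terms per
treatment), `kruskal_wallis.csv` and a `run_log.json` recording every
filter report and config value.

The same operations are available as a library:

```python
from pharmasent import (SyntheticCorpusConfig, generate_corpus,
                        PipelineConfig, run_pipeline)
```

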