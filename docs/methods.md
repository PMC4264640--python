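# Methods

This note documents the statistical model, the normalization and
filtering procedures, the synthetic-data generator, and the design
choices made where the design was genuinely open.

## The sentiment statistic

Each tweet is reduced to lowercase tokens and scored against an opinion
lexicon (disjoint positive and negative term sets):

    score = #(positive token occurrences) − #(negative token occurrences)

Polarity is positive (score > 0), negative (< 0) or neutral (= 0).
Choices inside this definition:

* **Occurrences, not unique words.** "bad bad nasty" scores −3. This is
  the conventional behaviour of count-difference lexicon scoring; the
  alternative (unique matches per tweet) is defensible but not what
  this package implements, and it is asserted in tests.
* **No negation or valence weighting.** "not good" scores +1. The
  statistic is the plain count difference; adding negation handling
  would change the quantity being estimated. This blindness to context
  and sarcasm is a known limitation of the approach, not of the
  implementation.
* **Single-word lexicon entries only.** The scorer matches tokens, so a
  multiword lexicon entry could never fire; such entries are rejected
  at load time rather than silently ignored. A term on both polarity
  lists is a fatal load error, because the count difference is
  ambiguous for it.
* Per-treatment aggregation reports the **sample** (n−1) standard
  deviation, with sd = 0 for a single tweet. Population vs sample SD is
  an open convention for this analysis; sample SD was chosen as the
  default every mainstream statistics package reports.

The packaged default lexicon (`data/synthetic_*_words.txt`, 62 positive
and 86 negative terms) is a compact synthetic stand-in, not the
published opinion lexicon of 2006 positive / 4783 negative terms; any
lexicon in the one-term-per-line dialect can be supplied instead. The
stand-in is screened so that no term contains a filter keyword as a
substring, which keeps sentiment scoring and keyword filtering
orthogonal on synthetic corpora.

## Filtering

Three stages, with per-stage `FilterReport`s (`n_in = n_removed +
n_out` and the removed-id list are asserted invariants):

1. **Deduplication.** "Directly copied retweet" is operationalized as:
   byte-identical text after stripping at most one leading
   `RT @handle:` prefix and surrounding whitespace. No fuzzy matching —
   reproducible and conservative. The survivor of a duplicate group is
   the record with the earliest timestamp (the original precedes its
   copies), ties broken by input order.
2. **Stock/share filter** and 3. **company filter.** Case-insensitive
   **substring** matching of fixed keyword lists against the raw
   (un-normalized) source string and text. Substring rather than token
   matching is forced by the lists themselves, which contain multiword
   terms ("dow jones") and a punctuation-bearing term ("business:").
   The consequence — "sec" also fires inside "second" — is accepted
   over-removal inherent to the rule and is pinned in a test.

Filters run before normalization: the keyword lists target raw text
(URLs in source strings, punctuation like "business:"), and
normalization would destroy some of their targets.

A tweet mentioning k treatments contributes one record to each of the
k per-treatment summaries. Some per-treatment attribution has to be
chosen for per-treatment tables; duplication across treatments is the
only convention that never discards signal, at the cost that summed
per-treatment counts can exceed the unique-tweet total (logged when it
happens).

## Normalization

A deterministic 7-step normalizer (lowercase; URL and @-mention
deletion; hashtag unmarking; emoticon table; elongation collapse;
non-alphanumeric split; abbreviation table), standing in for full
tweet-NLP systems, which are out of scope. Parameters:

* **Emoticon table** (`data/emoticons.csv`, 16 entries): maps emoticons
  to lexicon-bearing sentinel words ("good", "bad", "love") so
  emoticons contribute to sentiment. Declared as data to keep the
  score's provenance explicit and configurable.
* **Abbreviation table** (`data/abbreviations.csv`, 45 entries): common
  tweet slang ("gr8" → "great", "omg" → "oh my god"). Both tables are
  validated at load: expansions must be plain, elongation-free tokens
  that are not themselves table keys — this is exactly the condition
  under which normalization is idempotent, which a property test
  asserts.
* **Elongation collapses to 2 repeats, not 1**, so legitimate double
  letters ("good", "week") are never corrupted and "sooo"/"soooo"
  unify to "soo"; residual misses ("loove") are accepted noise.
* **Drug names bypass** the elongation and abbreviation steps, so
  treatment labels recomputed from tokens always equal those computed
  from raw text (asserted corpus-wide).

Token-level equality with any particular third-party normalizer is not
claimed and is not testable; the properties that matter downstream
(idempotence, drug-name preservation, lowercase alphanumeric output)
are.

## Rank test

The Kruskal–Wallis statistic is computed from its rank-sum definition
with midranks and the standard tie correction (see `stats.py`); the
p-value uses the chi-square upper tail with k−1 df. Sentiment scores
are small integers, so ties dominate and the correction is essential.
Numerical choices:

* An all-identical-values input has a vanishing tie-correction
  denominator; by convention the test returns H = 0, p = 1, keeping
  degenerate pipelines running.
* Tiny negative H from round-off is clamped to 0.
* No exact/permutation p-value: group sizes in this application are
  hundreds to thousands, where the chi-square approximation is
  adequate. Its calibration is verified empirically (type-I error of
  0.05-level tests across 1000 null replicates of 11 × 200 mixture
  scores falls in the binomial 99% band) and against an independent
  reference implementation to 1e-10 on tied instances.
* The test operates on the per-tweet score distributions grouped by
  treatment — not on the treatment means; comparing k means with a
  rank test is not meaningful, and the distribution-level test is the
  statistic actually computed here.
* No post-hoc pairwise comparisons or multiplicity correction: only
  the omnibus test is reported.

## Word frequency

Per-treatment token counts excluding a configurable stopword list
(default: the packaged 126-word English function-word list) and all
drug brand names; top-k by count with lexicographic tie-breaks for
reproducibility. Occurrence counting (not tweets-containing) is the
declared convention.

## Synthetic corpus generator

The generator emulates the structure the analysis assumes, with exact
ground truth:

* **Per-treatment mixtures and volumes.** Defaults encode a realistic
  corpus profile for this drug class: the 11 treatments' tweet volumes (110–14 542),
  their observed positive/negative polarity proportions
  (p⁺ 0.164–0.330, p⁻ 0.118–0.300), and their first-activity months
  (Jan 2008 – Feb 2009, all spans ending Jul 2014). A `scale` argument
  shrinks volumes proportionally (floor 30/treatment) for tractable
  runs.
* **Tweet construction.** A clean tweet is 3–7 neutral filler words, a
  brand-name token (random casing), exactly s⁺ positive-lexicon words
  if its class is positive (default s⁺ = 1), exactly s⁻
  negative-lexicon words if negative (default s⁻ = 1), optional marker
  terms, and typo noise. The closed-form expected mean score per
  treatment is s⁺·p⁺ − s⁻·p⁻.
* **Exactness by screening.** Sentiment words are drawn from the
  loaded lexicon itself; filler vocabulary is screened against the
  lexicon, both filter keyword lists, the abbreviation table and the
  drug names; typo elongation is applied to filler only and re-screened
  after the normalizer's collapse rule. Hence intended score ==
  realized pipeline score for every clean record, and no clean record
  can be caught by a filter — ground truth is exact, not approximate.
* **Contamination.** Duplicates are `RT @handle:` copies of clean
  tweets at `duplicate_rate` (default 0.2; the real rate is
  unknowable from the published counts, and 0.2 exercises the stage
  hard). Stock contaminants carry either a flagged source string or a
  stock keyword (default rate 0.055 ≈ the observed stock-filter
  removal fraction); company contaminants carry a manufacturer name
  (default 0.26 ≈ the observed company-filter removal fraction). Both
  kinds also mention a drug, as real finance tweets do, so the keyword
  filters — not treatment matching — must remove them, and the
  categories are constructed disjoint so filter recovery is exact.
* **Markers.** "flu"/"injection" for Avonex and Rebif,
  "pml"/"infusion" for Tysabri, planted with probability 0.3 per
  tweet, emulating the side-effect vocabulary that dominates real
  drug tweets (flu-like symptoms of the injectable interferons; the
  PML risk of natalizumab infusion). Face-validity tests assert they
  reach the top-10 rankings.
* **Determinism.** One `numpy` generator seeded from the config; same
  config + seed is byte-identical, distinct seeds differ.

What the generator does **not** model — and hence what passing tests do
not show about real data: real tweet linguistics (grammar, sarcasm,
misspellings beyond elongation), author and burst structure, near-
duplicate (non-identical) retweets, score magnitudes above s⁺/s⁻,
multi-drug tweets, or finance tweets that evade the keyword lists.
Recovery results certify the pipeline's correctness, not the lexicon's
validity on real language.

## Pipeline and problem sizes

The three analysis levels are produced in one run by checkpointing the
corpus after each filter stage, which makes the per-treatment count
nesting (all ≥ stock-removed ≥ stock+company-removed) hold by
construction. Each unique tweet is normalized and scored once; level
tables are computed over id subsets. Output csvs are schema-validated
before writing; a run log records every filter report and all config
values. Exit codes: 0 success, 2 configuration error, 3 input I/O
error, 4 degenerate data under `--strict`.

The test suite runs the recovery harness at 2000 tweets/treatment
(mean-score recovery within 3 standard errors, proportions within 3
binomial standard errors) and filter recovery at 500/treatment;
`scripts/acceptance.py` simulates at one tenth of the default volumes
(~6000 unique tweets). These sizes give standard errors an order of
magnitude below the effects of interest while keeping runs to seconds.

## Known limitations

* Count-difference scoring ignores negation, intensity and context.
* Substring filtering over-removes (e.g. "sec" ⊂ "second") and brand-
  name matching under-collects (generic names, misspellings) — both
  inherent to the keyword-list design.
* The chi-square p-value is approximate for very small groups; the
  all-identical convention (H = 0, p = 1) is a convention, not a
  statement about power.
* Ingestion assumes unique `tweet_id`s per file; cross-source merging
  is deduplication's job only insofar as texts are identical.
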