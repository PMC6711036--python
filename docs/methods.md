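# Methods

This note records the models, rules, parameters, and design choices behind
`bowelwatch`, and what the synthetic-data experiments do and do not
demonstrate.

## Corpus model and ingest

A corpus is a JSON-lines file of tweet records with a minimal subset of the
Twitter API v1.1 field names, so archived real data can be read by the same
loader. Ingest trusts the record's `lang` tag (no language identification is
performed), keeps English records only, and drops duplicate tweet ids
keeping the first occurrence. Timestamps are ISO-8601 and all calendar
bucketing is done in UTC.

## Text normalization

The cleaning cascade runs in a fixed order: structural stripping → hashtag
splitting → repeat squeezing → spelling correction → abbreviation expansion
→ tokenization. The order matters in two places: spelling correction runs
before abbreviation expansion so that dictionary misses can still expand,
and hashtag-derived words enter the same token stream as ordinary words, so
they are spell-checked and can participate in entity matching.

* **Structural stripping.** URLs and `@`-mentions are removed from the
  running text (and returned separately); hashtag bodies stay inline with
  the `#` marker removed; the characters `& ( ) * + < >` and typographic
  quotes are dropped; whitespace is collapsed.
* **Hashtag splitting** uses case and letter↔digit boundaries only
  (`gutHealth2018` → `gut / Health / 2018`). All-lowercase multiword tags
  stay unsplit: without a segmentation dictionary there is no boundary
  evidence, and a wrong split is worse than none. When a tag splits into
  several words, the split words are appended to the token stream while the
  unsplit body remains inline; single-word tags are left as the inline body,
  where abbreviation expansion may still apply (`#IBD` → `inflammatory
  bowel disease`).
* **Repeat squeezing** reduces every run of ≥ 3 identical characters to
  exactly two. Two-character runs are legitimate English; three or more are
  almost always emphasis.
* **Spelling correction.** A token absent from the spelling dictionary is
  replaced by the suggestion with the highest normalized Levenshtein
  similarity, 1 − d(a,b)/max(|a|,|b|) (two empty strings count as
  identical). The default suggester scans dictionary words within ±2
  characters of the token's length and a similarity floor of 0.7 — below
  that, "corrections" of genuinely out-of-vocabulary tokens (user names,
  concatenated hashtags) do more harm than good. Ties break to the
  lexicographically smallest suggestion so runs are reproducible.
  Correction applies only to purely alphabetic tokens.
* **Abbreviation expansion** is a case-insensitive dictionary lookup whose
  expansion words are marked with an `abbrev` origin, which the recognizer
  later reports as the match kind.
* **Tokenization** lowercases, deletes apostrophes (`crohn's` → `crohns`),
  maps hyphens and other punctuation to spaces (`gluten-free` → `gluten
  free`, aligning with lexicon normalization), removes stop words, and
  builds all contiguous 1/2/3-grams. The lemmatizer is a deliberately small
  suffix-stripping stub (regular plurals only); both it and the POS tagger
  are pluggable hooks, with tagging off by default. Emoji and ASCII
  emoticons are collected into a separate field — the profiler consumes
  them — and never enter the token or n-gram stream.

The full cascade is idempotent on its own output, which the suite checks on
generated corpora.

## User profiling

* **Gender** is resolved in two steps: the first whitespace-delimited token
  of the display name is looked up in a gender-name table carrying an
  explicit ambiguity flag; if that fails and a profile image exists, a
  pluggable image classifier (contract: image-ref → female / male /
  no-face) decides; otherwise gender is unknown. The package ships only a
  deterministic stub honouring the synthetic corpus's labelled
  `synthetic://face/<gender>/...` references — a trained face model is an
  external dependency by design.
* **Account type** is a fixed cascade. Organization evidence is tested
  first: (1) a country, country-code, or continent token in the display
  name, (2) a URL domain in the name, (3) non-personal keywords in the
  description. Only if none fire are the individual rules tried, in order:
  resolved gender, platform contributor/translator flag, first-person
  pronouns, emoji/emoticons, person abbreviations. Individuals carrying
  expert keywords (Dr, Prof, MD, PhD, …) as whole tokens become experts,
  the rest patients; no rule firing yields unknown. Keyword lists ship as
  an editable YAML resource because they are inherently open-ended seed
  lists, not closed vocabularies. An account matching both organization
  and individual evidence is an organization — cascade order decides.
  Exactly one audit tag (`matched_rule`) is recorded per account. Age
  estimation is deliberately out of scope.
* **Geolocation** lowercases the free-text location, applies an alias
  table (`NYC` → `New York City`), and matches against a gazetteer of
  (name, country, continent, time zone, UTC offset) rows. Ambiguous names
  are narrowed by time zone, then UTC offset; a filter is applied only if
  it leaves at least one candidate. If more than one candidate (necessarily
  in different countries) survives, the location is unknown — never a
  guess. Resolved locations therefore always carry a gazetteer country.

## Entity recognition

Lexicon rows (term, source vocabulary, category) are normalized in order:
lowercase; collapse whitespace; drop terms shorter than 2 characters or
longer than 280 (the maximum tweet length); replace special characters —
including hyphens — by spaces; purge any normalized term attached to more
than one meta-category (both entries are removed, since such a term cannot
be disambiguated by a dictionary matcher). A variant index maps the
lemmatized form of each entry to its canonical term.

Recognition is *inverted*: the tweet's 1–3-grams are the lookup keys,
which is cheap because a tweet holds at most a few dozen n-grams while the
lexicon may hold hundreds of thousands of terms. Windows are tried longest
first (3, 2, 1), left to right within a length; each window is tried
verbatim, then in lemmatized form; a match consumes its token positions so
no shorter overlapping mention can be reported (an `allow_overlap` flag
relaxes this). Mentions spanning abbreviation-expanded tokens are flagged
as abbreviation matches. For counting purposes a term counts once per
tweet regardless of repeats.

## Sentiment

The scorer follows the standard valence-lexicon-plus-rules recipe: each
token found in the lexicon contributes its mean valence, adjusted by
contextual rules — negation within the three preceding tokens flips and
damps the valence by −0.74; each booster in that window adds 0.293 toward
the word's sign; an ALL-CAPS sentiment word in mixed-case text is amplified
by 1.5; two or more trailing exclamation marks scale the final sum by
1.292 — and the sum *s* is normalized to s/√(s² + α) with α = 15, bounding
the compound in [−1, +1]. Labels use the community-standard ±0.05 cut
(inclusive on both sides). Scoring uses the raw tweet text because cleaning
destroys the emphasis cues; a flag allows scoring cleaned text instead, and
an external compound scorer can be plugged in for parity runs against
reference tools.

## Networks

The interaction graph is directed: an edge A→B accumulates A's mentions of
B, A's retweets of B (attributed retweeter → original author, so
information flow raises the author's in-degree), and — by default — A's
replies to B, since a reply embeds a mention; a flag excludes replies. The
co-occurrence graph links two terms whenever they appear in the same tweet,
weighted by tweet count, each edge carrying the modal polarity of its
contributing tweets (ties → neutral).

Metrics use the standard definitions: degree centrality degree/(n−1);
betweenness as the normalized shortest-path pair fraction; closeness in the
plain component-wise form (reachable − 1)/Σ distances (for digraphs, over
incoming distances); clustering 2·triangles/(k(k−1)) on the undirected
projection; characteristic path length as the mean shortest path over
connected (ordered, for digraphs) pairs; a single-node graph has all
centralities defined as zero. "Communities" are operationalized as
weakly-connected components with more than `min_size` (default 5) users —
the thematic labelling of communities is a manual, out-of-scope step — with
greedy modularity detection available behind a flag.

## Summary tables and arithmetic

All percentages are half-up-rounded: shares to two decimals
(100·count/total), event uplifts to whole percent
(100·window mean/baseline mean). Every percentage printed in a table is
exactly reproducible from the printed counts of its own row. A tweet
mentioning several categories counts once in each category row. Hashtag
counts for a term accept the term itself, its lemma form, or a leading
word-prefix (`#anxiety` counts toward `anxiety disorder`). Months are
bucketed in UTC and reported contiguously over the corpus range. URL tables
sort by the sum of tweet, retweet, and favorite counts; URL categories come
from an optional domain→category mapping and default to `uncategorized`.

## Synthetic corpus: what it emulates, and what it does not

The generator's defaults encode the emulated study conditions: 24,634
tweets from 13,295 users over 2018-02-01 … 2018-08-31; 4.1% non-English
records; a user-type mix with a 58.6% patient share (the organization,
expert, and unknown shares — 12%, 8%, 21.4% — are plausible fills, as the
study population reports only the patient share); the reported patient
gender shares (35.9% female, 49.5% male); per-category mention rates
proportioned to the reported category shares at ≈1.33 mentions/tweet;
sentiment proportions renormalized from the reported patient-tweet polarity
counts (53.1/14.3/32.7); a 5% misspelling rate (unreported; a typical
social-media rate); ~60% of users carrying a resolvable location; and a
May–June event window with interactions scaled ×3. Posting activity per
user is long-tailed (exponential-weight author sampling, rate 0.35), since
the emulated study does not report the per-user tweet distribution.

Construction guarantees drive the recovery tests: descriptions satisfy
exactly their true type's cascade rule; planted terms are separated by
neutral filler words disjoint from the lexicon so ground-truth alignment is
exact; perturbed tokens are single edits verified at generation time to
have the original as their unique best suggestion; polarity clauses use
valence words disjoint from the term lexicon. Consequently, on this corpus
user-type/gender recovery and planted-mention recall are exactly 100% and
sentiment label recovery is ≈100%. **These numbers certify the machinery,
not real-world accuracy**: real tweets have free word order, sarcasm,
out-of-template spelling errors, rule-violating profiles, unreliable
self-reported locations, and lexicon gaps, none of which the generator
models (non-goals: realistic language modelling, API rate limits). Note
also that because authorship is sampled independently of account type,
the patient share of *tweets* tracks the patient share of *users* (~59%)
rather than the lower tweet share a real corpus may show.

Determinism: all randomness flows through one `random.Random(seed)`;
identical configurations yield byte-identical JSONL, and the end-to-end
pipeline writes byte-identical tables across runs.

## Numerical and degenerate-input choices

Spelling ties break lexicographically; mention/target sampling uses
cumulative-weight draws for O(log n) determinism; empty text yields empty
outputs everywhere; an empty lexicon input builds an empty lexicon with a
warning; `share_percentage` rejects a zero total; event uplift rejects an
empty baseline window or a zero baseline mean; a single-node graph returns
zero centralities; two empty strings have Levenshtein similarity 1.

## Problem sizes used in verification

The test suite exercises a 400-tweet/250-user shared corpus for
per-module checks, 1,200 tweets for matcher-oracle equivalence, 2,000
users/2,000 tweets for recovery-at-scale, 100 random graphs of ≤ 12 nodes
against brute-force enumeration oracles, and 10,000 random texts for
sentiment bounds. `scripts/acceptance.py` runs the full emulated study
scale (24,634 tweets, 13,295 users), completing in well under a minute.

## Known limitations

The lemmatizer is a plural-stripping stub; the hashtag splitter cannot
segment all-lowercase tags; the image-classifier contract ships only a
synthetic stub; the matcher performs no fuzzy matching (misspellings must
be repaired upstream); community labelling and URL categorization are
manual steps represented only by free-text/mapping hooks; and statistical
inference on the summary tables is out of scope — they are descriptive.
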