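# Methods

## The extraction model

`methyltext` extracts gene methylation–cancer associations from abstract
text in two binary-classification stages. A sentence is first tokenized and
tagged with gene, methylation and cancer mentions. If it holds several
candidate pairs it is *expanded*: one relation instance per (gene,
methylation) or (gene, cancer) combination, each carrying an independent
copy of the sentence annotation, so that every instance contains exactly one
pair. A gene–methylation (GM) classifier decides whether the gene is
actually described as methylated; only sentences with at least one positive
GM pair reach the cancer tagger and the gene–cancer (GC) classifier, and
only the genes from positive GM pairs are paired with cancer mentions. Each
positive GC decision becomes an *evidence sentence* carrying the GC model's
positive probability.

Evidence is aggregated per (gene, cancer) pair:

    ranking_score(G, C) = Σ_{i=1..n} P(positive | sentence_i)        (GC model)
    average_max_probability = ranking_score / n

where n is the number of evidence sentences. Associations are ranked by
`ranking_score` (ties broken by gene identifier, then cancer name), and the
evidence inside an association by its probability, highest first. The sum
form makes the score strictly monotone in added positive evidence — an
association supported by many moderately confident sentences can outrank
one supported by a single confident sentence, which is the intended
behaviour for literature aggregation.

Assumptions worth stating: relations are sentence-bounded (no
cross-sentence coreference); one entity span has one kind; a sentence's
methylation direction (hyper/hypo/unspecified) is read off the regex prefix
of the methylation mention in the positive GM pair; identical evidence
sentences appearing in different abstracts are *not* deduplicated before
summing (a recurring finding accumulates weight).

## Named entity recognition

* **Methylation**: the token-level pattern `(hyper|hypo)?(-)?(methylat.+)`,
  case-insensitive, must match the whole token; the trailing `.+` therefore
  requires at least one character after "methylat" inside the same token.
  The optional prefix sets the direction (HYPER/HYPO, else UNSPECIFIED).
* **Cancer**: four candidate sources, resolved longest-span-first then
  leftmost-first, one kind per span, every mention recording the rule that
  produced it: (a) case-insensitive longest n-gram match against a
  canonical-name dictionary; (1) case-sensitive acronym lookup ("NPC",
  "CRC"); (2) an anatomical-site token immediately followed by one of the
  fixed keywords {cancer, tumor, tumour, neoplasm, carcinogenesis,
  tumorigenesis, metastasis}, the span covering both tokens; (3) a token
  ending in `oma` (stem ≥ 3 characters, which suppresses "soma"/"aroma"
  noise the literal one-character minimum would admit) or
  `leukemia`/`leukaemia`.
* **Genes**: dictionary lookup over token n-grams, case-sensitive first and
  case-insensitive second, after closing each dictionary surface under
  orthographic variants: hyphen inserted at the trailing letter→digit
  boundary (BRCA1 ↔ BRCA-1), hyphens removed, lower/upper case folds; the
  variant set is a fixpoint under re-application. The tagger sits behind a
  narrow interface so a statistical gene tagger can replace it.

The packaged cancer dictionary, acronym list, tumor-site list (~40
single-token anatomical sites) and ~40-gene dictionary are fixtures
assembled for self-contained operation — they approximate, and do not
reproduce, any particular curated resource; loaders accept user-supplied
TSV files.

Tagging evaluation supports **exact** matching (identical kind and span)
and **approximate** matching (same kind, spans overlap by ≥ 1 character),
with greedy one-to-one assignment that prefers an identical-span partner
before a merely overlapping one — this makes approximate precision/recall
provably no worse than exact, the ordering the evaluation is meant to
exhibit. Degenerate denominators (no predictions, no gold) report 0 with an
explicit flag rather than NaN.

## Features

All features are binary. Groups: unigrams/bigrams of tokens strictly
between the pair; the two tokens before the first and after the second
entity (document order, boundary markers beyond the sentence); chunk heads
and the concatenated chunk-type sequence between the entities plus the
flanking chunk heads, from a packaged rule-based POS-guesser/NP-VP-PP
chunker; a parse-path feature that uses a pluggable constituency-parser
adapter when configured and otherwise falls back to the inter-entity
chunk-type sequence (prefixed `FALLBACK:`); the sentence's relative
position r = index/(total−1) in its abstract, discretized into quintiles
(r = 0 for a single-sentence abstract; a non-empty title counts as sentence
0); one feature per matching induced template; and a flag for whether the
gene precedes its partner. Word forms are lower-cased and numerals mapped
to a `NUM` placeholder (toggleable) to limit sparsity. Extraction is pure —
identical instances give identical vectors — and disabling a group removes
exactly that group, which the ablation harness relies on.

The chunker is deliberately simple and deterministic; it exists to make
chunk and path features reproducible without an external parser, not to be
a competitive shallow parser.

## Template induction

Positive sentences are slotified (entity spans → `<gene>`, `<methylation>`,
`<cancer>`; other tokens lower-cased) and all unordered pairs aligned with
token-level Smith–Waterman scoring +1 per match, −1 per mismatch, −1 per
gap. Slot symbols match only themselves. Ties in the DP are broken toward
the smallest end cell and diagonal-over-up-over-left in traceback, making
induction deterministic and order-invariant. Pairs are ranked by score
(ties by the lexicographic agreement subsequence); for each of the top 100
pairs the agreement subsequence (aligned positions where both sides carry
the same token; mismatches and gaps elided) becomes a template if it keeps
at least one slot and two tokens. A human-curation step over the top pairs
is replaced by this agreement filter, with a `--review` export for optional
manual pruning. Template matching as a feature is *contiguous* occurrence
in the slotified sentence; gapped matching was considered and rejected to
keep feature semantics sharp. The all-pairs pass is quadratic; corpora
beyond 5,000 positive sentences are subsampled with a seed.

## The maximum-entropy classifier

A two-class conditional maximum-entropy model is an L2-regularized binary
logistic regression; we fit it by minimizing the penalized negative
conditional log-likelihood with L-BFGS and an analytic gradient. Defaults:
Gaussian-prior variance σ² = 1.0 (penalty ‖w‖²/2σ², bias unpenalized),
projected-gradient tolerance 1e-6, decision threshold 0.5 (configurable).
The objective is strictly convex, so the fit is deterministic up to
tolerance regardless of initialization; the tests verify a vanishing
gradient at the optimum, restart-independence of predicted probabilities to
1e-4, and agreement with scikit-learn's independent logistic-regression
implementation at the equivalent penalty (C = σ²). Unseen features at
prediction time contribute zero; an all-unseen vector falls back to the
fitted bias.

Evaluation is stratified k-fold cross-validation (default k = 10) with
per-fold positive-class precision/recall, reported as mean ± sd. Expansion
copies of one source sentence share a group key and are kept inside a
single fold, so near-duplicate instances never straddle the train/test
split; ungrouped splitting is available. A fixed-train-size mode
(`train_n`, e.g. 900) subsamples each fold's training portion for protocols
stated that way; the default uses all k−1 folds.

## The synthetic-data generator

The generator emulates the *structure* of methylation-focused abstract
sentences: every sentence holds at least one gene, one methylation term and
one cancer mention, built from four frame pools (clearly relational cues,
hedged neutral-positive wording, explicit negation, non-relational
mentions), with numeric fillers exercising tokenization and optional
multi-gene list sentences that expand into several single-pair instances.
One hedged frame is deliberately shared between the neutral-positive and
non-relational pools, so a small fraction of instances is irreducibly
ambiguous and classifier scores stay below 100% even at strong signal.
Defaults: 250 abstracts × 8 sentences = 2,000 sentences → 2,000 instances
per corpus at `multi_entity_rate = 0`, `positive_fraction = 0.5` (1,000
positive / 1,000 negative, the corpus shape the classifiers are designed
for), `signal_strength = 0.9` (cue vs hedged wording among positives),
`negation_fraction = 0.5` (negated vs non-relational wording among
negatives). Everything derives from one seed; identical seeds give
byte-identical corpora.

What it does not emulate: real lexical diversity, discourse structure,
anaphora, tagger errors on unseen entity spellings, or label noise. Passing
the recovery properties therefore shows the machinery is correct and the
features separate relational from non-relational wording under controlled
conditions; it does not certify performance on PubMed text. The generator's
cue frames include the canonical promoter-methylation phrasings; template
induction tests use frames the inducer was not given, to avoid circularity.

## Problem sizes and numerical choices in the checks

The alignment oracle cross-checks the DP against exhaustive enumeration of
all gapped local alignments on every sequence pair of length ≤ 3 over a
3-symbol alphabet plus a 200–400-pair seeded sample at lengths 4–6 — a
scope chosen to keep the enumeration honest (it is exponential) while
covering all gap/mismatch interactions. Classifier recovery runs grouped
stratified 10-fold CV on the default 2,000-instance corpora without
template features (their ablation delta is measured separately by
`pipeline.template_ablation`, which induces templates from a 60-sentence
seeded subsample of the positives). Tagger agreement is measured by
re-tagging 100 generated abstracts from raw text against the generator's
gold mentions.

## Known limitations

Dictionary gene tagging cannot find genes absent from the lexicon and does
not disambiguate gene symbols that collide with common words beyond
dictionary membership. The rule-based chunker is a heuristic; its features
are stable but shallow. The bootstrap labeling rule (negation cue between
or shortly after the pair ⇒ negative) is intentionally weak — it exists for
corpus bootstrapping and the worked example, and is superseded by the
trained models. Cross-abstract deduplication of evidence sentences is not
performed before ranking.
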