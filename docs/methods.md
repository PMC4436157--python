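# Methods

## Sequence model and encoding

The unit of analysis is the sentence; no cross-sentence sequences are
built. A tagged sentence becomes an ordered list of atomic items: each
gene mention — possibly multi-token — collapses to the single placeholder
`AGENE` (the pattern language has exactly one gene placeholder, so a
multi-token name must occupy one position), and every other token becomes
`lemma@pos` with both halves lowercased for canonical matching. POS codes
follow the TreeTagger English tagset (`nn` common noun, `vvz` 3rd-person
present verb, `in/that` complementizer, `sent` sentence-final punctuation,
...). Lemmas may contain `/` or other punctuation; items are taken
verbatim. The final punctuation token is retained as an ordinary item
(`.@sent`) — it carries distributional information (it is in every
sentence) and is handled like any other item downstream.

Sentences with fewer than two gene mentions are dropped before mining:
with a single mention an interaction can only be expressed anaphorically,
and anaphora resolution is out of scope. Coordinates are 0-based,
half-open token spans in all APIs; the inline-marker and XML dialects are
converted at read time.

## Mining

Support is per-sequence: a sentence containing a pattern several times
counts once. `minsup` may be an absolute count or a relative fraction
`f`, converted to `ceil(f·N)` over `N` sequences ("at least that
fraction"). The miner is a prefix-projection (PrefixSpan-style) search;
the algorithm is not normative — the contract is "exactly the non-empty
patterns with support ≥ minsup, canonically ordered (length, then
lexicographic)", and a brute-force enumerator with the same contract
serves as the independent oracle in the tests. Items are atomic (no
itemsets), matching the simplified sequence form the method uses.

`max_pattern_length` defaults to 10: corpus-scale mining at low minsup
produces tens of millions of patterns, and no useful extraction rule in
this domain approaches ten items; the cap is configurable off. Gap
constraints are deliberately *not* part of mining — gaps matter at rule
application time and live in the matcher.

## Constraint conjunction

The admissibility tests are: at least two `AGENE` items (configurable to
exactly-two), and at least one noun or verb item. Noun/verb is decided by
POS-code prefix: nouns `n*` (nn, nns, np, nps), verbs `v*` (vb*, vh*,
vv*), with the modal `md` excluded. Auxiliaries (vb*, vh*) count as verbs
by default; that is the permissive reading, and curation prunes patterns
built on semantically empty verbs. `AGENE` is never a noun or verb.

Maximality is computed *among the admissible frequent patterns*: an
inadmissible superpattern (e.g. with one `AGENE`) cannot shadow an
admissible subpattern. The filter deduplicates, then applies a quadratic
pairwise inclusion test — quadratic is fine at post-constraint scale
(hundreds of patterns); the output is an antichain and the filter is
idempotent.

## Recursive condensation

One group per distinct noun/verb item occurring in the constrained set;
a pattern with several such keywords is duplicated into every group.
Keyword identity is the full `lemma@pos` item: merging tag variants of
one lemma (e.g. a past/participle pair) is a curation decision, not an
algorithmic one.

Each round treats the current group as a sequence database and mines at
the absolute threshold `ceil(|E|/k)` (the relative 1/k bound), keeps the
admissible patterns, applies maximality, and repeats until ≤ k remain.
The round threshold is 1/k alone — the corpus-level absolute minsup is
not re-imposed inside rounds. After the first round the set is an
antichain, so its full members have within-group support 1 < ceil(|E|/k)
whenever |E| > k; each round therefore strictly shrinks toward shared
subsequences and terminates. `max_iterations` (default 25) is a safety
net only and never triggers in the test suite.

Degenerate groups — members sharing no frequent admissible subsequence —
would otherwise reduce to nothing; the implementation returns the k
highest-support pre-round members and logs a warning. Patterns are not
re-required to contain the group keyword after round one (membership is
defined once, on the initial set); a `strict_keyword` mode adds that
round constraint.

The output is bounded by n×k for n groups; duplicates arising from
multi-keyword patterns are merged.

## Rule matching and characterization

Matching enumerates *every* order-preserving embedding of the rule into
the sentence, not just the first, with unbounded gaps by default —
applying rules sentence-wide maximizes recall at a known cost in false
positives when a sentence holds several clauses; an optional `max_gap`
and an optional stop-item list ("but", "however") are provided, both off
by default. `AGENE` rule items bind only gene-mention positions. The
detected pair is bound by the rule's first two `AGENE` items; any further
`AGENE` items must still bind (strict embedding).

Detections are deduplicated per (sentence, unordered mention pair);
supporting rules accumulate rather than multiply detections. Direction
is curation metadata defaulting to `unknown`; an opt-in heuristic tags
passive/nominalized `by@in` constructions as right-gene-is-agent.

A characterization rule attaches to a detection only when it matches the
same sentence *and* binds the same mention pair (the stricter reading);
`require_same_pair=False` gives the looser co-occurrence reading.

## Evaluation

Scoring is pair-level with unordered name pairs per sentence: distinct
unordered pairs, so repeated mentions of the same pair in one sentence
count once, and self-pairs cannot arise from distinct-position binding
of one mention. Percentages are reported rounded to one decimal;
internal arithmetic is unrounded. `f = 2PR/(P+R)`, zero when both are
zero.

Oracle validation applies each rule individually, deduplicates its
detections to distinct (unordered pair, PMID), and counts how many are
present in the oracle (case-insensitive on symbols). Precision is
undefined — reported as `undefined`, not 0 — for a rule retrieving
nothing. A per-sentence audit mode keeps one verdict row per sentence
without changing the counts.

## Gene NER

Tiers in priority order: official acronym, old acronym, alias, full
name, significant part, plural part. Ambiguous acronyms (common English
words) match only in full uppercase, in every acronym tier. Overlaps
resolve longest-match-first, then leftmost, then tier priority; output
spans never overlap. Matching is token-based over a simple
`\w+(-\w+)*` tokenizer (so `c-myc` is one token); character spans derive
from token offsets. Full-name keys drop pure-number tokens and Greek
letters.

Significant parts: a word ending in "in", a word ending in "ase" (both
at minimum length 5, preventing "in"/"as" pathologies), and the word
immediately preceding "protein" together with "protein" (one preceding
word, not the whole phrase — the narrow reading). The literal word
"protein" never forms a part by itself. Plurals append "s" and "es" to
the last word of a part.

## Synthetic corpus generator

The generator emulates the *statistical* structure of a training corpus
of interaction sentences, not fluent English: planted pattern templates
with random gene symbols, Poisson-distributed filler tokens in every gap
(mean 0.8 per gap), distractor sentences (2–3 genes, fillers only), and
background sentences (< 2 genes, exercising the corpus filter). Defaults
are the study conditions used throughout the suite: 300 sentences, 8
interaction templates planted 15× each, 4 characterization templates
planted 12× each, distractor rate 0.3, mined at minsup 10 and condensed
at k 4.

Two structural choices keep the conditions clean and are worth knowing
when interpreting test results. First, the filler vocabulary contains no
noun/verb items and is disjoint from all template items, so admissible
frequent patterns can only be built around planted keywords. Second,
each characterization sentence embeds one *uniformly random* interaction
template between the characterization pattern's final `AGENE` pair: the
characterization always has a detectable interaction to attach to, and
no specific char+interaction superpattern becomes frequent (expected
support ≈ plant_count/8 < minsup), which would otherwise shadow the
interaction template under maximality. Genes are drawn without
replacement within a sentence (no self-pairs; a flag enables them).
Every sentence ends with `.@sent`; recovered maximal patterns therefore
carry that item, and the planted template is recovered as a subsequence
of the final pattern — the recovery tests accept either direction of
inclusion.

What passing the end-to-end tests shows: the mining → constraints →
condensation → matching machinery recovers a planted grammar exactly and
transfers across corpora drawn from the same distribution. What it does
not show: performance on real biomedical prose, where interaction
vocabulary is Zipf-distributed, clause structure produces genuine false
positives, and gold annotation is noisy — corpus-scale scores require
the real corpora and expert curation and are out of scope here.

## Numerical and degenerate-input choices

Relative support on an empty database raises rather than returning 0.
The empty pattern has support |SDB| but is never emitted by mining.
Mining outputs, constraint outputs and reductions are always in the
canonical (length, lexicographic) order, so equal inputs give
byte-identical outputs. Rule matching returns embeddings in lexicographic
order. All generator randomness flows from one mandatory integer seed
through a single `numpy` generator.
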