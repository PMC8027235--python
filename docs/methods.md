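# Methods

## Model

`thermotriage` implements a rule-based document classifier for
identifying full-text articles that report experimental protein
thermodynamic-stability data. The model has three layers:

1. **Extraction.** An article (PMC-style full-text HTML) is reduced to
   its ordered paragraph and table elements. Inline markup is flattened
   with no inserted separator, so a subscripted symbol such as ΔG with a
   subscript U reconstructs as the contiguous token `ΔGU` that the
   symbol patterns expect. Table cell texts are joined with single
   spaces in row-major order, and a paragraph nested inside a table
   belongs to the table unit only (no double counting). HTML entities
   are decoded and text is normalized to composed Unicode (NFC),
   because the Greek delta appears both as an entity and as a literal.

2. **Matching.** Each unit is searched for the four scored term
   classes. Concept words (TC) are matched on lowercase noun-mode
   lemmas so plural and singular forms unify; symbols (TV) and units of
   measure (UM) are matched on the raw text, where case and
   punctuation are meaningful; computational concepts (CC) are matched
   word-bounded on lowercased raw text. Overlapping scored candidates
   are resolved greedily, longest span first and leftmost on ties:
   ΔΔG yields one +3 match rather than +3 and +2, and the composite
   "md simulation" (−2) suppresses the standalone "simulation" (−1).
   Binding-process terms and amino-acid variant mentions are matched
   for annotation only and never enter the score or the overlap
   resolution.

3. **Scoring and decision.** A unit's score sums its matched term
   weights with each canonical term counted at most once per unit
   ("without repetitions"); the dedup applies to the summation only —
   every occurrence is retained for highlighting. Document aggregates
   are the total, the maximum unit score (Max) and the mean unit score
   (Mean). Extraction is gated: with the TC class enabled, an article
   containing no concept word anywhere is scored 0 everywhere
   (`gated_out`). The classifier is a threshold on the active
   aggregate, inclusive (`score >= TH`); the default operating points
   are Max ≥ 3.00 and Mean ≥ 1.36.

## Parameters that matter

- **Term weights** (integers, dimensionless score points): TC words +1;
  bare Cp/Tm +1, single-difference symbols +2, double-difference +3;
  °C +1, energy-per-amount unit strings +2; CC words −1, composite
  "md simulation" −2. These are the published lexicon and are shipped
  as data (a serializable TSV), not code, so alternative pattern sets
  can be dropped in.
- **Mode** (`Max` | `Mean`) and **threshold**: Max ≥ 3.00 is the
  default; the Mean variant's operating point is 1.36.
- **Enabled classes**: dropping TC also disables the gate; this gives
  the class-ablation variants (TC alone, TV ∪ UM, TC ∪ TV ∪ UM, all
  four) used to attribute classification power.

## Design choices where the design was open

- **Mean denominator.** The mean unit score is taken over units with at
  least one scored match, not over all units. An operating point above
  1 would be implausible if the average ran over the many matchless
  paragraphs of a full article, and restricting to scored units makes
  the statistic comparable across article lengths.
- **Gate scope.** One concept word anywhere in the article unlocks
  extraction of every unit, and gating suppresses all classes
  (including the CC penalties and annotations).
- **Negative scores** are kept as-is; no flooring at zero. The CC class
  is explicitly a penalization and a document total can be negative.
- **Symbol boundaries.** TV and UM matches require a non-alphanumeric
  character on each side, so `ΔGunf` does not match; the °C pattern
  allows a preceding digit (`25°C`).
- **ASCII fallbacks.** The delta symbols accept `dG`/`ddG`/`DDG` and
  spelled-out `delta G` forms, since HTML flattening and author style
  vary. Unit strings are matched case-insensitively throughout
  (`Kcal/Mol` matches); the spec of stricter case handling for the
  energy prefix was ambiguous and the permissive reading was chosen.
- **CC word boundaries.** `predict` is matched as an exact word;
  derived forms (`predicted`, `prediction`) do not match. This is the
  literal reading of the word list; a stemming reading would score
  more aggressively and can be obtained with a custom lexicon.
- **Zero-background smoothing** in enrichment: a word absent from the
  background corpus gets p_bg = 1/(n_bg + 1), keeping its p-value
  finite while preserving the ranking's monotonicity in background
  frequency. Document frequency (presence/absence), not term
  frequency, is counted, and no multiple-testing correction is applied
  — the procedure ranks candidates, it does not test them.
- **Lemmatization** is a noun-mode suffix-rule morphologizer with a
  small irregular-plural table, written for this package. Noun mode
  guarantees that gerund-form domain terms ("unfolding") are not
  reduced to verb stems. It is deliberately conservative; words it
  cannot analyze are passed through unchanged.
- **Stopwords** are a frozen standard English list shipped as package
  data, so results cannot drift with library versions; it can be
  overridden per call.

## Evaluation conventions

- Any metric with a zero denominator is reported as 0, including MCC.
- AUC is the tie-aware Mann–Whitney probability computed through
  midranks; it equals a pairwise brute-force count exactly.
- AUPR uses step-wise interpolation (precision held constant to the
  right of each recall step); trapezoidal PR areas are optimistically
  biased and are not used. This can deviate slightly from figures
  produced with other interpolation rules.
- Candidate thresholds for MCC maximization are the observed distinct
  score values — document scores are small integers/rationals, so this
  is equivalent to a continuous sweep under the inclusive rule. Ties
  are broken toward the smallest threshold.
- A repeated-subsampling harness draws R equal-size negative subsets
  from a larger pool (default R = 10), evaluates each balanced set at a
  fixed threshold, and reports mean and min–max band per metric.

## Synthetic corpora

The generator emulates the statistical skeleton of a labeled triage
corpus: positive articles carry concept words, symbols and unit strings
at high per-unit injection rates (defaults 0.9 / 0.6 / 0.6), negative
articles at low rates (0.05) plus computational vocabulary (0.3).
Default corpus size is 50 + 50 articles of 4–8 units each. Filler text
is drawn from a fixed vocabulary of pronounceable pseudo-words
(consonant–vowel syllables), which by construction cannot collide with
any lexicon pattern; generation filters any candidate filler word that
matches, and a test asserts that pure filler scores zero. Generation is
a pure function of (spec, seed).

What the generator does **not** emulate: natural scientific prose,
section structure, citation boilerplate, tables with realistic numeric
layouts, or the subtle negative class of articles that *discuss*
thermodynamics without reporting measurements. Passing recovery tests
on these corpora therefore demonstrates the internal consistency of the
pipeline (matching, scoring, gating, ranking, threshold selection) —
not field performance on real literature, which depends on corpus
composition and the curator's labeling criteria.

## Degenerate inputs and numerical notes

- Unparseable HTML yields an empty document (logged warning), which
  scores 0 in every aggregate.
- An empty document or a document with no scored unit has total = max =
  mean = 0 and n_units_scored = 0.
- Mean scores are computed with exact rational arithmetic before
  conversion to float.
- The binomial survival probability P(X ≥ k) is evaluated through the
  distribution's survival function (stable in log space for large n);
  k = 0 returns exactly 1.

## Problem sizes

The test suite and the acceptance script run on minimal documents
(single paragraphs per published weight), randomized matcher inputs of
~1,000 strings, metric oracles up to n = 200 scores and 1,000 random
confusion tables, and synthetic corpora of 50 + 50 articles — sizes at
which every oracle comparison is exact and the full suite runs in a few
seconds.

## Known limitations

- The original symbol-matching regular expressions are not public; the
  patterns here are reconstructed from the published term lists and
  weights, and the lexicon's TSV serialization exists precisely so a
  recovered original can be substituted.
- Corpus-level performance numbers reported for the original tool
  (optimization and held-out test tables) require bulk full-text
  downloads with curated labels and are out of scope; nothing in this
  package claims to reproduce them.
- Concept matching is lexical; no named-entity recognition, numeric
  value extraction, or sentence-level context is attempted. The tool
  flags documents for curation, it does not extract ΔΔG values.
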