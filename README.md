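# thermotriage

Curation of experimental protein-stability data — melting temperatures
(Tm, ΔTm), unfolding free energies (ΔG, ΔΔG), heat capacities (ΔCp) —
still depends on domain experts reading full-text articles. Legacy
resources such as ProTherm are no longer maintained, and the articles
worth a curator's time are a fraction of a percent of the literature
that mentions "protein" and "stability". `thermotriage` is a
lexicon-based triage tool for that problem: it scores the paragraphs
and tables of a full-text HTML article with a four-class thermodynamic
vocabulary and flags the articles likely to report experimental
stability measurements.

## The scoring model

An article is split into its paragraph (`<p>`) and table (`<table>`)
units. Each unit is searched for four classes of terms with integer
weights:

| class | examples | weight |
|-------|----------|--------|
| TC — thermodynamic concepts | unfolding, two-state, denaturant, dichroism, midpoint | +1 |
| TV — thermodynamic variables | Cp, Tm (+1); ΔX (+2); ΔΔX (+3), X ∈ {Cp, Tm, UG, GU, G, H, T, U} | +1…+3 |
| UM — units of measure | °C (+1); kcal/mol, kJ/mol/K, … (+2) | +1/+2 |
| CC — computational concepts | simulation, molecular dynamics, force field, charmm, gromacs, amber, PBSA, GBSA, predict (−1); "md simulation" (−2) | −1/−2 |

A unit's score is the sum of its matched term weights *without
repetitions* (each term counts once per unit); overlapping matches are
resolved longest-first, so ΔΔG is a single +3, not +3 and +2.
Extraction is gated on the concept class: if no TC word occurs anywhere
in the article, nothing is extracted and the article scores 0. The
article-level decision thresholds the maximum unit score (default
Max ≥ 3.00; a mean-based variant uses 1.36). Binding-process terms and
amino-acid variant mentions (V31A, Ala123Gly) are annotated for the
curator but never scored.

The package also ships the machinery used to build and validate such a
scorer: binomial document-frequency enrichment for concept-word
selection (rank words by P(X ≥ k_pos), X ~ Binomial(n_pos, p_bg)), the
standard binary-classification metrics (Q2, TNR, NPV, TPR, PPV, MCC,
F1, AUC, AUPR) with MCC-maximizing threshold selection, a synthetic
labeled-corpus generator, and an annotated-HTML report renderer
(thermodynamic terms red, computational terms blue, variants green).

## Worked example

```python
from thermotriage import build_default_lexicon, score_document
from thermotriage.scoring import ClassifierConfig, classify
from thermotriage.synthetic import worked_example_document

doc = worked_example_document()   # three paragraphs, packaged example
ds = score_document(doc, build_default_lexicon(), ClassifierConfig())
print([u.score for u in ds.unit_scores], ds.total, ds.max_score)
print(classify(ds, ClassifierConfig(mode="Max", threshold=3.0)))
```

prints

```
[6, 1, -2] 5 6
positive
```

The first paragraph contains ΔΔG (+3), *unfolding* (+1) and kcal/mol
(+2) for a unit score of 6; the second only *midpoint* (+1); the third
triggers the "md simulation" penalty (−2). The maximum unit score 6
meets the Max ≥ 3 rule, so the article is flagged positive.

The same classifier is available as a scikit-learn estimator:

```python
from thermotriage import ThermoTriageClassifier
clf = ThermoTriageClassifier(mode="Max").fit(html_strings, labels)
clf.threshold_        # MCC-maximizing threshold on the training scores
clf.predict(html_strings)
```

and from the shell:

```sh
thermotriage scan articles/ -o scores.tsv        # ranked score table
thermotriage report article.html -o report.html  # highlighted curation view
thermotriage simulate --outdir corpus/           # synthetic labeled corpus
thermotriage rank-words --pos pos/ --bg bg/ -o words.tsv
thermotriage evaluate scores.tsv labels.tsv --optimize
```

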