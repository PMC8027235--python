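"""A scikit-learn-compatible estimator around the lexicon scorer.

The pipeline is a fixed rule system — lexicon matching, per-unit
summation, document aggregation — with exactly one free parameter, the
decision threshold on the active (Max or Mean) score. That makes it a
natural scikit-learn classifier: ``fit`` learns the threshold by
maximizing the Matthews correlation coefficient over observed scores
(or adopts a fixed one), ``decision_function`` exposes the document
scores, and ``predict`` applies the inclusive ``>=`` rule. The
estimator composes with sklearn model selection and pipelines.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .corpus import Document, parse_article_html
from .evaluation import evaluate_scores, optimize_threshold
from .lexicon import Lexicon, TermClass, build_default_lexicon
from .scoring import (
    DEFAULT_MAX_THRESHOLD,
    DEFAULT_MEAN_THRESHOLD,
    ClassifierConfig,
    score_document,
)

__all__ = ["ThermoTriageClassifier"]


class ThermoTriageClassifier(ClassifierMixin, BaseEstimator):
    """Lexicon-score document classifier with an MCC-fitted threshold.

    Parameters
    ----------
    mode : {"Max", "Mean"}, default="Max"
        Aggregate used as the decision score: the maximum unit score or
        the mean over units with at least one scored match.
    threshold : float or None, default=None
        Decision threshold. ``None`` learns it in :meth:`fit` by
        maximizing MCC over the training scores; a number fixes it
        (the canonical operating points are 3.00 for Max, 1.36 for
        Mean).
    term_classes : iterable of str, default=("TC", "TV", "UM", "CC")
        Scored classes to enable; dropping "TC" also disables the
        concept gate (class-ablation variants).
    lexicon : Lexicon or None
        Custom lexicon; ``None`` uses the packaged default.

    Attributes
    ----------
    threshold_ : float
        The operating threshold after fitting.
    classes_ : ndarray of shape (2,)
        Label vocabulary; ``classes_[1]`` is the positive class.
    train_result_ : EvalResult
        Full evaluation on the training data at ``threshold_``.
    """

    def __init__(
        self,
        mode: str = "Max",
        threshold: Optional[float] = None,
        term_classes: Iterable[str] = ("TC", "TV", "UM", "CC"),
        lexicon: Optional[Lexicon] = None,
    ):
        self.mode = mode
        self.threshold = threshold
        self.term_classes = term_classes
        self.lexicon = lexicon

    # --- internals -------------------------------------------------

    def _config(self) -> ClassifierConfig:
        enabled = frozenset(TermClass(c) for c in self.term_classes)
        default_th = (
            DEFAULT_MAX_THRESHOLD if self.mode == "Max" else DEFAULT_MEAN_THRESHOLD
        )
        th = default_th if self.threshold is None else self.threshold
        return ClassifierConfig(mode=self.mode, threshold=th, enabled_classes=enabled)

    def _as_documents(self, X: Sequence[Union[Document, str]]) -> List[Document]:
        docs = []
        for i, x in enumerate(X):
            if isinstance(x, Document):
                docs.append(x)
            elif isinstance(x, str):
                docs.append(parse_article_html(x, doc_id=f"doc{i}"))
            else:
                raise TypeError(
                    "X must contain Document objects or HTML strings, "
                    f"got {type(x).__name__}"
                )
        return docs

    def _scores(self, X) -> np.ndarray:
        cfg = self._config()
        lex = self.lexicon if self.lexicon is not None else build_default_lexicon()
        return np.array(
            [score_document(d, lex, cfg).active(self.mode) for d in self._as_documents(X)]
        )

    # --- sklearn API -----------------------------------------------

    def fit(self, X, y):
        """Score the training documents and set the threshold.

        With ``threshold=None`` the MCC-maximizing threshold over the
        observed scores is selected (ties: smallest); otherwise the
        given threshold is adopted and only evaluated.
        """
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required for fitting")
        scores = self._scores(X)
        y_bool = y == self.classes_[1]
        if self.threshold is None:
            self.threshold_, self.train_result_ = optimize_threshold(scores, y_bool)
        else:
            self.threshold_ = float(self.threshold)
            self.train_result_ = evaluate_scores(scores, y_bool, self.threshold_)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Active document scores (Max or Mean per document)."""
        return self._scores(X)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        scores = self.decision_function(X)
        return self.classes_[(scores >= self.threshold_).astype(int)]
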