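"""Linear-SVM relation classifier with development-set grid search.

Protocol: for each regularization strength in the grid, fit one-vs-rest
linear SVMs on the training examples and score macro-F1 on the development
set; the winning setting is refitted on train ∪ dev.  No sentence-level
features exist, so intra- and intersentential pairs are classified jointly
by a single model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import LinearSVC

from .candidates import CandidateExample
from .evaluation import score
from .features import FeatureResources, extract_features
from .types import NONE_LABEL, AnnotatedDocument

log = logging.getLogger(__name__)

DEFAULT_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class SVMModel:
    vectorizer: DictVectorizer
    classifier: LinearSVC
    resources: FeatureResources
    window: int
    chosen_c: float
    selection_trace: list[dict] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [str(c) for c in self.classifier.classes_]

    def predict(
        self,
        examples: list[CandidateExample],
        docs: dict[str, AnnotatedDocument],
    ) -> list[str]:
        if not examples:
            return []
        feats = [
            extract_features(ex, docs[ex.doc_id], self.resources, self.window)
            for ex in examples
        ]
        X = _index32(self.vectorizer.transform(feats))
        return [str(y) for y in self.classifier.predict(X)]


def _index32(X):
    # liblinear accepts 32-bit sparse indices only
    import numpy as np

    X = X.tocsr()
    X.indices = X.indices.astype(np.int32)
    X.indptr = X.indptr.astype(np.int32)
    return X


def _fit_svc(X, y, c: float, seed: int) -> LinearSVC:
    clf = LinearSVC(C=c, random_state=seed, max_iter=5000)
    clf.fit(_index32(X), y)
    return clf


def train_svm(
    train_examples: list[CandidateExample],
    dev_examples: list[CandidateExample],
    docs: dict[str, AnnotatedDocument],
    resources: FeatureResources,
    grid: tuple[float, ...] = DEFAULT_GRID,
    seed: int = 0,
    window: int | None = None,
) -> SVMModel:
    """Grid search on dev, then refit the winner on train ∪ dev."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    w = resources.window if window is None else window
    train_labels = sorted({ex.label for ex in train_examples})
    if len(train_labels) < 2:
        raise ValueError(f"training data has a single class: {train_labels}")

    def featurize(examples: list[CandidateExample]):
        return [extract_features(ex, docs[ex.doc_id], resources, w) for ex in examples]

    train_feats = featurize(train_examples)
    y_train = [ex.label for ex in train_examples]
    vectorizer = DictVectorizer()
    X_train = vectorizer.fit_transform(train_feats)
    dev_feats = featurize(dev_examples)
    X_dev = vectorizer.transform(dev_feats)
    y_dev = [ex.label for ex in dev_examples]
    dev_positives = sorted({y for y in y_dev if y != NONE_LABEL})

    trace = []
    best_c, best_f1 = None, -1.0
    for c in grid:
        clf = _fit_svc(X_train, y_train, c, seed)
        dev_pred = [str(p) for p in clf.predict(_index32(X_dev))]
        f1 = score(y_dev, dev_pred, dev_positives).macro_f1
        trace.append({"C": c, "dev_macro_f1": f1})
        log.info("grid C=%g dev macro-F1=%.2f", c, f1)
        if f1 > best_f1:
            best_c, best_f1 = c, f1

    all_feats = train_feats + dev_feats
    y_all = y_train + y_dev
    X_all = vectorizer.transform(all_feats)
    final = _fit_svc(X_all, y_all, best_c, seed)
    return SVMModel(
        vectorizer=vectorizer,
        classifier=final,
        resources=resources,
        window=w,
        chosen_c=best_c,
        selection_trace=trace,
    )


def predict_svm(
    model: SVMModel, example: CandidateExample, doc: AnnotatedDocument
) -> str:
    return model.predict([example], {doc.doc_id: doc})[0]
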