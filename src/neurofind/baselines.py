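"""Traditional sentence classifiers over word-vector features.

Logistic regression, linear-kernel SVM and random forest, each consuming
either the mean-pooled embedding of a sentence (default) or a bag-of-words
count vector over the training vocabulary. Document aggregation reuses the
max-score rule of the CNN path.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from neurofind.corpus_io import Label
from neurofind.embedding_cnn import EmbeddingTable, aggregate_document
from neurofind.errors import DegenerateInputError


class FeatureMode(enum.Enum):
    MEAN_POOL = "mean_pool"
    BOW = "bow"


class ModelKind(enum.Enum):
    LOGREG = "logreg"
    SVM = "svm"
    RANDOM_FOREST = "rf"


def mean_pool(tokens: Sequence[str], table: EmbeddingTable) -> np.ndarray:
    """Arithmetic mean of the tokens' embedding rows (OOV -> sentinel)."""
    if not tokens:
        raise DegenerateInputError("cannot featurize an empty token list")
    rows = table.vectors[[table.index_of(t) for t in tokens]]
    return rows.mean(axis=0)


def build_bow_vocabulary(sentences: Sequence[Sequence[str]]) -> dict[str, int]:
    vocab: dict[str, int] = {}
    for toks in sentences:
        for t in toks:
            vocab.setdefault(t, len(vocab))
    return vocab


def bow_vector(tokens: Sequence[str], vocabulary: dict[str, int]) -> np.ndarray:
    if not tokens:
        raise DegenerateInputError("cannot featurize an empty token list")
    v = np.zeros(len(vocabulary))
    for t in tokens:
        i = vocabulary.get(t)
        if i is not None:
            v[i] += 1
    return v


def featurize(
    tokens: Sequence[str],
    table: EmbeddingTable | None = None,
    mode: FeatureMode = FeatureMode.MEAN_POOL,
    vocabulary: dict[str, int] | None = None,
) -> np.ndarray:
    if mode is FeatureMode.MEAN_POOL:
        if table is None:
            raise ValueError("MEAN_POOL mode requires an embedding table")
        return mean_pool(tokens, table)
    if vocabulary is None:
        raise ValueError("BOW mode requires a training vocabulary")
    return bow_vector(tokens, vocabulary)


@dataclass
class BaselineModel:
    """A fitted baseline with its featurization context."""

    kind: ModelKind
    estimator: object
    mode: FeatureMode
    table: EmbeddingTable | None = None
    vocabulary: dict[str, int] | None = None
    tau_pos: float = 0.5

    def _features(self, sentences: Sequence[Sequence[str]]) -> np.ndarray:
        return np.array(
            [featurize(t, self.table, self.mode, self.vocabulary) for t in sentences]
        )

    def sentence_scores(self, sentences: Sequence[Sequence[str]]) -> np.ndarray:
        if not sentences:
            return np.zeros(0)
        return self.estimator.predict_proba(self._features(sentences))[:, 1]

    def classify_document(self, sentences: Sequence[Sequence[str]]) -> Label:
        return aggregate_document(self.sentence_scores(sentences), self.tau_pos)


def _make_estimator(kind: ModelKind, seed: int):
    if kind is ModelKind.LOGREG:
        # default penalty is L2; C=1
        return LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    if kind is ModelKind.SVM:
        # probability=True enables Platt scaling so the max-score document
        # rule applies uniformly across model kinds
        return SVC(kernel="linear", C=1.0, probability=True, random_state=seed)
    return RandomForestClassifier(n_estimators=500, random_state=seed)


def train_baseline(
    model_kind: ModelKind | str,
    sentences: Sequence[Sequence[str]],
    labels: Sequence[int],
    table: EmbeddingTable | None = None,
    mode: FeatureMode = FeatureMode.MEAN_POOL,
    seed: int = 0,
    tau_pos: float = 0.5,
) -> BaselineModel:
    """Fit one traditional classifier on featurized sentences (0/1 labels)."""
    kind = ModelKind(model_kind) if not isinstance(model_kind, ModelKind) else model_kind
    if len(set(labels)) < 2:
        raise DegenerateInputError("training data must contain both classes")
    vocabulary = build_bow_vocabulary(sentences) if mode is FeatureMode.BOW else None
    model = BaselineModel(
        kind=kind,
        estimator=_make_estimator(kind, seed),
        mode=mode,
        table=table,
        vocabulary=vocabulary,
        tau_pos=tau_pos,
    )
    X = model._features(sentences)
    model.estimator.fit(X, np.asarray(labels, dtype=int))
    return model
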