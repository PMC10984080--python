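"""TF-IDF features, classical classifiers, and the note-classification model.

Feature extraction
------------------
Notes are encoded as TF-IDF vectors over unigrams, bigrams and trigrams after
English stopword removal and document-frequency thresholding (terms must
appear in at least ``min_df`` documents and at most ``max_df`` of the corpus).
The idf variant is the smoothed form

    idf(t) = ln((1 + N) / (1 + df(t))) + 1

with L2 row normalization, so a document's weight vector has unit norm.

Classification
--------------
Four classifiers with probability outputs are supported — logistic
regression, random forest, multilayer perceptron and gradient-boosted trees
(XGBoost) — all seed-pinned for reproducibility. Hyperparameters follow the
library defaults, except XGBoost which defaults to many rounds of shallow
(depth-2) trees: on L2-normalized sparse text features the class signal is a
sum of many weak presence features, which additive shallow boosting captures
far better than deep trees. The decision threshold is 0.5 with ties positive.

Model/Results interface
-----------------------
:class:`NoteClassifier` is built from a corpus (optionally pre-selected to a
keyword tier), and ``fit()`` returns a :class:`NoteClassifierResults` carrying
the held-out-test metrics with bootstrap CIs, the predictions, and a
``summary()`` table. The train/validation/test partition (default 70/15/15,
stratified by label) is drawn once from the model's seed so that competing
methods can share an identical test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

from .evaluation import BootstrapSpec, MetricsReport, bootstrap_metrics
from .selection import SelectionTier, select_sentences
from .textprep import Note

__all__ = [
    "TfidfConfig",
    "TfidfModel",
    "SplitSpec",
    "fit_tfidf",
    "transform_tfidf",
    "train_classifier",
    "predict",
    "labels_from_scores",
    "NoteClassifier",
    "NoteClassifierResults",
    "MODEL_TYPES",
]

MODEL_TYPES = ("logreg", "random_forest", "mlp", "xgboost")
ModelType = Literal["logreg", "random_forest", "mlp", "xgboost"]


class FeatureConfigError(RuntimeError):
    """Raised when TF-IDF filtering leaves an empty vocabulary."""


@dataclass(frozen=True)
class TfidfConfig:
    """TF-IDF featurization choices (n-gram span, df thresholds, stopwords)."""

    ngram_range: tuple[int, int] = (1, 3)
    min_df: int = 5
    max_df: float = 0.9
    stop_words: str | None = "english"
    norm: str | None = "l2"
    lowercase: bool = True


@dataclass
class TfidfModel:
    """A fitted vectorizer: vocabulary (term -> column), idf weights, config."""

    vectorizer: TfidfVectorizer
    config: TfidfConfig
    n_documents: int

    @property
    def vocabulary(self) -> dict[str, int]:
        return self.vectorizer.vocabulary_

    @property
    def idf(self) -> np.ndarray:
        return self.vectorizer.idf_


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (must sum to 1) and stratification."""

    train: float = 0.70
    validation: float = 0.15
    test: float = 0.15
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train, self.validation, self.test)
        if any(f <= 0 for f in fracs):
            raise ValueError("split fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fracs)}")


def split_indices(labels: Sequence, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint (train, validation, test) index arrays covering the corpus."""
    y = np.asarray(labels)
    idx = np.arange(len(y))
    strat = y if spec.stratify else None
    rest, test = train_test_split(
        idx, test_size=spec.test, stratify=strat, random_state=spec.seed
    )
    val_frac = spec.validation / (spec.train + spec.validation)
    strat_rest = y[rest] if spec.stratify else None
    train, val = train_test_split(
        rest, test_size=val_frac, stratify=strat_rest, random_state=spec.seed
    )
    return np.sort(train), np.sort(val), np.sort(test)


def fit_tfidf(corpus: Sequence[str], config: TfidfConfig = TfidfConfig()) -> TfidfModel:
    """Fit the TF-IDF vocabulary and idf weights on ``corpus``.

    Deterministic given the corpus and config. Raises
    :class:`FeatureConfigError` with diagnostic counts when stopword removal
    and df thresholding leave nothing.
    """
    if len(corpus) == 0:
        raise ValueError("corpus must be non-empty")
    vec = TfidfVectorizer(
        ngram_range=config.ngram_range,
        min_df=config.min_df,
        max_df=config.max_df,
        stop_words=config.stop_words,
        norm=config.norm,
        lowercase=config.lowercase,
        smooth_idf=True,
        sublinear_tf=False,
    )
    try:
        vec.fit(corpus)
    except ValueError as exc:
        raise FeatureConfigError(
            f"TF-IDF vocabulary is empty after filtering {len(corpus)} documents "
            f"(min_df={config.min_df}, max_df={config.max_df}, "
            f"stop_words={config.stop_words!r}): {exc}"
        ) from exc
    return TfidfModel(vectorizer=vec, config=config, n_documents=len(corpus))


def transform_tfidf(model: TfidfModel, corpus: Sequence[str]) -> sp.csr_matrix:
    """Weight matrix (documents x vocabulary); out-of-vocabulary terms ignored."""
    return model.vectorizer.transform(corpus)


_DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "logreg": {"max_iter": 1000},
    "random_forest": {"n_estimators": 300, "n_jobs": 1},
    "mlp": {"hidden_layer_sizes": (64,), "max_iter": 300},
    # shallow trees with more boosting rounds: on sparse TF-IDF rows the signal
    # is a sum of many weak presence features, which additive stumps capture
    # far better than the deep-tree default
    "xgboost": {
        "n_estimators": 400,
        "max_depth": 2,
        "n_jobs": 1,
        "tree_method": "hist",
        "eval_metric": "logloss",
    },
}

_ESTIMATORS = {
    "logreg": LogisticRegression,
    "random_forest": RandomForestClassifier,
    "mlp": MLPClassifier,
    "xgboost": XGBClassifier,
}


def _make_estimator(model_type: ModelType, hyperparams: dict | None, seed: int):
    if model_type not in _ESTIMATORS:
        raise ValueError(f"unknown model_type {model_type!r}; expected one of {MODEL_TYPES}")
    hp = {**_DEFAULT_HYPERPARAMS[model_type], **(hyperparams or {}), "random_state": seed}
    return _ESTIMATORS[model_type](**hp)


def train_classifier(
    X,
    y,
    model_type: ModelType = "xgboost",
    hyperparams: dict | None = None,
    seed: int = 0,
):
    """Fit one of the four classifiers; all stochastic elements follow ``seed``."""
    y = np.asarray(y).astype(int)
    if X.shape[0] != len(y):
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)} labels")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training data contains a single class: {classes[0]}")
    est = _make_estimator(model_type, hyperparams, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def labels_from_scores(scores, threshold: float = 0.5) -> np.ndarray:
    """Threshold scores into labels; a score exactly at threshold is positive."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def predict(model, X, threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """(labels, scores) with scores in [0, 1] from the probability interface."""
    n_feat = getattr(model, "n_features_in_", None)
    if n_feat is not None and X.shape[1] != n_feat:
        raise ValueError(f"X has {X.shape[1]} features but model expects {n_feat}")
    scores = model.predict_proba(X)[:, 1]
    return labels_from_scores(scores, threshold), scores


# --- Model / Results ----------------------------------------------------------


class NoteClassifier:
    """A TF-IDF note classifier for one (tier, model type) configuration.

    Parameters
    ----------
    notes : sequence of Note
        The corpus; every note needs a label ("case"/"control" or 0/1) unless
        ``labels`` is given separately.
    tier : {"full", "broad", "base"}
        Sentence pre-selection variant applied before featurization.
    model_type : {"logreg", "random_forest", "mlp", "xgboost"}
    """

    def __init__(
        self,
        notes: Sequence[Note],
        labels: Sequence | None = None,
        *,
        tier: SelectionTier = "base",
        model_type: ModelType = "xgboost",
        tfidf: TfidfConfig = TfidfConfig(),
        split: SplitSpec | None = None,
        hyperparams: dict | None = None,
        threshold: float = 0.5,
        seed: int = 0,
    ) -> None:
        self.notes = list(notes)
        if labels is not None:
            y = labels
        else:
            missing = [n.note_id for n in self.notes if n.label is None]
            if missing:
                raise ValueError(f"notes without labels: {missing[:5]}...")
            y = [n.label for n in self.notes]
        yarr = np.asarray(y)
        if yarr.dtype.kind in "OUS":
            yarr = (yarr == "case").astype(int)
        self.y = yarr.astype(int)
        if len(self.y) != len(self.notes):
            raise ValueError("labels and notes differ in length")
        self.tier = tier
        self.model_type = model_type
        self.tfidf_config = tfidf
        self.seed = seed
        self.split_spec = split if split is not None else SplitSpec(seed=seed)
        self.hyperparams = hyperparams
        self.threshold = threshold

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, text_col: str = "text", label_col: str = "label", **kw
    ) -> "NoteClassifier":
        notes = [
            Note(note_id=str(i), text=row[text_col]) for i, row in df.iterrows()
        ]
        return cls(notes, labels=df[label_col].to_numpy(), **kw)

    def fit(self, bootstrap: BootstrapSpec | None = None) -> "NoteClassifierResults":
        """Pre-select, split, featurize, train, and evaluate on the test split."""
        texts = [select_sentences(n, tier=self.tier).text for n in self.notes]
        tr, va, te = split_indices(self.y, self.split_spec)
        tfidf = fit_tfidf([texts[i] for i in tr], self.tfidf_config)
        X_tr = transform_tfidf(tfidf, [texts[i] for i in tr])
        est = train_classifier(
            X_tr, self.y[tr], self.model_type, self.hyperparams, seed=self.seed
        )
        out = {}
        for name, idx in (("validation", va), ("test", te)):
            X = transform_tfidf(tfidf, [texts[i] for i in idx])
            labels, scores = predict(est, X, self.threshold)
            out[name] = pd.DataFrame(
                {
                    "note_id": [self.notes[i].note_id for i in idx],
                    "y_true": self.y[idx],
                    "score": scores,
                    "label": labels,
                }
            )
        te_pred = out["test"]
        if bootstrap is not None:
            metrics = bootstrap_metrics(
                te_pred["y_true"], te_pred["score"], bootstrap, self.threshold
            )
        else:
            from .evaluation import auprc as _auprc
            from .evaluation import auroc as _auroc
            from .evaluation import confusion_metrics

            metrics = confusion_metrics(te_pred["y_true"], te_pred["label"])
            metrics.point["auroc"] = _auroc(te_pred["y_true"], te_pred["score"])
            metrics.point["auprc"] = _auprc(te_pred["y_true"], te_pred["score"])
        return NoteClassifierResults(
            model=self,
            estimator=est,
            tfidf=tfidf,
            split=(tr, va, te),
            predictions=te_pred,
            validation_predictions=out["validation"],
            metrics=metrics,
        )


@dataclass
class NoteClassifierResults:
    """Fitted estimator, feature model, held-out predictions and metrics."""

    model: NoteClassifier
    estimator: object
    tfidf: TfidfModel
    split: tuple[np.ndarray, np.ndarray, np.ndarray]
    predictions: pd.DataFrame
    validation_predictions: pd.DataFrame
    metrics: MetricsReport

    @property
    def test_note_ids(self) -> list[str]:
        return list(self.predictions["note_id"])

    def tune_threshold(self, grid: np.ndarray | None = None) -> float:
        """Pick the F1-maximizing threshold on the validation split (optional;
        the default pipeline keeps 0.5)."""
        from .evaluation import confusion_metrics

        grid = np.linspace(0.05, 0.95, 19) if grid is None else grid
        vp = self.validation_predictions
        best_t, best_f1 = 0.5, -1.0
        for t in grid:
            f1 = confusion_metrics(vp["y_true"], labels_from_scores(vp["score"], t))["f1"]
            if not np.isnan(f1) and f1 > best_f1:
                best_t, best_f1 = float(t), float(f1)
        return best_t

    def summary(self) -> str:
        m = self.model
        head = (
            f"NoteClassifier results\n"
            f"  model_type: {m.model_type}   tier: {m.tier}   seed: {m.seed}\n"
            f"  corpus: {len(m.notes)} notes "
            f"(train/val/test = {len(self.split[0])}/{len(self.split[1])}/{len(self.split[2])})\n"
            f"  vocabulary: {len(self.tfidf.vocabulary)} n-grams "
            f"(ngram_range={m.tfidf_config.ngram_range}, "
            f"min_df={m.tfidf_config.min_df}, max_df={m.tfidf_config.max_df})\n"
        )
        return head + self.metrics.summary()
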