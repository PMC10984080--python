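"""TF-IDF featurization, classifier training, Model/Results interface."""

import numpy as np
import pytest
import scipy.sparse as sp

from psychnote.modeling import (
    FeatureConfigError,
    NoteClassifier,
    SplitSpec,
    TfidfConfig,
    fit_tfidf,
    labels_from_scores,
    predict,
    split_indices,
    train_classifier,
    transform_tfidf,
)

PLAIN = TfidfConfig(ngram_range=(1, 1), min_df=1, max_df=1.0, stop_words=None)


def tfidf_oracle(fit_corpus, transform_corpus, ngram=1):
    """Nested-loop smoothed tf-idf with L2 rows: ln((1+N)/(1+df)) + 1."""
    import re

    def grams(doc):
        toks = re.findall(r"(?u)\b\w\w+\b", doc.lower())
        return [" ".join(toks[i : i + ngram]) for i in range(len(toks) - ngram + 1)]

    vocab = sorted({g for d in fit_corpus for g in grams(d)})
    n = len(fit_corpus)
    df = {t: sum(t in grams(d) for d in fit_corpus) for t in vocab}
    idf = {t: np.log((1 + n) / (1 + df[t])) + 1 for t in vocab}
    rows = []
    for d in transform_corpus:
        gs = grams(d)
        row = np.array([gs.count(t) * idf[t] for t in vocab], dtype=float)
        norm = np.linalg.norm(row)
        rows.append(row / norm if norm > 0 else row)
    return vocab, np.vstack(rows)


class TestFitTfidf:
    def test_common_term_gets_lower_idf(self):
        model = fit_tfidf(["hears voices", "hears nothing"], PLAIN)
        vocab = model.vocabulary
        assert model.idf[vocab["hears"]] < model.idf[vocab["voices"]]

    def test_identical_docs_with_low_max_df_error(self):
        cfg = TfidfConfig(ngram_range=(1, 1), min_df=1, max_df=0.5, stop_words=None)
        with pytest.raises(FeatureConfigError, match="max_df"):
            fit_tfidf(["same text here"] * 4, cfg)

    def test_deterministic(self):
        corpus = ["alpha beta gamma", "beta gamma delta", "gamma delta epsilon"]
        m1, m2 = fit_tfidf(corpus, PLAIN), fit_tfidf(corpus, PLAIN)
        assert m1.vocabulary == m2.vocabulary
        np.testing.assert_array_equal(m1.idf, m2.idf)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_tfidf([], PLAIN)


class TestTransformTfidf:
    def test_matches_nested_loop_oracle_on_random_corpora(self, rng):
        words = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
        for trial in range(10):
            corpus = [
                " ".join(rng.choice(words, size=rng.integers(3, 10))) for _ in range(5)
            ]
            model = fit_tfidf(corpus, PLAIN)
            X = transform_tfidf(model, corpus).toarray()
            vocab, expected = tfidf_oracle(corpus, corpus)
            order = [model.vocabulary[t] for t in vocab]
            np.testing.assert_allclose(X[:, order], expected, atol=1e-10)

    def test_out_of_vocabulary_doc_is_zero_row(self):
        model = fit_tfidf(["alpha beta", "beta gamma"], PLAIN)
        X = transform_tfidf(model, ["omega psi"]).toarray()
        assert not X.any()

    def test_single_term_doc_has_unit_weight(self):
        model = fit_tfidf(["alpha beta", "beta gamma"], PLAIN)
        X = transform_tfidf(model, ["alpha alpha"]).toarray()
        assert X.max() == pytest.approx(1.0)


class TestClassifiers:
    def test_logreg_separable_data_perfect_train_accuracy(self):
        X = sp.csr_matrix(np.array([[0.0, 1.0], [0.1, 0.9], [1.0, 0.0], [0.9, 0.1]]))
        y = [1, 1, 0, 0]
        model = train_classifier(X, y, "logreg", seed=0)
        labels, _ = predict(model, X)
        assert list(labels) == y

    def test_logreg_cannot_fit_xor(self):
        X = sp.csr_matrix(np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float))
        y = [0, 1, 1, 0]
        model = train_classifier(X, y, "logreg", seed=0)
        labels, _ = predict(model, X)
        assert np.mean(labels == y) <= 0.75

    def test_xgboost_deterministic_given_seed(self, rng):
        X = sp.csr_matrix(rng.random((60, 8)))
        y = rng.integers(0, 2, size=60)
        while len(set(y)) < 2:
            y = rng.integers(0, 2, size=60)
        p1 = predict(train_classifier(X, y, "xgboost", seed=5), X)[1]
        p2 = predict(train_classifier(X, y, "xgboost", seed=5), X)[1]
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_training_error_names_class(self):
        X = sp.csr_matrix(np.ones((4, 2)))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(X, [1, 1, 1, 1], "logreg")

    def test_threshold_tie_is_positive(self):
        assert list(labels_from_scores([0.5, 0.49, 0.51])) == [1, 0, 1]

    def test_dimension_mismatch_rejected(self):
        X = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]] * 3))
        model = train_classifier(X, [0, 1] * 3, "logreg")
        with pytest.raises(ValueError, match="features"):
            predict(model, sp.csr_matrix(np.ones((2, 5))))


class TestSplitSpec:
    def test_fractions_validated(self):
        with pytest.raises(ValueError):
            SplitSpec(train=0.5, validation=0.2, test=0.2)

    def test_split_is_a_partition_and_stratified(self):
        y = np.array([1] * 30 + [0] * 70)
        tr, va, te = split_indices(y, SplitSpec(seed=3))
        all_idx = np.concatenate([tr, va, te])
        assert sorted(all_idx) == list(range(100))
        assert y[te].mean() == pytest.approx(0.3, abs=0.05)


class TestNoteClassifier:
    def test_fit_returns_results_with_summary(self, short_note_corpus):
        res = NoteClassifier(
            short_note_corpus, tier="base", model_type="logreg", seed=0
        ).fit()
        assert set(res.metrics.point) >= {"f1", "auroc", "sensitivity"}
        text = res.summary()
        assert "logreg" in text and "base" in text
        assert len(res.predictions) == len(res.split[2])

    def test_from_dataframe_constructor(self, short_note_corpus):
        import pandas as pd

        df = pd.DataFrame(
            {
                "text": [n.text for n in short_note_corpus],
                "label": [n.label for n in short_note_corpus],
            }
        )
        res = NoteClassifier.from_dataframe(df, tier="base", model_type="logreg").fit()
        assert 0.5 <= res.metrics.point["auroc"] <= 1.0

    def test_same_seed_reproducible(self, short_note_corpus):
        kw = dict(tier="base", model_type="xgboost", seed=4)
        r1 = NoteClassifier(short_note_corpus, **kw).fit()
        r2 = NoteClassifier(short_note_corpus, **kw).fit()
        np.testing.assert_array_equal(r1.predictions["score"], r2.predictions["score"])
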