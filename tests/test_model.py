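"""tf-idf vectorization, the feature union, and the classifier families."""

import numpy as np
import pytest

from personamine import (
    ClassifierSpec,
    Corpus,
    FeatureUnionSpec,
    PipelineConfig,
    PostRecord,
    UserRecord,
    VectorizerSpec,
    fit_tfidf,
    generate_corpus,
    load_model,
    make_stratified_split,
    metrics,
    ppd_like,
    predict,
    rsdd_like,
    save_model,
    train,
)
from personamine.model import FAMILIES, ModelError


@pytest.fixture(scope="module")
def small_split():
    corpus = generate_corpus(rsdd_like(seed=9, n_control=40, n_positive=40))
    return make_stratified_split(corpus, 0.2, seed=0)


class TestFitTfidf:
    def test_document_frequency_counting(self):
        vec = fit_tfidf([["sad", "sad", "tired"], ["happy", "tired"]],
                        VectorizerSpec(min_df=1))
        assert list(vec.get_feature_names_out()) == ["happy", "sad", "tired"]

    def test_min_df_threshold(self):
        vec = fit_tfidf([["sad", "sad", "tired"], ["happy", "tired"]],
                        VectorizerSpec(min_df=2))
        assert list(vec.get_feature_names_out()) == ["tired"]

    def test_single_term_normalizes_to_one(self):
        vec = fit_tfidf([["word"]], VectorizerSpec(min_df=1))
        row = vec.transform([["word"]]).toarray()
        assert row.shape == (1, 1)
        assert row[0, 0] == pytest.approx(1.0)

    def test_vocabulary_is_lexicographic_and_deterministic(self):
        docs = [["zebra", "apple", "mango"], ["apple", "zebra"], ["mango", "apple"]]
        a = fit_tfidf(docs, VectorizerSpec(min_df=1))
        b = fit_tfidf(docs, VectorizerSpec(min_df=1))
        names = list(a.get_feature_names_out())
        assert names == sorted(names)
        assert names == list(b.get_feature_names_out())

    def test_empty_vocabulary_names_threshold(self):
        with pytest.raises(ModelError, match="min_df=5"):
            fit_tfidf([["rare"]], VectorizerSpec(min_df=5))


def _tiny_corpus(unit="user"):
    recs = []
    for i, (label, body) in enumerate([
        ("positive", "i always feel that nothing matters and i must rest"),
        ("positive", "everything hurts and i never sleep at night lately"),
        ("control", "went cycling with friends and enjoyed the warm weather"),
        ("control", "the garden tomatoes are finally ripening this weekend"),
    ]):
        recs.append(UserRecord(f"u{i}", label,
                               [PostRecord(f"u{i}_p0", body=body)]))
    return Corpus(name="tiny", unit=unit, records=recs)


class TestTrainValidation:
    def test_single_class_rejected(self):
        corpus = _tiny_corpus()
        corpus.records = [r for r in corpus.records if r.label == "control"]
        with pytest.raises(ModelError, match="both classes"):
            train(corpus)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ModelError, match="empty"):
            train(Corpus(name="e", unit="user", records=[]))

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ModelError, match="does not recognise"):
            ClassifierSpec(family="multinomial_bayes", hyperparams={"l1_ratio": 0.5})

    def test_union_needs_positive_weights(self):
        with pytest.raises(ModelError):
            FeatureUnionSpec(blocks=("tfidf",), weights=(0.0,))


class TestTrainPredict:
    @pytest.mark.parametrize(
        "family, union",
        [
            # the feature union is paired with margin classifiers; the
            # naive Bayes family runs on bag-of-words/tf-idf alone
            ("passive_aggressive", ("tfidf", "rule")),
            ("svm_sgd", ("tfidf", "rule")),
            ("perceptron", ("tfidf", "rule")),
            ("multinomial_bayes", ("tfidf",)),
        ],
    )
    def test_every_family_separates_training_set(self, family, union, small_split):
        corpus = small_split.split_part("train")
        cfg = PipelineConfig(
            union=FeatureUnionSpec(blocks=union, weights=(1.0,) * len(union)),
            classifier=ClassifierSpec(family=family, seed=0),
        )
        model = train(corpus, cfg)
        result = metrics(corpus.labels(), list(predict(model, corpus).labels))
        assert result.accuracy > 0.9

    def test_training_determinism(self, small_split):
        tr, te = small_split.split_part("train"), small_split.split_part("test")
        cfg = PipelineConfig(classifier=ClassifierSpec(seed=3))
        p1 = predict(train(tr, cfg), te)
        p2 = predict(train(tr, cfg), te)
        assert p1 == p2

    def test_tfidf_only_model_ignores_rule_features(self, small_split):
        tr = small_split.split_part("train")
        cfg = PipelineConfig(union=FeatureUnionSpec(blocks=("tfidf",), weights=(1.0,)))
        model = train(tr, cfg)
        assert model.rule_scaler is None and model.minmax_rule is None
        assert model.classifier.coef_.shape[1] == len(
            model.vectorizer.get_feature_names_out()
        )

    def test_zero_token_unit_gets_majority_class_without_rule_block(self):
        corpus = _tiny_corpus()
        corpus.records.append(
            UserRecord("u9", "control", [PostRecord("u9_p0", title="...", body="!!")])
        )
        cfg = PipelineConfig(
            vectorizer=VectorizerSpec(min_df=1),
            union=FeatureUnionSpec(blocks=("tfidf",), weights=(1.0,)),
        )
        model = train(corpus, cfg)
        empty = Corpus(name="e", unit="user", records=[
            UserRecord("q1", "positive", [PostRecord("q1_p0", title="?!", body="123")])
        ])
        preds = predict(model, empty)
        assert preds.labels == (model.majority_label,)

    def test_unit_mismatch_rejected(self, small_split):
        model = train(small_split.split_part("train"))
        post_corpus = generate_corpus(ppd_like(seed=0, n_control=5, n_positive=5))
        with pytest.raises(ModelError, match="unit mismatch"):
            predict(model, post_corpus)

    def test_multinomial_bayes_rule_block_is_nonnegative(self):
        corpus = _tiny_corpus()
        cfg = PipelineConfig(
            vectorizer=VectorizerSpec(min_df=1),
            classifier=ClassifierSpec(family="multinomial_bayes"),
        )
        model = train(corpus, cfg)  # would raise inside MNB on negative input
        assert model.minmax_rule is not None
        preds = predict(model, corpus)
        assert len(preds.labels) == len(corpus)

    def test_equal_weight_scale_invariance(self, small_split):
        """Scaling both block weights by the same constant leaves the
        perceptron's decisions unchanged (mistake-driven updates scale
        linearly with the features; no regularization)."""
        tr, te = small_split.split_part("train"), small_split.split_part("test")
        base = None
        for k in (1.0, 3.5):
            cfg = PipelineConfig(
                union=FeatureUnionSpec(blocks=("tfidf", "rule"), weights=(k, k)),
                classifier=ClassifierSpec(family="perceptron", seed=0),
            )
            labels = predict(train(tr, cfg), te).labels
            base = labels if base is None else base
        assert labels == base


class TestSerialization:
    def test_round_trip_preserves_predictions(self, small_split, tmp_path):
        tr, te = small_split.split_part("train"), small_split.split_part("test")
        model = train(tr, PipelineConfig())
        before = predict(model, te)
        path = tmp_path / "model.bin"
        save_model(model, path)
        after = predict(load_model(path), te)
        assert before == after

    def test_version_mismatch_fails_loudly(self, tmp_path):
        import pickle

        path = tmp_path / "model.bin"
        path.write_bytes(pickle.dumps({"format_version": 999, "model": None}))
        with pytest.raises(ModelError, match="version"):
            load_model(path)
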