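"""Metrics, corpus statistics, and the within/cross-corpus harnesses."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from personamine import (
    ClassifierSpec,
    Corpus,
    CorpusFormatError,
    PipelineConfig,
    PostRecord,
    UserRecord,
    corpus_stats,
    cross_evaluate,
    evaluate_within,
    generate_corpus,
    make_stratified_split,
    metrics,
    rsdd_like,
)
from personamine.evaluation import ConfusionMatrix, confusion, metrics_from_confusion


def _labels_from_cm(tp, fp, fn, tn):
    true = ["positive"] * tp + ["control"] * fp + ["positive"] * fn + ["control"] * tn
    pred = ["positive"] * tp + ["positive"] * fp + ["control"] * fn + ["control"] * tn
    return true, pred


class TestMetrics:
    def test_closed_form_example(self):
        true, pred = _labels_from_cm(tp=9, fp=1, fn=3, tn=87)
        r = metrics(true, pred)
        assert r.precision == pytest.approx(0.9)
        assert r.recall == pytest.approx(0.75)
        assert r.f1 == pytest.approx(0.8182, abs=1e-4)
        assert r.accuracy == pytest.approx(0.96)

    def test_perfect_prediction(self):
        true, pred = _labels_from_cm(tp=5, fp=0, fn=0, tn=5)
        r = metrics(true, pred)
        assert (r.precision, r.recall, r.f1, r.accuracy) == (1, 1, 1, 1)

    def test_zero_denominators_yield_zero_with_warning(self, caplog):
        true, pred = _labels_from_cm(tp=0, fp=0, fn=4, tn=6)
        with caplog.at_level("WARNING"):
            r = metrics(true, pred)
        assert r.precision == 0.0 and r.recall == 0.0 and r.f1 == 0.0
        assert "zero denominator" in caplog.text

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            metrics(["control"], ["control", "positive"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="control/positive"):
            metrics(["depressed"], ["control"])

    def test_agrees_with_reference_on_all_small_confusions(self):
        """Exhaustive check against scikit-learn over every confusion
        matrix with at most 6 units."""
        for tp in range(7):
            for fp in range(7 - tp):
                for fn in range(7 - tp - fp):
                    for tn in range(7 - tp - fp - fn):
                        if tp + fp + fn + tn == 0:
                            continue
                        true, pred = _labels_from_cm(tp, fp, fn, tn)
                        r = metrics(true, pred)
                        p, rec, f1, _ = precision_recall_fscore_support(
                            true, pred, labels=["positive"], average=None,
                            zero_division=0,
                        )
                        assert r.precision == pytest.approx(p[0])
                        assert r.recall == pytest.approx(rec[0])
                        assert r.f1 == pytest.approx(f1[0])
                        assert r.accuracy == pytest.approx((tp + tn) / (tp + fp + fn + tn))

    def test_confusion_counting(self):
        true, pred = _labels_from_cm(2, 3, 4, 5)
        assert confusion(true, pred) == ConfusionMatrix(tp=2, fp=3, fn=4, tn=5)


def _user(uid, label, n_tokens):
    return UserRecord(uid, label, [PostRecord(f"{uid}_p", body=" ".join(["walk"] * n_tokens))])


class TestCorpusStats:
    def test_mean_words(self):
        corpus = Corpus(name="s", unit="user", records=[
            _user("a", "control", 100), _user("b", "control", 300),
            _user("c", "positive", 50),
        ])
        table = corpus_stats(corpus)
        assert table.per_class["control"].avg_words == pytest.approx(200)
        assert table.per_class["control"].n_subjects == 2

    def test_shuffle_invariance(self):
        records = [_user(f"u{i}", "control" if i % 2 else "positive", 10 + i)
                   for i in range(10)]
        a = corpus_stats(Corpus(name="x", unit="user", records=records))
        rng = np.random.default_rng(1)
        shuffled = list(records)
        rng.shuffle(shuffled)
        b = corpus_stats(Corpus(name="x", unit="user", records=shuffled))
        assert a.per_class == b.per_class

    def test_empty_class_gets_null_averages(self):
        corpus = Corpus(name="s", unit="user", records=[_user("a", "control", 10)])
        table = corpus_stats(corpus)
        assert table.per_class["positive"].n_subjects == 0
        assert table.per_class["positive"].avg_words is None

    def test_user_with_no_posts_counts_zero_words(self):
        corpus = Corpus(name="s", unit="user", records=[
            UserRecord("a", "control", []), _user("b", "positive", 5),
        ])
        assert corpus_stats(corpus).per_class["control"].avg_words == 0


class TestSplits:
    def test_partition_and_stratification(self):
        corpus = generate_corpus(rsdd_like(seed=2, n_control=20, n_positive=10))
        sc = make_stratified_split(corpus, 0.2, seed=0)
        assert set(sc.split) == {r.user_id for r in corpus.records}
        test_ids = {rid for rid, p in sc.split.items() if p == "test"}
        by_label = {r.user_id: r.label for r in corpus.records}
        assert sum(by_label[i] == "control" for i in test_ids) == 4
        assert sum(by_label[i] == "positive" for i in test_ids) == 2

    def test_split_determinism(self):
        corpus = generate_corpus(rsdd_like(seed=2, n_control=20, n_positive=10))
        a = make_stratified_split(corpus, 0.2, seed=5).split
        b = make_stratified_split(corpus, 0.2, seed=5).split
        assert a == b

    def test_too_small_class_rejected(self):
        corpus = Corpus(name="s", unit="user", records=[
            _user("a", "control", 5), _user("b", "positive", 5),
        ])
        with pytest.raises(ValueError, match="too small"):
            make_stratified_split(corpus, 0.5, seed=0)


class TestHarnesses:
    def test_missing_split_rejected(self):
        corpus = generate_corpus(rsdd_like(seed=2, n_control=10, n_positive=10))
        with pytest.raises(CorpusFormatError, match="split"):
            evaluate_within(corpus)

    def test_within_determinism(self):
        corpus = make_stratified_split(
            generate_corpus(rsdd_like(seed=4, n_control=30, n_positive=30)), 0.2, 0
        )
        cfg = PipelineConfig(classifier=ClassifierSpec(seed=1))
        assert evaluate_within(corpus, cfg) == evaluate_within(corpus, cfg)

    def test_unit_mismatch_rejected(self):
        from personamine import ppd_like

        a = make_stratified_split(
            generate_corpus(rsdd_like(seed=1, n_control=10, n_positive=10)), 0.2, 0
        )
        b = generate_corpus(ppd_like(seed=1, n_control=10, n_positive=10))
        with pytest.raises(ValueError, match="unit mismatch"):
            cross_evaluate(a, b)

    def test_same_distribution_cross_matches_in_domain(self):
        """Identical generative distributions in both domains (zero shift):
        cross-domain F1 lands within seed noise of in-domain F1."""
        a = make_stratified_split(
            generate_corpus(rsdd_like(seed=21, n_control=80, n_positive=80)), 0.2, 0
        )
        b = generate_corpus(rsdd_like(seed=22, n_control=80, n_positive=80, name="b"))
        report = cross_evaluate(a, b, PipelineConfig())
        assert abs(report.cross_domain.f1 - report.in_domain.f1) <= 0.1

    def test_swapping_roles_exchanges_corpus_names(self):
        a = make_stratified_split(
            generate_corpus(rsdd_like(seed=23, n_control=30, n_positive=30, name="a")), 0.2, 0
        )
        b = make_stratified_split(
            generate_corpus(rsdd_like(seed=24, n_control=30, n_positive=30, name="b")), 0.2, 0
        )
        r1 = cross_evaluate(a, b, PipelineConfig())
        r2 = cross_evaluate(b, a, PipelineConfig())
        assert (r1.train_corpus, r1.test_corpus) == ("a", "b")
        assert (r2.train_corpus, r2.test_corpus) == ("b", "a")
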