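"""Evaluation: confusion-matrix metrics, corpus statistics tables, and the
within- vs cross-corpus evaluation harness.

Precision, recall and F1 are reported for the positive (depressed/PPD)
class; accuracy is overall.  The cross-evaluation harness trains one
model on the *entirety* of a source corpus (train and test splits merged)
and evaluates it on the entirety of a target corpus, alongside the
in-domain result on the source corpus's own split — the comparison that
measures how much of a model's performance survives the move to a
different collection of the same kind of data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import CONTROL, POSITIVE, Corpus, CorpusFormatError
from .model import PipelineConfig, predict, train
from .preprocess import PreprocessConfig, unit_tokens
from .psycholing import profile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts with positive = the depressed/PPD class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    f1: float
    accuracy: float
    confusion: ConfusionMatrix

    def as_row(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
        }


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator computing %s; reporting 0", what)
        return 0.0
    return num / den


def confusion(true_labels: Sequence[str], pred_labels: Sequence[str]) -> ConfusionMatrix:
    if len(true_labels) != len(pred_labels):
        raise ValueError(
            f"label lists differ in length: {len(true_labels)} vs {len(pred_labels)}"
        )
    tp = fp = fn = tn = 0
    for t, p in zip(true_labels, pred_labels):
        if t not in (CONTROL, POSITIVE) or p not in (CONTROL, POSITIVE):
            raise ValueError(f"labels must be control/positive, got ({t!r}, {p!r})")
        if t == POSITIVE and p == POSITIVE:
            tp += 1
        elif t == CONTROL and p == POSITIVE:
            fp += 1
        elif t == POSITIVE and p == CONTROL:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics_from_confusion(cm: ConfusionMatrix) -> EvalResult:
    precision = _safe_div(cm.tp, cm.tp + cm.fp, "precision")
    recall = _safe_div(cm.tp, cm.tp + cm.fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    accuracy = _safe_div(cm.tp + cm.tn, cm.total, "accuracy")
    return EvalResult(
        precision=precision, recall=recall, f1=f1, accuracy=accuracy, confusion=cm
    )


def metrics(true_labels: Sequence[str], pred_labels: Sequence[str]) -> EvalResult:
    """Positive-class precision/recall/F1 and overall accuracy.

    Zero denominators yield 0 with a logged warning.
    """
    return metrics_from_confusion(confusion(true_labels, pred_labels))


# ---------------------------------------------------------------------------
# corpus statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassStats:
    n_subjects: int
    avg_words: float | None
    avg_absolutist: float | None
    avg_self_related: float | None


@dataclass(frozen=True)
class CorpusStatsTable:
    """Per-class subject counts and mean raw-token / lexicon counts."""

    corpus_name: str
    per_class: Mapping[str, ClassStats]

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for label, st in self.per_class.items():
            rows[label] = {
                "n_subjects": st.n_subjects,
                "avg_words": st.avg_words,
                "avg_absolutist": st.avg_absolutist,
                "avg_self_related": st.avg_self_related,
            }
        return pd.DataFrame(rows).T.rename_axis("class")

    def render(self) -> str:
        frame = self.to_frame().copy()
        for col in ("avg_words", "avg_absolutist", "avg_self_related"):
            frame[col] = frame[col].map(
                lambda v: "-" if v is None or pd.isna(v) else f"{round(v):d}"
            )
        return frame.to_string()


def corpus_stats(
    corpus: Corpus, preprocess_cfg: PreprocessConfig | None = None
) -> CorpusStatsTable:
    """Per-class unit counts and mean words / absolutist / self-related
    counts, computed over raw tokens."""
    cfg = preprocess_cfg or PreprocessConfig()
    acc: dict[str, list] = {CONTROL: [], POSITIVE: []}
    for rec in corpus.records:
        acc[rec.label].append(profile(unit_tokens(rec, cfg)))
    per_class = {}
    for label, profs in acc.items():
        if not profs:
            per_class[label] = ClassStats(0, None, None, None)
            continue
        per_class[label] = ClassStats(
            n_subjects=len(profs),
            avg_words=float(np.mean([p.raw_token_count for p in profs])),
            avg_absolutist=float(np.mean([p.absolutist_count for p in profs])),
            avg_self_related=float(np.mean([p.self_count for p in profs])),
        )
    return CorpusStatsTable(corpus_name=corpus.name, per_class=per_class)


# ---------------------------------------------------------------------------
# splits and harnesses
# ---------------------------------------------------------------------------


def make_stratified_split(
    corpus: Corpus, test_fraction: float = 0.2, seed: int = 0
) -> Corpus:
    """A copy of the corpus with a stratified train/test split attached."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    split: dict[str, str] = {}
    for label in (CONTROL, POSITIVE):
        ids = [r.user_id for r in corpus.records if r.label == label]
        n_test = max(1, round(test_fraction * len(ids)))
        if n_test >= len(ids):
            raise ValueError(f"class {label!r} too small to split")
        test_ids = set(rng.choice(ids, size=n_test, replace=False))
        for rid in ids:
            split[rid] = "test" if rid in test_ids else "train"
    return Corpus(
        name=corpus.name, unit=corpus.unit, records=list(corpus.records), split=split
    )


def evaluate_within(corpus: Corpus, config: PipelineConfig = PipelineConfig()) -> EvalResult:
    """Train on the corpus's train split, evaluate on its test split."""
    if corpus.split is None:
        raise CorpusFormatError(
            f"corpus {corpus.name!r} has no train/test split; attach one with "
            "make_stratified_split"
        )
    train_part = corpus.split_part("train")
    test_part = corpus.split_part("test")
    if not test_part.records or not train_part.records:
        raise CorpusFormatError("degenerate split: empty train or test part")
    model = train(train_part, config)
    preds = predict(model, test_part)
    return metrics(test_part.labels(), list(preds.labels))


@dataclass(frozen=True)
class XEvalReport:
    """In-domain result (source split) vs cross-domain result (train on all
    of source, test on all of target), from identically configured pipelines."""

    train_corpus: str
    test_corpus: str
    in_domain: EvalResult
    cross_domain: EvalResult
    classifier_family: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "in_domain": self.in_domain.as_row(),
                "cross_domain": self.cross_domain.as_row(),
            }
        ).T.rename_axis("setting")


def cross_evaluate(
    train_corpus: Corpus,
    test_corpus: Corpus,
    config: PipelineConfig = PipelineConfig(),
) -> XEvalReport:
    """Train on ALL of the source corpus, evaluate on ALL of the target;
    also compute the in-domain result on the source's own split."""
    if train_corpus.unit != test_corpus.unit:
        raise ValueError(
            f"unit mismatch: {train_corpus.unit!r} vs {test_corpus.unit!r}"
        )
    in_domain = evaluate_within(train_corpus, config)
    full_train = Corpus(
        name=train_corpus.name,
        unit=train_corpus.unit,
        records=list(train_corpus.records),
    )
    model = train(full_train, config)
    preds = predict(model, test_corpus)
    cross = metrics(test_corpus.labels(), list(preds.labels))
    return XEvalReport(
        train_corpus=train_corpus.name,
        test_corpus=test_corpus.name,
        in_domain=in_domain,
        cross_domain=cross,
        classifier_family=config.classifier.family,
        seed=config.classifier.seed,
    )
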