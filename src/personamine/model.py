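"""Classification layer: tf-idf bag-of-words, the equal-weight feature
union with the rule-based psycholinguistic estimator, and four linear
classifier families.

The document representation is smoothed-idf tf-idf over model tokens —
``idf(t) = ln((1+N)/(1+df(t))) + 1``, document vectors L2-normalised —
with the vocabulary restricted to terms meeting ``min_df`` and ordered
lexicographically for determinism.  The optional rule block is the
standardised 3-vector (absolutist rate, self-related rate, log volume);
both blocks are concatenated with per-block weights (default 1.0 each:
the equal-weight union).

Classifier families and their default hyperparameters:

* ``multinomial_bayes`` — multinomial naive Bayes, alpha=1.  This family
  requires non-negative features, so its rule block is min-max rescaled to
  [0, 1] instead of z-scored.
* ``passive_aggressive`` — squared-hinge loss.
* ``svm_sgd`` — linear SVM by stochastic gradient descent, hinge loss,
  elastic-net penalty with l1 ratio 0.95.
* ``perceptron``.

The decision threshold sits at margin 0 with ties broken toward control
(conservative screening).  Units with no model tokens fall back to the
rule-features-only decision, or to the majority training class when the
union has no rule block.
"""

from __future__ import annotations

import hashlib
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import Perceptron, PassiveAggressiveClassifier, SGDClassifier
from sklearn.naive_bayes import MultinomialNB

from .corpus_io import CONTROL, POSITIVE, Corpus
from .preprocess import PreprocessConfig, TokenStream, unit_tokens
from .psycholing import (
    PsycholingProfile,
    RuleScaler,
    fit_rule_scaler,
    profile,
    rule_features,
)

SERIALIZATION_VERSION = 1

FAMILIES = ("multinomial_bayes", "passive_aggressive", "svm_sgd", "perceptron")


class ModelError(ValueError):
    """Invalid model configuration or usage."""


@dataclass(frozen=True)
class VectorizerSpec:
    min_df: int = 2
    max_features: int | None = None
    sublinear_tf: bool = False
    idf_smoothing: bool = True

    def __post_init__(self) -> None:
        if self.min_df < 1:
            raise ModelError("min_df must be >= 1")


@dataclass(frozen=True)
class ClassifierSpec:
    family: str = "passive_aggressive"
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        allowed = {
            "multinomial_bayes": {"alpha"},
            "passive_aggressive": {"loss", "C", "max_iter", "tol"},
            "svm_sgd": {"loss", "penalty", "l1_ratio", "alpha", "max_iter", "tol"},
            "perceptron": {"penalty", "alpha", "eta0", "max_iter", "tol"},
        }[self.family]
        unknown = set(self.hyperparams) - allowed
        if unknown:
            raise ModelError(
                f"family {self.family!r} does not recognise hyperparameters "
                f"{sorted(unknown)} (allowed: {sorted(allowed)})"
            )


@dataclass(frozen=True)
class FeatureUnionSpec:
    blocks: tuple[str, ...] = ("tfidf", "rule")
    weights: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ModelError("at least one feature block is required")
        bad = set(self.blocks) - {"tfidf", "rule"}
        if bad:
            raise ModelError(f"unknown feature blocks {sorted(bad)}")
        if len(self.weights) != len(self.blocks):
            raise ModelError("one weight per block is required")
        if any(w <= 0 for w in self.weights):
            raise ModelError("block weights must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """The full pipeline configuration handed to :func:`train`."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    vectorizer: VectorizerSpec = field(default_factory=VectorizerSpec)
    union: FeatureUnionSpec = field(default_factory=FeatureUnionSpec)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)


def _identity_analyzer(tokens):
    # documents arrive pre-tokenized
    return tokens


def fit_tfidf(
    token_docs: Sequence[Sequence[str]], spec: VectorizerSpec = VectorizerSpec()
) -> TfidfVectorizer:
    """Fit the tf-idf vectorizer on pre-tokenized documents.

    Vocabulary = terms meeting ``min_df``, sorted lexicographically;
    smoothed idf; L2-normalised document vectors.
    """
    if not token_docs:
        raise ModelError("fit_tfidf needs at least one document")
    vec = TfidfVectorizer(
        analyzer=_identity_analyzer,
        min_df=spec.min_df,
        max_features=spec.max_features,
        sublinear_tf=spec.sublinear_tf,
        smooth_idf=spec.idf_smoothing,
        norm="l2",
        lowercase=False,
    )
    try:
        vec.fit(list(token_docs))
    except ValueError as exc:
        raise ModelError(
            f"empty vocabulary after applying min_df={spec.min_df}"
        ) from exc
    return vec


@dataclass
class _MinMaxRule:
    """[0,1] rescaling of the raw rule vector, for the non-negative family."""

    lo: np.ndarray
    span: np.ndarray

    @classmethod
    def fit(cls, mat: np.ndarray) -> "_MinMaxRule":
        lo = mat.min(axis=0)
        span = mat.max(axis=0) - lo
        span[span == 0.0] = 1.0
        return cls(lo=lo, span=span)

    def transform(self, mat: np.ndarray) -> np.ndarray:
        return np.clip((mat - self.lo) / self.span, 0.0, 1.0)


def _build_classifier(spec: ClassifierSpec):
    hp = spec.hyperparams
    if spec.family == "multinomial_bayes":
        return MultinomialNB(alpha=hp.get("alpha", 1.0))
    if spec.family == "passive_aggressive":
        with warnings.catch_warnings():
            # scheduled for replacement by an SGDClassifier spelling upstream
            warnings.simplefilter("ignore", FutureWarning)
            return PassiveAggressiveClassifier(
                loss=hp.get("loss", "squared_hinge"),
                C=hp.get("C", 1.0),
                max_iter=hp.get("max_iter", 1000),
                tol=hp.get("tol", 1e-3),
                random_state=spec.seed,
            )
    if spec.family == "svm_sgd":
        return SGDClassifier(
            loss=hp.get("loss", "hinge"),
            penalty=hp.get("penalty", "elasticnet"),
            l1_ratio=hp.get("l1_ratio", 0.95),
            alpha=hp.get("alpha", 1e-4),
            max_iter=hp.get("max_iter", 1000),
            tol=hp.get("tol", 1e-3),
            random_state=spec.seed,
        )
    return Perceptron(
        penalty=hp.get("penalty"),
        alpha=hp.get("alpha", 1e-4),
        eta0=hp.get("eta0", 1.0),
        max_iter=hp.get("max_iter", 1000),
        tol=hp.get("tol", 1e-3),
        random_state=spec.seed,
    )


@dataclass
class TrainedModel:
    """Fitted vectorizer + rule scaler + classifier, with a deterministic
    predict contract and exact serialize→load→predict round-tripping."""

    config: PipelineConfig
    unit: str
    vectorizer: TfidfVectorizer | None
    rule_scaler: RuleScaler | None
    minmax_rule: _MinMaxRule | None
    classifier: object
    majority_label: str
    training_fingerprint: str

    @property
    def has_rule_block(self) -> bool:
        return "rule" in self.config.union.blocks

    @property
    def has_tfidf_block(self) -> bool:
        return "tfidf" in self.config.union.blocks


def _corpus_fingerprint(corpus: Corpus) -> str:
    h = hashlib.sha256()
    for rec in corpus.records:
        h.update(rec.user_id.encode())
        h.update(rec.label.encode())
    return h.hexdigest()[:16]


def _streams_and_profiles(
    corpus: Corpus, cfg: PreprocessConfig
) -> tuple[list[TokenStream], list[PsycholingProfile]]:
    streams = [unit_tokens(rec, cfg) for rec in corpus.records]
    return streams, [profile(s) for s in streams]


def _rule_matrix(
    profiles: Sequence[PsycholingProfile],
    scaler: RuleScaler | None,
    minmax: _MinMaxRule | None,
) -> np.ndarray:
    if minmax is not None:
        return minmax.transform(np.array([p.as_vector() for p in profiles]))
    return np.array([rule_features(p, scaler) for p in profiles])


def _assemble(
    model_blocks: dict[str, object], union: FeatureUnionSpec
) -> sp.csr_matrix:
    mats = []
    for block, weight in zip(union.blocks, union.weights):
        mat = model_blocks[block]
        mats.append(sp.csr_matrix(mat) * weight)
    return sp.hstack(mats, format="csr") if len(mats) > 1 else mats[0]


def train(corpus: Corpus, config: PipelineConfig = PipelineConfig()) -> TrainedModel:
    """Fit the full pipeline on a labelled corpus.

    The vectorizer and rule scaler are fitted on the given records only;
    both classes must be present.
    """
    if not corpus.records:
        raise ModelError("cannot train on an empty corpus")
    labels = corpus.labels()
    present = set(labels)
    if present != {CONTROL, POSITIVE}:
        raise ModelError(
            f"training corpus must contain both classes; found {sorted(present)}"
        )
    streams, profiles = _streams_and_profiles(corpus, config.preprocess)

    vectorizer = None
    rule_scaler = None
    minmax = None
    blocks: dict[str, object] = {}
    if "tfidf" in config.union.blocks:
        vectorizer = fit_tfidf([s.model_tokens for s in streams], config.vectorizer)
        blocks["tfidf"] = vectorizer.transform([s.model_tokens for s in streams])
    if "rule" in config.union.blocks:
        if config.classifier.family == "multinomial_bayes":
            minmax = _MinMaxRule.fit(np.array([p.as_vector() for p in profiles]))
        else:
            rule_scaler = fit_rule_scaler(profiles)
        blocks["rule"] = _rule_matrix(profiles, rule_scaler, minmax)

    X = _assemble(blocks, config.union)
    y = np.array(labels)
    clf = _build_classifier(config.classifier)
    clf.fit(X, y)

    counts = corpus.n_by_label()
    majority = CONTROL if counts[CONTROL] >= counts[POSITIVE] else POSITIVE
    return TrainedModel(
        config=config,
        unit=corpus.unit,
        vectorizer=vectorizer,
        rule_scaler=rule_scaler,
        minmax_rule=minmax,
        classifier=clf,
        majority_label=majority,
        training_fingerprint=_corpus_fingerprint(corpus),
    )


@dataclass(frozen=True)
class Predictions:
    """Per-unit predicted labels (corpus order) with margin scores where
    the family provides them."""

    ids: tuple[str, ...]
    labels: tuple[str, ...]
    scores: tuple[float, ...] | None


def predict(model: TrainedModel, corpus: Corpus) -> Predictions:
    """Predict labels for every unit of a corpus, in corpus order.

    Out-of-vocabulary terms are ignored by construction.  Units with zero
    model tokens receive the rule-features-only decision, or the majority
    training class when the union has no rule block.
    """
    if corpus.unit != model.unit:
        raise ModelError(
            f"unit mismatch: model was trained on unit={model.unit!r}, "
            f"corpus has unit={corpus.unit!r}"
        )
    streams, profiles = _streams_and_profiles(corpus, model.config.preprocess)
    blocks: dict[str, object] = {}
    if model.has_tfidf_block:
        blocks["tfidf"] = model.vectorizer.transform([s.model_tokens for s in streams])
    if model.has_rule_block:
        blocks["rule"] = _rule_matrix(profiles, model.rule_scaler, model.minmax_rule)
    X = _assemble(blocks, model.config.union)

    clf = model.classifier
    labels = list(clf.predict(X))
    scores: tuple[float, ...] | None
    if hasattr(clf, "decision_function"):
        scores = tuple(float(v) for v in clf.decision_function(X))
    elif hasattr(clf, "predict_log_proba"):
        lp = clf.predict_log_proba(X)
        pos = list(clf.classes_).index(POSITIVE)
        scores = tuple(float(v) for v in (lp[:, pos] - lp[:, 1 - pos]))
    else:  # pragma: no cover - all four families provide one of the above
        scores = None

    if not model.has_rule_block:
        for i, s in enumerate(streams):
            if not s.model_tokens:
                labels[i] = model.majority_label
    return Predictions(
        ids=tuple(rec.user_id for rec in corpus.records),
        labels=tuple(labels),
        scores=scores,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize to a single versioned file; loading checks the version tag."""
    payload = {"format_version": SERIALIZATION_VERSION, "model": model}
    Path(path).write_bytes(pickle.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    with warnings.catch_warnings():
        # re-instantiating the passive-aggressive family warns; see _build_classifier
        warnings.simplefilter("ignore", FutureWarning)
        payload = pickle.loads(Path(path).read_bytes())
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelError(f"{path}: not a serialized model")
    if payload["format_version"] != SERIALIZATION_VERSION:
        raise ModelError(
            f"{path}: serialized with format version {payload['format_version']}, "
            f"this build reads version {SERIALIZATION_VERSION}"
        )
    return payload["model"]
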