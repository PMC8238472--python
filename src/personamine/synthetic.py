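"""Synthetic two-class, two-domain user-post corpora.

Real self-reported-diagnosis collections are access-restricted, so the
pipeline is exercised on generated corpora that reproduce the statistical
structure the downstream features actually see: class-conditional writing
volume, per-token absolutist and self-related word rates, a class topic
vocabulary, and a Zipf-distributed background vocabulary.  Generation is
token-level — each emitted token is an independent draw from a four-way
mixture (absolutist / self-related / class topic / background) — because
every downstream feature is a bag-of-words or lexicon count, so token
marginals are the only structure that matters.

Counts follow the simplest laws with closed-form expectations: posts per
user are shifted-Poisson (≥1), tokens per post Poisson, giving
``E[tokens] = posts_per_user_mean · tokens_per_post_mean`` exactly — the
oracle used by :func:`expected_profile`.

A ``DomainSpec`` models the contrast between two collections drawn from
the same platform: a shared background vocabulary plus per-class topic
lexicons of which a fraction ``shift`` is replaced by domain-specific
synonym words.  ``shift=0`` means the two domains share topic vocabulary
exactly; ``shift=1`` makes the topic vocabularies disjoint.

Two presets mirror the contrast between the reference collections:

* ``rsdd_like`` — strong class separation: positive personas write ~3.3×
  more, with per-token absolutist/self rates ~1.1×/1.25× the control ones.
* ``losada_like`` — positive personas write *less* than controls, the
  absolutist rate is equal across classes (the feature is uninformative),
  and only the self-related rate separates.

Reproducibility: the seed feeds one root ``SeedSequence``; each unit's
stream is derived by stable spawning from (seed, class, unit index), so
corpus content is invariant to generation order and identical configs give
byte-identical canonical JSONL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .corpus_io import CONTROL, POSITIVE, Corpus, PostRecord, UserRecord
from .psycholing import absolutist_lexicon, self_related_lexicon

# Default class topic lexicons: depression-support vocabulary for the
# positive class, everyday parenting vocabulary for the control class.
# Both are disjoint from the absolutist and self-related lexicons.
POSITIVE_TOPIC_WORDS = (
    "therapy", "hopeless", "worthless", "exhausted", "crying", "numb",
    "anxiety", "medication", "insomnia", "guilt", "lonely", "empty",
    "overwhelmed", "struggling", "sadness", "despair", "fatigue", "panic",
    "isolation", "counselor", "sertraline", "intrusive", "tearful",
    "breakdown", "darkness", "burden", "ashamed", "helpless", "misery",
    "grief", "dread", "restless", "hollow", "drowning", "suffocating",
    "paralyzed", "crumbling", "aching", "weeping", "broken",
)
CONTROL_TOPIC_WORDS = (
    "stroller", "naptime", "daycare", "recipe", "playground", "weekend",
    "vacation", "birthday", "toddler", "bedtime", "snack", "laundry",
    "grocery", "carseat", "teething", "diaper", "bathtime", "milestone",
    "crawling", "babbling", "registry", "nursery", "onesie", "swaddle",
    "pediatrician", "formula", "pumping", "weaning", "solids", "napping",
    "playdate", "sibling", "grandma", "photos", "giggles", "cuddles",
    "outfits", "crafts", "garden", "picnic",
)


class ConfigError(ValueError):
    """A generator configuration violates an invariant."""


@dataclass(frozen=True)
class ClassProfile:
    """Class-conditional generation parameters for one label.

    ``p_abs`` and ``p_self`` are per-token emission probabilities for the
    absolutist and self-related lexicons; ``topic_weight`` is the mass on
    the class topic lexicon; the remainder goes to the Zipf background.
    """

    n_units: int
    posts_per_user_mean: float
    tokens_per_post_mean: float
    p_abs: float
    p_self: float
    topic_weight: float

    def validate(self) -> None:
        if self.n_units < 1:
            raise ConfigError("n_units must be >= 1")
        if self.posts_per_user_mean < 1:
            raise ConfigError("posts_per_user_mean must be >= 1")
        if self.tokens_per_post_mean <= 0:
            raise ConfigError("tokens_per_post_mean must be positive")
        for name in ("p_abs", "p_self", "topic_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.p_abs + self.p_self + self.topic_weight > 1.0:
            raise ConfigError("p_abs + p_self + topic_weight must be <= 1")


@dataclass(frozen=True)
class DomainSpec:
    """Vocabulary structure of one domain (collection)."""

    background_vocab_size: int = 5000
    zipf_exponent: float = 1.1
    topic_lexicons: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            CONTROL: CONTROL_TOPIC_WORDS,
            POSITIVE: POSITIVE_TOPIC_WORDS,
        }
    )
    shift: float = 0.0

    def validate(self) -> None:
        if self.background_vocab_size < 1:
            raise ConfigError("background_vocab_size must be >= 1")
        if self.zipf_exponent <= 0:
            raise ConfigError("zipf_exponent must be positive")
        if not 0.0 <= self.shift <= 1.0:
            raise ConfigError("shift must lie in [0, 1]")
        reserved = absolutist_lexicon().entries | self_related_lexicon().entries
        for label in (CONTROL, POSITIVE):
            lex = self.topic_lexicons.get(label)
            if not lex:
                raise ConfigError(f"missing topic lexicon for class {label!r}")
            clash = set(lex) & reserved
            if clash:
                raise ConfigError(
                    f"topic lexicon for {label!r} overlaps the absolutist/"
                    f"self-related lexicons: {sorted(clash)[:5]}"
                )

    def effective_topic_lexicon(self, label: str) -> tuple[str, ...]:
        """The topic lexicon after the domain shift: the first
        ``floor(shift·n)`` entries are replaced by domain-specific synonym
        words (deterministic ``<word>alt`` spellings)."""
        base = tuple(self.topic_lexicons[label])
        k = math.floor(self.shift * len(base))
        return tuple(w + "alt" for w in base[:k]) + base[k:]


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that determines a generated corpus, including the seed."""

    seed: int
    control: ClassProfile
    positive: ClassProfile
    domain: DomainSpec = field(default_factory=DomainSpec)
    unit: str = "user"
    name: str = "synthetic"

    def validate(self) -> None:
        if self.unit not in ("user", "post"):
            raise ConfigError(f"unknown unit {self.unit!r}")
        self.control.validate()
        self.positive.validate()
        self.domain.validate()

    def profile_for(self, label: str) -> ClassProfile:
        return self.control if label == CONTROL else self.positive


@dataclass(frozen=True)
class ExpectedProfile:
    """Closed-form per-user expectations (the test oracle)."""

    tokens: float
    absolutist: float
    self_related: float


def expected_profile(profile: ClassProfile) -> ExpectedProfile:
    """E[tokens] = posts·tokens-per-post; E[abs] = p_abs·E[tokens]; likewise self."""
    profile.validate()
    e_tokens = profile.posts_per_user_mean * profile.tokens_per_post_mean
    return ExpectedProfile(
        tokens=e_tokens,
        absolutist=profile.p_abs * e_tokens,
        self_related=profile.p_self * e_tokens,
    )


def _background_words(size: int) -> list[str]:
    # deterministic alphabetic background vocabulary: "w" + base-26 rank
    words = []
    for i in range(size):
        s, n = "", i
        for _ in range(4):
            s = chr(ord("a") + n % 26) + s
            n //= 26
        words.append("w" + s)
    return words


def _zipf_cdf(size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    p = ranks ** (-exponent)
    p /= p.sum()
    return np.cumsum(p)


_CLASS_CODE = {CONTROL: 0, POSITIVE: 1}


def _unit_posts(
    rng: np.random.Generator,
    prof: ClassProfile,
    n_posts: int,
    abs_words: list[str],
    self_words: list[str],
    topic_words: tuple[str, ...],
    bg_words: list[str],
    bg_cdf: np.ndarray,
    uid: str,
) -> list[PostRecord]:
    cut = np.cumsum([prof.p_abs, prof.p_self, prof.topic_weight])
    posts = []
    for j in range(n_posts):
        n_tok = int(rng.poisson(prof.tokens_per_post_mean))
        tokens: list[str] = [""] * n_tok
        if n_tok:
            u = rng.random(n_tok)
            cat = np.searchsorted(cut, u, side="right")  # 0=abs 1=self 2=topic 3=bg
            for k, lex in ((0, abs_words), (1, self_words), (2, list(topic_words))):
                idx = np.flatnonzero(cat == k)
                if idx.size:
                    picks = rng.integers(0, len(lex), size=idx.size)
                    for pos, pick in zip(idx, picks):
                        tokens[pos] = lex[pick]
            idx = np.flatnonzero(cat == 3)
            if idx.size:
                picks = np.searchsorted(bg_cdf, rng.random(idx.size), side="right")
                for pos, pick in zip(idx, picks):
                    tokens[pos] = bg_words[pick]
        posts.append(
            PostRecord(
                post_id=f"{uid}_p{j}",
                body=" ".join(tokens),
                created_utc=1_600_000_000 + 3600 * j,
            )
        )
    return posts


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate a labelled corpus; same config (incl. seed) → identical corpus."""
    config.validate()
    abs_words = sorted(absolutist_lexicon().entries)
    self_words = sorted(self_related_lexicon().entries)
    bg_words = _background_words(config.domain.background_vocab_size)
    bg_cdf = _zipf_cdf(config.domain.background_vocab_size, config.domain.zipf_exponent)

    records: list[UserRecord] = []
    for label in (CONTROL, POSITIVE):
        prof = config.profile_for(label)
        topic = config.domain.effective_topic_lexicon(label)
        tag = "ctl" if label == CONTROL else "pos"
        for i in range(prof.n_units):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, _CLASS_CODE[label], i])
            )
            uid = f"{tag}{i:05d}"
            if config.unit == "user":
                n_posts = 1 + int(rng.poisson(prof.posts_per_user_mean - 1.0))
            else:
                n_posts = 1
            posts = _unit_posts(
                rng, prof, n_posts, abs_words, self_words, topic,
                bg_words, bg_cdf, uid,
            )
            records.append(UserRecord(user_id=uid, label=label, posts=posts))
    corpus = Corpus(name=config.name, unit=config.unit, records=records)
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------
# Per-token rates are taken from the reference collections' printed per-user
# averages (absolutist and self-related counts divided by words per user);
# volumes are scaled down ~35x so that desk-scale corpora of hundreds of
# personas generate in seconds while preserving the between-class ratios.


def rsdd_like(
    seed: int = 0,
    n_control: int = 200,
    n_positive: int = 200,
    shift: float = 0.0,
    name: str = "rsdd_like",
) -> GeneratorConfig:
    """Strong separation: positive personas write ~3.3× more, with
    absolutist/self rates ~1.1×/1.25× the control rates."""
    return GeneratorConfig(
        seed=seed,
        control=ClassProfile(
            n_units=n_control, posts_per_user_mean=10, tokens_per_post_mean=60,
            p_abs=0.0091, p_self=0.0278, topic_weight=0.05,
        ),
        positive=ClassProfile(
            n_units=n_positive, posts_per_user_mean=15, tokens_per_post_mean=132,
            p_abs=0.0101, p_self=0.0347, topic_weight=0.05,
        ),
        domain=DomainSpec(shift=shift),
        unit="user",
        name=name,
    )


def losada_like(
    seed: int = 0,
    n_control: int = 200,
    n_positive: int = 200,
    shift: float = 0.0,
    name: str = "losada_like",
) -> GeneratorConfig:
    """No absolutist separation (equal p_abs), positive personas write
    *less* than controls; only the self-related rate separates."""
    return GeneratorConfig(
        seed=seed,
        control=ClassProfile(
            n_units=n_control, posts_per_user_mean=10, tokens_per_post_mean=60,
            p_abs=0.0083, p_self=0.0202, topic_weight=0.05,
        ),
        positive=ClassProfile(
            n_units=n_positive, posts_per_user_mean=7, tokens_per_post_mean=66,
            p_abs=0.0083, p_self=0.0445, topic_weight=0.05,
        ),
        domain=DomainSpec(shift=shift),
        unit="user",
        name=name,
    )


def ppd_like(
    seed: int = 0,
    n_control: int = 300,
    n_positive: int = 150,
    shift: float = 0.0,
    name: str = "ppd_like",
) -> GeneratorConfig:
    """Post-unit corpus: individually labelled posts, ~2:1 control:positive,
    equal post lengths, class signal carried by topic vocabulary and the
    self-related rate."""
    return GeneratorConfig(
        seed=seed,
        control=ClassProfile(
            n_units=n_control, posts_per_user_mean=1, tokens_per_post_mean=80,
            p_abs=0.0091, p_self=0.0278, topic_weight=0.08,
        ),
        positive=ClassProfile(
            n_units=n_positive, posts_per_user_mean=1, tokens_per_post_mean=80,
            p_abs=0.0101, p_self=0.0347, topic_weight=0.08,
        ),
        domain=DomainSpec(shift=shift),
        unit="post",
        name=name,
    )


PRESETS = {"rsdd_like": rsdd_like, "losada_like": losada_like, "ppd_like": ppd_like}


# ---------------------------------------------------------------------------
# config (de)serialization for the CLI
# ---------------------------------------------------------------------------


def config_to_dict(config: GeneratorConfig) -> dict:
    d = {
        "seed": config.seed,
        "unit": config.unit,
        "name": config.name,
        "control": vars(config.control).copy(),
        "positive": vars(config.positive).copy(),
        "domain": {
            "background_vocab_size": config.domain.background_vocab_size,
            "zipf_exponent": config.domain.zipf_exponent,
            "shift": config.domain.shift,
            "topic_lexicons": {
                k: list(v) for k, v in config.domain.topic_lexicons.items()
            },
        },
    }
    return d


def config_from_dict(d: Mapping) -> GeneratorConfig:
    dom = dict(d.get("domain", {}))
    if "topic_lexicons" in dom:
        dom["topic_lexicons"] = {k: tuple(v) for k, v in dom["topic_lexicons"].items()}
    cfg = GeneratorConfig(
        seed=int(d["seed"]),
        control=ClassProfile(**d["control"]),
        positive=ClassProfile(**d["positive"]),
        domain=DomainSpec(**dom),
        unit=d.get("unit", "user"),
        name=d.get("name", "synthetic"),
    )
    cfg.validate()
    return cfg


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """The same configuration under a different seed."""
    return replace(config, seed=seed)
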