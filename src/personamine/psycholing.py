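"""Psycholinguistic features of depressed writing: absolutist words,
self-related (first-person singular) words, and writing volume.

Elevated absolutist-word frequency is a validated marker of the
black-and-white thinking common to anxiety and depression forums; the
19-word absolutist dictionary is vendored verbatim.  Self-related words
(i, me, my, mine, myself) and total writing volume are the other two cues.
Counting is exact string equality over *raw* tokens — the stopword filter
would otherwise remove most of the self-related lexicon — and rates are
expressed per 1,000 raw tokens.  Volume enters models as log10(1 + tokens)
to stabilise a scale that spans orders of magnitude across personas.

The three cues feed a rule-based estimator: a per-feature standardised
3-vector ``(abs_rate, self_rate, log_volume)`` that joins the tf-idf block
in a feature union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .preprocess import TokenStream

FEATURE_NAMES = ("abs_rate", "self_rate", "log_volume")


@dataclass(frozen=True)
class Lexicon:
    """A named set of lowercase alphabetic words."""

    name: str
    entries: frozenset[str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"lexicon {self.name!r} is empty")
        bad = [w for w in self.entries if not w.isalpha() or w != w.lower()]
        if bad:
            raise ValueError(
                f"lexicon {self.name!r} has non-lowercase/non-alphabetic entries: {bad[:5]}"
            )

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def _load_lexicon(name: str, filename: str) -> Lexicon:
    text = (resources.files("personamine") / "data" / filename).read_text(
        encoding="utf-8"
    )
    return Lexicon(name=name, entries=frozenset(w for w in text.split() if w))


@lru_cache(maxsize=1)
def absolutist_lexicon() -> Lexicon:
    """The validated 19-word absolutist dictionary."""
    return _load_lexicon("absolutist", "absolutist.txt")


@lru_cache(maxsize=1)
def self_related_lexicon() -> Lexicon:
    """First-person singular pronouns and possessives: i, me, my, mine, myself."""
    return _load_lexicon("self_related", "self_related.txt")


def count_lexicon(raw_tokens: Sequence[str], lexicon: Lexicon) -> int:
    """Number of tokens exactly equal to a lexicon entry (multiplicities count)."""
    entries = lexicon.entries
    return sum(1 for t in raw_tokens if t in entries)


@dataclass(frozen=True)
class PsycholingProfile:
    """Per-unit counts and rates of the three psycholinguistic cues."""

    raw_token_count: int
    absolutist_count: int
    self_count: int

    @property
    def abs_rate(self) -> float:
        """Absolutist words per 1,000 raw tokens (0 for empty units)."""
        if self.raw_token_count == 0:
            return 0.0
        return 1000.0 * self.absolutist_count / self.raw_token_count

    @property
    def self_rate(self) -> float:
        """Self-related words per 1,000 raw tokens (0 for empty units)."""
        if self.raw_token_count == 0:
            return 0.0
        return 1000.0 * self.self_count / self.raw_token_count

    @property
    def log_volume(self) -> float:
        """log10(1 + raw token count)."""
        return math.log10(1 + self.raw_token_count)

    def as_vector(self) -> np.ndarray:
        return np.array([self.abs_rate, self.self_rate, self.log_volume])


def profile(
    tokens: TokenStream,
    absolutist: Lexicon | None = None,
    self_related: Lexicon | None = None,
) -> PsycholingProfile:
    """Count the cue lexicons over the raw-token view of one unit."""
    absolutist = absolutist or absolutist_lexicon()
    self_related = self_related or self_related_lexicon()
    raw = tokens.raw_tokens
    return PsycholingProfile(
        raw_token_count=len(raw),
        absolutist_count=count_lexicon(raw, absolutist),
        self_count=count_lexicon(raw, self_related),
    )


@dataclass(frozen=True)
class RuleScaler:
    """Per-feature location/scale for (abs_rate, self_rate, log_volume).

    Fitted on training profiles with population statistics; a degenerate
    (constant) feature gets scale 1 so transforms stay finite.
    """

    location: tuple[float, float, float]
    scale: tuple[float, float, float]


def fit_rule_scaler(profiles: Iterable[PsycholingProfile]) -> RuleScaler:
    """Fit mean and population standard deviation per feature; needs ≥2 profiles."""
    mat = np.array([p.as_vector() for p in profiles])
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("fit_rule_scaler needs at least 2 profiles")
    loc = mat.mean(axis=0)
    scale = mat.std(axis=0)  # population SD
    scale[scale == 0.0] = 1.0
    return RuleScaler(location=tuple(loc), scale=tuple(scale))


def rule_features(prof: PsycholingProfile, scaler: RuleScaler) -> np.ndarray:
    """Standardised 3-vector ((abs_rate, self_rate, log_volume) − loc) / scale."""
    if not isinstance(scaler, RuleScaler):
        raise TypeError("rule_features requires a fitted RuleScaler")
    return (prof.as_vector() - np.array(scaler.location)) / np.array(scaler.scale)
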