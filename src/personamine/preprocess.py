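"""Text normalisation: lowercasing, alphabetic tokenization, length and
stopword filtering.

Every unit of text is reduced to two token views:

* ``raw_tokens`` — lowercase alphabetic tokens of any length, obtained by
  treating every non-alphabetic character as a separator.  All
  psycholinguistic counting happens on this view, because the stopword
  list contains first-person pronouns ("i", "me", "my", "myself") and the
  absolutist word "all" — filtering first would make those uncountable.
* ``model_tokens`` — ``raw_tokens`` after dropping short tokens and
  stopwords; this is what the bag-of-words vectorizer consumes.

The 127-entry English stopword list is vendored as a plain-text data file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .corpus_io import PostRecord, UserRecord

_TOKEN_RE = re.compile(r"[a-z]+")


@lru_cache(maxsize=1)
def default_stopwords() -> frozenset[str]:
    """The vendored 127-word English stopword list."""
    text = (resources.files("personamine") / "data" / "stopwords.txt").read_text(
        encoding="utf-8"
    )
    return frozenset(w for w in text.split() if w)


@dataclass(frozen=True)
class PreprocessConfig:
    """Normalisation settings.

    ``min_token_len`` keeps tokens of at least that many characters in the
    model view (default 3: tokens are words of more than two letters).
    ``concat_title`` prepends each post's title to its body before
    tokenization.
    """

    min_token_len: int = 3
    stopwords: frozenset[str] = field(default_factory=default_stopwords)
    concat_title: bool = True

    def __post_init__(self) -> None:
        if self.min_token_len < 1:
            raise ValueError("min_token_len must be >= 1")
        if any(w != w.lower() for w in self.stopwords):
            raise ValueError("stopwords must be lowercase")


@dataclass(frozen=True)
class TokenStream:
    """The dual token views of one unit's text (model ⊆ raw, order preserved)."""

    raw_tokens: tuple[str, ...]
    model_tokens: tuple[str, ...]


def tokenize_raw(text: str) -> list[str]:
    """Lowercase and split into maximal alphabetic runs.

    Non-alphabetic characters act as separators, so ``"can't"`` yields
    ``["can", "t"]`` rather than a fabricated ``"cant"``.  No length or
    stopword filtering is applied here.
    """
    return _TOKEN_RE.findall(text.lower())


def to_model_tokens(raw: list[str] | tuple[str, ...], config: PreprocessConfig) -> list[str]:
    """Drop tokens shorter than ``min_token_len``, then stopwords; keep order."""
    return [
        t
        for t in raw
        if len(t) >= config.min_token_len and t not in config.stopwords
    ]


def unit_text(record: UserRecord | PostRecord, config: PreprocessConfig) -> str:
    """Concatenate a unit's text in stored post order (title first per post
    when ``concat_title`` is on)."""
    if isinstance(record, PostRecord):
        posts = [record]
    else:
        posts = record.posts
    parts: list[str] = []
    for p in posts:
        if config.concat_title and p.title:
            parts.append(p.title)
        if p.body:
            parts.append(p.body)
    return " ".join(parts)


def unit_tokens(record: UserRecord | PostRecord, config: PreprocessConfig | None = None) -> TokenStream:
    """Assemble one unit's :class:`TokenStream` (both token views)."""
    config = config or PreprocessConfig()
    raw = tokenize_raw(unit_text(record, config))
    return TokenStream(
        raw_tokens=tuple(raw),
        model_tokens=tuple(to_model_tokens(raw, config)),
    )
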