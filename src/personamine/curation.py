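"""Corpus curation: the three-stage post-cleaning protocol for building a
PPD corpus from subreddit dumps, the term-exclusion rule for control
collections, and the depression-term-removal corpus transformation.

The three stages are deterministic predicates over single posts, applied
sequentially with an exact retention report:

1. ``title_filter`` — drop posts whose title contains an advertising /
   boilerplate phrase ("Share your story here", "Volunteers needed for a
   study", …).
2. ``content_filter`` — drop link-only posts and courtesy replies
   ("Thank you for the support") with too little substantive text.
3. ``term_exclusion`` — drop posts mentioning any of a term list (used to
   keep depression vocabulary out of the control collection: "postpartum
   depression", "ppd", "depression").

Separately, :func:`strip_terms` *deletes term occurrences from the text*
of an existing corpus without dropping posts — the ablation that measures
how much of a classifier's signal is carried by the explicit depression
wording itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

from .corpus_io import Corpus, PostRecord, UserRecord
from .preprocess import tokenize_raw

DEFAULT_TITLE_BLACKLIST = (
    "share your story here",
    "volunteers needed for a study",
)
DEFAULT_COURTESY_PHRASES = (
    "thank you for the support",
    "thank you",
    "thanks",
)
DEFAULT_EXCLUDED_TERMS = ("postpartum depression", "ppd", "depression")
DEFAULT_MIN_SUBSTANTIVE_TOKENS = 5

STAGES = ("title_filter", "content_filter", "term_exclusion")

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)


@dataclass(frozen=True)
class CurationRule:
    """One pure per-post predicate with its stage and parameters."""

    name: str
    stage: str
    phrases: tuple[str, ...] = ()
    terms: tuple[str, ...] = ()
    min_substantive_tokens: int = DEFAULT_MIN_SUBSTANTIVE_TOKENS

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")


@dataclass
class StageReport:
    stage: str
    input_count: int
    removed_count: int
    surviving_count: int
    removed_ids: list[str]


@dataclass
class CurationReport:
    """Per-stage retention accounting; input = removed + surviving at each stage."""

    stages: list[StageReport] = field(default_factory=list)

    @property
    def survivor_count(self) -> int:
        return self.stages[-1].surviving_count if self.stages else 0

    def rows(self) -> list[tuple[str, int, int, int]]:
        return [
            (s.stage, s.input_count, s.removed_count, s.surviving_count)
            for s in self.stages
        ]


# ---------------------------------------------------------------------------
# stage predicates
# ---------------------------------------------------------------------------


def filter_titles(
    posts: Sequence[PostRecord],
    blacklist_phrases: Sequence[str] = DEFAULT_TITLE_BLACKLIST,
) -> tuple[list[PostRecord], list[PostRecord]]:
    """Remove posts whose lowercased title contains a blacklist phrase as a
    substring; title-less posts are kept."""
    if any(p != p.lower() for p in blacklist_phrases):
        raise ValueError("blacklist phrases must be lowercase")
    kept, removed = [], []
    for post in posts:
        title = (post.title or "").lower()
        if title and any(ph in title for ph in blacklist_phrases):
            removed.append(post)
        else:
            kept.append(post)
    return kept, removed


def _normalize_phrase(text: str) -> str:
    # lowercase, collapse whitespace, strip edge punctuation
    return re.sub(r"\s+", " ", text.lower()).strip(" \t.!?,;:")


def filter_content(
    posts: Sequence[PostRecord],
    courtesy_phrases: Sequence[str] = DEFAULT_COURTESY_PHRASES,
    min_substantive_tokens: int = DEFAULT_MIN_SUBSTANTIVE_TOKENS,
) -> tuple[list[PostRecord], list[PostRecord]]:
    """Remove link-only / too-short posts and whole-body courtesy phrases.

    A post is removed when its body, after deleting URL spans, has fewer
    than ``min_substantive_tokens`` raw tokens, or when the full body
    (case-insensitive, whitespace-normalised) matches a courtesy phrase.
    """
    normalized_courtesy = {_normalize_phrase(p) for p in courtesy_phrases}
    kept, removed = [], []
    for post in posts:
        body_no_urls = _URL_RE.sub(" ", post.body or "")
        n_tokens = len(tokenize_raw(body_no_urls))
        if n_tokens < min_substantive_tokens or (
            _normalize_phrase(post.body or "") in normalized_courtesy
        ):
            removed.append(post)
        else:
            kept.append(post)
    return kept, removed


def _term_pattern(terms: Sequence[str]) -> re.Pattern:
    # single words match as whole tokens; multi-word terms as substrings
    # (with flexible whitespace between words)
    parts = []
    for term in terms:
        words = term.lower().split()
        if not words:
            continue
        if len(words) == 1:
            parts.append(rf"\b{re.escape(words[0])}\b")
        else:
            parts.append(r"\b" + r"\s+".join(re.escape(w) for w in words) + r"\b")
    if not parts:
        raise ValueError("terms must be non-empty")
    return re.compile("|".join(parts), re.IGNORECASE)


def exclude_by_terms(
    posts: Sequence[PostRecord],
    terms: Sequence[str] = DEFAULT_EXCLUDED_TERMS,
) -> tuple[list[PostRecord], list[PostRecord]]:
    """Remove posts whose title+body mentions any of the terms."""
    pattern = _term_pattern(terms)
    kept, removed = [], []
    for post in posts:
        if pattern.search(post.text):
            removed.append(post)
        else:
            kept.append(post)
    return kept, removed


# ---------------------------------------------------------------------------
# corpus transformation (term removal without post deletion)
# ---------------------------------------------------------------------------


def _strip_text(text: str | None, pattern: re.Pattern) -> str | None:
    if not text:
        return text
    stripped, n = pattern.subn("", text)
    if n == 0:
        return text  # untouched texts round-trip exactly
    return re.sub(r"[ \t]{2,}", " ", stripped).strip()


def strip_terms(corpus: Corpus, terms: Sequence[str]) -> Corpus:
    """Delete every occurrence of the terms from all post titles and bodies.

    Labels, ids and record order are unchanged; posts are never dropped.
    Idempotent: stripping twice equals stripping once.
    """
    pattern = _term_pattern(terms)
    records = []
    for rec in corpus.records:
        posts = [
            replace(
                p,
                title=_strip_text(p.title, pattern),
                body=_strip_text(p.body, pattern) or "",
            )
            for p in rec.posts
        ]
        records.append(UserRecord(user_id=rec.user_id, label=rec.label, posts=posts))
    return Corpus(
        name=corpus.name, unit=corpus.unit, records=records,
        split=dict(corpus.split) if corpus.split else None,
    )


# ---------------------------------------------------------------------------
# the sequential pipeline
# ---------------------------------------------------------------------------


def default_rules(
    blacklist: Sequence[str] = DEFAULT_TITLE_BLACKLIST,
    courtesy: Sequence[str] = DEFAULT_COURTESY_PHRASES,
    min_substantive_tokens: int = DEFAULT_MIN_SUBSTANTIVE_TOKENS,
    terms: Sequence[str] = DEFAULT_EXCLUDED_TERMS,
) -> list[CurationRule]:
    """The three-stage protocol with its default parameters."""
    return [
        CurationRule("advertising titles", "title_filter", phrases=tuple(blacklist)),
        CurationRule(
            "link-only and courtesy posts", "content_filter",
            phrases=tuple(courtesy), min_substantive_tokens=min_substantive_tokens,
        ),
        CurationRule("term exclusion", "term_exclusion", terms=tuple(terms)),
    ]


def _apply_rule(
    posts: Sequence[PostRecord], rule: CurationRule
) -> tuple[list[PostRecord], list[PostRecord]]:
    if rule.stage == "title_filter":
        return filter_titles(posts, rule.phrases)
    if rule.stage == "content_filter":
        return filter_content(posts, rule.phrases, rule.min_substantive_tokens)
    return exclude_by_terms(posts, rule.terms)


def curate(
    posts: Sequence[PostRecord],
    rules: Sequence[CurationRule],
    label: str = "positive",
    name: str = "curated",
) -> tuple[Corpus, CurationReport]:
    """Apply the rule stages sequentially and account for every post.

    Returns a post-unit corpus of the survivors (each post its own
    labelled record) and a report whose counts reconcile exactly at each
    stage.
    """
    report = CurationReport()
    current = list(posts)
    for rule in rules:
        kept, removed = _apply_rule(current, rule)
        report.stages.append(
            StageReport(
                stage=rule.stage,
                input_count=len(current),
                removed_count=len(removed),
                surviving_count=len(kept),
                removed_ids=[p.post_id for p in removed],
            )
        )
        current = kept
    corpus = Corpus(
        name=name,
        unit="post",
        records=[
            UserRecord(user_id=p.post_id, label=label, posts=[p]) for p in current
        ],
    )
    corpus.validate()
    return corpus, report
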