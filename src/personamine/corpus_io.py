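"""Corpus data model and readers/writers for user-post collections.

The unit of classification is a pseudonymous *persona*: an author together
with a labelled, time-ordered post history.  Two-class corpora (``control``
vs ``positive``, the positive class being the depressed/PPD one) come in
several on-disk dialects:

* ``jsonl`` — the canonical internal format, one unit record per line:
  ``{"id", "label", "posts": [{"id","title","body","created_utc","subreddit"}], "split"?}``
* ``rsdd_json`` — one JSON object per line with a ``label`` field and a
  ``posts`` array of ``[timestamp, text]`` pairs (self-reported-diagnosis
  collections are distributed line-oriented like this).
* ``erisk_xml`` — a directory of per-subject XML files (root ``INDIVIDUAL``,
  repeated ``WRITING`` elements with ``TITLE``/``DATE``/``TEXT`` children)
  plus a golden-truth text file mapping subject id to raw label.
* ``post_csv`` — a flat CSV of individually labelled posts
  (``id,subreddit,title,body,label``), the input to the curation pipeline.

Post-unit corpora reuse the user-record shape with exactly one post per
record, so a single canonical writer serves both units.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from lxml import etree

CONTROL = "control"
POSITIVE = "positive"
VALID_LABELS = frozenset({CONTROL, POSITIVE})

FORMATS = ("jsonl", "rsdd_json", "erisk_xml", "post_csv")
UNITS = ("user", "post")

#: raw-label normalisation applied when the caller supplies none
DEFAULT_LABEL_MAPS = {
    "rsdd_json": {"depression": POSITIVE, "control": CONTROL},
    "erisk_xml": {"1": POSITIVE, "0": CONTROL},
}


class CorpusFormatError(ValueError):
    """A record failed schema validation; the message names line/element and field."""


@dataclass(frozen=True)
class PostRecord:
    """One post: an id, optional title, body text, optional timestamp/subreddit."""

    post_id: str
    title: str | None = None
    body: str = ""
    created_utc: int | None = None
    subreddit: str | None = None

    def validate(self, where: str = "") -> None:
        if not self.post_id:
            raise CorpusFormatError(f"{where}: post is missing field 'id'")
        if not (self.title or self.body):
            raise CorpusFormatError(
                f"{where}: post {self.post_id!r} has neither title nor body"
            )

    @property
    def text(self) -> str:
        """Title and body joined (title first), skipping empty parts."""
        return " ".join(p for p in (self.title, self.body) if p)


@dataclass
class UserRecord:
    """A labelled unit: a persona with its post history (or one post, unit=post)."""

    user_id: str
    label: str
    posts: list[PostRecord] = field(default_factory=list)

    def validate(self, where: str = "") -> None:
        if not self.user_id:
            raise CorpusFormatError(f"{where}: record is missing field 'id'")
        if self.label not in VALID_LABELS:
            raise CorpusFormatError(
                f"{where}: record {self.user_id!r} has label {self.label!r}; "
                f"permitted labels are {sorted(VALID_LABELS)}"
            )
        seen: set[str] = set()
        for post in self.posts:
            post.validate(where or self.user_id)
            if post.post_id in seen:
                raise CorpusFormatError(
                    f"{where}: duplicate post id {post.post_id!r} in record "
                    f"{self.user_id!r}"
                )
            seen.add(post.post_id)


@dataclass
class Corpus:
    """A named, unit-uniform collection of labelled records with an optional split."""

    name: str
    unit: str
    records: list[UserRecord] = field(default_factory=list)
    split: dict[str, str] | None = None

    def validate(self) -> None:
        if self.unit not in UNITS:
            raise CorpusFormatError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        seen: set[str] = set()
        for rec in self.records:
            rec.validate()
            if rec.user_id in seen:
                raise CorpusFormatError(f"duplicate record id {rec.user_id!r}")
            seen.add(rec.user_id)
            if self.unit == "post" and len(rec.posts) != 1:
                raise CorpusFormatError(
                    f"record {rec.user_id!r}: unit=post records hold exactly one post"
                )
        if self.split is not None:
            if set(self.split) != seen:
                raise CorpusFormatError("split does not partition the record ids")
            bad = {v for v in self.split.values()} - {"train", "test"}
            if bad:
                raise CorpusFormatError(f"split values must be train/test, got {bad}")

    def labels(self) -> list[str]:
        return [rec.label for rec in self.records]

    def n_by_label(self) -> dict[str, int]:
        out = {CONTROL: 0, POSITIVE: 0}
        for rec in self.records:
            out[rec.label] += 1
        return out

    def subset(self, ids: Iterable[str], name: str | None = None) -> "Corpus":
        wanted = set(ids)
        return Corpus(
            name=name or self.name,
            unit=self.unit,
            records=[r for r in self.records if r.user_id in wanted],
        )

    def split_part(self, part: str) -> "Corpus":
        if self.split is None:
            raise CorpusFormatError(f"corpus {self.name!r} has no train/test split")
        ids = [rid for rid, p in self.split.items() if p == part]
        return self.subset(ids, name=f"{self.name}-{part}")

    def __len__(self) -> int:
        return len(self.records)


def _order_posts(posts: list[PostRecord]) -> list[PostRecord]:
    # ascending created_utc when every post carries one; otherwise file order
    if posts and all(p.created_utc is not None for p in posts):
        return sorted(posts, key=lambda p: p.created_utc)  # stable
    return posts


def _map_label(raw: object, label_map: Mapping[str, str] | None, where: str) -> str:
    raw_s = str(raw)
    if label_map is not None:
        if raw_s not in label_map:
            raise CorpusFormatError(
                f"{where}: unknown label {raw_s!r}; permitted raw labels are "
                f"{sorted(label_map)}"
            )
        mapped = label_map[raw_s]
    else:
        mapped = raw_s
    if mapped not in VALID_LABELS:
        raise CorpusFormatError(
            f"{where}: label {raw_s!r} maps to {mapped!r}, not one of "
            f"{sorted(VALID_LABELS)}"
        )
    return mapped


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_jsonl(path: Path, label_map: Mapping[str, str] | None) -> Iterator[tuple[UserRecord, str | None]]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            where = f"{path.name}:{lineno}"
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{where}: malformed JSON ({exc.msg})") from exc
            if not isinstance(obj, dict):
                raise CorpusFormatError(f"{where}: expected a JSON object")
            for fld in ("id", "label", "posts"):
                if fld not in obj:
                    raise CorpusFormatError(f"{where}: record is missing field {fld!r}")
            posts = []
            for i, p in enumerate(obj["posts"]):
                if not isinstance(p, dict) or "body" not in p:
                    raise CorpusFormatError(
                        f"{where}: post #{i} is missing field 'body'"
                    )
                posts.append(
                    PostRecord(
                        post_id=str(p.get("id", f"{obj['id']}_p{i}")),
                        title=p.get("title"),
                        body=p["body"],
                        created_utc=p.get("created_utc"),
                        subreddit=p.get("subreddit"),
                    )
                )
            rec = UserRecord(
                user_id=str(obj["id"]),
                label=_map_label(obj["label"], label_map, where),
                posts=_order_posts(posts),
            )
            yield rec, obj.get("split")


def _read_rsdd_json(path: Path, label_map: Mapping[str, str] | None) -> Iterator[tuple[UserRecord, None]]:
    label_map = label_map or DEFAULT_LABEL_MAPS["rsdd_json"]
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            where = f"{path.name}:{lineno}"
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{where}: malformed JSON ({exc.msg})") from exc
            if isinstance(obj, list):  # some dumps wrap each record in a list
                if len(obj) != 1:
                    raise CorpusFormatError(f"{where}: expected one record per line")
                obj = obj[0]
            if not isinstance(obj, dict) or "label" not in obj or "posts" not in obj:
                raise CorpusFormatError(f"{where}: record needs 'label' and 'posts'")
            uid = str(obj.get("id", f"u{lineno}"))
            posts = []
            for i, pair in enumerate(obj["posts"]):
                if not isinstance(pair, (list, tuple)) or len(pair) != 2:
                    raise CorpusFormatError(
                        f"{where}: post #{i} is not a [timestamp, text] pair"
                    )
                ts, text = pair
                posts.append(
                    PostRecord(
                        post_id=f"{uid}_p{i}",
                        body=str(text),
                        created_utc=int(ts) if ts is not None else None,
                    )
                )
            yield UserRecord(
                user_id=uid,
                label=_map_label(obj["label"], label_map, where),
                posts=_order_posts(posts),
            ), None


_TRUTH_NAMES = ("risk_golden_truth.txt", "golden_truth.txt")


def _parse_erisk_date(text: str | None) -> int | None:
    if not text:
        return None
    for fmt in ("%Y-%m-%d %H:%M:%S", "%Y-%m-%dT%H:%M:%S", "%Y-%m-%d"):
        try:
            dt = datetime.strptime(text.strip(), fmt).replace(tzinfo=timezone.utc)
            return int(dt.timestamp())
        except ValueError:
            continue
    return None


def _read_erisk_xml(path: Path, label_map: Mapping[str, str] | None) -> Iterator[tuple[UserRecord, None]]:
    label_map = label_map or DEFAULT_LABEL_MAPS["erisk_xml"]
    if not path.is_dir():
        raise CorpusFormatError(
            f"{path}: erisk_xml expects a directory of per-subject XML files"
        )
    truth: dict[str, str] = {}
    for name in _TRUTH_NAMES:
        tf = path / name
        if tf.exists():
            for lineno, line in enumerate(tf.read_text(encoding="utf-8").splitlines(), 1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise CorpusFormatError(
                        f"{name}:{lineno}: expected 'subject label'"
                    )
                truth[parts[0]] = parts[1]
            break
    else:
        raise CorpusFormatError(
            f"{path}: no golden-truth file found (looked for {_TRUTH_NAMES})"
        )
    xml_files = sorted(path.glob("*.xml"))
    if not xml_files:
        raise CorpusFormatError(f"{path}: no XML files found")
    for xf in xml_files:
        try:
            root = etree.parse(str(xf)).getroot()
        except etree.XMLSyntaxError as exc:
            raise CorpusFormatError(f"{xf.name}: malformed XML ({exc})") from exc
        if root.tag != "INDIVIDUAL":
            raise CorpusFormatError(f"{xf.name}: root element is {root.tag!r}, "
                                    "expected INDIVIDUAL")
        sid_el = root.find("ID")
        sid = sid_el.text.strip() if sid_el is not None and sid_el.text else xf.stem
        if sid not in truth:
            raise CorpusFormatError(f"{xf.name}: subject {sid!r} absent from golden truth")
        posts = []
        for i, w in enumerate(root.findall("WRITING")):
            title_el, date_el, text_el = w.find("TITLE"), w.find("DATE"), w.find("TEXT")
            title = title_el.text.strip() if title_el is not None and title_el.text else None
            body = text_el.text.strip() if text_el is not None and text_el.text else ""
            if not (title or body):
                raise CorpusFormatError(
                    f"{xf.name}: WRITING #{i} has neither TITLE nor TEXT"
                )
            posts.append(
                PostRecord(
                    post_id=f"{sid}_w{i}",
                    title=title,
                    body=body,
                    created_utc=_parse_erisk_date(
                        date_el.text if date_el is not None else None
                    ),
                )
            )
        yield UserRecord(
            user_id=sid,
            label=_map_label(truth[sid], label_map, xf.name),
            posts=_order_posts(posts),
        ), None


_CSV_COLUMNS = ("id", "subreddit", "title", "body", "label")


def _read_post_csv(path: Path, label_map: Mapping[str, str] | None) -> Iterator[tuple[UserRecord, None]]:
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CorpusFormatError(f"{path.name}: empty corpus")
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CorpusFormatError(
                f"{path.name}: header is missing columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            where = f"{path.name}:{lineno}"
            post = PostRecord(
                post_id=row["id"],
                title=row["title"] or None,
                body=row["body"] or "",
                subreddit=row["subreddit"] or None,
            )
            yield UserRecord(
                user_id=row["id"],
                label=_map_label(row["label"], label_map, where),
                posts=[post],
            ), None


_READERS = {
    "jsonl": _read_jsonl,
    "rsdd_json": _read_rsdd_json,
    "erisk_xml": _read_erisk_xml,
    "post_csv": _read_post_csv,
}


def read_corpus(
    path: str | Path,
    format: str = "jsonl",
    unit: str = "user",
    label_map: Mapping[str, str] | None = None,
    name: str | None = None,
) -> Corpus:
    """Read a labelled corpus from disk.

    Records that fail schema validation raise :class:`CorpusFormatError`
    naming the offending line/element and field — nothing is silently
    dropped.  Reading is order-stable: two reads of the same file yield
    identical record order and content.

    Parameters
    ----------
    path:
        File (``jsonl``/``rsdd_json``/``post_csv``) or directory
        (``erisk_xml``) to read.
    format:
        One of ``jsonl``, ``rsdd_json``, ``erisk_xml``, ``post_csv``.
    unit:
        ``user`` or ``post``; ``post_csv`` implies ``post``.
    label_map:
        Mapping from raw label strings to ``control``/``positive``.  Each
        dialect has a sensible default; unknown raw labels are an error.
    """
    path = Path(path)
    if format not in _READERS:
        raise CorpusFormatError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "post_csv":
        unit = "post"

    records: list[UserRecord] = []
    split: dict[str, str] = {}
    for rec, part in _READERS[format](path, label_map):
        records.append(rec)
        if part is not None:
            split[rec.user_id] = part
    if not records:
        raise CorpusFormatError(f"{path}: empty corpus")
    corpus = Corpus(
        name=name or path.stem,
        unit=unit,
        records=records,
        split=split if split else None,
    )
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# writer (canonical JSONL)
# ---------------------------------------------------------------------------


def _record_to_obj(rec: UserRecord, split: Mapping[str, str] | None) -> dict:
    obj: dict = {
        "id": rec.user_id,
        "label": rec.label,
        "posts": [
            {
                "id": p.post_id,
                "title": p.title,
                "body": p.body,
                "created_utc": p.created_utc,
                "subreddit": p.subreddit,
            }
            for p in rec.posts
        ],
    }
    if split is not None and rec.user_id in split:
        obj["split"] = split[rec.user_id]
    return obj


def corpus_to_jsonl(corpus: Corpus) -> str:
    """Render the canonical JSONL dialect (UTF-8, one record per line, sorted keys)."""
    lines = [
        json.dumps(
            _record_to_obj(rec, corpus.split),
            ensure_ascii=False,
            sort_keys=True,
            separators=(",", ":"),
        )
        for rec in corpus.records
    ]
    return "\n".join(lines) + "\n"


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the canonical JSONL dialect; ``read_corpus(write_corpus(c))`` is identity."""
    corpus.validate()
    Path(path).write_text(corpus_to_jsonl(corpus), encoding="utf-8")


def strip_split(corpus: Corpus) -> Corpus:
    """A copy of the corpus without its train/test split."""
    return Corpus(name=corpus.name, unit=corpus.unit,
                  records=[replace(r) for r in corpus.records], split=None)
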