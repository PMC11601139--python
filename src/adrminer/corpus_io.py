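"""Read, validate and write post corpora (JSON-lines) and run configurations.

A corpus file holds one JSON object per line with fields ``id``, ``channel``,
``date``, ``text`` and ``label``.  An optional leading line of the form
``{"_meta": {...}}`` carries provenance (source, generation seed) and is
round-tripped verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import yaml

CHANNELS = ("blog", "cafe", "qna", "synthetic")


class CorpusValidationError(ValueError):
    """Raised when one or more corpus records violate the record contract.

    ``errors`` is a list of ``(line_number, message)`` pairs (1-based lines).
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors)
        super().__init__(f"invalid corpus record(s): {lines}")


@dataclass
class Post:
    """One social-media document."""

    id: str
    channel: str = "synthetic"
    date: Optional[str] = None
    text: str = ""
    label: Optional[int] = None

    def validate(self) -> list[str]:
        problems = []
        if not isinstance(self.id, str) or not self.id:
            problems.append("missing or empty field 'id'")
        if self.channel not in CHANNELS:
            problems.append(f"field 'channel' must be one of {CHANNELS}, got {self.channel!r}")
        if not isinstance(self.text, str) or not self.text.strip():
            problems.append("missing or empty field 'text'")
        if self.label is not None and self.label not in (0, 1):
            problems.append(f"field 'label' must be 0 or 1, got {self.label!r}")
        return problems

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "channel": self.channel,
            "date": self.date,
            "text": self.text,
            "label": self.label,
        }


@dataclass
class Corpus:
    """An ordered collection of posts plus free-form provenance metadata."""

    posts: list[Post] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)

    def labels(self) -> list[Optional[int]]:
        return [p.label for p in self.posts]


def read_corpus(path: str | Path, require_labels: bool = False) -> Corpus:
    """Read a JSON-lines corpus, validating every record.

    Records failing the invariants are reported with their line numbers in a
    single :class:`CorpusValidationError`.
    """
    path = Path(path)
    posts: list[Post] = []
    provenance: dict = {}
    errors: list[tuple[int, str]] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                errors.append((lineno, f"malformed JSON: {exc.msg}"))
                continue
            if not isinstance(rec, dict):
                errors.append((lineno, "record is not an object"))
                continue
            if "_meta" in rec:
                provenance = rec["_meta"]
                continue
            post = Post(
                id=rec.get("id", ""),
                channel=rec.get("channel", "synthetic"),
                date=rec.get("date"),
                text=rec.get("text", ""),
                label=rec.get("label"),
            )
            problems = post.validate()
            if require_labels and post.label is None:
                problems.append("missing required field 'label'")
            if post.id in seen:
                problems.append(f"duplicate id {post.id!r}")
            for msg in problems:
                errors.append((lineno, msg))
            if not problems:
                seen.add(post.id)
                posts.append(post)
    if errors:
        raise CorpusValidationError(errors)
    return Corpus(posts=posts, provenance=provenance)


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus as JSON-lines; round-trips losslessly through read_corpus."""
    path = Path(path)
    dup = _duplicate_ids(corpus)
    if dup:
        raise CorpusValidationError([(0, f"duplicate id {d!r}") for d in dup])
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps({"_meta": corpus.provenance}, ensure_ascii=False) + "\n")
        for post in corpus.posts:
            problems = post.validate()
            if problems:
                raise CorpusValidationError([(0, m) for m in problems])
            fh.write(json.dumps(post.to_dict(), ensure_ascii=False) + "\n")
    return path


def _duplicate_ids(corpus: Corpus) -> list[str]:
    seen: set[str] = set()
    dup = []
    for p in corpus.posts:
        if p.id in seen:
            dup.append(p.id)
        seen.add(p.id)
    return dup


def summarize(corpus: Corpus) -> dict:
    """Corpus-level label accounting.

    Returns counts of labeled/unlabeled posts plus the ADR and non-ADR shares
    of the labeled subset as exact fractions in [0, 1].
    """
    labels = [p.label for p in corpus.posts if p.label is not None]
    n_adr = sum(1 for y in labels if y == 1)
    n_non = len(labels) - n_adr
    out = {
        "n_posts": len(corpus.posts),
        "n_labeled": len(labels),
        "n_adr": n_adr,
        "n_non_adr": n_non,
        "adr_share": n_adr / len(labels) if labels else float("nan"),
        "non_adr_share": n_non / len(labels) if labels else float("nan"),
    }
    return out


def read_config(path: str | Path) -> dict:
    """Load a flat YAML run configuration."""
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(cfg).__name__}")
    return cfg


def write_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True, allow_unicode=True)
    return path
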