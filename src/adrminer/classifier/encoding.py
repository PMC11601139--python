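"""Frequency-based integer encoding and left padding of tokenized posts."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from ..preprocess import TokenizedPost

PAD_INDEX = 0
OOV_INDEX = 1


@dataclass
class VocabularyEncoding:
    """term -> dense integer index, ranked by descending corpus frequency.

    Index 0 is reserved for padding, 1 for out-of-vocabulary terms; the most
    frequent term gets index 2 (frequency ties break lexicographically).
    """

    index: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.index) + 2  # + PAD + OOV

    def encode_term(self, term: str) -> int:
        return self.index.get(term, OOV_INDEX)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("term\tindex\n")
            for term, idx in sorted(self.index.items(), key=lambda kv: kv[1]):
                fh.write(f"{term}\t{idx}\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "VocabularyEncoding":
        index: dict[str, int] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                term, idx = line.rstrip("\n").rsplit("\t", 1)
                index[term] = int(idx)
        return cls(index)


@dataclass
class EncodedPost:
    post_id: str
    sequence: np.ndarray  # fixed length L, left-padded with 0
    label: Optional[int] = None


def build_vocabulary(posts: Iterable[TokenizedPost]) -> VocabularyEncoding:
    counts: Counter[str] = Counter()
    n = 0
    for p in posts:
        n += 1
        counts.update(p.rendered)
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty post stream")
    ordered = sorted(counts, key=lambda t: (-counts[t], t))
    return VocabularyEncoding({t: i + 2 for i, t in enumerate(ordered)})


def encode_and_pad(
    posts: Iterable[TokenizedPost],
    encoding: VocabularyEncoding,
    max_len: Union[int, str] = "auto",
) -> list[EncodedPost]:
    """Encode posts as integer sequences of one fixed length.

    ``max_len="auto"`` uses the longest sequence seen; longer sequences are
    truncated at the tail (the first ``L`` tokens are kept) and shorter ones
    left-padded with the reserved 0 index.
    """
    posts = list(posts)
    if max_len == "auto":
        if not posts:
            raise ValueError("max_len='auto' needs at least one post")
        L = max((len(p.tokens) for p in posts), default=1) or 1
    else:
        L = int(max_len)
        if L < 1:
            raise ValueError(f"max_len must be >= 1, got {L}")
    out = []
    for p in posts:
        ids = [encoding.encode_term(t) for t in p.rendered][:L]
        seq = np.zeros(L, dtype=np.int64)
        if ids:
            seq[L - len(ids) :] = ids
        out.append(EncodedPost(p.post_id, seq, p.label))
    return out


def as_matrix(posts: Sequence[EncodedPost]) -> tuple[np.ndarray, np.ndarray]:
    """Stack encoded posts into (X, y); unlabeled posts get label -1."""
    X = np.stack([p.sequence for p in posts])
    y = np.array([-1 if p.label is None else int(p.label) for p in posts], dtype=np.int64)
    return X, y
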