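"""Text normalization, tokenization, stop-word removal and drug/ADR tagging.

Language-specific morphological analysis is deliberately a plugin point: a
tokenizer is any callable ``text -> ordered list of Token`` over the
normalized string.  The default tokenizer splits on unicode word boundaries
and then greedily merges adjacent tokens into known multiword lexicon
surfaces (longest match first), so ADR terms like "muscle pain" become a
single token.

Tagged tokens render as ``surface_id_class`` with class strings ``drug`` and
``ADR``; plain tokens render as their surface.  The rendering parses back
unambiguously.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from .lexicon import Lexicon, normalize_surface

_URL = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_CTRL = re.compile(r"[\x00-\x08\x0b-\x1f\x7f]")
_WS = re.compile(r"\s+")
_WORD = re.compile(r"\w+", re.UNICODE)

# rendered tag classes exactly as printed in tagged posts
TAG_CLASS = {"drug": "drug", "adr": "ADR"}
_TAG_CLASS_INV = {v: k for k, v in TAG_CLASS.items()}


@dataclass(frozen=True)
class Token:
    """A span over the normalized text; offsets are 0-based half-open."""

    surface: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"token span must satisfy start < end, got [{self.start}, {self.end})")


@dataclass(frozen=True)
class TaggedToken:
    token: Token
    term_id: Optional[int] = None
    term_class: Optional[str] = None  # "drug" | "adr" | None

    def __post_init__(self):
        if (self.term_id is None) != (self.term_class is None):
            raise ValueError("term_id and term_class must be present together")
        if self.term_class is not None and self.term_class not in TAG_CLASS:
            raise ValueError(f"term_class must be 'drug' or 'adr', got {self.term_class!r}")

    @property
    def rendered(self) -> str:
        if self.term_class is None:
            return self.token.surface
        return f"{self.token.surface}_{self.term_id}_{TAG_CLASS[self.term_class]}"


def parse_rendered(rendered: str) -> tuple[str, Optional[int], Optional[str]]:
    """Inverse of TaggedToken.rendered: -> (surface, term_id, term_class)."""
    parts = rendered.rsplit("_", 2)
    if len(parts) == 3 and parts[1].isdigit() and parts[2] in _TAG_CLASS_INV:
        return parts[0], int(parts[1]), _TAG_CLASS_INV[parts[2]]
    return rendered, None, None


@dataclass
class TokenizedPost:
    """A post after normalization, tokenization, stop-word removal and tagging."""

    post_id: str
    tokens: list[TaggedToken] = field(default_factory=list)
    label: Optional[int] = None

    @property
    def rendered(self) -> list[str]:
        return [t.rendered for t in self.tokens]

    def tagged_terms(self) -> set[str]:
        return {t.rendered for t in self.tokens if t.term_class is not None}

    def is_empty(self) -> bool:
        return not self.tokens


def normalize(text: str) -> str:
    """Remove URLs and control characters, collapse whitespace, case-fold.

    Idempotent: normalize(normalize(t)) == normalize(t).
    """
    text = _URL.sub(" ", text)
    text = _CTRL.sub(" ", text)
    text = _WS.sub(" ", text).strip()
    return text.casefold()


class TokenizerError(RuntimeError):
    """Wraps a failure inside a pluggable tokenizer, naming the plugin."""


def word_tokenize(text: str) -> list[Token]:
    """Unicode word-boundary tokenizer (the plugin default's first stage)."""
    return [Token(m.group(0), m.start(), m.end()) for m in _WORD.finditer(text)]


def merge_multiword(tokens: Sequence[Token], text: str, lexicons: Iterable[Lexicon]) -> list[Token]:
    """Greedily merge adjacent tokens into known multiword lexicon surfaces.

    At each position the longest matching word sequence wins (exhaustive over
    the lexicons' multiword surfaces, longest first).
    """
    multi: set[tuple[str, ...]] = set()
    max_words = 1
    for lex in lexicons:
        multi.update(lex.multiword_surfaces())
        max_words = max(max_words, lex.max_words)
    if not multi:
        return list(tokens)
    words = [normalize_surface(t.surface) for t in tokens]
    out: list[Token] = []
    i = 0
    while i < len(tokens):
        merged = None
        for n in range(min(max_words, len(tokens) - i), 1, -1):
            if tuple(words[i : i + n]) in multi:
                start, end = tokens[i].start, tokens[i + n - 1].end
                merged = Token(text[start:end], start, end)
                i += n
                break
        if merged is None:
            out.append(tokens[i])
            i += 1
        else:
            out.append(merged)
    return out


def tokenize(
    text: str,
    tokenizer: Optional[Callable[[str], list[Token]]] = None,
    lexicons: Iterable[Lexicon] = (),
) -> list[Token]:
    """Tokenize normalized text into ordered, non-overlapping spans.

    ``tokenizer`` is the plugin point; the default is unicode word splitting
    followed by greedy longest-match merging of multiword lexicon surfaces.
    """
    if tokenizer is None:
        return merge_multiword(word_tokenize(text), text, lexicons)
    try:
        toks = tokenizer(text)
    except Exception as exc:  # surfaced with the plugin's name
        name = getattr(tokenizer, "__name__", repr(tokenizer))
        raise TokenizerError(f"tokenizer plugin {name!r} failed: {exc}") from exc
    return merge_multiword(toks, text, lexicons)


def tag_and_filter(
    tokens: Sequence[Token],
    drug: Lexicon,
    adr: Lexicon,
    stop: Lexicon,
    post_id: str = "",
    label: Optional[int] = None,
) -> TokenizedPost:
    """Drop stop words and annotate drug/ADR tokens with (term_id, class).

    A surface in both the drug and ADR lexicons is tagged as drug (drug
    precedence).
    """
    tagged: list[TaggedToken] = []
    for tok in tokens:
        if stop.lookup(tok.surface) is not None:
            continue
        entry = drug.lookup(tok.surface)
        if entry is not None:
            tagged.append(TaggedToken(tok, entry.term_id, "drug"))
            continue
        entry = adr.lookup(tok.surface)
        if entry is not None:
            tagged.append(TaggedToken(tok, entry.term_id, "adr"))
            continue
        tagged.append(TaggedToken(tok))
    return TokenizedPost(post_id=post_id, tokens=tagged, label=label)


def preprocess_post(
    post_id: str,
    text: str,
    drug: Lexicon,
    adr: Lexicon,
    stop: Lexicon,
    label: Optional[int] = None,
    tokenizer: Optional[Callable[[str], list[Token]]] = None,
) -> TokenizedPost:
    norm = normalize(text)
    toks = tokenize(norm, tokenizer=tokenizer, lexicons=(drug, adr))
    return tag_and_filter(toks, drug, adr, stop, post_id=post_id, label=label)


def preprocess_corpus(
    corpus,
    drug: Lexicon,
    adr: Lexicon,
    stop: Lexicon,
    tokenizer: Optional[Callable[[str], list[Token]]] = None,
) -> tuple[list[TokenizedPost], dict]:
    """Preprocess every post; posts that come out empty are excluded and counted."""
    kept: list[TokenizedPost] = []
    n_empty = 0
    for post in corpus:
        tp = preprocess_post(
            post.id, post.text, drug, adr, stop, label=post.label, tokenizer=tokenizer
        )
        if tp.is_empty():
            n_empty += 1
        else:
            kept.append(tp)
    report = {"n_input": len(corpus), "n_empty_excluded": n_empty, "n_kept": len(kept)}
    return kept, report


# --- JSON-lines persistence of tokenized posts -------------------------------


def write_tokenized(posts: Iterable[TokenizedPost], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in posts:
            rec = {"post_id": p.post_id, "tokens": p.rendered, "label": p.label}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    return path


def read_tokenized(path: str | Path) -> list[TokenizedPost]:
    """Rebuild TokenizedPost records from rendered token strings.

    Character offsets are reconstructed on the space-joined surface string
    (the original raw-text offsets are not persisted).
    """
    out: list[TokenizedPost] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            toks: list[TaggedToken] = []
            cursor = 0
            for rendered in rec["tokens"]:
                surface, term_id, term_class = parse_rendered(rendered)
                tok = Token(surface, cursor, cursor + len(surface))
                cursor += len(surface) + 1
                toks.append(TaggedToken(tok, term_id, term_class))
            out.append(TokenizedPost(rec["post_id"], toks, rec.get("label")))
    return out
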