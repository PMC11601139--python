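"""Shared test helpers: tiny corpora, lexicons and tokenized-post builders."""

from __future__ import annotations

from typing import Optional, Sequence

from adrminer.lexicon import Lexicon, LexiconEntry
from adrminer.preprocess import TaggedToken, Token, TokenizedPost, parse_rendered


def make_lexicon(surfaces: Sequence[str], term_class: str, start_id: int = 0) -> Lexicon:
    return Lexicon(
        [
            LexiconEntry(s, start_id + i, term_class, canonical=s, source="test")
            for i, s in enumerate(surfaces)
        ],
        term_class,
    )


def tokenized(tokens: Sequence[str], post_id: str = "p0", label: Optional[int] = None) -> TokenizedPost:
    """Build a TokenizedPost from rendered token strings (tags parsed back)."""
    out = []
    cursor = 0
    for rendered in tokens:
        surface, term_id, term_class = parse_rendered(rendered)
        tok = Token(surface, cursor, cursor + len(surface))
        cursor += len(surface) + 1
        out.append(TaggedToken(tok, term_id, term_class))
    return TokenizedPost(post_id, out, label)
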