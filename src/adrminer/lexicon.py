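"""Lexicons of drug brand names, ADR terms and stop words.

Lexicon files are UTF-8 tab-separated tables with a header row and columns
``surface`` / ``term_id`` / ``canonical`` / ``source`` (``term_id`` is
optional for stop words and is assigned by stable file-order enumeration when
absent).  Lookup is exact-match after surface normalization (case folding and
whitespace collapsing), and multiword surfaces are supported downstream via
greedy longest-match tokenization.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

TERM_CLASSES = ("drug", "adr", "stopword")

_WS = re.compile(r"\s+")


def normalize_surface(surface: str) -> str:
    """Canonical match form of a surface: casefold + collapse whitespace."""
    return _WS.sub(" ", surface.strip()).casefold()


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    term_id: int
    term_class: str
    canonical: str = ""
    source: str = "manual"

    def __post_init__(self):
        if not self.surface or not self.surface.strip():
            raise ValueError("lexicon surface must be non-empty")
        if self.term_class not in TERM_CLASSES:
            raise ValueError(f"term_class must be one of {TERM_CLASSES}, got {self.term_class!r}")
        if self.term_id < 0:
            raise ValueError(f"term_id must be non-negative, got {self.term_id}")


class Lexicon:
    """Entries of one term class with a normalized-surface index."""

    def __init__(self, entries: Iterable[LexiconEntry], term_class: str):
        if term_class not in TERM_CLASSES:
            raise ValueError(f"unknown term_class {term_class!r}")
        self.term_class = term_class
        self.entries: list[LexiconEntry] = []
        self._by_surface: dict[str, LexiconEntry] = {}
        ids: set[int] = set()
        dup_surfaces, dup_ids = [], []
        for e in entries:
            if e.term_class != term_class:
                raise ValueError(
                    f"entry {e.surface!r} has class {e.term_class!r}, expected {term_class!r}"
                )
            key = normalize_surface(e.surface)
            if key in self._by_surface:
                dup_surfaces.append(e.surface)
                continue
            if e.term_id in ids:
                dup_ids.append(e.term_id)
                continue
            self._by_surface[key] = e
            ids.add(e.term_id)
            self.entries.append(e)
        if dup_surfaces:
            raise ValueError(
                f"duplicate surfaces in {term_class} lexicon: {sorted(set(dup_surfaces))}"
            )
        if dup_ids:
            raise ValueError(f"duplicate term_ids in {term_class} lexicon: {sorted(set(dup_ids))}")
        # longest multiword surface, in words, for the longest-match tokenizer
        self.max_words = max((len(k.split()) for k in self._by_surface), default=0)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surface: str) -> bool:
        return normalize_surface(surface) in self._by_surface

    def lookup(self, surface: str) -> Optional[LexiconEntry]:
        """Entry for a surface after normalization, or None. Never raises on miss."""
        return self._by_surface.get(normalize_surface(surface))

    def surfaces(self) -> list[str]:
        return list(self._by_surface)

    def multiword_surfaces(self) -> list[tuple[str, ...]]:
        return [tuple(k.split()) for k in self._by_surface if " " in k]


def load_lexicon(path: str | Path, term_class: str) -> Lexicon:
    """Load one lexicon from a tab-separated table.

    Rows missing ``term_id`` get stable file-order ids starting after the
    largest explicit id.  Duplicate surfaces within the class are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "surface" not in df.columns:
        raise ValueError(f"{path}: lexicon table must have a 'surface' column")
    if df.empty:
        raise ValueError(f"{path}: lexicon file has no entries")
    explicit = [int(v) for v in df.get("term_id", pd.Series(dtype=str)) if str(v).strip() != ""]
    next_id = max(explicit, default=-1) + 1
    entries = []
    for _, row in df.iterrows():
        raw_id = str(row.get("term_id", "")).strip()
        if raw_id == "":
            term_id, next_id = next_id, next_id + 1
        else:
            term_id = int(raw_id)
        entries.append(
            LexiconEntry(
                surface=str(row["surface"]),
                term_id=term_id,
                term_class=term_class,
                canonical=str(row.get("canonical", "")) or str(row["surface"]),
                source=str(row.get("source", "")) or "manual",
            )
        )
    return Lexicon(entries, term_class)


def dump_lexicon(lexicon: Lexicon, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "surface": e.surface,
                "term_id": e.term_id,
                "canonical": e.canonical,
                "source": e.source,
            }
            for e in lexicon.entries
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def check_disjoint(a: Lexicon, b: Lexicon, error: bool = True) -> list[str]:
    """Surfaces shared between two lexicons (normalized comparison).

    Used to validate that the stop-word and ADR lexicons do not overlap.
    """
    shared = sorted(set(a.surfaces()) & set(b.surfaces()))
    if shared and error:
        raise ValueError(
            f"lexicons {a.term_class!r} and {b.term_class!r} share surfaces: {shared}"
        )
    return shared


def warn_drug_adr_collisions(drug: Lexicon, adr: Lexicon) -> list[str]:
    """Warn about surfaces present in both drug and ADR lexicons.

    Such surfaces are tagged as drug (drug precedence) during tagging.
    """
    shared = check_disjoint(drug, adr, error=False)
    if shared:
        warnings.warn(
            f"surfaces in both drug and ADR lexicons are tagged as drug: {shared}",
            stacklevel=2,
        )
    return shared
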