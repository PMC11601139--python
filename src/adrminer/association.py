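"""Drug->ADR association-rule mining over tagged posts, and rule-based filtering.

Each tokenized post becomes a transaction: the set of its tagged drug/ADR
terms (rendered forms).  Rules are restricted to single-antecedent (drug),
single-consequent (ADR) pairs with

    support    = n(drug & adr) / N
    confidence = n(drug & adr) / n(drug)
    lift       = confidence / (n(adr) / N)

Default thresholds: support 0.01, confidence 0.6.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .preprocess import TokenizedPost, parse_rendered

DEFAULT_MIN_SUPPORT = 0.01
DEFAULT_MIN_CONFIDENCE = 0.6


@dataclass(frozen=True)
class Transaction:
    post_id: str
    items: frozenset[str]


@dataclass(frozen=True)
class AssociationRule:
    antecedent: str  # rendered drug term
    consequent: str  # rendered ADR term
    support: float
    confidence: float
    lift: float
    n_joint: int

    def __post_init__(self):
        if not (0.0 <= self.support <= 1.0 and 0.0 <= self.confidence <= 1.0):
            raise ValueError("support and confidence must lie in [0, 1]")
        if self.confidence + 1e-12 < self.support:
            raise ValueError("confidence cannot be smaller than support")


def build_transactions(posts: Iterable[TokenizedPost]) -> tuple[list[Transaction], dict]:
    """One transaction per post holding its tagged terms; untagged posts are
    omitted and counted in the report."""
    txns: list[Transaction] = []
    n_untagged = 0
    n_posts = 0
    for p in posts:
        n_posts += 1
        items = p.tagged_terms()
        if items:
            txns.append(Transaction(p.post_id, frozenset(items)))
        else:
            n_untagged += 1
    return txns, {"n_posts": n_posts, "n_untagged_omitted": n_untagged, "n_transactions": len(txns)}


def _split_classes(items: Iterable[str]) -> tuple[list[str], list[str]]:
    drugs, adrs = [], []
    for it in items:
        _, _, cls = parse_rendered(it)
        if cls == "drug":
            drugs.append(it)
        elif cls == "adr":
            adrs.append(it)
    return drugs, adrs


def mine_rules(
    transactions: Sequence[Transaction],
    min_support: float = DEFAULT_MIN_SUPPORT,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[AssociationRule]:
    """All drug->ADR pairs meeting both thresholds.

    Sorted by (confidence desc, support desc, antecedent, consequent) for
    deterministic output.
    """
    if not transactions:
        raise ValueError("cannot mine rules from an empty transaction set")
    for name, v in (("min_support", min_support), ("min_confidence", min_confidence)):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    n = len(transactions)
    drug_count: Counter[str] = Counter()
    adr_count: Counter[str] = Counter()
    joint: Counter[tuple[str, str]] = Counter()
    for t in transactions:
        drugs, adrs = _split_classes(t.items)
        drug_count.update(drugs)
        adr_count.update(adrs)
        for d in drugs:
            for a in adrs:
                joint[(d, a)] += 1
    rules = []
    for (d, a), n_joint in joint.items():
        support = n_joint / n
        confidence = n_joint / drug_count[d]
        if support >= min_support and confidence >= min_confidence:
            lift = confidence / (adr_count[a] / n)
            rules.append(AssociationRule(d, a, support, confidence, lift, n_joint))
    rules.sort(key=lambda r: (-r.confidence, -r.support, r.antecedent, r.consequent))
    return rules


def filter_posts(
    posts: Iterable[TokenizedPost], rules: Sequence[AssociationRule]
) -> tuple[list[TokenizedPost], dict]:
    """Keep exactly the posts whose tagged terms contain both members of at
    least one rule; input order preserved."""
    if not rules:
        raise ValueError("filter_posts requires a non-empty rule set")
    pairs = [(r.antecedent, r.consequent) for r in rules]
    kept: list[TokenizedPost] = []
    n_in = 0
    for p in posts:
        n_in += 1
        items = p.tagged_terms()
        if any(d in items and a in items for d, a in pairs):
            kept.append(p)
    return kept, {"n_input": n_in, "n_retained": len(kept), "n_dropped": n_in - len(kept)}


def write_rules(rules: Sequence[AssociationRule], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "antecedent": r.antecedent,
                "consequent": r.consequent,
                "support": r.support,
                "confidence": r.confidence,
                "lift": r.lift,
                "n_joint": r.n_joint,
            }
            for r in rules
        ],
        columns=["antecedent", "consequent", "support", "confidence", "lift", "n_joint"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_rules(path: str | Path) -> list[AssociationRule]:
    df = pd.read_csv(path, sep="\t")
    return [
        AssociationRule(
            str(r.antecedent),
            str(r.consequent),
            float(r.support),
            float(r.confidence),
            float(r.lift),
            int(r.n_joint),
        )
        for r in df.itertuples(index=False)
    ]
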