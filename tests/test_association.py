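import itertools

import numpy as np
import pytest

from adrminer.association import (
    AssociationRule,
    Transaction,
    build_transactions,
    filter_posts,
    mine_rules,
    read_rules,
    write_rules,
)

from util import tokenized


def _txn(post_id, items):
    return Transaction(post_id, frozenset(items))


def brute_force_rules(transactions, min_support, min_confidence):
    """Independent oracle: enumerate all drug x ADR pairs with direct counting."""
    drugs = sorted({i for t in transactions for i in t.items if i.endswith("_drug")})
    adrs = sorted({i for t in transactions for i in t.items if i.endswith("_ADR")})
    n = len(transactions)
    out = set()
    for d, a in itertools.product(drugs, adrs):
        n_joint = sum(1 for t in transactions if d in t.items and a in t.items)
        n_d = sum(1 for t in transactions if d in t.items)
        n_a = sum(1 for t in transactions if a in t.items)
        if n_joint == 0 or n_d == 0:
            continue
        support = n_joint / n
        confidence = n_joint / n_d
        if support >= min_support and confidence >= min_confidence:
            out.add((d, a, round(support, 12), round(confidence, 12), round(confidence / (n_a / n), 12)))
    return out


def _random_transactions(rng, n_posts=100, n_drugs=5, n_adrs=10):
    txns = []
    for i in range(n_posts):
        items = set()
        for d in range(n_drugs):
            if rng.random() < 0.25:
                items.add(f"d{d}_{d}_drug")
        for a in range(n_adrs):
            if rng.random() < 0.2:
                items.add(f"a{a}_{a}_ADR")
        if items:
            txns.append(_txn(f"p{i}", items))
    return txns


class TestBuildTransactions:
    def test_tagged_items_only(self):
        p = tokenized(["got", "blisters_153_ADR", "ketotop_1_drug"], "p1")
        txns, rep = build_transactions([p])
        assert txns[0].items == frozenset({"blisters_153_ADR", "ketotop_1_drug"})
        assert rep["n_untagged_omitted"] == 0

    def test_duplicates_collapse(self):
        p = tokenized(["itch_156_ADR", "bad", "itch_156_ADR"], "p1")
        txns, _ = build_transactions([p])
        assert txns[0].items == frozenset({"itch_156_ADR"})

    def test_untagged_posts_omitted_and_counted(self):
        posts = [tokenized(["plain", "words"], "p1"), tokenized(["x_1_drug"], "p2")]
        txns, rep = build_transactions(posts)
        assert [t.post_id for t in txns] == ["p2"]
        assert rep == {"n_posts": 2, "n_untagged_omitted": 1, "n_transactions": 1}

    def test_no_tagged_posts(self):
        txns, rep = build_transactions([tokenized(["a"], "p1")])
        assert txns == [] and rep["n_untagged_omitted"] == 1


class TestMineRules:
    def test_degenerate_maximum(self):
        txns = [_txn(f"p{i}", {"x_0_drug", "y_0_ADR"}) for i in range(8)]
        rules = mine_rules(txns)
        assert len(rules) == 1
        r = rules[0]
        assert (r.support, r.confidence, r.n_joint) == (1.0, 1.0, 8)

    def test_hand_counted_fixture(self):
        # drugX in 10 of 100 posts, {drugX, adrY} in 7 of them; adrY in 20 overall
        txns = []
        for i in range(7):
            txns.append(_txn(f"j{i}", {"drugx_0_drug", "adry_0_ADR"}))
        for i in range(3):
            txns.append(_txn(f"d{i}", {"drugx_0_drug"}))
        for i in range(13):
            txns.append(_txn(f"a{i}", {"adry_0_ADR"}))
        for i in range(77):
            txns.append(_txn(f"f{i}", {"other_1_ADR"}))
        rules = mine_rules(txns, min_support=0.01, min_confidence=0.6)
        r = next(r for r in rules if r.antecedent == "drugx_0_drug")
        assert r.support == pytest.approx(0.07)
        assert r.confidence == pytest.approx(0.7)
        assert r.lift == pytest.approx(0.7 / 0.20)
        assert r.n_joint == 7

    def test_below_support_excluded(self):
        txns = [_txn(f"j{i}", {"x_0_drug", "y_0_ADR"}) for i in range(5)]
        txns += [_txn(f"f{i}", {"z_1_drug"}) for i in range(995)]
        assert mine_rules(txns, min_support=0.01, min_confidence=0.6) == []

    def test_empty_transactions_error(self):
        with pytest.raises(ValueError, match="empty"):
            mine_rules([])

    def test_threshold_validation(self):
        txns = [_txn("p", {"x_0_drug"})]
        with pytest.raises(ValueError):
            mine_rules(txns, min_support=0.0)
        with pytest.raises(ValueError):
            mine_rules(txns, min_confidence=1.5)

    def test_matches_bruteforce_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            txns = _random_transactions(rng)
            if not txns:
                continue
            got = {
                (r.antecedent, r.consequent, round(r.support, 12), round(r.confidence, 12), round(r.lift, 12))
                for r in mine_rules(txns, 0.05, 0.3)
            }
            assert got == brute_force_rules(txns, 0.05, 0.3)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        txns = _random_transactions(rng)
        base = {(r.antecedent, r.consequent) for r in mine_rules(txns, 0.02, 0.2)}
        for ms, mc in [(0.05, 0.2), (0.02, 0.4), (0.1, 0.6)]:
            tighter = {(r.antecedent, r.consequent) for r in mine_rules(txns, ms, mc)}
            assert tighter <= base

    def test_deterministic_ordering(self):
        rng = np.random.default_rng(5)
        txns = _random_transactions(rng)
        r1 = mine_rules(txns, 0.02, 0.2)
        r2 = mine_rules(txns, 0.02, 0.2)
        assert r1 == r2
        keys = [(-r.confidence, -r.support, r.antecedent, r.consequent) for r in r1]
        assert keys == sorted(keys)

    def test_planted_signal_recovery(self):
        # pair planted with joint frequency >= 2*min_support and conditional
        # rate >= min_confidence + 0.1 must be recovered in >= 95% of seeds
        min_support, min_confidence = 0.01, 0.6
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            txns = []
            for i in range(200):
                items = set()
                if rng.random() < 0.25:  # antecedent present
                    items.add("px_0_drug")
                    if rng.random() < min_confidence + 0.2:  # conditional rate 0.8
                        items.add("py_0_ADR")
                if rng.random() < 0.3:
                    items.add(f"a{rng.integers(5)}_1_ADR")
                if items:
                    txns.append(_txn(f"p{i}", items))
            rules = mine_rules(txns, min_support, min_confidence)
            hits += any(r.antecedent == "px_0_drug" and r.consequent == "py_0_ADR" for r in rules)
        assert hits >= 95


class TestFilterPosts:
    RULES = [AssociationRule("x_0_drug", "y_0_ADR", 0.1, 0.7, 2.0, 10)]

    def test_pair_retained(self):
        posts = [tokenized(["x_0_drug", "w", "y_0_ADR"], "p1")]
        kept, rep = filter_posts(posts, self.RULES)
        assert [p.post_id for p in kept] == ["p1"]
        assert rep == {"n_input": 1, "n_retained": 1, "n_dropped": 0}

    def test_antecedent_only_dropped(self):
        posts = [tokenized(["x_0_drug", "w"], "p1")]
        kept, rep = filter_posts(posts, self.RULES)
        assert kept == [] and rep["n_dropped"] == 1

    def test_empty_rules_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            filter_posts([], [])

    def test_matches_exhaustive_scan(self, keto_bundle):
        from adrminer import preprocess

        b = keto_bundle
        toks, _ = preprocess.preprocess_corpus(
            b.corpus, b.drug_lexicon, b.adr_lexicon, b.stop_lexicon
        )
        txns, _ = build_transactions(toks)
        rules = mine_rules(txns)
        kept, _ = filter_posts(toks, rules)
        pairs = [(r.antecedent, r.consequent) for r in rules]
        expected = [
            p.post_id
            for p in toks
            if any(d in p.tagged_terms() and a in p.tagged_terms() for d, a in pairs)
        ]
        assert [p.post_id for p in kept] == expected


def test_rules_tsv_roundtrip(tmp_path):
    rules = [
        AssociationRule("x_0_drug", "y_0_ADR", 0.25, 0.8, 1.6, 25),
        AssociationRule("z_1_drug", "y_0_ADR", 0.1, 0.625, 1.25, 10),
    ]
    again = read_rules(write_rules(rules, tmp_path / "rules.tsv"))
    assert again == rules
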