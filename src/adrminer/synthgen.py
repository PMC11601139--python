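"""Synthetic labeled corpora, lexicons and paired annotator labels.

Generated posts have the statistical structure the pipeline assumes: ADR
posts carry a drug term plus an ADR term drawn from a drug x ADR pair matrix
(placed adjacently so embedding windows see the pair), non-ADR posts carry
drug mentions and incidental ADR words at a configurable rate, filler words
are drawn from label-dependent topic distributions (the classifier's signal),
and stop words are interleaved.  Two presets mirror the study's main and
extra-drug datasets: ``ketoprofen-like`` (576 posts, 42.4% ADR) and
``geworin-like`` (236 posts, 66/236 ADR).

Synthetic "text" is space-delimited ASCII-safe tokens; a Hangul token style
exists to exercise unicode handling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .corpus_io import Corpus, Post, write_corpus
from .lexicon import Lexicon, LexiconEntry, dump_lexicon

_TOPIC_DECAY = 0.93  # geometric decay of the label-dependent filler topics


@dataclass
class GeneratorConfig:
    n_posts: int = 576
    n_drugs: int = 2
    n_adr_terms: int = 12
    n_filler: int = 40
    n_stopwords: int = 8
    adr_prevalence: float = 0.424
    pair_matrix: Optional[np.ndarray] = None  # drug x ADR pair probabilities for ADR posts
    incidental_adr_rate: float = 0.5
    nonadr_drug_rate: float = 0.5  # share of non-ADR posts mentioning a drug
    extra_adr_rate: float = 0.5  # chance of a second, random ADR term in an ADR post
    post_length: tuple[int, int] = (6, 18)
    stopword_rate: float = 0.15
    label_noise: float = 0.0
    annotator_agreement: float = 0.93
    token_style: str = "ascii"  # "ascii" | "hangul"
    seed: int = 0

    def validate(self) -> None:
        if self.n_posts < 10:
            raise ValueError(f"n_posts must be >= 10, got {self.n_posts}")
        for name in (
            "adr_prevalence",
            "incidental_adr_rate",
            "nonadr_drug_rate",
            "extra_adr_rate",
            "stopword_rate",
            "label_noise",
            "annotator_agreement",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.post_length
        if lo > hi or lo < 4:
            raise ValueError(
                f"post_length must satisfy 4 <= min <= max (room for drug+ADR core), got {self.post_length}"
            )
        if min(self.n_drugs, self.n_adr_terms, self.n_filler, self.n_stopwords) < 1:
            raise ValueError("vocabulary sizes must all be >= 1")
        if self.token_style not in ("ascii", "hangul"):
            raise ValueError(f"token_style must be 'ascii' or 'hangul', got {self.token_style!r}")
        pm = self.resolved_pair_matrix()
        if pm.shape != (self.n_drugs, self.n_adr_terms):
            raise ValueError(
                f"pair_matrix shape {pm.shape} != (n_drugs, n_adr_terms) = "
                f"({self.n_drugs}, {self.n_adr_terms})"
            )
        if (pm < 0).any() or (pm.sum(axis=1) > 1.0 + 1e-9).any():
            raise ValueError("pair_matrix entries must be >= 0 with row sums <= 1")

    def resolved_pair_matrix(self) -> np.ndarray:
        if self.pair_matrix is not None:
            return np.asarray(self.pair_matrix, dtype=float)
        pm = np.zeros((self.n_drugs, self.n_adr_terms))
        for i in range(self.n_drugs):
            pm[i, i % self.n_adr_terms] = 0.9
        return pm


def _surfaces(config: GeneratorConfig) -> dict[str, list[str]]:
    if config.token_style == "hangul":
        return {
            "drug": [f"약물{i}" for i in range(config.n_drugs)],
            "adr": [f"증상{j}" for j in range(config.n_adr_terms)],
            "stop": [f"그냥{k}" for k in range(config.n_stopwords)],
            "filler": [f"말{m}" for m in range(config.n_filler)],
        }
    return {
        "drug": [f"drug_{i}" for i in range(config.n_drugs)],
        "adr": [f"adr_{j}" for j in range(config.n_adr_terms)],
        "stop": [f"stop_{k}" for k in range(config.n_stopwords)],
        "filler": [f"w_{m}" for m in range(config.n_filler)],
    }


@dataclass
class SyntheticBundle:
    corpus: Corpus
    drug_lexicon: Lexicon
    adr_lexicon: Lexicon
    stop_lexicon: Lexicon
    truth: list[dict]
    annotator_labels: tuple[np.ndarray, np.ndarray]
    planted_pairs: list[tuple[str, str]]  # (drug surface, ADR surface) high-signal pairs
    config: GeneratorConfig = field(default_factory=GeneratorConfig)


def agreement_for_kappa(kappa: float, prevalence: float) -> float:
    """Observed-agreement level that yields a target Cohen's kappa.

    Under the annotator model (each rater flips the true label independently
    with probability eps), solves for eps by bisection and returns the
    expected observed agreement (1-eps)^2 + eps^2.
    """
    if not (0.0 < kappa <= 1.0):
        raise ValueError(f"target kappa must lie in (0, 1], got {kappa}")

    def kappa_of(eps: float) -> float:
        p_o = (1 - eps) ** 2 + eps**2
        p1 = prevalence * (1 - eps) + (1 - prevalence) * eps
        p_e = p1**2 + (1 - p1) ** 2
        if 1 - p_e < 1e-15:
            return 1.0
        return (p_o - p_e) / (1 - p_e)

    lo, hi = 0.0, 0.5
    for _ in range(200):
        mid = (lo + hi) / 2
        if kappa_of(mid) > kappa:
            lo = mid
        else:
            hi = mid
    eps = (lo + hi) / 2
    return (1 - eps) ** 2 + eps**2


def make_annotators(
    truth: np.ndarray, agreement: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two simulated annotator label vectors with tunable expected agreement.

    Each annotator equals the true label independently with probability
    1 - eps where (1-eps)^2 + eps^2 == agreement.
    """
    if not (0.5 <= agreement <= 1.0):
        raise ValueError(f"agreement must lie in [0.5, 1], got {agreement}")
    truth = np.asarray(truth, dtype=np.int64)
    eps = (1.0 - math.sqrt(2.0 * agreement - 1.0)) / 2.0
    rng = np.random.default_rng(seed)
    a = np.where(rng.random(truth.size) < eps, 1 - truth, truth)
    b = np.where(rng.random(truth.size) < eps, 1 - truth, truth)
    return a, b


def _build_lexicons(config: GeneratorConfig) -> tuple[Lexicon, Lexicon, Lexicon, dict]:
    surf = _surfaces(config)
    drug = Lexicon(
        [
            LexiconEntry(s, i, "drug", canonical=f"generic_{i}", source="synthetic")
            for i, s in enumerate(surf["drug"])
        ],
        "drug",
    )
    adr = Lexicon(
        [
            LexiconEntry(s, j, "adr", canonical=s, source="synthetic")
            for j, s in enumerate(surf["adr"])
        ],
        "adr",
    )
    stop = Lexicon(
        [
            LexiconEntry(s, k, "stopword", canonical=s, source="synthetic")
            for k, s in enumerate(surf["stop"])
        ],
        "stopword",
    )
    return drug, adr, stop, surf


def generate(config: GeneratorConfig) -> SyntheticBundle:
    """Generate a full synthetic bundle; identical seeds give identical bundles."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pm = config.resolved_pair_matrix()
    drug_lex, adr_lex, stop_lex, surf = _build_lexicons(config)
    n_adr_posts = round(config.n_posts * config.adr_prevalence)
    true_labels = np.zeros(config.n_posts, dtype=np.int64)
    true_labels[rng.permutation(config.n_posts)[:n_adr_posts]] = 1

    # label-dependent filler topics: geometric decay from opposite ends
    decay = _TOPIC_DECAY ** np.arange(config.n_filler)
    topic_pos = decay / decay.sum()
    topic_neg = decay[::-1] / decay.sum()

    posts: list[Post] = []
    truth: list[dict] = []
    lo, hi = config.post_length
    for idx in range(config.n_posts):
        true_y = int(true_labels[idx])
        core: list[str] = []
        drug_surface = adr_surface = None
        if true_y == 1:
            d = int(rng.integers(config.n_drugs))
            probs = pm[d] + (1.0 - pm[d].sum()) / config.n_adr_terms
            a = int(rng.choice(config.n_adr_terms, p=probs / probs.sum()))
            drug_surface, adr_surface = surf["drug"][d], surf["adr"][a]
            core = [drug_surface, adr_surface]
            if rng.random() < config.extra_adr_rate:
                core.append(surf["adr"][int(rng.integers(config.n_adr_terms))])
        else:
            if rng.random() < config.nonadr_drug_rate:
                d = int(rng.integers(config.n_drugs))
                drug_surface = surf["drug"][d]
                core = [drug_surface]
                if rng.random() < config.incidental_adr_rate:
                    probs = pm[d] + (1.0 - pm[d].sum()) / config.n_adr_terms
                    a = int(rng.choice(config.n_adr_terms, p=probs / probs.sum()))
                    adr_surface = surf["adr"][a]
                    core.append(adr_surface)
        length = int(rng.integers(lo, hi + 1))
        n_rest = max(1, length - len(core))
        n_stop = int(rng.binomial(n_rest, config.stopword_rate))
        n_fill = n_rest - n_stop
        topic = topic_pos if true_y == 1 else topic_neg
        fillers = [surf["filler"][int(i)] for i in rng.choice(config.n_filler, n_fill, p=topic)]
        stops = [surf["stop"][int(i)] for i in rng.integers(0, config.n_stopwords, n_stop)]
        rest = fillers + stops
        rest = [rest[i] for i in rng.permutation(len(rest))]
        cut = int(rng.integers(0, len(rest) + 1))
        tokens = rest[:cut] + core + rest[cut:]

        observed = true_y
        if config.label_noise > 0 and rng.random() < config.label_noise:
            observed = 1 - true_y
        post_id = f"p{idx:05d}"
        posts.append(
            Post(id=post_id, channel="synthetic", date=None, text=" ".join(tokens), label=observed)
        )
        truth.append(
            {
                "post_id": post_id,
                "true_label": true_y,
                "observed_label": observed,
                "drug": drug_surface,
                "adr": adr_surface,
            }
        )

    annotators = make_annotators(true_labels, config.annotator_agreement, config.seed + 104729)
    planted = [
        (surf["drug"][i], surf["adr"][j])
        for i in range(config.n_drugs)
        for j in range(config.n_adr_terms)
        if pm[i, j] >= 0.5
    ]
    corpus = Corpus(
        posts=posts,
        provenance={"source": "adrminer.synthgen", "seed": config.seed, "n_posts": config.n_posts},
    )
    return SyntheticBundle(
        corpus=corpus,
        drug_lexicon=drug_lex,
        adr_lexicon=adr_lex,
        stop_lexicon=stop_lex,
        truth=truth,
        annotator_labels=annotators,
        planted_pairs=planted,
        config=config,
    )


def preset(name: str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Named generator configurations mirroring the study's two datasets."""
    if name == "ketoprofen-like":
        cfg = GeneratorConfig(
            n_posts=576,
            adr_prevalence=0.424,
            annotator_agreement=agreement_for_kappa(0.8, 0.424),
            seed=seed,
        )
    elif name == "geworin-like":
        cfg = GeneratorConfig(
            n_posts=236,
            adr_prevalence=66 / 236,
            annotator_agreement=agreement_for_kappa(0.8, 66 / 236),
            seed=seed,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose 'ketoprofen-like' or 'geworin-like'")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


PRESETS = ("ketoprofen-like", "geworin-like")


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> Path:
    """Persist corpus, lexicons, truth and annotator labels as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_corpus(bundle.corpus, outdir / "corpus.jsonl")
    dump_lexicon(bundle.drug_lexicon, outdir / "drug_lexicon.tsv")
    dump_lexicon(bundle.adr_lexicon, outdir / "adr_lexicon.tsv")
    dump_lexicon(bundle.stop_lexicon, outdir / "stop_lexicon.tsv")
    with (outdir / "truth.jsonl").open("w", encoding="utf-8") as fh:
        for rec in bundle.truth:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    a, b = bundle.annotator_labels
    with (outdir / "annotators.jsonl").open("w", encoding="utf-8") as fh:
        for rec, ya, yb in zip(bundle.truth, a, b):
            fh.write(
                json.dumps({"post_id": rec["post_id"], "a": int(ya), "b": int(yb)}) + "\n"
            )
    cfg = {k: v for k, v in vars(bundle.config).items() if k != "pair_matrix"}
    cfg["pair_matrix"] = bundle.config.resolved_pair_matrix().tolist()
    cfg["post_length"] = list(bundle.config.post_length)
    (outdir / "generator_config.json").write_text(
        json.dumps(cfg, indent=2), encoding="utf-8"
    )
    return outdir
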