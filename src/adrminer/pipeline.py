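"""End-to-end orchestration: simulate/load -> preprocess -> mine -> filter ->
embed -> train -> evaluate, driven by one YAML configuration.

All randomness flows from a single master seed; per-stage seeds are derived
deterministically, so two runs with the same configuration produce identical
reports apart from timings.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np

from . import association, corpus_io, embedding, evaluate, lexicon, preprocess, synthgen
from .classifier import (
    ModelConfig,
    build_vocabulary,
    classify,
    encode_and_pad,
    predict_proba,
    save_model,
    split_train_test,
    train,
)

log = logging.getLogger("adrminer")

_STAGE_SEED_OFFSETS = {"simulate": 0, "embed": 1, "train": 2, "split": 3, "annotate": 4}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _stage_seed(master: int, stage: str) -> int:
    return int(master) + _STAGE_SEED_OFFSETS[stage]


def _validate_config(cfg: dict) -> None:
    if "preset" not in cfg and "generator" not in cfg:
        needed = ("corpus", "drug_lexicon", "adr_lexicon", "stop_lexicon")
        missing = [k for k in needed if k not in cfg]
        if missing:
            raise ValueError(
                f"configuration needs either a simulation preset or input paths; missing: {missing}"
            )


def run_pipeline(config: dict | str | Path, out_dir: Optional[str | Path] = None) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    if not isinstance(config, dict):
        config = corpus_io.read_config(config)
    _validate_config(config)
    master_seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "adrminer_run"))
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {"config": _jsonable(config), "seed": master_seed, "stages": {}, "warnings": []}
    t_all = time.perf_counter()

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                report["stages"].setdefault(name, {})
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                elapsed = time.perf_counter() - self.t0
                report["stages"].setdefault(name, {})["seconds"] = round(elapsed, 3)
                _write_report(report, out)
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                    raise PipelineError(name, exc) from exc
                log.info("stage %s: done in %.2fs", name, elapsed)
                return False

        return _Ctx()

    # --- stage 1: corpus + lexicons -----------------------------------------
    annotators = None
    with stage("corpus"):
        if "preset" in config:
            gen_cfg = synthgen.preset(
                config["preset"],
                seed=_stage_seed(master_seed, "simulate"),
                **config.get("generator", {}),
            )
        elif "generator" in config:
            gen_cfg = synthgen.GeneratorConfig(
                seed=_stage_seed(master_seed, "simulate"), **config["generator"]
            )
        else:
            gen_cfg = None
        if gen_cfg is not None:
            bundle = synthgen.generate(gen_cfg)
            sim_dir = out / "simulate"
            synthgen.write_bundle(bundle, sim_dir)
            corpus = bundle.corpus
            drug, adr, stop = bundle.drug_lexicon, bundle.adr_lexicon, bundle.stop_lexicon
            annotators = bundle.annotator_labels
        else:
            corpus = corpus_io.read_corpus(config["corpus"])
            drug = lexicon.load_lexicon(config["drug_lexicon"], "drug")
            adr = lexicon.load_lexicon(config["adr_lexicon"], "adr")
            stop = lexicon.load_lexicon(config["stop_lexicon"], "stopword")
        collisions = lexicon.warn_drug_adr_collisions(drug, adr)
        if collisions:
            report["warnings"].append(f"drug/ADR lexicon collisions (drug precedence): {collisions}")
        lexicon.check_disjoint(stop, adr)
        report["stages"]["corpus"].update(
            {"n_posts": len(corpus), "n_drug_terms": len(drug), "n_adr_terms": len(adr)}
        )

    with stage("preprocess"):
        tokenized, pre_report = preprocess.preprocess_corpus(corpus, drug, adr, stop)
        preprocess.write_tokenized(tokenized, out / "tokens.jsonl")
        report["stages"]["preprocess"].update(pre_report)
        if pre_report["n_empty_excluded"]:
            report["warnings"].append(
                f"{pre_report['n_empty_excluded']} post(s) empty after preprocessing; excluded"
            )

    with stage("mine"):
        txns, txn_report = association.build_transactions(tokenized)
        rules = association.mine_rules(
            txns,
            min_support=float(config.get("min_support", association.DEFAULT_MIN_SUPPORT)),
            min_confidence=float(config.get("min_confidence", association.DEFAULT_MIN_CONFIDENCE)),
        )
        association.write_rules(rules, out / "rules.tsv")
        report["stages"]["mine"].update({**txn_report, "n_rules": len(rules)})

    with stage("filter"):
        filtered, filt_report = association.filter_posts(tokenized, rules)
        preprocess.write_tokenized(filtered, out / "filtered.jsonl")
        report["stages"]["filter"].update(filt_report)

    emb_cfg = dict(config.get("embedding", {}))
    with stage("embed"):
        emb = embedding.train_embeddings(
            filtered,
            dim=int(emb_cfg.get("dim", 300)),
            window=int(emb_cfg.get("window", 5)),
            min_count=int(emb_cfg.get("min_count", 1)),
            epochs=int(emb_cfg.get("epochs", 5)),
            negative=int(emb_cfg.get("negative", 5)),
            seed=_stage_seed(master_seed, "embed"),
        )
        embedding.save_word2vec(emb, out / "vectors.txt")
        report["stages"]["embed"].update({"vocab_size": len(emb.vocabulary), "dim": emb.dim})

    with stage("train"):
        labeled = [p for p in filtered if p.label is not None]
        n_unlabeled = len(filtered) - len(labeled)
        model_cfg = ModelConfig(
            embedding_dim=emb.dim,
            seed=_stage_seed(master_seed, "train"),
            **{k: v for k, v in dict(config.get("model", {})).items() if k != "embedding_dim"},
        )
        encoding = build_vocabulary(labeled)
        encoded = encode_and_pad(labeled, encoding, max_len=config.get("max_len", "auto"))
        train_set, test_set = split_train_test(
            encoded, ratio=model_cfg.split_ratio, seed=_stage_seed(master_seed, "split")
        )
        model = train(train_set, model_cfg, encoding, init_vectors=emb)
        save_model(model, out / "model")
        report["stages"]["train"].update(
            {
                "n_labeled": len(labeled),
                "n_unlabeled_dropped": n_unlabeled,
                "n_train": len(train_set),
                "n_test": len(test_set),
                "epochs_run": len(model.training_log),
                "final_loss": model.training_log[-1]["loss"] if model.training_log else None,
            }
        )

    with stage("evaluate"):
        scores = predict_proba(model, test_set)
        y_true = np.array([p.label for p in test_set], dtype=np.int64)
        eval_report = evaluate.evaluation_report(y_true, scores, threshold=model_cfg.threshold)
        if annotators is not None:
            kappa = evaluate.cohens_kappa(annotators[0], annotators[1])
            eval_report["annotator_cohens_kappa"] = kappa
        (out / "evaluation.json").write_text(
            json.dumps(eval_report, indent=2), encoding="utf-8"
        )
        try:
            curve = evaluate.roc(y_true, scores)
            evaluate.plot_roc(curve, out / "roc.png")
        except Exception as exc:  # plotting is best-effort
            report["warnings"].append(f"ROC plot skipped: {exc}")
        report["stages"]["evaluate"].update(
            {
                "auc": eval_report["auc"],
                "accuracy": eval_report["metrics"]["accuracy"],
                "confusion": eval_report["confusion"],
            }
        )

    report["total_seconds"] = round(time.perf_counter() - t_all, 3)
    _check_count_consistency(report)
    _write_report(report, out)
    return report


def _check_count_consistency(report: dict) -> None:
    st = report["stages"]
    filt = st.get("filter", {})
    if filt and filt.get("n_retained", 0) + filt.get("n_dropped", 0) != filt.get("n_input", -1):
        raise AssertionError("filter stage counts are inconsistent")
    pre = st.get("preprocess", {})
    if pre and pre.get("n_kept", 0) + pre.get("n_empty_excluded", 0) != pre.get("n_input", -1):
        raise AssertionError("preprocess stage counts are inconsistent")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2), encoding="utf-8"
    )
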