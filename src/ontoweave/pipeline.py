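"""Pipeline orchestration: validated configuration, staged artifacts, manifest.

Stages chain ``simulate -> apply -> (mv | lm) -> train/export/eval/sweep``;
each stage writes versioned artifacts into the output directory together
with a run manifest recording the config hash, seed, stage timings and
artifact digests.  Re-running with the same config skips up-to-date
artifacts unless forced.  A crashing labeling function is confined to its
label-matrix column (see :func:`~ontoweave.labeling.build_label_matrix`), so
imperfect sources never kill a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import aggregation, endmodel, evaluation, labeling, ontology, synthesis
from .corpus import read_documents_jsonl, read_spans_jsonl, write_documents_jsonl, write_spans_jsonl

logger = logging.getLogger(__name__)

STAGES = ("simulate", "apply", "mv", "lm", "train", "export", "eval", "sweep")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TaskConfig(_Model):
    k: int = 1
    classes: list[str] = ["entity"]


class LabelModelConfig(_Model):
    init_prior: float = 0.7
    max_iter: int = 500
    tol: float = 1e-6
    l2: float = 0.0
    seed: int = 0


class TrainConfig(_Model):
    epochs: int = 150
    lr: float = 0.5
    l2: float = 1e-4


class SimulateConfig(_Model):
    n_docs: int = 50
    sentences_per_doc: int = 5
    vocab_size: int = 300
    lexicon_size: int = 40
    entity_rate: float = 0.8
    accuracies: list[float] = [0.9, 0.75, 0.65, 0.6]
    coverages: list[float] = [0.8, 0.7, 0.6, 0.6]


class PipelineConfig(_Model):
    """Validated before any stage runs; unknown keys are rejected."""

    output_dir: str
    task: TaskConfig = TaskConfig()
    corpus_path: Optional[str] = None
    terminology_paths: list[str] = []
    sty_map_path: Optional[str] = None
    cue_lexicon_path: Optional[str] = None
    gold_spans_path: Optional[str] = None
    partition_s: Optional[int] = None
    include_merged_remainder: bool = True
    sweep_s_values: list[int] = [1, 2, 4]
    label_model: LabelModelConfig = LabelModelConfig()
    train: TrainConfig = TrainConfig()
    tokenizer: str = "default"
    simulate: SimulateConfig = SimulateConfig()

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return PipelineConfig(**(yaml.safe_load(fh) or {}))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Run:
    def __init__(self, cfg: PipelineConfig, seed: int, force: bool):
        self.cfg = cfg
        self.seed = seed
        self.force = force
        self.out = Path(cfg.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
            if self.manifest.get("config_hash") != cfg.config_hash():
                self.manifest = {}
        else:
            self.manifest = {}
        self.manifest.setdefault("config_hash", cfg.config_hash())
        self.manifest.setdefault("seed", seed)
        self.manifest.setdefault("stages", {})

    def up_to_date(self, stage: str, artifacts: Sequence[str]) -> bool:
        if self.force:
            return False
        rec = self.manifest["stages"].get(stage)
        return rec is not None and all((self.out / a).exists() for a in artifacts)

    def record(self, stage: str, artifacts: Sequence[str], elapsed: float) -> None:
        self.manifest["stages"][stage] = {
            "artifacts": {a: _digest(self.out / a) for a in artifacts},
            "seconds": round(elapsed, 3),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def require(self, artifact: str, producing_stage: str) -> Path:
        p = self.out / artifact
        if not p.exists():
            raise FileNotFoundError(
                f"missing artifact {artifact}: run the '{producing_stage}' stage first"
            )
        return p


def run_pipeline(
    cfg: PipelineConfig,
    stages: Sequence[str],
    seed: int = 0,
    force: bool = False,
) -> dict:
    """Run the requested stages in canonical order; returns the manifest."""
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    run = _Run(cfg, seed, force)
    for stage in [s for s in STAGES if s in stages]:
        fn = globals()[f"_stage_{stage}"]
        artifacts = fn(run, dry=True)
        if run.up_to_date(stage, artifacts):
            logger.info("stage %s up to date; skipping", stage)
            continue
        t0 = time.perf_counter()
        fn(run, dry=False)
        run.record(stage, artifacts, time.perf_counter() - t0)
        logger.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)
    return run.manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(run: _Run, dry: bool) -> list[str]:
    arts = ["data/corpus.jsonl", "data/gold_spans.jsonl", "data/sty_map.json"]
    sim = run.cfg.simulate
    n_src = len(sim.accuracies)
    arts += [f"data/terminology_{j}.tsv" for j in range(n_src)]
    if dry:
        return arts
    (run.out / "data").mkdir(exist_ok=True)
    spec = synthesis.CorpusSpec(
        seed=run.seed,
        n_docs=sim.n_docs,
        sentences_per_doc=sim.sentences_per_doc,
        vocab_size=sim.vocab_size,
        lexicon_size=sim.lexicon_size,
        entity_rate=sim.entity_rate,
        k=run.cfg.task.k,
    )
    docs, spans, _tags, lex = synthesis.generate_gold_corpus(spec)
    specs = [
        synthesis.SourceSpec(accuracy=a, coverage=c)
        for a, c in zip(sim.accuracies, sim.coverages)
    ]
    terms = synthesis.generate_terminologies(lex, specs, seed=run.seed + 1, k=run.cfg.task.k)
    write_documents_jsonl(run.out / "data/corpus.jsonl", docs)
    write_spans_jsonl(run.out / "data/gold_spans.jsonl", spans)
    for j, t in enumerate(terms):
        with open(run.out / f"data/terminology_{j}.tsv", "w", encoding="utf-8") as fh:
            for term, vec in sorted(t.terms.items()):
                fh.write(f"{term}\tCLASS_{int(np.argmax(vec))}\n")
    sty_map = {f"CLASS_{c}": c for c in range(run.cfg.task.k + 1)}
    (run.out / "data/sty_map.json").write_text(json.dumps(sty_map))
    return arts


def _load_corpus(run: _Run):
    path = run.cfg.corpus_path or run.require("data/corpus.jsonl", "simulate")
    return read_documents_jsonl(path)


def _load_terminologies(run: _Run) -> list[ontology.Terminology]:
    paths = run.cfg.terminology_paths or sorted(
        str(p) for p in (run.out / "data").glob("terminology_*.tsv")
    )
    if not paths:
        raise FileNotFoundError("no terminologies: configure terminology_paths or run simulate")
    sty_path = run.cfg.sty_map_path or (
        run.out / "data/sty_map.json" if (run.out / "data/sty_map.json").exists() else None
    )
    sty_map = ontology.read_sty_map(sty_path) if sty_path else None
    out = []
    for p in paths:
        raw = ontology.read_term_tsv(p)
        t = ontology.preprocess_terms(raw, name=Path(p).stem, k=run.cfg.task.k)
        if sty_map is not None:
            t = ontology.map_semantic_types(t, sty_map, k=run.cfg.task.k)
        out.append(t)
    return out


def _stage_apply(run: _Run, dry: bool) -> list[str]:
    arts = ["label_matrix.npz"]
    if dry:
        return arts
    corpus = _load_corpus(run)
    terms = _load_terminologies(run)
    ranked = ontology.rank_terminologies(terms, corpus)
    if run.cfg.partition_s is not None:
        sources = ontology.partition_terminologies(
            ranked,
            ontology.PartitionConfig(
                s=run.cfg.partition_s,
                include_merged_remainder=run.cfg.include_merged_remainder,
            ),
        )
    else:
        sources = [t for t, _ in ranked]
    lfs = [labeling.semantic_type_lf(t) for t in sources]
    L = labeling.build_label_matrix(lfs, corpus, k=run.cfg.task.k)
    L.save(run.out / "label_matrix.npz")
    return arts


def _posteriors_to_tsv(post, word_index, path) -> None:
    post.to_frame(word_index).to_csv(path, sep="\t", index=False, float_format="%.6f")


def _stage_mv(run: _Run, dry: bool) -> list[str]:
    arts = ["posteriors_mv.tsv"]
    if dry:
        return arts
    L = labeling.LabelMatrix.load(run.require("label_matrix.npz", "apply"))
    mv = aggregation.majority_vote(L, default_class=aggregation.mv_default_class(L))
    _posteriors_to_tsv(mv, L.word_index, run.out / "posteriors_mv.tsv")
    return arts


def _stage_lm(run: _Run, dry: bool) -> list[str]:
    arts = ["posteriors_lm.tsv", "label_model.json", "label_model_summary.txt"]
    if dry:
        return arts
    lm_cfg = run.cfg.label_model
    L = labeling.LabelMatrix.load(run.require("label_matrix.npz", "apply"))
    res = aggregation.LabelModel(L).fit(
        init_prior=lm_cfg.init_prior, max_iter=lm_cfg.max_iter,
        tol=lm_cfg.tol, l2=lm_cfg.l2, seed=lm_cfg.seed,
    )
    post = res.predict_proba()
    _posteriors_to_tsv(post, L.word_index, run.out / "posteriors_lm.tsv")
    (run.out / "label_model.json").write_text(
        json.dumps(
            {
                "accuracies": res.params.accuracies.tolist(),
                "coverage": res.params.coverage.tolist(),
                "prior": res.params.prior.tolist(),
                "sources": L.source_names,
                "converged": res.converged,
                "n_iter": res.n_iter,
                "loglike": res.loglike,
            },
            indent=2,
        )
    )
    (run.out / "label_model_summary.txt").write_text(res.summary() + "\n")
    return arts


def _load_lm_dataset(run: _Run):
    import pandas as pd

    corpus = _load_corpus(run)
    df = pd.read_csv(run.require("posteriors_lm.tsv", "lm"), sep="\t")
    K = run.cfg.task.k + 1
    probs = df[[f"P{y}" for y in range(K)]].to_numpy()
    post = aggregation.PosteriorLabels(
        probs=probs, hard=df["hard"].to_numpy(), abstain=df["abstain"].to_numpy(dtype=bool)
    )
    return corpus, endmodel.assemble_dataset(corpus, post)


def _stage_train(run: _Run, dry: bool) -> list[str]:
    arts = ["token_classifier.json", "predictions_ws.tsv"]
    if dry:
        return arts
    corpus, data = _load_lm_dataset(run)
    clf = endmodel.train_token_classifier(
        data, epochs=run.cfg.train.epochs, lr=run.cfg.train.lr,
        l2=run.cfg.train.l2, seed=run.seed,
    )
    clf.save(run.out / "token_classifier.json")
    preds = clf.predict_corpus(corpus)
    word_index = [(d.doc_id, w) for d in corpus for w in range(d.n_words)]
    with open(run.out / "predictions_ws.tsv", "w", encoding="utf-8") as fh:
        fh.write("doc_id\tword\tpred\n")
        for (doc_id, w), y in zip(word_index, preds):
            fh.write(f"{doc_id}\t{w}\t{int(y)}\n")
    return arts


def _stage_export(run: _Run, dry: bool) -> list[str]:
    arts = ["probabilistic.conll"]
    if dry:
        return arts
    _, data = _load_lm_dataset(run)
    endmodel.export_probabilistic_conll(data, run.out / "probabilistic.conll")
    return arts


def _stage_eval(run: _Run, dry: bool) -> list[str]:
    arts = ["metrics.json"]
    if dry:
        return arts
    import pandas as pd

    corpus = _load_corpus(run)
    gold_path = run.cfg.gold_spans_path or run.require("data/gold_spans.jsonl", "simulate")
    gold = read_spans_jsonl(gold_path)
    metrics = {}
    for model_name, art in (("mv", "posteriors_mv.tsv"), ("lm", "posteriors_lm.tsv")):
        p = run.out / art
        if not p.exists():
            continue
        hard = pd.read_csv(p, sep="\t")["hard"].to_numpy()
        spans = evaluation.word_predictions_to_spans(corpus, hard)
        metrics[model_name] = evaluation.exact_span_prf(gold, spans).as_dict()
    ws = run.out / "predictions_ws.tsv"
    if ws.exists():
        hard = pd.read_csv(ws, sep="\t")["pred"].to_numpy()
        spans = evaluation.word_predictions_to_spans(corpus, hard)
        metrics["ws"] = evaluation.exact_span_prf(gold, spans).as_dict()
    if not metrics:
        raise FileNotFoundError("no posteriors to evaluate: run the 'mv' or 'lm' stage first")
    (run.out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    return arts


def _stage_sweep(run: _Run, dry: bool) -> list[str]:
    arts = ["sweep.csv"]
    if dry:
        return arts
    corpus = _load_corpus(run)
    gold_path = run.cfg.gold_spans_path or run.require("data/gold_spans.jsonl", "simulate")
    gold = read_spans_jsonl(gold_path)
    terms = _load_terminologies(run)
    ranked = ontology.rank_terminologies(terms, corpus)
    s_values = [s for s in run.cfg.sweep_s_values if s <= len(ranked)]
    table = aggregation.sweep_partitions(
        corpus, [t for t, _ in ranked], [], s_values, gold,
        k=run.cfg.task.k, seed=run.seed,
        init_prior=run.cfg.label_model.init_prior, l2=run.cfg.label_model.l2,
    )
    table.to_csv(run.out / "sweep.csv", index=False)
    return arts
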