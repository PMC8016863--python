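"""Benchmark experiments exercised by the test suite and the acceptance script.

Each function regenerates its inputs from the synthetic generators at the
given seed, runs the relevant part of the pipeline, and measures the result.
The study conditions (source accuracies, coverages, corpus sizes) are fixed
here as module constants; they are the package's reference benchmark
settings, chosen to exercise heterogeneous-quality sources at desk scale.
"""

from __future__ import annotations

import numpy as np

from .aggregation import LabelModel, majority_vote, mv_default_class, estimate_accuracies_triplet, sweep_partitions
from .evaluation import exact_span_prf, word_predictions_to_spans
from .labeling import build_label_matrix, semantic_type_lf
from .ontology import rank_terminologies
from .synthesis import (
    CorpusSpec,
    SourceSpec,
    generate_gold_corpus,
    generate_terminologies,
    gold_word_labels,
    sample_label_matrix,
)

# reference benchmark settings
TRIPLET_TRUTHS = (0.6, 0.7, 0.8, 0.9, 0.95)
GAIN_SOURCES = (0.95, 0.55, 0.55)
E2E_QUALITY = [(0.95, 0.9), (0.85, 0.7), (0.75, 0.6), (0.7, 0.6), (0.65, 0.5), (0.6, 0.5)]
SWEEP_QUALITY = [(0.95, 0.9), (0.7, 0.7), (0.65, 0.6), (0.6, 0.6),
                 (0.6, 0.5), (0.55, 0.5), (0.55, 0.5), (0.55, 0.5)]


def _sub(seed: int, offset: int) -> int:
    return int((seed * 7919 + offset) % (2**31 - 1))


def triplet_recovery_mae(
    seed: int,
    coverage: float = 1.0,
    n: int = 10_000,
    n_seeds: int = 10,
    truths=TRIPLET_TRUTHS,
) -> np.ndarray:
    """Mean absolute triplet-estimation error per source over replicates."""
    errs = np.zeros((n_seeds, len(truths)))
    for r in range(n_seeds):
        rng = np.random.default_rng(_sub(seed, r))
        y = (rng.random(n) < 0.5).astype(int)
        L = sample_label_matrix(y, [SourceSpec(p, coverage) for p in truths],
                                seed=_sub(seed, 100 + r))
        errs[r] = np.abs(estimate_accuracies_triplet(L) - np.asarray(truths))
    return errs.mean(axis=0)


def em_triplet_agreement(seed: int, n: int = 20_000, coverage: float = 0.8,
                         truths=TRIPLET_TRUTHS) -> float:
    """Max elementwise gap between EM and triplet estimates on one matrix."""
    rng = np.random.default_rng(_sub(seed, 1))
    y = (rng.random(n) < 0.5).astype(int)
    L = sample_label_matrix(y, [SourceSpec(p, coverage) for p in truths], seed=_sub(seed, 2))
    em = LabelModel(L).fit().params.accuracies
    trip = estimate_accuracies_triplet(L)
    return float(np.abs(em - trip).max())


def lm_mv_gain(seed: int, n: int = 50_000, sources=GAIN_SOURCES) -> dict:
    """Hard-label accuracy of the label model vs majority vote on a matrix
    with one strong and two weak full-coverage sources, uniform prior."""
    rng = np.random.default_rng(_sub(seed, 3))
    y = (rng.random(n) < 0.5).astype(int)
    L = sample_label_matrix(y, [SourceSpec(p) for p in sources], seed=_sub(seed, 4))
    mv_acc = float((majority_vote(L, default_class=0).hard == y).mean())
    lm = LabelModel(L).fit().predict_proba(default_class=0)
    lm_acc = float((lm.hard == y).mean())
    return {"mv_accuracy": mv_acc, "lm_accuracy": lm_acc, "gain": lm_acc - mv_acc, "n": n}


def end_to_end_recovery(seed: int, n_docs: int = 200) -> dict:
    """Corpus + terminologies -> LFs -> label matrix -> EM accuracies vs the
    LFs' measured word-level accuracies, plus MV/LM exact-span F1."""
    docs, spans, _, lex = generate_gold_corpus(CorpusSpec(seed=_sub(seed, 5), n_docs=n_docs))
    y = gold_word_labels(docs, spans)
    specs = [SourceSpec(a, c) for a, c in E2E_QUALITY]
    terms = generate_terminologies(lex, specs, seed=_sub(seed, 6))
    L = build_label_matrix([semantic_type_lf(t) for t in terms], docs, k=1)
    measured = np.array([
        (L.values[:, j][L.values[:, j] >= 0] == y[L.values[:, j] >= 0]).mean()
        for j in range(L.m)
    ])
    res = LabelModel(L).fit()
    default = mv_default_class(L)
    mv = majority_vote(L, default_class=default)
    lm = res.predict_proba(default_class=default)
    mv_f1 = exact_span_prf(spans, word_predictions_to_spans(docs, mv.hard)).f1
    lm_f1 = exact_span_prf(spans, word_predictions_to_spans(docs, lm.hard)).f1
    return {
        "measured": measured,
        "estimated": res.params.accuracies,
        "max_abs_error": float(np.abs(res.params.accuracies - measured).max()),
        "mv_f1": float(mv_f1),
        "lm_f1": float(lm_f1),
        "n_words": L.n,
    }


def partition_sweep_experiment(seed: int, n_docs: int = 200, s_values=(1, 2, 4, 8)):
    """Rank 8 synthetic terminologies by coverage and sweep the partition
    size; returns the score table and per-s predictions."""
    docs, spans, _, lex = generate_gold_corpus(CorpusSpec(seed=_sub(seed, 7), n_docs=n_docs))
    terms = generate_terminologies(
        lex, [SourceSpec(a, c) for a, c in SWEEP_QUALITY], seed=_sub(seed, 8)
    )
    ranked = rank_terminologies(terms, docs)
    table, details = sweep_partitions(
        docs, [t for t, _ in ranked], [], list(s_values), spans, k=1, return_details=True
    )
    return table, details


def correlation_stress(seed: int, n_seeds: int = 10, n: int = 10_000) -> dict:
    """Label-model accuracy drop when 3 perfectly correlated copies of the
    weakest (0.6) source join an uncorrelated (0.9, 0.7, 0.6) baseline."""
    drops = []
    for r in range(n_seeds):
        rng = np.random.default_rng(_sub(seed, 9 + r))
        y = (rng.random(n) < 0.5).astype(int)
        base = [SourceSpec(0.9), SourceSpec(0.7), SourceSpec(0.6)]
        Lb = sample_label_matrix(y, base, seed=_sub(seed, 50 + r))
        acc_b = (LabelModel(Lb).fit().predict_proba(default_class=0).hard == y).mean()
        dup = base + [SourceSpec(0.6, correlate_with=2, rho=1.0)] * 3
        Lc = sample_label_matrix(y, dup, seed=_sub(seed, 50 + r))
        acc_c = (LabelModel(Lc).fit().predict_proba(default_class=0).hard == y).mean()
        drops.append(float(acc_b - acc_c))
    return {"median_drop": float(np.median(drops)), "drops": drops, "n": n}
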