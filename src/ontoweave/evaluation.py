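"""Exact-span NER metrics and micro-averaged span-attribute metrics.

NER scoring uses exact span matching: a predicted entity counts only if its
document, word boundaries and class all equal a gold span.  Word-level IO
predictions are first converted to BIO by the O-to-I-transition rule before
span extraction, so head-word errors are counted; adjacent same-class IO
entities cannot be split by construction (documented IO limitation).
Span-attribute tasks (e.g. 4-class document-relative time) pool decisions
over all classes before computing precision/recall/F1 (microaveraging).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import Document, EntitySpan, TagSequence, tags_to_spans

__all__ = ["PRFResult", "exact_span_prf", "micro_prf", "word_predictions_to_spans"]


@dataclass(frozen=True)
class PRFResult:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        d = self.true_positives + self.false_positives
        return self.true_positives / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.true_positives + self.false_negatives
        return self.true_positives / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {
            "TP": self.true_positives,
            "FP": self.false_positives,
            "FN": self.false_negatives,
            "P": self.precision,
            "R": self.recall,
            "F1": self.f1,
        }


def _check_no_overlap(spans: Sequence[EntitySpan], which: str) -> None:
    by_doc: dict[str, list[EntitySpan]] = {}
    for s in spans:
        by_doc.setdefault(s.doc_id, []).append(s)
    for doc_id, ss in by_doc.items():
        ss = sorted(ss, key=lambda s: s.start_word)
        for a, b in zip(ss, ss[1:]):
            if b.start_word < a.end_word:
                raise ValueError(f"overlapping {which} spans in {doc_id}: {a} / {b}")


def exact_span_prf(gold: Sequence[EntitySpan], pred: Sequence[EntitySpan]) -> PRFResult:
    """Exact-match span scoring on (doc_id, start, end, class) identity."""
    _check_no_overlap(gold, "gold")
    _check_no_overlap(pred, "predicted")
    key = lambda s: (s.doc_id, s.start_word, s.end_word, s.class_label)
    gold_set = {key(s) for s in gold}
    pred_set = {key(s) for s in pred}
    tp = len(gold_set & pred_set)
    return PRFResult(tp, len(pred_set) - tp, len(gold_set) - tp)


def micro_prf(gold_labels: Sequence[int], pred_labels: Sequence[int],
              classes: Sequence[int]) -> PRFResult:
    """Micro-averaged multiclass P/R/F1: per-class TP/FP/FN pooled over all
    listed classes before computing the ratios.  Over all classes this
    reduces to pooled accuracy-style counts."""
    if len(gold_labels) != len(pred_labels):
        raise ValueError(
            f"length mismatch: {len(gold_labels)} gold vs {len(pred_labels)} predicted"
        )
    gold_arr = np.asarray(gold_labels)
    pred_arr = np.asarray(pred_labels)
    tp = fp = fn = 0
    for c in classes:
        tp += int(((gold_arr == c) & (pred_arr == c)).sum())
        fp += int(((gold_arr != c) & (pred_arr == c)).sum())
        fn += int(((gold_arr == c) & (pred_arr != c)).sum())
    return PRFResult(tp, fp, fn)


def word_predictions_to_spans(
    corpus: Sequence[Document], hard_labels: np.ndarray
) -> list[EntitySpan]:
    """Decode corpus-ordered word class predictions (0 = outside) into entity
    spans via IO tags and the transition rule."""
    spans: list[EntitySpan] = []
    pos = 0
    for doc in corpus:
        labels = hard_labels[pos : pos + doc.n_words]
        pos += doc.n_words
        tags = ["O" if int(y) == 0 else f"I-{int(y)}" for y in labels]
        # IO entities must not cross sentence boundaries
        doc_spans = []
        for lo, hi in doc.sentence_bounds():
            seq = TagSequence(doc.doc_id, tags[lo:hi], "IO", max(int(labels.max(initial=1)), 1))
            for sp in tags_to_spans(seq):
                doc_spans.append(
                    EntitySpan(doc.doc_id, sp.start_word + lo, sp.end_word + lo,
                               sp.class_label, provenance="prediction")
                )
        spans.extend(doc_spans)
    if pos != len(hard_labels):
        raise ValueError(f"{len(hard_labels)} labels for {pos} corpus words")
    return spans
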