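"""Noise-aware training on probabilistic labels.

The label model's word posteriors are regrouped into sentence sequences with
an abstain mask (:class:`ProbabilisticSequenceDataset`).  Training minimizes
the noise-aware loss: the expected cross-entropy under the probabilistic
label distribution, with masked (all-sources-abstained) words contributing
exactly zero.  The discriminative model here is a linear token classifier
over sparse lexical features (word identity, casing/shape, affixes,
neighbors within a window of 2) — a deliberately lightweight stand-in that
exercises the loss, masking and dataset plumbing end to end and can
generalize beyond the labeling sources; heavyweight contextual encoders
train externally on the exported probabilistic CoNLL file.
"""

from __future__ import annotations

import base64
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.special import logsumexp

from .corpus import Document
from .aggregation import PosteriorLabels

logger = logging.getLogger(__name__)

_CLIP = 1e-12

__all__ = [
    "SequenceExample",
    "ProbabilisticSequenceDataset",
    "assemble_dataset",
    "noise_aware_loss",
    "noise_aware_loss_and_grad",
    "TokenClassifier",
    "train_token_classifier",
    "export_probabilistic_conll",
    "read_probabilistic_conll",
]


@dataclass
class SequenceExample:
    doc_id: str
    tokens: list[str]
    probs: np.ndarray  # (T, k+1) per-word class distributions
    mask: np.ndarray  # (T,) bool, True = excluded from the loss (all abstained)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.probs.shape[0] != len(self.tokens) or self.mask.shape[0] != len(self.tokens):
            raise ValueError("sequence example shapes disagree")


@dataclass
class ProbabilisticSequenceDataset:
    """Sentence sequences with per-word class distributions and abstain mask."""

    sequences: list[SequenceExample]
    k: int

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_words(self) -> int:
        return sum(len(s.tokens) for s in self.sequences)

    @property
    def n_unmasked(self) -> int:
        return int(sum((~s.mask).sum() for s in self.sequences))


def assemble_dataset(
    corpus: Sequence[Document], posteriors: PosteriorLabels
) -> ProbabilisticSequenceDataset:
    """Regroup corpus-ordered word posteriors into sentence sequences; words
    on which every source abstained are masked out of any loss."""
    n_words = sum(d.n_words for d in corpus)
    if len(posteriors) != n_words:
        raise ValueError(
            f"posterior rows ({len(posteriors)}) do not align with corpus words "
            f"({n_words}); first offending row is {min(len(posteriors), n_words)}"
        )
    k = posteriors.probs.shape[1] - 1
    seqs: list[SequenceExample] = []
    pos = 0
    for doc in corpus:
        for sent in doc.sentences:
            T = len(sent)
            seqs.append(
                SequenceExample(
                    doc_id=doc.doc_id,
                    tokens=sent.surfaces(),
                    probs=posteriors.probs[pos : pos + T].copy(),
                    mask=posteriors.abstain[pos : pos + T].copy(),
                )
            )
            pos += T
    return ProbabilisticSequenceDataset(sequences=seqs, k=k)


# ---------------------------------------------------------------------------
# noise-aware loss
# ---------------------------------------------------------------------------


def noise_aware_loss(
    pred_dists: np.ndarray, target_dists: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Mean over unmasked words of the expected cross-entropy
    E_{y ~ target}[-log pred(y)] = -sum_y target(y) log pred(y).

    One-hot targets reduce exactly to standard cross-entropy; masked words
    contribute exactly 0 regardless of their target values.  Zero predicted
    probability on a supported class is clipped at 1e-12 with a warning.
    """
    pred = np.asarray(pred_dists, dtype=float)
    tgt = np.asarray(target_dists, dtype=float)
    if pred.shape != tgt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {tgt.shape}")
    keep = np.ones(pred.shape[0], dtype=bool) if mask is None else ~np.asarray(mask, dtype=bool)
    if not keep.any():
        return 0.0
    p, t = pred[keep], tgt[keep]
    if ((p <= 0) & (t > 0)).any():
        warnings.warn("zero predicted probability on a supported class; clipping at 1e-12")
    return float(-(t * np.log(np.clip(p, _CLIP, None))).sum(axis=1).mean())


def noise_aware_loss_and_grad(
    logits: np.ndarray, target_dists: np.ndarray, mask: Optional[np.ndarray] = None
) -> tuple[float, np.ndarray]:
    """Loss as above with predictions parameterized by logits (softmax), plus
    the analytic gradient with respect to the logits: (softmax - target) / n
    on unmasked rows and exactly zero on masked rows."""
    logits = np.asarray(logits, dtype=float)
    tgt = np.asarray(target_dists, dtype=float)
    keep = np.ones(logits.shape[0], dtype=bool) if mask is None else ~np.asarray(mask, dtype=bool)
    grad = np.zeros_like(logits)
    if not keep.any():
        return 0.0, grad
    z = logits[keep]
    lse = logsumexp(z, axis=1)
    logp = z - lse[:, None]
    n = int(keep.sum())
    loss = float(-(tgt[keep] * logp).sum() / n)
    grad[keep] = (np.exp(logp) - tgt[keep]) / n
    return loss, grad


# ---------------------------------------------------------------------------
# linear token classifier
# ---------------------------------------------------------------------------


def _shape(word: str) -> str:
    return "".join("X" if c.isupper() else "x" if c.islower() else "d" if c.isdigit() else c
                   for c in word)[:8]


def token_features(tokens: Sequence[str], i: int) -> list[str]:
    """Sparse lexical features: identity, shape/casing, affixes up to length
    3, and neighboring word identities within a window of 2."""
    w = tokens[i]
    low = w.lower()
    feats = [
        f"w={low}",
        f"shape={_shape(w)}",
        f"suf1={low[-1:]}",
        f"suf2={low[-2:]}",
        f"suf3={low[-3:]}",
        f"pre2={low[:2]}",
        f"pre3={low[:3]}",
    ]
    if w.isupper():
        feats.append("allcaps")
    if w.istitle():
        feats.append("title")
    if w.isdigit():
        feats.append("digit")
    for off in (-2, -1, 1, 2):
        j = i + off
        feats.append(f"w[{off}]={tokens[j].lower()}" if 0 <= j < len(tokens) else f"w[{off}]=<pad>")
    return feats


@dataclass
class TokenClassifier:
    """Linear softmax token classifier; prediction is deterministic given the
    parameter matrix and input."""

    feature_index: dict[str, int]
    weights: np.ndarray  # (n_features, k+1)
    k: int

    def _featurize(self, sentences: Sequence[Sequence[str]]) -> sparse.csr_matrix:
        rows, cols = [], []
        r = 0
        for toks in sentences:
            for i in range(len(toks)):
                for f in token_features(toks, i):
                    j = self.feature_index.get(f)
                    if j is not None:
                        rows.append(r)
                        cols.append(j)
                r += 1
        return sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(r, len(self.feature_index))
        )

    def decision_scores(self, sentences: Sequence[Sequence[str]]) -> np.ndarray:
        return self._featurize(sentences) @ self.weights

    def predict(self, sentences: Sequence[Sequence[str]]) -> np.ndarray:
        return self.decision_scores(sentences).argmax(axis=1)

    def predict_proba(self, sentences: Sequence[Sequence[str]]) -> np.ndarray:
        z = self.decision_scores(sentences)
        return np.exp(z - logsumexp(z, axis=1)[:, None])

    def predict_corpus(self, corpus: Sequence[Document]) -> np.ndarray:
        return self.predict([s.surfaces() for d in corpus for s in d.sentences])

    def save(self, path) -> None:
        blob = base64.b64encode(self.weights.astype(np.float64).tobytes()).decode()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "format": "ontoweave-token-classifier/1",
                    "k": self.k,
                    "n_features": self.weights.shape[0],
                    "features": list(self.feature_index),
                    "weights_b64": blob,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "TokenClassifier":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        w = np.frombuffer(base64.b64decode(obj["weights_b64"]), dtype=np.float64)
        w = w.reshape(obj["n_features"], obj["k"] + 1).copy()
        return cls(
            feature_index={f: i for i, f in enumerate(obj["features"])},
            weights=w,
            k=obj["k"],
        )


def train_token_classifier(
    data: ProbabilisticSequenceDataset,
    epochs: int = 150,
    lr: float = 0.5,
    l2: float = 1e-4,
    seed: int = 0,
) -> TokenClassifier:
    """Full-batch gradient descent on the noise-aware loss plus an L2 penalty.

    Weights start at zero, so the fit is deterministic at any seed (the seed
    argument is kept for interface compatibility with stochastic trainers).
    """
    if data.n_unmasked == 0:
        raise ValueError("all words are masked; nothing to train on")
    feature_index: dict[str, int] = {}
    for seq in data.sequences:
        for i in range(len(seq.tokens)):
            for f in token_features(seq.tokens, i):
                feature_index.setdefault(f, len(feature_index))
    clf = TokenClassifier(
        feature_index=feature_index,
        weights=np.zeros((len(feature_index), data.k + 1)),
        k=data.k,
    )
    X = clf._featurize([s.tokens for s in data.sequences])
    T = np.concatenate([s.probs for s in data.sequences], axis=0)
    mask = np.concatenate([s.mask for s in data.sequences], axis=0)
    for _ in range(epochs):
        logits = X @ clf.weights
        _, g_logits = noise_aware_loss_and_grad(logits, T, mask)
        grad = X.T @ g_logits + l2 * clf.weights
        clf.weights -= lr * grad
    return clf


# ---------------------------------------------------------------------------
# probabilistic CoNLL export
# ---------------------------------------------------------------------------


def export_probabilistic_conll(data: ProbabilisticSequenceDataset, path) -> None:
    """Columns ``token<TAB>mask<TAB>P(0)..P(k)`` (6 decimals), blank line
    between sentences, ``-DOCSTART- <doc_id>`` between documents; the
    training-data interchange format for external contextual models."""
    with open(path, "w", encoding="utf-8") as fh:
        last_doc = None
        for seq in data.sequences:
            if seq.doc_id != last_doc:
                fh.write(f"-DOCSTART- {seq.doc_id}\n\n")
                last_doc = seq.doc_id
            for tok, p, m in zip(seq.tokens, seq.probs, seq.mask):
                probs = "\t".join(f"{v:.6f}" for v in p)
                fh.write(f"{tok}\t{int(m)}\t{probs}\n")
            fh.write("\n")


def read_probabilistic_conll(path) -> ProbabilisticSequenceDataset:
    seqs: list[SequenceExample] = []
    doc_id = "doc"
    tokens: list[str] = []
    probs: list[list[float]] = []
    mask: list[bool] = []

    def flush():
        nonlocal tokens, probs, mask
        if tokens:
            seqs.append(
                SequenceExample(doc_id, tokens, np.array(probs), np.array(mask, dtype=bool))
            )
        tokens, probs, mask = [], [], []

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("-DOCSTART-"):
                flush()
                doc_id = line.split(maxsplit=1)[1] if " " in line else "doc"
            elif not line.strip():
                flush()
            else:
                parts = line.split("\t")
                tokens.append(parts[0])
                mask.append(bool(int(parts[1])))
                probs.append([float(v) for v in parts[2:]])
    flush()
    k = seqs[0].probs.shape[1] - 1 if seqs else 0
    return ProbabilisticSequenceDataset(sequences=seqs, k=k)
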