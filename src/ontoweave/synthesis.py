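"""Synthetic benchmarks: corpora with planted entities, imperfect
terminologies, and directly sampled label matrices.

Every stage of the pipeline is testable without licensed ontologies or
gated corpora: :func:`generate_gold_corpus` plants gold entity spans drawn
from a generated multi-word lexicon into background sentences;
:func:`generate_terminologies` derives label sources of controlled accuracy
and coverage from that lexicon (including both positive entity terms and
negative background terms, so induced labeling functions vote both classes
and source accuracies are identifiable from agreements); and
:func:`sample_label_matrix` samples votes directly from the label model's
own generative assumptions with known source parameters, optionally with
correlated source pairs that deliberately violate the independence
assumption.  All randomness flows through one explicit seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus import Document, EntitySpan, Sentence, TagSequence, Token, spans_to_tags
from .labeling import LabelMatrix
from .ontology import Terminology

ABSTAIN = -1

__all__ = [
    "SourceSpec",
    "CorpusSpec",
    "GoldLexicon",
    "generate_gold_corpus",
    "generate_terminologies",
    "sample_label_matrix",
]


@dataclass(frozen=True)
class SourceSpec:
    """Quality knobs for one synthetic label source.

    ``accuracy``: probability a vote is correct given the source votes;
    ``coverage``: probability the source votes on an item (for terminology
    generation: the probability a term/word enters the term list);
    ``correlate_with``/``rho``: optional partner source whose per-item
    outcomes are copied with probability rho (rho=1 duplicates the source).
    """

    accuracy: float
    coverage: float = 1.0
    correlate_with: Optional[int] = None
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.accuracy < 1.0:
            raise ValueError("accuracy must be in (0, 1)")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")


@dataclass
class CorpusSpec:
    """Shape of a synthetic corpus; the seed is mandatory."""

    seed: int
    n_docs: int = 50
    vocab_size: int = 300
    lexicon_size: int = 40
    entity_vocab_size: int = 60
    sentences_per_doc: int = 5
    mean_sentence_len: float = 9.0
    min_sentence_len: int = 4
    entity_rate: float = 0.8  # expected planted entities per sentence
    entity_len_probs: tuple = (0.45, 0.40, 0.15)  # P(term has 1, 2, 3 words)
    k: int = 1

    def __post_init__(self) -> None:
        if self.entity_rate < 0 or abs(sum(self.entity_len_probs) - 1.0) > 1e-9:
            raise ValueError("invalid rates in corpus spec")
        if len(self.entity_len_probs) > self.min_sentence_len:
            raise ValueError(
                "impossible spec: maximum entity length exceeds the minimum sentence length"
            )


@dataclass
class GoldLexicon:
    """Generated entity surface forms: term word-tuples with class labels."""

    terms: dict[tuple, int]  # word tuple -> class in 1..k
    background_vocab: list[str]
    entity_vocab: list[str]

    def term_strings(self) -> dict[str, int]:
        return {" ".join(t): c for t, c in self.terms.items()}


def _make_lexicon(spec: CorpusSpec, rng: np.random.Generator) -> GoldLexicon:
    background = [f"bkg{i:03d}" for i in range(spec.vocab_size)]
    entity = [f"ent{i:03d}" for i in range(spec.entity_vocab_size)]
    lengths = 1 + rng.choice(len(spec.entity_len_probs), size=spec.lexicon_size,
                             p=spec.entity_len_probs)
    terms: dict[tuple, int] = {}
    while len(terms) < spec.lexicon_size:
        L = int(lengths[len(terms) % len(lengths)])
        words = tuple(entity[i] for i in rng.choice(len(entity), size=L, replace=False))
        if words not in terms:
            terms[words] = 1 + int(rng.integers(spec.k))
    return GoldLexicon(terms=terms, background_vocab=background, entity_vocab=entity)


def generate_gold_corpus(
    spec: CorpusSpec,
) -> tuple[list[Document], list[EntitySpan], list[TagSequence], GoldLexicon]:
    """Plant gold entities into background sentences.

    Background and entity vocabularies are disjoint, so gold word labels are
    exact: words inside planted spans carry the term's class, all others are
    outside (class 0).  Deterministic at a fixed seed; gold BIO tags are
    derived from the planted spans.
    """
    rng = np.random.default_rng(spec.seed)
    lex = _make_lexicon(spec, rng)
    term_list = list(lex.terms.items())
    docs: list[Document] = []
    all_spans: list[EntitySpan] = []
    all_tags: list[TagSequence] = []
    for d in range(spec.n_docs):
        sentences: list[Sentence] = []
        doc_spans: list[tuple[int, int, int]] = []  # word-index spans
        parts: list[str] = []
        char = 0
        word_pos = 0
        for _ in range(spec.sentences_per_doc):
            L = max(spec.min_sentence_len, int(rng.poisson(spec.mean_sentence_len)))
            words = [lex.background_vocab[i] for i in rng.integers(0, spec.vocab_size, size=L)]
            n_ent = int(rng.poisson(spec.entity_rate)) if spec.entity_rate > 0 else 0
            local_spans: list[tuple[int, int, int]] = []
            for _ in range(n_ent):
                words_t, cls = term_list[int(rng.integers(len(term_list)))]
                # never splice inside an already-planted entity
                candidates = [
                    p for p in range(len(words) + 1)
                    if all(not (s < p < e) for s, e, _ in local_spans)
                ]
                pos = candidates[int(rng.integers(len(candidates)))]
                words[pos:pos] = list(words_t)
                local_spans = [
                    (s + len(words_t), e + len(words_t), c) if s >= pos else (s, e, c)
                    for (s, e, c) in local_spans
                ]
                local_spans.append((pos, pos + len(words_t), cls))
            doc_spans.extend((word_pos + s, word_pos + e, c) for s, e, c in local_spans)
            tokens = []
            for w in words:
                tokens.append(Token(w, char, char + len(w)))
                char += len(w) + 1
            parts.append(" ".join(words))
            char += 1  # the second newline of the blank-line separator
            sentences.append(Sentence(tokens))
            word_pos += len(words)
        text = "\n\n".join(parts)
        doc = Document(doc_id=f"synth{d:04d}", text=text, sentences=sentences)
        doc.validate()
        spans = [
            EntitySpan(doc.doc_id, s, e, c, provenance="gold")
            for s, e, c in sorted(doc_spans)
        ]
        docs.append(doc)
        all_spans.extend(spans)
        all_tags.append(spans_to_tags(doc, spans, scheme="BIO"))
    return docs, all_spans, all_tags, lex


def gold_word_labels(docs: Sequence[Document], spans: Sequence[EntitySpan]) -> np.ndarray:
    """Corpus-ordered word class labels (0 = outside) implied by gold spans."""
    offsets: dict[str, int] = {}
    pos = 0
    for d in docs:
        offsets[d.doc_id] = pos
        pos += d.n_words
    labels = np.zeros(pos, dtype=np.int64)
    for sp in spans:
        o = offsets[sp.doc_id]
        labels[o + sp.start_word : o + sp.end_word] = sp.class_label
    return labels


def generate_terminologies(
    gold_lexicon: GoldLexicon,
    specs: Sequence[SourceSpec],
    seed: int,
    k: int = 1,
    name_prefix: str = "synth_term",
) -> list[Terminology]:
    """Derive imperfect terminologies from the gold lexicon.

    Source j includes each gold term with probability ``coverage`` and labels
    it with its true class with probability ``accuracy`` (otherwise a wrong
    class — class 0 for binary tasks); it likewise includes each background
    word with probability ``coverage`` as a negative (class 0) term, wrong
    with probability 1 - ``accuracy`` (a class-1..k false positive).  The
    induced dictionary LF therefore votes on both entity and background
    words with word-level accuracy approximately ``accuracy`` and matching
    coverage.  Correlated pairs copy the partner's per-item outcome with
    probability rho.
    """
    if not specs:
        raise ValueError("no source specs given")
    rng = np.random.default_rng(seed)
    items = [(" ".join(t), cls) for t, cls in gold_lexicon.terms.items()]
    items += [(w, 0) for w in gold_lexicon.background_vocab]
    n_items = len(items)
    decisions: list[tuple[np.ndarray, np.ndarray]] = []  # (included, assigned class)
    for spec in specs:
        include = rng.random(n_items) < spec.coverage
        correct = rng.random(n_items) < spec.accuracy
        wrong_cls = np.empty(n_items, dtype=np.int64)
        for i, (_, cls) in enumerate(items):
            others = [c for c in range(k + 1) if c != cls]
            wrong_cls[i] = others[int(rng.integers(len(others)))]
        assigned = np.where(correct, [c for _, c in items], wrong_cls)
        if spec.correlate_with is not None:
            p_inc, p_cls = decisions[spec.correlate_with]
            copy = rng.random(n_items) < spec.rho
            include = np.where(copy, p_inc, include)
            assigned = np.where(copy, p_cls, assigned)
        decisions.append((include, assigned))
    out = []
    for j, (include, assigned) in enumerate(decisions):
        terms = {}
        for i, (term, _) in enumerate(items):
            if include[i]:
                vec = np.zeros(k + 1)
                vec[int(assigned[i])] = 1.0
                terms[term] = vec
        if not terms:  # degenerate draw; keep the source non-empty
            vec = np.zeros(k + 1)
            vec[items[0][1]] = 1.0
            terms[items[0][0]] = vec
        out.append(Terminology(name=f"{name_prefix}_{j}", terms=terms, k=k))
    return out


def sample_label_matrix(
    true_labels: np.ndarray,
    specs: Sequence[SourceSpec],
    seed: int,
    k: int = 1,
) -> LabelMatrix:
    """Sample votes directly from the label model's generative assumptions.

    Each entry abstains with probability 1 - coverage; otherwise it equals
    the true label with probability ``accuracy`` and is uniform over the
    wrong classes with the remainder.  Correlated pairs copy the partner's
    realized entry with probability rho.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(true_labels, dtype=np.int64)
    n = len(y)
    cols = []
    for spec in specs:
        votes = np.full(n, ABSTAIN, dtype=np.int16)
        voting = rng.random(n) < spec.coverage
        correct = rng.random(n) < spec.accuracy
        offset = rng.integers(1, k + 1, size=n)  # uniform over the k wrong classes
        wrong = (y + offset) % (k + 1)
        votes[voting & correct] = y[voting & correct]
        votes[voting & ~correct] = wrong[voting & ~correct]
        if spec.correlate_with is not None:
            copy = rng.random(n) < spec.rho
            votes = np.where(copy, cols[spec.correlate_with], votes).astype(np.int16)
        cols.append(votes)
    return LabelMatrix(
        values=np.stack(cols, axis=1),
        word_index=[("sim", i) for i in range(n)],
        source_names=[f"sim_src_{j}" for j in range(len(specs))],
        k=k,
    )
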