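"""Terminology ingestion, preprocessing, class mapping, ranking, partitioning.

A terminology (one source vocabulary, e.g. a single UMLS source or ChEBI) is
preprocessed into a set of normalized terms, each carrying a probability
vector over target entity classes derived from its semantic-type (STY)
assignments.  Terminologies are ranked by term coverage on an unlabeled
corpus and partitioned into the top-``s`` individual label sources plus one
merged remainder, which is how a large metathesaurus becomes a tractable set
of labeling functions.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._stopwords import ENGLISH_STOPWORDS, load_stopwords

logger = logging.getLogger(__name__)

__all__ = [
    "Terminology",
    "SynsetCollection",
    "BigramGraph",
    "PartitionConfig",
    "normalize_term",
    "preprocess_terms",
    "map_semantic_types",
    "rank_terminologies",
    "partition_terminologies",
    "build_bigram_graph",
    "read_term_tsv",
    "read_synset_tsv",
    "read_sty_map",
    "read_umls_rrf",
]

ABSTAIN = -1


@dataclass
class Terminology:
    """A preprocessed term set; one label source.

    ``terms`` maps each normalized term string to a probability vector of
    length k+1 over classes 0..k.  Terms in ``case_sensitive_terms`` are
    matched verbatim (abbreviation preservation); all others are stored
    lowercased and matched case-insensitively.
    """

    name: str
    terms: dict[str, np.ndarray]
    k: int
    case_sensitive_terms: set[str] = field(default_factory=set)
    term_stys: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, v in self.terms.items():
            if not t:
                raise ValueError(f"{self.name}: empty term string")
            if len(t) == 1:
                raise ValueError(f"{self.name}: single-character term {t!r}")
            v = np.asarray(v, dtype=float)
            if v.shape != (self.k + 1,) or (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: bad probability vector for {t!r}")
            self.terms[t] = v

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def max_term_tokens(self) -> int:
        return max((len(t.split()) for t in self.terms), default=0)


@dataclass
class SynsetCollection:
    """Bidirectional concept-id <-> synonym maps (e.g. CUI synsets)."""

    concept_to_terms: dict[str, set[str]]
    term_to_concepts: dict[str, set[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SynsetCollection":
        c2t: dict[str, set[str]] = {}
        t2c: dict[str, set[str]] = {}
        for cid, term in pairs:
            c2t.setdefault(cid, set()).add(term)
            t2c.setdefault(term, set()).add(cid)
        return cls(c2t, t2c)

    def validate(self) -> None:
        for cid, terms in self.concept_to_terms.items():
            for t in terms:
                if cid not in self.term_to_concepts.get(t, set()):
                    raise ValueError(f"inconsistent synset maps at ({cid}, {t})")
        for t, cids in self.term_to_concepts.items():
            for cid in cids:
                if t not in self.concept_to_terms.get(cid, set()):
                    raise ValueError(f"inconsistent synset maps at ({cid}, {t})")


@dataclass
class BigramGraph:
    """Adjacent word pairs harvested from multi-word terms (lowercased)."""

    pairs: set[tuple[str, str]]
    vocabulary: set[str]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return (pair[0].lower(), pair[1].lower()) in self.pairs


@dataclass
class PartitionConfig:
    s: int = 1
    include_merged_remainder: bool = True

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("partition size s must be >= 1")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

_NUMBER_RE = re.compile(r"[\d.,%/+-]+")


def _abbreviation_like(token: str, abbrev_max_len: int) -> bool:
    # all-caps short forms (DMD) or internal capitals within a word (pH, mmHg)
    if token.isupper() and any(c.isalpha() for c in token) and len(token) <= abbrev_max_len:
        return True
    return any(c.isupper() for c in token[1:]) and not token.isupper()


def normalize_term(term: str, abbrev_max_len: int = 5) -> tuple[str, bool]:
    """Case-normalization heuristic preserving abbreviations.

    Returns ``(normalized, case_sensitive)``: the term is lowercased unless
    any of its tokens looks like an abbreviation (all-uppercase of length <=
    ``abbrev_max_len``, or mixed case with internal capitals), in which case
    it is kept verbatim and flagged for case-sensitive matching.
    """
    term = " ".join(term.split())
    if any(_abbreviation_like(tok, abbrev_max_len) for tok in term.split()):
        return term, True
    return term.lower(), False


def preprocess_terms(
    raw_terms: Sequence[tuple[str, Optional[str]]],
    stopwords: Optional[frozenset] = None,
    *,
    name: str = "terminology",
    abbrev_max_len: int = 5,
    k: int = 1,
    default_class: int = 1,
) -> Terminology:
    """Filter and normalize a raw ``(term, semantic_type)`` list.

    Stopwords, pure-number terms and single-character terms are removed;
    letter case is normalized by :func:`normalize_term`.  Every surviving
    term is provisionally assigned ``default_class`` with probability 1
    (the single-class convention for non-typed ontologies); use
    :func:`map_semantic_types` to derive class vectors from the collected
    STY assignments.
    """
    if not raw_terms:
        raise ValueError("raw term list is empty")
    stopwords = ENGLISH_STOPWORDS if stopwords is None else stopwords
    terms: dict[str, np.ndarray] = {}
    cs: set[str] = set()
    stys: dict[str, list[str]] = {}
    onehot = np.zeros(k + 1)
    onehot[default_class] = 1.0
    for raw, sty in raw_terms:
        norm, case_sensitive = normalize_term(raw, abbrev_max_len)
        if not norm or len(norm) == 1:
            continue
        if norm.lower() in stopwords:
            continue
        if _NUMBER_RE.fullmatch(norm) and any(c.isdigit() for c in norm):
            continue
        terms[norm] = onehot.copy()
        if case_sensitive:
            cs.add(norm)
        if sty is not None:
            stys.setdefault(norm, [])
            if sty not in stys[norm]:
                stys[norm].append(sty)
    if not terms:
        raise ValueError(f"{name}: terminology empty after filtering")
    return Terminology(name=name, terms=terms, k=k, case_sensitive_terms=cs, term_stys=stys)


def map_semantic_types(
    terminology: Terminology,
    sty_to_class: dict[str, object],
    k: int,
    default: Optional[object] = None,
) -> Terminology:
    """Derive per-term class probability vectors from STY assignments.

    Each term's vector is the normalized count of its STYs' class
    assignments; terms whose STYs all map to abstain are dropped.  Terms
    without any STY keep a single-class assignment to ``default`` (which may
    also be "abstain" to drop them).  Unknown STYs with no default raise.
    """
    unknown = sorted(
        {s for stys in terminology.term_stys.values() for s in stys if s not in sty_to_class}
    )
    if unknown and default is None:
        raise ValueError(f"unmapped semantic types: {', '.join(unknown)}")
    terms: dict[str, np.ndarray] = {}
    stys_out: dict[str, list[str]] = {}
    for term in terminology.terms:
        stys = terminology.term_stys.get(term, [])
        votes = [sty_to_class.get(s, default) for s in stys] if stys else [default]
        counts = np.zeros(k + 1)
        for v in votes:
            if v == "abstain" or v is None:
                continue
            counts[int(v)] += 1
        if counts.sum() == 0:
            continue
        terms[term] = counts / counts.sum()
        if stys:
            stys_out[term] = list(stys)
    if not terms:
        raise ValueError(f"{terminology.name}: terminology empty after STY mapping")
    return Terminology(
        name=terminology.name,
        terms=terms,
        k=k,
        case_sensitive_terms={t for t in terminology.case_sensitive_terms if t in terms},
        term_stys=stys_out,
    )


# ---------------------------------------------------------------------------
# ranking and partitioning
# ---------------------------------------------------------------------------


def rank_terminologies(
    terminologies: Sequence[Terminology], corpus: Sequence
) -> list[tuple[Terminology, int]]:
    """Rank by term coverage: each term's document frequency (number of corpus
    documents in which the term occurs as a longest match), summed over the
    terminology; descending score, ties broken by terminology name."""
    from .labeling import find_terminology_matches  # local import avoids a cycle

    if not corpus:
        raise ValueError("corpus is empty")
    scores = []
    for term in terminologies:
        df: dict[str, int] = {}
        for doc in corpus:
            matched = {m.term for m in find_terminology_matches(doc, term)}
            for t in matched:
                df[t] = df.get(t, 0) + 1
        scores.append((term, sum(df.values())))
    return sorted(scores, key=lambda ts: (-ts[1], ts[0].name))


def partition_terminologies(
    ranked: Sequence[Terminology] | Sequence[tuple[Terminology, int]],
    cfg: PartitionConfig,
) -> list[Terminology]:
    """Top-``s`` terminologies as individual sources plus, when enabled and
    non-empty, one merged-remainder source whose per-term class vectors are
    averaged across the contributing terminologies."""
    terms_only = [t[0] if isinstance(t, tuple) else t for t in ranked]
    if cfg.s > len(terms_only):
        raise ValueError(f"s={cfg.s} exceeds number of terminologies ({len(terms_only)})")
    top = list(terms_only[: cfg.s])
    rest = terms_only[cfg.s :]
    if not cfg.include_merged_remainder or not rest:
        return top
    return top + [merge_terminologies(rest, name="merged_remainder")]


def merge_terminologies(parts: Sequence[Terminology], name: str) -> Terminology:
    k = parts[0].k
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    cs: set[str] = set()
    stys: dict[str, list[str]] = {}
    for t in parts:
        if t.k != k:
            raise ValueError("cannot merge terminologies with differing k")
        for term, vec in t.terms.items():
            if term in sums:
                sums[term] = sums[term] + vec
                counts[term] += 1
            else:
                sums[term] = vec.copy()
                counts[term] = 1
        cs |= t.case_sensitive_terms
        for term, ss in t.term_stys.items():
            cur = stys.setdefault(term, [])
            cur.extend(s for s in ss if s not in cur)
    terms = {term: sums[term] / counts[term] for term in sums}
    return Terminology(
        name=name, terms=terms, k=k, case_sensitive_terms=cs & set(terms), term_stys=stys
    )


def build_bigram_graph(terminologies: Sequence[Terminology]) -> BigramGraph:
    """Adjacent word pairs of all multi-word terms (post-preprocessing)."""
    pairs: set[tuple[str, str]] = set()
    vocab: set[str] = set()
    for term in terminologies:
        for t in term.terms:
            words = t.lower().split()
            for a, b in zip(words, words[1:]):
                pairs.add((a, b))
                vocab.update((a, b))
    if not pairs:
        raise ValueError("no multi-word terms: bigram graph is empty")
    return BigramGraph(pairs=pairs, vocabulary=vocab)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_term_tsv(path) -> list[tuple[str, Optional[str]]]:
    """Term lists as TSV ``term<TAB>semantic_type`` (STY column optional;
    repeat rows to assign multiple STYs)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            out.append((parts[0], parts[1] if len(parts) > 1 and parts[1] else None))
    return out


def read_synset_tsv(path) -> SynsetCollection:
    """Synsets as TSV ``concept_id<TAB>term``."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cid, term = line.split("\t")[:2]
            pairs.append((cid, term))
    return SynsetCollection.from_pairs(pairs)


def read_sty_map(path) -> dict[str, object]:
    """STY-to-class map as YAML or JSON ``{sty: class | "abstain"}``."""
    text = open(path, encoding="utf-8").read()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        import yaml

        return yaml.safe_load(text)


def read_umls_rrf(
    mrconso_path,
    mrsty_path,
    language: str = "ENG",
    min_terms: int = 500,
) -> tuple[dict[str, list[tuple[str, str]]], SynsetCollection]:
    """Optional reader for the pipe-delimited MRCONSO/MRSTY dialect.

    Returns raw ``(term, sty)`` lists per source vocabulary (SAB), dropping
    vocabularies with fewer than ``min_terms`` terms, plus CUI synsets.
    Suppressible-term flags are ignored by design: term-type metadata is not
    generally available outside this dialect, and sources are treated as
    plug-and-play.  License-gated data; never required by tests.
    """
    cui_stys: dict[str, list[str]] = {}
    with open(mrsty_path, encoding="utf-8") as fh:
        for line in fh:
            f = line.rstrip("\n").split("|")
            if len(f) > 3:
                cui_stys.setdefault(f[0], []).append(f[3])
    by_sab: dict[str, list[tuple[str, str]]] = {}
    synset_pairs: list[tuple[str, str]] = []
    with open(mrconso_path, encoding="utf-8") as fh:
        for line in fh:
            f = line.rstrip("\n").split("|")
            if len(f) < 15 or f[1] != language:
                continue
            cui, sab, term = f[0], f[11], f[14]
            if not term:
                continue
            for sty in cui_stys.get(cui, [None]):
                by_sab.setdefault(sab, []).append((term, sty))
            synset_pairs.append((cui, term))
    kept = {sab: rows for sab, rows in by_sab.items() if len({t for t, _ in rows}) >= min_terms}
    dropped = sorted(set(by_sab) - set(kept))
    if dropped:
        logger.info("dropped %d sources under %d terms: %s", len(dropped), min_terms, dropped)
    return kept, SynsetCollection.from_pairs(synset_pairs)
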