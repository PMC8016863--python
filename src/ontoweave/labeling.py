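"""Labeling functions: the imperfect label sources combined by the label model.

A labeling function (LF) maps a document to one integer vote per word (word
scope), or one vote per pre-identified entity span (span scope), in the
domain {-1, 0, .., k} where -1 means abstain.  Templates here turn
terminologies, synsets, bigram graphs, regexes, dictionaries, context-window
cues, datetime distances and section headers into LFs with no custom coding.
Applying a list of LFs over a corpus yields the label matrix (rows = words or
spans, columns = sources) that drives accuracy estimation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Callable, Optional, Sequence

import numpy as np

from .corpus import Document, EntitySpan
from .ontology import BigramGraph, SynsetCollection, Terminology, normalize_term

logger = logging.getLogger(__name__)

ABSTAIN = -1

__all__ = [
    "ABSTAIN",
    "LabelingFunction",
    "LabelMatrix",
    "TermMatch",
    "find_terminology_matches",
    "semantic_type_lf",
    "synset_lf",
    "SHPair",
    "schwartz_hearst_pairs",
    "regex_lf",
    "dict_lf",
    "fuzzy_bigram_lf",
    "context_window_lf",
    "datetime_distance_lf",
    "section_header_lf",
    "build_label_matrix",
    "read_cue_lexicon",
]


class LabelingFunction:
    """One label source: ``name``, ``scope`` ('word' | 'span') and an emit
    procedure.  Word scope: ``fn(doc) -> votes[n_words]``.  Span scope:
    ``fn(doc, spans) -> votes[n_spans]``."""

    def __init__(self, name: str, scope: str, fn: Callable):
        if scope not in ("word", "span"):
            raise ValueError(f"unknown scope {scope!r}")
        self.name = name
        self.scope = scope
        self._fn = fn

    def __call__(self, doc: Document, spans: Optional[Sequence[EntitySpan]] = None) -> np.ndarray:
        if self.scope == "word":
            votes = np.asarray(self._fn(doc), dtype=np.int16)
            expected = doc.n_words
        else:
            if spans is None:
                raise ValueError(f"span-scope LF {self.name} requires target spans")
            votes = np.asarray(self._fn(doc, spans), dtype=np.int16)
            expected = len(spans)
        if votes.shape != (expected,):
            raise ValueError(f"LF {self.name}: expected {expected} votes, got {votes.shape}")
        return votes

    def __repr__(self) -> str:
        return f"LabelingFunction({self.name!r}, scope={self.scope!r})"


@dataclass
class LabelMatrix:
    """Votes over {-1, 0..k}: rows are words (or spans), columns are sources."""

    values: np.ndarray  # (n, m) int
    word_index: list[tuple[str, int]]  # row -> (doc_id, word or span position)
    source_names: list[str]
    k: int
    mode: str = "word"  # "word" | "span"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.word_index):
            raise ValueError("label matrix shape inconsistent with word index")
        if self.values.shape[1] != len(self.source_names):
            raise ValueError("label matrix shape inconsistent with source names")
        if self.values.size and (self.values.min() < -1 or self.values.max() > self.k):
            raise ValueError(f"votes outside {{-1, 0..{self.k}}}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def digest(self) -> str:
        h = hashlib.sha256(self.values.tobytes())
        h.update(json.dumps([self.source_names, self.k, self.mode]).encode())
        h.update(json.dumps(self.word_index).encode())
        return h.hexdigest()

    def save(self, path) -> None:
        meta = {
            "source_names": self.source_names,
            "k": self.k,
            "mode": self.mode,
            "word_index": [list(t) for t in self.word_index],
        }
        np.savez_compressed(path, values=self.values, meta=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "LabelMatrix":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(
                values=z["values"],
                word_index=[(d, int(i)) for d, i in meta["word_index"]],
                source_names=meta["source_names"],
                k=meta["k"],
                mode=meta["mode"],
            )


# ---------------------------------------------------------------------------
# terminology matching (greedy longest match)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermMatch:
    term: str
    start_word: int  # document-scoped
    end_word: int
    vector: tuple  # class probability vector


class _TermIndex:
    """Token-tuple lookup: case-sensitive terms verbatim, the rest lowercased."""

    def __init__(self, terminology: Terminology):
        self.ci: dict[tuple, tuple[str, np.ndarray]] = {}
        self.cs: dict[tuple, tuple[str, np.ndarray]] = {}
        for term, vec in terminology.terms.items():
            toks = tuple(term.split())
            if term in terminology.case_sensitive_terms:
                self.cs[toks] = (term, vec)
            else:
                self.ci[tuple(t.lower() for t in toks)] = (term, vec)
        self.max_len = max((len(t) for t in (*self.ci, *self.cs)), default=0)

    def lookup(self, surfaces: Sequence[str]):
        hit = self.cs.get(tuple(surfaces))
        if hit is None:
            hit = self.ci.get(tuple(s.lower() for s in surfaces))
        return hit


def _greedy_matches(index: _TermIndex, doc: Document) -> list[TermMatch]:
    matches: list[TermMatch] = []
    offset = 0
    for sent in doc.sentences:
        surfaces = sent.surfaces()
        i = 0
        while i < len(surfaces):
            hit = None
            for L in range(min(index.max_len, len(surfaces) - i), 0, -1):
                hit = index.lookup(surfaces[i : i + L])
                if hit is not None:
                    term, vec = hit
                    matches.append(TermMatch(term, offset + i, offset + i + L, tuple(vec)))
                    i += L
                    break
            if hit is None:
                i += 1
        offset += len(surfaces)
    return matches


def find_terminology_matches(doc: Document, terminology: Terminology) -> list[TermMatch]:
    """All longest-term matches (token length, left-to-right, non-overlapping)."""
    return _greedy_matches(_TermIndex(terminology), doc)


def _vote_from_vector(vec: np.ndarray) -> int:
    """Most probable class; abstain on ties."""
    vec = np.asarray(vec)
    top = vec.max()
    if (vec >= top - 1e-12).sum() > 1:
        return ABSTAIN
    return int(vec.argmax())


# ---------------------------------------------------------------------------
# ontology-based LF templates
# ---------------------------------------------------------------------------


def semantic_type_lf(
    term_source: Terminology, slot_patterns: Sequence[str] = ()
) -> LabelingFunction:
    """Dictionary LF from a semantic-typed terminology.

    Greedy longest-match scan; matched words are voted the term's most
    probable class, abstaining on vector ties; all other words abstain.
    ``slot_patterns`` may contain ``"{*} ({*})"`` to merge compositional
    mentions like ``Tylenol (Acetaminophen)`` into a single match.
    """
    if not len(term_source):
        raise ValueError(f"{term_source.name}: empty terminology")
    index = _TermIndex(term_source)
    merge_paren = "{*} ({*})" in slot_patterns

    def fn(doc: Document) -> np.ndarray:
        votes = np.full(doc.n_words, ABSTAIN, dtype=np.int16)
        matches = _greedy_matches(index, doc)
        if merge_paren:
            matches = _merge_paren_matches(matches, doc)
        for m in matches:
            votes[m.start_word : m.end_word] = _vote_from_vector(np.asarray(m.vector))
        return votes

    return LabelingFunction(f"sty:{term_source.name}", "word", fn)


def _merge_paren_matches(matches: list[TermMatch], doc: Document) -> list[TermMatch]:
    """Fuse ``A ( B )`` where A and B are both matches into one match."""
    words = doc.words()
    by_start = {m.start_word: m for m in matches}
    merged: list[TermMatch] = []
    used: set[int] = set()
    for m in matches:
        if m.start_word in used:
            continue
        o = m.end_word
        inner = by_start.get(o + 1)
        if (
            o + 1 < len(words)
            and words[o] == "("
            and inner is not None
            and inner.end_word < len(words)
            and words[inner.end_word] == ")"
        ):
            vec = (np.asarray(m.vector) + np.asarray(inner.vector)) / 2.0
            merged.append(TermMatch(f"{m.term} ({inner.term})", m.start_word,
                                    inner.end_word + 1, tuple(vec)))
            used.add(inner.start_word)
        else:
            merged.append(m)
    return merged


def synset_lf(
    synsets: SynsetCollection,
    term_source: Terminology,
    use_schwartz_hearst: bool = False,
    name: str = "synset",
) -> LabelingFunction:
    """Synonym-evidence LF: votes only when more than one distinct synonym of
    the same concept occurs in a document, then labels every occurrence of
    those synonyms with the concept's class (from ``term_source`` vectors).

    With ``use_schwartz_hearst``, short forms licensed by an in-document
    ``LONG (SHORT)`` definition whose long form is in the dictionary are
    voted even when the short form itself is out-of-dictionary.
    """
    norm_to_concepts: dict[str, set[str]] = {}
    syn_terms: dict[str, np.ndarray] = {}
    dummy = np.zeros(term_source.k + 1)
    dummy[-1] = 1.0
    for term, cids in synsets.term_to_concepts.items():
        norm, _ = normalize_term(term)
        if len(norm) < 2:
            continue
        norm_to_concepts.setdefault(norm, set()).update(cids)
        syn_terms[norm] = dummy  # placeholder vector; class comes from term_source
    syn_index = _TermIndex(
        Terminology(name=f"_syn_{name}", terms=syn_terms, k=term_source.k)
    )

    def concept_class(cid: str) -> int:
        vecs = []
        for t in synsets.concept_to_terms.get(cid, ()):
            norm, _ = normalize_term(t)
            if norm in term_source.terms:
                vecs.append(term_source.terms[norm])
        if not vecs:
            return ABSTAIN
        return _vote_from_vector(np.mean(vecs, axis=0))

    def fn(doc: Document) -> np.ndarray:
        votes = np.full(doc.n_words, ABSTAIN, dtype=np.int16)
        matches = _greedy_matches(syn_index, doc)
        by_concept: dict[str, list[TermMatch]] = {}
        for m in matches:
            for cid in norm_to_concepts.get(m.term, ()):
                by_concept.setdefault(cid, []).append(m)
        candidate: dict[int, set[int]] = {}  # word -> candidate votes
        for cid, ms in by_concept.items():
            if len({m.term for m in ms}) < 2:
                continue
            cls = concept_class(cid)
            if cls == ABSTAIN:
                continue
            for m in ms:
                for w in range(m.start_word, m.end_word):
                    candidate.setdefault(w, set()).add(cls)
        if use_schwartz_hearst:
            for pair in schwartz_hearst_pairs(doc):
                long_norm, _ = normalize_term(pair.long_form)
                if long_norm not in term_source.terms:
                    continue
                cls = _vote_from_vector(term_source.terms[long_norm])
                if cls == ABSTAIN:
                    continue
                words = doc.words()
                sf_len = pair.short_words[1] - pair.short_words[0]
                sf = words[pair.short_words[0] : pair.short_words[1]]
                for w0 in range(doc.n_words - sf_len + 1):
                    if words[w0 : w0 + sf_len] == sf:
                        for w in range(w0, w0 + sf_len):
                            candidate.setdefault(w, set()).add(cls)
                for w in range(*pair.long_words):
                    candidate.setdefault(w, set()).add(cls)
        for w, classes in candidate.items():
            if len(classes) == 1:  # conflicting concepts abstain
                votes[w] = classes.pop()
        return votes

    return LabelingFunction(f"synset:{name}", "word", fn)


# ---------------------------------------------------------------------------
# Schwartz-Hearst abbreviation pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SHPair:
    short_form: str
    long_form: str
    short_words: tuple[int, int]  # document-scoped word range of the short form
    long_words: tuple[int, int]


def _best_long_form(short: str, candidate: str) -> Optional[str]:
    """Right-to-left character alignment of the short form into the candidate
    long form; the first character of the short form must start a word."""
    i, j = len(short) - 1, len(candidate) - 1
    while i >= 0:
        c = short[i].lower()
        if not c.isalnum():
            i -= 1
            continue
        while j >= 0 and (
            candidate[j].lower() != c
            or (i == 0 and j > 0 and candidate[j - 1].isalnum())
        ):
            j -= 1
        if j < 0:
            return None
        i -= 1
        j -= 1
    start = candidate.rfind(" ", 0, j + 1) + 1
    return candidate[start:]


def schwartz_hearst_pairs(doc: Document) -> list[SHPair]:
    """Deterministic ``LONG (SHORT)`` definition-pair extraction.

    Candidate short forms are parenthesized, 2-10 characters, at most two
    tokens, contain a letter and start alphanumeric; the long-form window is
    ``min(|short|+5, 2*|short|)`` preceding words in the same sentence.
    """
    pairs: list[SHPair] = []
    offset = 0
    for sent in doc.sentences:
        toks = sent.tokens
        n = len(toks)
        for i, tok in enumerate(toks):
            if tok.surface != "(":
                continue
            close = next((j for j in range(i + 1, min(i + 4, n)) if toks[j].surface == ")"), None)
            if close is None or close == i + 1 or close - i - 1 > 2:
                continue
            short = " ".join(t.surface for t in toks[i + 1 : close])
            if not (2 <= len(short) <= 10 and any(c.isalpha() for c in short)
                    and short[0].isalnum()):
                continue
            max_words = min(len(short) + 5, 2 * len(short))
            lo = max(0, i - max_words)
            candidate = " ".join(t.surface for t in toks[lo:i])
            best = _best_long_form(short, candidate)
            if not best or len(best) <= len(short) or best.lower() == short.lower():
                continue
            n_long = len(best.split())
            pairs.append(
                SHPair(
                    short_form=short,
                    long_form=best,
                    short_words=(offset + i + 1, offset + close),
                    long_words=(offset + i - n_long, offset + i),
                )
            )
        offset += n
    return pairs


# ---------------------------------------------------------------------------
# pattern / dictionary / fuzzy templates
# ---------------------------------------------------------------------------


def regex_lf(name: str, patterns: Sequence[str], vote: int, flags: int = re.IGNORECASE) -> LabelingFunction:
    """Words covered by any regex match (over the raw text) receive ``vote``."""
    try:
        compiled = [re.compile(p, flags) for p in patterns]
    except re.error as e:
        raise ValueError(f"LF {name}: invalid regex: {e}") from e

    def fn(doc: Document) -> np.ndarray:
        votes = np.full(doc.n_words, ABSTAIN, dtype=np.int16)
        toks = doc.tokens()
        for pat in compiled:
            for m in pat.finditer(doc.text):
                for w, t in enumerate(toks):
                    if t.start < m.end() and m.start() < t.end:
                        votes[w] = vote
        return votes

    return LabelingFunction(name, "word", fn)


def dict_lf(name: str, terms: set[str], vote: int) -> LabelingFunction:
    """Small-dictionary LF (longest match, case-insensitive); supports
    negative-class dictionaries such as punctuation, numbers and stopwords
    voting class 0."""
    by_len: dict[tuple, None] = {tuple(t.lower().split()): None for t in terms if t.strip()}
    max_len = max((len(t) for t in by_len), default=0)

    def fn(doc: Document) -> np.ndarray:
        votes = np.full(doc.n_words, ABSTAIN, dtype=np.int16)
        offset = 0
        for sent in doc.sentences:
            low = [t.lower() for t in sent.surfaces()]
            i = 0
            while i < len(low):
                hit_len = 0
                for L in range(min(max_len, len(low) - i), 0, -1):
                    if tuple(low[i : i + L]) in by_len:
                        hit_len = L
                        break
                if hit_len:
                    votes[offset + i : offset + i + hit_len] = vote
                    i += hit_len
                else:
                    i += 1
            offset += len(low)
        return votes

    return LabelingFunction(name, "word", fn)


def fuzzy_bigram_lf(graph: BigramGraph, vote: int, min_len: int = 2,
                    name: str = "fuzzy_bigram") -> LabelingFunction:
    """Votes on maximal word runs (length >= ``min_len``) whose every adjacent
    pair occurs in the ontology bigram co-occurrence graph."""
    if not graph.pairs:
        raise ValueError("bigram graph is empty")

    def fn(doc: Document) -> np.ndarray:
        votes = np.full(doc.n_words, ABSTAIN, dtype=np.int16)
        offset = 0
        for sent in doc.sentences:
            low = [t.lower() for t in sent.surfaces()]
            run_start = 0
            for i in range(len(low)):
                linked = i + 1 < len(low) and (low[i], low[i + 1]) in graph.pairs
                if not linked:
                    if i + 1 - run_start >= min_len:
                        votes[offset + run_start : offset + i + 1] = vote
                    run_start = i + 1
            offset += len(low)
        return votes

    return LabelingFunction(name, "word", fn)


# ---------------------------------------------------------------------------
# span-scope cue LFs
# ---------------------------------------------------------------------------


def read_cue_lexicon(path) -> list[tuple[str, str, int, int]]:
    """Cue lexicon TSV: ``phrase<TAB>direction<TAB>max_distance<TAB>vote``."""
    cues = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            phrase, direction, dist, vote = line.split("\t")
            cues.append((phrase, direction, int(dist), int(vote)))
    return cues


def default_negation_cues() -> list[tuple[str, str, int, int]]:
    """The packaged seed NegEx-style negation cue lexicon (vote 1 = negated);
    copy and edit ``data/negation_cues.tsv`` to customize."""
    from importlib.resources import files

    return read_cue_lexicon(files("ontoweave").joinpath("data/negation_cues.tsv"))


def context_window_lf(
    cues: Sequence[tuple[str, str, int, int]], name: str = "context_window"
) -> LabelingFunction:
    """NegEx/ConText-style cue search in directional windows around a target
    span (token distance, within the sentence).  The nearest matching cue
    wins; conflicting votes at equal distance abstain."""
    parsed = []
    for phrase, direction, max_dist, vote in cues:
        if direction not in ("left", "right"):
            raise ValueError(f"cue direction must be left|right, got {direction!r}")
        parsed.append((tuple(phrase.lower().split()), direction, max_dist, vote))

    def fn(doc: Document, spans: Sequence[EntitySpan]) -> np.ndarray:
        votes = np.full(len(spans), ABSTAIN, dtype=np.int16)
        low = [w.lower() for w in doc.words()]
        bounds = doc.sentence_bounds()
        sent_of = doc.word_sentence_index()
        for si, sp in enumerate(spans):
            if sp.end_word > len(low):
                raise ValueError(f"span {sp} outside document {doc.doc_id}")
            s_lo, s_hi = bounds[sent_of[sp.start_word]]
            best: dict[int, set[int]] = {}
            for phrase, direction, max_dist, vote in parsed:
                L = len(phrase)
                if direction == "left":
                    starts = range(max(s_lo, sp.start_word - max_dist - L), sp.start_word - L + 1)
                else:
                    starts = range(sp.end_word, min(s_hi, sp.end_word + max_dist + L) - L + 1)
                for c0 in starts:
                    if tuple(low[c0 : c0 + L]) != phrase:
                        continue
                    dist = sp.start_word - (c0 + L) if direction == "left" else c0 - sp.end_word
                    if 0 <= dist <= max_dist:
                        best.setdefault(dist, set()).add(vote)
            if best:
                nearest = best[min(best)]
                if len(nearest) == 1:
                    votes[si] = nearest.pop()
        return votes

    return LabelingFunction(name, "span", fn)


_MONTHS = {
    m.lower(): i + 1
    for i, m in enumerate(
        ["January", "February", "March", "April", "May", "June", "July",
         "August", "September", "October", "November", "December"]
    )
}
_MONTHS.update({m[:3]: n for m, n in list(_MONTHS.items())})

_DATE_PATTERNS = [
    (re.compile(r"\b(\d{4})-(\d{2})-(\d{2})\b"), "iso"),
    (re.compile(r"\b(\d{1,2})/(\d{1,2})/(\d{2,4})\b"), "mdy"),
    (re.compile(
        r"\b(January|February|March|April|May|June|July|August|September|"
        r"October|November|December|Jan|Feb|Mar|Apr|Jun|Jul|Aug|Sep|Oct|Nov|Dec)"
        r"\.?\s+(\d{1,2})\s*,?\s+(\d{4})\b", re.IGNORECASE), "month_name"),
    (re.compile(r"\b(\d+)\s+(day|week|month|year)s?\s+ago\b", re.IGNORECASE), "relative"),
]


def _resolve_date(kind: str, m: re.Match, anchor: Optional[datetime]) -> Optional[datetime]:
    try:
        if kind == "iso":
            return datetime(int(m.group(1)), int(m.group(2)), int(m.group(3)))
        if kind == "mdy":
            y = int(m.group(3))
            y += 2000 if y < 50 else (1900 if y < 100 else 0)
            return datetime(y, int(m.group(1)), int(m.group(2)))
        if kind == "month_name":
            return datetime(int(m.group(3)), _MONTHS[m.group(1).lower()[:3]], int(m.group(2)))
        if kind == "relative":
            if anchor is None:
                return None
            n, unit = int(m.group(1)), m.group(2).lower()
            days = {"day": 1, "week": 7, "month": 30, "year": 365}[unit] * n
            return anchor - timedelta(days=days)
    except (ValueError, KeyError):
        return None
    return None


def datetime_distance_lf(
    vote_map: Optional[dict[str, int]] = None, name: str = "datetime_distance"
) -> LabelingFunction:
    """Document-relative time heuristic: each target span is voted by the
    nearest explicit datetime mention (token distance).  A mention resolving
    strictly before the document timestamp votes BEFORE, strictly after votes
    AFTER, the same calendar day votes OVERLAP; equidistant mentions or
    unresolvable anchors abstain.

    ``vote_map`` maps {"before", "after", "overlap"} to class integers
    (defaults 1, 2, 3; class 0 left for the remaining task class).
    """
    vm = vote_map or {"before": 1, "after": 2, "overlap": 3}

    def fn(doc: Document, spans: Sequence[EntitySpan]) -> np.ndarray:
        votes = np.full(len(spans), ABSTAIN, dtype=np.int16)
        anchor = doc.parsed_timestamp()
        if anchor is None:
            return votes
        toks = doc.tokens()
        mentions = []  # (word_start, word_end, resolved datetime)
        for pat, kind in _DATE_PATTERNS:
            for m in pat.finditer(doc.text):
                resolved = _resolve_date(kind, m, anchor)
                if resolved is None:
                    continue
                ws = [w for w, t in enumerate(toks) if t.start < m.end() and m.start() < t.end]
                if ws:
                    mentions.append((min(ws), max(ws) + 1, resolved))
        for si, sp in enumerate(spans):
            if not mentions:
                break
            dists = []
            for w0, w1, when in mentions:
                if w1 <= sp.start_word:
                    d = sp.start_word - w1
                elif w0 >= sp.end_word:
                    d = w0 - sp.end_word
                else:
                    d = 0
                dists.append((d, when))
            dmin = min(d for d, _ in dists)
            nearest = [when for d, when in dists if d == dmin]
            if len(nearest) > 1:
                continue  # equidistant mentions: abstain
            when = nearest[0]
            if when.date() == anchor.date():
                votes[si] = vm["overlap"]
            elif when < anchor:
                votes[si] = vm["before"]
            else:
                votes[si] = vm["after"]
        return votes

    return LabelingFunction(name, "span", fn)


def section_header_lf(
    header_votes: dict[str, int], name: str = "section_header"
) -> LabelingFunction:
    """Votes the configured class for spans falling inside matching document
    sections (e.g. "past medical history" -> BEFORE)."""
    norm = {h.strip().rstrip(":").lower(): v for h, v in header_votes.items()}

    def fn(doc: Document, spans: Sequence[EntitySpan]) -> np.ndarray:
        votes = np.full(len(spans), ABSTAIN, dtype=np.int16)
        if not doc.section_spans:
            return votes
        toks = doc.tokens()
        for si, sp in enumerate(spans):
            c0 = toks[sp.start_word].start
            for header, lo, hi in doc.section_spans:
                if lo <= c0 < hi:
                    for key, vote in norm.items():
                        if key in header:
                            votes[si] = vote
                    break
        return votes

    return LabelingFunction(name, "span", fn)


# ---------------------------------------------------------------------------
# label-matrix construction
# ---------------------------------------------------------------------------


def build_label_matrix(
    lfs: Sequence[LabelingFunction],
    corpus: Sequence[Document],
    k: int,
    spans: Optional[Sequence[EntitySpan]] = None,
) -> LabelMatrix:
    """Apply every LF over the corpus: column j is LF j in corpus order.

    All LFs must share one scope; word and span rows never mix.  A crashing
    LF never kills the run: its column is filled with abstain and the error
    is logged (fault isolation for imperfect sources).
    """
    scopes = {lf.scope for lf in lfs}
    if len(scopes) > 1:
        raise ValueError("cannot mix word-scope and span-scope LFs in one matrix")
    scope = scopes.pop() if scopes else "word"
    if scope == "span" and spans is None:
        raise ValueError("span-scope LFs require target spans")

    if scope == "word":
        word_index = [(d.doc_id, w) for d in corpus for w in range(d.n_words)]
        n = len(word_index)
    else:
        by_doc: dict[str, list[EntitySpan]] = {}
        for sp in spans:
            by_doc.setdefault(sp.doc_id, []).append(sp)
        word_index = [(sp.doc_id, i) for d in corpus for i, sp in enumerate(by_doc.get(d.doc_id, []))]
        n = len(word_index)

    values = np.full((n, len(lfs)), ABSTAIN, dtype=np.int16)
    for j, lf in enumerate(lfs):
        try:
            cols = []
            for d in corpus:
                if scope == "word":
                    cols.append(lf(d))
                else:
                    cols.append(lf(d, by_doc.get(d.doc_id, [])))
            col = np.concatenate(cols) if cols else np.zeros(0, dtype=np.int16)
            if col.min(initial=-1) < -1 or col.max(initial=-1) > k:
                raise ValueError(f"votes outside {{-1..{k}}}")
            values[:, j] = col
        except Exception:
            logger.exception("LF %s failed; column set to abstain", lf.name)
            values[:, j] = ABSTAIN
    return LabelMatrix(
        values=values,
        word_index=word_index,
        source_names=[lf.name for lf in lfs],
        k=k,
        mode=scope,
    )
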