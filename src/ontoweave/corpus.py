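"""Document containers, rule-based tokenization, tagging schemes, and standard I/O.

A :class:`Document` is the unit of weak supervision: a tokenized text whose
words are addressed by a single flat, document-scoped 0-based index so that
label-matrix rows map one-to-one onto words.  Character offsets are 0-based
half-open and always round-trip: ``text[tok.start:tok.end] == tok.surface``.

Entity annotations live either as word-index spans (:class:`EntitySpan`) or as
per-word tag sequences (:class:`TagSequence`) in the IO or BIO scheme; the two
encodings interconvert with :func:`spans_to_tags` / :func:`tags_to_spans`.
"""

from __future__ import annotations

import json
import logging
import re
import string
from dataclasses import dataclass, field
from datetime import datetime
from typing import Callable, Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "Sentence",
    "Document",
    "EntitySpan",
    "TagSequence",
    "TokenizerConfig",
    "tokenize",
    "spans_to_tags",
    "tags_to_spans",
    "read_documents_jsonl",
    "write_documents_jsonl",
    "read_spans_jsonl",
    "write_spans_jsonl",
    "read_conll",
    "write_conll",
]


@dataclass(frozen=True)
class Token:
    surface: str
    start: int  # character offset, 0-based inclusive
    end: int  # character offset, exclusive

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad token offsets ({self.start},{self.end})")


@dataclass
class Sentence:
    """Ordered, non-overlapping tokens of one sentence."""

    tokens: list[Token]

    def __len__(self) -> int:
        return len(self.tokens)

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


@dataclass
class Document:
    """A tokenized document; the sequence X_i fed to labeling functions.

    ``timestamp`` (ISO-8601) anchors document-relative time heuristics;
    ``section_spans`` holds ``(header_name, char_start, char_end)`` triples
    found by the section detector.
    """

    doc_id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)
    timestamp: Optional[str] = None
    section_spans: Optional[list[tuple[str, int, int]]] = None

    @property
    def n_words(self) -> int:
        return sum(len(s) for s in self.sentences)

    def words(self) -> list[str]:
        return [t.surface for s in self.sentences for t in s.tokens]

    def tokens(self) -> list[Token]:
        return [t for s in self.sentences for t in s.tokens]

    def sentence_bounds(self) -> list[tuple[int, int]]:
        """Word-index half-open range of each sentence."""
        out, pos = [], 0
        for s in self.sentences:
            out.append((pos, pos + len(s)))
            pos += len(s)
        return out

    def word_sentence_index(self) -> list[int]:
        out = []
        for i, s in enumerate(self.sentences):
            out.extend([i] * len(s))
        return out

    def validate(self) -> None:
        prev_end = -1
        for tok in self.tokens():
            if tok.start < prev_end:
                raise ValueError(f"{self.doc_id}: overlapping/unordered token at {tok}")
            if self.text[tok.start : tok.end] != tok.surface:
                raise ValueError(
                    f"{self.doc_id}: token {tok.surface!r} does not round-trip "
                    f"to text[{tok.start}:{tok.end}]"
                )
            prev_end = tok.end

    def parsed_timestamp(self) -> Optional[datetime]:
        if self.timestamp is None:
            return None
        try:
            return datetime.fromisoformat(self.timestamp)
        except ValueError:
            logger.warning("%s: unparseable timestamp %r", self.doc_id, self.timestamp)
            return None


@dataclass(frozen=True)
class EntitySpan:
    """A word-index entity span; class_label in 1..k, 0 is reserved for outside."""

    doc_id: str
    start_word: int
    end_word: int  # exclusive
    class_label: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start_word < self.end_word):
            raise ValueError(f"bad span ({self.start_word},{self.end_word})")
        if self.class_label < 1:
            raise ValueError("class_label must be >= 1 (0 means outside)")


@dataclass
class TagSequence:
    """Per-word scheme symbols for one document: 'O', 'I-<c>' and (BIO) 'B-<c>'."""

    doc_id: str
    tags: list[str]
    scheme: str  # "IO" | "BIO"
    k: int

    def __post_init__(self) -> None:
        if self.scheme not in ("IO", "BIO"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

_PUNCT = set(string.punctuation)
# sentence break: terminal [.!?] run followed by whitespace+capital, or blank line
_SENT_BREAK = re.compile(r"([.!?]+)([ \t]*\n[ \t]*\n|\s+(?=[A-Z]))|(\n[ \t]*\n)")


@dataclass
class TokenizerConfig:
    """Rule-based default tokenizer: whitespace split, peel edge punctuation,
    keep internal hyphens/digits/periods; sentence break on terminal [.!?]
    before whitespace+capital, or on a blank line.  Swap in an external
    biomedical pipeline by passing any ``(text) -> Document``-shaped callable
    where tokenization is pluggable."""

    section_headers: Sequence[str] = ()  # regexes matched line-initially, case-insensitive


def _sentence_ranges(text: str) -> list[tuple[int, int]]:
    ranges: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BREAK.finditer(text):
        end = m.end(1) if m.group(1) else m.start(3)
        if text[start:end].strip():
            ranges.append((start, end))
        start = m.end()
    if text[start:].strip():
        ranges.append((start, len(text)))
    return ranges


def _tokenize_range(text: str, start: int, end: int) -> list[Token]:
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text[start:end]):
        lo, hi = start + m.start(), start + m.end()
        # peel leading punctuation characters as single-char tokens
        while lo < hi and text[lo] in _PUNCT:
            tokens.append(Token(text[lo], lo, lo + 1))
            lo += 1
        # find trailing punctuation run (kept for after the core token)
        trail = hi
        while trail > lo and text[trail - 1] in _PUNCT:
            trail -= 1
        if trail > lo:
            tokens.append(Token(text[lo:trail], lo, trail))
        for i in range(trail, hi):
            tokens.append(Token(text[i], i, i + 1))
    return tokens


def _detect_sections(text: str, header_patterns: Sequence[str]) -> list[tuple[str, int, int]]:
    """Each matched line-initial header opens a section that runs to the next
    header (or end of text)."""
    if not header_patterns:
        return []
    pat = re.compile(
        "|".join(f"(?:{p})" for p in header_patterns), re.IGNORECASE | re.MULTILINE
    )
    hits = [(m.group(0), m.start()) for m in pat.finditer(text) if _line_initial(text, m.start())]
    spans = []
    for i, (name, pos) in enumerate(hits):
        end = hits[i + 1][1] if i + 1 < len(hits) else len(text)
        spans.append((name.strip().rstrip(":").lower(), pos, end))
    return spans


def _line_initial(text: str, pos: int) -> bool:
    j = pos
    while j > 0 and text[j - 1] in " \t":
        j -= 1
    return j == 0 or text[j - 1] == "\n"


def tokenize(
    text: str,
    config: Optional[TokenizerConfig] = None,
    doc_id: str = "doc",
    timestamp: Optional[str] = None,
) -> Document:
    """Deterministic rule-based segmentation; offsets reconstruct ``text``.

    Empty (or whitespace-only) text yields a document with zero sentences.
    """
    config = config or TokenizerConfig()
    sentences = [
        Sentence(_tokenize_range(text, lo, hi)) for lo, hi in _sentence_ranges(text)
    ]
    sentences = [s for s in sentences if s.tokens]
    doc = Document(
        doc_id=doc_id,
        text=text,
        sentences=sentences,
        timestamp=timestamp,
        section_spans=_detect_sections(text, config.section_headers) or None,
    )
    doc.validate()
    return doc


Tokenizer = Callable[..., Document]


# ---------------------------------------------------------------------------
# tagging schemes
# ---------------------------------------------------------------------------


def spans_to_tags(doc: Document, spans: Sequence[EntitySpan], scheme: str = "BIO") -> TagSequence:
    """Encode non-overlapping word spans as an IO or BIO tag sequence.

    Words inside a span get its class symbol (BIO marks the head word with B);
    all other words get O.  Overlapping spans raise, naming the colliding pair.
    """
    if scheme not in ("IO", "BIO"):
        raise ValueError(f"unknown scheme {scheme!r}")
    n = doc.n_words
    k = max((s.class_label for s in spans), default=1)
    tags = ["O"] * n
    owner: list[Optional[EntitySpan]] = [None] * n
    for sp in sorted(spans, key=lambda s: s.start_word):
        if sp.end_word > n:
            raise ValueError(f"span {sp} exceeds document length {n}")
        for w in range(sp.start_word, sp.end_word):
            if owner[w] is not None:
                raise ValueError(f"overlapping spans {owner[w]} and {sp}")
            owner[w] = sp
            head = scheme == "BIO" and w == sp.start_word
            tags[w] = f"{'B' if head else 'I'}-{sp.class_label}"
    return TagSequence(doc_id=doc.doc_id, tags=tags, scheme=scheme, k=k)


_TAG_RE = re.compile(r"^(O|[BI]-\d+)$")


def tags_to_spans(tag_seq: TagSequence) -> list[EntitySpan]:
    """Decode a tag sequence back to spans.

    IO: a span begins at every O-to-I transition or class change; adjacent
    same-class entities therefore merge (inherent IO limitation).  BIO: spans
    begin at B; a dangling I (after O, or after a differing class) is repaired
    by treating it as B, with a logged warning.
    """
    spans: list[EntitySpan] = []
    cur_start, cur_class = None, None

    def flush(end: int) -> None:
        nonlocal cur_start, cur_class
        if cur_start is not None:
            spans.append(
                EntitySpan(tag_seq.doc_id, cur_start, end, cur_class, provenance="tags")
            )
        cur_start, cur_class = None, None

    for w, tag in enumerate(tag_seq.tags):
        if not _TAG_RE.match(tag):
            raise ValueError(f"invalid tag {tag!r} at word {w}")
        if tag == "O":
            flush(w)
            continue
        prefix, cls = tag.split("-")
        cls = int(cls)
        if tag_seq.scheme == "IO":
            if cur_class != cls:
                flush(w)
                cur_start, cur_class = w, cls
        else:  # BIO
            if prefix == "B":
                flush(w)
                cur_start, cur_class = w, cls
            elif cur_class != cls:  # dangling I: repair as B
                logger.warning(
                    "%s: dangling I-%d at word %d treated as B", tag_seq.doc_id, cls, w
                )
                flush(w)
                cur_start, cur_class = w, cls
    flush(len(tag_seq.tags))
    return spans


# ---------------------------------------------------------------------------
# I/O: JSONL documents/spans, CoNLL tags
# ---------------------------------------------------------------------------


def read_documents_jsonl(
    path,
    tokenizer: Optional[Tokenizer] = None,
    config: Optional[TokenizerConfig] = None,
) -> list[Document]:
    """Read documents from JSONL: ``{doc_id, text, timestamp?}`` or the
    pre-tokenized form ``{doc_id, text, sentences: [[[tok, start, end], ...], ...]}``."""
    tok = tokenizer or tokenize
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "sentences" in obj:
                doc = Document(
                    doc_id=obj["doc_id"],
                    text=obj["text"],
                    sentences=[
                        Sentence([Token(s, a, b) for s, a, b in sent])
                        for sent in obj["sentences"]
                    ],
                    timestamp=obj.get("timestamp"),
                    section_spans=[tuple(t) for t in obj["section_spans"]]
                    if obj.get("section_spans")
                    else None,
                )
                doc.validate()
            else:
                doc = tok(
                    obj["text"],
                    config,
                    doc_id=obj["doc_id"],
                    timestamp=obj.get("timestamp"),
                )
            docs.append(doc)
    return docs


def write_documents_jsonl(path, docs: Iterable[Document], pretokenized: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            obj: dict = {"doc_id": d.doc_id, "text": d.text}
            if d.timestamp is not None:
                obj["timestamp"] = d.timestamp
            if pretokenized:
                obj["sentences"] = [
                    [[t.surface, t.start, t.end] for t in s.tokens] for s in d.sentences
                ]
                if d.section_spans:
                    obj["section_spans"] = [list(t) for t in d.section_spans]
            fh.write(json.dumps(obj) + "\n")


def read_spans_jsonl(path) -> list[EntitySpan]:
    spans = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            o = json.loads(line)
            spans.append(
                EntitySpan(
                    o["doc_id"],
                    o["start_word"],
                    o["end_word"],
                    o["class_label"],
                    o.get("provenance", ""),
                )
            )
    return spans


def write_spans_jsonl(path, spans: Iterable[EntitySpan]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in spans:
            fh.write(
                json.dumps(
                    {
                        "doc_id": s.doc_id,
                        "start_word": s.start_word,
                        "end_word": s.end_word,
                        "class_label": s.class_label,
                    }
                )
                + "\n"
            )


def write_conll(path, docs: Sequence[Document], tag_seqs: Sequence[TagSequence]) -> None:
    """CoNLL-2003-style two-column (token, tag) with blank lines between
    sentences and ``-DOCSTART- <doc_id>`` separating documents."""
    by_id = {t.doc_id: t for t in tag_seqs}
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            tags = by_id[doc.doc_id].tags
            fh.write(f"-DOCSTART- {doc.doc_id}\n\n")
            w = 0
            for sent in doc.sentences:
                for tok in sent.tokens:
                    fh.write(f"{tok.surface}\t{tags[w]}\n")
                    w += 1
                fh.write("\n")


def read_conll(path, scheme: str = "BIO", k: int = 1) -> list[TagSequence]:
    """Read two-column CoNLL tags back into per-document TagSequences."""
    seqs: list[TagSequence] = []
    doc_id, tags = None, []

    def flush():
        nonlocal doc_id, tags
        if doc_id is not None:
            seqs.append(TagSequence(doc_id, tags, scheme, k))
        doc_id, tags = None, []

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("-DOCSTART-"):
                flush()
                doc_id = line.split(maxsplit=1)[1] if " " in line else "doc"
            elif line.strip():
                tags.append(line.split("\t")[1])
    flush()
    return seqs
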