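"""Corpus handling for ADR mention extraction.

Reads and writes annotated review corpora in two interchange formats —
brat-style standoff (one ``.txt`` + one ``.ann`` file per document) and
CoNLL-2003-style token-per-line files — and provides the span/tag
plumbing the tagger needs: tokenization with character offsets,
resolution of overlapping ADR annotations into single maximal spans,
and conversion between character-offset entity spans and per-token BIO
tag sequences.

Conventions
-----------
* All character offsets are 0-based, half-open ``[start, end)`` (the
  brat convention).
* The tag inventory is ``O``, ``B-ADR``, ``I-ADR``; spans decode from
  maximal ``B-ADR (I-ADR)*`` runs.
* A token belongs to a span if their character intervals intersect at
  all; this maximizes agreement with offset-level annotations whose
  boundaries fall inside tokens.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ADR_LABEL",
    "TAGS",
    "TAG_TO_INDEX",
    "EntitySpan",
    "Token",
    "Sentence",
    "Document",
    "BratParseError",
    "SpanTextMismatchWarning",
    "tokenize",
    "split_sentences",
    "read_brat",
    "write_brat",
    "resolve_overlaps",
    "spans_to_bio",
    "bio_to_spans",
    "read_conll",
    "write_conll",
    "split_corpus",
]

ADR_LABEL = "ADR"

#: BIO tag inventory.  ``O`` deliberately sits at index 0 so an all-zero
#: score lattice decodes (with lowest-index tie-breaking) to "no entities".
TAGS = ("O", "B-ADR", "I-ADR")
TAG_TO_INDEX = {t: i for i, t in enumerate(TAGS)}


class BratParseError(ValueError):
    """A malformed line in a brat ``.ann`` file."""


class SpanTextMismatchWarning(UserWarning):
    """An annotation's quoted text disagrees with the document substring.

    Offsets are treated as authoritative; the warning carries enough
    context to audit the annotation by hand.
    """


@dataclass(frozen=True)
class EntitySpan:
    """A labelled character-offset span; the unit of annotation."""

    start: int
    end: int
    label: str = ADR_LABEL
    text: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span offsets [{self.start}, {self.end})")
        if not self.label:
            raise ValueError("span label must be nonempty")

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid token offsets [{self.start}, {self.end})")


@dataclass(frozen=True)
class Sentence:
    """A tokenized sentence — the unit of tagging."""

    doc_id: str
    index: int
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("sentence must contain at least one token")
        for a, b in zip(self.tokens, self.tokens[1:]):
            if b.start < a.end:
                raise ValueError("tokens must be ordered and non-overlapping")

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


@dataclass
class Document:
    """A review/post with its (possibly unresolved) entity annotations."""

    doc_id: str
    text: str
    spans: list[EntitySpan] = field(default_factory=list)

    def validate(self) -> None:
        for s in self.spans:
            if s.end > len(self.text):
                raise ValueError(
                    f"{self.doc_id}: span [{s.start},{s.end}) exceeds text length"
                )


# ---------------------------------------------------------------------------
# Tokenization.  Rule-based and offset-true: split on whitespace, then peel
# punctuation off token edges.  Pluggable — anything returning Token tuples
# with faithful offsets works downstream.
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"\S+")
# punctuation peeled off token edges; apostrophes stay inside words
_EDGE_PUNCT = ".,;:!?\"'()[]{}<>/\\*&%$#@~`+=|"
_SENT_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")


def _split_piece(piece: str, offset: int) -> list[Token]:
    """Split one whitespace-delimited chunk into word + punctuation tokens."""
    toks: list[Token] = []
    start, end = 0, len(piece)
    # leading punctuation
    while start < end and piece[start] in _EDGE_PUNCT:
        toks.append(Token(piece[start], offset + start, offset + start + 1))
        start += 1
    # trailing punctuation (collected, then emitted after the core)
    trail: list[Token] = []
    while end > start and piece[end - 1] in _EDGE_PUNCT:
        trail.append(Token(piece[end - 1], offset + end - 1, offset + end))
        end -= 1
    if start < end:
        toks.append(Token(piece[start:end], offset + start, offset + end))
    toks.extend(reversed(trail))
    return toks


def tokenize(text: str, base_offset: int = 0) -> list[Token]:
    """Tokenize ``text``, recording character offsets relative to the document.

    Concatenating token surfaces with the gaps between recorded offsets
    reconstructs the input exactly (offset conservation).
    """
    tokens: list[Token] = []
    for m in _WORD_RE.finditer(text):
        tokens.extend(_split_piece(m.group(), base_offset + m.start()))
    return tokens


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Punctuation-based sentence splitting; returns char intervals."""
    bounds: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY_RE.finditer(text):
        end = m.end()
        if text[start:end].strip():
            bounds.append((start, end))
        start = end
    if text[start:].strip():
        bounds.append((start, len(text)))
    return bounds


def sentences_of(doc: Document) -> list[Sentence]:
    """Sentence-split and tokenize a document, preserving offsets."""
    out: list[Sentence] = []
    for i, (a, b) in enumerate(split_sentences(doc.text)):
        toks = tokenize(doc.text[a:b], base_offset=a)
        if toks:
            out.append(Sentence(doc.doc_id, i, tuple(toks)))
    return out


# ---------------------------------------------------------------------------
# brat standoff format
# ---------------------------------------------------------------------------

_BRAT_T_RE = re.compile(r"^(T\d+)\t(\S+) ([\d; ]+)\t(.*)$", re.DOTALL)


def read_brat(text: str, ann: str, doc_id: str = "doc") -> Document:
    """Parse a brat ``.txt``/``.ann`` pair into a :class:`Document`.

    Discontinuous spans (``start end;start end``) are collapsed to their
    minimal covering interval, consistent with resolving every ADR to
    its longest continuous span.  If an annotation's quoted text
    disagrees with the document substring at its offsets, offsets win
    and a :class:`SpanTextMismatchWarning` is issued.
    """
    spans: list[EntitySpan] = []
    for lineno, line in enumerate(ann.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            continue  # relation/attribute/note lines are out of scope
        m = _BRAT_T_RE.match(line)
        if m is None:
            raise BratParseError(f"malformed annotation at line {lineno}: {line!r}")
        _tid, label, offsets_str, quoted = m.groups()
        try:
            fragments = [
                tuple(int(x) for x in frag.split())
                for frag in offsets_str.split(";")
            ]
            if any(len(f) != 2 for f in fragments):
                raise ValueError
        except ValueError:
            raise BratParseError(
                f"malformed offsets at line {lineno}: {offsets_str!r}"
            ) from None
        start = min(f[0] for f in fragments)
        end = max(f[1] for f in fragments)
        if not (0 <= start < end <= len(text)):
            raise BratParseError(
                f"offsets [{start},{end}) out of document bounds at line {lineno}"
            )
        actual = text[start:end]
        if len(fragments) == 1 and quoted != actual:
            warnings.warn(
                f"{doc_id} line {lineno}: annotation text {quoted!r} != "
                f"document substring {actual!r}; keeping offsets",
                SpanTextMismatchWarning,
                stacklevel=2,
            )
        spans.append(EntitySpan(start, end, label, actual))
    doc = Document(doc_id, text, spans)
    doc.validate()
    return doc


def write_brat(doc: Document) -> tuple[str, str]:
    """Serialize a document to a ``(text, ann)`` brat standoff pair."""
    lines = [
        f"T{i + 1}\t{s.label} {s.start} {s.end}\t{doc.text[s.start:s.end]}"
        for i, s in enumerate(sorted(doc.spans, key=lambda s: (s.start, s.end)))
    ]
    return doc.text, "".join(line + "\n" for line in lines)


# ---------------------------------------------------------------------------
# Overlap resolution: each connected group of mutually/transitively
# overlapping spans collapses to the single longest continuous span
# covering the whole group.
# ---------------------------------------------------------------------------


def resolve_overlaps(spans: list[EntitySpan]) -> list[EntitySpan]:
    """Merge transitively overlapping spans into their covering intervals.

    Idempotent; output is sorted by start and pairwise non-overlapping.
    Non-overlapping input spans pass through unchanged.
    """
    if not spans:
        return []
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    merged: list[EntitySpan] = [ordered[0]]
    for s in ordered[1:]:
        last = merged[-1]
        if s.start < last.end:  # strict overlap (touching spans stay separate)
            merged[-1] = EntitySpan(
                last.start, max(last.end, s.end), last.label, ""
            )
        else:
            merged.append(s)
    return merged


# ---------------------------------------------------------------------------
# BIO codec
# ---------------------------------------------------------------------------


def spans_to_bio(sentence: Sentence, spans: list[EntitySpan]) -> list[str]:
    """Project character spans onto the sentence's tokens as BIO tags.

    A token whose interval intersects a span gets ``B-ADR`` if it is the
    first such token of that span, ``I-ADR`` otherwise.  Spans must be
    non-overlapping (run :func:`resolve_overlaps` first).
    """
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValueError(
                "overlapping spans; call resolve_overlaps() before tagging"
            )
    tags = ["O"] * len(sentence.tokens)
    for span in ordered:
        first = True
        for i, tok in enumerate(sentence.tokens):
            if tok.start < span.end and span.start < tok.end:
                tags[i] = "B-ADR" if first else "I-ADR"
                first = False
    return tags


def bio_to_spans(
    sentence: Sentence, tags: list[str], invalid: str = "repair"
) -> list[EntitySpan]:
    """Decode BIO tags back into character-offset spans.

    Maximal ``B-ADR (I-ADR)*`` runs become spans from the first token's
    start to the last token's end.  An ``I-ADR`` following ``O`` or the
    sentence start is repaired to open a new span (``invalid="repair"``,
    the default — softmax heads emit such sequences and the task
    evaluates them anyway) or rejected (``invalid="strict"``).
    """
    if len(tags) != len(sentence.tokens):
        raise ValueError(
            f"{len(tags)} tags for {len(sentence.tokens)} tokens"
        )
    if invalid not in ("repair", "strict"):
        raise ValueError(f"unknown invalid-tag mode {invalid!r}")
    spans: list[EntitySpan] = []
    run_start: int | None = None  # token index opening the current span
    run_end = -1

    def flush() -> None:
        nonlocal run_start
        if run_start is not None:
            s = sentence.tokens[run_start].start
            e = sentence.tokens[run_end].end
            spans.append(EntitySpan(s, e, ADR_LABEL, ""))
            run_start = None

    for i, tag in enumerate(tags):
        if tag == "B-ADR":
            flush()
            run_start, run_end = i, i
        elif tag == "I-ADR":
            if run_start is None:
                if invalid == "strict":
                    raise ValueError(f"orphan I-ADR at token {i}")
                run_start, run_end = i, i  # repaired to B-ADR
            else:
                run_end = i
        elif tag == "O":
            flush()
        else:
            raise ValueError(f"unknown tag {tag!r} at position {i}")
    flush()
    return spans


def spans_to_token_intervals(
    sentence: Sentence, spans: list[EntitySpan]
) -> list[tuple[int, int]]:
    """Half-open token-index intervals of spans intersecting the sentence.

    A token belongs to a span if their character intervals intersect;
    spans with no token in this sentence are dropped.
    """
    intervals: list[tuple[int, int]] = []
    for span in sorted(spans, key=lambda s: (s.start, s.end)):
        hit = [i for i, tok in enumerate(sentence.tokens)
               if tok.start < span.end and span.start < tok.end]
        if hit:
            intervals.append((hit[0], hit[-1] + 1))
    return intervals


# ---------------------------------------------------------------------------
# CoNLL token-per-line format: "surface<TAB>tag", blank line between
# sentences.  Bit-exact roundtrip (write ∘ read = identity on the text).
# ---------------------------------------------------------------------------


def write_conll(sentences: list[Sentence], tag_sequences: list[list[str]]) -> str:
    if len(sentences) != len(tag_sequences):
        raise ValueError("one tag sequence per sentence required")
    blocks = []
    for sent, tags in zip(sentences, tag_sequences):
        if len(tags) != len(sent.tokens):
            raise ValueError("tag/token length mismatch")
        blocks.append(
            "".join(f"{t.surface}\t{tag}\n" for t, tag in zip(sent.tokens, tags))
        )
    return "\n".join(blocks)


def read_conll(text: str, doc_id: str = "conll") -> tuple[list[Sentence], list[list[str]]]:
    """Parse CoNLL text; offsets are synthesized by single-space joining.

    Character offsets are not stored in CoNLL files, so each sentence is
    laid out independently with one space between surfaces; BIO tags and
    token identities roundtrip bit-exactly through :func:`write_conll`.
    """
    sentences: list[Sentence] = []
    tag_sequences: list[list[str]] = []
    for idx, block in enumerate(b for b in text.split("\n\n") if b.strip()):
        tokens: list[Token] = []
        tags: list[str] = []
        offset = 0
        for lineno, line in enumerate(block.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                surface, tag = line.split("\t")
            except ValueError:
                raise ValueError(
                    f"malformed CoNLL line {lineno} in sentence {idx}: {line!r}"
                ) from None
            tokens.append(Token(surface, offset, offset + len(surface)))
            tags.append(tag)
            offset += len(surface) + 1
        sentences.append(Sentence(doc_id, idx, tuple(tokens)))
        tag_sequences.append(tags)
    return sentences, tag_sequences


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------


def split_corpus(
    documents: list[Document], train_fraction: float = 0.70, seed: int = 0
) -> tuple[list[Document], list[Document]]:
    """Deterministic document-level train/test split.

    The split is at document (review) granularity, never sentence
    granularity, so no review contributes to both sides.  1250 documents
    at the default fraction give the 875/375 partition.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(documents) < 2:
        raise ValueError("need at least 2 documents to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(documents))
    n_train = int(round(train_fraction * len(documents)))
    n_train = min(max(n_train, 1), len(documents) - 1)
    train_idx = sorted(order[:n_train].tolist())
    test_idx = sorted(order[n_train:].tolist())
    return [documents[i] for i in train_idx], [documents[i] for i in test_idx]
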