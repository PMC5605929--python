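import numpy as np
import pytest

from adrtag.corpus_io import Document, EntitySpan, Sentence, Token, tokenize


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


#: The running example: a review sentence containing four ADR mentions.
EXAMPLE_TEXT = (
    "1st pill taken with food, a few hours after I experienced shortness "
    "of breath, a sense of depression, cramping, upset stomach"
)
EXAMPLE_ADRS = ("shortness of breath", "depression", "cramping", "upset stomach")


@pytest.fixture
def example_doc():
    spans = []
    for phrase in EXAMPLE_ADRS:
        start = EXAMPLE_TEXT.index(phrase)
        spans.append(EntitySpan(start, start + len(phrase), "ADR", phrase))
    return Document("example", EXAMPLE_TEXT, spans)


@pytest.fixture
def example_ann():
    lines = []
    for i, phrase in enumerate(EXAMPLE_ADRS, start=1):
        start = EXAMPLE_TEXT.index(phrase)
        lines.append(f"T{i}\tADR {start} {start + len(phrase)}\t{phrase}")
    return "\n".join(lines) + "\n"


def sentence_from_text(text: str, doc_id: str = "t", index: int = 0) -> Sentence:
    return Sentence(doc_id, index, tuple(tokenize(text)))


def random_sentence(rng: np.random.Generator, n_tokens: int) -> Sentence:
    """Sentence of single-character tokens with random gaps."""
    toks, off = [], 0
    for i in range(n_tokens):
        length = int(rng.integers(1, 6))
        toks.append(Token("x" * length, off, off + length))
        off += length + int(rng.integers(1, 3))
    return Sentence("rand", 0, tuple(toks))


def random_token_aligned_spans(rng: np.random.Generator, sent: Sentence):
    """Non-overlapping spans aligned to whole tokens of ``sent``."""
    n = len(sent.tokens)
    spans = []
    i = 0
    while i < n:
        if rng.random() < 0.35:
            j = min(n - 1, i + int(rng.integers(0, 3)))
            spans.append(EntitySpan(sent.tokens[i].start, sent.tokens[j].end,
                                    "ADR", ""))
            i = j + 2  # gap guarantees decoded spans cannot merge
        else:
            i += 1
    return spans
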