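"""Synthetic annotated review corpora for exercising the tagger end-to-end.

The generator emulates the statistical structure of patient drug-review
corpora: short documents of templated sentences in which 0-4 multi-word
ADR phrases from a fixed lexicon are planted into experience contexts
("i experienced {ADR} ...") and recorded as gold character-offset
spans.  Two controlled difficulty knobs make the learning task
non-trivial:

* ``transition_noise_rate`` — lexicon phrases also appear in non-ADR
  contexts ("i read about {ADR-phrase} online") where they are *not*
  annotated, so a pure lexicon lookup has perfect recall but imperfect
  precision and the tagger must use context;
* ``overlap_injection_rate`` — optional duplicate annotations
  overlapping gold spans, giving the overlap-resolution step real work
  and a known expected outcome.

A matching toy word-embedding file (word2vec text format) is emitted
covering ~97% of the generated vocabulary, mirroring the partial
pretrained-embedding coverage regime the tagger's OOV initialization
is designed for.

The lexicon defaults to ADR surface forms actually reported by patients
(e.g. "shortness of breath", "weight gain", "dry mouth").  No grammar
or misspelling model is attempted: the corpus exists to exercise the
tagging machinery, not to pass for English.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Document, EntitySpan, sentences_of, spans_to_bio

__all__ = [
    "GeneratorConfig",
    "SyntheticCorpus",
    "generate",
    "inject_overlaps",
    "expected_sentence_span_rate",
    "tagged_sentences",
    "DEFAULT_LEXICON",
    "DEFAULT_TEMPLATES",
]

#: Multi-word ADR surface forms as patients write them in drug reviews.
DEFAULT_LEXICON: tuple[str, ...] = (
    "anxiety", "depression", "panic attacks", "pain", "weight gain",
    "nausea", "headaches", "dizziness", "insomnia", "mood swings",
    "dry mouth", "sweating", "rash", "heartburn", "severe nausea",
    "heart racing", "stiffness", "severe migraines", "cramping",
    "neck pain", "twitching", "fever", "skin problems",
    "pins and needles", "burning sensations", "loose bowels",
    "night sweat", "chest pressure", "blisters", "clammy hands",
    "jaw pain", "frequent headaches", "stomach pains", "severe dizziness",
    "intrusive thoughts", "nervous breakdown", "aches and pains",
    "swelling", "muscle aches", "profuse sweating", "indigestion",
    "ringing in my ears", "spasms", "trouble urinating", "palpitations",
    "cough", "dry cough", "fatigue", "hair loss", "shortness of breath",
    "tiredness", "diarrhea", "chest pain", "joint pain", "blurred vision",
    "heart palpitations", "hives", "hot flashes", "nightmares",
    "cold hands and feet", "weight loss", "upset stomach", "numbness",
    "constipation", "nerve pain", "back pain", "vomiting", "drowsiness",
    "trouble sleeping", "vertigo", "tremors", "itching",
)

#: Sentence templates.  "{ADR}" slots take annotated lexicon phrases
#: (with probability ``p_adr_per_slot``, otherwise neutral filler);
#: "{NOISE}" slots take *unannotated* lexicon phrases (with probability
#: ``transition_noise_rate``); "{F}" is always neutral filler.  The cue
#: words around the two slot kinds differ, so context determines the label.
DEFAULT_TEMPLATES: tuple[str, ...] = (
    "i experienced {ADR} and {ADR} after two days",
    "this drug gave me {ADR} within the first week",
    "i had {ADR} then {ADR} and later {ADR}",
    "it caused {ADR} and i stopped taking it",
    "side effects were {ADR} and {ADR} and {ADR} and {ADR}",
    "i suffered from {ADR} since the second dose",
    "after the first pill i had {ADR} and some {F}",
    "my doctor said the {F} was normal for this dose",
    "i have been taking it for two weeks with no {F} at all",
    "the pharmacist warned me about {NOISE} but i felt fine",
    "i read about {NOISE} online before starting",
    "an article mentioned {NOISE} as a rare problem",
    "my friend asked whether {NOISE} was common with this drug",
    "it worked well although i experienced {ADR} sometimes",
    "i had {ADR} but the leaflet also lists {NOISE} for others",
)

_FILLER_WORDS: tuple[str, ...] = (
    "improvement", "discomfort", "issues", "trouble", "problems", "change",
    "effect", "reaction", "benefit", "relief", "symptoms", "complaints",
    "concerns", "difference", "results", "progress", "episodes", "feelings",
    "sensations", "troubles", "changes", "effects", "reactions", "benefits",
    "worries", "doubts", "questions", "notes", "signs", "events",
)


@dataclass
class GeneratorConfig:
    n_documents: int = 625
    sentences_per_document: tuple[int, int] = (4, 4)  # inclusive range
    adr_lexicon: tuple[str, ...] = DEFAULT_LEXICON
    carrier_templates: tuple[str, ...] = DEFAULT_TEMPLATES
    p_adr_per_slot: float = 0.7
    overlap_injection_rate: float = 0.0
    vocabulary_size: int = 30          # number of filler words in use
    embedding_dim: int = 50
    embedding_coverage: float = 0.97   # fraction of vocabulary given file vectors
    transition_noise_rate: float = 0.2
    seed: int = 13

    def __post_init__(self) -> None:
        for p in (self.p_adr_per_slot, self.overlap_injection_rate,
                  self.transition_noise_rate, self.embedding_coverage):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.adr_lexicon:
            raise ValueError("lexicon must be non-empty")
        lo, hi = self.sentences_per_document
        if not 1 <= lo <= hi:
            raise ValueError("invalid sentences_per_document range")
        for phrase in self.adr_lexicon:
            if not 1 <= len(phrase.split()) <= 4:
                raise ValueError(f"lexicon phrases must be 1-4 tokens: {phrase!r}")


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    embedding_text: str                 # word2vec text format
    vocabulary: list[str]
    #: doc_id -> expected spans after overlap resolution (equals the gold
    #: spans until inject_overlaps adds raw duplicates)
    expected_resolved: dict[str, list[tuple[int, int]]] = field(
        default_factory=dict)


def _fill_sentence(template: str, cfg: GeneratorConfig,
                   rng: np.random.Generator, char_offset: int,
                   ) -> tuple[str, list[EntitySpan]]:
    """Expand one template; returns (sentence text, gold spans)."""
    parts: list[str] = []
    spans: list[EntitySpan] = []
    pos = char_offset
    fillers = _FILLER_WORDS[: max(1, min(cfg.vocabulary_size, len(_FILLER_WORDS)))]
    for token in template.split():
        if token == "{ADR}" and rng.random() < cfg.p_adr_per_slot:
            phrase = str(rng.choice(cfg.adr_lexicon))
            spans.append(EntitySpan(pos, pos + len(phrase), text=phrase))
            piece = phrase
        elif token == "{NOISE}" and rng.random() < cfg.transition_noise_rate:
            piece = str(rng.choice(cfg.adr_lexicon))  # deliberately unannotated
        elif token in ("{ADR}", "{NOISE}", "{F}"):
            piece = str(rng.choice(fillers))
        else:
            piece = token
        parts.append(piece)
        pos += len(piece) + 1
    text = " ".join(parts)
    return text, spans


def generate(config: GeneratorConfig | None = None) -> SyntheticCorpus:
    """Generate a corpus + toy embedding file, deterministically by seed.

    Every planted lexicon phrase is recorded as a gold span whose text
    equals the document substring at its offsets; noise occurrences are
    not annotated; gold spans never overlap by construction.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    docs: list[Document] = []
    lo, hi = cfg.sentences_per_document
    for d in range(cfg.n_documents):
        n_sents = int(rng.integers(lo, hi + 1))
        text_parts: list[str] = []
        spans: list[EntitySpan] = []
        offset = 0
        for _ in range(n_sents):
            template = str(rng.choice(cfg.carrier_templates))
            sent_text, sent_spans = _fill_sentence(template, cfg, rng, offset)
            sent_text += "."
            text_parts.append(sent_text)
            spans.extend(sent_spans)
            offset += len(sent_text) + 1
        doc = Document(f"synth-{d:05d}", " ".join(text_parts), spans)
        doc.validate()
        docs.append(doc)

    vocab = _corpus_vocabulary(docs)
    embedding_text = _toy_embeddings(vocab, cfg, rng)
    corpus = SyntheticCorpus(docs, embedding_text, vocab)
    corpus.expected_resolved = {
        d.doc_id: [(s.start, s.end) for s in sorted(d.spans,
                                                    key=lambda s: s.start)]
        for d in docs
    }
    if cfg.overlap_injection_rate > 0:
        corpus = inject_overlaps(corpus, cfg.overlap_injection_rate,
                                 int(rng.integers(0, 2 ** 31)))
    return corpus


def _corpus_vocabulary(docs: list[Document]) -> list[str]:
    vocab = sorted({t.surface.lower()
                    for d in docs for s in sentences_of(d) for t in s.tokens})
    return vocab


def _toy_embeddings(vocab: list[str], cfg: GeneratorConfig,
                    rng: np.random.Generator) -> str:
    """word2vec text covering ``embedding_coverage`` of the vocabulary."""
    n_covered = int(round(cfg.embedding_coverage * len(vocab)))
    covered_idx = rng.choice(len(vocab), size=n_covered, replace=False)
    covered = [vocab[i] for i in sorted(covered_idx)]
    lines = [f"{len(covered)} {cfg.embedding_dim}"]
    for w in covered:
        vec = rng.uniform(-0.25, 0.25, size=cfg.embedding_dim)
        lines.append(w + " " + " ".join(f"{v:.6f}" for v in vec))
    return "\n".join(lines) + "\n"


def inject_overlaps(corpus: SyntheticCorpus, rate: float,
                    seed: int) -> SyntheticCorpus:
    """Add raw annotations overlapping gold spans, at the given rate.

    Each selected gold span gains one extra raw span — either a strict
    sub-span or an extension one character into the following gap — so
    overlap resolution has real work to do.  The expected post-resolution
    intervals are recorded on the returned corpus for oracle checks.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    new_docs: list[Document] = []
    expected: dict[str, list[tuple[int, int]]] = {}
    for doc in corpus.documents:
        gold = sorted(doc.spans, key=lambda s: s.start)
        extra: list[EntitySpan] = []
        exp: list[tuple[int, int]] = []
        for s in gold:
            lo, hi = s.start, s.end
            if rng.random() < rate:
                if hi - lo > 2 and rng.random() < 0.5:
                    # strict sub-span: resolution restores the original
                    a = lo + int(rng.integers(1, hi - lo - 1))
                    extra.append(EntitySpan(a, hi, text=""))
                    exp.append((lo, hi))
                else:
                    # extension into the following gap character
                    ext = min(hi + 1, len(doc.text))
                    if ext > hi:
                        extra.append(EntitySpan(lo, ext, text=""))
                        exp.append((lo, ext))
                    else:
                        exp.append((lo, hi))
            else:
                exp.append((lo, hi))
        new_docs.append(Document(doc.doc_id, doc.text, gold + extra))
        expected[doc.doc_id] = exp
    return SyntheticCorpus(new_docs, corpus.embedding_text, corpus.vocabulary,
                           expected)


def expected_sentence_span_rate(config: GeneratorConfig) -> float:
    """Analytic P(sentence has >= 1 gold span) under uniform templates."""
    p = config.p_adr_per_slot
    probs = [1.0 - (1.0 - p) ** t.split().count("{ADR}")
             for t in config.carrier_templates]
    return float(np.mean(probs))


def tagged_sentences(documents: list[Document]
                     ) -> list[tuple[list[str], list[str]]]:
    """Sentence-split, tokenize and BIO-tag documents for the tagger."""
    out = []
    for doc in documents:
        for sent in sentences_of(doc):
            tags = spans_to_bio(sent, [
                s for s in doc.spans
                if s.start < sent.tokens[-1].end and s.end > sent.tokens[0].start
            ])
            out.append((sent.surfaces, tags))
    return out
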