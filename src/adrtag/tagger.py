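"""Neural sequence tagger for ADR mention extraction.

The encoder follows the joint architecture: each token is represented by
a pretrained word embedding optionally concatenated with a feature
vector from a character-level CNN; the sequence runs through a stack of
bidirectional LSTM or GRU layers (forward and backward hidden states
concatenated, each layer consuming the previous layer's concatenated
outputs); the recurrent outputs pass through dropout and a linear dense
layer whose output size equals the number of tags.  Those per-token
unary scores feed either a per-token softmax head (baseline) or a
linear-chain CRF head (the joint model), which is trained by exact NLL
and decoded with Viterbi.

Training uses mini-batch Adam with default parameters (batch size 128
by default), a fixed epoch budget with dev-best checkpointing, and a
single integer seed controlling parameter init, OOV embedding
sampling, dropout masks, and batch shuffling.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autodiff as ad
from . import crf as crf_mod
from .corpus_io import (
    TAGS,
    TAG_TO_INDEX,
    EntitySpan,
    Sentence,
    bio_to_spans,
)

__all__ = [
    "EmbeddingTable",
    "CharCNNConfig",
    "TaggerConfig",
    "TaggerModel",
    "load_embeddings",
    "char_features",
    "encode",
    "train",
    "predict",
    "predict_tags",
    "save_checkpoint",
    "load_checkpoint",
]

PAD, UNK = "<pad>", "<unk>"


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingTable:
    vocabulary: dict[str, int]
    vectors: np.ndarray
    oov_policy: tuple[float, float]  # (low, high) sampling range used for OOV
    n_oov: int = 0

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def parse_word2vec_text(stream) -> tuple[dict[str, np.ndarray], int]:
    """Parse word2vec text format: header ``count dim``, then vector lines."""
    header = stream.readline().split()
    if len(header) != 2:
        raise ValueError("expected word2vec header 'count dim'")
    count, dim = int(header[0]), int(header[1])
    table: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(stream, start=2):
        parts = line.rstrip("\n").split(" ")
        if len(parts) < 2:
            continue
        word, vals = parts[0], parts[1:]
        if len(vals) != dim:
            raise ValueError(
                f"line {lineno}: expected {dim} components, got {len(vals)}"
            )
        table[word] = np.array(vals, dtype=float)
    if count != len(table):
        # header count is advisory; tolerate but do not hide dim errors
        pass
    return table, dim


def load_embeddings(path, vocabulary: list[str], seed: int = 0) -> EmbeddingTable:
    """Build an embedding table for ``vocabulary`` from a word2vec text file.

    In-vocabulary words take their file vectors; out-of-vocabulary words
    are sampled i.i.d. uniformly from the [min, max] range of the loaded
    embedding weights, deterministically given ``seed``.  ``<pad>`` maps
    to the zero vector and is prepended; ``<unk>`` is sampled like any
    OOV word.
    """
    if isinstance(path, io.TextIOBase):
        file_vecs, dim = parse_word2vec_text(path)
    else:
        with open(path, "r", encoding="utf8") as fh:
            file_vecs, dim = parse_word2vec_text(fh)
    lo = min(float(v.min()) for v in file_vecs.values()) if file_vecs else -0.25
    hi = max(float(v.max()) for v in file_vecs.values()) if file_vecs else 0.25
    rng = np.random.default_rng(seed)
    words = [PAD, UNK] + [w for w in vocabulary if w not in (PAD, UNK)]
    vocab = {w: i for i, w in enumerate(words)}
    vectors = np.zeros((len(words), dim))
    n_oov = 0
    for w, i in vocab.items():
        if w == PAD:
            continue
        if w in file_vecs:
            vectors[i] = file_vecs[w]
        else:
            vectors[i] = rng.uniform(lo, hi, size=dim)
            if w != UNK:
                n_oov += 1
    return EmbeddingTable(vocab, vectors, (lo, hi), n_oov=n_oov)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class CharCNNConfig:
    char_vocabulary: dict[str, int] = field(default_factory=dict)
    char_embedding_dim: int = 25
    filter_widths: tuple[int, ...] = (2, 3, 4)
    filters_per_width: int = 25
    max_word_length: int = 20

    def __post_init__(self) -> None:
        if self.char_embedding_dim < 1 or self.filters_per_width < 1 \
                or self.max_word_length < 1 or any(w < 1 for w in self.filter_widths):
            raise ValueError("char-CNN dimensions must be positive")

    @property
    def feature_dim(self) -> int:
        return len(self.filter_widths) * self.filters_per_width


@dataclass
class TaggerConfig:
    cell: str = "GRU"                 # "LSTM" | "GRU"
    num_layers: int = 2               # 1..4 stacked bidirectional layers
    hidden_size: int = 100            # per direction
    dropout_rate: float = 0.5         # on RNN outputs, before the dense layer
    use_char_cnn: bool = True
    head: str = "crf"                 # "crf" | "softmax"
    batch_size: int = 128
    max_epochs: int = 100
    learning_rate: float = 0.001      # Adam default
    seed: int = 0
    char_cnn: CharCNNConfig = field(default_factory=CharCNNConfig)
    constrain_decoding: bool = False  # forbid BIO-invalid transitions at decode

    def __post_init__(self) -> None:
        if self.cell not in ("LSTM", "GRU"):
            raise ValueError(f"unknown cell {self.cell!r}")
        if not 1 <= self.num_layers <= 4:
            raise ValueError("num_layers must be in [1, 4]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.head not in ("crf", "softmax"):
            raise ValueError(f"unknown head {self.head!r}")


# ---------------------------------------------------------------------------
# Model: parameter store + encoder
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    s = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-s, s, size=shape)


class TaggerModel:
    """Parameters + vocabularies for one trained (or initializing) tagger."""

    def __init__(self, config: TaggerConfig, embeddings: EmbeddingTable,
                 tags: tuple[str, ...] = TAGS):
        self.config = config
        self.tags = tags
        self.word_vocab = embeddings.vocabulary
        self.char_vocab = dict(config.char_cnn.char_vocabulary)
        if PAD not in self.char_vocab:
            raise ValueError("char vocabulary must contain <pad>")
        rng = np.random.default_rng(config.seed)
        K = len(tags)
        H = config.hidden_size
        cc = config.char_cnn
        gates = 4 if config.cell == "LSTM" else 3
        in_dim = embeddings.dim + (cc.feature_dim if config.use_char_cnn else 0)

        p: dict[str, ad.Tensor] = {}
        p["word_emb"] = ad.Tensor(embeddings.vectors.copy(), requires_grad=True)
        if config.use_char_cnn:
            ce = rng.uniform(-np.sqrt(3.0 / cc.char_embedding_dim),
                             np.sqrt(3.0 / cc.char_embedding_dim),
                             size=(len(self.char_vocab), cc.char_embedding_dim))
            ce[self.char_vocab[PAD]] = 0.0
            p["char_emb"] = ad.Tensor(ce, requires_grad=True)
            for w in cc.filter_widths:
                p[f"conv{w}_W"] = ad.Tensor(
                    _glorot(rng, (w * cc.char_embedding_dim, cc.filters_per_width)),
                    requires_grad=True)
                p[f"conv{w}_b"] = ad.Tensor(
                    np.zeros(cc.filters_per_width), requires_grad=True)
        layer_in = in_dim
        for layer in range(config.num_layers):
            for d in ("f", "b"):
                p[f"l{layer}{d}_W"] = ad.Tensor(
                    _glorot(rng, (layer_in, gates * H)), requires_grad=True)
                p[f"l{layer}{d}_U"] = ad.Tensor(
                    _glorot(rng, (H, gates * H)), requires_grad=True)
                b = np.zeros(gates * H)
                if config.cell == "LSTM":
                    b[H:2 * H] = 1.0  # forget-gate bias init
                p[f"l{layer}{d}_b"] = ad.Tensor(b, requires_grad=True)
            layer_in = 2 * H
        p["dense_W"] = ad.Tensor(_glorot(rng, (2 * H, K)), requires_grad=True)
        p["dense_b"] = ad.Tensor(np.zeros(K), requires_grad=True)
        if config.head == "crf":
            p["crf_trans"] = ad.Tensor(np.zeros((K, K)), requires_grad=True)
            p["crf_start"] = ad.Tensor(np.zeros(K), requires_grad=True)
            p["crf_stop"] = ad.Tensor(np.zeros(K), requires_grad=True)
        self.params = p

    # -- vocab helpers -----------------------------------------------------

    def word_index(self, surface: str) -> int:
        return self.word_vocab.get(surface.lower(), self.word_vocab[UNK])

    def char_indices(self, surface: str) -> list[int]:
        cc = self.config.char_cnn
        unk = self.char_vocab.get(UNK, self.char_vocab[PAD])
        # case preserved: character features keep the shape information the
        # lowercased lookup discards
        return [self.char_vocab.get(c, unk) for c in surface[: cc.max_word_length]]

    def parameter_snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_snapshot(self, snap: dict[str, np.ndarray]) -> None:
        for k, v in snap.items():
            self.params[k].data = v.copy()


def build_char_vocab(sentences: list[list[str]]) -> dict[str, int]:
    chars = sorted({c for sent in sentences for w in sent for c in w})
    vocab = {PAD: 0, UNK: 1}
    for c in chars:
        vocab[c] = len(vocab)
    return vocab


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------


def _char_cnn_batch(model: TaggerModel, char_idx: np.ndarray,
                    char_mask: np.ndarray) -> ad.Tensor:
    """(B, T, L) char indices -> (B, T, F_total) pooled features."""
    cc = model.config.char_cnn
    emb = ad.embedding_lookup(model.params["char_emb"], char_idx)  # (B,T,L,dc)
    feats = []
    L = char_idx.shape[2]
    for w in cc.filter_widths:
        P = L - w + 1
        if P < 1:
            raise ValueError("max_word_length shorter than a filter width")
        window = ad.concat(
            [emb[:, :, i:i + P, :] for i in range(w)], axis=-1
        )  # (B,T,P,w*dc)
        conv = window @ model.params[f"conv{w}_W"] + model.params[f"conv{w}_b"]
        # linear convolution; a window is valid iff its last char is real
        valid = char_mask[:, :, w - 1:][..., None]
        feats.append(ad.max_pool_axis(conv, axis=2, mask=valid))
    return ad.concat(feats, axis=-1)


def _rnn_layer(model: TaggerModel, x: ad.Tensor, mask: np.ndarray,
               layer: int, direction: str) -> ad.Tensor:
    """One direction of one recurrent layer over (B, T, D) -> (B, T, H)."""
    cfg = model.config
    B, T, _ = x.shape
    H = cfg.hidden_size
    W = model.params[f"l{layer}{direction}_W"]
    U = model.params[f"l{layer}{direction}_U"]
    b = model.params[f"l{layer}{direction}_b"]
    xw = x @ W + b  # precompute input contributions for all timesteps
    h = ad.Tensor(np.zeros((B, H)))
    c = ad.Tensor(np.zeros((B, H)))  # LSTM cell state
    steps = range(T) if direction == "f" else range(T - 1, -1, -1)
    outputs: dict[int, ad.Tensor] = {}
    for t in steps:
        g = xw[:, t, :] + h @ U
        m = mask[:, t:t + 1]  # (B,1); carry state through padding
        if cfg.cell == "GRU":
            z = ad.sigmoid(g[:, 0:H])
            r = ad.sigmoid(g[:, H:2 * H])
            # candidate uses the reset-gated state: recompute its recurrent term
            n = ad.tanh(xw[:, t, 2 * H:3 * H] + (r * h) @ U[:, 2 * H:3 * H])
            h_new = z * h + (1.0 - z) * n
        else:
            i = ad.sigmoid(g[:, 0:H])
            f = ad.sigmoid(g[:, H:2 * H])
            cand = ad.tanh(g[:, 2 * H:3 * H])
            o = ad.sigmoid(g[:, 3 * H:4 * H])
            c_new = f * c + i * cand
            c = c_new * m + c * (1.0 - m)
            h_new = o * ad.tanh(c_new)
        h = h_new * m + h * (1.0 - m)
        outputs[t] = h
    return ad.stack([outputs[t] for t in range(T)], axis=1)


def encode_batch(model: TaggerModel, word_idx: np.ndarray, char_idx,
                 char_mask, mask: np.ndarray, training: bool,
                 rng: np.random.Generator | None = None) -> ad.Tensor:
    """Full encoder: embeddings -> BiRNN stack -> dropout -> dense.

    Returns the (B, T, K) unary score lattice as an autodiff tensor.
    """
    cfg = model.config
    x = ad.embedding_lookup(model.params["word_emb"], word_idx)
    if cfg.use_char_cnn:
        x = ad.concat([x, _char_cnn_batch(model, char_idx, char_mask)], axis=-1)
    for layer in range(cfg.num_layers):
        fw = _rnn_layer(model, x, mask, layer, "f")
        bw = _rnn_layer(model, x, mask, layer, "b")
        x = ad.concat([fw, bw], axis=-1)
    if training:
        if rng is None:
            raise ValueError("training-mode encoding needs an RNG for dropout")
        x = ad.dropout(x, cfg.dropout_rate, rng, training=True)
    return x @ model.params["dense_W"] + model.params["dense_b"]


def encode(model: TaggerModel, surfaces: list[str]) -> np.ndarray:
    """Deterministic evaluation-mode unary scores for one sentence (n, K)."""
    if not surfaces:
        raise ValueError("cannot encode an empty sentence")
    word_idx, char_idx, char_mask, mask, _ = _prepare_batch(model, [surfaces])
    lattice = encode_batch(model, word_idx, char_idx, char_mask, mask,
                           training=False)
    return lattice.data[0]


def char_features(word: str, model: TaggerModel) -> np.ndarray:
    """Character-CNN feature vector for a single word (length Σ filters)."""
    if not word:
        raise ValueError("word must be non-empty")
    cc = model.config.char_cnn
    L = max(cc.max_word_length, max(cc.filter_widths))
    idx = np.zeros((1, 1, L), dtype=int)
    msk = np.zeros((1, 1, L), dtype=bool)
    ci = model.char_indices(word)
    idx[0, 0, :len(ci)] = ci
    msk[0, 0, :len(ci)] = True
    return _char_cnn_batch(model, idx, msk).data[0, 0]


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------


def _prepare_batch(model: TaggerModel, batch_surfaces: list[list[str]],
                   batch_tags: list[list[int]] | None = None):
    cc = model.config.char_cnn
    B = len(batch_surfaces)
    T = max(len(s) for s in batch_surfaces)
    L = max(cc.max_word_length, max(cc.filter_widths))
    word_idx = np.zeros((B, T), dtype=int)
    char_idx = np.zeros((B, T, L), dtype=int)
    char_mask = np.zeros((B, T, L), dtype=bool)
    mask = np.zeros((B, T))
    tags = np.zeros((B, T), dtype=int)
    lengths = np.zeros(B, dtype=int)
    for b, sent in enumerate(batch_surfaces):
        lengths[b] = len(sent)
        mask[b, :len(sent)] = 1.0
        for t, wrd in enumerate(sent):
            word_idx[b, t] = model.word_index(wrd)
            ci = model.char_indices(wrd)
            char_idx[b, t, :len(ci)] = ci
            char_mask[b, t, :len(ci)] = True
        if batch_tags is not None:
            tags[b, :len(sent)] = batch_tags[b]
    return word_idx, char_idx, char_mask, mask, (tags, lengths)


def _crf_loss(model: TaggerModel, unary: ad.Tensor, tags: np.ndarray,
              lengths: np.ndarray) -> ad.Tensor:
    """CRF NLL as a custom autodiff op (backward = forward-backward marginals)."""
    trans = model.params["crf_trans"]
    start = model.params["crf_start"]
    stop = model.params["crf_stop"]
    total, g_u, g_t, g_s, g_p = crf_mod.batch_nll_and_grads(
        unary.data, tags, lengths, trans.data, start.data, stop.data)
    out = ad.Tensor(total, parents=(unary, trans, start, stop))

    def backward(g: np.ndarray) -> None:
        scale = float(g)
        unary._accumulate(scale * g_u)
        trans._accumulate(scale * g_t)
        start._accumulate(scale * g_s)
        stop._accumulate(scale * g_p)

    out._backward = backward
    return out


class _Adam:
    """Adam with the customary defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: dict[str, ad.Tensor], lr: float = 0.001):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------


TaggedSentence = tuple[list[str], list[str]]  # (surfaces, BIO tags)


def _to_indices(tags: list[str]) -> list[int]:
    return [TAG_TO_INDEX[t] for t in tags]


def train(train_corpus: list[TaggedSentence],
          dev_corpus: list[TaggedSentence] | None,
          config: TaggerConfig,
          embeddings: EmbeddingTable,
          epoch_callback=None) -> tuple[TaggerModel, list[dict]]:
    """Train a tagger; returns the dev-best model and the per-epoch log.

    The loss is the CRF NLL (``head="crf"``) or summed per-token
    cross-entropy (``head="softmax"``), minimized by mini-batch Adam for
    a fixed epoch budget; after each epoch the dev exact-match F1 is
    logged and the best-scoring parameter snapshot is restored at the
    end.  Without a dev corpus the final epoch's parameters are kept.
    """
    if not train_corpus:
        raise ValueError("training corpus is empty")
    cc_vocab = config.char_cnn.char_vocabulary or build_char_vocab(
        [s for s, _ in train_corpus])
    config.char_cnn.char_vocabulary = cc_vocab
    model = TaggerModel(config, embeddings)
    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model.params, lr=config.learning_rate)
    history: list[dict] = []
    best_f1, best_snap = -1.0, None

    surfaces = [s for s, _ in train_corpus]
    tag_idx = [_to_indices(t) for _, t in train_corpus]

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_corpus))
        total_loss, total_tokens = 0.0, 0
        for lo in range(0, len(order), config.batch_size):
            sel = order[lo:lo + config.batch_size]
            bs = [surfaces[i] for i in sel]
            bt = [tag_idx[i] for i in sel]
            word_idx, char_idx, char_mask, mask, (tags, lengths) = \
                _prepare_batch(model, bs, bt)
            unary = encode_batch(model, word_idx, char_idx, char_mask, mask,
                                 training=True, rng=rng)
            if config.head == "crf":
                loss = _crf_loss(model, unary, tags, lengths)
            else:
                loss = ad.softmax_cross_entropy(unary, tags, weights=mask)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.data)
            total_tokens += int(lengths.sum())
        entry = {"epoch": epoch, "train_loss": total_loss,
                 "train_loss_per_token": total_loss / max(total_tokens, 1)}
        if dev_corpus:
            p, r, f1 = _dev_exact_f1(model, dev_corpus)
            entry.update(dev_precision=p, dev_recall=r, dev_f1=f1)
            if f1 > best_f1:
                best_f1, best_snap = f1, model.parameter_snapshot()
        history.append(entry)
        if epoch_callback is not None:
            epoch_callback(entry)
    if best_snap is not None:
        model.load_snapshot(best_snap)
    return model, history


def predict_tags(model: TaggerModel, sentences: list[list[str]],
                 batch_size: int = 256) -> list[list[str]]:
    """Decode BIO tag sequences for tokenized sentences (deterministic)."""
    cfg = model.config
    forbidden = (crf_mod.bio_forbidden_transitions(model.tags)
                 if cfg.constrain_decoding else None)
    out: list[list[str]] = []
    for lo in range(0, len(sentences), batch_size):
        chunk = sentences[lo:lo + batch_size]
        word_idx, char_idx, char_mask, mask, (_, lengths) = \
            _prepare_batch(model, chunk)
        unary = encode_batch(model, word_idx, char_idx, char_mask, mask,
                             training=False).data
        if cfg.head == "crf":
            trans = model.params["crf_trans"].data
            start = model.params["crf_start"].data
            stop = model.params["crf_stop"].data
            paths = crf_mod.batch_viterbi(unary, lengths, trans, start, stop,
                                          forbidden=forbidden)
        elif forbidden is not None:
            # softmax head with BIO constraints: zero-transition Viterbi
            K = len(model.tags)
            paths = crf_mod.batch_viterbi(unary, lengths, np.zeros((K, K)),
                                          np.zeros(K), np.zeros(K),
                                          forbidden=forbidden)
        else:
            paths = [list(np.argmax(unary[b, :lengths[b]], axis=1))
                     for b in range(len(chunk))]
        out.extend([[model.tags[i] for i in p] for p in paths])
    return out


def predict(model: TaggerModel, sentences: list[Sentence]) -> list[list[EntitySpan]]:
    """Predict ADR spans (with document character offsets) per sentence."""
    tag_seqs = predict_tags(model, [s.surfaces for s in sentences])
    return [bio_to_spans(sent, tags, invalid="repair")
            for sent, tags in zip(sentences, tag_seqs)]


# ---------------------------------------------------------------------------
# Dev metric + checkpointing
# ---------------------------------------------------------------------------


def _dev_exact_f1(model: TaggerModel, corpus: list[TaggedSentence]):
    """Exact-match P/R/F over token-index spans (micro counts)."""
    from .evaluation import exact_counts, prf
    from .corpus_io import Token

    pred_tags = predict_tags(model, [s for s, _ in corpus])
    tp = fp = fn = 0
    for (surfs, gold_tags), ptags in zip(corpus, pred_tags):
        sent = _dummy_sentence(surfs)
        gold = {(s.start, s.end) for s in bio_to_spans(sent, list(gold_tags))}
        pred = {(s.start, s.end) for s in bio_to_spans(sent, ptags)}
        c = exact_counts(gold, pred)
        tp, fp, fn = tp + c.TP, fp + c.FP, fn + c.FN
    from .evaluation import EvalCounts
    return prf(EvalCounts(tp, fp, fn))


def _dummy_sentence(surfaces: list[str]) -> Sentence:
    from .corpus_io import Token
    toks, off = [], 0
    for s in surfaces:
        toks.append(Token(s, off, off + len(s)))
        off += len(s) + 1
    return Sentence("dev", 0, tuple(toks))


def save_checkpoint(model: TaggerModel, path) -> None:
    """Single-archive checkpoint: config + vocabularies + parameter arrays."""
    meta = {
        "config": {**asdict(model.config),
                   "char_cnn": asdict(model.config.char_cnn)},
        "tags": list(model.tags),
        "word_vocab": model.word_vocab,
    }
    arrays = {k: v.data for k, v in model.params.items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode("utf8"), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> TaggerModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode("utf8"))
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg_d = meta["config"]
    cc_d = cfg_d.pop("char_cnn")
    cc_d["filter_widths"] = tuple(cc_d["filter_widths"])
    config = TaggerConfig(**{**cfg_d, "char_cnn": CharCNNConfig(**cc_d)})
    emb = EmbeddingTable(meta["word_vocab"], arrays["word_emb"], (0.0, 0.0))
    model = TaggerModel(config, emb, tags=tuple(meta["tags"]))
    model.load_snapshot(arrays)
    return model
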