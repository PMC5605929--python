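"""Neural tagger: embeddings, char-CNN, encoder, training, prediction."""

import io

import numpy as np
import pytest

from adrtag import crf, synthetic, tagger
from adrtag.corpus_io import TAGS
from adrtag.tagger import (
    CharCNNConfig,
    TaggerConfig,
    TaggerModel,
    load_checkpoint,
    load_embeddings,
    save_checkpoint,
)


def _emb_file(words, dim=4, lo=-0.3, hi=0.3, seed=0):
    rng = np.random.default_rng(seed)
    lines = [f"{len(words)} {dim}"]
    for w in words:
        lines.append(w + " " + " ".join(
            f"{v:.5f}" for v in rng.uniform(lo, hi, size=dim)))
    return io.StringIO("\n".join(lines) + "\n")


def tiny_model(head="crf", use_char_cnn=True, seed=0, **kw):
    vocab = ["pain", "nausea", "felt", "i", "the", "and"]
    table = load_embeddings(_emb_file(vocab), vocab, seed=seed)
    cc = CharCNNConfig(
        char_vocabulary={c: i for i, c in enumerate(
            ["<pad>", "<unk>"] + sorted(set("".join(vocab))))},
        char_embedding_dim=5, filter_widths=(2, 3), filters_per_width=4,
        max_word_length=12)
    cfg = TaggerConfig(cell="GRU", num_layers=1, hidden_size=8,
                       dropout_rate=0.0, use_char_cnn=use_char_cnn,
                       head=head, seed=seed, char_cnn=cc, **kw)
    return TaggerModel(cfg, table)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------


def test_load_embeddings_full_coverage():
    table = load_embeddings(_emb_file(["pain", "ache"]), ["pain", "ache"])
    assert table.n_oov == 0


def test_load_embeddings_oov_sampled_within_file_range():
    words = [f"w{i}" for i in range(100)]
    table = load_embeddings(_emb_file(words[:97]), words, seed=5)
    assert table.n_oov == 3
    lo, hi = table.oov_policy
    for w in words[97:]:
        vec = table.vectors[table.vocabulary[w]]
        assert np.all(vec >= lo) and np.all(vec <= hi)
    for w in words[:97]:  # in-vocabulary words keep their file vectors
        assert w in table.vocabulary


def test_load_embeddings_deterministic():
    words = [f"w{i}" for i in range(20)]
    t1 = load_embeddings(_emb_file(words[:15]), words, seed=9)
    t2 = load_embeddings(_emb_file(words[:15]), words, seed=9)
    assert np.array_equal(t1.vectors, t2.vectors)


def test_load_embeddings_dimension_mismatch():
    bad = io.StringIO("2 3\na 0.1 0.2 0.3\nb 0.1 0.2\n")
    with pytest.raises(ValueError, match="components"):
        load_embeddings(bad, ["a", "b"])


# ---------------------------------------------------------------------------
# char-CNN
# ---------------------------------------------------------------------------


def test_char_features_zero_weights_zero_output():
    model = tiny_model()
    for w in model.config.char_cnn.filter_widths:
        model.params[f"conv{w}_W"].data[:] = 0.0
        model.params[f"conv{w}_b"].data[:] = 0.0
    assert np.allclose(tagger.char_features("pain", model), 0.0)


def test_char_features_width1_copy_filter_is_max_over_chars():
    """A width-1 filter copying one embedding coordinate max-pools to the
    maximum of that coordinate over the word's characters."""
    vocab = ["ab"]
    table = load_embeddings(_emb_file(vocab), vocab)
    cc = CharCNNConfig(char_vocabulary={"<pad>": 0, "<unk>": 1, "a": 2, "b": 3,
                                        "c": 4},
                       char_embedding_dim=3, filter_widths=(1,),
                       filters_per_width=1, max_word_length=8)
    cfg = TaggerConfig(num_layers=1, hidden_size=4, dropout_rate=0.0,
                       char_cnn=cc, seed=1)
    model = TaggerModel(cfg, table)
    W = model.params["conv1_W"]
    W.data[:] = 0.0
    W.data[0, 0] = 1.0  # copy coordinate 0 of the char embedding
    model.params["conv1_b"].data[:] = 0.0
    for word in ("ab", "ba", "abc", "cab"):
        expected = max(model.params["char_emb"].data[model.char_vocab[c], 0]
                       for c in word)
        got = tagger.char_features(word, model)
        assert got.shape == (1,)
        assert got[0] == pytest.approx(expected)


def test_char_features_width1_permutation_invariant():
    model = tiny_model()
    cc = model.config.char_cnn
    # keep only width-2 filters out of the picture: compare words under
    # a width-adapted model
    vocab = ["x"]
    table = load_embeddings(_emb_file(vocab), vocab)
    cc1 = CharCNNConfig(char_vocabulary=dict(cc.char_vocabulary),
                        char_embedding_dim=5, filter_widths=(1,),
                        filters_per_width=6, max_word_length=12)
    cfg = TaggerConfig(num_layers=1, hidden_size=4, dropout_rate=0.0,
                       char_cnn=cc1, seed=3)
    m = TaggerModel(cfg, table)
    a = tagger.char_features("pain", m)
    b = tagger.char_features("nipa", m)
    assert np.allclose(a, b)


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------


def test_encode_eval_mode_deterministic_and_shaped():
    model = tiny_model()
    s = ["i", "felt", "pain"]
    a, b = tagger.encode(model, s), tagger.encode(model, s)
    assert a.shape == (3, len(TAGS))
    assert np.array_equal(a, b)


def test_encode_zero_network_zero_lattice():
    model = tiny_model(use_char_cnn=False)
    for name, p in model.params.items():
        if name.startswith(("l0", "dense")):
            p.data[:] = 0.0
    assert np.allclose(tagger.encode(model, ["pain", "and", "nausea"]), 0.0)


def test_encode_empty_sentence_raises():
    with pytest.raises(ValueError):
        tagger.encode(tiny_model(), [])


@pytest.mark.parametrize("cell", ["GRU", "LSTM"])
def test_encoder_gradients_match_finite_differences(cell):
    """End-to-end check: d(loss)/d(params) through char-CNN + BiRNN + CRF."""
    from adrtag import _autodiff as ad

    model = tiny_model()
    model.config.cell = cell
    model = TaggerModel(model.config, load_embeddings(
        _emb_file(["pain", "i"]), ["pain", "i"]))
    sents = [["i", "pain"], ["pain"]]
    tags = [[0, 1], [1]]
    word_idx, char_idx, char_mask, mask, (tg, lengths) = \
        tagger._prepare_batch(model, sents, tags)

    def loss_value():
        unary = tagger.encode_batch(model, word_idx, char_idx, char_mask,
                                    mask, training=False)
        return tagger._crf_loss(model, unary, tg, lengths)

    for p in model.params.values():
        p.zero_grad()
    loss_value().backward()
    eps = 1e-6
    for name in ("l0f_W", "l0f_U", "l0b_b", "dense_W", "crf_trans",
                 "char_emb", "conv2_W", "word_emb"):
        p = model.params[name]
        flat = p.data.reshape(-1)
        for i in np.random.default_rng(1).choice(flat.size,
                                                 size=min(6, flat.size),
                                                 replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            fp = float(loss_value().data)
            flat[i] = orig - eps
            fm = float(loss_value().data)
            flat[i] = orig
            num = (fp - fm) / (2 * eps)
            ana = p.grad.reshape(-1)[i]
            assert abs(num - ana) < 1e-5 * max(1.0, abs(num)), (name, i)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


def _tiny_corpus():
    return [(["i", "felt", "pain", "and", "nausea"],
             ["O", "O", "B-ADR", "O", "B-ADR"])]


def test_training_memorizes_single_sentence():
    corpus = _tiny_corpus()
    vocab = sorted({w for s, _ in corpus for w in s})
    table = load_embeddings(_emb_file(vocab), vocab)
    cfg = TaggerConfig(num_layers=1, hidden_size=12, dropout_rate=0.0,
                       use_char_cnn=False, head="crf", batch_size=4,
                       max_epochs=200, learning_rate=0.02, seed=2)
    model, hist = tagger.train(corpus, None, cfg, table)
    assert hist[-1]["train_loss"] < 0.01
    pred = tagger.predict_tags(model, [corpus[0][0]])[0]
    assert pred == corpus[0][1]


def test_training_loss_decreases_early():
    corpus = synthetic.tagged_sentences(
        synthetic.generate(synthetic.GeneratorConfig(
            n_documents=25, seed=4)).documents)
    vocab = sorted({w.lower() for s, _ in corpus for w in s})
    table = load_embeddings(_emb_file(vocab, dim=16), vocab)
    cfg = TaggerConfig(num_layers=1, hidden_size=16, use_char_cnn=False,
                       head="crf", batch_size=32, max_epochs=5, seed=0)
    _, hist = tagger.train(corpus, None, cfg, table)
    losses = [h["train_loss"] for h in hist]
    assert all(b < a for a, b in zip(losses, losses[1:]))


def test_training_reproducible_with_fixed_seed():
    corpus = _tiny_corpus() * 6
    vocab = sorted({w for s, _ in corpus for w in s})
    cfg = dict(num_layers=1, hidden_size=8, dropout_rate=0.0,
               use_char_cnn=False, head="softmax", batch_size=4,
               max_epochs=3, seed=7)
    runs = []
    for _ in range(2):
        table = load_embeddings(_emb_file(vocab), vocab, seed=7)
        model, hist = tagger.train(corpus, None, TaggerConfig(**cfg), table)
        runs.append([h["train_loss"] for h in hist])
    assert runs[0] == runs[1]


def test_untrained_zero_model_predicts_no_spans():
    model = tiny_model()
    for name, p in model.params.items():
        if name.startswith(("l0", "dense", "crf")):
            p.data[:] = 0.0
    model.config.constrain_decoding = True
    spans = tagger.predict(model, [_dummy_sent(["i", "felt", "pain"])])
    assert spans == [[]]  # tie-break to tag 0 = O everywhere


def _dummy_sent(surfaces):
    from adrtag.corpus_io import Sentence, Token
    toks, off = [], 0
    for s in surfaces:
        toks.append(Token(s, off, off + len(s)))
        off += len(s) + 1
    return Sentence("d", 0, tuple(toks))


def test_softmax_predictions_decode_to_valid_spans(rng):
    """Orphan I-ADR emissions always repair to well-formed spans."""
    from adrtag.corpus_io import bio_to_spans

    for _ in range(1000):
        n = int(rng.integers(1, 10))
        tags = [TAGS[i] for i in rng.integers(0, 3, size=n)]
        sent = _dummy_sent(["w"] * n)
        spans = bio_to_spans(sent, tags, invalid="repair")
        for a, b in zip(spans, spans[1:]):
            assert a.end <= b.start
        # every non-O tag is covered by exactly one span
        covered = sum(1 for t in sent.tokens
                      if any(s.start <= t.start < s.end for s in spans))
        assert covered == sum(1 for t in tags if t != "O")


def test_checkpoint_roundtrip(tmp_path):
    corpus = _tiny_corpus()
    vocab = sorted({w for s, _ in corpus for w in s})
    table = load_embeddings(_emb_file(vocab), vocab)
    cfg = TaggerConfig(num_layers=1, hidden_size=8, dropout_rate=0.0,
                       head="crf", batch_size=2, max_epochs=5, seed=3)
    model, _ = tagger.train(corpus, None, cfg, table)
    path = tmp_path / "ck.npz"
    save_checkpoint(model, path)
    loaded = load_checkpoint(path)
    sent = ["i", "felt", "pain"]
    assert np.allclose(tagger.encode(model, sent), tagger.encode(loaded, sent))
    assert tagger.predict_tags(model, [sent]) == \
        tagger.predict_tags(loaded, [sent])
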