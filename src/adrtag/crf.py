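"""Linear-chain conditional random field over tag sequences.

The model assigns a label sequence :math:`y_{1..n}` the unnormalized
log-score

.. math::

    s(x, y) = \\mathrm{start}_{y_1} + \\sum_{t=2}^{n} A_{y_{t-1}, y_t}
              + \\sum_{t=1}^{n} U_{t, y_t} + \\mathrm{stop}_{y_n}

where ``U`` is the matrix of per-position unary scores (here emitted by
a neural encoder), ``A`` is the tag-transition matrix (row = from-tag,
column = to-tag), and learned start/stop vectors handle the chain
boundaries (equivalently a virtual BOS/EOS tag).  The conditional
probability is ``exp(s(x, y)) / Z(x)`` with the partition function
``Z(x)`` summing over all ``|Y|^n`` paths.

Everything is computed in log space with log-sum-exp stabilization;
``log Z``, the NLL gradient (via forward-backward marginals) and Viterbi
decoding all run in ``O(n |Y|^2)``.  Batched variants accept padded
``(B, T, |Y|)`` arrays with explicit per-sequence lengths; padded
positions contribute nothing to score, partition, or loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScoreLattice",
    "sequence_score",
    "log_partition",
    "nll",
    "nll_and_grad",
    "viterbi",
    "constrained_viterbi",
    "bio_forbidden_transitions",
    "batch_log_partition",
    "batch_sequence_score",
    "batch_nll_and_grads",
    "batch_viterbi",
]


@dataclass
class ScoreLattice:
    """Per-token unary tag scores plus tag-transition scores.

    ``unary`` is ``(n, |Y|)``; ``transitions`` is ``(|Y|, |Y|)`` with
    entry ``[i, j]`` scoring the move from tag ``i`` to tag ``j``.
    ``start``/``stop`` default to zero vectors (no boundary preference).
    """

    unary: np.ndarray
    transitions: np.ndarray
    start: np.ndarray = field(default=None)  # type: ignore[assignment]
    stop: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.unary = np.asarray(self.unary, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.unary.ndim != 2 or self.unary.shape[0] < 1:
            raise ValueError("unary must be (n >= 1, |Y|)")
        k = self.unary.shape[1]
        if self.transitions.shape != (k, k):
            raise ValueError("transitions must be (|Y|, |Y|)")
        self.start = (
            np.zeros(k) if self.start is None else np.asarray(self.start, dtype=float)
        )
        self.stop = (
            np.zeros(k) if self.stop is None else np.asarray(self.stop, dtype=float)
        )
        if self.start.shape != (k,) or self.stop.shape != (k,):
            raise ValueError("start/stop must be length-|Y| vectors")
        if not np.all(np.isfinite(self.unary)):
            raise ValueError("unary scores must be finite")
        # -inf is allowed in transitions/start/stop: it encodes hard
        # constraints (forbidden transitions or start/stop states)
        for arr in (self.transitions, self.start, self.stop):
            if np.any(np.isposinf(arr)) or np.any(np.isnan(arr)):
                raise ValueError("transition scores must be finite or -inf")

    @property
    def n(self) -> int:
        return self.unary.shape[0]

    @property
    def n_tags(self) -> int:
        return self.unary.shape[1]


def _check_path(lattice: ScoreLattice, path: np.ndarray) -> np.ndarray:
    path = np.asarray(path, dtype=int)
    if path.shape != (lattice.n,):
        raise ValueError(f"path length {path.shape} != lattice length {lattice.n}")
    if path.min() < 0 or path.max() >= lattice.n_tags:
        raise ValueError("path contains out-of-range tag indices")
    return path


def sequence_score(lattice: ScoreLattice, path) -> float:
    """Unnormalized log-score of one tag path (the log-numerator)."""
    path = _check_path(lattice, path)
    score = lattice.start[path[0]] + lattice.stop[path[-1]]
    score += lattice.unary[np.arange(lattice.n), path].sum()
    if lattice.n > 1:
        score += lattice.transitions[path[:-1], path[1:]].sum()
    return float(score)


def log_partition(lattice: ScoreLattice) -> float:
    """``log Z``: log-sum-exp of sequence_score over all tag paths."""
    from scipy.special import logsumexp

    alpha = lattice.start + lattice.unary[0]
    for t in range(1, lattice.n):
        # alpha[j] = LSE_i(alpha[i] + A[i,j]) + U[t,j]
        alpha = logsumexp(alpha[:, None] + lattice.transitions, axis=0) + lattice.unary[t]
    return float(logsumexp(alpha + lattice.stop))


def nll(lattice: ScoreLattice, gold) -> float:
    """Negative log-likelihood of the gold path: ``log Z - s(x, gold)``."""
    return log_partition(lattice) - sequence_score(lattice, gold)


def _forward_backward(lattice: ScoreLattice):
    """Forward/backward log messages; returns (alpha, beta, logZ)."""
    from scipy.special import logsumexp

    n, k = lattice.n, lattice.n_tags
    alpha = np.empty((n, k))
    beta = np.empty((n, k))
    alpha[0] = lattice.start + lattice.unary[0]
    for t in range(1, n):
        alpha[t] = (
            logsumexp(alpha[t - 1][:, None] + lattice.transitions, axis=0)
            + lattice.unary[t]
        )
    beta[-1] = lattice.stop
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(
            lattice.transitions + (lattice.unary[t + 1] + beta[t + 1])[None, :], axis=1
        )
    log_z = float(logsumexp(alpha[-1] + lattice.stop))
    return alpha, beta, log_z


def nll_and_grad(lattice: ScoreLattice, gold):
    """NLL and its analytic gradients w.r.t. every lattice component.

    The gradient of ``log Z`` is the vector of model marginals, so the
    NLL gradient is marginals minus the gold indicator counts:
    ``d nll / d U[t, y] = p(y_t = y | x) - 1[gold_t = y]`` and likewise
    for transitions (pairwise marginals) and start/stop.
    """
    gold = _check_path(lattice, gold)
    n, k = lattice.n, lattice.n_tags
    alpha, beta, log_z = _forward_backward(lattice)

    # unary marginals p(y_t = j)
    marg = np.exp(alpha + beta - log_z)

    # pairwise marginals p(y_{t-1}=i, y_t=j), accumulated into (k, k)
    grad_trans = np.zeros((k, k))
    for t in range(1, n):
        log_pair = (
            alpha[t - 1][:, None]
            + lattice.transitions
            + (lattice.unary[t] + beta[t])[None, :]
            - log_z
        )
        grad_trans += np.exp(log_pair)

    grad_unary = marg.copy()
    grad_unary[np.arange(n), gold] -= 1.0
    if n > 1:
        np.subtract.at(grad_trans, (gold[:-1], gold[1:]), 1.0)
    grad_start = marg[0].copy() if n >= 1 else np.zeros(k)
    # start marginal equals p(y_1); recompute directly for clarity
    grad_start = np.exp(alpha[0] + beta[0] - log_z)
    grad_start[gold[0]] -= 1.0
    grad_stop = np.exp(alpha[-1] + lattice.stop - log_z)
    grad_stop[gold[-1]] -= 1.0

    value = log_z - sequence_score(lattice, gold)
    return value, {
        "unary": grad_unary,
        "transitions": grad_trans,
        "start": grad_start,
        "stop": grad_stop,
    }


def viterbi(lattice: ScoreLattice) -> tuple[list[int], float]:
    """Highest-scoring tag path and its score (max-product decoding).

    Ties break to the lowest tag index at every position, making the
    output deterministic.
    """
    n, k = lattice.n, lattice.n_tags
    delta = lattice.start + lattice.unary[0]
    back = np.empty((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + lattice.transitions  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # argmax returns lowest index on ties
        delta = cand[back[t], np.arange(k)] + lattice.unary[t]
    delta = delta + lattice.stop
    last = int(np.argmax(delta))
    score = float(delta[last])
    path = [last]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t][path[-1]]))
    path.reverse()
    return path, score


def bio_forbidden_transitions(tags=("O", "B-ADR", "I-ADR")) -> set[tuple[int, int]]:
    """Transition pairs forbidden by the BIO grammar.

    ``I-X`` may only follow ``B-X`` or ``I-X``; the virtual start state
    is encoded as from-index ``-1``.
    """
    forbidden: set[tuple[int, int]] = set()
    for j, tj in enumerate(tags):
        if not tj.startswith("I-"):
            continue
        ent = tj[2:]
        forbidden.add((-1, j))  # start -> I
        for i, ti in enumerate(tags):
            if ti not in (f"B-{ent}", f"I-{ent}"):
                forbidden.add((i, j))
    return forbidden


def constrained_viterbi(
    lattice: ScoreLattice, forbidden_transitions: set[tuple[int, int]]
) -> tuple[list[int], float]:
    """Viterbi restricted to paths avoiding the given transitions.

    ``(-1, j)`` forbids starting in tag ``j``.  Implemented by masking
    the corresponding scores to ``-inf``; raises if no path is feasible.
    """
    trans = lattice.transitions.copy()
    start = lattice.start.copy()
    for i, j in forbidden_transitions:
        if i == -1:
            start[j] = -np.inf
        else:
            trans[i, j] = -np.inf
    masked = ScoreLattice(lattice.unary, trans, start, lattice.stop)
    path, score = viterbi(masked)
    if not np.isfinite(score):
        raise ValueError("no feasible path under the given constraints")
    return path, score


# ---------------------------------------------------------------------------
# Batched (padded) variants used by the neural tagger's training loop.
# All accept unary (B, T, K), integer lengths (B,), shared transitions /
# start / stop; positions at or beyond a sequence's length are ignored.
# ---------------------------------------------------------------------------


def _logsumexp_last(x: np.ndarray) -> np.ndarray:
    m = np.max(x, axis=-1, keepdims=True)
    return (m + np.log(np.sum(np.exp(x - m), axis=-1, keepdims=True)))[..., 0]


def batch_sequence_score(unary, tags, lengths, transitions, start, stop) -> np.ndarray:
    """Gold-path scores for a padded batch; returns (B,)."""
    B, T, K = unary.shape
    tags = np.asarray(tags, dtype=int)
    lengths = np.asarray(lengths, dtype=int)
    pos = np.arange(T)[None, :]
    mask = pos < lengths[:, None]
    rows = np.arange(B)[:, None]
    un = unary[rows, pos, tags] * mask
    score = un.sum(axis=1) + start[tags[:, 0]]
    if T > 1:
        tmask = pos[:, 1:] < lengths[:, None]
        tr = transitions[tags[:, :-1], tags[:, 1:]] * tmask
        score = score + tr.sum(axis=1)
    last = tags[np.arange(B), lengths - 1]
    return score + stop[last]


def batch_log_partition(unary, lengths, transitions, start, stop) -> np.ndarray:
    """log Z per sequence for a padded batch; returns (B,)."""
    from scipy.special import logsumexp

    B, T, K = unary.shape
    lengths = np.asarray(lengths, dtype=int)
    alpha = start[None, :] + unary[:, 0, :]
    result = np.where(lengths == 1, _logsumexp_last(alpha + stop[None, :]), 0.0)
    for t in range(1, T):
        # alpha'[b, j] = LSE_i(alpha[b, i] + A[i, j]) + U[b, t, j]
        new_alpha = (
            logsumexp(alpha[:, :, None] + transitions[None, :, :], axis=1)
            + unary[:, t, :]
        )
        active = (t < lengths)[:, None]
        alpha = np.where(active, new_alpha, alpha)
        done_now = lengths == t + 1
        if np.any(done_now):
            z = _logsumexp_last(alpha + stop[None, :])
            result = np.where(done_now, z, result)
    return result


def _lse(x: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    return np.squeeze(m, axis) + np.log(np.sum(np.exp(x - m), axis=axis))


def batch_nll_and_grads(unary, tags, lengths, transitions, start, stop):
    """Summed NLL over a padded batch plus gradients for every input.

    Returns ``(total_nll, grad_unary, grad_transitions, grad_start,
    grad_stop)``.  The forward-backward recursions run vectorized over
    the batch; entries at or beyond a sequence's length are never read.
    """
    B, T, K = unary.shape
    lengths = np.asarray(lengths, dtype=int)
    tags = np.asarray(tags, dtype=int)
    rows = np.arange(B)

    alpha = np.empty((B, T, K))
    alpha[:, 0] = start[None, :] + unary[:, 0]
    for t in range(1, T):
        alpha[:, t] = (
            _lse(alpha[:, t - 1, :, None] + transitions[None, :, :], axis=1)
            + unary[:, t]
        )
    beta = np.zeros((B, T, K))
    beta[rows, lengths - 1] = stop[None, :]
    for t in range(T - 2, -1, -1):
        interior = t < lengths - 1
        if np.any(interior):
            val = _lse(
                transitions[None, :, :]
                + (unary[:, t + 1] + beta[:, t + 1])[:, None, :], axis=2)
            beta[:, t] = np.where(interior[:, None], val, beta[:, t])
    log_z = _lse(alpha[rows, lengths - 1] + stop[None, :], axis=1)

    valid = np.arange(T)[None, :] < lengths[:, None]  # (B, T)
    log_marg = np.where(valid[:, :, None],
                        alpha + beta - log_z[:, None, None], -np.inf)
    grad_unary = np.exp(log_marg)
    np.subtract.at(grad_unary, (rows[:, None], np.arange(T)[None, :], tags),
                   valid.astype(float))

    grad_trans = np.zeros_like(transitions)
    for t in range(1, T):
        active = t < lengths
        if not np.any(active):
            break
        log_pair = (
            alpha[active, t - 1, :, None]
            + transitions[None, :, :]
            + (unary[active, t] + beta[active, t])[:, None, :]
            - log_z[active, None, None]
        )
        grad_trans += np.exp(log_pair).sum(axis=0)
    tmask = (np.arange(1, T)[None, :] < lengths[:, None])
    if T > 1:
        np.subtract.at(grad_trans,
                       (tags[:, :-1][tmask], tags[:, 1:][tmask]), 1.0)

    grad_start = np.exp(alpha[:, 0] + beta[:, 0] - log_z[:, None])
    np.subtract.at(grad_start, (rows, tags[:, 0]), 1.0)
    grad_start = grad_start.sum(axis=0)
    grad_stop = np.exp(alpha[rows, lengths - 1] + stop[None, :]
                       - log_z[:, None])
    np.subtract.at(grad_stop, (rows, tags[rows, lengths - 1]), 1.0)
    grad_stop = grad_stop.sum(axis=0)

    gold = batch_sequence_score(unary, tags, lengths, transitions, start, stop)
    total = float((log_z - gold).sum())
    return total, grad_unary, grad_trans, grad_start, grad_stop


def batch_viterbi(unary, lengths, transitions, start, stop,
                  forbidden: set[tuple[int, int]] | None = None) -> list[list[int]]:
    """Decode each sequence of a padded batch; returns a list of paths.

    The max-product recursion is vectorized over the batch; only the
    backtrace runs per sequence.  Ties break to the lowest tag index.
    """
    B, T, K = unary.shape
    lengths = np.asarray(lengths, dtype=int)
    trans = transitions.astype(float).copy()
    start = start.astype(float).copy()
    if forbidden:
        for i, j in forbidden:
            if i == -1:
                start[j] = -np.inf
            else:
                trans[i, j] = -np.inf
    delta = start[None, :] + unary[:, 0]
    back = np.zeros((B, T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, :, None] + trans[None, :, :]  # (B, from, to)
        back[:, t] = np.argmax(cand, axis=1)
        new_delta = np.take_along_axis(
            cand, back[:, t][:, None, :], axis=1)[:, 0, :] + unary[:, t]
        delta = np.where((t < lengths)[:, None], new_delta, delta)
    final = delta + stop[None, :]
    if forbidden and not np.all(np.isfinite(final.max(axis=1))):
        raise ValueError("no feasible path under the given constraints")
    last = np.argmax(final, axis=1)
    paths: list[list[int]] = []
    for b in range(B):
        n = int(lengths[b])
        path = [int(last[b])]
        for t in range(n - 1, 0, -1):
            path.append(int(back[b, t, path[-1]]))
        path.reverse()
        paths.append(path)
    return paths
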