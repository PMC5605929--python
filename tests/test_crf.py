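"""Linear-chain CRF: scoring, partition, NLL gradients, Viterbi.

The independent oracle throughout is exhaustive path enumeration, which
is exact for the small lattices used here (n <= 6, |Y| <= 4).
"""

from itertools import product

import numpy as np
import pytest
from scipy.special import logsumexp

from adrtag import crf
from adrtag.crf import (
    ScoreLattice,
    bio_forbidden_transitions,
    constrained_viterbi,
    log_partition,
    nll,
    nll_and_grad,
    sequence_score,
    viterbi,
)


def random_lattice(rng, n=None, k=None, with_boundary=True):
    n = n or int(rng.integers(1, 7))
    k = k or int(rng.integers(2, 5))
    return ScoreLattice(
        rng.normal(size=(n, k)), rng.normal(size=(k, k)),
        rng.normal(size=k) if with_boundary else None,
        rng.normal(size=k) if with_boundary else None,
    )


def enumerate_scores(lat):
    return [sequence_score(lat, list(p))
            for p in product(range(lat.n_tags), repeat=lat.n)]


def naive_score(lat, path):
    """Term-by-term summation, written independently of sequence_score."""
    total = lat.start[path[0]]
    for t, y in enumerate(path):
        total += lat.unary[t, y]
        if t > 0:
            total += lat.transitions[path[t - 1], y]
    return total + lat.stop[path[-1]]


# ---------------------------------------------------------------------------
# sequence_score
# ---------------------------------------------------------------------------


def test_sequence_score_zero_lattice():
    lat = ScoreLattice(np.zeros((4, 3)), np.zeros((3, 3)))
    assert sequence_score(lat, [0, 1, 2, 0]) == 0.0


def test_sequence_score_single_position():
    lat = ScoreLattice(np.array([[1.5, -0.5]]), np.zeros((2, 2)))
    assert sequence_score(lat, [0]) == pytest.approx(1.5)


def test_sequence_score_matches_naive_oracle(rng):
    for _ in range(200):
        lat = random_lattice(rng, k=3)
        path = rng.integers(0, 3, size=lat.n)
        assert sequence_score(lat, path) == pytest.approx(
            naive_score(lat, list(path)), abs=1e-10)


def test_sequence_score_length_mismatch():
    lat = ScoreLattice(np.zeros((3, 2)), np.zeros((2, 2)))
    with pytest.raises(ValueError):
        sequence_score(lat, [0, 1])


# ---------------------------------------------------------------------------
# log_partition
# ---------------------------------------------------------------------------


def test_log_partition_uniform_lattice():
    lat = ScoreLattice(np.zeros((3, 2)), np.zeros((2, 2)))
    assert log_partition(lat) == pytest.approx(3 * np.log(2), abs=1e-12)


def test_log_partition_single_position_closed_form():
    a, b = 0.7, -1.2
    lat = ScoreLattice(np.array([[a, b]]), np.zeros((2, 2)))
    assert log_partition(lat) == pytest.approx(np.log(np.exp(a) + np.exp(b)))


def test_log_partition_matches_enumeration(rng):
    for _ in range(200):
        lat = random_lattice(rng)
        assert log_partition(lat) == pytest.approx(
            logsumexp(enumerate_scores(lat)), abs=1e-8)


def test_log_partition_unary_shift_covariance(rng):
    """Adding c to every unary score at one position adds exactly c."""
    lat = random_lattice(rng, n=5, k=3)
    base = log_partition(lat)
    shifted = lat.unary.copy()
    shifted[2] += 3.7
    lat2 = ScoreLattice(shifted, lat.transitions, lat.start, lat.stop)
    assert log_partition(lat2) == pytest.approx(base + 3.7, abs=1e-10)


def test_path_probabilities_sum_to_one(rng):
    for _ in range(20):
        lat = random_lattice(rng, n=int(rng.integers(1, 6)))
        lz = log_partition(lat)
        total = sum(np.exp(s - lz) for s in enumerate_scores(lat))
        assert total == pytest.approx(1.0, abs=1e-10)


# ---------------------------------------------------------------------------
# nll
# ---------------------------------------------------------------------------


def test_nll_uniform_lattice():
    lat = ScoreLattice(np.zeros((2, 2)), np.zeros((2, 2)))
    assert nll(lat, [1, 0]) == pytest.approx(2 * np.log(2))


def test_nll_favoring_gold_is_tiny():
    gold = [0, 1, 2, 1]
    unary = np.zeros((4, 3))
    unary[np.arange(4), gold] = 10.0
    lat = ScoreLattice(unary, np.zeros((3, 3)))
    assert 0.0 <= nll(lat, gold) < 0.01


def test_nll_nonnegative_and_matches_enumeration(rng):
    for _ in range(50):
        lat = random_lattice(rng)
        gold = rng.integers(0, lat.n_tags, size=lat.n)
        value = nll(lat, gold)
        assert value >= -1e-12
        expected = logsumexp(enumerate_scores(lat)) - sequence_score(lat, gold)
        assert value == pytest.approx(expected, abs=1e-8)


def test_nll_gradient_matches_finite_differences(rng):
    """Analytic gradients vs central differences, all lattice components."""
    eps, tol = 1e-6, 1e-4
    for _ in range(50):
        lat = random_lattice(rng, n=int(rng.integers(1, 6)), k=3)
        gold = rng.integers(0, 3, size=lat.n)
        _, grads = nll_and_grad(lat, gold)

        def perturbed(component, index, delta):
            arrays = {"unary": lat.unary.copy(),
                      "transitions": lat.transitions.copy(),
                      "start": lat.start.copy(), "stop": lat.stop.copy()}
            arrays[component][index] += delta
            return nll(ScoreLattice(arrays["unary"], arrays["transitions"],
                                    arrays["start"], arrays["stop"]), gold)

        for comp in ("unary", "transitions", "start", "stop"):
            arr = getattr(lat, comp if comp != "transitions" else "transitions")
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                num = (perturbed(comp, idx, eps)
                       - perturbed(comp, idx, -eps)) / (2 * eps)
                ana = grads[comp][idx]
                assert abs(num - ana) <= tol * max(1.0, abs(num)), (comp, idx)


# ---------------------------------------------------------------------------
# viterbi
# ---------------------------------------------------------------------------


def test_viterbi_single_position():
    lat = ScoreLattice(np.array([[2.0, 1.0, 0.0]]), np.zeros((3, 3)))
    assert viterbi(lat) == ([0], 2.0)


def test_viterbi_tie_breaks_to_lowest_index():
    lat = ScoreLattice(np.zeros((4, 3)), np.zeros((3, 3)))
    path, score = viterbi(lat)
    assert path == [0, 0, 0, 0] and score == 0.0


def test_viterbi_matches_enumeration(rng):
    for _ in range(200):
        lat = random_lattice(rng)
        path, score = viterbi(lat)
        assert score == pytest.approx(max(enumerate_scores(lat)), abs=1e-10)
        assert sequence_score(lat, path) == pytest.approx(score, abs=1e-10)


def test_viterbi_dominates_sampled_paths(rng):
    lat = random_lattice(rng, n=6, k=3)
    _, best = viterbi(lat)
    for _ in range(1000):
        assert best >= sequence_score(lat, rng.integers(0, 3, size=6)) - 1e-10


def test_viterbi_argmax_scale_covariant(rng):
    lat = random_lattice(rng, n=5, k=3, with_boundary=False)
    path1, _ = viterbi(lat)
    lat2 = ScoreLattice(2.0 * lat.unary, 2.0 * lat.transitions)
    path2, _ = viterbi(lat2)
    assert path1 == path2


# ---------------------------------------------------------------------------
# constrained viterbi
# ---------------------------------------------------------------------------


def test_constrained_empty_set_equals_viterbi(rng):
    for _ in range(20):
        lat = random_lattice(rng)
        assert constrained_viterbi(lat, set()) == viterbi(lat)


def test_constrained_forces_bio_validity():
    # adversarial lattice: O then I-ADR is the unconstrained optimum
    unary = np.array([[5.0, 0.0, 0.0], [0.0, 0.0, 5.0]])
    lat = ScoreLattice(unary, np.zeros((3, 3)))
    unconstrained, _ = viterbi(lat)
    assert unconstrained == [0, 2]  # O, I-ADR: invalid BIO
    path, _ = constrained_viterbi(lat, bio_forbidden_transitions())
    assert path != unconstrained
    assert _is_bio_valid(path)


def _is_bio_valid(path):
    prev = None
    for y in path:
        if y == 2 and prev not in (1, 2):  # I-ADR after O/start
            return False
        prev = y
    return True


def test_constrained_matches_filtered_enumeration(rng):
    forbidden = bio_forbidden_transitions()
    for _ in range(100):
        lat = random_lattice(rng, k=3)
        path, score = constrained_viterbi(lat, forbidden)
        valid = [p for p in product(range(3), repeat=lat.n)
                 if _is_bio_valid(p)]
        best = max(sequence_score(lat, list(p)) for p in valid)
        assert score == pytest.approx(best, abs=1e-10)
        assert _is_bio_valid(path)


def test_constrained_infeasible_raises():
    lat = ScoreLattice(np.zeros((1, 2)), np.zeros((2, 2)))
    with pytest.raises(ValueError, match="feasible"):
        constrained_viterbi(lat, {(-1, 0), (-1, 1)})


# ---------------------------------------------------------------------------
# batched contract
# ---------------------------------------------------------------------------


def test_batched_ops_match_single_sequence(rng):
    """Padded positions contribute nothing to score, partition or loss."""
    B, T, K = 5, 7, 3
    unary = rng.normal(size=(B, T, K))
    trans, start, stop = rng.normal(size=(K, K)), rng.normal(size=K), rng.normal(size=K)
    lengths = rng.integers(1, T + 1, size=B)
    tags = rng.integers(0, K, size=(B, T))
    lz = crf.batch_log_partition(unary, lengths, trans, start, stop)
    sc = crf.batch_sequence_score(unary, tags, lengths, trans, start, stop)
    total, gU, *_ = crf.batch_nll_and_grads(unary, tags, lengths, trans,
                                            start, stop)
    paths = crf.batch_viterbi(unary, lengths, trans, start, stop)
    expected_total = 0.0
    for b in range(B):
        n = int(lengths[b])
        lat = ScoreLattice(unary[b, :n], trans, start, stop)
        assert lz[b] == pytest.approx(log_partition(lat), abs=1e-10)
        assert sc[b] == pytest.approx(
            sequence_score(lat, tags[b, :n]), abs=1e-10)
        expected_total += nll(lat, tags[b, :n])
        assert paths[b] == viterbi(lat)[0]
        assert np.all(gU[b, n:] == 0.0)  # padding receives zero gradient
    assert total == pytest.approx(expected_total, abs=1e-8)
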