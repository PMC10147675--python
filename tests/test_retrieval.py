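"""Loss-formula oracles (brute-force scalar evaluation) and exact-MIPS
equivalence with inner-product argsort."""

import math

import numpy as np
import pytest

from subretro.retrieval import (
    EmbeddingBatch,
    RetrievalIndex,
    bow_loss,
    build_index,
    combined_loss,
    rank_loss,
    score_matrix,
)


def brute_rank_loss(S, i, variant):
    """Element-by-element scalar evaluation of the ranking loss."""
    num = math.exp(S[i][i])
    den = math.exp(S[i][i]) + sum(
        math.exp(S[i][j]) for j in range(len(S[i])) if j != i
    )
    p = num / den
    return -p if variant == "as_printed" else -math.log(p)


def brute_bow_loss(p_ids, r_ids, x, y, W, b):
    def log_probs(v):
        logits = [sum(v[k] * W[k][j] for k in range(len(v))) + b[j]
                  for j in range(len(b))]
        m = max(logits)
        z = sum(math.exp(l - m) for l in logits)
        return [l - m - math.log(z) for l in logits]

    lx, ly = log_probs(x), log_probs(y)
    return -sum(lx[t] for t in r_ids) - sum(ly[t] for t in p_ids)


def test_rank_loss_degenerate_single_pair():
    S = np.array([[3.7]])
    assert rank_loss(S, 0, "as_printed") == pytest.approx(-1.0)
    assert rank_loss(S, 0, "log_softmax") == pytest.approx(0.0)


def test_rank_loss_uniform_scores():
    S = np.zeros((4, 4))
    assert rank_loss(S, 2, "as_printed") == pytest.approx(-0.25)
    assert rank_loss(S, 2, "log_softmax") == pytest.approx(math.log(4))


@pytest.mark.parametrize("variant", ["log_softmax", "as_printed"])
def test_rank_loss_matches_scalar_oracle(variant):
    rng = np.random.default_rng(7)
    for _ in range(20):
        B = rng.integers(2, 8)
        S = rng.normal(size=(B, B)) * 2
        i = int(rng.integers(B))
        assert rank_loss(S, i, variant) == pytest.approx(
            brute_rank_loss(S.tolist(), i, variant), abs=1e-9
        )


def test_rank_loss_invariant_to_nontarget_column_permutation():
    rng = np.random.default_rng(8)
    S = rng.normal(size=(5, 5))
    i = 2
    base = rank_loss(S, i)
    permuted = S.copy()
    others = [j for j in range(5) if j != i]
    permuted[i, others] = S[i, list(reversed(others))]
    assert rank_loss(permuted, i) == pytest.approx(base, abs=1e-12)


def test_rank_loss_rejects_nonfinite():
    S = np.array([[1.0, np.inf], [0.0, 1.0]])
    with pytest.raises(ValueError):
        rank_loss(S, 0)


def test_bow_loss_uniform_projection():
    V, d = 23, 6
    W = np.zeros((d, V))
    loss = bow_loss([4], [9], np.ones(d), np.ones(d), W)
    assert loss == pytest.approx(2 * math.log(V), abs=1e-12)


def test_bow_loss_perfect_prediction_near_zero():
    V, d = 5, 4
    W = np.zeros((d, V))
    W[:, 2] = 200.0  # both sides predict token 2 with p ~ 1
    loss = bow_loss([2], [2], np.ones(d), np.ones(d), W)
    assert loss == pytest.approx(0.0, abs=1e-9)


def test_bow_loss_matches_scalar_oracle():
    rng = np.random.default_rng(9)
    for _ in range(20):
        V, d = int(rng.integers(5, 50)), int(rng.integers(2, 16))
        W = rng.normal(size=(d, V))
        b = rng.normal(size=V)
        x, y = rng.normal(size=d), rng.normal(size=d)
        p_ids = rng.integers(0, V, size=3).tolist()
        r_ids = rng.integers(0, V, size=3).tolist()
        assert bow_loss(p_ids, r_ids, x, y, W, b) == pytest.approx(
            brute_bow_loss(p_ids, r_ids, x.tolist(), y.tolist(),
                           W.tolist(), b.tolist()),
            abs=1e-9,
        )


def test_bow_loss_empty_sequence_errors():
    with pytest.raises(ValueError):
        bow_loss([], [1], np.ones(2), np.ones(2), np.zeros((2, 3)))


def test_combined_loss_is_batch_mean_of_components():
    rng = np.random.default_rng(10)
    B, d, V = 4, 6, 12
    X, Y = rng.normal(size=(B, d)), rng.normal(size=(B, d))
    W, b = rng.normal(size=(d, V)), rng.normal(size=V)
    p_ids = [rng.integers(0, V, size=4).tolist() for _ in range(B)]
    r_ids = [rng.integers(0, V, size=3).tolist() for _ in range(B)]
    batch = EmbeddingBatch(X=X, Y=Y)
    S = batch.scores()
    expected = sum(
        brute_rank_loss(S.tolist(), i, "log_softmax")
        + brute_bow_loss(p_ids[i], r_ids[i], X[i].tolist(), Y[i].tolist(),
                         W.tolist(), b.tolist())
        for i in range(B)
    ) / B
    assert combined_loss(batch, p_ids, r_ids, W, b) == pytest.approx(
        expected, abs=1e-9
    )


def test_score_matrix_scaling_preserves_retrieval_order():
    rng = np.random.default_rng(11)
    X, Y = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
    S = score_matrix(X, Y)
    S_scaled = score_matrix(3.0 * X, 3.0 * Y)
    np.testing.assert_allclose(S_scaled, 9.0 * S, atol=1e-12)
    assert (S_scaled.argsort(axis=1) == S.argsort(axis=1)).all()


def test_mips_exact_equals_brute_force():
    rng = np.random.default_rng(12)
    N, d, k = 1000, 16, 20
    vectors = rng.normal(size=(N, d))
    ids = [f"id{i:04d}" for i in range(N)]
    index = build_index(vectors, ids)
    queries = rng.normal(size=(50, d))
    for q in queries:
        scores = vectors @ q
        expected = [
            ids[j]
            for j in sorted(range(N), key=lambda j: (-scores[j], ids[j]))[:k]
        ]
        assert index.query(q, k) == expected


def test_mips_identity_and_full_permutation():
    vectors = np.eye(5)
    ids = ["a", "b", "c", "d", "e"]
    index = build_index(vectors, ids)
    assert index.query(np.eye(5)[3], k=1) == ["d"]
    full = index.query(np.array([5.0, 4.0, 3.0, 2.0, 1.0]), k=5)
    assert full == ["a", "b", "c", "d", "e"]


def test_mips_tie_break_ascending_id():
    vectors = np.ones((4, 3))
    index = build_index(vectors, ["d", "b", "c", "a"])
    assert index.query(np.ones(3), k=4) == ["a", "b", "c", "d"]


def test_index_rejects_bad_inputs():
    with pytest.raises(ValueError):
        RetrievalIndex(vectors=np.zeros((0, 3)), ids=())
    index = build_index(np.ones((3, 2)), ["a", "b", "c"])
    with pytest.raises(ValueError):
        index.query(np.ones(2), k=4)
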