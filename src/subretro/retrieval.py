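"""Dual-encoder reaction retrieval.

Two independent Transformer encoder stacks map a product SMILES and a
reactant-set SMILES into one d-dimensional space (the encoded [BOS] vector is
the sequence representation).  For a training batch of B product–reactant
pairs with encoded matrices X, Y (each B x d), the score matrix is
S = X Yᵀ; the contrastive objective drives the diagonal up:

    rank loss (default, log form):   -log softmax(S_i)_i
    rank loss (literal form):        -exp(S_ii) / sum_j exp(S_ij)

A bag-of-words loss cross-aligns the two spaces at the token level: from X_i
the model must assign probability to every token of reactant i (and
symmetrically from Y_i to the product tokens), through one shared linear
projection + softmax.  The overall loss is the batch mean of rank + bow.

Retrieval is maximum inner product search over the pre-encoded reactant pool
(training + validation reactions only); the exact backend is the contract and
is brute-force-verified in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from . import nn
from .chem import ReactionRecord, tokenize
from .vocab import BOS, Vocabulary


@dataclass(frozen=True)
class EncoderConfig:
    """Dual-encoder hyper-parameters.

    Defaults are the full-scale settings (embedding 512, hidden 256,
    feed-forward 2048, 3 blocks, 8 heads, 500k max steps, 4000 warmup,
    dropout 0.1); :func:`desk_scale` shrinks them for CPU-sized corpora.
    """

    embedding_size: int = 512
    hidden_size: int = 256
    feedforward_size: int = 2048
    num_blocks: int = 3
    num_heads: int = 8
    max_steps: int = 500_000
    warmup_steps: int = 4000
    dropout: float = 0.1
    learning_rate: float = 1e-4
    label_smoothing: float = 0.1
    batch_pairs: int = 16
    max_len: int = 160
    eval_interval: int = 50
    patience: int = 4

    def desk_scale(self) -> "EncoderConfig":
        return replace(
            self,
            embedding_size=48,
            hidden_size=32,
            feedforward_size=64,
            num_blocks=1,
            num_heads=2,
            max_steps=360,
            warmup_steps=40,
            dropout=0.0,
            learning_rate=3e-3,
        )


@dataclass(frozen=True)
class EmbeddingBatch:
    """Row-aligned encoded product (X) and reactant (Y) matrices, B x d."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must be the same shape")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("non-finite embeddings")

    @property
    def B(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def scores(self) -> np.ndarray:
        return score_matrix(self.X, self.Y)


def score_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """S = X Yᵀ; S[i, j] scores product i against reactants j."""
    return X @ Y.T


def rank_loss(S: np.ndarray, i: int, variant: str = "log_softmax") -> float:
    """Contrastive ranking loss of the i-th product-reactants pair.

    ``log_softmax`` (default) is the negative log of the row-softmax
    probability of the diagonal entry; ``as_printed`` is the negative
    softmax probability itself.
    """
    S = np.asarray(S, dtype=float)
    if not np.isfinite(S).all():
        raise ValueError("non-finite score matrix")
    if not 0 <= i < S.shape[0]:
        raise IndexError(f"row {i} out of range for B={S.shape[0]}")
    row = S[i]
    log_p = row[i] - logsumexp(row)
    if variant == "log_softmax":
        return float(-log_p)
    if variant == "as_printed":
        return float(-np.exp(log_p))
    raise ValueError(f"unknown variant {variant!r}")


def bow_loss(
    product_token_ids: Sequence[int],
    reactant_token_ids: Sequence[int],
    x_i: np.ndarray,
    y_i: np.ndarray,
    projection_weight: np.ndarray,
    projection_bias: np.ndarray | None = None,
) -> float:
    """Bag-of-words cross-alignment loss for one pair.

    Both sums are penalties: -sum_{w_y} log p(w_y | X_i) - sum_{w_x}
    log p(w_x | Y_i), with p given by a linear projection followed by a
    softmax.  Repeated tokens contribute once per occurrence.
    """
    if len(product_token_ids) == 0 or len(reactant_token_ids) == 0:
        raise ValueError("empty token sequence")
    if projection_bias is None:
        projection_bias = np.zeros(projection_weight.shape[1])
    logits_x = x_i @ projection_weight + projection_bias
    logits_y = y_i @ projection_weight + projection_bias
    logp_x = logits_x - logsumexp(logits_x)
    logp_y = logits_y - logsumexp(logits_y)
    return float(
        -logp_x[np.asarray(reactant_token_ids)].sum()
        - logp_y[np.asarray(product_token_ids)].sum()
    )


def combined_loss(
    batch: EmbeddingBatch,
    product_token_ids: Sequence[Sequence[int]],
    reactant_token_ids: Sequence[Sequence[int]],
    projection_weight: np.ndarray,
    projection_bias: np.ndarray | None = None,
    variant: str = "log_softmax",
) -> float:
    """(1/B) * sum_i (rank_loss_i + bow_loss_i)."""
    S = batch.scores()
    total = 0.0
    for i in range(batch.B):
        total += rank_loss(S, i, variant=variant)
        total += bow_loss(
            product_token_ids[i],
            reactant_token_ids[i],
            batch.X[i],
            batch.Y[i],
            projection_weight,
            projection_bias,
        )
    return total / batch.B


# ---------------------------------------------------------------------------
# Trainable dual encoder
# ---------------------------------------------------------------------------


def _prepare(vocab: Vocabulary, token_lists: list[list[str]], max_len: int):
    """Pad [BOS]-prefixed id sequences into an id matrix + length vector."""
    bos = vocab.index[BOS]
    rows = [[bos] + vocab.encode(toks)[: max_len - 1] for toks in token_lists]
    lengths = np.array([len(r) for r in rows])
    width = int(lengths.max())
    ids = np.full((len(rows), width), vocab.pad_id, dtype=np.int64)
    for i, row in enumerate(rows):
        ids[i, : len(row)] = row
    return ids, lengths


class DualEncoder:
    """Product and reactant Transformer encoders sharing one vocabulary."""

    def __init__(self, config: EncoderConfig, vocab: Vocabulary, seed: int):
        rng = np.random.default_rng(seed)
        kwargs = dict(
            vocab_size=len(vocab),
            embedding_size=config.embedding_size,
            hidden_size=config.hidden_size,
            feedforward_size=config.feedforward_size,
            num_blocks=config.num_blocks,
            num_heads=config.num_heads,
            max_len=config.max_len,
        )
        self.product_encoder = nn.TransformerEncoder(rng=rng, **kwargs)
        self.reactant_encoder = nn.TransformerEncoder(rng=rng, **kwargs)
        self.bow_projection = nn.Linear(config.hidden_size, len(vocab), rng)
        self.config = config
        self.vocab = vocab

    def _modules(self):
        return (self.product_encoder, self.reactant_encoder, self.bow_projection)

    def parameters(self) -> list[nn.Tensor]:
        params: list[nn.Tensor] = []
        for module in self._modules():
            params.extend(module.parameters())
        return params

    def _encode(self, encoder, token_lists: list[list[str]]) -> nn.Tensor:
        ids, lengths = _prepare(self.vocab, token_lists, self.config.max_len)
        hidden = encoder(ids, lengths)
        return hidden[:, 0, :]  # [BOS] position represents the sequence

    def encode_products(self, smiles: Sequence[str]) -> np.ndarray:
        toks = [list(tokenize(s)) for s in smiles]
        return self._encode(self.product_encoder, toks).data

    def encode_reactants(self, smiles: Sequence[str]) -> np.ndarray:
        toks = [list(tokenize(s)) for s in smiles]
        return self._encode(self.reactant_encoder, toks).data

    def batch_loss(
        self, product_tokens: list[list[str]], reactant_tokens: list[list[str]]
    ) -> nn.Tensor:
        """Differentiable combined rank + bag-of-words batch loss
        (log-softmax rank variant)."""
        X = self._encode(self.product_encoder, product_tokens)
        Y = self._encode(self.reactant_encoder, reactant_tokens)
        B = len(product_tokens)
        S = X @ Y.transpose()
        logp = nn.log_softmax(S, axis=-1)
        rank = -logp[np.arange(B), np.arange(B)].sum()
        logp_x = nn.log_softmax(self.bow_projection(X), axis=-1)
        logp_y = nn.log_softmax(self.bow_projection(Y), axis=-1)
        bow_terms = []
        for i in range(B):
            y_ids = np.array(self.vocab.encode(reactant_tokens[i]))
            x_ids = np.array(self.vocab.encode(product_tokens[i]))
            bow_terms.append(-logp_x[i][y_ids].sum() - logp_y[i][x_ids].sum())
        bow = bow_terms[0]
        for term in bow_terms[1:]:
            bow = bow + term
        return (rank + bow) * (1.0 / B)

    def alignment_accuracy(
        self, products: Sequence[str], reactants: Sequence[str]
    ) -> float:
        """In-batch accuracy: fraction of rows whose own reactants score top."""
        X = self.encode_products(products)
        Y = self.encode_reactants(reactants)
        S = score_matrix(X, Y)
        return float(np.mean(S.argmax(axis=1) == np.arange(S.shape[0])))


def train_dual_encoder(
    records: Sequence[ReactionRecord],
    config: EncoderConfig,
    seed: int,
    validation: Sequence[ReactionRecord] = (),
    verbose: bool = False,
) -> tuple[DualEncoder, list[float]]:
    """Train the dual encoder; returns the model and the loss trajectory.

    Stops at ``max_steps`` or earlier when the in-batch alignment accuracy
    on the validation records has not improved for ``patience`` evaluations.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 reactions (rank loss degenerate at B=1)")
    products = [r.product.canonical_smiles for r in records]
    reactants = [r.reactants_smiles for r in records]
    vocab = Vocabulary.build(
        [list(tokenize(s)) for s in products + reactants]
    )
    model = DualEncoder(config, vocab, seed=seed)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(seed + 1)
    losses: list[float] = []
    best_acc, since_best = -1.0, 0
    val_products = [r.product.canonical_smiles for r in validation]
    val_reactants = [r.reactants_smiles for r in validation]
    n = len(records)
    B = min(config.batch_pairs, n)
    for step in range(1, config.max_steps + 1):
        idx = rng.choice(n, size=B, replace=False)
        ptoks = [list(tokenize(products[i])) for i in idx]
        rtoks = [list(tokenize(reactants[i])) for i in idx]
        loss = model.batch_loss(ptoks, rtoks)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        losses.append(loss.item())
        if validation and step % config.eval_interval == 0:
            acc = model.alignment_accuracy(val_products, val_reactants)
            if verbose:  # pragma: no cover
                print(f"step {step}: loss {loss.item():.3f} val-align {acc:.3f}")
            if acc > best_acc:
                best_acc, since_best = acc, 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    return model, losses


# ---------------------------------------------------------------------------
# Maximum inner product search (exact backend)
# ---------------------------------------------------------------------------


@dataclass
class RetrievalIndex:
    """Dense reactant vectors over the training+validation pool.

    Queries return only indexed ids, so test reactions (never indexed) can
    never be retrieved as their own candidates.
    """

    vectors: np.ndarray
    ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.vectors.ndim != 2 or self.vectors.shape[0] == 0:
            raise ValueError("index requires a non-empty N x d matrix")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("ids and vectors disagree in length")

    def query(self, query_vector: np.ndarray, k: int) -> list[str]:
        """The k ids with largest inner product, descending; ties broken by
        ascending id for determinism."""
        if k > len(self.ids):
            raise ValueError(f"k={k} exceeds index size {len(self.ids)}")
        scores = self.vectors @ np.asarray(query_vector)
        order = sorted(range(len(self.ids)), key=lambda j: (-scores[j], self.ids[j]))
        return [self.ids[j] for j in order[:k]]

    def query_batch(self, queries: np.ndarray, k: int) -> list[list[str]]:
        return [self.query(q, k) for q in np.asarray(queries)]


def build_index(
    reactant_vectors: np.ndarray, ids: Sequence[str]
) -> RetrievalIndex:
    return RetrievalIndex(vectors=np.asarray(reactant_vectors, dtype=float),
                          ids=tuple(ids))
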