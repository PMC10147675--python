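"""Pair-wise neural reranker over assembled predictions.

Different substructures of the same product often lead to the same reactant
set at different beam ranks; because predicted fragment lengths differ
across substructures, raw beam scores are not a reliable final ranking.
Instead, per distinct reactant set the ranker consumes symmetric aggregate
features — frequency (how many substructure groups, counted with candidate
multiplicity, produced it), the fraction of groups ranking it first and in
the top 2, and average beam ranks over all and over unique substructures —
and scores them with a three-layer network of width 400.  Training is
pair-wise on (golden, non-golden) feature pairs collected from validation
predictions: a softmax over the two scores with label-smoothed cross-entropy
pushes golden above non-golden.

Ranks enter the network as reciprocal ranks and features are min-max scaled
on the training pairs (bounded inputs stabilize the small network).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .model_infer import Prediction

N_FEATURES = 5


@dataclass(frozen=True)
class RankingFeatures:
    frequency: float  # substructure-group count (with multiplicity) producing the set
    top1_fraction: float
    top2_fraction: float
    mean_rank_all: float  # average beam rank over all substructures
    mean_rank_unique: float  # average beam rank over unique substructures

    def vector(self) -> np.ndarray:
        """Bounded encoding: log1p frequency, fractions, reciprocal ranks."""
        return np.array(
            [
                np.log1p(self.frequency),
                self.top1_fraction,
                self.top2_fraction,
                1.0 / self.mean_rank_all,
                1.0 / self.mean_rank_unique,
            ]
        )


@dataclass(frozen=True)
class PairExample:
    positive: RankingFeatures  # golden reactants
    negative: RankingFeatures  # a non-golden prediction from the same pool
    product_id: str


def extract_features(
    predictions: Sequence[Prediction],
) -> dict[tuple[str, ...], RankingFeatures]:
    """One feature vector per distinct reactant set for a single product.

    A set absent from a group contributes nothing to that group's fractions
    or rank averages for it.
    """
    by_group: dict[str, dict[tuple[str, ...], Prediction]] = {}
    multiplicity: dict[str, int] = {}
    for p in predictions:
        group = by_group.setdefault(p.group_id, {})
        if p.reactant_key not in group or p.beam_rank < group[p.reactant_key].beam_rank:
            group[p.reactant_key] = p
        multiplicity[p.group_id] = p.group_multiplicity

    features: dict[tuple[str, ...], RankingFeatures] = {}
    keys = {p.reactant_key for p in predictions}
    for key in keys:
        freq = 0.0
        top1_w = top2_w = 0.0
        total_w = 0.0
        ranks_all: list[float] = []
        ranks_unique: list[int] = []
        for group_id, members in by_group.items():
            if key not in members:
                continue
            w = multiplicity[group_id]
            rank = members[key].beam_rank
            freq += w
            total_w += w
            top1_w += w * (rank == 1)
            top2_w += w * (rank <= 2)
            ranks_all.extend([rank] * w)
            ranks_unique.append(rank)
        features[key] = RankingFeatures(
            frequency=freq,
            top1_fraction=top1_w / total_w,
            top2_fraction=top2_w / total_w,
            mean_rank_all=float(np.mean(ranks_all)),
            mean_rank_unique=float(np.mean(ranks_unique)),
        )
    return features


def collect_pairs(
    prediction_pools: Mapping[str, Sequence[Prediction]],
    golden: Mapping[str, tuple[str, ...]],
    max_pairs: int = 10,
) -> list[PairExample]:
    """(golden, non-golden) feature pairs from validation prediction pools.

    Only products whose pool contains the golden set contribute; at most
    ``max_pairs`` pairs per product, negatives in deterministic key order.
    """
    pairs: list[PairExample] = []
    for product_id in sorted(prediction_pools):
        pool = prediction_pools[product_id]
        features = extract_features(pool)
        gold_key = golden[product_id]
        if gold_key not in features:
            continue
        positive = features[gold_key]
        negatives = [k for k in sorted(features) if k != gold_key]
        for key in negatives[:max_pairs]:
            pairs.append(
                PairExample(
                    positive=positive,
                    negative=features[key],
                    product_id=product_id,
                )
            )
    return pairs


class RankerModel:
    """Three linear layers of width 400 with ReLU, scalar output score."""

    def __init__(self, seed: int, width: int = 400):
        rng = np.random.default_rng(seed)
        self.layers = [
            nn.Linear(N_FEATURES, width, rng),
            nn.Linear(width, width, rng),
            nn.Linear(width, width, rng),
        ]
        self.out = nn.Linear(width, 1, rng)
        self.feature_min = np.zeros(N_FEATURES)
        self.feature_max = np.ones(N_FEATURES)

    def parameters(self) -> list[nn.Tensor]:
        params: list[nn.Tensor] = []
        for layer in self.layers:
            params.extend(layer.parameters())
        params.extend(self.out.parameters())
        return params

    def fit_scaler(self, vectors: np.ndarray) -> None:
        self.feature_min = vectors.min(axis=0)
        self.feature_max = vectors.max(axis=0)

    def _scale(self, vectors: np.ndarray) -> np.ndarray:
        span = np.where(
            self.feature_max > self.feature_min,
            self.feature_max - self.feature_min,
            1.0,
        )
        return (vectors - self.feature_min) / span

    def forward(self, vectors: np.ndarray) -> nn.Tensor:
        x = nn.Tensor(self._scale(np.atleast_2d(vectors)))
        for layer in self.layers:
            x = layer(x).relu()
        return self.out(x)

    def score(self, features: RankingFeatures) -> float:
        return float(self.forward(features.vector()).data[0, 0])

    def score_many(self, feature_list: Sequence[RankingFeatures]) -> np.ndarray:
        vectors = np.stack([f.vector() for f in feature_list])
        return self.forward(vectors).data[:, 0]


def train_ranker(
    pairs: Sequence[PairExample],
    seed: int,
    label_smoothing: float = 0.1,
    learning_rate: float = 1e-3,
    max_epochs: int = 60,
    patience: int = 8,
    split_fraction: float = 0.6,
) -> tuple[RankerModel, float]:
    """Pair-wise training with a 60/40 train/validation split of the pairs.

    The objective is a label-smoothed softmax over the (positive, negative)
    score pair; training stops when pair-classification accuracy on the 40%
    validation split plateaus.  Pairs with identical features are skipped.
    Returns the model and its final validation pair accuracy.
    """
    usable = [
        p
        for p in pairs
        if not np.allclose(p.positive.vector(), p.negative.vector())
    ]
    skipped = len(pairs) - len(usable)
    if skipped:  # pragma: no cover - diagnostic only
        import warnings

        warnings.warn(f"skipped {skipped} degenerate identical-feature pairs")
    if not usable:
        raise ValueError("no usable training pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(usable))
    n_train = max(1, int(round(split_fraction * len(usable))))
    train_pairs = [usable[i] for i in order[:n_train]]
    valid_pairs = [usable[i] for i in order[n_train:]] or train_pairs

    model = RankerModel(seed=seed + 1)
    all_vectors = np.stack(
        [p.positive.vector() for p in train_pairs]
        + [p.negative.vector() for p in train_pairs]
    )
    model.fit_scaler(all_vectors)
    optimizer = nn.Adam(model.parameters(), lr=learning_rate)

    pos = np.stack([p.positive.vector() for p in train_pairs])
    neg = np.stack([p.negative.vector() for p in train_pairs])

    def pair_accuracy(pair_list: Sequence[PairExample]) -> float:
        p_scores = model.forward(
            np.stack([p.positive.vector() for p in pair_list])
        ).data[:, 0]
        n_scores = model.forward(
            np.stack([p.negative.vector() for p in pair_list])
        ).data[:, 0]
        return float(np.mean(p_scores > n_scores))

    best_acc, since_best = -1.0, 0
    eps = label_smoothing
    for _ in range(max_epochs):
        s_pos = model.forward(pos)
        s_neg = model.forward(neg)
        # softmax over the two scores; smoothed target (1-eps/2, eps/2)
        diff = s_neg - s_pos
        log_p_pos = -(1.0 + diff.exp()).log()
        log_p_neg = -((-diff).exp() + 1.0).log()
        loss = -((1.0 - eps / 2.0) * log_p_pos + (eps / 2.0) * log_p_neg).mean()
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        acc = pair_accuracy(valid_pairs)
        if acc > best_acc:
            best_acc, since_best = acc, 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    return model, best_acc


def rerank(
    predictions: Sequence[Prediction], ranker: RankerModel
) -> list[tuple[str, ...]]:
    """Distinct reactant sets by descending ranker score.

    Ties break deterministically: higher frequency, then better (lower)
    mean unique rank, then lexicographic canonical SMILES.  Reranking is a
    permutation of the candidate sets — nothing is added or removed.
    """
    features = extract_features(predictions)
    if not features:
        return []
    keys = sorted(features)
    scores = ranker.score_many([features[k] for k in keys])
    by_key = dict(zip(keys, scores))
    return sorted(
        keys,
        key=lambda k: (
            -round(by_key[k], 9),
            -features[k].frequency,
            features[k].mean_rank_unique,
            k,
        ),
    )
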