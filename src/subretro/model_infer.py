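"""Transformer encoder-decoder over substructure-level examples: training
with label-smoothed cross-entropy and perplexity-plateau stopping, beam
search decoding, prediction assembly/grouping, and top-k exact-match
evaluation.

Beam hypotheses are scored by length-normalized log-probability (predicted
fragment lengths differ across substructures, so unnormalized scores are not
comparable when aggregating over substructure groups).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import nn
from .chem import Molecule, canonicalize, reactant_set_key
from .dataset import Seq2SeqExample
from .split_assemble import ChemistryError, MergeError, merge
from .vocab import Vocabulary


@dataclass(frozen=True)
class Seq2SeqConfig:
    """Substructure-level seq2seq hyper-parameters (full-scale defaults:
    embedding/hidden 512, feed-forward 2048, 10 blocks, 8 heads, Adam
    beta2 0.998, Noam scale 2 with 8000 warmup steps, dropout 0.1)."""

    embedding_size: int = 512
    hidden_size: int = 512
    feedforward_size: int = 2048
    num_blocks: int = 10
    num_heads: int = 8
    max_steps: int = 500_000
    warmup_steps: int = 8000
    dropout: float = 0.1
    label_smoothing: float = 0.1
    adam_betas: tuple[float, float] = (0.9, 0.998)
    noam_scale: float = 2.0
    batch_examples: int = 16
    max_len: int = 160
    max_decode_len: int = 96
    eval_interval: int = 50
    patience: int = 6

    def desk_scale(self) -> "Seq2SeqConfig":
        return replace(
            self,
            embedding_size=64,
            hidden_size=64,
            feedforward_size=128,
            num_blocks=2,
            num_heads=2,
            max_steps=3000,
            warmup_steps=200,
            dropout=0.0,
            noam_scale=0.25,
            max_decode_len=72,
        )


def _pad_batch(rows: list[list[int]], pad: int) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(r) for r in rows])
    ids = np.full((len(rows), int(lengths.max())), pad, dtype=np.int64)
    for i, row in enumerate(rows):
        ids[i, : len(row)] = row
    return ids, lengths


class Seq2SeqModel:
    """Encoder-decoder Transformer with a token vocabulary."""

    def __init__(self, config: Seq2SeqConfig, vocab: Vocabulary, seed: int):
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
        self.encoder = nn.TransformerEncoder(rng=rng, **kwargs)
        self.decoder = nn.TransformerDecoder(rng=rng, **kwargs)
        self.config = config
        self.vocab = vocab

    def parameters(self) -> list[nn.Tensor]:
        return self.encoder.parameters() + self.decoder.parameters()

    def _encode_sources(self, sources: list[list[str]]):
        rows = [self.vocab.encode(toks)[: self.config.max_len] for toks in sources]
        ids, lengths = _pad_batch(rows, self.vocab.pad_id)
        return self.encoder(ids, lengths), lengths

    def batch_loss(
        self, sources: list[list[str]], targets: list[list[str]]
    ) -> nn.Tensor:
        memory, mem_lengths = self._encode_sources(sources)
        bos, eos = self.vocab.bos_id, self.vocab.eos_id
        rows_in, rows_out = [], []
        for toks in targets:
            ids = self.vocab.encode(toks)[: self.config.max_len - 1]
            rows_in.append([bos] + ids)
            rows_out.append(ids + [eos])
        tgt_in, tgt_lengths = _pad_batch(rows_in, self.vocab.pad_id)
        tgt_out, _ = _pad_batch(rows_out, self.vocab.pad_id)
        logits = self.decoder(tgt_in, memory, mem_lengths)
        batch, t = tgt_in.shape
        mask = (np.arange(t)[None, :] < tgt_lengths[:, None]).astype(float)
        return nn.label_smoothed_nll(
            logits.reshape(batch * t, len(self.vocab)),
            tgt_out.reshape(-1),
            mask.reshape(-1),
            self.config.label_smoothing,
        )

    def step_logprobs_factory(
        self, source_tokens: list[str]
    ) -> Callable[[np.ndarray], np.ndarray]:
        """A closure mapping prefix id arrays (n, t) to next-token log-probs
        (n, V), conditioned on one encoded source."""
        memory, mem_lengths = self._encode_sources([source_tokens])

        def step(prefixes: np.ndarray) -> np.ndarray:
            n = prefixes.shape[0]
            mem = nn.Tensor(np.repeat(memory.data, n, axis=0))
            lengths = np.repeat(mem_lengths, n)
            logits = self.decoder(prefixes, mem, lengths)
            last = logits.data[:, -1, :]
            shift = last - last.max(axis=-1, keepdims=True)
            return shift - np.log(np.exp(shift).sum(axis=-1, keepdims=True))

        return step


def train(
    corpus: Sequence[Seq2SeqExample],
    config: Seq2SeqConfig,
    seed: int,
    verbose: bool = False,
) -> tuple[Seq2SeqModel, list[float]]:
    """Train until the training perplexity plateaus (or max_steps).

    Returns the model and the per-step label-smoothed loss trajectory;
    deterministic given the seed.
    """
    if not corpus:
        raise ValueError("empty corpus")
    sources = [list(e.source_tokens) for e in corpus]
    targets = [list(e.target_tokens) for e in corpus]
    vocab = Vocabulary.build(sources + targets)
    model = Seq2SeqModel(config, vocab, seed=seed)
    # fail fast if any corpus token failed to enter the vocabulary
    for toks in sources + targets:
        vocab.encode(toks, strict=True)
    optimizer = nn.Adam(model.parameters(), betas=config.adam_betas)
    rng = np.random.default_rng(seed + 1)
    n = len(corpus)
    batch = min(config.batch_examples, n)
    # length-bucketed batching: sample a contiguous window of the
    # length-sorted corpus to keep padding waste low
    by_length = sorted(
        range(n), key=lambda i: len(sources[i]) + len(targets[i])
    )
    losses: list[float] = []
    best_ppl, since_best = math.inf, 0
    for step in range(1, config.max_steps + 1):
        start = int(rng.integers(0, max(n - batch, 0) + 1))
        idx = by_length[start : start + batch]
        loss = model.batch_loss([sources[i] for i in idx], [targets[i] for i in idx])
        optimizer.zero_grad()
        loss.backward()
        lr = nn.noam_lr(step, config.hidden_size, config.warmup_steps, config.noam_scale)
        optimizer.step(lr=lr)
        losses.append(loss.item())
        if step % config.eval_interval == 0:
            window = losses[-config.eval_interval :]
            ppl = math.exp(min(sum(window) / len(window), 50.0))
            if verbose:  # pragma: no cover
                print(f"step {step}: train ppl {ppl:.3f}")
            if ppl < best_ppl - 1e-3:
                best_ppl, since_best = ppl, 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    return model, losses


# ---------------------------------------------------------------------------
# Beam search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Hypothesis:
    tokens: tuple[int, ...]  # emitted ids, including the terminal EOS if any
    logprob: float

    def score(self, length_normalize: bool) -> float:
        if not length_normalize:
            return self.logprob
        return self.logprob / max(len(self.tokens), 1)


def beam_search(
    step_fn: Callable[[np.ndarray], np.ndarray],
    bos: int,
    eos: int,
    beam_size: int,
    max_len: int,
    length_normalize: bool = True,
    forbidden: Sequence[int] = (),
) -> list[Hypothesis]:
    """Breadth-limited search keeping the ``beam_size`` best partial
    sequences per step; returns up to ``beam_size`` hypotheses sorted by
    descending (optionally length-normalized) log-probability.

    ``step_fn`` maps an (n, t) prefix id array (prefixes start with BOS) to
    (n, V) next-token log-probabilities.  With ``beam_size`` at least the
    number of possible prefixes the search is exhaustive.
    """
    if beam_size < 1:
        raise ValueError("beam_size must be >= 1")
    live: list[Hypothesis] = [Hypothesis(tokens=(), logprob=0.0)]
    finished: list[Hypothesis] = []
    forbidden = [t for t in forbidden if t != eos]
    for _ in range(max_len):
        if not live:
            break
        prefixes = np.array(
            [[bos, *h.tokens] for h in live], dtype=np.int64
        )
        logprobs = step_fn(prefixes)
        candidates: list[Hypothesis] = []
        for h, row in zip(live, logprobs):
            for token in np.argsort(-row):
                token = int(token)
                if token in forbidden or token == bos:
                    continue
                candidates.append(
                    Hypothesis(
                        tokens=h.tokens + (token,),
                        logprob=h.logprob + float(row[token]),
                    )
                )
        candidates.sort(key=lambda h: (-h.logprob, h.tokens))
        kept = candidates[:beam_size]
        live = []
        for h in kept:
            if h.tokens[-1] == eos:
                finished.append(h)
            else:
                live.append(h)
    finished.extend(live)  # length-capped, unterminated hypotheses
    finished.sort(key=lambda h: (-h.score(length_normalize), h.tokens))
    return finished[:beam_size]


def decode(
    model: Seq2SeqModel,
    inputs: Sequence[Seq2SeqExample],
    beam_size: int = 10,
) -> list[list[tuple[tuple[str, ...], float]]]:
    """Beam-decode each input; per input, up to ``beam_size`` (token tuple,
    normalized score) hypotheses in descending score order."""
    vocab = model.vocab
    pad, bos, eos = vocab.pad_id, vocab.bos_id, vocab.eos_id
    unk = vocab.index["[UNK]"]
    results = []
    for example in inputs:
        step_fn = model.step_logprobs_factory(list(example.source_tokens))
        hyps = beam_search(
            step_fn,
            bos=bos,
            eos=eos,
            beam_size=beam_size,
            max_len=model.config.max_decode_len,
            forbidden=(pad, unk),
        )
        decoded = []
        for h in hyps:
            tokens = tuple(
                vocab.tokens[t] for t in h.tokens if t != eos
            )
            decoded.append((tokens, h.score(length_normalize=True)))
        results.append(decoded)
    return results


# ---------------------------------------------------------------------------
# Assembly, grouping, evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Prediction:
    """One assembled reactant-set prediction from one substructure group."""

    reactant_key: tuple[str, ...]  # sorted canonical SMILES multiset key
    molecules: tuple[Molecule, ...] = field(compare=False, repr=False)
    group_id: str  # identifies the substructure (or fallback) group
    substructure_atoms: frozenset[int]
    beam_rank: int  # 1-based rank within its group
    score: float
    group_multiplicity: int = 1  # candidates that produced this substructure


@dataclass
class AssemblyReport:
    n_hypotheses: int = 0
    n_dropped: int = 0

    @property
    def dropped_rate(self) -> float:
        return self.n_dropped / self.n_hypotheses if self.n_hypotheses else 0.0


def assemble_predictions(
    hypotheses_per_input: Sequence[Sequence[tuple[tuple[str, ...], float]]],
    inputs: Sequence[Seq2SeqExample],
    group_multiplicities: dict[frozenset[int], int] | None = None,
    report: AssemblyReport | None = None,
) -> list[Prediction]:
    """Merge decoded fragments with their substructures.

    Invalid merges (dangling labels, valence errors, unparseable SMILES) are
    dropped and counted; the same reactant set reached from several
    substructures yields several Prediction entries (the ranker consumes the
    multiplicity).
    """
    report = report if report is not None else AssemblyReport()
    predictions: list[Prediction] = []
    for example, hypotheses in zip(inputs, hypotheses_per_input):
        group_id = (
            "fallback"
            if example.is_fallback
            else "sub:" + ",".join(map(str, sorted(example.substructure_atoms)))
        )
        multiplicity = 1
        if group_multiplicities and example.substructure_atoms in group_multiplicities:
            multiplicity = group_multiplicities[example.substructure_atoms]
        rank = 0
        for tokens, score in hypotheses:
            report.n_hypotheses += 1
            text = "".join(tokens)
            try:
                if example.is_fallback:
                    molecules = [
                        canonicalize(s) for s in text.split(".") if s
                    ]
                    if not molecules:
                        raise MergeError("empty prediction")
                else:
                    molecules = merge(
                        example.substructure_smiles, text, example.bond_orders
                    )
            except (MergeError, ChemistryError, ValueError):
                report.n_dropped += 1
                continue
            rank += 1
            predictions.append(
                Prediction(
                    reactant_key=reactant_set_key(molecules),
                    molecules=tuple(molecules),
                    group_id=group_id,
                    substructure_atoms=example.substructure_atoms,
                    beam_rank=rank,
                    score=score,
                    group_multiplicity=multiplicity,
                )
            )
    return predictions


def group_by_substructure(
    predictions: Sequence[Prediction],
) -> dict[str, list[Prediction]]:
    """Per-substructure ranked lists (the expert-inspection view)."""
    groups: dict[str, list[Prediction]] = {}
    for prediction in predictions:
        groups.setdefault(prediction.group_id, []).append(prediction)
    for members in groups.values():
        members.sort(key=lambda p: p.beam_rank)
    return groups


def rank_by_beam_score(predictions: Sequence[Prediction]) -> list[tuple[str, ...]]:
    """Baseline final ranking: distinct reactant sets by best normalized
    beam score (ties by key)."""
    best: dict[tuple[str, ...], float] = {}
    for p in predictions:
        if p.reactant_key not in best or p.score > best[p.reactant_key]:
            best[p.reactant_key] = p.score
    return sorted(best, key=lambda k: (-best[k], k))


def evaluate_topk(
    ranked_predictions: Sequence[Sequence[tuple[str, ...]]],
    golden: Sequence[tuple[str, ...]],
    ks: Sequence[int] = (1, 5, 10),
) -> dict[int, float]:
    """Top-k exact-match accuracy over products.

    ``ranked_predictions[i]`` is the final ranked list of reactant-set keys
    for product i; ``golden[i]`` its golden key (order-free canonical
    multiset, so the metric is invariant to SMILES writing).
    """
    if len(ranked_predictions) != len(golden):
        raise ValueError("prediction and golden lists differ in length")
    n = len(golden)
    out = {}
    for k in ks:
        hits = sum(
            1
            for ranked, gold in zip(ranked_predictions, golden)
            if gold in list(ranked)[:k]
        )
        out[k] = hits / n if n else 0.0
    return out


def average_checkpoints(models: Sequence[Seq2SeqModel]) -> Seq2SeqModel:
    """Parameter averaging across checkpoints (optional training utility)."""
    if not models:
        raise ValueError("no models")
    base = models[0]
    params = [m.parameters() for m in models]
    for group in zip(*params):
        group[0].data = np.mean([p.data for p in group], axis=0)
    return base
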