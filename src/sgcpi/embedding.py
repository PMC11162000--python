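"""Skip-gram with negative sampling (SGNS) over token corpora.

The embedding model is word2vec's skip-gram trained with negative
sampling. For a center token w with context u and negative draws z, the
per-pair likelihood is

    p = sigma(V(w)^T theta_u)            for the true context (label 1)
    p = 1 - sigma(V(w)^T theta_z)        for each negative (label 0)

and the per-pair objective g(w) = log sigma(V^T theta_u)
+ sum_z log(1 - sigma(V^T theta_z)) is maximized by SGD. Separate tables
are trained per modality (compound tokens vs protein 3-mers). Entity
vectors are token-vector means; out-of-vocabulary tokens contribute the
mean of all vocabulary vectors under the default ``averaged`` policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .tokenizer import TokenSequence

__all__ = [
    "Vocab",
    "SkipgramConfig",
    "EmbeddingTable",
    "EntityEmbedding",
    "build_vocab",
    "negative_sampling_distribution",
    "sgns_pair_probability",
    "sgns_step",
    "train_skipgram",
    "oov_vector",
    "embed_entity",
    "save_word2vec_text",
    "load_word2vec_text",
]


@dataclass(frozen=True)
class Vocab:
    """Token inventory with counts and the negative-sampling distribution.

    Tokens are indexed by descending count, ties broken lexicographically.
    """

    index: dict[str, int]
    counts: np.ndarray  # shape (|vocab|,)
    min_count: int

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def tokens(self) -> list[str]:
        out = [""] * len(self.index)
        for t, i in self.index.items():
            out[i] = t
        return out


def build_vocab(corpus: list[TokenSequence], min_count: int = 1) -> Vocab:
    """Count tokens over the corpus and retain those with count >= min_count."""
    if not corpus:
        raise ValueError("empty corpus")
    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    kept = [(t, c) for t, c in counts.items() if c >= min_count]
    if not kept:
        raise ValueError("empty vocabulary: no token reaches min_count")
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    index = {t: i for i, (t, _) in enumerate(kept)}
    return Vocab(index=index, counts=np.array([c for _, c in kept], dtype=float),
                 min_count=min_count)


def negative_sampling_distribution(vocab: Vocab, power: float = 0.75) -> np.ndarray:
    """Unigram distribution raised to ``power`` and normalized: p(w) ~ count^power."""
    if power <= 0:
        raise ValueError("power must be > 0")
    p = vocab.counts.astype(float) ** power
    return p / p.sum()


@dataclass(frozen=True)
class SkipgramConfig:
    d: int = 100
    window: int = 5  # maximum center-context distance C
    negatives: int = 5  # negative draws per positive pair
    epochs: int = 15
    lr: float = 0.025
    lr_min: float = 1e-4
    power: float = 0.75  # negative-sampling distribution exponent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d <= 0 or self.window <= 0:
            raise ValueError("dimension and window must be positive")
        if self.negatives < 0 or self.epochs < 0 or self.lr <= 0:
            raise ValueError("invalid training config")


@dataclass
class EmbeddingTable:
    """SGNS parameters: input vectors V (one row per token) and output vectors theta."""

    vocab: Vocab
    V: np.ndarray  # (|vocab|, d) input vectors
    theta: np.ndarray  # (|vocab|, d) output vectors
    config: SkipgramConfig

    @property
    def d(self) -> int:
        return self.V.shape[1]

    def vector(self, token: str) -> np.ndarray:
        return self.V[self.vocab.index[token]]


@dataclass(frozen=True)
class EntityEmbedding:
    entity_id: str
    vector: np.ndarray
    oov_fraction: float


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def sgns_pair_probability(v: np.ndarray, theta: np.ndarray, label: int) -> float:
    """Likelihood of one (center, candidate) pair under the SGNS model.

    sigma(v^T theta) for a true context (label 1), 1 - sigma(v^T theta)
    for a negative sample (label 0).
    """
    v = np.asarray(v, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if v.shape != theta.shape:
        raise ValueError(f"dimension mismatch: {v.shape} vs {theta.shape}")
    s = float(_sigmoid(v @ theta))
    return s if label == 1 else 1.0 - s


def init_table(vocab: Vocab, config: SkipgramConfig) -> EmbeddingTable:
    """Seeded initialization: V uniform in [-0.5/d, 0.5/d), theta zero (word2vec)."""
    rng = np.random.default_rng(config.seed)
    n, d = len(vocab), config.d
    V = (rng.random((n, d)) - 0.5) / d
    theta = np.zeros((n, d))
    return EmbeddingTable(vocab=vocab, V=V, theta=theta, config=config)


def _step_indices(
    table: EmbeddingTable, ci: int, ui: int, neg_idx: np.ndarray, lr: float
) -> float:
    """One simultaneous SGD ascent step on the pair objective; returns the
    pre-step objective value. Updates the table in place."""
    v = table.V[ci]
    idx = np.concatenate(([ui], neg_idx))
    U = table.theta[idx]  # (1+neg, d), pre-step values
    s = _sigmoid(U @ v)
    labels = np.zeros(len(idx))
    labels[0] = 1.0
    with np.errstate(divide="ignore"):
        obj = float(np.log(s[0]) + np.log1p(-s[1:]).sum())
    g = labels - s  # d(obj)/d(v^T theta_u)
    dv = U.T @ g
    np.add.at(table.theta, idx, lr * np.outer(g, v))
    table.V[ci] = v + lr * dv
    return obj


def sgns_step(
    center_token: str,
    context_token: str,
    negatives: list[str],
    table: EmbeddingTable,
    lr: float,
) -> float:
    """One SGD ascent step for (center, context, negatives); returns the
    pre-step objective log sigma(v.theta_u) + sum log(1 - sigma(v.theta_z)).

    All gradients are evaluated at the pre-step parameters (simultaneous
    update), so the step is exactly one ascent step of the objective.
    """
    if lr < 0:
        raise ValueError("learning rate must be >= 0")
    vocab = table.vocab
    for tok in [center_token, context_token, *negatives]:
        if tok not in vocab:
            raise KeyError(f"token not in vocabulary: {tok!r}")
    ci = vocab.index[center_token]
    ui = vocab.index[context_token]
    neg_idx = np.array([vocab.index[t] for t in negatives], dtype=int)
    return _step_indices(table, ci, ui, neg_idx, lr)


def pair_objective(
    table: EmbeddingTable, ci: int, ui: int, neg_idx: np.ndarray
) -> float:
    """Objective of one (center, context, negatives) tuple without stepping."""
    v = table.V[ci]
    idx = np.concatenate(([ui], neg_idx))
    s = _sigmoid(table.theta[idx] @ v)
    with np.errstate(divide="ignore"):
        return float(np.log(s[0]) + np.log1p(-s[1:]).sum())


def train_skipgram(
    corpus: list[TokenSequence],
    vocab: Vocab,
    config: SkipgramConfig | None = None,
) -> tuple[EmbeddingTable, list[float]]:
    """Train SGNS over the corpus; returns the table and per-epoch mean objective.

    Deterministic for a fixed seed: sentences are visited in corpus order,
    every (center, other) pair within distance <= window generates one
    positive example, and negatives are drawn from the count^power
    distribution with a seeded generator. The learning rate decays
    linearly from ``lr`` to ``lr_min`` over all steps.
    """
    config = config or SkipgramConfig()
    rng = np.random.default_rng(config.seed)
    table = init_table(vocab, config)
    sentences = [
        np.array([vocab.index[t] for t in sent.tokens if t in vocab], dtype=int)
        for sent in corpus
    ]
    sentences = [s for s in sentences if len(s) >= 2]
    if config.epochs == 0 or not sentences:
        return table, []

    dist = negative_sampling_distribution(vocab, config.power)
    cum = np.cumsum(dist)
    C = config.window
    n_pairs = sum(
        min(i + C + 1, len(s)) - max(0, i - C) - 1
        for s in sentences
        for i in range(len(s))
    )
    total_steps = config.epochs * n_pairs
    step = 0
    epoch_objectives: list[float] = []
    for _epoch in range(config.epochs):
        obj_sum = 0.0
        for sent in sentences:
            for i, ci in enumerate(sent):
                lo, hi = max(0, i - C), min(i + C + 1, len(sent))
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ui = int(sent[j])
                    neg = np.searchsorted(cum, rng.random(config.negatives))
                    # redraw negatives that collide with the true context
                    while np.any(neg == ui):
                        mask = neg == ui
                        neg[mask] = np.searchsorted(cum, rng.random(int(mask.sum())))
                    lr = max(
                        config.lr_min,
                        config.lr * (1.0 - step / total_steps),
                    )
                    obj_sum += _step_indices(table, int(ci), ui, neg, lr)
                    step += 1
        epoch_objectives.append(obj_sum / n_pairs)
    return table, epoch_objectives


def oov_vector(table: EmbeddingTable) -> np.ndarray:
    """Mean of all in-vocabulary input vectors: the OOV replacement vector."""
    if table.V.shape[0] == 0:
        raise ValueError("empty embedding table")
    return table.V.mean(axis=0)


def embed_entity(
    tokens: TokenSequence,
    table: EmbeddingTable,
    oov_policy: str = "averaged",
    rng: np.random.Generator | None = None,
) -> EntityEmbedding:
    """Entity embedding: mean of token vectors.

    OOV tokens contribute the vocabulary-mean vector under ``averaged``,
    a seeded random vector under ``random`` (the ablation baseline the
    averaged policy is compared against), or raise under ``error``.
    """
    if not tokens.tokens:
        raise ValueError(f"entity {tokens.entity_id!r} has no tokens")
    if oov_policy not in ("averaged", "random", "error"):
        raise ValueError(f"unknown oov policy {oov_policy!r}")
    vocab = table.vocab
    rows = []
    n_oov = 0
    mean_vec = None
    for tok in tokens.tokens:
        if tok in vocab:
            rows.append(table.V[vocab.index[tok]])
        else:
            n_oov += 1
            if oov_policy == "error":
                raise KeyError(
                    f"OOV token {tok!r} in entity {tokens.entity_id!r} under policy 'error'"
                )
            if oov_policy == "averaged":
                if mean_vec is None:
                    mean_vec = oov_vector(table)
                rows.append(mean_vec)
            else:  # random
                rng = rng or np.random.default_rng(0)
                rows.append((rng.random(table.d) - 0.5) / table.d)
    vec = np.mean(rows, axis=0)
    return EntityEmbedding(
        entity_id=tokens.entity_id,
        vector=vec,
        oov_fraction=n_oov / len(tokens.tokens),
    )


def save_word2vec_text(table: EmbeddingTable, path) -> None:
    """Persist the input vectors in word2vec text format ("count dim" header)."""
    toks = table.vocab.tokens
    with open(path, "w") as fh:
        fh.write(f"{len(toks)} {table.d}\n")
        for i, tok in enumerate(toks):
            vals = " ".join(repr(float(x)) for x in table.V[i])
            fh.write(f"{tok} {vals}\n")


def load_word2vec_text(path) -> tuple[list[str], np.ndarray]:
    """Load vectors from word2vec text format; returns (tokens, matrix)."""
    with open(path) as fh:
        header = fh.readline().split()
        n, d = int(header[0]), int(header[1])
        toks, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            toks.append(parts[0])
            rows.append(np.array([float(x) for x in parts[1 : d + 1]]))
    if len(toks) != n:
        raise ValueError(f"header promised {n} vectors, file has {len(toks)}")
    return toks, np.vstack(rows)
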