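"""GCN / simplified-GCN (SGC) stacks over the pair graph.

A GCN layer transforms node representations as H' = ReLU(S H Theta) with
a trainable Theta per layer; an SGC layer is the parameter-free smoothing
H' = S H. Classification is always closed by a single logistic head, so a
stack of K SGC layers collapses exactly to the closed form

    y_hat = sigmoid(S^K X Theta),

i.e. K-hop feature smoothing followed by plain logistic regression. That
collapse is what makes pure-SGC training cheap: the smoothing S^K X is
precomputed once, and the number of propagations is independent of the
number of optimization epochs. Mixed stacks are trained by full-batch
gradient descent on the masked binary cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression

from .pairgraph import PairGraph, propagate

__all__ = [
    "GCN",
    "SGC",
    "StackSpec",
    "parse_stack",
    "TrainConfig",
    "ModelParams",
    "gcn_layer",
    "sgc_forward",
    "stack_forward",
    "train_pure_sgc",
    "train_stack",
    "predict",
    "stack_loss_and_grads",
]

GCN = "gcn"
SGC = "sgc"


@dataclass(frozen=True)
class StackSpec:
    """Ordered layer kinds; hop count K equals the number of layers."""

    layers: tuple[str, ...]
    hidden: int = 64

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        bad = [l for l in self.layers if l not in (GCN, SGC)]
        if bad:
            raise ValueError(f"unknown layer kinds: {bad}")

    @property
    def K(self) -> int:
        return len(self.layers)

    @property
    def is_pure_sgc(self) -> bool:
        return all(l == SGC for l in self.layers)

    def __str__(self) -> str:
        return "+".join("SGCN" if l == SGC else "GCN" for l in self.layers)


def parse_stack(spec: str, hidden: int = 64) -> StackSpec:
    """Parse a stack grammar string like "GCN+SGCN+SGCN" (case-insensitive;
    "SGC" is accepted as an alias for "SGCN")."""
    layers = []
    for part in spec.split("+"):
        name = part.strip().lower()
        if name == "gcn":
            layers.append(GCN)
        elif name in ("sgcn", "sgc"):
            layers.append(SGC)
        else:
            raise ValueError(f"unparseable stack layer {part!r} in {spec!r}")
    return StackSpec(layers=tuple(layers), hidden=hidden)


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-2
    epochs: int = 300
    l2: float = 1e-4
    patience: int | None = 30
    val_fraction: float = 0.1
    seed: int = 0
    class_weight: str | None = None  # None | "balanced"

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.epochs < 0:
            raise ValueError("step size must be positive and epochs >= 0")


@dataclass
class ModelParams:
    """Trained weights: one Theta per GCN layer plus the logistic head."""

    stack: StackSpec | None
    thetas: list[np.ndarray]
    head_w: np.ndarray
    head_b: float
    seed: int
    trained: bool = False
    info: dict = field(default_factory=dict)


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def gcn_layer(S: sp.spmatrix, H: np.ndarray, Theta: np.ndarray) -> np.ndarray:
    """One graph-convolution layer: ReLU(S H Theta)."""
    if S.shape[1] != H.shape[0] or H.shape[1] != Theta.shape[0]:
        raise ValueError(
            f"shape mismatch: S {S.shape}, H {H.shape}, Theta {Theta.shape}"
        )
    return np.maximum(0.0, (S @ H) @ Theta)


def sgc_forward(
    S: sp.spmatrix, X: np.ndarray, K: int, head_w: np.ndarray, head_b: float
) -> np.ndarray:
    """Closed-form SGC: sigmoid(S^K X w + b) per node."""
    H = propagate(S, X, K)
    return _sigmoid(H @ head_w + head_b)


def init_params(stack: StackSpec, in_dim: int, seed: int = 0) -> ModelParams:
    """Glorot-style seeded initialization; SGC layers carry no parameters."""
    rng = np.random.default_rng(seed)
    thetas = []
    width = in_dim
    for layer in stack.layers:
        if layer == GCN:
            out = stack.hidden
            scale = np.sqrt(6.0 / (width + out))
            thetas.append(rng.uniform(-scale, scale, size=(width, out)))
            width = out
    scale = np.sqrt(6.0 / (width + 1))
    head_w = rng.uniform(-scale, scale, size=width)
    return ModelParams(stack=stack, thetas=thetas, head_w=head_w, head_b=0.0,
                       seed=seed)


def _forward(S, X, stack: StackSpec, params: ModelParams):
    """Forward pass; returns (prob, caches, n_propagations)."""
    H = X
    caches = []  # per layer: (kind, H_in, SH, Z) with SH = S @ H_in
    props = 0
    t = 0
    for layer in stack.layers:
        SH = S @ H
        props += 1
        if layer == SGC:
            caches.append((SGC, H, SH, None))
            H = SH
        else:
            Z = SH @ params.thetas[t]
            caches.append((GCN, H, SH, Z))
            H = np.maximum(0.0, Z)
            t += 1
    logits = H @ params.head_w + params.head_b
    return _sigmoid(logits), (caches, H), props


def stack_forward(
    S: sp.spmatrix, X: np.ndarray, stack: StackSpec, params: ModelParams
) -> np.ndarray:
    """Probability vector of an ordered GCN/SGC stack plus logistic head.

    A stack of K SGC layers reproduces :func:`sgc_forward` with hop count
    K bit-for-bit, because both apply the same sequence of sparse
    multiplications before the identical head.
    """
    n_gcn = sum(1 for l in stack.layers if l == GCN)
    if len(params.thetas) != n_gcn:
        raise ValueError(
            f"stack has {n_gcn} GCN layers but params carry {len(params.thetas)} Theta matrices"
        )
    p, _, _ = _forward(S, X, stack, params)
    return p


def train_pure_sgc(
    S: sp.spmatrix,
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    train_mask: np.ndarray,
    config: TrainConfig | None = None,
) -> ModelParams:
    """Fit the closed-form SGC: one K-hop smoothing precompute, then
    L2-regularized logistic regression on the masked rows.

    The propagation count is exactly one precompute regardless of the
    number of optimizer iterations — the structural efficiency property
    of the simplified model.
    """
    config = config or TrainConfig()
    y = np.asarray(y)
    ym = y[train_mask]
    if len(np.unique(ym)) < 2:
        raise ValueError("training labels contain a single class; cannot fit")
    Xhat = propagate(S, X, K)  # the single precompute
    clf = LogisticRegression(
        C=1.0 / max(config.l2 * ym.size, 1e-12),
        solver="lbfgs",
        max_iter=1000,
        tol=1e-10,
        class_weight=config.class_weight,
        random_state=config.seed,
    )
    clf.fit(Xhat[train_mask], ym)
    # K=0 is plain logistic regression; stack is None in that degenerate case
    params = ModelParams(
        stack=StackSpec(layers=(SGC,) * K) if K > 0 else None,
        thetas=[],
        head_w=clf.coef_.ravel().astype(float),
        head_b=float(clf.intercept_[0]),
        seed=config.seed,
        trained=True,
        info={
            "K": K,
            "propagation_precomputes": 1,
            "propagations_per_epoch": 0,
            "total_propagations": K,
        },
    )
    return params


def stack_loss_and_grads(
    S,
    X,
    y: np.ndarray,
    stack: StackSpec,
    params: ModelParams,
    mask: np.ndarray,
    l2: float,
    sample_weight: np.ndarray | None = None,
):
    """Masked mean binary cross-entropy + (l2/2)*||params||^2 and its gradients.

    Returns (loss, grad_thetas, grad_head_w, grad_head_b, n_propagations).
    Used both by the trainer and by finite-difference gradient checks.
    """
    y = np.asarray(y, dtype=float)
    p, (caches, H_final), props = _forward(S, X, stack, params)
    m = np.asarray(mask, dtype=bool)
    w = np.zeros(len(y))
    if sample_weight is None:
        w[m] = 1.0 / m.sum()
    else:
        w[m] = sample_weight[m] / sample_weight[m].sum()
    eps = 1e-12
    loss = -np.sum(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    loss += 0.5 * l2 * (
        sum(float(np.sum(t * t)) for t in params.thetas)
        + float(params.head_w @ params.head_w)
    )
    dlogits = w * (p - y)
    g_head_w = H_final.T @ dlogits + l2 * params.head_w
    g_head_b = float(dlogits.sum())
    dH = np.outer(dlogits, params.head_w)
    g_thetas = [np.zeros_like(t) for t in params.thetas]
    t_idx = len(params.thetas)
    for kind, H_in, SH, Z in reversed(caches):
        if kind == GCN:
            t_idx -= 1
            dZ = dH * (Z > 0)
            g_thetas[t_idx] = SH.T @ dZ + l2 * params.thetas[t_idx]
            dH = S @ (dZ @ params.thetas[t_idx].T)  # S symmetric
        else:
            dH = S @ dH
    return loss, g_thetas, g_head_w, g_head_b, props


def train_stack(
    S: sp.spmatrix,
    X: np.ndarray,
    y: np.ndarray,
    stack: StackSpec,
    train_mask: np.ndarray,
    config: TrainConfig | None = None,
) -> ModelParams:
    """Train a mixed GCN/SGC stack by full-batch gradient descent.

    Every epoch re-runs the forward pass, so the propagation count per
    epoch equals the number of layers — the structural contrast with
    :func:`train_pure_sgc`. Early stopping monitors the loss on a held-out
    validation slice of the training mask when ``patience`` is set.
    Returns params whose ``info`` carries the loss trajectory and
    propagation counters.
    """
    config = config or TrainConfig()
    y = np.asarray(y)
    m = np.asarray(train_mask, dtype=bool)
    if len(np.unique(y[m])) < 2:
        raise ValueError("training labels contain a single class; cannot fit")
    params = init_params(stack, X.shape[1], seed=config.seed)

    sample_weight = None
    if config.class_weight == "balanced":
        ym = y[m]
        freq = {c: np.mean(ym == c) for c in (0, 1)}
        sample_weight = np.where(y == 1, 0.5 / freq[1], 0.5 / freq[0])

    fit_mask, val_mask = m, None
    if config.patience is not None and config.val_fraction > 0:
        rng = np.random.default_rng(config.seed + 1)
        idx = np.flatnonzero(m)
        n_val = max(1, int(round(config.val_fraction * len(idx))))
        val_idx = rng.choice(idx, size=n_val, replace=False)
        val_mask = np.zeros_like(m)
        val_mask[val_idx] = True
        fit_mask = m & ~val_mask
        # keep both classes in the fit slice; otherwise fall back to no split
        if len(np.unique(y[fit_mask])) < 2 or len(np.unique(y[val_mask])) < 2:
            fit_mask, val_mask = m, None

    trajectory: list[float] = []
    total_props = 0
    best = None
    best_val = np.inf
    since_best = 0
    for _epoch in range(config.epochs):
        loss, g_t, g_w, g_b, props = stack_loss_and_grads(
            S, X, y, stack, params, fit_mask, config.l2, sample_weight
        )
        total_props += props
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged (non-finite loss); trajectory={trajectory}"
            )
        trajectory.append(float(loss))
        for t, g in zip(params.thetas, g_t):
            t -= config.lr * g
        params.head_w = params.head_w - config.lr * g_w
        params.head_b = params.head_b - config.lr * g_b
        if val_mask is not None:
            val_loss, *_ = stack_loss_and_grads(
                S, X, y, stack, params, val_mask, 0.0, sample_weight
            )
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best = ([t.copy() for t in params.thetas], params.head_w.copy(),
                        params.head_b)
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if best is not None:
        params.thetas, params.head_w, params.head_b = best
    params.trained = True
    params.info = {
        "loss_trajectory": trajectory,
        "epochs_run": len(trajectory),
        "propagation_precomputes": 0,
        "propagations_per_epoch": stack.K,
        "total_propagations": total_props,
    }
    return params


def predict(
    graph: PairGraph,
    stack: StackSpec,
    params: ModelParams,
    node_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard labels (probability >= 0.5 -> 1) for masked nodes."""
    if not params.trained:
        raise ValueError("params are untrained")
    p = stack_forward(graph.S, graph.X, stack, params)
    if node_mask is not None:
        p = p[np.asarray(node_mask, dtype=bool)]
    return p, (p >= 0.5).astype(int)
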