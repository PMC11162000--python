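"""Homogeneous pair-node graph construction and normalized propagation.

Each node is one compound-protein pair carrying the concatenation of the
two entity embeddings (2d = 200 features by default). Edges come from
cosine similarity between node feature vectors: each node is linked to
its k most-similar other nodes and the adjacency is symmetrized by
elementwise max. Feature smoothing uses the self-looped symmetric
normalization

    S = D~^(-1/2) (A + I) D~^(-1/2),   D~ = degree matrix of A + I,

whose eigenvalues lie in [-1, 1], so repeated propagation S^k X is
stable for any hop count k.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "PairNode",
    "PairGraph",
    "concat_features",
    "build_similarity_adjacency",
    "normalize_adjacency",
    "propagate",
    "build_pair_graph",
    "attach_test_nodes",
    "save_edge_list",
]


@dataclass(frozen=True)
class PairNode:
    pair_id: str
    compound_id: str
    protein_id: str
    features: np.ndarray
    label: int | None = None  # 1 interacting, 0 not, None unlabeled
    split: str = "train"  # "train" | "test"

    def __post_init__(self) -> None:
        if self.label not in (None, 0, 1):
            raise ValueError(f"label must be 0/1/None, got {self.label!r}")
        if self.split not in ("train", "test"):
            raise ValueError(f"unknown split {self.split!r}")


@dataclass
class PairGraph:
    """Ordered nodes plus sparse adjacency A and propagation operator S."""

    nodes: list[PairNode]
    X: np.ndarray  # (n, 2d) node features, row order == nodes order
    A: sp.csr_matrix
    S: sp.csr_matrix
    config: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def y(self) -> np.ndarray:
        """Labels with -1 for unlabeled nodes."""
        return np.array([-1 if nd.label is None else nd.label for nd in self.nodes])

    def mask(self, split: str) -> np.ndarray:
        return np.array([nd.split == split for nd in self.nodes])


def concat_features(
    compound_vec: np.ndarray, protein_vec: np.ndarray, d: int | None = None
) -> np.ndarray:
    """Pair feature vector: compound block first, protein block second."""
    c = np.asarray(compound_vec, dtype=float)
    p = np.asarray(protein_vec, dtype=float)
    if c.ndim != 1 or p.ndim != 1:
        raise ValueError("feature vectors must be one-dimensional")
    if d is not None and (c.shape[0] != d or p.shape[0] != d):
        raise ValueError(
            f"expected per-modality dimension {d}, got {c.shape[0]} and {p.shape[0]}"
        )
    if not (np.isfinite(c).all() and np.isfinite(p).all()):
        raise ValueError("non-finite feature values")
    return np.concatenate([c, p])


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"cosine similarity undefined for all-zero feature row {bad}")
    return X / norms[:, None]


def _topk_indices(sim_row: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest similarities, ties broken by lowest index."""
    order = np.lexsort((np.arange(len(sim_row)), -sim_row))
    return order[:k]


def build_similarity_adjacency(
    features: np.ndarray,
    k: int = 10,
    metric: str = "cosine",
    mode: str = "binary",
) -> sp.csr_matrix:
    """kNN similarity graph over node features.

    Every node connects to its k most-similar other nodes under cosine
    similarity (ties broken by lowest node index); the result is
    symmetrized by elementwise max, has a zero diagonal, and in
    ``weighted`` mode stores cosine similarities clipped to [0, 1].
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two nodes")
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n, got k={k}, n={n}")
    if metric != "cosine":
        raise ValueError(f"unsupported metric {metric!r}")
    if mode not in ("binary", "weighted"):
        raise ValueError(f"unsupported mode {mode!r}")
    Xn = _unit_rows(X)
    sims = Xn @ Xn.T
    np.fill_diagonal(sims, -np.inf)
    rows, cols, vals = [], [], []
    for i in range(n):
        nbrs = _topk_indices(sims[i], k)
        for j in nbrs:
            w = 1.0 if mode == "binary" else float(np.clip(sims[i, j], 0.0, 1.0))
            rows.append(i)
            cols.append(int(j))
            vals.append(w)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A = A.maximum(A.T)
    A.setdiag(0)
    A.eliminate_zeros()
    return A


def normalize_adjacency(A: sp.spmatrix) -> sp.csr_matrix:
    """Self-looped symmetric normalization S = D~^(-1/2) (A+I) D~^(-1/2)."""
    A = sp.csr_matrix(A)
    if A.nnz and A.data.min() < 0:
        raise ValueError("adjacency must be non-negative")
    if abs(A - A.T).max() > 1e-12:
        raise ValueError("adjacency must be symmetric")
    if abs(A.diagonal()).max() > 0:
        raise ValueError("adjacency must have zero diagonal")
    n = A.shape[0]
    At = A + sp.identity(n, format="csr")
    deg = np.asarray(At.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(deg)  # self-loop guarantees deg > 0
    D = sp.diags(dinv)
    return sp.csr_matrix(D @ At @ D)


def propagate(S: sp.spmatrix, X: np.ndarray, k: int) -> np.ndarray:
    """k-hop feature smoothing S^k X by repeated sparse multiplication."""
    if k < 0:
        raise ValueError("hop count must be >= 0")
    X = np.asarray(X, dtype=float)
    if S.shape[1] != X.shape[0]:
        raise ValueError(f"shape mismatch: S {S.shape} vs X {X.shape}")
    H = X
    for _ in range(k):
        H = S @ H
    return H


def build_pair_graph(
    nodes: list[PairNode],
    k: int = 10,
    metric: str = "cosine",
    mode: str = "binary",
) -> PairGraph:
    """Assemble a PairGraph; node order is the sorted order of pair_ids."""
    if len(nodes) != len({nd.pair_id for nd in nodes}):
        raise ValueError("duplicate pair_ids")
    nodes = sorted(nodes, key=lambda nd: nd.pair_id)
    X = np.vstack([nd.features for nd in nodes])
    A = build_similarity_adjacency(X, k=k, metric=metric, mode=mode)
    S = normalize_adjacency(A)
    return PairGraph(nodes=nodes, X=X, A=A, S=S,
                     config={"k": k, "metric": metric, "mode": mode})


def attach_test_nodes(
    train_graph: PairGraph, test_nodes: list[PairNode], k: int | None = None
) -> PairGraph:
    """Transductive attachment: each test node gains edges to its k
    most-similar TRAIN nodes only (no test-test edges), and S is
    recomputed. The train block of the new adjacency equals the old
    adjacency, so no information flows between held-out nodes.
    """
    if not test_nodes:
        raise ValueError("empty test node list")
    k = k if k is not None else train_graph.config.get("k", 10)
    mode = train_graph.config.get("mode", "binary")
    test_nodes = sorted(test_nodes, key=lambda nd: nd.pair_id)
    Xtr = train_graph.X
    Xte = np.vstack([nd.features for nd in test_nodes])
    if Xte.shape[1] != Xtr.shape[1]:
        raise ValueError("test feature dimension mismatch")
    n_tr, n_te = Xtr.shape[0], Xte.shape[0]
    sims = _unit_rows(Xte) @ _unit_rows(Xtr).T
    rows, cols, vals = [], [], []
    for i in range(n_te):
        for j in _topk_indices(sims[i], min(k, n_tr)):
            w = 1.0 if mode == "binary" else float(np.clip(sims[i, j], 0.0, 1.0))
            rows.append(i)
            cols.append(int(j))
            vals.append(w)
    B = sp.coo_matrix((vals, (rows, cols)), shape=(n_te, n_tr)).tocsr()
    A = sp.bmat(
        [[train_graph.A, B.T], [B, sp.csr_matrix((n_te, n_te))]], format="csr"
    )
    S = normalize_adjacency(A)
    nodes = list(train_graph.nodes) + [replace(nd, split="test") for nd in test_nodes]
    X = np.vstack([Xtr, Xte])
    cfg = dict(train_graph.config)
    cfg["attached_test_nodes"] = n_te
    return PairGraph(nodes=nodes, X=X, A=A, S=S, config=cfg)


def save_edge_list(graph: PairGraph, edges_path, nodes_path=None) -> None:
    """Persist the adjacency as `src dst weight` TSV plus an optional node table."""
    coo = sp.coo_matrix(sp.triu(graph.A))
    with open(edges_path, "w") as fh:
        fh.write("src\tdst\tweight\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{graph.nodes[i].pair_id}\t{graph.nodes[j].pair_id}\t{w:g}\n")
    if nodes_path is not None:
        with open(nodes_path, "w") as fh:
            fh.write("pair_id\tcompound_id\tprotein_id\tlabel\tsplit\n")
            for nd in graph.nodes:
                lab = "" if nd.label is None else nd.label
                fh.write(
                    f"{nd.pair_id}\t{nd.compound_id}\t{nd.protein_id}\t{lab}\t{nd.split}\n"
                )
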