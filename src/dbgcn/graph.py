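"""Pearson-correlation brain networks and the graph machinery of the classifier.

Electrodes are graph nodes; the edge weight between channels i and j is the
Pearson correlation of their (preprocessed, continuous) time series, giving a
dense symmetric adjacency A with unit diagonal.  From A we derive

    S = D_tilde^{-1/2} (A' + I) D_tilde^{-1/2},

the symmetric-normalized propagation operator with self-loops used by graph
convolution, where A' resolves the sign of correlations (absolute value by
default: negative correlations still carry connectivity strength, and the
degree normalization requires non-negative weights).

Pooling halves the node count per level via deterministic greedy heavy-edge
matching on |A|: the strongest-correlated unmatched pair merges first, ties
break toward lower indices, and a left-over node forms a singleton group.
Coarse edge weights are sums of the fine edge weights between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BrainGraph",
    "PoolingLevel",
    "pearson",
    "adjacency_from_data",
    "propagation_matrix",
    "build_pooling_hierarchy",
]


@dataclass
class BrainGraph:
    """Dense correlation adjacency over named channels."""

    adjacency: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=np.float64)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got {A.shape}")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.abs(A) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class PoolingLevel:
    """One coarsening step: fine-node -> group assignment and the coarse graph."""

    assignment: np.ndarray  # (n_fine,) coarse index per fine node
    groups: list[np.ndarray] = field(repr=False)  # coarse index -> fine indices
    coarse_adjacency: np.ndarray = field(repr=False)

    @property
    def n_fine(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_coarse(self) -> int:
        return len(self.groups)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient between two equal-length series.

    r = sum((x_i - x_bar)(y_i - y_bar)) / sqrt(sum((x_i - x_bar)^2) sum((y_i - y_bar)^2))
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def adjacency_from_data(data: np.ndarray, channel_names: list[str]) -> BrainGraph:
    """Correlation adjacency of a (channels x samples) matrix."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError(f"need a (>=2 channels, >=2 samples) matrix, got {data.shape}")
    stds = data.std(axis=1)
    # relative tolerance: a constant channel leaves only rounding residue
    degenerate = stds <= 1e-12 * np.maximum(1.0, np.abs(data).max(axis=1))
    if np.any(degenerate):
        bad = [channel_names[i] for i in np.flatnonzero(degenerate)]
        raise ValueError(f"constant channel(s) make correlation undefined: {bad}")
    A = np.corrcoef(data)
    A = np.clip((A + A.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(A, 1.0)
    return BrainGraph(adjacency=A, channel_names=list(channel_names))


def _signed(A: np.ndarray, signed_policy: str) -> np.ndarray:
    if signed_policy == "abs":
        return np.abs(A)
    if signed_policy == "clip_negative":
        return np.maximum(A, 0.0)
    raise ValueError(f"unknown signed_policy {signed_policy!r}; use 'abs' or 'clip_negative'")


def propagation_matrix(adjacency: "BrainGraph | np.ndarray", signed_policy: str = "abs") -> np.ndarray:
    """Symmetric-normalized propagation operator with self-loops.

    A' (sign-resolved, zero diagonal) gains an identity self-loop, and is
    normalized by the inverse square root of its degree matrix.  With +I every
    degree is strictly positive, so S is always well-defined.
    """
    if isinstance(adjacency, BrainGraph):
        adjacency = adjacency.adjacency
    A = np.asarray(adjacency, dtype=np.float64)
    Ap = _signed(A, signed_policy).copy()
    np.fill_diagonal(Ap, 0.0)
    A_tilde = Ap + np.eye(A.shape[0])
    deg = A_tilde.sum(axis=1)
    assert np.all(deg > 0), "self-loops guarantee positive degrees"
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return d_inv_sqrt[:, None] * A_tilde * d_inv_sqrt[None, :]


def _heavy_edge_matching(A: np.ndarray) -> list[np.ndarray]:
    """Greedy maximum-weight pairing on |A|; deterministic low-index tie-break.

    Edges are visited in decreasing |weight| (ties by lower (i, j)); each node
    is matched at most once; left-over nodes become singletons ordered by index.
    """
    n = A.shape[0]
    W = np.abs(np.asarray(A, dtype=np.float64))
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, -W[iu, ju]))  # weight desc, then i asc, then j asc
    matched = np.zeros(n, dtype=bool)
    groups: list[np.ndarray] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if not matched[i] and not matched[j]:
            matched[i] = matched[j] = True
            groups.append(np.array([i, j]))
    for i in np.flatnonzero(~matched):
        groups.append(np.array([int(i)]))
    # stable ordering of coarse nodes: by smallest member index
    groups.sort(key=lambda g: int(g[0]))
    return groups


def build_pooling_hierarchy(g: BrainGraph, levels: int = 2, signed_policy: str = "abs") -> list[PoolingLevel]:
    """Coarsening hierarchy for 50% pooling: level k has ceil(n / 2^k) nodes.

    Also used to pre-compute the propagation operator at every depth of the
    network (fine graph for layer 1, each coarse graph for deeper layers).
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if g.n_nodes < 2 ** levels:
        raise ValueError(
            f"{g.n_nodes} nodes cannot support {levels} halving levels "
            f"(need at least {2 ** levels})"
        )
    hierarchy: list[PoolingLevel] = []
    A = _signed(g.adjacency, signed_policy).copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    for _ in range(levels):
        groups = _heavy_edge_matching(A)
        n_coarse = len(groups)
        assert n_coarse == int(np.ceil(n / 2))
        assignment = np.empty(n, dtype=np.int64)
        for ci, members in enumerate(groups):
            assignment[members] = ci
        # coarse edge = sum of fine edges between the two groups
        pool = np.zeros((n, n_coarse))
        pool[np.arange(n), assignment] = 1.0
        A_coarse = pool.T @ A @ pool
        np.fill_diagonal(A_coarse, 0.0)
        hierarchy.append(PoolingLevel(assignment=assignment, groups=groups, coarse_adjacency=A_coarse))
        A = A_coarse
        n = n_coarse
    return hierarchy
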