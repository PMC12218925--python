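"""k-nearest-neighbour hypergraph construction and the normalised
feature-propagation operator.

Every sample is a vertex; for each vertex ``i`` one hyperedge is formed
containing ``i`` and its ``k`` nearest neighbours under Euclidean distance,
so the incidence matrix ``H`` (|V| x |E|, binary) has N columns each with
exactly ``k + 1`` nonzeros.  Hyperedge weights start at 1 (diagonal ``W``).
Degrees are

    Dv(v) = sum_e w(e) H(v, e)        (vertex degree)
    De(e) = sum_v H(v, e)             (hyperedge degree)

and the propagation operator used by the hypergraph convolution
``X' = sigma(P X Theta)`` is

    P = Dv^(-1/2) H W De^(-1) H^T Dv^(-1/2).

``P`` is symmetric and non-negative, has spectral radius <= 1, and fixes
the vector ``Dv^(1/2) 1`` — diffusion conserves the degree-weighted mass.

Neighbour ties are broken by ascending vertex index so construction is
deterministic; duplicate points (distance 0) rank first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .exceptions import DegenerateInputError, FormatError, ShapeError
from .feature_table import FeatureTable
from .nn_ops import relu

__all__ = [
    "Hypergraph",
    "PropagationOperator",
    "euclidean_distance",
    "k_nearest",
    "build_hypergraph",
    "propagation_operator",
    "hypergraph_convolve",
    "save_hypergraph",
    "load_hypergraph",
]


def euclidean_distance(p, q) -> float:
    """L2 distance ``sqrt(sum_i (q_i - p_i)^2)`` between two vectors."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ShapeError(f"dimension mismatch: {p.shape} vs {q.shape}")
    return float(np.sqrt(np.sum((q - p) ** 2)))


def _feature_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureTable):
        X = X.features
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ShapeError(f"expected an (N, D) feature matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ShapeError("feature matrix contains NaN or Inf entries")
    return X


def _neighbour_order(X: np.ndarray) -> np.ndarray:
    """Row i: all other vertices sorted by (distance to i, index)."""
    d = cdist(X, X)
    np.fill_diagonal(d, -1.0)  # self always sorts first, then dropped
    order = np.argsort(d, axis=1, kind="stable")  # stable => index tie-break
    return order[:, 1:]


def k_nearest(i: int, X, k: int) -> np.ndarray:
    """Indices of the ``k`` nearest vertices to vertex ``i`` (excluding i).

    Ordered by increasing Euclidean distance; exact ties are broken by the
    lower vertex index.
    """
    X = _feature_matrix(X)
    n = X.shape[0]
    if not (0 <= i < n):
        raise ShapeError(f"vertex index {i} out of range for N={n}")
    if not (1 <= k <= n - 1):
        raise DegenerateInputError(f"k must satisfy 1 <= k <= N-1, got k={k}, N={n}")
    d = np.sqrt(np.sum((X - X[i]) ** 2, axis=1))
    d[i] = -1.0
    order = np.argsort(d, kind="stable")
    return order[1 : k + 1]


@dataclass
class Hypergraph:
    """Incidence structure of a kNN hypergraph.

    Attributes
    ----------
    H : scipy.sparse.csr_matrix, shape (|V|, |E|)
        Binary incidence matrix; column e lists the members of hyperedge e.
    W : ndarray, shape (|E|,)
        Hyperedge weights (all 1 at construction).
    k : int
        Neighbour count used to build the hyperedges.
    """

    H: sp.csr_matrix
    W: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.H = sp.csr_matrix(self.H)
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.shape != (self.H.shape[1],):
            raise ShapeError("W must have one weight per hyperedge")
        data = self.H.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ShapeError("incidence matrix entries must be binary")

    @property
    def n_vertices(self) -> int:
        return self.H.shape[0]

    @property
    def n_edges(self) -> int:
        return self.H.shape[1]

    @property
    def vertex_degrees(self) -> np.ndarray:
        """Dv(v) = sum_e w(e) H(v, e)."""
        return np.asarray(self.H @ self.W).ravel()

    @property
    def edge_degrees(self) -> np.ndarray:
        """De(e) = sum_v H(v, e)."""
        return np.asarray(self.H.sum(axis=0)).ravel()

    # short aliases used throughout
    @property
    def Dv(self) -> np.ndarray:
        return self.vertex_degrees

    @property
    def De(self) -> np.ndarray:
        return self.edge_degrees


def build_hypergraph(X, k: int) -> Hypergraph:
    """Build the kNN hypergraph of a feature table or matrix.

    One hyperedge per vertex: ``e_i = {i} ∪ kNN(i)`` with weight 1, so
    every incidence column has exactly ``k + 1`` entries (``k = 0`` gives
    self-only hyperedges, H = I).
    """
    X = _feature_matrix(X)
    n = X.shape[0]
    if n < 2:
        raise DegenerateInputError(f"need at least 2 vertices, got {n}")
    if not (0 <= k <= n - 1):
        raise DegenerateInputError(f"k must satisfy 0 <= k <= N-1, got k={k}, N={n}")
    if k == 0:
        members = np.arange(n)[:, None]
    else:
        members = np.concatenate(
            [np.arange(n)[:, None], _neighbour_order(X)[:, :k]], axis=1
        )
    rows = members.ravel()
    cols = np.repeat(np.arange(n), k + 1)
    H = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    )
    # a vertex may appear in many hyperedges but only once per edge
    H.data[:] = 1.0
    return Hypergraph(H=H, W=np.ones(n), k=k)


@dataclass
class PropagationOperator:
    """The normalised diffusion matrix P = Dv^-1/2 H W De^-1 H^T Dv^-1/2."""

    matrix: sp.csr_matrix

    def dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    @property
    def shape(self):
        return self.matrix.shape

    def __matmul__(self, other):
        return self.matrix @ other


def propagation_operator(hg: Hypergraph) -> PropagationOperator:
    """Form the normalised propagation operator of a hypergraph.

    Raises
    ------
    DegenerateInputError
        If a vertex belongs to no hyperedge (Dv = 0) or an empty hyperedge
        exists (De = 0), which would make the normalisation singular.
    """
    dv = hg.vertex_degrees
    de = hg.edge_degrees
    if np.any(dv <= 0):
        raise DegenerateInputError("hypergraph has an isolated vertex (Dv = 0)")
    if np.any(de <= 0):
        raise DegenerateInputError("hypergraph has an empty hyperedge (De = 0)")
    dv_isqrt = sp.diags(1.0 / np.sqrt(dv))
    edge_scale = sp.diags(hg.W / de)
    P = dv_isqrt @ hg.H @ edge_scale @ hg.H.T @ dv_isqrt
    return PropagationOperator(matrix=sp.csr_matrix(P))


def hypergraph_convolve(
    hg: Union[Hypergraph, PropagationOperator],
    X_l: np.ndarray,
    Theta: np.ndarray,
    activation: Optional[Callable] = relu,
) -> np.ndarray:
    """One hypergraph convolution: ``sigma(P @ X_l @ Theta)``.

    ``activation=None`` (identity) makes the map linear in ``X_l``.
    """
    P = hg if isinstance(hg, PropagationOperator) else propagation_operator(hg)
    X_l = np.asarray(X_l, dtype=np.float64)
    Theta = np.asarray(Theta, dtype=np.float64)
    if X_l.ndim != 2 or X_l.shape[0] != P.shape[0]:
        raise ShapeError(
            f"X_l must be (N, C1) with N={P.shape[0]} vertices, got {X_l.shape}"
        )
    if Theta.ndim != 2 or Theta.shape[0] != X_l.shape[1]:
        raise ShapeError(
            f"Theta must be ({X_l.shape[1]}, C2), got {Theta.shape}"
        )
    out = P @ (X_l @ Theta)
    return out if activation is None else activation(out)


# --------------------------------------------------------------------- #
# serialisation: edge-list text + JSON sidecar


def save_hypergraph(hg: Hypergraph, path) -> None:
    """Write one line per hyperedge: ``edge_id weight v1 v2 ...``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Hc = hg.H.tocsc()
    lines = []
    for e in range(hg.n_edges):
        members = Hc.indices[Hc.indptr[e] : Hc.indptr[e + 1]]
        lines.append(
            f"{e}\t{hg.W[e]:.17g}\t" + " ".join(str(v) for v in sorted(members))
        )
    path.write_text("\n".join(lines) + "\n")
    sidecar = {"n_vertices": hg.n_vertices, "n_edges": hg.n_edges, "k": hg.k}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_hypergraph(path) -> Hypergraph:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing hypergraph sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    n_v, n_e = int(meta["n_vertices"]), int(meta["n_edges"])
    weights = np.ones(n_e)
    rows, cols = [], []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"malformed hyperedge line in {path}: {line!r}")
        e = int(parts[0])
        weights[e] = float(parts[1])
        for v in parts[2].split():
            rows.append(int(v))
            cols.append(e)
    H = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_v, n_e))
    return Hypergraph(H=H, W=weights, k=int(meta["k"]))
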