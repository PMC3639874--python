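"""Optimal-assignment (OA) molecular similarity with assignment-edge weights.

The OA similarity of two molecular graphs A (atoms a1..am) and B (atoms
b1..bn) is the maximum, over injective mappings pi of the smaller
molecule's atoms onto the larger one's, of the summed pairwise atom
similarities S[i, pi(i)].  Pairwise atom similarities combine a radial
basis function (RBF) over standardized physico-chemical descriptor
vectors with a recursive comparison of the topological neighborhoods up
to depth 2, down-weighted by a decay d(dist) = (1 - dist/3)^2.  The raw
OA score is normalized to [0, 1] by S(A,B) / sqrt(S(A,A) S(B,B)).

A query molecule can carry per-atom assignment-edge weights w (w_i >= 0,
sum w_i = m) expressing how important each query atom is; the weighted
objective maximizes sum_i w_i S[i, pi(i)], i.e. the OA of the row-scaled
matrix diag(w) S.  The weights are fixed throughout the similarity
calculations of a complete virtual-screening run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .chemgraph import MoleculeGraph

__all__ = [
    "DECAY_AT",
    "decay",
    "atom_similarity",
    "pairwise_matrix",
    "SimilarityMatrix",
    "AssignmentResult",
    "optimal_assignment",
    "self_similarity",
    "normalized_similarity",
    "normalize_weights",
    "weighted_similarity",
    "VirtualScreen",
    "save_weights",
    "load_weights",
]

MAX_DEPTH = 2
#: decay d(dist) = (1 - dist/3)^2 at distances 0, 1, 2
DECAY_AT = ((1.0, (1 - 1 / 3) ** 2, (1 - 2 / 3) ** 2))
#: default RBF width on [0,1]-standardized descriptors, chosen so that two
#: different first-row heavy atoms in otherwise identical environments score
#: around 0.5 instead of the near-1 plateau a width of 1/k_a would give
DEFAULT_GAMMA = 4.0


def decay(mol: MoleculeGraph, center: int, nb: int) -> float:
    """Neighbor-influence decay d = (1 - dist/3)^2 for dist <= 2.

    1 at the center itself, decreasing with topological distance, and 0
    at distance 3 (just beyond the depth-2 neighborhood cutoff).
    """
    from .chemgraph import topo_distance

    dist = topo_distance(mol, center, nb)
    if not dist <= MAX_DEPTH:
        raise ValueError(f"decay undefined beyond depth {MAX_DEPTH}: dist({center},{nb}) = {dist}")
    return (1.0 - dist / 3.0) ** 2


@dataclass
class SimilarityMatrix:
    """m x n pairwise inter-molecule atom similarities, entries in [0, 1]."""

    entries: np.ndarray
    row_id: str
    col_id: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


@dataclass
class AssignmentResult:
    """Solved (weighted) optimal assignment.

    ``mapping`` maps atom indices of the smaller molecule to atom indices
    of the larger one (|mapping| = min(m, n), injective); ``raw_score``
    is the maximized sum of (weighted) mapped similarities.
    """

    row_ind: np.ndarray
    col_ind: np.ndarray
    raw_score: float
    n_rows: int
    n_cols: int
    normalized_score: float | None = None

    @property
    def mapping(self) -> dict[int, int]:
        if self.n_rows <= self.n_cols:
            return dict(zip(self.row_ind.tolist(), self.col_ind.tolist()))
        return dict(zip(self.col_ind.tolist(), self.row_ind.tolist()))


def _rbf(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(X, Y, metric="sqeuclidean"))


def _matched_sum(M: np.ndarray) -> float:
    """Maximum-weight assignment value of a small nonnegative matrix."""
    if min(M.shape) == 1:
        return float(M.max())
    r, c = linear_sum_assignment(M, maximize=True)
    return float(M[r, c].sum())


def pairwise_matrix(A: MoleculeGraph, B: MoleculeGraph, depth: int = MAX_DEPTH,
                    gamma: float | None = None) -> SimilarityMatrix:
    """All pairwise atom similarities between A and B.

    Entry (i, j) combines the center RBF term exp(-gamma ||x_i - x_j||^2)
    with a neighbor-environment term: the neighbors of i and j are matched
    by a small optimal assignment of their pairwise similarities (bond-RBF
    times the depth-reduced atom similarity), and center and matched
    neighbors are averaged with decay weights::

        S_r(i, j) = (S_0(i, j) + d(1) * sum_matched M_r) / (1 + d(1) * max(|N_i|, |N_j|))

    where M_r[a, b] = rbf_bond(e_ia, e_jb) * S_{r-1}(a, b).  Unmatched
    neighbors (size mismatch) contribute zero similarity at full decay
    weight, so a missing neighbor is penalized.  Identical atoms in
    identical environments score exactly 1.
    """
    if A.atom_descriptors is None or B.atom_descriptors is None:
        raise ValueError("descriptors must be computed on both molecules")
    if A.atom_descriptors.shape[1] != B.atom_descriptors.shape[1]:
        raise ValueError("descriptor length mismatch between molecules")
    if A.n_atoms == 0 or B.n_atoms == 0:
        raise ValueError("cannot compare an empty molecule")

    if gamma is None:
        gamma = DEFAULT_GAMMA
    k_b = A.bond_descriptors.shape[1]
    gamma_b = 1.0 / max(k_b, 1)
    d1 = DECAY_AT[1]

    S0 = _rbf(A.atom_descriptors, B.atom_descriptors, gamma)
    if A.bond_descriptors.shape[0] and B.bond_descriptors.shape[0]:
        Eb = _rbf(A.bond_descriptors, B.bond_descriptors, gamma_b)
    else:
        Eb = np.empty((A.bond_descriptors.shape[0], B.bond_descriptors.shape[0]))

    m, n = S0.shape
    S_prev = S0
    for _ in range(depth):
        S_new = np.empty_like(S0)
        for i in range(m):
            Ni, Ei = A.neighbors[i], A.edge_index[i]
            for j in range(n):
                Nj, Ej = B.neighbors[j], B.edge_index[j]
                k = max(len(Ni), len(Nj))
                if k == 0:
                    S_new[i, j] = S0[i, j]
                    continue
                if len(Ni) == 0 or len(Nj) == 0:
                    matched = 0.0
                else:
                    M = Eb[np.ix_(Ei, Ej)] * S_prev[np.ix_(Ni, Nj)]
                    matched = _matched_sum(M)
                S_new[i, j] = (S0[i, j] + d1 * matched) / (1.0 + d1 * k)
        S_prev = S_new
    np.clip(S_prev, 0.0, 1.0, out=S_prev)
    return SimilarityMatrix(entries=S_prev, row_id=A.source_id, col_id=B.source_id)


def atom_similarity(A: MoleculeGraph, i: int, B: MoleculeGraph, j: int,
                    depth: int = MAX_DEPTH) -> float:
    """Recursive neighborhood-aware similarity of atom i of A and atom j of B."""
    return float(pairwise_matrix(A, B, depth=depth).entries[i, j])


def optimal_assignment(S: SimilarityMatrix | np.ndarray) -> AssignmentResult:
    """Solve the OA problem on S by the Hungarian method.

    Maximizes the summed mapped entries over injective mappings of the
    smaller side onto the larger side; O(max(m, n)^3).
    """
    entries = S.entries if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if entries.ndim != 2 or entries.size == 0:
        raise ValueError("similarity matrix must be 2-D and nonempty")
    if not np.isfinite(entries).all():
        raise ValueError("similarity matrix must be finite")
    row_ind, col_ind = linear_sum_assignment(entries, maximize=True)
    raw = float(entries[row_ind, col_ind].sum())
    return AssignmentResult(row_ind=row_ind, col_ind=col_ind, raw_score=raw,
                            n_rows=entries.shape[0], n_cols=entries.shape[1])


def self_similarity(A: MoleculeGraph, depth: int = MAX_DEPTH,
                    gamma: float | None = None) -> float:
    """Raw OA self score S(A, A); equals the atom count for a unit diagonal."""
    return optimal_assignment(pairwise_matrix(A, A, depth=depth, gamma=gamma)).raw_score


def normalized_similarity(A: MoleculeGraph, B: MoleculeGraph, depth: int = MAX_DEPTH,
                          gamma: float | None = None) -> float:
    """Size-normalized OA similarity S(A,B) / sqrt(S(A,A) S(B,B)) in [0, 1]."""
    raw = optimal_assignment(pairwise_matrix(A, B, depth=depth, gamma=gamma)).raw_score
    denom = self_similarity(A, depth, gamma) * self_similarity(B, depth, gamma)
    if denom <= 0:
        raise ValueError("zero self-similarity")
    return min(1.0, raw / np.sqrt(denom))


def normalize_weights(raw: np.ndarray) -> np.ndarray:
    """Map a raw search-space vector in [-0.5, 0.5]^m onto the constraint set.

    Values are clipped to the bounds, shifted by +0.5 into [0, 1], and
    scaled so the result is nonnegative and sums to m.  A degenerate
    all-zero shifted vector falls back to the uniform weight vector.
    """
    raw = np.asarray(raw, dtype=float)
    m = raw.size
    if m == 0:
        raise ValueError("empty weight vector")
    shifted = np.clip(raw, -0.5, 0.5) + 0.5
    total = shifted.sum()
    if total <= 0.0:
        return np.ones(m)
    return shifted * (m / total)


def check_weight_vector(w: np.ndarray, m: int, tol: float = 1e-9) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.size != m:
        raise ValueError(f"weight vector length {w.size} != query atom count {m}")
    if (w < -tol).any():
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - m) > max(tol, 1e-9 * m):
        raise ValueError(f"weights must sum to {m}, got {w.sum()}")
    return w


def weighted_similarity(Q: MoleculeGraph, B: MoleculeGraph, w: np.ndarray,
                        S: SimilarityMatrix | None = None,
                        self_B: float | None = None,
                        depth: int = MAX_DEPTH) -> AssignmentResult:
    """Edge-weighted OA of query Q against library molecule B.

    Maximizes sum_i w_i S[i, pi(i)] with the weight always attached to the
    query-atom side of each assignment edge, i.e. the OA of the row-scaled
    matrix diag(w) S.  The normalized score divides by
    sqrt(S_w(Q,Q) S(B,B)) with S_w(Q,Q) = sum_i w_i S_ii = m (the weighted
    identity self-assignment).  With uniform weights this reproduces the
    unweighted pipeline exactly.
    """
    w = check_weight_vector(w, Q.n_atoms)
    if S is None:
        S = pairwise_matrix(Q, B, depth=depth)
    scaled = w[:, None] * S.entries
    result = optimal_assignment(scaled)
    if self_B is None:
        self_B = self_similarity(B, depth)
    result.normalized_score = float(result.raw_score / np.sqrt(Q.n_atoms * self_B))
    return result


class VirtualScreen:
    """One query against a fixed library, with precomputed similarities.

    The pairwise similarity matrices S(Q, B) and the library self scores
    do not depend on the edge weights, so they are computed once; scoring
    a weight vector then only re-solves the (row-scaled) assignments.
    """

    def __init__(self, query: MoleculeGraph, library: list[MoleculeGraph],
                 depth: int = MAX_DEPTH, gamma: float | None = None):
        self.query = query
        self.library = library
        self.depth = depth
        self._S = [pairwise_matrix(query, b, depth=depth, gamma=gamma).entries for b in library]
        self._self_B = np.array([self_similarity(b, depth, gamma) for b in library])
        self._m = query.n_atoms

    def __len__(self) -> int:
        return len(self.library)

    def subset(self, indices) -> "VirtualScreen":
        view = object.__new__(VirtualScreen)
        view.query = self.query
        view.library = [self.library[i] for i in indices]
        view.depth = self.depth
        view._S = [self._S[i] for i in indices]
        view._self_B = self._self_B[list(indices)]
        view._m = self._m
        return view

    def scores(self, weights: np.ndarray | None = None) -> np.ndarray:
        """Normalized (weighted) OA score of every library molecule."""
        if weights is None:
            weights = np.ones(self._m)
        else:
            weights = check_weight_vector(weights, self._m)
        raw = np.empty(len(self._S))
        for k, S in enumerate(self._S):
            raw[k] = _matched_sum(weights[:, None] * S)
        return raw / np.sqrt(self._m * self._self_B)


def save_weights(path, w: np.ndarray, query_id: str) -> None:
    """Write a weight file (JSON: query id, m, 0-based per-atom weights)."""
    import json

    w = np.asarray(w, dtype=float)
    payload = {"query_id": query_id, "m": int(w.size), "weights": w.tolist()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_weights(path) -> tuple[np.ndarray, str]:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    # plain weight files carry "weights"; optimization run artifacts "best_weights"
    key = "weights" if "weights" in payload else "best_weights"
    w = np.asarray(payload[key], dtype=float)
    if w.size != payload.get("m", w.size):
        raise ValueError("weight file header m does not match weight count")
    return w, payload.get("query_id", "")
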