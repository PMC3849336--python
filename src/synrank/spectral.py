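"""Subnetwork objective, exact bounded-size maximum-weighted-clique search,
and the spectral (leading-eigenvector) relaxation used for feature ranking."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ComplexityGuardError, InputError
from .network import SynergyMatrix, SynergyNetwork, to_matrix

__all__ = [
    "SpectralRanking",
    "SubnetworkSolution",
    "subnetwork_objective",
    "solve_exact",
    "leading_eigenpair",
    "rank_features",
    "spectral_topk",
]

_EXACT_MAX_NODES = 25
# ranking keys are rounded so that analytically tied scores break by the
# documented convention instead of eigen-solver noise
_TIE_DECIMALS = 10


@dataclass
class SpectralRanking:
    """Per-feature scores |x*| from the leading eigenvector of M.

    ``order`` sorts features by score descending, breaking ties by node
    weight descending then feature index ascending.  When M is diagonal
    (lam = 0 or an all-zero edge matrix) the eigenvector ranking is
    degenerate and the individual-power ordering is returned instead, with
    ``diagonal_fallback_used`` set.
    """

    scores: np.ndarray
    eigenvalue: float
    order: np.ndarray
    diagonal_fallback_used: bool
    unstable: bool
    feature_names: list[str]


@dataclass
class SubnetworkSolution:
    subset: tuple[int, ...]
    objective: float
    K: int


def subnetwork_objective(subset, network: SynergyNetwork) -> float:
    """Sum of node weights plus lam times the sum over internal unordered pairs."""
    idx = np.asarray(sorted(set(int(i) for i in subset)), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= network.n_features):
        raise InputError("subset contains out-of-range feature indices")
    if idx.size == 0:
        return 0.0
    node_sum = float(network.node_weights[idx].sum())
    edge_sum = float(network.edge_weights[np.ix_(idx, idx)].sum()) / 2.0
    return node_sum + network.lam * edge_sum


def solve_exact(network: SynergyNetwork, K: int) -> SubnetworkSolution:
    """Enumerate all subsets of size <= K and return the objective maximizer.

    Ties are broken toward the smaller subset, then lexicographically
    smallest indices. Guarded to <= 25 nodes.
    """
    n = network.n_features
    if n > _EXACT_MAX_NODES:
        raise ComplexityGuardError(
            f"exact search is limited to {_EXACT_MAX_NODES} nodes (got {n}); "
            "use the spectral ranking instead"
        )
    if K < 1:
        raise InputError("K must be a positive integer")
    K = min(K, n)
    best_subset: tuple[int, ...] = ()
    best_obj = 0.0  # empty subset
    f = network.node_weights
    s = network.edge_weights
    lam = network.lam
    for size in range(1, K + 1):
        for subset in combinations(range(n), size):
            idx = np.asarray(subset)
            obj = float(f[idx].sum()) + lam * float(s[np.ix_(idx, idx)].sum()) / 2.0
            if obj > best_obj:
                best_obj, best_subset = obj, subset
    return SubnetworkSolution(subset=best_subset, objective=best_obj, K=K)


def leading_eigenpair(M: SynergyMatrix | np.ndarray) -> tuple[float, np.ndarray]:
    """Largest eigenvalue and unit-norm eigenvector of a symmetric matrix."""
    A = M.M if isinstance(M, SynergyMatrix) else np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InputError("matrix must be square")
    if not np.isfinite(A).all():
        raise InputError("matrix contains non-finite entries")
    vals, vecs = np.linalg.eigh((A + A.T) / 2.0)
    return float(vals[-1]), vecs[:, -1]


def _ordering(scores: np.ndarray, node_weights: np.ndarray) -> np.ndarray:
    s = np.round(scores, _TIE_DECIMALS)
    w = np.round(node_weights, _TIE_DECIMALS)
    n = scores.shape[0]
    # lexsort: last key is primary
    return np.lexsort((np.arange(n), -w, -s))


def rank_features(network: SynergyNetwork) -> SpectralRanking:
    """Rank features by |leading eigenvector| of the synergy matrix."""
    mat = to_matrix(network)
    n = network.n_features
    diagonal = network.lam == 0.0 or not network.edge_weights.any()
    if diagonal:
        nw = network.node_weights.astype(float)
        norm = np.linalg.norm(nw)
        scores = nw / norm if norm > 0 else np.full(n, 1.0 / np.sqrt(n))
        return SpectralRanking(
            scores=scores,
            eigenvalue=float(nw.max()) if n else 0.0,
            order=_ordering(nw, nw),
            diagonal_fallback_used=True,
            unstable=False,
            feature_names=list(network.feature_names),
        )
    vals, vecs = np.linalg.eigh(mat.M)
    alpha = float(vals[-1])
    scores = np.abs(vecs[:, -1])
    fro = np.linalg.norm(mat.M)
    unstable = n > 1 and (vals[-1] - vals[-2]) < 1e-10 * fro
    return SpectralRanking(
        scores=scores,
        eigenvalue=alpha,
        order=_ordering(scores, network.node_weights),
        diagonal_fallback_used=False,
        unstable=bool(unstable),
        feature_names=list(network.feature_names),
    )


def spectral_topk(
    ranking: SpectralRanking, K: int, network: SynergyNetwork
) -> SubnetworkSolution:
    """Take the top-K ranked features as the approximate subnetwork."""
    n = network.n_features
    if not 1 <= K <= n:
        raise InputError(f"K must be in [1, {n}]")
    subset = tuple(sorted(int(i) for i in ranking.order[:K]))
    return SubnetworkSolution(
        subset=subset, objective=subnetwork_objective(subset, network), K=K
    )
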