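"""Synergy-network construction from logistic coefficient p-values.

Each feature gets a node weight equal to the negative log p-value of its
slope in a single-feature logistic model of the outcome; each unordered
feature pair gets an edge weight equal to the negative log p-value of the
product-term coefficient in a two-feature logistic model with interaction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._logistic import COLLINEAR, FAILED, OK, P_FLOOR, coef_pvalues_batch
from .data import CaseControlDataset
from .errors import DegenerateFeatureError, InputError

__all__ = [
    "SynergyNetwork",
    "SynergyMatrix",
    "individual_power",
    "pairwise_synergy",
    "build_network",
    "node_weight_vector",
    "to_matrix",
    "average_networks",
]


@dataclass
class SynergyNetwork:
    """Weighted graph of individual and pairwise synergistic power.

    ``node_weights[i]`` is the individual power of feature i and
    ``edge_weights[i, j]`` the synergistic power of the pair (i, j), both in
    negative-natural-log p-value units; ``lam`` is the individual-vs-synergy
    weighting coefficient used when the network is collapsed to a matrix.
    """

    node_weights: np.ndarray
    edge_weights: np.ndarray
    lam: float
    feature_names: list[str]
    node_pvalues: np.ndarray | None = None
    edge_pvalues: np.ndarray | None = None
    fit_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_weights = np.asarray(self.node_weights, dtype=float)
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        n = self.node_weights.shape[0]
        if self.edge_weights.shape != (n, n):
            raise InputError("edge_weights must be n x n")
        if not (np.isfinite(self.node_weights).all() and np.isfinite(self.edge_weights).all()):
            raise InputError("weights must be finite")
        if (self.node_weights < 0).any() or (self.edge_weights < 0).any():
            raise InputError("weights must be nonnegative")
        if not np.array_equal(self.edge_weights, self.edge_weights.T):
            raise InputError("edge_weights must be exactly symmetric")
        if np.diagonal(self.edge_weights).any():
            raise InputError("edge_weights diagonal must be zero")
        if not 0.0 <= self.lam <= 1.0:
            raise InputError("lambda must be in [0, 1]")
        if len(self.feature_names) != n:
            raise InputError("feature_names length mismatch")

    @property
    def n_features(self) -> int:
        return self.node_weights.shape[0]

    @property
    def n_pairs(self) -> int:
        n = self.n_features
        return n * (n - 1) // 2


@dataclass
class SynergyMatrix:
    """Symmetric matrix form: diagonal = node weights, off-diagonal = lam * edge weights."""

    M: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise InputError("M must be square")


def _design_single(v: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(v), v])


def _design_pair(vi: np.ndarray, vj: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(vi), vi, vj, vi * vj])


def _maybe_center(features: np.ndarray, center: bool) -> np.ndarray:
    return features - features.mean(axis=0) if center else features


def individual_power(
    dataset: CaseControlDataset,
    i: int,
    *,
    test: str = "wald",
    p_floor: float = P_FLOOR,
    center: bool = False,
) -> tuple[float, float]:
    """Individual predictive power of feature ``i``.

    Fits ``logit P(y=1|v_i) = a0 + a1 v_i`` and returns
    ``(-log(p), p)`` for the two-sided test of ``a1 = 0``.
    """
    if not 0 <= i < dataset.n_features:
        raise InputError(f"feature index {i} out of range")
    v = _maybe_center(dataset.features, center)[:, i]
    if np.ptp(v) == 0:
        raise DegenerateFeatureError(
            f"feature {dataset.feature_names[i]!r} is constant"
        )
    p, status = coef_pvalues_batch(
        _design_single(v)[None], dataset.outcome, coef_index=1, test=test, p_floor=p_floor
    )
    if status[0] in (FAILED, COLLINEAR):
        warnings.warn(
            f"individual fit failed for feature {dataset.feature_names[i]!r}; weight set to 0"
        )
        return 0.0, 1.0
    return float(-math.log(p[0])), float(p[0])


def pairwise_synergy(
    dataset: CaseControlDataset,
    i: int,
    j: int,
    *,
    test: str = "wald",
    p_floor: float = P_FLOOR,
    center: bool = False,
) -> tuple[float, float]:
    """Synergistic power of the unordered pair ``(i, j)``.

    Fits ``logit P(y=1|v_i,v_j) = a0 + a1 v_i + a2 v_j + b v_i v_j`` and
    returns ``(-log(p), p)`` for the product-term coefficient ``b`` only.
    Symmetric in (i, j) bit-for-bit.
    """
    if i == j:
        raise InputError("pairwise synergy requires two distinct features")
    for k in (i, j):
        if not 0 <= k < dataset.n_features:
            raise InputError(f"feature index {k} out of range")
    a, b = (i, j) if i < j else (j, i)
    feats = _maybe_center(dataset.features, center)
    va, vb = feats[:, a], feats[:, b]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise DegenerateFeatureError("pairwise synergy with a constant feature")
    p, status = coef_pvalues_batch(
        _design_pair(va, vb)[None], dataset.outcome, coef_index=3, test=test, p_floor=p_floor
    )
    if status[0] in (FAILED, COLLINEAR):
        warnings.warn(
            f"interaction fit degenerate for pair "
            f"({dataset.feature_names[a]!r}, {dataset.feature_names[b]!r}); weight set to 0"
        )
        return 0.0, 1.0
    return float(-math.log(p[0])), float(p[0])


def node_weight_vector(
    dataset: CaseControlDataset,
    *,
    test: str = "wald",
    p_floor: float = P_FLOOR,
    center: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Individual powers of all features at once: (weights, p-values, warnings)."""
    feats = _maybe_center(dataset.features, center)
    n, d = feats.shape
    X = np.empty((d, n, 2))
    X[:, :, 0] = 1.0
    X[:, :, 1] = feats.T
    p, status = coef_pvalues_batch(X, dataset.outcome, coef_index=1, test=test, p_floor=p_floor)
    w = -np.log(p)
    bad = np.isin(status, (FAILED, COLLINEAR))
    w[bad] = 0.0
    p[bad] = 1.0
    msgs = [
        f"individual fit degenerate for feature {dataset.feature_names[k]!r}; weight 0"
        for k in np.flatnonzero(bad)
    ]
    return w, p, msgs


def build_network(
    dataset: CaseControlDataset,
    lam: float = 1.0,
    *,
    test: str = "wald",
    p_floor: float = P_FLOOR,
    center: bool = False,
) -> SynergyNetwork:
    """Fit all n single-feature and n(n-1)/2 pairwise interaction models.

    Per-fit failures (constant features, collinear product terms,
    unrecoverable non-convergence) degrade to zero weight with a recorded
    warning; only an invalid dataset or lambda raises.
    """
    if not 0.0 <= lam <= 1.0:
        raise InputError("lambda must be in [0, 1]")
    feats = _maybe_center(dataset.features, center)
    n, d = feats.shape
    y = dataset.outcome

    node_w, node_p, msgs = node_weight_vector(
        dataset, test=test, p_floor=p_floor, center=center
    )

    pairs = list(combinations(range(d), 2))
    Xp = np.empty((len(pairs), n, 4))
    Xp[:, :, 0] = 1.0
    ii = np.fromiter((a for a, _ in pairs), dtype=int)
    jj = np.fromiter((b for _, b in pairs), dtype=int)
    Xp[:, :, 1] = feats.T[ii]
    Xp[:, :, 2] = feats.T[jj]
    Xp[:, :, 3] = Xp[:, :, 1] * Xp[:, :, 2]
    p, status = coef_pvalues_batch(Xp, y, coef_index=3, test=test, p_floor=p_floor)
    w = -np.log(p)
    bad = np.isin(status, (FAILED, COLLINEAR))
    w[bad] = 0.0
    p[bad] = 1.0
    for k in np.flatnonzero(bad):
        a, b = pairs[k]
        msgs.append(
            f"interaction fit degenerate for pair "
            f"({dataset.feature_names[a]!r}, {dataset.feature_names[b]!r}); weight 0"
        )

    edge_w = np.zeros((d, d))
    edge_p = np.ones((d, d))
    edge_w[ii, jj] = w
    edge_w[jj, ii] = w
    edge_p[ii, jj] = p
    edge_p[jj, ii] = p
    return SynergyNetwork(
        node_weights=node_w,
        edge_weights=edge_w,
        lam=float(lam),
        feature_names=list(dataset.feature_names),
        node_pvalues=node_p,
        edge_pvalues=edge_p,
        fit_warnings=msgs,
    )


def to_matrix(network: SynergyNetwork) -> SynergyMatrix:
    """Collapse a network to its matrix form M (diag f, off-diag lam * s)."""
    M = network.lam * network.edge_weights.copy()
    np.fill_diagonal(M, network.node_weights)
    return SynergyMatrix(M=M, feature_names=list(network.feature_names))


def average_networks(networks: list[SynergyNetwork]) -> SynergyNetwork:
    """Element-wise arithmetic mean of node and edge weights."""
    if not networks:
        raise InputError("average_networks requires a non-empty list")
    ref = networks[0]
    for net in networks[1:]:
        if net.feature_names != ref.feature_names:
            raise InputError("cannot average networks with different feature sets")
        if net.lam != ref.lam:
            raise InputError("cannot average networks with different lambda")
    node = np.mean([net.node_weights for net in networks], axis=0)
    edge = np.mean([net.edge_weights for net in networks], axis=0)
    edge = (edge + edge.T) / 2.0  # keep exact symmetry under fp averaging
    return SynergyNetwork(
        node_weights=node,
        edge_weights=edge,
        lam=ref.lam,
        feature_names=list(ref.feature_names),
    )
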