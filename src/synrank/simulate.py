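"""Case-control simulator: mixture-of-Gaussian features and a sparse
pairwise-interaction logistic outcome model, with retained ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
from scipy.special import expit

from .data import CaseControlDataset
from .errors import InputError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "draw_ground_truth",
    "simulate_dataset",
    "generate_ensemble",
]


@dataclass
class SimulationConfig:
    """Parameters of the simulated disease model.

    Features are i.i.d. draws from an equal-weight two-component Gaussian
    mixture (means ``mixture_means``, common variance ``mixture_variance``).
    The outcome is Bernoulli with logit
    ``alpha0 + sum_i alpha_i v_i + sum_{i<j} beta_ij v_i v_j`` where
    ``n_synergy_pairs`` interaction coefficients and ``individual_effects``
    individual coefficients are drawn from N(0, 1) and all others are zero.
    """

    n_features: int = 30
    n_samples: int = 200
    n_synergy_pairs: int = 10
    individual_effects: int = 0
    alpha0: float = 0.0
    mixture_means: tuple[float, float] = (-1.0, 1.0)
    mixture_variance: float = 1.0

    def __post_init__(self) -> None:
        if self.n_features < 2:
            raise InputError("n_features must be >= 2")
        if self.n_samples < 1:
            raise InputError("n_samples must be positive")
        max_pairs = self.n_features * (self.n_features - 1) // 2
        if not 0 <= self.n_synergy_pairs <= max_pairs:
            raise InputError(
                f"n_synergy_pairs must be in [0, {max_pairs}]"
            )
        if not 0 <= self.individual_effects <= self.n_features:
            raise InputError("individual_effects must be in [0, n_features]")
        if self.mixture_variance <= 0:
            raise InputError("mixture_variance must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mixture_means"] = list(self.mixture_means)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "mixture_means" in d:
            d["mixture_means"] = tuple(d["mixture_means"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True coefficients of the generating logistic model."""

    alpha: np.ndarray                      # (n_features,)
    beta: dict[tuple[int, int], float]     # sparse, keys (i, j) with i < j
    alpha0: float = 0.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        for (i, j) in self.beta:
            if not i < j:
                raise InputError("beta keys must be ordered pairs (i, j) with i < j")

    @property
    def support_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.beta)

    @property
    def support_features(self) -> tuple[int, ...]:
        feats = set(np.flatnonzero(self.alpha != 0).tolist())
        for i, j in self.beta:
            feats.update((i, j))
        return tuple(sorted(feats))

    def beta_matrix(self, n: int) -> np.ndarray:
        B = np.zeros((n, n))
        for (i, j), v in self.beta.items():
            B[i, j] = v
            B[j, i] = v
        return B

    def to_dict(self) -> dict:
        return {
            "alpha0": self.alpha0,
            "alpha": self.alpha.tolist(),
            "beta": [[i, j, v] for (i, j), v in sorted(self.beta.items())],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            alpha=np.asarray(d["alpha"], dtype=float),
            beta={(int(i), int(j)): float(v) for i, j, v in d["beta"]},
            alpha0=float(d["alpha0"]),
        )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, (np.random.Generator,)):
        return seed
    return np.random.default_rng(seed)


def draw_ground_truth(config: SimulationConfig, seed=0) -> GroundTruth:
    """Draw sparse N(0,1) coefficients on uniformly chosen supports."""
    rng = _rng(seed)
    pairs = list(combinations(range(config.n_features), 2))
    chosen = rng.choice(len(pairs), size=config.n_synergy_pairs, replace=False)
    beta = {pairs[k]: float(rng.standard_normal()) for k in sorted(chosen)}
    alpha = np.zeros(config.n_features)
    if config.individual_effects:
        support = rng.choice(
            config.n_features, size=config.individual_effects, replace=False
        )
        alpha[np.sort(support)] = rng.standard_normal(config.individual_effects)
    return GroundTruth(alpha=alpha, beta=beta, alpha0=config.alpha0)


def simulate_dataset(
    config: SimulationConfig, truth: GroundTruth, seed=0
) -> CaseControlDataset:
    """Sample features from the Gaussian mixture and the Bernoulli outcome."""
    if truth.alpha.shape[0] != config.n_features:
        raise InputError("ground truth dimension does not match config")
    rng = _rng(seed)
    n, d = config.n_samples, config.n_features
    comp = rng.integers(0, 2, size=(n, d))
    means = np.asarray(config.mixture_means)[comp]
    v = rng.normal(means, np.sqrt(config.mixture_variance))
    B = truth.beta_matrix(d)
    logit = truth.alpha0 + v @ truth.alpha + 0.5 * np.einsum("ni,ij,nj->n", v, B, v)
    prob = expit(logit)
    y = rng.binomial(1, prob)
    if y.min() == y.max():  # astronomically unlikely at the default scale
        y[rng.integers(0, n)] = 1 - y[0]
    return CaseControlDataset(v, y, [f"v{i + 1}" for i in range(d)])


def generate_ensemble(
    config: SimulationConfig, n_datasets: int = 20, seed: int = 0
) -> list[tuple[CaseControlDataset, GroundTruth]]:
    """Independent (dataset, ground truth) pairs with per-element derived seeds."""
    if n_datasets < 1:
        raise InputError("n_datasets must be positive")
    out = []
    for k in range(n_datasets):
        truth = draw_ground_truth(
            config, np.random.SeedSequence([3, int(seed), k, 0])
        )
        ds = simulate_dataset(
            config, truth, np.random.SeedSequence([3, int(seed), k, 1])
        )
        out.append((ds, truth))
    return out
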