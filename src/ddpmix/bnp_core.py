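"""Shared Bayesian-nonparametric machinery.

Stick-breaking (GEM) weights, Chinese-restaurant-process quantities,
Algorithm-8 assignment probabilities, the squared-exponential covariance
used to couple group shifts across ages, and concentration-parameter
resampling (Escobar--West for a single DP, Teh's auxiliary-variable scheme
for the lower level of an HDP, Antoniak table-count simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

__all__ = [
    "StickWeights",
    "KernelSpec",
    "ConcentrationPrior",
    "sample_gem",
    "expected_cluster_count",
    "assignment_probabilities",
    "build_kernel",
    "resample_concentration",
    "resample_hdp_alpha",
    "sample_table_count",
]


@dataclass(frozen=True)
class KernelSpec:
    """Squared-exponential kernel hyperparameters.

    Parameters
    ----------
    variance : float
        Marginal variance of the Gaussian-process shifts (squared time
        units; the reference configuration uses 0.05 h^2, i.e. a prior
        standard deviation of roughly 13 minutes).
    lengthscale : float
        Correlation length ``nu`` across the covariate (years of age).
        Larger values force neighbouring age groups to share their shift.
    jitter : float
        Diagonal jitter ``kappa`` guarding the Cholesky factorisation; it
        can be read as the measurement error of the recorded times.
    """

    variance: float
    lengthscale: float
    jitter: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.variance > 0):
            raise ValueError(f"kernel variance must be > 0, got {self.variance}")
        if not (self.lengthscale > 0):
            raise ValueError(f"kernel lengthscale must be > 0, got {self.lengthscale}")
        if self.jitter < 0:
            raise ValueError(f"kernel jitter must be >= 0, got {self.jitter}")

    def scaled(self, factor: float) -> "KernelSpec":
        """Return a copy with variance-like fields multiplied by ``factor``."""
        return KernelSpec(self.variance * factor, self.lengthscale, self.jitter * factor)


@dataclass(frozen=True)
class ConcentrationPrior:
    """Gamma prior on a DP concentration parameter.

    ``shape``/``scale`` parameterisation; the reference configuration is
    Gamma(shape=1, scale=10), a weak prior favouring moderate cluster
    counts.
    """

    shape: float = 1.0
    scale: float = 10.0

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("ConcentrationPrior shape and scale must be > 0")

    @property
    def rate(self) -> float:
        return 1.0 / self.scale


@dataclass
class StickWeights:
    """Truncated stick-breaking weights of a Dirichlet process draw."""

    weights: np.ndarray
    concentration: float
    remainder: float = field(default=0.0)

    @property
    def truncation_level(self) -> int:
        return len(self.weights)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("stick weights must be non-negative")
        if self.weights.sum() > 1 + 1e-12:
            raise ValueError("stick weights must sum to at most 1")


def sample_gem(concentration: float, truncation: int, rng: np.random.Generator) -> StickWeights:
    """Draw truncated GEM(concentration) stick-breaking weights.

    ``w_k = b_k * prod_{l<k} (1 - b_l)`` with ``b_k ~ Beta(1, concentration)``.
    The untruncated construction telescopes to total mass one; the mass not
    covered by the first ``truncation`` sticks is returned as ``remainder``.
    """
    if not concentration > 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    if not (isinstance(truncation, (int, np.integer)) and truncation >= 1):
        raise ValueError(f"truncation must be a positive integer, got {truncation}")
    b = rng.beta(1.0, concentration, size=truncation)
    b = np.minimum(b, 1.0 - 1e-16)  # guard log1p at the boundary
    log_stick = np.concatenate(([0.0], np.cumsum(np.log1p(-b))[:-1]))
    w = b * np.exp(log_stick)
    remainder = float(np.exp(log_stick[-1]) * (1.0 - b[-1]))
    return StickWeights(weights=w, concentration=float(concentration), remainder=remainder)


def expected_cluster_count(concentration: float, n: int) -> float:
    """Exact expected number of occupied CRP tables after ``n`` customers.

    ``sum_{i=1}^{n} alpha / (alpha + i - 1)``, which grows like
    ``alpha * log(n)``.
    """
    if not concentration > 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    if not n >= 1:
        raise ValueError(f"n must be >= 1, got {n}")
    a = float(concentration)
    # digamma identity avoids the O(n) sum for large n
    return float(a * (digamma(a + n) - digamma(a)))


def assignment_probabilities(
    counts_per_cluster: np.ndarray,
    concentration: float,
    n_aux: int,
    loglik_per_candidate: np.ndarray,
) -> np.ndarray:
    """Algorithm-8 reassignment probabilities for one item.

    Occupied cluster ``k`` gets prior mass ``count_k``; each of the
    ``n_aux`` auxiliary (fresh) clusters gets ``concentration / n_aux``.
    The returned vector is the likelihood-weighted normalisation of those
    masses and sums to one.
    """
    counts = np.asarray(counts_per_cluster, dtype=float)
    ll = np.asarray(loglik_per_candidate, dtype=float)
    if not concentration > 0:
        raise ValueError("concentration must be > 0")
    if not n_aux >= 1:
        raise ValueError("n_aux must be >= 1")
    if np.any(counts < 0):
        raise ValueError("cluster counts must be non-negative")
    if len(ll) != len(counts) + n_aux:
        raise ValueError(
            f"loglik length {len(ll)} != occupied ({len(counts)}) + auxiliary ({n_aux})"
        )
    prior = np.concatenate([counts, np.full(n_aux, concentration / n_aux)])
    logw = np.log(prior, out=np.full_like(prior, -np.inf), where=prior > 0) + ll
    m = logw.max()
    if not np.isfinite(m):
        raise FloatingPointError("degenerate assignment distribution: all candidates have zero mass")
    p = np.exp(logw - m)
    return p / p.sum()


def build_kernel(positions: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Squared-exponential covariance over covariate positions.

    ``K[l, j] = variance * exp(-(pos_l - pos_j)^2 / (2 lengthscale^2))``
    plus ``jitter`` on the diagonal.  Symmetric positive definite for any
    valid spec.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 1:
        raise ValueError("positions must be a 1-d array")
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")
    d = pos[:, None] - pos[None, :]
    K = spec.variance * np.exp(-(d**2) / (2.0 * spec.lengthscale**2))
    K[np.diag_indices_from(K)] += spec.jitter
    return K


def resample_concentration(
    current: float,
    n_clusters: int,
    n_items: int,
    prior: ConcentrationPrior,
    rng: np.random.Generator,
) -> float:
    """One Escobar--West auxiliary-variable update of a DP concentration.

    Draws ``eta ~ Beta(alpha + 1, n)`` then alpha from the implied
    two-component Gamma mixture; leaves the conditional
    ``p(alpha | K clusters among n items)`` invariant under the Gamma
    prior.
    """
    if not current > 0:
        raise ValueError("current concentration must be > 0")
    if n_clusters < 1 or n_items < 1:
        raise ValueError("n_clusters and n_items must be >= 1")
    if n_clusters > n_items:
        raise ValueError(f"n_clusters ({n_clusters}) cannot exceed n_items ({n_items})")
    if n_items == 1:
        # a single item always occupies one table; the likelihood is flat
        return float(rng.gamma(prior.shape, prior.scale))
    eta = rng.beta(current + 1.0, n_items)
    rate = prior.rate - np.log(eta)
    odds = (prior.shape + n_clusters - 1.0) / (n_items * rate)
    shape = prior.shape + n_clusters
    if rng.random() >= odds / (1.0 + odds):
        shape -= 1.0
    return float(rng.gamma(shape, 1.0 / rate))


def resample_hdp_alpha(
    current: float,
    group_sizes: np.ndarray,
    total_tables: int,
    prior: ConcentrationPrior,
    rng: np.random.Generator,
    n_steps: int = 3,
) -> float:
    """Auxiliary-variable update of the lower-level HDP concentration.

    Teh et al.'s scheme: for each restaurant ``r`` with ``n_r`` customers
    draw ``w_r ~ Beta(alpha + 1, n_r)`` and ``s_r ~ Bernoulli(n_r /
    (n_r + alpha))``; then ``alpha ~ Gamma(shape + m.. - sum s_r,
    rate - sum log w_r)`` where ``m..`` is the total table count.
    """
    sizes = np.asarray(group_sizes, dtype=float)
    sizes = sizes[sizes > 0]
    if sizes.size == 0 or total_tables < 1:
        return float(rng.gamma(prior.shape, prior.scale))
    alpha = float(current)
    for _ in range(n_steps):
        w = rng.beta(alpha + 1.0, sizes)
        s = rng.random(sizes.size) < sizes / (sizes + alpha)
        shape = prior.shape + total_tables - s.sum()
        rate = prior.rate - np.sum(np.log(w))
        alpha = float(rng.gamma(shape, 1.0 / rate))
    return alpha


def sample_table_count(n: int, mass: float, rng: np.random.Generator) -> int:
    """Sample the number of CRP tables among ``n`` customers at total prior
    mass ``mass`` (the Antoniak distribution), by the Bernoulli recursion:
    customer ``i`` opens a table with probability ``mass / (mass + i - 1)``.
    """
    if n <= 0:
        return 0
    if mass <= 0:
        return 1 if n > 0 else 0
    i = np.arange(n, dtype=float)
    return int(np.count_nonzero(rng.random(n) < mass / (mass + i)))
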