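"""Atom-dependent Dirichlet process (ADDP) mixture models for grouped
finishing times.

The family shares a single likelihood skeleton: finishing time ``x_ji`` of a
runner in age/gender group ``j`` is Gaussian around a cluster mean ``mu_k``
plus a group shift, with one shared noise variance ``sigma_x^2`` so that
clusters are ordered and comparable.  The variants differ in how the shift
enters:

========================  =============================  ====================
variant                   atom weights                   atom location
========================  =============================  ====================
``basic``                 ``pi_k`` (shared)              ``mu_k + theta_j``
``hierarchical``          ``pi_rk`` (per race, HDP)      ``mu_k + theta_j``
``interaction``           ``pi_k``                       ``mu_k + theta_j + g (delta + omega_j)``
``cluster_shifts``        ``pi_k``                       ``mu_k + theta_jk``
========================  =============================  ====================

The shifts ``theta`` follow a zero-mean Gaussian process over age with a
squared-exponential kernel (independent per gender except in the
``interaction`` variant, where a shared ``theta`` plus a gender effect
``delta`` and age-gender interactions ``omega_j`` capture the male/female
gap).  Inference is Gibbs sampling with Neal's Algorithm 8 (auxiliary
clusters) for the non-conjugate assignment step; the hierarchical variant
uses the HDP direct-assignment (Chinese restaurant franchise) form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .archive import PosteriorArchive
from .bnp_core import (
    ConcentrationPrior,
    KernelSpec,
    build_kernel,
    resample_concentration,
    resample_hdp_alpha,
    sample_table_count,
)

__all__ = [
    "ADDPConfig",
    "ADDPMixture",
    "fit_addp",
    "paper_hyperparameters",
    "VARIANTS",
]

VARIANTS = ("basic", "hierarchical", "interaction", "cluster_shifts")

_LOG2PI = math.log(2.0 * math.pi)
_logger = logging.getLogger("ddpmix")


def paper_hyperparameters(unit: str = "minutes") -> dict:
    """Reference prior settings of the marathon study, in hours or minutes.

    The published configuration is expressed on an hours scale (``mu0 = 5``
    hours, ``sigma0_sq = 1`` hour^2, shift-kernel variance 0.05 hour^2,
    inverse-gamma ``a = b = 1``).  Since this package works in minutes
    internally, means scale by 60 and variances (including the
    inverse-gamma scale ``b`` and the kernel jitter) by 3600.
    """
    h = dict(
        mu0=5.0,
        sigma0_sq=1.0,
        a=1.0,
        b=1.0,
        kernel_variance=0.05,
        kernel_lengthscale=10.0,
        kernel_jitter=1e-6,
        gender_variance=0.05,
    )
    if unit == "hours":
        return h
    if unit != "minutes":
        raise ValueError(f"unit must be 'hours' or 'minutes', got {unit!r}")
    m = dict(h)
    m["mu0"] *= 60.0
    for key in ("sigma0_sq", "b", "kernel_variance", "kernel_jitter", "gender_variance"):
        m[key] *= 3600.0
    return m


@dataclass
class ADDPConfig:
    """Full hyperparameter set for any ADDP variant (minutes scale)."""

    variant: str = "basic"
    mu0: float = 300.0
    sigma0_sq: float = 3600.0
    a: float = 1.0
    b: float = 3600.0
    kernel: KernelSpec = field(default_factory=lambda: KernelSpec(180.0, 10.0, 3.6e-3))
    gender_variance: float = 180.0
    omega_scale: float = 0.5
    theta_mean: float = 0.0
    alpha_prior: ConcentrationPrior = field(default_factory=ConcentrationPrior)
    gamma_prior: ConcentrationPrior = field(default_factory=ConcentrationPrior)
    n_aux: int = 10
    n_iter: int = 2000
    n_average: Optional[int] = None
    thin: int = 5
    seed: int = 0
    sample_alpha: bool = True
    sample_shifts: bool = True
    sample_variance: bool = True
    fixed_sigma_x2: Optional[float] = None
    store_assignments: bool = True
    init_clusters: int = 12

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.sigma0_sq <= 0 or self.a <= 0 or self.b <= 0:
            raise ValueError("sigma0_sq, a, b must all be > 0")
        if self.sample_shifts and self.sigma0_sq <= self.kernel.variance:
            raise ValueError(
                "sigma0_sq must exceed the shift-kernel variance: the cluster-mean "
                "prior carries the overall time scale, the shifts only the "
                "between-group differences"
            )
        if self.n_aux < 1 or self.n_iter < 1 or self.thin < 1:
            raise ValueError("n_aux, n_iter and thin must be positive")
        if self.n_average is None:
            self.n_average = max(1, self.n_iter // 5)
        if self.n_average > self.n_iter:
            raise ValueError("n_average cannot exceed n_iter")


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


class _ADDPData:
    """Validated design arrays shared by all variants."""

    def __init__(self, df: pd.DataFrame, variant: str):
        if len(df) == 0:
            raise ValueError("empty dataset")
        if "finish_time" not in df.columns:
            raise ValueError("data must contain a 'finish_time' column (minutes)")
        self.x = np.ascontiguousarray(df["finish_time"].to_numpy(dtype=float))
        if np.any(~np.isfinite(self.x)) or np.any(self.x <= 0):
            raise ValueError("finish times must be finite and positive")
        self.n = len(self.x)

        age = df["age"].to_numpy() if "age" in df.columns else np.zeros(self.n, dtype=int)
        self.ages = np.unique(age)
        age_idx = np.searchsorted(self.ages, age)

        gender_raw = df["gender"].to_numpy() if "gender" in df.columns else np.zeros(self.n)
        self.gender = _encode_gender(gender_raw)

        if variant == "hierarchical" and "race" in df.columns:
            race_codes, self.races = pd.factorize(df["race"], sort=True)
            self.race_idx = np.ascontiguousarray(race_codes)
        else:
            self.races = np.array(["all"])
            self.race_idx = np.zeros(self.n, dtype=np.intp)
        self.n_races = len(self.races)

        A = len(self.ages)
        self.age_idx = np.ascontiguousarray(age_idx)
        if variant == "interaction":
            # groups are age only; gender enters through delta + omega
            self.group_idx = self.age_idx.copy()
            self.J = A
            self.group_positions = self.ages.astype(float)
            self.group_labels = [("*", int(a)) for a in self.ages]
            self.gender_blocks = [np.arange(A)]
        else:
            genders = np.unique(self.gender)
            self.J = A * len(genders)
            self.group_idx = np.ascontiguousarray(
                np.searchsorted(genders, self.gender) * A + age_idx
            )
            self.group_positions = np.tile(self.ages.astype(float), len(genders))
            self.group_labels = [
                ("male" if g == 0 else "female", int(a)) for g in genders for a in self.ages
            ]
            self.gender_blocks = [np.arange(i * A, (i + 1) * A) for i in range(len(genders))]
        self.group_sizes = np.bincount(self.group_idx, minlength=self.J)


def _encode_gender(raw: np.ndarray) -> np.ndarray:
    out = np.zeros(len(raw), dtype=np.intp)
    for i, v in enumerate(raw):
        if v in (0, 1):
            out[i] = int(v)
        elif isinstance(v, str) and v.upper() in ("M", "MALE"):
            out[i] = 0
        elif isinstance(v, str) and v.upper() in ("F", "FEMALE", "W"):
            out[i] = 1
        else:
            raise ValueError(f"unrecognised gender value {v!r}")
    return out


# ---------------------------------------------------------------------------
# closed-form conditionals (exposed for verification)
# ---------------------------------------------------------------------------


def normal_mean_conditional(
    n_k: int, resid_sum: float, sigma_x2: float, mu0: float, sigma0_sq: float
) -> tuple[float, float]:
    """Posterior (mean, variance) of a cluster mean under the normal-normal
    conjugacy: precision ``1/sigma0^2 + n_k/sigma_x^2``."""
    prec = 1.0 / sigma0_sq + n_k / sigma_x2
    var = 1.0 / prec
    mean = var * (mu0 / sigma0_sq + resid_sum / sigma_x2)
    return mean, var


def gp_shift_conditional(
    K: np.ndarray,
    counts: np.ndarray,
    resid_sums: np.ndarray,
    sigma_x2: float,
    prior_mean: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (mean, covariance) of a Gaussian-process shift vector.

    Precision is ``K^{-1} + diag(counts / sigma_x^2)``; the mean solves the
    usual normal linear-model conditional given per-group residual sums.
    Groups with zero counts are shrunk to the prior conditional.
    """
    Kc = cho_factor(K, lower=True)
    Kinv = cho_solve(Kc, np.eye(K.shape[0]))
    prec = Kinv + np.diag(counts / sigma_x2)
    pc = cho_factor(prec, lower=True)
    cov = cho_solve(pc, np.eye(K.shape[0]))
    rhs = resid_sums / sigma_x2
    if prior_mean is not None:
        rhs = rhs + Kinv @ prior_mean
    mean = cho_solve(pc, rhs)
    return mean, cov


def variance_conditional(n: int, sse: float, a: float, b: float) -> tuple[float, float]:
    """Inverse-gamma posterior (shape, scale) of the shared noise variance."""
    return a + 0.5 * n, b + 0.5 * sse


def _sample_mvn(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # jitter should prevent this
        raise np.linalg.LinAlgError(
            "singular shift-update covariance; increase the kernel jitter"
        ) from exc
    return mean + L @ rng.standard_normal(len(mean))


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------


class _ADDPSampler:
    """One Gibbs chain for any ADDP variant.

    Auxiliary-cluster bookkeeping: ``occ`` holds occupied columns of the
    capacity arrays, ``aux`` exactly ``n_aux`` candidate columns whose
    parameters are prior draws (refreshed at each sweep and whenever one is
    promoted); a cluster emptied mid-sweep re-enters the pool with its
    parameter, evicting a fresh draw, which is Neal's singleton rule.
    """

    def __init__(self, data: _ADDPData, cfg: ADDPConfig, rng: np.random.Generator):
        self.data = data
        self.cfg = cfg
        self.rng = rng
        n, J = data.n, data.J

        self.Kmat = self._build_group_kernel()
        Kc = cho_factor(self.Kmat, lower=True)
        self.Kinv = cho_solve(Kc, np.eye(J))
        self.K_chol = np.linalg.cholesky(self.Kmat)
        self.theta_prior_mean = np.full(J, cfg.theta_mean)

        if cfg.variant == "interaction":
            self.Omega = cfg.omega_scale * build_kernel(data.ages.astype(float), cfg.kernel)

        cap = 8 + cfg.n_aux
        self._cap = cap
        self.mu = np.zeros(cap)
        self.counts = np.zeros(cap, dtype=np.int64)
        self.LL = np.zeros((n, cap))
        if cfg.variant == "cluster_shifts":
            self.theta_k = np.zeros((J, cap))
        if cfg.variant == "hierarchical":
            self.counts_rk = np.zeros((data.n_races, cap), dtype=np.int64)
            self.v = np.zeros(cap)
            self.v_rem = 1.0

        # initial state: records binned into quantile clusters of the raw
        # times.  Single-site Gibbs merges redundant clusters quickly but
        # splits very slowly, so an over-clustered start mixes far better
        # than the single-cluster one.  The gender effect starts at its
        # method-of-moments estimate (the empirical female-male gap) so the
        # interaction variant bins genders onto shared clusters instead of
        # locking women into parallel clusters of their own.
        x_init = data.x
        if cfg.variant == "interaction":
            fem = data.gender == 1
            if fem.any() and (~fem).any():
                self.delta0 = float(data.x[fem].mean() - data.x[~fem].mean())
                x_init = data.x - data.gender * self.delta0
            else:
                self.delta0 = 0.0
        n_init = int(min(cfg.init_clusters, n))
        edges = np.quantile(x_init, np.linspace(0, 1, n_init + 1)[1:-1])
        self.c = np.searchsorted(edges, x_init).astype(np.intp)
        used = np.unique(self.c)
        remap = np.zeros(used.max() + 1, dtype=np.intp)
        remap[used] = np.arange(len(used))
        self.c = remap[self.c]
        k0 = len(used)
        while cap < k0 + cfg.n_aux + 4:
            cap *= 2
        if cap != self._cap:
            self._cap = cap
            self.mu = np.zeros(cap)
            self.counts = np.zeros(cap, dtype=np.int64)
            self.LL = np.zeros((n, cap))
            if cfg.variant == "cluster_shifts":
                self.theta_k = np.zeros((J, cap))
            if cfg.variant == "hierarchical":
                self.counts_rk = np.zeros((data.n_races, cap), dtype=np.int64)
                self.v = np.zeros(cap)
        self.occ: list[int] = list(range(k0))
        self.aux: list[int] = list(range(k0, k0 + cfg.n_aux))
        self.free: list[int] = list(range(k0 + cfg.n_aux, cap))
        for k in range(k0):
            self.mu[k] = float(np.mean(x_init[self.c == k]))
        np.add.at(self.counts, self.c, 1)
        if cfg.variant == "hierarchical":
            np.add.at(self.counts_rk, (data.race_idx, self.c), 1)
            self.v[:k0] = 0.5 / k0
            self.v_rem = 0.5
        self.theta = np.zeros(J)
        self.delta = getattr(self, "delta0", 0.0)
        self.omega = np.zeros(len(data.ages))
        self.sigma_x2 = (
            cfg.fixed_sigma_x2
            if cfg.fixed_sigma_x2 is not None
            else max(float(np.var(x_init - self.mu[self.c])), 1e-6)
        )
        self.alpha = 1.0
        self.gamma = 1.0
        self.pi_r = None  # hierarchical per-race weights, set by _update_weights

    # -- kernel -------------------------------------------------------------

    def _build_group_kernel(self) -> np.ndarray:
        d = self.data
        K = np.zeros((d.J, d.J))
        for block in d.gender_blocks:
            K[np.ix_(block, block)] = build_kernel(d.group_positions[block], self.cfg.kernel)
        return K

    # -- per-record likelihood helpers ---------------------------------------

    def _offsets(self) -> np.ndarray:
        """Per-record location offset excluding the cluster mean."""
        d, cfg = self.data, self.cfg
        if cfg.variant == "interaction":
            return self.theta[d.group_idx] + d.gender * (self.delta + self.omega[d.age_idx])
        if cfg.variant == "cluster_shifts":
            return np.zeros(d.n)
        return self.theta[d.group_idx]

    def record_means(self) -> np.ndarray:
        """Likelihood mean for every record under the current state."""
        if self.cfg.variant == "cluster_shifts":
            return self.mu[self.c] + self.theta_k[self.data.group_idx, self.c]
        return self.mu[self.c] + self._offsets()

    def simulate_data(self, rng: Optional[np.random.Generator] = None) -> None:
        """Redraw the observations from the likelihood given the state
        (used by joint-distribution / Geweke-style checks)."""
        rng = rng or self.rng
        means = self.record_means()
        self.data.x = means + math.sqrt(self.sigma_x2) * rng.standard_normal(self.data.n)

    def _grow(self) -> None:
        extra = self._cap
        self._cap *= 2
        self.mu = np.concatenate([self.mu, np.zeros(extra)])
        self.counts = np.concatenate([self.counts, np.zeros(extra, dtype=np.int64)])
        self.LL = np.concatenate([self.LL, np.zeros((self.data.n, extra))], axis=1)
        if self.cfg.variant == "cluster_shifts":
            self.theta_k = np.concatenate([self.theta_k, np.zeros((self.data.J, extra))], axis=1)
        if self.cfg.variant == "hierarchical":
            self.counts_rk = np.concatenate(
                [self.counts_rk, np.zeros((self.data.n_races, extra), dtype=np.int64)], axis=1
            )
            self.v = np.concatenate([self.v, np.zeros(extra)])
        self.free.extend(range(self._cap - extra, self._cap))

    def _draw_fresh_params(self, col: int) -> None:
        cfg = self.cfg
        self.mu[col] = self.rng.normal(cfg.mu0, math.sqrt(cfg.sigma0_sq))
        if cfg.variant == "cluster_shifts":
            z = self.rng.standard_normal(self.data.J)
            self.theta_k[:, col] = self.theta_prior_mean + self.K_chol @ z

    def _ll_column(self, col: int, resid: np.ndarray, const: float, inv2s: float) -> None:
        if self.cfg.variant == "cluster_shifts":
            dev = resid - self.mu[col] - self.theta_k[self.data.group_idx, col]
        else:
            dev = resid - self.mu[col]
        self.LL[:, col] = const - dev * dev * inv2s

    # -- Gibbs blocks ---------------------------------------------------------

    def update_assignments(self) -> None:
        d, cfg, rng = self.data, self.cfg, self.rng
        m = cfg.n_aux
        hier = cfg.variant == "hierarchical"
        resid = d.x - self._offsets()
        const = -0.5 * (_LOG2PI + math.log(self.sigma_x2))
        inv2s = 0.5 / self.sigma_x2

        # refresh the auxiliary pool and all candidate likelihood columns
        for col in self.aux:
            self._draw_fresh_params(col)
        for col in self.occ + self.aux:
            self._ll_column(col, resid, const, inv2s)

        counts = self.counts
        occ, aux, free = self.occ, self.aux, self.free
        LL = self.LL
        alpha = self.alpha
        c = self.c
        race_idx = d.race_idx
        counts_rk = self.counts_rk if hier else None
        u = rng.random(d.n)

        for i in range(d.n):
            k = c[i]
            counts[k] -= 1
            if hier:
                counts_rk[race_idx[i], k] -= 1
            if counts[k] == 0:
                occ.remove(k)
                free.append(aux.pop())
                aux.append(k)
                if hier:
                    self.v_rem += self.v[k]
                    self.v[k] = 0.0
            cand = occ + aux
            nocc = len(occ)
            ll = LL[i, cand]
            if hier:
                w = counts_rk[race_idx[i], cand].astype(float)
                w[:nocc] += alpha * self.v[cand[:nocc]]
                w[nocc:] = alpha * self.v_rem / m
            else:
                w = counts[cand].astype(float)
                w[nocc:] = alpha / m
            p = w * np.exp(ll - ll.max())
            tot = p.sum()
            if not tot > 0:
                raise FloatingPointError("degenerate assignment distribution")
            idx = int(np.searchsorted(np.cumsum(p), u[i] * tot))
            idx = min(idx, len(cand) - 1)
            k_new = cand[idx]
            if idx >= nocc:
                aux.remove(k_new)
                occ.append(k_new)
                if hier:
                    b = rng.beta(1.0, self.gamma)
                    self.v[k_new] = b * self.v_rem
                    self.v_rem *= 1.0 - b
                if not free:
                    self._grow()
                    LL = self.LL
                    counts = self.counts
                    counts_rk = self.counts_rk if hier else None
                col = free.pop()
                self._draw_fresh_params(col)
                self._ll_column(col, resid, const, inv2s)
                aux.append(col)
            counts[k_new] += 1
            if hier:
                counts_rk[race_idx[i], k_new] += 1
            c[i] = k_new

    def update_cluster_means(self) -> None:
        d, cfg, rng = self.data, self.cfg, self.rng
        if cfg.variant == "cluster_shifts":
            resid = d.x - self.theta_k[d.group_idx, self.c]
        else:
            resid = d.x - self._offsets()
        for k in self.occ:
            mask = self.c == k
            mean, var = normal_mean_conditional(
                int(self.counts[k]), float(resid[mask].sum()), self.sigma_x2, cfg.mu0, cfg.sigma0_sq
            )
            self.mu[k] = rng.normal(mean, math.sqrt(var))

    def update_shifts(self) -> None:
        d, cfg, rng = self.data, self.cfg, self.rng
        if not cfg.sample_shifts:
            return
        if cfg.variant == "cluster_shifts":
            self._update_cluster_shifts()
            return
        # theta | rest : GP conditional given per-group residual sums
        if cfg.variant == "interaction":
            resid = d.x - self.mu[self.c] - d.gender * (self.delta + self.omega[d.age_idx])
        else:
            resid = d.x - self.mu[self.c]
        sums = np.bincount(d.group_idx, weights=resid, minlength=d.J)
        mean, cov = gp_shift_conditional(self.Kmat, d.group_sizes, sums, self.sigma_x2)
        self.theta = _sample_mvn(mean, cov, rng)
        if cfg.variant == "interaction":
            self._update_gender_terms()

    def _update_gender_terms(self) -> None:
        d, cfg, rng = self.data, self.cfg, self.rng
        fem = d.gender == 1
        n_f = int(fem.sum())
        base = d.x - self.mu[self.c] - self.theta[d.group_idx]
        # delta | rest
        r_delta = base[fem] - self.omega[d.age_idx[fem]]
        mean, var = normal_mean_conditional(
            n_f, float(r_delta.sum()), self.sigma_x2, 0.0, cfg.gender_variance
        )
        self.delta = rng.normal(mean, math.sqrt(var))
        # omega | rest
        r_omega = base[fem] - self.delta
        counts = np.bincount(d.age_idx[fem], minlength=len(d.ages)).astype(float)
        sums = np.bincount(d.age_idx[fem], weights=r_omega, minlength=len(d.ages))
        mean_w, cov_w = gp_shift_conditional(self.Omega, counts, sums, self.sigma_x2)
        self.omega = _sample_mvn(mean_w, cov_w, rng)

    def _update_cluster_shifts(self) -> None:
        d, rng = self.data, self.rng
        for k in self.occ:
            mask = self.c == k
            gi = d.group_idx[mask]
            counts = np.bincount(gi, minlength=d.J).astype(float)
            sums = np.bincount(gi, weights=d.x[mask] - self.mu[k], minlength=d.J)
            mean, cov = gp_shift_conditional(
                self.Kmat, counts, sums, self.sigma_x2, self.theta_prior_mean
            )
            self.theta_k[:, k] = _sample_mvn(mean, cov, rng)

    def update_noise_variance(self) -> None:
        cfg, rng = self.cfg, self.rng
        if not cfg.sample_variance:
            return
        resid = self.data.x - self.record_means()
        shape, scale = variance_conditional(self.data.n, float(resid @ resid), cfg.a, cfg.b)
        self.sigma_x2 = scale / rng.gamma(shape)

    def update_weights(self) -> None:
        """Hierarchical variant only: HDP direct-assignment weight update via
        simulated table counts.  Non-hierarchical variants carry their
        weights implicitly through the CRP occupancy counts."""
        if self.cfg.variant != "hierarchical":
            return
        d, rng = self.data, self.rng
        occ = self.occ
        K = len(occ)
        tables = np.zeros((d.n_races, K), dtype=np.int64)
        for r in range(d.n_races):
            for kk, k in enumerate(occ):
                tables[r, kk] = sample_table_count(
                    int(self.counts_rk[r, k]), self.alpha * max(self.v[k], 1e-300), rng
                )
        m_dot = tables.sum(axis=0)
        self._total_tables = int(m_dot.sum())
        v_full = rng.dirichlet(np.concatenate([m_dot + 1e-12, [self.gamma]]))
        for kk, k in enumerate(occ):
            self.v[k] = v_full[kk]
        self.v_rem = float(v_full[-1])
        pi = np.zeros((d.n_races, K + 1))
        for r in range(d.n_races):
            conc = np.concatenate(
                [
                    self.alpha * self.v[occ] + self.counts_rk[r, occ],
                    [self.alpha * self.v_rem],
                ]
            )
            pi[r] = rng.dirichlet(np.maximum(conc, 1e-12))
        self.pi_r = pi

    def update_concentrations(self) -> None:
        cfg, rng = self.cfg, self.rng
        if not cfg.sample_alpha:
            return
        K = len(self.occ)
        if cfg.variant == "hierarchical":
            total_tables = getattr(self, "_total_tables", K)
            sizes = np.bincount(self.data.race_idx, minlength=self.data.n_races)
            self.alpha = resample_hdp_alpha(self.alpha, sizes, total_tables, cfg.alpha_prior, rng)
            self.gamma = resample_concentration(
                self.gamma, K, max(total_tables, K), cfg.gamma_prior, rng
            )
        else:
            self.alpha = resample_concentration(self.alpha, K, self.data.n, cfg.alpha_prior, rng)

    def sweep(self) -> None:
        self.update_assignments()
        self.update_cluster_means()
        self.update_shifts()
        self.update_noise_variance()
        self.update_weights()
        self.update_concentrations()

    # -- state snapshot -------------------------------------------------------

    def snapshot(self, iteration: int) -> dict:
        d, cfg = self.data, self.cfg
        occ = np.array(self.occ, dtype=np.intp)
        mu = self.mu[occ]
        order = np.argsort(mu)  # clusters reported sorted ascending by mean
        occ = occ[order]
        state = {
            "iteration": iteration,
            "mu": self.mu[occ].copy(),
            "counts": self.counts[occ].copy(),
            "weights": self.counts[occ] / d.n,
            "sigma_x2": float(self.sigma_x2),
            "alpha": float(self.alpha),
            "n_clusters": len(occ),
            "theta": self.theta.copy(),
        }
        if cfg.variant == "interaction":
            state["delta"] = float(self.delta)
            state["omega"] = self.omega.copy()
        if cfg.variant == "cluster_shifts":
            state["theta_k"] = self.theta_k[:, occ].copy()
        if cfg.variant == "hierarchical":
            state["gamma"] = float(self.gamma)
            state["v"] = self.v[occ].copy()
            state["v_rem"] = float(self.v_rem)
            if self.pi_r is not None:
                pi = np.zeros((d.n_races, len(occ) + 1))
                # pi_r columns follow the pre-sort occupied order; re-map
                inv = {int(k): i for i, k in enumerate(self.occ)}
                for col, k in enumerate(occ):
                    pi[:, col] = self.pi_r[:, inv[int(k)]]
                pi[:, -1] = self.pi_r[:, -1]
                state["pi_r"] = pi
        if cfg.store_assignments:
            # relabel assignments to the sorted cluster order
            remap = np.zeros(self._cap, dtype=np.intp)
            remap[occ] = np.arange(len(occ))
            state["assignments"] = remap[self.c]
        return state


# ---------------------------------------------------------------------------
# estimator surface
# ---------------------------------------------------------------------------


class ADDPMixture(BaseEstimator):
    """Dependent Dirichlet process mixture of grouped finishing times.

    A scikit-learn style wrapper over the Gibbs sampler.  ``fit`` expects a
    DataFrame with columns ``finish_time`` (minutes), ``age``, ``gender``
    (0/'M' male, 1/'F' female) and, for the hierarchical variant, ``race``.

    Parameters default to the reference prior configuration converted to a
    minutes scale (see :func:`paper_hyperparameters`).

    Attributes (after ``fit``)
    --------------------------
    archive_ : PosteriorArchive
        Thinned Gibbs states.
    cluster_means_ : ndarray
        Posterior-averaged, relabeled, spurious-filtered cluster means
        (minutes, ascending), displayed at the reference group
        (``mu_k + theta_ref``).
    weights_ : ndarray
        Matching posterior-averaged occupancy fractions.
    sigma_x_ : float
        Posterior mean noise standard deviation (minutes).
    theta_ : ndarray
        Posterior mean group shifts.
    """

    def __init__(
        self,
        variant: str = "basic",
        mu0: float = 300.0,
        sigma0_sq: float = 3600.0,
        a: float = 1.0,
        b: float = 3600.0,
        kernel_variance: float = 180.0,
        kernel_lengthscale: float = 10.0,
        kernel_jitter: float = 3.6e-3,
        gender_variance: float = 180.0,
        omega_scale: float = 0.5,
        theta_mean: float = 0.0,
        alpha_prior_shape: float = 1.0,
        alpha_prior_scale: float = 10.0,
        n_aux: int = 10,
        n_iter: int = 2000,
        n_average: Optional[int] = None,
        thin: int = 5,
        seed: int = 0,
        sample_alpha: bool = True,
        sample_shifts: bool = True,
        sample_variance: bool = True,
        fixed_sigma_x2: Optional[float] = None,
        min_weight: float = 0.005,
        store_assignments: bool = True,
        init_clusters: int = 12,
    ):
        self.variant = variant
        self.mu0 = mu0
        self.sigma0_sq = sigma0_sq
        self.a = a
        self.b = b
        self.kernel_variance = kernel_variance
        self.kernel_lengthscale = kernel_lengthscale
        self.kernel_jitter = kernel_jitter
        self.gender_variance = gender_variance
        self.omega_scale = omega_scale
        self.theta_mean = theta_mean
        self.alpha_prior_shape = alpha_prior_shape
        self.alpha_prior_scale = alpha_prior_scale
        self.n_aux = n_aux
        self.n_iter = n_iter
        self.n_average = n_average
        self.thin = thin
        self.seed = seed
        self.sample_alpha = sample_alpha
        self.sample_shifts = sample_shifts
        self.sample_variance = sample_variance
        self.fixed_sigma_x2 = fixed_sigma_x2
        self.min_weight = min_weight
        self.store_assignments = store_assignments
        self.init_clusters = init_clusters

    def _config(self) -> ADDPConfig:
        return ADDPConfig(
            variant=self.variant,
            mu0=self.mu0,
            sigma0_sq=self.sigma0_sq,
            a=self.a,
            b=self.b,
            kernel=KernelSpec(self.kernel_variance, self.kernel_lengthscale, self.kernel_jitter),
            gender_variance=self.gender_variance,
            omega_scale=self.omega_scale,
            theta_mean=self.theta_mean,
            alpha_prior=ConcentrationPrior(self.alpha_prior_shape, self.alpha_prior_scale),
            gamma_prior=ConcentrationPrior(self.alpha_prior_shape, self.alpha_prior_scale),
            n_aux=self.n_aux,
            n_iter=self.n_iter,
            n_average=self.n_average,
            thin=self.thin,
            seed=self.seed,
            sample_alpha=self.sample_alpha,
            sample_shifts=self.sample_shifts,
            sample_variance=self.sample_variance,
            fixed_sigma_x2=self.fixed_sigma_x2,
            store_assignments=self.store_assignments,
            init_clusters=self.init_clusters,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "ADDPMixture":
        from . import postprocess

        cfg = self._config()
        data = _ADDPData(X, cfg.variant)
        rng = np.random.default_rng(cfg.seed)
        sampler = _ADDPSampler(data, cfg, rng)
        states = []
        for t in range(1, cfg.n_iter + 1):
            sampler.sweep()
            if t % cfg.thin == 0 or t == cfg.n_iter:
                states.append(sampler.snapshot(t))
            if t % 1000 == 0:
                _logger.info(
                    "addp[%s] iter %d: %d clusters, sigma_x=%.2f, alpha=%.2f",
                    cfg.variant, t, len(sampler.occ),
                    math.sqrt(sampler.sigma_x2), sampler.alpha,
                )
        manifest = {
            "model": "addp",
            "variant": cfg.variant,
            "seed": cfg.seed,
            "n_iter": cfg.n_iter,
            "n_average": cfg.n_average,
            "thin": cfg.thin,
            "n_records": data.n,
            "groups": data.group_labels,
            "ages": data.ages.tolist(),
            "races": list(map(str, data.races)),
            "kernel_form": "squared_exponential: variance*exp(-(l-j)^2/(2*lengthscale^2)) + jitter*I",
            "params": {k: v for k, v in self.get_params().items()},
        }
        self.archive_ = PosteriorArchive(states, manifest)
        self.sampler_ = sampler
        self.groups_ = data.group_labels
        self.ages_ = data.ages
        self.n_features_in_ = X.shape[1]

        window = self.archive_.window(cfg.n_average)
        # drop transient low-occupancy clusters state by state, then
        # summarise over the modal cluster-count states so that spurious
        # clusters do not smear the persistent ones
        filtered = [postprocess.filter_state(s, self.min_weight) for s in window]
        ref = postprocess.reference_group_index(data.group_labels)
        if cfg.variant == "cluster_shifts":
            # only mu_k + theta_jk is identified; display at the reference
            # group and let the relabel matching act on that quantity
            for s in filtered:
                s["mu"] = np.asarray(s["mu"]) + np.asarray(s["theta_k"])[ref]
        ks = np.array([s["n_clusters"] for s in filtered])
        modal_k = int(np.bincount(ks).argmax())
        modal_states = [s for s in filtered if s["n_clusters"] == modal_k] or filtered
        aligned = postprocess.relabel_archive_states(modal_states)
        summary = postprocess.summarize_aligned(aligned)
        theta_mat = np.stack([s["theta"] for s in window])
        self.theta_ = theta_mat.mean(axis=0)
        self.theta_sd_ = theta_mat.std(axis=0)
        if cfg.variant == "cluster_shifts":
            self.cluster_means_ = summary.mean
        else:
            self.cluster_means_ = summary.mean + self.theta_[ref]
        self.cluster_means_sd_ = summary.sd
        self.weights_ = summary.weight
        self.sigma_x_ = float(np.mean([math.sqrt(s["sigma_x2"]) for s in window]))
        self.alpha_ = float(np.mean([s["alpha"] for s in window]))
        self.n_clusters_ = len(summary.mean)
        if cfg.variant == "interaction":
            self.delta_ = float(np.mean([s["delta"] for s in window]))
            self.omega_ = np.stack([s["omega"] for s in window]).mean(axis=0)
        return self

    def score_samples(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean log density of finishing times under the averaged
        mixture (basic/interaction variants)."""
        from scipy.special import logsumexp

        from .postprocess import reference_group_index

        data = _ADDPData(X, self.variant)
        ref = reference_group_index(self.groups_)
        offsets = self.theta_[data.group_idx] - self.theta_[ref]
        if self.variant == "interaction":
            offsets = offsets + data.gender * (self.delta_ + self.omega_[data.age_idx])
        means = self.cluster_means_[None, :] + offsets[:, None]
        w = np.maximum(self.weights_, 1e-300)
        ll = (
            -0.5 * _LOG2PI
            - math.log(self.sigma_x_)
            - 0.5 * ((data.x[:, None] - means) / self.sigma_x_) ** 2
        )
        return logsumexp(ll + np.log(w / w.sum()), axis=1)


def addp_loglik(
    x: float,
    k: int,
    mu: np.ndarray,
    theta,
    sigma_x2: float,
    variant: str = "basic",
    group: int = 0,
    gender: int = 0,
    delta: float = 0.0,
    omega=None,
) -> float:
    """Gaussian log likelihood of one finishing time under cluster ``k``.

    The location is ``mu_k + theta_j`` (basic/hierarchical),
    ``mu_k + theta_j + g (delta + omega_j)`` (interaction) or
    ``mu_k + theta_jk`` (cluster-dependent shifts).
    """
    mu = np.asarray(mu, dtype=float)
    if variant == "cluster_shifts":
        th = np.asarray(theta)[group, k]
    else:
        th = np.asarray(theta)[group]
    m = mu[k] + th
    if variant == "interaction":
        m += gender * (delta + (0.0 if omega is None else np.asarray(omega)[group]))
    return float(-0.5 * (_LOG2PI + math.log(sigma_x2)) - 0.5 * (x - m) ** 2 / sigma_x2)


def fit_addp(data: pd.DataFrame, config: Optional[ADDPConfig] = None, **overrides) -> PosteriorArchive:
    """Functional wrapper: fit any ADDP variant and return its archive."""
    if config is not None:
        params = dict(
            variant=config.variant,
            mu0=config.mu0,
            sigma0_sq=config.sigma0_sq,
            a=config.a,
            b=config.b,
            kernel_variance=config.kernel.variance,
            kernel_lengthscale=config.kernel.lengthscale,
            kernel_jitter=config.kernel.jitter,
            gender_variance=config.gender_variance,
            omega_scale=config.omega_scale,
            theta_mean=config.theta_mean,
            alpha_prior_shape=config.alpha_prior.shape,
            alpha_prior_scale=config.alpha_prior.scale,
            n_aux=config.n_aux,
            n_iter=config.n_iter,
            n_average=config.n_average,
            thin=config.thin,
            seed=config.seed,
            sample_alpha=config.sample_alpha,
            sample_shifts=config.sample_shifts,
            sample_variance=config.sample_variance,
            fixed_sigma_x2=config.fixed_sigma_x2,
            store_assignments=config.store_assignments,
        )
    else:
        params = {}
    params.update(overrides)
    return ADDPMixture(**params).fit(data).archive_
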