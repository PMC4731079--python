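"""Hierarchical Dirichlet process over pacing profiles, and the
finish-time predictor built on it.

Each runner is represented by the fraction of their total time spent in
each course interval — a point on the simplex — so that clustering acts on
pacing shape rather than absolute speed.  The likelihood of a profile
``x`` under cluster pattern ``p`` is ``Dirichlet(tau * p)``: ``tau`` plays
the role of an inverse variance, and each pattern ``p_k`` carries a
``Dirichlet(epsilon * l_1, ..., epsilon * l_D)`` prior whose base measure
is proportional to the interval lengths (constant-pace profiles are the
prior centre).  Groups (age-group x gender) share the patterns through an
HDP and differ only in their mixing weights.

Pattern updates are Metropolis--Hastings with a ``Dirichlet(s * p_k)``
random-walk proposal (the Dirichlet parameter, not its mean, carries
``p_k``, so the conditional is non-conjugate); ``s`` adapts per cluster
during burn-in to a 20--40% acceptance rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .archive import PosteriorArchive
from .bnp_core import (
    ConcentrationPrior,
    resample_concentration,
    resample_hdp_alpha,
    sample_table_count,
)

__all__ = [
    "DEFAULT_INTERVALS",
    "PatternConfig",
    "PredictionResult",
    "normalize_splits",
    "dirichlet_pattern_loglik",
    "partial_profile_loglik",
    "HDPPatternModel",
    "FinishTimePredictor",
    "fit_hdp_patterns",
    "predict_finish",
]

#: Marathon interval scheme: eight 5-km legs plus the final 2.195 km.
DEFAULT_INTERVALS = (5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 2.195)

_FLOOR = 1e-10
_logger = logging.getLogger("ddpmix")


@dataclass
class PatternConfig:
    """Hyperparameters of the HDP pattern model."""

    tau: float = 5000.0
    epsilon: float = 0.2  # per-km prior concentration
    interval_lengths: tuple = DEFAULT_INTERVALS
    alpha_prior: ConcentrationPrior = field(default_factory=ConcentrationPrior)
    gamma_prior: ConcentrationPrior = field(default_factory=ConcentrationPrior)
    mh_proposal_concentration: float = 1e4
    n_aux: int = 10
    n_iter: int = 1500
    n_average: Optional[int] = None
    thin: int = 5
    seed: int = 0
    init_clusters: int = 12

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.epsilon <= 0:
            raise ValueError("tau and epsilon must be > 0")
        self.interval_lengths = tuple(float(l) for l in self.interval_lengths)
        if any(l <= 0 for l in self.interval_lengths):
            raise ValueError("interval lengths must be positive")
        if self.n_average is None:
            self.n_average = max(1, self.n_iter // 5)


@dataclass
class PredictionResult:
    """Finish-time projection for one runner with ``D`` observed records."""

    D: int
    predicted_finish: float
    per_cluster_factors: np.ndarray
    membership_probs: np.ndarray


def normalize_splits(cumulative_times, interval_lengths=None) -> np.ndarray:
    """Per-interval elapsed-time fractions from cumulative split times.

    The input must be strictly increasing with the final entry equal to the
    finishing time; the output sums to one.  Non-monotone or non-positive
    records raise ``ValueError`` (callers flag and exclude such rows).
    """
    cum = np.asarray(cumulative_times, dtype=float)
    if cum.ndim != 1 or len(cum) < 1:
        raise ValueError("cumulative times must be a non-empty 1-d vector")
    if interval_lengths is not None and len(cum) != len(interval_lengths):
        raise ValueError(
            f"expected {len(interval_lengths)} records for the declared interval "
            f"scheme, got {len(cum)}"
        )
    if not np.all(np.isfinite(cum)) or cum[0] <= 0 or np.any(np.diff(cum) <= 0):
        raise ValueError("cumulative split times must be finite, positive, strictly increasing")
    return np.diff(cum, prepend=0.0) / cum[-1]


def _interior(x: np.ndarray) -> np.ndarray:
    """Floor boundary zeros and renormalize (Dirichlet densities are
    undefined on the simplex boundary)."""
    x = np.maximum(np.asarray(x, dtype=float), _FLOOR)
    return x / x.sum()


def _dirichlet_logpdf(x: np.ndarray, conc: np.ndarray) -> float:
    return float(
        gammaln(conc.sum()) - gammaln(conc).sum() + np.dot(conc - 1.0, np.log(x))
    )


def dirichlet_pattern_loglik(profile, pattern, tau: float) -> float:
    """Log ``Dirichlet(tau * pattern)`` density at a simplex profile."""
    p = np.asarray(pattern, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pattern must be strictly positive on every coordinate")
    x = _interior(profile)
    return _dirichlet_logpdf(x, tau * p)


def partial_profile_loglik(observed_fractions, pattern, tau: float) -> float:
    """Score the first ``D`` interval times of a runner against a
    full-length pattern.

    By the Dirichlet aggregation property, the head of a
    ``Dirichlet(tau * p)`` vector renormalized to sum to one is itself
    ``Dirichlet(tau * p_1, ..., tau * p_D)`` — equivalently Dirichlet with
    concentration ``tau * sum_{d<=D} p_d`` around the renormalized head of
    the pattern.  Used only for relative weighting across clusters.
    """
    obs = np.asarray(observed_fractions, dtype=float)
    D = len(obs)
    if D == 0:
        raise ValueError("need at least one observed interval")
    p = np.asarray(pattern, dtype=float)[:D]
    if np.any(p <= 0):
        raise ValueError("pattern must be strictly positive on every coordinate")
    if D == 1:
        return 0.0  # a single renormalized fraction is identically one
    x = _interior(obs)
    return _dirichlet_logpdf(x, tau * p)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class _PatternData:
    def __init__(self, profiles: np.ndarray, groups: np.ndarray):
        X = np.asarray(profiles, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("profiles must be a non-empty 2-d array")
        if np.any(X < 0) or np.any(np.abs(X.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("profiles must be simplex vectors (non-negative, summing to 1)")
        X = np.maximum(X, _FLOOR)
        self.X = X / X.sum(axis=1, keepdims=True)
        self.logX = np.log(self.X)
        self.n, self.D = X.shape
        codes, self.group_labels = pd.factorize(np.asarray(groups), sort=True)
        self.group_idx = np.ascontiguousarray(codes)
        self.J = len(self.group_labels)
        self.group_sizes = np.bincount(self.group_idx, minlength=self.J)


class _HDPPatternSampler:
    def __init__(self, data: _PatternData, cfg: PatternConfig, rng: np.random.Generator):
        if data.D != len(cfg.interval_lengths):
            raise ValueError(
                f"profiles have {data.D} intervals but the scheme declares "
                f"{len(cfg.interval_lengths)}"
            )
        self.data = data
        self.cfg = cfg
        self.rng = rng
        self.prior_conc = cfg.epsilon * np.asarray(cfg.interval_lengths)

        cap = 8 + cfg.n_aux
        self._cap = cap
        self.P = np.zeros((cap, data.D))
        self.counts = np.zeros(cap, dtype=np.int64)
        self.counts_jk = np.zeros((data.J, cap), dtype=np.int64)
        self.v = np.zeros(cap)
        self.v_rem = 0.5
        self.LL = np.zeros((data.n, cap))
        self.mh_scale = np.full(cap, cfg.mh_proposal_concentration)
        self.mh_acc = np.zeros(cap, dtype=np.int64)
        self.mh_att = np.zeros(cap, dtype=np.int64)
        self.acceptance_rate = float("nan")

        # over-clustered k-means start: single-site Gibbs merges redundant
        # clusters quickly but splits extremely slowly under a sharp
        # likelihood, so initialise with more clusters than expected
        n_init = int(min(cfg.init_clusters, data.n))
        if data.D == 1 or float(data.X.var(axis=0).sum()) < 1e-12:
            n_init = 1  # degenerate profiles carry no clustering information
        if n_init > 1 and data.n > n_init:
            from sklearn.cluster import KMeans

            km = KMeans(n_clusters=n_init, n_init=3, random_state=int(rng.integers(2**31)))
            self.c = km.fit_predict(data.X).astype(np.intp)
        else:
            self.c = np.zeros(data.n, dtype=np.intp)
        used = np.unique(self.c)
        remap = np.zeros(used.max() + 1, dtype=np.intp)
        remap[used] = np.arange(len(used))
        self.c = remap[self.c]
        k0 = len(used)
        while self._cap < k0 + cfg.n_aux + 4:
            self._grow_static(k0)
        self.occ = list(range(k0))
        self.aux = list(range(k0, k0 + cfg.n_aux))
        self.free = list(range(k0 + cfg.n_aux, self._cap))
        for k in range(k0):
            self.P[k] = _interior(data.X[self.c == k].mean(axis=0))
        np.add.at(self.counts, self.c, 1)
        np.add.at(self.counts_jk, (data.group_idx, self.c), 1)
        self.v[:k0] = 0.5 / k0
        self.v_rem = 0.5
        self.alpha = 1.0
        self.gamma = 1.0
        self.pi_j = None
        self._adapting = True

    def _grow_static(self, _k0: int) -> None:
        # capacity growth before occ/aux lists exist
        extra = self._cap
        self._cap *= 2
        self.P = np.concatenate([self.P, np.zeros((extra, self.data.D))])
        self.counts = np.concatenate([self.counts, np.zeros(extra, dtype=np.int64)])
        self.counts_jk = np.concatenate(
            [self.counts_jk, np.zeros((self.data.J, extra), dtype=np.int64)], axis=1
        )
        self.v = np.concatenate([self.v, np.zeros(extra)])
        self.LL = np.concatenate([self.LL, np.zeros((self.data.n, extra))], axis=1)
        self.mh_scale = np.concatenate(
            [self.mh_scale, np.full(extra, self.cfg.mh_proposal_concentration)]
        )
        self.mh_acc = np.concatenate([self.mh_acc, np.zeros(extra, dtype=np.int64)])
        self.mh_att = np.concatenate([self.mh_att, np.zeros(extra, dtype=np.int64)])

    def _grow(self) -> None:
        extra = self._cap
        self._cap *= 2
        self.P = np.concatenate([self.P, np.zeros((extra, self.data.D))])
        self.counts = np.concatenate([self.counts, np.zeros(extra, dtype=np.int64)])
        self.counts_jk = np.concatenate(
            [self.counts_jk, np.zeros((self.data.J, extra), dtype=np.int64)], axis=1
        )
        self.v = np.concatenate([self.v, np.zeros(extra)])
        self.LL = np.concatenate([self.LL, np.zeros((self.data.n, extra))], axis=1)
        self.mh_scale = np.concatenate(
            [self.mh_scale, np.full(extra, self.cfg.mh_proposal_concentration)]
        )
        self.mh_acc = np.concatenate([self.mh_acc, np.zeros(extra, dtype=np.int64)])
        self.mh_att = np.concatenate([self.mh_att, np.zeros(extra, dtype=np.int64)])
        self.free.extend(range(self._cap - extra, self._cap))

    def _draw_prior_pattern(self, col: int) -> None:
        self.P[col] = _interior(self.rng.dirichlet(self.prior_conc))
        self.mh_scale[col] = self.cfg.mh_proposal_concentration
        self.mh_acc[col] = 0
        self.mh_att[col] = 0

    def _ll_column(self, col: int) -> None:
        p = self.P[col]
        tau = self.cfg.tau
        const = gammaln(tau) - gammaln(tau * p).sum()
        self.LL[:, col] = const + self.data.logX @ (tau * p - 1.0)

    def update_assignments(self) -> None:
        d, cfg, rng = self.data, self.cfg, self.rng
        m = cfg.n_aux
        for col in self.aux:
            self._draw_prior_pattern(col)
        for col in self.occ + self.aux:
            self._ll_column(col)
        counts, counts_jk = self.counts, self.counts_jk
        occ, aux, free = self.occ, self.aux, self.free
        LL, v = self.LL, self.v
        alpha = self.alpha
        c, gi = self.c, d.group_idx
        u = rng.random(d.n)
        for i in range(d.n):
            k = c[i]
            counts[k] -= 1
            counts_jk[gi[i], k] -= 1
            if counts[k] == 0:
                occ.remove(k)
                free.append(aux.pop())
                aux.append(k)
                self.v_rem += v[k]
                v[k] = 0.0
            cand = occ + aux
            nocc = len(occ)
            ll = LL[i, cand]
            w = counts_jk[gi[i], cand].astype(float)
            w[:nocc] += alpha * v[cand[:nocc]]
            w[nocc:] = alpha * self.v_rem / m
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
                b = rng.beta(1.0, self.gamma)
                v[k_new] = b * self.v_rem
                self.v_rem *= 1.0 - b
                if not free:
                    self._grow()
                    counts, counts_jk = self.counts, self.counts_jk
                    LL, v = self.LL, self.v
                col = free.pop()
                self._draw_prior_pattern(col)
                self._ll_column(col)
                aux.append(col)
            counts[k_new] += 1
            counts_jk[gi[i], k_new] += 1
            c[i] = k_new

    def update_patterns(self) -> None:
        """Metropolis--Hastings sweep over the occupied cluster patterns."""
        d, cfg, rng = self.data, self.cfg, self.rng
        tau = cfg.tau
        for k in self.occ:
            members = self.c == k
            n_k = int(self.counts[k])
            S = self.data.logX[members].sum(axis=0)
            p = self.P[k]
            s = self.mh_scale[k]
            prop = _interior(rng.dirichlet(s * p))

            def logpost(q: np.ndarray) -> float:
                lik = n_k * (gammaln(tau) - gammaln(tau * q).sum()) + np.dot(tau * q - 1.0, S)
                return lik + _dirichlet_logpdf(q, self.prior_conc)

            log_ratio = (
                logpost(prop)
                - logpost(p)
                + _dirichlet_logpdf(p, s * prop)
                - _dirichlet_logpdf(prop, s * p)
            )
            self.mh_att[k] += 1
            if math.log(rng.random()) < log_ratio:
                self.P[k] = prop
                self.mh_acc[k] += 1

    def adapt_proposals(self) -> None:
        """Double/halve per-cluster proposal concentrations toward a
        20--40% acceptance rate (burn-in only)."""
        for k in self.occ:
            if self.mh_att[k] >= 10:
                rate = self.mh_acc[k] / self.mh_att[k]
                if rate < 0.2:
                    self.mh_scale[k] = min(self.mh_scale[k] * 2.0, 1e13)
                elif rate > 0.4:
                    self.mh_scale[k] = max(self.mh_scale[k] / 2.0, 10.0)
                self.mh_acc[k] = 0
                self.mh_att[k] = 0

    def update_weights(self) -> None:
        d, rng = self.data, self.rng
        occ = self.occ
        K = len(occ)
        tables = np.zeros((d.J, K), dtype=np.int64)
        for j in range(d.J):
            for kk, k in enumerate(occ):
                tables[j, kk] = sample_table_count(
                    int(self.counts_jk[j, k]), self.alpha * max(self.v[k], 1e-300), rng
                )
        m_dot = tables.sum(axis=0)
        self._total_tables = int(m_dot.sum())
        v_full = rng.dirichlet(np.concatenate([m_dot + 1e-12, [self.gamma]]))
        for kk, k in enumerate(occ):
            self.v[k] = v_full[kk]
        self.v_rem = float(v_full[-1])
        pi = np.zeros((d.J, K + 1))
        for j in range(d.J):
            conc = np.concatenate(
                [self.alpha * self.v[occ] + self.counts_jk[j, occ], [self.alpha * self.v_rem]]
            )
            pi[j] = rng.dirichlet(np.maximum(conc, 1e-12))
        self.pi_j = pi

    def update_concentrations(self) -> None:
        cfg, rng = self.cfg, self.rng
        K = len(self.occ)
        total_tables = getattr(self, "_total_tables", K)
        self.alpha = resample_hdp_alpha(
            self.alpha, self.data.group_sizes, total_tables, cfg.alpha_prior, rng
        )
        self.gamma = resample_concentration(
            self.gamma, K, max(total_tables, K), cfg.gamma_prior, rng
        )

    def sweep(self, adapt: bool = False) -> None:
        self.update_assignments()
        self.update_patterns()
        if adapt:
            self.adapt_proposals()
        self.update_weights()
        self.update_concentrations()

    def snapshot(self, iteration: int) -> dict:
        occ = np.array(self.occ, dtype=np.intp)
        att = self.mh_att[occ].sum()
        state = {
            "iteration": iteration,
            "patterns": self.P[occ].copy(),
            "counts": self.counts[occ].copy(),
            "weights": self.counts[occ] / self.data.n,
            "v": self.v[occ].copy(),
            "v_rem": float(self.v_rem),
            "pi_j": self.pi_j[:, :].copy() if self.pi_j is not None else None,
            "alpha": float(self.alpha),
            "gamma": float(self.gamma),
            "n_clusters": len(occ),
            "assignments": _compress_assignments(self.c, occ),
            "acceptance_rate": float(self.mh_acc[occ].sum() / att) if att else float("nan"),
        }
        return state


def _compress_assignments(c: np.ndarray, occ: np.ndarray) -> np.ndarray:
    remap = np.zeros(occ.max() + 1, dtype=np.intp)
    remap[occ] = np.arange(len(occ))
    return remap[c]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class HDPPatternModel(BaseEstimator):
    """HDP mixture of Dirichlet-distributed pacing profiles.

    ``fit(X, groups)`` takes an ``(n, D)`` array of simplex profiles (see
    :func:`normalize_splits`) and a length-``n`` group label vector
    (age-group x gender).  Fitted attributes: ``archive_``, posterior
    mode cluster count ``modal_n_clusters_``, aligned posterior-mean
    ``patterns_`` and matching occupancy ``pattern_weights_``, and
    per-group mixing ``group_weights_``.
    """

    def __init__(
        self,
        tau: float = 5000.0,
        epsilon: float = 0.2,
        interval_lengths: Sequence[float] = DEFAULT_INTERVALS,
        mh_proposal_concentration: float = 1e4,
        alpha_prior_shape: float = 1.0,
        alpha_prior_scale: float = 10.0,
        n_aux: int = 10,
        n_iter: int = 1500,
        n_average: Optional[int] = None,
        thin: int = 5,
        seed: int = 0,
        burn_in_fraction: float = 0.5,
        init_clusters: int = 12,
    ):
        self.tau = tau
        self.epsilon = epsilon
        self.interval_lengths = interval_lengths
        self.mh_proposal_concentration = mh_proposal_concentration
        self.alpha_prior_shape = alpha_prior_shape
        self.alpha_prior_scale = alpha_prior_scale
        self.n_aux = n_aux
        self.n_iter = n_iter
        self.n_average = n_average
        self.thin = thin
        self.seed = seed
        self.burn_in_fraction = burn_in_fraction
        self.init_clusters = init_clusters

    def _config(self) -> PatternConfig:
        return PatternConfig(
            tau=self.tau,
            epsilon=self.epsilon,
            interval_lengths=tuple(self.interval_lengths),
            alpha_prior=ConcentrationPrior(self.alpha_prior_shape, self.alpha_prior_scale),
            gamma_prior=ConcentrationPrior(self.alpha_prior_shape, self.alpha_prior_scale),
            mh_proposal_concentration=self.mh_proposal_concentration,
            n_aux=self.n_aux,
            n_iter=self.n_iter,
            n_average=self.n_average,
            thin=self.thin,
            seed=self.seed,
            init_clusters=self.init_clusters,
        )

    def fit(self, X, groups=None, y=None) -> "HDPPatternModel":
        cfg = self._config()
        if groups is None:
            groups = np.zeros(len(X), dtype=int)
        data = _PatternData(X, groups)
        rng = np.random.default_rng(cfg.seed)
        sampler = _HDPPatternSampler(data, cfg, rng)
        burn = int(self.burn_in_fraction * cfg.n_iter)
        states = []
        for t in range(1, cfg.n_iter + 1):
            sampler.sweep(adapt=(t <= burn and t % 20 == 0))
            if t % cfg.thin == 0 or t == cfg.n_iter:
                states.append(sampler.snapshot(t))
            if t % 1000 == 0:
                att = sampler.mh_att[sampler.occ].sum()
                acc = sampler.mh_acc[sampler.occ].sum() / att if att else float("nan")
                _logger.info(
                    "hdp iter %d: %d clusters, MH acceptance %.2f, alpha=%.2f, gamma=%.2f",
                    t, len(sampler.occ), acc, sampler.alpha, sampler.gamma,
                )
        manifest = {
            "model": "hdp_patterns",
            "seed": cfg.seed,
            "n_iter": cfg.n_iter,
            "n_average": cfg.n_average,
            "thin": cfg.thin,
            "n_records": data.n,
            "tau": cfg.tau,
            "epsilon": cfg.epsilon,
            "interval_lengths": list(cfg.interval_lengths),
            "groups": list(map(str, data.group_labels)),
            "membership_prior": "group_weights",
        }
        self.archive_ = PosteriorArchive(states, manifest)
        self.sampler_ = sampler
        self.group_labels_ = data.group_labels
        self.n_features_in_ = data.D

        window = self.archive_.window(cfg.n_average)
        ks = np.array([s["n_clusters"] for s in window])
        self.modal_n_clusters_ = int(np.bincount(ks).argmax())
        self.patterns_, self.pattern_weights_, self.group_weights_ = _average_patterns(
            window, self.modal_n_clusters_
        )
        return self

    def predict_proba(self, X, groups=None) -> np.ndarray:
        """Posterior-averaged cluster membership of new profiles (against
        the aligned posterior-mean patterns and group weights)."""
        data = _PatternData(X, groups if groups is not None else np.zeros(len(X), dtype=int))
        tau = self.tau
        P = self.patterns_
        const = gammaln(tau) - gammaln(tau * P).sum(axis=1)
        ll = data.logX @ (tau * P - 1.0).T + const
        gw = self.group_weights_.T[data.group_idx]
        logw = ll + np.log(np.maximum(gw, 1e-300))
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        return w / w.sum(axis=1, keepdims=True)


def _average_patterns(window: list[dict], modal_k: int):
    """Align patterns across modal-K states by L1 assignment matching and
    average them, their occupancy, and the per-group weights."""
    states = [s for s in window if s["n_clusters"] == modal_k] or [window[-1]]
    ref = states[-1]["patterns"]
    J = states[-1]["pi_j"].shape[0] if states[-1]["pi_j"] is not None else 1
    acc_p = np.zeros_like(ref)
    acc_w = np.zeros(len(ref))
    acc_pi = np.zeros((J, len(ref)))
    for s in states:
        P = s["patterns"]
        K = len(P)
        cost = np.abs(P[:, None, :] - ref[None, : len(P), :]).sum(axis=2)
        rows, cols = linear_sum_assignment(cost[:, : min(K, len(ref))])
        for r, cidx in zip(rows, cols):
            acc_p[cidx] += P[r]
            acc_w[cidx] += s["weights"][r]
            if s["pi_j"] is not None:
                acc_pi[:, cidx] += s["pi_j"][:, r]
    n = len(states)
    patterns = acc_p / np.maximum(acc_p.sum(axis=1, keepdims=True), 1e-300)
    return patterns, acc_w / n, acc_pi / n


class FinishTimePredictor(BaseEstimator):
    """Project finishing times from the first ``D`` cumulative records.

    Fits the HDP pattern model on head-renormalized profiles truncated at
    interval ``D`` (a separate fit per ``D``), then, per archived posterior
    state, weights the per-cluster median quotient ``q_k = median(finish /
    elapsed_D)`` of the training members by each test runner's posterior
    cluster membership (group mixing weights times the Dirichlet
    likelihood of the renormalized head) and projects
    ``prediction = elapsed_D * sum_k prob_k q_k``, averaging over states.
    Predictions are scale-equivariant in the test runner's elapsed times.
    """

    def __init__(
        self,
        D: int = 4,
        interval_lengths: Sequence[float] = DEFAULT_INTERVALS,
        tau: float = 5000.0,
        epsilon: float = 0.2,
        mh_proposal_concentration: float = 1e4,
        alpha_prior_shape: float = 1.0,
        alpha_prior_scale: float = 10.0,
        n_aux: int = 10,
        n_iter: int = 800,
        n_average: Optional[int] = None,
        thin: int = 5,
        seed: int = 0,
        init_clusters: int = 12,
    ):
        self.D = D
        self.interval_lengths = interval_lengths
        self.tau = tau
        self.epsilon = epsilon
        self.mh_proposal_concentration = mh_proposal_concentration
        self.alpha_prior_shape = alpha_prior_shape
        self.alpha_prior_scale = alpha_prior_scale
        self.n_aux = n_aux
        self.n_iter = n_iter
        self.n_average = n_average
        self.thin = thin
        self.seed = seed
        self.init_clusters = init_clusters

    def _head_profiles(self, cum: np.ndarray) -> np.ndarray:
        head = cum[:, : self.D]
        frac = np.diff(head, prepend=0.0, axis=1)
        if np.any(frac <= 0):
            raise ValueError("cumulative times must be strictly increasing")
        return frac / head[:, -1:]

    def fit(self, cumulative_times, groups=None, y=None) -> "FinishTimePredictor":
        cum = np.asarray(cumulative_times, dtype=float)
        D_total = cum.shape[1]
        if not 1 <= self.D <= D_total:
            raise ValueError(f"D must be in 1..{D_total}, got {self.D}")
        if groups is None:
            groups = np.zeros(len(cum), dtype=int)
        self.model_ = HDPPatternModel(
            tau=self.tau,
            epsilon=self.epsilon,
            interval_lengths=tuple(self.interval_lengths)[: self.D],
            mh_proposal_concentration=self.mh_proposal_concentration,
            alpha_prior_shape=self.alpha_prior_shape,
            alpha_prior_scale=self.alpha_prior_scale,
            n_aux=self.n_aux,
            n_iter=self.n_iter,
            n_average=self.n_average,
            thin=self.thin,
            seed=self.seed,
            init_clusters=self.init_clusters,
        )
        self.model_.fit(self._head_profiles(cum), groups)
        self.train_elapsed_ = cum[:, self.D - 1]
        self.train_finish_ = cum[:, -1]
        self.train_quotients_ = self.train_finish_ / self.train_elapsed_
        self.global_q_ = float(np.median(self.train_quotients_))
        self.fallback_used_ = 0
        return self

    def predict(self, cumulative_times, groups=None) -> np.ndarray:
        return np.array([r.predicted_finish for r in self.predict_detailed(cumulative_times, groups)])

    def predict_detailed(self, cumulative_times, groups=None) -> list[PredictionResult]:
        cum = np.asarray(cumulative_times, dtype=float)
        if cum.ndim == 1:
            cum = cum[None, :]
        if cum.shape[1] < self.D:
            raise ValueError(f"need at least {self.D} cumulative records")
        if groups is None:
            groups = np.zeros(len(cum), dtype=int)
        model = self.model_
        data_head = self._head_profiles(cum[:, : self.D])
        logX = np.log(np.maximum(data_head, _FLOOR))
        elapsed = cum[:, self.D - 1]
        group_codes = _map_groups(groups, model.group_labels_)
        tau = self.tau
        window = model.archive_.window()
        n_test = len(cum)
        acc_pred = np.zeros(n_test)
        acc_prob: Optional[np.ndarray] = None
        acc_q: Optional[np.ndarray] = None
        n_states = 0
        for s in window:
            P = s["patterns"]
            K = len(P)
            const = gammaln(tau) - gammaln(tau * P).sum(axis=1)
            ll = logX @ (tau * P - 1.0).T + const
            pi = s["pi_j"]
            gw = pi[group_codes, :K] if pi is not None else np.ones((n_test, K))
            logw = ll + np.log(np.maximum(gw, 1e-300))
            logw -= logw.max(axis=1, keepdims=True)
            w = np.exp(logw)
            probs = w / w.sum(axis=1, keepdims=True)
            q = np.empty(K)
            for k in range(K):
                members = s["assignments"] == k
                if members.any():
                    q[k] = np.median(self.train_quotients_[members])
                else:
                    q[k] = self.global_q_
                    self.fallback_used_ += 1
            acc_pred += elapsed * (probs @ q)
            if acc_prob is None or probs.shape[1] > acc_prob.shape[1]:
                pad = probs.shape[1] - (0 if acc_prob is None else acc_prob.shape[1])
                if acc_prob is None:
                    acc_prob = np.zeros((n_test, probs.shape[1]))
                    acc_q = np.zeros(probs.shape[1])
                else:
                    acc_prob = np.pad(acc_prob, ((0, 0), (0, pad)))
                    acc_q = np.pad(acc_q, (0, pad))
            acc_prob[:, : probs.shape[1]] += probs
            acc_q[: len(q)] += q
            n_states += 1
        preds = acc_pred / n_states
        mean_prob = acc_prob / n_states
        mean_q = acc_q / n_states
        return [
            PredictionResult(
                D=self.D,
                predicted_finish=float(preds[i]),
                per_cluster_factors=mean_q.copy(),
                membership_probs=mean_prob[i] / mean_prob[i].sum(),
            )
            for i in range(n_test)
        ]


def _map_groups(groups, group_labels) -> np.ndarray:
    lookup = {str(g): i for i, g in enumerate(group_labels)}
    out = np.zeros(len(groups), dtype=np.intp)
    for i, g in enumerate(np.asarray(groups)):
        out[i] = lookup.get(str(g), 0)
    return out


def fit_hdp_patterns(profiles, groups=None, config: Optional[PatternConfig] = None, **overrides):
    """Functional wrapper: fit the HDP pattern model, return its archive."""
    params = {}
    if config is not None:
        params = dict(
            tau=config.tau,
            epsilon=config.epsilon,
            interval_lengths=config.interval_lengths,
            mh_proposal_concentration=config.mh_proposal_concentration,
            alpha_prior_shape=config.alpha_prior.shape,
            alpha_prior_scale=config.alpha_prior.scale,
            n_aux=config.n_aux,
            n_iter=config.n_iter,
            n_average=config.n_average,
            thin=config.thin,
            seed=config.seed,
        )
    params.update(overrides)
    return HDPPatternModel(**params).fit(profiles, groups).archive_


def predict_finish(
    cumulative_times_test,
    groups_test,
    cumulative_times_train,
    groups_train,
    D: int,
    **predictor_params,
) -> list[PredictionResult]:
    """Functional wrapper over :class:`FinishTimePredictor`."""
    pred = FinishTimePredictor(D=D, **predictor_params)
    pred.fit(cumulative_times_train, groups_train)
    return pred.predict_detailed(cumulative_times_test, groups_test)
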