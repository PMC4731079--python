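"""Chain diagnostics: effective sample size, moment comparison for
joint-distribution (Geweke-style) checks, and a minimal trace plot."""

from __future__ import annotations

import numpy as np

__all__ = ["effective_sample_size", "moment_zscores", "plot_trace"]


def effective_sample_size(x: np.ndarray, max_lag: int | None = None) -> float:
    """ESS by the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    max_lag = max_lag or n // 3
    rho_sum = 0.0
    for lag in range(1, max_lag):
        pair = acf[lag] + (acf[lag + 1] if lag + 1 < n else 0.0)
        if pair < 0:
            break
        rho_sum += pair
    return float(np.clip(n / (1.0 + 2.0 * rho_sum), 1.0, n))


def moment_zscores(forward: np.ndarray, successive: np.ndarray) -> float:
    """z-score of the mean difference between two samples of the same
    functional, with the successive-conditional side corrected for
    autocorrelation via its effective sample size."""
    forward = np.asarray(forward, dtype=float)
    successive = np.asarray(successive, dtype=float)
    se_f = forward.std(ddof=1) / np.sqrt(len(forward))
    ess = effective_sample_size(successive)
    se_s = successive.std(ddof=1) / np.sqrt(ess)
    se = float(np.hypot(se_f, se_s))
    if se == 0:
        return 0.0
    return float((forward.mean() - successive.mean()) / se)


def plot_trace(values, ax=None, label: str | None = None):
    """Plot a scalar trace (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2.5))
    ax.plot(np.asarray(values), lw=0.7, label=label)
    ax.set_xlabel("archived state")
    if label:
        ax.legend(loc="best", frameon=False)
    return ax
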