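"""Post-processing of MCMC archives.

Turns raw thinned Gibbs states into reportable objects: label-switching
repair by minimum-cost matching of cluster means, posterior averaging,
spurious-cluster filtering, age/gender grading tables and runner
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .archive import PosteriorArchive

__all__ = [
    "ClusterSummary",
    "GradingTable",
    "relabel_archive",
    "relabel_archive_states",
    "summarize_aligned",
    "summarize_archive",
    "filter_state",
    "filter_spurious",
    "build_grading_table",
    "compare_runners",
    "reference_group_index",
]


@dataclass
class ClusterSummary:
    """Posterior-averaged cluster table, sorted ascending by mean."""

    mean: np.ndarray
    sd: np.ndarray
    weight: np.ndarray
    occupancy_count: np.ndarray
    spread: float = float("nan")  # posterior mean sigma_x

    def __post_init__(self) -> None:
        order = np.argsort(self.mean)
        self.mean = np.asarray(self.mean)[order]
        self.sd = np.asarray(self.sd)[order]
        self.weight = np.asarray(self.weight)[order]
        self.occupancy_count = np.asarray(self.occupancy_count)[order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.mean,
                "sd": self.sd,
                "weight": self.weight,
                "occupancy_count": self.occupancy_count,
            }
        )


# ---------------------------------------------------------------------------
# label-switching repair
# ---------------------------------------------------------------------------

_PER_CLUSTER_KEYS = ("mu", "weights", "counts", "v")


def relabel_archive_states(states: Sequence[dict]) -> dict:
    """Match clusters across states by minimum-cost assignment on the
    absolute difference of cluster means against a running reference.

    Returns a dict of NaN-padded matrices (``n_states x K_total``) for
    ``mu``, ``weights`` and ``counts``, plus the per-state column
    permutations, so that column ``k`` traces one persistent cluster.
    """
    if len(states) < 1:
        raise ValueError("need at least one state")
    ref_mean = np.asarray(states[0]["mu"], dtype=float).copy()
    ref_n = np.ones(len(ref_mean))
    columns: list[np.ndarray] = []  # per state: column index of each cluster
    for s in states:
        mu = np.asarray(s["mu"], dtype=float)
        K = len(mu)
        cost = np.abs(mu[:, None] - ref_mean[None, :])
        rows, cols = linear_sum_assignment(cost)
        assign = np.full(K, -1, dtype=int)
        assign[rows] = cols
        for k in np.flatnonzero(assign < 0):  # more clusters than reference
            ref_mean = np.append(ref_mean, mu[k])
            ref_n = np.append(ref_n, 0.0)
            assign[k] = len(ref_mean) - 1
        # running-mean update keeps the reference stable but adaptive
        for k, col in enumerate(assign):
            ref_n[col] += 1.0
            ref_mean[col] += (mu[k] - ref_mean[col]) / ref_n[col]
        columns.append(assign)
    K_total = len(ref_mean)
    out = {
        "columns": columns,
        "mu": np.full((len(states), K_total), np.nan),
        "weights": np.full((len(states), K_total), np.nan),
        "counts": np.full((len(states), K_total), np.nan),
    }
    for i, (s, assign) in enumerate(zip(states, columns)):
        out["mu"][i, assign] = s["mu"]
        out["weights"][i, assign] = s["weights"]
        out["counts"][i, assign] = s["counts"]
    return out


def relabel_archive(archive: PosteriorArchive) -> PosteriorArchive:
    """Return a copy of the archive with every per-cluster block permuted to
    a consistent labelling across states."""
    if len(archive) < 2:
        raise ValueError("relabeling needs at least two archived states")
    aligned = relabel_archive_states(archive.states)
    new_states = []
    for s, assign in zip(archive.states, aligned["columns"]):
        t = dict(s)
        K_total = aligned["mu"].shape[1]
        for key in _PER_CLUSTER_KEYS:
            if key in s:
                arr = np.full(K_total, np.nan)
                arr[assign] = np.asarray(s[key], dtype=float)
                t[key] = arr
        if "pi_r" in s:
            pi = np.asarray(s["pi_r"])
            out = np.full((pi.shape[0], K_total + 1), np.nan)
            out[:, assign] = pi[:, :-1]
            out[:, -1] = pi[:, -1]
            t["pi_r"] = out
        if "theta_k" in s:
            tk = np.asarray(s["theta_k"])
            out = np.full((tk.shape[0], K_total), np.nan)
            out[:, assign] = tk
            t["theta_k"] = out
        if "assignments" in s:
            t["assignments"] = assign[np.asarray(s["assignments"], dtype=np.intp)]
        new_states.append(t)
    manifest = dict(archive.manifest)
    manifest["relabeled"] = True
    return PosteriorArchive(new_states, manifest)


def summarize_aligned(aligned: dict) -> ClusterSummary:
    """Posterior averages over an aligned (relabeled) state block.

    A cluster absent from a state contributes zero weight for that state;
    its mean is averaged only over the states where it exists.
    """
    mu = aligned["mu"]
    w = np.nan_to_num(aligned["weights"], nan=0.0)
    counts = np.nan_to_num(aligned["counts"], nan=0.0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mu, axis=0)
        sd = np.nanstd(mu, axis=0)
    return ClusterSummary(
        mean=mean,
        sd=sd,
        weight=w.mean(axis=0),
        occupancy_count=counts.mean(axis=0),
    )


def summarize_archive(
    archive: PosteriorArchive, n_average: Optional[int] = None, min_weight: float = 0.0
) -> ClusterSummary:
    window = archive.window(n_average)
    summary = summarize_aligned(relabel_archive_states(window))
    summary.spread = float(np.mean(np.sqrt([s["sigma_x2"] for s in window])))
    if min_weight > 0:
        summary = filter_spurious(summary, min_weight)
    return summary


def filter_state(state: dict, min_weight: float = 0.005) -> dict:
    """Drop transient low-occupancy clusters from one archived state.

    Per-cluster blocks are trimmed in concert; assignments are left
    untouched (records of dropped clusters keep their labels, which simply
    have no summary column).
    """
    keep = np.asarray(state["weights"]) >= min_weight
    if not keep.any():
        keep = np.asarray(state["weights"]) == np.max(state["weights"])
    out = dict(state)
    for key in _PER_CLUSTER_KEYS:
        if key in state:
            out[key] = np.asarray(state[key])[keep]
    if "theta_k" in state:
        out["theta_k"] = np.asarray(state["theta_k"])[:, keep]
    if "pi_r" in state:
        pi = np.asarray(state["pi_r"])
        out["pi_r"] = np.concatenate([pi[:, :-1][:, keep], pi[:, -1:]], axis=1)
    out["n_clusters"] = int(keep.sum())
    return out


def filter_spurious(summary: ClusterSummary, min_weight: float = 0.005) -> ClusterSummary:
    """Drop clusters whose posterior-mean occupancy falls below
    ``min_weight`` (transient low-occupancy clusters are an artefact of the
    nonparametric sampler)."""
    keep = summary.weight >= min_weight
    if not np.any(keep):
        raise ValueError(
            f"min_weight={min_weight} filters out every cluster "
            f"(max weight {summary.weight.max():.4g})"
        )
    out = ClusterSummary(
        mean=summary.mean[keep],
        sd=summary.sd[keep],
        weight=summary.weight[keep],
        occupancy_count=summary.occupancy_count[keep],
        spread=summary.spread,
    )
    out.removed_mass = float(summary.weight[~keep].sum())
    return out


# ---------------------------------------------------------------------------
# grading tables
# ---------------------------------------------------------------------------


def reference_group_index(
    group_labels: Sequence[tuple], reference: Optional[tuple] = None
) -> int:
    """Index of the reference cell among group labels ``(gender, age)``.

    Defaults to 28-year-old men when present (the conventional zero of the
    grading table), else the first group.
    """
    labels = list(group_labels)
    if reference is not None:
        if tuple(reference) not in labels:
            raise KeyError(f"reference group {reference} not among groups")
        return labels.index(tuple(reference))
    for cand in (("male", 28), ("*", 28)):
        if cand in labels:
            return labels.index(cand)
    return 0


@dataclass
class GradingTable:
    """Posterior mean shift per (age, gender) relative to a reference cell.

    ``men[age]`` is ``E[theta_age] - E[theta_ref]``; ``women[age]`` is
    ``E[theta_age + delta + omega_age] - E[theta_ref]``.  Minutes; the
    reference cell is exactly zero.
    """

    ages: np.ndarray
    men: np.ndarray
    women: np.ndarray
    reference_age: int
    reference_gender: str = "male"

    def __getitem__(self, cell: tuple) -> float:
        gender, age = cell
        idx = np.flatnonzero(self.ages == age)
        if len(idx) == 0:
            raise KeyError(f"age {age} not in grading table")
        g = str(gender).lower()
        if g in ("male", "m", "men", "0"):
            return float(self.men[idx[0]])
        if g in ("female", "f", "women", "w", "1"):
            return float(self.women[idx[0]])
        raise KeyError(f"unknown gender {gender!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "men": self.men, "women": self.women})

    def to_text(self) -> str:
        lines = []
        ages = self.ages
        for start in range(0, len(ages), 10):
            blk = slice(start, start + 10)
            lines.append("age    " + "".join(f"{a:>8d}" for a in ages[blk]))
            lines.append("men    " + "".join(f"{v:>8.2f}" for v in self.men[blk]))
            lines.append("women  " + "".join(f"{v:>8.2f}" for v in self.women[blk]))
            lines.append("")
        return "\n".join(lines)


def build_grading_table(
    archive: PosteriorArchive,
    n_average: Optional[int] = None,
    reference_age: int = 28,
) -> GradingTable:
    """Grading table from an age-gender interaction ADDP archive.

    Entries are posterior mean shifts in minutes relative to the male
    reference age; comparing two runners is the difference of their cells.
    Invariant to the additive non-identifiability between cluster means and
    shifts, since only shift contrasts enter.
    """
    if archive.manifest.get("variant") != "interaction":
        raise ValueError("grading tables require an interaction-variant archive")
    window = archive.window(n_average)
    ages = np.asarray(archive.manifest["ages"], dtype=int)
    theta = np.stack([s["theta"] for s in window]).mean(axis=0)
    delta = float(np.mean([s["delta"] for s in window]))
    omega = np.stack([s["omega"] for s in window]).mean(axis=0)
    if reference_age not in ages:
        raise KeyError(f"reference age {reference_age} not among modeled ages")
    ref = int(np.flatnonzero(ages == reference_age)[0])
    men = theta - theta[ref]
    women = theta + delta + omega - theta[ref]
    return GradingTable(ages=ages, men=men, women=women, reference_age=reference_age)


def compare_runners(
    time1: float, cell1: tuple, time2: float, cell2: tuple, table: GradingTable
) -> float:
    """Age/gender-adjusted difference of two finishing times, in minutes.

    ``(time1 - table[cell1]) - (time2 - table[cell2])``: positive means
    runner 1 is effectively slower once their group handicap is removed.
    """
    return (time1 - table[cell1]) - (time2 - table[cell2])
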