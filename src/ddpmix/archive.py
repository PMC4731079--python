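"""Posterior sample archives.

A :class:`PosteriorArchive` is a list of thinned Gibbs-state snapshots plus
a manifest (model, variant, seed, iteration metadata) sufficient to
reproduce the run.  Archives serialise to a directory of delimited-text
tables — one long-format CSV per latent block — plus a JSON manifest.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = ["PosteriorArchive"]

_SCALAR_KEYS = ("sigma_x2", "alpha", "gamma", "delta", "n_clusters", "v_rem")
_GROUP_KEYS = ("theta", "omega")


class PosteriorArchive:
    def __init__(self, states: list[dict], manifest: Optional[dict] = None):
        if not states:
            raise ValueError("archive must contain at least one state")
        self.states = states
        self.manifest = dict(manifest or {})
        self.manifest.setdefault("written_at", time.strftime("%Y-%m-%dT%H:%M:%S"))

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterable[dict]:
        return iter(self.states)

    def window(self, n_average: Optional[int] = None) -> list[dict]:
        """States from the final averaging window (last ``n_average``
        iterations; defaults to the manifest's value, else the last 20%)."""
        n_iter = self.manifest.get("n_iter", self.states[-1]["iteration"])
        if n_average is None:
            n_average = self.manifest.get("n_average") or max(1, n_iter // 5)
        cut = n_iter - n_average
        out = [s for s in self.states if s["iteration"] > cut]
        return out if out else [self.states[-1]]

    def stack(self, key: str) -> np.ndarray:
        """Stack a per-state quantity with constant shape across states."""
        return np.stack([np.asarray(s[key]) for s in self.states])

    def trace(self, key: str) -> np.ndarray:
        return np.array([s[key] for s in self.states], dtype=float)

    # -- serialisation -------------------------------------------------------

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows_cluster, rows_scalar, rows_group, rows_pi, rows_assign, rows_theta_k = (
            [], [], [], [], [], [],
        )
        rows_patterns, rows_pi_j = [], []
        for s in self.states:
            t = s["iteration"]
            for k in range(len(s.get("mu", s.get("patterns", [])))):
                row = {
                    "iteration": t,
                    "cluster": k,
                    "weight": s["weights"][k],
                    "count": int(s["counts"][k]),
                    "v": float(s["v"][k]) if "v" in s else np.nan,
                }
                if "mu" in s:
                    row["mu"] = s["mu"][k]
                rows_cluster.append(row)
            if "patterns" in s:
                P = np.asarray(s["patterns"])
                for k in range(P.shape[0]):
                    for d in range(P.shape[1]):
                        rows_patterns.append(
                            {"iteration": t, "cluster": k, "interval": d, "value": P[k, d]}
                        )
            if s.get("pi_j") is not None:
                pi = np.asarray(s["pi_j"])
                for j in range(pi.shape[0]):
                    for k in range(pi.shape[1]):
                        rows_pi_j.append({"iteration": t, "group": j, "cluster": k, "pi": pi[j, k]})
            row = {"iteration": t}
            for key in _SCALAR_KEYS:
                if key in s:
                    row[key] = s[key]
            rows_scalar.append(row)
            for key in _GROUP_KEYS:
                if key in s:
                    for j, val in enumerate(np.asarray(s[key])):
                        rows_group.append({"iteration": t, "block": key, "index": j, "value": val})
            if "pi_r" in s:
                pi = np.asarray(s["pi_r"])
                for r in range(pi.shape[0]):
                    for k in range(pi.shape[1]):
                        rows_pi.append({"iteration": t, "race": r, "cluster": k, "pi": pi[r, k]})
            if "theta_k" in s:
                tk = np.asarray(s["theta_k"])
                for j in range(tk.shape[0]):
                    for k in range(tk.shape[1]):
                        rows_theta_k.append(
                            {"iteration": t, "group": j, "cluster": k, "theta": tk[j, k]}
                        )
            if "assignments" in s:
                rows_assign.append(
                    {"iteration": t, "assignments": " ".join(map(str, s["assignments"]))}
                )
        pd.DataFrame(rows_cluster).to_csv(path / "clusters.csv", index=False)
        pd.DataFrame(rows_scalar).to_csv(path / "scalars.csv", index=False)
        if rows_patterns:
            pd.DataFrame(rows_patterns).to_csv(path / "patterns.csv", index=False)
        if rows_pi_j:
            pd.DataFrame(rows_pi_j).to_csv(path / "group_weights.csv", index=False)
        if rows_group:
            pd.DataFrame(rows_group).to_csv(path / "group_effects.csv", index=False)
        if rows_pi:
            pd.DataFrame(rows_pi).to_csv(path / "race_weights.csv", index=False)
        if rows_theta_k:
            pd.DataFrame(rows_theta_k).to_csv(path / "cluster_shifts.csv", index=False)
        if rows_assign:
            pd.DataFrame(rows_assign).to_csv(path / "assignments.csv", index=False)
        with open(path / "manifest.json", "w") as fh:
            json.dump(_jsonable(self.manifest), fh, indent=2)

    @classmethod
    def from_dir(cls, path) -> "PosteriorArchive":
        path = Path(path)
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
        clusters = pd.read_csv(path / "clusters.csv")
        scalars = pd.read_csv(path / "scalars.csv")
        groups = None
        if (path / "group_effects.csv").exists():
            groups = pd.read_csv(path / "group_effects.csv")
        pis = pd.read_csv(path / "race_weights.csv") if (path / "race_weights.csv").exists() else None
        tks = (
            pd.read_csv(path / "cluster_shifts.csv")
            if (path / "cluster_shifts.csv").exists()
            else None
        )
        assigns = (
            pd.read_csv(path / "assignments.csv") if (path / "assignments.csv").exists() else None
        )
        patterns = pd.read_csv(path / "patterns.csv") if (path / "patterns.csv").exists() else None
        pi_js = (
            pd.read_csv(path / "group_weights.csv")
            if (path / "group_weights.csv").exists()
            else None
        )
        states = []
        for _, row in scalars.iterrows():
            t = int(row["iteration"])
            cl = clusters[clusters["iteration"] == t].sort_values("cluster")
            state = {
                "iteration": t,
                "weights": cl["weight"].to_numpy(),
                "counts": cl["count"].to_numpy(),
            }
            if "mu" in cl.columns and cl["mu"].notna().any():
                state["mu"] = cl["mu"].to_numpy()
            if cl["v"].notna().any():
                state["v"] = cl["v"].to_numpy()
            for key in _SCALAR_KEYS:
                if key in row.index and not pd.isna(row[key]):
                    state[key] = float(row[key]) if key != "n_clusters" else int(row[key])
            if groups is not None:
                g = groups[groups["iteration"] == t]
                for key in _GROUP_KEYS:
                    blk = g[g["block"] == key].sort_values("index")
                    if len(blk):
                        state[key] = blk["value"].to_numpy()
            if pis is not None:
                p = pis[pis["iteration"] == t]
                if len(p):
                    state["pi_r"] = (
                        p.pivot(index="race", columns="cluster", values="pi").to_numpy()
                    )
            if tks is not None:
                tk = tks[tks["iteration"] == t]
                if len(tk):
                    state["theta_k"] = (
                        tk.pivot(index="group", columns="cluster", values="theta").to_numpy()
                    )
            if patterns is not None:
                p = patterns[patterns["iteration"] == t]
                if len(p):
                    state["patterns"] = (
                        p.pivot(index="cluster", columns="interval", values="value").to_numpy()
                    )
            if pi_js is not None:
                p = pi_js[pi_js["iteration"] == t]
                if len(p):
                    state["pi_j"] = p.pivot(index="group", columns="cluster", values="pi").to_numpy()
            if assigns is not None:
                a = assigns[assigns["iteration"] == t]
                if len(a):
                    state["assignments"] = np.array(
                        a["assignments"].iloc[0].split(), dtype=np.intp
                    )
            states.append(state)
        return cls(states, manifest)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
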