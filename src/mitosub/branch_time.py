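"""Uncalibrated node-time estimation by identity-link Poisson regression.

Each branch's substitution count ``c_b`` is modeled as Poisson with mean
equal to the branch duration ``mu_b = t_parent - t_child`` (the rate is
normalized to one substitution per time unit, which fixes the otherwise
arbitrary time scale).  Tip times are fixed at 0 and internal node times
are found by maximizing the joint Poisson log-likelihood

    sum_b [ c_b * log(mu_b) - mu_b ]

subject to every branch duration being non-negative.  The problem is
concave in the node times with linear constraints; it is solved with SLSQP
from a feasible deterministic start (each node's time initialized to the
maximum cumulative substitution count on any path down to a tip).  A small
floor (1e-9) inside the logarithm handles zero-duration branches at the
boundary.  Times are in expected-substitution units and defined only up to
a global scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .phylo import PhyloTree

_EPS = 1e-9


@dataclass
class NodeTimes:
    """Estimated node times plus optimizer diagnostics."""

    times: dict[str, float]
    converged: bool
    log_likelihood: float

    def duration(self, parent_id: str, child_id: str) -> float:
        return self.times[parent_id] - self.times[child_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": list(self.times), "time": list(self.times.values())}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def estimate_node_times(
    tree: PhyloTree, counts: dict[str, int] | None = None
) -> NodeTimes:
    """Estimate uncalibrated node times from per-branch substitution counts.

    ``counts`` maps child-node id to the branch's total count; by default the
    length of each branch's substitution list is used.  Tips are fixed at
    time 0.
    """
    if counts is None:
        counts = {
            child.id: len(child.substitutions) for _, child in tree.branches()
        }
    branch_list = [(p.id, c.id) for p, c in tree.branches()]
    c = np.array([counts.get(child, 0) for _, child in branch_list], dtype=float)
    if np.any(c < 0):
        raise ValueError("branch substitution counts must be non-negative")

    free_nodes = [n.id for n in tree.nodes.values() if not n.is_tip]
    pos = {nid: i for i, nid in enumerate(free_nodes)}
    n_free = len(free_nodes)

    # init: max cumulative count on any path down to a tip (feasible by construction)
    init = {nid: 0.0 for nid in tree.nodes}
    for parent, child in reversed(list(tree.branches())):
        init[parent.id] = max(
            init[parent.id], init[child.id] + counts.get(child.id, 0)
        )
    x0 = np.array([init[nid] for nid in free_nodes], dtype=float)

    p_idx = np.array([pos.get(p, -1) for p, _ in branch_list])
    c_idx = np.array([pos.get(ch, -1) for _, ch in branch_list])

    def durations(x: np.ndarray) -> np.ndarray:
        tp = np.where(p_idx >= 0, x[np.clip(p_idx, 0, None)], 0.0)
        tc = np.where(c_idx >= 0, x[np.clip(c_idx, 0, None)], 0.0)
        return tp - tc

    def neg_ll(x: np.ndarray) -> float:
        mu = durations(x)
        return -float(np.sum(c * np.log(np.maximum(mu, _EPS)) - mu))

    def grad(x: np.ndarray) -> np.ndarray:
        mu = durations(x)
        d = c / np.maximum(mu, _EPS) - 1.0  # d(ll)/d(mu)
        g = np.zeros(n_free)
        np.add.at(g, p_idx[p_idx >= 0], -d[p_idx >= 0])
        np.add.at(g, c_idx[c_idx >= 0], d[c_idx >= 0])
        return g

    if n_free == 0:
        times = {nid: 0.0 for nid in tree.nodes}
        return NodeTimes(times, True, 0.0)

    res = minimize(
        neg_ll,
        x0,
        jac=grad,
        method="SLSQP",
        constraints=[
            {
                "type": "ineq",
                "fun": lambda x: durations(x),
                "jac": _duration_jac(p_idx, c_idx, n_free),
            }
        ],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    x = np.maximum(res.x, 0.0)
    times = {nid: 0.0 for nid in tree.nodes}
    for nid, i in pos.items():
        times[nid] = float(x[i])
    return NodeTimes(times, bool(res.success), -neg_ll(x))


def _duration_jac(p_idx: np.ndarray, c_idx: np.ndarray, n_free: int):
    n_b = len(p_idx)
    J = np.zeros((n_b, n_free))
    rows = np.arange(n_b)
    mask = p_idx >= 0
    J[rows[mask], p_idx[mask]] = 1.0
    mask = c_idx >= 0
    J[rows[mask], c_idx[mask]] += -1.0

    def jac(_x: np.ndarray) -> np.ndarray:
        return J

    return jac
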