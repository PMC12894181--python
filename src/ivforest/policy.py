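"""Exhaustive depth-limited policy-tree learning from doubly robust scores.

A policy pi maps a covariate profile to a treat / not-treat action; its
empirical value is

    A_n(pi) = (1/N) sum_i (2 pi(X_i) - 1) Gamma_i,

the average score among treated units minus the average among untreated
ones.  ``learn_tree`` maximises A_n exactly over all binary decision
trees of bounded depth on indicator covariates (thresholds fixed at 0.5),
by exhaustive recursion: at each node either stop with the best constant
action, or split on any covariate and solve both children optimally.
Depth-1 subproblems are vectorised over covariates; ties break
lexicographically (stop before split, lowest covariate index first,
not-treat before treat), so the search is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .drscores import DRScores

__all__ = ["PolicyTree", "PolicyValue", "learn_tree", "policy_value", "apply_policy"]


@dataclass
class PolicyTree:
    """A depth-limited treat/not-treat decision tree.

    ``root`` is a nested record: internal nodes
    ``{"variable": name, "threshold": 0.5, "left": ..., "right": ...}``
    (left branch taken when ``x <= threshold``) and leaves
    ``{"action": 0 | 1}``.
    """

    root: dict
    depth: int
    feature_names: list[str]
    nodes_opened: int = 0  # subproblems evaluated during the search

    def to_dict(self) -> dict:
        return {"depth": self.depth, "feature_names": self.feature_names,
                "root": self.root}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PolicyTree":
        d = json.loads(Path(path).read_text())
        return cls(root=d["root"], depth=d["depth"], feature_names=d["feature_names"])

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: dict, indent: int) -> None:
            pad = "  " * indent
            if "action" in node:
                lines.append(f"{pad}-> {'treat' if node['action'] else 'not-treat'}")
            else:
                lines.append(f"{pad}{node['variable']} <= {node['threshold']}?")
                walk(node["left"], indent + 1)
                walk(node["right"], indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


@dataclass(frozen=True)
class PolicyValue:
    value: float
    treat_all: float
    treat_none: float

    @property
    def advantage(self) -> float:
        """Gain over the best constant (treat-all / treat-none) policy."""
        return self.value - max(self.treat_all, self.treat_none)


def _as_gamma(gamma) -> np.ndarray:
    return gamma.gamma if isinstance(gamma, DRScores) else np.asarray(gamma, dtype=float)


def _check_binary_x(x: pd.DataFrame) -> np.ndarray:
    mat = x.to_numpy(dtype=float)
    if not np.all((mat == 0.0) | (mat == 1.0)):
        bad = [c for c in x.columns if not np.all(np.isin(x[c].to_numpy(), (0, 1)))]
        raise ValueError(
            f"policy trees require binary indicator covariates; encode "
            f"{bad} with tercile_encode first"
        )
    return mat


def _leaf(total: float) -> tuple[float, dict]:
    # action order: not-treat first, so an exact zero sum -> not-treat
    if total > 0:
        return total, {"action": 1}
    return -total, {"action": 0}


def learn_tree(x: pd.DataFrame, gamma, depth: int = 2) -> PolicyTree:
    """Exact exhaustive search for the value-maximising depth-``depth`` tree."""
    if depth not in (1, 2, 3):
        raise ValueError("depth must be 1, 2 or 3")
    g = _as_gamma(gamma)
    mat = _check_binary_x(x)
    if len(g) != mat.shape[0]:
        raise ValueError("gamma and x must be aligned")
    names = list(x.columns)
    counter = {"opened": 0}

    def solve(idx: np.ndarray, d: int) -> tuple[float, dict]:
        counter["opened"] += 1
        sub = g[idx]
        total = float(sub.sum())
        best_val, best_node = _leaf(total)
        if d == 0 or len(idx) == 0:
            return best_val, best_node
        xm = mat[idx]
        if d == 1:
            # vectorised over covariates: split value = |sum left| + |sum right|
            s1 = sub @ xm
            c1 = xm.sum(axis=0)
            nontrivial = (c1 > 0) & (c1 < len(idx))
            vals = np.abs(total - s1) + np.abs(s1)
            vals = np.where(nontrivial, vals, -np.inf)
            j = int(np.argmax(vals))
            if np.isfinite(vals[j]) and vals[j] > best_val:
                left_sum = total - s1[j]
                lv, ln = _leaf(left_sum)
                rv, rn = _leaf(float(s1[j]))
                return float(vals[j]), {
                    "variable": names[j], "threshold": 0.5, "left": ln, "right": rn,
                }
            return best_val, best_node
        for j in range(mat.shape[1]):
            col = xm[:, j]
            right_mask = col == 1.0
            if not right_mask.any() or right_mask.all():
                continue  # constant on this subset: covered by the leaf case
            lv, ln = solve(idx[~right_mask], d - 1)
            rv, rn = solve(idx[right_mask], d - 1)
            if lv + rv > best_val:
                best_val = lv + rv
                best_node = {"variable": names[j], "threshold": 0.5,
                             "left": ln, "right": rn}
        return best_val, best_node

    _, root = solve(np.arange(len(g)), depth)
    return PolicyTree(root=root, depth=depth, feature_names=names,
                      nodes_opened=counter["opened"])


def apply_policy(tree: PolicyTree, x: pd.DataFrame) -> np.ndarray:
    """Deterministic routing of every unit to its assigned action."""
    missing = [c for c in tree.feature_names if c not in x.columns]
    if missing:
        raise ValueError(f"profiles lack covariates used by the tree: {missing}")
    n = len(x)
    actions = np.zeros(n, dtype=np.int8)
    idx = np.arange(n)

    def walk(node: dict, rows: np.ndarray) -> None:
        if "action" in node:
            actions[rows] = node["action"]
            return
        v = x[node["variable"]].to_numpy(dtype=float)[rows]
        go_left = v <= node["threshold"]
        walk(node["left"], rows[go_left])
        walk(node["right"], rows[~go_left])

    walk(tree.root, idx)
    return actions


def policy_value(tree: PolicyTree, x: pd.DataFrame, gamma) -> PolicyValue:
    """Plug-in value of a tree plus the constant-policy baselines."""
    g = _as_gamma(gamma)
    pi = apply_policy(tree, x)
    mean_g = float(g.mean())
    return PolicyValue(
        value=float(np.mean((2.0 * pi - 1.0) * g)),
        treat_all=mean_g,
        treat_none=-mean_g,
    )
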