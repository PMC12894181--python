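"""Honest, subsampled tree ensembles with out-of-bag prediction.

This is the shared chassis for the nuisance regression forests and the
instrumental forest.  Each tree is grown on a subsample drawn *without*
replacement; under honesty the subsample is split into a *structure* half
that places the splits and an *estimation* half that supplies the leaf
statistics, so no unit influences both where a split falls and what the
leaf estimates.  Predictions for training units are out-of-bag (OOB):
only trees whose subsample excluded the unit contribute.

Similarity weights: a forest induces, for any covariate profile ``x``,
weights over the training units,

    alpha_i(x) = (1/B) sum_b  1{i in L_b(x), estimation half} / |L_b(x)|,

the average co-leaf-membership frequency normalised by leaf size.  They
are non-negative and sum to one, and turn the ensemble into an adaptive
kernel: downstream estimators solve locally weighted moment equations
with these weights.

The split criterion is expressed through per-unit *scores* rho supplied
by the caller for each node: a split maximises

    (sum_{left} rho)^2 / n_left + (sum_{right} rho)^2 / n_right,

which for rho equal to the regression target is the classical CART
variance-reduction rule, and for the instrumental pseudo-outcomes (see
``ivforest.instrumental``) targets heterogeneity in the local IV effect.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

__all__ = ["ForestParams", "HonestTree", "Forest", "fit_regression_forest", "predict_oob", "forest_weights"]

_EPS_DEGENERATE = 1e-10


@dataclass(frozen=True)
class ForestParams:
    """Hyperparameters of an honest forest.

    num_trees : ensemble size (2000 in the full analysis profile).
    mtry : covariates tried per split; default min(p, ceil(sqrt(p)) + 20).
    sample_fraction : subsample share per tree, in (0, 1]; at 1.0 no
        out-of-bag trees exist and OOB prediction raises.
    honesty / honesty_fraction : whether to split each subsample into a
        structure half (places splits) and an estimation half (supplies
        leaf statistics), and the structure share.
    alpha : minimum child share of its parent, in (0, 0.25].
    min_node_size : minimum units per child (structure half).
    seed : drives all subsampling and split-candidate draws.
    """

    num_trees: int = 2000
    mtry: int | None = None
    sample_fraction: float = 0.5
    honesty: bool = True
    honesty_fraction: float = 0.5
    alpha: float = 0.05
    min_node_size: int = 5
    seed: int = 0
    feature_subset: tuple[int, ...] | None = None  # indices eligible for splits

    def __post_init__(self) -> None:
        if self.num_trees < 1:
            raise ValueError("num_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if not (0.0 < self.sample_fraction <= 1.0):
            raise ValueError("sample_fraction must lie in (0, 1]")
        if not (0.0 < self.honesty_fraction < 1.0):
            raise ValueError("honesty_fraction must lie in (0, 1)")
        if not (0.0 < self.alpha <= 0.25):
            raise ValueError("alpha must lie in (0, 0.25]")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is not None:
            return min(self.mtry, p)
        return min(p, math.ceil(math.sqrt(p)) + 20)


@dataclass
class HonestTree:
    """A single honest tree: split structure plus estimation-half membership.

    ``feature[k] == -1`` marks node ``k`` as a leaf.  ``est_idx`` holds the
    global indices of the estimation-half units and ``est_leaf`` the leaf
    node each of them fell into; leaf statistics are always computed from
    these, never from the structure half.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    node_depth: np.ndarray
    subsample: np.ndarray  # sorted global indices in this tree's subsample
    struct_idx: np.ndarray
    est_idx: np.ndarray
    est_leaf: np.ndarray

    def route(self, x: np.ndarray) -> np.ndarray:
        """Vectorised routing: leaf node id for every row of ``x``."""
        n = x.shape[0]
        node = np.zeros(n, dtype=np.int64)
        while True:
            f = self.feature[node]
            active = f >= 0
            if not active.any():
                return node
            rows = np.nonzero(active)[0]
            nd = node[rows]
            vals = x[rows, self.feature[nd]]
            go_left = vals <= self.threshold[nd]
            node[rows] = np.where(go_left, self.left[nd], self.right[nd])

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "node_depth": self.node_depth.tolist(),
            "subsample": self.subsample.tolist(),
            "struct_idx": self.struct_idx.tolist(),
            "est_idx": self.est_idx.tolist(),
            "est_leaf": self.est_leaf.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HonestTree":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=np.int64),
            right=np.asarray(d["right"], dtype=np.int64),
            node_depth=np.asarray(d["node_depth"], dtype=np.int64),
            subsample=np.asarray(d["subsample"], dtype=np.int64),
            struct_idx=np.asarray(d["struct_idx"], dtype=np.int64),
            est_idx=np.asarray(d["est_idx"], dtype=np.int64),
            est_leaf=np.asarray(d["est_leaf"], dtype=np.int64),
        )


def _best_split(x_node: np.ndarray, rho: np.ndarray, feats: np.ndarray,
                is_binary: np.ndarray, min_child: int):
    """Best (criterion, feature, threshold) at a node, or None.

    Ties broken toward the lowest covariate index, then lowest threshold.
    ``feats`` must be sorted ascending.
    """
    m = len(rho)
    total = rho.sum()
    candidates: list[tuple[float, int, float]] = []

    bin_pos = is_binary[feats]
    if bin_pos.any():
        bf = feats[bin_pos]
        xb = x_node[:, bin_pos]
        right_sum = rho @ xb
        right_cnt = xb.sum(axis=0)
        left_cnt = m - right_cnt
        valid = (right_cnt >= min_child) & (left_cnt >= min_child)
        if valid.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                crit = (total - right_sum) ** 2 / left_cnt + right_sum ** 2 / right_cnt
            crit = np.where(valid, crit, -np.inf)
            k = int(np.argmax(crit))  # first max -> lowest feature index
            if np.isfinite(crit[k]):
                candidates.append((float(crit[k]), int(bf[k]), 0.5))

    for j in np.nonzero(~bin_pos)[0]:
        xv = x_node[:, j]
        order = np.argsort(xv, kind="stable")
        xs = xv[order]
        rs = np.cumsum(rho[order])
        # candidate cuts between distinct consecutive values
        distinct = xs[:-1] < xs[1:]
        pos = np.nonzero(distinct)[0]  # left child = units [0..pos]
        if len(pos) == 0:
            continue
        nl = pos + 1
        nr = m - nl
        ok = (nl >= min_child) & (nr >= min_child)
        if not ok.any():
            continue
        sl = rs[pos]
        with np.errstate(divide="ignore", invalid="ignore"):
            crit = sl ** 2 / nl + (total - sl) ** 2 / nr
        crit = np.where(ok, crit, -np.inf)
        k = int(np.argmax(crit))  # first max -> lowest threshold
        if np.isfinite(crit[k]):
            thr = 0.5 * (xs[k] + xs[k + 1])
            candidates.append((float(crit[k]), int(feats[j]), float(thr)))

    if not candidates:
        return None
    # max criterion; ties -> lowest feature index, then lowest threshold
    return max(candidates, key=lambda c: (c[0], -c[1], -c[2]))


def _grow_tree(x: np.ndarray, struct_idx: np.ndarray, score_fn, params: ForestParams,
               mtry: int, is_binary: np.ndarray, rng: np.random.Generator,
               pool: np.ndarray | None = None):
    """Grow split structure on the structure half.

    ``score_fn(idx)`` returns per-unit scores rho for the units ``idx`` or
    None when the node's local problem is degenerate (node becomes a leaf).
    """
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    depth: list[int] = []
    if pool is None:
        pool = np.arange(x.shape[1])

    def new_node(d: int) -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        depth.append(d)
        return len(feature) - 1

    root = new_node(0)
    stack = [(root, struct_idx)]
    while stack:
        node_id, idx = stack.pop()
        m = len(idx)
        min_child = max(params.min_node_size, int(math.ceil(params.alpha * m)))
        if m < 2 * min_child:
            continue
        rho = score_fn(idx)
        if rho is None:
            continue
        feats = np.sort(rng.choice(pool, size=mtry, replace=False))
        found = _best_split(x[idx][:, feats], rho, feats, is_binary, min_child)
        if found is None:
            continue
        _, f, thr = found
        go_left = x[idx, f] <= thr
        feature[node_id] = f
        threshold[node_id] = thr
        lid = new_node(depth[node_id] + 1)
        rid = new_node(depth[node_id] + 1)
        left[node_id] = lid
        right[node_id] = rid
        stack.append((lid, idx[go_left]))
        stack.append((rid, idx[~go_left]))

    return (
        np.asarray(feature, dtype=np.int64),
        np.asarray(threshold, dtype=float),
        np.asarray(left, dtype=np.int64),
        np.asarray(right, dtype=np.int64),
        np.asarray(depth, dtype=np.int64),
    )


@dataclass
class Forest:
    """An ensemble of honest trees over a fixed training matrix.

    For a regression forest ``leaf_values[b][k]`` is the estimation-half
    mean of the target in node ``k`` of tree ``b`` (NaN for empty leaves).
    """

    trees: list[HonestTree]
    params: ForestParams
    feature_names: list[str]
    x_train: np.ndarray
    target: np.ndarray | None = None
    leaf_values: list[np.ndarray] | None = None
    is_binary: np.ndarray | None = None

    @property
    def n_train(self) -> int:
        return self.x_train.shape[0]

    # -- membership -------------------------------------------------------
    def in_subsample(self) -> np.ndarray:
        """Boolean matrix (num_trees, n_train): unit in tree's subsample."""
        out = np.zeros((len(self.trees), self.n_train), dtype=bool)
        for b, t in enumerate(self.trees):
            out[b, t.subsample] = True
        return out

    def refit_leaves(self, target: np.ndarray) -> None:
        """Recompute leaf values from the estimation halves only.

        Honesty makes this a pure function of the estimation-half targets:
        structure-half target values never enter a leaf estimate.
        """
        target = np.asarray(target, dtype=float)
        values = []
        for t in self.trees:
            v = np.full(t.n_nodes, np.nan)
            cnt = np.bincount(t.est_leaf, minlength=t.n_nodes)
            s = np.bincount(t.est_leaf, weights=target[t.est_idx], minlength=t.n_nodes)
            nz = cnt > 0
            v[nz] = s[nz] / cnt[nz]
            values.append(v)
        self.leaf_values = values
        self.target = target

    # -- prediction -------------------------------------------------------
    def predict(self, x: np.ndarray) -> np.ndarray:
        """In-sample prediction at arbitrary profiles (all trees used)."""
        x = np.asarray(x, dtype=float)
        acc = np.zeros(x.shape[0])
        cnt = np.zeros(x.shape[0])
        for t, v in zip(self.trees, self.leaf_values):
            leaf = t.route(x)
            val = v[leaf]
            good = np.isfinite(val)
            acc[good] += val[good]
            cnt[good] += 1
        if (cnt == 0).any():
            warnings.warn("some profiles reached only empty leaves", UserWarning, stacklevel=2)
        with np.errstate(invalid="ignore"):
            return acc / cnt

    def predict_oob(self) -> np.ndarray:
        """OOB prediction for every training unit.

        Uses only trees whose subsample excluded the unit; units covered by
        no OOB tree come back NaN (and a warning is raised).
        """
        if self.params.sample_fraction >= 1.0:
            raise ValueError(
                "sample_fraction = 1 leaves no out-of-bag trees; "
                "use predict() for in-sample estimates"
            )
        n = self.n_train
        acc = np.zeros(n)
        cnt = np.zeros(n)
        for t, v in zip(self.trees, self.leaf_values):
            leaf = t.route(self.x_train)
            val = v[leaf]
            oob = np.ones(n, dtype=bool)
            oob[t.subsample] = False
            good = oob & np.isfinite(val)
            acc[good] += val[good]
            cnt[good] += 1
        missing = cnt == 0
        if missing.any():
            warnings.warn(
                f"{int(missing.sum())} unit(s) appear in every subsample; "
                "their OOB prediction is NaN",
                UserWarning,
                stacklevel=2,
            )
        with np.errstate(invalid="ignore"):
            return np.where(missing, np.nan, acc / np.maximum(cnt, 1))

    def weights(self, x: np.ndarray) -> np.ndarray:
        """Similarity weights alpha_i(x) over training units for one profile."""
        x = np.asarray(x, dtype=float).reshape(1, -1)
        w = np.zeros(self.n_train)
        used = 0
        for t in self.trees:
            leaf = int(t.route(x)[0])
            members = t.est_idx[t.est_leaf == leaf]
            if len(members) == 0:
                continue  # empty estimation leaf: tree skipped for this x
            w[members] += 1.0 / len(members)
            used += 1
        if used == 0:
            raise ValueError("every tree had an empty leaf at this profile")
        return w / used

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "feature_names": list(self.feature_names),
            "x_train": self.x_train.tolist(),
            "target": None if self.target is None else self.target.tolist(),
            "leaf_values": None
            if self.leaf_values is None
            else [v.tolist() for v in self.leaf_values],
            "trees": [t.to_dict() for t in self.trees],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "Forest":
        f = cls(
            trees=[HonestTree.from_dict(t) for t in d["trees"]],
            params=ForestParams(**d["params"]),
            feature_names=list(d["feature_names"]),
            x_train=np.asarray(d["x_train"], dtype=float),
            target=None if d["target"] is None else np.asarray(d["target"], dtype=float),
            leaf_values=None
            if d["leaf_values"] is None
            else [np.asarray(v, dtype=float) for v in d["leaf_values"]],
        )
        f.is_binary = _binary_columns(f.x_train)
        return f

    @classmethod
    def load(cls, path: str | Path) -> "Forest":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _binary_columns(x: np.ndarray) -> np.ndarray:
    out = np.zeros(x.shape[1], dtype=bool)
    for j in range(x.shape[1]):
        col = x[:, j]
        out[j] = np.all((col == 0.0) | (col == 1.0))
    return out


def _draw_halves(n: int, params: ForestParams, rng: np.random.Generator):
    """Subsample without replacement and split into structure/estimation."""
    s = max(2, int(round(params.sample_fraction * n)))
    s = min(s, n)
    sub = rng.choice(n, size=s, replace=False)
    if params.honesty:
        n_struct = max(1, int(round(params.honesty_fraction * s)))
        n_struct = min(n_struct, s - 1)
        struct = sub[:n_struct]
        est = sub[n_struct:]
    else:
        struct = sub
        est = sub
    return np.sort(sub), struct, est


def grow_forest(x: np.ndarray, params: ForestParams, score_factory) -> list[HonestTree]:
    """Grow the split structures of a forest.

    ``score_factory(struct_idx)`` returns the node-score function used for
    one tree (so callers can precompute per-tree quantities).
    """
    n, p = x.shape
    pool = np.arange(p) if params.feature_subset is None else np.asarray(
        params.feature_subset, dtype=np.int64)
    if len(pool) == 0 or pool.min() < 0 or pool.max() >= p:
        raise ValueError("feature_subset must index existing covariates")
    mtry = min(params.resolve_mtry(p), len(pool))
    is_binary = _binary_columns(x)
    seeds = np.random.SeedSequence(params.seed).spawn(params.num_trees)
    trees = []
    for b in range(params.num_trees):
        rng = np.random.default_rng(seeds[b])
        sub, struct, est = _draw_halves(n, params, rng)
        score_fn = score_factory(struct)
        feat, thr, lft, rgt, dep = _grow_tree(
            x, struct, score_fn, params, mtry, is_binary, rng, pool)
        tree = HonestTree(
            feature=feat, threshold=thr, left=lft, right=rgt, node_depth=dep,
            subsample=sub, struct_idx=struct, est_idx=est,
            est_leaf=np.empty(0, dtype=np.int64),
        )
        tree.est_leaf = tree.route(x[est])
        trees.append(tree)
    return trees


def fit_regression_forest(x, t, params: ForestParams | None = None,
                          feature_names: list[str] | None = None) -> Forest:
    """Fit an honest regression forest of E[t | x].

    Splits minimise within-child variance of ``t`` on the structure half;
    leaf values are estimation-half means.  Deterministic given
    ``params.seed``.
    """
    x = np.ascontiguousarray(np.asarray(x, dtype=float))
    t = np.asarray(t, dtype=float)
    if x.ndim != 2 or len(t) != x.shape[0]:
        raise ValueError("x must be 2-D with one target value per row")
    if np.isnan(x).any() or np.isnan(t).any():
        raise ValueError("missing values are not supported")
    params = params or ForestParams()
    if x.shape[0] < 2:
        raise ValueError("need at least two training units")
    if t.min() == t.max():
        warnings.warn("constant target: every tree is a single leaf", UserWarning, stacklevel=2)

    def score_factory(struct_idx):
        def score_fn(idx):
            return t[idx]
        return score_fn

    trees = grow_forest(x, params, score_factory)
    f = Forest(
        trees=trees, params=params,
        feature_names=feature_names or [f"x{j}" for j in range(x.shape[1])],
        x_train=x,
    )
    f.is_binary = _binary_columns(x)
    f.refit_leaves(t)
    return f


def predict_oob(forest: Forest) -> np.ndarray:
    """Out-of-bag predictions for the training units (module-level alias)."""
    return forest.predict_oob()


def forest_weights(forest: Forest, x: np.ndarray) -> np.ndarray:
    """Similarity weights alpha_i(x) for one profile (module-level alias)."""
    return forest.weights(x)
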