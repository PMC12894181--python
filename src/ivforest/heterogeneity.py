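"""Heterogeneity summaries computed from the doubly robust scores.

Three complementary views of how the complier effect varies with
covariates:

* **BLP** — the best linear predictor: OLS of Gamma_i on X_i.  The
  coefficients are partial linear associations with the effect surface,
  never causal effects of the covariates themselves.
* **CLAN** — classification analysis: units are ranked into quartiles of
  Gamma_i, and for each effect modifier the mean in the most-affected
  quartile is compared with the mean in the least-affected quartile,
  one modifier at a time.
* **Variable importance** — depth-weighted split frequencies from the
  fitted instrumental forest; only the relative ranking is meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

import statsmodels.api as sm
from scipy import stats as sps

from .drscores import DRScores
from .instrumental import IVForestModel

__all__ = ["BLPResult", "CLANResult", "VIRanking", "blp", "clan", "variable_importance"]


@dataclass
class BLPResult:
    table: pd.DataFrame  # coef, se, ci_low, ci_high, pvalue per term
    dropped_references: list[str]
    robust: bool

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "coef"])


@dataclass
class CLANResult:
    table: pd.DataFrame  # mean_most, mean_least, diff, se, ci_low, ci_high, pvalue
    n_most: int
    n_least: int
    rank_by: str


@dataclass
class VIRanking:
    table: pd.DataFrame  # importance (sums to 1), rank
    mode: str

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.head(k)


def blp(gamma: DRScores | np.ndarray, x: pd.DataFrame,
        drop_references: list[str] | None = None, robust: bool = True) -> BLPResult:
    """OLS of the doubly robust scores on the covariates.

    ``drop_references`` removes one reference indicator per tercile family
    (or any other redundant level) before fitting; sandwich (HC1) standard
    errors by default, classical with ``robust=False``.
    """
    g = gamma.gamma if isinstance(gamma, DRScores) else np.asarray(gamma, dtype=float)
    drop_references = drop_references or []
    missing = [c for c in drop_references if c not in x.columns]
    if missing:
        raise ValueError(f"reference columns not present: {missing}")
    design = x.drop(columns=drop_references)
    mat = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    names = ["const", *design.columns]
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        offenders = [
            names[j - 1]
            for j in range(1, mat.shape[1] + 1)
            if np.linalg.matrix_rank(mat[:, :j]) < j
        ]
        raise ValueError(
            f"collinear design; drop or re-reference columns: {offenders}"
        )
    fit = sm.OLS(g, mat).fit(cov_type="HC1" if robust else "nonrobust")
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "ci_low": fit.params - 1.96 * fit.bse,
            "ci_high": fit.params + 1.96 * fit.bse,
            "pvalue": fit.pvalues,
        },
        index=pd.Index(names, name="term"),
    )
    return BLPResult(table=table, dropped_references=list(drop_references), robust=robust)


def clan(gamma: DRScores | np.ndarray, x: pd.DataFrame, n_groups: int = 4,
         rank_by: np.ndarray | None = None) -> CLANResult:
    """Most- vs least-affected group comparison for each modifier.

    Units are ranked by Gamma (stable sort, so ties keep input order) and
    cut into ``n_groups`` near-equal groups; ``rank_by`` substitutes an
    alternative ranking variable (e.g. the CLATEs) for sensitivity checks.
    """
    g = gamma.gamma if isinstance(gamma, DRScores) else np.asarray(gamma, dtype=float)
    n = len(g)
    if n < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} units for {n_groups} groups")
    key = g if rank_by is None else np.asarray(rank_by, dtype=float)
    order = np.argsort(key, kind="stable")
    chunks = np.array_split(order, n_groups)
    least, most = chunks[0], chunks[-1]
    rows = []
    for name in x.columns:
        v = x[name].to_numpy(dtype=float)
        vm, vl = v[most], v[least]
        diff = vm.mean() - vl.mean()
        var_m = vm.var(ddof=1) if len(vm) > 1 else 0.0
        var_l = vl.var(ddof=1) if len(vl) > 1 else 0.0
        se = np.sqrt(var_m / len(vm) + var_l / len(vl))
        degenerate = se == 0.0
        if degenerate:
            pvalue = np.nan
        else:
            pvalue = 2.0 * sps.norm.sf(abs(diff) / se)
        rows.append(
            {"modifier": name, "mean_most": vm.mean(), "mean_least": vl.mean(),
             "diff": diff, "se": se, "ci_low": diff - 1.96 * se,
             "ci_high": diff + 1.96 * se, "pvalue": pvalue,
             "degenerate_se": degenerate}
        )
    return CLANResult(
        table=pd.DataFrame(rows).set_index("modifier"),
        n_most=len(most), n_least=len(least),
        rank_by="gamma" if rank_by is None else "custom",
    )


def variable_importance(model: IVForestModel, max_depth: int = 4,
                        decay: float = 2.0, mode: str = "frequency") -> VIRanking:
    """Depth-weighted split importance of each covariate.

    ``frequency`` (default): importance_k = sum_{d<=max_depth}
    [share of depth-d splits using k] * d^(-decay), normalised to sum 1.
    ``variance`` weights each split by the between-child spread of the
    estimation-half effect estimates instead of counting it once.
    Only the ranking carries meaning; the numeric scale does not.
    """
    if not model.trees:
        raise ValueError("empty forest")
    p = len(model.feature_names)
    weights = np.zeros((p, max_depth))
    if mode == "frequency":
        counts = model.split_counts(max_depth=max_depth).to_numpy(dtype=float)
        weights = counts
    elif mode == "variance":
        from .instrumental import _node_tau
        for tree, stats in zip(model.trees, model.node_stats):
            parent = np.full(tree.n_nodes, -1, dtype=np.int64)
            for k in range(tree.n_nodes):
                if tree.feature[k] >= 0:
                    parent[tree.left[k]] = k
                    parent[tree.right[k]] = k
            tau, _ = _node_tau(stats, parent, model.global_wald)
            cnt = stats["cnt"]
            for k in range(tree.n_nodes):
                f = tree.feature[k]
                d = tree.node_depth[k] + 1
                if f < 0 or d > max_depth:
                    continue
                l, r = tree.left[k], tree.right[k]
                spread = cnt[l] * (tau[l] - tau[k]) ** 2 + cnt[r] * (tau[r] - tau[k]) ** 2
                if np.isfinite(spread):
                    weights[f, d - 1] += spread
    else:
        raise ValueError("mode must be 'frequency' or 'variance'")
    col_tot = weights.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(col_tot > 0, weights / col_tot, 0.0)
    depth_w = np.arange(1, max_depth + 1, dtype=float) ** (-decay)
    raw = share @ depth_w
    total = raw.sum()
    importance = raw / total if total > 0 else raw
    table = pd.DataFrame(
        {"importance": importance},
        index=pd.Index(model.feature_names, name="covariate"),
    ).sort_values("importance", ascending=False, kind="stable")
    table["rank"] = np.arange(1, p + 1)
    return VIRanking(table=table, mode=mode)
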