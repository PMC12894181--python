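"""The instrumental causal forest.

Under a binary instrument Z that is (conditionally) randomised, affects
the outcome only through the received treatment D, and shifts D
monotonically, the conditional local average treatment effect (CLATE)

    tau(x) = Cov[Y, Z | X = x] / Cov[D, Z | X = x]

is the conditional Wald ratio: the intention-to-treat effect at x over
the complier share at x.  The forest estimates tau(x) by local two-stage
least squares on *residualised* data — Y - m(x), D - e(x), Z - g(x),
where m, e, g are out-of-bag regression-forest fits of the conditional
outcome mean, treatment propensity, and instrument propensity — inside
adaptive neighbourhoods defined by honest trees.

Trees are grown to maximise heterogeneity of the local effect: at each
parent with Wald estimate tau_P and A_P = mean(Zr * Dr), the per-unit
pseudo-outcome

    rho_i = Zr_i * (Yr_i - tau_P * Dr_i) / A_P

is the influence-function surrogate for d tau / d (unit i), and the
split maximises sum_children (sum_{i in child} rho_i)^2 / n_child.
Predictions solve the alpha-weighted moment condition, i.e. the
similarity-weighted covariance ratio, with out-of-bag weights for
training units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forest import Forest, ForestParams, HonestTree, _binary_columns, fit_regression_forest, grow_forest
from .strata import TrialDataset

__all__ = [
    "NuisanceEstimates",
    "IVForestModel",
    "CLATEs",
    "TuneResult",
    "estimate_nuisances",
    "residualise",
    "leaf_wald",
    "fit_iv_forest",
    "predict_clate",
    "tune",
]

_DEGENERATE = 1e-10
_PROP_CLIP = (0.01, 0.99)


@dataclass
class NuisanceEstimates:
    """Out-of-bag nuisance fits m̂(x) = E[Y|X], ê(x) = P(D=1|X), ĝ(x) = P(Z=1|X).

    Propensities are clipped to [0.01, 0.99]; the number of clipped units
    is recorded.  ``e_features`` documents which covariates the treatment
    propensity forest was allowed to split on (supply-side columns are
    excluded by default because supply-side readiness entered eligibility).
    """

    m_hat: np.ndarray
    e_hat: np.ndarray
    g_hat: np.ndarray
    m_features: list[str]
    e_features: list[str]
    g_features: list[str]
    n_clipped_e: int = 0
    n_clipped_g: int = 0
    forests: dict = field(default_factory=dict)


def _oob_or_insample(f: Forest) -> np.ndarray:
    """OOB predictions, falling back to in-sample where OOB is unavailable."""
    if f.params.sample_fraction >= 1.0:
        return f.predict(f.x_train)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = f.predict_oob()
    bad = ~np.isfinite(pred)
    if bad.any():
        pred[bad] = f.predict(f.x_train[bad])
    return pred


def estimate_nuisances(ds: TrialDataset, params: ForestParams | None = None,
                       exclude_supply_from_e: bool = True) -> NuisanceEstimates:
    """Fit the three nuisance regression forests with OOB prediction."""
    params = params or ForestParams()
    all_cols = ds.covariate_names
    if exclude_supply_from_e:
        if not ds.supply_tags:
            raise ValueError(
                "exclude_supply_from_e=True requires supply-tagged columns on "
                "the dataset; tag them or pass exclude_supply_from_e=False"
            )
        e_cols = [c for c in all_cols if c not in ds.supply_tags]
    else:
        e_cols = all_cols
    x_all = ds.x.to_numpy(dtype=float)
    x_e = ds.x[e_cols].to_numpy(dtype=float)
    seeds = np.random.SeedSequence(params.seed).spawn(3)

    def sub(seed_seq):
        return replace(params, seed=int(seed_seq.generate_state(1)[0] % (2**31)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        f_m = fit_regression_forest(x_all, ds.y, sub(seeds[0]), all_cols)
        f_e = fit_regression_forest(x_e, ds.d, sub(seeds[1]), e_cols)
        f_g = fit_regression_forest(x_all, ds.z, sub(seeds[2]), all_cols)

    m_hat = _oob_or_insample(f_m)
    e_raw = _oob_or_insample(f_e)
    g_raw = _oob_or_insample(f_g)
    e_hat = np.clip(e_raw, *_PROP_CLIP)
    g_hat = np.clip(g_raw, *_PROP_CLIP)
    return NuisanceEstimates(
        m_hat=m_hat, e_hat=e_hat, g_hat=g_hat,
        m_features=all_cols, e_features=e_cols, g_features=all_cols,
        n_clipped_e=int((e_raw != e_hat).sum()),
        n_clipped_g=int((g_raw != g_hat).sum()),
        forests={"m": f_m, "e": f_e, "g": f_g},
    )


def residualise(ds: TrialDataset, nu: NuisanceEstimates):
    """Centred triples (Yr, Dr, Zr) = (Y - m̂, D - ê, Z - ĝ)."""
    if not (len(nu.m_hat) == len(nu.e_hat) == len(nu.g_hat) == ds.n):
        raise ValueError("nuisance estimates do not match the dataset length")
    return ds.y - nu.m_hat, ds.d - nu.e_hat, ds.z - nu.g_hat


def leaf_wald(yr: np.ndarray, dr: np.ndarray, zr: np.ndarray) -> float:
    """Sample-covariance Wald ratio Cov(Yr, Zr) / Cov(Dr, Zr).

    Returns NaN (the degenerate marker) when the first-stage covariance is
    below 1e-10 in magnitude; callers inherit the parent estimate.
    """
    yr = np.asarray(yr, dtype=float)
    dr = np.asarray(dr, dtype=float)
    zr = np.asarray(zr, dtype=float)
    if not (len(yr) == len(dr) == len(zr)):
        raise ValueError("residual vectors must have equal length")
    if len(yr) < 2:
        raise ValueError("need at least two units")
    zc = zr - zr.mean()
    cov_dz = float(np.mean(dr * zc))
    if abs(cov_dz) < _DEGENERATE:
        return float("nan")
    return float(np.mean(yr * zc)) / cov_dz


@dataclass
class IVForestModel:
    """A fitted instrumental forest plus the residual triples it was grown on."""

    trees: list[HonestTree]
    params: ForestParams
    feature_names: list[str]
    x_train: np.ndarray
    yr: np.ndarray
    dr: np.ndarray
    zr: np.ndarray
    global_wald: float
    # per-tree node-level estimation-half statistics
    node_stats: list[dict] = field(default_factory=list)

    @property
    def n_train(self) -> int:
        return self.x_train.shape[0]

    def split_counts(self, max_depth: int | None = None) -> pd.DataFrame:
        """Split counts per covariate per depth (root depth = 1)."""
        depths = []
        feats = []
        for t in self.trees:
            internal = t.feature >= 0
            feats.append(t.feature[internal])
            depths.append(t.node_depth[internal] + 1)
        feats = np.concatenate(feats) if feats else np.empty(0, dtype=int)
        depths = np.concatenate(depths) if depths else np.empty(0, dtype=int)
        dmax = max_depth or (int(depths.max()) if len(depths) else 1)
        table = np.zeros((len(self.feature_names), dmax), dtype=np.int64)
        for f, d in zip(feats, depths):
            if d <= dmax:
                table[f, d - 1] += 1
        return pd.DataFrame(
            table, index=self.feature_names,
            columns=[f"depth_{d}" for d in range(1, dmax + 1)],
        )


@dataclass
class CLATEs:
    """Per-unit CLATE predictions with provenance flags."""

    tau: np.ndarray
    oob: bool
    fallback: np.ndarray  # True where the degenerate global-Wald fallback fired

    def summary(self) -> dict:
        q = np.quantile(self.tau, [0.05, 0.25, 0.5, 0.75, 0.95])
        return {
            "mean": float(self.tau.mean()),
            "sd": float(self.tau.std(ddof=1)) if len(self.tau) > 1 else 0.0,
            "q05": float(q[0]), "q25": float(q[1]), "median": float(q[2]),
            "q75": float(q[3]), "q95": float(q[4]),
            "n_fallback": int(self.fallback.sum()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": np.arange(len(self.tau)), "tau_hat": self.tau,
             "oob_flag": int(self.oob), "fallback_flag": self.fallback.astype(int)}
        )


def _node_moment_stats(tree: HonestTree, yr, dr, zr) -> dict:
    """Estimation-half moment sums for every node (children aggregate up)."""
    nn = tree.n_nodes
    e = tree.est_idx
    leaf = tree.est_leaf
    cnt = np.bincount(leaf, minlength=nn).astype(float)

    def agg(v):
        return np.bincount(leaf, weights=v[e], minlength=nn)

    s = {
        "cnt": cnt, "sy": agg(yr), "sd": agg(dr), "sz": agg(zr),
        "syz": agg(yr * zr), "sdz": agg(dr * zr), "szz": agg(zr * zr),
    }
    # children were appended after their parent, so reverse id order visits
    # every child before its parent
    for k in range(nn - 1, -1, -1):
        if tree.feature[k] >= 0:
            l, r = tree.left[k], tree.right[k]
            for key in s:
                s[key][k] = s[key][l] + s[key][r]
    return s


def _node_tau(stats: dict, parent_of: np.ndarray, global_wald: float):
    """Per-node Wald estimates with parent inheritance for degenerate nodes."""
    cnt = stats["cnt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        my = stats["sy"] / cnt
        md = stats["sd"] / cnt
        mz = stats["sz"] / cnt
        cov_yz = stats["syz"] / cnt - my * mz
        cov_dz = stats["sdz"] / cnt - md * mz
    valid = (cnt >= 2) & (np.abs(cov_dz) >= _DEGENERATE)
    tau = np.full(len(cnt), np.nan)
    tau[valid] = cov_yz[valid] / cov_dz[valid]
    eff = np.full(len(cnt), np.nan)
    inherited = np.zeros(len(cnt), dtype=bool)
    for k in range(len(cnt)):  # parents precede children in id order
        if valid[k]:
            eff[k] = tau[k]
        elif parent_of[k] >= 0:
            eff[k] = eff[parent_of[k]]
            inherited[k] = True
        else:
            eff[k] = global_wald
            inherited[k] = True
    return eff, inherited


def fit_iv_forest(ds: TrialDataset, nu: NuisanceEstimates,
                  params: ForestParams | None = None) -> IVForestModel:
    """Grow an instrumental forest on residualised (Y, D, Z).

    Splits maximise treatment-effect heterogeneity through the gradient
    pseudo-outcomes described in the module docstring; leaf estimates are
    honest local Wald ratios on the estimation half.
    """
    params = params or ForestParams()
    yr, dr, zr = residualise(ds, nu)
    x = np.ascontiguousarray(ds.x.to_numpy(dtype=float))
    gw = leaf_wald(yr, dr, zr)
    if not np.isfinite(gw):
        raise ValueError(
            "weak instrument: Cov(D - ê, Z - ĝ) is numerically zero on the "
            "full sample; the IV forest is not identified"
        )

    def score_factory(struct_idx):
        def score_fn(idx):
            z_n, d_n, y_n = zr[idx], dr[idx], yr[idx]
            a_p = float(np.mean(z_n * d_n))
            if abs(a_p) < _DEGENERATE:
                return None
            zc = z_n - z_n.mean()
            cov_dz = float(np.mean(d_n * zc))
            if abs(cov_dz) < _DEGENERATE:
                return None
            tau_p = float(np.mean(y_n * zc)) / cov_dz
            return z_n * (y_n - tau_p * d_n) / a_p
        return score_fn

    trees = grow_forest(x, params, score_factory)
    model = IVForestModel(
        trees=trees, params=params, feature_names=ds.covariate_names,
        x_train=x, yr=yr, dr=dr, zr=zr, global_wald=gw,
    )
    for t in trees:
        model.node_stats.append(_node_moment_stats(t, yr, dr, zr))
    return model


def predict_clate(model: IVForestModel, x_new: pd.DataFrame | np.ndarray | None = None) -> CLATEs:
    """CLATEs by solving the similarity-weighted moment condition.

    With no ``x_new`` the training units are predicted out-of-bag (all
    trees are used when ``sample_fraction = 1``, where no OOB trees
    exist).  A degenerate weighted first stage falls back to the global
    Wald estimate and is flagged.
    """
    oob = x_new is None and model.params.sample_fraction < 1.0
    if x_new is None:
        xq = model.x_train
    else:
        if isinstance(x_new, pd.DataFrame):
            if list(x_new.columns) != model.feature_names:
                raise ValueError(
                    f"profile schema mismatch: expected columns {model.feature_names}"
                )
            xq = x_new.to_numpy(dtype=float)
        else:
            xq = np.asarray(x_new, dtype=float)
            if xq.shape[1] != len(model.feature_names):
                raise ValueError("profile schema mismatch: wrong column count")
    nq = xq.shape[0]
    acc = {k: np.zeros(nq) for k in ("my", "md", "mz", "myz", "mdz")}
    used = np.zeros(nq)
    for tree, stats in zip(model.trees, model.node_stats):
        leaf = tree.route(xq)
        cnt = stats["cnt"][leaf]
        ok = cnt > 0
        if oob:
            in_bag = np.zeros(nq, dtype=bool)
            in_bag[tree.subsample] = True
            ok &= ~in_bag
        if not ok.any():
            continue
        c = cnt[ok]
        lf = leaf[ok]
        acc["my"][ok] += stats["sy"][lf] / c
        acc["md"][ok] += stats["sd"][lf] / c
        acc["mz"][ok] += stats["sz"][lf] / c
        acc["myz"][ok] += stats["syz"][lf] / c
        acc["mdz"][ok] += stats["sdz"][lf] / c
        used[ok] += 1
    covered = used > 0
    tau = np.full(nq, model.global_wald)
    fallback = ~covered
    if covered.any():
        u = used[covered]
        my, md, mz = acc["my"][covered] / u, acc["md"][covered] / u, acc["mz"][covered] / u
        myz, mdz = acc["myz"][covered] / u, acc["mdz"][covered] / u
        num = myz - my * mz
        den = mdz - md * mz
        good = np.abs(den) >= _DEGENERATE
        vals = np.where(good, num / np.where(good, den, 1.0), model.global_wald)
        tau[covered] = vals
        fb = fallback[covered]
        fb |= ~good
        fallback[covered] = fb
    return CLATEs(tau=tau, oob=oob, fallback=fallback)


@dataclass
class TuneResult:
    best: ForestParams
    scores: pd.DataFrame


def tune(ds: TrialDataset, nu: NuisanceEstimates, grid: list[ForestParams]) -> TuneResult:
    """Grid search minimising the OOB empirical-moment violation.

    The selection loss is mean_i [ (Yr_i - tau_oob(X_i) * Dr_i) * Zr_i ]^2,
    the squared violation of the instrument-orthogonality moment at the
    OOB CLATEs — an R-loss style proxy for fit of the effect function.
    Ties break toward smaller mtry, then larger min_node_size.
    """
    if not grid:
        raise ValueError("the tuning grid is empty")
    yr, dr, zr = residualise(ds, nu)
    p = ds.x.shape[1]
    rows = []
    for k, params in enumerate(grid):
        try:
            model = fit_iv_forest(ds, nu, params)
            tau = predict_clate(model).tau
            loss = float(np.mean(((yr - tau * dr) * zr) ** 2))
        except ValueError:
            loss = float("inf")
        rows.append({"grid_index": k, "loss": loss,
                     "mtry": params.resolve_mtry(p),
                     "min_node_size": params.min_node_size})
    table = pd.DataFrame(rows)
    if not np.isfinite(table["loss"]).any():
        raise ValueError("every grid point was degenerate")
    order = sorted(
        range(len(grid)),
        key=lambda k: (rows[k]["loss"], rows[k]["mtry"], -rows[k]["min_node_size"], k),
    )
    return TuneResult(best=grid[order[0]], scores=table)
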