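"""End-to-end orchestration of one per-outcome analysis run.

The run mirrors the estimation protocol for a randomised encouragement
design: strata accounting and balance checks, nuisance regression
forests, the (optionally tuned) instrumental forest, OOB CLATEs,
compliance and doubly robust scores, the AIPW LATE with a 2SLS baseline,
the three heterogeneity summaries, and depth-2/-3 policy trees.  All
artefacts are written as delimited text or JSON nested records, plus a
manifest (written last, as the completion marker) with content hashes so
a bundle can be verified and reproduced bit-identically from its config
and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .drscores import (LATEEstimate, baseline_2sls, compliance_score, dr_score, late)
from .forest import ForestParams
from .heterogeneity import BLPResult, CLANResult, VIRanking, blp, clan, variable_importance
from .instrumental import (CLATEs, IVForestModel, estimate_nuisances, fit_iv_forest,
                           predict_clate, tune)
from .policy import PolicyTree, PolicyValue, learn_tree, policy_value
from .strata import CrossTab, StrataShares, TrialDataset, contingency, smd, strata_shares
from .synthgen import generate, make_config

__all__ = ["RunConfig", "ReportBundle", "read_dataset", "run_pipeline", "write_report"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (exactly one of preset / input_path)."""

    preset: str | None = None
    input_path: str | None = None
    n: int = 2000  # units, when simulating
    outcome: str = "y"
    y_col: str = "y"
    d_col: str = "d"
    z_col: str = "z"
    supply_tags: tuple[str, ...] = ()
    num_trees: int = 2000
    forest: ForestParams | None = None
    tuning_grid: tuple[ForestParams, ...] | None = None
    exclude_supply_from_e: bool = True
    blp_robust_se: bool = True
    clan_rank_by: str = "gamma"  # or "clate"
    vi_mode: str = "frequency"
    policy_depths: tuple[int, ...] = (2, 3)
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if (self.preset is None) == (self.input_path is None):
            raise ValueError("set exactly one of preset / input_path")
        if self.tuning_grid is not None and len(self.tuning_grid) == 0:
            raise ValueError("the tuning grid is empty")


@dataclass
class ReportBundle:
    config: RunConfig
    dataset: TrialDataset
    crosstab: CrossTab
    shares: StrataShares
    shares_raw: StrataShares
    smd_table: pd.DataFrame
    nuisances: object
    model: IVForestModel
    clates: CLATEs
    gamma: object
    late_forest: LATEEstimate
    late_tsls: LATEEstimate
    blp_result: BLPResult
    clan_result: CLANResult
    vi: VIRanking
    policy_trees: dict[int, PolicyTree]
    policy_values: dict[int, PolicyValue]
    true_late: float | None = None
    timings: dict[str, float] = field(default_factory=dict)

    def late_table(self) -> pd.DataFrame:
        rows = []
        for est in (self.late_forest, self.late_tsls):
            rows.append({"method": est.method, "estimate": est.tau_hat, "se": est.se,
                         "ci_low": est.ci95[0], "ci_high": est.ci95[1], "n": est.n})
        return pd.DataFrame(rows)


def read_dataset(path: str | Path, y: str = "y", d: str = "d", z: str = "z",
                 supply_tags: tuple[str, ...] = (),
                 cluster: str | None = None) -> TrialDataset:
    """Read a delimited-text trial file and apply the complete-case filter."""
    frame = pd.read_csv(path)
    for col in (y, d, z):
        if col not in frame.columns:
            raise ValueError(f"schema error: column {col!r} missing from {path}")
    n_before = len(frame)
    frame = frame.dropna()
    dropped = n_before - len(frame)
    if dropped:
        warnings.warn(f"complete-case filter removed {dropped} row(s)", UserWarning,
                      stacklevel=2)
    for col in (d, z):
        vals = frame[col].unique()
        if not np.all(np.isin(vals, (0, 1))):
            bad = frame.index[~frame[col].isin((0, 1))].tolist()[:10]
            raise ValueError(f"column {col!r} must be binary; offending rows: {bad}")
    drop = [y, d, z] + ([cluster] if cluster else [])
    x = frame.drop(columns=drop)
    return TrialDataset(
        y=frame[y].to_numpy(dtype=float),
        d=frame[d].to_numpy(), z=frame[z].to_numpy(), x=x.reset_index(drop=True),
        supply_tags=supply_tags,
        cluster=frame[cluster].to_numpy() if cluster else None,
    )


def _reference_columns(ds: TrialDataset) -> list[str]:
    """One reference indicator per tercile family (the ``*_q3`` column)."""
    refs = []
    for col in ds.covariate_names:
        if col.endswith("_q3"):
            family = col[:-3]
            if f"{family}_q1" in ds.covariate_names and f"{family}_q2" in ds.covariate_names:
                refs.append(col)
    return refs


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute every stage; any failure aborts naming the stage."""
    timings: dict[str, float] = {}
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        timings[name] = time.perf_counter() - t0
        return out

    def load():
        if cfg.preset is not None:
            sds = generate(make_config(cfg.preset, n=cfg.n, seed=cfg.seed))
            state["truth"] = sds
            return sds.dataset
        return read_dataset(cfg.input_path, y=cfg.y_col, d=cfg.d_col, z=cfg.z_col,
                            supply_tags=cfg.supply_tags)

    ds = stage("load", load)
    tab = stage("strata", lambda: contingency(ds))
    shares = strata_shares(tab, "one_decimal_percent")
    shares_raw = strata_shares(tab, "raw")
    smd_table = stage("balance", lambda: smd(ds, "z"))

    base = cfg.forest or ForestParams(num_trees=cfg.num_trees)
    seeds = np.random.SeedSequence(cfg.seed).spawn(3)

    def seeded(params: ForestParams, s) -> ForestParams:
        return replace(params, seed=int(s.generate_state(1)[0] % (2 ** 31)))

    exclude = cfg.exclude_supply_from_e and bool(ds.supply_tags)
    nu = stage("nuisances", lambda: estimate_nuisances(
        ds, seeded(base, seeds[0]), exclude_supply_from_e=exclude))

    if cfg.tuning_grid is not None:
        result = stage("tune", lambda: tune(ds, nu, [seeded(p, seeds[1])
                                                     for p in cfg.tuning_grid]))
        iv_params = result.best
    else:
        iv_params = seeded(base, seeds[1])
    model = stage("iv_forest", lambda: fit_iv_forest(ds, nu, iv_params))
    clates = stage("clate", lambda: predict_clate(model))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        cs = stage("compliance", lambda: compliance_score(ds, nu, seeded(base, seeds[2])))
    gamma = stage("dr_scores", lambda: dr_score(ds, clates, nu, cs))
    late_forest = stage("late", lambda: late(gamma))
    late_tsls = stage("tsls_baseline", lambda: baseline_2sls(ds))

    refs = _reference_columns(ds)
    blp_result = stage("blp", lambda: blp(gamma, ds.x, drop_references=refs,
                                          robust=cfg.blp_robust_se))
    rank_by = clates.tau if cfg.clan_rank_by == "clate" else None
    clan_result = stage("clan", lambda: clan(gamma, ds.x, rank_by=rank_by))
    vi = stage("variable_importance", lambda: variable_importance(model, mode=cfg.vi_mode))

    trees: dict[int, PolicyTree] = {}
    values: dict[int, PolicyValue] = {}
    for depth in cfg.policy_depths:
        trees[depth] = stage(f"policy_depth{depth}",
                             lambda d=depth: learn_tree(ds.x, gamma, depth=d))
        values[depth] = policy_value(trees[depth], ds.x, gamma)

    truth = state.get("truth")
    tl = None
    if truth is not None:
        from .synthgen import true_late as _tl
        try:
            tl = _tl(truth)
        except ValueError:
            tl = None
    return ReportBundle(
        config=cfg, dataset=ds, crosstab=tab, shares=shares, shares_raw=shares_raw,
        smd_table=smd_table, nuisances=nu, model=model, clates=clates, gamma=gamma,
        late_forest=late_forest, late_tsls=late_tsls, blp_result=blp_result,
        clan_result=clan_result, vi=vi, policy_trees=trees, policy_values=values,
        true_late=tl, timings=timings,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _plot_bundle(bundle: ReportBundle, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = []
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(bundle.clates.tau, bins=30, color="steelblue", edgecolor="white")
    ax.axvline(bundle.late_forest.tau_hat, color="black", linestyle="--")
    for c in bundle.late_forest.ci95:
        ax.axvline(c, color="gray", linestyle=":")
    ax.axvline(0.0, color="red")
    ax.set_xlabel("estimated CLATE")
    ax.set_ylabel("units")
    fig.tight_layout()
    p = out / "clate_histogram.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    files.append(p)

    for name, table in (("blp", bundle.blp_result.table.drop(index="const")),
                        ("clan", bundle.clan_result.table)):
        est_col = "coef" if name == "blp" else "diff"
        fig, ax = plt.subplots(figsize=(5, 0.25 * len(table) + 1.5))
        ypos = np.arange(len(table))
        ax.errorbar(table[est_col], ypos,
                    xerr=1.96 * table["se"], fmt="o", color="darkslategray",
                    ecolor="gray", capsize=2)
        ax.axvline(0.0, color="red", linewidth=0.8)
        ax.set_yticks(ypos)
        ax.set_yticklabels(table.index)
        ax.invert_yaxis()
        ax.set_xlabel("estimate (95% CI)")
        fig.tight_layout()
        p = out / f"{name}_coefficients.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        files.append(p)
    return files


def write_report(bundle: ReportBundle, path: str | Path, overwrite: bool = False) -> Path:
    """Write every artefact; the manifest lands last as the completion marker."""
    out = Path(path)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{out} already holds a report; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    files: list[Path] = []

    def emit(name: str, writer) -> None:
        p = out / name
        writer(p)
        files.append(p)

    emit("crosstab.csv", lambda p: bundle.crosstab.to_frame().to_csv(p))
    emit("strata_shares.csv", lambda p: pd.DataFrame(
        [{"convention": "one_decimal_percent", "p_always": bundle.shares.p_always,
          "p_never": bundle.shares.p_never, "p_complier": bundle.shares.p_complier},
         {"convention": "raw", "p_always": bundle.shares_raw.p_always,
          "p_never": bundle.shares_raw.p_never,
          "p_complier": bundle.shares_raw.p_complier}]).to_csv(p, index=False))
    emit("smd.csv", lambda p: bundle.smd_table.to_csv(p))
    emit("late.csv", lambda p: bundle.late_table().to_csv(p, index=False))
    emit("clates.csv", lambda p: bundle.clates.to_frame().to_csv(p, index=False))
    emit("gamma.csv", lambda p: bundle.gamma.to_frame().to_csv(p, index=False))
    emit("blp.csv", lambda p: bundle.blp_result.table.to_csv(p))
    emit("clan.csv", lambda p: bundle.clan_result.table.to_csv(p))
    emit("variable_importance.csv", lambda p: bundle.vi.table.to_csv(p))
    for depth, tree in bundle.policy_trees.items():
        emit(f"policy_tree_depth{depth}.json", tree.save)
        emit(f"policy_tree_depth{depth}.txt",
             lambda p, t=tree: p.write_text(t.to_text() + "\n"))
    emit("policy_values.csv", lambda p: pd.DataFrame(
        [{"depth": d, "value": v.value, "treat_all": v.treat_all,
          "treat_none": v.treat_none, "advantage": v.advantage}
         for d, v in bundle.policy_values.items()]).to_csv(p, index=False))
    if bundle.config.make_plots:
        files.extend(_plot_bundle(bundle, out))

    cfg_dict = dataclasses.asdict(bundle.config)
    cfg_dict["forest"] = None if bundle.config.forest is None else dataclasses.asdict(
        bundle.config.forest)
    cfg_dict["tuning_grid"] = None if bundle.config.tuning_grid is None else [
        dataclasses.asdict(g) for g in bundle.config.tuning_grid]
    manifest = {
        "package": "ivforest",
        "version": __version__,
        "config": cfg_dict,
        "seed": bundle.config.seed,
        "non_default_trees": bundle.config.num_trees != 2000,
        "late": {"forest": bundle.late_forest.tau_hat, "tsls": bundle.late_tsls.tau_hat},
        "true_late": bundle.true_late,
        "timings_sec": {k: round(v, 4) for k, v in bundle.timings.items()},
        "files": {p.name: _sha256(p) for p in files},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return out
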