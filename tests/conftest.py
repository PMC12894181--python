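import warnings

import numpy as np
import pandas as pd
import pytest

import ivforest as iv


@pytest.fixture(scope="session")
def table_2009() -> iv.CrossTab:
    """Enrolment-by-assignment counts of the 2009 wave."""
    return iv.CrossTab(np.array([[929, 525], [99, 512]]))


@pytest.fixture(scope="session")
def table_2013() -> iv.CrossTab:
    return iv.CrossTab(np.array([[884, 501], [140, 464]]))


@pytest.fixture(scope="session")
def grouped_2009_prenatal():
    """Grouped pseudo-data reproducing the 2009 first stage and the
    pre-natal outcome means by assignment arm (0.644 control, 0.700 treated).

    Covariances against Z depend only on the group means, so constant
    within-arm outcome values give the identical Wald ratio.
    """
    n0, n1 = 1028, 1037
    d1_z0, d1_z1 = 99, 512
    z = np.concatenate([np.zeros(n0), np.ones(n1)])
    d = np.concatenate([
        np.r_[np.ones(d1_z0), np.zeros(n0 - d1_z0)],
        np.r_[np.ones(d1_z1), np.zeros(n1 - d1_z1)],
    ])
    y = np.concatenate([np.full(n0, 0.644), np.full(n1, 0.700)])
    return y, d, z


@pytest.fixture(scope="session")
def homog4000():
    """One fitted homogeneous-effect run (tau = 0.2), shared read-only."""
    sds = iv.generate(iv.make_config("homogeneous", n=4000, seed=11))
    ds = sds.dataset
    params = iv.ForestParams(num_trees=200, min_node_size=25, seed=7)
    nu = iv.estimate_nuisances(ds, params)
    model = iv.fit_iv_forest(ds, nu, params)
    clates = iv.predict_clate(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        cs = iv.compliance_score(ds, nu, params)
    gamma = iv.dr_score(ds, clates, nu, cs)
    return {"sds": sds, "ds": ds, "params": params, "nu": nu, "model": model,
            "clates": clates, "cs": cs, "gamma": gamma}


@pytest.fixture(scope="session")
def planted4000():
    """One fitted planted-heterogeneity run (tau = 0 vs 0.4 by x1)."""
    sds = iv.generate(iv.make_config("planted_binary", n=4000, seed=21))
    ds = sds.dataset
    params = iv.ForestParams(num_trees=200, min_node_size=25, seed=9)
    nu = iv.estimate_nuisances(ds, params, exclude_supply_from_e=False)
    model = iv.fit_iv_forest(ds, nu, params)
    clates = iv.predict_clate(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        cs = iv.compliance_score(ds, nu, params)
    gamma = iv.dr_score(ds, clates, nu, cs)
    return {"sds": sds, "ds": ds, "params": params, "nu": nu, "model": model,
            "clates": clates, "cs": cs, "gamma": gamma}


def brute_force_depth2(x: pd.DataFrame, gamma: np.ndarray) -> float:
    """Oracle: enumerate every (root var, left var, right var, 4 actions)
    depth-2 policy tree and return the best empirical value."""
    import itertools

    cols = list(x.columns)
    mat = x.to_numpy(dtype=float)
    best = -np.inf
    for root in cols:
        r = mat[:, cols.index(root)] == 1.0
        for lv, rv in itertools.product(cols, repeat=2):
            lcol = mat[:, cols.index(lv)] == 1.0
            rcol = mat[:, cols.index(rv)] == 1.0
            for actions in itertools.product((0, 1), repeat=4):
                pi = np.where(
                    ~r,
                    np.where(~lcol, actions[0], actions[1]),
                    np.where(~rcol, actions[2], actions[3]),
                )
                best = max(best, float(np.mean((2 * pi - 1) * gamma)))
    return best


def make_trial(n=200, p=3, seed=0, tau=0.3):
    """Small helper trial with full compliance for unit tests."""
    rng = np.random.default_rng(seed)
    x = pd.DataFrame({f"x{j}": rng.integers(0, 2, n) for j in range(p)})
    z = rng.integers(0, 2, n)
    d = z.copy()
    y = (rng.random(n) < 0.4 + tau * d * x["x0"].to_numpy()).astype(float)
    return iv.TrialDataset(y=y, d=d, z=z, x=x)
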