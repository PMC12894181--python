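"""Doubly robust (AIPW) scores for the LATE and the 2SLS baseline.

The per-unit doubly robust score augments the forest's CLATE with an
instrument-propensity-weighted residual correction, rescaled by the
conditional first stage (the *compliance score*
delta(x) = E[D | X, Z=1] - E[D | X, Z=0]):

    Gamma_i = tau_hat(X_i)
              + [ (Z_i - g_hat) / (g_hat (1 - g_hat)) ] / delta_hat(X_i)
                * ( (Y_i - m_hat_i) - (D_i - e_hat_i) * tau_hat(X_i) )

Its mean estimates the LATE and is consistent if either the outcome
model or the propensity/instrument models are correct; the correction
factor is mean-zero given X under either, which is why the residual must
read (Y - m_hat) - (D - e_hat) * tau_hat.  Standard errors use the i.i.d.
formula SD(Gamma)/sqrt(N).

delta(x) is estimated by an auxiliary causal forest: the instrumental
machinery applied with D as the outcome and Z as both treatment and
instrument (a randomised treatment is its own instrument).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .forest import ForestParams
from .instrumental import CLATEs, NuisanceEstimates, fit_iv_forest, predict_clate
from .strata import TrialDataset

__all__ = [
    "ComplianceScores",
    "DRScores",
    "LATEEstimate",
    "compliance_score",
    "dr_score",
    "late",
    "baseline_2sls",
]

_DELTA_FLOOR = 0.01


@dataclass
class ComplianceScores:
    """Per-unit conditional first stage delta_hat(X), floor-clipped at 0.01."""

    delta_hat: np.ndarray
    clipped: np.ndarray  # True where the raw estimate was below the floor
    n_negative_raw: int = 0


@dataclass
class DRScores:
    """Per-unit doubly robust scores Gamma_i (outcome units)."""

    gamma: np.ndarray
    delta_clipped: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"unit": np.arange(len(self.gamma)), "gamma": self.gamma})
        if self.delta_clipped is not None:
            out["delta_clipped"] = self.delta_clipped.astype(int)
        return out


@dataclass(frozen=True)
class LATEEstimate:
    tau_hat: float
    se: float
    n: int
    method: str  # "aipw_forest" | "tsls" | "wald"

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.tau_hat - 1.96 * self.se, self.tau_hat + 1.96 * self.se)


def compliance_score(ds: TrialDataset, nu: NuisanceEstimates,
                     params: ForestParams | None = None) -> ComplianceScores:
    """Estimate delta(x) via the self-instrumented auxiliary causal forest.

    Reuses the treatment propensity e_hat as E[D|X] and the instrument
    propensity g_hat for the (randomised) treatment Z.
    """
    aux_ds = TrialDataset(y=ds.d.astype(float), d=ds.z, z=ds.z, x=ds.x,
                          supply_tags=ds.supply_tags)
    aux_nu = NuisanceEstimates(
        m_hat=nu.e_hat, e_hat=nu.g_hat, g_hat=nu.g_hat,
        m_features=nu.e_features, e_features=nu.g_features, g_features=nu.g_features,
    )
    try:
        model = fit_iv_forest(aux_ds, aux_nu, params)
    except ValueError as err:
        raise ValueError(
            "compliance score is degenerate: the instrument does not move "
            "treatment uptake (no compliers?)"
        ) from err
    raw = predict_clate(model).tau
    if np.all(raw < _DELTA_FLOOR):
        raise ValueError(
            "compliance score is degenerate everywhere: the instrument does "
            "not move treatment uptake (no compliers?)"
        )
    clipped = raw < _DELTA_FLOOR
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} compliance score(s) floor-clipped at "
            f"{_DELTA_FLOOR}", UserWarning, stacklevel=2,
        )
    return ComplianceScores(
        delta_hat=np.maximum(raw, _DELTA_FLOOR),
        clipped=clipped,
        n_negative_raw=int((raw < 0).sum()),
    )


def dr_score(ds: TrialDataset, clates: CLATEs, nu: NuisanceEstimates,
             cs: ComplianceScores) -> DRScores:
    """Per-unit AIPW scores Gamma_i (see module docstring for the formula)."""
    tau = np.asarray(clates.tau, dtype=float)
    if not (len(tau) == ds.n == len(cs.delta_hat)):
        raise ValueError("inputs are not aligned to the dataset")
    g = nu.g_hat
    weight = (ds.z - g) / (g * (1.0 - g)) / cs.delta_hat
    residual = (ds.y - nu.m_hat) - (ds.d - nu.e_hat) * tau
    return DRScores(gamma=tau + weight * residual, delta_clipped=cs.clipped)


def late(scores: DRScores) -> LATEEstimate:
    """LATE = mean(Gamma); SE = SD(Gamma)/sqrt(N)."""
    g = np.asarray(scores.gamma, dtype=float)
    n = len(g)
    if n < 2:
        raise ValueError("need at least two scores")
    se = float(g.std(ddof=1) / np.sqrt(n))
    return LATEEstimate(tau_hat=float(g.mean()), se=se, n=n, method="aipw_forest")


def _named_rank_check(mat: np.ndarray, names: list[str], label: str) -> None:
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify the first column that adds no rank
        offenders = []
        for j in range(1, mat.shape[1] + 1):
            if np.linalg.matrix_rank(mat[:, :j]) < j:
                offenders.append(names[j - 1])
        raise ValueError(f"rank-deficient {label}; collinear columns: {offenders}")


def baseline_2sls(ds: TrialDataset, covariates: list[str] | None = None,
                  robust: bool = False) -> LATEEstimate:
    """Conventional linear 2SLS of Y on D instrumented by Z.

    Optional linear covariate adjustment; with no covariates the point
    estimate equals the unconditional Wald ratio exactly.  Standard errors
    use the just-identified IV sandwich — homoskedastic by default,
    heteroskedasticity-robust with ``robust=True``.
    """
    n = ds.n
    if covariates:
        missing = [c for c in covariates if c not in ds.x.columns]
        if missing:
            raise ValueError(f"unknown covariates: {missing}")
        xc = ds.x[covariates].to_numpy(dtype=float)
    else:
        covariates = []
        xc = np.empty((n, 0))
    ones = np.ones((n, 1))
    w = np.hstack([ones, xc, ds.d.reshape(-1, 1).astype(float)])  # regressors
    m = np.hstack([ones, xc, ds.z.reshape(-1, 1).astype(float)])  # instruments
    w_names = ["const", *covariates, "d"]
    m_names = ["const", *covariates, "z"]
    _named_rank_check(w, w_names, "regressor matrix")
    _named_rank_check(m, m_names, "instrument matrix")
    mw = m.T @ w
    if abs(np.linalg.det(mw)) < 1e-12 * n ** w.shape[1]:
        raise ValueError("weak or irrelevant instrument: M'W is singular")
    mw_inv = np.linalg.inv(mw)
    beta = mw_inv @ (m.T @ ds.y)
    u = ds.y - w @ beta
    k = w.shape[1]
    if robust:
        meat = m.T @ (m * (u ** 2)[:, None])
        cov = mw_inv @ meat @ mw_inv.T
    else:
        sigma2 = float(u @ u) / (n - k)
        cov = sigma2 * (mw_inv @ (m.T @ m) @ mw_inv.T)
    j = k - 1  # D is the last regressor
    return LATEEstimate(
        tau_hat=float(beta[j]), se=float(np.sqrt(cov[j, j])), n=n, method="tsls"
    )
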