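"""Synthetic randomised-encouragement trials with known ground truth.

The generator emulates the statistical structure of a cluster-randomised
conditional-cash-transfer experiment with non-compliance: a roughly
50/50 randomised assignment Z, principal strata (compliers /
always-takers / never-takers) drawn with configurable shares, binary
utilisation outcomes with baseline rates in the 0.3-0.85 band, and
treatment effects that vary with supply-side and household-amenity
covariates.  Every unit carries its stratum, its true conditional
effect, and both potential outcomes, so downstream estimators can be
tested against exact ground truth.

The structural model is a clipped linear-probability design:

    P(Y(d) = 1 | x) = clip(m(x) + tau(x) * d, 0.01, 0.99)

with m(x) = mu0 + sum_k beta_k x_k and tau(x) = tau0 + sum_k gamma_k x_k,
so the true effect is expressed directly in risk-difference units.
Monotonicity and the exclusion restriction hold by construction:
D = 1 iff (always-taker) or (complier and Z = 1), and potential outcomes
are drawn without reference to Z.  A single integer seed drives four
independent sub-streams (covariates, strata, assignment, outcome noise),
so e.g. the assignment can be resampled while everything else is held
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .strata import TrialDataset, tercile_encode

__all__ = ["SynthConfig", "SynthDataset", "make_config", "generate", "true_late", "PRESETS"]

_CLIP = (0.01, 0.99)
STRATA = ("complier", "always", "never")


@dataclass(frozen=True)
class SynthConfig:
    """Declarative description of one synthetic trial.

    covariate_spec entries are ``(name, "binary", prob)`` or
    ``(name, "tercile", None)``; a tercile entry expands into three
    indicator columns ``name_q1`` (lowest tercile) .. ``name_q3``.
    tau_spec / baseline_spec coefficients are keyed by the *expanded*
    column names and are in risk-difference units.
    """

    n: int
    p_assign: float = 0.5
    strata_probs: tuple[float, float, float] = (0.5, 0.1, 0.4)  # (complier, always, never)
    covariate_spec: tuple = ()
    tau0: float = 0.2
    tau_coefs: tuple = ()  # ((column, coef), ...)
    mu0: float = 0.4
    baseline_coefs: tuple = ()
    noise_sd: float = 0.1  # latent noise SD; used only for continuous outcomes
    outcome: str = "binary"
    supply_tags: tuple[str, ...] = ()
    n_clusters: int | None = None
    strata_tilt: tuple | None = None  # (column, coef): logistic shift of the complier share
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not (0.0 < self.p_assign < 1.0):
            raise ValueError("p_assign must lie in (0, 1)")
        probs = np.asarray(self.strata_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any():
            raise ValueError("strata_probs must be three non-negative shares")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("strata_probs must sum to 1 within 1e-12")
        if self.outcome not in ("binary", "continuous"):
            raise ValueError("outcome must be 'binary' or 'continuous'")
        names = self.column_names()
        for col, _ in tuple(self.tau_coefs) + tuple(self.baseline_coefs):
            if col not in names:
                raise ValueError(f"effect spec references undeclared covariate {col!r}")
        for tag in self.supply_tags:
            if tag not in names:
                raise ValueError(f"supply tag {tag!r} is not a declared covariate")
        if self.strata_tilt is not None and self.strata_tilt[0] not in names:
            raise ValueError(
                f"strata_tilt references undeclared covariate {self.strata_tilt[0]!r}"
            )

    def column_names(self) -> list[str]:
        out = []
        for name, kind, *_ in self.covariate_spec:
            if kind == "binary":
                out.append(name)
            elif kind == "tercile":
                out.extend(f"{name}_q{j}" for j in (1, 2, 3))
            else:
                raise ValueError(f"unknown covariate kind {kind!r}")
        return out

    # -- flat key-value round trip ---------------------------------------
    def to_keyvalues(self, path: str | Path) -> None:
        """Write as a flat ``key = value`` file (structured fields as JSON)."""
        lines = []
        for key, value in self.__dict__.items():
            lines.append(f"{key} = {json.dumps(value)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_keyvalues(cls, path: str | Path) -> "SynthConfig":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = json.loads(value.strip())
        for key in ("strata_probs", "covariate_spec", "tau_coefs",
                    "baseline_coefs", "supply_tags", "strata_tilt"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in kwargs[key]
                )
        return cls(**kwargs)


@dataclass
class SynthDataset:
    """A TrialDataset plus its generating ground truth."""

    dataset: TrialDataset
    stratum: np.ndarray  # strings in {"complier", "always", "never"}
    true_tau: np.ndarray  # P(Y(1)=1|x) - P(Y(0)=1|x), post-clipping
    true_m: np.ndarray  # P(Y(0)=1|x), post-clipping
    y0: np.ndarray
    y1: np.ndarray
    config: SynthConfig | None = None

    def write(self, path: str | Path) -> None:
        """Write the trial as CSV and the ground truth to ``<path>.truth``."""
        path = Path(path)
        self.dataset.write(path)
        truth = pd.DataFrame(
            {"stratum": self.stratum, "true_tau": self.true_tau,
             "true_m": self.true_m, "y0": self.y0, "y1": self.y1}
        )
        truth.to_csv(path.with_suffix(path.suffix + ".truth"), index=False)


_PKH_COVARIATES = (
    ("urban", "binary", 0.12),
    ("java", "binary", 0.61),
    ("mother_educated", "binary", 0.82),
    ("mother_employed", "binary", 0.21),
    ("subsidised_insurance", "binary", 0.74),
    ("hoh_agriculture", "binary", 0.61),
    ("no_latrine", "binary", 0.49),
    ("no_electricity", "binary", 0.21),
    ("doctors", "tercile", None),
    ("nurses", "tercile", None),
    ("lack_facilities", "binary", 0.31),
)
_PKH_SUPPLY = (
    "doctors_q1", "doctors_q2", "doctors_q3",
    "nurses_q1", "nurses_q2", "nurses_q3",
    "lack_facilities",
)
_PKH_BASELINE = (
    ("java", 0.08), ("mother_educated", 0.06), ("urban", 0.05),
    ("no_electricity", -0.06),
)
# heterogeneity driven by supply-side availability and household amenities
_PKH_TAU = (("doctors_q3", 0.08), ("no_latrine", 0.06), ("urban", 0.05))


def make_config(preset: str, n: int = 2000, seed: int = 0) -> SynthConfig:
    """Named study conditions.

    ``pkh2009`` / ``pkh2013``: strata shares (complier, always, never) =
    (0.398, 0.096, 0.506) and (0.344, 0.137, 0.519), a realistic covariate
    battery with tagged supply-side columns, and supply/amenity-driven
    effect heterogeneity.  ``homogeneous``: constant tau = 0.2 (no
    heterogeneity) under the 2009 strata.  ``planted_binary``: a single
    binary covariate switches tau between 0 and 0.4.
    """
    if preset == "pkh2009":
        return SynthConfig(
            n=n, seed=seed, strata_probs=(0.398, 0.096, 0.506),
            covariate_spec=_PKH_COVARIATES, supply_tags=_PKH_SUPPLY,
            mu0=0.40, baseline_coefs=_PKH_BASELINE,
            tau0=0.12, tau_coefs=_PKH_TAU,
        )
    if preset == "pkh2013":
        return SynthConfig(
            n=n, seed=seed, strata_probs=(0.344, 0.137, 0.519),
            covariate_spec=_PKH_COVARIATES, supply_tags=_PKH_SUPPLY,
            mu0=0.55, baseline_coefs=_PKH_BASELINE,
            tau0=0.15, tau_coefs=_PKH_TAU,
        )
    if preset == "homogeneous":
        return SynthConfig(
            n=n, seed=seed, strata_probs=(0.398, 0.096, 0.506),
            covariate_spec=(
                ("urban", "binary", 0.12),
                ("no_latrine", "binary", 0.49),
                ("mother_educated", "binary", 0.82),
                ("doctors", "tercile", None),
            ),
            supply_tags=("doctors_q1", "doctors_q2", "doctors_q3"),
            mu0=0.40, baseline_coefs=(("mother_educated", 0.08), ("urban", 0.05)),
            tau0=0.2, tau_coefs=(),
        )
    if preset == "planted_binary":
        return SynthConfig(
            n=n, seed=seed, strata_probs=(0.5, 0.1, 0.4),
            covariate_spec=(
                ("x1", "binary", 0.5),
                ("x2", "binary", 0.3),
                ("x3", "binary", 0.6),
                ("x4", "binary", 0.5),
                ("x5", "binary", 0.2),
            ),
            mu0=0.35, baseline_coefs=(("x2", 0.10),),
            tau0=0.0, tau_coefs=(("x1", 0.4),),
        )
    raise ValueError(f"unknown preset {preset!r}; known presets: {sorted(PRESETS)}")


PRESETS = {"pkh2009", "pkh2013", "homogeneous", "planted_binary"}


def _linear(x: pd.DataFrame, intercept: float, coefs) -> np.ndarray:
    out = np.full(len(x), float(intercept))
    for col, coef in coefs:
        out += float(coef) * x[col].to_numpy(dtype=float)
    return out


def generate(config: SynthConfig, assignment_seed: int | None = None) -> SynthDataset:
    """Draw one trial from a configuration.

    ``assignment_seed`` resamples only the Z stream (clusters and
    assignment), holding covariates, strata and potential outcomes
    bit-identical — the generator-level statement of the exclusion
    restriction.
    """
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_x = np.random.default_rng(ss[0])
    rng_s = np.random.default_rng(ss[1])
    rng_z = np.random.default_rng(
        ss[2] if assignment_seed is None else np.random.SeedSequence(assignment_seed)
    )
    rng_u = np.random.default_rng(ss[3])
    n = config.n

    # covariates
    cols = {}
    for name, kind, *rest in config.covariate_spec:
        if kind == "binary":
            cols[name] = (rng_x.random(n) < float(rest[0])).astype(np.int8)
        else:  # tercile: uniform latent discretised into three indicators
            latent = rng_x.random(n)
            enc = tercile_encode(latent, name)
            for c in enc.columns:
                cols[c] = enc[c].to_numpy()
    x = pd.DataFrame(cols) if cols else pd.DataFrame(index=range(n))

    # principal strata (independent of X unless a tilt is configured)
    if config.strata_tilt is None:
        stratum = rng_s.choice(np.array(STRATA), size=n,
                               p=np.asarray(config.strata_probs))
    else:
        col, coef = config.strata_tilt
        pc, pa, pn = config.strata_probs
        logit = np.log(pc / (1.0 - pc)) + float(coef) * x[col].to_numpy(dtype=float)
        pc_i = 1.0 / (1.0 + np.exp(-logit))
        # always/never shares rescaled to keep their relative mix
        rest = np.where(pa + pn > 0, (1.0 - pc_i) / max(pa + pn, 1e-12), 0.0)
        probs = np.column_stack([pc_i, pa * rest, pn * rest])
        u = rng_s.random(n)
        cum = np.cumsum(probs, axis=1)
        stratum = np.array(STRATA)[(u[:, None] > cum).sum(axis=1)]

    # assignment (cluster-constant if clusters configured)
    cluster = None
    if config.n_clusters:
        cluster = rng_z.integers(config.n_clusters, size=n)
        z_cluster = (rng_z.random(config.n_clusters) < config.p_assign).astype(np.int8)
        z = z_cluster[cluster]
    else:
        z = (rng_z.random(n) < config.p_assign).astype(np.int8)

    # monotone treatment uptake: no defiers by construction
    d = ((stratum == "always") | ((stratum == "complier") & (z == 1))).astype(np.int8)

    m_lin = _linear(x, config.mu0, config.baseline_coefs)
    tau_lin = _linear(x, config.tau0, config.tau_coefs)
    p0 = np.clip(m_lin, *_CLIP)
    p1 = np.clip(m_lin + tau_lin, *_CLIP)

    if config.outcome == "binary":
        u = rng_u.random(n)  # shared draw couples the potential outcomes
        y0 = (u < p0).astype(np.int8)
        y1 = (u < p1).astype(np.int8)
        true_tau = p1 - p0
        true_m = p0
    else:
        eps = rng_u.normal(0.0, config.noise_sd, size=n)
        y0 = m_lin + eps
        y1 = m_lin + tau_lin + eps
        true_tau = tau_lin
        true_m = m_lin
    y = np.where(d == 1, y1, y0)

    ds = TrialDataset(y=y.astype(float), d=d, z=z, x=x,
                      supply_tags=config.supply_tags, cluster=cluster)
    return SynthDataset(
        dataset=ds, stratum=stratum, true_tau=true_tau, true_m=true_m,
        y0=np.asarray(y0, dtype=float), y1=np.asarray(y1, dtype=float),
        config=config,
    )


def true_late(sds: SynthDataset) -> float:
    """Ground-truth complier-average effect: mean true effect over compliers."""
    mask = sds.stratum == "complier"
    if not mask.any():
        raise ValueError("no compliers in the sample; the LATE is undefined")
    return float(sds.true_tau[mask].mean())
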