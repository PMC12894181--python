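"""Principal-strata accounting and trial preprocessing.

A randomised encouragement design observes, for every unit, a binary
outcome ``Y``, the treatment actually received ``D``, and the randomised
assignment ``Z`` used as an instrument.  Under monotonicity (no defiers)
the population splits into three principal strata: always-takers
(``D = 1`` regardless of ``Z``), never-takers (``D = 0`` regardless of
``Z``) and compliers (``D = Z``).  Their shares are point-identified from
the ``D × Z`` contingency table:

    P(always)   = P(D = 1 | Z = 0)
    P(never)    = P(D = 0 | Z = 1)
    P(complier) = 1 - P(always) - P(never)
                = P(D = 1 | Z = 1) - P(D = 1 | Z = 0)   (first stage)

This module also provides the standardised-mean-difference balance
diagnostic and the tercile discretisation used to turn continuous
covariates into overlap-friendly indicator columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrialDataset",
    "CrossTab",
    "StrataShares",
    "contingency",
    "strata_shares",
    "smd",
    "tercile_encode",
]


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        bad = [v for v in vals if v not in (0, 1)]
        raise ValueError(f"{name} must be strictly binary; found values {bad}")
    return a.astype(np.int8)


@dataclass
class TrialDataset:
    """Unit-level records of a randomised trial with non-compliance.

    Parameters
    ----------
    y, d, z
        Outcome, treatment received, and randomised assignment.  ``d`` and
        ``z`` must be binary; ``y`` is binary in the main analysis but a
        numeric outcome is accepted (for continuous-outcome robustness).
    x
        Covariate matrix with named columns; indicator (0/1) columns after
        tercile encoding.
    supply_tags
        Names of supply-side covariate columns (health-worker availability
        terciles and village-concern indicators).  These are excluded from
        the treatment-propensity model because programme eligibility was
        determined partly through supply-side readiness.
    cluster
        Optional assignment-cluster labels (``z`` constant within cluster).
    """

    y: np.ndarray
    d: np.ndarray
    z: np.ndarray
    x: pd.DataFrame
    supply_tags: tuple[str, ...] = ()
    cluster: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.d = _check_binary(self.d, "d")
        self.z = _check_binary(self.z, "z")
        if not isinstance(self.x, pd.DataFrame):
            self.x = pd.DataFrame(np.asarray(self.x))
            self.x.columns = [f"x{j}" for j in range(self.x.shape[1])]
        n = len(self.y)
        if n < 1:
            raise ValueError("dataset must contain at least one unit")
        if not (len(self.d) == len(self.z) == len(self.x) == n):
            raise ValueError("y, d, z, x must have equal length")
        if np.isnan(self.y).any() or self.x.isna().any().any():
            raise ValueError("missing values present; complete cases required")
        missing = [t for t in self.supply_tags if t not in self.x.columns]
        if missing:
            raise ValueError(f"supply_tags not found among covariates: {missing}")
        self.supply_tags = tuple(self.supply_tags)
        if self.cluster is not None:
            self.cluster = np.asarray(self.cluster)
            if len(self.cluster) != n:
                raise ValueError("cluster labels must match the unit count")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.x.columns)

    def to_frame(self) -> pd.DataFrame:
        cols = {"y": self.y, "d": self.d, "z": self.z}
        if self.cluster is not None:
            cols["cluster"] = self.cluster
        return pd.concat([pd.DataFrame(cols), self.x.reset_index(drop=True)], axis=1)

    def write(self, path: str | Path) -> None:
        """Write as delimited text with header (CSV)."""
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CrossTab:
    """2x2 enrolment-by-assignment contingency table.

    ``counts[d, z]`` is the number of units with treatment status ``d``
    under assignment ``z``; ``col_pct`` gives within-assignment-column
    percentages rounded to whole percents (the reporting convention for
    such tables).
    """

    counts: np.ndarray  # shape (2, 2), indexed [d, z]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2) or (c < 0).any():
            raise ValueError("counts must be a non-negative 2x2 array")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_pct(self) -> np.ndarray:
        """Within-column percentages rounded to whole percents."""
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / self.col_totals
        return np.round(np.nan_to_num(pct)).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index([0, 1], name="d"),
            columns=pd.Index([0, 1], name="z"),
        )


@dataclass(frozen=True)
class StrataShares:
    """Principal-strata shares; on the percent scale when rounded."""

    p_always: float
    p_never: float
    p_complier: float
    monotonicity_violated: bool = False
    scale: str = "proportion"  # "proportion" or "percent"

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_always, self.p_never, self.p_complier)


def contingency(ds: TrialDataset) -> CrossTab:
    """Cross-tabulate treatment received against randomised assignment."""
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (ds.d, ds.z), 1)
    return CrossTab(counts)


def strata_shares(tab: CrossTab, rounding: str = "one_decimal_percent") -> StrataShares:
    """Estimate always-taker / never-taker / complier shares from a 2x2 table.

    ``one_decimal_percent`` reproduces the reporting convention in which
    the always- and never-taker shares are rounded to one decimal in
    percent units and the complier share is their complement to 100 —
    the only convention under which the three printed shares are mutually
    consistent.  ``raw`` returns unrounded proportions with the complier
    share equal to the first-stage difference exactly.
    """
    n0, n1 = tab.col_totals
    if n0 == 0 or n1 == 0:
        raise ValueError("both assignment columns must be non-empty")
    p_always = tab.counts[1, 0] / n0  # P(D=1 | Z=0)
    p_never = tab.counts[0, 1] / n1  # P(D=0 | Z=1)
    p_complier = tab.counts[1, 1] / n1 - p_always  # first stage
    violated = p_complier < 0
    if violated:
        warnings.warn(
            "negative raw complier share: monotonicity (no defiers) is "
            "implausible for this table",
            UserWarning,
            stacklevel=2,
        )
    if rounding == "raw":
        return StrataShares(p_always, p_never, p_complier, violated, "proportion")
    if rounding == "one_decimal_percent":
        a = round(100.0 * p_always, 1)
        nv = round(100.0 * p_never, 1)
        return StrataShares(a, nv, round(100.0 - a - nv, 1), violated, "percent")
    raise ValueError(f"unknown rounding convention: {rounding!r}")


def smd(ds: TrialDataset, group: str = "z") -> pd.DataFrame:
    """Standardised mean differences between the two levels of ``z`` or ``d``.

    For each covariate and for the outcome, (mean1 - mean0) / s_pooled with
    s_pooled = sqrt((s0^2 + s1^2) / 2); sample variances use ddof=1.
    Zero-variance columns give SMD 0 when the group means agree and are
    flagged ``degenerate`` otherwise.
    """
    if group not in ("z", "d"):
        raise ValueError("group must be 'z' or 'd'")
    g = ds.z if group == "z" else ds.d
    if g.min() == g.max():
        raise ValueError(f"both {group}-groups must be non-empty")
    cols = pd.concat([pd.Series(ds.y, name="y"), ds.x.reset_index(drop=True)], axis=1)
    rows = []
    for name in cols.columns:
        v = cols[name].to_numpy(dtype=float)
        v0, v1 = v[g == 0], v[g == 1]
        m0, m1 = v0.mean(), v1.mean()
        s0 = v0.var(ddof=1) if len(v0) > 1 else 0.0
        s1 = v1.var(ddof=1) if len(v1) > 1 else 0.0
        pooled = np.sqrt((s0 + s1) / 2.0)
        degenerate = False
        if pooled == 0.0:
            value = 0.0
            degenerate = not np.isclose(m0, m1)
        else:
            value = (m1 - m0) / pooled
        rows.append(
            {"column": name, "mean0": m0, "mean1": m1, "smd": value, "degenerate": degenerate}
        )
    return pd.DataFrame(rows).set_index("column")


def tercile_encode(v, name: str = "x") -> pd.DataFrame:
    """Discretise a numeric column into three tercile indicator columns.

    Cut points are the inclusive (linear-interpolation) empirical 1/3 and
    2/3 quantiles; ties at a cut point fall in the lower tercile.  Returns
    a DataFrame with columns ``{name}_q1``, ``{name}_q2``, ``{name}_q3``
    that partition the sample.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError("need a one-dimensional column of length >= 3")
    if np.isnan(v).any():
        raise ValueError("missing values present")
    lo, hi = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0], method="linear")
    if v.min() == v.max():
        raise ValueError("constant column has no terciles")
    q1 = v <= lo
    q2 = (v > lo) & (v <= hi)
    q3 = v > hi
    out = pd.DataFrame(
        {f"{name}_q1": q1, f"{name}_q2": q2, f"{name}_q3": q3}
    ).astype(np.int8)
    return out
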