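"""Comparative statistics: group summaries, Welch tests, OLS R², PCA.

These operate on per-organism values or on the organisms x 6 CAZyme-category
count matrix.  Conventions follow the common R defaults the field reports
with: medians as the midpoint of the central order statistics, quartiles by
type-7 linear interpolation, sample standard deviation with the n-1
denominator, covariance (unscaled) PCA with mean-centred columns as in
``prcomp``, and raw (uncorrected) pairwise Welch p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .vocab import Category

CATEGORY_ORDER = [c.value for c in Category]  # GH GT PL CE AA CBM


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    level: str
    n: int
    median: float
    sample_sd: float | None
    q1: float
    q3: float


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    dof: float
    p_value: float
    groups: tuple[str, str]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class PCAResult:
    variance_fraction: np.ndarray  # non-increasing, sums to 1
    loadings: np.ndarray  # components x variables, rows orthonormal
    scores: np.ndarray  # observations x components
    columns: tuple[str, ...]


def group_summarize(
    values: Mapping[str, float] | pd.Series,
    grouping: Mapping[str, str],
    *,
    level: str = "group",
) -> list[GroupSummary]:
    """Per-group median, sample SD and type-7 quartiles of organism values.

    ``values`` maps organism -> value and ``grouping`` organism -> group
    label; every organism must carry a label.  Groups with no values are
    omitted with a warning.  SD is None for singleton groups.
    """
    if isinstance(values, pd.Series):
        values = values.to_dict()
    unlabeled = sorted(set(values) - set(grouping))
    if unlabeled:
        raise ValueError(f"organisms without a group label: {unlabeled}")
    by_group: dict[str, list[float]] = {}
    for org, v in values.items():
        by_group.setdefault(grouping[org], []).append(float(v))
    empties = sorted(set(grouping.values()) - set(by_group))
    if empties:
        warnings.warn(f"groups with no values omitted: {empties}", stacklevel=2)
    out = []
    for label in sorted(by_group):
        x = np.asarray(by_group[label], dtype=float)
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # type-7 default
        sd = float(np.std(x, ddof=1)) if x.size >= 2 else None
        out.append(GroupSummary(label, level, int(x.size), float(med), sd, float(q1), float(q3)))
    return out


def welch_test(
    a: Sequence[float],
    b: Sequence[float],
    groups: tuple[str, str] = ("a", "b"),
) -> WelchResult:
    """Two-sided Welch's t-test (unequal variances, Welch-Satterthwaite dof).

    Degenerate zero-variance inputs are handled without division failures:
    equal-mean constant samples give t=0, p=1; unequal-mean constant samples
    give p -> 0.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        dof = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return WelchResult(0.0, dof, 1.0, groups)
        t = np.inf if x.mean() > y.mean() else -np.inf
        return WelchResult(float(t), dof, 0.0, groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(x, y, equal_var=False)
    se_sq = vx / x.size + vy / y.size
    dof = se_sq**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    return WelchResult(float(t), float(dof), float(p), groups)


def pairwise_welch(
    values: Mapping[str, float] | pd.Series,
    grouping: Mapping[str, str],
    *,
    correction: str | None = None,
) -> list[WelchResult]:
    """Welch's t-test for every pair of groups with >= 2 members.

    Raw p-values by default; ``correction`` may be ``"bonferroni"`` or
    ``"bh"`` (Benjamini-Hochberg) to adjust them.
    """
    if isinstance(values, pd.Series):
        values = values.to_dict()
    by_group: dict[str, list[float]] = {}
    for org, v in values.items():
        by_group.setdefault(grouping[org], []).append(float(v))
    labels = sorted(g for g, xs in by_group.items() if len(xs) >= 2)
    results = [
        welch_test(by_group[g1], by_group[g2], (g1, g2))
        for g1, g2 in combinations(labels, 2)
    ]
    if correction is not None and results:
        ps = np.array([r.p_value for r in results])
        if correction == "bonferroni":
            adj = np.minimum(ps * ps.size, 1.0)
        elif correction == "bh":
            order = np.argsort(ps)
            ranked = ps[order] * ps.size / (np.arange(ps.size) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            adj = np.empty_like(ps)
            adj[order] = np.minimum(ranked, 1.0)
        else:
            raise ValueError(f"unknown correction {correction!r}")
        results = [
            WelchResult(r.t_statistic, r.dof, float(p), r.groups)
            for r, p in zip(results, adj)
        ]
    return results


def ols_r2(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least-squares fit of y on x with R² = 1 - SSres/SStot.

    Constant x is rejected; constant y returns R² = 0 by convention.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("need at least three points")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant; no regression line is defined")
    if np.ptp(yv) == 0:
        return RegressionResult(0.0, float(yv[0]), 0.0, int(xv.size))
    fit = sps.linregress(xv, yv)
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2), int(xv.size)
    )


def pca_counts(
    matrix: pd.DataFrame | np.ndarray,
    *,
    scale: bool = False,
    columns: Sequence[str] | None = None,
) -> PCAResult:
    """Covariance PCA of an organisms x categories count matrix.

    Columns are mean-centred; with ``scale`` they are additionally divided
    by their sample SD (correlation PCA).  Variance fractions are the
    eigenvalue shares, non-increasing and summing to 1.  Each component's
    sign is fixed so its largest-magnitude loading is positive.
    """
    if isinstance(matrix, pd.DataFrame):
        cols = tuple(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        cols = tuple(columns) if columns is not None else tuple(
            f"x{i}" for i in range(X.shape[1])
        )
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least three observations")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing cells")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            names = [cols[i] for i in dead]
            raise ValueError(f"zero-variance columns with scale=True: {names}")
        Xc = Xc / sd
    # SVD of the centred data == eigendecomposition of its covariance
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    total = eigvals.sum()
    if total == 0:
        raise ValueError("matrix has no variance")
    # sign convention: largest-magnitude loading of each component positive
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U * s
    return PCAResult(
        variance_fraction=eigvals / total,
        loadings=Vt,
        scores=scores,
        columns=cols,
    )


def category_matrix(profiles_frame: pd.DataFrame) -> pd.DataFrame:
    """Extract the organisms x 6 category count matrix from a profile table."""
    cols = [f"n_{c}" for c in CATEGORY_ORDER]
    missing = [c for c in cols if c not in profiles_frame.columns]
    if missing:
        raise ValueError(f"profile table missing category columns {missing}")
    m = profiles_frame.set_index("tag")[cols] if "tag" in profiles_frame.columns \
        else profiles_frame[cols]
    return m.rename(columns=dict(zip(cols, CATEGORY_ORDER)))
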