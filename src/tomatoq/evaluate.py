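"""Composite quality scoring, group comparisons, correlation and PCA.

The membership-function composite index min–max normalises every quality
indicator across the variety panel,

    u_ij = (x_ij − min_j) / (max_j − min_j)          (larger is better)
    u_ij = 1 − (x_ij − min_j) / (max_j − min_j)      (smaller is better)

and averages over indicators to a per-variety composite score in [0, 1];
varieties are ranked by descending score.  Alongside it: percent
differences between group means, Pearson correlation matrices with
t-based two-sided p-values and significance stars, standardized PCA with
a deterministic sign convention, and 95% confidence ellipses for group
score clouds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

logger = logging.getLogger(__name__)

__all__ = [
    "IndicatorMatrix",
    "MembershipResult",
    "CorrelationResult",
    "PCAResult",
    "ConfidenceEllipse",
    "membership",
    "composite_scores",
    "group_percent_difference",
    "pearson_matrix",
    "pca",
    "ellipse_95",
]


class DegenerateIndicatorError(ValueError):
    """All values of an indicator coincide: min–max normalisation undefined."""


@dataclass
class IndicatorMatrix:
    """Varieties × indicators value matrix with per-indicator directions.

    ``directions`` maps indicator → 'positive' (larger is better) or
    'negative' (smaller is better); unlisted indicators default to
    positive.  ``groups`` optionally labels each variety's group.
    """

    values: pd.DataFrame  # index: varieties, columns: indicators
    directions: Mapping[str, str] | None = None
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"indicator matrix has missing values in {bad}")
        dirs = dict(self.directions or {})
        for k, v in dirs.items():
            if v not in ("positive", "negative"):
                raise ValueError(f"direction for {k!r} must be positive|negative")
        self.directions = dirs
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(self.values.index)

    def direction(self, indicator: str) -> str:
        return self.directions.get(indicator, "positive")


@dataclass
class MembershipResult:
    """Per-indicator memberships, per-variety composite scores and ranks."""

    memberships: pd.DataFrame  # varieties × non-degenerate indicators, in [0,1]
    composite: pd.Series  # per-variety mean membership
    rank: pd.Series  # 1 = best; permutation of 1..n
    n_used: int  # indicators averaged (degenerate ones excluded)
    excluded: tuple[str, ...] = ()  # degenerate indicators


def membership(x: float, xmin: float, xmax: float, direction: str = "positive") -> float:
    """Min–max membership of one indicator value, in [0, 1].

    For a 'negative' indicator (smaller is better) the normalised value is
    inverted.  ``xmax == xmin`` is a degenerate indicator and raises
    :class:`DegenerateIndicatorError`; x outside [xmin, xmax] is a domain
    error.
    """
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be positive|negative, got {direction!r}")
    if xmax == xmin:
        raise DegenerateIndicatorError(
            f"degenerate indicator: min == max == {xmin}"
        )
    if xmax < xmin:
        raise ValueError("xmax must exceed xmin")
    if not xmin <= x <= xmax:
        raise ValueError(f"x={x} outside [{xmin}, {xmax}]")
    u = (x - xmin) / (xmax - xmin)
    return 1.0 - u if direction == "negative" else u


def composite_scores(matrix: IndicatorMatrix) -> MembershipResult:
    """Membership-function composite score and rank for every variety.

    Degenerate indicators (max == min) carry no discriminating
    information; they are excluded from the average with a warning, and
    the divisor n adjusts accordingly.  Ranks are by descending composite
    score, ties broken by input order (stable).
    """
    if len(matrix.values) < 2:
        raise ValueError("composite scoring needs at least 2 varieties")
    cols = {}
    excluded = []
    for ind in matrix.values.columns:
        col = matrix.values[ind].astype(float)
        lo, hi = col.min(), col.max()
        if hi == lo:
            excluded.append(ind)
            continue
        u = (col - lo) / (hi - lo)
        if matrix.direction(ind) == "negative":
            u = 1.0 - u
        cols[ind] = u
    if excluded:
        logger.warning("excluding degenerate indicators: %s", excluded)
    if not cols:
        raise ValueError("all indicators are degenerate; composite score undefined")
    memberships = pd.DataFrame(cols)
    composite = memberships.mean(axis=1)
    order = np.argsort(-composite.to_numpy(), kind="stable")
    rank = pd.Series(0, index=composite.index, dtype=int)
    rank.iloc[order] = np.arange(1, len(composite) + 1)
    return MembershipResult(
        memberships=memberships,
        composite=composite.rename("composite"),
        rank=rank.rename("rank"),
        n_used=memberships.shape[1],
        excluded=tuple(excluded),
    )


def group_percent_difference(
    values: pd.Series, groups: pd.Series, a: str, b: str
) -> float:
    """Percent by which group ``a``'s mean exceeds group ``b``'s: (ā/b̄ − 1)·100."""
    values = pd.Series(values)
    groups = pd.Series(groups)
    mean_a = values[groups.to_numpy() == a].mean()
    mean_b = values[groups.to_numpy() == b].mean()
    if np.isnan(mean_a) or np.isnan(mean_b):
        raise ValueError(f"empty group among ({a!r}, {b!r})")
    if mean_b == 0:
        raise ValueError(f"group {b!r} has zero mean; percent difference undefined")
    return (mean_a / mean_b - 1.0) * 100.0


@dataclass
class CorrelationResult:
    """Pearson r, two-sided p, and significance stars ('' | '*' | '**')."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    constant_columns: tuple[str, ...] = ()


def pearson_matrix(data: pd.DataFrame) -> CorrelationResult:
    """All-pairs Pearson correlation with t-based significance.

    p-values come from t = r·√((n−2)/(1−r²)) on n−2 df, two-sided; stars
    mark p < 0.05 (*) and p < 0.01 (**).  Constant columns make r
    undefined for their pairs: those entries are NaN and the columns are
    reported in ``constant_columns`` rather than silently dropped.
    """
    X = data.astype(float)
    n = len(X)
    if n < 3:
        raise ValueError("need at least 3 observations for significance testing")
    sd = X.std(ddof=0)
    constant = tuple(X.columns[sd == 0])
    if constant:
        logger.warning("constant columns (r undefined): %s", list(constant))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X.to_numpy(), rowvar=False)
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        rr = np.where(np.abs(r) < 1.0, r, np.nan)
        t = r * np.sqrt((n - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    cols = X.columns
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    np.fill_diagonal(p_df.to_numpy(), 0.0)
    stars = pd.DataFrame("", index=cols, columns=cols)
    stars = stars.mask(p_df < 0.05, "*").mask(p_df < 0.01, "**")
    np.fill_diagonal(stars.to_numpy(), "")
    for c in constant:
        r_df.loc[c, :] = np.nan
        r_df.loc[:, c] = np.nan
        p_df.loc[c, :] = np.nan
        p_df.loc[:, c] = np.nan
        stars.loc[c, :] = ""
        stars.loc[:, c] = ""
    return CorrelationResult(r=r_df, p=p_df, stars=stars, constant_columns=constant)


@dataclass
class PCAResult:
    """Standardized-PCA scores, unit-norm loadings and variance fractions."""

    scores: pd.DataFrame  # varieties × components
    loadings: pd.DataFrame  # indicators × components, orthonormal columns
    explained_variance_fraction: np.ndarray  # per component, non-increasing


def pca(data: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA on column-standardized data with a deterministic sign convention.

    Columns are centred and scaled to unit (population) variance; the
    decomposition is by singular values.  Each component is flipped so
    its largest-magnitude loading is positive, making outputs
    reproducible across BLAS implementations.  A zero-variance column
    cannot be standardized and raises, naming the indicator.
    """
    X = data.astype(float)
    sd = X.std(ddof=0)
    zero = X.columns[sd == 0].tolist()
    if zero:
        raise ValueError(f"cannot standardize zero-variance indicators: {zero}")
    Z = (X - X.mean()) / sd
    max_rank = min(len(X), X.shape[1])
    k = max_rank if n_components is None else int(n_components)
    if not 1 <= k <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}], got {k}")
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(Z.to_numpy())
    loadings = model.components_.T  # indicators × components
    # sign convention: largest-|loading| entry of each component positive
    flips = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flips[flips == 0] = 1.0
    loadings = loadings * flips
    scores = scores * flips
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
        explained_variance_fraction=model.explained_variance_ratio_.copy(),
    )


@dataclass
class ConfidenceEllipse:
    """95% confidence ellipse of a 2-D point cloud (bivariate-normal model)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    angle_deg: float  # orientation of the major axis, counter-clockwise

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse (Mahalanobis test)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        theta = math.radians(self.angle_deg)
        rot = np.array(
            [[math.cos(theta), math.sin(theta)], [-math.sin(theta), math.cos(theta)]]
        )
        local = pts @ rot.T
        a, b = self.semi_axes
        if b == 0:
            return np.zeros(len(local), dtype=bool)
        return (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 <= 1.0


def ellipse_95(points: np.ndarray | pd.DataFrame) -> ConfidenceEllipse:
    """95% confidence ellipse from the sample covariance of PC1–PC2 points.

    Axes are the covariance eigenvectors scaled by √(λ·χ²₀.₉₅(2)); under a
    bivariate normal, ~95% of draws fall inside at large n.  Needs ≥ 3
    points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of PC1-PC2 points")
    if len(pts) < 3:
        raise ValueError("confidence ellipse needs at least 3 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    q = stats.chi2.ppf(0.95, df=2)
    semi = np.sqrt(eigvals * q)
    angle = math.degrees(math.atan2(eigvecs[1, 0], eigvecs[0, 0]))
    return ConfidenceEllipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        angle_deg=float(angle),
    )
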