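"""Variance comparison, PCA of the Z-score covariance, density ellipses.

Three related views of population morphological variation:

* per-trait variance with explicit degrees-of-freedom conventions (own-mean,
  pooled per-subgroup, or external reference-mean centering), and the
  per-trait variance-ratio profile between two panels;
* PCA of the column-centered (unscaled) Z-score matrix -- the Z-scores are
  already variance-standardized by construction, so the covariance (not
  correlation) matrix is decomposed;
* bivariate equiprobability density ellipses in a two-dimensional PC score
  space: a Gaussian (or equal-weight two-component mixture) is fit to the
  scores, its density evaluated on a 200 x 200 grid, and the contour level
  enclosing a given probability mass located; the areas of two populations'
  ellipses at the same mass level compare their broadness (their ratio
  equals sqrt(det Sigma_A / det Sigma_B)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal
from sklearn.decomposition import PCA

from morphovar.zscore import ZScoreMatrix

logger = logging.getLogger(__name__)


@dataclass
class VarianceEstimate:
    param_id: str
    group: str
    variance: float
    df_used: int
    centering: str


@dataclass
class PCModel:
    """Loadings, scores and explained variance of a Z-matrix PCA."""

    loadings: pd.DataFrame  # parameter x component
    scores: pd.DataFrame  # strain x component
    explained_variance: np.ndarray
    explained_ratio: np.ndarray
    cumulative_ratio: np.ndarray
    mean_: np.ndarray  # column means removed before projection

    def transform(self, vectors) -> np.ndarray:
        """Project new parameter-space vectors into the PC score space."""
        v = np.atleast_2d(np.asarray(vectors, float))
        return (v - self.mean_) @ self.loadings.to_numpy()

    def n_components_for_ratio(self, target: float) -> int:
        """Smallest number of leading components reaching the cumulative ratio."""
        return int(np.searchsorted(self.cumulative_ratio, target) + 1)


@dataclass
class EllipseSpec:
    """A fitted bivariate density with its equiprobability contour."""

    mean: np.ndarray
    covariance: np.ndarray
    mass_level: float
    level: float  # density value of the contour
    grid: np.ndarray  # grid_size x grid_size density values
    x_range: tuple
    y_range: tuple
    area: float  # grid-estimated area enclosed by the contour
    mixture_means: list = field(default_factory=list)


def _as_frame(z) -> pd.DataFrame:
    return z.z if isinstance(z, ZScoreMatrix) else pd.DataFrame(z)


def per_trait_variance(
    values_by_subgroup: dict,
    centering: str = "own_mean",
    center: float | None = None,
    param_id: str = "",
) -> VarianceEstimate:
    """Variance of one trait under an explicit centering convention.

    ``own_mean``: all values pooled and centered by their common mean,
    SS / (n - 1).  ``per_subgroup_mean``: each subgroup centered by its own
    mean, pooled SS divided by sum(n_g - 1) (e.g. two parental triplicates
    give df 4).  ``reference_mean``: centered by the externally supplied
    ``center``, SS / n (unbiased when the center is known).
    """
    groups = {g: np.asarray(v, float) for g, v in values_by_subgroup.items()}
    for g, v in groups.items():
        if v.size == 0:
            raise ValueError(f"subgroup {g!r} is empty")
    allv = np.concatenate(list(groups.values()))
    if allv.size < 2:
        raise ValueError("need at least two values in total")
    label = "+".join(sorted(groups))
    if centering == "own_mean":
        df = allv.size - 1
        ss = np.sum((allv - allv.mean()) ** 2)
    elif centering == "per_subgroup_mean":
        df = sum(v.size - 1 for v in groups.values())
        ss = sum(np.sum((v - v.mean()) ** 2) for v in groups.values())
    elif centering == "reference_mean":
        if center is None:
            raise ValueError("reference_mean centering requires a center")
        df = allv.size
        ss = np.sum((allv - center) ** 2)
    else:
        raise ValueError(f"unknown centering {centering!r}")
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    return VarianceEstimate(param_id, label, float(ss / df), int(df), centering)


def variance_ratio_profile(zA, zB) -> tuple[pd.Series, int]:
    """Per-parameter var(A)/var(B) with own-mean centering, and the count > 1.

    Each panel's variance uses its own mean and divisor n-1 (e.g. 109 for a
    110-strain panel).  Parameters with zero denominator variance get an
    infinite ratio and are excluded from the exceedance count with a log.
    """
    A, B = _as_frame(zA), _as_frame(zB)
    shared = [c for c in A.columns if c in set(B.columns)]
    if not shared:
        raise ValueError("no shared parameter columns")
    vA = A[shared].var(axis=0, ddof=1)
    vB = B[shared].var(axis=0, ddof=1)
    ratio = vA / vB
    inf_mask = ~np.isfinite(ratio)
    if inf_mask.any():
        logger.info(
            "variance_ratio_profile: %d parameters with zero denominator excluded",
            int(inf_mask.sum()),
        )
    count = int((ratio[~inf_mask] > 1).sum())
    return ratio, count


def pca_z(z) -> PCModel:
    """Column-centered, unscaled PCA of a Z-score matrix."""
    zf = _as_frame(z)
    X = zf.to_numpy(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least two strains and two parameters")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant matrix has no principal components")
    k = min(X.shape)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    names = [f"PC{j + 1}" for j in range(k)]
    ev = model.explained_variance_
    ratio = ev / ev.sum()
    return PCModel(
        loadings=pd.DataFrame(loadings, index=zf.columns, columns=names),
        scores=pd.DataFrame(scores, index=zf.index, columns=names),
        explained_variance=ev,
        explained_ratio=ratio,
        cumulative_ratio=np.cumsum(ratio),
        mean_=model.mean_,
    )


def _density_grid(pdfs, weights, points, grid_size):
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    sd = points.std(axis=0, ddof=1)
    x = np.linspace(lo[0] - 3 * sd[0], hi[0] + 3 * sd[0], grid_size)
    y = np.linspace(lo[1] - 3 * sd[1], hi[1] + 3 * sd[1], grid_size)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    dens = np.zeros(len(pts))
    for w, pdf in zip(weights, pdfs):
        dens += w * pdf.pdf(pts)
    return dens.reshape(grid_size, grid_size), (x[0], x[-1]), (y[0], y[-1])


def equiprobability_ellipse(
    points,
    mass_level: float = 0.95,
    mixture=None,
    grid_size: int = 200,
) -> EllipseSpec:
    """Fit a bivariate normal (or two-component mixture) and find its contour.

    The density is evaluated on a ``grid_size x grid_size`` grid spanning the
    data range plus three marginal standard deviations; the contour level is
    the density value whose superlevel set encloses ``mass_level`` of the
    fitted probability mass (located by sorting grid cells by density).
    """
    P = np.asarray(points, float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("points must be an n x 2 array")
    if P.shape[0] < 3:
        raise ValueError("need at least three points")
    sets = [P]
    if mixture is not None:
        Q = np.asarray(mixture, float)
        if Q.shape[0] < 3:
            raise ValueError("need at least three points in the second set")
        sets.append(Q)
    pdfs, means, covs = [], [], []
    for S in sets:
        mu = S.mean(axis=0)
        cov = np.cov(S, rowvar=False)
        if np.linalg.det(cov) <= 0 or not np.all(np.isfinite(cov)):
            raise ValueError("degenerate (collinear) points")
        pdfs.append(multivariate_normal(mu, cov))
        means.append(mu)
        covs.append(cov)
    w = 1.0 / len(sets)
    allpts = np.vstack(sets)
    grid, x_range, y_range = _density_grid(pdfs, [w] * len(sets), allpts, grid_size)
    dx = (x_range[1] - x_range[0]) / (grid_size - 1)
    dy = (y_range[1] - y_range[0]) / (grid_size - 1)
    cell = dx * dy
    flat = np.sort(grid.ravel())[::-1]
    cum = np.cumsum(flat) * cell
    idx = int(np.searchsorted(cum, mass_level))
    idx = min(idx, len(flat) - 1)
    level = float(flat[idx])
    area = float((grid >= level).sum() * cell)
    if len(sets) == 1:
        mean, cov = means[0], covs[0]
    else:
        # moments of the equal-weight mixture
        mean = np.mean(means, axis=0)
        cov = sum(
            w * (c + np.outer(m - mean, m - mean)) for m, c in zip(means, covs)
        )
    return EllipseSpec(
        mean=np.asarray(mean),
        covariance=np.asarray(cov),
        mass_level=mass_level,
        level=level,
        grid=grid,
        x_range=x_range,
        y_range=y_range,
        area=area,
        mixture_means=[np.asarray(m) for m in means] if len(sets) > 1 else [],
    )


def broadness_ratio(ellipse_a: EllipseSpec, ellipse_b: EllipseSpec) -> float:
    """Area ratio of two equiprobability ellipses at the same mass level.

    For Gaussian contours at a common mass level the area ratio equals
    sqrt(det Sigma_A / det Sigma_B); this closed form is used rather than the
    grid areas so the ratio is resolution-independent.
    """
    if ellipse_a.mass_level != ellipse_b.mass_level:
        raise ValueError("ellipses must share the same mass level")
    dA = np.linalg.det(ellipse_a.covariance)
    dB = np.linalg.det(ellipse_b.covariance)
    return float(np.sqrt(dA / dB))
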