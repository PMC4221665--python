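"""Mahalanobis ranking and representative-strain selection.

Strains are ranked by their Mahalanobis distance from the center of the
wild-type replicate Z-score distribution -- a unitless, scale-invariant
multivariate distance.  The representative set is the top-k strains by
distance plus k_edge additional strains lying at the edge of the PC1..PC20
score space, so that directions of variation not captured by sheer global
distance are still represented.

With many more parameters than reference replicates the sample covariance is
singular; the default estimator is therefore the diagonal of the sample
covariance (variance per parameter, floored), with optional linear shrinkage
of the full covariance toward its diagonal, or the full sample covariance
when the reference panel is large enough.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from morphovar.zscore import ZScoreMatrix
from morphovar.variance import pca_z


@dataclass
class MahalanobisResult:
    strain_id: str
    distance: float
    rank: int
    selection_reason: str = "none"


def _as_frame(z) -> pd.DataFrame:
    return z.z if isinstance(z, ZScoreMatrix) else pd.DataFrame(z)


def mahalanobis_distances(
    z,
    reference_replicates,
    covariance: str = "diagonal",
    shrinkage: float = 0.0,
    floor: float = 1e-6,
) -> list[MahalanobisResult]:
    """Mahalanobis distance of every strain from the reference center.

    ``covariance`` selects the reference covariance estimator: ``"diagonal"``
    (default; per-parameter variances with a floor), ``"shrinkage"`` (linear
    combination ``(1-w) * S + w * diag(S)`` with weight ``shrinkage``), or
    ``"full"`` (sample covariance; requires more replicates than parameters).
    Ties in distance are broken by ascending strain_id.
    """
    zf = _as_frame(z)
    ref = _as_frame(reference_replicates)
    if ref.shape[0] < 2:
        raise ValueError("need at least two reference replicate rows")
    ref = ref[zf.columns]
    mu = ref.mean(axis=0).to_numpy()
    centered = zf.to_numpy(float) - mu
    if covariance == "diagonal":
        var = np.maximum(ref.var(axis=0, ddof=1).to_numpy(), floor)
        d2 = (centered**2 / var).sum(axis=1)
    else:
        S = np.cov(ref.to_numpy(float), rowvar=False)
        if covariance == "shrinkage":
            S = (1 - shrinkage) * S + shrinkage * np.diag(np.maximum(np.diag(S), floor))
        elif covariance != "full":
            raise ValueError(f"unknown covariance mode {covariance!r}")
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"reference covariance is not invertible (condition number {cond:.3g}); "
                "use diagonal or shrinkage regularization"
            )
        d2 = np.einsum("ij,ij->i", centered, np.linalg.solve(S, centered.T).T)
    dist = np.sqrt(np.maximum(d2, 0.0))
    order = sorted(zip(zf.index, dist), key=lambda t: (-t[1], t[0]))
    ranks = {s: i + 1 for i, (s, _) in enumerate(order)}
    return [
        MahalanobisResult(strain_id=s, distance=float(d), rank=ranks[s])
        for s, d in zip(zf.index, dist)
    ]


def select_strains(
    distances: list[MahalanobisResult],
    z,
    k_top: int = 100,
    k_edge: int = 20,
    n_pcs: int = 20,
) -> list[MahalanobisResult]:
    """Representative set: top-k by distance plus PC-space edge strains.

    The ``k_top`` strains with the highest Mahalanobis distance are selected
    first (reason ``top_distance``).  Among the remaining strains, PCA scores
    over the first ``n_pcs`` components are standardized per component and
    the ``k_edge`` strains with the largest maximum absolute standardized
    score are added (reason ``pc_edge``).  All ties break by ascending
    strain_id.
    """
    zf = _as_frame(z)
    n = len(distances)
    if k_top + k_edge > n:
        raise ValueError("k_top + k_edge exceeds the number of strains")
    ranked = sorted(distances, key=lambda r: (-r.distance, r.strain_id))
    results = {r.strain_id: MahalanobisResult(r.strain_id, r.distance, r.rank) for r in distances}
    top = [r.strain_id for r in ranked[:k_top]]
    for s in top:
        results[s].selection_reason = "top_distance"
    if k_edge > 0:
        model = pca_z(zf)
        n_avail = model.scores.shape[1]
        if n_pcs > n_avail:
            import warnings

            warnings.warn(
                f"n_pcs={n_pcs} exceeds available components ({n_avail}); clipped"
            )
            n_pcs = n_avail
        scores = model.scores.iloc[:, :n_pcs]
        sd = scores.std(axis=0, ddof=1).replace(0.0, np.nan)
        edge_stat = (scores / sd).abs().max(axis=1)
        remainder = edge_stat.drop(index=top).sort_index()
        edge = remainder.sort_values(ascending=False, kind="stable").index[:k_edge]
        for s in edge:
            results[s].selection_reason = "pc_edge"
    return [results[s] for s in zf.index]


def selection_table(results: list[MahalanobisResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.strain_id, r.distance, r.rank, r.selection_reason) for r in results],
        columns=["strain_id", "distance", "rank", "selection_reason"],
    )
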