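"""Detection of strains beyond natural variation ("heteroclite" strains).

For each principal component, the natural strains' score spread is estimated
by centering at the wild-type reference's score and taking the
root-mean-square deviation (divisor n, unbiased for a known center).  Each
deletion strain then receives a one-sample two-sided test of normal
distribution per component,

    z = (score - center) / sd_natural,   p = 2 * (1 - Phi(|z|)),

with Bonferroni family-wise control over m = n_strains x n_components tests
(e.g. 110 strains x PC1-PC4 = 440 tests).  A strain significant in at least
one component is called heteroclite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_COMPONENTS = (1, 2, 3, 4)


@dataclass
class DetectionResult:
    strain_id: str
    component: str
    z_stat: float
    p_two_sided: float
    significant: bool
    m_tests: int
    alpha: float


@dataclass
class DetectionSummary:
    """All per-strain x component tests plus the heteroclite strain set."""

    results: list[DetectionResult]
    heteroclites: list[str]
    m_tests: int
    alpha: float
    sd_natural: pd.Series

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.strain_id, r.component, r.z_stat, r.p_two_sided, r.significant)
                for r in self.results
            ],
            columns=["strain_id", "component", "z_stat", "p_two_sided", "significant"],
        )


def _component_cols(components) -> list[str]:
    return [c if isinstance(c, str) else f"PC{c}" for c in components]


def natural_variance_per_pc(
    natural_scores: pd.DataFrame, reference_center
) -> pd.Series:
    """Per-component sd of natural strains around the reference center.

    sd_c = sqrt( sum_i (score_ic - center_c)^2 / n ), the unbiased estimator
    when the center is externally known.  A zero sd is a degenerate component
    and raises.
    """
    scores = pd.DataFrame(natural_scores)
    if scores.shape[0] < 2:
        raise ValueError("need at least two natural strains")
    center = pd.Series(reference_center, index=scores.columns) if not isinstance(
        reference_center, pd.Series
    ) else reference_center.reindex(scores.columns)
    sd = np.sqrt(((scores - center) ** 2).mean(axis=0))
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"degenerate component(s) with zero natural variance: {bad}")
    return sd


def detect(
    deletion_scores: pd.DataFrame,
    natural_scores: pd.DataFrame,
    reference_center,
    components=DEFAULT_COMPONENTS,
    alpha: float = 0.05,
) -> DetectionSummary:
    """One-sample two-sided normal tests per deletion strain per component."""
    cols = _component_cols(components)
    dele = pd.DataFrame(deletion_scores)
    nat = pd.DataFrame(natural_scores)
    missing = [c for c in cols if c not in dele.columns or c not in nat.columns]
    if missing:
        raise KeyError(f"components missing from score matrices: {missing}")
    center = (
        reference_center.reindex(cols)
        if isinstance(reference_center, pd.Series)
        else pd.Series(np.asarray(reference_center, float)[: len(cols)], index=cols)
    )
    sd = natural_variance_per_pc(nat[cols], center)
    m = dele.shape[0] * len(cols)
    if dele.shape[0] == 0:
        return DetectionSummary([], [], 0, alpha, sd)
    zmat = (dele[cols].to_numpy(float) - center.to_numpy()) / sd.to_numpy()
    pmat = 2.0 * norm.sf(np.abs(zmat))
    sigmat = pmat < alpha / m
    results: list[DetectionResult] = []
    hetero: set[str] = set()
    for i, s in enumerate(dele.index):
        for j, c in enumerate(cols):
            sig = bool(sigmat[i, j])
            results.append(
                DetectionResult(s, c, float(zmat[i, j]), float(pmat[i, j]), sig, m, alpha)
            )
            if sig:
                hetero.add(s)
    return DetectionSummary(results, sorted(hetero), m, alpha, sd)


def overlap_summary(summary: DetectionSummary) -> dict:
    """Per-component detection counts and cross-component overlaps."""
    if not summary.results:
        raise ValueError("empty detection results")
    per_component: dict[str, int] = {}
    per_strain: dict[str, int] = {}
    for r in summary.results:
        per_component.setdefault(r.component, 0)
        if r.significant:
            per_component[r.component] += 1
            per_strain[r.strain_id] = per_strain.get(r.strain_id, 0) + 1
    exactly_one = sum(1 for v in per_strain.values() if v == 1)
    two_or_more = sum(1 for v in per_strain.values() if v >= 2)
    return {
        "per_component": per_component,
        "exactly_one_component": exactly_one,
        "multiple_components": two_or_more,
        "union": len(per_strain),
    }


def planted_power_simulation(
    magnitudes,
    n_natural: int = 37,
    n_deletion: int = 110,
    n_components: int = 4,
    planted_component: int = 1,
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Monte-Carlo detection probability of one planted strain per magnitude.

    Score-space simulation: natural and deletion scores are standard normal
    around the reference center (the global null), and one deletion strain is
    shifted by ``magnitude * sd_natural`` along the planted component.  The
    returned mapping gives, per magnitude, the fraction of replicates in
    which the planted strain is called heteroclite.
    """
    rng = np.random.default_rng(seed)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    planted_col = f"PC{planted_component}"
    center = pd.Series(0.0, index=cols)
    power = {}
    for mag in magnitudes:
        hits = 0
        for _ in range(n_reps):
            nat = pd.DataFrame(
                rng.standard_normal((n_natural, n_components)), columns=cols
            )
            dele = pd.DataFrame(
                rng.standard_normal((n_deletion, n_components)),
                columns=cols,
                index=[f"DEL{i + 1:03d}" for i in range(n_deletion)],
            )
            sd_true = 1.0
            dele.loc["DEL001", planted_col] += mag * sd_true
            summary = detect(dele, nat, center, components=cols, alpha=alpha)
            if "DEL001" in summary.heteroclites:
                hits += 1
        power[float(mag)] = hits / n_reps
    return power
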