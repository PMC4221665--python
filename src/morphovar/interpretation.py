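"""Which parameters characterize each principal component.

A parameter characterizes a PC when its Z column correlates strongly with
the PC score column: the loading (correlation) must exceed a threshold
(default 0.6) and the correlation-test p-value must fall below a corrected
threshold (default 1.95e-3).

Correlated parameters often measure the same underlying morphology.  To
collapse them, a second PCA is run on wild-type replicate Z-scores
(null-distributed data): parameters whose null-PCA loadings pass the same
significance rule on a common null component co-vary even without any
strain effect and are grouped as biologically equivalent, each group
represented by its member with the strongest loading on the primary PC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from morphovar.variance import PCModel, pca_z

logger = logging.getLogger(__name__)

DEFAULT_LOADING_THRESHOLD = 0.6
DEFAULT_P_THRESHOLD = 1.95e-3


@dataclass
class LoadingCall:
    param_id: str
    component: str
    loading: float
    p_value: float
    passes: bool


@dataclass
class ParameterGroup:
    """Parameters deemed biologically equivalent by the null-replicate PCA."""

    params: list[str]
    representative: str
    null_components: list[str] = field(default_factory=list)


def _as_frame(z) -> pd.DataFrame:
    from morphovar.zscore import ZScoreMatrix

    return z.z if isinstance(z, ZScoreMatrix) else pd.DataFrame(z)


def significant_loadings(
    z,
    pc_model: PCModel,
    components=("PC1", "PC2", "PC4"),
    loading_threshold: float = DEFAULT_LOADING_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[LoadingCall]:
    """Correlation loadings of every parameter on the requested components."""
    zf = _as_frame(z)
    cols = [c if isinstance(c, str) else f"PC{c}" for c in components]
    missing = [c for c in cols if c not in pc_model.scores.columns]
    if missing:
        raise KeyError(f"components not in the PC model: {missing}")
    calls: list[LoadingCall] = []
    for p in zf.columns:
        x = zf[p].to_numpy(float)
        if np.var(x) == 0:
            logger.info("significant_loadings: constant column %s skipped", p)
            continue
        for c in cols:
            r, pv = pearsonr(x, pc_model.scores[c].to_numpy())
            calls.append(
                LoadingCall(
                    param_id=p,
                    component=c,
                    loading=float(r),
                    p_value=float(pv),
                    passes=bool(abs(r) > loading_threshold and pv < p_threshold),
                )
            )
    return calls


def calls_table(calls: list[LoadingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.param_id, c.component, c.loading, c.p_value, c.passes) for c in calls],
        columns=["param_id", "component", "loading", "p_value", "passes"],
    )


def representative_parameters(
    calls: list[LoadingCall],
    null_z,
    loading_threshold: float = DEFAULT_LOADING_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[ParameterGroup]:
    """Group passing parameters that co-vary in null-distributed data.

    A PCA is run on the wild-type replicate Z matrix; each passing parameter
    is assigned the set of null components on which it passes the same
    (|loading|, p) rule.  Parameters sharing any null component merge into
    one group (transitively); parameters passing on no null component stay
    singletons.  The representative of each group is the member with the
    largest absolute loading on its primary-analysis component (ties broken
    by ascending param_id).
    """
    nz = _as_frame(null_z)
    if nz.shape[0] < 3:
        raise ValueError("need at least three null replicate rows")
    passing = [c for c in calls if c.passes]
    if not passing:
        raise ValueError("no passing loading calls to group")
    # strongest primary |loading| per parameter, for representative choice
    best: dict[str, float] = {}
    for c in passing:
        best[c.param_id] = max(best.get(c.param_id, 0.0), abs(c.loading))
    params = sorted(best)
    null_model = pca_z(nz[params]) if len(params) > 1 else None
    membership: dict[str, set[str]] = {p: set() for p in params}
    if null_model is not None:
        for p in params:
            x = nz[p].to_numpy(float)
            if np.var(x) == 0:
                continue
            for c in null_model.scores.columns:
                s = null_model.scores[c].to_numpy()
                if np.var(s) < 1e-12:
                    continue
                r, pv = pearsonr(x, s)
                if abs(r) > loading_threshold and pv < p_threshold:
                    membership[p].add(c)
    # union-find over shared null components
    parent = {p: p for p in params}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_component: dict[str, list[str]] = {}
    for p, comps in membership.items():
        for c in comps:
            by_component.setdefault(c, []).append(p)
    for members in by_component.values():
        for other in members[1:]:
            union(members[0], other)
    clusters: dict[str, list[str]] = {}
    for p in params:
        clusters.setdefault(find(p), []).append(p)
    groups = []
    for members in clusters.values():
        members = sorted(members)
        rep = sorted(members, key=lambda p: (-best[p], p))[0]
        comps = sorted(set().union(*(membership[p] for p in members)))
        groups.append(ParameterGroup(params=members, representative=rep, null_components=comps))
    groups.sort(key=lambda g: g.params[0])
    return groups
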