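"""GO-level association statistics and auxiliary group comparisons.

Given the detected (heteroclite) genes, GO terms annotated to at least
``min_hits`` of them among terms annotated to fewer than ``max_genome``
genes genome-wide are tested for association with morphology: the PC score
profile (PC1, PC2, PC4 by default) is regressed on the strain-background
factor ``s`` under the null model and on ``s`` plus the GO-membership dummy
``x`` under the alternative, and the two multivariate linear models are
compared by an F-test (Pillai trace by default, Wilks' lambda optional).

GO terms are clustered by the similarity of their annotated gene sets
(complete linkage on 1 - Jaccard distance).  Auxiliary comparisons of
fitness, protein abundance, and genetic-interaction degree between gene
groups use the Mann-Whitney U-test with continuity and tie corrections
(exact enumeration for small tie-free samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import f as f_dist
from scipy.stats import mannwhitneyu

#: Genetic-interaction score cutoffs: negative below, positive above.
EPSILON_NEGATIVE = -0.12
EPSILON_POSITIVE = 0.16
INTERACTION_P = 0.05


@dataclass(frozen=True)
class GOSet:
    go_id: str
    genes: frozenset
    genome_annotation_count: int
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"GO set {self.go_id!r} has an empty gene set")
        if self.genome_annotation_count < len(self.genes):
            raise ValueError(
                f"GO set {self.go_id!r}: genome annotation count below local gene count"
            )


@dataclass
class ManovaResult:
    go_id: str
    statistic: float
    F_approx: float
    df1: float
    df2: float
    p_value: float
    n_strains_used: int
    pillai_or_wilks: str


def read_gmt(path, genome_counts=None) -> list[GOSet]:
    """Read GO gene sets from a GMT file (go_id, description, genes...).

    ``genome_counts`` optionally maps go_id to the genome-wide annotation
    count; without it the local gene-set size is used.
    """
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            go_id, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            count = (genome_counts or {}).get(go_id, len(genes))
            sets.append(GOSet(go_id, frozenset(genes), count, desc))
    return sets


def select_gos(
    annotations: list[GOSet],
    focal_genes,
    min_hits: int = 3,
    max_genome: int = 100,
) -> list[GOSet]:
    """GO terms annotated to >= min_hits focal genes, below the genome cap."""
    focal = set(focal_genes)
    return [
        g
        for g in annotations
        if g.genome_annotation_count < max_genome and len(g.genes & focal) >= min_hits
    ]


def _design(factor) -> np.ndarray:
    """Intercept + treatment-coded dummies for a categorical factor."""
    factor = pd.Series(factor).astype(str)
    levels = sorted(factor.unique())
    X = [np.ones(len(factor))]
    for lev in levels[1:]:
        X.append((factor == lev).to_numpy(float))
    return np.column_stack(X)


def manova_go(
    scores: pd.DataFrame,
    background,
    membership,
    go_id: str = "",
    statistic: str = "pillai",
) -> ManovaResult:
    """Nested multivariate linear-model comparison for one GO term.

    Null model: scores ~ background factor.  Alternative: scores ~
    background + GO-membership dummy.  The hypothesis sum-of-squares matrix
    H and error matrix E yield the eigenvalues of E^-1 H, from which the
    Pillai trace (or Wilks' lambda) and its F approximation are computed;
    for a single-degree-of-freedom hypothesis the F statistic is exact.
    """
    Y = pd.DataFrame(scores).to_numpy(float)
    x = np.asarray(membership, float)
    if x.std() == 0:
        raise ValueError(f"GO {go_id or '?'} indistinguishable from background")
    if int(x.sum()) < 2:
        raise ValueError("need at least two member strains")
    X0 = _design(background)
    X1 = np.column_stack([X0, x])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("alternative design matrix is rank deficient")
    n, p = Y.shape

    def residual_cross(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ beta
        return R.T @ R

    E0 = residual_cross(X0)
    E1 = residual_cross(X1)
    H = E0 - E1
    q = X1.shape[1] - X0.shape[1]
    v = n - X1.shape[1]
    if v <= p:
        raise ValueError("too few error degrees of freedom for the multivariate test")
    lam = np.real(np.linalg.eigvals(np.linalg.solve(E1, H)))
    lam = np.clip(lam, 0.0, None)
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (v - p - 1) / 2.0
    if statistic == "pillai":
        V = float(np.sum(lam / (1.0 + lam)))
        df1 = s * (2 * m + s + 1)
        df2 = s * (2 * nn + s + 1)
        F = (df2 / df1) * (V / (s - V))
        stat = V
    elif statistic == "wilks":
        W = float(np.prod(1.0 / (1.0 + lam)))
        r = v - (p - q + 1) / 2.0
        u = (p * q - 2) / 4.0
        t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if p**2 + q**2 - 5 > 0 else 1.0
        df1 = p * q
        df2 = r * t - 2 * u
        F = ((1 - W ** (1 / t)) / (W ** (1 / t))) * (df2 / df1)
        stat = W
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    pval = float(f_dist.sf(F, df1, df2))
    return ManovaResult(
        go_id=go_id,
        statistic=stat,
        F_approx=float(F),
        df1=float(df1),
        df2=float(df2),
        p_value=pval,
        n_strains_used=n,
        pillai_or_wilks=statistic,
    )


def manova_table(
    scores: pd.DataFrame,
    background,
    deletion_gene_of_strain: dict,
    gos: list[GOSet],
    statistic: str = "pillai",
    include_unannotated: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the GO MANOVA across a selected GO list.

    For each GO, the strains entering the model are the background strains
    (natural + wild-type, membership 0) and the deletion strains whose
    deleted gene is annotated to the GO (membership 1); deletion strains
    with unannotated genes are excluded unless ``include_unannotated``.
    Significance is Bonferroni-corrected over the number of tested GOs.
    """
    rows = []
    strains = list(scores.index)
    bg = pd.Series(background, index=strains)
    for go in gos:
        member = pd.Series(
            [
                1.0
                if deletion_gene_of_strain.get(s) in go.genes
                else 0.0
                for s in strains
            ],
            index=strains,
        )
        is_deletion = pd.Series(
            [s in deletion_gene_of_strain for s in strains], index=strains
        )
        keep = ~is_deletion | (member == 1) if not include_unannotated else pd.Series(True, index=strains)
        try:
            res = manova_go(
                scores.loc[keep],
                bg.loc[keep],
                member.loc[keep],
                go_id=go.go_id,
                statistic=statistic,
            )
            rows.append(
                (go.go_id, res.statistic, res.F_approx, res.p_value, res.n_strains_used)
            )
        except ValueError:
            rows.append((go.go_id, np.nan, np.nan, np.nan, 0))
    out = pd.DataFrame(
        rows, columns=["go_id", "statistic", "F_approx", "p_value", "n_strains_used"]
    )
    m = out["p_value"].notna().sum()
    out["significant"] = out["p_value"] < (alpha / m if m else np.nan)
    return out


def cluster_gos(gos: list[GOSet], metric: str = "jaccard") -> np.ndarray:
    """Complete-linkage clustering of GO terms by gene-set dissimilarity.

    Distance is 1 - Jaccard (default) or Dice dissimilarity of the annotated
    gene sets; returns the scipy linkage matrix (merge order and heights),
    with rows ordered as in ``gos``.
    """
    if len(gos) < 2:
        raise ValueError("need at least two GO terms to cluster")
    ids = [g.go_id for g in gos]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate go_id in GO list")
    n = len(gos)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = gos[i].genes, gos[j].genes
            inter = len(a & b)
            if metric == "jaccard":
                d = 1.0 - inter / len(a | b)
            elif metric == "dice":
                d = 1.0 - 2.0 * inter / (len(a) + len(b))
            else:
                raise ValueError(f"unknown metric {metric!r}")
            D[i, j] = D[j, i] = d
    return linkage(squareform(D, checks=False), method="complete")


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (for group A) and two-sided p.

    Exact enumeration p when both samples have n <= 8 and no ties; otherwise
    the normal approximation with continuity and tie corrections.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def interaction_counts(records: pd.DataFrame, genes) -> pd.Series:
    """Per-gene number of significant genetic interactions.

    A record counts when (epsilon < -0.12 and p < 0.05) or (epsilon > 0.16
    and p < 0.05); interactions between the stringent cutoffs are ignored.
    Both partners of a counting record accrue the interaction.
    """
    counts = pd.Series(0, index=list(genes), dtype=int)
    if len(records) == 0:
        return counts
    sig = (records["p"] < INTERACTION_P) & (
        (records["epsilon"] < EPSILON_NEGATIVE) | (records["epsilon"] > EPSILON_POSITIVE)
    )
    for col in ("gene_a", "gene_b"):
        hits = records.loc[sig, col].value_counts()
        shared = counts.index.intersection(hits.index)
        counts.loc[shared] += hits.loc[shared].astype(int)
    return counts
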