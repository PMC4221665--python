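"""GLM trait normalization: per-strain Wald Z-scores against the reference.

Every trait value is reduced to a single normalized number per strain by a
two-group generalized linear model

    eta(E[y_i]) = beta0 + beta1 * x_i

where ``x_i`` is 0 for reference (wild-type) cultures and 1 for the strain's
cultures, ``eta`` is the family's link, and the Wald statistic
``z = beta1 / se(beta1)`` of the strain effect is the trait's Z-score.

Families are fit as follows:

* ``gamma`` -- GLM with log link; dispersion estimated by Pearson chi-square.
* ``beta`` -- mean-precision beta regression with logit mean link and a
  common precision across the two groups.
* ``binomial_od`` -- quasi-binomial: logit-link binomial GLM whose standard
  errors are inflated by the Pearson dispersion estimate.
* ``gaussian_cv`` -- ordinary least squares on the Lowess residuals (see
  :func:`normalize_cv`), which equals the pooled-variance two-sample
  statistic.

CV traits must first be uncoupled from their paired mean trait: their
dependence on the mean is removed by a robust locally weighted regression
(Lowess, smoothing span 0.4, three robustness iterations) across all
cultures, and the residuals are modeled as Gaussian.

A strain measured as a single culture is fit against the replicated
reference; the dispersion estimate is then dominated by the reference
residuals, since one observation contributes none.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess
from statsmodels.othermod.betareg import BetaModel

from morphovar.catalog import (
    META_COLUMNS,
    ParameterDescriptor,
    TraitTable,
    catalog_by_id,
    catalog_hash,
)

logger = logging.getLogger(__name__)

#: Default Lowess smoothing span for the CV-vs-mean uncoupling.
DEFAULT_SPAN = 0.4


@dataclass
class GlmFit:
    """Wald fit of one strain's effect on one parameter."""

    param_id: str
    strain_id: str
    beta0: float
    beta1: float
    se_beta1: float
    z: float
    fitted_mean: float  # response scale, reference + effect
    fitted_link: float  # link scale, beta0 + beta1
    converged: bool


@dataclass
class ZScoreMatrix:
    """Strain x parameter matrix of Wald Z-scores with provenance."""

    z: pd.DataFrame
    reference: str = ""
    catalog_hash: str = ""
    dropped_params: tuple = ()

    @property
    def strains(self) -> list[str]:
        return list(self.z.index)

    @property
    def params(self) -> list[str]:
        return list(self.z.columns)

    def write(self, path) -> None:
        self.z.to_csv(path, sep="\t", index_label="strain_id")

    @classmethod
    def read(cls, path, reference: str = "") -> "ZScoreMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="strain_id"), reference)


def normalize_cv(
    table: TraitTable,
    catalog: list[ParameterDescriptor],
    span: float = DEFAULT_SPAN,
    reference_only: bool = False,
    iterations: int = 3,
) -> TraitTable:
    """Replace each CV column by its Lowess residual against the partner mean.

    The local regression is fit across all cultures jointly by default
    (reference and mutant strains), or against the reference cultures only if
    ``reference_only`` is set; residuals are evaluated for every culture in
    either case.
    """
    index = catalog_by_id(catalog)
    values = table.values.copy()
    present = set(table.param_columns)
    for d in catalog:
        if d.family != "gaussian_cv" or d.param_id not in present:
            continue
        if d.mean_partner_id not in present:
            raise KeyError(
                f"CV parameter {d.param_id!r} requires its mean partner "
                f"{d.mean_partner_id!r} in the table"
            )
        cv = values[d.param_id].to_numpy(float)
        mean = values[d.mean_partner_id].to_numpy(float)
        ok = np.isfinite(cv) & np.isfinite(mean)
        if reference_only:
            fit_mask = ok & (values["group"] == "wildtype").to_numpy()
        else:
            fit_mask = ok
        if fit_mask.sum() < 3:
            raise ValueError(f"too few cultures to fit Lowess for {d.param_id!r}")
        # Fit on the training cultures, then interpolate fitted values at
        # every culture's mean (matches evaluating the smooth at new points).
        fitted_sorted = _lowess(cv[fit_mask], mean[fit_mask], frac=span, it=iterations)
        xs, ys = fitted_sorted[:, 0], fitted_sorted[:, 1]
        xs, uniq = np.unique(xs, return_index=True)
        pred = np.interp(mean[ok], xs, ys[uniq])
        resid = np.full_like(cv, np.nan)
        resid[ok] = cv[ok] - pred
        values[d.param_id] = resid
    return TraitTable(values, table.trials)


def _wald_from_results(res, param_id, strain_id, inv_link) -> GlmFit:
    beta0, beta1 = res.params[0], res.params[1]
    se = res.bse[1]
    z = beta1 / se if se > 0 else np.nan
    return GlmFit(
        param_id=param_id,
        strain_id=strain_id,
        beta0=float(beta0),
        beta1=float(beta1),
        se_beta1=float(se),
        z=float(z),
        fitted_mean=float(inv_link(beta0 + beta1)),
        fitted_link=float(beta0 + beta1),
        converged=bool(np.isfinite(z)),
    )


def fit_strain_effect(
    reference_values,
    strain_values,
    family: str,
    reference_trials=None,
    strain_trials=None,
    param_id: str = "",
    strain_id: str = "",
) -> GlmFit:
    """Fit the two-group GLM for one parameter and return the Wald Z.

    ``reference_values`` must contain at least two cultures; a strain may be
    a single culture.  For ``binomial_od`` the values are success counts and
    the matching trial counts are required.
    """
    ref = np.asarray(reference_values, float)
    stn = np.asarray(strain_values, float)
    if len(ref) < 2:
        raise ValueError("need at least two reference cultures")
    if len(stn) < 1:
        raise ValueError("need at least one strain culture")
    y = np.concatenate([ref, stn])
    x = np.concatenate([np.zeros(len(ref)), np.ones(len(stn))])
    X = sm.add_constant(x)

    def failed() -> GlmFit:
        return GlmFit(param_id, strain_id, np.nan, np.nan, np.nan, np.nan,
                      np.nan, np.nan, False)

    if not np.all(np.isfinite(y)):
        return failed()

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if family == "gaussian_cv":
                if np.var(y) == 0:
                    return failed()
                res = sm.OLS(y, X).fit()
                return _wald_from_results(res, param_id, strain_id, lambda e: e)
            if family == "gamma":
                if np.any(y <= 0):
                    raise ValueError("gamma values must be strictly positive")
                res = sm.GLM(
                    y, X, family=sm.families.Gamma(sm.families.links.Log())
                ).fit()
                return _wald_from_results(res, param_id, strain_id, np.exp)
            if family == "beta":
                if np.any((y <= 0) | (y >= 1)):
                    raise ValueError("beta values must lie in (0, 1)")
                if np.var(y) == 0:
                    return failed()
                res = BetaModel(y, X).fit(disp=0)
                inv = lambda e: 1.0 / (1.0 + np.exp(-e))
                return _wald_from_results(res, param_id, strain_id, inv)
            if family == "binomial_od":
                if reference_trials is None or strain_trials is None:
                    raise ValueError("binomial_od requires trial counts")
                n = np.concatenate(
                    [np.asarray(reference_trials, float), np.asarray(strain_trials, float)]
                )
                if np.any((y < 0) | (y > n)):
                    raise ValueError("counts must lie in [0, trials]")
                # proportions with the trial counts as variance weights, so the
                # Pearson dispersion estimate carries the binomial denominator
                res = sm.GLM(
                    y / n, X, family=sm.families.Binomial(), var_weights=n
                ).fit(scale="X2")
                inv = lambda e: 1.0 / (1.0 + np.exp(-e))
                return _wald_from_results(res, param_id, strain_id, inv)
    except (ValueError, np.linalg.LinAlgError) as err:
        if "must" in str(err):  # support violations propagate
            raise
        return failed()
    raise ValueError(f"unknown family {family!r}")


def zscore_matrix(
    table: TraitTable,
    catalog: list[ParameterDescriptor],
    reference_group: str = "wildtype",
    span: float = DEFAULT_SPAN,
    reference_only_lowess: bool = False,
) -> ZScoreMatrix:
    """Z-scores of every non-reference strain for every parameter.

    Applies :func:`normalize_cv`, then fits the two-group GLM per strain and
    parameter against the reference cultures.  Parameters whose fit fails
    (missing values, non-convergence, degenerate data) for any strain are
    dropped from the matrix with a logged count.
    """
    index = catalog_by_id(catalog)
    groups = table.values["group"]
    if not (groups == reference_group).any():
        raise ValueError(f"reference group {reference_group!r} absent from table")
    norm = normalize_cv(table, catalog, span=span, reference_only=reference_only_lowess)
    ref_mask = (groups == reference_group).to_numpy()
    if ref_mask.sum() < 2:
        raise ValueError("reference group must have at least two cultures")
    params = [c for c in norm.param_columns if c in index]
    strains = [
        s
        for s in norm.values.loc[~ref_mask, "strain_id"].unique()
    ]
    z = pd.DataFrame(np.nan, index=strains, columns=params)
    for p in params:
        fam = index[p].family
        ref_vals = norm.values.loc[ref_mask, p].to_numpy(float)
        ref_tri = (
            norm.trials.loc[ref_mask, p].to_numpy(float)
            if fam == "binomial_od"
            else None
        )
        for s in strains:
            s_mask = (norm.values["strain_id"] == s).to_numpy()
            vals = norm.values.loc[s_mask, p].to_numpy(float)
            tri = (
                norm.trials.loc[s_mask, p].to_numpy(float)
                if fam == "binomial_od"
                else None
            )
            keep = np.isfinite(vals)
            if keep.sum() == 0:
                continue
            fit = fit_strain_effect(
                ref_vals[np.isfinite(ref_vals)],
                vals[keep],
                fam,
                reference_trials=ref_tri[np.isfinite(ref_vals)] if tri is not None else None,
                strain_trials=tri[keep] if tri is not None else None,
                param_id=p,
                strain_id=s,
            )
            z.loc[s, p] = fit.z
    dropped = tuple(z.columns[z.isna().any(axis=0)])
    if dropped:
        logger.info("zscore_matrix: dropping %d parameters with failed fits", len(dropped))
        z = z.drop(columns=list(dropped))
    ref_id = table.values.loc[ref_mask, "strain_id"].iloc[0]
    return ZScoreMatrix(z, reference=ref_id, catalog_hash=catalog_hash(catalog),
                        dropped_params=dropped)


def reference_replicate_zscores(
    table: TraitTable,
    catalog: list[ParameterDescriptor],
    reference_group: str = "wildtype",
    span: float = DEFAULT_SPAN,
) -> ZScoreMatrix:
    """Leave-one-out Z-scores for the reference replicates themselves.

    Each reference culture is treated as a pseudo-strain of one culture and
    fit against the remaining reference cultures.  The resulting replicate
    Z matrix serves as null-distributed data for the replicate PCA and for
    the Mahalanobis reference covariance.
    """
    index = catalog_by_id(catalog)
    norm = normalize_cv(table, catalog, span=span)
    ref_mask = (norm.values["group"] == reference_group).to_numpy()
    n_ref = int(ref_mask.sum())
    if n_ref < 3:
        raise ValueError("need at least three reference cultures for leave-one-out")
    params = [c for c in norm.param_columns if c in index]
    rows = np.flatnonzero(ref_mask)
    labels = [f"{norm.values.loc[i, 'strain_id']}_rep{norm.values.loc[i, 'replicate_index']}"
              for i in rows]
    z = pd.DataFrame(np.nan, index=labels, columns=params)
    for p in params:
        fam = index[p].family
        vals = norm.values.loc[ref_mask, p].to_numpy(float)
        tri = (
            norm.trials.loc[ref_mask, p].to_numpy(float)
            if fam == "binomial_od"
            else None
        )
        for j, label in enumerate(labels):
            others = np.delete(vals, j)
            held = vals[j : j + 1]
            if not np.isfinite(held).all() or not np.all(np.isfinite(others)):
                continue
            fit = fit_strain_effect(
                others,
                held,
                fam,
                reference_trials=np.delete(tri, j) if tri is not None else None,
                strain_trials=tri[j : j + 1] if tri is not None else None,
                param_id=p,
                strain_id=label,
            )
            z.loc[label, p] = fit.z
    dropped = tuple(z.columns[z.isna().any(axis=0)])
    if dropped:
        z = z.drop(columns=list(dropped))
    return ZScoreMatrix(z, reference=reference_group,
                        catalog_hash=catalog_hash(catalog), dropped_params=dropped)
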