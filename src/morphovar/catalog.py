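"""Trait catalog: probability families, links and CV-to-mean pairing.

CalMorph-style morphometric data consist of ~501 quantitative parameters per
culture.  Each parameter is modeled by one of four probability families:

``gamma``
    positive continuous mean morphologies (e.g. cell sizes, lengths).
``beta``
    continuous morphologies bounded in the open interval (0, 1) (e.g. axis
    ratios, relative positions).
``binomial_od``
    cell-category counts out of the number of cells examined per culture,
    binomial with overdispersion (extra-binomial variance between cultures).
``gaussian_cv``
    coefficients of variation of a paired mean parameter, treated as Gaussian
    after their dependence on the paired mean has been removed by Lowess
    regression.

The default catalog partitions 501 parameters as 220 gaussian_cv / 183 gamma
/ 37 beta / 61 binomial_od, with every CV trait paired one-to-one with a
gamma or beta mean trait.  Identifiers are synthetic but stable across runs
and follow the CalMorph naming style (``C``/``A``/``D`` prefixes for cell
wall, actin and nuclear DNA traits); real CalMorph exports can be analyzed
by supplying a user catalog TSV instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAMILIES = ("gaussian_cv", "gamma", "beta", "binomial_od")

#: Canonical default link per family (overridable via a user catalog file).
DEFAULT_LINKS = {
    "gaussian_cv": "identity",
    "gamma": "log",
    "beta": "logit",
    "binomial_od": "logit",
}

#: Metadata columns every trait table carries ahead of the parameter columns.
META_COLUMNS = ("strain_id", "group", "replicate_index")

GROUPS = ("wildtype", "natural", "deletion")


@dataclass(frozen=True)
class ParameterDescriptor:
    """One morphological trait: identity, probability family and link."""

    param_id: str
    family: str
    link: str = ""
    mean_partner_id: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r} for {self.param_id!r}")
        if not self.link:
            object.__setattr__(self, "link", DEFAULT_LINKS[self.family])
        if self.family == "gaussian_cv" and not self.mean_partner_id:
            raise ValueError(
                f"gaussian_cv parameter {self.param_id!r} requires a mean_partner_id"
            )


def _cv_id(partner_id: str) -> str:
    # "C105_A" -> "CCV105_A": insert CV after the organelle prefix letter.
    return partner_id[0] + "CV" + partner_id[1:]


def build_catalog(
    n_gamma: int = 183,
    n_beta: int = 37,
    n_binomial: int = 61,
    n_cv: int = 220,
) -> list[ParameterDescriptor]:
    """Build a catalog with the given family counts.

    CV traits are paired, in order, with the gamma traits first and then the
    beta traits, so ``n_cv`` must not exceed ``n_gamma + n_beta``.  The
    default counts reproduce the standard 501-parameter catalog.
    """
    if n_cv > n_gamma + n_beta:
        raise ValueError("n_cv cannot exceed the number of gamma + beta mean traits")
    catalog: list[ParameterDescriptor] = []
    gamma_ids = [f"C{101 + i}_A" for i in range(n_gamma)]
    beta_ids = [f"A{101 + i}_B" for i in range(n_beta)]
    binom_ids = [f"D{101 + i}_C" for i in range(n_binomial)]
    for pid in gamma_ids:
        catalog.append(
            ParameterDescriptor(pid, "gamma", description="synthetic mean trait (gamma)")
        )
    for pid in beta_ids:
        catalog.append(
            ParameterDescriptor(pid, "beta", description="synthetic ratio trait (beta)")
        )
    for pid in binom_ids:
        catalog.append(
            ParameterDescriptor(
                pid, "binomial_od", description="synthetic cell-count trait (binomial)"
            )
        )
    for partner in (gamma_ids + beta_ids)[:n_cv]:
        catalog.append(
            ParameterDescriptor(
                _cv_id(partner),
                "gaussian_cv",
                mean_partner_id=partner,
                description=f"coefficient of variation of {partner}",
            )
        )
    return catalog


def build_default_catalog() -> list[ParameterDescriptor]:
    """The standard 501-parameter catalog (220 CV / 183 gamma / 37 beta / 61 binomial)."""
    return build_catalog()


def catalog_by_id(catalog: list[ParameterDescriptor]) -> dict[str, ParameterDescriptor]:
    index = {d.param_id: d for d in catalog}
    if len(index) != len(catalog):
        raise ValueError("duplicate param_id in catalog")
    for d in catalog:
        if d.family == "gaussian_cv" and d.mean_partner_id not in index:
            raise ValueError(
                f"CV parameter {d.param_id!r} pairs with unknown trait {d.mean_partner_id!r}"
            )
    return index


def catalog_hash(catalog: list[ParameterDescriptor]) -> str:
    """Stable short hash of the catalog content, recorded as provenance."""
    import hashlib

    text = "\n".join(
        f"{d.param_id}\t{d.family}\t{d.link}\t{d.mean_partner_id}" for d in catalog
    )
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_catalog(catalog: list[ParameterDescriptor], path) -> None:
    df = pd.DataFrame(
        [
            (d.param_id, d.family, d.link, d.mean_partner_id, d.description)
            for d in catalog
        ],
        columns=["param_id", "family", "link", "mean_partner_id", "description"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list[ParameterDescriptor]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        ParameterDescriptor(
            r.param_id, r.family, r.link, r.mean_partner_id, r.description
        )
        for r in df.itertuples()
    ]


@dataclass
class TraitTable:
    """Replicate-level trait observations.

    ``values`` has one row per culture with metadata columns ``strain_id``,
    ``group`` (wildtype / natural / deletion), ``replicate_index`` followed by
    one column per parameter.  For binomial parameters the value column holds
    success counts; ``trials`` holds the matching per-culture trial counts
    (cells examined), with the same row order.
    """

    values: pd.DataFrame
    trials: pd.DataFrame | None = None

    @property
    def param_columns(self) -> list[str]:
        return [c for c in self.values.columns if c not in META_COLUMNS]

    def subset(self, mask) -> "TraitTable":
        trials = None if self.trials is None else self.trials.loc[mask].reset_index(drop=True)
        return TraitTable(self.values.loc[mask].reset_index(drop=True), trials)

    def write(self, values_path, trials_path=None) -> None:
        self.values.to_csv(values_path, sep="\t", index=False)
        if self.trials is not None and trials_path is not None:
            self.trials.to_csv(trials_path, sep="\t", index=False)

    @classmethod
    def read(cls, values_path, trials_path=None) -> "TraitTable":
        values = pd.read_csv(values_path, sep="\t")
        trials = None if trials_path is None else pd.read_csv(trials_path, sep="\t")
        return cls(values, trials)


@dataclass
class ValidationReport:
    """Outcome of validating a trait table against a catalog."""

    dropped_params: list[str] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_table(
    table: TraitTable, catalog: list[ParameterDescriptor]
) -> ValidationReport:
    """Check family support and completeness of a trait table.

    Parameters with missing values for any culture are listed as dropped
    (mirroring the practice of discarding traits that lack a value for a
    required strain).  Support violations (negative gamma values, beta values
    outside the open unit interval, malformed counts) are listed per
    parameter.  An unknown parameter column is a hard error.
    """
    index = catalog_by_id(catalog)
    report = ValidationReport()
    for col in table.param_columns:
        if col not in index:
            raise KeyError(f"column {col!r} is not in the catalog")
        desc = index[col]
        vals = table.values[col]
        finite = vals.dropna()
        if vals.isna().any():
            report.dropped_params.append(col)
        if desc.family == "gamma":
            if (finite <= 0).any():
                report.violations.append(f"{col}: gamma values must be strictly positive")
        elif desc.family == "beta":
            if ((finite <= 0) | (finite >= 1)).any():
                report.violations.append(
                    f"{col}: beta values must lie in the open interval (0, 1)"
                )
        elif desc.family == "binomial_od":
            if table.trials is None or col not in table.trials.columns:
                report.violations.append(f"{col}: binomial parameter lacks a trials column")
            else:
                trials = table.trials[col]
                bad = (
                    (finite < 0)
                    | (finite > trials.loc[finite.index])
                    | (finite != np.round(finite))
                )
                if bad.any():
                    report.violations.append(
                        f"{col}: counts must be integers in [0, trials]"
                    )
    if report.dropped_params:
        logger.info(
            "validate_table: %d parameters have missing values and would be dropped",
            len(report.dropped_params),
        )
    return report
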