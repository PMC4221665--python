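"""Synthetic replicate-level trait tables with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes for a yeast morphological screen:

* a wild-type reference strain grown as many replicate cultures (default 40),
  a panel of natural isolates with a few replicates each (default 36 strains
  x 5 cultures), and a panel of gene-deletion strains with a single culture
  each (default 110);
* per-parameter culture values drawn from the family the catalog declares
  (gamma, beta, beta-binomial counts over >= 200 cells, or a CV trait coupled
  to its partner mean through a smooth decreasing trend);
* strain effects on the link scale drawn once per strain, correlated within
  parameter blocks (size / actin / nucleus / noise) through a shared latent
  factor so the downstream PCA has structure;
* a deletion panel with inflated effect scale relative to the natural panel;
* optionally, planted "heteroclite" strains with a known block-directional
  effect of chosen magnitude, recorded in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from morphovar.catalog import META_COLUMNS, ParameterDescriptor, TraitTable, catalog_by_id

BLOCKS = ("size", "actin", "nucleus", "noise")


@dataclass(frozen=True)
class PlantedEffect:
    """A strain planted with a known directional effect.

    ``direction`` maps block names to weights; ``magnitude`` is the shift
    applied per parameter of the targeted blocks, in units of the deletion
    effect scale on the link scale.
    """

    strain_id: str
    direction: dict
    magnitude: float

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("planted magnitude must be >= 0")
        unknown = set(self.direction) - set(BLOCKS)
        if unknown:
            raise ValueError(f"unknown blocks in planted direction: {sorted(unknown)}")


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the synthetic screen."""

    seed: int = 0
    n_wildtype_reps: int = 40
    n_natural: int = 36
    reps_per_natural: int = 5
    n_deletion: int = 110
    reps_per_deletion: int = 1
    trials_per_culture: int = 200
    natural_effect_sd: float = 0.15
    deletion_effect_sd: float = 0.35
    block_correlation: float = 0.5
    overdispersion_rho: float = 0.05
    cv_noise_sd: float = 0.02
    planted_heteroclites: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.natural_effect_sd < 0 or self.deletion_effect_sd < 0:
            raise ValueError("effect scales must be >= 0")
        if not 0 <= self.block_correlation <= 1:
            raise ValueError("block_correlation must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually planted: per-strain link-scale effects."""

    effects: pd.DataFrame  # strain x parameter, link scale
    blocks: dict  # param_id -> block name
    groups: dict  # strain_id -> group
    planted: dict  # strain_id -> PlantedEffect

    def to_json_dict(self) -> dict:
        return {
            "blocks": self.blocks,
            "groups": self.groups,
            "planted": {
                s: {"direction": p.direction, "magnitude": p.magnitude}
                for s, p in self.planted.items()
            },
            "effects": {s: row.to_dict() for s, row in self.effects.iterrows()},
        }


def _assign_blocks(catalog: list[ParameterDescriptor]) -> dict:
    """Deterministic block assignment; a CV trait inherits its partner's block."""
    blocks: dict[str, str] = {}
    i = 0
    for d in catalog:
        if d.family != "gaussian_cv":
            blocks[d.param_id] = BLOCKS[i % len(BLOCKS)]
            i += 1
    for d in catalog:
        if d.family == "gaussian_cv":
            blocks[d.param_id] = blocks[d.mean_partner_id]
    return blocks


def _baselines(catalog, rng) -> dict:
    """Per-parameter wild-type baselines on the link scale, drawn once."""
    base = {}
    for d in catalog:
        if d.family == "gamma":
            base[d.param_id] = rng.uniform(np.log(2.0), np.log(50.0))
        elif d.family == "beta":
            base[d.param_id] = rng.uniform(logit(0.15), logit(0.85))
        elif d.family == "binomial_od":
            base[d.param_id] = rng.uniform(logit(0.05), logit(0.8))
        else:  # gaussian_cv: trend coefficient for the CV-mean coupling
            base[d.param_id] = rng.uniform(0.2, 0.6)
    return base


def _strain_effects(
    strains: list[str],
    groups: dict,
    catalog,
    blocks,
    config: SimulationConfig,
    rng,
) -> pd.DataFrame:
    """Link-scale effect per strain x parameter, drawn once per strain."""
    params = [d.param_id for d in catalog]
    block_of = np.array([BLOCKS.index(blocks[p]) for p in params])
    rho = config.block_correlation
    eff = np.zeros((len(strains), len(params)))
    planted = {p.strain_id: p for p in config.planted_heteroclites}
    known = set(strains)
    for p in planted.values():
        if p.strain_id not in known:
            raise ValueError(f"planted strain {p.strain_id!r} is not in the panel")
    for i, s in enumerate(strains):
        scale = {
            "wildtype": 0.0,
            "natural": config.natural_effect_sd,
            "deletion": config.deletion_effect_sd,
        }[groups[s]]
        u = rng.standard_normal(len(BLOCKS))  # shared block factors
        e = rng.standard_normal(len(params))  # parameter-private part
        eff[i] = scale * (np.sqrt(rho) * u[block_of] + np.sqrt(1 - rho) * e)
        if s in planted:
            p = planted[s]
            dvec = np.array([p.direction.get(blocks[q], 0.0) for q in params])
            eff[i] += p.magnitude * config.deletion_effect_sd * dvec
    return pd.DataFrame(eff, index=strains, columns=params)


def _draw_cultures(
    catalog,
    effects_row: pd.Series,
    baselines: dict,
    n_reps: int,
    config: SimulationConfig,
    rng,
):
    """Culture-level draws for one strain; returns (values dict, trials dict)."""
    values: dict[str, np.ndarray] = {}
    trials: dict[str, np.ndarray] = {}
    gamma_shape = 50.0
    beta_precision = 100.0
    for d in catalog:
        if d.family == "gaussian_cv":
            continue
        eta = baselines[d.param_id] + effects_row[d.param_id]
        if d.family == "gamma":
            mean = np.exp(eta)
            values[d.param_id] = rng.gamma(gamma_shape, mean / gamma_shape, n_reps)
        elif d.family == "beta":
            mu = expit(eta)
            values[d.param_id] = rng.beta(
                mu * beta_precision, (1 - mu) * beta_precision, n_reps
            )
        else:  # binomial_od: beta-binomial over the per-culture trial counts
            mu = expit(eta)
            n_trials = config.trials_per_culture + rng.poisson(20, n_reps)
            rho = config.overdispersion_rho
            if rho > 0:
                conc = 1.0 / rho - 1.0
                p_culture = rng.beta(mu * conc, (1 - mu) * conc, n_reps)
            else:
                p_culture = np.full(n_reps, mu)
            values[d.param_id] = rng.binomial(n_trials, p_culture).astype(float)
            trials[d.param_id] = n_trials
    for d in catalog:
        if d.family != "gaussian_cv":
            continue
        partner = values[d.mean_partner_id]
        # CV depends on the realized partner mean through a decreasing trend
        # (Taylor-law-like), which the Lowess stage is expected to remove.
        trend = baselines[d.param_id] / np.sqrt(np.abs(partner) + 0.05)
        shift = 0.1 * effects_row[d.param_id]
        values[d.param_id] = trend + shift + rng.normal(0.0, config.cv_noise_sd, n_reps)
    return values, trials


def _panel(config: SimulationConfig):
    """Strain ids, groups and replicate counts implied by the design."""
    strains = ["BY4743"]
    groups = {"BY4743": "wildtype"}
    reps = {"BY4743": config.n_wildtype_reps}
    for i in range(config.n_natural):
        s = f"NAT{i + 1:03d}"
        strains.append(s)
        groups[s] = "natural"
        reps[s] = config.reps_per_natural
    for i in range(config.n_deletion):
        s = f"DEL{i + 1:03d}"
        strains.append(s)
        groups[s] = "deletion"
        reps[s] = config.reps_per_deletion
    return strains, groups, reps


def simulate(
    config: SimulationConfig, catalog: list[ParameterDescriptor]
) -> tuple[TraitTable, GroundTruth]:
    """Generate a full synthetic screen and its ground truth.

    The seed fully determines the output.  Baselines, strain effects and
    culture draws use independent seed streams spawned from the root seed, so
    ``null_reference`` can reproduce the identical wild-type generative state
    without drawing the mutant panels.
    """
    catalog_by_id(catalog)  # validates
    ss = np.random.SeedSequence(config.seed)
    base_seed, effect_seed, culture_seed = ss.spawn(3)
    blocks = _assign_blocks(catalog)
    baselines = _baselines(catalog, np.random.default_rng(base_seed))

    strains, groups, reps = _panel(config)
    effects = _strain_effects(
        strains, groups, catalog, blocks, config, np.random.default_rng(effect_seed)
    )

    rows = []
    trial_rows = []
    culture_rngs = culture_seed.spawn(len(strains))
    params = [d.param_id for d in catalog]
    binom_params = [d.param_id for d in catalog if d.family == "binomial_od"]
    for s, child in zip(strains, culture_rngs):
        rng = np.random.default_rng(child)
        values, trials = _draw_cultures(
            catalog, effects.loc[s], baselines, reps[s], config, rng
        )
        for r in range(reps[s]):
            row = {"strain_id": s, "group": groups[s], "replicate_index": r + 1}
            row.update({p: values[p][r] for p in params})
            rows.append(row)
            trow = {"strain_id": s, "group": groups[s], "replicate_index": r + 1}
            trow.update({p: trials[p][r] for p in binom_params})
            trial_rows.append(trow)
    values_df = pd.DataFrame(rows, columns=list(META_COLUMNS) + params)
    trials_df = pd.DataFrame(trial_rows, columns=list(META_COLUMNS) + binom_params)
    table = TraitTable(values_df, trials_df)
    truth = GroundTruth(
        effects=effects,
        blocks=blocks,
        groups=groups,
        planted={p.strain_id: p for p in config.planted_heteroclites},
    )
    return table, truth


def null_reference(
    config: SimulationConfig, catalog: list[ParameterDescriptor]
) -> TraitTable:
    """Wild-type replicate cultures only, from the same generative state.

    Suitable as null-distributed data for the replicate PCA and for the
    Mahalanobis reference covariance.
    """
    table, _ = simulate(config, catalog)
    return table.subset(table.values["group"] == "wildtype")


def simulate_zscore_panel(
    n_strains: int,
    n_params: int,
    n_reference: int,
    effect_sd: float = 1.0,
    seed: int = 0,
):
    """Z-score-level panel generator for selection-scale experiments.

    Produces a strain x parameter matrix of Wald-type Z-scores directly
    (standard normal noise plus per-strain effects of scale ``effect_sd``)
    together with a reference-replicate Z matrix, skipping the trait-level
    GLM stage.  Useful for exercising Mahalanobis ranking and strain
    selection at genome-wide panel sizes (thousands of strains).
    """
    rng = np.random.default_rng(seed)
    params = [f"P{i + 1:04d}" for i in range(n_params)]
    strains = [f"S{i + 1:05d}" for i in range(n_strains)]
    effects = effect_sd * rng.standard_normal((n_strains, 1)) * rng.standard_normal(
        (1, n_params)
    )
    z = rng.standard_normal((n_strains, n_params)) + effects
    ref = rng.standard_normal((n_reference, n_params))
    refs = [f"WT{i + 1:04d}" for i in range(n_reference)]
    return (
        pd.DataFrame(z, index=strains, columns=params),
        pd.DataFrame(ref, index=refs, columns=params),
    )
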