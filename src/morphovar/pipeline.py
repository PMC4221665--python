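"""End-to-end orchestration: simulate -> zscore -> select -> PCA -> detect.

The pipeline is driven by a flat configuration whose defaults are the
analysis constants of the standard screen: Lowess span 0.4, selection quotas
100 + 20 over PC1-PC20, detection on PC1-PC4 at alpha 0.05, loading
thresholds (0.6, 1.95e-3), 95% mass ellipses on a 200 x 200 grid.  All
randomness flows from a single root seed; every stage output carries the
configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import morphovar.catalog as cat
import morphovar.detection as detection
import morphovar.interpretation as interpretation
import morphovar.selection as selection
import morphovar.variance as variance
from morphovar.simulate import SimulationConfig, simulate as simulate_table
import morphovar.zscore as zs

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    # simulation scale
    n_wildtype_reps: int = 40
    n_natural: int = 36
    reps_per_natural: int = 5
    n_deletion: int = 110
    reps_per_deletion: int = 1
    trials_per_culture: int = 200
    natural_effect_sd: float = 0.15
    deletion_effect_sd: float = 0.35
    # catalog scale (default: the standard 501-parameter catalog)
    n_gamma: int = 183
    n_beta: int = 37
    n_binomial: int = 61
    n_cv: int = 220
    # analysis constants
    span: float = 0.4
    k_top: int = 100
    k_edge: int = 20
    n_pcs: int = 20
    components: tuple = (1, 2, 3, 4)
    pc_rule: str = "fixed"  # or "cumulative"
    cumulative_target: float = 0.6
    alpha: float = 0.05
    loading_threshold: float = 0.6
    p_threshold: float = 1.95e-3
    mass_level: float = 0.95
    grid_size: int = 200
    run_selection: bool = False
    run_interpretation: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "components" in raw:
            raw["components"] = tuple(raw["components"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    z: zs.ZScoreMatrix
    wt_z: zs.ZScoreMatrix
    pc_model: variance.PCModel
    components: tuple
    reference_center: pd.Series
    detection_summary: detection.DetectionSummary
    summary: dict
    selection: pd.DataFrame | None = None
    loadings: pd.DataFrame | None = None
    groups: list = field(default_factory=list)


def _choose_components(pc_model: variance.PCModel, config: PipelineConfig) -> tuple:
    if config.pc_rule == "cumulative":
        k = pc_model.n_components_for_ratio(config.cumulative_target)
        return tuple(range(1, k + 1))
    if config.pc_rule == "fixed":
        return tuple(config.components)
    raise ValueError(f"unknown pc_rule {config.pc_rule!r}")


def run_all(config: PipelineConfig, table: cat.TraitTable | None = None,
            catalog: list | None = None) -> PipelineResult:
    """Execute the full analysis on simulated (default) or supplied data."""
    if catalog is None:
        catalog = cat.build_catalog(
            config.n_gamma, config.n_beta, config.n_binomial, config.n_cv
        )
    if table is None:
        sim_config = SimulationConfig(
            seed=config.seed,
            n_wildtype_reps=config.n_wildtype_reps,
            n_natural=config.n_natural,
            reps_per_natural=config.reps_per_natural,
            n_deletion=config.n_deletion,
            reps_per_deletion=config.reps_per_deletion,
            trials_per_culture=config.trials_per_culture,
            natural_effect_sd=config.natural_effect_sd,
            deletion_effect_sd=config.deletion_effect_sd,
        )
        table, _ = simulate_table(sim_config, catalog)
    report = cat.validate_table(table, catalog)
    if not report.ok:
        raise ValueError(f"stage validate: trait table violates family support: "
                         f"{report.violations[:3]}")

    logger.info("stage zscore: %d cultures x %d parameters",
                len(table.values), len(table.param_columns))
    z = zs.zscore_matrix(table, catalog, span=config.span)
    wt_z = zs.reference_replicate_zscores(table, catalog, span=config.span)
    shared = [p for p in z.params if p in set(wt_z.params)]
    z.z = z.z[shared]
    wt_z.z = wt_z.z[shared]

    groups = table.values.drop_duplicates("strain_id").set_index("strain_id")["group"]
    natural = [s for s in z.strains if groups[s] == "natural"]
    deletion = [s for s in z.strains if groups[s] == "deletion"]

    sel_table = None
    if config.run_selection:
        dist = selection.mahalanobis_distances(z.z.loc[deletion], wt_z)
        sel = selection.select_strains(
            dist, z.z.loc[deletion], k_top=min(config.k_top, len(deletion) - config.k_edge),
            k_edge=config.k_edge, n_pcs=config.n_pcs,
        )
        sel_table = selection.selection_table(sel)

    ratio, exceed = variance.variance_ratio_profile(z.z.loc[deletion], z.z.loc[natural])
    pc_model = variance.pca_z(z.z)
    components = _choose_components(pc_model, config)
    comp_cols = [f"PC{c}" for c in components]

    center = pd.Series(
        pc_model.transform(np.zeros(len(shared)))[0], index=pc_model.scores.columns
    )
    det = detection.detect(
        pc_model.scores.loc[deletion],
        pc_model.scores.loc[natural],
        center,
        components=comp_cols,
        alpha=config.alpha,
    )
    overlap = detection.overlap_summary(det) if det.results else {}

    e_del = variance.equiprobability_ellipse(
        pc_model.scores.loc[deletion, ["PC1", "PC2"]].to_numpy(),
        mass_level=config.mass_level, grid_size=config.grid_size,
    )
    e_nat = variance.equiprobability_ellipse(
        pc_model.scores.loc[natural, ["PC1", "PC2"]].to_numpy(),
        mass_level=config.mass_level, grid_size=config.grid_size,
    )
    broadness = variance.broadness_ratio(e_del, e_nat)

    loadings_df = None
    groups_out: list = []
    if config.run_interpretation:
        calls = interpretation.significant_loadings(
            z.z, pc_model, components=comp_cols,
            loading_threshold=config.loading_threshold, p_threshold=config.p_threshold,
        )
        loadings_df = interpretation.calls_table(calls)
        if any(c.passes for c in calls):
            groups_out = interpretation.representative_parameters(
                calls, wt_z.z,
                loading_threshold=config.loading_threshold,
                p_threshold=config.p_threshold,
            )

    per_pc = {
        c: [r.strain_id for r in det.results if r.component == c and r.significant]
        for c in comp_cols
    }
    summary = {
        "config_hash": config.hash(),
        "n_parameters_used": len(shared),
        "dropped_params": sorted(set(z.dropped_params) | set(wt_z.dropped_params)),
        "variance_ratio_exceedance": exceed,
        "variance_ratio_total": int(np.isfinite(ratio).sum()),
        "pc_cumulative_ratio": [float(x) for x in pc_model.cumulative_ratio[:10]],
        "components_used": list(components),
        "broadness_ratio_pc1_pc2": float(broadness),
        "heteroclites": det.heteroclites,
        "per_component_detections": per_pc,
        "overlap": overlap,
        "m_tests": det.m_tests,
    }
    return PipelineResult(
        config=config, z=z, wt_z=wt_z, pc_model=pc_model, components=components,
        reference_center=center, detection_summary=det, summary=summary,
        selection=sel_table, loadings=loadings_df, groups=groups_out,
    )


def write_results(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.z.write(out / "z.tsv")
    result.wt_z.write(out / "wt_z.tsv")
    result.pc_model.scores.to_csv(out / "scores.tsv", sep="\t", index_label="strain_id")
    result.pc_model.loadings.to_csv(out / "loadings.tsv", sep="\t", index_label="param_id")
    result.detection_summary.table().to_csv(out / "detections.tsv", sep="\t", index=False)
    if result.selection is not None:
        result.selection.to_csv(out / "selection.tsv", sep="\t", index=False)
    if result.loadings is not None:
        result.loadings.to_csv(out / "loading_calls.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
    lines = [
        f"parameters used: {result.summary['n_parameters_used']}",
        f"variance ratio > 1: {result.summary['variance_ratio_exceedance']}"
        f" / {result.summary['variance_ratio_total']}",
        f"components used: {result.summary['components_used']}",
        f"broadness ratio (PC1-PC2): {result.summary['broadness_ratio_pc1_pc2']:.2f}",
        f"heteroclite strains ({len(result.summary['heteroclites'])}): "
        + ", ".join(result.summary["heteroclites"]),
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
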