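import numpy as np
import pandas as pd
import pytest

from morphovar.catalog import build_catalog
from morphovar.simulate import SimulationConfig, simulate
from morphovar.zscore import reference_replicate_zscores, zscore_matrix


@pytest.fixture(scope="session")
def small_catalog():
    """Reduced catalog (32 parameters) keeping all four families."""
    return build_catalog(n_gamma=12, n_beta=4, n_binomial=8, n_cv=8)


@pytest.fixture(scope="session")
def small_screen(small_catalog):
    """One simulated screen: 12 wt reps, 8 natural x 3, 15 deletion x 1."""
    config = SimulationConfig(
        seed=5,
        n_wildtype_reps=12,
        n_natural=8,
        reps_per_natural=3,
        n_deletion=15,
    )
    table, truth = simulate(config, small_catalog)
    return config, table, truth


@pytest.fixture(scope="session")
def small_z(small_screen, small_catalog):
    """GLM Z-score matrices (strains and wild-type replicates) for the screen."""
    _, table, _ = small_screen
    z = zscore_matrix(table, small_catalog)
    wt_z = reference_replicate_zscores(table, small_catalog)
    shared = [p for p in z.params if p in set(wt_z.params)]
    z.z = z.z[shared]
    wt_z.z = wt_z.z[shared]
    return z, wt_z


def moment_zscores(table, params=None):
    """Cheap moment-based standardization against the wild-type cultures.

    Used where a Z-like matrix is needed at scales where per-trait GLM fits
    would dominate the runtime (e.g. many-seed Mahalanobis experiments).
    """
    v = table.values
    if params is None:
        params = [c for c in v.columns if c not in ("strain_id", "group", "replicate_index")]
    wt = v[v.group == "wildtype"]
    mu, sd = wt[params].mean(), wt[params].std(ddof=1)
    by_strain = v[v.group != "wildtype"].groupby("strain_id")[params].mean()
    z = (by_strain - mu) / sd
    zw = (wt.set_index("strain_id")[params] - mu) / sd
    zw.index = [f"wt_rep{i}" for i in range(len(zw))]
    return z, zw
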