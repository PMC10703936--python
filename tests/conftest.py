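import numpy as np
import pandas as pd
import pytest

from mddpipe import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-region cohort with the default planted structure, desk scale."""
    cfg = simulate.SimConfig(
        n_genes=300,
        samples_per_region={"DLPFC": (25, 25), "nACC": (20, 20)},
        de_genes=(simulate.DEGeneSpec("G0000", -1.0, ("DLPFC", "nACC")),),
        module_specs=(),
        pathway_specs=simulate.PathwaySpec(
            n_pathways=8, genes_per_pathway=10, informative_pathway_ids=(0,),
            informative_effect=0.0,
        ),
        seed=42,
    )
    pathways = simulate.generate_pathways(cfg)
    metadata = simulate.generate_metadata(cfg)
    counts, truth = simulate.generate_counts(cfg, metadata, pathways)
    return cfg, counts, metadata, pathways, truth


def two_group_counts(rng, n_genes=50, n_per_group=30, mu=100.0, alpha=0.1,
                     log2fc=0.0):
    """Plain two-group NB counts without the full cohort machinery."""
    n = 2 * n_per_group
    group = np.repeat([0, 1], n_per_group)
    mu_mat = np.full((n_genes, n), mu)
    mu_mat[:, group == 1] *= 2.0**log2fc
    if alpha > 0:
        counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu_mat))
    else:
        counts = rng.poisson(mu_mat)
    cdf = pd.DataFrame(
        counts, index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n)],
    )
    meta = pd.DataFrame(
        {"condition": np.where(group == 1, "CASE", "CTRL")}, index=cdf.columns
    )
    return cdf, meta
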