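import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import phenoz

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_config(
    n_lines: int = 8,
    families=("endpoint_continuous",),
    effects: dict | None = None,
    block_sd: float = 0.0,
    n_blocks: int = 1,
    n_per_cell: int = 15,
    seed: int = 0,
    noise_sd: float = 1.0,
    twin_allele_genes: int = 0,
) -> phenoz.SimConfig:
    """Small single-allele-per-gene configuration for unit tests.

    ``effects`` maps (gene_index, assay_index) -> planted effect in residual
    SDs; unlisted cells are null.
    """
    n_genes = n_lines - twin_allele_genes
    genes = [f"G{i}" for i in range(n_genes)]
    allele_map = {}
    for i, g in enumerate(genes):
        allele_map[f"{g.lower()}a"] = g
        if i < twin_allele_genes:
            allele_map[f"{g.lower()}b"] = g
    assays = []
    for j, fam in enumerate(families):
        tps = ()
        if fam == "timecourse_continuous":
            tps = (0.0, 24.0)
        elif fam == "germination_curve":
            tps = tuple(float(t) for t in range(0, 55, 5))
        assays.append(
            phenoz.AssayDesign(f"a{j}_{fam}", fam, timepoints=tps,
                               noise_sd=noise_sd, n_blocks=n_blocks)
        )
    eff = pd.DataFrame(0.0, index=genes, columns=[a.assay_id for a in assays])
    for (gi, aj), v in (effects or {}).items():
        eff.iloc[gi, aj] = v
    return phenoz.SimConfig(
        allele_map=allele_map, assays=assays, effect_matrix=eff,
        block_sd=block_sd, n_per_cell=n_per_cell, seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def null_table():
    """One null endpoint assay, 8 lines, one block."""
    return phenoz.simulate_dataset(make_config(seed=7))
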