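import numpy as np
import pandas as pd
import pytest

from apemeth import synthetic_data as sd


@pytest.fixture(scope="session")
def ape_tree():
    return sd.great_ape_tree()


@pytest.fixture(scope="session")
def manifest_small():
    """2,000-probe manifest shared across tests (seeded, deterministic)."""
    manifest, genes, islands = sd.simulate_manifest(2000, seed=1)
    return manifest, genes, islands


@pytest.fixture(scope="session")
def cohort_small(ape_tree, manifest_small):
    """A 2,000-probe, 4x6-sample cohort with planted lineage effects."""
    manifest, _, _ = manifest_small
    planted = sd.PlantedConfig(n_dm=80, dm_lineages=("Human",), n_xci_escape=10)
    betas, sheet, truth = sd.simulate_betas(
        ape_tree, manifest, n_per_taxon=6, planted=planted, seed=7
    )
    return betas, sheet, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_sheet(n_per_taxon=6, taxa=("Human", "Pan", "Gorilla", "Pongo")):
    rows = []
    for t in taxa:
        for i in range(n_per_taxon):
            rows.append((f"{t}{i + 1:02d}", t, t, "F" if i % 2 == 0 else "M"))
    return pd.DataFrame(rows, columns=["sample", "species", "genus", "sex"]).set_index(
        "sample"
    )
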