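"""Shared fixtures: random datasets and on-disk synthetic Visium bundles."""

import numpy as np
import pandas as pd
import pytest

import spotframe as sf


def random_dataset(rng, n_features=5, n_obs=6, n_samples=1, with_visium_cols=False,
                   with_reduced=True, sparse=False):
    """Small random SpatialDataset for property-style checks."""
    import scipy.sparse as sp

    counts = rng.integers(0, 20, size=(n_features, n_obs))
    assays = {"counts": sp.csr_matrix(counts) if sparse else counts}
    rows = pd.DataFrame(
        {
            "feature_id": [f"g{i}" for i in range(n_features)],
            "symbol": [f"Sym{i}" for i in range(n_features)],
        }
    )
    samples = [f"s{1 + (j * n_samples) // n_obs}" for j in range(n_obs)]
    cols = pd.DataFrame({"barcode_id": [f"bc{j}" for j in range(n_obs)], "sample_id": samples})
    if with_visium_cols:
        cols["in_tissue"] = rng.random(n_obs) < 0.5
        cols["array_row"] = rng.integers(0, 10, n_obs)
        cols["array_col"] = rng.integers(0, 10, n_obs)
    coords = rng.uniform(0, 1000, size=(n_obs, 2))
    reduced = {"pca": rng.normal(size=(n_obs, 3))} if with_reduced else None
    return sf.SpatialDataset(
        assays,
        row_annotations=rows,
        col_annotations=cols,
        spatial_coords=coords,
        reduced_dims=reduced,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)


@pytest.fixture(scope="session")
def visium_bundle(tmp_path_factory):
    """One synthetic Space Ranger bundle plus its manifest (session-wide)."""
    root = tmp_path_factory.mktemp("bundle")
    manifest = sf.make_visium_fixture(
        root, n_array_rows=8, n_array_cols=8, n_genes=60, tissue_fraction=0.5, seed=11
    )
    return root, manifest


@pytest.fixture(scope="session")
def molecule_fixture():
    table, manifest = sf.make_molecule_fixture(
        n_cells=15, n_genes=8, mean_molecules_per_pair=2.5, seed=7
    )
    return table, manifest
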