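import warnings

import numpy as np
import pytest

from microrepop.simulate import default_params, generate_counts


@pytest.fixture(scope="session")
def small_params():
    """Study-structured generator parameters at a desk-test scale."""
    return default_params(n_genes=600, n_cells_per_sample=150, seed=42)


@pytest.fixture(scope="session")
def small_matrix(small_params):
    return generate_counts(small_params)


@pytest.fixture(scope="session")
def clustered_pipeline():
    """QC'd, normalised, clustered synthetic dataset shared across tests."""
    from microrepop.preprocess import (
        log_normalize,
        reduce_pca,
        regress_covariates,
        select_hvgs,
    )
    from microrepop.clustering import cluster_cells
    from microrepop.qc import apply_qc, cell_stats

    params = default_params(n_cells_per_sample=400, seed=5)
    matrix = generate_counts(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, _ = apply_qc(matrix)
    norm_raw = log_normalize(matrix)
    stats = cell_stats(matrix)
    reg = regress_covariates(norm_raw, stats[["total_umi", "pct_mito"]])
    hvgs = select_hvgs(reg, 3000)
    scores, _ = reduce_pca(reg, hvgs, n_pcs=10, seed=0)
    assignment = cluster_cells(scores, resolution=0.2, seed=0)
    return {
        "params": params,
        "matrix": matrix,
        "norm_raw": norm_raw,
        "reg": reg,
        "scores": scores,
        "assignment": assignment,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
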