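"""Shared fixtures: small synthetic panels with recorded truth."""

import numpy as np
import pandas as pd
import pytest

from spermrec import (
    SimConfig,
    simulate_donor,
    simulate_gametes,
)
from spermrec.datatypes import GenotypeMatrix


@pytest.fixture(scope="session")
def noiseless_panel():
    """Error-free, dropout-free panel: 2 chromosomes, 40 cells."""
    cfg = SimConfig(
        chrom_lengths={"chr1": 10_000_000, "chr2": 8_000_000},
        htsnp_density=100,
        map_length=1.0,
        distal_enrichment=0.0,
        error_rate=0.0,
        missing_rate=0.0,
        n_cells=40,
        seed=1,
    )
    donor, sites = simulate_donor(cfg)
    matrix, truth = simulate_gametes(donor, cfg)
    return cfg, donor, matrix, truth


@pytest.fixture(scope="session")
def dropout_panel():
    """Error-free panel with 40% dropout: exercises both imputation stages."""
    cfg = SimConfig(
        chrom_lengths={"chr1": 10_000_000},
        htsnp_density=100,
        map_length=1.0,
        distal_enrichment=0.0,
        error_rate=0.0,
        missing_rate=0.4,
        n_cells=40,
        seed=2,
    )
    donor, _ = simulate_donor(cfg)
    matrix, truth = simulate_gametes(donor, cfg)
    return cfg, donor, matrix, truth


@pytest.fixture(scope="session")
def noisy_panel():
    """Small panel at realistic noise: error 1%, dropout 50%."""
    cfg = SimConfig(
        chrom_lengths={"chr1": 12_000_000, "chr2": 10_000_000},
        htsnp_density=80,
        map_length=1.0,
        distal_enrichment=0.2,
        error_rate=0.01,
        missing_rate=0.5,
        n_cells=50,
        seed=3,
    )
    donor, _ = simulate_donor(cfg)
    matrix, truth = simulate_gametes(donor, cfg)
    return cfg, donor, matrix, truth


def make_matrix(calls, positions=None, chrom="chr1", cells=None, ad=None):
    """Hand-built GenotypeMatrix for unit fixtures."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_cells = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    if cells is None:
        cells = [f"c{i}" for i in range(n_cells)]
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": np.asarray(positions, dtype=np.int64),
        "ref": "A",
        "alt": "G",
    })
    return GenotypeMatrix(sites=sites, calls=calls, cells=list(cells), ad=ad)
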