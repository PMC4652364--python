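"""Shared fixtures: small simulated populations built at test time."""

import numpy as np
import pandas as pd
import pytest

from salmopred import genio, simdata


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down full-sib design for fast module-level tests."""
    return simdata.SimConfig(
        n_sires=8, n_dams=12, n_families=12, total_offspring=120,
        n_chromosomes=5, n_snps=600, n_causal=100,
        n_base_generations=4, n_base_individuals=30,
    )


@pytest.fixture(scope="session")
def small_pop(small_config):
    return simdata.simulate_population(small_config, seed=7)


@pytest.fixture(scope="session")
def default_pop():
    """One population at the full matched design (534 offspring, 5K SNPs)."""
    return simdata.simulate_population(seed=1)


@pytest.fixture
def trio_pedigree():
    """Two unrelated parents and two full-sib offspring."""
    return genio.Pedigree.from_records(pd.DataFrame({
        "id": ["SIRE", "DAM", "KID1", "KID2"],
        "sire": ["0", "0", "SIRE", "SIRE"],
        "dam": ["0", "0", "DAM", "DAM"],
        "sex": ["M", "F", "M", "F"],
    }))


def make_genotypes(dosages, sample_ids=None, chrom=None, contig=None):
    """Small helper to build a GenotypeMatrix from a raw dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    sample_ids = sample_ids or [f"IND{i}" for i in range(n)]
    snps = pd.DataFrame({
        "id": [f"M{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": np.arange(1, m + 1) * 1000,
        "cm": np.arange(1, m + 1, dtype=float),
        "contig": contig if contig is not None else [f"c{j}" for j in range(m)],
        "a1": "A", "a2": "B",
    })
    return genio.GenotypeMatrix(samples=sample_ids, snps=snps, dosages=dosages)
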