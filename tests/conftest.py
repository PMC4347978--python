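"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pandas as pd
import pytest

from eduroh.genotypes import GenotypeMatrix
from eduroh.synthetic_data import simulate_families, simulate_genotypes


@pytest.fixture(scope="session")
def families_5k():
    """Large family table at default study conditions (no genotypes)."""
    return simulate_families(5000, seed=101)


@pytest.fixture(scope="session")
def cohort_small():
    """600-family cohort with genotypes at default study conditions."""
    fam = simulate_families(600, seed=202)
    gm, truth = simulate_genotypes(fam, seed=303)
    return fam, gm, truth


def make_genotype_matrix(calls, positions=None, chrom="1", sample_prefix="s"):
    """Assemble a GenotypeMatrix from a raw call array on one chromosome."""
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[None, :]
    m = calls.shape[1]
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    snp_map = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions),
            "snp": [f"snp{j}" for j in range(m)],
            "a1": "A",
            "a2": "B",
        }
    )
    ids = [f"{sample_prefix}{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(calls=calls, snp_map=snp_map, sample_ids=ids)
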