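"""In-memory genotype container shared by the simulator, ROH caller and PCA."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = ["GenotypeMatrix", "MISSING"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs matrix of counted-allele calls with a physical map.

    calls
        int8 array of shape (n_samples, n_snps); values 0/1/2 count copies
        of allele ``a1``, -1 marks a missing call.
    snp_map
        DataFrame with columns ``chrom`` (label), ``pos`` (1-based bp),
        ``snp`` (identifier), ``a1``, ``a2``; positions strictly increasing
        within each chromosome.
    sample_ids
        One identifier per row of ``calls``.
    """

    calls: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x SNPs)")
        if len(self.snp_map) != self.calls.shape[1]:
            raise ValueError(
                f"snp_map has {len(self.snp_map)} rows for "
                f"{self.calls.shape[1]} SNP columns"
            )
        if len(self.sample_ids) != self.calls.shape[0]:
            raise ValueError("sample_ids length must match number of rows")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,missing}")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def subset_snps(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given SNP column indices (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            calls=self.calls[:, index],
            snp_map=self.snp_map.iloc[index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )
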