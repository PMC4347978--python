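"""Published summary tables used as inputs and generator targets.

These are printed summary statistics from a Dutch twin-family cohort study
of educational attainment (EA), migration and homozygosity: the 4x4 spouse
EA crosstab (2,058 spouse pairs) and the mean parent-offspring /
parent-parent birthplace distances per EA level.  They serve two purposes:

* reconstruction checks — the crosstab statistics (chi-square, Spearman's
  rho, expected counts) can be recomputed exactly from the printed counts;
* generator targets — the synthetic cohort defaults (EA marginals,
  assortment strength, migration scales) are taken from these tables.

EA levels: 1 = primary, 2 = secondary, 3 = higher secondary, 4 = tertiary.
"""

from __future__ import annotations

import numpy as np

#: Observed spouse-pair counts, rows = father EA 1-4, columns = mother EA 1-4.
SPOUSE_EA_OBSERVED = np.array(
    [
        [273, 79, 11, 8],
        [110, 528, 70, 24],
        [38, 190, 151, 31],
        [13, 120, 161, 251],
    ],
    dtype=np.int64,
)

#: Father-side EA marginal probabilities derived from the crosstab rows.
EA_MARGINALS = SPOUSE_EA_OBSERVED.sum(axis=1) / SPOUSE_EA_OBSERVED.sum()

#: Reported spouse-EA Spearman correlation (the assortment target).
SPOUSE_SPEARMAN_RHO = 0.664

#: Reported parent-offspring EA Spearman correlation (paternal; maternal .38).
PARENT_OFFSPRING_SPEARMAN_RHO = 0.40

#: Mean birthplace distance (km), SD and N per EA level.
#: keys: "father_own" = paternal vs own birthplace by paternal EA,
#:       "mother_own" = maternal vs own birthplace by maternal EA,
#:       "parents_by_father" / "parents_by_mother" = paternal vs maternal
#:       birthplace by paternal / maternal EA.
MIGRATION_KM_BY_EA = {
    "father_own": {
        "mean": np.array([19.2, 16.3, 28.7, 49.8]),
        "sd": np.array([32.4, 30.8, 46.0, 55.3]),
        "n": np.array([172, 512, 291, 375]),
    },
    "mother_own": {
        "mean": np.array([19.2, 24.1, 34.6, 56.7]),
        "sd": np.array([34.7, 37.8, 44.2, 52.6]),
        "n": np.array([245, 722, 293, 223]),
    },
    "parents_by_father": {
        "mean": np.array([22.8, 23.5, 34.0, 46.4]),
        "sd": np.array([34.9, 39.7, 49.8, 50.5]),
        "n": np.array([144, 483, 284, 383]),
    },
    "parents_by_mother": {
        "mean": np.array([25.5, 24.8, 36.2, 54.7]),
        "sd": np.array([47.8, 39.9, 46.6, 52.7]),
        "n": np.array([145, 641, 283, 222]),
    },
}

#: Reported moderated PC-geography trend for PC1 vs paternal EA:
#: rho_g = RHO0_PC1 + g * RHO1_PC1_PATERNAL for EA group g in {0,1,2,3}.
RHO0_PC1 = 0.74
RHO1_PC1_PATERNAL = -0.06

#: SNP-mappable autosomal length (bp) used as the F_roh denominator on the
#: real genotyping array; synthetic cohorts use their own mapped length.
REAL_ARRAY_DENOMINATOR_BP = 2.77e9
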