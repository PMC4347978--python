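"""Generator: deme grid geometry, assortment calibration, migration scales,
HBD truth structure and determinism."""

import numpy as np
import pytest
from scipy import stats

from eduroh.geo import great_circle_km, pairwise_km
from eduroh.reference_tables import MIGRATION_KM_BY_EA
from eduroh.synthetic_data import (
    build_deme_map,
    default_snp_map,
    latent_corr_for_spearman,
    simulate_families,
    simulate_genotypes,
)


class TestDemeMap:
    def test_single_point_grid(self):
        dm = build_deme_map(1, 1, 10.0, origin=(52.0, 5.0))
        assert dm.n_demes == 1
        assert dm.latitude[0] == 52.0 and dm.longitude[0] == 5.0

    def test_two_demes_spacing(self):
        dm = build_deme_map(2, 1, 10.0, origin=(52.0, 5.0))
        d = great_circle_km(
            (dm.latitude[0], dm.longitude[0]), (dm.latitude[1], dm.longitude[1])
        )
        assert d == pytest.approx(10.0, rel=0.01)

    def test_grid_extent(self):
        dm = build_deme_map(10, 10, 15.0, origin=(52.0, 5.0))
        assert dm.n_demes == 100
        # bounding box spans 9 spacings per axis
        south_west = (dm.latitude.min(), dm.longitude.min())
        north_west = (dm.latitude.max(), dm.longitude.min())
        assert great_circle_km(south_west, north_west) == pytest.approx(135.0, rel=0.02)

    def test_adjacent_spacing_within_one_percent(self):
        dm = build_deme_map(8, 8, 12.0, origin=(51.0, 4.0))
        lat = dm.latitude.reshape(8, 8)
        lon = dm.longitude.reshape(8, 8)
        for i in range(8):
            for j in range(7):
                d_ew = great_circle_km((lat[i, j], lon[i, j]), (lat[i, j + 1], lon[i, j + 1]))
                d_ns = great_circle_km((lat[j, i], lon[j, i]), (lat[j + 1, i], lon[j + 1, i]))
                assert d_ew == pytest.approx(12.0, rel=0.01)
                assert d_ns == pytest.approx(12.0, rel=0.01)

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError, match="grid dimensions"):
            build_deme_map(0, 3, 10.0)
        with pytest.raises(ValueError, match="spacing"):
            build_deme_map(2, 2, -1.0)


class TestAssortment:
    def test_independence_case(self):
        fam = simulate_families(5000, assortment_rho=0.0, seed=7)
        rho = stats.spearmanr(fam.father_ea, fam.mother_ea).statistic
        assert abs(rho) < 0.05

    def test_target_rho_recovered(self, families_5k):
        rho = stats.spearmanr(families_5k.father_ea, families_5k.mother_ea).statistic
        assert 0.61 <= rho <= 0.71

    def test_parent_offspring_rho(self, families_5k):
        for col in ("father_ea", "mother_ea"):
            rho = stats.spearmanr(families_5k[col], families_5k.offspring_ea).statistic
            assert rho == pytest.approx(0.40, abs=0.05)

    def test_monotone_in_target(self):
        observed = []
        for target in (0.2, 0.5, 0.8):
            fam = simulate_families(5000, assortment_rho=target, seed=11)
            observed.append(stats.spearmanr(fam.father_ea, fam.mother_ea).statistic)
        assert observed[0] < observed[1] < observed[2]

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            simulate_families(10, assortment_rho=1.0, seed=0)

    def test_latent_calibration_population_exact(self):
        # the calibrated latent correlation reproduces the target Spearman
        # in a huge Monte Carlo sample
        marg = [0.25, 0.25, 0.25, 0.25]
        r = latent_corr_for_spearman(0.5, marg)
        rng = np.random.default_rng(5)
        z1 = rng.standard_normal(200_000)
        z2 = r * z1 + np.sqrt(1 - r**2) * rng.standard_normal(200_000)
        thr = stats.norm.ppf(np.cumsum(marg)[:-1])
        rho = stats.spearmanr(np.searchsorted(thr, z1), np.searchsorted(thr, z2)).statistic
        assert rho == pytest.approx(0.5, abs=0.01)


class TestMigration:
    def test_father_offspring_distance_tracks_ea(self, families_5k):
        mig = MIGRATION_KM_BY_EA["father_own"]["mean"]
        d = pairwise_km(
            families_5k.f_lat, families_5k.f_lon, families_5k.o_lat, families_5k.o_lon
        )
        for lev in range(1, 5):
            mean = d[families_5k.father_ea == lev].mean()
            assert mean == pytest.approx(mig[lev - 1], rel=0.15)

    def test_parental_distance_mean(self, families_5k):
        # father-mother distance mean approximates the average of the two
        # spouses' EA-specific migration scales
        d = pairwise_km(
            families_5k.f_lat, families_5k.f_lon, families_5k.m_lat, families_5k.m_lon
        )
        mig = MIGRATION_KM_BY_EA["father_own"]["mean"]
        mu_f = mig[families_5k.father_ea - 1]
        mu_m = mig[families_5k.mother_ea - 1]
        assert d.mean() == pytest.approx(((mu_f + mu_m) / 2).mean(), rel=0.15)

    def test_marginals_match(self, families_5k):
        from eduroh.reference_tables import EA_MARGINALS

        counts = np.bincount(families_5k.father_ea, minlength=5)[1:]
        se = np.sqrt(EA_MARGINALS * (1 - EA_MARGINALS) / 5000)
        assert np.all(np.abs(counts / 5000 - EA_MARGINALS) < 4 * se)

    def test_coordinates_inside_bounding_box(self, families_5k):
        from eduroh.synthetic_data import default_deme_map

        lat_min, lat_max, lon_min, lon_max = default_deme_map().bounding_box
        for prefix in ("f", "m", "o"):
            assert families_5k[f"{prefix}_lat"].between(lat_min, lat_max).all()
            assert families_5k[f"{prefix}_lon"].between(lon_min, lon_max).all()

    def test_ea_levels_valid(self, families_5k):
        for col in ("father_ea", "mother_ea", "offspring_ea"):
            assert families_5k[col].isin([1, 2, 3, 4]).all()
        assert not families_5k.isna().any().any()

    def test_deterministic(self):
        a = simulate_families(200, seed=42)
        b = simulate_families(200, seed=42)
        assert a.equals(b)

    def test_requested_missingness(self):
        fam = simulate_families(1000, seed=13, missing_rate=0.1)
        for col in ("father_ea", "mother_ea", "f_lat", "m_lat"):
            assert fam[col].isna().mean() == pytest.approx(0.1, abs=0.04)
        assert not fam[["offspring_ea", "o_lat", "o_lon"]].isna().any().any()


class TestGenotypes:
    def test_no_kinship_no_hbd(self, families_5k):
        fam = families_5k.head(50)
        _, truth = simulate_genotypes(fam, kinship_kernel=(0.0, 40.0), seed=1)
        assert len(truth.hbd_segments) == 0
        assert np.all(truth.kinship == 0)

    def test_stationary_hbd_fraction(self):
        # phi=0.1 at zero distance: expected HBD genome fraction = phi/2
        fam = simulate_families(500, seed=8)
        _, truth = simulate_genotypes(fam, kinship_kernel=(0.1, 1e12), seed=9)
        frac = truth.hbd_fraction(fam.family_id)
        assert frac.mean() == pytest.approx(0.05, rel=0.2)

    def test_hbd_fraction_decreases_with_distance(self, cohort_small):
        fam, gm, truth = cohort_small
        frac = truth.hbd_fraction(gm.sample_ids)
        d = truth.parental_distance_km
        bins = np.digitize(d, [10, 30, 60])
        means = [frac[bins == b].mean() for b in range(4) if np.any(bins == b)]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_kinship_kernel_formula(self, cohort_small):
        fam, gm, truth = cohort_small
        phi0 = truth.params["phi0"]
        lam = truth.params["lambda_km"]
        expected = phi0 * np.exp(-truth.parental_distance_km / lam)
        np.testing.assert_allclose(truth.kinship, expected, rtol=1e-12)

    def test_hbd_segments_non_overlapping(self, cohort_small):
        _, _, truth = cohort_small
        for (sample, chrom), grp in truth.hbd_segments.groupby(["sample", "chrom"]):
            spans = grp.sort_values("start")
            assert (spans["start"].to_numpy()[1:] > spans["end"].to_numpy()[:-1]).all()

    def test_deterministic(self):
        fam = simulate_families(40, seed=3)
        g1, t1 = simulate_genotypes(fam, seed=4)
        g2, t2 = simulate_genotypes(fam, seed=4)
        assert np.array_equal(g1.calls, g2.calls)
        assert t1.hbd_segments.equals(t2.hbd_segments)

    def test_empty_snp_map_rejected(self, families_5k):
        import pandas as pd

        empty = default_snp_map().iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            simulate_genotypes(families_5k.head(5), empty, seed=0)

    def test_calls_valid(self, cohort_small):
        _, gm, _ = cohort_small
        assert np.isin(gm.calls, [0, 1, 2]).all()
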