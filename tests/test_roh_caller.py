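"""ROH calling against a brute-force oracle, VIF pruning against direct
regression, and the F_roh arithmetic."""

import numpy as np
import pytest

from eduroh.roh_caller import (
    ROHSegment,
    call_rohs,
    compute_froh,
    mappable_length_bp,
    vif_prune,
)

from conftest import make_genotype_matrix


def brute_force_rohs(calls, positions, min_snps, missing_breaks=True):
    """Oracle: examine every (start, end) index pair for valid maximal runs.

    A valid run starts and ends at homozygous calls and contains no
    heterozygote (nor, with ``missing_breaks``, any missing call).  It is
    maximal when the nearest non-breaking call beyond either edge is not
    homozygous.
    """

    def hom(c):
        return c in (0, 2)

    def extendable(idx, step):
        # nearest call beyond the edge that could prolong the run
        i = idx + step
        L = len(calls)
        while 0 <= i < L:
            if hom(calls[i]):
                return True
            if calls[i] == 1 or (missing_breaks and calls[i] == -1):
                return False
            i += step  # skip a tolerated missing call
        return False

    runs = []
    L = len(calls)
    for a in range(L):
        for b in range(a, L):
            window = calls[a : b + 1]
            if not (hom(window[0]) and hom(window[-1])):
                continue
            if any(c == 1 or (missing_breaks and c == -1) for c in window):
                continue
            if extendable(a, -1) or extendable(b, +1):
                continue
            n_hom = sum(hom(c) for c in window)
            if n_hom >= min_snps:
                runs.append((int(positions[a]), int(positions[b]), n_hom))
    return runs


class TestCallRohs:
    @pytest.mark.parametrize("n_hom,expect", [(64, 0), (65, 1), (66, 1)])
    def test_min_snps_boundary(self, n_hom, expect):
        calls = np.ones(140, dtype=np.int8)  # heterozygous background
        calls[10 : 10 + n_hom] = 2
        gm = make_genotype_matrix(calls)
        segs = call_rohs(gm, min_snps=65)
        assert len(segs) == expect
        if expect:
            assert segs[0].n_snps == n_hom

    def test_het_splits_run(self):
        # 130 homozygous calls with one heterozygote after the 65th:
        # left flank of 65 qualifies, right flank of 64 does not
        calls = np.full(130, 2, dtype=np.int8)
        calls[65] = 1
        gm = make_genotype_matrix(calls)
        segs = call_rohs(gm, min_snps=65)
        assert len(segs) == 1
        assert segs[0].n_snps == 65
        assert segs[0].start_bp == 1000 and segs[0].end_bp == 65000

    def test_all_heterozygous(self):
        gm = make_genotype_matrix(np.ones(200, dtype=np.int8))
        assert call_rohs(gm, min_snps=65) == []

    def test_missing_breaks_run(self):
        calls = np.full(100, 0, dtype=np.int8)
        calls[66] = -1
        gm = make_genotype_matrix(calls)
        assert len(call_rohs(gm, min_snps=65)) == 1  # only the left flank (66)
        assert len(call_rohs(gm, min_snps=65, missing_breaks=False)) == 1
        seg = call_rohs(gm, min_snps=65, missing_breaks=False)[0]
        assert seg.n_snps == 99  # missing call inside span, not counted

    def test_runs_do_not_span_chromosomes(self):
        import pandas as pd

        calls = np.full((1, 130), 2, dtype=np.int8)
        snp_map = pd.DataFrame(
            {
                "chrom": ["1"] * 65 + ["2"] * 65,
                "pos": list(range(1, 66)) + list(range(1, 66)),
                "snp": [f"s{i}" for i in range(130)],
                "a1": "A",
                "a2": "B",
            }
        )
        from eduroh.genotypes import GenotypeMatrix

        gm = GenotypeMatrix(calls=calls, snp_map=snp_map, sample_ids=["x"])
        segs = call_rohs(gm, min_snps=65)
        assert len(segs) == 2
        assert {s.chromosome for s in segs} == {"1", "2"}

    @pytest.mark.parametrize("missing_breaks", [True, False])
    def test_agrees_with_brute_force_oracle(self, missing_breaks):
        """Exhaustive agreement on 1,000 random 200-SNP vectors."""
        rng = np.random.default_rng(12345)
        positions = np.sort(rng.choice(np.arange(1, 10**6), size=200, replace=False))
        for trial in range(1000):
            # mixture tuned to produce long homozygous stretches sometimes
            p_state = rng.uniform(0.3, 0.95)
            calls = rng.choice(
                [0, 2, 1, -1],
                size=200,
                p=[p_state / 2, p_state / 2, (1 - p_state) * 0.8, (1 - p_state) * 0.2],
            ).astype(np.int8)
            min_snps = int(rng.integers(2, 80))
            gm = make_genotype_matrix(calls, positions=positions)
            got = [
                (s.start_bp, s.end_bp, s.n_snps)
                for s in call_rohs(gm, min_snps=min_snps, missing_breaks=missing_breaks)
            ]
            want = brute_force_rohs(calls, positions, min_snps, missing_breaks)
            assert got == want, f"trial {trial}: {got} != {want}"

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(77)
        calls = rng.choice([0, 1, 2], size=(5, 300), p=[0.45, 0.1, 0.45]).astype(np.int8)
        gm = make_genotype_matrix(calls)
        flipped = make_genotype_matrix((2 - calls).astype(np.int8))
        a = [(s.sample_id, s.start_bp, s.end_bp) for s in call_rohs(gm, min_snps=20)]
        b = [(s.sample_id, s.start_bp, s.end_bp) for s in call_rohs(flipped, min_snps=20)]
        assert a == b


class TestVifPrune:
    def test_duplicated_snp_removed(self):
        rng = np.random.default_rng(1)
        base = rng.choice([0, 1, 2], size=(300, 10)).astype(np.int8)
        base[:, 5] = base[:, 4]  # exact duplicate
        gm = make_genotype_matrix(base)
        kept = vif_prune(gm, window_snps=10, step_snps=5)
        assert (4 in kept) != (5 in kept)  # exactly one of the pair survives
        assert kept.size == 9

    def test_independent_snps_kept(self):
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, rng.uniform(0.2, 0.8, 400), size=(500, 400)).astype(np.int8)
        gm = make_genotype_matrix(calls)
        kept = vif_prune(gm)
        assert kept.size >= 0.95 * 400

    def test_toy_window_matches_direct_vif(self):
        # three SNPs, two strongly correlated: the max-VIF SNP is removed
        rng = np.random.default_rng(3)
        n = 2000
        a = rng.binomial(2, 0.5, n)
        noise = rng.random(n) < 0.2
        b = np.where(noise, rng.binomial(2, 0.5, n), a)  # r^2 ~ 0.64 with a
        c = rng.binomial(2, 0.5, n)
        calls = np.column_stack([a, b, c]).astype(np.int8)

        # direct VIF oracle by explicit regression
        Z = (calls - calls.mean(0)) / calls.std(0)
        vifs = []
        for j in range(3):
            others = np.delete(Z, j, axis=1)
            coef, *_ = np.linalg.lstsq(others, Z[:, j], rcond=None)
            r2 = 1 - np.sum((Z[:, j] - others @ coef) ** 2) / n
            vifs.append(1 / (1 - r2))
        assert max(vifs) >= 2.0  # the pair exceeds the threshold

        gm = make_genotype_matrix(calls)
        kept = vif_prune(gm, window_snps=3, step_snps=2, vif_threshold=2.0)
        dropped = set(range(3)) - set(kept.tolist())
        assert dropped == {int(np.argmax(vifs))}

    def test_uncorrelated_toy_window_all_kept(self):
        rng = np.random.default_rng(4)
        calls = rng.binomial(2, 0.5, size=(1000, 3)).astype(np.int8)
        gm = make_genotype_matrix(calls)
        kept = vif_prune(gm, window_snps=3, step_snps=2, vif_threshold=2.0)
        assert kept.size == 3

    def test_monomorphic_dropped(self):
        rng = np.random.default_rng(5)
        calls = rng.binomial(2, 0.5, size=(100, 5)).astype(np.int8)
        calls[:, 2] = 2
        gm = make_genotype_matrix(calls)
        kept = vif_prune(gm, window_snps=5, step_snps=2)
        assert 2 not in kept

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        calls = rng.binomial(2, 0.5, size=(200, 120)).astype(np.int8)
        gm = make_genotype_matrix(calls)
        k1 = vif_prune(gm)
        k2 = vif_prune(gm)
        assert np.array_equal(k1, k2)
        assert np.all(np.diff(k1) > 0)  # order-preserving

    def test_parameter_validation(self):
        gm = make_genotype_matrix(np.zeros((10, 10), dtype=np.int8))
        with pytest.raises(ValueError):
            vif_prune(gm, window_snps=5, step_snps=5)
        with pytest.raises(ValueError):
            vif_prune(gm, vif_threshold=1.0)


class TestFroh:
    def test_no_segments_zero(self):
        out = compute_froh([], 2.77e9, sample_ids=["a", "b"])
        assert (out["froh"] == 0).all()

    def test_forced_arithmetic(self):
        seg = ROHSegment("a", "1", 1_000_000, 28_700_000, 1000)
        out = compute_froh([seg], 2.77e9)
        assert out.loc[0, "froh"] == pytest.approx(27_700_000 / 2.77e9)
        assert out.loc[0, "froh"] == pytest.approx(0.01)

    def test_overlap_rejected(self):
        segs = [
            ROHSegment("a", "1", 100, 500, 65),
            ROHSegment("a", "1", 400, 900, 65),
        ]
        with pytest.raises(ValueError, match="overlap"):
            compute_froh(segs, 1e6)

    def test_bad_denominator(self):
        with pytest.raises(ValueError):
            compute_froh([], 0)

    def test_froh_tracks_truth(self, cohort_small):
        """Called F_roh rank-correlates > 0.9 with the generator's true HBD
        fraction at default marker density."""
        from scipy import stats

        fam, gm, truth = cohort_small
        kept = vif_prune(gm)
        segs = call_rohs(gm.subset_snps(kept), min_snps=65)
        froh = compute_froh(segs, mappable_length_bp(gm.snp_map), sample_ids=gm.sample_ids)
        frac = truth.hbd_fraction(gm.sample_ids)
        rho = stats.spearmanr(froh["froh"], frac).statistic
        assert rho > 0.9

    def test_mappable_length(self):
        import pandas as pd

        sm = pd.DataFrame({"chrom": ["1", "1", "2", "2"], "pos": [100, 900, 50, 250]})
        assert mappable_length_bp(sm) == 800 + 200
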