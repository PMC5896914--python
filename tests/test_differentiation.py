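"""AMOVA, pairwise Fst, Fst ceilings, geographic distances and Mantel."""

import math

import numpy as np
import pytest

import msatnet as mn
from msatnet.differentiation import EARTH_RADIUS_KM, combined_fst_p_table

from conftest import make_table


def fixed_sites_table(n=6):
    """Two sites, each fixed for a different allele at one locus."""
    return make_table(
        {
            "A": [((1, 1),)] * n,
            "B": [((2, 2),)] * n,
        }
    )


class TestAmova:
    def test_fixed_differences_give_fst_one(self):
        res = mn.amova(fixed_sites_table(), n_perm=99, seed=0)
        assert res.fst == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_identical_individuals_give_fst_zero(self):
        t = make_table({"A": [((1, 2),)] * 4, "B": [((1, 2),)] * 4})
        res = mn.amova(t, n_perm=49, seed=0)
        assert res.fst == 0.0
        assert res.ss_among == pytest.approx(0.0)

    def test_single_site_raises(self):
        t = make_table({"A": [((1, 2),), ((1, 1),)]})
        with pytest.raises(ValueError):
            mn.amova(t, n_perm=0)

    def test_close_to_weir_cockerham(self, study_table):
        table, _ = study_table
        a = mn.amova(table, n_perm=0).fst
        wc = mn.weir_cockerham_theta(table)
        assert a == pytest.approx(wc, abs=0.01)


class TestPairwiseFst:
    def test_symmetry_zero_diagonal(self, study_table):
        table, _ = study_table
        fst, _ = mn.pairwise_fst(table, n_perm=0)
        assert np.allclose(fst.values, fst.values.T)
        assert np.allclose(np.diag(fst.values), 0.0)

    def test_fixed_pair_minimal_p(self):
        fst, p = mn.pairwise_fst(fixed_sites_table(), n_perm=99, seed=0)
        assert fst.values[0, 1] == pytest.approx(1.0)
        assert p.iloc[0, 1] == pytest.approx(1 / 100)

    def test_two_site_amova_matches_pairwise(self):
        t = make_table(
            {
                "A": [((1, 1),), ((1, 2),), ((2, 2),)],
                "B": [((2, 3),), ((3, 3),), ((3, 3),)],
            }
        )
        fst, _ = mn.pairwise_fst(t, n_perm=0)
        assert fst.values[0, 1] == pytest.approx(mn.amova(t, n_perm=0).fst)

    def test_tiny_site_flagged(self):
        t = make_table(
            {
                "A": [((1, 1),), ((1, 2),)],
                "B": [((2, 2),)],
                "C": [((1, 2),), ((2, 2),)],
            }
        )
        fst, _ = mn.pairwise_fst(t, n_perm=0)
        assert math.isnan(fst.values[0, 1])
        assert np.isfinite(fst.values[0, 2])

    def test_weir_cockerham_estimator_mode(self, study_table):
        table, _ = study_table
        fst, _ = mn.pairwise_fst(table, n_perm=0, estimator="weir_cockerham")
        assert np.isfinite(fst.condensed()).all()

    def test_combined_table_layout(self):
        fst, p = mn.pairwise_fst(fixed_sites_table(), n_perm=19, seed=0)
        comb = combined_fst_p_table(fst, p)
        assert comb.loc["B", "A"] == pytest.approx(1.0)  # Fst below diagonal
        assert comb.loc["A", "B"] == pytest.approx(1 / 20)  # p above


def brute_force_bound(constraint, value, K, n_extra=6, n_grid=120_000, seed=0):
    """Random-search oracle for the maximum Gst given a pooled-frequency
    constraint; subpopulations are equally weighted."""
    rng = np.random.default_rng(seed)
    best = 0.0
    A = K + n_extra
    for _ in range(n_grid // 100):
        P = rng.dirichlet(np.full(A, rng.uniform(0.05, 1.0)), size=K)
        # push towards extreme configurations half of the time
        if rng.random() < 0.5:
            P = np.where(P > rng.uniform(0.2, 0.8), P, 0)
            P = P + 1e-12
            P /= P.sum(axis=1, keepdims=True)
        pooled = P.mean(axis=0)
        if constraint == "M":
            # rescale so the most common allele hits the target frequency
            top = pooled.argmax()
            if pooled[top] <= 0:
                continue
            # mix with a configuration fixed on allele `top`
            lo, hi = 0.0, 1.0
            fixed = np.zeros(A)
            fixed[top] = 1.0
            for _ in range(40):
                mid = (lo + hi) / 2
                Q = (1 - mid) * P + mid * fixed
                if Q.mean(axis=0)[top] < value:
                    lo = mid
                else:
                    hi = mid
            Q = (1 - hi) * P + hi * fixed
            pooledq = Q.mean(axis=0)
            if abs(pooledq.max() - value) > 1e-3 or pooledq.argmax() != top:
                continue
        else:  # homozygosity
            target = value
            uniform = np.full((K, A), 1.0 / A)
            lo, hi = 0.0, 1.0
            for _ in range(40):
                mid = (lo + hi) / 2
                Q = (1 - mid) * uniform + mid * P
                if (Q.mean(axis=0) ** 2).sum() < target:
                    lo = mid
                else:
                    hi = mid
            Q = (1 - hi) * uniform + hi * P
            if abs((Q.mean(axis=0) ** 2).sum() - target) > 1e-3:
                continue
        j_s = (Q**2).sum(axis=1).mean()
        j_t = (Q.mean(axis=0) ** 2).sum()
        if j_t < 1:
            best = max(best, (j_s - j_t) / (1 - j_t))
    return best


class TestFstBounds:
    def test_biallelic_even_split_allows_full_fixation(self):
        assert mn.max_fst_given_M(0.5, 2) == pytest.approx(1.0)

    def test_biallelic_m_three_quarters(self):
        # attained at subpopulation frequencies (1, 0.5)
        assert mn.max_fst_given_M(0.75, 2) == pytest.approx(1 / 3)

    def test_lattice_homozygosity_allows_full_fixation(self):
        assert mn.max_fst_given_homozygosity(0.5, 2) == pytest.approx(1.0)

    @pytest.mark.parametrize("K", [2, 3])
    @pytest.mark.parametrize("M", [0.55, 0.6, 0.75, 0.9])
    def test_bound_M_not_exceeded_by_random_search(self, K, M):
        oracle = brute_force_bound("M", M, K, seed=K * 100 + int(M * 100))
        bound = mn.max_fst_given_M(M, K)
        assert oracle <= bound + 1e-3

    @pytest.mark.parametrize("K", [2, 3])
    @pytest.mark.parametrize("jt", [0.2, 0.35, 0.5, 0.7])
    def test_bound_HT_not_exceeded_by_random_search(self, K, jt):
        oracle = brute_force_bound("HT", jt, K, seed=K * 100 + int(jt * 100))
        bound = mn.max_fst_given_homozygosity(jt, K)
        assert oracle <= bound + 1e-3

    @staticmethod
    def gst(P):
        """Direct Gst of a K x A subpopulation frequency matrix."""
        j_s = (P**2).sum(axis=1).mean()
        j_t = (P.mean(axis=0) ** 2).sum()
        return (j_s - j_t) / (1 - j_t)

    @pytest.mark.parametrize("K,M", [(2, 0.75), (2, 0.6), (3, 0.5), (4, 0.3)])
    def test_bound_M_attained_by_extremal_configuration(self, K, M):
        """The closed-form ceiling is achieved by the configuration that
        fixes floor(K*M) subpopulations on the common allele, leaves the
        fractional remainder in one subpopulation and makes every other
        allele private."""
        j = int(np.floor(K * M))
        x = K * M - j
        A = K + 2
        P = np.zeros((K, A))
        for k in range(j):
            P[k, 0] = 1.0
        if x > 0:
            P[j, 0] = x
            P[j, 1] = 1.0 - x
        for k in range(j + 1, K):
            P[k, k + 1] = 1.0
        pooled = P.mean(axis=0)
        assert pooled.max() == pytest.approx(M)
        assert self.gst(P) == pytest.approx(mn.max_fst_given_M(M, K), abs=1e-12)

    @pytest.mark.parametrize("K,jt", [(2, 0.35), (2, 0.5), (3, 0.25), (3, 0.6)])
    def test_bound_HT_attained_by_extremal_configuration(self, K, jt):
        """A configuration achieving the homozygosity ceiling exists: below
        the 1/K lattice all alleles are private (pooled homozygosity is
        exactly 1/K of the within-subpopulation mean), above it
        subpopulations fix shared alleles with one partial mixer."""
        bound = mn.max_fst_given_homozygosity(jt, K)
        if jt <= 1 / K:
            # all-private: each subpopulation on two alleles (x, 1-x) with
            # homozygosity K*jt (requires K*jt >= 1/2, true for these cases)
            h = K * jt
            x = (1 + math.sqrt(2 * h - 1)) / 2
            P = np.zeros((K, 2 * K))
            for k in range(K):
                P[k, 2 * k] = x
                P[k, 2 * k + 1] = 1 - x
        else:
            best = None
            for j in range(1, K):
                # solve (j+x)^2 + (1-x)^2 + (K-j-1) = K^2 jt for x in [0, 1]
                target = K**2 * jt - (K - j - 1)
                roots = np.roots([2.0, 2.0 * j - 2.0, j**2 + 1.0 - target])
                for x in roots:
                    if abs(x.imag) < 1e-12 and -1e-9 <= x.real <= 1 + 1e-9:
                        best = (j, float(np.clip(x.real, 0, 1)))
                if best:
                    break
            assert best is not None
            j, x = best
            A = K + 2
            P = np.zeros((K, A))
            for k in range(j):
                P[k, 0] = 1.0
            P[j, 0] = x
            P[j, 1] = 1 - x
            for k in range(j + 1, K):
                P[k, k + 1] = 1.0
        assert (P.mean(axis=0) ** 2).sum() == pytest.approx(jt, abs=1e-4)
        assert self.gst(P) == pytest.approx(bound, abs=1e-3)

    def test_observed_fst_below_mean_bounds(self, study_table):
        table, _ = study_table
        fst = mn.amova(table, n_perm=0).fst
        bounds = mn.fst_upper_bounds(mn.allele_frequencies(table), K=len(table.sites))
        assert fst <= bounds.mean_bound_M + 1e-9
        assert fst <= bounds.mean_bound_HT + 1e-9

    def test_monomorphic_locus_flagged(self):
        t = make_table({"A": [((1, 1), (1, 2))] * 3, "B": [((1, 1), (2, 2))] * 3})
        bounds = mn.fst_upper_bounds(mn.allele_frequencies(t), K=2)
        row = bounds.per_locus.set_index("locus")
        assert math.isnan(row.loc["L1", "bound_M"])
        assert np.isfinite(row.loc["L2", "bound_M"])


class TestLinearizeFst:
    def test_known_values_and_monotonicity(self):
        m = mn.DistanceMatrix(
            np.array([[0, 0.0, 0.5], [0.0, 0, 0.8], [0.5, 0.8, 0]]), ["a", "b", "c"], "fst"
        )
        lin = mn.linearize_fst(m)
        assert lin.values[0, 1] == pytest.approx(0.0)
        assert lin.values[0, 2] == pytest.approx(1.0)
        assert lin.values[1, 2] == pytest.approx(0.8 / 0.2)

    def test_negative_clamped(self):
        m = mn.DistanceMatrix(np.array([[0, -0.01], [-0.01, 0]]), ["a", "b"], "fst")
        with pytest.warns(UserWarning, match="clamped"):
            lin = mn.linearize_fst(m)
        assert lin.values[0, 1] == 0.0

    def test_unity_errors_by_default(self):
        m = mn.DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ["a", "b"], "fst")
        with pytest.raises(ValueError):
            mn.linearize_fst(m)


class TestGeography:
    def make_sites(self, rows):
        import pandas as pd

        return mn.SiteTable(pd.DataFrame(rows, columns=["site", "lat", "lon"]))

    def test_identical_coordinates(self):
        s = self.make_sites([("a", 30.0, 35.0), ("b", 30.0, 35.0)])
        assert mn.geographic_distances(s).values[0, 1] == pytest.approx(0.0)

    def test_one_degree_latitude(self):
        s = self.make_sites([("a", 30.0, 35.0), ("b", 31.0, 35.0)])
        expected = EARTH_RADIUS_KM * math.pi / 180
        assert mn.geographic_distances(s).values[0, 1] == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx(111.19, abs=0.01)


class TestMantel:
    def rand_dm(self, seed, n=8, ids=None):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 2))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        return mn.DistanceMatrix(d, ids or [f"s{i}" for i in range(n)], "geographic_km")

    def test_affine_copy_gives_r_one(self):
        d1 = self.rand_dm(0)
        d2 = mn.DistanceMatrix(2 * d1.values, d1.ids, "cgd")
        res = mn.mantel_test(d1, d2, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_same_seed_same_p(self):
        d1, d2 = self.rand_dm(1), self.rand_dm(2)
        r1 = mn.mantel_test(d1, d2, n_perm=199, seed=5)
        r2 = mn.mantel_test(d1, d2, n_perm=199, seed=5)
        assert r1.p_value == r2.p_value

    def test_constant_matrix_raises(self):
        d1 = self.rand_dm(3)
        ones = np.ones((8, 8)) - np.eye(8)
        d2 = mn.DistanceMatrix(ones, d1.ids, "cgd")
        with pytest.raises(ValueError, match="constant"):
            mn.mantel_test(d1, d2, n_perm=99, seed=0)

    def test_mismatched_ids_raise(self):
        d1 = self.rand_dm(4)
        d2 = self.rand_dm(5, ids=[f"t{i}" for i in range(8)])
        with pytest.raises(ValueError):
            mn.mantel_test(d1, d2)

    def test_statistic_matches_scikit_bio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d1, d2 = self.rand_dm(6), self.rand_dm(7)
        res = mn.mantel_test(d1, d2, n_perm=999, seed=0)
        r, p, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values, d1.ids),
            skbio_distance.DistanceMatrix(d2.values, d2.ids),
            method="pearson", permutations=999, alternative="greater",
        )
        assert res.statistic == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=0.05)
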