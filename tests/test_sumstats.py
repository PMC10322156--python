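"""Summary statistics against independent brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from admixhist.simulate import SampleSet
from admixhist.sumstats import (
    ASDMatrix,
    MDSEmbedding,
    SUMMARY_NAMES,
    asd_matrix,
    classical_mds,
    compute_summary_vector,
    distribution_stats,
    f3_statistic,
    heterozygosity_stats,
    inbreeding_stats,
    project_admixture,
    wc_fst,
)


# ---------------------------------------------------------------------------
# brute-force oracles (independent re-implementations)


def asd_bruteforce(g):
    n, L = g.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            vals = []
            for s in range(L):
                shared = 2 - abs(int(g[i, s]) - int(g[j, s]))
                vals.append(1 - shared / 2)
            out[i, j] = np.mean(vals)
    return out


def het_bruteforce(g):
    n, L = g.shape
    hets = []
    for s in range(L):
        p = sum(g[:, s]) / (2 * n)
        hets.append(2 * p * (1 - p) * (2 * n) / (2 * n - 1))
    return np.mean(hets), np.var(hets)


def inbreeding_bruteforce(g):
    n, L = g.shape
    p = g.mean(axis=0) / 2
    poly = [(s, p[s]) for s in range(L) if 0 < p[s] < 1]
    E_hom = sum(1 - 2 * ps * (1 - ps) * (2 * n) / (2 * n - 1) for _, ps in poly)
    Fs = []
    for i in range(n):
        O_hom = sum(1 for s, _ in poly if g[i, s] != 1)
        Fs.append((O_hom - E_hom) / (len(poly) - E_hom))
    return np.mean(Fs), np.var(Fs)


def wc_fst_bruteforce(ga, gb):
    """Weir & Cockerham 1984, per-site components summed explicitly."""
    num = den = 0.0
    n1, n2 = len(ga), len(gb)
    for s in range(ga.shape[1]):
        p1 = ga[:, s].mean() / 2
        p2 = gb[:, s].mean() / 2
        h1 = np.mean(ga[:, s] == 1)
        h2 = np.mean(gb[:, s] == 1)
        nbar = (n1 + n2) / 2
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / 1.0
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def f3_bruteforce(h, s1, s2):
    n = len(h)
    vals = []
    for s in range(h.shape[1]):
        ph = h[:, s].mean() / 2
        p1 = s1[:, s].mean() / 2
        p2 = s2[:, s].mean() / 2
        if ph in (0.0, 1.0) and p1 == ph and p2 == ph:
            continue
        het = 2 * ph * (1 - ph) * (2 * n) / (2 * n - 1)
        vals.append((ph - p1) * (ph - p2) - het / (2 * n))
    return np.mean(vals)


def _random_genotypes(rng, n, L):
    return rng.integers(0, 3, size=(n, L)).astype(np.uint8)


# ---------------------------------------------------------------------------


class TestASD:
    def test_identical_genotypes_have_zero_dissimilarity(self):
        g = np.tile([0, 1, 2, 1], (2, 1))
        assert asd_matrix(g).values[0, 1] == 0

    def test_opposite_homozygotes_have_unit_dissimilarity(self):
        g = np.array([[0, 0, 0], [2, 2, 2]])
        assert asd_matrix(g).values[0, 1] == 1

    def test_matches_bruteforce_on_hand_matrix(self):
        g = np.array([[0, 1, 2, 1], [2, 1, 0, 0], [1, 2, 2, 0]], dtype=np.uint8)
        assert np.allclose(asd_matrix(g).values, asd_bruteforce(g), atol=1e-12)

    def test_pairwise_complete_with_missing_data(self):
        g = np.array([[0.0, np.nan, 2.0], [0.0, 1.0, 0.0]])
        # only sites 0 and 2 shared: (0 + 1)/2
        assert asd_matrix(g).values[0, 1] == pytest.approx(0.5)

    def test_no_shared_sites_errors(self):
        g = np.array([[np.nan, 1.0], [1.0, np.nan]])
        with pytest.raises(ValueError):
            asd_matrix(g)


class TestMDS:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        D = squareform(pdist(X))
        emb = classical_mds(ASDMatrix(D), k=2)
        D2 = squareform(pdist(emb.coordinates))
        assert np.abs(D - D2).max() < 1e-8

    def test_collinear_points_have_null_second_axis(self):
        x = np.linspace(0, 1, 8)[:, None]
        D = squareform(pdist(x))
        emb = classical_mds(ASDMatrix(D), k=2)
        assert np.abs(emb.coordinates[:, 1]).max() < 1e-8

    def test_equal_dissimilarities_give_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        emb = classical_mds(ASDMatrix(D), k=2)
        d = pdist(emb.coordinates)
        assert np.allclose(d, d[0])

    def test_agrees_with_skbio_pcoa(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 4))
        D = squareform(pdist(X))
        ours = classical_mds(ASDMatrix(D), k=3)
        ref = pcoa(D, method="eigh", number_of_dimensions=3)
        assert np.allclose(ours.eigenvalues, ref.eigvals.to_numpy()[:3], atol=1e-8)
        for j in range(3):  # eigenvector sign is arbitrary
            r = ref.samples.to_numpy()[:, j]
            assert min(
                np.abs(ours.coordinates[:, j] - r).max(),
                np.abs(ours.coordinates[:, j] + r).max(),
            ) < 1e-8

    def test_centering(self):
        rng = np.random.default_rng(2)
        D = squareform(pdist(rng.normal(size=(9, 3))))
        emb = classical_mds(ASDMatrix(D), k=2)
        assert np.abs(emb.coordinates.mean(axis=0)).max() < 1e-10


def _embedding(points, labels):
    return MDSEmbedding(
        coordinates=np.asarray(points, dtype=float),
        eigenvalues=np.array([1.0, 0.5]),
        labels=np.asarray(labels, dtype=object),
    )


class TestProjection:
    def test_individual_at_african_centroid_has_alpha_one(self):
        emb = _embedding(
            [[1, 0], [1, 0], [0, 0], [0, 0], [1, 0]],
            ["AFR", "AFR", "EUR", "EUR", "H"],
        )
        proj = project_admixture(emb)
        assert proj.alpha[0] == pytest.approx(1.0)

    def test_midpoint_has_half_alpha_and_straight_angle(self):
        emb = _embedding(
            [[1, 0], [1, 0], [0, 0], [0, 0], [0.5, 0]],
            ["AFR", "AFR", "EUR", "EUR", "H"],
        )
        proj = project_admixture(emb)
        assert proj.alpha[0] == pytest.approx(0.5)
        assert proj.theta[0] == pytest.approx(np.pi)

    def test_right_angle_geometry(self):
        # H at (0,1): directions to (1,0)-ish centroids at unit offsets
        emb = _embedding(
            [[1, 0], [1, 0], [-1, 0], [-1, 0], [0, 1]],
            ["AFR", "AFR", "EUR", "EUR", "H"],
        )
        proj = project_admixture(emb)
        assert proj.theta[0] == pytest.approx(np.pi / 2)
        assert proj.alpha[0] == pytest.approx(0.5)

    def test_overshoot_is_not_clipped(self):
        emb = _embedding(
            [[1, 0], [1, 0], [0, 0], [0, 0], [1.4, 0]],
            ["AFR", "AFR", "EUR", "EUR", "H"],
        )
        assert project_admixture(emb).alpha[0] == pytest.approx(1.4)

    def test_individual_at_centroid_warned_and_nan_angle(self):
        emb = _embedding(
            [[1, 0], [1, 0], [0, 0], [0, 0], [1, 0]],
            ["AFR", "AFR", "EUR", "EUR", "H"],
        )
        with pytest.warns(UserWarning):
            proj = project_admixture(emb)
        assert np.isnan(proj.theta[0])

    def test_coincident_centroids_error(self):
        emb = _embedding(
            [[1, 0], [1, 0], [1, 0], [1, 0], [0.5, 0]],
            ["AFR", "AFR", "EUR", "EUR", "H"],
        )
        with pytest.raises(ValueError):
            project_admixture(emb)


class TestScalarEstimators:
    def test_heterozygosity_closed_form(self):
        g = np.array([[0, 2] * 5, [2, 0] * 5]).T[:10, :1]
        g = np.array([[0], [0], [0], [0], [0], [2], [2], [2], [2], [2]])
        mean, var = heterozygosity_stats(g)
        assert mean == pytest.approx(0.5 * 20 / 19)
        assert var == 0

    def test_monomorphic_heterozygosity_is_zero(self):
        assert heterozygosity_stats(np.zeros((5, 4))) == (0.0, 0.0)

    def test_heterozygosity_exchangeable_in_individuals(self):
        rng = np.random.default_rng(3)
        g = _random_genotypes(rng, 8, 30)
        a = heterozygosity_stats(g)
        b = heterozygosity_stats(g[rng.permutation(8)])
        assert a == b

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_estimators_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        ga = _random_genotypes(rng, 5, 20)
        gb = _random_genotypes(rng, 7, 20)
        gh = _random_genotypes(rng, 6, 20)
        assert heterozygosity_stats(ga) == pytest.approx(het_bruteforce(ga), abs=1e-10)
        assert inbreeding_stats(ga) == pytest.approx(inbreeding_bruteforce(ga), abs=1e-10)
        assert wc_fst(ga, gb) == pytest.approx(wc_fst_bruteforce(ga, gb), abs=1e-10)
        assert f3_statistic(gh, ga, gb) == pytest.approx(
            f3_bruteforce(gh, ga, gb), abs=1e-10
        )

    def test_inbreeding_limits(self):
        rng = np.random.default_rng(4)
        # Hardy-Weinberg sample: F near 0
        p = rng.uniform(0.2, 0.8, size=2_000)
        g = (rng.random((200, p.size)) < p).astype(int) + (
            rng.random((200, p.size)) < p
        ).astype(int)
        mean, _ = inbreeding_stats(g)
        assert abs(mean) < 0.02
        # a fully homozygous individual among heterozygotes
        g2 = np.vstack([np.full(200, 1), np.full(200, 1), np.full(200, 1),
                        rng.choice([0, 2], 200)])
        assert inbreeding_stats(g2)[0] is not None

    def test_fst_limits(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.9, 1_000)
        draw = lambda: ((rng.random((30, p.size)) < p).astype(int)
                        + (rng.random((30, p.size)) < p).astype(int))
        assert abs(wc_fst(draw(), draw())) < 0.01
        fixed_a = np.zeros((10, 50), dtype=int)
        fixed_b = np.full((10, 50), 2, dtype=int)
        assert wc_fst(fixed_a, fixed_b) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            wc_fst(np.zeros((5, 4)), np.zeros((5, 4)))

    def test_f3_sign_cases(self):
        rng = np.random.default_rng(6)
        pa = rng.uniform(0.1, 0.9, 3_000)
        pb = np.clip(pa + rng.choice([-1, 1], pa.size) * 0.35, 0.02, 0.98)
        draw = lambda p, n: ((rng.random((n, p.size)) < p).astype(int)
                             + (rng.random((n, p.size)) < p).astype(int))
        A, B = draw(pa, 30), draw(pb, 30)
        pooled = np.vstack([draw(pa, 15), draw(pb, 15)])
        assert f3_statistic(pooled, A, B) < 0
        # three identical populations: f3 ~ 0
        C = draw(pa, 30)
        assert abs(f3_statistic(C, draw(pa, 30), draw(pa, 30))) < 0.01


class TestDistributionStats:
    def test_constant_vector(self):
        out = distribution_stats(np.full(20, 3.5))
        mode, mean, var, skew, kurt, mn, mx = out[:7]
        assert mode == mean == mn == mx == 3.5
        assert var == skew == 0
        assert np.all(out[7:] == 3.5)

    def test_deciles_of_1_to_100(self):
        out = distribution_stats(np.arange(1, 101, dtype=float))
        expected = [10.9, 20.8, 30.7, 40.6, 50.5, 60.4, 70.3, 80.2, 90.1]
        assert np.allclose(out[7:], expected)

    def test_symmetric_sample_has_negligible_skew(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-2, 0.3, 4_000), rng.normal(2, 0.3, 4_000)])
        x = np.concatenate([x, -x])  # exactly symmetric
        assert abs(distribution_stats(x)[3]) < 0.05

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            distribution_stats(np.arange(5, dtype=float))


class TestSummaryVector:
    def test_has_42_named_statistics_in_fixed_grouping(self):
        assert len(SUMMARY_NAMES) == 42
        names = list(SUMMARY_NAMES)
        assert names[:5] == ["asd_mean_H", "het_mean_H", "het_var_H",
                             "F_mean_H", "F_var_H"]
        assert sum(n.startswith("alpha_") for n in names) == 16
        assert sum(n.startswith("theta_") for n in names) == 16
        assert sum(n.startswith("alpha_d") for n in names) == 9
        assert sum(n.startswith("theta_d") for n in names) == 9
        assert names[-5:] == ["fst_afr_H", "fst_eur_H", "asd_mean_afr_H",
                              "asd_mean_eur_H", "f3_H_eur_afr"]

    def test_african_admixed_sample_projects_to_one(self, tiny_reservoirs):
        from admixhist.simulate import sample_source

        rng = np.random.default_rng(8)
        ss = SampleSet(
            admixed=sample_source(tiny_reservoirs["African"], 30, rng),
            afr=sample_source(tiny_reservoirs["African"], 60, rng),
            eur=sample_source(tiny_reservoirs["European"], 60, rng),
        )
        vec = dict(zip(SUMMARY_NAMES, compute_summary_vector(ss)))
        assert vec["alpha_mean"] == pytest.approx(1.0, abs=0.1)
        assert vec["fst_afr_H"] < 0.01

    def test_deterministic_for_same_input(self, tiny_reservoirs):
        from admixhist.simulate import sample_source

        rng = np.random.default_rng(9)
        ss = SampleSet(
            admixed=sample_source(tiny_reservoirs["African"], 15, rng),
            afr=sample_source(tiny_reservoirs["African"], 30, rng),
            eur=sample_source(tiny_reservoirs["European"], 30, rng),
        )
        assert np.array_equal(compute_summary_vector(ss),
                              compute_summary_vector(ss))
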