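import numpy as np
import pandas as pd
import pytest

from rhinoload.load import (
    GenotypeMatrix,
    fitness_matrix,
    fixed_deleterious_test,
    genome_fitness,
    heterozygosity,
    load_summary,
    private_alleles,
    project_sfs2d,
    projection_weights,
    realized_load,
    realized_load_matrix,
)

from conftest import annotated_toy_table, make_gm, toy_table


class TestFitnessAndLoad:
    def test_empty_genome_is_neutral(self):
        table = toy_table([(-0.002, 0.033)])
        assert genome_fitness(np.array([0]), table) == 1.0
        assert realized_load(np.array([0]), table) == 0.0

    def test_single_homozygous_severe_site(self):
        table = toy_table([(-0.002, 0.033)])
        assert genome_fitness(np.array([2]), table) == pytest.approx(0.998, abs=1e-12)

    def test_het_moderate_plus_hom_mild(self):
        table = toy_table([(-0.001, 0.062), (-0.0001, 0.293)])
        w = genome_fitness(np.array([1, 2]), table)
        assert w == pytest.approx((1 + 0.062 * -0.001) * (1 - 0.0001), rel=1e-12)
        assert round(w, 8) == 0.99983801
        lr = realized_load(np.array([1, 2]), table)
        assert lr == pytest.approx(0.062 * 0.001 + 0.0001, rel=1e-12)
        assert lr == pytest.approx(0.000162, rel=1e-9)

    def test_realized_load_scale_anchor(self):
        # 375 homozygous severe sites carry the whole-genome-scale burden 0.75
        table = toy_table([(-0.002, 0.033)] * 375)
        assert realized_load(np.full(375, 2), table) == pytest.approx(0.75, rel=1e-12)

    def test_matrix_forms_match_scalar(self):
        rng = np.random.default_rng(3)
        table = annotated_toy_table(
            rng.uniform(-2, 8, size=50), rng.choice(["LOW", "MODERATE", "LOF"], 50)
        )
        d = rng.integers(0, 3, size=(6, 50))
        w = fitness_matrix(d, table)
        lr = realized_load_matrix(d, table)
        for i in range(6):
            assert w[i] == pytest.approx(genome_fitness(d[i], table), rel=1e-12)
            assert lr[i] == pytest.approx(realized_load(d[i], table), rel=1e-12)

    def test_exp_load_approximates_fitness_for_weak_selection(self):
        rng = np.random.default_rng(4)
        table = annotated_toy_table(
            rng.uniform(-2, 8, size=200), ["NONE"] * 200
        )  # default coefficients: |s| <= 0.002
        for _ in range(20):
            d = rng.integers(0, 3, size=200)
            w = genome_fitness(d, table)
            lr = realized_load(d, table)
            assert np.exp(-lr) == pytest.approx(w, rel=1e-4)

    def test_missing_dosage_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            genome_fitness(np.array([-1]), toy_table([(-0.002, 0.033)]))


class TestLoadSummary:
    def test_hom_het_counting(self):
        table = annotated_toy_table([5.0, 5.0, 5.0], ["MODERATE"] * 3)
        gm = make_gm([[2, 1, 0]])
        out = load_summary(gm, table)["individual"]
        assert out["hom_conserved_deleterious"].iloc[0] == 1
        assert out["het_conserved_deleterious"].iloc[0] == 1

    def test_fixed_derived_and_fixed_deleterious(self):
        table = annotated_toy_table([5.0, 1.0], ["MODERATE", "LOW"])
        gm = make_gm([[2, 2], [2, 2]])
        pop = load_summary(gm, table)["population"]
        assert pop["fixed_derived"].iloc[0] == 2
        assert pop["fixed_deleterious"].iloc[0] == 1  # only the RS > 4 site
        assert pop["prop_fixed_deleterious"].iloc[0] == 0.5

    def test_missing_site_excluded_everywhere(self):
        table = annotated_toy_table([5.0, 5.0], ["MODERATE", "MODERATE"])
        gm = make_gm([[2, -1], [2, 2]])
        out = load_summary(gm, table)
        assert out["individual"]["hom_conserved_deleterious"].tolist() == [1, 1]
        assert out["population"]["fixed_derived"].iloc[0] == 1

    def test_segregating_and_fixed_partition_derived_sites(self):
        rng = np.random.default_rng(5)
        table = annotated_toy_table(rng.uniform(3, 7, 40), ["MODERATE"] * 40)
        gm = make_gm(rng.integers(0, 3, size=(5, 40)))
        pop = load_summary(gm, table)["population"].iloc[0]
        d = gm.dosages
        carries = (d > 0).any(axis=0)
        fixed = (d == 2).all(axis=0)
        assert pop["sites_with_derived"] == carries.sum()
        assert pop["fixed_derived"] == fixed.sum()
        # segregating + fixed is a disjoint, exhaustive split of derived-carrying sites
        assert (carries & ~fixed).sum() + fixed.sum() == carries.sum()

    def test_empty_population_rejected(self):
        table = annotated_toy_table([5.0], ["MODERATE"])
        with pytest.raises(ValueError):
            load_summary(make_gm(np.empty((0, 1), dtype=np.int8)), table)


class TestFixedDeleteriousTest:
    def test_identical_proportions_give_zero(self):
        chi2, p = fixed_deleterious_test((10, 90), (10, 90))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_chi_square(self):
        # Sum over cells of (O-E)^2/E with margins (30,170)x(100,100)
        chi2, _ = fixed_deleterious_test((20, 80), (10, 90))
        expected = 0.0
        obs = np.array([[20, 80], [10, 90]], dtype=float)
        e = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        expected = ((obs - e) ** 2 / e).sum()
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert round(chi2, 4) == 3.9216

    def test_statistic_scales_with_counts(self):
        chi2, _ = fixed_deleterious_test((20, 80), (10, 90))
        chi2x2, _ = fixed_deleterious_test((40, 160), (20, 180))
        assert chi2x2 == pytest.approx(2 * chi2, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fixed_deleterious_test((0, 10), (0, 90))


class TestHeterozygosity:
    def test_direct_division(self):
        d = np.array([[1, 1, 1, 1, 1, 0, 0, 0, 0, 0]])
        assert heterozygosity(d, None, 1000)[0] == pytest.approx(0.005)

    def test_call_rate_adjustment_doubles_estimate(self):
        # half the retained sites uncalled for this sample -> call rate 0.5
        d = np.array(
            [[1, 1, 1, 1, 1, -1, -1, -1, -1, -1],
             [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
             [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
             [0, 0, 0, 0, 0, 0, 0, 0, 0, 0]]
        )
        assert heterozygosity(d, None, 1000)[0] == pytest.approx(0.01)

    def test_no_hets_is_zero(self):
        d = np.zeros((2, 10), dtype=np.int8)
        assert heterozygosity(d, None, 1000).tolist() == [0.0, 0.0]

    def test_low_gq_genotypes_become_missing(self):
        d = np.array([[1, 1], [0, 0]])
        gq = np.array([[10, 99], [99, 99]])
        # sample 0's genotype at site 0 is masked, halving its call rate
        h = heterozygosity(d, gq, 1000, max_missing=0.5)
        assert h[0] == pytest.approx(1 / (1000 * 0.5))

    def test_cohort_missingness_filter_drops_sites(self):
        d = np.array([[1, 1], [-1, 0], [-1, 0]])
        h = heterozygosity(d, None, 1000)  # site 0 is 2/3 missing -> dropped
        assert h[0] == pytest.approx(1 / 1000)


class TestPrivateAlleles:
    def test_definitions(self):
        gmA = make_gm([[1, 2, 0], [1, 2, 0]])
        gmB = make_gm([[0, 2, 1], [0, 2, 0]])
        out = private_alleles(gmA, gmB)
        # site 0 private to A; site 1 fixed in both (private to neither); site 2 private to B
        assert out["private"].tolist() == [1, 1]

    def test_counts_match_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(6)
        dA = rng.integers(0, 3, size=(4, 50))
        dB = rng.integers(0, 3, size=(6, 50))
        out = private_alleles(make_gm(dA), make_gm(dB))
        privA = privB = 0
        for j in range(50):
            inA, inB = (dA[:, j] > 0).any(), (dB[:, j] > 0).any()
            privA += inA and not inB
            privB += inB and not inA
        assert out["private"].tolist() == [privA, privB]


class TestSfsProjection:
    def test_combinatorial_weights(self):
        w = projection_weights(2, 4, 2)
        assert np.allclose(w, [1 / 6, 4 / 6, 1 / 6])

    def test_monomorphic_site_keeps_all_mass_at_zero(self):
        w = projection_weights(0, 8, 4)
        assert w[0] == pytest.approx(1.0)
        assert np.allclose(w[1:], 0.0)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            m = int(rng.integers(1, n + 1))
            d = int(rng.integers(0, n + 1))
            assert projection_weights(d, n, m).sum() == pytest.approx(1.0, abs=1e-12)

    def test_total_mass_counts_projectable_sites(self):
        rng = np.random.default_rng(8)
        gmA = make_gm(rng.integers(0, 3, size=(4, 30)))
        gmB = make_gm(rng.integers(0, 3, size=(5, 30)))
        sfs = project_sfs2d(gmA, gmB, 4, 6)
        assert sfs.sum() == pytest.approx(30.0, abs=1e-9)

    def test_full_size_projection_is_identity(self):
        rng = np.random.default_rng(9)
        gmA = make_gm(rng.integers(0, 3, size=(3, 40)))
        gmB = make_gm(rng.integers(0, 3, size=(4, 40)))
        sfs = project_sfs2d(gmA, gmB, 6, 8)
        direct = np.zeros_like(sfs)
        for j in range(40):
            direct[gmA.dosages[:, j].sum(), gmB.dosages[:, j].sum()] += 1
        assert np.allclose(sfs, direct, atol=1e-9)

    def test_sites_below_projection_size_are_dropped(self):
        dA = np.array([[1], [-1]])  # only 2 called alleles
        gmA = make_gm(dA)
        gmB = make_gm(np.array([[1], [1]]))
        assert project_sfs2d(gmA, gmB, 4, 4).sum() == 0.0


def test_metrics_invariant_to_orderings():
    rng = np.random.default_rng(10)
    table = annotated_toy_table(rng.uniform(-2, 8, 30), ["MODERATE"] * 30)
    d = rng.integers(0, 3, size=(5, 30))
    gm = make_gm(d)
    base = load_summary(gm, table)["individual"]

    perm = rng.permutation(30)
    gm_p = make_gm(d[:, perm])
    table_p = table.iloc[perm].reset_index(drop=True)
    permuted = load_summary(gm_p, table_p)["individual"]
    pd.testing.assert_frame_equal(base, permuted)

    iperm = rng.permutation(5)
    gm_i = GenotypeMatrix(
        samples=[gm.samples[i] for i in iperm],
        populations=["pop"] * 5,
        dosages=d[iperm],
    )
    byind = load_summary(gm_i, table)["individual"].set_index("sample").sort_index()
    pd.testing.assert_frame_equal(base.set_index("sample").sort_index(), byind)
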