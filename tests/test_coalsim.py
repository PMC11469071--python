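"""Calibration of the structured-coalescent simulator against theory and
against an independent coalescent implementation (msprime)."""

import numpy as np
import pytest

from primrose.coalsim import (DemographicModel, Population, SampleConfig,
                              SizeChange, Split, drop_mutations,
                              expected_joint_sfs, expected_joint_sfs_weights,
                              expected_sfs_single_pop, haplotypes_to_diploids,
                              load_model, model_from_dict, save_model,
                              simulate_genealogy, years_to_generations)


def one_deme(N=1000.0):
    return DemographicModel([Population("A", N)])


class TestTimeConversion:
    @pytest.mark.parametrize("years,expected", [(79_000, 39_500), (0, 0),
                                                (100, 50)])
    def test_two_year_generation(self, years, expected):
        assert years_to_generations(years, one_deme()) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            years_to_generations(-1, one_deme())


class TestGenealogy:
    def test_pairwise_tmrca_is_2n(self):
        """E[T2] = 2N generations for two lineages in a constant deme."""
        model, config = one_deme(1000.0), SampleConfig({"A": 2})
        rng = np.random.default_rng(1)
        t = np.array([simulate_genealogy(model, config, rng)
                      .total_branch_length / 2 for _ in range(5000)])
        se = t.std() / np.sqrt(len(t))
        assert abs(t.mean() - 2000.0) < 3 * se

    def test_total_branch_length_harmonic(self):
        """E[L] = 4N * (1 + 1/2 + ... + 1/(n-1)) for n = 5."""
        model, config = one_deme(500.0), SampleConfig({"A": 5})
        rng = np.random.default_rng(2)
        L = np.array([simulate_genealogy(model, config, rng)
                      .total_branch_length for _ in range(5000)])
        expected = 4 * 500.0 * (1 + 1 / 2 + 1 / 3 + 1 / 4)
        se = L.std() / np.sqrt(len(L))
        assert abs(L.mean() - expected) < 3 * se

    def test_no_coalescence_before_split(self):
        """Lineages sampled in different demes cannot coalesce until the
        backward-in-time merge."""
        model = DemographicModel(
            [Population("A", 500.0), Population("B", 500.0)],
            [Split(2000.0, "B", "A")])
        config = SampleConfig({"A": 1, "B": 1})
        rng = np.random.default_rng(3)
        tm = np.array([simulate_genealogy(model, config, rng)
                       .total_branch_length / 2 for _ in range(400)])
        assert (tm >= 2000.0).all()
        # beyond the split the pair coalesces at rate 1/(2*500)
        assert abs((tm - 2000).mean() - 1000) < 3 * (tm.std() / 20)

    def test_stranded_deme_rejected(self):
        model = DemographicModel([Population("A", 100.0),
                                  Population("B", 100.0)])
        with pytest.raises(ValueError, match="route to a single root"):
            simulate_genealogy(model, SampleConfig({"A": 1, "B": 1}), 0)

    def test_reproducible_under_seed(self):
        model, config = one_deme(), SampleConfig({"A": 4})
        g1 = simulate_genealogy(model, config, 7)
        g2 = simulate_genealogy(model, config, 7)
        assert g1.branches == g2.branches


class TestMutations:
    def test_zero_rate_zero_sites(self):
        g = simulate_genealogy(one_deme(), SampleConfig({"A": 4}), 0)
        pos, hap = drop_mutations(g, 0.0, 1000, 0)
        assert len(pos) == 0 and hap.shape == (0, 4)

    def test_neutral_sfs_proportional_to_inverse_i(self):
        """Mean xi_i over replicates tracks theta/i for n = 4."""
        model, config = one_deme(500.0), SampleConfig({"A": 4}, L=20_000)
        rng = np.random.default_rng(5)
        mu = 1e-6
        counts = np.zeros((3000, 3))
        for r in range(3000):
            g = simulate_genealogy(model, config, rng)
            pos, hap = drop_mutations(g, mu, config.L, rng)
            if len(pos):
                freq = hap.sum(axis=1)
                counts[r] = np.bincount(freq, minlength=4)[1:4]
        mean = counts.mean(axis=0)
        se = counts.std(axis=0) / np.sqrt(len(counts))
        theta = 4 * 500.0 * mu * config.L
        for i in range(3):
            assert abs(mean[i] - theta / (i + 1)) < 3 * se[i]

    def test_singleton_from_leaf_branch(self):
        g = simulate_genealogy(one_deme(), SampleConfig({"A": 3}), 11)
        pos, hap = drop_mutations(g, 1e-4, 10_000, 2)
        assert ((hap.sum(axis=1) >= 1) & (hap.sum(axis=1) <= 2)).all()


class TestExpectedJointSfs:
    def test_single_deme_marginal_matches_neutral(self):
        sfs = expected_joint_sfs(one_deme(), SampleConfig({"A": 4}),
                                 30_000, seed=3)
        expected = np.array([1, 0.5, 1 / 3]) / (11 / 6)
        assert np.allclose(sfs.cells[1:4], expected, atol=0.01)

    def test_ancient_split_means_private_polymorphism(self):
        model = DemographicModel(
            [Population("A", 200.0), Population("B", 200.0)],
            [Split(1e6, "B", "A", ancestral_size=200.0)])
        sfs = expected_joint_sfs(model, SampleConfig({"A": 4, "B": 4}),
                                 5000, seed=4)
        shared = sfs.cells[1:4, 1:4].sum()
        assert shared < 0.01

    def test_same_seed_identical(self):
        model = one_deme()
        a = expected_joint_sfs_weights(model, SampleConfig({"A": 6}), 500, 9)
        b = expected_joint_sfs_weights(model, SampleConfig({"A": 6}), 500, 9)
        assert np.array_equal(a, b)

    def test_monte_carlo_matches_analytic_two_epoch(self):
        """The numba MC kernel and the death-chain closed form agree on a
        bottleneck history."""
        model = DemographicModel([Population("A", 400.0)],
                                 [SizeChange(300.0, "A", 4000.0)])
        n = 8
        mc = expected_joint_sfs_weights(model, SampleConfig({"A": n}),
                                        60_000, seed=5)[1:n]
        exact = expected_sfs_single_pop([(300.0, 400.0), (np.inf, 4000.0)], n)
        assert np.allclose(mc / mc.sum(), exact / exact.sum(), atol=0.01)

    def test_python_engine_matches_numba_kernel(self):
        """Both engines implement the same process: mean SFS agreement."""
        model = DemographicModel(
            [Population("A", 300.0), Population("B", 150.0)],
            [Split(400.0, "B", "A")])
        config = SampleConfig({"A": 3, "B": 3})
        rng = np.random.default_rng(6)
        W_py = np.zeros((4, 4))
        reps = 20_000
        for _ in range(reps):
            g = simulate_genealogy(model, config, rng)
            comps = g.branch_compositions()
            for (mask, length), comp in zip(g.branches, comps):
                W_py[comp[0], comp[1]] += length
        W_py /= reps
        W_nb = expected_joint_sfs_weights(model, config, 60_000, seed=8)
        poly = np.ones((4, 4), bool)
        poly[0, 0] = poly[3, 3] = False
        a, b = W_py[poly], W_nb[poly]
        assert np.allclose(a / a.sum(), b / b.sum(), atol=0.012)


class TestAnalyticSinglePop:
    def test_constant_size_is_theta_over_i(self):
        n, N = 12, 1234.0
        w = expected_sfs_single_pop([(np.inf, N)], n)
        assert np.allclose(w, 4 * N / np.arange(1, n), rtol=1e-9)

    def test_recent_growth_skews_to_singletons(self):
        grown = expected_sfs_single_pop([(100.0, 10_000.0), (np.inf, 100.0)],
                                        10)
        const = expected_sfs_single_pop([(np.inf, 10_000.0)], 10)
        assert (grown[0] / grown.sum()) > (const[0] / const.sum())


@pytest.mark.parametrize("t_split", [500.0, 4000.0])
def test_agreement_with_msprime_oracle(t_split):
    """Mean joint SFS of a two-deme split model matches the independent
    msprime simulator within Monte-Carlo error."""
    msprime = pytest.importorskip("msprime")
    NA, NB, NANC = 800.0, 300.0, 600.0
    model = DemographicModel(
        [Population("A", NA), Population("B", NB)],
        [Split(t_split, "B", "A", ancestral_size=NANC)])
    config = SampleConfig({"A": 4, "B": 4})
    ours = expected_joint_sfs_weights(model, config, 120_000, seed=10)

    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=NA)
    dem.add_population(name="B", initial_size=NB)
    dem.add_population(name="ANC", initial_size=NANC)
    dem.add_population_split(time=t_split, derived=["A", "B"],
                             ancestral="ANC")
    W_ms = np.zeros((5, 5))
    reps = 40_000
    ts_reps = msprime.sim_ancestry(
        samples={"A": 2, "B": 2}, demography=dem, ploidy=2,
        num_replicates=reps, random_seed=1234)
    for ts in ts_reps:
        pops = np.array([ts.node(s).population for s in ts.samples()])
        tree = ts.first()
        for node in tree.nodes():
            if tree.parent(node) == -1:
                continue
            leaves = list(tree.samples(node))
            ca = int(np.sum(pops[leaves] == 0))
            cb = len(leaves) - ca
            W_ms[ca, cb] += tree.branch_length(node)
    W_ms /= reps
    poly = np.ones((5, 5), bool)
    poly[0, 0] = poly[4, 4] = False
    a, b = ours[poly], W_ms[poly]
    assert np.allclose(a / a.sum(), b / b.sum(), atol=0.012)


class TestDiploidsAndInbreeding:
    def test_full_selfing_removes_heterozygosity(self):
        model, config = one_deme(500.0), SampleConfig(
            {"A": 8}, L=50_000, inbreeding={"A": 1.0})
        rng = np.random.default_rng(12)
        g = simulate_genealogy(model, config, rng)
        pos, hap = drop_mutations(g, 1e-5, config.L, rng)
        dosage = haplotypes_to_diploids(hap, g.leaf_pops, g.pop_names,
                                        {"A": 1.0}, rng)
        assert (dosage != 1).all()

    def test_no_inbreeding_keeps_heterozygotes(self):
        model, config = one_deme(500.0), SampleConfig({"A": 8}, L=50_000)
        rng = np.random.default_rng(12)
        g = simulate_genealogy(model, config, rng)
        pos, hap = drop_mutations(g, 1e-5, config.L, rng)
        dosage = haplotypes_to_diploids(hap, g.leaf_pops, g.pop_names, None,
                                        rng)
        assert (dosage == 1).any()


class TestModelConfig:
    def test_roundtrip(self, tmp_path):
        model = DemographicModel(
            [Population("X", 1000.0), Population("Y", 2000.0)],
            [SizeChange(50.0, "Y", 300.0), Split(500.0, "Y", "X",
                                                 ancestral_size=800.0)])
        path = tmp_path / "model.yaml"
        save_model(model, str(path))
        back = load_model(str(path))
        assert [p.size for p in back.populations] == [1000.0, 2000.0]
        assert back.events[1].ancestral_size == 800.0

    def test_haploid_units_and_years_converted(self):
        doc = {"ne_units": "haploid", "time_units": "years",
               "generation_time_years": 2.0,
               "populations": [{"name": "A", "size": 2000}],
               "events": []}
        model = model_from_dict(doc)
        assert model.populations[0].size == 1000.0

    def test_missing_units_tag_rejected(self):
        with pytest.raises(ValueError, match="ne_units"):
            model_from_dict({"time_units": "years",
                             "populations": [{"name": "A", "size": 1}]})
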