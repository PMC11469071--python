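"""Diversity estimators, windows, LD, PCA, rank tests."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from primrose import popgen_stats as pg
from primrose.io_preprocess import AccessibilityMask
from primrose.sfs_tools import SFS1D
from primrose.synthdata import generate_block_ld
from conftest import make_matrix


class TestWatterson:
    @pytest.mark.parametrize("S,n,L,expected", [
        (5, 2, 100, 0.05),
        (3, 4, 1, 18 / 11),        # a_3 = 11/6
        (0, 10, 1000, 0.0),
    ])
    def test_values(self, S, n, L, expected):
        assert pg.watterson_theta(S, n, L) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            pg.watterson_theta(1, 4, 0)


class TestPi:
    def test_two_haplotypes_three_diffs(self):
        # one diploid individual het at 3 of 100 accessible sites
        m = make_matrix([[1, 1, 1]])
        assert pg.nucleotide_diversity(m, 100) == pytest.approx(0.03)

    def test_site_term_matches_all_pairs_oracle(self):
        # n=4 haplotypes, derived count 2: brute force over all 6 pairs
        hap = np.array([1, 1, 0, 0])
        diffs = [a != b for a, b in itertools.combinations(hap, 2)]
        assert np.mean(diffs) == pytest.approx(2 / 3)
        m = make_matrix([[2], [0]])  # two diploids, dosage 2 and 0
        assert pg.nucleotide_diversity(m, 1) == pytest.approx(2 / 3)

    def test_divisor_linearity(self):
        m = make_matrix([[1, 0, 1], [0, 1, 1]])
        assert pg.nucleotide_diversity(m, 50) == pytest.approx(
            2 * pg.nucleotide_diversity(m, 100))

    def test_pi_from_sfs_equals_pairwise(self):
        """Dual-route identity on random complete-data fixtures."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_ind, n_sites = rng.integers(2, 8), rng.integers(2, 40)
            calls = rng.integers(0, 3, size=(n_ind, n_sites))
            m = make_matrix(calls)
            sfs = pg_sfs_from_calls(calls, 2 * n_ind)
            assert pg.pi_from_sfs(sfs) == pytest.approx(
                pg.nucleotide_diversity(m, 1.0), rel=1e-9)


def pg_sfs_from_calls(calls, n):
    counts = calls.sum(axis=0)
    xi = np.bincount(counts[(counts > 0) & (counts < n)], minlength=n)[1:n]
    return SFS1D(n=n, xi=xi.astype(float))


class TestTajimasD:
    def test_zero_when_pi_equals_watterson(self):
        # n=2: pi == S/a_1 always, so D would be 0/0-free only via identity
        n = 4
        # construct a spectrum with pi_total == S/a_{n-1}
        # pi = (2/12)*(3*xi1 + 4*xi2); S/a3 = S*6/11
        # choose xi = [22, 0, 11]: S=33, pi=(1/6)*(66+0)+... solve directly:
        xi = np.array([4.0, 0.0, 2.9999999])
        sfs = SFS1D(n=n, xi=xi)
        pi = pg.pi_from_sfs(sfs)
        target = sfs.S / pg.harmonic(n - 1)
        # adjust xi2 so pi == S/a3 exactly, then D == 0
        # pi = 0.5*xi1 + (2/3)*xi2 + 0.5*xi3 ; vary xi2
        # 0.5*4 + (2/3)*x + 0.5*3 = (7+x)*6/11  -> x solves linearly
        x = (6 / 11 * 7 - 3.5) / (2 / 3 - 6 / 11)
        sfs = SFS1D(n=n, xi=[4.0, x, 3.0])
        assert pg.tajimas_d(sfs) == pytest.approx(0.0, abs=1e-9)

    def test_intermediate_excess_positive(self):
        sfs = SFS1D(n=4, xi=[0, 10, 0])  # all doubletons
        assert pg.tajimas_d(sfs) > 0

    def test_singleton_excess_negative(self):
        sfs = SFS1D(n=10, xi=[50, 2, 1, 1, 0, 0, 0, 0, 0])
        assert pg.tajimas_d(sfs) < 0

    def test_undefined_for_empty(self):
        with pytest.raises(ValueError):
            pg.tajimas_d(SFS1D(n=4, xi=[0, 0, 0]))


class TestWindows:
    def test_uniform_fixture_window_pi_equals_global(self):
        calls = np.tile([[1], [0]], (1, 40))
        m = make_matrix(calls, positions=np.arange(40) * 250)
        mask = AccessibilityMask({"chr1": np.ones(10_000, bool)})
        ws = pg.windowed_stats(m, mask, window_size=2_500)
        assert len(ws) == 4
        pis = [w.pi for w in ws]
        assert np.allclose(pis, pis[0])
        global_pi = pg.nucleotide_diversity(m, 10_000)
        assert np.mean(pis) == pytest.approx(global_pi)

    def test_per_window_counts_match_hand_count(self):
        pos = np.array([10, 20, 1200, 1300, 1400, 2600])
        calls = np.tile([[1], [0]], (1, 6))
        m = make_matrix(calls, positions=pos)
        mask = AccessibilityMask({"chr1": np.ones(3000, bool)})
        ws = pg.windowed_stats(m, mask, window_size=1000)
        assert [w.S for w in ws] == [2, 3, 1]

    def test_accessibility_correction(self):
        """Masked half of the window doubles per-site pi with the same
        variants."""
        calls = np.tile([[1], [0]], (1, 10))
        m = make_matrix(calls, positions=np.arange(10) * 10)
        full = AccessibilityMask({"chr1": np.ones(1000, bool)})
        half_arr = np.ones(1000, bool)
        half_arr[500:] = False
        half = AccessibilityMask({"chr1": half_arr})
        w_full = pg.windowed_stats(m, full, window_size=1000)[0]
        w_half = pg.windowed_stats(m, half, window_size=1000)[0]
        assert w_half.pi == pytest.approx(2 * w_full.pi)

    def test_zero_accessible_window_skipped(self):
        m = make_matrix([[1], [0]], positions=np.array([5]))
        arr = np.zeros(100, bool)
        mask = AccessibilityMask({"chr1": arr})
        assert pg.windowed_stats(m, mask, window_size=50) == []


class TestPinPs:
    def test_equal_diversities(self):
        assert pg.pinps_ratio(0.01, 0.01) == 1.0

    def test_undefined_when_ps_zero(self):
        with pytest.raises(ValueError):
            pg.pinps_ratio(0.01, 0.0)


class TestLdR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert pg.ld_r2(g, g) == pytest.approx(1.0)

    def test_symmetry_under_reversal(self):
        a = np.array([0, 1, 2, 2, 1, 0])
        b = np.array([2, 2, 1, 0, 0, 1])
        assert pg.ld_r2(a, b) == pytest.approx(pg.ld_r2(b, a))

    def test_matches_hand_oracle(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([0, 1, 1, 2, 2, 2])
        r = np.corrcoef(a, b)[0, 1]
        assert pg.ld_r2(a, b) == pytest.approx(r * r)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pg.ld_r2(np.array([1, 1, 1]), np.array([0, 1, 2]))


class TestLdPrune:
    def _brute_force(self, matrix, window_bp, step_bp, r2_max):
        keep = np.ones(matrix.n_sites, bool)
        w = int(matrix.pos.min())
        while w <= int(matrix.pos.max()):
            live = [j for j in range(matrix.n_sites)
                    if keep[j] and w <= matrix.pos[j] < w + window_bp]
            for i, ja in enumerate(live):
                if not keep[ja]:
                    continue
                for jb in live[i + 1:]:
                    if not keep[jb]:
                        continue
                    try:
                        if pg.ld_r2(matrix.calls[:, ja],
                                    matrix.calls[:, jb]) > r2_max:
                            keep[jb] = False
                    except ValueError:
                        pass
            w += step_bp
        return np.flatnonzero(keep)

    def test_duplicate_site_removed(self):
        calls = np.array([[0, 0], [1, 1], [2, 2], [1, 1]])
        m = make_matrix(calls, positions=np.array([100, 200]))
        assert pg.ld_prune(m).tolist() == [0]

    def test_low_ld_identity(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(50, 8))
        m = make_matrix(calls, positions=np.arange(8) * 100_000)
        # far apart: never in the same window
        assert pg.ld_prune(m).tolist() == list(range(8))

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(4)
        for rep in range(10):
            calls = rng.integers(0, 3, size=(12, 10))
            pos = np.sort(rng.choice(100_000, size=10, replace=False))
            m = make_matrix(calls, positions=pos)
            got = pg.ld_prune(m, window_bp=50_000, step_bp=10_000,
                              r2_max=0.1)
            expected = self._brute_force(m, 50_000, 10_000, 0.1)
            assert got.tolist() == expected.tolist()

    def test_no_high_ld_pair_survives(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 3, size=(30, 1))
        calls = np.hstack([base + rng.integers(0, 2, size=(30, 1)) * 0
                           for _ in range(6)])
        calls += rng.integers(0, 2, size=calls.shape)
        calls = np.clip(calls, 0, 2)
        m = make_matrix(calls, positions=np.arange(6) * 1000)
        kept = pg.ld_prune(m, r2_max=0.1)
        for a, b in itertools.combinations(kept, 2):
            if abs(m.pos[a] - m.pos[b]) < 50_000:
                assert pg.ld_r2(m.calls[:, a], m.calls[:, b]) <= 0.1


class TestLdDecay:
    def test_unlinked_flat_at_finite_sample_baseline(self):
        rng = np.random.default_rng(6)
        n_ind = 40
        p = rng.uniform(0.2, 0.8, size=60)
        calls = rng.binomial(2, p, size=(n_ind, 60)).astype(np.int8)
        m = make_matrix(calls, positions=np.sort(
            rng.choice(60_000, 60, replace=False)))
        curve = pg.ld_decay_curve(m, max_dist=60_000, bin_width=15_000)
        ok = curve.n_pairs > 20
        assert (np.nanmax(curve.mean_r2[ok]) < 4 / n_ind)
        # no trend: first and last bins comparable
        assert abs(curve.mean_r2[ok][0] - curve.mean_r2[ok][-1]) < 2 / n_ind

    def test_singletons_excluded_by_default_maf(self):
        calls = np.zeros((10, 3), dtype=np.int8)
        calls[0, 0] = 1          # singleton
        calls[:5, 1] = 1
        calls[:5, 2] = 1
        m = make_matrix(calls, positions=np.array([0, 100, 200]))
        curve = pg.ld_decay_curve(m, max_dist=1000, bin_width=1000)
        assert curve.n_pairs.sum() == 1  # only the non-singleton pair

    def test_block_correlated_data_decays(self):
        rng = np.random.default_rng(7)
        n_ind, n_sites = 60, 120
        p = rng.uniform(0.2, 0.8, size=n_sites)
        calls = rng.binomial(2, p, size=(n_ind, n_sites)).astype(np.int8)
        m = make_matrix(calls, positions=np.arange(n_sites) * 100)
        linked = generate_block_ld(m, block_bp=1000.0, rho=0.9, seed=8)
        curve = pg.ld_decay_curve(linked, max_dist=8000, bin_width=2000)
        assert curve.mean_r2[0] > curve.mean_r2[2] > curve.mean_r2[3] - 0.05
        assert curve.mean_r2[0] > 0.3


class TestPca:
    def test_two_demes_separate_on_pc1(self):
        rng = np.random.default_rng(9)
        fa = rng.uniform(0.02, 0.10, 200)
        fb = 1.0 - fa          # near-fixed differences between the demes
        calls = np.vstack([rng.binomial(2, fa, size=(15, 200)),
                           rng.binomial(2, fb, size=(15, 200))]).astype(np.int8)
        m = make_matrix(calls)
        coords, var = pg.genotype_pca(m, n_components=5)
        assert var[0] > 0.5
        assert (coords[:15, 0] > 0).all() != (coords[15:, 0] > 0).any()
        assert np.all(np.diff(var) <= 1e-12)

    def test_permuting_individuals_permutes_rows(self):
        rng = np.random.default_rng(10)
        calls = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        m = make_matrix(calls)
        perm = rng.permutation(10)
        coords, _ = pg.genotype_pca(m, n_components=3)
        coords_p, _ = pg.genotype_pca(m.take_samples(perm), n_components=3)
        assert np.allclose(np.abs(coords_p), np.abs(coords[perm]), atol=1e-8)


class TestRankTests:
    def test_spearman_perfect_monotone(self):
        r, p = pg.spearman([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        r, _ = pg.spearman([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_spearman_constant_rejected(self):
        with pytest.raises(ValueError):
            pg.spearman([1, 1, 1], [1, 2, 3])

    def test_kw_equals_squared_standardized_wilcoxon(self):
        """For two tie-free groups the Kruskal-Wallis statistic equals the
        square of the standardized rank-sum statistic."""
        a = [1.2, 3.4, 5.1, 7.7, 9.0]
        b = [2.2, 4.1, 6.3, 8.8]
        stat, df, _ = pg.kruskal_wallis([a, b])
        U, _ = pg.wilcoxon_ranksum(a, b)
        n1, n2 = len(a), len(b)
        z = (U - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert df == 1
        assert stat == pytest.approx(z * z)

    def test_bonferroni_caps_at_one(self):
        adj = pg.bonferroni([0.01, 0.5, 0.04])
        assert np.allclose(adj, [0.03, 1.0, 0.12])
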