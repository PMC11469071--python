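"""Composite likelihood, coordinate-search fitting, AIC selection,
bootstrap CIs, and the published model family."""

import math

import numpy as np
import pytest

from primrose.coalsim import (DemographicModel, Population, SampleConfig,
                              SizeChange, expected_sfs_single_pop)
from primrose import demog_fit as dg
from primrose.demog_fit import (EpochModel, FitResult, FreeParameter,
                                ModelTemplate, composite_loglik,
                                encode_published_models, fit_model,
                                fit_single_population_epochs, model_select,
                                model5_truth_generations,
                                parametric_bootstrap_ci, poisson_loglik,
                                select_epoch_model, simulate_observed_sfs)
from primrose.sfs_tools import SFS1D, JointSFS


def _joint(cells, pops=None):
    cells = np.asarray(cells, dtype=float)
    return JointSFS(cells=cells, pops=pops or
                    [f"p{i}" for i in range(cells.ndim)])


class TestCompositeLoglik:
    def test_hand_computed_two_by_two(self):
        obs = _joint([[0, 3], [2, 0]])
        exp = _joint([[0, 0.25], [0.75, 0]])
        lnl = composite_loglik(obs, exp, min_entry=0)
        assert lnl == pytest.approx(3 * math.log(0.25) + 2 * math.log(0.75))

    def test_saturated_is_maximum(self):
        rng = np.random.default_rng(0)
        obs = _joint(rng.integers(0, 30, size=(4, 4)).astype(float))
        sat = dg.saturated_loglik(obs, min_entry=0)
        probs = obs.normalized()
        assert composite_loglik(obs, probs, min_entry=0) == pytest.approx(sat)
        # any other distribution does worse
        other = _joint(rng.uniform(0.1, 1, size=(4, 4)))
        assert composite_loglik(obs, other, min_entry=0) <= sat

    def test_lumping_pools_small_cells(self):
        obs = _joint([[0, 3], [3, 3]])
        exp = _joint([[0, 0.2], [0.3, 0.5]])
        # all three polymorphic cells are below min_entry=10: one pooled
        # cell with count 9 and probability 1
        lnl = composite_loglik(obs, exp, min_entry=10)
        assert lnl == pytest.approx(9 * math.log(1.0))

    def test_cell_permutation_invariance(self):
        rng = np.random.default_rng(1)
        obs_c = rng.integers(0, 50, size=(3, 3)).astype(float)
        exp_c = rng.uniform(0.1, 1, size=(3, 3))
        base = composite_loglik(_joint(obs_c), _joint(exp_c), min_entry=0)
        # permute the interior cells consistently
        perm_obs, perm_exp = obs_c.copy(), exp_c.copy()
        perm_obs[0, 1], perm_obs[1, 2] = obs_c[1, 2], obs_c[0, 1]
        perm_exp[0, 1], perm_exp[1, 2] = exp_c[1, 2], exp_c[0, 1]
        assert composite_loglik(_joint(perm_obs), _joint(perm_exp),
                                min_entry=0) == pytest.approx(base)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_loglik(_joint(np.ones((3, 3))),
                             _joint(np.ones((4, 4))))


class TestAicAndSelection:
    def test_aic_identity(self):
        fit = FitResult("m", {}, loglik=-100.0, n_params=5, n_runs=1,
                        run_logliks=[-100.0], converged=True)
        assert fit.aic == 210.0

    def test_identical_fits_tied(self):
        a = FitResult("a", {}, -50.0, 3, 2, [-50.0, -51.0], True)
        b = FitResult("b", {}, -50.0, 3, 2, [-50.0, -51.0], True)
        groups = model_select([a, b])
        assert len(groups[0]) == 2

    def test_clearly_better_model_separated(self):
        a = FitResult("a", {}, -50.0, 3, 2, [-50.0, -50.5], True)
        b = FitResult("b", {}, -500.0, 3, 2, [-500.0, -501.0], True)
        groups = model_select([a, b])
        assert [g[0].model_name for g in groups] == ["a", "b"]


def _two_epoch_template(t_fixed=500.0):
    def builder(v):
        return DemographicModel(
            [Population("A", float(v["N_CUR"]))],
            [SizeChange(t_fixed, "A", float(v["N_ANC"]))])
    return ModelTemplate("two_epoch", [
        FreeParameter("N_CUR", 50.0, 100_000.0),
        FreeParameter("N_ANC", 50.0, 1_000_000.0)], builder)


class TestFitModel:
    def test_same_seed_identical_result(self):
        template = _two_epoch_template()
        truth = {"N_CUR": 1000.0, "N_ANC": 10_000.0}
        model = template.build(truth)
        config = SampleConfig({"A": 10})
        obs, L = simulate_observed_sfs(model, config, 2000, seed=3,
                                       n_reps=5000)
        kw = dict(n_runs=2, n_cycles=4, sims_per_eval=500, seed=5,
                  likelihood="poisson", mu=model.mutation_rate, L=L)
        f1 = fit_model(template, obs, config, **kw)
        f2 = fit_model(template, obs, config, **kw)
        assert f1.params == f2.params
        assert f1.loglik == f2.loglik

    def test_two_epoch_parameter_recovery(self):
        """Bottleneck truth (10,000 -> 1,000 at 500 generations) recovered
        within a factor 1.5 in >= 80% of replicates."""
        template = _two_epoch_template()
        truth = {"N_CUR": 1000.0, "N_ANC": 10_000.0}
        model = template.build(truth)
        config = SampleConfig({"A": 10})
        mu = model.mutation_rate
        hits = 0
        n_reps = 10
        for rep in range(n_reps):
            obs, L = simulate_observed_sfs(model, config, 5000,
                                           seed=100 + rep, n_reps=20_000)
            fit = fit_model(template, obs, config, n_runs=4, n_cycles=8,
                            sims_per_eval=1500, seed=rep,
                            likelihood="poisson", mu=mu, L=L)
            ok = all(truth[k] / 1.5 <= fit.params[k] <= truth[k] * 1.5
                     for k in truth)
            hits += ok
        assert hits >= 0.8 * n_reps

    def test_truth_beats_perturbed_parameters(self):
        """lnL at the generating values exceeds lnL at strongly perturbed
        values for the same data (local-maximum sanity)."""
        template = _two_epoch_template()
        truth = {"N_CUR": 1000.0, "N_ANC": 10_000.0}
        model = template.build(truth)
        config = SampleConfig({"A": 10})
        obs, L = simulate_observed_sfs(model, config, 20_000, seed=17,
                                       n_reps=30_000)
        ev = dg._make_eval(template, obs, config, 20_000, 99, 10,
                           "poisson", model.mutation_rate, L)
        assert ev(truth) > ev({"N_CUR": 4000.0, "N_ANC": 10_000.0})
        assert ev(truth) > ev({"N_CUR": 1000.0, "N_ANC": 2000.0})

    def test_invalid_parameter_region_is_minus_inf(self):
        templates = {t.name: t for t in encode_published_models()}
        m5 = templates["model5"]
        bad = model5_truth_generations()
        bad["T_CH_EN_SPLIT"] = bad["T_TR_EU_SPLIT"] * 2  # violates nesting
        config = SampleConfig({"TR": 4, "CH": 4, "EN1": 4, "EN6": 4})
        obs, L = simulate_observed_sfs(
            m5.build(model5_truth_generations()), config, 500, seed=1,
            n_reps=2000)
        ev = dg._make_eval(m5, obs, config, 200, 1, 10, "multinomial",
                           None, None)
        assert ev(bad) == -math.inf


class TestEpochFit:
    def test_constant_size_prefers_one_epoch(self):
        rng = np.random.default_rng(21)
        n = 16
        w = expected_sfs_single_pop([(np.inf, 5000.0)], n)
        wins = 0
        for rep in range(7):
            xi = rng.multinomial(4000, w / w.sum()).astype(float)
            k, _ = select_epoch_model(SFS1D(n=n, xi=xi), k_max=2,
                                      seed=rep, n_starts=5)
            wins += (k == 1)
        assert wins >= 4

    def test_bottleneck_detected(self):
        """Recent 10x contraction: fitted recent size below ancestral."""
        rng = np.random.default_rng(22)
        n = 16
        w = expected_sfs_single_pop([(500.0, 1000.0), (np.inf, 10_000.0)], n)
        hits = 0
        for rep in range(10):
            xi = rng.multinomial(5000, w / w.sum()).astype(float)
            em, _, _ = fit_single_population_epochs(
                SFS1D(n=n, xi=xi), 2, seed=rep, n_starts=6)
            hits += em.epochs[0][1] < em.epochs[-1][1]
        assert hits >= 9

    def test_seed_reproducibility(self):
        xi = np.maximum(1, (1000 / np.arange(1, 12)).astype(int)).astype(float)
        sfs = SFS1D(n=12, xi=xi)
        a = fit_single_population_epochs(sfs, 2, seed=4, n_starts=3)
        b = fit_single_population_epochs(sfs, 2, seed=4, n_starts=3)
        assert a[0].epochs == b[0].epochs

    def test_too_many_parameters_rejected(self):
        with pytest.raises(ValueError, match="free parameters"):
            fit_single_population_epochs(SFS1D(n=4, xi=[5, 3, 1]), 3)


class TestPublishedModels:
    def test_model5_validates_and_orders_events(self):
        templates = {t.name: t for t in encode_published_models()}
        model = templates["model5"].build(model5_truth_generations())
        model.validate()
        times = [e.time for e in model.events]
        assert times == sorted(times)

    def test_published_values_in_generations(self):
        truth = model5_truth_generations()
        assert truth["T_TR_EU_SPLIT"] == 39_500.0   # 79,000 y at 2 y/gen
        assert truth["T_CH_EN_SPLIT"] == 32_750.0
        assert truth["T_EN1_EN6_SPLIT"] == 12_000.0
        assert truth["N_ANC"] == 13_419.0
        assert truth["N_TR"] == 95_627.0

    def test_three_templates_share_parameter_names(self):
        templates = encode_published_models()
        names = [sorted(p.name for p in t.params) for t in templates]
        assert all(n == names[0] for n in names)


class TestBootstrap:
    def test_percentiles_ordered_and_contain_plausible_mass(self):
        template = _two_epoch_template()
        truth = {"N_CUR": 1000.0, "N_ANC": 10_000.0}
        model = template.build(truth)
        config = SampleConfig({"A": 10})
        obs, L = simulate_observed_sfs(model, config, 5000, seed=31,
                                       n_reps=20_000)
        fit = fit_model(template, obs, config, n_runs=3, n_cycles=8,
                        sims_per_eval=1500, seed=32, likelihood="poisson",
                        mu=model.mutation_rate, L=L)
        cis, draws, n_failed = parametric_bootstrap_ci(
            template, fit, config, seed=33, n_boot=6, runs_per_boot=2,
            n_cycles=6, sims_per_eval=1000, likelihood="poisson",
            mu=model.mutation_rate, L=L, sim_reps=8000)
        for name, (lo, hi) in cis.items():
            assert lo <= hi
            assert len(draws[name]) + n_failed == 6
        assert fit.bootstrap_ci is cis
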