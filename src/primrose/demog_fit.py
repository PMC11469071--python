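"""Composite-likelihood demographic inference on the joint SFS.

The likelihood treats SFS cells as independent. Two modes are provided:

* ``multinomial`` (default): the observed polymorphic-site total is taken
  as fixed and cell probabilities come from the normalized expected SFS.
  Because the relative spectrum is invariant to a joint rescaling of all
  sizes and times, at least one absolute quantity must be fixed (a nuisance
  size, or use the Poisson mode).
* ``poisson``: expected per-cell counts are ``mu * L * W_cell`` with ``W``
  the Monte-Carlo branch-length weights; the expected total number of
  segregating sites then anchors the absolute parameter scale, as when a
  mutation rate and sequence length are specified externally.

Cells with observed count below ``min_entry`` are pooled into a single
lumped cell before evaluation, mirroring the minimum-entry device of
SFS-based inference tools.

Optimization is a multi-run cyclic coordinate search on log-transformed
parameters with geometric step shrinkage, approximating an
expectation/conditional-maximization protocol; each run uses common random
numbers for its Monte-Carlo likelihood evaluations so that the surface it
searches is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .coalsim import (DemographicModel, Population, SampleConfig, SizeChange,
                      Split, expected_joint_sfs_weights,
                      expected_sfs_single_pop)
from .sfs_tools import SFS1D, JointSFS

logger = logging.getLogger(__name__)

__all__ = [
    "FreeParameter", "ModelTemplate", "FitResult", "EpochModel",
    "composite_loglik", "poisson_loglik", "fit_model", "model_select",
    "parametric_bootstrap_ci", "fit_single_population_epochs",
    "select_epoch_model", "encode_published_models",
]


@dataclass
class FreeParameter:
    name: str
    lower: float
    upper: float
    kind: str = "size"       # "size" or "time" (informational)


@dataclass
class ModelTemplate:
    """A demographic model family: a builder mapping free parameters to a
    concrete :class:`DemographicModel`, plus parameter bounds.

    The builder raises ``ValueError`` for parameter combinations that
    violate event ordering; the fitter treats those as log-likelihood
    negative infinity.
    """

    name: str
    params: list[FreeParameter]
    builder: Callable[[Mapping[str, float]], DemographicModel]
    description: str = ""

    def build(self, values: Mapping[str, float]) -> DemographicModel:
        model = self.builder(values)
        model.validate()
        return model

    @property
    def k(self) -> int:
        return len(self.params)


@dataclass
class FitResult:
    model_name: str
    params: dict[str, float]
    loglik: float
    n_params: int
    n_runs: int
    run_logliks: list[float]
    converged: bool
    bootstrap_ci: dict[str, tuple[float, float]] | None = None

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik


@dataclass
class EpochModel:
    """Piecewise-constant single-population history, present backward:
    epochs[i] = (duration_generations, N_e); last duration is open-ended."""

    epochs: list[tuple[float, float]]

    @property
    def k(self) -> int:
        return len(self.epochs)


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _lump(obs: np.ndarray, expected: np.ndarray, min_entry: int
          ) -> tuple[np.ndarray, np.ndarray]:
    """Pool cells with observed count < min_entry into one lumped cell."""
    small = obs < min_entry
    if min_entry <= 0 or not small.any():
        return obs, expected
    obs_out = np.concatenate([obs[~small], [obs[small].sum()]])
    exp_out = np.concatenate([expected[~small], [expected[small].sum()]])
    return obs_out, exp_out


def composite_loglik(obs: JointSFS, expected: JointSFS,
                     min_entry: int = 10, eps: float = 1e-300) -> float:
    """Multinomial composite log-likelihood over polymorphic cells."""
    if obs.dims != expected.dims:
        raise ValueError("observed and expected SFS dims differ")
    mask = obs.polymorphic_mask()
    m = obs.cells[mask]
    p = expected.normalized().cells[mask]
    m, p = _lump(m, p, min_entry)
    if eps <= 0 and np.any((p == 0) & (m > 0)):
        import warnings
        warnings.warn("expected mass 0 where observed > 0; -inf likelihood")
        return -math.inf
    p = np.maximum(p, eps)
    return float(np.sum(m * np.log(p)))


def poisson_loglik(obs: JointSFS, weights: np.ndarray, mu: float, L: float,
                   min_entry: int = 10, eps: float = 1e-300) -> float:
    """Poisson composite log-likelihood with expected counts mu*L*W."""
    mask = obs.polymorphic_mask()
    m = obs.cells[mask]
    lam = mu * L * weights[mask]
    m, lam = _lump(m, lam, min_entry)
    lam = np.maximum(lam, eps)
    return float(np.sum(m * np.log(lam) - lam))


def saturated_loglik(obs: JointSFS, min_entry: int = 10) -> float:
    """Best achievable multinomial lnL (obs proportions as probabilities)."""
    mask = obs.polymorphic_mask()
    m = obs.cells[mask]
    m, _ = _lump(m, m, min_entry)
    tot = m.sum()
    nz = m > 0
    return float(np.sum(m[nz] * np.log(m[nz] / tot)))


# ---------------------------------------------------------------------------
# multi-run coordinate-search fitting
# ---------------------------------------------------------------------------

def _make_eval(template: ModelTemplate, obs: JointSFS, config: SampleConfig,
               sims_per_eval: int, crn_seed: int, min_entry: int,
               likelihood: str, mu: float | None, L: float | None):
    pops_in_obs = obs.pops

    def evaluate(values: Mapping[str, float]) -> float:
        try:
            model = template.build(values)
        except ValueError:
            return -math.inf
        W = expected_joint_sfs_weights(model, config, sims_per_eval, crn_seed)
        # align axes to the observed SFS's population order
        names = [n for n in model.pop_names if config.n_per_pop.get(n, 0) > 0]
        keep_axes = [i for i, n in enumerate(model.pop_names)
                     if config.n_per_pop.get(n, 0) > 0]
        Wq = np.squeeze(W, axis=tuple(i for i in range(W.ndim)
                                      if i not in keep_axes))
        if names != pops_in_obs:
            Wq = np.moveaxis(Wq, [names.index(p) for p in pops_in_obs],
                             range(len(pops_in_obs)))
        if likelihood == "poisson":
            return poisson_loglik(obs, Wq, mu, L, min_entry=min_entry)
        exp_sfs = JointSFS(cells=Wq, pops=list(pops_in_obs))
        try:
            return composite_loglik(obs, exp_sfs.normalized(),
                                    min_entry=min_entry)
        except ValueError:
            return -math.inf

    return evaluate


def fit_model(template: ModelTemplate, obs: JointSFS, config: SampleConfig,
              n_runs: int = 50, n_cycles: int = 40,
              sims_per_eval: int = 2000, seed: int = 0,
              min_entry: int = 10, likelihood: str = "multinomial",
              mu: float | None = None, L: float | None = None,
              init: Mapping[str, float] | None = None,
              init_spread: float = 1.5,
              step0: float = 1.6, shrink: float = 0.88) -> FitResult:
    """Maximize the composite likelihood by multi-run coordinate search.

    Each run draws a random start (log-uniform within bounds, or within a
    factor ``init_spread`` of ``init`` when given), then performs
    ``n_cycles`` of cyclic coordinate moves on the log scale, proposing
    multiplicative steps whose size shrinks geometrically. Run winners are
    re-evaluated with a common seed and four-fold simulation count before
    the best run is chosen, so the comparison across runs is fair.
    """
    if likelihood == "poisson" and (mu is None or L is None):
        raise ValueError("poisson likelihood needs mu and L")
    rng = np.random.default_rng(seed)
    names = [p.name for p in template.params]
    lo = np.log(np.array([p.lower for p in template.params]))
    hi = np.log(np.array([p.upper for p in template.params]))

    run_results: list[tuple[np.ndarray, float]] = []
    improved_any = []
    for run in range(n_runs):
        crn_seed = int(rng.integers(2**31 - 1))
        evaluate = _make_eval(template, obs, config, sims_per_eval, crn_seed,
                              min_entry, likelihood, mu, L)
        if init is not None:
            x = np.array([
                np.clip(math.log(init[n]) + rng.uniform(
                    -math.log(init_spread), math.log(init_spread)),
                    lo[i], hi[i])
                for i, n in enumerate(names)])
        else:
            x = rng.uniform(lo, hi)
        f = evaluate(dict(zip(names, np.exp(x))))
        tries = 0
        while not np.isfinite(f) and tries < 50:
            x = rng.uniform(lo, hi)
            f = evaluate(dict(zip(names, np.exp(x))))
            tries += 1
        f0 = f
        step = math.log(step0)
        order = np.arange(len(names))
        for cycle in range(n_cycles):
            rng.shuffle(order)
            for j in order:
                for delta in (step, -step):
                    xc = x.copy()
                    xc[j] = np.clip(x[j] + delta, lo[j], hi[j])
                    if xc[j] == x[j]:
                        continue
                    fc = evaluate(dict(zip(names, np.exp(xc))))
                    if fc > f:
                        x, f = xc, fc
                        # line search: extend while the move keeps paying
                        for _ in range(8):
                            xc = x.copy()
                            xc[j] = np.clip(x[j] + delta, lo[j], hi[j])
                            if xc[j] == x[j]:
                                break
                            fc = evaluate(dict(zip(names, np.exp(xc))))
                            if fc > f:
                                x, f = xc, fc
                            else:
                                break
                        break
            step = max(step * shrink, 0.01)
        run_results.append((x, f))
        improved_any.append(f > f0)
        logger.debug("run %d: lnL %.3f", run, f)

    # fair cross-run comparison: common seed, more simulations
    ref_seed = int(rng.integers(2**31 - 1))
    evaluate_ref = _make_eval(template, obs, config, 4 * sims_per_eval,
                              ref_seed, min_entry, likelihood, mu, L)
    finals = [evaluate_ref(dict(zip(names, np.exp(x))))
              for x, _ in run_results]
    best = int(np.argmax(finals))
    x_best = run_results[best][0]
    return FitResult(
        model_name=template.name,
        params=dict(zip(names, np.exp(x_best))),
        loglik=float(finals[best]),
        n_params=template.k,
        n_runs=n_runs,
        run_logliks=[float(f) for f in finals],
        converged=any(improved_any),
    )


def model_select(results: Sequence[FitResult], tie_delta: float = 2.0
                 ) -> list[list[FitResult]]:
    """Rank fitted models by AIC, lumping into tie groups.

    Models are tied when their AICs differ by less than ``tie_delta`` or
    their per-run likelihood distributions overlap. The first group is the
    selected set.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 fitted models to select among")
    ordered = sorted(results, key=lambda r: r.aic)
    groups: list[list[FitResult]] = [[ordered[0]]]
    for r in ordered[1:]:
        head = groups[-1][0]
        overlap = (max(r.run_logliks) >= min(head.run_logliks)
                   and max(head.run_logliks) >= min(r.run_logliks))
        if r.aic - head.aic < tie_delta or overlap:
            groups[-1].append(r)
        else:
            groups.append([r])
    return groups


def simulate_observed_sfs(model: DemographicModel, config: SampleConfig,
                          n_snps: float | None, seed: int,
                          n_reps: int = 50_000, mu: float | None = None,
                          L: float | None = None
                          ) -> tuple[JointSFS, float]:
    """Draw an observed joint SFS from a model.

    With ``n_snps`` given, cell counts are multinomial with that total;
    with ``mu`` and ``L`` given instead, counts are Poisson with mean
    ``mu*L*W``. Returns the SFS and the implied sequence length (for the
    multinomial case, the L whose expected S equals ``n_snps``).
    """
    rng = np.random.default_rng(seed)
    W = expected_joint_sfs_weights(model, config, n_reps,
                                   int(rng.integers(2**31 - 1)))
    mask_corner = np.ones(W.shape, dtype=bool)
    mask_corner[tuple(0 for _ in W.shape)] = False
    mask_corner[tuple(d - 1 for d in W.shape)] = False
    Wp = np.where(mask_corner, W, 0.0)
    mu_eff = mu if mu is not None else model.mutation_rate
    if n_snps is not None:
        L_eff = float(n_snps) / (mu_eff * Wp.sum())
        counts = rng.poisson(mu_eff * L_eff * Wp)
    else:
        if L is None:
            raise ValueError("need n_snps or L")
        L_eff = float(L)
        counts = rng.poisson(mu_eff * L_eff * Wp)
    names = [n for n in model.pop_names if config.n_per_pop.get(n, 0) > 0]
    keep_axes = [i for i, n in enumerate(model.pop_names)
                 if config.n_per_pop.get(n, 0) > 0]
    counts = np.squeeze(counts, axis=tuple(i for i in range(counts.ndim)
                                           if i not in keep_axes))
    return JointSFS(cells=counts.astype(float), pops=names), L_eff


def parametric_bootstrap_ci(template: ModelTemplate, fit: FitResult,
                            config: SampleConfig, seed: int,
                            n_boot: int = 100, runs_per_boot: int = 20,
                            n_cycles: int = 12, sims_per_eval: int = 2000,
                            min_entry: int = 10,
                            likelihood: str = "multinomial",
                            mu: float | None = None, L: float | None = None,
                            n_snps: float | None = None,
                            sim_reps: int = 20_000,
                            ) -> tuple[dict[str, tuple[float, float]],
                                       dict[str, np.ndarray], int]:
    """Percentile parametric-bootstrap confidence intervals.

    Simulates ``n_boot`` observed SFSs from the fitted model, re-fits each
    starting near the fitted values (the initial-values protocol), and
    reports the empirical 2.5/97.5 percentiles per parameter. Returns
    (CIs, per-parameter bootstrap draws, number of non-converged replicates
    excluded).
    """
    rng = np.random.default_rng(seed)
    model_hat = template.build(fit.params)
    draws: dict[str, list[float]] = {p.name: [] for p in template.params}
    n_failed = 0
    for b in range(n_boot):
        bseed = int(rng.integers(2**31 - 1))
        if likelihood == "poisson":
            obs_b, _ = simulate_observed_sfs(model_hat, config, None, bseed,
                                             n_reps=sim_reps, mu=mu, L=L)
        else:
            obs_b, _ = simulate_observed_sfs(model_hat, config,
                                             n_snps, bseed, n_reps=sim_reps)
        refit = fit_model(template, obs_b, config, n_runs=runs_per_boot,
                          n_cycles=n_cycles, sims_per_eval=sims_per_eval,
                          seed=bseed ^ 0x5DEECE, min_entry=min_entry,
                          likelihood=likelihood, mu=mu, L=L,
                          init=fit.params)
        if not refit.converged and not np.isfinite(refit.loglik):
            n_failed += 1
            continue
        for k, v in refit.params.items():
            draws[k].append(v)
    cis = {}
    arrays = {}
    for k, vals in draws.items():
        arr = np.array(vals)
        arrays[k] = arr
        if len(arr):
            cis[k] = (float(np.percentile(arr, 2.5)),
                      float(np.percentile(arr, 97.5)))
        else:
            cis[k] = (math.nan, math.nan)
    fit.bootstrap_ci = cis
    return cis, arrays, n_failed


# ---------------------------------------------------------------------------
# single-population multi-epoch ML fit (deterministic expected SFS)
# ---------------------------------------------------------------------------

def _epoch_loglik(sfs: SFS1D, epochs: list[tuple[float, float]],
                  min_entry: int) -> float:
    try:
        w = expected_sfs_single_pop(epochs, sfs.n)
    except (ValueError, FloatingPointError):
        return -math.inf
    if not np.all(np.isfinite(w)) or w.sum() <= 0:
        return -math.inf
    p = w / w.sum()
    m, p = _lump(sfs.xi, p, min_entry)
    p = np.maximum(p, 1e-300)
    return float(np.sum(m * np.log(p)))


def fit_single_population_epochs(sfs: SFS1D, k_epochs: int, seed: int = 0,
                                 n_starts: int = 10, min_entry: int = 0,
                                 n_bounds: tuple[float, float] = (50.0, 1e7),
                                 t_bounds: tuple[float, float] = (1.0, 1e6),
                                 init: EpochModel | None = None,
                                 ) -> tuple[EpochModel, float, float]:
    """ML piecewise-constant history for one population from its unfolded
    SFS (relative spectrum; sizes identified up to the time/size scale set
    by the epoch durations).

    Parameters are k sizes plus k-1 epoch durations, optimized on the log
    scale by Nelder-Mead from ``n_starts`` random starts. Returns
    (epoch model, max lnL, AIC).
    """
    if k_epochs < 1:
        raise ValueError("k_epochs must be >= 1")
    n_free = 2 * k_epochs - 1
    if n_free > sfs.n - 1:
        raise ValueError(f"{n_free} free parameters exceed the {sfs.n - 1} "
                         "spectrum entries")
    rng = np.random.default_rng(seed)

    def unpack(x: np.ndarray) -> list[tuple[float, float]]:
        sizes = np.exp(x[:k_epochs])
        durs = np.exp(x[k_epochs:])
        eps = [(float(durs[i]), float(sizes[i])) for i in range(k_epochs - 1)]
        eps.append((math.inf, float(sizes[-1])))
        return eps

    def neg(x: np.ndarray) -> float:
        return -_epoch_loglik(sfs, unpack(x), min_entry)

    best_x, best_f = None, math.inf
    lo = np.concatenate([np.full(k_epochs, math.log(n_bounds[0])),
                         np.full(k_epochs - 1, math.log(t_bounds[0]))])
    hi = np.concatenate([np.full(k_epochs, math.log(n_bounds[1])),
                         np.full(k_epochs - 1, math.log(t_bounds[1]))])
    x_init = None
    if init is not None:
        if init.k != k_epochs:
            raise ValueError("init epoch count mismatch")
        x_init = np.log(np.concatenate(
            [[N for _, N in init.epochs],
             [d for d, _ in init.epochs[:-1]]]))
    for s in range(n_starts):
        if x_init is not None:
            x0 = np.clip(x_init + rng.normal(0, 0.3, size=len(x_init)),
                         lo, hi)
        else:
            x0 = rng.uniform(lo, hi)
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-4,
                                "fatol": 1e-7})
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    lnl = -best_f
    aic = 2 * n_free - 2 * lnl
    return EpochModel(epochs=unpack(best_x)), lnl, aic


def select_epoch_model(sfs: SFS1D, k_max: int = 4, seed: int = 0,
                       n_starts: int = 10, min_entry: int = 0
                       ) -> tuple[int, dict[int, tuple[EpochModel, float, float]]]:
    """Fit k = 1..k_max epoch models and select k by AIC."""
    fits = {}
    for k in range(1, k_max + 1):
        try:
            fits[k] = fit_single_population_epochs(
                sfs, k, seed=seed + k, n_starts=n_starts, min_entry=min_entry)
        except ValueError:
            break
    best_k = min(fits, key=lambda k: fits[k][2])
    return best_k, fits


# ---------------------------------------------------------------------------
# the published four-population model family
# ---------------------------------------------------------------------------

#: published point estimates (diploid N_e; times in years before present)
MODEL5_PUBLISHED = {
    "T_TR_EU_SPLIT_Y": 79_000.0,
    "T_CH_EN_SPLIT_Y": 65_500.0,
    "T_CH_CONTRACT_Y": 64_000.0,
    "T_CH_RECOVER_Y": 62_300.0,
    "T_EN_CONTRACT_Y": 48_000.0,
    "T_EN_RECOVER_Y": 31_000.0,
    "T_EN1_EN6_SPLIT_Y": 24_000.0,
    "T_EN6_CONTRACT_Y": 100.0,
    "N_ANC": 13_419.0,
    "N_TR": 95_627.0,
}

#: sizes the source analysis does not print; package choices of plausible
#: magnitude (diploid N_e), declining along the westward expansion
MODEL5_UNPUBLISHED = {
    "N_CH": 40_000.0,
    "N_EN1": 30_000.0,
    "N_EN6": 5_000.0,
    "N_EN6_PRE": 30_000.0,
    "N_CH_BOT": 3_000.0,
    "N_CH_PRE": 20_000.0,
    "N_EN_BOT": 2_000.0,
    "N_EN_PRE": 20_000.0,
    "N_ANC_CH_EN": 20_000.0,
}

GENERATION_TIME_YEARS = 2.0


def _model5_builder(free: Mapping[str, float]) -> DemographicModel:
    """Four-population history: TR -> (CH -> (EN1 -> EN6)) with bottleneck/
    recovery pairs on the CH and EN lineages and a very recent contraction
    in the monomorphic deme EN6.

    Free parameters: the three split times (generations) and the two
    printed sizes; the bottleneck/recovery times ride along as fixed
    fractions of their lineage's split time so that event ordering is
    preserved for any admissible split times.
    """
    g = GENERATION_TIME_YEARS
    pub, unp = MODEL5_PUBLISHED, MODEL5_UNPUBLISHED
    t_tr = float(free["T_TR_EU_SPLIT"])
    t_ch = float(free["T_CH_EN_SPLIT"])
    t_en6 = float(free["T_EN1_EN6_SPLIT"])
    n_tr = float(free["N_TR"])
    n_anc = float(free["N_ANC"])
    if not (t_tr > t_ch > t_en6 > 0):
        raise ValueError("split times must be strictly nested")
    # bottleneck/recovery times as fixed fractions of the CH/EN split time
    frac = {k: pub[k] / pub["T_CH_EN_SPLIT_Y"]
            for k in ("T_CH_CONTRACT_Y", "T_CH_RECOVER_Y",
                      "T_EN_CONTRACT_Y", "T_EN_RECOVER_Y")}
    t_ch_con = t_ch * frac["T_CH_CONTRACT_Y"]
    t_ch_rec = t_ch * frac["T_CH_RECOVER_Y"]
    t_en_con = t_ch * frac["T_EN_CONTRACT_Y"]
    t_en_rec = t_ch * frac["T_EN_RECOVER_Y"]
    t_en6_con = pub["T_EN6_CONTRACT_Y"] / g
    if not (t_en_rec > t_en6 > t_en6_con):
        raise ValueError("EN1/EN6 split must postdate the EN recovery and "
                         "predate the EN6 contraction")
    pops = [Population("TR", n_tr), Population("CH", unp["N_CH"]),
            Population("EN1", unp["N_EN1"]), Population("EN6", unp["N_EN6"])]
    events = [
        SizeChange(t_en6_con, "EN6", unp["N_EN6_PRE"]),
        Split(t_en6, "EN6", "EN1"),
        SizeChange(t_en_rec, "EN1", unp["N_EN_BOT"]),
        SizeChange(t_en_con, "EN1", unp["N_EN_PRE"]),
        SizeChange(t_ch_rec, "CH", unp["N_CH_BOT"]),
        SizeChange(t_ch_con, "CH", unp["N_CH_PRE"]),
        Split(t_ch, "EN1", "CH", ancestral_size=unp["N_ANC_CH_EN"]),
        Split(t_tr, "CH", "TR", ancestral_size=n_anc),
    ]
    return DemographicModel(populations=pops, events=events,
                            generation_time_years=g)


def _no_bottleneck_builder(free: Mapping[str, float]) -> DemographicModel:
    g = GENERATION_TIME_YEARS
    unp = MODEL5_UNPUBLISHED
    t_tr = float(free["T_TR_EU_SPLIT"])
    t_ch = float(free["T_CH_EN_SPLIT"])
    t_en6 = float(free["T_EN1_EN6_SPLIT"])
    if not (t_tr > t_ch > t_en6 > 0):
        raise ValueError("split times must be strictly nested")
    pops = [Population("TR", float(free["N_TR"])),
            Population("CH", unp["N_CH"]), Population("EN1", unp["N_EN1"]),
            Population("EN6", unp["N_EN6"])]
    events = [
        Split(t_en6, "EN6", "EN1"),
        Split(t_ch, "EN1", "CH", ancestral_size=unp["N_ANC_CH_EN"]),
        Split(t_tr, "CH", "TR", ancestral_size=float(free["N_ANC"])),
    ]
    return DemographicModel(populations=pops, events=events,
                            generation_time_years=g)


def _single_bottleneck_builder(free: Mapping[str, float]) -> DemographicModel:
    g = GENERATION_TIME_YEARS
    pub, unp = MODEL5_PUBLISHED, MODEL5_UNPUBLISHED
    t_tr = float(free["T_TR_EU_SPLIT"])
    t_ch = float(free["T_CH_EN_SPLIT"])
    t_en6 = float(free["T_EN1_EN6_SPLIT"])
    if not (t_tr > t_ch > t_en6 > 0):
        raise ValueError("split times must be strictly nested")
    t_en_con = t_ch * pub["T_EN_CONTRACT_Y"] / pub["T_CH_EN_SPLIT_Y"]
    t_en_rec = t_ch * pub["T_EN_RECOVER_Y"] / pub["T_CH_EN_SPLIT_Y"]
    if not t_en_rec > t_en6:
        raise ValueError("EN1/EN6 split must postdate the EN recovery")
    pops = [Population("TR", float(free["N_TR"])),
            Population("CH", unp["N_CH"]), Population("EN1", unp["N_EN1"]),
            Population("EN6", unp["N_EN6"])]
    events = [
        Split(t_en6, "EN6", "EN1"),
        SizeChange(t_en_rec, "EN1", unp["N_EN_BOT"]),
        SizeChange(t_en_con, "EN1", unp["N_EN_PRE"]),
        Split(t_ch, "EN1", "CH", ancestral_size=unp["N_ANC_CH_EN"]),
        Split(t_tr, "CH", "TR", ancestral_size=float(free["N_ANC"])),
    ]
    return DemographicModel(populations=pops, events=events,
                            generation_time_years=g)


def model5_truth_generations() -> dict[str, float]:
    """Published point values of the free parameters, times in generations."""
    g = GENERATION_TIME_YEARS
    pub = MODEL5_PUBLISHED
    return {
        "T_TR_EU_SPLIT": pub["T_TR_EU_SPLIT_Y"] / g,
        "T_CH_EN_SPLIT": pub["T_CH_EN_SPLIT_Y"] / g,
        "T_EN1_EN6_SPLIT": pub["T_EN1_EN6_SPLIT_Y"] / g,
        "N_TR": pub["N_TR"],
        "N_ANC": pub["N_ANC"],
    }


def model5_recovery_experiment(seed: int, n_snps: int = 10_000,
                               haploids_per_pop: int = 8,
                               n_runs: int = 12, n_cycles: int = 12,
                               sims_per_eval: int = 3000,
                               obs_sim_reps: int = 50_000) -> dict:
    """Simulate-then-refit experiment on the best-supported history.

    A joint SFS of roughly ``n_snps`` polymorphic sites is simulated under
    the published parameter values; the five printed parameters (three
    split times, the TR and root ancestral sizes) are then re-estimated
    from scratch by the multi-run coordinate-search fitter with the Poisson
    composite likelihood (the mutation rate and implied sequence length
    anchor the absolute scale, as in the source protocol where both are
    fixed externally). Returns the fit and the recovered values with times
    converted to years at 2 years per generation.
    """
    template = next(t for t in encode_published_models() if t.name == "model5")
    truth = model5_truth_generations()
    model = template.build(truth)
    config = SampleConfig(n_per_pop={p: haploids_per_pop
                                     for p in model.pop_names})
    rng = np.random.default_rng(seed)
    obs, L = simulate_observed_sfs(model, config, n_snps,
                                   seed=int(rng.integers(2**31 - 1)),
                                   n_reps=obs_sim_reps)
    fit = fit_model(template, obs, config, n_runs=n_runs, n_cycles=n_cycles,
                    sims_per_eval=sims_per_eval,
                    seed=int(rng.integers(2**31 - 1)),
                    likelihood="poisson", mu=model.mutation_rate, L=L)
    g = GENERATION_TIME_YEARS
    recovered = {
        "tr_eu_split_years": fit.params["T_TR_EU_SPLIT"] * g,
        "ch_en_split_years": fit.params["T_CH_EN_SPLIT"] * g,
        "en1_en6_split_years": fit.params["T_EN1_EN6_SPLIT"] * g,
        "ne_tr": fit.params["N_TR"],
        "ne_ancestral": fit.params["N_ANC"],
    }
    return {"fit": fit, "recovered": recovered, "template": template,
            "config": config, "obs": obs, "L": L, "mu": model.mutation_rate,
            "n_snps_observed": obs.S}


def encode_published_models() -> list[ModelTemplate]:
    """The four-population model family: the best-supported history (three
    nested splits with bottleneck/recovery pairs on the CH and EN lineages
    and a recent EN6 contraction) plus two simplified stand-in alternates.
    """
    params = [
        FreeParameter("T_TR_EU_SPLIT", 2_000.0, 400_000.0, "time"),
        FreeParameter("T_CH_EN_SPLIT", 1_000.0, 300_000.0, "time"),
        FreeParameter("T_EN1_EN6_SPLIT", 100.0, 100_000.0, "time"),
        FreeParameter("N_TR", 1_000.0, 1_000_000.0, "size"),
        FreeParameter("N_ANC", 500.0, 500_000.0, "size"),
    ]
    return [
        ModelTemplate("model5", list(params), _model5_builder,
                      "splits TR/(CH/(EN1/EN6)) with CH and EN bottleneck-"
                      "recovery pairs and a recent EN6 contraction"),
        ModelTemplate("no_bottleneck", list(params), _no_bottleneck_builder,
                      "same split topology, no size changes (stand-in)"),
        ModelTemplate("single_bottleneck", list(params),
                      _single_bottleneck_builder,
                      "same split topology, EN bottleneck only (stand-in)"),
    ]
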