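"""Genomic TE content from normalized sequencing depth.

Per-individual mean read depth over each TE superfamily's consensus,
divided by that individual's genome-wide depth, proxies the genomic copy
number of the superfamily. Population and superfamily effects are tested
with a Gaussian interaction linear model (depth ~ population * superfamily,
treatment coding with a chosen reference population) and with pairwise
rank-sum tests against the reference, Bonferroni-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .popgen_stats import bonferroni, wilcoxon_ranksum

logger = logging.getLogger(__name__)

__all__ = ["TE_SUPERFAMILIES", "read_te_table", "normalize_depth",
           "coverage_filter", "population_means", "interaction_lm",
           "pairwise_wilcoxon_bonferroni", "LinearModelFit"]

TE_SUPERFAMILIES = ("CACTA", "hAT", "Helitron", "Mutator", "PIF-Harbinger",
                    "Tc1-Mariner", "LTR/Copia", "LTR/Gypsy")

REQUIRED_COLUMNS = ("individual", "population", "superfamily", "te_depth",
                    "genome_depth", "coverage")


def read_te_table(path: str) -> pd.DataFrame:
    """Read a TE depth TSV with columns individual, population, superfamily,
    te_depth, genome_depth, coverage."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TE table missing columns: {missing}")
    return df


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"TE table missing columns: {missing}")
    if (table.te_depth < 0).any():
        raise ValueError("negative TE depth")
    if ((table.coverage < 0) | (table.coverage > 1)).any():
        raise ValueError("coverage outside [0, 1]")


def normalize_depth(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``norm_depth`` = te_depth / genome_depth per row."""
    _validate(table)
    bad = table.loc[table.genome_depth <= 0, "individual"].unique()
    if len(bad):
        raise ValueError(
            f"zero genome-wide depth for individuals: {', '.join(map(str, bad))}")
    out = table.copy()
    out["norm_depth"] = out.te_depth / out.genome_depth
    return out


def coverage_filter(table: pd.DataFrame, min_cov: float = 0.80
                    ) -> pd.DataFrame:
    """Keep superfamilies whose mean consensus coverage across individuals
    is at least ``min_cov``; exclusions are logged."""
    _validate(table)
    mean_cov = table.groupby("superfamily").coverage.mean()
    kept = mean_cov[mean_cov >= min_cov].index
    dropped = sorted(set(mean_cov.index) - set(kept))
    if dropped:
        logger.info("coverage filter (< %.0f%%) excluded superfamilies: %s",
                    100 * min_cov, ", ".join(dropped))
    return table[table.superfamily.isin(kept)].copy()


def population_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean normalized depth per (population, superfamily)."""
    if "norm_depth" not in table.columns:
        table = normalize_depth(table)
    return table.pivot_table(index="population", columns="superfamily",
                             values="norm_depth", aggfunc="mean")


@dataclass
class LinearModelFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fitted: np.ndarray
    reference_population: str
    reference_superfamily: str
    model: object  # statsmodels results, for diagnostics

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse,
                             "t": self.tvalues, "p": self.pvalues})


def interaction_lm(table: pd.DataFrame, intercept_population: str,
                   intercept_superfamily: str | None = None
                   ) -> LinearModelFit:
    """Gaussian interaction model norm_depth ~ population * superfamily.

    Ordinary least squares with treatment coding; ``intercept_population``
    sets the reference level (releveling changes coefficients, never fitted
    values).
    """
    if "norm_depth" not in table.columns:
        table = normalize_depth(table)
    pops = table.population.unique()
    sfs = table.superfamily.unique()
    if len(pops) < 2 or len(sfs) < 2:
        raise ValueError("need >= 2 populations and >= 2 superfamilies")
    if intercept_population not in pops:
        raise ValueError(f"unknown reference population {intercept_population!r}")
    ref_sf = intercept_superfamily or sorted(sfs)[0]
    formula = (f"norm_depth ~ C(population, Treatment('{intercept_population}'))"
               f" * C(superfamily, Treatment('{ref_sf}'))")
    res = smf.ols(formula, data=table).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        aliased = [name for name, ok in zip(res.model.exog_names,
                                            np.isfinite(res.bse))
                   if not ok]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")

    def _clean(name: str) -> str:
        return (name
                .replace(f"C(population, Treatment('{intercept_population}'))[T.", "pop[")
                .replace(f"C(superfamily, Treatment('{ref_sf}'))[T.", "sf["))

    rename = {n: _clean(n) for n in res.params.index}
    return LinearModelFit(
        params=res.params.rename(rename), bse=res.bse.rename(rename),
        tvalues=res.tvalues.rename(rename), pvalues=res.pvalues.rename(rename),
        fitted=np.asarray(res.fittedvalues),
        reference_population=intercept_population,
        reference_superfamily=ref_sf, model=res)


def pairwise_wilcoxon_bonferroni(table: pd.DataFrame,
                                 reference_population: str,
                                 alpha: float = 0.05) -> pd.DataFrame:
    """Per superfamily, rank-sum test of each population against the
    reference, Bonferroni-corrected over the populations compared."""
    if "norm_depth" not in table.columns:
        table = normalize_depth(table)
    rows = []
    for sf, sub in table.groupby("superfamily"):
        ref = sub.loc[sub.population == reference_population, "norm_depth"]
        others = [p for p in sub.population.unique()
                  if p != reference_population]
        raw = []
        for pop in others:
            vals = sub.loc[sub.population == pop, "norm_depth"]
            if len(vals) < 2 or len(ref) < 2:
                logger.warning("skipping %s vs %s for %s: group too small",
                               pop, reference_population, sf)
                raw.append((pop, np.nan, np.nan))
                continue
            W, p = wilcoxon_ranksum(vals, ref)
            raw.append((pop, W, p))
        n_tests = sum(1 for _, _, p in raw if np.isfinite(p))
        logger.info("%s: Bonferroni over %d comparisons", sf, n_tests)
        ps = np.array([p for _, _, p in raw])
        adj = np.where(np.isfinite(ps), np.minimum(ps * max(n_tests, 1), 1.0),
                       np.nan)
        for (pop, W, p), pa in zip(raw, adj):
            rows.append({"superfamily": sf, "population": pop,
                         "reference": reference_population, "W": W,
                         "p_raw": p, "p_bonferroni": pa,
                         "significant": bool(pa < alpha)
                         if np.isfinite(pa) else False})
    return pd.DataFrame(rows)
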