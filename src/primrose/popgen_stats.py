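"""Windowed diversity statistics, LD, PCA, and rank-based tests.

Diversity estimators (Watterson's theta, pi, Tajima's D) are computed per
window of accessible sites with the accessible-site count — not the raw
window width — as the denominator, so missing-data regions do not deflate
per-site estimates. LD is measured as the squared Pearson correlation of
unphased diploid dosages (composite r^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .io_preprocess import AccessibilityMask, GenotypeMatrix
from .sfs_tools import SFS1D

logger = logging.getLogger(__name__)

__all__ = [
    "WindowStats", "LDDecayCurve", "watterson_theta",
    "nucleotide_diversity", "pi_from_sfs", "tajimas_d", "windowed_stats",
    "pinps_ratio", "ld_r2", "ld_decay_curve", "ld_prune", "genotype_pca",
    "spearman", "kruskal_wallis", "wilcoxon_ranksum", "bonferroni",
]


@dataclass
class WindowStats:
    chrom: str
    start: int            # 0-based, inclusive
    end: int              # exclusive
    n_accessible: int
    S: int
    theta_w: float
    pi: float
    tajima_d: float | None


@dataclass
class LDDecayCurve:
    bin_edges: np.ndarray     # distance bin edges in bp
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def harmonic(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else 0.0


def watterson_theta(S: float, n: int, L_accessible: float) -> float:
    """Watterson's theta per site: S / (a_{n-1} * L)."""
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    if L_accessible <= 0:
        raise ValueError("accessible length must be positive")
    if S == 0:
        return 0.0
    return S / (harmonic(n - 1) * L_accessible)


def _site_pi_terms(calls: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference 2c(n-c)/(n(n-1)) over called
    haplotypes; sites with fewer than 2 called haplotypes contribute 0."""
    called = 2 * (calls >= 0).sum(axis=0)
    c = np.where(calls >= 0, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(called >= 2,
                         2.0 * c * (called - c) / (called * (called - 1.0)),
                         0.0)
    return terms


def nucleotide_diversity(matrix: GenotypeMatrix,
                         L_accessible: float | None = None) -> float:
    """Pairwise nucleotide diversity per site, divided by the accessible
    length (defaults to the number of sites in the matrix, i.e. an
    all-variant window)."""
    L = float(L_accessible) if L_accessible is not None else matrix.n_sites
    if L <= 0:
        raise ValueError("accessible length must be positive")
    return float(_site_pi_terms(matrix.calls).sum() / L)


def pi_from_sfs(sfs: SFS1D) -> float:
    """Total pairwise diversity (not per site) implied by an unfolded SFS."""
    n = sfs.n
    i = np.arange(1, n)
    return float(np.sum(sfs.xi * 2.0 * i * (n - i) / (n * (n - 1.0))))


def tajimas_d(sfs: SFS1D) -> float:
    """Tajima's D from an unfolded spectrum with the standard constants."""
    n = sfs.n
    S = sfs.S
    if S <= 0:
        raise ValueError("Tajima's D undefined for S = 0")
    a1 = harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        raise ValueError("variance term non-positive; D undefined")
    return float((pi_from_sfs(sfs) - S / a1) / np.sqrt(var))


def _tajimas_d_from_window(calls: np.ndarray) -> float | None:
    """D for a window of dosage calls without missing-data projection
    (sites used with their own call counts for pi; constants use the modal
    call count)."""
    called = 2 * (calls >= 0).sum(axis=0)
    usable = called >= 4
    if not usable.any():
        return None
    calls = calls[:, usable]
    called = called[usable]
    n = int(np.bincount(called).argmax())
    full = called == n
    if full.sum() < 1:
        return None
    c = np.where(calls[:, full] >= 0, calls[:, full], 0).sum(axis=0)
    poly = (c > 0) & (c < n)
    if poly.sum() == 0:
        return None
    xi = np.bincount(c[poly], minlength=n)[1:n].astype(float)
    return tajimas_d(SFS1D(n=n, xi=xi))


def windowed_stats(matrix: GenotypeMatrix, mask: AccessibilityMask,
                   window_size: int = 50_000,
                   site_class_positions: dict[str, np.ndarray] | None = None,
                   mode: str = "accessible-sites") -> list[WindowStats]:
    """Non-overlapping windows of ``window_size`` accessible sites.

    ``mode="accessible-sites"`` tiles each chromosome so every window holds
    exactly ``window_size`` accessible positions (final partial window
    kept); ``mode="bp"`` tiles by raw coordinates instead.
    ``site_class_positions`` optionally restricts the analysis (both the
    variants and the accessible-site denominator) to given positions per
    chromosome, e.g. 4-fold degenerate sites.
    """
    out: list[WindowStats] = []
    n_hap_full = 2 * matrix.n_samples
    for chrom in dict.fromkeys(matrix.chrom.tolist()):
        acc = mask[chrom].copy()
        if site_class_positions is not None:
            restrict = np.zeros(len(acc), dtype=bool)
            restrict[site_class_positions[chrom]] = True
            acc &= restrict
        on_chrom = matrix.chrom == chrom
        pos = matrix.pos[on_chrom]
        calls = matrix.calls[:, on_chrom]
        in_class = acc[pos]
        pos, calls = pos[in_class], calls[:, in_class]

        if mode == "accessible-sites":
            cum = np.cumsum(acc)
            total = int(cum[-1]) if len(cum) else 0
            if total == 0:
                logger.info("window skipped: %s has no accessible sites", chrom)
                continue
            n_win = int(np.ceil(total / window_size))
            bounds = [0]
            for w in range(1, n_win):
                bounds.append(int(np.searchsorted(cum, w * window_size) + 1))
            bounds.append(len(acc))
        elif mode == "bp":
            bounds = list(range(0, len(acc), window_size)) + [len(acc)]
        else:
            raise ValueError(f"unknown mode {mode!r}")

        for start, end in zip(bounds[:-1], bounds[1:]):
            n_acc = int(acc[start:end].sum())
            if n_acc == 0:
                logger.info("window %s:[%d,%d) skipped: no accessible sites",
                            chrom, start, end)
                continue
            in_win = (pos >= start) & (pos < end)
            wcalls = calls[:, in_win]
            terms = _site_pi_terms(wcalls)
            c = np.where(wcalls >= 0, wcalls, 0).sum(axis=0)
            an = 2 * (wcalls >= 0).sum(axis=0)
            poly = (c > 0) & (c < an) & (an >= 2)
            S = int(poly.sum())
            theta = watterson_theta(S, n_hap_full, n_acc) if S else 0.0
            pi = float(terms.sum() / n_acc)
            d = _tajimas_d_from_window(wcalls[:, poly]) if S else None
            out.append(WindowStats(chrom=chrom, start=start, end=end,
                                   n_accessible=n_acc, S=S, theta_w=theta,
                                   pi=pi, tajima_d=d))
    return out


def pinps_ratio(pi_0fold: float, pi_4fold: float) -> float:
    """Ratio of nonsynonymous to synonymous diversity (pi_N / pi_S)."""
    if pi_4fold <= 0:
        raise ValueError("pi at synonymous sites is zero; ratio undefined")
    return pi_0fold / pi_4fold


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Composite genotype r^2: squared Pearson correlation of diploid
    dosages over individuals called at both sites."""
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    ok = (a >= 0) & (b >= 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 individuals called at both sites")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance at a site; r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_r2_matrix(calls: np.ndarray) -> np.ndarray:
    """r^2 between all columns, treating missing as the site mean."""
    X = calls.astype(float)
    X[calls < 0] = np.nan
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xn = X / sd
    corr = (Xn.T @ Xn) / X.shape[0]
    return corr**2


def ld_decay_curve(matrix: GenotypeMatrix, max_dist: int = 100_000,
                   bin_width: int = 5_000,
                   maf_min: float | None = None) -> LDDecayCurve:
    """Mean r^2 by physical distance over intra-chromosomal site pairs.

    ``maf_min`` defaults to 1.5/(2n) so that singleton sites are excluded,
    matching the per-population rule of tuning the minor-allele cutoff to
    the sample size.
    """
    n_ind = matrix.n_samples
    if maf_min is None:
        maf_min = 1.5 / (2 * n_ind)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    ac = matrix.alt_counts()
    an = matrix.called_haplotypes()
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(an > 0, ac / an, 0.0)
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_min
    for chrom in dict.fromkeys(matrix.chrom.tolist()):
        idx = np.flatnonzero((matrix.chrom == chrom) & keep)
        if len(idx) < 2:
            continue
        pos = matrix.pos[idx]
        calls = matrix.calls[:, idx]
        r2 = _pairwise_r2_matrix(calls)
        for i in range(len(idx) - 1):
            d = pos[i + 1:] - pos[i]
            within = d <= max_dist
            if not within.any():
                continue
            b = np.minimum((d[within] // bin_width), len(sums) - 1)
            vals = r2[i, i + 1:][within]
            good = np.isfinite(vals)
            np.add.at(sums, b[good], vals[good])
            np.add.at(counts, b[good], 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(bin_edges=edges, mean_r2=mean, n_pairs=counts)


def ld_prune(matrix: GenotypeMatrix, window_bp: int = 50_000,
             step_bp: int = 10_000, r2_max: float = 0.1) -> np.ndarray:
    """Greedy LD pruning; returns indices of retained sites.

    Sites are scanned left to right in sliding windows of ``window_bp``
    advanced by ``step_bp``; within a window, the later site of any pair
    with r^2 > ``r2_max`` is removed. Deterministic.
    """
    keep = np.ones(matrix.n_sites, dtype=bool)
    for chrom in dict.fromkeys(matrix.chrom.tolist()):
        idx = np.flatnonzero(matrix.chrom == chrom)
        pos = matrix.pos[idx]
        start = int(pos.min()) if len(pos) else 0
        stop = int(pos.max()) if len(pos) else 0
        w = start
        while w <= stop:
            in_win = idx[(pos >= w) & (pos < w + window_bp)]
            live = [j for j in in_win if keep[j]]
            for a_i in range(len(live)):
                ja = live[a_i]
                if not keep[ja]:
                    continue
                for jb in live[a_i + 1:]:
                    if not keep[jb]:
                        continue
                    try:
                        r2 = ld_r2(matrix.calls[:, ja], matrix.calls[:, jb])
                    except ValueError:
                        continue
                    if r2 > r2_max:
                        keep[jb] = False
            w += step_bp
    return np.flatnonzero(keep)


def genotype_pca(matrix: GenotypeMatrix, n_components: int = 10,
                 scale: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the dosage matrix (individuals x sites).

    Missing dosages are mean-imputed per site; columns are centered and
    optionally variance-scaled. Returns (coordinates, variance fractions).
    """
    X = matrix.calls.astype(float)
    X[matrix.calls < 0] = np.nan
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    X -= X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X /= sd
    rank = min(X.shape) - 1 if min(X.shape) > 1 else 1
    if n_components > rank:
        import warnings
        warnings.warn(f"requested {n_components} components, rank allows "
                      f"{rank}; truncating")
        n_components = rank
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# rank-based tests
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector; Spearman undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Iterable[Sequence[float]]
                   ) -> tuple[float, int, float]:
    """Kruskal-Wallis H (tie-corrected) with chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    stat, p = sps.kruskal(*groups)
    return float(stat), len(groups) - 1, float(p)


def wilcoxon_ranksum(a: Sequence[float], b: Sequence[float]
                     ) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) with normal approximation and
    continuity correction."""
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment: multiply by the number of tests, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * len(p), 1.0)
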