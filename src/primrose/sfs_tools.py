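"""Site-frequency spectra: construction, folding, projection, serialization.

Spectra are polarized by matching alleles against an assigned ancestral
state (here, following the reference-allele convention: alleles matching
the reference are ancestral). 1D spectra support hypergeometric projection
down to a smaller sample size, which is how sites with missing genotypes
contribute without being discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .io_preprocess import GenotypeMatrix, MISSING

__all__ = ["SFS1D", "JointSFS", "unfolded_sfs", "fold_sfs", "project_sfs",
           "joint_sfs", "read_sfs", "write_sfs"]


class EmptySFSError(ValueError):
    pass


@dataclass
class SFS1D:
    """1D frequency spectrum of derived (unfolded) or minor (folded) alleles.

    ``xi`` has length n-1 for an unfolded spectrum (xi_1..xi_{n-1}) and
    floor(n/2) for a folded one. Entries may be fractional after projection.
    """

    n: int
    xi: np.ndarray
    folded: bool = False
    monomorphic0: float | None = None
    monomorphicN: float | None = None
    n_excluded: int = 0      # sites whose alleles matched no ancestral state

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        expected = self.n // 2 if self.folded else self.n - 1
        if len(self.xi) != expected:
            raise ValueError(
                f"spectrum length {len(self.xi)} does not match n={self.n} "
                f"({'folded' if self.folded else 'unfolded'})")
        if (self.xi < -1e-9).any():
            raise ValueError("negative SFS entry")

    @property
    def S(self) -> float:
        """Number of polymorphic sites (sum of spectrum entries)."""
        return float(self.xi.sum())


@dataclass
class JointSFS:
    """Multidimensional SFS across populations.

    ``cells`` has shape ``(n_1+1, ..., n_k+1)``; the all-zero and all-n
    corner cells hold monomorphic sites and are excluded from the
    polymorphic mass.
    """

    cells: np.ndarray
    pops: list[str]

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.ndim != len(self.pops):
            raise ValueError("cells dimensionality != number of populations")

    @property
    def dims(self) -> tuple[int, ...]:
        return self.cells.shape

    @property
    def sample_sizes(self) -> tuple[int, ...]:
        return tuple(d - 1 for d in self.cells.shape)

    def polymorphic_mask(self) -> np.ndarray:
        mask = np.ones(self.cells.shape, dtype=bool)
        mask[tuple(0 for _ in self.cells.shape)] = False
        mask[tuple(d - 1 for d in self.cells.shape)] = False
        return mask

    @property
    def S(self) -> float:
        return float(self.cells[self.polymorphic_mask()].sum())

    def normalized(self) -> "JointSFS":
        mask = self.polymorphic_mask()
        out = np.where(mask, self.cells, 0.0)
        total = out.sum()
        if total <= 0:
            raise EmptySFSError("no polymorphic mass in joint SFS")
        return JointSFS(cells=out / total, pops=list(self.pops))

    def marginal(self, pop: str) -> SFS1D:
        """Marginal 1D spectrum of one population (polymorphic cells only)."""
        axis = self.pops.index(pop)
        other = tuple(i for i in range(self.cells.ndim) if i != axis)
        marg = np.where(self.polymorphic_mask(), self.cells, 0.0).sum(axis=other)
        n = self.cells.shape[axis] - 1
        return SFS1D(n=n, xi=marg[1:n], monomorphic0=float(marg[0]),
                     monomorphicN=float(marg[n]))


def _polarize(matrix: GenotypeMatrix, ancestral: Sequence[str] | str
              ) -> tuple[np.ndarray, np.ndarray]:
    """Derived-dosage calls and a keep-mask given ancestral alleles.

    ``ancestral`` is either the string ``"ref"`` (reference allele is
    ancestral everywhere) or one allele per site. Sites where the ancestral
    allele matches neither ref nor alt are dropped (mask False).
    """
    calls = matrix.calls
    if isinstance(ancestral, str) and ancestral == "ref":
        return calls, np.ones(matrix.n_sites, dtype=bool)
    anc = np.asarray(ancestral, dtype=object)
    if len(anc) != matrix.n_sites:
        raise ValueError("ancestral allele list length mismatch")
    is_ref = anc == matrix.ref
    is_alt = anc == matrix.alt
    keep = is_ref | is_alt
    flipped = np.where(calls >= 0, 2 - calls, MISSING).astype(np.int8)
    out = np.where(is_alt[None, :], flipped, calls).astype(np.int8)
    return out, keep


def unfolded_sfs(matrix: GenotypeMatrix,
                 ancestral: Sequence[str] | str = "ref",
                 n_project: int | None = None) -> SFS1D:
    """Build the unfolded SFS, projecting sites with missing calls.

    Sites with all genotypes called contribute unit counts; a site with
    ``nc < n`` called haplotypes contributes its expected spectrum under
    hypergeometric subsampling at ``n_project`` (which must be <= the
    smallest per-site call count among retained sites; default: that
    minimum, or the full 2 x individuals when there is no missing data).
    """
    calls, keep = _polarize(matrix, ancestral)
    n_excluded = int((~keep).sum())
    calls = calls[:, keep]
    n_full = 2 * matrix.n_samples
    called = 2 * (calls >= 0).sum(axis=0)
    derived = np.where(calls >= 0, calls, 0).sum(axis=0)
    usable = called >= 2
    called, derived = called[usable], derived[usable]
    if called.size == 0:
        raise EmptySFSError("no usable sites for the SFS")
    m = int(n_project) if n_project is not None else int(called.min())
    if m < 2 or m > n_full:
        raise ValueError(f"projection size {m} out of range")
    if (called < m).any():
        raise ValueError(
            f"{int((called < m).sum())} sites have fewer than {m} called "
            "haplotypes; lower n_project")
    xi = np.zeros(m - 1)
    mono0 = monoN = 0.0
    exact = called == m
    for c in derived[exact]:
        if c == 0:
            mono0 += 1
        elif c == m:
            monoN += 1
        else:
            xi[c - 1] += 1
    for nc, c in zip(called[~exact], derived[~exact]):
        j = np.arange(0, m + 1)
        p = hypergeom.pmf(j, nc, c, m)
        mono0 += p[0]
        monoN += p[m]
        xi += p[1:m]
    return SFS1D(n=m, xi=xi, monomorphic0=mono0, monomorphicN=monoN,
                 n_excluded=n_excluded)


def fold_sfs(sfs: SFS1D) -> SFS1D:
    """Fold an unfolded spectrum to minor-allele counts."""
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    n = sfs.n
    eta = np.zeros(n // 2)
    for i in range(1, n):
        j = min(i, n - i)
        if i == n - i:
            eta[j - 1] += sfs.xi[i - 1]
        elif i < n - i:
            eta[j - 1] += sfs.xi[i - 1] + sfs.xi[n - i - 1]
    return SFS1D(n=n, xi=eta, folded=True,
                 monomorphic0=sfs.monomorphic0, monomorphicN=sfs.monomorphicN,
                 n_excluded=sfs.n_excluded)


def project_sfs(sfs: SFS1D, m: int) -> SFS1D:
    """Project an unfolded spectrum to sample size ``m`` by hypergeometric
    expectation. Mass landing in the monomorphic cells is recorded there;
    total polymorphic mass never increases."""
    if sfs.folded:
        raise ValueError("projection requires an unfolded spectrum")
    if m > sfs.n:
        raise ValueError(f"cannot project n={sfs.n} up to m={m}")
    if m < 2:
        raise ValueError("m must be >= 2")
    if m == sfs.n:
        return SFS1D(n=m, xi=sfs.xi.copy(), monomorphic0=sfs.monomorphic0,
                     monomorphicN=sfs.monomorphicN, n_excluded=sfs.n_excluded)
    xi = np.zeros(m - 1)
    mono0 = sfs.monomorphic0 or 0.0
    monoN = sfs.monomorphicN or 0.0
    j = np.arange(0, m + 1)
    for i in range(1, sfs.n):
        if sfs.xi[i - 1] == 0:
            continue
        p = hypergeom.pmf(j, sfs.n, i, m)
        mono0 += sfs.xi[i - 1] * p[0]
        monoN += sfs.xi[i - 1] * p[m]
        xi += sfs.xi[i - 1] * p[1:m]
    return SFS1D(n=m, xi=xi, monomorphic0=mono0, monomorphicN=monoN,
                 n_excluded=sfs.n_excluded)


def joint_sfs(matrix: GenotypeMatrix, populations: Mapping[str, Sequence[str]]
              | None = None, ancestral: Sequence[str] | str = "ref",
              ) -> tuple["JointSFS", int]:
    """Build a multidimensional SFS across populations.

    Only sites genotyped in every individual are used (strict no-missing
    rule); the number of rejected sites is returned alongside the spectrum.

    ``populations`` maps population name -> sample ids; defaults to the
    matrix's own population labels.
    """
    if populations is None:
        if matrix.populations is None:
            raise ValueError("no population labels available")
        populations = {}
        for s, p in zip(matrix.samples, matrix.populations):
            populations.setdefault(p, []).append(s)
    pops = list(populations)
    sample_idx = {s: i for i, s in enumerate(matrix.samples)}
    groups = [np.array([sample_idx[s] for s in populations[p]]) for p in pops]
    calls, keep = _polarize(matrix, ancestral)
    all_idx = np.concatenate(groups)
    complete = (calls[all_idx, :] >= 0).all(axis=0) & keep
    n_rejected = int(matrix.n_sites - complete.sum())
    dims = tuple(2 * len(g) + 1 for g in groups)
    cells = np.zeros(dims)
    sub = calls[:, complete]
    counts = np.stack([np.where(sub[g, :] >= 0, sub[g, :], 0).sum(axis=0)
                       for g in groups])
    for s in range(counts.shape[1]):
        cells[tuple(counts[:, s])] += 1
    return JointSFS(cells=cells, pops=pops), n_rejected


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_sfs(sfs: SFS1D | JointSFS, path: str, dialect: str = "dadi") -> None:
    """Write a spectrum in one of three text dialects.

    ``dadi``: header ``d_1 ... d_k [un]folded`` then the row-major flattened
    array including monomorphic corners.
    ``multisfs``: header comment with populations and dims, then the
    row-major flattened counts on one line (first-listed population varying
    slowest).
    ``tsv``: one ``index<TAB>count`` row per cell (1D only).
    """
    if dialect == "dadi":
        if isinstance(sfs, SFS1D):
            if sfs.folded:
                raise ValueError("dadi dialect here stores unfolded spectra")
            arr = np.concatenate([[sfs.monomorphic0 or 0.0], sfs.xi,
                                  [sfs.monomorphicN or 0.0]])
            header = f"{sfs.n + 1} unfolded"
        else:
            arr = sfs.cells.ravel(order="C")
            header = " ".join(str(d) for d in sfs.dims) + " unfolded"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            fh.write(" ".join(f"{x:.10g}" for x in arr) + "\n")
    elif dialect == "multisfs":
        if isinstance(sfs, SFS1D):
            raise ValueError("multisfs dialect is for joint spectra")
        with open(path, "w") as fh:
            fh.write("# multiSFS pops=" + ",".join(sfs.pops)
                     + " dims=" + ",".join(str(d) for d in sfs.dims)
                     + " order=row-major,first-pop-slowest\n")
            fh.write(" ".join(f"{x:.10g}"
                              for x in sfs.cells.ravel(order="C")) + "\n")
    elif dialect == "tsv":
        if not isinstance(sfs, SFS1D):
            raise ValueError("tsv dialect is for 1D spectra")
        with open(path, "w") as fh:
            fh.write("derived_count\tn_sites\n")
            for i, x in enumerate(sfs.xi, start=1):
                fh.write(f"{i}\t{x:.10g}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_sfs(path: str, dialect: str = "dadi") -> SFS1D | JointSFS:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if dialect == "dadi":
        header = lines[0].split()
        dims = [int(x) for x in header if x.isdigit()]
        vals = np.array([float(x) for x in lines[1].split()])
        if len(vals) != int(np.prod(dims)):
            raise ValueError(
                f"dadi SFS body has {len(vals)} entries, header implies "
                f"{int(np.prod(dims))}")
        if len(dims) == 1:
            n = dims[0] - 1
            return SFS1D(n=n, xi=vals[1:n], monomorphic0=float(vals[0]),
                         monomorphicN=float(vals[n]))
        return JointSFS(cells=vals.reshape(dims),
                        pops=[f"pop{i}" for i in range(len(dims))])
    if dialect == "multisfs":
        header = lines[0]
        meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split()
                    if "=" in tok)
        pops = meta["pops"].split(",")
        dims = [int(d) for d in meta["dims"].split(",")]
        vals = np.array([float(x) for x in lines[1].split()])
        if len(vals) != int(np.prod(dims)):
            raise ValueError("multiSFS body length does not match dims")
        return JointSFS(cells=vals.reshape(dims), pops=pops)
    if dialect == "tsv":
        import pandas as pd
        df = pd.read_csv(path, sep="\t")
        n = int(df.derived_count.max()) + 1
        xi = np.zeros(n - 1)
        xi[df.derived_count.to_numpy() - 1] = df.n_sites.to_numpy()
        return SFS1D(n=n, xi=xi)
    raise ValueError(f"unknown dialect {dialect!r}")
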