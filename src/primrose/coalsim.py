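"""Structured-coalescent simulator with split and size-change events.

The simulator works backward in time in units of generations. Within a deme
of diploid effective size N, each pair of lineages coalesces at rate
1/(2N) per generation. A SPLIT event (backward in time) merges all lineages
of a derived deme into its ancestral deme, optionally resetting the
ancestral deme's size; a SIZE_CHANGE event instantaneously changes one
deme's size. Mutations are dropped under the infinite-sites model.

Two engines share the same event semantics:

* a pure-Python engine producing full genealogies (branch leaf-sets), used
  for data generation;
* a numba kernel that accumulates branch lengths directly into joint-SFS
  cells over many replicates, used for likelihood evaluation where only the
  expected spectrum is needed.

For a single population with piecewise-constant size the expected spectrum
is also available in closed form (:func:`expected_sfs_single_pop`) through
the lineage-count death chain, avoiding Monte Carlo error entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from numba import njit
from scipy.linalg import expm
from scipy.special import gammaln

__all__ = [
    "Population", "Split", "SizeChange", "DemographicModel", "SampleConfig",
    "Genealogy", "years_to_generations", "simulate_genealogy",
    "drop_mutations", "expected_joint_sfs", "expected_sfs_single_pop",
    "haplotypes_to_diploids", "load_model", "save_model",
]


@dataclass
class Population:
    name: str
    size: float  # present-day diploid effective size


@dataclass
class Split:
    """Backward-in-time merge of ``derived`` into ``ancestral`` at ``time``
    generations before present; ``ancestral_size`` (diploid) optionally
    resets the ancestral deme's size from this time on (into the past)."""

    time: float
    derived: str
    ancestral: str
    ancestral_size: float | None = None


@dataclass
class SizeChange:
    """``population`` has diploid size ``size`` from ``time`` generations
    ago further into the past (until the next older event)."""

    time: float
    population: str
    size: float


@dataclass
class DemographicModel:
    populations: list[Population]
    events: list[Split | SizeChange] = field(default_factory=list)
    mutation_rate: float = 1.23e-8          # per site per generation
    generation_time_years: float = 2.0

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time)

    @property
    def pop_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def pop_index(self, name: str) -> int:
        return self.pop_names.index(name)

    def validate(self) -> None:
        names = self.pop_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for p in self.populations:
            if p.size <= 0:
                raise ValueError(f"population {p.name} has non-positive size")
        active = set(names)
        last_t = 0.0
        for ev in self.events:
            if ev.time < 0:
                raise ValueError("event times must be non-negative")
            if ev.time < last_t:
                raise ValueError("events out of order")
            last_t = ev.time
            if isinstance(ev, Split):
                if ev.derived not in active:
                    raise ValueError(
                        f"split at t={ev.time}: deme {ev.derived!r} is not "
                        "active (already merged or unknown)")
                if ev.ancestral not in active:
                    raise ValueError(
                        f"split at t={ev.time}: ancestral deme "
                        f"{ev.ancestral!r} is not active")
                active.remove(ev.derived)
            else:
                if ev.population not in active:
                    raise ValueError(
                        f"size change at t={ev.time}: deme "
                        f"{ev.population!r} is not active")
                if ev.size <= 0:
                    raise ValueError("size change to non-positive size")
        if len(active) != 1:
            raise ValueError(
                f"lineages in demes {sorted(active)} have no route to a "
                "single root; add split events")

    def _event_arrays(self):
        """Events as flat numpy arrays for the simulation kernels."""
        idx = {n: i for i, n in enumerate(self.pop_names)}
        n_ev = len(self.events)
        t = np.zeros(n_ev)
        kind = np.zeros(n_ev, dtype=np.int64)   # 0 split, 1 size change
        a = np.zeros(n_ev, dtype=np.int64)
        b = np.zeros(n_ev, dtype=np.int64)
        size = np.full(n_ev, np.nan)
        for i, ev in enumerate(self.events):
            t[i] = ev.time
            if isinstance(ev, Split):
                kind[i] = 0
                a[i] = idx[ev.derived]
                b[i] = idx[ev.ancestral]
                if ev.ancestral_size is not None:
                    size[i] = ev.ancestral_size
            else:
                kind[i] = 1
                a[i] = idx[ev.population]
                b[i] = -1
                size[i] = ev.size
        return t, kind, a, b, size


@dataclass
class SampleConfig:
    """Haploid sample sizes per population, sequence length, and optional
    per-population inbreeding coefficients used at diploid formation."""

    n_per_pop: Mapping[str, int]
    L: int = 1
    inbreeding: Mapping[str, float] | None = None

    def validate(self, model: DemographicModel) -> None:
        total = 0
        for name, n in self.n_per_pop.items():
            if name not in model.pop_names:
                raise ValueError(f"unknown population {name!r} in sample")
            if n < 0:
                raise ValueError("negative sample size")
            total += n
        if total < 2:
            raise ValueError("need at least 2 sampled haplotypes")
        if self.L < 1:
            raise ValueError("sequence length must be >= 1")
        if self.inbreeding:
            for f in self.inbreeding.values():
                if not 0 <= f <= 1:
                    raise ValueError("inbreeding coefficient outside [0, 1]")


@dataclass
class Genealogy:
    """A coalescent tree stored as branches with leaf bitmasks."""

    branches: list[tuple[int, float]]   # (leaf bitmask, branch length in gen)
    n_leaves: int
    leaf_pops: np.ndarray               # (n_leaves,) population index
    pop_names: list[str]

    @property
    def total_branch_length(self) -> float:
        return sum(length for _, length in self.branches)

    def branch_compositions(self) -> np.ndarray:
        """(n_branches, n_pops) counts of subtended leaves per population."""
        npop = len(self.pop_names)
        pop_masks = []
        for p in range(npop):
            m = 0
            for leaf in np.flatnonzero(self.leaf_pops == p):
                m |= 1 << int(leaf)
            pop_masks.append(m)
        out = np.zeros((len(self.branches), npop), dtype=np.int64)
        for i, (mask, _) in enumerate(self.branches):
            for p in range(npop):
                out[i, p] = (mask & pop_masks[p]).bit_count()
        return out


def years_to_generations(t_years: float, model: DemographicModel) -> float:
    """Convert years before present to generations before present."""
    if t_years < 0:
        raise ValueError("time must be non-negative")
    return t_years / model.generation_time_years


def generations_to_years(t_gen: float, model: DemographicModel) -> float:
    return t_gen * model.generation_time_years


# ---------------------------------------------------------------------------
# pure-Python genealogy engine
# ---------------------------------------------------------------------------

def simulate_genealogy(model: DemographicModel, config: SampleConfig,
                       seed: int | np.random.Generator) -> Genealogy:
    """Simulate one genealogy of the full sample under the model."""
    model.validate()
    config.validate(model)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    names = model.pop_names
    sizes = np.array([p.size for p in model.populations], dtype=float)
    ev_t, ev_kind, ev_a, ev_b, ev_size = model._event_arrays()

    leaf_pops: list[int] = []
    # lineages: parallel lists (mask, deme, birth time)
    masks: list[int] = []
    demes: list[int] = []
    births: list[float] = []
    leaf = 0
    for p, name in enumerate(names):
        for _ in range(int(config.n_per_pop.get(name, 0))):
            masks.append(1 << leaf)
            demes.append(p)
            births.append(0.0)
            leaf_pops.append(p)
            leaf += 1
    n_leaves = leaf

    branches: list[tuple[int, float]] = []
    t = 0.0
    ei = 0
    n_ev = len(ev_t)
    npop = len(names)
    while len(masks) > 1:
        k = np.bincount(demes, minlength=npop)
        rates = k * (k - 1) / (4.0 * sizes)
        total = rates.sum()
        if total > 0:
            dt = rng.exponential(1.0 / total)
        else:
            dt = math.inf
        if ei < n_ev and t + dt >= ev_t[ei]:
            t = ev_t[ei]
            if ev_kind[ei] == 0:
                src, dst = ev_a[ei], ev_b[ei]
                for i in range(len(demes)):
                    if demes[i] == src:
                        demes[i] = dst
                if np.isfinite(ev_size[ei]):
                    sizes[dst] = ev_size[ei]
            else:
                sizes[ev_a[ei]] = ev_size[ei]
            ei += 1
            continue
        if total == 0:
            raise RuntimeError("lineages stranded in isolated demes")
        t += dt
        d = rng.choice(npop, p=rates / total)
        members = [i for i in range(len(demes)) if demes[i] == d]
        i1, i2 = rng.choice(len(members), size=2, replace=False)
        i1, i2 = members[i1], members[i2]
        if i2 < i1:
            i1, i2 = i2, i1
        branches.append((masks[i1], t - births[i1]))
        branches.append((masks[i2], t - births[i2]))
        masks[i1] |= masks[i2]
        births[i1] = t
        del masks[i2], demes[i2], births[i2]
    return Genealogy(branches=branches, n_leaves=n_leaves,
                     leaf_pops=np.array(leaf_pops, dtype=np.int64),
                     pop_names=names)


def drop_mutations(genealogy: Genealogy, mu: float, L: int,
                   seed: int | np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Drop infinite-sites mutations on a genealogy.

    Returns ``(positions, haplotypes)``: sorted unique 0-based positions in
    ``[0, L)`` and a boolean matrix (n_sites, n_leaves) of derived-allele
    carriage. The number of mutations is Poisson with mean
    ``mu * L * total_branch_length``.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    T = genealogy.total_branch_length
    n_mut = rng.poisson(mu * L * T)
    n_mut = min(n_mut, L)  # infinite-sites: unique positions
    if n_mut == 0:
        return (np.zeros(0, dtype=np.int64),
                np.zeros((0, genealogy.n_leaves), dtype=bool))
    lengths = np.array([b[1] for b in genealogy.branches])
    probs = lengths / lengths.sum()
    which = rng.choice(len(lengths), size=n_mut, p=probs)
    positions = rng.choice(L, size=n_mut, replace=False)
    order = np.argsort(positions)
    positions = positions[order]
    which = which[order]
    hap = np.zeros((n_mut, genealogy.n_leaves), dtype=bool)
    for row, bi in enumerate(which):
        mask = genealogy.branches[bi][0]
        for leaf in range(genealogy.n_leaves):
            if mask >> leaf & 1:
                hap[row, leaf] = True
    return positions.astype(np.int64), hap


def haplotypes_to_diploids(hap: np.ndarray, leaf_pops: np.ndarray,
                           pop_names: Sequence[str],
                           inbreeding: Mapping[str, float] | None,
                           rng: np.random.Generator) -> np.ndarray:
    """Pair consecutive haplotypes within each population into diploids.

    With per-population inbreeding coefficient F, each individual's second
    haplotype is replaced by a copy of its first with probability F — a
    pragmatic stand-in for partial selfing. Returns an int8 dosage matrix
    (n_individuals, n_sites).
    """
    inbreeding = inbreeding or {}
    dosage_rows = []
    for p, name in enumerate(pop_names):
        leaves = np.flatnonzero(leaf_pops == p)
        if len(leaves) % 2:
            raise ValueError(f"population {name} has odd haploid sample size")
        F = float(inbreeding.get(name, 0.0))
        for a, b in zip(leaves[::2], leaves[1::2]):
            h1 = hap[:, a]
            h2 = h1 if (F > 0 and rng.random() < F) else hap[:, b]
            dosage_rows.append(h1.astype(np.int8) + h2.astype(np.int8))
    return np.array(dosage_rows, dtype=np.int8)


# ---------------------------------------------------------------------------
# numba kernel: Monte-Carlo expected joint SFS
# ---------------------------------------------------------------------------

@njit(cache=True)
def _expected_sfs_kernel(n_reps, seed, n_per_pop, sizes0,
                         ev_t, ev_kind, ev_a, ev_b, ev_size,
                         strides, W):  # pragma: no cover - compiled
    np.random.seed(seed)
    npop = n_per_pop.shape[0]
    ntot = 0
    for p in range(npop):
        ntot += n_per_pop[p]
    n_ev = ev_t.shape[0]
    comp = np.zeros((ntot, npop), dtype=np.int64)
    deme = np.zeros(ntot, dtype=np.int64)
    birth = np.zeros(ntot)
    k = np.zeros(npop, dtype=np.int64)
    rates = np.zeros(npop)
    for rep in range(n_reps):
        sizes = sizes0.copy()
        cur = 0
        for p in range(npop):
            for _ in range(n_per_pop[p]):
                for q in range(npop):
                    comp[cur, q] = 0
                comp[cur, p] = 1
                deme[cur] = p
                birth[cur] = 0.0
                cur += 1
        t = 0.0
        ei = 0
        while cur > 1:
            for p in range(npop):
                k[p] = 0
            for i in range(cur):
                k[deme[i]] += 1
            total = 0.0
            for p in range(npop):
                rates[p] = k[p] * (k[p] - 1) / (4.0 * sizes[p])
                total += rates[p]
            if total > 0.0:
                dt = np.random.exponential(1.0 / total)
            else:
                dt = 1e300
            if ei < n_ev and t + dt >= ev_t[ei]:
                t = ev_t[ei]
                if ev_kind[ei] == 0:
                    src = ev_a[ei]
                    dst = ev_b[ei]
                    for i in range(cur):
                        if deme[i] == src:
                            deme[i] = dst
                    if not np.isnan(ev_size[ei]):
                        sizes[dst] = ev_size[ei]
                else:
                    sizes[ev_a[ei]] = ev_size[ei]
                ei += 1
                continue
            if total == 0.0:
                break
            t += dt
            u = np.random.random() * total
            d = 0
            acc = rates[0]
            while acc < u and d < npop - 1:
                d += 1
                acc += rates[d]
            # choose an ordered random pair within deme d
            m = k[d]
            r1 = int(np.random.random() * m)
            r2 = int(np.random.random() * (m - 1))
            if r2 >= r1:
                r2 += 1
            i1 = -1
            i2 = -1
            seen = 0
            for i in range(cur):
                if deme[i] == d:
                    if seen == r1:
                        i1 = i
                    if seen == r2:
                        i2 = i
                    seen += 1
            if i2 < i1:
                i1, i2 = i2, i1
            idx1 = 0
            idx2 = 0
            for p in range(npop):
                idx1 += comp[i1, p] * strides[p]
                idx2 += comp[i2, p] * strides[p]
            W[idx1] += t - birth[i1]
            W[idx2] += t - birth[i2]
            for p in range(npop):
                comp[i1, p] += comp[i2, p]
            birth[i1] = t
            # remove i2 by swapping in the last lineage
            last = cur - 1
            if i2 != last:
                for p in range(npop):
                    comp[i2, p] = comp[last, p]
                deme[i2] = deme[last]
                birth[i2] = birth[last]
            cur -= 1


def expected_joint_sfs_weights(model: DemographicModel, config: SampleConfig,
                               n_reps: int, seed: int) -> np.ndarray:
    """Monte-Carlo branch-length weights per joint-SFS cell.

    Returns an array of shape ``(n_1+1, ..., n_k+1)`` whose entry is the
    mean (over replicates) total branch length subtending that derived-count
    configuration, in generations. Multiply by ``mu * L`` for expected
    counts of segregating sites.
    """
    model.validate()
    config.validate(model)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    names = model.pop_names
    n_per_pop = np.array([int(config.n_per_pop.get(n, 0)) for n in names],
                         dtype=np.int64)
    sizes0 = np.array([p.size for p in model.populations], dtype=float)
    ev_t, ev_kind, ev_a, ev_b, ev_size = model._event_arrays()
    dims = n_per_pop + 1
    strides = np.ones(len(dims), dtype=np.int64)
    for p in range(len(dims) - 2, -1, -1):
        strides[p] = strides[p + 1] * dims[p + 1]
    W = np.zeros(int(np.prod(dims)))
    _expected_sfs_kernel(int(n_reps), int(seed) % (2**31 - 1), n_per_pop,
                         sizes0, ev_t, ev_kind, ev_a, ev_b, ev_size,
                         strides, W)
    return (W / n_reps).reshape(tuple(dims))


def expected_joint_sfs(model: DemographicModel, config: SampleConfig,
                       n_reps: int, seed: int):
    """Normalized Monte-Carlo expected joint SFS (probabilities over
    polymorphic cells). Returns a :class:`primrose.sfs_tools.JointSFS`."""
    from .sfs_tools import JointSFS

    W = expected_joint_sfs_weights(model, config, n_reps, seed)
    corner = tuple(0 for _ in W.shape)
    full = tuple(d - 1 for d in W.shape)
    W = W.copy()
    W[corner] = 0.0
    W[full] = 0.0
    total = W.sum()
    if total <= 0:
        raise RuntimeError("no polymorphic branch mass simulated")
    names = model.pop_names
    sampled = [n for n in names if config.n_per_pop.get(n, 0) > 0]
    # squeeze axes of unsampled populations (dimension 1)
    keep_axes = [i for i, n in enumerate(names)
                 if config.n_per_pop.get(n, 0) > 0]
    Wq = np.squeeze(W, axis=tuple(i for i in range(W.ndim)
                                  if i not in keep_axes))
    return JointSFS(cells=Wq / total, pops=sampled)


# ---------------------------------------------------------------------------
# analytic expected SFS for one population, piecewise-constant size
# ---------------------------------------------------------------------------

def expected_sfs_single_pop(epochs: Sequence[tuple[float, float]],
                            n: int) -> np.ndarray:
    """Expected branch length subtending i leaves (i = 1..n-1), in
    generations, for one population with piecewise-constant diploid size.

    ``epochs`` lists (duration_in_generations, N_e) from the present
    backward; the last epoch's duration may be ``inf`` (it is treated as
    open-ended regardless). Multiply by ``mu * L`` for expected site counts
    E[xi_i].

    Uses the lineage-count death chain: within an epoch the number of
    ancestral lineages K(t) falls from k to k-1 at rate k(k-1)/(4N); the
    expected time spent at each level, combined with the standard
    probability that a branch present while K=k subtends i of n sampled
    leaves, gives the expected spectrum without Monte Carlo error.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not epochs:
        raise ValueError("need at least one epoch")
    # states n, n-1, ..., 2 (index 0 .. n-2); absorbing state 1 dropped
    ks = np.arange(n, 1, -1)
    ET = np.zeros(n - 1)  # expected time with K = ks[j]
    v = np.zeros(n - 1)
    v[0] = 1.0  # start with n lineages
    for e, (dur, N) in enumerate(epochs):
        if N <= 0:
            raise ValueError("epoch size must be positive")
        lam = ks * (ks - 1) / (4.0 * N)
        last = (e == len(epochs) - 1) or not np.isfinite(dur)
        if last:
            # death chain visits every remaining level with certainty
            reach = np.cumsum(v)  # P(K at epoch start >= ks[j])
            ET += reach / lam
            break
        m = n - 1
        Q = np.zeros((m, m))
        for j in range(m):
            Q[j, j] = -lam[j]
            if j + 1 < m:
                Q[j, j + 1] = lam[j]
        # integral of v @ expm(Q t) over [0, dur] via the augmented matrix
        A = np.zeros((2 * m, 2 * m))
        A[:m, :m] = Q
        A[:m, m:] = np.eye(m)
        E = expm(A * dur)
        ET += v @ E[:m, m:]
        v = v @ E[:m, :m]
        # mass absorbed at K=1 simply leaves the chain
    # P(a branch while K=k subtends i of n leaves), times k branches
    out = np.zeros(n - 1)
    i_arr = np.arange(1, n)

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    for j, k in enumerate(ks):
        if ET[j] == 0:
            continue
        valid = i_arr <= n - k + 1
        i_v = i_arr[valid]
        logp = (log_comb(n - i_v - 1, k - 2) - log_comb(n - 1, k - 1))
        out[valid] += k * ET[j] * np.exp(logp)
    return out


# ---------------------------------------------------------------------------
# model config serialization
# ---------------------------------------------------------------------------

def load_model(path: str) -> DemographicModel:
    """Load a demographic model from a YAML config.

    The config must carry explicit ``ne_units`` (``diploid`` or ``haploid``)
    and ``time_units`` (``generations`` or ``years``) tags; sizes and times
    are converted to diploid N_e and generations on load.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return model_from_dict(doc)


def model_from_dict(doc: dict) -> DemographicModel:
    ne_units = doc.get("ne_units")
    if ne_units not in ("diploid", "haploid"):
        raise ValueError("model config must set ne_units: diploid|haploid")
    time_units = doc.get("time_units")
    if time_units not in ("generations", "years"):
        raise ValueError("model config must set time_units: generations|years")
    gen_time = float(doc.get("generation_time_years", 2.0))
    ne_scale = 0.5 if ne_units == "haploid" else 1.0
    t_scale = 1.0 / gen_time if time_units == "years" else 1.0
    pops = [Population(p["name"], float(p["size"]) * ne_scale)
            for p in doc["populations"]]
    events: list[Split | SizeChange] = []
    for ev in doc.get("events", []):
        t = float(ev["time"]) * t_scale
        if ev["type"] == "split":
            anc = ev.get("ancestral_size")
            events.append(Split(t, ev["derived"], ev["ancestral"],
                                float(anc) * ne_scale if anc is not None else None))
        elif ev["type"] == "size_change":
            events.append(SizeChange(t, ev["population"],
                                     float(ev["size"]) * ne_scale))
        else:
            raise ValueError(f"unknown event type {ev['type']!r}")
    model = DemographicModel(
        populations=pops, events=events,
        mutation_rate=float(doc.get("mutation_rate", 1.23e-8)),
        generation_time_years=gen_time)
    model.validate()
    return model


def save_model(model: DemographicModel, path: str) -> None:
    doc = {
        "ne_units": "diploid",
        "time_units": "generations",
        "mutation_rate": model.mutation_rate,
        "generation_time_years": model.generation_time_years,
        "populations": [{"name": p.name, "size": float(p.size)}
                        for p in model.populations],
        "events": [],
    }
    for ev in model.events:
        if isinstance(ev, Split):
            d = {"type": "split", "time": float(ev.time),
                 "derived": ev.derived, "ancestral": ev.ancestral}
            if ev.ancestral_size is not None:
                d["ancestral_size"] = float(ev.ancestral_size)
        else:
            d = {"type": "size_change", "time": float(ev.time),
                 "population": ev.population, "size": float(ev.size)}
        doc["events"].append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
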