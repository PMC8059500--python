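"""Two-deme structured-coalescent simulator with piecewise-constant migration.

The engine simulates genealogies backward in time for samples drawn from two
contemporary populations (demes) that merge into a single ancestral
population ``T_split`` generations in the past.  Migration between the two
demes is piecewise constant in time: each :class:`MigrationEpoch` specifies a
backward per-lineage, per-generation migration rate that applies while the
current time lies inside the epoch.  Outside every epoch the demes are fully
isolated.

Time is measured in generations before present; population sizes are diploid
effective sizes, so ``k`` lineages in a deme of size ``N`` coalesce at rate
``k (k - 1) / (4 N)`` per generation.  Mutations follow the infinite-sites
model: each mutation creates a new biallelic site whose derived allele is
carried by the sampled leaves below the mutated branch.

Five preset divergence scenarios are exposed through :func:`make_model`:

=====  ==========================================================
label  gene-flow history (times in generations before present)
=====  ==========================================================
M1     complete isolation since the split
M2     gene flow from the split until 200 000
M3     secondary contact between 100 000 and 10 000
M4     secondary contact between 150 000 and 100 000
M5     continuous gene flow from the split until 10 000
=====  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sfs import JointSFS

__all__ = [
    "MigrationEpoch",
    "DemographicModel",
    "SimConfig",
    "Genealogy",
    "make_model",
    "simulate_genealogy",
    "drop_mutations",
    "drop_mutations_leafwise",
    "simulate_joint_sfs",
]

PRESET_LABELS = ("M1", "M2", "M3", "M4", "M5")


@dataclass(frozen=True)
class MigrationEpoch:
    """Time interval with constant backward migration rates.

    ``m12`` is the per-generation probability that a lineage currently in
    deme 1 traces its ancestry to deme 2 (backward migration); ``m21`` is the
    reverse.  Bounds are generations before present, ``t_start < t_end``.
    """

    t_start: float
    t_end: float
    m12: float
    m21: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_start < self.t_end):
            raise ValueError(
                f"epoch bounds must satisfy 0 <= t_start < t_end, got "
                f"[{self.t_start}, {self.t_end}]"
            )
        if self.m12 < 0 or self.m21 < 0:
            raise ValueError("migration rates must be non-negative")


@dataclass(frozen=True)
class DemographicModel:
    """Split time, three diploid sizes, and a list of migration epochs.

    Epochs with both rates zero are dropped on construction: they cannot
    affect the process, and removing them keeps the event stream (hence the
    seeded output) identical to the epoch-free model.
    """

    label: str
    T_split: float
    N1: float
    N2: float
    N_anc: float
    epochs: tuple[MigrationEpoch, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.T_split <= 0:
            raise ValueError("T_split must be positive")
        if min(self.N1, self.N2, self.N_anc) <= 0:
            raise ValueError("population sizes must be positive")
        kept = tuple(
            e for e in self.epochs if (e.m12 > 0 or e.m21 > 0)
        )
        for e in kept:
            if e.t_end > self.T_split:
                raise ValueError(
                    f"epoch [{e.t_start}, {e.t_end}] extends past "
                    f"T_split={self.T_split}"
                )
        for a, b in zip(sorted(kept, key=lambda e: e.t_start),
                        sorted(kept, key=lambda e: e.t_start)[1:]):
            if b.t_start < a.t_end:
                raise ValueError("migration epochs must not overlap")
        object.__setattr__(self, "epochs", kept)


@dataclass(frozen=True)
class SimConfig:
    """Sampling and mutation configuration for SFS simulation.

    ``n1``/``n2`` are haploid sample sizes (two lineages per diploid
    individual, so both must be even when genotypes are wanted); ``mu`` is
    the mutation rate per bp per generation.
    """

    n1: int
    n2: int
    mu: float = 1e-8
    locus_length: int = 1000
    n_loci: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least 2 haploid samples per deme")
        if self.n1 % 2 or self.n2 % 2:
            raise ValueError("haploid sample sizes must be even")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.n_loci < 0:
            raise ValueError("n_loci must be non-negative")


class Genealogy:
    """A coalescent tree over ``n1 + n2`` sampled lineages.

    Leaves ``0..n1-1`` belong to deme 1, ``n1..n1+n2-1`` to deme 2; internal
    nodes are appended in coalescence order, so node times are non-decreasing
    with index and the last node is the root.  ``below1[i]`` / ``below2[i]``
    count the sampled leaves of each deme below node ``i``.
    """

    __slots__ = ("n1", "n2", "times", "parent", "below1", "below2")

    def __init__(self, n1: int, n2: int, times, parent, below1, below2):
        self.n1 = n1
        self.n2 = n2
        self.times = np.asarray(times, dtype=float)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.below1 = np.asarray(below1, dtype=np.int64)
        self.below2 = np.asarray(below2, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return self.times.shape[0]

    @property
    def tmrca(self) -> float:
        return float(self.times[-1])

    def branch_lengths(self) -> np.ndarray:
        """Length in generations of the branch above each non-root node."""
        return self.times[self.parent[:-1]] - self.times[:-1]

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_leaves) matrix: leaf j descends from node i."""
        n = self.n1 + self.n2
        below = np.zeros((self.n_nodes, n), dtype=bool)
        below[np.arange(n), np.arange(n)] = True
        for child in range(self.n_nodes - 1):
            below[self.parent[child]] |= below[child]
        return below


def make_model(
    label: str,
    T_split: float = 1_000_000.0,
    N1: float = 100_000.0,
    N2: float = 100_000.0,
    N_anc: float = 500_000.0,
    m: float = 1e-5,
) -> DemographicModel:
    """Build one of the five preset divergence scenarios.

    ``m`` is applied symmetrically (``m12 = m21 = m``) inside the scenario's
    gene-flow epoch; M1 ignores it.  Asymmetric rates or other epoch layouts
    are available by constructing :class:`DemographicModel` directly with
    ``label='custom'``.
    """
    if label not in PRESET_LABELS:
        raise ValueError(f"unknown scenario {label!r}; expected one of {PRESET_LABELS}")
    bounds = {
        "M1": None,
        "M2": (200_000.0, float(T_split)),
        "M3": (10_000.0, 100_000.0),
        "M4": (100_000.0, 150_000.0),
        "M5": (10_000.0, float(T_split)),
    }[label]
    epochs: tuple[MigrationEpoch, ...] = ()
    if bounds is not None and m > 0:
        lo, hi = bounds
        if hi > T_split or lo >= hi:
            raise ValueError(
                f"{label} gene-flow epoch [{lo}, {hi}] does not fit inside "
                f"T_split={T_split}"
            )
        epochs = (MigrationEpoch(lo, hi, m, m),)
    return DemographicModel(label, float(T_split), float(N1), float(N2),
                            float(N_anc), epochs)


def _interval_rates(model: DemographicModel):
    """Partition [0, T_split) at epoch boundaries; rate pair per interval."""
    cuts = {0.0, model.T_split}
    for e in model.epochs:
        cuts.add(float(e.t_start))
        cuts.add(float(e.t_end))
    bounds = sorted(cuts)
    rates = []
    for lo, hi in zip(bounds, bounds[1:]):
        mid = 0.5 * (lo + hi)
        m12 = m21 = 0.0
        for e in model.epochs:
            if e.t_start <= mid < e.t_end:
                m12, m21 = e.m12, e.m21
                break
        rates.append((m12, m21))
    return bounds, rates


def simulate_genealogy(
    model: DemographicModel, n1: int, n2: int, rng: np.random.Generator
) -> Genealogy:
    """Simulate one genealogy for ``n1 + n2`` haploid lineages.

    Continuous-time backward simulation: within-deme coalescence at rate
    ``k (k-1) / (4 N)``, per-lineage migration at the current epoch's rate,
    a merge of both demes into the ancestral deme at ``T_split``.  Waiting
    times are exponential and re-drawn at every rate-change boundary, which
    is exact by memorylessness.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least one lineage per deme")
    n = n1 + n2
    times = [0.0] * n
    parent = [-1] * (2 * n - 1)
    below1 = [1] * n1 + [0] * n2
    below2 = [0] * n1 + [1] * n2
    deme1 = list(range(n1))
    deme2 = list(range(n1, n))
    next_id = n

    bounds, rates = _interval_rates(model)
    t = 0.0
    iv = 0
    n_iv = len(rates)
    inv4N1 = 1.0 / (4.0 * model.N1)
    inv4N2 = 1.0 / (4.0 * model.N2)
    exp = rng.exponential
    uni = rng.random
    randint = rng.integers

    def coalesce(pool: list[int], when: float) -> None:
        nonlocal next_id
        k = len(pool)
        i = int(randint(k))
        j = int(randint(k - 1))
        if j >= i:
            j += 1
        a, b = pool[i], pool[j]
        c = next_id
        next_id += 1
        times.append(when)
        parent[a] = c
        parent[b] = c
        below1.append(below1[a] + below1[b])
        below2.append(below2[a] + below2[b])
        # replace a by c, delete b (order within pool is irrelevant)
        pool[i] = c
        pool[j] = pool[-1]
        pool.pop()

    # phase 1: two demes, up to T_split
    while len(deme1) + len(deme2) > 1 and t < model.T_split:
        k1 = len(deme1)
        k2 = len(deme2)
        m12, m21 = rates[iv]
        rc1 = k1 * (k1 - 1) * inv4N1
        rc2 = k2 * (k2 - 1) * inv4N2
        rm12 = k1 * m12
        rm21 = k2 * m21
        total = rc1 + rc2 + rm12 + rm21
        boundary = bounds[iv + 1]
        if total == 0.0:
            t = boundary
            if iv + 1 < n_iv:
                iv += 1
            continue
        wait = exp(1.0 / total)
        if t + wait >= boundary:
            t = boundary
            if iv + 1 < n_iv:
                iv += 1
            continue
        t += wait
        u = uni() * total
        if u < rc1:
            coalesce(deme1, t)
        elif u < rc1 + rc2:
            coalesce(deme2, t)
        elif u < rc1 + rc2 + rm12:
            i = int(randint(k1))
            deme2.append(deme1[i])
            deme1[i] = deme1[-1]
            deme1.pop()
        else:
            i = int(randint(k2))
            deme1.append(deme2[i])
            deme2[i] = deme2[-1]
            deme2.pop()

    # phase 2: ancestral panmictic deme
    pool = deme1 + deme2
    if len(pool) > 1:
        t = max(t, model.T_split)
        inv4Na = 1.0 / (4.0 * model.N_anc)
        while len(pool) > 1:
            k = len(pool)
            t += exp(1.0 / (k * (k - 1) * inv4Na))
            coalesce(pool, t)

    assert next_id == 2 * n - 1, "wrong number of coalescent events"
    return Genealogy(n1, n2, times, parent, below1, below2)


def drop_mutations(
    g: Genealogy, mu: float, L: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Drop infinite-sites mutations; return per-site derived counts.

    The number of mutations on each branch is Poisson with mean
    ``branch length x mu x L`` (equivalently: a Poisson total placed
    proportionally to branch length).  Each mutation yields one biallelic
    site whose derived allele count pair is the number of deme-1 and deme-2
    leaves below the branch; counts 0 and n1+n2 cannot occur because every
    branch subtends a proper, non-empty subset of the leaves.
    """
    if mu == 0 or L == 0:
        return []
    lens = g.branch_lengths()
    counts = rng.poisson(lens * (mu * L))
    sites: list[tuple[int, int]] = []
    for node in np.nonzero(counts)[0]:
        pair = (int(g.below1[node]), int(g.below2[node]))
        sites.extend([pair] * int(counts[node]))
    return sites


def drop_mutations_leafwise(
    g: Genealogy, mu: float, L: int, rng: np.random.Generator
) -> np.ndarray:
    """Like :func:`drop_mutations`, returning a (sites, leaves) carrier matrix.

    Row order is by mutated branch (node index); used by the fixture
    generator, which needs per-lineage genotypes rather than counts.
    """
    n = g.n1 + g.n2
    if mu == 0 or L == 0:
        return np.zeros((0, n), dtype=bool)
    lens = g.branch_lengths()
    counts = rng.poisson(lens * (mu * L))
    hit = np.nonzero(counts)[0]
    if hit.size == 0:
        return np.zeros((0, n), dtype=bool)
    below = g.leaf_matrix()
    rows = np.repeat(hit, counts[hit])
    return below[rows]


def simulate_joint_sfs(
    model: DemographicModel,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> JointSFS:
    """Aggregate mutations over ``cfg.n_loci`` independent genealogies.

    Returns an unfolded joint SFS at haploid resolution,
    ``(n1+1) x (n2+1)``; the (0,0) and (n1,n2) corners stay empty.  Loci are
    unlinked; sites within a locus share one genealogy (no intra-locus
    recombination).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mat = np.zeros((cfg.n1 + 1, cfg.n2 + 1), dtype=np.int64)
    for _ in range(cfg.n_loci):
        g = simulate_genealogy(model, cfg.n1, cfg.n2, rng)
        lens = g.branch_lengths()
        counts = rng.poisson(lens * (cfg.mu * cfg.locus_length))
        hit = np.nonzero(counts)[0]
        if hit.size:
            np.add.at(mat, (g.below1[hit], g.below2[hit]), counts[hit])
    return JointSFS(mat, folded=False)
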