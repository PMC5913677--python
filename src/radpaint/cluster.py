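"""MCMC clustering of individuals into populations from a coancestry matrix.

Model
-----
Entries of the coancestry matrix are first scaled to effective counts
``y = round(x / c)`` using the jackknife-calibrated constant *c*, so that
the multinomial sampling noise of ``y`` matches the true statistical
uncertainty of the matrix.  Given a partition of the individuals into
populations, each recipient individual's row of ``y`` is modelled as a
multinomial draw over donor *individuals* whose cell probabilities are
tied at the population level: a recipient in population ``a`` donates to
population ``b`` with total probability ``P_ab``, spread uniformly over
the ``n_b`` available donors in ``b`` (the recipient itself is excluded
from its own population's donor pool).  The probability vectors ``P_a``
carry a symmetric Dirichlet(beta) prior, shared by all recipients of
population ``a``, and are integrated out analytically.  Up to a
partition-independent constant the log marginal likelihood is

    sum_a [ ln G(K b) - ln G(K b + Y_a.)
            + sum_b ( ln G(b + Y_ab) - ln G(b) ) ]
    - sum_{i,b} n_ib * ln m_ib

with ``n_ib`` the counts of recipient ``i`` into donor population ``b``,
``Y_ab`` their sums over recipients of population ``a``, and ``m_ib`` the
donor-pool size of ``b`` seen from ``i``.  One population (K = 1) forces
every row towards uniformity over donors; splits are rewarded exactly
when rows differ by more than the calibrated multinomial noise.  The
prior over partitions is uniform.

Sampling
--------
A Metropolis–Hastings chain over set partitions with four proposal
types, each chosen with probability 1/4: merge two populations, split
one uniformly at random into two non-empty parts, merge-then-resplit a
pair, and move a single individual to another (or a brand-new)
population.  Proposal asymmetries are corrected by exact Hastings
ratios; inapplicable proposals count as rejections.  The chain is
bitwise reproducible given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .painter import CoancestryMatrix

__all__ = [
    "Partition",
    "PosteriorSample",
    "ClusterResult",
    "log_marginal_likelihood",
    "mcmc_run",
    "summarize",
    "enumerate_partitions",
    "exact_log_posterior",
]


@dataclass(frozen=True)
class Partition:
    """An assignment of individuals to populations.

    ``labels[i]`` is the population of individual ``i``; labels are
    contiguous ``1..K`` in order of first appearance.
    """

    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        seen: list[int] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        if seen != list(range(1, len(seen) + 1)):
            raise ValueError(
                "labels must be contiguous 1..K in order of first appearance"
            )

    @classmethod
    def from_labels(cls, labels) -> "Partition":
        """Build from any hashable labels, canonicalising to 1..K."""
        mapping: dict = {}
        out = []
        for lab in labels:
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            out.append(mapping[lab])
        return cls(tuple(out))

    @property
    def K(self) -> int:
        return max(self.labels) if self.labels else 0

    @property
    def n(self) -> int:
        return len(self.labels)

    def populations(self) -> list[frozenset[int]]:
        pops: dict[int, set[int]] = {}
        for i, lab in enumerate(self.labels):
            pops.setdefault(lab, set()).add(i)
        return [frozenset(pops[k]) for k in range(1, self.K + 1)]

    def as_sets(self) -> frozenset[frozenset[int]]:
        return frozenset(self.populations())


@dataclass(frozen=True)
class PosteriorSample:
    partition: Partition
    log_posterior: float
    iteration: int


@dataclass
class ClusterResult:
    map_partition: Partition
    coincidence: np.ndarray
    population_matrix: np.ndarray
    population_ids: list[str]
    population_members: dict[str, list[str]]
    tree_newick: str
    population_support: dict[str, float]


# ---------------------------------------------------------------------------
# likelihood


def _scaled_counts(matrix: CoancestryMatrix | np.ndarray, c: float) -> np.ndarray:
    if c <= 0:
        raise ValueError("c must be positive")
    x = matrix.x if isinstance(matrix, CoancestryMatrix) else np.asarray(matrix)
    y = np.rint(x / c)  # numpy rounds half to even
    np.fill_diagonal(y, 0.0)  # self-coancestry is structural, never modelled
    return y


def _log_ml_from_counts(
    y: np.ndarray, labels: np.ndarray, beta: float = 1.0
) -> float:
    """Log marginal likelihood (up to a partition-free constant)."""
    n = y.shape[0]
    K = int(labels.max()) + 1
    member = np.zeros((n, K))
    member[np.arange(n), labels] = 1.0

    n_ib = y @ member                      # recipient-individual x donor-pop
    pool = member.sum(axis=0)              # population sizes
    m_ib = pool[None, :] - member          # donor-pool sizes, self excluded
    with np.errstate(divide="ignore"):
        log_m = np.where(m_ib > 0, np.log(np.maximum(m_ib, 1.0)), 0.0)
    uniform_term = -(n_ib * log_m).sum()

    Y_ab = member.T @ n_ib                 # recipient-pop x donor-pop
    Y_a = Y_ab.sum(axis=1)
    dir_term = float(
        (gammaln(K * beta) - gammaln(K * beta + Y_a)).sum()
        + (gammaln(beta + Y_ab) - gammaln(beta)).sum()
    )
    return dir_term + uniform_term


def log_marginal_likelihood(
    matrix: CoancestryMatrix | np.ndarray,
    partition: Partition,
    c: float,
    beta: float = 1.0,
) -> float:
    """Log marginal likelihood of a partition given the coancestry matrix.

    Invariant under relabelling of populations and under permutation of
    individuals within a population; finite for every valid input.
    """
    y = _scaled_counts(matrix, c)
    labels = np.asarray(partition.labels) - 1
    return _log_ml_from_counts(y, labels, beta)


# ---------------------------------------------------------------------------
# proposals


def _log_pow2_minus1(m: int) -> float:
    """log(2**(m-1) - 1), overflow-safe (number of bipartitions of m items)."""
    if m < 2:
        raise ValueError("need m >= 2")
    return (m - 1) * math.log(2.0) + math.log1p(-(2.0 ** -(m - 1)))


def _canonical(labels: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[int(lab)] = len(mapping)
        out[i] = mapping[int(lab)]
    return out


def _random_bipartition(
    members: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform over the 2**(m-1) - 1 unordered pairs of non-empty parts."""
    m = members.size
    while True:
        bits = rng.integers(0, 2, size=m)
        if 0 < bits.sum() < m:
            return members[bits == 0], members[bits == 1]


def _propose(
    labels: np.ndarray, K: int, rng: np.random.Generator
) -> tuple[np.ndarray, float] | None:
    """One MH proposal; returns (new labels, log Hastings correction) or
    ``None`` when the drawn move type is inapplicable (counts as reject)."""
    n = labels.size
    move = int(rng.integers(0, 4))

    if move == 0:  # merge two populations
        if K < 2:
            return None
        a, b = rng.choice(K, size=2, replace=False)
        new = labels.copy()
        new[new == b] = a
        m = int((new == a).sum())
        log_h = (
            math.log(K * (K - 1) / 2)
            - math.log(K - 1)
            - _log_pow2_minus1(m)
        )
        return _canonical(new), log_h

    if move == 1:  # split a population uniformly into two non-empty parts
        a = int(rng.integers(0, K))
        members = np.nonzero(labels == a)[0]
        m = members.size
        if m < 2:
            return None
        part0, part1 = _random_bipartition(members, rng)
        new = labels.copy()
        new[part1] = K  # provisional fresh label
        log_h = (
            math.log(K)
            + _log_pow2_minus1(m)
            - math.log((K + 1) * K / 2)
        )
        return _canonical(new), log_h

    if move == 2:  # merge a pair then resplit it at random (symmetric)
        if K < 2:
            return None
        a, b = rng.choice(K, size=2, replace=False)
        members = np.nonzero((labels == a) | (labels == b))[0]
        part0, part1 = _random_bipartition(members, rng)
        new = labels.copy()
        new[part0] = a
        new[part1] = b
        return _canonical(new), 0.0

    # move == 3: move one individual to another or a brand-new population
    i = int(rng.integers(0, n))
    a = int(labels[i])
    size_a = int((labels == a).sum())
    targets = [k for k in range(K) if k != a]
    if size_a > 1:
        targets.append(K)  # a brand-new singleton population
    if not targets:
        return None
    t = targets[int(rng.integers(0, len(targets)))]
    new = labels.copy()
    new[i] = t
    return _canonical(new), 0.0  # forward/reverse option counts always match


def mcmc_run(
    matrix: CoancestryMatrix | np.ndarray,
    c: float,
    iterations: int = 100000,
    burn_in: int = 50000,
    thin: int = 50,
    seed: int = 1,
    beta: float = 1.0,
    initial: Partition | None = None,
) -> list[PosteriorSample]:
    """Sample partitions from the posterior by Metropolis–Hastings.

    Starts from the all-singletons partition unless ``initial`` is given.
    Returns the post-burn-in samples taken every ``thin`` iterations; the
    sample's ``log_posterior`` is the (unnormalised) log posterior under
    the uniform partition prior.
    """
    y = _scaled_counts(matrix, c)
    n = y.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least two individuals")
    if not iterations > burn_in >= 0:
        raise ValueError("need iterations > burn_in >= 0")
    rng = np.random.default_rng(seed)

    if initial is None:
        labels = np.arange(n)
    else:
        labels = np.asarray(initial.labels) - 1
    labels = _canonical(labels)
    log_ml = _log_ml_from_counts(y, labels, beta)

    samples: list[PosteriorSample] = []
    for it in range(iterations):
        K = int(labels.max()) + 1
        prop = _propose(labels, K, rng)
        accept_draw = rng.random()  # drawn unconditionally: fixed stream
        if prop is not None:
            new_labels, log_h = prop
            new_ml = _log_ml_from_counts(y, new_labels, beta)
            if math.log(max(accept_draw, 1e-300)) < (new_ml - log_ml) + log_h:
                labels = new_labels
                log_ml = new_ml
        if it >= burn_in and (it - burn_in) % thin == 0:
            samples.append(
                PosteriorSample(
                    Partition.from_labels(labels), log_ml, it
                )
            )
    return samples


# ---------------------------------------------------------------------------
# exact posterior on small problems


def enumerate_partitions(n: int):
    """Yield every set partition of ``n`` items as a Partition
    (restricted-growth enumeration; Bell(n) of them)."""

    def rec(prefix: list[int], next_label: int):
        if len(prefix) == n:
            yield Partition.from_labels(prefix)
            return
        for lab in range(1, next_label + 1):
            yield from rec(prefix + [lab], max(next_label, lab + 1))

    yield from rec([1], 2) if n else iter(())


def exact_log_posterior(
    matrix: CoancestryMatrix | np.ndarray, c: float, beta: float = 1.0
) -> dict[frozenset[frozenset[int]], float]:
    """Normalised log posterior of every partition (small n only)."""
    y = _scaled_counts(matrix, c)
    n = y.shape[0]
    parts = list(enumerate_partitions(n))
    logs = np.array(
        [
            _log_ml_from_counts(np.asarray(y), np.asarray(p.labels) - 1, beta)
            for p in parts
        ]
    )
    logz = float(np.logaddexp.reduce(logs))
    return {p.as_sets(): float(l - logz) for p, l in zip(parts, logs)}


# ---------------------------------------------------------------------------
# posterior summaries and the illustrative tree


def _greedy_tree(
    y: np.ndarray,
    map_partition: Partition,
    beta: float,
    support: dict[frozenset[int], float],
    pop_names: dict[frozenset[int], str],
) -> str:
    """Successively merge the pair of populations losing the least log
    likelihood; the merge order defines the (illustrative) topology."""
    nodes: list[tuple[frozenset[int], str]] = []
    for pop in map_partition.populations():
        name = pop_names[pop]
        nodes.append((pop, name))
    labels = np.asarray(map_partition.labels) - 1

    def labels_for(groups: list[frozenset[int]]) -> np.ndarray:
        lab = np.empty(labels.size, dtype=int)
        for g, members in enumerate(groups):
            for i in members:
                lab[i] = g
        return lab

    while len(nodes) > 1:
        best = None
        for ai in range(len(nodes)):
            for bi in range(ai + 1, len(nodes)):
                groups = [
                    g for k, (g, _) in enumerate(nodes) if k not in (ai, bi)
                ]
                groups.append(nodes[ai][0] | nodes[bi][0])
                ml = _log_ml_from_counts(y, labels_for(groups), beta)
                if best is None or ml > best[0]:
                    best = (ml, ai, bi)
        _, ai, bi = best
        merged = nodes[ai][0] | nodes[bi][0]
        sup = support.get(merged, 0.0)
        text = f"({nodes[ai][1]},{nodes[bi][1]}){sup:.2f}"
        nodes = [nd for k, nd in enumerate(nodes) if k not in (ai, bi)]
        nodes.append((merged, text))
    return nodes[0][1] + ";"


def summarize(
    samples: list[PosteriorSample],
    matrix: CoancestryMatrix,
    c: float = 1.0,
    beta: float = 1.0,
) -> ClusterResult:
    """Condense posterior samples into the standard outputs.

    The MAP partition is the sampled partition of highest posterior; the
    coincidence matrix gives the fraction of samples in which two
    individuals share a population; the population-averaged matrix is the
    block mean of the coancestry matrix under the MAP; and the tree is a
    greedy merge dendrogram over the MAP populations, annotated with the
    fraction of samples in which each node's exact set of individuals
    forms one population.
    """
    if not samples:
        raise ValueError("no posterior samples to summarise")
    n = matrix.x.shape[0]
    ids = matrix.individual_ids

    map_sample = max(samples, key=lambda s: s.log_posterior)
    map_partition = map_sample.partition

    coincidence = np.zeros((n, n))
    pop_freq: dict[frozenset[int], int] = {}
    for s in samples:
        lab = np.asarray(s.partition.labels)
        coincidence += lab[:, None] == lab[None, :]
        for pop in s.partition.populations():
            pop_freq[pop] = pop_freq.get(pop, 0) + 1
    coincidence /= len(samples)
    support = {pop: cnt / len(samples) for pop, cnt in pop_freq.items()}

    pops = map_partition.populations()
    pop_ids = [f"Pop{k + 1}" for k in range(len(pops))]
    pop_names = dict(zip(pops, pop_ids))
    members = {
        pop_names[pop]: sorted(ids[i] for i in pop) for pop in pops
    }
    K = len(pops)
    pop_matrix = np.zeros((K, K))
    for ai, pa in enumerate(pops):
        for bi, pb in enumerate(pops):
            block = matrix.x[np.ix_(sorted(pa), sorted(pb))]
            pop_matrix[ai, bi] = block.mean()

    y = _scaled_counts(matrix, c)
    leaf_support = {pop_names[pop]: support.get(pop, 0.0) for pop in pops}
    tree = _greedy_tree(y, map_partition, beta, support, pop_names)
    return ClusterResult(
        map_partition=map_partition,
        coincidence=coincidence,
        population_matrix=pop_matrix,
        population_ids=pop_ids,
        population_members=members,
        tree_newick=tree,
        population_support=leaf_support,
    )
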