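"""Discrete-time threshold contagion of patrol knowledge on a social network.

A fraction ``E`` of the community (proportional to patrol effort) starts with
first-hand knowledge of ranger patrols; by default the least-connected
individuals are seeded, reflecting hunting being concentrated among
marginalised, poorly connected people at forest edges.  At each of ``n_steps``
synchronous time-steps, every still-uninformed individual who is directly
connected to at least ``T`` informed contacts (the listening threshold,
proxying the need for repeated independent transmission) takes up the
information with probability ``L`` (the listening probability).  Knowledge is
absorbing: nobody forgets.  The per-step informed counts form a trajectory
whose sum — the area under the cumulative-receipt curve (AUC) — is the rate-
of-information-flow statistic, bounded by ``n_steps * node_count``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .netgen import SocialNetwork

__all__ = [
    "DiffusionParams",
    "Trajectory",
    "seed_knowledge",
    "diffusion_step",
    "run_diffusion",
    "compute_auc",
    "exact_expected_counts",
    "monte_carlo_expected_counts",
]

STRATEGIES = ("least_connected", "best_connected")


@dataclass(frozen=True)
class DiffusionParams:
    """Knowledge-exchange rules: threshold T, listening probability L,
    patrol effort E, and the number of discrete time-steps.

    By default L applies once per listener per step.  With ``per_contact``
    each informed neighbour is an independent chance to listen, so an
    eligible node with k informed contacts takes up the information with
    probability 1 - (1-L)^k; a sensitivity-analysis variant.
    """

    T: int
    L: float
    E: float
    n_steps: int = 50
    per_contact: bool = False

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("listening threshold T must be >= 1")
        if not 0.0 <= self.L <= 1.0:
            raise ValueError("listening probability L must lie in [0, 1]")
        if not 0.0 <= self.E <= 1.0:
            raise ValueError("patrol effort E must lie in [0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass(frozen=True)
class Trajectory:
    """Informed count at the end of each step, plus the AUC statistic."""

    counts: tuple[int, ...]
    node_count: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if np.any(np.diff(c) < 0):
            raise ValueError("informed counts must be non-decreasing")
        if c.size and (c.min() < 0 or c.max() > self.node_count):
            raise ValueError("counts must lie in [0, node_count]")

    @property
    def auc(self) -> int:
        return int(sum(self.counts))

    @property
    def final_count(self) -> int:
        return int(self.counts[-1]) if self.counts else 0


def seed_count(E: float, n: int) -> int:
    """Number of individuals seeded: round(E*n), half away from zero."""
    return int(np.floor(E * n + 0.5))


def seed_knowledge(
    network: SocialNetwork,
    E: float,
    strategy: str = "least_connected",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Seed ``round(E*n)`` individuals, by ascending or descending degree.

    Ties in degree are broken uniformly at random.  Returns the per-node
    boolean informed state.
    """
    if not 0.0 <= E <= 1.0:
        raise ValueError("patrol effort E must lie in [0, 1]")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown seeding strategy {strategy!r}; use one of {STRATEGIES}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = network.node_count
    k = seed_count(E, n)
    informed = np.zeros(n, dtype=bool)
    if k == 0:
        return informed
    degs = network.degree_sequence
    perm = rng.permutation(n)  # random tie-break under stable sort
    key = degs[perm] if strategy == "least_connected" else -degs[perm]
    order = perm[np.argsort(key, kind="stable")]
    informed[order[:k]] = True
    return informed


def diffusion_step(
    informed: np.ndarray,
    network: SocialNetwork,
    T: int,
    L: float,
    rng: np.random.Generator,
    per_contact: bool = False,
) -> np.ndarray:
    """One synchronous update of the knowledge state.

    Every individual uninformed at step start who has >= T informed
    neighbours (counted at step start) becomes informed independently with
    probability L (or 1-(1-L)^k for k informed neighbours when
    ``per_contact`` is set).  Informed individuals stay informed.
    """
    informed = np.asarray(informed, dtype=bool)
    n_informed_nbrs = network.adjacency @ informed.astype(np.float32)
    eligible = (~informed) & (n_informed_nbrs >= T - 0.5)
    if per_contact:
        p = 1.0 - (1.0 - L) ** np.rint(n_informed_nbrs)
    else:
        p = L
    listens = rng.random(informed.size) < p
    return informed | (eligible & listens)


def run_diffusion(
    network: SocialNetwork,
    params: DiffusionParams,
    strategy: str = "least_connected",
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Seed knowledge, run ``n_steps`` synchronous steps, record the curve.

    The informed count is recorded at the end of every step (the seeded state
    itself is not a curve point), so the AUC maximum is exactly
    ``n_steps * node_count``.
    """
    if network.node_count == 0:
        raise ValueError("network must be non-empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    informed = seed_knowledge(network, params.E, strategy, rng)
    counts = []
    for _ in range(params.n_steps):
        informed = diffusion_step(
            informed, network, params.T, params.L, rng, params.per_contact
        )
        counts.append(int(informed.sum()))
    return Trajectory(counts=tuple(counts), node_count=network.node_count)


def compute_auc(trajectory: Trajectory) -> int:
    """AUC of the cumulative-receipt curve: the sum of per-step counts
    (discrete rectangle rule)."""
    return trajectory.auc


# ---------------------------------------------------------------------------
# verification oracles


def exact_expected_counts(
    network: SocialNetwork,
    params: DiffusionParams,
    seeds: set[int] | list[int],
) -> np.ndarray:
    """Exact per-step expected informed counts by full state-space propagation.

    Propagates the probability distribution over knowledge states (bitmasks)
    under the synchronous rule; feasible only for small communities, so
    networks above 12 nodes are refused.  Serves as the independent oracle
    for the Monte-Carlo simulator.
    """
    n = network.node_count
    if n > 12:
        raise ValueError(
            f"exact enumeration over 2^{n} knowledge states is intractable; "
            "use networks of at most 12 nodes"
        )
    seeds = sorted(set(int(s) for s in seeds))
    if any(s < 0 or s >= n for s in seeds):
        raise ValueError("seed node ids must lie in [0, n)")
    nbr_mask = [0] * n
    for u, v in network.graph.edges:
        nbr_mask[u] |= 1 << v
        nbr_mask[v] |= 1 << u

    state0 = 0
    for s in seeds:
        state0 |= 1 << s
    dist: dict[int, float] = {state0: 1.0}
    T, L = params.T, params.L
    expected = np.empty(params.n_steps, dtype=float)

    for step in range(params.n_steps):
        new_dist: dict[int, float] = {}
        for state, p in dist.items():
            eligible: list[int] = []
            take_up: list[float] = []  # per-node uptake probability
            for i in range(n):
                if (state >> i) & 1:
                    continue
                k = (state & nbr_mask[i]).bit_count()
                if k >= T:
                    eligible.append(i)
                    take_up.append(1.0 - (1.0 - L) ** k if params.per_contact else L)
            e = len(eligible)
            if e == 0 or L == 0.0:
                new_dist[state] = new_dist.get(state, 0.0) + p
                continue
            for k in range(e + 1):
                for combo in combinations(range(e), k):
                    chosen = set(combo)
                    pk = 1.0
                    for j in range(e):
                        pk *= take_up[j] if j in chosen else 1.0 - take_up[j]
                    if pk == 0.0:
                        continue
                    s2 = state
                    for j in chosen:
                        s2 |= 1 << eligible[j]
                    new_dist[s2] = new_dist.get(s2, 0.0) + p * pk
        dist = new_dist
        expected[step] = sum(p * state.bit_count() for state, p in dist.items())
    return expected


def monte_carlo_expected_counts(
    network: SocialNetwork,
    params: DiffusionParams,
    seeds: set[int] | list[int],
    n_reps: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo mean per-step informed counts from fixed seed nodes.

    Vectorised over replicates; returns ``(mean, standard_error)`` arrays of
    length ``n_steps`` for comparison against :func:`exact_expected_counts`.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = network.node_count
    adj = network.adjacency
    informed = np.zeros((n_reps, n), dtype=bool)
    informed[:, sorted(set(int(s) for s in seeds))] = True
    counts = np.empty((params.n_steps, n_reps), dtype=np.int32)
    for step in range(params.n_steps):
        n_informed_nbrs = informed.astype(np.float32) @ adj
        eligible = (~informed) & (n_informed_nbrs >= params.T - 0.5)
        if params.per_contact:
            p = 1.0 - (1.0 - params.L) ** np.rint(n_informed_nbrs)
        else:
            p = params.L
        listens = rng.random((n_reps, n)) < p
        informed |= eligible & listens
        counts[step] = informed.sum(axis=1)
    mean = counts.mean(axis=1)
    se = counts.std(axis=1, ddof=1) / np.sqrt(n_reps)
    return mean, se
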