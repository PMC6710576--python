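"""Generation of small social networks with skewed degree distributions.

Communities are modelled as undirected simple graphs of ``n`` individuals
whose degree distributions are lightly, moderately or highly skewed towards
the star-graph extreme (one hub connected to everyone, no other ties).
Target degrees are drawn from a discretised lognormal with a fixed mean
degree and a preset-specific sigma, then realised exactly by Havel-Hakimi
construction followed by seeded double-edge-swap randomisation.  Degree-
preserving cross-component swaps enforce connectivity by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats as sps

__all__ = [
    "SkewPreset",
    "PRESETS",
    "SocialNetwork",
    "NetworkGenerationError",
    "generate_degree_sequence",
    "realize_network",
    "generate_network",
    "star_network",
    "degree_skewness",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
]


class NetworkGenerationError(RuntimeError):
    """Raised when a degree sequence cannot be realised as a simple graph."""


@dataclass(frozen=True)
class SkewPreset:
    """Parameters of the discretised-lognormal degree distribution.

    ``mean_degree`` fixes the expected number of direct social contacts per
    individual; ``sigma`` is the lognormal shape parameter controlling how
    skewed the contact distribution is (larger sigma -> heavier hub tail).
    """

    mean_degree: float = 4.0
    sigma: float = 0.6

    def __post_init__(self) -> None:
        if self.mean_degree <= 0 or self.sigma <= 0:
            raise ValueError("mean_degree and sigma must be positive")


#: Community-structure presets: evenness of connectedness decreases (skew
#: increases) from light to high.
PRESETS: dict[str, SkewPreset] = {
    "light": SkewPreset(mean_degree=4.0, sigma=0.2),
    "moderate": SkewPreset(mean_degree=4.0, sigma=0.6),
    "high": SkewPreset(mean_degree=4.0, sigma=1.2),
}


@dataclass
class SocialNetwork:
    """An undirected simple graph of individuals, with generation provenance."""

    graph: nx.Graph
    structure_label: str = "custom"
    generator_seed: int | None = None
    _adjacency: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges):
            raise ValueError("self-loops are not allowed in a social network")
        # relabel to contiguous 0-based integers so array code can index nodes
        if sorted(g.nodes) != list(range(g.number_of_nodes())):
            mapping = {v: i for i, v in enumerate(sorted(g.nodes, key=str))}
            self.graph = nx.relabel_nodes(g, mapping)

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degree_sequence(self) -> np.ndarray:
        """Per-node degrees, indexed by node id."""
        n = self.node_count
        out = np.zeros(n, dtype=np.int64)
        for v, d in self.graph.degree:
            out[v] = d
        return out

    @property
    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix (float32, cached) in node-id order."""
        if self._adjacency is None:
            self._adjacency = nx.to_numpy_array(
                self.graph, nodelist=range(self.node_count), dtype=np.float32
            )
        return self._adjacency

    def is_connected(self) -> bool:
        return self.node_count > 0 and nx.is_connected(self.graph)

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset((min(u, v), max(u, v)) for u, v in self.graph.edges)


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _resolve_preset(skew_preset: str | SkewPreset) -> SkewPreset:
    if isinstance(skew_preset, SkewPreset):
        return skew_preset
    try:
        return PRESETS[skew_preset]
    except KeyError:
        raise ValueError(
            f"unknown skew preset {skew_preset!r}; expected one of {sorted(PRESETS)}"
        ) from None


def generate_degree_sequence(
    n: int,
    skew_preset: str | SkewPreset,
    rng: np.random.Generator | int | None = None,
) -> list[int]:
    """Draw a target degree sequence for ``n`` individuals.

    Degrees are lognormal draws with mean ``preset.mean_degree`` and shape
    ``preset.sigma``, rounded to the nearest integer and truncated to
    ``[1, n-1]``.  An odd degree sum is repaired by incrementing the smallest
    entry (minimal perturbation), so the result is always pairable.
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    preset = _resolve_preset(skew_preset)
    rng = _as_rng(rng)
    # lognormal parameterised so the *mean* equals mean_degree
    mu = math.log(preset.mean_degree) - preset.sigma**2 / 2.0
    draws = rng.lognormal(mean=mu, sigma=preset.sigma, size=n)
    degrees = np.clip(np.rint(draws).astype(int), 1, n - 1)
    if degrees.sum() % 2 == 1:
        i = int(np.argmin(degrees))
        if degrees[i] < n - 1:
            degrees[i] += 1
        else:  # all entries at the cap: decrement the largest instead
            degrees[int(np.argmax(degrees))] -= 1
    return degrees.tolist()


def _repair_to_graphical(degrees: list[int], max_attempts: int = 100) -> list[int]:
    """Minimally shrink hub degrees until the sequence is graphical."""
    seq = list(degrees)
    for _ in range(max_attempts):
        if nx.is_graphical(seq):
            return seq
        # reduce the two largest entries by 1 each (parity-preserving)
        order = sorted(range(len(seq)), key=lambda i: -seq[i])
        a, b = order[0], order[1]
        if seq[a] <= 1 or seq[b] <= 1:
            break
        seq[a] -= 1
        seq[b] -= 1
    raise NetworkGenerationError(
        f"degree sequence {degrees} is not graphical and could not be repaired"
    )


def realize_network(
    degree_sequence: list[int],
    rng: np.random.Generator | int | None = None,
    enforce_connected: bool = True,
) -> SocialNetwork:
    """Build a random simple graph with the given degree sequence.

    The sequence is realised exactly when graphical (Havel-Hakimi, then
    randomised by double edge swaps, which preserve every degree); a
    non-graphical sequence is first repaired by shrinking its largest
    entries.  With ``enforce_connected`` the components are merged by
    degree-preserving cross-component edge swaps.
    """
    degrees = [int(d) for d in degree_sequence]
    n = len(degrees)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if any(d < 0 or d > n - 1 for d in degrees):
        raise ValueError("each degree must lie in [0, n-1]")
    if sum(degrees) % 2 == 1:
        raise ValueError("degree sum must be even")
    rng = _as_rng(rng)

    seq = _repair_to_graphical(degrees)
    m = sum(seq) // 2
    if enforce_connected and m < n - 1:
        raise NetworkGenerationError(
            f"cannot build a connected graph on {n} nodes with only {m} edges"
        )

    g = nx.havel_hakimi_graph(seq)
    if m >= 2 and n >= 4:
        _double_edge_swap(g, nswap=4 * m, rng=rng)

    if enforce_connected:
        _connect_components(g, rng)

    net = SocialNetwork(graph=g)
    realized = sorted(d for _, d in g.degree)
    if realized != sorted(seq):  # pragma: no cover - swaps preserve degrees
        raise NetworkGenerationError("realised degrees do not match the target")
    return net


def _double_edge_swap(g: nx.Graph, nswap: int, rng: np.random.Generator) -> None:
    """Randomise ``g`` in place by ``nswap`` accepted double edge swaps.

    Picks two edges (u,v), (x,y) uniformly and rewires them to (u,x), (v,y)
    unless that would create a self-loop or duplicate edge; every degree is
    preserved exactly.  Random draws come from the supplied numpy generator,
    in pre-drawn batches for speed.
    """
    edges = [(min(u, v), max(u, v)) for u, v in sorted(g.edges)]
    edge_set = set(edges)
    m = len(edges)
    accepted = 0
    max_tries = 100 * nswap
    tries = 0
    while accepted < nswap and tries < max_tries:
        batch = min(4 * nswap, max_tries - tries)
        idx = rng.integers(0, m, size=(batch, 2))
        flip = rng.integers(0, 2, size=batch)
        for (i, j), f in zip(idx, flip):
            tries += 1
            if i == j:
                continue
            u, v = edges[i]
            x, y = edges[j]
            if f:
                x, y = y, x
            # rewire (u,v),(x,y) -> (u,x),(v,y)
            if u == x or v == y:
                continue
            e1 = (min(u, x), max(u, x))
            e2 = (min(v, y), max(v, y))
            if e1 in edge_set or e2 in edge_set:
                continue
            edge_set.discard(edges[i])
            edge_set.discard(edges[j])
            edges[i] = e1
            edges[j] = e2
            edge_set.add(e1)
            edge_set.add(e2)
            accepted += 1
            if accepted >= nswap:
                break
    g.remove_edges_from(list(g.edges))
    g.add_edges_from(edges)


def _connect_components(g: nx.Graph, rng: np.random.Generator) -> None:
    """Merge components in place via degree-preserving edge swaps.

    Picks one edge in each of two components and rewires (a,b),(c,d) to
    (a,c),(b,d); since the components are disjoint the new edges cannot
    duplicate existing ones, and all degrees are unchanged.
    """
    while True:
        comps = [sorted(c) for c in nx.connected_components(g)]
        if len(comps) <= 1:
            return
        comps.sort(key=lambda c: c[0])
        e0 = _pick_edge(g, comps[0], rng)
        e1 = _pick_edge(g, comps[1], rng)
        if e0 is None or e1 is None:
            raise NetworkGenerationError(
                "cannot connect components containing isolated (degree-0) nodes"
            )
        (a, b), (c, d) = e0, e1
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, c)
        g.add_edge(b, d)


def _pick_edge(g, comp, rng) -> tuple[int, int] | None:
    edges = sorted(
        (min(u, v), max(u, v)) for u, v in g.edges(comp)
    )
    if not edges:
        return None
    return edges[rng.integers(len(edges))]


def generate_network(
    n: int,
    skew_preset: str | SkewPreset,
    rng: np.random.Generator | int | None = None,
    enforce_connected: bool = True,
) -> SocialNetwork:
    """Generate a connected ``n``-individual community with the given skew.

    Composition of :func:`generate_degree_sequence` and
    :func:`realize_network`; records the structure label and (when the rng is
    given as an integer seed) the generating seed for provenance.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = _as_rng(rng)
    for _ in range(100):
        seq = generate_degree_sequence(n, skew_preset, rng)
        # a heavily skewed draw can have fewer than n-1 edges, which no
        # connected graph can carry; redraw rather than fail
        if enforce_connected and sum(seq) // 2 < n - 1:
            continue
        break
    else:
        raise NetworkGenerationError(
            f"could not draw a connectable degree sequence for preset "
            f"{skew_preset!r} at n={n} within 100 attempts"
        )
    net = realize_network(seq, rng, enforce_connected=enforce_connected)
    net.structure_label = (
        skew_preset if isinstance(skew_preset, str) else "custom"
    )
    net.generator_seed = None if seed is None else int(seed)
    return net


def star_network(n: int) -> SocialNetwork:
    """The theoretical skew extreme: node 0 tied to everyone, no other ties."""
    if n < 2:
        raise ValueError("a star needs at least 2 individuals")
    return SocialNetwork(graph=nx.star_graph(n - 1), structure_label="custom")


def degree_skewness(network: SocialNetwork | np.ndarray | list[int]) -> float:
    """Bias-corrected sample skewness of the degree sequence.

    Describes the (un)evenness of connectedness: near zero for regular-ish
    communities, large and positive when a few hubs hold most ties.  Returns
    ``nan`` (a flagged sentinel, not an exception) when the degree variance
    is zero and the statistic is undefined.
    """
    degs = (
        network.degree_sequence
        if isinstance(network, SocialNetwork)
        else np.asarray(network, dtype=float)
    )
    if degs.size < 3 or np.ptp(degs) == 0:
        return float("nan")
    return float(sps.skew(degs, bias=False))


# ---------------------------------------------------------------------------
# plain-text IO: whitespace-separated 0-based edge lists, and GraphML


def write_edgelist(network: SocialNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(network.edge_set()):
            fh.write(f"{u} {v}\n")


def read_edgelist(path: str | Path, node_count: int | None = None) -> SocialNetwork:
    g = nx.read_edgelist(path, nodetype=int)
    if node_count is not None:
        g.add_nodes_from(range(node_count))
    return SocialNetwork(graph=g)


def write_graphml(network: SocialNetwork, path: str | Path) -> None:
    g = network.graph.copy()
    g.graph["structure_label"] = network.structure_label
    if network.generator_seed is not None:
        g.graph["generator_seed"] = int(network.generator_seed)
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> SocialNetwork:
    g = nx.read_graphml(path, node_type=int)
    label = g.graph.pop("structure_label", "custom")
    seed = g.graph.pop("generator_seed", None)
    return SocialNetwork(
        graph=nx.Graph(g),
        structure_label=label,
        generator_seed=None if seed is None else int(seed),
    )
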