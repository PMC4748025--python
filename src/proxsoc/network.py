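"""Weighted intersexual proximity networks, metrics and community detection.

Edge weight between a female and a male is the number of scans in which the
male was recorded within the radius of that female.  The 2-m network uses
the inner ring only; the 5-m network uses the union of both rings (the
cumulative "within 5 m" relation).  Degree and density treat the graph as
unweighted (an edge exists if the dyad co-occurred at least once); weighted
strength is reported separately.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import (
    ConfigurationError,
    EmptyNetworkError,
    PartitionError,
    UndefinedMetricError,
)
from .records import ScanRecord, Sex

logger = logging.getLogger(__name__)

__all__ = [
    "RadiusClass",
    "WeightedNetwork",
    "Partition",
    "NetworkMetrics",
    "DegreeStats",
    "build_network",
    "density",
    "degree_stats",
    "modularity",
    "walktrap",
    "potts_communities",
    "pairing_success",
    "network_metrics",
    "write_edgelist_csv",
    "write_graphml",
]


class RadiusClass(enum.Enum):
    TWO_M = "2m"
    FIVE_M = "5m"


@dataclass
class WeightedNetwork:
    """Undirected weighted female-male proximity graph."""

    graph: nx.Graph
    radius_class: RadiusClass
    window: tuple[int, int] | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_dyads(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def weight(self, u: str, v: str) -> int:
        return self.graph[u][v]["weight"]

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        radius_class: RadiusClass = RadiusClass.TWO_M,
        window: tuple[int, int] | None = None,
        node_attrs: Mapping[str, Mapping[str, str]] | None = None,
    ) -> "WeightedNetwork":
        g = nx.Graph()
        for u, v, w in edges:
            if u == v:
                raise PartitionError(f"self-loop on {u!r}")
            if w <= 0:
                raise ConfigurationError("edge weights must be positive")
            g.add_edge(u, v, weight=int(w))
        if node_attrs:
            for node, attrs in node_attrs.items():
                if node in g:
                    g.nodes[node].update(attrs)
        return cls(graph=g, radius_class=radius_class, window=window)


@dataclass(frozen=True)
class Partition:
    """Node -> community labelling with labels contiguous from 1."""

    community_of: Mapping[str, int]
    n_communities: int

    @classmethod
    def from_labels(cls, labels: Mapping[str, int]) -> "Partition":
        # Relabel contiguously from 1, ordered by first appearance over
        # sorted nodes for determinism.
        mapping: dict[int, int] = {}
        out: dict[str, int] = {}
        for node in sorted(labels):
            raw = labels[node]
            if raw not in mapping:
                mapping[raw] = len(mapping) + 1
            out[node] = mapping[raw]
        return cls(community_of=out, n_communities=len(mapping))

    def communities(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_communities)]
        for node, label in self.community_of.items():
            out[label - 1].add(node)
        return out


@dataclass(frozen=True)
class DegreeStats:
    degree_range: tuple[int, int]
    degree_mean: float
    degree_of: Mapping[str, int]
    strength_of: Mapping[str, float]


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_dyads: int
    degree_range: tuple[int, int]
    degree_mean: float
    density: float
    modularity_q: Mapping[str, float]
    n_communities: Mapping[str, int]


def build_network(
    scans: Sequence[ScanRecord],
    radius_class: RadiusClass,
    window: tuple[int, int] | None = None,
    roster=None,
    statuses=None,
) -> WeightedNetwork:
    """Count dyadic co-scans into a weighted graph.

    Nodes that never co-occur with anyone inside the radius are dropped,
    which is why the two radii can yield different node counts.
    """
    if window is not None:
        scans = [s for s in scans if window[0] <= s.time.day <= window[1]]
    if not scans:
        raise EmptyNetworkError("no scans fall inside the requested window")

    counts: dict[tuple[str, str], int] = {}
    for scan in scans:
        in_radius = (
            scan.males_2m
            if radius_class is RadiusClass.TWO_M
            else scan.males_2m | scan.males_5m
        )
        for male in in_radius:
            key = (scan.focal_female, male)
            counts[key] = counts.get(key, 0) + 1

    g = nx.Graph()
    for (female, male), w in sorted(counts.items()):
        g.add_edge(female, male, weight=w)
        g.nodes[female]["sex"] = "F"
        g.nodes[male]["sex"] = "M"
    if roster is not None:
        for ind in roster:
            if ind.id in g:
                g.nodes[ind.id]["sex"] = ind.sex.value
                g.nodes[ind.id]["age_class"] = ind.age_class.value
    return WeightedNetwork(graph=g, radius_class=radius_class, window=window)


def density(network: WeightedNetwork) -> float:
    """Unweighted edge density: n_dyads / C(n_nodes, 2)."""
    n = network.n_nodes
    if n < 2:
        raise UndefinedMetricError("density undefined for networks with < 2 nodes")
    return network.n_dyads / (n * (n - 1) / 2)


def degree_stats(network: WeightedNetwork) -> DegreeStats:
    if network.n_nodes == 0:
        raise UndefinedMetricError("degree stats undefined for an empty network")
    degree = {node: int(d) for node, d in network.graph.degree()}
    strength = {
        node: float(s) for node, s in network.graph.degree(weight="weight")
    }
    values = sorted(degree.values())
    return DegreeStats(
        degree_range=(values[0], values[-1]),
        degree_mean=2 * network.n_dyads / network.n_nodes,
        degree_of=degree,
        strength_of=strength,
    )


def modularity(network: WeightedNetwork, partition: Partition) -> float:
    """Newman weighted modularity Q of the given partition.

    Q = (1/2m) * sum_ij (A_ij - k_i k_j / 2m) * [c_i == c_j], with weighted
    adjacency A, node strength k and total edge weight m.
    """
    missing = set(network.graph.nodes) - set(partition.community_of)
    if missing:
        raise PartitionError(f"partition does not cover nodes: {sorted(missing)}")
    m = network.graph.size(weight="weight")
    if m == 0:
        return 0.0
    strength = dict(network.graph.degree(weight="weight"))
    q = 0.0
    for u, v, w in network.graph.edges(data="weight"):
        if partition.community_of[u] == partition.community_of[v]:
            q += w / m  # both (u,v) and (v,u) in the double sum
    comm_strength: dict[int, float] = {}
    for node, label in partition.community_of.items():
        if node in strength:
            comm_strength[label] = comm_strength.get(label, 0.0) + strength[node]
    q -= sum((s / (2 * m)) ** 2 for s in comm_strength.values())
    return q


# ---------------------------------------------------------------------------
# Walktrap (short-random-walk agglomerative community detection)
# ---------------------------------------------------------------------------


def _walktrap_component(
    g: nx.Graph, nodes: list[str], t: int
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Return the merge sequence for one connected component.

    Distances come from t-step transition probability vectors; the merge
    criterion is the Ward-style increase in mean squared distance, and only
    adjacent communities may merge.  Ties break on the lexicographically
    smallest community pair, making the dendrogram deterministic.
    """
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v, w in g.subgraph(nodes).edges(data="weight"):
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    d = a.sum(axis=1)
    p = a / d[:, None]
    pt = np.linalg.matrix_power(p, t)  # row i: t-step probabilities from i

    # Community state: members, probability vector (mean of member rows),
    # adjacency between communities.
    comms: dict[int, frozenset[str]] = {i: frozenset([nodes[i]]) for i in range(n)}
    vec: dict[int, np.ndarray] = {i: pt[i].copy() for i in range(n)}
    size: dict[int, int] = {i: 1 for i in range(n)}
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for u, v in g.subgraph(nodes).edges():
        adj[idx[u]].add(idx[v])
        adj[idx[v]].add(idx[u])

    inv_d = 1.0 / d

    def delta_sigma(i: int, j: int) -> float:
        diff = vec[i] - vec[j]
        r2 = float(np.dot(diff * diff, inv_d))
        return size[i] * size[j] / (size[i] + size[j]) / n * r2

    merges: list[tuple[frozenset[str], frozenset[str]]] = []
    next_label = n
    active = set(range(n))
    while len(active) > 1:
        best = None
        best_pair = None
        for i in sorted(active):
            for j in sorted(adj[i]):
                if j <= i:
                    continue
                ds = delta_sigma(i, j)
                key = (ds, min(comms[i]), min(comms[j]))
                if best is None or key < best:
                    best = key
                    best_pair = (i, j)
        if best_pair is None:  # no adjacent pairs left (cannot happen if connected)
            break
        i, j = best_pair
        merges.append((comms[i], comms[j]))
        new = next_label
        next_label += 1
        comms[new] = comms[i] | comms[j]
        vec[new] = (size[i] * vec[i] + size[j] * vec[j]) / (size[i] + size[j])
        size[new] = size[i] + size[j]
        adj[new] = (adj[i] | adj[j]) - {i, j}
        for k in adj[new]:
            adj[k].discard(i)
            adj[k].discard(j)
            adj[k].add(new)
        for old in (i, j):
            del comms[old], vec[old], size[old], adj[old]
            active.discard(old)
        active.add(new)
    return merges


def _best_cut(network: WeightedNetwork,
              merges: list[tuple[frozenset[str], frozenset[str]]]) -> dict[str, int]:
    """Sweep a merge sequence; return the labels maximising modularity
    (ties toward fewer communities)."""
    g = network.graph
    label_of: dict[str, int] = {node: i for i, node in enumerate(sorted(g.nodes))}
    parent: dict[frozenset[str], int] = {
        frozenset([node]): label_of[node] for node in g.nodes
    }
    best_labels = dict(label_of)
    best_q = modularity(network, Partition.from_labels(label_of))
    best_ncomm = len(set(label_of.values()))
    for left, right in merges:
        target = parent[left]
        source = parent[right]
        for node, lab in label_of.items():
            if lab == source:
                label_of[node] = target
        parent[left | right] = target
        q = modularity(network, Partition.from_labels(label_of))
        ncomm = len(set(label_of.values()))
        # prefer strictly higher Q; on (near-)ties prefer fewer communities
        if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12 and ncomm < best_ncomm):
            best_q = q
            best_labels = dict(label_of)
            best_ncomm = ncomm
    return best_labels


def _refine_partition(network: WeightedNetwork, labels: dict[str, int],
                      t: int, depth: int = 0) -> dict[str, int]:
    """Deterministic modularity refinement of a labelling.

    Repeats three deterministic passes to a fixed point: best single-node
    moves, merges of adjacent communities, and walktrap-driven splits of
    individual communities (accepted only when global modularity rises).
    The exact Ward-style dendrogram can park the best cut in a local
    optimum on heterogeneous weighted graphs; this pass is what makes the
    returned partition competitive with exhaustive search on small graphs.
    """
    g = network.graph
    labels = dict(labels)

    def q_of(lbls: dict[str, int]) -> float:
        return modularity(network, Partition.from_labels(lbls))

    current_q = q_of(labels)
    improved = True
    while improved:
        improved = False
        # pass 1: single-node best moves
        moved = True
        while moved:
            moved = False
            for node in sorted(g.nodes):
                neighbour_labels = sorted({labels[nb] for nb in g.neighbors(node)})
                free = max(labels.values(), default=0) + 1
                best_lab, best_q = labels[node], current_q
                for cand in neighbour_labels + [free]:
                    if cand == labels[node]:
                        continue
                    trial = dict(labels)
                    trial[node] = cand
                    q = q_of(trial)
                    if q > best_q + 1e-12:
                        best_q, best_lab = q, cand
                if best_lab != labels[node]:
                    labels[node] = best_lab
                    current_q = best_q
                    moved = True
                    improved = True
        # pass 1b: move connected pairs together (escapes single-move traps)
        for u, v in sorted(g.edges):
            if labels[u] != labels[v]:
                continue
            free = max(labels.values()) + 1
            targets = sorted({labels[nb] for node in (u, v)
                              for nb in g.neighbors(node)} - {labels[u]})
            for cand in targets + [free]:
                trial = dict(labels)
                trial[u] = trial[v] = cand
                q = q_of(trial)
                if q > current_q + 1e-12:
                    labels, current_q = trial, q
                    improved = True
                    break
        # pass 2: merge adjacent communities
        merged = True
        while merged:
            merged = False
            pairs = sorted({
                tuple(sorted((labels[u], labels[v])))
                for u, v in g.edges
                if labels[u] != labels[v]
            })
            for la, lb in pairs:
                trial = {n: (la if l == lb else l) for n, l in labels.items()}
                q = q_of(trial)
                if q > current_q + 1e-12:
                    labels, current_q = trial, q
                    merged = True
                    improved = True
                    break
        # pass 3: try splitting each community via a nested walktrap
        if depth < 2:
            for lab in sorted(set(labels.values())):
                members = sorted(n for n, l in labels.items() if l == lab)
                if len(members) < 3:
                    continue
                sub = network.graph.subgraph(members)
                if sub.number_of_edges() == 0:
                    continue
                subnet = WeightedNetwork(graph=nx.Graph(sub),
                                         radius_class=network.radius_class)
                sub_merges = []
                for comp in sorted(nx.connected_components(subnet.graph),
                                   key=lambda c: sorted(c)[0]):
                    if len(comp) > 1:
                        sub_merges.extend(
                            _walktrap_component(subnet.graph, sorted(comp), t))
                sub_labels = _best_cut(subnet, sub_merges)
                if len(set(sub_labels.values())) <= 1:
                    continue
                offset = max(labels.values()) + 1
                trial = dict(labels)
                for n in members:
                    trial[n] = offset + sub_labels[n]
                trial_ref = _refine_partition(network, trial, t, depth + 1)
                q = q_of(trial_ref)
                if q > current_q + 1e-12:
                    labels, current_q = trial_ref, q
                    improved = True
    return labels


def walktrap(
    network: WeightedNetwork, t: int = 4, refine: bool = True
) -> tuple[list[tuple[frozenset[str], frozenset[str]]], Partition]:
    """Random-walk agglomerative community detection.

    Connected components are handled independently; the dendrogram cut is
    chosen to maximise global modularity, ties broken toward fewer
    communities, then polished by a deterministic refinement stage (see
    :func:`_refine_partition`).  Returns (merge sequence, best partition).
    """
    if t < 1:
        raise ConfigurationError("walk length t must be >= 1")
    g = network.graph
    if g.number_of_edges() == 0:
        labels = {node: i + 1 for i, node in enumerate(sorted(g.nodes))}
        return [], Partition.from_labels(labels)

    merges: list[tuple[frozenset[str], frozenset[str]]] = []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        comp_nodes = sorted(comp)
        if len(comp_nodes) == 1:
            continue
        merges.extend(_walktrap_component(g, comp_nodes, t))

    best_labels = _best_cut(network, merges)
    if refine:
        candidates = [
            _refine_partition(network, best_labels, t),
            # second deterministic start: all singletons (greedy agglomeration
            # inside the refinement escapes poor dendrogram cuts)
            _refine_partition(
                network, {node: i for i, node in enumerate(sorted(g.nodes))}, t),
        ]
        best_labels = max(
            candidates,
            key=lambda lbls: (modularity(network, Partition.from_labels(lbls)),
                              -len(set(lbls.values()))),
        )
    return merges, Partition.from_labels(best_labels)


# ---------------------------------------------------------------------------
# Potts-model simulated annealing
# ---------------------------------------------------------------------------


def _potts_energy_terms(network: WeightedNetwork, gamma: float):
    nodes = network.nodes()
    idx = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    strength = np.zeros(n)
    neighbours: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for u, v, w in network.graph.edges(data="weight"):
        iu, iv = idx[u], idx[v]
        strength[iu] += w
        strength[iv] += w
        neighbours[iu].append((iv, float(w)))
        neighbours[iv].append((iu, float(w)))
    two_m = strength.sum()
    return nodes, strength, neighbours, two_m


def potts_communities(
    network: WeightedNetwork,
    gamma: float = 1.0,
    schedule: Mapping[str, float] | None = None,
    seed: int = 0,
    restarts: int = 20,
) -> Partition:
    """Minimise the configuration-null Potts Hamiltonian by annealing.

    At gamma = 1 this is equivalent to maximising Newman modularity.  The
    annealer uses geometric cooling with single-node label moves, followed
    by a greedy polish; the best of ``restarts`` independent runs is
    returned.  Fully reproducible given ``seed``.
    """
    if gamma <= 0:
        raise ConfigurationError("gamma must be positive")
    if network.n_nodes == 0:
        raise EmptyNetworkError("cannot partition an empty network")
    sched = {"t_start": 1.0, "t_end": 0.005, "cooling": 0.95, "sweeps_per_t": 10}
    if schedule:
        sched.update(schedule)

    nodes, strength, neighbours, two_m = _potts_energy_terms(network, gamma)
    n = len(nodes)
    if two_m == 0:
        return Partition.from_labels({node: i + 1 for i, node in enumerate(nodes)})

    def energy_delta(labels, comm_strength, i, new_lab):
        old_lab = labels[i]
        if new_lab == old_lab:
            return 0.0
        w_old = w_new = 0.0
        for j, w in neighbours[i]:
            if labels[j] == old_lab:
                w_old += w
            elif labels[j] == new_lab:
                w_new += w
        k = strength[i]
        null_old = gamma * k * (comm_strength[old_lab] - k) / two_m
        null_new = gamma * k * comm_strength[new_lab] / two_m
        # leaving old community: +w_old - null_old ; joining new: -w_new + null_new
        return (w_old - null_old) + (null_new - w_new)

    best_labels = None
    best_h = np.inf
    max_labels = min(n, 25)
    for restart in range(restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0x506F7474, restart])
        )
        labels = rng.integers(0, max_labels, size=n)
        comm_strength = np.zeros(max_labels)
        for i in range(n):
            comm_strength[labels[i]] += strength[i]
        temp = sched["t_start"]
        while temp > sched["t_end"]:
            for _ in range(int(sched["sweeps_per_t"])):
                for i in rng.permutation(n):
                    new_lab = int(rng.integers(max_labels))
                    dh = energy_delta(labels, comm_strength, i, new_lab)
                    if dh <= 0 or rng.random() < np.exp(-dh / temp):
                        comm_strength[labels[i]] -= strength[i]
                        labels[i] = new_lab
                        comm_strength[new_lab] += strength[i]
            temp *= sched["cooling"]
        # greedy polish: move nodes while any single move lowers H
        improved = True
        while improved:
            improved = False
            for i in range(n):
                candidates = {labels[j] for j, _ in neighbours[i]}
                candidates.add(int((comm_strength == 0).argmax()))  # an empty label
                best_dh, best_lab = 0.0, labels[i]
                for lab in sorted(candidates):
                    dh = energy_delta(labels, comm_strength, i, lab)
                    if dh < best_dh - 1e-12:
                        best_dh, best_lab = dh, lab
                if best_lab != labels[i]:
                    comm_strength[labels[i]] -= strength[i]
                    labels[i] = best_lab
                    comm_strength[best_lab] += strength[i]
                    improved = True
        h = 0.0
        for i in range(n):
            for j, w in neighbours[i]:
                if j > i and labels[i] == labels[j]:
                    h -= w
        for lab in np.unique(labels):
            s = strength[labels == lab]
            tot = s.sum()
            h += gamma * (tot * tot - np.dot(s, s)) / (2.0 * two_m)
        if h < best_h - 1e-12:
            best_h = h
            best_labels = labels.copy()
    assert best_labels is not None
    return Partition.from_labels({nodes[i]: int(best_labels[i]) for i in range(n)})


def pairing_success(
    network: WeightedNetwork,
    partition: Partition,
    primary_of: Mapping[str, str],
) -> float:
    """Fraction of females co-assigned with their primary male.

    Only informative for multi-community partitions: a single community
    trivially scores 1.0.  Females whose primary male is absent from the
    network count as failures (logged).
    """
    females = [f for f in primary_of if f in partition.community_of]
    if not females:
        raise UndefinedMetricError("no females with a primary male appear in the partition")
    hits = 0
    for female in females:
        male = primary_of[female]
        if male not in partition.community_of:
            logger.warning("primary male %s of %s absent from network; counted as failure",
                           male, female)
            continue
        if partition.community_of[female] == partition.community_of[male]:
            hits += 1
    return hits / len(females)


def network_metrics(
    network: WeightedNetwork, partitions: Mapping[str, Partition] | None = None
) -> NetworkMetrics:
    stats = degree_stats(network)
    partitions = partitions or {}
    return NetworkMetrics(
        n_nodes=network.n_nodes,
        n_dyads=network.n_dyads,
        degree_range=stats.degree_range,
        degree_mean=stats.degree_mean,
        density=density(network),
        modularity_q={name: modularity(network, p) for name, p in partitions.items()},
        n_communities={name: p.n_communities for name, p in partitions.items()},
    )


def write_edgelist_csv(path: str | Path, network: WeightedNetwork) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["female", "male", "weight"])
        for u, v, w in sorted(network.graph.edges(data="weight")):
            female, male = (u, v) if network.graph.nodes[u].get("sex") == "F" else (v, u)
            writer.writerow([female, male, w])


def write_graphml(path: str | Path, network: WeightedNetwork,
                  partition: Partition | None = None) -> None:
    g = network.graph.copy()
    if partition is not None:
        for node in g.nodes:
            g.nodes[node]["community"] = partition.community_of.get(node, 0)
    nx.write_graphml(g, path)
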