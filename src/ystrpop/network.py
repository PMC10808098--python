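"""Median-joining networks for Y-STR haplotypes.

Implements the Bandelt–Forster–Röhl median-joining construction:

1. build the epsilon-relaxed minimum spanning network (MSN) over the
   current haplotype set under weighted single-step distances
   d(u, v) = Σ_l w_l |u_l − v_l|;
2. for every triple (u, v, w) in which v and w are both MSN neighbors
   of u, form the per-locus median (for integer repeat counts the
   median of three values is unique, so no tie rule is needed); collect
   novel medians and add those whose connection cost to their triple is
   within epsilon of the minimum;
3. repeat until no median vector is added;
4. prune obsolete median vectors (degree ≤ 1 in the rebuilt MSN),
   iterating to a fixed point.

Loci are weighted inversely to their repeat variance, the convention
for Y-STR networks (a highly mutable locus should count less toward a
link). Reported "mutational steps" on edges are always the unweighted
step counts Σ_l |Δ|; weights enter only link selection.

All iteration orders are lexicographic in the haplotype vectors, so
the network is a deterministic function of the input set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .exceptions import ValidationError
from .io import HaplotypeTable, filter_complete

Haplotype = tuple[int, ...]


@dataclass(frozen=True)
class LocusWeights:
    """Positive per-locus weights for network link selection."""

    weights: dict[str, int]

    def __post_init__(self) -> None:
        for locus, w in self.weights.items():
            if not (0 < w < float("inf")):
                raise ValidationError(f"weight for {locus} must be positive, got {w}")

    def vector(self, panel) -> np.ndarray:
        missing = [l for l in panel if l not in self.weights]
        if missing:
            raise LookupError(f"no weight for loci: {missing}")
        return np.array([self.weights[l] for l in panel], dtype=np.int64)


def locus_weights_inverse_variance(
    table: HaplotypeTable, cap: int = 10
) -> LocusWeights:
    """Weights proportional to 1/variance, on a 1..cap integer scale.

    The least variable polymorphic locus gets the cap; others scale down
    in proportion (so variances 1.0 and 2.0 give weights in ratio 2:1).
    Monomorphic loci have no variance signal and receive the cap.
    """
    table.require_normalized("locus_weights_inverse_variance")
    complete = filter_complete(table)
    if len(complete) < 2:
        raise ValidationError("inverse-variance weights need >= 2 complete records")
    X = complete.matrix().astype(float)
    var = X.var(axis=0, ddof=1)
    weights: dict[str, int] = {}
    poly = var[var > 0]
    vmin = poly.min() if len(poly) else None
    for locus, v in zip(complete.panel, var):
        if v <= 0:
            weights[locus] = cap
        else:
            weights[locus] = int(np.clip(round(cap * vmin / v), 1, cap))
    return LocusWeights(weights=weights)


def pairwise_steps(h1, h2) -> tuple[tuple[int, ...], int]:
    """Per-locus and total mutational steps between two haplotypes."""
    a, b = np.asarray(h1, dtype=np.int64), np.asarray(h2, dtype=np.int64)
    if a.shape != b.shape:
        raise ValidationError("haplotypes typed on different panels")
    diffs = np.abs(a - b)
    return tuple(int(d) for d in diffs), int(diffs.sum())


def _wdist(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> int:
    return int(np.abs(a - b) @ w)


def _minimum_spanning_network(
    nodes: list[Haplotype], w: np.ndarray, epsilon: int
) -> set[frozenset]:
    """Edges of the epsilon-relaxed minimum spanning network.

    A link (u, v) belongs iff d(u, v) ≤ λ(u, v) + epsilon, where
    λ(u, v) is the smallest distance level at which u and v fall into
    one connected component of the level filtration (for epsilon = 0
    this is exactly the union of all minimum spanning trees).
    """
    n = len(nodes)
    arr = [np.asarray(h, dtype=np.int64) for h in nodes]
    dist = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[(i, j)] = _wdist(arr[i], arr[j], w)

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    lam = {}
    levels = sorted(set(dist.values()))
    for level in levels:
        for (i, j), d in dist.items():
            if d == level:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
        for pair in dist:
            if pair not in lam and find(pair[0]) == find(pair[1]):
                lam[pair] = level

    edges = set()
    for pair, d in dist.items():
        if d <= lam[pair] + epsilon:
            edges.add(frozenset((nodes[pair[0]], nodes[pair[1]])))
    return edges


def _median_triple(u: np.ndarray, v: np.ndarray, t: np.ndarray) -> Haplotype:
    stacked = np.stack([u, v, t])
    return tuple(int(x) for x in np.median(stacked, axis=0).astype(np.int64))


def _mj_node_set(
    observed: list[Haplotype], w: np.ndarray, epsilon: int
) -> tuple[list[Haplotype], set[frozenset]]:
    """Run the MJ iteration; return final nodes and MSN edges."""
    current: list[Haplotype] = sorted(set(observed))
    observed_set = set(observed)
    while True:
        edges = _minimum_spanning_network(current, w, epsilon)
        adjacency: dict[Haplotype, list[Haplotype]] = {h: [] for h in current}
        for e in edges:
            a, b = sorted(e)
            adjacency[a].append(b)
            adjacency[b].append(a)
        candidates: dict[Haplotype, int] = {}
        known = set(current)
        for u in current:
            u_arr = np.asarray(u, dtype=np.int64)
            for v, t in itertools.combinations(sorted(adjacency[u]), 2):
                m = _median_triple(
                    u_arr,
                    np.asarray(v, dtype=np.int64),
                    np.asarray(t, dtype=np.int64),
                )
                if m in known:
                    continue
                m_arr = np.asarray(m, dtype=np.int64)
                cost = (
                    _wdist(m_arr, u_arr, w)
                    + _wdist(m_arr, np.asarray(v, dtype=np.int64), w)
                    + _wdist(m_arr, np.asarray(t, dtype=np.int64), w)
                )
                if m not in candidates or cost < candidates[m]:
                    candidates[m] = cost
        if not candidates:
            break
        cmin = min(candidates.values())
        new = sorted(m for m, c in candidates.items() if c <= cmin + epsilon)
        current = sorted(set(current) | set(new))

    # prune median vectors that end up peripheral (degree <= 1)
    while True:
        edges = _minimum_spanning_network(current, w, epsilon)
        degree: dict[Haplotype, int] = {h: 0 for h in current}
        for e in edges:
            for h in e:
                degree[h] += 1
        drop = [
            h for h in current if h not in observed_set and degree[h] <= 1
        ]
        if not drop:
            break
        current = [h for h in current if h not in drop]
    return current, edges


def median_joining(
    table: HaplotypeTable,
    weights: LocusWeights | None = None,
    epsilon: int = 0,
) -> nx.Graph:
    """Median-joining network of a normalized haplotype table.

    Returns a networkx Graph whose nodes are haplotype tuples with
    attributes ``label`` (H1.., mv1..), ``count``, ``populations``
    (label → multiplicity) and ``is_median``; edges carry ``steps``
    (unweighted Σ|Δ|), ``weight`` (weighted length) and ``locus_diffs``.
    """
    return MedianJoiningNetwork(epsilon=epsilon, weights=weights).fit(table).graph_


class MedianJoiningNetwork:
    """Median-joining network estimator (fit once, query the graph).

    Parameters
    ----------
    epsilon : int
        Relaxation of the spanning network and of median admission;
        0 reproduces the strict minimum spanning network backbone.
    weights : LocusWeights, dict, "inverse_variance" or None
        Per-locus link weights. The string (default) derives them from
        the fitted table's repeat variances; None means unit weights.
    weight_cap : int
        Cap for the inverse-variance rescaling.

    Attributes
    ----------
    graph_ : networkx.Graph
        The network (see :func:`median_joining` for the attribute schema).
    weights_ : LocusWeights
        Weights actually used.
    n_median_vectors_ : int
        Median (inferred, unsampled) haplotypes retained after pruning.
    """

    def __init__(
        self,
        epsilon: int = 0,
        weights="inverse_variance",
        weight_cap: int = 10,
    ):
        self.epsilon = epsilon
        self.weights = weights
        self.weight_cap = weight_cap

    def get_params(self, deep: bool = True) -> dict:
        return {
            "epsilon": self.epsilon,
            "weights": self.weights,
            "weight_cap": self.weight_cap,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _resolve_weights(self, table: HaplotypeTable) -> LocusWeights:
        if isinstance(self.weights, LocusWeights):
            return self.weights
        if isinstance(self.weights, dict):
            return LocusWeights(weights=dict(self.weights))
        if self.weights == "inverse_variance":
            try:
                return locus_weights_inverse_variance(table, cap=self.weight_cap)
            except ValidationError:
                return LocusWeights(weights={l: 1 for l in table.panel})
        if self.weights is None:
            return LocusWeights(weights={l: 1 for l in table.panel})
        raise ValueError(f"unrecognized weights spec {self.weights!r}")

    def fit(self, X, y=None):
        if not isinstance(X, HaplotypeTable):
            raise TypeError("MedianJoiningNetwork.fit expects a HaplotypeTable")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        X.require_normalized("median_joining")
        complete = filter_complete(X)
        if len(complete) == 0:
            raise ValidationError("median_joining needs >= 1 complete haplotype")

        weights = self._resolve_weights(complete)
        w = weights.vector(complete.panel)
        M = complete.matrix()
        pops = complete.populations.to_numpy()
        observed: list[Haplotype] = [tuple(int(x) for x in row) for row in M]

        node_pops: dict[Haplotype, dict[str, int]] = {}
        for hap, pop in zip(observed, pops):
            node_pops.setdefault(hap, {})
            node_pops[hap][pop] = node_pops[hap].get(pop, 0) + 1

        nodes, edges = _mj_node_set(observed, w, self.epsilon)

        graph = nx.Graph(epsilon=self.epsilon, panel=",".join(complete.panel))
        n_obs = n_med = 0
        for hap in nodes:
            if hap in node_pops:
                n_obs += 1
                graph.add_node(
                    hap,
                    label=f"H{n_obs}",
                    count=sum(node_pops[hap].values()),
                    populations=dict(sorted(node_pops[hap].items())),
                    is_median=False,
                )
            else:
                n_med += 1
                graph.add_node(
                    hap,
                    label=f"mv{n_med}",
                    count=0,
                    populations={},
                    is_median=True,
                )
        for e in sorted(tuple(sorted(e)) for e in edges):
            a, b = e
            diffs, steps = pairwise_steps(a, b)
            graph.add_edge(
                a,
                b,
                steps=steps,
                weight=_wdist(
                    np.asarray(a, dtype=np.int64), np.asarray(b, dtype=np.int64), w
                ),
                locus_diffs=diffs,
            )

        self.graph_ = graph
        self.weights_ = weights
        self.n_median_vectors_ = n_med
        return self


def group_separation(network: nx.Graph, group_a, group_b) -> int:
    """Minimum mutational steps between haplotypes of two population groups.

    ``group_a`` / ``group_b`` are sets of population labels; the result
    is the minimum over (a-bearing node, b-bearing node) pairs of the
    shortest-path length through the network with edge length = steps.
    A haplotype shared by both groups gives 0.
    """
    group_a, group_b = set(group_a), set(group_b)

    def bearing(group):
        return [
            n
            for n, d in network.nodes(data=True)
            if set(d.get("populations", {})) & group
        ]

    nodes_a, nodes_b = bearing(group_a), bearing(group_b)
    if not nodes_a:
        raise ValidationError(f"no network node carries populations {sorted(group_a)}")
    if not nodes_b:
        raise ValidationError(f"no network node carries populations {sorted(group_b)}")
    if set(nodes_a) & set(nodes_b):
        return 0
    lengths = nx.multi_source_dijkstra_path_length(network, nodes_a, weight="steps")
    return int(min(lengths[n] for n in nodes_b if n in lengths))


# ----------------------------------------------------------------------
# export / import
# ----------------------------------------------------------------------
def _serialize(graph: nx.Graph) -> nx.Graph:
    """Copy with node keys and attrs flattened to GraphML-safe scalars."""
    out = nx.Graph(**graph.graph)
    for hap, d in graph.nodes(data=True):
        out.add_node(
            d["label"],
            haplotype=",".join(str(x) for x in hap),
            count=int(d["count"]),
            populations=";".join(f"{p}:{c}" for p, c in d["populations"].items()),
            is_median=bool(d["is_median"]),
        )
    for a, b, d in graph.edges(data=True):
        out.add_edge(
            graph.nodes[a]["label"],
            graph.nodes[b]["label"],
            steps=int(d["steps"]),
            weight=int(d["weight"]),
        )
    return out


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(_serialize(graph), path)


def read_graphml(path) -> nx.Graph:
    """Read a network written by :func:`write_graphml` back into the
    haplotype-keyed representation."""
    flat = nx.read_graphml(path)
    out = nx.Graph(**flat.graph)
    key = {}
    for label, d in flat.nodes(data=True):
        hap = tuple(int(x) for x in d["haplotype"].split(","))
        key[label] = hap
        pops = {}
        if d.get("populations"):
            for item in d["populations"].split(";"):
                p, c = item.rsplit(":", 1)
                pops[p] = int(c)
        out.add_node(
            hap,
            label=label,
            count=int(d["count"]),
            populations=pops,
            is_median=bool(d["is_median"]),
        )
    for a, b, d in flat.edges(data=True):
        ha, hb = key[a], key[b]
        diffs, steps = pairwise_steps(ha, hb)
        out.add_edge(ha, hb, steps=int(d["steps"]), weight=int(d["weight"]),
                     locus_diffs=diffs)
    return out


def write_dot(graph: nx.Graph, path) -> None:
    """Minimal DOT export (node label/size class, edge step count)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("graph mj_network {\n")
        for hap, d in graph.nodes(data=True):
            shape = "point" if d["is_median"] else "circle"
            pops = ";".join(f"{p}:{c}" for p, c in d["populations"].items())
            fh.write(
                f'  "{d["label"]}" [shape={shape}, count={d["count"]}, '
                f'populations="{pops}"];\n'
            )
        for a, b, d in graph.edges(data=True):
            fh.write(
                f'  "{graph.nodes[a]["label"]}" -- "{graph.nodes[b]["label"]}" '
                f'[label={d["steps"]}];\n'
            )
        fh.write("}\n")


__all__ = [
    "LocusWeights",
    "locus_weights_inverse_variance",
    "pairwise_steps",
    "median_joining",
    "MedianJoiningNetwork",
    "group_separation",
    "write_graphml",
    "read_graphml",
    "write_dot",
]
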