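"""Spanning-tree analysis of the top-level graph under mutation.

Vertex weights (one descriptor-derived entry per substructure) are turned
into edge weights — each edge gets the sum, or the average, of its two
endpoint weights; the two schemes differ by a factor of two and therefore
always produce the same minimum spanning tree.  The MST is computed with
deterministic tie-breaking, and its uniqueness is decided exactly: a
spanning tree of minimum total weight is the *only* one iff every non-tree
edge is strictly heavier than the heaviest tree edge on the cycle it closes.

The mutation-resampling experiment repeatedly draws random subsets of a
mutation list, applies them as weight-only mutants, and records the MST
vertex degrees; substructures whose degree never moves are "stable" under
mutation, the rest "sensitive".  The sampling design is summarized by the
expected number of occurrences of each mutation across the experiment
(samples × sample size / number of mutations), the quantity used to choose
samples and sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .hierarchy import HierarchicalGraph
from .mutations import MutationSpec, reweight_mutant
from .residues import DescriptorTable

__all__ = [
    "vertex_to_edge_weights",
    "MSTResult",
    "minimum_spanning_tree",
    "mst_for_mutations",
    "suggest_resampling_design",
    "ResamplingReport",
    "mutation_resampling",
    "stability_classification",
]

_TIE_ATOL = 1e-12


def vertex_to_edge_weights(g: nx.Graph, descriptor: str, scheme: str = "sum") -> nx.Graph:
    """Edge-weighted copy of a vertex-weighted graph.

    ``descriptor`` names an entry of each vertex's ``weights`` vector (for a
    plain node attribute graph, the attribute itself).  Each edge
    ``{u, v}`` receives ``w(u)+w(v)`` (scheme ``"sum"``) or
    ``(w(u)+w(v))/2`` (scheme ``"average"``); vertex weights are kept
    alongside under ``"weight"``.
    """
    if scheme not in ("sum", "average"):
        raise ValueError(f"unknown scheme {scheme!r}; use 'sum' or 'average'")
    out = nx.Graph(**g.graph)
    for v, data in g.nodes(data=True):
        if "weights" in data:
            if descriptor not in data["weights"]:
                raise ValueError(f"vertex {v!r} has no descriptor {descriptor!r}")
            w = float(data["weights"][descriptor])
        elif descriptor in data:
            w = float(data[descriptor])
        else:
            raise ValueError(f"vertex {v!r} has no descriptor {descriptor!r}")
        out.add_node(v, weight=w)
    for u, v in g.edges:
        s = out.nodes[u]["weight"] + out.nodes[v]["weight"]
        out.add_edge(u, v, weight=s if scheme == "sum" else s / 2.0)
    return out


@dataclass
class MSTResult:
    """A minimum (or maximum) spanning tree with exact uniqueness flag."""

    edges: list[tuple]
    total_weight: float
    unique: bool
    degrees: dict = field(default_factory=dict)

    @property
    def tree(self) -> nx.Graph:
        t = nx.Graph()
        t.add_nodes_from(self.degrees)
        t.add_edges_from(self.edges)
        return t


def _sorted_edge(u, v) -> tuple:
    return (u, v) if repr(u) <= repr(v) else (v, u)


def minimum_spanning_tree(
    g: nx.Graph, weight: str = "weight", maximize: bool = False
) -> MSTResult:
    """Kruskal MST with lexicographic tie-breaking and exact uniqueness.

    Edges are greedily taken in ``(weight, endpoint labels)`` order, making
    the returned tree reproducible across platforms.  ``unique`` is decided
    by the cycle property: the minimum spanning tree is unique iff every
    non-tree edge is strictly heavier than every tree edge on the tree path
    between its endpoints (ties within ``1e-12`` count as equal).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("spanning tree undefined on the empty graph")
    if not nx.is_connected(g):
        comps = [sorted(c, key=repr) for c in nx.connected_components(g)]
        raise ValueError(f"graph is disconnected; components: {comps}")
    sign = -1.0 if maximize else 1.0
    edges = sorted(
        ((float(d[weight]), *_sorted_edge(u, v)) for u, v, d in g.edges(data=True)),
        key=lambda e: (sign * e[0], repr(e[1]), repr(e[2])),
    )
    parent = {v: v for v in g}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree_edges: list[tuple] = []
    t = nx.Graph()
    t.add_nodes_from(g)
    for w, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree_edges.append((u, v))
            t.add_edge(u, v, **{weight: w})

    # uniqueness via the cycle property on the signed weights
    wmap = {_sorted_edge(u, v): sign * float(d[weight]) for u, v, d in g.edges(data=True)}
    tset = {_sorted_edge(u, v) for u, v in tree_edges}
    unique = True
    for key, w in wmap.items():
        if key in tset:
            continue
        path = nx.shortest_path(t, key[0], key[1])
        heaviest = max(
            wmap[_sorted_edge(path[i], path[i + 1])] for i in range(len(path) - 1)
        )
        if w <= heaviest + _TIE_ATOL:
            unique = False
            break
    return MSTResult(
        edges=[_sorted_edge(u, v) for u, v in tree_edges],
        total_weight=sign * sum(wmap[_sorted_edge(u, v)] for u, v in tree_edges),
        unique=unique,
        degrees={v: int(t.degree[v]) for v in g},
    )


def mst_for_mutations(
    h: HierarchicalGraph,
    specs: list[MutationSpec],
    table: DescriptorTable,
    descriptor: str,
    scheme: str = "sum",
    maximize: bool = False,
) -> MSTResult:
    """MST of the top-level graph after a weight-only mutant reweighting.

    The top-level edge set is the wild-type one throughout — this mode never
    changes topology, only vertex weights.
    """
    mut = reweight_mutant(h, specs, table) if specs else h
    gw = vertex_to_edge_weights(mut.top, descriptor, scheme)
    return minimum_spanning_tree(gw, maximize=maximize)


def suggest_resampling_design(
    n_mutations: int, expectation: float = 2.5, sample_size: int | None = None
) -> tuple[int, int]:
    """(samples, sample size) so each mutation is expected ``expectation`` times.

    Expected occurrences of one mutation = samples × sample size / mutation
    count.  With the default, half of the mutations are drawn per sample.
    """
    if n_mutations < 1:
        raise ValueError("need at least one mutation")
    if sample_size is None:
        sample_size = max(1, math.ceil(n_mutations / 2))
    sample_size = min(sample_size, n_mutations)
    samples = max(1, round(expectation * n_mutations / sample_size))
    return samples, sample_size


@dataclass
class ResamplingReport:
    """Per-vertex MST degree statistics across mutation resamples."""

    stats: pd.DataFrame  # index: vertex label; columns: mean_degree, sd_degree
    samples: int
    sample_size: int
    n_mutations: int
    seed: int
    descriptor: str
    scheme: str

    @property
    def expected_occurrences(self) -> float:
        return self.samples * self.sample_size / self.n_mutations

    def to_csv(self) -> str:
        df = self.stats.copy()
        df.index.name = "vertex"
        return df.to_csv(float_format="%.10g")


def mutation_resampling(
    h: HierarchicalGraph,
    specs: list[MutationSpec],
    samples: int,
    sample_size: int,
    seed: int,
    table: DescriptorTable,
    descriptor: str,
    scheme: str = "sum",
) -> ResamplingReport:
    """Degree-stability experiment over random mutation subsets.

    Each resample draws ``sample_size`` mutations uniformly without
    replacement (a mutation set, not a multiset), computes the weight-only
    mutant MST and records the vertex degrees.  Reports the per-vertex mean
    and population standard deviation.  Deterministic given ``seed``.
    """
    if not specs:
        raise ValueError("no mutations supplied")
    if sample_size > len(specs):
        raise ValueError(f"sample size {sample_size} exceeds mutation count {len(specs)}")
    rng = np.random.default_rng(seed)
    labels = sorted(h.top.nodes, key=repr)
    rows = np.empty((samples, len(labels)), dtype=float)
    for s in range(samples):
        pick = rng.choice(len(specs), size=sample_size, replace=False)
        subset = [specs[i] for i in sorted(pick)]
        result = mst_for_mutations(h, subset, table, descriptor, scheme)
        rows[s] = [result.degrees[v] for v in labels]
    stats = pd.DataFrame(
        {"mean_degree": rows.mean(axis=0), "sd_degree": rows.std(axis=0, ddof=0)},
        index=labels,
    )
    return ResamplingReport(
        stats=stats,
        samples=samples,
        sample_size=sample_size,
        n_mutations=len(specs),
        seed=seed,
        descriptor=descriptor,
        scheme=scheme,
    )


def stability_classification(
    report: ResamplingReport, tolerance: float = 0.0
) -> dict[str, list]:
    """Partition vertices into mutation-stable and mutation-sensitive.

    A vertex is stable when the standard deviation of its MST degree across
    resamples is at most ``tolerance`` (default 0: the degree never moved).
    """
    stable = [v for v, sd in report.stats["sd_degree"].items() if sd <= tolerance]
    sensitive = [v for v in report.stats.index if v not in stable]
    return {"stable": stable, "sensitive": sensitive}
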