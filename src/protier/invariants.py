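"""Vertex-weighted graph invariants.

Classical graph invariants (degree, domination number, distance, diameter,
periphery) generalize to vertex-weighted graphs by replacing set cardinality
with total vertex weight: with all weights equal to one, every weighted
invariant reduces to its classical counterpart.  The definitions used here:

* weighted degree of ``v``: sum of the weights of the neighbors of ``v``;
* weighted domination number: minimum total weight over dominating sets
  (lower) and maximum total weight over *minimal* dominating sets (upper);
* weighted length of a path: sum of vertex weights along it excluding the
  start vertex, so unit weights recover the edge count.  Weighted distance,
  eccentricity, diameter and periphery follow from this length.  Because the
  start vertex is excluded the distance is directed; the diameter is taken
  over ordered pairs;
* circumference: number of vertices in a longest simple cycle (0 if acyclic),
  kept unweighted.

All algorithms are exact.  Domination and circumference are solved by
branch-and-bound searches that are exponential in the worst case but fast on
the small graphs that arise here (residue graphs have at most 14 heavy atoms;
substructure contact graphs a few dozen residues).  A separate brute-force
oracle (:func:`brute_force_oracle`) recomputes every invariant by exhaustive
enumeration for graphs with at most 14 vertices and is used to validate the
optimized routines.

Graphs are :class:`networkx.Graph` instances whose nodes carry a numeric
weight attribute (default ``"weight"``).
"""

from __future__ import annotations

import math
from typing import Hashable, Iterable, Iterator

import networkx as nx

__all__ = [
    "weighted_degree",
    "max_weighted_degree",
    "average_weighted_degree",
    "minimal_dominating_sets",
    "weighted_domination",
    "domination_from_minimal_sets",
    "weighted_distance",
    "weighted_eccentricity",
    "weighted_diameter",
    "weighted_periphery",
    "circumference",
    "brute_force_oracle",
]

#: Absolute tolerance for comparing weighted eccentricities against the
#: diameter when extracting the periphery (guards against float summation
#: order effects; weights are typically table values summed a few times).
_ECC_ATOL = 1e-9


def _weights(g: nx.Graph, weight: str) -> dict[Hashable, float]:
    try:
        return {v: float(g.nodes[v][weight]) for v in g}
    except KeyError as exc:
        raise ValueError(f"vertex {exc.args[0]!r} has no {weight!r} attribute") from exc


def _require_nonnegative(w: dict[Hashable, float], what: str) -> None:
    bad = [v for v, x in w.items() if x < 0 or not math.isfinite(x)]
    if bad:
        raise ValueError(
            f"{what} requires finite non-negative vertex weights; "
            f"offending vertices: {bad[:5]}"
        )


def _require_nonempty(g: nx.Graph) -> None:
    if g.number_of_nodes() == 0:
        raise ValueError("invariant undefined on the empty graph")


# ---------------------------------------------------------------------------
# degree family
# ---------------------------------------------------------------------------

def weighted_degree(g: nx.Graph, v: Hashable, weight: str = "weight") -> float:
    """Sum of the weights of the neighbors of ``v``."""
    if v not in g:
        raise KeyError(f"vertex {v!r} not in graph")
    # fsum: exact regardless of neighbor iteration order, so the value is
    # invariant under vertex relabeling
    return math.fsum(g.nodes[u][weight] for u in g[v])


def max_weighted_degree(g: nx.Graph, weight: str = "weight") -> float:
    """Maximum weighted degree over all vertices."""
    _require_nonempty(g)
    return max(weighted_degree(g, v, weight) for v in g)


def average_weighted_degree(g: nx.Graph, weight: str = "weight") -> float:
    """Arithmetic mean of the weighted degrees."""
    _require_nonempty(g)
    return math.fsum(weighted_degree(g, v, weight) for v in g) / g.number_of_nodes()


# ---------------------------------------------------------------------------
# domination
# ---------------------------------------------------------------------------

def minimal_dominating_sets(g: nx.Graph) -> list[frozenset]:
    """Enumerate all minimal dominating sets of ``g``.

    A dominating set is minimal when no proper subset dominates.  The search
    branches on the closed neighborhood of the first undominated vertex; each
    branch commits one neighbor and excludes the neighbors already tried, so
    every dominating set is generated at most once.  Sets that end up
    non-minimal (a committed vertex made redundant later) are filtered out.

    Depends only on the topology, so callers evaluating several weightings of
    one graph can enumerate once and score with
    :func:`domination_from_minimal_sets`.
    """
    _require_nonempty(g)
    nodes = sorted(g, key=repr)
    closed = {v: frozenset(g[v]) | {v} for v in nodes}
    out: list[frozenset] = []

    def is_minimal(s: frozenset) -> bool:
        for v in s:
            rest = s - {v}
            covered = set()
            for u in rest:
                covered |= closed[u]
            if covered >= set(nodes):
                return False
        return True

    def rec(chosen: set, dominated: set, excluded: set) -> None:
        target = next((v for v in nodes if v not in dominated), None)
        if target is None:
            s = frozenset(chosen)
            if is_minimal(s):
                out.append(s)
            return
        tried: set = set()
        for u in sorted(closed[target], key=repr):
            if u in excluded:
                continue
            chosen.add(u)
            rec(chosen, dominated | closed[u], excluded | tried)
            chosen.remove(u)
            tried.add(u)

    rec(set(), set(), set())
    return out


def domination_from_minimal_sets(
    sets: Iterable[frozenset], weights: dict[Hashable, float]
) -> tuple[float, float]:
    """(lower, upper) weighted domination from pre-enumerated minimal sets.

    With non-negative weights the minimum over *all* dominating sets is
    attained on a minimal one (every dominating set contains a minimal subset
    of no greater weight), so the lower number is the minimum over minimal
    sets; the upper number is the maximum over minimal sets by definition.
    """
    totals = [math.fsum(weights[v] for v in s) for s in sets]
    if not totals:
        raise ValueError("no dominating sets supplied")
    return min(totals), max(totals)


def weighted_domination(g: nx.Graph, weight: str = "weight") -> tuple[float, float]:
    """Weighted (lower, upper) domination numbers of ``g``.

    lower: minimum total vertex weight over all dominating sets.
    upper: maximum total vertex weight over all minimal dominating sets.
    """
    w = _weights(g, weight)
    _require_nonnegative(w, "weighted domination")
    return domination_from_minimal_sets(minimal_dominating_sets(g), w)


# ---------------------------------------------------------------------------
# weighted distances
# ---------------------------------------------------------------------------

def _distance_digraph(g: nx.Graph, weight: str) -> nx.DiGraph:
    # Path length excludes the start vertex, i.e. every step into a vertex
    # pays that vertex's weight: encode as a digraph with edge weight equal
    # to the weight of the head vertex and run ordinary Dijkstra.
    w = _weights(g, weight)
    _require_nonnegative(w, "weighted distance")
    d = nx.DiGraph()
    d.add_nodes_from(g)
    for u, v in g.edges:
        d.add_edge(u, v, cost=w[v])
        d.add_edge(v, u, cost=w[u])
    return d


def weighted_distance(g: nx.Graph, u: Hashable, v: Hashable, weight: str = "weight") -> float:
    """Minimum weighted path length from ``u`` to ``v`` (start vertex excluded)."""
    d = _distance_digraph(g, weight)
    try:
        return float(nx.dijkstra_path_length(d, u, v, weight="cost"))
    except nx.NetworkXNoPath:
        raise ValueError(f"no path between {u!r} and {v!r}") from None


def _all_eccentricities(g: nx.Graph, weight: str) -> dict[Hashable, float]:
    if not nx.is_connected(g):
        comps = [sorted(c, key=repr) for c in nx.connected_components(g)]
        raise ValueError(f"graph is disconnected; components: {comps}")
    d = _distance_digraph(g, weight)
    ecc = {}
    for v in g:
        lengths = nx.single_source_dijkstra_path_length(d, v, weight="cost")
        ecc[v] = max(lengths[u] for u in g)
    return ecc


def weighted_eccentricity(g: nx.Graph, v: Hashable, weight: str = "weight") -> float:
    """Maximum weighted distance from ``v`` to any vertex."""
    return _all_eccentricities(g, weight)[v]


def weighted_diameter(g: nx.Graph, weight: str = "weight") -> float:
    """Maximum weighted distance over all ordered vertex pairs."""
    _require_nonempty(g)
    return max(_all_eccentricities(g, weight).values())


def weighted_periphery(g: nx.Graph, weight: str = "weight") -> frozenset:
    """Vertices whose weighted eccentricity attains the weighted diameter."""
    ecc = _all_eccentricities(g, weight)
    diam = max(ecc.values())
    return frozenset(v for v, e in ecc.items() if abs(e - diam) <= _ECC_ATOL)


# ---------------------------------------------------------------------------
# circumference
# ---------------------------------------------------------------------------

def circumference(g: nx.Graph) -> int:
    """Number of vertices in a longest simple cycle; 0 for acyclic graphs.

    Exact depth-first search over simple paths, anchored at the minimum
    vertex of each candidate cycle to avoid revisiting rotations.
    """
    nodes = sorted(g, key=repr)
    order = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    best = 0

    def extend(start, current, visited: set) -> None:
        nonlocal best
        if best == n:
            return
        for u in g[current]:
            if u == start and len(visited) >= 3:
                best = max(best, len(visited))
            elif u not in visited and order[u] > order[start]:
                visited.add(u)
                extend(start, u, visited)
                visited.remove(u)

    for s in nodes:
        extend(s, s, {s})
        if best == n:
            break
    return best


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

_ORACLE_MAX = 14


def _subsets(items: list) -> Iterator[frozenset]:
    n = len(items)
    for mask in range(1 << n):
        yield frozenset(items[i] for i in range(n) if mask >> i & 1)


def _oracle_dominating(g: nx.Graph, weight: str) -> tuple[float, float]:
    w = _weights(g, weight)
    closed = {v: set(g[v]) | {v} for v in g}
    nodes = list(g)
    universe = set(nodes)

    def dominates(s: frozenset) -> bool:
        covered: set = set()
        for v in s:
            covered |= closed[v]
        return covered >= universe

    lower = math.inf
    upper = -math.inf
    for s in _subsets(nodes):
        if not dominates(s):
            continue
        total = sum(w[v] for v in s)
        lower = min(lower, total)
        if all(not dominates(s - {v}) for v in s):
            upper = max(upper, total)
    return lower, upper


def _oracle_distances(g: nx.Graph, weight: str) -> dict[tuple, float]:
    w = _weights(g, weight)
    dist: dict[tuple, float] = {}
    for u in g:
        for v in g:
            if u == v:
                dist[(u, v)] = 0.0
                continue
            best = math.inf
            for path in nx.all_simple_paths(g, u, v):
                best = min(best, sum(w[x] for x in path[1:]))
            dist[(u, v)] = best
    return dist


def _oracle_circumference(g: nx.Graph) -> int:
    longest = 0
    for cyc in nx.simple_cycles(g):
        longest = max(longest, len(cyc))
    return longest


def brute_force_oracle(g: nx.Graph, invariant: str, weight: str = "weight"):
    """Exhaustive-enumeration reference value for a named invariant.

    Independent of the optimized implementations: domination iterates over
    all vertex subsets, distances over all simple paths, circumference over
    all simple cycles.  Refuses graphs with more than 14 vertices.

    ``invariant`` is one of ``weighted_lower_domination``,
    ``weighted_upper_domination``, ``weighted_diameter``,
    ``weighted_periphery``, ``circumference``.
    """
    if g.number_of_nodes() > _ORACLE_MAX:
        raise ValueError(f"oracle limited to {_ORACLE_MAX} vertices")
    _require_nonempty(g)
    if invariant == "weighted_lower_domination":
        return _oracle_dominating(g, weight)[0]
    if invariant == "weighted_upper_domination":
        return _oracle_dominating(g, weight)[1]
    if invariant == "weighted_diameter":
        if not nx.is_connected(g):
            raise ValueError("graph is disconnected")
        return max(_oracle_distances(g, weight).values())
    if invariant == "weighted_periphery":
        if not nx.is_connected(g):
            raise ValueError("graph is disconnected")
        dist = _oracle_distances(g, weight)
        ecc = {u: max(dist[(u, v)] for v in g) for u in g}
        diam = max(ecc.values())
        return frozenset(v for v, e in ecc.items() if abs(e - diam) <= _ECC_ATOL)
    if invariant == "circumference":
        return _oracle_circumference(g)
    raise ValueError(f"unknown invariant {invariant!r}")
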