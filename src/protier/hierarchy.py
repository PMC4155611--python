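"""Assembly of the three-tier hierarchical protein graph.

Bottom tier: one rooted heavy-atom graph per residue type (:mod:`protier.residues`).
Mid tier: one contact graph per substructure — vertices are residue indices,
edges are contact-map pairs inside the substructure's interval, weighted by
atom contact counts.
Top tier: one vertex per substructure; two substructures are adjacent when at
least ``min_pairs_top`` residue pairs (one residue in each, shared boundary
residues excluded) are in contact, the edge weighted by the total
inter-substructure contact count.

Weight propagation carries information up the tiers: every mid vertex gets
its residue's descriptor vector, and every top vertex gets, for each
descriptor and each vertex-weighted invariant, the invariant of its mid graph
weighted by that descriptor (entries named ``"invariant:descriptor"``).
Invariants defined only for non-negative weights (domination, distances) are
skipped for descriptors with negative values; degree-based invariants are
computed for every descriptor.  Circumference is topology-only and stored
once, unprefixed.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable

import networkx as nx

from . import invariants as inv
from .residues import DescriptorTable, enumerate_bottom_level
from .structures import ContactMap, ResidueRecord, SubstructureDefinition, build_contact_map

__all__ = [
    "DEFAULT_INVARIANTS",
    "build_midlevel_graph",
    "build_top_level",
    "HierarchicalGraph",
    "build_hierarchy",
    "propagate_weights",
    "hierarchies_equal",
]


def build_midlevel_graph(
    cm: ContactMap,
    definition: SubstructureDefinition,
    residues: Iterable[ResidueRecord],
    min_contacts: int = 1,
) -> nx.Graph:
    """Contact graph of one substructure.

    Vertices are the residue indices of ``definition``'s interval that are
    present in the structure (node attribute ``residue`` holds the 3-letter
    code); an edge joins two vertices when the contact map stores the pair
    with at least ``min_contacts`` contacts (edge attribute ``contacts``).
    """
    present = {r.index: r for r in residues if r.index in definition.residue_range}
    if not present:
        raise ValueError(
            f"substructure {definition.label}: no residues of range "
            f"{definition.start}-{definition.end} present in the structure"
        )
    g = nx.Graph(level="mid", label=definition.label, kind=definition.kind)
    for idx in sorted(present):
        g.add_node(idx, residue=present[idx].code)
    indices = sorted(present)
    for a_pos, i in enumerate(indices):
        for j in indices[a_pos + 1 :]:
            entry = cm.get(i, j)
            if entry is not None and entry.count >= min_contacts:
                g.add_edge(i, j, contacts=entry.count)
    return g


def build_top_level(
    cm: ContactMap,
    defs: list[SubstructureDefinition],
    min_pairs: int = 2,
) -> nx.Graph:
    """Substructure-level graph: one vertex per definition.

    ``Di`` and ``Dj`` are adjacent when at least ``min_pairs`` contact-map
    pairs span the two substructures, one residue in each; residues that the
    two intervals share (boundary overlap) never contribute to their own
    pair count.  The edge attribute ``contacts`` is the total atom-contact
    count over those spanning pairs.
    """
    if not defs:
        raise ValueError("no substructure definitions supplied")
    labels = [d.label for d in defs]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate substructure labels: {dupes}")
    g = nx.Graph(level="top")
    for d in defs:
        g.add_node(d.label, kind=d.kind, start=d.start, end=d.end)
    members = {d.label: set(d.residue_range) for d in defs}
    for a in range(len(defs)):
        for b in range(a + 1, len(defs)):
            da, db = defs[a], defs[b]
            shared = members[da.label] & members[db.label]
            pairs = 0
            contacts = 0
            for (i, j), entry in cm.entries.items():
                if i in shared or j in shared:
                    continue
                if (i in members[da.label] and j in members[db.label]) or (
                    j in members[da.label] and i in members[db.label]
                ):
                    pairs += 1
                    contacts += entry.count
            if pairs >= min_pairs:
                g.add_edge(da.label, db.label, contacts=contacts, pairs=pairs)
    return g


@dataclass
class HierarchicalGraph:
    """The assembled three-tier graph plus its provenance.

    ``codes`` maps residue index → 3-letter code for the residues covered by
    at least one substructure (the mutable record that in-silico mutations
    rewrite); ``bottom`` holds the atom graphs of the residue types present.
    """

    definitions: list[SubstructureDefinition]
    codes: dict[int, str]
    bottom: dict[str, nx.Graph]
    mid: dict[str, nx.Graph]
    top: nx.Graph
    contact_map: ContactMap
    provenance: dict = field(default_factory=dict)
    _dom_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def copy(self) -> "HierarchicalGraph":
        return copy.deepcopy(self)

    def substructures_containing(self, position: int) -> list[str]:
        return [d.label for d in self.definitions if position in d.residue_range]


def build_hierarchy(
    residues: list[ResidueRecord],
    defs: list[SubstructureDefinition],
    metric: str = "calpha",
    threshold: float = 7.0,
    count_metric: str = "all_atom",
    min_contacts_mid: int = 1,
    min_pairs_top: int = 2,
    structure_id: str = "",
    contact_map: ContactMap | None = None,
) -> HierarchicalGraph:
    """Build the full hierarchy from a residue list and a substructure table.

    Residues outside every substructure interval are dropped from the
    hierarchy with a warning (the contact map still sees them).
    """
    cm = contact_map or build_contact_map(residues, metric, threshold, count_metric)
    covered = set()
    for d in defs:
        covered |= set(d.residue_range)
    orphans = sorted(r.index for r in residues if r.index not in covered)
    if orphans:
        warnings.warn(
            f"{len(orphans)} residues outside every substructure interval "
            f"dropped from the hierarchy (e.g. {orphans[:4]})",
            stacklevel=2,
        )
    mid = {d.label: build_midlevel_graph(cm, d, residues, min_contacts_mid) for d in defs}
    top = build_top_level(cm, defs, min_pairs_top)
    codes = {r.index: r.code for r in residues if r.index in covered}
    present_types = sorted({c for c in codes.values()})
    all_bottom = enumerate_bottom_level()
    bottom = {c: all_bottom[c] for c in present_types if c in all_bottom}
    chain = residues[0].chain if residues else ""
    return HierarchicalGraph(
        definitions=list(defs),
        codes=codes,
        bottom=bottom,
        mid=mid,
        top=top,
        contact_map=cm,
        provenance={
            "structure_id": structure_id,
            "chain": chain,
            "metric": cm.metric,
            "threshold": cm.threshold,
            "count_metric": cm.count_metric,
            "min_contacts_mid": min_contacts_mid,
            "min_pairs_top": min_pairs_top,
        },
    )


# ---------------------------------------------------------------------------
# weight propagation
# ---------------------------------------------------------------------------

def _domination_values(g: nx.Graph, weights, cache) -> tuple[float, float]:
    label = g.graph.get("label")
    sets = cache.get(label)
    if sets is None or cache.get((label, "edges")) != g.number_of_edges():
        sets = inv.minimal_dominating_sets(g)
        cache[label] = sets
        cache[(label, "edges")] = g.number_of_edges()
    return inv.domination_from_minimal_sets(sets, weights)


def _diameter_periphery(g: nx.Graph) -> tuple[float, int]:
    # Mid graphs are usually connected (consecutive residues are within any
    # sensible threshold); if not, take the maximum diameter over components
    # and count peripheral vertices attaining it.
    if g.number_of_nodes() == 1:
        return 0.0, 1
    if nx.is_connected(g):
        ecc = inv._all_eccentricities(g, "weight")
    else:
        ecc = {}
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            if len(comp) == 1:
                ecc[next(iter(comp))] = 0.0
            else:
                ecc.update(inv._all_eccentricities(sub, "weight"))
    diam = max(ecc.values())
    per = sum(1 for e in ecc.values() if abs(e - diam) <= inv._ECC_ATOL)
    return float(diam), per


#: invariant name -> (needs non-negative weights?).  The callable surface is
#: internal to propagate_weights; the names are the public vocabulary.
DEFAULT_INVARIANTS: tuple[str, ...] = (
    "max_weighted_degree",
    "average_weighted_degree",
    "weighted_lower_domination",
    "weighted_upper_domination",
    "weighted_diameter",
    "weighted_periphery_size",
    "circumference",
)

_NONNEG_ONLY = {
    "weighted_lower_domination",
    "weighted_upper_domination",
    "weighted_diameter",
    "weighted_periphery_size",
}


def propagate_weights(
    h: HierarchicalGraph,
    table: DescriptorTable,
    invariant_set: Iterable[str] = DEFAULT_INVARIANTS,
) -> HierarchicalGraph:
    """Propagate descriptor weights bottom → mid → top, in place.

    Every mid vertex receives its residue's descriptor vector (node
    attribute ``weights``).  Every top vertex receives one entry per
    (invariant, descriptor) pair, named ``"invariant:descriptor"``, holding
    that invariant of the mid graph under that descriptor weighting; the
    topology-only ``circumference`` is stored once under its own name.
    Idempotent: repeated calls rewrite identical values.
    """
    invariant_set = tuple(invariant_set)
    unknown = sorted(set(invariant_set) - set(DEFAULT_INVARIANTS))
    if unknown:
        raise ValueError(f"unknown invariants: {unknown}")
    descriptors = table.descriptors
    negatives = {d for d in descriptors if table.has_negative(d)}
    skipped = [i for i in invariant_set if i in _NONNEG_ONLY and negatives]
    if skipped and negatives:
        warnings.warn(
            f"descriptors with negative values ({sorted(negatives)}) skipped for "
            f"non-negative-only invariants ({sorted(set(skipped))})",
            stacklevel=2,
        )
    for label, g in h.mid.items():
        for idx in g.nodes:
            code = g.nodes[idx]["residue"]
            if code != h.codes.get(idx, code):
                g.nodes[idx]["residue"] = h.codes[idx]
                code = h.codes[idx]
            try:
                g.nodes[idx]["weights"] = table.vector(code)
            except KeyError:
                raise ValueError(
                    f"residue {code} at position {idx} (substructure {label}) "
                    "absent from the descriptor table"
                ) from None

    for label, g in h.mid.items():
        top_weights: dict[str, float] = {}
        if "circumference" in invariant_set:
            top_weights["circumference"] = float(inv.circumference(g))
        for desc in descriptors:
            wmap = {idx: g.nodes[idx]["weights"][desc] for idx in g.nodes}
            nx.set_node_attributes(g, wmap, "weight")
            if "max_weighted_degree" in invariant_set:
                top_weights[f"max_weighted_degree:{desc}"] = inv.max_weighted_degree(g)
            if "average_weighted_degree" in invariant_set:
                top_weights[f"average_weighted_degree:{desc}"] = inv.average_weighted_degree(g)
            if desc in negatives:
                continue
            if (
                "weighted_lower_domination" in invariant_set
                or "weighted_upper_domination" in invariant_set
            ):
                lower, upper = _domination_values(g, wmap, h._dom_cache)
                if "weighted_lower_domination" in invariant_set:
                    top_weights[f"weighted_lower_domination:{desc}"] = lower
                if "weighted_upper_domination" in invariant_set:
                    top_weights[f"weighted_upper_domination:{desc}"] = upper
            if "weighted_diameter" in invariant_set or "weighted_periphery_size" in invariant_set:
                diam, per = _diameter_periphery(g)
                if "weighted_diameter" in invariant_set:
                    top_weights[f"weighted_diameter:{desc}"] = diam
                if "weighted_periphery_size" in invariant_set:
                    top_weights[f"weighted_periphery_size:{desc}"] = float(per)
        h.top.nodes[label]["weights"] = top_weights
    h.provenance["invariants"] = list(invariant_set)
    return h


def hierarchies_equal(a: HierarchicalGraph, b: HierarchicalGraph) -> bool:
    """Exact equality of two hierarchies (structure, codes and weights)."""
    if a.codes != b.codes:
        return False
    if set(a.mid) != set(b.mid):
        return False
    for label in a.mid:
        ga, gb = a.mid[label], b.mid[label]
        if dict(ga.nodes(data=True)) != dict(gb.nodes(data=True)):
            return False
        if nx.utils.graphs_equal(ga, gb) is False:
            return False
    return nx.utils.graphs_equal(a.top, b.top)
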