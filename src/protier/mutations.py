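"""In-silico mutations: parsing, sequence editing, hierarchy reweighting.

A point substitution swaps one residue's descriptor vector at the mid level
and therefore changes only the weights — never the edges — of the hierarchy;
the affected top-level vertices are exactly those of the substructures
containing the mutated position (one, or two when the position is a shared
boundary residue).  Insertions and deletions change the residue count of a
mid graph, so they require a user-supplied (e.g. predicted) structure and a
full rebuild (:func:`rebuild_mutant_from_structure`).

Mutations are written compactly: ``V51R`` (substitution), ``F508del``
(deletion), ``508insG`` (insertion of G after position 508).  Positions are
1-based and always refer to the *original* numbering; batches are applied
right-to-left so earlier edits cannot shift later positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import networkx as nx

from .hierarchy import HierarchicalGraph, build_hierarchy, propagate_weights
from .residues import DescriptorTable, ONE_TO_THREE, THREE_TO_ONE
from .structures import SubstructureDefinition, read_structure

__all__ = [
    "MutationSpec",
    "parse_mutation",
    "parse_mutation_list",
    "apply_mutations",
    "reweight_mutant",
    "shift_definitions",
    "rebuild_mutant_from_structure",
    "GraphDiff",
    "diff_top_graphs",
]

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_DEL_RE = re.compile(r"^([A-Z])(\d+)del$", re.IGNORECASE)
_INS_RE = re.compile(r"^(\d+)ins([A-Z])$", re.IGNORECASE)
_GRAMMARS = "substitution 'V51R', deletion 'F508del', insertion '508insG'"


@dataclass(frozen=True)
class MutationSpec:
    kind: str  # substitution | insertion | deletion
    position: int  # 1-based, original numbering
    wild: str | None = None  # one-letter (substitution/deletion)
    new: str | None = None  # one-letter (substitution/insertion)

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be ≥ 1, got {self.position}")
        for code in (self.wild, self.new):
            if code is not None and code not in ONE_TO_THREE:
                raise ValueError(f"non-canonical residue code {code!r}")
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")

    def __str__(self) -> str:
        if self.kind == "substitution":
            return f"{self.wild}{self.position}{self.new}"
        if self.kind == "deletion":
            return f"{self.wild}{self.position}del"
        return f"{self.position}ins{self.new}"


def parse_mutation(text: str) -> MutationSpec:
    """Parse one compact mutation string."""
    text = text.strip()
    if m := _SUB_RE.match(text):
        return MutationSpec("substitution", int(m.group(2)), wild=m.group(1), new=m.group(3))
    if m := _DEL_RE.match(text):
        return MutationSpec("deletion", int(m.group(2)), wild=m.group(1).upper())
    if m := _INS_RE.match(text):
        return MutationSpec("insertion", int(m.group(1)), new=m.group(2).upper())
    raise ValueError(f"cannot parse mutation {text!r}; expected {_GRAMMARS}")


def parse_mutation_list(text: str) -> list[MutationSpec]:
    """Parse a mutation file: one mutation per line, '#' comments."""
    specs = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            specs.append(parse_mutation(line))
    return specs


def apply_mutations(sequence: str, specs: list[MutationSpec]) -> str:
    """Apply mutations to a one-letter sequence (positions in original numbering)."""
    seq = list(sequence)
    n = len(seq)
    for spec in sorted(specs, key=lambda s: s.position, reverse=True):
        pos = spec.position
        if spec.kind == "insertion":
            if not 0 <= pos <= n:
                raise ValueError(f"{spec}: position {pos} outside sequence of length {n}")
            seq.insert(pos, spec.new)
            continue
        if not 1 <= pos <= n:
            raise ValueError(f"{spec}: position {pos} outside sequence of length {n}")
        found = seq[pos - 1]
        if spec.wild is not None and found != spec.wild:
            raise ValueError(
                f"{spec}: expected wild residue {spec.wild} at position {pos}, found {found}"
            )
        if spec.kind == "substitution":
            seq[pos - 1] = spec.new
        else:  # deletion
            del seq[pos - 1]
    return "".join(seq)


# ---------------------------------------------------------------------------
# weight-only mutants
# ---------------------------------------------------------------------------

def reweight_mutant(
    h: HierarchicalGraph,
    specs: list[MutationSpec],
    table: DescriptorTable,
) -> HierarchicalGraph:
    """Mutant hierarchy with unchanged topology and re-derived weights.

    Substitutions only: each mutated mid vertex gets the new residue's
    descriptor vector, then top weights are recomputed.  Edge sets at every
    tier are untouched.  Returns a new hierarchy; the input is not modified.
    """
    for spec in specs:
        if spec.kind != "substitution":
            raise ValueError(
                f"{spec}: only substitutions preserve the graph topology; "
                "use rebuild_mutant_from_structure with a predicted structure "
                "for insertions or deletions"
            )
    mut = h.copy()
    for spec in specs:
        pos = spec.position
        if pos not in mut.codes:
            raise ValueError(
                f"{spec}: position {pos} lies outside every substructure of the hierarchy"
            )
        found_one = THREE_TO_ONE.get(mut.codes[pos], "X")
        if spec.wild is not None and found_one != spec.wild:
            raise ValueError(
                f"{spec}: expected wild residue {spec.wild} at position {pos}, found {found_one}"
            )
        mut.codes[pos] = ONE_TO_THREE[spec.new]
    invariants = h.provenance.get("invariants")
    if invariants:
        propagate_weights(mut, table, invariants)
    else:
        propagate_weights(mut, table)
    mut.provenance = dict(mut.provenance)
    mut.provenance["mutations"] = [str(s) for s in specs]
    return mut


# ---------------------------------------------------------------------------
# structure-backed mutants
# ---------------------------------------------------------------------------

def shift_definitions(
    defs: list[SubstructureDefinition], specs: list[MutationSpec]
) -> list[SubstructureDefinition]:
    """Re-map substructure intervals to the mutant numbering after indels.

    Each interval boundary is shifted by the cumulative insertion/deletion
    offset accumulated strictly before it; substitutions shift nothing.
    Sequences are kept as given (they describe the wild type and are not the
    authority for the mutant; consistency is checked against the structure).
    """
    events = []  # (position, delta)
    for s in specs:
        if s.kind == "insertion":
            events.append((s.position, +1))
        elif s.kind == "deletion":
            events.append((s.position, -1))
    if not events:
        return list(defs)

    def offset(pos: int) -> int:
        return sum(delta for p, delta in events if p < pos)

    out = []
    for d in defs:
        out.append(
            SubstructureDefinition(
                label=d.label,
                kind=d.kind,
                start=d.start + offset(d.start),
                end=d.end + offset(d.end + 1),
                sequence=d.sequence,
            )
        )
    return out


def rebuild_mutant_from_structure(
    pdb: str,
    defs: list[SubstructureDefinition],
    specs: list[MutationSpec],
    table: DescriptorTable | None = None,
    chain: str = "A",
    **build_kwargs,
) -> HierarchicalGraph:
    """Full hierarchy from a user-supplied (e.g. predicted) mutant structure.

    The structure is the authority for coordinates; this function checks
    that it is consistent with the declared mutations (each substituted
    position holds the new residue) and raises on the first mismatch.
    Substructure intervals are re-mapped to the mutant numbering when indels
    shift positions.  When ``table`` is given, weights are propagated.
    """
    residues = read_structure(pdb, chain)
    mut_defs = shift_definitions(defs, specs)
    codes = {r.index: r for r in residues}
    events = [
        (s.position, +1 if s.kind == "insertion" else -1)
        for s in specs
        if s.kind in ("insertion", "deletion")
    ]

    def to_mutant(pos: int) -> int:
        return pos + sum(delta for p, delta in events if p < pos)

    for spec in sorted(specs, key=lambda s: s.position):
        if spec.kind != "substitution":
            continue
        mpos = to_mutant(spec.position)
        rec = codes.get(mpos)
        if rec is None:
            raise ValueError(f"{spec}: mutant structure has no residue at position {mpos}")
        found = THREE_TO_ONE.get(rec.code, "X")
        if found != spec.new:
            raise ValueError(
                f"structure inconsistent with mutations at position {mpos}: "
                f"expected {spec.new} ({spec}), found {found}"
            )
    h = build_hierarchy(residues, mut_defs, **build_kwargs)
    h.provenance["mutations"] = [str(s) for s in specs]
    if table is not None:
        propagate_weights(h, table)
    return h


# ---------------------------------------------------------------------------
# graph diffs
# ---------------------------------------------------------------------------

@dataclass
class GraphDiff:
    """Exact differences between two top-level graphs over one label set."""

    edges_gained: list[tuple]
    edges_lost: list[tuple]
    changed_weights: dict  # label -> {descriptor/weight name: delta}
    cycles_lost: list[tuple]
    cycles_gained: list[tuple]

    @property
    def empty(self) -> bool:
        return not (
            self.edges_gained or self.edges_lost or self.changed_weights
            or self.cycles_lost or self.cycles_gained
        )


def _edge_key(u, v) -> tuple:
    return (u, v) if repr(u) <= repr(v) else (v, u)


def _cycles(g: nx.Graph, bound: int) -> dict[frozenset, tuple]:
    out = {}
    for cyc in nx.simple_cycles(g, length_bound=bound):
        key = frozenset(_edge_key(cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc)))
        out.setdefault(key, tuple(cyc))
    return out


def diff_top_graphs(wild: nx.Graph, mutant: nx.Graph, cycle_length_bound: int = 8) -> GraphDiff:
    """Diff two top-level graphs: edges, per-vertex weight deltas, cycles.

    Both graphs must share one vertex label set (indel-shifted labels are
    the caller's responsibility).  Cycle reporting enumerates simple cycles
    up to ``cycle_length_bound`` vertices; set 0 to skip it.
    """
    if set(wild.nodes) != set(mutant.nodes):
        sym = sorted(set(wild.nodes) ^ set(mutant.nodes), key=repr)
        raise ValueError(f"vertex label sets differ; symmetric difference: {sym}")
    wild_edges = {_edge_key(u, v) for u, v in wild.edges}
    mut_edges = {_edge_key(u, v) for u, v in mutant.edges}
    gained = sorted(mut_edges - wild_edges, key=repr)
    lost = sorted(wild_edges - mut_edges, key=repr)
    changed: dict = {}
    for v in wild.nodes:
        ww = wild.nodes[v].get("weights", {})
        mw = mutant.nodes[v].get("weights", {})
        deltas = {
            name: mw[name] - ww[name]
            for name in sorted(set(ww) & set(mw))
            if mw[name] != ww[name]
        }
        for name in sorted(set(ww) ^ set(mw)):
            deltas[name] = None  # present on one side only
        if deltas:
            changed[v] = deltas
    cycles_lost: list[tuple] = []
    cycles_gained: list[tuple] = []
    if cycle_length_bound:
        wc = _cycles(wild, cycle_length_bound)
        mc = _cycles(mutant, cycle_length_bound)
        cycles_lost = [wc[k] for k in sorted(set(wc) - set(mc), key=repr)]
        cycles_gained = [mc[k] for k in sorted(set(mc) - set(wc), key=repr)]
    return GraphDiff(
        edges_gained=gained,
        edges_lost=lost,
        changed_weights=changed,
        cycles_lost=cycles_lost,
        cycles_gained=cycles_gained,
    )
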