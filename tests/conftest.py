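"""Shared fixtures: synthetic chains, small weighted graphs, random graphs."""

import networkx as nx
import numpy as np
import pytest

import protier as p
from protier.residues import ONE_TO_THREE


def wgraph(edges, weights):
    """Weighted graph from an edge list and a vertex→weight mapping."""
    g = nx.Graph()
    for v, w in weights.items():
        g.add_node(v, weight=w)
    g.add_edges_from(edges)
    return g


def random_connected_graph(rng, n_max=10, p=0.3, unit_weights=False):
    """Seeded connected Erdős–Rényi graph with random positive weights."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        if nx.is_connected(g):
            break
    for v in g.nodes:
        g.nodes[v]["weight"] = 1.0 if unit_weights else float(rng.uniform(0.1, 5.0))
    return g


def single_atom_residue(index, code="GLY", xyz=(0.0, 0.0, 0.0), name="CA"):
    return p.ResidueRecord(
        chain="A", index=index, icode="", code=code, atoms=((name, "C", tuple(xyz)),)
    )


def square_loop_residues(side=6, spacing=3.8, sequence=None):
    """Cα-only chain tracing a closed square: 4 sides of ``side`` residues.

    Consecutive sides are spatially adjacent at the corners and the last
    side closes back onto the first, so a 4-substructure split of the chain
    yields a 4-cycle top-level graph at an 8 Å threshold.
    """
    n = 4 * side
    seq = sequence or "G" * n
    assert len(seq) == n
    pts = []
    x, y = 0.0, 0.0
    directions = [(1, 0), (0, 1), (-1, 0), (0, -1)]
    for s in range(4):
        dx, dy = directions[s]
        for i in range(side):
            pts.append((x, y, 0.0))
            x += dx * spacing
            y += dy * spacing
    return [
        single_atom_residue(i + 1, ONE_TO_THREE[seq[i]], pts[i]) for i in range(n)
    ]


@pytest.fixture(scope="session")
def table():
    return p.default_descriptor_table()


@pytest.fixture(scope="session")
def colinear_defs():
    return p.parse_substructure_table(
        "label,kind,range,sequence\n"
        "D1,alpha,1-5,GGGGG\nD2,alpha,6-10,GGGGG\nD3,alpha,11-15,GGGGG\n"
    )


@pytest.fixture(scope="session")
def colinear_residues():
    pdb = p.generate_synthetic_structure(
        p.SyntheticStructureSpec(sequence="G" * 15), seed=0
    )
    return p.read_structure(pdb, "A")


@pytest.fixture(scope="session")
def valine_hierarchy(table):
    """Colinear 15-mer with a V at position 8 (interior to D2), 8 Å threshold."""
    defs = p.parse_substructure_table(
        "label,kind,range,sequence\n"
        "D1,alpha,1-5,GGGGG\nD2,alpha,6-10,GGVGG\nD3,alpha,11-15,GGGGG\n"
    )
    pdb = p.generate_synthetic_structure(
        p.SyntheticStructureSpec(sequence="GGGGGGGVGGGGGGG"), seed=0
    )
    res = p.read_structure(pdb, "A")
    h = p.build_hierarchy(res, defs, threshold=8.0)
    p.propagate_weights(h, table)
    return h


@pytest.fixture(scope="session")
def square_hierarchy(table):
    """Closed square chain split into 4 substructures: top graph is a 4-cycle.

    Each side holds 3 residues of one type (A, I, S, T), so hydropathy-based
    vertex weights differ between substructures and single substitutions can
    move them far enough to change which edge the minimum spanning tree drops.
    """
    seq = "AAA" + "III" + "SSS" + "TTT"
    residues = square_loop_residues(side=3, sequence=seq)
    defs = p.parse_substructure_table(
        "label,kind,range,sequence\n"
        "D1,alpha,1-3,AAA\nD2,alpha,4-6,III\n"
        "D3,alpha,7-9,SSS\nD4,alpha,10-12,TTT\n"
    )
    h = p.build_hierarchy(residues, defs, threshold=8.0)
    p.propagate_weights(h, table)
    return h
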