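"""Bottom level: rooted heavy-atom graphs of the 20 amino acids.

Each canonical residue is modelled as a hydrogen-suppressed graph whose
vertices are heavy atoms (weighted by standard atomic mass, in unified
atomic mass units) and whose edges are covalent bonds; the backbone Cα is
the root.  Residue graphs are independent of each other — the peptide bond
is not an edge — and use the generic in-chain form (no terminal OXT).
Aromatic rings are plain cycles: this is a graph model, not a bond-order
model.

The module also manages the amino-acid descriptor table: a per-residue
vector combining graph-derived invariants of the atom graphs (computed
here, on mass weights) with tabulated physicochemical indices (polarity,
charge, Kyte–Doolittle hydropathy, van der Waals volume, isoelectric point,
electron–ion interaction potential, ...).  These vectors become the
mid-level vertex weights of the hierarchical protein graph.
"""

from __future__ import annotations

import functools
import io
import json
from importlib import resources

import networkx as nx
import pandas as pd

from . import invariants as inv

__all__ = [
    "CANONICAL_RESIDUES",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
    "GRAPH_DESCRIPTORS",
    "PHYSICOCHEMICAL_DESCRIPTORS",
    "atomic_masses",
    "build_residue_atom_graph",
    "enumerate_bottom_level",
    "compute_graph_descriptors",
    "DescriptorTable",
    "load_descriptor_table",
    "default_descriptor_table",
]

#: Graph-derived descriptor names (computed on the mass-weighted atom graphs).
GRAPH_DESCRIPTORS = (
    "WeightedLowerDomination",
    "WeightedUpperDomination",
    "WeightedDiameter",
    "Circumference",
    "AverageWeightedDegree",
    "WeightedPeripherySize",
)

#: Tabulated physicochemical descriptor names, as conventionally abbreviated.
PHYSICOCHEMICAL_DESCRIPTORS = (
    "Plr",
    "Chrg",
    "Hydpthy",
    "stablty",
    "ss-stability",
    "vanderWaal",
    "chargetransf",
    "chargedonar",
    "averhydrophocitiy",
    "coilConformation",
    "IsoElectric",
    "Balaban index",
    "RofGyr",
    "ShapeIndex",
    "EIIP",
)


def _data_text(name: str) -> str:
    return resources.files("protier.data").joinpath(name).read_text()


@functools.cache
def _topology() -> dict:
    data = json.loads(_data_text("residue_topology.json"))
    data.pop("_format", None)
    return data


@functools.cache
def atomic_masses() -> dict[str, float]:
    """Standard atomic weights (3 decimals) of the protein heavy elements."""
    df = pd.read_csv(io.StringIO(_data_text("atomic_masses.csv")))
    return dict(zip(df["element"], df["mass"].astype(float)))


CANONICAL_RESIDUES = tuple(sorted(_topology()))
ONE_TO_THREE = {spec["one"]: code for code, spec in _topology().items()}
THREE_TO_ONE = {code: spec["one"] for code, spec in _topology().items()}


def build_residue_atom_graph(residue_code: str) -> nx.Graph:
    """Rooted, hydrogen-suppressed heavy-atom graph of one amino acid.

    Nodes are PDB atom names carrying ``element`` and ``weight`` (atomic
    mass); the graph attribute ``root`` is ``"CA"`` and ``residue`` the
    3-letter code.

    Raises ``KeyError`` for an unknown code, with a hint that nonstandard
    residues need a user-supplied topology entry.
    """
    code = residue_code.upper()
    topo = _topology()
    if code not in topo:
        raise KeyError(
            f"unknown residue code {residue_code!r}; canonical codes are "
            f"{CANONICAL_RESIDUES}. Nonstandard residues require an entry in "
            "the residue topology table."
        )
    masses = atomic_masses()
    g = nx.Graph(residue=code, root="CA")
    for atom, element in topo[code]["atoms"].items():
        g.add_node(atom, element=element, weight=masses[element])
    g.add_edges_from(topo[code]["bonds"])
    return g


@functools.cache
def enumerate_bottom_level() -> dict[str, nx.Graph]:
    """The 20 canonical residue atom graphs, keyed by 3-letter code."""
    return {code: build_residue_atom_graph(code) for code in CANONICAL_RESIDUES}


def compute_graph_descriptors(g: nx.Graph) -> dict[str, float]:
    """Graph-derived descriptor vector of one atom graph (mass weights).

    The weighted periphery is a vertex set; its cardinality is stored as the
    numeric descriptor.
    """
    lower, upper = inv.weighted_domination(g)
    n = g.number_of_nodes()
    return {
        "WeightedLowerDomination": lower,
        "WeightedUpperDomination": upper,
        "WeightedDiameter": inv.weighted_diameter(g) if n > 1 else 0.0,
        "Circumference": float(inv.circumference(g)),
        "AverageWeightedDegree": inv.average_weighted_degree(g),
        "WeightedPeripherySize": float(len(inv.weighted_periphery(g))) if n > 1 else 1.0,
    }


class DescriptorTable:
    """Named per-residue descriptor vectors for the 20 canonical residues.

    Thin wrapper around a :class:`pandas.DataFrame` indexed by 3-letter
    residue code with one column per descriptor.
    """

    def __init__(self, frame: pd.DataFrame):
        missing_rows = sorted(set(CANONICAL_RESIDUES) - set(frame.index))
        if missing_rows:
            raise ValueError(f"descriptor table missing residues: {missing_rows}")
        required = PHYSICOCHEMICAL_DESCRIPTORS + GRAPH_DESCRIPTORS
        missing_cols = [c for c in required if c not in frame.columns]
        if missing_cols:
            raise ValueError(f"descriptor table missing columns: {missing_cols}")
        if frame.loc[list(CANONICAL_RESIDUES), list(required)].isna().any().any():
            raise ValueError("descriptor table contains missing values")
        self.frame = frame.loc[list(CANONICAL_RESIDUES)].astype(float)

    @property
    def descriptors(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def vector(self, residue_code: str) -> dict[str, float]:
        """Descriptor vector of one residue (3- or 1-letter code)."""
        code = residue_code.upper()
        if len(code) == 1:
            code = ONE_TO_THREE[code]
        return self.frame.loc[code].to_dict()

    def column(self, descriptor: str) -> dict[str, float]:
        return self.frame[descriptor].to_dict()

    def has_negative(self, descriptor: str) -> bool:
        return bool((self.frame[descriptor] < 0).any())

    def __eq__(self, other) -> bool:
        return isinstance(other, DescriptorTable) and self.frame.equals(other.frame)


def _with_graph_columns(df: pd.DataFrame) -> pd.DataFrame:
    if all(c in df.columns for c in GRAPH_DESCRIPTORS):
        return df
    derived = pd.DataFrame.from_dict(
        {code: compute_graph_descriptors(g) for code, g in enumerate_bottom_level().items()},
        orient="index",
    )
    return df.join(derived)


def load_descriptor_table(source) -> DescriptorTable:
    """Load a descriptor table from CSV text, a path, or a DataFrame.

    The CSV must have a ``residue`` column of 3-letter codes plus one column
    per physicochemical descriptor; graph-derived columns are computed from
    the bundled atom graphs when absent.  Missing residues or descriptor
    columns raise ``ValueError`` naming the offender.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith("residue"):
            with open(text) as fh:
                text = fh.read()
        df = pd.read_csv(io.StringIO(text))
    if "residue" in df.columns:
        df = df.set_index("residue")
    df.index = [str(i).upper() for i in df.index]
    return DescriptorTable(_with_graph_columns(df))


@functools.cache
def default_descriptor_table() -> DescriptorTable:
    """The bundled default descriptor table.

    Physicochemical columns are compiled from widely used amino-acid index
    scales (Kyte–Doolittle hydropathy, Grantham polarity, Fauchère van der
    Waals volume, Veljković EIIP, Eisenberg consensus hydrophobicity,
    Pace–Scholtz helix propensity, standard isoelectric points, Balaban's J
    of the heavy-atom residue graphs, and companion scales); graph-derived
    columns are recomputed from :func:`enumerate_bottom_level` at load time.
    """
    return load_descriptor_table(_data_text("aa_descriptors.csv"))
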