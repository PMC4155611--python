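"""Structures, substructure tables, contact maps and synthetic fixtures.

A protein chain is reduced to a list of :class:`ResidueRecord` (heavy atoms
only, one chain, first model) read with Bio.PDB.  A :class:`ContactMap`
stores, for every residue pair whose distance under a chosen metric is
within a threshold, the number of atom-level contacts and the minimum atom
distance; contact counts become edge weights in the hierarchy.

Substructure tables list the secondary-structure intervals (label, kind,
1-based inclusive residue range, sequence) that define the top-level
vertices.  Adjacent intervals may share their boundary residue; the shared
residue belongs to both substructures.  The table is validated but never
silently repaired: a row whose sequence length disagrees with its range is
flagged via :meth:`SubstructureDefinition.is_self_consistent` and
:func:`audit_definitions`.

:func:`generate_synthetic_structure` writes small single-chain PDB files
with controllable geometry (colinear Cα trace, ideal α-helix, seeded random
coil) so contact-map and hierarchy construction are testable without
external structure files.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .residues import ONE_TO_THREE, THREE_TO_ONE, atomic_masses

__all__ = [
    "SubstructureDefinition",
    "parse_substructure_table",
    "audit_definitions",
    "default_substructure_table",
    "ResidueRecord",
    "read_structure",
    "residue_distance",
    "ContactMap",
    "build_contact_map",
    "SyntheticStructureSpec",
    "generate_synthetic_structure",
]

_AMINO_ONE = set(ONE_TO_THREE)
_BACKBONE = {"N", "CA", "C", "O", "OXT"}
_RANGE_RE = re.compile(r"^\s*(\d+)\s*-\s*(\d+)\s*$")

METRICS = ("calpha", "centroid", "center_of_mass", "all_atom")
COUNT_METRICS = ("all_atom", "side_chain")


# ---------------------------------------------------------------------------
# substructure tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstructureDefinition:
    """One secondary-structure interval: a top-level vertex."""

    label: str
    kind: str  # alpha | beta | loop
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    sequence: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.label}: start {self.start} > end {self.end}")
        if not self.sequence:
            raise ValueError(f"{self.label}: empty sequence")
        bad = sorted(set(self.sequence) - _AMINO_ONE)
        if bad:
            raise ValueError(f"{self.label}: non-amino-acid characters {bad} in sequence")
        if self.kind not in ("alpha", "beta", "loop"):
            raise ValueError(f"{self.label}: unknown kind {self.kind!r}")

    @property
    def residue_range(self) -> range:
        return range(self.start, self.end + 1)

    def is_self_consistent(self) -> bool:
        """True when the sequence length matches the residue range."""
        return len(self.sequence) == self.end - self.start + 1


def _parse_range(text: str, label: str) -> tuple[int, int]:
    m = _RANGE_RE.match(str(text))
    if not m:
        raise ValueError(f"row {label!r}: malformed range {text!r} (expected 'a-b')")
    return int(m.group(1)), int(m.group(2))


def parse_substructure_table(source) -> list[SubstructureDefinition]:
    """Parse a substructure table from CSV/TSV text, a path, or a DataFrame.

    Expected columns: ``label``, ``kind``, ``range`` (text ``"a-b"``,
    1-based inclusive) and ``sequence``.  A combined ``name`` column in the
    form ``"D1 -beta"`` is split into label and kind.  Row order is
    preserved; self-inconsistent rows (sequence length vs. range) are
    accepted and flagged with a warning, never repaired.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        text = str(source)
        if "\n" not in text:
            with open(text) as fh:
                text = fh.read()
        sep = "\t" if "\t" in text.splitlines()[0] else ","
        df = pd.read_csv(io.StringIO(text), sep=sep)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "name" in df.columns and "label" not in df.columns:
        parts = df["name"].astype(str).str.split(r"\s*-\s*", n=1, expand=True)
        df["label"] = parts[0].str.strip()
        df["kind"] = parts[1].str.strip()
    for col in ("label", "kind", "range", "sequence"):
        if col not in df.columns:
            raise ValueError(f"substructure table missing column {col!r}")
    defs = []
    for _, row in df.iterrows():
        start, end = _parse_range(row["range"], str(row["label"]))
        d = SubstructureDefinition(
            label=str(row["label"]).strip(),
            kind=str(row["kind"]).strip().lower(),
            start=start,
            end=end,
            sequence=str(row["sequence"]).strip().upper(),
        )
        if not d.is_self_consistent():
            warnings.warn(
                f"substructure {d.label}: sequence length {len(d.sequence)} "
                f"!= range size {d.end - d.start + 1} ({d.start}-{d.end}); "
                "row kept as printed",
                stacklevel=2,
            )
        defs.append(d)
    return defs


def audit_definitions(defs: list[SubstructureDefinition]) -> list[dict]:
    """Report rows whose sequence length disagrees with their range."""
    out = []
    for d in defs:
        if not d.is_self_consistent():
            out.append(
                {
                    "label": d.label,
                    "range_size": d.end - d.start + 1,
                    "sequence_length": len(d.sequence),
                }
            )
    return out


def default_substructure_table() -> list[SubstructureDefinition]:
    """The bundled 19-substructure table for yeast triosephosphate isomerase."""
    from importlib import resources

    text = resources.files("protier.data").joinpath("substructures_sctim.csv").read_text()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the D10 row is knowingly inconsistent
        return parse_substructure_table(text)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueRecord:
    """One residue of a chain: heavy atoms with coordinates in Å."""

    chain: str
    index: int  # PDB residue number
    icode: str
    code: str  # 3-letter residue code
    atoms: tuple[tuple[str, str, tuple[float, float, float]], ...]  # (name, element, xyz)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.code, "X")

    def coords(self, names: set[str] | None = None, exclude: set[str] | None = None) -> np.ndarray:
        pts = [
            xyz
            for name, _el, xyz in self.atoms
            if (names is None or name in names) and (exclude is None or name not in exclude)
        ]
        return np.asarray(pts, dtype=float)

    @property
    def calpha(self) -> np.ndarray:
        for name, _el, xyz in self.atoms:
            if name == "CA":
                return np.asarray(xyz, dtype=float)
        raise ValueError(f"residue {self.code}{self.index}: no Cα atom")

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(el for _n, el, _x in self.atoms)


def read_structure(pdb: str, chain: str) -> list[ResidueRecord]:
    """Read one chain of a PDB-format structure into ResidueRecords.

    ``pdb`` is PDB text or a path.  First model only; HETATM and hydrogen
    (H/D) atoms excluded; alternate locations resolved by keeping the blank
    or ``"A"`` conformer.  Residues are returned in ascending residue-number
    order.  Raises ``ValueError`` if the chain is absent (listing available
    chains) or no ATOM records are found.
    """
    text = pdb if "\n" in pdb or pdb.lstrip().startswith(("ATOM", "HEADER", "MODEL")) else None
    if text is None:
        with open(pdb) as fh:
            text = fh.read()
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", io.StringIO(text))
    models = list(structure)
    if not models or not any(len(c) for c in models[0]):
        raise ValueError("no ATOM records found in structure")
    model = models[0]
    chains = {c.id for c in model}
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not found; available chains: {sorted(chains)}")
    records = []
    for res in model[chain]:
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue  # HETATM / water
        atoms = []
        for atom in res.get_atoms():  # DisorderedAtom yields the selected altloc
            if atom.element in ("H", "D"):
                continue
            altloc = atom.get_altloc()
            if altloc not in (" ", "", "A"):
                continue
            xyz = tuple(float(x) for x in atom.coord)
            atoms.append((atom.get_name(), atom.element, xyz))
        if not atoms:
            continue
        records.append(
            ResidueRecord(
                chain=chain,
                index=int(resseq),
                icode=icode.strip(),
                code=res.get_resname().strip().upper(),
                atoms=tuple(atoms),
            )
        )
    if not records:
        raise ValueError(f"chain {chain!r} holds no polymer residues")
    records.sort(key=lambda r: (r.index, r.icode))
    return records


def _representative(residue: ResidueRecord, metric: str) -> np.ndarray:
    if metric == "calpha":
        return residue.calpha
    pts = residue.coords()
    if metric == "centroid":
        return pts.mean(axis=0)
    if metric == "center_of_mass":
        masses = atomic_masses()
        w = np.array([masses[e] for e in residue.elements], dtype=float)
        return (pts * w[:, None]).sum(axis=0) / w.sum()
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def residue_distance(r1: ResidueRecord, r2: ResidueRecord, metric: str = "calpha") -> float:
    """Distance in Å between two residues under the named metric.

    ``calpha``: Euclidean Cα–Cα; ``centroid``: between unweighted heavy-atom
    centroids; ``center_of_mass``: between mass-weighted centroids;
    ``all_atom``: minimum over heavy-atom pairs.
    """
    if metric == "all_atom":
        a, b = r1.coords(), r2.coords()
        diff = a[:, None, :] - b[None, :, :]
        return float(np.sqrt((diff**2).sum(axis=2)).min())
    return float(np.linalg.norm(_representative(r1, metric) - _representative(r2, metric)))


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactEntry:
    count: int
    min_distance: float


@dataclass
class ContactMap:
    """Residue-pair contacts under one metric/threshold.

    ``entries`` maps unordered index pairs ``(i, j)`` with ``i < j`` to a
    :class:`ContactEntry`.  Symmetric by construction.
    """

    metric: str
    threshold: float
    count_metric: str
    entries: dict[tuple[int, int], ContactEntry] = field(default_factory=dict)

    @staticmethod
    def key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return self.key(*pair) in self.entries

    def get(self, i: int, j: int) -> ContactEntry | None:
        return self.entries.get(self.key(i, j))

    def pairs(self) -> set[tuple[int, int]]:
        return set(self.entries)


def _count_atoms(residue: ResidueRecord, count_metric: str) -> np.ndarray:
    if count_metric == "all_atom":
        return residue.coords()
    if count_metric == "side_chain":
        return residue.coords(exclude=_BACKBONE)
    raise ValueError(f"unknown count metric {count_metric!r}; choose from {COUNT_METRICS}")


def build_contact_map(
    residues: list[ResidueRecord],
    metric: str = "calpha",
    threshold: float = 7.0,
    count_metric: str = "all_atom",
) -> ContactMap:
    """Contact map over a residue list.

    A pair ``(i, j)`` qualifies when its distance under ``metric`` is at
    most ``threshold``.  Each qualifying pair is annotated with the number
    of atom pairs within ``threshold`` under ``count_metric`` (all heavy
    atoms, or side-chain atoms only — glycine contributes none) and the
    minimum distance among those atom pairs.  A qualifying pair with zero
    witnessing atom contacts is not stored; with the default settings the
    Cα pair itself is always a witness, so storage is exactly the metric
    rule.  Fewer than two residues yield an empty map.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cm = ContactMap(metric=metric, threshold=threshold, count_metric=count_metric)
    if len(residues) < 2:
        return cm
    idx = [r.index for r in residues]
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate residue indices in chain")

    # qualifying pairs under the residue metric
    if metric == "all_atom":
        qualifying = None  # determined by the atom-pair pass below
    else:
        reps = np.vstack([_representative(r, metric) for r in residues])
        tree = cKDTree(reps)
        qualifying = {
            (min(idx[a], idx[b]), max(idx[a], idx[b]))
            for a, b in tree.query_pairs(threshold)
        }

    # atom-pair contacts under the count metric
    atom_xyz, atom_res = [], []
    for r in residues:
        pts = _count_atoms(r, count_metric)
        for p in pts:
            atom_xyz.append(p)
            atom_res.append(r.index)
    counts: dict[tuple[int, int], int] = {}
    mins: dict[tuple[int, int], float] = {}
    if atom_xyz:
        pts = np.asarray(atom_xyz)
        tree = cKDTree(pts)
        for a, b in tree.query_pairs(threshold):
            ri, rj = atom_res[a], atom_res[b]
            if ri == rj:
                continue
            key = ContactMap.key(ri, rj)
            d = float(np.linalg.norm(pts[a] - pts[b]))
            counts[key] = counts.get(key, 0) + 1
            mins[key] = min(mins.get(key, np.inf), d)

    if qualifying is None:
        # all_atom metric: a pair qualifies iff any heavy-atom pair is within
        # threshold; recompute on heavy atoms regardless of count metric
        heavy: dict[tuple[int, int], bool] = {}
        pts_all, res_all = [], []
        for r in residues:
            for p in r.coords():
                pts_all.append(p)
                res_all.append(r.index)
        pa = np.asarray(pts_all)
        tree = cKDTree(pa)
        for a, b in tree.query_pairs(threshold):
            if res_all[a] != res_all[b]:
                heavy[ContactMap.key(res_all[a], res_all[b])] = True
        qualifying = set(heavy)

    for key in sorted(qualifying):
        if key in counts:
            cm.entries[key] = ContactEntry(count=counts[key], min_distance=mins[key])
    return cm


# ---------------------------------------------------------------------------
# synthetic structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticStructureSpec:
    """Geometry description for a synthetic single-chain PDB fixture.

    ``mode``: ``colinear`` (Cα atoms on the x-axis at ``spacing`` Å),
    ``helix`` (ideal α-helix: radius 2.3 Å, rise 1.5 Å/residue, 100°/turn)
    or ``coil`` (seeded random walk with 3.8 Å steps).  ``sequence`` is
    one-letter codes.  With ``sidechains`` a Cβ-like side-chain atom is
    placed 1.5 Å from the Cα of every non-glycine residue.
    """

    sequence: str
    mode: str = "colinear"
    spacing: float = 3.8
    chain_id: str = "A"
    start_index: int = 1
    sidechains: bool = False

    def __post_init__(self):
        bad = sorted(set(self.sequence.upper()) - _AMINO_ONE)
        if bad:
            raise ValueError(f"unknown residue codes in sequence: {bad}")
        if self.mode not in ("colinear", "helix", "coil"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")


def _ca_trace(spec: SyntheticStructureSpec, rng: np.random.Generator) -> np.ndarray:
    n = len(spec.sequence)
    if spec.mode == "colinear":
        pts = np.zeros((n, 3))
        pts[:, 0] = np.arange(n) * spec.spacing
        return pts
    if spec.mode == "helix":
        t = np.arange(n) * np.deg2rad(100.0)
        return np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)])
    # seeded random walk; steps of 3.8 Å with a mild persistence so the
    # chain does not immediately self-intersect
    pts = np.zeros((n, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n):
        perturb = rng.normal(scale=0.6, size=3)
        direction = direction + perturb
        direction /= np.linalg.norm(direction)
        pts[i] = pts[i - 1] + 3.8 * direction
    return pts


def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, element) -> str:
    pad = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {pad:<4s} {resname:<3s} {chain:1s}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}\n"
    )


def generate_synthetic_structure(spec: SyntheticStructureSpec, seed: int = 0) -> str:
    """PDB-format text for a synthetic chain; byte-deterministic given seed."""
    rng = np.random.default_rng(seed)
    trace = _ca_trace(spec, rng)
    lines = []
    serial = 1
    for i, one in enumerate(spec.sequence.upper()):
        resname = ONE_TO_THREE[one]
        resseq = spec.start_index + i
        lines.append(
            _pdb_atom_line(serial, "CA", resname, spec.chain_id, resseq, trace[i], "C")
        )
        serial += 1
        if spec.sidechains and one != "G":
            offset = np.array([0.0, 1.5, 0.0])
            lines.append(
                _pdb_atom_line(
                    serial, "CB", resname, spec.chain_id, resseq, trace[i] + offset, "C"
                )
            )
            serial += 1
    lines.append("END\n")
    return "".join(lines)
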