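"""GraphML serialization of weighted tier graphs.

Vertex weight vectors (the nested ``weights`` dict used by the hierarchy)
are flattened to one typed GraphML attribute per entry, prefixed ``w|`` so
imports can rebuild the nested form; all other scalar attributes pass
through unchanged.  Floats survive the round trip exactly (shortest-repr
serialization).  The exported files load directly into GraphML consumers
such as Cytoscape.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx

__all__ = ["export_graphml", "import_graphml", "save_hierarchy"]

_PREFIX = "w|"
_SCALARS = (bool, int, float, str)


def _flatten(g: nx.Graph) -> nx.Graph:
    out = nx.Graph()
    out.graph.update({k: v for k, v in g.graph.items() if isinstance(v, _SCALARS)})
    for v, data in g.nodes(data=True):
        attrs = {}
        for k, val in data.items():
            if k == "weights" and isinstance(val, dict):
                for name, x in val.items():
                    attrs[_PREFIX + name] = float(x)
            elif isinstance(val, _SCALARS):
                attrs[k] = val
        out.add_node(v, **attrs)
    for u, v, data in g.edges(data=True):
        out.add_edge(u, v, **{k: x for k, x in data.items() if isinstance(x, _SCALARS)})
    return out


def export_graphml(g: nx.Graph, path) -> None:
    """Write a (tier or plain weighted) graph as standard GraphML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(_flatten(g), path)


def import_graphml(path) -> nx.Graph:
    """Read GraphML back, re-nesting ``w|``-prefixed attributes into ``weights``."""
    g = nx.read_graphml(Path(path))
    out = nx.Graph()
    out.graph.update(g.graph)
    for v, data in g.nodes(data=True):
        node = _maybe_int(v)
        weights = {k[len(_PREFIX):]: float(x) for k, x in data.items() if k.startswith(_PREFIX)}
        attrs = {k: x for k, x in data.items() if not k.startswith(_PREFIX)}
        if weights:
            attrs["weights"] = weights
        out.add_node(node, **attrs)
    for u, v, data in g.edges(data=True):
        out.add_edge(_maybe_int(u), _maybe_int(v), **data)
    return out


def _maybe_int(label):
    # GraphML node ids are strings; mid-level vertices are residue indices
    try:
        return int(label)
    except (TypeError, ValueError):
        return label


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_hierarchy(h, outdir, config: dict | None = None) -> Path:
    """Serialize a hierarchy as a directory of GraphML files plus a manifest.

    Writes ``top.graphml``, one ``mid_<label>.graphml`` per substructure,
    one ``bottom_<code>.graphml`` per residue type present, and
    ``manifest.json`` echoing the provenance/config with a checksum of every
    written graph file — enough to re-run the build bit-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    export_graphml(h.top, outdir / "top.graphml")
    written["top.graphml"] = _sha256(outdir / "top.graphml")
    for label, g in h.mid.items():
        name = f"mid_{label}.graphml"
        export_graphml(g, outdir / name)
        written[name] = _sha256(outdir / name)
    for code, g in h.bottom.items():
        name = f"bottom_{code}.graphml"
        export_graphml(g, outdir / name)
        written[name] = _sha256(outdir / name)
    manifest = {
        "provenance": h.provenance,
        "config": config or {},
        "files": written,
        "substructures": [
            {"label": d.label, "kind": d.kind, "start": d.start, "end": d.end}
            for d in h.definitions
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
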