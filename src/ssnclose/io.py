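"""Graph input/output: GraphML, XGMML (Cytoscape), and edge-list TSV.

GraphML goes through networkx.  XGMML is written (and read back) with
lxml in the dialect Cytoscape imports, carrying node and edge attributes
as typed ``<att>`` elements.  The edge-list dialect is two node ids per
line separated by a tab, with ``#`` comments; isolated nodes are written
as single-column lines.
"""

from __future__ import annotations

from typing import IO

import networkx as nx
from lxml import etree

__all__ = [
    "read_graph",
    "write_graph",
    "read_edgelist_tsv",
    "write_edgelist_tsv",
    "read_xgmml",
    "write_xgmml",
]

_XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def _att_type(value) -> tuple[str, str]:
    if isinstance(value, bool):
        return "boolean", str(value).lower()
    if isinstance(value, int):
        return "integer", str(value)
    if isinstance(value, float):
        return "real", repr(value)
    return "string", str(value)


def write_xgmml(g: nx.Graph, path: str, label: str = "network") -> None:
    """Write a graph as Cytoscape-readable XGMML with typed attributes."""
    root = etree.Element(
        "graph",
        nsmap={None: _XGMML_NS},
        label=label,
        directed="0",
    )
    node_elem_id = {n: str(i) for i, n in enumerate(sorted(g.nodes, key=str))}
    for n in sorted(g.nodes, key=str):
        el = etree.SubElement(root, "node", id=node_elem_id[n], label=str(n))
        for key, value in sorted(g.nodes[n].items()):
            t, v = _att_type(value)
            etree.SubElement(el, "att", name=str(key), type=t, value=v)
    for u, v in sorted(g.edges, key=lambda e: (str(e[0]), str(e[1]))):
        el = etree.SubElement(
            root,
            "edge",
            source=node_elem_id[u],
            target=node_elem_id[v],
            label=f"{u}-{v}",
        )
        for key, value in sorted(g.edges[u, v].items()):
            t, val = _att_type(value)
            etree.SubElement(el, "att", name=str(key), type=t, value=val)
    etree.ElementTree(root).write(
        path, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def _parse_att(el) -> tuple[str, object]:
    name = el.get("name")
    t = el.get("type", "string")
    raw = el.get("value", "")
    if t == "integer":
        return name, int(raw)
    if t == "real":
        return name, float(raw)
    if t == "boolean":
        return name, raw.lower() == "true"
    return name, raw


def read_xgmml(path: str) -> nx.Graph:
    """Read an XGMML network (node labels become node ids)."""
    tree = etree.parse(path)
    root = tree.getroot()
    g = nx.Graph()
    ns = {"x": _XGMML_NS} if root.tag.startswith("{") else None
    node_tag = f"{{{_XGMML_NS}}}node" if ns else "node"
    edge_tag = f"{{{_XGMML_NS}}}edge" if ns else "edge"
    att_tag = f"{{{_XGMML_NS}}}att" if ns else "att"
    by_id: dict[str, str] = {}
    for el in root.iter(node_tag):
        label = el.get("label", el.get("id"))
        by_id[el.get("id", label)] = label
        attrs = dict(_parse_att(a) for a in el.iter(att_tag))
        g.add_node(label, **attrs)
    for el in root.iter(edge_tag):
        u = by_id.get(el.get("source"), el.get("source"))
        v = by_id.get(el.get("target"), el.get("target"))
        attrs = dict(_parse_att(a) for a in el.iter(att_tag))
        g.add_edge(u, v, **attrs)
    return g


def write_edgelist_tsv(g: nx.Graph, path: str | IO[str]) -> None:
    handle = open(path, "w") if isinstance(path, str) else path
    try:
        handle.write("# node_a\tnode_b (single column = isolated node)\n")
        for u, v in sorted(g.edges, key=lambda e: (str(e[0]), str(e[1]))):
            handle.write(f"{u}\t{v}\n")
        for n in sorted((n for n in g.nodes if g.degree[n] == 0), key=str):
            handle.write(f"{n}\n")
    finally:
        if isinstance(path, str):
            handle.close()


def read_edgelist_tsv(path: str | IO[str]) -> nx.Graph:
    g = nx.Graph()
    handle = open(path) if isinstance(path, str) else path
    try:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1 or parts[0] == parts[1]:
                g.add_node(parts[0])
            else:
                g.add_edge(parts[0], parts[1])
    finally:
        if isinstance(path, str):
            handle.close()
    return g


def read_graph(path: str) -> nx.Graph:
    """Read a graph, dispatching on extension (.graphml, .xgmml, else
    edge-list TSV).  Directed inputs are converted to undirected simple
    graphs."""
    lower = path.lower()
    if lower.endswith(".graphml"):
        g = nx.read_graphml(path)
    elif lower.endswith(".xgmml") or lower.endswith(".xml"):
        g = read_xgmml(path)
    else:
        g = read_edgelist_tsv(path)
    if g.is_directed():
        g = g.to_undirected()
    g.remove_edges_from(nx.selfloop_edges(g))
    return nx.Graph(g)


def write_graph(g: nx.Graph, path: str, label: str = "network") -> None:
    """Write a graph, dispatching on extension (.graphml, .xgmml, else
    edge-list TSV)."""
    lower = path.lower()
    if lower.endswith(".graphml"):
        nx.write_graphml(g, path)
    elif lower.endswith(".xgmml") or lower.endswith(".xml"):
        write_xgmml(g, path, label=label)
    else:
        write_edgelist_tsv(g, path)
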