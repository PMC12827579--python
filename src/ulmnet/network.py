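"""Physical cell-cell interaction networks from multiplet compositions.

Doublet/multiplet barcodes are tallied by composition; rare compositions
are filtered out; each retained multiplet of size k then contributes its
frequency to every one of its C(k, 2) unordered cell-type pairs (clique
expansion), giving an undirected graph whose edge weights count supporting
multiplet barcodes.
"""

from __future__ import annotations

import json
import warnings
from itertools import combinations
from math import comb
from pathlib import Path

import networkx as nx
import pandas as pd

from ._errors import ValidationError
from .classify import BarcodeClassification

__all__ = [
    "tabulate_multiplets",
    "filter_multiplets",
    "build_network",
    "export_network",
    "import_network",
    "total_edge_weight",
]


def tabulate_multiplets(cls: list[BarcodeClassification]) -> pd.DataFrame:
    """Frequency table of distinct doublet/multiplet compositions.

    Columns: composition (canonical label), size (member count), frequency.
    Singlets and unassigned barcodes are excluded.
    """
    comps = [c.composition for c in cls if c.category in ("doublet", "multiplet")]
    if not comps:
        return pd.DataFrame(columns=["composition", "size", "frequency"])
    counts = pd.Series(comps).value_counts()
    df = pd.DataFrame({
        "composition": counts.index,
        "size": [len(c.split("_")) for c in counts.index],
        "frequency": counts.to_numpy(),
    })
    return df.sort_values(
        ["frequency", "composition"], ascending=[False, True], ignore_index=True
    )


def filter_multiplets(table: pd.DataFrame, min_count: int = 10) -> pd.DataFrame:
    """Retain multiplet types with frequency >= min_count (noise filter)."""
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    out = table[table["frequency"] >= min_count].reset_index(drop=True)
    if len(table) and out.empty:
        warnings.warn(
            f"min_count={min_count} removed every multiplet type", stacklevel=2)
    return out


def build_network(table: pd.DataFrame) -> nx.Graph:
    """Decompose multiplet types into a weighted undirected cell-type graph.

    A multiplet of size k adds its frequency to all C(k, 2) member pairs;
    pair weights sum across multiplet types.  No self-loops arise because
    composition members are distinct by construction.
    """
    g = nx.Graph()
    for row in table.itertuples(index=False):
        members = sorted(set(row.composition.split("_")))
        g.add_nodes_from(members)
        for a, b in combinations(members, 2):
            w = g.edges[a, b]["weight"] if g.has_edge(a, b) else 0
            g.add_edge(a, b, weight=w + int(row.frequency))
    return g


def total_edge_weight(g: nx.Graph) -> int:
    return int(sum(d["weight"] for _, _, d in g.edges(data=True)))


def expected_total_weight(table: pd.DataFrame) -> int:
    """Conservation identity: sum over types of frequency * C(size, 2)."""
    return int(sum(
        int(r.frequency) * comb(int(r.size), 2) for r in table.itertuples(index=False)
    ))


def export_network(g: nx.Graph, path, fmt: str | None = None) -> None:
    """Lossless export as GraphML, TSV edge list or JSON {nodes, edges}."""
    path = Path(path)
    fmt = fmt or {"": "edgelist_tsv", ".graphml": "graphml", ".tsv": "edgelist_tsv",
                  ".json": "json"}.get(path.suffix.lower(), None)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edgelist_tsv":
        rows = [(a, b, d["weight"]) for a, b, d in g.edges(data=True)]
        df = pd.DataFrame(rows, columns=["source", "target", "weight"])
        df = df.sort_values(["source", "target"], ignore_index=True)
        header = "#nodes\t" + ",".join(sorted(g.nodes)) + "\n"
        path.write_text(header + df.to_csv(sep="\t", index=False))
    elif fmt == "json":
        payload = {
            "nodes": sorted(g.nodes),
            "edges": sorted(
                [sorted([a, b]) + [int(d["weight"])] for a, b, d in g.edges(data=True)]
            ),
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValidationError(f"unknown network format: {fmt!r}")


def import_network(path, fmt: str | None = None) -> nx.Graph:
    path = Path(path)
    fmt = fmt or {".graphml": "graphml", ".tsv": "edgelist_tsv",
                  ".json": "json"}.get(path.suffix.lower(), None)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        out.add_nodes_from(g.nodes)
        for a, b, d in g.edges(data=True):
            out.add_edge(a, b, weight=int(d["weight"]))
        return out
    if fmt == "edgelist_tsv":
        lines = path.read_text().splitlines()
        g = nx.Graph()
        if lines and lines[0].startswith("#nodes\t"):
            nodes = lines[0].split("\t", 1)[1]
            if nodes:
                g.add_nodes_from(nodes.split(","))
            lines = lines[1:]
        if lines:
            from io import StringIO
            df = pd.read_csv(StringIO("\n".join(lines)), sep="\t")
            for r in df.itertuples(index=False):
                g.add_edge(str(r.source), str(r.target), weight=int(r.weight))
        return g
    if fmt == "json":
        payload = json.loads(path.read_text())
        g = nx.Graph()
        g.add_nodes_from(payload["nodes"])
        for a, b, w in payload["edges"]:
            g.add_edge(a, b, weight=int(w))
        return g
    raise ValidationError(f"unknown network format: {fmt!r}")


def plot_network(g: nx.Graph, path, weight_scale: float = 10.0, seed: int = 0) -> None:
    """Spring-layout rendering with edge width proportional to weight."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(g, seed=seed)
    widths = [d["weight"] / weight_scale for _, _, d in g.edges(data=True)]
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx(g, pos=pos, ax=ax, width=widths, node_color="#a6cee3",
                     edge_color="#666666")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
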