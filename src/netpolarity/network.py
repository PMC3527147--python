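"""Directed signaling networks and hierarchy metrics.

A signaling network is a directed graph whose nodes are genes (opaque,
case-sensitive identifiers) and whose edges are signed regulatory
interactions (activate / inhibit / unspecified).  The hierarchy of a gene is
summarized by its in-degree (number of upstream modulators), out-degree
(number of direct downstream targets), and H — the number of distinct other
genes reachable downstream through directed paths of any length.

Genes with out-degree > 0 and in-degree = 0 sit at the extreme upstream end
of the network; in-degree > 0 with out-degree = 0 is the extreme downstream
end; both positive is intermediate; both zero is isolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import networkx as nx
import pandas as pd

__all__ = [
    "SignalingNetwork",
    "HierarchyProfile",
    "LoadReport",
    "load_edge_list",
    "degree_profile",
    "downstream_closure",
    "classify_positions",
    "hierarchy_profiles",
    "pathway_positions",
    "write_edge_list",
    "write_hierarchy",
    "network_from_edges",
]

SIGN_TOKENS = {"+": "activate", "-": "inhibit", "?": "unspecified",
               "activate": "activate", "inhibit": "inhibit",
               "unspecified": "unspecified"}
UNDIRECTED_TOKENS = {"u", "undirected"}
POSITION_CLASSES = ("upstream", "downstream", "intermediate", "isolated")


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list input, naming the offending line."""


@dataclass
class LoadReport:
    """Bookkeeping from :func:`load_edge_list`."""

    n_rows: int = 0
    n_dropped_undirected: int = 0
    n_collapsed_duplicates: int = 0


@dataclass
class SignalingNetwork:
    """A directed, signed, non-redundant signaling network.

    ``edges`` maps each ordered (source, target) pair to its sign; at most
    one edge exists per ordered pair.  ``nodes`` may include genes without
    any edge (isolated).
    """

    nodes: set[str]
    edges: dict[tuple[str, str], str]
    load_report: LoadReport | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        for (s, t) in self.edges:
            self.nodes.add(s)
            self.nodes.add(t)
        self._graph: nx.DiGraph | None = None

    @property
    def graph(self) -> nx.DiGraph:
        """The network as a networkx DiGraph (built lazily, cached)."""
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.nodes)
            for (s, t), sign in self.edges.items():
                g.add_edge(s, t, sign=sign)
            self._graph = g
        return self._graph

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_node(self, gene: str) -> bool:
        return gene in self.nodes


@dataclass
class HierarchyProfile:
    """Hierarchy metrics of a single gene."""

    gene: str
    in_degree: int
    out_degree: int
    H: int
    position_class: str


def load_edge_list(
    source: str | Path | TextIO,
    columns: Mapping[str, str] | None = None,
) -> SignalingNetwork:
    """Load a tab-separated directed edge list.

    The file must carry a header naming at least a source and a target
    column (default names ``source``/``target``/``sign``; remap via
    ``columns``, e.g. ``{"source": "from", "target": "to"}``).  The sign
    column is optional and defaults to unspecified.  Rows whose sign token
    marks the interaction as undirected are dropped — an undirected physical
    interaction carries no hierarchy information.  Duplicate ordered pairs
    collapse to a single edge; when the duplicates disagree on sign the
    collapsed edge is marked unspecified.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source, "r", encoding="utf-8")
        close = True
    else:
        handle = source
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise EdgeListParseError("edge list is empty")

    colmap = {"source": "source", "target": "target", "sign": "sign"}
    if columns:
        colmap.update(columns)
    header = [h.strip() for h in lines[0].split("\t")]
    try:
        i_src = header.index(colmap["source"])
        i_tgt = header.index(colmap["target"])
    except ValueError as exc:
        raise EdgeListParseError(
            f"header must contain columns {colmap['source']!r} and "
            f"{colmap['target']!r}; got {header!r}") from exc
    i_sign = header.index(colmap["sign"]) if colmap["sign"] in header else None

    report = LoadReport()
    edges: dict[tuple[str, str], str] = {}
    nodes: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise EdgeListParseError(
                f"line {lineno}: expected {len(header)} columns, got {len(fields)}")
        report.n_rows += 1
        s = fields[i_src].strip()
        t = fields[i_tgt].strip()
        if not s or not t:
            raise EdgeListParseError(f"line {lineno}: empty gene identifier")
        raw_sign = fields[i_sign].strip() if i_sign is not None else "?"
        if raw_sign.lower() in UNDIRECTED_TOKENS:
            report.n_dropped_undirected += 1
            continue
        sign = SIGN_TOKENS.get(raw_sign, "unspecified")
        key = (s, t)
        if key in edges:
            report.n_collapsed_duplicates += 1
            if edges[key] != sign:
                edges[key] = "unspecified"
        else:
            edges[key] = sign
        nodes.add(s)
        nodes.add(t)
    if not edges:
        raise EdgeListParseError("edge list contains no directed edges")
    return SignalingNetwork(nodes=nodes, edges=edges, load_report=report)


def degree_profile(network: SignalingNetwork) -> dict[str, tuple[int, int]]:
    """Per-gene (in_degree, out_degree).  A self-loop adds 1 to each."""
    g = network.graph
    return {n: (g.in_degree(n), g.out_degree(n)) for n in g.nodes}


def downstream_closure(network: SignalingNetwork, gene: str) -> tuple[set[str], int]:
    """All genes reachable downstream of ``gene``, and their count H.

    The reachable set contains every gene with a directed path of length
    >= 1 from the focal gene — including the focal gene itself when it lies
    on a cycle.  H excludes the focal gene (it counts *other* proteins
    acting downstream).
    """
    if not network.has_node(gene):
        raise KeyError(f"unknown gene: {gene!r}")
    g = network.graph
    desc = nx.descendants(g, gene)
    reachable = set(desc)
    if g.has_edge(gene, gene) or any(
            t != gene and nx.has_path(g, t, gene) for t in g.successors(gene)):
        reachable.add(gene)
    return reachable, len(desc - {gene})


def classify_positions(
    degrees: Mapping[str, tuple[int, int]],
) -> dict[str, str]:
    """Partition genes into upstream / downstream / intermediate / isolated."""
    out = {}
    for gene, (ind, outd) in degrees.items():
        if outd > 0 and ind == 0:
            out[gene] = "upstream"
        elif ind > 0 and outd == 0:
            out[gene] = "downstream"
        elif ind > 0 and outd > 0:
            out[gene] = "intermediate"
        else:
            out[gene] = "isolated"
    return out


def hierarchy_profiles(network: SignalingNetwork) -> pd.DataFrame:
    """Degrees, H and position class for every gene, as a DataFrame.

    H for all genes at once is computed on the condensation of the graph
    (strongly connected components), accumulating downstream membership as
    bitmasks in reverse topological order — linear in edges rather than one
    graph traversal per gene.
    """
    g = network.graph
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    cond = nx.condensation(g)
    full_mask = {
        c: sum(1 << idx[m] for m in cond.nodes[c]["members"])
        for c in cond.nodes
    }
    reach: dict[int, int] = {}
    for c in reversed(list(nx.topological_sort(cond))):
        acc = 0
        for d in cond.successors(c):
            acc |= full_mask[d] | reach[d]
        reach[c] = acc

    comp_of = {}
    for c in cond.nodes:
        for m in cond.nodes[c]["members"]:
            comp_of[m] = c

    rows = []
    degs = degree_profile(network)
    classes = classify_positions(degs)
    for n in nodes:
        c = comp_of[n]
        in_cycle = len(cond.nodes[c]["members"]) > 1 or g.has_edge(n, n)
        mask = reach[c] | (full_mask[c] if in_cycle else 0)
        h = (mask & ~(1 << idx[n])).bit_count()
        ind, outd = degs[n]
        rows.append((n, ind, outd, h, classes[n]))
    return pd.DataFrame(
        rows, columns=["gene", "in_degree", "out_degree", "H", "position_class"],
    ).set_index("gene")


def pathway_positions(network: SignalingNetwork, source: str) -> dict[str, int]:
    """Shortest directed step count from ``source`` to each reachable gene.

    The source itself is at position 0.  Genes not reachable from the source
    are absent from the result (treated as missing downstream, not
    infinity).
    """
    if not network.has_node(source):
        raise KeyError(f"unknown source gene: {source!r}")
    return dict(nx.single_source_shortest_path_length(network.graph, source))


def write_edge_list(network: SignalingNetwork, path: str | Path) -> None:
    """Serialize the network as the tab-separated dialect read back by
    :func:`load_edge_list`."""
    token = {"activate": "+", "inhibit": "-", "unspecified": "?"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tsign\n")
        for (s, t) in sorted(network.edges):
            fh.write(f"{s}\t{t}\t{token[network.edges[(s, t)]]}\n")


def write_hierarchy(profiles: pd.DataFrame, path: str | Path) -> None:
    """Write the hierarchy table (gene, degrees, H, position class) as TSV."""
    profiles.to_csv(path, sep="\t")


def network_from_edges(
    edges: Iterable[tuple[str, str]] | Iterable[tuple[str, str, str]],
    nodes: Iterable[str] = (),
) -> SignalingNetwork:
    """Build a network from in-memory edge tuples (sign optional)."""
    edict: dict[tuple[str, str], str] = {}
    for e in edges:
        if len(e) == 3:
            s, t, sign = e  # type: ignore[misc]
        else:
            (s, t), sign = e, "unspecified"  # type: ignore[misc]
        key = (s, t)
        if key in edict and edict[key] != sign:
            edict[key] = "unspecified"
        else:
            edict[key] = sign
    return SignalingNetwork(nodes=set(nodes), edges=edict)
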