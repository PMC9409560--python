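"""Graph and gene-set data model plus readers/writers for the text formats the
pipeline consumes.

The interactome is held as an undirected simple :class:`networkx.Graph` whose
nodes are gene symbols.  Loaders enforce the invariants every downstream stage
relies on: no self-loops, no duplicate edges, non-empty trimmed symbols.

Gene-symbol matching is case-sensitive exact matching after whitespace
trimming; pass ``uppercase=True`` to a loader to force symbols to upper case
(useful when mixing sources with inconsistent capitalisation).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "load_edge_list",
    "write_edge_list",
    "merge_interactomes",
    "load_gene_set",
    "write_gene_set",
    "load_ortholog_table",
    "map_orthologs",
    "induced_subgraph",
]


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated, order-preserving collection of gene symbols."""

    name: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        cleaned: list[str] = []
        seen: set[str] = set()
        for g in self.genes:
            g = g.strip()
            if not g:
                raise ValueError(f"gene set {self.name!r} contains an empty symbol")
            if g not in seen:
                seen.add(g)
                cleaned.append(g)
        object.__setattr__(self, "genes", tuple(cleaned))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def intersection(self, other: "GeneSet | Iterable[str]", name: str | None = None) -> "GeneSet":
        """Order-preserving intersection (order of ``self``)."""
        other_set = set(other)
        return GeneSet(
            name or f"{self.name}&{getattr(other, 'name', 'set')}",
            tuple(g for g in self.genes if g in other_set),
        )

    def union(self, other: "GeneSet | Iterable[str]", name: str | None = None) -> "GeneSet":
        """Order-preserving union: members of ``self`` then new members of ``other``."""
        mine = set(self.genes)
        extra = tuple(g for g in other if g not in mine)
        return GeneSet(
            name or f"{self.name}|{getattr(other, 'name', 'set')}",
            self.genes + extra,
        )

    def difference(self, other: "GeneSet | Iterable[str]", name: str | None = None) -> "GeneSet":
        other_set = set(other)
        return GeneSet(
            name or f"{self.name}-{getattr(other, 'name', 'set')}",
            tuple(g for g in self.genes if g not in other_set),
        )

    def uppercased(self) -> "GeneSet":
        return GeneSet(self.name, tuple(g.upper() for g in self.genes))


def _parse_edge_line(fields: list[str], fmt: str) -> list[tuple[str, str]]:
    if fmt == "tsv":
        return [(fields[0], fields[1])]
    # SIF: nodeA <tab> relation <tab> nodeB [nodeC ...]
    src = fields[0]
    return [(src, tgt) for tgt in fields[2:]]


def load_edge_list(path: str | Path, fmt: str = "tsv", uppercase: bool = False) -> nx.Graph:
    """Read an undirected interactome from a two-column TSV or SIF file.

    Blank lines and lines starting with ``#`` are skipped.  Self-loops are
    dropped and duplicate edges collapsed; both events are counted in a logged
    load report.

    Parameters
    ----------
    path
        Edge-list file.  TSV: one edge per line, first two whitespace/tab
        separated fields are the endpoints.  SIF: ``nodeA<TAB>rel<TAB>nodeB...``
        with one edge per trailing node.
    fmt
        ``"tsv"`` or ``"sif"``.
    uppercase
        Force gene symbols to upper case on load.

    Raises
    ------
    ValueError
        On a malformed line (fewer fields than the format requires, naming the
        line number) or if the resulting graph has no edges and no nodes.
    """
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {fmt!r}; expected 'tsv' or 'sif'")
    path = Path(path)
    graph = nx.Graph()
    n_self_loops = 0
    n_duplicates = 0
    min_fields = 2 if fmt == "tsv" else 3
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t" if "\t" in line else None)]
            fields = [f for f in fields if f]
            if len(fields) < min_fields:
                raise ValueError(
                    f"{path}:{lineno}: malformed line (expected >= {min_fields} fields, "
                    f"got {len(fields)}): {line!r}"
                )
            for u, v in _parse_edge_line(fields, fmt):
                if uppercase:
                    u, v = u.upper(), v.upper()
                if u == v:
                    n_self_loops += 1
                    continue
                if graph.has_edge(u, v):
                    n_duplicates += 1
                    continue
                graph.add_edge(u, v)
    if graph.number_of_nodes() == 0:
        raise ValueError(f"{path}: empty graph (no valid edges)")
    logger.info(
        "loaded %s: %d nodes, %d edges (%d self-loops dropped, %d duplicate edges collapsed)",
        path, graph.number_of_nodes(), graph.number_of_edges(), n_self_loops, n_duplicates,
    )
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a canonical (lexicographically sorted) two-column TSV edge list."""
    path = Path(path)
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    with path.open("w") as fh:
        fh.write("# source\ttarget\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
    logger.info("wrote %s: %d edges", path, len(edges))


def merge_interactomes(graphs: Iterable[nx.Graph]) -> nx.Graph:
    """Union several edge lists into one interactome (e.g. multiple PPI sources)."""
    merged = nx.Graph()
    for g in graphs:
        merged.add_nodes_from(g.nodes())
        merged.add_edges_from(g.edges())
    return merged


def load_gene_set(path: str | Path, name: str | None = None, uppercase: bool = False) -> GeneSet:
    """Read a gene list: one symbol per line, ``#`` comments and blanks ignored.

    Duplicates are removed (order-preserving) and their count logged.

    Raises
    ------
    ValueError
        If the file contains no gene symbols.
    """
    path = Path(path)
    symbols: list[str] = []
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            symbols.append(line.upper() if uppercase else line)
    if not symbols:
        raise ValueError(f"{path}: no gene symbols found")
    gs = GeneSet(name or path.stem, tuple(symbols))
    n_dup = len(symbols) - len(gs)
    if n_dup:
        logger.info("loaded %s: %d genes (%d duplicates removed)", path, len(gs), n_dup)
    else:
        logger.info("loaded %s: %d genes", path, len(gs))
    return gs


def write_gene_set(genes: GeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes.genes))


def load_ortholog_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping source symbols to target symbols.

    Only one-to-one pairs are retained: any source mapping to several targets,
    or target mapped from several sources, is dropped (with a logged count).
    """
    path = Path(path)
    src_to_tgts: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed ortholog line: {line!r}")
            src_to_tgts.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    tgt_counts: dict[str, int] = {}
    for tgts in src_to_tgts.values():
        for t in tgts:
            tgt_counts[t] = tgt_counts.get(t, 0) + 1
    table = {
        s: next(iter(tgts))
        for s, tgts in src_to_tgts.items()
        if len(tgts) == 1 and tgt_counts[next(iter(tgts))] == 1
    }
    n_dropped = len(src_to_tgts) - len(table)
    if n_dropped:
        logger.info("%s: kept %d one-to-one pairs, dropped %d ambiguous", path, len(table), n_dropped)
    return table


def map_orthologs(genes: GeneSet, table: Mapping[str, str]) -> GeneSet:
    """Map a gene set through an ortholog table, dropping unmapped genes.

    Returns the mapped symbols (order-preserving, deduplicated).  Genes absent
    from the table are dropped and counted in the log; an empty result only
    produces a warning.
    """
    if not table:
        raise ValueError("ortholog table is empty")
    mapped = [table[g] for g in genes if g in table]
    n_dropped = len(genes) - len(mapped)
    if n_dropped:
        logger.info("ortholog mapping of %s: %d mapped, %d dropped", genes.name, len(mapped), n_dropped)
    if not mapped:
        logger.warning("ortholog mapping of %s: no genes mapped", genes.name)
        return GeneSet(genes.name, ())
    return GeneSet(genes.name, tuple(mapped))


def induced_subgraph(net: nx.Graph, genes: GeneSet | Iterable[str]) -> nx.Graph:
    """Subgraph induced by ``genes`` ∩ ``net`` nodes.

    Nodes are the mapped genes; edges are the interactome edges with both
    endpoints mapped.  An empty result is allowed (warning only).
    """
    members = [g for g in genes if g in net]
    if not members:
        logger.warning("induced_subgraph: no input genes map onto the interactome")
    return net.subgraph(members).copy()
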