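"""Seeded synthetic-data generators with planted structure.

Every input the pipeline consumes can be simulated here: a sparse interactome,
gene sets planted as localized modules with tunable mutual proximity, a GMT
collection with one genuinely enriched set, and an annotated single-cell
expression matrix with planted cell-type markers.  Because the planted
structure is known, localization, proximity, enrichment and EWCE stages can
each be tested for parameter recovery and null calibration without any
external download.

All generators are pure functions of their configuration and seed: the same
config yields bit-identical outputs.

Default scales emulate the study conditions the pipeline targets: an
interactome of ~10^4 nodes with mean degree ~5 (sparse, like curated PPI
networks), planted modules of a few dozen genes (the scale of disease gene
sets), and a few hundred cells split over a handful of cell types with
negative-binomially distributed counts (overdispersed, as scRNA-seq counts
are), 40 markers per type at 5x baseline expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from netoverlap.interactome import GeneSet, write_edge_list, write_gene_set
from netoverlap.overlap_stats import write_gmt

__all__ = [
    "SimulationConfig",
    "simulate_interactome",
    "plant_module",
    "plant_overlapping_sets",
    "simulate_expression",
    "simulate_gene_set_collection",
    "write_fixture_bundle",
]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic inputs.

    model_params holds graph-model parameters (``p`` for erdos_renyi, ``m``
    for barabasi_albert, ``p``/``q`` retention for duplication_divergence)
    and expression parameters (``n_genes``, ``mu`` baseline NB mean,
    ``theta`` NB dispersion, ``markers_per_type``).
    """

    seed: int = 0
    n_nodes: int = 10_000
    graph_model: str = "erdos_renyi"
    model_params: dict = field(default_factory=dict)
    module_size: int = 30
    module_edge_prob: float = 0.3
    marker_fold: float = 5.0
    n_cell_types: int = 4
    cells_per_type: int = 100

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.module_size < 1 or self.n_cell_types < 1 or self.cells_per_type < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.module_edge_prob <= 1:
            raise ValueError("module_edge_prob must lie in [0, 1]")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def simulate_interactome(cfg: SimulationConfig) -> nx.Graph:
    """Sparse random interactome with zero-padded symbolic gene names."""
    width = max(4, len(str(cfg.n_nodes)))
    params = cfg.model_params
    if cfg.graph_model == "erdos_renyi":
        p = params.get("p", 5.0 / max(cfg.n_nodes - 1, 1))  # mean degree ~5
        g = nx.gnp_random_graph(cfg.n_nodes, p, seed=cfg.seed)
    elif cfg.graph_model == "barabasi_albert":
        m = params.get("m", 3)
        if not 1 <= m < cfg.n_nodes:
            raise ValueError(f"barabasi_albert needs 1 <= m < n_nodes, got m={m}")
        g = nx.barabasi_albert_graph(cfg.n_nodes, m, seed=cfg.seed)
    elif cfg.graph_model == "duplication_divergence":
        p = params.get("p", 0.3)
        if not 0 < p <= 1:
            raise ValueError("duplication_divergence retention p must lie in (0, 1]")
        g = nx.duplication_divergence_graph(cfg.n_nodes, p, seed=cfg.seed)
    else:
        raise ValueError(f"unknown graph model {cfg.graph_model!r}")
    return nx.relabel_nodes(g, {i: _gene_name(i, width) for i in g.nodes()})


def plant_module(net: nx.Graph, size: int, edge_prob: float, seed: int,
                 name: str = "planted_module") -> GeneSet:
    """Plant a localized module: snowball-sample nodes, densify internally.

    A random-walk (snowball) sample guarantees the selected node set induces a
    connected subgraph even before densification; internal edges are then
    added independently with probability ``edge_prob``.  The interactome is
    modified in place; the planted gene set is returned.
    """
    if size > net.number_of_nodes():
        raise ValueError("module size exceeds interactome size")
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes())
    module: list[str] = [nodes[rng.integers(len(nodes))]]
    chosen = set(module)
    while len(module) < size:
        frontier = sorted(
            {nb for m in module for nb in net.neighbors(m)} - chosen
        )
        if frontier:
            nxt = frontier[rng.integers(len(frontier))]
        else:
            # component exhausted: jump to a fresh node and wire it in so the
            # induced subgraph stays connected
            outside = sorted(set(nodes) - chosen)
            nxt = outside[rng.integers(len(outside))]
            net.add_edge(module[rng.integers(len(module))], nxt)
        module.append(nxt)
        chosen.add(nxt)
    for i in range(size):
        for j in range(i + 1, size):
            if rng.random() < edge_prob:
                net.add_edge(module[i], module[j])
    return GeneSet(name, tuple(module))


def plant_overlapping_sets(
    net: nx.Graph,
    size_a: int,
    size_b: int,
    shared: int,
    seed: int,
    edge_prob: float = 0.3,
) -> tuple[GeneSet, GeneSet]:
    """Two gene sets drawn from one planted module, with ``shared`` common genes.

    Both sets live inside a single dense module of size
    ``size_a + size_b - shared``, so their separation score is expected to be
    negative and to decrease as the shared fraction grows.
    """
    if shared > min(size_a, size_b):
        raise ValueError("shared cannot exceed either set size")
    total = size_a + size_b - shared
    if total > net.number_of_nodes():
        raise ValueError("combined set size exceeds interactome size")
    module = plant_module(net, total, edge_prob, seed, name="planted_overlap_module")
    genes = list(module.genes)
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(len(genes))
    shared_g = [genes[i] for i in perm[:shared]]
    a_only = [genes[i] for i in perm[shared:shared + size_a - shared]]
    b_only = [genes[i] for i in perm[shared + size_a - shared:]]
    return (
        GeneSet("planted_A", tuple(shared_g + a_only)),
        GeneSet("planted_B", tuple(shared_g + b_only)),
    )


def simulate_expression(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Annotated single-cell count matrix with planted cell-type markers.

    Counts follow a negative binomial with baseline mean ``mu`` and dispersion
    ``theta`` (``model_params``; defaults mu=2, theta=2); each cell type owns
    a disjoint marker block whose mean is ``mu * marker_fold`` within its own
    type.  Returns (genes x cells counts, cell -> type annotations, truth
    table of planted markers).
    """
    params = cfg.model_params
    mu = float(params.get("mu", 2.0))
    theta = float(params.get("theta", 2.0))
    markers_per_type = int(params.get("markers_per_type", 40))
    n_genes = int(params.get("n_genes", max(500, 2 * markers_per_type * cfg.n_cell_types)))
    if mu <= 0 or theta <= 0:
        raise ValueError("mu and theta must be positive")
    if markers_per_type * cfg.n_cell_types > n_genes:
        raise ValueError("marker blocks exceed the number of genes")
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(n_genes)))
    genes = [_gene_name(i, width) for i in range(n_genes)]
    types = [f"type{t + 1}" for t in range(cfg.n_cell_types)]
    n_cells = cfg.n_cell_types * cfg.cells_per_type
    cells = [f"C{i:05d}" for i in range(n_cells)]
    labels = np.repeat(types, cfg.cells_per_type)

    mean = np.full((n_genes, n_cells), mu)
    truth_rows = []
    for t, typ in enumerate(types):
        lo, hi = t * markers_per_type, (t + 1) * markers_per_type
        mean[lo:hi, labels == typ] = mu * cfg.marker_fold
        if cfg.marker_fold > 1:
            truth_rows += [(genes[i], typ) for i in range(lo, hi)]
    # NB(mean, dispersion theta): p = theta / (theta + mean)
    counts = rng.negative_binomial(theta, theta / (theta + mean))
    expr = pd.DataFrame(counts, index=genes, columns=cells)
    annot = pd.Series(labels, index=cells, name="cell_type")
    truth = pd.DataFrame(truth_rows, columns=["gene", "marker_of"])
    return expr, annot, truth


def simulate_gene_set_collection(
    query: GeneSet,
    universe: GeneSet,
    seed: int,
    n_sets: int = 50,
    set_size: int = 40,
    planted_fraction: float = 0.8,
    planted_name: str = "planted_set",
) -> list[GeneSet]:
    """GMT collection with one planted enriched set among random decoys.

    The planted set contains ``planted_fraction`` of the query (topped up with
    random universe genes to ``set_size``); the remaining ``n_sets - 1`` sets
    are uniform samples from the universe.
    """
    if not 0 < planted_fraction <= 1:
        raise ValueError("planted_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    uni = list(universe.genes)
    n_from_query = min(int(round(planted_fraction * len(query))), set_size)
    picked = [query.genes[i] for i in rng.permutation(len(query))[:n_from_query]]
    filler_pool = [g for g in uni if g not in set(picked)]
    filler_idx = rng.permutation(len(filler_pool))[: max(0, set_size - n_from_query)]
    planted = GeneSet(planted_name, tuple(picked + [filler_pool[i] for i in filler_idx]))
    sets = [planted]
    for s in range(n_sets - 1):
        idx = rng.permutation(len(uni))[:set_size]
        sets.append(GeneSet(f"random_set_{s + 1:03d}", tuple(uni[i] for i in idx)))
    return sets


def write_fixture_bundle(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate every pipeline input and write it under ``outdir``.

    Writes edges.tsv, genes_a.txt, genes_b.txt, universe.txt, sets.gmt,
    expr.tsv, annot.tsv, truth.tsv and orthologs.tsv (identity map for the
    planted query so the EWCE stage can exercise ortholog mapping).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = simulate_interactome(cfg)
    a, b = plant_overlapping_sets(
        net, cfg.module_size, cfg.module_size,
        shared=cfg.module_size // 3, seed=cfg.seed + 1,
        edge_prob=cfg.module_edge_prob,
    )
    universe = GeneSet("universe", tuple(sorted(net.nodes())))
    sets = simulate_gene_set_collection(a, universe, seed=cfg.seed + 2)
    expr, annot, truth = simulate_expression(cfg)

    paths = {
        "network": outdir / "edges.tsv",
        "genes_a": outdir / "genes_a.txt",
        "genes_b": outdir / "genes_b.txt",
        "universe": outdir / "universe.txt",
        "gmt": outdir / "sets.gmt",
        "expression": outdir / "expr.tsv",
        "annotations": outdir / "annot.tsv",
        "truth": outdir / "truth.tsv",
        "orthologs": outdir / "orthologs.tsv",
    }
    write_edge_list(net, paths["network"])
    write_gene_set(a, paths["genes_a"])
    write_gene_set(b, paths["genes_b"])
    write_gene_set(universe, paths["universe"])
    write_gmt(sets, paths["gmt"])
    expr.to_csv(paths["expression"], sep="\t")
    annot.rename_axis("cell_id").to_frame().to_csv(paths["annotations"], sep="\t", header=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    # identity orthologs over the expression genes (pipeline smoke use)
    with paths["orthologs"].open("w") as fh:
        for g in expr.index:
            fh.write(f"{g}\t{g}\n")
    return paths
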