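"""Exact gene-set overlap statistics and GMT-collection enrichment.

Fisher's exact test (two-sided, point-probability rule — the convention of
R's ``fisher.test``) quantifies whether two gene sets overlap more than
expected in a stated background universe; hypergeometric upper-tail tests
score a query list against every set of a GMT collection, with
Benjamini–Hochberg and Bonferroni adjustment across sets.

The background universe is an explicit, required input — either a gene list
(membership is then checked) or a plain integer count.  The reported odds
ratio is the sample estimate ad/bc (infinite when b·c = 0); the
conditional-MLE estimate is also computed for comparison with R.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path
from collections.abc import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from netoverlap.interactome import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "OverlapResult",
    "EnrichmentRecord",
    "fisher_overlap",
    "gmt_enrichment",
    "adjust_pvalues",
    "load_gmt",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 membership table: a in both, b in B only, c in A only, d in neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class OverlapResult:
    table: ContingencyTable
    odds_ratio: float  # sample OR ad/bc; inf when b*c == 0
    odds_ratio_cmle: float  # conditional-MLE OR, as R's fisher.test reports
    p_value: float  # two-sided exact
    overlap_genes: GeneSet

    def as_dict(self) -> dict:
        d = asdict(self)
        d["overlap_genes"] = list(self.overlap_genes.genes)
        return d


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    fdr: float = math.nan
    bonferroni: float = math.nan
    overlap_genes: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return asdict(self)


def _universe_members(universe: GeneSet | Sequence[str] | int) -> tuple[set[str] | None, int]:
    if isinstance(universe, int):
        if universe < 2:
            raise ValueError("universe size must be >= 2")
        return None, universe
    members = set(universe)
    if len(members) < 2:
        raise ValueError("universe must contain at least 2 genes")
    return members, len(members)


def fisher_overlap(
    A: GeneSet,
    B: GeneSet,
    universe: GeneSet | Sequence[str] | int,
) -> OverlapResult:
    """Fisher's exact test for over-representation of B members within A.

    Builds the 2x2 table from set memberships against the universe.  Genes of
    A or B outside a gene-list universe are dropped with a warning; with an
    integer universe, membership cannot be checked and sizes are used as-is.
    """
    members, n_universe = _universe_members(universe)
    genes_a, genes_b = A, B
    if members is not None:
        kept_a = A.intersection(members, name=A.name)
        kept_b = B.intersection(members, name=B.name)
        if len(kept_a) < len(A) or len(kept_b) < len(B):
            logger.warning(
                "fisher_overlap: dropped %d genes of %s and %d of %s outside the universe",
                len(A) - len(kept_a), A.name, len(B) - len(kept_b), B.name,
            )
        genes_a, genes_b = kept_a, kept_b
    overlap = genes_a.intersection(genes_b, name=f"{A.name}&{B.name}")
    a = len(overlap)
    c = len(genes_a) - a
    b = len(genes_b) - a
    d = n_universe - a - b - c
    table = ContingencyTable(a=a, b=b, c=c, d=d)
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    sample_or = (a * d / (b * c)) if b * c else math.inf
    cmle = stats.contingency.odds_ratio(table.as_array(), kind="conditional")
    return OverlapResult(
        table=table,
        odds_ratio=sample_or,
        odds_ratio_cmle=float(cmle.statistic),
        p_value=float(p),
        overlap_genes=overlap,
    )


def load_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT collection: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >= 1 gene")
            genes = tuple(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: GMT set {fields[0]!r} has no genes")
            sets.append(GeneSet(fields[0], genes))
    if not sets:
        raise ValueError(f"{path}: empty GMT collection")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")


def gmt_enrichment(
    query: GeneSet,
    collection: Sequence[GeneSet] | str | Path,
    universe: GeneSet | Sequence[str],
) -> list[EnrichmentRecord]:
    """Hypergeometric upper-tail enrichment of a query list in each GMT set.

    For each set, p = P(X >= overlap) with X ~ Hypergeom(universe, set ∩
    universe, query ∩ universe).  BH (FDR) and Bonferroni columns are adjusted
    over all tested sets; records are returned sorted by raw p-value.  Sets
    with no member in the universe are skipped with a warning.
    """
    if isinstance(collection, (str, Path)):
        collection = load_gmt(collection)
    if not collection:
        raise ValueError("empty gene-set collection")
    members, n_universe = _universe_members(universe)
    assert members is not None, "gmt_enrichment needs an explicit gene-list universe"
    q = query.intersection(members, name=query.name)
    if len(q) == 0:
        raise ValueError("query has no genes in the universe")
    records: list[EnrichmentRecord] = []
    for s in collection:
        s_in = s.intersection(members, name=s.name)
        if len(s_in) == 0:
            logger.warning("gmt_enrichment: set %s has no genes in the universe, skipped", s.name)
            continue
        hit = q.intersection(s_in, name=s.name)
        k = len(hit)
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(s_in), len(q)))
        records.append(
            EnrichmentRecord(
                set_name=s.name,
                overlap=k,
                set_size=len(s_in),
                query_size=len(q),
                universe_size=n_universe,
                p_value=p,
                overlap_genes=hit.genes,
            )
        )
    if not records:
        raise ValueError("no gene set intersects the universe")
    raw = [r.p_value for r in records]
    fdr = adjust_pvalues(raw, method="bh")
    bonf = adjust_pvalues(raw, method="bonferroni")
    adjusted = [
        EnrichmentRecord(**{**r.as_dict(), "fdr": f, "bonferroni": b,
                            "overlap_genes": r.overlap_genes})
        for r, f, b in zip(records, fdr, bonf)
    ]
    return sorted(adjusted, key=lambda r: (r.p_value, r.set_name))


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment, order-preserving.

    ``bonferroni``: min(1, m*p).  ``bh``: Benjamini–Hochberg step-up with
    monotone enforcement.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        sm_method = "fdr_bh"
    elif method == "bonferroni":
        sm_method = "bonferroni"
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    _, adj, _, _ = multipletests(arr, alpha=0.05, method=sm_method)
    return [float(x) for x in adj]
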