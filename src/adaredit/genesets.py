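"""Gene-list bookkeeping and in-repo pathway overrepresentation.

Gene lists (e.g., a disease-association list and a differential-expression
list) are loaded into normalized sets; intersections/unions reproduce the
list arithmetic of a typical editing study (genes of interest = DE list
intersected with the disease list).  Pathway overrepresentation replaces a
web-service lookup with a binomial upper-tail test against a GMT-defined
universe, Benjamini-Hochberg adjusted, with the reporting filters applied as
flags: at least ``min_genes`` query genes in the pathway, at least
``min_fraction`` of the query list in the pathway, and FDR below ``alpha``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calling import EditingEvent

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "PathwayUniverse",
    "load_gene_list",
    "load_gmt",
    "intersect",
    "union_unique",
    "genes_of_significance",
    "edited_gene_lists",
    "enrich",
]

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_id(gene_id: str, case_insensitive: bool = False) -> str:
    """Strip whitespace and Ensembl-style version suffixes; optionally fold case."""
    g = _VERSION_SUFFIX.sub("", str(gene_id).strip())
    return g.upper() if case_insensitive else g


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def load_gene_list(
    path: str | Path,
    id_column: str = "gene_id",
    sheet: str | int | None = None,
    name: str | None = None,
    case_insensitive: bool = False,
) -> GeneSet:
    """Load a gene list from TSV/CSV or XLSX, deduplicating identifiers.

    ``sheet`` selects a worksheet for XLSX inputs.  Duplicate identifiers are
    collapsed with a logged count; an empty identifier column is an error.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
    if id_column not in df.columns:
        raise ValueError(f"{path}: no column {id_column!r} (have {list(df.columns)})")
    ids = [normalize_id(g, case_insensitive) for g in df[id_column].dropna() if str(g).strip()]
    if not ids:
        raise ValueError(f"{path}: identifier column {id_column!r} is empty")
    unique = frozenset(ids)
    dups = len(ids) - len(unique)
    if dups:
        logger.info("%s: collapsed %d duplicate identifiers", path.name, dups)
    return GeneSet(name=name or path.stem, genes=unique)


def intersect(a: GeneSet, b: GeneSet) -> GeneSet:
    return GeneSet(name=f"{a.name}&{b.name}", genes=a.genes & b.genes)


def union_unique(a: GeneSet, b: GeneSet) -> GeneSet:
    return GeneSet(name=f"{a.name}|{b.name}", genes=a.genes | b.genes)


def genes_of_significance(pre: GeneSet, post: GeneSet) -> dict[str, GeneSet]:
    """Partition two condition-specific edited-gene sets into shared,
    unique-to-pre, unique-to-post, and the combined list."""
    return {
        "shared": GeneSet("shared", pre.genes & post.genes),
        "unique_pre": GeneSet("unique_pre", pre.genes - post.genes),
        "unique_post": GeneSet("unique_post", post.genes - pre.genes),
        "combined": GeneSet("combined", pre.genes | post.genes),
    }


def edited_gene_lists(
    events: Iterable[EditingEvent],
    groups: Mapping[str, str],
    restrict_to: GeneSet | None = None,
    impacts: Sequence[str] | None = ("HIGH", "MODERATE"),
) -> dict[str, GeneSet]:
    """Per-group sets of unique genes with at least one qualifying event.

    ``impacts`` keeps only events of those impact categories (None keeps all);
    ``restrict_to`` intersects with a reference list (e.g., a disease gene
    list).  Events should already have passed the recurrence filter.
    """
    out: dict[str, set[str]] = {}
    for ev in events:
        if ev.gene_id is None:
            continue
        if impacts is not None and ev.impact not in impacts:
            continue
        gene = normalize_id(ev.gene_id)
        if restrict_to is not None and gene not in restrict_to:
            continue
        out.setdefault(groups[ev.sample_id], set()).add(gene)
    return {g: GeneSet(name=g, genes=frozenset(s)) for g, s in out.items()}


@dataclass(frozen=True)
class PathwayUniverse:
    """Pathway name -> member genes, plus the background gene universe."""

    pathways: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    @property
    def n_genes(self) -> int:
        return len(self.universe)


def load_gmt(path: str | Path, background: Iterable[str] | None = None) -> PathwayUniverse:
    """Read a GMT file (name, description, members per tab-separated line).

    The background defaults to all distinct genes across the annotation; a
    user-supplied background (e.g., all expressed genes) overrides it.
    """
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            members = frozenset(normalize_id(g) for g in parts[2:] if g.strip())
            if members:
                pathways[parts[0]] = members
    if not pathways:
        raise ValueError(f"{path}: no pathways parsed")
    if background is not None:
        universe = frozenset(normalize_id(g) for g in background)
    else:
        universe = frozenset().union(*pathways.values())
    return PathwayUniverse(pathways=pathways, universe=universe)


def enrich(
    gene_set: GeneSet,
    universe: PathwayUniverse,
    min_genes: int = 10,
    min_fraction: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Binomial pathway overrepresentation with BH FDR.

    For each pathway with at least one query gene, p = P(X >= k) where
    X ~ Binomial(n, K/N): n = effective query-list size (genes present in the
    universe), k = query genes in the pathway, K = pathway size, N = universe
    size.  ``reported`` is True iff k >= min_genes, k/n >= min_fraction and
    fdr < alpha.  Results sorted by fdr then p.
    """
    effective = gene_set.genes & universe.universe
    dropped = len(gene_set.genes) - len(effective)
    if dropped:
        logger.info("%s: %d genes absent from the universe dropped", gene_set.name, dropped)
    if not effective:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the universe")
    n = len(effective)
    N = universe.n_genes
    rows = []
    for name, members in universe.pathways.items():
        K = len(members)
        k = len(effective & members)
        if K < 1 or k < 1:
            continue
        p = float(stats.binom.sf(k - 1, n, K / N))
        rows.append({"pathway": name, "k": k, "n": n, "K": K, "N": N,
                     "pct_of_list": k / n, "p_value": p})
    df = pd.DataFrame(rows)
    if df.empty:
        df["fdr"] = []
        df["reported"] = []
        return df
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["reported"] = (
        (df["k"] >= min_genes)
        & (df["pct_of_list"] >= min_fraction)
        & (df["fdr"] < alpha)
    )
    return df.sort_values(["fdr", "p_value"], kind="mergesort").reset_index(drop=True)
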