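"""Rank-based scan of GO categories for accelerated protein evolution.

Instead of thresholding genes into a "fast" set, every retained GO
category is tested with a one-sided Mann-Whitney U test asking whether
its member orthologs rank higher than all remaining orthologs with
respect to dS, dN or dN/dS. Annotations are first propagated to all
ancestors (is_a and, by default, part_of); categories with fewer than 5
members or holding more than 25% of all orthologs are discarded;
categories with identical member sets collapse to the most specific
term. Benjamini-Hochberg step-up control flags categories passing a 10%
FDR, separately per statistic and per GO namespace. Retained categories
are also clustered (average linkage on 1 - |shared|/min size) for the
heat-map-style export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode
from statsmodels.stats.multitest import multipletests

from .io_core import GoOntology, GoScanConfig
from .rate_stats import mwu

STATISTICS = ("dS", "dN", "omega")


def propagate_annotations(
    gene_go: dict[str, set[str]], ontology: GoOntology
) -> dict[str, set[str]]:
    """Close each gene's annotation set under the ancestor relation.

    Unknown term IDs are skipped (annotation sources routinely lag the
    ontology release). Idempotent: propagating a closed mapping returns
    it unchanged.
    """
    closed: dict[str, set[str]] = {}
    for gene, terms in gene_go.items():
        out: set[str] = set()
        for term in terms:
            if term not in ontology.terms:
                continue
            out.add(term)
            out |= ontology.ancestors(term)
        closed[gene] = out
    return closed


def categories_from_mapping(
    gene_go: dict[str, set[str]], namespace: str, ontology: GoOntology
) -> dict[str, set[str]]:
    """Invert a propagated gene->terms mapping into term->gene sets for
    one namespace."""
    cats: dict[str, set[str]] = {}
    for gene, terms in gene_go.items():
        for term in terms:
            if ontology.namespace(term) == namespace:
                cats.setdefault(term, set()).add(gene)
    return cats


def filter_categories(
    cats: dict[str, set[str]], n_total: int, min_n: int = 5, max_frac: float = 0.25
) -> dict[str, set[str]]:
    """Drop categories represented by fewer than ``min_n`` orthologs or
    containing more than ``max_frac`` of all orthologs (strict: exactly
    min_n is kept, exactly the fraction bound is kept)."""
    cap = int(np.floor(max_frac * n_total))
    return {t: g for t, g in cats.items() if len(g) >= min_n and len(g) <= cap}


def dedupe_categories(cats: dict[str, set[str]], ontology: GoOntology) -> dict[str, set[str]]:
    """Among categories with identical gene sets keep the most specific
    (greatest depth; ties -> smallest term ID)."""
    by_set: dict[frozenset, list[str]] = {}
    for term, genes in cats.items():
        by_set.setdefault(frozenset(genes), []).append(term)
    out: dict[str, set[str]] = {}
    for genes, terms in by_set.items():
        winner = min(terms, key=lambda t: (-ontology.depth(t), t))
        out[winner] = set(genes)
    return out


def category_similarity(a: set[str], b: set[str]) -> float:
    """|a n b| / min(|a|, |b|)."""
    if not a or not b:
        raise ValueError("category similarity requires non-empty sets")
    return len(a & b) / min(len(a), len(b))


def cluster_categories(cats: dict[str, set[str]]) -> tuple[TreeNode, list[str]]:
    """Average-linkage (UPGMA) clustering of categories on dissimilarity
    1 - similarity; returns (tree, leaf order). A single category gives
    a single-leaf tree."""
    terms = sorted(cats)
    if len(terms) < 2:
        tree = TreeNode(name=terms[0] if terms else None)
        return tree, terms
    n = len(terms)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - category_similarity(cats[terms[i]], cats[terms[j]])
            D[i, j] = D[j, i] = d
    Z = linkage(squareform(D, checks=False), method="average")
    tree = TreeNode.from_linkage_matrix(Z, terms)
    order = [terms[i] for i in leaves_list(Z)]
    return tree, order


def rank_scan(
    cats: dict[str, set[str]],
    stat_values: dict[str, dict[str, float]],
    cfg: GoScanConfig | None = None,
) -> pd.DataFrame:
    """One-sided MWU per (category, statistic): members vs non-members,
    alternative 'members rank higher'.

    ``stat_values`` maps statistic name -> {gene -> value} over the
    analyzed ortholog set. Categories whose complement is empty are
    skipped. Returns a frame with term, statistic, n_members, U, p_raw.
    """
    cfg = cfg or GoScanConfig()
    rows = []
    for term in sorted(cats):
        members = cats[term]
        for stat in STATISTICS:
            values = stat_values.get(stat)
            if values is None:
                continue
            x = [values[g] for g in sorted(members) if g in values]
            y = [values[g] for g in sorted(set(values) - members)]
            if not x or not y:
                continue
            u, p = mwu(x, y, "greater", exact_max_n=cfg.exact_max_n)
            rows.append(
                {"term": term, "statistic": stat, "n_members": len(x), "U": u, "p_raw": p}
            )
    return pd.DataFrame(rows, columns=["term", "statistic", "n_members", "U", "p_raw"])


def bh_adjust(pvals: list[float] | np.ndarray, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted P-values and pass flags
    (adjusted P <= q)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("P-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


@dataclass
class CategoryScanResult:
    """Scan output for one GO namespace."""

    namespace: str
    table: pd.DataFrame  # term, statistic, n_members, U, p_raw, p_adj, passes_fdr
    categories: dict[str, set[str]]
    tree: TreeNode = None
    leaf_order: list[str] = field(default_factory=list)


def scan_namespace(
    gene_go: dict[str, set[str]],
    ontology: GoOntology,
    namespace: str,
    stat_values: dict[str, dict[str, float]],
    cfg: GoScanConfig | None = None,
) -> CategoryScanResult:
    """Full category scan for one namespace: propagate, filter, dedupe,
    rank-test, BH-adjust (per statistic), cluster."""
    cfg = cfg or GoScanConfig()
    closed = propagate_annotations(gene_go, ontology)
    cats = categories_from_mapping(closed, namespace, ontology)
    # population: orthologs carrying at least one term in this namespace
    n_total = sum(1 for terms in closed.values() if any(
        ontology.namespace(t) == namespace for t in terms
    ))
    cats = filter_categories(cats, n_total, cfg.min_n, cfg.max_frac)
    cats = dedupe_categories(cats, ontology)
    table = rank_scan(cats, stat_values, cfg)
    if len(table):
        parts = []
        for stat, grp in table.groupby("statistic", sort=False):
            adj, flags = bh_adjust(grp["p_raw"].to_numpy(), cfg.fdr_q)
            grp = grp.assign(p_adj=adj, passes_fdr=flags)
            parts.append(grp)
        table = pd.concat(parts, ignore_index=True)
    else:
        table = table.assign(p_adj=[], passes_fdr=[])
    tree, order = cluster_categories(cats)
    return CategoryScanResult(
        namespace=namespace, table=table, categories=cats, tree=tree, leaf_order=order
    )


def export_scan(result: CategoryScanResult, tsv_path, newick_path) -> pd.DataFrame:
    """Write the scan as a heat-map-shaped TSV (rows in dendrogram leaf
    order, columns -log10 raw P per statistic plus adjusted P and pass
    flags) and the category dendrogram as newick."""
    wide = result.table.pivot(index="term", columns="statistic", values="p_raw")
    adj = result.table.pivot(index="term", columns="statistic", values="p_adj")
    flags = result.table.pivot(index="term", columns="statistic", values="passes_fdr")
    nm = result.table.drop_duplicates("term").set_index("term")["n_members"]
    rows = []
    for term in result.leaf_order:
        row = {"term": term, "n_members": int(nm.get(term, 0))}
        for stat in STATISTICS:
            if stat in wide.columns and not np.isnan(wide.at[term, stat]):
                row[f"neglog10_p_{stat}"] = -np.log10(max(float(wide.at[term, stat]), 1e-300))
                row[f"p_adj_{stat}"] = float(adj.at[term, stat])
                row[f"passes_fdr_{stat}"] = bool(flags.at[term, stat])
        rows.append(row)
    df = pd.DataFrame(rows)
    from .io_core import write_tsv

    write_tsv(tsv_path, df, comment=f"GO scan, namespace {result.namespace}")
    with open(newick_path, "w") as fh:
        result.tree.write(fh)
    return df
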