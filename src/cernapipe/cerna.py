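"""Competing-endogenous-RNA triplet construction and network export.

A triplet (lncRNA, miRNA, mRNA) is emitted when the lncRNA and the mRNA
are both predicted targets of the same differentially expressed miRNA and
their expression profiles are co-expressed with Pearson r > 0.9 at
p < 0.05 (two-sided t transform). The positive-only correlation gate is
deliberate: competition predicts positive lncRNA-mRNA co-expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PCC = 0.9
DEFAULT_P = 0.05


@dataclass(frozen=True)
class CeRNATriplet:
    lncrna: str
    mirna: str
    mrna: str
    pcc: float
    pcc_p: float


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t transform.

    t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom; r = +/-1
    gives p = 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    return float(r), float(p)


def build_triplets(
    de_mirnas,
    de_lncrnas,
    de_mrnas,
    site_table: pd.DataFrame,
    expression: pd.DataFrame,
    *,
    pcc_threshold: float = DEFAULT_PCC,
    p_threshold: float = DEFAULT_P,
) -> list[CeRNATriplet]:
    """Assemble co-expression competing triplets.

    For each DE miRNA m, every pair (l, g) of its predicted DE lncRNA and
    DE mRNA targets is tested for co-expression; pairs with PCC >
    ``pcc_threshold`` and p < ``p_threshold`` become triplets (l, m, g).
    ``site_table`` needs columns ``mirna`` and ``target``; ``expression``
    is features x samples and must cover every DE lncRNA and mRNA. Output
    is deduplicated and sorted by ids.
    """
    de_mirnas = set(de_mirnas)
    de_lncrnas = set(de_lncrnas)
    de_mrnas = set(de_mrnas)
    if site_table.empty or not de_mirnas:
        return []
    pair_cache: dict[tuple[str, str], tuple[float, float]] = {}
    out: set[CeRNATriplet] = set()
    grouped = site_table.groupby("mirna")["target"]
    for m in sorted(de_mirnas):
        if m not in grouped.groups:
            continue
        targets = set(grouped.get_group(m))
        lncs = sorted(targets & de_lncrnas)
        genes = sorted(targets & de_mrnas)
        for l in lncs:
            for g in genes:
                key = (l, g)
                if key not in pair_cache:
                    xl = expression.loc[l].to_numpy(dtype=float)
                    xg = expression.loc[g].to_numpy(dtype=float)
                    if xl.std() == 0 or xg.std() == 0:
                        pair_cache[key] = (np.nan, 1.0)
                    else:
                        pair_cache[key] = pearson_with_p(xl, xg)
                r, p = pair_cache[key]
                if np.isfinite(r) and r > pcc_threshold and p < p_threshold:
                    out.add(CeRNATriplet(l, m, g, r, p))
    return sorted(out, key=lambda t: (t.lncrna, t.mirna, t.mrna))


def to_networkx(
    triplets: list[CeRNATriplet],
    node_attrs: dict[str, dict] | None = None,
) -> nx.Graph:
    """Undirected graph with lncRNA-miRNA and miRNA-mRNA edges.

    Multiple sites of the same miRNA on one target collapse to one edge.
    """
    g = nx.Graph()
    for t in triplets:
        g.add_node(t.lncrna, node_type="lncRNA")
        g.add_node(t.mirna, node_type="miRNA")
        g.add_node(t.mrna, node_type="mRNA")
        g.add_edge(t.mirna, t.lncrna, interaction="mirna-lncrna")
        g.add_edge(t.mirna, t.mrna, interaction="mirna-mrna")
    if node_attrs:
        for node, attrs in node_attrs.items():
            if node in g:
                g.nodes[node].update(attrs)
    return g


def export_network(
    triplets: list[CeRNATriplet],
    outdir: str | Path,
    *,
    de_direction: dict[str, str] | None = None,
    prefix: str = "cerna",
) -> nx.Graph:
    """Write GraphML, SIF and node-attribute TSV for the triplet network."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    attrs = (
        {n: {"de_direction": d} for n, d in de_direction.items()}
        if de_direction
        else None
    )
    g = to_networkx(triplets, attrs)
    nx.write_graphml(g, outdir / f"{prefix}.graphml")
    with open(outdir / f"{prefix}.sif", "w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{data['interaction']}\t{v}\n")
    with open(outdir / f"{prefix}_nodes.tsv", "w") as fh:
        fh.write("node\tnode_type\tde_direction\n")
        for n in sorted(g.nodes):
            nd = g.nodes[n]
            fh.write(f"{n}\t{nd.get('node_type', '')}\t{nd.get('de_direction', '')}\n")
    with open(outdir / f"{prefix}_triplets.tsv", "w") as fh:
        fh.write("lncrna\tmirna\tmrna\tpcc\tpcc_p\n")
        for t in triplets:
            fh.write(f"{t.lncrna}\t{t.mirna}\t{t.mrna}\t{t.pcc:.6g}\t{t.pcc_p:.6g}\n")
    return g


def subnetwork_by_genes(
    triplets: list[CeRNATriplet], gene_ids
) -> tuple[list[CeRNATriplet], tuple[int, int, int]]:
    """Triplets whose mRNA is in ``gene_ids``, with node counts.

    Returns the subset plus (#miRNA, #mRNA, #lncRNA) node counts.
    """
    gene_ids = set(gene_ids)
    if not gene_ids:
        raise ValueError("gene list must be non-empty")
    sub = [t for t in triplets if t.mrna in gene_ids]
    counts = (
        len({t.mirna for t in sub}),
        len({t.mrna for t in sub}),
        len({t.lncrna for t in sub}),
    )
    return sub, counts
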