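"""SNP -> nearest gene -> pathway/grouping association networks.

Significant SNPs are annotated with the nearest gene on their chromosome
(signed distance, 0 when the position falls inside the closed gene span;
ties broken lexicographically by symbol).  Genes are linked through shared
pathway or grouping membership (GMT files from GO / KEGG / pathway
resources, all consumed through one parser), and per-stratum typed graphs
are built over SNP, gene, grouping and phenotype-class nodes.  Pruning
keeps only connected components in which two or more PheWAS-significant
SNPs have their genes linked through at least one shared grouping node —
single-SNP stars are dropped.

Coordinates are 1-based with closed gene intervals; strand is ignored for
distance, and context strings (intron, intergenic, nearGene-3, ...) are
consumed from the annotation input, not recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

NODE_SNP = "snp"
NODE_GENE = "gene"
NODE_GROUPING = "grouping"
NODE_CLASS = "phenotype_class"


@dataclass(frozen=True)
class GeneAnnotation:
    snp: str
    chrom: str
    position: int
    gene: str
    distance: int  # signed; 0 when inside the gene span
    context: str = ""


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """BED-like TSV with columns chrom, start, end, symbol (1-based, closed)."""
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str, "symbol": str})
    required = {"chrom", "start", "end", "symbol"}
    if not required <= set(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    return genes


def read_gmt(path: str | Path, source: str = "") -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> gene...

    Returns grouping name -> member gene set; the source label, when given,
    prefixes the grouping name so provenance is recorded per grouping.
    """
    groupings: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            log.warning("GMT line with fewer than 3 fields skipped: %r", line[:60])
            continue
        name = f"{source}:{parts[0]}" if source else parts[0]
        groupings[name] = {g for g in parts[2:] if g}
    return groupings


def annotate_nearest_gene(
    snps: pd.DataFrame, genes: pd.DataFrame, contexts: Mapping[str, str] | None = None
) -> list[GeneAnnotation]:
    """Nearest gene per SNP: minimal absolute distance on the same chromosome.

    ``snps`` columns: snp, chrom, position.  Distance is 0 inside the closed
    [start, end] span, signed otherwise (negative upstream of start); ties
    on |distance| break lexicographically by gene symbol.  SNPs on a
    chromosome with no genes are left unannotated and logged.
    """
    contexts = contexts or {}
    out: list[GeneAnnotation] = []
    by_chrom = {str(c): sub.sort_values(["start", "end", "symbol"]) for c, sub in genes.groupby("chrom")}
    for rec in snps.itertuples(index=False):
        chrom = str(rec.chrom)
        sub = by_chrom.get(chrom)
        if sub is None or sub.empty:
            log.warning("%s: no genes on chromosome %s; unannotated", rec.snp, chrom)
            continue
        pos = int(rec.position)
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        inside = (start <= pos) & (pos <= end)
        # distance to the nearer span boundary, signed: negative before start
        dist = np.where(inside, 0, np.where(pos < start, pos - start, pos - end))
        absdist = np.abs(dist)
        order = np.lexsort((sub["symbol"].to_numpy(), absdist))
        best = order[0]
        out.append(
            GeneAnnotation(
                snp=str(rec.snp),
                chrom=chrom,
                position=pos,
                gene=str(sub["symbol"].iloc[best]),
                distance=int(dist[best]),
                context=contexts.get(str(rec.snp), ""),
            )
        )
    return out


def build_graph(
    results: pd.DataFrame,
    annotations: Sequence[GeneAnnotation],
    groupings: Mapping[str, set[str]],
    stratum: str = "",
) -> nx.Graph:
    """Typed association network for one stratum.

    ``results`` needs columns snp, class_label, direction (already filtered
    to one stratum by the caller when stratified graphs are wanted).  Edges:
    snp-class (association), snp-gene (annotation), gene-grouping
    (membership).  Grouping nodes are added only when at least one member
    gene is present, so no grouping node is orphaned.
    """
    g = nx.Graph(stratum=stratum)
    ann_by_snp = {a.snp: a for a in annotations}
    for rec in results.itertuples(index=False):
        snp = str(rec.snp)
        g.add_node(snp, node_type=NODE_SNP)
        cls = f"class:{rec.class_label}"
        g.add_node(cls, node_type=NODE_CLASS, label=str(rec.class_label))
        g.add_edge(snp, cls, edge_type="association", direction=getattr(rec, "direction", ""))
        ann = ann_by_snp.get(snp)
        if ann is None:
            log.warning("%s has no gene annotation; SNP node kept without gene edge", snp)
            continue
        g.add_node(ann.gene, node_type=NODE_GENE)
        g.add_edge(snp, ann.gene, edge_type="annotation", distance=ann.distance, context=ann.context)
    gene_nodes = {n for n, d in g.nodes(data=True) if d["node_type"] == NODE_GENE}
    for name, members in sorted(groupings.items()):
        present = sorted(members & gene_nodes)
        if not present:
            continue
        g.add_node(name, node_type=NODE_GROUPING)
        for gene in present:
            g.add_edge(gene, name, edge_type="membership")
    return g


def prune_components(graph: nx.Graph) -> nx.Graph:
    """Keep components where >=2 SNPs' genes are linked via a shared grouping.

    A component survives only if, considering gene and grouping nodes alone,
    the nearest genes of at least two distinct significant SNPs fall in one
    connected cluster that contains at least one grouping node.  Everything
    else (single-SNP stars, SNPs linked only through a shared phenotype
    class, gene pairs with no shared grouping) is dropped.  Idempotent.
    """
    keep_nodes: set = set()
    gene_grouping = graph.subgraph(
        [n for n, d in graph.nodes(data=True) if d["node_type"] in (NODE_GENE, NODE_GROUPING)]
    )
    for cluster in nx.connected_components(gene_grouping):
        has_grouping = any(graph.nodes[n]["node_type"] == NODE_GROUPING for n in cluster)
        if not has_grouping:
            continue
        snps = {
            nbr
            for n in cluster
            if graph.nodes[n]["node_type"] == NODE_GENE
            for nbr in graph.neighbors(n)
            if graph.nodes[nbr]["node_type"] == NODE_SNP
        }
        if len(snps) >= 2:
            keep_nodes |= set(cluster) | snps
            # carry the SNPs' phenotype-class nodes along for context
            for snp in snps:
                keep_nodes |= {
                    nbr for nbr in graph.neighbors(snp)
                    if graph.nodes[nbr]["node_type"] == NODE_CLASS
                }
    return graph.subgraph(keep_nodes).copy()


def write_sif(graph: nx.Graph, path: str | Path) -> None:
    lines = [
        f"{a}\t{d.get('edge_type', 'link')}\t{b}"
        for a, b, d in sorted(graph.edges(data=True))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def nearest_gene_frame(annotations: Iterable[GeneAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp": a.snp,
                "chrom": a.chrom,
                "position": a.position,
                "gene": a.gene,
                "distance": a.distance,
                "context": a.context,
            }
            for a in annotations
        ],
        columns=["snp", "chrom", "position", "gene", "distance", "context"],
    )
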