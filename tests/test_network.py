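"""Nearest-gene annotation and SNP-gene-pathway network pruning."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from survey_phewas.network import (
    NODE_GENE,
    NODE_GROUPING,
    NODE_SNP,
    annotate_nearest_gene,
    build_graph,
    prune_components,
    read_gmt,
    write_sif,
)
from conftest import random_gene_table


def _snps(rows):
    return pd.DataFrame(rows, columns=["snp", "chrom", "position"])


def _genes(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "symbol"])


class TestNearestGene:
    def test_inside_span_distance_zero(self):
        genes = _genes([("1", 100, 200, "GENE1")])
        out = annotate_nearest_gene(_snps([("rs1", "1", 150)]), genes)
        assert out[0].gene == "GENE1" and out[0].distance == 0

    def test_boundaries_inclusive(self):
        genes = _genes([("1", 100, 200, "GENE1")])
        for pos in (100, 200):
            out = annotate_nearest_gene(_snps([("rs1", "1", pos)]), genes)
            assert out[0].distance == 0

    def test_intergenic_signed_distance(self):
        genes = _genes([("1", 100, 200, "A"), ("1", 1000, 1100, "B")])
        out = annotate_nearest_gene(_snps([("rs1", "1", 230)]), genes)
        assert out[0].gene == "A" and out[0].distance == 30
        out = annotate_nearest_gene(_snps([("rs1", "1", 950)]), genes)
        assert out[0].gene == "B" and out[0].distance == -50

    def test_tie_broken_lexicographically(self):
        genes = _genes([("1", 100, 200, "ZZZ"), ("1", 300, 400, "AAA")])
        out = annotate_nearest_gene(_snps([("rs1", "1", 250)]), genes)
        assert out[0].gene == "AAA"

    def test_no_genes_on_chromosome_left_unannotated(self):
        genes = _genes([("2", 100, 200, "A")])
        assert annotate_nearest_gene(_snps([("rs1", "1", 150)]), genes) == []

    def test_matches_exhaustive_oracle_on_random_configurations(self, rng):
        """Brute-force scan over every gene agrees with the implementation."""
        for _ in range(300):
            genes = random_gene_table(rng)
            chrom = str(rng.integers(1, 4))
            pos = int(rng.integers(1, 1_100_000))
            out = annotate_nearest_gene(_snps([("rs1", chrom, pos)]), genes)
            best = None
            for g in genes.itertuples(index=False):
                if str(g.chrom) != chrom:
                    continue
                if g.start <= pos <= g.end:
                    d = 0
                elif pos < g.start:
                    d = pos - g.start
                else:
                    d = pos - g.end
                key = (abs(d), g.symbol)
                if best is None or key < best[0]:
                    best = (key, g.symbol, d)
            if best is None:
                assert out == []
            else:
                assert out[0].gene == best[1]
                assert out[0].distance == best[2]


def _results(rows):
    return pd.DataFrame(rows, columns=["snp", "class_label", "stratum", "direction"])


def _graph(results, gene_for, groupings):
    genes = _genes(
        [("1", 100 + 1000 * i, 200 + 1000 * i, g) for i, g in enumerate(sorted(set(gene_for.values())))]
    )
    snps = _snps([(s, "1", 150 + 1000 * sorted(set(gene_for.values())).index(g)) for s, g in gene_for.items()])
    annotations = annotate_nearest_gene(snps, genes)
    return build_graph(results, annotations, groupings)


class TestGraphAndPruning:
    def test_shared_pathway_connects_two_snps(self):
        """Two lipid-gene SNPs joined through one shared signalling pathway."""
        results = _results([
            ("rs328", "HDL Cholesterol", "MA", "+"),
            ("rs174547", "Ferritin", "MA", "+"),
        ])
        g = _graph(results, {"rs328": "LPL", "rs174547": "FADS1"},
                   {"TGF-beta receptor": {"LPL", "FADS1"}})
        pruned = prune_components(g)
        assert nx.has_path(pruned, "rs328", "rs174547")
        snps = [n for n, d in pruned.nodes(data=True) if d["node_type"] == NODE_SNP]
        assert sorted(snps) == ["rs174547", "rs328"]

    def test_two_genes_one_process_three_snps_one_component(self):
        """Urate-transporter pattern: three SNPs, two genes, one GO process."""
        results = _results([
            ("rs2231142", "Kidney (Uric Acid)", "MA", "-"),
            ("rs7442295", "Kidney (Uric Acid)", "MA", "-"),
            ("rs6855911", "Kidney (Uric Acid)", "MA", "-"),
        ])
        g = _graph(
            results,
            {"rs2231142": "ABCG2", "rs7442295": "SLC2A9", "rs6855911": "SLC2A9"},
            {"urate metabolic process": {"ABCG2", "SLC2A9"}},
        )
        pruned = prune_components(g)
        comps = list(nx.connected_components(pruned))
        assert len(comps) == 1
        snps = {n for n, d in pruned.nodes(data=True) if d["node_type"] == NODE_SNP}
        assert snps == {"rs2231142", "rs7442295", "rs6855911"}

    def test_chained_pathways_form_single_component(self):
        """Chained sharing: A-B share one pathway, B-C another; all three SNPs
        stay in one retained component."""
        results = _results([
            ("rs1800588", "Folate", "MA", "-"),
            ("rs328", "HDL Cholesterol", "MA", "+"),
            ("rs3135506", "Triglycerides", "MA", "+"),
        ])
        g = _graph(
            results,
            {"rs1800588": "LIPC", "rs328": "LPL", "rs3135506": "APOA5"},
            {
                "glycerolipid metabolism": {"LIPC", "LPL"},
                "PPAR signaling": {"LPL", "APOA5"},
            },
        )
        pruned = prune_components(g)
        comps = list(nx.connected_components(pruned))
        assert len(comps) == 1
        snps = {n for n, d in pruned.nodes(data=True) if d["node_type"] == NODE_SNP}
        assert snps == {"rs1800588", "rs328", "rs3135506"}

    def test_single_snp_component_dropped(self):
        results = _results([("rs1", "A", "NHW", "+")])
        g = _graph(results, {"rs1": "G1"}, {"pathway": {"G1"}})
        assert len(prune_components(g)) == 0

    def test_two_snps_without_shared_grouping_dropped(self):
        results = _results([("rs1", "A", "NHW", "+"), ("rs2", "B", "NHW", "+")])
        g = _graph(results, {"rs1": "G1", "rs2": "G2"},
                   {"p1": {"G1"}, "p2": {"G2"}})
        assert len(prune_components(g)) == 0

    def test_shared_class_alone_does_not_rescue_component(self):
        """Two SNPs associated with the same phenotype class but whose genes
        share no grouping must still be dropped."""
        results = _results([("rs1", "Same Class", "NHW", "+"), ("rs2", "Same Class", "NHW", "+")])
        g = _graph(results, {"rs1": "G1", "rs2": "G2"}, {})
        assert len(prune_components(g)) == 0

    def test_pruning_idempotent(self):
        results = _results([
            ("rs328", "HDL Cholesterol", "MA", "+"),
            ("rs174547", "Ferritin", "MA", "+"),
        ])
        g = _graph(results, {"rs328": "LPL", "rs174547": "FADS1"},
                   {"TGF": {"LPL", "FADS1"}})
        once = prune_components(g)
        twice = prune_components(once)
        assert set(once.nodes) == set(twice.nodes)
        assert set(once.edges) == set(twice.edges)

    def test_no_orphan_grouping_nodes(self):
        results = _results([("rs1", "A", "NHW", "+")])
        g = _graph(results, {"rs1": "G1"}, {"empty": {"OTHER"}, "member": {"G1"}})
        groupings = [n for n, d in g.nodes(data=True) if d["node_type"] == NODE_GROUPING]
        assert groupings == ["member"]
        assert all(g.degree(n) > 0 for n in groupings)


class TestIO:
    def test_gmt_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SET1\tdesc\tA\tB\nSET2\tdesc\tB\tC\tD\n")
        sets = read_gmt(path, source="go")
        assert sets == {"go:SET1": {"A", "B"}, "go:SET2": {"B", "C", "D"}}

    def test_sif_export_lists_typed_edges(self, tmp_path):
        results = _results([("rs1", "A", "NHW", "+"), ("rs2", "B", "NHW", "-")])
        g = _graph(results, {"rs1": "G1", "rs2": "G2"}, {"p": {"G1", "G2"}})
        pruned = prune_components(g)
        out = tmp_path / "net.sif"
        write_sif(pruned, out)
        lines = out.read_text().splitlines()
        assert any("membership" in l for l in lines)
        assert any("annotation" in l for l in lines)
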