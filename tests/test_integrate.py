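from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirnomics import diffexpr, integrate, synthdata
from mirnomics.diffexpr import DEResult
from mirnomics.integrate import (
    build_triomics_network,
    call_genomic_clusters,
    chromosome_enrichment,
    consensus_targets,
    locus_summary,
    methylation_mirna_overlap,
)
from mirnomics.iokit import MirGeneAnnotation


def ann(gene, chrom, tss, strand="+"):
    return MirGeneAnnotation(gene, chrom, tss, tss + 80, strand) if strand == "+" \
        else MirGeneAnnotation(gene, chrom, tss - 80, tss, strand)


def de(fid, log2fc=1.0, p_raw=0.01, p_adj=0.01, mean_a=0.5, mean_b=0.5):
    direction = "up" if log2fc > 0 else ("down" if log2fc < 0 else "none")
    return DEResult(fid, mean_a, mean_b, log2fc, p_raw, p_adj, direction)


class TestGenomicClusters:
    def test_chaining_arithmetic(self):
        anns = [ann("g1", "chr1", 0), ann("g2", "chr1", 5000), ann("g3", "chr1", 30000)]
        dirs = {"g1": "up", "g2": "up", "g3": "up"}
        clusters = call_genomic_clusters(anns, dirs, max_gap=10_000)
        assert len(clusters) == 1
        assert clusters[0].members == ["g1", "g2"]
        assert clusters[0].span_bp == 5000

    def test_zero_gap_no_clusters(self):
        anns = [ann("g1", "chr1", 0), ann("g2", "chr1", 5000)]
        clusters = call_genomic_clusters(anns, {"g1": "up", "g2": "up"}, max_gap=0)
        assert clusters == []

    def test_planted_cluster_full_consensus(self, small_cohort):
        planted = set(small_cohort.truth["cluster_members"])
        dirs = {g: small_cohort.truth["de_mirna"][m]["direction"]
                for g, m in zip(small_cohort.truth["cluster_members"],
                                small_cohort.truth["cluster_member_matures"])}
        clusters = call_genomic_clusters(small_cohort.annotation, dirs, max_gap=10_000)
        assert len(clusters) == 1
        assert set(clusters[0].members) == planted
        assert clusters[0].direction_consensus == 1.0

    def test_translation_invariance(self):
        anns_a = [ann("g1", "chr1", 100), ann("g2", "chr1", 4100), ann("g3", "chr1", 40_000)]
        anns_b = [ann("g1", "chr1", 100 + 7777), ann("g2", "chr1", 4100 + 7777),
                  ann("g3", "chr1", 40_000 + 7777)]
        dirs = {"g1": "up", "g2": "down", "g3": "up"}
        ca = call_genomic_clusters(anns_a, dirs)
        cb = call_genomic_clusters(anns_b, dirs)
        assert [(c.members, c.span_bp, c.direction_consensus) for c in ca] == \
               [(c.members, c.span_bp, c.direction_consensus) for c in cb]

    def test_clusters_plus_singletons_cover_de_set(self):
        anns = [ann(f"g{i}", "chr1", i * 4000) for i in range(6)] + \
               [ann("far", "chr2", 10)]
        dirs = {a.gene_id: "up" for a in anns}
        clusters = call_genomic_clusters(anns, dirs, max_gap=5000)
        clustered = {m for c in clusters for m in c.members}
        assert clustered <= set(dirs)
        assert clustered == {f"g{i}" for i in range(6)}  # far gene is a singleton


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration over tables with the
    observed margins, in exact rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = pmf(x)
        if px <= p_obs + Fraction(1, 10**12):
            total += px
    return float(min(total, Fraction(1)))


class TestChromosomeEnrichment:
    def _anns(self, n_per_chrom):
        out = []
        i = 0
        for chrom, k in n_per_chrom.items():
            for _ in range(k):
                out.append(ann(f"g{i}", chrom, 1000 + i * 50_000))
                i += 1
        return out

    def test_no_de_gives_p_one(self):
        anns = self._anns({"chr1": 5, "chr2": 5})
        table = chromosome_enrichment(anns, set(), {a.gene_id for a in anns})
        assert (table["p"] == 1.0).all()

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 16, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
            assert p_scipy == pytest.approx(fisher_enumeration(a, b, c, d), rel=1e-7)

    def test_specific_table_oracle(self):
        _, p = stats.fisher_exact([[5, 10], [5, 80]])
        assert p == pytest.approx(fisher_enumeration(5, 10, 5, 80), rel=1e-9)

    def test_concentrated_de_significant(self):
        anns = self._anns({"chr1": 6, "chr2": 30})
        de_set = {a.gene_id for a in anns if a.chrom == "chr1"}
        table = chromosome_enrichment(anns, de_set, {a.gene_id for a in anns})
        assert table.loc["chr1", "p"] < 0.05

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            chromosome_enrichment([], set(), set())

    def test_de_not_subset_rejected(self):
        anns = self._anns({"chr1": 2})
        with pytest.raises(ValueError, match="subset"):
            chromosome_enrichment(anns, {"zzz"}, {a.gene_id for a in anns})


class TestConsensusTargets:
    def test_three_tools_validated_kept(self):
        ev = synthdata.toy_target_evidence()
        kept = consensus_targets(ev)
        assert {(t.mirna_id, t.mrna_id) for t in kept} == {
            ("toy-miR-1", "geneA"), ("toy-miR-2", "geneD"),
            ("toy-miR-3", "geneF"), ("toy-miR-5", "geneI"),
        }

    def test_five_tools_unvalidated_dropped(self):
        ev = pd.DataFrame([("m", "g", 1, 1, 1, 1, 1, 0)],
                          columns=["mirna", "mrna", "tool1", "tool2", "tool3",
                                   "tool4", "tool5", "validated"])
        assert consensus_targets(ev) == []

    def test_two_tools_validated_dropped(self):
        ev = pd.DataFrame([("m", "g", 1, 1, 0, 0, 0, 1)],
                          columns=["mirna", "mrna", "tool1", "tool2", "tool3",
                                   "tool4", "tool5", "validated"])
        assert consensus_targets(ev) == []

    def test_monotone_in_thresholds(self):
        ev = synthdata.toy_target_evidence()
        strict = {(t.mirna_id, t.mrna_id) for t in consensus_targets(ev, min_tools=3)}
        loose_tools = {(t.mirna_id, t.mrna_id) for t in consensus_targets(ev, min_tools=2)}
        no_valid = {(t.mirna_id, t.mrna_id)
                    for t in consensus_targets(ev, require_validated=False)}
        assert strict <= loose_tools
        assert strict <= no_valid

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            consensus_targets(pd.DataFrame({"mirna": ["m"], "mrna": ["g"]}))


class TestTriomicsNetwork:
    def _pairs(self):
        ev = pd.DataFrame([
            ("miR-up", "gene1", 1, 1, 1, 0, 0, 1),
            ("miR-up", "gene2", 1, 1, 1, 1, 0, 1),
        ], columns=["mirna", "mrna", "tool1", "tool2", "tool3", "tool4", "tool5",
                    "validated"])
        return consensus_targets(ev)

    def test_protein_layer_edge_opposite(self):
        edges, graph = build_triomics_network(
            self._pairs(),
            {"miR-up": de("miR-up", log2fc=1.0)},
            {"gene1": de("gene1", log2fc=-1.0, p_adj=0.001),
             "gene2": de("gene2", log2fc=-1.0, p_adj=0.5)},
            {"P_gene1": de("P_gene1", log2fc=-0.6, p_raw=0.01)},
            mrna_to_protein={"gene1": "P_gene1", "gene2": "P_gene2"},
        )
        layers = {(e.target_id, e.layer) for e in edges}
        assert ("gene1", "mRNA") in layers
        assert ("P_gene1", "protein") in layers
        assert ("gene2", "mRNA") not in layers  # fails mRNA adjusted p
        prot_edge = next(e for e in edges if e.layer == "protein")
        assert prot_edge.opposite
        assert graph.has_edge("miR-up", "P_gene1")

    def test_weak_protein_fold_change_no_edge(self):
        edges, _ = build_triomics_network(
            self._pairs(),
            {"miR-up": de("miR-up", log2fc=1.0)},
            {"gene1": de("gene1", log2fc=-1.0, p_adj=0.001)},
            {"P_gene1": de("P_gene1", log2fc=-0.4, p_raw=0.01)},
            mrna_to_protein={"gene1": "P_gene1"},
        )
        assert not any(e.layer == "protein" for e in edges)

    def test_non_significant_mirna_no_edges(self):
        edges, _ = build_triomics_network(
            self._pairs(),
            {"miR-up": de("miR-up", log2fc=1.0, p_raw=0.5)},
            {"gene1": de("gene1", log2fc=-1.0, p_adj=0.001)},
            {},
        )
        assert edges == []

    def test_toy_fixture_hand_count(self):
        # consensus pairs from the toy table: miR-1->A, miR-2->D, miR-3->F,
        # miR-5->I; give A and D significant mRNA DE, F borderline-fail,
        # I missing from the table -> exactly 2 mRNA edges by hand count
        pairs = consensus_targets(synthdata.toy_target_evidence())
        mirna_de = {t.mirna_id: de(t.mirna_id, log2fc=1.0) for t in pairs}
        mrna_de = {
            "geneA": de("geneA", log2fc=-1.0, p_adj=0.01),
            "geneD": de("geneD", log2fc=1.0, p_adj=0.04),
            "geneF": de("geneF", log2fc=-1.0, p_adj=0.2),
        }
        edges, _ = build_triomics_network(pairs, mirna_de, mrna_de, {})
        assert len(edges) == 2
        assert {(e.mirna_id, e.target_id) for e in edges} == {
            ("toy-miR-1", "geneA"), ("toy-miR-2", "geneD")}

    def test_edges_subset_of_consensus(self, rng):
        pairs = self._pairs()
        edges, _ = build_triomics_network(
            pairs, {"miR-up": de("miR-up")},
            {"gene1": de("gene1", log2fc=-1.0, p_adj=0.001),
             "gene2": de("gene2", log2fc=-1.0, p_adj=0.001)},
            {})
        pair_keys = {(p.mirna_id, p.mrna_id) for p in pairs}
        assert {(e.mirna_id, e.target_id) for e in edges if e.layer == "mRNA"} <= pair_keys


class TestMethylationOverlap:
    def _cpg_de(self, n_sig, n_total, gene="gX"):
        table = {}
        mapping = {}
        for i in range(n_total):
            cid = f"cg{i}"
            p = 0.001 if i < n_sig else 0.5
            table[cid] = de(cid, log2fc=0.05, p_raw=p, mean_a=0.5, mean_b=0.55)
            mapping[cid] = gene
        return table, mapping

    def test_locus_seven_of_eight(self):
        cpg_de, mapping = self._cpg_de(7, 8)
        overlap = methylation_mirna_overlap(cpg_de, mapping, {"gX"})
        summary = locus_summary(overlap, {"gX": "icr-locus"})
        row = summary[summary["locus"] == "icr-locus"].iloc[0]
        assert (row["n_cpg"], row["n_significant"]) == (8, 7)

    def test_alpha_zero_empty(self):
        cpg_de, mapping = self._cpg_de(7, 8)
        overlap = methylation_mirna_overlap(cpg_de, mapping, {"gX"}, alpha=0.0)
        assert not overlap["significant"].any()

    def test_gene_without_cpg_absent(self):
        cpg_de, mapping = self._cpg_de(1, 2)
        overlap = methylation_mirna_overlap(cpg_de, mapping, {"gX", "gNoCpg"})
        assert "gNoCpg" not in set(overlap["gene_id"])

    def test_percent_change_column(self):
        cpg_de, mapping = self._cpg_de(1, 1)
        overlap = methylation_mirna_overlap(cpg_de, mapping, {"gX"})
        assert overlap["abs_pct_change"].iloc[0] == pytest.approx(5.0)
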