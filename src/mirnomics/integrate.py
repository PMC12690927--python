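"""Genomic clustering, chromosome enrichment, consensus target mapping,
tri-omics directional networks and methylation overlap.

Direction convention throughout: "up"/"down" in the case group (DP)
relative to the control group (DR); log2 fold changes are case/control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult, benjamini_hochberg
from .iokit import MirGeneAnnotation

logger = logging.getLogger(__name__)


@dataclass
class GenomicCluster:
    cluster_id: str
    chrom: str
    members: list[str]
    span_bp: int
    direction_consensus: float


@dataclass
class TargetEvidence:
    mirna_id: str
    mrna_id: str
    tool_support: int
    validated: bool
    mrna_de: DEResult | None = None
    protein_de: DEResult | None = None


@dataclass
class TriOmicsEdge:
    mirna_id: str
    target_id: str
    layer: str  # "mRNA" | "protein"
    mirna_direction: str
    target_direction: str
    opposite: bool


def call_genomic_clusters(
    annotations: Sequence[MirGeneAnnotation],
    de_directions: Mapping[str, str],
    max_gap: int = 10_000,
) -> list[GenomicCluster]:
    """Single-linkage chaining of DE miRNA gene TSS positions per chromosome.

    Genes whose consecutive TSS gap is <= ``max_gap`` join a chain; chains
    of size >= 2 are reported with the fraction of members sharing the
    majority DE direction.
    """
    by_chrom: dict[str, list[MirGeneAnnotation]] = {}
    for ann in annotations:
        if ann.gene_id in de_directions:
            by_chrom.setdefault(ann.chrom, []).append(ann)
    clusters: list[GenomicCluster] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda a: (a.tss, a.gene_id))
        chain: list[MirGeneAnnotation] = [genes[0]]
        chains: list[list[MirGeneAnnotation]] = []
        for gene in genes[1:]:
            if gene.tss - chain[-1].tss <= max_gap:
                chain.append(gene)
            else:
                chains.append(chain)
                chain = [gene]
        chains.append(chain)
        for i, chain in enumerate(c for c in chains if len(c) >= 2):
            directions = [de_directions[g.gene_id] for g in chain]
            counts = pd.Series(directions).value_counts()
            clusters.append(GenomicCluster(
                cluster_id=f"{chrom}_c{i + 1}",
                chrom=chrom,
                members=[g.gene_id for g in chain],
                span_bp=chain[-1].tss - chain[0].tss,
                direction_consensus=float(counts.iloc[0] / len(chain)),
            ))
    return clusters


def chromosome_enrichment(
    annotations: Sequence[MirGeneAnnotation],
    de_set: set[str],
    background_set: set[str],
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-chromosome 2x2 Fisher's exact test of DE membership.

    Background is the detected (post-filter) miRNA universe; the DE set
    must be a subset of it. Returns odds ratio and two-sided p per
    chromosome (optionally BH-adjusted across chromosomes).
    """
    if not background_set:
        raise ValueError("background set is empty")
    if not de_set <= background_set:
        raise ValueError("de_set must be a subset of background_set")
    chrom_of = {a.gene_id: a.chrom for a in annotations}
    missing = background_set - set(chrom_of)
    if missing:
        raise KeyError(f"genes without annotation: {sorted(missing)[:3]}")
    rows = []
    n_de = len(de_set)
    n_bg = len(background_set)
    for chrom in sorted({chrom_of[g] for g in background_set}):
        on_chrom = {g for g in background_set if chrom_of[g] == chrom}
        a = len(de_set & on_chrom)
        b = n_de - a
        c = len(on_chrom) - a
        d = (n_bg - n_de) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"chrom": chrom, "de_on": a, "de_off": b,
                     "bg_on": c, "bg_off": d, "odds_ratio": odds, "p": p})
    table = pd.DataFrame(rows).set_index("chrom")
    if adjust:
        table["p_adj"] = benjamini_hochberg(table["p"].to_numpy())
    return table


def consensus_targets(
    evidence: pd.DataFrame,
    min_tools: int = 3,
    require_validated: bool = True,
    n_tools: int = 5,
) -> list[TargetEvidence]:
    """Keep miRNA-mRNA pairs with tool support >= min_tools and (by
    default) experimental validation.

    ``evidence`` columns: mirna, mrna, tool1..tool{n_tools} (0/1),
    validated (0/1). Rows whose support exceeds the configured tool count
    are rejected.
    """
    tool_cols = [f"tool{i}" for i in range(1, n_tools + 1)]
    missing = [c for c in ["mirna", "mrna", "validated", *tool_cols] if c not in evidence.columns]
    if missing:
        raise ValueError(f"evidence table missing columns: {missing}")
    kept: list[TargetEvidence] = []
    for _, row in evidence.iterrows():
        support = int(sum(int(row[c]) for c in tool_cols))
        if support > n_tools:
            raise ValueError(
                f"pair {row['mirna']}->{row['mrna']}: support {support} exceeds {n_tools} tools"
            )
        validated = bool(int(row["validated"]))
        if support >= min_tools and (validated or not require_validated):
            kept.append(TargetEvidence(
                mirna_id=str(row["mirna"]), mrna_id=str(row["mrna"]),
                tool_support=support, validated=validated,
            ))
    return kept


def build_triomics_network(
    pairs: Sequence[TargetEvidence],
    mirna_de: Mapping[str, DEResult],
    mrna_de: Mapping[str, DEResult],
    protein_de: Mapping[str, DEResult],
    mrna_to_protein: Mapping[str, str] | None = None,
    mirna_alpha: float = 0.05,
    mrna_alpha_adj: float = 0.05,
    protein_alpha: float = 0.05,
    protein_lfc: float = 0.5,
) -> tuple[list[TriOmicsEdge], nx.Graph]:
    """Directional miRNA -> target edges across the mRNA and protein layers.

    mRNA edge: miRNA nominally DE and target mRNA DE at adjusted p.
    Protein edge: additionally the mapped protein passes p < protein_alpha
    and |log2FC| > protein_lfc. Each edge carries an ``opposite`` flag
    (miRNA and target changing in opposite directions).
    """
    mrna_to_protein = mrna_to_protein or {}
    edges: list[TriOmicsEdge] = []
    graph = nx.Graph()
    for pair in pairs:
        mir = mirna_de.get(pair.mirna_id)
        if mir is None or mir.p_raw >= mirna_alpha:
            continue
        tgt = mrna_de.get(pair.mrna_id)
        if tgt is None:
            logger.info("target %s absent from mRNA DE table; edge skipped", pair.mrna_id)
            continue
        if tgt.p_adj < mrna_alpha_adj:
            edges.append(_edge(pair.mirna_id, pair.mrna_id, "mRNA", mir, tgt))
        prot_id = mrna_to_protein.get(pair.mrna_id, pair.mrna_id)
        prot = protein_de.get(prot_id)
        if (prot is not None and prot.p_raw < protein_alpha
                and abs(prot.log2fc) > protein_lfc):
            edges.append(_edge(pair.mirna_id, prot_id, "protein", mir, prot))
    for e in edges:
        graph.add_node(e.mirna_id, bipartite="mirna")
        graph.add_node(e.target_id, bipartite=e.layer)
        graph.add_edge(e.mirna_id, e.target_id, layer=e.layer, opposite=e.opposite)
    return edges, graph


def _edge(mirna_id: str, target_id: str, layer: str,
          mir: DEResult, tgt: DEResult) -> TriOmicsEdge:
    return TriOmicsEdge(
        mirna_id=mirna_id, target_id=target_id, layer=layer,
        mirna_direction=mir.direction, target_direction=tgt.direction,
        opposite=mir.direction != tgt.direction,
    )


def triomics_table(edges: Sequence[TriOmicsEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [e.mirna_id for e in edges],
            "target_id": [e.target_id for e in edges],
            "layer": [e.layer for e in edges],
            "mirna_direction": [e.mirna_direction for e in edges],
            "target_direction": [e.target_direction for e in edges],
            "opposite": [e.opposite for e in edges],
        }
    )


def methylation_mirna_overlap(
    cpg_de: Mapping[str, DEResult],
    cpg_to_gene: Mapping[str, str],
    de_mirna_genes: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per DE miRNA gene: annotated CpGs reaching p < alpha.

    Returns one row per (gene, CpG) with the beta difference, absolute
    percentage change and direction; genes without any annotated CpG are
    absent (callers can count them from the DE set). CpGs mapping to
    unknown genes are logged and skipped.
    """
    rows = []
    known = set()
    for cpg_id, gene in cpg_to_gene.items():
        if cpg_id not in cpg_de:
            continue
        known.add(gene)
        if gene not in de_mirna_genes:
            continue
        de = cpg_de[cpg_id]
        rows.append({
            "gene_id": gene,
            "cpg_id": cpg_id,
            "beta_case": de.mean_b,
            "beta_control": de.mean_a,
            "abs_pct_change": abs(de.mean_b - de.mean_a) * 100.0,
            "direction": de.direction,
            "p": de.p_raw,
            "significant": de.p_raw < alpha,
        })
    table = pd.DataFrame(rows, columns=[
        "gene_id", "cpg_id", "beta_case", "beta_control",
        "abs_pct_change", "direction", "p", "significant",
    ])
    return table.sort_values(["gene_id", "cpg_id"]).reset_index(drop=True)


def locus_summary(overlap: pd.DataFrame,
                  gene_to_locus: Mapping[str, str]) -> pd.DataFrame:
    """Counts of significant / total CpGs per locus label."""
    if overlap.empty:
        return pd.DataFrame(columns=["locus", "n_cpg", "n_significant"])
    df = overlap.copy()
    df["locus"] = [gene_to_locus.get(g, "unlabelled") for g in df["gene_id"]]
    dedup = df.drop_duplicates(subset=["locus", "cpg_id"])
    grouped = dedup.groupby("locus").agg(
        n_cpg=("cpg_id", "size"), n_significant=("significant", "sum")
    )
    return grouped.reset_index()
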