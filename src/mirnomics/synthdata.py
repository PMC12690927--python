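"""Synthetic cohort generator.

Produces a fully self-contained two-group cohort with the statistical
structure every downstream stage assumes: negative-binomial miRNA/mRNA
counts with planted fold changes, mature/hairpin linkage, a genomically
clustered miRNA block with a coordinated direction, latent-factor
co-expression modules with a designated max-loading hub, miRNA -> mRNA
repression propagated to a protein subset, group-shifted imprinted-locus
CpG beta values, promoters with planted motif occurrences, ortholog
sequences with controlled longest-match runs, and per-sample phenotypes.
Every planted effect is recorded in a truth ledger. All randomness flows
through one seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import iokit
from .iokit import ExpressionMatrix, MirGeneAnnotation, PWM

LN2_SQ = math.log(2.0) ** 2
_RNA_BASES = np.array(list("ACGU"))
_DNA_BYTES = b"ACGT"


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort. The seed fully determines every
    output byte."""

    n_per_group: int = 15
    n_mirna: int = 300
    hairpin_per_mature: int = 1
    n_mrna: int = 2000
    n_protein: int = 800
    nb_dispersion: float = 0.1
    de_fraction: float = 0.2
    planted_log2fc: float = 1.5
    n_modules: int = 3
    module_size: int = 40
    within_module_cor: float = 0.7
    cluster_size: int = 22
    cluster_span_bp: int = 10_000
    icr_beta_shift: float = 0.05
    target_log2fc: float = 1.0
    targets_per_mirna: int = 3
    conserved_fraction: float = 0.6
    motif_copies: int = 5
    library_size_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3 (downstream tests undefined below)")
        for name in ("n_mirna", "n_mrna", "n_protein", "hairpin_per_mature"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.hairpin_per_mature != 1:
            raise ValueError("exactly one hairpin per mature miRNA is supported")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for name in ("de_fraction", "conserved_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.within_module_cor < 1.0):
            raise ValueError("within_module_cor must lie in (0, 1)")
        if self.n_modules * self.module_size > self.n_mirna - self.cluster_size:
            raise ValueError("modules + genomic cluster need more miRNAs than n_mirna")
        if self.n_protein > self.n_mrna:
            raise ValueError("n_protein cannot exceed n_mrna")


@dataclass
class CohortBundle:
    config: SimConfig
    mirna_counts: ExpressionMatrix
    mrna_counts: ExpressionMatrix
    protein_abundance: ExpressionMatrix
    protein_table: pd.DataFrame  # index protein_id: log2fc, p
    methylation: ExpressionMatrix  # beta values, class "cpg"
    cpg_to_gene: dict[str, str]
    target_evidence: pd.DataFrame
    annotation: list[MirGeneAnnotation]
    mature_to_hairpin: dict[str, str]
    mouse_sequences: dict[str, str]
    human_sequences: dict[str, str]
    genome: dict[str, str]
    pfms: list[PWM]
    phenotypes: pd.DataFrame
    diameters: pd.DataFrame  # long: sample_id, diameter
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _log_noise_var(mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Approximate variance of log2 counts around the log2 mean."""
    return (1.0 / mean + dispersion) / LN2_SQ


def _random_dna(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 4, size=length)
    return np.frombuffer(_DNA_BYTES, dtype=np.uint8)[idx].tobytes().decode("ascii")


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(_RNA_BASES[rng.integers(0, 4, size=length)])


def _brute_longest_run(a: str, b: str) -> int:
    """Independent O(n^2 m) longest-common-substring check used to verify
    planted ortholog runs (deliberately not the pipeline implementation)."""
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            if a[i:j] in b:
                best = j - i
            else:
                break
    return best


def _mutate_to_max_run(rng: np.random.Generator, seq: str, run: int) -> str:
    """Substitute bases so the same-index preserved run length equals
    ``run`` (break points every run + 1 positions)."""
    bases = "ACGU"
    out = list(seq)
    pos = run
    while pos < len(out):
        cur = out[pos]
        choices = [b for b in bases if b != cur]
        out[pos] = choices[int(rng.integers(0, 3))]
        pos += run + 1
    return "".join(out)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> CohortBundle:
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    samples = [f"DP_{i + 1:02d}" for i in range(n)] + [f"DR_{i + 1:02d}" for i in range(n)]
    group = np.array(["DP"] * n + ["DR"] * n)
    group_sign = np.where(group == "DP", 1.0, -1.0)
    sample_meta = pd.DataFrame({"group": group, "sex": "F"}, index=pd.Index(samples, name="sample_id"))

    truth: dict = {"seed": config.seed}

    # ---- gene identities and genomic layout -------------------------------
    gene_ids = [f"syn-mir-{i + 1:04d}" for i in range(config.n_mirna)]
    mature_ids = [f"syn-miR-{i + 1:04d}" for i in range(config.n_mirna)]
    hairpin_ids = [f"{g}-hp" for g in gene_ids]
    mature_to_hairpin = dict(zip(mature_ids, hairpin_ids))
    mature_of_gene = dict(zip(gene_ids, mature_ids))

    cluster_idx = list(range(config.cluster_size))
    cluster_genes = [gene_ids[i] for i in cluster_idx]
    spacing = 3 * config.cluster_span_bp
    chroms = [f"chr{c}" for c in range(1, 20)]
    annotation: list[MirGeneAnnotation] = []
    per_chrom_count: dict[str, int] = {c: 0 for c in chroms}
    cluster_chrom = "chr12"
    if config.cluster_size:
        step = max(1, config.cluster_span_bp // max(1, config.cluster_size - 1))
        base = spacing
        for j, i in enumerate(cluster_idx):
            tss = base + j * step
            strand = "+" if rng.integers(0, 2) else "-"
            annotation.append(_make_gene(gene_ids[i], cluster_chrom, tss, strand,
                                         mature_ids[i], hairpin_ids[i], "icr-locus"))
    other_chroms = [c for c in chroms if c != cluster_chrom]
    for i in range(config.cluster_size, config.n_mirna):
        chrom = other_chroms[i % len(other_chroms)]
        per_chrom_count[chrom] += 1
        tss = per_chrom_count[chrom] * spacing
        strand = "+" if rng.integers(0, 2) else "-"
        annotation.append(_make_gene(gene_ids[i], chrom, tss, strand,
                                     mature_ids[i], hairpin_ids[i], None))

    # ---- planted differential expression ----------------------------------
    de_sign = np.zeros(config.n_mirna)
    if config.de_fraction > 0:
        n_de = max(int(round(config.de_fraction * config.n_mirna)), config.cluster_size)
        de_sign[cluster_idx] = 1.0  # coordinated up-direction at the clustered locus
        extra = n_de - config.cluster_size
        if extra > 0:
            pool = np.arange(config.cluster_size, config.n_mirna)
            chosen = rng.choice(pool, size=extra, replace=False)
            de_sign[chosen] = rng.choice([-1.0, 1.0], size=extra)
    de_idx = np.nonzero(de_sign)[0]
    truth["de_mirna"] = {
        mature_ids[i]: {"direction": "up" if de_sign[i] > 0 else "down",
                        "log2fc": config.planted_log2fc * de_sign[i]}
        for i in de_idx
    }
    truth["cluster_members"] = cluster_genes
    truth["cluster_member_matures"] = [mature_ids[i] for i in cluster_idx]
    truth["cluster_chrom"] = cluster_chrom

    # ---- co-expression modules --------------------------------------------
    module_label = np.zeros(config.n_mirna, dtype=int)
    member_cor = np.zeros(config.n_mirna)
    hub_of_module: dict[int, str] = {}
    non_cluster = np.arange(config.cluster_size, config.n_mirna)
    module_pool = rng.permutation(non_cluster)
    pos = 0
    for m in range(1, config.n_modules + 1):
        members = module_pool[pos: pos + config.module_size]
        pos += config.module_size
        module_label[members] = m
        cors = np.clip(
            config.within_module_cor + rng.uniform(-0.07, 0.05, size=members.size),
            0.05, 0.95,
        )
        member_cor[members] = cors
        hub = members[0]
        member_cor[hub] = min(0.97, config.within_module_cor + 0.27)
        hub_of_module[m] = mature_ids[hub]
    truth["modules"] = {mature_ids[i]: int(module_label[i])
                        for i in range(config.n_mirna) if module_label[i]}
    truth["module_hubs"] = hub_of_module

    # ---- miRNA counts ------------------------------------------------------
    base_log2 = rng.uniform(5.0, 10.0, size=config.n_mirna)
    factors = rng.standard_normal((config.n_modules + 1, 2 * n))  # row 0 unused
    mu_base = 2.0 ** base_log2
    noise_var = _log_noise_var(mu_base, config.nb_dispersion)
    loading = np.sqrt(member_cor * noise_var / np.maximum(1e-12, 1.0 - member_cor))
    log2_mean = (
        base_log2[:, None]
        + 0.5 * config.planted_log2fc * de_sign[:, None] * group_sign[None, :]
        + loading[:, None] * factors[module_label, :]
    )
    lib_sigma = math.sqrt(math.log(1.0 + config.library_size_cv ** 2))
    lib = np.exp(rng.normal(0.0, lib_sigma, size=2 * n))
    lib /= np.exp(np.mean(np.log(lib)))
    mature_mu = (2.0 ** log2_mean) * lib[None, :]
    mature_counts = _nb_draw(rng, mature_mu, config.nb_dispersion)
    hairpin_mu = 0.5 * mature_mu  # shared group + module effects, scaled down
    hairpin_counts = _nb_draw(rng, hairpin_mu, config.nb_dispersion)

    mirna_values = pd.DataFrame(
        np.vstack([mature_counts, hairpin_counts]),
        index=mature_ids + hairpin_ids, columns=samples,
    )
    mirna_counts = ExpressionMatrix(
        values=mirna_values,
        feature_class=pd.Series(["mature"] * config.n_mirna + ["hairpin"] * config.n_mirna,
                                index=mature_ids + hairpin_ids),
        sample_meta=sample_meta,
    )

    # ---- mRNA counts with planted target repression -----------------------
    mrna_ids = [f"gene{i + 1:05d}" for i in range(config.n_mrna)]
    mrna_sign = np.zeros(config.n_mrna)
    repressed: dict[str, list[str]] = {}
    if de_idx.size:
        want = min(de_idx.size * config.targets_per_mirna, config.n_mrna)
        target_pool = rng.choice(config.n_mrna, size=want, replace=False)
        pos = 0
        for i in de_idx:
            take = target_pool[pos: pos + config.targets_per_mirna]
            pos += config.targets_per_mirna
            if take.size == 0:
                break
            # targets shift opposite to the miRNA
            mrna_sign[take] = -de_sign[i]
            repressed[mature_ids[i]] = [mrna_ids[t] for t in take]
    truth["repressed_targets"] = repressed

    mrna_base = rng.uniform(4.0, 10.0, size=config.n_mrna)
    mrna_log2_mean = (
        mrna_base[:, None]
        + 0.5 * config.target_log2fc * mrna_sign[:, None] * group_sign[None, :]
    )
    mrna_lib = np.exp(rng.normal(0.0, lib_sigma, size=2 * n))
    mrna_lib /= np.exp(np.mean(np.log(mrna_lib)))
    mrna_mu = (2.0 ** mrna_log2_mean) * mrna_lib[None, :]
    mrna_counts_arr = _nb_draw(rng, mrna_mu, config.nb_dispersion)
    mrna_counts = ExpressionMatrix(
        values=pd.DataFrame(mrna_counts_arr, index=mrna_ids, columns=samples),
        feature_class=pd.Series("mRNA", index=mrna_ids),
        sample_meta=sample_meta,
    )

    # ---- proteins: subset of targets propagated ---------------------------
    protein_ids = [f"P_{g}" for g in mrna_ids[: config.n_protein]]
    protein_of_mrna = {g: f"P_{g}" for g in mrna_ids[: config.n_protein]}
    prot_sign = np.zeros(config.n_protein)
    propagated: list[str] = []
    shifted_mrnas = {g for targets in repressed.values() for g in targets}
    # deterministic propagation: every second shifted target with a protein
    propagate_candidates = sorted(g for g in shifted_mrnas if g in protein_of_mrna)
    for j, g in enumerate(propagate_candidates):
        if j % 2 == 0:
            idx = mrna_ids.index(g)
            prot_sign[idx] = mrna_sign[idx]
            propagated.append(protein_of_mrna[g])
    truth["protein_propagated"] = propagated

    # ---- target-evidence table --------------------------------------------
    evidence_rows: list[tuple] = []
    for mir in sorted(repressed):
        for g in repressed[mir]:
            support = int(rng.integers(3, 6))  # planted pairs pass the 3-of-5 gate
            flags = np.zeros(5, dtype=int)
            flags[rng.choice(5, size=support, replace=False)] = 1
            evidence_rows.append((mir, g, *flags.tolist(), 1))
    n_background_pairs = 2 * len(evidence_rows) + 10
    for _ in range(n_background_pairs):
        mir = mature_ids[int(rng.integers(0, config.n_mirna))]
        g = mrna_ids[int(rng.integers(0, config.n_mrna))]
        support = int(rng.integers(0, 6))
        flags = np.zeros(5, dtype=int)
        if support:
            flags[rng.choice(5, size=support, replace=False)] = 1
        evidence_rows.append((mir, g, *flags.tolist(), int(rng.random() < 0.3)))
    target_evidence = pd.DataFrame(
        evidence_rows,
        columns=["mirna", "mrna", "tool1", "tool2", "tool3", "tool4", "tool5", "validated"],
    ).drop_duplicates(subset=["mirna", "mrna"], keep="first").reset_index(drop=True)

    prot_base = rng.uniform(18.0, 24.0, size=config.n_protein)  # log2 abundance scale
    prot_mean = (
        prot_base[:, None]
        + 0.5 * 0.8 * prot_sign[:, None] * group_sign[None, :]
    )
    prot_values = prot_mean + rng.normal(0.0, 0.25, size=(config.n_protein, 2 * n))
    protein_abundance = ExpressionMatrix(
        values=pd.DataFrame(prot_values, index=protein_ids, columns=samples),
        feature_class=pd.Series("protein", index=protein_ids),
        sample_meta=sample_meta,
        is_counts=False,
    )
    protein_table = _protein_summary(protein_abundance)

    # ---- methylation -------------------------------------------------------
    cpg_ids: list[str] = []
    cpg_to_gene: dict[str, str] = {}
    icr_cpgs: list[str] = []
    for j in range(8):  # imprinting-control-region block on the clustered locus
        if not cluster_genes:
            break
        cid = f"cg_icr_{j + 1:02d}"
        cpg_ids.append(cid)
        cpg_to_gene[cid] = cluster_genes[j % len(cluster_genes)]
        icr_cpgs.append(cid)
    for g in gene_ids[config.cluster_size:]:
        cid = f"cg_{g}"
        cpg_ids.append(cid)
        cpg_to_gene[cid] = g
    truth["icr_cpgs"] = icr_cpgs

    beta_base = rng.uniform(0.2, 0.8, size=len(cpg_ids))
    shift = np.zeros(len(cpg_ids))
    shift[: len(icr_cpgs)] = config.icr_beta_shift  # DP hypermethylated
    conc = 200.0
    beta_mean = np.clip(
        beta_base[:, None] + 0.5 * shift[:, None] * group_sign[None, :], 0.01, 0.99
    )
    beta_vals = rng.beta(beta_mean * conc, (1.0 - beta_mean) * conc)
    methylation = ExpressionMatrix(
        values=pd.DataFrame(beta_vals, index=cpg_ids, columns=samples),
        feature_class=pd.Series("cpg", index=cpg_ids),
        sample_meta=sample_meta,
        is_counts=False,
    )

    # ---- mature sequences and ortholog candidates -------------------------
    mouse_sequences: dict[str, str] = {}
    human_sequences: dict[str, str] = {}
    conserved_truth: dict[str, bool] = {}
    for mid in mature_ids:
        conserved = bool(rng.random() < config.conserved_fraction)
        target_run = 8 if conserved else 6
        while True:
            mouse = _random_rna(rng, 22)
            human = _mutate_to_max_run(rng, mouse, target_run)
            run = _brute_longest_run(mouse, human)
            if (conserved and run >= 7) or (not conserved and run < 7):
                break
        mouse_sequences[mid] = mouse
        human_sequences[f"hsa-{mid}"] = human
        conserved_truth[mid] = conserved
    truth["conserved_pairs"] = conserved_truth
    for ann in annotation:
        ann.mature_sequence = mouse_sequences[mature_of_gene[ann.gene_id]]

    # ---- genome, promoters and planted motifs -----------------------------
    contig_len: dict[str, int] = {}
    for ann in annotation:
        need = max(ann.end, ann.tss) + 2 * spacing
        contig_len[ann.chrom] = max(contig_len.get(ann.chrom, 0), need)
    genome = {c: _random_dna(rng, contig_len[c]) for c in sorted(contig_len)}

    pfms = [_make_pfm(rng, "SYN1", "SYNMOTIF1", 10), _make_pfm(rng, "SYN2", "SYNMOTIF2", 10)]
    focal_gene = cluster_genes[0] if cluster_genes else gene_ids[0]
    singles: list[str] = []
    by_id = {a.gene_id: a for a in annotation}
    window = 500
    genome_mut = {c: bytearray(s, "ascii") for c, s in genome.items()}
    _plant_motif(genome_mut, by_id[focal_gene], pfms[0], config.motif_copies, window)
    for g in gene_ids:
        if g == focal_gene:
            continue
        if rng.random() < 0.2:
            _plant_motif(genome_mut, by_id[g], pfms[0], 1, window)
            singles.append(g)
    genome = {c: bytes(b).decode("ascii") for c, b in genome_mut.items()}
    truth["motif_focal_promoter"] = focal_gene
    truth["motif_pwm"] = pfms[0].id
    truth["motif_single_copy_promoters"] = singles

    # ---- phenotypes --------------------------------------------------------
    insulin = np.exp(rng.normal(0.0, 0.25, size=2 * n)) * np.where(group == "DP", 2.0, 1.0)
    ffa = 0.5 * np.exp(rng.normal(0.0, 0.2, size=2 * n)) * np.where(group == "DP", 2.0, 1.0)
    glucose = rng.normal(6.0, 0.5, size=2 * n) + np.where(group == "DP", 0.6, 0.0)
    hba1c = rng.normal(4.5, 0.2, size=2 * n) + np.where(group == "DP", 0.15, 0.0)
    phenotypes = pd.DataFrame(
        {
            "group": group, "sex": "F",
            "insulin": insulin, "ffa": ffa,
            "glucose": glucose, "hba1c": hba1c,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    diam_rows = []
    for s, g in zip(samples, group):
        mu_d = math.log(95.0 if g == "DP" else 80.0)
        d = np.exp(rng.normal(mu_d, 0.35, size=200))
        diam_rows.append(pd.DataFrame({"sample_id": s, "diameter_um": d}))
    diameters = pd.concat(diam_rows, ignore_index=True)
    truth["phenotype_effects"] = {"adipo_ir_ratio": 4.0, "insulin_ratio": 2.0, "ffa_ratio": 2.0}

    return CohortBundle(
        config=config,
        mirna_counts=mirna_counts,
        mrna_counts=mrna_counts,
        protein_abundance=protein_abundance,
        protein_table=protein_table,
        methylation=methylation,
        cpg_to_gene=cpg_to_gene,
        target_evidence=target_evidence,
        annotation=annotation,
        mature_to_hairpin=mature_to_hairpin,
        mouse_sequences=mouse_sequences,
        human_sequences=human_sequences,
        genome=genome,
        pfms=pfms,
        phenotypes=phenotypes,
        diameters=diameters,
        truth=truth,
    )


def _make_gene(gene_id: str, chrom: str, tss: int, strand: str,
               mature_id: str, hairpin_id: str, locus: str | None) -> MirGeneAnnotation:
    length = 80
    if strand == "+":
        start, end = tss, tss + length
    else:
        start, end = tss - length, tss
    return MirGeneAnnotation(
        gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
        locus_label=locus, mature_ids=[mature_id], hairpin_id=hairpin_id,
    )


def _protein_summary(abundance: ExpressionMatrix) -> pd.DataFrame:
    """Per-protein log2FC (DP/DR) and unpaired Welch t p-value, computed
    from the abundance matrix (log2 scale)."""
    from scipy import stats

    groups = abundance.groups()
    dp = abundance.values[groups.index[groups == "DP"]].to_numpy()
    dr = abundance.values[groups.index[groups == "DR"]].to_numpy()
    log2fc = dp.mean(axis=1) - dr.mean(axis=1)
    _, p = stats.ttest_ind(dp, dr, axis=1, equal_var=False)
    return pd.DataFrame({"log2fc": log2fc, "p": p},
                        index=pd.Index(abundance.feature_ids, name="protein_id"))


def _make_pfm(rng: np.random.Generator, pfm_id: str, name: str, length: int) -> PWM:
    consensus = rng.integers(0, 4, size=length)
    counts = np.ones((4, length))
    counts[consensus, np.arange(length)] = 18.0
    return PWM(id=pfm_id, name=name, counts=counts)


def _plant_motif(genome: dict[str, bytearray], ann: MirGeneAnnotation,
                 pfm: PWM, copies: int, window: int) -> None:
    """Write ``copies`` consensus occurrences into the upstream window of a
    gene, oriented so the promoter-strand sequence contains the consensus."""
    from .motifscan import reverse_complement

    consensus = pfm.consensus()
    contig = genome[ann.chrom]
    if ann.strand == "+":
        start, end = max(0, ann.tss - window), ann.tss
        insert = consensus
    else:
        start, end = ann.tss, min(len(contig), ann.tss + window)
        insert = reverse_complement(consensus)
    avail = end - start
    if copies <= 0 or avail < len(consensus):
        return
    stride = max(len(consensus), avail // max(copies, 1))
    placed = 0
    offset = start
    while placed < copies and offset + len(consensus) <= end:
        contig[offset: offset + len(consensus)] = insert.encode("ascii")
        offset += stride
        placed += 1


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

def write_bundle(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every layer of the bundle as plain-text files; returns the
    path map. Equal seeds produce byte-identical trees."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_counts": out / "mirna_counts.tsv",
        "mrna_counts": out / "mrna_counts.tsv",
        "protein_abundance": out / "protein_abundance.tsv",
        "protein_table": out / "protein_de.tsv",
        "methylation": out / "methylation_beta.tsv",
        "cpg_to_gene": out / "cpg_to_gene.tsv",
        "target_evidence": out / "target_evidence.tsv",
        "annotation": out / "mirna_genes.bed",
        "linkage": out / "mature_to_hairpin.tsv",
        "mouse_fasta": out / "mature_mouse.fa",
        "human_fasta": out / "mature_human_candidates.fa",
        "genome": out / "genome.fa",
        "pfms": out / "motifs.jaspar",
        "sample_sheet": out / "samples.csv",
        "phenotypes": out / "phenotypes.csv",
        "diameters": out / "adipocyte_diameters.csv",
        "truth": out / "truth.json",
    }
    iokit.write_counts_tsv(bundle.mirna_counts, paths["mirna_counts"])
    iokit.write_counts_tsv(bundle.mrna_counts, paths["mrna_counts"])
    iokit.write_counts_tsv(bundle.protein_abundance, paths["protein_abundance"])
    bundle.protein_table.to_csv(paths["protein_table"], sep="\t", lineterminator="\n")
    iokit.write_counts_tsv(bundle.methylation, paths["methylation"])
    pd.Series(bundle.cpg_to_gene, name="gene_id").rename_axis("cpg_id").to_csv(
        paths["cpg_to_gene"], sep="\t", lineterminator="\n")
    bundle.target_evidence.to_csv(paths["target_evidence"], sep="\t", index=False,
                                  lineterminator="\n")
    iokit.write_bed(bundle.annotation, paths["annotation"])
    pd.Series(bundle.mature_to_hairpin, name="hairpin_id").rename_axis("mature_id").to_csv(
        paths["linkage"], sep="\t", lineterminator="\n")
    iokit.write_fasta(bundle.mouse_sequences, paths["mouse_fasta"])
    iokit.write_fasta(bundle.human_sequences, paths["human_fasta"])
    iokit.write_fasta(bundle.genome, paths["genome"])
    iokit.write_jaspar_pfm(bundle.pfms, paths["pfms"])
    iokit.write_sample_sheet(bundle.mirna_counts.sample_meta, paths["sample_sheet"])
    bundle.phenotypes.to_csv(paths["phenotypes"], lineterminator="\n")
    bundle.diameters.to_csv(paths["diameters"], index=False, lineterminator="\n")
    iokit.write_json(bundle.truth, paths["truth"])
    return paths


def load_bundle(indir: str | Path, config: SimConfig | None = None) -> CohortBundle:
    """Read a bundle tree written by :func:`write_bundle`."""
    ind = Path(indir)
    sample_meta = iokit.read_sample_sheet(ind / "samples.csv")
    mirna_counts = iokit.read_counts_tsv(ind / "mirna_counts.tsv", sample_meta)
    mrna_counts = iokit.read_counts_tsv(ind / "mrna_counts.tsv", sample_meta)
    protein_abundance = iokit.read_counts_tsv(
        ind / "protein_abundance.tsv", sample_meta, is_counts=False)
    protein_table = pd.read_csv(ind / "protein_de.tsv", sep="\t", index_col="protein_id")
    methylation = iokit.read_counts_tsv(ind / "methylation_beta.tsv", sample_meta,
                                        is_counts=False)
    cpg_map = pd.read_csv(ind / "cpg_to_gene.tsv", sep="\t", index_col="cpg_id")
    target_evidence = pd.read_csv(ind / "target_evidence.tsv", sep="\t")
    annotation = iokit.read_bed(ind / "mirna_genes.bed")
    linkage = pd.read_csv(ind / "mature_to_hairpin.tsv", sep="\t", index_col="mature_id")
    mature_to_hairpin = linkage["hairpin_id"].to_dict()
    mouse = iokit.read_fasta(ind / "mature_mouse.fa")
    human = iokit.read_fasta(ind / "mature_human_candidates.fa")
    genome = iokit.read_fasta(ind / "genome.fa")
    pfms = iokit.read_jaspar_pfm(ind / "motifs.jaspar")
    phenotypes = pd.read_csv(ind / "phenotypes.csv", index_col="sample_id")
    diameters = pd.read_csv(ind / "adipocyte_diameters.csv")
    truth = iokit.read_json(ind / "truth.json")
    gene_of_mature = {m: m.replace("miR", "mir") for m in mature_to_hairpin}
    for ann in annotation:
        matures = [m for m, g in gene_of_mature.items() if g == ann.gene_id]
        ann.mature_ids = matures
        ann.hairpin_id = mature_to_hairpin.get(matures[0]) if matures else None
        if matures:
            ann.mature_sequence = mouse.get(matures[0])
    return CohortBundle(
        config=config or SimConfig(),
        mirna_counts=mirna_counts, mrna_counts=mrna_counts,
        protein_abundance=protein_abundance, protein_table=protein_table,
        methylation=methylation, cpg_to_gene=cpg_map["gene_id"].to_dict(),
        target_evidence=target_evidence, annotation=annotation,
        mature_to_hairpin=mature_to_hairpin, mouse_sequences=mouse,
        human_sequences=human, genome=genome, pfms=pfms,
        phenotypes=phenotypes, diameters=diameters, truth=truth,
    )


# ---------------------------------------------------------------------------
# tiny worked-example fixtures
# ---------------------------------------------------------------------------

# Reference imprinted-locus CpG beta-value summary used as a worked example:
# per-CpG group means with the published absolute percentage change and p.
REFERENCE_CPG_ROWS = [
    # locus, cpg_id, chrom, beta_case(DP), beta_control(DR), printed |%| change, printed p
    ("Mest", "cg43264716", "chr6", 0.522, 0.494, 2.75, 0.007828),
    ("Mest", "cg43264721", "chr6", 0.393, 0.416, 2.33, 0.040658),
    ("Dlk1-Gtl2", "cg31119458", "chr12", 0.699, 0.643, 5.64, 3.7e-07),
    ("Dlk1-Gtl2", "cg31119465", "chr12", 0.505, 0.451, 5.36, 0.000483),
    ("Dlk1-Gtl2", "cg31119460", "chr12", 0.558, 0.526, 3.20, 0.000718),
    ("Dlk1-Gtl2", "cg31119462", "chr12", 0.520, 0.500, 2.07, 0.01158),
    ("Dlk1-Gtl2", "cg31119459", "chr12", 0.798, 0.775, 2.29, 0.021666),
    ("Dlk1-Gtl2", "cg31119463", "chr12", 0.457, 0.434, 2.30, 0.025192),
    ("Dlk1-Gtl2", "cg31119469", "chr12", 0.271, 0.252, 1.92, 0.033323),
]


def reference_cpg_table() -> pd.DataFrame:
    return pd.DataFrame(
        REFERENCE_CPG_ROWS,
        columns=["locus", "cpg_id", "chrom", "beta_case", "beta_control",
                 "printed_abs_pct_change", "printed_p"],
    )


def reference_beta_matrix(n_per_group: int = 3) -> ExpressionMatrix:
    """Beta matrix whose group means equal the reference table exactly
    (per-group constant columns)."""
    table = reference_cpg_table()
    samples = [f"DP_{i + 1}" for i in range(n_per_group)] + \
              [f"DR_{i + 1}" for i in range(n_per_group)]
    meta = pd.DataFrame(
        {"group": ["DP"] * n_per_group + ["DR"] * n_per_group, "sex": "F"},
        index=pd.Index(samples, name="sample_id"),
    )
    values = pd.DataFrame(
        np.column_stack([
            np.repeat(table["beta_case"].to_numpy()[:, None], n_per_group, axis=1),
            np.repeat(table["beta_control"].to_numpy()[:, None], n_per_group, axis=1),
        ]),
        index=table["cpg_id"], columns=samples,
    )
    return ExpressionMatrix(
        values=values,
        feature_class=pd.Series("cpg", index=values.index),
        sample_meta=meta,
        is_counts=False,
    )


def toy_network_matrix() -> ExpressionMatrix:
    """Six miRNAs in two clean 3-feature blocks over 8 samples."""
    rng = np.random.default_rng(1234)
    f1, f2 = rng.standard_normal(8), rng.standard_normal(8)
    rows = [f1 + 0.1 * rng.standard_normal(8) for _ in range(3)]
    rows += [f2 + 0.1 * rng.standard_normal(8) for _ in range(3)]
    ids = [f"toy-miR-{i + 1}" for i in range(6)]
    samples = [f"S{i + 1}" for i in range(8)]
    meta = pd.DataFrame({"group": ["DP"] * 4 + ["DR"] * 4, "sex": "F"},
                        index=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(
        values=pd.DataFrame(np.array(rows), index=ids, columns=samples),
        feature_class=pd.Series("mature", index=ids),
        sample_meta=meta,
        is_counts=False,
    )


def toy_target_evidence() -> pd.DataFrame:
    """Ten miRNA-mRNA pairs with known consensus outcome (4 pass the
    >= 3 tools + validated gate)."""
    rows = [
        ("toy-miR-1", "geneA", 1, 1, 1, 0, 0, 1),  # 3 tools, validated -> keep
        ("toy-miR-1", "geneB", 1, 1, 1, 1, 1, 0),  # 5 tools, not validated -> drop
        ("toy-miR-2", "geneC", 1, 1, 0, 0, 0, 1),  # 2 tools -> drop
        ("toy-miR-2", "geneD", 1, 1, 1, 1, 0, 1),  # keep
        ("toy-miR-3", "geneE", 1, 1, 1, 0, 0, 0),  # not validated -> drop
        ("toy-miR-3", "geneF", 1, 1, 1, 1, 1, 1),  # keep
        ("toy-miR-4", "geneG", 1, 0, 0, 0, 0, 0),  # drop
        ("toy-miR-4", "geneH", 0, 0, 0, 0, 0, 1),  # drop
        ("toy-miR-5", "geneI", 0, 1, 1, 1, 0, 1),  # keep
        ("toy-miR-5", "geneJ", 1, 1, 0, 1, 0, 0),  # drop
    ]
    return pd.DataFrame(rows, columns=["mirna", "mrna", "tool1", "tool2", "tool3",
                                       "tool4", "tool5", "validated"])


def toy_promoter_fixture() -> tuple[dict[str, str], list[PWM]]:
    """Two PFMs and a small promoter set with planted consensus copies in
    the first promoter only."""
    rng = np.random.default_rng(99)
    pfm_a = _make_pfm(rng, "TOYA", "TOYMOTIFA", 8)
    pfm_b = _make_pfm(rng, "TOYB", "TOYMOTIFB", 8)
    promoters: dict[str, str] = {}
    for i in range(6):
        promoters[f"prom{i + 1}"] = _random_dna(rng, 200)
    seq = bytearray(promoters["prom1"], "ascii")
    cons = pfm_a.consensus().encode("ascii")
    for offset in (10, 60, 110, 160):
        seq[offset: offset + len(cons)] = cons
    promoters["prom1"] = bytes(seq).decode("ascii")
    return promoters, [pfm_a, pfm_b]


def make_worked_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the tiny worked-example fixtures used by the acceptance suite."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta_matrix": out / "reference_beta.tsv",
        "beta_reference": out / "reference_cpg_table.tsv",
        "toy_network": out / "toy_network.tsv",
        "toy_targets": out / "toy_target_evidence.tsv",
        "toy_promoters": out / "toy_promoters.fa",
        "toy_pfms": out / "toy_motifs.jaspar",
    }
    iokit.write_counts_tsv(reference_beta_matrix(), paths["beta_matrix"])
    reference_cpg_table().to_csv(paths["beta_reference"], sep="\t", index=False,
                                 lineterminator="\n")
    iokit.write_counts_tsv(toy_network_matrix(), paths["toy_network"])
    toy_target_evidence().to_csv(paths["toy_targets"], sep="\t", index=False,
                                 lineterminator="\n")
    promoters, pfms = toy_promoter_fixture()
    iokit.write_fasta(promoters, paths["toy_promoters"])
    iokit.write_jaspar_pfm(pfms, paths["toy_pfms"])
    return paths
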