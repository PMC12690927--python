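"""Readers and writers for every external format the pipeline touches.

All tabular containers round-trip losslessly through their writer/reader
pair. Coordinates follow BED conventions: 0-based, half-open; the TSS of a
minus-strand gene is the interval *end*.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


VALID_FEATURE_CLASSES = frozenset({"mature", "hairpin", "mRNA", "protein", "cpg"})


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples numeric table with per-feature class labels.

    ``values`` is a DataFrame indexed by feature ID with sample IDs as
    columns. ``feature_class`` assigns each feature one label from
    ``VALID_FEATURE_CLASSES``; ``sample_meta`` (indexed by sample ID) must
    carry at least a ``group`` column.
    """

    values: pd.DataFrame
    feature_class: pd.Series
    sample_meta: pd.DataFrame
    is_counts: bool = True

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate feature ID: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID: {dup!r}")
        self.feature_class = self.feature_class.reindex(self.values.index)
        if self.feature_class.isna().any():
            missing = self.feature_class.index[self.feature_class.isna()][0]
            raise FormatError(f"feature {missing!r} has no class label")
        bad = set(self.feature_class.unique()) - VALID_FEATURE_CLASSES
        if bad:
            raise FormatError(f"unknown feature class(es): {sorted(bad)}")
        if not set(self.values.columns) <= set(self.sample_meta.index):
            orphan = sorted(set(self.values.columns) - set(self.sample_meta.index))
            raise FormatError(f"samples without metadata: {orphan}")
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]
        if "group" not in self.sample_meta.columns or self.sample_meta["group"].isna().any():
            raise FormatError("every sample needs a group label")
        if self.is_counts:
            arr = self.values.to_numpy()
            if np.isnan(arr).any():
                raise FormatError("count matrix contains missing values")
            if (arr < 0).any():
                raise FormatError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def subset_class(self, cls: str) -> "ExpressionMatrix":
        keep = self.feature_class[self.feature_class == cls].index
        return self.subset_features(list(keep))

    def subset_features(self, ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(ids)],
            feature_class=self.feature_class.loc[list(ids)],
            sample_meta=self.sample_meta,
            is_counts=self.is_counts,
        )

    def groups(self) -> pd.Series:
        return self.sample_meta["group"]


@dataclass
class MirGeneAnnotation:
    """Genomic record for one miRNA gene.

    The BED interval is stored as (chrom, start, end, strand); the promoter
    anchor ``tss`` is derived: start on plus strand, end on minus strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    locus_label: str | None = None
    mature_ids: list[str] = field(default_factory=list)
    hairpin_id: str | None = None
    mature_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start <= self.end):
            raise FormatError(f"{self.gene_id}: invalid interval [{self.start}, {self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class PWM:
    """Position frequency matrix with log-odds scoring support.

    ``counts`` rows are A, C, G, T. Scoring adds ``pseudocount`` to every
    cell, normalizes per column and takes log2 odds against ``background``.
    """

    id: str
    name: str
    counts: np.ndarray
    pseudocount: float = 0.25
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise FormatError(f"PWM {self.id}: counts must be 4 x L with L >= 4")
        if (self.counts < 0).any() or np.isnan(self.counts).any():
            raise FormatError(f"PWM {self.id}: counts must be non-negative numbers")
        if (self.counts.sum(axis=0) <= 0).any():
            raise FormatError(f"PWM {self.id}: zero column sum")
        if self.pseudocount <= 0:
            raise FormatError(f"PWM {self.id}: pseudocount must be positive")
        if (self.background <= 0).any() or abs(self.background.sum() - 1.0) > 1e-6:
            raise FormatError(f"PWM {self.id}: background must be strictly positive and sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """4 x L log2-odds matrix from pseudocounted column frequencies."""
        bg = self.background if background is None else np.asarray(background, float)
        padded = self.counts + self.pseudocount
        probs = padded / padded.sum(axis=0, keepdims=True)
        return np.log2(probs / bg[:, None])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


# ---------------------------------------------------------------------------
# Count matrices / sample sheets
# ---------------------------------------------------------------------------

def write_counts_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write features x samples values as TSV with a ``feature_class`` column."""
    df = matrix.values.copy()
    df.insert(0, "feature_class", matrix.feature_class)
    df.to_csv(path, sep="\t", index_label="feature_id", lineterminator="\n")


def read_counts_tsv(path: str | Path, sample_meta: pd.DataFrame,
                    is_counts: bool = True) -> ExpressionMatrix:
    """Read a TSV written by :func:`write_counts_tsv`.

    Rejects duplicate feature IDs and ragged rows (reported with the line
    number of the first offending row).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise FormatError(f"{path}: empty file")
    width = len(rows[0])
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(f"{path}:{lineno}: ragged row ({len(row)} fields, expected {width})")
    header = rows[0]
    if header[:2] != ["feature_id", "feature_class"]:
        raise FormatError(f"{path}: expected 'feature_id' and 'feature_class' leading columns")
    sample_ids = header[2:]
    ids, classes, data = [], [], []
    seen: set[str] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if row[0] in seen:
            raise FormatError(f"{path}:{lineno}: duplicate feature ID {row[0]!r}")
        seen.add(row[0])
        ids.append(row[0])
        classes.append(row[1])
        try:
            data.append([float(x) for x in row[2:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    arr = np.array(data, dtype=float) if data else np.empty((0, len(sample_ids)))
    if is_counts and arr.size and np.allclose(arr, np.round(arr)):
        values = pd.DataFrame(arr.astype(np.int64), index=ids, columns=sample_ids)
    else:
        values = pd.DataFrame(arr, index=ids, columns=sample_ids)
    return ExpressionMatrix(
        values=values,
        feature_class=pd.Series(classes, index=ids),
        sample_meta=sample_meta,
        is_counts=is_counts,
    )


def write_sample_sheet(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index_label="sample_id", lineterminator="\n")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col="sample_id")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    if "group" not in meta.columns:
        raise FormatError(f"{path}: sample sheet needs a 'group' column")
    return meta


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(annotations: Iterable[MirGeneAnnotation], path: str | Path) -> None:
    """BED6: chrom, start, end, name (= gene ID), score 0, strand."""
    with open(path, "w") as fh:
        for ann in annotations:
            fh.write(f"{ann.chrom}\t{ann.start}\t{ann.end}\t{ann.gene_id}\t0\t{ann.strand}\n")


def read_bed(path: str | Path) -> list[MirGeneAnnotation]:
    path = Path(path)
    out: list[MirGeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene ID {name!r}")
            seen.add(name)
            try:
                out.append(MirGeneAnnotation(
                    gene_id=name, chrom=chrom, start=int(start), end=int(end), strand=strand,
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    """ID -> uppercase sequence. U is preserved as given (uppercased)."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise FormatError(f"{path}: duplicate sequence ID {record.id!r}")
        out[record.id] = str(record.seq).upper()
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

def write_jaspar_pfm(pwms: Iterable[PWM], path: str | Path) -> None:
    """JASPAR 2016+ text: '>ID NAME' then A/C/G/T rows with bracketed counts."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id} {pwm.name}\n")
            for base, row in zip("ACGT", pwm.counts):
                cells = " ".join(
                    f"{int(v):6d}" if float(v).is_integer() else f"{v:6.2f}" for v in row
                )
                fh.write(f"{base}  [ {cells} ]\n")


def read_jaspar_pfm(path: str | Path, pseudocount: float = 0.25,
                    background: np.ndarray | None = None) -> list[PWM]:
    with open(path) as fh:
        try:
            parsed = motifs.parse(fh, "jaspar")
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
    out: list[PWM] = []
    for mot in parsed:
        counts = np.array([mot.counts[b] for b in "ACGT"], dtype=float)
        out.append(PWM(
            id=mot.matrix_id or mot.name,
            name=mot.name or mot.matrix_id,
            counts=counts,
            pseudocount=pseudocount,
            background=background if background is not None else np.full(4, 0.25),
        ))
    if not out:
        raise FormatError(f"{path}: no PFM records found")
    return out


# ---------------------------------------------------------------------------
# Networks / misc
# ---------------------------------------------------------------------------

def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    """Edge table (source, target, plus weight columns) as TSV."""
    if not {"source", "target"} <= set(edges.columns):
        raise FormatError("edge list needs 'source' and 'target' columns")
    edges.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    if not {"source", "target"} <= set(edges.columns):
        raise FormatError(f"{path}: edge list needs 'source' and 'target' columns")
    return edges


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> object:
    with open(path) as fh:
        return json.load(fh)
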