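"""Promoter extraction, PWM scanning and single-case motif enrichment.

Promoters are the ``window`` bp upstream of each gene's TSS (strand-aware,
clipped at contig bounds). Scanning slides the log-odds matrix over both
strands and counts windows whose score reaches a fraction of the
achievable score range. Enrichment of a motif in one promoter against all
other promoters uses the Crawford-Garthwaite single-case t statistic
t = (x - mean(ref)) / (sd(ref) * sqrt((n + 1) / n)) with n - 1 degrees of
freedom, one-sided in the enrichment direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .iokit import PWM, MirGeneAnnotation

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Promoter:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    clipped: bool = False


@dataclass
class PromoterSet:
    promoters: dict[str, Promoter]
    window: int = 500

    def sequences(self) -> dict[str, str]:
        return {g: p.sequence for g, p in self.promoters.items()}


@dataclass
class MotifEnrichmentResult:
    gene_id: str
    pwm_id: str
    count_focal: int
    ref_mean: float
    ref_sd: float
    t_cg: float
    p: float
    significant: bool
    degenerate: bool = False


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def extract_promoters(
    annotations: Sequence[MirGeneAnnotation],
    genome: Mapping[str, str],
    window: int = 500,
) -> PromoterSet:
    """Strand-aware upstream windows.

    Plus strand: [tss - window, tss); minus strand: [tss, tss + window),
    reverse-complemented so the returned sequence reads 5'->3' towards the
    TSS. Windows are clipped at contig bounds with a warning.
    """
    promoters: dict[str, Promoter] = {}
    for ann in annotations:
        if ann.chrom not in genome:
            raise KeyError(f"gene {ann.gene_id!r}: contig {ann.chrom!r} not in genome")
        contig = genome[ann.chrom]
        tss = ann.tss
        if ann.strand == "+":
            start, end = max(0, tss - window), tss
        else:
            start, end = tss, min(len(contig), tss + window)
        clipped = (end - start) < window
        if clipped:
            logger.warning("promoter of %s clipped to %d bp at contig bound",
                           ann.gene_id, end - start)
        seq = contig[start:end].upper()
        if ann.strand == "-":
            seq = reverse_complement(seq)
        promoters[ann.gene_id] = Promoter(
            gene_id=ann.gene_id, chrom=ann.chrom, start=start, end=end,
            strand=ann.strand, sequence=seq, clipped=clipped,
        )
    return PromoterSet(promoters=promoters, window=window)


def estimate_background(sequences: Mapping[str, str]) -> np.ndarray:
    """Pooled A/C/G/T frequencies over a promoter set (N excluded)."""
    counts = np.zeros(4)
    for seq in sequences.values():
        s = seq.upper()
        for i, base in enumerate("ACGT"):
            counts[i] += s.count(base)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    freqs = counts / counts.sum()
    # guard against degenerate zero-frequency backgrounds
    freqs = np.clip(freqs, 1e-3, None)
    return freqs / freqs.sum()


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def scan_pwm(
    sequence: str,
    pwm: PWM,
    min_score_frac: float = 0.8,
    background: np.ndarray | None = None,
) -> int:
    """Count log-odds hits of a PWM on both strands of a sequence.

    A window is a hit when its score reaches
    ``min + min_score_frac * (max - min)`` of the achievable log-odds
    range. N positions contribute 0 log-odds. Overlapping hits all count.
    """
    L = pwm.length
    seq = sequence.upper()
    if len(seq) < L:
        return 0
    lo = pwm.log_odds(background)
    lo5 = np.vstack([lo, np.zeros(L)])  # row 4 = N -> 0 contribution
    max_score = lo.max(axis=0).sum()
    min_score = lo.min(axis=0).sum()
    threshold = min_score + min_score_frac * (max_score - min_score)
    total = 0
    for strand_seq in (seq, reverse_complement(seq)):
        idx = np.fromiter((_BASE_INDEX.get(c, 4) for c in strand_seq),
                          dtype=np.intp, count=len(strand_seq))
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)
        scores = lo5[windows, np.arange(L)].sum(axis=1)
        total += int((scores >= threshold - 1e-12).sum())
    return total


def crawford_garthwaite(x_focal: float, reference: Sequence[float]) -> tuple[float, float, bool]:
    """Single-case t and one-sided (enrichment) p versus a reference sample.

    Returns (t, p, degenerate). With zero reference SD the p-value is
    undefined; a flagged result is returned (p = 1 when the focal value
    does not exceed the reference mean, else p = 0).
    """
    ref = np.asarray(reference, dtype=float)
    n = ref.size
    if n < 3:
        raise ValueError("reference sample must have at least 3 observations")
    mean = ref.mean()
    sd = ref.std(ddof=1)
    if sd == 0:
        logger.warning("degenerate reference (sd = 0) in single-case test")
        if x_focal > mean:
            return float("inf"), 0.0, True
        return (0.0 if x_focal == mean else float("-inf"),
                1.0, True)
    t = (x_focal - mean) / (sd * np.sqrt((n + 1) / n))
    p = float(stats.t.sf(t, df=n - 1))
    return float(t), p, False


def enrich_counts(
    counts: pd.DataFrame,
    threshold: float = 1e-6,
) -> list[MotifEnrichmentResult]:
    """Single-case enrichment of each cell against the other rows.

    ``counts`` is promoters x PWMs; each focal promoter is compared, per
    PWM, against the counts of all *other* promoters.
    """
    if counts.shape[0] < 4:
        raise ValueError("need at least 4 promoters for the reference distribution")
    results: list[MotifEnrichmentResult] = []
    for pwm_id in counts.columns:
        col = counts[pwm_id].to_numpy(dtype=float)
        for i, gene_id in enumerate(counts.index):
            ref = np.delete(col, i)
            t, p, degenerate = crawford_garthwaite(col[i], ref)
            results.append(MotifEnrichmentResult(
                gene_id=str(gene_id), pwm_id=str(pwm_id),
                count_focal=int(col[i]), ref_mean=float(ref.mean()),
                ref_sd=float(ref.std(ddof=1)), t_cg=t, p=p,
                significant=bool(p < threshold), degenerate=degenerate,
            ))
    return results


def count_table(
    promoters: PromoterSet,
    pwms: Sequence[PWM],
    min_score_frac: float = 0.8,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Hit counts, promoters x PWMs."""
    if background is None:
        background = estimate_background(promoters.sequences())
    data = {
        pwm.id: [
            scan_pwm(p.sequence, pwm, min_score_frac=min_score_frac, background=background)
            for p in promoters.promoters.values()
        ]
        for pwm in pwms
    }
    return pd.DataFrame(data, index=list(promoters.promoters))


def enrich_promoters(
    promoters: PromoterSet,
    pwms: Sequence[PWM],
    threshold: float = 1e-6,
    min_score_frac: float = 0.8,
    background: np.ndarray | None = None,
) -> list[MotifEnrichmentResult]:
    """Full table of per-(promoter, PWM) single-case enrichment results."""
    counts = count_table(promoters, pwms, min_score_frac=min_score_frac,
                         background=background)
    return enrich_counts(counts, threshold=threshold)


def enrichment_table(results: list[MotifEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "pwm_id": [r.pwm_id for r in results],
            "count_focal": [r.count_focal for r in results],
            "ref_mean": [r.ref_mean for r in results],
            "ref_sd": [r.ref_sd for r in results],
            "t_cg": [r.t_cg for r in results],
            "p": [r.p for r in results],
            "significant": [r.significant for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
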