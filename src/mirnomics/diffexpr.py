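"""Low-expression filtering, normalization, two-group tests and the
mature/hairpin concordance filter.

Group comparisons use a Welch t-test on normalized values with
Benjamini-Hochberg adjustment within the tested family. Fold changes are
log2(B/A) on the expression scale; CpG layers are compared on the beta
scale, where the effect is a plain difference of group means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iokit import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    feature_id: str
    mean_a: float
    mean_b: float
    log2fc: float
    p_raw: float
    p_adj: float
    direction: str  # "up" | "down" | "none" in group B relative to A
    degenerate: bool = False


@dataclass
class ConcordanceCall:
    mature_id: str
    hairpin_id: str
    mature_de: DEResult
    hairpin_de: DEResult
    concordant: bool


def de_table(results: list[DEResult]) -> pd.DataFrame:
    """DE results as a DataFrame indexed by feature ID."""
    return pd.DataFrame(
        {
            "mean_a": [r.mean_a for r in results],
            "mean_b": [r.mean_b for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "direction": [r.direction for r in results],
            "degenerate": [r.degenerate for r in results],
        },
        index=pd.Index([r.feature_id for r in results], name="feature_id"),
    )


def filter_low_expression(matrix: ExpressionMatrix, min_mean: float = 10.0) -> ExpressionMatrix:
    """Keep features whose overall mean is strictly greater than ``min_mean``.

    Default 10 for miRNA read counts; use 1 for mean-FPKM filtering of mRNA.
    """
    if matrix.is_counts and (matrix.values.to_numpy() < 0).any():
        raise ValueError("count filter applied to non-count input")
    means = matrix.values.mean(axis=1)
    keep = means.index[means > min_mean]
    return matrix.subset_features(list(keep))


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference row).

    Features with a zero count in any sample are excluded from the
    reference, as is conventional. Factors are scaled to geometric mean 1.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) <= 0).any():
        zero = counts.columns[arr.sum(axis=0) <= 0][0]
        raise ValueError(f"sample {zero!r} has zero total count")
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature has positive counts in every sample")
    logs = np.log(arr[positive])
    ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - ref[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def normalize_cpm(matrix: ExpressionMatrix, prior: float = 1.0) -> ExpressionMatrix:
    """log2 counts-per-million with a prior count.

    Each sample is scaled by an effective library size — its median-of-
    ratios size factor times the geometric-mean total count — which keeps
    the normalization robust to asymmetric differential expression
    (composition bias). An exact scalar multiple of a sample normalizes to
    an identical column.
    """
    factors = size_factors_median_of_ratios(matrix.values)
    geo_total = float(np.exp(np.mean(np.log(matrix.values.sum(axis=0)))))
    eff_lib = factors * geo_total
    cpm = matrix.values / eff_lib * 1e6
    logcpm = np.log2(cpm + prior)
    return ExpressionMatrix(
        values=logcpm,
        feature_class=matrix.feature_class,
        sample_meta=matrix.sample_meta,
        is_counts=False,
    )


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values over the whole input family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def test_two_groups(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    effect: str = "log2fc",
) -> list[DEResult]:
    """Per-feature Welch t-test of group B versus group A.

    ``effect`` selects the reported effect size: ``"log2fc"`` treats values
    as log2-scale expression and reports mean difference as log2(B/A);
    ``"difference"`` (for beta-value matrices) reports the plain difference.
    Constant features in both groups are flagged degenerate with p = 1.
    """
    groups = matrix.groups()
    cols_a = groups.index[groups == group_a]
    cols_b = groups.index[groups == group_b]
    if len(cols_a) < 3 or len(cols_b) < 3:
        raise ValueError("need at least 3 samples per group")
    a = matrix.values[cols_a].to_numpy(dtype=float)
    b = matrix.values[cols_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_ind(b, a, axis=1, equal_var=False)
    effect_size = mean_b - mean_a
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    pval = np.where(degenerate | np.isnan(pval), 1.0, pval)
    effect_size = np.where(degenerate & (effect_size == 0), 0.0, effect_size)
    padj = benjamini_hochberg(pval)
    results = []
    for i, fid in enumerate(matrix.feature_ids):
        eff = float(effect_size[i])
        if degenerate[i] and eff == 0.0:
            direction = "none"
        else:
            direction = "up" if eff > 0 else ("down" if eff < 0 else "none")
        results.append(DEResult(
            feature_id=fid,
            mean_a=float(mean_a[i]),
            mean_b=float(mean_b[i]),
            log2fc=eff,
            p_raw=float(pval[i]),
            p_adj=float(padj[i]),
            direction=direction,
            degenerate=bool(degenerate[i]),
        ))
    return results


def concordance_filter(
    mature_de: list[DEResult],
    hairpin_de: list[DEResult],
    linkage: dict[str, str],
    alpha: float = 0.05,
    require_hairpin_significance: bool = True,
) -> list[ConcordanceCall]:
    """Retain mature miRNAs whose linked hairpin follows the same pattern.

    Concordant iff mature p_raw < alpha AND hairpin log2fc shares the
    mature sign AND (by default) hairpin p_raw < alpha. Mature features
    without a linked hairpin in the data are excluded and logged.
    """
    hairpin_by_id = {r.feature_id: r for r in hairpin_de}
    calls: list[ConcordanceCall] = []
    for mat in mature_de:
        hp_id = linkage.get(mat.feature_id)
        if hp_id is None or hp_id not in hairpin_by_id:
            logger.info("mature %s has no linked hairpin in the data; excluded", mat.feature_id)
            continue
        hp = hairpin_by_id[hp_id]
        ok = mat.p_raw < alpha and np.sign(hp.log2fc) == np.sign(mat.log2fc) != 0
        if require_hairpin_significance:
            ok = ok and hp.p_raw < alpha
        calls.append(ConcordanceCall(
            mature_id=mat.feature_id, hairpin_id=hp_id,
            mature_de=mat, hairpin_de=hp, concordant=bool(ok),
        ))
    return calls


def percent_methylation_change(de: DEResult) -> float:
    """Absolute percentage-point difference of group mean beta values."""
    for mean in (de.mean_a, de.mean_b):
        if not (0.0 <= mean <= 1.0):
            raise ValueError(f"beta-scale mean outside [0, 1]: {mean}")
    return abs(de.mean_a - de.mean_b) * 100.0


def protein_significance(log2fc: float, p: float, lfc_threshold: float = 0.5,
                         alpha: float = 0.05) -> bool:
    """Protein DE gate: |log2FC| > threshold AND p < alpha."""
    return abs(log2fc) > lfc_threshold and p < alpha
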