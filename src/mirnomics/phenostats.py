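"""Phenotype-level statistics.

Includes the adipose insulin-resistance index (insulin x free fatty
acids), adipocyte diameter histograms, Spearman correlation with exact
permutation p for small n, an exact paired Wilcoxon signed-rank test, and
stratified (e.g. sex-specific) association wrappers.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    statistic: float
    p: float
    n: int
    method: str
    degenerate: bool = False


def adipo_ir(insulin: float | np.ndarray, ffa: float | np.ndarray,
             units: str = "insulin_units*ffa_units") -> tuple[np.ndarray, str]:
    """Adipose insulin-resistance index: plasma insulin times FFA.

    Units are propagated, not converted.
    """
    ins = np.asarray(insulin, dtype=float)
    fat = np.asarray(ffa, dtype=float)
    if (ins < 0).any() or (fat < 0).any():
        raise ValueError("insulin and FFA must be non-negative")
    return ins * fat, units


def diameter_histogram(
    diameters_by_group: dict[str, np.ndarray],
    bin_edges: np.ndarray,
) -> pd.DataFrame:
    """Relative-frequency (%) of adipocyte diameters per bin and group.

    Values outside the bin range are counted in flagged underflow/overflow
    bins so every group's percentages sum to 100.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    columns = {}
    overflow_seen = False
    for group, diam in diameters_by_group.items():
        d = np.asarray(diam, dtype=float)
        if d.size == 0:
            raise ValueError(f"group {group!r} has no diameters")
        if (d <= 0).any():
            raise ValueError("diameters must be positive")
        counts, _ = np.histogram(d, bins=edges)
        under = int((d < edges[0]).sum())
        over = int((d > edges[-1]).sum())
        if under or over:
            overflow_seen = True
            logger.warning("group %s: %d diameters outside bin range", group, under + over)
        columns[group] = np.concatenate([counts, [under, over]]) / d.size * 100.0
    table = pd.DataFrame(columns, index=labels + ["underflow", "overflow"])
    if not overflow_seen:
        table = table.drop(index=["underflow", "overflow"])
    return table


def _rank(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def spearman_assoc(x: np.ndarray, y: np.ndarray,
                   exact_max_n: int = 9) -> AssociationResult:
    """Spearman rank correlation with average ranks for ties.

    Missing values are dropped pairwise. The two-sided p is exact (full
    permutation enumeration) for n <= ``exact_max_n``, and uses the
    t-approximation otherwise. Constant input is flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant vector: Spearman rho undefined")
        return AssociationResult(float("nan"), 1.0, n, "spearman", degenerate=True)
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        rx_c = rx - rx.mean()
        denom = math.sqrt(float((rx_c ** 2).sum()))
        for perm in itertools.permutations(range(n)):
            ry_p = ry[list(perm)]
            ry_c = ry_p - ry_p.mean()
            r = float(rx_c @ ry_c) / (denom * math.sqrt(float((ry_c ** 2).sum())))
            if abs(r) >= target:
                count += 1
            total += 1
        return AssociationResult(rho, count / total, n, "spearman-exact")
    if abs(rho) == 1.0:
        return AssociationResult(rho, 0.0, n, "spearman-t")
    t = rho * math.sqrt((n - 2) / (1 - rho ** 2))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return AssociationResult(rho, min(p, 1.0), n, "spearman-t")


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p for the signed-rank statistic via generating
    polynomial over all 2^n sign assignments.

    ``ranks2`` are doubled ranks (integers even with average-rank ties);
    ``w2`` is the doubled observed positive-rank sum.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2i = int(round(w2))
    p_low = dist[: w2i + 1].sum()
    p_high = dist[w2i:].sum()
    return float(min(1.0, 2 * min(p_low, p_high)))


def paired_wilcoxon(values_a: np.ndarray, values_b: np.ndarray,
                    exact_max_n: int = 25) -> AssociationResult:
    """Paired two-tailed Wilcoxon signed-rank test (b - a).

    Zero differences are dropped. The p-value is exact (full sign-pattern
    distribution, valid with tied ranks) for n <= ``exact_max_n`` non-zero
    differences and uses the normal approximation with continuity
    correction beyond. All-zero differences give a flagged p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all paired differences are zero; degenerate test")
        return AssociationResult(0.0, 1.0, 0, "wilcoxon", degenerate=True)
    if n < 3:
        raise ValueError("need at least 3 non-zero differences")
    ranks = _rank(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _signed_rank_exact_p(np.round(2 * ranks), 2 * w_plus)
        return AssociationResult(w_plus, p, n, "wilcoxon-exact")
    mean_w = n * (n + 1) / 4
    # variance with tie correction
    var_w = (n * (n + 1) * (2 * n + 1) - 0.5 * _tie_term(ranks)) / 24
    z = (w_plus - mean_w - 0.5 * np.sign(w_plus - mean_w)) / math.sqrt(var_w)
    p = float(2 * stats.norm.sf(abs(z)))
    return AssociationResult(w_plus, min(p, 1.0), n, "wilcoxon-normal")


def _tie_term(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float((counts ** 3 - counts).sum())


def stratified_assoc(
    table: pd.DataFrame,
    value_a: str,
    value_b: str | None,
    stratum_col: str,
    x_col: str | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Run the paired Wilcoxon (value_a vs value_b) or Spearman
    (value_a vs x_col) within each level of ``stratum_col``.

    Strata smaller than the test's precondition are refused (reported with
    a NaN statistic and reason). Reports n per stratum alongside results.
    """
    if stratum_col not in table.columns:
        raise ValueError(f"stratum column {stratum_col!r} not present")
    rows = []
    for level, sub in table.groupby(stratum_col, sort=True):
        n = len(sub)
        try:
            if value_b is not None:
                if n < min_pairs:
                    raise ValueError(f"stratum too small (n={n})")
                res = paired_wilcoxon(sub[value_a].to_numpy(), sub[value_b].to_numpy())
            else:
                res = spearman_assoc(sub[value_a].to_numpy(), sub[x_col].to_numpy())
            rows.append({"stratum": level, "n": n, "statistic": res.statistic,
                         "p": res.p, "method": res.method, "note": ""})
        except ValueError as exc:
            logger.warning("stratum %r refused: %s", level, exc)
            rows.append({"stratum": level, "n": n, "statistic": float("nan"),
                         "p": float("nan"), "method": "refused", "note": str(exc)})
    return pd.DataFrame(rows)
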