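"""Signed weighted co-expression network analysis.

Builds a signed adjacency a_ij = ((1 + cor_ij) / 2) ** beta, transforms it
to a topological overlap matrix, detects modules by average-linkage
clustering of 1 - TOM with merging of undersized clusters, summarizes
modules by eigengenes / module membership / intramodular connectivity, and
calls hubs as the top-5 connectivity features with MM > 0.75.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class NetworkParams:
    beta: int = 12
    signed: bool = True
    min_module_size: int = 10
    cut_height_frac: float = 0.95  # fraction of the max merge height
    mm_hub_threshold: float = 0.75
    top_k_hubs: int = 5

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not (0 < self.mm_hub_threshold <= 1):
            raise ValueError("mm_hub_threshold must lie in (0, 1]")


@dataclass
class CoexpressionModel:
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    modules: pd.Series  # feature -> integer label, 0 = unassigned
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x modules
    mm: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    k_within: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    hubs: dict[int, list[str]] = field(default_factory=dict)
    params: NetworkParams = field(default_factory=NetworkParams)


def signed_adjacency(corr: pd.DataFrame | np.ndarray, beta: int) -> pd.DataFrame | np.ndarray:
    """a_ij = ((1 + cor_ij) / 2) ** beta with unit diagonal."""
    arr = np.asarray(corr, dtype=float)
    if np.nanmax(np.abs(arr)) > 1 + 1e-9:
        raise ValueError("correlation entries must lie in [-1, 1]")
    adj = ((1.0 + np.clip(arr, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    if isinstance(corr, pd.DataFrame):
        return pd.DataFrame(adj, index=corr.index, columns=corr.columns)
    return adj


def topological_overlap(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    The numerator sum excludes u in {i, j}; k is the row sum excluding the
    diagonal; the diagonal of the result is 1.
    """
    a = np.asarray(adjacency, dtype=float)
    _validate_adjacency(a)
    k = a.sum(axis=0) - np.diag(a)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    # (a0 @ a0)_ij sums a_iu a_uj over all u; the u in {i, j} terms vanish
    # because the diagonal of a0 is zero.
    shared = a0 @ a0
    numer = shared + a0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def _validate_adjacency(a: np.ndarray) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log10 p(k) ~ log10 k regression and the slope.

    R^2 is negated when the slope is positive, penalizing non-scale-free
    (increasing) degree distributions, so the returned fit lies in [-1, 1].
    """
    k = adjacency.sum(axis=0) - np.diag(adjacency)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        log_k.append(np.log10(k[mask].mean()))
        log_p.append(np.log10(mask.mean()))
    if len(log_k) < 3:
        return 0.0, 0.0
    log_k_arr = np.array(log_k)
    log_p_arr = np.array(log_p)
    slope, intercept = np.polyfit(log_k_arr, log_p_arr, 1)
    fitted = slope * log_k_arr + intercept
    ss_res = ((log_p_arr - fitted) ** 2).sum()
    ss_tot = ((log_p_arr - log_p_arr.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_betas: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    fit_cut: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest candidate beta whose scale-free fit reaches ``fit_cut``.

    Falls back (with a warning) to the argmax-fit beta when no candidate
    reaches the cut. ``expr`` is features x samples on a normalized scale.
    """
    if expr.shape[1] < 8:
        raise ValueError("need at least 8 samples for soft-threshold selection")
    if expr.shape[0] < 20:
        raise ValueError("need at least 20 features for a meaningful scale-free fit")
    corr = np.corrcoef(expr.to_numpy(dtype=float))
    rows = []
    for beta in candidate_betas:
        adj = signed_adjacency(corr, beta)
        fit, slope = scale_free_fit(adj)
        k = adj.sum(axis=0) - 1.0
        rows.append({"beta": beta, "fit": fit, "slope": slope,
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    passing = table[table["fit"] >= fit_cut]
    if len(passing):
        chosen = int(passing["beta"].iloc[0])
    else:
        chosen = int(table.loc[table["fit"].idxmax(), "beta"])
        logger.warning("no candidate beta reached fit %.2f; falling back to argmax (beta=%d)",
                       fit_cut, chosen)
    return chosen, table


def detect_modules(tom: pd.DataFrame, params: NetworkParams) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with small-cluster merging.

    The dendrogram is cut at ``cut_height_frac`` of the maximum merge
    height; clusters below ``min_module_size`` are then iteratively merged
    into the cluster with the highest mean inter-cluster TOM. Labels are
    1..K ordered by decreasing module size (no feature is left unassigned).
    """
    ids = list(tom.index)
    n = len(ids)
    tom_arr = tom.to_numpy(dtype=float)
    if n < params.min_module_size:
        logger.warning("only %d features (< min_module_size); assigning one module", n)
        return pd.Series(1, index=ids)
    diss = 1.0 - tom_arr
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    cut = params.cut_height_frac * z[:, 2].max()
    labels = fcluster(z, t=cut, criterion="distance")

    # iterative merge of undersized clusters by mean inter-cluster TOM
    while True:
        sizes = pd.Series(labels).value_counts()
        small = sizes[sizes < params.min_module_size]
        if small.empty or len(sizes) == 1:
            break
        # merge the smallest cluster first (ties: lowest label) for determinism
        lab = sorted(small.index, key=lambda l: (sizes[l], l))[0]
        members = labels == lab
        best_lab, best_sim = None, -np.inf
        for other in sorted(sizes.index):
            if other == lab:
                continue
            sim = tom_arr[np.ix_(members, labels == other)].mean()
            if sim > best_sim:
                best_sim, best_lab = sim, other
        labels[members] = best_lab

    # relabel by decreasing size; ties by first appearance for determinism
    sizes = pd.Series(labels).value_counts()
    order = sorted(sizes.index, key=lambda l: (-sizes[l], list(labels).index(l)))
    remap = {old: new for new, old in enumerate(order, start=1)}
    return pd.Series([remap[l] for l in labels], index=ids)


def module_summaries(
    expr: pd.DataFrame,
    modules: pd.Series,
    adjacency: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Eigengenes, module membership and intramodular connectivity.

    The eigengene is the first principal component of the module's
    standardized expression across samples, sign-oriented to correlate
    positively with the module mean profile. MM_i is the Pearson
    correlation of feature i with its own module's eigengene; k_within_i is
    the summed adjacency to same-module members (self excluded).
    """
    samples = list(expr.columns)
    eigengenes: dict[int, np.ndarray] = {}
    for label in sorted(modules.unique()):
        member_ids = modules.index[modules == label]
        block = expr.loc[member_ids].to_numpy(dtype=float)
        z = _standardize_rows(block)
        if z.shape[0] == 1:
            eig = z[0]
        else:
            # first right singular vector of the feature x sample block
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            eig = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        eigengenes[label] = eig
    eig_df = pd.DataFrame({lab: vec for lab, vec in eigengenes.items()}, index=samples)

    mm = pd.Series(index=modules.index, dtype=float)
    for fid in modules.index:
        eig = eigengenes[modules[fid]]
        profile = expr.loc[fid].to_numpy(dtype=float)
        if profile.std() == 0 or eig.std() == 0:
            mm[fid] = 0.0
        else:
            mm[fid] = float(np.corrcoef(profile, eig)[0, 1])

    adj = adjacency.to_numpy(dtype=float)
    ids = list(adjacency.index)
    pos = {fid: i for i, fid in enumerate(ids)}
    k_within = pd.Series(index=modules.index, dtype=float)
    for label in sorted(modules.unique()):
        member_ids = list(modules.index[modules == label])
        rows = [pos[f] for f in member_ids]
        sub = adj[np.ix_(rows, rows)]
        k_within[member_ids] = sub.sum(axis=1) - np.diag(sub)
    return eig_df, mm, k_within


def _standardize_rows(block: np.ndarray) -> np.ndarray:
    mu = block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (block - mu) / sd


def call_hubs(
    mm: pd.Series,
    k_within: pd.Series,
    modules: pd.Series,
    params: NetworkParams,
) -> dict[int, list[str]]:
    """Per module: rank by k_within descending, keep rank <= top_k with
    MM strictly greater than the threshold. Ties broken by MM, then ID."""
    hubs: dict[int, list[str]] = {}
    for label in sorted(modules.unique()):
        member_ids = list(modules.index[modules == label])
        ranked = sorted(member_ids, key=lambda f: (-k_within[f], -mm[f], f))
        top = ranked[: params.top_k_hubs]
        hubs[int(label)] = [f for f in top if mm[f] > params.mm_hub_threshold]
    return hubs


def fit_network(expr: pd.DataFrame, params: NetworkParams | None = None) -> CoexpressionModel:
    """Full pipeline: correlation -> adjacency -> TOM -> modules -> hubs."""
    params = params or NetworkParams()
    corr = pd.DataFrame(
        np.corrcoef(expr.to_numpy(dtype=float)), index=expr.index, columns=expr.index
    )
    adjacency = signed_adjacency(corr, params.beta)
    tom = topological_overlap(adjacency)
    modules = detect_modules(tom, params)
    eigengenes, mm, k_within = module_summaries(expr, modules, adjacency)
    hubs = call_hubs(mm, k_within, modules, params)
    return CoexpressionModel(
        adjacency=adjacency, tom=tom, modules=modules,
        eigengenes=eigengenes, mm=mm, k_within=k_within, hubs=hubs, params=params,
    )
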