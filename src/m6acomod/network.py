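"""Signed weighted co-methylation network, module detection and eigengenes.

Peaks whose m6A ratios covary across cell lines form co-methylation modules.
The network is a signed weighted adjacency ``a_ij = ((1 + r_ij) / 2) ** beta``
(default beta = 7) over variable peaks; the average-linkage tree of
``1 - adjacency`` is cut with a simplified dynamic hybrid procedure into
modules; each module is summarized by its eigengene (first principal
component of the standardized member profiles, the module's "m6A index");
modules with correlated eigengenes can be merged into combined modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

SOFT_POWER = 7
MIN_MODULE_SIZE = 30
MERGE_COUNT = 12
GREY = 0


def signed_adjacency(m: pd.DataFrame, beta: float = SOFT_POWER, min_shared: int = 3) -> pd.DataFrame:
    """Signed adjacency ((1 + r) / 2) ** beta over peak rows of ``m``.

    Pearson correlations use pairwise-complete observations; anti-correlated
    peaks get adjacency near 0, uncorrelated near 0.5 ** beta.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    notna = m.notna().astype(int)
    shared = notna @ notna.T
    if (shared.to_numpy() < min_shared).any():
        idx = np.argwhere(shared.to_numpy() < min_shared)
        pairs = [(m.index[i], m.index[j]) for i, j in idx[:5]]
        raise ValueError(f"peak pairs with < {min_shared} shared observations, e.g. {pairs}")
    r = np.corrcoef(m.to_numpy()) if not m.isna().any().any() else m.T.corr(method="pearson").to_numpy()
    r = np.clip(r, -1.0, 1.0)
    adj = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=m.index, columns=m.index)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap of a weighted adjacency (optional dissimilarity base)."""
    a = adj.to_numpy().copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModulePartition:
    """Peak -> module assignment; module 0 is grey (unassigned)."""

    labels: pd.Series  # peak_id -> int module id
    min_module_size: int

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {GREY})

    def members(self, module_id: int) -> pd.Index:
        return self.labels.index[self.labels == module_id]


def cut_modules(
    adj: pd.DataFrame,
    min_module_size: int = MIN_MODULE_SIZE,
    max_cut_fraction: float = 0.985,
    cohesion_factor: float = 2.0,
    attach_r: float = 0.3,
    attach_fraction: float = 0.5,
    use_tom: bool = False,
) -> ModulePartition:
    """Cut the co-methylation tree into modules (simplified dynamic hybrid).

    The average-linkage tree of ``1 - adjacency`` (or 1 - TOM) is cut at the
    largest gap in its sorted merge heights (restricted to the upper half of
    merges, capped at ``max_cut_fraction`` of the maximum height): tight
    within-module merges sit well below the joins between modules and to
    background, so the widest gap separates branches from their gluing merges.
    Branches smaller than ``min_module_size`` are dissolved, as are incoherent
    branches whose mean within-branch adjacency does not exceed
    ``cohesion_factor`` times their mean adjacency to outside peaks and an
    absolute adjacency floor of ``((1 + attach_r) / 2) ** beta``.  Dissolved
    peaks are then attached, PAM-like, to the module of highest mean adjacency
    when that exceeds both the floor and ``attach_fraction`` of the module's
    internal mean adjacency; the rest stay grey.
    """
    n = len(adj)
    peak_ids = adj.index
    if n < min_module_size:
        logger.warning("fewer peaks (%d) than min_module_size; all grey", n)
        return ModulePartition(pd.Series(GREY, index=peak_ids), min_module_size)
    sim = tom_similarity(adj) if use_tom else adj
    dist = 1.0 - sim.to_numpy()
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(np.clip(dist, 0.0, None), checks=False), method="average")
    heights = np.sort(z[:, 2])
    upper = heights[heights >= np.median(heights)]
    if upper.size >= 2:
        gaps = np.diff(upper)
        g = int(np.argmax(gaps))
        cut_h = (upper[g] + upper[g + 1]) / 2.0
    else:
        cut_h = heights[-1]
    cut_h = min(cut_h, max_cut_fraction * heights[-1])
    raw = hierarchy.fcluster(z, t=cut_h, criterion="distance")

    a = adj.to_numpy()
    # absolute adjacency floor corresponding to a modest positive correlation
    # on the same transform family as the adjacency itself
    floor = ((1.0 + attach_r) / 2.0) ** SOFT_POWER

    labels = np.zeros(n, dtype=int)
    within_means: dict[int, float] = {}
    next_id = 1
    for cid in np.unique(raw):
        members = np.flatnonzero(raw == cid)
        if members.size < min_module_size:
            continue
        block = a[np.ix_(members, members)]
        within = (block.sum() - members.size) / (members.size * (members.size - 1))
        outside = np.setdiff1d(np.arange(n), members)
        if outside.size:
            between = a[np.ix_(members, outside)].mean()
            coherent = within > cohesion_factor * between and within > floor
        else:
            coherent = within > floor
        if not coherent:
            continue
        labels[members] = next_id
        within_means[next_id] = within
        next_id += 1

    module_ids = list(range(1, next_id))
    if module_ids:
        unassigned = np.flatnonzero(labels == GREY)
        member_idx = {mid: np.flatnonzero(labels == mid) for mid in module_ids}
        for i in unassigned:
            means = np.array([a[i, member_idx[mid]].mean() for mid in module_ids])
            best = int(np.argmax(means))
            mid = module_ids[best]
            if means[best] > max(floor, attach_fraction * within_means[mid]):
                labels[i] = mid
    # relabel by size, largest first
    series = pd.Series(labels, index=peak_ids)
    sizes = series[series != GREY].value_counts()
    remap = {old: new for new, old in enumerate(sizes.index, start=1)}
    remap[GREY] = GREY
    series = series.map(remap)
    logger.info(
        "cut_modules: %d modules, %d grey of %d peaks",
        len(sizes), int((series == GREY).sum()), n,
    )
    return ModulePartition(series, min_module_size)


def module_eigengene(sub: pd.DataFrame) -> tuple[pd.Series, float]:
    """Eigengene (first PC over cell lines) of one module's peak submatrix.

    Rows are standardized (mean 0, sd 1 over observed cells; missing imputed
    at the row mean, i.e. 0 after centering); the unit-norm first right
    singular vector is returned, sign-aligned so its mean correlation with
    member profiles is non-negative; the second value is the fraction of
    variance explained.
    """
    if len(sub) < 2:
        raise ValueError("module must contain at least 2 peaks")
    x = sub.to_numpy(dtype=float)
    mean = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        logger.warning("module_eigengene: dropping %d zero-variance rows", int((~keep).sum()))
    x = (x[keep] - mean[keep]) / sd[keep]
    x = np.nan_to_num(x, nan=0.0)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    corrs = [np.corrcoef(row, eig)[0, 1] for row in x if np.std(row) > 0]
    if np.mean(corrs) < 0:
        eig = -eig
    return pd.Series(eig, index=sub.columns), var_explained


def eigengene_set(m: pd.DataFrame, partition: ModulePartition) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengenes of every non-grey module: module x cell-line frame + variance explained."""
    rows, varex = {}, {}
    for mid in partition.module_ids:
        eig, ve = module_eigengene(m.loc[partition.members(mid)])
        rows[mid] = eig
        varex[mid] = ve
    eigs = pd.DataFrame(rows).T
    eigs.index.name = "module_id"
    return eigs, pd.Series(varex, name="variance_explained")


def merge_modules(
    eigs: pd.DataFrame,
    m: pd.DataFrame,
    partition: ModulePartition,
    target_count: int | None = MERGE_COUNT,
    corr_threshold: float | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster module eigengenes (distance 1 - r) into combined modules.

    Either ``target_count`` combined modules or a correlation threshold (merge
    modules with eigengene r above it) may be given.  Returns the
    module -> combined-module mapping and the recomputed combined eigengenes
    from pooled member peaks.
    """
    if len(eigs) < 2:
        raise ValueError("need at least 2 modules to merge")
    if target_count is not None and target_count > len(eigs):
        raise ValueError("target count exceeds module count")
    if target_count is not None and target_count == len(eigs):
        mapping = pd.Series(eigs.index, index=eigs.index)
    else:
        dist = 1.0 - np.corrcoef(eigs.to_numpy())
        z = hierarchy.linkage(squareform(np.clip(dist, 0.0, None), checks=False), method="average")
        if target_count is not None:
            flat = hierarchy.fcluster(z, t=target_count, criterion="maxclust")
        else:
            flat = hierarchy.fcluster(z, t=1.0 - corr_threshold, criterion="distance")
        mapping = pd.Series(flat, index=eigs.index)
    combined = {}
    for cid in sorted(mapping.unique()):
        mods = mapping.index[mapping == cid]
        pooled = m.loc[partition.labels.index[partition.labels.isin(mods)]]
        combined[cid], _ = module_eigengene(pooled)
    comb = pd.DataFrame(combined).T
    comb.index.name = "combined_module_id"
    return mapping, comb
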