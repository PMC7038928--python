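"""Cross-sample m6A-ratio matrix assembly.

Peaks x samples ratio matrices are held as pandas DataFrames with NaN marking
missing (low input coverage) cells.  This module filters by missingness,
quantile-normalizes across samples, averages replicates into cell lines,
splits peaks into stable/variable classes by coefficient of variation, and
clusters samples on correlation distance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

MAX_MISSING_FRACTION = 0.5
CV_THRESHOLD = 0.3


def filter_missingness(m: pd.DataFrame, max_missing_fraction: float = MAX_MISSING_FRACTION) -> pd.DataFrame:
    """Drop peaks missing in more than ``max_missing_fraction`` of samples."""
    if not 0 < max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in (0, 1]")
    frac = m.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_missingness: dropped %d of %d peaks", dropped, len(m))
    out = m.loc[keep]
    if out.empty:
        raise ValueError("no peaks survive the missingness filter")
    return out


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every column shares one distribution.

    The reference is the mean of the per-column quantile functions evaluated
    on the full row grid; each column's observed values are replaced by the
    reference interpolated to that column's observed count, assigned back by
    rank (ties receive the mean of their tied reference values).  Missing
    cells stay missing.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    n = m.shape[0]
    grid = np.linspace(0.0, 1.0, n)
    qfuns = []
    for col in m.columns:
        obs = m[col].dropna().to_numpy()
        if obs.size < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        qfuns.append(np.quantile(obs, grid))
    ref = np.mean(qfuns, axis=0)
    out = m.copy()
    for col in m.columns:
        vals = m[col].to_numpy(dtype=float)
        obs_idx = np.flatnonzero(~np.isnan(vals))
        mcount = obs_idx.size
        target = np.interp(np.linspace(0.0, 1.0, mcount), grid, ref)
        order = np.argsort(vals[obs_idx], kind="mergesort")
        new = np.full(n, np.nan)
        new[obs_idx[order]] = target
        # average tied ranks so equal inputs map to equal outputs
        obs_vals = vals[obs_idx]
        uniq, inv = np.unique(obs_vals, return_inverse=True)
        if uniq.size < mcount:
            sums = np.zeros(uniq.size)
            cnts = np.zeros(uniq.size)
            np.add.at(sums, inv, new[obs_idx])
            np.add.at(cnts, inv, 1.0)
            new[obs_idx] = (sums / cnts)[inv]
        out[col] = new
    return out


def average_replicates(m: pd.DataFrame, grouping: dict[str, str]) -> pd.DataFrame:
    """Average replicate columns into cell lines (mean over observed values)."""
    unknown = [s for s in m.columns if s not in grouping]
    if unknown:
        raise ValueError(f"samples without cell-line assignment: {unknown}")
    groups = pd.Series({s: grouping[s] for s in m.columns})
    return m.T.groupby(groups).mean().T


def coefficient_of_variation(
    m: pd.DataFrame, cv_threshold: float = CV_THRESHOLD, min_obs: int = 3
) -> pd.DataFrame:
    """Per-peak CV (sample sd / mean over observed cell lines) and class.

    Class is ``variable`` iff CV strictly exceeds ``cv_threshold``, else
    ``stable``; peaks with fewer than ``min_obs`` observations or non-positive
    mean get a missing CV and no class.
    """
    mean = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    nobs = m.notna().sum(axis=1)
    cv = sd / mean
    bad = (nobs < min_obs) | (mean <= 0)
    if bad.any():
        logger.info("coefficient_of_variation: %d peaks with undefined CV", int(bad.sum()))
    cv[bad] = np.nan
    cls = pd.Series(pd.NA, index=m.index, dtype="object")
    cls[cv.notna() & (cv > cv_threshold)] = "variable"
    cls[cv.notna() & (cv <= cv_threshold)] = "stable"
    return pd.DataFrame({"cv": cv, "class": cls})


def correlation_distance(m: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """1 - pairwise-complete Pearson correlation between columns."""
    shared = m.notna().astype(int).T @ m.notna().astype(int)
    if (shared.to_numpy() < min_shared).any():
        bad = [
            (a, b)
            for a in m.columns
            for b in m.columns
            if shared.loc[a, b] < min_shared
        ]
        raise ValueError(f"sample pairs with < {min_shared} shared observations: {bad[:5]}")
    return 1.0 - m.corr(method="pearson")


def cluster_samples(
    m: pd.DataFrame,
    cv_threshold: float | None = 0.7,
    top_k_by_cv: int | None = None,
    linkage_method: str = "average",
):
    """Hierarchically cluster samples on 1 - Pearson distance.

    Features (rows) are selected either as those with CV above ``cv_threshold``
    or as the ``top_k_by_cv`` rows with the largest CVs.  Returns the scipy
    linkage matrix and the sample labels.
    """
    cv = (m.std(axis=1, ddof=1) / m.mean(axis=1)).dropna()
    if top_k_by_cv is not None:
        feats = cv.nlargest(top_k_by_cv).index
    elif cv_threshold is not None:
        feats = cv.index[cv > cv_threshold]
    else:
        feats = m.index
    if len(feats) < 2:
        raise ValueError("feature selection yields fewer than 2 features")
    dist = correlation_distance(m.loc[feats])
    z = hierarchy.linkage(squareform(np.clip(dist.to_numpy(), 0, None), checks=False), method=linkage_method)
    return z, list(m.columns)


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height):
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
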