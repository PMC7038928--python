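"""Outlier-robust screen for trans regulators of m6A.

Each candidate RNA-binding protein's expression profile across cell lines is
correlated with every module eigengene.  Pearson correlation is fragile to a
single extreme cell line, so each test reports a jackknife p-value: the
maximum of the n leave-one-cell-line-out two-sided correlation p-values.  The
significance cutoff is calibrated empirically: sample labels of the
expression matrix are permuted (default 10 rounds), the full jackknife scan
is repeated on each permutation, and the cutoff is the largest observed
p-value at which the mean number of null calls is at most ``target_fdr``
(default 0.2, the "one fifth" rule) times the number of observed calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger(__name__)

N_PERMUTATIONS = 10
TARGET_FDR = 0.2
EXPRESSION_FLOOR = 1.0


def pearson_p(r: np.ndarray, n) -> np.ndarray:
    """Two-sided p of Pearson r via the t transform; |r| = 1 maps to p = 0."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = r * r * df / (1.0 - r * r)
    p = np.where(np.abs(r) >= 1.0, 0.0, special.betainc(0.5 * df, 0.5, np.clip(df / (df + t2), 0.0, 1.0)))
    return p


def _loo_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All n leave-one-out Pearson correlations, O(n) via running sums."""
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    m = n - 1
    lsx, lsy = sx - x, sy - y
    lsxx, lsyy, lsxy = sxx - x * x, syy - y * y, sxy - x * y
    cov = lsxy - lsx * lsy / m
    vx = lsxx - lsx**2 / m
    vy = lsyy - lsy**2 / m
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(vx * vy)
    r[(vx <= 0) | (vy <= 0)] = np.nan  # zero variance in the subset
    return np.clip(r, -1.0, 1.0)


def jackknife_correlation(x, y) -> tuple[float, float]:
    """Full-data Pearson r and the jackknife p (max of leave-one-out p-values).

    A subset with zero variance contributes p = 1, so a profile whose signal
    rests on one cell line can never appear significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need paired vectors of length >= 5")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    r_loo = _loo_correlations(x, y)
    p_loo = np.where(np.isnan(r_loo), 1.0, pearson_p(np.nan_to_num(r_loo), x.size - 1))
    r_full = float(np.corrcoef(x, y)[0, 1]) if np.std(x) > 0 and np.std(y) > 0 else np.nan
    return r_full, float(p_loo.max())


def expressed_rbps(expression: pd.DataFrame, rbp_ids: list[str], floor: float = EXPRESSION_FLOOR) -> pd.DataFrame:
    """Restrict an RBP catalog to genes with mean expression above ``floor``."""
    present = [g for g in rbp_ids if g in expression.index]
    cat = expression.loc[present]
    keep = cat.mean(axis=1) > floor
    logger.info("expressed_rbps: %d of %d RBPs retained", int(keep.sum()), len(rbp_ids))
    return cat.loc[keep]


def scan(catalog: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Jackknife correlation of every RBP against every module eigengene.

    Returns one row per (rbp, module) pair with ``r_full`` and ``p_jack``, in
    deterministic (rbp, module) order.  Leave-one-out correlations for the
    whole grid are computed at once from running sums.
    """
    shared = [c for c in catalog.columns if c in eigengenes.columns]
    if len(shared) < 5:
        raise ValueError("fewer than 5 shared cell lines")
    x = catalog[shared].to_numpy(dtype=float)  # R x n
    y = eigengenes[shared].to_numpy(dtype=float)  # M x n
    n = len(shared)
    sx, sy = x.sum(axis=1), y.sum(axis=1)
    sxx, syy = (x * x).sum(axis=1), (y * y).sum(axis=1)
    sxy = x @ y.T  # R x M
    m = n - 1
    p_max = np.zeros(sxy.shape)
    for i in range(n):
        lsx = (sx - x[:, i])[:, None]
        lsy = (sy - y[:, i])[None, :]
        lvx = (sxx - x[:, i] ** 2)[:, None] - lsx**2 / m
        lvy = (syy - y[:, i] ** 2)[None, :] - lsy**2 / m
        cov = sxy - np.outer(x[:, i], y[:, i]) - lsx * lsy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cov / np.sqrt(lvx * lvy)
        r = np.clip(r, -1.0, 1.0)
        p = pearson_p(np.nan_to_num(r), m)
        p[(lvx <= 0) | (lvy <= 0)] = 1.0  # zero variance in the subset
        np.maximum(p_max, p, out=p_max)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_full = (sxy - np.outer(sx, sy) / n) / np.sqrt(
            np.outer(sxx - sx**2 / n, syy - sy**2 / n)
        )
    r_full = np.clip(r_full, -1.0, 1.0)
    ridx = np.repeat(catalog.index.to_numpy(), len(eigengenes))
    midx = np.tile(eigengenes.index.to_numpy(), len(catalog))
    return pd.DataFrame(
        {"rbp_id": ridx, "module_id": midx, "r_full": r_full.ravel(), "p_jack": p_max.ravel()}
    )


def permutation_null(
    catalog: pd.DataFrame,
    eigengenes: pd.DataFrame,
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
) -> list[np.ndarray]:
    """Null jackknife p-values from sample-relabeling permutations.

    Each round applies one shared random permutation of cell-line labels to
    the expression matrix (eigengenes fixed), preserving RBP-RBP dependence,
    and repeats the full scan.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    shared = [c for c in catalog.columns if c in eigengenes.columns]
    out = []
    for _ in range(n_perm):
        perm = rng.permutation(len(shared))
        shuffled = catalog[shared].copy()
        shuffled.columns = [shared[k] for k in perm]
        res = scan(shuffled[shared], eigengenes)
        out.append(res["p_jack"].to_numpy())
    return out


@dataclass
class CutoffResult:
    p_cutoff: float
    observed_significant: int
    mean_null_significant: float
    achieved_ratio: float


def fdr_cutoff(observed_p: np.ndarray, null_p: list[np.ndarray], target_fdr: float = TARGET_FDR) -> CutoffResult:
    """Largest p cutoff at which mean null calls / observed calls <= target_fdr.

    Candidate cutoffs are the distinct observed p-values; significance is
    inclusive (p <= cutoff).  When no cutoff qualifies, nothing is called.
    """
    if not 0 < target_fdr <= 1:
        raise ValueError("target_fdr must be in (0, 1]")
    observed_p = np.asarray(observed_p, dtype=float)
    if observed_p.size == 0:
        raise ValueError("no observed p-values")
    candidates = np.unique(observed_p)
    null_sorted = [np.sort(p) for p in null_p]
    obs_sorted = np.sort(observed_p)
    best = None
    for c in candidates:
        n_obs = int(np.searchsorted(obs_sorted, c, side="right"))
        mean_null = float(np.mean([np.searchsorted(p, c, side="right") for p in null_sorted]))
        ratio = mean_null / n_obs
        if ratio <= target_fdr:
            best = CutoffResult(float(c), n_obs, mean_null, ratio)
    if best is None:
        logger.warning("fdr_cutoff: no cutoff achieves target FDR %.2f; zero significant", target_fdr)
        return CutoffResult(-np.inf, 0, 0.0, 0.0)
    return best


def screen(
    catalog: pd.DataFrame,
    eigengenes: pd.DataFrame,
    n_perm: int = N_PERMUTATIONS,
    target_fdr: float = TARGET_FDR,
    seed: int = 0,
) -> tuple[pd.DataFrame, CutoffResult]:
    """Full regulator screen: scan, permutation calibration, significance flags."""
    records = scan(catalog, eigengenes)
    null_p = permutation_null(catalog, eigengenes, n_perm=n_perm, seed=seed)
    cutoff = fdr_cutoff(records["p_jack"].to_numpy(), null_p, target_fdr=target_fdr)
    records["significant"] = records["p_jack"] <= cutoff.p_cutoff
    logger.info(
        "screen: %d significant pairs at p <= %.3g (mean null %.1f, ratio %.3f)",
        cutoff.observed_significant, cutoff.p_cutoff, cutoff.mean_null_significant, cutoff.achieved_ratio,
    )
    return records, cutoff
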