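"""Knockdown validation of predicted m6A regulators.

Depleting a genuine regulator should shift the m6A ratios of the peaks it
controls — those in its associated module(s) and those near its binding
sites — more than the remaining peaks.  Peaks are filtered for reliable
quantification (input window RPKM > 5 in all samples, control ratio > 0.1 in
both control replicates), per-peak log2 fold changes of mean knockdown vs
mean control ratio are computed, and strata (in-module, CLIP-bound) are
compared with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

MIN_INPUT_RPKM = 5.0
MIN_CONTROL_RATIO = 0.1


def fold_changes(
    ratios: pd.DataFrame,
    input_rpkm: pd.DataFrame,
    control_samples: list[str],
    knockdown_samples: list[str],
    min_input_rpkm: float = MIN_INPUT_RPKM,
    min_ctrl_ratio: float = MIN_CONTROL_RATIO,
) -> pd.DataFrame:
    """Per-peak log2 fold change of m6A ratio upon knockdown.

    A peak passes filters only if its input window RPKM exceeds
    ``min_input_rpkm`` in every sample (both conditions) and its m6A ratio
    exceeds ``min_ctrl_ratio`` in every control replicate; small denominators
    otherwise make fold changes meaningless.  Replicates are averaged before
    the ratio of means is taken.
    """
    all_samples = list(control_samples) + list(knockdown_samples)
    depth_ok = (input_rpkm[all_samples] > min_input_rpkm).all(axis=1)
    ctrl_ok = (ratios[control_samples] > min_ctrl_ratio).all(axis=1) & ratios[control_samples].notna().all(axis=1)
    passed = depth_ok & ctrl_ok & ratios[all_samples].notna().all(axis=1)
    mean_ctrl = ratios[control_samples].mean(axis=1)
    mean_kd = ratios[knockdown_samples].mean(axis=1)
    log2fc = pd.Series(np.nan, index=ratios.index)
    log2fc[passed] = np.log2(mean_kd[passed] / mean_ctrl[passed])
    logger.info("fold_changes: %d of %d peaks pass filters", int(passed.sum()), len(ratios))
    return pd.DataFrame({"log2fc": log2fc, "passed_filters": passed})


def stratified_shift_test(
    records: pd.DataFrame,
    stratum_flags: pd.Series,
    min_stratum: int = 5,
) -> dict:
    """Two-sided rank-sum comparison of log2fc between a stratum and its complement.

    ``stratum_flags`` marks peaks in the stratum of interest (e.g. members of
    the regulator's pooled modules, or CLIP-bound peaks).  Returns the p-value,
    group medians and ECDF coordinates for plotting cumulative fractions.
    """
    ok = records["passed_filters"]
    flags = stratum_flags.reindex(records.index).fillna(False).astype(bool)
    grp = records.loc[ok & flags, "log2fc"].to_numpy()
    rest = records.loc[ok & ~flags, "log2fc"].to_numpy()
    if grp.size == 0 or rest.size == 0:
        raise ValueError("empty stratum among filtered peaks")
    if min(grp.size, rest.size) < min_stratum:
        logger.warning("stratified_shift_test: stratum of size %d; low power", min(grp.size, rest.size))
    p = float(mannwhitneyu(grp, rest, alternative="two-sided").pvalue)

    def ecdf(v):
        s = np.sort(v)
        return s, np.arange(1, s.size + 1) / s.size

    gx, gy = ecdf(grp)
    rx, ry = ecdf(rest)
    return {
        "p": p,
        "n_stratum": int(grp.size),
        "n_rest": int(rest.size),
        "median_stratum": float(np.median(grp)),
        "median_rest": float(np.median(rest)),
        "ecdf_stratum": (gx, gy),
        "ecdf_rest": (rx, ry),
    }
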