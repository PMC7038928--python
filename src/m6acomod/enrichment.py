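"""CLIP-seq / motif enrichment of RBP binding in co-methylation modules.

A regulator predicted from expression alone is corroborated when its binding
evidence concentrates in the predicted module: the fraction of the module's
m6A peaks overlapping the RBP's CLIP peaks (>= 1 bp) or containing its IUPAC
motif is compared with all other modules (background) by a 2x2 chi-square
test without continuity correction, adjusted by Benjamini-Hochberg across all
tests.  Correlation and positive enrichment in the same module promote an RBP
to high confidence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

Q_THRESHOLD = 0.05

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}

DRACH = "DRACH"


@dataclass
class Motif:
    rbp_id: str
    consensus: str

    def __post_init__(self):
        cons = self.consensus.upper().replace("U", "T")
        bad = set(cons) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in motif {self.consensus!r}: {sorted(bad)}")
        self.consensus = cons

    def regex(self) -> re.Pattern:
        return re.compile("".join(IUPAC[c] for c in self.consensus))


def overlap_flags(
    peaks: pd.DataFrame,
    clip: pd.DataFrame,
    min_overlap: int = 1,
    stranded: bool = True,
) -> pd.Series:
    """True for each peak sharing >= ``min_overlap`` bp with any CLIP interval.

    ``peaks`` needs chrom/start/end/strand columns (0-based half-open);
    ``clip`` likewise.  Strand-aware by default.
    """
    if (clip["start"] >= clip["end"]).any():
        bad = np.flatnonzero((clip["start"] >= clip["end"]).to_numpy())[0]
        raise ValueError(f"malformed CLIP interval at row {bad}: start >= end")
    trees: dict = {}
    for _, row in clip.iterrows():
        key = (row["chrom"], row["strand"]) if stranded else row["chrom"]
        trees.setdefault(key, IntervalTree()).addi(int(row["start"]), int(row["end"]))
    flags = []
    for _, p in peaks.iterrows():
        key = (p["chrom"], p["strand"]) if stranded else p["chrom"]
        tree = trees.get(key)
        hit = False
        if tree is not None:
            for iv in tree.overlap(int(p["start"]), int(p["end"])):
                if min(iv.end, p["end"]) - max(iv.begin, p["start"]) >= min_overlap:
                    hit = True
                    break
        flags.append(hit)
    return pd.Series(flags, index=peaks.index)


def motif_flags(sequences: pd.Series, motif: Motif) -> pd.Series:
    """True for each peak sequence containing the IUPAC consensus (given strand)."""
    pat = motif.regex()
    return sequences.str.upper().str.replace("U", "T").map(lambda s: pat.search(s) is not None)


def chi_square_enrichment(module_flags, background_flags) -> tuple[float, float, np.ndarray, bool]:
    """Pearson chi-square (df=1, no continuity correction) on the 2x2 table
    (module vs background) x (flagged vs not).

    Returns (chi2, p, table, enriched) where ``enriched`` is True when the
    module's flagged fraction exceeds the background's.  Tables with an
    expected cell below 1 are unreliable and report p = 1.
    """
    mf = np.asarray(module_flags, dtype=bool)
    bf = np.asarray(background_flags, dtype=bool)
    if mf.size == 0 or bf.size == 0:
        raise ValueError("both groups must be non-empty")
    table = np.array([[mf.sum(), (~mf).sum()], [bf.sum(), (~bf).sum()]], dtype=float)
    enriched = (table[0, 0] / mf.size) > (table[1, 0] / bf.size)
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    expected = np.outer(rows, cols) / table.sum()
    if (expected < 1).any() or (cols == 0).any():
        logger.warning("chi_square_enrichment: expected count < 1; test unreliable, p = 1")
        return 0.0, 1.0, table, enriched
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return float(chi2), float(p), table, enriched


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrichment_scan(
    peaks: pd.DataFrame,
    partition_labels: pd.Series,
    clip_sets: dict[str, pd.DataFrame] | None = None,
    motifs: dict[str, Motif] | None = None,
    sequences: pd.Series | None = None,
) -> pd.DataFrame:
    """Chi-square enrichment of every RBP's CLIP peaks / motif in every module.

    Background for a module is the peaks of all other modules (grey excluded).
    q-values are BH-adjusted across all tests jointly.
    """
    module_ids = sorted(set(partition_labels) - {0})
    in_module = {mid: partition_labels.index[partition_labels == mid] for mid in module_ids}
    assigned = partition_labels.index[partition_labels != 0]
    flag_sets: list[tuple[str, str, pd.Series]] = []
    for rbp, clip in (clip_sets or {}).items():
        flag_sets.append((rbp, "clip", overlap_flags(peaks.loc[assigned], clip)))
    if motifs and sequences is not None:
        for rbp, motif in motifs.items():
            flag_sets.append((rbp, "motif", motif_flags(sequences.loc[assigned], motif)))
    rows = []
    for rbp, evidence, flags in flag_sets:
        for mid in module_ids:
            members = in_module[mid]
            bg = assigned.difference(members)
            chi2, p, table, enriched = chi_square_enrichment(flags.loc[members], flags.loc[bg])
            rows.append(
                {
                    "rbp_id": rbp, "module_id": mid, "evidence": evidence,
                    "module_hit": int(table[0, 0]), "module_miss": int(table[0, 1]),
                    "background_hit": int(table[1, 0]), "background_miss": int(table[1, 1]),
                    "chi2": chi2, "p": p, "enriched": enriched,
                }
            )
    res = pd.DataFrame(
        rows,
        columns=[
            "rbp_id", "module_id", "evidence", "module_hit", "module_miss",
            "background_hit", "background_miss", "chi2", "p", "enriched",
        ],
    )
    res["q"] = bh_fdr(res["p"].to_numpy()) if len(res) else []
    return res


def integrate_calls(
    correlations: pd.DataFrame,
    enrichments: pd.DataFrame,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Combine the correlation screen with binding enrichment into tiers.

    low_confidence: any significant correlation.  high_confidence: significant
    correlation and positive CLIP or motif enrichment (q < threshold) in the
    SAME module.  RBPs with no CLIP/motif evidence at all are flagged
    unevaluable and stay low confidence.
    """
    sig = correlations[correlations["significant"]]
    evaluable = set(enrichments["rbp_id"]) if len(enrichments) else set()
    good = (
        enrichments[(enrichments["q"] < q_threshold) & enrichments["enriched"]]
        if len(enrichments)
        else enrichments
    )
    good_pairs = set(zip(good["rbp_id"], good["module_id"])) if len(good) else set()
    rows = []
    for rbp, grp in sig.groupby("rbp_id", sort=True):
        mods = sorted(grp["module_id"])
        hc_mods = [m for m in mods if (rbp, m) in good_pairs]
        rows.append(
            {
                "rbp_id": rbp,
                "module_ids": ",".join(map(str, mods)),
                "tier": "high_confidence" if hc_mods else "low_confidence",
                "enriched_modules": ",".join(map(str, hc_mods)),
                "unevaluable": rbp not in evaluable,
            }
        )
    return pd.DataFrame(rows, columns=["rbp_id", "module_ids", "tier", "enriched_modules", "unevaluable"])


def motif_proximity_profile(
    sequences: pd.Series,
    rbp_motif: Motif,
    anchor_motif: Motif | None = None,
    max_offset: int = 200,
) -> np.ndarray:
    """Histogram of distances between nearest RBP-motif and anchor-motif centers.

    The anchor defaults to DRACH (the m6A consensus).  For every sequence with
    both motifs, the absolute center-to-center distance of each RBP match to
    its nearest anchor match is recorded; the histogram covers 0..max_offset.
    """
    anchor = anchor_motif or Motif("anchor", DRACH)
    pat_r, pat_a = rbp_motif.regex(), anchor.regex()
    half_r = len(rbp_motif.consensus) / 2.0
    half_a = len(anchor.consensus) / 2.0
    hist = np.zeros(max_offset + 1, dtype=int)
    for seq in sequences.str.upper().str.replace("U", "T"):
        anchors = [m.start() + half_a for m in re.finditer(f"(?=({pat_a.pattern}))", seq)]
        if not anchors:
            continue
        anchors = np.asarray(anchors)
        for m in re.finditer(f"(?=({pat_r.pattern}))", seq):
            d = int(round(np.abs(anchors - (m.start() + half_r)).min()))
            if d <= max_offset:
                hist[d] += 1
    return hist
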