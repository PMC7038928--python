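"""Window-based m6A peak calling and quantification.

m6A-seq produces paired IP and input libraries; methylation is inferred from
local IP enrichment over input.  Genes are tiled with sliding windows (100 bp,
50 bp step by default) over their spliced exonic sequence, windows are scored
with the pseudocounted fold enrichment ``winscore = (RPKM_IP + 1) /
(RPKM_input + 1)``, windows scoring strictly above a threshold are called as
peaks per sample, calls are unioned across samples, merged into contiguous
peaks (split at five windows / 300 bp), and quantified per sample with the
pseudocount-free ratio ``RPKM_IP / RPKM_input`` (missing when input coverage
is low), taking the maximum ratio across a merged peak's windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 100
WINDOW_STEP = 50
WINSCORE_THRESHOLD = 2.0
MAX_PEAK_WINDOWS = 5
MIN_INPUT_RPKM = 5.0


@dataclass
class TranscriptModel:
    """Exon structure and mRNA region lengths of one (representative) transcript."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, sorted by start
    utr5_len: int
    cds_len: int
    utr3_len: int

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class WindowCountTable:
    """Per-window IP/input read counts for a set of samples.

    ``counts_ip`` and ``counts_input`` are windows x samples frames sharing the
    index of ``windows``; ``lib_ip`` / ``lib_input`` hold total mapped reads of
    each sample's IP and input library.
    """

    windows: pd.DataFrame
    counts_ip: pd.DataFrame
    counts_input: pd.DataFrame
    lib_ip: pd.Series
    lib_input: pd.Series

    @property
    def samples(self) -> list[str]:
        return list(self.counts_ip.columns)

    def validate(self) -> None:
        if not self.counts_ip.index.equals(self.windows.index):
            raise ValueError("counts_ip index does not match window grid")
        if not self.counts_input.index.equals(self.windows.index):
            raise ValueError("counts_input index does not match window grid")
        missing = [s for s in self.counts_ip.columns if s not in self.counts_input.columns]
        if missing or list(self.counts_ip.columns) != list(self.counts_input.columns):
            raise ValueError(f"samples lacking a paired IP/input library: {missing or 'column order mismatch'}")
        if (self.counts_ip.to_numpy() < 0).any() or (self.counts_input.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        for lib in (self.lib_ip, self.lib_input):
            if (lib <= 0).any():
                raise ValueError("library sizes must be positive")


def _spliced_to_genomic(exons: list[tuple[int, int]], strand: str, sstart: int, send: int) -> list[tuple[int, int]]:
    """Project a spliced (transcript) interval back to genomic blocks.

    Exons are walked 5'->3': ascending genomic order on '+', descending on '-'.
    """
    ordered = sorted(exons) if strand == "+" else sorted(exons, reverse=True)
    blocks: list[tuple[int, int]] = []
    off = 0
    for gs, ge in ordered:
        ln = ge - gs
        lo, hi = max(sstart - off, 0), min(send - off, ln)
        if lo < hi:
            if strand == "+":
                blocks.append((gs + lo, gs + hi))
            else:
                blocks.append((ge - hi, ge - lo))
        off += ln
    return sorted(blocks)


def make_windows(
    exon_regions: dict[str, tuple[str, str, list[tuple[int, int]]]],
    window_length: int = WINDOW_LENGTH,
    step: int = WINDOW_STEP,
) -> pd.DataFrame:
    """Tile each gene's spliced exonic sequence with sliding windows.

    Parameters
    ----------
    exon_regions
        gene_id -> (chrom, strand, non-overlapping exon intervals, genomic
        0-based half-open).
    window_length, step
        Window size and stride in spliced coordinates; windows cross exon
        junctions.  A terminal window shorter than ``window_length`` is kept
        and its true length is used downstream in RPKM.

    Returns
    -------
    DataFrame indexed by window_id (``gene:ordinal``) with spliced
    (sstart/send) and projected genomic (gstart/gend, span of blocks)
    coordinates.
    """
    if not (window_length > step > 0):
        raise ValueError("require window_length > step > 0")
    rows = []
    for gene_id, (chrom, strand, exons) in exon_regions.items():
        if not exons:
            logger.warning("gene %s has no exons; skipped", gene_id)
            continue
        total = sum(e - s for s, e in exons)
        if total > window_length:
            n_win = int(np.ceil((total - window_length) / step)) + 1
        else:
            n_win = 1
        for widx in range(n_win):
            sstart = widx * step
            send = min(sstart + window_length, total)
            blocks = _spliced_to_genomic(exons, strand, sstart, send)
            rows.append(
                {
                    "window_id": f"{gene_id}:{widx}",
                    "gene_id": gene_id,
                    "widx": widx,
                    "sstart": sstart,
                    "send": send,
                    "length": send - sstart,
                    "chrom": chrom,
                    "strand": strand,
                    "gstart": blocks[0][0],
                    "gend": blocks[-1][1],
                }
            )
    df = pd.DataFrame(rows)
    return df.set_index("window_id")


def rpkm(count, library_size, length):
    """Reads per kilobase per million mapped reads: count * 1e9 / (library_size * length)."""
    return np.asarray(count, dtype=float) * 1e9 / (np.asarray(library_size, dtype=float) * np.asarray(length, dtype=float))


def winscore(ip_rpkm, input_rpkm):
    """Pseudocounted IP/input fold enrichment, (RPKM_IP + 1) / (RPKM_input + 1).

    The +1 penalizes windows with low coverage whose raw ratio is unstable.
    """
    return (np.asarray(ip_rpkm, dtype=float) + 1.0) / (np.asarray(input_rpkm, dtype=float) + 1.0)


def window_rpkms(table: WindowCountTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window IP and input RPKM frames (windows x samples)."""
    length = table.windows["length"].to_numpy()[:, None]
    ip = table.counts_ip.to_numpy(dtype=float) * 1e9 / (table.lib_ip[table.samples].to_numpy()[None, :] * length)
    inp = table.counts_input.to_numpy(dtype=float) * 1e9 / (table.lib_input[table.samples].to_numpy()[None, :] * length)
    idx, cols = table.windows.index, table.samples
    return pd.DataFrame(ip, index=idx, columns=cols), pd.DataFrame(inp, index=idx, columns=cols)


def call_peaks(table: WindowCountTable, threshold: float = WINSCORE_THRESHOLD) -> pd.DataFrame:
    """Call per-sample m6A peak windows: winscore strictly greater than threshold."""
    table.validate()
    ip, inp = window_rpkms(table)
    scores = winscore(ip.to_numpy(), inp.to_numpy())
    return pd.DataFrame(scores > threshold, index=table.windows.index, columns=table.samples)


def union_merge_split(
    windows: pd.DataFrame,
    called: pd.DataFrame,
    max_windows: int = MAX_PEAK_WINDOWS,
) -> pd.DataFrame:
    """Union window calls across samples, merge contiguous runs, split long runs.

    Windows called in any sample are unioned; runs of consecutive windows
    (adjacent indices on the shared grid, hence overlapping spans) within one
    gene are merged; runs longer than ``max_windows`` are split 5'->3' into
    chunks of at most ``max_windows`` windows, remainder last.  Peak ids are
    deterministic (``gene_id.ordinal``).
    """
    if not called.index.equals(windows.index):
        raise ValueError("calls come from a different window grid")
    any_called = called.to_numpy().any(axis=1)
    win = windows.loc[any_called]
    rows = []
    for gene_id, sub in win.groupby("gene_id", sort=True):
        sub = sub.sort_values("widx")
        widx = sub["widx"].to_numpy()
        run_breaks = np.flatnonzero(np.diff(widx) != 1) + 1
        ordinal = 1
        for run in np.split(np.arange(len(widx)), run_breaks):
            for lo in range(0, len(run), max_windows):
                chunk = sub.iloc[run[lo : lo + max_windows]]
                rows.append(
                    {
                        "peak_id": f"{gene_id}.{ordinal}",
                        "gene_id": gene_id,
                        "chrom": chunk["chrom"].iat[0],
                        "strand": chunk["strand"].iat[0],
                        "start": int(chunk["gstart"].min()),
                        "end": int(chunk["gend"].max()),
                        "sstart": int(chunk["sstart"].min()),
                        "send": int(chunk["send"].max()),
                        "widx_first": int(chunk["widx"].iat[0]),
                        "widx_last": int(chunk["widx"].iat[-1]),
                        "member_windows": ",".join(chunk.index),
                    }
                )
                ordinal += 1
    cols = [
        "peak_id", "gene_id", "chrom", "strand", "start", "end",
        "sstart", "send", "widx_first", "widx_last", "member_windows",
    ]
    return pd.DataFrame(rows, columns=cols).set_index("peak_id")


def peak_ratios(
    peaks: pd.DataFrame,
    table: WindowCountTable,
    min_input_rpkm: float = MIN_INPUT_RPKM,
) -> pd.DataFrame:
    """Per-sample m6A ratio of each merged peak.

    Window ratio = RPKM_IP / RPKM_input with no pseudocount; windows with
    input RPKM below ``min_input_rpkm`` are missing; the peak ratio is the
    maximum over its windows' non-missing ratios (robust to peak-center shifts
    between libraries), missing if every window is missing.
    """
    ip, inp = window_rpkms(table)
    ip_a, inp_a = ip.to_numpy(), inp.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(inp_a >= min_input_rpkm, ip_a / inp_a, np.nan)
    ratio_df = pd.DataFrame(ratio, index=table.windows.index, columns=table.samples)
    out = np.full((len(peaks), len(table.samples)), np.nan)
    for i, members in enumerate(peaks["member_windows"]):
        sub = ratio_df.loc[members.split(",")]
        out[i] = sub.max(axis=0, skipna=True).to_numpy()
    return pd.DataFrame(out, index=peaks.index, columns=table.samples)


def metagene_profile(
    peaks: pd.DataFrame,
    models: dict[str, TranscriptModel],
    bins_per_region: int = 10,
    normalize: str = "region-length",
) -> pd.DataFrame:
    """Metagene density of peak centers over 5'UTR / CDS / 3'UTR bins.

    Each peak's center (spliced coordinates) is assigned proportionally to one
    of ``3 * bins_per_region`` bins; region boundaries are half-open, so the
    last CDS nucleotide stays in the CDS.  With ``normalize='region-length'``
    per-bin peak fractions are divided by the mean region-length fraction per
    bin across transcripts (the standard normalized metagene); ``'none'``
    returns raw fractions.
    """
    counts = np.zeros(3 * bins_per_region)
    skipped = 0
    for peak_id, row in peaks.iterrows():
        model = models.get(row["gene_id"])
        if model is None:
            skipped += 1
            continue
        center = (row["sstart"] + row["send"]) / 2.0
        bounds = [model.utr5_len, model.cds_len, model.utr3_len]
        offsets = np.concatenate([[0], np.cumsum(bounds)])
        if center >= offsets[-1]:
            logger.warning("peak %s center outside transcript %s; skipped", peak_id, row["gene_id"])
            skipped += 1
            continue
        region = int(np.searchsorted(offsets[1:], center, side="right"))
        rlen = bounds[region]
        if rlen == 0:
            skipped += 1
            continue
        b = min(int((center - offsets[region]) / rlen * bins_per_region), bins_per_region - 1)
        counts[region * bins_per_region + b] += 1
    if skipped:
        logger.info("metagene: %d peaks skipped (no model / outside transcript)", skipped)
    total = counts.sum()
    frac = counts / total if total else counts
    if normalize == "region-length":
        lens = np.array([[m.utr5_len, m.cds_len, m.utr3_len] for m in models.values()], dtype=float)
        region_frac = (lens / lens.sum(axis=1, keepdims=True)).mean(axis=0)
        dens = frac / np.repeat(region_frac / bins_per_region, bins_per_region)
    elif normalize == "none":
        dens = frac
    else:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    region = np.repeat(["5'UTR", "CDS", "3'UTR"], bins_per_region)
    return pd.DataFrame({"region": region, "bin": np.tile(np.arange(bins_per_region), 3), "density": dens})
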