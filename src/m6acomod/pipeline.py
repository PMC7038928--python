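"""End-to-end orchestration: counts -> peaks -> matrix -> network -> regulators.

``PipelineConfig`` carries every stage parameter with its standard default
(window 100/step 50, winscore > 2, max 5 windows per peak, input RPKM >= 5,
half-missing filter, CV 0.3 split, soft power 7, module merge target,
10 permutations at target FDR 0.2, enrichment q < 0.05).  ``run_pipeline``
executes the stages in order on in-memory inputs and returns every
intermediate; ``run_to_directory`` additionally writes each stage's output as
TSV/BED/FASTA so stages can be inspected or rerun.  One global seed fans out
to per-stage seeds, making reruns byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from . import matrix as mmat
from . import network as mnet
from . import peaks as mpk
from . import regulators as mreg
from .enrichment import Motif, enrichment_scan, integrate_calls
from .simulate import SyntheticDataset, transcript_sequence

logger = logging.getLogger(__name__)

_CONFIG_FIELDS = dict(
    window_length=100,
    step=50,
    winscore_threshold=2.0,
    max_windows=5,
    min_input_rpkm=5.0,
    max_missing_fraction=0.5,
    cv_threshold=0.3,
    beta=7,
    min_module_size=30,
    merge_count=12,
    n_perm=10,
    target_fdr=0.2,
    q_threshold=0.05,
    expression_floor=1.0,
    seed=0,
)


@dataclass
class PipelineConfig:
    window_length: int = 100
    step: int = 50
    winscore_threshold: float = 2.0
    max_windows: int = 5
    min_input_rpkm: float = 5.0
    max_missing_fraction: float = 0.5
    cv_threshold: float = 0.3
    beta: float = 7
    min_module_size: int = 30
    merge_count: int | None = 12
    n_perm: int = 10
    target_fdr: float = 0.2
    q_threshold: float = 0.05
    expression_floor: float = 1.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("window_length", "step", "max_windows", "min_module_size", "n_perm"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"config {name} must be a positive integer, got {v!r}")
        for name in ("winscore_threshold", "min_input_rpkm", "cv_threshold", "beta"):
            v = getattr(self, name)
            if not isinstance(v, (int, float, np.floating)) or isinstance(v, bool):
                raise ValueError(f"config {name} must be numeric, got {v!r}")
        if not self.window_length > self.step:
            raise ValueError("window_length must exceed step")
        if not 0 < self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in (0, 1]")
        if not 0 < self.target_fdr <= 1:
            raise ValueError("target_fdr must be in (0, 1]")

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class PipelineResult:
    config: PipelineConfig
    called: pd.DataFrame
    peaks: pd.DataFrame
    ratios: pd.DataFrame
    normalized: pd.DataFrame
    cell_line_matrix: pd.DataFrame
    variability: pd.DataFrame
    partition: "mnet.ModulePartition"
    eigengenes: pd.DataFrame
    variance_explained: pd.Series
    merge_map: pd.Series | None
    records: pd.DataFrame
    cutoff: "mreg.CutoffResult"
    enrichments: pd.DataFrame
    calls: pd.DataFrame
    log: dict = field(default_factory=dict)


def run_pipeline(
    table: mpk.WindowCountTable,
    grouping: dict[str, str],
    expression: pd.DataFrame,
    rbp_ids: list[str] | None = None,
    clip_sets: dict[str, pd.DataFrame] | None = None,
    motifs: dict[str, Motif] | None = None,
    sequences: pd.Series | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the discovery pipeline on a window-count table.

    ``expression`` is an RBP x sample (or cell line) TPM matrix; ``sequences``
    maps peak gene ids to spliced transcript sequences (peak subsequences are
    extracted internally) or may be omitted with ``motifs`` absent.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    log: dict = {}

    called = mpk.call_peaks(table, threshold=cfg.winscore_threshold)
    peaks = mpk.union_merge_split(table.windows, called, max_windows=cfg.max_windows)
    ratios = mpk.peak_ratios(peaks, table, min_input_rpkm=cfg.min_input_rpkm)
    log["n_called_windows"] = int(called.to_numpy().any(axis=1).sum())
    log["n_merged_peaks"] = len(peaks)

    filtered = mmat.filter_missingness(ratios, cfg.max_missing_fraction)
    log["n_peaks_after_missingness"] = len(filtered)
    normalized = mmat.quantile_normalize(filtered)
    cell = mmat.average_replicates(normalized, grouping)
    variability = mmat.coefficient_of_variation(cell, cv_threshold=cfg.cv_threshold)
    variable = variability.index[variability["class"] == "variable"]
    log["n_variable"] = len(variable)
    log["n_stable"] = int((variability["class"] == "stable").sum())

    var_mat = cell.loc[variable]
    adj = mnet.signed_adjacency(var_mat, beta=cfg.beta)
    partition = mnet.cut_modules(adj, min_module_size=cfg.min_module_size)
    eigengenes, varex = mnet.eigengene_set(var_mat, partition)
    log["n_modules"] = len(partition.module_ids)
    log["module_sizes"] = {int(m): int((partition.labels == m).sum()) for m in partition.module_ids}

    merge_map = None
    if cfg.merge_count is not None and len(eigengenes) > cfg.merge_count:
        merge_map, _ = mnet.merge_modules(eigengenes, var_mat, partition, target_count=cfg.merge_count)

    # expression columns may be samples: average to cell lines if needed
    expr = expression
    if set(expr.columns) == set(grouping):
        expr = mmat.average_replicates(expr, grouping)
    if rbp_ids is not None:
        catalog = mreg.expressed_rbps(expr, rbp_ids, floor=cfg.expression_floor)
    else:
        catalog = expr[expr.mean(axis=1) > cfg.expression_floor]
    records, cutoff = mreg.screen(
        catalog, eigengenes, n_perm=cfg.n_perm, target_fdr=cfg.target_fdr, seed=cfg.stage_seed("scan")
    )
    log["n_significant_pairs"] = int(records["significant"].sum())
    log["p_cutoff"] = cutoff.p_cutoff

    peak_seqs = None
    if sequences is not None:
        peak_seqs = peak_sequences(peaks, sequences)
    enrichments = enrichment_scan(
        peaks, partition.labels, clip_sets=clip_sets, motifs=motifs, sequences=peak_seqs
    )
    calls = integrate_calls(records, enrichments, q_threshold=cfg.q_threshold)
    log["n_low_confidence"] = int((calls["tier"] == "low_confidence").sum()) if len(calls) else 0
    log["n_high_confidence"] = int((calls["tier"] == "high_confidence").sum()) if len(calls) else 0

    return PipelineResult(
        config=cfg, called=called, peaks=peaks, ratios=ratios, normalized=normalized,
        cell_line_matrix=cell, variability=variability, partition=partition,
        eigengenes=eigengenes, variance_explained=varex, merge_map=merge_map,
        records=records, cutoff=cutoff, enrichments=enrichments, calls=calls, log=log,
    )


def peak_sequences(peaks: pd.DataFrame, transcript_seqs: pd.Series | dict) -> pd.Series:
    """Spliced sequence of each merged peak from its gene's transcript sequence."""
    seqs = dict(transcript_seqs)
    out = {}
    for pid, row in peaks.iterrows():
        ts = seqs.get(row["gene_id"])
        out[pid] = "" if ts is None else ts[int(row["sstart"]) : int(row["send"])]
    return pd.Series(out)


def dataset_sequences(ds: SyntheticDataset) -> pd.Series:
    """Transcript sequences of a synthetic dataset, keyed by gene id."""
    return pd.Series({g: transcript_sequence(m, ds.genome) for g, m in ds.models.items()})


def run_on_dataset(ds: SyntheticDataset, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full pipeline on a synthetic dataset's inputs."""
    return run_pipeline(
        ds.table,
        ds.grouping,
        ds.expression,
        clip_sets=ds.clip_sets,
        motifs=ds.motifs,
        sequences=dataset_sequences(ds),
        config=config,
    )


# ---------------------------------------------------------------------------
# evaluation against planted truth


def map_peaks_to_truth(peaks: pd.DataFrame, planted: pd.DataFrame) -> pd.Series:
    """Planted peak label of each merged peak (spliced overlap within gene), or ''."""
    out = {}
    by_gene = {g: sub for g, sub in planted.groupby("gene_id")}
    for pid, row in peaks.iterrows():
        label = ""
        sub = by_gene.get(row["gene_id"])
        if sub is not None:
            ov = np.minimum(sub["send"], row["send"]) - np.maximum(sub["sstart"], row["sstart"])
            if (ov > 0).any():
                label = sub.index[int(np.argmax(ov.to_numpy()))]
        out[pid] = label
    return pd.Series(out)


def window_call_metrics(called: pd.DataFrame, window_truth: pd.DataFrame) -> tuple[float, float]:
    """Precision and recall of union window calls against planted windows."""
    called_any = called.to_numpy().any(axis=1)
    truth = (window_truth["overlap_frac"] > 0).to_numpy()
    tp = int((called_any & truth).sum())
    precision = tp / max(int(called_any.sum()), 1)
    recall = tp / max(int(truth.sum()), 1)
    return precision, recall


def regulator_metrics(result: PipelineResult, ds: SyntheticDataset) -> dict:
    """Sensitivity and false calls of the high-confidence regulator list."""
    true_rbps = set(ds.rbp_truth.index[ds.rbp_truth["is_regulator"]])
    hc = set(result.calls.loc[result.calls["tier"] == "high_confidence", "rbp_id"]) if len(result.calls) else set()
    sig = set(result.calls["rbp_id"]) if len(result.calls) else set()
    return {
        "hc_sensitivity": len(hc & true_rbps) / max(len(true_rbps), 1),
        "hc_false_calls": len(hc - true_rbps),
        "screen_sensitivity": len(sig & true_rbps) / max(len(true_rbps), 1),
        "n_high_confidence": len(hc),
    }


# ---------------------------------------------------------------------------
# directory runner with provenance


def run_to_directory(ds: SyntheticDataset, out_dir, config: PipelineConfig | None = None) -> PipelineResult:
    """Run on a synthetic dataset and write every stage output under ``out_dir``."""
    out = mio.ensure_dir(out_dir)
    result = run_on_dataset(ds, config=config)
    mio.write_bed6(result.peaks, out / "peaks.bed")
    mio.write_matrix(result.ratios, out / "peak_ratios.tsv", index_label="peak_id")
    mio.write_matrix(result.cell_line_matrix, out / "cell_line_matrix.tsv", index_label="peak_id")
    result.variability.to_csv(out / "peak_variability.tsv", sep="\t", na_rep="NA", index_label="peak_id")
    part = result.partition.labels.rename("module_id").to_frame()
    if result.merge_map is not None:
        part["combined_module_id"] = result.partition.labels.map(result.merge_map).fillna(0).astype(int)
    part.to_csv(out / "module_partition.tsv", sep="\t", index_label="peak_id")
    mio.write_matrix(result.eigengenes, out / "eigengenes.tsv", index_label="module_id")
    result.records.to_csv(out / "regulator_records.tsv", sep="\t", index=False)
    result.enrichments.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    result.calls.to_csv(out / "regulator_calls.tsv", sep="\t", index=False)
    manifest = {
        "config": dataclasses.asdict(result.config),
        "log": result.log,
        "dataset_params": {k: (v if isinstance(v, (int, float, str)) else str(v)) for k, v in ds.params.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return result
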