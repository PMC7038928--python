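"""Synthetic m6A-seq data with planted ground truth.

Every input the pipeline consumes can be generated here: a transcriptome with
random sequence, IP/input window read counts with planted enriched peaks,
m6A-ratio matrices with planted co-methylation modules, RBP expression with
planted regulators, and CLIP peaks / motifs planted preferentially into
target modules.  All generators are pure functions of (parameters, seed).

The ``paper-scale-small`` preset in :func:`build_dataset` wires these
together into one coherent dataset: planted peak enrichment folds are
modulated across cell lines by module profiles, so co-methylation structure
originates in the read counts and propagates through every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import Motif
from .peaks import TranscriptModel, WindowCountTable, make_windows

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_transcriptome(
    n_genes: int,
    seed: int = 0,
    utr5_meanlog: float = np.log(150),
    utr5_sdlog: float = 0.4,
    cds_meanlog: float = np.log(1200),
    cds_sdlog: float = 0.4,
    utr3_meanlog: float = np.log(900),
    utr3_sdlog: float = 0.5,
    multi_exon_fraction: float = 0.3,
    chrom: str = "chr1",
) -> tuple[dict[str, TranscriptModel], dict[str, str]]:
    """Random transcript models plus a genome sequence.

    Region lengths are log-normal (rounded, floored at 60 nt); a fraction of
    genes get 2-4 exons with 200-nt introns and half the genes sit on the
    minus strand, exercising spliced-coordinate projection.  Genes are laid
    end to end on one chromosome with 500-nt gaps.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    models: dict[str, TranscriptModel] = {}
    pieces: list[str] = []
    pos = 0
    for g in range(n_genes):
        u5 = max(60, int(rng.lognormal(utr5_meanlog, utr5_sdlog)))
        cds = max(60, int(rng.lognormal(cds_meanlog, cds_sdlog)))
        u3 = max(60, int(rng.lognormal(utr3_meanlog, utr3_sdlog)))
        total = u5 + cds + u3
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < multi_exon_fraction:
            n_exons = int(rng.integers(2, 5))
        else:
            n_exons = 1
        cuts = np.sort(rng.choice(np.arange(100, total - 100), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
        exon_lens = np.diff(np.concatenate([[0], cuts, [total]]))
        intron = 200
        exons = []
        p = pos
        for ln in exon_lens:
            exons.append((p, p + int(ln)))
            p += int(ln) + intron
        gene_end = exons[-1][1]
        gene_id = f"g{g:04d}"
        models[gene_id] = TranscriptModel(gene_id, chrom, strand, exons, u5, cds, u3)
        pieces.append(_random_seq(rng, gene_end - pos + 500))
        pos = gene_end + 500
    genome = {chrom: "".join(pieces)}
    return models, genome


def transcript_sequence(model: TranscriptModel, genome: dict[str, str]) -> str:
    """Spliced 5'->3' transcript sequence from genome and exon structure."""
    seq = "".join(genome[model.chrom][s:e] for s, e in sorted(model.exons))
    return _revcomp(seq) if model.strand == "-" else seq


def plant_peaks(
    models: dict[str, TranscriptModel],
    n_peaks: int,
    seed: int = 0,
    peak_length: int = 150,
    min_gap: int = 400,
) -> pd.DataFrame:
    """Choose planted peak positions (spliced coordinates, grid-aligned).

    Peaks are placed on the 50-nt window grid, at most 3 per gene, separated
    by >= ``min_gap`` nt so merged calls map one-to-one to planted peaks.
    """
    rng = np.random.default_rng(seed)
    rows = []
    gene_ids = list(models)
    gi = 0
    while len(rows) < n_peaks:
        gene = gene_ids[gi % len(gene_ids)]
        gi += 1
        total = models[gene].spliced_length
        slots = np.arange(100, max(101, total - peak_length - 100), 50)
        if slots.size == 0:
            continue
        n_here = min(3, n_peaks - len(rows))
        chosen: list[int] = []
        for s in rng.permutation(slots):
            if all(abs(int(s) - c) >= peak_length + min_gap for c in chosen):
                chosen.append(int(s))
            if len(chosen) == n_here:
                break
        for s in sorted(chosen):
            rows.append({"peak_label": f"p{len(rows):04d}", "gene_id": gene, "sstart": s, "send": s + peak_length})
    return pd.DataFrame(rows).set_index("peak_label")


def simulate_coverage(
    models: dict[str, TranscriptModel],
    planted: pd.DataFrame,
    fold,
    depth: float = 30.0,
    n_samples: int = 1,
    sample_ids: list[str] | None = None,
    seed: int = 0,
    window_length: int = 100,
    step: int = 50,
    expr_sdlog: float = 0.4,
    library_scale: float = 100.0,
) -> tuple[WindowCountTable, pd.DataFrame]:
    """Poisson IP/input window counts with planted enrichment.

    ``fold`` is either a scalar (same IP enrichment everywhere inside planted
    peaks, every sample) or a planted-peak x sample DataFrame of per-sample
    folds.  Input counts are Poisson(depth x gene expression factor x window
    length / window_length); IP counts multiply the mean by ``1 + (fold - 1)
    x overlap fraction`` of the window with a planted peak.  Returns the count
    table and the per-window truth (max overlap fraction with any planted
    peak, and the planted peak's label).

    ``library_scale`` emulates the fact that exonic windows hold only a small
    share of a real sequencing library: the recorded library size is the
    window-count total times this factor, putting window RPKMs on the scale
    (around 10 for the default depth) where the winscore's +1 low-coverage
    penalty and the input-RPKM missing-value rule behave as on real data.
    """
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"s{i:02d}" for i in range(n_samples)]
    n_samples = len(sample_ids)
    exon_regions = {g: (m.chrom, m.strand, m.exons) for g, m in models.items()}
    windows = make_windows(exon_regions, window_length=window_length, step=step)
    expr = pd.Series(rng.lognormal(0.0, expr_sdlog, size=len(models)), index=list(models))

    if np.isscalar(fold):
        fold_mat = pd.DataFrame(float(fold), index=planted.index, columns=sample_ids)
    else:
        fold_mat = fold.reindex(index=planted.index, columns=sample_ids)
    if (fold_mat.to_numpy() < 1).any():
        raise ValueError("fold must be >= 1")

    overlap = np.zeros(len(windows))
    which = np.full(len(windows), "", dtype=object)
    win_gene = windows["gene_id"].to_numpy()
    ws, we = windows["sstart"].to_numpy(), windows["send"].to_numpy()
    wlen = windows["length"].to_numpy().astype(float)
    for label, row in planted.iterrows():
        in_gene = np.flatnonzero(win_gene == row["gene_id"])
        ov = np.minimum(we[in_gene], row["send"]) - np.maximum(ws[in_gene], row["sstart"])
        frac = np.clip(ov, 0, None) / wlen[in_gene]
        better = frac > overlap[in_gene]
        overlap[in_gene[better]] = frac[better]
        which[in_gene[better]] = label
    truth = pd.DataFrame({"overlap_frac": overlap, "peak_label": which}, index=windows.index)

    base_mean = depth * expr[win_gene].to_numpy() * wlen / window_length
    counts_input = np.empty((len(windows), n_samples), dtype=int)
    counts_ip = np.empty_like(counts_input)
    label_pos = {lab: i for i, lab in enumerate(planted.index)}
    fold_arr = fold_mat.to_numpy()
    widx_of_label = np.array([label_pos.get(l, -1) for l in which])
    for j in range(n_samples):
        counts_input[:, j] = rng.poisson(base_mean)
        fold_w = np.ones(len(windows))
        hit = widx_of_label >= 0
        fold_w[hit] = 1.0 + (fold_arr[widx_of_label[hit], j] - 1.0) * overlap[hit]
        counts_ip[:, j] = rng.poisson(base_mean * fold_w)
    ci = pd.DataFrame(counts_ip, index=windows.index, columns=sample_ids)
    cn = pd.DataFrame(counts_input, index=windows.index, columns=sample_ids)
    lib_ip = (ci.sum(axis=0).astype(float) * library_scale).clip(lower=1.0)
    lib_input = (cn.sum(axis=0).astype(float) * library_scale).clip(lower=1.0)
    table = WindowCountTable(windows, ci, cn, lib_ip, lib_input)
    return table, truth


def simulate_methylome(
    n_peaks: int,
    n_cell_lines: int,
    module_sizes: list[int],
    noise_sd: float = 0.3,
    amplitude: float = 1.0,
    baseline: float = 2.0,
    na_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Peak x cell-line ratio matrix with planted co-methylation modules.

    Module peaks follow ``baseline + amplitude * profile + N(0, noise_sd)``
    with a shared standard-normal module profile over cell lines; remaining
    peaks are i.i.d. noise around the baseline.  Ratios are clipped at 0 and
    masked missing at ``na_fraction``.  Returns (matrix, truth labels with 0
    for noise peaks, module profiles).
    """
    if sum(module_sizes) > n_peaks:
        raise ValueError("module sizes exceed n_peaks")
    rng = np.random.default_rng(seed)
    cell_lines = [f"cl{i:02d}" for i in range(n_cell_lines)]
    profiles = rng.standard_normal((len(module_sizes), n_cell_lines))
    labels = np.zeros(n_peaks, dtype=int)
    x = np.empty((n_peaks, n_cell_lines))
    i = 0
    for m, size in enumerate(module_sizes, start=1):
        labels[i : i + size] = m
        x[i : i + size] = baseline + amplitude * profiles[m - 1] + rng.normal(0, noise_sd, (size, n_cell_lines))
        i += size
    n_noise = n_peaks - i
    x[i:] = baseline + rng.normal(0, np.sqrt(amplitude**2 + noise_sd**2), (n_noise, n_cell_lines))
    x = np.clip(x, 0.0, None)
    if na_fraction > 0:
        x[rng.random(x.shape) < na_fraction] = np.nan
    idx = [f"pk{i:05d}" for i in range(n_peaks)]
    mat = pd.DataFrame(x, index=idx, columns=cell_lines)
    prof = pd.DataFrame(profiles, index=range(1, len(module_sizes) + 1), columns=cell_lines)
    return mat, pd.Series(labels, index=idx, name="module"), prof


def simulate_regulators(
    profiles: pd.DataFrame,
    n_true_per_module: int,
    n_null: int,
    target_r: float = 0.8,
    base: float = 50.0,
    scale: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RBP expression with planted regulators tracking module profiles.

    A true regulator's expression is an affine image of its module profile
    plus a noise component orthogonalized against the profile and scaled so
    the realized sample Pearson correlation equals ``target_r`` exactly (the
    planted condition holds in every draw, not just in expectation); sign
    alternates between positive and negative regulators.  Null RBPs are
    i.i.d. with matched marginal variance.  Returns (expression matrix,
    truth table).
    """
    if not 0 < target_r <= 1:
        raise ValueError("target_r must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(max(1.0 / target_r**2 - 1.0, 0.0))
    cell_lines = list(profiles.columns)
    rows, truth = {}, []
    k = 0
    for mid in profiles.index:
        z = profiles.loc[mid].to_numpy()
        zs = (z - z.mean()) / z.std(ddof=0)
        for t in range(n_true_per_module):
            sign = 1.0 if t % 2 == 0 else -1.0
            name = f"RBP_T{k:03d}"
            e = rng.standard_normal(len(cell_lines))
            e = e - e.mean() - np.dot(e - e.mean(), zs) / len(zs) * zs
            e = e / e.std(ddof=0) if e.std(ddof=0) > 0 else e
            rows[name] = base + scale * (sign * zs + sigma * e)
            truth.append({"rbp_id": name, "module": mid, "sign": sign, "is_regulator": True})
            k += 1
    total_sd = np.sqrt(1.0 + sigma**2)
    for j in range(n_null):
        name = f"RBP_N{j:03d}"
        rows[name] = base + scale * total_sd * rng.standard_normal(len(cell_lines))
        truth.append({"rbp_id": name, "module": 0, "sign": 0.0, "is_regulator": False})
    expr = pd.DataFrame(rows, index=cell_lines).T
    return expr, pd.DataFrame(truth).set_index("rbp_id")


def odds_to_p1(odds_ratio: float, p0: float) -> float:
    """Target-module overlap probability given background p0 and an odds ratio."""
    o = odds_ratio * p0 / (1.0 - p0)
    return o / (1.0 + o)


def simulate_clip(
    peaks: pd.DataFrame,
    target_flags: pd.Series,
    odds_ratio: float = 5.0,
    p0: float = 0.1,
    clip_width: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """CLIP intervals planted preferentially into target peaks.

    Each peak receives a ``clip_width`` interval inside its genomic span with
    probability p1 (targets, where ``p1/(1-p1) = OR * p0/(1-p0)``) or p0
    (background).  ``peaks`` needs chrom/start/end/strand columns.
    """
    if odds_ratio < 1:
        raise ValueError("odds_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    p1 = odds_to_p1(odds_ratio, p0)
    rows = []
    for pid, row in peaks.iterrows():
        p = p1 if bool(target_flags.get(pid, False)) else p0
        if rng.random() < p:
            span = row["end"] - row["start"]
            off = int(rng.integers(0, max(span - clip_width, 1)))
            rows.append(
                {
                    "chrom": row["chrom"],
                    "start": row["start"] + off,
                    "end": min(row["start"] + off + clip_width, row["end"]),
                    "strand": row["strand"],
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def plant_motif_in_genome(
    genome: dict[str, str],
    models: dict[str, TranscriptModel],
    planted: pd.DataFrame,
    target_labels: list[str],
    motif: Motif,
    rate: float = 0.6,
    seed: int = 0,
) -> dict[str, str]:
    """Write concrete motif instances into target planted peaks' sequence.

    Each target peak receives, with probability ``rate``, one realization of
    the IUPAC consensus at a random offset inside its spliced interval; the
    genome copy is edited in place on the transcript strand.
    """
    rng = np.random.default_rng(seed)
    iupac_choices = {
        "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
        "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    genome = {c: list(s) for c, s in genome.items()}
    from .peaks import _spliced_to_genomic

    for label in target_labels:
        if rng.random() >= rate:
            continue
        row = planted.loc[label]
        model = models[row["gene_id"]]
        instance = "".join(rng.choice(list(iupac_choices[c])) for c in motif.consensus)
        width = row["send"] - row["sstart"] - len(instance)
        off = int(rng.integers(0, max(width, 1)))
        s0 = row["sstart"] + off
        write = instance if model.strand == "+" else _revcomp(instance)
        blocks = _spliced_to_genomic(model.exons, model.strand, int(s0), int(s0 + len(instance)))
        # write only when the instance lies in one exon block (common case)
        if len(blocks) == 1:
            gs, ge = blocks[0]
            genome[model.chrom][gs:ge] = list(write)
    return {c: "".join(s) for c, s in genome.items()}


@dataclass
class SyntheticDataset:
    """All pipeline inputs for one synthetic study, plus planted ground truth."""

    models: dict[str, TranscriptModel]
    genome: dict[str, str]
    table: WindowCountTable
    window_truth: pd.DataFrame
    planted_peaks: pd.DataFrame          # peak_label -> gene/sstart/send/module
    module_profiles: pd.DataFrame        # module x cell line
    expression: pd.DataFrame             # RBP x cell line TPM-like
    rbp_truth: pd.DataFrame
    clip_sets: dict[str, pd.DataFrame]
    motifs: dict[str, Motif]
    grouping: dict[str, str]             # sample -> cell line
    params: dict = field(default_factory=dict)


PRESETS = {
    "paper-scale-small": dict(
        n_genes=120,
        n_peaks=320,
        n_cell_lines=25,
        n_modules=4,
        module_size=60,
        fold=8.0,
        depth=30.0,
        amplitude=0.5,
        ratio_noise=0.12,
        n_true_per_module=2,
        n_null_rbps=52,
        target_r=0.8,
        clip_odds_ratio=6.0,
        clip_p0=0.1,
        motif_rate=0.6,
    ),
}


def build_dataset(preset: str = "paper-scale-small", seed: int = 0, **overrides) -> SyntheticDataset:
    """Generate a coherent end-to-end dataset with planted regulators.

    Planted peaks are split into co-methylated modules (whose IP enrichment
    fold varies across cell lines following a module profile on the log scale)
    and stable peaks (constant fold).  True-regulator expression tracks the
    module profiles; CLIP peaks and one motif per true regulator are planted
    into the regulator's module.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {list(PRESETS)}")
    p = dict(PRESETS[preset], **overrides)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    models, genome = simulate_transcriptome(p["n_genes"], seed=int(seeds[0]))
    planted = plant_peaks(models, p["n_peaks"], seed=int(seeds[1]))

    cell_lines = [f"cl{i:02d}" for i in range(p["n_cell_lines"])]
    n_module_peaks = p["n_modules"] * p["module_size"]
    if n_module_peaks > len(planted):
        raise ValueError("module peaks exceed planted peaks")
    labels = np.zeros(len(planted), dtype=int)
    order = rng.permutation(len(planted))
    for m in range(p["n_modules"]):
        labels[order[m * p["module_size"] : (m + 1) * p["module_size"]]] = m + 1
    planted = planted.copy()
    planted["module"] = labels

    profiles = pd.DataFrame(
        rng.standard_normal((p["n_modules"], p["n_cell_lines"])),
        index=range(1, p["n_modules"] + 1),
        columns=cell_lines,
    )
    # per-sample fold: log-scale modulation by the module profile
    base = np.log(p["fold"])
    fold_mat = pd.DataFrame(p["fold"], index=planted.index, columns=cell_lines)
    for m in range(1, p["n_modules"] + 1):
        members = planted.index[planted["module"] == m]
        mod = np.exp(base + p["amplitude"] * profiles.loc[m].to_numpy()[None, :]
                     + rng.normal(0, p["ratio_noise"], (len(members), p["n_cell_lines"])))
        fold_mat.loc[members] = np.clip(mod, 1.0, None)

    # motifs and CLIP for true regulators, planted into their module's peaks
    motif_pool = ["TGCATG", "GGACTT", "TTAGGW", "CATCRC", "ACWTGC", "GTRTGA", "CTSAGC", "AGGWAC"]
    motifs: dict[str, Motif] = {}
    clip_sets: dict[str, pd.DataFrame] = {}

    expr, rbp_truth = simulate_regulators(
        profiles, p["n_true_per_module"], p["n_null_rbps"], target_r=p["target_r"], seed=int(seeds[2])
    )

    genome_edit = genome
    true_rbps = rbp_truth.index[rbp_truth["is_regulator"]]
    for k, rbp in enumerate(true_rbps):
        mid = int(rbp_truth.loc[rbp, "module"])
        targets = list(planted.index[planted["module"] == mid])
        motif = Motif(rbp, motif_pool[k % len(motif_pool)])
        motifs[rbp] = motif
        genome_edit = plant_motif_in_genome(
            genome_edit, models, planted, targets, motif, rate=p["motif_rate"], seed=int(seeds[3]) + k
        )

    table, window_truth = simulate_coverage(
        models, planted, fold_mat, depth=p["depth"], sample_ids=cell_lines, seed=int(seeds[4])
    )

    # CLIP planting needs genomic spans of planted peaks
    from .peaks import _spliced_to_genomic

    spans = []
    for label, row in planted.iterrows():
        model = models[row["gene_id"]]
        blocks = _spliced_to_genomic(model.exons, model.strand, int(row["sstart"]), int(row["send"]))
        spans.append({"chrom": model.chrom, "start": blocks[0][0], "end": blocks[-1][1], "strand": model.strand})
    planted_spans = pd.DataFrame(spans, index=planted.index)
    for k, rbp in enumerate(true_rbps):
        mid = int(rbp_truth.loc[rbp, "module"])
        target_flags = planted["module"] == mid
        clip_sets[rbp] = simulate_clip(
            planted_spans, target_flags, odds_ratio=p["clip_odds_ratio"], p0=p["clip_p0"], seed=int(seeds[5]) + k
        )

    grouping = {c: c for c in cell_lines}
    return SyntheticDataset(
        models=models,
        genome=genome_edit,
        table=table,
        window_truth=window_truth,
        planted_peaks=planted,
        module_profiles=profiles,
        expression=expr,
        rbp_truth=rbp_truth,
        clip_sets=clip_sets,
        motifs=motifs,
        grouping=grouping,
        params=dict(p, seed=seed),
    )


def simulate_knockdown(
    peak_ids: pd.Index,
    affected: pd.Series,
    effect_log2fc: float = -0.8,
    baseline_ratio: float = 1.0,
    noise_sd: float = 0.1,
    input_rpkm_mean: float = 40.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Control/knockdown ratio and input-RPKM tables for validation tests.

    Affected peaks' knockdown ratios shift by ``effect_log2fc`` on the log2
    scale; two replicates per condition with multiplicative log-normal noise.
    """
    rng = np.random.default_rng(seed)
    samples = ["ctrl_1", "ctrl_2", "kd_1", "kd_2"]
    n = len(peak_ids)
    base = baseline_ratio * rng.lognormal(0.0, 0.4, size=n)
    eff = np.where(affected.reindex(peak_ids).fillna(False).to_numpy(dtype=bool), 2.0**effect_log2fc, 1.0)
    vals = {}
    for s in samples:
        mu = base * (eff if s.startswith("kd") else 1.0)
        vals[s] = mu * rng.lognormal(0.0, noise_sd, size=n)
    ratios = pd.DataFrame(vals, index=peak_ids)
    inp = pd.DataFrame(
        rng.lognormal(np.log(input_rpkm_mean), 0.3, size=(n, len(samples))), index=peak_ids, columns=samples
    )
    return ratios, inp
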