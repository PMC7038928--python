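"""Readers and writers for the pipeline's on-disk formats.

Window-count TSV + library manifest, BED12 transcript models, BED6 peak /
CLIP intervals, NA-coded ratio matrices, motif tables, FASTA peak sequences.
Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import Motif
from .peaks import TranscriptModel, WindowCountTable

NA = "NA"


def write_matrix(m: pd.DataFrame, path, index_label: str = "id") -> None:
    m.to_csv(path, sep="\t", na_rep=NA, index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])


def write_window_counts(table: WindowCountTable, counts_path, manifest_path) -> None:
    """Window-count TSV (window metadata + per-library counts) and manifest."""
    meta = table.windows[["chrom", "gstart", "gend", "strand", "gene_id", "widx", "sstart", "send", "length"]].copy()
    meta.columns = ["chrom", "start", "end", "strand", "gene_id", "widx", "sstart", "send", "length"]
    out = meta.copy()
    for s in table.samples:
        out[f"{s}.IP"] = table.counts_ip[s]
        out[f"{s}.input"] = table.counts_input[s]
    out.to_csv(counts_path, sep="\t", index_label="window_id")
    rows = []
    for s in table.samples:
        rows.append({"library_id": f"{s}.IP", "sample_id": s, "role": "IP", "library_size": int(table.lib_ip[s])})
        rows.append({"library_id": f"{s}.input", "sample_id": s, "role": "input", "library_size": int(table.lib_input[s])})
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)


def read_window_counts(counts_path, manifest_path) -> WindowCountTable:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    manifest = pd.read_csv(manifest_path, sep="\t")
    meta_cols = ["chrom", "start", "end", "strand", "gene_id", "widx", "sstart", "send", "length"]
    windows = df[meta_cols].rename(columns={"start": "gstart", "end": "gend"})
    samples = sorted(manifest["sample_id"].unique())
    counts_ip, counts_input, lib_ip, lib_input = {}, {}, {}, {}
    for s in samples:
        sub = manifest[manifest["sample_id"] == s]
        roles = dict(zip(sub["role"], sub["library_id"]))
        if "IP" not in roles or "input" not in roles:
            raise ValueError(f"sample {s!r} lacks an IP or input library")
        counts_ip[s] = df[roles["IP"]]
        counts_input[s] = df[roles["input"]]
        sizes = dict(zip(sub["role"], sub["library_size"]))
        lib_ip[s], lib_input[s] = float(sizes["IP"]), float(sizes["input"])
    return WindowCountTable(
        windows,
        pd.DataFrame(counts_ip),
        pd.DataFrame(counts_input),
        pd.Series(lib_ip),
        pd.Series(lib_input),
    )


def write_bed6(df: pd.DataFrame, path, name_col: str | None = None) -> None:
    """BED6 from a frame with chrom/start/end/strand (+ optional name column/index)."""
    names = df.index if name_col is None else df[name_col]
    with open(path, "w") as fh:
        for name, (_, row) in zip(names, df.iterrows()):
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{name}\t0\t{row['strand']}\n")


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if (df["start"] >= df["end"]).any():
        bad = int((df["start"] >= df["end"]).idxmax()) + 1
        raise ValueError(f"malformed interval at line {bad}: start >= end")
    return df


def write_bed12(models: dict[str, TranscriptModel], path, utr_table_path=None) -> None:
    """Transcript models as BED12 (thickStart/thickEnd = CDS in transcript order).

    BED12 cannot carry spliced UTR/CDS lengths losslessly for minus-strand
    multi-exon genes without re-projection, so an optional side table with the
    region lengths can be written too.
    """
    with open(path, "w") as fh:
        for m in models.values():
            exons = sorted(m.exons)
            start, end = exons[0][0], exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in exons) + ","
            starts = ",".join(str(s - start) for s, _ in exons) + ","
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{m.gene_id}\t0\t{m.strand}\t{start}\t{end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )
    if utr_table_path is not None:
        pd.DataFrame(
            [
                {"gene_id": m.gene_id, "utr5_len": m.utr5_len, "cds_len": m.cds_len, "utr3_len": m.utr3_len}
                for m in models.values()
            ]
        ).to_csv(utr_table_path, sep="\t", index=False)


def read_bed12(path, utr_table_path=None) -> dict[str, TranscriptModel]:
    models = {}
    utrs = None
    if utr_table_path is not None:
        utrs = pd.read_csv(utr_table_path, sep="\t").set_index("gene_id")
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            total = sum(sizes)
            if utrs is not None and name in utrs.index:
                u5, cds, u3 = (int(utrs.loc[name, c]) for c in ("utr5_len", "cds_len", "utr3_len"))
            else:
                u5, cds, u3 = 0, total, 0
            models[name] = TranscriptModel(name, chrom, strand, exons, u5, cds, u3)
    return models


def write_fasta(seqs: dict[str, str] | pd.Series, path) -> None:
    records = [SeqRecord(Seq(s), id=str(k), description="") for k, s in dict(seqs).items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> pd.Series:
    return pd.Series({rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")})


def write_motifs(motifs: dict[str, Motif], path) -> None:
    pd.DataFrame([{"rbp_id": m.rbp_id, "consensus": m.consensus} for m in motifs.values()]).to_csv(
        path, sep="\t", index=False
    )


def read_motifs(path) -> dict[str, Motif]:
    df = pd.read_csv(path, sep="\t")
    return {row["rbp_id"]: Motif(row["rbp_id"], row["consensus"]) for _, row in df.iterrows()}


def write_clip_bed(clip_sets: dict[str, pd.DataFrame], path) -> None:
    """All CLIP sets in one BED6, name = rbp_id."""
    with open(path, "w") as fh:
        for rbp, df in clip_sets.items():
            for _, row in df.iterrows():
                fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{rbp}\t0\t{row['strand']}\n")


def read_clip_bed(path) -> dict[str, pd.DataFrame]:
    df = read_bed6(path)
    return {rbp: sub[["chrom", "start", "end", "strand"]].reset_index(drop=True) for rbp, sub in df.groupby("name")}


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
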