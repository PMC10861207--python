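"""Readers and writers for the plain-text dialects the pipeline uses.

Survival tables and tracks travel as CSV, DE tables and summaries as
TSV, promoters/genomes as FASTA, gene features as GFF3 (read-only),
motif hits as BED6, and results/truth sidecars as JSON.  Readers
validate and report offending line numbers; writers and readers are
mutual inverses on valid data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locomotion import Track
from .regulatory import DegRecord, MotifHit, PromoterSeq
from .survival import EventTable

__all__ = [
    "RunConfig",
    "read_survival_csv",
    "write_survival_csv",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_fasta",
    "write_fasta",
    "read_de_table",
    "write_de_table",
    "read_gff3_genes",
    "write_bed",
    "read_panel_csv",
]


@dataclasses.dataclass
class RunConfig:
    """Run-wide thresholds and paths; round-trips losslessly through YAML."""

    output_dir: str = "."
    speed_threshold: float = 0.015
    slow_fraction_threshold: float = 0.80
    angle_threshold: float = 90.0
    min_step: float = 0.005
    fc_min: float = 2.0
    fdr_max: float = 0.05
    flank: int = 1500
    both_strands: bool = True
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.slow_fraction_threshold < 1:
            raise ValueError("slow_fraction_threshold must lie in (0, 1)")
        if self.speed_threshold <= 0 or self.min_step < 0:
            raise ValueError("speed thresholds out of range")
        if not 0 <= self.fdr_max <= 1:
            raise ValueError("fdr_max must lie in [0, 1]")
        if self.fc_min < 1 or self.flank < 1:
            raise ValueError("fc_min must be >= 1 and flank >= 1")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def read_survival_csv(path, time_unit: str = "days") -> EventTable:
    """Read subject-level survival data.

    Required columns: subject_id, group, time, event.  Malformed time or
    event values are reported with their 1-based file line numbers.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str},
                     float_precision="round_trip")
    for col in ("subject_id", "group", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    bad_lines = []
    times = pd.to_numeric(df["time"], errors="coerce")
    events = pd.to_numeric(df["event"], errors="coerce")
    for i in range(len(df)):
        line_no = i + 2  # header is line 1
        if not np.isfinite(times.iloc[i]) or times.iloc[i] < 0:
            bad_lines.append(f"line {line_no}: bad time {df['time'].iloc[i]!r}")
        elif events.iloc[i] not in (0, 1):
            bad_lines.append(f"line {line_no}: bad event {df['event'].iloc[i]!r}")
    if bad_lines:
        raise ValueError("malformed rows: " + "; ".join(bad_lines))
    return EventTable(df["subject_id"].to_numpy(), df["group"].to_numpy(),
                      times.to_numpy(), events.astype(int).to_numpy(), time_unit)


def write_survival_csv(events: EventTable, path) -> None:
    # 17 significant digits so float64 times round-trip exactly
    events.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_tracks_csv(path) -> list[Track]:
    """Long-format tracks: worm_id, t_s, x_mm, y_mm, one row per frame."""
    df = pd.read_csv(path)
    for col in ("worm_id", "t_s", "x_mm", "y_mm"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    tracks = []
    for wid, sub in df.groupby("worm_id", sort=False):
        sub = sub.sort_values("t_s")
        tracks.append(Track(str(wid), sub["t_s"].to_numpy(),
                            sub["x_mm"].to_numpy(), sub["y_mm"].to_numpy()))
    return tracks


def write_tracks_csv(tracks: list[Track], path) -> None:
    frames = [
        pd.DataFrame({"worm_id": tr.worm_id, "t_s": tr.t, "x_mm": tr.x, "y_mm": tr.y})
        for tr in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_fasta(path) -> list[PromoterSeq]:
    """FASTA records as promoters: ids from headers, sequences uppercased;
    duplicate ids or an empty file are errors."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append(PromoterSeq(gene_id=rec.id, seq=str(rec.seq).upper()))
    return out


def write_fasta(promoters: list[PromoterSeq], path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(p.seq), id=p.gene_id, description="") for p in promoters]
    SeqIO.write(recs, str(path), "fasta")


def read_de_table(path) -> list[DegRecord]:
    """TSV with columns gene_id, log2fc, fdr."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("gene_id", "log2fc", "fdr"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    return [DegRecord(str(r.gene_id), float(r.log2fc), float(r.fdr))
            for r in df.itertuples(index=False)]


def write_de_table(degs: list[DegRecord], path) -> None:
    pd.DataFrame(
        {"gene_id": [d.gene_id for d in degs],
         "log2fc": [d.log2fc for d in degs],
         "fdr": [d.fdr for d in degs]}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from GFF3: gene_id, contig, start, end, strand
    (1-based inclusive, as in the file)."""
    rows = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {raw.strip()!r}")
            contig, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
            if gene_id is None:
                raise ValueError(f"gene feature without ID attribute: {raw.strip()!r}")
            rows.append({"gene_id": gene_id, "contig": contig,
                         "start": int(start), "end": int(end), "strand": strand})
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])


def write_bed(hits: list[MotifHit], path) -> None:
    """BED6: chrom = gene_id, 0-based half-open interval, name = motif
    pattern, score 0, strand; stable-sorted by (chrom, start)."""
    for h in hits:
        if h.start < 0:
            raise ValueError(f"negative start in hit {h}")
    ordered = sorted(hits, key=lambda h: (h.gene_id, h.start))
    with open(path, "w") as fh:
        for h in ordered:
            fh.write(f"{h.gene_id}\t{h.start}\t{h.end}\t{h.pattern}\t0\t{h.strand}\n")


def read_panel_csv(path) -> pd.DataFrame:
    """Fitness panel CSV: group, metric, value[, n]."""
    df = pd.read_csv(path)
    for col in ("group", "metric", "value"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    return df
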