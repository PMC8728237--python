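"""File I/O: FASTA/FASTQ readers (gzip-aware), TSV writers, run configuration.

Sequences are normalised to the internal DNA alphabet (uppercase, U -> T)
on input. FASTQ is parsed directly from the 4-line format so that a
truncated quartet can be reported with its line number.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._align import normalize_seq

logger = logging.getLogger("tsrkit.io")


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[tuple[str, str]]:
    """(record id, normalized sequence) pairs from a FASTA file."""
    with _open_text(path) as fh:
        return [(rec.id, normalize_seq(str(rec.seq))) for rec in SeqIO.parse(fh, "fasta")]


def read_fastq(path) -> list[tuple[str, str]]:
    """(record id, normalized sequence) pairs from a FASTQ file.

    Raises ValueError with the offending line number on a truncated or
    malformed quartet.
    """
    records = []
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            if not header.startswith("@"):
                raise ValueError(f"line {lineno}: FASTQ header must start with '@'")
            quartet = [fh.readline() for _ in range(3)]
            if any(not ln for ln in quartet):
                raise ValueError(f"line {lineno}: truncated FASTQ quartet")
            seq, plus, qual = (ln.rstrip("\n") for ln in quartet)
            lineno += 3
            if not plus.startswith("+"):
                raise ValueError(f"line {lineno - 1}: expected '+' separator")
            if len(qual) != len(seq):
                raise ValueError(f"line {lineno}: quality length differs from sequence length")
            records.append((header[1:].split()[0], normalize_seq(seq)))
    return records


def read_sequences(path) -> list[tuple[str, str]]:
    """Dispatch on extension: .fa/.fasta vs .fq/.fastq, optionally .gz."""
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bed_intervals(path) -> list[tuple[str, int, int, str]]:
    """BED (0-based half-open) -> 1-based closed (chrom, start, end, name)."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: BED row needs >= 3 columns")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            out.append((chrom, s + 1, e, parts[3] if len(parts) > 3 else ""))
    return out


def read_conservation_track(path, lengths: dict[str, int]):
    """bedGraph-like (id, start0, end0, value) rows -> per-base arrays."""
    import numpy as np

    track = {tid: np.zeros(n) for tid, n in lengths.items()}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            tid, s, e, v = line.split()[:4]
            if tid in track:
                track[tid][int(s): int(e)] = float(v)
    return track


@dataclass
class RunConfig:
    """Resolved thresholds of a run; written next to the outputs."""

    p_threshold: float = 0.01
    energy_cutoff: float = -10.0
    conservation_cutoff: float = 0.3
    fdr_threshold: float = 0.05
    min_len: int = 14
    max_len: int = 45
    max_edits: int = 1
    min_score: float = 0.0
    count_mode: str = "start"
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must be in (0, 1]")
        if not (0.0 < self.fdr_threshold <= 1.0):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.count_mode not in {"start", "end"}:
            raise ValueError("count_mode must be 'start' or 'end'")

    def write(self, out_dir) -> None:
        path = Path(out_dir) / "run_config.json"
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def calls_to_frame(calls) -> pd.DataFrame:
    """TsRNACall list -> output TSV schema."""
    rows = []
    for c in calls:
        src = ";".join(f"{g}:{kind}:{s}-{e}" for g, kind, s, e in c.sources)
        starts = [s for _, _, s, _ in c.sources]
        ends = [e for _, _, _, e in c.sources]
        rows.append((c.name, c.seq, c.tsrna_type, src,
                     min(starts) if starts else 0, max(ends) if ends else 0,
                     c.count, c.pvalue, c.whitelisted))
    return pd.DataFrame(rows, columns=[
        "name", "seq", "type", "sources", "start", "end", "count", "pvalue", "whitelisted",
    ])


def interactions_to_frame(interactions) -> pd.DataFrame:
    rows = []
    for it in interactions:
        rows.append((
            it.tsrna_name, it.target_id, it.site[0], it.site[1],
            it.duplex.seed_ok, it.duplex.duplex_score, it.duplex.mismatches,
            it.duplex.conservation_mean if it.duplex.conservation_mean is not None else "",
            it.evidence, it.experiment_id,
        ))
    return pd.DataFrame(rows, columns=[
        "tsrna_name", "target_id", "site_start", "site_end", "seed_ok",
        "duplex_score", "mismatches", "conservation_mean", "evidence", "experiment_id",
    ])
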