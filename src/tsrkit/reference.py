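"""Mature-tRNA reference construction.

A tRNA gene is transcribed as a precursor that may contain an intron
(typically just 3' of the anticodon); the mature transcript is the spliced
exonic sequence with the non-templated CCA tail appended by the CCA-adding
enzyme. tRF-1 fragments derive not from the mature tRNA but from the 3'
trailer of the precursor, so a fixed-length stretch of genomic sequence
immediately downstream of each gene is extracted as a second reference.

Coordinates are 1-based closed intervals throughout; readers of BED-style
files convert at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from ._align import normalize_seq, revcomp

logger = logging.getLogger("tsrkit.reference")

#: offsets (relative to the first anticodon base) delimiting the anticodon
#: loop: a 7-nt loop with the anticodon at positions 3-5, i.e. [a-2, a+4].
ANTICODON_LOOP_OFFSETS = (-2, 4)

TRAILER_LENGTH = 50


@dataclass
class TRNAGeneRecord:
    """A tRNA gene as annotated on the genome (unspliced)."""

    gene_id: str
    amino_acid: str
    anticodon: str
    chrom: str
    start: int  # 1-based, closed
    end: int
    strand: str
    intron_intervals: list[tuple[int, int]] = field(default_factory=list)
    genomic_seq: str = ""  # unspliced transcript, 5'->3' (strand-corrected)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if len(self.anticodon) != 3:
            raise ValueError(f"{self.gene_id}: anticodon must be 3 nt")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        self.anticodon = normalize_seq(self.anticodon)
        self.genomic_seq = normalize_seq(self.genomic_seq)
        ivs = sorted(self.intron_intervals)
        for (s, e) in ivs:
            if not (1 <= s <= e <= len(self.genomic_seq) or not self.genomic_seq):
                raise ValueError(f"{self.gene_id}: intron ({s},{e}) outside transcript")
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping introns")
        self.intron_intervals = ivs


@dataclass
class MatureTRNA:
    """Spliced, CCA-appended tRNA transcript with anticodon-loop coordinates."""

    gene_id: str
    seq: str
    anticodon_start: int  # 1-based position of the first anticodon base
    anticodon_loop: tuple[int, int]  # 1-based closed interval
    kind: str = "mature"

    @property
    def L(self) -> int:
        return len(self.seq)


@dataclass
class TrailerSeq:
    """Genomic sequence immediately 3' of a tRNA gene (tRF-1 source)."""

    gene_id: str
    seq: str
    kind: str = "trailer"

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def L(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ModificationSite:
    gene_id: str
    position: int  # 1-based on the mature sequence
    mod_type: str


def splice(seq: str, introns: Iterable[tuple[int, int]]) -> str:
    """Remove 1-based closed intron intervals from an unspliced transcript."""
    keep = []
    prev = 1
    for s, e in sorted(introns):
        keep.append(seq[prev - 1 : s - 1])
        prev = e + 1
    keep.append(seq[prev - 1 :])
    return "".join(keep)


def build_mature_trna(
    gene: TRNAGeneRecord,
    loop_offsets: tuple[int, int] = ANTICODON_LOOP_OFFSETS,
) -> MatureTRNA:
    """Splice out introns, append the CCA tail, and locate the anticodon loop.

    The anticodon triplet is searched on the spliced sequence and the
    occurrence nearest the sequence midpoint is taken (the anticodon sits in
    the central loop of the cloverleaf, so spurious occurrences near either
    end are rejected by the midpoint rule).
    """
    if not gene.genomic_seq:
        raise ValueError(f"{gene.gene_id}: genomic_seq missing")
    spliced = splice(gene.genomic_seq, gene.intron_intervals)
    mid = (len(spliced) + 1) / 2
    occurrences = []
    pos = spliced.find(gene.anticodon)
    while pos != -1:
        occurrences.append(pos + 1)  # 1-based
        pos = spliced.find(gene.anticodon, pos + 1)
    if not occurrences:
        raise ValueError(
            f"anticodon {gene.anticodon} not found in spliced sequence of {gene.gene_id}"
        )
    a = min(occurrences, key=lambda p: (abs(p + 1 - mid), p))
    seq = spliced + "CCA"
    L = len(seq)
    loop = (max(1, a + loop_offsets[0]), min(L, a + loop_offsets[1]))
    return MatureTRNA(gene_id=gene.gene_id, seq=seq, anticodon_start=a, anticodon_loop=loop)


def extract_trailer(
    gene: TRNAGeneRecord,
    genome: Mapping[str, str],
    length: int = TRAILER_LENGTH,
) -> TrailerSeq:
    """Extract the ``length``-nt genomic sequence immediately 3' of the gene.

    On the + strand this is genome[end+1 .. end+length]; on the - strand the
    reverse complement of genome[start-length .. start-1]. Truncated with a
    warning at chromosome boundaries.
    """
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} not found in genome")
    chrom_seq = genome[gene.chrom]
    n = len(chrom_seq)
    if gene.strand == "+":
        lo = gene.end + 1
        hi = min(gene.end + length, n)
        seq = chrom_seq[lo - 1 : hi]
    else:
        hi = gene.start - 1
        lo = max(1, gene.start - length)
        seq = revcomp(chrom_seq[lo - 1 : hi])
    if len(seq) < length:
        logger.warning(
            "trailer of %s truncated to %d nt at chromosome boundary", gene.gene_id, len(seq)
        )
    return TrailerSeq(gene_id=gene.gene_id, seq=normalize_seq(seq))


def genomic_to_mature_position(gene: TRNAGeneRecord, genomic_pos: int) -> int | None:
    """Lift a genomic coordinate onto the mature (spliced) transcript.

    Returns None for positions outside the gene or inside an intron. The CCA
    tail is non-templated and therefore unreachable from genomic coordinates.
    """
    if not (gene.start <= genomic_pos <= gene.end):
        return None
    if gene.strand == "+":
        u = genomic_pos - gene.start + 1
    else:
        u = gene.end - genomic_pos + 1
    offset = 0
    for s, e in gene.intron_intervals:
        if s <= u <= e:
            return None
        if e < u:
            offset += e - s + 1
    return u - offset


def load_modification_sites(
    table,
    matures: Mapping[str, MatureTRNA] | None = None,
) -> list[ModificationSite]:
    """Ingest an RMBase-style table of (gene_id, position, mod_type) rows.

    ``table`` may be a path to a TSV, a pandas DataFrame, or an iterable of
    row tuples. Positions are 1-based on the mature sequence; rows whose
    position falls outside [1, L] are dropped with a logged count, duplicate
    (gene, position) rows are deduplicated, and malformed rows raise with
    their line number.
    """
    if isinstance(table, (str,)) or hasattr(table, "__fspath__"):
        df = pd.read_csv(table, sep="\t", header=None, names=["gene_id", "position", "mod_type"],
                         dtype=str, comment="#")
        rows = list(df.itertuples(index=False, name=None))
    elif isinstance(table, pd.DataFrame):
        rows = list(table.itertuples(index=False, name=None))
    else:
        rows = list(table)

    sites: dict[tuple[str, int], ModificationSite] = {}
    dropped = 0
    for lineno, row in enumerate(rows, start=1):
        try:
            gene_id, position, mod_type = row[0], int(row[1]), str(row[2])
        except (ValueError, TypeError, IndexError) as exc:
            raise ValueError(f"malformed modification-site row at line {lineno}: {row!r}") from exc
        L = matures[gene_id].L if matures and gene_id in matures else None
        if position < 1 or (L is not None and position > L):
            dropped += 1
            continue
        sites.setdefault((gene_id, position), ModificationSite(gene_id, position, mod_type))
    if dropped:
        logger.warning("dropped %d modification sites outside the mature length", dropped)
    return sorted(sites.values(), key=lambda s: (s.gene_id, s.position))


def mod_site_index(sites: Iterable[ModificationSite]) -> dict[str, frozenset[int]]:
    """gene_id -> set of modified 1-based mature positions."""
    idx: dict[str, set[int]] = {}
    for s in sites:
        idx.setdefault(s.gene_id, set()).add(s.position)
    return {g: frozenset(v) for g, v in idx.items()}
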