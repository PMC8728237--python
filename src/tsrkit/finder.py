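"""tsRNA identification from small RNA-seq reads.

The caller distinguishes bona fide tsRNAs (products of site-specific
cleavage) from random tRNA degradation by a per-position binomial
enrichment test. Under the null of unbiased degradation a read falls at any
of the L - l + 1 admissible start positions of a transcript of length L
with equal probability p = 1/(L - l + 1); the probability of observing k or
more of the n transcript tags at one position is the upper binomial tail

    P(X >= k) = sum_{x=k..n} C(n, x) p^x (1-p)^(n-x)

and positions with P < 0.01 (default) are reported as cleavage sites.

Alignment scoring is modification-aware: tRNA chemical modifications cause
reverse-transcription errors, so a mismatch or indel at a catalogued
modification site is penalised -0.5 instead of the plain -1, while every
matched base scores +1.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace

import edlib
import numpy as np
from scipy.stats import binom

from ._align import VALID_BASES, normalize_seq, revcomp, scan_mismatch
from .reference import MatureTRNA, TrailerSeq

logger = logging.getLogger("tsrkit.finder")

TSRNA_TYPES = ("tRF-5", "tRF-3", "tRF-i", "tRF-1", "tiRNA-5", "tiRNA-3")

#: name code per fragment class; tiRNAs get two-character codes so that the
#: name alone distinguishes halves from tRFs.
TYPE_CODES = {
    "tRF-5": "5",
    "tRF-3": "3",
    "tRF-i": "i",
    "tRF-1": "1",
    "tiRNA-5": "5i",
    "tiRNA-3": "3i",
}

MOD_PENALTY = 0.5
PLAIN_PENALTY = 1.0


@dataclass
class ReadAlignment:
    read_seq: str
    read_count: int
    gene_id: str
    ref_kind: str  # "mature" | "trailer"
    start: int  # 1-based on the reference
    end: int
    n_match: int = 0
    n_mismatch_plain: int = 0
    n_mismatch_mod: int = 0
    n_indel_plain: int = 0
    n_indel_mod: int = 0

    @property
    def score(self) -> float:
        return (
            self.n_match
            - PLAIN_PENALTY * (self.n_mismatch_plain + self.n_indel_plain)
            - MOD_PENALTY * (self.n_mismatch_mod + self.n_indel_mod)
        )

    @property
    def n_edits(self) -> int:
        return (
            self.n_mismatch_plain + self.n_mismatch_mod + self.n_indel_plain + self.n_indel_mod
        )


@dataclass
class PositionEnrichment:
    gene_id: str
    ref_kind: str
    position: int
    k: int
    n: int
    L: int
    l: int
    p: float
    pvalue: float


@dataclass
class TsRNACall:
    seq: str
    tsrna_type: str
    name: str = ""
    sources: list[tuple[str, str, int, int]] = field(default_factory=list)
    count: int = 0
    pvalue: float = 1.0
    whitelisted: bool = False


def collapse_reads(seqs) -> dict[str, int]:
    """Collapse raw read sequences to unique sequences with multiplicities."""
    counts: dict[str, int] = defaultdict(int)
    for s in seqs:
        counts[normalize_seq(s)] += 1
    return dict(counts)


def filter_reads(
    reads: dict[str, int],
    exclusion_refs=(),
    genome=None,
    keep_refs=(),
    max_edits: int = 1,
) -> dict[str, int]:
    """Remove reads explained by non-tRNA transcripts or absent from the genome.

    A read matching any exclusion reference (mRNA, rRNA, sno/snRNA, miRNA,
    repeat) within the mismatch budget is discarded; if a genome is supplied,
    reads without a genomic match on either strand are discarded as
    exogenous. Reads matching a ``keep_refs`` sequence (the mature/trailer
    tRNA space) bypass the genomic check: the CCA tail is non-templated and
    intron-containing tRNAs are spliced, so genuine tsRNA reads need not
    occur contiguously in the genome.
    """
    exclusion = [normalize_seq(r) for r in exclusion_refs]
    keep = [normalize_seq(getattr(r, "seq", r)) for r in keep_refs]
    genome_seqs = list(genome.values()) if genome else None
    kept: dict[str, int] = {}
    n_excluded = n_exogenous = 0
    for seq, count in reads.items():
        if any(scan_mismatch(seq, ref, max_edits) for ref in exclusion):
            n_excluded += 1
            continue
        if genome_seqs is not None:
            found = any(scan_mismatch(seq, ref, max_edits) for ref in keep) or any(
                scan_mismatch(q, chrom, max_edits)
                for chrom in genome_seqs
                for q in (seq, revcomp(seq))
            )
            if not found:
                n_exogenous += 1
                continue
        kept[seq] = count
    logger.info(
        "filter_reads: %d kept, %d excluded (known RNA), %d exogenous",
        len(kept), n_excluded, n_exogenous,
    )
    return kept


def _parse_edlib_cigar(cigar: str):
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def align_to_trna(
    read_seq: str,
    read_count: int,
    refs,
    mod_sites: dict[str, frozenset[int]] | None = None,
    max_edits: int = 1,
    min_score: float = 0.0,
) -> list[ReadAlignment]:
    """All placements of a read on the mature/trailer references.

    Ungapped placements are found by an exhaustive sliding scan; when the
    edit budget allows indels, edlib's infix search supplies additional
    gapped placements which are rescored with the modification-aware rule.
    Placements with more than ``max_edits`` edits or score below
    ``min_score`` are dropped.
    """
    seq = normalize_seq(read_seq)
    if set(seq) - VALID_BASES:
        raise ValueError(f"read contains non-ACGTUN characters: {read_seq!r}")
    mod_sites = mod_sites or {}
    out: list[ReadAlignment] = []
    for ref in refs:
        mods = mod_sites.get(ref.gene_id, frozenset()) if ref.kind == "mature" else frozenset()
        seen_spans = set()
        for start0, mm_offsets in scan_mismatch(seq, ref.seq, max_edits):
            n_mod = sum(1 for off in mm_offsets if (start0 + off + 1) in mods)
            aln = ReadAlignment(
                read_seq=seq,
                read_count=read_count,
                gene_id=ref.gene_id,
                ref_kind=ref.kind,
                start=start0 + 1,
                end=start0 + len(seq),
                n_match=len(seq) - len(mm_offsets),
                n_mismatch_plain=len(mm_offsets) - n_mod,
                n_mismatch_mod=n_mod,
            )
            if aln.score >= min_score:
                out.append(aln)
                seen_spans.add((aln.start, aln.end))
        if max_edits >= 1 and len(seq) <= len(ref.seq):
            res = edlib.align(seq, ref.seq, mode="HW", task="path", k=max_edits)
            if res["editDistance"] != -1 and res["editDistance"] <= max_edits:
                for loc in res["locations"]:
                    aln = _alignment_from_path(seq, read_count, ref, res["cigar"], loc, mods)
                    if aln is None:
                        continue
                    if (aln.start, aln.end) in seen_spans or aln.n_edits > max_edits:
                        continue
                    if aln.n_indel_plain + aln.n_indel_mod == 0:
                        continue  # ungapped placements already enumerated exhaustively
                    if aln.score >= min_score:
                        out.append(aln)
                        seen_spans.add((aln.start, aln.end))
    return out


def _alignment_from_path(seq, count, ref, cigar, loc, mods):
    if cigar is None:
        return None
    ref_pos = loc[0] + 1  # 1-based
    n_match = n_mm_plain = n_mm_mod = n_ind_plain = n_ind_mod = 0
    for length, op in _parse_edlib_cigar(cigar):
        if op == "=":
            n_match += length
            ref_pos += length
        elif op == "X":
            for _ in range(length):
                if ref_pos in mods:
                    n_mm_mod += 1
                else:
                    n_mm_plain += 1
                ref_pos += 1
        elif op == "I":  # read base absent from reference: gap sits before ref_pos
            if ref_pos in mods:
                n_ind_mod += length
            else:
                n_ind_plain += length
        elif op == "D":  # reference base skipped by the read
            for _ in range(length):
                if ref_pos in mods:
                    n_ind_mod += 1
                else:
                    n_ind_plain += 1
                ref_pos += 1
    return ReadAlignment(
        read_seq=seq,
        read_count=count,
        gene_id=ref.gene_id,
        ref_kind=ref.kind,
        start=loc[0] + 1,
        end=loc[1] + 1,
        n_match=n_match,
        n_mismatch_plain=n_mm_plain,
        n_mismatch_mod=n_mm_mod,
        n_indel_plain=n_ind_plain,
        n_indel_mod=n_ind_mod,
    )


def best_alignments(alignments: list[ReadAlignment]) -> list[ReadAlignment]:
    """Keep, per read sequence, only the best-scoring placements.

    Multi-mapping across isodecoders is preserved: every placement tying the
    best score keeps the read's full count.
    """
    by_read: dict[str, list[ReadAlignment]] = defaultdict(list)
    for a in alignments:
        by_read[a.read_seq].append(a)
    kept: list[ReadAlignment] = []
    for alns in by_read.values():
        top = max(a.score for a in alns)
        kept.extend(a for a in alns if a.score == top)
    return kept


def binomial_site_pvalue(k: int, n: int, L: int, l: int) -> float:
    """Exact upper-tail binomial probability of >= k of n tags at one position.

    p = 1/(L - l + 1) is the null per-position placement probability for a
    read of length l on a transcript of length L.
    """
    if L < l:
        raise ValueError(f"transcript length L={L} shorter than read length l={l}")
    if l < 1:
        raise ValueError("read length must be >= 1")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    p = 1.0 / (L - l + 1)
    return float(binom.sf(k - 1, n, p))


def classify_tsrna(
    source: tuple[int, int],
    ref: MatureTRNA | TrailerSeq,
    s5: int = 2,
    s3: int = 3,
) -> str:
    """Assign the fragment class from the cleavage-site position.

    Trailer-derived fragments are tRF-1. On the mature tRNA, fragments
    anchored at the 5' end (start within the first ``s5`` bases) are tiRNA-5
    if they end inside the anticodon loop (anticodon-loop cleavage) and
    tRF-5 if they end before it; fragments anchored at the 3' end (end
    within the last ``s3`` bases, the CCA tail) are tiRNA-3 if they start
    inside the loop and tRF-3 if they start after it; anything else is an
    internal fragment, tRF-i.
    """
    start, end = source
    L = ref.L
    if not (1 <= start <= end <= L):
        raise ValueError(f"interval ({start},{end}) outside reference of length {L}")
    if ref.kind == "trailer":
        return "tRF-1"
    loop_s, loop_e = ref.anticodon_loop
    if start <= s5:
        if loop_s <= end <= loop_e:
            return "tiRNA-5"
        if end < loop_s:
            return "tRF-5"
    if end >= L - s3 + 1:
        if loop_s <= start <= loop_e:
            return "tiRNA-3"
        if start > loop_e:
            return "tRF-3"
    return "tRF-i"


def call_tsrnas(
    alignments: list[ReadAlignment],
    refs: dict[tuple[str, str], MatureTRNA | TrailerSeq],
    p_threshold: float = 0.01,
    min_len: int = 14,
    max_len: int = 45,
    count_mode: str = "start",
    unique_tags: bool = False,
    s5: int = 2,
    s3: int = 3,
) -> list[TsRNACall]:
    """Call significantly enriched cleavage positions per transcript.

    For each reference transcript, n is the total tag count mapped to it and
    k the tag count sharing a fragment start (or end, per ``count_mode``);
    each fragment is tested with its own length l. Fragments passing the
    threshold and the length gate become calls; identical sequences from
    multiple tRNAs merge into one call listing all sources.
    """
    if count_mode not in {"start", "end"}:
        raise ValueError("count_mode must be 'start' or 'end'")
    by_ref: dict[tuple[str, str], list[ReadAlignment]] = defaultdict(list)
    for a in alignments:
        by_ref[(a.gene_id, a.ref_kind)].append(a)

    calls: dict[str, TsRNACall] = {}
    for key, alns in sorted(by_ref.items()):
        ref = refs[key]
        weight = (lambda a: 1) if unique_tags else (lambda a: a.read_count)
        n = sum(weight(a) for a in alns)
        pos_of = (lambda a: a.start) if count_mode == "start" else (lambda a: a.end)
        k_at: dict[int, int] = defaultdict(int)
        for a in alns:
            k_at[pos_of(a)] += weight(a)
        for a in sorted(alns, key=lambda a: (a.start, a.read_seq)):
            l = len(a.read_seq)
            if not (min_len <= l <= max_len):
                continue
            if ref.L < l:
                continue
            pv = binomial_site_pvalue(k_at[pos_of(a)], n, ref.L, l)
            if pv >= p_threshold:
                continue
            call = calls.get(a.read_seq)
            if call is None:
                call = TsRNACall(seq=a.read_seq, tsrna_type="", count=a.read_count, pvalue=pv)
                calls[a.read_seq] = call
            src = (a.gene_id, a.ref_kind, a.start, a.end)
            if src not in call.sources:
                call.sources.append(src)
            if pv < call.pvalue:
                call.pvalue = pv
            call.count = max(call.count, a.read_count)
    # classify from the source with the best p-value (recomputed per source)
    out = []
    for call in calls.values():
        types = []
        for gene_id, ref_kind, start, end in call.sources:
            types.append(classify_tsrna((start, end), refs[(gene_id, ref_kind)], s5=s5, s3=s3))
        call.tsrna_type = types[0]
        if len(set(types)) > 1:
            logger.warning("call %s... maps to multiple fragment classes %s; using %s",
                           call.seq[:12], sorted(set(types)), call.tsrna_type)
        out.append(call)
    return sorted(out, key=lambda c: c.seq)


def amino_acid_of(gene_id: str) -> str:
    """Parse the amino-acid label out of a GtRNAdb-style gene id."""
    parts = gene_id.split("-")
    if len(parts) >= 2 and parts[1]:
        return parts[1]
    return "Und"


def name_tsrnas(calls: list[TsRNACall]) -> list[TsRNACall]:
    """Assign reproducible names: tsRNA-<amino acid>-<type code>-<serial>.

    Identical sequences are merged (counts summed, sources unioned, minimum
    p-value retained) before naming; serials are unique within
    (amino acid, type) and assigned in lexicographic sequence order.
    """
    merged: dict[str, TsRNACall] = {}
    for call in calls:
        prev = merged.get(call.seq)
        if prev is None:
            merged[call.seq] = replace(call, sources=list(call.sources))
        else:
            prev.count += call.count
            prev.pvalue = min(prev.pvalue, call.pvalue)
            for src in call.sources:
                if src not in prev.sources:
                    prev.sources.append(src)
    result = sorted(merged.values(), key=lambda c: c.seq)
    serial: dict[tuple[str, str], int] = defaultdict(int)
    for call in result:
        aas = sorted({amino_acid_of(g) for g, _, _, _ in call.sources}) or ["Und"]
        if len(aas) > 1:
            logger.warning("call %s... spans amino acids %s; naming by %s",
                           call.seq[:12], aas, aas[0])
        aa = aas[0]
        code = TYPE_CODES[call.tsrna_type]
        serial[(aa, code)] += 1
        call.name = f"tsRNA-{aa}-{code}-{serial[(aa, code)]:04d}"
    return result


def annotate_whitelist(calls: list[TsRNACall], whitelist) -> list[TsRNACall]:
    """Flag calls whose sequence appears in the experimental whitelist.

    The whitelist catalogues tsRNAs supported by modification-erasing
    protocols (e.g. PANDORA-seq); membership is annotation-only and does not
    rescue sub-threshold fragments.
    """
    wl = {normalize_seq(s) for s in whitelist}
    for call in calls:
        call.whitelisted = normalize_seq(call.seq) in wl
    return calls


def find_tsrnas(
    reads,
    matures: list[MatureTRNA],
    trailers: list[TrailerSeq] = (),
    mod_sites: dict[str, frozenset[int]] | None = None,
    exclusion_refs=(),
    genome=None,
    whitelist=(),
    p_threshold: float = 0.01,
    min_len: int = 14,
    max_len: int = 45,
    max_edits: int = 1,
    min_score: float = 0.0,
    count_mode: str = "start",
    unique_tags: bool = False,
) -> list[TsRNACall]:
    """End-to-end caller: collapse, filter, align, test, classify, name, annotate."""
    if isinstance(reads, dict):
        collapsed = {normalize_seq(s): c for s, c in reads.items()}
    else:
        collapsed = collapse_reads(reads)
    refs = list(matures) + list(trailers)
    collapsed = filter_reads(collapsed, exclusion_refs, genome, keep_refs=refs,
                             max_edits=max_edits)
    ref_map = {(r.gene_id, r.kind): r for r in refs}
    alignments: list[ReadAlignment] = []
    for seq in sorted(collapsed):
        if not (min_len <= len(seq) <= max_len):
            continue
        alignments.extend(
            align_to_trna(seq, collapsed[seq], refs, mod_sites,
                          max_edits=max_edits, min_score=min_score)
        )
    alignments = best_alignments(alignments)
    calls = call_tsrnas(
        alignments, ref_map, p_threshold=p_threshold,
        min_len=min_len, max_len=max_len, count_mode=count_mode, unique_tags=unique_tags,
    )
    calls = name_tsrnas(calls)
    return annotate_whitelist(calls, whitelist)
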