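"""tsRNA target discovery from CLIP tags and CLASH/CLEAR chimeric reads.

Two evidence routes converge on the same duplex model:

* CLIP: Argonaute-bound tags are collapsed, stacked into per-position
  coverage on each target transcript, and local maxima become candidate
  binding peaks; each (tsRNA, peak) pair is then screened for a seed-anchored
  RNA duplex.
* CLASH/CLEAR: ligation chimeras are cleaned of "fake" chimeras (reads that
  are in fact one contiguous genomic fragment), split into a tRNA-matching
  arm (14-40 nt) and a target arm (> 8 nt), and the two arms are screened
  for a duplex.

The duplex model requires the tsRNA seed (positions 2-7) to be a fully
paired contiguous helix, allows a bounded number of interior mismatches and
per-strand bulged bases, and scores stability with a surrogate stacking
energy of -3/-2/-1 per GC/AU/GU pair (+1 per mismatch or bulged base), so
that the default cutoff of -10 demands roughly a 5-7 bp stable helix.
Binding sites are finally filtered on mean per-base conservation > 0.3.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._align import normalize_seq, prefix_match_lengths, revcomp, scan_mismatch, suffix_match_length

logger = logging.getLogger("tsrkit.targets")

#: surrogate pair stabilities (positive magnitudes; score subtracts them)
PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}

MISMATCH_COST = 1.0
BULGE_COST = 1.0


@dataclass
class CLIPTag:
    seq: str
    count: int
    target_id: str
    start: int  # 1-based on the target transcript
    end: int
    strand: str = "+"


@dataclass
class Peak:
    target_id: str
    summit: int
    height: int
    start: int
    end: int
    seq: str = ""


@dataclass
class ChimeraRead:
    seq: str
    tsrna_arm: tuple[int, int]  # 1-based on the read
    target_arm: tuple[int, int]
    source_gene_id: str


@dataclass
class DuplexPairing:
    tsrna_seq: str
    target_seq: str
    pair_map: list[tuple[int, int]]  # (tsRNA pos, target pos), 1-based
    seed_ok: bool
    duplex_score: float
    mismatches: int
    conservation_mean: float | None = None

    @property
    def target_start(self) -> int:
        return min(j for _, j in self.pair_map)

    @property
    def target_end(self) -> int:
        return max(j for _, j in self.pair_map)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_map)


@dataclass
class TargetInteraction:
    tsrna_name: str
    target_id: str
    site: tuple[int, int]
    duplex: DuplexPairing
    evidence: str  # CLIP | CLASH | CLEAR
    experiment_id: str = ""


def collapse_and_filter_tags(
    reads,
    min_len: int = 14,
    trna_refs=(),
    max_edits: int = 1,
) -> dict[str, int]:
    """Collapse reads to unique tags, dropping short and antisense-tRNA reads.

    Only reads on the same strand as the source tRNA transcript can be tsRNA
    fragments; a read that matches a tRNA reference only as its reverse
    complement is excluded.
    """
    counts: dict[str, int] = defaultdict(int)
    n_short = 0
    for r in reads:
        seq = normalize_seq(r)
        if len(seq) < min_len:
            n_short += 1
            continue
        counts[seq] += 1
    refs = [normalize_seq(getattr(r, "seq", r)) for r in trna_refs]
    kept: dict[str, int] = {}
    n_antisense = 0
    for seq, c in counts.items():
        if refs:
            sense = any(scan_mismatch(seq, ref, max_edits) for ref in refs)
            antisense = any(scan_mismatch(revcomp(seq), ref, max_edits) for ref in refs)
            if antisense and not sense:
                n_antisense += 1
                continue
        kept[seq] = c
    logger.info("collapse_and_filter_tags: %d tags kept, %d short reads, %d antisense",
                len(kept), n_short, n_antisense)
    return kept


def coverage_from_tags(tags, length: int) -> np.ndarray:
    """Per-position tag coverage (1-based positions -> index 0..length-1)."""
    cov = np.zeros(length, dtype=int)
    for t in tags:
        cov[t.start - 1 : t.end] += t.count
    return cov


def call_peaks(coverage, min_height: int, target_id: str = "", seq: str = "") -> list[Peak]:
    """Local-maxima peak calling on a coverage vector.

    A summit is a position with coverage >= min_height that is strictly
    greater than both flanking positions (for plateaus, the leftmost plateau
    position; coverage beyond the vector is 0). The peak interval extends
    from the summit while coverage stays >= half the summit height and does
    not rise again; when the half-height regions of adjacent summits would
    overlap, the boundary is drawn at the coverage minimum between them.
    """
    cov = np.asarray(coverage, dtype=float)
    n = cov.size
    summits: list[int] = []  # 0-based
    i = 0
    while i < n:
        j = i
        while j + 1 < n and cov[j + 1] == cov[i]:
            j += 1
        left = cov[i - 1] if i > 0 else 0.0
        right = cov[j + 1] if j + 1 < n else 0.0
        if cov[i] >= min_height and cov[i] > left and cov[i] > right:
            summits.append(i)
        i = j + 1
    peaks: list[Peak] = []
    for s in summits:
        half = cov[s] / 2.0
        lo = s
        while lo - 1 >= 0 and half <= cov[lo - 1] <= cov[lo]:
            lo -= 1
        hi = s
        while hi + 1 < n and half <= cov[hi + 1] <= cov[hi]:
            hi += 1
        peaks.append(Peak(target_id=target_id, summit=s + 1, height=int(cov[s]),
                          start=lo + 1, end=hi + 1))
    # resolve overlaps between adjacent peaks at the inter-summit minimum
    for a, b in zip(peaks, peaks[1:]):
        if a.end >= b.start:
            between = cov[a.summit - 1 : b.summit]
            cut = a.summit + int(np.argmin(between))  # 1-based position of the minimum
            a.end = min(a.end, cut)
            b.start = max(b.start, cut + 1)
    if seq:
        for p in peaks:
            p.seq = seq[p.start - 1 : p.end]
    return peaks


def _pair_weight(a: str, b: str):
    return PAIR_WEIGHT.get((a, b))


def find_duplex(
    tsrna: str,
    target: str,
    max_mismatch: int = 2,
    max_bulge_tsrna: int = 2,
    max_bulge_target: int = 2,
    seed_span: tuple[int, int] = (2, 7),
    energy_cutoff: float = -10.0,
) -> DuplexPairing | None:
    """Best seed-anchored antiparallel duplex between a tsRNA and a target.

    All target registers where the tsRNA seed (positions ``seed_span``) forms
    a contiguous fully paired helix are anchors; each anchor is extended in
    both directions allowing at most ``max_mismatch`` interior mismatches and
    ``max_bulge_*`` unpaired bases per strand (terminal columns must be
    pairs). The best duplex minimises
    (score, -n_pairs, target site start) and is returned iff its score is at
    or below ``energy_cutoff``.
    """
    ts = normalize_seq(tsrna)
    tg = normalize_seq(target)
    s0, s1 = seed_span
    w = s1 - s0 + 1
    if len(ts) < s1 + 1 or len(ts) < 8:
        return None
    n, m = len(ts), len(tg)

    best: list = [None]  # [ (key, pairs, mm) ]

    def consider(score, pairs, mm):
        key = (score, -len(pairs), min(j for _, j in pairs))
        if best[0] is None or key < best[0][0]:
            best[0] = (key, list(pairs), mm)

    def extend_right(i, jr, mm, bt, bg, score, pairs):
        # invariant: the last placed column is a pair -> valid stopping point
        consider(score, pairs, mm)
        if best[0] is not None and score - 3 * min(n - i + 1, jr) > best[0][0][0]:
            return
        mm_left = max_mismatch - mm
        bt_left = max_bulge_tsrna - bt
        bg_left = max_bulge_target - bg
        for x in range(0, mm_left + bt_left + 1):  # tsRNA bases consumed before next pair
            if i + x > n:
                break
            for y in range(0, mm_left + bg_left + 1):  # target bases consumed
                if jr - y < 1:
                    break
                wgt = _pair_weight(ts[i + x - 1], tg[jr - y - 1])
                if wgt is None:
                    continue
                for q in range(0, min(x, y, mm_left) + 1):
                    u, v = x - q, y - q
                    if u > bt_left or v > bg_left:
                        continue
                    penalty = MISMATCH_COST * q + BULGE_COST * (u + v)
                    extend_right(
                        i + x + 1, jr - y - 1, mm + q, bt + u, bg + v,
                        score - wgt + penalty,
                        pairs + [(i + x, jr - y)],
                    )

    def left_options(j_anchor):
        """Completed left extensions over tsRNA positions s0-1 .. 1."""
        opts = [(0, 0.0, [], 0, 0, 0)]  # (npairs, dscore, pairs, mm, bt, bg)
        def rec(i, jl, mm, bt, bg, dscore, pairs):
            if pairs:
                opts.append((len(pairs), dscore, list(pairs), mm, bt, bg))
            if i < 1 or jl > m:
                return
            mm_left = max_mismatch - mm
            bt_left = max_bulge_tsrna - bt
            bg_left = max_bulge_target - bg
            for x in range(0, mm_left + bt_left + 1):
                if i - x < 1:
                    break
                for y in range(0, mm_left + bg_left + 1):
                    if jl + y > m:
                        break
                    wgt = _pair_weight(ts[i - x - 1], tg[jl + y - 1])
                    if wgt is None:
                        continue
                    for q in range(0, min(x, y, mm_left) + 1):
                        u, v = x - q, y - q
                        if u > bt_left or v > bg_left:
                            continue
                        penalty = MISMATCH_COST * q + BULGE_COST * (u + v)
                        rec(i - x - 1, jl + y + 1, mm + q, bt + u, bg + v,
                            dscore - wgt + penalty, pairs + [(i - x, jl + y)])
        rec(s0 - 1, j_anchor + 1, 0, 0, 0, 0.0, [])
        return opts

    for j in range(w, m + 1):  # target position paired with tsRNA position s0
        weights = []
        for d in range(w):
            wgt = _pair_weight(ts[s0 - 1 + d], tg[j - 1 - d])
            if wgt is None:
                break
            weights.append(wgt)
        if len(weights) < w:
            continue
        anchor_score = -float(sum(weights))
        anchor_pairs = [(s0 + d, j - d) for d in range(w)]
        for _, dscore, lpairs, mm, bt, bg in left_options(j):
            extend_right(
                s1 + 1, j - w, mm, bt, bg,
                anchor_score + dscore, lpairs + anchor_pairs,
            )

    if best[0] is None:
        return None
    key, pairs, mm = best[0]
    score = key[0]
    if score > energy_cutoff:
        return None
    return DuplexPairing(
        tsrna_seq=ts,
        target_seq=tg,
        pair_map=sorted(pairs),
        seed_ok=True,
        duplex_score=score,
        mismatches=mm,
    )


def split_chimera(
    read: str,
    trna_refs,
    min_tsrna: int = 14,
    max_tsrna: int = 40,
    min_target: int = 9,
    max_edits: int = 1,
) -> ChimeraRead | None:
    """Split a ligation chimera into its tRNA arm and target arm.

    The maximal read prefix (or suffix) matching a tRNA reference within the
    edit budget becomes the tsRNA arm if its length is within
    [min_tsrna, max_tsrna] and the remainder is at least ``min_target`` nt;
    both ligation orders are searched and the longer valid arm wins.
    """
    seq = normalize_seq(read)
    if len(seq) < min_tsrna + min_target:
        return None
    best = None  # (arm_len, orientation, gene_id)
    for ref in trna_refs:
        plen = prefix_match_lengths(seq, ref.seq, max_edits)
        slen = suffix_match_length(seq, ref.seq, max_edits)
        for arm_len, orient in ((plen, "prefix"), (slen, "suffix")):
            if min_tsrna <= arm_len <= max_tsrna and len(seq) - arm_len >= min_target:
                if best is None or arm_len > best[0]:
                    best = (arm_len, orient, ref.gene_id)
    if best is None:
        return None
    arm_len, orient, gene_id = best
    if orient == "prefix":
        return ChimeraRead(seq=seq, tsrna_arm=(1, arm_len),
                           target_arm=(arm_len + 1, len(seq)), source_gene_id=gene_id)
    return ChimeraRead(seq=seq, tsrna_arm=(len(seq) - arm_len + 1, len(seq)),
                       target_arm=(1, len(seq) - arm_len), source_gene_id=gene_id)


def detect_fake_chimera(read: str, genome, max_edits: int = 1) -> bool:
    """True iff the whole read maps contiguously to the genome.

    A ligation product joins two loci and cannot align end-to-end at one
    genomic position; a read that does is a plain genomic fragment.
    """
    seq = normalize_seq(read)
    for chrom_seq in genome.values():
        for q in (seq, revcomp(seq)):
            if scan_mismatch(q, chrom_seq, max_edits):
                return True
    return False


def conservation_filter(
    interactions: list[TargetInteraction],
    track: dict[str, np.ndarray],
    cutoff: float = 0.3,
) -> list[TargetInteraction]:
    """Keep interactions whose binding site exceeds the conservation cutoff.

    The score is the mean per-base conservation over the reported site;
    positions missing from the track count as 0.
    """
    kept = []
    for it in interactions:
        values = track.get(it.target_id, np.zeros(0))
        s, e = it.site
        site_vals = np.zeros(e - s + 1)
        lo, hi = max(s, 1), min(e, len(values))
        if hi >= lo:
            site_vals[lo - s : hi - s + 1] = values[lo - 1 : hi]
        mean = float(np.mean(site_vals))
        it.duplex.conservation_mean = mean
        if mean > cutoff:
            kept.append(it)
    logger.info("conservation_filter: %d/%d interactions kept at cutoff %.2f",
                len(kept), len(interactions), cutoff)
    return kept


def run_clip_pipeline(
    tags: list[CLIPTag],
    tsrnas: dict[str, str],
    target_seqs: dict[str, str],
    min_height: int = 5,
    track: dict[str, np.ndarray] | None = None,
    conservation_cutoff: float = 0.3,
    experiment_id: str = "",
    all_sites: bool = False,
    **duplex_kwargs,
) -> list[TargetInteraction]:
    """CLIP route: coverage -> peaks -> duplex screen -> conservation filter."""
    by_target: dict[str, list[CLIPTag]] = defaultdict(list)
    for t in tags:
        by_target[t.target_id].append(t)
    interactions: list[TargetInteraction] = []
    for target_id in sorted(by_target):
        seq = normalize_seq(target_seqs[target_id])
        cov = coverage_from_tags(by_target[target_id], len(seq))
        peaks = call_peaks(cov, min_height, target_id=target_id, seq=seq)
        for name in sorted(tsrnas):
            hits = []
            for peak in peaks:
                duplex = find_duplex(tsrnas[name], peak.seq, **duplex_kwargs)
                if duplex is None:
                    continue
                site = (peak.start + duplex.target_start - 1,
                        peak.start + duplex.target_end - 1)
                hits.append(TargetInteraction(
                    tsrna_name=name, target_id=target_id, site=site,
                    duplex=duplex, evidence="CLIP", experiment_id=experiment_id,
                ))
            if hits and not all_sites:
                hits = [min(hits, key=lambda h: (h.duplex.duplex_score,
                                                 -h.duplex.n_pairs, h.site[0]))]
            interactions.extend(hits)
    if track is not None:
        interactions = conservation_filter(interactions, track, conservation_cutoff)
    return interactions


def run_clash_pipeline(
    reads,
    trna_refs,
    genome,
    target_seqs: dict[str, str],
    tsrna_names: dict[str, str] | None = None,
    evidence: str = "CLASH",
    track: dict[str, np.ndarray] | None = None,
    conservation_cutoff: float = 0.3,
    experiment_id: str = "",
    max_edits: int = 1,
    **duplex_kwargs,
) -> list[TargetInteraction]:
    """CLASH/CLEAR route: fake-chimera removal -> arm split -> duplex screen.

    ``tsrna_names`` optionally maps arm sequences to tsRNA names; unnamed
    arms are reported under their sequence.
    """
    interactions: list[TargetInteraction] = []
    n_fake = n_unsplit = 0
    for read in reads:
        seq = normalize_seq(read)
        if detect_fake_chimera(seq, genome, max_edits=max_edits):
            n_fake += 1
            continue
        chim = split_chimera(seq, trna_refs, max_edits=max_edits)
        if chim is None:
            n_unsplit += 1
            continue
        ts_arm = seq[chim.tsrna_arm[0] - 1 : chim.tsrna_arm[1]]
        tg_arm = seq[chim.target_arm[0] - 1 : chim.target_arm[1]]
        placed = None
        for target_id in sorted(target_seqs):
            hits = scan_mismatch(tg_arm, normalize_seq(target_seqs[target_id]), max_edits)
            if hits:
                placed = (target_id, hits[0][0] + 1)
                break
        if placed is None:
            continue
        duplex = find_duplex(ts_arm, tg_arm, **duplex_kwargs)
        if duplex is None:
            continue
        target_id, offset = placed
        site = (offset + duplex.target_start - 1, offset + duplex.target_end - 1)
        name = (tsrna_names or {}).get(ts_arm, ts_arm)
        interactions.append(TargetInteraction(
            tsrna_name=name, target_id=target_id, site=site,
            duplex=duplex, evidence=evidence, experiment_id=experiment_id,
        ))
    logger.info("clash pipeline: %d interactions, %d fake chimeras, %d unsplittable",
                len(interactions), n_fake, n_unsplit)
    if track is not None:
        interactions = conservation_filter(interactions, track, conservation_cutoff)
    return interactions
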