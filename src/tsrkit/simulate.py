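"""Seeded synthetic-data generators for every input the toolkit consumes.

The generators emulate the structure of the real inputs — GtRNAdb-style
gene sets, small RNA-seq libraries containing planted cleavage products on
top of uniform tRNA degradation, CLASH-style ligation chimeras, and a
per-base conservation track — without any download. Background degradation
is modelled as uniform start positions with geometric-tailed lengths, the
simplest model under which the caller's binomial null (uniform placement)
holds exactly, so its type-I error is directly checkable. All output is
bit-reproducible per seed, and every generator returns a ground-truth
manifest sufficient to score precision/recall of downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import revcomp, scan_mismatch
from .reference import MatureTRNA, TRNAGeneRecord, build_mature_trna, extract_trailer

BASES = np.array(list("ACGT"))

#: anticodon -> amino-acid label used for generated gene ids
ANTICODON_AA = {
    "AGC": "Ala", "CGC": "Ala", "GCA": "Cys", "GTC": "Asp", "TTC": "Glu",
    "GAA": "Phe", "GCC": "Gly", "GTG": "His", "GAT": "Ile", "CTT": "Lys",
    "CAA": "Leu", "CAT": "Met", "GTT": "Asn", "TGG": "Pro", "CTG": "Gln",
    "TCT": "Arg", "GCT": "Ser", "TGT": "Thr", "TAC": "Val", "GTA": "Tyr",
}

MOD_TYPES = ("m1A", "m5C", "m7G", "pseudouridine")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_trnas: int = 20
    trna_len_range: tuple[int, int] = (72, 90)
    planted_tsrnas: list[tuple[int, int, int, int]] = field(default_factory=list)
    background_depth: float = 1.0  # expected tags per transcript position
    n_noise_reads: int = 2000
    mismatch_rate: float = 0.01
    mod_sites_per_trna: int = 2
    intron_prob: float = 0.3

    def __post_init__(self):
        if not (0.0 <= self.mismatch_rate <= 1.0):
            raise ValueError("mismatch_rate must be in [0, 1]")
        for p in self.planted_tsrnas:
            if p[3] < 1:
                raise ValueError("planted abundances must be >= 1")


@dataclass
class GroundTruth:
    planted: list[dict] = field(default_factory=list)
    n_background: int = 0
    n_noise: int = 0


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def generate_trna_reference(config: SimulationConfig):
    """Random tRNA-like gene set on a toy chromosome.

    Each gene is 72-90 nt (configurable) with a valid anticodon embedded at
    mid-sequence and, with probability ``intron_prob``, an 8-20 nt intron
    just 3' of the anticodon (where real tRNA introns sit). Genes are placed
    on one toy chromosome with >= 60 nt flanks. Returns
    (genes, modification table, genome dict).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.trna_len_range
    if hi < lo or lo < 40:
        raise ValueError("trna_len_range too small to place an anticodon")
    anticodons = sorted(ANTICODON_AA)
    genes: list[TRNAGeneRecord] = []
    mod_rows = []
    chrom_parts = [_random_seq(rng, 100)]
    pos = 100
    for i in range(config.n_trnas):
        body_len = int(rng.integers(lo, hi + 1)) - 3  # mature body, CCA appended later
        body = list(_random_seq(rng, body_len))
        anticodon = anticodons[int(rng.integers(len(anticodons)))]
        a = body_len // 2 - 1  # 0-based anticodon start, mid-sequence
        body[a : a + 3] = list(anticodon)
        spliced = "".join(body)
        introns: list[tuple[int, int]] = []
        unspliced = spliced
        if rng.random() < config.intron_prob:
            ilen = int(rng.integers(8, 21))
            ins = a + 3 + 2  # 0-based insertion point just 3' of the anticodon
            unspliced = spliced[:ins] + _random_seq(rng, ilen) + spliced[ins:]
            introns = [(ins + 1, ins + ilen)]
        strand = "+" if rng.random() < 0.5 else "-"
        gene_seq_on_chrom = unspliced if strand == "+" else revcomp(unspliced)
        start = pos + 1
        end = pos + len(unspliced)
        chrom_parts.append(gene_seq_on_chrom)
        chrom_parts.append(_random_seq(rng, 100))
        pos = end + 100
        aa = ANTICODON_AA[anticodon]
        gene_id = f"tRNA-{aa}-{anticodon}-{i + 1}-1"
        genes.append(TRNAGeneRecord(
            gene_id=gene_id, amino_acid=aa, anticodon=anticodon,
            chrom="chrT", start=start, end=end, strand=strand,
            intron_intervals=introns, genomic_seq=unspliced,
        ))
        L_mature = len(spliced) + 3
        for p in sorted(rng.choice(L_mature, size=min(config.mod_sites_per_trna, L_mature),
                                   replace=False)):
            mod_rows.append((gene_id, int(p) + 1, MOD_TYPES[int(rng.integers(len(MOD_TYPES)))]))
    genome = {"chrT": "".join(chrom_parts)}
    mod_table = pd.DataFrame(mod_rows, columns=["gene_id", "position", "mod_type"])
    return genes, mod_table, genome


def plant_fragments(matures: list[MatureTRNA], n: int, abundance: int, rng) -> list:
    """Choose ``n`` plausible cleavage products across the gene set.

    Cycles through the fragment classes (5' fragments, 3' fragments reaching
    the CCA end, internal fragments) so planted truth covers the caller's
    classification space. Returns (gene index, start, end, abundance) tuples.
    """
    planted = []
    for i in range(n):
        gi = i % len(matures)
        L = matures[gi].L
        kind = i % 3
        frag_len = int(rng.integers(16, 31))
        if kind == 0:  # 5' end
            start, end = 1, min(frag_len, L)
        elif kind == 1:  # 3' end, includes the CCA tail
            start, end = max(1, L - frag_len + 1), L
        else:  # internal
            start = int(rng.integers(5, max(6, L - frag_len - 4)))
            end = min(start + frag_len - 1, L)
        planted.append((gi, start, end, abundance))
    return planted


def _mutate(seq: str, rng, rate: float, mod_positions=frozenset(), offset: int = 0) -> str:
    """Per-base substitutions at ``rate``, 5x elevated on modification sites."""
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        r = min(0.5, rate * 5) if (offset + i + 1) in mod_positions else rate
        if rng.random() < r:
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def simulate_small_rna_library(
    config: SimulationConfig,
    genes: list[TRNAGeneRecord],
    mod_table: pd.DataFrame | None = None,
    matures: list[MatureTRNA] | None = None,
):
    """Small RNA-seq library: planted tsRNAs + uniform degradation + noise.

    Planted fragments are emitted at their stated abundance with per-base
    mismatches (elevated at modification sites). Background degradation
    draws Poisson(``background_depth``) tags per mature position with
    geometric-tailed lengths in [14, 40]. Noise reads are random non-tRNA
    sequences. Returns (reads, GroundTruth).
    """
    rng = np.random.default_rng(config.seed + 1)
    if matures is None:
        matures = [build_mature_trna(g) for g in genes]
    mods: dict[str, set[int]] = {}
    if mod_table is not None:
        for row in mod_table.itertuples(index=False):
            mods.setdefault(row.gene_id, set()).add(int(row.position))
    reads: list[str] = []
    truth = GroundTruth()
    for gi, start, end, abundance in config.planted_tsrnas:
        mat = matures[gi]
        frag = mat.seq[start - 1 : end]
        gene_mods = frozenset(mods.get(mat.gene_id, ()))
        for _ in range(abundance):
            reads.append(_mutate(frag, rng, config.mismatch_rate, gene_mods, offset=start - 1))
        truth.planted.append({
            "gene_id": mat.gene_id, "start": start, "end": end,
            "seq": frag, "count": abundance,
        })
    for mat in matures:
        L = mat.L
        gene_mods = frozenset(mods.get(mat.gene_id, ()))
        n_tags = rng.poisson(config.background_depth, size=L)
        for pos0 in range(L):
            for _ in range(int(n_tags[pos0])):
                length = 14 + int(rng.geometric(0.25)) - 1
                length = min(max(length, 14), 40, L - pos0)
                if length < 14:
                    continue
                frag = mat.seq[pos0 : pos0 + length]
                reads.append(_mutate(frag, rng, config.mismatch_rate, gene_mods, offset=pos0))
                truth.n_background += 1
    mature_seqs = [m.seq for m in matures]
    while truth.n_noise < config.n_noise_reads:
        cand = _random_seq(rng, int(rng.integers(16, 36)))
        if any(scan_mismatch(cand, ref, 1) for ref in mature_seqs):
            continue
        reads.append(cand)
        truth.n_noise += 1
    return reads, truth


def simulate_chimeras(
    config: SimulationConfig,
    matures: list[MatureTRNA],
    genome: dict[str, str],
    n_true: int = 10,
    n_fake: int = 10,
    n_boundary: int = 4,
    n_targets: int = 5,
    target_len: int = 200,
):
    """CLASH-style chimeras plus target transcripts with embedded sites.

    True chimeras join a tsRNA arm (14-40 nt from a mature tRNA 3' end) to a
    target arm (> 8 nt) in both ligation orders; the target transcripts
    carry the reverse complement of each tsRNA arm so the duplex screen can
    recover the planted site. Fake chimeras are contiguous genome fragments.
    Boundary cases probe the 14/40/9 arm-length gates. Returns
    (reads, target_seqs, truth records, conserved site list).
    """
    rng = np.random.default_rng(config.seed + 2)
    chrom = genome["chrT"]
    target_seqs: dict[str, str] = {}
    conserved_sites: list[tuple[str, int, int]] = []
    truth: list[dict] = []
    reads: list[str] = []

    arms = []
    for i in range(n_true):
        mat = matures[i % len(matures)]
        arm_len = int(rng.integers(16, 26))
        ts_arm = mat.seq[-arm_len:]
        arms.append((mat.gene_id, ts_arm))
    # every embedded site needs its 60-nt slot plus flanks to fit
    target_len = max(target_len, 20 + ((n_true - 1) // n_targets) * 60 + 60)
    for t in range(n_targets):
        target_seqs[f"mRNA-{t + 1}"] = _random_seq(rng, target_len)
    mature_by_id = {m.gene_id: m for m in matures}
    for i, (gene_id, ts_arm) in enumerate(arms):
        tid = f"mRNA-{(i % n_targets) + 1}"
        site_seq = revcomp(ts_arm)
        pos = 20 + (i // n_targets) * 60
        extra = int(rng.integers(3, 6))  # random flank so the arm covers the site
        seq = target_seqs[tid]
        target_seqs[tid] = seq[:pos] + site_seq + seq[pos + len(site_seq):]
        site = (pos + 1, pos + len(site_seq))
        conserved_sites.append((tid, site[0], site[1]))
        # the two flank bases adjacent to the ligation junction must differ
        # from the mature's continuation so the arm split is unambiguous
        mat_seq = mature_by_id[gene_id].seq
        tgt = list(target_seqs[tid])
        for back in (1, 2):
            idx = pos + len(site_seq) + extra - back
            forbidden = mat_seq[-len(ts_arm) - back]
            if tgt[idx] == forbidden:
                tgt[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[forbidden]
        target_seqs[tid] = "".join(tgt)
        tg_arm = target_seqs[tid][pos : pos + len(site_seq) + extra]
        if i % 2 == 0:  # tsRNA-first ligation
            read = ts_arm + tg_arm
            split = (1, len(ts_arm))
        else:  # target-first ligation
            read = tg_arm + ts_arm
            split = (len(tg_arm) + 1, len(tg_arm) + len(ts_arm))
        reads.append(read)
        truth.append({"kind": "true", "read": read, "gene_id": gene_id,
                      "tsrna_arm": split, "target_id": tid, "site": site,
                      "ts_seq": ts_arm})
    for i in range(n_fake):
        flen = int(rng.integers(30, 51))
        pos = int(rng.integers(0, len(chrom) - flen))
        read = chrom[pos : pos + flen]
        reads.append(read)
        truth.append({"kind": "fake", "read": read})
    for i in range(n_boundary):
        mat = matures[i % len(matures)]
        if i % 2 == 0:  # target arm of exactly 8 nt: below the > 8 gate
            read = mat.seq[-20:] + _random_seq(rng, 8)
            truth.append({"kind": "reject_short_target", "read": read})
        else:  # tsRNA arm of 13 nt: below the 14 nt gate
            read = mat.seq[-13:] + _random_seq(rng, 15)
            truth.append({"kind": "reject_short_tsrna", "read": read})
        reads.append(read)
    return reads, target_seqs, truth, conserved_sites


def simulate_conservation_track(
    target_seqs: dict[str, str],
    conserved_sites: list[tuple[str, int, int]],
    high: float = 0.6,
    low: float = 0.05,
) -> dict[str, np.ndarray]:
    """Per-base track: ``high`` on conserved sites, ``low`` elsewhere."""
    track = {tid: np.full(len(seq), low) for tid, seq in target_seqs.items()}
    for tid, s, e in conserved_sites:
        if not (1 <= s <= e <= len(track[tid])):
            raise ValueError(f"site ({s},{e}) outside target {tid}")
        track[tid][s - 1 : e] = high
    return track


def reference_bundle(config: SimulationConfig):
    """Convenience: genes, matures, trailers, modification index, genome."""
    from .reference import load_modification_sites, mod_site_index

    genes, mod_table, genome = generate_trna_reference(config)
    matures = [build_mature_trna(g) for g in genes]
    trailers = [extract_trailer(g, genome) for g in genes]
    sites = load_modification_sites(mod_table, {m.gene_id: m for m in matures})
    return genes, matures, trailers, mod_site_index(sites), genome
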