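# Methods

## Reference construction

A tRNA gene record carries its unspliced, strand-corrected transcript and
1-based closed intron intervals. The mature transcript is the spliced
sequence with the non-templated `CCA` tail appended. The anticodon is
located by searching the spliced sequence for the anticodon triplet and
taking the occurrence nearest the midpoint (the anticodon sits in the
central loop of the cloverleaf; spurious hits near the ends are thereby
rejected). The anticodon loop is taken as the 7-nt window `[a−2, a+4]`
around the first anticodon base — the canonical loop geometry — and both
offsets are configurable, since loop boundaries are a structural
convention rather than an annotation.

tRF-1 fragments derive from the precursor's 3′ trailer, not the mature
tRNA, so a 50-nt genomic window immediately downstream of each gene
(reverse-complemented on the − strand, truncated with a warning at
chromosome ends) forms a second reference per gene.

Modification sites are interpreted on the mature (spliced, CCA-appended)
coordinate system; a converter (`genomic_to_mature_position`) lifts
genomic positions across introns and strand for tables annotated
genomically. Coordinates are 1-based closed everywhere in the API; BED
readers convert at the boundary.

## tsRNA calling

**Null model.** Degradation places a read of length *l* uniformly over
the *L* − *l* + 1 admissible starts of a transcript of length *L*. The
per-position enrichment p-value is the exact binomial upper tail
(`scipy.stats.binom.sf`), with *n* the transcript's total tag count and
*k* the count at the tested start. Each fragment is tested with its own
length *l* (so *p* is per-fragment); *k* aggregates all tags sharing the
start regardless of length. Counting fragment starts is the default
(`count_mode=start`, switchable to `end`), and *n* counts read copies by
default (`unique_tags` switches to distinct sequences).

**Alignment.** Reads are collapsed to unique sequences, screened against
exclusion references (rRNA/snRNA/miRNA/repeat space) and, when a genome is
supplied, against the genome: reads with no genomic match on either strand
are dropped as exogenous — except reads matching the mature/trailer tRNA
space, which legitimately lack a contiguous genomic image (CCA tail,
splice junctions). Placement on the tiny tRNA reference space uses an
exhaustive sliding mismatch scan (vectorised over windows); when the edit
budget (default 1) admits indels, edlib's infix search supplies gapped
placements, rescored by our modification-aware rule: +1 per match, −1 per
plain mismatch/indel, −0.5 when the edit sits on a catalogued modification
site. All placements tying the best score keep the read's full count
(multi-mapping across isodecoders is biological signal here, not noise —
identical fragments from several isodecoders are one molecule).

**Classification.** Per source interval: trailer → tRF-1; start within
the first s5 = 2 bases → tiRNA-5 if the end lies inside the anticodon
loop, tRF-5 if before it; end within the last s3 = 3 bases (the CCA tail)
→ tiRNA-3 if the start lies inside the loop, tRF-3 if after it; otherwise
tRF-i. Every interval receives exactly one class (partition property,
tested exhaustively on a toy tRNA).

**Naming.** `tsRNA-<amino acid>-<code>-<serial>` with codes
5/3/i/1/5i/3i; tiRNA halves get two-character codes so names alone
distinguish halves from tRFs. Identical sequences are merged first
(counts summed, sources unioned, minimal p-value kept); serials are
assigned in lexicographic sequence order within each (amino acid, code)
group, so naming is reproducible regardless of input order. Calls whose
sources span amino acids are named by the lexicographically first, with a
warning. Whitelist membership (catalogues from modification-erasing
protocols such as PANDORA-seq) is annotation-only — it never rescues
sub-threshold fragments.

## Quantification and normalization

RPM = 10⁶·C/N with N the sample's total tRNA-mapped count; N = 0 returns
0 with a warning. The pan-cohort transform is the rank-based
inverse-Gaussian: zᵢ = Φ⁻¹((rᵢ − 0.5)/m) with average ranks, scaled by
max|z| to [−1, 1] (zero vector, with a warning, for constant input). The
0.5 rank offset is one of several standard inverse-normal variants; it is
exposed as a module constant. The transform is applied per tsRNA row of
an RPM matrix; whether to transform per cohort and pool or pool first is
left to the caller, who controls the matrix handed in. Expression
summaries per group are plain mean/median tables — plotting is out of
scope.

## Target discovery

**CLIP route.** Tags are collapsed (reads < 14 nt dropped; reads matching
the tRNA space only antisense are excluded — tsRNA fragments lie on the
source strand), stacked into per-position coverage, and summits are
strict local maxima above `min_height` (plateaus: leftmost position).
Peak intervals extend while coverage stays above half the summit height
without rising again; when two peaks' half-height regions would meet, the
boundary is the inter-summit coverage minimum, so peaks never overlap.

**CLASH/CLEAR route.** A read that maps contiguously to the genome
(either strand, within the edit budget) is a fake chimera — one genomic
fragment, not a ligation product — and is removed. Remaining reads are
split at the maximal prefix or suffix matching a mature tRNA (trailing
mismatches trimmed so a chance edit cannot push the arm past its true
boundary); the split is accepted when the tRNA arm is 14–40 nt and the
remainder is at least 9 nt. Both ligation orders are searched.

**Duplex model.** Both routes screen candidate (tsRNA, target) pairs with
the same seed-anchored search: every target register where tsRNA
positions 2–7 form a contiguous, fully Watson–Crick/G·U-paired helix is
an anchor, extended in both directions through interior mismatches
(≤ 2) and per-strand bulges (≤ 2 bases), terminal columns always pairs.
The score is a surrogate stacking energy, −3/−2/−1 per GC/AU/GU pair,
+1 per mismatch or bulged base; a duplex is reported iff its score is at
or below −10, which demands roughly a 5–7 bp stable helix beyond the
seed. Ties break toward more pairs, then the leftmost target site. The
search is exact: it provably agrees with exhaustive enumeration of all
admissible structures (tested on 500 random and mutated-complement pairs).
This surrogate deliberately trades nearest-neighbour thermodynamic rigor
for exactness, testability and zero external binaries; the weights and
cutoff are parameters.

Binding sites are finally filtered on mean per-base conservation > 0.3
over the reported site (positions missing from the track count as 0). By
default one best site per (tsRNA, target) pair is reported
(`--all-sites` relaxes).

## ceRNA scoring

For every (miRNA, tsRNA) pair with at least one shared mRNA target, the
hypergeometric upper tail of the overlap (`scipy.stats.hypergeom.sf`) is
corrected by Benjamini–Hochberg (statsmodels); pairs at FDR < 0.05 become
"competes" edges in a typed directed graph (networkx) alongside the
supporting "targets" edges. The universe N defaults to the number of
distinct mRNAs observed in either table and is overridable upward; pairs
with zero shared targets are skipped — they cannot reach significance and
would only dilute the correction (skipped count logged).

## Synthetic data

The generators emulate the toolkit's inputs end to end: random tRNA-like
genes (72–90 nt, valid anticodon mid-sequence, 30% carrying an 8–20 nt
intron just 3′ of the anticodon, random strand) on a toy chromosome with
100-nt flanks; modification sites sampled per gene; libraries made of
planted cleavage products at stated abundances (per-base error rate 1%,
five-fold elevated on modification sites), uniform degradation background
(Poisson tags per position, geometric-tailed lengths in 14–40 nt), and
random non-tRNA noise reads; CLASH chimeras in both ligation orders with
embedded reverse-complement target sites, contiguous-genome fake
chimeras, and arm-length boundary probes; and a two-level conservation
track (0.6 on sites, 0.05 elsewhere) that the 0.3 cutoff separates
exactly. The degradation model makes the caller's binomial null literally
true, so its type-I error is directly checkable. Everything is
bit-reproducible per seed, and ground-truth manifests score every stage
without re-deriving truth.

What the generators do *not* emulate: platform-specific error profiles,
adapter artefacts, ligation biases, isodecoder families with near-identical
sequences, or expression heterogeneity across a real transcriptome.
Passing tests therefore demonstrate correctness of the statistics and the
bookkeeping under the stated models, not field performance on real
libraries.

## Evaluation choices and problem sizes

Planted-recovery precision and recall are evaluated at the cleavage-site
level (gene, start position) — the unit the enrichment test discovers;
sequencing-error variants of a planted fragment and low-count tags riding
an already-significant start are not counted as separate discoveries.
Default evaluation sizes: 20 genes with 20 planted fragments at 50× the
per-position background for recovery; 200 four-gene degradation-only
libraries for type-I calibration (checked one-sidedly against the nominal
level, because the discrete binomial test is conservative); 200
permutation-null replicates for ceRNA FDR control; 500 sequence pairs for
duplex-search exactness. At these sizes the whole suite runs in well
under a minute per component. In the sparse-library regime (~1
degradation tag per transcript) the caller is silent on ≥ 95% of seeds;
at realistic depths, chance two-tag pile-ups just below the 0.01
threshold appear at a rate of about one site per 20-gene library, which
bounds attainable precision — the same trade-off the binomial filter
makes on real data.

## Known limitations

- The duplex energy is a surrogate, not ΔG; rankings can differ from
  nearest-neighbour models for GU-rich helices.
- Peak calling is a strict-local-maximum model with half-height
  extension, adequate for sharp CLIP summits but blunt for broad or
  composite peaks.
- Chimera splitting assumes exactly one tRNA arm per read.
- Multi-mapped reads contribute full counts to every tying source; no
  fractional assignment is attempted.
- The caller tests one position per fragment start (or end); joint tests
  over both cleavage ends are not implemented.
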