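# Methods

## The simulated transcriptome

Each gene family starts from one random "parent-1" coding sequence
(uniform base composition, length drawn from `gene_length_range`,
default 400–800 bp). A "parent-2" haplotype is derived by placing
exactly `round((1 − t) · L)` substitutions, where the homeologue
identity target *t* is drawn per family from
`homeologue_identity_range` (default 0.85–0.95). A substituted base is
never the original base, so the realized identity equals the target to
the nearest achievable count: identity has an exact, position-wise
meaning throughout the package because divergence is substitution-only
(indels are deliberately out of scope — percent identity between
homeologues would otherwise depend on alignment parameters, and the
chimera audit below would lose its exactness).

The two haplotypes become the A and B homeologues of species `sp1`. The
sister species `sp2` receives both copies with species-level
substitutions applied at shared ancestral coordinates: outside
parent-divergent sites both copies get the same new base; at
parent-divergent sites the two new bases are kept unequal. This models
divergence that postdates the shared hybridization event and has a
useful exact consequence: homeologue identity is *t* in both species
and orthologue identity is exactly the drawn value (default 0.95–0.99)
for both copies. An independent-mutation scheme would systematically
push the second species' homeologue identity about 2·(1−o) below
target and break the truth invariants.

**Planted identical windows.** To reproduce the regime where two
homeologues share literal identical stretches (the 35–47 bp windows
seen between real homeologue pairs), a configurable fraction of
families receives non-overlapping windows that are excluded from
substitution placement, with one substitution *anchored* at each window
edge. Without the anchors, the mutation-free gaps flanking a window
would extend the identical run past its nominal length and the
"complete single-copy contigs appear only at k > window length" law
would key on an unobservable quantity. Conversely, `max_identical_run`
caps all identical runs (used to build pairs guaranteed free of ≥40 bp
windows for the merge-safety and chimera analyses).

**Expression.** Weights are log-normal. Real RNA-seq abundances span
four to five orders of magnitude, so the generator default is
`expression_log_sd = 2.5`; a configured fraction of genes
(`high_expression_fraction`, default 0.03) is rescaled in closed form so
its *predicted* RPKM (1e9·w / Σ w·L) lands above 1000, guaranteeing the
very-high-expression regime that the correlation analysis excludes.

**Reads.** Source genes are sampled with probability ∝ weight × length,
start positions uniformly, strand with probability 0.5. Substitution
errors follow a two-level per-cycle profile: `pre_knee_error` (default
0.002 ≈ Q27) before the knee cycle and `post_knee_error` (default 0.02
≈ Q17) after it; the knee defaults to cycle 45 for paired-end and 60
for single-end reads. FASTQ qualities are exactly the Phred values
implied by those probabilities, so Q20 trimming removes the post-knee
tail just as it would on real data. The truth table records every
read's source gene, 0-based half-open coordinates and strand.

**Reference library.** Two reference sequences per family (`<fam>|r1`,
`<fam>|r2`), derived from the two parental haplotypes at
`reference_identity` (default 0.96), emulate the union of two close
outgroup species' CDS sets; hits to either collapse to one family.

What the simulator does *not* emulate: indel sequencing errors and
indel divergence, alternative splicing, sequence-composition bias,
duplicated (three-copy) families, and PCR/optical duplicates. Passing
tests therefore demonstrate the parameter-coupling phenomena under
substitution-only divergence, not performance on real libraries.

## Read QC

A read is trimmed to the longest contiguous window in which every base
is ≥ Q20 (inclusive comparison — Q20 is "one error in 100 bases";
leftmost window on ties; configurable via `inclusive=False`). Reads
shorter than 30 bp after trimming are discarded; a pair survives only
if both mates do, otherwise the surviving mate joins the single-end
pool. Provenance counts (kept / demoted / discarded) always sum to the
input count.

## Assembler

K-mers are stored canonically (lexicographic min of k-mer and reverse
complement); k must be odd so no k-mer equals its own reverse
complement. The coverage cutoff *c* removes k-mers seen fewer than *c*
times, before traversal — where in the pipeline a production assembler
applies its cutoff is implementation-defined, and applying it to raw
multiplicities keeps every grid cell a pure function of (reads, k, c).

Traversal emits maximal unambiguous paths: a node is extended only
while it has exactly one surviving successor whose only predecessor is
the node itself, orientation-aware. There is no tip-clipping, bubble
popping or paired-end linkage. The payoff is a provable property:
wherever two homeologues share an identical run of ≥ k bases the walk
meets a branch and stops, so no contig can cross from one copy's
discriminating sites into the other's. The cost is fragmentation —
exactly the trade-off under study. Contigs ≤ 100 bp are discarded;
output is canonical-oriented and sorted (longest first, then
lexicographic) for determinism.

`auto_cutoff` returns `max(2, round(sqrt(median multiplicity of k-mers
seen ≥ 2 times)))`. The formula is this package's own: it is monotone
in depth, floors at 2, and reproduces the qualitative behaviour that
pooling a low-coverage gene set into a high-coverage one collapses the
median and drags the automatic cutoff down to 2.

## Reference mapping and RPKM

Contig-to-reference alignment is seed-and-extend: an exact shared
15-mer (either strand) nominates a reference; the contig is then
aligned end-to-end against a reference substring by banded edit
distance (edlib, infix mode). Identity is matches / alignment columns;
reference coverage is covered reference bases / reference length. "No
shared seed" is reported as *no hit*, distinct from a low-identity hit.
Hits below 80% identity are dropped and only the longest hit per contig
is kept (ties: higher identity, then smaller reference id). A reference
is a **complete transcript** in a cell when some contig covers ≥95% of
it (boundary inclusive).

Read mapping is end-to-end Hamming placement on either strand with
0–3 substitutions, found by pigeonhole seeding: of m+1 disjoint read
chunks one must be error-free, so exact 12-mer seeds from each chunk
enumerate every valid placement; reads too short for the guarantee fall
back to an exhaustive vectorized scan. A read counts once per target it
places on (shared reads between homeologues are a measured phenomenon,
not an artifact to resolve), and counts are non-decreasing in the
mismatch allowance by construction. Percent increases between the
0-mismatch and 3-mismatch counts are truncated toward zero — the only
integer rule consistent with the worked examples (a 2.296 ratio prints
as 229%, not 230%).

RPKM uses M_A = the summed mapped-read count over all targets. In the
study pipeline the targets are one representative full-length contig
per completely assembled gene (the longest contig reaching the 95%
coverage threshold anywhere on the grid), mirroring quantification
against the assembled transcriptome rather than the truth.

## Merging and classification

Contigs whose best hit covers **more than** 55% of a reference (strict,
versus the **at least** 95% completeness rule — both boundaries follow
their respective wording and are configurable) are pooled per family
and merged greedily: the pair with the longest suffix–prefix overlap of
≥40 bp at ≥98% identity merges first; containments are absorbed under
the same identity budget; overlap columns take the first-seen member's
bases (majority-of-two ties). The input pool is canonically ordered
first, so the result is invariant under input permutation. Two pooled
contigs covering >55% of the same reference necessarily overlap by
≥10% of it (2×0.55 − 1), comfortably above the 40 bp floor for any
transcript-scale reference.

One supercontig per family/species is a single-copy call, two a
candidate homeologous pair, more than two a flag (possible chimera or
unmodelled duplication, excluded from pair counts). Cross-species calls
use global (edlib NW) identity: strictly above 95% → orthologue,
otherwise paralogue; symmetric in species order.

**Chimera audit.** Because divergence is substitution-only, the two
true copies align column-for-column and the positions where they differ
are *discriminating*. A supercontig is placed gaplessly (best Hamming
placement, both orientations, against both copies) and is chimeric iff
it matches copy A at ≥1 discriminating position and copy B at ≥1.
This operationalizes "chimera" exactly where the hazard is defined —
sequences mixing copy-specific variants — without an arbitrary window
or score threshold.

## Metrics and the correlation analysis

N50/N90 follow the smallest-contig-covering-≥50%/90%-of-bases
definition; length classes are upper-inclusive with boundaries
100/200/500/1000. The overlap statistic between two assemblies'
complete-transcript sets is `|A∩B| / (|A|+|B|) / 0.5` (1 for equal
sets, 0 for disjoint, undefined for two empty sets); set membership is
by reference id, the deterministic synthetic equivalent of matching
sequences at 100% identity.

For the correlation analysis each gene's profile counts the distinct
k-mer sizes (n_k) and cutoffs (n_c) yielding a complete transcript.
Genes with RPKM strictly above 1000 are excluded; the remainder are
binned by n_k (separately n_c), and Pearson's r is computed between bin
index and the bin's **mean** RPKM over nonempty bins (bin means, not
per-gene values, match the described procedure; a per-gene mode exists
as a separate call path). Fewer than three nonempty bins, or bin means
with zero variance, report r as absent rather than ±1 or NaN.

## Problem sizes

The desk-scale study run behind the correlation test uses 100 families
(200 homeologous genes, 400–800 bp), 2 million single-end 75 bp reads
trimmed at the cycle-60 knee, and a 4×5 grid (k ∈ {25, 31, 41, 51},
c ∈ {2..6}), all seeded. The size is not arbitrary: ΣRPKM over targets
is fixed at ~10^6 / (mean length in kb) regardless of expression
weights, so with only ~10^2 genes the sub-1000-RPKM band is populated
only when mapped depth is high enough that genes at the assembly
threshold (~20× base coverage) sit below 1000 RPKM; 2M reads is the
smallest read set where that band holds enough genes to bin. The
chimera-safety run uses 50 families at 90–95% identity with identical
runs capped at 39 bp, 120k reads, and a 2×2 grid.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open everywhere. Phred encoding is Sanger
offset 33. Empty contig sets report metrics as absent, not zero; an
empty read after trimming is legal; RPKM with zero total mapped reads
is an error; percent increase from a zero baseline is undefined and
reported as `None`. All randomness flows from a single integer seed per
configuration; identical configurations produce byte-identical FASTA
and FASTQ output.

## Known limitations

The assembler is deliberately minimal: no error correction, so
recurring sequencing errors at very high coverage fragment assemblies
(this reproduces, rather than avoids, the fragmentation of very highly
expressed genes at low cutoffs). The aligner assumes transcript-scale,
mostly-colinear sequences; it is not a general-purpose spliced or
protein-level aligner. The merge step is a deterministic stand-in for a
production overlap assembler: thresholds (40 bp, 98%) are honored
bit-exactly but consensus handling is majority/first-seen, not
quality-weighted. The chimera audit requires substitution-only truth
and gapless placement; it is a simulator-side instrument, not a tool
for real data.
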