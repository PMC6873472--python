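# Methods

This note documents the models and procedures the toolkit implements,
the parameters that matter, the design choices made where the underlying
conventions are genuinely open, and the limits of what the synthetic
benchmarks demonstrate.

## Read filtering

Filtering is whole-read and pair-level: a pair is removed if either mate
fails any rule, with no trimming or orphan retention, because the
intended consumer is a de Bruijn assembler fed with intact pairs. Rules
are applied in a fixed order and every removed pair is attributed to the
*first* rule it fails, so per-rule counts are order-dependent (this is
deliberate and matches how filtering pipelines report their logs); the
accounting identity `pairs_in = pairs_kept + Σ removed` holds on every
input.

The rules and their thresholds, per preset:

| rule | test | preset A (cvestalis) | preset B (dcollaris) |
|---|---|---|---|
| N fraction | `count(N)/len > t`, strict | 2% short / 5% large | 2% all |
| low quality | fraction of bases with Phred ≤ 7 `> t`, strict | 30% / 40% | 40% / 60% |
| adapter | ungapped overlap ≥ 10 bp, ≤ 2 mismatches | same | same |
| mate overlap | suffix/prefix overlap ≥ 10 bp, ≤ 10% mismatches (short-insert only) | same | same |
| duplicate | exact `(mate1_seq, mate2_seq)` equality | same | same |
| k-mer frequency | any 17-mer with library count < 4 | inactive | active |

Boundary semantics follow the defining wording: "over" and "more than"
are strict inequalities for the N and quality rules, while the adapter
and overlap lengths are inclusive (an exact 10 bp overlap fails the
read). Quality strings are fixed to Phred+33; Phred ≤ 7 corresponds to a
base error probability ≥ 20%.

Adapter matching scans every ungapped register of the adapter against
the read, including registers where the adapter dangles beyond the 3'
end, and reports a hit when the full overlap at some register has ≤ 2
mismatches over ≥ 10 bp. This is 3'-contamination semantics: a partial
adapter at the read end matches, while an interior adapter-like word
followed by genomic sequence does not (the register's overlap would
extend past it and accumulate mismatches).

Duplicate removal is sequence-only exact matching of the ordered mate
pair: qualities are ignored, and neither swapped-mate nor
reverse-complement duplicates are collapsed — PCR duplicates of the same
fragment sequenced in the same orientation are byte-identical, and a
stricter definition would remove genuine fragments. Duplicate state only
advances for pairs that survive the earlier rules, so a defective copy
of a duplicated fragment is attributed to its defect.

The k-mer frequency rule uses a canonical 17-mer table built from the
raw input library itself; no error-correction pass is applied before
counting. Pipelines that correct reads first will count fewer singleton
k-mers, so this rule's removed counts are an upper bound relative to
corrected workflows; the threshold (< 4) and k are configurable.

## Genome-size estimation

At sufficient depth, the frequency of genomic k-mers is approximately
Poisson around the modal frequency. The estimator is

    G = K_num / K_depth

with K_depth the modal frequency of the canonical k-mer histogram and
K_num the total number of counted k-mers. A read of length L contributes
L − k + 1 k-mers, minus windows containing N. Counting is exact
(sorted-array unique counts over base-4 integer codes, no probabilistic
sketches) and canonical — each k-mer is identified with the
lexicographic minimum of itself and its reverse complement, since
shotgun reads sample both strands; k must be odd so no k-mer is its own
reverse complement. Default k = 17.

Sequencing errors create a spike of low-frequency k-mers. The valley —
the first local minimum of the histogram scanning up from frequency 1 —
separates this error region from the coverage peak; K_num excludes
sub-valley k-mers by default because the Poisson picture only applies
above it, and `include_error_kmers=True` preserves the literal
"total number of k-mers" reading (biased upward in the presence of
errors; both modes are exposed because published estimates rarely state
which was used). K_depth is the argmax at or above the valley, ties
broken toward the smaller frequency; a monotonically decreasing
histogram (no interior peak) raises an error asking for an explicit
valley. On error-free histograms the count rises from frequency 1
toward the mode, so the valley resolves to 1 and nothing is excluded.

Note a small, expected bias: with read length L, per-k-mer depth is
depth × (L − k + 1)/L, and rounding of the integer mode makes recovered
sizes deviate by 1–3% at 50×; the synthetic-recovery tolerance of 5%
reflects this, not noise.

## Contamination screening

Each scaffold is tiled with non-overlapping windows (10 kb and 20 kb are
the conventional sizes at ~100× short-read depth; configurable). A
terminal partial window is kept when it covers at least half a window —
long enough for a stable GC estimate — and windows that are mostly N
(n_frac > 0.5) are excluded from summaries. GC is computed over non-N
bases, so the length-weighted mean of window GC reproduces scaffold GC
exactly; mean depth comes from a bedGraph-like track with uncovered
positions at depth 0.

Flagging is a deterministic surrogate for the visual GC × depth scatter
inspection: per-axis bounds are median ± 5·MAD over usable windows
(auto-bounds refuse to engage below 10 windows), a window is a
contaminant candidate only when it falls outside the bounds on *both*
axes, and scaffolds take the majority label of their windows. Requiring
both axes keeps single-axis excursions (GC-rich host regions, coverage
dips) unflagged; the multiplier 5 puts the cut at ≈ 3.4 σ per axis for
roughly normal scatter. Bacterial contaminants in an insect assembly are
typically separated by ≥ 0.15 GC and several-fold depth, far outside
these bounds. The screen labels scaffolds; it does not assign taxonomy
or decontaminate reads.

## Orthology

Orthologue calling is the operational reciprocal-best-hit definition:
the best hit of each query is the minimal e-value, with ties broken by
higher bitscore, then higher identity, then lexicographic subject id (a
deterministic chain; hit tables carry no natural order), and a pair is
emitted iff each gene is the other's best hit with both e-values
strictly below 0.01. Duplicate (query, subject) rows keep the last
occurrence with a warning, matching append-style workflows. The output
is a partial matching.

The family table is a single-linkage surrogate: an undirected edge joins
two genes when either direction of their hits has e < 1e-7, and families
are connected components of size ≥ 2. This chains cliques through
spurious bridge hits — documented single-linkage behaviour — and exists
so the classifier and Venn counter have a family structure to consume;
tables from tree-aware methods can be supplied in the same shape.

The classifier partitions every gene of every species into exactly one
category, in priority order: **1:1:1** (family with exactly one member
per present genome, at most one genome absent), **N:N:N** (at most one
genome absent, any copy number), **clade-specific** (family confined to
a named clade with at most one absence inside it; clades tried in the
given order and required to span ≥ 2 species), **SD** (family entirely
within one species), **Homology** (no family, but a cross-species hit at
e < 1e-7 in either direction), **Unblast** (no such hit), **Others**
(family members fitting none of the family categories). "Absence in
less than 2 genomes" is read as ≤ 1 absent genome, and the listing
order doubles as precedence since a family can satisfy several
definitions. The cross-species hit requirement is either-direction;
requiring both would only move genes between Homology and Unblast.

Venn counts assign each family to the region given by the exact subset
of the chosen 2–4 species it touches; families outside the subset are
not counted, and all 2^n − 1 regions are reported. Identity
distributions bin the A→B alignment identities of RBH pairs over
[0, 100] and report per-bin probability mass plus mean and median.

## Microsynteny

A block is ≥ 3 orthologue anchor pairs on a single scaffold in each
species, with ≤ 5 intervening gene ranks between consecutive anchors.
Ranks are 0-based order indices along each scaffold, assigned by start
coordinate. Two readings were open and settled as follows: the gap
constraint applies in *both* genomes (the symmetric, stricter reading —
a one-sided mode would accept blocks dispersed in the partner genome),
and collinearity is *not* required, because the definition asks for
clustering rather than order preservation; orientation
(collinear_forward / collinear_reverse / mixed) is reported so a
collinear-only analysis is a one-line filter. Anchors are restricted to
RBH pairs, which sidesteps multi-orthologue ambiguity.

Chaining is greedy along species-A order: within each (scaffoldA,
scaffoldB) group, anchors sorted by rankA are split wherever the gap
test fails between consecutive anchors. Under this cluster-based
definition the greedy split *is* the maximal chaining — no dynamic
program is needed — and the test suite pins this with an independent
exhaustive-split oracle plus a standalone block validator. Each anchor
belongs to at most one block. The syntenic-gene ratio is the fraction of
a species' placed genes that anchor at least one block.

## Synthetic data

The generators produce the study conditions the pipeline is tested
under, with complete truth labels.

**Genomes** are i.i.d. base draws at a target GC — no repeats, no
heterozygosity, no composition structure. **Libraries** sample fragments
uniformly from a circular view of the genome (uniform coverage; linear
sampling would leave contig-edge k-mers under-covered and make clean
reads fail the k-mer rule), orient mates inward (forward–reverse), and
draw clean base qualities uniformly in Q30–40. Defect classes are drawn
per pair and planted at magnitudes chosen once, well beyond every preset
threshold — 10% N, 70% of bases at Q2, a 15 bp exact adapter tail, a
1.5×-read-length insert giving 50% mate overlap, a single random
substitution for the error-k-mer class — and duplicates are byte-exact
copies of clean pairs appended at about `dup_frac` of the pair count.
Default scale for filter benchmarks is a 4 kb genome at 50× (≈ 1,000
pairs, k-mer coverage λ ≈ 42, so genomic 17-mers essentially never fall
below frequency 4); genome-size benchmarks use 100 kb at 50×.

Two guarantees keep truth labels authoritative rather than merely
probable. Originals are resampled on byte-collision, so only planted
duplicates are identical (at 50× on a small genome, fragment start
collisions would otherwise create hundreds of unplanned duplicates); and
with `verify_profile` set, each pair is redrawn until its label equals
the first rule it fails under that profile — without this, roughly 1 in
10³ clean 100-mers contains a chance ≥ 10 bp adapter-like word with ≤ 2
mismatches, which is a property of the rule's literal definition, not an
implementation defect. Duplicates copy clean pairs only, since a copy of
a defective pair would be attributed to the earlier rule.

**Orthology scenarios** split species A's genes into contiguous
segments (one per block) over its scaffolds; species B places each
segment on its own scaffold, reversing it with probability
`inversion_frac`. Genes are then made unalignable (dropped from both hit
tables), relocated in B (`shuffle_frac`, breaking them out of their
block), or duplicated in B (`dup_frac`, an extra copy whose e-value is
≥ 10× worse than the orthologue's, so RBH truth is unambiguous).
Orthologue e-values are drawn log-uniform in [1e-60, 1e-20] and
identities Normal(60, 8) truncated to [0, 100] — the identity scale of
orthologues between confamilial wasp genomes. True blocks are re-derived
from the final gene orders by applying the block definition to the
surviving anchors of each planted segment, so gaps opened by removals or
insertions are respected; one scaffold-pair per block prevents planted
blocks from merging. At high shuffle fractions relocated genes can, in
principle, assemble into coincidental blocks that the truth list does
not contain, so exact-recovery claims are made at `shuffle_frac 0`.

**Contaminated assemblies** append scaffolds whose GC is shifted by at
least 0.10 from the host mean and whose per-kilobase depth segments are
drawn at `depth_shift` × the host mean (5% CV Gaussian noise, host
default 100×).

What passing these benchmarks shows: the rules, estimators and chainers
implement their definitions exactly (oracle equivalence), and recover
planted signal perfectly when the signal is unambiguous by construction.
What they do not show: performance on real libraries with
quality-correlated errors, optical duplicates, repeat- and
heterozygosity-driven k-mer spectra, tandem arrays, or assemblies where
host and contaminant clouds overlap. The generators deliberately omit
those complications; results on real data depend on threshold choices in
ways the synthetic truth cannot probe.

## Numerical and interface choices

- Gene coordinates are GFF3-style 1-based inclusive; window and depth
  arithmetic is 0-based half-open; readers and writers are the only
  crossing points. Ranks within a scaffold are consecutive from 0, with
  start ties broken by end then gene id.
- Benchmark problem sizes (4 kb / 100 kb genomes, 1,000-pair libraries,
  ≤ 300-gene scenarios, 500–1,000 oracle trials) were chosen as the
  smallest scales at which every estimator's statistical regime — k-mer
  coverage λ well above the error threshold, ≥ 10 windows per
  auto-bound fit — is comfortably reached.
- All generators take an explicit integer seed and are deterministic
  given it; library code draws no global randomness.
- Validation errors raise `ValueError` (or a `ParseError` subclass with
  file and record context); the CLI maps them to non-zero exit status.
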