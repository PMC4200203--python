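# Methods

This note documents the models, conventions and design choices behind
`cleavecat`, in the order data flows through the package.

## Coordinates and transcript identity

All internal coordinates are 0-based half-open on the genome forward
strand; GTF (1-based inclusive) is converted at the I/O boundary and BED
and bedGraph are native. A spliced transcript's identity is its intron
chain — the ordered gaps between consecutive exons. Two records with the
same chromosome and intron chain are the same structure regardless of
their terminal exon extents, which assemblers place imprecisely;
single-exon structures are matched by interval with a configurable
±25 bp end slack instead. Strand is three-valued (`+`, `−`, unknown):
the assemblies come from non-strand-specific libraries, so unknown is an
ordinary state, compatible with either orientation wherever strands are
compared.

## Class codes

`classify()` returns exactly one cuffcompare-style code per query against
a reference set, the highest-priority code over all references within
2 kb, with priority `= > c > j > e > o > s > i > p > x > u`. The priority
order is a fixed convention of this package (the code definitions do not
themselves induce a total order). Resolutions of under-specified cases,
chosen once and tested:

* `=` between two single-exon transcripts requires identical exon
  intervals; an empty intron chain alone is not a match.
* `c` (contained) requires the query to have at least one intron — its
  chain must be a contiguous *proper* sub-chain of the reference's and
  its span inside the reference span. Single-exon containment falls to
  `e`/`o`.
* `s` and `x` (antisense codes) require both strands set; unknown-strand
  queries can never be antisense to anything.
* `p` (polymerase run-on) requires a set reference strand — "downstream"
  is undefined otherwise — and places the query within 2 kb past the
  reference 3′ end with no exonic overlap. The window is configurable as
  a module constant.
* The fall-through for a reference within 2 kb that matches no rule is
  `u`, the same code as "no reference nearby".

## Consensus and loci

A structure is retained iff (a) both assemblers detected it in the same
cell, or (b) one assembler detected it in ≥ 2 cells. The retained record
merges terminal extents (widest bounds) over the structure group and
keeps the lexicographically smallest member id, so output is
deterministic. Loci are connected components of the
exonic-overlap-on-compatible-strand graph; unknown strand overlaps both
orientations. This operational definition of "locus" is a package
convention.

## Coverage, integrity and the learned threshold

Coverage tracks are piecewise-constant interval signals (the in-memory
form of a bedGraph). Integrity is the fraction of exonic bases at depth
≥ 1 (the depth floor is a parameter; 1 is the default because coverage
"by reads" states no depth). Max coverage is the maximum per-base exonic
depth. In the pipeline both statistics are evaluated per structure as the
best value over the cells in which that structure was assembled:
single-cell tracks are sparse, and assembly evidence is pooled across
cells, so judging a structure by its best-supported cell matches how the
evidence arose. The threshold learner builds, per reference class
(coding, non-coding), the ROC of max coverage as a score for the
well-reconstructed label (integrity ≥ 0.75), reports the AUC, and picks
the candidate cutoff (a sorted unique score) maximising Youden's
J = sensitivity + specificity − 1, ties toward the smaller cutoff — AUC
itself does not yield an operating point, so a point-picking rule had to
be fixed. The final threshold is the arithmetic mean of the two class
cutoffs; the packaged constant when learning is skipped is
3.77881 reads/base. A class with a single label falls back to the
constant with a warning.

## Strand inference and the basic filters

Strand comes from junction dinucleotides: every intron GT..AG on the
forward strand ⇒ `+`; every intron CT..AC ⇒ `−`; anything mixed or
non-canonical ⇒ unknown. The pipeline drops multi-exon transcripts whose
strand cannot be resolved (their junctions are untrustworthy), while
single-exon transcripts pass through unresolved and are removed by the
next stage, which excludes single-exon and < 200 nt (spliced length)
transcripts; 200 nt exactly is kept.

## Coding potential

The score is a documented stand-in for SVM-based coding-potential
classifiers, preserving their feature semantics (size, coverage and
integrity of the longest ORF) and the published cutoff orientation
(negative ⇒ non-coding; the classification rule is strictly
score < −0.5, so −0.5 itself is coding-side). The functional form is

    score = 1.2·tanh((3L − 150)/120) + 0.8·C + 0.15·start + 0.15·stop − 0.8

with L the longest ORF length in codons (ATG..stop inclusive; stop-less
runs to the sequence end count as integrity-deficient ORFs), C the ORF's
fraction of the transcript, and start/stop the integrity flags. It is
monotone in all features, scores a no-ORF transcript at −1.82 and an
intact > 90%-coverage ORF of a ≥ 300 nt transcript above +1. The trained
SVM and its protein-database features are deliberately not reproduced:
they depend on an external database and a trained model. Real homology
evidence enters through a pluggable oracle (tabular hits → E-values),
removing candidates with any hit at E < 10⁻⁴ from either tool class; the
packaged default oracle returns no hits. Strand-unknown transcripts are
scanned in both orientations and the better-scoring one used.

## Neighbour analysis

Two pairing modes mirror two analyses: gene-body mode (minimal
span-to-span distance < 10 kb, strict inequality, direction ignored,
overlap = 0) and TSS mode (|TSS − TSS| < 10 kb). lncRNA:lncRNA pairs are
not emitted. Pair correlation is Pearson on log₂(FPKM + 0.05); pairs with
a constant profile are flagged undefined and excluded from distributions,
with counts available to the caller. The random null draws, per
permutation, n distinct unordered coding-gene pairs uniformly without
replacement and pools correlations over permutations (default 100). The
orientation convention: distances are measured from the coding gene's
TSS, positive downstream of its transcription direction; opposite
strands with distance ≤ 0 are divergent (bidirectional-promoter
candidates), > 0 convergent, same strand tandem — the ≤ 0 boundary is
this package's resolution of nested/overlapping geometries, stated as a
truth table in the tests rather than inferred intent. Distribution
comparisons use the two-sample KS test.

## Temporal specificity

Per condition c, the score is 1 − JSdist(p, e_c), where p is the
transcript's log₁₀(FPKM + 1) profile normalised to sum 1 and JSdist the
square root of the Jensen-Shannon divergence in base-2 logarithms — so
the distance lives in [0, 1] and exclusive expression scores exactly 1.
A transcript's overall specificity is its maximum over conditions.
Conditions default to individual cells (24 here); a stage-grouped mode
averages FPKM within stage first, for designs mixing embryonic cells
with somatic tissue panels. An all-zero profile scores 0 everywhere:
unexpressed features are maximally non-specific by convention.

## Co-expression network

Signed adjacency a = ((1 + r)/2)^β with β = 6 and unit diagonal. "Signed
correlation raised to a power" is ambiguous — even powers destroy sign —
so the standard signed-network map is the default and the naive r^β is
available behind a flag. The topological overlap is
TOM_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
ℓ_ij = Σ_{u≠i,j} a_iu a_uj. The scale-free fit index bins connectivity
into 10 equal-width bins and returns −sign(slope)·R² from the log-log
regression of bin frequency on mean connectivity.

Module detection is a simplified member of the dynamic tree cut family,
fully specified so it is testable: (1) average-linkage clustering of
1 − TOM; (2) a static cut at the 0.99 quantile of merge heights;
(3) deep split — each branch is recursively re-cut at the largest jump
of its sorted internal merge heights when that jump exceeds 0.03 (a
branch whose agglomeration history jumps consists of a tight core plus
loosely attached material), refusing splits that leave no part of module
size; (4) a branch becomes a module only if it has ≥ 30 genes and is
cohesive — median internal merge height below
min(q05 + 0.55·(root height − q05), 0.9), the relative cap separating
tight branches from the loose background of the same dendrogram and the
absolute cap rejecting "modules" whose members barely co-vary (which is
what an unstructured dataset produces); (5) kME refinement — eigengenes
are recomputed and every gene reassigned to its best-correlated module
if that correlation reaches 0.6, else released to the background (the
analogue of the membership-based assignment stage of the hybrid cut).
The small gap threshold deliberately over-splits: the eigengene merge
step (iteratively merging the most-correlated module pair while
r > 0.75, recomputing after each merge, deterministic label-order
tie-breaks) reunites genuine modules, so over-splitting is harmless
while under-splitting is not. All tie-breaks are lexicographic; the
whole stage is deterministic.

Eigengenes are first principal components of the module's per-gene
standardised expression, unit-normalised, sign-oriented so mean member
correlation is non-negative. kME is the gene–eigengene Pearson
correlation with p-values from the t distribution on n − 2 df (n = 24
samples here); module–trait correlations use the same asymptotics, and a
module is flagged stage-specific at r > 0.7 and p < 10⁻⁴. A permutation
mode was considered and rejected in favour of asymptotics for
determinism at n = 24. Enrichment is the hypergeometric upper tail per
gene set with Benjamini–Hochberg adjustment across sets, a local
replacement for web-service annotation tools.

## The generator: what it emulates, and what it does not

Sampling conventions (defaults; all exposed on `SimulationConfig`):
exon counts are shifted Poisson (2 + Poisson(mean − 2), matching the
target means of 3.7 exons for lncRNAs and 11 for coding transcripts
while keeping everything multi-exonic unless planted otherwise); spliced
lengths are lognormal around 550 nt (lncRNA) and 3162 nt (coding);
introns are uniform with a 160 bp floor (room for the slot-coded
junction-break offsets below). Coding cDNAs carry an intact ORF covering
~85% of the transcript; lncRNA and decoy cDNAs are ATG-free on the sense
strand, so their coding score is the no-ORF floor. Every planted intron
gets canonical donor/acceptor motifs on its strand.

The expression model is lognormal FPKM over latent stage factors: the
24-sample design is 2 WT + 2 dicer-knockout oocytes, 8 two-cell, 6
four-cell and 6 eight-cell cells; six planted modules load on the five
(stage, genotype) groups plus a monotone time trend, with member genes
y = √cor·z + √(1−cor)·ε so pairwise within-module correlation targets
`module_cor` (0.8). lncRNAs get lower baseline FPKM than mRNAs and
stage-restricted members are zeroed off-stage; additional background
lncRNAs are expressed in only 1–3 random cells (the "restricted to an
individual cell" regime). Divergent head-to-head lncRNA:coding pairs
(30% of lncRNAs) are planted with TSS separations mostly 0–400 bp and
lncRNA expression correlated to the partner at r ≈ 0.6; partners are
background coding genes so the pairs do not contaminate module
structure. Intergenic gaps exceed the 2 kb run-on window so planted
novel loci are never in the `p`-code shadow of a reference gene.

Assembler emulation uses common random numbers: detection uniforms are
drawn per (transcript, cell, assembler) independently of the rates and
compared against them, so raising dropout yields a nested detection set
under the same seed — degradation under noise is then a coupling
property, not a statistical accident. Fragmentation drops a terminal
exon and shifts the junction adjacent to the cut by a slot-coded offset
(5 + 3·slot), so fragments of the same parent from different
(assembler, cell) slots never share an intron chain and the consensus
rule rejects them; terminal-end jitter (≤ 15 bp, within the single-exon
slack) accompanies fragmentation and vanishes at rate 0, so degenerate
parameters reproduce the truth exactly. Coverage is piecewise-constant
per transcript per cell, proportional to FPKM with mean
`coverage_depth_expressed` (20): read-level Poisson noise is *not*
simulated, deliberately — the max-per-base filter is about depth levels,
and per-base noise would make the maximum of a background locus grow
with its length, destroying the separation the filter is supposed to
exercise. "Gapped" transcripts are covered over only the first 60% of
each exon (integrity < 0.75 in every cell); noise loci get depth 0.8,
below the 3.77881 floor. Conservation is emitted as ~50 bp
piecewise-constant segments, coding exons from Beta(8, 2)
(phastCons-like) and N(1.5, 0.5) (phyloP-like) versus Beta(2, 8) and
N(0, 0.5) for lncRNAs, with a configurable fraction of segments left
unscored.

`GroundTruth.true_novel_ids` is bookkeeping, not prescription: it is the
set of planted novel lncRNAs that, under the realised draws, satisfy the
consensus rule, reach the coverage floor in an assembled cell, are not
gapped, and pass the structural filters — i.e. the set a correct
pipeline must recover exactly. All randomness flows from one seed
through deterministically spawned sub-streams (one per output kind), and
all writers emit records in sorted order, so a fixed seed gives
byte-identical files.

What passing tests on this generator do **not** show: real single-cell
coverage is bursty and 3′-biased, real assemblers make correlated
structure-dependent errors (not i.i.d. dropout), real FPKM noise is not
lognormal-with-clean-zeros, and real conservation tracks have
genome-scale autocorrelation. The fixtures demonstrate that each rule
implements its specification and that the cascade composes correctly —
not that the thresholds are optimal for any particular real dataset.

## Problem sizes and degenerate inputs

The packaged full-size fixture uses 900 coding genes, 600 lncRNAs and
24 cells on 4 × 4 Mb chromosomes (~1500 genes plus decoys and noise
loci), chosen so every filter removes a non-trivial planted class while
the whole suite — including three full simulate-plus-pipeline runs and
the network analysis — completes in well under a minute. Unit fixtures
are 10–100× smaller. Degenerate inputs are handled by convention rather
than error where a convention is defensible: empty assembler input gives
an empty catalog and an all-zero report; a transcript with no scored
conservation bases is flagged undefined, not zero; an all-zero
expression profile scores 0 specificity; constant profiles yield
undefined correlations and are excluded from distributions with counts
logged; a reference class with one label falls back to the packaged
coverage constant with a warning.

## Known limitations

* The coding-potential score preserves cutoff semantics, not the scale
  of any trained classifier; absolute scores are not comparable to CPC
  output.
* The simplified dynamic cut is validated by planted-partition recovery,
  not label-for-label agreement with any reference implementation; on
  strongly overlapping latent modules (e.g. a late-stage module versus a
  monotone time module) it may return them as one module, which the
  eigengene merge step by design does not undo when their correlation
  exceeds the merge cut.
* FPKM is consumed as given; no quantification, normalisation or batch
  correction is performed.
* The homology filter is only as good as the oracle supplied to it; the
  default null oracle makes it the identity.
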