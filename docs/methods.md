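# Methods

## Coordinate and data model

All internal coordinates are 1-based inclusive, the GFF3 convention, so the
call positions can be reasoned about directly as genomic positions; bedGraph
(0-based half-open) and BED are converted only at the file boundary. Strand
is carried per profile because bedGraph has no strand column: every stranded
library is a pair of files (`.plus`/`.minus`). One replicon is modelled per
run; multi-contig genomes must be split upstream, which keeps every
per-position operation a flat map from position to count. A gene's 5′-most
coding position (the start codon) is its `start` on the plus strand and its
`end` on the minus strand; all windows and distances are mirrored through
that convention. Input bedGraphs are assumed to be already strand-corrected
for protocols that sequence the reverse complement.

## TSS calling

TAP(+) 5′-end positions with at least one read are candidates. Candidates
less than 100 bp apart are chained into clusters (a gap of 99 joins, 100
splits). Within a cluster, sub-clusters are built greedily left-to-right:
the next position joins the current sub-cluster only while the population
standard deviation of the member positions stays below 10 nt. The greedy
scan is deterministic and independent of input order once candidates are
sorted; no specific sub-clustering algorithm is canonical for this rule, and
the greedy form honours the SD bound exactly. A sub-cluster is reported only
when its TAP(+) total exceeds three reads; whether that count filter should
apply at cluster or sub-cluster level is ambiguous, so both are implemented
(`count_filter_level`), with sub-cluster as default since the filter is
naturally read as acting on the unit that emits a site. The emitted position
is the sub-cluster member with the maximum count; ties go to the 5′-most
member, biasing toward the longer transcript, a conservative TU boundary.
Finally a site is discarded when the TAP(−) library has strictly more reads
at that position; ties are retained because only "more" reads in TAP(−)
indicate a processed end.

Genuine initiation produces a step up in RNA-Seq density. The optional
transcriptome-consistency check (`tss_coverage_step`) passes a call when
mean RNA-Seq depth over the 50 nt downstream reaches 1× and is at least
twice the upstream mean. It automates the inspection of calls against the
transcriptome that is otherwise manual; the pipeline can ignore it, record
it, or drop failing calls (`tss_coverage_filter = off | flag | drop`).
Internal TSSs of genuinely nested transcripts can fail this test, which is
why flagging rather than deletion is the recommended mode on real data.

## TEP calling

Only 3′-end positions outside every same-strand gene body are candidates,
except that the 10 bp immediately downstream of a gene's stop codon always
qualify (even when they overlap the next annotation) — terminators sit at
or just past the gene end. The alternative reading, "the last 10 bp inside
the gene", is available by passing a negative-shifted window but is not the
default. Candidates less than 10 bp apart are chained; the cluster is the
full span from first to last read-bearing member, and span positions with
no reads belong to it with count zero. Zero-padding matters: it makes an
isolated spike score far above the cluster mean, which is the intended
behaviour of the score.

The modified z-score of position x compares its count with the leave-one-out
mean and SD over the other span positions (see README for the formulas).
Degenerate cases are defined as: a singleton cluster scores +inf, and a
zero-SD cluster scores +inf when r(x) exceeds the mean and 0 otherwise, so
clean isolated peaks survive on the read-count filter alone and perfectly
flat clusters never pass. Positions with fewer than 3 reads or score below
3 are discarded (both thresholds inclusive on the keep side). For replicate
reconciliation, each pair of overlapping clusters (one per replicate)
defines a selection window, their span intersection; among positions that
survived filtering in *both* replicates inside the window, the one with the
highest read count is emitted. Which replicate's count ranks is not
canonical; the default ranks by the sum of both (`rank = sum | max | r1`),
ties go 5′-most, and duplicates from one cluster overlapping two partners
are emitted once.

## Classification

TSS: a site within 500 nt upstream to 100 nt downstream of a same-strand
gene's start codon is assigned to that gene (nearest start codon when
several qualify, lexicographic gene id on exact ties); per gene the assigned
site with the most TAP(+) reads is primary (P), the rest secondary (S).
Ranking uses TAP(+) counts alone, not pooled TAP counts. Unassigned sites
are internal (I) inside a same-strand gene, antisense (A) inside an
opposite-strand gene, else intergenic (N); assignment takes precedence over
the positional fallbacks.

TEP: rules are evaluated in the order C, P/S, A, N. A site lying between a
gene's primary TSS and that gene's start codon, at least 60 nt from the
TSS, is cis-regulatory (C) — C is tested first so 5′-UTR-internal ends are
not absorbed by an upstream gene's primary call. Otherwise a site less than
500 nt downstream of a same-strand gene's 3′ end is assigned to the nearest
such gene; the assigned site with the highest combined replicate count is
primary. Antisense requires lying strictly inside the opposite-strand gene
body (no flank). Categories always partition the input, and each gene has
at most one primary TSS and one primary TEP.

## TU assembly

From every P/S/I TSS the builder walks downstream gene by gene on the TSS
strand (starting at the assigned or host gene), stopping at the first
intergenic gap above 500 bp; the valid extent ends 500 bp past the last
chained gene's stop codon. Every TEP inside the extent closes one TU, so
nested and overlapping variants are enumerated rather than only the
farthest — loci genuinely carry overlapping transcripts sharing genes.
Cis-regulatory TEPs pair only with TSSs assigned to their own gene.
Antisense/intergenic TSSs scan 1 kbp downstream: the first TEP closes a
gene-less TU; if a gene start codon appears first, the walking rules take
over from that gene. Taking only the first TEP (not all within 1 kbp) is
the default (`scan_all` overrides).

Associated genes are the same-strand genes fully inside the TU span,
excluding the host gene of an internal TSS. One gene makes the TU
mono-cistronic, several poly-cistronic; a gene-less TU is cis-regulatory
when the next same-strand gene start lies within 500 bp of the TSS, else
sRNA. The RNA-Seq consistency score of a TU is the fraction of span
positions with depth at least 1×; TUs scoring below 0.9 are flagged, never
silently removed. TU clusters are the connected components of the TU–gene
bipartite graph (union–find); gene-less TUs are singletons. A TEP inside a
TU together with a coverage step is reported only as a diagnostic of
possible endonucleolytic processing, never used to split a TU
automatically.

## Synthetic data

The generator plants operons along a random genome (default GC fraction
0.72, the regime of GC-rich actinobacteria): operon sizes 1/2/3 with
probabilities 0.75/0.15/0.10, intra-operon gaps 20–400 bp (at most 500, so
the assembler's walk can cross them), inter-operon gaps 700–1500 bp (always
above 500, so walks stop between operons and each operon's sites stay clear
of its neighbour's). Each operon receives one TSS — at the start codon for
a leaderless fraction of 0.20, otherwise 10–300 nt upstream — and one TEP
20–200 nt past the last stop codon. With probability 0.3 an intra-operon
gap carries an additional 3′ end, the signature of a processed
poly-cistronic transcript, which adds an overlapping prefix TU to the
ground truth and gives TU clusters with more genes more member TUs. Start
and stop codons are planted in the sequence (ATG/GTG/TTG at 0.7/0.2/0.1).

Profiles: every true TSS emits Poisson(mean 10) TAP(+) reads spread by
integer-rounded Gaussian jitter (SD 1 nt); TAP(−) receives a per-read
binomial thinning (p = 0.2) of the same reads. Processed 5′ ends are
planted uniformly at 0.01 sites/kb/strand with independent equal-mean peaks
in both TAP libraries — the contrast the TAP filter exploits, and the main
source of designed false positives. Both Term-Seq replicates draw
independent Poisson(10) counts exactly at each true TEP. All end libraries
add uniform Poisson background (0.01 reads/nt). RNA-Seq coverage is a
Poisson plateau per TU between TSS and TEP (per-TU level lognormal around
50×); Ribo-Seq covers each CDS at the TU level times the gene's true TE
factor (lognormal, log-SD 0.5). `noise_free=True` replaces every count by
its expectation and suppresses jitter and background, enabling exact
recovery checks.

What the simulation does not emulate: read-length effects and mapping
artifacts, rRNA contamination, growth-phase mixtures, condition-dependent
TU switching, Rho-dependent versus intrinsic terminator sequence context,
and gene-dense overlaps between strands. Passing recovery tests therefore
demonstrates the correctness of the algorithms under the stated statistical
assumptions, not performance on real libraries.

## Benchmark conditions and numerical choices

The recovery benchmark used by the test suite simulates 200 genes on a
400-kb genome (seed 42) with peak means of 10 reads, 1-nt jitter and
0.01 reads/nt background; both callers must recover at least 95% of planted
sites within 2 nt with at most 5% spurious calls, with the TSS list taken
after the transcriptome-consistency check in `drop` mode (on this
benchmark the check removes background clumps and about half of the
processed sites, which pass the TAP comparison by chance, while leaving
every recovered true site in place). The noise-free variant of the same
configuration — and additionally no processed sites, which are confounders
rather than noise — must reproduce the planted sites and TUs exactly. The
problem size keeps the full suite under a minute of simulation time while
leaving several thousand background reads per library to stress the
callers.

Translation efficiency is reported as the ratio of per-gene RPKMs, with
read counts derived from coverage as summed depth divided by the read
length (default 50 nt, matching short-read Ribo-Seq/Term-Seq libraries);
each library is normalised by its own total by default, so planted TE
factors are recovered on their own scale only when both libraries are
normalised identically (explicit `total_rna`/`total_ribo`), while TE ratios
between genes are normalisation-free. TE is undefined (NaN) for genes with
zero RNA-Seq RPKM rather than an error.

Promoter windows are inclusive of their quoted endpoints: the −10 search
window spans 20 bp upstream through 1 bp downstream of the TSS (22 nt
including the TSS itself), the −35 window 40 through 25 bp upstream
(16 nt); terminator context spans 41 bp upstream through 20 bp downstream
of the TEP, with the upstream 41 nt emitted separately for folding-energy
prediction. RBS windows take up to 25 UTR nucleotides ending at the start
codon, only for genes whose 5′-UTR exceeds 10 nt. The spacer between
promoter elements counts the nucleotides strictly between the −35 element's
3′ end and the −10 element's 5′ end; overlapping elements report 0 with a
warning. The intergenic background sampler for nucleotide enrichment
excludes positions inside any gene on either strand and is seeded for
reproducibility.

## Known limitations

Motif inference, RNA folding, and functional enrichment are out of scope:
the package emits the exact sequence windows those external tools consume.
The Term-Seq score cannot distinguish termination from processing — by
construction every reported TEP is simply a reproducible transcript 3′
boundary. All coordinates assume a single replicon; chromosome ends are
handled by dropping windows that would run off the sequence, not by
wrapping.
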