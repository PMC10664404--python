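# Methods

This note records the models, conventions and numerical choices behind
`pithorep`, and what the synthetic data do and do not establish.

## Repeat detection

**Self-alignment.** The internal aligner is a seed-and-extend word
matcher: exact words (default 11 nt, the classic BLASTN minimum) are
hashed over the forward sequence and its reverse complement; seed pairs
sharing a diagonal are merged into segments and extended without gaps
under an X-drop rule (match +1, mismatch −2, X = 25; N mismatches
everything). E-values use the ungapped Karlin–Altschul statistics for
these scores (λ = 1.28, K = 0.46) with search space L², and hits are
kept at E ≤ 10⁻¹⁰. The trivial full-length self-hit never arises because
forward seed pairs are restricted to strictly positive diagonals;
symmetric duplicates are canonicalized (query interval leftmost) and
deduplicated. An external BLASTN-compatible aligner can be substituted
by importing its 12-column tabular output; the internal backend is
validated against an exact quadratic-time ungapped local-alignment
oracle on small genomes. Ungapped extension is a deliberate choice: the
repeat copies diverge almost exclusively by substitutions and terminal
truncation, and gapped extension would bridge the short random spacers
between adjacent elements, erasing the unit-boundary signal that step
(iv) depends on.

**Coverage and regions.** Every hit increments the coverage vector *y*
over both its query and subject intervals; Σ*y* therefore equals the
summed hit lengths exactly (a tested invariant). *y*, its smoothed form
*ys* (circular centered sliding mean, window 500 nt) and the derivative
are all computed on the circular sequence; threshold crossings are
reported on linearized coordinates, with runs crossing the origin split
and flagged. τ = mean(*ys*)/sensitivity: the alternative affine reading
(mean × sensitivity − 1) is available as `tau_mode="affine"`, but a
larger "sensitivity" must lower the threshold for the name to make
sense, so division is the default. Runs shorter than window/5 are
suppressed as single-crossing noise (configurable).

**Units.** Within a region, unit boundaries are strict local maxima
(plateaus resolved leftmost, for determinism) of the twice-smoothed
absolute first difference of *y* (window 20 nt before and after
differencing, |·| taken between the two smoothings) that exceed the
cutoff 10. Maxima closer than the derivative window are merged to the
strongest: the down-step of one element and the up-step of the next are
a few nt apart and describe one junction, not two. Flanking units whose
mean raw coverage stays below τ are threshold-crossing overhang (the
sliding window smears each region boundary by up to half the window)
and are dropped; refined region bounds are then the span of the
retained units. A region with no internal boundary yields a single
unit.

**Scale dependence.** With a sharp coverage step of height *h*, the
twice-smoothed |derivative| peaks near *h*/20, so the printed cutoff 10
expects steps of roughly 200 alignments — the regime of a genome with
several hundred copies per family. On much smaller simulations (tens of
copies) junction peaks fall below the cutoff and adjacent units merge;
test fixtures therefore keep copy numbers in the realistic range.
Junctions whose element end/start steps balance almost exactly can
cancel within the 20-nt smoothing window; with ~100 regions the
expected imbalance (#M1 − #M2 ≈ number of regions) keeps most junctions
above cutoff, but occasional family-consensus draws leave a few percent
of junctions marginal. This is a known limitation of the printed
parameter set, not of the implementation.

## Repeat clustering and grammar

Global identities follow the EMBOSS-needle convention: Needleman–
Wunsch with match +5 / mismatch −4, affine gaps 10 open / 0.5 extend,
end gaps free, identity = matches over all alignment columns including
end gaps. The default engine is Biopython's `PairwiseAligner` with that
scoring; for unit sets larger than 200 the pairwise matrix switches to
edlib's unit-cost global alignment with the same matches-over-columns
identity (~30× faster). At the divergences that matter near the 70%
membership threshold the two backends agree to < 2 identity points, and
a test asserts they produce identical partitions on mixed-family sets.

Greedy clustering processes units in ascending mean distance
(100 − identity) to their 10 nearest neighbors (all available neighbors
when fewer than 10), ties broken by genomic coordinate; each unit joins
the first reference at ≥ 70% identity or founds a new cluster. Clusters
merge when more than half of *each* cluster's members reach 70% to the
other's reference (both directions, transitively closed; the merged
cluster keeps the larger constituent's reference). Labels: largest
cluster M1, second M2, smaller clusters whose reference aligns to one
of those references at ≥ 70% become "M1-like"/"M2-like"; supplying a
reference FASTA overrides the size rule.

Grammar validation checks, per region, that (1) M2 never occurs
without M1, (2) M1 may stand alone, (3) consecutive M1 copies are
separated by ~140 nt — measured end-to-start, since a 145 nt element
cannot have 140 nt start-to-start spacing — within a ±60 nt band, and
(4) any two M2 copies have an intervening M1. TSDs are the longest
exact duplication (≤ 6 nt) immediately flanking an interval, read on
the circular sequence. TIR length maximizes matches-minus-edits among
prefix lengths whose banded alignment to the reverse-complemented
suffix reaches 80% identity; maximizing identity alone would
over-extend past the true TIR, since identity decays slowly once the
TIR ends. Near-homopolymer units are guarded to (0, length).

## Synthetic data

The generator plants what the analyses assume: a circular genome
(default 600 kb) of i.i.d. background at GC 0.36 with 100 repeat-rich
regions of structure (M1-M2){n}-M1, n uniform on 1..8. Family consensi
are random palindromes (TIR + internal + reverse-complemented TIR; M1
54/37, M2 47/37) drawn at GC 0.24 — repeat arrays in these genomes are
markedly AT-richer than their background, which is also why masking
repeats raises genome GC. Each copy is the consensus mutated at the
per-site divergence rate (default 2%) and truncated by 0–4 nt at each
terminus; spacers between consecutive M1 copies carry the M2 element
with flanking "TA" TSDs and jitter around a median of 140 nt; regions
are flanked by "TA" and separated by ≥ 800 nt of background. Spacer
jitter and terminal truncation are essential realism, not decoration:
with perfectly regular arrays every cross-copy alignment runs through
whole regions on a single diagonal and the unit-boundary derivative
signal vanishes. An optional per-region consensus drift makes repeats
from the same region more similar than repeats from different regions,
reproducing the within- vs between-region identity contrast of real
arrays. Genes are interval annotations tiled at a target density, so
gene-level statistics can be scored against planted in-region flags.

What the simulations do not emulate: insertions/deletions inside
elements, partial or nested elements, satellite-like higher-order
structure, compositional heterogeneity of the background, or any
transcription/annotation signal. Passing the planted-recovery tests
therefore shows the pipeline is correct and well-calibrated for
substitution-plus-truncation divergence at realistic copy numbers; it
does not certify performance on heavily indel-diverged repeats.

HOG matrices: every genome carries all core HOGs; a finite accessory
pool is shared with presence probability 0.5 per genome (a closed
pan-genome); per-genome novel HOGs arrive at a constant (or power-law
decaying) rate (an open pan-genome); duplications add a chosen fraction
of extra gene slots to present HOGs. CDS pairs evolve from a common
ancestor by proposed point mutations accepted always when synonymous,
with probability ω when nonsynonymous, never into stops.

## Comparative statistics

**Rarefaction and openness.** Core/pan/new counts are exact over all
genome orderings up to a cap (default 5000), beyond which a seeded
uniform sample of orderings is used. Heaps' α is fitted by log–log
least squares to the permutation-averaged new-HOG curve, excluding the
first genome (where "new" is the whole genome) and zero steps; no new
HOGs at all yields α = +∞ (closed). `n_perm=0` fits the given genome
order once — the only regime in which a generation-order decay exponent
is identifiable, because per-genome-unique novelty is exchangeable
under permutation and permutation-averaged curves are flat regardless
of the planted decay.

**Duplication.** Default counts copies in excess of one per HOG per
genome over total genes; the alternative reading (all members of
multi-copy HOGs) is `mode="multi"` and shifts values upward.

**RSCU.** Whole-genome codon counts; RSCU(c) = count(c)·n_syn/count(aa).
Stop codons and the single-codon Trp/Met families (whose RSCU is
identically 1) are excluded, leaving 59 informative codons; family
means equal 1 whenever the family occurs (tested exactly).

**AAI.** Reciprocal best hits by local protein alignment (BLOSUM62,
gap 11/1); pairs kept at identity ≥ 15% over the alignment and aligned
columns covering ≥ 0.4 of the shorter protein (the "aligned fraction"
reading of the length filter); AAI is the mean identity of reciprocal
pairs averaged over both directions.

**dN/dS.** The Nei–Gojobori (1986) counting method with Jukes–Cantor
correction replaces likelihood engines: deterministic, dependency-free
and sufficient for the rank-based in/out comparisons it feeds.
Conventions follow the reference counting implementations — each codon
position contributes one site split by the synonymous fraction of its
three neighbors, mutations into stops count as nonsynonymous, and
differences average over all shortest codon paths; our estimates match
Biopython's NG86 to machine precision on simulated pairs (a tested
dual-route check). Pair estimates are accepted when 0.1 < dS < 1.5 and
ω < 10; per-gene values are means over accepted pairs.

**Contingency tests.** Pearson χ² without continuity correction
(optional Yates flag); Cochran–Armitage uses integer scores 0..k−1 over
ancestry nodes ordered ancient→recent (root-to-focal-leaf path; a
gene's node is the LCA of the genomes in its HOG, including the focal
genome), two-sided normal p; both are validated against permutation
oracles. Gene-in-region assignment uses midpoint containment by default
so each gene lands on exactly one side (any-overlap is available).
Modified bases are positions with IPD ratio > 4.5; the
conservative/creative halves are user intervals, with a helper that
splits the circle at the 21-gene core-density extremes. P-values are
reported raw, uncorrected.

## Determinism

Every stochastic component (generators, ordering subsampling,
permutation tests, pair subsampling) takes an explicit integer seed;
identical seeds give byte-identical outputs, and the CLI logs the seed
of every run.
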