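# Methods

`mhcloci` infers a lower bound on the number of loci of a multi-copy gene
(the motivating case is teleost *MHC* class II *B*) from cloned allele
sequences, when no reference genome or BAC library resolves the loci
directly. This note records the models, conventions and design choices
behind each stage, and what the simulation-backed tests do and do not
establish.

## The inference problem

Cloning and sequencing a multigene family from diploid individuals yields
a set of sequence variants ("alleles") with no locus labels. Two facts
constrain the unknown locus number:

1. a diploid individual carries at most two alleles of any one locus, so
   an individual with *k* validated alleles implies at least ⌈*k*/2⌉ loci;
2. a candidate locus group is only credible if it never holds more than
   two alleles of the same individual.

The pipeline operationalises the second fact as a hard constraint on
agglomerative clustering and reports the resulting group count, anchored
on the most allele-rich individual, as a **minimum** locus estimate. It is
a lower bound by construction: two closely related loci whose alleles
intermingle cannot be split on sequence distance alone, and the output is
labelled accordingly (`estimate_is_lower_bound`).

## Clone-support validation

PCR and cloning introduce per-molecule errors, so a sequence is accepted
as a real allele only when at least `min_support` (default 3) identical
clones from a single individual carry it; sequences seen in only one or
two clones are listed in a discard report, as is any sequence containing
N. Support is counted within individuals because each individual's clone
set is an independent experiment; once an allele is validated anywhere,
every individual contributing at least one clone is recorded as a carrier.
A sequence observed twice in each of two individuals (total four clones,
never three in one) is discarded but flagged with a distinct reason so the
borderline case is visible. Comparison is exact string identity — the
validation rule itself is the error filter, and error-tolerant collapsing
would blur the allele/artifact boundary it is meant to draw.

## Exon–intron annotation

Genomic alleles are annotated by spliced alignment of a cDNA: maximal
exact matches are chained in order, with gaps allowed only where the
genomic sequence offers a canonical GT…AG intron, every exon of a
multi-exon chain at least `min_exon` (default 20) nt. Among valid chains
the aligner prefers fewest introns, then leftmost intron starts, making
the output deterministic; the search is exhaustive with memoisation,
which is inexpensive at single-gene scale (≤ ~5 kb). Mismatch tolerance
is zero by default because cDNA and gDNA from the same allele and
individual should agree exactly; cross-allele annotation would need a
budget and is deliberately not the default. Only the forward (mRNA-sense)
strand is handled. If no GT–AG-consistent chain covers the cDNA the error
carries the longest partial match found.

The peptide binding region (PBR) is identified with the cDNA span of
exons 2–3, clipped to the ORF and snapped outward to whole codons of the
ORF frame (start rounded down, end rounded up) so the codon-based test
sees complete codons. The PBR and non-PBR intervals exactly tile the ORF;
the terminal stop codon is inside the partition but is dropped pairwise by
the codon statistics.

## Polymorphism and the codon-based selection test

Equal-length allele sets (the usual case: full-length cDNAs of one gene)
are stacked positionally; ragged inputs go through progressive pairwise
alignment (match +1, mismatch −1, gap open −5, gap extend −1, guide order
= input order) against a running consensus. A column is polymorphic when
it holds two distinct unambiguous bases among non-gap residues.

Synonymous/nonsynonymous analysis follows Nei–Gojobori (1986) counting:

- per-codon site fractions enumerate the nine single-base neighbours;
  changes creating stop codons are excluded from the denominator (the
  common MEGA convention; `stops="nonsyn"` switches to counting them as
  nonsynonymous);
- multi-hit codons average synonymous/nonsynonymous steps over all
  minimal substitution pathways that avoid stops, equally weighted; if
  every pathway passes a stop (rare) all pathways are used;
- codons containing gaps, N or stops in either sequence of a pair are
  dropped pairwise, maximising usable data;
- proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
  d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 yields an undefined (NaN) distance
  with the raw proportion retained.

The region-restricted test reports dN and dS as means of the pairwise
distances over all sequence pairs. The standard error of dN − dS comes
from a seeded bootstrap over codon columns (default 1000 replicates,
implemented as multinomial column weights, identical in distribution to
index resampling and much faster), Z = (dN − dS)/SE, and the p-value is
the one-tailed normal tail for H1: dN > dS — one-tailed because the
hypothesis of interest is positive selection on the PBR. The test is
bit-for-bit reproducible given inputs, replicate count and seed. Under
neutral simulation (20 sequences × 200 codons, substitutions accepted
regardless of coding effect) the empirical type-I error at p < 0.05 sits
near the nominal 5% (the acceptance suite checks 200 replicates against
the band [0.02, 0.08]).

Substitution nomenclature uses 1-based ORF coordinates for nucleotides
("242A>G") and Met-numbered protein positions ("E74G"); numbering from
the initiator Met rather than the mature peptide is a convention choice,
recorded here because signal-peptide-relative numbering is also seen in
the literature.

## Locus grouping

Pairwise p-distances (mismatched columns / compared columns, gap columns
excluded) feed average-linkage agglomeration in which a merge is refused
whenever the merged cluster would hold more than two alleles of any
individual; merging continues until no legal merge remains, with ties
broken by the lexicographically smallest label pair. When full-length and
partial alleles are mixed, distances are taken over the shared annotated
exon span. A neighbor-joining tree over the same matrix is emitted for
inspection, with negative branch lengths clamped to zero; tree estimation
is presentation, not inference — the constraint logic, not the tree
estimator, carries the locus deduction, which is why no Bayesian tree
machinery is re-implemented. A NEXUS export (data block plus a
GTR+gamma MrBayes stub) lets users rebuild a posterior tree externally.

Two refinements matter in edge cases:

- **Isolated alleles.** An allele whose nearest neighbour lies beyond the
  `outlier_quantile` (default 0.90) of all pairwise distances is set
  aside as `unassigned` *before* clustering: absorbed into a group it
  would only dilute the evidence, and left as a singleton it would
  inflate the group count. The pre-clustering placement is deliberate —
  greedy merging would otherwise always absorb such alleles, and the
  quantile default mirrors excluding a couple of orphans out of ~28.
- **Greedy deadlock.** Constrained agglomeration is not guaranteed to
  reach the minimum legal group count: three clusters can be pairwise
  blocked by three different individuals while a legal two-group
  partition exists. When the greedy count exceeds the per-individual
  lower bound and at most `exact_limit` (default 10) alleles are
  assigned, an exhaustive branch-and-bound over legal partitions replaces
  the greedy result (fewest groups, then smallest within-group distance
  sum). Small inputs therefore come with a minimality guarantee; large
  inputs keep the greedy behaviour.

The reported estimate is max(number of groups containing an allele of the
most allele-rich individual, ⌈max per-individual allele count / 2⌉).
Anchoring on one individual mirrors how the deduction is actually made
from such data — groups not touched by that individual may be loci it
does not carry, but they are not evidence it does — and the ceiling bound
guarantees the estimate never falls below what allele counts alone imply.

## Tandem repeats and intron profiling

Locus-diagnostic intron length differences in this gene family are driven
by repeat copy number (a GT microsatellite, the decamer GTCCAGTTGA, the
16-mer ACCTGTCTGTCTGCTC), so the profiler detects repeats with a
period-*u* self-match scan: positions matching the base *u* earlier form
runs, runs merge across impurities while purity stays ≥ `min_purity`
(default 0.85, admitting slightly degenerate real repeats), and calls
need ≥ 2 copies (≥ 6 for homopolymers, which are otherwise noise). The
repeat unit is read from the middle of the run (merged spans can start a
few impure bases into the flank) and reported in its lexicographically
smallest rotation so calls are phase-invariant; non-primitive units
(powers of a shorter unit) are discarded in favour of the shorter period.
Overlapping calls keep the larger purity × span, ties to the shorter
unit. This is a deliberately simple autocorrelation detector, not a
reimplementation of alignment-scored tools such as Tandem Repeats Finder:
the repeats of interest are short and near-perfect, where the two agree.

The intron table lists, per allele × intron, the length and the dominant
(largest-span) repeat call, requiring all models to share one exon count.

## The synthetic-data generator

The simulator emulates the data-generating process the pipeline assumes,
with defaults fixed to the motivating study's conditions:

| parameter | default | rationale |
|---|---|---|
| loci × individuals | 4 × 8 | study scale for the diploid panel |
| allele pool per locus | 4 | a handful of segregating alleles per locus |
| gene architecture | 6 exons / 5 introns | shared flatfish class II B layout |
| cDNA | 794 nt = 25 nt 5'UTR + 747 nt ORF + 22 nt 3'UTR | study transcript dimensions |
| intron repeats | GT ×5–30, GTCCAGTTGA ×4–60, ACCTGTCTGTCTGCTC ×2–8 (per locus) | spans the observed intron-length ranges (intron 3 ≈ 136–770 bp, intron 4 ≈ 82–170 bp) |
| locus divergence | 0.03 subs/base | well-separated loci (between ≫ within distance) |
| within-locus allele mutation | 0.004 subs/base | distinct but tightly clustered alleles |
| PBR nonsynonymous multiplier | 3 | diversifying selection on exons 2–3; applied to locus divergence and allele mutation alike, since selection acts over the whole genealogy |
| clone depth | 8–20 per individual-allele | screening depth typical of colony PCR |
| clone error | 2×10⁻⁴ /base | high-fidelity polymerase + Sanger consensus scale |
| missing-locus probability | 0.125 | loci are not carried by every individual |

Coding mutations are placed codon-aware: a candidate substitution is
classified by translation and accepted or rejected against the requested
synonymous/nonsynonymous target, never creating or destroying a stop, so
the generator's regional dN/dS contrast is controllable ground truth.
Intron bodies are random with planted repeat blocks, GT…AG termini, and
flanks guarded against extending the repeat phase. Clone errors are
substitutions only, matching the exact-identity validation rule (indel
errors would demand error-tolerant collapsing, a non-goal). Every
generated allele is verified at generation time to re-annotate to its own
exon coordinates, with regeneration on the rare ambiguous draw, so
annotation truth is exact by construction. Two runs with the same config
and seed are byte-identical.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: coalescent-realistic
genealogies, recombination and gene conversion between loci,
chimeric PCR products, indel sequencing errors, primer bias, and loci so
recently duplicated that their allele pools overlap. The locus estimate
on real data remains a lower bound precisely because of that last case.

## Problem sizes and numerical conventions

Test and acceptance workloads use the default study scale (4 loci × 8
individuals, ~1.5–2k clones per run): 50 seeded end-to-end runs for the
recovery rate, 200 neutral replicates of 20 × 200 codons for test
calibration, 200 randomized grouping problems for the constraint
invariant, 150 ≤6-allele instances against brute-force partition
enumeration, and 100 seeds of annotation round-trips. Quantile
computation uses linear interpolation (NumPy default); grouping
tie-breaks are lexicographic; all stochastic steps take explicit seeds
and the pipeline summary records seed, tool version and a config hash.

## Known limitations

- The spliced aligner assumes the cDNA is error-free relative to its
  genomic allele; a nonzero mismatch budget is configurable but untested
  against real cross-allele pairs.
- The exact-minimality refinement is exponential and capped at
  `exact_limit` alleles; beyond that the greedy group count can in
  principle exceed the true minimum.
- The bootstrap Z test inherits the usual normal-tail approximation;
  for very short regions (few codons) its calibration degrades.
- The repeat detector reports one dominant call per overlap region and
  does not model nested or higher-order repeat structure.
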