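# Methods

This note records the models, algorithms and design choices behind ihakit —
what each stage assumes, which knobs matter, and what the synthetic
benchmarks do and do not demonstrate about real data.

## The iteration loop

The loop implements coverage-targeted genome recovery for communities with
a wide abundance range. Its premise: an assembler has a coverage floor, so
a single pass recovers only organisms whose abundance puts them above it;
removing the reads of well-assembled genomes raises everyone else's
effective coverage in the next pass. One cycle is subsample → assemble →
bin → refine → assess → gate → deplete.

**Stop rules.** The source workflow iterates "until a satisfactory result";
we make that deterministic: stop at `max_cycles` (default 5), when a cycle
yields zero newly qualified MAGs (after cycle 1), or when the residual pool
empties. Depletion always runs against the *cumulative* qualified set, so a
read recruited in cycle c can never reappear in cycle c′ > c.

**The gate.** Default `hq_hc`: tier FINISHED or HQ *and* ≤ 5 contigs. A
`dq_hc` gate is available; the stricter default avoids depleting reads
against half-finished references, which would strand the missing pieces of
those genomes in the residual pool.

**Final pooling.** Accumulated qualified MAGs plus the *last* cycle's
DQ-or-better non-qualified MAGs (earlier cycles' rejects are simply
rediscovered later, usually in better shape), dereplicated at MinHash
d ≤ 0.05 keeping the higher (completeness − 5×contamination) score, ties by
fewer contigs, larger N50, then id.

**Cycle sizing.** Defaults are the study proportions — 6 Gbp short reads +
22 Gbp long reads in cycle 1, then 20 M pairs + 1 M long reads — times a
user scale factor (`IhaConfig.scaled`). Desk-scale runs in the tests use
35 Mbp / 15 Mbp cycles over a 90 Mbp / 45 Mbp pool; these sizes were chosen
by coverage accounting (below), not tuned to outcomes.

## Quality model

Completeness and contamination follow the single-copy core-gene
convention: with K markers expected once each,
completeness = 100·|{markers seen ≥ 1×}|/K and
contamination = 100·Σ max(copies−1, 0)/K. The tier rules use strict
inequalities exactly as stated: HQ needs completeness > 90, contamination
< 5, at least one each of 5S/16S/23S rRNA and ≥ 18 tRNAs; DQ needs > 70,
< 10, a 16S and ≥ 18 tRNAs; LQ is DQ-except-16S; FINISHED is a single
circular sequence that also meets HQ; high contiguity means ≤ 5 contigs.
"Multiple (23S/16S/5S) rRNA genes" is read as ≥ 1 of each gene (the
standard minimum-information reading), not ≥ 2 copies.

Marker and cassette detection is alignment-based: 15-mer anchor seeding
(cassettes are short, 75–2900 bp, and may carry clustered substitutions
that leave no intact 31-mer), colinear chaining, edlib scoring; a copy
counts at identity ≥ `min_identity` (default 0.95) and query coverage
≥ `min_coverage` (default 0.95). When a community is generated with
diverged cassette homologs (below), the engine scans at the matching
identity level (`IhaConfig.marker_min_identity`, 0.85 in the benchmark).

The manifest summary statistics use the sample standard deviation (n−1); a
single-MAG subset reports sd 0 with a `sd_defined` flag.

## Synthetic communities

`ihakit.synthetic` builds truth-known genomes: i.i.d. GC-weighted
background with planted, non-overlapping elements — K single-copy marker
genes (ORF-structured, planted behind an in-frame stop so the ORF caller
recovers exactly the planted gene), one or more 5S+16S+23S rRNA operons, 18+
copies of a tRNA cassette, long intragenomic repeats (the benchmark's
dominant genome carries a 2,100 bp element at 13 copies), and circular
plasmids whose copy number multiplies their read-sampling weight.

`abundance_weight` is the genome's relative DNA (base) fraction: replicon
sampling probability is weight × (replicon length × copy number) normalised
within the genome, which makes realised per-genome base fractions converge
to the weights (the spec-level invariant the simulators are tested
against).

Short reads are 150 bp pairs with a Gaussian ~350 bp insert, sampled across
the origin of circular replicons, substitution errors only. Long reads are
log-normal (σ = 0.55, location set so the length-weighted median meets the
N50 target, 23 kbp by default), minimum 1 kbp, with a 60/20/20
substitution/insertion/deletion error mix at 10% by default. Quality-score
profiles, chimeras and inter-genome homology gradients are *not* modelled.

**Cassette divergence.** By default every genome carries the library
cassettes verbatim. That is the simplest reading, and all planted-recovery
behaviour holds under the default scan thresholds — but it is also
unrealistically adversarial for the loop itself: identical cassettes across
genomes mean (a) reads inside marker/rRNA interiors of *unassembled*
genomes get recruited to the first qualified MAG, punching coverage holes
everywhere, and (b) k-mer graphs tangle across genomes. Real single-copy
core genes are homologous, not identical, between taxa. `GenomeSpec`
therefore exposes `cassette_divergence`; the benchmark community uses 0.10
(codon-preserving replacements for genes, exact-count substitutions for
RNA cassettes), which keeps alignment-level detection trivial while making
21-mer and 31-mer sets effectively genome-private.

## The toy assembler

A deliberately small hybrid assembler for error-free or low-error synthetic
short reads; it does no error correction and is not a production tool (real
assemblers slot in via the adapter contract
`callable(pairs, long_reads, workdir, seed) → contigs`).

* de Bruijn graph on short-read k-mers (k = 31, both strands), counts below
  `min_depth` dropped; maximal unitigs extracted vectorised; twin (reverse
  complement) unitigs deduplicated; isolated cycles are circular contigs.
* Long-read bridging: each read is walked as an ordered chain of oriented
  unitigs via sampled exact k-mer anchors; chains are expanded through
  short "boundary" unitigs (< 2k bp) along unique graph paths, because such
  unitigs carry too few anchors to be seen directly. Votes are tallied per
  transition and, crucially, per (context, current) pair where the context
  is the last non-repeat unitig on the walk — one unique flank then
  disambiguates the exits of a multi-copy cassette. A junction is crossed
  when the best candidate has ≥ 2 votes and strictly beats the runner-up;
  junction sequence always comes from the unitig copy, so contigs never
  contain a k-mer absent from the short reads.
* Repeat unitigs are recognised topologically (branching on both sides, or
  < 2k bp); their reuse per walk is capped by a depth-derived multiplicity
  estimate. A walk that returns to its first unitig closes a circular
  contig. Contigs below 1 kbp are discarded (the standard downstream
  filter). All tie-breaks are lexicographic, so assembly is deterministic.
* At 10% long-read error the 31-mer anchor survival is ~4%, which still
  leaves dozens of anchors per kbp for chain detection, but bridging
  *votes* become scarcer; tests that rely on bridging use ≤ 2% long-read
  error.

The binner clusters contigs greedily (longest first) on L1-normalised
tetranucleotide frequencies plus log₁₀ depth; distance to a centroid is
cosine + 0.2·|Δlog depth|, new cluster above 0.06. Those two constants were
set from the measured geometry of the feature space: within-genome contig
distances sit near 0.001–0.01 (large contigs) while genomes ≥ 0.07 apart in
GC sit at ≥ 0.04 cosine before the depth term. Refinement drops bins at
completeness ≤ 70 or contamination ≥ 10 (the usual bin-refinement
thresholds) and evicts contigs whose markers duplicate a larger contig's.

## Read depletion

Short reads: a mate maps when ≥ 60% of its sampled canonical 21-mers occur
in the combined qualified-MAG set (a deliberate stand-in for a sensitive
aligner; an external PAF can replace it). Both mates mapped → pair
recruited; neither → residual; exactly one → discarded, keeping the
residual pool properly paired — "unpaired reads are filtered" is read as
removing mate orphans, and an either-mate recruitment mode is available
behind a flag. Long reads are recruited when *any* alignment reaches
coverage ≥ 0.80 and identity ≥ 0.80, both inclusive; the built-in aligner
uses near-unique anchors with a 3 kbp chain gap so reads step across
multi-copy regions on flanking anchors.

## Evaluation metrics

Contigs are aligned to references by unique 31-mer anchors (strided for
long queries), chained colinearly with a 1 kbp gap bound on both axes, and
each chain is rescored by edlib edit alignment (flanks up to ~100 bp are
included so exact copies reach full coverage). NGA50 is the aligned-fragment
length at which the cumulative aligned length reaches half the reference (0
when under half is covered). AGF counts reference positions once; purity is
1 − unaligned-contig-bp / total-contig-bp (the published operational
definition of the phrase "fraction of unaligned contig length"). A
misassembly is a reference switch, strand flip, or > 1 kbp coordinate jump
between consecutive blocks of one contig (the QUAST-style default).
Mismatch/indel rates are reported per *aligned* Mbp (the denominator choice
is not fixed by the source description; it is flagged here). Chains cannot
cross repeats longer than the gap bound, so heavily repetitive references
depress AGF slightly — a known limitation.

Gene recovery and MAG-pair comparison use one ORF caller (6-frame,
starts ATG/GTG/TTG, standard code, ≥ 90 nt, longest-ORF-per-stop) and exact
protein-string identity (the 100%/100% rule makes alignment unnecessary).
Functional sets: per function with copy counts a (hybrid) and b
(short-read-only): equal → I, a > b > 0 → II, b = 0 → III, a = 0 → IV;
b > a > 0 (not covered by the source rules) is assigned to set I so the
four sets partition the union; weighted tallies count max(a, b) genes so
they sum to the multiset-union gene count. MinHash sketches are bottom-1000
over canonical 21-mers (splitmix64), distance −(1/k)·ln(2j/(1+j)), capped
at 1 when no hashes are shared.

## The six-genome benchmark

`ihakit.engine.rare_recovery_benchmark` fixes the study conditions used by
the end-to-end tests: six genomes of 800/650/500/400/300/150 kbp (~2.8 Mbp
total) at base abundances 40/25/15/10/7/3%, GC 0.28–0.72, three circular
chromosomes, a 13-copy 2.1 kbp repeat plus a 2-copy 30 kbp plasmid on the
dominant genome, 10% cassette divergence; 90 Mbp of error-free short-read
pairs and 45 Mbp of 2%-error long reads; cycle subsamples of 35 Mbp /
15 Mbp with `min_depth` 1 (every error-free k-mer counts).

The sizes come from gap statistics: with L = 150, k = 31, a genome at
per-base coverage c has ≈ N·e^(−0.79c) zero-coverage k-mer gaps (N = read
count), so at the cycle-1 subsample only the 40% and 25% genomes assemble
into ≤ 5 contigs, while the 3% genome (≈ 7× coverage) fragments; after one
or two depletions its share of the pool triples and it assembles cleanly —
the mechanism the loop exists to demonstrate. On seed 1 all six genomes are
recovered at MinHash d ≈ 0, four of them only in cycle ≥ 2.

**What passing does not show.** Error-free short reads, substitution-only
divergence, no strain mixtures, no conserved-operon homology between
genomes, and a toy assembler: real communities add error correction,
shared mobile elements and much larger graphs. The benchmark validates the
*loop logic* — gating, depletion, enrichment, bookkeeping — and the exact
semantics of every metric, not assembler performance on real reads.

## Numerical and degenerate-input choices

* k-mers pack 2 bits/base into uint64 (k ≤ 31, odd k avoids palindromes);
  canonical form is min(word, revcomp); hashing is the splitmix64
  finaliser.
* Spearman correlation is undefined (flagged, NaN) under 3 points or on a
  constant vector; single-element standard deviations report 0 with a flag.
* Subsampling draws a seeded permutation and returns selections in pool
  order; byte targets never overshoot for pairs and overshoot ≤ 1% for
  long reads (reads are large relative to budgets, so undershoot would
  bias low).
* Every stage derives its RNG from a stable (seed, stage-name, cycle) hash,
  so inserting a stage never perturbs the others.
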