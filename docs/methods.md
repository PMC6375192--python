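# Methods

## The problem

A whole-genome duplication (WGD, polyploidy) copies every gene at once.
Millions of years later its footprint survives as a *wave* of paralog
pairs of similar age. Age is proxied by dS (Ks) — synonymous
substitutions per synonymous site — because synonymous changes are
close to neutral and accumulate roughly clock-like. Plotting the
distribution of paralog-pair dS for one genome therefore shows peaks at
the dS depths of past WGDs, on top of the exponential-like background
of continuous small-scale duplication and loss.

The approach implemented here needs no gene-order (synteny)
information: it works from nothing but each gene's CDS and protein
sequence, which makes it applicable to fragmented draft genomes and
transcriptome assemblies. The price is redundancy: a gene family of n
members arose through n−1 retained duplications but contributes
n(n−1)/2 pairwise dS values, massively over-counting old events. The
core of the package is the correction that collapses those pairs back
into per-duplication-event dS values.

## Pipeline stages

1. **Input QC (`seqio`).** CDS and protein FASTA are joined on
   identifier. Terminal stop codons are trimmed; records whose CDS does
   not translate exactly to the given protein (standard nuclear code),
   records with internal stop codons, and proteins shorter than 50
   residues are dropped. With an isoform map, only the longest CDS per
   gene is kept (ties: smallest isoform id).

2. **Similarity graph (`similarity`).** All-vs-all protein similarity,
   either parsed from an external 12-column tabular file (BLAST
   `-outfmt 6` / MMseqs2 `m8` — the route for genome-scale input) or
   computed by the built-in search: shared-4-mer seeding (≥ 5 distinct
   shared words; words in > 200 sequences ignored as low-complexity)
   followed by Smith–Waterman with BLOSUM62 (gap open 11, extend 1) and
   Karlin–Altschul E-values, E = K·m·n·e^(−λS) with fixed ungapped
   parameters λ = 0.267, K = 0.041. Hits with E ≤ 1e-10 (inclusive
   boundary) become edges weighted −log10 E, capped at 200 (E = 0 maps
   to the cap); reciprocal weights are averaged.

3. **Families (`mcl`).** Markov clustering on the column-stochastic
   matrix of the graph, per connected component, with self-loops at
   each node's maximum incident weight, expansion 2, inflation 2.0
   (canonical default; the governing resolution parameter, exposed as
   `--inflation`), pruning at 1e-5, convergence at max-change < 1e-8.
   Clusters are read from attractor rows; nodes attracted to several
   attractor systems go to the strongest (ties to the smallest member
   id), so the output is a deterministic partition.

4. **Codon alignment (`codon_align`).** Each family's proteins are
   aligned (built-in progressive aligner: 3-mer cosine guide tree +
   profile–profile Gotoh, BLOSUM62, gap open 10 / extend 0.5; or any
   external aligner producing aligned FASTA, e.g. MAFFT), then
   back-translated codon-by-codon (gap → `---`). For every member pair,
   columns with a gap, an N, or a stop codon in either row are removed
   pairwise; pairs with stripped length strictly greater than 90 bp are
   kept. Pairwise stripping (rather than global column removal) retains
   the most data per pair.

5. **Pairwise dS (`ng86`).** Nei–Gojobori (1986) counting: fractional
   synonymous sites per codon (changes creating stop codons excluded
   from numerator and denominator), pathway-averaged synonymous /
   nonsynonymous differences for multi-position codon pairs (pathways
   through stop codons discarded; if all are blocked, every pathway is
   used with stop-creating steps counted nonsynonymous), and the
   Jukes–Cantor multiple-hit correction dS = −(3/4)·ln(1 − (4/3)·pS).
   pS ≥ 3/4 is saturation: the pair carries a flag instead of a number.
   All 64×64 codon-pair counts are precomputed, so a pair costs a table
   lookup per column; the implementation is checked against an
   exhaustive brute-force oracle to 1e-12.

6. **Redundancy correction (`dedup`).** Per family, the pairwise dS
   values form a dissimilarity matrix; unmeasurable pairs (saturated,
   filtered, absent) are filled with 10 — above the subfamily threshold
   of 5, so they can never be clustered together — and excluded from
   all averages. An average-linkage (UPGMA-style) tree is cut into
   k = 1…n clusters; the smallest k whose clusters contain only
   measured within-cluster dS < 5 defines the *subfamilies* (each keeps
   as many genes as possible). Each subfamily of m ≥ 3 genes is
   re-clustered and cut into exactly two child clades; the
   combination-weighted mean of the between-clade dS values is the
   subfamily's duplication-event dS (two-gene subfamilies contribute
   their single value). The default `deepest_split` mode emits one
   event per subfamily; `recursive` mode also descends into the clades
   (≤ m−1 events), preserving shallow duplications nested inside old
   subfamilies. All agglomeration and cutting ties break
   lexicographically on member ids, so the event table is byte-stable.

7. **Distribution and peaks (`peaks`).** Gaussian KDE of the corrected
   dS values on a 512-point grid over [0, 5] (the subfamily threshold
   caps the range), with reflection at 0 to remove the boundary
   deficit of a plain KDE — a genuine excess of near-zero values, e.g.
   unmerged haplotypes, still appears as a peak. Bandwidth: Silverman's
   rule by default, fixed override available. Peaks are strict local
   maxima with prominence ≥ 5% of the maximum density, greedily thinned
   to a minimum separation of 0.1 dS.

## Synthetic paranome generator

`simulate` exists so the whole pipeline can be validated against known
ground truth. Each family starts from one random stop-free CDS
(default 300 codons). WGD waves, applied oldest-first, duplicate every
surviving lineage with a retention probability at the wave's dS depth;
optional small-scale duplications hit uniformly chosen lineages at
uniform depths. Gene ids encode the lineage path, so every pair's true
divergence depth is recoverable from ids alone.

Sequence divergence is generated per site rather than with a full codon
model (GY94-style): every position with synonymous single-nucleotide
alternatives evolves as a uniform Markov chain over its frozen
synonymous state set, and a small nonsynonymous component (default
dN/dS = 0.2) runs on positions that have no synonymous alternatives.
The chain time applied for a requested depth d is found by numerical
inversion so that the *mean NG86 estimate* equals d: the expected pS
and its variance are computed per site class (with a first-order
correction for the drift of the synonymous-site count), pushed through
the Jukes–Cantor transform by numerical integration of a truncated
normal (the transform's convexity and the exclusion of saturated
replicates both matter near saturation), and a cached Monte-Carlo
refinement factor (fixed internal seed; model-based Newton steps on the
time axis) absorbs what the independence approximation misses —
chiefly within-codon interactions, where a second change can render a
"synonymous" difference nonsynonymous in context. Measured accuracy:
mean estimated dS within about ±2% of target across 0.1–2.0 (the
module's contract is ±5%). Chain times compose additively along the
lineage tree, so nested duplications stay mutually consistent: an edge
from a split at depth d1 to one at d2 carries time g(d1) − g(d2) with
g = half the inverted pair time.

What the generator does **not** emulate: codon-usage bias, selection
heterogeneity among sites and lineages, indels (so alignment is easy by
construction), gene conversion, tandem-array structure, and synteny.
Passing the recovery tests therefore demonstrates the pipeline's
statistical machinery — family construction, dS estimation,
redundancy correction, peak reading — not robustness to alignment
error or rate variation in real genomes.

## Behaviour near saturation (known limitation)

For waves deeper than dS ≈ 1.5 the detected peak sits systematically
below the true depth even though the mean pairwise estimate is
calibrated: the Jukes–Cantor transform is convex, so the estimate
distribution is right-skewed and its *mode* falls below its mean (for
300-codon genes at depth 1.9, single-pair events peak near 1.65,
four-pair averaged events near 1.75), and saturated pairs censor the
most-diverged families out of the event list entirely (a subfamily may
not contain an unmeasured pair, so one saturated pair can delete a
family's ancient event). In the two-wave validation the ancient peak is
therefore detected around dS 1.7 for a true depth of 1.9, while the
recent peak is recovered within a few hundredths. This matches the
field's experience that ancient-WGD peak positions are method-dependent
once dS exceeds ~1; positions of deep peaks should be read as lower
bounds.

## Numerical and design choices

- Standard nuclear genetic code only; codons containing N translate to
  X and are stripped from pairs (NG86 cannot count them).
- E-value cutoff boundary inclusive (≤ 1e-10); edge weights
  −log10 E capped at 200; one-directional hits keep their single weight.
- Karlin–Altschul parameters are fixed constants, not looked up per gap
  penalty — a documented approximation adequate for thresholding.
- MCL runs densely per connected component (bounds memory by the
  largest component); a fully pruned column restarts as a self-loop.
- Saturated pairs are flagged, never given an arbitrary large dS; the
  fill value 10 only steers subfamily construction.
- Problem sizes in the validation suite (500 families for the
  single-wave check, 1000 for the two-wave check, 300 codons per gene)
  are the package's standard demonstration conditions; the pipeline
  itself is size-agnostic and streams per family.
- Pipeline stages cache on a parameter hash plus input mtimes; a
  changed upstream flag invalidates everything downstream. Per-family
  work parallelizes over processes with output order independent of
  worker count.
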