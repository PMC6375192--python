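# ksforge

Detect whole-genome duplication (WGD) signatures in a single genome or
transcriptome from nothing but its coding sequences: build gene families,
estimate paralog synonymous distances (dS / Ks), correct the redundancy of
within-family pairs, and read WGD waves as peaks in the corrected dS
distribution.

**Who it is for.** Researchers asking "has this lineage been through
polyploidy, and how long ago?" for organisms whose genomes are draft-quality
or known only through transcriptomes — i.e. whenever synteny-based methods
are off the table. The only inputs are two FASTA files with matching
identifiers: CDS nucleotide sequences and their protein translations.

## Method in brief

For paralogs *i, j* the synonymous distance is estimated by Nei–Gojobori
(1986) counting with the Jukes–Cantor multiple-hit correction:

    pS = Sd / S,      dS = -(3/4) · ln(1 - (4/3) · pS)

where S is the (fractional) number of synonymous sites and Sd the
pathway-averaged number of synonymous differences; pS ≥ 3/4 is saturation.

Because a family of *n* genes arose through *n−1* duplications but yields
*n(n−1)/2* pairs, the raw pair distribution over-counts old events. Each
family is therefore clustered by average linkage on its dS matrix, split
into subfamilies whose mutual dS values are all below 5 (keeping as many
genes per subfamily as possible), and every subfamily is cut into exactly
two child clades: the combination-weighted mean of the between-clade dS
values is that subfamily's duplication-event dS. The corrected values are
smoothed with a Gaussian kernel (reflected at 0) and peaks — candidate WGD
waves — are reported.

The pipeline mirrors the classic family-based Ks workflow: similarity
search (built-in Smith–Waterman engine, or any BLAST/MMseqs2 tabular file),
Markov clustering (MCL) into families, MAFFT-style protein alignment with
codon back-translation, NG86 dS, redundancy correction, density + peaks —
all with one command.

## Worked example

Simulate a paranome with a known WGD at dS 0.6 (200 families, 40% retention
per gene), then run the full pipeline:

```sh
ksforge simulate --n-families 200 --wgd-depths 0.6 --retention 0.4 --seed 3 \
    --out-cds demo/cds.fa --out-pep demo/pep.fa --out-truth demo/truth.tsv
# wrote 283 genes, 83 duplication events

ksforge run --input-cds demo/cds.fa --input-pep demo/pep.fa \
    --output-dir demo/out --tmp-dir demo/tmp
# genes=283 families=200 pairs=83 events=83
# peak at dS 0.597 (density 5.839)
```

283 genes pass QC and cluster into 200 families (117 singletons, 83 pairs —
the simulated retention losses); the 83 redundancy-corrected duplication
events produce a single density peak at dS 0.597, recovering the simulated
wave at 0.6. `demo/out/` contains the event table, the flat dS list, the
plot (SVG/PNG), the peak table and a machine-readable manifest:

```
family_id  subfamily  ds        weight  member_count
F000001    0          0.542299  1       2
F000002    0          0.634756  1       2
F000003    0          0.672258  1       2
```

For genome-scale data, run the similarity step externally and feed the
tabular result in: `ksforge run --engine tabular --hits allvsall.m8 ...`.
`ksforge plot` re-plots any dS list; `ksforge ds` prints the pairwise dS
table for one pre-grouped family.

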