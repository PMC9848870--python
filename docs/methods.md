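# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinate and naming conventions

All internal coordinates are 0-based half-open; GenBank's 1-based inclusive
convention is converted once, at the I/O boundary. Strands are J (major)
and N (minor). Gene names use the mitogenomics vocabulary (nad1–6, nad4l,
cox1–3, atp6/8, cob, trnX with trnL(uur)/trnL(cun) and trnS(ucn)/trnS(agy),
rrnS, rrnL, CR); raw annotation labels (ND3, COIII, CYTB, "12S ribosomal
RNA", D-loop, …) are canonicalized through an editable alias map. Leucine
and serine tRNAs are disambiguated by anticodon when annotated, else by
genomic context (trnL after rrnL is trnL(uur); trnS after cox1 is
trnS(ucn); the H-S-L cluster fixes the others), else by order of
occurrence. A feature spanning the circular origin is stored as two
intervals ordered 5'→3' in gene orientation.

## Composition and skew

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C). A zero denominator makes
the skew undefined (reported as missing), because reporting 0 would assert
a symmetry the data cannot show. Percentages use the unambiguous-base
denominator (A+C+G+T); IUPAC ambiguity codes are excluded from numerators
and denominators so the skew bounds [−1, 1] are exact. Both choices are
configurable where they matter (the percentage denominator in particular,
since published tables rarely state theirs). Reported percentages are
rounded half-away-from-zero to one decimal, matching the precision of
printed comparative tables; full precision is kept internally.

Codon-position statistics are computed in reading frame, not genome
strand: N-strand genes are reverse-complemented first, `codon_start`
offsets applied, the trailing partial codon dropped, and a complete stop
codon dropped by default (so "PCGs excluding stop codons" is the natural
partition; a flag keeps stops for the alternative convention).

## Codon usage

The genetic code defaults to vertebrate mitochondrial (NCBI table 2):
AGA/AGG are stops, ATA joins the Met family, TGA joins Trp, so every
amino-acid family has ≥ 2 members and RSCU is defined family-wise as
count × family size / family total. Families with zero counts have
undefined RSCU rather than 0. Stop codons are excluded from families.
Trailing T/TA at a PCG 3' end is an incomplete stop (post-transcriptional
polyadenylation completes it); incomplete stops are excluded from codon
counts. Internal stops trigger a warning naming the codon position —
they usually indicate a mis-annotation and are never silently removed.
Ranking of "most used" codons is by RSCU, ties broken by raw count then
alphabetically, so results are deterministic.

## Gene order and spacers

A gene order is the circular list of (gene, strand) pairs in J-strand
genome order, rotated to the trnF anchor (the start of conventional avian
numbering); when the anchor is missing the lexicographically minimal
rotation is used. Adjacencies are strand-aware and orientation-normalized
((x→y) equals (y→x) with both strands flipped), following rearrangement
conventions; breakpoints between two orders count adjacencies of one
absent from the other, and "identical" means zero breakpoints. Spacers are
computed on the circular topology (the pair across the origin included);
gap = downstream start − upstream end, negative values are overlaps, and
spacer summaries count only gaps ≥ 1 bp, matching how intergenic spacers
are reported in mitogenome descriptions. The control region is included as
a (non-gene) token in order comparisons.

## Control region

Domain boundaries (ETAS domain I / central domain II / CSB domain III) are
not derivable from a single sequence, so they are configuration: explicit
coordinates, or anchor mode in which domain II starts at the best F-box
hit and domain III at the best CSB1 hit (an absent anchor is an error, not
a guess). Conserved-box consensi live in an editable TSV
(`mitokit/data/cr_motifs.tsv`); the poly-C tract pattern
(CCCCCCCCCCTTCCCCCCCC) is the conserved wagtail domain-I tract, while the
F/E/D/C/B, bird-similarity-box and CSB1 defaults are constructed
placeholder patterns — the software treats every row purely as a search
pattern and users analysing real data should substitute curated consensi.
Motif search is IUPAC-aware Hamming matching with a per-motif mismatch
budget; overlapping hits are allowed and sorted by (mismatches, start).

A column of a gapped alignment is variable iff it holds ≥ 2 distinct
non-gap residues; the default denominator is columns with ≥ 2 non-gap
residues (columns where no comparison is possible carry no information),
with total-column denominator available as an option.

Tandem repeats: for each unit length u, maximal runs of positions matching
the position u ahead define loci; copies = span/u (fractional allowed);
with purity < 1, adjacent pure runs are merged greedily while the matching
fraction stays above the threshold. Reports of one locus at multiples of a
smaller unit collapse to the smallest unit. Defaults are unit 2–200 bp,
≥ 2 copies, purity ≥ 0.9; summaries additionally require a 24 bp total
span, because every random kilobase contains two-copy dinucleotide
repeats and a "contains no tandem repeats" statement refers to repeats of
reportable size.

## tRNA cloverleaf folding

Folding is an exhaustive search over a parametric cloverleaf layout
(acceptor stem fixed at 7 pairs; D stem 0–4 pairs; anticodon stem 5; T
stem 4–5; bounded loop, spacer, variable-region and 3'-tail windows),
maximizing a pair score of +2 per Watson–Crick pair, +1 per G·U wobble,
−1 per mismatch. Mismatched pairs (C·C, A·A, U·U and the like, which occur
in real mitochondrial tRNAs) are penalized, not forbidden. When the
anticodon is known its placement in the anticodon loop (≥ 2 loop bases on
each side) is a hard constraint. Ties break toward a larger D stem, then
toward canonical arm lengths — a biological prior for the standard
cloverleaf. The DHU arm counts as present when the D stem keeps ≥ 2 pairs;
metazoan mitochondrial trnS(agy) characteristically folds without one. A
fold scoring below a threshold (default 20; a perfect canonical fold
scores 42) raises "no cloverleaf". This is template decomposition, not
thermodynamic folding: it reports arm presence, sizes and mismatches, not
free energies.

## Distance phylogenetics

Alignments are consumed, never computed (multiple alignment is a separate
problem with its own tools). Concatenation gap-fills missing taxa per gene
and records a partition map that tiles the columns. Distances use pairwise
deletion of gap/ambiguous sites; K2P is d = −½ln(1−2P−Q) − ¼ln(1−2Q) with
P, Q the transition/transversion proportions (undefined when the logs'
arguments are non-positive). Neighbor joining is the standard
agglomeration with a deterministic tie-break (lexicographically smallest
label pair among Q-minimizers), so results are exactly reproducible;
negative branch lengths are clamped to zero with a warning. Model-based
inference (ModelFinder/IQ-TREE/MrBayes) is out of scope by design; the
package exports relaxed PHYLIP and NEXUS-with-charsets supermatrices for
those tools and verifies topologies (RF distance, monophyly, pattern
matching on bipartitions) rather than inferring support values.

## Synthetic data: what it emulates, and what it does not

The generator builds a circular ~16.85 kb genome with the canonical
passerine arrangement (…cob–trnT–trnP–nad6–trnE–CR–trnF–rrnS…), 37 genes
plus one CR, nad6 and eight tRNAs on the N strand. Defaults mirror the
study system: whole-genome A+T ≈ 54% with A-skew and C-skew, rrnS 973 bp /
rrnL 1595 bp, tRNAs 66–72 nt, CR 1250 bp in three domains, intergenic
spacers of 1–23 bp with the longest between trnP and nad6, ATG starts with
nad3 starting ATT, TAA stops with incomplete T stops in cox3 and nad4, and
codon-usage targets whose top codons are CUA (Leu), CGA (Arg) and UCC
(Ser). Base frequencies per partition are solved uniquely from (A+T%,
AT-skew, GC-skew); infeasible targets raise rather than being projected.
PCGs are sampled codon-by-codon from the RSCU targets with uniform
amino-acid usage; tRNAs are instantiated from perfect cloverleaf templates
(Watson–Crick stems, anticodon seated in the loop), with an optional
DHU-less serine template whose D region is drawn from {A,C} so no spurious
stem can form, and optional planted stem mismatches. The CR implants the
poly-C tract in domain I, the boxes in domain II (F-box at the domain
boundary, matching the anchor convention), CSB1 at the domain III
boundary, and optionally a tandem repeat whose borders are broken so
detection is exact.

Randomness comes from one root seed with named substreams per component
(gene, spacer, CR, evolution), so adding a component does not shift other
draws; output is byte-identical for a fixed seed.

Sequence evolution is K80 (default κ = 4) with independent sites, no
indels, and per-interval rate multipliers. The default CR domain rates
(0.17 / 0.11 / 0.39 for domains I/II/III) put variable-site percentages
under the default six-taxon guide tree at the scale observed in wagtail
control regions (a few percent in domains I and II, ~9% in domain III,
rank III > I > II).

What the generator does **not** emulate: real covariation between genes,
indels and alignment uncertainty, site-rate heterogeneity within a domain,
selection on codons, rRNA secondary structure, and real control-region
repeat polymorphism. Passing recovery tests therefore demonstrates that
the analysis operations are correct and calibrated on data satisfying
their assumptions — not that those assumptions hold for any particular
real genome.

## Problem sizes used in checks

The recovery checks use 100 kb partitions for composition targets
(tolerance 0.02 on skews), ~180,000 codons for RSCU targets (tolerance
±0.1, comfortably above the sampling noise at that size), and 40-seed
batches for topology-recovery rates. The tandem-repeat detector is checked
against an exhaustive brute-force oracle on every {A,C} string up to
length 14 and on random samples at lengths 15–20; the cloverleaf search is
checked against an independent exhaustive enumeration on a restricted
window set. These sizes are the package's own verification choices and are
stated here so they can be scaled by anyone re-running the checks.

## Known limitations

* De novo annotation (ORF finding, tRNA scanning) is out of scope; records
  must arrive annotated.
* Anchor-based CR partitioning inherits the box configuration's quality;
  with the shipped placeholder patterns it is only meaningful on synthetic
  or pre-screened data.
* The greedy merge in impure tandem-repeat detection is not guaranteed
  optimal for purity < 1 (the pure case is exact and oracle-verified).
* The cloverleaf template cannot represent tRNAs whose acceptor stem has
  fewer than 7 pairs, and scores are heuristic, not thermodynamic.
* NJ is exact only on additive matrices; on real data it is a sanity-check
  topology, not a substitute for model-based inference.
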