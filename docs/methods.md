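# Methods

`mitomarker` screens the core protein-coding genes of annotated fungal
mitogenomes for short DNA-barcode markers, the way a genus-scale
phylogenetics study would: extract genes, align, build per-gene and
concatenated neighbor-joining (NJ) trees, demand topological concordance,
and rank the concordant genes by length. This note documents the models,
the numerical choices, and what the synthetic data do and do not emulate.

## The screening model

A candidate gene (the 15 core PCGs — atp6/8/9, cob, cox1–3, nad1–6,
nad4L, rps3 — plus the two rRNAs rrnL and rrnS) is **selected** as a
barcode marker iff all of the following hold:

1. **Tree concordance.** The NJ tree built from the gene alone has
   Robinson–Foulds (RF) distance 0 to the reference tree built from the
   concatenated 15-gene supermatrix. RF = 0 is the strictest faithful
   operationalization of "the single-gene tree matches the multi-gene
   tree"; anything softer would require an arbitrary cutoff.
2. **Diagnostic power.** The gene carries at least one between-group
   diagnostic site: a column invariant within every taxon group but
   different between at least two groups.
3. **Barcode length.** Median length ≤ `max_barcode_length`
   (default 300 bp — Sanger-friendly, printable as a four-color barcode).
4. **Length stability.** All taxa carry the gene at identical length.

Failures map to graded verdicts: length-unstable rRNAs are
`excluded_length_unstable` (intron gain/loss makes their alignment and
even their annotation unreliable); CDS genes with indel-driven length
variation or with variable sites above `max_candidate_variable_fraction`
(default 10% of columns) are `excluded_too_long_variable`; genes that are
tree-discordant or carry no diagnostic site are
`excluded_insufficient_resolution`; genes passing everything except the
length bound are `candidate` (good phylogenetic markers, poor barcodes).

**Taxon groups.** "Interspecies" requires a grouping, but species labels
are deliberately metadata-only (names in public records frequently
contradict the molecules). By default two taxa share a group iff their
concatenated core-gene sequences are identical; any grouping can be
supplied via `ScreeningConfig.groups`.

**Indel evidence.** A pairwise aligner will occasionally place a
score-neutral or score-favorable micro-gap between two length-conserved
sequences (shift-matching windows). Gene verdicts therefore treat *length
variation across taxa* as the indel signal, not the presence of gap
columns in the alignment; gap columns are still reported per gene.

**Clades.** After selection, taxa are partitioned into clades of zero
pairwise SNPs in *every* selected marker (identical aligned rows). Each
clade is then annotated with the SNP count and the `ref→alt at N`
positions of a representative member against the designated barcode
standard sequence. Clade numbering follows tree traversal order starting
from the standard's leaf.

## Alignment

Global alignment is Needleman–Wunsch with affine gaps (Gotoh's
three-state recurrence), vectorized row-by-row with numpy; the horizontal
gap state is computed by a running-maximum identity so each row is a
constant number of vector operations. Traceback tie-breaking is fixed
(diagonal, then up, then left) for bit-reproducibility.

Scoring defaults are match +1, mismatch −2, gap open −2, gap extend −1,
with a gap run of length L costing `open + (L−1)·extend`. The mismatch
and gap weights were chosen so that the canonical single-base-indel
layout between distant mitogenomes — `ATAT-TA` vs `AT-TCTA`, two
one-base gap runs, zero mismatches — is the strict optimum for that
fragment pair (with the milder mismatch −1 the gapless four-match
alignment would win). The suite verifies optimality against exhaustive
enumeration of all alignments for every sequence pair of length ≤ 6 over
a two-letter alphabet.

The multiple aligner stacks equal-length inputs unchanged whenever the
most divergent pair is gap-free-optimal (the usual case for
length-conserved mitochondrial genes); otherwise it falls back to a
center-star construction: the sequence minimizing total k-mer distance is
the center, all others are pairwise-aligned to it, and the pairwise
alignments are merged on the center's coordinates ("once a gap, always a
gap"). Center-star was preferred over guide-tree progressive alignment
for determinism and simplicity; at the within-genus divergences targeted
here (a few percent) the two give equivalent distance estimates.

## Trees

Distances are p-distances (optionally Jukes–Cantor corrected) with
pairwise or complete gap deletion. A substitution model beyond JC is
deliberately out of scope: the divergences involved are 1–6 substitutions
per short gene, where model choice is immaterial.

NJ is Saitou–Nei with two determinism guarantees. First, *zero-distance
taxa are coalesced before the NJ loop* into a label-ordered caterpillar
of zero-length branches. Identical sequences are common in this setting
(whole clades share a barcode haplotype), and the Q-criterion ties they
produce would otherwise resolve differently depending on the surrounding
matrix — making two trees disagree about taxa that are *identical* in
both genes. Pre-coalescing makes identical-taxon resolution a function of
the labels only, so single-gene and reference trees agree wherever the
data do. Second, remaining Q ties break on the lexicographically smallest
canonical label pair. Negative branch-length estimates are clamped to 0.
Trees are compared unrooted via RF distance on nontrivial bipartitions
(normalized by 2(n−3) for binary trees); no rooting method is assumed.

## Barcodes

Each base maps to one solid vertical bar: A green (0,128,0), T red,
G black, C blue, in sequence order. Encoding and decoding are exact
inverses (nearest-match is *not* used: an off-palette pixel is an error,
so a decoded sequence is guaranteed authentic). SVG is the canonical
resolution-independent artifact; PNG is also written. The QR contract is
the payload text — a single FASTA entry `>accession|organism|gene` plus
the sequence — which any standard QR encoder renders; the package emits
the payload rather than bundling a QR rasterizer.

## Synthetic data

The simulator emulates a genus-scale collection of annotated circular
mitogenomes with known ground truth:

- **Genes.** 15 core PCGs at the canonical conserved lengths
  (atp9 222 bp, nad4L 267 bp, atp8 159 bp, … nad5 1983 bp) generated as
  valid table-4 CDSs (ATG start, sense codons, single terminal stop), and
  two rRNAs that acquire 1–4 introns of 100–400 bp per taxon, so realized
  rRNA lengths vary taxon-to-taxon as in real records.
- **Evolution.** Continuous-time Jukes–Cantor substitutions along a
  random ultrametric binary tree (or a supplied newick); per-gene rate
  overrides; Poisson indel events (1–3 bp) at a configurable rate;
  optional synonymous-only mode restricting proposals to amino-acid-
  preserving changes; nonsense mutations are rejected (purifying
  selection), so simulated CDSs always translate. The default per-site
  rate is 0.01 per unit branch length — a few substitutions per short
  gene across the tree, matching low within-genus divergence.
- **Tree prior.** Successive coalescence heights are separated by a
  minimum gap (0.5 pre-scaling, depth normalized to 1), so every internal
  branch represents measurable divergence. This encodes the intended
  regime — distinct clades differing by one-to-several SNPs per short
  gene — rather than letting the prior generate effectively unresolvable
  polytomies.
- **Genome context.** Genes are placed on alternating strands with
  GC-controlled intergenic spacers; base probabilities for CDS generation
  are bias-corrected for stop-codon rejection so realized genome GC lands
  within ±1 point of the target (default 27%, a typical fungal
  mitochondrial value).
- **Ground truth.** Every event is logged per branch; replaying the log
  from the root sequences must reproduce each leaf exactly (tested), and
  the identical-marker clade partition is recorded for recovery tests.
  `plant_diagnostics` injects fixed clade-diagnostic substitutions,
  refusing positions that collide with logged mutations.

The `example_genus_collection` fixture is the worked study emulation:
nine taxa in three clades of three identical genomes, markers carrying
two planted synonymous diagnostics each (so marker proteins remain
identical across all taxa while nucleotides discriminate every clade),
atp8 frozen at zero variation, nad5 accumulating stem indels, rRNAs
intron-riddled. On it the screen must select exactly {atp9, nad4L}.

**What the simulator does not emulate:** genome rearrangements, mobile
ORFs/homing endonucleases, tRNA evolution, annotation errors other than
rRNA length instability, recombination, and rate heterogeneity across
sites. Passing tests therefore demonstrate algorithmic correctness and
recovery under the stated generative model, not robustness to every
artifact of public records.

## Problem sizes and tolerances

The verification battery uses nine-taxon collections (50 replicates for
topology recovery, expecting ≥95% under the default rate), 100 random
4–8-taxon trees for NJ consistency on additive matrices (expecting 100%),
all 123 binary topologies on 4–6 leaves for RF correctness, all 15,876
two-letter sequence pairs of length ≤ 6 for alignment optimality, and
500 random 222-mers for the barcode codec. Newick branch lengths round-
trip at 6 decimals; floating-point score comparisons in traceback use an
absolute tolerance of 1e−9 (scores are small integer sums).

## Known limitations

- Center-star MSA is O(n·L²) per gene and not profile-refined; for
  deeply diverged rRNAs with many introns the alignment is serviceable
  for exclusion decisions but not publication-grade.
- The "interspecies" grouping defaults to exact genomic identity; real
  datasets with within-species variation need an explicit `groups` map.
- RF concordance is binary; a gene one rearrangement away from the
  reference is treated the same as a hopeless one.
- GenBank parsing trusts the feature table; genes annotated under
  nonstandard names outside the synonym map are invisible to the screen.
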