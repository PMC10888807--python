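# Methods

`shuffleseq` simulates and analyses experiments in which barcoded "shuffle
cassettes" are scattered through a genome by piggyBac transposition and
then recombined by Cre at their loxPsym sites, so that every induced
structural variant (SV) becomes readable as a novel barcode pair. This
note records the model, the numerical choices, and what the synthetic data
do and do not establish about real data.

## The cassette and its readouts

The default cassette is 176 bp: convergent T7 promoters at the ends, the
10x capture sequences CS2 (left) and CS1 (right), and two random 20-nt
barcodes (BC1 CS2-proximal, BC2 CS1-proximal) flanking the 34-bp
palindromic loxPsym site. The published design fixes the element order,
the total length, the barcode lengths, and the extraction anchors
(`TGAGC·BC1·ATAAC`, `GTTAT·BC2`, and `AAAGC`/`GTTAT` on the bottom
strand); the spacer sequences between elements are not published, so the
default design pads with fixed arbitrary spacers chosen once. Analyses
depend only on the anchors and element order, never on spacer content.

Three readouts are emitted:

1. **T7 IVT mapping reads.** Each cassette end transcribes through the
   barcodes and out into flanking genomic DNA. Read 1 carries the barcode
   region in the transcript's frame; read 2 carries flank sequence whose
   RT-primed far end varies per read (its first 8 nt double as a read-2
   UMI) and whose near end is pinned at the integration junction.
2. **Bulk amplicons.** UMI-tagged PCR products spanning BC1–loxPsym–BC2.
   Products carrying the same capture sequence on both sides are removed
   by suppressive PCR; the simulator never templates them, in either
   dialect (2-primer or 4-primer).
3. **Single-cell T7 feature reads.** 10x 3′ layout: 16-nt cell barcode +
   12-nt UMI in read 1; the captured transcript in read 2 with the first
   anchor at read position 15 (1-based) and the second barcode's GTTAT
   anchor at position 69 — the layout follows from a 14-nt context prefix
   plus the 34-bp loxPsym.

## Recombination model

Each cassette in genome frame has a left half and a right half around the
loxPsym site: a `top-CS2` insertion contributes (BC1, CS2) on the left and
(BC2, CS1) on the right; a `bottom-CS1` insertion the mirror image. Cre
crossover between cassettes A and B resolves in one of two registers,
drawn as an independent fair coin (the loxPsym spacer is symmetric, so the
published expectation is "roughly equal frequencies"; no sharper number is
given):

* **direct** — products A.left+B.right and B.left+A.right. In cis this is
  a deletion: the first product is the genomic scar, the second the
  excised circle (ecDNA), in 1:1 stoichiometry at formation.
* **inverted** — products A.left+rc(B.left) and rc(A.right)+B.right. In
  cis this is an inversion.

A product is detectable iff its halves carry different capture sequences.
The algebra reproduces the published detection rules with no further
assumptions: detected deletions arise only between same-orientation
insertions, detected inversions only between opposite orientations,
roughly half of all products are invisible, and for two `top-CS2`
insertions X (left) and Y (right) the ecDNA carries (BC1 of Y, BC2 of X)
while the scar keeps (BC1 of X, BC2 of Y), mirrored for `bottom-CS1`
pairs.

Cis partner choice is weighted by `exp(−d/λ)` with λ = 200 kb by default
(the efficiency of site-specific recombination drops exponentially with
genomic distance; on the 1-Mb desk chromosomes a 200-kb decay keeps both
short- and long-range events represented). Translocations are reciprocal
and occur with probability `trans_rate` (default 0.1 — a free parameter,
as no per-event trans probability is published). Events per clone are
Poisson(`cre_rate`).

## Genome and insertion model

The reference is a small diploid genome (default three 1-Mb chromosomes)
with two haplotypes (BL6/CAST) distinguished by heterozygous SNVs at a
mean spacing of 150 bp. Variants are substitutions only and are never
placed inside TTAA motifs, so both haplotypes share coordinates and TTAA
sites exactly; the real hybrid line also carries indels, which this model
omits to keep a common coordinate system. Insertions occupy TTAA sites
with target-site duplication (the TTAA appears on both sides of the
cassette), sampled without replacement across the whole population: on a
genome-scale reference two independent integrations essentially never hit
the same TTAA, and global without-replacement sampling reproduces that
sparsity on a small genome where per-clone sampling would produce ~20%
cross-clone site collisions.

## Insertion mapping

Barcodes are extracted by exact anchor matches; reads without both anchors
are rejected. The bundled placer is a seed-and-verify exact matcher for
the synthetic genome (16-mer seeds at three offsets, full-length verify
with a small mismatch allowance so reads from the non-reference haplotype
place across their SNVs); it is not a general aligner, and real-genome
alignment is out of scope. Reads that do not land on a TTAA junction, map
to more than one location, or carry internally contradictory allele
evidence are dropped.

Junction coordinates follow the BED convention: a plus-strand alignment's
position is its end, a minus-strand alignment's its start − 1. With
target-site duplication the two clusters of one insertion then sit exactly
4 bp apart, minus cluster first. Observations at one (chromosome,
position) are clustered by single linkage under a joint barcode budget —
the sum of the two per-barcode Levenshtein distances ≤ 6, one budget for
the cassette's whole barcode region (the published budget does not state
per-barcode vs summed; summed is the stricter reading and is
configurable). Representatives are modal with lexicographic tie-breaks for
determinism; the cluster allele is the majority ignoring noVariant
members. Replicates (N ≥ 1, default 2) are intersected on position,
strand and barcodes. The support filter removes clusters with < 6 reads
AND < 3 unique alignment lengths in the support replicate — the literal
conjunction of the published removal rule. Cluster pairs 4 bp apart on
(−,+) strands with opposite cassette strands and mutually
reverse-complementary barcodes become insertions; the insertion allele
reconciles the two clusters (one-sided noVariant defers to the other
side; disagreement → inconclusive). Finally, pairs must exceed the
parental amplicon thresholds (> 50 reads and > 30 UMIs, applied to
depth-normalized counts averaged across the four parental replicates and
rescaled to the mean replicate depth), and sites with several candidate
pairs keep the one with more unique lengths on the minus side.

With flanks of 30–110 bp and variants every ~150 bp, about a fifth of
insertions have no variant within reach of any read; their allele is an
honest `inconclusive`, matching the ~80% allele-assignment rate the
method achieves on real data. Recovery tests therefore demand exact
position/orientation/barcodes and *no wrong-haplotype* calls, not 100%
allele assignment.

## Bulk SV calling

Barcode pairs are counted per read and per unique UMI; 4-primer data are
collapsed over amplicon types, discarding pairs seen with only one type.
Depth normalization is counts-per-million (the published normalization is
not specified beyond "for sequencing depth"). A rearrangement is a pair
whose two barcodes are both in the bonafide insertion list but never
co-occur there, supported by ≥ 2 UMIs; barcode matching is exact by
default (amplicon reads are short and high quality), with an optional
Levenshtein-tolerant mode. Classification: same chromosome + same
orientation → deletion; same chromosome + opposite orientation →
inversion; different chromosomes → translocation; size is the distance
between insertion positions; deletion topology (scar vs ecDNA) follows
the crossover algebra above. Same-chromosome pairs on different
haplotypes are classified by the same rules and flagged `inter_homolog`.
Clone-well barcode sets use read count > mean + 1 population SD (ddof=0)
within wells above a 100k-read floor. IVT validation marks a call
supported iff at least one post-Cre IVT cluster carries the novel pair
while parental IVT data lacks it; a stricter mode additionally requires
the cluster's junction to match one of the call's parental junctions
(barcode-only is the default, since the published validation is stated in
terms of transcript support for the call).

## Single-cell genotyping

Cell barcodes are matched exactly against the whitelist (the vendor's
error-correction is out of scope; a 1-mismatch mode would be an easy
extension). Within each (cell, UMI), barcode/side combinations with read
share < 0.2 are discarded as chimeras. UMI counts are connected components
of the Hamming ≤ 1 graph. Capture sides are summed into a sparse
pair × cell matrix. Cells pass QC with > 1000 transcriptome UMIs, 1–12%
mitochondrial reads and doublet score < 0.4.

Clonotype reconstruction thresholds the matrix at ≥ 3 UMIs per pair per
cell, drops cells and pairs under 20 total UMIs, embeds cells
(library-size normalization to 10,000, top-100 PCs, 10-NN graph, Leiden at
resolution 1 — any modularity-style partitioner qualifies; clonotypes are
threshold-driven afterwards), rank-orders each community's pair detection
fractions and cuts at the first fold-change > 1.5. The ranked list runs
over the full pair universe of the working matrix, and a drop to zero —
including the implicit one past the end of the list — counts as an
inflection (a clean community would otherwise never inflect); a candidate
with no inflection at all is rejected. Candidates need a maximum
detection fraction > 0.5 and > 6 pairs; candidates whose pair
co-detection matrix splits into two blocks with cross-block co-detection
under 10% of the within-block level are dropped as fused doublets
(spectral bipartition — an automated stand-in for the published manual
inspection); near-duplicates merge on a Jaccard > 0.1 graph by
intersection. Bulk-derived clonotypes join the de novo set unless they
overlap one (Jaccard > 0.05). Discovery iterates: assign, remove
assignable cells, re-reconstruct, until a round adds nothing.

Assignment uses the cell's BC1 set at ≥ 2 UMIs (single barcodes, so
rearranged cells are not penalized): the top clonotype by precision is
accepted iff recall > 0.1 and precision > 0.75; a second-best recall
> 0.1 rejects the cell as a probable doublet; recall ≤ 0.1 is labeled
low capture. The precision–recall table averages per-cell detection
precision/recall against the assigned clonotype across UMI thresholds
1–10; cells with nothing detected at a threshold are excluded from the
precision mean (undefined) and contribute zero recall. Single-cell SV
calls apply the bulk rules per assigned cell at ≥ 2 UMIs; a call is
congruent iff both barcodes belong to the cell's clonotype, and
incongruent calls are flagged as probable ambient RNA and excluded from
the validated set.

## Synthetic-data defaults and their rationale

| parameter | default | why |
|---|---|---|
| chromosomes | 3 × 1 Mb | ~12k TTAA sites, enough for 5,000 insertions |
| variant spacing | 150 bp | published heterozygous variant density |
| clones × insertions | 100 × 50 | the bottlenecked population's scale |
| cre_rate | 5 events/clone | ~500 events, SVs rare vs parental pairs |
| λ (cis decay) | 200 kb | exponential-with-distance efficiency at desk scale |
| trans_rate | 0.1 | free parameter; translocations present but minority |
| IVT depth/error | 10 per side, 0.1% | enough reads and unique lengths to clear the support filter |
| amplicon molecules × UMIs | 30 × 2 | parental pairs must exceed their own > 50 read / > 30 UMI filter |
| chimera rate | 1% | visible artifact load, removed by the ≥ 2 UMI rule |
| cells / capture / UMI depth | 2000 / 0.7 / Poisson(6) | per-pair detection 0.7 · P(Pois(6) ≥ 3) ≈ 0.66, above the 0.5 max-detection-fraction acceptance rule; at depth 3 no uniform-abundance clone could ever be accepted |
| ambient / doublets | 2% / 3% | typical contamination; ambient is drawn from the pooled population abundance including rearranged pairs, so the congruence filter is exercised |

What the simulator does **not** model: chromatin context and positional
expression bias (all cassettes express equally), read indels (substitution
errors only — the Levenshtein budget is still exercised), ecDNA
replication/segregation (the observed excess detection of ecDNA over scar
in real data is a downstream biology/bias question; the simulator emits
both products 1:1), Cre toxicity and SV fitness effects, real-genome
repeats (multimapping is tested but rare on random sequence), and
transcriptome reads beyond the per-cell QC table. Passing tests therefore
establish algorithmic correctness and recovery under the stated noise
model, not robustness to every artifact of real libraries.

## Numerical and determinism notes

All randomness flows from named integer seeds through
`numpy.random.default_rng`; fixed seeds give byte-identical outputs
(tested). Modal representatives, cluster ordering, and multi-pair
resolution break ties lexicographically. Clustering is order-independent
by canonical pre-sorting. Degenerate inputs (empty observation tables,
empty matrices, wells with a single pair, communities with no inflection)
return empty results rather than raising. Problem sizes in the test suite
(e.g. 150-kb to 1-Mb chromosomes, 2,000 cells) were chosen as the
smallest scales at which the statistical assertions are well powered.
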