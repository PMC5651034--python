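# Methods

## Scope and model

The package re-implements, as a tested pipeline over synthetic data, a
targeted-capture analysis of gene-copy variation in an allotetraploid and
its two diploid progenitors. All inference operates on two inputs only:
per-base read depth from two mapping modes (strict and gapped) and filtered
variant calls. Nothing downstream looks at read sequences, so the simulator
abstracts reads as placed intervals without base-call errors or quality
strings; what it does model carefully is everything that shapes depth —
capture enrichment, subgenome divergence, InDel junctions, duplicated
templates, and homologous placement across subgenomes.

## Coordinates and containers

Internally all coordinates are 0-based half-open; GFF3 and VCF use their
native 1-based conventions at the I/O boundary, and BED/BedGraph are
0-based half-open. References are plain chromosome-name → sequence maps;
depth tracks carry one int array per chromosome plus the total mapped read
count and read length needed for normalization. Trees are scikit-bio
`TreeNode` objects; distance matrices are scikit-bio `DistanceMatrix`.

## Normalized coverage

`nc = (read_count / region_length) × (genome_size / total_mapped_reads)`.

The normalization factors (region length, genotype read number, genome
size) are fixed by the analysis convention; their arrangement here is
chosen so that (a) NC is dimensionless and scale-free in sequencing effort,
(b) NC equals 1 at genome-average read density, making on-target NC the
effective capture enrichment, and (c) a diploid genotype mapped on the
tetraploid reference at equal read number shows the expected ~200% of the
tetraploid control over its own subgenome's targets, because its sequenced
gene space is half as large. A read counts toward a region if it overlaps
it by at least one base (reads spanning two regions count in both); when a
track is loaded from BedGraph without placements, the count is estimated as
depth mass / read length.

## Decision procedures

**Two-genotype CNV.** Step 1 requires the higher NC to be at least
`unbalance_factor` (1.5) times the lower. Two phrasings of this test
circulate — "at least 50% higher" (high/low ≥ 1.5) and "less than 50% of
the other" (low/high < 0.5); only the former is consistent with the printed
duplication call at low/high = 0.57, so 1.5 is the default and the factor
is configurable. Step 2 calls a deletion below `deletion_ratio` (0.3) of
the partner. Step 3 compares the *low* genotype's own-reference NC directly
to the tetraploid population mean without ploidy correction — the only
reading consistent with the printed deletion at low/pop = 0.254 — and
splits deletion (< 0.3) from duplication-in-the-partner (≥ 0.3). With no
population baseline available step 3 returns `unresolved`. Three printed
table rows (Bna.PHYB.A03, Bna.CRY2.A08, Bna.CO-li.A10) are not reproducible
under any stated threshold combination (their derived ratios land in the
duplication branch); they are recorded as unreconciled in
`worked_examples.py` and excluded from acceptance checks.

**Cross-species bands.** The published percentages anchor the bands: 2–13%
was read as absent, 41–51% as reduced, ≥ 87% as present, and ≥ 136%
supported exchange. The defaults interpolate these as `absent_pct` 30,
`present_pct` 60, `exchange_pct` 120 (all configurable). An exchange is
called only when the matching progenitor is absent/reduced *and* every
value from the other progenitor clears the exchange band.

**Zero-coverage window scan.** Candidates are maximal runs of ≥
`zero_window` (19) bases with strict-mode depth exactly 0 in the carrier.
"Strongly covered in the other genotype" and "low gapped coverage" are not
quantified in the source convention; the defaults are mean other-genotype
depth ≥ 10 (`strong_cov_min`) and mean carrier gapped depth ≤ 2
(`low_cov_max`). The other-genotype condition removes shared dropouts
(reference-mapping problems); the gapped condition removes events the
short-InDel pathway already explains.

**Grantham classes.** The full 20×20 Grantham (1974) matrix is embedded;
bins ≤ 50 / 51–100 / 101–150 / > 150 follow the classical
conservative→radical convention. Against the 29 published substitution
labels this reproduces 27; H81Y (83) and T176N (65) are printed as
moderately radical but fall in the moderately-conservative bin — treated
as a source-side inconsistency and left mismatched rather than bending the
bins.

**Consequence annotation.** "Silent" means non-CDS/non-splice within the
analyzed neighborhood, distinct from synonymous. Splice sites are fixed at
the two canonical intron-terminal bases per side. Variants are annotated
against each overlapping gene copy independently. CDS substitutions
translate the affected codon strand-aware (codons may straddle exon
junctions); InDels are classified by length mod 3. Genes whose CDS length
is not a codon multiple are flagged as putative pseudogenes and
translation-dependent categories are skipped (CDS substitutions fall back
to silent with the flag set). The severity order used for per-copy
reporting is frameshift > stop gain/loss > splice > nonsynonymous (radical
→ conservative) > in-frame InDel > synonymous > silent.

**Neighbor joining.** p-distances ignore sites gapped in either sequence
(the distance model of the original GUI tool is unstated; topology, not
branch length, is the tested contract). The Q-criterion minimum is taken at
the lowest index pair for determinism; negative branch lengths are clamped
to zero and flagged. Bootstrap support is the percentage of
column-resampled replicates containing each internal bipartition of the
full-data tree; each bipartition is scored exactly once.

## The synthetic dataset

**What it emulates.** Two collinear subgenome chromosomes (C derived from A
by per-base substitution at `subgenome_divergence`, default 5%, followed by
gene-structure repair), 20 three-exon genes per subgenome (1.2 kb span,
900 bp in-frame CDS with terminal stop, GT/AG introns, one exon length
deliberately not a codon multiple), 100 bp single-end reads, 1e5 reads per
genotype, 100:1 on-target enrichment (the capture efficiency of the real
assay is unreported; 100:1 yields the ~350x on-target / ~0.35x off-target
contrast typical of small-panel capture). Defaults put ~21 kb of intergenic
sequence per gene so that on-target NC (~15) clears the region-discovery
threshold of 10.

**Read placement.** Each read is compared at its homologous coordinate on
its own chromosome and on the partner subgenome chromosome; it is placed at
the candidate with fewer mismatches if that count is ≤ `max_mismatches`
(2 per 100 bp, mirroring a strict short-read mapper). With no sequencing
errors simulated, cross-subgenome placement succeeds only where a read
window happens to be identity-conserved — about 5–12% of windows at 5%
divergence, which lands residual coverage of absent copies inside the
published 2–13% band. Strict mode rejects reads crossing any InDel
junction; gapped mode additionally places reads across a single gap of ≤ 18
bp (`max_short_indel`) and records the gap, which is what the short-InDel
caller aggregates (≥ 2 identical gap observations). The 18 bp boundary of
criterion-style sweeps is therefore reproduced by construction of gapped
placement, exactly as the real limit arises from the mapper's gap model.

**Homoeologous exchange** is injected into the tetraploid reference as a
*reciprocal* swap of the homoeologous gene spans (the standard meiotic
crossover outcome). A one-directional replacement cannot reproduce the
published observable — donor-subgenome reads concentrating at ≥ 120% on the
exchanged locus — because under best-match placement the donor's reads stay
on their own intact locus; after the reciprocal swap the exchanged locus is
the unique best match and both directions show the published pattern
(~20% matching progenitor, ~175–180% other progenitor in the default
dataset; the residual 20% is flank- and conserved-window carryover).

**Zygosity.** Genotypes carry two haplotypes; homozygous events go to both,
heterozygous to one, so heterozygous depth effects are halved and GT fields
derive directly. VCF records of injected small variants get MQ drawn as
N(55, 6) for SNPs and N(40, 8) for InDels (clipped to [0, 60]) and DP ~
Poisson(30), so the filter stage has realistic records to reject.

**The default study dataset** (seed-parameterized) has four diploid
genotypes (L1/L2 on A, K1/K2 on C) carrying 10 homozygous duplications and
8 homozygous whole-copy losses across the 40 copies, one homozygous 57 bp
deletion spanning an exon/intron boundary, SNPs of every consequence class
in both zygosities, InDels of 1–9 bp, the reciprocal exchange in family
G05, and three reconciliation scenarios: a tetraploid-only copy (gained), a
diploid-only copy (lost), and a copy covered but unannotated in the diploid
(annotation dropped, bait kept). Scenario copies are appended at staggered
chromosome ends so shared coordinates never collide between references.
The population baseline is 20 CNV-free tetraploid genotypes (the real
baseline had 280; 20 keeps the run in seconds while the per-copy
coefficient of variation stays below 2% at this depth).

**What the generator does not model** — and hence what passing tests do not
show about real data: base-call errors and quality-dependent filtering,
GC-bias and mappability variation, paralogous off-target capture beyond the
two subgenomes, alignment ambiguity beyond the two homologous candidates,
library duplicates, and real reference misassembly (the reference-patching
operation is provided and tested, but the default dataset does not need
it). CNV ratios on real data are noisier than the near-exact 2× and 0×
contrasts simulated here; the recovery rates measured on this dataset are
upper bounds.

## Problem sizes and runtimes

Defaults were chosen so the full analysis stays interactive: 424 kb per
subgenome, 1e5 reads per genotype and mapping, 20-genotype population. The
complete default dataset builds in ~7 s; the full test suite runs in under
a minute; the acceptance script in ~2 s. The dedicated deletion-scan and
InDel-boundary experiments run at ~30x on-target (8.4k and 12.6k reads) to
match the depth regime in which the zero-window statistics are interesting.

## Determinism

Every stochastic step takes a `numpy` Generator or integer seed; dataset
construction spawns independent child streams per component from one master
seed. Rerunning any stage, the file-based pipeline bundle, or the
acceptance script with the same seed is byte-identical (the bundle manifest
records thresholds, seed and package version).

## Known limitations

Besides the generator simplifications above: multi-allelic sites are not
decomposed (first alt only); the annotator reports one gene copy at a time
rather than a collapsed worst-across-genes record; region discovery and
gene-position coverage are alternative region proxies, with gene positions
preferred wherever annotation exists; NJ branch lengths on non-additive
inputs are conventional (clamped at zero) and only topology and support are
contractual.
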