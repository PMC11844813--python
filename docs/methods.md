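# Methods

This note documents the statistical models, algorithmic choices and
defaults behind `fingercore`, and what the synthetic-data tests do and
do not establish about real collections.

## Genotype model

All stages consume a samples × loci matrix of unordered biallelic
calls, stored as alt-allele dosages (0/1/2, −1 missing). Heterozygous
calls are unordered (`0/1` ≡ `1/0`); multiallelic and indel records are
excluded at import rather than split, because every downstream
statistic (MAF ≤ 0.5, PIC ≤ 0.375, the 10-class genotype spectrum)
assumes biallelic SNPs. Coordinates are 1-based closed intervals,
matching VCF and FASTA.

## Diversity statistics

For called-allele frequencies p, q = 1 − p at a locus:

* He = Nei's gene diversity = 1 − (p² + q²), the plain (uncorrected)
  estimator, whose biallelic ceiling is exactly 0.5. The 2n/(2n−1)
  small-sample correction is deliberately not applied; the "Nei" column
  is reported separately from "He" for table parity with the
  PowerMarker-style reports this layer replaces, though the two are
  identical for biallelic loci.
* Shannon–Wiener index = −(p ln p + q ln q), natural log (maximum ln 2).
* PIC = He − 2p²q² (Botstein's formula restricted to two alleles,
  ceiling 0.375 at p = 0.5).
* Ho = fraction of heterozygous calls among called samples.
* HWE: the Levene/Haldane exact conditional test. Conditioning on the
  observed allele counts, the heterozygote count n_Aa has probability
  `n!/(n_AA! n_Aa! n_aa!) · 2^{n_Aa} · n_A! n_a!/(2n)!`; the p-value
  sums the probabilities of all same-parity heterozygote counts whose
  probability does not exceed the observed one. Computed in log space
  (gammaln); an exact-rational enumeration oracle in the test suite
  verifies it exhaustively for all genotype triples with n ≤ 20.

Missing calls are excluded locus-wise (complete case per locus) from
every frequency computation; the screening cascade's default of zero
tolerated missingness makes this choice immaterial for surviving loci.

## Marker screening cascade

Six per-locus verdicts are combined as an order-free conjunction:
flanking-window uniqueness, missingness ≤ 0 (default), MAF ≥ 0.2,
PIC ≥ 0.35, exact-HWE p > 0.01 (strict inequality), and isolation
(no other variant within ±100 bp, **inclusive**: neighbours exactly
100 bp apart fail; the inclusive reading is the conservative one and
the distance is configurable).

Specificity uses a 2·flank+1 = 401 bp window centered on the SNP and an
exact full-window occurrence scan of both strands of the reference
(palindromic windows counted once per location). This is a
deterministic, conservative uniqueness predicate; the backend is
pluggable so an external aligner (e.g. BLAST) can substitute for
inexact matching on real genomes. Windows truncated by a contig end
fail the criterion. Dropping the specificity criterion
(`require_specificity=False`) reproduces the relaxed-panel variant and
provably yields a superset of the strict panel.

Note one structural coupling: for biallelic loci PIC is a monotone
function of MAF, and PIC ≥ 0.35 already implies MAF ≳ 0.337. A locus
therefore cannot fail the MAF criterion alone — it always drags PIC
down with it — and the panel means that emerge from the cascade
(PIC ≈ 0.366, MAF ≈ 0.42, Nei ≈ 0.485, Shannon ≈ 0.677) are largely
consequences of truncating the MAF spectrum at the PIC floor, not free
parameters.

**Chromosome-balanced panel selection.** Survivors are thinned to a
target size (e.g. 52 over 14 chromosomes) by quota-and-rank: base quota
⌊target/n_chrom⌋ per chromosome, remainder to the chromosomes holding
the most survivors (ties by name); within a chromosome, rank by
(PIC desc, MAF desc, locus id asc). Chromosomes short of quota
contribute what they have and the shortfall is redistributed, with a
warning. The rule is deterministic; published panel reductions of this
kind rarely state their exact cutoffs, so this rule is this package's
own, stated here so results are reproducible.

## Core-collection optimization

Objective: 0.7 · MR + 0.3 · SH over candidate subsets, where

* MR = mean pairwise modified Rogers distance,
  `MRD(i,j) = sqrt( Σ_l Σ_a (p_ila − p_jla)² / 2L )` with per-sample
  allele "frequencies" dosage/2 ∈ {0, ½, 1} and pairwise deletion of
  loci missing in either sample (L reduced accordingly). For biallelic
  loci this reduces to `sqrt( Σ_l (d_il − d_jl)² / 4L )`. MRD is a
  metric on call vectors (verified exhaustively on small fixtures).
* SH = pooled subset allele diversity `−Σ p̄ ln p̄`, averaged over loci.
  The per-locus normalization keeps SH on MR's O(1) scale so the
  0.7/0.3 weights are meaningful.

Search: steepest-ascent over single-sample swaps from seeded random
starts, 10 restarts by default, terminating at the first sweep with no
improving swap (hard cap 200 sweeps). Incremental update formulas make
one sweep O(k·(N−k)·L) in vectorized numpy. On every instance small
enough to enumerate (N ≤ 12, k ≤ 4) the search attains the exhaustive
optimum in the test suite; no global-optimality claim is made beyond
that.

The fraction sweep (grid 0.1–0.9, step 0.1) freezes each smaller core
inside the next larger one. Nesting guarantees a monotone
allele-coverage curve (coverage is monotone under supersets) and makes
the sweep cheap; the cost is that larger cores are conditionally rather
than independently optimized. The recommended fraction is the smallest
whose allele coverage CV = (observed locus–allele pairs in core) /
(observed in full collection) reaches the configurable goal (default
0.99).

## Fingerprints and barcodes

Fingerprints render homozygotes by base (C/C yellow, A/A green, T/T
blue, G/G purple), all heterozygotes as one class (white) and missing
calls gray; the barcode payload retains the full two-allele call the
coloring collapses. Payload grammar:
`FP1|sample=<label>|panel=<8-hex sha1 of the panel>|id=call;...` in
panel order; it round-trips through the bundled parser. Pair
distinguishability counts mismatches over loci called in both samples;
a pair with no shared called locus is flagged "uncomparable", never
"identical".

## Population structure

* p-distance: mismatch proportion between unordered calls with pairwise
  deletion; a heterozygote differs from either homozygote (call-level
  distance). This is the simplest model consistent with landmark
  distances such as 1/18 = 0.0556 and 1/7 = 0.1429 on small KASP panels.
* Neighbor joining: Saitou–Nei with the standard Q criterion,
  deterministic (Q ties broken by the lexicographically smallest pair
  of cluster representative labels, a cluster represented by its
  smallest leaf). Negative branch lengths are clamped to zero and
  flagged. NJ recovers additive matrices exactly; the suite checks 100
  random additive trees and cross-checks topologies against
  scikit-bio's independent implementation.
* Bootstrap: loci resampled with replacement per replicate; support is
  the percentage of replicate trees containing each internal
  bipartition of the full-panel tree.
* PCA: dosages mean-imputed per locus, column-centered, SVD; components
  ordered by eigenvalue with the largest-magnitude loading made
  positive (a fixed sign convention).
* Population assignment: nearest population by mean distance to
  reference samples (query excluded from its own references); the
  margin is the gap to the runner-up and exact ties return "ambiguous".

## KASP design

Forward allele-specific primers share a genomic 3′ segment ending
exactly on the SNP, one per allele, prepended with the standard FAM
(`GAAGGTGACCAAGTTCATGCT`) and VIC (`GAAGGTCGGAGTCAACGGATT`) tails.
Segment length is the first in 18–25 nt for which both allele versions
satisfy GC 30–60% and Tm 55–61 °C; otherwise the least-violating length
is kept and the verdicts record the failure. The common reverse primer
is the first (nearest, then shortest) downstream opposite-strand
18–25-mer meeting the same constraints with product ≤ 120 bp; if none
exists the assay returns a design-failure report rather than raising.
Tm defaults to the simple GC-count formula
`64.9 + 41·(G+C − 16.4)/N` on the genomic segment (tails excluded);
the model is pluggable (nearest-neighbor thermodynamics could be
injected), since only the constraint ranges — not the thermodynamic
model — are part of the design contract. The 1:1:3
(fwd1:fwd2:common) mix ratio is carried as annotation only.

## Synthetic data generator

The generator emulates a structured wild collection: 90 accessions in
four populations on 14 chromosomes of 50 kb (a desk-scale stand-in for
a multi-Gb genome), 1,000 loci by default (2,000 in the acceptance
pipeline so that the screened panel comfortably exceeds 52 markers with
all 14 chromosomes represented). Divergence follows Balding–Nichols:
ancestral alt frequency p₀ ~ U(0.05, 0.5), population frequency
p_k ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F). QTP diverges at F = 0.3; NW, NC
and NE descend from one shared intermediate ancestor (itself at F = 0.3
from the root) and differ mutually at only F = 0.02 — producing the
qualitative structure the pipeline must resolve: QTP separates cleanly,
the northern populations confuse. Sample counts default to 12/26/26/26
(QTP smallest); genotypes are binomial(2, p_k) dosages; missing calls
are masked independently at rate 0.005 (deep-resequencing-like
completeness); optional exact duplicates and an optional planted
inter-chromosomal duplication exercise the distinguishability and
specificity checks.

What the generator does **not** emulate: linkage disequilibrium and
recombination structure, a realistic (skewed) site-frequency spectrum,
genotyping error, null alleles, polyploid dosage ambiguity, and
repeat-rich genome architecture. Passing tests therefore demonstrate
the correctness of the algorithms and the qualitative behaviour of the
pipeline under controlled divergence — not calibrated performance on
real resequencing data, where specificity screening against a large
repetitive genome is the binding constraint.

## Numerical choices and degenerate inputs

* Exact-test p-values are capped at 1; comparisons use a 1e−12 relative
  slack to absorb log-space rounding.
* Screening threshold comparisons use a 1e−12 tolerance so that loci
  exactly at a boundary (MAF = 0.2, PIC = 0.35) pass, while HWE uses
  strict inequality (p > α) by design.
* Monomorphic loci have He = Shannon = PIC = 0 and HWE p = 1; all-missing
  loci are an error (or skipped where a subset makes them unavoidable).
* The optimizer treats objective improvements below 1e−12 as ties and
  keeps the incumbent, making runs reproducible for a fixed seed.

## Problem sizes

The bundled tests and the acceptance script run on simulated instances
sized for completeness of coverage: 2,000 loci × 90 samples for the
screening/fingerprinting/assignment pipeline, 200 loci for the
core-collection search (a 10× thinning; the objective is a per-locus
mean, so thinning changes estimates only by sampling noise), exhaustive
enumeration up to N = 12 accessions for optimizer validation, and 100
bootstrap replicates in tree tests. These sizes are the package's test
defaults, not limits of the implementation.
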