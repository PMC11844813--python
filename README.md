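# fingercore

Tools for building a **core germplasm collection** and a **SNP
fingerprinting system** from multi-sample genotype data, aimed at
curators of wild plant collections (the package's defaults emulate a
collection of ~90 wild *Elymus sibiricus* accessions from four Chinese
populations: the Qinghai–Tibet Plateau, Northwest, North and Northeast).

The pipeline covers, end to end:

1. **Core collection selection** — choose a subset of accessions
   maximizing the weighted blend `0.7 · MR + 0.3 · SH`, where MR is the
   mean pairwise *modified Rogers distance*
   `MRD(i,j) = sqrt( Σ_l Σ_alleles (p_il − p_jl)² / 2L )`
   within the subset and SH the subset's per-locus mean Shannon–Wiener
   allele diversity `−Σ p ln p`. A fraction sweep (10%…90%) with nested
   cores yields a monotone allele-coverage (CV) curve from which the
   smallest sufficient core size is read off.
2. **Marker screening** — reduce genome-wide SNPs to a candidate
   fingerprinting panel by five criteria: flanking-window (401 bp)
   uniqueness in the reference genome, zero missingness, MAF ≥ 0.2,
   PIC ≥ 0.35 (Botstein's `1 − Σp² − 2p²q²`), exact Hardy–Weinberg
   test p > 0.01, plus a ±100 bp isolation requirement; then thin the
   survivors to a fixed-size panel balanced over the 14 chromosomes.
3. **Fingerprinting** — per-accession call strings over the core panel,
   pairwise distinguishability, and text payloads for 2D barcodes.
4. **KASP assay design** — two tailed allele-specific forward primers
   (FAM/VIC) ending on the SNP plus a common reverse primer, validated
   against GC (30–60%), Tm (55–61 °C) and product-size (≤ 120 bp)
   constraints.
5. **Population identification** — p-distance matrices, neighbor-joining
   trees with bootstrap support, PCA on dosages, and nearest-population
   assignment of unknown accessions.

A seeded synthetic-data generator (Balding–Nichols population model, one
strongly diverged population and three weakly diverged sister
populations) produces complete VCF + FASTA + metadata datasets so every
stage is testable without external downloads.

## Worked example

```python
from fingercore.synthetic_data import SimConfig, simulate_dataset
from fingercore import marker_screen, core_select, popstruct

g, genome, truth = simulate_dataset(SimConfig(n_loci=2000), seed=42)

report = marker_screen.screen_cascade(g, genome)
panel = marker_screen.chromosome_balanced_select(report, 52)
surv = report.stats.loc[report.candidates]
print(len(report.candidates), round(surv.pic.mean(), 3), round(surv.maf.mean(), 3))

core = core_select.optimize_core(g.subset_loci(range(0, 2000, 10)), 0.4,
                                 core_select.CoreObjectiveConfig(restarts=3), seed=1)
print(core.size, round(core.cv, 3))

dm = popstruct.p_distance_matrix(g, report.candidates)
calls = popstruct.assign_population(dm, truth.sample_populations, g.samples)
qtp = [c for c in calls if truth.sample_populations[c.sample] == "QTP"]
print(sum(c.population == "QTP" for c in qtp), "/", len(qtp))
```

prints

```
167 0.367 0.422
36 0.997
12 / 12
```

i.e. 167 of 2,000 loci survive the screen (their mean PIC of 0.367 sits
just under the biallelic ceiling of 0.375, a direct consequence of the
PIC ≥ 0.35 floor), a 36-accession core at the 40% fraction captures
99.7% of the observed alleles, and every Qinghai–Tibet-Plateau accession
is assigned to its source population — while the three northern
populations remain partly confusable, as expected from their weak
divergence.

The same stages are available from the shell:

```bash
fingercore simulate --seed 42 --n-loci 2000 --out data/
fingercore screen --vcf data/genotypes.vcf --ref data/reference.fa \
    --core-size 52 --out report.tsv
fingercore core --vcf data/genotypes.vcf --fraction 0.4 --seed 17 --out core.txt
fingercore tree --vcf data/genotypes.vcf --panel report.panel.txt \
    --bootstrap 100 --seed 7 --out tree.nwk
fingercore kasp --ref data/reference.fa --vcf data/genotypes.vcf \
    --panel report.panel.txt --out assays.tsv
```

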