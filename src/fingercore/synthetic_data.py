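"""Structured synthetic datasets: reference genome + VCF + metadata + truth.

Emulates a wild-germplasm collection of ~90 accessions from four
geographic populations genotyped at biallelic SNPs on 14 chromosomes.
Population structure follows the Balding-Nichols model: each locus has
an ancestral alt-allele frequency p0, and population k draws its
frequency from Beta(p0 (1-F_k)/F_k, (1-p0)(1-F_k)/F_k).  The QTP
population is strongly diverged (F = 0.3 by default); NW, NC and NE
descend from a shared intermediate ancestor (itself diverged from the
root at F = 0.3) and differ from one another only weakly (F = 0.02),
so they are mutually confusable while QTP separates cleanly — the
structure the downstream population-identification stages must resolve.

Genotypes are binomial(2, p_k) alt dosages; missing calls are masked at
a configurable rate; exact duplicate samples can be appended to exercise
distinguishability checks.  Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import (
    GenotypeMatrix,
    LocusRecord,
    ReferenceGenome,
    write_metadata,
    write_reference,
    write_vcf,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    n_chromosomes: int = 14
    chromosome_length: int = 50_000
    n_loci: int = 1000
    # population -> sample count; ~90 accessions, QTP the smallest group
    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {"QTP": 12, "NW": 26, "NC": 26, "NE": 26}
    )
    f_qtp: float = 0.3
    f_north_split: float = 0.3  # divergence of the shared NW/NC/NE ancestor
    f_within_north: float = 0.02
    maf_range: tuple[float, float] = (0.05, 0.5)  # ancestral alt frequency, uniform
    missing_rate: float = 0.005
    n_duplicates: int = 0
    plant_duplication: bool = False  # copy a segment between chromosomes
    duplication_length: int = 600

    def __post_init__(self) -> None:
        for f in (self.f_qtp, self.f_north_split, self.f_within_north):
            if not 0.0 < f < 1.0:
                raise ValueError("divergence parameters F must lie in (0, 1)")
        if self.chromosome_length < 1000:
            raise ValueError("chromosome length must be >= 1000")
        if any(n < 0 for n in self.pop_sizes.values()):
            raise ValueError("population sizes must be nonnegative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return sum(self.pop_sizes.values()) + self.n_duplicates

    @property
    def duplication_site(self) -> tuple[str, int, str, int]:
        """(source chrom, source start, target chrom, target start), 1-based."""
        return ("chr01", 10_001, "chr02", 10_001)


@dataclass
class TruthReport:
    sample_populations: dict[str, str]
    ancestral_freqs: np.ndarray  # alt frequency p0 per locus
    pop_freqs: dict[str, np.ndarray]  # per-population drawn alt frequencies
    duplicate_pairs: list[tuple[str, str]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_populations": self.sample_populations,
                "ancestral_freqs": [round(float(x), 6) for x in self.ancestral_freqs],
                "pop_freqs": {
                    k: [round(float(x), 6) for x in v] for k, v in self.pop_freqs.items()
                },
                "duplicate_pairs": self.duplicate_pairs,
            },
            indent=1,
        )


def _chrom_name(i: int) -> str:
    return f"chr{i + 1:02d}"


def simulate_reference(cfg: SimConfig, seed: int = 0) -> ReferenceGenome:
    """Seeded random chromosomes; optional planted inter-chromosome
    duplication so flanking windows inside it are non-unique."""
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    for i in range(cfg.n_chromosomes):
        seqs[_chrom_name(i)] = "".join(
            rng.choice(_BASES, size=cfg.chromosome_length)
        )
    if cfg.plant_duplication:
        src_c, src_s, dst_c, dst_s = cfg.duplication_site
        L = cfg.duplication_length
        segment = seqs[src_c][src_s - 1 : src_s - 1 + L]
        dst = seqs[dst_c]
        seqs[dst_c] = dst[: dst_s - 1] + segment + dst[dst_s - 1 + L :]
    return ReferenceGenome(seqs)


def _balding_nichols(rng: np.random.Generator, p0: np.ndarray, f: float) -> np.ndarray:
    scale = (1.0 - f) / f
    p = rng.beta(np.maximum(p0 * scale, 1e-9), np.maximum((1.0 - p0) * scale, 1e-9))
    return np.clip(p, 0.0, 1.0)


def simulate_genotypes(
    cfg: SimConfig, genome: ReferenceGenome, seed: int = 0
) -> tuple[GenotypeMatrix, TruthReport]:
    """Draw loci, population frequencies and genotypes under the model."""
    rng = np.random.default_rng(seed)

    # spread loci across chromosomes as evenly as possible
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_loci // cfg.n_chromosomes)
    per_chrom[: cfg.n_loci % cfg.n_chromosomes] += 1
    loci: list[LocusRecord] = []
    for i in range(cfg.n_chromosomes):
        chrom = _chrom_name(i)
        clen = genome.length(chrom)
        positions = np.sort(rng.choice(np.arange(1, clen + 1), size=per_chrom[i], replace=False))
        for pos in positions:
            ref = genome.base(chrom, int(pos))
            alt = rng.choice([b for b in "ACGT" if b != ref])
            loci.append(LocusRecord(chrom, int(pos), ref, str(alt)))

    L = len(loci)
    lo, hi = cfg.maf_range
    p0 = rng.uniform(lo, hi, size=L)
    p_north = _balding_nichols(rng, p0, cfg.f_north_split)
    pop_freqs: dict[str, np.ndarray] = {}
    for pop in cfg.pop_sizes:
        if pop == "QTP":
            pop_freqs[pop] = _balding_nichols(rng, p0, cfg.f_qtp)
        else:
            pop_freqs[pop] = _balding_nichols(rng, p_north, cfg.f_within_north)

    samples: list[str] = []
    meta: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for pop, n in cfg.pop_sizes.items():
        for s in range(n):
            label = f"{pop}{s + 1:02d}"
            samples.append(label)
            meta[label] = pop
            rows.append(rng.binomial(2, pop_freqs[pop]).astype(np.int8))
    calls = np.stack(rows, axis=0)

    duplicate_pairs: list[tuple[str, str]] = []
    if cfg.n_duplicates > 0:
        src = rng.choice(len(samples), size=cfg.n_duplicates, replace=False)
        dup_rows = [calls[i].copy() for i in src]
        for i, row in zip(src, dup_rows):
            label = f"{samples[i]}-dup"
            duplicate_pairs.append((samples[i], label))
            meta[label] = meta[samples[i]]
            samples.append(label)
        calls = np.vstack([calls, np.stack(dup_rows)])

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = calls.copy()
        calls[mask] = -1

    g = GenotypeMatrix(samples, loci, calls)
    truth = TruthReport(
        sample_populations=meta,
        ancestral_freqs=p0,
        pop_freqs=pop_freqs,
        duplicate_pairs=duplicate_pairs,
    )
    return g, truth


def simulate_dataset(
    cfg: SimConfig | None = None, seed: int = 0
) -> tuple[GenotypeMatrix, ReferenceGenome, TruthReport]:
    """Convenience wrapper: genome then genotypes, from one master seed."""
    cfg = cfg or SimConfig()
    genome = simulate_reference(cfg, seed=seed)
    g, truth = simulate_genotypes(cfg, genome, seed=seed + 1)
    return g, genome, truth


def write_dataset(
    g: GenotypeMatrix,
    genome: ReferenceGenome,
    truth: TruthReport,
    outdir: str | Path,
) -> dict[str, Path]:
    """Emit VCF + FASTA + metadata TSV + truth JSON; seeded runs are
    byte-identical and the VCF round-trips through the reader."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "fasta": outdir / "reference.fa",
        "metadata": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(g, paths["vcf"])
    write_reference(genome, paths["fasta"])
    write_metadata(truth.sample_populations, paths["metadata"])
    paths["truth"].write_text(truth.to_json())
    return paths
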