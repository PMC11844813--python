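"""Genotype, reference-genome and sample-metadata I/O.

The central in-memory object is :class:`GenotypeMatrix`: samples x loci
unordered biallelic allele-pair calls, stored compactly as alt-allele
dosages (0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing).  Every
downstream stage — diversity statistics, marker screening, core-collection
optimization, fingerprinting, distance/tree analyses and KASP design —
consumes this object together with a :class:`ReferenceGenome`.

Coordinates are 1-based throughout, matching VCF and FASTA conventions;
windows are 1-based closed intervals.  Heterozygous calls are unordered:
``0/1`` and ``1/0`` are the same call.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

NUCLEOTIDES = frozenset("ACGT")

MISSING = -1


class FingercoreError(Exception):
    """Base class for all package errors."""


class VcfParseError(FingercoreError):
    pass


class EmptyInputError(FingercoreError):
    pass


class ReferenceMismatchError(FingercoreError):
    pass


class DuplicateContigError(FingercoreError):
    pass


POPULATIONS = ("QTP", "NW", "NC", "NE", "UNKNOWN")


@dataclass(frozen=True)
class LocusRecord:
    """A biallelic SNP locus: chromosome, 1-based position, ref/alt bases."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus position must be >= 1, got {self.pos}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(
                f"ref/alt must be single bases in ACGT, got {self.ref!r}/{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref}) at {self.chrom}:{self.pos}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}_{self.pos}")

    def genotype_classes(self) -> tuple[str, str, str]:
        """Unordered genotype class labels for dosage 0, 1, 2."""
        het = "".join(sorted(self.ref + self.alt))
        return self.ref * 2, het, self.alt * 2


@dataclass
class GenotypeMatrix:
    """Samples x loci unordered allele-pair calls over {ref, alt} per locus.

    ``calls[i, j]`` is the alt-allele dosage of sample ``i`` at locus ``j``
    (0/1/2) or :data:`MISSING`.
    """

    samples: list[str]
    loci: list[LocusRecord]
    calls: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample labels must be unique")
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("calls must be 0, 1, 2 or MISSING (-1)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, label: str) -> int:
        try:
            return self.samples.index(label)
        except ValueError:
            raise KeyError(f"unknown sample {label!r}") from None

    def locus_index(self, locus_id: str) -> int:
        for j, loc in enumerate(self.loci):
            if loc.id == locus_id:
                return j
        raise KeyError(f"unknown locus {locus_id!r}")

    def call(self, i: int, j: int) -> tuple[str, str] | None:
        """Unordered allele pair (alphabetical) or None when missing."""
        d = int(self.calls[i, j])
        if d == MISSING:
            return None
        loc = self.loci[j]
        pair = {0: (loc.ref, loc.ref), 1: tuple(sorted((loc.ref, loc.alt))), 2: (loc.alt, loc.alt)}[d]
        return pair  # type: ignore[return-value]

    def dosage(self) -> np.ma.MaskedArray:
        return dosage_matrix(self)

    def subset_samples(self, labels: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in labels]
        return GenotypeMatrix(list(labels), list(self.loci), self.calls[idx, :])

    def subset_loci(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(list(self.samples), [self.loci[j] for j in idx], self.calls[:, idx])


@dataclass
class ReferenceGenome:
    """Chromosome id -> nucleotide sequence (uppercase, ACGTN)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}
        for chrom, seq in self.sequences.items():
            extra = set(seq) - set("ACGTN")
            if extra:
                raise ValueError(f"contig {chrom} contains non-ACGTN characters {sorted(extra)}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Base at 1-based position."""
        if pos < 1 or pos > len(self.sequences[chrom]):
            raise IndexError(f"position {pos} outside contig {chrom}")
        return self.sequences[chrom][pos - 1]

    def validate_locus(self, locus: LocusRecord) -> None:
        if locus.chrom not in self.sequences:
            raise ReferenceMismatchError(f"contig {locus.chrom} absent from reference")
        base = self.base(locus.chrom, locus.pos)
        if base != locus.ref:
            raise ReferenceMismatchError(
                f"locus {locus.id}: reference has {base} at {locus.chrom}:{locus.pos}, "
                f"expected ref allele {locus.ref}"
            )


@dataclass(frozen=True)
class FlankWindow:
    """Sequence window centered on a SNP, with truncation bookkeeping."""

    seq: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    center_offset: int  # 0-based index of the SNP base within seq
    truncated: bool


def extract_flanks(genome: ReferenceGenome, locus: LocusRecord, flank: int) -> FlankWindow:
    """Window of ``2*flank + 1`` bases centered on the SNP position.

    Windows running off a contig end are truncated and flagged rather than
    silently shortened.  With flank=200 an interior window is 401 bp, the
    length used for marker-specificity screening and KASP flank extraction.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if locus.chrom not in genome:
        raise ReferenceMismatchError(f"contig {locus.chrom} absent from reference")
    clen = genome.length(locus.chrom)
    lo = locus.pos - flank
    hi = locus.pos + flank
    start = max(1, lo)
    end = min(clen, hi)
    seq = genome.sequences[locus.chrom][start - 1 : end]
    return FlankWindow(
        seq=seq,
        start=start,
        end=end,
        center_offset=locus.pos - start,
        truncated=(lo < 1 or hi > clen),
    )


def dosage_matrix(g: GenotypeMatrix) -> np.ma.MaskedArray:
    """Alt-allele dosage matrix in {0,1,2} with missing calls masked."""
    calls = g.calls
    return np.ma.masked_array(calls, mask=(calls == MISSING))


def read_vcf(path: str | Path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    With ``biallelic_only`` set (the default), multiallelic records and
    indels are dropped and counted in the result's ``n_dropped``.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises assorted OSError/Exception types
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise EmptyInputError(f"VCF {path} contains no samples")

    loci: list[LocusRecord] = []
    rows: list[np.ndarray] = []
    dropped = 0
    try:
        for lineno, var in enumerate(vcf, start=1):
            alts = var.ALT
            is_snp = (
                len(alts) == 1
                and len(var.REF) == 1
                and len(alts[0]) == 1
                and var.REF in NUCLEOTIDES
                and alts[0] in NUCLEOTIDES
            )
            if not is_snp:
                if biallelic_only:
                    dropped += 1
                    continue
                raise VcfParseError(
                    f"record {lineno} ({var.CHROM}:{var.POS}) is not a biallelic SNP "
                    "and biallelic_only is off"
                )
            locus_id = var.ID if var.ID not in (None, ".", "") else f"{var.CHROM}_{var.POS}"
            loci.append(LocusRecord(var.CHROM, var.POS, var.REF, alts[0], locus_id))
            # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            gt = np.asarray(var.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING
            rows.append(gt)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF {path} near record {len(loci) + dropped + 1}: {exc}") from exc

    calls = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, loci, calls, n_dropped=dropped)


def write_vcf(g: GenotypeMatrix, path: str | Path, reference_name: str = "synthetic") -> None:
    """Write the matrix as a minimal VCF 4.2 file (GT only).

    Round-trips through :func:`read_vcf`: sample order, locus order and
    every call are preserved.
    """
    contigs: dict[str, int] = {}
    for loc in g.loci:
        contigs[loc.chrom] = max(contigs.get(loc.chrom, 0), loc.pos)
    gt_str = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        for chrom, maxpos in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.samples) + "\n")
        for j, loc in enumerate(g.loci):
            gts = "\t".join(gt_str[int(d)] for d in g.calls[:, j])
            fh.write(f"{loc.chrom}\t{loc.pos}\t{loc.id}\t{loc.ref}\t{loc.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_reference(path: str | Path) -> ReferenceGenome:
    """Load a FASTA reference; duplicate contig names are an error."""
    from Bio import SeqIO

    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise DuplicateContigError(f"duplicate contig name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise EmptyInputError(f"no FASTA records in {path}")
    return ReferenceGenome(sequences)


def write_reference(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_metadata(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample, population) into a mapping.

    Populations must be one of QTP/NW/NC/NE/UNKNOWN.  A header line
    ``sample<TAB>population`` is permitted and skipped.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise VcfParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sample, pop = parts
            if lineno == 1 and (sample, pop) == ("sample", "population"):
                continue
            if pop not in POPULATIONS:
                raise ValueError(f"{path}:{lineno}: unknown population {pop!r}")
            if sample in meta:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            meta[sample] = pop
    return meta


def write_metadata(meta: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for sample, pop in meta.items():
            fh.write(f"{sample}\t{pop}\n")
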