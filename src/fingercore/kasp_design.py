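"""KASP (Kompetitive Allele-Specific PCR) assay assembly and validation.

Each assay comprises two allele-specific forward primers — a genomic 3'
segment ending exactly on the SNP position, carrying the ref or alt
allele, prepended with the FAM or VIC universal tail — plus one common
reverse primer on the opposite strand downstream.  Constraint ranges:
GC between 30 and 60 percent (optimum 45), melting temperature between
55 and 61 degrees C, PCR product at most 120 bp.  Tm uses a simple
GC-count formula on the genomic segment (tails excluded) by default;
the formula is pluggable.  Assays are mixed 1:1:3 (fwd1:fwd2:common).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd
from Bio.SeqUtils import gc_fraction

from .genotype_io import LocusRecord, ReferenceGenome, extract_flanks
from .marker_screen import reverse_complement

FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
VIC_TAIL = "GAAGGTCGGAGTCAACGGATT"

MIX_RATIO = "1:1:3"  # forward1 : forward2 : common reverse, by volume


def tm_basic(seq: str) -> float:
    """Tm = 64.9 + 41 * (G+C - 16.4) / N  (simple GC-count formula)."""
    gc = sum(seq.count(b) for b in "GC")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def gc_percent(seq: str) -> float:
    return 100.0 * gc_fraction(seq)


@dataclass
class KaspConfig:
    flank: int = 200
    max_product: int = 120
    primer_len: tuple[int, int] = (18, 25)
    gc_range: tuple[float, float] = (30.0, 60.0)
    gc_optimum: float = 45.0
    tm_range: tuple[float, float] = (55.0, 61.0)
    tm_model: Callable[[str], float] = tm_basic


@dataclass
class ConstraintCheck:
    name: str
    value: float
    ok: bool


@dataclass
class KaspAssay:
    locus: LocusRecord
    fwd_ref: str  # FAM tail + genomic segment ending on the ref allele
    fwd_alt: str  # VIC tail + genomic segment ending on the alt allele
    fwd_segment_ref: str
    fwd_segment_alt: str
    common_reverse: str
    product_length: int
    checks: list[ConstraintCheck]
    success: bool
    failure_reason: str = ""
    mix_ratio: str = MIX_RATIO

    @property
    def passed_all(self) -> bool:
        return self.success and all(c.ok for c in self.checks)


def _segment_ok(seq: str, cfg: KaspConfig) -> bool:
    gc = gc_percent(seq)
    tm = cfg.tm_model(seq)
    return cfg.gc_range[0] <= gc <= cfg.gc_range[1] and cfg.tm_range[0] <= tm <= cfg.tm_range[1]


def _segment_penalty(seq: str, cfg: KaspConfig) -> float:
    gc = gc_percent(seq)
    tm = cfg.tm_model(seq)
    pen = max(0.0, cfg.gc_range[0] - gc) + max(0.0, gc - cfg.gc_range[1])
    pen += max(0.0, cfg.tm_range[0] - tm) + max(0.0, tm - cfg.tm_range[1])
    return pen


def assemble_kasp_assay(
    genome: ReferenceGenome, locus: LocusRecord, cfg: KaspConfig | None = None
) -> KaspAssay:
    """Assemble primers for one SNP; deterministic for fixed genome/config.

    Forward segment length is the first in the configured range whose
    ref- and alt-allele versions both satisfy GC and Tm; failing that,
    the least-penalized length is kept and the verdicts record the
    violation.  The common reverse primer is the first (closest, then
    shortest) downstream opposite-strand 18-25-mer satisfying GC/Tm with
    product length within bound; absence of any such placement yields a
    design-failure report, not an exception.
    """
    cfg = cfg or KaspConfig()

    def failure(reason: str) -> KaspAssay:
        return KaspAssay(
            locus=locus,
            fwd_ref="",
            fwd_alt="",
            fwd_segment_ref="",
            fwd_segment_alt="",
            common_reverse="",
            product_length=0,
            checks=[],
            success=False,
            failure_reason=reason,
        )

    window = extract_flanks(genome, locus, cfg.flank)
    if window.truncated:
        return failure("edge: flanking window truncated at contig end")
    genome.validate_locus(locus)
    seq = window.seq
    center = window.center_offset

    lo, hi = cfg.primer_len
    best_len, best_pen = None, float("inf")
    for n in range(lo, hi + 1):
        upstream = seq[center - n + 1 : center]
        ref_seg = upstream + locus.ref
        alt_seg = upstream + locus.alt
        pen = _segment_penalty(ref_seg, cfg) + _segment_penalty(alt_seg, cfg)
        if pen == 0.0:
            best_len, best_pen = n, 0.0
            break
        if pen < best_pen:
            best_len, best_pen = n, pen
    n = best_len
    upstream = seq[center - n + 1 : center]
    ref_seg = upstream + locus.ref
    alt_seg = upstream + locus.alt
    fwd_start = center - n + 1  # 0-based offset of forward primer within window

    # common reverse primer: scan downstream placements, nearest first
    placement = None
    for gap in range(1, len(seq)):
        for rlen in range(lo, hi + 1):
            start = center + gap  # 0-based start of the primed genomic block
            end = start + rlen
            product = end - fwd_start
            if product > cfg.max_product:
                break
            if end > len(seq):
                break
            block = seq[start:end]
            rev = reverse_complement(block)
            if _segment_ok(rev, cfg):
                placement = (rev, product)
                break
        if placement:
            break
        if center + gap + lo - fwd_start > cfg.max_product:
            break
    if placement is None:
        return failure("no reverse-primer placement satisfies the constraints")
    rev, product = placement

    assay = KaspAssay(
        locus=locus,
        fwd_ref=FAM_TAIL + ref_seg,
        fwd_alt=VIC_TAIL + alt_seg,
        fwd_segment_ref=ref_seg,
        fwd_segment_alt=alt_seg,
        common_reverse=rev,
        product_length=product,
        checks=[],
        success=True,
    )
    assay.checks = validate_kasp_assay(assay, cfg)
    return assay


def validate_kasp_assay(a: KaspAssay, cfg: KaspConfig | None = None) -> list[ConstraintCheck]:
    """GC, Tm and product-length verdicts with measured values.

    Metrics are computed on genomic segments, excluding the universal
    tails.
    """
    cfg = cfg or KaspConfig()
    checks: list[ConstraintCheck] = []
    for name, seg in (
        ("fwd_ref", a.fwd_segment_ref),
        ("fwd_alt", a.fwd_segment_alt),
        ("common_reverse", a.common_reverse),
    ):
        if not seg:
            checks.append(ConstraintCheck(f"{name}_gc", float("nan"), False))
            checks.append(ConstraintCheck(f"{name}_tm", float("nan"), False))
            continue
        gc = gc_percent(seg)
        tm = cfg.tm_model(seg)
        checks.append(ConstraintCheck(f"{name}_gc", gc, cfg.gc_range[0] <= gc <= cfg.gc_range[1]))
        checks.append(ConstraintCheck(f"{name}_tm", tm, cfg.tm_range[0] <= tm <= cfg.tm_range[1]))
    checks.append(
        ConstraintCheck("product_length", a.product_length, 0 < a.product_length <= cfg.max_product)
    )
    return checks


def design_panel(
    genome: ReferenceGenome, loci: Sequence[LocusRecord], cfg: KaspConfig | None = None
) -> pd.DataFrame:
    """Assay sheet for a marker panel (one row per locus)."""
    cfg = cfg or KaspConfig()
    rows = []
    for loc in loci:
        a = assemble_kasp_assay(genome, loc, cfg)
        row = {
            "locus": loc.id,
            "chrom": loc.chrom,
            "pos": loc.pos,
            "fwd_ref": a.fwd_ref,
            "fwd_alt": a.fwd_alt,
            "common_reverse": a.common_reverse,
            "product_length": a.product_length,
            "success": a.success,
            "all_constraints_pass": a.passed_all,
            "failure_reason": a.failure_reason,
            "mix_ratio": a.mix_ratio,
        }
        for c in a.checks:
            row[c.name] = c.value
        rows.append(row)
    return pd.DataFrame(rows).set_index("locus")
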