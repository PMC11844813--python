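"""Candidate-marker screening cascade and chromosome-balanced core selection.

Genome-wide SNPs are reduced to a fingerprinting candidate panel by five
criteria, applied as an order-free conjunction:

1. specificity — the flanking window (default 200 bp each side, 401 bp
   total) occurs exactly once in the reference genome, both strands;
2. completeness — missing-call rate at most ``max_missing`` (default 0);
3. informativeness by frequency — MAF at least ``min_maf`` (default 0.2);
4. informativeness by PIC — PIC at least ``min_pic`` (default 0.35);
5. Hardy-Weinberg equilibrium — exact-test p strictly above ``hwe_alpha``
   (default 0.01);
plus an isolation requirement: no other variant within ``isolation`` bp
(default 100, closed interval) on the same chromosome.

Dropping the specificity criterion yields a larger panel (the screen's
relaxed variant for collections where single-copy windows are scarce).
The surviving candidates can then be thinned to a fixed-size core panel
spread evenly over the chromosomes by a deterministic quota-and-rank rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import divstats
from .genotype_io import (
    FingercoreError,
    GenotypeMatrix,
    LocusRecord,
    ReferenceGenome,
    extract_flanks,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CRITERIA = ("specificity", "missing", "maf", "pic", "hwe", "isolation")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _count_overlapping(haystack: str, needle: str) -> int:
    count = 0
    start = haystack.find(needle)
    while start != -1:
        count += 1
        start = haystack.find(needle, start + 1)
    return count


def count_genome_occurrences(genome: ReferenceGenome, window: str) -> int:
    """Occurrences of ``window`` in the genome, both strands, overlap-aware.

    A palindromic window (equal to its reverse complement) is counted once
    per location, not once per strand.
    """
    rc = reverse_complement(window)
    total = 0
    for seq in genome.sequences.values():
        total += _count_overlapping(seq, window)
        if rc != window:
            total += _count_overlapping(seq, rc)
    return total


def flank_uniqueness(
    genome: ReferenceGenome,
    locus: LocusRecord,
    flank: int = 200,
    backend: Callable[[ReferenceGenome, str], int] | None = None,
) -> bool:
    """True iff the full flanking window maps uniquely to the genome.

    Truncated windows (locus within ``flank`` bp of a contig end) fail.
    ``backend`` is a pluggable occurrence counter ``(genome, window) -> int``;
    the built-in is an exact full-window scan of both strands, a
    conservative stand-in for unique-alignment checks.
    """
    win = extract_flanks(genome, locus, flank)
    if win.truncated:
        return False
    counter = backend or count_genome_occurrences
    return counter(genome, win.seq) == 1


def isolation_filter(loci: Sequence[LocusRecord], isolation: int = 100) -> list[bool]:
    """Per-locus verdict: no other variant within ±``isolation`` bp (closed).

    Input must be sorted by (chrom, pos); neighbours at a distance of
    exactly ``isolation`` fail (inclusive window).
    """
    keys = [(loc.chrom, loc.pos) for loc in loci]
    if keys != sorted(keys):
        raise ValueError("loci must be sorted by (chrom, pos)")
    verdicts = [True] * len(loci)
    for i in range(len(loci) - 1):
        a, b = loci[i], loci[i + 1]
        if a.chrom == b.chrom and b.pos - a.pos <= isolation:
            verdicts[i] = False
            verdicts[i + 1] = False
    return verdicts


@dataclass
class ScreenConfig:
    """Thresholds of the screening cascade; defaults are the strict panel's."""

    flank: int = 200
    max_missing: float = 0.0
    min_maf: float = 0.2
    min_pic: float = 0.35
    hwe_alpha: float = 0.01
    isolation: int = 100
    require_specificity: bool = True
    specificity_backend: Callable[[ReferenceGenome, str], int] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing <= 1 and 0 <= self.min_maf <= 0.5 and 0 <= self.min_pic <= 0.375):
            raise ValueError("screening thresholds out of range")
        if not 0 <= self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must be in [0, 1)")
        if self.isolation < 0:
            raise ValueError("isolation must be nonnegative")
        if self.require_specificity and self.flank < self.isolation:
            raise ValueError("flank must be >= isolation")


@dataclass
class ScreenReport:
    """Per-locus criterion verdicts plus the surviving panels."""

    verdicts: pd.DataFrame  # index locus id, boolean column per criterion + overall
    stats: pd.DataFrame  # per-locus diversity statistics
    candidates: list[str]  # surviving locus ids, genome order
    config: ScreenConfig

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


def screen_cascade(
    g: GenotypeMatrix, genome: ReferenceGenome | None, cfg: ScreenConfig | None = None
) -> ScreenReport:
    """Apply all criteria to every locus; the overall verdict is their AND.

    ``genome`` may be None only when ``require_specificity`` is off.
    Loci must be sorted by (chrom, pos) for the isolation check.
    """
    cfg = cfg or ScreenConfig()
    if cfg.require_specificity and genome is None:
        raise FingercoreError("specificity screening requires a reference genome")

    stats = divstats.locus_stats_table(g)
    iso = isolation_filter(g.loci, cfg.isolation)

    rows = {}
    for j, loc in enumerate(g.loci):
        s = stats.loc[loc.id]
        if cfg.require_specificity:
            spec_ok = flank_uniqueness(genome, loc, cfg.flank, cfg.specificity_backend)
        else:
            spec_ok = True
        rows[loc.id] = {
            "specificity": bool(spec_ok),
            "missing": bool(s["missing_rate"] <= cfg.max_missing + 1e-12),
            "maf": bool(s["maf"] >= cfg.min_maf - 1e-12),
            "pic": bool(s["pic"] >= cfg.min_pic - 1e-12),
            "hwe": bool(s["hwe_p"] > cfg.hwe_alpha),
            "isolation": bool(iso[j]),
        }
    verdicts = pd.DataFrame.from_dict(rows, orient="index")
    verdicts["overall"] = verdicts[list(CRITERIA)].all(axis=1)
    candidates = [loc.id for loc in g.loci if bool(verdicts.loc[loc.id, "overall"])]
    return ScreenReport(verdicts=verdicts, stats=stats, candidates=candidates, config=cfg)


def chromosome_balanced_select(
    report: ScreenReport,
    target_size: int,
    chromosomes: Sequence[str] | None = None,
) -> list[str]:
    """Deterministic quota-and-rank reduction of the candidate panel.

    Per-chromosome quota = floor(target / n_chrom), with the remainder
    assigned to the chromosomes holding the most survivors (ties by
    chromosome name).  Within a chromosome, candidates are ranked by
    (PIC desc, MAF desc, locus id asc) and the quota taken from the top.
    Chromosomes short of their quota contribute what they have and the
    shortfall is redistributed to the best-stocked chromosomes, with a
    warning.
    """
    if target_size > report.n_candidates:
        raise ValueError(
            f"target size {target_size} exceeds {report.n_candidates} surviving candidates"
        )
    stats = report.stats
    by_chrom: dict[str, list[str]] = {}
    for lid in report.candidates:
        by_chrom.setdefault(str(stats.loc[lid, "chrom"]), []).append(lid)
    if chromosomes is None:
        chromosomes = sorted(by_chrom)
    chromosomes = list(chromosomes)
    n_chrom = len(chromosomes)
    if n_chrom == 0:
        raise ValueError("no chromosomes among survivors")

    ranked = {
        c: sorted(
            by_chrom.get(c, []),
            key=lambda lid: (-stats.loc[lid, "pic"], -stats.loc[lid, "maf"], lid),
        )
        for c in chromosomes
    }

    base, rem = divmod(target_size, n_chrom)
    order = sorted(chromosomes, key=lambda c: (-len(ranked[c]), c))
    quota = {c: base for c in chromosomes}
    for c in order[:rem]:
        quota[c] += 1

    take = {c: min(quota[c], len(ranked[c])) for c in chromosomes}
    shortfall = target_size - sum(take.values())
    if shortfall > 0:
        warnings.warn(
            f"{sum(1 for c in chromosomes if len(ranked[c]) < quota[c])} chromosome(s) "
            f"short of quota; redistributing {shortfall} slot(s)",
            stacklevel=2,
        )
    while shortfall > 0:
        spare = sorted(
            (c for c in chromosomes if len(ranked[c]) > take[c]),
            key=lambda c: (-(len(ranked[c]) - take[c]), c),
        )
        take[spare[0]] += 1
        shortfall -= 1

    chosen = {lid for c in chromosomes for lid in ranked[c][: take[c]]}
    return [lid for lid in report.candidates if lid in chosen]  # genome order
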