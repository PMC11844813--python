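"""Per-locus and collection-level genetic diversity statistics.

For a biallelic SNP with called-allele frequencies p (ref) and q = 1 - p:

* observed heterozygosity  Ho  = n_het / n_called
* expected heterozygosity  He  = 1 - (p^2 + q^2)   (Nei's gene diversity;
  the plain, uncorrected form, whose biallelic ceiling is exactly 0.5)
* Shannon-Wiener index          = -(p ln p + q ln q), natural log
* PIC (Botstein 1980, 2 alleles) = He - 2 p^2 q^2, ceiling 0.375 at q = 0.5
* HWE p-value: Levene/Haldane exact conditional test on genotype counts.

Missing calls are excluded locus-wise (complete case per locus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import linregress

from .genotype_io import MISSING, GenotypeMatrix

#: The 10 unordered genotype classes over {A,C,G,T}: 4 homozygous + C(4,2) het.
GENOTYPE_CLASSES = ("AA", "CC", "GG", "TT", "AC", "AG", "AT", "CG", "CT", "GT")


@dataclass(frozen=True)
class LocusStats:
    p_ref: float
    p_alt: float
    maf: float
    ho: float
    he: float
    nei: float  # identical to he for biallelic loci; kept for report parity
    shannon: float
    pic: float
    hwe_p: float
    missing_rate: float
    n_called: int


def _entropy2(p: float) -> float:
    q = 1.0 - p
    h = 0.0
    if p > 0.0:
        h -= p * math.log(p)
    if q > 0.0:
        h -= q * math.log(q)
    return h


def locus_stats(g: GenotypeMatrix, j: int) -> LocusStats:
    """All diversity statistics for locus ``j`` from its called samples."""
    col = g.calls[:, j]
    called = col[col != MISSING]
    n = called.size
    if n == 0:
        raise ValueError(f"locus {g.loci[j].id} has no called samples")
    n_het = int(np.sum(called == 1))
    n_aa = int(np.sum(called == 2))
    n_rr = n - n_het - n_aa
    p_alt = (n_het + 2 * n_aa) / (2 * n)
    p_ref = 1.0 - p_alt
    he = 1.0 - (p_ref**2 + p_alt**2)
    pic = he - 2.0 * p_ref**2 * p_alt**2
    return LocusStats(
        p_ref=p_ref,
        p_alt=p_alt,
        maf=min(p_ref, p_alt),
        ho=n_het / n,
        he=he,
        nei=he,
        shannon=_entropy2(p_ref),
        pic=pic,
        hwe_p=hwe_exact_test(n_rr, n_het, n_aa),
        missing_rate=1.0 - n / g.n_samples,
        n_called=n,
    )


def locus_stats_table(g: GenotypeMatrix, skip_uncalled: bool = False) -> pd.DataFrame:
    """Per-locus stats as a DataFrame indexed by locus id.

    ``skip_uncalled`` drops loci with zero called samples (useful on small
    subsets) instead of raising.
    """
    rows = {}
    for j, loc in enumerate(g.loci):
        try:
            s = locus_stats(g, j)
        except ValueError:
            if skip_uncalled:
                continue
            raise
        rows[loc.id] = {
            "chrom": loc.chrom,
            "pos": loc.pos,
            "maf": s.maf,
            "ho": s.ho,
            "he": s.he,
            "nei": s.nei,
            "shannon": s.shannon,
            "pic": s.pic,
            "hwe_p": s.hwe_p,
            "missing_rate": s.missing_rate,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional (Levene/Haldane) Hardy-Weinberg test.

    Conditions on the observed allele counts; the p-value sums, over all
    heterozygote counts of the same parity as the observed one, the
    probabilities no greater than the observed configuration's:

        P(n_het | n, n_A, n_a) = n! / (n_AA! n_Aa! n_aa!) * 2^n_Aa
                                 * n_A! n_a! / (2n)!
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_alt = n_het + 2 * n_homalt
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0  # monomorphic: single possible outcome

    def logprob(het: int) -> float:
        a = (rare - het) // 2  # rare-allele homozygotes
        b = n - het - a  # common-allele homozygotes
        return (
            gammaln(n + 1)
            - gammaln(a + 1)
            - gammaln(het + 1)
            - gammaln(b + 1)
            + het * math.log(2.0)
            + gammaln(rare + 1)
            + gammaln(2 * n - rare + 1)
            - gammaln(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logps = {h: logprob(h) for h in hets}
    obs = logps[n_het]
    p = sum(math.exp(lp) for lp in logps.values() if lp <= obs + 1e-12)
    return min(p, 1.0)


def maf_spectrum(mafs, bin_edges=None) -> pd.Series:
    """Relative-frequency histogram of MAF values over bins covering [0, 0.5]."""
    mafs = np.asarray(list(mafs), dtype=float)
    if mafs.size == 0:
        raise ValueError("no MAF values supplied")
    if bin_edges is None:
        bin_edges = np.arange(0.0, 0.5001, 0.05)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges[0] > 0.0 or bin_edges[-1] < 0.5 - 1e-12:
        raise ValueError("bins must cover [0, 0.5]")
    counts, _ = np.histogram(mafs, bins=bin_edges)
    labels = [
        f"[{lo:.2f},{hi:.2f})" if i < len(counts) - 1 else f"[{lo:.2f},{hi:.2f}]"
        for i, (lo, hi) in enumerate(zip(bin_edges[:-1], bin_edges[1:]))
    ]
    return pd.Series(counts / mafs.size, index=labels, name="frequency")


def genotype_spectrum(g: GenotypeMatrix) -> pd.Series:
    """Relative frequencies of the 10 unordered genotype classes.

    Four nucleotides yield 4 homozygous plus C(4,2) = 6 heterozygous
    classes; missing calls are excluded from the normalization.
    """
    counts = dict.fromkeys(GENOTYPE_CLASSES, 0)
    total = 0
    for j, loc in enumerate(g.loci):
        classes = loc.genotype_classes()
        col = g.calls[:, j]
        for d in (0, 1, 2):
            c = int(np.sum(col == d))
            counts[classes[d]] += c
            total += c
    freqs = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return pd.Series(freqs, name="frequency")


def spectrum_concordance(spec_a: pd.Series, spec_b: pd.Series) -> float:
    """R^2 of the least-squares line fitted between two spectra."""
    a = np.asarray(spec_a, dtype=float)
    b = np.asarray(spec_b.reindex(spec_a.index) if isinstance(spec_b, pd.Series) else spec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spectra must share bins")
    if np.allclose(a, b):
        return 1.0
    return float(linregress(a, b).rvalue ** 2)
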