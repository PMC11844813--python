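"""Shared fixtures: hand-built genotype fixtures, the default synthetic
collection, and independent oracles (exact HWE enumeration, random
additive trees)."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from fingercore.genotype_io import GenotypeMatrix, LocusRecord, ReferenceGenome
from fingercore.marker_screen import ScreenConfig, screen_cascade
from fingercore.synthetic_data import SimConfig, simulate_dataset


def make_matrix(dosages, loci=None, samples=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a samples x loci dosage array
    (-1 = missing), defaulting loci to A/G SNPs 1 kb apart."""
    calls = np.asarray(dosages, dtype=np.int8)
    n, L = calls.shape
    if loci is None:
        loci = [LocusRecord("chr01", 1000 * (j + 1), "A", "G") for j in range(L)]
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(list(samples), list(loci), calls)


def hwe_enumeration_oracle(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact-rational Levene enumeration over all heterozygote counts
    compatible with the observed allele counts (independent of the
    log-space implementation under test)."""
    n = n_homref + n_het + n_homalt
    n_alt = n_het + 2 * n_homalt
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0
    denom = comb(2 * n, rare)  # ways to choose rare-allele slots
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        a = (rare - het) // 2
        b = n - het - a
        # multinomial count of genotype configurations times 2^het
        ways = Fraction(
            comb(n, a) * comb(n - a, het) * (2**het), denom
        )
        probs[het] = ways
    total = sum(probs.values())
    obs = probs[n_het]
    p = sum(v for v in probs.values() if v <= obs) / total
    return float(p)


def random_additive_tree(n: int, rng: np.random.Generator):
    """Random binary tree with positive branch lengths; returns
    (labels, leaf-to-leaf distance matrix).  Distances on such a matrix
    are additive, so neighbor joining must recover the tree exactly."""
    adj: dict[str, dict[str, float]] = {}

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    add_edge("L0", "L1", rng.uniform(0.1, 1.0))
    internal = 0
    for i in range(2, n):
        edges = sorted((a, b) for a in adj for b in adj[a] if a < b)
        a, b = edges[rng.integers(len(edges))]
        w = adj[a].pop(b)
        adj[b].pop(a)
        m = f"I{internal}"
        internal += 1
        f = rng.uniform(0.2, 0.8)
        add_edge(a, m, w * f)
        add_edge(m, b, w * (1 - f))
        add_edge(m, f"L{i}", rng.uniform(0.1, 1.0))

    labels = [f"L{i}" for i in range(n)]
    D = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(labels):
            D[i, j] = dist[dst]
    return labels, D


@pytest.fixture(scope="session")
def default_dataset():
    """The default structured collection: 90 samples, 4 populations,
    QTP strongly diverged, 2000 loci on 14 chromosomes, seed 42."""
    g, genome, truth = simulate_dataset(SimConfig(n_loci=2000), seed=42)
    return g, genome, truth


@pytest.fixture(scope="session")
def default_screen(default_dataset):
    g, genome, _ = default_dataset
    return screen_cascade(g, genome, ScreenConfig())


def _hand_screen_calls(n=90):
    """Call columns for the 7-locus screening fixture (see fixture below)."""
    clean = np.array([0] * 23 + [1] * 45 + [2] * 22, dtype=np.int8)
    low_maf = np.array([1] * 18 + [0] * 72, dtype=np.int8)  # maf 0.1
    no_het = np.array([0] * 45 + [2] * 45, dtype=np.int8)  # extreme het deficit
    miss = clean.copy()
    miss[0] = -1
    return clean, low_maf, no_het, miss


@pytest.fixture(scope="session")
def screen_fixture():
    """Seven loci, each designed to violate exactly one screening
    criterion (plus one clean survivor):

    * L1 @ chrA:500   clean — passes everything
    * L2 @ chrA:1000  specificity fail (its 401 bp window also planted
      on chrB)
    * L3 @ chrA:1500  one missing call
    * L4 @ chrA:2000  MAF 0.1 (< 0.2); low MAF necessarily also drags
      PIC below 0.35, so this locus carries two false verdicts
    * L5 @ chrA:2500  extreme heterozygote deficit (HWE p ~ 0)
    * L6 @ chrA:3000 and L7 @ chrA:3060 — isolation pair, 60 bp apart
    """
    rng = np.random.default_rng(7)
    chrA = "".join(rng.choice(list("ACGT"), size=4000))
    chrB = "".join(rng.choice(list("ACGT"), size=1200))
    # plant L2's full window (pos 1000 +/- 200 -> chrA[799:1200]) on chrB
    chrB = chrB[:300] + chrA[799:1200] + chrB[701:]
    genome = ReferenceGenome({"chrA": chrA, "chrB": chrB})

    positions = [500, 1000, 1500, 2000, 2500, 3000, 3060]
    loci = []
    for k, pos in enumerate(positions):
        ref = genome.base("chrA", pos)
        alt = "A" if ref != "A" else "G"
        loci.append(LocusRecord("chrA", pos, ref, alt, id=f"L{k + 1}"))

    clean, low_maf, no_het, miss = _hand_screen_calls()
    cols = [clean, clean, miss, low_maf, no_het, clean, clean]
    calls = np.stack(cols, axis=1)
    g = GenotypeMatrix([f"s{i:02d}" for i in range(90)], loci, calls)
    return g, genome
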