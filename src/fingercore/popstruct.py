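"""Population structure: p-distances, neighbor-joining trees with
bootstrap support, PCA on dosages, and nearest-population assignment.

The distance model is the simple mismatch proportion between unordered
genotype calls (p-distance) with pairwise deletion of missing data; a
heterozygote versus either homozygote counts as a full mismatch.  Trees
are built with Saitou-Nei neighbor joining (exact on additive matrices),
deterministic with Q-criterion ties broken by the smallest label pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


class ZeroVarianceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal; NaN for uncomparable pairs
    n_compared: np.ndarray  # loci compared per pair

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_compared = np.asarray(self.n_compared, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def uncomparable_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                if self.n_compared[i, j] == 0:
                    out.append((self.labels[i], self.labels[j]))
        return out


def p_distance_matrix(g: GenotypeMatrix, panel: Sequence[str] | None = None) -> DistanceMatrix:
    """Mismatch proportion between unordered calls, pairwise deletion.

    ``panel`` restricts the comparison to the listed locus ids; pairs
    sharing no called locus get NaN distance and are flagged.
    """
    if panel is not None:
        g = g.subset_loci([g.locus_index(lid) for lid in panel])
    calls = g.calls
    called = calls != MISSING
    n = g.n_samples
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = called[i] & called
        comp[i] = both.sum(axis=1)
        diff = ((calls[i] != calls) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d[i] = np.where(comp[i] > 0, diff / np.maximum(comp[i], 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(g.samples), d, comp)


@dataclass
class PhyloTree:
    """Unrooted tree over sample labels, with optional bootstrap supports."""

    tree: dendropy.Tree
    negative_clamped: bool = False
    supports: dict[frozenset, float] | None = None  # bipartition -> % support

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def bipartitions(self) -> set[frozenset]:
        return tree_bipartitions(self.tree)


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial splits as frozensets of the side not containing the
    lexicographically smallest leaf (a canonical representation)."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    anchor = leaves[0]
    total = len(leaves)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = frozenset(set(leaves) - side)
        if 2 <= len(side) <= total - 2:
            out.add(side)
    return out


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Deterministic: ties in Q are broken by the lexicographically smallest
    pair of cluster representative labels (a cluster is represented by
    its smallest leaf label).  Negative branch lengths are clamped to
    zero and flagged.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 samples")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains uncomparable pairs")

    taxa = dendropy.TaxonNamespace(d.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    clamped = False

    nodes = []
    for lab in d.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    reps = list(d.labels)
    D = d.values.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                ia, ib = active[a], active[b]
                pair = tuple(sorted((reps[ia], reps[ib])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        ia, ib = active[a], active[b]
        dab = sub[a, b]
        va = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        vb = dab - va
        parent = dendropy.Node()
        na, nb = nodes[ia], nodes[ib]
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = clamp(va)
        nb.edge.length = clamp(vb)
        # new distances to the joined cluster
        newdist = np.zeros(D.shape[0] + 1)
        for c in active:
            if c in (ia, ib):
                continue
            newdist[c] = 0.5 * (D[ia, c] + D[ib, c] - dab)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newdist) - 1] = newdist[:-1]
        D[: len(newdist) - 1, -1] = newdist[:-1]
        nodes.append(parent)
        reps.append(min(reps[ia], reps[ib]))
        active = [c for c in active if c not in (ia, ib)] + [len(nodes) - 1]

    # join the last two clusters with a single edge
    ia, ib = active
    if nodes[ib].is_leaf():
        root, child = nodes[ia], nodes[ib]
    else:
        root, child = nodes[ib], nodes[ia]
    root.add_child(child)
    child.edge.length = clamp(D[ia, ib])
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return PhyloTree(tree=tree, negative_clamped=clamped)


def bootstrap_support(
    g: GenotypeMatrix,
    panel: Sequence[str] | None = None,
    replicates: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with bootstrap supports from locus resampling.

    Panel loci are resampled with replacement per replicate; each internal
    bipartition's support is the percentage of replicate trees containing
    it.  Seeded and deterministic.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if panel is not None:
        g = g.subset_loci([g.locus_index(lid) for lid in panel])
    base = nj_tree(p_distance_matrix(g))
    target = base.bipartitions()
    counts = dict.fromkeys(target, 0)
    rng = np.random.default_rng(seed)
    L = g.n_loci
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rep = g.subset_loci(list(cols))
        dm = p_distance_matrix(rep)
        if np.isnan(dm.values).any():
            continue  # replicate lost all shared loci for some pair
        for bp in nj_tree(dm).bipartitions():
            if bp in counts:
                counts[bp] += 1
    base.supports = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    _annotate_supports(base)
    return base


def _annotate_supports(pt: PhyloTree) -> None:
    leaves = sorted(pt.leaf_labels())
    anchor = leaves[0]
    total = len(leaves)
    for node in pt.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = frozenset(set(leaves) - side)
        if 2 <= len(side) <= total - 2 and pt.supports and side in pt.supports:
            node.label = f"{pt.supports[side]:.0f}"


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # fraction per component, non-increasing
    loadings: np.ndarray  # components x loci


def pca_dosage(g: GenotypeMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of the column-centered dosage matrix.

    Missing dosages are imputed to the locus mean before centering.  The
    sign convention makes each component's largest-magnitude locus
    loading positive, so coordinates are reproducible across runs and
    sample orderings (up to that fixed convention).
    """
    if g.n_samples < 2 or g.n_loci < 2:
        raise ValueError("PCA requires at least 2 samples and 2 loci")
    d = g.calls.astype(float)
    d[g.calls == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    x = d - d.mean(axis=0)
    total_var = float(np.sum(x**2))
    if total_var == 0.0:
        raise ZeroVarianceError("dosage matrix is constant; no variance to decompose")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for k in range(vt.shape[0]):
        if vt[k, np.argmax(np.abs(vt[k]))] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    k = n_components or min(g.n_samples - 1, g.n_loci, 10)
    coords = u[:, :k] * s[:k]
    varexp = (s**2 / total_var)[:k]
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=g.samples, columns=cols),
        variance_explained=varexp,
        loadings=vt[:k],
    )


@dataclass
class PopulationCall:
    sample: str
    population: str  # assigned population, or "ambiguous"
    margin: float  # gap between best and second-best mean distance
    mean_distances: dict[str, float]


def assign_population(
    d: DistanceMatrix,
    meta: Mapping[str, str],
    query_samples: Sequence[str],
    exclude_self: bool = True,
) -> list[PopulationCall]:
    """Nearest-population call by minimum mean distance to references.

    Reference samples are those in ``meta`` with a known population
    (not UNKNOWN); a query is excluded from its own reference set.  An
    exact tie between the two best populations yields "ambiguous".
    """
    idx = {s: i for i, s in enumerate(d.labels)}
    pops: dict[str, list[str]] = {}
    for s, p in meta.items():
        if p != "UNKNOWN" and s in idx:
            pops.setdefault(p, []).append(s)
    if not pops:
        raise ValueError("no reference samples with known population")
    calls = []
    for q in query_samples:
        if q not in idx:
            raise KeyError(f"query sample {q!r} not in distance matrix")
        qi = idx[q]
        means: dict[str, float] = {}
        for p, refs in pops.items():
            vals = [
                d.values[qi, idx[r]]
                for r in refs
                if (r != q or not exclude_self) and d.n_compared[qi, idx[r]] > 0
            ]
            if vals:
                means[p] = float(np.mean(vals))
        if not means:
            raise ValueError(f"query {q!r} has no comparable reference samples")
        ordered = sorted(means.items(), key=lambda kv: (kv[1], kv[0]))
        if len(ordered) > 1 and abs(ordered[0][1] - ordered[1][1]) < 1e-12:
            calls.append(PopulationCall(q, "ambiguous", 0.0, means))
        else:
            margin = (ordered[1][1] - ordered[0][1]) if len(ordered) > 1 else float("inf")
            calls.append(PopulationCall(q, ordered[0][0], margin, means))
    return calls
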