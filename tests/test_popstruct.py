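"""Distances, neighbor joining (vs additive-matrix and scikit-bio
oracles), bootstrap supports, PCA and population assignment."""

import numpy as np
import pytest

from conftest import make_matrix, random_additive_tree
from fingercore import popstruct
from fingercore.genotype_io import LocusRecord
from fingercore.popstruct import (
    DistanceMatrix,
    ZeroVarianceError,
    assign_population,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
    pca_dosage,
)
from fingercore.synthetic_data import SimConfig, simulate_dataset


def _two_pop_dataset(seed=0, n_per=20, loci=500):
    cfg = SimConfig(
        n_loci=loci, pop_sizes={"QTP": n_per, "NW": n_per}, missing_rate=0.0,
        chromosome_length=20000, n_chromosomes=4,
    )
    return simulate_dataset(cfg, seed=seed)


class TestPDistance:
    def test_identical_calls_give_zero(self):
        g = make_matrix([[0, 1, 2], [0, 1, 2]])
        assert p_distance_matrix(g).values[0, 1] == 0.0

    def test_one_mismatch_in_18_shared_loci(self):
        a = [0] * 18
        b = [0] * 17 + [2]
        d = p_distance_matrix(make_matrix([a, b])).values[0, 1]
        assert round(d, 4) == 0.0556

    def test_one_mismatch_in_7_shared_loci(self):
        a = [1] * 7
        b = [1] * 6 + [0]
        d = p_distance_matrix(make_matrix([a, b])).values[0, 1]
        assert round(d, 4) == 0.1429

    def test_het_vs_homozygote_is_a_full_mismatch(self):
        g = make_matrix([[1], [0]])
        assert p_distance_matrix(g).values[0, 1] == 1.0

    def test_pairwise_deletion_and_uncomparable_flag(self):
        g = make_matrix([[0, -1, 2], [2, 1, -1], [-1, 1, -1]])
        dm = p_distance_matrix(g)
        assert dm.n_compared[0, 1] == 1 and dm.values[0, 1] == 1.0
        assert ("s0", "s2") in dm.uncomparable_pairs()
        assert np.isnan(dm.values[0, 2])

    def test_zero_distance_iff_fingerprints_indistinguishable(self):
        from fingercore.fingerprint import build_fingerprint, pairwise_distinguishability

        rng = np.random.default_rng(14)
        g = make_matrix(rng.integers(-1, 3, size=(12, 30)))
        dm = p_distance_matrix(g)
        rep = pairwise_distinguishability(build_fingerprint(g, [l.id for l in g.loci]))
        for i in range(12):
            for j in range(i + 1, 12):
                pair = (g.samples[i], g.samples[j])
                if dm.n_compared[i, j] == 0:
                    continue
                assert (dm.values[i, j] == 0) == (pair in rep.indistinguishable)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        labels = ["a", "b", "c"]
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        pt = nj_tree(DistanceMatrix(labels, D, np.ones((3, 3), int)))
        pdm = pt.tree.phylogenetic_distance_matrix()
        tn = pt.tree.taxon_namespace
        for i in range(3):
            for j in range(i + 1, 3):
                assert pdm.distance(tn.get_taxon(labels[i]), tn.get_taxon(labels[j])) == pytest.approx(D[i, j])

    def test_recovers_additive_four_taxon_matrix(self):
        rng = np.random.default_rng(0)
        labels, D = random_additive_tree(4, rng)
        pt = nj_tree(DistanceMatrix(labels, D, np.ones_like(D, dtype=int)))
        pdm = pt.tree.phylogenetic_distance_matrix()
        tn = pt.tree.taxon_namespace
        for i in range(4):
            for j in range(i + 1, 4):
                assert pdm.distance(tn.get_taxon(labels[i]), tn.get_taxon(labels[j])) == pytest.approx(D[i, j])

    def test_topology_matches_scikit_bio_on_random_matrices(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(5, 9))
            x = rng.random((n, 4))
            D = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(D, 0)
            labels = [f"s{i}" for i in range(n)]
            mine = nj_tree(DistanceMatrix(labels, D, np.ones_like(D, dtype=int)))
            sk = sknj(SkDM(D, ids=labels))
            anchor = labels[0]
            sk_bip = set()
            for node in sk.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if anchor in side:
                    side = frozenset(set(labels) - side)
                if 2 <= len(side) <= n - 2:
                    sk_bip.add(side)
            assert mine.bipartitions() == sk_bip

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        labels, D = random_additive_tree(6, rng)
        pt1 = nj_tree(DistanceMatrix(labels, D, np.ones_like(D, dtype=int)))
        perm = rng.permutation(6)
        pt2 = nj_tree(
            DistanceMatrix(
                [labels[i] for i in perm], D[np.ix_(perm, perm)], np.ones_like(D, dtype=int)
            )
        )
        assert pt1.bipartitions() == pt2.bipartitions()

    def test_fewer_than_three_samples_rejected(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], D, np.ones((2, 2), int)))


class TestBootstrap:
    def test_strong_between_population_split_gets_high_support(self):
        g, _, truth = _two_pop_dataset(seed=1, n_per=8, loci=300)
        pt = bootstrap_support(g, replicates=100, seed=0)
        qtp = frozenset(s for s, p in truth.sample_populations.items() if p == "QTP")
        anchor = sorted(pt.leaf_labels())[0]
        split = qtp if anchor not in qtp else frozenset(pt.leaf_labels() - qtp)
        assert pt.supports is not None
        assert pt.supports.get(split, 0.0) >= 95.0

    def test_single_replicate_supports_are_zero_or_hundred(self):
        g, _, _ = _two_pop_dataset(seed=2, n_per=5, loci=100)
        pt = bootstrap_support(g, replicates=1, seed=3)
        assert set(pt.supports.values()) <= {0.0, 100.0}

    def test_seed_reproducibility(self):
        g, _, _ = _two_pop_dataset(seed=2, n_per=5, loci=100)
        a = bootstrap_support(g, replicates=20, seed=11)
        b = bootstrap_support(g, replicates=20, seed=11)
        assert a.supports == b.supports


class TestPca:
    def test_variance_explained_is_a_decreasing_subunit_partition(self):
        g, _, _ = _two_pop_dataset(seed=4, n_per=10, loci=200)
        res = pca_dosage(g)
        v = res.variance_explained
        assert np.all(np.diff(v) <= 1e-12)
        assert 0 < v.sum() <= 1 + 1e-9

    def test_first_component_separates_diverged_populations(self):
        g, _, truth = _two_pop_dataset(seed=5, n_per=20, loci=500)
        res = pca_dosage(g)
        pc1 = res.coordinates["PC1"]
        qtp = [s for s, p in truth.sample_populations.items() if p == "QTP"]
        other = [s for s in g.samples if s not in qtp]
        lo, hi = sorted([pc1[qtp].to_numpy(), pc1[other].to_numpy()], key=lambda x: x.mean())
        assert lo.max() < hi.min()  # no overlap along PC1

    def test_duplicated_sample_gets_identical_coordinates(self):
        rng = np.random.default_rng(6)
        base = rng.integers(0, 3, size=(8, 50))
        dosages = np.vstack([base, base[0]])
        g = make_matrix(dosages)
        res = pca_dosage(g)
        assert np.allclose(res.coordinates.iloc[0], res.coordinates.iloc[-1])

    def test_constant_matrix_is_zero_variance_error(self):
        g = make_matrix(np.ones((4, 5), dtype=int))
        with pytest.raises(ZeroVarianceError):
            pca_dosage(g)

    def test_coordinates_invariant_up_to_order_under_sample_permutation(self):
        g, _, _ = _two_pop_dataset(seed=8, n_per=6, loci=100)
        res1 = pca_dosage(g)
        perm = list(np.random.default_rng(1).permutation(g.samples))
        res2 = pca_dosage(g.subset_samples(perm))
        assert np.allclose(
            res1.coordinates.loc[perm].to_numpy(), res2.coordinates.to_numpy(), atol=1e-8
        )


class TestAssignPopulation:
    def test_query_identical_to_reference_called_with_margin(self):
        g, _, truth = _two_pop_dataset(seed=9, n_per=6, loci=200)
        dm = p_distance_matrix(g)
        calls = assign_population(dm, truth.sample_populations, ["QTP01"])
        assert calls[0].population == "QTP"
        assert calls[0].margin > 0

    def test_equidistant_query_is_ambiguous(self):
        labels = ["q", "r1", "r2"]
        D = np.array([[0, 0.5, 0.5], [0.5, 0, 0.9], [0.5, 0.9, 0]])
        dm = DistanceMatrix(labels, D, np.full((3, 3), 5))
        calls = assign_population(dm, {"r1": "NW", "r2": "NE"}, ["q"])
        assert calls[0].population == "ambiguous"

    def test_no_comparable_references_is_an_error(self):
        g = make_matrix([[0, 1], [-1, -1], [0, 1]], samples=["q", "r", "r2"])
        dm = p_distance_matrix(g)
        with pytest.raises(ValueError):
            assign_population(dm, {"r": "NW"}, ["q"])

    def test_four_population_structure_qtp_resolves_north_confuses(
        self, default_dataset, default_screen
    ):
        g, _, truth = default_dataset
        dm = p_distance_matrix(g, default_screen.candidates)
        calls = assign_population(dm, truth.sample_populations, g.samples)
        qtp = [c for c in calls if truth.sample_populations[c.sample] == "QTP"]
        north = [c for c in calls if truth.sample_populations[c.sample] != "QTP"]
        qtp_acc = sum(c.population == "QTP" for c in qtp) / len(qtp)
        north_errors = sum(
            c.population != truth.sample_populations[c.sample] for c in north
        )
        assert qtp_acc >= 0.95
        assert north_errors > 0  # NW/NC/NE remain mutually confusable
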