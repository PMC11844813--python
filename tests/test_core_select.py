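"""Core-collection objective, metric properties of the modified Rogers
distance, and optimizer correctness vs exhaustive enumeration."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_matrix
from fingercore import core_select
from fingercore.core_select import (
    CoreObjectiveConfig,
    allele_coverage,
    compare_diversity,
    fraction_sweep,
    modified_rogers_distance,
    mrd_matrix,
    optimize_core,
    weighted_objective,
)
from fingercore.synthetic_data import SimConfig, simulate_dataset


def _small_dataset(seed=3, n=10, loci=60):
    cfg = SimConfig(
        n_loci=loci, pop_sizes={"QTP": n // 2, "NW": n - n // 2},
        missing_rate=0.0, chromosome_length=5000, n_chromosomes=3,
    )
    g, _, _ = simulate_dataset(cfg, seed=seed)
    return g


class TestModifiedRogersDistance:
    def test_identical_samples_distance_zero(self):
        g = make_matrix([[0, 1, 2], [0, 1, 2]])
        assert modified_rogers_distance(g, 0, 1) == 0.0

    def test_opposite_homozygotes_distance_one(self):
        g = make_matrix([[0, 0, 0], [2, 2, 2]])
        assert modified_rogers_distance(g, 0, 1) == pytest.approx(1.0)

    def test_hom_vs_het_single_locus(self):
        g = make_matrix([[0], [1]])  # (A,A) vs (A,G)
        assert modified_rogers_distance(g, 0, 1) == pytest.approx(0.5)

    def test_missing_loci_excluded_pairwise(self):
        g = make_matrix([[0, -1, 2], [2, 1, -1]])  # only locus 0 shared
        assert modified_rogers_distance(g, 0, 1) == pytest.approx(1.0)

    def test_no_shared_loci_is_an_error(self):
        g = make_matrix([[0, -1], [-1, 2]])
        with pytest.raises(ValueError):
            modified_rogers_distance(g, 0, 1)

    def test_metric_properties_exhaustive_small_fixture(self):
        g = _small_dataset(seed=9, n=6, loci=40)
        D = mrd_matrix(g)
        n = g.n_samples
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)
        for i, j, k in itertools.permutations(range(n), 3):
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-9

    def test_matrix_agrees_with_pairwise_function(self):
        g = _small_dataset(seed=4, n=7, loci=30)
        D = mrd_matrix(g)
        for i in range(g.n_samples):
            for j in range(i + 1, g.n_samples):
                assert D[i, j] == pytest.approx(modified_rogers_distance(g, i, j))


class TestWeightedObjective:
    def test_monomorphic_identical_subset_scores_zero(self):
        g = make_matrix([[0, 0], [0, 0], [2, 1]])
        obj, mr, sh = weighted_objective(g, [0, 1])
        assert obj == 0.0 and mr == 0.0 and sh == 0.0

    def test_balanced_loci_give_ln2_diversity_component(self):
        g = make_matrix([[0, 0], [2, 2]])  # pooled p = 0.5 at both loci
        _, _, sh = weighted_objective(g, [0, 1])
        assert sh == pytest.approx(math.log(2))

    def test_blend_equals_componentwise_recomputation(self):
        g = _small_dataset(seed=5)
        cfg = CoreObjectiveConfig()
        for subset in ([0, 1, 2], [1, 3, 5, 7], list(range(8))):
            obj, mr, sh = weighted_objective(g, subset, cfg)
            # independent recomputation of the components
            D = mrd_matrix(g)
            idx = np.array(subset)
            mr2 = D[np.ix_(idx, idx)].sum() / (len(idx) * (len(idx) - 1))
            d = g.calls[idx].astype(float)
            ps = d.sum(axis=0) / (2 * len(idx))
            sh2 = np.mean(
                [-(p * math.log(p) + (1 - p) * math.log(1 - p)) if 0 < p < 1 else 0.0 for p in ps]
            )
            assert mr == pytest.approx(mr2) and sh == pytest.approx(sh2)
            assert obj == pytest.approx(0.7 * mr2 + 0.3 * sh2)

    def test_singleton_subset_rejected(self):
        g = _small_dataset()
        with pytest.raises(ValueError):
            weighted_objective(g, [0])


class TestAlleleCoverage:
    def test_full_collection_covers_everything(self):
        g = _small_dataset()
        assert allele_coverage(g, list(range(g.n_samples))) == 1.0

    def test_direct_count_example(self):
        # full collection has both alleles at 2 loci (4 pairs); the subset
        # carries only one allele at the second locus -> 3/4
        g = make_matrix([[1, 0], [1, 2]])
        assert allele_coverage(g, [0]) == pytest.approx(3 / 4)

    def test_adding_a_sample_never_decreases_coverage(self):
        g = _small_dataset(seed=21)
        rng = np.random.default_rng(0)
        subset = list(rng.choice(g.n_samples, size=3, replace=False))
        cv = allele_coverage(g, subset)
        for extra in range(g.n_samples):
            if extra not in subset:
                assert allele_coverage(g, subset + [extra]) >= cv - 1e-12


class TestOptimizeCore:
    @pytest.mark.parametrize("n,k", [(10, 3), (12, 4)])
    def test_matches_exhaustive_enumeration(self, n, k):
        g = _small_dataset(seed=3, n=n, loci=60)
        cfg = CoreObjectiveConfig(restarts=5)
        best = max(
            (weighted_objective(g, s, cfg)[0] for s in itertools.combinations(range(n), k))
        )
        sel = optimize_core(g, k / n, cfg, seed=0)
        assert sel.objective == pytest.approx(best, abs=1e-9)

    def test_duplicates_fixture_attains_full_coverage(self):
        cfg0 = SimConfig(
            n_loci=50, pop_sizes={"QTP": 10}, n_duplicates=10,
            missing_rate=0.0, chromosome_length=5000, n_chromosomes=2,
        )
        g, _, truth = simulate_dataset(cfg0, seed=8)
        cfg = CoreObjectiveConfig(restarts=5)
        sel = optimize_core(g, 0.5, cfg, seed=1)
        assert sel.cv == 1.0
        # keeping any duplicate pair cannot beat the optimum
        dup_subset = [a for a, _ in truth.duplicate_pairs][:5] + [
            b for _, b in truth.duplicate_pairs
        ][:5]
        assert sel.objective >= weighted_objective(g, dup_subset, cfg)[0] - 1e-9

    def test_same_seed_reproduces_selection(self):
        g = _small_dataset(seed=13, n=12, loci=80)
        cfg = CoreObjectiveConfig(restarts=3)
        a = optimize_core(g, 0.4, cfg, seed=17)
        b = optimize_core(g, 0.4, cfg, seed=17)
        assert a.samples == b.samples and a.objective == b.objective

    def test_infeasible_size_rejected(self):
        g = _small_dataset()
        with pytest.raises(ValueError):
            optimize_core(g, 0.05)  # rounds to < 2 samples

    def test_never_below_best_random_start(self):
        g = _small_dataset(seed=30, n=12, loci=60)
        cfg = CoreObjectiveConfig(restarts=4)
        sel = optimize_core(g, 0.33, cfg, seed=2)
        rng = np.random.default_rng(2)
        for _ in range(cfg.restarts):
            start = rng.choice(12, size=4, replace=False)
            assert sel.objective >= weighted_objective(g, list(start), cfg)[0] - 1e-9


@pytest.fixture(scope="module")
def sweep():
    g = _small_dataset(seed=6, n=20, loci=80)
    cfg = CoreObjectiveConfig(restarts=2)
    return g, fraction_sweep(g, cfg, seed=5)


class TestFractionSweep:

    def test_one_selection_per_fraction(self, sweep):
        _, res = sweep
        assert len(res.selections) == 9
        assert [s.fraction for s in res.selections] == [round(0.1 * i, 1) for i in range(1, 10)]

    def test_coverage_monotone_under_nesting(self, sweep):
        _, res = sweep
        cvs = [s.cv for s in res.selections]
        assert all(b >= a - 1e-12 for a, b in zip(cvs, cvs[1:]))
        prev = set()
        for s in res.selections:
            assert prev <= set(s.samples)  # nested cores
            prev = set(s.samples)

    def test_recommendation_is_smallest_fraction_reaching_goal(self, sweep):
        _, res = sweep
        goal = CoreObjectiveConfig().coverage_goal
        reaching = [s.fraction for s in res.selections if s.cv >= goal]
        assert res.recommended_fraction == (reaching[0] if reaching else 0.9)


class TestCompareDiversity:
    def test_full_subset_retains_everything(self):
        g = _small_dataset(seed=2)
        comp = compare_diversity(g, list(range(g.n_samples)))
        assert np.allclose(comp.table["ratio"], 1.0)
        assert comp.genotype_r2 == 1.0

    def test_schema_has_five_statistics_and_two_spectra(self):
        g = _small_dataset(seed=2)
        comp = compare_diversity(g, [0, 1, 2, 3])
        assert list(comp.table.index) == ["he", "ho", "nei", "shannon", "pic"]
        assert comp.maf_spectrum_core.sum() == pytest.approx(1.0)
        assert comp.maf_spectrum_full.sum() == pytest.approx(1.0)

    def test_random_40pct_core_of_panmictic_collection_retains_he(self):
        cfg0 = SimConfig(
            n_loci=200, pop_sizes={"NW": 30}, missing_rate=0.0,
            chromosome_length=20000, n_chromosomes=4,
        )
        g, _, _ = simulate_dataset(cfg0, seed=19)
        rng = np.random.default_rng(1)
        subset = list(rng.choice(g.n_samples, size=12, replace=False))
        comp = compare_diversity(g, subset)
        assert comp.table.loc["he", "ratio"] == pytest.approx(1.0, abs=0.1)
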