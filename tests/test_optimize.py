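"""Tests of the NSGA-II primitives and the surrogate-driven optimizer."""

import numpy as np
import pytest

from gabamorph.exceptions import OptimizationError, SelectionError
from gabamorph.optimize import (
    NSGAConfig,
    VariableBounds,
    composite_fitness,
    crowding_distance,
    fast_non_dominated_sort,
    mutate,
    roulette_selection,
    run_nsga2,
    two_point_crossover,
)
from gabamorph.synthetic import TRAITS


def brute_force_fronts(F):
    """O(n^2 m) peeling oracle for non-dominated sorting (maximization)."""
    F = np.asarray(F, dtype=float)
    remaining = list(range(len(F)))
    fronts = []
    while remaining:
        front = []
        for i in remaining:
            dominated = any(
                np.all(F[j] >= F[i]) and np.any(F[j] > F[i]) for j in remaining if j != i
            )
            if not dominated:
                front.append(i)
        fronts.append(front)
        remaining = [i for i in remaining if i not in front]
    return fronts


# ---------------------------------------------------------------------------
# sorting and crowding
# ---------------------------------------------------------------------------

def test_non_dominated_sort_example():
    fronts = fast_non_dominated_sort(np.array([[1, 2], [2, 1], [0, 0]]))
    assert sorted(fronts[0].tolist()) == [0, 1]
    assert fronts[1].tolist() == [2]


def test_identical_vectors_form_single_front():
    fronts = fast_non_dominated_sort(np.ones((6, 3)))
    assert len(fronts) == 1 and len(fronts[0]) == 6


def test_sort_matches_brute_force_oracle_on_random_populations():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(1, 21))
        m = int(rng.integers(2, 6))
        F = rng.normal(size=(n, m))
        if rng.random() < 0.5:
            F = np.round(F, 1)  # induce ties and duplicates
        ours = [sorted(f.tolist()) for f in fast_non_dominated_sort(F)]
        oracle = [sorted(f) for f in brute_force_fronts(F)]
        assert ours == oracle


def test_non_finite_objectives_rejected():
    with pytest.raises(OptimizationError):
        fast_non_dominated_sort(np.array([[1.0, np.nan]]))


def test_crowding_two_member_front_all_infinite():
    assert np.all(np.isinf(crowding_distance(np.array([[0, 1], [1, 0]]))))


def test_crowding_collinear_equally_spaced():
    # middle point: gap (2-0)/range(=2) per objective, two objectives -> 2.0
    F = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
    dist = crowding_distance(F)
    assert np.isinf(dist[0]) and np.isinf(dist[2])
    assert dist[1] == pytest.approx(2.0)


def test_crowding_invariant_to_permutation():
    rng = np.random.default_rng(1)
    F = rng.normal(size=(9, 3))
    base = crowding_distance(F)
    perm = rng.permutation(9)
    assert np.allclose(crowding_distance(F[perm]), base[perm])


# ---------------------------------------------------------------------------
# selection and variation
# ---------------------------------------------------------------------------

def test_roulette_single_positive_score_always_chosen():
    rng = np.random.default_rng(2)
    scores = np.array([0.0, 1.0, 0.0])
    assert np.all(roulette_selection(scores, 50, rng) == 1)


def test_roulette_uniform_frequencies_within_three_sigma():
    rng = np.random.default_rng(3)
    draws = roulette_selection(np.ones(4), 10_000, rng)
    freqs = np.bincount(draws, minlength=4) / 10_000
    sigma = np.sqrt(0.25 * 0.75 / 10_000)
    assert np.all(np.abs(freqs - 0.25) < 3 * sigma)


def test_roulette_scale_invariance_and_zero_scores():
    picks_a = roulette_selection(np.array([1.0, 2.0, 3.0]), 100, np.random.default_rng(4))
    picks_b = roulette_selection(np.array([2.0, 4.0, 6.0]), 100, np.random.default_rng(4))
    assert np.array_equal(picks_a, picks_b)
    with pytest.raises(SelectionError):
        roulette_selection(np.zeros(3), 5, np.random.default_rng(0))


class _FixedCutsRNG:
    """Deterministic stand-in generator: crossover fires and cuts at 1, 3."""

    def random(self, *args):
        return 0.0

    def choice(self, options, size=None, replace=True):
        return np.array([1, 3])


def test_two_point_crossover_swaps_middle_segment():
    p1 = np.array([1.0, 0.0, 5.0, 10.0])
    p2 = np.array([2.0, 3.0, 35.0, 40.0])
    c1, c2 = two_point_crossover(p1, p2, probability=0.8, rng=_FixedCutsRNG())
    # cuts (1, 3) exchange exactly the stress and gaba genes
    assert c1.tolist() == [1.0, 3.0, 35.0, 10.0]
    assert c2.tolist() == [2.0, 0.0, 5.0, 40.0]


def test_crossover_probability_zero_copies_parents():
    rng = np.random.default_rng(5)
    p1 = np.array([1.0, 0.0, 5.0, 10.0])
    p2 = np.array([2.0, 3.0, 35.0, 40.0])
    c1, c2 = two_point_crossover(p1, p2, probability=0.0, rng=rng)
    assert np.array_equal(c1, p1) and np.array_equal(c2, p2)


def test_mutation_rates_zero_and_one():
    bounds = VariableBounds()
    chrom = np.array([1.0, 0.0, 5.0, 10.0])
    rng = np.random.default_rng(6)
    assert np.array_equal(mutate(chrom, 0.0, bounds, rng), chrom)
    mutated = mutate(chrom, 1.0, bounds, rng)
    assert mutated[0] in bounds.cultivar_codes and mutated[1] in bounds.stress_codes
    assert bounds.gaba_mM[0] <= mutated[2] <= bounds.gaba_mM[1]
    assert bounds.day[0] <= mutated[3] <= bounds.day[1]


def test_composite_fitness_examples():
    ideal = np.array([10.0, 10.0, 10.0, 10.0, 10.0])
    assert composite_fitness(ideal, ideal) == 0.0
    objs = ideal - np.array([3.0, 4.0, 0.0, 0.0, 0.0])
    assert composite_fitness(objs, ideal) == pytest.approx(5.0)
    # monotone in each coordinate gap
    worse = ideal - np.array([3.0, 5.0, 0.0, 0.0, 0.0])
    assert composite_fitness(worse, ideal) > composite_fitness(objs, ideal)


# ---------------------------------------------------------------------------
# full runs on analytic surrogates
# ---------------------------------------------------------------------------

class _MonotoneSurrogate:
    """All five traits increase in GABA dose and day; best at the corner."""

    trait_names = TRAITS
    encoding = None
    y_train_max = np.full(5, 100.0)

    def predict_encoded(self, X):
        X = np.atleast_2d(X)
        score = X[:, 2] / 40.0 + X[:, 3] / 45.0  # in [0, 2]
        return np.outer(score, np.ones(5)) * 10.0


def test_monotone_surrogate_drives_to_the_corner():
    result = run_nsga2(_MonotoneSurrogate(), NSGAConfig(pop_size=40, generations=250, seed=7))
    rec = result.recommendation
    assert rec["gaba_mM"] > 39.6  # within 1% of the upper bound
    assert rec["day"] > 44.55


def test_best_fitness_trajectory_non_increasing():
    result = run_nsga2(_MonotoneSurrogate(), NSGAConfig(pop_size=30, generations=40, seed=8))
    best = result.history["best_F"].to_numpy()
    assert np.all(np.diff(best) <= 1e-9)


def test_final_population_respects_bounds_and_is_reproducible():
    cfg = NSGAConfig(pop_size=30, generations=30, seed=9)
    a = run_nsga2(_MonotoneSurrogate(), cfg)
    b = run_nsga2(_MonotoneSurrogate(), cfg)
    assert np.array_equal(a.population, b.population)
    pop = a.population
    assert set(pop[:, 0]) <= {1.0, 2.0}
    assert set(pop[:, 1]) <= {0.0, 1.0, 2.0, 3.0}
    assert pop[:, 2].min() >= 0.0 and pop[:, 2].max() <= 40.0
    assert pop[:, 3].min() >= 0.0 and pop[:, 3].max() <= 45.0


def test_final_front_is_mutually_non_dominated():
    result = run_nsga2(_MonotoneSurrogate(), NSGAConfig(pop_size=30, generations=20, seed=10))
    front_objs = result.objectives[result.fronts[0]]
    oracle = brute_force_fronts(front_objs)
    assert len(oracle) == 1  # no member dominates another


class _ConflictingSurrogate:
    """Two conflicting objectives traded off along the GABA axis."""

    trait_names = ("up", "down")
    encoding = None
    y_train_max = np.array([40.0, 40.0])

    def predict_encoded(self, X):
        X = np.atleast_2d(X)
        return np.column_stack([X[:, 2], 40.0 - X[:, 2]])


def _hypervolume_2d(front, ref=(0.0, 0.0)):
    pts = front[np.argsort(-front[:, 0], kind="stable")]
    hv, prev_y = 0.0, ref[1]
    for x, y in pts:
        if y > prev_y:
            hv += (x - ref[0]) * (y - prev_y)
            prev_y = y
    return hv


def test_front_hypervolume_non_decreasing_along_the_run():
    """With two conflicting objectives the dominated hypervolume of the
    first front grows (sampled along one deterministic trajectory)."""
    hvs = []
    for gens in (5, 20, 60):
        result = run_nsga2(
            _ConflictingSurrogate(), NSGAConfig(pop_size=40, generations=gens, seed=11)
        )
        front = result.objectives[result.fronts[0]]
        hvs.append(_hypervolume_2d(front))
    # crowding-based truncation can trade individual points, so allow
    # sub-percent dips while requiring overall growth
    tol = 0.01 * hvs[-1]
    assert hvs[0] <= hvs[1] + tol and hvs[1] <= hvs[2] + tol
    assert hvs[-1] > hvs[0]
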