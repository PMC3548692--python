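"""Thresholding, confusion counts, fitness, GA operators, LOOCV grid."""

import numpy as np
import pytest

import varprio.ga as ga
from varprio.errors import ConfigurationError
from varprio.ga import (
    EPSILON_GRID,
    PENALTY_FITNESS,
    TR_GRID,
    ConfusionCounts,
    DiseaseBenchmark,
    GaConfig,
    Individual,
    PreparedBenchmark,
    confusion,
    fitness,
    high_scoring_set,
    init_population,
    loocv_grid,
    next_generation,
    recombine,
    run_ga,
    score_threshold,
)


def make_bench(disease_id, F, a_idx):
    a = np.zeros(F.shape[0], dtype=bool)
    a[list(a_idx)] = True
    return PreparedBenchmark(disease_id, np.asarray(F, float), a,
                             [f"rs{i}" for i in range(F.shape[0])])


class TestThreshold:
    def test_product(self):
        assert score_threshold(np.array([2.0, 1.0]), 0.3) == pytest.approx(0.6)

    def test_epsilon_one_empties_y(self):
        scores = np.array([0.4, 0.9, 0.9])
        t = score_threshold(scores, 1.0)
        assert not high_scoring_set(scores, t).any()   # strict > at the max

    def test_grid_has_ten_steps(self):
        assert EPSILON_GRID == (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
        assert TR_GRID == (0.25, 0.50, 0.75, 1.00)

    def test_degenerate_all_zero_scores(self):
        assert score_threshold(np.zeros(4), 0.5) == 0.0

    def test_strict_comparison(self):
        y = high_scoring_set(np.array([0.9, 0.6, 0.2]), 0.6)
        assert y.tolist() == [True, False, False]

    def test_monotone_decreasing_in_epsilon(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0, 3, 200)
        prev = None
        for eps in EPSILON_GRID:
            y = set(np.flatnonzero(
                high_scoring_set(scores, score_threshold(scores, eps))))
            if prev is not None:
                assert y <= prev
            prev = y


class TestConfusion:
    def test_worked_example(self):
        # |S| = 10, |A| = 4, Y holds 3 of A plus 2 others
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], bool)
        y = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0], bool)
        cm = confusion(y, a)
        assert (cm.P, cm.N, cm.FP, cm.TN) == (3, 1, 2, 4)
        assert cm.sensitivity == pytest.approx(0.75)
        assert cm.specificity == pytest.approx(4 / 6)
        assert cm.accuracy == pytest.approx(0.7)

    def test_y_equals_s(self):
        a = np.array([1, 0, 0], bool)
        cm = confusion(np.ones(3, bool), a)
        assert cm.sensitivity == 1.0 and cm.specificity == 0.0

    def test_y_empty(self):
        a = np.array([1, 0, 0], bool)
        cm = confusion(np.zeros(3, bool), a)
        assert cm.sensitivity == 0.0 and cm.specificity == 1.0

    def test_counts_partition_s_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            a = rng.random(n) < 0.4
            if not a.any():
                continue
            y = rng.random(n) < rng.random()
            cm = confusion(y, a)
            # brute-force tally through explicit set operations
            A = set(np.flatnonzero(a)); Y = set(np.flatnonzero(y))
            S = set(range(n))
            assert cm.P == len(A & Y) and cm.N == len(A - Y)
            assert cm.FP == len(Y - A) and cm.TN == len(S - (A | Y))
            assert cm.P + cm.N == len(A)
            assert cm.P + cm.N + cm.FP + cm.TN == n
            assert cm.sensitivity + cm.N / len(A) == pytest.approx(1.0)

    def test_empty_certified_set_rejected(self):
        with pytest.raises(ValueError, match="sensitivity undefined"):
            confusion(np.ones(3, bool), np.zeros(3, bool))


class TestFitness:
    # one informative feature; certified SNPs carry it, background does not
    def perfect_bench(self, n=20, n_cert=2, did="d"):
        F = np.zeros((n, 2))
        F[:n_cert, 0] = 1.0
        return make_bench(did, F, range(n_cert))

    def test_perfect_and_feasible_gives_zero(self):
        benches = [self.perfect_bench(did="d1"), self.perfect_bench(did="d2")]
        w = np.array([1.0, 0.0])
        assert fitness(w, benches, epsilon=0.5, tr=0.25) == 0.0

    def test_violation_returns_dominating_penalty(self):
        # all SNPs score equally -> |Y|/|S| = 1 at eps < 1
        F = np.ones((10, 2))
        bench = make_bench("d", F, [0, 1])
        f = fitness(np.array([1.0, 1.0]), [bench], epsilon=0.5, tr=0.25)
        assert f >= PENALTY_FITNESS
        assert f > 1.0  # strictly dominates every feasible fitness

    def test_penalty_graded_by_worst_excess(self):
        F = np.ones((10, 2))
        worst = fitness(np.ones(2), [make_bench("d", F, [0])], 0.5, 0.25)
        milder = fitness(np.ones(2), [make_bench("d", F, [0])], 0.5, 0.75)
        assert worst > milder >= PENALTY_FITNESS

    def test_mean_aggregation(self):
        # disease 1: full sensitivity; disease 2: half the certified recovered
        b1 = self.perfect_bench(did="d1")
        F = np.zeros((20, 2))
        F[0, 0] = 1.0          # first certified carries the feature
        b2 = make_bench("d2", F, [0, 1])   # second certified does not
        w = np.array([1.0, 0.0])
        assert fitness(w, [b1, b2], epsilon=0.5, tr=0.25) == pytest.approx(0.25)

    def test_pooled_aggregation_flag(self):
        b1 = self.perfect_bench(did="d1")           # 2/2
        F = np.zeros((20, 2)); F[0, 0] = 1.0
        b2 = make_bench("d2", F, [0, 1])            # 1/2
        w = np.array([1.0, 0.0])
        assert fitness(w, [b1, b2], 0.5, 0.25, aggregate="pooled") == pytest.approx(
            1 - 3 / 4)


class TestPopulation:
    def test_size_and_determinism(self):
        pop1 = init_population(31, 120, np.random.default_rng(7))
        pop2 = init_population(31, 120, np.random.default_rng(7))
        assert len(pop1) == 120
        assert all((a.w == b.w).all() for a, b in zip(pop1, pop2))
        assert all((0 <= ind.w).all() and (ind.w <= 1).all() for ind in pop1)

    def test_coefficient_mean_near_half(self):
        pop = init_population(10, 1000, np.random.default_rng(0))
        mean = np.mean([ind.w for ind in pop])
        assert mean == pytest.approx(0.5, abs=0.02)


class TestRecombine:
    def test_identical_parents_no_mutation(self):
        w = np.random.default_rng(1).uniform(0, 1, 8)
        child = recombine(Individual(w), Individual(w),
                          np.random.default_rng(2), mutation_rate=0.0)
        assert (child.w == w).all() and child.provenance == "recombinant"

    def test_child_within_parent_envelope(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p1, p2 = rng.uniform(0, 1, 6), rng.uniform(0, 1, 6)
            child = recombine(Individual(p1), Individual(p2), rng).w
            lo = np.minimum(p1, p2) - 0.3
            hi = np.maximum(p1, p2) + 0.3
            assert (child >= np.maximum(lo, 0.0) - 1e-12).all()
            assert (child <= np.minimum(hi, 1.0) + 1e-12).all()

    def test_seeded_reproducibility(self):
        p1 = Individual(np.linspace(0, 1, 5))
        p2 = Individual(np.linspace(1, 0, 5))
        c1 = recombine(p1, p2, np.random.default_rng(9))
        c2 = recombine(p1, p2, np.random.default_rng(9))
        assert (c1.w == c2.w).all()


class TestNextGeneration:
    def evaluated_pop(self, rng, config):
        pop = init_population(5, config.population, rng)
        return [Individual(ind.w, fitness=float(i % 7) / 7, provenance=ind.provenance)
                for i, ind in enumerate(pop)]

    def test_default_scheme_counts(self):
        config = GaConfig()
        rng = np.random.default_rng(0)
        pop = self.evaluated_pop(rng, config)
        new = next_generation(pop, config, rng)
        assert len(new) == 120
        counts = {p: sum(ind.provenance == p for ind in new)
                  for p in ("random", "elite", "recombinant")}
        assert counts == {"random": 10, "elite": 10, "recombinant": 100}

    def test_elites_are_the_best_and_tie_broken_by_index(self):
        config = GaConfig(population=6, elite_pool=4, n_random_per_gen=1,
                          n_elite_carry=2, n_recombinants=3)
        rng = np.random.default_rng(0)
        pop = [Individual(np.full(3, i / 10), fitness=f)
               for i, f in enumerate([0.5, 0.5, 0.1, 0.5, 0.1, 0.9])]
        new = next_generation(pop, config, rng)
        elites = [ind for ind in new if ind.provenance == "elite"]
        # the two fitness-0.1 individuals, in original index order (2 then 4)
        assert (elites[0].w == pop[2].w).all() and (elites[1].w == pop[4].w).all()

    def test_all_equal_fitness_elites_by_index(self):
        config = GaConfig(population=5, elite_pool=3, n_random_per_gen=1,
                          n_elite_carry=2, n_recombinants=2)
        pop = [Individual(np.full(3, i / 10.0), fitness=0.4) for i in range(5)]
        new = next_generation(pop, config, np.random.default_rng(1))
        elites = [ind for ind in new if ind.provenance == "elite"]
        assert (elites[0].w == pop[0].w).all() and (elites[1].w == pop[1].w).all()

    def test_unevaluated_population_rejected(self):
        config = GaConfig(population=4, elite_pool=2, n_random_per_gen=1,
                          n_elite_carry=1, n_recombinants=2)
        pop = init_population(3, 4, np.random.default_rng(0))
        with pytest.raises(ConfigurationError, match="evaluated"):
            next_generation(pop, config, np.random.default_rng(0))

    def test_bad_scheme_sums_rejected(self):
        with pytest.raises(ConfigurationError):
            GaConfig(population=100)   # 10 + 10 + 100 != 100
        with pytest.raises(ConfigurationError):
            GaConfig(population=30, elite_pool=50, n_random_per_gen=10,
                     n_elite_carry=10, n_recombinants=10)


@pytest.fixture(scope="module")
def tiny_benchmarks():
    rng = np.random.default_rng(42)
    benches = []
    for d in range(3):
        F = (rng.random((30, 6)) < 0.2).astype(float)
        a_idx = rng.choice(30, 4, replace=False)
        F[a_idx, :2] = (rng.random((4, 2)) < 0.9).astype(float)
        benches.append(make_bench(f"d{d}", F, a_idx))
    return benches


class TestRunGa:
    def test_runs_requested_generations_and_elitism(self, tiny_benchmarks):
        cfg = GaConfig(generations=100, population=12, elite_pool=6,
                       n_random_per_gen=2, n_elite_carry=2, n_recombinants=8,
                       seed=5)
        best, traj = run_ga(tiny_benchmarks, cfg)
        assert len(traj) == 100
        assert all(a >= b for a, b in zip(traj, traj[1:]))  # non-increasing
        assert traj[-1] == best.fitness

    def test_seeded_run_reproducible(self, tiny_benchmarks):
        cfg = GaConfig(generations=10, population=12, elite_pool=6,
                       n_random_per_gen=2, n_elite_carry=2, n_recombinants=8,
                       seed=3)
        b1, t1 = run_ga(tiny_benchmarks, cfg)
        b2, t2 = run_ga(tiny_benchmarks, cfg)
        assert t1 == t2 and (b1.w == b2.w).all()


class TestLoocvGrid:
    def stub(self, n_features=6):
        ind = Individual(np.linspace(0.1, 1.0, n_features), fitness=0.5)
        return lambda training, cfg: ind

    def test_two_diseases_one_cell(self, tiny_benchmarks):
        report = loocv_grid(tiny_benchmarks[:2], (0.3,), (0.5,),
                            GaConfig(seed=0), train_fn=self.stub())
        assert report.n_runs == 2
        assert sorted(report.runs["disease"]) == ["d0", "d1"]
        assert len(report.cells) == 1 and report.cells["n_runs"][0] == 2

    def test_cell_means_match_hand_recomputation(self, tiny_benchmarks):
        report = loocv_grid(tiny_benchmarks, (0.2, 0.6), (0.5,),
                            GaConfig(seed=0), train_fn=self.stub())
        for _, cell in report.cells.iterrows():
            sub = report.runs[(report.runs["epsilon"] == cell["epsilon"])
                              & (report.runs["Tr"] == cell["Tr"])]
            assert cell["mean_sensitivity"] == pytest.approx(sub["sensitivity"].mean())
            assert cell["mean_specificity"] == pytest.approx(sub["specificity"].mean())

    def test_each_disease_validated_once_per_cell(self, tiny_benchmarks):
        report = loocv_grid(tiny_benchmarks, (0.3, 0.7), (0.25, 0.75),
                            GaConfig(seed=1), train_fn=self.stub())
        assert report.n_runs == 3 * 2 * 2
        per_cell = report.runs.groupby(["epsilon", "Tr"])["disease"].apply(list)
        for diseases in per_cell:
            assert sorted(diseases) == ["d0", "d1", "d2"]

    def test_sensitivity_specificity_monotone_in_epsilon(self, tiny_benchmarks):
        report = loocv_grid(tiny_benchmarks, EPSILON_GRID, (1.0,),
                            GaConfig(seed=0), train_fn=self.stub())
        cells = report.cells.sort_values("epsilon")
        sens = cells["mean_sensitivity"].to_numpy()
        spec = cells["mean_specificity"].to_numpy()
        assert (np.diff(sens) <= 1e-12).all()
        assert (np.diff(spec) >= -1e-12).all()

    def test_fewer_than_two_diseases_rejected(self, tiny_benchmarks):
        with pytest.raises(ConfigurationError):
            loocv_grid(tiny_benchmarks[:1], (0.3,), (0.5,), GaConfig())


class TestDiseaseBenchmark:
    def test_certified_outside_s_dropped(self, caplog):
        b = DiseaseBenchmark("d", {"G1"}, S=["rs1", "rs2"], A={"rs1", "rsX"})
        assert b.A == {"rs1"}

    def test_yaml_round_trip(self, tmp_path):
        b = DiseaseBenchmark("d7", {"G1", "G2"}, S=["rs1", "rs2", "rs3"],
                             A={"rs2"})
        p = tmp_path / "d7.yaml"
        b.to_yaml(p)
        back = DiseaseBenchmark.from_yaml(p)
        assert (back.disease_id, back.genes, back.S, back.A) == (
            "d7", b.genes, b.S, b.A)
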