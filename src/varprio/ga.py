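"""Genetic-algorithm learning of feature weights against disease benchmarks.

A disease benchmark is (S, A): S the candidate SNP universe — every SNP
within the flanking window of the disease's genes — and A ⊆ S the SNPs
certified as disease-associated.  For a weight vector w, the high-scoring
set is

    Y = { s_i in S : sigma_i(w) > T_eps },   T_eps = eps * max_i sigma_i(w),

and the optimizer minimizes 1 - sensitivity = 1 - |A ∩ Y| / |A| averaged
over the training diseases, subject to the filtering constraint
|Y| / |S| < Tr: any violating configuration receives the sentinel fitness
2.0, strictly worse than every feasible value in [0, 1].

Default generational scheme (per generation of 120 individuals): 10 fresh
random individuals, the 10 best of the previous generation carried
unmodified, and 100 recombinants of the top 50 (uniform crossover, 5%
per-coefficient Gaussian mutation sd 0.1, clipped to [0, 1]).  All weights
live in [0, 1].  Model assessment is leave-one-out cross-validation over
diseases, swept across the (eps, Tr) grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .registry import FeatureRegistry

logger = logging.getLogger(__name__)

PENALTY_FITNESS = 2.0
EPSILON_GRID = tuple(round(0.1 * k, 1) for k in range(1, 11))  # 0.1 .. 1.0
TR_GRID = (0.25, 0.50, 0.75, 1.00)


# --------------------------------------------------------------------------
# Benchmarks
# --------------------------------------------------------------------------

@dataclass
class DiseaseBenchmark:
    """One disease: its gene set, candidate SNP universe S, certified set A."""

    disease_id: str
    genes: set[str]
    S: list[str]
    A: set[str]

    def __post_init__(self):
        s_set = set(self.S)
        if not s_set:
            raise ConfigurationError(f"{self.disease_id}: empty SNP universe S")
        outside = self.A - s_set
        if outside:
            logger.warning(
                "%s: %d certified SNP(s) outside S dropped", self.disease_id, len(outside)
            )
            self.A = self.A & s_set

    @classmethod
    def from_yaml(cls, path: str | Path, gene_map=None, snps=None) -> "DiseaseBenchmark":
        """Load a benchmark file: disease_id, genes, certified_snps[, snps].

        When the file omits the explicit S list, it is assembled from the
        supplied GeneSnpMap (gene ids or symbols must match the map)."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        genes = set(str(g) for g in doc["genes"])
        certified = set(doc["certified_snps"])
        if "snps" in doc:
            S = list(doc["snps"])
        else:
            if gene_map is None:
                raise ConfigurationError(f"{path}: no SNP list and no gene map given")
            S = sorted(
                {r for g, r in gene_map.pairs if str(g) in genes}
            )
        return cls(disease_id=str(doc["disease_id"]), genes=genes, S=S, A=certified)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "disease_id": self.disease_id,
            "genes": sorted(self.genes),
            "certified_snps": sorted(self.A),
            "snps": list(self.S),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class PreparedBenchmark:
    """Benchmark with its normalized feature matrix, ready for fast scoring."""

    disease_id: str
    F: np.ndarray          # |S| x n normalized feature scores
    a_mask: np.ndarray     # bool, |S|
    rsids: list[str]

    @property
    def n_certified(self) -> int:
        return int(self.a_mask.sum())


def prepare_benchmark(
    bench: DiseaseBenchmark, matrix, registry: FeatureRegistry,
    contexts: dict[str, str] | None = None,
) -> PreparedBenchmark:
    """Normalize the benchmark's S rows of the raw feature matrix."""
    from .scoring import feature_score_matrix
    from .annotation_store import FeatureMatrix

    sub = FeatureMatrix(snps=list(bench.S), features=matrix.features)
    s_set = set(bench.S)
    sub.values = {k: v for k, v in matrix.values.items() if k[0] in s_set}
    F = feature_score_matrix(sub, registry, contexts=contexts)
    a_mask = np.array([r in bench.A for r in bench.S], dtype=bool)
    return PreparedBenchmark(bench.disease_id, F, a_mask, list(bench.S))


# --------------------------------------------------------------------------
# Thresholding and the confusion table
# --------------------------------------------------------------------------

def score_threshold(scores: np.ndarray, epsilon: float) -> float:
    """T_eps = eps * max sigma over S (relative threshold)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("S is empty")
    m = float(scores.max())
    if m == 0.0:
        logger.warning("all scores zero: degenerate weights, T_eps = 0")
        return 0.0
    return epsilon * m


def high_scoring_set(scores: np.ndarray, t_epsilon: float) -> np.ndarray:
    """Boolean mask of Y = { sigma > T_eps } (strict comparison)."""
    return np.asarray(scores, dtype=float) > t_epsilon


@dataclass(frozen=True)
class ConfusionCounts:
    P: int    # |A ∩ Y| true positives
    N: int    # |A \ Y| false negatives
    FP: int   # |Y \ A|
    TN: int   # |S \ (A ∪ Y)|

    @property
    def sensitivity(self) -> float:
        return self.P / (self.P + self.N)

    @property
    def specificity(self) -> float:
        denom = self.TN + self.FP
        return self.TN / denom if denom else 1.0

    @property
    def accuracy(self) -> float:
        return (self.P + self.TN) / (self.P + self.N + self.FP + self.TN)


def confusion(y_mask: np.ndarray, a_mask: np.ndarray) -> ConfusionCounts:
    """Confusion table of the high-scoring set against the certified set."""
    y = np.asarray(y_mask, dtype=bool)
    a = np.asarray(a_mask, dtype=bool)
    if not a.any():
        raise ValueError("benchmark has no certified SNPs: sensitivity undefined")
    return ConfusionCounts(
        P=int((y & a).sum()),
        N=int((~y & a).sum()),
        FP=int((y & ~a).sum()),
        TN=int((~y & ~a).sum()),
    )


def fitness(
    w: np.ndarray,
    training: list[PreparedBenchmark],
    epsilon: float,
    tr: float,
    aggregate: str = "mean",
) -> float:
    """1 - sensitivity over the training diseases, or an infeasibility
    penalty when any disease retains |Y|/|S| >= Tr.

    The penalty is graded: 2.0 plus the worst violation excess
    max_d(|Y_d|/|S_d| - Tr).  Every infeasible value is therefore >= 2.0,
    strictly dominating the feasible range [0, 1], while configurations
    closer to satisfying the filtering constraint still rank better than
    configurations further away — without a graded term the search has no
    descent direction through the (large) infeasible region.

    ``aggregate='pooled'`` pools the P/(P+N) counts across diseases
    instead of averaging per-disease sensitivities."""
    if not training:
        raise ValueError("no training benchmarks")
    w = np.asarray(w, dtype=float)
    sens, pooled_p, pooled_a = [], 0, 0
    violated, worst_excess = False, 0.0
    for bench in training:
        if bench.n_certified == 0:
            logger.warning("%s: no certified SNPs, excluded", bench.disease_id)
            continue
        sigma = bench.F @ w
        y = high_scoring_set(sigma, score_threshold(sigma, epsilon))
        frac = y.sum() / y.size
        if frac >= tr:
            violated = True
            worst_excess = max(worst_excess, frac - tr)
        p = int((y & bench.a_mask).sum())
        sens.append(p / bench.n_certified)
        pooled_p += p
        pooled_a += bench.n_certified
    if not sens:
        raise ValueError("every training benchmark lacked certified SNPs")
    if violated:
        return PENALTY_FITNESS + worst_excess
    if aggregate == "pooled":
        return 1.0 - pooled_p / pooled_a
    return 1.0 - float(np.mean(sens))


# --------------------------------------------------------------------------
# The genetic algorithm
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    w: np.ndarray
    fitness: float | None = None
    provenance: str = "random"


@dataclass
class GaConfig:
    generations: int = 100
    population: int = 120
    elite_pool: int = 50
    n_random_per_gen: int = 10
    n_elite_carry: int = 10
    n_recombinants: int = 100
    epsilon: float = 0.3
    tr: float = 0.25
    seed: int = 0
    mutation_rate: float = 0.05
    mutation_sd: float = 0.1
    aggregate: str = "mean"

    def __post_init__(self):
        if self.n_random_per_gen + self.n_elite_carry + self.n_recombinants != self.population:
            raise ConfigurationError(
                "n_random + n_elite + n_recombinants must equal population"
            )
        if self.population < self.elite_pool:
            raise ConfigurationError("population smaller than elite_pool")

    @classmethod
    def scaled(cls, population: int, generations: int, **kw) -> "GaConfig":
        """Shrink the default 120/50/10/10/100 scheme proportionally."""
        s = population / 120
        n_random = max(1, round(10 * s))
        n_elite = max(1, round(10 * s))
        return cls(
            generations=generations,
            population=population,
            elite_pool=max(2, round(50 * s)),
            n_random_per_gen=n_random,
            n_elite_carry=n_elite,
            n_recombinants=population - n_random - n_elite,
            **kw,
        )


def init_population(
    n_features: int, size: int, rng: np.random.Generator
) -> list[Individual]:
    """Coefficients i.i.d. uniform on [0, 1]."""
    if size <= 0:
        raise ConfigurationError("population size must be positive")
    return [Individual(w=rng.uniform(0, 1, n_features)) for _ in range(size)]


def recombine(
    p1: Individual, p2: Individual, rng: np.random.Generator,
    mutation_rate: float = 0.05, mutation_sd: float = 0.1,
) -> Individual:
    """Uniform crossover, then per-coefficient Gaussian mutation.

    Mutation steps are truncated at +-3 sd, so a child coefficient always
    stays within [min(parents) - 3 sd, max(parents) + 3 sd], and the result
    is clipped to [0, 1]."""
    if p1.w.shape != p2.w.shape:
        raise ValueError("parents have misaligned weight vectors")
    take_first = rng.random(p1.w.shape[0]) < 0.5
    child = np.where(take_first, p1.w, p2.w)
    if mutation_rate > 0:
        mut = rng.random(child.shape[0]) < mutation_rate
        if mut.any():
            step = rng.normal(0.0, mutation_sd, int(mut.sum()))
            step = np.clip(step, -3.0 * mutation_sd, 3.0 * mutation_sd)
            child = child.copy()
            child[mut] += step
            child = np.clip(child, 0.0, 1.0)
    return Individual(w=child, provenance="recombinant")


def _sorted_by_fitness(pop: list[Individual]) -> list[Individual]:
    # stable: equal fitness resolved by original index
    return sorted(pop, key=lambda ind: ind.fitness)


def next_generation(
    pop: list[Individual], config: GaConfig, rng: np.random.Generator
) -> list[Individual]:
    """One reproduction step: fresh randoms + unmodified elites + recombinants
    of the elite pool (parents distinct within a pairing)."""
    if len(pop) != config.population:
        raise ConfigurationError(
            f"population of {len(pop)}, expected {config.population}"
        )
    if any(ind.fitness is None for ind in pop):
        raise ConfigurationError("all fitnesses must be evaluated before reproduction")
    ranked = _sorted_by_fitness(pop)
    n_feat = pop[0].w.shape[0]
    new: list[Individual] = list(init_population(n_feat, config.n_random_per_gen, rng))
    new += [
        Individual(w=ind.w, fitness=ind.fitness, provenance="elite")
        for ind in ranked[: config.n_elite_carry]
    ]
    top = ranked[: config.elite_pool]
    for _ in range(config.n_recombinants):
        i = rng.integers(len(top))
        j = rng.integers(len(top) - 1)
        if j >= i:
            j += 1
        new.append(
            recombine(top[i], top[j], rng, config.mutation_rate, config.mutation_sd)
        )
    return new


def run_ga(
    training: list[PreparedBenchmark], config: GaConfig
) -> tuple[Individual, list[float]]:
    """Run the GA; returns the best-ever individual and the non-increasing
    best-fitness trajectory (one value per generation)."""
    rng = np.random.default_rng(config.seed)
    n_feat = training[0].F.shape[1]

    def evaluate(pop):
        return [
            ind if ind.fitness is not None else replace(
                ind, fitness=fitness(ind.w, training, config.epsilon, config.tr,
                                     config.aggregate)
            )
            for ind in pop
        ]

    pop = evaluate(init_population(n_feat, config.population, rng))
    best = min(pop, key=lambda ind: ind.fitness)
    trajectory = [best.fitness]
    for _ in range(config.generations - 1):
        pop = evaluate(next_generation(pop, config, rng))
        gen_best = min(pop, key=lambda ind: ind.fitness)
        if gen_best.fitness < best.fitness:
            best = gen_best
        trajectory.append(best.fitness)
    return best, trajectory


# --------------------------------------------------------------------------
# LOOCV over the (epsilon, Tr) grid
# --------------------------------------------------------------------------

@dataclass
class LoocvReport:
    """Per-run records and per-(eps, Tr)-cell means over held-out diseases."""

    runs: pd.DataFrame
    cells: pd.DataFrame

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def to_tsv(self, path: str | Path) -> None:
        self.cells.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def runs_to_tsv(self, path: str | Path) -> None:
        self.runs.to_csv(path, sep="\t", index=False, float_format="%.6f")


def loocv_grid(
    diseases: list[PreparedBenchmark],
    epsilon_grid=EPSILON_GRID,
    tr_grid=TR_GRID,
    config: GaConfig | None = None,
    train_fn=None,
) -> LoocvReport:
    """Leave-one-disease-out cross-validation across the (eps, Tr) grid.

    For every grid cell and every held-out disease, train on the remaining
    diseases (sub-seed derived deterministically from the master seed and
    the cell/disease indices) and evaluate sensitivity, specificity and
    accuracy on the held-out disease.  ``train_fn(training, cfg) -> Individual``
    defaults to the GA; a stub lets the grid be enumerated cheaply.
    """
    if len(diseases) < 2:
        raise ConfigurationError("LOOCV needs at least 2 diseases")
    config = config or GaConfig()
    if train_fn is None:
        train_fn = lambda training, cfg: run_ga(training, cfg)[0]

    rows = []
    for ei, eps in enumerate(epsilon_grid):
        for ti, tr in enumerate(tr_grid):
            for di, held in enumerate(diseases):
                sub_seed = int(
                    np.random.SeedSequence(config.seed, spawn_key=(ei, ti, di))
                    .generate_state(1)[0] % (2**31)
                )
                cfg = replace(config, epsilon=eps, tr=tr, seed=sub_seed)
                training = diseases[:di] + diseases[di + 1:]
                best = train_fn(training, cfg)
                sigma = held.F @ best.w
                y = high_scoring_set(sigma, score_threshold(sigma, eps))
                cm = confusion(y, held.a_mask)
                rows.append({
                    "disease": held.disease_id,
                    "epsilon": eps,
                    "Tr": tr,
                    "sensitivity": cm.sensitivity,
                    "specificity": cm.specificity,
                    "accuracy": cm.accuracy,
                    "n_S": len(held.rsids),
                    "n_A": held.n_certified,
                    "n_Y": int(y.sum()),
                    "train_fitness": best.fitness,
                })
    runs = pd.DataFrame(rows)
    cells = (
        runs.groupby(["epsilon", "Tr"], as_index=False)
        .agg(
            mean_sensitivity=("sensitivity", "mean"),
            mean_specificity=("specificity", "mean"),
            mean_accuracy=("accuracy", "mean"),
            n_runs=("disease", "size"),
        )
        .sort_values(["epsilon", "Tr"], ignore_index=True)
    )
    return LoocvReport(runs=runs, cells=cells)


def save_learned_weights(
    best: Individual, registry: FeatureRegistry, path: str | Path
) -> None:
    """Emit learned weights in the registry config format scoring consumes."""
    registry.with_weights(best.w).to_yaml(path)
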