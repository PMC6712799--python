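"""Genetic algorithm with tabu memory over Bayesian-network structures.

The search seeds an initial network from the mutual-information ranking
of SNP pairs, perturbs it into a population of DAG individuals, and
evolves the population with roulette selection, a ring-avoiding column
crossover guarded by a tabu list, and a fitness-improving point mutation
guarded by a second tabu list.  Fitness is the decomposable BIC score;
the best individual ever seen is tracked outside the population
(elitism), and the run stops at the iteration cap, after ``stagnation_k``
generations without improvement, or at an optional fitness threshold.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, replace

import numpy as np

from .bayesnet import (
    DagIndividual,
    EditRejectedError,
    ScoreCache,
    apply_edit,
    is_acyclic,
)
from .infotheory import MIResult, rank_all_pairs
from .io import GenotypeTable, encode_bits

__all__ = [
    "GAConfig",
    "TabuList",
    "Population",
    "SearchResult",
    "build_initial_network",
    "generate_initial_population",
    "roulette_probabilities",
    "roulette_select",
    "selection_weights",
    "crossover",
    "tabu_crossover",
    "mutate",
    "tabu_mutate",
    "run",
]

#: additive constant keeping transformed roulette fitness strictly positive
FITNESS_DELTA = 1.0


@dataclass(frozen=True)
class GAConfig:
    """Search parameters.

    Defaults follow the published configuration: population 50,
    crossover probability 0.7, mutation probability 0.002, tabu list
    length 30, at most 60 iterations, stop after 3 stagnant generations.
    """

    population_size: int = 50
    crossover_prob: float = 0.7
    mutation_prob: float = 0.002
    tabu_length: int = 30
    max_iterations: int = 60
    stagnation_k: int = 3
    fitness_threshold: float | None = None
    top_n: int = 5
    max_crossover_retries: int = 10
    log_base: float | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in [0, 1]")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")
        for name in ("population_size", "tabu_length", "stagnation_k", "top_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")

    def with_seed(self, seed: int | None) -> "GAConfig":
        return replace(self, rng_seed=seed)


class TabuList:
    """Bounded FIFO of individual fingerprints with exact-equality lookup."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("tabu capacity must be >= 1")
        self.capacity = capacity
        self._fifo: deque[bytes] = deque()
        self._members: Counter[bytes] = Counter()

    def __contains__(self, fingerprint: bytes) -> bool:
        return self._members[fingerprint] > 0

    def __len__(self) -> int:
        return len(self._fifo)

    def add(self, fingerprint: bytes) -> None:
        self._fifo.append(fingerprint)
        self._members[fingerprint] += 1
        while len(self._fifo) > self.capacity:
            old = self._fifo.popleft()
            self._members[old] -= 1
            if self._members[old] == 0:
                del self._members[old]


@dataclass
class Population:
    """Fixed-size set of scored individuals at one generation."""

    individuals: list[DagIndividual]
    fitness: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.fitness = np.asarray(self.fitness, dtype=float)
        if len(self.individuals) != self.fitness.size:
            raise ValueError("fitness length must match population size")

    @property
    def size(self) -> int:
        return len(self.individuals)

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.fitness))


@dataclass
class SearchResult:
    """Outcome of one run: elitist best network plus per-generation history."""

    best: DagIndividual
    best_score: float
    history: list[dict]
    ranked_pairs: list[MIResult]
    generations_run: int
    stopped_by: str
    config: GAConfig


def build_initial_network(
    ranked: list[MIResult],
    top_n: int,
    n_nodes: int,
    node_names: list[str] | None = None,
) -> DagIndividual:
    """Seed network from the MI ranking.

    Each top-N combination contributes an edge from the Class node to
    each of its SNPs plus within-combination SNP-SNP edges oriented
    lower index -> higher index (the interaction hypothesis; the
    orientation can never form a cycle).  Every SNP absent from the
    top-N is then covered by its first-appearing combination in the
    remainder of the ranking, which contributes Class->SNP edges only —
    low-MI coverage pairs carry no evidence of interaction, and adding
    their SNP-SNP edges would only inflate parent sets.  SNPs appearing
    in no ranked combination simply stay isolated.

    The phenotype is the root (Class->SNP) rather than the sink: with a
    sink orientation the Class node would collect one parent per covered
    SNP, its parent-combination count 3^n_snps would reduce the BIC to
    a pure penalty (every sample gets a unique parent configuration, so
    the likelihood term is exactly zero) and the early search would
    degenerate into blind penalty pruning.
    """
    if not ranked:
        raise ValueError("ranked MI list is empty")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    class_index = n_nodes - 1
    if node_names is None:
        node_names = [f"SNP{i}" for i in range(n_nodes - 1)] + ["Class"]
    adjacency = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    covered: set[int] = set()
    for res in ranked[:top_n]:
        idx = sorted(res.snp_indices)
        for i in idx:
            adjacency[class_index, i] = 1
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                adjacency[idx[a], idx[b]] = 1
        covered.update(idx)
    for res in ranked[top_n:]:
        if len(covered) == n_nodes - 1:
            break
        if any(i not in covered for i in res.snp_indices):
            for i in res.snp_indices:
                adjacency[class_index, i] = 1
            covered.update(res.snp_indices)
    ind = DagIndividual(adjacency, node_names)
    assert is_acyclic(ind)
    return ind


def _random_edit(ind: DagIndividual, rng: np.random.Generator) -> DagIndividual:
    """One random applicable add/drop/reverse, retried until legal."""
    n = ind.n_nodes
    for attempt in range(200):
        edges = np.argwhere(ind.adjacency == 1)
        ops = ["add"] if attempt < 150 else []
        if edges.size:
            ops += ["drop", "reverse"]
        if not ops:
            ops = ["add"]
        op = ops[rng.integers(len(ops))]
        if op == "add":
            frm = int(rng.integers(n))
            to = int(rng.integers(n))
        else:
            frm, to = (int(v) for v in edges[rng.integers(edges.shape[0])])
        try:
            return apply_edit(ind, op, frm, to)
        except EditRejectedError:
            continue
    return ind.copy()  # saturated graph with nothing editable; keep as-is


def generate_initial_population(
    seed_network: DagIndividual,
    cfg: GAConfig,
    rng: np.random.Generator,
    scorer: ScoreCache,
) -> Population:
    """Chain single-edit perturbations from the seed up to population size."""
    individuals = [seed_network.copy()]
    current = seed_network
    while len(individuals) < cfg.population_size:
        current = _random_edit(current, rng)
        individuals.append(current)
    fitness = np.array([scorer.score(ind) for ind in individuals])
    return Population(individuals=individuals, fitness=fitness, generation=0)


def roulette_probabilities(fitness) -> np.ndarray:
    """Selection probabilities P_i = f_i / sum f_i (fitness strictly positive)."""
    f = np.asarray(fitness, dtype=float)
    if f.size == 0:
        raise ValueError("empty fitness vector")
    if np.any(f <= 0):
        raise ValueError("roulette selection requires strictly positive fitness")
    return f / f.sum()


def roulette_select(fitness, rng: np.random.Generator) -> int:
    """Sample one index with probability proportional to fitness."""
    return int(rng.choice(len(fitness), p=roulette_probabilities(fitness)))


def selection_weights(scores, delta: float = FITNESS_DELTA) -> np.ndarray:
    """Shift raw BIC scores into strictly positive roulette fitness.

    f_i = BIC_i - min(BIC) + delta preserves ranking and degenerates to
    uniform sampling when all scores are equal.
    """
    s = np.asarray(scores, dtype=float)
    return s - s.min() + delta


def _select_parent(pop: Population, rng: np.random.Generator) -> int:
    return roulette_select(selection_weights(pop.fitness), rng)


def crossover(
    parent1: DagIndividual,
    parent2: DagIndividual,
    rng: np.random.Generator,
) -> tuple[DagIndividual, DagIndividual]:
    """Two-column crossover with row-wise ring avoidance.

    Two columns (parent sets of two nodes) are chosen at random and
    exchanged between the parents row by row; a row whose exchange would
    close a cycle in either offspring-in-progress is skipped.  Offspring
    are therefore always acyclic; in the worst case every row is skipped
    and the offspring equal the parents, and identical parents always
    yield identical offspring.  Exchanging columns at the same node
    index in both parents keeps node identity intact — the offspring's
    parent set for node j is one of its parents' parent sets for node j,
    never that of an unrelated node.
    """
    if parent1.n_nodes != parent2.n_nodes:
        raise ValueError("parents must share the node set")
    n = parent1.n_nodes
    cols = rng.choice(n, size=2, replace=False)
    off1 = parent1.adjacency.copy()
    off2 = parent2.adjacency.copy()
    for col in cols:
        for row in range(n):
            a = off1[row, col]
            b = off2[row, col]
            if a == b:
                continue
            off1[row, col], off2[row, col] = b, a
            if not (is_acyclic(off1) and is_acyclic(off2)):
                off1[row, col], off2[row, col] = a, b  # skip the ring-forming row
    return (
        DagIndividual(off1, parent1.node_names),
        DagIndividual(off2, parent2.node_names),
    )


def tabu_crossover(
    parent1: DagIndividual,
    parent2: DagIndividual,
    tabu: TabuList,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> tuple[DagIndividual, DagIndividual, bool]:
    """Crossover repeated until both offspring fall outside the tabu list.

    Accepted offspring are appended to the list (oldest entries evicted
    beyond capacity).  After ``max_retries`` collisions the last offspring
    are returned with the flag set and are *not* recorded.
    Returns ``(child1, child2, exhausted_flag)``.
    """
    child1 = child2 = None
    for _ in range(max_retries):
        child1, child2 = crossover(parent1, parent2, rng)
        if child1.fingerprint() not in tabu and child2.fingerprint() not in tabu:
            tabu.add(child1.fingerprint())
            tabu.add(child2.fingerprint())
            return child1, child2, False
    return child1, child2, True  # type: ignore[return-value]


def _random_flip(
    ind: DagIndividual, rng: np.random.Generator
) -> DagIndividual | None:
    """Flip one uniformly chosen off-diagonal adjacency entry; None if cyclic."""
    n = ind.n_nodes
    k = int(rng.integers(n * (n - 1)))
    i, rem = divmod(k, n - 1)
    j = rem if rem < i else rem + 1
    adj = ind.adjacency.copy()
    adj[i, j] ^= 1
    if not is_acyclic(adj):
        return None
    return DagIndividual(adj, ind.node_names)


def mutate(
    ind: DagIndividual,
    p_m: float,
    rng: np.random.Generator,
    scorer: ScoreCache,
) -> DagIndividual:
    """Point mutation accepted only when acyclic and fitness-improving."""
    if rng.random() >= p_m:
        return ind
    candidate = _random_flip(ind, rng)
    if candidate is None:
        return ind
    if scorer.score(candidate) > scorer.score(ind):
        return candidate
    return ind


def tabu_mutate(
    pop: Population,
    tabu: TabuList,
    cfg: GAConfig,
    rng: np.random.Generator,
    scorer: ScoreCache,
) -> int:
    """In-place tabu mutation pass over the population.

    The mutation probability is applied per locus, i.e. per off-diagonal
    adjacency entry — the standard genetic-algorithm convention, which
    at the default 0.002 over an n-node matrix gives each individual
    close to one flip attempt per generation (an inert per-individual
    reading would leave the operator without any climbing ability).  A
    candidate mutant is accepted iff it is acyclic, fitness-improving
    and not in the tabu list; a fitness-degrading mutant is recorded in
    the tabu list so the search does not revisit it.  Returns the number
    of accepted mutations.
    """
    accepted = 0
    n = pop.individuals[0].n_nodes
    n_entries = n * (n - 1)
    for i in range(pop.size):
        for _ in range(rng.binomial(n_entries, cfg.mutation_prob)):
            candidate = _random_flip(pop.individuals[i], rng)
            if candidate is None:
                continue
            if candidate.fingerprint() in tabu:
                continue
            new_fit = scorer.score(candidate)
            if new_fit > pop.fitness[i]:
                pop.individuals[i] = candidate
                pop.fitness[i] = new_fit
                accepted += 1
            elif new_fit < pop.fitness[i]:
                tabu.add(candidate.fingerprint())
    return accepted


def run(
    table: GenotypeTable,
    cfg: GAConfig | None = None,
    rng: np.random.Generator | None = None,
    mi_k: int = 2,
) -> SearchResult:
    """Full search: MI ranking -> seed network -> evolve -> best individual.

    Each generation draws parents by roulette, crosses them at
    ``crossover_prob`` under the crossover tabu list, re-injects the
    elitist best-ever individual, applies tabu mutation and re-evaluates.
    The run stops at ``max_iterations``, when neither the best nor the
    population-mean fitness has improved for ``stagnation_k`` consecutive
    generations, or at the optional ``fitness_threshold``.  Reproducible
    under a fixed ``cfg.rng_seed`` (or an explicitly passed generator).
    History records generation index, best and mean BIC of the
    population, the running elitist best, and tabu collision counts.
    """
    cfg = cfg or GAConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    bits = encode_bits(table)
    ranked = rank_all_pairs(bits, k=mi_k, base=cfg.log_base)
    n_nodes = table.n_snps + 1
    node_names = [*table.snp_names, table.class_name]
    seed_net = build_initial_network(ranked, cfg.top_n, n_nodes, node_names)
    scorer = ScoreCache(table, base=cfg.log_base)
    pop = generate_initial_population(seed_net, cfg, rng, scorer)

    best_idx = pop.best_index
    best = pop.individuals[best_idx].copy()
    best_score = float(pop.fitness[best_idx])
    best_mean = float(pop.fitness.mean())
    history = [
        {
            "generation": 0,
            "best": float(pop.fitness.max()),
            "mean": float(pop.fitness.mean()),
            "best_ever": best_score,
            "tabu_hits": 0,
            "mutations": 0,
        }
    ]
    cross_tabu = TabuList(cfg.tabu_length)
    mut_tabu = TabuList(cfg.tabu_length)
    stall = 0
    stopped_by = "max_iterations"
    generations_run = 0
    if cfg.fitness_threshold is not None and best_score >= cfg.fitness_threshold:
        stopped_by = "fitness_threshold"
    else:
        for generation in range(1, cfg.max_iterations + 1):
            offspring: list[DagIndividual] = []
            tabu_hits = 0
            while len(offspring) < cfg.population_size:
                p1 = pop.individuals[_select_parent(pop, rng)]
                p2 = pop.individuals[_select_parent(pop, rng)]
                if rng.random() < cfg.crossover_prob:
                    c1, c2, exhausted = tabu_crossover(
                        p1, p2, cross_tabu, rng, cfg.max_crossover_retries
                    )
                    tabu_hits += exhausted
                else:
                    c1, c2 = p1.copy(), p2.copy()
                offspring.extend([c1, c2])
            offspring = offspring[: cfg.population_size]
            # elitism: the running best keeps breeding instead of only being
            # remembered, which protects likelihood-carrying edges from drift
            offspring[-1] = best.copy()
            fitness = np.array([scorer.score(ind) for ind in offspring])
            pop = Population(offspring, fitness, generation)
            mutations = tabu_mutate(pop, mut_tabu, cfg, rng, scorer)
            generations_run = generation

            improved = False
            gen_best_idx = pop.best_index
            if pop.fitness[gen_best_idx] > best_score:
                best = pop.individuals[gen_best_idx].copy()
                best_score = float(pop.fitness[gen_best_idx])
                improved = True
            # stagnation watches the population as well as the best
            # individual: the search keeps going while the mean fitness
            # still climbs, even when the front-runner is momentarily flat
            if pop.fitness.mean() > best_mean:
                best_mean = float(pop.fitness.mean())
                improved = True
            stall = 0 if improved else stall + 1
            history.append(
                {
                    "generation": generation,
                    "best": float(pop.fitness.max()),
                    "mean": float(pop.fitness.mean()),
                    "best_ever": best_score,
                    "tabu_hits": tabu_hits,
                    "mutations": mutations,
                }
            )
            if cfg.fitness_threshold is not None and best_score >= cfg.fitness_threshold:
                stopped_by = "fitness_threshold"
                break
            if stall >= cfg.stagnation_k:
                stopped_by = "stagnation"
                break
    return SearchResult(
        best=best,
        best_score=best_score,
        history=history,
        ranked_pairs=ranked,
        generations_run=generations_run,
        stopped_by=stopped_by,
        config=cfg,
    )
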