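"""Multi-objective evolutionary machinery over latent vectors.

NSGA-II style non-dominated ranking and crowding distance drive binary
tournament selection; uniform crossover and Gaussian coordinate mutation
act directly on latent vectors, which the generative model decodes back to
molecules.  ``run_del`` wires the full data/model co-evolution loop:
pretrain, evolve, decode, evaluate, truncate elitistically, fine-tune.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem import Molecule
from .fragmentation import preprocess_dataset
from .metrics import GenerationReport, generation_report, reference_point
from .objectives import ObjectiveVector, PropertyRecord, evaluate_objectives

logger = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "Population",
    "DELConfig",
    "RunHistory",
    "dominates",
    "non_dominated_sort",
    "crowding_distance",
    "assign_ranks",
    "tournament_select",
    "crossover_latent",
    "mutate_latent",
    "evolve_generation",
    "run_del",
]


@dataclass
class Individual:
    molecule: Molecule
    latent: np.ndarray
    objectives: ObjectiveVector
    rank: int | None = None
    crowding: float | None = None

    def record(self) -> PropertyRecord:
        return PropertyRecord(smiles=self.molecule.smiles, objectives=self.objectives)


@dataclass
class Population:
    generation: int
    members: list[Individual]
    size_target: int

    def front(self, rank: int = 1) -> list[Individual]:
        return [m for m in self.members if m.rank == rank]

    def records(self) -> list[PropertyRecord]:
        return [m.record() for m in self.members]


@dataclass
class DELConfig:
    """Evolution-loop hyperparameters (defaults follow the study settings)."""

    generations: int = 10
    population_size: int = 20000
    initial_epochs: int = 20
    subsequent_epochs: int = 10
    annealing_rate: float = 0.8
    tournament_p: float = 0.95
    mutation_rate: float = 0.01
    mutation_sigma_scale: float = 0.1  # x per-dimension latent std
    crossover_swap_p: float = 0.5
    elite_fraction: float = 0.5
    finetune_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.tournament_p <= 1.0):
            raise ValueError("tournament_p must be in (0, 1]")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# Pareto machinery
# ---------------------------------------------------------------------------


def _vec(obj) -> tuple[float, ...]:
    return obj.as_tuple() if isinstance(obj, ObjectiveVector) else tuple(obj)


def dominates(a, b) -> bool:
    """True iff a <= b componentwise with at least one strict improvement."""
    a, b = _vec(a), _vec(b)
    if len(a) != len(b):
        raise ValueError("objective vectors differ in dimension")
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def non_dominated_sort(objs) -> list[int]:
    """NSGA-II fast non-dominated sort; returns 1-based Pareto ranks."""
    pts = [np.asarray(_vec(o), dtype=float) for o in objs]
    n = len(pts)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominators = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            le = (pts[i] <= pts[j]).all()
            ge = (pts[i] >= pts[j]).all()
            if le and not ge:
                dominated_by[i].append(j)
                n_dominators[j] += 1
            elif ge and not le:
                dominated_by[j].append(i)
                n_dominators[i] += 1
    ranks = [0] * n
    current = [i for i in range(n) if n_dominators[i] == 0]
    r = 1
    while current:
        nxt = []
        for i in current:
            ranks[i] = r
            for j in dominated_by[i]:
                n_dominators[j] -= 1
                if n_dominators[j] == 0:
                    nxt.append(j)
        current = nxt
        r += 1
    return ranks


def crowding_distance(front) -> list[float]:
    """NSGA-II crowding distance within one front (boundary points +inf)."""
    pts = np.array([_vec(o) for o in front], dtype=float)
    n, d = pts.shape
    if n <= 2:
        return [float("inf")] * n
    dist = np.zeros(n)
    for k in range(d):
        order = np.argsort(pts[:, k], kind="stable")
        lo, hi = pts[order[0], k], pts[order[-1], k]
        dist[order[0]] = dist[order[-1]] = float("inf")
        if hi > lo:
            gaps = (pts[order[2:], k] - pts[order[:-2], k]) / (hi - lo)
            dist[order[1:-1]] += gaps
    return [float(x) for x in dist]


def assign_ranks(members: list[Individual]) -> None:
    """Assign Pareto rank and per-front crowding distance in place."""
    if not members:
        return
    ranks = non_dominated_sort([m.objectives for m in members])
    for m, r in zip(members, ranks):
        m.rank = r
    for r in set(ranks):
        front = [m for m in members if m.rank == r]
        for m, c in zip(front, crowding_distance([m.objectives for m in front])):
            m.crowding = c


def _better(a: Individual, b: Individual) -> bool:
    """NSGA-II crowded-comparison: lower rank, then larger crowding."""
    if a.rank != b.rank:
        return a.rank < b.rank
    return (a.crowding or 0.0) > (b.crowding or 0.0)


def tournament_select(pop: Population, rng: np.random.Generator,
                      p: float = 0.95) -> Individual:
    """Binary tournament: the crowded-comparison winner with probability p."""
    if len(pop.members) < 2:
        raise ValueError("tournament selection needs a population of >= 2")
    i, j = rng.choice(len(pop.members), size=2, replace=False)
    a, b = pop.members[i], pop.members[j]
    winner, loser = (a, b) if _better(a, b) else (b, a)
    return winner if rng.random() < p else loser


def crossover_latent(z1: np.ndarray, z2: np.ndarray, rng: np.random.Generator,
                     swap_p: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-coordinate uniform crossover (swap with probability ``swap_p``)."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("latent vectors differ in length")
    mask = rng.random(z1.shape) < swap_p
    c1, c2 = z1.copy(), z2.copy()
    c1[mask], c2[mask] = z2[mask], z1[mask]
    return c1, c2


def mutate_latent(z: np.ndarray, rate: float, sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian coordinate mutation: each coordinate perturbed w.p. ``rate``."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("mutation rate must be in [0, 1]")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    z = np.asarray(z, dtype=float).copy()
    mask = rng.random(z.shape) < rate
    z[mask] += rng.normal(0.0, sigma, size=int(mask.sum()))
    return z


# ---------------------------------------------------------------------------
# Generation loop
# ---------------------------------------------------------------------------


def evolve_generation(pop: Population, model, config: DELConfig,
                      rng: np.random.Generator, scorer,
                      known_smiles: set[str] | None = None,
                      ) -> tuple[Population, int, int]:
    """One DEL generation: select/cross/mutate in latent space, decode,
    filter invalid and duplicate offspring, evaluate, merge elitistically.

    Returns (next population, decode attempts, valid decodes) so the caller
    can report a validity ratio over the raw decoder output.
    """
    known = set(known_smiles or ())
    latents = np.stack([m.latent for m in pop.members])
    sigma = config.mutation_sigma_scale * float(np.mean(latents.std(axis=0)))
    if sigma == 0.0:
        sigma = config.mutation_sigma_scale

    attempts = 0
    n_valid = 0
    offspring: list[Individual] = []
    seen = {m.molecule.smiles for m in pop.members} | known
    while attempts < pop.size_target:
        p1 = tournament_select(pop, rng, config.tournament_p)
        p2 = tournament_select(pop, rng, config.tournament_p)
        c1, c2 = crossover_latent(p1.latent, p2.latent, rng, config.crossover_swap_p)
        for z in (c1, c2):
            if attempts >= pop.size_target:
                break
            z = mutate_latent(z, config.mutation_rate, sigma, rng)
            attempts += 1
            mol = model.decode(z)
            if mol is None or not mol.valid:
                continue
            n_valid += 1
            if mol.smiles in seen:
                continue
            seen.add(mol.smiles)
            offspring.append(Individual(molecule=mol, latent=z, objectives=None))

    records = evaluate_objectives([o.molecule for o in offspring], scorer)
    kept = []
    for ind, rec in zip(offspring, records):
        if rec.objectives.is_finite():
            ind.objectives = rec.objectives
            kept.append(ind)

    # previous population contributes at most elite_fraction of the merged
    # pool (default 0.5: all of it when offspring fill their quota)
    elite_cap = max(2, int(round(config.elite_fraction * 2 * pop.size_target)))
    previous = sorted(pop.members, key=lambda m: (m.rank, -(m.crowding or 0.0)))
    pool = previous[:elite_cap] + kept
    assign_ranks(pool)
    pool.sort(key=lambda m: (m.rank, -(m.crowding or 0.0)))
    members = pool[:pop.size_target]
    assign_ranks(members)
    return Population(generation=pop.generation + 1, members=members,
                      size_target=pop.size_target), attempts, n_valid


@dataclass
class RunHistory:
    config: DELConfig
    populations: list[Population] = field(default_factory=list)
    metrics: list[GenerationReport] = field(default_factory=list)
    loss_history: list[dict] = field(default_factory=list)
    reference: tuple[float, ...] | None = None
    model: object | None = None

    def metrics_frame(self):
        import pandas as pd

        return pd.DataFrame([m.as_dict() for m in self.metrics])

    def population_frame(self, generation: int = -1):
        import pandas as pd

        pop = self.populations[generation]
        return pd.DataFrame([
            {"smiles": m.molecule.smiles, "sas": m.objectives.sas,
             "logp": m.objectives.logp, "bas": m.objectives.bas,
             "rank": m.rank, "crowding": m.crowding}
            for m in pop.members
        ])

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics_frame().to_csv(out / "metrics.csv", index=False)
        for g in range(len(self.populations)):
            self.population_frame(g).to_csv(out / f"population_gen{g}.csv", index=False)
        if self.reference is not None:
            (out / "reference_point.txt").write_text(
                ",".join(f"{v:.6f}" for v in self.reference) + "\n")


def run_del(dataset, config: DELConfig, model_factory, scorer,
            extra_initial: list[Molecule] | None = None) -> RunHistory:
    """Full deep-evolutionary-learning run at the configured scale.

    ``model_factory(dataset, seed)`` must return an untrained generative
    model exposing ``fit(mols, epochs, lr, ...)``, ``encode`` and
    ``decode``.  ``scorer`` provides the binding-affinity objective.
    ``extra_initial`` molecules (e.g. known drugs) are appended to the
    initial population.
    """
    data = preprocess_dataset(dataset)
    if not data:
        raise ValueError("dataset is empty after preprocessing")
    rng = np.random.default_rng(config.seed)
    model = model_factory(data, config.seed)

    base_lr = getattr(model.config, "learning_rate", 1e-4)
    records_all = evaluate_objectives(data, scorer)
    target_map = {r.smiles: r.objectives for r in records_all}
    losses = model.fit(data, epochs=config.initial_epochs, lr=base_lr,
                       targets=target_map)
    history = RunHistory(config=config)
    history.model = model
    history.loss_history.append({"phase": "pretrain", "losses": losses})

    n_init = min(config.population_size, len(data))
    idx = rng.choice(len(data), size=n_init, replace=False)
    initial_mols = [data[i] for i in sorted(idx)]
    if extra_initial:
        seen = {m.smiles for m in initial_mols}
        initial_mols += [m for m in extra_initial if m.valid and m.smiles not in seen]

    members = []
    init_records = []
    for m in initial_mols:
        obj = target_map.get(m.smiles)
        if obj is None:
            rec = evaluate_objectives([m], scorer)
            if not rec:
                continue
            obj = rec[0].objectives
        if not obj.is_finite():
            continue
        members.append(Individual(molecule=m, latent=model.encode(m).mean,
                                  objectives=obj))
        init_records.append(PropertyRecord(smiles=m.smiles, objectives=obj))
    assign_ranks(members)
    pop = Population(generation=0, members=members,
                     size_target=config.population_size)
    history.populations.append(pop)

    ref = reference_point([m.objectives for m in pop.front(1)])
    history.reference = ref
    training_smiles = {m.smiles for m in data}
    history.metrics.append(generation_report(
        0, pop.records(), [m.objectives for m in pop.front(1)],
        init_records, training_smiles, ref))

    for g in range(1, config.generations + 1):
        pop, attempts, n_valid = evolve_generation(
            pop, model, config, rng, scorer, known_smiles=training_smiles)
        history.populations.append(pop)
        history.metrics.append(generation_report(
            g, pop.records(), [m.objectives for m in pop.front(1)],
            init_records, training_smiles, ref,
            n_decoded=attempts, n_valid_decoded=n_valid))
        logger.info("generation %d: %s", g, history.metrics[-1])

        elite = sorted(pop.members, key=lambda m: (m.rank, -(m.crowding or 0.0)))
        n_ft = max(2, int(round(config.finetune_fraction * len(elite))))
        ft_mols = [m.molecule for m in elite[:n_ft]]
        ft_targets = {m.molecule.smiles: m.objectives for m in elite[:n_ft]}
        lr = base_lr * config.annealing_rate ** g
        try:
            losses = model.fit(ft_mols, epochs=config.subsequent_epochs, lr=lr,
                               targets=ft_targets)
            history.loss_history.append({"phase": f"finetune_gen{g}", "losses": losses})
        except Exception as exc:
            logger.warning("fine-tuning skipped at generation %d: %s", g, exc)
    return history
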