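"""Pareto machinery and the evolutionary loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delmol.evolution import (DELConfig, Individual, Population, assign_ranks,
                              crossover_latent, crowding_distance, dominates,
                              evolve_generation, mutate_latent,
                              non_dominated_sort, run_del, tournament_select)
from delmol.generative import ModelConfig, SequenceVAE
from delmol.objectives import ObjectiveVector, surrogate_bas


class TestDominance:
    def test_strict_domination(self):
        assert dominates((1, 1, 1), (2, 2, 2))

    def test_equal_points_do_not_dominate(self):
        assert not dominates((1, 1, 1), (1, 1, 1))

    def test_incomparable(self):
        assert not dominates((1, 3, 2), (3, 1, 2))
        assert not dominates((3, 1, 2), (1, 3, 2))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            dominates((1, 2), (1, 2, 3))


def brute_force_ranks(points):
    """O(n^2)-per-front peeling oracle."""
    points = [tuple(p) for p in points]
    remaining = dict(enumerate(points))
    ranks = {}
    r = 1
    while remaining:
        front = [i for i, p in remaining.items()
                 if not any(dominates(q, p) for j, q in remaining.items() if j != i)]
        for i in front:
            ranks[i] = r
            del remaining[i]
        r += 1
    return [ranks[i] for i in range(len(points))]


class TestNonDominatedSort:
    def test_single_point(self):
        assert non_dominated_sort([(1.0, 2.0)]) == [1]

    def test_total_order_chain(self):
        assert non_dominated_sort([(1, 1), (2, 2), (3, 3)]) == [1, 2, 3]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = rng.integers(0, 6, size=(40, 3)).astype(float)
            assert non_dominated_sort(pts) == brute_force_ranks(pts)

    def test_ranks_partition_population(self):
        rng = np.random.default_rng(1)
        pts = rng.random((50, 3))
        ranks = non_dominated_sort(pts)
        assert all(r >= 1 for r in ranks)
        assert len(ranks) == 50


class TestCrowdingDistance:
    def test_small_fronts_all_infinite(self):
        assert crowding_distance([(0, 1)]) == [np.inf]
        assert crowding_distance([(0, 1), (1, 0)]) == [np.inf, np.inf]

    def test_hand_computed_interior_point(self):
        d = crowding_distance([(0, 2), (1, 1), (2, 0)])
        assert d[0] == np.inf and d[2] == np.inf
        assert d[1] == pytest.approx(2.0)  # (2-0)/2 + (2-0)/2

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        pts = [tuple(p) for p in rng.random((12, 3))]
        base = dict(zip(pts, crowding_distance(pts)))
        perm = pts[::-1]
        assert dict(zip(perm, crowding_distance(perm))) == base

    def test_zero_range_objective_contributes_nothing(self):
        d = crowding_distance([(0.0, 5.0), (1.0, 5.0), (2.0, 5.0)])
        assert d[1] == pytest.approx(1.0)  # only the first objective counts


def _toy_population(objs, size_target=None, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    from delmol.chem import Molecule

    members = [Individual(molecule=Molecule.from_smiles("C" * (i + 1)),
                          latent=rng.standard_normal(8),
                          objectives=ObjectiveVector(*o))
               for i, o in enumerate(objs)]
    assign_ranks(members)
    return Population(generation=0, members=members,
                      size_target=size_target or len(members))


class TestTournament:
    def test_winner_frequency_matches_probability(self):
        pop = _toy_population([(1, 1, 1), (2, 2, 2)])
        rng = np.random.default_rng(123)
        wins = sum(tournament_select(pop, rng, p=0.95).rank == 1
                   for _ in range(10_000))
        assert wins / 10_000 == pytest.approx(0.95, abs=0.01)

    def test_symmetric_tie(self):
        pop = _toy_population([(1, 2, 3), (3, 2, 1)])  # same rank, inf crowding
        rng = np.random.default_rng(7)
        picks = sum(tournament_select(pop, rng).molecule.smiles == "C"
                    for _ in range(10_000))
        assert picks / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_seeded_determinism(self):
        pop = _toy_population([(1, 1, 1), (2, 2, 2), (1, 2, 1)])
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            seqs.append([tournament_select(pop, rng).molecule.smiles
                         for _ in range(50)])
        assert seqs[0] == seqs[1]

    def test_too_small_population(self):
        pop = _toy_population([(1, 1, 1)])
        with pytest.raises(ValueError):
            tournament_select(pop, np.random.default_rng(0))


class TestVariationOperators:
    def test_identical_parents_identical_children(self):
        z = np.arange(8.0)
        c1, c2 = crossover_latent(z, z, np.random.default_rng(0))
        assert np.array_equal(c1, z) and np.array_equal(c2, z)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_crossover_conserves_coordinates(self, seed):
        rng = np.random.default_rng(seed)
        z1, z2 = rng.normal(size=16), rng.normal(size=16)
        c1, c2 = crossover_latent(z1, z2, rng)
        assert np.allclose(c1 + c2, z1 + z2)
        for i in range(16):
            assert {c1[i], c2[i]} == {z1[i], z2[i]}

    def test_crossover_length_mismatch(self):
        with pytest.raises(ValueError):
            crossover_latent(np.zeros(3), np.zeros(4), np.random.default_rng(0))

    def test_mutation_rate_zero_is_identity(self):
        z = np.arange(6.0)
        assert np.array_equal(mutate_latent(z, 0.0, 1.0, np.random.default_rng(0)), z)

    def test_mutation_sigma_zero_is_identity(self):
        z = np.arange(6.0)
        assert np.array_equal(mutate_latent(z, 1.0, 0.0, np.random.default_rng(0)), z)

    def test_expected_touched_coordinates(self):
        """Binomial expectation: rate 0.01 x dim 64 = 0.64 per draw."""
        rng = np.random.default_rng(99)
        z = np.zeros(64)
        touched = [np.count_nonzero(mutate_latent(z, 0.01, 1.0, rng))
                   for _ in range(10_000)]
        assert np.mean(touched) == pytest.approx(0.64, abs=0.05)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            mutate_latent(np.zeros(3), 0.5, -1.0, np.random.default_rng(0))


class _ClosedModel:
    """Decoder that never yields a new molecule (no variation enters)."""

    config = ModelConfig.tiny()

    def decode(self, z):
        return None


class TestEvolveGeneration:
    def test_closed_decoder_preserves_fronts(self):
        pop = _toy_population([(1, 2, 2), (2, 1, 2), (2, 2, 1), (3, 3, 3)])
        cfg = DELConfig(population_size=4, mutation_rate=0.0, seed=0)
        nxt, attempts, n_valid = evolve_generation(
            pop, _ClosedModel(), cfg, np.random.default_rng(0),
            lambda m: surrogate_bas(m))
        assert attempts == 4 and n_valid == 0
        assert {m.molecule.smiles for m in nxt.members} == \
            {m.molecule.smiles for m in pop.members}
        assert [m.rank for m in nxt.members] == [m.rank for m in pop.members]
        assert nxt.generation == 1

    def test_seeded_determinism(self, trained_jtvae, library20):
        from delmol.objectives import evaluate_objectives

        recs = evaluate_objectives(library20, surrogate_bas)
        members = [Individual(molecule=m, latent=trained_jtvae.encode(m).mean,
                              objectives=r.objectives)
                   for m, r in zip(library20, recs)]
        assign_ranks(members)
        outs = []
        for _ in range(2):
            pop = Population(generation=0,
                             members=[Individual(**vars(m)) for m in members],
                             size_target=20)
            nxt, _, _ = evolve_generation(pop, trained_jtvae,
                                          DELConfig(population_size=20, seed=0),
                                          np.random.default_rng(5),
                                          lambda m: surrogate_bas(m))
            outs.append(sorted(m.molecule.smiles for m in nxt.members))
        assert outs[0] == outs[1]


@pytest.fixture(scope="module")
def tiny_run(library200):
    cfg = DELConfig(generations=3, population_size=60, initial_epochs=6,
                    subsequent_epochs=2, seed=7)
    mc = ModelConfig.tiny()
    factory = lambda data, seed: SequenceVAE.from_dataset(
        data, mc, kind="fragvae", seed=seed)
    return run_del(library200, cfg, factory,
                   lambda m: surrogate_bas(m, seed=7))


class TestRunDel:
    def test_zero_generations(self, library200):
        cfg = DELConfig(generations=0, population_size=30, initial_epochs=2,
                        subsequent_epochs=1, seed=1)
        mc = ModelConfig.tiny()
        factory = lambda data, seed: SequenceVAE.from_dataset(
            data, mc, kind="jtvae", seed=seed)
        hist = run_del(library200[:60], cfg, factory,
                       lambda m: surrogate_bas(m))
        assert len(hist.populations) == 1
        assert hist.model is not None
        assert len(hist.metrics) == 1

    def test_history_structure(self, tiny_run):
        assert len(tiny_run.populations) == 4
        assert [m.generation for m in tiny_run.metrics] == [0, 1, 2, 3]
        for pop in tiny_run.populations:
            assert len(pop.members) <= pop.size_target
            smiles = [m.molecule.smiles for m in pop.members]
            assert len(smiles) == len(set(smiles))
            ranks = {m.rank for m in pop.members}
            assert min(ranks) == 1

    def test_reproducible_bit_identical(self, library200, tiny_run):
        cfg = DELConfig(generations=3, population_size=60, initial_epochs=6,
                        subsequent_epochs=2, seed=7)
        mc = ModelConfig.tiny()
        factory = lambda data, seed: SequenceVAE.from_dataset(
            data, mc, kind="fragvae", seed=seed)
        again = run_del(library200, cfg, factory,
                        lambda m: surrogate_bas(m, seed=7))
        for p1, p2 in zip(tiny_run.populations, again.populations):
            assert [m.molecule.smiles for m in p1.members] == \
                [m.molecule.smiles for m in p2.members]
        assert tiny_run.metrics_frame().equals(again.metrics_frame())

    def test_population_csv_layout(self, tiny_run, tmp_path):
        tiny_run.save(tmp_path / "run")
        import pandas as pd

        df = pd.read_csv(tmp_path / "run" / "population_gen3.csv")
        assert list(df.columns) == ["smiles", "sas", "logp", "bas",
                                    "rank", "crowding"]
        assert (tmp_path / "run" / "metrics.csv").exists()
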