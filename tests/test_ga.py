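"""Genetic-algorithm machinery: fitness functions, optimizer contracts, pipeline."""

import numpy as np
import pytest

from solvcontact import fixtures
from solvcontact.atomtypes import TypeAssignment
from solvcontact.energy import solvation_energy
from solvcontact.ga import (FitDataset, GAConfig, Genome, fit_pipeline, fitness_FS,
                            fitness_FV, ga_run)
from solvcontact.mol import Atom, Molecule
from solvcontact.parameters import AtomParameters, ParameterTable


def chain_dataset(n_molecules=6, seed=0, noise_sd=0.0, mc_trials=50_000):
    truth, te = fixtures.two_type_truth()
    spec = fixtures.SyntheticDatasetSpec(
        truth=truth, type_elements=te, n_molecules=n_molecules,
        noise_sd=noise_sd, mc_trials=mc_trials, seed=seed)
    return truth, fixtures.make_synthetic_dataset(spec)


def truth_genome_SOP(truth):
    labels = sorted(truth.entries)
    keys = [(l, p) for l in labels for p in ("S", "O_max", "P")]
    vals = np.array([getattr(truth[l], p) for l in labels for p in ("S", "O_max", "P")])
    return Genome.from_bounds(keys, values=vals)


class TestGenome:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError, match="bounds"):
            Genome.from_bounds([("A", "V")], values=np.array([999.0]))

    def test_default_bounds_bracket_published_tables(self, table37):
        from solvcontact.ga import DEFAULT_BOUNDS

        for p in table37.entries.values():
            assert DEFAULT_BOUNDS["V"][0] < p.V <= DEFAULT_BOUNDS["V"][1]
            assert DEFAULT_BOUNDS["O_max"][0] <= p.O_max <= DEFAULT_BOUNDS["O_max"][1]
            assert DEFAULT_BOUNDS["S"][0] <= p.S <= DEFAULT_BOUNDS["S"][1]
            assert DEFAULT_BOUNDS["P"][0] <= p.P <= DEFAULT_BOUNDS["P"][1]


class TestFitnessFV:
    def test_perfect_decomposition_is_zero(self):
        truth, data = chain_dataset(n_molecules=4, mc_trials=50_000)
        labels = sorted(truth.entries)
        genome = Genome.from_bounds([(l, "V") for l in labels],
                                    values=np.array([truth[l].V for l in labels]))
        # disjoint spheres: targets differ from the exact decomposition only by MC noise
        assert fitness_FV(genome, data).mean < 1.0

    def test_single_molecule_arithmetic(self):
        m = Molecule("AB", [Atom(0, "C", np.zeros(3)), Atom(1, "O", np.array([5.0, 0, 0]))])
        asg = TypeAssignment(scheme="custom", labels=["A", "B"])
        data = FitDataset(molecules=[(m, asg)], volume_targets=[20.0])
        genome = Genome.from_bounds([("A", "V"), ("B", "V")], values=np.array([8.0, 9.0]))
        assert fitness_FV(genome, data).value == pytest.approx(3.0)

    def test_matches_brute_force_loop(self, rng):
        truth, data = chain_dataset(n_molecules=5, mc_trials=20_000)
        labels = sorted(truth.entries)
        values = rng.uniform(1.0, 30.0, size=2)
        genome = Genome.from_bounds([(l, "V") for l in labels], values=values)
        vmap = dict(zip(labels, values))
        expected = sum(abs(data.volume_targets[k] - sum(vmap[l] for l in asg.labels))
                       for k, (_, asg) in enumerate(data.molecules))
        assert fitness_FV(genome, data).value == pytest.approx(expected, abs=1e-9)

    def test_no_volume_targets(self):
        truth, data = chain_dataset(n_molecules=2, mc_trials=10_000)
        data.volume_targets = None
        genome = Genome.from_bounds([("X.c", "V"), ("X.o", "V")])
        with pytest.raises(ValueError, match="volume"):
            fitness_FV(genome, data)


class TestFitnessFS:
    def test_truth_genome_scores_zero_on_noise_free_data(self):
        truth, data = chain_dataset(n_molecules=5, mc_trials=10_000)
        genome = truth_genome_SOP(truth)
        fixed_V = {l: truth[l].V for l in truth.entries}
        assert fitness_FS(genome, fixed_V, data).value == pytest.approx(0.0, abs=1e-8)

    def test_single_atom_arithmetic(self):
        m = Molecule("A", [Atom(0, "C", np.zeros(3))])
        asg = TypeAssignment(scheme="custom", labels=["A"])
        data = FitDataset(molecules=[(m, asg)], dg_targets=[0.0])
        genome = Genome.from_bounds([("A", "S"), ("A", "O_max"), ("A", "P")],
                                    values=np.array([5.0 / 300.0, 300.0, 0.0]))
        fixed_V = {"A": 10.0}
        assert fitness_FS(genome, fixed_V, data).value == pytest.approx(5.0, abs=1e-9)

    def test_matches_energy_module_loop(self, rng):
        """Aggregated fast path vs molecule-by-molecule solvation_energy calls."""
        truth, data = chain_dataset(n_molecules=5, mc_trials=10_000)
        labels = sorted(truth.entries)
        vals = np.concatenate([[rng.uniform(-1, 1), rng.uniform(260, 410),
                                rng.uniform(-1, 1)] for _ in labels])
        keys = [(l, p) for l in labels for p in ("S", "O_max", "P")]
        genome = Genome.from_bounds(keys, values=vals)
        fixed_V = {l: truth[l].V for l in labels}
        table = ParameterTable(scheme="custom", entries={
            l: AtomParameters(V=fixed_V[l], O_max=genome.param(l, "O_max"),
                              S=genome.param(l, "S"), P=genome.param(l, "P"))
            for l in labels})
        expected = sum(
            abs(data.dg_targets[k]
                - solvation_energy(m, table, include_self=True, assignment=asg).total)
            for k, (m, asg) in enumerate(data.molecules))
        assert fitness_FS(genome, fixed_V, data).value == pytest.approx(expected, rel=1e-9)


class TestGaRun:
    def _abs_fitness(self, target=3.0):
        from solvcontact.ga import FitnessValue

        def fitness(g):
            return FitnessValue(value=abs(float(g.values[0]) - target), kind="F_V")
        return fitness

    def _template(self):
        return Genome(keys=(("x", "V"),), values=np.array([5.0]),
                      lower=np.array([0.0]), upper=np.array([10.0]))

    def test_converges_on_convex_surrogate(self):
        cfg = GAConfig(population_size=20, survivors=10, mutation_prob=0.5,
                       max_generations=200, seed=1, plateau_generations=1000)
        res = ga_run(self._abs_fitness(), cfg, self._template(), include_template=False)
        assert abs(res.best.values[0] - 3.0) < 1e-2

    def test_zero_generations_returns_initial_best(self):
        cfg = GAConfig(population_size=20, survivors=10, max_generations=0, seed=1)
        res = ga_run(self._abs_fitness(), cfg, self._template())
        assert res.generations == 0 and len(res.history) == 1

    def test_same_seed_identical_history(self):
        cfg = GAConfig(population_size=20, survivors=10, mutation_prob=0.3,
                       max_generations=50, seed=9, plateau_generations=1000)
        a = ga_run(self._abs_fitness(), cfg, self._template())
        b = ga_run(self._abs_fitness(), cfg, self._template())
        assert np.array_equal(a.history, b.history)
        assert np.array_equal(a.best.values, b.best.values)

    def test_history_monotone_non_increasing(self):
        cfg = GAConfig(population_size=20, survivors=10, mutation_prob=0.5,
                       max_generations=100, seed=2, plateau_generations=1000)
        res = ga_run(self._abs_fitness(), cfg, self._template())
        assert np.all(np.diff(res.history) <= 0)

    def test_every_evaluated_genome_within_bounds(self):
        from solvcontact.ga import FitnessValue

        seen = []

        def fitness(g):
            seen.append(g.values.copy())
            return FitnessValue(value=abs(float(g.values[0]) - 3.0), kind="F_V")

        cfg = GAConfig(population_size=16, survivors=8, mutation_prob=0.8,
                       max_generations=40, seed=3, plateau_generations=1000)
        ga_run(fitness, cfg, self._template())
        arr = np.array(seen)
        assert np.all(arr >= 0.0) and np.all(arr <= 10.0)

    def test_non_finite_fitness_aborts_with_genome_dump(self):
        from solvcontact.ga import FitnessValue

        def fitness(g):
            return FitnessValue(value=float("nan"), kind="F_V")

        cfg = GAConfig(population_size=4, survivors=2, max_generations=5, seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            ga_run(fitness, cfg, self._template())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=10, survivors=10)
        with pytest.raises(ValueError):
            GAConfig(mutation_prob=1.5)
        with pytest.raises(ValueError):
            GAConfig(selection="roulette")

    def test_tournament_selection_also_converges(self):
        cfg = GAConfig(population_size=20, survivors=10, mutation_prob=0.5,
                       max_generations=300, seed=4, selection="tournament",
                       plateau_generations=1000)
        res = ga_run(self._abs_fitness(), cfg, self._template())
        assert abs(res.best.values[0] - 3.0) < 0.1
        assert np.all(np.diff(res.history) <= 0)  # elitism holds under tournament too


class TestFitPipeline:
    def test_smoke_on_tiny_dataset(self):
        truth, data = chain_dataset(n_molecules=6, mc_trials=50_000)
        cfg = GAConfig(seed=5, max_generations=300, mutation_prob=0.3)
        with pytest.warns(UserWarning, match="under-determined"):
            table = fit_pipeline(data, cfg)
        assert table.scheme == "custom"
        assert set(table.entries) == set(truth.entries)
        meta = table.metadata
        assert meta["stage1"]["F_V_sum"] >= 0 and meta["stage2"]["F_s_sum"] >= 0
        assert meta["stage2"]["F_s_mean"] == pytest.approx(
            meta["stage2"]["F_s_sum"] / len(data.molecules))

    def test_reproducible_given_seed(self):
        _, data = chain_dataset(n_molecules=6, mc_trials=20_000)
        cfg = GAConfig(seed=8, max_generations=100, mutation_prob=0.3)
        t1 = fit_pipeline(data, cfg)
        t2 = fit_pipeline(data, cfg)
        assert t1.checksum() == t2.checksum()

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_pipeline(FitDataset(molecules=[], dg_targets=[], volume_targets=[]),
                         GAConfig(seed=0))

    def test_missing_targets_rejected(self):
        _, data = chain_dataset(n_molecules=2, mc_trials=10_000)
        data.volume_targets = None
        with pytest.raises(ValueError, match="both"):
            fit_pipeline(data, GAConfig(seed=0))
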