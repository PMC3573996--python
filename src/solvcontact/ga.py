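"""Genetic-algorithm parameterization of the solvation model.

Fitting proceeds in two stages, because the fragmental volumes converge
badly when optimized jointly with the energetic parameters:

1. the per-type fragmental volumes V_j are fit to Monte Carlo molecular
   volumes by minimizing F_V = sum_k | V_mol^k - sum_atoms V_type(atom) |;
2. with V_j frozen, the energetic parameters (S, O_max and, for models with
   the self-solvation term, P) are fit to reference solvation free energies
   by minimizing F_s = sum_k | dG_exp^k - dG_calc^k |.

The GA is elitist: each generation keeps the best ``survivors`` genomes by
truncation (or tournament, configurable) and refills the population with
children produced by uniform crossover (probability ``crossover_prob`` per
child) followed by per-entry point mutation (probability ``mutation_prob``).
A mutated entry is either resampled uniformly within its bounds or nudged
by clipped Gaussian noise; the mix of global and local moves lets the
search both escape poor basins and refine near an optimum.  Elitism makes
the per-generation best fitness monotonically non-increasing.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from solvcontact.atomtypes import TypeAssignment
from solvcontact.energy import occupancies
from solvcontact.mol import Molecule
from solvcontact.parameters import DEFAULT_SIGMA, AtomParameters, ParameterTable

# Default parameter bounds; bracket the published tables with margin.
DEFAULT_BOUNDS = {
    "V": (1e-3, 40.0),        # A^3
    "O_max": (250.0, 420.0),  # A^3
    "S": (-30.0, 30.0),       # kcal/(mol*A^3)
    "P": (-30.0, 30.0),       # kcal/(mol*A^3)
}


@dataclass
class Genome:
    """An ordered real parameter vector keyed by (atom type, parameter name)."""

    keys: tuple[tuple[str, str], ...]
    values: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (len(self.keys) == self.values.size == self.lower.size == self.upper.size):
            raise ValueError("keys, values and bounds must have equal length")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")
        if np.any(self.values < self.lower) or np.any(self.values > self.upper):
            raise ValueError("genome values violate their bounds")

    @classmethod
    def from_bounds(cls, keys: Sequence[tuple[str, str]],
                    bounds: dict[str, tuple[float, float]] | None = None,
                    values: np.ndarray | None = None) -> "Genome":
        bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
        lo = np.array([bounds[param][0] for _, param in keys])
        hi = np.array([bounds[param][1] for _, param in keys])
        if values is None:
            values = (lo + hi) / 2.0
        return cls(keys=tuple((t, p) for t, p in keys), values=np.asarray(values, float),
                   lower=lo, upper=hi)

    def param(self, label: str, name: str) -> float:
        return float(self.values[self.keys.index((label, name))])

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {k: float(v) for k, v in zip(self.keys, self.values)}


@dataclass
class GAConfig:
    population_size: int = 100
    survivors: int = 50
    mutation_prob: float = 0.01      # per-entry point-mutation probability; 0.01 suits
                                     # full-size ~150-entry genomes (about 1.5 mutations
                                     # per child) — scale it up to ~2/n for small genomes
    crossover_prob: float = 0.6      # per-child crossover probability
    max_generations: int = 10_000
    seed: int | None = None
    tolerance: float = 1e-6          # plateau threshold on the best fitness
    plateau_generations: int = 500
    selection: str = "truncation"    # or "tournament"
    blend_prob: float = 0.5          # fraction of crossovers done as arithmetic blends
                                     # (children sampled along the parent difference),
                                     # which supplies the correlated moves that plain
                                     # entry swapping cannot produce
    local_mutation_prob: float = 0.7  # fraction of mutations that are local nudges
    local_mutation_sd: float = 0.1    # largest nudge sd as a fraction of the bound width
    local_mutation_decades: float = 6.0  # nudge sd is log-uniform over this many decades

    def __post_init__(self) -> None:
        if not 0 < self.survivors < self.population_size:
            raise ValueError("need 0 < survivors < population_size")
        for name in ("mutation_prob", "crossover_prob", "local_mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.selection not in ("truncation", "tournament"):
            raise ValueError("selection must be 'truncation' or 'tournament'")


@dataclass
class FitnessValue:
    value: float
    kind: str  # "F_V" (A^3) or "F_s" (kcal/mol)
    n_molecules: int = 0

    @property
    def mean(self) -> float:
        """Per-molecule mean absolute error (the sum divided by dataset size)."""
        return self.value / self.n_molecules if self.n_molecules else self.value


@dataclass
class FitDataset:
    """Typed molecules with reference targets for fitting.

    ``dg_targets`` are reference solvation free energies (kcal/mol);
    ``volume_targets`` are Monte Carlo molecular volumes (A^3).  Either may
    be absent when only one fitting stage is wanted.
    """

    molecules: list[tuple[Molecule, TypeAssignment]]
    dg_targets: np.ndarray | None = None
    volume_targets: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.molecules)
        for name in ("dg_targets", "volume_targets"):
            t = getattr(self, name)
            if t is not None:
                t = np.asarray(t, dtype=float)
                setattr(self, name, t)
                if t.size != n:
                    raise ValueError(f"{name} has {t.size} entries for {n} molecules")

    @property
    def labels(self) -> list[str]:
        """Sorted set of type labels present in the dataset."""
        seen: set[str] = set()
        for _, asg in self.molecules:
            for lbl in asg.labels:
                if lbl is None:
                    raise ValueError("dataset contains untyped atoms")
                seen.add(lbl)
        return sorted(seen)

    def type_count_matrix(self, labels: Sequence[str]) -> np.ndarray:
        """(n_molecules, n_types) matrix of atom counts per type."""
        idx = {lbl: k for k, lbl in enumerate(labels)}
        out = np.zeros((len(self.molecules), len(labels)))
        for k, (_, asg) in enumerate(self.molecules):
            for lbl in asg.labels:
                if lbl not in idx:
                    raise KeyError(f"type {lbl!r} missing from the genome's label set")
                out[k, idx[lbl]] += 1
        return out


# --------------------------------------------------------------------------
# Fitness functions
# --------------------------------------------------------------------------

def fitness_FV(genome: Genome, data: FitDataset) -> FitnessValue:
    """Volume-decomposition error: sum_k |V_mol^k - sum_atoms V_type(atom)|."""
    if data.volume_targets is None:
        raise ValueError("dataset carries no molecular-volume targets")
    labels = [t for t, p in genome.keys if p == "V"]
    vvec = np.array([genome.param(t, "V") for t in labels])
    counts = data.type_count_matrix(labels)
    pred = counts @ vvec
    value = float(np.abs(data.volume_targets - pred).sum())
    return FitnessValue(value=value, kind="F_V", n_molecules=len(data.molecules))


def _stage2_aggregates(data: FitDataset, labels: Sequence[str],
                       fixed_V: dict[str, float], sigma: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-molecule, per-type atom counts N and summed occupancies Osum.

    With V frozen the occupancies are constants, so the model energy reduces
    to dG_k = sum_t [ S_t (N_kt O_max_t - Osum_kt) + P_t Osum_kt ].
    """
    idx = {lbl: k for k, lbl in enumerate(labels)}
    vol_table = ParameterTable(scheme="custom", sigma=sigma, entries={
        lbl: AtomParameters(V=fixed_V[lbl], O_max=1.0, S=0.0) for lbl in labels})
    n_mat = np.zeros((len(data.molecules), len(labels)))
    osum = np.zeros_like(n_mat)
    for k, (mol, asg) in enumerate(data.molecules):
        occ = occupancies(mol, asg, vol_table)
        for i, lbl in enumerate(asg.labels):
            n_mat[k, idx[lbl]] += 1
            osum[k, idx[lbl]] += occ[i]
    return n_mat, osum


def _predict_dg(genome: Genome, labels: Sequence[str], n_mat: np.ndarray,
                osum: np.ndarray, include_self: bool) -> np.ndarray:
    s = np.array([genome.param(t, "S") for t in labels])
    omax = np.array([genome.param(t, "O_max") for t in labels])
    if include_self:
        p = np.array([genome.param(t, "P") for t in labels])
    else:
        p = np.zeros_like(s)
    return (n_mat * (s * omax)[None, :]).sum(axis=1) + (osum * (p - s)[None, :]).sum(axis=1)


def fitness_FS(genome: Genome, fixed_V: dict[str, float], data: FitDataset,
               include_self: bool = True, sigma: float = DEFAULT_SIGMA) -> FitnessValue:
    """Solvation-fit error: sum_k |dG_ref^k - dG_model^k| with V frozen."""
    if data.dg_targets is None:
        raise ValueError("dataset carries no solvation free energy targets")
    labels = sorted({t for t, p in genome.keys})
    missing = set(data.labels) - set(labels)
    if missing:
        raise KeyError(f"genome lacks entries for types {sorted(missing)}")
    n_mat, osum = _stage2_aggregates(data, labels, fixed_V, sigma)
    pred = _predict_dg(genome, labels, n_mat, osum, include_self)
    value = float(np.abs(data.dg_targets - pred).sum())
    return FitnessValue(value=value, kind="F_s", n_molecules=len(data.molecules))


# --------------------------------------------------------------------------
# The optimizer
# --------------------------------------------------------------------------

@dataclass
class GAResult:
    best: Genome
    best_fitness: FitnessValue
    history: np.ndarray       # per-generation best fitness, non-increasing
    generations: int
    seed: int | None
    converged: bool           # stopped on the fitness plateau


def ga_run(fitness: Callable[[Genome], FitnessValue], config: GAConfig,
           template: Genome, include_template: bool = True) -> GAResult:
    """Elitist GA minimization of a genome fitness.

    The initial population is uniform random within bounds; the template's
    own values occupy one slot when ``include_template`` (warm start).
    ``max_generations = 0`` returns the best of the initial population.
    """
    rng = np.random.default_rng(config.seed)
    n_param = len(template.keys)
    lo, hi = template.lower, template.upper
    width = hi - lo

    pop = rng.uniform(lo, hi, size=(config.population_size, n_param))
    if include_template:
        pop[0] = np.clip(template.values, lo, hi)

    def evaluate(rows: np.ndarray) -> np.ndarray:
        vals = np.empty(len(rows))
        for k, row in enumerate(rows):
            fv = fitness(replace(template, values=row))
            if not np.isfinite(fv.value):
                raise RuntimeError(
                    f"non-finite fitness {fv.value} for genome {dict(zip(template.keys, row))}")
            vals[k] = fv.value
        return vals

    fit = evaluate(pop)
    history: list[float] = []
    converged = False
    gen = 0
    for gen in range(1, config.max_generations + 1):
        order = np.argsort(fit, kind="stable")
        if config.selection == "truncation":
            surv_idx = order[:config.survivors]
        else:  # tournament: best always survives, rest drawn by pairwise contest
            surv_idx = [order[0]]
            while len(surv_idx) < config.survivors:
                a, b = rng.integers(0, config.population_size, size=2)
                surv_idx.append(a if fit[a] <= fit[b] else b)
            surv_idx = np.asarray(surv_idx)
        survivors = pop[surv_idx]
        surv_fit = fit[surv_idx]

        history.append(float(surv_fit.min()))
        if (len(history) > config.plateau_generations
                and history[-1 - config.plateau_generations] - history[-1] < config.tolerance):
            converged = True
            pop, fit = survivors, surv_fit
            break

        n_children = config.population_size - config.survivors
        children = np.empty((n_children, n_param))
        for c in range(n_children):
            child = survivors[rng.integers(config.survivors)].copy()
            if rng.random() < config.crossover_prob:
                other = survivors[rng.integers(config.survivors)]
                if rng.random() < config.blend_prob:
                    u = rng.uniform(-0.25, 1.25)
                    child = np.clip(child + u * (other - child), lo, hi)
                else:
                    mask = rng.random(n_param) < 0.5
                    child[mask] = other[mask]
            mut_mask = rng.random(n_param) < config.mutation_prob
            for m in np.nonzero(mut_mask)[0]:
                if rng.random() < config.local_mutation_prob:
                    # multi-scale nudge: sd log-uniform over several decades so the
                    # search can refine far below the bound width
                    sd = config.local_mutation_sd * width[m] * 10.0 ** rng.uniform(
                        -config.local_mutation_decades, 0.0)
                    child[m] = np.clip(child[m] + rng.normal(0.0, sd), lo[m], hi[m])
                else:
                    child[m] = rng.uniform(lo[m], hi[m])
            children[c] = child
        child_fit = evaluate(children)
        pop = np.vstack([survivors, children])
        fit = np.concatenate([surv_fit, child_fit])
    else:
        if config.max_generations == 0:
            history.append(float(fit.min()))

    best_idx = int(np.argmin(fit))
    best = replace(template, values=pop[best_idx])
    best_fv = fitness(best)
    hist = np.asarray(history if history else [best_fv.value])
    return GAResult(best=best, best_fitness=best_fv, history=hist,
                    generations=gen, seed=config.seed, converged=converged)


# --------------------------------------------------------------------------
# Two-stage pipeline
# --------------------------------------------------------------------------

def fit_pipeline(data: FitDataset, config: GAConfig,
                 bounds: dict[str, tuple[float, float]] | None = None,
                 include_self: bool = True,
                 sigma: float = DEFAULT_SIGMA) -> ParameterTable:
    """Fit a full parameter table: volumes first (F_V), then S/O_max/P (F_s).

    Returns a ``custom``-scheme :class:`ParameterTable` whose metadata
    records the seeds, generation counts and final fitness of both stages
    (F_s both as the raw sum and as the per-molecule mean).
    """
    if not data.molecules:
        raise ValueError("cannot fit an empty dataset")
    if data.volume_targets is None or data.dg_targets is None:
        raise ValueError("fit_pipeline needs both molecular-volume and dG targets")
    labels = data.labels
    n_params = len(labels) * (3 + include_self)
    if len(data.molecules) < n_params:
        _warnings.warn(
            f"under-determined fit: {n_params} parameters from "
            f"{len(data.molecules)} molecules", stacklevel=2)

    ss = np.random.SeedSequence(config.seed)
    seed_v, seed_s = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))

    # Stage 1: fragmental volumes against Monte Carlo molecular volumes.
    genome_v = Genome.from_bounds([(lbl, "V") for lbl in labels], bounds)
    cfg_v = replace(config, seed=seed_v)
    res_v = ga_run(lambda g: fitness_FV(g, data), cfg_v, genome_v)
    fitted_V = {lbl: res_v.best.param(lbl, "V") for lbl in labels}

    # Stage 2: energetic parameters with V frozen; the occupancy aggregates
    # are precomputed once since they no longer depend on the genome.
    n_mat, osum = _stage2_aggregates(data, labels, fitted_V, sigma)
    params = ["S", "O_max"] + (["P"] if include_self else [])
    keys = [(lbl, p) for lbl in labels for p in params]
    genome_s = Genome.from_bounds(keys, bounds)
    targets = data.dg_targets

    def fs(genome: Genome) -> FitnessValue:
        pred = _predict_dg(genome, labels, n_mat, osum, include_self)
        return FitnessValue(value=float(np.abs(targets - pred).sum()), kind="F_s",
                            n_molecules=len(data.molecules))

    cfg_s = replace(config, seed=seed_s)
    res_s = ga_run(fs, cfg_s, genome_s)

    entries = {}
    for lbl in labels:
        entries[lbl] = AtomParameters(
            V=fitted_V[lbl],
            O_max=res_s.best.param(lbl, "O_max"),
            S=res_s.best.param(lbl, "S"),
            P=res_s.best.param(lbl, "P") if include_self else None)
    metadata = {
        "fitted_by": "two-stage elitist GA",
        "seed": config.seed,
        "stage1": {"seed": seed_v, "generations": res_v.generations,
                   "F_V_sum": res_v.best_fitness.value,
                   "F_V_mean": res_v.best_fitness.mean,
                   "converged": res_v.converged},
        "stage2": {"seed": seed_s, "generations": res_s.generations,
                   "F_s_sum": res_s.best_fitness.value,
                   "F_s_mean": res_s.best_fitness.mean,
                   "converged": res_s.converged},
        "n_molecules": len(data.molecules),
        "include_self": include_self,
    }
    return ParameterTable(scheme="custom", entries=entries, sigma=sigma,
                          metadata=metadata)
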