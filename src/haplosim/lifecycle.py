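"""Non-overlapping generations with fitness-proportional parentage.

Each generation produces exactly ``Nf`` daughters and ``Nm`` sons (hard,
deterministic census — soft selection).  For every offspring, the mother is
drawn from the females with probability proportional to fitness (with
replacement) and the father likewise from the males.  Under haplodiploidy a
daughter unites a recombined maternal gamete with a clonal (then mutated)
copy of her father's single genome, while a son develops from an
unfertilized egg: one recombined maternal gamete plus a null genome — sons
have no father.  Under diploidy every offspring unites one recombined
gamete from each parent.

Two equivalent implementations are provided: :func:`next_generation`
advances the object model one step (readable reference, used for invariant
checking and tiny populations), and :func:`run_simulation` drives the
compiled array engine for long runs.  Both are mirrored by the exact chain
in :mod:`haplosim.markov_oracle`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .fitness import individual_fitness
from .gametogenesis import (
    MeiosisParams,
    apply_mutations,
    copy_genome,
    draw_crossovers,
    draw_new_mutations,
    recombine,
)
from .genome_core import (
    DIPLOID,
    FEMALE,
    HAPLODIPLOID,
    MALE,
    Genome,
    Individual,
    Population,
)

__all__ = [
    "SimulationConfig",
    "PopulationExtinctionError",
    "next_generation",
    "run_simulation",
    "single_copy_fate",
]


class PopulationExtinctionError(RuntimeError):
    """All fitnesses in one sex are zero: no parents can be drawn."""


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulation run.

    The standard full-scale treatment is 1,000 males and 1,000 females,
    L = 1e6 loci, mu = 1e-8, r = 1e-6, 15,000 burn-in + 35,000 recorded
    generations, with a single mutation type (s, h) and haploid dominance 1.
    """

    mode: str
    Nm: int
    Nf: int
    meiosis: MeiosisParams
    s: float
    h: float
    burn_in: int
    run_generations: int
    seed: int
    h_haploid: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in (HAPLODIPLOID, DIPLOID):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.Nm < 1 or self.Nf < 1:
            raise ValueError("Nm and Nf must be >= 1")
        if self.burn_in < 0 or self.run_generations < 1:
            raise ValueError("burn_in >= 0 and run_generations >= 1 required")

    @property
    def total_generations(self) -> int:
        return self.burn_in + self.run_generations

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "Nm": self.Nm,
            "Nf": self.Nf,
            "L": self.meiosis.L,
            "mu": self.meiosis.mu,
            "r": self.meiosis.r,
            "s": self.s,
            "h": self.h,
            "h_haploid": self.h_haploid,
            "burn_in": self.burn_in,
            "run_generations": self.run_generations,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(
            mode=d["mode"],
            Nm=int(d["Nm"]),
            Nf=int(d["Nf"]),
            meiosis=MeiosisParams(L=int(d["L"]), mu=float(d["mu"]), r=float(d["r"])),
            s=float(d["s"]),
            h=float(d["h"]),
            h_haploid=float(d.get("h_haploid", 1.0)),
            burn_in=int(d["burn_in"]),
            run_generations=int(d["run_generations"]),
            seed=int(d["seed"]),
        )


def _maternal_gamete(
    mother: Individual, config: SimulationConfig, rng: np.random.Generator, registry
) -> Genome:
    bps = draw_crossovers(rng, config.meiosis)
    start = "a" if rng.integers(0, 2) == 0 else "b"
    gamete = recombine(mother.genomes[0], mother.genomes[1], bps, start, registry)
    return _mutate(gamete, config, rng, registry)


def _paternal_gamete(
    father: Individual, config: SimulationConfig, rng: np.random.Generator, registry
) -> Genome:
    if config.mode == HAPLODIPLOID:
        gamete = copy_genome(father.genomes[0])
    else:
        bps = draw_crossovers(rng, config.meiosis)
        start = "a" if rng.integers(0, 2) == 0 else "b"
        gamete = recombine(father.genomes[0], father.genomes[1], bps, start, registry)
    return _mutate(gamete, config, rng, registry)


def _mutate(gamete, config, rng, registry) -> Genome:
    new = draw_new_mutations(
        rng,
        config.meiosis,
        config.s,
        config.h,
        generation=registry_generation(registry),
        registry=registry,
        h_haploid=config.h_haploid,
    )
    return apply_mutations(gamete, new, registry)


def registry_generation(registry) -> int:
    # origin generation is stamped by next_generation via this attribute
    return getattr(registry, "current_generation", 0)


def _weighted_indices(
    rng: np.random.Generator, weights: np.ndarray, size: int
) -> np.ndarray:
    total = weights.sum()
    if total <= 0:
        raise PopulationExtinctionError("all fitnesses are zero within a sex")
    return np.searchsorted(
        np.cumsum(weights), rng.random(size) * total, side="right"
    ).clip(max=len(weights) - 1)


def next_generation(
    pop: Population, config: SimulationConfig, rng: np.random.Generator
) -> Population:
    """Advance the object-model population by exactly one generation.

    Returns a new :class:`Population` sharing the (updated) mutation
    registry; copy counts are fully recounted on the offspring.
    """
    registry = pop.registry
    registry.current_generation = pop.generation + 1

    wf = np.array([individual_fitness(f, registry) for f in pop.females])
    wm = np.array([individual_fitness(m, registry) for m in pop.males])

    mothers_d = _weighted_indices(rng, wf, config.Nf)
    fathers_d = _weighted_indices(rng, wm, config.Nf)
    mothers_s = _weighted_indices(rng, wf, config.Nm)
    fathers_s = (
        _weighted_indices(rng, wm, config.Nm) if config.mode == DIPLOID else None
    )

    daughters = []
    for mi, fi in zip(mothers_d, fathers_d):
        egg = _maternal_gamete(pop.females[mi], config, rng, registry)
        sperm = _paternal_gamete(pop.males[fi], config, rng, registry)
        daughters.append(Individual(FEMALE, (egg, sperm)))
    sons = []
    for k, mi in enumerate(mothers_s):
        egg = _maternal_gamete(pop.females[mi], config, rng, registry)
        if config.mode == HAPLODIPLOID:
            sons.append(Individual(MALE, (egg, Genome.null())))
        else:
            sperm = _paternal_gamete(pop.males[fathers_s[k]], config, rng, registry)
            sons.append(Individual(MALE, (egg, sperm)))

    offspring = Population(
        mode=pop.mode,
        males=sons,
        females=daughters,
        registry=registry,
        generation=pop.generation + 1,
    )
    registry.counts = registry.recount(offspring)
    # registered ids that left every genome this generation keep count 0
    for mid in registry.records:
        registry.counts.setdefault(mid, 0)
    return offspring


def run_simulation(config: SimulationConfig, engine: str = "compiled"):
    """Run burn-in plus recorded generations from a mutation-free start.

    ``engine='compiled'`` uses the numba array engine (the default for any
    serious run); ``engine='python'`` drives the object model and is only
    sensible for tiny censuses and short horizons.  Both are bit-reproducible
    from (config, seed); the two engines use distinct random streams and so
    agree in distribution, not draw-for-draw.
    """
    from .substitution_tracker import SimulationResult, classify_and_purge

    if engine == "compiled":
        return _run_compiled(config)
    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")

    rng = np.random.default_rng(config.seed)
    pop = Population.founders(config.mode, config.Nm, config.Nf)
    rows = []
    log = []
    n_total = config.total_generations
    for _ in range(n_total):
        wf = np.mean([individual_fitness(f, pop.registry) for f in pop.females])
        wm = np.mean([individual_fitness(m, pop.registry) for m in pop.males])
        pop = next_generation(pop, config, rng)
        n_fixed, _ = classify_and_purge(pop, log)
        n_seg = sum(1 for c in pop.registry.counts.values() if c > 0)
        rows.append((pop.generation, n_fixed, n_seg, wf, wm))
    return SimulationResult.from_rows(
        config, rows, log, final_population=pop,
        n_mutations_created=pop.registry.n_created,
    )


def _run_compiled(config: SimulationConfig):
    from .substitution_tracker import SimulationResult

    seed32 = int(np.random.SeedSequence(config.seed).generate_state(1)[0] & 0x7FFFFFFF)
    is_hap = config.mode == HAPLODIPLOID
    G = 2 * config.Nf + (config.Nm if is_hap else 2 * config.Nm)
    (
        err,
        subs,
        seg,
        mwf,
        mwm,
        log_id,
        log_gen,
        data,
        indptr,
        pos_of,
        origin_of,
        next_id,
        n_created,
    ) = _engine._run_sim(
        is_hap,
        config.Nm,
        config.Nf,
        config.meiosis.L,
        config.meiosis.mu,
        config.meiosis.r,
        config.s,
        config.h,
        config.h_haploid,
        config.total_generations,
        seed32,
        np.zeros(0, dtype=np.int64),
        np.zeros(G + 1, dtype=np.int64),
        np.zeros(8, dtype=np.int64),
        np.zeros(8, dtype=np.int64),
        0,
        0,
    )
    if err == _engine.EXTINCT_FEMALES:
        raise PopulationExtinctionError("all female fitnesses are zero")
    if err == _engine.EXTINCT_MALES:
        raise PopulationExtinctionError("all male fitnesses are zero")

    rows = [
        (g + 1, int(subs[g]), int(seg[g]), float(mwf[g]), float(mwm[g]))
        for g in range(config.total_generations)
    ]
    log = [
        (int(m), int(pos_of[m]), config.s, config.h, int(origin_of[m]), int(fg))
        for m, fg in zip(log_id, log_gen)
    ]
    final = _population_from_arrays(config, data, indptr, pos_of, origin_of)
    return SimulationResult.from_rows(
        config, rows, log, final_population=final,
        n_mutations_created=int(n_created),
    )


def _population_from_arrays(config, data, indptr, pos_of, origin_of) -> Population:
    """Rebuild the object model from the engine's final genome arrays."""
    from .genome_core import MutationRecord

    pop = Population.founders(config.mode, config.Nm, config.Nf)
    reg = pop.registry
    for mid in sorted(set(int(m) for m in data)):
        # preserve engine ids so genomes and registry agree
        reg.records[mid] = MutationRecord(
            id=mid,
            position=int(pos_of[mid]),
            s=config.s,
            h=config.h,
            h_haploid=config.h_haploid,
            origin_generation=int(origin_of[mid]),
        )
        reg.counts[mid] = 0
        reg._next_id = mid + 1

    def fill(genome: Genome, slot: int) -> None:
        genome.mutation_ids = [int(m) for m in data[indptr[slot] : indptr[slot + 1]]]

    for i, fem in enumerate(pop.females):
        fill(fem.genomes[0], 2 * i)
        fill(fem.genomes[1], 2 * i + 1)
    off = 2 * config.Nf
    for j, male in enumerate(pop.males):
        if config.mode == HAPLODIPLOID:
            fill(male.genomes[0], off + j)
        else:
            fill(male.genomes[0], off + 2 * j)
            fill(male.genomes[1], off + 2 * j + 1)
    reg.counts = reg.recount(pop)
    for mid in reg.records:
        reg.counts.setdefault(mid, 0)
    pop.generation = config.total_generations
    return pop


def single_copy_fate(
    mode: str,
    Nm: int,
    Nf: int,
    s: float,
    h: float,
    n_replicates: int,
    seed: int,
    placement: str = "female",
    h_haploid: float = 1.0,
    max_generations: int = 1_000_000,
) -> int:
    """Number of replicates (out of ``n_replicates``) in which a single
    initial mutant copy fixes, with mutation switched off.

    ``placement`` is 'female' (the copy starts in one female genome) or
    'male' (in one male genome).  Used to validate the simulator against
    the exact Markov chain at tiny censuses.
    """
    is_hap = mode == HAPLODIPLOID
    if placement == "female":
        slot = 0
    elif placement == "male":
        slot = 2 * Nf
    else:
        raise ValueError("placement must be 'female' or 'male'")
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) & 0x7FFFFFFF
    n_fixed = 0
    for rep_seed in seeds:
        out = _engine._run_fate(
            is_hap, Nm, Nf, s, h, h_haploid, slot, int(rep_seed), max_generations
        )
        if out < 0:
            raise RuntimeError("single-copy fate run not absorbed")
        n_fixed += out
    return n_fixed
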