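"""Generation stepping: census constancy, inheritance rules, determinism,
and agreement between the reference and compiled engines."""

import math

import numpy as np
import pytest

from haplosim.gametogenesis import MeiosisParams
from haplosim.genome_core import DIPLOID, HAPLODIPLOID, Population, validate_population
from haplosim.lifecycle import (
    PopulationExtinctionError,
    SimulationConfig,
    next_generation,
    run_simulation,
    single_copy_fate,
)
from haplosim.markov_oracle import single_copy_fixation_probability


def _config(mode, Nm=5, Nf=5, L=100, mu=1e-3, r=1e-3, s=0.0, h=0.0, **kw):
    kw.setdefault("burn_in", 0)
    kw.setdefault("run_generations", 1)
    kw.setdefault("seed", 0)
    return SimulationConfig(
        mode=mode, Nm=Nm, Nf=Nf, meiosis=MeiosisParams(L=L, mu=mu, r=r),
        s=s, h=h, **kw,
    )


@pytest.mark.parametrize("mode", [HAPLODIPLOID, DIPLOID])
def test_census_constant_and_population_valid(mode):
    config = _config(mode, Nm=4, Nf=6)
    rng = np.random.default_rng(1)
    pop = Population.founders(mode, 4, 6)
    for _ in range(10):
        pop = next_generation(pop, config, rng)
        assert len(pop.males) == 4 and len(pop.females) == 6
        assert validate_population(pop) == []


def test_haplodiploid_sons_have_null_genome_and_no_father():
    """Sons develop from unfertilized eggs: second slot null, and with a
    single mother and mu=0 their mutations come from her two genomes."""
    config = _config(HAPLODIPLOID, Nm=6, Nf=1, mu=0.0)
    rng = np.random.default_rng(2)
    pop = Population.founders(HAPLODIPLOID, 6, 1)
    mother = pop.females[0]
    for g, positions in zip(mother.genomes, ([3, 40], [10])):
        for p in positions:
            rec = pop.registry.new_record(position=p, s=0.0, h=0.0)
            g.mutation_ids.append(rec.id)
    mother.genomes[0].mutation_ids.sort(key=pop.registry.sort_key)
    pop.registry.counts = pop.registry.recount(pop)
    maternal_union = set(mother.genomes[0].mutation_ids) | set(
        mother.genomes[1].mutation_ids
    )
    # give the males distinct mutations so a paternal leak would be visible
    for male in pop.males:
        rec = pop.registry.new_record(position=50, s=0.0, h=0.0)
        male.genomes[0].mutation_ids.append(rec.id)
    pop.registry.counts = pop.registry.recount(pop)

    offspring = next_generation(pop, config, rng)
    for son in offspring.males:
        assert son.genomes[1].is_null
        assert set(son.genomes[0].mutation_ids) <= maternal_union


def test_neutral_parentage_is_uniform():
    """With s = 0 every parent is drawn uniformly: mother usage across many
    draws is flat by a chi-square check."""
    config = _config(HAPLODIPLOID, Nm=200, Nf=10, mu=0.0)
    rng = np.random.default_rng(3)
    pop = Population.founders(HAPLODIPLOID, 200, 10)
    # tag each female genome pair with a private neutral marker
    markers = {}
    for i, fem in enumerate(pop.females):
        rec = pop.registry.new_record(position=i, s=0.0, h=0.0)
        fem.genomes[0].mutation_ids.append(rec.id)
        fem.genomes[1].mutation_ids.append(rec.id)
        markers[rec.id] = i
    pop.registry.counts = pop.registry.recount(pop)
    offspring = next_generation(pop, config, rng)
    usage = np.zeros(10)
    for son in offspring.males:
        for mid in son.genomes[0].mutation_ids:
            usage[markers[mid]] += 1
    from scipy import stats

    _, p = stats.chisquare(usage)
    assert p > 0.001


def test_same_seed_same_offspring():
    for mode in (HAPLODIPLOID, DIPLOID):
        config = _config(mode, s=0.01, h=0.5)
        pops = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            pop = Population.founders(mode, 5, 5)
            for _ in range(5):
                pop = next_generation(pop, config, rng)
            pops.append(pop)
        a, b = pops
        for ia, ib in zip(a.individuals(), b.individuals()):
            for ga, gb in zip(ia.genomes, ib.genomes):
                ga_pos = [a.registry.position_of(m) for m in ga.mutation_ids]
                gb_pos = [b.registry.position_of(m) for m in gb.mutation_ids]
                assert ga_pos == gb_pos


def test_extinction_raises():
    config = _config(HAPLODIPLOID, s=-1.0, h=1.0, mu=0.0)
    rng = np.random.default_rng(8)
    pop = Population.founders(HAPLODIPLOID, 5, 5)
    for fem in pop.females:
        rec = pop.registry.new_record(position=0, s=-1.0, h=1.0)
        fem.genomes[0].mutation_ids.append(rec.id)
    pop.registry.counts = pop.registry.recount(pop)
    with pytest.raises(PopulationExtinctionError):
        next_generation(pop, config, rng)


@pytest.mark.parametrize("engine", ["python", "compiled"])
def test_mutation_free_run_stays_empty(engine):
    config = _config(HAPLODIPLOID, mu=0.0, run_generations=5)
    result = run_simulation(config, engine=engine)
    assert result.total_fixations("all") == 0
    assert (result.per_generation["segregating_count"] == 0).all()


@pytest.mark.parametrize("engine", ["python", "compiled"])
def test_run_reproducible_and_seed_sensitive(engine):
    config = _config(HAPLODIPLOID, Nm=8, Nf=8, mu=1e-3, run_generations=30, seed=5)
    a = run_simulation(config, engine=engine)
    b = run_simulation(config, engine=engine)
    assert a.per_generation.equals(b.per_generation)
    assert a.substitution_log.equals(b.substitution_log)
    import dataclasses

    c = run_simulation(dataclasses.replace(config, seed=6), engine=engine)
    assert not a.per_generation.equals(c.per_generation)


def test_neutral_substitution_rate_small_scale():
    """Neutral fixations per generation ~ mu*L regardless of mode, checked
    at a small census over 10^4 recorded generations (3 Poisson SD)."""
    for mode in (HAPLODIPLOID, DIPLOID):
        config = _config(
            mode, Nm=20, Nf=20, L=10**5, mu=1e-7, r=1e-6,
            burn_in=2_000, run_generations=10_000, seed=9,
        )
        result = run_simulation(config)
        expected = config.meiosis.mu * config.meiosis.L * 10_000  # 100
        observed = result.total_fixations("recorded")
        assert abs(observed - expected) < 3 * math.sqrt(expected)


@pytest.mark.parametrize(
    "mode,copies_per_n", [(HAPLODIPLOID, 3), (DIPLOID, 4)]
)
def test_mutation_influx_accounting(mode, copies_per_n):
    """Across a whole run, new mutations arrive at 3N*mu*L (haplodiploid)
    or 4N*mu*L (diploid) per generation — one gamete per offspring genome —
    within 3 Poisson SE."""
    N, gens, L, mu = 20, 2_000, 1_000, 1e-4
    config = _config(
        mode, Nm=N, Nf=N, L=L, mu=mu, r=0.0,
        burn_in=0, run_generations=gens, seed=21,
    )
    result = run_simulation(config)
    lam = copies_per_n * N * mu * L * gens
    assert abs(result.n_mutations_created - lam) < 3 * math.sqrt(lam)


def test_reference_engine_agrees_with_exact_chain():
    """The pure-Python stepper reproduces the exact neutral fixation
    probability of a single copy at a tiny census (within a wide 99% CI:
    this is a distribution-level bridge between the two engines; the
    compiled engine is held to the same oracle at far higher replication)."""
    p_exact = single_copy_fixation_probability(HAPLODIPLOID, 3, 3, 0.0, 0.0)
    config = _config(HAPLODIPLOID, Nm=3, Nf=3, L=2, mu=0.0, r=0.0)
    n = 800
    master = np.random.default_rng(11)
    fixed = 0
    for _ in range(n):
        pop = Population.founders(HAPLODIPLOID, 3, 3)
        rec = pop.registry.new_record(position=0, s=0.0, h=0.0)
        pop.females[0].genomes[0].mutation_ids.append(rec.id)
        pop.registry.counts = pop.registry.recount(pop)
        rng = np.random.default_rng(master.integers(2**31))
        while True:
            pop = next_generation(pop, config, rng)
            count = pop.registry.counts.get(rec.id, 0)
            if count == 0:
                break
            if count == pop.n_genome_copies:
                fixed += 1
                break
    se = math.sqrt(p_exact * (1 - p_exact) / n)
    assert abs(fixed / n - p_exact) < 2.576 * se


def test_compiled_fate_runner_matches_male_placement():
    """Neutral single copy starting in a male genome also fixes with
    probability 1/(3N) in haplodiploids."""
    n = 10_000
    fixed = single_copy_fate(
        HAPLODIPLOID, 3, 3, s=0.0, h=0.0, n_replicates=n, seed=13, placement="male"
    )
    p_exact = single_copy_fixation_probability(
        HAPLODIPLOID, 3, 3, 0.0, 0.0, placement="male"
    )
    assert p_exact == pytest.approx(1 / 9, abs=1e-12)
    se = math.sqrt(p_exact * (1 - p_exact) / n)
    assert abs(fixed / n - p_exact) < 2.576 * se
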