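"""Core domain types for forward simulation of haplodiploid and diploid genomes.

Haplodiploid species (ants, bees, wasps, thrips, bark beetles, ...) produce
haploid males from unfertilized eggs and diploid females from fertilized eggs
(arrhenotoky).  We represent a haploid male as a diploid individual whose
second genome slot is a *null genome* — an empty placeholder that never
carries mutations and never participates in meiosis.  A matched, purely
diploid population model uses the same types with both slots real.

Genomes are sparse: a genome is the sorted collection of identifiers of the
mutations it carries, relative to a mutation-free ancestral reference.
Mutations are objects — two mutations at the same locus are distinct records
with distinct ids, and homozygosity is defined per id, never per position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "HAPLODIPLOID",
    "DIPLOID",
    "MALE",
    "FEMALE",
    "MutationRecord",
    "Genome",
    "Individual",
    "MutationRegistry",
    "Population",
    "CensusSummary",
    "census",
    "validate_population",
    "ValidationError",
]

HAPLODIPLOID = "haplodiploid"
DIPLOID = "diploid"
MALE = "male"
FEMALE = "female"


class ValidationError(ValueError):
    """A population or individual violates a structural invariant."""


@dataclass(frozen=True)
class MutationRecord:
    """A unique mutation event.

    Parameters
    ----------
    id
        Unique integer within a simulation run.
    position
        0-based locus index in ``[0, L)``.
    s
        Selection coefficient: the full (homozygous / hemizygous) fitness
        effect is a factor of ``1 + s``.
    h
        Dominance coefficient in diploid heterozygotes (factor ``1 + s*h``).
    h_haploid
        Dominance coefficient expressed by a hemizygous (haploid) carrier;
        fixed at 1 in all standard treatments, so male carriers have fitness
        ``1 + s``.
    origin_generation
        Generation in which the mutation arose.
    """

    id: int
    position: int
    s: float
    h: float
    h_haploid: float = 1.0
    origin_generation: int = 0


@dataclass
class Genome:
    """A sparse genome: sorted mutation ids, or a null placeholder.

    ``mutation_ids`` is kept sorted by ``(position, id)`` and duplicate-free;
    the position order is maintained by the gametogenesis operations via the
    registry.  A null genome carries no mutations, ever.
    """

    mutation_ids: list[int] = field(default_factory=list)
    is_null: bool = False

    def __post_init__(self) -> None:
        if self.is_null and self.mutation_ids:
            raise ValidationError("null genome must carry zero mutations")

    @classmethod
    def null(cls) -> "Genome":
        return cls(mutation_ids=[], is_null=True)

    @classmethod
    def empty(cls) -> "Genome":
        return cls(mutation_ids=[], is_null=False)

    def __contains__(self, mutation_id: int) -> bool:
        return mutation_id in self.mutation_ids

    def __len__(self) -> int:
        return len(self.mutation_ids)


@dataclass
class Individual:
    """One individual: a sex and exactly two genome slots.

    In haplodiploid mode males carry one real genome and one null genome;
    females carry two real genomes.  In diploid mode both slots are real for
    both sexes.
    """

    sex: str
    genomes: tuple[Genome, Genome]

    def non_null_genomes(self) -> list[Genome]:
        return [g for g in self.genomes if not g.is_null]

    @property
    def ploidy(self) -> int:
        return len(self.non_null_genomes())


class MutationRegistry:
    """Registry of all segregating mutations with per-mutation copy counts.

    Maps id -> (record, copy_count).  Copy counts equal the number of
    non-null genomes carrying the id; they are maintained by the lifecycle
    (full recount after reproduction) and checked by brute-force recount in
    tests.
    """

    def __init__(self) -> None:
        self.records: dict[int, MutationRecord] = {}
        self.counts: dict[int, int] = {}
        self._next_id: int = 0
        self.n_created: int = 0

    def new_record(
        self,
        position: int,
        s: float,
        h: float,
        h_haploid: float = 1.0,
        origin_generation: int = 0,
    ) -> MutationRecord:
        """Create, register (copy count 1) and return a fresh mutation."""
        rec = MutationRecord(
            id=self._next_id,
            position=position,
            s=s,
            h=h,
            h_haploid=h_haploid,
            origin_generation=origin_generation,
        )
        self._next_id += 1
        self.n_created += 1
        self.records[rec.id] = rec
        self.counts[rec.id] = 1
        return rec

    def position_of(self, mutation_id: int) -> int:
        return self.records[mutation_id].position

    def sort_key(self, mutation_id: int) -> tuple[int, int]:
        return (self.records[mutation_id].position, mutation_id)

    def drop(self, mutation_id: int) -> MutationRecord:
        self.counts.pop(mutation_id)
        return self.records.pop(mutation_id)

    def recount(self, population: "Population") -> dict[int, int]:
        """Brute-force recount of copy numbers over all non-null genomes."""
        counts: dict[int, int] = {}
        for ind in population.individuals():
            for g in ind.non_null_genomes():
                for mid in g.mutation_ids:
                    counts[mid] = counts.get(mid, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Population:
    """Fixed-census population: males, females, and the mutation registry."""

    mode: str
    males: list[Individual]
    females: list[Individual]
    registry: MutationRegistry = field(default_factory=MutationRegistry)
    generation: int = 0

    def individuals(self) -> Iterator[Individual]:
        yield from self.females
        yield from self.males

    @property
    def n_genome_copies(self) -> int:
        """Number of non-null genomes across the whole population."""
        return sum(ind.ploidy for ind in self.individuals())

    @classmethod
    def founders(cls, mode: str, n_males: int, n_females: int) -> "Population":
        """A mutation-free founding population of the requested censuses."""
        if mode not in (HAPLODIPLOID, DIPLOID):
            raise ValueError(f"unknown mode {mode!r}")
        females = [
            Individual(FEMALE, (Genome.empty(), Genome.empty()))
            for _ in range(n_females)
        ]
        if mode == HAPLODIPLOID:
            males = [
                Individual(MALE, (Genome.empty(), Genome.null()))
                for _ in range(n_males)
            ]
        else:
            males = [
                Individual(MALE, (Genome.empty(), Genome.empty()))
                for _ in range(n_males)
            ]
        return cls(mode=mode, males=males, females=females)


@dataclass(frozen=True)
class CensusSummary:
    """Chromosome accounting for a population.

    For a 1:1 sex ratio with N males and N females, a haplodiploid
    population carries 3N genome copies (1.5 per individual) against the
    diploid 4N (2 per individual); the expected mutation influx per
    generation, n_genome_copies × μ × L, is therefore 3NμL vs 4NμL.
    """

    n_individuals: int
    n_genome_copies: int
    expected_mutation_influx: Optional[float] = None


def census(population: Population, meiosis=None) -> CensusSummary:
    """Count individuals and non-null genome copies.

    If ``meiosis`` (a :class:`~haplosim.gametogenesis.MeiosisParams`) is
    given, also report the expected number of new mutations entering the
    population per generation, ``n_genome_copies * mu * L``.

    Raises :class:`ValidationError` if any individual is malformed for the
    population's mode.
    """
    violations = _individual_violations(population)
    if violations:
        raise ValidationError("; ".join(violations))
    n_ind = len(population.males) + len(population.females)
    n_copies = population.n_genome_copies
    influx = None
    if meiosis is not None:
        influx = n_copies * meiosis.mu * meiosis.L
    return CensusSummary(
        n_individuals=n_ind,
        n_genome_copies=n_copies,
        expected_mutation_influx=influx,
    )


def _individual_violations(population: Population) -> list[str]:
    out: list[str] = []
    for label, group, sex in (
        ("female", population.females, FEMALE),
        ("male", population.males, MALE),
    ):
        for i, ind in enumerate(group):
            name = f"{label}[{i}]"
            if ind.sex != sex:
                out.append(f"{name}: sex is {ind.sex!r}, expected {sex!r}")
            if len(ind.genomes) != 2:
                out.append(f"{name}: must have exactly 2 genome slots")
                continue
            n_real = ind.ploidy
            if population.mode == HAPLODIPLOID:
                want = 1 if sex == MALE else 2
            else:
                want = 2
            if n_real != want:
                out.append(
                    f"{name}: {n_real} non-null genomes, expected {want} "
                    f"in {population.mode} mode"
                )
            for j, g in enumerate(ind.genomes):
                if g.is_null and g.mutation_ids:
                    out.append(f"{name}: null genome slot {j} carries mutations")
                ids = g.mutation_ids
                if len(set(ids)) != len(ids):
                    out.append(f"{name}: genome slot {j} has duplicate mutation ids")
    return out


def validate_population(population: Population) -> list[str]:
    """Report every structural-invariant violation (never raises).

    Checks individual shape for the population's mode, genome sort order and
    duplicates, and registry copy counts against a brute-force recount.
    Returns an empty list iff the population is fully consistent.
    """
    out = _individual_violations(population)
    reg = population.registry
    for ind_label, ind in _labelled(population):
        for j, g in enumerate(ind.genomes):
            keys = []
            for mid in g.mutation_ids:
                if mid not in reg.records:
                    out.append(
                        f"{ind_label}: genome slot {j} carries unregistered id {mid}"
                    )
                else:
                    keys.append(reg.sort_key(mid))
            if keys != sorted(keys):
                out.append(
                    f"{ind_label}: genome slot {j} not sorted by (position, id)"
                )
    actual = reg.recount(population)
    for mid, rec in reg.records.items():
        stored = reg.counts.get(mid, 0)
        real = actual.get(mid, 0)
        if stored != real:
            out.append(
                f"mutation {mid}: registered copy_count {stored} != recount {real}"
            )
    for mid in actual:
        if mid not in reg.records:
            out.append(f"mutation {mid}: present in genomes but not registered")
    return out


def _labelled(population: Population):
    for i, ind in enumerate(population.females):
        yield f"female[{i}]", ind
    for i, ind in enumerate(population.males):
        yield f"male[{i}]", ind
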