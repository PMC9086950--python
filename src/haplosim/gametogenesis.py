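"""Meiosis: crossover recombination and de novo mutation.

The genetic map is flat: crossover count per meiosis is Poisson with mean
``r * (L - 1)`` (one opportunity between each adjacent locus pair), with
uniform integer breakpoints and no interference.  Haploid males do not
recombine — a father transmits a clonal copy of his single genome, which is
then subject to de novo mutation like every other transmitted gamete.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from .genome_core import Genome, MutationRecord, MutationRegistry

__all__ = [
    "MeiosisParams",
    "draw_crossovers",
    "recombine",
    "copy_genome",
    "draw_new_mutations",
    "apply_mutations",
]


@dataclass(frozen=True)
class MeiosisParams:
    """Genome length and per-locus mutation / recombination rates.

    L : genome length in loci (positions are 0-based in ``[0, L)``)
    mu : per-locus per-generation mutation rate
    r : per-adjacent-locus-pair per-generation recombination rate
    """

    L: int
    mu: float
    r: float

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mu and r must be non-negative")

    @property
    def expected_crossovers(self) -> float:
        return self.r * (self.L - 1)

    @property
    def expected_mutations(self) -> float:
        return self.mu * self.L


def draw_crossovers(rng: np.random.Generator, params: MeiosisParams) -> list[int]:
    """Draw sorted, duplicate-free crossover breakpoints for one meiosis.

    The count is Poisson(``r * (L - 1)``); breakpoints are uniform integers
    in ``[1, L)`` (a breakpoint at b separates loci ``< b`` from ``>= b``).
    Duplicate draws are re-drawn.
    """
    lam = params.expected_crossovers
    if lam == 0:
        return []
    n = rng.poisson(lam)
    if n == 0:
        return []
    while True:
        bps = sorted(int(b) for b in rng.integers(1, params.L, size=n))
        if all(bps[i] < bps[i + 1] for i in range(len(bps) - 1)):
            return bps


def recombine(
    genome_a: Genome,
    genome_b: Genome,
    breakpoints: list[int],
    start_strand: str,
    registry: MutationRegistry,
) -> Genome:
    """Build a recombinant gamete from two parental genomes.

    Segments between consecutive breakpoints are half-open
    ``[prev_bp, bp)``; the gamete copies the alternating strand, beginning
    with ``start_strand`` ('a' or 'b').  Both genomes must be non-null
    (haploid transmission uses :func:`copy_genome` instead).
    """
    if genome_a.is_null or genome_b.is_null:
        raise ValueError("cannot recombine with a null genome; use copy_genome")
    if start_strand not in ("a", "b"):
        raise ValueError("start_strand must be 'a' or 'b'")
    start = 0 if start_strand == "a" else 1
    out: list[int] = []
    for offset, genome in ((0, genome_a), (1, genome_b)):
        for mid in genome.mutation_ids:
            pos = registry.position_of(mid)
            segment = bisect.bisect_right(breakpoints, pos)
            if (segment + start + offset) % 2 == 0:
                out.append(mid)
    out.sort(key=registry.sort_key)
    return Genome(mutation_ids=out)


def copy_genome(genome: Genome) -> Genome:
    """Clonal copy of a haploid father's single genome (pre-mutation)."""
    if genome.is_null:
        raise ValueError("cannot transmit a null genome")
    return Genome(mutation_ids=list(genome.mutation_ids))


def draw_new_mutations(
    rng: np.random.Generator,
    params: MeiosisParams,
    s: float,
    h: float,
    generation: int,
    registry: MutationRegistry,
    h_haploid: float = 1.0,
) -> list[MutationRecord]:
    """Draw de novo mutations for one transmitted gamete.

    The count is Poisson(``mu * L``) with positions uniform on ``[0, L)``.
    Every event creates a fresh record with its own id (mutation stacking:
    records never collide even at an occupied position), registered with
    copy count 1.  ``s`` and ``h`` come from the treatment — a single
    mutation type per run.
    """
    lam = params.expected_mutations
    if lam == 0:
        return []
    n = rng.poisson(lam)
    if n == 0:
        return []
    positions = rng.integers(0, params.L, size=n)
    return [
        registry.new_record(
            position=int(p),
            s=s,
            h=h,
            h_haploid=h_haploid,
            origin_generation=generation,
        )
        for p in positions
    ]


def apply_mutations(
    gamete: Genome, new_records: list[MutationRecord], registry: MutationRegistry
) -> Genome:
    """Insert de novo mutations into a gamete, keeping (position, id) order."""
    for rec in new_records:
        key = (rec.position, rec.id)
        ids = gamete.mutation_ids
        lo = bisect.bisect_left([registry.sort_key(m) for m in ids], key)
        ids.insert(lo, rec.id)
    return gamete
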