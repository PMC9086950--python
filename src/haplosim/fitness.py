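"""Genotype-to-fitness mapping used as reproduction success.

Fitness is relative and multiplicative across mutations.  A hemizygous
(haploid) carrier expresses the full effect scaled by the haploid dominance
coefficient, which is 1 in all standard treatments — male carriers have
fitness ``1 + s``.  Diploid heterozygotes express ``1 + s*h``, homozygotes
``1 + s``.  Homozygosity is per mutation id: two distinct mutations at the
same position never form a homozygote.  The product is clamped below at 0
(reachable only for s < -1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genome_core import Individual, MutationRecord, MutationRegistry

__all__ = ["FitnessPolicy", "genotype_factor", "individual_fitness"]

HEMIZYGOUS = "hemizygous"
HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"


@dataclass(frozen=True)
class FitnessPolicy:
    """Combining rule: multiplicative across mutations, floor at 0.

    A mutation-free individual has fitness exactly 1 (empty product).
    """

    haploid_dominance: float = 1.0


def genotype_factor(mut: MutationRecord, zygosity: str) -> float:
    """Fitness multiplier contributed by one mutation at a given zygosity."""
    if zygosity == HEMIZYGOUS:
        return 1.0 + mut.s * mut.h_haploid
    if zygosity == HETEROZYGOUS:
        return 1.0 + mut.s * mut.h
    if zygosity == HOMOZYGOUS:
        return 1.0 + mut.s
    raise ValueError(f"unknown zygosity {zygosity!r}")


def individual_fitness(ind: Individual, registry: MutationRegistry) -> float:
    """Relative fitness: product of per-mutation factors, clamped at 0.

    Zygosity per id: present in both non-null genomes -> homozygous; in one
    of two non-null genomes -> heterozygous; in the sole non-null genome of
    a haploid -> hemizygous.
    """
    real = ind.non_null_genomes()
    w = 1.0
    if len(real) == 1:
        for mid in real[0].mutation_ids:
            w *= genotype_factor(registry.records[mid], HEMIZYGOUS)
    else:
        tally: Counter[int] = Counter(real[0].mutation_ids)
        tally.update(real[1].mutation_ids)
        for mid, n in tally.items():
            zyg = HOMOZYGOUS if n == 2 else HETEROZYGOUS
            w *= genotype_factor(registry.records[mid], zyg)
    return max(w, 0.0)
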