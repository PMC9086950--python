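"""Fixation/loss bookkeeping, per-generation time series, and TSV output.

A mutation is *fixed* (a substitution) once its copy count equals the
census number of non-null genome copies — in a haplodiploid population,
present twice in every female and once in every male.  Fixed mutations are
purged from genomes and registry (relative fitness ranking is unaffected by
removing a factor shared by every individual within each sex) and appended
to the substitution log; lost mutations (copy count 0) are purged silently.
Fixation is checked once per generation, after reproduction, and attributed
to that generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .genome_core import Population

__all__ = [
    "SimulationResult",
    "classify_and_purge",
    "summarize",
    "PER_GENERATION_COLUMNS",
    "SUBSTITUTION_COLUMNS",
]

PER_GENERATION_COLUMNS = [
    "generation",
    "substitutions_this_gen",
    "cumulative_substitutions",
    "segregating_count",
    "mean_fitness_females",
    "mean_fitness_males",
]

SUBSTITUTION_COLUMNS = [
    "mutation_id",
    "position",
    "s",
    "h",
    "origin_generation",
    "fixation_generation",
]


@dataclass
class SimulationResult:
    """Per-generation time series plus the substitution log for one run."""

    per_generation: pd.DataFrame
    substitution_log: pd.DataFrame
    config: "SimulationConfig"
    final_population: Optional[Population] = None
    n_mutations_created: int = 0

    @classmethod
    def from_rows(cls, config, rows, log, final_population=None, n_mutations_created=0):
        per_gen = pd.DataFrame(
            rows,
            columns=[
                "generation",
                "substitutions_this_gen",
                "segregating_count",
                "mean_fitness_females",
                "mean_fitness_males",
            ],
        )
        per_gen["cumulative_substitutions"] = per_gen["substitutions_this_gen"].cumsum()
        per_gen = per_gen[PER_GENERATION_COLUMNS]
        sub_log = pd.DataFrame(log, columns=SUBSTITUTION_COLUMNS)
        return cls(
            per_generation=per_gen,
            substitution_log=sub_log,
            config=config,
            final_population=final_population,
            n_mutations_created=n_mutations_created,
        )

    # -- window helpers -------------------------------------------------
    def recorded_window(self) -> pd.DataFrame:
        return self.per_generation[
            self.per_generation["generation"] > self.config.burn_in
        ]

    def total_fixations(self, window: str = "recorded") -> int:
        frame = self.recorded_window() if window == "recorded" else self.per_generation
        return int(frame["substitutions_this_gen"].sum())

    # -- serialization --------------------------------------------------
    def write_tsv(self, out_dir) -> None:
        """Write timeseries.tsv and substitutions.tsv (tab-separated)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_generation.to_csv(out / "timeseries.tsv", sep="\t", index=False)
        self.substitution_log.to_csv(out / "substitutions.tsv", sep="\t", index=False)


def classify_and_purge(pop: Population, log: Optional[list] = None) -> tuple[int, int]:
    """Detect fixation and loss on the object model; purge both.

    Appends ``(id, position, s, h, origin_generation, fixation_generation)``
    for each new substitution to ``log`` when given.  Returns
    ``(n_fixed_now, n_lost_now)``.
    """
    reg = pop.registry
    n_copies = pop.n_genome_copies
    fixed, lost = [], []
    for mid, count in reg.counts.items():
        if count > n_copies:
            raise RuntimeError(
                f"mutation {mid}: copy_count {count} exceeds census {n_copies}"
            )
        if count == n_copies:
            fixed.append(mid)
        elif count == 0:
            lost.append(mid)
    if fixed:
        fixed_set = set(fixed)
        for ind in pop.individuals():
            for g in ind.non_null_genomes():
                g.mutation_ids = [m for m in g.mutation_ids if m not in fixed_set]
        for mid in fixed:
            rec = reg.drop(mid)
            if log is not None:
                log.append(
                    (rec.id, rec.position, rec.s, rec.h,
                     rec.origin_generation, pop.generation)
                )
    for mid in lost:
        reg.drop(mid)
    return len(fixed), len(lost)


def summarize(result: SimulationResult, window: str = "recorded") -> dict:
    """Headline numbers for one run.

    ``fixations_per_generation`` is total substitutions in the window over
    the window length; under neutrality it converges to the genome-wide
    mutation rate mu*L in both inheritance modes.
    """
    if window == "recorded":
        frame = result.recorded_window()
    elif window == "all":
        frame = result.per_generation
    else:
        raise ValueError("window must be 'recorded' or 'all'")
    n = len(frame)
    if n == 0:
        raise ValueError(f"window {window!r} is empty")
    total = int(frame["substitutions_this_gen"].sum())
    return {
        "window": window,
        "window_length": n,
        "total_fixations": total,
        "fixations_per_generation": total / n,
        "final_segregating": int(frame["segregating_count"].iloc[-1]),
    }
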