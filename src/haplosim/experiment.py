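"""Treatment grids, replicate comparisons, and file output.

Reproduces the experimental design used to compare mutation fates between
haplodiploid and diploid populations: a grid of (s, h) treatments, many
replicate runs per arm, and a Wilcoxon rank-sum comparison of fixation
counts between the two inheritance modes.  Arms may be paired at equal
numbers of *individuals* (the standard design: the haplodiploid arm then
carries 1.5N genome copies against the diploid 2N) or at equal numbers of
*chromosomes* (the diploid census is shrunk so both arms carry the same
number of genome copies, isolating selection efficacy from mutation
influx).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gametogenesis import MeiosisParams
from .genome_core import DIPLOID, HAPLODIPLOID, Population
from .lifecycle import SimulationConfig, run_simulation

__all__ = [
    "Treatment",
    "TreatmentGrid",
    "CompareResult",
    "run_grid",
    "diploid_census_for_pairing",
    "compare_population_types",
    "exact_rank_sum_test",
    "normal_approx_rank_sum_test",
    "export_vcf",
    "figure1_scaled_preset",
    "figure1_full_preset",
    "equal_chromosomes_scaled_preset",
    "PRESETS",
]

EQUAL_INDIVIDUALS = "equal_individuals"
EQUAL_CHROMOSOMES = "equal_chromosomes"

# refuse grids above this many offspring-generations without the
# acknowledge flag (full-scale grids are hours to days of compute)
_GUARD_OFFSPRING_GENERATIONS = 2e9


@dataclass(frozen=True)
class Treatment:
    label: str
    s: float
    h: float


@dataclass
class TreatmentGrid:
    treatments: list[Treatment]
    replicates: int
    base_seed: int
    census_pairing: str = EQUAL_INDIVIDUALS
    modes: tuple = (HAPLODIPLOID, DIPLOID)


def replicate_seed(base_seed: int, label: str, mode: str, replicate: int) -> int:
    """Deterministic per-replicate seed: base_seed offset by a stable hash."""
    digest = zlib.crc32(f"{label}|{mode}|{replicate}".encode())
    return (base_seed + digest) % (2**31)


def diploid_census_for_pairing(Nm: int, Nf: int, pairing: str) -> tuple[int, int]:
    """Diploid-arm census matched to a haplodiploid arm of (Nm, Nf).

    equal_individuals keeps the census; equal_chromosomes solves
    ``2(Nm' + Nf') = 2*Nf + Nm`` at a 1:1 sex ratio (a haplodiploid
    1000 males + 1000 females carries 3000 genomes, matching a diploid
    750 + 750).
    """
    if pairing == EQUAL_INDIVIDUALS:
        return Nm, Nf
    if pairing != EQUAL_CHROMOSOMES:
        raise ValueError(f"unknown census pairing {pairing!r}")
    copies = 2 * Nf + Nm
    if copies % 4:
        raise ValueError(
            f"haplodiploid census {Nm}+{Nf} carries {copies} genomes, "
            "not matchable by an equal-sex-ratio diploid census"
        )
    n = copies // 4
    return n, n


def run_grid(
    grid: TreatmentGrid,
    template: SimulationConfig,
    acknowledge_long_run: bool = False,
    progress: bool = False,
) -> pd.DataFrame:
    """One run per (treatment, mode, replicate).

    ``template`` supplies censuses (interpreted as the haplodiploid arm),
    meiosis parameters and generation counts; its s, h and seed are
    overridden per run.  Returns one row per run with the total number of
    fixations in the recorded window.
    """
    arms = []
    for treatment, mode in itertools.product(grid.treatments, grid.modes):
        if mode == HAPLODIPLOID:
            nm, nf = template.Nm, template.Nf
        else:
            nm, nf = diploid_census_for_pairing(
                template.Nm, template.Nf, grid.census_pairing
            )
        arms.append((treatment, mode, nm, nf))

    cost = sum(
        (nm + nf) * template.total_generations * grid.replicates
        for (_, _, nm, nf) in arms
    )
    if cost > _GUARD_OFFSPRING_GENERATIONS and not acknowledge_long_run:
        raise RuntimeError(
            f"grid would simulate ~{cost:.2g} offspring-generations "
            "(hours to days); pass acknowledge_long_run=True to proceed"
        )

    rows = []
    for treatment, mode, nm, nf in arms:
        for rep in range(grid.replicates):
            seed = replicate_seed(grid.base_seed, treatment.label, mode, rep)
            config = replace(
                template, mode=mode, Nm=nm, Nf=nf,
                s=treatment.s, h=treatment.h, seed=seed,
            )
            result = run_simulation(config)
            rows.append(
                {
                    "treatment": treatment.label,
                    "s": treatment.s,
                    "h": treatment.h,
                    "mode": mode,
                    "Nm": nm,
                    "Nf": nf,
                    "replicate": rep,
                    "seed": seed,
                    "total_fixations": result.total_fixations("recorded"),
                }
            )
            if progress:
                print(
                    f"[grid] {treatment.label} {mode} replicate {rep}: "
                    f"{rows[-1]['total_fixations']} fixations"
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompareResult:
    statistic: float  # rank sum of the haplodiploid sample
    p_value: float
    mean_difference: float  # mean(hap) - mean(dip)
    method: str


def exact_rank_sum_test(
    x, y, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Exact rank-sum test by full enumeration of group assignments.

    Enumerates every way the pooled observations could have been split
    into groups of the observed sizes and compares the rank sum of the
    first group against the permutation distribution (average ranks under
    ties; two-sided p doubles the smaller tail, capped at 1).  Intended
    for small samples (min group size <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)]
    )
    eps = 1e-9
    p_ge = np.mean(sums >= w_obs - eps)
    p_le = np.mean(sums <= w_obs + eps)
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w_obs, float(p)


def normal_approx_rank_sum_test(
    x, y, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Rank-sum test by normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="asymptotic", use_continuity=True
    )
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U1 -> rank sum
    return w, float(res.pvalue)


def compare_population_types(
    fixations_hap, fixations_dip, alternative: str = "two-sided"
) -> CompareResult:
    """Wilcoxon rank-sum comparison of fixation counts between modes.

    Uses exact enumeration when either group has <= 8 replicates and the
    normal approximation (with tie correction) otherwise.  The mean
    difference is haplodiploid minus diploid.
    """
    x = np.asarray(fixations_hap, dtype=float)
    y = np.asarray(fixations_dip, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if min(len(x), len(y)) <= 8:
        w, p = exact_rank_sum_test(x, y, alternative)
        method = "exact"
    else:
        w, p = normal_approx_rank_sum_test(x, y, alternative)
        method = "normal_approx"
    return CompareResult(
        statistic=w,
        p_value=p,
        mean_difference=float(x.mean() - y.mean()),
        method=method,
    )


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------


def export_vcf(pop: Population, path, L: int | None = None) -> None:
    """Write segregating variants as VCF 4.2.

    One record per segregating mutation (positions converted to 1-based),
    one sample column per individual.  Haplodiploid males are emitted as
    haploid genotypes ("0"/"1"); females and diploids as unphased diploid
    genotypes.  INFO carries S, H and ORIGIN (origin generation).
    """
    reg = pop.registry
    segregating = sorted(
        (mid for mid, c in reg.counts.items() if c > 0),
        key=reg.sort_key,
    )
    if L is None:
        L = 1 + max((reg.records[m].position for m in segregating), default=0)
    females = [(f"F{i}", ind) for i, ind in enumerate(pop.females)]
    males = [(f"M{i}", ind) for i, ind in enumerate(pop.males)]
    samples = females + males

    lines = [
        "##fileformat=VCFv4.2",
        "##source=haplosim",
        f"##contig=<ID=1,length={L}>",
        '##INFO=<ID=S,Number=1,Type=Float,Description="Selection coefficient">',
        '##INFO=<ID=H,Number=1,Type=Float,Description="Dominance coefficient">',
        '##INFO=<ID=ORIGIN,Number=1,Type=Integer,Description="Origin generation">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(name for name, _ in samples),
    ]
    for mid in segregating:
        rec = reg.records[mid]
        gts = []
        for _, ind in samples:
            real = ind.non_null_genomes()
            if len(real) == 1:
                gts.append("1" if mid in real[0].mutation_ids else "0")
            else:
                a = int(mid in real[0].mutation_ids)
                b = int(mid in real[1].mutation_ids)
                gts.append(f"{min(a, b)}/{max(a, b)}")
        info = f"S={rec.s:g};H={rec.h:g};ORIGIN={rec.origin_generation}"
        lines.append(
            f"1\t{rec.position + 1}\tmut{rec.id}\tA\tT\t.\tPASS\t{info}\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def figure1_scaled_preset(base_seed: int = 0) -> tuple[TreatmentGrid, SimulationConfig]:
    """Scaled-down selection-efficacy design.

    100 males + 100 females per arm, L = 2e3 loci at mu = 1e-6 (raised so
    fixation counts give the rank-sum test power at this census), map
    length ~1 crossover per meiosis, 2,000 burn-in + 8,000 recorded
    generations, 50 replicates per arm.  Advantageous mutations (s = 0.01)
    fully recessive vs fully dominant.
    """
    L = 2_000
    grid = TreatmentGrid(
        treatments=[
            Treatment("recessive_advantageous", s=0.01, h=0.0),
            Treatment("dominant_advantageous", s=0.01, h=1.0),
        ],
        replicates=50,
        base_seed=base_seed,
        census_pairing=EQUAL_INDIVIDUALS,
    )
    template = SimulationConfig(
        mode=HAPLODIPLOID, Nm=100, Nf=100,
        meiosis=MeiosisParams(L=L, mu=1e-6, r=1.0 / (L - 1)),
        s=0.01, h=0.0, burn_in=2_000, run_generations=8_000, seed=base_seed,
    )
    return grid, template


def equal_chromosomes_scaled_preset(
    base_seed: int = 0,
) -> tuple[TreatmentGrid, SimulationConfig]:
    """Scaled equal-chromosome design: both arms carry 300 genome copies
    (haplodiploid 100+100 vs diploid 75+75); the haplodiploid advantage for
    advantageous mutations should grow as h decreases."""
    grid, template = figure1_scaled_preset(base_seed)
    grid.census_pairing = EQUAL_CHROMOSOMES
    grid.treatments = [
        Treatment("recessive_advantageous", s=0.01, h=0.0),
        Treatment("intermediate_advantageous", s=0.01, h=0.5),
    ]
    return grid, template


def figure1_full_preset(base_seed: int = 0) -> tuple[TreatmentGrid, SimulationConfig]:
    """Full-scale design: 200 replicates of 1,000 males + 1,000 females,
    L = 1e6 loci, mu = 1e-8, r = 1e-6, 15,000 burn-in + 35,000 recorded
    generations.  Treatments: neutral; advantageous and deleterious
    recessive mutations over a log-spaced s grid (the printed values
    s = -0.003 and s = -0.01 included); dominance sweep at s = 0.001.
    Requires ``acknowledge_long_run=True`` — this is days of compute.
    """
    treatments = [Treatment("neutral", s=0.0, h=0.0)]
    for s in (0.0001, 0.0003, 0.001, 0.003, 0.01):
        treatments.append(Treatment(f"advantageous_s{s:g}", s=s, h=0.0))
    for s in (-0.0001, -0.0003, -0.001, -0.003, -0.01):
        treatments.append(Treatment(f"deleterious_s{s:g}", s=s, h=0.0))
    for h in (0.0, 0.25, 0.5, 0.75, 1.0):
        treatments.append(Treatment(f"dominance_h{h:g}", s=0.001, h=h))
    grid = TreatmentGrid(
        treatments=treatments,
        replicates=200,
        base_seed=base_seed,
        census_pairing=EQUAL_INDIVIDUALS,
    )
    template = SimulationConfig(
        mode=HAPLODIPLOID, Nm=1_000, Nf=1_000,
        meiosis=MeiosisParams(L=1_000_000, mu=1e-8, r=1e-6),
        s=0.0, h=0.0, burn_in=15_000, run_generations=35_000, seed=base_seed,
    )
    return grid, template


PRESETS = {
    "figure1_scaled": figure1_scaled_preset,
    "figure1_full": figure1_full_preset,
    "equal_chromosomes_scaled": equal_chromosomes_scaled_preset,
}
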