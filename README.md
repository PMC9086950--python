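# haplosim

Individual-based, forward-in-time simulation of genome evolution in
**haplodiploid** organisms — ants, bees, wasps, thrips, bark beetles —
alongside a matched diploid model, so that the fates of neutral,
advantageous, and deleterious mutations can be compared between the two
inheritance systems.

In haplodiploid species, unfertilized (haploid) eggs develop into males and
fertilized (diploid) eggs into females.  Sons therefore inherit a single
recombined genome from their mother and nothing from a father; the missing
second chromosome set is modeled as an empty *null genome*.  A mutation
with selection coefficient *s* and dominance *h* contributes fitness
factors

* 1 + *s* in homozygotes,
* 1 + *s·h* in diploid heterozygotes,
* 1 + *s* in hemizygous (haploid) males (haploid dominance fixed at 1),

multiplicatively across loci, and fitness acts as reproduction success:
each offspring's mother and father are drawn within their sex with
probability proportional to fitness, in non-overlapping generations at a
hard census.  Recessive mutations are thus fully exposed to selection in
haploid males but masked in heterozygous diploid males, while a
haplodiploid population at equal census carries fewer genome copies than a
diploid one (1.5*N* vs 2*N* at a 1:1 sex ratio) and so receives fewer new
mutations per generation (1.5*Nμ* vs 2*Nμ* per locus).

The package is aimed at population geneticists who want a haplodiploidy-
aware null model for interpreting genome scans or exploring selection
efficacy: it provides the simulator (`run_simulation`, with a readable
pure-Python reference implementation and a fast compiled engine), an exact
Markov-chain oracle for tiny censuses (`markov_oracle`), treatment grids
with Wilcoxon rank-sum comparisons (`experiment`), TSV time series, and
VCF export of segregating variants.  See `docs/methods.md` for the full
model description.

## Worked example

One haplodiploid run at a small census — 20 males + 20 females, 10⁴ loci,
μ = 10⁻⁶ per locus (genome-wide mutation rate μL = 0.01 per gamete per
generation), 100 burn-in + 500 recorded generations:

```bash
haplosim simulate --mode haplodiploid --males 20 --females 20 \
    --loci 10000 --mu 1e-6 --recomb 1e-4 --s 0 --h 0 \
    --generations 500 --burnin 100 --seed 3 --out runs/demo
```

prints

```json
{
  "window": "recorded",
  "window_length": 500,
  "total_fixations": 6,
  "fixations_per_generation": 0.012,
  "final_segregating": 6
}
```

Six neutral substitutions in 500 recorded generations — a rate of 0.012
per generation, matching the neutral expectation that the substitution
rate equals the genome-wide mutation rate μL = 0.01 regardless of census
or inheritance system (the residual is Poisson noise on 6 counts).
`runs/demo/` contains the per-generation time series, the substitution
log, and the config echo.

The exact oracle makes the headline selection asymmetry visible at a
six-individual census:

```bash
haplosim oracle --males 3 --females 3 --s 0 --s 0.05 --h 0
```

| mode | s | h | fixation probability (copy in a female genome) |
|---|---|---|---|
| haplodiploid | 0 | 0 | 0.1111 (= 1/3N) |
| diploid | 0 | 0 | 0.0833 (= 1/4N) |
| haplodiploid | 0.05 | 0 | 0.1282 |
| diploid | 0.05 | 0 | 0.0930 |

Neutral copies fix with probability one over the number of genome copies;
for an advantageous *recessive* mutation the haplodiploid advantage
(0.1282/0.0930 ≈ 1.38) exceeds the neutral census ratio (4/3), because
selection sees the mutation in every hemizygous male.

Other subcommands: `haplosim grid` (replicated treatment grids;
`--preset figure1_full` reproduces the full-scale design behind
`--acknowledge-long-run`), `haplosim compare` (rank-sum comparison of two
results tables), `haplosim export-vcf` (VCF 4.2 of segregating variants,
haploid males as single-allele genotypes).

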