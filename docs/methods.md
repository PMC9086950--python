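# Methods

## The model

`haplosim` is an individual-based, forward-in-time simulator of genome
evolution under two inheritance systems:

* **Haplodiploid** (arrhenotokous): males develop from unfertilized eggs and
  are haploid; females develop from fertilized eggs and are diploid.  A male
  is represented as an individual whose second genome slot is a *null
  genome* — an empty placeholder that never carries mutations and never
  recombines.  A daughter unites a recombined maternal gamete with a clonal
  copy of her father's single genome; a son receives one recombined maternal
  gamete and no paternal contribution at all.
* **Diploid** (the matched control): both sexes are diploid and every
  offspring unites one recombined gamete from each parent.

Generations are non-overlapping with a hard census: exactly `Nf` daughters
and `Nm` sons every generation.  Fitness acts through reproduction success —
for each offspring, the mother is drawn from the females with probability
proportional to fitness, with replacement, and the father likewise from the
males (soft selection; absolute fitness never changes the census).  With a
fixed census and independent weighted draws this behaves like a
Wright–Fisher model with separate sexes.

The central biological asymmetry: a recessive mutation (dominance `h = 0`)
is invisible to selection in a heterozygous diploid but fully exposed in a
hemizygous haploid male.  Selection on (partially) recessive mutations is
therefore more effective under haplodiploidy.  Pulling the other way, a
haplodiploid population at the same census carries fewer genome copies —
1.5 per individual against the diploid 2 (3N vs 4N at a 1:1 sex ratio with
N per sex) — so fewer mutations enter it each generation (1.5Nμ vs 2Nμ per
locus), and fewer can ultimately fix.  Which force wins depends on `h`:
haplodiploids fix more advantageous mutations when `h` is low and fewer
when `h` is high.  The `equal_chromosomes` census pairing isolates the
efficacy effect by shrinking the diploid census so both arms carry the same
number of genome copies (e.g. haplodiploid 1000♂+1000♀ = 3000 genomes vs
diploid 750♂+750♀).

## Genetics

* **Genomes** are sparse: sorted collections of mutation identifiers
  relative to a mutation-free ancestral reference, on a single linear
  chromosome of `L` loci indexed `0..L-1` (VCF export converts to 1-based).
* **Mutation**: every transmitted gamete — including a father's clonal
  copy — receives a Poisson(`μL`) number of de novo mutations at uniform
  positions.  Each event is a fresh record with its own identity; two
  mutations at the same position stack rather than collide, and
  homozygosity is defined per identity, never per position.  A run uses a
  single mutation type `(s, h)`.
* **Recombination**: crossover counts are Poisson(`r·(L−1)`) per meiosis
  with uniform integer breakpoints, no interference, and a fair choice of
  starting strand; segments are half-open `[prev_bp, bp)`.  Haploid males
  do not recombine — there is nothing to recombine with a null genome.
* **Fitness**: multiplicative across mutations; per-mutation factors are
  `1 + s` (homozygote), `1 + s·h` (heterozygote), `1 + s·h_haploid`
  (hemizygote), with the haploid dominance coefficient fixed at 1 in all
  standard treatments so male carriers have fitness `1 + s`.  A
  mutation-free individual has fitness exactly 1; products clamp at 0
  (reachable only for `s < −1`).
* **Fixation**: checked once per generation, after reproduction.  A
  mutation is fixed when its copy count equals the census number of
  non-null genome copies; it is then logged as a substitution and purged
  from genomes and registry.  Purging a shared factor cannot change
  fitness *ranking* within a sex, and parents are only ever compared
  within their sex, so the purge is selectively neutral bookkeeping.
  Mutations arising in burn-in but fixing afterwards count in the recorded
  window (the window of a substitution is the window of its fixation
  generation).

Under neutrality these rules give the classical substitution-rate law: per
generation, `3NμL` mutations enter a haplodiploid population and each fixes
with probability `1/(3N)` (respectively `4NμL` and `1/(4N)` for diploids),
so both population types substitute `μL` mutations per generation — 0.01
at the standard `μ = 10⁻⁸`, `L = 10⁶`.

## Two engines, one law

The generation step is implemented twice:

* a pure-Python **object model** (`lifecycle.next_generation`) written for
  clarity, used by the structural-invariant tests and tiny populations;
* a compiled **array engine** (`_engine`, numba) holding each generation's
  genomes in a CSR layout, used by `run_simulation` for anything long.

Both are deterministic given `(config, seed)` but use distinct random
streams, so they agree in distribution rather than draw-for-draw.  The test
suite bridges them distributionally (neutral single-copy fixation
frequencies at a tiny census) and holds the compiled engine to the exact
Markov chain at high replication.

## The exact oracle

`markov_oracle` builds the finite Markov chain of the single-locus model at
tiny censuses and solves absorption probabilities by a dense linear solve.
Because parent draws are independent given the parental genotype
composition, and the allele count alone does not determine that composition,
the chain state is genotype-resolved: `(n_hom_females, n_het_females,
n_carrier_males)` for haplodiploids and `(n_hom_f, n_het_f, n_hom_m,
n_het_m)` for diploids.  Offspring transitions are multinomial over
genotype classes (daughters) and binomial/multinomial (sons), with maternal
transmission probability weighted by female genotype fitnesses and
analogously for fathers.  The oracle deliberately mirrors the lifecycle's
parent-sampling scheme; any change there must be mirrored here.  Allele-
count initial conditions are mapped heterozygote-first onto genotypes.
Transition rows sum to 1 within 1e-12; absorption probabilities come from
solving `(I − Q)u = R` exactly, and the neutral closed forms `1/(3N)` and
`1/(4N)` are reproduced to 1e-10.

## Parameters and presets

| parameter | meaning | full-scale default |
|---|---|---|
| `Nm`, `Nf` | census per sex | 1,000 each |
| `L` | loci per genome | 10⁶ |
| `μ` | per-locus mutation rate / generation | 10⁻⁸ |
| `r` | per-adjacent-pair recombination rate | 10⁻⁶ (~1 crossover/meiosis) |
| `s` | selection coefficient | treatment |
| `h` | diploid dominance coefficient | treatment |
| `h_haploid` | hemizygous dominance | 1 |
| burn-in | generations excluded from reporting | 15,000 |
| recorded | generations reported | 35,000 |

The burn-in exists because the two population types have different
effective sizes and reach mutation–drift balance at different times;
starting from a mutation-free population, reported statistics begin only
after the segregating pool has equilibrated.

**Scaled presets.**  The full-scale design (200 replicates per treatment of
the configuration above) is hours-to-days of compute and sits behind an
explicit `--acknowledge-long-run` flag.  The shipped desk-scale presets
were sized once, from power and runtime analysis, and are the package's
standard test conditions:

* *Neutral-rate check*: `Nm = Nf = 50`, full-scale genome (`L = 10⁶`,
  `μ = 10⁻⁸`, `r = 10⁻⁶`), 5,000 + 20,000 generations — expected 200
  neutral fixations per run, so a single run pins the rate within ~7%.
* *`figure1_scaled`*: `Nm = Nf = 100`, `μ = 10⁻⁶`, `L = 2,000`
  (`μL = 0.002`), `r = 1/(L−1)` to keep ~1 crossover per meiosis,
  2,000 + 8,000 generations, 50 replicates per arm, `s = 0.01` at `h = 0`
  and `h = 1`.  The raised per-locus `μ` keeps per-run fixation counts in
  the tens despite the small genome; a 15-replicate pilot puts the
  between-mode effects at ~2–2.7 within-arm standard deviations, so the
  one-sided rank-sum tests at 50 replicates have overwhelming power.
* *`equal_chromosomes_scaled`*: as above with the diploid arm at 75♂+75♀
  (300 genome copies in both arms) and `h ∈ {0, 0.5}`.

## Statistics

Replicate fixation counts between modes are compared with the two-sample
Wilcoxon rank-sum test: exact enumeration of all group assignments
(average ranks under ties; two-sided p doubles the smaller tail) when a
group has ≤ 8 replicates, and the normal approximation with tie correction
(scipy's `mannwhitneyu`, asymptotic) otherwise.  The exact enumerator is
kept in-repo and doubles as the test oracle for the asymptotic path; the
two agree within 0.01 at n = 8 in the decision-relevant range (the
worst-case discrepancy over the whole distribution, ~0.011, sits at
p ≈ 0.45 where nothing is decided).

## What the synthetic conditions do and do not show

All inputs are simulated; there is no external data.  The model emulates a
single panmictic population with discrete generations, an even and fixed
sex ratio, one linear chromosome with a flat genetic map, a single mutation
type per run, and multiplicative fitness.  It does not emulate demographic
structure or migration, overlapping generations or age structure, variable
recombination maps, sex-specific selection, epistasis, or the social
structure of real hymenopteran colonies.  Passing tests therefore show that
the inheritance machinery, the fitness asymmetry between hemizygous and
heterozygous carriers, and the chromosome accounting behave exactly as the
population-genetic theory of haplodiploidy predicts — not that any
particular natural population evolves at these rates.

## Numerical choices and edge cases

* All randomness in a run flows from one seeded generator (compiled engine:
  a single `np.random.seed` derived from the config seed via
  `SeedSequence`), so runs are bit-reproducible; replicate seeds in grids
  are `base_seed` offset by a CRC32 hash of (treatment, mode, replicate),
  kept below 2³¹.
* Crossover breakpoints are drawn uniform in `[1, L)` and re-drawn wholesale
  on duplicates; positions of ties in genome ordering break by mutation id.
* If every individual of one sex has fitness 0 (only reachable at
  `s ≤ −1`), the step raises a population-extinction error rather than
  dividing by zero.
* The oracle refuses state spaces above 10⁴ states; absorption solves are
  exact (LAPACK dense solve), no iteration or tolerance tuning.
* An empty summary window (`run_generations = 0`) is an error, not a NaN.

## Known limitations

* Mean fitness is logged per sex for the breeding adults of each
  generation (cross-sex fitness is never compared because parents are
  sampled within sex).
* The substitution log stores `(id, position, s, h, origin, fixation)`
  only; site-frequency spectra and diversity statistics (π, Watterson's θ)
  are easy extensions but not implemented.
* Whether a real implementation should mutate a father's clonal gamete is
  a modeling choice; here *every* transmitted genome mutates, which keeps
  the per-genome mutation process uniform and gives the clean `3NμL`/`4NμL`
  influx accounting.
* VCF export writes one biallelic record per mutation identity (A→T
  placeholder alleles); two stacked mutations at one position produce two
  records at the same POS.
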