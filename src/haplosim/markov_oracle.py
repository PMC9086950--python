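"""Exact single-locus fixation probabilities for tiny censuses.

This is the brute-force validation oracle for the simulator: a finite
Markov chain whose one-generation transition law matches the lifecycle
module exactly in distribution.  Parent sampling there is independent and
fitness-proportional with replacement, so given the parental *genotype
composition* every offspring is i.i.d.; daughters are multinomial over
genotype classes and sons binomial (haplodiploid) or multinomial (diploid).

The allele copy count alone does not determine the transition law — how
the copies are arranged into homozygous and heterozygous females changes
both the fitness weighting and the transmission probability — so the chain
state is genotype-resolved:

* haplodiploid: ``(n_hom_females, n_het_females, n_carrier_males)``
* diploid: ``(n_hom_f, n_het_f, n_hom_m, n_het_m)``

Genotype fitnesses are 1, 1+s*h, 1+s for diploids and 1, 1+s*h_haploid for
haploid males (h_haploid = 1 in all standard treatments).  Any change to
the lifecycle's parent-sampling scheme must be mirrored here — that
coupling is the point of the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .genome_core import DIPLOID, HAPLODIPLOID

__all__ = [
    "AlleleState",
    "MarkovChain",
    "build_chain",
    "fixation_probability",
    "single_copy_fixation_probability",
    "oracle_table",
]

MAX_STATES = 10_000


@dataclass(frozen=True)
class AlleleState:
    """Allele copy counts: ``i_f`` among female genomes, ``i_m`` among male
    genomes.  Mapped onto a genotype-resolved state heterozygote-first
    (copies pair into homozygotes only once every female is a carrier)."""

    i_f: int
    i_m: int


@dataclass
class MarkovChain:
    mode: str
    Nm: int
    Nf: int
    s: float
    h: float
    h_haploid: float
    states: list[tuple]
    index: dict[tuple, int]
    T: np.ndarray  # dense one-generation transition matrix
    loss_state: tuple
    fix_state: tuple


def _clamp(w: float) -> float:
    return w if w > 0.0 else 0.0


def _multinomial_pmf_table(n: int, q: tuple[float, float, float]) -> np.ndarray:
    """P(a, b) for a hom, b het, n-a-b wild offspring out of n draws."""
    q0, q1, q2 = q
    out = np.zeros((n + 1, n + 1))
    lg = gammaln(np.arange(n + 2))
    for a in range(n + 1):
        for b in range(n - a + 1):
            c = n - a - b
            logp = (
                lg[n + 1] - lg[a + 1] - lg[b + 1] - lg[c + 1]
                + xlogy(a, q0) + xlogy(b, q1) + xlogy(c, q2)
            )
            out[a, b] = np.exp(logp)
    return out


def _binom_pmf(n: int, p: float) -> np.ndarray:
    lg = gammaln(np.arange(n + 2))
    k = np.arange(n + 1)
    return np.exp(lg[n + 1] - lg[k + 1] - lg[n - k + 1] + xlogy(k, p) + xlogy(n - k, 1 - p))


def _offspring_genotype_probs(pm: float, pp: float) -> tuple[float, float, float]:
    # random union of one maternal and one paternal gamete
    q_hom = pm * pp
    q_het = pm * (1 - pp) + (1 - pm) * pp
    return (q_hom, q_het, 1.0 - q_hom - q_het)


def build_chain(
    mode: str, Nm: int, Nf: int, s: float, h: float, h_haploid: float = 1.0
) -> MarkovChain:
    """Enumerate the genotype-resolved state space and its transition matrix."""
    if mode not in (HAPLODIPLOID, DIPLOID):
        raise ValueError(f"unknown mode {mode!r}")

    female_states = [(a, b) for a in range(Nf + 1) for b in range(Nf - a + 1)]
    if mode == HAPLODIPLOID:
        male_states: list = list(range(Nm + 1))
        states = [(a, b, m) for (a, b) in female_states for m in male_states]
        loss, fix = (0, 0, 0), (Nf, 0, Nm)
    else:
        male_states = [(a, b) for a in range(Nm + 1) for b in range(Nm - a + 1)]
        states = [
            (af, bf, am, bm)
            for (af, bf) in female_states
            for (am, bm) in male_states
        ]
        loss, fix = (0, 0, 0, 0), (Nf, 0, Nm, 0)
    n = len(states)
    if n > MAX_STATES:
        raise ValueError(f"state space of size {n} exceeds {MAX_STATES}")
    index = {st: i for i, st in enumerate(states)}

    w_hom, w_het, w_wild = _clamp(1.0 + s), _clamp(1.0 + s * h), 1.0
    w_male_carrier = _clamp(1.0 + s * h_haploid)

    T = np.zeros((n, n))
    for st in states:
        i = index[st]
        if st == loss or st == fix:
            T[i, i] = 1.0
            continue
        if mode == HAPLODIPLOID:
            a, b, m = st
            Wf = a * w_hom + b * w_het + (Nf - a - b) * w_wild
            Wm = m * w_male_carrier + (Nm - m) * 1.0
            if Wf <= 0.0 or Wm <= 0.0:
                raise ValueError("all fitnesses zero within a sex (s <= -1)")
            pm = (a * w_hom + 0.5 * b * w_het) / Wf
            pp = m * w_male_carrier / Wm
            daughters = _multinomial_pmf_table(Nf, _offspring_genotype_probs(pm, pp))
            sons = _binom_pmf(Nm, pm)
            for a2 in range(Nf + 1):
                for b2 in range(Nf - a2 + 1):
                    pd_ = daughters[a2, b2]
                    if pd_ == 0.0:
                        continue
                    for m2 in range(Nm + 1):
                        p = pd_ * sons[m2]
                        if p > 0.0:
                            T[i, index[(a2, b2, m2)]] += p
        else:
            af, bf, am, bm = st
            Wf = af * w_hom + bf * w_het + (Nf - af - bf) * w_wild
            Wm = am * w_hom + bm * w_het + (Nm - am - bm) * w_wild
            if Wf <= 0.0 or Wm <= 0.0:
                raise ValueError("all fitnesses zero within a sex (s <= -1)")
            pm = (af * w_hom + 0.5 * bf * w_het) / Wf
            pp = (am * w_hom + 0.5 * bm * w_het) / Wm
            q = _offspring_genotype_probs(pm, pp)
            daughters = _multinomial_pmf_table(Nf, q)
            sons_t = _multinomial_pmf_table(Nm, q)
            for af2 in range(Nf + 1):
                for bf2 in range(Nf - af2 + 1):
                    pd_ = daughters[af2, bf2]
                    if pd_ == 0.0:
                        continue
                    for am2 in range(Nm + 1):
                        for bm2 in range(Nm - am2 + 1):
                            p = pd_ * sons_t[am2, bm2]
                            if p > 0.0:
                                T[i, index[(af2, bf2, am2, bm2)]] += p

    return MarkovChain(
        mode=mode, Nm=Nm, Nf=Nf, s=s, h=h, h_haploid=h_haploid,
        states=states, index=index, T=T, loss_state=loss, fix_state=fix,
    )


def _genotype_state(chain: MarkovChain, allele: AlleleState) -> tuple:
    """Heterozygote-first mapping of allele copy counts onto genotypes."""
    Nf, Nm = chain.Nf, chain.Nm
    if not 0 <= allele.i_f <= 2 * Nf:
        raise ValueError(f"i_f out of range [0, {2 * Nf}]")
    # copies fill heterozygotes until every female carries one, then pair up
    af = max(allele.i_f - Nf, 0)
    bf = allele.i_f - 2 * af
    if chain.mode == HAPLODIPLOID:
        if not 0 <= allele.i_m <= Nm:
            raise ValueError(f"i_m out of range [0, {Nm}]")
        return (af, bf, allele.i_m)
    if not 0 <= allele.i_m <= 2 * Nm:
        raise ValueError(f"i_m out of range [0, {2 * Nm}]")
    am = max(allele.i_m - Nm, 0)
    bm = allele.i_m - 2 * am
    return (af, bf, am, bm)


def fixation_probability(chain: MarkovChain, initial) -> float:
    """Absorption probability into the all-copies state, by linear solve.

    ``initial`` is either an :class:`AlleleState` or a raw genotype-resolved
    state tuple from ``chain.states``.
    """
    if isinstance(initial, AlleleState):
        initial = _genotype_state(chain, initial)
    if initial not in chain.index:
        raise ValueError(f"unknown state {initial!r}")
    i_fix = chain.index[chain.fix_state]
    i_loss = chain.index[chain.loss_state]
    transient = [i for i in range(len(chain.states)) if i not in (i_fix, i_loss)]
    ti = {g: k for k, g in enumerate(transient)}
    Q = chain.T[np.ix_(transient, transient)]
    b = chain.T[transient, i_fix]
    u = np.linalg.solve(np.eye(len(transient)) - Q, b)
    i0 = chain.index[initial]
    if i0 == i_fix:
        return 1.0
    if i0 == i_loss:
        return 0.0
    return float(u[ti[i0]])


def single_copy_fixation_probability(
    mode: str,
    Nm: int,
    Nf: int,
    s: float,
    h: float,
    placement: str = "female",
    h_haploid: float = 1.0,
) -> float:
    """Exact fixation probability of one mutant copy, by placement.

    Neutral check: a single copy fixes with probability 1 over the number
    of genome copies — 1/(3N) in a haplodiploid population with Nm=Nf=N
    (whether placed in a male or a female genome) and 1/(4N) in a diploid.
    """
    chain = build_chain(mode, Nm, Nf, s, h, h_haploid)
    if placement == "female":
        allele = AlleleState(i_f=1, i_m=0)
    elif placement == "male":
        allele = AlleleState(i_f=0, i_m=1)
    else:
        raise ValueError("placement must be 'female' or 'male'")
    return fixation_probability(chain, allele)


def oracle_table(
    modes: Iterable[str],
    Nm: int,
    Nf: int,
    s_values: Iterable[float],
    h_values: Iterable[float],
    h_haploid: float = 1.0,
) -> pd.DataFrame:
    """Exact fixation probabilities over a parameter grid, both placements."""
    rows = []
    for mode in modes:
        for s in s_values:
            for h in h_values:
                for placement in ("female", "male"):
                    p = single_copy_fixation_probability(
                        mode, Nm, Nf, s, h, placement, h_haploid
                    )
                    rows.append(
                        {
                            "mode": mode,
                            "Nm": Nm,
                            "Nf": Nf,
                            "s": s,
                            "h": h,
                            "initial_placement": placement,
                            "fixation_probability": p,
                        }
                    )
    return pd.DataFrame(rows)
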