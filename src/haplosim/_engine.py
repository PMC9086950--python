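"""Compiled (numba) generation loop for long simulations.

The object model in :mod:`haplosim.genome_core` / :mod:`haplosim.lifecycle`
is the readable reference implementation; this module is the same algorithm
laid out over flat arrays so that multi-thousand-generation runs are fast.

Layout
------
All genomes of one generation live in a CSR-like structure: ``data`` holds
the concatenated mutation ids (each genome sorted by ``(position, id)``) and
``indptr`` delimits genome slots.  Slot order: female ``i`` owns slots
``2i`` and ``2i+1``; in haplodiploid mode male ``j`` owns the single slot
``2*Nf + j`` (his null genome is implicit), in diploid mode slots
``2*Nf + 2j`` and ``2*Nf + 2j + 1``.

Per-mutation attributes (``position``, ``origin_generation``, transient copy
counts) are arrays indexed by id; a run uses a single mutation type, so ``s``
and ``h`` are scalars.  All randomness flows from one ``np.random.seed``
call inside the jitted run, making runs bit-reproducible from the seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# error codes returned by the jitted runs
OK = 0
EXTINCT_FEMALES = 1
EXTINCT_MALES = 2


@njit(cache=True)
def _grow_i8(arr, need):
    if need <= arr.shape[0]:
        return arr
    cap = max(arr.shape[0], 8)
    while cap < need:
        cap *= 2
    new = np.zeros(cap, dtype=np.int64)
    new[: arr.shape[0]] = arr
    return new


@njit(cache=True)
def _key_less(pos_of, i, j):
    # order mutations by (position, id)
    pi = pos_of[i]
    pj = pos_of[j]
    if pi != pj:
        return pi < pj
    return i < j


@njit(cache=True)
def _pick(cum, total):
    # weighted parent index from a cumulative-sum array
    u = np.random.random() * total
    lo = 0
    hi = cum.shape[0] - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cum[mid] > u:
            hi = mid
        else:
            lo = mid + 1
    return lo


@njit(cache=True)
def _draw_breakpoints(L, r, buf):
    # Poisson(r*(L-1)) crossovers, uniform integer breakpoints in [1, L),
    # sorted and duplicate-free (whole set re-drawn on collision)
    lam = r * (L - 1)
    if lam <= 0.0:
        return 0
    n = np.random.poisson(lam)
    if n == 0:
        return 0
    if n > buf.shape[0]:
        n = buf.shape[0]  # unreachable at sane maps (buffer = 64, mean ~1)
    while True:
        for i in range(n):
            buf[i] = 1 + np.random.randint(0, L - 1)
        buf[:n].sort()
        ok = True
        for i in range(1, n):
            if buf[i] == buf[i - 1]:
                ok = False
                break
        if ok:
            return n


@njit(cache=True)
def _write_recombinant(data, pos_of, a0, a1, b0, b1, bps, nbp, start, out, o):
    """Merge-walk both parental genomes, keeping the alternating strand.

    A mutation at position p belongs to segment ``#{bp <= p}``; strand `a`
    contributes segments of parity ``start``, strand `b` the others.
    Output stays sorted by (position, id).  Returns the new write offset.
    """
    ia = a0
    ib = b0
    bpa = 0
    bpb = 0
    while ia < a1 or ib < b1:
        take_a = False
        if ib >= b1:
            take_a = True
        elif ia < a1:
            take_a = _key_less(pos_of, data[ia], data[ib])
        if take_a:
            m = data[ia]
            ia += 1
            p = pos_of[m]
            while bpa < nbp and bps[bpa] <= p:
                bpa += 1
            if (bpa + start) % 2 == 0:
                out[o] = m
                o += 1
        else:
            m = data[ib]
            ib += 1
            p = pos_of[m]
            while bpb < nbp and bps[bpb] <= p:
                bpb += 1
            if (bpb + start) % 2 == 1:
                out[o] = m
                o += 1
    return o


@njit(cache=True)
def _denovo(out, g0, o, pos_of, origin_of, counts, next_id, L, mu, gen):
    """Apply Poisson(mu*L) de novo mutations to the gamete in out[g0:o]."""
    lam = mu * L
    if lam <= 0.0:
        return o, pos_of, origin_of, counts, next_id
    k = np.random.poisson(lam)
    for _ in range(k):
        p = np.random.randint(0, L)
        pos_of = _grow_i8(pos_of, next_id + 1)
        origin_of = _grow_i8(origin_of, next_id + 1)
        counts = _grow_i8(counts, next_id + 1)
        pos_of[next_id] = p
        origin_of[next_id] = gen
        counts[next_id] = 0
        # insertion point: after every mutation with position <= p
        # (fresh ids exceed all existing ids, so ties sort after)
        lo = g0
        while lo < o and pos_of[out[lo]] <= p:
            lo += 1
        for t in range(o, lo, -1):
            out[t] = out[t - 1]
        out[lo] = next_id
        o += 1
        next_id += 1
    return o, pos_of, origin_of, counts, next_id


@njit(cache=True)
def _pair_fitness(data, pos_of, a0, a1, b0, b1, s, h):
    """Diploid fitness: (1+s)^hom * (1+s*h)^het over a genome pair."""
    ia = a0
    ib = b0
    hom = 0
    while ia < a1 and ib < b1:
        da = data[ia]
        db = data[ib]
        if da == db:
            hom += 1
            ia += 1
            ib += 1
        elif _key_less(pos_of, da, db):
            ia += 1
        else:
            ib += 1
    het = (a1 - a0 - hom) + (b1 - b0 - hom)
    w = (1.0 + s) ** hom * (1.0 + s * h) ** het
    if w < 0.0:
        w = 0.0
    return w


@njit(cache=True)
def _run_sim(
    is_hap,
    Nm,
    Nf,
    L,
    mu,
    r,
    s,
    h,
    h_hap,
    n_generations,
    seed,
    data,
    indptr,
    pos_of,
    origin_of,
    next_id,
    start_generation,
):
    """Advance ``n_generations`` non-overlapping generations.

    Returns per-generation statistics, the substitution log, and the final
    genome arrays.  ``data``/``indptr`` describe the starting genomes (the
    founding population is mutation-free: empty data).
    """
    np.random.seed(seed)
    G = 2 * Nf + (Nm if is_hap else 2 * Nm)

    subs = np.zeros(n_generations, dtype=np.int64)
    seg = np.zeros(n_generations, dtype=np.int64)
    mwf = np.ones(n_generations, dtype=np.float64)
    mwm = np.ones(n_generations, dtype=np.float64)

    log_cap = 1024
    log_id = np.zeros(log_cap, dtype=np.int64)
    log_gen = np.zeros(log_cap, dtype=np.int64)
    n_logged = 0

    counts = np.zeros(max(pos_of.shape[0], 8), dtype=np.int64)
    pos_of = _grow_i8(pos_of, counts.shape[0])
    origin_of = _grow_i8(origin_of, counts.shape[0])
    for t in range(indptr[G]):
        counts[data[t]] += 1

    wf = np.ones(Nf, dtype=np.float64)
    wm = np.ones(Nm, dtype=np.float64)
    cwf = np.zeros(Nf, dtype=np.float64)
    cwm = np.zeros(Nm, dtype=np.float64)
    bps = np.zeros(64, dtype=np.int64)

    err = OK
    n_created = 0

    for g in range(n_generations):
        gen = start_generation + g + 1

        # --- parent fitness (the adults about to reproduce) ---
        for i in range(Nf):
            wf[i] = _pair_fitness(
                data, pos_of, indptr[2 * i], indptr[2 * i + 1],
                indptr[2 * i + 1], indptr[2 * i + 2], s, h,
            )
        if is_hap:
            for j in range(Nm):
                n = indptr[2 * Nf + j + 1] - indptr[2 * Nf + j]
                w = (1.0 + s * h_hap) ** n
                wm[j] = w if w > 0.0 else 0.0
        else:
            for j in range(Nm):
                a0 = indptr[2 * Nf + 2 * j]
                wm[j] = _pair_fitness(
                    data, pos_of, a0, indptr[2 * Nf + 2 * j + 1],
                    indptr[2 * Nf + 2 * j + 1], indptr[2 * Nf + 2 * j + 2], s, h,
                )
        tot_f = 0.0
        for i in range(Nf):
            tot_f += wf[i]
            cwf[i] = tot_f
        tot_m = 0.0
        for j in range(Nm):
            tot_m += wm[j]
            cwm[j] = tot_m
        if tot_f <= 0.0:
            err = EXTINCT_FEMALES
            break
        if tot_m <= 0.0:
            err = EXTINCT_MALES
            break
        mwf[g] = tot_f / Nf
        mwm[g] = tot_m / Nm

        # --- build offspring genomes ---
        out = np.zeros(max(2 * indptr[G] + 64, 256), dtype=np.int64)
        new_indptr = np.zeros(G + 1, dtype=np.int64)
        o = 0
        slot = 0
        n_id_before = next_id

        for i in range(Nf):  # daughters: maternal recombinant + paternal gamete
            mom = _pick(cwf, tot_f)
            dad = _pick(cwm, tot_m)
            ma0 = indptr[2 * mom]
            ma1 = indptr[2 * mom + 1]
            mb1 = indptr[2 * mom + 2]
            if is_hap:
                pa0 = indptr[2 * Nf + dad]
                pa1 = indptr[2 * Nf + dad + 1]
                plen = pa1 - pa0
            else:
                pa0 = indptr[2 * Nf + 2 * dad]
                pa1 = indptr[2 * Nf + 2 * dad + 1]
                pb1 = indptr[2 * Nf + 2 * dad + 2]
                plen = pb1 - pa0
            need = o + (mb1 - ma0) + plen + 32
            if need > out.shape[0]:
                out = _grow_i8(out, need)

            g0 = o
            nbp = _draw_breakpoints(L, r, bps)
            start = np.random.randint(0, 2)
            o = _write_recombinant(data, pos_of, ma0, ma1, ma1, mb1, bps, nbp, start, out, g0)
            o, pos_of, origin_of, counts, next_id = _denovo(
                out, g0, o, pos_of, origin_of, counts, next_id, L, mu, gen
            )
            slot += 1
            new_indptr[slot] = o

            g0 = o
            if is_hap:  # father transmits a clonal copy of his single genome
                for t in range(pa0, pa1):
                    out[o] = data[t]
                    o += 1
            else:
                nbp = _draw_breakpoints(L, r, bps)
                start = np.random.randint(0, 2)
                o = _write_recombinant(data, pos_of, pa0, pa1, pa1, pb1, bps, nbp, start, out, g0)
            o, pos_of, origin_of, counts, next_id = _denovo(
                out, g0, o, pos_of, origin_of, counts, next_id, L, mu, gen
            )
            slot += 1
            new_indptr[slot] = o

        for j in range(Nm):  # sons
            mom = _pick(cwf, tot_f)
            ma0 = indptr[2 * mom]
            ma1 = indptr[2 * mom + 1]
            mb1 = indptr[2 * mom + 2]
            if is_hap:
                need = o + (mb1 - ma0) + 32
            else:
                dad = _pick(cwm, tot_m)
                pa0 = indptr[2 * Nf + 2 * dad]
                pa1 = indptr[2 * Nf + 2 * dad + 1]
                pb1 = indptr[2 * Nf + 2 * dad + 2]
                need = o + (mb1 - ma0) + (pb1 - pa0) + 32
            if need > out.shape[0]:
                out = _grow_i8(out, need)

            g0 = o
            nbp = _draw_breakpoints(L, r, bps)
            start = np.random.randint(0, 2)
            o = _write_recombinant(data, pos_of, ma0, ma1, ma1, mb1, bps, nbp, start, out, g0)
            o, pos_of, origin_of, counts, next_id = _denovo(
                out, g0, o, pos_of, origin_of, counts, next_id, L, mu, gen
            )
            slot += 1
            new_indptr[slot] = o

            if not is_hap:
                g0 = o
                nbp = _draw_breakpoints(L, r, bps)
                start = np.random.randint(0, 2)
                o = _write_recombinant(data, pos_of, pa0, pa1, pa1, pb1, bps, nbp, start, out, g0)
                o, pos_of, origin_of, counts, next_id = _denovo(
                    out, g0, o, pos_of, origin_of, counts, next_id, L, mu, gen
                )
                slot += 1
                new_indptr[slot] = o

        n_created += next_id - n_id_before

        # --- recount copy numbers (zero via the parents' ids first) ---
        for t in range(indptr[G]):
            counts[data[t]] = 0
        n_active = 0
        for t in range(o):
            m = out[t]
            if counts[m] == 0:
                n_active += 1
            counts[m] += 1

        # --- classify: fixed ids are logged and purged; lost ids vanish ---
        n_fixed = 0
        for t in range(o):
            m = out[t]
            if counts[m] == G:
                if n_logged == log_cap:
                    log_cap *= 2
                    nid = np.zeros(log_cap, dtype=np.int64)
                    ngn = np.zeros(log_cap, dtype=np.int64)
                    nid[:n_logged] = log_id[:n_logged]
                    ngn[:n_logged] = log_gen[:n_logged]
                    log_id = nid
                    log_gen = ngn
                log_id[n_logged] = m
                log_gen[n_logged] = gen
                n_logged += 1
                n_fixed += 1
                counts[m] = -1  # mark for purge
        if n_fixed > 0:
            new_o = 0
            for gslot in range(G):
                lo = new_indptr[gslot]
                hi = new_indptr[gslot + 1]
                new_indptr[gslot] = new_o
                for t in range(lo, hi):
                    if counts[out[t]] != -1:
                        out[new_o] = out[t]
                        new_o += 1
            new_indptr[G] = new_o
            o = new_o
            for t in range(n_logged - n_fixed, n_logged):
                counts[log_id[t]] = 0

        subs[g] = n_fixed
        seg[g] = n_active - n_fixed

        data = out[:o]
        indptr = new_indptr

    return (
        err,
        subs,
        seg,
        mwf,
        mwm,
        log_id[:n_logged],
        log_gen[:n_logged],
        data[: indptr[G]].copy(),
        indptr.copy(),
        pos_of,
        origin_of,
        next_id,
        n_created,
    )


@njit(cache=True)
def _run_fate(is_hap, Nm, Nf, s, h, h_hap, carrier_slot, seed, max_gens):
    """Fate of one pre-existing mutant copy with mutation switched off.

    A single-locus specialization of the generation loop (L = 1, mu = 0:
    no crossovers, transmission is a fair strand choice).  ``carrier_slot``
    indexes the genome slot holding the initial copy, in the layout of
    :func:`_run_sim`.  Returns 1 if the mutation fixes, 0 if it is lost,
    -1 if not absorbed within ``max_gens``.
    """
    np.random.seed(seed)
    G = 2 * Nf + (Nm if is_hap else 2 * Nm)
    geno = np.zeros(G, dtype=np.uint8)
    geno[carrier_slot] = 1
    new = np.zeros(G, dtype=np.uint8)
    wf = np.ones(Nf, dtype=np.float64)
    wm = np.ones(Nm, dtype=np.float64)
    cwf = np.zeros(Nf, dtype=np.float64)
    cwm = np.zeros(Nm, dtype=np.float64)

    for _ in range(max_gens):
        for i in range(Nf):
            n = geno[2 * i] + geno[2 * i + 1]
            if n == 2:
                wf[i] = 1.0 + s
            elif n == 1:
                wf[i] = 1.0 + s * h
            else:
                wf[i] = 1.0
            if wf[i] < 0.0:
                wf[i] = 0.0
        if is_hap:
            for j in range(Nm):
                wm[j] = 1.0 + s * h_hap if geno[2 * Nf + j] == 1 else 1.0
                if wm[j] < 0.0:
                    wm[j] = 0.0
        else:
            for j in range(Nm):
                n = geno[2 * Nf + 2 * j] + geno[2 * Nf + 2 * j + 1]
                if n == 2:
                    wm[j] = 1.0 + s
                elif n == 1:
                    wm[j] = 1.0 + s * h
                else:
                    wm[j] = 1.0
                if wm[j] < 0.0:
                    wm[j] = 0.0
        tot_f = 0.0
        for i in range(Nf):
            tot_f += wf[i]
            cwf[i] = tot_f
        tot_m = 0.0
        for j in range(Nm):
            tot_m += wm[j]
            cwm[j] = tot_m
        if tot_f <= 0.0 or tot_m <= 0.0:
            return 0  # only carriers can have w=0 here (s=-1); allele dies

        for i in range(Nf):
            mom = _pick(cwf, tot_f)
            dad = _pick(cwm, tot_m)
            new[2 * i] = geno[2 * mom + np.random.randint(0, 2)]
            if is_hap:
                new[2 * i + 1] = geno[2 * Nf + dad]
            else:
                new[2 * i + 1] = geno[2 * Nf + 2 * dad + np.random.randint(0, 2)]
        for j in range(Nm):
            mom = _pick(cwf, tot_f)
            if is_hap:
                new[2 * Nf + j] = geno[2 * mom + np.random.randint(0, 2)]
            else:
                dad = _pick(cwm, tot_m)
                new[2 * Nf + 2 * j] = geno[2 * mom + np.random.randint(0, 2)]
                new[2 * Nf + 2 * j + 1] = geno[2 * Nf + 2 * dad + np.random.randint(0, 2)]

        tot = 0
        for t in range(G):
            geno[t] = new[t]
            tot += new[t]
        if tot == 0:
            return 0
        if tot == G:
            return 1
    return -1
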