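"""Jitted inner loops of the simulation step.

Each kernel mutates preallocated state arrays in place and draws from the
single ``np.random.Generator`` of the run, in the scheduled order, so a whole
run is reproducible bit-for-bit from (config, seed).  The per-individual
helpers (``copy_with_error``, ``forage_one``, ``learn_one``, ...) are the
semantic units the operation modules expose; the phase kernels just loop over
them in the shuffled processing order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Consuming more than this close to the cap counts as "no headroom".
_EPS = 1e-12


@njit(cache=False)
def copy_with_error(value, p_err, max_skill, rng):
    """Copy a skill value with the +-1 transmission error, clamped to [1, max]."""
    v = value
    if p_err > 0.0 and rng.random() < p_err:
        if rng.random() < 0.5:
            v = v + 1
        else:
            v = v - 1
        if v < 1:
            v = 1
        elif v > max_skill:
            v = max_skill
    return v


@njit(cache=False)
def metabolize_one(i, energy, age, step_req):
    """Age one year and pay the per-step energy requirement (floored at 0)."""
    age[i] += 1
    e = energy[i] - step_req
    starving = e < 0.0
    if starving:
        e = 0.0
    energy[i] = e
    return starving


@njit(cache=False)
def forage_pass(i, x, y, energy, skills, ntraits, stocks, taken,
                basic_rate, sel_diff, energy_cap, step_req, max_skill,
                budget):
    """One foraging pass over the owned traits, in descending extraction
    rate order (rate ties broken by trait index).

    Each trait yields min(remaining per-step rate, remaining stock, storage
    headroom, remaining pass budget).  ``taken[t]`` accumulates what trait t
    already yielded this step, so the per-step rate cap spans passes.
    Returns the amount consumed in this pass.
    """
    e = energy[i]
    k = ntraits[i]
    got = 0.0
    for s in range(max_skill, 0, -1):
        if energy_cap - e <= _EPS or budget - got <= _EPS:
            break
        for t in range(k):
            if skills[i, t] != s:
                continue
            room = energy_cap - e
            if room <= _EPS:
                break
            take = basic_rate + sel_diff * (s - 1) - taken[t]
            if take > room:
                take = room
            st = stocks[x, y, t]
            if take > st:
                take = st
            rem = budget - got
            if take > rem:
                take = rem
            if take > 0.0:
                stocks[x, y, t] = st - take
                taken[t] += take
                e += take
                got += take
    energy[i] = e
    return got


@njit(cache=False)
def forage_one(i, x, y, energy, skills, ntraits, stocks, intake, pressure,
               basic_rate, sel_diff, energy_cap, step_req, max_skill,
               forage_mode, taken):
    """Forage on the individual's own square; sets intake and pressure.

    Modes: 0 = needs-first (secure the per-step requirement, then hoard
    toward the cap from what is left -- the default), 1 = greedy to the
    storage cap, 2 = stop at the requirement.  ``under_pressure`` is set iff
    the realized intake fell short of the per-step requirement.
    """
    for t in range(ntraits[i]):
        taken[t] = 0.0
    if forage_mode == 0:
        got = forage_pass(i, x, y, energy, skills, ntraits, stocks, taken,
                          basic_rate, sel_diff, energy_cap, step_req,
                          max_skill, step_req)
        got += forage_pass(i, x, y, energy, skills, ntraits, stocks, taken,
                           basic_rate, sel_diff, energy_cap, step_req,
                           max_skill, energy_cap)
    elif forage_mode == 1:
        got = forage_pass(i, x, y, energy, skills, ntraits, stocks, taken,
                          basic_rate, sel_diff, energy_cap, step_req,
                          max_skill, energy_cap)
    else:
        got = forage_pass(i, x, y, energy, skills, ntraits, stocks, taken,
                          basic_rate, sel_diff, energy_cap, step_req,
                          max_skill, step_req)
    intake[i] = got
    pressure[i] = got < step_req
    return got


@njit(cache=False)
def forage_phase(order, alive, age, energy, group, skills, ntraits, intake,
                 pressure, gx, gy, gcount, stocks, taken, basic_rate,
                 sel_diff, energy_cap, step_req, max_age, max_skill,
                 forage_mode):
    """Unconditional individual phase: metabolize, forage, resolve deaths.

    In needs-first mode the requirement pass of *every* individual precedes
    any hoarding: individuals first secure (up to) the per-step requirement
    in the shuffled order, then, in the same order, fill their stores from
    whatever stock is left.  ``taken`` is an (n, n_types) scratch tracking
    per-trait extraction so the per-step rate cap spans both passes.
    """
    for oi in range(order.shape[0]):
        i = order[oi]
        if not alive[i]:
            continue
        metabolize_one(i, energy, age, step_req)
        g = group[i]
        for t in range(ntraits[i]):
            taken[i, t] = 0.0
        budget = energy_cap if forage_mode == 1 else step_req
        intake[i] = forage_pass(i, gx[g], gy[g], energy, skills, ntraits,
                                stocks, taken[i], basic_rate, sel_diff,
                                energy_cap, step_req, max_skill, budget)
    if forage_mode == 0:
        for oi in range(order.shape[0]):
            i = order[oi]
            if not alive[i]:
                continue
            g = group[i]
            intake[i] += forage_pass(i, gx[g], gy[g], energy, skills,
                                     ntraits, stocks, taken[i], basic_rate,
                                     sel_diff, energy_cap, step_req,
                                     max_skill, energy_cap)
    for oi in range(order.shape[0]):
        i = order[oi]
        if not alive[i]:
            continue
        pressure[i] = intake[i] < step_req
        if energy[i] <= 0.0 or age[i] > max_age:
            alive[i] = False
            gcount[group[i]] -= 1


@njit(cache=False)
def build_hists(order, alive, group, skills, ntraits, hist):
    """Per-group skill histograms: hist[g, t, v] = members with trait t at value v."""
    for oi in range(order.shape[0]):
        i = order[oi]
        if not alive[i]:
            continue
        g = group[i]
        for t in range(ntraits[i]):
            hist[g, t, skills[i, t]] += 1


@njit(cache=False)
def _elig_remove(i, key, elig_flat, elig_off, elig_cnt, elig_pos):
    """Remove slot i from the partner-eligibility list of (group, sex) `key`."""
    p = elig_pos[i]
    base = elig_off[key]
    if p < base or p >= base + elig_cnt[key]:
        return
    last = base + elig_cnt[key] - 1
    j = elig_flat[last]
    elig_flat[p] = j
    elig_pos[j] = p
    elig_flat[last] = i
    elig_pos[i] = last
    elig_cnt[key] -= 1


@njit(cache=False)
def learn_one(i, g, skills, ntraits, energy, hist, ngroups, nglen,
              p_err, max_skill, n_types, learn_cost, rng):
    """One social learning attempt for an individual under resource pressure.

    Preference order: (a) acquire the next trait k+1 from a uniformly chosen
    model that holds it; (b) otherwise improve one owned trait (chosen
    uniformly among traits for which some model is strictly better) by
    copying the maximum model value.  Both copies pass through the +-1 error.
    Returns True iff a value was learned; on success the learning cost is
    deducted from the learner's energy.
    """
    if energy[i] <= learn_cost:
        return False
    k = ntraits[i]
    # (a) acquire trait k+1
    if k < n_types:
        total = 0
        for a in range(nglen[g]):
            g2 = ngroups[g, a]
            for v in range(1, max_skill + 1):
                total += hist[g2, k, v]
        if total > 0:
            r = rng.integers(0, total)
            val = 0
            for a in range(nglen[g]):
                g2 = ngroups[g, a]
                if val > 0:
                    break
                for v in range(1, max_skill + 1):
                    c = hist[g2, k, v]
                    if r < c:
                        val = v
                        break
                    r -= c
            newv = copy_with_error(val, p_err, max_skill, rng)
            skills[i, k] = newv
            ntraits[i] = k + 1
            hist[g, k, newv] += 1
            energy[i] -= learn_cost
            return True
    # (b) improve an owned trait some model is strictly better at
    n_improvable = 0
    for t in range(k):
        own = skills[i, t]
        for a in range(nglen[g]):
            g2 = ngroups[g, a]
            found = False
            for v in range(own + 1, max_skill + 1):
                if hist[g2, t, v] > 0:
                    found = True
                    break
            if found:
                n_improvable += 1
                break
    if n_improvable == 0:
        return False
    r = rng.integers(0, n_improvable)
    idx = 0
    for t in range(k):
        own = skills[i, t]
        n_better = 0
        for a in range(nglen[g]):
            g2 = ngroups[g, a]
            for v in range(own + 1, max_skill + 1):
                n_better += hist[g2, t, v]
        if n_better > 0:
            if idx == r:
                # copy a uniformly chosen model holding the trait (any value,
                # learner excluded): transmission is unbiased, so higher
                # values spread only when selection retains them
                n_models = -1          # excludes the learner
                for a in range(nglen[g]):
                    g2 = ngroups[g, a]
                    for v in range(1, max_skill + 1):
                        n_models += hist[g2, t, v]
                r2 = rng.integers(0, n_models)
                val = 0
                for a in range(nglen[g]):
                    g2 = ngroups[g, a]
                    if val > 0:
                        break
                    for v in range(1, max_skill + 1):
                        c = hist[g2, t, v]
                        if g2 == g and v == own:
                            c -= 1
                        if r2 < c:
                            val = v
                            break
                        r2 -= c
                newv = copy_with_error(val, p_err, max_skill, rng)
                hist[g, t, skills[i, t]] -= 1
                hist[g, t, newv] += 1
                skills[i, t] = newv
                energy[i] -= learn_cost
                return True
            idx += 1
    return False


@njit(cache=False)
def invent_one(i, g, skills, ntraits, energy, hist, max_skill, n_types,
               invent_cost):
    """Invent trait k+1 at value 1 iff trait k is mastered and energy allows."""
    k = ntraits[i]
    if k < n_types and skills[i, k - 1] == max_skill and energy[i] > invent_cost:
        skills[i, k] = 1
        ntraits[i] = k + 1
        energy[i] -= invent_cost
        hist[g, k, 1] += 1
        return True
    return False


@njit(cache=False)
def transmit_vertical(nb, mi, fi, skills, ntraits, p_err, max_skill, rng):
    """Newborn trait vector: prefix of length min(k_mother, k_father); each
    value copied from a uniformly chosen parent through the copy error."""
    km = ntraits[mi]
    kf = ntraits[fi]
    kk = km if km < kf else kf
    for t in range(kk):
        src = mi if rng.integers(0, 2) == 0 else fi
        skills[nb, t] = copy_with_error(skills[src, t], p_err, max_skill, rng)
    for t in range(kk, skills.shape[1]):
        skills[nb, t] = 0
    ntraits[nb] = kk


@njit(cache=False)
def reproduce_pair(mi, fi, nb, sex, age, energy, group, skills, ntraits,
                   intake, pressure, alive, transfer, energy_cap, p_err,
                   max_skill, gcount, rng):
    """Create the newborn in slot nb; both parents pay the energy transfer.

    Draw order: newborn sex, then per-trait parent choice and copy error.
    The newborn joins the mother's group and does not act this step.
    """
    sex[nb] = rng.integers(0, 2)
    age[nb] = 0
    e = 2.0 * transfer
    if e > energy_cap:
        e = energy_cap
    energy[nb] = e
    energy[mi] -= transfer
    energy[fi] -= transfer
    g = group[mi]
    group[nb] = g
    gcount[g] += 1
    alive[nb] = True
    intake[nb] = 0.0
    pressure[nb] = False
    transmit_vertical(nb, mi, fi, skills, ntraits, p_err, max_skill, rng)


@njit(cache=False)
def learn_repro_phase(order, alive, sex, age, energy, group, skills, ntraits,
                      intake, pressure, paired, ids, gcount, hist, ngroups, nglen,
                      elig_flat, elig_off, elig_cnt, elig_pos,
                      ev_id, ev_group, ev_trait, n_slots,
                      p_err, max_skill, n_types, learn_cost, invent_cost,
                      min_repro_age, erep, transfer, energy_cap, rng):
    """Conditional individual phase, in the same shuffled order as foraging.

    Per surviving individual: if under pressure, one social learning attempt,
    then an invention attempt if learning failed; then partner search and
    reproduction if eligible (age, energy, not yet paired this step).
    Returns (new slot top, number of invention events logged).
    """
    n_ev = 0
    top = n_slots
    for oi in range(order.shape[0]):
        i = order[oi]
        if not alive[i]:
            continue
        g = group[i]
        if pressure[i]:
            learned = learn_one(i, g, skills, ntraits, energy, hist, ngroups,
                                nglen, p_err, max_skill, n_types, learn_cost,
                                rng)
            invented = False
            if not learned:
                invented = invent_one(i, g, skills, ntraits, energy, hist,
                                      max_skill, n_types, invent_cost)
                if invented:
                    ev_id[n_ev] = ids[i]
                    ev_group[n_ev] = g
                    ev_trait[n_ev] = ntraits[i]
                    n_ev += 1
            if (learned or invented) and energy[i] < erep:
                _elig_remove(i, g * 2 + sex[i], elig_flat, elig_off,
                             elig_cnt, elig_pos)
        if paired[i] or age[i] < min_repro_age or energy[i] < erep:
            continue
        okey = 1 - sex[i]
        total = 0
        for a in range(nglen[g]):
            total += elig_cnt[ngroups[g, a] * 2 + okey]
        if total == 0:
            continue
        r = rng.integers(0, total)
        j = -1
        for a in range(nglen[g]):
            g2 = ngroups[g, a]
            c = elig_cnt[g2 * 2 + okey]
            if r < c:
                j = elig_flat[elig_off[g2 * 2 + okey] + r]
                break
            r -= c
        paired[i] = True
        paired[j] = True
        _elig_remove(i, g * 2 + sex[i], elig_flat, elig_off, elig_cnt,
                     elig_pos)
        _elig_remove(j, group[j] * 2 + sex[j], elig_flat, elig_off, elig_cnt,
                     elig_pos)
        if sex[i] == 0:
            mi, fi = i, j
        else:
            mi, fi = j, i
        reproduce_pair(mi, fi, top, sex, age, energy, group, skills, ntraits,
                       intake, pressure, alive, transfer, energy_cap, p_err,
                       max_skill, gcount, rng)
        top += 1
    return top, n_ev
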