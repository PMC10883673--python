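"""Numba core of the stochastic engine.

The production engine samples the first-reaction minimum exactly: with all
candidate waiting times redrawn each step from independent exponentials, the
executed event is the candidate with the shortest time, the step duration is
exponential with the total rate, and the winning candidate is distributed
proportionally to its rate.  The kernel therefore draws ``dt ~ Exp(R_total)``
and selects the event category/target by its rate weight, which is the exact
joint law of the per-candidate minimum (not an approximation).  A literal
per-candidate implementation lives in :mod:`ebtip.reference` and the two are
held equivalent by tests.

State layout (all 0-based, interface ``i`` = seam between protofilaments
``i`` and ``(i+1) % n_pf``):

- ``length[p]``                protofilament lengths in dimers
- ``gdp[p, j]``                1 if dimer hydrolyzed
- ``bond[i, j]``               1 if lateral bond formed
- ``occ[i, j]`` / ``origin``   EB1 occupancy and class at binding
- ``site_state[i, j]``         cached pocket class: 0 none, 1 edge, 2 closed

Aggregate counters (per-interface unoccupied edge/closed pocket counts, bond
counts, non-seed GTP count, occupied-pocket list) are maintained
incrementally; a pure-python from-scratch reclassification is compared
against the cache in tests.
"""

import numpy as np
from numba import njit

# parameter slots in the packed P array
P_TUB_CONC = 0
P_K_ON_TUB = 1
P_OFF_GTP0 = 2
P_OFF_GTP1 = 3
P_OFF_GTP2 = 4
P_OFF_GDP0 = 5
P_OFF_GDP1 = 6
P_OFF_GDP2 = 7
P_K_HYD = 8
P_K_FORM = 9
P_K_BREAK_BASE = 10
P_PI_BREAK = 11
P_BOOST = 12
P_MAX_TAPER = 13
P_EB1_CONC = 14
P_K_ON_EDGE = 15
P_K_ON_CLOSED = 16
P_KOFF_CG = 17
P_KOFF_CD = 18
P_KOFF_EG = 19
P_KOFF_ED = 20
P_MONOMER = 21
P_FLARE = 22
N_PARAMS = 23

# tally slots
T_TUB_ON = 0
T_TUB_OFF = 1
T_FORM = 2
T_BREAK = 3
T_EB1_ON_EDGE = 4
T_EB1_ON_CLOSED = 5
T_EB1_OFF = 6
T_FORCED = 7
T_HYDROLYSIS = 8
N_TALLIES = 9

# run exit status
STATUS_STEPS = 0
STATUS_TIME = 1
STATUS_CAPACITY = 2
STATUS_CATASTROPHE = 3
STATUS_STORE_FULL = 4


@njit(cache=True, inline="always")
def _classify(length, i, j, n_pf, flare, maxbond_i):
    r = (i + 1) % n_pf
    mi = length[i] - j
    if mi < 0:
        mi = 0
    elif mi > 2:
        mi = 2
    mr = length[r] - j
    if mr < 0:
        mr = 0
    elif mr > 2:
        mr = 2
    m = mi + mr
    if m < 2:
        return 0
    if m == 4 and (flare == 0 or j <= maxbond_i):
        return 2
    return 1


@njit(cache=True)
def _refresh_site(
    i, j, length, occ, origin, site_state, n_edge_unocc, n_closed_unocc,
    occ_i, occ_j, n_occ, tallies, n_pf, flare, maxbond,
):
    """Recompute the cached class of pocket (i, j); maintain counters.

    Returns the updated occupied-list length (drops force-released EB1s).
    """
    if j < 0:
        return n_occ
    old = site_state[i, j]
    new = _classify(length, i, j, n_pf, flare, maxbond[i])
    if new == old:
        return n_occ
    if occ[i, j]:
        if new == 0:
            # pocket dropped below 2 member dimers: forced EB1 release
            occ[i, j] = 0
            origin[i, j] = 0
            tallies[T_FORCED] += 1
            for k in range(n_occ):
                if occ_i[k] == i and occ_j[k] == j:
                    occ_i[k] = occ_i[n_occ - 1]
                    occ_j[k] = occ_j[n_occ - 1]
                    n_occ -= 1
                    break
    else:
        if old == 1:
            n_edge_unocc[i] -= 1
        elif old == 2:
            n_closed_unocc[i] -= 1
        if new == 1:
            n_edge_unocc[i] += 1
        elif new == 2:
            n_closed_unocc[i] += 1
    site_state[i, j] = new
    return n_occ


@njit(cache=True)
def _refresh_interface_range(
    i, j_lo, j_hi, length, occ, origin, site_state, n_edge_unocc, n_closed_unocc,
    occ_i, occ_j, n_occ, tallies, n_pf, flare, maxbond,
):
    for j in range(max(j_lo, 0), j_hi + 1):
        n_occ = _refresh_site(
            i, j, length, occ, origin, site_state, n_edge_unocc, n_closed_unocc,
            occ_i, occ_j, n_occ, tallies, n_pf, flare, maxbond,
        )
    return n_occ


@njit(cache=True)
def run_kernel(
    seed,
    n_steps,
    max_time,
    record_interval,
    seed_len,
    P,
    sw_time,
    sw_slot,
    sw_value,
    stop_cat_dimers,  # stop at first boost trip once mean length >= this (0 = off)
    # mutable state (initialized by caller)
    length,
    gdp,
    bond,
    occ,
    origin,
    site_state,
    # outputs
    snap_time,
    snap_len,
    snap_counts,
    snap_tallies,
    occ_store_i,
    occ_store_j,
    occ_store_orig,
    occ_offsets,
    gtp_store_p,
    gtp_store_j,
    gtp_offsets,
    boost_times,
    boost_flags,
):
    np.random.seed(seed)
    n_pf = length.shape[0]
    cap = gdp.shape[1]

    # ---- counters initialized from the given state -------------------- #
    n_edge_unocc = np.zeros(n_pf, dtype=np.int64)
    n_closed_unocc = np.zeros(n_pf, dtype=np.int64)
    nbonds_if = np.zeros(n_pf, dtype=np.int64)
    maxbond = np.full(n_pf, -1, dtype=np.int64)
    occ_i = np.zeros(4096, dtype=np.int64)
    occ_j = np.zeros(4096, dtype=np.int64)
    n_occ = 0
    n_gtp = 0
    flare = int(P[P_FLARE])
    for i in range(n_pf):
        for j in range(cap):
            if bond[i, j]:
                nbonds_if[i] += 1
                if j > maxbond[i]:
                    maxbond[i] = j
    for p in range(n_pf):
        for j in range(seed_len, length[p]):
            if gdp[p, j] == 0:
                n_gtp += 1
    for i in range(n_pf):
        r = (i + 1) % n_pf
        top = max(length[i], length[r])
        for j in range(top):
            s = _classify(length, i, j, n_pf, flare, maxbond[i])
            site_state[i, j] = s
            if occ[i, j]:
                occ_i[n_occ] = i
                occ_j[n_occ] = j
                n_occ += 1
            elif s == 1:
                n_edge_unocc[i] += 1
            elif s == 2:
                n_closed_unocc[i] += 1

    tallies = np.zeros(N_TALLIES, dtype=np.int64)
    toff_pf = np.zeros(n_pf, dtype=np.float64)
    off_rates = np.zeros(4096, dtype=np.float64)

    t = 0.0
    boosted = False
    n_snap = 0
    n_boost = 0
    occ_ptr = 0
    gtp_ptr = 0
    sw_next = 0
    status = STATUS_STEPS

    max_snap = snap_time.shape[0]
    occ_store_cap = occ_store_i.shape[0]
    gtp_store_cap = gtp_store_p.shape[0]

    step = 0
    while step < n_steps:
        step += 1

        # pending parameter switches (applied at the first step at/after t)
        while sw_next < sw_time.shape[0] and t >= sw_time[sw_next]:
            P[int(sw_slot[sw_next])] = sw_value[sw_next]
            flare = int(P[P_FLARE])
            sw_next += 1

        boost = P[P_BOOST] if boosted else 1.0
        off_g0 = P[P_OFF_GTP0] * boost
        off_g1 = P[P_OFF_GTP1] * boost
        off_g2 = P[P_OFF_GTP2] * boost
        off_d0 = P[P_OFF_GDP0] * boost
        off_d1 = P[P_OFF_GDP1] * boost
        off_d2 = P[P_OFF_GDP2] * boost
        k_break = P[P_K_BREAK_BASE] / P[P_PI_BREAK] * boost
        mono = 4.0 if P[P_MONOMER] > 0 else 1.0
        koff_cg = P[P_KOFF_CG] * mono
        koff_cd = P[P_KOFF_CD] * mono
        koff_eg = P[P_KOFF_EG] * mono
        koff_ed = P[P_KOFF_ED] * mono

        # ---- total rates -------------------------------------------- #
        r_arr = n_pf * P[P_K_ON_TUB] * P[P_TUB_CONC]

        r_toff = 0.0
        for p in range(n_pf):
            if length[p] > seed_len:
                h = length[p] - 1
                left = (p - 1) % n_pf
                nb = bond[left, h] + bond[p, h]
                if gdp[p, h]:
                    rr = off_d0 if nb == 0 else (off_d1 if nb == 1 else off_d2)
                else:
                    rr = off_g0 if nb == 0 else (off_g1 if nb == 1 else off_g2)
                toff_pf[p] = rr
                r_toff += rr
            else:
                toff_pf[p] = 0.0

        n_formable = 0
        n_bonds = 0
        for i in range(n_pf):
            r = (i + 1) % n_pf
            lo = min(length[i], length[r])
            n_formable += lo - nbonds_if[i]
            n_bonds += nbonds_if[i]
        r_form = P[P_K_FORM] * n_formable
        r_break = k_break * n_bonds

        ne_un = 0
        nc_un = 0
        for i in range(n_pf):
            ne_un += n_edge_unocc[i]
            nc_un += n_closed_unocc[i]
        r_on_edge = P[P_K_ON_EDGE] * P[P_EB1_CONC] * ne_un
        r_on_closed = P[P_K_ON_CLOSED] * P[P_EB1_CONC] * nc_un

        r_eboff = 0.0
        for k in range(n_occ):
            i = occ_i[k]
            j = occ_j[k]
            r = (i + 1) % n_pf
            is_gdp = gdp[i, j] | gdp[r, j]
            if site_state[i, j] == 2:
                rr = koff_cd if is_gdp else koff_cg
            else:
                rr = koff_ed if is_gdp else koff_eg
            off_rates[k] = rr
            r_eboff += rr

        R = r_arr + r_toff + r_form + r_break + r_on_edge + r_on_closed + r_eboff
        if R <= 0.0:
            status = STATUS_TIME
            break

        dt = -np.log(1.0 - np.random.random()) / R
        t += dt
        if t > max_time:
            t = max_time
            status = STATUS_TIME
            break

        # ---- select and execute one event --------------------------- #
        x = np.random.random() * R
        if x < r_arr:
            # tubulin arrival
            p = int(np.random.random() * n_pf)
            if p >= n_pf:
                p = n_pf - 1
            h = length[p]
            if h >= cap - 1:
                status = STATUS_CAPACITY
                break
            gdp[p, h] = 0
            length[p] = h + 1
            n_gtp += 1
            tallies[T_TUB_ON] += 1
            left = (p - 1) % n_pf
            for i in (left, p):
                for j in (h - 1, h):
                    n_occ = _refresh_site(
                        i, j, length, occ, origin, site_state, n_edge_unocc,
                        n_closed_unocc, occ_i, occ_j, n_occ, tallies, n_pf,
                        flare, maxbond,
                    )
        elif x < r_arr + r_toff:
            x -= r_arr
            p = 0
            while p < n_pf - 1 and x >= toff_pf[p]:
                x -= toff_pf[p]
                p += 1
            h = length[p] - 1
            if gdp[p, h] == 0:
                n_gtp -= 1
            gdp[p, h] = 0
            left = (p - 1) % n_pf
            for i in (left, p):
                if bond[i, h]:
                    bond[i, h] = 0
                    nbonds_if[i] -= 1
                    if flare and maxbond[i] == h:
                        mb = -1
                        for jj in range(h - 1, -1, -1):
                            if bond[i, jj]:
                                mb = jj
                                break
                        old_mb = maxbond[i]
                        maxbond[i] = mb
                        n_occ = _refresh_interface_range(
                            i, mb + 1, old_mb, length, occ, origin, site_state,
                            n_edge_unocc, n_closed_unocc, occ_i, occ_j, n_occ,
                            tallies, n_pf, flare, maxbond,
                        )
            length[p] = h
            tallies[T_TUB_OFF] += 1
            for i in (left, p):
                for j in (h - 1, h):
                    n_occ = _refresh_site(
                        i, j, length, occ, origin, site_state, n_edge_unocc,
                        n_closed_unocc, occ_i, occ_j, n_occ, tallies, n_pf,
                        flare, maxbond,
                    )
        elif x < r_arr + r_toff + r_form:
            x -= r_arr + r_toff
            m = int(x / P[P_K_FORM])  # index among formable bonds
            i = 0
            while i < n_pf - 1:
                r = (i + 1) % n_pf
                cnt = min(length[i], length[r]) - nbonds_if[i]
                if m < cnt:
                    break
                m -= cnt
                i += 1
            r = (i + 1) % n_pf
            lo = min(length[i], length[r])
            j = -1
            seen = 0
            for jj in range(lo - 1, -1, -1):  # formable bonds cluster at the tip
                if bond[i, jj] == 0:
                    if seen == m:
                        j = jj
                        break
                    seen += 1
            if j >= 0:
                bond[i, j] = 1
                nbonds_if[i] += 1
                tallies[T_FORM] += 1
                if flare and j > maxbond[i]:
                    old_mb = maxbond[i]
                    maxbond[i] = j
                    n_occ = _refresh_interface_range(
                        i, old_mb + 1, j, length, occ, origin, site_state,
                        n_edge_unocc, n_closed_unocc, occ_i, occ_j, n_occ,
                        tallies, n_pf, flare, maxbond,
                    )
        elif x < r_arr + r_toff + r_form + r_break:
            x -= r_arr + r_toff + r_form
            m = int(x / k_break)
            i = 0
            while i < n_pf - 1:
                if m < nbonds_if[i]:
                    break
                m -= nbonds_if[i]
                i += 1
            j = -1
            seen = 0
            r = (i + 1) % n_pf
            lo = min(length[i], length[r])
            for jj in range(lo - 1, -1, -1):
                if bond[i, jj]:
                    if seen == m:
                        j = jj
                        break
                    seen += 1
            if j >= 0:
                bond[i, j] = 0
                nbonds_if[i] -= 1
                tallies[T_BREAK] += 1
                if flare and maxbond[i] == j:
                    mb = -1
                    for jj in range(j - 1, -1, -1):
                        if bond[i, jj]:
                            mb = jj
                            break
                    maxbond[i] = mb
                    n_occ = _refresh_interface_range(
                        i, mb + 1, j, length, occ, origin, site_state,
                        n_edge_unocc, n_closed_unocc, occ_i, occ_j, n_occ,
                        tallies, n_pf, flare, maxbond,
                    )
        elif x < r_arr + r_toff + r_form + r_break + r_on_edge + r_on_closed:
            x -= r_arr + r_toff + r_form + r_break
            if x < r_on_edge:
                cls = 1
                m = int(x / (P[P_K_ON_EDGE] * P[P_EB1_CONC]))
                counts = n_edge_unocc
            else:
                cls = 2
                m = int((x - r_on_edge) / (P[P_K_ON_CLOSED] * P[P_EB1_CONC]))
                counts = n_closed_unocc
            i = 0
            while i < n_pf - 1:
                if m < counts[i]:
                    break
                m -= counts[i]
                i += 1
            r = (i + 1) % n_pf
            top = max(length[i], length[r])
            j = -1
            seen = 0
            for jj in range(top - 1, -1, -1):
                if site_state[i, jj] == cls and occ[i, jj] == 0:
                    if seen == m:
                        j = jj
                        break
                    seen += 1
            if j >= 0 and n_occ < occ_i.shape[0]:
                occ[i, j] = 1
                origin[i, j] = cls
                occ_i[n_occ] = i
                occ_j[n_occ] = j
                n_occ += 1
                counts[i] -= 1
                if cls == 1:
                    tallies[T_EB1_ON_EDGE] += 1
                else:
                    tallies[T_EB1_ON_CLOSED] += 1
        else:
            x -= r_arr + r_toff + r_form + r_break + r_on_edge + r_on_closed
            k = 0
            while k < n_occ - 1 and x >= off_rates[k]:
                x -= off_rates[k]
                k += 1
            i = occ_i[k]
            j = occ_j[k]
            occ[i, j] = 0
            origin[i, j] = 0
            occ_i[k] = occ_i[n_occ - 1]
            occ_j[k] = occ_j[n_occ - 1]
            n_occ -= 1
            if site_state[i, j] == 1:
                n_edge_unocc[i] += 1
            else:
                n_closed_unocc[i] += 1
            tallies[T_EB1_OFF] += 1

        # ---- hydrolysis sub-step ------------------------------------ #
        if n_gtp > 0 and P[P_K_HYD] > 0.0:
            t_hyd = -np.log(1.0 - np.random.random()) / (P[P_K_HYD] * n_gtp)
            if t_hyd < dt:
                total_nonseed = 0
                for p in range(n_pf):
                    total_nonseed += length[p] - seed_len
                while True:
                    m = int(np.random.random() * total_nonseed)
                    p = 0
                    while p < n_pf - 1 and m >= length[p] - seed_len:
                        m -= length[p] - seed_len
                        p += 1
                    j = seed_len + m
                    if j < length[p] and gdp[p, j] == 0:
                        gdp[p, j] = 1
                        n_gtp -= 1
                        tallies[T_HYDROLYSIS] += 1
                        break

        # ---- catastrophe rule --------------------------------------- #
        mx = 0
        mn1 = 1 << 60
        mn2 = 1 << 60
        tot_len = 0
        for p in range(n_pf):
            L = length[p]
            tot_len += L
            if L > mx:
                mx = L
            if L < mn1:
                mn2 = mn1
                mn1 = L
            elif L < mn2:
                mn2 = L
        new_boost = (mx - mn2) > int(P[P_MAX_TAPER])
        if new_boost != boosted:
            boosted = new_boost
            if n_boost < boost_times.shape[0]:
                boost_times[n_boost] = t
                boost_flags[n_boost] = 1 if boosted else 0
                n_boost += 1
            if (
                boosted
                and stop_cat_dimers > 0
                and tot_len >= n_pf * stop_cat_dimers
            ):
                status = STATUS_CATASTROPHE
                break

        # ---- snapshot recording ------------------------------------- #
        if step % record_interval == 0:
            if n_snap >= max_snap:
                status = STATUS_STORE_FULL
                break
            snap_time[n_snap] = t
            for p in range(n_pf):
                snap_len[n_snap, p] = length[p]
            c_cg = 0
            c_cd = 0
            c_eg = 0
            c_ed = 0
            occ_offsets[n_snap] = occ_ptr
            for k in range(n_occ):
                i = occ_i[k]
                j = occ_j[k]
                r = (i + 1) % n_pf
                is_gdp = gdp[i, j] | gdp[r, j]
                if site_state[i, j] == 2:
                    if is_gdp:
                        c_cd += 1
                    else:
                        c_cg += 1
                else:
                    if is_gdp:
                        c_ed += 1
                    else:
                        c_eg += 1
                if occ_ptr < occ_store_cap:
                    occ_store_i[occ_ptr] = i
                    occ_store_j[occ_ptr] = j
                    occ_store_orig[occ_ptr] = origin[i, j]
                    occ_ptr += 1
            snap_counts[n_snap, 0] = c_cg
            snap_counts[n_snap, 1] = c_cd
            snap_counts[n_snap, 2] = c_eg
            snap_counts[n_snap, 3] = c_ed
            for k in range(N_TALLIES):
                snap_tallies[n_snap, k] = tallies[k]
            gtp_offsets[n_snap] = gtp_ptr
            for p in range(n_pf):
                for j in range(seed_len, length[p]):
                    if gdp[p, j] == 0 and gtp_ptr < gtp_store_cap:
                        gtp_store_p[gtp_ptr] = p
                        gtp_store_j[gtp_ptr] = j
                        gtp_ptr += 1
            n_snap += 1

    occ_offsets[n_snap] = occ_ptr
    gtp_offsets[n_snap] = gtp_ptr
    return status, n_snap, n_boost, t, tallies
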