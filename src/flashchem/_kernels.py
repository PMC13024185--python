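"""Numba kernels for the independent-reaction-times engine.

Everything here works on packed integer/float arrays prepared by
:mod:`flashchem.irt`.  The kernels are deliberately free of Python objects:
a single event-driven loop samples first-passage reaction times for all
eligible particle pairs and continuum scavenging channels, processes events
in time order, and spawns products that are re-sampled against the survivors.

Distances are in nm, times in ns, rates in 1/ns.  The segment is periodic
along the beam (Y) axis.  The inverse complementary error function is
implemented locally (rational approximation + one Newton refinement against
math.erfc) because scipy.special is not callable from nopython code; it is
validated against scipy in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: time offset used for "already in contact" events
EPS_T = 1e-9

_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _rnd(state) -> float:
    """xorshift128+ uniform draw in (0, 1]; state is a uint64[2] array."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 = s1 ^ s0 ^ (s1 >> np.uint64(18)) ^ (s0 >> np.uint64(5))
    state[1] = s1
    return float(((s1 + s0) >> np.uint64(11)) + np.uint64(1)) * _INV_2_53


@njit(cache=True, inline="always")
def _randn3(state):
    """Three independent standard normals (Box-Muller on xorshift draws)."""
    u1 = _rnd(state)
    u2 = _rnd(state)
    u3 = _rnd(state)
    u4 = _rnd(state)
    r1 = math.sqrt(-2.0 * math.log(u1))
    r2 = math.sqrt(-2.0 * math.log(u3))
    return (r1 * math.cos(2.0 * math.pi * u2),
            r1 * math.sin(2.0 * math.pi * u2),
            r2 * math.cos(2.0 * math.pi * u4))


@njit(cache=True)
def _seed_state(seed: int):
    state = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for k in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        w = (w ^ (w >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        w = w ^ (w >> np.uint64(31))
        state[k] = w | np.uint64(1)
    return state

# ---------------------------------------------------------------------------
# inverse error function machinery

_A = (-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
      1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00)
_B = (-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
      6.680131188771972e+01, -1.328068155288572e+01)
_C = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
      -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00)
_D = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
      3.754408661907416e+00)

_SQRT_PI_OVER_2 = math.sqrt(math.pi) / 2.0


@njit(cache=True)
def _ndtri(p: float) -> float:
    """Standard-normal quantile (Acklam rational approximation), p in (0, 0.5]."""
    if p < 0.02425:
        q = math.sqrt(-2.0 * math.log(p))
        return (((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4]) * q + _C[5]) / \
               ((((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1.0)
    q = p - 0.5
    r = q * q
    return (((((_A[0] * r + _A[1]) * r + _A[2]) * r + _A[3]) * r + _A[4]) * r + _A[5]) * q / \
           (((((_B[0] * r + _B[1]) * r + _B[2]) * r + _B[3]) * r + _B[4]) * r + 1.0)


@njit(cache=True)
def erfcinv(y: float) -> float:
    """Inverse of erfc on (0, 2); refined to ~1e-14 with one Newton step."""
    x = -_ndtri(0.5 * y) / math.sqrt(2.0) if y <= 1.0 else _ndtri(0.5 * (2.0 - y)) / math.sqrt(2.0)
    # Newton refinement: d erfc/dx = -2/sqrt(pi) exp(-x^2)
    for _ in range(2):
        err = math.erfc(x) - y
        x += err * _SQRT_PI_OVER_2 * math.exp(min(700.0, x * x))
    return x


# ---------------------------------------------------------------------------
# heap utilities (parallel-array binary min-heap keyed on time)

@njit(cache=True, inline="always")
def _pack(i, j, r):
    # i, j < 2^24; r < 2^15; j = -1 encoded as 0
    return (np.int64(i) << np.int64(40)) | (np.int64(j + 1) << np.int64(16)) | np.int64(r)


@njit(cache=True)
def _heap_push(ht, hp, hn, t, payload):
    k = hn
    ht[k] = t
    hp[k] = payload
    while k > 0:
        parent = (k - 1) >> 1
        if ht[k] < ht[parent]:
            ht[k], ht[parent] = ht[parent], ht[k]
            hp[k], hp[parent] = hp[parent], hp[k]
            k = parent
        else:
            break


@njit(cache=True)
def _heap_pop(ht, hp, hn):
    t = ht[0]
    payload = hp[0]
    hn -= 1
    ht[0] = ht[hn]
    hp[0] = hp[hn]
    k = 0
    while True:
        left = 2 * k + 1
        if left >= hn:
            break
        small = left
        right = left + 1
        if right < hn and ht[right] < ht[left]:
            small = right
        if ht[small] < ht[k]:
            ht[k], ht[small] = ht[small], ht[k]
            hp[k], hp[small] = hp[small], hp[k]
            k = small
        else:
            break
    return t, payload


# ---------------------------------------------------------------------------
# pair-time sampling

@njit(cache=True, inline="always")
def _debye_x(qrc: float, r: float) -> float:
    """Debye-transformed separation; identity for neutral pairs."""
    if qrc == 0.0:
        return r
    return qrc / math.expm1(qrc / r)


@njit(cache=True, fastmath=True, inline="always")
def _pair_candidate_u(d2: float, reff: float, dsum: float, qrc: float,
                      urej2: float, horizon: float, u: float) -> float:
    """Pair waiting time given a pre-drawn uniform u (nested rejection must
    reuse the same draw to stay unbiased).

    ``urej2`` = (R_eff + m)^2 with m >= r0 - x(r0) (m = max(0.5, |q r_c|)):
    since W_inf = R_eff/x(r0) <= R_eff/(r0 - m), a draw u with
    u^2 d2 >= urej2 >= (R_eff + u m)^2 can never react and is rejected
    without sqrt/expm1/erfcinv work.
    """
    if u * u * d2 >= urej2:
        return -1.0
    r0 = math.sqrt(d2)
    if r0 < 1e-9:
        return EPS_T
    x = _debye_x(qrc, r0)
    if x <= reff:
        return EPS_T
    if u >= reff / x:
        return -1.0
    arg = erfcinv(u * x / reff)
    if arg <= 0.0:
        return -1.0
    dt = ((x - reff) / arg) ** 2 / (4.0 * dsum)
    if dt > horizon:
        return -1.0
    return dt if dt > EPS_T else EPS_T


@njit(cache=True, fastmath=True, inline="always")
def _pair_candidate(d2: float, reff: float, dsum: float, qrc: float,
                    urej2: float, horizon: float, state) -> float:
    return _pair_candidate_u(d2, reff, dsum, qrc, urej2, horizon, _rnd(state))


@njit(cache=True, inline="always")
def _cell_coord(x: float, lo: float, size: float, ncells: int) -> int:
    c = int((x - lo) / size)
    if c < 0:
        return 0
    if c >= ncells:
        return ncells - 1
    return c


@njit(cache=True, fastmath=True)
def run_irt_kernel(
    pos0,            # (n0, 3) float64
    sp0,             # (n0,) int32
    diff,            # (ns,) float64 nm^2/ns
    scav_total,      # (ns,) float64 1/ns
    scav_cum,        # (ns, mc) float64 cumulative channel probabilities
    scav_rid,        # (ns, mc) int32 reaction row per channel
    pair_rxn,        # (ns, ns) int32 reaction row or -1
    pair_reff,       # (ns, ns) float64 effective radius nm
    pair_dsum,       # (ns, ns) float64 summed D nm^2/ns
    pair_qrc,        # (ns, ns) float64 z1 z2 * Onsager radius nm
    pair_cut2,       # (ns, ns) float64 squared candidate cutoff nm^2
    pair_urej2,      # (ns, ns) float64 squared early-rejection radius nm^2
    spawn_sp,        # (nrxn, 4) int32 species codes to spawn, -1 padded
    cell_start,      # (ncx*ncz + 1,) int64; initial particles sorted by cell
    cell_size: float,
    xmin: float,
    zmin: float,
    ncx: int,
    ncz: int,
    t_start: float,  # ns (birth time of the pulse, 1 ps)
    t_switch: float,  # ns
    period_y: float,  # nm
    seed: int,
    age_partners: bool,
):
    """Event-driven IRT from t_start to t_switch.

    The initial inventory arrives sorted by (x, z) cell, with contiguous
    per-cell ranges in ``cell_start``; the cell size bounds the candidate
    reach, so scanning the 3x3 neighbourhood is exhaustive.  Products are
    held in per-cell linked lists.

    ``age_partners``: if True, separations between newborn products and older
    survivors are aged by the survivor's diffusion since birth (slightly more
    faithful, considerably slower); the default convention samples against
    stored positions (no retroactive re-draws).

    Returns (event_times, event_rxn, alive_species_codes).
    """
    state = _seed_state(seed)
    n0 = pos0.shape[0]
    ns = diff.shape[0]
    cap = n0 * 4 + 64
    pos = np.empty((cap, 3), dtype=np.float64)
    sp = np.empty(cap, dtype=np.int32)
    alive = np.zeros(cap, dtype=np.bool_)
    born = np.empty(cap, dtype=np.float64)
    pos[:n0] = pos0
    sp[:n0] = sp0
    alive[:n0] = True
    born[:n0] = t_start
    n = n0

    # per-pair-type diffusive reach factor for horizon-shrunk rescan cutoffs
    cutfac = np.empty((ns, ns), dtype=np.float64)
    for a in range(ns):
        for b in range(ns):
            cutfac[a, b] = 3.0 * math.sqrt(4.0 * pair_dsum[a, b])

    # per-cell linked lists for newborn products
    nb_head = np.full(ncx * ncz, -1, dtype=np.int32)
    nxt = np.full(cap, -1, dtype=np.int32)

    hcap = 8 * n0 + 1024
    ht = np.empty(hcap, dtype=np.float64)
    hp = np.empty(hcap, dtype=np.int64)
    hn = 0

    ecap = 2 * n0 + 256
    ev_t = np.empty(ecap, dtype=np.float64)
    ev_r = np.empty(ecap, dtype=np.int32)
    ne = 0

    half_y = 0.5 * period_y
    horizon0 = t_switch - t_start

    # --- scavenging times for the initial inventory
    for i in range(n0):
        s = sp[i]
        tot = scav_total[s]
        if tot > 0.0:
            t = t_start - math.log(_rnd(state)) / tot
            if t <= t_switch:
                u = _rnd(state)
                mc = scav_cum.shape[1]
                rid = scav_rid[s, 0]
                for c in range(mc):
                    if u <= scav_cum[s, c]:
                        rid = scav_rid[s, c]
                        break
                if hn >= ht.shape[0]:
                    ht, hp = _grow_heap(ht, hp)
                _heap_push(ht, hp, hn, t, _pack(i, -1, rid))
                hn += 1

    # --- initial pair candidates (3x3 cell ranges; j < i avoids doubles)
    for i in range(n0):
        sa = sp[i]
        rxn_row = pair_rxn[sa]
        reff_row = pair_reff[sa]
        dsum_row = pair_dsum[sa]
        qrc_row = pair_qrc[sa]
        cut2_row = pair_cut2[sa]
        urej2_row = pair_urej2[sa]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        cxi = _cell_coord(xi, xmin, cell_size, ncx)
        czi = _cell_coord(zi, zmin, cell_size, ncz)
        for cx in range(max(0, cxi - 1), min(ncx, cxi + 2)):
            for cz in range(max(0, czi - 1), min(ncz, czi + 2)):
                cell = cx * ncz + cz
                j_hi = cell_start[cell + 1]
                if cell_start[cell] >= i:
                    continue
                if j_hi > i:
                    j_hi = i
                for j in range(cell_start[cell], j_hi):
                    sb = sp[j]
                    r = rxn_row[sb]
                    if r < 0:
                        continue
                    dx = pos[j, 0] - xi
                    dy = pos[j, 1] - yi
                    if dy > half_y:
                        dy -= period_y
                    elif dy < -half_y:
                        dy += period_y
                    dz = pos[j, 2] - zi
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 > cut2_row[sb]:
                        continue
                    dt = _pair_candidate(
                        d2, reff_row[sb], dsum_row[sb], qrc_row[sb],
                        urej2_row[sb], horizon0, state,
                    )
                    if dt < 0.0:
                        continue
                    if hn >= ht.shape[0]:
                        ht, hp = _grow_heap(ht, hp)
                    _heap_push(ht, hp, hn, t_start + dt, _pack(i, j, r))
                    hn += 1

    # --- event loop
    while hn > 0:
        t, payload = _heap_pop(ht, hp, hn)
        hn -= 1
        i = np.int64(payload) >> np.int64(40)
        j = ((payload >> np.int64(16)) & np.int64(0xFFFFFF)) - 1
        r = payload & np.int64(0xFFFF)

        if not alive[i]:
            continue
        if j >= 0 and not alive[j]:
            continue
        if t > t_switch:
            break

        if ne >= ev_t.shape[0]:
            ev_t2 = np.empty(ev_t.shape[0] * 2, dtype=np.float64)
            ev_r2 = np.empty(ev_t.shape[0] * 2, dtype=np.int32)
            ev_t2[:ne] = ev_t[:ne]
            ev_r2[:ne] = ev_r[:ne]
            ev_t = ev_t2
            ev_r = ev_r2
        ev_t[ne] = t
        ev_r[ne] = np.int32(r)
        ne += 1

        alive[i] = False
        px = pos[i, 0]
        py = pos[i, 1]
        pz = pos[i, 2]
        if j < 0:
            # scavenging / first-order decay is spatially homogeneous, so the
            # particle's position at death is free diffusion from its birth
            var = 2.0 * diff[sp[i]] * (t - born[i])
            if var > 0.0:
                sd = math.sqrt(var)
                gx, gy, gz = _randn3(state)
                px += sd * gx
                py += sd * gy
                pz += sd * gz
                if py < 0.0:
                    py = py % period_y
                elif py >= period_y:
                    py = py % period_y
        if j >= 0:
            alive[j] = False
            da = diff[sp[i]]
            db = diff[sp[j]]
            tot = da + db
            w = 0.5 if tot <= 0.0 else da / tot
            dx = pos[j, 0] - px
            dy = pos[j, 1] - py
            if dy > half_y:
                dy -= period_y
            elif dy < -half_y:
                dy += period_y
            dz = pos[j, 2] - pz
            px += w * dx
            py += w * dy
            pz += w * dz
            # the pair's centre-of-diffusion coordinate diffuses freely
            # (independently of the relative coordinate that hit contact):
            # spread the encounter point accordingly
            if tot > 0.0:
                var = 2.0 * (da * db / tot) * (t - max(born[i], born[j]))
                if var > 0.0:
                    sd = math.sqrt(var)
                    gx, gy, gz = _randn3(state)
                    px += sd * gx
                    py += sd * gy
                    pz += sd * gz
            if py < 0.0:
                py = py % period_y
            elif py >= period_y:
                py = py % period_y

        sqrt_h = math.sqrt(t_switch - t) if t_switch > t else 0.0

        for kprod in range(4):
            s_new = spawn_sp[np.int32(r), kprod]
            if s_new < 0:
                break
            if n >= pos.shape[0]:
                pos2 = np.empty((pos.shape[0] * 2, 3), dtype=np.float64)
                sp2 = np.empty(pos.shape[0] * 2, dtype=np.int32)
                alive2 = np.zeros(pos.shape[0] * 2, dtype=np.bool_)
                born2 = np.empty(pos.shape[0] * 2, dtype=np.float64)
                nxt2 = np.full(pos.shape[0] * 2, -1, dtype=np.int32)
                pos2[:n] = pos[:n]
                sp2[:n] = sp[:n]
                alive2[:n] = alive[:n]
                born2[:n] = born[:n]
                nxt2[:n] = nxt[:n]
                pos = pos2
                sp = sp2
                alive = alive2
                born = born2
                nxt = nxt2
            k = n
            n += 1
            pos[k, 0] = px
            pos[k, 1] = py
            pos[k, 2] = pz
            sp[k] = s_new
            alive[k] = True
            born[k] = t

            # scavenging for the newborn
            tot = scav_total[s_new]
            if tot > 0.0:
                ts = t - math.log(_rnd(state)) / tot
                if ts <= t_switch:
                    u = _rnd(state)
                    mc = scav_cum.shape[1]
                    rid = scav_rid[s_new, 0]
                    for c in range(mc):
                        if u <= scav_cum[s_new, c]:
                            rid = scav_rid[s_new, c]
                            break
                    if hn >= ht.shape[0]:
                        ht, hp = _grow_heap(ht, hp)
                    _heap_push(ht, hp, hn, ts, _pack(k, -1, rid))
                    hn += 1

            # pair candidates newborn vs survivors in the 3x3 neighbourhood
            # (initial members are contiguous ranges; newborns chained)
            rxn_row = pair_rxn[s_new]
            reff_row = pair_reff[s_new]
            dsum_row = pair_dsum[s_new]
            qrc_row = pair_qrc[s_new]
            cut2_row = pair_cut2[s_new]
            urej2_row = pair_urej2[s_new]
            fac_row = cutfac[s_new]
            horizon = t_switch - t
            cxi = _cell_coord(px, xmin, cell_size, ncx)
            czi = _cell_coord(pz, zmin, cell_size, ncz)
            for cx in range(max(0, cxi - 1), min(ncx, cxi + 2)):
                for cz in range(max(0, czi - 1), min(ncz, czi + 2)):
                    cell = cx * ncz + cz
                    m = cell_start[cell]
                    chained = False
                    while True:
                        if not chained:
                            if m >= cell_start[cell + 1]:
                                m = nb_head[cell]
                                chained = True
                                if m < 0:
                                    break
                        elif m < 0:
                            break
                        idx = m
                        m = nxt[idx] if chained else m + 1
                        if idx == k or not alive[idx]:
                            continue
                        sb = sp[idx]
                        rr = rxn_row[sb]
                        if rr < 0:
                            continue
                        dx = pos[idx, 0] - px
                        dy = pos[idx, 1] - py
                        if dy > half_y:
                            dy -= period_y
                        elif dy < -half_y:
                            dy += period_y
                        dz = pos[idx, 2] - pz
                        d2 = dx * dx + dy * dy + dz * dz
                        if age_partners:
                            age_var = 2.0 * diff[sb] * (t - born[idx])
                            s_age = math.sqrt(3.0 * age_var)
                            cut = reff_row[sb] + fac_row[sb] * sqrt_h + 3.0 * s_age
                            if d2 > cut * cut:
                                continue
                            u = _rnd(state)
                            r_lb = math.sqrt(d2) - 3.0 * s_age
                            if r_lb > 0.0 and u * u * r_lb * r_lb >= urej2_row[sb]:
                                continue
                            if age_var > 0.0:
                                sd = math.sqrt(age_var)
                                gx, gy, gz = _randn3(state)
                                ax = dx + sd * gx
                                ay = dy + sd * gy
                                az = dz + sd * gz
                                d2 = ax * ax + ay * ay + az * az
                        else:
                            cut = reff_row[sb] + fac_row[sb] * sqrt_h
                            if d2 > cut * cut:
                                continue
                            u = _rnd(state)
                        dtp = _pair_candidate_u(
                            d2, reff_row[sb], dsum_row[sb], qrc_row[sb],
                            urej2_row[sb], horizon, u,
                        )
                        if dtp < 0.0:
                            continue
                        if hn >= ht.shape[0]:
                            ht, hp = _grow_heap(ht, hp)
                        _heap_push(ht, hp, hn, t + dtp, _pack(k, idx, rr))
                        hn += 1
            # register the newborn in its cell's chain
            cell = cxi * ncz + czi
            nxt[k] = nb_head[cell]
            nb_head[cell] = k

    return ev_t[:ne].copy(), ev_r[:ne].copy(), sp[:n][alive[:n]].copy()


@njit(cache=True)
def _grow_heap(ht, hp):
    new = ht.shape[0] * 2
    ht2 = np.empty(new, dtype=np.float64)
    hp2 = np.empty(new, dtype=np.int64)
    ht2[:ht.shape[0]] = ht
    hp2[:ht.shape[0]] = hp
    return ht2, hp2


# ---------------------------------------------------------------------------
# step-by-step random-walk reference (test oracle)

@njit(cache=True, fastmath=True)
def random_walk_kernel(
    pos0, sp0, diff,
    scav_total, scav_cum, scav_rid,
    pair_rxn, pair_radius, pair_paccept,
    spawn_sp,
    t_start, t_switch, period_y, dt, seed,
):
    """Brute-force diffusion/reaction simulation (small n only).

    Particles take Gaussian steps of variance 2 D dt per axis; pairs react on
    encounter of the effective absorbing sphere (with a Brownian-bridge
    crossing correction between steps); continuum scavenging fires with
    probability 1 - exp(-k S dt) per step.  This emulates exactly the
    effective-radius model the IRT kernel samples, so discrepancies measure
    the IRT method's many-body approximations, not model differences.
    Returns (event_times, event_rxn, alive_species_codes).
    """
    np.random.seed(seed)
    n0 = pos0.shape[0]
    cap = n0 * 6 + 64
    pos = np.empty((cap, 3), dtype=np.float64)
    sp = np.empty(cap, dtype=np.int32)
    alive = np.zeros(cap, dtype=np.bool_)
    pos[:n0] = pos0
    sp[:n0] = sp0
    alive[:n0] = True
    n = n0

    ev_t = np.empty(4 * cap, dtype=np.float64)
    ev_r = np.empty(4 * cap, dtype=np.int32)
    ne = 0
    half_y = 0.5 * period_y

    nsteps = int(math.ceil((t_switch - t_start) / dt))
    old = np.empty((cap, 3), dtype=np.float64)

    for step in range(nsteps):
        t_now = t_start + step * dt
        t_next = min(t_now + dt, t_switch)
        h = t_next - t_now

        # remember pre-step positions for the bridge correction
        for i in range(n):
            if alive[i]:
                old[i, 0] = pos[i, 0]
                old[i, 1] = pos[i, 1]
                old[i, 2] = pos[i, 2]

        # diffuse
        for i in range(n):
            if not alive[i]:
                continue
            sd = math.sqrt(2.0 * diff[sp[i]] * h)
            if sd > 0.0:
                pos[i, 0] += sd * np.random.standard_normal()
                pos[i, 1] += sd * np.random.standard_normal()
                pos[i, 2] += sd * np.random.standard_normal()
            if pos[i, 1] < 0.0:
                pos[i, 1] = pos[i, 1] % period_y
            elif pos[i, 1] >= period_y:
                pos[i, 1] = pos[i, 1] % period_y

        # pair encounters
        for i in range(n):
            if not alive[i]:
                continue
            for j in range(i + 1, n):
                if not alive[j] or not alive[i]:
                    continue
                r = pair_rxn[sp[i], sp[j]]
                if r < 0:
                    continue
                radius = pair_radius[sp[i], sp[j]]
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                if dy > half_y:
                    dy -= period_y
                elif dy < -half_y:
                    dy += period_y
                dz = pos[j, 2] - pos[i, 2]
                d_new = math.sqrt(dx * dx + dy * dy + dz * dz)
                hit = d_new <= radius
                if not hit:
                    ox = old[j, 0] - old[i, 0]
                    oy = old[j, 1] - old[i, 1]
                    if oy > half_y:
                        oy -= period_y
                    elif oy < -half_y:
                        oy += period_y
                    oz = old[j, 2] - old[i, 2]
                    d_old = math.sqrt(ox * ox + oy * oy + oz * oz)
                    if d_old > radius:
                        dsum = diff[sp[i]] + diff[sp[j]]
                        if dsum > 0.0:
                            pb = math.exp(
                                -(d_old - radius) * (d_new - radius) / (dsum * h)
                            )
                            hit = np.random.random() < pb
                if hit and np.random.random() < pair_paccept[sp[i], sp[j]]:
                    ev_t[ne] = t_next
                    ev_r[ne] = r
                    ne += 1
                    alive[i] = False
                    alive[j] = False
                    da = diff[sp[i]]
                    db = diff[sp[j]]
                    w = 0.5 if da + db <= 0.0 else da / (da + db)
                    px = pos[i, 0] + w * dx
                    py = pos[i, 1] + w * dy
                    pz = pos[i, 2] + w * dz
                    for kprod in range(4):
                        s_new = spawn_sp[r, kprod]
                        if s_new < 0:
                            break
                        pos[n, 0] = px
                        pos[n, 1] = py % period_y
                        pos[n, 2] = pz
                        sp[n] = s_new
                        alive[n] = True
                        n += 1
                    break

        # continuum scavenging
        for i in range(n):
            if not alive[i]:
                continue
            tot = scav_total[sp[i]]
            if tot <= 0.0:
                continue
            if np.random.random() < 1.0 - math.exp(-tot * h):
                u = np.random.random()
                mc = scav_cum.shape[1]
                rid = scav_rid[sp[i], 0]
                for c in range(mc):
                    if u <= scav_cum[sp[i], c]:
                        rid = scav_rid[sp[i], c]
                        break
                ev_t[ne] = t_next
                ev_r[ne] = rid
                ne += 1
                alive[i] = False
                for kprod in range(4):
                    s_new = spawn_sp[rid, kprod]
                    if s_new < 0:
                        break
                    pos[n, 0] = pos[i, 0]
                    pos[n, 1] = pos[i, 1]
                    pos[n, 2] = pos[i, 2]
                    sp[n] = s_new
                    alive[n] = True
                    n += 1

    return ev_t[:ne].copy(), ev_r[:ne].copy(), sp[:n][alive[:n]].copy()
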