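"""Compiled MCMC core.

One iteration is a systematic sweep: every latent state (species in
topological order, sites in order) is redrawn from its exact full
conditional on a truncated support, then every regression/interaction
coefficient takes one adaptive random-walk Metropolis step.  The latent
full conditional is normalized by explicit enumeration over 0..N_max
(0..1 for occupancy states), including the state-density terms of all
downstream species in which the value appears; the scan stops early once
the log-mass has fallen 34 nats below the running maximum and is
decreasing, which bounds the neglected tail well below any tolerance used
elsewhere in the package.

When every submodel is intercept-only (no covariates, year dummies or
interaction modifiers), sites with equal sufficient statistics and equal
neighbouring latent states share the same full conditional.  The kernel
then computes each distinct conditional once per sweep and draws all
matching sites from it, and pools likelihood sums over those equivalence
classes in the Metropolis steps.  The collapsed path performs exactly the
same arithmetic on representative sites and consumes the random stream in
the same order, so chains are bit-identical to the generic path.

Everything here is plain arrays so numba can compile it; the translation
from ModelGraph/DetectionData lives in :mod:`abundint.samplers`.
"""

import math

import numpy as np
from numba import njit

_EPS = 1e-12
_NEG_INF = -np.inf
_DROP = 34.0  # nats below the max at which the support scan stops
_FM = {"contract", "reassoc", "nsz", "arcp"}


@njit(inline="always", cache=True, fastmath=_FM)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(inline="always", cache=True, fastmath=_FM)
def _log_sigmoid(x):
    if x > 0.0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


@njit(inline="always", cache=True)
def _contrib(e, i, theta, lat, e_src, e_g0, e_g1, e_ind, e_mod):
    f = float(lat[e_src[e], i])
    if e_ind[e] == 1 and f > 0.0:
        f = 1.0
    g = theta[e_g0[e]]
    if e_g1[e] >= 0:
        g += theta[e_g1[e]] * e_mod[e, i]
    return g * f


@njit(inline="always", cache=True)
def _edge_gain(e, i, theta, e_g0, e_g1, e_mod):
    g = theta[e_g0[e]]
    if e_g1[e] >= 0:
        g += theta[e_g1[e]] * e_mod[e, i]
    return g


@njit(inline="always", cache=True, fastmath=_FM)
def _eta(s, i, theta, lat, X, nC, par, ptr, idx, e_src, e_g0, e_g1, e_ind, e_mod):
    v = 0.0
    for k in range(nC[s]):
        v += X[s, i, k] * theta[par[s, k]]
    for q in range(ptr[s], ptr[s + 1]):
        v += _contrib(idx[q], i, theta, lat, e_src, e_g0, e_g1, e_ind, e_mod)
    return v


@njit(inline="always", cache=True, fastmath=_FM)
def _state_logdens(kind, val, eta, lgam):
    if kind == 0:
        return val * eta - math.exp(eta) - lgam[int(val)]
    if val > 0:
        return _log_sigmoid(eta)
    return _log_sigmoid(-eta)


@njit(inline="always", cache=True, fastmath=_FM)
def _obs_loglik(kind, nval, eta_d, Yv, Tv):
    if Tv <= 0.0:
        return 0.0
    if nval == 0:
        if Yv > 0.0:
            return _NEG_INF
        return 0.0
    p = _sigmoid(eta_d)
    if p < _EPS:
        p = _EPS
    elif p > 1.0 - _EPS:
        p = 1.0 - _EPS
    if kind == 0:
        l1mp = math.log1p(-p)
        if Yv == 0.0:
            return Tv * nval * l1mp
        pe = -math.expm1(nval * l1mp)
        if pe < _EPS:
            pe = _EPS
        return Yv * math.log(pe) + (Tv - Yv) * nval * l1mp
    return Yv * math.log(p) + (Tv - Yv) * math.log1p(-p)


@njit(cache=True, fastmath=_FM)
def _site_loglik(s, which, i, theta, lat, state_kind, Xs, nP, spar, Xd, nQ, dpar,
                 ins_ptr, ins_idx, ind_ptr, ind_idx,
                 e_src, e_g0, e_g1, e_ind, e_mod, Y, T, lgam):
    """State (which=0) or observation (which=1) log-density of species s
    at one site, at the current latent configuration."""
    kind = state_kind[s]
    if which == 0:
        eta = _eta(s, i, theta, lat, Xs, nP, spar, ins_ptr, ins_idx,
                   e_src, e_g0, e_g1, e_ind, e_mod)
        return _state_logdens(kind, float(lat[s, i]), eta, lgam)
    eta = _eta(s, i, theta, lat, Xd, nQ, dpar, ind_ptr, ind_idx,
               e_src, e_g0, e_g1, e_ind, e_mod)
    return _obs_loglik(kind, lat[s, i], eta, Y[s, i], T[s, i])


@njit(cache=True, fastmath=_FM)
def _species_loglik(s, which, theta, lat, state_kind, Xs, nP, spar, Xd, nQ, dpar,
                    ins_ptr, ins_idx, ind_ptr, ind_idx,
                    e_src, e_g0, e_g1, e_ind, e_mod, Y, T, lgam):
    """Sum of _site_loglik over all sites."""
    I = Xs.shape[1]
    total = 0.0
    for i in range(I):
        total += _site_loglik(s, which, i, theta, lat, state_kind, Xs, nP, spar,
                              Xd, nQ, dpar, ins_ptr, ins_idx, ind_ptr, ind_idx,
                              e_src, e_g0, e_g1, e_ind, e_mod, Y, T, lgam)
    return total


@njit(cache=True, fastmath=_FM)
def _site_cond_row(
    s, i, theta, lat, kind, hi,
    state_kind, Xs, nP, spar, Xd, nQ, dpar,
    e_src, e_tgt, e_sub, e_g0, e_g1, e_ind, e_mod,
    ins_ptr, ins_idx, ind_ptr, ind_idx, out_ptr, out_idx,
    Y, T, anydet, lgam, row, base_e, gain_e, N_max, full_scan,
):
    """Unnormalized full-conditional weights of lat[s, i] over its support.

    Fills row[lo..hi_used] with exp(logmass - max) and returns
    (lo, hi_used, total, trunc): total <= 0 signals that the conditional
    lost all mass.  trunc is 1 when the weight at N_max carries more than
    1e-6 of the mass (truncation warning).  ``full_scan`` disables the
    early-termination scan.
    """
    lo = 1 if anydet[s, i] == 1 else 0
    eta_s = _eta(s, i, theta, lat, Xs, nP, spar, ins_ptr, ins_idx,
                 e_src, e_g0, e_g1, e_ind, e_mod)
    eta_d = _eta(s, i, theta, lat, Xd, nQ, dpar, ind_ptr, ind_idx,
                 e_src, e_g0, e_g1, e_ind, e_mod)
    Yv = Y[s, i]
    Tv = T[s, i]
    r = _sigmoid(eta_d)
    if r < _EPS:
        r = _EPS
    elif r > 1.0 - _EPS:
        r = 1.0 - _EPS
    l1mr = math.log1p(-r)
    n_out = out_ptr[s + 1] - out_ptr[s]
    for w in range(n_out):
        e = out_idx[out_ptr[s] + w]
        t = e_tgt[e]
        if e_sub[e] == 0:
            full = _eta(t, i, theta, lat, Xs, nP, spar, ins_ptr, ins_idx,
                        e_src, e_g0, e_g1, e_ind, e_mod)
        else:
            full = _eta(t, i, theta, lat, Xd, nQ, dpar, ind_ptr, ind_idx,
                        e_src, e_g0, e_g1, e_ind, e_mod)
        base_e[e] = full - _contrib(e, i, theta, lat, e_src, e_g0, e_g1, e_ind, e_mod)
        gain_e[e] = _edge_gain(e, i, theta, e_g0, e_g1, e_mod)
    lp_max = _NEG_INF
    hi_used = hi
    for n in range(lo, hi + 1):
        if kind == 0:
            v = n * eta_s - lgam[n]  # Poisson, constant -lambda dropped
            if n == 0:
                if Yv > 0.0:
                    v = _NEG_INF
            elif Tv > 0.0:
                if Yv == 0.0:
                    v += Tv * n * l1mr
                else:
                    pe = -math.expm1(n * l1mr)
                    if pe < _EPS:
                        pe = _EPS
                    v += Yv * math.log(pe) + (Tv - Yv) * n * l1mr
        else:
            v = _log_sigmoid(eta_s) if n == 1 else _log_sigmoid(-eta_s)
            v += _obs_loglik(1, n, eta_d, Yv, Tv)
        if v > _NEG_INF:
            for w in range(n_out):
                e = out_idx[out_ptr[s] + w]
                t = e_tgt[e]
                f = float(n)
                if e_ind[e] == 1 and f > 0.0:
                    f = 1.0
                eta_t = base_e[e] + gain_e[e] * f
                if e_sub[e] == 0:
                    v += _state_logdens(state_kind[t], float(lat[t, i]), eta_t, lgam)
                else:
                    v += _obs_loglik(state_kind[t], lat[t, i], eta_t, Y[t, i], T[t, i])
        row[n] = v
        if v > lp_max:
            lp_max = v
        if (not full_scan) and n >= lo + 2 and v < row[n - 1] and v < lp_max - _DROP:
            hi_used = n
            break
    if lp_max == _NEG_INF:
        return lo, hi_used, -1.0, 0
    total = 0.0
    for n in range(lo, hi_used + 1):
        row[n] = math.exp(row[n] - lp_max)
        total += row[n]
    trunc = 0
    if kind == 0 and hi_used == N_max and row[N_max] / total > 1e-6:
        trunc = 1
    return lo, hi_used, total, trunc


@njit(inline="always", cache=True, fastmath=_FM)
def _draw_from_row(row, lo, hi_used, total):
    u = np.random.random() * total
    pick = hi_used
    c = 0.0
    for n in range(lo, hi_used + 1):
        c += row[n]
        if u <= c:
            pick = n
            break
    return pick


@njit(cache=True, fastmath=_FM)
def _update_latent_species(
    s, theta, lat, kind, hi,
    state_kind, Xs, nP, spar, Xd, nQ, dpar,
    e_src, e_tgt, e_sub, e_g0, e_g1, e_ind, e_mod,
    ins_ptr, ins_idx, ind_ptr, ind_idx, out_ptr, out_idx,
    Y, T, anydet, lgam, lp, base_e, gain_e, N_max, full_scan,
):
    """Generic per-site Gibbs update of species s at every site.

    Returns (err_site, trunc_count); err_site is -1 when all sites were
    updated, otherwise the first site whose conditional lost all mass.
    """
    I = lat.shape[1]
    trunc_count = 0
    for i in range(I):
        lo, hi_used, total, trunc = _site_cond_row(
            s, i, theta, lat, kind, hi,
            state_kind, Xs, nP, spar, Xd, nQ, dpar,
            e_src, e_tgt, e_sub, e_g0, e_g1, e_ind, e_mod,
            ins_ptr, ins_idx, ind_ptr, ind_idx, out_ptr, out_idx,
            Y, T, anydet, lgam, lp, base_e, gain_e, N_max, full_scan,
        )
        if total <= 0.0:
            return i, trunc_count
        trunc_count += trunc
        lat[s, i] = _draw_from_row(lp, lo, hi_used, total)
    return -1, trunc_count


@njit(inline="always", cache=True)
def _encode_sig(i, s_excl, lat, dcls, D, N1):
    """Equivalence-class id of site i for updates of species s_excl
    (s_excl = -1 encodes all species' latents, for likelihood pooling)."""
    S = lat.shape[0]
    code = dcls[i]
    mult = D
    for t in range(S):
        if t != s_excl:
            code += lat[t, i] * mult
            mult *= N1
    return code


@njit(cache=True, fastmath=_FM)
def _update_latent_species_grouped(
    s, theta, lat, kind, hi,
    state_kind, Xs, nP, spar, Xd, nQ, dpar,
    e_src, e_tgt, e_sub, e_g0, e_g1, e_ind, e_mod,
    ins_ptr, ins_idx, ind_ptr, ind_idx, out_ptr, out_idx,
    Y, T, anydet, lgam, base_e, gain_e, N_max,
    dcls, D, table, tab_lo, tab_hi, tab_total, tab_trunc, stamp, stamp_val,
):
    """Collapsed Gibbs update: one conditional per distinct equivalence
    class, one categorical draw per site.  Identical arithmetic and random
    stream to the generic update."""
    I = lat.shape[1]
    N1 = N_max + 1
    trunc_count = 0
    for i in range(I):
        sg = _encode_sig(i, s, lat, dcls, D, N1)
        if stamp[sg] != stamp_val:
            lo, hi_used, total, trunc = _site_cond_row(
                s, i, theta, lat, kind, hi,
                state_kind, Xs, nP, spar, Xd, nQ, dpar,
                e_src, e_tgt, e_sub, e_g0, e_g1, e_ind, e_mod,
                ins_ptr, ins_idx, ind_ptr, ind_idx, out_ptr, out_idx,
                Y, T, anydet, lgam, table[sg], base_e, gain_e, N_max, False,
            )
            tab_lo[sg] = lo
            tab_hi[sg] = hi_used
            tab_total[sg] = total
            tab_trunc[sg] = trunc
            stamp[sg] = stamp_val
        if tab_total[sg] <= 0.0:
            return i, trunc_count
        trunc_count += tab_trunc[sg]
        lat[s, i] = _draw_from_row(table[sg], tab_lo[sg], tab_hi[sg], tab_total[sg])
    return -1, trunc_count


@njit(cache=True, fastmath=_FM)
def _build_classes(lat, dcls, D, N1, slot, stampB, stamp_val, rep, count):
    """Pool sites into full-latent equivalence classes; returns how many
    distinct classes are present (their representative site and size are
    written into rep/count)."""
    I = lat.shape[1]
    n_pres = 0
    for i in range(I):
        sg = _encode_sig(i, -1, lat, dcls, D, N1)
        if stampB[sg] != stamp_val:
            stampB[sg] = stamp_val
            slot[sg] = n_pres
            rep[n_pres] = i
            count[n_pres] = 0
            n_pres += 1
        count[slot[sg]] += 1
    return n_pres


@njit(cache=True, fastmath=_FM)
def _species_loglik_pooled(s, which, theta, lat, state_kind, Xs, nP, spar,
                           Xd, nQ, dpar, ins_ptr, ins_idx, ind_ptr, ind_idx,
                           e_src, e_g0, e_g1, e_ind, e_mod, Y, T, lgam,
                           n_pres, rep, count):
    """Likelihood sum over sites via equivalence-class pooling."""
    total = 0.0
    for k in range(n_pres):
        total += count[k] * _site_loglik(
            s, which, rep[k], theta, lat, state_kind, Xs, nP, spar,
            Xd, nQ, dpar, ins_ptr, ins_idx, ind_ptr, ind_idx,
            e_src, e_g0, e_g1, e_ind, e_mod, Y, T, lgam)
    return total


@njit(cache=True, fastmath=_FM)
def run_chain_kernel(
    seed, n_iter, burn_in, thin, record_latent,
    theta, lat, scales,
    adapt_interval, target_accept,
    state_kind, Xs, nP, spar, Xd, nQ, dpar,
    e_src, e_tgt, e_sub, e_g0, e_g1, e_ind, e_mod,
    ins_ptr, ins_idx, ind_ptr, ind_idx, out_ptr, out_idx,
    Y, T, anydet, prior_sd, role_sp, role_sub, N_max,
    use_fast, dcls, D,
    pair_a, pair_b, pair_sp, pair_sub,
):
    np.random.seed(seed)
    S, I = lat.shape
    n_par = theta.shape[0]
    N1 = N_max + 1
    n_keep = (n_iter - burn_in + thin - 1) // thin
    draws = np.empty((n_keep, n_par))
    if record_latent:
        lat_draws = np.empty((n_keep, S, I), dtype=np.int16)
    else:
        lat_draws = np.empty((0, S, I), dtype=np.int16)
    acc_total = np.zeros(n_par)
    acc_win = np.zeros(n_par)
    log_scales = np.log(scales)
    n_pairs = len(pair_a)
    pair_scales = np.full(n_pairs, 0.3)
    pair_log_scales = np.log(pair_scales)
    pair_acc_win = np.zeros(n_pairs)
    lp = np.empty(N1)
    base_e = np.empty(max(len(e_src), 1))
    gain_e = np.empty(max(len(e_src), 1))
    lgam = np.empty(N1)
    for n in range(N1):
        lgam[n] = math.lgamma(n + 1.0)
    cur_state = np.empty(S)
    cur_det = np.empty(S)
    # collapsed-path workspaces (size 1 when unused)
    n_sig_upd = D * N1 ** (S - 1) if use_fast else 1
    n_sig_full = D * N1**S if use_fast else 1
    table = np.empty((n_sig_upd, N1))
    tab_lo = np.zeros(n_sig_upd, dtype=np.int32)
    tab_hi = np.zeros(n_sig_upd, dtype=np.int32)
    tab_total = np.zeros(n_sig_upd)
    tab_trunc = np.zeros(n_sig_upd, dtype=np.int32)
    stampA = np.zeros(n_sig_upd, dtype=np.int64)
    stampB = np.zeros(n_sig_full, dtype=np.int64)
    slot = np.zeros(n_sig_full, dtype=np.int32)
    rep = np.zeros(I, dtype=np.int64)
    count = np.zeros(I, dtype=np.int64)
    stamp_val = 0
    trunc_hits = 0
    n_adapt = 0
    status = 0
    err_info = np.zeros(3, dtype=np.int64)
    kept = 0

    for it in range(n_iter):
        # --- latent sweep (topological order = species order) ---
        for s in range(S):
            kind = state_kind[s]
            hi = 1 if kind == 1 else N_max
            if use_fast:
                stamp_val += 1
                err_site, trunc = _update_latent_species_grouped(
                    s, theta, lat, kind, hi,
                    state_kind, Xs, nP, spar, Xd, nQ, dpar,
                    e_src, e_tgt, e_sub, e_g0, e_g1, e_ind, e_mod,
                    ins_ptr, ins_idx, ind_ptr, ind_idx, out_ptr, out_idx,
                    Y, T, anydet, lgam, base_e, gain_e, N_max,
                    dcls, D, table, tab_lo, tab_hi, tab_total, tab_trunc,
                    stampA, stamp_val,
                )
            else:
                err_site, trunc = _update_latent_species(
                    s, theta, lat, kind, hi,
                    state_kind, Xs, nP, spar, Xd, nQ, dpar,
                    e_src, e_tgt, e_sub, e_g0, e_g1, e_ind, e_mod,
                    ins_ptr, ins_idx, ind_ptr, ind_idx, out_ptr, out_idx,
                    Y, T, anydet, lgam, lp, base_e, gain_e, N_max, False,
                )
            trunc_hits += trunc
            if err_site >= 0:
                status = 1
                err_info[0] = it
                err_info[1] = s
                err_info[2] = err_site
                return (draws[:kept], lat_draws[:kept], acc_total,
                        trunc_hits, status, err_info)

        # --- coefficient sweep, one submodel block at a time ---
        n_pres = 0
        if use_fast:
            stamp_val += 1
            n_pres = _build_classes(lat, dcls, D, N1, slot, stampB, stamp_val,
                                    rep, count)
        for s in range(S):
            for which in range(2):
                if use_fast:
                    ll = _species_loglik_pooled(
                        s, which, theta, lat, state_kind, Xs, nP, spar,
                        Xd, nQ, dpar, ins_ptr, ins_idx, ind_ptr, ind_idx,
                        e_src, e_g0, e_g1, e_ind, e_mod, Y, T, lgam,
                        n_pres, rep, count)
                else:
                    ll = _species_loglik(
                        s, which, theta, lat, state_kind, Xs, nP, spar,
                        Xd, nQ, dpar, ins_ptr, ins_idx, ind_ptr, ind_idx,
                        e_src, e_g0, e_g1, e_ind, e_mod, Y, T, lgam)
                if which == 0:
                    cur_state[s] = ll
                else:
                    cur_det[s] = ll
        for j in range(n_par):
            s = role_sp[j]
            which = role_sub[j]
            old = theta[j]
            theta[j] = old + scales[j] * np.random.normal()
            if use_fast:
                new_ll = _species_loglik_pooled(
                    s, which, theta, lat, state_kind, Xs, nP, spar,
                    Xd, nQ, dpar, ins_ptr, ins_idx, ind_ptr, ind_idx,
                    e_src, e_g0, e_g1, e_ind, e_mod, Y, T, lgam,
                    n_pres, rep, count)
            else:
                new_ll = _species_loglik(
                    s, which, theta, lat, state_kind, Xs, nP, spar,
                    Xd, nQ, dpar, ins_ptr, ins_idx, ind_ptr, ind_idx,
                    e_src, e_g0, e_g1, e_ind, e_mod, Y, T, lgam)
            cur_ll = cur_state[s] if which == 0 else cur_det[s]
            sd = prior_sd[j]
            dprior = -0.5 * (theta[j] * theta[j] - old * old) / (sd * sd)
            delta = new_ll - cur_ll + dprior
            if math.isfinite(new_ll) and math.log(np.random.random()) < delta:
                if which == 0:
                    cur_state[s] = new_ll
                else:
                    cur_det[s] = new_ll
                acc_total[j] += 1.0
                acc_win[j] += 1.0
            else:
                theta[j] = old

        # --- joint ridge moves: intercept and gamma0 of each edge shift in
        # opposite directions, traversing the near-collinear direction that
        # per-parameter walks cannot ---
        for q in range(n_pairs):
            a = pair_a[q]
            b = pair_b[q]
            s = pair_sp[q]
            which = pair_sub[q]
            old_a = theta[a]
            old_b = theta[b]
            dlt = pair_scales[q] * np.random.normal()
            theta[a] = old_a + dlt
            theta[b] = old_b - dlt
            if use_fast:
                new_ll = _species_loglik_pooled(
                    s, which, theta, lat, state_kind, Xs, nP, spar,
                    Xd, nQ, dpar, ins_ptr, ins_idx, ind_ptr, ind_idx,
                    e_src, e_g0, e_g1, e_ind, e_mod, Y, T, lgam,
                    n_pres, rep, count)
            else:
                new_ll = _species_loglik(
                    s, which, theta, lat, state_kind, Xs, nP, spar,
                    Xd, nQ, dpar, ins_ptr, ins_idx, ind_ptr, ind_idx,
                    e_src, e_g0, e_g1, e_ind, e_mod, Y, T, lgam)
            cur_ll = cur_state[s] if which == 0 else cur_det[s]
            dprior = (-0.5 * (theta[a] ** 2 - old_a**2) / (prior_sd[a] ** 2)
                      - 0.5 * (theta[b] ** 2 - old_b**2) / (prior_sd[b] ** 2))
            delta = new_ll - cur_ll + dprior
            if math.isfinite(new_ll) and math.log(np.random.random()) < delta:
                if which == 0:
                    cur_state[s] = new_ll
                else:
                    cur_det[s] = new_ll
                pair_acc_win[q] += 1.0
            else:
                theta[a] = old_a
                theta[b] = old_b

        # --- Robbins-Monro proposal adaptation (burn-in only) ---
        if it < burn_in and (it + 1) % adapt_interval == 0:
            n_adapt += 1
            step = 1.0 / math.sqrt(n_adapt)
            for j in range(n_par):
                rate = acc_win[j] / adapt_interval
                log_scales[j] += step * (rate - target_accept)
                scales[j] = math.exp(log_scales[j])
                acc_win[j] = 0.0
            for q in range(n_pairs):
                rate = pair_acc_win[q] / adapt_interval
                pair_log_scales[q] += step * (rate - target_accept)
                pair_scales[q] = math.exp(pair_log_scales[q])
                pair_acc_win[q] = 0.0

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(n_par):
                draws[kept, j] = theta[j]
            if record_latent:
                for s in range(S):
                    for i in range(I):
                        lat_draws[kept, s, i] = np.int16(lat[s, i])
            kept += 1

    return draws[:kept], lat_draws[:kept], acc_total, trunc_hits, status, err_info


@njit(cache=True, fastmath=_FM)
def gibbs_latent_kernel(
    seed, n_draws, theta, lat,
    state_kind, Xs, nP, spar, Xd, nQ, dpar,
    e_src, e_tgt, e_sub, e_g0, e_g1, e_ind, e_mod,
    ins_ptr, ins_idx, ind_ptr, ind_idx, out_ptr, out_idx,
    Y, T, anydet, N_max,
):
    """Latent-only Gibbs sweeps at fixed coefficients; records every draw.

    Runs the generic (uncollapsed) update with the early-termination scan
    disabled, so recorded draws come from the fully enumerated truncated
    conditional.  Used by the full-conditional oracle tests and by
    posterior-predictive machinery that needs latent states regenerated at
    fixed theta.
    """
    np.random.seed(seed)
    S, I = lat.shape
    out = np.empty((n_draws, S, I), dtype=np.int16)
    lp = np.empty(N_max + 1)
    base_e = np.empty(max(len(e_src), 1))
    gain_e = np.empty(max(len(e_src), 1))
    lgam = np.empty(N_max + 1)
    for n in range(N_max + 1):
        lgam[n] = math.lgamma(n + 1.0)
    for d in range(n_draws):
        for s in range(S):
            kind = state_kind[s]
            hi = 1 if kind == 1 else N_max
            err_site, _ = _update_latent_species(
                s, theta, lat, kind, hi,
                state_kind, Xs, nP, spar, Xd, nQ, dpar,
                e_src, e_tgt, e_sub, e_g0, e_g1, e_ind, e_mod,
                ins_ptr, ins_idx, ind_ptr, ind_idx, out_ptr, out_idx,
                Y, T, anydet, lgam, lp, base_e, gain_e, N_max, True,
            )
            if err_site >= 0:
                out[d, s] = np.int16(-1)
                continue
            for i in range(I):
                out[d, s, i] = np.int16(lat[s, i])
    return out
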