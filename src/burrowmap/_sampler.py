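"""Numba kernels for Metropolis-Hastings simulation of Gibbs point processes.

The chain operates on flat coordinate/type arrays: indices [0, n_fixed) hold
conditioning (frozen) points that never move; active points live in
[n_fixed, n_fixed + n). Birth/death/shift proposals target active points only.
All randomness flows through numpy's legacy global RNG seeded inside the
kernel, so a fixed seed gives byte-identical chains.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the chain kernels
OK = 0
CAPACITY_EXCEEDED = 1


@njit(cache=True)
def _cond_int(ux, uy, m, px, py, pt, n_tot, skip,
              log_beta, h2, r2, gamma,
              cov_coef, cov_rx, cov_ry, cov_off):
    """Papangelou conditional intensity at (ux, uy) for a point of type m.

    Returns 0.0 on any hard-core violation (d <= h for an active pair).
    ``skip`` removes one index from the interaction sum (self-exclusion).
    """
    prod = 1.0
    for j in range(n_tot):
        if j == skip:
            continue
        dx = px[j] - ux
        dy = py[j] - uy
        d2 = dx * dx + dy * dy
        tj = pt[j]
        if d2 <= h2[m, tj]:
            return 0.0
        if d2 <= r2[m, tj]:
            g = gamma[m, tj]
            if g != 1.0:
                if g == 0.0:
                    return 0.0
                prod *= g
    lin = log_beta[m]
    for c in range(cov_coef.shape[0]):
        coef = cov_coef[c, m]
        if coef != 0.0:
            best = 1e300
            for k in range(cov_off[c], cov_off[c + 1]):
                dx = cov_rx[k] - ux
                dy = cov_ry[k] - uy
                d2 = dx * dx + dy * dy
                if d2 < best:
                    best = d2
            lin += coef * np.sqrt(best)
    return np.exp(lin) * prod


@njit(cache=True)
def run_chain(seed, n_burn, n_draws, thin, cap,
              px, py, pt, n_fixed, n_active0,
              sim_types,
              x0, x1, y0, y1,
              log_beta, h2, r2, gamma,
              cov_coef, cov_rx, cov_ry, cov_off,
              p_birth, p_death, fixed_n):
    """Birth/death/shift Metropolis-Hastings chain for a multitype Gibbs model.

    ``px, py, pt`` must have length n_fixed + cap and carry the fixed points
    followed by the initial active points. Draws are collected every ``thin``
    proposals after ``n_burn`` proposals of burn-in.

    Returns (status, out_n, out_x, out_y, out_t, trace_n) where out_* hold one
    draw per row (first out_n[k] entries valid) and trace_n records the active
    count every 100 proposals for mixing diagnostics.
    """
    np.random.seed(seed)
    area = (x1 - x0) * (y1 - y0)
    K = sim_types.shape[0]
    n = n_active0
    out_n = np.zeros(n_draws, np.int64)
    out_x = np.zeros((n_draws, cap))
    out_y = np.zeros((n_draws, cap))
    out_t = np.zeros((n_draws, cap), np.int64)
    total = n_burn + n_draws * thin
    trace_n = np.zeros(total // 100 + 1, np.int64)
    draw = 0
    for step in range(total):
        u = np.random.random()
        ntot = n_fixed + n
        if (not fixed_n) and u < p_birth:
            m = sim_types[np.random.randint(K)]
            bx = x0 + np.random.random() * (x1 - x0)
            by = y0 + np.random.random() * (y1 - y0)
            lam = _cond_int(bx, by, m, px, py, pt, ntot, -1,
                            log_beta, h2, r2, gamma,
                            cov_coef, cov_rx, cov_ry, cov_off)
            if lam > 0.0:
                a = lam * area * K / (n + 1.0) * (p_death / p_birth)
                if a >= 1.0 or np.random.random() < a:
                    if n >= cap:
                        return CAPACITY_EXCEEDED, out_n, out_x, out_y, out_t, trace_n
                    idx = n_fixed + n
                    px[idx] = bx
                    py[idx] = by
                    pt[idx] = m
                    n += 1
        elif (not fixed_n) and u < p_birth + p_death:
            if n > 0:
                i = n_fixed + np.random.randint(n)
                lam = _cond_int(px[i], py[i], pt[i], px, py, pt, ntot, i,
                                log_beta, h2, r2, gamma,
                                cov_coef, cov_rx, cov_ry, cov_off)
                accept = True
                if lam > 0.0:
                    a = n / (lam * area * K) * (p_birth / p_death)
                    accept = a >= 1.0 or np.random.random() < a
                if accept:
                    last = n_fixed + n - 1
                    px[i] = px[last]
                    py[i] = py[last]
                    pt[i] = pt[last]
                    n -= 1
        else:
            if n > 0:
                i = n_fixed + np.random.randint(n)
                bx = x0 + np.random.random() * (x1 - x0)
                by = y0 + np.random.random() * (y1 - y0)
                lam_new = _cond_int(bx, by, pt[i], px, py, pt, ntot, i,
                                    log_beta, h2, r2, gamma,
                                    cov_coef, cov_rx, cov_ry, cov_off)
                if lam_new > 0.0:
                    lam_old = _cond_int(px[i], py[i], pt[i], px, py, pt, ntot, i,
                                        log_beta, h2, r2, gamma,
                                        cov_coef, cov_rx, cov_ry, cov_off)
                    a = lam_new / lam_old
                    if a >= 1.0 or np.random.random() < a:
                        px[i] = bx
                        py[i] = by
        if step % 100 == 0:
            trace_n[step // 100] = n
        if step >= n_burn and (step - n_burn + 1) % thin == 0 and draw < n_draws:
            out_n[draw] = n
            for j in range(n):
                out_x[draw, j] = px[n_fixed + j]
                out_y[draw, j] = py[n_fixed + j]
                out_t[draw, j] = pt[n_fixed + j]
            draw += 1
    return OK, out_n, out_x, out_y, out_t, trace_n
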