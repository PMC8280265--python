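"""Numba kernels for the explicit finite-difference solver.

Discretization notes (uniform node-centred grid r_j = j*dr on [0, 1]):

* Diffusion and chemotaxis are written in conservative flux form. Face fluxes
  at r_{j+1/2} combine a central diffusive part with a first-order upwind
  chemotactic part (the tanh production switch with delta = 0.01 creates
  near-discontinuous fronts; upwinding keeps them monotone).
* The r = 0 singularity of (1/r) d/dr (r d/dr) is removed by the symmetric
  limit 2 d2u/dr2, which is what the finite-volume divergence over the axis
  cell [0, dr/2] evaluates to.
* The vessel-deposition source is the inward tip flux +mu_n dn/dr
  - chi n da/dr (tips sweeping toward the centre lay down vessels; outward
  flux removes them), evaluated at nodes as the mean of the two adjacent
  upwinded face fluxes so that n-transport and b-deposition see the same
  discrete flux.
* Time step: diffusive bound safety*dr^2/max(1, mu_n, mu_b*max n, Dm/Da)
  plus an advective CFL bound adv_safety*dr/max|chi da/dr| and explicit
  reaction bounds 0.25/(lambda2 + 2 lambda0 max n) and
  0.25/(lambda4 + lambda5 max b), recomputed every step.
* Negative values produced by explicit undershoot are clipped to zero with
  the clipped mass accumulated per field (units: dimensionless mass on the
  unit disc, i.e. integral of 2 r dr).

Field order for status/clip arrays: 0 = n, 1 = a, 2 = b, 3 = m.
"""

import math

import numpy as np
from numba import njit

__all__ = ["compute_rhs", "advance", "advance_am"]


@njit(cache=True)
def _tanh_switch(x):
    # tanh with saturation shortcut; |x| > 20 is 1 to machine precision.
    if x > 20.0:
        return 1.0
    if x < -20.0:
        return -1.0
    return math.tanh(x)


@njit(cache=True)
def compute_rhs(n, a, b, m, dr,
                lam0, lam1, lam2, mu_n, chi, lam4, lam5, lam7,
                delta, mu_b, b_hat,
                dm_ratio, k1_nd, lam8, k_gen,
                Jn, dn, da, db, dm):
    """Fill dn..dm with time derivatives; Jn with upwinded tip face fluxes.

    Edge-node (j = N-1) entries of dn and db are set to 0: n and b carry
    Dirichlet values there and are imposed by the caller. a and m get full
    finite-volume updates at the edge with Robin outflow at r = 1.
    """
    N = n.shape[0]
    inv_dr = 1.0 / dr

    # --- face fluxes (faces j+1/2, j = 0..N-2) ---
    for j in range(N - 1):
        grad_a = (a[j + 1] - a[j]) * inv_dr
        grad_n = (n[j + 1] - n[j]) * inv_dr
        v = chi * grad_a
        n_up = n[j] if v > 0.0 else n[j + 1]
        Jn[j] = -mu_n * grad_n + v * n_up

    # --- interior nodes ---
    for j in range(1, N - 1):
        r_j = j * dr
        r_p = (j + 0.5) * dr
        r_m_ = (j - 0.5) * dr
        inv_rv = 1.0 / (r_j * dr)

        grad_a_p = (a[j + 1] - a[j]) * inv_dr
        grad_a_m = (a[j] - a[j - 1]) * inv_dr
        grad_n_p = (n[j + 1] - n[j]) * inv_dr
        grad_n_m = (n[j] - n[j - 1]) * inv_dr
        grad_b_p = (b[j + 1] - b[j]) * inv_dr
        grad_b_m = (b[j] - b[j - 1]) * inv_dr
        grad_m_p = (m[j + 1] - m[j]) * inv_dr
        grad_m_m = (m[j] - m[j - 1]) * inv_dr

        # n: conservative transport + kinetics
        div_Jn = (r_p * Jn[j] - r_m_ * Jn[j - 1]) * inv_rv
        dn[j] = (-div_Jn + lam1 * a[j] * b[j] - lam2 * n[j]
                 - lam0 * n[j] * n[j])

        # a: diffusion (D = 1), production switch, removal, mRNA coupling
        lap_a = (r_p * grad_a_p - r_m_ * grad_a_m) * inv_rv
        prod = 0.5 * lam4 * (1.0 + _tanh_switch((1.0 - b[j]) / delta))
        da[j] = (lap_a + prod - (lam4 + lam5 * b[j]) * a[j]
                 + k_gen * m[j])

        # b: tip-assisted motility + deposition by the inward tip flux
        n_face_p = 0.5 * (n[j] + n[j + 1])
        n_face_m = 0.5 * (n[j] + n[j - 1])
        div_b = (r_p * mu_b * n_face_p * grad_b_p
                 - r_m_ * mu_b * n_face_m * grad_b_m) * inv_rv
        J_node = 0.5 * (Jn[j] + Jn[j - 1])
        db[j] = div_b - J_node

        # m: diffusion + degradation
        lap_m = (r_p * grad_m_p - r_m_ * grad_m_m) * inv_rv
        dm[j] = dm_ratio * lap_m - k1_nd * m[j]

    # --- axis node (j = 0): FV over [0, dr/2]; symmetry => J(0) = 0 ---
    vol0 = dr * dr / 8.0  # integral of r dr over the axis cell
    r_half = 0.5 * dr
    fac = r_half / vol0   # = 4/dr
    dn[0] = (-fac * Jn[0] + lam1 * a[0] * b[0] - lam2 * n[0]
             - lam0 * n[0] * n[0])
    prod0 = 0.5 * lam4 * (1.0 + _tanh_switch((1.0 - b[0]) / delta))
    da[0] = (fac * (a[1] - a[0]) * inv_dr + prod0
             - (lam4 + lam5 * b[0]) * a[0] + k_gen * m[0])
    n_face0 = 0.5 * (n[0] + n[1])
    db[0] = fac * mu_b * n_face0 * (b[1] - b[0]) * inv_dr  # J(0) = 0
    dm[0] = fac * dm_ratio * (m[1] - m[0]) * inv_dr - k1_nd * m[0]

    # --- edge node (j = N-1): Dirichlet n, b; Robin outflow for a, m ---
    dn[N - 1] = 0.0
    db[N - 1] = 0.0
    vol_e = 0.5 * (dr - 0.25 * dr * dr)  # integral of r dr over [1-dr/2, 1]
    r_in = 1.0 - 0.5 * dr
    # outward flux at r = 1 from the Robin conditions
    flux_a_out = lam7 * b_hat * a[N - 1]
    flux_m_out = dm_ratio * lam8 * b_hat * m[N - 1]
    Fa_in = -(a[N - 1] - a[N - 2]) * inv_dr
    Fm_in = -dm_ratio * (m[N - 1] - m[N - 2]) * inv_dr
    prod_e = 0.5 * lam4 * (1.0 + _tanh_switch((1.0 - b[N - 1]) / delta))
    da[N - 1] = (-(1.0 * flux_a_out - r_in * Fa_in) / vol_e
                 + prod_e - (lam4 + lam5 * b[N - 1]) * a[N - 1]
                 + k_gen * m[N - 1])
    dm[N - 1] = (-(1.0 * flux_m_out - r_in * Fm_in) / vol_e
                 - k1_nd * m[N - 1])


@njit(cache=True)
def _stable_dt(n, a, b, dr, mu_n, chi, mu_b, dm_ratio,
               lam0, lam2, lam4, lam5, safety, adv_safety):
    N = n.shape[0]
    inv_dr = 1.0 / dr
    maxv = 0.0
    maxn = 0.0
    maxb = 0.0
    for j in range(N):
        if n[j] > maxn:
            maxn = n[j]
        if b[j] > maxb:
            maxb = b[j]
        if j < N - 1:
            v = chi * (a[j + 1] - a[j]) * inv_dr
            if v < 0.0:
                v = -v
            if v > maxv:
                maxv = v
    dmax = 1.0
    if mu_n > dmax:
        dmax = mu_n
    if mu_b * maxn > dmax:
        dmax = mu_b * maxn
    if dm_ratio > dmax:
        dmax = dm_ratio
    dt = safety * dr * dr / dmax
    if maxv > 0.0:
        dt_adv = adv_safety * dr / maxv
        if dt_adv < dt:
            dt = dt_adv
    rate_n = lam2 + 2.0 * lam0 * maxn
    if rate_n > 0.0:
        dt_rn = 0.25 / rate_n
        if dt_rn < dt:
            dt = dt_rn
    rate_a = lam4 + lam5 * maxb
    if rate_a > 0.0:
        dt_ra = 0.25 / rate_a
        if dt_ra < dt:
            dt = dt_ra
    return dt


@njit(cache=True)
def advance(n, a, b, m, t, t_end, dr,
            lam0, lam1, lam2, mu_n, chi, n_hat, alpha,
            lam4, lam5, lam7, delta, mu_b, b_hat,
            dm_ratio, k1_nd, lam8, k_gen,
            safety, adv_safety, max_field, clip):
    """Advance all fields in place from t to t_end.

    Returns (t, n_steps, status_field, status_node); status_field is -1 on
    success, else the index of the first non-finite/overflowing field.
    ``clip`` (float64[4]) accumulates clipped negative mass per field.
    """
    N = n.shape[0]
    Jn = np.empty(N - 1)
    dn = np.empty(N)
    da = np.empty(N)
    db = np.empty(N)
    dm = np.empty(N)
    vols = np.empty(N)
    for j in range(N):
        vols[j] = 2.0 * j * dr * dr
    vols[0] = dr * dr / 4.0
    vols[N - 1] = dr - dr * dr / 4.0

    steps = 0
    while t < t_end - 1e-14:
        dt = _stable_dt(n, a, b, dr, mu_n, chi, mu_b, dm_ratio,
                        lam0, lam2, lam4, lam5, safety, adv_safety)
        if t + dt > t_end:
            dt = t_end - t

        compute_rhs(n, a, b, m, dr,
                    lam0, lam1, lam2, mu_n, chi, lam4, lam5, lam7,
                    delta, mu_b, b_hat,
                    dm_ratio, k1_nd, lam8, k_gen,
                    Jn, dn, da, db, dm)

        for j in range(N):
            n[j] += dt * dn[j]
            a[j] += dt * da[j]
            b[j] += dt * db[j]
            m[j] += dt * dm[j]

        t += dt
        steps += 1

        # Dirichlet edge values at the new time
        n[N - 1] = n_hat * math.exp(-alpha * t)
        b[N - 1] = b_hat

        # clip negatives (logged) and detect blow-up
        for j in range(N):
            if n[j] < 0.0:
                clip[0] -= n[j] * vols[j]
                n[j] = 0.0
            if a[j] < 0.0:
                clip[1] -= a[j] * vols[j]
                a[j] = 0.0
            if b[j] < 0.0:
                clip[2] -= b[j] * vols[j]
                b[j] = 0.0
            if m[j] < 0.0:
                clip[3] -= m[j] * vols[j]
                m[j] = 0.0
            if not math.isfinite(n[j]) or n[j] > max_field:
                return t, steps, 0, j
            if not math.isfinite(a[j]) or a[j] > max_field:
                return t, steps, 1, j
            if not math.isfinite(b[j]) or b[j] > max_field:
                return t, steps, 2, j
            if not math.isfinite(m[j]) or m[j] > max_field:
                return t, steps, 3, j

    return t, steps, -1, -1


@njit(cache=True)
def advance_am(a, m, b, t, t_end, dr,
               lam4, lam5, lam7, delta, b_hat,
               dm_ratio, k1_nd, lam8, k_gen,
               safety):
    """Chemoattractant-mRNA subsystem on a frozen vessel field (tips absent).

    Used for the healed-wound PK calibration of k_gen: with n = 0 and b
    stationary the net chemoattractant response is exactly linear in k_gen.
    Advances a and m in place; returns (t, n_steps).
    """
    N = a.shape[0]
    da = np.empty(N)
    dm = np.empty(N)
    inv_dr = 1.0 / dr
    dmax = 1.0 if dm_ratio <= 1.0 else dm_ratio
    dt0 = safety * dr * dr / dmax
    steps = 0
    while t < t_end - 1e-14:
        dt = dt0
        if t + dt > t_end:
            dt = t_end - t
        for j in range(1, N - 1):
            r_j = j * dr
            r_p = (j + 0.5) * dr
            r_m_ = (j - 0.5) * dr
            inv_rv = 1.0 / (r_j * dr)
            lap_a = (r_p * (a[j + 1] - a[j]) - r_m_ * (a[j] - a[j - 1])) \
                * inv_dr * inv_rv
            lap_m = (r_p * (m[j + 1] - m[j]) - r_m_ * (m[j] - m[j - 1])) \
                * inv_dr * inv_rv
            prod = 0.5 * lam4 * (1.0 + _tanh_switch((1.0 - b[j]) / delta))
            da[j] = lap_a + prod - (lam4 + lam5 * b[j]) * a[j] + k_gen * m[j]
            dm[j] = dm_ratio * lap_m - k1_nd * m[j]
        fac = (0.5 * dr) / (dr * dr / 8.0)
        prod0 = 0.5 * lam4 * (1.0 + _tanh_switch((1.0 - b[0]) / delta))
        da[0] = (fac * (a[1] - a[0]) * inv_dr + prod0
                 - (lam4 + lam5 * b[0]) * a[0] + k_gen * m[0])
        dm[0] = fac * dm_ratio * (m[1] - m[0]) * inv_dr - k1_nd * m[0]
        vol_e = 0.5 * (dr - 0.25 * dr * dr)
        r_in = 1.0 - 0.5 * dr
        flux_a_out = lam7 * b_hat * a[N - 1]
        flux_m_out = dm_ratio * lam8 * b_hat * m[N - 1]
        Fa_in = -(a[N - 1] - a[N - 2]) * inv_dr
        Fm_in = -dm_ratio * (m[N - 1] - m[N - 2]) * inv_dr
        prod_e = 0.5 * lam4 * (1.0 + _tanh_switch((1.0 - b[N - 1]) / delta))
        da[N - 1] = (-(flux_a_out - r_in * Fa_in) / vol_e + prod_e
                     - (lam4 + lam5 * b[N - 1]) * a[N - 1]
                     + k_gen * m[N - 1])
        dm[N - 1] = -(flux_m_out - r_in * Fm_in) / vol_e - k1_nd * m[N - 1]
        for j in range(N):
            a[j] += dt * da[j]
            m[j] += dt * dm[j]
            if a[j] < 0.0:
                a[j] = 0.0
            if m[j] < 0.0:
                m[j] = 0.0
        t += dt
        steps += 1
    return t, steps
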