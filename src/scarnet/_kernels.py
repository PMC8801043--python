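"""Compiled fast path for the contraction simulation.

This module contains a numba translation of the reference Picard/backward-
Euler loop in :mod:`scarnet.fem_solver`.  It implements *the same*
discretization (same block-tridiagonal system, same lagged coefficients,
same clipping and commit rules); the only difference is the linear-algebra
backend (a block-Thomas elimination instead of LAPACK ``gbsv``).  A test
cross-checks both paths on the same problem.

Everything here is private; :func:`scarnet.fem_solver.simulate` dispatches
to it automatically when numba is importable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


# parameter-vector layout consumed by the kernel
_PARAM_FIELDS = (
    "D_c", "D_F", "chi_F", "k_c", "a_c_I", "a_c_II", "a_c_III", "a_c_IV",
    "delta_c", "eta_I", "eta_II", "k_F", "r_F", "r_F_max", "kappa_F",
    "delta_N", "delta_M", "k_rho_max", "delta_rho", "rho_t", "mu",
    "E_stiff", "xi", "R_traction", "zeta", "N_bar", "rho_bar", "c_w",
)
# two derived entries appended: k_rho, 1+q
_NP = len(_PARAM_FIELDS)

# kernel exit codes
OK = 0
PICARD_FAIL = 1
MESH_TANGLED = 2
CLIP_OVERFLOW = 3
NONFINITE = 4
STRAIN_BLOWUP = 5
EDGE_COLLAPSED = 6


def param_vector(params) -> np.ndarray:
    pv = np.empty(_NP + 2)
    for i, name in enumerate(_PARAM_FIELDS):
        pv[i] = getattr(params, name)
    pv[_NP] = params.k_rho
    pv[_NP + 1] = 1.0 + params.q_exponent
    return pv


@njit(cache=True, fastmath=False)
def _gauss_solve_multi(A, B):
    """Solve A X = B in place for a small dense A (m x m) and B (m x k),
    Gaussian elimination with partial pivoting; result left in B."""
    m = A.shape[0]
    k = B.shape[1]
    for col in range(m):
        # pivot
        piv = col
        best = abs(A[col, col])
        for r in range(col + 1, m):
            a = abs(A[r, col])
            if a > best:
                best = a
                piv = r
        if piv != col:
            for j in range(m):
                A[col, j], A[piv, j] = A[piv, j], A[col, j]
            for j in range(k):
                B[col, j], B[piv, j] = B[piv, j], B[col, j]
        inv_p = 1.0 / A[col, col]
        for r in range(col + 1, m):
            factor = A[r, col] * inv_p
            if factor != 0.0:
                for j in range(col + 1, m):
                    A[r, j] -= factor * A[col, j]
                for j in range(k):
                    B[r, j] -= factor * B[col, j]
    for col in range(m - 1, -1, -1):
        inv_p = 1.0 / A[col, col]
        for j in range(k):
            x = B[col, j]
            for r in range(col + 1, m):
                x -= A[col, r] * B[r, j]
            B[col, j] = x * inv_p
    return B


@njit(cache=True)
def _block_thomas(sub, diag, sup, rhs):
    """Solve the block-tridiagonal system with 6x6 blocks (forward block
    elimination, hand-rolled small-matrix kernels)."""
    n = diag.shape[0]
    m = diag.shape[1]
    Dp = diag.copy()
    rp = rhs.copy()
    work = np.empty((m, m + 1))
    for i in range(1, n):
        # work <- inv(Dp[i-1]) @ [sup[i-1] | rp[i-1]]
        for r in range(m):
            for cc in range(m):
                work[r, cc] = sup[i - 1, r, cc]
            work[r, m] = rp[i - 1, r]
        A = Dp[i - 1].copy()
        _gauss_solve_multi(A, work)
        # Dp[i] -= sub[i-1] @ work[:, :m];  rp[i] -= sub[i-1] @ work[:, m]
        for r in range(m):
            for cc in range(m):
                acc = 0.0
                for t in range(m):
                    acc += sub[i - 1, r, t] * work[t, cc]
                Dp[i, r, cc] -= acc
            acc = 0.0
            for t in range(m):
                acc += sub[i - 1, r, t] * work[t, m]
            rp[i, r] -= acc
    u = np.empty((n, m))
    b = np.empty((m, 1))
    for r in range(m):
        b[r, 0] = rp[n - 1, r]
    A = Dp[n - 1].copy()
    _gauss_solve_multi(A, b)
    for r in range(m):
        u[n - 1, r] = b[r, 0]
    for i in range(n - 2, -1, -1):
        for r in range(m):
            acc = rp[i, r]
            for t in range(m):
                acc -= sup[i, r, t] * u[i + 1, t]
            b[r, 0] = acc
        A = Dp[i].copy()
        _gauss_solve_multi(A, b)
        for r in range(m):
            u[i, r] = b[r, 0]
    return u


@njit(cache=True)
def simulate_kernel(x0, c0, N0, M0, rho0, v0, eps0, pv, dt,
                    total_steps, steps_per_day, n_days,
                    picard_tol, max_iter, clip_abort_frac,
                    j_edge, wgt_edge, L):
    """Full time loop; returns (status, rsa, edge, iters, clipped_fraction)."""
    D_c = pv[0]; D_F = pv[1]; chi_F = pv[2]; k_c = pv[3]
    a_c_I = pv[4]; a_c_II = pv[5]; a_c_III = pv[6]; a_c_IV = pv[7]
    delta_c = pv[8]; eta_I = pv[9]; eta_II = pv[10]; k_F = pv[11]
    r_F = pv[12]; r_F_max = pv[13]; kappa_F = pv[14]; delta_N = pv[15]
    delta_M = pv[16]; k_rho_max = pv[17]; delta_rho = pv[18]; rho_t = pv[19]
    mu = pv[20]; E_stiff = pv[21]; xi = pv[22]; R_tr = pv[23]; zeta = pv[24]
    N_bar = pv[25]; rho_bar = pv[26]; c_w = pv[27]
    k_rho = pv[28]
    opq = pv[29]

    n = x0.shape[0]
    x = x0.copy()
    c = c0.copy(); N = N0.copy(); M = M0.copy()
    rho = rho0.copy(); v = v0.copy(); eps = eps0.copy()

    rsa = np.zeros(n_days)
    edge_traj = np.zeros(n_days)
    iters = np.zeros(total_steps, dtype=np.int64)
    clipped = np.zeros(4)

    # initial species totals (trapezoid weights on the initial mesh)
    w0 = np.zeros(n)
    for e in range(n - 1):
        he = x0[e + 1] - x0[e]
        w0[e] += 0.5 * he
        w0[e + 1] += 0.5 * he
    tot0 = np.zeros(4)
    for i in range(n):
        tot0[0] += w0[i] * c0[i]
        tot0[1] += w0[i] * N0[i]
        tot0[2] += w0[i] * M0[i]
        tot0[3] += w0[i] * rho0[i]

    diag = np.zeros((n, 6, 6))
    sub = np.zeros((n - 1, 6, 6))
    sup = np.zeros((n - 1, 6, 6))
    rhs = np.zeros((n, 6))
    floors = np.array([c_w, N_bar, N_bar, rho_bar, 1e-3, 1e-3])

    day = 0
    for step in range(total_steps):
        # previous-step fields
        cp = c.copy(); Np = N.copy(); Mp = M.copy()
        rhop = rho.copy(); vp = v.copy(); epsp = eps.copy()
        x_old = x.copy()

        converged = False
        n_it = 0
        for _ in range(max_iter):
            n_it += 1
            x_new = x_old + dt * v
            diag[:] = 0.0; sub[:] = 0.0; sup[:] = 0.0; rhs[:] = 0.0

            # geometry on the trial mesh
            tangled = False
            for e in range(n - 1):
                if x_new[e + 1] - x_new[e] <= 0.0:
                    tangled = True
            if tangled:
                return (MESH_TANGLED, rsa, edge_traj, iters, clipped)

            # nodal terms
            for i in range(n):
                hl = x_new[i] - x_new[i - 1] if i > 0 else 0.0
                hr = x_new[i + 1] - x_new[i] if i < n - 1 else 0.0
                ML = 0.5 * (hl + hr)
                dv_int = 0.0
                if i > 0:
                    dv_int += 0.5 * (v[i] - v[i - 1])
                if i < n - 1:
                    dv_int += 0.5 * (v[i + 1] - v[i])

                ci = c[i]; Ni = N[i]; Mi = M[i]; rhoi = rho[i]

                protease = (Ni + eta_II * Mi) / (1.0 + a_c_III * ci) * rhoi
                lam_c = delta_c * protease
                lam_N = delta_N + k_F * ci
                lam_M = delta_M
                lam_rho = delta_rho * protease

                R_c = (k_c * ci / (a_c_II + ci) * (Ni + eta_II * Mi)
                       - delta_c * protease * ci)
                crowd = 1.0 - kappa_F * (Ni + Mi)
                enh = ci / (a_c_I + ci)
                N_pow = Ni ** opq if Ni > 0.0 else 0.0
                M_pow = Mi ** opq if Mi > 0.0 else 0.0
                R_N = (r_F * (1.0 + r_F_max * enh) * crowd * N_pow
                       - k_F * ci * Ni - delta_N * Ni)
                R_M = (r_F * (1.0 + r_F_max) * enh * crowd * M_pow
                       + k_F * ci * Ni - delta_M * Mi)
                R_rho = (k_rho * (1.0 + k_rho_max * ci / (a_c_IV + ci))
                         * (Ni + eta_I * Mi) - delta_rho * protease * rhoi)

                diag[i, 0, 0] += ML * (1.0 / dt + lam_c) + dv_int
                diag[i, 1, 1] += ML * (1.0 / dt + lam_N) + dv_int
                diag[i, 2, 2] += ML * (1.0 / dt + lam_M) + dv_int
                diag[i, 3, 3] += ML * (1.0 / dt + lam_rho) + dv_int
                rhs[i, 0] += ML * (cp[i] / dt + R_c + lam_c * ci)
                rhs[i, 1] += ML * (Np[i] / dt + R_N + lam_N * Ni)
                rhs[i, 2] += ML * (Mp[i] / dt + R_M + lam_M * Mi)
                rhs[i, 3] += ML * (rhop[i] / dt + R_rho + lam_rho * rhoi)

                # velocity: inertia
                diag[i, 4, 4] += rho_t * ML / dt
                rhs[i, 4] += rho_t * ML * vp[i] / dt

                # strain: mass + implicit growth
                g = zeta * ci * Mi
                diag[i, 5, 5] += ML * (1.0 / dt + g)
                rhs[i, 5] += ML * epsp[i] / dt

            # elementwise terms
            for e in range(n - 1):
                he = x_new[e + 1] - x_new[e]
                # species diffusion
                keC = D_c / he
                Nmid = 0.5 * (N[e] + N[e + 1])
                Mmid = 0.5 * (M[e] + M[e + 1])
                keF = D_F * (Nmid + Mmid) / he
                ce = chi_F * (c[e + 1] - c[e]) / he

                diag[e, 0, 0] += keC
                diag[e + 1, 0, 0] += keC
                sup[e, 0, 0] -= keC
                sub[e, 0, 0] -= keC
                for k in range(1, 3):
                    diag[e, k, k] += keF + 0.5 * ce
                    diag[e + 1, k, k] += keF - 0.5 * ce
                    sup[e, k, k] += -keF + 0.5 * ce
                    sub[e, k, k] += -keF - 0.5 * ce

                # velocity: convection, viscous stiffness, elastic coupling
                vmid = 0.5 * (v[e] + v[e + 1])
                vc = 0.5 * rho_t * vmid
                diag[e, 4, 4] -= vc
                sup[e, 4, 4] += vc
                diag[e + 1, 4, 4] += vc
                sub[e, 4, 4] -= vc

                kmu = mu / he
                diag[e, 4, 4] += kmu
                diag[e + 1, 4, 4] += kmu
                sup[e, 4, 4] -= kmu
                sub[e, 4, 4] -= kmu

                rhomid = 0.5 * (rho[e] + rho[e + 1])
                Emid = 0.5 * E_stiff * np.sqrt(rhomid)
                diag[e, 4, 5] -= Emid
                sup[e, 4, 5] -= Emid
                diag[e + 1, 4, 5] += Emid
                sub[e, 4, 5] += Emid

                # traction body force
                psi_l = xi * M[e] * rho[e] / (R_tr * R_tr + rho[e] * rho[e])
                psi_r = (xi * M[e + 1] * rho[e + 1]
                         / (R_tr * R_tr + rho[e + 1] * rho[e + 1]))
                psi_mid = 0.5 * (psi_l + psi_r)
                rhs[e, 4] += psi_mid
                rhs[e + 1, 4] -= psi_mid

                # strain-velocity coupling: (eps_i - 1) int (v+)' phi_i
                cl = 0.5 * (eps[e] - 1.0)
                cr = 0.5 * (eps[e + 1] - 1.0)
                diag[e, 5, 4] -= cl
                sup[e, 5, 4] += cl
                diag[e + 1, 5, 4] += cr
                sub[e, 5, 4] -= cr

            # Dirichlet rows: v at both ends; c, N, M at the far end
            bc_nodes = (0, n - 1, n - 1, n - 1, n - 1)
            bc_field = (4, 4, 0, 1, 2)
            bc_value = (0.0, 0.0, 0.0, N_bar, 0.0)
            for b in range(5):
                node = bc_nodes[b]
                k = bc_field[b]
                for j in range(6):
                    diag[node, k, j] = 0.0
                if node > 0:
                    for j in range(6):
                        sub[node - 1, k, j] = 0.0
                if node < n - 1:
                    for j in range(6):
                        sup[node, k, j] = 0.0
                diag[node, k, k] = 1.0
                rhs[node, k] = bc_value[b]

            u = _block_thomas(sub, diag, sup, rhs)

            # convergence: combined relative update norm
            ok = True
            worst = 0.0
            for k in range(6):
                dmax = 0.0
                smax = floors[k]
                for i in range(n):
                    ui = u[i, k]
                    if not np.isfinite(ui):
                        ok = False
                    if k == 0:
                        d = abs(ui - c[i])
                    elif k == 1:
                        d = abs(ui - N[i])
                    elif k == 2:
                        d = abs(ui - M[i])
                    elif k == 3:
                        d = abs(ui - rho[i])
                    elif k == 4:
                        d = abs(ui - v[i])
                    else:
                        d = abs(ui - eps[i])
                    if d > dmax:
                        dmax = d
                    if abs(ui) > smax:
                        smax = abs(ui)
                r = dmax / smax
                if r > worst:
                    worst = r
            if not ok:
                return (NONFINITE, rsa, edge_traj, iters, clipped)

            c = u[:, 0].copy(); N = u[:, 1].copy(); M = u[:, 2].copy()
            rho = u[:, 3].copy(); v = u[:, 4].copy(); eps = u[:, 5].copy()
            if worst < picard_tol:
                converged = True
                break

        iters[step] = n_it
        if not converged:
            return (PICARD_FAIL, rsa, edge_traj, iters, clipped)

        # commit mesh with the converged velocity
        x = x_old + dt * v
        for e in range(n - 1):
            if x[e + 1] - x[e] <= 0.0:
                return (MESH_TANGLED, rsa, edge_traj, iters, clipped)

        # clip negative species, track clipped mass
        w = np.zeros(n)
        for e in range(n - 1):
            he = x[e + 1] - x[e]
            w[e] += 0.5 * he
            w[e + 1] += 0.5 * he
        for k in range(4):
            arr = c if k == 0 else (N if k == 1 else (M if k == 2 else rho))
            neg = 0.0
            tot = 0.0
            for i in range(n):
                tot += w[i] * abs(arr[i])
                if arr[i] < 0.0:
                    neg -= w[i] * arr[i]
                    arr[i] = 0.0
            if neg > 0.0:
                clipped[k] += neg
                if tot > 0.0 and neg / tot > clip_abort_frac:
                    return (CLIP_OVERFLOW, rsa, edge_traj, iters, clipped)

        for i in range(n):
            if eps[i] >= 1.0:
                return (STRAIN_BLOWUP, rsa, edge_traj, iters, clipped)

        if (step + 1) % steps_per_day == 0 and day < n_days:
            e_pos = (1.0 - wgt_edge) * x[j_edge] + wgt_edge * x[j_edge + 1]
            if e_pos <= 0.0:
                return (EDGE_COLLAPSED, rsa, edge_traj, iters, clipped)
            edge_traj[day] = e_pos
            r = e_pos / L
            rsa[day] = r if r < 1.0 else 1.0
            day += 1

    for k in range(4):
        if tot0[k] > 0.0:
            clipped[k] /= tot0[k]

    return (OK, rsa, edge_traj, iters, clipped)
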