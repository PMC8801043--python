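"""Solver verification: fixed points, analytic/ODE oracles, convergence
orders, RSA extraction, and the fast-kernel/reference cross-check."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import scarnet as sn
from scarnet.errors import (GeometryError, SolverError,
                            UnstableParametersError)
from scarnet.fem_solver import LinearSystem, _pack

from conftest import make_uniform_state


def diffusion_only_params(D=2.0):
    """All couplings switched off: the signaling equation reduces to the
    heat equation (zero-flux at x=0, zero Dirichlet at the far end)."""
    return sn.ParameterSet(
        D_c=D, D_F=0.0, chi_F=0.0, k_c=0.0, k_F=0.0, r_F=0.0,
        xi=0.0, zeta=0.0,
        delta_c=1e-30, delta_N=1e-30, delta_M=1e-30, delta_rho=1e-30)


def reaction_only_params():
    """Fluxes and mechanics off: every node follows the 0-D reaction ODEs."""
    return sn.ParameterSet(D_c=0.0, D_F=0.0, chi_F=0.0, xi=0.0, zeta=0.0)


def reaction_rhs(params):
    """Independent hand-coded 0-D reaction system for the ODE oracle."""
    p = params
    opq = 1.0 + p.q_exponent

    def rhs(t, y):
        c, N, M, rho = y
        prot = (N + p.eta_II * M) * rho / (1 + p.a_c_III * c)
        Rc = p.k_c * c / (p.a_c_II + c) * (N + p.eta_II * M) - p.delta_c * prot * c
        crowd = 1 - p.kappa_F * (N + M)
        enh = c / (p.a_c_I + c)
        RN = p.r_F * (1 + p.r_F_max * enh) * crowd * N ** opq \
            - p.k_F * c * N - p.delta_N * N
        RM = p.r_F * (1 + p.r_F_max) * enh * crowd * M ** opq \
            + p.k_F * c * N - p.delta_M * M
        Rrho = p.k_rho * (1 + p.k_rho_max * c / (p.a_c_IV + c)) \
            * (N + p.eta_I * M) - p.delta_rho * prot * rho
        return [Rc, RN, RM, Rrho]

    return rhs


def run_steps(state, params, dt, n_steps):
    cfg = sn.SolverConfig(dt=dt, total_time=max(dt * n_steps, 1.0))
    for _ in range(n_steps):
        state = sn.time_step(state, None, params, cfg)
    return state


# ----------------------------------------------------------------------
# fixed points
# ----------------------------------------------------------------------

def test_equilibrium_solves_the_assembled_system(default_params):
    state = make_uniform_state(default_params, n=21)
    system = sn.assemble_step(state, state, sn.Mesh(state.x),
                              default_params, dt=1.0)
    res = np.abs(system.residual(_pack(state))).reshape(-1, 6)
    scales = np.array([default_params.c_w, default_params.N_bar,
                       default_params.N_bar, default_params.rho_bar,
                       1.0, 1.0])
    assert np.all(res / scales < 1e-8)


def test_assembly_is_bitwise_deterministic(default_params):
    state = make_uniform_state(default_params, n=21, c=3e-9, M=400.0)
    mesh = sn.Mesh(state.x)
    s1 = sn.assemble_step(state, state, mesh, default_params, dt=1.0)
    s2 = sn.assemble_step(state, state, mesh, default_params, dt=1.0)
    assert np.array_equal(s1.ab, s2.ab)
    assert np.array_equal(s1.rhs, s2.rhs)


def test_equilibrium_initial_data_keeps_rsa_at_one(default_params):
    mesh = sn.Mesh.uniform(202, 10.0)
    eq = sn.equilibrium_state(default_params, mesh.nodes)
    res = sn.simulate(default_params, mesh, sn.SolverConfig(),
                      initial_state=eq)
    assert np.max(np.abs(res.rsa - 1.0)) < 1e-6


def test_time_step_preserves_equilibrium(default_params):
    state = make_uniform_state(default_params, n=31)
    out = run_steps(state.copy(), default_params, dt=1.0, n_steps=5)
    assert np.max(np.abs(out.N - default_params.N_bar)) / default_params.N_bar < 1e-9
    assert np.max(np.abs(out.rho - default_params.rho_bar)) / default_params.rho_bar < 1e-9
    assert np.max(np.abs(out.v)) < 1e-12


# ----------------------------------------------------------------------
# analytic and ODE oracles
# ----------------------------------------------------------------------

def test_pure_diffusion_matches_single_mode_decay():
    D, T, dt = 2.0, 10.0, 0.05
    p = diffusion_only_params(D)
    x = np.linspace(0.0, 10.0, 202)
    state = sn.equilibrium_state(p, x)
    A = 1e-8
    state.c = A * np.cos(np.pi * x / 20.0)
    out = run_steps(state, p, dt, int(T / dt))
    exact = A * np.cos(np.pi * x / 20.0) * np.exp(-D * (np.pi / 20.0) ** 2 * T)
    assert np.max(np.abs(out.c - exact)) / A < 0.01


def test_homogeneous_reduction_matches_stiff_ode_oracle():
    p = reaction_only_params()
    y0 = (5e-9, 4e3, 5e2, 0.04)
    T, dt = 5.0, 0.01
    state = make_uniform_state(p, n=21, c=y0[0], N=y0[1], M=y0[2], rho=y0[3])
    out = run_steps(state, p, dt, int(T / dt))
    sol = solve_ivp(reaction_rhs(p), (0, T), y0, method="LSODA",
                    rtol=1e-10, atol=[1e-20, 1e-6, 1e-6, 1e-12])
    ref = sol.y[:, -1]
    node = 5  # interior node, away from the far-field Dirichlet row
    num = np.array([out.c[node], out.N[node], out.M[node], out.rho[node]])
    assert np.all(np.abs(num - ref) / np.abs(ref) < 0.005)


def test_backward_euler_is_first_order_in_time():
    p = reaction_only_params()
    y0 = (5e-9, 4e3, 5e2, 0.04)
    T = 4.0
    sol = solve_ivp(reaction_rhs(p), (0, T), y0, method="LSODA",
                    rtol=1e-11, atol=[1e-21, 1e-7, 1e-7, 1e-13])
    ref = sol.y[:, -1]

    def error(dt):
        state = make_uniform_state(p, n=11, c=y0[0], N=y0[1], M=y0[2],
                                   rho=y0[3])
        out = run_steps(state, p, dt, int(round(T / dt)))
        num = np.array([out.c[3], out.N[3], out.M[3], out.rho[3]])
        return np.max(np.abs(num - ref) / np.abs(ref))

    errs = [error(dt) for dt in (0.4, 0.2, 0.1)]
    orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
    assert np.all(np.array(errs[:-1]) > np.array(errs[1:]))
    assert np.all(orders > 0.9), orders
    assert np.all(orders < 1.3), orders


def test_linear_elements_are_second_order_in_space():
    D, T, dt = 2.0, 10.0, 0.05
    p = diffusion_only_params(D)

    def solve_on(n):
        x = np.linspace(0.0, 10.0, n)
        state = sn.equilibrium_state(p, x)
        state.c = 1e-8 * np.cos(np.pi * x / 20.0)
        return run_steps(state, p, dt, int(T / dt)).c

    c26, c51, c101 = solve_on(26), solve_on(51), solve_on(101)
    d1 = np.max(np.abs(c26 - c51[::2]))
    d2 = np.max(np.abs(c51 - c101[::2]))
    order = np.log2(d1 / d2)
    assert 1.7 < order < 2.3, order


# ----------------------------------------------------------------------
# full simulation behavior
# ----------------------------------------------------------------------

def test_zero_traction_means_no_contraction(default_params, mesh61):
    p = default_params.replace(xi=0.0)
    res = sn.simulate(p, mesh61, sn.SolverConfig())
    assert np.max(np.abs(res.rsa - 1.0)) < 1e-9


def test_wounded_run_dips_then_retracts(wounded_result):
    rsa = wounded_result.rsa
    assert rsa.shape == (365,)
    assert np.all((rsa > 0) & (rsa <= 1))
    imin = int(np.argmin(rsa))
    assert imin < 364                      # maximum contraction before the end
    assert rsa[-1] > rsa[imin]             # retraction after the minimum
    assert wounded_result.min_rsa <= wounded_result.last_rsa


def test_more_traction_never_lessens_peak_contraction(default_params, mesh61):
    mins = []
    for xi in (0.6e-3, 1.2e-3, 1.8e-3):
        res = sn.simulate(default_params.replace(xi=xi), mesh61,
                          sn.SolverConfig())
        mins.append(res.min_rsa)
    assert mins[0] >= mins[1] >= mins[2]


def test_unstable_parameters_are_refused():
    p = sn.ParameterSet(k_c=1.0)
    with pytest.raises(UnstableParametersError):
        sn.simulate(p, sn.Mesh.uniform(31, 10.0))


def test_fast_kernel_matches_reference_loop(default_params):
    mesh = sn.Mesh.uniform(41, 10.0)
    cfg = sn.SolverConfig(total_time=120.0)
    fast = sn.simulate(default_params, mesh, cfg, fast=True)
    ref = sn.simulate(default_params, mesh, cfg, fast=False)
    assert np.max(np.abs(fast.rsa - ref.rsa)) < 1e-9
    assert np.array_equal(fast.picard_iterations, ref.picard_iterations)


# ----------------------------------------------------------------------
# RSA utilities
# ----------------------------------------------------------------------

def test_compute_rsa_basics():
    edge = np.array([2.0, 1.0, 1.5])
    assert np.allclose(sn.compute_rsa(edge, 2.0), [1.0, 0.5, 0.75])
    with pytest.raises(GeometryError):
        sn.compute_rsa(edge, 0.0)
    with pytest.raises(GeometryError):
        sn.compute_rsa(np.array([1.0, -0.1]), 1.0)


def test_edge_advection_matches_exponential_closed_form():
    k, x0, T, dt = 0.3, 2.0, 1.0, 0.01
    traj = sn.advect_edge(lambda x, t: -k * x, x0, T, dt)
    exact = x0 * np.exp(-k * np.arange(len(traj)) * dt)
    assert np.max(np.abs(traj - exact) / exact) < 1e-3


def test_mesh_and_config_validation():
    with pytest.raises(SolverError):
        sn.Mesh(np.array([0.0, 1.0, 0.5]))
    with pytest.raises(SolverError):
        sn.SolverConfig(dt=-1.0)
    mesh = sn.Mesh.uniform(11, 10.0)
    assert mesh.n_nodes == 11
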