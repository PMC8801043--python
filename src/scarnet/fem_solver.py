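"""Finite-element solver for the 1D morphoelastic contraction model.

Linear (P1) elements in space, backward Euler in time, all six unknowns
(c, N, M, rho, v, eps) solved monolithically with inner Picard iterations
that lag the nonlinear coefficients.  The mesh is updated-Lagrangian:
nodes are material points advected with the displacement velocity each
step, so the material derivative is simply the nodal time difference and
the only remaining convective contribution is the dilution term z*v'.

Geometry: half domain [0, domain_length] with a symmetry boundary at
x=0 (v=0, zero species flux) and far-field dermal conditions at the
outer boundary (v=0, c=0, N=N_bar, M=0).  The wound occupies [0, L) with
a smooth sigmoidal initial profile.

The relative surface area (RSA) is the wound-interval length relative to
its initial length; the wound edge is the material point initially at
x = L and is tracked by interpolating its position on the moving mesh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.linalg.lapack import dgbsv as _dgbsv

from . import _kernels
from .errors import (GeometryError, SolverError, StateValidityError,
                     StepFailureError, UnstableParametersError)
from .model_core import (ParameterSet, StateField, elastic_modulus,
                         equilibrium_state, growth_rate_coefficient,
                         reaction_terms, traction_potential)

logger = logging.getLogger(__name__)

__all__ = [
    "Mesh",
    "SolverConfig",
    "SimulationResult",
    "LinearSystem",
    "make_initial_state",
    "assemble_step",
    "time_step",
    "simulate",
    "compute_rsa",
    "advect_edge",
]

_NF = 6  # unknowns per node: c, N, M, rho, v, eps
_BAND = 2 * _NF - 1  # bandwidth of the interleaved block-tridiagonal system
_GB_ROWS = 3 * _BAND + 1  # LAPACK gbsv storage rows (kl extra workspace rows)

# Per-mesh-size cache of the fancy-index arrays that scatter 6x6 node blocks
# into LAPACK general-band storage (row = kl + ku + i - j).
_IDX_CACHE: Dict[int, tuple] = {}


def _band_indices(n: int) -> tuple:
    try:
        return _IDX_CACHE[n]
    except KeyError:
        a, b = np.meshgrid(np.arange(_NF), np.arange(_NF), indexing="ij")
        rows_diag = (2 * _BAND + a - b)[None]
        rows_sub = (2 * _BAND + _NF + a - b)[None]
        rows_sup = (2 * _BAND - _NF + a - b)[None]
        cols_diag = _NF * np.arange(n)[:, None, None] + b
        cols_off = _NF * np.arange(n - 1)[:, None, None] + b
        _IDX_CACHE[n] = (rows_diag, rows_sub, rows_sup, cols_diag, cols_off)
        return _IDX_CACHE[n]


@dataclass(frozen=True)
class Mesh:
    """1D mesh: node coordinates in cm, implicit (i, i+1) connectivity."""

    nodes: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        if nodes.ndim != 1 or nodes.size < 3:
            raise SolverError("mesh needs at least 3 nodes")
        if np.any(np.diff(nodes) <= 0):
            raise SolverError("mesh node coordinates must be strictly increasing")

    @classmethod
    def uniform(cls, n_nodes: int = 202, length: float = 10.0) -> "Mesh":
        return cls(np.linspace(0.0, length, n_nodes))

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]


@dataclass(frozen=True)
class SolverConfig:
    """Time stepping and Picard controls."""

    dt: float = 1.0                 # time step [days]
    total_time: float = 365.0       # horizon [days]
    picard_tol: float = 1e-4        # combined relative-update tolerance
    picard_max_iter: int = 50
    clip_negative: bool = True
    abort_clip_fraction: float = 1e-3   # fatal clipped-mass fraction per species
    store_snapshots: bool = False
    snapshot_every: int = 30            # days between stored snapshots

    def __post_init__(self):
        if self.dt <= 0 or self.total_time <= 0:
            raise SolverError("dt and total_time must be positive")


@dataclass
class SimulationResult:
    """Daily RSA course plus the wound-edge trajectory and solver diagnostics."""

    days: np.ndarray                 # day stamps, 1..total_days
    rsa: np.ndarray                  # relative surface area, in (0, 1]
    edge: np.ndarray                 # wound-edge position [cm]
    picard_iterations: np.ndarray    # iterations per time step
    clipped_fraction: Dict[str, float] = field(default_factory=dict)
    snapshots: Dict[int, StateField] = field(default_factory=dict)

    @property
    def min_rsa(self) -> float:
        return float(np.min(self.rsa))

    @property
    def last_rsa(self) -> float:
        return float(self.rsa[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"day": self.days, "rsa": self.rsa, "edge": self.edge})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ----------------------------------------------------------------------
# initial condition
# ----------------------------------------------------------------------

def make_initial_state(params: ParameterSet, mesh: Mesh) -> StateField:
    """Wounded initial condition: smooth sigmoidal transition at x = L.

    Inside the wound signaling is elevated (c_w) while fibroblasts and
    collagen are reduced to their wound fractions; myofibroblasts appear
    only later through signaling-driven differentiation.
    """
    x = mesh.nodes
    w = 1.0 / (1.0 + np.exp(np.clip(params.steepness * (x - params.L), -60, 60)))
    state = equilibrium_state(params, x)
    state.c = params.c_w * w
    state.N = params.N_bar * (1.0 - (1.0 - params.wound_cell_fraction) * w)
    state.rho = params.rho_bar * (1.0 - (1.0 - params.wound_collagen_fraction) * w)
    return state


# ----------------------------------------------------------------------
# assembly
# ----------------------------------------------------------------------

@dataclass
class LinearSystem:
    """One monolithic Picard step: banded matrix (LAPACK gbsv layout) + rhs.

    Unknown ordering is node-major, field-minor: index 6*i + f with
    f in (c, N, M, rho, v, eps).  A[i, j] lives at ab[2*band + i - j, j];
    the first ``band`` rows are LAPACK fill-in workspace.
    """

    ab: np.ndarray    # (3*band+1, 6n) LAPACK general-band storage
    rhs: np.ndarray   # (6n,)

    def solve(self, overwrite: bool = False) -> np.ndarray:
        _, _, x, info = _dgbsv(_BAND, _BAND, self.ab, self.rhs,
                               overwrite_ab=overwrite, overwrite_b=overwrite)
        if info != 0:
            raise SolverError(f"singular Picard system (gbsv info={info})")
        return x

    def to_dense(self) -> np.ndarray:
        """Dense matrix (tests only)."""
        n = self.rhs.size
        A = np.zeros((n, n))
        for i in range(n):
            lo, hi = max(0, i - _BAND), min(n, i + _BAND + 1)
            for j in range(lo, hi):
                A[i, j] = self.ab[2 * _BAND + i - j, j]
        return A

    def residual(self, solution_vector: np.ndarray) -> np.ndarray:
        return self.to_dense() @ solution_vector - self.rhs


def _pack(state: StateField) -> np.ndarray:
    u = np.empty(_NF * state.n_nodes)
    for k, name in enumerate(("c", "N", "M", "rho", "v", "eps")):
        u[k::_NF] = getattr(state, name)
    return u


def _assemble(prev: StateField, it: StateField, x_new: np.ndarray,
              params: ParameterSet, dt: float) -> LinearSystem:
    """Assemble the banded backward-Euler/Picard system on the mesh x_new.

    All nonlinear coefficients are frozen at the current Picard iterate
    ``it``; reaction sources use the exact closures from model_core with an
    extra nonnegative implicit damping so that the converged fixed point is
    the fully implicit backward-Euler state.
    """
    p = params
    n = x_new.shape[0]
    h = np.diff(x_new)
    if np.any(h <= 0):
        raise SolverError("mesh tangling: node ordering lost during motion")

    # lumped masses on the new mesh
    ML = np.zeros(n)
    ML[:-1] += 0.5 * h
    ML[1:] += 0.5 * h

    def mid(a):
        return 0.5 * (a[1:] + a[:-1])

    c, N, M, rho, v, eps = it.c, it.N, it.M, it.rho, it.v, it.eps

    # dilution integral per node: int v' phi_i dx (piecewise-linear v)
    dv_int = np.zeros(n)
    dv_elem = np.diff(v)
    dv_int[:-1] += 0.5 * dv_elem
    dv_int[1:] += 0.5 * dv_elem

    # block containers
    diag = np.zeros((n, _NF, _NF))
    sub = np.zeros((n - 1, _NF, _NF))   # row block i+1, col block i
    sup = np.zeros((n - 1, _NF, _NF))   # row block i, col block i+1
    rhs = np.zeros((n, _NF))

    # ---------- species rows (c=0, N=1, M=2, rho=3) ----------
    R = reaction_terms(it, p, validate=False)
    protease = (N + p.eta_II * M) / (1.0 + p.a_c_III * c) * rho
    lam = {
        "c": p.delta_c * protease,
        "N": p.delta_N + p.k_F * c,
        "M": np.full(n, p.delta_M),
        "rho": p.delta_rho * protease,
    }
    z_it = {"c": c, "N": N, "M": M, "rho": rho}
    z_prev = {"c": prev.c, "N": prev.N, "M": prev.M, "rho": prev.rho}

    # diffusivities at element midpoints
    total_mid = mid(N) + mid(M)
    diff_coef = {
        "c": np.full(n - 1, p.D_c),
        "N": p.D_F * total_mid,
        "M": p.D_F * total_mid,
        "rho": None,
    }
    dc_elem = np.diff(c) / h  # signaling gradient per element (chemotaxis)

    for k, name in enumerate(("c", "N", "M", "rho")):
        diag[:, k, k] += ML * (1.0 / dt + lam[name]) + dv_int
        rhs[:, k] += ML * (z_prev[name] / dt + R[name] + lam[name] * z_it[name])
        Dk = diff_coef[name]
        if Dk is not None:
            ke = Dk / h
            diag[:-1, k, k] += ke
            diag[1:, k, k] += ke
            sup[:, k, k] -= ke
            sub[:, k, k] -= ke
        if name in ("N", "M") and p.chi_F != 0.0:
            # -chi * c'_e * int phi_j phi_i'  -> local [[-1/2,-1/2],[1/2,1/2]]
            ce = p.chi_F * dc_elem
            diag[:-1, k, k] += 0.5 * ce
            sup[:, k, k] += 0.5 * ce
            diag[1:, k, k] -= 0.5 * ce
            sub[:, k, k] -= 0.5 * ce

    # ---------- velocity row (4) ----------
    kv = 4
    diag[:, kv, kv] += p.rho_t * ML / dt
    rhs[:, kv] += p.rho_t * ML * prev.v / dt

    # inertia convection: rho_t * v_it * (v+)' per element, int phi_i = h/2
    vconv = 0.5 * p.rho_t * mid(v)
    diag[:-1, kv, kv] -= vconv
    sup[:, kv, kv] += vconv
    diag[1:, kv, kv] += vconv
    sub[:, kv, kv] -= vconv

    # viscous stiffness mu * int v' phi_i'
    ke = p.mu / h
    diag[:-1, kv, kv] += ke
    diag[1:, kv, kv] += ke
    sup[:, kv, kv] -= ke
    sub[:, kv, kv] -= ke

    # elastic coupling: int E sqrt(rho) eps+ phi_i'  (eps columns)
    Emid = elastic_modulus(mid(rho), p)
    # node i, right element: -E_r/2 on eps_i and eps_{i+1}
    diag[:-1, kv, 5] -= 0.5 * Emid
    sup[:, kv, 5] -= 0.5 * Emid
    # node i, left element: +E_l/2 on eps_{i-1} and eps_i
    diag[1:, kv, 5] += 0.5 * Emid
    sub[:, kv, 5] += 0.5 * Emid

    # traction body force: rhs += psi_r - psi_l (element midpoint potential)
    psi_mid = mid(traction_potential(M, rho, p))
    rhs[:-1, kv] += psi_mid
    rhs[1:, kv] -= psi_mid

    # ---------- strain row (5) ----------
    ks = 5
    g = growth_rate_coefficient(c, M, p)  # G = g * eps, implicit
    diag[:, ks, ks] += ML * (1.0 / dt + g)
    rhs[:, ks] += ML * prev.eps / dt
    # (eps_it - 1) * int (v+)' phi_i
    coef = 0.5 * (eps - 1.0)
    diag[:-1, ks, kv] -= coef[:-1]
    sup[:, ks, kv] += coef[:-1]
    diag[1:, ks, kv] += coef[1:]
    sub[:, ks, kv] -= coef[1:]

    # ---------- boundary conditions ----------
    # x=0: symmetry, v=0 (species fluxes natural -> nothing to do)
    def dirichlet(node, k, value):
        diag[node, k, :] = 0.0
        if node > 0:
            sub[node - 1, k, :] = 0.0
        if node < n - 1:
            sup[node, k, :] = 0.0
        diag[node, k, k] = 1.0
        rhs[node, k] = value

    dirichlet(0, kv, 0.0)
    dirichlet(n - 1, kv, 0.0)
    dirichlet(n - 1, 0, 0.0)          # far-field signaling
    dirichlet(n - 1, 1, p.N_bar)      # far-field fibroblasts
    dirichlet(n - 1, 2, 0.0)          # far-field myofibroblasts

    # ---------- pack into LAPACK general-band storage ----------
    rows_diag, rows_sub, rows_sup, cols_diag, cols_off = _band_indices(n)
    ab = np.zeros((_GB_ROWS, _NF * n))
    ab[rows_diag, cols_diag] = diag
    ab[rows_sub, cols_off] = sub
    ab[rows_sup, cols_off + _NF] = sup

    return LinearSystem(ab=ab, rhs=rhs.ravel())


def assemble_step(state_prev: StateField, iterate: StateField, mesh: Mesh,
                  params: ParameterSet, dt: float) -> LinearSystem:
    """Public assembly entry point: the linear system for the next Picard
    iterate on the given mesh (coefficients lagged at ``iterate``)."""
    state_prev.validate()
    return _assemble(state_prev, iterate, np.asarray(mesh.nodes, float), params, dt)


# ----------------------------------------------------------------------
# time stepping
# ----------------------------------------------------------------------

_FIELD_SCALES = ("c_w", "N_bar", "N_bar", "rho_bar", None, None)


def _update_norm(new: np.ndarray, old: np.ndarray, params: ParameterSet) -> float:
    """Combined relative update norm over all six fields."""
    floors = np.array([params.c_w, params.N_bar, params.N_bar,
                       params.rho_bar, 1e-3, 1e-3])
    d = np.abs(new - old).reshape(-1, _NF).max(axis=0)
    scale = np.maximum(np.abs(new).reshape(-1, _NF).max(axis=0), floors)
    return float(np.max(d / scale))


def time_step(state: StateField, mesh: Optional[Mesh], params: ParameterSet,
              config: SolverConfig) -> StateField:
    """Advance one backward-Euler step with inner Picard iterations.

    Returns the converged state on the advected mesh; raises
    :class:`StepFailureError` with the residual history if the Picard loop
    exhausts its iteration budget.
    """
    dt = config.dt
    x_old = state.x
    it = state.copy()
    u_old_vec = _pack(state)
    u_it = u_old_vec.copy()
    history: List[float] = []
    n = state.n_nodes

    for k in range(config.picard_max_iter):
        x_new = x_old + dt * it.v
        system = _assemble(state, it, x_new, params, dt)
        u_new = system.solve(overwrite=True)
        if not np.all(np.isfinite(u_new)):
            raise StepFailureError("non-finite Picard iterate",
                                   residual_history=history)
        norm = _update_norm(u_new, u_it, params)
        history.append(norm)
        u_it = u_new
        it = StateField(x=x_new, c=u_new[0::_NF], N=u_new[1::_NF],
                        M=u_new[2::_NF], rho=u_new[3::_NF], v=u_new[4::_NF],
                        eps=u_new[5::_NF], t=state.t + dt)
        if norm < config.picard_tol:
            break
    else:
        raise StepFailureError(
            f"Picard did not converge in {config.picard_max_iter} iterations "
            f"at t={state.t + dt:.3f} (last update {history[-1]:.3e})",
            residual_history=history)

    # commit mesh with the converged velocity
    it.x = x_old + dt * it.v
    if np.any(np.diff(it.x) <= 0):
        raise SolverError(f"mesh tangling at t={it.t:.2f}")
    it._picard_iterations = len(history)  # diagnostic, read by simulate()
    return it


def _clip_species(state: StateField, clipped_mass: Dict[str, float],
                  config: SolverConfig) -> None:
    h = np.diff(state.x)
    w = np.zeros(state.n_nodes)
    w[:-1] += 0.5 * h
    w[1:] += 0.5 * h
    for name in ("c", "N", "M", "rho"):
        arr = getattr(state, name)
        neg = arr < 0
        if np.any(neg):
            clipped = -np.sum(w[neg] * arr[neg])
            total = np.sum(w * np.abs(arr))
            clipped_mass[name] = clipped_mass.get(name, 0.0) + clipped
            if total > 0 and clipped / total > config.abort_clip_fraction:
                raise SolverError(
                    f"clipped negative mass in {name} exceeds "
                    f"{config.abort_clip_fraction:.1e} of the species total")
            arr[neg] = 0.0


def simulate(params: ParameterSet, mesh: Optional[Mesh] = None,
             config: Optional[SolverConfig] = None,
             initial_state: Optional[StateField] = None,
             fast: bool = True) -> SimulationResult:
    """Run the full 365-day (by default) contraction simulation.

    Requires a stable parameter set.  The RSA is recorded once per day;
    entry k is the state after k+1 days.

    When ``fast`` is true (and snapshots are not requested) the compiled
    kernel in :mod:`scarnet._kernels` is used; it implements the identical
    discretization and is cross-checked against this reference loop in the
    test suite.
    """
    if not params.is_stable:
        raise UnstableParametersError(
            "parameter set violates k_c < delta_c * rho_bar * a_c_II")
    mesh = mesh or Mesh.uniform()
    config = config or SolverConfig()
    state = initial_state.copy() if initial_state is not None \
        else make_initial_state(params, mesh)
    state.validate()

    steps_per_day = int(round(1.0 / config.dt))
    if abs(steps_per_day * config.dt - 1.0) > 1e-9:
        # non-divisor time steps: record at nearest day boundaries
        steps_per_day = max(1, steps_per_day)
    total_days = int(round(config.total_time))
    total_steps = int(round(config.total_time / config.dt))

    x0 = state.x
    L = params.L
    j = int(np.searchsorted(x0, L, side="right") - 1)
    j = min(max(j, 0), len(x0) - 2)
    wgt = (L - x0[j]) / (x0[j + 1] - x0[j])
    if not (x0[0] < L <= x0[-1]):
        raise GeometryError("wound edge L outside the mesh")

    if (fast and _kernels.HAVE_NUMBA and config.clip_negative
            and not config.store_snapshots):
        return _simulate_fast(params, config, state, total_days, total_steps,
                              steps_per_day, j, wgt)

    days, rsa, edge_traj, iters = [], [], [], []
    clipped: Dict[str, float] = {}
    snapshots: Dict[int, StateField] = {}

    for step in range(1, total_steps + 1):
        state = time_step(state, None, params, config)
        if config.clip_negative:
            _clip_species(state, clipped, config)
        state.validate()
        iters.append(getattr(state, "_picard_iterations", 0))
        if step % steps_per_day == 0:
            day = step // steps_per_day
            edge = (1.0 - wgt) * state.x[j] + wgt * state.x[j + 1]
            if edge <= 0:
                raise GeometryError(f"wound edge collapsed through 0 at day {day}")
            days.append(day)
            edge_traj.append(edge)
            rsa.append(min(edge / L, 1.0))
            if config.store_snapshots and day % config.snapshot_every == 0:
                snapshots[day] = state.copy()
        if len(days) >= total_days:
            break

    # species totals for the clip diagnostic, relative to initial totals
    clip_frac = {}
    h0 = np.diff(x0)
    w0 = np.zeros(len(x0))
    w0[:-1] += 0.5 * h0
    w0[1:] += 0.5 * h0
    init = make_initial_state(params, Mesh(x0)) if initial_state is None \
        else initial_state
    for name, mass in clipped.items():
        total0 = float(np.sum(w0 * getattr(init, name)))
        clip_frac[name] = mass / total0 if total0 > 0 else 0.0

    return SimulationResult(
        days=np.asarray(days, dtype=int),
        rsa=np.asarray(rsa),
        edge=np.asarray(edge_traj),
        picard_iterations=np.asarray(iters, dtype=int),
        clipped_fraction=clip_frac,
        snapshots=snapshots,
    )


def _simulate_fast(params: ParameterSet, config: SolverConfig,
                   state: StateField, total_days: int, total_steps: int,
                   steps_per_day: int, j_edge: int,
                   wgt_edge: float) -> SimulationResult:
    """Dispatch to the compiled kernel and translate its exit status."""
    status, rsa, edge, iters, clipped = _kernels.simulate_kernel(
        state.x, state.c, state.N, state.M, state.rho, state.v, state.eps,
        _kernels.param_vector(params), config.dt,
        total_steps, steps_per_day, total_days,
        config.picard_tol, config.picard_max_iter,
        config.abort_clip_fraction, j_edge, wgt_edge, params.L)
    if status == _kernels.PICARD_FAIL:
        raise StepFailureError(
            f"Picard did not converge in {config.picard_max_iter} iterations")
    if status == _kernels.MESH_TANGLED:
        raise SolverError("mesh tangling: node ordering lost during motion")
    if status == _kernels.CLIP_OVERFLOW:
        raise SolverError("clipped negative mass exceeds the abort threshold")
    if status == _kernels.NONFINITE:
        raise StepFailureError("non-finite Picard iterate")
    if status == _kernels.STRAIN_BLOWUP:
        raise StateValidityError("effective strain reached eps >= 1")
    if status == _kernels.EDGE_COLLAPSED:
        raise GeometryError("wound edge collapsed through 0")
    names = ("c", "N", "M", "rho")
    clip_frac = {names[k]: float(clipped[k]) for k in range(4)
                 if clipped[k] > 0.0}
    return SimulationResult(
        days=np.arange(1, total_days + 1),
        rsa=rsa,
        edge=edge,
        picard_iterations=iters,
        clipped_fraction=clip_frac,
        snapshots={},
    )


# ----------------------------------------------------------------------
# RSA utilities
# ----------------------------------------------------------------------

def compute_rsa(edge_trajectory: np.ndarray, initial_edge: float) -> np.ndarray:
    """RSA(t) = edge(t) / initial_edge (in 1D the wound 'area' is its length)."""
    if initial_edge <= 0:
        raise GeometryError("initial wound edge must be positive")
    edge = np.asarray(edge_trajectory, dtype=float)
    if np.any(edge <= 0):
        raise GeometryError("edge trajectory contains nonpositive positions")
    return edge / initial_edge


def advect_edge(velocity, x0: float, t_end: float, dt: float) -> np.ndarray:
    """Integrate the wound-edge kinematics dx/dt = v(x, t) with classical RK4.

    ``velocity`` is a callable v(x, t).  Returns the edge position at every
    step, including t=0 (length round(t_end/dt)+1).
    """
    n = int(round(t_end / dt))
    out = np.empty(n + 1)
    out[0] = x = x0
    t = 0.0
    for i in range(n):
        k1 = velocity(x, t)
        k2 = velocity(x + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = velocity(x + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = velocity(x + dt * k3, t + dt)
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
        out[i + 1] = x
    return out
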