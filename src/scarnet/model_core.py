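"""Constitutive core of the 1D morphoelastic scar-contraction model.

The model tracks four dermal constituents on a deforming 1D domain —
signaling molecules ``c``, fibroblasts ``N``, myofibroblasts ``M`` and
collagen ``rho`` — together with the displacement velocity ``v`` and the
effective (elastic) strain ``eps``.  Each constituent obeys a
reaction–convection–diffusion balance

    dz/dt + (z v)' = -J_z' + R_z,

the velocity obeys a viscoelastic momentum balance driven by
myofibroblast traction, and the effective strain evolves
morphoelastically: a growth/plasticity term ``G`` converts elastic
strain into permanent deformation wherever myofibroblasts and signaling
are present.

This module houses the constitutive closures (fluxes, reactions, stress,
body force, growth) and the linear-stability admissibility check

    k_c < delta_c * rho_bar * a_c_II,

which guarantees that the homeostatic dermal equilibrium is stable so a
simulation relaxes to a scar instead of blowing up.  The closures are
isolated here so the finite-element solver never hard-codes an algebraic
form.

Units: time in days, space in cm, cells in cells/cm^3, collagen and
signaling in g/cm^3, stress in N/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Dict, Tuple

import numpy as np

from .errors import ParameterValidationError, StateValidityError

__all__ = [
    "ParameterSet",
    "StateField",
    "equilibrium_state",
    "reaction_terms",
    "flux_terms",
    "stress_and_body_force",
    "growth_term",
    "check_stability",
    "VARIED_PARAMETERS",
]

#: The 25 patient/wound parameters that vary between simulations and form
#: the surrogate input vector (order is the canonical feature order).
VARIED_PARAMETERS: Tuple[str, ...] = (
    "L",
    "D_c",
    "D_F",
    "chi_F",
    "k_c",
    "a_c_I",
    "a_c_II",
    "a_c_III",
    "a_c_IV",
    "eta_I",
    "eta_II",
    "k_F",
    "r_F",
    "r_F_max",
    "kappa_F",
    "k_rho_max",
    "delta_c",
    "delta_N",
    "delta_M",
    "delta_rho",
    "mu",
    "E_stiff",
    "xi",
    "R_traction",
    "zeta",
)

# Parameters that may legitimately be zero (switching a mechanism off),
# as opposed to densities/lengths/scales that must be strictly positive.
_NONNEGATIVE_OK = frozenset(
    {"D_c", "D_F", "chi_F", "k_c", "k_F", "r_F", "r_F_max", "k_rho_max",
     "xi", "zeta", "kappa_F"}
)


@dataclass(frozen=True)
class ParameterSet:
    """All model constants for one simulated patient/wound.

    Defaults are physiologically plausible values for human dermis in the
    units above; the 25 entries named in :data:`VARIED_PARAMETERS` are the
    ones drawn per patient when building a training corpus.
    """

    # --- wound geometry ---
    L: float = 2.5                 # wound half-length [cm]
    steepness: float = 40.0        # initial wound-profile steepness [1/cm]
    domain_length: float = 10.0    # half-domain length [cm]

    # --- transport ---
    D_c: float = 2.9e-3            # signaling diffusivity [cm^2/day]
    D_F: float = 1.0e-7            # cell random-walk coefficient [cm^5/(cells day)]
    chi_F: float = 2.0e-3          # chemotactic sensitivity [cm^5/(g day)]

    # --- signaling kinetics ---
    k_c: float = 4.0e-13           # secretion rate [g/(cells day)]
    a_c_I: float = 1.0e-8          # proliferation-enhancement saturation [g/cm^3]
    a_c_II: float = 1.0e-8         # secretion saturation [g/cm^3]
    a_c_III: float = 2.0e8         # protease inhibition [cm^3/g]
    a_c_IV: float = 1.0e-9         # collagen-secretion saturation [g/cm^3]
    delta_c: float = 5.0e-4        # protease-mediated decay [cm^6/(cells g day)]

    # --- cell kinetics ---
    eta_I: float = 2.0             # myofibroblast collagen-secretion weight [-]
    eta_II: float = 0.5            # myofibroblast protease weight [-]
    k_F: float = 1.08e7            # differentiation rate [cm^3/(g day)]
    r_F: float = 0.924             # fibroblast proliferation rate [1/day]
    r_F_max: float = 2.0           # max chemical proliferation enhancement [-]
    kappa_F: float = 1.0e-6        # crowding coefficient [cm^3/cells]
    delta_N: float = 0.02          # fibroblast apoptosis rate [1/day]
    delta_M: float = 0.06          # myofibroblast apoptosis rate [1/day]

    # --- collagen kinetics ---
    k_rho_max: float = 10.0        # secretion enhancement by signaling [-]
    delta_rho: float = 6.0e-6      # protease-mediated decay [cm^6/(cells g day)]

    # --- mechanics ---
    rho_t: float = 1.02            # tissue density [g/cm^3]
    mu: float = 100.0              # viscosity [N day/cm^2]
    E_stiff: float = 32.0          # stiffness scale, sigma_el = E*sqrt(rho)*eps
    xi: float = 1.2e-3             # traction potential magnitude [N cm^3/(cells g)]
    R_traction: float = 0.3        # collagen saturation in traction [g/cm^3]
    zeta: float = 1.5e2            # plasticity (strain remodeling) rate [cm^6/(cells g day)]

    # --- homeostatic densities & wound initial condition ---
    N_bar: float = 1.0e4           # equilibrium fibroblast density [cells/cm^3]
    rho_bar: float = 0.1           # equilibrium collagen density [g/cm^3]
    c_w: float = 1.0e-8            # initial wound signaling level [g/cm^3]
    wound_cell_fraction: float = 0.2     # N(0)/N_bar inside the wound
    wound_collagen_fraction: float = 0.2  # rho(0)/rho_bar inside the wound

    def __post_init__(self):
        for f in fields(self):
            val = getattr(self, f.name)
            if not np.isfinite(val):
                raise ParameterValidationError(f"{f.name} is not finite: {val!r}")
            if f.name in _NONNEGATIVE_OK:
                if val < 0:
                    raise ParameterValidationError(f"{f.name} must be >= 0, got {val}")
            elif val <= 0:
                raise ParameterValidationError(f"{f.name} must be > 0, got {val}")
        if not self.L < self.domain_length:
            raise ParameterValidationError(
                f"wound length L={self.L} must be smaller than the domain "
                f"({self.domain_length} cm)")
        if not 0.0 < self.wound_cell_fraction <= 1.0:
            raise ParameterValidationError("wound_cell_fraction must be in (0, 1]")
        if not 0.0 < self.wound_collagen_fraction <= 1.0:
            raise ParameterValidationError("wound_collagen_fraction must be in (0, 1]")

    # ------------------------------------------------------------------
    # derived quantities pinned by the homeostatic equilibrium
    # ------------------------------------------------------------------
    @property
    def k_rho(self) -> float:
        """Baseline collagen secretion rate; fixed by R_rho = 0 at equilibrium."""
        return self.delta_rho * self.rho_bar ** 2

    @property
    def q_exponent(self) -> float:
        """Proliferation exponent ``q`` in N^(1+q); fixed by R_N = 0 at equilibrium.

        Solves r_F (1 - kappa_F N_bar) N_bar^(1+q) = delta_N N_bar.  When
        proliferation or apoptosis is switched off the balance is trivial and
        q defaults to 0.
        """
        base = self.r_F * (1.0 - self.kappa_F * self.N_bar)
        if base <= 0.0 or self.delta_N <= 0.0 or self.N_bar == 1.0 or self.r_F == 0.0:
            return 0.0
        return math.log(self.delta_N / base) / math.log(self.N_bar)

    @property
    def is_stable(self) -> bool:
        """Linear stability of the homeostatic equilibrium (strict inequality)."""
        return self.k_c < self.delta_c * self.rho_bar * self.a_c_II

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    def to_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class StateField:
    """Nodal values of all unknowns on the (moving) material mesh at time t."""

    x: np.ndarray      # node coordinates [cm], strictly increasing
    c: np.ndarray      # signaling [g/cm^3]
    N: np.ndarray      # fibroblasts [cells/cm^3]
    M: np.ndarray      # myofibroblasts [cells/cm^3]
    rho: np.ndarray    # collagen [g/cm^3]
    v: np.ndarray      # displacement velocity [cm/day]
    eps: np.ndarray    # effective (elastic) strain [-]
    t: float = 0.0     # time [days]

    def __post_init__(self):
        arrays = [self.x, self.c, self.N, self.M, self.rho, self.v, self.eps]
        n = self.x.shape[0]
        if any(a.shape != (n,) for a in arrays):
            raise StateValidityError("all state arrays must share the node count")

    def validate(self) -> None:
        """Raise :class:`StateValidityError` on any invariant violation."""
        for name in ("c", "N", "M", "rho"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise StateValidityError(f"non-finite values in {name}")
            if np.any(arr < 0):
                raise StateValidityError(f"negative values in species {name}")
        for name in ("x", "v", "eps"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise StateValidityError(f"non-finite values in {name}")
        if np.any(self.eps >= 1.0):
            raise StateValidityError("effective strain reached eps >= 1")
        if np.any(np.diff(self.x) <= 0):
            raise StateValidityError("mesh coordinates not strictly increasing")

    def copy(self) -> "StateField":
        return StateField(*(getattr(self, f).copy() for f in
                            ("x", "c", "N", "M", "rho", "v", "eps")), t=self.t)

    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]


def equilibrium_state(params: ParameterSet, x: np.ndarray) -> StateField:
    """The homeostatic (unwounded) state: c=0, M=0, N=N_bar, rho=rho_bar, v=0, eps=0.

    All reaction terms, the stress and the body force vanish here, so it is a
    fixed point of the dynamics.
    """
    n = x.shape[0]
    z = np.zeros(n)
    return StateField(
        x=np.asarray(x, dtype=float).copy(),
        c=z.copy(),
        N=np.full(n, params.N_bar),
        M=z.copy(),
        rho=np.full(n, params.rho_bar),
        v=z.copy(),
        eps=z.copy(),
        t=0.0,
    )


# ----------------------------------------------------------------------
# constitutive closures
# ----------------------------------------------------------------------

def _protease_activity(c, N, M, params: ParameterSet):
    """Generic protease (MMP) concentration proxy: (N + eta_II M) rho / (1 + a_c_III c)
    without the rho factor — callers multiply by rho where the closure needs it."""
    return (N + params.eta_II * M) / (1.0 + params.a_c_III * c)


def reaction_terms(state: StateField, params: ParameterSet,
                   validate: bool = True) -> Dict[str, np.ndarray]:
    """Nodewise chemical reaction rates R_z for z in {c, N, M, rho}.

    Closures: Michaelis–Menten (saturating in c) secretion of signaling by
    both cell types; protease-mediated signaling decay; logistic
    proliferation with chemical enhancement, signaling-driven
    fibroblast-to-myofibroblast differentiation and apoptosis for the two
    cell types; signaling-enhanced collagen secretion with
    protease-mediated degradation.
    """
    if validate:
        state.validate()
    c, N, M, rho = state.c, state.N, state.M, state.rho
    p = params

    protease = _protease_activity(c, N, M, p) * rho

    R_c = (p.k_c * c / (p.a_c_II + c) * (N + p.eta_II * M)
           - p.delta_c * protease * c)

    crowding = 1.0 - p.kappa_F * (N + M)
    enh = c / (p.a_c_I + c)
    one_plus_q = 1.0 + p.q_exponent
    # z**(1+q) with q<0 is safe for z>=0 (1+q>0); guard exact zeros anyway.
    N_pow = np.where(N > 0, np.power(np.maximum(N, 1e-300), one_plus_q), 0.0)
    M_pow = np.where(M > 0, np.power(np.maximum(M, 1e-300), one_plus_q), 0.0)

    R_N = (p.r_F * (1.0 + p.r_F_max * enh) * crowding * N_pow
           - p.k_F * c * N - p.delta_N * N)
    R_M = (p.r_F * (1.0 + p.r_F_max) * enh * crowding * M_pow
           + p.k_F * c * N - p.delta_M * M)
    R_rho = (p.k_rho * (1.0 + p.k_rho_max * c / (p.a_c_IV + c)) * (N + p.eta_I * M)
             - p.delta_rho * protease * rho)

    return {"c": R_c, "N": R_N, "M": R_M, "rho": R_rho}


def flux_terms(state: StateField, params: ParameterSet,
               validate: bool = True) -> Dict[str, np.ndarray]:
    """Non-convective fluxes J_z evaluated at element midpoints (length n-1).

    J_c is Fickian; fibroblasts and myofibroblasts undergo a
    cell-density-dependent random walk plus chemotaxis up the signaling
    gradient; collagen does not migrate (J_rho = 0).
    """
    if validate:
        state.validate()
    p = params
    h = np.diff(state.x)
    dc = np.diff(state.c) / h
    dN = np.diff(state.N) / h
    dM = np.diff(state.M) / h

    def mid(a):
        return 0.5 * (a[1:] + a[:-1])

    total = mid(state.N) + mid(state.M)
    J_c = -p.D_c * dc
    J_N = -p.D_F * total * dN + p.chi_F * mid(state.N) * dc
    J_M = -p.D_F * total * dM + p.chi_F * mid(state.M) * dc
    J_rho = np.zeros_like(J_c)
    return {"c": J_c, "N": J_N, "M": J_M, "rho": J_rho}


def elastic_modulus(rho: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Collagen-dependent stiffness E*sqrt(rho) of the elastic stress branch."""
    return params.E_stiff * np.sqrt(rho)


def traction_potential(M: np.ndarray, rho: np.ndarray,
                       params: ParameterSet) -> np.ndarray:
    """Myofibroblast traction potential psi = xi * M * rho / (R^2 + rho^2).

    The body force is its spatial derivative, f = psi'.
    """
    return params.xi * M * rho / (params.R_traction ** 2 + rho ** 2)


def stress_and_body_force(state: StateField, params: ParameterSet,
                          validate: bool = True) -> Tuple[np.ndarray, np.ndarray]:
    """Viscoelastic stress sigma and traction body force f at element midpoints.

    sigma = mu * v' + E sqrt(rho) * eps;  f = d/dx [ xi M rho / (R^2 + rho^2) ].
    Both vanish at the homeostatic equilibrium.
    """
    if validate:
        state.validate()
    h = np.diff(state.x)
    dv = np.diff(state.v) / h

    def mid(a):
        return 0.5 * (a[1:] + a[:-1])

    sigma = params.mu * dv + elastic_modulus(mid(state.rho), params) * mid(state.eps)
    psi = traction_potential(state.M, state.rho, params)
    f = np.diff(psi) / h
    return sigma, f


def growth_rate_coefficient(c: np.ndarray, M: np.ndarray,
                            params: ParameterSet) -> np.ndarray:
    """Coefficient g(c, M) = zeta * c * M such that G = g * eps."""
    return params.zeta * c * M


def growth_term(state: StateField, params: ParameterSet,
                validate: bool = True) -> np.ndarray:
    """Morphoelastic growth/plasticity term G = zeta * c * M * eps (nodewise).

    G vanishes wherever myofibroblasts, signaling or elastic strain are
    absent; where all are present it relaxes the elastic strain toward zero,
    making the accumulated deformation permanent.
    """
    if validate:
        state.validate()
    return growth_rate_coefficient(state.c, state.M, params) * state.eps


def check_stability(params: ParameterSet) -> bool:
    """True iff k_c < delta_c * rho_bar * a_c_II (strict).

    This is the admissibility condition under which the homeostatic
    equilibrium of the reaction system is linearly stable; corpus sampling
    rejects parameter draws that violate it.
    """
    for name in ("k_c", "delta_c", "rho_bar", "a_c_II"):
        if getattr(params, name) <= 0:
            raise ParameterValidationError(
                f"stability check requires {name} > 0")
    return params.k_c < params.delta_c * params.rho_bar * params.a_c_II
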