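"""Field-evolution schemes: PNP, KNP, VC and DO.

All schemes advance ion concentration fields c_k (and, where applicable,
the electric potential) with an implicit Euler step on a structured grid.

PNP couples the Nernst-Planck species equations to Poisson's equation and
resolves nanosecond charge relaxation. KNP replaces Poisson by the bulk
electroneutrality constraint d(rho)/dt = -i_cap and solves an elliptic
equation for the quasi-steady potential, split into a volume-conductor
part phi_VC (driven by membrane currents) and a diffusive part phi_diff
(driven by grad b). VC keeps concentrations frozen and computes phi_VC
only. DO evolves each species by pure diffusion with phi = 0.

The nonlinear implicit systems are solved monolithically with Newton's
method and an analytically assembled Jacobian (sigma and b are linear in
c; the migration term is bilinear in c and phi). The Jacobian
factorisation is reused across iterations and steps and refreshed
whenever the contraction stalls, which leaves the converged states
unchanged while avoiding a sparse refactorisation per iteration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .electrolyte import IonSet
from .grid import (
    ScalarField,
    StructuredGrid,
    apply_div_a_grad,
    assemble_div_a_grad,
    assemble_div_grad_wrt_coeff,
    _set_identity_rows,
)
from .sources import SourceSet, deposit

logger = logging.getLogger(__name__)

__all__ = [
    "BoundarySpec",
    "NewtonOptions",
    "SchemeConfig",
    "SimulationState",
    "StepReport",
    "NewtonError",
    "newton_solve",
    "apply_zero_mean",
    "electroneutrality_drift",
    "initial_state",
    "make_scheme",
    "DOScheme",
    "VCScheme",
    "KNPScheme",
    "PNPScheme",
    "step_do",
    "step_knp",
    "step_pnp",
    "solve_vc_potential",
    "solve_diff_potential",
]


# ---------------------------------------------------------------------------
# Configuration types

@dataclass(frozen=True)
class BoundarySpec:
    """Boundary treatment for species and potentials.

    kind='sealed': zero normal species flux (no ions leave the box).
    kind='clamp': concentrations held at clamp_concentrations on the
        boundary (a reservoir); the potentials then satisfy zero net
        normal charge flux for phi_diff and zero normal gradient for
        phi_VC.
    potential_bc: 'neumann' (the scheme's native condition, plus a
        zero-mean constraint) or 'grounded' (phi = 0 on the boundary;
        useful for free-space comparisons against point-source formulas).
    """

    kind: str = "sealed"
    clamp_concentrations: tuple[float, ...] | None = None
    potential_bc: str = "neumann"

    def __post_init__(self) -> None:
        if self.kind not in ("sealed", "clamp"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")
        if self.potential_bc not in ("neumann", "grounded"):
            raise ValueError(f"unknown potential boundary {self.potential_bc!r}")

    def clamp_values(self, ions: IonSet) -> np.ndarray:
        if self.clamp_concentrations is not None:
            return np.asarray(self.clamp_concentrations, dtype=float)
        return ions.c_baseline.copy()


@dataclass(frozen=True)
class NewtonOptions:
    """Stopping rules for the Newton iteration on the scaled residual.

    abs_tol: RMS of the dimensionless residual; rel_tol: accepted
    reduction relative to the initial residual; step_tol: accepted when
    the scaled update falls below this (roundoff floor); max_iter: hard
    limit, exceeded -> NewtonError and the step is rejected.
    """

    abs_tol: float = 1e-10
    rel_tol: float = 1e-8
    step_tol: float = 1e-12
    max_iter: int = 20

    def __post_init__(self) -> None:
        if min(self.abs_tol, self.rel_tol, self.step_tol) <= 0 or self.max_iter < 1:
            raise ValueError("Newton tolerances must be positive and max_iter >= 1")


@dataclass(frozen=True)
class SchemeConfig:
    """Scheme selection and numerical parameters."""

    scheme: str = "KNP"
    dt: float = 1e-3
    t_end: float = 1.0
    newton: NewtonOptions = field(default_factory=NewtonOptions)
    linear_tol: float = 1e-8
    zero_mean: bool = True
    # optional modes
    frozen_coefficients: bool = False      # lag sigma and b by one iteration
    vc_constant_sigma: bool = False        # classical VC: sigma from baseline
    knp_disable_diffusive: bool = False    # force grad b = 0 (VC recovery)
    knp_freeze_concentrations: bool = False
    knp_disable_migration: bool = False    # drop migration term (DO recovery)

    def __post_init__(self) -> None:
        if self.scheme not in ("PNP", "KNP", "VC", "DO"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.linear_tol <= 0:
            raise ValueError("linear_tol must be positive")


@dataclass
class SimulationState:
    """Per-node fields at one instant: c_k, phi, phi_VC, phi_diff, time."""

    grid: StructuredGrid
    ions: IonSet
    c: np.ndarray          # (n_species, N), mol/m^3
    phi: np.ndarray        # (N,), V (total potential)
    phi_vc: np.ndarray     # (N,), V
    phi_diff: np.ndarray   # (N,), V
    t: float = 0.0

    def __post_init__(self) -> None:
        self.c = np.atleast_2d(np.asarray(self.c, dtype=float))
        if self.c.shape != (len(self.ions), self.grid.n_nodes):
            raise ValueError(
                f"c has shape {self.c.shape}, expected "
                f"({len(self.ions)}, {self.grid.n_nodes})")
        for name in ("phi", "phi_vc", "phi_diff"):
            v = np.asarray(getattr(self, name), dtype=float).ravel()
            if v.shape != (self.grid.n_nodes,):
                raise ValueError(f"{name} has wrong shape")
            setattr(self, name, v)
        if np.any(self.c < 0):
            warnings.warn("state contains negative concentrations", stacklevel=2)

    def copy(self) -> "SimulationState":
        return SimulationState(self.grid, self.ions, self.c.copy(), self.phi.copy(),
                               self.phi_vc.copy(), self.phi_diff.copy(), self.t)


@dataclass
class StepReport:
    """Per-step diagnostics streamed to the run log."""

    t: float
    newton_iters: int
    residual: float
    charge_drift: float = float("nan")
    mass_change: dict[str, float] = field(default_factory=dict)
    clipped: float = 0.0


def initial_state(grid: StructuredGrid, ions: IonSet,
                  c: np.ndarray | None = None, t: float = 0.0) -> SimulationState:
    """State with uniform baseline concentrations and zero potentials."""
    N = grid.n_nodes
    if c is None:
        c = np.repeat(ions.c_baseline[:, None], N, axis=1)
    return SimulationState(grid, ions, np.array(c, dtype=float),
                           np.zeros(N), np.zeros(N), np.zeros(N), t)


# ---------------------------------------------------------------------------
# Generic Newton solver

class NewtonError(RuntimeError):
    """Newton failed to converge (or hit a singular Jacobian)."""


class _DirectSolver:
    """Sparse LU of the full Jacobian (small and 1-D systems)."""

    def __init__(self, J: sp.spmatrix) -> None:
        try:
            self._lu = spla.splu(sp.csc_matrix(J))
        except RuntimeError as exc:
            raise NewtonError(f"singular Jacobian: {exc}") from exc

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return self._lu.solve(rhs)


class _BlockKrylovSolver:
    """GMRES on the full Jacobian with a block Gauss-Seidel preconditioner.

    Memory-bounded alternative to a monolithic LU for large 3-D systems:
    each field's diagonal block is factorised separately (7-point
    stencils, modest fill) and applied in a lower-triangular sweep that
    captures the species -> potential coupling. The outer GMRES makes the
    linear solve exact to `rtol`, so Newton semantics are unchanged.
    """

    def __init__(self, J: sp.spmatrix, n_blocks: int, block_size: int,
                 rtol: float = 1e-8, maxiter: int = 300) -> None:
        self.J = sp.csr_matrix(J)
        self.nb, self.N = n_blocks, block_size
        self.rtol, self.maxiter = rtol, maxiter
        N = block_size
        try:
            self._lus = [
                spla.splu(self.J[b * N : (b + 1) * N, b * N : (b + 1) * N].tocsc())
                for b in range(n_blocks)
            ]
        except RuntimeError as exc:
            raise NewtonError(f"singular Jacobian block: {exc}") from exc
        self._low = {}
        for i in range(n_blocks):
            for j in range(i):
                blk = self.J[i * N : (i + 1) * N, j * N : (j + 1) * N].tocsr()
                if blk.nnz:
                    self._low[i, j] = blk

    def _precondition(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.empty(x.shape[0])
        N = self.N
        for i in range(self.nb):
            rhs = x[i * N : (i + 1) * N].copy()
            for j in range(i):
                blk = self._low.get((i, j))
                if blk is not None:
                    rhs -= blk @ out[j * N : (j + 1) * N]
            out[i * N : (i + 1) * N] = self._lus[i].solve(rhs)
        return out

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        M = spla.LinearOperator(self.J.shape, matvec=self._precondition, dtype=float)
        x, info = spla.gmres(self.J, rhs, M=M, rtol=self.rtol, atol=0.0,
                             maxiter=self.maxiter)
        if info != 0:
            raise NewtonError(f"inner GMRES did not converge (info={info})")
        return x


# systems above this size switch from monolithic LU to block-Krylov
_DIRECT_SOLVER_MAX_UNKNOWNS = 60_000


class _JacobianCache:
    """Holds a factorised Jacobian for reuse across iterations and steps."""

    def __init__(self, factory: Callable[[sp.spmatrix], object] | None = None) -> None:
        self.lu = None
        self.factory = factory or _DirectSolver

    def refresh(self, J: sp.spmatrix) -> None:
        self.lu = self.factory(J)


def _rms(r: np.ndarray) -> float:
    return float(np.sqrt(np.mean(r * r)))


def newton_solve(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    jacobian_fn: Callable[[np.ndarray], sp.spmatrix],
    u0: np.ndarray,
    options: NewtonOptions | None = None,
    cache: _JacobianCache | None = None,
    u_scale: float = 1.0,
) -> tuple[np.ndarray, int, float]:
    """Newton iteration with reusable factorisation.

    Returns (solution, iteration count, final residual RMS). The cached
    factorisation is used as long as it contracts the residual; a stalled
    contraction triggers one refresh at the current iterate before the
    step counts as failed.
    """
    opts = options or NewtonOptions()
    own_cache = cache if cache is not None else _JacobianCache()
    u = np.array(u0, dtype=float)
    r = residual_fn(u)
    rnorm = _rms(r)
    rnorm0 = max(rnorm, np.finfo(float).tiny)
    iters = 0
    while rnorm > opts.abs_tol and rnorm / rnorm0 > opts.rel_tol:
        if iters >= opts.max_iter:
            raise NewtonError(
                f"no convergence after {opts.max_iter} iterations "
                f"(residual RMS {rnorm:.3e})")
        fresh = own_cache.lu is None
        if fresh:
            own_cache.refresh(jacobian_fn(u))
        du = own_cache.lu.solve(-r)
        if not np.all(np.isfinite(du)):
            raise NewtonError("linear solve produced non-finite update")
        u_new = u + du
        r_new = residual_fn(u_new)
        rnorm_new = _rms(r_new)
        if rnorm_new > 0.1 * rnorm and not fresh:
            # stale factorisation no longer contracting: rebuild, redo
            own_cache.lu = None
            continue
        iters += 1
        step = _rms(du) / max(u_scale, np.finfo(float).tiny)
        u, r, rnorm = u_new, r_new, rnorm_new
        if step < opts.step_tol:
            break
    return u, iters, rnorm


# ---------------------------------------------------------------------------
# Shared helpers

def apply_zero_mean(phi, grid: StructuredGrid | None = None):
    """Subtract the volume-weighted mean so that the field integrates to 0."""
    if isinstance(phi, ScalarField):
        shifted = apply_zero_mean(phi.values, phi.grid)
        return ScalarField(phi.grid, shifted, phi.units)
    if grid is None:
        raise ValueError("apply_zero_mean of a bare array needs the grid")
    v = np.asarray(phi, dtype=float).ravel()
    w = grid.node_volumes()
    return v - np.dot(w, v) / w.sum()


def electroneutrality_drift(state_old: SimulationState, state_new: SimulationState,
                            i_cap: np.ndarray | None, dt: float) -> float:
    """Max nodal |d(rho)/dt + i_cap| between two consecutive states, C/(m^3 s).

    This is the defining constraint of the electroneutral scheme; for KNP
    it is enforced to Newton tolerance (with i_cap = 0 it reduces to
    d(rho)/dt = 0), while DO violates it freely.
    """
    F = state_old.ions.constants.F
    drho = F * np.tensordot(state_old.ions.z, state_new.c - state_old.c, axes=(0, 0)) / dt
    if i_cap is not None:
        drho = drho + i_cap
    return float(np.max(np.abs(drho)))


def _resolve_sources(sources, grid: StructuredGrid, ions: IonSet, t: float,
                     dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Accept None, a SourceSet, or a precomputed (f_hat, i_cap) pair."""
    K, N = len(ions), grid.n_nodes
    if sources is None:
        return np.zeros((K, N)), np.zeros(N)
    if isinstance(sources, SourceSet):
        return deposit(sources, grid, t, dt, ions)
    f_hat, i_cap = sources
    f_hat = np.zeros((K, N)) if f_hat is None else np.asarray(f_hat, dtype=float)
    i_cap = np.zeros(N) if i_cap is None else np.asarray(i_cap, dtype=float).ravel()
    return f_hat, i_cap


def _solve_pinned(A: sp.spmatrix, rhs: np.ndarray, grid: StructuredGrid,
                  boundary: BoundarySpec, zero_mean: bool,
                  check_balance: bool = False) -> np.ndarray:
    """Solve A phi = rhs with the potential boundary handling.

    Neumann: the singular system is made definite by pinning node 0 and
    the solution shifted to zero volume mean afterwards (identical up to
    the shift). Grounded: Dirichlet-0 rows on the boundary. The zero
    constraints are applied symmetrically (row and column), so the system
    stays symmetric negative definite; large systems are solved with
    conjugate gradients, small ones with a sparse LU.
    """
    rhs = rhs.copy()
    if boundary.potential_bc == "grounded":
        mask = grid.boundary_mask()
    else:
        if check_balance:
            w = grid.node_volumes()
            total = float(np.dot(w, rhs))
            scale = float(np.dot(w, np.abs(rhs)))
            if scale > 0 and abs(total) > 1e-8 * scale:
                raise ValueError(
                    "current sources do not balance "
                    f"(net {total:g} A) with all-Neumann potential boundaries")
        mask = np.zeros(grid.n_nodes, dtype=bool)
        mask[0] = True
    if grid.n_nodes <= 80_000:
        keep = sp.diags((~mask).astype(float))
        fix = sp.diags(mask.astype(float))
        Aeff = keep @ sp.csr_matrix(A) @ keep + fix
        rhs = rhs.copy()
        rhs[mask] = 0.0
        phi = spla.spsolve(sp.csc_matrix(Aeff), rhs)
    else:
        # volume-scaled symmetric form: S = diag(V) A is SPD after
        # constraint elimination (grounded) or on the range (neumann)
        V = grid.node_volumes()
        S = (sp.diags(V) @ sp.csr_matrix(A)).tocsr()
        rhs_s = -(V * rhs)
        if boundary.potential_bc == "grounded":
            keep = sp.diags((~mask).astype(float))
            fix = sp.diags(mask.astype(float))
            Spos = (fix - keep @ S @ keep).tocsr()
            rhs_s[mask] = 0.0
            M = sp.diags(1.0 / Spos.diagonal())
            phi, info = spla.cg(Spos, rhs_s, M=M, rtol=1e-10, atol=0.0,
                                maxiter=20_000)
        else:
            # singular consistent system: deflate the constant nullspace
            n = grid.n_nodes
            proj = lambda x: x - x.mean()
            matvec = lambda x: proj(-(S @ proj(x)))
            Op = spla.LinearOperator((n, n), matvec=matvec, dtype=float)
            d = -S.diagonal()
            M = spla.LinearOperator((n, n), matvec=lambda x: proj(x / d), dtype=float)
            phi, info = spla.cg(Op, proj(rhs_s), M=M, rtol=1e-10, atol=0.0,
                                maxiter=20_000)
        if info != 0:
            raise NewtonError(f"CG on the elliptic solve did not converge (info={info})")
    if boundary.potential_bc == "neumann" and zero_mean:
        phi = apply_zero_mean(phi, grid)
    return phi


# ---------------------------------------------------------------------------
# Scheme base

class _SchemeBase:
    name = "?"

    def __init__(self, grid: StructuredGrid, ions: IonSet,
                 boundary: BoundarySpec | None = None,
                 cfg: SchemeConfig | None = None) -> None:
        self.grid = grid
        self.ions = ions
        self.boundary = boundary or BoundarySpec()
        self.cfg = cfg or SchemeConfig(scheme=self.name)
        self.constants = ions.constants
        self.psi = ions.constants.psi
        self.F = ions.constants.F
        self.clamp_mask = (grid.boundary_mask() if self.boundary.kind == "clamp"
                           else np.zeros(grid.n_nodes, dtype=bool))
        self.c_clamp = self.boundary.clamp_values(ions)
        # characteristic scales for the dimensionless residual
        self.c_scale = float(np.max(ions.c_baseline)) or 1.0
        self.sigma_ref = float(
            self.F * np.dot(ions.D_eff * ions.z**2, ions.c_baseline) / self.psi) or 1.0
        self.h_min = float(min(grid.spacing))

    # overridden by subclasses
    def step(self, state: SimulationState, sources=None,
             dt: float | None = None) -> tuple[SimulationState, StepReport]:
        raise NotImplementedError

    def _solver_factory(self, n_blocks: int, block_size: int):
        """Direct LU for small systems, block-Krylov beyond the threshold."""
        if n_blocks * block_size > _DIRECT_SOLVER_MAX_UNKNOWNS:
            rtol = self.cfg.linear_tol
            return lambda J: _BlockKrylovSolver(J, n_blocks, block_size, rtol=rtol)
        return _DirectSolver

    def _mass_change(self, c_old: np.ndarray, c_new: np.ndarray) -> dict[str, float]:
        w = self.grid.node_volumes()
        return {name: float(np.dot(w, c_new[k] - c_old[k]))
                for k, name in enumerate(self.ions.names)}

    def _clip_negative(self, c: np.ndarray) -> float:
        worst = float(-np.min(c)) if np.any(c < 0) else 0.0
        if worst > 0:
            if worst > 1e-6 * self.c_scale:
                raise NewtonError(
                    f"negative concentration {worst:g} mol/m^3 exceeds "
                    "1e-6 of the baseline scale; step rejected")
            logger.warning("clipped negative concentrations (worst %g mol/m^3)", worst)
            np.clip(c, 0.0, None, out=c)
        return worst


# ---------------------------------------------------------------------------
# Diffusion-only scheme

class DOScheme(_SchemeBase):
    """Independent implicit-Euler diffusion per species; phi = 0."""

    name = "DO"

    def __init__(self, grid, ions, boundary=None, cfg=None) -> None:
        super().__init__(grid, ions, boundary, cfg)
        self._lus: dict[tuple[int, float], spla.SuperLU] = {}

    def _lu(self, k: int, dt: float) -> spla.SuperLU:
        key = (k, dt)
        if key not in self._lus:
            L = assemble_div_a_grad(self.grid, np.full(self.grid.n_nodes, self.ions.D_eff[k]))
            A = sp.eye(self.grid.n_nodes) / dt - L
            A = _set_identity_rows(sp.csr_matrix(A), self.clamp_mask)
            self._lus[key] = spla.splu(sp.csc_matrix(A))
        return self._lus[key]

    def step(self, state, sources=None, dt=None):
        dt = self.cfg.dt if dt is None else dt
        f_hat, _ = _resolve_sources(sources, self.grid, self.ions, state.t, dt)
        c_new = np.empty_like(state.c)
        for k in range(len(self.ions)):
            rhs = state.c[k] / dt + f_hat[k]
            rhs[self.clamp_mask] = self.c_clamp[k]
            c_new[k] = self._lu(k, dt).solve(rhs)
        clipped = self._clip_negative(c_new)
        N = self.grid.n_nodes
        new = SimulationState(self.grid, self.ions, c_new, np.zeros(N),
                              np.zeros(N), np.zeros(N), state.t + dt)
        report = StepReport(new.t, 0, 0.0,
                            electroneutrality_drift(state, new, None, dt),
                            self._mass_change(state.c, c_new), clipped)
        return new, report


# ---------------------------------------------------------------------------
# Volume-conductor scheme

class VCScheme(_SchemeBase):
    """Ohmic potential from membrane current sources; concentrations frozen."""

    name = "VC"

    def _sigma(self, state: SimulationState) -> np.ndarray:
        if self.cfg.vc_constant_sigma:
            return np.full(self.grid.n_nodes, self.sigma_ref)
        w = self.F * self.ions.D_eff * self.ions.z**2 / self.psi
        return np.tensordot(w, state.c, axes=(0, 0))

    def solve_potential(self, state: SimulationState, f_hat: np.ndarray,
                        i_cap: np.ndarray) -> np.ndarray:
        src = self.F * np.tensordot(self.ions.z, f_hat, axes=(0, 0)) + i_cap
        A = assemble_div_a_grad(self.grid, self._sigma(state))
        return _solve_pinned(A, -src, self.grid, self.boundary,
                             self.cfg.zero_mean, check_balance=True)

    def step(self, state, sources=None, dt=None):
        dt = self.cfg.dt if dt is None else dt
        f_hat, i_cap = _resolve_sources(sources, self.grid, self.ions, state.t, dt)
        phi_vc = self.solve_potential(state, f_hat, i_cap)
        new = SimulationState(self.grid, self.ions, state.c.copy(), phi_vc.copy(),
                              phi_vc, np.zeros(self.grid.n_nodes), state.t + dt)
        return new, StepReport(new.t, 0, 0.0, 0.0, self._mass_change(state.c, new.c))


# ---------------------------------------------------------------------------
# Electroneutral (KNP) scheme

class KNPScheme(_SchemeBase):
    """Monolithic implicit Euler in {c_k, phi_VC, phi_diff} solved by Newton.

    The species equations carry phi = phi_VC + phi_diff; the elliptic
    potential equations enforce the electroneutrality constraint, with
    capacitive currents sourcing only the potential equation, never the
    species equations.
    """

    name = "KNP"

    def __init__(self, grid, ions, boundary=None, cfg=None) -> None:
        super().__init__(grid, ions, boundary, cfg)
        K, N = len(ions), grid.n_nodes
        self.K, self.N = K, N
        self._cache = _JacobianCache(self._solver_factory(K + 2, N))
        self._L1 = assemble_div_a_grad(grid, np.ones(N))
        self._Lk = [assemble_div_a_grad(grid, np.full(N, D)) for D in ions.D_eff]
        self._w_sigma = self.F * ions.D_eff * ions.z**2 / self.psi   # sigma = w . c
        self._w_b = self.F * ions.D_eff * ions.z                     # b = w . c
        self._mig = ions.D_eff * ions.z / self.psi                   # u_k = mig_k * c_k
        # row scalings making the residual dimensionless
        self._s_c = 1.0 / self.c_scale  # multiplied by dt inside step
        self._s_phi = self.h_min**2 / (self.sigma_ref * self.psi)
        if self.boundary.potential_bc == "grounded":
            self._pot_fix = grid.boundary_mask()
        else:
            self._pot_fix = np.zeros(N, dtype=bool)
            self._pot_fix[0] = True
        self._u_scale = max(self.c_scale, 1.0)

    # -- packing ------------------------------------------------------------

    def _pack(self, c: np.ndarray, pvc: np.ndarray, pdf: np.ndarray) -> np.ndarray:
        return np.concatenate([c.ravel(), pvc, pdf])

    def _unpack(self, u: np.ndarray):
        K, N = self.K, self.N
        return (u[: K * N].reshape(K, N).copy(),
                u[K * N : (K + 1) * N].copy(), u[(K + 1) * N :].copy())

    # -- residual and Jacobian ---------------------------------------------

    def _residual(self, u, c_old, f_hat, src_charge, dt):
        K, N, grid = self.K, self.N, self.grid
        c = u[: K * N].reshape(K, N)
        pvc = u[K * N : (K + 1) * N]
        pdf = u[(K + 1) * N :]
        phi = pvc + pdf
        R = np.empty((K + 2) * N)
        sc = dt * self._s_c
        for k in range(K):
            if self.cfg.knp_freeze_concentrations:
                r = c[k] - c_old[k]
            else:
                r = (c[k] - c_old[k]) / dt - self._Lk[k] @ c[k] - f_hat[k]
                if not self.cfg.knp_disable_migration:
                    r -= apply_div_a_grad(grid, self._mig[k] * c[k], phi)
                r *= sc
                r[self.clamp_mask] = c[k][self.clamp_mask] - self.c_clamp[k]
            R[k * N : (k + 1) * N] = r
        sigma = np.tensordot(self._w_sigma, c, axes=(0, 0))
        r_vc = (apply_div_a_grad(grid, sigma, pvc) + src_charge) * self._s_phi
        r_vc[self._pot_fix] = pvc[self._pot_fix]
        r_df = apply_div_a_grad(grid, sigma, pdf)
        if not self.cfg.knp_disable_diffusive:
            r_df += self._L1 @ (np.tensordot(self._w_b, c, axes=(0, 0)))
        r_df *= self._s_phi
        r_df[self._pot_fix] = pdf[self._pot_fix]
        R[K * N : (K + 1) * N] = r_vc
        R[(K + 1) * N :] = r_df
        return R

    def _jacobian(self, u, dt) -> sp.csr_matrix:
        K, N, grid = self.K, self.N, self.grid
        c = u[: K * N].reshape(K, N)
        pvc = u[K * N : (K + 1) * N]
        pdf = u[(K + 1) * N :]
        phi = pvc + pdf
        sigma = np.tensordot(self._w_sigma, c, axes=(0, 0))
        sc = dt * self._s_c
        frozen_c = self.cfg.knp_freeze_concentrations
        lagged = self.cfg.frozen_coefficients
        M_phi = None if self.cfg.knp_disable_migration else assemble_div_grad_wrt_coeff(grid, phi)
        A_sigma = assemble_div_a_grad(grid, np.maximum(sigma, 1e-300))
        M_vc = assemble_div_grad_wrt_coeff(grid, pvc)
        M_df = assemble_div_grad_wrt_coeff(grid, pdf)
        blocks = [[None] * (K + 2) for _ in range(K + 2)]
        I = sp.eye(N, format="csr")
        for k in range(K):
            if frozen_c:
                blocks[k][k] = I
                continue
            Jkk = I / dt - self._Lk[k]
            if M_phi is not None and not lagged:
                Jkk = Jkk - self._mig[k] * M_phi
            blocks[k][k] = sc * Jkk
            if M_phi is not None:
                A_uk = self._signed_div(self._mig[k] * c[k])
                blocks[k][K] = -sc * A_uk
                blocks[k][K + 1] = -sc * A_uk
        for k in range(K):
            if frozen_c or lagged:
                break
            blocks[K][k] = self._s_phi * self._w_sigma[k] * M_vc
            Jdk = self._s_phi * self._w_sigma[k] * M_df
            if not self.cfg.knp_disable_diffusive:
                Jdk = Jdk + self._s_phi * self._w_b[k] * self._L1
            blocks[K + 1][k] = Jdk
        blocks[K][K] = self._s_phi * A_sigma
        blocks[K + 1][K + 1] = self._s_phi * A_sigma
        J = sp.bmat(blocks, format="csr")
        # clamped species rows and pinned/grounded potential rows -> identity
        mask = np.zeros((K + 2) * N, dtype=bool)
        for k in range(K):
            mask[k * N : (k + 1) * N] = self.clamp_mask
        mask[K * N : (K + 1) * N] = self._pot_fix
        mask[(K + 1) * N :] = self._pot_fix
        return _set_identity_rows(J, mask)

    def _signed_div(self, a: np.ndarray) -> sp.csr_matrix:
        """div(a grad .) for a coefficient of either sign."""
        pos = np.maximum(a, 0.0) + 1e-300
        neg = np.maximum(-a, 0.0) + 1e-300
        return assemble_div_a_grad(self.grid, pos) - assemble_div_a_grad(self.grid, neg)

    # -- stepping -----------------------------------------------------------

    def step(self, state, sources=None, dt=None):
        dt = self.cfg.dt if dt is None else dt
        f_hat, i_cap = _resolve_sources(sources, self.grid, self.ions, state.t, dt)
        src_charge = self.F * np.tensordot(self.ions.z, f_hat, axes=(0, 0)) + i_cap
        c_old = state.c
        u0 = self._pack(state.c, state.phi_vc, state.phi_diff)
        residual = lambda u: self._residual(u, c_old, f_hat, src_charge, dt)
        jac = lambda u: self._jacobian(u, dt)
        u, iters, rnorm = newton_solve(residual, jac, u0, self.cfg.newton,
                                       cache=self._cache, u_scale=self._u_scale)
        c_new, pvc, pdf = self._unpack(u)
        if self.cfg.knp_freeze_concentrations:
            c_new = c_old.copy()
        clipped = self._clip_negative(c_new)
        if self.boundary.potential_bc == "neumann" and self.cfg.zero_mean:
            pvc = apply_zero_mean(pvc, self.grid)
            pdf = apply_zero_mean(pdf, self.grid)
        new = SimulationState(self.grid, self.ions, c_new, pvc + pdf, pvc, pdf,
                              state.t + dt)
        drift = electroneutrality_drift(state, new, i_cap, dt)
        report = StepReport(new.t, iters, rnorm, drift,
                            self._mass_change(c_old, c_new), clipped)
        return new, report

    def drift_tolerance(self, dt: float) -> float:
        """SI bound on the nodal electroneutrality drift implied by the
        Newton stopping rule (converts the dimensionless residual RMS
        back to C/(m^3 s) and bounds the max by the l2 norm)."""
        n_tot = (self.K + 2) * self.N
        per_row = (self.F * float(np.sum(np.abs(self.ions.z))) * self.c_scale / dt
                   + 2.0 / self._s_phi)
        return self.cfg.newton.abs_tol * np.sqrt(n_tot) * per_row


# ---------------------------------------------------------------------------
# Poisson-Nernst-Planck scheme

class PNPScheme(_SchemeBase):
    """Monolithic implicit Euler in {c_k, phi} with Poisson's equation.

    Resolves the charge-relaxation (Debye) dynamics and therefore needs
    nanometre grids and sub-nanosecond steps; a warning is issued for
    spacings above 1 nm.
    """

    name = "PNP"

    def __init__(self, grid, ions, boundary=None, cfg=None) -> None:
        super().__init__(grid, ions, boundary, cfg)
        if max(grid.spacing) > 1e-9:
            warnings.warn(
                f"PNP on a grid with h = {max(grid.spacing):g} m; the Debye "
                "layer (~1 nm) is unresolved", stacklevel=2)
        K, N = len(ions), grid.n_nodes
        self.K, self.N = K, N
        self._cache = _JacobianCache(self._solver_factory(K + 1, N))
        self._L1 = assemble_div_a_grad(grid, np.ones(N))
        self._Lk = [assemble_div_a_grad(grid, np.full(N, D)) for D in ions.D_eff]
        self._mig = ions.D_eff * ions.z / self.psi
        self.eps = ions.constants.eps
        self._s_c = 1.0 / self.c_scale
        self._s_phi = self.h_min**2 / self.psi
        if self.boundary.potential_bc == "grounded":
            self._pot_fix = grid.boundary_mask()
        else:
            self._pot_fix = np.zeros(N, dtype=bool)
            self._pot_fix[0] = True
        self._u_scale = max(self.c_scale, 1.0)

    def _residual(self, u, c_old, f_hat, dt):
        K, N, grid = self.K, self.N, self.grid
        c = u[: K * N].reshape(K, N)
        phi = u[K * N :]
        R = np.empty((K + 1) * N)
        sc = dt * self._s_c
        for k in range(K):
            r = (c[k] - c_old[k]) / dt - self._Lk[k] @ c[k] \
                - apply_div_a_grad(grid, self._mig[k] * c[k], phi) - f_hat[k]
            r *= sc
            r[self.clamp_mask] = c[k][self.clamp_mask] - self.c_clamp[k]
            R[k * N : (k + 1) * N] = r
        rho = self.F * np.tensordot(self.ions.z, c, axes=(0, 0))
        r_phi = (self._L1 @ phi + rho / self.eps) * self._s_phi
        r_phi[self._pot_fix] = phi[self._pot_fix]
        R[K * N :] = r_phi
        return R

    def _jacobian(self, u, dt) -> sp.csr_matrix:
        K, N, grid = self.K, self.N, self.grid
        c = u[: K * N].reshape(K, N)
        phi = u[K * N :]
        M_phi = assemble_div_grad_wrt_coeff(grid, phi)
        sc = dt * self._s_c
        blocks = [[None] * (K + 1) for _ in range(K + 1)]
        I = sp.eye(N, format="csr")
        for k in range(K):
            blocks[k][k] = sc * (I / dt - self._Lk[k] - self._mig[k] * M_phi)
            pos = np.maximum(self._mig[k] * c[k], 0.0) + 1e-300
            neg = np.maximum(-self._mig[k] * c[k], 0.0) + 1e-300
            A_uk = assemble_div_a_grad(grid, pos) - assemble_div_a_grad(grid, neg)
            blocks[k][K] = -sc * A_uk
            blocks[K][k] = self._s_phi * (self.F * self.ions.z[k] / self.eps) * I
        blocks[K][K] = self._s_phi * self._L1
        J = sp.bmat(blocks, format="csr")
        mask = np.zeros((K + 1) * N, dtype=bool)
        for k in range(K):
            mask[k * N : (k + 1) * N] = self.clamp_mask
        mask[K * N :] = self._pot_fix
        return _set_identity_rows(J, mask)

    def step(self, state, sources=None, dt=None):
        dt = self.cfg.dt if dt is None else dt
        f_hat, _ = _resolve_sources(sources, self.grid, self.ions, state.t, dt)
        c_old = state.c
        u0 = np.concatenate([state.c.ravel(), state.phi])
        residual = lambda u: self._residual(u, c_old, f_hat, dt)
        jac = lambda u: self._jacobian(u, dt)
        u, iters, rnorm = newton_solve(residual, jac, u0, self.cfg.newton,
                                       cache=self._cache, u_scale=self._u_scale)
        c_new = u[: self.K * self.N].reshape(self.K, self.N).copy()
        phi = u[self.K * self.N :].copy()
        clipped = self._clip_negative(c_new)
        if self.boundary.potential_bc == "neumann" and self.cfg.zero_mean:
            phi = apply_zero_mean(phi, self.grid)
        N = self.grid.n_nodes
        new = SimulationState(self.grid, self.ions, c_new, phi, np.zeros(N),
                              np.zeros(N), state.t + dt)
        report = StepReport(new.t, iters, rnorm, float("nan"),
                            self._mass_change(c_old, c_new), clipped)
        return new, report


# ---------------------------------------------------------------------------
# Factory and functional wrappers

_SCHEMES = {"DO": DOScheme, "VC": VCScheme, "KNP": KNPScheme, "PNP": PNPScheme}


def make_scheme(name: str, grid: StructuredGrid, ions: IonSet,
                boundary: BoundarySpec | None = None,
                cfg: SchemeConfig | None = None) -> _SchemeBase:
    if name not in _SCHEMES:
        raise ValueError(f"unknown scheme {name!r}; choose from {sorted(_SCHEMES)}")
    if cfg is not None and cfg.scheme != name:
        cfg = replace(cfg, scheme=name)
    return _SCHEMES[name](grid, ions, boundary, cfg)


def step_do(state: SimulationState, sources=None, cfg: SchemeConfig | None = None,
            boundary: BoundarySpec | None = None) -> SimulationState:
    """One DO step (functional wrapper; see DOScheme for the stateful API)."""
    scheme = DOScheme(state.grid, state.ions, boundary, cfg)
    return scheme.step(state, sources)[0]


def step_knp(state: SimulationState, sources=None, cfg: SchemeConfig | None = None,
             boundary: BoundarySpec | None = None) -> SimulationState:
    scheme = KNPScheme(state.grid, state.ions, boundary, cfg)
    return scheme.step(state, sources)[0]


def step_pnp(state: SimulationState, sources=None, cfg: SchemeConfig | None = None,
             boundary: BoundarySpec | None = None) -> SimulationState:
    scheme = PNPScheme(state.grid, state.ions, boundary, cfg)
    return scheme.step(state, sources)[0]


def solve_vc_potential(state: SimulationState, sources=None,
                       cfg: SchemeConfig | None = None,
                       boundary: BoundarySpec | None = None,
                       dt: float = 1.0) -> np.ndarray:
    """Volume-conductor potential phi_VC for the current concentrations."""
    scheme = VCScheme(state.grid, state.ions, boundary, cfg)
    f_hat, i_cap = _resolve_sources(sources, state.grid, state.ions, state.t, dt)
    return scheme.solve_potential(state, f_hat, i_cap)


def solve_diff_potential(state: SimulationState, cfg: SchemeConfig | None = None,
                         boundary: BoundarySpec | None = None) -> np.ndarray:
    """Diffusion potential phi_diff: div(sigma grad phi_diff + grad b) = 0."""
    cfg = cfg or SchemeConfig(scheme="KNP")
    boundary = boundary or BoundarySpec()
    ions = state.ions
    w_sigma = ions.constants.F * ions.D_eff * ions.z**2 / ions.constants.psi
    w_b = ions.constants.F * ions.D_eff * ions.z
    sigma = np.tensordot(w_sigma, state.c, axes=(0, 0))
    b = np.tensordot(w_b, state.c, axes=(0, 0))
    L1 = assemble_div_a_grad(state.grid, np.ones(state.grid.n_nodes))
    A = assemble_div_a_grad(state.grid, sigma)
    return _solve_pinned(A, -(L1 @ b), state.grid, boundary, cfg.zero_mean)
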