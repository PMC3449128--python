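"""Method-of-lines simulation of the full and linearized systems.

Uniform vertex-centred grids on intervals or rectangles, homogeneous
Neumann (no-flux) boundaries.  Discretization choices (all second order):

* diffusion and the linearized cross-Laplacian chemotaxis terms use the
  3-point (5-point in 2D) stencil with ghost-point mirroring at the
  boundary;
* nonlinear chemotaxis fluxes use the conservative form — interface
  gradients, interface-averaged carrier density, zero boundary flux, and a
  half-cell divergence at boundary nodes.  On this grid the half-cell
  conservative divergence of a pure gradient flux coincides with the
  mirrored stencil, so the two simulators discretize diffusion
  identically, and the trapezoid-weighted spatial mean is conserved
  exactly by every transport term.

On the mirrored stencil the cosine modes ``cos(n pi x / L)`` are exact
discrete eigenvectors with eigenvalue ``mu_h = (2 - 2 cos(n pi h / L)) /
h^2 -> (n pi / L)^2``, which is what makes single-mode runs clean tests of
the closed-form modal rates.

Time integration is implicit (BDF) by default — the linearized system is
stiff once diffusion dominates; an explicit RK45 option with no implicit
solve is available for small runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from .kinetics import STATE_NAMES, Trajectory, heaviside, reaction_rhs
from .linear import LinearCoefficients, reaction_matrix
from .params import ModelParams

__all__ = [
    "Grid",
    "FieldSolution",
    "GrowthRate",
    "neumann_laplacian_modes",
    "laplacian_matrix",
    "simulate_linearized",
    "simulate_full",
    "growth_rate_estimate",
]


@dataclass(frozen=True)
class Grid:
    """Uniform vertex-centred grid on an interval or rectangle."""

    extents: tuple[float, ...]
    n_points: tuple[int, ...]

    def __post_init__(self):
        if len(self.extents) not in (1, 2) or len(self.extents) != len(self.n_points):
            raise ValueError("Grid: 1 or 2 axes, extents and n_points matching")
        if any(L <= 0 for L in self.extents):
            raise ValueError("Grid extents must be positive")
        if any(n < 8 for n in self.n_points):
            raise ValueError("Grid needs at least 8 points per axis")

    @classmethod
    def interval(cls, length: float, n: int) -> "Grid":
        return cls(extents=(length,), n_points=(n,))

    @classmethod
    def rectangle(cls, lengths: tuple[float, float], n: tuple[int, int]) -> "Grid":
        return cls(extents=tuple(lengths), n_points=tuple(n))

    @property
    def ndim(self) -> int:
        return len(self.extents)

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(L / (n - 1) for L, n in zip(self.extents, self.n_points))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.n_points

    @property
    def size(self) -> int:
        return int(np.prod(self.n_points))

    @property
    def axes(self) -> tuple[np.ndarray, ...]:
        return tuple(np.linspace(0.0, L, n) for L, n in zip(self.extents, self.n_points))

    def quad_weights(self) -> np.ndarray:
        """Trapezoid quadrature weights, shaped like the grid."""
        ws = []
        for h, n in zip(self.spacing, self.n_points):
            w = np.full(n, h)
            w[0] = w[-1] = h / 2.0
            ws.append(w)
        if self.ndim == 1:
            return ws[0]
        return np.outer(ws[0], ws[1])


def _laplacian_1d(n: int, h: float) -> sp.csr_matrix:
    main = np.full(n, -2.0)
    off = np.ones(n - 1)
    L = sp.diags([off, main, off], [-1, 0, 1], format="lil")
    L[0, 1] = 2.0  # ghost-point mirror
    L[-1, -2] = 2.0
    return (L / (h * h)).tocsr()


def laplacian_matrix(g: Grid) -> sp.csr_matrix:
    """Discrete Neumann Laplacian (mirrored stencil) on the flattened grid."""
    if g.ndim == 1:
        return _laplacian_1d(g.n_points[0], g.spacing[0])
    Lx = _laplacian_1d(g.n_points[0], g.spacing[0])
    Ly = _laplacian_1d(g.n_points[1], g.spacing[1])
    Ix = sp.identity(g.n_points[0], format="csr")
    Iy = sp.identity(g.n_points[1], format="csr")
    return (sp.kron(Lx, Iy) + sp.kron(Ix, Ly)).tocsr()


def neumann_laplacian_modes(g: Grid, k: int) -> list[tuple[float, np.ndarray]]:
    """First ``k`` Neumann eigenpairs ``(mu_n, phi_n)`` sampled on the grid.

    Intervals: ``mu_n = (n pi / L)^2``, ``phi_n = cos(n pi x / L)``,
    ``n = 0..k-1`` (the ``n = 0`` ground mode is constant).  Rectangles:
    tensor products, sorted by ``mu``.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > min(g.n_points):
        raise ValueError(f"k = {k} exceeds resolvable modes on {min(g.n_points)} points")
    if g.ndim == 1:
        (L,), (x,) = g.extents, g.axes
        return [((n * np.pi / L) ** 2, np.cos(n * np.pi * x / L)) for n in range(k)]
    (Lx, Ly) = g.extents
    x, y = g.axes
    cand = []
    for nx in range(k):
        for ny in range(k):
            mu = (nx * np.pi / Lx) ** 2 + (ny * np.pi / Ly) ** 2
            cand.append((mu, nx, ny))
    cand.sort()
    out = []
    for mu, nx, ny in cand[:k]:
        phi = np.outer(np.cos(nx * np.pi * x / Lx), np.cos(ny * np.pi * y / Ly))
        out.append((mu, phi))
    return out


@dataclass(frozen=True)
class FieldSolution:
    """Space-time solution with L2-norm and spatial-mean time series.

    ``l2_norms[i] = sqrt(int sum_k (u_k - ref_k)^2 dx)`` with the reference
    given at simulation time (zero for perturbation runs); ``means`` are the
    trapezoid-weighted spatial means of the raw fields.  ``blowup`` marks a
    run terminated by the norm cap before ``t_end``.
    """

    grid: Grid
    times: np.ndarray  # (nt,)
    fields: np.ndarray  # (nt, 5, *grid.shape)
    l2_norms: np.ndarray  # (nt,)
    means: np.ndarray  # (nt, 5)
    blowup: bool = False

    def norms_dataframe(self) -> pd.DataFrame:
        cols = {"t": self.times, "l2": self.l2_norms}
        for i, n in enumerate(STATE_NAMES):
            cols[f"mean_{n.lower()}"] = self.means[:, i]
        return pd.DataFrame(cols)

    def slice_dataframe(self, time_index: int) -> pd.DataFrame:
        if self.grid.ndim != 1:
            raise ValueError("slice export is 1D only")
        cols = {"x": self.grid.axes[0]}
        for i, n in enumerate(STATE_NAMES):
            cols[n.lower()] = self.fields[time_index, i]
        return pd.DataFrame(cols)


def _wrap_solution(g: Grid, sol, reference: np.ndarray | None, blowup: bool) -> FieldSolution:
    nt = sol.t.size
    fields = sol.y.T.reshape(nt, 5, *g.shape)
    w = g.quad_weights()
    ref = np.zeros((5, *g.shape)) if reference is None else reference
    dev = fields - ref[None]
    spatial_axes = tuple(range(2, fields.ndim))
    l2 = np.sqrt((dev**2 * w).sum(axis=(1, *spatial_axes)))
    means = (fields * w).sum(axis=spatial_axes) / w.sum()
    return FieldSolution(grid=g, times=sol.t, fields=fields, l2_norms=l2, means=means, blowup=blowup)


def _integrate(rhs, y0, t_end, n_out, method, rtol, atol, jac, jac_sparsity, cap):
    events = None
    if cap is not None and np.linalg.norm(y0) > 0:
        limit = cap * np.linalg.norm(y0)

        def blowup_event(t, y):
            return np.linalg.norm(y) - limit

        blowup_event.terminal = True
        blowup_event.direction = 1.0
        events = blowup_event
    kwargs = {}
    if method in ("BDF", "Radau", "LSODA"):
        if jac is not None:
            kwargs["jac"] = jac
        elif jac_sparsity is not None and method != "LSODA":
            kwargs["jac_sparsity"] = jac_sparsity
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, t_eval=np.linspace(0.0, t_end, n_out),
        method=method, rtol=rtol, atol=atol, events=events, **kwargs,
    )
    blowup = bool(sol.status == 1)
    if sol.status == -1:
        raise RuntimeError(f"PDE integration failed: {sol.message}")
    if sol.t.size < 2:
        raise RuntimeError("PDE integration terminated immediately (blow-up cap hit at t=0?)")
    return sol, blowup


def linearized_operator(c: LinearCoefficients, p, g: Grid) -> sp.csr_matrix:
    """System matrix of the linearized dynamics on the grid.

    ``du/dt = (Dmat kron Lap) u - (B kron I) u`` where ``Dmat`` carries the
    diffusivities on the diagonal and the chemotaxis couplings
    ``-chif, -chim, -chie1, -chie2`` off it (they multiply ``lap c`` /
    ``lap f`` in the f, m, e equations).
    """
    Lap = laplacian_matrix(g)
    n = g.size
    Dmat = np.diag([p.Dd, p.Dc, p.Df, p.Dm, p.De]).astype(float)
    Dmat[2, 1] = -c.chif
    Dmat[3, 1] = -c.chim
    Dmat[4, 1] = -c.chie2
    Dmat[4, 2] = -c.chie1
    B = reaction_matrix(c)
    return (sp.kron(Dmat, Lap) - sp.kron(B, sp.identity(n))).tocsr()


def simulate_linearized(
    c: LinearCoefficients,
    p,
    init: np.ndarray,
    g: Grid,
    t_end: float,
    *,
    n_out: int = 101,
    method: str = "BDF",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    blowup_cap: float | None = 1e8,
) -> FieldSolution:
    """Integrate the constant-coefficient linearized system.

    ``init`` is the 5-field perturbation, shape ``(5, *grid.shape)``.
    ``p`` supplies diffusivities.  A perturbation proportional to a single
    Neumann mode stays on that mode and evolves under the corresponding
    modal matrix — with ``mu`` equal to the *discrete* eigenvalue
    ``mu_h = (2 - 2 cos(n pi h / L)) / h^2``.
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (5, *g.shape):
        raise ValueError(f"init must have shape (5, {g.shape}), got {init.shape}")
    A = linearized_operator(c, p, g)
    sol, blowup = _integrate(
        lambda t, y: A @ y, init.ravel(), t_end, n_out, method, rtol, atol,
        jac=A if method in ("BDF", "Radau") else None, jac_sparsity=None, cap=blowup_cap,
    )
    return _wrap_solution(g, sol, reference=None, blowup=blowup)


def _flux_divergence(carrier: np.ndarray, potential: np.ndarray, g: Grid, upwind: bool) -> np.ndarray:
    """Half-cell conservative ``div(carrier * grad potential)``, no-flux walls."""
    out = np.zeros_like(potential)
    for axis, h in enumerate(g.spacing):
        pot = np.moveaxis(potential, axis, 0)
        car = np.moveaxis(carrier, axis, 0)
        res = np.moveaxis(out, axis, 0)
        grad = (pot[1:] - pot[:-1]) / h  # interface gradients
        if upwind:
            car_face = np.where(grad > 0, car[1:], car[:-1])
        else:
            car_face = 0.5 * (car[1:] + car[:-1])
        flux = car_face * grad
        res[0] += 2.0 * flux[0] / h
        res[1:-1] += (flux[1:] - flux[:-1]) / h
        res[-1] += -2.0 * flux[-1] / h
    return out


def simulate_full(
    p: ModelParams,
    init: np.ndarray,
    g: Grid,
    t_end: float,
    *,
    n_out: int = 101,
    method: str = "BDF",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    blowup_cap: float | None = 1e8,
    upwind: bool = False,
    heaviside_steepness: float | None = None,
    reference: np.ndarray | None = None,
) -> FieldSolution:
    """Integrate the full nonlinear reaction-diffusion-chemotaxis system.

    ``init`` holds the five nonnegative fields, shape ``(5, *grid.shape)``.
    Transport: diffusion for every species, fibroblast chemotaxis
    ``-chi0 div(F grad C)``, macrophage chemotaxis
    ``-chi1 div(M H(M0-M) grad C)`` and the ECM flux
    ``-div[(B Df/F0) E grad F + (B chij/F0) E F H(F0-F) grad C]``.
    ``upwind=True`` switches the carrier interpolation to upwind for
    advection-dominated (large chi) runs.  ``reference`` (e.g. the uniform
    equilibrium) defines the deviation whose L2 norm is recorded.

    Spatially uniform initial data evolves exactly as the reaction ODE
    system (all transport stencils vanish on constants).
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (5, *g.shape):
        raise ValueError(f"init must have shape (5, {g.shape}), got {init.shape}")
    if np.any(init < 0):
        raise ValueError("initial fields must be nonnegative")
    Lap = laplacian_matrix(g)
    diffs = np.array([p.Dd, p.Dc, p.Df, p.Dm, p.De])

    def rhs(t, y):
        u = y.reshape(5, *g.shape)
        rates = reaction_rhs(u, p, heaviside_steepness)
        D, C, F, M, E = u
        for k in range(5):
            rates[k] += diffs[k] * (Lap @ u[k].ravel()).reshape(g.shape)
        HF = heaviside(p.F0 - F, heaviside_steepness)
        HM = heaviside(p.M0 - M, heaviside_steepness)
        rates[2] += -p.chi0 * _flux_divergence(F, C, g, upwind)
        rates[3] += -p.chi1 * _flux_divergence(M * HM, C, g, upwind)
        rates[4] += -(p.Bcoef * p.Df / p.F0) * _flux_divergence(E, F, g, upwind)
        rates[4] += -(p.Bcoef * p.chij / p.F0) * _flux_divergence(E * F * HF, C, g, upwind)
        return rates.ravel()

    pattern = (sp.kron(np.ones((5, 5)), (abs(Lap) > 0) + sp.identity(g.size)) > 0).astype(float)
    sol, blowup = _integrate(
        rhs, init.ravel(), t_end, n_out, method, rtol, atol,
        jac=None, jac_sparsity=pattern if method in ("BDF", "Radau") else None, cap=blowup_cap,
    )
    return _wrap_solution(g, sol, reference=reference, blowup=blowup)


@dataclass(frozen=True)
class GrowthRate:
    """Exponential growth/decay rate fitted to log L2 norms."""

    rate: float
    stderr: float
    r_squared: float
    window: tuple[float, float]


def growth_rate_estimate(sol: FieldSolution, window: tuple[float, float] | None = None) -> GrowthRate:
    """Least-squares slope of ``log ||u||_L2`` over a time window."""
    t, norms = sol.times, sol.l2_norms
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, norms = t[mask], norms[mask]
    else:
        window = (float(sol.times[0]), float(sol.times[-1]))
    if t.size < 3:
        raise ValueError("growth window contains fewer than 3 samples")
    if np.any(norms <= 0):
        raise ValueError("L2 norms must be positive on the fit window")
    fit = linregress(t, np.log(norms))
    return GrowthRate(
        rate=float(fit.slope),
        stderr=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
        window=(float(t[0]), float(t[-1])),
    )


def discrete_mode_eigenvalue(g: Grid, n: int, axis: int = 0) -> float:
    """Discrete Laplacian eigenvalue of the ``n``-th cosine mode on one axis."""
    L = g.extents[axis]
    h = g.spacing[axis]
    return float((2.0 - 2.0 * np.cos(n * np.pi * h / L)) / h**2)


def ode_reference_trajectory(sol: FieldSolution, p: ModelParams) -> Trajectory:
    """Reaction-only trajectory from the initial spatial means (oracle aid)."""
    from .kinetics import integrate_reactions

    return integrate_reactions(sol.means[0], p, float(sol.times[-1]), n_out=sol.times.size)
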