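"""Per-mode spectrum of the linearized PDE system on a Neumann domain.

Expanding a perturbation in Neumann Laplacian eigenfunctions
(``-laplacian phi = mu phi``, ``mu >= 0`` on a convex domain) turns the
linearized reaction-diffusion-chemotaxis system into one 5x5 problem per
mode: the amplitude of mode ``mu`` obeys ``u' = -M(mu) u`` with
``M(0) = B``.  At the interior equilibrium (``b44 = b14 = 0``) the modal
eigenvalues are closed-form::

    sigma1 = -b11 - Dd mu
    sigma2,3 = [-(b22 + Dc mu + Dm mu) -/+ sqrt((b22 + Dc mu + Dm mu)^2 + 4 eps)] / 2
    sigma4 = -b33 - Df mu
    sigma5 = -b55 - De mu

with ``eps = (b42 - chim mu) b24 - Dm mu (b22 + Dc mu)``.  The central
theorem follows by inspection: ODE stability means ``b24 > 0`` (and
``b42 < 0`` always), so ``eps < 0`` for every ``mu, Dm, Dc, chim > 0`` —
diffusion and chemotaxis can never destabilize a reaction-stable inflamed
state.  Conversely, a reaction-unstable state (``b24 < 0``) is stabilized
at a fixed mode ``mu > 0`` whenever the mobilities are large enough to make
``eps < 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linear import STABILITY_TOL, LinearCoefficients, ode_stability_report, reaction_matrix

__all__ = [
    "ModalSpectrum",
    "modal_matrix",
    "modal_epsilon",
    "modal_eigenvalues",
    "modal_spectrum_scan",
    "pde_stability_report",
    "diffusion_stabilization_threshold",
    "default_mu_grid",
]


def modal_matrix(c: LinearCoefficients, p, mu: float) -> np.ndarray:
    """Matrix ``M(mu)`` of the modal dynamics ``u' = -M(mu) u``.

    ``p`` supplies diffusivities ``Dd..De`` (a :class:`~fibrostab.params.ModelParams`
    or :class:`~fibrostab.params.Diffusivities`); the chemotaxis couplings
    come from ``c``.  ``M(0)`` equals the reaction matrix ``B``.
    """
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    B = reaction_matrix(c)
    M = B.copy()
    M += mu * np.diag([p.Dd, p.Dc, p.Df, p.Dm, p.De])
    # cross-Laplacian chemotaxis couplings
    M[2, 1] += -c.chif * mu
    M[3, 1] += -c.chim * mu
    M[4, 1] += -c.chie2 * mu
    M[4, 2] += -c.chie1 * mu
    return M


def modal_epsilon(c: LinearCoefficients, p, mu: float) -> float:
    """``eps(mu) = (b42 - chim mu) b24 - Dm mu (b22 + Dc mu)``.

    The sign of ``eps`` decides the chemoattractant-macrophage block:
    ``eps < 0`` (with ``b22 + (Dc + Dm) mu > 0``) puts both roots in the
    left half-plane; ``eps > 0`` produces exactly one positive root.
    """
    return (c.b42 - c.chim * mu) * c.b24 - p.Dm * mu * (c.b22 + p.Dc * mu)


def modal_eigenvalues(c: LinearCoefficients, p, mu: float) -> tuple[np.ndarray, float]:
    """Closed-form modal eigenvalues and ``eps`` at one mode.

    Returns ``(sigmas, eps)`` with sigmas ordered (1, 2, 3, 4, 5); both
    quadratic roots are returned.  Requires the equilibrium identities
    ``b44 = b14 = 0``; otherwise falls back to the dense eigensolver of
    ``-M(mu)`` (with a warning), in which case the ordering is arbitrary.
    """
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    eps = modal_epsilon(c, p, mu)
    if not c.at_equilibrium:
        import warnings

        warnings.warn(
            "modal_eigenvalues: b44/b14 nonzero; falling back to dense eigensolver",
            stacklevel=2,
        )
        return np.linalg.eigvals(-modal_matrix(c, p, mu)), eps
    s = c.b22 + (p.Dc + p.Dm) * mu
    root = np.sqrt(complex(s * s + 4.0 * eps))
    sigmas = np.array(
        [
            -c.b11 - p.Dd * mu,
            (-s - root) / 2.0,
            (-s + root) / 2.0,
            -c.b33 - p.Df * mu,
            -c.b55 - p.De * mu,
        ],
        dtype=complex,
    )
    return sigmas, eps


def default_mu_grid(length: float = np.pi, n: int = 60) -> np.ndarray:
    """0 plus log-spaced modes up to ``mu_max = (10 pi / L)^2``.

    Covers the first ~10 Neumann modes of an interval of length ``L`` and
    the large-``mu`` diffusion-dominated regime.
    """
    mu_max = (10.0 * np.pi / length) ** 2
    return np.concatenate([[0.0], np.geomspace(mu_max * 1e-4, mu_max, n - 1)])


@dataclass(frozen=True)
class ModalSpectrum:
    """Spectrum scan over a grid of Laplacian eigenvalues."""

    mu_values: np.ndarray  # (n,)
    eigenvalues: np.ndarray  # (n, 5) complex
    epsilon: np.ndarray  # (n,)
    max_re: np.ndarray  # (n,)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"mu": self.mu_values}
        for k in range(5):
            cols[f"re_sigma_{k + 1}"] = self.eigenvalues[:, k].real
        for k in range(5):
            cols[f"im_sigma_{k + 1}"] = self.eigenvalues[:, k].imag
        cols["epsilon"] = self.epsilon
        cols["max_re"] = self.max_re
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def modal_spectrum_scan(c: LinearCoefficients, p, mu_grid: np.ndarray) -> ModalSpectrum:
    """Closed-form spectrum over a mu grid."""
    mu_grid = np.asarray(mu_grid, dtype=float)
    sig = np.empty((mu_grid.size, 5), dtype=complex)
    eps = np.empty(mu_grid.size)
    for i, mu in enumerate(mu_grid):
        sig[i], eps[i] = modal_eigenvalues(c, p, mu)
    return ModalSpectrum(
        mu_values=mu_grid, eigenvalues=sig, epsilon=eps, max_re=sig.real.max(axis=1)
    )


@dataclass(frozen=True)
class PdeStabilityReport:
    spectrum: ModalSpectrum
    stable_on_grid: bool
    ode_classification: str
    condition_trace_positive: np.ndarray  # b22 + (Dc+Dm) mu > 0 per mu
    condition_eps_negative: np.ndarray  # eps < 0 per mu


def pde_stability_report(
    c: LinearCoefficients, p, mu_grid: np.ndarray, tol: float = STABILITY_TOL
) -> PdeStabilityReport:
    """Evaluate per-mode stability over a mu grid and check the theorem.

    The grid must include ``mu = 0`` (the ODE limit).  If the ODE system is
    asymptotically stable the verdict is asserted stable at every mode —
    a failure there would be a counterexample to the theorem (or a bug),
    so it raises rather than reporting quietly.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if mu_grid.size == 0:
        raise ValueError("empty mu grid")
    if mu_grid.min() < 0:
        raise ValueError("mu grid must be nonnegative")
    if not np.any(mu_grid == 0.0):
        raise ValueError("mu grid must include 0 (the ODE limit)")
    spec = modal_spectrum_scan(c, p, mu_grid)
    trace_ok = (c.b22 + (p.Dc + p.Dm) * mu_grid) > 0
    eps_ok = spec.epsilon < 0
    stable = bool(np.all(spec.max_re < -tol))
    ode = ode_stability_report(c, tol=tol)
    if ode.classification == "asymptotically_stable" and not stable:
        raise AssertionError(
            "reaction-stable coefficients produced a modal eigenvalue with "
            "nonnegative real part — violates the ODE-implies-PDE stability theorem"
        )
    return PdeStabilityReport(
        spectrum=spec,
        stable_on_grid=stable,
        ode_classification=ode.classification,
        condition_trace_positive=trace_ok,
        condition_eps_negative=eps_ok,
    )


@dataclass(frozen=True)
class StabilizationThreshold:
    """Mobility bounds making ``eps(mu) < 0`` at a fixed mode.

    ``chim_max`` solves ``eps = 0`` for the chemotaxis coefficient at the
    given ``(Dm, Dc)``; ``dm_dc_product_printed`` is the cruder printed
    sufficient bound ``Dm*Dc > (b42 - chim*mu)*b24/mu`` retained only for
    cross-reference (it is dimensionally inconsistent with ``eps < 0`` and
    is not used by any other operation).
    """

    mu: float
    epsilon: float
    stabilized: bool
    chim_max: float
    dm_dc_product_printed: float


def diffusion_stabilization_threshold(c: LinearCoefficients, p, mu: float) -> StabilizationThreshold:
    """Exact ``eps < 0`` boundary in the mobility parameters, at one mode.

    Only meaningful in the reaction-unstable case ``b24 < 0`` (otherwise
    ``eps < 0`` holds for free); requires ``mu > 0`` (at ``mu = 0`` the
    mobilities drop out and the condition is vacuous).

    The stabilizing set is ``(b42 - chim*mu)*b24 < Dm*mu*(b22 + Dc*mu)``;
    solved for chim (with ``b24 < 0``, larger chemotaxis destabilizes)::

        chim < chim_max = b42/mu - Dm*(b22 + Dc*mu)/b24
    """
    if mu <= 0:
        raise ValueError("mu must be positive (condition is vacuous at mu = 0)")
    if c.b24 >= 0:
        raise ValueError("diffusion stabilization applies to the b24 < 0 case")
    eps = modal_epsilon(c, p, mu)
    chim_max = c.b42 / mu - p.Dm * (c.b22 + p.Dc * mu) / c.b24
    return StabilizationThreshold(
        mu=float(mu),
        epsilon=float(eps),
        stabilized=bool(eps < 0),
        chim_max=float(chim_max),
        dm_dc_product_printed=float((c.b42 - c.chim * mu) * c.b24 / mu),
    )
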