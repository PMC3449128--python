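"""Reaction kinetics of the spatially uniform (well-mixed) system.

With spatial variation removed the model reduces to five coupled ODEs::

    dD/dt = -f0*l1*M*D + f0~*l3*M
    dC/dt =  f1*D + f2*l3*M - f3*l2*M*C - f4*C
    dF/dt =  a1*l1*M + a2*F*(1 - F/F0) - a3*F + a12*C*F*H(F0 - F)
    dM/dt = -a0*M + a11*C*M*H(M0 - M)
    dE/dt =  a16*F*(1 - E/E0)

``H`` is the Heaviside switch; it is evaluated sharply with ``H(0) = 1``
(the analysis lives in the below-threshold regime where ``H == 1``), with an
optional logistic surrogate for integrator robustness near a threshold.
State order is ``(D, C, F, M, E)`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParams

__all__ = ["Trajectory", "heaviside", "reaction_rhs", "reaction_jacobian", "integrate_reactions"]

STATE_NAMES = ("D", "C", "F", "M", "E")


def heaviside(x: np.ndarray | float, steepness: float | None = None):
    """Sharp Heaviside with H(0) = 1, or a logistic surrogate.

    ``steepness`` switches to ``1/(1 + exp(-steepness*x))``, which smooths the
    switch over a width ~1/steepness around the threshold.
    """
    if steepness is None:
        return np.where(np.asarray(x) >= 0, 1.0, 0.0)
    return 1.0 / (1.0 + np.exp(-steepness * np.asarray(x)))


def reaction_rhs(
    s: np.ndarray, p: ModelParams, heaviside_steepness: float | None = None
) -> np.ndarray:
    """Right-hand side of the reaction ODE system at state ``s = (D,C,F,M,E)``.

    Works pointwise on gridded states as well: ``s`` may have shape
    ``(5, ...)``; the rate array has the same shape.
    """
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("reaction_rhs: state contains non-finite entries")
    D, C, F, M, E = s[0], s[1], s[2], s[3], s[4]
    HF = heaviside(p.F0 - F, heaviside_steepness)
    HM = heaviside(p.M0 - M, heaviside_steepness)
    dD = -p.f0 * p.lambda1 * M * D + p.f0_tilde * p.lambda3 * M
    dC = p.f1 * D + p.f2 * p.lambda3 * M - p.f3 * p.lambda2 * M * C - p.f4 * C
    dF = p.a1 * p.lambda1 * M + p.a2 * F * (1.0 - F / p.F0) - p.a3 * F + p.a12 * C * F * HF
    dM = -p.a0 * M + p.a11 * C * M * HM
    dE = p.a16 * F * (1.0 - E / p.E0)
    return np.stack([dD, dC, dF, dM, dE])


def reaction_jacobian(s: np.ndarray, p: ModelParams) -> np.ndarray:
    """Jacobian of :func:`reaction_rhs` at a single state (below threshold).

    Heaviside factors are treated as constants (their derivative is a Dirac
    spike the sharp convention ignores), matching the linearization used in
    the stability analysis.
    """
    D, C, F, M, E = np.asarray(s, dtype=float)
    HF = float(heaviside(p.F0 - F))
    HM = float(heaviside(p.M0 - M))
    J = np.zeros((5, 5))
    J[0, 0] = -p.f0 * p.lambda1 * M
    J[0, 3] = -p.f0 * p.lambda1 * D + p.f0_tilde * p.lambda3
    J[1, 0] = p.f1
    J[1, 1] = -p.f3 * p.lambda2 * M - p.f4
    J[1, 3] = p.f2 * p.lambda3 - p.f3 * p.lambda2 * C
    J[2, 1] = p.a12 * F * HF
    J[2, 2] = p.a2 * (1.0 - 2.0 * F / p.F0) - p.a3 + p.a12 * C * HF
    J[2, 3] = p.a1 * p.lambda1
    J[3, 1] = p.a11 * M * HM
    J[3, 3] = -p.a0 + p.a11 * C * HM
    J[4, 2] = p.a16 * (1.0 - E / p.E0)
    J[4, 4] = -p.a16 * F / p.E0
    return J


@dataclass(frozen=True)
class Trajectory:
    """Time series of the five-component state."""

    times: np.ndarray  # (nt,), strictly increasing
    states: np.ndarray  # (nt, 5)

    def __post_init__(self):
        if self.states.shape != (self.times.size, 5):
            raise ValueError("Trajectory: states shape must be (len(times), 5)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("Trajectory: times must be strictly increasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, **{n: self.states[:, i] for i, n in enumerate(STATE_NAMES)}}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def integrate_reactions(
    s0: np.ndarray,
    p: ModelParams,
    t_end: float,
    *,
    n_out: int = 201,
    method: str = "LSODA",
    rtol: float = 1e-9,
    atol: float = 1e-11,
    heaviside_steepness: float | None = None,
) -> Trajectory:
    """Integrate the well-mixed reaction system from ``s0`` to ``t_end``."""
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    s0 = np.asarray(s0, dtype=float)
    times = np.linspace(0.0, t_end, n_out)
    kwargs = {}
    if heaviside_steepness is None and method in ("LSODA", "BDF", "Radau"):
        kwargs["jac"] = lambda t, y: reaction_jacobian(y, p)
    sol = solve_ivp(
        lambda t, y: reaction_rhs(y, p, heaviside_steepness),
        (0.0, t_end),
        s0,
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
        **kwargs,
    )
    if not sol.success:
        raise RuntimeError(f"reaction ODE integration failed: {sol.message}")
    return Trajectory(times=sol.t, states=sol.y.T)
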