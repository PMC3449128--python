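"""Linearized reaction system: coefficients, matrix and closed-form spectrum.

Sign convention (kept exactly as the analysis states it): the ``b`` entries
are stored with the signs of the linearized system written as
``u' = -B u`` for the perturbation ``u = (d, c, f, m, e)``, so the decay
rates are the eigenvalues ``sigma`` of ``-B``.  Every operation in this
module and downstream documents this to prevent double-negation bugs.

At the interior equilibrium three entries vanish identically:
``b44 = a0 - a11*ce = 0``, ``b14 = -(f0~ l3 - f0 l1 de) = 0`` and
``b53 = -a16 (1 - ee/E0) = 0``, which decouples the characteristic
polynomial into a 3-block (d, c, m) and a triangular 2-block (f, e)::

    sigma1 = -b11
    sigma2 = (-b22 - sqrt(b22^2 + 4 b42 b24)) / 2
    sigma3 = (-b22 + sqrt(b22^2 + 4 b42 b24)) / 2
    sigma4 = -b33
    sigma5 = -b55

``sigma1``, ``sigma2``, ``sigma5`` are negative for any positive parameter
set; stability therefore reduces to ``b33 > 0`` (fibroblast growth beaten by
fibroblast death) and ``b24 > 0`` (regulatory macrophage clearance of the
chemoattractant outweighing inflammatory production).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields

import numpy as np

from .equilibrium import EquilibriumState
from .params import ModelParams

__all__ = [
    "LinearCoefficients",
    "StabilityReport",
    "linear_coefficients",
    "reaction_matrix",
    "ode_eigenvalues",
    "ode_stability_report",
]

#: tolerance on Re(sigma) separating stable / marginal / unstable
STABILITY_TOL = 1e-10


@dataclass(frozen=True)
class LinearCoefficients:
    """Jacobian entries of ``u' = -B u`` plus linearized chemotaxis couplings.

    ``chif = fe*chi0``, ``chim = chi1*me``, ``chie1 = Bcoef*Df*ee/F0``,
    ``chie2 = Bcoef*chij*ee*fe/F0`` multiply cross-Laplacian terms in the
    linearized PDE system; they are irrelevant at the ODE level.
    """

    b11: float
    b14: float
    b21: float
    b22: float
    b24: float
    b32: float
    b33: float
    b34: float
    b42: float
    b44: float
    b53: float
    b55: float
    chif: float = 0.0
    chim: float = 0.0
    chie1: float = 0.0
    chie2: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @property
    def at_equilibrium(self) -> bool:
        """True when the equilibrium zero-identities b44 = b14 = 0 hold."""
        scale = max(abs(self.b11), abs(self.b22), abs(self.b33), abs(self.b55), 1.0)
        return abs(self.b44) <= 1e-9 * scale and abs(self.b14) <= 1e-9 * scale


def linear_coefficients(p: ModelParams, eq: EquilibriumState) -> LinearCoefficients:
    """Linearize the reaction-diffusion-chemotaxis system at a uniform state.

    ``eq`` is normally the interior equilibrium, in which case
    ``b44 = b14 = b53 = 0`` hold by construction; any admissible uniform
    state (below the Heaviside thresholds) is accepted for off-equilibrium
    linearization.
    """
    de, ce, fe, me, ee = eq.de, eq.ce, eq.fe, eq.me, eq.ee
    return LinearCoefficients(
        b11=p.f0 * p.lambda1 * me,
        b14=-(p.f0_tilde * p.lambda3 - p.f0 * p.lambda1 * de),
        b21=-p.f1,
        b22=p.f3 * p.lambda2 * me + p.f4,
        b24=-(p.f2 * p.lambda3 - p.f3 * p.lambda2 * ce),
        b32=-p.a12 * fe,
        b33=-(p.a2 * (1.0 - 2.0 * fe / p.F0) + p.a12 * ce - p.a3),
        b34=-p.a1 * p.lambda1,
        b42=-p.a11 * me,
        b44=p.a0 - p.a11 * ce,
        b53=-p.a16 * (1.0 - ee / p.E0),
        b55=p.a16 * fe / p.E0,
        chif=fe * p.chi0,
        chim=p.chi1 * me,
        chie1=p.Bcoef * p.Df * ee / p.F0,
        chie2=p.Bcoef * p.chij * ee * fe / p.F0,
    )


def reaction_matrix(c: LinearCoefficients) -> np.ndarray:
    """The 5x5 matrix ``B`` of ``u' = -B u``, rows/cols ordered (d,c,f,m,e)."""
    return np.array(
        [
            [c.b11, 0.0, 0.0, c.b14, 0.0],
            [c.b21, c.b22, 0.0, c.b24, 0.0],
            [0.0, c.b32, c.b33, c.b34, 0.0],
            [0.0, c.b42, 0.0, c.b44, 0.0],
            [0.0, 0.0, c.b53, 0.0, c.b55],
        ]
    )


def _closed_form_sigmas(c: LinearCoefficients) -> np.ndarray:
    disc = complex(c.b22 * c.b22 + 4.0 * c.b42 * c.b24)
    root = np.sqrt(disc)
    return np.array(
        [
            -c.b11,
            (-c.b22 - root) / 2.0,
            (-c.b22 + root) / 2.0,
            -c.b33,
            -c.b55,
        ],
        dtype=complex,
    )


def ode_eigenvalues(c: LinearCoefficients) -> np.ndarray:
    """Closed-form eigenvalues ``sigma1..sigma5`` of ``-B``.

    The closed forms assume the equilibrium identities ``b44 = b14 = 0``;
    off equilibrium they do not apply, and the dense eigensolver is used
    instead (with a warning).  Order: (sigma1, sigma2, sigma3, sigma4,
    sigma5) in the closed-form labelling, or unordered numeric eigenvalues
    in the fallback.
    """
    if not c.at_equilibrium:
        warnings.warn(
            "ode_eigenvalues: b44/b14 nonzero (off-equilibrium coefficients); "
            "falling back to the dense eigensolver",
            stacklevel=2,
        )
        return np.linalg.eigvals(-reaction_matrix(c))
    return _closed_form_sigmas(c)


@dataclass(frozen=True)
class StabilityReport:
    """Spectrum and classification of the linearized reaction system."""

    eigenvalues: np.ndarray  # 5 complex sigmas of -B
    classification: str  # asymptotically_stable | marginal | unstable
    b33_positive: bool
    b33_margin: float
    b24_positive: bool
    b24_margin: float
    interpretation: str

    @property
    def max_real_part(self) -> float:
        return float(np.max(self.eigenvalues.real))

    def to_json(self) -> str:
        return json.dumps(
            {
                "eigenvalues": [[z.real, z.imag] for z in self.eigenvalues],
                "classification": self.classification,
                "max_real_part": self.max_real_part,
                "conditions": {
                    "b33_positive": self.b33_positive,
                    "b33_margin": self.b33_margin,
                    "b24_positive": self.b24_positive,
                    "b24_margin": self.b24_margin,
                },
                "interpretation": self.interpretation,
            },
            indent=2,
        )


def ode_stability_report(c: LinearCoefficients, tol: float = STABILITY_TOL) -> StabilityReport:
    """Classify the inflamed steady state for the reaction-only dynamics.

    ``asymptotically_stable`` iff every ``Re sigma < -tol``; ``marginal``
    when the largest real part sits within ``tol`` of zero.
    """
    sig = ode_eigenvalues(c)
    max_re = float(np.max(sig.real))
    if max_re < -tol:
        cls = "asymptotically_stable"
    elif max_re <= tol:
        cls = "marginal"
    else:
        cls = "unstable"
    if c.b24 > 0:
        reading = (
            "regulatory macrophages dominate inflammatory ones (b24 > 0): "
            "chemoattractant perturbations are cleared"
        )
    else:
        reading = (
            "inflammatory macrophages dominate regulatory ones (b24 <= 0): "
            "sigma3 >= 0, reaction-only dynamics do not damp the perturbation"
        )
    return StabilityReport(
        eigenvalues=sig,
        classification=cls,
        b33_positive=bool(c.b33 > 0),
        b33_margin=float(c.b33),
        b24_positive=bool(c.b24 > 0),
        b24_margin=float(c.b24),
        interpretation=reading,
    )
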