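"""Energy (Lyapunov) method: sufficient stability conditions and the
counter-example showing PDE stability without reaction stability.

Multiplying each linearized equation by its own perturbation field,
integrating by parts over the Neumann domain and applying the Poincare
inequality ``Cp * int u^2 <= int |grad u|^2 + (int u)^2`` bounds the decay
of the weighted energy

    V(t) = 1/2 [ int d^2 + lambda1 * int (c^2 + f^2 + m^2 + e^2) ]

by a sum of 2x2 quadratic forms in the fields and their gradients.  Eight
sufficient conditions — one per form — certify that each form is positive
semidefinite; all eight holding (strictly) gives Lyapunov (asymptotic)
stability for zero-spatial-mean initial data, with no reference to the
reaction-only spectrum.  Each condition reads ``sqrt(alpha*gamma) >=
|beta|/2`` for a form ``alpha u^2 + beta u v + gamma v^2``, which is exactly
positive semidefiniteness when ``alpha, gamma >= 0``.

The counter-example lives on the interval ``[0, pi]`` (``Cp = 1``, first
cosine mode ``mu = 1``) with ``b22 = 4 Dc / 5`` and
``b24 = -sqrt(Dc Dm / 20) < 0`` — reaction-unstable by construction.  Small
macrophage chemotaxis (below the Condition-5 bound) leaves all eight
conditions intact and the mode decays; large chemotaxis (above the exact
``eps = 0`` growth threshold) produces a positive modal eigenvalue and the
L2 norm grows without bound.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .equilibrium import EquilibriumState
from .linear import LinearCoefficients, linear_coefficients
from .params import Diffusivities, ModelParams

__all__ = [
    "DomainSpec",
    "ConditionEntry",
    "ConditionReport",
    "poincare_constant",
    "energy_forms",
    "conditions_from_forms",
    "energy_conditions_report",
    "lyapunov_functional",
    "CounterexampleSystem",
    "counterexample_params",
]


@dataclass(frozen=True)
class DomainSpec:
    """Geometry entering the analysis only through the Poincare constant.

    ``kind`` is "interval" or "rectangle"; ``lengths`` has one entry per
    axis.  ``Cp_override`` replaces the closed-form zero-mean Neumann
    constant when set.
    """

    kind: str
    lengths: tuple[float, ...]
    Cp_override: float | None = None

    def __post_init__(self):
        if self.kind not in ("interval", "rectangle"):
            raise ValueError(f"unknown domain kind {self.kind!r}")
        n_expected = 1 if self.kind == "interval" else 2
        if len(self.lengths) != n_expected:
            raise ValueError(f"{self.kind} domain needs {n_expected} length(s)")
        if any(L <= 0 for L in self.lengths):
            raise ValueError("domain lengths must be positive")

    @property
    def Cp(self) -> float:
        return poincare_constant(self)


def poincare_constant(d: DomainSpec) -> float:
    """Zero-mean Neumann Poincare constant of the domain.

    For an interval of length ``L`` this is the first nonzero Neumann
    eigenvalue ``(pi/L)^2``; for a rectangle, the minimum over axes.
    """
    if d.Cp_override is not None:
        if d.Cp_override <= 0:
            raise ValueError("Cp override must be positive")
        return d.Cp_override
    return min((math.pi / L) ** 2 for L in d.lengths)


# --- the eight quadratic forms -------------------------------------------

#: ordered names; each maps to (alpha, beta, gamma) of alpha u^2 + beta uv + gamma v^2
FORM_NAMES = (
    "B(c,d)",
    "B(f,m)",
    "B(c,m)",
    "B(c,f)",
    "B(grad c,grad m)",
    "B(grad c,grad f)",
    "B(grad f,grad e)",
    "B(grad c,grad e)",
)


def energy_forms(
    c: LinearCoefficients, diff, Cp: float, m2_extra: float = 0.0
) -> dict[str, tuple[float, float, float]]:
    """Coefficient triples of the eight quadratic forms.

    ``diff`` supplies diffusivities ``Dd..De``.  ``m2_extra`` is the extra
    ``m^2`` coefficient ``a11*me - a0`` appearing in the macrophage form
    (zero at the interior equilibrium, free in the counter-example
    construction, where ``a11*me >= a0`` keeps it well posed).

    The d^2 coefficient of ``B(c,d)`` is ``b11 + Dd*Cp`` — the coefficient
    the energy estimate actually produces (``b11 = f0*lambda1*me``).
    """
    return {
        "B(c,d)": (diff.Dc * Cp / 6.0 + c.b22, c.b21, c.b11 + diff.Dd * Cp),
        "B(f,m)": (diff.Df * Cp / 4.0 + c.b33, c.b34, diff.Dm * Cp / 3.0),
        "B(c,m)": (diff.Dc * Cp / 6.0 + c.b22, c.b24, diff.Dm * Cp / 3.0 + m2_extra),
        "B(c,f)": (diff.Dc * Cp / 6.0, c.b32, diff.Df * Cp / 3.0),
        "B(grad c,grad m)": (diff.Dc / 6.0, -c.chim, diff.Dm / 3.0),
        "B(grad c,grad f)": (diff.Dc / 6.0, -c.chif, diff.Df / 4.0),
        "B(grad f,grad e)": (diff.Df / 4.0, -c.chie1, diff.De / 2.0),
        "B(grad c,grad e)": (diff.Dc / 6.0, -c.chie2, diff.De / 2.0),
    }


@dataclass(frozen=True)
class ConditionEntry:
    name: str
    alpha: float
    beta: float
    gamma: float
    holds: bool
    strict: bool
    margin: float  # sqrt(alpha*gamma) - |beta|/2 when alpha,gamma >= 0, else min(alpha,gamma)
    applicable: bool = True
    note: str = ""


@dataclass(frozen=True)
class ConditionReport:
    conditions: tuple[ConditionEntry, ...]
    overall: str  # asymptotically-stable | Lyapunov-stable | inconclusive
    A_value: float | None = None

    def __getitem__(self, i: int) -> ConditionEntry:
        """1-based access matching the condition numbering."""
        return self.conditions[i - 1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "overall": self.overall,
                "A_value": self.A_value,
                "conditions": [
                    {
                        "index": i + 1,
                        "name": e.name,
                        "alpha": e.alpha,
                        "beta": e.beta,
                        "gamma": e.gamma,
                        "holds": e.holds,
                        "strict": e.strict,
                        "margin": e.margin,
                        "applicable": e.applicable,
                        "note": e.note,
                    }
                    for i, e in enumerate(self.conditions)
                ],
            },
            indent=2,
        )


def _evaluate_form(name: str, alpha: float, beta: float, gamma: float) -> ConditionEntry:
    applicable = True
    note = ""
    if alpha < 0 or gamma < 0:
        holds = strict = False
        margin = min(alpha, gamma)
        if name == "B(c,m)":
            applicable = False
            note = "well-posedness failed: a diagonal coefficient is negative"
    else:
        lhs = math.sqrt(alpha * gamma)
        margin = lhs - abs(beta) / 2.0
        holds = margin >= 0
        strict = margin > 0 and alpha > 0 and gamma > 0
    return ConditionEntry(
        name=name, alpha=alpha, beta=beta, gamma=gamma,
        holds=holds, strict=strict, margin=margin, applicable=applicable, note=note,
    )


def conditions_from_forms(
    forms: dict[str, tuple[float, float, float]], A_value: float | None = None
) -> ConditionReport:
    entries = tuple(_evaluate_form(name, *forms[name]) for name in FORM_NAMES)
    if all(e.holds and e.strict for e in entries):
        overall = "asymptotically-stable"
    elif all(e.holds for e in entries):
        overall = "Lyapunov-stable"
    else:
        overall = "inconclusive"
    return ConditionReport(conditions=entries, overall=overall, A_value=A_value)


def energy_conditions_report(
    p: ModelParams, eq: EquilibriumState, d: DomainSpec
) -> ConditionReport:
    """Evaluate Conditions 1-8 at the interior equilibrium on a domain.

    Conditions are sufficient only: "inconclusive" does not mean unstable.
    ``A_value`` is the auxiliary constant ``A = L1^2`` of the simplified
    fibroblast-macrophage condition.
    """
    c = linear_coefficients(p, eq)
    m2_extra = p.a11 * eq.me - p.a0
    forms = energy_forms(c, p, poincare_constant(d), m2_extra=m2_extra)
    return conditions_from_forms(forms, A_value=eq.L1 ** 2)


def lyapunov_functional(fields: np.ndarray, lambda1: float, spacing) -> float:
    """``V = 1/2 [int d^2 + lambda1 int (c^2+f^2+m^2+e^2)]`` by trapezoid rule.

    ``fields`` has shape ``(5, nx)`` or ``(5, nx, ny)``; ``spacing`` is the
    grid spacing per axis (scalar or sequence matching the dimension).
    """
    fields = np.asarray(fields, dtype=float)
    if fields.ndim not in (2, 3) or fields.shape[0] != 5:
        raise ValueError("fields must have shape (5, nx) or (5, nx, ny)")
    spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
    if spacing.size != fields.ndim - 1:
        raise ValueError("spacing must provide one value per spatial axis")

    def integrate(u2: np.ndarray) -> float:
        for dx in spacing[::-1]:
            u2 = np.trapezoid(u2, dx=dx, axis=-1)
        return float(u2)

    d2 = integrate(fields[0] ** 2)
    rest = sum(integrate(fields[k] ** 2) for k in range(1, 5))
    return 0.5 * (d2 + lambda1 * rest)


# --- the [0, pi] counter-example construction ----------------------------


@dataclass(frozen=True)
class CounterexampleSystem:
    """Linearized system realizing the conditional-stability dichotomy."""

    coeffs: LinearCoefficients
    diffusivities: Diffusivities
    domain: DomainSpec
    regime: str
    mu: float
    chim: float
    chim_energy_threshold: float  # Condition-5 bound: decay certified below
    chim_growth_threshold: float  # exact eps = 0 boundary at mu: growth above
    predicted_sign: int  # sign of the dominant modal eigenvalue at mu
    m2_extra: float = 0.0  # a11*me - a0 of the construction

    def energy_report(self) -> ConditionReport:
        forms = energy_forms(
            self.coeffs, self.diffusivities, poincare_constant(self.domain),
            m2_extra=self.m2_extra,
        )
        return conditions_from_forms(forms)

    def to_config(self) -> dict:
        return {
            "regime": self.regime,
            "domain": {"kind": self.domain.kind, "lengths": list(self.domain.lengths)},
            "mu": self.mu,
            "chim": self.chim,
            "chim_energy_threshold": self.chim_energy_threshold,
            "chim_growth_threshold": self.chim_growth_threshold,
            "predicted_sign": self.predicted_sign,
            "diffusivities": {k: getattr(self.diffusivities, k) for k in ("Dd", "Dc", "Df", "Dm", "De")},
            "derived_b": self.coeffs.as_dict(),
        }


def counterexample_params(
    Dc: float,
    Dm: float,
    regime: str,
    *,
    a0: float = 1.0,
    b11: float = 1.0,
    b21: float = -0.1,
    b32: float = -0.1,
    b33: float = 1.0,
    b34: float = -0.1,
    b55: float = 1.0,
    Dd: float = 1.0,
    Df: float = 1.0,
    De: float = 1.0,
    safety: float = 1.25,
) -> CounterexampleSystem:
    """Emit the ``[0, pi]`` construction in the requested regime.

    Pinned by the construction: ``b22 = 4 Dc / 5``,
    ``b24 = -sqrt(Dc Dm / 20)`` (reaction-unstable), ``a11*me = a0`` (so
    ``b42 = -a0`` and the macrophage form stays well posed with
    ``m2_extra = 0``), first cosine mode ``mu = 1``, ``Cp = 1``.  The
    remaining coefficients are free; the documented defaults are chosen
    small/stabilizing so Conditions 1, 2, 4, 6-8 hold and only the
    chemotaxis strength ``chim`` decides the outcome:

    - ``regime="stable"``: ``chim`` at 90% of the Condition-5 bound
      ``2 sqrt(Dc Dm / 18)`` — all eight conditions hold strictly, the mode
      decays.
    - ``regime="unstable"``: ``chim`` at ``safety`` times the exact growth
      threshold (the ``eps = 0`` boundary) — one positive modal eigenvalue,
      the L2 norm grows without bound.

    Either way the reaction-only (``mu = 0``) system has ``b24 < 0``, hence
    ``sigma3 > 0``: the dichotomy is purely spatial.
    """
    if Dc <= 0 or Dm <= 0:
        raise ValueError("Dc and Dm must be positive")
    if regime not in ("stable", "unstable"):
        raise ValueError("regime must be 'stable' or 'unstable'")
    mu = 1.0
    b22 = 0.8 * Dc
    b24 = -math.sqrt(Dc * Dm / 20.0)
    b42 = -a0
    chim_energy = 2.0 * math.sqrt((Dc / 6.0) * (Dm / 3.0))
    # eps(mu=1) = 0 boundary solved for chim (b24 < 0)
    chim_growth = b42 / mu - Dm * (b22 + Dc * mu) / b24
    if regime == "stable":
        chim = 0.9 * chim_energy
        predicted = -1
        # The printed macrophage condition ignores the b42 cross term, so the
        # Condition-5 bound does not by itself keep chim below the exact
        # eps = 0 boundary when Dc*Dm is small relative to a0; refuse to emit
        # an inconsistent "stable" system rather than mislabel it.
        eps_at_mu = (b42 - chim) * b24 - Dm * (b22 + Dc * mu)
        if eps_at_mu >= 0:
            raise ValueError(
                "stable regime unattainable for these (Dc, Dm, a0): the "
                f"Condition-5 chemotaxis bound {chim_energy:.4g} exceeds the exact "
                f"growth threshold {chim_growth:.4g}; increase Dc*Dm or decrease a0"
            )
    else:
        chim = max(safety * chim_growth, chim_growth + 1.0)
        predicted = +1
    coeffs = LinearCoefficients(
        b11=b11, b14=0.0, b21=b21, b22=b22, b24=b24,
        b32=b32, b33=b33, b34=b34, b42=b42, b44=0.0, b53=0.0, b55=b55,
        chif=0.0, chim=chim, chie1=0.0, chie2=0.0,
    )
    return CounterexampleSystem(
        coeffs=coeffs,
        diffusivities=Diffusivities(Dd=Dd, Dc=Dc, Df=Df, Dm=Dm, De=De),
        domain=DomainSpec(kind="interval", lengths=(math.pi,)),
        regime=regime,
        mu=mu,
        chim=chim,
        chim_energy_threshold=chim_energy,
        chim_growth_threshold=chim_growth,
        predicted_sign=predicted,
        m2_extra=0.0,
    )
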