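"""Closed-form interior (inflammatory) equilibrium and its existence region.

The interior equilibrium is the unique spatially uniform steady state with
all five components strictly positive::

    de = f0~ l3 / (f0 l1)
    ce = a0 / a11
    ee = E0
    me = (f4 f0 l1 a0 - a11 f1 f0~ l3) / (f0 l1 (f2 l3 a11 - f3 a0 l2))
    fe = (F0 / (2 a2)) [ (a2 - a3 + a12 a0/a11) + L1 ]

with ``L1 = sqrt((a2 - a3 + a12 a0/a11)^2 + 4 (a2/F0) a1 l1 me)``.  It
exists iff ``me > 0``, i.e. iff numerator and denominator share a sign:
either inflammatory macrophages beat regulatory clearance on both counts
(branch "Eq13": ``f2 l3 a11 > f3 a0 l2`` and ``f4 f0 l1 a0 > a11 f1 f0~ l3``)
or both inequalities reverse (branch "Eq14").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import reaction_rhs
from .params import ModelParams

__all__ = [
    "EquilibriumState",
    "ExistenceReport",
    "NoInteriorEquilibrium",
    "interior_equilibrium",
    "existence_report",
    "phenotype_region_scan",
]


class NoInteriorEquilibrium(ValueError):
    """Raised when the phenotype balance admits no positive equilibrium."""


@dataclass(frozen=True)
class EquilibriumState:
    """Interior equilibrium; ``L1`` is the square-root term in ``fe``."""

    de: float
    ce: float
    fe: float
    me: float
    ee: float
    L1: float

    def as_array(self) -> np.ndarray:
        """State vector in (D, C, F, M, E) order."""
        return np.array([self.de, self.ce, self.fe, self.me, self.ee])


@dataclass(frozen=True)
class ExistenceReport:
    exists: bool
    branch: str  # "Eq13" | "Eq14" | "none"
    me_value: float
    fe_below_F0: bool | None
    me_below_M0: bool | None


def _me_fraction(p: ModelParams) -> tuple[float, float, float]:
    """(me, numerator, denominator) of the macrophage equilibrium."""
    num = p.f4 * p.f0 * p.lambda1 * p.a0 - p.a11 * p.f1 * p.f0_tilde * p.lambda3
    den = p.f0 * p.lambda1 * (p.f2 * p.lambda3 * p.a11 - p.f3 * p.a0 * p.lambda2)
    # degenerate phenotype balance: no finite equilibrium, me undefined
    me = np.nan if den == 0 else num / den
    return me, num, den


def interior_equilibrium(p: ModelParams) -> EquilibriumState:
    """Evaluate the closed-form interior equilibrium.

    Raises
    ------
    NoInteriorEquilibrium
        If the phenotype-balance condition fails (``me <= 0``), carrying the
        failing inequality.
    """
    me, num, den = _me_fraction(p)
    if not np.isfinite(me) or me <= 0:
        detail = (
            f"f4*f0*l1*a0 - a11*f1*f0~*l3 = {num:.6g}, "
            f"f0*l1*(f2*l3*a11 - f3*a0*l2) = {den:.6g} (need same sign, both nonzero)"
        )
        raise NoInteriorEquilibrium(f"me = {me:.6g} <= 0: {detail}")
    de = p.f0_tilde * p.lambda3 / (p.f0 * p.lambda1)
    ce = p.a0 / p.a11
    q = p.a2 - p.a3 + p.a12 * ce
    L1 = float(np.sqrt(q * q + 4.0 * (p.a2 / p.F0) * p.a1 * p.lambda1 * me))
    fe = (p.F0 / (2.0 * p.a2)) * (q + L1)  # "+" root; the "-" root is <= 0 when me > 0
    return EquilibriumState(de=de, ce=ce, fe=fe, me=me, ee=p.E0, L1=L1)


def existence_report(p: ModelParams) -> ExistenceReport:
    """Evaluate both sign branches of the existence condition."""
    me, num, den = _me_fraction(p)
    exists = bool(np.isfinite(me) and me > 0)
    if den > 0 and num > 0:
        branch = "Eq13"
    elif den < 0 and num < 0:
        branch = "Eq14"
    else:
        branch = "none"
    fe_ok = me_ok = None
    if exists:
        eq = interior_equilibrium(p)
        fe_ok = bool(eq.fe <= p.F0)
        me_ok = bool(eq.me <= p.M0)
    return ExistenceReport(exists=exists, branch=branch, me_value=float(me), fe_below_F0=fe_ok, me_below_M0=me_ok)


def residual_at_equilibrium(p: ModelParams) -> np.ndarray:
    """Reaction rates at the closed-form equilibrium (zero up to round-off)."""
    return reaction_rhs(interior_equilibrium(p).as_array(), p)


def phenotype_region_scan(p: ModelParams, resolution: int = 40) -> pd.DataFrame:
    """Scan the macrophage-phenotype simplex for equilibrium existence.

    Evaluates :func:`existence_report` on a barycentric grid of
    ``(lambda1, lambda2, lambda3)`` with the stated ``resolution`` (grid
    points ``i/resolution`` with all three fractions strictly positive;
    the sum is normalized to 1 before evaluation).  All other coefficients
    are taken from ``p``.

    Returns a DataFrame with columns
    ``lambda1, lambda2, lambda3, exists, branch, me``.
    """
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    rows = []
    for i, j in itertools.product(range(1, resolution), repeat=2):
        k = resolution - i - j
        if k < 1:
            continue
        lam = np.array([i, j, k], dtype=float) / resolution
        rep = existence_report(p.replace(lambda1=lam[0], lambda2=lam[1], lambda3=lam[2]))
        rows.append(
            {
                "lambda1": lam[0],
                "lambda2": lam[1],
                "lambda3": lam[2],
                "exists": rep.exists,
                "branch": rep.branch,
                "me": rep.me_value,
            }
        )
    if not rows:
        raise ValueError("empty phenotype grid")
    return pd.DataFrame(rows)
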