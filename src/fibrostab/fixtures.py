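"""Seeded generation of parameter sets realizing the named regimes.

The analysis prints no fitted rates, so regime fixtures are produced by
rejection sampling: coefficients are drawn log-uniformly over plausible
positive ranges, phenotype fractions from a flat Dirichlet on the simplex,
and a draw is kept when the regime's defining inequalities hold (plus the
below-threshold regime the closed forms assume).  Deterministic given the
seed.
"""

from __future__ import annotations

import numpy as np

from .equilibrium import existence_report, interior_equilibrium
from .linear import linear_coefficients, ode_stability_report
from .params import ModelParams, validate_params

__all__ = ["REGIMES", "generate_fixture_params", "sample_ensemble"]

REGIMES = (
    "existence_eq13",
    "existence_eq14",
    "ode_stable",
    "ode_unstable_b24",
    "counterexample",
)


def _draw(rng: np.random.Generator) -> ModelParams:
    def logu(lo, hi, n=None):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    lam = rng.dirichlet(np.ones(3))
    # keep fractions strictly inside (0, 1)
    lam = 0.9 * lam + 0.1 / 3.0
    r = logu(0.05, 2.0, 13)
    return ModelParams(
        Dd=logu(0.01, 1.0), Dc=logu(0.01, 1.0), Df=logu(0.01, 1.0),
        Dm=logu(0.01, 1.0), De=logu(0.01, 1.0),
        chi0=logu(0.005, 0.2), chi1=logu(0.005, 0.2), chij=logu(0.005, 0.2),
        Bcoef=logu(0.01, 0.5),
        f0=r[0], f0_tilde=r[1], f1=r[2], f2=r[3], f3=r[4], f4=r[5],
        a0=r[6], a1=r[7], a2=r[8], a3=r[9], a11=r[10], a12=r[11], a16=r[12],
        lambda1=lam[0], lambda2=lam[1], lambda3=lam[2],
        F0=logu(5.0, 20.0), M0=logu(2.0, 10.0), E0=logu(0.5, 2.0),
    )


def _in_threshold_regime(p: ModelParams) -> bool:
    eq = interior_equilibrium(p)
    return eq.fe <= p.F0 and eq.me <= p.M0


def _accept(p: ModelParams, regime: str) -> bool:
    rep = existence_report(p)
    if not rep.exists:
        return False
    if regime == "existence_eq13":
        return rep.branch == "Eq13" and _in_threshold_regime(p)
    if regime == "existence_eq14":
        return rep.branch == "Eq14" and _in_threshold_regime(p)
    if not _in_threshold_regime(p):
        return False
    c = linear_coefficients(p, interior_equilibrium(p))
    if regime == "ode_stable":
        return ode_stability_report(c).classification == "asymptotically_stable"
    if regime in ("ode_unstable_b24", "counterexample"):
        return c.b24 < 0
    raise ValueError(f"unknown regime {regime!r}; choose from {REGIMES}")


def generate_fixture_params(regime: str, seed: int, *, max_attempts: int = 20000) -> ModelParams:
    """Rejection-sample a positive parameter set in the named regime.

    Regimes: ``existence_eq13`` / ``existence_eq14`` — the two sign branches
    of the equilibrium existence condition; ``ode_stable`` — reaction-only
    asymptotic stability (forces branch Eq14); ``ode_unstable_b24`` —
    inflammatory dominance ``b24 < 0``, hence ``sigma3 > 0``;
    ``counterexample`` — an ``ode_unstable_b24`` set with chemoattractant
    and macrophage mobilities scaled up 100x, the kinetic analogue of the
    diffusion-stabilization regime.

    Deterministic given ``seed``; raises if the sampling budget is
    exhausted (suggesting the bounds are too tight for the regime).
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {REGIMES}")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        p = _draw(rng)
        try:
            ok = _accept(p, regime)
        except (ZeroDivisionError, FloatingPointError):
            continue
        if not ok:
            continue
        if regime == "counterexample":
            p = p.replace(Dm=100.0 * p.Dm, Dc=100.0 * p.Dc)
        if any(i.severity == "error" for i in validate_params(p)):
            continue
        return p
    raise RuntimeError(
        f"could not sample regime {regime!r} in {max_attempts} attempts; relax the bounds"
    )


def sample_ensemble(
    regime: str, n: int, seed: int, *, max_attempts: int | None = None
) -> list[ModelParams]:
    """``n`` independent parameter sets in a regime from one seeded stream."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {REGIMES}")
    rng = np.random.default_rng(seed)
    budget = max_attempts if max_attempts is not None else 2000 * n
    out: list[ModelParams] = []
    for _ in range(budget):
        p = _draw(rng)
        try:
            ok = _accept(p, regime)
        except (ZeroDivisionError, FloatingPointError):
            continue
        if ok:
            if regime == "counterexample":
                p = p.replace(Dm=100.0 * p.Dm, Dc=100.0 * p.Dc)
            out.append(p)
            if len(out) == n:
                return out
    raise RuntimeError(f"sampled only {len(out)}/{n} sets for regime {regime!r}")
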