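"""Model parameters for the five-field fibrotic-reaction model.

The model couples debris ``D``, chemoattractant ``C`` (chiefly TGF-beta),
fibroblasts ``F``, macrophages ``M`` and extracellular matrix ``E`` through
mass-action kinetics, Fickian diffusion and chemotaxis up the chemoattractant
gradient.  Macrophages are a fixed mix of classical, regulatory and
inflammatory phenotypes with proportions ``lambda1``, ``lambda2``,
``lambda3``; the mix decides both existence and stability of the inflamed
steady state.

All coefficients are positive; time is in arbitrary units (days), lengths in
arbitrary units — there is no unit-conversion layer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "ModelParams",
    "Diffusivities",
    "ValidationIssue",
    "validate_params",
    "load_params",
    "save_params",
    "DEFAULT_STABLE",
    "DEFAULT_UNSTABLE_B24",
]


@dataclass(frozen=True)
class ModelParams:
    """Complete coefficient set of the fibrotic-reaction model.

    Parameters
    ----------
    Dd, Dc, Df, Dm, De
        Diffusion coefficients of debris, chemoattractant, fibroblasts,
        macrophages and ECM (length^2 / time).
    chi0, chi1, chij
        Chemotaxis coefficients: fibroblast taxis, macrophage taxis, and the
        chemotactic part of the ECM transport flux.
    Bcoef
        Scaling constant ``B`` of the ECM transport flux
        ``Phi = (B*Df/F0) E grad F + (B*chij/F0) E F H(F0-F) grad C``.
    f0, f0_tilde, f1, f2, f3, f4
        Debris/chemoattractant kinetics: phagocytosis of debris by classical
        macrophages (``f0``), debris shedding by inflammatory macrophages
        (``f0_tilde``), chemoattractant production by debris (``f1``) and by
        inflammatory macrophages (``f2``), clearance by regulatory
        macrophages (``f3``) and natural decay (``f4``).
    a0, a1, a2, a3, a11, a12, a16
        Macrophage apoptosis (``a0``) and chemoattractant-driven
        proliferation (``a11``); fibroblast recruitment by classical
        macrophages (``a1``), logistic growth (``a2``), death (``a3``) and
        chemoattractant-driven proliferation (``a12``); collagen secretion
        (``a16``).
    lambda1, lambda2, lambda3
        Classical / regulatory / inflammatory macrophage phenotype fractions,
        each in (0, 1).
    F0, M0, E0
        Saturation thresholds for fibroblasts, macrophages and ECM.
    """

    Dd: float
    Dc: float
    Df: float
    Dm: float
    De: float
    chi0: float
    chi1: float
    chij: float
    Bcoef: float
    f0: float
    f0_tilde: float
    f1: float
    f2: float
    f3: float
    f4: float
    a0: float
    a1: float
    a2: float
    a3: float
    a11: float
    a12: float
    a16: float
    lambda1: float
    lambda2: float
    lambda3: float
    F0: float
    M0: float
    E0: float

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.as_dict().items())


@dataclass(frozen=True)
class Diffusivities:
    """Just the five diffusion coefficients.

    Any object exposing ``Dd, Dc, Df, Dm, De`` (a full :class:`ModelParams`
    included) is accepted wherever diffusivities are needed; this bundle
    exists for constructions that prescribe the linearized coefficients
    directly without an underlying kinetic parameter set.
    """

    Dd: float
    Dc: float
    Df: float
    Dm: float
    De: float


@dataclass(frozen=True)
class ValidationIssue:
    """One finding of :func:`validate_params`."""

    severity: str  # "error" | "warning"
    field: str
    message: str


def validate_params(p: ModelParams) -> list[ValidationIssue]:
    """Check positivity, phenotype-fraction bounds and the analysis regime.

    Errors are structural (non-positive coefficients, fractions outside
    (0, 1)).  Warnings flag parameter sets that are legal but outside the
    regime the closed-form analysis assumes: the interior equilibrium must
    exist (the phenotype-balance condition on ``m_e > 0``) and sit below the
    Heaviside thresholds ``F0`` and ``M0`` so the switches stay on.

    Never mutates ``p``; never raises.
    """
    issues: list[ValidationIssue] = []
    for name, value in p:
        if not (value > 0):
            issues.append(ValidationIssue("error", name, f"{name} must be strictly positive, got {value!r}"))
    for name in ("lambda1", "lambda2", "lambda3"):
        v = getattr(p, name)
        if v > 0 and not (v < 1):
            issues.append(ValidationIssue("error", name, f"{name} must lie in (0, 1), got {v!r}"))
    if issues:
        return issues

    lam_sum = p.lambda1 + p.lambda2 + p.lambda3
    if abs(lam_sum - 1.0) > 1e-9:
        issues.append(
            ValidationIssue(
                "warning",
                "lambda1",
                f"phenotype fractions sum to {lam_sum:.6g}, not 1 (the model does not require it)",
            )
        )

    # Threshold-regime warnings need the equilibrium; import here to avoid a cycle.
    from .equilibrium import NoInteriorEquilibrium, interior_equilibrium

    try:
        eq = interior_equilibrium(p)
    except NoInteriorEquilibrium as exc:
        issues.append(
            ValidationIssue("warning", "lambda3", f"no interior equilibrium: {exc}")
        )
        return issues
    if eq.fe > p.F0:
        issues.append(
            ValidationIssue(
                "warning", "F0", f"threshold regime violated: fe = {eq.fe:.6g} exceeds F0 = {p.F0:.6g}"
            )
        )
    if eq.me > p.M0:
        issues.append(
            ValidationIssue(
                "warning", "M0", f"threshold regime violated: me = {eq.me:.6g} exceeds M0 = {p.M0:.6g}"
            )
        )
    return issues


def load_params(path: str | Path) -> ModelParams:
    """Read a flat key/value config (YAML or JSON, by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a flat mapping")
    known = {f.name for f in dataclasses.fields(ModelParams)}
    extra = set(data) - known - {"schema"}
    if extra:
        raise ValueError(f"unknown parameter keys in {path}: {sorted(extra)}")
    missing = known - set(data)
    if missing:
        raise ValueError(f"missing parameter keys in {path}: {sorted(missing)}")
    return ModelParams(**{k: float(data[k]) for k in known})


def save_params(p: ModelParams, path: str | Path) -> None:
    """Write a flat key/value config (YAML or JSON, by extension)."""
    path = Path(path)
    data = p.as_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# Documented default coefficient sets.  The underlying analysis prints no
# numbers, so these are fixtures chosen to realize the two qualitative
# regimes, not claims about biology.

#: Interior equilibrium exists with regulatory macrophages dominating
#: inflammatory ones (f3*lambda2*ce > f2*lambda3, hence b24 > 0): the inflamed
#: state is asymptotically stable for the reaction ODE system, therefore for
#: the full PDE system as well.  Equilibrium: de=0.25, ce=0.5, me=1, fe~3.56,
#: ee=1.
DEFAULT_STABLE = ModelParams(
    Dd=0.1, Dc=0.1, Df=0.1, Dm=0.1, De=0.1,
    chi0=0.05, chi1=0.05, chij=0.05, Bcoef=0.1,
    f0=1.0, f0_tilde=0.5, f1=0.8, f2=0.5, f3=1.0, f4=0.2,
    a0=0.5, a1=0.5, a2=1.0, a3=0.8, a11=1.0, a12=0.2, a16=0.3,
    lambda1=0.4, lambda2=0.4, lambda3=0.2,
    F0=10.0, M0=5.0, E0=1.0,
)

#: Interior equilibrium exists with inflammatory macrophages dominating
#: (f2*lambda3 > f3*lambda2*ce, hence b24 < 0 and sigma3 > 0): the reaction
#: ODE system is unstable at the inflamed state.
DEFAULT_UNSTABLE_B24 = ModelParams(
    Dd=0.1, Dc=0.1, Df=0.1, Dm=0.1, De=0.1,
    chi0=0.05, chi1=0.05, chij=0.05, Bcoef=0.1,
    f0=1.0, f0_tilde=0.2, f1=0.5, f2=1.0, f3=0.5, f4=0.5,
    a0=0.5, a1=0.5, a2=1.0, a3=0.8, a11=1.0, a12=0.2, a16=0.3,
    lambda1=0.3, lambda2=0.2, lambda3=0.5,
    F0=10.0, M0=5.0, E0=1.0,
)
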