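# Methods

## The model

Five fields on a convex domain Ω with homogeneous Neumann boundaries:
debris `D`, chemoattractant `C`, fibroblasts `F`, macrophages `M`,
extracellular matrix `E`.  All coefficients are strictly positive; time is
in arbitrary units (days) and no unit conversion is attempted.  Macrophages
carry fixed phenotype fractions `λ1` (classical), `λ2` (regulatory), `λ3`
(inflammatory); the model does not require `λ1+λ2+λ3 = 1` and the validator
only warns when the sum differs from 1.

The Heaviside switches `H(F0−F)`, `H(M0−M)` model saturation of the
chemoattractant-driven proliferation terms.  They are evaluated sharply with
`H(0) = 1`; the whole analytical apparatus lives in the below-threshold
regime where `H ≡ 1`, so the convention matters only on the boundary.  A
logistic surrogate `1/(1+exp(−k x))` with configurable steepness `k` is
available for integrator robustness when trajectories cross a threshold.

The fibroblast equation is implemented in the unambiguous kinetic form
`a1 λ1 M + a2 F (1 − F/F0) − a3 F + a12 C F H(F0−F)` (logistic growth with
carrying capacity `F0`, death `a3 F`, chemoattractant-driven proliferation).

## Interior equilibrium

Setting the reaction rates to zero and taking the below-threshold branch
gives the unique strictly positive ("interior", inflamed) steady state

    de = f̃0 λ3 / (f0 λ1),   ce = a0 / a11,   ee = E0,
    me = (f4 f0 λ1 a0 − a11 f1 f̃0 λ3) / (f0 λ1 (f2 λ3 a11 − f3 a0 λ2)),
    fe = (F0 / 2a2) [ q + L1 ],   q = a2 − a3 + a12 ce,
    L1 = sqrt(q² + 4 (a2/F0) a1 λ1 me).

It exists iff `me > 0`, i.e. iff the numerator and denominator above share a
sign — either inflammatory dominance on both counts (branch "Eq13") or
regulatory/classical dominance on both (branch "Eq14").  A degenerate zero
denominator is reported as non-existence (`me = NaN`).  `fe` is the `+`
root of its quadratic; the `−` root is ≤ 0 whenever `me > 0` (verified on
ensembles, not proven symbolically).  When the computed `fe` or `me` exceeds
its threshold (`F0`, `M0`) the closed form no longer solves the switched
kinetics; `validate_params` emits a regime warning and downstream stability
claims should not be trusted.

## Linearized calculus

Coefficients `b_ij` are stored exactly in the sign convention of the system
`u' = −B u` for the perturbation `u = (d, c, f, m, e)`; decay rates are
eigenvalues of `−B`.  This is documented on every operation because the
double negation is the easiest bug to write in this calculus.

At the interior equilibrium, `b44 = a0 − a11 ce = 0` and
`b14 = −(f̃0 λ3 − f0 λ1 de) = 0` identically (these are the package's two
acceptance targets, checked in exact rational arithmetic and on random
ensembles), and `b53 = −a16(1 − ee/E0) = 0` since `ee = E0`.  The published analysis
prints `b44` once with `me` and once with `ce`; linearizing
`−a0 M + a11 C M` in `M` gives `a11 ce − a0`, so the `ce` form is used.
Likewise `b55` is `a16 fe / E0` (linearization of the ECM equation), not
the variant with `f0`.

The characteristic polynomial factors into a (d, c, m) 3-block and a
triangular (f, e) 2-block, giving

    σ1 = −b11,  σ2,3 = (−b22 ∓ sqrt(b22² + 4 b42 b24))/2,  σ4 = −b33,  σ5 = −b55.

`σ1, σ2, σ5 < 0` always; at the `+` equilibrium root `b33 = L1 > 0`
automatically, so **reaction stability is decided by `b24 > 0` alone**,
i.e. by `f3 λ2 ce > f2 λ3` — regulatory clearance of the chemoattractant
outweighing inflammatory production.  Classification uses a tolerance of
1e-10 on `max Re σ` ("marginal" within it), chosen because the proved-zero
eigenvalue directions sit exactly on the boundary in exact arithmetic.
Closed-form and numeric spectra are compared after minimal-cost assignment
(`scipy.optimize.linear_sum_assignment`), since eigenvalue ordering is
undefined.

## Modal analysis

Perturbations expand in Neumann Laplacian eigenfunctions (`μ ≥ 0` on convex
domains); mode `μ` evolves under `u' = −M(μ) u` with `M(0) = B`.  Closed
forms at the equilibrium:

    σ1 = −b11 − Dd μ,   σ4 = −b33 − Df μ,   σ5 = −b55 − De μ,
    σ2,3 = [−s ∓ sqrt(s² + 4ε)]/2,   s = b22 + (Dc + Dm) μ,
    ε = (b42 − χm μ) b24 − Dm μ (b22 + Dc μ).

The discriminant is typographically garbled in the published analysis; the
reading `s²` above is the unique one reproducing the dense eigensolver, and
the equivalence is enforced by tests rather than assumed.  Both quadratic
roots are always reported.

The central theorem is read off the formulas: reaction stability means
`b24 > 0` (with `b42 < 0` always), so `ε < 0` for every `μ, χm, Dm, Dc > 0`
and no mode can grow — `pde_stability_report` asserts this and raises on a
violation.  For reaction-unstable sets (`b24 < 0`) the exact stabilization
condition at a fixed mode is `ε(μ) < 0`, exposed solved for the chemotaxis
coefficient: `χm < b42/μ − Dm (b22 + Dc μ)/b24`.  The cruder printed bound
on `Dm Dc` is dimensionally inconsistent with `ε < 0` and is carried only
as a documented cross-reference field, never used.

Default μ-grid: 0 plus 59 log-spaced points up to `(10π/L)²` — the first
~10 modes of an interval of length `L` plus the diffusion-dominated tail.

## Energy method

Testing each linearized equation against its own field, integrating by
parts and applying the Poincaré inequality
`Cp ∫u² ≤ ∫|∇u|² + (∫u)²` bounds the decay of
`V = ½[∫d² + λ1 ∫(c²+f²+m²+e²)]` by eight 2×2 quadratic forms.  Each
sufficient condition reads `sqrt(αγ) ≥ |β|/2` for a form
`α u² + β uv + γ v²`, which is exactly positive semidefiniteness for
`α, γ ≥ 0`; the report evaluates both routes and they must agree.  The
published fractions are printed flattened ("16DcCp" = `Dc Cp/6` etc.);
each reading is fixed by matching the bilinear forms, and the
discriminant cross-check makes any misreading fail loudly.  Two further
readings were fixed here: the `d²` coefficient of the debris–chemoattractant
form is `b11 + Dd Cp` (what the estimate produces), and the ECM gradient
forms pair `χe1` with `∇f·∇e` and `χe2` with `∇c·∇e`, following the flux
definitions.  All eight conditions hold for large enough diffusivities, so
"inconclusive" never means unstable — the conditions are sufficient only.

Known gap, kept deliberately: the printed macrophage–chemoattractant
condition carries only the `b24` cross term although the estimate produces
`b24 + b42`.  The package implements the printed form (the counter-example
construction relies on it) and therefore refuses to emit a "stable"
counter-example whose exact modal test contradicts the certificate (see
below).  Users should treat the eight conditions as originally stated:
a certificate family, not a sharp boundary.

Poincaré constants: `(π/L)²` for an interval (the first nonzero Neumann
eigenvalue for zero-mean data), the minimum over axes for a rectangle, with
a user override for other geometries.  All integrals use the trapezoid rule
on uniform grids — second order, matching the simulator.

### Counter-example family

On `[0, π]` (`Cp = 1`, first cosine mode `μ = 1`) with `b22 = 4Dc/5`,
`b24 = −sqrt(DcDm/20)` (reaction-unstable by construction) and
`a11 me = a0` (the printed `a11 me ≥ a0` at equality, keeping `b44 = 0` so
the closed modal forms stay valid), the dichotomy is decided by `χm` alone:

* *stable regime*: `χm` at 90% of the Condition-5 bound `2 sqrt(DcDm/18)`
  — all eight conditions hold strictly and the mode decays;
* *unstable regime*: `χm` 25% above the exact growth threshold (the
  `ε(1) = 0` boundary `χm = b42 − Dm(b22+Dc)/b24`) — one positive modal
  eigenvalue, L2 growth without bound.

The two published threshold constants are typographically
ambiguous; both are derived from first principles here and the dichotomy is
verified by simulation, with the transition bracketed numerically around
the exact boundary.  Free coefficients of the construction (`b11`, `b21`,
`b32`, `b33`, `b34`, `b55`, the remaining diffusivities) default to small
stabilizing values and are user-settable.  For small `Dc·Dm` relative to
`a0` the stable regime is unattainable (a consequence of the dropped `b42`
term noted above) and the constructor raises rather than mislabel.

## Simulation

Uniform vertex-centred grids; diffusion and linearized cross-Laplacian
chemotaxis use the mirrored 3-point (5-point in 2D) stencil; nonlinear
chemotaxis fluxes use the conservative interface form with half-cell
divergences at the walls, which (a) coincides with the mirrored stencil for
pure diffusion and (b) conserves the trapezoid-weighted mean exactly —
zero-mean perturbations stay zero-mean to solver tolerance, as the
energy-method setting requires.  An upwind carrier option exists for
advection-dominated (large χ) runs.  Cosine modes are exact eigenvectors of
the discrete Laplacian with `μ_h = (2 − 2 cos(nπh/L))/h² = (nπ/L)² + O(h²)`,
so single-mode runs reproduce closed-form rates to integrator accuracy at
`μ_h` and to second order in `h` at the continuum `μ`.

Time stepping: `scipy.integrate.solve_ivp` BDF by default (the exact sparse
Jacobian is supplied for the linearized system, a sparsity pattern for the
nonlinear one); rtol 1e-8 / atol 1e-10 defaults.  Blow-up is detected by a
terminal event at `1e8 ×` the initial norm (configurable) and reported as a
flag instead of propagating NaNs.  Growth/decay rates are least-squares
slopes of `log ||u||_L2` over a stated window, with the fit R² reported;
windows late in the run isolate the dominant eigenvalue.

## Fixtures and synthetic inputs

The underlying analysis prints **no numeric parameter values**, so every
concrete number in this package is a synthetic fixture, not biology: the
two shipped default sets realize the stable (branch Eq14, `b24 > 0`) and
unstable (branch Eq13, `b24 < 0`) regimes with O(0.1–1) rates and
equilibria comfortably below thresholds; ensembles are rejection-sampled
log-uniformly over [0.05, 2] for rates, [0.01, 1] for diffusivities,
Dirichlet phenotype fractions, constrained to the named regime and the
below-threshold regime.  A green ensemble test therefore establishes the
*mathematical* claims (identities, spectra, theorem, dichotomy) over that
stated world — it says nothing about measured tissue kinetics, spatial
heterogeneity of phenotype fractions, or above-threshold dynamics.

## Limitations

* Only the interior equilibrium is analyzed; the model's other (non-strictly
  positive) equilibria are out of scope except the origin as a validation aid.
* Convex domains only (interval/rectangle closed forms); no 3D, no FEM,
  no adaptive meshing.
* The energy conditions are certificates, not sharp boundaries, and inherit
  the printed-form gap documented above.
* No parameter estimation: nothing here fits data, and the defaults are
  fixtures chosen to realize regimes.
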