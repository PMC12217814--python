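# Methods

## Model

The package studies a mixture of self-propelled and passive particles on a
periodic two-dimensional square lattice with hard-core exclusion (at most
one particle per site). Three species live on the lattice: right-moving
active particles (orientation +1), left-moving active particles
(orientation −1), and passive particles. In rescaled units (time in units
of the inverse tumble rate, length in units of the persistence length
√(D_T/D_R)) the microscopic rates are

* passive jumps to each of the four neighbours at rate 1/h²,
* active horizontal jumps at rate 1/h² ± Pe/(2h) along/against the
  orientation and vertical jumps at 1/h²,
* orientation flips at rate 1,
* any jump into an occupied site is aborted.

Here h is the lattice spacing and Pe = v₀/√(D_T·D_R) is the Péclet number.
The backward active rate is negative when h > 2/Pe; the lattice module
rejects such configurations.

In the hydrodynamic limit h → 0 at fixed volume fractions the species
densities ρ₊, ρ₋, ρ₀ obey, in one space dimension (self-propulsion is
horizontal only, so transverse variations relax diffusively),

    ∂t ρσ = ∂x[ d_s(ρ) ∂x ρσ + ρσ D(ρ) ∂x ρ ]
            − Pe ∂x[ ρσ s(ρ) m + σ d_s(ρ) ρσ ] − σ m ,

with ρ the total density, m = ρ₊ − ρ₋ the magnetization,
D(ρ) = (1 − d_s(ρ))/ρ and s = D − 1. d_s(ρ) is the self-diffusion
coefficient of a tagged particle in the symmetric exclusion process; the
default is the cubic approximation d_s = (1−ρ)(1 − αρ + α(2α−1)ρ²/(2α+1)),
α = π/2 − 1, which is exact in value and slope at ρ = 0 and ρ = 1. The
coefficient interface is pluggable (any d_s with an analytic derivative);
all derived coefficients keep the identity ρD + d_s = 1 exactly, which
makes the total density obey ∂t ρ = ∂x[∂x ρ − Pe(1−ρ)m].

## Numerics

**Time stepping.** First-order finite volumes with upwinded advective
fluxes (on the sign of the local advective velocity) and centred
diffusive fluxes; forward Euler with dt = cfl·min(Δx²/2, Δx/max|u|)
(the diffusive bound is exact because the total-density diffusivity is
identically 1) and a positivity guard that halves dt on violation. A
centred second-order flux variant exists for linear-response work, where
upwind numerical diffusion would bias measured growth rates. The scheme
conserves the active and passive cell averages to round-off.

**Linear stability.** Perturbing the uniform state with plane waves
reduces the linearization to a 3×3 eigenvalue problem; the matrix is
assembled from the analytic coefficient derivatives and was verified
symbolically against the PDE and numerically against a
Richardson-extrapolated finite-difference Jacobian of the discrete
right-hand side (agreement ~1e-11). At q = 0 the spectrum is exactly
{0, 0, −2}. The spinodal is the zero set of the supremum over continuous
q of the dominant growth rate, traced by bisection along rays from the
interior of the unstable region; codimension-two (Bogdanov–Takens)
points are located by bisection of the real↔complex transition of the
dominant eigenvalue along the spinodal arc. The printed perturbation
ansatz "exp(λt + iqxt)" is read as the standard plane wave exp(λt+iqx).

**Phase coexistence.** For stationary phase-separated states the
zero-flux first integrals give m = ∂x ρ/(Pe(1−ρ)) and the slaving law
ρ₀ = ν(1−ρ) with ν = φ_p/(1−φ). Eliminating m and ρ₀ leaves a planar
profile equation g₀(ρ) + Λ(ρ)(∂xρ)² − κ(ρ)∂x²ρ = const with the closed
forms (derived by computer algebra, frozen in code, and validated by a
residual oracle on relaxed PDE steady states)

    g₀ = −(2/Pe) ln(1−ρ) + Pe d_s(ρ) [ρ − ν(1−ρ)],
    Λ  = −2 d_s(ρ) / (Pe (1−ρ)²),
    κ  =    d_s(ρ) / (Pe (1−ρ)).

The gradient terms become exact against a transformed density R(ρ) with
κR″ + (Λ+κ′)R′ = 0, i.e. R′ = 1/((1−ρ)d_s(ρ)); an effective potential
Φ(R) with dΦ/dR = g₀ then yields the coexisting densities by the common
tangent construction. Numerically the two conditions collapse to a
single monotone scalar equation in the common level ḡ (bisection), which
is robust arbitrarily close to the critical point; the liquid branch is
resolved in u = −ln(1−ρ) because it approaches full packing
exponentially fast at large Pe. The interface profile is obtained from
the exact reduction of the profile equation to a linear first-order ODE
for p(ρ) = (∂xρ)², integrated across the miscibility gap and mapped to
real space by quadrature; the construction guarantees p returns to zero
at the liquid density, which is checked.

**Traveling waves.** The co-moving profiles at finite L solve a periodic
boundary-value problem discretized with second-order centred
conservative differences: unknowns are the three profiles plus the speed
c, constrained by the species-mass averages and a translational gauge
(total density pinned at one node). The bordered sparse system is
solved by damped Newton with a colored finite-difference Jacobian (the
banded blocks cost a handful of residual evaluations; constraint rows
are assembled analytically). Branches are threaded by continuation in
domain size and composition.

In the thermodynamic limit the magnetization is slaved,
m = −(Pe/2L) d/dz[d_s(ρ)ρ_a] + O(1/L²), and the system reduces to two
outer equations for ρ_a and ρ₀ on the unit-scaled coordinate. We
validated this reduction directly: converged finite-L solutions satisfy
the outer equations to O(1/L) in their smooth regions. Two evaluation
routes are provided for the outer speed:

1. a direct Dirichlet/periodic Newton solve of the outer equations
   (N grid points, interface endpoint values from the coexistence
   construction). For traveling states the stationary relation
   ν = φ_p/(1−φ) does not bind (the fluxes J, J₀ are nonzero), so the
   interface tie-line ratio ν̂ is kept as a matching unknown — with ν
   fixed the discrete problem is overdetermined by one equation and
   stalls at a grid-independent residual floor. The direct solve is
   sensitive to how the interfacial boundary layer is truncated;
2. the defining limit: Richardson extrapolation in 1/L of the finite-L
   Newton speeds at L ∈ {140, 200, 280, 400}. This is the default in
   the benchmark pipeline because it is insensitive to the boundary
   layer and its history doubles as the domain-size convergence check.

An exact structural result is enforced and tested: summing the co-moving
equations and integrating gives (c/L)ρ + ρ′ − Pe(1−ρ)m = J, so a
traveling profile (c ≠ 0) cannot carry two flat bulk plateaus of
different density. The plateau detector requires both a small gradient
and a small within-run density variation, so the smoothly varying outer
regions of traveling profiles (gradients O(1/L), variation O(1)) are not
mistaken for bulks.

**Classification.** Long-time PDE states are labeled H/PS/T/CP from two
metrics, the approximate speed c̃ = ‖∂tρσ‖₂/‖∂xρσ‖₂ (all species
stacked; equal to the wave velocity for rigid translation) and the
distance from uniform d_H = (Σσ‖ρσ−φσ‖₂)^{1/2} (the square root of the
sum of norms, as this composition is defined in the source material; the
units are unusual but it is reproduced as printed). Norms are continuum
L2 norms. Decision thresholds 0.05 (d_H), 0.01 (c̃), 1e-5 (sup|c̃′|)
with a 500-unit window ending at t* ≥ 700 are the defaults; t* is
understood adaptively (integrate until a rule fires — near-marginal
traveling attractors can drift slowly and settle only after t ≈ 1000).
c̃′ uses a sliding-window least-squares slope so frame-sampling noise
cannot flip the T/CP rules.

**Lattice simulation.** Exact continuous-time sampling with a
rejection-style Gillespie scheme: per-particle total rates are
configuration independent (blocked jumps are retained as null events),
so each event is O(1). Mesoscopic densities are y-averaged top-hat
window counts (radius r, default 0.1; a Gaussian window is available —
the precise mesoscopic kernel of the source data is not documented, so
the top-hat is a package choice), normalized to volume fractions.

## Parameter choices and scaling

* Default lattice spacing for desk-scale runs is h = 0.025 (the
  finest documented value h = 0.01 is supported but costly); kymograph
  runs use aspect ratio ℓy = ℓx/4.
* The initial-condition generator uses mean-subtracted per-cell uniform
  noise at relative amplitude 1e-3 and eigenmode kicks of amplitude
  0.05 by default. The benchmark composition (Pe = 7.5, φ_a = 0.36,
  φ_p = 0.30) is *marginally stable* in this implementation (dominant
  growth −2·10⁻⁴), so reaching the traveling attractor requires a
  finite-amplitude kick along the least-stable mode
  (`allow_stable=True`); the attractor and its speed are insensitive to
  the kick amplitude over 0.05–0.15.
* Co-moving solves use ~20 grid points per unit length so the O(1)-wide
  interfacial structure stays resolved at every L.
* The benchmark pipeline (`aplg.experiments.acceptance_targets`) runs
  the time-stepped reference experiment at Δx = 0.05 to t = 500 and
  evaluates thermodynamic-limit speeds at the reference composition,
  at reduced passive load (φ_p = 0.26), at the computed terminal
  composition of the traveling branch (where the single-structure
  branch folds, located by step-halving continuation), and slightly
  below it in φ_a.

## What the synthetic runs do and do not show

All verification inputs are parameter sets; there is no external data.
The PDE fixtures probe the deterministic hydrodynamic limit only;
agreement between the lattice simulation and the PDE is checked at
scaled-down h = 0.025 and says nothing about fluctuation corrections at
finite h beyond that resolution. The phase-diagram constructions are
exact within the cubic d_s approximation; an alternative d_s changes the
curves quantitatively (the interface to swap it in is provided, and all
constructions go through the generic coefficient API).

## Known limitations

* The traveling-state landscape at moderate Pe is multistable. The
  attractor selected by time stepping depends on the initial kick; the
  co-moving Newton solver converges to the branch of its seed. Branches
  whose interfaces follow a quasi-static tie line through the
  documented compositions were not found in this implementation — the
  interface ratio of the converged branch settles near 0.52 at the
  reference composition rather than the stationary-law value 0.88, and
  the computed speeds differ accordingly from some published reference
  values (see the benchmark notes in the repository).
* The direct outer Dirichlet solver is fragile away from an excellent
  seed (interior degeneracies of the effective diffusion matrix make
  the Jacobian near-singular); the 1/L extrapolation route is the
  recommended way to evaluate thermodynamic-limit speeds.
* The two-interface outer construction is implemented but has no
  robustly converged reference case in the test suite; the transition
  composition is instead located as the fold of the single-structure
  branch.
* Stability analysis of inhomogeneous (phase-separated) base states is
  out of scope.
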