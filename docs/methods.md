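# Methods

## Scope and model

`rsbeam` models the lateral growth of a scanned proton pencil beam that
traverses a range shifter (RS) — a slab of polycarbonate (Lexan) placed
between the nozzle and the patient to reach shallow treatment depths —
and evaluates a commissioning-driven treatment-planning-system (TPS)
model of that growth against two first-principles references.

Per transverse axis, a Gaussian pencil beam is fully described by the
Fermi–Eyges second moments at a reference plane: position variance
A (cm²), position–angle covariance B (cm·rad) and angular variance
C (rad²). Under a free drift of length `dz` along the beam,

    A' = C dz² + 2 B dz + A,   B' = C dz + B,   C' = C,

which conserves the determinant AC − B² (the squared minimum achievable
spot size in free drift, up to 1/C). A scatterer adds increments
(ΔA, ΔB, ΔC) obtained by integrating its scattering power T(z′) over
depth with lever arms to the reference plane:

    ΔA = ∫ (S + t − z′)² T(z′) dz′,  ΔB = ∫ (S + t − z′) T(z′) dz′,
    ΔC = ∫ T(z′) dz′,

with S the air gap between the slab exit face and the reference plane
and t the slab thickness. Three independent routes to these increments
are implemented:

1. **Analytical reference** (`scattering.rs_fermi_eyges_moments`):
   T(z′) = (14.1 MeV / pv(z′))² · ρ/L_R from the Highland
   parameterization, with pv(z′) from the slab's range–energy law.
   Following the usual practice for thick targets, the logarithmic
   thickness correction is not applied inside the integral; it can be
   applied once on the full slab thickness (off by default — the
   convention of the analytical reference this package implements).
2. **Monte Carlo reference** (`montecarlo`): condensed-history ensemble
   transport (below).
3. **The TPS V-parameter model** (`commissioning`): the model under
   evaluation (below).

Axes are treated independently throughout (no x–y coupling); dose is
out of scope — only fluence geometry (spot sigma) is modelled.

## Coordinates, units and conventions

Positions are **cm from isocenter, positive toward the nozzle**; the
beam travels toward decreasing position, so the drift distance from the
reference plane `z_ref` to a plane `z` is `z_ref − z`. All internal
quantities are cm, g/cm², MeV, rad; spot datasets carry sigma in mm and
are converted at the I/O boundary.

Two bookkeeping conventions for the A parameter exist in the field:
`variance` (σ² = A, the package default) and the cylindrically
symmetric `eclipse_cylindrical` (A = 2σ²). The convention is an
explicit attribute of every `PhaseSpace`; all cross-convention
comparisons go through `sigma_at`, and scattering increments are scaled
by the convention factor when added, so spot sigmas are convention
independent (this is the factor-of-two trap the commissioning
literature warns about).

## Kinematics and range–energy law

pv = E(E + 2E₀)/(E + E₀) with E₀ = 938.272 MeV; β = √(1 − (E₀/(E+E₀))²).
Ranges follow a Bragg–Kleeman power law R = αE^p per material, with
(α, p) fitted once, over 50–250 MeV, against a continuous-slowing-down
range obtained by integrating the uncorrected Bethe stopping power with
the material's Z/A and mean excitation energy (stored alongside the
coefficients in `data/materials.yaml`; water: p = 1.7427, Lexan:
p = 1.7432, ρ = 1.20 g/cm³, L_R = 41.5 g/cm²). The fit agrees with its
own quadrature to <1% over 70–230 MeV and ~2% at the band edges; the
package uses the same law in all three routes, so cross-route
comparisons are insensitive to its residual error. Energy after a depth
d inverts the law on the residual range. The slab's water-equivalent
thickness (WET) is computed from range differences at a reference
energy of 160 MeV — for the 6.5 cm Lexan slab this gives 7.43 cm,
mildly energy dependent (<1% over the clinical band).

## The V-parameter model

The TPS model does not use nominal slab properties. It represents the
slab by a single energy-independent scattering constant V (MeV),
extracted during commissioning, and writes the moment increments in
closed form using three nested integrals over speed β ("five-thirds
approximation" of the stopping power):

    φ(β) = ∫ dβ′ / (β′^{4/3}(1−β′²)^{4/3}),
    χ(β) = ∫ φ(β′) β′^{8/3}/(1−β′²)^{3/2} dβ′,
    ψ(β) = ∫ χ(β′) β′^{8/3}/(1−β′²)^{3/2} dβ′,

all from a lower cutoff β_c that regularizes the φ singularity at β = 0.
The increments are

    ΔA = V/(α³E₀){α²[(S+L)²φᵢ − S²φₒ] − 2αE₀[(S+L)χᵢ − Sχₒ] + 2E₀²(ψᵢ−ψₒ)}
    ΔB = V/(α²E₀){α[(S+L)φᵢ − Sφₒ] − E₀(χᵢ−χₒ)}
    ΔC = V/(αE₀)(φᵢ − φₒ)

with L the slab WET, α the material factor, and φᵢ/φₒ etc. evaluated at
the entrance and exit speeds. The χ/ψ weight is exactly the derivative
of the model's residual-range relation, dr/dβ = (E₀/α)β^{8/3}(1−β²)^{−3/2},
i.e. stopping power ∝ β^{−5/3} — which is what makes the lever-arm
forms above exact after the depth→β change of variables. Two design
choices follow from demanding this self-consistency:

* **Exit speed.** βₒ is solved from the model's own range relation,
  G(βᵢ) − G(βₒ) = αL/E₀ with G′ the χ/ψ weight (not from the water
  power law). This keeps the by-parts identities exact at every energy
  and makes β_c cancel exactly from all entrance−exit differences
  (asserted by test at 1e-6); with a water-law exit speed the three
  V equations drift apart by ~20% at 225 MeV.
* **α calibration.** α is fixed once so that the model's range relation
  reproduces the fitted water power law across the commissioning slab
  at 160 MeV (mid commissioning range); it is stored in `VModel` and
  overridable. β_c defaults to 0.05, far below any clinical proton.

**Extraction and averaging.** Each of the three equations is linear in
V; commissioning solves all three from the measured (ΔA, ΔB, ΔC) at
every energy. Against data generated from the Highland Fermi–Eyges
reference the three estimates agree to ≈2.4% at each energy (the model
works in water-equivalent geometry, so its effective lever arms differ
slightly from the physical ones), but the estimates drift ≈17% from
105 to 160 MeV because the model's implied scattering power
(∝ β⁻⁴(1−β²)^{1/6}) differs relativistically from Highland's 1/pv².
The estimator therefore supports two averaging policies: `global`
(one V averaged over all equations and energies — the behaviour of the
evaluated TPS, and the default) and `per_energy` (isolating the model's
geometric fidelity). With per-energy averaging the predicted envelopes
at displaced slab positions stay within 2% of the analytical reference
below 165 MeV; with the global average, deviations up to ~8% appear at
the band edges — both figures are computed by the acceptance script,
not assumed. An optional multiplicative Lynch–Dahl correction
((13.6/14.1)² (1+0.038 ln L/X₀)², off by default) mirrors the
vendor-documented refinement; because extraction and prediction share
the factor it cancels in all round trips and would matter only across
slab thicknesses, which are not varied here.

## Constrained phase-space fitting

σ²(d)·(convention factor) is a quadratic C d² + 2B d + A in the
propagation distance d; fitting it to spot sigmas at ≥3 planes is a
linear least-squares problem that recovers noise-free data exactly. The
physical region is A, C ≥ 0, AC − B² ≥ 0; when the unconstrained
optimum leaves it, the fit is re-solved by SLSQP with the determinant
as an inequality constraint (boundary parameterization B = ±√(AC) as a
fallback; smallest-residual solution wins) and the result is snapped
onto the determinant-zero surface with `constraint_active` set. The
strictness is deliberate: silently repairing a negative determinant is
precisely the TPS defect the pipeline must detect, so the core always
raises or flags and never adjusts quietly.

## Defect emulations (opt-in)

* **Parameter clamp**: for table entries whose in-air isocenter sigma
  falls below a threshold (default 3.8 mm), (A, B, C) are replaced by
  the values at the highest unaffected energy and flagged. The
  continuation rule is configurable; constant continuation matches the
  observed flat parameter plateau.
* **Envelope-discard condition**: `check_rs_correction_validity`
  compares with-RS and open envelopes either downstream of the slab
  face only (physically meaningful — scattering can only widen the
  beam there) or over the full ±50 cm axis (the flawed comparison,
  which for a narrow-waist corrected beam reports σ_RS < σ_open
  upstream of the slab and can trigger a spurious discard of the
  correction).

Both are gated behind explicit options (`--emulate-eclipse-bugs` in the
CLI); the default pipeline is strictly correct physics.

## Monte Carlo

The benchmark ensemble samples (x, θx) and (y, θy) independently per
axis from the zero-mean bivariate Gaussian with covariance
[[A, B], [B, C]] of the phase space back-projected 50 cm upstream of
isocenter. Air regions are exact drifts. Inside the slab,
condensed-history steps of at most 1 mm draw correlated lateral and
angular kicks with the exact within-step Fermi–Eyges moments
(θ_s², θ_s²Δs/2, θ_s²Δs²/3), θ_s being the log-free Highland width for
the step's mass thickness at the step-midpoint pv, so convergence is
second order in step size; at the default step the bias is far below
the statistical error of 200,000 protons (verified against the
closed form). The ensemble is monoenergetic and shares a common energy
per step (path lengthening ~θ²/2 ≲ 1e-4 is neglected); consequently
"stopping inside the slab" is an all-or-nothing condition and raises.
Only the Gaussian core of multiple Coulomb scattering is modelled — no
single-scattering tails, nuclear interactions or secondaries — matching
the analytical reference's assumptions, so the MC is an independent
check of the *transport*, not of those excluded physics. RNG streams
are per-axis children of an explicit `SeedSequence`; identical seeds
give bit-identical tallies.

Spot sizes are extracted from binned tallies by maximum likelihood with
exact per-bin Gaussian probabilities (unbiased to O(1/n), free of
Sheppard binning bias; SE = σ/√(2n)), mirroring the screen-measurement
procedure; 2-D images (e.g. RT-Dose planes read via pydicom) are fitted
with a least-squares elliptical Gaussian.

## Synthetic data

No public spot-size dataset exists for this setup, so the generator
emulates one: per energy and axis, open-beam sigmas follow the truth
phase space exactly and with-RS sigmas add the slab's Fermi–Eyges
moments (or, on request, the V-model increments, for exact round-trip
tests), with i.i.d. Gaussian noise (default 0.05 mm, well under the
0.5 mm screen pixel). The default truth table is a fixture, not a
physics claim: isocenter sigma falls from 6.0 mm (x) at 105 MeV as
(105/E)^0.9 to 3.0 mm at 226.7 MeV — crossing the 3.8 mm clamp
threshold between 160 and 225 MeV — with angular spread ~3 mrad
scaling as (105/E)^0.45 and a waist 2–3 cm downstream of isocenter;
the y axis is 5% wider. The default measurement grid is ±20 cm in
10 cm steps (the screen protocol); the evaluation planes are ±20 cm in
5 cm steps. Passing tests on this generator demonstrates correctness of
the transport, commissioning and comparison machinery under Gaussian
beams and Gaussian noise; it does not validate the excluded physics
(halo, straggling, detector blur) against real measurements.

## Scenario set and problem sizes

The benchmark factorial is 5 energies (105, 140, 160, 225, 226.7 MeV)
× 3 slab positions (exit face at 17.5, 26.5, 36.5 cm) plus 5 open-beam
runs; commissioning uses the 36.5 cm position. Monte Carlo runs use
200,000 protons per scenario — enough that the 3·SE band on sigma is
0.02–0.15 mm, resolving the 0.1 mm agreement criterion — and the whole
20-scenario comparison completes in well under a minute on one core.
Planes lying inside or upstream of the slab are excluded from the MC
column (the additive-moment envelope is only physical downstream of
the exit face); the analytical columns still tabulate the extrapolated
envelope there, which is exactly the quantity the envelope-discard
check scrutinizes.

## Numerical choices

* Slab moment integrals: composite Simpson on 257 nodes (smooth
  integrand; doubling changes results < 1e-6, asserted).
* Five-thirds integrals: solved jointly as an ODE in β (DOP853,
  rtol 1e-11), checked against brute-force Riemann sums to 1e-6.
* Exit-speed inversion: Brent's method on the cumulative weight
  integral, xtol 1e-13.
* Constrained fit: SLSQP (ftol 1e-14) with analytic gradient; boundary
  fallback via Levenberg–Marquardt on the B = ±ac parameterization.
* Degenerate inputs raise typed exceptions (`StoppedBeamError`,
  `NonPhysicalPhaseSpaceError`, `DegenerateDataError`, `GeometryError`)
  rather than returning repaired values.

## Known limitations

* The V model's printed closed forms are reconstructed from an
  ambiguous source; the reading implemented here is the unique one that
  is dimensionally and variationally self-consistent (see the module
  docstring of `rsbeam.commissioning`), but the vendor's exact
  internals (including how the Lynch–Dahl refinement enters) are not
  public, so bit-level agreement with any TPS is out of scope.
* The Bragg–Kleeman law omits straggling and shell corrections; only
  lateral spot geometry is modelled, not depth dose.
* Real measured beams have non-Gaussian halo at the few-percent level
  that neither reference here reproduces.
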