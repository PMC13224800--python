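# Methods

This note documents the models, numerical choices and validation scope of
`rheoref`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the example scripts, not copied
from elsewhere.

## 1. The measurement being modelled

A double wall–ring (DWR) interfacial shear rheometer drives a titanium ring
of diamond cross-section (diagonal 1 mm, side L ≈ 0.707 mm) suspended at a
fluid interface inside a double-gap annular channel (inner cup wall
R_i = 20 mm, contact lines R4 = 23 mm and R5 = 24 mm, outer wall
R_o = 28.79 mm). Oscillating the ring at angular frequency ω and measuring
the torque and angular-displacement phasors gives the complex amplitude
ratio

    AR = (T0/θ0) e^{iφ}.

The probe's torque balance in the frequency domain (time factor e^{+iωt})
is

    AR = −I ω² + iω (K_i + K_b),

with I the rotor+probe inertia and K_i, K_b the interfacial and bulk drag
torques per unit angular velocity. The interfacial state enters through the
complex Boussinesq number Bo* = η_s*/(η a), where η_s* is the complex
interfacial shear viscosity, η the subphase viscosity and a = L the probe's
area-to-perimeter length. Moduli follow G* = iω η_s*, so G″ = ω Re η_s*
and G′ = −ω Im η_s*. The sign convention is pinned by two physical checks
(enforced in tests): a purely viscous interface yields drag in quadrature
with displacement, a purely elastic one in phase opposition.

### Contact-line radii and inertia

R4 and R5 are not manufacturing data we possess; the defaults (23.0 and
24.0 mm) satisfy the ring-gap = diagonal constraint and sit near the
equal-contact-line-strain design condition R_i²/(R4²−R_i²) ≈ R_o²/(R_o²−R5²)
(left/right terms 1.64e-3 / 1.89e-3 m² with the defaults). The rotor+probe
inertia defaults to I = 1.0e-5 kg·m²; it is a config parameter intended to
be calibrated from a clean-interface frequency sweep
(`inversion.calibrate_inertia`, which fits AR(ω) = −Iω² + iωK_b(ω) and
flags residual interfacial drag through its misfit diagnostics). All of
these are overridable in the run configuration.

## 2. Analytic geometry quantities

* **Average strain** (high-Bo limit): each gap carries the annular-Couette
  profile u = C1 r + C2/r, whose displacement strain is γ(r) = −2C2θ0/r².
  Averaging over the annular area of both gaps gives

      γ = 4θ0 [R_i²R4² ln(R4/R_i)/(R4²−R_i²) + R5²R_o² ln(R_o/R5)/(R_o²−R5²)]
          / [(R4²−R_i²)+(R_o²−R5²)],

  ≈ 6.0·θ0 for the default geometry (3 % strain ↔ θ0 ≈ 5 mrad). A
  numerical-quadrature oracle checks this to <0.1 %.
* **High-Bo drag coefficient**: g1 = 4π[R_i²R4²/(R4²−R_i²) +
  R5²R_o²/(R_o²−R5²)] ≈ 4.43e-2 m³ for the defaults, validated against the
  PDE solver's elastic-plate limit to <1 %.
* **Inertia limit**: G_lim = Iω²/g1, the modulus floor below which the
  rotor inertia masks the interfacial response; at 0.5 Hz with the default
  inertia it is ≈ 2.2e-3 N/m.
* **Capillary length**: sqrt(σ/ρg) with g = 9.81 m/s².

## 3. Flow solver

The azimuthal velocity amplitude u(r, z) obeys the oscillatory Stokes
equation η(∂rr + r⁻¹∂r − r⁻² + ∂zz)u = iωρu in each bulk phase, no-slip on
walls, u = rΩ on the probe, and the Boussinesq–Scriven balance
η_s*(∂rr + r⁻¹∂r − r⁻²)u = Σ_p η_p ∂u/∂n_p on the free interface rows.
The fluid-inertia term can be switched off (the Couette oracles are
steady). The upper phase defaults to off (air contributes <2 %, verified);
a mirrored two-phase mesh exists for configurations where it matters.

**Mesh.** Radial nodes are uniform within each of the three regions
[R_i,R4], [R4,R5], [R5,R_o] and snapped exactly onto the four radii; the
vertical spacing equals the ring-gap spacing, so the diamond's faces lie
exactly on grid diagonals and the probe boundary carries no staircase
error. The `resolution` parameter is the interval count across the ring
gap (rounded up to even). The channel depth is snapped to a whole number
of vertical steps; the default 5 mm depth is not a printed value but keeps
the bottom ≥3 gap-widths away (bottom effects <1 %). Non-uniform 3-point
stencils appear only at the two junction columns below the probe.

**Corner treatment.** The diamond's submerged vertex is a 270° re-entrant
corner where the field behaves as ρ^{2/3}; untreated, it pollutes drag
functionals at O(h^{4/3}) (observed error ratio ≈ 2.5 per mesh halving
instead of 4). The solver therefore subtracts the leading wedge mode
c·ρ^{2/3}sin(2φ/3): c is estimated by projecting the first solve onto the
mode on a sampling ring of radius half the diamond half-diagonal, and a
second solve (same LU factorisation) uses the analytic operator action on
the mode. On two-phase meshes the mode's branch cut would cross the
mirrored domain, so the subtraction is restricted to single-phase meshes.

**Drag functionals.**

* K_i = η_s*·2π[R4³w′(R4⁻) − R5³w′(R5⁺)] with w = u/r on the interface row
  and second-order one-sided stencils on the interface side of each contact
  line.
* K_b is obtained from an exact angular-momentum identity: the total drag
  equals the torque transmitted across a fixed contour enclosing the probe
  (bulk shear on two mid-gap cylinders and a mid-depth plane, plus the
  interfacial membrane stress where the contour crosses the interface)
  minus iω times the enclosed fluid angular momentum; K_b = K_total − K_i.
  Direct traction quadrature on the probe surface is kept as a diagnostic
  (`wetted_surface_torque`, consistent within a few percent) but is not
  used, because the corner-adjacent tractions converge slowly.

With these two measures both K_i and K_b show Richardson error ratios of
3.8–4.2 per halving in the interface-dominated regime (|Bo| ≳ 10³,
including complex Bo). At low Bo (≲10) the contact lines develop their own
ρ^{2/3} wedge modes (free-surface/Dirichlet junction) and the observed
order of K_b degrades toward O(h^{4/3}); this regime is far below the
instrument's sensitivity floor and is not treated specially.

**Linear algebra.** One sparse LU factorisation (SuperLU) per (Bo, ω)
solve, reused for the corner-corrected right-hand side; solutions are
cached per (geometry, phases, resolution, Bo, ω) so sweeps and fixed-point
iterations stay fast. Default resolution 16 (≈11k unknowns, ~0.1 s per
solve); the round-trip error of forward+inverse at this resolution is
≲1e-4 relative, far below measurement noise.

## 4. Inversion (FFBDA)

Given a measured AR, the interfacial torque required by the equation of
motion is iωK_i = AR + Iω² − iωK_b, and since K_i = Bo·ηa·J(Bo) with J the
contact-line stress functional only weakly dependent on Bo, the fixed point

    Bo_{k+1} = (AR + Iω² − iω K_b(Bo_k)) / (iω ηa J(Bo_k))

converges in 3–20 iterations over |Bo| from 0 to 1e6 (each iteration is
one flow solve). The seed inverts the interface-dominated closed form
AR ≈ −Iω² + g1G*. Convergence: relative Bo update ≤ 1e-6, with an
absolute floor (|Bo| < 1e-6 is treated as numerically clean, as for a bare
interface). States with |G*| below Iω²/g1 are flagged `inertia_limited`;
G″ < 0 beyond 3σ of the propagated measurement noise is flagged as
unphysical. Measurement uncertainties propagate to the moduli through
|dG*/dAR| = 1/|J|.

## 5. Signal processing

Records carry four channels: angle (600 V/rad), torque through two
amplifier gains (defaults 1e4 and 1e6 V/(N·m) — placeholders, the real
gains are instrument settings), and a trigger. Segments are cut at trigger
rising edges; the leading 20 % of each segment (configurable) is discarded
as transient and the longest integer-period suffix is kept, so the DFT bin
at the drive frequency is leakage-free (exact for a pure tone). The
dual-gain merge takes the high-gain channel unless its raw peak exceeds
95 % of the ADC range. Noise floors are estimated from the periodogram
with DC, the fundamental and its first three harmonics (±1 guard bin)
excluded; for white noise of per-sample variance σ² this gives
σ_amp = σ√(2/N) and σ_phase = σ_amp/A, verified against Monte-Carlo spread
within 20 % across SNR 3–1000. Higher harmonics are available as
diagnostics but unused by the inversion.

## 6. Synthetic instrument

The generator realises the second-order probe dynamics: for each requested
frequency it evaluates the full forward model AR(ω; G*, geometry, I) and
emits θ(t) = θ0 cos ωt, T(t) = |AR|θ0 cos(ωt + arg AR), scaled by the
channel gains, with white Gaussian noise per channel and 16-bit
quantisation over ±10 V. θ0 is set exactly from the target average strain
(default 3 %): strain control is idealised rather than emulating the
rheometer's proprietary feedback loop, which is irrelevant to validating
the analysis chain. Each block carries a trigger edge and a 3-period
lead-in that the transient discard removes. Records are bit-identical
under a fixed seed.

What the generator does *not* emulate: motor torque ripple, bearing drift,
1/f noise, trough vibration, meniscus dynamics, nonlinear (large-strain)
response. Passing end-to-end tests therefore demonstrates correctness of
the analysis chain under the stated noise model, not robustness to every
instrumental artefact.

## 7. Reflectometry

Specular reflectivity is computed by the Abeles transfer-matrix method
with Nevot–Croce roughness factors; SLDs are in the conventional 1e-6 Å⁻²
units. Resolution smearing is a Gaussian of constant relative FWHM
dQ/Q = dλ/λ = 7 % (time-of-flight dominated; angular divergence is not
folded in separately), applied by 17-point Gauss–Legendre quadrature over
±3.5σ and validated against direct numerical quadrature to <0.1 %.

The monolayer model is molecular: tails (V_AC = 759 Å³, SLD 8.08 for
chain-deuterated lipid) form a solvent-free layer of thickness
d_AC = V_AC/A_mol; heads (V_head = 344 Å³, SLD 1.74, d_head = 9 Å) share
the same A_mol and carry solvent fraction 1 − V_head/(A_mol·d_head).
A single capillary-wave roughness σ applies to all three interfaces
(per-interface override available). Across isotopic contrasts (D₂O,
air-contrast-matched water with SLD 0) the structural parameters are
shared; only subphase SLD and background differ. Co-refinement minimises
the dR-weighted squared residuals over all curves with bounded least
squares and a 3-start multi-start on A_mol (guarding against fringe
aliasing); by default A_mol and the non-contrast-matched subphase SLDs
float while literature volumes, σ and backgrounds stay fixed.
Uncertainties come from the local quadratic (Jᵀ J) approximation.

The synthetic generator uses a 120-point logarithmic Qz grid over
0.01–0.35 Å⁻¹ (a typical time-of-flight span) with 5 % relative Gaussian
noise. Two-contrast co-refinement recovers A_mol within 1 % under these
conditions. The ACMW composition solves x·SLD_D2O + (1−x)·SLD_H2O = 0,
giving 8.09 % D₂O by volume; a mass-fraction conversion is provided
separately since published recipes do not always state the convention.

## 8. Problem sizes and runtimes

Defaults were chosen so a full validation pass is desk-scale: flow meshes
at resolution 8–32 (3k–45k unknowns), refinement studies to resolution 32,
the recovery study over 4 frequencies × 3 loss moduli with one record per
condition (~10 oscillation periods at 100 S/s), and 120-point two-contrast
reflectivity fits. The complete test suite runs in a few minutes on one
CPU.

## 9. Known limitations

* The channel's true "double-step" bottom profile is approximated by a
  flat-bottom annulus; wall-step meniscus pinning details are out of scope.
* Marangoni stresses, meniscus curvature, contact-angle dynamics and
  finite-Reynolds advection are outside the Boussinesq–Scriven single-
  component model.
* Only the fundamental harmonic is inverted; nonlinear (LAOS) analysis is
  out of scope.
* The two-phase (meshed upper fluid) path skips the vertex-mode
  subtraction and uses side-wall closure above the interface; it is
  adequate for air but approximate for viscous upper phases.
* Low-Bo (≲10) drag convergence order is reduced (Section 3); moduli in
  that regime sit below the inertia floor anyway.
* Measured DPPC moduli and their pressure dependence require beamline
  data and are not reproduced here; the package validates the machinery on
  synthetic ground truth.
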