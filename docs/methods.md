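# Methods

## Acoustic model and solver

Propagation is linear acoustics in a heterogeneous absorbing medium, written
as three coupled first-order equations: mass conservation
(∂ρ/∂t = −ρ₀∇·u − u·∇ρ₀), momentum (∂u/∂t = −∇p/ρ₀), and an equation of
state p = c₀²(ρ + heterogeneity and absorption corrections). Power-law
absorption α(f) = α₀ f^γ is modeled with two fractional-Laplacian terms in
the equation of state — one producing the absorption, one the dispersion
that causality requires — applied as multiplicative k-space corrections each
step. α₀ is accepted in the conventional dB·MHz⁻ᵞ·cm⁻¹ and converted to
Np·(rad/s)⁻ᵞ·m⁻¹ internally (factor 100·(10⁻⁶/2π)^γ·ln10/20). The operator
is defined for 1 < γ < 3; construction rejects exponents outside that range
wherever absorption is non-zero.

The solver is a first-order staggered k-space pseudospectral scheme:
spectral derivatives with half-voxel staggering shifts e^(±ik·Δx/2) and the
temporal correction factor κ = sinc(c_ref·k·Δt/2), with c_ref the maximum
sound speed. In a homogeneous medium at c_ref the discrete dispersion
relation is exact for any CFL ≤ 1; heterogeneous regions with c < c_ref
carry a residual dispersion error that scales with Δt² (measured: a few
degrees of phase over tens of wavelengths at CFL 0.3, shrinking
quadratically at smaller CFL — the convergence test exploits exactly this).
Heterogeneous density enters through the staggered ρ₀ in the momentum update
and the split-density formulation of the mass equation; this realizes the
d·∇ρ₀ heterogeneity term of the equation of state through the equivalent
density-gradient correction rather than through an explicit particle-
displacement variable. The mass source is injected additively into the split
densities (so superposition over sources holds exactly, which the multi-
target recording relies on), sampled at t − Δt/2 by trapezoidal averaging so
the drive phase matches the pressure time base; the measured free-field
phase error at λ/10 sampling is ≈ 0.6°.

The time step is Δt = CFL·Δx/c_max (CFL 0.3 by default), then snapped down so
the drive period is an exact integer number of steps; steady-state phase and
amplitude are extracted by quadrature demodulation over a whole number of
trailing periods (≥ 5 enforced), which makes DC and all harmonics exactly
orthogonal to the kernels. The first 60% of a trace is discarded by default;
the recording routines extend this to cover the worst-case transit time.

### Absorbing boundary

A split-field PML occupies the outermost 10 voxels (polynomial grading of
order 4, profile scaled for a nominal 10⁻⁴ reflection). Discretization
limits the achieved reflection to ≈ −30 dB at 10 voxels and ≈ −42 dB at 20;
the default stays at 10 (adequate for the refocusing work, where fields are
evaluated far from the boundary), and the solver exposes `pml_width` for
calculations that need a cleaner boundary — the translation-invariance and
convergence tests use 20. PML reflections are the noise floor for several
invariants; reciprocity is immune (symmetric geometry) and holds to ~10⁻¹³°.

### Validity limits

The equation-of-state absorption uses the lossless substitution
∂ρ/∂t ≈ −ρ₀∇·u, accurate to first order in α; the measured attenuation
error grows quadratically with α₀ (0.8% at 2 dB·MHz⁻¹·⁵·cm⁻¹ over ~1.5 cm,
~3% at 5). Strongly absorbing bone is therefore quantitatively approximate
in amplitude; phases, which drive the lens design, are much less affected.
Shear waves, mode conversion, and nonlinearity are out of scope.

## Synthetic aberrator

Real skull data being out of scope, the aberrator is an ellipsoidal bone
shell restricted to the half facing the transducer — a cranial cap, like the
excised dorsal half-skull used in ex vivo beam mapping. A uniform-thickness
cap is mostly a weak lens, so the generator modulates the wall thickness
azimuthally, t(θ) = t̄ + Σ aₘ·cos(mθ + φₘ): the m = 1 (wedge) term steers an
uncompensated beam off target, higher terms defocus and spread it. All terms
are smooth (refractive) aberrations, the regime in which a phase-only
conjugate lens over a uniform-amplitude aperture can fully correct the
beam; fine-scale screens (lobe size approaching λ) scatter into speckle
that phase-only re-emission cannot remove, which is a physical limit of the
method, not of the implementation.

Two standard configurations are provided (`demo_config`):

- **moderate** — t̄ = 2.1 mm, harmonics (1, 0.9 mm), (3, 0.7 mm); used for
  the single- and dual-focus demonstrations and the seeded localization
  runs. Conjugation recovers diffraction-limited foci (deviation well within
  the FWHM).
- **strong** — t̄ = 2.6 mm, harmonics (1, 0.9 mm), (4, 1.0 mm), (7, 0.6 mm);
  a deliberately aberrating screen for quantifying the correction gain.
  The uncompensated Fresnel focus is displaced ~1.5 mm and loses more than
  half its on-target intensity; the conjugate lens still lands on target.

The cap must shadow the whole emitting aperture — any clear water path
around it lets an uncompensated beam focus unperturbed — so the recording
plane carries an explicit finite `aperture` confined to the cap's shadow.
Default material values (overridable everywhere): water ρ = 1000 kg/m³,
c = 1482 m/s, α₀ = 0.0022 dB·MHz⁻²·cm⁻¹ (γ = 2); skull bone ρ = 1900,
c = 2800, α₀ = 8 dB·MHz⁻¹·¹·cm⁻¹ (γ = 1.1) — commonly used transcranial-
simulation values. Mesh import assumes millimeter STL units (printer
convention) unless told otherwise; inside/outside is a vertical ray-parity
test at voxel centers with a tiny deterministic lateral nudge of the ray
origin to break exact edge alignments.

## Holography

Recording drives all targets simultaneously as monochromatic sources with
zero relative phase and the given amplitude weights (solver linearity makes
this exactly the coherent sum of per-target recordings — verified to
~10⁻¹³ degrees). Fewer than 20 drive cycles is rejected: the steady state is
not clean below that. Conjugation negates and rewraps the phase to (−π, π]
with −π ↦ +π. Re-emission is phase-only with uniform amplitude by default
(a passive thickness-only lens over a uniform planar transducer);
amplitude-weighted re-emission is available as an option.

Phase convention: a pixel's phase is the initial phase of its drive
sin(ωt + φ). A focusing (Fresnel) map is therefore
φ(x, y) = +k(√(z² + r²) − z): farther pixels lead. The recorded-and-
conjugated map in free water matches this analytic reference to < 1° RMS.

Focal fields are demodulated over the trailing 8 drive periods across the
whole grid during the run (no full time-series storage). The evaluation
`region` argument zeroes the field outside a requested volume; the pipeline
default emulates a hydrophone raster referenced to the targets (target
bounding box padded by 2 wavelengths per axis, clipped to the skull cavity),
so energy piled on the bone surface itself does not enter focal metrics.

## Lens synthesis

Thickness follows the thin-lens inversion T = T₀ − wrap(Δφ)/(k_B − k_A),
with the wrap chosen so T ∈ (T₀ − 2π/|k_B − k_A|, T₀]; designs whose full
2π span would violate the minimum printable thickness are rejected.
`LensMaterials.with_full_wrap` picks the thinnest T₀ giving full 2π
coverage, rounded up to 0.05 mm (for the resin/PDMS pair at 2 MHz the 2π
span is 0.91 mm, consistent with millimeter-class lenses above 1 MHz).
Transmission is modeled as a pure 1D phase delay; internal reflections are
neglected in design (the resin/PDMS intensity reflection coefficient 0.22
is reported as a diagnostic) — the 1D consistency test against the wave
solver uses a mild-contrast pair precisely so multiple-reflection phase
(~r² radians at worst) stays below the 3° tolerance.

Phase quantization rounds to the printer's phase unit (2π/10 by default,
ties to the lower level); in free water it costs ~3% of focal |p|².
STL export writes a base-plate slab plus one closed box per pixel column in
millimeters — the printer-conventional overlapping-solids construction,
whose shells are individually closed so the mesh is watertight by
construction, its volume is exactly area·base + pitch²·ΣT, and re-sampling
the mesh by vertical ray casting reproduces T to well under 1 µm. The
default pixel pitch honors the ~0.01 mm² printable-area floor.

## CMUT lumped model

The cell is a clamped circular silicon plate (defaults E = 150 GPa,
ν = 0.27, ρ = 2330 kg/m³, overridable) over a vacuum gap. Fundamental
resonance f = (10.21/2πa²)·√(D/ρh); the one-degree-of-freedom reduction
uses the Rayleigh-quotient modal mass m_eff = ρhπa²/5 of the mode shape
(1 − (r/a)²)² and k_eff = ω₀²·m_eff. Electrostatics is parallel-plate with
the vacuum-equivalent gap g_eff = g + t_i/ε_r and electrode area equal to
the cell area. Spring softening is evaluated at the *deflected* static
equilibrium (k·x(g−x)² = ε₀AV²/2 solved on the stable branch x ≤ g/3), with
k_e = ε₀AV²/(g_eff − x)³ — in this form the softened frequency is strictly
decreasing and reaches zero exactly at the static pull-in voltage
V_pi = √(8k_eff·g_eff³/27ε₀A), so the dynamic and static instability
criteria coincide by construction. A fixed-gap softening formula would put
the frequency zero at √(27/8)·V_pi instead; the deflection-consistent model
is the standard one. For the 18 µm/1 µm/200 nm reference geometry the plate
resonance evaluates to 12.1 MHz in air and V_pi ≈ 33 V (tens of volts, as
observed pull-in behavior requires); the lumped plate model carries no
fitted corrections, so its absolute in-air frequency should be read as a
design-scaling tool rather than a calibrated prediction.

The electrical side is C₀ in parallel with a series mechanical branch
(R_m, L_m, C_m), behind series parasitics R_s and C_s; C_s = 0 denotes an
absent (shorted) series capacitor, the case measured fits typically give.
Fitting is least squares on stacked real/imaginary parts weighted by 1/|Z|,
parameters in log space (positivity), automatic initialization from the
capacitive baseline and the resonance/antiresonance landmarks, with
perturbed restarts. Noiseless synthetic spectra are recovered to ~10⁻¹¹
relative; 1% multiplicative complex noise leaves C₀, R_m, L_m, C_m within
~1%. Impulse bandwidth uses the −6 dB convention (switchable to −3 dB) on
the zero-padded magnitude spectrum with interpolated band edges.

## Behavior analytics

Speed is total step length over elapsed time and distance the plain step-sum
(so speed·time ≡ distance exactly); no smoothing is applied before either.
Occupancy gives every arena pixel, each frame, the Gaussian weight
exp(−(Δx² + Δy²)/2σ²) with σ = 1 cm, summed over frames; a single frame then
integrates to ≈ 2πσ²/pixel-area. The default pixel pitch is 0.5 cm — fine
enough that the discrete Gaussian sum matches the integral to well under 1%,
coarse enough that a 30 × 30 cm arena stays a 60 × 60 map. The synthetic
open-field generator is a bounded correlated random walk (Gaussian step
scale 0.5 cm/frame, persistence 0.6, reflective walls, seeded); it emulates
the spatial statistics of exploratory locomotion but not posture, rearing,
or wall-following bias, so passing behavior tests validate the metric
implementations, not any biological claim. Arena size is always an input
(open fields differ between rigs).

## Problem sizes

The verification chain runs in 2D: recording/refocus demonstrations on a
256² grid at 1 MHz (λ/8 sampling, ~47 mm square), seeded localization runs
on 192², free-water cases on 160², solver oracles in 1D at λ/10. These sizes
put every published check within a few minutes on a single core while
keeping ≥ 8 points per wavelength everywhere; 3D runs use the same code
paths (the solver is dimension-generic) at correspondingly larger cost.

## Known limitations

- Phase-only correction cannot undo amplitude scrambling: diffusive
  (fine-scale) aberrators leave speckle sidelobes; the provided aberrators
  are refractive by design.
- Absorption amplitude is first-order accurate in α₀ (see above).
- The PML underperforms its nominal target at 10 voxels; widen it when an
  invariant depends on boundary cleanliness.
- The lumped CMUT model ignores cell-to-cell crosstalk, fluid loading
  (in-water resonance is far below the in-air value), and electrode
  coverage fractions.
- Trajectories are consumed as tracked coordinates; pose estimation and
  group statistics live outside the package.
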