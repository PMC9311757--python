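# Methods

## Scope and model

`porinflux` covers the post-simulation half of a porin-permeation study.
The physical picture: a small molecule (an antibiotic or β-lactamase
inhibitor) diffuses through a size-constricted β-barrel channel along an
axis z (z = 0 at the constriction, increasing from the extracellular *cis*
side to the periplasmic *trans* side).  Sampling — plain MD of the solvated
molecule for conformer ensembles, biased dynamics for free-energy surfaces —
is outside the package; `porinflux` takes those outputs (or seeded synthetic
stand-ins) and computes descriptors, 1D profiles and transport observables.

## Descriptors

A conformer's projection area along a direction n̂ is the area of the union
of its atoms' van-der-Waals disks after projecting the centers on the plane
normal to n̂.  The union area is computed from shapely polygonal buffers
with `quad_segs=64` (relative circle-area deficit ≈ 1×10⁻⁴, recorded in the
output metadata; tolerance budget 0.2%).  The minimal projection area (MPA)
is minimized over directions with a Fibonacci hemisphere scan (default 512
directions, antipodes identified, coarse `quad_segs=16` areas) followed by
Nelder–Mead refinement on (θ, φ) at full resolution; ties go to the first
direction found.  Validation: the search agrees with a 10⁴-direction dense
grid within 1% on random clusters, and with analytic limits (single atom,
long rod) — see the test suite and `scripts/acceptance.py`.

Dipoles are μ = Σ qᵢ(rᵢ − r₀) with 1 e·Å = 4.8032 D.  For net-charged
species μ depends on r₀; the default convention is the center of mass and
is recorded in the output metadata (the transversal component additionally
depends on the MPA direction).  The transversal dipole is |μ − (μ·n̂)n̂|.

Distribution summaries use fixed-width histograms (0.1 Å for Rmin, matching
the precision at which such radii are usually reported; ~1 D for dipoles).
Modes are bin centers of local maxima exceeding both neighbors by ≥1% of the
peak density, so genuinely bimodal ensembles report two modes.  The overlap
coefficient between two distributions is ∫ min(pdf_A, pdf_B) dx after
re-binning both piecewise-constant densities on a common fine grid.

The pore-size profile inflates each atom by the probe radius (default
1.4 Å, a water-sized probe) per z-slab and measures the accessible area of
the connected component containing the channel axis (x = y = 0), clipped to
an outer box; the slice radius is sqrt(area/π).  Taking the axis-connected
component (rather than all accessible area in the box) is what makes the
number a lumen radius; slices with no atoms are flagged open rather than
treated as pore.

## 2D → 1D marginalization

F₁D(z) = −kT ln [Σ_cv1 exp(−F(cv1, z)/kT) Δcv1] with trapezoid weights,
evaluated with log-sum-exp.  Masked (non-finite) cells are dropped with
renormalization of the CV1 measure; a column >50% masked is warned about,
an entirely masked column is an error.  k_B = 0.0019872 kcal/mol/K, so
kT = 0.59616 kcal/mol at 300 K.

Bulk referencing subtracts the joint mean of the two bulk windows (default:
outer 20% of the z range at each end); a plateau asymmetry beyond
0.5 kcal/mol is a warning, not an error, since real surfaces are never
perfectly converged.  The channel interval [z_cis, z_trans] is detected as
the outermost points where |F| exceeds 0.5 kT moving inward from the bulk
windows (overridable).  Features: wells are interior local minima with
prominence above `level_tol`; the barrier is the global maximum inside the
channel; on 2D surfaces saddles are reported by the 4-neighbor criterion.

The exact Jensen bounds min_cv1 F − kT ln W ≤ F₁D_raw ≤ max_cv1 F − kT ln W
(W the CV1 integration width) and the T→0 pointwise convergence of the
marginal to min_cv1 F are enforced as property tests.

## Transport

Internal units are Å, ns, kcal/mol; reported rates are s⁻¹ and
concentrations M.  Conversion constants are module-level and single-sourced
(`constants.py`): γ = 6.0221×10⁻⁴ molecules/Å³ per M, 1 nm²/ns = 100 Å²/ns.

* **Permeability**: P = D σ_ref γ / ∫ exp(βF) dz over the channel interval,
  computed in log-space (huge barriers underflow to P = 0 instead of
  overflowing).  σ_ref converts a 3D concentration into a 1D boundary
  density; it defaults to π·17² Ų, the cross-section of a 17 Å reference
  cylinder around the pore axis, and is an explicit logged parameter
  because this geometric conversion is a modeling choice, not a measured
  quantity.
* **Smoluchowski oracle**: the stationary equation
  d/dz[D e^{−βF} d/dz(e^{βF}ρ)] = 0 discretized with interface-averaged
  mobilities and solved as a tridiagonal system; boundary values are
  equilibrated with the bulk reservoirs (u = e^{βF}ρ = cγσ_ref), so equal
  concentrations give exactly zero flux.  Agreement with the Kramers
  integral within 1% is an acceptance property.
* **MFPT**: double-quadrature solution of the adjoint equation with two
  absorbing boundaries (or one reflecting end), on a 4001-point grid with
  max-subtracted exponentials.  Cross-checked against an exact discrete
  master-equation solve and, for the full rate construction, against a
  seeded 10⁵-trajectory Gillespie simulation on the discretized profile
  (hop rates k(i→i±1) = (D/Δz²)·exp(−βΔF/2), numba-compiled).
* **Rates**: the occupied state is the deepest channel well (wells within
  0.5 kT: the widest wins with a warning; no well: the deepest interior
  point, flagged).  koff_{cis,trans} = φ_{cis,trans}/τ_escape with
  φ_trans = ∫_{cis}^{well} e^{βF} / ∫_{cis}^{trans} e^{βF}.  kon_cis is
  fixed by linear-regime consistency kon_cis = P(koff_cis+koff_trans)/
  koff_trans (mirrored for kon_trans), which makes the Markov current's
  initial slope equal P by construction — a deliberate choice, recorded in
  output metadata, since the entry rate is not independently constrained
  by a 1D profile.
* **Markov current**: I = (kon_cis c_cis koff_trans − kon_trans c_trans
  koff_cis)/(kon_cis c_cis + kon_trans c_trans + koff_cis + koff_trans);
  saturates at Imax = koff_trans with K_half = (koff_cis+koff_trans)/kon_cis;
  dwell time τ_b = 1/(koff_trans + koff_cis).

D is position-independent (a single effective value, default 1 nm²/ns);
position-dependent diffusivity, multi-occupancy and voltage effects are out
of scope.

## Synthetic data

The generator emulates the two expensive inputs with known ground truth.
Conformers: rigid rods, rigid seeded clusters, or flexible chains whose
bond directions random-walk with a stated rms angle per frame; zero
flexibility yields bitwise-identical frames, hence zero descriptor
variance.  Surfaces: a Gaussian barrier in z (default σ = 3 Å), Gaussian
wells, an optional harmonic CV1 confinement, and seeded band-limited cosine
roughness, all multiplied by a smoothstep mask that is exactly zero over a
bulk plateau (default 5 Å) at both z ends.  In the separable case the
analytic 1D marginal ships with the surface (the CV1 term cancels in
referencing), which is what makes the ≤0.05 kcal/mol recovery check exact.

What the generator does **not** emulate: real force-field energetics,
metadynamics convergence error (the roughness amplitude is a smooth
stand-in, not a statistical model of it), protein flexibility, or
position-dependent diffusion.  Passing tests therefore demonstrate the
correctness of the analysis chain, not the accuracy of any particular
simulation input.

Default study conditions used by the demo pipeline and the acceptance
script: three profile archetypes A/B/C with barriers 4.5/3.5/2.5 kcal/mol
and a single 6 kcal/mol affinity well at z = 5 Å only in C — a
high-affinity binder archetype (deep enough that its half-saturation falls
orders of magnitude below the barrier-only profiles, as observed for
strong channel binders); D = 1 nm²/ns; T = 300 K; σ_ref = π·17² Ų;
channel span ±25 Å with 501 grid points.  The stochastic rate validation
uses 161 lattice sites and 10⁵ trajectories, which puts the standard error
of the mean escape time near 0.3%, comfortably inside the 2% check.

## Numerical notes and limitations

* Quadratures are trapezoidal; the MFPT grid (4001 points) and the
  Smoluchowski grid (2000 points) keep discretization error well below the
  1–2% oracle tolerances for barriers up to ~8 kcal/mol.
* Channel-interval detection on nearly flat profiles falls back to the
  whole interior; rate construction on a barrier-only profile places the
  occupied state at the deepest interior point and flags it — dwell times
  for such profiles are diffusive, not activated, and should be read
  accordingly.
* Absolute currents inherit the uncertainty of D and σ_ref linearly;
  orderings between profiles and saturation trends are insensitive to both.
* The FES text dialect is a simple whitespace grid ('#' headers, rows
  `cv1 z F` with cv1 fastest); a permissive variant accepts any declared
  column order.  XYZ/PDB conformer I/O goes through MDAnalysis; XYZ stores
  coordinates at 10⁻⁴ Å precision, which bounds round-trip fidelity.
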