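# Methods

This note records the mathematical and numerical choices behind `lnflow`:
what is solved, how, at which resolutions, and what the verification suite
does and does not establish.

## Unit system and parameters

All quantities are expressed in mm / s / mg / mPa, so that
1 mg mm⁻¹ s⁻² = 1 mPa and the published physiological values enter without
conversion.  The defaults (see `lnflow.params`) are: viscosity
μ = 1 mg mm⁻¹ s⁻¹, porosity φ = 0.75 with effective-viscosity ratio
μ* = 1/φ, interstitial permeability K̂_m = 3.84×10⁻⁹ mm², microscale
spacing d = 0.02 mm and cylinder radius r_c = 1.7×10⁻³ mm (r̄ = 0.085),
vascular conductivity K_v d²/μ = 1.1×10⁻⁶ mm³ s/mg, Staverman coefficient
σ = 0.9, oncotic difference Δπ = 1.02×10⁶ mPa, wall conductivity
L_p = 5.475×10⁻¹¹ mm s⁻¹ mPa⁻¹, vessel surface S_tot = 13.4 mm² and volume
|Ω_v^tot| = 0.0322 mm³, mean blood pressure p̄_v = 1.06×10⁶ mPa, inlet
speed v_in = 0.22 mm/s, outlet pressure p_out = 6.18×10⁵ mPa.  Several of
these are published as ranges (σ ∈ [0.88, 0.9], L_p, Δπ, p̄_v); the
defaults are the documented working values, and the range exploration is a
postprocessing sweep, not a parameter type.  σ = 0.9 is the value for which
the lumped inversion estimate p̄_m + σΔπ reproduces the known inversion
threshold (see below).

### The |Ω_m^tot| convention

The Starling sink coefficient is C_m = L_p S_tot/|Ω_m^tot|.  Because the
homogenized equations live on the whole LC, integrating the sink over the
LC yields a total wall conductance L_p S_tot · V_LC/|Ω_m^tot|.  We take
|Ω_m^tot| = V_LC (config `exchange.interstitial_volume = "lc_total"`), so
the lumped conductance is exactly L_p S_tot; the alternative
`"lc_minus_vascular"` (|Ω_m^tot| = V_LC − |Ω_v^tot|) overshoots it by
V_LC/V_m ≈ 1.075 and is kept as a config switch.  With the default the
sphere flux table is reproduced to ~3%.

## Microscale cell problems

The unit cell is the unit cube with a tricylinder inclusion (three
orthogonal cylinders of radius r̄ through the centre).  Its volume follows
inclusion–exclusion with Steinmetz intersection volumes,
V = 3πr̄² − 16r̄³ + 8(2−√2)r̄³ ≈ 0.0611 at r̄ = 0.085.

**Symmetry reduction.**  Both cell problems are periodic on the cube
faces.  The geometry has full cubic symmetry and the loads are coordinate
directions, so the periodic solution is even or odd, component by
component, across every face and mid-plane.  We therefore solve on the
octant [0, ½]³ with reflection conditions instead of periodic DOF pairing:

* Poisson corrector for direction 1: g = 0 on the planes y₁ ∈ {0, ½}
  (odd), natural elsewhere (even).  This also fixes the zero-mean gauge:
  the full-cell mean of an odd function vanishes identically.
* Brinkman column 1: w₂ = w₃ = 0 on y₁-planes, w₂ = 0 on y₂-planes,
  w₃ = 0 on y₃-planes, all other components natural.  The cell pressure
  g_m is odd across the y₁-planes, so its full-cell mean is exactly zero.

This is mathematically identical to the periodic formulation for these
loads; solving permuted directions on the same (unsymmetrically split)
mesh provides a numerical isotropy check (diagonal entries agree to
<0.5%, off-diagonal full-cell averages vanish by construction).

**Meshing.**  Graded tensor-product grids on the octant are split into six
Kuhn tetrahedra per hexahedron (conforming on stretched grids).  Vertices
within 0.35·h of the tricylinder surface are projected onto it (moves
capped at 0.45·h to protect element quality), then tetrahedra are assigned
to Ω_m/Ω_v by the sign of the signed distance at their centroid.  The two
phases use separately graded grids: the tiny vascular phase affords
transverse spacings of 0.016/0.008/0.0055 (coarse/medium/fine) near the
cylinders, the interstitial phase 0.030/0.020/0.015.  With straight P2
tetrahedra the inscribed-surface geometric error at the medium spacing is
~0.1–0.2%, far below the 2% at which the averaged coefficients are
compared, so isoparametric curved elements were not needed.

**Poisson corrector (Ω_v).**  Scalar P2 Laplace with Neumann data −n₁ on
Γ (facet normals; consistent with the divergence theorem on the polyhedral
surface).  Direct sparse solve.  The physical picture: the two cylinder
families transverse to the load are dead ends (corrector gradient −1),
the aligned family conducts with a small junction enhancement, giving
⟨G_v⟩ ≈ −(1 − |aligned|/|Ω_v|) ≈ −0.60.  Computed values: −0.6103
(coarse), −0.6043 (medium), converging toward the published −0.60060.

**Brinkman cell problem (Ω_m).**  P2³/P1 mixed elements for (w, g_m) with
K⁻¹w − μ*Δw + ∇g_m = e₁ and ∇·w = 0.  On Γ, no-penetration w·n = 0 is
imposed by a normal penalty (coefficient 30/K, leaving a penetration
residual ~10⁻³ of the velocity scale K ≈ 10⁻⁵) and the BJS slip enters as
a natural Robin term with coefficient μ*α/√K (α = 1).  Seam edges where
two cylinders meet use the facet normal of each integration facet.  The
Brinkman boundary layer has width √(μ*K) ≈ 3.6×10⁻³, thinner than the
wall-adjacent elements; the unresolved layer perturbs ⟨W_m⟩ by an
estimated ≲0.5% (the layer's flux deficit is O(√K)·surface), accepted
within the 2% comparison band.  Computed values: 9.056×10⁻⁶ (coarse),
9.080×10⁻⁶ (medium), converging toward the published 9.1163×10⁻⁶, with a
dilute-inclusion potential-flow estimate K(1 − 2f_transverse/|Ω_m|) ≈
9.14×10⁻⁶ as an independent sanity bound.

**Linear solver.**  The saddle system is solved by MINRES with a
block-diagonal preconditioner: Jacobi on the (mass-dominated) velocity
block and a factored Schur surrogate K·(P1 pressure Laplacian) — in the
Darcy-dominated regime A ≈ K⁻¹M, so the pressure Schur complement is
spectrally a scaled Laplacian.  Because the penalty rows dominate the
preconditioned residual norm, the loop restarts at machine-precision rtol
until the *true* relative residual reaches 10⁻⁸ or stagnates; the
functional ⟨W_m⟩ is converged to ~10⁻⁶ relative well before that.  The
effective conductivities are K̄_m = (d²/μ)⟨W_m⟩ and K̄_v = (d²/μ)K_v(1+⟨G_v⟩);
for macroscale runs the tabulated K̄_v = 4.12×10⁻⁷ (which differs by ~6%
from the formula value 4.39×10⁻⁷ — the published averaging convention for
the vascular tensor is not recoverable) is used by default, and both
values are always reported side by side, never silently reconciled.

## Macroscale geometry and mesh

The node is a body of revolution; all data are rotationally invariant, so
the 3D problem reduces exactly to the meridian (r, z) half-plane with the
axisymmetric measure r dr dz, with symmetry conditions (u_r = 0, zero
flux) on the axis.  The capsule is a sphere (R = 0.49) or oblate spheroid
(a = 0.5, b = 0.35); the LC boundary Γ_M is its inward normal offset by
h = 0.01 (well below the minimal curvature radius b²/a, so the offset is
smooth).  Flat circular apertures of radius R_LV = 0.04 mm truncate the
capsule at the poles — R_LV is chosen so the analytic inlet flow
π R_LV² v_in = 1.106×10⁻³ mm³/s matches the published analytic value
1.1×10⁻³ (the source geometry never states the vessel radius); there are
no vessel stubs, the capsule wall closes the shell up to the aperture rim,
and the rim vertex belongs to the no-slip wall.  The meridian aperture
segments are geometrically clustered toward the rim (ratio ½) so that the
no-slip rim removes <0.2% of the prescribed inlet flux.

The SCS shell is meshed with a structured quadrilateral-split grid
(3/4/5 element layers across h at coarse/medium/fine, 96/192/320 capsule
subdivisions); the LC interior with a Delaunay triangulation of graded
shrunken copies of its boundary curve, glued conformally to the shell
along Γ_M.  Mesh volumes match the closed-form revolved volumes to
<0.5% (coarse) / <0.01% (medium).

## Coupled solver

Monolithic assembly of [u (P2²), p_f (P1), p_m (P2), p_v (P2)] and one
sparse direct solve (~35k DOF at medium, <1 s).  The Stokes block uses
the symmetric-gradient (Cauchy stress) form, so prescribed-traction
conditions are natural: the outlet applies −p_out n with pinned
tangential velocity, and Γ_M carries the normal-stress load
+∫ p_m (v·n).  Normal-velocity continuity enters the interstitial Darcy
equation as −∫ (u·n) q.  The BJS tangential term is the Robin penalty
μ α_M/√(μ K̄_m) ∫(u·τ)(v·τ); α_M → ∞ (the default, following the
simplified tangential no-slip condition) is realised with α_M = 10⁶,
leaving a slip residual ~10⁻¹⁰ of the velocity scale, so one code path
serves both finite and infinite α_M.

The vascular pressure takes the Dirichlet value p̄_v on Γ_M: the vascular
compartment exchanges a nonzero net volume with the interstitium, so a
pure no-flux problem would be unsolvable; the Dirichlet datum lets that
volume leave through the vascular tree at its mean pressure.  Only the
interstitial phase exchanges across Γ_M.  This choice reproduces the
known flow-inversion thresholds (1.543×10⁶ vs 1.54×10⁶ mPa published at
p_out = 6.18×10⁵; 1.325×10⁶ vs 1.35×10⁶ at p_out = 4×10⁵) and is exposed
as a solver option.

The full discrete system is affine in (v_in, p_out, p̄_v, σΔπ); the
verification suite checks superposition to ~10⁻⁹ relative.  The
flow-inversion pressure is therefore obtained from two solves by a secant
step, with a bisection fallback (tolerance 10³ mPa) guarding non-affine
user configurations.

## Verification

* **Closed-form sphere oracle.**  For constant coefficients and uniform
  Dirichlet data in a sphere, the Starling bracket satisfies a modified
  Helmholtz equation ΔB = λ²B, λ² = C_m/K̄_m + C_v/K̄_v, with regular
  solution B = A sinh(λr)/r, and (K̄_m/C_m)p_m + (K̄_v/C_v)p_v is harmonic,
  hence constant — note the weights 1/C_γ; the unweighted combination is
  harmonic only if C_m = C_v.  The LC-only FEM solve matches the oracle to
  ~10⁻⁶ relative L² (gate: 1%), including the closed-form net exchange.
* **Manufactured axisymmetric Stokes solution** (annular channel,
  non-polynomial velocity and pressure, hand-derived body force):
  Taylor–Hood rates ≈3.0 (velocity) and ≈2.1 (pressure) observed.
* **Exact states.**  v_in = 0 with p̄_v = p_out + σΔπ is an exact rest
  state (B ≡ 0) and is reproduced to solver precision; the no-inclusion
  Brinkman cell recovers W = K·I to 10⁻⁹ relative; a single cylinder
  loaded along (transverse to) its axis gives G = 0 (G = −1 exactly).
* **Lumped balances.**  C_m V_m (p̄_m − p̄_v + σΔπ) tracks the FEM
  exchange flux to <10%, and p̄_m + σΔπ predicts the inversion root to 3%.

## Resolutions and runtime

Production ("medium") resolutions — 192 meridian subdivisions / 4 SCS
layers for the macro mesh, transverse cell spacings 0.008 (Ω_v) and 0.020
(Ω_m) — were chosen as the coarsest level at which the mesh-convergence
deltas of the reported quantities fall below 0.5% (coarse→medium:
⟨W_m⟩ 0.26%, ⟨G_v⟩ 1.0%, flux table <0.5%).  On one CPU: a coupled macro
solve runs in under a second, the Poisson cell problem in ~35 s, the
Brinkman cell problem in ~60 s; the full test suite takes ~3.5 min.

## Known limitations

* Steady state only: no pulsatile inlet, no lymphangion coupling, no
  storage terms; the SCS→LC and LC→blood fluxes are identical by
  construction.
* Rigid porous matrix (no poroelasticity); isotropic constant effective
  conductivities; no solute/oncotic transport (σΔπ is a fixed datum).
* The published spheroid run implies a smaller lumped wall conductance
  than the sphere runs; with the anatomical constants held fixed our
  spheroid outlet flow sits ~5% below the published value, at the edge of
  the comparison band.
* The axisymmetric reduction is exact for the model as posed, but excludes
  non-axisymmetric vessel placements or multiple afferent vessels.
* The cell-problem meshes are body-fitted only to first order (warped
  straight facets); the resulting geometric error is ~0.1–0.2% at medium
  resolution, which bounds how far the averaged coefficients can be
  refined without isoparametric elements.
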