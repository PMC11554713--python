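# lnflow — multiscale steady fluid flow through a lymph node

`lnflow` models the steady transport of lymph through a whole lymph node.
Lymph enters through the afferent vessel, spreads through the **subcapsular
sinus** (SCS) — a free-fluid channel ~10 µm thick under the capsule — and
either leaves through the efferent vessel or percolates into the porous
**lymphoid compartment** (LC), where part of it is drained into the blood
microcirculation across the capillary walls.  The balance between these two
routes regulates fluid homeostasis; its failure is implicated in
lymphœdema, and the wall shear stress on the SCS/LC interface matters for
cell adhesion and metastatic seeding.  The package is written for
researchers in computational biofluid mechanics who want a transparent,
scriptable implementation of this coupled multiscale model.

## Model

**Microscale.**  The LC interior is a periodic arrangement of fibroblastic
reticular cell (FRC) conduits (phase Ω_m) interwoven with vascularized
regions, idealized as a tricylinder of radius r̄ = r_c/d in a unit cell
(phase Ω_v).  Two homogenization cell problems give the effective hydraulic
conductivities:

* a Brinkman-type problem for the tensor **W**_m on Ω_m with a
  Beavers–Joseph–Saffman (BJS) slip on the interphase surface Γ, yielding
  K̄_m = (d²/μ)⟨W_m⟩;
* a Poisson-type problem for the corrector **g**_v on Ω_v with Neumann data
  −**n** on Γ, yielding K̄_v = (d²/μ)K_v(1 + ⟨G_v⟩), where
  G_v = ∂g_v,1/∂y₁.

**Macroscale.**  In an axisymmetric node (sphere R = 0.49 mm or oblate
spheroid a = 0.5, b = 0.35 mm; SCS thickness h = 0.01 mm):

* SCS: incompressible Stokes flow, μΔ**u**^f = ∇p^f, ∇·**u**^f = 0;
* LC: two exchange-coupled Darcy fields with a Starling-type transmural
  term,

      ∇·(−K̄_m ∇p_m) = −C_m B,   ∇·(−K̄_v ∇p_v) = +C_v B,
      B = p_m − p_v + σΔπ,       C_γ = L_p S_tot / |Ω_γ^tot|,

  where σ is the Staverman reflection coefficient and Δπ = π_v − π_m the
  oncotic pressure difference: even though blood pressure exceeds the
  interstitial pressure, the oncotic term keeps B > 0, so lymph drains
  *into* the blood;
* interface Γ_M: continuity of the normal velocity with the interstitial
  Darcy flux, normal-stress balance −(**T n**)·**n** = p_m, and the BJS
  tangential condition (the α_M → ∞ no-slip limit by default).

The discretization is Taylor–Hood (P2/P1) for Stokes, quadratic elements
for both Darcy pressures, assembled monolithically in the meridian plane
and solved with a sparse direct solver.  The 3D cell problems are solved
on a symmetry-reduced octant of the unit cell with P2 tetrahedra.

## Worked example

```bash
lnflow node-solve --out run        # sphere, Table defaults, medium mesh
cat run/fluxes.csv
```

prints (mm³/s):

```
Q_in,Q_out,Q_scs_to_lc,Q_lc_to_blood,residual
0.0011057507989603943,0.000755380850840553,0.0003503699703271932,0.0003503699849636179,-2.2207351897066824e-11
```

Reading: of the 1.106×10⁻³ mm³/s entering the node (π R_LV² v_in with
v_in = 0.22 mm/s), 0.76×10⁻³ leaves through the efferent vessel and
0.35×10⁻³ crosses into the LC and drains into the blood (wall conductivity
L_p = 5.475×10⁻¹¹ mm s⁻¹ mPa⁻¹); the mass-balance residual is at solver
precision, and the SCS→LC and LC→blood fluxes coincide because the steady
LC stores no fluid.  The same run writes `midline_velocity.csv` (peak SCS
speed ≈ 0.65 mm/s just downstream of the inlet) and `interface_shear.csv`
(peak wall shear ≈ 265 mPa near the inlet).

```bash
lnflow invert --p-out 618000 --out inv
# flow inversion at p_v_bar = 1.5431e+06 mPa
```

i.e. raising the mean blood pressure to ≈1.54×10⁶ mPa (≈11.6 mmHg)
reverses the direction of the transmural exchange.

Other commands: `lnflow cell-solve` (micro-cell problems and effective
conductivities), `lnflow mesh` (tagged meridian meshes, Gmsh MSH),
`lnflow sweep` (flux tables over L_p, p̄_v, Δπ, v_in), `lnflow verify`
(closed-form and manufactured-solution oracles).

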