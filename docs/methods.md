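# Methods

`cellnet` models a single endothelial cell (or a monolayer of such
cells) as a two-dimensional discrete network of elastic fibres, couples
it to an elastic substrate at the focal adhesions, and analyses the
resulting substrate deformation exactly the way a multistep
traction-force-microscopy (TFM) experiment would. This note documents
the model, the numerical choices, and what the synthetic data do and do
not represent.

## The cell model

A cell is a planar central-force network: nodes (fibre cross-links and
connection points) joined by bonds (fibre segments). Six components are
represented, all projected onto the plane of the cellular floor:

* **Cell membrane** — a convex polygon (convex hull of 6 uniform points
  in a 100 × 100 μm box), subdivided into ~2 μm segments. Polygons are
  resampled until their area falls in 5000–7500 μm², which keeps the
  automatic focal-adhesion count (below) inside its observed range.
* **Nucleus** — an ellipse placed inside the polygon (semi-axes sampled
  from 8–15 μm × 5–10 μm, uniform orientation), its boundary subdivided
  into 40 nuclear-membrane segments, treated as quasi-rigid through a
  1 μN pseudo-stiffness of the nuclear membrane and the 50 random
  nuclear-actin chords spanning it.
* **Actin cortex** — the Voronoi diagram of a Poisson-disc point set
  seeded in the polygon, clipped to the polygon; edges crossing the
  boundary are re-terminated at the nearest membrane point. The seeding
  radius (1.8 μm) is calibrated so the mean cortex bond length is
  ≈ 1.5 μm, the filament length from which the cortex bond stiffness is
  derived (43.7 nN/μm → 29.1 nN per filament).
* **Focal adhesions (FAs)** — a random subset of interior cortex nodes
  at a surface density of 0.04 FAs/μm² (count = round(0.04 · area),
  clipped to [200, 300]); candidates underneath the nucleus carry half
  weight, reflecting the sparser adhesion observed there.
* **Ventral stress fibres** — 35–40 single bonds between FA pairs at
  least 30 μm apart.
* **Perinuclear stress fibres** — 10–20 two-segment paths FA → nuclear
  membrane → FA, built from FA chords that pass within 5 μm of the
  nucleus without crossing it; the relay point is the nuclear-membrane
  point closest to the chord for which neither leg cuts the nucleus.

Monolayers are generated by Voronoi-partitioning a domain, shrinking
every cell polygon towards its centroid by δ (default 1 μm), running
the single-cell pipeline per polygon, and joining adjacent cells with
junction bonds between nearest membrane points. The junction law is a
configurable linear placeholder (100 nN); no validated constitutive law
for tight/adherens junctions exists in this framework, so monolayer
mechanics beyond generation is out of scope.

All randomness flows through a single seeded generator; identical
parameters reproduce networks bitwise.

## Bond law and parameters

Each bond follows a bilinear elastic law in the elastic stretch
λₑ = r/rₐ, with tensile modulus `K_t` and compressive modulus
`K_c = K_t/10` (in nN, force per unit strain) and zero force at the
activated rest length rₐ = a·r₀:

    F(r) = K_t⟨(r − rₐ)/rₐ⟩ − K_c⟨(rₐ − r)/rₐ⟩,   ⟨x⟩ = max(x, 0).

The activation a < 1 shortens the rest length multiplicatively and
models myosin contraction; the energy is defined with an rₐ prefactor,
E = ½ rₐ [K_t⟨(r−rₐ)/rₐ⟩² + K_c⟨(rₐ−r)/rₐ⟩²], so that dE/dr = F
exactly. (A strain-quadratic energy without this prefactor would have
force units and an r-derivative inconsistent with the force–stretch
law; the force law is taken as the physical contract.)

Default materials (K_t [nN], K_c [nN], a): cortex 29.1 / 2.91 / 0.95;
ventral SF 20.2 / 2.02 / 0.81; perinuclear SF 5.05 / 0.505 / 0.9;
nuclear actin 1000 / 100 / 1; cell membrane 0.1 / 0.01; nuclear
membrane 1000 / 100. The derived constants are computed, not merely
stored: cortex stiffness 43.7/1.5 = 29.1 nN (the printed convention for
referring the filament spring constant to the 1.5 μm length), cortex
activation 1 − (1−0.81)/4 = 0.95 (a quarter of the ventral shortening),
perinuclear stiffness 20.2/4 = 5.05 nN (out-of-plane inclination).

## Equilibrium solution

Displacement boundary conditions at the FAs define a boundary-value
problem solved by minimising total energy over the free nodes. These
networks are sub-isostatic (the Voronoi graph has mean coordination
~3), so Newton solvers on the full Hessian are unreliable far from
equilibrium; the solver therefore interleaves

1. limited-memory BFGS descent (robust far from equilibrium), and
2. a regularised Newton iteration on the residual force vector, using
   the analytic sparse tangent (material term (K/rₐ)nnᵀ plus geometric
   term (F/r)(I − nnᵀ) per bond), with a force-norm line search.

Convergence requires the 2-norm of the free-node force vector to fall
below 1 pN (1e-3 nN). Activation is ramped from 1 to its target in 5
equal steps, re-minimising at each (intermediate steps to a relaxed
tolerance), which stabilises the floppy-mode descent. Warm starts skip
the ramp and usually converge in a few Newton steps.

Because floppy directions carry (near-)zero force, the reachable force
norm saturates around 1e-4–1e-5 nN on full-size cells; identities that
hold exactly at a stationary point (e.g. the vanishing sum of
constrained-node reactions) are therefore verified to the solver
tolerance, not to machine precision.

## Substrate operator

The substrate (a 1000 × 1000 × 100 μm silicone block, neo-Hookean
C10 = 1.166 kPa, D1 = 1.2008 MPa⁻¹) is represented by the tangential
surface Green's function of an incompressible linear-elastic half space
(Cerruti kernel), with small-strain modulus E = 6·C10 ≈ 7 kPa. At the
strains considered (≤ ~10%) and with FA spacing (~5 μm) much smaller
than the layer thickness (100 μm), the linearised half-space response
is an accurate, purely algebraic stand-in for a finite-element block;
finite-thickness corrections are deliberately out of scope.

Each FA acts through a rigid elliptical patch (2 × 1 μm, ~30 sunflower
sample points). Patch self-compliance comes from rigid condensation of
the within-patch kernel with a uniform-traction disc regularisation of
the self-term; patch–patch coupling uses sample-averaged kernels for
near pairs and centre-to-centre kernels beyond four major axes. The
resulting compliance matrix is symmetric positive definite; its inverse
maps imposed rigid-patch displacements (relative to the far-field
equibiaxial motion u_aff = (√(1+ε_A) − 1)X) to patch forces. A
discretised circular patch reproduces the closed-form tangential
flat-punch stiffness 8Ga/(2 − ν) within ~9%, and reactions change by
~1.4% when the patch resolution is doubled.

Sign convention: both the cell-side force f_C and the substrate-side
force f_S are "the force required to hold the constraint at its
displacement", so force balance at an FA reads R = f_S + f_C = 0 and
the coupling Jacobians ∂R/∂u are positive definite.

## Cell–substrate coupling

The two models are solved separately and coupled weakly by enforcing
equal FA displacements, driving the cell-scale residual
R̄cell = √Σₖ|R⁽ᵏ⁾|² to zero with a damped Gauss–Newton scheme of
Levenberg–Marquardt type. Design choices that matter:

* **Initialisation** — u = 0 (0% substrate area strain) or
  u = (√1.1 − 1)X (10% case). Patch major axes are oriented along the
  initial displacement (10%) or randomly (0%) and then frozen;
  re-orienting along the evolving force estimate mid-run changes the
  operator between iterations and was found to destabilise the 10%
  case, for a physically negligible effect.
* **Jacobians** — the substrate block of ∂R⁽ᵏ⁾/∂u⁽ᵏ⁾ is analytic (the
  patch-stiffness diagonal block); the cell block is the static
  condensation (Schur complement) of the analytic network tangent onto
  the FA degrees of freedom, refreshed every iteration (it costs a
  single sparse factorisation). A finite-difference estimator with the
  same "other FAs held fixed" semantics is provided and agrees with the
  condensed blocks; it is used for verification, not production.
* **Sweep structure** — updating all FAs simultaneously from 2 × 2
  diagonal Jacobians is a Jacobi-type iteration; through the long-range
  (1/r) substrate kernel its updates interfere and the residual
  plateaus near 20% of its initial value. The FA set is therefore swept
  in three fixed groups per iteration (Gauss–Seidel style), each group
  taking a damped step from its in-group Jacobian block (substrate
  coupling within the group plus condensed cell tangent). Groups are
  proximity-clustered: FAs closer than 4 μm always share a group,
  because splitting a strongly coupled near pair across groups makes
  the sweep contraction arbitrarily slow. Per-FA damping μₖ follows
  the usual LM update (halved on improvement, quadrupled otherwise);
  a rejected group step is retried with raised damping and finally
  with the full Jacobian column block of the group, whose damped steps
  are guaranteed descent directions of ‖R‖². Steps are capped at 2 μm,
  and a step is adopted only if it does not increase R̄cell — the
  residual history is non-increasing by construction.
* **Acceleration** — partitioned fixed-point iterations of this kind
  converge geometrically; an Anderson-type mixing of the recent
  post-sweep iterates (coefficients minimising the linear combination
  of their stored force residuals, window 4) is attempted each
  iteration and kept only when it lowers the residual. This is the
  standard accelerator for partitioned multiphysics coupling.
* **Adhesion separation** — the generator enforces a 2 μm minimum
  FA–FA distance (one patch major axis): two adhesion patches cannot
  overlap on the substrate. Without it, nearly coincident cortex
  nodes chosen as FAs produce near-singular patch pairs that dominate
  the residual and cap the achievable reduction near 10%.

With the default 10 iterations the cell-scale residual typically falls
below 0.1% of its initial value in both load cases, comfortably inside
the few-percent regime reported for this class of weak coupling.

## Virtual TFM

The coupled solution yields an exact surface displacement closure.
The virtual experiment then deliberately degrades it the way the
laboratory pipeline does:

1. ~1500 markers are seeded uniformly at random in a 200 × 200 μm
   window and displaced by the surface field (marker images at
   0.229 μm/px with 9 px Gaussian dots can be rendered for external
   registration tools);
2. a tensor-product cubic B-spline displacement field on an 8 × 8
   control grid is fit to the marker displacements by ridge-regularised
   least squares. Because marker correspondences are known exactly in
   silico, pixel-based image registration is bypassed; the 8 × 8 spline
   space — the scientifically relevant smoothing bottleneck of the
   registration — is retained. Affine fields are reproduced to
   < 1e-6 μm, and a known random spline field is recovered to < 0.1%
   from 2000 markers;
3. the local area strain ε_A = λ₁λ₂ − 1 = det(I + ∇u) − 1 is evaluated
   per 0.229 μm pixel from the analytic spline gradient;
4. pixel strains underneath the cell (deformed membrane outline) and in
   its vicinity (outline scaled about its centroid to 4× area, minus
   the cell) are each histogrammed into four equal-width bins spanning
   the combined value range of both regions (shared edges, as when the
   two normalised histograms are drawn on one axis). The under-cell
   aggregate is the occurrence-weighted mean of the two lowest bin
   centres; the surrounding aggregate is the modal bin centre; their
   difference Δε_A (> 0 for a contracting cell) is the read-out. Bin
   value = centre, equal-width bins, shared edges, and the deformed
   outline are deliberate conventions exposed as arguments. Shared
   edges matter: with per-region ranges the vicinity modal bin sits on
   a knife edge and flips with the random marker set (≈20% relative
   spread of Δε_A), whereas shared edges reproduce the marker-choice
   robustness observed experimentally (<10%); the price is a mild
   centre-quantisation of idealised two-level fields.

## Study drivers and problem sizes

The replication study runs n = 5 statistically independent cells × two
load cases × 10 coupling iterations, then the TFM pipeline; on one CPU
this takes roughly 10 minutes, with one full-size cell solve at ~3 s
cold and ~1–2 s warm. The sensitivity analysis reuses the same cells
and varies one parameter at a time: cortex or ventral-SF stiffness
+30%, activation shortening +30% (a → 0.935 or 0.75), or per-bond
stiffness draws from a normal distribution with CoV 30% (negative
draws set to zero). The bundled test suite runs the deterministic
stiffness/activation variants on two cells for the unstretched case,
which is sufficient to resolve the ordering of their effects; the full
six-variant grid is available through `cellnet sensitivity --variants
all`.

## What the synthetic data do not show

The generator realises the *statistical* geometry of spread endothelial
cells (polygonal outline, cortex mesh density, FA density, SF counts);
it does not reproduce any particular imaged cell, peripheral FA
densification, dorsal stress fibres, transverse arcs, intermediate
filaments, microtubules, or any out-of-plane structure. The substrate
is a linearised half space rather than a finite hyperelastic block, so
absolute traction magnitudes carry a few-percent systematic error at
10% pre-stretch. Passing tests therefore demonstrate internal
consistency of the model chain and agreement with the published
summary statistics under matched conditions — not cell-by-cell
predictive power for real TFM images.

## Known limitations

* No dynamics, viscosity, bond turnover, or rupture; equilibrium only.
* The bilinear law has no buckling model; slender-fibre compression is
  represented solely by K_c = K_t/10.
* The interior of sub-isostatic networks admits floppy modes; reported
  equilibria are force-balanced to tolerance but not unique in the
  zero-stiffness directions.
* The per-FA residual formulation neglects cross-FA Jacobian terms
  between groups; convergence relies on the sweep structure and
  acceleration rather than a monolithic solve (which is out of scope by
  design).
* Monolayer junction mechanics is a placeholder pending a junction
  constitutive law.
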