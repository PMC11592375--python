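# Methods

## Scaffold geometry

The three unit cells are level sets of the classical implicit surfaces,
evaluated on normalized cell coordinates u, v, w ∈ [0, 1) so that all three
share a unit period (the Gyroid and Diamond equations, conventionally
written with radian arguments, are scaled by 2π internally; the gyroid
equation's third term is read as cos(z)·sin(x)):

- Diamond: sin x sin y sin z + sin x cos y cos z + cos x sin y cos z + cos x cos y sin z
- Gyroid: cos x sin y + cos y sin z + cos z sin x
- I-WP: 2(cos x cos y + cos y cos z + cos x cos z) − (cos 2x + cos 2y + cos 2z)

**Level-offset calibration.** The porosity (80% by default) fixes the level
offset c, not the other way round: no closed form exists, so c is found by
bisection on the voxel-measured void fraction of one unit cell, sampled at
64³ voxel centers, to within 0.5 percentage points. The material phase is
the side of the offset surface whose volume equals 1 − porosity; which
labyrinth that is per structure is a genuine modelling choice (the printed
scaffolds' topology at 80% porosity is not recoverable from the equations
alone). The defaults pick, per structure, the side whose voxelized network
is best face-connected: the F − c < 0 side for Diamond and Gyroid, the
mirror side for I-WP.

**Mirrored lattice.** Cells are replicated by mirroring across shared faces
(odd-index cells are flipped), which keeps the combined implicit field
continuous across cell boundaries and the lattice exactly mirror-symmetric
about its central planes — the property the quarter-symmetry reduction
rests on.

**Connectivity repair.** At practical voxel resolutions (default 20 voxels
per cell edge) a strut whose continuum cross-section is thinner than one
voxel can be severed; the mirrored gyroid in particular touches its
reflection in nearly tangential patches and loses one octant of its network
at 20–32 voxels/cell. Disconnected solid components are therefore bridged
along minimal-cost voxel paths through the implicit field (void voxels cost
their signed field value, so bridges follow the surface's thinnest necks),
with every bridge applied together with its mirror images to preserve the
lattice symmetry. At default resolution this adds a few dozen voxels
(≈0.06 percentage points of porosity) and restores a single face-connected
solid.

**Quarter model.** One quadrant of the lattice is retained (cut along the
two vertical central planes); pore space inside the scaffold bounding box
is labeled the healing region; 2-voxel bone endplates span the full cross
section above and below; 2-voxel soft lateral bone wraps the two exterior
vertical faces (the two cut faces carry symmetry boundary conditions
instead). Plate and side-bone thicknesses are not physically constrained —
they exist to transmit load and seed ossification — and are configurable.

## Elasticity

Every non-void voxel is an 8-node trilinear hexahedron with 2×2×2 Gauss
quadrature; a structured voxel mesh replaces unstructured tetrahedra
because it is meshing-free, conforming by construction (the tie constraint
between scaffold and granulation surfaces becomes node sharing), and
adequate for element-level stimuli. The isotropic element stiffness is
decomposed into its Lamé parts, K<sub>e</sub> = a(λK<sub>λ</sub> + μK<sub>μ</sub>)
with a the voxel edge, so reassembly under evolving tissue properties is a
vectorized array operation with a frozen sparsity pattern.

Drained linear elasticity is solved: the stimuli are strain invariants and
no fluid-phase parameters enter the model, so a poroelastic formulation
would be unparameterizable here. Units are MPa and µm throughout; strains
are dimensionless and reported in percent.

**Boundary conditions.** Uniform traction p = 0.5 MPa (consistent nodal
forces) on the top face of the superior endplate; the inferior endplate
fully fixed; zero normal displacement on the two symmetry planes. A
frictionless-roller base variant exists for analytic fixtures (it makes the
homogeneous-block solution exactly uniaxial, ε<sub>zz</sub> = −p/E). The
lateral side-bone faces are traction-free and share nodes with the
scaffold.

**Solvers.** Small systems use a sparse direct factorization (relative
residual ≲ 10⁻¹⁰). The production-scale models (~65 000 free DOFs) are
solved, once per regulation iteration, by conjugate gradients preconditioned
with a recycled single-precision banded Cholesky factorization: free DOFs
are renumbered so the two short grid axes vary fastest (bandwidth ≈ 1600),
the factorization is refreshed whenever the preconditioned iteration stops
converging quickly (materials drift as tissue differentiates), and each
solve warm-starts from the previous displacement field. The iterative
tolerance is 10⁻⁵ on the relative residual — strain stimuli are classified
against windows no finer than 0.1% strain, so solver error is orders of
magnitude below classification resolution. The scheme is deterministic.

Per-element strains are evaluated at the element centroid from the
trilinear shape-function gradients; principal strains are eigenvalues of
the symmetric strain tensor, sorted descending.

## Differentiation rules

Stimuli are expressed in percent strain. The rule windows (all strict
inequalities, signed ε<sub>H</sub> exactly as printed in the standard rule
table) are:

| event | window | additional rules | rate per iteration |
|---|---|---|---|
| destruction | ε<sub>H</sub> > 5 or ε<sub>d</sub> > 15 | — | reset to granulation |
| fibrous | (−1 < ε<sub>H</sub> < 5 and 5 < ε<sub>d</sub> < 15) or (1 < ε<sub>H</sub> < 5 and ε<sub>d</sub> < 15) | — | 0.2 from granulation |
| cartilage | −5 < ε<sub>H</sub> < −1 and 5 < ε<sub>d</sub> < 15 | m<sub>cart</sub> < 0.25 and m<sub>bone</sub> < 0.75 | 0.1 from granulation |
| endochondral | −5 < ε<sub>H</sub> < −0.1 and ε<sub>d</sub> < 5 | vascularized, bone neighbour, m<sub>cart</sub> > 0.25 | 0.1·m<sub>cart</sub> cartilage→bone |
| intramembranous | (−0.1 < ε<sub>H</sub> < 1 and 1 < ε<sub>d</sub> < 5) or (0.1 < ε<sub>H</sub> < 1 and ε<sub>d</sub> < 1) | vascularized, bone neighbour, m<sub>cart</sub> < 0.25 | 0.1 from granulation |
| resorption | −0.1 < ε<sub>H</sub> < 0.1 and ε<sub>d</sub> < 1 | — | 0.05·m<sub>bone</sub> bone→granulation |

Design choices where the rule table is silent:

- **Unclassified stimuli** (e.g. ε<sub>H</sub> < −5% with ε<sub>d</sub> < 15%)
  leave the element unchanged: the table enumerates events, not the whole
  strain plane, and inventing behaviour there would be arbitrary.
- **Vascularization** is always true: the healing region is initialized as
  well-vascularized granulation tissue and no vascular model exists here.
- **Bone neighbour** means any face-adjacent (6-neighbourhood) element with
  m<sub>bone</sub> > 0.25; endplate and side-bone elements count as bone,
  so ossification seeds from the surrounding bone surfaces and grows as a
  connected front.
- **Rates**: flat rates draw from granulation and are clamped to its
  availability; "based on fraction" rates are proportional transfers.
- Events are tested in priority order destruction → fibrous → cartilage →
  endochondral → intramembranous → resorption (the windows are disjoint by
  construction; the priority is a safety net).
- Only healing elements are regulated; scaffold, endplates and side bone
  keep their table materials (scaffold 1000 MPa/0.2, endplates
  10 000 MPa/0.325, side bone 0.01 MPa/0.325; tissues: granulation
  0.2 MPa, fibrous 2 MPa, cartilage 10 MPa, new bone 1000 MPa, ν = 0.167
  except bone 0.325).

**Homogenization** uses cubic weights for E and linear for ν. A strictly
positive floor (10⁻³ × the granulation modulus) guards the stiffness of
degenerate compositions; with fractions summing to one the floor is in
practice never reached.

**Convergence** compares consecutive 10-iteration samples of the healing
region's mean bone fraction: |vf₁₀₍ᵢ₊₁₎ − vf₁₀ᵢ| / vf₁₀₍ᵢ₊₁₎ < 0.05, read
as relative change against the later sample (zero change of a zero fraction
converges). A floor of 150 iterations must pass first — tissue fractions
level off only after roughly that many iterations — and a cap of 500
guards non-convergence. Both are configurable.

## Bone-fraction descriptions

All three descriptions integrate over the healing region with uniform voxel
volumes (kept explicit for future non-uniform meshes):

1. **proportion** — volume-weighted mean of m<sub>bone</sub>;
2. **tissue-fraction threshold** — elements with m<sub>bone</sub> ≥ 0.25
   contribute their whole volume, the rest their bone share;
3. **elastic-modulus threshold** — as (2) with the criterion E ≥ 10 MPa on
   the homogenized modulus (pure cartilage, at exactly 10 MPa, counts).

For the four-tissue tables under the threshold descriptions, an
above-threshold element's non-bone mass is dropped and the remaining
tissues keep their shares over the unchanged total healing volume — the
only reading under which each description's four fractions sum to 100%.
Both thresholded bone estimates dominate the plain proportion by
construction.

## Problem sizes and what the defaults emulate

The default configuration — h = 1560 µm cells, 80% porosity, 2×2×2 mirrored
lattice, quarter symmetry, 20 voxels per cell (quarter model 22×22×44
voxels, ≈21 000 elements, ≈12 800 of them healing), p = 0.5 MPa — is the
reference compression set-up of a scaffold implanted between vertebral
endplates. Twenty voxels per cell resolves the strut network and the
per-element stimulus field but is far coarser than a conforming
tetrahedral mesh of the smooth surfaces: thin struts carry one or two
voxels of cross-section, so the voxel models are mechanically softer than
their continuum counterparts, most visibly for the gyroid (whose
mirror-contact necks are tangential). Converged bone volume fractions
reproduce the reference study's scaffold ranking and magnitudes to within
tens of percent, but per-tissue splits in the softest (most
stimulus-sensitive) scaffold deviate further; the test suite's comparison
tolerances reflect that mesh substitution. What passing tests show is that
the algorithm — geometry, stimuli, rules, descriptions — behaves correctly
and reproduces the comparative osteogenesis conclusions; they do not show
mesh-converged absolute fractions for real scaffolds.

## Known limitations

- Linear elasticity, no poroelastic fluid phase, no contact or large
  deformation; tissues are isotropic.
- No cell migration/diffusion model: differentiation is purely local, plus
  the bone-neighbour seeding rule.
- Voxel staircase geometry; no mesh adaptivity. Resolution is configurable
  upward at cubic cost in solve time.
- The calibrated level offsets and the material side of each surface are
  modelling choices; the printed scaffolds' exact topology at 80% porosity
  is not recoverable from the equations alone.
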