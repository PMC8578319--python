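# Methods

`ventmech` models the quasistatic mechanical loading of the ependymal cell
layer lining the lateral ventricles during peak hemodynamic pressure, on a
single 2D axial slice, and relates the resulting wall-stretch mechanomarkers
to the geometry of the ventricular horns and to the location of
periventricular white matter hyperintensities (pvWMH).  This note documents
the model, its assumptions, the synthetic study conditions, and the
numerical choices.

## Mechanical model

The slice is a plane-strain continuum with three tissue regions: white
matter, a gray-matter rim, and an outer subarachnoid CSF layer bounded by a
rigid skull.  The ventricular cavity itself is not meshed; it is a fluid
cavity loaded by pressure on its wall.

All tissues share one hyperelastic strain-energy density in the isochoric
principal stretches λ̄ᵢ and the volume ratio J = det **F**:

    Ψ = μ/2 (λ̄₁² + λ̄₂² + λ̄₃² − 3) + κ/4 (J² − 1 − 2 ln J)

This is the α = 2 member of the one-term Ogden family — equivalently an
isochoric neo-Hookean solid — plus a logarithmic volumetric penalty.
Defaults (shear μ, bulk κ, in kPa): gray matter (0.34, 3.3), white matter
(0.68, 6.6) — a 2× white/gray stiffness ratio at Poisson ratio 0.45 — and an
ultrasoft compressible CSF surrogate with (μ, κ) converted from
E = 0.1 kPa, ν = 0.3.  Using the same energy form for CSF keeps one
material routine with identical small-strain behaviour to a linear
description.

Loading: a ventricular pressure of 20 Pa (0.15 mmHg) as a follower
(deformed-normal) pressure on the cavity wall, and a subarachnoid pressure
of 1 Pa (0.0075 mmHg).  The subarachnoid pressure is applied as a
*one-sided* follower traction on the outer gray-matter surface, pressing
the brain inward, while the meshed CSF layer remains attached and carries
the reaction to the fixed skull.  An alternative treatment — a pressurized
fluid film at the interface, realised by duplicating the interface nodes
and loading both faces — was implemented and rejected: the resulting crack
disconnects the brain from its only kinematic support, leaving a floating
body whose near-singular rigid modes contaminate the solution.  The skull
is a zero-displacement constraint on the outer periphery.  Plane strain is
enforced by fixing the out-of-plane stretch at 1 inside **F**.

Discretization: 3-node linear triangles with analytic first
Piola–Kirchhoff stress and consistent tangent (both validated against
finite differences of Ψ), assembled into a full Newton iteration with the
nonsymmetric follower-load stiffness, backtracking line search on the
residual norm, and a fall-back of up to 10 uniform load increments.
Convergence requires a relative residual of 1e−9.  At the default loads
strains stay below ~6% and ν = 0.45 is far enough from incompressibility
that displacement-based linear triangles do not lock; the Lamé-annulus
benchmark (0.1% error) and the mesh-convergence check (<1% change in peak
wall stretch between the production edge length and half of it) guard this
choice.

A known property of this constitutive class: pressurized-cavity *tension*
growth is geometrically softening, so the excess stretch (λ_t − 1) grows
slightly faster than linearly in the load (≈10.9× at 10× pressure on the
default subject; ≈10.1× even for a circular cavity).  The stretch value
itself grows strongly sub-proportionally (λ_t rises from 1.044 to 1.48 for
a 10× load increase), and wall *compression* saturates.  Materials with
strain-stiffening isochoric response (Ogden exponents other than 2) would
be needed for sub-linear excess growth; that is outside this model.

## Direction fields and mechanomarkers

Reference wall frames come from a Laplace problem on the white- and
gray-matter triangles with Dirichlet values 1.0 on the ventricular wall,
0.2 on the gray/white interface and 0.0 on the gray-matter/CSF interface.
Element gradients of the harmonic field are averaged to nodes with area
weights; at each wall node the steepest-descent direction gives the
reference normal n₀ (oriented outward from the cavity, with a geometric
fall-back for degenerate gradients), and t₀ = n₀ rotated +90°.

The right Cauchy–Green tensor **C** is averaged onto wall nodes from the
adjacent white-matter elements (the ependyma belongs to tissue, not
cavity) and projected:

    λ_t = √(t₀·C t₀)   (cell tension, tangential)
    λ_c = √(n₀·C n₀)   (cell compression, normal)

Maximum principal strain is the largest eigenvalue of the Green–Lagrange
strain E = ½(C − I) per element.

The wall is traversed as a closed loop ordered counter-clockwise (in the
x–y frame with y increasing anterior), starting at the posterior wall node
on the midline between the two posterior horns.  Horn peaks are the four
highest arclength-separated local maxima of λ_t (minimum separation 5% of
the wall length; ties break toward smaller arclength).  Reported peak
*locations* are the excess-weighted centroid of the wall section within
70% of the peak excess — the argmax node of a flat-topped discrete peak is
not a stable location estimator, the centroid is.

**The 10% rule.**  Horn radius is the circumradius of the circle through
the tension peak and the two flanking points where the *excess* tension
(λ_t − 1) first falls to 10% of the peak excess (linear interpolation
between nodes); the wall fraction under elevated stretch is the arclength
where excess tension exceeds 10% of the global peak excess, divided by the
total wall length.  The excess convention is deliberate: 10% of a raw
stretch near 1.05 would be ≈0.105, meaningless for a quantity bounded
below by ~1.  This is the single most consequential convention in the
marker layer and is recorded in every report.

## Synthetic subjects

No imaging data ships with the package; the study conditions are a
parametric family of synthetic subjects.  The cavity is one connected
butterfly: two wings joined across the midline by a septal channel
(default height 3 mm), giving a single closed wall path that passes the
four horns in the posterior–anterior–anterior–posterior order.  Each wing
is built as a tangent-continuous chain of circular arcs:

- the horn tips are *exact* circular arcs with the prescribed anterior
  (2.0 mm) and posterior (2.5 mm) radii — the ground truth the stretch
  based circle fit is tested against;
- a concave notch at the base of each horn plus small grazing cuts set the
  horn off from the wall, mimicking the structures that indent the real
  ventricular wall (caudate head at the anterior horn, calcar avis at the
  posterior horn); without them the tension concentration of a pressurized
  slit decays like √(r/d) and never reaches the 10% level within the wing,
  so the circle fit would measure global geometry instead of horn size;
- the lateral wall carries a long shallow concave arc and the medial wall
  a gently convex arc (wing body width 10 mm), both with curvature far
  below any horn tip's 1/r, so the sustained-curvature maxima of the
  boundary are exactly the four tips.

The surrounding white-matter annulus, gray-matter rim (elliptical cortex,
semiaxes 62 × 50 mm, 3 mm gray matter) and 4 mm CSF layer complete the
slice.  Geometry is deterministic and independent of the seed.

The FLAIR-like image is a rasterization (0.7 mm pixels, matching a typical
in-plane FLAIR resolution) with uniform brain-tissue background, dark CSF,
additive Gaussian noise (sd 5% of background), and planted bright lesions
(contrast 1.0, radius 3 mm) placed as periventricular caps just outside
each horn tip.  One extra bright bar is placed inside the septal channel,
fully surrounded by ventricular CSF, as a septum/choroid-plexus surrogate
that the segmentation's pruning rule must remove.  What the surrogate does
*not* emulate: 3D partial-volume effects, bias fields, anatomical texture,
or realistic lesion shapes — segmentation results here validate the
thresholding/pruning logic, not clinical performance.

## Lesion segmentation

Bright voxels are thresholded from a brain mask Ω by s(v) > μ + kσ with
k = 2.5, population (1/N) σ, and strict inequality; connected components
whose exterior boundary is more than 50% face-adjacent to CSF are removed.
Ω is taken from the label image as tissue plus the ventricular cavity (the
whole-brain-mask convention; intraventricular structures can only be
caught and pruned if they are inside Ω), and the CSF mask as subarachnoid
plus intraventricular CSF.  Pixel connectivity (4 or 8) and the σ
convention are exposed as flags because reference implementations differ;
defaults are 4-connectivity and population σ.

## Statistics

The embedded eight-subject reference table (age, CSF/ventricle/lesion
volumes, Fazekas score) feeds Pearson correlations (two-sided t-based
p-values), ordinary least squares fits — linear in the radius and linear in
the transformed regressor 1/r for the reciprocal model, with R² always on
the original scale — and summary statistics with sample (1/(n−1))
standard deviations, which reproduce the printed summaries.  Stretch is
compared between lesion-positive and lesion-negative wall points by
sampling 30 equidistant arclength positions from the wall origin; a point
is lesion-positive if its nearest wall node lies within 1.5 pixels of a
segmented lesion pixel (the reference pipeline's labelling rule is
unstated; this one is documented and deterministic).  The two-sample test
is Welch's unequal-variance t with Welch–Satterthwaite degrees of freedom —
pooled degrees of freedom are inconsistent with the reference analysis's
reported df.

## Problem sizes and determinism

Production resolution is a 0.35 mm wall edge length grading to 2.6 mm far
from the cavity (~14k triangles per subject); the radius sweep uses five
subjects with both horn radii set to 1.2–3.6 mm; the sensitivity sweeps
use pressure scales {0.5, 1, 5, 10} and white-matter stiffness scales
{0.25, 0.5, 1, 2, 4}.  Every stage is deterministic given the
configuration; the seed enters only through image noise.  Run manifests
hash the configuration, mesh, displacement, wall profile and segmentation
so any nondeterminism regression is detectable.

## Known limitations

- 2D plane strain on one slice; no ventricular 3D dynamics, pulsatile CSF
  flow, or fluid–structure interaction.
- No damage, growth or fatigue model: the analysis is a single quasistatic
  load case.
- The synthetic wall is smooth and piecewise-circular; real ventricular
  walls are irregular, which broadens stretch peaks and changes absolute
  marker values.  Passing tests demonstrate correctness of the pipeline's
  operations and the direction of its geometric trends, not clinical
  effect sizes.
- The α = 2 energy softens geometrically under cavity pressurization (see
  above); sensitivity factors on the stretch value are comparable to
  published patient-geometry values, but excess-stretch growth is mildly
  super-linear by construction.
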