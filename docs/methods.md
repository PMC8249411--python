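# Methods

## Shape model

The discocyte is the zero set of the quartic
F(x,y,z) = (x²+y²+z²)² + P(x²+y²) + Qz² + R. The coefficients are functions
of three principal distances (all µm):

| parameter | meaning | default |
|---|---|---|
| d | main diameter | 8.0 |
| b | thickness at the dimple centre | 1.0 |
| h | maximum height at the rim | 2.12 |

P carries the rim-height constraint through the term
(h²/2)(d²/b²−1)(1−(1−b²/h²)^½); Q and R are chosen so the rim circle
(radius d/2, z=0) and the dimple-centre points (0,0,±b/2) lie on the
surface *identically* — both hold for any P, which one can verify by
substitution, so only h distinguishes admissible shapes of given d, b.
Validity requires 0 < b ≤ h < d; b > h makes the square root imaginary and
is rejected. With the defaults, P ≈ −15.260353 µm², Q ≈ 47.087409 µm²,
R ≈ −11.834352 µm⁴, and the maximum half-height of the zero set is exactly
h/2 = 1.06 µm. The defaults reproduce the physiological mean cell volume of
86 fL; the model's area of 128 µm² sits below the 137±17 µm² reported by
other methods, and we keep the volume-faithful parameterization without
attempting to reconcile the area (the shape family cannot match both).

F grows like |x|⁴ at infinity, so ∇F/|∇F| on the zero set is the outward
normal. All derivatives (gradient, Hessian, adjugate of the Hessian) are
closed-form; finite differences appear only as test oracles. The on-surface
tolerance is |F| < 10⁻⁹·d⁴ (quartic units scale as length⁴) and gradients
below 10⁻¹⁰·d³ are treated as singular (the axis points x=y=0 inside the
cell, never reached on the surface).

## Deformation

Orientation and strain enter as M = S_ξ·R_θ: first the Euler rotation R_θ
about x (θ in degrees at every interface; the symmetry of the disc makes
rotations about any in-plane axis equivalent), then the uniaxial strain
S_ξ = diag(1/√ξ, 1/√ξ, ξ), which has unit determinant, so every deformation
here is volume-preserving by construction. The deformed surface is
evaluated as F(M⁻¹p); gradients and Hessians follow by the chain rule
(∇→M⁻ᵀ∇, H→M⁻ᵀHM⁻¹), so curvature of the strained state is exact, not
re-fitted. ξ < 1 (compression) is accepted; the physically interesting
range used throughout is ξ ∈ [1, 1.75], since real cells haemolyse around
two-fold stretch.

## Triangularization

The target mesh density is that of the spectrin network: ~121,000 edges, i.e.
~80,667 triangles and ~40,336 nodes on a closed genus-0 surface
(F − E + V = 2, E = 3F/2). The pipeline:

1. **Sampling.** F is evaluated on a regular lattice of pitch p over the
   surface's bounding box. The lattice is tilted by a fixed rotation
   (11°, 7°, 13° about x, y, z) relative to the cell and shifted by fixed
   irrational fractions of p; both are undone on the output vertices. This
   matters: the dimple floor and the disc plane are otherwise nearly
   parallel to lattice planes, which makes the extracted triangle count
   jump erratically with pitch and orientation, and puts lattice nodes
   exactly on the zero set of this highly symmetric surface (producing
   degenerate triangles). Any node value within 10⁻¹³·d⁴ of zero is nudged
   off the level set.
2. **Extraction.** scikit-image marching cubes at level 0. The result must
   be watertight; a surface clipped by the box is an error, not a warning.
3. **Edge-count control.** The pitch is iterated by a secant rule in
   log-log space (edge count scales roughly as p⁻², with the local exponent
   estimated from successive trials) until the edge count is within ±0.5%
   of the target (±2% is the hard failure bound).
4. **Connectivity regularization.** Three passes of greedy edge flips that
   minimize Σ(valence−6)², each followed by relaxation. Flips preserve
   orientation and watertightness; a flip that would duplicate an edge or
   push a valence below 3 is skipped. This moves ~80% of vertices to
   valence 6, with the remaining 5/7 defects scattered — the same
   qualitative picture as the quasi-hexagonal spectrin lattice.
5. **Relaxation + projection.** Uniform-Laplacian tangential relaxation
   (damping 0.7, 20 sweeps) alternating with Newton projection of every
   vertex onto {F = 0} along ∇F, finishing with a projection to the
   on-surface tolerance. Connectivity is frozen here, so counts are stable.
6. **Orientation.** Face windings are flipped, if needed, so normals agree
   with ∇F (outward).

Every step is deterministic: identical inputs give byte-identical meshes.
Volume is the signed-tetrahedron (divergence-theorem) sum; area is the
cross-product formula per face. Both converge as O(edge²): doubling the
edge target changes them by well under 0.2%, and an inscribed mesh
underestimates slightly (at 121,000 edges the sphere test is ~0.03% low).

## Curvature

K_G and K_M come from the gradient–Hessian–adjugate expressions quoted in
the README; k₁ ≥ k₂ follow algebraically, with the discriminant
K_M² − K_G clamped at zero when it dips below by rounding (beyond
~10⁻¹²·(1+K_M²) it is an error, not noise). Note the mean-curvature
numerator uses |∇F|²·tr H; the K_M = (k₁+k₂)/2 identity and the sphere
closed form force this form. Under the outward-normal convention convex
regions have K_M < 0; comparisons with rendered curvature maps should use
value ranges, not absolute signs.

Per-triangle values support three estimators: `vertex_mean` (evaluate at
the three vertices and average; the default), `centroid` (flat-triangle
centroid Newton-projected onto the surface), and `centroid_raw`
(unprojected; values deviate O(edge²), ~0.5% on a coarse sphere, and it is
kept for comparison with workflows that evaluate at raw centroids). On
meshes of ≥10,000 faces the area-weighted means of the two projected modes
agree to <1%.

Validation is by closed forms and invariants rather than reference data:
spheres and ellipsoids (exact K_G, K_M at machine precision), the
profile-curve oracle at the rim (circumferential curvature exactly
−2/d), the scaling law (K_G ~ s⁻², K_M ~ s⁻¹), and the Gauss–Bonnet
theorem: Σ K_G·area = 4π within 0.03% at 121,000 edges, relaxed or
strained.

## Analyses

* **Binning** (curvature maps): linear bins spanning [min, max] of the
  per-triangle field, last bin right-inclusive; a constant field collapses
  to one bin. Per-bin area fractions sum to 1 exactly.
* **Sweeps** remesh the transformed implicit surface per (θ, ξ) cell;
  failures are recorded per cell and the sweep continues. On the default
  3×4 grid (θ ∈ {0°,45°,90°}, ξ ∈ {1,1.25,1.5,1.75}), area falls ~17% at
  θ=0°, ξ=1.75, rises ~23% at θ=90°, ξ=1.75, and volume stays within 1% of
  86 fL everywhere.
* **Push-forward maps** (area-change partition, curvature differences) mesh
  the relaxed cell once and map vertices by M, so triangle identity is
  preserved; areas change but volume is exactly conserved (det M = 1). The
  expanded/diminished classes partition the faces (threshold |ΔA|/A <
  10⁻¹², effectively a sign test under anisotropic strain); connected
  components of each class are counted by face-adjacency flood fill, but
  their exact topology is mesh-dependent and not asserted.
* **Cytoskeleton arithmetic**: triangle count = (2/3)·edges on a closed
  surface; equilateral area a²√3/4. Two printed-precision conventions are
  preserved deliberately: the implied tessellation area (1397 µm²) uses the
  unrounded 200 nm-triangle area, while the implied internodal side
  (60.8 nm) is derived from the mean triangle area rounded to 4 decimals
  (0.0016 µm²), matching how these figures are conventionally quoted.

## Design notes and limitations

* **Mesh statistics are pipeline-specific.** Intrinsic summaries (area,
  volume, weighted curvature) are orientation-invariant to <0.1%, but edge-
  length statistics inherit the sampling lattice's anisotropy: at matched
  edge count the mean edge varies by up to ~1% with θ. The mean edge at
  121,000 edges is ~61.2 nm (close to the ideal equilateral 60.5 nm for
  128 µm² over 80,700 triangles); histogram *shapes* (modality, tail
  structure) are mesher artifacts and are reported but never asserted.
* The strain response of area is a property of the implicit model, checked
  three independent ways (remeshing at multiple resolutions, vertex
  push-forward, and exact quadrature of the surface of revolution with
  area(M·S) = ∫|M⁻ᵀn| dA): the θ=90°, ξ=1.75 increase is 22.8%.
* Problem sizes: unit and property tests run at 3,000–24,000 edges; the
  full 121,000-edge meshes are exercised in the end-to-end suite and the
  acceptance script (a few seconds each on one CPU).
* Out of scope: disc-cyclide coordinates, non-uniaxial or time-dependent
  strain, discrete (mesh-only) curvature estimators, curvature flow,
  cytoskeletal dynamics, and population averaging over continuous θ
  (exposed only as a sweep).
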