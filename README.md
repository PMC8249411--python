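# rbcmesh

Geometry of the human red blood cell membrane under strain: a quartic
implicit model of the biconcave discocyte, volume-preserving affine
deformation, triangularization at the scale of the spectrin cytoskeleton,
and differential-geometric curvature analysis.

## The problem

Red blood cells suspended in a gel that is then stretched or compressed
change shape, and those shape changes feed back on membrane physiology
(mechanosensitive channels such as Piezo1, glycolytic flux). Reasoning about
this requires quantitative maps of membrane curvature at the nanometre-to-
micrometre scale, and a mesh of the membrane at the density of the spectrin
network (~121,000 α/β-spectrin tetramer struts) so that per-triangle area
changes can stand in for local tension changes. `rbcmesh` builds exactly
that toolchain for anyone modelling RBC membrane mechanics.

## The model

The membrane is the zero set of a degree-4 polynomial in Cartesian
coordinates,

    F(x,y,z) = (x² + y² + z²)² + P(x² + y²) + Q z² + R = 0,

with P, Q, R fixed by three principal distances: main diameter *d* = 8 µm,
dimple thickness *b* = 1 µm, rim height *h* = 2.12 µm. These defaults give
an enclosed volume of 86 µm³ (= 86 fL, the physiological mean) and a
surface area of 128 µm².

A cell at orientation θ (rotation about the x-axis) in a uniaxial strain
field along z deforms by M = S_ξ·R_θ with the volume-preserving strain
tensor S_ξ = diag(1/√ξ, 1/√ξ, ξ); the deformed membrane is evaluated
implicitly as F(M⁻¹p). Curvature comes from the exact gradient ∇F, Hessian
H and Hessian adjugate H*:

    K_G = ∇F·H*·∇Fᵀ / |∇F|⁴            (Gaussian, µm⁻²)
    K_M = (∇F·H·∇Fᵀ − |∇F|² tr H) / (2|∇F|³)   (mean, µm⁻¹)
    k₁,₂ = K_M ± √(K_M² − K_G)          (principal, µm⁻¹)

with the outward-normal convention n = ∇F/|∇F| (a sphere of radius r has
K_M = −1/r). Meshing is marching cubes on a tilted sampling lattice,
valence-regularizing edge flips, tangential relaxation and Newton
projection of every vertex onto {F = 0}, with the edge count steered to a
target (±0.5%).

## Worked example

```
$ rbcmesh build --target-edges 121000 --out-dir rbc_out
wrote mesh + stats to rbc_out (V=40372, E=121110, F=80740, chi=2)
```

`rbc_out/stats.json` then contains (abridged):

```json
{
  "area_um2": 128.015415,
  "volume_um3": 85.9684878,
  "euler_characteristic": 2,
  "mean_edge_nm": 61.2252879,
  "total_gaussian_curvature_sr": 12.5631835,
  "valence_census": {"4": 5, "5": 3776, "6": 32819, "7": 3770, "8": 2}
}
```

Reading these numbers: the watertight mesh closes (F − E + V = 40372 −
121110 + 80740 = 2, a genus-0 surface); volume and area reproduce the
physiological 86 fL / 128 µm²; the mean strut length of ~61 nm matches the
in-situ spectrin internodal distance (60–70 nm), far below the ~200 nm
fully extended tetramer length; the total Gaussian curvature 12.563 ≈ 4π
verifies the whole curvature chain via the Gauss–Bonnet theorem; and almost
every mesh node is met by six triangles, as in the quasi-hexagonal spectrin
network. The same cytoskeleton arithmetic in closed form:

```
$ rbcmesh report --out cyto.json        # 121,000 struts, 128 µm², 0.79 µm² patch
{"n_triangles": 80667, "extended_triangle_area_um2": 0.0173205081,
 "implied_total_area_um2": 1397.19342, "area_ratio": 10.9155736,
 "implied_side_nm": 60.7868549, "patch_triangle_count": 497.866641}
```

i.e. fully extended spectrin would tessellate 10.9× the real membrane area,
the real area implies ~61 nm struts, and a patch-clamp-sized 0.79 µm² patch
spans ~500 cytoskeletal triangles.

Other subcommands: `rbcmesh sweep` (area/volume over a θ×ξ grid — at
θ=90°, ξ=1.75 the area rises by ~23%, at θ=0° it falls, volume stays within
1% of 86 fL), `rbcmesh curvature` (binned area-fraction profiles of K_G,
K_M, k₁, k₂), `rbcmesh partition` (triangle-by-triangle expanded/diminished
map under push-forward strain).

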