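"""Derived analyses of the meshed cell.

Covers the survey quantities built on top of the shape/deformation/meshing/
curvature layers: linear value-binning of curvature fields with area
fractions (the colour-map data), edge-length and triangle-area histograms,
(θ, ξ) strain sweeps of area and volume, the triangle-by-triangle area
change and curvature-difference maps under push-forward, and the spectrin
cytoskeleton back-of-envelope geometry.

Two deformation workflows are exposed deliberately:

* *remesh*: triangularize the transformed implicit surface afresh (used for
  sweeps and curvature profiles — areas/volumes of the deformed shape).
* *push-forward*: map the vertices of the relaxed mesh by M so every
  triangle keeps its identity (used for area-change partitions and
  curvature differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import trimesh

from .curvature import CurvatureField, per_triangle_curvature
from .deformation import AffineDeformation, transformed_surface
from .meshing import (MeshingError, euler_characteristic, mesh_area,
                      mesh_surface, mesh_volume)
from .shape import RBCGeometry, discocyte_surface

__all__ = [
    "BinnedSurfaceMap",
    "Histogram",
    "AreaChangePartition",
    "CurvatureDifferenceMap",
    "bin_curvature",
    "curvature_profile",
    "strain_sweep",
    "edge_length_histogram",
    "triangle_area_histogram",
    "area_change_partition",
    "curvature_difference_map",
    "cytoskeleton_report",
    "CURVATURE_NAMES",
]

CURVATURE_NAMES = ("kg", "k1", "k2", "km")


# ---------------------------------------------------------------------------
# value binning (the colour-map data structure)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinnedSurfaceMap:
    """A per-triangle scalar field split into linear value bins.

    ``bin_edges`` has n_bins+1 entries spanning [min, max] of the field
    (last bin right-inclusive); ``area_fraction`` is each bin's share of the
    total mesh area. A constant field degenerates to a single bin.
    """

    name: str
    bin_edges: np.ndarray
    bin_index: np.ndarray          # per-triangle bin assignment
    mean_value: np.ndarray         # per-bin mean of the field (NaN if empty)
    bin_area: np.ndarray           # per-bin total area, µm²
    area_fraction: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": np.arange(self.n_bins),
            "lower": self.bin_edges[:-1],
            "upper": self.bin_edges[1:],
            "mean_value": self.mean_value,
            "area_um2": self.bin_area,
            "area_fraction": self.area_fraction,
        })


def bin_curvature(values: np.ndarray, areas: np.ndarray,
                  n_bins: int = 10, name: str = "") -> BinnedSurfaceMap:
    """Partition a per-triangle field into ``n_bins`` linear value bins."""
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bin an empty field")
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        # constant field: a single bin carrying everything
        edges = np.array([vmin, vmax])
        idx = np.zeros(len(values), dtype=int)
        n_bins = 1
    else:
        edges = np.linspace(vmin, vmax, n_bins + 1)
        idx = np.clip(((values - vmin) / (vmax - vmin) * n_bins).astype(int),
                      0, n_bins - 1)
    bin_area = np.bincount(idx, weights=areas, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_value = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedSurfaceMap(
        name=name, bin_edges=edges, bin_index=idx, mean_value=mean_value,
        bin_area=bin_area, area_fraction=bin_area / areas.sum(),
    )


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Histogram:
    """Linear histogram over [min, max] with simple summary statistics."""

    counts: np.ndarray
    bin_edges: np.ndarray
    mean: float

    @property
    def modal_bin(self) -> int:
        return int(np.argmax(self.counts))

    @property
    def modal_bin_span(self) -> tuple[float, float]:
        i = self.modal_bin
        return float(self.bin_edges[i]), float(self.bin_edges[i + 1])

    def top_mass(self, k: int = 1) -> float:
        """Fraction of all entries held by the k most populated bins."""
        top = np.sort(self.counts)[::-1][:k]
        return float(top.sum() / self.counts.sum())


def _edge_lengths(mesh: trimesh.Trimesh) -> np.ndarray:
    e = mesh.edges_unique
    return np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)


def edge_length_histogram(mesh: trimesh.Trimesh, n_bins: int = 20) -> Histogram:
    """Distribution of unique edge lengths (µm) in linear bins."""
    lengths = _edge_lengths(mesh)
    counts, edges = np.histogram(lengths, bins=n_bins,
                                 range=(lengths.min(), lengths.max()))
    return Histogram(counts=counts, bin_edges=edges, mean=float(lengths.mean()))


@dataclass(frozen=True)
class TriangleAreaHistogram(Histogram):
    mean_area_per_bin: np.ndarray = field(default_factory=lambda: np.array([]))
    area_share: np.ndarray = field(default_factory=lambda: np.array([]))


def triangle_area_histogram(mesh: trimesh.Trimesh, n_bins: int = 10) -> TriangleAreaHistogram:
    """Per-bin triangle count, mean area and share of total area (µm²)."""
    areas = mesh.area_faces
    counts, edges = np.histogram(areas, bins=n_bins, range=(areas.min(), areas.max()))
    idx = np.clip(((areas - areas.min()) / max(np.ptp(areas), 1e-300) * n_bins).astype(int),
                  0, n_bins - 1)
    sums = np.bincount(idx, weights=areas, minlength=n_bins)
    cnt = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_per_bin = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
    return TriangleAreaHistogram(
        counts=counts, bin_edges=edges, mean=float(areas.mean()),
        mean_area_per_bin=mean_per_bin, area_share=sums / areas.sum(),
    )


# ---------------------------------------------------------------------------
# (θ, ξ) sweeps — remesh workflow
# ---------------------------------------------------------------------------

def _deformed_mesh(geom: RBCGeometry, theta: float, xi: float,
                   target_edges: int) -> trimesh.Trimesh:
    surface = discocyte_surface(geom)
    deformed = transformed_surface(surface, AffineDeformation(theta, xi))
    return mesh_surface(deformed, target_edges=target_edges)


def strain_sweep(geom: RBCGeometry,
                 thetas: Sequence[float] = (0.0, 45.0, 90.0),
                 xis: Sequence[float] = (1.0, 1.25, 1.5, 1.75),
                 target_edges: int = 121_000) -> pd.DataFrame:
    """Area/volume/edge-length table over the (θ, ξ) grid.

    Each cell remeshes the transformed implicit surface from scratch.
    Meshing failures are recorded in the ``error`` column and the sweep
    continues.
    """
    if len(thetas) == 0 or len(xis) == 0:
        raise ValueError("theta and xi lists must be non-empty")
    rows = []
    for theta in thetas:
        for xi in xis:
            row: Dict[str, object] = {"theta_deg": float(theta), "xi": float(xi)}
            try:
                mesh = _deformed_mesh(geom, theta, xi, target_edges)
                row.update(
                    area_um2=mesh_area(mesh),
                    volume_um3=mesh_volume(mesh),
                    mean_edge_nm=float(_edge_lengths(mesh).mean() * 1e3),
                    n_vertices=len(mesh.vertices),
                    n_edges=len(mesh.edges_unique),
                    n_faces=len(mesh.faces),
                    euler_characteristic=euler_characteristic(mesh),
                    error="",
                )
            except MeshingError as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def curvature_profile(geom: RBCGeometry, theta: float = 0.0, xi: float = 1.0,
                      target_edges: int = 121_000, n_bins: int = 10,
                      mode: str = "vertex_mean") -> pd.DataFrame:
    """Binned area-fraction profile of all four curvatures of a deformed cell.

    Returns one row per (curvature type, bin): the bin's mean curvature
    value and the fraction of the membrane area carrying it — the tabular
    form of the polygonal curvature graphs.
    """
    mesh = _deformed_mesh(geom, theta, xi, target_edges)
    surface = transformed_surface(discocyte_surface(geom),
                                  AffineDeformation(theta, xi))
    cf = per_triangle_curvature(mesh, surface, mode=mode)
    areas = mesh.area_faces
    frames = []
    for name in CURVATURE_NAMES:
        bm = bin_curvature(cf.by_name(name), areas, n_bins=n_bins, name=name)
        f = bm.to_frame()
        f.insert(0, "curvature", name)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "xi", float(xi))
    out.insert(0, "theta_deg", float(theta))
    return out


# ---------------------------------------------------------------------------
# push-forward workflow: triangle-identity-preserving deformation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AreaChangePartition:
    """Per-triangle signed relative area change under push-forward by M.

    ``expanded``/``diminished``/``unchanged`` are disjoint face-index sets
    covering the mesh exactly once. Component counts are connected
    components of each class in the face-adjacency graph.
    """

    relative_change: np.ndarray
    expanded: np.ndarray
    diminished: np.ndarray
    unchanged: np.ndarray
    area_before: np.ndarray
    area_after: np.ndarray
    n_components_expanded: int
    n_components_diminished: int

    @property
    def total_area_before(self) -> float:
        return float(self.area_before.sum())

    @property
    def total_area_after(self) -> float:
        return float(self.area_after.sum())


def _component_count(mesh: trimesh.Trimesh, face_subset: np.ndarray) -> int:
    if len(face_subset) == 0:
        return 0
    keep = np.zeros(len(mesh.faces), dtype=bool)
    keep[face_subset] = True
    adj = mesh.face_adjacency
    inside = adj[keep[adj[:, 0]] & keep[adj[:, 1]]]
    comps = trimesh.graph.connected_components(inside, nodes=face_subset)
    return len(comps)


def area_change_partition(geom: RBCGeometry, theta: float, xi: float,
                          target_edges: int = 13_000,
                          unchanged_rtol: float = 1e-12) -> AreaChangePartition:
    """Partition triangles into area-expanded vs area-diminished under strain.

    The relaxed cell is meshed once and its vertices pushed forward by
    M = S_ξ·R_θ, so each triangle has a direct counterpart in the stretched
    state. A det-1 anisotropic map leaves essentially no triangle exactly
    unchanged, so the ``unchanged`` class is effectively a sign threshold.
    """
    mesh = mesh_surface(discocyte_surface(geom), target_edges=target_edges)
    M = AffineDeformation(theta, xi).matrix
    pushed = trimesh.Trimesh(mesh.vertices @ M.T, mesh.faces, process=False)
    a0 = mesh.area_faces
    a1 = pushed.area_faces
    rel = (a1 - a0) / a0
    unchanged = np.flatnonzero(np.abs(rel) < unchanged_rtol)
    expanded = np.flatnonzero(rel >= unchanged_rtol)
    diminished = np.flatnonzero(rel <= -unchanged_rtol)
    return AreaChangePartition(
        relative_change=rel, expanded=expanded, diminished=diminished,
        unchanged=unchanged, area_before=a0, area_after=a1,
        n_components_expanded=_component_count(mesh, expanded),
        n_components_diminished=_component_count(mesh, diminished),
    )


@dataclass(frozen=True)
class CurvatureDifferenceMap:
    """Per-triangle curvature differences between relaxed and strained states.

    The strained values are evaluated with the transformed implicit surface
    at the pushed-forward triangles, so differences are triangle-by-triangle
    on identical connectivity. ``delta_*`` is strained − relaxed.
    """

    relaxed: CurvatureField
    deformed: CurvatureField
    delta_kg: np.ndarray
    delta_km: np.ndarray
    delta_k1: np.ndarray
    delta_k2: np.ndarray
    area_before: np.ndarray
    area_after: np.ndarray


def curvature_difference_map(geom: RBCGeometry, theta: float, xi: float,
                             target_edges: int = 13_000,
                             mode: str = "vertex_mean") -> CurvatureDifferenceMap:
    """Map the change of all four curvatures under push-forward by M."""
    surface = discocyte_surface(geom)
    mesh = mesh_surface(surface, target_edges=target_edges)
    deformation = AffineDeformation(theta, xi)
    deformed_surface = transformed_surface(surface, deformation)
    pushed = trimesh.Trimesh(mesh.vertices @ deformation.matrix.T, mesh.faces,
                             process=False)
    cf0 = per_triangle_curvature(mesh, surface, mode=mode)
    cf1 = per_triangle_curvature(pushed, deformed_surface, mode=mode)
    return CurvatureDifferenceMap(
        relaxed=cf0, deformed=cf1,
        delta_kg=cf1.kg - cf0.kg, delta_km=cf1.km - cf0.km,
        delta_k1=cf1.k1 - cf0.k1, delta_k2=cf1.k2 - cf0.k2,
        area_before=mesh.area_faces, area_after=pushed.area_faces,
    )


# ---------------------------------------------------------------------------
# spectrin cytoskeleton arithmetic
# ---------------------------------------------------------------------------

def cytoskeleton_report(n_edges: int = 121_000,
                        extended_strut_length_nm: float = 200.0,
                        total_area_um2: float = 128.0,
                        patch_area_um2: Optional[float] = None) -> Dict[str, float]:
    """Closed-form geometry of the spectrin network as a triangular tessellation.

    On a closed single-sheet surface each edge is shared by two triangles and
    each triangle has three edges, so the triangle count is 2/3 of the edge
    (spectrin tetramer) count. Comparing the tessellation area at the fully
    extended strut length (~200 nm) with the real membrane area shows how
    strongly in-situ spectrin must be contracted; conversely the mean
    triangle area implied by the real membrane gives the in-situ internodal
    distance (equilateral side a has area a²√3/4). ``mean_triangle_area
    _printed_um2`` carries the 4-decimal rounding used when quoting the
    implied side length.
    """
    if n_edges <= 0 or extended_strut_length_nm <= 0 or total_area_um2 <= 0:
        raise ValueError("inputs must be positive")
    n_triangles = round(2 * n_edges / 3)
    a_um = extended_strut_length_nm / 1e3
    extended_area = a_um**2 * np.sqrt(3.0) / 4.0
    implied_total = n_triangles * extended_area
    mean_area = total_area_um2 / n_triangles
    mean_area_printed = round(mean_area, 4)
    implied_side_nm = float(np.sqrt(4.0 * mean_area_printed / np.sqrt(3.0)) * 1e3)
    report: Dict[str, float] = {
        "n_edges": float(n_edges),
        "n_triangles": float(n_triangles),
        "extended_strut_length_nm": float(extended_strut_length_nm),
        "extended_triangle_area_um2": float(extended_area),
        "implied_total_area_um2": float(implied_total),
        "area_ratio": float(implied_total / total_area_um2),
        "mean_triangle_area_um2": float(mean_area),
        "mean_triangle_area_printed_um2": float(mean_area_printed),
        "implied_side_nm": implied_side_nm,
    }
    if patch_area_um2 is not None:
        if patch_area_um2 <= 0:
            raise ValueError("patch area must be positive")
        report["patch_area_um2"] = float(patch_area_um2)
        report["patch_triangle_count"] = float(
            n_triangles * patch_area_um2 / total_area_um2)
    return report
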