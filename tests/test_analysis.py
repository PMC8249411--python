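"""Binning, histograms, strain sweeps, push-forward maps, cytoskeleton arithmetic."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from rbcmesh import (RBCGeometry, area_change_partition, bin_curvature,
                     curvature_difference_map, curvature_profile,
                     cytoskeleton_report, edge_length_histogram, mesh_area,
                     per_triangle_curvature, strain_sweep,
                     total_gaussian_curvature, triangle_area_histogram,
                     weighted_average_curvature)

SWEEP_EDGES = 6_000


# ---------------------------------------------------------------- binning

def test_bin_constant_field_degenerates_to_single_bin():
    bm = bin_curvature(np.full(50, 3.3), np.ones(50), n_bins=10)
    assert bm.n_bins == 1
    assert bm.area_fraction[0] == pytest.approx(1.0)


def test_bin_uniform_values_equal_fractions():
    values = np.arange(10, dtype=float)
    bm = bin_curvature(values, np.ones(10), n_bins=10)
    np.testing.assert_allclose(bm.area_fraction, 0.1)
    # last bin is right-inclusive: the maximum value lands in bin 9
    assert bm.bin_index[-1] == 9


def test_bin_fractions_sum_to_one_on_rbc(surface, rbc_mesh_12k):
    cf = per_triangle_curvature(rbc_mesh_12k, surface)
    areas = rbc_mesh_12k.area_faces
    bm = bin_curvature(cf.kg, areas, n_bins=10)
    assert bm.area_fraction.sum() == pytest.approx(1.0, abs=1e-12)
    # binning conserves area exactly
    assert bm.bin_area.sum() == pytest.approx(areas.sum(), rel=1e-12)


def test_bin_rejects_empty_field():
    with pytest.raises(ValueError):
        bin_curvature(np.array([]), np.array([]))


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(1, 25), st.integers(2, 200))
def test_bin_partition_property(n_bins, n):
    """Every triangle lands in exactly one bin and area is conserved."""
    rng = np.random.default_rng(n * 1000 + n_bins)
    values = rng.normal(size=n)
    areas = rng.uniform(0.1, 2.0, size=n)
    bm = bin_curvature(values, areas, n_bins=n_bins)
    assert bm.bin_index.min() >= 0 and bm.bin_index.max() < bm.n_bins
    assert bm.bin_area.sum() == pytest.approx(areas.sum(), rel=1e-12)
    assert np.all(np.diff(bm.bin_edges) > 0) or bm.n_bins == 1


# ------------------------------------------------------------- histograms

def test_edge_histogram_counts_sum_to_edges(rbc_mesh_12k):
    for n_bins in (20, 200):
        h = edge_length_histogram(rbc_mesh_12k, n_bins=n_bins)
        assert h.counts.sum() == len(rbc_mesh_12k.edges_unique)
    h20 = edge_length_histogram(rbc_mesh_12k, n_bins=20)
    lo, hi = h20.modal_bin_span
    assert lo < h20.mean < hi or h20.top_mass(2) > h20.top_mass(1)


def test_edge_histogram_mean_scales_with_mesh(rbc_mesh_12k):
    doubled = trimesh.Trimesh(2.0 * rbc_mesh_12k.vertices, rbc_mesh_12k.faces,
                              process=False)
    h1 = edge_length_histogram(rbc_mesh_12k)
    h2 = edge_length_histogram(doubled)
    assert h2.mean == pytest.approx(2.0 * h1.mean, rel=1e-12)


def test_triangle_area_histogram_shares(rbc_mesh_12k):
    h = triangle_area_histogram(rbc_mesh_12k, n_bins=10)
    assert h.counts.sum() == len(rbc_mesh_12k.faces)
    assert h.area_share.sum() == pytest.approx(1.0, rel=1e-12)
    assert h.mean == pytest.approx(mesh_area(rbc_mesh_12k) / len(rbc_mesh_12k.faces),
                                   rel=1e-12)


def test_triangle_area_histogram_equal_area_mesh():
    # two congruent triangles -> a single occupied bin
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
    m = trimesh.Trimesh(v, [[0, 1, 2], [1, 3, 2]], process=False)
    h = triangle_area_histogram(m, n_bins=10)
    assert np.count_nonzero(h.counts) == 1


# ------------------------------------------------------------------ sweeps

def test_strain_sweep_grid(geometry):
    table = strain_sweep(geometry, thetas=(0.0, 90.0), xis=(1.0, 1.75),
                         target_edges=SWEEP_EDGES)
    assert len(table) == 4
    for col in ("theta_deg", "xi", "area_um2", "volume_um3", "mean_edge_nm"):
        assert col in table.columns
    assert (table["error"] == "").all()
    get = lambda th, xi: table[(table.theta_deg == th) & (table.xi == xi)].iloc[0]
    relaxed = get(0, 1.0)
    # across the strain field the area shrinks; aligned with it, it grows
    assert get(0, 1.75).area_um2 < relaxed.area_um2
    assert get(90, 1.75).area_um2 > relaxed.area_um2
    # volume barely moves anywhere on the grid
    assert np.allclose(table["volume_um3"], 86.0, rtol=0.01)
    # ξ=1 rows are θ-independent (intrinsic shape unchanged by rotation)
    assert get(90, 1.0).area_um2 == pytest.approx(relaxed.area_um2, rel=0.005)
    assert (table["euler_characteristic"] == 2).all()


def test_strain_sweep_rejects_empty_grid(geometry):
    with pytest.raises(ValueError):
        strain_sweep(geometry, thetas=(), xis=(1.0,))


def test_curvature_profile_structure_and_rotation_invariance(geometry):
    prof0 = curvature_profile(geometry, 0.0, 1.0, target_edges=SWEEP_EDGES)
    assert len(prof0) == 4 * 10
    for name, grp in prof0.groupby("curvature"):
        assert grp["area_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
    prof90 = curvature_profile(geometry, 90.0, 1.0, target_edges=SWEEP_EDGES)

    def wmean(prof, name):
        g = prof[prof.curvature == name]
        return float((g.mean_value * g.area_fraction).sum())

    # bin-mean × area-fraction is a coarse (10-bin) estimate of the true
    # area-weighted mean, so allow binning noise on top of re-mesh noise
    for name in ("kg", "km", "k1", "k2"):
        assert wmean(prof90, name) == pytest.approx(wmean(prof0, name), rel=0.01,
                                                    abs=2e-3)


def test_curvature_profile_shifts_under_strain(geometry):
    """Stretching rearranges the curvature distribution; rotation alone does not."""
    relaxed = curvature_profile(geometry, 45.0, 1.0, target_edges=SWEEP_EDGES)
    strained = curvature_profile(geometry, 45.0, 1.75, target_edges=SWEEP_EDGES)
    kg0 = relaxed[relaxed.curvature == "kg"]
    kg1 = strained[strained.curvature == "kg"]
    # the value domain itself moves...
    assert kg1["upper"].max() != pytest.approx(kg0["upper"].max(), rel=0.05)
    # ...and the area distribution over bins shifts materially
    shift = np.abs(kg1["area_fraction"].values - kg0["area_fraction"].values).sum()
    assert shift > 0.05


# ----------------------------------------------- push-forward correspondence

def test_partition_identity_strain(geometry):
    part = area_change_partition(geometry, 0.0, 1.0, target_edges=3_000)
    assert len(part.expanded) == 0 and len(part.diminished) == 0
    assert len(part.unchanged) == len(part.relative_change)


def test_partition_covers_mesh_exactly_once(geometry):
    part = area_change_partition(geometry, 0.0, 1.75, target_edges=SWEEP_EDGES)
    n = len(part.relative_change)
    assert len(part.expanded) > 0 and len(part.diminished) > 0
    union = np.concatenate([part.expanded, part.diminished, part.unchanged])
    assert len(union) == n and len(np.unique(union)) == n
    # det-1 push-forward: total volume (not area) is exactly preserved
    assert part.total_area_after != pytest.approx(part.total_area_before, rel=1e-6)
    assert part.n_components_expanded >= 1
    assert part.n_components_diminished >= 1


def test_curvature_difference_map_identity(geometry):
    dm = curvature_difference_map(geometry, 0.0, 1.0, target_edges=3_000)
    for delta in (dm.delta_kg, dm.delta_km, dm.delta_k1, dm.delta_k2):
        np.testing.assert_allclose(delta, 0.0, atol=1e-9)


def test_curvature_difference_map_strained(geometry):
    dm = curvature_difference_map(geometry, 45.0, 1.75, target_edges=SWEEP_EDGES)
    # both states satisfy the closed-surface total-curvature constraint,
    # so the area-weighted K_G difference integrates to ~zero
    t0 = total_gaussian_curvature(dm.relaxed.kg, dm.area_before)
    t1 = total_gaussian_curvature(dm.deformed.kg, dm.area_after)
    assert t0 == pytest.approx(4 * np.pi, rel=0.01)
    assert t1 == pytest.approx(4 * np.pi, rel=0.01)
    assert dm.delta_kg.min() < 0 < dm.delta_kg.max()


# ------------------------------------------------------ cytoskeleton report

def test_cytoskeleton_report_printed_values():
    rep = cytoskeleton_report(121_000, 200.0, 128.0, patch_area_um2=0.79)
    assert rep["n_triangles"] == 80_667
    assert round(rep["extended_triangle_area_um2"], 4) == 0.0173
    assert round(rep["implied_total_area_um2"]) == 1397
    assert round(rep["area_ratio"], 1) == 10.9
    assert rep["mean_triangle_area_printed_um2"] == 0.0016
    assert round(rep["implied_side_nm"], 1) == 60.8
    assert round(rep["patch_triangle_count"], -2) == 500


def test_cytoskeleton_report_rejects_bad_inputs():
    with pytest.raises(ValueError):
        cytoskeleton_report(n_edges=0)
    with pytest.raises(ValueError):
        cytoskeleton_report(patch_area_um2=-1.0)


def test_cytoskeleton_triangle_edge_relation():
    # closed single-sheet surface: 3 edges per triangle, each shared by 2
    for e in (12_000, 121_000, 300_000):
        rep = cytoskeleton_report(n_edges=e)
        assert rep["n_triangles"] == round(2 * e / 3)
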