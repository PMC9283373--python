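import math

import numpy as np
import pytest

from hlecell import CellParameters, ControlNet, deform
from hlecell.errors import InvalidKinematicsError
from hlecell.free_energy import (
    active_stress,
    angular_concentration,
    angular_grid,
    bound_enthalpy,
    bound_potential,
    fibre_stretches,
    passive_energy_density,
    passive_stress,
    solve_unbound,
    staining_fields,
    steady_state_units,
    total_free_energy,
    traction_field,
    unbound_potential,
)
from hlecell.morphology import REGION_CYTOPLASM, REGION_NUCLEUS

from conftest import random_admissible_net


# ----------------------------------------------------------------------
# functional-unit chemistry
# ----------------------------------------------------------------------
def test_steady_state_units_examples(params):
    assert steady_state_units(1.354, params) == pytest.approx(1.0)
    assert steady_state_units(1.0, params) == pytest.approx(1.0 / 1.354)
    assert steady_state_units(2.708, params) == pytest.approx(2.0)
    with pytest.raises(InvalidKinematicsError):
        steady_state_units(-0.1, params)


def test_bound_enthalpy():
    p = CellParameters()
    # mu_b = mu_b0 - sigma_max*Omega*(1+eps); all in kBT with mu_b0 = dmu
    expected = 1.0 - p.sigma_omega_over_kBT * 1.354
    assert bound_enthalpy(p) == pytest.approx(expected)
    assert bound_enthalpy(p.replace(sigma_max=0.0)) == pytest.approx(1.0)
    assert bound_enthalpy(p.replace(Omega_log10_um3=-300.0)) == pytest.approx(1.0)


def test_angular_concentration_limits(params):
    lam = np.array([0.8, 1.0, 1.6])
    assert np.allclose(angular_concentration(0.0, lam, params), 0.0)
    # monotone in Nu_hat and strictly below eta_max
    etas = [angular_concentration(Nu, lam, params) for Nu in (0.1, 0.4, 0.9)]
    assert np.all(np.diff(np.stack(etas), axis=0) > 0)
    for eta in etas:
        assert np.all(eta < params.eta_max)


def test_angular_concentration_neutral_exponent():
    # mu_u = mu_b  ->  eta = Nu*eta_max / (pi*nss*eta_max + Nu)
    p = CellParameters(sigma_max=0.0, dmu_over_kBT=0.0)
    assert p.delta_mu_net == 0.0
    Nu, lam = 0.3, 1.1
    nss = lam / 1.354
    expected = Nu * p.eta_max / (math.pi * nss * p.eta_max + Nu)
    assert angular_concentration(Nu, lam, p) == pytest.approx(expected, rel=1e-12)


def test_angular_concentration_overflow_guard():
    # an absurdly contractile parameter set must not overflow
    p = CellParameters(Omega_log10_um3=-4.0)
    eta = angular_concentration(0.5, 3.0, p)
    # saturates at eta_max to machine precision without overflowing
    assert np.isfinite(eta) and eta <= p.eta_max


# ----------------------------------------------------------------------
# conservation solve
# ----------------------------------------------------------------------
def test_solve_unbound_all_free_when_eta_suppressed(mesh, rng):
    # eta -> 0 when binding is infinitely unfavourable -> Nu = 1
    p = CellParameters(sigma_max=0.0, dmu_over_kBT=60.0)
    cfg = deform(mesh, random_admissible_net(rng))
    state = solve_unbound(cfg, p)
    assert state.Nu_hat == pytest.approx(1.0, abs=1e-6)


def test_solve_unbound_brute_force_oracle(mesh, params):
    """Root agrees with a brute-force residual scan at 1e-6 resolution."""
    cfg = deform(mesh, ControlNet.zeros())
    state = solve_unbound(cfg, params)
    phi, dphi = state.phi, state.dphi
    lam = fibre_stretches(cfg, phi, elements=state.elements)
    vols = mesh.element_volumes(params)[state.elements]
    VC = vols.sum()
    grid = np.linspace(1e-6, 1, 1_000_000)
    # brute force on the uniform configuration: lambda = 1 everywhere
    nss = 1.0 / (1.0 + params.eps_ss)
    E = math.exp(nss * params.delta_mu_net)
    eta = grid * params.eta_max * E / (math.pi * nss * params.eta_max + grid * E)
    res = grid + math.pi * eta * nss - 1.0
    brute = grid[np.argmin(np.abs(res))]
    assert state.Nu_hat == pytest.approx(brute, abs=2e-6)
    assert abs(state.residual) < 1e-10


def test_conservation_residual_contract(mesh, params, rng):
    for _ in range(5):
        cfg = deform(mesh, random_admissible_net(rng))
        state = solve_unbound(cfg, params)
        assert abs(state.residual) < 1e-10


def test_chemical_equilibrium_uniformity(mesh, params, rng):
    """chi_b equals chi_u at every element and angular bin after the solve."""
    cfg = deform(mesh, random_admissible_net(rng, scale=0.08))
    state = solve_unbound(cfg, params)
    chi_b = bound_potential(state, params)
    assert np.max(np.abs(chi_b - state.chi_u)) < 1e-8 * abs(state.chi_u)


def test_unbound_potential_log_law(mesh, params):
    cfg = deform(mesh, ControlNet.zeros())
    state = solve_unbound(cfg, params)
    assert unbound_potential(state, params) == pytest.approx(state.chi_u)
    # chi_u = mu_u + ln(Nu/(pi NL)): doubling Nu adds ln 2
    s2 = type(state)(
        Nu_hat=2 * state.Nu_hat, eta_hat=state.eta_hat, nss_hat=state.nss_hat,
        chi_u=0.0, phi=state.phi, dphi=state.dphi, elements=state.elements,
        residual=0.0,
    )
    assert unbound_potential(s2, params) - unbound_potential(state, params) == (
        pytest.approx(math.log(2.0))
    )


# ----------------------------------------------------------------------
# passive elasticity
# ----------------------------------------------------------------------
def test_passive_energy_reference_state(params):
    assert passive_energy_density(1.0, 1.0, REGION_CYTOPLASM, params) == 0.0
    assert passive_energy_density(1.0, 1.0, REGION_NUCLEUS, params) == 0.0


def test_passive_energy_equibiaxial(params):
    lam = 1.2  # J = 1.44 > Jc: deviatoric bracket vanishes
    psi = passive_energy_density(lam, lam, REGION_CYTOPLASM, params)
    assert psi == pytest.approx(0.5 * params.kappa_C * (lam**2 - 1) ** 2)


def test_penalty_continuous_at_activation(params):
    lam = math.sqrt(params.Jc)
    below = passive_energy_density(lam * 0.9999, lam, REGION_CYTOPLASM, params)
    at = passive_energy_density(lam, lam, REGION_CYTOPLASM, params)
    no_pen = 0.5 * params.kappa_C * (params.Jc - 1) ** 2 + (
        2 * params.mu_C / params.m_C**2
    ) * ((lam / lam) ** 2.5 + 1 - 2)
    assert at == pytest.approx(no_pen)
    assert below == pytest.approx(at, rel=1e-3)  # continuity across Jc


def test_passive_stress_identity_and_symmetry(params):
    eye = np.eye(2)
    assert np.allclose(passive_stress(1.0, 1.0, eye, REGION_CYTOPLASM, params), 0.0)
    sig = passive_stress(1.3, 1.3, eye, REGION_CYTOPLASM, params)
    assert sig[0, 0] == pytest.approx(sig[1, 1])
    assert sig[0, 1] == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("region", [REGION_CYTOPLASM, REGION_NUCLEUS])
def test_passive_stress_matches_energy_derivative(params, region, rng):
    """sigma_k = lambda_k dPsi/dlambda_k via central finite differences."""
    for _ in range(5):
        lI = rng.uniform(0.8, 1.8)
        lII = rng.uniform(0.7, lI)
        h = 1e-7
        dI = (
            passive_energy_density(lI + h, lII, region, params)
            - passive_energy_density(lI - h, lII, region, params)
        ) / (2 * h)
        dII = (
            passive_energy_density(lI, lII + h, region, params)
            - passive_energy_density(lI, lII - h, region, params)
        ) / (2 * h)
        sig = passive_stress(lI, lII, np.eye(2), region, params)
        assert sig[0, 0] == pytest.approx(lI * dI, rel=1e-5, abs=1e-6)
        assert sig[1, 1] == pytest.approx(lII * dII, rel=1e-5, abs=1e-6)


# ----------------------------------------------------------------------
# active stress
# ----------------------------------------------------------------------
def test_active_stress_vanishes_without_fibres(mesh, rng):
    p = CellParameters(sigma_max=0.0, dmu_over_kBT=60.0)  # eta ~ 0
    cfg = deform(mesh, random_admissible_net(rng))
    state = solve_unbound(cfg, p)
    sig = active_stress(cfg, state, p)
    assert np.max(np.abs(sig)) < 1e-10


def test_active_stress_isotropic_closed_form(mesh, params):
    """Uniform lambda = 1: sigma_A = (pi/2) H0 sigma_max eta I."""
    cfg = deform(mesh, ControlNet.zeros())
    state = solve_unbound(cfg, params)
    sig = active_stress(cfg, state, params)
    eta = state.eta_hat[0, 0]  # uniform
    expected = 0.5 * math.pi * params.H0 * params.sigma_max * eta
    cyto = state.elements
    assert np.allclose(sig[cyto, 0, 0], expected, rtol=1e-10)
    assert np.allclose(sig[cyto, 1, 1], expected, rtol=1e-10)
    assert np.allclose(sig[cyto, 0, 1], 0.0, atol=1e-12)


def test_active_stress_single_bundle_along_x2(mesh, params):
    """A delta bundle at phi = 0 pulls only along x2."""
    cfg = deform(mesh, ControlNet.zeros())
    state = solve_unbound(cfg, params)
    eta = np.zeros_like(state.eta_hat)
    i0 = np.argmin(np.abs(state.phi))  # bin closest to phi = 0
    assert state.phi[i0] == pytest.approx(0.0, abs=state.dphi)
    eta[:, i0] = 0.3
    state.eta_hat = eta
    sig = active_stress(cfg, state, params)
    cyto = state.elements
    s0 = np.abs(state.phi[i0])
    assert np.all(sig[cyto, 1, 1] > 0)
    # 11-component scales as sin^2(phi_bin) ~ 0 for the near-axis bin
    assert np.max(np.abs(sig[cyto, 0, 0])) <= np.max(sig[cyto, 1, 1]) * (
        math.sin(s0) ** 2 / math.cos(s0) ** 2 + 1e-12
    )


# ----------------------------------------------------------------------
# total free energy
# ----------------------------------------------------------------------
def test_seeded_suspension_energy_close_to_GS(mesh, params):
    from hlecell.homeostatic import suspension_state

    s = suspension_state(params)
    net = ControlNet.affine(s.lambda_susp, s.lambda_susp)
    bd = total_free_energy(net, mesh, params, GS=s.GS)
    # uniform contraction of the whole disc also compresses the nucleus,
    # whose bulk term shifts the energy slightly above the idealised
    # suspension value (undeformed nucleus)
    assert bd.G_hat == pytest.approx(-1.0, abs=0.01)


def test_energy_additivity(mesh, params, rng):
    bd = total_free_energy(random_admissible_net(rng), mesh, params, GS=None)
    assert bd.G == pytest.approx(
        bd.cyto_term + bd.passive_cyto + bd.passive_nucleus, rel=1e-12
    )


def test_cytoskeletal_energy_collapses_to_chi_u(mesh, params, rng):
    """The full angular free-energy integral equals rho0 V_C chi_u.

    At chemical equilibrium chi_b = chi_u and conservation holds, so
    rho0 (Nu chi_u + int eta nss chi_b dphi) integrates to rho0 V_C chi_u.
    """
    cfg = deform(mesh, random_admissible_net(rng))
    state = solve_unbound(cfg, params)
    chi_b = bound_potential(state, params)
    vols = mesh.element_volumes(params)[state.elements]
    VC = vols.sum()
    integral = state.Nu_hat * state.chi_u * VC + float(
        vols @ ((state.eta_hat * state.nss_hat * chi_b).sum(axis=1) * state.dphi)
    )
    assert params.rho0_kBT_kPa * integral == pytest.approx(
        params.rho0_kBT_kPa * VC * state.chi_u, rel=1e-9
    )


def test_mu_u_shift_moves_all_energies_equally(mesh, params, rng):
    net = random_admissible_net(rng)
    net2 = random_admissible_net(rng)
    dmu = 0.7
    p2 = params.replace(mu_u_ref=params.mu_u_ref + dmu, dmu_over_kBT=params.dmu_over_kBT)
    shift = params.rho0_kBT_kPa * params.V_C * dmu
    for n in (net, net2):
        G1 = total_free_energy(n, mesh, params).G
        G2 = total_free_energy(n, mesh, p2).G
        vols = mesh.element_volumes(params)
        VC = vols[mesh.region == REGION_CYTOPLASM].sum()
        assert G2 - G1 == pytest.approx(params.rho0_kBT_kPa * VC * dmu, rel=1e-9)


def test_rotation_invariance(mesh, params):
    """Rigidly rotating a configuration leaves G unchanged (quadrature tol)."""
    base = ControlNet.affine(1.2, 0.9)
    G1 = total_free_energy(base, mesh, params).G
    th = math.radians(30)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    g = -1.0 + 2.0 * np.array([0, 1 / 3, 2 / 3, 1.0])
    # rotate the deformed positions of the affine map
    pos = np.stack(np.meshgrid(g, g, indexing="ij"), axis=-1)
    mapped = pos.copy()
    mapped[..., 0] *= 1.2
    mapped[..., 1] *= 0.9
    rotated = mapped @ R.T
    net_rot = ControlNet(rotated - pos)
    G2 = total_free_energy(net_rot, mesh, params).G
    assert G2 == pytest.approx(G1, rel=2e-3)


# ----------------------------------------------------------------------
# tractions
# ----------------------------------------------------------------------
def test_uniform_stress_interior_tractions_vanish(mesh, params):
    cfg = deform(mesh, ControlNet.zeros())
    sig = np.tile(np.array([[2.0, 0.5], [0.5, -1.0]]), (mesh.n_elements, 1, 1))
    T = traction_field(cfg, sig)
    rad = np.hypot(*mesh.nodes.T)
    interior = rad < 1.0 - 1e-6
    assert np.max(np.abs(T[interior])) < 1e-10
    # boundary carries the load; global equilibrium: nodal sum = 0
    assert np.max(np.abs(T.sum(axis=0))) < 1e-10
    assert np.max(np.abs(T[~interior])) > 1e-3


def test_manufactured_linear_stress_divergence(mesh, params):
    """T = -b div(Sigma): linear Sigma11 = x1 gives div = (1, 0) b per volume."""
    cfg = deform(mesh, ControlNet.zeros(), b0_over_R0=params.b0_over_R0)
    centroids = mesh.nodes[mesh.triangles].mean(axis=1)
    sig = np.zeros((mesh.n_elements, 2, 2))
    sig[:, 0, 0] = centroids[:, 0]  # Sigma_11 = x1
    T = traction_field(cfg, sig)
    rad = np.hypot(*mesh.nodes.T)
    interior = rad < 0.8
    # nodal equivalent force of div Sigma = (1, 0): -b * (patch area) in x1
    patch_area = np.zeros(mesh.n_nodes)
    for e, tr in enumerate(mesh.triangles):
        patch_area[tr] += mesh.areas[e] / 3.0
    expected = -params.b0_over_R0 * patch_area
    got = T[interior, 0]
    assert np.allclose(got, expected[interior], rtol=0.05, atol=2e-4)
    assert np.max(np.abs(T[interior, 1])) < 1e-3 * params.b0_over_R0


# ----------------------------------------------------------------------
# staining fields
# ----------------------------------------------------------------------
def test_staining_bound_density_isotropic(mesh, params):
    """Uniform lambda = 1: N_b = pi * eta / (1 + eps)."""
    cfg = deform(mesh, ControlNet.zeros())
    state = solve_unbound(cfg, params)
    stain = staining_fields(cfg, state)
    eta = state.eta_hat[0, 0]
    expected = math.pi * eta / 1.354
    cyto = state.elements
    assert np.allclose(stain.Nb_hat[cyto], expected, rtol=1e-6)
    nuc = mesh.region == REGION_NUCLEUS
    assert np.all(stain.Nb_hat[nuc] == 0.0)


def test_staining_zero_eta(mesh, rng):
    p = CellParameters(sigma_max=0.0, dmu_over_kBT=60.0)
    cfg = deform(mesh, random_admissible_net(rng))
    state = solve_unbound(cfg, p)
    stain = staining_fields(cfg, state)
    assert np.max(stain.Nb_hat) < 1e-8


def test_staining_delta_bundle_direction_and_ties(mesh, params):
    cfg = deform(mesh, ControlNet.zeros())
    state = solve_unbound(cfg, params)
    phi0 = state.phi[5]
    eta = np.full_like(state.eta_hat, 1e-6)
    eta[:, 5] = 0.5
    state.eta_hat = eta
    stain = staining_fields(cfg, state)
    assert np.allclose(stain.phi_max[state.elements], phi0)
    # exact tie between two symmetric bins resolves to the smaller |phi|
    eta2 = np.zeros_like(state.eta_hat)
    i_small = np.argmin(np.abs(state.phi))
    i_large = 1
    eta2[:, i_small] = 0.4
    eta2[:, i_large] = 0.4
    state.eta_hat = eta2
    state.nss_hat = np.ones_like(eta2)
    stain2 = staining_fields(cfg, state)
    assert np.allclose(stain2.phi_max[state.elements], state.phi[i_small])


def test_angular_grid_bins():
    phi, dphi = angular_grid(36)
    assert len(phi) == 36
    assert dphi == pytest.approx(math.pi / 36)
    assert phi[0] >= -math.pi / 2 and phi[-1] < math.pi / 2
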