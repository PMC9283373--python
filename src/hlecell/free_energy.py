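"""Gibbs free energy of a morphological microstate.

The cell free energy combines three ingredients:

* **Stress-fibre chemistry.**  At every cytoplasm material point, contractile
  actomyosin bundles at orientation ``phi`` (measured from the x2 axis in the
  reference configuration) carry a steady-state number of functional units
  ``n_ss = lambda(phi) / (1 + eps_ss)`` proportional to the fibre stretch.
  Bound and unbound proteins exchange until their chemical potentials are
  equal, which yields a closed form for the angular fibre concentration
  ``eta(x, phi)`` in terms of a single global unknown, the unbound fraction
  ``Nu_hat``, fixed by conservation of total stress-fibre protein.  At
  chemical equilibrium the entire cytoskeletal free energy collapses to
  ``rho0 * V_C * chi_u`` with ``chi_u`` the unbound chemical potential.

* **Passive elasticity.**  Cytoplasm and nucleus are 2D Ogden hyperelastic
  solids in the principal in-plane stretches, plus a quadratic area penalty
  activating below the compression threshold ``Jc`` that prevents unphysical
  in-plane collapse.

* **Rigid substrate.**  The substrate stores no energy and the adhesion term
  is configuration-independent on densely coated patterns, so both drop out
  of energy differences.

Energies are in kPa * R0^3; chemical potentials per packet in k_B T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidKinematicsError, SolverError
from .morphology import (
    REGION_CYTOPLASM,
    REGION_NUCLEUS,
    ControlNet,
    DeformedConfiguration,
    ReferenceMesh,
    deform,
)
from .parameters import CellParameters

__all__ = [
    "CytoskeletalState",
    "EnergyBreakdown",
    "StainingFields",
    "angular_grid",
    "steady_state_units",
    "bound_enthalpy",
    "angular_concentration",
    "fibre_stretches",
    "solve_unbound",
    "unbound_potential",
    "bound_potential",
    "passive_energy_density",
    "passive_stress",
    "active_stress",
    "total_free_energy",
    "traction_field",
    "staining_fields",
]

#: default angular resolution (36 bins of 5 degrees over a half-turn)
N_PHI_DEFAULT = 36


def angular_grid(n_phi: int = N_PHI_DEFAULT) -> tuple[np.ndarray, float]:
    """Uniform angular bins on [-pi/2, pi/2).

    Returns bin centres and the bin width.  The integrands are pi-periodic,
    so the uniform mid-point rule used throughout is the (spectrally
    accurate) trapezoid rule for periodic functions.
    """
    dphi = math.pi / n_phi
    phi = -0.5 * math.pi + (np.arange(n_phi) + 0.5) * dphi
    return phi, dphi


# ----------------------------------------------------------------------
# chemistry
# ----------------------------------------------------------------------
def steady_state_units(lambda_phi, params: CellParameters):
    """Steady-state functional-unit count n_ss (normalised by n^R).

    Fibres at stretch ``lambda`` hold ``lambda / (1 + eps_ss)`` functional
    units: stretching a bundle recruits units in series so that each unit
    sits at its steady-state strain ``eps_ss``.
    """
    lam = np.asarray(lambda_phi, dtype=float)
    if np.any(lam <= 0):
        raise InvalidKinematicsError("fibre stretch must be positive")
    return lam / (1.0 + params.eps_ss)


def bound_enthalpy(params: CellParameters) -> float:
    """Enthalpy mu_b of a bound packet at steady state, in k_B T.

    The isometric tension ``sigma_max`` acting through the packet volume
    ``Omega`` at stretch ``1 + eps_ss`` lowers the bound-state enthalpy
    relative to the reference internal energy ``mu_b0``.
    """
    return params.mu_b_over_kBT


def angular_concentration(Nu_hat, lambda_phi, params: CellParameters):
    """Equilibrium angular stress-fibre concentration eta_hat(x, phi).

    Closed form from equating bound and unbound chemical potentials.  The
    Boltzmann factor ``exp(n_ss (mu_u - mu_b) / kBT)`` is evaluated in the
    log domain so that strongly contractile parameter sets cannot overflow;
    the result saturates strictly below ``eta_max``.
    """
    Nu = np.asarray(Nu_hat, dtype=float)
    if np.any(Nu < 0) or np.any(Nu > 1):
        raise SolverError("Nu_hat must lie in [0, 1]")
    nss = steady_state_units(lambda_phi, params)
    # eta = Nu*eta_max*E / (pi*nss*eta_max + Nu*E) with E = exp(nss*delta);
    # divide through by E:   eta = Nu*eta_max / (exp(log(pi*nss*eta_max) - nss*delta) + Nu)
    log_denom = np.log(math.pi * nss * params.eta_max) - nss * params.delta_mu_net
    denom = np.exp(np.minimum(log_denom, 700.0)) + Nu
    with np.errstate(invalid="ignore"):
        eta = np.where(denom > 0.0, Nu * params.eta_max / denom, 0.0)
    return eta if np.ndim(eta) else float(eta)


def fibre_stretches(
    config: DeformedConfiguration,
    phi: np.ndarray,
    elements: np.ndarray | None = None,
) -> np.ndarray:
    """Fibre stretch lambda(x, phi) on (element x angular-bin).

    ``phi`` is measured from the x2 axis in the reference configuration; the
    stretch of a material line at reference angle phi is
    ``sqrt(m . C m)`` with ``m = (-sin phi, cos phi)`` and ``C`` the right
    Cauchy-Green tensor.
    """
    C = config.right_cauchy_green()
    if elements is not None:
        C = C[elements]
    s, c = np.sin(phi), np.cos(phi)
    lam2 = (
        np.outer(C[:, 0, 0], s**2)
        - 2.0 * np.outer(C[:, 0, 1], s * c)
        + np.outer(C[:, 1, 1], c**2)
    )
    return np.sqrt(np.maximum(lam2, 1e-300))


@dataclass
class CytoskeletalState:
    """Solved chemical equilibrium of the stress-fibre system."""

    Nu_hat: float              # global unbound fraction
    eta_hat: np.ndarray        # (n_cyto, n_phi) angular concentration
    nss_hat: np.ndarray        # (n_cyto, n_phi) functional-unit counts
    chi_u: float               # unbound chemical potential [k_B T]
    phi: np.ndarray            # angular bin centres
    dphi: float
    elements: np.ndarray       # cytoplasm element indices into the mesh
    residual: float            # conservation residual at the solution


def _conservation_residual(Nu, eta_args, vols, VC, dphi, params):
    lam = eta_args
    eta = angular_concentration(Nu, lam, params)
    nss = steady_state_units(lam, params)
    bound = float(vols @ ((eta * nss).sum(axis=1) * dphi)) / VC
    return Nu + bound - 1.0


def solve_unbound(
    config: DeformedConfiguration,
    params: CellParameters,
    n_phi: int = N_PHI_DEFAULT,
) -> CytoskeletalState:
    """Solve protein conservation for the unbound fraction ``Nu_hat``.

    The residual ``Nu + <bound fraction>(Nu) - 1`` is strictly increasing in
    ``Nu`` and brackets a root in [0, 1]; it is driven below 1e-12 here
    (the documented contract is 1e-10).
    """
    phi, dphi = angular_grid(n_phi)
    cyto = np.where(config.mesh.region == REGION_CYTOPLASM)[0]
    lam = fibre_stretches(config, phi, elements=cyto)
    vols = config.mesh.element_volumes(params)[cyto]
    VC = float(vols.sum())
    f = lambda Nu: _conservation_residual(Nu, lam, vols, VC, dphi, params)
    lo, hi = f(0.0), f(1.0)
    if lo > 0 or hi < 0:
        raise SolverError(
            f"conservation residual does not bracket a root: f(0)={lo:g}, f(1)={hi:g}"
        )
    Nu = brentq(f, 0.0, 1.0, xtol=1e-16, rtol=8.9e-16, maxiter=200)
    eta = angular_concentration(Nu, lam, params)
    nss = steady_state_units(lam, params)
    chi_u = params.mu_u_ref + math.log(max(Nu, 1e-300)) - params.log_pi_NL
    return CytoskeletalState(
        Nu_hat=float(Nu),
        eta_hat=eta,
        nss_hat=nss,
        chi_u=float(chi_u),
        phi=phi,
        dphi=dphi,
        elements=cyto,
        residual=float(f(Nu)),
    )


def unbound_potential(state: CytoskeletalState, params: CellParameters) -> float:
    """Unbound chemical potential chi_u [k_B T]; stress-independent."""
    if state.Nu_hat <= 0:
        raise SolverError("chi_u diverges: Nu_hat = 0")
    return params.mu_u_ref + math.log(state.Nu_hat) - params.log_pi_NL


def bound_potential(state: CytoskeletalState, params: CellParameters) -> np.ndarray:
    """Bound chemical potential chi_b(x, phi) [k_B T].

    At the solved equilibrium this equals ``chi_u`` everywhere (used as an
    internal consistency check).
    """
    eta, nss = state.eta_hat, state.nss_hat
    ratio = (math.pi * eta * nss) / (
        state.Nu_hat * (1.0 - eta / params.eta_max)
    )
    return (
        params.mu_b_over_kBT
        + np.log(ratio) / nss
        + math.log(state.Nu_hat) - params.log_pi_NL
    )


# ----------------------------------------------------------------------
# passive elasticity
# ----------------------------------------------------------------------
def _region_moduli(region: int, params: CellParameters) -> tuple[float, float, float]:
    if region == REGION_NUCLEUS:
        return params.mu_N, params.m_N, params.kappa_N
    return params.mu_C, params.m_C, params.kappa_C


def passive_energy_density(lI, lII, region: int, params: CellParameters):
    """2D Ogden strain-energy density [kPa] incl. the compression penalty.

    ``Psi = (2 mu / m^2) [ (lI/lII)^(m/2) + (lII/lI)^(m/2) - 2 ]
            + (kappa/2) (lI lII - 1)^2 + P``

    with ``P = kappa_bar * (J - Jc)^2`` for ``J = lI lII < Jc`` (zero above,
    continuous at the activation threshold).
    """
    lI = np.asarray(lI, dtype=float)
    lII = np.asarray(lII, dtype=float)
    if np.any(lI <= 0) or np.any(lII <= 0):
        raise InvalidKinematicsError("principal stretches must be positive")
    mu, m, kappa = _region_moduli(region, params)
    ratio = lI / lII
    dev = (2.0 * mu / m**2) * (ratio ** (m / 2.0) + ratio ** (-m / 2.0) - 2.0)
    J = lI * lII
    bulk = 0.5 * kappa * (J - 1.0) ** 2
    pen = np.where(J < params.Jc, params.kappa_bar * (J - params.Jc) ** 2, 0.0)
    return dev + bulk + pen


def _principal_passive(lI, lII, region, params):
    """Principal Cauchy stresses sigma_k = lambda_k dPsi/dlambda_k [kPa]."""
    mu, m, kappa = _region_moduli(region, params)
    ratio = np.asarray(lI, dtype=float) / np.asarray(lII, dtype=float)
    dev = (mu / m) * (ratio ** (m / 2.0) - ratio ** (-m / 2.0))
    J = np.asarray(lI) * np.asarray(lII)
    bulk = kappa * (J - 1.0) * J
    pen = np.where(J < params.Jc, 2.0 * params.kappa_bar * (J - params.Jc) * J, 0.0)
    return dev + bulk + pen, -dev + bulk + pen


def passive_stress(lI, lII, principal_dirs, region: int, params: CellParameters):
    """Passive Cauchy stress tensor(s) rotated to the x1-x2 frame."""
    sI, sII = _principal_passive(lI, lII, region, params)
    dirs = np.asarray(principal_dirs, dtype=float)
    single = dirs.ndim == 2
    if single:
        dirs = dirs[None]
        sI, sII = np.atleast_1d(sI), np.atleast_1d(sII)
    vI, vII = dirs[:, :, 0], dirs[:, :, 1]
    sig = (
        sI[:, None, None] * np.einsum("ei,ej->eij", vI, vI)
        + sII[:, None, None] * np.einsum("ei,ej->eij", vII, vII)
    )
    return sig[0] if single else sig


# ----------------------------------------------------------------------
# active stress
# ----------------------------------------------------------------------
def active_stress(
    config: DeformedConfiguration,
    state: CytoskeletalState,
    params: CellParameters,
) -> np.ndarray:
    """Active Cauchy stress per mesh element [kPa] (zero in the nucleus).

    Angular quadrature of the fibre tension: each bundle at reference angle
    phi contributes ``H0 sigma_max eta lambda(phi)`` along its push-forward
    direction ``F m / |F m|`` in the deformed configuration.
    """
    m_el = config.mesh.n_elements
    sig = np.zeros((m_el, 2, 2))
    phi, dphi = state.phi, state.dphi
    mdir = np.stack([-np.sin(phi), np.cos(phi)], axis=0)  # (2, n_phi)
    F = config.F[state.elements]
    Fm = np.einsum("eij,jk->eik", F, mdir)  # (n_cyto, 2, n_phi)
    norm = np.linalg.norm(Fm, axis=1, keepdims=True)
    mhat = Fm / np.maximum(norm, 1e-300)
    lam = norm[:, 0, :]
    w = params.H0 * params.sigma_max * state.eta_hat * lam * dphi
    s_cyto = np.einsum("ek,eik,ejk->eij", w, mhat, mhat)
    sig[state.elements] = s_cyto
    return sig


# ----------------------------------------------------------------------
# total free energy
# ----------------------------------------------------------------------
@dataclass
class EnergyBreakdown:
    """Additive decomposition of the microstate Gibbs free energy."""

    G: float                 # total [kPa R0^3]
    G_hat: float             # G / |G_S| (nan if no reference supplied)
    cyto_term: float         # rho0 V_C chi_u
    passive_cyto: float      # integral of Psi_C (includes its penalty part)
    passive_nucleus: float   # integral of Psi_N (includes its penalty part)
    penalty_term: float      # penalty contribution inside the Psi integrals
    Nu_hat: float
    state: CytoskeletalState


def total_free_energy(
    net: ControlNet | DeformedConfiguration,
    mesh: ReferenceMesh,
    params: CellParameters,
    GS: float | None = None,
    n_phi: int = N_PHI_DEFAULT,
) -> EnergyBreakdown:
    """Gibbs free energy of a microstate on a rigid substrate.

    ``G = rho0 V_C chi_u + int Psi_C dV + int Psi_N dV``; the substrate term
    vanishes (rigid) and the adhesion term is dropped as configuration-
    independent.  Volume integrals use reference-configuration quadrature
    (equal to current volumes by incompressibility).
    """
    config = (
        net
        if isinstance(net, DeformedConfiguration)
        else deform(mesh, net, b0_over_R0=params.b0_over_R0)
    )
    state = solve_unbound(config, params, n_phi=n_phi)
    chi_u = state.chi_u
    vols = config.mesh.element_volumes(params)
    VC = float(vols[config.mesh.region == REGION_CYTOPLASM].sum())
    cyto_term = params.rho0_kBT_kPa * VC * chi_u
    passive = {REGION_CYTOPLASM: 0.0, REGION_NUCLEUS: 0.0}
    penalty = 0.0
    for region in (REGION_CYTOPLASM, REGION_NUCLEUS):
        sel = config.mesh.region == region
        psi = passive_energy_density(config.lI[sel], config.lII[sel], region, params)
        passive[region] = float(vols[sel] @ psi)
        J = config.lI[sel] * config.lII[sel]
        pen = np.where(J < params.Jc, params.kappa_bar * (J - params.Jc) ** 2, 0.0)
        penalty += float(vols[sel] @ pen)
    G = cyto_term + passive[REGION_CYTOPLASM] + passive[REGION_NUCLEUS]
    return EnergyBreakdown(
        G=G,
        G_hat=G / abs(GS) if GS else float("nan"),
        cyto_term=cyto_term,
        passive_cyto=passive[REGION_CYTOPLASM],
        passive_nucleus=passive[REGION_NUCLEUS],
        penalty_term=penalty,
        Nu_hat=state.Nu_hat,
        state=state,
    )


# ----------------------------------------------------------------------
# tractions and staining
# ----------------------------------------------------------------------
def traction_field(
    config: DeformedConfiguration,
    total_stress: np.ndarray,
) -> np.ndarray:
    """Nodal substrate tractions T_i = -b * div(Sigma) [kPa * R0].

    Assembled as nodal-equivalent internal forces on the deformed mesh with
    the current thickness ``b = b0 / (lI lII)``: the substrate traction on
    each node is exactly the force needed to equilibrate the cell stress
    there.  Interior tractions vanish for a uniform stress field and the
    nodal sum vanishes identically (global equilibrium).
    """
    mesh = config.mesh
    x, tri = config.x, mesh.triangles
    d1 = x[tri[:, 1]] - x[tri[:, 0]]
    d2 = x[tri[:, 2]] - x[tri[:, 0]]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    area = 0.5 * np.abs(det)
    # gradients of the linear shape functions in deformed coordinates
    dm = np.stack([d1, d2], axis=-1)
    dminv = np.linalg.inv(dm)
    gradN = np.empty((len(tri), 3, 2))
    gradN[:, 1, :] = dminv[:, 0, :]
    gradN[:, 2, :] = dminv[:, 1, :]
    gradN[:, 0, :] = -gradN[:, 1, :] - gradN[:, 2, :]
    b = config.thickness
    f_el = np.einsum("e,eij,enj->eni", area * b, total_stress, gradN)
    T = np.zeros_like(x)
    np.add.at(T, tri.reshape(-1), f_el.reshape(-1, 2))
    return T


@dataclass
class StainingFields:
    """Pseudo-staining maps derived from the internal state variables."""

    Nb_hat: np.ndarray        # (m,) bound density per element (0 in nucleus)
    phi_max: np.ndarray       # (m,) dominant fibre direction [rad from x2]
    traction_mag: np.ndarray  # (n_nodes,) |T| [kPa R0]


def staining_fields(
    config: DeformedConfiguration,
    state: CytoskeletalState,
    tractions: np.ndarray | None = None,
) -> StainingFields:
    """Actin-like and adhesion-like visualisation fields.

    ``Nb_hat`` is the angular integral of ``eta * n_ss`` (local bound
    density); ``phi_max`` the bin direction maximising ``eta * n_ss`` with
    ties broken toward the smallest ``|phi|``; traction magnitudes act as a
    focal-adhesion proxy.
    """
    m_el = config.mesh.n_elements
    Nb = np.zeros(m_el)
    phim = np.zeros(m_el)
    v = state.eta_hat * state.nss_hat
    Nb[state.elements] = v.sum(axis=1) * state.dphi
    vmax = v.max(axis=1, keepdims=True)
    is_max = v >= vmax * (1.0 - 1e-12)
    cost = np.where(is_max, np.abs(state.phi)[None, :], np.inf)
    phim[state.elements] = state.phi[np.argmin(cost, axis=1)]
    if tractions is None:
        tmag = np.zeros(len(config.x))
    else:
        tmag = np.linalg.norm(tractions, axis=1)
    return StainingFields(Nb_hat=Nb, phi_max=phim, traction_mag=tmag)
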