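"""Reduced two-degree-of-freedom ellipse model of cell spreading.

The cell is restricted to a spatially uniform ellipse with axes along
x1/x2: the homogeneous deformation ``F = diag(lambda1, lambda2)`` of the
reference disc fully specifies the morphology.  The full free-energy model
(chemistry + Ogden elasticity for cytoplasm and nucleus) is evaluated for
this deformation, giving a 2D energy landscape ``G_hat(lambda1, lambda2)``
whose gradient flow

    dlambda_i/dt_hat = -dG_hat/dlambda_i

reproduces the two morphological timescales: a fast spreading regime
(area grows at aspect ratio ~ 1) followed by a slow elongation regime
(aspect ratio grows at nearly constant area), set purely by the topology of
the landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidKinematicsError, SolverError
from .free_energy import angular_concentration, steady_state_units
from .parameters import CellParameters

__all__ = ["EllipseState", "ellipse_energy", "ellipse_gradient",
           "gradient_flow", "landscape_map", "suspension_start"]

#: angular quadrature for the uniform-field conservation integral; the
#: integrand is smooth and pi-periodic, so 256 uniform bins are effectively
#: exact (periodic trapezoid rule converges spectrally)
N_PHI_REDUCED = 256


@dataclass(frozen=True)
class EllipseState:
    """Principal-axis stretches of the uniform elliptical cell."""

    l1: float
    l2: float

    def __post_init__(self) -> None:
        if self.l1 <= 0 or self.l2 <= 0:
            raise InvalidKinematicsError("ellipse stretches must be positive")

    @property
    def area(self) -> float:
        """Cell area lambda1 lambda2 pi R0^2."""
        return self.l1 * self.l2 * math.pi

    @property
    def aspect_ratio(self) -> float:
        return max(self.l1, self.l2) / min(self.l1, self.l2)


def _uniform_field_chemistry(l1, l2, params, n_phi=N_PHI_REDUCED):
    dphi = math.pi / n_phi
    phi = -0.5 * math.pi + (np.arange(n_phi) + 0.5) * dphi
    lam = np.sqrt((l1 * np.sin(phi)) ** 2 + (l2 * np.cos(phi)) ** 2)
    nss = steady_state_units(lam, params)

    def res(Nu):
        eta = angular_concentration(Nu, lam, params)
        return Nu + float((eta * nss).sum() * dphi) - 1.0

    Nu = brentq(res, 0.0, 1.0, xtol=1e-16, rtol=8.9e-16)
    return float(Nu)


def _psi(l1, l2, mu, m, kappa, params):
    lI, lII = max(l1, l2), min(l1, l2)
    ratio = lI / lII
    dev = (2.0 * mu / m**2) * (ratio ** (m / 2.0) + ratio ** (-m / 2.0) - 2.0)
    J = lI * lII
    bulk = 0.5 * kappa * (J - 1.0) ** 2
    pen = params.kappa_bar * (J - params.Jc) ** 2 if J < params.Jc else 0.0
    return dev + bulk + pen, pen > 0


def ellipse_energy(
    l1: float,
    l2: float,
    params: CellParameters | None = None,
    GS: float | None = None,
    n_phi: int = N_PHI_REDUCED,
) -> float:
    """Free energy of the uniform elliptical cell.

    Homogeneous deformation of the whole reference disc (the nucleus
    deforms affinely with the cytoplasm); single global conservation solve
    with the analytic uniform stretch field ``lambda(phi)^2 =
    l1^2 sin^2 phi + l2^2 cos^2 phi``.  Returns ``G`` in kPa R0^3, or
    ``G/|G_S|`` if a reference energy is supplied.  Symmetric under
    ``l1 <-> l2``.
    """
    if l1 <= 0 or l2 <= 0:
        raise InvalidKinematicsError("stretches must be positive")
    params = params or CellParameters()
    Nu = _uniform_field_chemistry(l1, l2, params, n_phi)
    chi_u = params.mu_u_ref + math.log(Nu) - params.log_pi_NL
    psi_C, _ = _psi(l1, l2, params.mu_C, params.m_C, params.kappa_C, params)
    psi_N, _ = _psi(l1, l2, params.mu_N, params.m_N, params.kappa_N, params)
    G = params.rho0_kBT_kPa * params.V_C * chi_u + params.V_C * psi_C + params.V_N * psi_N
    return G / abs(GS) if GS else G


def penalty_active(l1: float, l2: float, params: CellParameters | None = None) -> bool:
    """True when the compression penalty dominates at (l1, l2)."""
    params = params or CellParameters()
    return l1 * l2 < params.Jc


def ellipse_gradient(l1, l2, params=None, GS=None, h=1e-6, n_phi=N_PHI_REDUCED):
    """Central-difference gradient of the landscape at (l1, l2)."""
    gp = lambda a, b: ellipse_energy(a, b, params, GS, n_phi=n_phi)
    return np.array(
        [
            (gp(l1 + h, l2) - gp(l1 - h, l2)) / (2 * h),
            (gp(l1, l2 + h) - gp(l1, l2 - h)) / (2 * h),
        ]
    )


def suspension_start(
    params: CellParameters | None = None,
    asymmetry: float = 1e-3,
) -> EllipseState:
    """Seeding state: the suspension circle with a tiny symmetry break.

    Pure gradient flow started exactly on the symmetric diagonal stays
    symmetric forever (the symmetric spread state is a saddle); a small
    ``l1`` excess lets the elongation regime develop deterministically.
    The default 1e-3 is large enough to outgrow the stopping tolerance in
    a few time units; smaller values give the same path with a delayed
    regime-II onset.
    """
    from .homeostatic import suspension_state

    lam = suspension_state(params).lambda_susp
    return EllipseState(lam * (1.0 + asymmetry), lam)


@dataclass
class FlowResult:
    t_hat: np.ndarray     # (F,)
    l1: np.ndarray
    l2: np.ndarray
    G_hat: np.ndarray
    converged: bool

    @property
    def area_ratio(self) -> np.ndarray:
        """A / A_R with A_R the suspension-circle area."""
        lam_R = math.sqrt(self.l1[0] * self.l2[0])
        return self.l1 * self.l2 / lam_R**2

    @property
    def aspect_ratio(self) -> np.ndarray:
        return np.maximum(self.l1, self.l2) / np.minimum(self.l1, self.l2)


def gradient_flow(
    start: EllipseState,
    params: CellParameters | None = None,
    dt_hat: float = 5e-3,
    tol: float = 1e-4,
    max_steps: int = 20_000,
    record_every: int = 20,
    GS: float | None = None,
    n_phi: int = 128,
) -> FlowResult:
    """Deterministic steepest-descent path of the ellipse landscape.

    Forward-Euler flow until ``||grad G_hat|| < tol`` (or ``max_steps``,
    in which case ``converged`` is False and the partial path returned).
    """
    params = params or CellParameters()
    if GS is None:
        from .homeostatic import suspension_state

        GS = suspension_state(params).GS
    l = np.array([start.l1, start.l2], dtype=float)
    ts, l1s, l2s, Gs = [], [], [], []
    converged = False
    for step in range(max_steps + 1):
        g = ellipse_gradient(l[0], l[1], params, GS, n_phi=n_phi)
        if step % record_every == 0:
            ts.append(step * dt_hat)
            l1s.append(l[0])
            l2s.append(l[1])
            Gs.append(ellipse_energy(l[0], l[1], params, GS, n_phi=n_phi))
        if np.linalg.norm(g) < tol:
            if step % record_every != 0:
                ts.append(step * dt_hat)
                l1s.append(l[0])
                l2s.append(l[1])
                Gs.append(ellipse_energy(l[0], l[1], params, GS, n_phi=n_phi))
            converged = True
            break
        l = l - dt_hat * g
        if np.any(l <= 0):
            raise SolverError("gradient flow left the positive-stretch domain")
    return FlowResult(
        t_hat=np.array(ts), l1=np.array(l1s), l2=np.array(l2s),
        G_hat=np.array(Gs), converged=converged,
    )


def landscape_map(
    l1_grid: np.ndarray,
    l2_grid: np.ndarray,
    params: CellParameters | None = None,
    GS: float | None = None,
):
    """Normalised free-energy landscape plus isoline families.

    Returns a dict with the ``G_hat`` array over the grid, the
    ``A / A_R = l1 l2 / lambda_susp^2`` and ``AS = l1 / l2`` isoline fields
    and a mask of penalty-dominated grid points.
    """
    params = params or CellParameters()
    if GS is None:
        from .homeostatic import suspension_state

        susp = suspension_state(params)
        GS, lam_R = susp.GS, susp.lambda_susp
    else:
        from .homeostatic import suspension_state

        lam_R = suspension_state(params).lambda_susp
    l1_grid = np.asarray(l1_grid, float)
    l2_grid = np.asarray(l2_grid, float)
    G = np.empty((len(l1_grid), len(l2_grid)))
    pen = np.zeros_like(G, dtype=bool)
    for i, a in enumerate(l1_grid):
        for j, b in enumerate(l2_grid):
            G[i, j] = ellipse_energy(a, b, params, GS)
            pen[i, j] = penalty_active(a, b, params)
    L1, L2 = np.meshgrid(l1_grid, l2_grid, indexing="ij")
    return {
        "l1": l1_grid,
        "l2": l2_grid,
        "G_hat": G,
        "area_ratio": L1 * L2 / lam_R**2,
        "aspect_ratio": np.maximum(L1, L2) / np.minimum(L1, L2),
        "penalty_active": pen,
    }
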