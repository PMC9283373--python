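"""High-level cell model binding mesh + parameters + substrate pattern.

``CellModel`` packs everything the compiled kernels need, exposes scalar
energy/gradient evaluation for a 32-component control vector, and carries the
suspension reference energy ``G_S`` used to normalise the free energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import InadmissibleMicrostateError
from .free_energy import N_PHI_DEFAULT, angular_grid, total_free_energy
from .morphology import (
    ControlNet,
    ReferenceMesh,
    StripePattern,
    build_reference_mesh,
    deform,
)
from .parameters import CellParameters

__all__ = ["CellModel"]


def _consts_vector(p: CellParameters, lambda_max: float) -> np.ndarray:
    return np.array(
        [
            p.eps_ss,
            p.delta_mu_net,
            p.eta_max,
            p.rho0_kBT_kPa,
            p.mu_C,
            p.m_C,
            p.kappa_C,
            p.mu_N,
            p.m_N,
            p.kappa_N,
            p.kappa_bar,
            p.Jc,
            p.mu_u_ref,
            p.log_pi_NL,
            p.b0_over_R0,
            lambda_max,
        ]
    )


@dataclass
class _KernelArgs:
    basis: np.ndarray
    X: np.ndarray
    tri: np.ndarray
    Dinv: np.ndarray
    region: np.ndarray
    vols: np.ndarray
    sphi: np.ndarray
    cphi: np.ndarray
    dphi: float
    consts: np.ndarray

    def as_tuple(self):
        return (
            self.basis, self.X, self.tri, self.Dinv, self.region, self.vols,
            self.sphi, self.cphi, self.dphi, self.consts,
        )


class CellModel:
    """Free-energy evaluator for morphological microstates.

    Parameters
    ----------
    params
        Material/chemical parameter set.
    mesh
        Reference triangulation; built at ``target_edge`` if omitted.
    pattern
        Substrate pattern (unpatterned by default).
    n_phi
        Angular quadrature bins over ``[-pi/2, pi/2)``.
    barrier_stiffness
        Quartic stripe-barrier stiffness used by the Langevin integrator,
        in normalised-energy units per node.
    lambda_max
        Admissibility cap on the local major principal stretch.  The
        fibre-recruitment chemistry (functional units proportional to
        stretch) and the moderate-strain Ogden calibration are not meant
        for many-fold local stretches; microstates containing them are
        excluded from the morphological ensemble.
    """

    def __init__(
        self,
        params: CellParameters | None = None,
        mesh: ReferenceMesh | None = None,
        pattern: StripePattern | None = None,
        n_phi: int = N_PHI_DEFAULT,
        barrier_stiffness: float = 1.0e4,
        target_edge: float = 0.1,
        lambda_max: float = 4.0,
    ) -> None:
        self.params = params or CellParameters()
        self.mesh = mesh or build_reference_mesh(self.params, target_edge=target_edge)
        self.pattern = pattern or StripePattern()
        self.n_phi = n_phi
        self.barrier_stiffness = float(barrier_stiffness)
        self.lambda_max = float(lambda_max)
        phi, dphi = angular_grid(n_phi)
        self.phi = phi
        self._args = _KernelArgs(
            basis=np.ascontiguousarray(self.mesh.basis),
            X=np.ascontiguousarray(self.mesh.nodes),
            tri=np.ascontiguousarray(self.mesh.triangles.astype(np.int64)),
            Dinv=np.ascontiguousarray(self.mesh.Dinv),
            region=np.ascontiguousarray(self.mesh.region.astype(np.int64)),
            vols=np.ascontiguousarray(self.mesh.element_volumes(self.params)),
            sphi=np.sin(phi),
            cphi=np.cos(phi),
            dphi=dphi,
            consts=_consts_vector(self.params, self.lambda_max),
        )
        self._suspension = None

    # ------------------------------------------------------------------
    @property
    def w_half(self) -> float:
        return self.pattern.half_width if self.pattern.patterned else math.inf

    @property
    def suspension(self):
        """Suspension reference state (solved lazily and cached)."""
        if self._suspension is None:
            from .homeostatic import suspension_state

            self._suspension = suspension_state(self.params)
        return self._suspension

    @property
    def GS(self) -> float:
        return self.suspension.GS

    @property
    def GS_abs(self) -> float:
        return abs(self.suspension.GS)

    @property
    def G_hat_S(self) -> float:
        """Normalised suspension energy, i.e. sign(G_S)."""
        return math.copysign(1.0, self.GS)

    def seeded_net(self) -> ControlNet:
        """Microstate of the cell freshly seeded from suspension.

        Uniform equibiaxial contraction to the suspension stretch, centred
        on the origin (the stripe axis for patterned substrates).
        """
        lam = self.suspension.lambda_susp
        return ControlNet.affine(lam, lam)

    # ------------------------------------------------------------------
    # energy evaluation
    # ------------------------------------------------------------------
    def energy_raw(self, c: np.ndarray, Nu_warm: float = 0.1):
        """Kernel energy: returns (G [kPa R0^3], barrier, Nu_hat, status)."""
        return _kernels.energy_kernel(
            np.ascontiguousarray(c, dtype=float),
            *self._args.as_tuple(),
            self.w_half,
            self.barrier_stiffness,
            Nu_warm,
        )

    def energy(self, c: np.ndarray) -> float:
        """Gibbs free energy [kPa R0^3]; raises on inadmissible kinematics."""
        G, _, _, status = self.energy_raw(c)
        if status != _kernels.OK:
            raise InadmissibleMicrostateError(f"energy kernel status {status}")
        return G

    def energy_hat(self, c: np.ndarray, with_barrier: bool = True) -> float:
        """Normalised free energy G/|G_S| (+ stripe barrier for dynamics)."""
        G, barrier, _, status = self.energy_raw(c)
        if status != _kernels.OK:
            raise InadmissibleMicrostateError(f"energy kernel status {status}")
        return G / self.GS_abs + (barrier if with_barrier else 0.0)

    def gradient_hat(self, c: np.ndarray, h: float = 1e-6):
        """Plain central-difference gradient of the normalised total energy."""
        g, status = _kernels.gradient_kernel(
            np.ascontiguousarray(c, dtype=float),
            h,
            self.GS_abs,
            *self._args.as_tuple(),
            self.w_half,
            self.barrier_stiffness,
            0.1,
        )
        if status != _kernels.OK:
            raise InadmissibleMicrostateError(f"gradient kernel status {status}")
        return g

    def admissible(self, c: np.ndarray) -> bool:
        """Fold-over-free and (for MCMC-style hard constraints) on-stripe."""
        _, _, _, status = self.energy_raw(c)
        if status != _kernels.OK:
            return False
        if self.pattern.patterned:
            x = self.mesh.nodes[:, 0] + self.mesh.basis @ np.asarray(c).reshape(16, 2)[:, 0]
            return bool(np.all(np.abs(x) <= self.w_half))
        return True

    # ------------------------------------------------------------------
    def breakdown(self, net: ControlNet | np.ndarray, GS: float | None = None):
        """Full reference-path energy breakdown (numpy implementation)."""
        if not isinstance(net, ControlNet):
            net = ControlNet.from_flat(net)
        return total_free_energy(
            net,
            self.mesh,
            self.params,
            GS=self.GS if GS is None else GS,
            n_phi=self.n_phi,
        )

    def deformed(self, net: ControlNet | np.ndarray):
        if not isinstance(net, ControlNet):
            net = ControlNet.from_flat(net)
        return deform(self.mesh, net, b0_over_R0=self.params.b0_over_R0)

    def kernel_args(self):
        return self._args.as_tuple()
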