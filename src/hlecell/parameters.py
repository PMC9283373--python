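"""Material, chemical and geometric parameters of the single-cell model.

The cell is an incompressible 2D body (thickness ``b0``) of radius ``R0`` in
its elastic resting state, with a concentric nucleus of radius ``R_N``.  Its
free energy combines an active stress-fibre cytoskeleton (chemical potentials
of bound/unbound actomyosin functional units) with passive 2D Ogden
hyperelasticity of cytoplasm and nucleus.

Internal unit system
--------------------
* lengths in units of ``R0`` (so ``R0 = 1`` everywhere),
* stresses, moduli and energy densities in kPa,
* energies in kPa * R0^3,
* chemical potentials per protein packet in units of ``k_B T``.

The bridge between the chemical and mechanical scales is the protein packet
density ``rho0``: ``rho0 * k_B * T`` expressed in kPa (about 12.84 kPa for the
default fibroblast values) multiplies the per-packet potential ``chi_u``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError

#: Boltzmann constant [J/K]
K_BOLTZMANN = 1.380649e-23

#: 1 kPa * um^3 expressed in joules (1e3 Pa * 1e-18 m^3)
KPA_UM3_TO_J = 1.0e-15

#: 1 J / um^3 expressed in kPa
J_PER_UM3_TO_KPA = 1.0e15


@dataclass(frozen=True)
class CellParameters:
    """Complete parameter set of the cell free-energy model.

    Defaults are the fibroblast (myofibroblast) calibration.  All moduli are
    in kPa, the temperature in K, ``Omega`` is carried as ``log10`` of its
    value in um^3, and ``dmu_over_kBT`` is the difference between the
    reference bound and unbound chemical potentials ``mu_b0 - mu_u`` in units
    of ``k_B T`` (per packet of ``n^R`` functional units).

    ``NL_hat`` (the normalised number of lattice sites available to unbound
    proteins) and ``mu_u_ref`` (the unbound internal energy per packet, in
    ``k_B T``) have no independent calibration; the defaults ``pi * NL_hat = 1``
    and ``mu_u_ref = 0`` fix the absolute scale of the free energy.  A
    constant shift of ``mu_u_ref`` shifts the energy of every configuration
    by the same amount and therefore changes only the normalisation of the
    dimensionless free energy, not the physics.
    """

    T_K: float = 310.0
    dmu_over_kBT: float = 1.0
    sigma_max: float = 240.0
    eps_ss: float = 0.354
    eta_max: float = 0.75
    rho0_per_um3: float = 3.0e6
    mu_C: float = 1.67
    m_C: float = 5.0
    kappa_C: float = 35.0
    mu_N: float = 3.3
    m_N: float = 20.0
    kappa_N: float = 35.0
    b0_over_R0: float = 0.05
    RN_over_R0: float = 0.256 * math.sqrt(math.pi)
    H0: float = 0.032
    Omega_log10_um3: float = -7.1
    kappa_bar: float = 1.0e5
    Jc: float = 0.6
    NL_hat: float = 1.0 / math.pi
    mu_u_ref: float = 0.0

    def __post_init__(self) -> None:
        nonneg = (
            "sigma_max mu_C kappa_C mu_N kappa_N kappa_bar rho0_per_um3 H0"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.T_K <= 0:
            raise ParameterError("T_K must be positive")
        if not 0.0 < self.eta_max <= 1.0:
            raise ParameterError("eta_max must lie in (0, 1]")
        if not 0.0 < self.Jc < 1.0:
            raise ParameterError("Jc must lie in (0, 1)")
        if self.eps_ss <= -1.0:
            raise ParameterError("eps_ss must exceed -1")
        if not 0.0 < self.RN_over_R0 < 1.0:
            raise ParameterError("RN_over_R0 must lie in (0, 1)")
        if self.b0_over_R0 <= 0:
            raise ParameterError("b0_over_R0 must be positive")
        if self.NL_hat <= 0:
            raise ParameterError("NL_hat must be positive")

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    @property
    def kBT_J(self) -> float:
        """Thermal energy k_B T [J]."""
        return K_BOLTZMANN * self.T_K

    @property
    def Omega_um3(self) -> float:
        """Volume of one packet of n^R functional units [um^3]."""
        return 10.0 ** self.Omega_log10_um3

    @property
    def sigma_omega_over_kBT(self) -> float:
        """Mechanical work scale sigma_max * Omega / (k_B T), dimensionless."""
        return self.sigma_max * self.Omega_um3 * KPA_UM3_TO_J / self.kBT_J

    @property
    def mu_b_over_kBT(self) -> float:
        """Bound-packet enthalpy mu_b / k_B T (isometric-tension corrected)."""
        mu_b0 = self.mu_u_ref + self.dmu_over_kBT
        return mu_b0 - self.sigma_omega_over_kBT * (1.0 + self.eps_ss)

    @property
    def delta_mu_net(self) -> float:
        """(mu_u - mu_b) / k_B T, the driving force for fibre assembly."""
        return self.mu_u_ref - self.mu_b_over_kBT

    @property
    def rho0_kBT_kPa(self) -> float:
        """rho0 * k_B T as an energy density [kPa]."""
        return self.rho0_per_um3 * self.kBT_J * J_PER_UM3_TO_KPA

    @property
    def log_pi_NL(self) -> float:
        """log(pi * NL_hat), the lattice-entropy offset of chi_u."""
        return math.log(math.pi * self.NL_hat)

    @property
    def V_C(self) -> float:
        """Reference cytoplasm volume [R0^3]."""
        return math.pi * (1.0 - self.RN_over_R0**2) * self.b0_over_R0

    @property
    def V_N(self) -> float:
        """Reference nucleus volume [R0^3]."""
        return math.pi * self.RN_over_R0**2 * self.b0_over_R0

    # ------------------------------------------------------------------
    # config file round trip
    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "CellParameters":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "CellParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown parameter key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**{k: float(v) for k, v in data.items()})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "CellParameters":
        """Load a flat key-value parameter file; absent keys take defaults."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"parameter file {path} is not a key-value map")
        return cls.from_dict(data)
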