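"""Suspension reference state, homeostatic-ensemble sampling and calibration.

A cell in suspension must self-equilibrate: the compressive elastic stress of
the cytoplasm balances the tensile stress of a spatially uniform stress-fibre
distribution, fixing a unique equibiaxial stretch ``lambda_susp`` (the
nucleus stays undeformed) and the reference Gibbs energy ``G_S``.

On a substrate the cell fluctuates over morphological microstates with
stationary probability ``P propto exp(-zeta * G)``.  The distribution
parameter ``zeta`` is not free: it is calibrated so that the ensemble mean
free energy equals the suspension value, ``<G> = G_S`` (the homeostatic
constraint).  ``1/zeta_hat = 1/(zeta |G_S|)`` plays the role of a
(non-thermal) homeostatic temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .errors import ParameterError, SolverError
from .free_energy import angular_concentration, steady_state_units
from .model import CellModel
from .parameters import CellParameters

__all__ = [
    "SuspensionState",
    "MCMCResult",
    "HomeostaticCalibration",
    "suspension_state",
    "uniform_equibiaxial_stress",
    "metropolis",
    "mcmc_sample",
    "calibrate_zeta_generic",
    "calibrate_zeta",
]


# ----------------------------------------------------------------------
# suspension state
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SuspensionState:
    lambda_susp: float      # uniform cytoplasm stretch
    radius_ratio: float     # deformed cell radius / R0
    GS: float               # suspension Gibbs energy [kPa R0^3]
    Nu_hat: float
    eta_hat: float
    stress_residual: float  # |Sigma(lambda_susp)| [kPa]


def _uniform_chemistry(lam: float, params: CellParameters) -> tuple[float, float, float]:
    """Solve conservation for a spatially uniform stretch field."""
    nss = float(steady_state_units(lam, params))

    def res(Nu):
        eta = float(angular_concentration(Nu, lam, params))
        return Nu + math.pi * eta * nss - 1.0

    Nu = brentq(res, 0.0, 1.0, xtol=1e-16, rtol=8.9e-16)
    eta = float(angular_concentration(Nu, lam, params))
    return Nu, eta, nss


def uniform_equibiaxial_stress(lam: float, params: CellParameters) -> float:
    """Total in-plane Cauchy stress of a uniform equibiaxial cytoplasm [kPa].

    Active part: the isotropic angular integral
    ``(pi/2) H0 sigma_max eta lambda``.  Passive part: the equibiaxial Ogden
    stress (deviatoric term vanishes by symmetry) ``kappa_C J (J - 1)`` plus
    the compression penalty below ``Jc``.
    """
    Nu, eta, _ = _uniform_chemistry(lam, params)
    active = 0.5 * math.pi * params.H0 * params.sigma_max * eta * lam
    J = lam * lam
    passive = params.kappa_C * J * (J - 1.0)
    if J < params.Jc:
        passive += 2.0 * params.kappa_bar * (J - params.Jc) * J
    return active + passive


def suspension_state(params: CellParameters | None = None) -> SuspensionState:
    """Traction-free suspension configuration and reference energy ``G_S``.

    Solves the 1-DOF condition ``Sigma(lambda) = 0`` for the uniform
    equibiaxial cytoplasm stretch (undeformed nucleus carries no stress and
    no stress-fibres), then evaluates the free energy at that state.
    """
    params = params or CellParameters()
    f = lambda lam: uniform_equibiaxial_stress(lam, params)
    lo, hi = 0.3, 1.5
    if f(lo) * f(hi) > 0:
        raise ParameterError(
            "no traction-free suspension stretch in (0.3, 1.5) for this "
            "parameter set"
        )
    lam = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    Nu, eta, nss = _uniform_chemistry(lam, params)
    chi_u = params.mu_u_ref + math.log(Nu) - params.log_pi_NL
    J = lam * lam
    psi = 0.5 * params.kappa_C * (J - 1.0) ** 2
    if J < params.Jc:
        psi += params.kappa_bar * (J - params.Jc) ** 2
    VC = params.V_C
    GS = params.rho0_kBT_kPa * VC * chi_u + VC * psi  # nucleus undeformed: Psi_N = 0
    return SuspensionState(
        lambda_susp=float(lam),
        radius_ratio=float(lam),
        GS=float(GS),
        Nu_hat=float(Nu),
        eta_hat=float(eta),
        stress_residual=abs(f(lam)),
    )


# ----------------------------------------------------------------------
# Metropolis sampling
# ----------------------------------------------------------------------
@dataclass
class MCMCResult:
    samples: np.ndarray          # (n_keep, d)
    G_hat: np.ndarray            # (n_keep,) energy trace (normalised)
    acceptance: float
    step_size: float
    mean_G_hat: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_G_hat = float(np.mean(self.G_hat)) if len(self.G_hat) else math.nan


def metropolis(
    energy: Callable[[np.ndarray], float],
    x0: np.ndarray,
    zeta: float,
    n_steps: int,
    rng: np.random.Generator,
    step_size: float = 0.1,
    thin: int = 1,
    admissible: Callable[[np.ndarray], bool] | None = None,
) -> MCMCResult:
    """Generic random-walk Metropolis targeting ``exp(-zeta * energy)``.

    One uniformly chosen coordinate receives a Gaussian perturbation per
    step; proposals failing ``admissible`` are rejected outright.  Used for
    the low-dimensional validation systems; the cell model runs through the
    compiled sampler in :func:`mcmc_sample`.
    """
    x = np.array(x0, dtype=float)
    d = x.size
    E = energy(x)
    keep = n_steps // thin
    samples = np.empty((keep, d))
    trace = np.empty(keep)
    n_acc = 0
    kept = 0
    idx = rng.integers(0, d, size=n_steps)
    steps = rng.normal(size=n_steps) * step_size
    us = rng.random(n_steps)
    for i in range(n_steps):
        q = idx[i]
        old = x[q]
        x[q] = old + steps[i]
        ok = admissible is None or admissible(x)
        if ok:
            try:
                En = energy(x)
            except Exception:
                ok = False
        if ok and (En - E <= 0 or us[i] < math.exp(-zeta * (En - E))):
            E = En
            n_acc += 1
        else:
            x[q] = old
        if (i + 1) % thin == 0 and kept < keep:
            samples[kept] = x
            trace[kept] = E
            kept += 1
    return MCMCResult(samples[:kept], trace[:kept], n_acc / n_steps, step_size)


def _adapt_step(model: CellModel, c0, zeta_hat, seed, step0=0.05, rounds=6, n=600):
    """Tune the proposal s.d. toward ~30% acceptance during burn-in."""
    step = step0
    c = c0.copy()
    for r in range(rounds):
        rng = np.random.default_rng((seed, 977, r))
        samples, _, acc = _kernels.mcmc_kernel(
            c, n, step, zeta_hat, model.GS_abs,
            rng.integers(0, 32, size=n),
            rng.normal(size=n),
            rng.random(n),
            max(n // 4, 1),
            *model.kernel_args(),
            model.w_half,
        )
        if len(samples):
            c = samples[-1].copy()
        if acc < 0.2:
            step *= 0.6
        elif acc > 0.45:
            step *= 1.6
        else:
            break
    return step, c


def mcmc_sample(
    model: CellModel,
    zeta_hat: float,
    n_samples: int,
    seed: int,
    thin: int = 10,
    burn_in: int | None = None,
    step_size: float | None = None,
    start: np.ndarray | None = None,
) -> MCMCResult:
    """Sample the stationary morphological ensemble of the cell model.

    Metropolis chain over the 32 control-point coordinates targeting
    ``exp(-zeta_hat * G_hat)`` with hard rejection of fold-over and
    off-stripe proposals.  ``n_samples`` retained states are returned after
    ``burn_in`` discarded steps (default: 10 * thin * sqrt(n_samples)).
    """
    if zeta_hat <= 0:
        raise ParameterError("zeta_hat must be positive")
    c0 = model.seeded_net().flat() if start is None else np.asarray(start, float)
    if step_size is None:
        step_size, c0 = _adapt_step(model, c0, zeta_hat, seed)
    if burn_in is None:
        burn_in = int(10 * thin * math.sqrt(n_samples))
    n_steps = burn_in + n_samples * thin
    rng = np.random.default_rng((seed, 1031))
    samples, trace, acc = _kernels.mcmc_kernel(
        c0, n_steps, step_size, zeta_hat, model.GS_abs,
        rng.integers(0, 32, size=n_steps),
        rng.normal(size=n_steps),
        rng.random(n_steps),
        thin,
        *model.kernel_args(),
        model.w_half,
    )
    skip = burn_in // thin
    return MCMCResult(samples[skip:], trace[skip:], acc, step_size)


# ----------------------------------------------------------------------
# homeostatic calibration
# ----------------------------------------------------------------------
@dataclass
class HomeostaticCalibration:
    zeta_hat: float
    GS: float
    lambda_susp: float
    target_G_hat: float
    achieved_G_hat: float
    acceptance: float
    history: list = field(default_factory=list)  # (zeta_hat, <G_hat>) pairs


def calibrate_zeta_generic(
    mean_energy: Callable[[float], float],
    target: float,
    zeta0: float = 1.0,
    rtol: float = 5e-3,
    max_iter: int = 40,
) -> tuple[float, list]:
    """Root-find ``zeta`` such that ``<E>(zeta) = target``.

    ``<E>`` decreases monotonically with ``zeta`` (variance identity of the
    exponential family), so a doubling search brackets the root before a
    bisection/secant hybrid polishes it.  ``mean_energy`` should use common
    random numbers across calls for a stable solve.
    """
    history = []

    def g(z):
        m = mean_energy(z)
        history.append((z, m))
        return m - target

    scale = max(abs(target), 1e-12)
    z_lo = z_hi = zeta0
    g0 = g(zeta0)
    if abs(g0) <= rtol * scale:
        return zeta0, history
    if g0 > 0:  # mean too high -> need larger zeta
        for _ in range(max_iter):
            z_hi *= 2.0
            if g(z_hi) <= 0:
                break
            z_lo = z_hi
        else:
            raise SolverError(
                f"could not bracket the homeostatic constraint; "
                f"<E> at zeta={z_hi:g} is {history[-1][1]:g} vs target {target:g}"
            )
    else:
        for _ in range(max_iter):
            z_lo /= 2.0
            if g(z_lo) >= 0:
                break
            z_hi = z_lo
        else:
            raise SolverError(
                f"could not bracket the homeostatic constraint; "
                f"<E> at zeta={z_lo:g} is {history[-1][1]:g} vs target {target:g}"
            )
    # bisection with secant acceleration on the bracketed interval
    f_lo = [v - target for z, v in history if z == z_lo][-1]
    f_hi = [v - target for z, v in history if z == z_hi][-1]
    for _ in range(max_iter):
        if abs(f_lo) <= rtol * scale:
            return z_lo, history
        if abs(f_hi) <= rtol * scale:
            return z_hi, history
        denom = f_hi - f_lo
        z_mid = 0.5 * (z_lo + z_hi)
        if abs(denom) > 0:
            z_sec = z_lo - f_lo * (z_hi - z_lo) / denom
            if z_lo < z_sec < z_hi:
                z_mid = z_sec
        f_mid = g(z_mid)
        if f_mid > 0:
            z_lo, f_lo = z_mid, f_mid
        else:
            z_hi, f_hi = z_mid, f_mid
        # Monte-Carlo noise in <E> eventually dominates the sign test; once
        # the bracket is tight relative to that noise, stop.
        if (z_hi - z_lo) <= 0.02 * z_hi:
            break
    z = 0.5 * (z_lo + z_hi)
    return z, history


def calibrate_zeta(
    model: CellModel,
    n_samples: int = 2000,
    seed: int = 0,
    zeta0: float = 2.0,
    rtol: float = 0.05,
    thin: int = 20,
    n_chains: int = 3,
) -> HomeostaticCalibration:
    """Calibrate ``zeta_hat`` so that ``<G_hat> = sign(G_S)`` for the model.

    The ensemble mean is estimated by averaging ``n_chains`` independent
    Metropolis chains with fixed seeds per ``zeta_hat`` iterate (common
    random numbers across iterates), and the root is found by the generic
    monotone search.  The residual Monte-Carlo error in ``zeta_hat`` is of
    the order of the chain-to-chain spread divided by the local slope
    ``d<G_hat>/dzeta_hat``.
    """
    target = model.G_hat_S
    last = {}

    def mean_G(z):
        means, accs = [], []
        for k in range(n_chains):
            res = mcmc_sample(model, z, n_samples, seed=seed + 7919 * k, thin=thin)
            means.append(res.mean_G_hat)
            accs.append(res.acceptance)
        last["acc"] = float(np.mean(accs))
        return float(np.mean(means))

    zeta, history = calibrate_zeta_generic(mean_G, target, zeta0=zeta0, rtol=rtol)
    return HomeostaticCalibration(
        zeta_hat=float(zeta),
        GS=model.GS,
        lambda_susp=model.suspension.lambda_susp,
        target_G_hat=target,
        achieved_G_hat=history[-1][1],
        acceptance=last["acc"],
        history=history,
    )
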