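"""Overdamped Langevin integration of the morphology dynamics.

The 32 control-point coordinates evolve by the normalised stochastic
equation

    dr_hat/dt_hat = -dG_hat/dr_hat + sqrt(2 / (zeta_hat * dt_hat)) N(0, 1),

integrated with the forward Euler(-Maruyama) scheme.  The noise amplitude is
fixed by requiring that the Fokker-Planck stationary law coincide with the
homeostatic ensemble ``exp(-zeta_hat * G_hat)``; ``zeta_hat`` therefore sets
the fluctuation magnitude while the mobility enters only through the time
unit ``(gamma R0^2)/|G_S|`` (about 10 minutes for fibroblasts).  The
dynamics is valid on timescales long compared to the noise correlation time
and hence captures diffusive, not ballistic, motility.

On striped substrates a smooth quartic barrier confines the nodes; steps
that would fold the mesh over are re-drawn from a spare noise pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from ._diff import central_gradient, richardson_gradient
from .errors import SolverError
from .errors import NonSimpleBoundaryError
from .homeostatic import HomeostaticCalibration
from .model import CellModel
from .morphology import geometry_observables

__all__ = ["SimulationSettings", "Trajectory", "energy_gradient",
           "langevin_step", "run_trajectory", "run_ensemble"]


@dataclass(frozen=True)
class SimulationSettings:
    """Integration settings for one ensemble of trajectories."""

    dt_hat: float = 0.001
    T_sim_hat: float = 10.0
    seed: int = 0
    n_traj: int = 1
    thin: int = 10
    gamma_R02_over_GS_minutes: float = 10.0
    gradient_scheme: str = "central"   # "central" | "richardson"
    fd_step: float = 1e-6
    max_retries: int = 25
    drift_cap: float = 0.05
    dG_max: float = 20.0
    compute_G: bool = True

    def __post_init__(self) -> None:
        if self.dt_hat <= 0 or self.T_sim_hat <= 0:
            raise SolverError("dt_hat and T_sim_hat must be positive")
        if self.gradient_scheme not in ("central", "richardson"):
            raise SolverError(f"unknown gradient scheme {self.gradient_scheme!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.T_sim_hat / self.dt_hat))


@dataclass
class Trajectory:
    """Thinned time series of one Langevin run."""

    t_hat: np.ndarray          # (F,)
    nets: np.ndarray           # (F, 32) control displacements
    centroids: np.ndarray      # (F, 2), origin at t_hat = 0
    observables: pd.DataFrame  # columns t_hat, x_c, y_c, A, AS, FF, phi_cell, G_hat
    seed: int
    zeta_hat: float
    GS: float
    W_hat: float
    settings: SimulationSettings
    status: str = "ok"

    @property
    def n_frames(self) -> int:
        return len(self.t_hat)


def energy_gradient(
    model: CellModel,
    c: np.ndarray,
    scheme: str = "richardson",
    h: float = 1e-3,
) -> np.ndarray:
    """Gradient of the normalised total energy (free energy + barrier).

    ``richardson`` (default) runs adaptive central differences with
    Richardson extrapolation; ``central`` is the plain second-order stencil
    used by the fast compiled path.
    """
    if scheme == "richardson":
        g, _ = richardson_gradient(lambda x: model.energy_hat(x), np.asarray(c, float), h0=h)
        return g
    return central_gradient(lambda x: model.energy_hat(x), np.asarray(c, float), h=h)


def langevin_step(
    c: np.ndarray,
    grad: np.ndarray,
    zeta_hat: float,
    dt_hat: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One forward-Euler update of the normalised Langevin equation."""
    noise = rng.standard_normal(np.asarray(c).shape)
    return np.asarray(c, float) + (-np.asarray(grad, float)
                                   + math.sqrt(2.0 / (zeta_hat * dt_hat)) * noise) * dt_hat


def _frame_observables(model: CellModel, nets, t_hat, compute_G=True):
    rows = []
    centroids = np.zeros((len(nets), 2))
    for i, c in enumerate(nets):
        try:
            cfg = model.deformed(c)
            geo = geometry_observables(cfg)
            centroids[i] = geo.centroid
            if compute_G:
                G, _, _, status = model.energy_raw(c)
                Ghat = G / model.GS_abs if status == _kernels.OK else np.nan
            else:
                Ghat = np.nan
            rows.append((t_hat[i], geo.centroid[0], geo.centroid[1], geo.A,
                         geo.AS, geo.FF, geo.phi_cell, Ghat))
        except NonSimpleBoundaryError:
            rows.append((t_hat[i],) + (np.nan,) * 7)
            centroids[i] = np.nan
    df = pd.DataFrame(
        rows, columns=["t_hat", "x_c", "y_c", "A", "AS", "FF", "phi_cell", "G_hat"]
    )
    return df, centroids


def run_trajectory(
    model: CellModel,
    calibration: HomeostaticCalibration | float,
    settings: SimulationSettings,
    traj_index: int = 0,
    start: np.ndarray | None = None,
) -> Trajectory:
    """Integrate one trajectory from the suspension seed at the origin.

    The RNG is seeded with ``settings.seed + traj_index``; pre-generated
    noise makes runs bit-reproducible and independent of how often the
    retry pool is consulted elsewhere.
    """
    zeta_hat = (
        calibration.zeta_hat
        if isinstance(calibration, HomeostaticCalibration)
        else float(calibration)
    )
    c0 = model.seeded_net().flat() if start is None else np.asarray(start, float)
    n_steps = settings.n_steps
    rng = np.random.default_rng(settings.seed + traj_index)
    pool = 2 * n_steps + 2000  # generous redraw pool for near-degenerate states
    noise = rng.standard_normal((n_steps + pool, 32))
    frames, n_rec, status, _ = _kernels.langevin_kernel(
        c0, n_steps, settings.dt_hat, zeta_hat, model.GS_abs, noise,
        settings.thin, settings.fd_step, settings.max_retries,
        settings.drift_cap, settings.dG_max,
        *model.kernel_args(), model.w_half, model.barrier_stiffness,
    )
    t_hat = np.arange(n_rec) * settings.thin * settings.dt_hat
    obs, centroids = _frame_observables(model, frames, t_hat, settings.compute_G)
    # centroid convention: displacement measured from the seeding position
    origin = centroids[0].copy()
    centroids = centroids - origin
    obs["x_c"] -= origin[0]
    obs["y_c"] -= origin[1]
    return Trajectory(
        t_hat=t_hat,
        nets=frames,
        centroids=centroids,
        observables=obs,
        seed=settings.seed + traj_index,
        zeta_hat=zeta_hat,
        GS=model.GS,
        W_hat=model.pattern.W_hat,
        settings=settings,
        status="ok" if status == _kernels.OK else f"aborted (code {status})",
    )


def run_ensemble(
    model: CellModel,
    calibration: HomeostaticCalibration | float,
    settings: SimulationSettings,
) -> list[Trajectory]:
    """Run ``settings.n_traj`` independent trajectories (seeds seed+k)."""
    return [
        run_trajectory(model, calibration, settings, traj_index=k)
        for k in range(settings.n_traj)
    ]
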