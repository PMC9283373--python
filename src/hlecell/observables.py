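"""Ensemble observables: spreading curves, MSD, order parameters, timescales.

All angular statistics use the doubled-angle construction appropriate for
axial (head-tail symmetric) data: an orientation ``phi`` enters through
``cos 2 phi`` and ``sin 2 phi``, so the statistics are invariant under
``phi -> phi + pi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import SolverError
from .free_energy import solve_unbound, staining_fields
from .morphology import REGION_CYTOPLASM

__all__ = [
    "normalized_area",
    "msd",
    "msd_slope",
    "directional_msd_and_dimensionality",
    "order_parameter",
    "cyto_order_single",
    "cyto_order",
    "fit_timescale",
    "TimescaleFit",
    "EnsembleSummary",
    "ensemble_summary",
]


def normalized_area(A_bar: np.ndarray, A_R: float, A_inf: float) -> np.ndarray:
    """Spreading coordinate ``A_hat = (A - A_R)/(A_inf - A_R)``.

    Zero at seeding (suspension area ``A_R``) and fluctuating around one at
    convergence.
    """
    if A_inf == A_R:
        raise SolverError("degenerate normalisation: A_inf equals A_R")
    return (np.asarray(A_bar, float) - A_R) / (A_inf - A_R)


def msd(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared displacement per trajectory and its ensemble mean.

    ``centroids``: array (n_traj, n_frames, 2) of centroid positions in R0
    units, origin at seeding.  Returns ``(R2, MSD)`` with ``R2`` of shape
    (n_traj, n_frames).
    """
    centroids = np.asarray(centroids, float)
    if centroids.ndim != 3 or centroids.shape[-1] != 2:
        raise SolverError("centroids must have shape (n_traj, n_frames, 2)")
    R2 = centroids[..., 0] ** 2 + centroids[..., 1] ** 2
    return R2, R2.mean(axis=0)


def msd_slope(
    t_hat: np.ndarray,
    MSD: np.ndarray,
    window: tuple[float, float] | None = None,
) -> float:
    """Linear-fit slope of the MSD over a late-time window.

    Default window ``[0.1 T, T]`` skips the seeding transient; the window
    actually used should be recorded alongside the value.
    """
    t_hat = np.asarray(t_hat, float)
    MSD = np.asarray(MSD, float)
    if window is None:
        window = (0.1 * t_hat[-1], t_hat[-1])
    sel = (t_hat >= window[0]) & (t_hat <= window[1])
    if sel.sum() < 2:
        raise SolverError("MSD fit window contains fewer than 2 points")
    return float(np.polyfit(t_hat[sel], MSD[sel], 1)[0])


def directional_msd_and_dimensionality(
    centroids: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Stripe-direction MSD and the motility-dimensionality parameter.

    ``MSD_y = <y^2>`` (stripe axis = x2 = y) and
    ``Lambda_hat = 2 (MSD - MSD_y)/MSD``: 1 for isotropic 2D motion, 0 when
    motion is confined to the stripe axis.  ``Lambda_hat`` is undefined
    where ``MSD = 0`` (reported as NaN).
    """
    centroids = np.asarray(centroids, float)
    _, MSD = msd(centroids)
    MSD_y = (centroids[..., 1] ** 2).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = 2.0 * (MSD - MSD_y) / MSD
    lam[MSD == 0] = np.nan
    return MSD_y, lam


def order_parameter(phis: np.ndarray) -> float:
    """Axial order parameter ``Theta`` of a set of orientations.

    ``Theta = sqrt(<cos 2 phi>^2 + <sin 2 phi>^2)``: 0 for uniformly
    distributed axes, 1 when all coincide (mod pi).
    """
    phis = np.asarray(phis, float)
    phis = phis[np.isfinite(phis)]
    if phis.size == 0:
        raise SolverError("order parameter of an empty angle set")
    return float(
        math.hypot(np.mean(np.cos(2 * phis)), np.mean(np.sin(2 * phis)))
    )


def cyto_order_single(phi_max: np.ndarray, weights: np.ndarray) -> float:
    """Stress-fibre order of one configuration.

    The dominant-bundle direction field is first centred by its
    volume-average, ``phi_centred = phi_max - <phi_max>_V`` (making the
    measure rotation-invariant), then the axial order parameter is applied
    to the volume-weighted spatial distribution of ``phi_centred``.
    """
    phi_max = np.asarray(phi_max, float)
    w = np.asarray(weights, float)
    w = w / w.sum()
    centred = phi_max - float(w @ phi_max)
    return float(
        math.hypot(w @ np.cos(2 * centred), w @ np.sin(2 * centred))
    )


def cyto_order(model, nets: np.ndarray) -> float:
    """Ensemble-mean cytoskeletal order over one frame of many trajectories.

    For each configuration the spatial order is computed from the per-element
    dominant fibre directions (volume weighted over the cytoplasm); the
    ensemble value is the mean over configurations.
    """
    vals = []
    vols = model.mesh.element_volumes(model.params)
    cyto = model.mesh.region == REGION_CYTOPLASM
    for c in np.atleast_2d(nets):
        cfg = model.deformed(c)
        state = solve_unbound(cfg, model.params, n_phi=model.n_phi)
        stain = staining_fields(cfg, state)
        vals.append(cyto_order_single(stain.phi_max[cyto], vols[cyto]))
    return float(np.mean(vals))


@dataclass
class TimescaleFit:
    """Single-timescale exponential relaxation fit."""

    x_inf: float
    x_R: float
    tau: float
    residual: float

    def __call__(self, t_hat: np.ndarray) -> np.ndarray:
        return self.x_inf - (self.x_inf - self.x_R) * np.exp(
            -np.asarray(t_hat, float) / self.tau
        )


def fit_timescale(
    t_hat: np.ndarray,
    x: np.ndarray,
    x_R: float | None = None,
    x_inf: float | None = None,
) -> TimescaleFit:
    """Fit ``x(t) = x_inf - (x_inf - x_R) exp(-t/tau)`` for ``tau`` only.

    The endpoints ``x_R`` (seeding value) and ``x_inf`` (late-time value)
    are taken from the data when not given — the time constant is the only
    fitted parameter, found by least squares.
    """
    t_hat = np.asarray(t_hat, float)
    x = np.asarray(x, float)
    good = np.isfinite(x)
    t_hat, x = t_hat[good], x[good]
    if x_R is None:
        x_R = float(x[0])
    if x_inf is None:
        tail = max(1, len(x) // 10)
        x_inf = float(x[-tail:].mean())
    if x_inf == x_R:
        raise SolverError("flat series: no timescale to fit")

    def f(t, tau):
        return x_inf - (x_inf - x_R) * np.exp(-t / tau)

    span = t_hat[-1] - t_hat[0]
    tau0 = max(span / 10.0, 1e-12)
    popt, _ = curve_fit(f, t_hat, x, p0=[tau0], bounds=(1e-12, np.inf), maxfev=10000)
    tau = float(popt[0])
    res = float(np.sqrt(np.mean((f(t_hat, tau) - x) ** 2)))
    return TimescaleFit(x_inf=x_inf, x_R=x_R, tau=tau, residual=res)


@dataclass
class EnsembleSummary:
    """Time-resolved ensemble means and motility metrics."""

    t_hat: np.ndarray
    table: pd.DataFrame        # tidy: t_hat, metric, mean, sd, n
    A_hat: np.ndarray
    AS_mean: np.ndarray
    FF_mean: np.ndarray
    MSD: np.ndarray
    MSD_y: np.ndarray
    Lambda_hat: np.ndarray
    Theta: np.ndarray
    n_traj: int


def ensemble_summary(trajectories) -> EnsembleSummary:
    """Aggregate a list of trajectories sharing one time grid."""
    if not trajectories:
        raise SolverError("empty ensemble")
    n_frames = min(t.n_frames for t in trajectories)
    t_hat = trajectories[0].t_hat[:n_frames]
    for t in trajectories:
        if not np.allclose(t.t_hat[:n_frames], t_hat):
            raise SolverError("trajectories use different time grids")
    def col(name):
        return np.stack([t.observables[name].to_numpy()[:n_frames] for t in trajectories])

    A = col("A")
    AS = col("AS")
    FF = col("FF")
    phi = col("phi_cell")
    centroids = np.stack([t.centroids[:n_frames] for t in trajectories])
    A_bar = np.nanmean(A, axis=0)
    A_R = float(A_bar[0])
    tail = max(1, n_frames // 10)
    A_inf = float(A_bar[-tail:].mean())
    A_hat = normalized_area(A_bar, A_R, A_inf) if A_inf != A_R else np.zeros_like(A_bar)
    _, MSD = msd(centroids)
    MSD_y, lam = directional_msd_and_dimensionality(centroids)
    Theta = np.array([
        order_parameter(phi[:, k][np.isfinite(phi[:, k])]) for k in range(n_frames)
    ])
    rows = []
    for name, arr in (("A", A), ("AS", AS), ("FF", FF)):
        rows.append(pd.DataFrame({
            "t_hat": t_hat, "metric": name,
            "mean": np.nanmean(arr, axis=0), "sd": np.nanstd(arr, axis=0),
            "n": arr.shape[0],
        }))
    for name, arr in (("A_hat", A_hat), ("MSD", MSD), ("MSD_y", MSD_y),
                      ("Lambda_hat", lam), ("Theta", Theta)):
        rows.append(pd.DataFrame({
            "t_hat": t_hat, "metric": name, "mean": arr,
            "sd": np.nan, "n": len(trajectories),
        }))
    return EnsembleSummary(
        t_hat=t_hat,
        table=pd.concat(rows, ignore_index=True),
        A_hat=A_hat,
        AS_mean=np.nanmean(AS, axis=0),
        FF_mean=np.nanmean(FF, axis=0),
        MSD=MSD,
        MSD_y=MSD_y,
        Lambda_hat=lam,
        Theta=Theta,
        n_traj=len(trajectories),
    )
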