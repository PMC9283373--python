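"""Trajectory store (HDF5) and flat CSV exports.

One hierarchical container per run: a ``meta`` group with the full
configuration echo (parameters, pattern, settings, seed, zeta_hat, G_S) and
a ``data`` group with frame times, control nets, centroids and the
observable table.  A finished store is immutable; partial reads by time
window are supported.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import SimulationSettings, Trajectory
from .errors import HLECellError

__all__ = ["save_trajectory", "load_trajectory", "export_observables_csv"]

_OBS_COLS = ["t_hat", "x_c", "y_c", "A", "AS", "FF", "phi_cell", "G_hat"]


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["seed"] = traj.seed
        meta.attrs["zeta_hat"] = traj.zeta_hat
        meta.attrs["GS"] = traj.GS
        meta.attrs["W_hat"] = traj.W_hat
        meta.attrs["status"] = traj.status
        meta.attrs["settings"] = json.dumps(
            {k: getattr(traj.settings, k) for k in traj.settings.__dataclass_fields__}
        )
        data = f.create_group("data")
        data.create_dataset("t_hat", data=traj.t_hat)
        data.create_dataset("nets", data=traj.nets)
        data.create_dataset("centroids", data=traj.centroids)
        data.create_dataset(
            "observables", data=traj.observables[_OBS_COLS].to_numpy()
        )
        data.attrs["observable_columns"] = ",".join(_OBS_COLS)


def load_trajectory(
    path: str | Path,
    t_window: tuple[float, float] | None = None,
) -> Trajectory:
    """Read a trajectory store, optionally restricted to a time window."""
    try:
        with h5py.File(path, "r") as f:
            meta = f["meta"].attrs
            data = f["data"]
            t_hat = data["t_hat"][...]
            sel = slice(None)
            if t_window is not None:
                mask = (t_hat >= t_window[0]) & (t_hat <= t_window[1])
                idx = np.where(mask)[0]
                sel = slice(idx[0], idx[-1] + 1) if len(idx) else slice(0, 0)
            cols = data.attrs["observable_columns"].split(",")
            obs = pd.DataFrame(data["observables"][sel], columns=cols)
            settings = SimulationSettings(**json.loads(meta["settings"]))
            return Trajectory(
                t_hat=t_hat[sel],
                nets=data["nets"][sel],
                centroids=data["centroids"][sel],
                observables=obs,
                seed=int(meta["seed"]),
                zeta_hat=float(meta["zeta_hat"]),
                GS=float(meta["GS"]),
                W_hat=float(meta["W_hat"]),
                settings=settings,
                status=str(meta["status"]),
            )
    except (OSError, KeyError) as exc:
        raise HLECellError(f"corrupt or unreadable trajectory store {path}: {exc}")


def export_observables_csv(traj: Trajectory, path: str | Path) -> None:
    """Flat per-frame columnar export of the observable table."""
    traj.observables[_OBS_COLS].to_csv(path, index=False)
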